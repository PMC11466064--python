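"""Hill-equation fitting for GABA concentration-response and potentiation data.

The model is

    I(c) = baseline + I_max · c^n_h / (c^n_h + EC50^n_h)

with EC50 the half-maximal concentration (µM), n_h the Hill coefficient and
I_max the plateau above baseline (peak current, normalized response, or %
potentiation, in which case I_max plays the role of E_max). Potentiation
curves are fitted with the baseline fixed to 0. Optimization runs in
log10(EC50) and log10(n_h) space so both stay positive, via trust-region
nonlinear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = ["HillFit", "hill", "fit_hill", "fit_potentiation", "ec_fraction",
           "percent_potentiation"]


def hill(concentration, ec50: float, n_h: float, i_max: float,
         baseline: float = 0.0):
    """Evaluate the Hill equation at the given concentration(s)."""
    c = np.asarray(concentration, dtype=float)
    cn = c**n_h
    return baseline + i_max * cn / (cn + ec50**n_h)


@dataclass
class HillFit:
    """Fitted (or true, for simulation) Hill-curve parameters."""

    ec50: float                 # µM
    n_h: float                  # dimensionless steepness
    i_max: float                # response units above baseline
    baseline: float = 0.0
    ec50_se: float = float("nan")
    n_h_se: float = float("nan")
    i_max_se: float = float("nan")
    baseline_se: float = float("nan")
    converged: bool = True
    sse: float = float("nan")
    n_obs: int = 0
    message: str = ""

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("EC50 must be > 0")
        if self.n_h <= 0:
            raise ValueError("Hill coefficient must be > 0")

    @property
    def e_max(self) -> float:
        """Alias used when the response axis is % potentiation."""
        return self.i_max

    def predict(self, concentration):
        return hill(concentration, self.ec50, self.n_h, self.i_max, self.baseline)


def _validate_table(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if not {"concentration_uM", "response"}.issubset(table.columns):
        raise ValueError("table needs columns concentration_uM and response")
    c = table["concentration_uM"].to_numpy(dtype=float)
    y = table["response"].to_numpy(dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    if np.unique(c).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.ptp(y) == 0:
        raise ValueError("all responses equal; the Hill model is degenerate")
    return c, y


def fit_hill(table: pd.DataFrame, fix_baseline_to_zero: bool = True) -> HillFit:
    """Nonlinear least-squares fit of the Hill equation to a response table.

    ``table`` has columns ``concentration_uM`` and ``response`` (replicates are
    pooled as independent rows). The initializer is data-driven and
    deterministic: EC50 starts at the concentration whose response is nearest
    half the maximum, n_h at 1, I_max at the maximum observed response.
    Non-convergence is reported on the ``converged`` flag with the solver
    message, never as an exception.
    """
    c, y = _validate_table(table)
    y0 = float(y.min()) if not fix_baseline_to_zero else 0.0
    i_max0 = float(y.max()) - y0
    if i_max0 <= 0:
        i_max0 = max(abs(float(y.max())), 1e-6)
    half = y0 + 0.5 * i_max0
    ec50_0 = float(c[np.argmin(np.abs(y - half))])

    def unpack(x):
        ec50, n_h = 10.0 ** x[0], 10.0 ** x[1]
        i_max = x[2]
        base = 0.0 if fix_baseline_to_zero else x[3]
        return ec50, n_h, i_max, base

    def residuals(x):
        return hill(c, *unpack(x)) - y

    x0 = [np.log10(ec50_0), 0.0, i_max0] + ([] if fix_baseline_to_zero else [y0])
    sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14,
                        gtol=1e-14, max_nfev=20000)
    ec50, n_h, i_max, base = unpack(sol.x)
    sse = float(2 * sol.cost)

    # parameter SEs via the Gauss-Newton covariance, delta method for the
    # log-parametrized EC50 and n_h
    n_par = sol.x.size
    ses = np.full(n_par, np.nan)
    dof = c.size - n_par
    if dof > 0:
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj) * (sse / dof)
            ses = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            pass
    ln10 = np.log(10.0)
    fit = HillFit(
        ec50=ec50, n_h=n_h, i_max=i_max, baseline=base,
        ec50_se=float(ses[0] * ln10 * ec50),
        n_h_se=float(ses[1] * ln10 * n_h),
        i_max_se=float(ses[2]),
        baseline_se=float("nan") if fix_baseline_to_zero else float(ses[3]),
        converged=bool(sol.success),
        sse=sse,
        n_obs=int(c.size),
        message=str(sol.message),
    )
    return fit


def fit_potentiation(table: pd.DataFrame) -> HillFit:
    """Fit a modulator potentiation curve (baseline fixed to 0).

    Rows are (modulator concentration µM, % potentiation); the fitted plateau
    ``i_max`` is the E_max of the modulator.
    """
    return fit_hill(table, fix_baseline_to_zero=True)


def ec_fraction(fit: HillFit, fraction: float = 0.05) -> float:
    """Concentration producing the given fraction of I_max (e.g. EC5).

    Closed form of the inverted Hill equation:
    EC_f = EC50 · (f/(1−f))^(1/n_h).
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    if not fit.converged:
        raise ValueError("cannot derive EC fraction from a non-converged fit")
    return fit.ec50 * (fraction / (1.0 - fraction)) ** (1.0 / fit.n_h)


def percent_potentiation(i_gaba: float, i_gaba_plus_modulator: float) -> float:
    """Percent potentiation of a GABA current by a coapplied modulator.

    100 · (I_with_modulator − I_GABA) / I_GABA, measured at a low
    (EC5-level) GABA concentration.
    """
    if i_gaba <= 0:
        raise ValueError("reference GABA current must be > 0")
    return 100.0 * (i_gaba_plus_modulator - i_gaba) / i_gaba
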