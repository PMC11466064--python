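"""Percent maximal possible effect (%MPE) on withdrawal-threshold series.

For an animal with pre-injury baseline E_preCCI, post-injury/pre-drug
baseline E_predrug, and post-drug thresholds E(t) (all in grams of von Frey
force),

    %MPE(t) = 100 · (E(t) − E_predrug) / (E_preCCI − E_predrug)

so 0% means no reversal of the injury-induced sensitization and 100% means
full return to the pre-injury threshold. Values are not clipped: thresholds
above the pre-injury baseline give >100% and further sensitization gives
negative values. The reported statistic is the per-animal mean over a time
window (default 0.5 and 1 h post drug), compared between groups with an
unpaired t test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colocal import GroupComparison, compare_groups

__all__ = ["BehaviorSeries", "MPEResult", "compute_mpe", "window_mean_mpe",
           "compare_mpe_groups", "bonferroni"]

DEFAULT_WINDOW = (0.5, 1.0)


@dataclass
class BehaviorSeries:
    """One animal's withdrawal-threshold time course around drug injection."""

    animal_id: str
    e_pre_cci: float              # grams, before nerve injury
    e_predrug: float              # grams, after injury / before drug
    thresholds: dict[float, float]  # time (h) after drug -> grams
    genotype: str = ""
    treatment: str = ""
    sex: str = ""

    def __post_init__(self) -> None:
        if self.e_pre_cci <= 0 or self.e_predrug <= 0:
            raise ValueError("baseline thresholds must be > 0")
        if any(v <= 0 for v in self.thresholds.values()):
            raise ValueError("thresholds must be > 0")
        # injury is expected to lower the threshold; the reverse is suspicious
        # but not fatal (e.g. a non-sensitized animal)
        self.sensitization_flag = self.e_predrug > self.e_pre_cci


@dataclass
class MPEResult:
    animal_id: str
    mpe_by_time: dict[float, float]
    window: tuple[float, ...]
    window_mean: float


def compute_mpe(series: BehaviorSeries, t: float) -> float:
    """%MPE at time point ``t`` (must be a recorded time)."""
    denom = series.e_pre_cci - series.e_predrug
    if denom == 0:
        raise ValueError(
            f"animal {series.animal_id}: E_preCCI equals E_predrug; "
            "no sensitization to reverse")
    if t not in series.thresholds:
        raise KeyError(f"animal {series.animal_id}: no threshold at t={t} h")
    # ratio first so E(t) == E_preCCI yields exactly 100 in floating point
    return 100.0 * ((series.thresholds[t] - series.e_predrug) / denom)


def window_mean_mpe(series: BehaviorSeries,
                    timepoints: tuple[float, ...] = DEFAULT_WINDOW) -> float:
    """Arithmetic mean of %MPE over the requested time window."""
    missing = [t for t in timepoints if t not in series.thresholds]
    if missing:
        raise KeyError(
            f"animal {series.animal_id}: missing timepoints {missing}")
    return float(np.mean([compute_mpe(series, t) for t in timepoints]))


def mpe_result(series: BehaviorSeries,
               timepoints: tuple[float, ...] = DEFAULT_WINDOW) -> MPEResult:
    """Full per-animal %MPE profile plus the window mean."""
    return MPEResult(
        animal_id=series.animal_id,
        mpe_by_time={t: compute_mpe(series, t) for t in sorted(series.thresholds)},
        window=tuple(timepoints),
        window_mean=window_mean_mpe(series, timepoints),
    )


def compare_mpe_groups(
    cohort_a: list[BehaviorSeries],
    cohort_b: list[BehaviorSeries],
    timepoints: tuple[float, ...] = DEFAULT_WINDOW,
    label_a: str = "group_a",
    label_b: str = "group_b",
) -> GroupComparison:
    """Unpaired t test on per-animal window-mean %MPE between two cohorts."""
    if len(cohort_a) < 2 or len(cohort_b) < 2:
        raise ValueError("need at least 2 animals per group")
    a = [window_mean_mpe(s, timepoints) for s in cohort_a]
    b = [window_mean_mpe(s, timepoints) for s in cohort_b]
    return compare_groups(a, b, measure="window_mean_mpe_percent",
                          control_label=label_a, test_label=label_b)


def bonferroni(p_value: float, n_tests: int) -> float:
    """Bonferroni-corrected p value: p·m capped at 1."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p_value * n_tests)
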