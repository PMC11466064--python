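# spincolocal

A tested, reusable implementation of the quantification stack used in
studies of GABA_A-receptor clustering in the spinal dorsal horn:

* **object-based colocalization** of synaptic puncta in two-channel
  immunofluorescence images — threshold detection, a 0.2–3 µm equivalent-
  diameter size filter, 0.1 µm dilation, and the ">50 % of the reference
  punctum's area overlapped" rule, with cluster densities per µm² and
  percent-reduction group statistics;
* **RNAscope cell calling** — nucleus segmentation, 2 µm nuclear expansion,
  the ≥3-dot positivity rule, and regional coexpression tables;
* **Hill-equation fitting** of concentration-response data,
  `I(c) = I_max·c^n_h/(c^n_h + EC50^n_h)`, including potentiation curves
  with baseline fixed to 0 and closed-form `EC_f` concentrations
  (`EC50·(f/(1−f))^(1/n_h)`, e.g. the EC5 used for modulator coapplication);
* **%MPE** behavioral statistics on von Frey withdrawal thresholds,
  `%MPE(t) = 100·(E(t) − E_predrug)/(E_preCCI − E_predrug)`, with
  time-window means and unpaired-t cohort comparisons;
* a **seeded synthetic-data generator** producing ground-truth-carrying
  puncta fields, FISH fields, dose-response tables and behavioral cohorts
  for every stage, so the whole stack is testable end to end without any
  microscope.

It is aimed at neuroscience labs quantifying inhibitory-synapse markers
(gephyrin, receptor subunits) and transcript coexpression, and at anyone
who wants a scriptable, validated alternative to ad hoc spreadsheet + plugin
workflows. See `docs/methods.md` for the full conventions and assumptions.

## Worked example

Simulate a noise-free two-channel field with a known colocalized fraction,
run the full detection → size filter → colocalization pipeline, and compare
a published pair of group-mean densities:

```python
import spincolocal as sc

params = sc.PunctaSimParams(
    field_size_um=(80.0, 80.0), seed=1, true_coloc_fraction=0.5,
    channels=[sc.PunctaChannelSpec(name="receptor", density_per_um2=0.1),
              sc.PunctaChannelSpec(name="gephyrin", density_per_um2=0.06)])
field, truth = sc.generate_puncta_field(params)

ref = sc.filter_by_size(sc.detect_puncta(field, "gephyrin"))
oth = sc.filter_by_size(sc.detect_puncta(field, "receptor"))
res = sc.colocalize(ref, oth, roi=sc.ROIMask.full_field(field))

print(f"detected gephyrin puncta: {len(ref)}")
print(f"colocalized: {res.n_colocalized} ({res.colocalized_fraction:.3f})")
print(f"colocalized density: {res.colocalized_density_per_um2:.4f} /um2")
print("reduction:", sc.percent_reduction(0.23, 0.005))
```

Output:

```
detected gephyrin puncta: 350
colocalized: 178 (0.509)
colocalized density: 0.0278 /um2
reduction: 97.8
```

374 true gephyrin spots were generated, half of them concentric with a
receptor spot; 350 survive detection plus the size filter (touching spots
merge), and the recovered colocalized fraction 0.509 sits within 0.01 of
the generating truth 0.5. `percent_reduction(0.23, 0.005)` reproduces the
97.8 % cluster-density reduction implied by those two group means.

## Command line

The same stages are scriptable via the `spincolocal` umbrella CLI:

```bash
spincolocal simulate puncta --seed 1 --density 0.08 --out sim/
spincolocal analyze colocal --image sim/field.tif \
    --ref-channel gephyrin --other-channel receptor --out result.json
spincolocal analyze dose --table curve.csv --out fit.json
spincolocal analyze mpe --table vonfrey.csv --window 0.5,1 --out mpe.csv
spincolocal run --config pipeline.yaml --seed 3 --out results/
```

`spincolocal run` executes a configured pipeline and writes a manifest
(config echo, seed, record counts, artifact SHA-256 checksums); identical
config + seed reproduces identical checksums.

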