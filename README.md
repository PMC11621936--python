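# phosphodyn

Dynamic phospho-proteogenomic analysis of drug response in cancer
cell-line panels.

Studies of resistance to DNA-damaging chemotherapy (5-fluorouracil,
cisplatin, etoposide) in gastric cancer cell lines combine several
platforms around one question — which signaling events separate sensitive
from resistant cells, and do they translate into patient survival?
`phosphodyn` implements that analysis chain as a tested library with a CLI,
for computational biologists who want each stage reproducible and
inspectable:

* **rppa** — reverse-phase protein array quantification: slide-layout
  bookkeeping (12 conditions × 5 time points × 8 lines × 4 replicates +
  80 control dots = 2000 spots), tetraplicate aggregation (median with
  MAD outlier exclusion), control-MIX normalization, and assembly of
  per-antibody time courses as log2 fold change from t = 0.
* **dose_response** — GI50 by log-linear interpolation of the first 50%
  viability crossing, normalized AUC over log10 dose, and
  sensitive/resistant segregation at the largest gap in the log10 GI50
  profile.
* **dynamics** — kinetic classification of time courses into early
  (peaked ≤ 6 h), intermediate (≤ 12 h), late (≤ 24 h) and no response
  (flat) via K-means (k = 7) on |log2FC| vectors with centroid-to-class
  mapping; class-proportion tables and responsive-vs-flat Fisher exact
  contrasts ("protein dynamics depletion").
* **association** — Pearson ranking of antibodies against log10 GI50
  across the panel and against anchor phosphoproteins across samples.
* **cnv** — ΔCNV between matched resistant/parental lines, merged
  loss/gain locus counts, per-gene shared-loss Fisher tests,
  Mann-Whitney contrasts of locus counts (exact for combined n ≤ 12).
* **survival** — median-split marker stratification, Kaplan-Meier with
  Greenwood variance, log-rank tests, univariable Cox hazard ratios
  (Efron ties), subgroup forest tables, and per-gene hazard screens.
* **simulate** — a first-class synthetic-data generator that plants known
  ground truth for every stage (kinetic archetypes, GI50 midpoints,
  shared-loss regions, stratum-specific hazard ratios), driven by one
  root seed through named substreams.
* **pipeline / cli** — `run-all` orchestrates
  simulate → quantify → gi50 → dynamics → correlate → cnv → survive from
  one YAML config, with plain-TSV intermediates and a JSON manifest;
  reruns are byte-identical.

The statistics at the core, in standard notation: GI50 solves
v(d) = 50 on the log-linear interpolant of measured viability;
AUC = ∫ v(d)/100 d log₁₀d / Δlog₁₀d ∈ [0, 1]; kinetic classes are peak
windows of |log₂(x_t/x_0)|; group contrasts use the two-sided Fisher exact
p = Σ_{P(T) ≤ P(obs)} P(T) on responsive-vs-flat counts; survival effects
are hazard ratios from the Cox partial likelihood with Efron tie
correction, with S(t) from the product-limit estimator
Ŝ(t) = Π_{t_i ≤ t} (1 − d_i/n_i).

## Worked example

```python
import numpy as np
from phosphodyn import simulate, dynamics, survival
from phosphodyn.dose_response import compute_gi50, segregate_by_gi50

# GI50 calls on a synthetic 8-line panel (planted: 1 uM x5, 30 uM x3)
doses = np.logspace(-2, 2, 9)
calls = {}
for i, line in enumerate(f"GC{j+1:02d}" for j in range(8)):
    prof, _ = simulate.gen_dose_response(
        30.0 if i >= 5 else 1.0, doses, noise_sd=3.0, seed=100 + i, cell_line=line
    )
    calls[line] = compute_gi50(prof)
labels = segregate_by_gi50(calls)

# kinetic classification of 4032 synthetic courses, k = 7
cfg = simulate.SimulationConfig(seed=1, n_antibodies=42)
tcs, truth = simulate.gen_timecourses(cfg)
classified = dynamics.classify_courses(tcs, k=7, seed=1)

# survival: planted HR 0.46 for adjuvant chemotherapy in the TLC+ stratum
cohort, _ = simulate.gen_cohort(2000, hr_by_stratum={"TLC+": 0.46}, seed=1)
est = survival.cox_hr(cohort, "arm", positive="S-1")
```

This prints (assembling the pieces as in `scripts/acceptance.py`):

```
GC01  GI50 =   1.19 uM  -> sensitive
GC02  GI50 =   0.89 uM  -> sensitive
GC03  GI50 =   1.00 uM  -> sensitive
GC04  GI50 =   0.99 uM  -> sensitive
GC05  GI50 =   0.81 uM  -> sensitive
GC06  GI50 =  38.42 uM  -> resistant
GC07  GI50 =  41.87 uM  -> resistant
GC08  GI50 =  30.72 uM  -> resistant

kinetic_class
none            2121
early            748
intermediate     589
late             574
agreement with planted classes: 0.997

Cox HR (S-1 vs surgery) = 0.49  95% CI (0.44, 0.56)  p = 1.1e-30
```

Reading it: the largest-gap rule recovers the planted bimodal sensitivity
split exactly; the classifier reproduces the planted class mix (50% flat)
with 99.7% agreement; and the Cox model recovers the planted protective
hazard ratio of 0.46 within its confidence interval on a 2000-patient
cohort.

The same analyses run from the shell:

```sh
phosphodyn run-all --config run.yaml --out results/
phosphodyn simulate courses --seed 1 --out courses.tsv
phosphodyn gi50 --viability viability.tsv --out calls.tsv
phosphodyn survive subgroup --cohort cohort.tsv --stratifier PD_L1 --treated S-1 --out forest.tsv
```

where `run.yaml` needs only a `seed:` key (sections `simulate`, `gi50`,
`dynamics`, `correlate`, `cnv`, `survive` override stage defaults).

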