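# phosphodia

Phosphorylation-aware data-independent acquisition (DIA) for biofluid
phosphoproteomics: isolation-window scheme design with forbidden-zone
edges, staggered-window demultiplexing, gas-phase-fractionation (GPF)
planning, phosphosite rollup quantification, and the label-free
differential statistics used to separate clear cell renal cell carcinoma
(ccRCC) grades from urinary extracellular-vesicle (EV) phosphoproteomes.

## Who this is for

Mass-spectrometrists designing DIA acquisition methods for
phospho-enriched samples, and computational proteomics analysts taking
search-software precursor reports through phosphosite-level differential
analysis and marker-panel evaluation.  Everything runs on plain delimited
text; no vendor raw files are touched.

## The method

**Forbidden zones.**  Tryptic peptide masses cluster by mass defect: for
integer nominal mass *m*, no (phospho)peptide precursor can sit at

&nbsp;&nbsp;&nbsp;&nbsp;*b(m)* = ceil(*m* / Δ) · Δ + *c*,&nbsp;&nbsp;
Δ = 1.00045475 m/z per Da,&nbsp; *c* = 0.18 m/z (phospho-enrichment shift),

so isolation-window edges placed at *b(m)* never bisect a precursor
isotope cluster and avoid quadrupole transmission edge effects.

**Staggered windows.**  Two interleaved window grids offset by half a
window width cover the precursor span (e.g. 400–1100 m/z at 8 m/z → 88
windows per phase).  Each scan observes the sum of its two constituent
half-width *effective* windows; solving the per-cycle nonnegative linear
system (bounded least squares on the full banded system) resolves signal
to effective windows of width/2 — 2 m/z for the 4 m/z GPF schemes.

**GPF library plans.**  The span is split across overlapping narrow-range
injections (default seven: 394.8–504.8 … 994.8–1104.8 m/z, 110 m/z span,
100 m/z step, 4 m/z MS2 windows) to build a deep, experiment-specific
chromatogram library.

**Site quantification.**  Precursor records are filtered to class-1
phosphosites (localization probability ≥ 0.75 library-based, ≥ 0.99
library-free), charge states of a modified peptide are summed, and a
site's abundance is the sum over all precursors containing it.

**Differential statistics.**  Raw intensities below 30 → missing; log2;
per-sample normality gate; per-comparison completeness filter (> 70%
observed in ≥ 1 group); left-censored imputation from a downshifted
normal (1.8 SD downshift, 0.3 SD width, per sample); per-sample median
normalization; Welch's two-sample *t* test with volcano classification at
*p* ≤ 0.05 and |log2 difference| ≥ 0.5 (≈ 1.414-fold).  Marker panels are
ranked by out-of-bag random-forest permutation importance, evaluated with
Hand–Till multiclass ROC AUC on leave-one-out discriminant scores, and
visualized by LDA projection.

A seeded synthetic-data generator emulates a urinary-EV cohort (2584
sites, four groups — healthy control, chronic kidney disease, ccRCC
low/high grade — of 15 samples, 79/17/4 pS/pT/pY, intensity-dependent
missingness, planted marker effects) so the whole pipeline is testable
without any download.

## Worked example

```bash
$ phosphodia design-windows --span 400:1100 --width 8 --align-forbidden-zones
n_windows_phase_a       88
n_windows_phase_b       88
span_lower      400.0
span_upper      1100.0
window_width    8.0
effective_window_width  4.0
aligned_to_forbidden_zones      True
```

88 windows per phase is the instrument loop count for the 400–1100 m/z
span; demultiplexing halves the 8 m/z windows to 4 m/z effective
selectivity.

```python
from phosphodia import *

records, truth = simulate_report(SimulationConfig(seed=1))
table = collapse_to_sites(class1_filter(records, 0.75), groups=truth.sample_groups)
print(table.n_sites, residue_distribution(table))
# 2376 sites; S 79.0%, T 16.9%, Y 4.1%

table = log2_transform(qc_floor(table))
table, report = sample_normality_gate(table)
results, completed = run_comparison(table, "high_grade", "HC",
                                    FilterParams(), ImputationParams(seed=7))
up = results[results.volcano_class == "up"]
# 2009 sites tested, 38 up in high_grade vs HC;
# 19/20 planted high-grade markers are among them

X = completed.abundance.loc[up.index].T
y = completed.groups.loc[X.index].to_numpy()
ranking = rf_importance(X, y, top_k=15, seed=17)
auc = multiclass_auc(X.loc[:, ranking.attrs["top_k_"]], y, cv="loo")
# leave-one-out AUC of the top-15 panel: 1.000
```

The numbers mean: of 2584 simulated sites, 2376 survive class-1
filtering; the residue mix matches the 79/17/4 target; the Welch volcano
at the printed cutoffs recovers 19 of the 20 planted +1.5 log2 markers,
and the selected 15-site panel separates the groups perfectly under
leave-one-out scoring.

The full pipeline (simulate → rollup → five pairwise comparisons →
feature selection, ROC, LDA) is one command:

```bash
phosphodia run --seed 0 --out run_out   # artifacts + summary.json
```

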