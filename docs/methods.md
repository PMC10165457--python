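# Methods

## Forbidden-zone window design

Peptide monoisotopic masses cluster tightly around a line in nominal
(integer) mass because the amino acid residues share a nearly uniform
positive mass defect.  For nominal mass *m* the boundary of the empty
band is

    b(m) = ceil(m / Δ) · Δ + c

with Δ the optimal m/z increment (default 1.00045475 m/z per Da) and *c*
an additive offset (default 0.18 m/z) accounting for the mass-defect
shift of the phosphate group in phospho-enriched samples.  Both are
user-settable: *c* = 0 recovers the unmodified-peptide lattice.  Over the
practically relevant range (m below Δ/(Δ−1) ≈ 2200 Da) the ceiling is the
identity and b(m) = mΔ + c exactly; the package exploits nothing beyond
double precision.

Window grids are half-open intervals [lower, upper): a shared edge
belongs to exactly one window, so coverage statements are unambiguous.
`build_staggered_scheme` lays `ceil(span/width)` contiguous windows from
the span start (phase a) and the same grid shifted by +width/2 (phase b).
Phase b therefore starts half a window above the span start and overhangs
the top by half a window; this preserves the exact half-width stagger the
demultiplexing model assumes, and reproduces the loop count of 88 for a
700 m/z span at 8 m/z.  Ceiling division means the last window may
overhang the span top.  With alignment enabled, every edge is replaced by
its nearest forbidden-zone boundary (ties broken toward the lower
boundary, deterministically); since boundaries are spaced Δ apart, each
edge moves by less than Δ/2 + c, and shared edges snap identically so
contiguity is preserved.  The MS1 scan range an instrument displays
(e.g. 389.8–1109.8) is treated as padded display metadata, not as the
window span (400–1100).

Gas-phase fractionation plans place injection k at
[lo + k·step, lo + k·step + span], k = 0..ceil((hi − lo − span)/step), so
consecutive injections overlap by span − step (10 m/z at the defaults)
and the union covers the full range; each injection carries its own
staggered scheme of narrow MS2 windows (default 4 m/z, effective 2 m/z).

## Staggered-window demultiplexing

In a staggered scheme every half-width effective window inside the span
is covered by one window of each phase (the first half-window only by
phase a).  Writing x for the per-effective-window intensities of one
fragment channel in one cycle, each scan observes the sum of its two
constituent effective windows, giving a banded system A x = y with 2n
scans and 2n in-span unknowns.  The system is a terminating chain and has
full rank, so noiseless point sources are recovered exactly; with noise
the bounded (nonnegative) least-squares solution is returned.

Two deliberate choices:

* **Full per-cycle system, not local sliding groups.**  Any strict
  subwindow of the chain is rank-deficient (a triplet of scans covers
  four unknowns), and a nonnegative solver then returns an arbitrary
  vertex of the solution set — verified numerically.  The full per-cycle
  system is tiny (tens of unknowns), unique, and exact on clean input.
* **Solver.**  `scipy.optimize.lsq_linear(method="bvls")` is used; the
  classic `nnls` routine returned measurably suboptimal solutions on
  mildly ill-conditioned chains (objective 129.4 vs 120.2 on a test
  instance).  Tests verify optimality through the KKT conditions rather
  than through a second call of the same solver.

Demultiplexing operates per fragment channel independently, mirroring
per-peak demultiplexing and keeping the systems small.  Span-edge
effective windows covered by scans of a single phase are flagged
(`single_phase`) and pass through unsplit.  Analytes are assumed to lie
inside the span; the generator enforces this.

## Site quantification

Class-1 filtering keeps site assignments with localization probability at
or above the cutoff (inclusive; 0.75 for library-based, 0.99 for
library-free analyses) and is applied per site: a multiply phosphorylated
precursor can keep a subset of its sites.  Records left without sites are
dropped.  Raising the cutoff can only shrink the resulting site set.

Rollup sums, per sample, the abundances of every precursor containing a
site; a doubly phosphorylated precursor contributes its full abundance to
both its sites, so total site abundance equals the sum over records of
abundance × retained-site count.  Charge states of the same modified
peptide are summed before rollup (sums commute, so the order is
immaterial for the values; merging first keeps provenance counts at the
modified-peptide level).  Zero intensities are treated as missing — search
software writes blanks and zeros interchangeably — and a site-sample cell
is missing iff every contributing precursor is missing there.  Site
positions are 1-based protein coordinates; conflicting residue letters at
one position are a hard error.  Shared (multi-protein) peptides go to the
first-listed accession and are flagged.

## Statistical pipeline

Stage order is fixed and regression-tested: intensity floor → log2 →
normality gate → per-comparison completeness filter → imputation → median
normalization → Welch test.  Imputation and normalization do not commute,
so the order is part of the contract.

* **Floor** (default 30, strict): raw intensities *below* 30 become
  missing; 30 itself is kept.
* **Completeness** (default 0.70, strict): a site is kept for a
  comparison iff observed in *more than* 70% of at least one of the two
  groups — at n = 14 per group that means ≥ 10 observed.
* **Imputation**: per sample (column-wise in the Perseus convention),
  missing cells are drawn from Normal(mean − 1.8·SD, (0.3·SD)²) of that
  sample's observed values.  Left-censored (intensity-dependent)
  missingness is exactly the regime this imputation assumes.
* **Median normalization** shifts each sample to the grand median of
  sample medians — an affine per-sample shift that keeps values on the
  original scale and leaves every test statistic unchanged relative to
  centering at zero.
* **Welch test**: difference of group means in log2 units, Satterthwaite
  degrees of freedom, two-sided p from the t distribution.  Zero variance
  in both groups with equal means yields p = 1.  Volcano classes use raw
  p values (p ≤ 0.05) and |log2 difference| ≥ 0.5, both boundaries
  inclusive; a Benjamini–Hochberg q column is available but off by
  default, matching the raw-p convention of the workflow this mirrors.
* **Heatmap marker selection**: unpaired two-sample Wilcoxon rank-sum,
  p ≤ 0.1 (inclusive) with a positive median shift in the target group,
  required against *all* other groups by default (an `any` mode exists).

### The normality gate

The gate uses the D'Agostino–Pearson omnibus statistic.  Two modes:

* `absolute` — classical testing at alpha (default 0.01).  Appropriate
  for complete data; the type-I behaviour and power against bimodality
  are unit-tested.
* `cohort` (pipeline default) — a sample is excluded when its statistic
  exceeds the cohort median by more than 5 scaled MADs.  With thousands
  of observed sites per sample, an absolute test has enormous power and
  rejects *every* left-censored sample for the shared censoring skew
  alone; the cohort mode flags only samples grossly less normal than
  their peers (bimodal, corrupted, deficient), which is what excluding a
  handful of samples from a 60-sample cohort operationally means.

Samples with fewer than 8 observed values are untestable and retained
with a flag; alpha = 0 disables exclusion entirely.

## Classification

* **Feature ranking** follows the ranger convention: out-of-bag
  permutation importance from a seeded random forest (500 trees,
  sqrt-features per split).  OOB evaluation matters: training-set
  permutation importance rewards features the forest memorized noise
  with, and in testing it let chance volcano false-positives outrank
  planted markers.  Ranking is per comparison (two-group design), the
  granularity at which "top 15 from each comparison" panels are built.
* **Multiclass ROC** is the Hand–Till mean of all pairwise AUCs.  Each
  pair is scored by a Fisher discriminant whose within-class covariance
  uses Ledoit–Wolf shrinkage (well defined for features ≥ samples and for
  zero scatter), with leave-one-out held-out scores by default; a
  resubstitution mode exists and is flagged as optimistic.  The AUC
  itself is the rank (Mann–Whitney) statistic with average ranks on ties,
  checked against a brute-force pair-counting oracle.
* **LDA projection**: at most groups − 1 ≤ 2 axes; a shrinkage eigen
  solver replaces the SVD solver (with a warning) when features reach the
  sample count; axis signs are fixed by forcing the largest-magnitude
  loading positive so plots reproduce.

## Synthetic data

The generator emulates a urinary-EV cohort: 2584 phosphosites
across four groups (HC, CKD, low-grade, high-grade) of 15 samples;
pS/pT/pY drawn at 79/17/4; latent log2 abundance = base (9.5) + per-site
N(0, 2.2) + planted group effect + N(0, 0.5) within-group noise; each
site emitted through 1–3 precursors (truncated geometric, Dirichlet
intensity split) so rollup summation is exercised; localization
probabilities from a mixture (85% Beta(20, 1), 15% Beta(2, 2)) that
straddles the class-1 cutoff; missingness logistic in the latent log2
intensity (steepness 1.2, midpoint 6.5) — monotone left censoring, the
assumption behind downshift imputation — with an MCAR switch for null
calibration.  The intensity scale places roughly the bottom 2% of raw
values under the QC floor of 30 so the floor stage does real work.
Default planted markers: 20 sites per non-control group at +1.5 log2.
Effect and missingness magnitudes are plausible settings, not estimates
from the deposited raw data.

What the generator does *not* emulate: fragment-level interference,
isotope structure, retention-time drift, batch effects, or
correlated-site biology.  Passing tests therefore demonstrate the
statistical machinery under the stated model, not performance on real
acquisitions.

## Determinism and problem sizes

All randomness flows from one master seed; per-stage substreams are
derived by hashing the stage name into a `SeedSequence`, so adding a
stage never perturbs the streams of existing ones.  Reruns with an
identical configuration reproduce byte-identical statistical outputs.

Test problem sizes are chosen to make the statistical assertions sharp at
desk scale: the imputation-moment experiment uses 100,000 cells (Monte
Carlo error ≈ 0.002 against a ±0.02 band), the null-calibration
simulation 2000 sites at n = 15 per group (binomial SE ≈ 0.005 against a
±0.01 band), and the end-to-end recovery experiment the full default
generator (2584 sites, 60 samples) with 50 forest seeds.

## Known limitations

* The demultiplexer consumes synthetic scan cycles or their TSV
  serialization, not mzML/vendor spectra; no centroiding or library
  search is performed (probabilities are consumed, not produced).
* Protein inference is first-accession assignment only.
* The per-comparison statistics apply no FDR control, by design fidelity;
  the q-value column is available for stricter use.
* AUCs at n ≈ 14 per group, even leave-one-out, come from a single small
  cohort; the package deliberately implements no external-validation
  logic.
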