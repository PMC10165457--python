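"""Differential phosphosite statistics.

The pipeline from raw site abundances to volcano-classified sites is, in
order: intensity floor (raw values below 30 become missing) -> log2
transform -> per-sample normality gate -> per-comparison group
completeness filter (more than 70% observed in at least one group) ->
left-censored imputation from a downshifted normal (1.8 SD downshift,
0.3 SD width, per sample) -> per-sample median normalization -> Welch's
two-sample t test with a volcano classification at p <= 0.05 and
|log2 difference| >= 0.5 (~1.414-fold).  Raw p values are used for the
volcano classes; a Benjamini-Hochberg q value is available but off by
default.  Heatmap marker selection uses the unpaired two-sample Wilcoxon
rank-sum test at p <= 0.1 against every other group.

The stages are scikit-learn transformers operating on samples x features
matrices; :class:`~phosphodia.sites.SiteTable`-level wrappers handle the
site x sample orientation and enforce the raw/log2 scale bookkeeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .sites import SiteTable

__all__ = [
    "FilterParams",
    "ImputationParams",
    "IntensityFloor",
    "Log2Transformer",
    "NormalityGate",
    "GroupCompletenessFilter",
    "DownshiftImputer",
    "MedianNormalizer",
    "welch_volcano",
    "heatmap_marker_selection",
    "qc_floor",
    "log2_transform",
    "sample_normality_gate",
    "group_completeness_filter",
    "impute_downshift",
    "median_normalize",
    "complete_table",
    "run_comparison",
]


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the statistical pipeline.

    ``intensity_floor``: raw intensities strictly below this become
    missing.  ``completeness_fraction``: a site is kept for a comparison
    iff its observed fraction is strictly greater than this in at least
    one of the two groups.  ``p_cutoff`` / ``log2_diff_cutoff``: volcano
    classification.  ``heatmap_p_cutoff``: Wilcoxon cutoff for heatmap
    marker selection (inclusive).
    """

    intensity_floor: float = 30.0
    completeness_fraction: float = 0.70
    p_cutoff: float = 0.05
    log2_diff_cutoff: float = 0.5
    heatmap_p_cutoff: float = 0.1

    def __post_init__(self) -> None:
        if self.intensity_floor < 0:
            raise ValueError("intensity_floor must be >= 0")
        if not 0.0 <= self.completeness_fraction < 1.0:
            raise ValueError("completeness_fraction must be in [0, 1)")
        for name in ("p_cutoff", "heatmap_p_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if self.log2_diff_cutoff < 0:
            raise ValueError("log2_diff_cutoff must be >= 0")


@dataclass(frozen=True)
class ImputationParams:
    """Downshifted-normal imputation parameters (Perseus convention)."""

    downshift_sd: float = 1.8
    width_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.width_sd > 0:
            raise ValueError(f"width_sd must be > 0, got {self.width_sd!r}")


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X.astype(float)
    return pd.DataFrame(np.asarray(X, dtype=float))


class IntensityFloor(TransformerMixin, BaseEstimator):
    """Replace raw intensities strictly below ``floor`` with NaN.

    Values exactly at the floor are kept ("below 30" is read strictly).
    """

    def __init__(self, floor: float = 30.0):
        self.floor = floor

    def fit(self, X, y=None):
        self.n_features_in_ = _as_frame(X).shape[1]
        return self

    def transform(self, X):
        out = _as_frame(X).copy()
        out[out < self.floor] = np.nan
        return out


class Log2Transformer(TransformerMixin, BaseEstimator):
    """Elementwise log2; missing values are preserved.

    Nonpositive observed values are rejected: the intensity floor must run
    first on raw data.
    """

    def fit(self, X, y=None):
        self.n_features_in_ = _as_frame(X).shape[1]
        return self

    def transform(self, X):
        out = _as_frame(X)
        bad = (out.to_numpy() <= 0) & np.isfinite(out.to_numpy())
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} nonpositive values; apply the intensity "
                "floor before the log2 transform"
            )
        return np.log2(out)


class NormalityGate(BaseEstimator):
    """Exclude samples whose observed log2 distribution fails a normality
    requirement.

    Two modes share the D'Agostino-Pearson omnibus statistic:

    ``mode='absolute'``
        Classical testing: a sample is excluded when its omnibus p value
        falls below ``alpha`` (default 0.01).  Appropriate for complete
        data; with thousands of observed sites the test has extreme power,
        so on left-censored (MNAR) intensities it rejects every sample for
        the censoring skew alone.
    ``mode='cohort'``
        Outlier screening: a sample is excluded when its omnibus statistic
        exceeds the cohort median by more than ``mad_factor`` scaled MADs.
        This flags samples that are grossly less normal than their peers
        (bimodal, corrupted) while tolerating the skew every censored
        sample shares; it is the full-pipeline default.

    Samples (rows) with fewer than ``min_observations`` observed values are
    flagged untestable and retained.  ``alpha = 0`` disables exclusion in
    either mode.

    Attributes
    ----------
    statistics_, pvalues_ : ndarray
        Per-sample omnibus statistic and p value (NaN if untestable).
    retained_ : ndarray of bool
        Mask of samples kept by :meth:`transform`.
    untestable_ : ndarray of bool
        Samples with too few observations to test.
    """

    def __init__(
        self,
        alpha: float = 0.01,
        min_observations: int = 8,
        mode: str = "absolute",
        mad_factor: float = 5.0,
    ):
        self.alpha = alpha
        self.min_observations = min_observations
        self.mode = mode
        self.mad_factor = mad_factor

    def fit(self, X, y=None):
        if self.mode not in ("absolute", "cohort"):
            raise ValueError(
                f"mode must be 'absolute' or 'cohort', got {self.mode!r}"
            )
        frame = _as_frame(X)
        values = frame.to_numpy()
        n = len(frame)
        self.statistics_ = np.full(n, np.nan)
        self.pvalues_ = np.full(n, np.nan)
        self.untestable_ = np.zeros(n, dtype=bool)
        for i in range(n):
            obs = values[i][np.isfinite(values[i])]
            if len(obs) < self.min_observations:
                self.untestable_[i] = True
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # kurtosistest small-n warning
                res = sps.normaltest(obs)
            self.statistics_[i] = res.statistic
            self.pvalues_[i] = res.pvalue
        testable = ~self.untestable_ & np.isfinite(self.statistics_)
        if self.alpha == 0 or not testable.any():
            self.retained_ = np.ones(n, dtype=bool)
        elif self.mode == "absolute":
            self.retained_ = ~testable | (self.pvalues_ >= self.alpha)
        else:
            stats = self.statistics_[testable]
            center = np.median(stats)
            mad = 1.4826 * np.median(np.abs(stats - center))
            cutoff = center + self.mad_factor * max(mad, 1e-12)
            self.retained_ = ~testable | (self.statistics_ <= cutoff)
        self.index_ = frame.index
        return self

    def transform(self, X):
        frame = _as_frame(X)
        return frame.loc[self.retained_]

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": self.statistics_,
                "p_value": self.pvalues_,
                "retained": self.retained_,
                "untestable": self.untestable_,
            },
            index=self.index_,
        )


class GroupCompletenessFilter(TransformerMixin, BaseEstimator):
    """Keep features observed in strictly more than ``fraction`` of the
    samples of at least one group ("more than 70%" is strict)."""

    def __init__(self, fraction: float = 0.70):
        self.fraction = fraction

    def fit(self, X, y):
        frame = _as_frame(X)
        y = np.asarray(y)
        if len(y) != len(frame):
            raise ValueError("y must have one group label per sample")
        groups = pd.unique(y)
        if any((y == g).sum() == 0 for g in groups) or len(groups) == 0:
            raise ValueError("empty group in design")
        observed = np.isfinite(frame.to_numpy())
        best = np.zeros(frame.shape[1])
        for g in groups:
            mask = y == g
            best = np.maximum(best, observed[mask].mean(axis=0))
        self.support_ = best > self.fraction
        self.n_features_in_ = frame.shape[1]
        return self

    def transform(self, X):
        frame = _as_frame(X)
        return frame.loc[:, self.support_]


class DownshiftImputer(TransformerMixin, BaseEstimator):
    """Left-censored imputation from a downshifted normal distribution.

    Per sample (row), missing cells are drawn from
    ``Normal(mean_obs - downshift_sd * sd_obs, (width_sd * sd_obs)**2)``
    where the moments come from that sample's observed values -- the
    Perseus column-wise convention.  Observed cells are untouched, and the
    draw is deterministic under a fixed ``random_state``.
    """

    def __init__(
        self,
        downshift_sd: float = 1.8,
        width_sd: float = 0.3,
        random_state: int | None = None,
    ):
        self.downshift_sd = downshift_sd
        self.width_sd = width_sd
        self.random_state = random_state

    def fit(self, X, y=None):
        if not self.width_sd > 0:
            raise ValueError(f"width_sd must be > 0, got {self.width_sd!r}")
        self.n_features_in_ = _as_frame(X).shape[1]
        return self

    def transform(self, X):
        if not self.width_sd > 0:
            raise ValueError(f"width_sd must be > 0, got {self.width_sd!r}")
        out = _as_frame(X).copy()
        rng = np.random.default_rng(self.random_state)
        values = out.to_numpy()
        for i in range(len(out)):
            row = values[i]
            observed = np.isfinite(row)
            if observed.sum() < 2:
                raise ValueError(
                    f"sample {out.index[i]!r} has fewer than 2 observed "
                    "values; cannot estimate imputation moments"
                )
            n_missing = int((~observed).sum())
            if n_missing == 0:
                continue
            mean = row[observed].mean()
            sd = row[observed].std(ddof=1)
            row[~observed] = rng.normal(
                mean - self.downshift_sd * sd,
                self.width_sd * sd,
                size=n_missing,
            )
        out.iloc[:, :] = values
        return out


class MedianNormalizer(TransformerMixin, BaseEstimator):
    """Shift each sample (row) so its median equals the grand median of
    the sample medians seen at fit time.

    An affine per-sample shift: within-sample differences, and therefore
    all test statistics, are unchanged by the choice of target.
    """

    def fit(self, X, y=None):
        frame = _as_frame(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            medians = np.nanmedian(frame.to_numpy(), axis=1)
        self.target_ = float(np.median(medians))
        self.n_features_in_ = frame.shape[1]
        return self

    def transform(self, X):
        frame = _as_frame(X).copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            medians = np.nanmedian(frame.to_numpy(), axis=1)
        return frame.sub(medians - self.target_, axis=0)


def welch_volcano(
    X,
    y,
    group_a: str,
    group_b: str,
    params: FilterParams | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """Welch's two-sample t test per feature with volcano classification.

    ``log2_difference`` is mean(group_a) - mean(group_b); degrees of
    freedom follow Welch-Satterthwaite; the two-sided p value comes from
    the t distribution.  A feature is ``up`` iff p <= p_cutoff and
    log2_difference >= log2_diff_cutoff, ``down`` symmetrically, otherwise
    ``not_significant``.  No multiple-testing correction is applied to the
    classification; ``fdr=True`` adds an informational Benjamini-Hochberg
    ``q_value`` column.
    """
    if params is None:
        params = FilterParams()
    frame = _as_frame(X)
    y = np.asarray(y)
    A = frame.loc[y == group_a].to_numpy()
    B = frame.loc[y == group_b].to_numpy()
    if len(A) < 2 or len(B) < 2:
        raise ValueError("both groups need at least 2 samples")
    if not (np.isfinite(A).all() and np.isfinite(B).all()):
        raise ValueError("welch_volcano requires a completed (imputed) table")

    with np.errstate(divide="ignore", invalid="ignore"):
        res = sps.ttest_ind(A, B, axis=0, equal_var=False)
        t = np.array(res.statistic, dtype=float)
        p = np.array(res.pvalue, dtype=float)
        df = np.array(res.df, dtype=float)
    diff = A.mean(axis=0) - B.mean(axis=0)

    # Degenerate: zero variance in both groups.
    va = A.var(axis=0, ddof=1)
    vb = B.var(axis=0, ddof=1)
    degenerate = (va == 0) & (vb == 0)
    both_equal = degenerate & (diff == 0)
    t[both_equal] = 0.0
    p[both_equal] = 1.0
    separated = degenerate & (diff != 0)
    t[separated] = np.sign(diff[separated]) * np.inf
    p[separated] = 0.0
    df[degenerate] = len(A) + len(B) - 2

    out = pd.DataFrame(
        {
            "log2_difference": diff,
            "t_statistic": t,
            "df": df,
            "p_value": p,
        },
        index=frame.columns,
    )
    if fdr:
        out["q_value"] = sps.false_discovery_control(p, method="bh")
    volcano = np.where(
        (p <= params.p_cutoff) & (diff >= params.log2_diff_cutoff),
        "up",
        np.where(
            (p <= params.p_cutoff) & (diff <= -params.log2_diff_cutoff),
            "down",
            "not_significant",
        ),
    )
    out["volcano_class"] = volcano
    return out


def heatmap_marker_selection(
    X,
    y,
    target_groups: tuple[str, ...] = ("low_grade", "high_grade"),
    p_cutoff: float = 0.1,
    mode: str = "all",
) -> dict[str, list]:
    """Heatmap marker selection by unpaired two-sample Wilcoxon rank-sum.

    For each target group G, a feature is selected when the rank-sum p
    value is <= ``p_cutoff`` (inclusive) and the shift (median difference)
    is positive in G for each pairwise comparison against every other
    group (``mode='all'``) or for at least one (``mode='any'``).
    """
    if mode not in ("all", "any"):
        raise ValueError(f"mode must be 'all' or 'any', got {mode!r}")
    frame = _as_frame(X)
    y = np.asarray(y)
    groups = list(pd.unique(y))
    for g in groups:
        if (y == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")
    combine = np.all if mode == "all" else np.any
    selected: dict[str, list] = {}
    for target in target_groups:
        if target not in groups:
            raise ValueError(f"target group {target!r} not in design")
        G = frame.loc[y == target].to_numpy()
        hits = []
        for other in groups:
            if other == target:
                continue
            O = frame.loc[y == other].to_numpy()
            p = sps.mannwhitneyu(
                G, O, axis=0, alternative="two-sided"
            ).pvalue
            shift = np.median(G, axis=0) - np.median(O, axis=0)
            hits.append((p <= p_cutoff) & (shift > 0))
        mask = combine(np.vstack(hits), axis=0)
        selected[target] = list(frame.columns[mask])
    return selected


# ---------------------------------------------------------------------------
# SiteTable-level wrappers (site x sample orientation, scale bookkeeping).
# ---------------------------------------------------------------------------


def _require_scale(table: SiteTable, scale: str, op: str) -> None:
    if table.scale != scale:
        raise ValueError(
            f"{op} requires a {scale}-scale table, got {table.scale!r}"
        )


def qc_floor(table: SiteTable, floor: float = 30.0) -> SiteTable:
    """Raw intensities strictly below ``floor`` become missing."""
    _require_scale(table, "raw", "qc_floor")
    floored = IntensityFloor(floor).fit_transform(table.abundance.T).T
    return table.replace(abundance=floored)


def log2_transform(table: SiteTable) -> SiteTable:
    _require_scale(table, "raw", "log2_transform")
    transformed = Log2Transformer().fit_transform(table.abundance.T).T
    return table.replace(abundance=transformed, scale="log2")


def sample_normality_gate(
    table: SiteTable,
    alpha: float = 0.01,
    min_observations: int = 8,
    mode: str = "cohort",
) -> tuple[SiteTable, pd.DataFrame]:
    """Drop samples failing the normality requirement; returns
    (table, report).  On censored site tables the cohort-outlier mode is
    the default (see :class:`NormalityGate`)."""
    _require_scale(table, "log2", "sample_normality_gate")
    gate = NormalityGate(
        alpha=alpha, min_observations=min_observations, mode=mode
    )
    gated = gate.fit(table.abundance.T).transform(table.abundance.T).T
    groups = table.groups
    if groups is not None:
        groups = groups.loc[gated.columns]
    return table.replace(abundance=gated, groups=groups), gate.report()


def group_completeness_filter(
    table: SiteTable,
    group_a: str,
    group_b: str,
    fraction: float = 0.70,
) -> SiteTable:
    """Restrict to the two groups' samples and keep sites observed in more
    than ``fraction`` of at least one group."""
    if table.groups is None:
        raise ValueError("table has no group design")
    mask = table.groups.isin([group_a, group_b])
    samples = [s for s in table.samples if mask.get(s, False)]
    sub = table.abundance[samples]
    y = table.groups.loc[samples].to_numpy()
    if (y == group_a).sum() == 0 or (y == group_b).sum() == 0:
        raise ValueError(
            f"empty group in comparison {group_a!r} vs {group_b!r}"
        )
    filt = GroupCompletenessFilter(fraction).fit(sub.T, y)
    kept = filt.transform(sub.T).T
    return table.replace(
        abundance=kept,
        groups=table.groups.loc[samples],
        provenance=None if table.provenance is None
        else table.provenance.loc[kept.index],
    )


def impute_downshift(
    table: SiteTable, params: ImputationParams | None = None
) -> SiteTable:
    _require_scale(table, "log2", "impute_downshift")
    if params is None:
        params = ImputationParams()
    imputer = DownshiftImputer(
        downshift_sd=params.downshift_sd,
        width_sd=params.width_sd,
        random_state=params.seed,
    )
    completed = imputer.fit_transform(table.abundance.T).T
    return table.replace(abundance=completed)


def median_normalize(table: SiteTable) -> SiteTable:
    _require_scale(table, "log2", "median_normalize")
    normalized = MedianNormalizer().fit_transform(table.abundance.T).T
    return table.replace(abundance=normalized)


def complete_table(
    table: SiteTable,
    filter_params: FilterParams | None = None,
    imputation_params: ImputationParams | None = None,
) -> SiteTable:
    """Completeness-filter (over all design groups), impute and
    median-normalize a gated log2 table, keeping every group's samples.

    Used for the multi-group classification stage, where a comparison-
    specific two-group restriction does not apply.
    """
    if filter_params is None:
        filter_params = FilterParams()
    if table.groups is None:
        raise ValueError("table has no group design")
    _require_scale(table, "log2", "complete_table")
    y = table.groups.loc[table.samples].to_numpy()
    filt = GroupCompletenessFilter(filter_params.completeness_fraction).fit(
        table.abundance.T, y
    )
    kept = filt.transform(table.abundance.T).T
    out = table.replace(
        abundance=kept,
        provenance=None
        if table.provenance is None
        else table.provenance.loc[kept.index],
    )
    out = impute_downshift(out, imputation_params)
    return median_normalize(out)


def run_comparison(
    table: SiteTable,
    group_a: str,
    group_b: str,
    filter_params: FilterParams | None = None,
    imputation_params: ImputationParams | None = None,
    fdr: bool = False,
) -> tuple[pd.DataFrame, SiteTable]:
    """One two-group comparison on a gated log2 table.

    Applies, in order, the per-comparison completeness filter, downshift
    imputation and median normalization, then the Welch volcano test.
    Returns the per-site results and the completed two-group table.
    """
    if filter_params is None:
        filter_params = FilterParams()
    sub = group_completeness_filter(
        table, group_a, group_b, filter_params.completeness_fraction
    )
    sub = impute_downshift(sub, imputation_params)
    sub = median_normalize(sub)
    results = welch_volcano(
        sub.abundance.T,
        sub.groups.loc[sub.samples].to_numpy(),
        group_a,
        group_b,
        filter_params,
        fdr=fdr,
    )
    return results, sub
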