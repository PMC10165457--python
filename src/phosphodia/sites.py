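"""Phosphosite-level quantification from precursor reports.

Search software exports modified-peptide precursors with per-site
localization probabilities and per-sample intensities.  This module filters
them to class-1 sites (localization probability above a confidence cutoff),
rolls precursor abundances up to protein-coordinate phosphosites by summing
every precursor that contains the site, and provides the residue-composition
and replicate-CV summaries plus the fragment-ion library filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "SiteAssignment",
    "SiteKey",
    "PrecursorRecord",
    "SiteTable",
    "FragmentIon",
    "class1_filter",
    "merge_charge_states",
    "collapse_to_sites",
    "residue_distribution",
    "replicate_cv",
    "filter_fragment_ions",
]

_RESIDUES = frozenset("STY")


class SiteKey(NamedTuple):
    """Protein-coordinate phosphosite identity."""

    protein_accession: str
    residue: str
    position: int

    def __str__(self) -> str:  # e.g. "P12345-S25"
        return f"{self.protein_accession}-{self.residue}{self.position}"


@dataclass(frozen=True)
class SiteAssignment:
    """One phosphosite assignment on a precursor, in protein coordinates."""

    position: int
    residue: str
    localization_probability: float

    def __post_init__(self) -> None:
        if self.residue not in _RESIDUES:
            raise ValueError(
                f"residue must be one of S/T/Y, got {self.residue!r}"
            )
        if not 0.0 <= self.localization_probability <= 1.0:
            raise ValueError(
                "localization_probability must be in [0, 1], got "
                f"{self.localization_probability!r}"
            )
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position!r}")


@dataclass(frozen=True)
class PrecursorRecord:
    """One modified-peptide precursor with its site assignments and
    per-sample raw intensities (NaN = missing).

    Shared (multi-protein) peptides are assigned to the first-listed
    accession; the remaining accessions are kept for the record.
    """

    modified_sequence: str
    protein_accession: str
    charge: int
    sites: tuple[SiteAssignment, ...]
    abundances: dict[str, float]
    other_accessions: tuple[str, ...] = ()

    @property
    def shared(self) -> bool:
        return len(self.other_accessions) > 0

    def site_keys(self) -> list[SiteKey]:
        return [
            SiteKey(self.protein_accession, s.residue, s.position)
            for s in self.sites
        ]


@dataclass
class SiteTable:
    """Phosphosite x sample abundance matrix with group design.

    ``abundance`` is indexed by (protein_accession, residue, position);
    ``groups`` maps sample id to group label; ``scale`` records whether the
    matrix holds raw intensities or log2 values; ``provenance`` counts the
    modified peptides contributing to each site.
    """

    abundance: pd.DataFrame
    groups: pd.Series | None = None
    scale: str = "raw"
    provenance: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        if self.abundance.index.has_duplicates:
            raise ValueError("duplicate SiteKey in abundance index")
        if self.groups is not None:
            missing = [s for s in self.abundance.columns if s not in self.groups.index]
            if missing:
                raise ValueError(f"samples without group label: {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def n_sites(self) -> int:
        return len(self.abundance)

    def site_keys(self) -> list[SiteKey]:
        return [SiteKey(*idx) for idx in self.abundance.index]

    def replace(self, **kwargs) -> "SiteTable":
        fields = {
            "abundance": self.abundance,
            "groups": self.groups,
            "scale": self.scale,
            "provenance": self.provenance,
        }
        fields.update(kwargs)
        return SiteTable(**fields)


@dataclass(frozen=True)
class FragmentIon:
    """One library fragment ion of a precursor."""

    mz: float
    relative_intensity: float
    residue_count: int
    neutral_loss: bool = False

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"mz must be > 0, got {self.mz!r}")
        if not 0.0 <= self.relative_intensity <= 1.0:
            raise ValueError(
                f"relative_intensity must be in [0, 1], got "
                f"{self.relative_intensity!r}"
            )


def class1_filter(
    records: Iterable[PrecursorRecord], cutoff: float = 0.75
) -> list[PrecursorRecord]:
    """Retain class-1 site assignments (localization probability >= cutoff).

    The cutoff is inclusive; a probability exactly at the cutoff passes.
    Records left with no confidently localized site are dropped.  The
    library-based default is 0.75; library-free (direct DIA) analyses use
    0.99.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff!r}")
    out = []
    for rec in records:
        kept = tuple(
            s for s in rec.sites if s.localization_probability >= cutoff
        )
        if kept:
            out.append(replace(rec, sites=kept))
    return out


def _nan_aware_sum(values: list[dict[str, float]], samples: list[str]) -> np.ndarray:
    """Sum dicts of per-sample abundances; a cell is NaN iff every
    contributor is missing there."""
    arr = np.full((len(values), len(samples)), np.nan)
    col = {s: j for j, s in enumerate(samples)}
    for i, ab in enumerate(values):
        for s, v in ab.items():
            if s in col and v is not None and np.isfinite(v) and v > 0:
                arr[i, col[s]] = v
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        total = np.nansum(arr, axis=0)
        total[np.all(np.isnan(arr), axis=0)] = np.nan
    return total


def merge_charge_states(
    records: Iterable[PrecursorRecord],
) -> list[PrecursorRecord]:
    """Sum abundances of charge states of the same modified peptide.

    Peptide grouping is by (accession, modified sequence, site set); the
    merged record keeps charge 0 as a sentinel for "summed over charges".
    Because site rollup is itself a sum, merging before or after rollup
    gives identical site abundances; merging first keeps provenance counts
    at the modified-peptide level.
    """
    groups: dict[tuple, list[PrecursorRecord]] = {}
    for rec in records:
        key = (rec.protein_accession, rec.modified_sequence, rec.sites)
        groups.setdefault(key, []).append(rec)
    merged = []
    for (_, _, _), recs in groups.items():
        if len(recs) == 1:
            merged.append(recs[0])
            continue
        samples = sorted({s for r in recs for s in r.abundances})
        total = _nan_aware_sum([r.abundances for r in recs], samples)
        merged.append(
            replace(
                recs[0],
                charge=0,
                abundances=dict(zip(samples, total)),
            )
        )
    return merged


def collapse_to_sites(
    records: Iterable[PrecursorRecord],
    groups: pd.Series | None = None,
) -> SiteTable:
    """Roll precursor abundances up to a phosphosite x sample table.

    The abundance of a site in a sample is the sum of the abundances of all
    precursors containing that site; a multiply phosphorylated precursor
    contributes its full abundance to each of its sites.  A site-sample
    cell is missing iff every contributing precursor is missing there.
    Zero intensities are treated as missing.  Charge states of the same
    modified peptide are summed first.
    """
    records = merge_charge_states(records)
    residue_at: dict[tuple[str, int], str] = {}
    contributors: dict[SiteKey, list[PrecursorRecord]] = {}
    for rec in records:
        for key in rec.site_keys():
            loc = (key.protein_accession, key.position)
            prev = residue_at.setdefault(loc, key.residue)
            if prev != key.residue:
                raise ValueError(
                    f"conflicting residues at {key.protein_accession} "
                    f"position {key.position}: {prev!r} vs {key.residue!r} "
                    f"(record {rec.modified_sequence!r})"
                )
            contributors.setdefault(key, []).append(rec)

    samples = sorted({s for rec in records for s in rec.abundances})
    keys = sorted(contributors)
    data = np.full((len(keys), len(samples)), np.nan)
    for i, key in enumerate(keys):
        data[i] = _nan_aware_sum(
            [r.abundances for r in contributors[key]], samples
        )
    index = pd.MultiIndex.from_tuples(
        keys, names=["protein_accession", "residue", "position"]
    )
    abundance = pd.DataFrame(data, index=index, columns=samples)
    provenance = pd.Series(
        [len(contributors[k]) for k in keys], index=index, name="n_precursors"
    )
    return SiteTable(
        abundance=abundance, groups=groups, scale="raw", provenance=provenance
    )


def residue_distribution(table: SiteTable) -> dict[str, float]:
    """Percentages of pSer/pThr/pTyr among quantified sites."""
    if table.n_sites == 0:
        raise ValueError("empty site table")
    residues = table.abundance.index.get_level_values("residue")
    counts = residues.value_counts()
    return {
        r: 100.0 * counts.get(r, 0) / len(residues) for r in ("S", "T", "Y")
    }


def replicate_cv(abundance: pd.DataFrame) -> pd.Series:
    """Coefficient of variation (%) per feature over replicate columns.

    Expects raw-scale intensities.  ``CV% = 100 * sd / mean`` with the
    sample (ddof=1) standard deviation.  Rows with fewer than two observed
    values yield NaN; a zero mean yields NaN with a warning.
    """
    values = abundance.to_numpy(dtype=float)
    n_obs = np.sum(np.isfinite(values), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(values, axis=1)
        sd = np.nanstd(values, axis=1, ddof=1)
    cv = np.full(len(values), np.nan)
    ok = n_obs >= 2
    zero_mean = ok & (mean == 0)
    if np.any(zero_mean):
        warnings.warn(
            f"{int(zero_mean.sum())} features have zero mean; CV undefined",
            stacklevel=2,
        )
    ok &= mean != 0
    cv[ok] = 100.0 * sd[ok] / mean[ok]
    return pd.Series(cv, index=abundance.index, name="cv_percent")


def filter_fragment_ions(
    ions: Iterable[FragmentIon],
    min_mz: float = 300.0,
    max_mz: float = 1800.0,
    min_relative_intensity: float = 0.05,
    min_residue_count: int = 3,
    top_n: int = 15,
) -> list[FragmentIon]:
    """Library fragment-ion filter.

    Keeps ions with m/z in [min_mz, max_mz], relative intensity >=
    min_relative_intensity and at least ``min_residue_count`` residues
    (neutral-loss ions are retained), then truncates to the ``top_n`` most
    intense.
    """
    passing = [
        ion
        for ion in ions
        if min_mz <= ion.mz <= max_mz
        and ion.relative_intensity >= min_relative_intensity
        and ion.residue_count >= min_residue_count
    ]
    passing.sort(key=lambda ion: ion.relative_intensity, reverse=True)
    return passing[:top_n]
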