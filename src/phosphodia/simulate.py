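"""Synthetic urinary-EV phosphoproteome reports and staggered scan cycles.

The generator emulates the statistical structure the analysis pipeline
assumes: log-normal precursor abundances, four patient groups (healthy
control, chronic kidney disease, clear cell low-grade and high-grade RCC)
of 15 samples each, planted log2 group effects on marker sites,
intensity-dependent left-censored (MNAR) missingness, localization
probabilities from a mixture straddling the class-1 cutoff, a pS/pT/pY
residue mix near 79/17/4, and one to three precursors (charge states /
missed cleavages) per site so that site rollup is exercised.

It also synthesizes staggered MS2 scan cycles with known effective-window
ground truth for the demultiplexer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demux import AnalyteSignal, Scan, ScanCycle
from .sites import PrecursorRecord, SiteAssignment, SiteKey
from .windows import WindowScheme

__all__ = [
    "MarkerSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_report",
    "simulate_scan_cycles",
]

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRVW"))  # no S/T/Y: sites explicit


@dataclass(frozen=True)
class MarkerSpec:
    """Planted marker set for one group: count and log2 effect size."""

    n_markers: int = 20
    effect_log2: float = 1.5


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic precursor report.

    Defaults emulate the urinary-EV cohort the pipeline targets: 2584
    phosphosites, four groups of 15 samples, residue mix 79/17/4, and 20
    planted markers (+1.5 log2) in each non-control group.  Latent log2
    abundances are ``base_log2_mean`` + per-site N(0, between_site_sd) +
    group effect + N(0, within_group_sd); missingness is logistic in the
    latent log2 intensity (MNAR) so that low-abundance cells are censored,
    with the scale placed so a low quantile of raw intensities falls below
    the QC floor of 30.
    """

    n_sites: int = 2584
    n_samples_per_group: int = 15
    groups: tuple[str, ...] = ("HC", "CKD", "low_grade", "high_grade")
    residue_probs: tuple[float, float, float] = (0.79, 0.17, 0.04)  # S, T, Y
    base_log2_mean: float = 9.5
    between_site_sd: float = 2.2
    within_group_sd: float = 0.5
    markers: dict = field(
        default_factory=lambda: {
            "CKD": MarkerSpec(),
            "low_grade": MarkerSpec(),
            "high_grade": MarkerSpec(),
        }
    )
    missing_mode: str = "MNAR"  # or "MCAR"
    missing_steepness: float = 1.2  # logistic steepness in log2 units
    missing_midpoint: float = 6.5  # log2 intensity of 50% missingness
    mcar_rate: float = 0.1
    loc_well_fraction: float = 0.85
    loc_well_beta: tuple[float, float] = (20.0, 1.0)
    loc_diffuse_beta: tuple[float, float] = (2.0, 2.0)
    precursor_geometric_p: float = 0.5
    max_precursors: int = 3
    sites_per_protein: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_samples_per_group < 1:
            raise ValueError("n_sites and n_samples_per_group must be >= 1")
        if abs(sum(self.residue_probs) - 1.0) > 1e-9:
            raise ValueError("residue_probs must sum to 1")
        for name in ("between_site_sd", "within_group_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.missing_mode not in ("MNAR", "MCAR"):
            raise ValueError("missing_mode must be 'MNAR' or 'MCAR'")
        for g, spec in self.markers.items():
            if g not in self.groups:
                raise ValueError(f"marker group {g!r} not in groups")
            if not np.isfinite(spec.effect_log2):
                raise ValueError("marker effects must be finite")


@dataclass
class GroundTruth:
    """What the generator actually planted.

    ``true_group_means``: site x group latent log2 means.
    ``marker_flags``: site x group booleans for planted markers.
    ``latent_log2``: site x sample latent log2 abundance before censoring.
    ``missing_site_sample``: site x sample booleans, True where every
    precursor of the site was censored.
    """

    site_keys: list[SiteKey]
    sample_groups: pd.Series
    true_group_means: pd.DataFrame
    marker_flags: pd.DataFrame
    latent_log2: pd.DataFrame
    missing_site_sample: pd.DataFrame

    def markers_of(self, group: str) -> list[SiteKey]:
        flags = self.marker_flags[group]
        return [SiteKey(*idx) for idx in self.marker_flags.index[flags]]


def _random_peptide(rng: np.random.Generator, residue: str) -> str:
    length = int(rng.integers(6, 15))
    pos = int(rng.integers(0, length))
    aas = rng.choice(_AMINO_ACIDS, size=length)
    seq = "".join(aas)
    return seq[:pos] + residue + "(ph)" + seq[pos:]


def simulate_report(
    config: SimulationConfig | None = None,
) -> tuple[list[PrecursorRecord], GroundTruth]:
    """Generate a precursor-level report and its ground truth.

    Deterministic under ``config.seed``.
    """
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.seed)

    n_sites = config.n_sites
    samples = [
        f"{g}_{i + 1:02d}"
        for g in config.groups
        for i in range(config.n_samples_per_group)
    ]
    sample_groups = pd.Series(
        [s.rsplit("_", 1)[0] for s in samples], index=samples, name="group"
    )

    # Site identities: proteins with a few sites each, residues ~ 79/17/4.
    n_proteins = max(1, int(np.ceil(n_sites / config.sites_per_protein)))
    residues = rng.choice(
        ["S", "T", "Y"], size=n_sites, p=list(config.residue_probs)
    )
    site_keys: list[SiteKey] = []
    used: set[tuple[str, int]] = set()
    for i in range(n_sites):
        acc = f"SYNP{i % n_proteins:04d}"
        while True:
            pos = int(rng.integers(1, 1000))
            if (acc, pos) not in used:
                used.add((acc, pos))
                break
        site_keys.append(SiteKey(acc, str(residues[i]), pos))
    index = pd.MultiIndex.from_tuples(
        site_keys, names=["protein_accession", "residue", "position"]
    )

    # Planted markers: disjoint site sets per group.
    marker_flags = pd.DataFrame(
        False, index=index, columns=list(config.groups)
    )
    effects = np.zeros((n_sites, len(config.groups)))
    available = rng.permutation(n_sites)
    cursor = 0
    for g, spec in config.markers.items():
        chosen = available[cursor : cursor + spec.n_markers]
        cursor += spec.n_markers
        col = list(config.groups).index(g)
        effects[chosen, col] = spec.effect_log2
        marker_flags.iloc[chosen, col] = True

    # Latent log2 abundances.
    baseline = config.base_log2_mean + rng.normal(
        0.0, config.between_site_sd, size=n_sites
    )
    group_of = np.array(
        [list(config.groups).index(g) for g in sample_groups.to_numpy()]
    )
    true_means = baseline[:, None] + effects  # site x group
    latent = (
        true_means[:, group_of]
        + rng.normal(0.0, config.within_group_sd, size=(n_sites, len(samples)))
    )

    # Precursors per site: truncated geometric on 1..max_precursors.
    k = np.arange(1, config.max_precursors + 1)
    pk = (1 - config.precursor_geometric_p) ** (k - 1) * config.precursor_geometric_p
    pk /= pk.sum()
    n_prec = rng.choice(k, size=n_sites, p=pk)

    records: list[PrecursorRecord] = []
    missing_site_sample = np.ones((n_sites, len(samples)), dtype=bool)
    for i, key in enumerate(site_keys):
        weights = rng.dirichlet(np.full(n_prec[i], 5.0))
        raw_site = np.power(2.0, latent[i])
        for p_idx in range(n_prec[i]):
            raw = weights[p_idx] * raw_site
            with np.errstate(divide="ignore"):
                log2_raw = np.log2(raw)
            if config.missing_mode == "MNAR":
                with np.errstate(over="ignore"):
                    p_missing = 1.0 / (
                        1.0
                        + np.exp(
                            config.missing_steepness
                            * (log2_raw - config.missing_midpoint)
                        )
                    )
            else:
                p_missing = np.full(len(samples), config.mcar_rate)
            missing = rng.random(len(samples)) < p_missing
            missing_site_sample[i] &= missing
            if missing.all():
                continue
            if rng.random() < config.loc_well_fraction:
                prob = rng.beta(*config.loc_well_beta)
            else:
                prob = rng.beta(*config.loc_diffuse_beta)
            abund = {
                s: (np.nan if missing[j] else float(raw[j]))
                for j, s in enumerate(samples)
            }
            records.append(
                PrecursorRecord(
                    modified_sequence=_random_peptide(rng, key.residue),
                    protein_accession=key.protein_accession,
                    charge=int(rng.choice([2, 3])),
                    sites=(
                        SiteAssignment(
                            position=key.position,
                            residue=key.residue,
                            localization_probability=float(
                                np.clip(prob, 0.0, 1.0)
                            ),
                        ),
                    ),
                    abundances=abund,
                )
            )

    truth = GroundTruth(
        site_keys=site_keys,
        sample_groups=sample_groups,
        true_group_means=pd.DataFrame(
            true_means, index=index, columns=list(config.groups)
        ),
        marker_flags=marker_flags,
        latent_log2=pd.DataFrame(latent, index=index, columns=samples),
        missing_site_sample=pd.DataFrame(
            missing_site_sample, index=index, columns=samples
        ),
    )
    return records, truth


def simulate_scan_cycles(
    scheme: WindowScheme,
    analytes,
    n_cycles: int = 4,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[ScanCycle], list[AnalyteSignal]]:
    """Synthesize staggered scan cycles for a list of analytes.

    ``analytes`` is an iterable of ``(precursor_mz, fragment_channel,
    intensity)`` where intensity is a scalar (constant trace) or a
    sequence of length ``n_cycles``.  Each scan observes the summed
    intensity of the analytes inside its window plus optional Gaussian
    noise (clipped at zero).  Returns the cycles and the ground-truth
    :class:`AnalyteSignal` list with true effective-window indices.
    """
    from .demux import effective_window_index  # local: avoids cycle at import

    rng = np.random.default_rng(seed)
    signals: list[AnalyteSignal] = []
    for mz, channel, intensity in analytes:
        trace = np.broadcast_to(
            np.asarray(intensity, dtype=float), (n_cycles,)
        ).copy() if np.ndim(intensity) == 0 else np.asarray(
            intensity, dtype=float
        )
        if len(trace) != n_cycles:
            raise ValueError(
                f"intensity trace length {len(trace)} != n_cycles {n_cycles}"
            )
        signals.append(
            AnalyteSignal(
                precursor_mz=float(mz),
                fragment_channel=str(channel),
                intensity_trace=tuple(trace),
                true_effective_window=effective_window_index(scheme, float(mz)),
            )
        )

    cycles: list[ScanCycle] = []
    for c in range(n_cycles):
        scans = []
        for phase, windows in (("a", scheme.phase_a), ("b", scheme.phase_b)):
            for win in windows:
                observed: dict[str, float] = {}
                for sig in signals:
                    if win.contains(sig.precursor_mz):
                        observed[sig.fragment_channel] = (
                            observed.get(sig.fragment_channel, 0.0)
                            + sig.intensity_trace[c]
                        )
                if noise_sd > 0:
                    for ch in list(observed):
                        observed[ch] = max(
                            0.0, observed[ch] + rng.normal(0.0, noise_sd)
                        )
                scans.append(Scan(window=win, phase=phase, observed=observed))
        cycles.append(ScanCycle(cycle_index=c, scans=tuple(scans)))
    return cycles, signals
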