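"""Readers and writers for the plain-text artifacts of the pipeline.

Everything is delimited text with documented headers: precursor reports
(long format, one row per precursor-sample cell), site tables (TSV with a
``#`` header block recording sample groups and scale), window lists (CSV
importable as an instrument window list), scan cycles and demultiplexing
results (TSV).  Numbers round-trip through ``repr`` so regression tests
can be exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demux import Scan, ScanCycle
from .sites import PrecursorRecord, SiteAssignment, SiteTable
from .windows import IsolationWindow, WindowScheme

__all__ = [
    "ReportReadResult",
    "write_precursor_report",
    "read_precursor_report",
    "write_site_table",
    "read_site_table",
    "write_window_list",
    "read_window_list",
    "write_scan_cycles",
    "read_scan_cycles",
]

REPORT_COLUMNS = [
    "protein_accession",
    "modified_sequence",
    "charge",
    "positions",
    "residues",
    "localization_probabilities",
    "sample",
    "intensity",
]


@dataclass
class ReportReadResult:
    """Parsed precursor records plus the malformed rows that were routed
    to the error report."""

    records: list[PrecursorRecord]
    errors: pd.DataFrame


def write_precursor_report(
    records: list[PrecursorRecord], path
) -> None:
    """Write records in the long search-export format (one row per
    precursor-sample; missing cells get an empty intensity field)."""
    rows = []
    for rec in records:
        accession = ";".join((rec.protein_accession,) + rec.other_accessions)
        positions = ";".join(str(s.position) for s in rec.sites)
        residues = ";".join(s.residue for s in rec.sites)
        probs = ";".join(
            repr(float(s.localization_probability)) for s in rec.sites
        )
        for sample in sorted(rec.abundances):
            v = rec.abundances[sample]
            rows.append(
                {
                    "protein_accession": accession,
                    "modified_sequence": rec.modified_sequence,
                    "charge": rec.charge,
                    "positions": positions,
                    "residues": residues,
                    "localization_probabilities": probs,
                    "sample": sample,
                    "intensity": "" if v is None or math.isnan(v) else repr(float(v)),
                }
            )
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def _parse_record_rows(key, rows) -> PrecursorRecord:
    accession, modified_sequence, charge, positions, residues, probs = key
    accessions = accession.split(";")
    sites = tuple(
        SiteAssignment(
            position=int(pos), residue=res, localization_probability=float(pr)
        )
        for pos, res, pr in zip(
            positions.split(";"), residues.split(";"), probs.split(";")
        )
    )
    abundances: dict[str, float] = {}
    for row in rows:
        raw = row["intensity"]
        if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
            abundances[str(row["sample"])] = float("nan")
        else:
            v = float(raw)
            abundances[str(row["sample"])] = v if v > 0 else float("nan")
    return PrecursorRecord(
        modified_sequence=modified_sequence,
        protein_accession=accessions[0],
        charge=int(charge),
        sites=sites,
        abundances=abundances,
        other_accessions=tuple(accessions[1:]),
    )


def read_precursor_report(path) -> ReportReadResult:
    """Read a long-format precursor report.

    Rows violating the type invariants (probability outside [0, 1],
    position < 1, unknown residue, unparsable numbers) are collected into
    the error report instead of aborting the read.  Zero intensities are
    treated as missing.  Missing mandatory columns reject the file.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in REPORT_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValueError(
            f"precursor report is missing mandatory columns: {missing_cols}"
        )
    key_cols = REPORT_COLUMNS[:6]
    grouped: dict[tuple, list[dict]] = {}
    errors = []
    for i, row in frame.iterrows():
        try:
            key = tuple(row[c] for c in key_cols)
            # Validate eagerly so the bad row, not the whole record, fails.
            _parse_record_rows(key, [row.to_dict()])
            grouped.setdefault(key, []).append(row.to_dict())
        except (ValueError, TypeError) as exc:
            errors.append({**row.to_dict(), "error": str(exc)})
    records = [_parse_record_rows(key, rows) for key, rows in grouped.items()]
    return ReportReadResult(
        records=records,
        errors=pd.DataFrame(errors, columns=REPORT_COLUMNS + ["error"]),
    )


def write_site_table(table: SiteTable, path) -> None:
    """Write a site table as TSV with a ``#`` header block holding the
    scale and the sample-group design."""
    with open(path, "w") as fh:
        fh.write(f"# scale={table.scale}\n")
        if table.groups is not None:
            for sample in table.samples:
                fh.write(f"# group\t{sample}\t{table.groups[sample]}\n")
        out = table.abundance.reset_index()
        if table.provenance is not None:
            out.insert(3, "n_precursors", table.provenance.to_numpy())
        out.to_csv(fh, sep="\t", index=False)


def read_site_table(path) -> SiteTable:
    scale = "raw"
    groups: dict[str, str] = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if body.startswith("scale="):
                scale = body.split("=", 1)[1]
            elif body.startswith("group\t"):
                _, sample, group = body.split("\t")
                groups[sample] = group
    frame = pd.read_csv(path, sep="\t", skiprows=header_lines)
    frame["position"] = frame["position"].astype(int)
    provenance = None
    if "n_precursors" in frame.columns:
        provenance = frame.pop("n_precursors")
    frame = frame.set_index(["protein_accession", "residue", "position"])
    if provenance is not None:
        provenance = pd.Series(
            provenance.to_numpy(), index=frame.index, name="n_precursors"
        )
    return SiteTable(
        abundance=frame.astype(float),
        groups=pd.Series(groups, name="group") if groups else None,
        scale=scale,
        provenance=provenance,
    )


def write_window_list(scheme: WindowScheme, path) -> None:
    """Export a scheme as an instrument-style window list (CSV).

    Columns ``center_mz``, ``width_mz``, ``phase`` ordered as acquired
    (phase a grid, then phase b), values printed with 6 decimals.  A ``#``
    header block records the scheme geometry so the file round-trips.
    """
    with open(path, "w") as fh:
        fh.write(
            f"# span_lower={scheme.span_lower!r} "
            f"span_upper={scheme.span_upper!r} "
            f"window_width={scheme.window_width!r} "
            f"aligned={int(scheme.aligned_to_forbidden_zones)}\n"
        )
        fh.write("center_mz,width_mz,phase\n")
        for phase, windows in (("a", scheme.phase_a), ("b", scheme.phase_b)):
            for win in windows:
                fh.write(f"{win.center:.6f},{win.width:.6f},{phase}\n")


def read_window_list(path) -> WindowScheme:
    with open(path) as fh:
        meta_line = fh.readline()
        if not meta_line.startswith("#"):
            raise ValueError("window list is missing its geometry header")
        meta = dict(
            item.split("=") for item in meta_line[1:].strip().split(" ")
        )
        frame = pd.read_csv(fh)
    phases: dict[str, list[IsolationWindow]] = {"a": [], "b": []}
    for _, row in frame.iterrows():
        half = row["width_mz"] / 2.0
        phases[row["phase"]].append(
            IsolationWindow(row["center_mz"] - half, row["center_mz"] + half)
        )
    return WindowScheme(
        span_lower=float(meta["span_lower"]),
        span_upper=float(meta["span_upper"]),
        window_width=float(meta["window_width"]),
        phase_a=tuple(sorted(phases["a"], key=lambda w: w.lower)),
        phase_b=tuple(sorted(phases["b"], key=lambda w: w.lower)),
        aligned_to_forbidden_zones=bool(int(meta["aligned"])),
    )


def write_scan_cycles(cycles: list[ScanCycle], path) -> None:
    """Serialize scan cycles as TSV: cycle, phase, window bounds, fragment
    channel, intensity."""
    rows = []
    for cycle in cycles:
        for scan in cycle.scans:
            if not scan.observed:
                rows.append(
                    {
                        "cycle": cycle.cycle_index,
                        "phase": scan.phase,
                        "window_lower": repr(float(scan.window.lower)),
                        "window_upper": repr(float(scan.window.upper)),
                        "fragment_channel": "",
                        "intensity": "",
                    }
                )
            for channel, intensity in sorted(scan.observed.items()):
                rows.append(
                    {
                        "cycle": cycle.cycle_index,
                        "phase": scan.phase,
                        "window_lower": repr(float(scan.window.lower)),
                        "window_upper": repr(float(scan.window.upper)),
                        "fragment_channel": channel,
                        "intensity": repr(float(intensity)),
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_scan_cycles(path) -> list[ScanCycle]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cycles: dict[int, dict[tuple, dict]] = {}
    for _, row in frame.iterrows():
        c = int(row["cycle"])
        key = (row["phase"], float(row["window_lower"]), float(row["window_upper"]))
        scan = cycles.setdefault(c, {}).setdefault(key, {})
        if row["fragment_channel"] != "":
            scan[row["fragment_channel"]] = float(row["intensity"])
    out = []
    for c in sorted(cycles):
        scans = tuple(
            Scan(
                window=IsolationWindow(lower, upper),
                phase=phase,
                observed=observed,
            )
            for (phase, lower, upper), observed in cycles[c].items()
        )
        out.append(ScanCycle(cycle_index=c, scans=scans))
    return out
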