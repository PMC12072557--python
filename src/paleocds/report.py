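"""Assemble per-sample substitution tables into the final report bundle:
damage summaries, the cross-sample presence/absence matrix used to order
mutations on the tree, and optional residue -> structural-region labels
from a user-supplied interval table (no 3-D computation is attempted).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .seqio import read_tsv_substitutions
from .substitutions import (
    SubstitutionRecord,
    comparative_report,
    damage_report,
    parse_c_notation,
)


class MissingInputError(FileNotFoundError):
    """One or more report inputs are absent."""


def read_region_annotations(path) -> pd.DataFrame:
    """Residue-interval table: columns start, end, label (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    required = {"start", "end", "label"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    return df


def region_for_residue(regions: Optional[pd.DataFrame], residue: int) -> str:
    if regions is None:
        return ""
    hits = regions[(regions["start"] <= residue) & (residue <= regions["end"])]
    return "; ".join(hits["label"]) if len(hits) else ""


def _records_from_tsv(path) -> list[SubstitutionRecord]:
    return [parse_c_notation(row["substitution"]) for row in read_tsv_substitutions(path)]


def run_report(
    sample_tables: dict[str, str | Path],
    control_table: Optional[str | Path] = None,
    control_length: int = 1,
    target_length: int = 1,
    region_table: Optional[str | Path] = None,
    site_annotations: Optional[dict[str, str]] = None,
    out_dir: str | Path = ".",
) -> dict:
    """Merge per-sample substitution TSVs into the report bundle.

    Writes ``comparative_sites.tsv`` and ``report_summary.json`` under
    ``out_dir`` and returns the summary dict. Raises
    :class:`MissingInputError` listing every absent input file.
    """
    if not sample_tables:
        raise ValueError("empty sample set")
    paths = dict(sample_tables)
    if control_table is not None:
        paths["__control__"] = control_table
    missing = [str(p) for p in paths.values() if not Path(p).exists()]
    if missing:
        raise MissingInputError(f"missing input files: {', '.join(sorted(missing))}")

    per_sample = {name: _records_from_tsv(path) for name, path in sample_tables.items()}
    regions = read_region_annotations(region_table) if region_table else None

    matrix = comparative_report(per_sample, site_annotations=site_annotations)
    if regions is not None and not matrix.empty:
        matrix["region"] = [
            region_for_residue(regions, (pos - 1) // 3 + 1) for pos in matrix["cds_pos"]
        ]

    summary: dict = {"samples": {}}
    for name, records in per_sample.items():
        rep = damage_report(records, max(control_length, 1), max(target_length, 1))
        summary["samples"][name] = {
            "n_total": rep.n_total,
            "n_ts1": rep.n_ts1,
            "n_ts2": rep.n_ts2,
            "n_none": rep.n_none,
            "deamination_consistent": f"{rep.n_ts} of {rep.n_total}",
        }
    if control_table is not None:
        control_records = _records_from_tsv(control_table)
        rep = damage_report(control_records, control_length, target_length)
        summary["control"] = {
            "n_total": rep.n_total,
            "n_ts": rep.n_ts,
            "deamination_consistent": f"{rep.n_ts} of {rep.n_total}",
            "expected_damage_in_target": rep.expected_damage_in_target,
        }
    if not matrix.empty:
        summary["shared_by_all_sites"] = sorted(
            matrix.index[matrix["shared_by_all"]].tolist()
        )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(out / "comparative_sites.tsv", sep="\t")
    (out / "report_summary.json").write_text(json.dumps(summary, indent=2))
    return summary
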