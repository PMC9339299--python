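"""Tetrad-table file format and analysis configuration.

Tetrad tables are tab-separated text with a mandatory versioned header
comment, one row per spore (four rows per tetrad)::

    # tetrad-table v1
    # seed=11 n=2 ...
    strain  tetrad_id  spore  viable  mating  HIS4  CEN3  ...
    sim     sim-1      1      1       a       P     Q     ...

Alleles are coded ``P``/``Q`` (the two parental alleles) or ``-``
(missing); dead spores are all ``-``.  Mating is ``a``, ``alpha``, ``non``
(nonmater) or ``nd`` (not determined).  Concrete allele names belong in
the marker-map configuration, not in data files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .model import (
    ALLELE_CODES,
    MATING_CODES,
    MISSING,
    MarkerMap,
    Spore,
    Tetrad,
    TetradError,
)

FORMAT_LINE = "# tetrad-table v1"
_FIXED_COLUMNS = ("strain", "tetrad_id", "spore", "viable", "mating")


def write_tetrad_table(
    path: str | Path,
    tetrads: Sequence[Tetrad],
    marker_map: MarkerMap,
    provenance: Mapping[str, object] | None = None,
) -> None:
    path = Path(path)
    markers = marker_map.marker_names
    lines = [FORMAT_LINE]
    if provenance:
        lines.append("# " + " ".join(f"{k}={v}" for k, v in provenance.items()))
    lines.append("\t".join(_FIXED_COLUMNS + markers))
    for tet in tetrads:
        for idx, spore in enumerate(tet.spores, start=1):
            row = [
                tet.strain, tet.tetrad_id, str(idx),
                "1" if spore.viable else "0", spore.mating,
            ]
            row.extend(spore.alleles.get(m, MISSING) for m in markers)
            lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_tetrad_table(
    path: str | Path, marker_map: MarkerMap | None = None
) -> list[Tetrad]:
    """Read and validate a tetrad table.

    Hard errors (with line numbers where applicable): missing or wrong
    format header, tetrads without exactly 4 spore rows, unknown allele or
    mating codes, and marker columns that do not match ``marker_map`` when
    one is given.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != FORMAT_LINE:
        raise TetradError(f"{path}: missing format header {FORMAT_LINE!r}")
    body = [
        (i + 1, ln) for i, ln in enumerate(lines)
        if ln.strip() and not ln.startswith("#")
    ]
    if not body:
        raise TetradError(f"{path}: no data rows")
    header = body[0][1].split("\t")
    if tuple(header[: len(_FIXED_COLUMNS)]) != _FIXED_COLUMNS:
        raise TetradError(f"{path}: bad column header, expected {_FIXED_COLUMNS}")
    markers = tuple(header[len(_FIXED_COLUMNS):])
    if marker_map is not None and markers != marker_map.marker_names:
        raise TetradError(
            f"{path}: marker columns {markers} do not match map "
            f"{marker_map.marker_names}"
        )
    grouped: dict[tuple[str, str], list[tuple[int, Spore]]] = {}
    order: list[tuple[str, str]] = []
    for lineno, ln in body[1:]:
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise TetradError(f"{path}:{lineno}: expected {len(header)} fields")
        strain, tetrad_id, spore_idx, viable, mating = fields[:5]
        if viable not in ("0", "1"):
            raise TetradError(f"{path}:{lineno}: viable must be 0 or 1")
        if mating not in MATING_CODES:
            raise TetradError(f"{path}:{lineno}: unknown mating code {mating!r}")
        alleles = {}
        for m, a in zip(markers, fields[5:]):
            if a not in ALLELE_CODES:
                raise TetradError(f"{path}:{lineno}: unknown allele code {a!r}")
            alleles[m] = a
        key = (strain, tetrad_id)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        try:
            grouped[key].append((int(spore_idx), Spore(viable == "1", mating, alleles)))
        except TetradError as exc:
            raise TetradError(f"{path}:{lineno}: {exc}") from exc
    tetrads = []
    for strain, tetrad_id in order:
        rows = grouped[(strain, tetrad_id)]
        if len(rows) != 4:
            raise TetradError(
                f"{path}: tetrad {tetrad_id!r} (strain {strain!r}) has "
                f"{len(rows)} spore rows, expected 4"
            )
        spores = tuple(s for _, s in sorted(rows, key=lambda r: r[0]))
        tetrads.append(Tetrad(strain=strain, tetrad_id=tetrad_id, spores=spores))
    return tetrads


@dataclass
class AnalysisConfig:
    """Validated analysis settings (marker map, reference strain, filters)."""

    marker_map: MarkerMap
    reference_strain: str = "wild_type"
    max_gene_conversions: int = 2
    mat_marker: str = "MAT"
    adjust_pvalues: bool = False
    interval_cm: dict[tuple[str, str], float] = field(default_factory=dict)


_CONFIG_KEYS = {
    "markers", "centromeres", "reference_strain", "max_gene_conversions",
    "mat_marker", "adjust_pvalues", "interval_cm",
}


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    """Load a YAML analysis configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise TetradError(f"{path}: configuration must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise TetradError(f"{path}: unknown configuration keys {sorted(unknown)}")
    if "markers" not in raw:
        raise TetradError(f"{path}: 'markers' is required")
    pairs = [(m["name"], m["chromosome"]) for m in raw["markers"]]
    marker_map = MarkerMap.from_pairs(pairs, raw.get("centromeres") or {})
    interval_cm = {}
    for key, value in (raw.get("interval_cm") or {}).items():
        a, b = key.split("-", 1)
        interval_cm[(a, b)] = float(value)
    return AnalysisConfig(
        marker_map=marker_map,
        reference_strain=raw.get("reference_strain", "wild_type"),
        max_gene_conversions=int(raw.get("max_gene_conversions", 2)),
        mat_marker=raw.get("mat_marker", "MAT"),
        adjust_pvalues=bool(raw.get("adjust_pvalues", False)),
        interval_cm=interval_cm,
    )


def _format_value(value: object, kind: str) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return "n.d."
    if kind == "cm":
        return f"{value:.1f}"
    if kind == "ratio":
        return f"{value:.2f}"
    if kind == "pct":
        return str(int(round(float(value))))
    if kind == "p":
        return f"{value:.4g}"
    return str(value)

#: report column -> presentation rounding class
_COLUMN_KINDS = {
    "cm": "cm", "se_cm": "cm", "cm_chrom": "cm",
    "ratio": "ratio", "se_ratio": "ratio", "npd_expected": "ratio",
    "gc_per_tetrad": "ratio", "rate_vs_reference": "ratio",
    "pct_wt": "pct", "pct_wt_chrom": "pct", "pct_with_gc": "pct",
    "pct_viability": "pct", "pct_chr_III": "pct", "pct_chr_VIII": "pct",
    "sporulation_pct": "pct",
    "p_freq": "p", "p_rate": "p", "p_fisher": "p",
    "ndj_pct": "ndj",
}


def format_report(df: pd.DataFrame) -> pd.DataFrame:
    """Apply the presentation rounding conventions (cM/SE to 1 decimal,
    ratios to 2, percentages to integers, NDJ% to 2 decimals, "n.d." for
    undefined cells)."""
    out = df.copy()
    for col in out.columns:
        kind = _COLUMN_KINDS.get(col)
        if kind == "ndj":
            out[col] = [
                "n.d." if v is None or pd.isna(v) else f"{v:.2f}" for v in out[col]
            ]
        elif kind:
            out[col] = [_format_value(v, kind) for v in out[col]]
    return out


def write_reports(outdir: str | Path, reports: Mapping[str, pd.DataFrame]) -> list[Path]:
    """Write each report as a formatted TSV plus a full-precision JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in reports.items():
        tsv = outdir / f"{name}.tsv"
        format_report(df).to_csv(tsv, sep="\t", index=False)
        js = outdir / f"{name}_full.json"
        js.write_text(
            json.dumps(
                json.loads(df.to_json(orient="records")), indent=1, allow_nan=True
            )
            + "\n"
        )
        written.extend([tsv, js])
    return written
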