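"""Dataset readers/writers with schema validation and column mapping.

The canonical comparison schema is one CSV/XLSX row per experimental
comparison.  Supplementary files from the literature rarely use canonical
headers, so every reader accepts a :class:`ColumnMap` that renames source
columns to canonical fields without editing the files.  Rows failing
validation (SD <= 0, n < 2, proportion outside [0, 1], ...) are rejected
with a per-row diagnostic -- never dropped silently.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .effect_sizes import ComparisonRecord, EffectSize, Polarity
from .prioritize import GridLayer
from .surveys import SurveyRecord

logger = logging.getLogger("birdcrop")

COMPARISON_FIELDS = (
    "study_id", "comparison_id", "mean_treatment", "mean_control",
    "sd_treatment", "sd_control", "n_treatment", "n_control",
    "outcome_polarity",
)
SURVEY_FIELDS = (
    "survey_id", "n_respondents", "outcome_kind", "proportion",
    "income", "bird_group", "stakeholder", "climate",
)

#: moderator columns picked up automatically when present
KNOWN_MODERATORS = (
    "stem_type", "food_type", "climate", "insecticide", "herbicide",
    "focal_animal", "crop", "stage", "category", "measure", "regional_richness",
)


@dataclasses.dataclass
class ColumnMap:
    """Canonical field name -> source column name."""

    mapping: Mapping[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        targets = list(self.mapping.values())
        if len(set(targets)) != len(targets):
            raise ValueError("duplicate source columns in column map")

    def source(self, field: str) -> str:
        return self.mapping.get(field, field)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColumnMap":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})


@dataclasses.dataclass
class RowIssue:
    row: int
    reason: str


@dataclasses.dataclass
class ComparisonData:
    """Validated comparison records plus any precomputed effect sizes."""

    records: list[ComparisonRecord]
    precomputed: list[EffectSize]
    rejects: list[RowIssue]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def _norm_token(v: Any) -> Any:
    """Moderator values are normalized to lowercase tokens at read time."""
    if isinstance(v, str):
        return v.strip().lower()
    return v


def _is_missing(v: Any) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def read_comparisons(path: str | Path, colmap: ColumnMap | None = None) -> ComparisonData:
    """Read a comparison dataset (raw summaries and/or precomputed g, v_g).

    A row with finite ``g`` and ``v_g`` columns is taken as a precomputed
    effect size; otherwise the raw summary columns are required.
    """
    colmap = colmap or ColumnMap()
    df = _read_table(path)
    for field in ("study_id", "comparison_id"):
        if colmap.source(field) not in df.columns:
            raise ValueError(f"missing mapped column {colmap.source(field)!r} for {field!r}")
    records: list[ComparisonRecord] = []
    precomputed: list[EffectSize] = []
    rejects: list[RowIssue] = []
    seen: set[tuple[str, str]] = set()
    has_g = colmap.source("g") in df.columns and colmap.source("v_g") in df.columns
    mod_cols = [m for m in KNOWN_MODERATORS if colmap.source(m) in df.columns]
    for i, row in df.iterrows():
        sid = str(row[colmap.source("study_id")])
        cid = str(row[colmap.source("comparison_id")])
        key = (sid, cid)
        if key in seen:
            rejects.append(RowIssue(int(i), f"duplicate (study_id, comparison_id) {key}"))
            continue
        seen.add(key)
        mods = {m: _norm_token(row[colmap.source(m)]) for m in mod_cols}
        mods = {k: v for k, v in mods.items() if not _is_missing(v)}
        if has_g and not _is_missing(row[colmap.source("g")]) and not _is_missing(row[colmap.source("v_g")]):
            try:
                precomputed.append(
                    EffectSize(
                        g=float(row[colmap.source("g")]),
                        v_g=float(row[colmap.source("v_g")]),
                        study_id=sid, comparison_id=cid, moderators=mods,
                    )
                )
            except ValueError as exc:
                rejects.append(RowIssue(int(i), str(exc)))
            continue
        try:
            nt = int(row[colmap.source("n_treatment")])
            nc = int(row[colmap.source("n_control")])
            if nt < 2:
                raise ValueError("n_treatment < 2")
            if nc < 2:
                raise ValueError("n_control < 2")
            pol = row.get(colmap.source("outcome_polarity"), "gain")
            if _is_missing(pol):
                pol = "gain"
            records.append(
                ComparisonRecord(
                    study_id=sid,
                    comparison_id=cid,
                    mean_treatment=float(row[colmap.source("mean_treatment")]),
                    mean_control=float(row[colmap.source("mean_control")]),
                    sd_treatment=float(row[colmap.source("sd_treatment")]),
                    sd_control=float(row[colmap.source("sd_control")]),
                    n_treatment=nt,
                    n_control=nc,
                    outcome_polarity=Polarity(_norm_token(pol)),
                    moderators=mods,
                )
            )
        except (ValueError, KeyError, TypeError) as exc:
            rejects.append(RowIssue(int(i), str(exc)))
    for issue in rejects:
        logger.warning("row %d rejected: %s", issue.row, issue.reason)
    if not records and not precomputed:
        raise ValueError(f"no valid rows in {path}")
    return ComparisonData(records=records, precomputed=precomputed, rejects=rejects)


def write_effects(effects: Sequence[EffectSize], path: str | Path) -> None:
    """Effect-size CSV: study_id, comparison_id, g, v_g, moderators."""
    mod_names: list[str] = []
    for e in effects:
        for m in e.moderators:
            if m not in mod_names:
                mod_names.append(m)
    rows = [
        {
            "study_id": e.study_id,
            "comparison_id": e.comparison_id,
            "g": e.g,
            "v_g": e.v_g,
            **{m: e.moderators.get(m) for m in mod_names},
        }
        for e in effects
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_effects(path: str | Path) -> list[EffectSize]:
    """Read an effect-size CSV written by :func:`write_effects`."""
    df = pd.read_csv(path)
    mod_cols = [c for c in df.columns if c not in ("study_id", "comparison_id", "g", "v_g")]
    out = []
    for _, row in df.iterrows():
        mods = {m: _norm_token(row[m]) for m in mod_cols if not _is_missing(row[m])}
        out.append(
            EffectSize(
                g=float(row["g"]), v_g=float(row["v_g"]),
                study_id=str(row["study_id"]), comparison_id=str(row["comparison_id"]),
                moderators=mods,
            )
        )
    return out


def write_comparisons(records: Sequence[ComparisonRecord], path: str | Path) -> None:
    mod_names: list[str] = []
    for r in records:
        for m in r.moderators:
            if m not in mod_names:
                mod_names.append(m)
    rows = [
        {
            **{f: getattr(r, f) for f in COMPARISON_FIELDS if f != "outcome_polarity"},
            "outcome_polarity": r.outcome_polarity.value,
            **{m: r.moderators.get(m) for m in mod_names},
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclasses.dataclass
class SurveyData:
    records: list[SurveyRecord]
    rejects: list[RowIssue]


def read_surveys(path: str | Path, colmap: ColumnMap | None = None) -> SurveyData:
    colmap = colmap or ColumnMap()
    df = _read_table(path)
    records: list[SurveyRecord] = []
    rejects: list[RowIssue] = []
    for i, row in df.iterrows():
        try:
            prop = float(row[colmap.source("proportion")])
            if not (0.0 <= prop <= 1.0):
                raise ValueError(f"proportion {prop} outside [0, 1]")
            kwargs = {}
            for f in ("income", "bird_group", "stakeholder", "climate"):
                v = row.get(colmap.source(f))
                kwargs[f] = None if _is_missing(v) else str(_norm_token(v))
            records.append(
                SurveyRecord(
                    survey_id=str(row[colmap.source("survey_id")]),
                    n_respondents=int(row[colmap.source("n_respondents")]),
                    outcome_kind=str(_norm_token(row[colmap.source("outcome_kind")])),
                    proportion=prop,
                    **kwargs,
                )
            )
        except (ValueError, KeyError, TypeError) as exc:
            rejects.append(RowIssue(int(i), str(exc)))
    for issue in rejects:
        logger.warning("row %d rejected: %s", issue.row, issue.reason)
    if not records:
        raise ValueError(f"no valid rows in {path}")
    return SurveyData(records=records, rejects=rejects)


def write_surveys(records: Sequence[SurveyRecord], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(path, index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Period/count table (one row per period, one count column per topic)."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ValueError("counts table needs a period column plus at least one count column")
    return df


# ---------------------------------------------------------------------------
# ESRI ASCII grids


def read_ascii_grid(path: str | Path) -> GridLayer:
    """Read an ESRI ASCII grid (cell-center registration)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                "yllcenter", "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    values = np.array(rows, dtype=float)
    if "ncols" in header and values.shape != (int(header["nrows"]), int(header["ncols"])):
        values = values.reshape(int(header["nrows"]), int(header["ncols"]))
    nodata = header.get("nodata_value")
    mask = np.isclose(values, nodata) if nodata is not None else None
    cs = header.get("cellsize", 1.0)
    xll = header.get("xllcorner", header.get("xllcenter", 0.0))
    yll = header.get("yllcorner", header.get("yllcenter", 0.0))
    # origin = center of the top-left cell
    origin = (xll + cs / 2.0, yll + cs * values.shape[0] - cs / 2.0)
    vals = values.copy()
    if mask is not None:
        vals[mask] = np.nan
    return GridLayer(vals, mask=mask, origin=origin, cellsize=cs)


def write_ascii_grid(layer: GridLayer, path: str | Path, nodata: float = -9999.0) -> None:
    nrows, ncols = layer.shape
    xll = layer.origin[0] - layer.cellsize / 2.0
    yll = layer.origin[1] + layer.cellsize / 2.0 - layer.cellsize * nrows
    vals = np.where(layer.mask, nodata, layer.values)
    with open(path, "w") as fh:
        fh.write(
            f"ncols {ncols}\nnrows {nrows}\n"
            f"xllcorner {xll:g}\nyllcorner {yll:g}\n"
            f"cellsize {layer.cellsize:g}\nNODATA_value {nodata:g}\n"
        )
        for r in range(nrows):
            fh.write(" ".join(f"{v:.10g}" for v in vals[r]) + "\n")


# ---------------------------------------------------------------------------
# run configuration


_RUNCONFIG_KEYS = {
    "seed", "alpha", "ci_type", "averaging", "trimfill_side",
    "random_structure", "output_dir", "log_level",
}


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    alpha: float = 0.05
    ci_type: str = "wald"
    averaging: str = "full"
    trimfill_side: str = "auto"
    random_structure: str = "study/comparison"
    output_dir: str = "."
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _RUNCONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def dump_json(obj: Any, path: str | Path) -> None:
    def default(o: Any):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
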