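"""CTC gating, morphotype classification and per-patient enumeration.

A circulating tumor cell is a nucleated cell that stains for the tumor
lineage marker and not for the pan-leukocyte marker CD45:
DAPI-positive / tumor-marker (AF488)-positive / CD45 (AF647)-negative.
Gated tumor cells are then assigned exactly one morphotype:

* ``cluster_member`` — part of a connected group of >= 2 touching tumor cells;
* ``multinucleated`` — a single body with >= 2 nuclei;
* ``large``          — equivalent diameter above 25 um;
* ``classical``      — the roundish 8-20 um phenotype (the diameter band up
  to 25 um falls here, since "large" is defined only by exceeding 25 um);
* ``sub_size``       — gated cells below 8 um, excluded from enumeration.

Cells failing the gate are ``non_tumor``.  CD74/CD44 expression is
categorised from the mean grey value: negative (<= 10), weak (10 < v < 21),
strong (>= 21).  Per-patient enumeration counts CTCs per 7.5 mL sample and
derives positivity at both reported cut-offs (>= 1 and >= 2 CTCs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "GateConfig",
    "GateConfigError",
    "gate_ctcs",
    "classify_morphotype",
    "categorize_expression",
    "classify_cells",
    "enumerate_patient",
    "enumerate_cohort",
    "PatientRecord",
]

MORPHOTYPES = ("classical", "large", "multinucleated", "cluster_member", "sub_size", "non_tumor")


class GateConfigError(ValueError):
    """Raised when gating thresholds are unset or inconsistent."""


@dataclass(frozen=True)
class GateConfig:
    """Thresholds for gating, morphotyping and expression categories.

    All intensity thresholds are on the mean-grey-value scale.  The
    expression anchors (negative <= 10, strong >= 21) double as default
    gating levels for the tumor marker and DAPI; the CD45-low cut reuses the
    negative anchor.
    """

    tumor_marker_min: float = 21.0
    cd45_max: float = 10.0
    dapi_min: float = 21.0
    classical_diameter_range: tuple[float, float] = (8.0, 20.0)
    large_diameter_min: float = 25.0
    expression_negative_max: float = 10.0
    expression_strong_min: float = 21.0

    def validate(self) -> None:
        for name in ("tumor_marker_min", "cd45_max", "dapi_min"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise GateConfigError(f"gating threshold {name} is unset")
        lo, hi = self.classical_diameter_range
        if not lo < hi:
            raise GateConfigError("classical diameter range must have lower < upper")
        if not self.expression_negative_max < self.expression_strong_min:
            raise GateConfigError("expression category anchors must satisfy negative < strong")


@dataclass
class PatientRecord:
    """Per-patient enumeration result (one 7.5 mL sample)."""

    patient_id: str
    entity: str
    ctc_count: int
    morphotype_counts: dict[str, int]
    ctc_positive_ge1: bool
    ctc_positive_ge2: bool
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------

def gate_ctcs(cells: pd.DataFrame, cfg: GateConfig = GateConfig()) -> pd.DataFrame:
    """Set ``is_ctc``: DAPI+, tumor-marker (AF488)+, CD45 (AF647)-.

    Expects mean-grey-value columns ``mean_DAPI``, ``mean_AF488_tumor`` and
    ``mean_AF647_CD45``.  Returns a copy.
    """
    cfg.validate()
    for col in ("mean_DAPI", "mean_AF488_tumor", "mean_AF647_CD45"):
        if col not in cells.columns:
            raise KeyError(f"cells table lacks column {col!r}")
    out = cells.copy()
    out["is_ctc"] = (
        (out["mean_DAPI"] >= cfg.dapi_min)
        & (out["mean_AF488_tumor"] >= cfg.tumor_marker_min)
        & (out["mean_AF647_CD45"] <= cfg.cd45_max)
    )
    return out


# ---------------------------------------------------------------------------
# morphotypes
# ---------------------------------------------------------------------------

def _connected_components(edges: dict[str, set[str]]) -> list[set[str]]:
    seen: set[str] = set()
    comps = []
    for start in edges:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(edges.get(node, ()))
        seen |= comp
        comps.append(comp)
    return comps


def classify_morphotype(cells: pd.DataFrame, cfg: GateConfig = GateConfig()) -> pd.DataFrame:
    """Assign each gated cell one morphotype (cluster > multinucleated >
    large > classical precedence) and a shared ``cluster_id`` per cluster.

    Requires ``is_ctc`` (from :func:`gate_ctcs`), ``equivalent_diameter_um``,
    ``n_nuclei`` and ``neighbor_ids`` (``;``-joined string or list).
    """
    cfg.validate()
    out = cells.copy()
    out["morphotype"] = "non_tumor"
    out["cluster_id"] = None
    out["sub_size"] = False

    is_ctc = out["is_ctc"].astype(bool)
    ctc_ids = set(out.loc[is_ctc, "cell_id"])

    def neigh_list(v):
        if isinstance(v, str):
            return [x for x in v.split(";") if x]
        if isinstance(v, (list, tuple)):
            return list(v)
        return []

    # tumor-tumor adjacency graph -> clusters
    edges: dict[str, set[str]] = {cid: set() for cid in ctc_ids}
    for _, row in out.loc[is_ctc].iterrows():
        for nb in neigh_list(row.get("neighbor_ids", "")):
            if nb in ctc_ids:
                edges[row["cell_id"]].add(nb)
                edges[nb].add(row["cell_id"])

    cluster_members: set[str] = set()
    cluster_of: dict[str, str] = {}
    k = 0
    for comp in _connected_components(edges):
        if len(comp) >= 2:
            cl_id = f"cl{k:02d}"
            k += 1
            for cid in comp:
                cluster_of[cid] = cl_id
            cluster_members |= comp

    lo, _ = cfg.classical_diameter_range
    for i in out.index[is_ctc]:
        cid = out.at[i, "cell_id"]
        diam = out.at[i, "equivalent_diameter_um"]
        if cid in cluster_members:
            out.at[i, "morphotype"] = "cluster_member"
            out.at[i, "cluster_id"] = cluster_of[cid]
        elif out.at[i, "n_nuclei"] >= 2:
            out.at[i, "morphotype"] = "multinucleated"
        elif diam > cfg.large_diameter_min:
            out.at[i, "morphotype"] = "large"
        elif diam >= lo:
            out.at[i, "morphotype"] = "classical"
        else:
            out.at[i, "morphotype"] = "sub_size"
            out.at[i, "sub_size"] = True
    return out


# ---------------------------------------------------------------------------
# expression categories
# ---------------------------------------------------------------------------

def expression_category(mean_grey_value: float, cfg: GateConfig = GateConfig()) -> str:
    """negative (<= 10), weak (10 < v < 21) or strong (>= 21)."""
    if mean_grey_value <= cfg.expression_negative_max:
        return "negative"
    if mean_grey_value < cfg.expression_strong_min:
        return "weak"
    return "strong"


def categorize_expression(cells: pd.DataFrame, cfg: GateConfig = GateConfig()) -> pd.DataFrame:
    """Add ``cd74_category`` and ``cd44_category`` from the marker means."""
    cfg.validate()
    out = cells.copy()
    for marker, col in (("cd74", "mean_CD74"), ("cd44", "mean_CD44")):
        if col not in out.columns:
            raise KeyError(f"cells table lacks column {col!r}")
        out[f"{marker}_category"] = out[col].map(lambda v: expression_category(v, cfg))
    return out


def classify_cells(cells: pd.DataFrame, cfg: GateConfig = GateConfig()) -> pd.DataFrame:
    """Gate, morphotype and categorise in one pass."""
    return categorize_expression(classify_morphotype(gate_ctcs(cells, cfg), cfg), cfg)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def enumerate_patient(
    cells: pd.DataFrame,
    patient_id: str,
    entity: str = "",
    metadata: Optional[dict] = None,
) -> PatientRecord:
    """Count CTCs per morphotype for one patient sample.

    Border-touching and sub-size cells are excluded from the count; both
    positivity cut-offs (>= 1 and >= 2 CTCs per 7.5 mL) are derived.
    """
    df = cells
    if "on_border" in df.columns:
        df = df[~df["on_border"].astype(bool)]
    countable = df[df["is_ctc"].astype(bool) & ~df["sub_size"].astype(bool)]
    morpho = {m: int((countable["morphotype"] == m).sum())
              for m in ("classical", "large", "multinucleated", "cluster_member")}
    morpho["sub_size"] = int((df["is_ctc"].astype(bool) & df["sub_size"].astype(bool)).sum())
    morpho["non_tumor"] = int((~df["is_ctc"].astype(bool)).sum())
    count = int(len(countable))
    return PatientRecord(
        patient_id=patient_id,
        entity=entity,
        ctc_count=count,
        morphotype_counts=morpho,
        ctc_positive_ge1=count >= 1,
        ctc_positive_ge2=count >= 2,
        metadata=dict(metadata or {}),
    )


def enumerate_cohort(
    cells: pd.DataFrame,
    patient_meta: Optional[pd.DataFrame] = None,
    patient_col: str = "patient_id",
) -> pd.DataFrame:
    """Enumerate every patient in a classified multi-patient cell table.

    Raises on duplicate patient ids in ``patient_meta``.
    """
    if patient_meta is not None and patient_meta[patient_col].duplicated().any():
        dups = patient_meta.loc[patient_meta[patient_col].duplicated(), patient_col]
        raise ValueError(f"duplicate patient_id(s): {sorted(set(dups))}")
    meta_by_id = {}
    if patient_meta is not None:
        meta_by_id = {r[patient_col]: r.to_dict() for _, r in patient_meta.iterrows()}
    rows = []
    for pid, grp in cells.groupby(patient_col, sort=True):
        meta = meta_by_id.get(pid, {})
        rec = enumerate_patient(grp, pid, entity=str(meta.get("entity", "")), metadata=meta)
        row = {
            "patient_id": rec.patient_id,
            "entity": rec.entity,
            "ctc_count": rec.ctc_count,
            "ctc_positive_ge1": rec.ctc_positive_ge1,
            "ctc_positive_ge2": rec.ctc_positive_ge2,
        }
        for m, v in rec.morphotype_counts.items():
            row[f"n_{m}"] = v
        for key, val in rec.metadata.items():
            row.setdefault(key, val)
        rows.append(row)
    return pd.DataFrame(rows)
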