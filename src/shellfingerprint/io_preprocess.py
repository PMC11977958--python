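"""Reading and preprocessing of larval-shell element:Ca ratio tables.

LA-ICP-MS output arrives as one row per ablation line with element:Ca ratios
in µmol mol⁻¹ (relative to ⁴²Ca) plus sample metadata.  The preprocessing
chain mirrors standard practice in shell-chemistry fingerprinting:

1. drop elements that sit below the limit of detection (LOD) in most broods,
2. average the replicate ablations of each brood into one signature,
3. natural-log transform and standardize (mean 0, unit variance),
4. remove multivariate outliers on the log scale.

Below-LOD cells are carried as explicit flags (NaN value + boolean mask),
never silently zeroed or imputed; an element leaves the analysis only as a
whole column via :func:`drop_low_detection_elements`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "META_COLUMNS",
    "ElementRatioTable",
    "SignatureSet",
    "TransformParams",
    "OutlierReport",
    "read_signature_table",
    "write_signature_set",
    "drop_low_detection_elements",
    "average_replicate_ablations",
    "log_transform",
    "log_standardize",
    "inverse_log_standardize",
    "remove_outliers",
]

#: metadata columns every ablation record carries
META_COLUMNS = [
    "sample_id",
    "stage",
    "site",
    "region",
    "date",
    "method",
    "shell_portion",
    "ablation_index",
]

STAGES = {"brood", "settler"}
METHODS = {"anesthetic", "lethal", "none"}
SHELL_PORTIONS = {"brooded", "planktonic", "settled", "homogenized"}


@dataclass
class ElementRatioTable:
    """Per-ablation element:Ca measurements with metadata.

    ``data`` holds the metadata columns plus one float column per element
    (µmol mol⁻¹; NaN where the cell is below LOD), ``below_lod`` is an
    aligned boolean frame marking flagged cells.
    """

    data: pd.DataFrame
    elements: list[str]
    below_lod: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing metadata columns: {missing}")
        if self.data["sample_id"].isna().any():
            raise ValueError("every record needs a sample_id")
        dup = self.data.duplicated(subset=["sample_id", "ablation_index"])
        if dup.any():
            raise ValueError(
                "ablation_index must be unique within sample_id; duplicates at "
                f"rows {list(self.data.index[dup])[:5]}"
            )
        vals = self.data[self.elements].to_numpy(float)
        flags = self.below_lod[self.elements].to_numpy(bool)
        bad = (vals <= 0) & ~np.isnan(vals) & ~flags
        if bad.any():
            raise ValueError("non-flagged ratio values must be positive")

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.data["sample_id"]))

    def subset_stage(self, stage: str) -> "ElementRatioTable":
        keep = self.data["stage"] == stage
        return ElementRatioTable(
            self.data.loc[keep].reset_index(drop=True),
            list(self.elements),
            self.below_lod.loc[keep.to_numpy()].reset_index(drop=True),
        )

    def to_csv(self, path) -> None:
        out = self.data.copy()
        for el in self.elements:
            col = out[el].map(lambda v: "" if pd.isna(v) else repr(float(v)))
            col[self.below_lod[el].to_numpy(bool)] = "<LOD"
            out[el] = col
        out.to_csv(path, index=False)


@dataclass
class TransformParams:
    """Frozen log/standardize parameters, for leakage-free reuse."""

    center: pd.Series
    scale: pd.Series
    fit_ids: tuple[str, ...]
    log_offset_policy: str = "none"  # values must be positive; no offset used

    def __post_init__(self) -> None:
        if (self.scale <= 0).any():
            raise ValueError("scale values must be positive")

    @property
    def elements(self) -> list[str]:
        return list(self.center.index)

    def to_dict(self) -> dict:
        return {
            "center": self.center.to_dict(),
            "scale": self.scale.to_dict(),
            "fit_ids": list(self.fit_ids),
            "log_offset_policy": self.log_offset_policy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransformParams":
        return cls(
            center=pd.Series(d["center"]),
            scale=pd.Series(d["scale"]),
            fit_ids=tuple(d["fit_ids"]),
            log_offset_policy=d.get("log_offset_policy", "none"),
        )


@dataclass
class SignatureSet:
    """One signature vector per individual, with group labels.

    ``values`` is indexed by sample_id with one column per retained element;
    ``meta`` carries site/region/date/method/stage per sample.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    transform_state: str = "raw"  # raw | log | log_standardized

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("signature values must be complete (no NaN)")
        if not self.values.index.equals(self.meta.index):
            raise ValueError("values and meta must share the sample_id index")
        if self.transform_state not in {"raw", "log", "log_standardized"}:
            raise ValueError(f"unknown transform_state {self.transform_state!r}")

    @property
    def elements(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n(self) -> int:
        return len(self.values)

    def select_elements(self, elements) -> "SignatureSet":
        missing = [e for e in elements if e not in self.values.columns]
        if missing:
            raise ValueError(f"elements not in panel: {missing}")
        return SignatureSet(self.values[list(elements)].copy(), self.meta.copy(),
                            self.transform_state)

    def select_samples(self, ids) -> "SignatureSet":
        return SignatureSet(self.values.loc[ids].copy(), self.meta.loc[ids].copy(),
                            self.transform_state)

    def to_csv(self, path) -> None:
        pd.concat([self.meta, self.values], axis=1).to_csv(path, index_label="sample_id")


@dataclass
class OutlierReport:
    """Which samples an outlier rule removed, and why."""

    removed: list[str]
    details: dict[str, dict[str, float]]  # sample_id -> {element: robust z}
    rule: str

    def to_dict(self) -> dict:
        return {"removed": self.removed, "details": self.details, "rule": self.rule}


# ---------------------------------------------------------------------------
# reading / writing

_LOD_TOKENS = {"<lod", "lod", "bdl", "<dl", "nd", "n.d."}


def _parse_ratio_cell(raw):
    """Return (value, below_lod_flag) for one ratio cell."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan, True
    if isinstance(raw, str):
        s = raw.strip()
        if not s or s.lower() in _LOD_TOKENS or s.startswith("<"):
            return np.nan, True
        raw = float(s)
    return float(raw), False


def read_signature_table(path, format_spec: dict) -> ElementRatioTable:
    """Read an ablation-level ratio table from CSV or XLSX.

    ``format_spec`` keys:

    * ``format``: ``"csv"`` or ``"xlsx"``
    * ``column_map``: maps each metadata name in :data:`META_COLUMNS` to the
      file's column header (identity entries may be omitted)
    * ``elements``: maps element name (e.g. ``"Mn"``) to its column header
    * ``sheet`` (xlsx only): sheet name or index

    Below-LOD cells (``<LOD``, ``<x``, blank, ``nd``) are flagged, never
    zeroed.  Non-positive numeric ratios are flagged with a warning and
    excluded from all downstream transforms.
    """
    fmt = format_spec.get("format", "csv").lower()
    if fmt == "csv":
        raw = pd.read_csv(path, dtype=object)
    elif fmt == "xlsx":
        raw = pd.read_excel(path, sheet_name=format_spec.get("sheet", 0), dtype=object)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected csv or xlsx")

    column_map = dict(format_spec.get("column_map", {}))
    elements_map = dict(format_spec["elements"])
    unmapped = [c for c in elements_map.values() if c not in raw.columns]
    if unmapped:
        raise ValueError(f"element columns not found in file: {unmapped}")

    meta = pd.DataFrame(index=raw.index)
    for name in META_COLUMNS:
        src = column_map.get(name, name)
        meta[name] = raw[src] if src in raw.columns else None
    meta["sample_id"] = meta["sample_id"].astype(str)
    meta["ablation_index"] = pd.to_numeric(meta["ablation_index"]).astype(int)

    values = pd.DataFrame(index=raw.index, dtype=float)
    flags = pd.DataFrame(index=raw.index, dtype=bool)
    elements = list(elements_map)
    for el, col in elements_map.items():
        parsed = [_parse_ratio_cell(v) for v in raw[col]]
        v = np.array([p[0] for p in parsed], dtype=float)
        f = np.array([p[1] for p in parsed], dtype=bool)
        nonpos = (v <= 0) & ~np.isnan(v)
        if nonpos.any():
            warnings.warn(
                f"{int(nonpos.sum())} non-positive {el} ratio(s) flagged and "
                "excluded from transforms", stacklevel=2)
            v[nonpos] = np.nan
            f[nonpos] = True
        values[el] = v
        flags[el] = f

    data = pd.concat([meta, values], axis=1)
    return ElementRatioTable(data, elements, flags)


def write_signature_set(sig: SignatureSet, path) -> None:
    """Tidy CSV export of a signature set (metadata + element columns)."""
    sig.to_csv(path)


# ---------------------------------------------------------------------------
# preprocessing operations

def drop_low_detection_elements(
    table: ElementRatioTable, max_below_lod_fraction: float = 0.5
) -> tuple[ElementRatioTable, list[str]]:
    """Remove elements mostly below LOD among brood records.

    An element is dropped when its below-LOD fraction across brood-stage
    records strictly exceeds ``max_below_lod_fraction``.  Idempotent.
    """
    if not 0 <= max_below_lod_fraction <= 1:
        raise ValueError("max_below_lod_fraction must lie in [0, 1]")
    brood = table.data["stage"] == "brood"
    ref = table.below_lod.loc[brood.to_numpy()] if brood.any() else table.below_lod
    frac = ref[table.elements].mean(axis=0)
    removed = [el for el in table.elements if frac[el] > max_below_lod_fraction]
    kept = [el for el in table.elements if el not in removed]
    if not kept:
        raise ValueError("LOD filter would remove every element")
    data = table.data.drop(columns=removed)
    flags = table.below_lod[kept].copy()
    return ElementRatioTable(data, kept, flags), removed


def average_replicate_ablations(table: ElementRatioTable) -> SignatureSet:
    """Collapse replicate ablation lines to one mean signature per sample.

    Below-LOD cells are excluded from the mean; a sample with zero usable
    ablations for some element is an error (it cannot be represented).
    """
    vals = table.data[table.elements].copy()
    vals[table.below_lod[table.elements].to_numpy(bool)] = np.nan
    grouped = vals.groupby(table.data["sample_id"], sort=False)
    means = grouped.mean()
    if means.isna().any().any():
        bad = [(sid, el) for sid in means.index for el in table.elements
               if pd.isna(means.at[sid, el])]
        raise ValueError(f"no usable ablations for sample/element pairs: {bad[:5]}")
    meta_cols = [c for c in META_COLUMNS if c != "ablation_index"]
    meta = table.data[meta_cols + []].groupby(table.data["sample_id"], sort=False).first()
    meta = meta.drop(columns=["sample_id"])
    means.index.name = "sample_id"
    meta.index.name = "sample_id"
    return SignatureSet(means, meta, transform_state="raw")


def log_transform(sig: SignatureSet) -> SignatureSet:
    """Natural-log transform of a raw signature set."""
    if sig.transform_state != "raw":
        raise ValueError(f"expected raw signatures, got {sig.transform_state}")
    if (sig.values <= 0).any().any():
        bad = sig.values.index[(sig.values <= 0).any(axis=1)]
        raise ValueError(f"non-positive ratio values for samples {list(bad)[:5]}")
    return SignatureSet(np.log(sig.values), sig.meta.copy(), "log")


def log_standardize(
    sig: SignatureSet, params: TransformParams | None = None
) -> tuple[SignatureSet, TransformParams]:
    """Log-transform then center/scale each element column.

    With ``params`` supplied the stored center/scale are applied without
    refitting — the leakage-free path for held-out or settler data.  The
    fitted path uses column mean and population-sd over the fitting set.
    """
    if sig.transform_state == "raw":
        sig = log_transform(sig)
    elif sig.transform_state != "log":
        raise ValueError("input already standardized")
    if params is None:
        center = sig.values.mean(axis=0)
        scale = sig.values.std(axis=0, ddof=0)
        if (scale <= 0).any():
            zero = list(scale.index[scale <= 0])
            raise ValueError(f"zero variance element(s): {zero}")
        params = TransformParams(center, scale, tuple(sig.values.index))
    else:
        if list(params.elements) != sig.elements:
            raise ValueError(
                f"element panel mismatch: params {params.elements} vs data {sig.elements}")
    z = (sig.values - params.center) / params.scale
    return SignatureSet(z, sig.meta.copy(), "log_standardized"), params


def inverse_log_standardize(sig: SignatureSet, params: TransformParams) -> SignatureSet:
    """Undo :func:`log_standardize`, returning ratios on the µmol mol⁻¹ scale."""
    if sig.transform_state != "log_standardized":
        raise ValueError("expected log_standardized input")
    raw = np.exp(sig.values * params.scale + params.center)
    return SignatureSet(raw, sig.meta.copy(), "raw")


def _robust_z(col: np.ndarray) -> np.ndarray:
    med = np.median(col)
    mad = np.median(np.abs(col - med))
    if mad == 0:
        return np.zeros_like(col)
    return (col - med) / (1.4826 * mad)


def remove_outliers(
    sig: SignatureSet,
    threshold: float = 3.5,
    group_by: str = "region",
    max_removed_fraction: float = 0.2,
) -> tuple[SignatureSet, OutlierReport]:
    """Remove within-group robust outliers on the log scale.

    A sample is flagged when any element's within-group robust z-score
    (median/MAD, MAD scaled by 1.4826) exceeds ``threshold`` in magnitude.
    Removing more than ``max_removed_fraction`` of the samples is treated as
    a misconfiguration and raises.
    """
    if sig.transform_state != "log":
        raise ValueError("outliers are judged on the log scale before standardization")
    groups = sig.meta[group_by].fillna("_none_")
    details: dict[str, dict[str, float]] = {}
    for _, idx in groups.groupby(groups).groups.items():
        block = sig.values.loc[idx]
        z = np.column_stack([_robust_z(block[el].to_numpy()) for el in sig.elements])
        for row, sid in enumerate(block.index):
            offenders = {
                el: float(z[row, j])
                for j, el in enumerate(sig.elements)
                if abs(z[row, j]) > threshold
            }
            if offenders:
                details[sid] = offenders
    removed = sorted(details)
    if len(removed) > max_removed_fraction * sig.n:
        raise ValueError(
            f"outlier rule would remove {len(removed)}/{sig.n} samples "
            f"(> {max_removed_fraction:.0%}); check configuration")
    keep = [sid for sid in sig.values.index if sid not in details]
    rule = f"within-{group_by} robust z (median/MAD), flag if any |z| > {threshold}"
    report = OutlierReport(removed, details, rule)
    out = SignatureSet(sig.values.loc[keep].copy(), sig.meta.loc[keep].copy(), "log")
    return out, report
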