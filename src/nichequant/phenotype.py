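"""Marker-intensity phenotyping, co-localization and apoptosis quantification.

Per-mask mean marker intensities are scaled by the per-stack sum of all mask
means (per marker) and natural-log transformed; the resulting distributions
are pooled across z-stacks and asymmetric percentile thresholds are taken
(40th for CD19, 95th for CD3 by default — asymmetric because B cells dominate
the mask population while T cells are rare). Cells strictly above a
threshold are positive for that marker; double-positive masks, optionally
together with directly adjacent CD19+/CD3+ mask pairs (surface gap <= 1
voxel, 26-connectivity), count as co-localized. Apoptotic B-cell fractions
are the caspase-3-positive share of CD19+ cells per stack, averaged over the
3-4 stacks of a condition and expressed as a ratio to a control condition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .stack import ImageStack3D

__all__ = [
    "MarkerThresholds",
    "StackCounts",
    "ApoptosisResult",
    "CaspaseRule",
    "extract_mask_intensities",
    "normalize_intensities",
    "pool_and_threshold",
    "classify_cells",
    "count_colocalized",
    "quantify_apoptosis",
    "regions_adjacent",
]

log = logging.getLogger(__name__)

DEFAULT_PERCENTILES = {"CD19": 40.0, "CD3": 95.0}


@dataclass(frozen=True)
class MarkerThresholds:
    """Percentile thresholds on the norm-log intensity scale, per marker."""

    percentiles: dict[str, float]
    thresholds: dict[str, float]
    n_pooled: dict[str, int]


@dataclass(frozen=True)
class StackCounts:
    stack_id: str
    n_total_masks: int
    n_cd19: int
    n_cd3: int
    n_double_pos: int
    n_coloc: int
    coloc_ids: tuple[int, ...] = field(default=())


@dataclass(frozen=True)
class CaspaseRule:
    """How a cell counts as caspase-3 positive.

    ``otsu`` (default) splits the pooled CASP3 norm-log values at the Otsu
    point, requiring the two modes to be at least ``min_separation`` apart on
    the log scale (about a two-fold intensity difference at 0.7); unimodal
    data yields no positives. ``percentile`` uses a fixed percentile of the
    pooled values instead.
    """

    method: str = "otsu"  # {otsu, percentile}
    percentile: float = 95.0
    min_separation: float = 0.7

    def threshold(self, values: np.ndarray) -> float | None:
        """Threshold for the pooled values, or None when nothing qualifies."""
        values = np.asarray(values, dtype=float)
        values = values[np.isfinite(values)]
        if values.size == 0:
            return None
        if self.method == "percentile":
            return float(np.percentile(values, self.percentile))
        if self.method != "otsu":
            raise ValueError(f"unknown caspase rule {self.method!r}")
        if values.min() == values.max():
            return None
        from skimage.filters import threshold_otsu

        thr = float(threshold_otsu(values, nbins=512))
        hi, lo_vals = values[values > thr], values[values <= thr]
        if hi.size == 0 or lo_vals.size == 0:
            return None
        if float(hi.mean() - lo_vals.mean()) < self.min_separation:
            return None  # unimodal: no caspase-high mode present
        return thr


@dataclass(frozen=True)
class ApoptosisResult:
    """Per-condition apoptotic B-cell fractions and ratios to control."""

    per_stack: dict[str, list[float]]
    condition_means: dict[str, float]
    ratios_vs_control: dict[str, float]
    control: str
    caspase_threshold: float | None


# ---------------------------------------------------------------------------

def extract_mask_intensities(
    labels: np.ndarray,
    stack: ImageStack3D,
    markers: list[str],
    stack_id: str = "stack",
) -> pd.DataFrame:
    """Per-mask geometry and raw mean intensity of each marker channel."""
    labels = np.asarray(labels)
    if labels.shape != stack.shape:
        raise ValueError(
            f"label grid {labels.shape} does not match stack grid {stack.shape}"
        )
    for marker in markers:
        stack[marker]  # raises with available channels listed
    ids = np.unique(labels)
    ids = ids[ids > 0]
    records = pd.DataFrame({"cell_id": ids.astype(int), "stack_id": stack_id})
    if ids.size == 0:
        for ax in "zyx":
            records[f"centroid_{ax}"] = pd.Series(dtype=float)
        records["voxel_count"] = pd.Series(dtype=int)
        for marker in markers:
            records[f"mean_{marker}"] = pd.Series(dtype=float)
        return records
    counts = ndi.sum_labels(np.ones_like(labels, dtype=np.float64), labels, ids)
    centroids = np.asarray(ndi.center_of_mass(np.ones_like(labels), labels, ids))
    records["voxel_count"] = counts.astype(int)
    records[["centroid_z", "centroid_y", "centroid_x"]] = centroids
    for marker in markers:
        channel = stack[marker].astype(np.float64)
        records[f"mean_{marker}"] = ndi.mean(channel, labels, ids)
    return records


def normalize_intensities(table: pd.DataFrame, markers: list[str]) -> pd.DataFrame:
    """Sum-scale and log-transform mean intensities, per stack and marker.

    Within each stack the mask means of a marker are divided by their sum
    (so scaled values sum to one) and natural-log transformed. Zero means
    are replaced by half the smallest positive scaled value of that stack
    and marker before the log; a marker with all-zero means in a stack gets
    NaN norm-log values (such cells classify as negative) and a warning.
    """
    out = table.copy()
    for marker in markers:
        out[f"normlog_{marker}"] = np.nan
    for stack_id, group in out.groupby("stack_id", sort=False):
        for marker in markers:
            means = group[f"mean_{marker}"].to_numpy(dtype=float)
            total = means.sum()
            if total <= 0:
                log.warning(
                    "stack %s: all %s mask means are zero; cells flagged negative",
                    stack_id, marker,
                )
                continue
            scaled = means / total
            pos = scaled[scaled > 0]
            scaled = np.where(scaled > 0, scaled, 0.5 * pos.min())
            out.loc[group.index, f"normlog_{marker}"] = np.log(scaled)
    return out


def pool_and_threshold(
    tables: list[pd.DataFrame],
    percentiles: dict[str, float] | None = None,
) -> MarkerThresholds:
    """Pool norm-log distributions across stacks and take percentile thresholds.

    Percentiles use the linear-interpolation definition between order
    statistics (numpy's default).
    """
    percentiles = dict(percentiles or DEFAULT_PERCENTILES)
    if not tables:
        raise ValueError("need at least one cell table")
    thresholds: dict[str, float] = {}
    n_pooled: dict[str, int] = {}
    for marker, pct in percentiles.items():
        if not 0.0 < pct < 100.0:
            raise ValueError(f"percentile for {marker} must be in (0, 100)")
        col = f"normlog_{marker}"
        pooled = np.concatenate(
            [t[col].to_numpy(dtype=float) for t in tables if col in t]
        ) if any(col in t for t in tables) else np.empty(0)
        pooled = pooled[np.isfinite(pooled)]
        if pooled.size == 0:
            raise ValueError(f"empty pooled distribution for marker {marker}")
        thresholds[marker] = float(np.percentile(pooled, pct))
        n_pooled[marker] = int(pooled.size)
    return MarkerThresholds(percentiles, thresholds, n_pooled)


def classify_cells(
    table: pd.DataFrame,
    thresholds: MarkerThresholds,
    cd19_marker: str = "CD19",
    cd3_marker: str = "CD3",
) -> pd.DataFrame:
    """Assign each mask one class: CD19pos, CD3pos, double_pos or negative.

    Positivity is strict (norm-log value > threshold); a cell exactly at a
    threshold, or with an undefined norm-log value, is negative for that
    marker.
    """
    out = table.copy()
    cd19 = out[f"normlog_{cd19_marker}"].to_numpy(dtype=float) \
        > thresholds.thresholds[cd19_marker]
    cd3 = out[f"normlog_{cd3_marker}"].to_numpy(dtype=float) \
        > thresholds.thresholds[cd3_marker]
    cls = np.where(
        cd19 & cd3, "double_pos",
        np.where(cd19, "CD19pos", np.where(cd3, "CD3pos", "negative")),
    )
    out["class"] = cls
    return out


# ---------------------------------------------------------------------------
# co-localization

def regions_adjacent(
    labels: np.ndarray, id_a: int, id_b: int, max_gap: int = 1, _objs=None
) -> bool:
    """True when two label regions are within `max_gap` voxels (26-connectivity).

    A gap of 0 means touching/overlapping; gap 1 allows one empty voxel
    between the regions (Chebyshev distance <= max_gap + 1 between voxels).
    """
    objs = _objs if _objs is not None else ndi.find_objects(labels)
    sl_a, sl_b = objs[id_a - 1], objs[id_b - 1]
    if sl_a is None or sl_b is None:
        return False
    pad = max_gap + 1
    lo = [max(0, min(a.start, b.start) - 1) for a, b in zip(sl_a, sl_b)]
    hi = [min(s, max(a.stop, b.stop) + 1) for a, b, s in zip(sl_a, sl_b, labels.shape)]
    if any(h <= l for l, h in zip(lo, hi)):
        return False
    crop = labels[tuple(slice(l, h) for l, h in zip(lo, hi))]
    va = np.argwhere(crop == id_a)
    vb = np.argwhere(crop == id_b)
    if va.size == 0 or vb.size == 0:
        return False
    # cheap bounding-box rejection before the exact Chebyshev distance
    if any(
        va[:, ax].min() - vb[:, ax].max() > pad or vb[:, ax].min() - va[:, ax].max() > pad
        for ax in range(3)
    ):
        return False
    cheb = np.abs(va[:, None, :] - vb[None, :, :]).max(axis=2)
    return bool(cheb.min() <= pad)


def count_colocalized(
    labels: np.ndarray,
    table: pd.DataFrame,
    mode: str = "double_pos_or_adjacent",
    max_gap: int = 1,
) -> tuple[StackCounts, pd.DataFrame]:
    """Count positive and co-localized masks in one stack.

    ``double_pos_only`` counts only masks positive for both markers;
    ``double_pos_or_adjacent`` (the figure-legend definition) additionally
    flags every CD19+ mask whose region lies within ``max_gap`` voxels of a
    CD3+ mask, together with that partner. Returns the counts and the table
    with a boolean ``coloc`` column.
    """
    if mode not in ("double_pos_only", "double_pos_or_adjacent"):
        raise ValueError(f"unknown mode {mode!r}")
    out = table.copy()
    cls = out["class"]
    cd19_ids = set(out.loc[cls.isin(["CD19pos", "double_pos"]), "cell_id"])
    cd3_ids = set(out.loc[cls.isin(["CD3pos", "double_pos"]), "cell_id"])
    double_ids = set(out.loc[cls == "double_pos", "cell_id"])

    coloc: set[int] = set(double_ids)
    if mode == "double_pos_or_adjacent":
        labels = np.asarray(labels)
        objs = ndi.find_objects(labels)
        pad = max_gap + 1

        def _bbox(i):
            return objs[i - 1]

        for a in sorted(cd19_ids - double_ids):
            for b in sorted(cd3_ids - {a}):
                sa, sb = _bbox(a), _bbox(b)
                if sa is None or sb is None:
                    continue
                if any(
                    sa[ax].start - sb[ax].stop > pad or sb[ax].start - sa[ax].stop > pad
                    for ax in range(3)
                ):
                    continue
                if regions_adjacent(labels, a, b, max_gap=max_gap, _objs=objs):
                    coloc.add(a)
                    coloc.add(b)

    out["coloc"] = out["cell_id"].isin(coloc)
    stack_id = str(out["stack_id"].iloc[0]) if len(out) else "stack"
    counts = StackCounts(
        stack_id=stack_id,
        n_total_masks=len(out),
        n_cd19=len(cd19_ids),
        n_cd3=len(cd3_ids),
        n_double_pos=len(double_ids),
        n_coloc=len(coloc),
        coloc_ids=tuple(sorted(coloc)),
    )
    return counts, out


# ---------------------------------------------------------------------------
# apoptosis

def quantify_apoptosis(
    tables_by_condition: dict[str, list[pd.DataFrame]],
    control: str,
    caspase_marker: str = "CASP3",
    rule: CaspaseRule | None = None,
) -> ApoptosisResult:
    """Caspase-3-positive fraction of CD19+ cells, per condition vs control.

    Caspase positivity is decided on the pooled (all stacks, all conditions)
    norm-log caspase distribution by ``rule``. Per stack the fraction is
    |CD19+ and caspase+| / |CD19+|; a stack with no CD19+ cells is excluded
    with a warning. Condition means are unweighted over stacks and the ratio
    is mean_condition / mean_control (0 when both are zero).
    """
    rule = rule or CaspaseRule()
    if control not in tables_by_condition:
        raise ValueError(f"control condition {control!r} not among conditions")
    col = f"normlog_{caspase_marker}"
    pooled = [
        t[col].to_numpy(dtype=float)
        for tables in tables_by_condition.values()
        for t in tables
        if col in t
    ]
    values = np.concatenate(pooled) if pooled else np.empty(0)
    thr = rule.threshold(values)

    per_stack: dict[str, list[float]] = {}
    means: dict[str, float] = {}
    for cond, tables in tables_by_condition.items():
        fractions = []
        for i, t in enumerate(tables):
            cd19 = t["class"].isin(["CD19pos", "double_pos"])
            n_b = int(cd19.sum())
            if n_b == 0:
                log.warning(
                    "condition %s stack %d: no CD19+ cells; stack excluded", cond, i
                )
                continue
            if thr is None:
                fractions.append(0.0)
                continue
            casp = t[col].to_numpy(dtype=float) > thr
            fractions.append(float((cd19.to_numpy() & casp).sum()) / n_b)
        per_stack[cond] = fractions
        means[cond] = float(np.mean(fractions)) if fractions else math.nan

    ratios: dict[str, float] = {}
    ctrl = means[control]
    for cond, m in means.items():
        if math.isnan(m) or math.isnan(ctrl):
            ratios[cond] = math.nan
        elif ctrl == 0.0:
            ratios[cond] = 0.0 if m == 0.0 else math.inf
        else:
            ratios[cond] = m / ctrl
    return ApoptosisResult(per_stack, means, ratios, control, thr)
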