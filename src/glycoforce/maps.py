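"""Force-map aggregation: per-cell / per-region summaries of pixel-wise
fits, cytochalasin-style before/after comparisons, and group statistics.

A :class:`ForceMap` holds a grid of per-pixel fits (full decompositions for
the spherical glycocalyx procedure, plain Hertz fits for pyramidal modulus
mapping), a boolean cell mask and a central mask.  "Central part of the
cell" is operationalised as the erosion of the cell mask to half its area
around the mask centroid (the nuclear region proxy); the fraction is
configurable via :func:`central_region`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .brush import CurveDecomposition
from .contact import HertzFit
from .curves import MapHeader
from .errors import GlycoforceError

__all__ = [
    "ForceMap",
    "CellSummary",
    "central_region",
    "summarize_cell",
    "percent_reduction",
    "compare_groups",
    "GroupComparison",
]

_MIN_VALID_PIXELS = 4


def central_region(mask: np.ndarray, area_fraction: float = 0.5) -> np.ndarray:
    """Inner region of a mask: pixels ranked by Euclidean distance to the
    mask boundary, keeping the deepest ``area_fraction`` of the mask area."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(mask)
    target = max(1, int(round(area_fraction * mask.sum())))
    vals = np.sort(dist[mask])[::-1]
    threshold = vals[target - 1]
    central = dist >= threshold
    return central & mask


@dataclass(frozen=True)
class ForceMap:
    """Grid of per-pixel fits with cell and central masks."""

    header: MapHeader
    pixels: tuple  # rows of tuples of CurveDecomposition | HertzFit | None
    cell_mask: np.ndarray
    central_mask: np.ndarray
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        rows, cols = self.header.grid_shape
        if len(self.pixels) != rows or any(len(r) != cols for r in self.pixels):
            raise GlycoforceError("pixel grid does not match header shape")
        cm = np.asarray(self.cell_mask, dtype=bool)
        cen = np.asarray(self.central_mask, dtype=bool)
        if cm.shape != (rows, cols) or cen.shape != (rows, cols):
            raise GlycoforceError("mask shapes do not match header shape")
        if np.any(cen & ~cm):
            raise GlycoforceError("central_mask must be a subset of cell_mask")
        object.__setattr__(self, "cell_mask", cm)
        object.__setattr__(self, "central_mask", cen)


@dataclass(frozen=True)
class CellSummary:
    """Per-cell aggregates of E (Pa) and L (nm) over the whole cell and its
    central region; ``None`` entries mean fewer than the minimum number of
    valid pixels, with the reason recorded."""

    cell_id: str
    E_whole_pa: float | None
    E_central_pa: float | None
    L_whole_nm: float | None
    L_central_nm: float | None
    n_valid_whole: int
    n_valid_central: int
    aggregation: str = "median"
    absent_reason: str = ""


def _pixel_values(pix) -> tuple[float | None, float | None]:
    """(E, L) of one pixel, or None for failed/absent components."""
    if pix is None:
        return None, None
    if isinstance(pix, CurveDecomposition):
        E = pix.hertz.E_pa if pix.hertz.success else None
        L = pix.brush.L_nm if pix.brush is not None else None
        return E, L
    if isinstance(pix, HertzFit):
        return (pix.E_pa if pix.success else None), None
    raise GlycoforceError(f"unsupported pixel type {type(pix).__name__}")


def _aggregate(values: list[float], how: str) -> float | None:
    if len(values) < _MIN_VALID_PIXELS:
        return None
    arr = np.asarray(values, dtype=float)
    return float(np.median(arr) if how == "median" else np.mean(arr))


def summarize_cell(fmap: ForceMap, aggregation: str = "median") -> CellSummary:
    """Aggregate valid pixels (default median) over the cell mask and the
    central mask separately, skipping flagged failures."""
    if aggregation not in ("median", "mean"):
        raise GlycoforceError("aggregation must be 'median' or 'mean'")
    regions = {"whole": fmap.cell_mask, "central": fmap.central_mask}
    agg: dict[str, float | None] = {}
    n_valid: dict[str, int] = {}
    reasons = []
    for name, mask in regions.items():
        Es, Ls = [], []
        for r, c in zip(*np.nonzero(mask)):
            E, L = _pixel_values(fmap.pixels[r][c])
            if E is not None:
                Es.append(E)
            if L is not None:
                Ls.append(L)
        n_valid[name] = len(Es)
        agg[f"E_{name}"] = _aggregate(Es, aggregation)
        agg[f"L_{name}"] = _aggregate(Ls, aggregation)
        if not mask.any():
            reasons.append(f"{name}: empty mask")
        elif len(Es) < _MIN_VALID_PIXELS:
            reasons.append(f"{name}: only {len(Es)} valid pixels")
    return CellSummary(
        cell_id=fmap.cell_id,
        E_whole_pa=agg["E_whole"], E_central_pa=agg["E_central"],
        L_whole_nm=agg["L_whole"], L_central_nm=agg["L_central"],
        n_valid_whole=n_valid["whole"], n_valid_central=n_valid["central"],
        aggregation=aggregation, absent_reason="; ".join(reasons),
    )


def percent_reduction(before: CellSummary | float, after: CellSummary | float,
                      field: str = "E_whole_pa") -> float:
    """Percentage reduction 100*(before - after)/before of a summary field
    (positive = reduction, e.g. after actin depolymerisation)."""
    b = getattr(before, field) if isinstance(before, CellSummary) else float(before)
    a = getattr(after, field) if isinstance(after, CellSummary) else float(after)
    if b is None or a is None:
        raise GlycoforceError(f"field {field} absent on one of the summaries")
    if b <= 0:
        raise GlycoforceError("'before' value must be > 0")
    return 100.0 * (b - a) / b


@dataclass(frozen=True)
class GroupComparison:
    """Output of :func:`compare_groups`: test name, statistic, p-value and
    per-group medians / sizes."""

    test: str
    statistic: float
    p_value: float
    group_medians: dict[str, float]
    group_sizes: dict[str, int]

    def __str__(self) -> str:
        meds = ", ".join(f"{g}: {m:.4g} (n={self.group_sizes[g]})"
                         for g, m in self.group_medians.items())
        return (f"{self.test}: statistic={self.statistic:.6g}, "
                f"p={self.p_value:.4g} [{meds}]")


def _coerce_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, pd.DataFrame):
        if not {"group", "value"} <= set(groups.columns):
            raise GlycoforceError("DataFrame needs 'group' and 'value' columns")
        return {str(g): sub["value"].to_numpy(dtype=float)
                for g, sub in groups.groupby("group", sort=True)}
    if isinstance(groups, Mapping):
        return {str(g): np.asarray(v, dtype=float) for g, v in groups.items()}
    raise GlycoforceError("groups must be a mapping label -> values or a DataFrame")


def compare_groups(groups, test: str = "kruskal") -> GroupComparison:
    """Kruskal-Wallis rank test or unpaired t-test across labelled groups
    of per-cell values (reporting plumbing over scipy.stats)."""
    data = _coerce_groups(groups)
    if len(data) < 2:
        raise GlycoforceError("need >= 2 groups")
    for g, v in data.items():
        if v.size < 3:
            raise GlycoforceError(f"group {g!r} has {v.size} observations (< 3)")
    labels = sorted(data)
    samples = [data[g] for g in labels]
    if test == "kruskal":
        stat, p = stats.kruskal(*samples)
        if np.isnan(stat) and all(
                np.array_equal(samples[0], s) for s in samples[1:]):
            stat, p = 0.0, 1.0
    elif test in ("ttest", "t-test"):
        if len(samples) != 2:
            raise GlycoforceError("t-test requires exactly 2 groups")
        stat, p = stats.ttest_ind(samples[0], samples[1], equal_var=False)
    else:
        raise GlycoforceError(f"unknown test {test!r}")
    return GroupComparison(
        test=test, statistic=float(stat), p_value=float(p),
        group_medians={g: float(np.median(data[g])) for g in labels},
        group_sizes={g: int(data[g].size) for g in labels},
    )


def summaries_to_frame(summaries: Iterable[tuple[str, CellSummary]] |
                       Sequence[CellSummary],
                       labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Tidy DataFrame of (group, cell_id, field, value) rows for group
    comparisons and CSV export."""
    if labels is not None:
        pairs = list(zip(labels, summaries))  # type: ignore[arg-type]
    else:
        pairs = list(summaries)  # type: ignore[assignment]
    rows = []
    for label, s in pairs:
        for f in ("E_whole_pa", "E_central_pa", "L_whole_nm", "L_central_nm"):
            v = getattr(s, f)
            if v is not None:
                rows.append({"group": label, "cell_id": s.cell_id,
                             "field": f, "value": v})
    return pd.DataFrame(rows)
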