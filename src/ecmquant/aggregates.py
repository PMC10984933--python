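"""Aggregate-size-distribution analysis of 2-D particle masks.

Implements the per-image chain used to quantify microbial aggregation
from calibrated phase-contrast segmentations:

1. measure connected components (area in µm², border contact),
2. drop particles < 1 µm² and border-touching particles,
3. sort the log10 areas into a rank curve and fit two change points,
4. classify each particle against a ±k·MAD band around the median of
   the middle (single-cell) segment: below the band = sub-cellular
   debris, above = aggregate, inside = single cell,
5. summarize: percent aggregates among cells+aggregates, and aggregate
   sizes normalized by the per-image mean single-cell area (µm²).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure as skmeasure
from skimage.filters import threshold_otsu

from .changepoint import ChangePointFit, fit_change_points

__all__ = [
    "measure_particles",
    "binarize_grayscale",
    "SizeSeries",
    "build_size_series",
    "fit_change_points",
    "SizeClassification",
    "classify_particles",
    "AggregationSummary",
    "summarize_aggregation",
    "BatchResult",
    "run_aggregation_batch",
]

log = logging.getLogger(__name__)

DEBRIS = "debris"
SINGLE = "single"
AGGREGATE = "aggregate"


def binarize_grayscale(image: np.ndarray) -> np.ndarray:
    """Two-class Otsu fallback for grayscale input (foreground = bright)."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("grayscale image must be 2-D")
    return image > threshold_otsu(image)


def measure_particles(
    mask: np.ndarray,
    pixel_size: float,
    min_area_um2: float = 1.0,
    exclude_border: bool = True,
    image_id: str = "",
) -> pd.DataFrame:
    """Measure and filter connected components of a binary mask.

    Components use 8-connectivity. Particles smaller than
    ``min_area_um2`` (default 1 µm²) or touching the image frame
    (first/last row or column) are excluded.

    Returns a DataFrame with columns ``particle_id``, ``image_id``,
    ``area_um2``, ``centroid_row``, ``centroid_col``,
    ``touches_border``, sorted by ``particle_id``; ``pixel_size`` is
    stored in ``DataFrame.attrs``.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.size == 0:
        raise ValueError("mask must be a non-empty 2-D array")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1, 255, True, False))):
        raise ValueError("mask must be binary (0/1, 0/255 or boolean)")
    binary = mask.astype(bool)

    labels = skmeasure.label(binary, connectivity=2)
    rows = []
    nr, nc = binary.shape
    for prop in skmeasure.regionprops(labels):
        r0, c0, r1, c1 = prop.bbox
        touches = r0 == 0 or c0 == 0 or r1 == nr or c1 == nc
        area = prop.area * pixel_size**2
        rows.append(
            dict(
                particle_id=int(prop.label),
                image_id=image_id,
                area_um2=float(area),
                centroid_row=float(prop.centroid[0]),
                centroid_col=float(prop.centroid[1]),
                touches_border=bool(touches),
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "particle_id",
            "image_id",
            "area_um2",
            "centroid_row",
            "centroid_col",
            "touches_border",
        ],
    )
    keep = table["area_um2"] >= min_area_um2
    if exclude_border:
        keep &= ~table["touches_border"]
    table = table[keep].sort_values("particle_id").reset_index(drop=True)
    table.attrs["pixel_size"] = float(pixel_size)
    return table


@dataclass(frozen=True)
class SizeSeries:
    """Sorted log10 particle areas with aligned particle ids."""

    values: np.ndarray  # ascending log10(area_um2)
    ids: np.ndarray  # particle_id aligned to values

    def __len__(self) -> int:
        return self.values.size


def build_size_series(table: pd.DataFrame) -> SizeSeries:
    """Sort log10 areas ascending; ties keep ascending particle_id order."""
    if len(table) == 0:
        raise ValueError("no particles after filtering")
    areas = table["area_um2"].to_numpy(dtype=float)
    if np.any(areas <= 0):
        raise ValueError("all particle areas must be > 0")
    logs = np.log10(areas)
    ids = table["particle_id"].to_numpy()
    order = np.lexsort((ids, logs))
    return SizeSeries(values=logs[order], ids=ids[order])


@dataclass(frozen=True)
class SizeClassification:
    """±k·MAD single-cell band on the log10 scale and per-particle labels.

    The median and raw MAD (no normal-consistency factor) are computed
    over the middle change-point segment. Comparisons are strict:
    aggregate iff log10 area > band upper bound, debris iff < lower
    bound, single otherwise.
    """

    median_single: float
    mad_single: float
    k: float
    band: tuple[float, float]
    labels: np.ndarray  # aligned to series order
    ids: np.ndarray
    mean_single_area: float  # linear-scale µm² mean over singles

    def counts(self) -> dict[str, int]:
        lab, cnt = np.unique(self.labels, return_counts=True)
        out = {DEBRIS: 0, SINGLE: 0, AGGREGATE: 0}
        out.update(dict(zip(lab.tolist(), cnt.tolist())))
        return out


def classify_particles(
    series: SizeSeries, fit: ChangePointFit, k: float = 3.0
) -> SizeClassification:
    """Label every particle as debris / single / aggregate.

    The middle segment [i1, i2) of the fitted curve defines the
    single-cell population; sizes more than ``k`` MADs above its median
    are aggregates, sizes more than ``k`` MADs below are non-cell
    debris (flagged for discarding).
    """
    v = np.asarray(series.values, dtype=float)
    if fit.n != v.size:
        raise ValueError("fit was computed on a different series length")
    mid = v[fit.i1 : fit.i2]
    if mid.size < 2:
        raise ValueError("middle segment shorter than 2 points")
    med = float(np.median(mid))
    mad = float(np.median(np.abs(mid - med)))
    lo, hi = med - k * mad, med + k * mad
    labels = np.full(v.size, SINGLE, dtype=object)
    labels[v > hi] = AGGREGATE
    labels[v < lo] = DEBRIS
    single_mask = labels == SINGLE
    mean_single = float(np.mean(10.0 ** v[single_mask])) if single_mask.any() else np.nan
    return SizeClassification(
        median_single=med,
        mad_single=mad,
        k=float(k),
        band=(lo, hi),
        labels=labels.astype(str),
        ids=series.ids.copy(),
        mean_single_area=mean_single,
    )


@dataclass
class AggregationSummary:
    """Per-image and pooled aggregation statistics.

    ``aggregate_percentage`` counts aggregates among single cells plus
    aggregates (debris excluded from the denominator). Relative sizes
    divide each aggregate area by the mean single-cell area (µm²,
    linear scale) of its own image; images with aggregates but no
    singles yield NaN relative sizes and a warning, never a crash.
    """

    per_image: pd.DataFrame
    relative_sizes: pd.DataFrame
    pooled: dict
    warnings: list = field(default_factory=list)


def _summarize_labeled(labeled: pd.DataFrame) -> AggregationSummary:
    warnings: list[str] = []
    per_rows = []
    rel_frames = []
    for image_id, sub in labeled.groupby("image_id", sort=True):
        n = sub["label"].value_counts()
        n_deb = int(n.get(DEBRIS, 0))
        n_sin = int(n.get(SINGLE, 0))
        n_agg = int(n.get(AGGREGATE, 0))
        denom = n_sin + n_agg
        pct = 100.0 * n_agg / denom if denom > 0 else np.nan
        singles = sub.loc[sub["label"] == SINGLE, "area_um2"]
        mean_single = float(singles.mean()) if n_sin > 0 else np.nan
        if n_agg > 0 and n_sin == 0:
            warnings.append(
                f"image {image_id!r}: aggregates present but no single cells; "
                "relative sizes undefined (NaN)"
            )
        aggs = sub[sub["label"] == AGGREGATE]
        if len(aggs):
            rel_frames.append(
                pd.DataFrame(
                    dict(
                        image_id=image_id,
                        particle_id=aggs["particle_id"].to_numpy(),
                        area_um2=aggs["area_um2"].to_numpy(),
                        relative_size=aggs["area_um2"].to_numpy() / mean_single,
                    )
                )
            )
        per_rows.append(
            dict(
                image_id=image_id,
                n_debris=n_deb,
                n_single=n_sin,
                n_aggregate=n_agg,
                aggregate_percentage=pct,
                mean_single_area_um2=mean_single,
            )
        )
    per_image = pd.DataFrame(per_rows)
    relative = (
        pd.concat(rel_frames, ignore_index=True)
        if rel_frames
        else pd.DataFrame(columns=["image_id", "particle_id", "area_um2", "relative_size"])
    )
    tot_sin = int(per_image["n_single"].sum())
    tot_agg = int(per_image["n_aggregate"].sum())
    tot_deb = int(per_image["n_debris"].sum())
    denom = tot_sin + tot_agg
    pooled = dict(
        n_debris=tot_deb,
        n_single=tot_sin,
        n_aggregate=tot_agg,
        aggregate_percentage=100.0 * tot_agg / denom if denom else np.nan,
    )
    for w in warnings:
        log.warning(w)
    return AggregationSummary(
        per_image=per_image, relative_sizes=relative, pooled=pooled, warnings=warnings
    )


def summarize_aggregation(
    classification: SizeClassification, table: pd.DataFrame
) -> AggregationSummary:
    """Summarize one classified image (or image set sharing one fit)."""
    labels = pd.DataFrame(
        dict(particle_id=classification.ids, label=classification.labels)
    )
    labeled = table.merge(labels, on="particle_id", how="inner")
    if len(labeled) != len(classification.ids):
        raise ValueError("labels do not cover every retained particle")
    return _summarize_labeled(labeled)


@dataclass
class BatchResult:
    """Full-chain outputs for a batch of calibrated masks."""

    particles: pd.DataFrame  # per-particle: image, group, area, label, relative_size
    per_image: pd.DataFrame
    group_summary: pd.DataFrame
    group_relative_sizes: dict[str, np.ndarray]
    warnings: list


def run_aggregation_batch(
    images,
    min_area_um2: float = 1.0,
    k: float = 3.0,
    min_seg: int = 5,
    exclude_border: bool = True,
) -> BatchResult:
    """Run the per-image chain over ``(mask, pixel_size, group, image_id)``
    tuples and pool relative aggregate sizes per group.

    ``image_id`` may be omitted (auto-numbered). A warning is logged if
    one group mixes pixel sizes; each image keeps its own calibration.
    """
    if not images:
        raise ValueError("need at least one image")
    norm = []
    for j, item in enumerate(images):
        if len(item) == 4:
            mask, px, group, image_id = item
        else:
            mask, px, group = item
            image_id = f"img{j:03d}"
        norm.append((mask, float(px), str(group), str(image_id)))

    sizes_by_group: dict[str, set] = {}
    for _, px, group, _ in norm:
        sizes_by_group.setdefault(group, set()).add(px)
    warnings = []
    for group, sizes in sizes_by_group.items():
        if len(sizes) > 1:
            msg = f"group {group!r} mixes pixel sizes {sorted(sizes)}; per-image calibration respected"
            warnings.append(msg)
            log.warning(msg)

    labeled_frames = []
    for mask, px, group, image_id in norm:
        table = measure_particles(
            mask, px, min_area_um2=min_area_um2, exclude_border=exclude_border,
            image_id=image_id,
        )
        series = build_size_series(table)
        fit = fit_change_points(series, min_seg=min_seg)
        cls = classify_particles(series, fit, k=k)
        labels = pd.DataFrame(dict(particle_id=cls.ids, label=cls.labels))
        lab = table.merge(labels, on="particle_id", how="inner")
        lab["group"] = group
        labeled_frames.append(lab)
    labeled = pd.concat(labeled_frames, ignore_index=True)

    summary = _summarize_labeled(labeled)
    warnings.extend(summary.warnings)

    particles = labeled.merge(
        summary.relative_sizes[["image_id", "particle_id", "relative_size"]],
        on=["image_id", "particle_id"],
        how="left",
    )
    per_image = summary.per_image.merge(
        labeled[["image_id", "group"]].drop_duplicates(), on="image_id"
    )
    grp_rows = []
    group_rel: dict[str, np.ndarray] = {}
    rel_with_group = summary.relative_sizes.merge(
        labeled[["image_id", "group"]].drop_duplicates(), on="image_id", how="left"
    )
    for group, sub in per_image.groupby("group", sort=True):
        rel = rel_with_group.loc[
            rel_with_group["group"] == group, "relative_size"
        ].to_numpy(dtype=float)
        group_rel[group] = rel
        grp_rows.append(
            dict(
                group=group,
                n_images=len(sub),
                n_debris=int(sub["n_debris"].sum()),
                n_single=int(sub["n_single"].sum()),
                n_aggregate=int(sub["n_aggregate"].sum()),
                aggregate_percentage=float(
                    100.0
                    * sub["n_aggregate"].sum()
                    / max(sub["n_single"].sum() + sub["n_aggregate"].sum(), 1)
                ),
                mean_image_aggregate_percentage=float(
                    sub["aggregate_percentage"].mean()
                ),
            )
        )
    return BatchResult(
        particles=particles,
        per_image=per_image,
        group_summary=pd.DataFrame(grp_rows),
        group_relative_sizes=group_rel,
        warnings=warnings,
    )
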