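"""Synthetic microscopy scenes with ground truth.

Two generators exercise the full pipeline without external data:

* :func:`generate_particle_scene` renders a calibrated 2-D binary mask
  of a mixed particle population — sub-cellular debris, log-normally
  sized single cells, and aggregates built from merged overlapping
  cells — with a per-particle truth table.
* :func:`generate_biofilm_stack` builds a two-channel 3-D stack: a cell
  channel (slab or substrate-attached colonies) and an EPS channel laid
  down as a shell around the cell mass with a controllable EPS/cell
  biovolume ratio and overlap fraction, plus Gaussian intensity noise.

Everything is a pure function of (params, seed): one documented numpy
Generator stream per scene drives all draws.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .biovolume import VolumeGrid

__all__ = [
    "Scene2DParams",
    "GroundTruth2D",
    "generate_particle_scene",
    "scene_params_for_fraction",
    "Scene3DParams",
    "GroundTruth3D",
    "generate_biofilm_stack",
    "write_fixtures",
]

log = logging.getLogger(__name__)

# single-cell log10-area draws are truncated at +/- TRUNC_SD standard
# deviations so the entire population sits inside a +/-3 MAD band
# (3*MAD of the truncated normal is ~2 sd > TRUNC_SD)
TRUNC_SD = 1.8
_MAD_NORMAL = 0.674489750196  # MAD of a standard normal


@dataclass(frozen=True)
class Scene2DParams:
    """Layout of a 2-D particle field.

    Defaults emulate a phase-contrast field of an algal-scale
    population at 0.65 µm/pixel: ~16 µm² single cells with a narrow
    log-normal spread, sub-cellular debris well below the cell band,
    and aggregates of 3–6 merged cells, 300 cells+aggregates per field.
    """

    image_shape: tuple[int, int] = (900, 900)
    pixel_size: float = 0.65  # µm/pixel
    n_single: int = 240
    log10_area_mean: float = 1.2  # log10 µm²
    log10_area_sd: float = 0.08
    n_debris: int = 80
    debris_area_range: tuple[float, float] = (1.5, 5.0)  # µm²
    n_aggregates: int = 60
    cells_per_aggregate_range: tuple[int, int] = (3, 6)
    border_particle_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if min(self.n_single, self.n_debris, self.n_aggregates) < 0:
            raise ValueError("particle counts must be >= 0")
        if not 0.0 <= self.border_particle_prob <= 1.0:
            raise ValueError("border_particle_prob must be in [0, 1]")
        lo, hi = self.cells_per_aggregate_range
        if lo < 2 or hi < lo:
            raise ValueError("cells_per_aggregate_range must be (>=2, >=lo)")
        dlo, dhi = self.debris_area_range
        if not 0 < dlo <= dhi:
            raise ValueError("debris_area_range must be positive and ordered")
        # separability by construction: debris stays below the lower edge
        # of the single-cell +/-3 MAD band (MAD proxy = 0.6745 sd)
        band_lo = 10 ** (self.log10_area_mean - 3 * _MAD_NORMAL * self.log10_area_sd)
        if dhi >= band_lo:
            raise ValueError(
                f"debris_area_range max {dhi} must stay below the single-cell "
                f"band lower edge {band_lo:.3g} µm²"
            )


@dataclass
class GroundTruth2D:
    """Per-particle truth for a rendered 2-D scene.

    ``true_area_um2`` is the realized area (rendered pixel count times
    pixel area) — the exact truth of the mask; ``target_area_um2`` is
    the sampled area the renderer aimed for (for aggregates, the sum of
    member-cell areas before merging).
    """

    table: pd.DataFrame
    label_image: np.ndarray
    params: Scene2DParams


def scene_params_for_fraction(
    aggregate_fraction: float,
    n_cells_and_aggregates: int = 300,
    n_debris: int = 80,
    seed: int = 0,
    **overrides,
) -> Scene2DParams:
    """Scene parameters with a designed aggregate fraction.

    The designed fraction counts aggregates among single cells plus
    aggregates, matching the analysis' aggregate-percentage definition.
    """
    n_agg = int(round(aggregate_fraction * n_cells_and_aggregates))
    return Scene2DParams(
        n_single=n_cells_and_aggregates - n_agg,
        n_aggregates=n_agg,
        n_debris=n_debris,
        seed=seed,
        **overrides,
    )


def _sample_single_log10_areas(rng, n, mean, sd):
    if n == 0:
        return np.empty(0)
    z = stats.truncnorm.rvs(-TRUNC_SD, TRUNC_SD, size=n, random_state=rng)
    return mean + sd * z


def _disk_offsets_radius(rng, params, kind):
    """Sample one particle's geometry: disk centers (relative) + radii in px.

    Returns (centers (k,2) float, radii (k,) float, target_area_um2, k).
    """
    px = params.pixel_size
    if kind == "single":
        area = 10 ** _sample_single_log10_areas(
            rng, 1, params.log10_area_mean, params.log10_area_sd
        )[0]
        r = np.sqrt(area / np.pi) / px
        return np.zeros((1, 2)), np.array([r]), float(area), 1
    if kind == "debris":
        area = rng.uniform(*params.debris_area_range)
        r = np.sqrt(area / np.pi) / px
        return np.zeros((1, 2)), np.array([r]), float(area), 1
    # aggregate: chain k cells; each new cell sits 0.55-0.75 of the
    # summed radii away from a random existing cell, guaranteeing merge
    # (distance < r_a + r_b) while keeping the union well above the
    # single-cell band even for minimal members
    lo, hi = params.cells_per_aggregate_range
    k = int(rng.integers(lo, hi + 1))
    areas = 10 ** _sample_single_log10_areas(
        rng, k, params.log10_area_mean, params.log10_area_sd
    )
    radii = np.sqrt(areas / np.pi) / px
    centers = np.zeros((k, 2))
    for i in range(1, k):
        j = int(rng.integers(0, i))
        ang = rng.uniform(0, 2 * np.pi)
        d = rng.uniform(0.55, 0.75) * (radii[j] + radii[i])
        centers[i] = centers[j] + d * np.array([np.sin(ang), np.cos(ang)])
    centers -= centers.mean(axis=0)
    return centers, radii, float(areas.sum()), k


def _render_particle(label_image, pid, center, disk_centers, radii):
    """Paint the union of disks into the label image; return pixel count."""
    nr, nc = label_image.shape
    cy, cx = center
    ys = disk_centers[:, 0] + cy
    xs = disk_centers[:, 1] + cx
    r0 = max(int(np.floor((ys - radii).min())), 0)
    r1 = min(int(np.ceil((ys + radii).max())) + 1, nr)
    c0 = max(int(np.floor((xs - radii).min())), 0)
    c1 = min(int(np.ceil((xs + radii).max())) + 1, nc)
    if r0 >= r1 or c0 >= c1:
        return 0
    yy, xx = np.mgrid[r0:r1, c0:c1]
    hit = np.zeros(yy.shape, bool)
    for (dy, dx), r in zip(np.column_stack((ys, xs)), radii):
        hit |= (yy - dy) ** 2 + (xx - dx) ** 2 <= r * r
    patch = label_image[r0:r1, c0:c1]
    hit &= patch == 0
    patch[hit] = pid
    return int(hit.sum())


def generate_particle_scene(params: Scene2DParams):
    """Render a 2-D particle mask and its ground truth.

    Returns ``(mask, truth)`` where ``mask`` is a boolean image in which
    every truth particle is exactly one 8-connected component, and
    ``truth`` is a :class:`GroundTruth2D`.
    """
    rng = np.random.default_rng(params.seed)
    nr, nc = params.image_shape
    label_image = np.zeros((nr, nc), dtype=np.int32)

    kinds = (
        ["aggregate"] * params.n_aggregates
        + ["single"] * params.n_single
        + ["debris"] * params.n_debris
    )
    placed_centers: list[tuple[float, float]] = []
    placed_radii: list[float] = []
    rows = []
    pid = 0
    for kind in kinds:
        disk_centers, radii, target_area, k = _disk_offsets_radius(rng, params, kind)
        bound = float(np.max(np.hypot(*disk_centers.T) + radii))
        on_border = bool(rng.random() < params.border_particle_prob)
        placed = False
        for _ in range(400):
            if on_border:
                side = int(rng.integers(0, 4))
                # put the first disk's center within its own radius of the
                # frame so the rendered particle is clipped by the border
                depth = rng.uniform(0.2, 0.7) * radii[0]
                along = rng.uniform(bound, (nc if side < 2 else nr) - bound)
                if side == 0:
                    center = (depth, along)
                elif side == 1:
                    center = (nr - 1 - depth, along)
                elif side == 2:
                    center = (along, depth)
                else:
                    center = (along, nc - 1 - depth)
                center = (center[0] - disk_centers[0, 0], center[1] - disk_centers[0, 1])
            else:
                lo = bound + 2.0
                if lo >= nr - bound - 2 or lo >= nc - bound - 2:
                    break
                center = (
                    rng.uniform(lo, nr - 1 - lo),
                    rng.uniform(lo, nc - 1 - lo),
                )
            if placed_centers:
                d = np.hypot(
                    np.array([c[0] for c in placed_centers]) - center[0],
                    np.array([c[1] for c in placed_centers]) - center[1],
                )
                if np.any(d <= np.array(placed_radii) + bound + 2.0):
                    continue
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place a {kind} particle after bounded retries: "
                f"too crowded (n_single={params.n_single}, "
                f"n_debris={params.n_debris}, n_aggregates={params.n_aggregates} "
                f"for image_shape={params.image_shape})"
            )
        pid += 1
        npx = _render_particle(label_image, pid, center, disk_centers, radii)
        if npx == 0:
            raise RuntimeError(f"{kind} particle rendered empty (radius too small?)")
        placed_centers.append(center)
        placed_radii.append(bound)
        rows.append(
            dict(
                particle_id=pid,
                true_class=kind,
                target_area_um2=target_area,
                component_count=k,
                centroid_row=center[0],
                centroid_col=center[1],
            )
        )

    mask = label_image > 0
    table = pd.DataFrame(
        rows,
        columns=[
            "particle_id",
            "true_class",
            "target_area_um2",
            "component_count",
            "centroid_row",
            "centroid_col",
        ],
    )
    if len(table):
        counts = np.bincount(label_image.ravel(), minlength=pid + 1)
        table["true_area_um2"] = counts[table["particle_id"].to_numpy()] * params.pixel_size**2
        border = np.zeros(pid + 1, bool)
        for edge in (label_image[0], label_image[-1], label_image[:, 0], label_image[:, -1]):
            border[np.unique(edge)] = True
        table["touches_border"] = border[table["particle_id"].to_numpy()]
    else:
        table["true_area_um2"] = np.empty(0)
        table["touches_border"] = np.empty(0, bool)
    return mask, GroundTruth2D(table=table, label_image=label_image, params=params)


# --------------------------------------------------------------------------
# 3-D scenes


@dataclass(frozen=True)
class Scene3DParams:
    """Layout and intensity model of a two-channel biofilm stack.

    The cell channel is either a uniform slab on the substrate or a set
    of substrate-attached hemispherical colonies grown until the target
    cell biovolume is reached. The EPS channel is constructed voxel by
    voxel to hit ``target_ratio`` (EPS/cell biovolume) with
    ``overlap_fraction`` of the EPS volume placed just inside the cell
    mask and the rest as a shell just outside it.

    Foreground voxels carry intensity ``background_level * (1 + snr)``;
    additive Gaussian noise (sd ``noise_sd``, default equal to
    ``background_level``, 0 for a noiseless scene) is clipped at zero
    and rounded to integer counts.
    """

    grid_shape: tuple[int, int, int] = (40, 64, 64)  # (z, y, x) voxels
    voxel_pitch: tuple[float, float, float] = (0.5, 0.25, 0.25)  # µm
    target_cell_biovolume: float = 800.0  # µm³
    target_ratio: float = 0.8
    overlap_fraction: float = 0.2
    geometry: str = "colonies"  # or "slab"
    slab_thickness: float = 5.0  # µm, slab mode
    colony_radius_range: tuple[float, float] = (1.5, 4.0)  # µm
    background_level: float = 40.0
    snr: float = 5.0
    noise_sd: float | None = None  # None -> background_level; 0 -> noiseless
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be three positive extents (z, y, x)")
        if any(p <= 0 for p in self.voxel_pitch):
            raise ValueError("voxel_pitch must be positive")
        if self.geometry not in ("slab", "colonies"):
            raise ValueError("geometry must be 'slab' or 'colonies'")
        if self.target_ratio < 0:
            raise ValueError("target_ratio must be >= 0")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.overlap_fraction * self.target_ratio > 1.0:
            raise ValueError(
                "overlap_fraction * target_ratio must be <= 1 "
                "(overlap volume cannot exceed the cell volume)"
            )
        v = float(np.prod(self.voxel_pitch))
        grid_volume = float(np.prod(self.grid_shape)) * v
        if self.geometry == "colonies" and self.target_cell_biovolume > grid_volume:
            raise ValueError(
                f"target_cell_biovolume {self.target_cell_biovolume} µm³ exceeds "
                f"grid volume {grid_volume:.1f} µm³"
            )
        if self.background_level <= 0 or self.snr < 0:
            raise ValueError("background_level must be > 0 and snr >= 0")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_pitch))


@dataclass
class GroundTruth3D:
    """Voxel-counted truth of a synthetic biofilm stack."""

    cell_volume: float  # µm³
    eps_volume: float
    overlap_volume: float
    thickness_map: np.ndarray  # 2-D µm over (y, x)
    cell_mask: np.ndarray
    eps_mask: np.ndarray
    params: Scene3DParams

    @property
    def mean_thickness(self) -> float:
        covered = self.cell_mask.any(axis=0)
        return float(self.thickness_map[covered].mean()) if covered.any() else 0.0


def _build_cell_mask(params: Scene3DParams, rng) -> np.ndarray:
    nz, ny, nx = params.grid_shape
    zp, yp, xp = params.voxel_pitch
    if params.geometry == "slab":
        n_planes = int(round(params.slab_thickness / zp))
        if n_planes < 1 or n_planes > nz:
            raise ValueError(
                f"slab_thickness {params.slab_thickness} µm needs {n_planes} z-planes; "
                f"grid has {nz}"
            )
        mask = np.zeros((nz, ny, nx), bool)
        mask[:n_planes] = True
        return mask
    target_vox = int(round(params.target_cell_biovolume / params.voxel_volume))
    if target_vox < 1:
        raise ValueError("target_cell_biovolume too small for this voxel pitch")
    mask = np.zeros((nz, ny, nx), bool)
    zz = (np.arange(nz) * zp)[:, None, None]
    yy = (np.arange(ny) * yp)[None, :, None]
    xx = (np.arange(nx) * xp)[None, None, :]
    for _ in range(10_000):
        if mask.sum() >= target_vox:
            break
        R = rng.uniform(*params.colony_radius_range)
        cy = rng.uniform(0, (ny - 1) * yp)
        cx = rng.uniform(0, (nx - 1) * xp)
        mask |= zz**2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= R * R
    else:
        raise RuntimeError("failed to reach target cell biovolume with colonies")
    return mask


def _pick_by_distance(mask_region: np.ndarray, count: int, pitch, rng) -> np.ndarray:
    """Flat indices of ``count`` voxels of the region nearest its boundary."""
    if count == 0:
        return np.empty(0, dtype=np.intp)
    dist = ndimage.distance_transform_edt(mask_region, sampling=pitch)
    flat = np.flatnonzero(mask_region.ravel())
    keys = dist.ravel()[flat]
    order = np.lexsort((rng.random(flat.size), keys))
    return flat[order[:count]]


def generate_biofilm_stack(params: Scene3DParams):
    """Build cell and EPS channels plus voxel-counted ground truth.

    Returns ``(cell_grid, eps_grid, truth)``; volumes in the truth are
    exact voxel counts times the voxel volume.
    """
    rng = np.random.default_rng(params.seed)
    v = params.voxel_volume
    cell_mask = _build_cell_mask(params, rng)
    n_cell = int(cell_mask.sum())
    if n_cell == 0:
        raise ValueError("cell mask is empty")

    n_eps = int(round(params.target_ratio * n_cell))
    n_overlap = min(int(round(params.overlap_fraction * n_eps)), n_cell)
    n_outside = n_eps - n_overlap
    outside_available = cell_mask.size - n_cell
    if n_outside > outside_available:
        raise ValueError(
            f"requested EPS volume needs {n_outside} voxels outside the cell mask "
            f"but only {outside_available} are available"
        )
    eps_mask = np.zeros_like(cell_mask)
    inside_idx = _pick_by_distance(cell_mask, n_overlap, params.voxel_pitch, rng)
    outside_idx = _pick_by_distance(~cell_mask, n_outside, params.voxel_pitch, rng)
    eps_mask.ravel()[inside_idx] = True
    eps_mask.ravel()[outside_idx] = True

    zp = params.voxel_pitch[0]
    nz = params.grid_shape[0]
    covered = cell_mask.any(axis=0)
    top = nz - 1 - np.argmax(cell_mask[::-1, :, :], axis=0)
    thickness = np.where(covered, (top + 1) * zp, 0.0)

    fg_level = params.background_level * (1.0 + params.snr)
    sd = params.background_level if params.noise_sd is None else params.noise_sd

    def render(mask, channel):
        img = np.full(mask.shape, params.background_level, dtype=float)
        img[mask] = fg_level
        if sd > 0:
            img += rng.normal(0.0, sd, size=mask.shape)
        img = np.round(np.clip(img, 0.0, None))
        return VolumeGrid(img, params.voxel_pitch, channel=channel)

    cell_grid = render(cell_mask, "cell")
    eps_grid = render(eps_mask, "eps")
    truth = GroundTruth3D(
        cell_volume=n_cell * v,
        eps_volume=int(eps_mask.sum()) * v,
        overlap_volume=int((eps_mask & cell_mask).sum()) * v,
        thickness_map=thickness,
        cell_mask=cell_mask,
        eps_mask=eps_mask,
        params=params,
    )
    return cell_grid, eps_grid, truth


# --------------------------------------------------------------------------
# fixtures on disk


def write_fixtures(directory, scenes2d=(), scenes3d=()) -> dict:
    """Write scenes as TIFF + CSV with a JSON manifest; returns the manifest.

    Each 2-D scene ``(mask, truth)`` becomes a mask TIFF and a truth
    CSV; each 3-D scene ``(cell, eps, truth)`` becomes a two-channel
    uint16 stack, a truth-mask stack, and a per-column thickness CSV.
    """
    from . import __version__
    from .imgio import write_mask, write_stack

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "scenes2d": [], "scenes3d": []}
    for i, (mask, truth) in enumerate(scenes2d):
        mask_path = directory / f"scene2d_{i:02d}_mask.tif"
        truth_path = directory / f"scene2d_{i:02d}_truth.csv"
        write_mask(mask_path, mask)
        truth.table.to_csv(truth_path, index=False)
        manifest["scenes2d"].append(
            dict(
                mask=mask_path.name,
                truth=truth_path.name,
                params=dataclasses.asdict(truth.params),
                seed=truth.params.seed,
            )
        )
    for i, (cell, eps, truth) in enumerate(scenes3d):
        stack_path = directory / f"scene3d_{i:02d}_stack.tif"
        masks_path = directory / f"scene3d_{i:02d}_truth_masks.tif"
        thick_path = directory / f"scene3d_{i:02d}_truth_thickness.csv"
        write_stack(stack_path, [cell, eps])
        write_stack(
            masks_path,
            [
                VolumeGrid(truth.cell_mask.astype(float), truth.params.voxel_pitch, "cell_mask"),
                VolumeGrid(truth.eps_mask.astype(float), truth.params.voxel_pitch, "eps_mask"),
            ],
        )
        ny, nx = truth.thickness_map.shape
        pd.DataFrame(
            dict(
                y=np.repeat(np.arange(ny), nx),
                x=np.tile(np.arange(nx), ny),
                thickness_um=truth.thickness_map.ravel(),
            )
        ).to_csv(thick_path, index=False)
        manifest["scenes3d"].append(
            dict(
                stack=stack_path.name,
                truth_masks=masks_path.name,
                truth_thickness=thick_path.name,
                channels=["cell", "eps"],
                true_cell_volume_um3=truth.cell_volume,
                true_eps_volume_um3=truth.eps_volume,
                true_overlap_volume_um3=truth.overlap_volume,
                params=dataclasses.asdict(truth.params),
                seed=truth.params.seed,
            )
        )
    try:
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except OSError as exc:
        raise OSError(f"failed writing manifest under {directory}: {exc}") from exc
    return manifest
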