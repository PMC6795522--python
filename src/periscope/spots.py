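"""FISH spot detection, signed spot-to-lamina distances, and peripheral
classification.

A spot is "peripheral" when the signed distance d from its intensity mass
centre to the lamina inner edge is smaller than or equal to the peripheral
heterochromatin layer thickness T (boundary equality counts as peripheral;
spots embedded in the lamina have d < 0 and are peripheral as well).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .confocal import LaminaSurface, PeripheryLayer
from .grids import BinaryMask3D, VoxelGrid3D

log = logging.getLogger(__name__)

# spots this far outside the nucleus edge are hybridization artifacts
_DISCARD_BEYOND_EDGE_UM = 2.0

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


@dataclass
class SpotCall:
    """A detected FISH spot (physical coordinates, μm)."""

    cell_id: str
    channel: str
    center_um: tuple[float, float, float]
    nominal_diameter_um: float = 0.25
    signed_distance_um: float | None = None
    peripheral: bool | None = None
    saturated: bool = False

    def __post_init__(self) -> None:
        if self.nominal_diameter_um <= 0:
            raise ValueError("nominal diameter must be positive")


@dataclass
class CellSummary:
    cell_id: str
    n_spots: dict[str, int]
    percent_peripheral: dict[str, float]
    distances_um: dict[str, list[float]]


@dataclass
class CohortSummary:
    pooled_distances_um: dict[str, np.ndarray]
    mean_percent_peripheral: dict[str, float]
    range_percent_peripheral: dict[str, tuple[float, float]]
    distance_percentiles: dict[str, dict[int, float]]  # 5/25/50/75/95
    n_cells: int
    reference_surface: str = "lamina"


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_spots(fish: VoxelGrid3D, nucleus: BinaryMask3D,
                 expected_diameter_um: float = 0.25,
                 cell_id: str = "", channel: str | None = None,
                 threshold_nsigma: float = 6.0) -> list[SpotCall]:
    """Detect diffraction-limited spots in a FISH channel.

    Local maxima of a band-pass (difference-of-Gaussians) filtered volume
    above a robust automatic threshold, refined to the intensity-weighted
    centroid within a sphere of the expected diameter; minimum pairwise
    separation equals the expected diameter. Returns an empty list when
    nothing exceeds the threshold.
    """
    if expected_diameter_um <= 0:
        raise ValueError("expected diameter must be positive")
    if fish.shape != nucleus.shape:
        raise ValueError("FISH channel and nucleus mask shapes differ")
    channel = channel if channel is not None else fish.channel_name

    dz, dy, dx = fish.sampling_zyx
    sig1 = np.array([expected_diameter_um / 4 / dz,
                     expected_diameter_um / 4 / dy,
                     expected_diameter_um / 4 / dx])
    dog = ndimage.gaussian_filter(fish.intensities, sig1) \
        - ndimage.gaussian_filter(fish.intensities, 3 * sig1)

    search = ndimage.binary_dilation(nucleus.mask, iterations=3)
    vals = dog[search]
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    thr = med + threshold_nsigma * 1.4826 * max(mad, 1e-12)

    saturated = bool(np.mean(fish.intensities >= fish.intensities.max()) > 0.01)
    if saturated:
        warnings.warn("FISH channel looks saturated; spot centroids may be biased")

    # local maxima with anisotropic physical footprint of the expected diameter
    fz = max(int(round(expected_diameter_um / dz)) | 1, 3)
    fy = max(int(round(expected_diameter_um / dy)) | 1, 3)
    fx = max(int(round(expected_diameter_um / dx)) | 1, 3)
    maxf = ndimage.maximum_filter(dog, size=(fz, fy, fx))
    peaks = (dog == maxf) & (dog > thr) & search
    coords = np.argwhere(peaks)
    if coords.size == 0:
        return []

    # order by peak strength; greedy suppression at the expected diameter
    order = np.argsort(dog[tuple(coords.T)])[::-1]
    coords = coords[order]
    scale = np.array([dz, dy, dx])
    kept: list[np.ndarray] = []
    for c in coords:
        pc = c * scale
        if all(np.linalg.norm(pc - k) >= expected_diameter_um for k in kept):
            kept.append(pc)
    centers_zyx = [k / scale for k in kept]

    # refine: intensity-weighted centroid within a sphere of expected diameter
    radius = expected_diameter_um
    rz, ry, rx = int(np.ceil(radius / dz)), int(np.ceil(radius / dy)), int(np.ceil(radius / dx))
    img = fish.intensities
    calls: list[SpotCall] = []
    nzyx = np.array(img.shape)
    for c in centers_zyx:
        ci = np.round(c).astype(int)
        lo = np.maximum(ci - [rz, ry, rx], 0)
        hi = np.minimum(ci + [rz, ry, rx] + 1, nzyx)
        sub = img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        zz, yy, xx = np.meshgrid(*(np.arange(lo[a], hi[a]) for a in range(3)), indexing="ij")
        dist2 = (((zz - c[0]) * dz) ** 2 + ((yy - c[1]) * dy) ** 2 + ((xx - c[2]) * dx) ** 2)
        w = np.where(dist2 <= radius ** 2, sub, 0.0)
        # weight above local floor so the centroid reflects the spot, not background
        w = np.clip(w - np.median(sub), 0, None)
        if w.sum() <= 0:
            continue
        cz = float((w * zz).sum() / w.sum())
        cy = float((w * yy).sum() / w.sum())
        cx = float((w * xx).sum() / w.sum())
        x_um, y_um, z_um = (cx + 0.5) * dx, (cy + 0.5) * dy, (cz + 0.5) * dz
        calls.append(SpotCall(cell_id=cell_id, channel=channel,
                              center_um=(x_um, y_um, z_um),
                              nominal_diameter_um=expected_diameter_um,
                              saturated=saturated))
    return calls


# ---------------------------------------------------------------------------
# distances and classification
# ---------------------------------------------------------------------------

def spot_distances(spots: list[SpotCall], lamina: LaminaSurface,
                   discard_beyond_um: float = _DISCARD_BEYOND_EDGE_UM) -> list[SpotCall]:
    """Attach signed lamina distances (trilinear sampling of the field).

    Spots falling further than ``discard_beyond_um`` outside the lamina
    region (beyond the outer shell face) are discarded with a warning —
    these are hybridization artifacts outside the nucleus.
    """
    if not spots:
        return []
    shape = lamina.signed_distance.shape
    dx, dy, dz = lamina.voxel_size
    extent = (shape[2] * dx, shape[1] * dy, shape[0] * dz)
    pts = np.array([s.center_um for s in spots])
    if np.any(pts < 0) or np.any(pts > np.array(extent)):
        raise ValueError("spot centre outside the volume bounds")
    d = lamina.distance_at(pts)
    out: list[SpotCall] = []
    n_discarded = 0
    shell_depth = float(np.min(lamina.signed_distance[lamina.lamina_mask.mask])) \
        if lamina.lamina_mask.mask.any() else 0.0
    for s, di in zip(spots, d):
        if di < shell_depth - discard_beyond_um:
            n_discarded += 1
            continue
        out.append(replace(s, signed_distance_um=float(di)))
    if n_discarded:
        log.warning("discarded %d spot(s) > %.1f μm outside the nuclear edge",
                    n_discarded, discard_beyond_um)
    return out


def classify_spot(spot: SpotCall, layer: PeripheryLayer) -> SpotCall:
    """Peripheral iff signed distance d ≤ layer thickness T (d = T counts;
    negative d, i.e. embedded in the lamina, counts)."""
    if spot.signed_distance_um is None:
        raise ValueError("spot has no signed distance; run spot_distances first")
    return replace(spot, peripheral=bool(spot.signed_distance_um <= layer.thickness_T))


def classify_spots(spots: list[SpotCall], layer: PeripheryLayer) -> list[SpotCall]:
    return [classify_spot(s, layer) for s in spots]


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

_PCTS = (5, 25, 50, 75, 95)


def summarize_cells(spots: list[SpotCall],
                    reference_surface: str = "lamina") -> tuple[list[CellSummary], CohortSummary]:
    """Per-cell percent-peripheral and cohort distance summaries.

    Cells contribute equally to the cohort mean (mean of per-cell
    percentages); distance percentiles (5/25/50/75/95, linear interpolation
    between order statistics) are computed on the pooled distances.
    Cells with zero classified spots are excluded with a logged warning.
    """
    if not spots:
        raise ValueError("no spots to summarize")
    for s in spots:
        if s.peripheral is None or s.signed_distance_um is None:
            raise ValueError("spots must be classified before summarizing")

    by_cell: dict[str, list[SpotCall]] = {}
    for s in spots:
        by_cell.setdefault(s.cell_id, []).append(s)

    channels = sorted({s.channel for s in spots})
    cell_summaries: list[CellSummary] = []
    for cell_id, cell_spots in sorted(by_cell.items()):
        if not cell_spots:
            log.warning("cell %s has zero spots; excluded", cell_id)
            continue
        n, pct, dists = {}, {}, {}
        for ch in channels:
            chs = [s for s in cell_spots if s.channel == ch]
            if not chs:
                continue
            n[ch] = len(chs)
            pct[ch] = 100.0 * sum(s.peripheral for s in chs) / len(chs)
            dists[ch] = [s.signed_distance_um for s in chs]
        cell_summaries.append(CellSummary(cell_id, n, pct, dists))

    pooled: dict[str, np.ndarray] = {}
    mean_pct: dict[str, float] = {}
    rng_pct: dict[str, tuple[float, float]] = {}
    percentiles: dict[str, dict[int, float]] = {}
    for ch in channels:
        pool = np.concatenate([np.asarray(c.distances_um[ch]) for c in cell_summaries
                               if ch in c.distances_um])
        pooled[ch] = pool
        pcts = [c.percent_peripheral[ch] for c in cell_summaries if ch in c.percent_peripheral]
        mean_pct[ch] = float(np.mean(pcts))
        rng_pct[ch] = (float(np.min(pcts)), float(np.max(pcts)))
        percentiles[ch] = {p: float(np.percentile(pool, p, method="linear")) for p in _PCTS}

    cohort = CohortSummary(
        pooled_distances_um=pooled,
        mean_percent_peripheral=mean_pct,
        range_percent_peripheral=rng_pct,
        distance_percentiles=percentiles,
        n_cells=len(cell_summaries),
        reference_surface=reference_surface,
    )
    return cell_summaries, cohort


def dna_edge_surface(nucleus: BinaryMask3D) -> LaminaSurface:
    """Alternative reference surface: the DNA (nucleus-mask) edge.

    Used for mitotic stages lacking a lamina: the "shell" is the one-voxel
    outer boundary of the nucleus mask and distances are measured from it
    with the same sign convention.
    """
    m = nucleus.mask
    eroded = ndimage.binary_erosion(m, structure=_FACE_STRUCT)
    edge = m & ~eroded
    interior = eroded
    dz_dy_dx = (nucleus.voxel_size[2], nucleus.voxel_size[1], nucleus.voxel_size[0])
    dist = ndimage.distance_transform_edt(~edge, sampling=dz_dy_dx)
    signed = np.where(interior, dist, -dist)
    signed[edge] = 0.0
    return LaminaSurface(
        lamina_mask=BinaryMask3D(edge, nucleus.voxel_size, provenance="dna-edge"),
        inner_edge_mask=BinaryMask3D(edge, nucleus.voxel_size, provenance="dna-edge"),
        interior_mask=BinaryMask3D(interior, nucleus.voxel_size, provenance="dna interior"),
        signed_distance=signed,
        voxel_size=nucleus.voxel_size,
    )
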