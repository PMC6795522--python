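"""Ground-truthed synthetic nuclei and single-molecule localization tables.

The generator emulates the specimens the downstream quantification is built
for: an ellipsoidal interphase nucleus whose boundary carries a thin lamina
shell, a peripheral heterochromatin band of configurable thickness T inside
the lamina inner edge, diffraction-limited FISH spots placed at controlled
signed distances from the lamina inner edge, and STORM-style 2D point clouds
mixing a uniform (CSR) background with denser clustered or peripheral-band
components.

Geometry convention: the nucleus ellipsoid (``center``, ``semi_axes``) is
the *outer* nuclear boundary; the lamina shell extends inward from it by
``lamina_shell_thickness`` and its inner edge is the offset surface at that
depth. Signed distances d are measured from the lamina inner edge, positive
toward the nuclear interior: the shell occupies ``-shell <= d <= 0`` and the
heterochromatin band ``0 < d <= T``, so the nuclear centre sits at
``d = min(semi_axes) - shell``. Because the Euclidean distance-to-ellipsoid
field D has unit gradient, the exact distance to the offset inner edge is
simply ``d = D - shell``; D itself comes from a numerical nearest-point
solve on the implicit surface, independent of any voxel-based segmentation
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import VoxelGrid3D

_PLACEMENT_RETRIES = 1000

# camera model constants: uniform background level (photons) and Gaussian
# read noise (photons); SNR = peak spot amplitude / sqrt(bg + read_sigma^2)
_BACKGROUND_PHOTONS = 20.0
_READ_NOISE_SIGMA = 3.0


# ---------------------------------------------------------------------------
# exact point-to-ellipsoid distance
# ---------------------------------------------------------------------------

def ellipsoid_signed_distance(points: np.ndarray, center: np.ndarray,
                              semi_axes: np.ndarray, iters: int = 100) -> np.ndarray:
    """Exact signed Euclidean distance from points to an ellipsoid surface.

    Positive inside the ellipsoid, negative outside. Solves the Lagrange
    nearest-point condition ``x_i = e_i^2 p_i / (e_i^2 + t)`` for the largest
    root of ``sum((e_i p_i / (e_i^2 + t))^2) = 1`` by vectorised bisection.

    Parameters
    ----------
    points : (n, 3) array, physical (x, y, z)
    center, semi_axes : (3,) arrays
    """
    p = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(center, dtype=float)
    e = np.asarray(semi_axes, dtype=float)
    if np.any(e <= 0):
        raise ValueError("semi-axes must be positive")
    e2 = e ** 2

    q = (p / e) ** 2
    inside = q.sum(axis=1) <= 1.0

    # bracket the largest root: f is strictly decreasing in t on (-min(e^2), inf)
    t_lo = np.full(len(p), -e2.min() * (1.0 - 1e-12))
    t_hi = np.full(len(p), np.linalg.norm(p, axis=1) * e.max() + e2.max() + 1.0)

    def f(t: np.ndarray) -> np.ndarray:
        return ((e * p) ** 2 / (e2 + t[:, None]) ** 2).sum(axis=1) - 1.0

    t = 0.5 * (t_lo + t_hi)
    for _ in range(iters):
        mid = 0.5 * (t_lo + t_hi)
        pos = f(mid) > 0
        t_lo = np.where(pos, mid, t_lo)
        t_hi = np.where(pos, t_hi, mid)
        t = 0.5 * (t_lo + t_hi)

    x = (e2 * p) / (e2 + t[:, None])
    dist = np.linalg.norm(x - p, axis=1)
    # degenerate: point at the exact centre -> nearest surface point on min axis
    at_center = np.all(p == 0.0, axis=1)
    dist = np.where(at_center, e.min(), dist)
    return np.where(inside, dist, -dist)


def _surface_point_and_normal(direction: np.ndarray, semi_axes: np.ndarray):
    """Surface point along a ray from the centre, with the inward unit normal."""
    e = np.asarray(semi_axes, dtype=float)
    u = direction / np.linalg.norm(direction)
    r = 1.0 / np.sqrt(((u / e) ** 2).sum())
    x = r * u
    grad = 2.0 * x / e ** 2  # outward normal direction
    n_in = -grad / np.linalg.norm(grad)
    return x, n_in


# ---------------------------------------------------------------------------
# parameter and ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class NucleusParams:
    """Generation parameters for one synthetic nucleus.

    All lengths in μm. ``semi_axes`` define the outer nuclear boundary; the
    lamina shell extends inward by ``lamina_shell_thickness`` and the
    peripheral heterochromatin band a further ``layer_thickness_T`` inward
    of the shell's inner edge.
    ``f_lad_peripheral`` / ``f_nonlad_peripheral`` are the probabilities that
    a LAD-like / non-LAD-like FISH spot is placed within the peripheral band
    (signed distance in ``[-shell, T]``); the complement is placed deeper in
    the nucleoplasm (distance in ``(T, depth_max]``). ``snr=None`` renders
    noiseless channels.
    """

    semi_axes: tuple[float, float, float] = (2.2, 1.8, 1.4)
    lamina_shell_thickness: float = 0.25
    layer_thickness_T: float = 0.4
    n_lad_spots: int = 20
    n_nonlad_spots: int = 20
    f_lad_peripheral: float = 0.82
    f_nonlad_peripheral: float = 0.11
    spot_sigma: tuple[float, float, float] = (0.08, 0.08, 0.12)  # (x, y, z)
    snr: float | None = 10.0
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.05)  # (dx, dy, dz)
    margin: float = 0.5
    min_spot_separation: float = 0.3
    signal_share_peripheral: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.semi_axes = tuple(float(a) for a in self.semi_axes)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.spot_sigma = tuple(float(s) for s in self.spot_sigma)
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi_axes must be positive")
        if self.lamina_shell_thickness <= 0:
            raise ValueError("lamina_shell_thickness must be positive")
        if not 0 <= self.f_lad_peripheral <= 1 or not 0 <= self.f_nonlad_peripheral <= 1:
            raise ValueError("peripheral placement probabilities must lie in [0, 1]")
        if self.layer_thickness_T <= 0:
            raise ValueError("layer_thickness_T must be positive")
        if self.layer_thickness_T >= min(self.semi_axes):
            raise ValueError("layer thickness T must be smaller than the smallest semi-axis")
        if self.layer_thickness_T + self.lamina_shell_thickness >= min(self.semi_axes):
            raise ValueError("shell + layer thickness must be smaller than the smallest semi-axis")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size components must be positive")
        if any(s <= 0 for s in self.spot_sigma):
            raise ValueError("spot_sigma components must be positive")
        if self.n_lad_spots < 0 or self.n_nonlad_spots < 0:
            raise ValueError("spot counts must be non-negative")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive (or None for noiseless)")
        if self.signal_share_peripheral is not None and not 0 < self.signal_share_peripheral < 1:
            raise ValueError("signal_share_peripheral must lie in (0, 1)")


@dataclass
class SpotTruth:
    label: str                       # "LAD" | "nonLAD"
    center_um: tuple[float, float, float]
    signed_distance_um: float        # exact distance to the lamina inner edge
    peripheral: bool                 # == (signed_distance_um <= T)


@dataclass
class NucleusGroundTruth:
    center_um: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float]      # lamina inner-edge ellipsoid
    shell_thickness_um: float
    layer_thickness_um: float
    spots: list[SpotTruth] = field(default_factory=list)
    signal_share_peripheral: float | None = None
    seed: int = 0


class SpotPlacementError(RuntimeError):
    """Raised when requested spots cannot be placed within the retry limit."""


# ---------------------------------------------------------------------------
# nucleus image generation
# ---------------------------------------------------------------------------

def _distance_field(shape_zyx, voxel_size, center, semi_axes) -> np.ndarray:
    nz, ny, nx = shape_zyx
    dx, dy, dz = voxel_size
    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dy
    z = (np.arange(nz) + 0.5) * dz
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    d = ellipsoid_signed_distance(pts, center, semi_axes)
    return d.reshape(shape_zyx)


def _place_spots(rng: np.random.Generator, n: int, f_peripheral: float,
                 params: NucleusParams, center: np.ndarray,
                 existing: list[np.ndarray]) -> list[tuple[np.ndarray, float, bool]]:
    """Place spots by class-conditional rejection sampling.

    Each spot first draws its class (peripheral with probability
    ``f_peripheral``), then a position whose *exact* signed distance to the
    inner-edge ellipsoid realises that class, keeping the ground-truth flag
    consistent with the distance by construction.
    """
    e = np.asarray(params.semi_axes)
    shell = params.lamina_shell_thickness
    T = params.layer_thickness_T
    depth_max = float(e.min()) - shell  # signed distance of the nuclear centre
    min_sep = params.min_spot_separation
    out: list[tuple[np.ndarray, float, bool]] = []
    placed = list(existing)

    for _ in range(n):
        peripheral = bool(rng.random() < f_peripheral)
        for attempt in range(_PLACEMENT_RETRIES):
            if peripheral:
                d_target = rng.uniform(-shell, T)
            else:
                d_target = rng.uniform(T, depth_max)
            u = rng.normal(size=3)
            xs, n_in = _surface_point_and_normal(u, e)
            pos = center + xs + (d_target + shell) * n_in
            # exact signed distance to the inner edge: D(outer ellipsoid) - shell
            d_exact = float(ellipsoid_signed_distance(pos[None, :], center, e)[0]) - shell
            ok_class = (d_exact <= T) if peripheral else (d_exact > T)
            # embedded spots must stay within the shell (inside the nucleus)
            if d_exact < -shell:
                ok_class = False
            if not ok_class:
                continue
            if placed and min(np.linalg.norm(pos - q) for q in placed) < min_sep:
                continue
            placed.append(pos)
            out.append((pos, d_exact, peripheral))
            break
        else:
            raise SpotPlacementError(
                f"could not place spot (peripheral={peripheral}) within "
                f"{_PLACEMENT_RETRIES} attempts; reduce counts or min separation"
            )
    return out


def _render_gaussian_spots(shape_zyx, voxel_size, centers_um, sigma_um) -> np.ndarray:
    """Render unit-amplitude anisotropic Gaussians at physical centres."""
    vol = np.zeros(shape_zyx, dtype=np.float64)
    if not centers_um:
        return vol
    nz, ny, nx = shape_zyx
    dx, dy, dz = voxel_size
    sx, sy, sz = sigma_um
    # evaluate each spot on a local 4-sigma window (separable product)
    for c in centers_um:
        cx, cy, cz = c
        ix0 = max(int((cx - 4 * sx) / dx), 0)
        ix1 = min(int((cx + 4 * sx) / dx) + 2, nx)
        iy0 = max(int((cy - 4 * sy) / dy), 0)
        iy1 = min(int((cy + 4 * sy) / dy) + 2, ny)
        iz0 = max(int((cz - 4 * sz) / dz), 0)
        iz1 = min(int((cz + 4 * sz) / dz) + 2, nz)
        if ix0 >= ix1 or iy0 >= iy1 or iz0 >= iz1:
            continue
        gx = np.exp(-((np.arange(ix0, ix1) + 0.5) * dx - cx) ** 2 / (2 * sx ** 2))
        gy = np.exp(-((np.arange(iy0, iy1) + 0.5) * dy - cy) ** 2 / (2 * sy ** 2))
        gz = np.exp(-((np.arange(iz0, iz1) + 0.5) * dz - cz) ** 2 / (2 * sz ** 2))
        vol[iz0:iz1, iy0:iy1, ix0:ix1] += gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    return vol


def _blur(volume: np.ndarray, sigma_um, voxel_size) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    sx, sy, sz = sigma_um
    dx, dy, dz = voxel_size
    return gaussian_filter(volume, sigma=(sz / dz, sy / dy, sx / dx))


def _add_noise(volume: np.ndarray, snr: float | None, rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise on the signal plus additive Gaussian read noise.

    ``volume`` holds the normalised structure in [0, ~1]; it is scaled so
    that a unit-amplitude feature has peak SNR ``snr`` against the
    background fluctuations, then Poisson-sampled.
    """
    if snr is None:
        return volume
    amp = snr * np.sqrt(_BACKGROUND_PHOTONS + _READ_NOISE_SIGMA ** 2)
    lam = _BACKGROUND_PHOTONS + amp * np.clip(volume, 0, None)
    counts = rng.poisson(lam).astype(np.float64)
    counts += rng.normal(0.0, _READ_NOISE_SIGMA, size=volume.shape)
    return np.clip(counts, 0, None)


def generate_nucleus_image(params: NucleusParams) -> tuple[dict[str, VoxelGrid3D], NucleusGroundTruth]:
    """Generate one synthetic nucleus as a set of channels plus ground truth.

    Returns
    -------
    channels : dict of VoxelGrid3D
        Keys ``dna``, ``lamina``, ``h3k9me2``, ``lad_fish``, ``nonlad_fish``
        and, when ``signal_share_peripheral`` is set, ``signal``.
    truth : NucleusGroundTruth
        Exact spot positions/distances/flags and the generating geometry.

    Identical params (including seed) give bit-identical outputs.
    """
    rng = np.random.default_rng(params.seed)
    e = np.asarray(params.semi_axes)
    shell = params.lamina_shell_thickness
    T = params.layer_thickness_T
    dx, dy, dz = params.voxel_size
    m = params.margin

    half = e + m
    nx = int(np.ceil(2 * half[0] / dx))
    ny = int(np.ceil(2 * half[1] / dy))
    nz = int(np.ceil(2 * half[2] / dz))
    shape = (nz, ny, nx)
    center = np.array([nx * dx / 2.0, ny * dy / 2.0, nz * dz / 2.0])

    # signed distance to the lamina inner edge (offset surface at depth shell)
    D = _distance_field(shape, params.voxel_size, center, e) - shell

    dna_mask = D >= -shell            # whole nucleus, outer boundary included
    lamina_mask = (D >= -shell) & (D <= 0.0)
    band_mask = (D > 0.0) & (D <= T)

    # spots: LADs first, then non-LADs, sharing the separation constraint
    lad = _place_spots(rng, params.n_lad_spots, params.f_lad_peripheral, params, center, [])
    nonlad = _place_spots(rng, params.n_nonlad_spots, params.f_nonlad_peripheral,
                          params, center, [p for p, _, _ in lad])

    truth = NucleusGroundTruth(
        center_um=tuple(center),
        semi_axes_um=tuple(e),
        shell_thickness_um=shell,
        layer_thickness_um=T,
        seed=params.seed,
        signal_share_peripheral=params.signal_share_peripheral,
    )
    for pos, d, flag in lad:
        truth.spots.append(SpotTruth("LAD", tuple(pos), d, flag))
    for pos, d, flag in nonlad:
        truth.spots.append(SpotTruth("nonLAD", tuple(pos), d, flag))

    sigma = params.spot_sigma
    vs = params.voxel_size
    raw = {
        "dna": _blur(dna_mask.astype(float), sigma, vs),
        "lamina": _blur(lamina_mask.astype(float), sigma, vs),
        "h3k9me2": _blur(band_mask.astype(float), sigma, vs),
        "lad_fish": _render_gaussian_spots(shape, vs, [p for p, _, _ in lad], sigma),
        "nonlad_fish": _render_gaussian_spots(shape, vs, [p for p, _, _ in nonlad], sigma),
    }

    if params.signal_share_peripheral is not None:
        s = params.signal_share_peripheral
        band_blur = raw["h3k9me2"]
        interior_mask = D > T
        int_blur = _blur(interior_mask.astype(float), sigma, vs)
        peri_region = dna_mask & (D <= T)
        nuc_region = dna_mask
        P_b, T_b = band_blur[peri_region].sum(), band_blur[nuc_region].sum()
        P_i, T_i = int_blur[peri_region].sum(), int_blur[nuc_region].sum()
        # solve amplitude so the noiseless rendered peripheral share equals s
        denom = P_b - s * T_b
        if denom <= 0:
            raise ValueError(f"requested peripheral share {s} is not renderable")
        ap = (s * T_i - P_i) / denom
        if ap <= 0:
            raise ValueError(f"requested peripheral share {s} is not renderable")
        raw["signal"] = ap * band_blur + int_blur

    channels = {
        name: VoxelGrid3D(_add_noise(vol, params.snr, rng), vs, channel_name=name)
        for name, vol in raw.items()
    }
    return channels, truth


# ---------------------------------------------------------------------------
# STORM localization generator
# ---------------------------------------------------------------------------

@dataclass
class StormParams:
    """Parameters for a synthetic 2D localization table (all lengths in nm).

    ``region`` is ``(xmin, ymin, xmax, ymax)``. Clusters are
    ``(cx, cy, radius, n)``; points are isotropic Gaussian with
    ``sigma = radius / 2`` truncated to the region. ``peripheral_band`` is
    ``(cx, cy, r_inner, r_outer, n)`` with points uniform over the annulus.
    """

    region: tuple[float, float, float, float] = (0.0, 0.0, 10000.0, 10000.0)
    n_background: int = 1000
    clusters: list[tuple[float, float, float, int]] = field(default_factory=list)
    peripheral_band: tuple[float, float, float, float, int] | None = None
    localization_jitter_sigma: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.region
        if x1 <= x0 or y1 <= y0:
            raise ValueError("region must have positive area")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")
        for c in self.clusters:
            if c[2] <= 0 or c[3] < 0:
                raise ValueError("cluster radii must be > 0 and counts >= 0")
        if self.localization_jitter_sigma < 0:
            raise ValueError("jitter sigma must be >= 0")


def generate_storm_localizations(params: StormParams) -> pd.DataFrame:
    """Generate a localization table mixing CSR background with clusters.

    Returns a DataFrame with columns ``x_nm, y_nm, frame, label`` where
    ``label`` is the ground-truth component (``background``, ``cluster_<i>``
    or ``band``). The uniform component realises a complete-spatial-
    randomness null. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    x0, y0, x1, y1 = params.region
    xs, ys, labels = [], [], []

    xs.append(rng.uniform(x0, x1, params.n_background))
    ys.append(rng.uniform(y0, y1, params.n_background))
    labels.extend(["background"] * params.n_background)

    for i, (cx, cy, radius, n) in enumerate(params.clusters):
        sigma = radius / 2.0
        pts = np.empty((0, 2))
        while len(pts) < n:
            cand = rng.normal([cx, cy], sigma, size=(max(n, 16), 2))
            keep = (cand[:, 0] >= x0) & (cand[:, 0] <= x1) & (cand[:, 1] >= y0) & (cand[:, 1] <= y1)
            pts = np.vstack([pts, cand[keep]])
        pts = pts[:n]
        xs.append(pts[:, 0])
        ys.append(pts[:, 1])
        labels.extend([f"cluster_{i}"] * n)

    if params.peripheral_band is not None:
        cx, cy, r_in, r_out, n = params.peripheral_band
        r = np.sqrt(rng.uniform(r_in ** 2, r_out ** 2, n))
        theta = rng.uniform(0, 2 * np.pi, n)
        bx = np.clip(cx + r * np.cos(theta), x0, x1)
        by = np.clip(cy + r * np.sin(theta), y0, y1)
        xs.append(bx)
        ys.append(by)
        labels.extend(["band"] * n)

    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if params.localization_jitter_sigma > 0:
        x = x + rng.normal(0, params.localization_jitter_sigma, len(x))
        y = y + rng.normal(0, params.localization_jitter_sigma, len(y))
    x = np.clip(x, x0, x1)
    y = np.clip(y, y0, y1)

    return pd.DataFrame({
        "x_nm": x,
        "y_nm": y,
        "frame": np.arange(len(x), dtype=int),
        "label": labels,
    })
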