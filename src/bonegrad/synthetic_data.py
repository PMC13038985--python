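"""Synthetic cortical-bone phantoms and compression curves with exact truth.

The phantom emulates a long-bone cortical shell: a hollow cylinder whose
wall carries straight, axis-parallel canal cylinders (the dominant
orientation of Haversian canals in shaft cortex).  Canal density and radius
follow prescribed profiles in longitudinal fraction and cortical depth, so
the phantom reproduces the gradients seen in real shaft cortex: a dense
mid-shaft (void fraction a few percent, canal diameters ~40 µm) grading to
porous ends (void fraction tens of percent, diameters ~110 µm), and a void
network that widens from the periosteal surface toward the medullary
cavity.  Placement is rejection sampling of non-overlapping cylinders, so
the ground-truth label volume is exact: every void voxel belongs to exactly
one canal and total void volume is the sum of per-canal volumes.

Synthetic compression records mirror the two-regime behaviour of transverse
bone slices under uniaxial load: a stiff first linear region, a compliant
second linear region joined continuously at a breakpoint strain, and an
optional terminal stress drop past the peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import gradient_profiling
from .gradient_profiling import ROISpec, SlicePlan
from .segmentation import GrayscaleVolume

__all__ = [
    "PhantomSpec",
    "CanalRecord",
    "PhantomGroundTruth",
    "SyntheticCurveSpec",
    "StressStrainData",
    "PackingError",
    "default_porosity_profile",
    "default_diameter_profile",
    "default_phantom_spec",
    "demo_phantom_spec",
    "generate_cortical_phantom",
    "true_profile",
    "generate_stress_strain",
    "moduli_from_porosity",
]


class PackingError(RuntimeError):
    """Raised when a target void fraction is unreachable at the drawn radii."""


def _edge_weight(s: float) -> float:
    """0 at mid-shaft, 1 at either end; quadratic in the offset from mid."""
    return (2.0 * (s - 0.5)) ** 2


def default_porosity_profile(s: float, depth_um: float) -> float:
    """Target void fraction: 0.05 at mid-shaft to 0.40 at the ends (at the
    750 µm reference depth), decreasing toward the periosteal surface."""
    radial = 0.5 + 0.5 * min(depth_um, 750.0) / 750.0
    return (0.05 + 0.35 * _edge_weight(s)) * radial


def default_diameter_profile(s: float, depth_um: float) -> float:
    """Mean canal diameter (µm): 40 at mid-shaft to 110 at the ends.

    The default carries the longitudinal gradient only; radial widening of
    the void network is expressed through the porosity profile.  A
    depth-dependent diameter profile can be supplied per spec.
    """
    return 40.0 + 70.0 * _edge_weight(s)


@dataclass
class CanalRecord:
    """One straight canal: in-plane centre, radius, and longitudinal span (µm)."""

    id: int
    center: tuple[float, float]  # (y, x) µm
    radius: float
    longitudinal_span: tuple[float, float]

    @property
    def center_path(self) -> list[tuple[float, float, float]]:
        z0, z1 = self.longitudinal_span
        cy, cx = self.center
        return [(z0, cy, cx), (z1, cy, cx)]

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass
class PhantomSpec:
    """Geometry, gradient profiles and imaging parameters of a phantom.

    The wall thickness is ``outer_radius - inner_radius`` at the ends and
    gains ``wall_gain`` µm at mid-shaft (so the cortical-thickness profile
    peaks centrally, as shaft cortex does); ``inner_radius_profile``
    overrides this with an arbitrary cavity-radius function of the
    longitudinal fraction.  Profiles are callables of
    (longitudinal_fraction in [0, 1], depth_um from the outer surface).
    """

    outer_radius: float = 1100.0
    inner_radius: float = 340.0
    length: float = 5000.0
    voxel_size: float = 5.8
    wall_gain: float = 190.0
    inner_radius_profile: Callable[[float], float] | None = None
    canal_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)  # (z, y, x)
    porosity_profile: Callable[[float, float], float] = default_porosity_profile
    diameter_profile: Callable[[float, float], float] = default_diameter_profile
    diameter_cv: float = 0.25
    min_diameter: float | None = None  # default: 4 voxels
    bone_intensity: int = 200
    void_intensity: int = 20
    noise_sd: float = 0.0
    seed: int = 0
    band_length: float = 1000.0
    cell_depth: float = 250.0
    forced_canals: Sequence[tuple[float, float, float]] | None = None  # (y, x, r) µm
    max_attempts_factor: int = 600

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if not self.inner_radius < self.outer_radius:
            raise ValueError("inner_radius must be smaller than outer_radius")
        if tuple(self.canal_axis) != (1.0, 0.0, 0.0):
            raise NotImplementedError("canals are modelled parallel to the long (z) axis")
        if not (self.bone_intensity >= 80 and self.void_intensity < 80):
            raise ValueError(
                "bone_intensity must be >= 80 and void_intensity < 80 so the default "
                "segmentation threshold separates the phases"
            )

    def inner_radius_at(self, s: float) -> float:
        if self.inner_radius_profile is not None:
            r = float(self.inner_radius_profile(s))
        else:
            wall = (self.outer_radius - self.inner_radius) + self.wall_gain * (1.0 - _edge_weight(s))
            r = self.outer_radius - wall
        if not 0.0 <= r < self.outer_radius:
            raise ValueError(f"inner radius {r:.1f} µm at s={s:.3f} outside [0, outer_radius)")
        return r

    @property
    def min_diameter_resolved(self) -> float:
        return self.min_diameter if self.min_diameter is not None else 4.0 * self.voxel_size


@dataclass
class PhantomGroundTruth:
    """Exact record of a generated phantom.

    ``label_volume``: 0 = background (exterior + medullary cavity), 1 =
    bone, canal id + 1 = that canal's void.
    """

    canals: list[CanalRecord]
    label_volume: np.ndarray
    spec: PhantomSpec

    @property
    def bone_mask(self) -> np.ndarray:
        return self.label_volume == 1

    @property
    def void_mask(self) -> np.ndarray:
        return self.label_volume >= 2


def default_phantom_spec(seed: int = 0, noise_sd: float = 0.0) -> PhantomSpec:
    """The reference graded phantom used throughout the synthetic study."""
    return PhantomSpec(seed=seed, noise_sd=noise_sd)


def demo_phantom_spec(seed: int = 0, noise_sd: float = 10.0) -> PhantomSpec:
    """A lighter phantom for the end-to-end demo pipeline."""
    return PhantomSpec(
        outer_radius=800.0,
        inner_radius=300.0,
        length=4000.0,
        wall_gain=150.0,
        noise_sd=noise_sd,
        seed=seed,
    )


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + cv * cv)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _grid(spec: PhantomSpec) -> tuple[int, int, np.ndarray, float]:
    """(nz, n, squared in-plane distance map, plane centre) for the phantom."""
    vox = spec.voxel_size
    half = spec.outer_radius + 4.0 * vox
    n = 2 * int(math.ceil(half / vox))
    nz = int(math.floor(spec.length / vox + 0.5))
    c0 = n * vox / 2.0
    coords = (np.arange(n) + 0.5) * vox - c0
    dist2 = coords[:, None] ** 2 + coords[None, :] ** 2
    return nz, n, dist2, c0


#: continuous bone gap kept between canal surfaces, in voxels.  Guarantees
#: that no bone sliver pinched between canals falls below the despeckle
#: size, so segmentation closure on noise-free phantoms is exact.
_CANAL_GAP_VOXELS = 2.0


class _BandState:
    """Canals accepted for the band currently being built."""

    def __init__(self) -> None:
        self.cy: list[float] = []
        self.cx: list[float] = []
        self.r: list[float] = []

    def overlaps(self, cy: float, cx: float, r: float, gap: float) -> bool:
        if not self.cy:
            return False
        ys = np.asarray(self.cy)
        xs = np.asarray(self.cx)
        rs = np.asarray(self.r)
        return bool(np.any((ys - cy) ** 2 + (xs - cx) ** 2 < (rs + r + gap) ** 2))

    def add(self, cy: float, cx: float, r: float) -> None:
        self.cy.append(cy)
        self.cx.append(cx)
        self.r.append(r)


def _band_cells(spec: PhantomSpec, wall_min: float) -> list[tuple[float, float]]:
    """Depth cells of ``cell_depth`` µm; the last cell absorbs the remainder."""
    edges = list(np.arange(0.0, wall_min, spec.cell_depth))
    edges.append(wall_min)
    if len(edges) > 2 and edges[-1] - edges[-2] < spec.cell_depth * 0.4:
        del edges[-2]
    return list(zip(edges[:-1], edges[1:]))


def _place_canals(spec: PhantomSpec, rng: np.random.Generator, length_eff: float) -> list[CanalRecord]:
    """Rejection-sampled, non-overlapping canal placement band by band.

    Canals are continued across band boundaries whenever the next band's
    target still needs them (their radius rescaled to the local mean), so
    tracks run the length of the shaft like Haversian canals and sphere-
    fitting end effects arise only where tracks are born or die.  Within a
    band, canal centres are confined to the depth cell whose porosity
    deficit they fill, giving the radial gradient.
    """
    vox = spec.voxel_size
    min_d = spec.min_diameter_resolved
    if min_d < 2.0 * vox:
        raise ValueError(
            f"minimum canal diameter {min_d:.2f} µm is below two voxels "
            f"({2 * vox:.2f} µm); the voxel grid cannot represent it"
        )
    gap = _CANAL_GAP_VOXELS * vox

    band_edges = np.arange(0.0, length_eff, spec.band_length)
    if len(band_edges) > 1 and length_eff - band_edges[-1] < 0.5 * spec.band_length:
        band_edges = band_edges[:-1]  # merge a trailing sliver into the last band
    band_edges = np.append(band_edges, length_eff)

    canals: list[CanalRecord] = []
    prev_tracks: list[tuple[float, float, float, float]] = []  # (cy, cx, r, prev_mean_d)

    for bi in range(len(band_edges) - 1):
        z_lo, z_hi = float(band_edges[bi]), float(band_edges[bi + 1])
        s_mid = (z_lo + z_hi) / 2.0 / length_eff
        ss = np.linspace(z_lo, z_hi, 9) / length_eff
        inner_max = max(spec.inner_radius_at(float(s)) for s in ss)
        wall_min = spec.outer_radius - inner_max
        if wall_min <= 2.0 * vox:
            prev_tracks = []
            continue
        state = _BandState()
        new_tracks: list[tuple[float, float, float, float]] = []
        cells = _band_cells(spec, wall_min)
        # bucket continuation candidates by the depth cell of their centre
        buckets: dict[int, list[tuple[float, float, float, float]]] = {j: [] for j in range(len(cells))}
        for trk in prev_tracks:
            depth = spec.outer_radius - math.hypot(trk[0], trk[1])
            for j, (d_lo, d_hi) in enumerate(cells):
                if d_lo <= depth < d_hi or (j == len(cells) - 1 and depth >= d_hi):
                    buckets[j].append(trk)
                    break

        for j, (d_lo, d_hi) in enumerate(cells):
            d_mid = (d_lo + d_hi) / 2.0
            p_target = float(spec.porosity_profile(s_mid, d_mid))
            if not 0.0 <= p_target <= 0.95:
                raise ValueError(f"porosity_profile out of [0, 0.95]: {p_target}")
            if p_target <= 0.0:
                continue
            mean_d = float(spec.diameter_profile(s_mid, d_mid))
            if mean_d < 2.0 * vox:
                raise ValueError(
                    f"diameter_profile {mean_d:.2f} µm at (s={s_mid:.2f}, d={d_mid:.0f}) "
                    f"below two voxels ({2 * vox:.2f} µm)"
                )
            mu, sigma = _lognormal_params(mean_d, spec.diameter_cv)
            d_cap = min(4.0 * mean_d, wall_min - 2.0 * vox)
            if d_cap < min_d:
                raise PackingError(
                    f"band [{z_lo:.0f}, {z_hi:.0f}] µm depth cell [{d_lo:.0f}, {d_hi:.0f}] µm: "
                    f"wall too thin for the minimum canal diameter"
                )
            r_cell_in = spec.outer_radius - d_hi
            r_cell_out = spec.outer_radius - d_lo
            cell_area = math.pi * (r_cell_out**2 - r_cell_in**2)
            target_area = p_target * cell_area
            achieved = 0.0

            def _accept(cy: float, cx: float, r: float) -> None:
                nonlocal achieved
                cid = len(canals) + 1
                canals.append(
                    CanalRecord(id=cid, center=(cy, cx), radius=r, longitudinal_span=(z_lo, z_hi))
                )
                state.add(cy, cx, r)
                new_tracks.append((cy, cx, r, mean_d))
                achieved += math.pi * r**2

            # 1) continue previous-band tracks, radius rescaled to this cell's mean
            cand = buckets.get(j, [])
            for k in rng.permutation(len(cand)):
                if achieved >= target_area:
                    break
                cy, cx, r_old, mean_old = cand[int(k)]
                r = r_old * mean_d / mean_old
                r = min(max(r, min_d / 2.0), d_cap / 2.0)
                rho = math.hypot(cy, cx)
                if not (inner_max + r + vox <= rho <= spec.outer_radius - r - vox):
                    continue
                if state.overlaps(cy, cx, r, gap):
                    continue
                _accept(cy, cx, r)

            # 2) fill the remaining deficit with newborn tracks
            est_n = max(1, int(target_area / (math.pi * (mean_d / 2.0) ** 2)))
            cap = max(20000, spec.max_attempts_factor * est_n)
            attempts = 0
            while achieved < target_area:
                attempts += 1
                if attempts > cap:
                    raise PackingError(
                        f"unreachable target porosity {p_target:.3f} in band "
                        f"[{z_lo:.0f}, {z_hi:.0f}] µm, depth cell [{d_lo:.0f}, {d_hi:.0f}] µm "
                        f"(achieved {achieved / cell_area:.3f})"
                    )
                d = float(rng.lognormal(mu, sigma))
                if not (min_d <= d <= d_cap):
                    continue
                r = d / 2.0
                rho_lo = max(r_cell_in, inner_max + r + vox)
                rho_hi = min(r_cell_out, spec.outer_radius - r - vox)
                if rho_hi <= rho_lo:
                    continue
                rho = math.sqrt(rng.uniform(rho_lo**2, rho_hi**2))
                theta = rng.uniform(0.0, 2.0 * math.pi)
                cy = rho * math.sin(theta)
                cx = rho * math.cos(theta)
                if state.overlaps(cy, cx, r, gap):
                    continue
                _accept(cy, cx, r)
        prev_tracks = new_tracks
    return canals


def generate_cortical_phantom(spec: PhantomSpec) -> tuple[GrayscaleVolume, PhantomGroundTruth]:
    """Generate a grayscale phantom and its exact ground truth.

    Deterministic for a fixed ``spec.seed``.  Raises :class:`PackingError`
    naming the offending band when a target void fraction cannot be packed,
    and ``ValueError`` when the voxel grid is too coarse for the smallest
    canal (diameter below two voxels).
    """
    rng = np.random.default_rng(spec.seed)
    vox = spec.voxel_size
    nz, n, dist2, c0 = _grid(spec)
    length_eff = nz * vox

    if spec.forced_canals is not None:
        canals = [
            CanalRecord(id=i + 1, center=(cy, cx), radius=r, longitudinal_span=(0.0, length_eff))
            for i, (cy, cx, r) in enumerate(spec.forced_canals)
        ]
        for c in canals:
            if c.diameter < 2.0 * vox:
                raise ValueError("forced canal diameter below two voxels")
    else:
        canals = _place_canals(spec, rng, length_eff)

    n_labels = len(canals) + 2
    dtype = np.uint16 if n_labels < 2**16 else np.uint32
    label = np.zeros((nz, n, n), dtype=dtype)

    outer2 = spec.outer_radius**2
    coords = (np.arange(n) + 0.5) * vox - c0
    for iz in range(nz):
        s = (iz + 0.5) * vox / length_eff
        inner = spec.inner_radius_at(s)
        label[iz][(dist2 <= outer2) & (dist2 >= inner * inner)] = 1

    for c in canals:
        cy, cx = c.center
        r = c.radius
        z0, z1 = c.longitudinal_span
        # half-open span [z0, z1): abutting track segments never share a voxel
        iz0 = max(0, int(math.ceil(z0 / vox - 0.5)))
        iz1 = min(nz - 1, int(math.ceil(z1 / vox - 0.5)) - 1)
        if abs(z1 - nz * vox) < 1e-9:
            iz1 = nz - 1
        if iz1 < iz0:
            continue
        iy0 = max(0, int(math.floor((cy + c0 - r) / vox - 0.5)))
        iy1 = min(n - 1, int(math.ceil((cy + c0 + r) / vox - 0.5)))
        ix0 = max(0, int(math.floor((cx + c0 - r) / vox - 0.5)))
        ix1 = min(n - 1, int(math.ceil((cx + c0 + r) / vox - 0.5)))
        disk = (coords[iy0 : iy1 + 1, None] - cy) ** 2 + (
            coords[None, ix0 : ix1 + 1] - cx
        ) ** 2 <= r * r
        block = label[iz0 : iz1 + 1, iy0 : iy1 + 1, ix0 : ix1 + 1]
        if spec.forced_canals is None and not np.all(block[:, disk] != 0):
            raise RuntimeError("internal error: canal voxel outside the cortical shell")
        block[:, disk] = c.id + 1

    gray = np.where(label == 1, float(spec.bone_intensity), float(spec.void_intensity))
    if spec.noise_sd > 0:
        gray = gray + rng.normal(0.0, spec.noise_sd, size=gray.shape)
    gray = np.clip(np.rint(gray), 0, 255).astype(np.uint8)

    truth = PhantomGroundTruth(canals=canals, label_volume=label, spec=spec)
    return GrayscaleVolume(voxels=gray, voxel_size=vox), truth


def true_profile(
    truth: PhantomGroundTruth,
    plan: SlicePlan,
    depths: tuple[float, ...] = (250.0, 500.0, 750.0),
    directions: tuple[str, ...] = tuple(gradient_profiling.DIRECTIONS),
    window: tuple[float, float] = (500.0, 250.0),
    per_direction: bool = False,
) -> pd.DataFrame:
    """Exact (position, depth) porosity and diameter profile from the truth.

    Porosity is counted on the label volume inside the analytic envelope
    (the outer-radius disk, so the medullary cavity counts as void, matching
    the measurement convention); mean diameter is volume-weighted over the
    canal radii on record, weighted by each canal's voxel count inside the
    window.  Windows are placed with the same scheme as the measurement
    pipeline.
    """
    spec = truth.spec
    label = truth.label_volume
    nz, ny, nx = label.shape
    vox = spec.voxel_size
    if np.any(plan.positions > nz * vox + 1e-9) or np.any(plan.positions < 0):
        raise ValueError("plan positions outside the phantom extent")

    _, _, dist2, _ = _grid(spec)
    env2d = dist2 <= spec.outer_radius**2
    frame = gradient_profiling.locate_directions(env2d)
    radii = np.array([c.radius for c in truth.canals])

    rows: list[dict] = []
    for pos in plan.positions:
        z0, z1 = plan.slab_range(pos, nz, vox)
        for d in directions:
            for depth in depths:
                roi2d = gradient_profiling.place_roi(
                    env2d, d, depth, vox, window=window, frame=frame
                )
                row = {
                    "position_um": float(pos), "direction": d, "depth_um": depth,
                    "true_porosity": np.nan, "true_mean_diameter_um": np.nan,
                }
                if roi2d.valid:
                    sub = label[z0:z1, roi2d.y_slice, roi2d.x_slice]
                    n_env = int(env2d[roi2d.y_slice, roi2d.x_slice].sum()) * (z1 - z0)
                    if n_env:
                        n_bone = int((sub == 1).sum())
                        row["true_porosity"] = (n_env - n_bone) / n_env
                        counts = np.bincount(sub.ravel(), minlength=len(radii) + 2)[2:]
                        tot = counts.sum()
                        if tot:
                            row["true_mean_diameter_um"] = float(
                                (counts * 2.0 * radii).sum() / tot
                            )
                rows.append(row)
    directional = pd.DataFrame(rows)
    if per_direction:
        return directional
    return (
        directional.groupby(["position_um", "depth_um"], as_index=False)
        .agg(
            true_porosity=("true_porosity", "mean"),
            true_mean_diameter_um=("true_mean_diameter_um", "mean"),
        )
        .sort_values(["position_um", "depth_um"], ignore_index=True)
    )


@dataclass
class SyntheticCurveSpec:
    """Parameters of a synthetic two-regime compression curve.

    Stress follows ``modulus1 * strain`` up to the breakpoint, continues
    with slope ``modulus2`` up to the start of failure, then (when
    ``peak_stress_drop_fraction > 0``) declines linearly over the final
    ``drop_tail_fraction`` of the strain range by that fraction of the peak
    stress.  Additive Gaussian noise, deterministic per seed.
    """

    modulus1_true: float = 15.0
    modulus2_true: float = 1.4
    breakpoint_strain: float = 0.02
    failure_strain: float = 0.08
    peak_stress_drop_fraction: float = 0.3
    n_points: int = 161
    noise_sd: float = 0.0
    seed: int = 0
    drop_tail_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.breakpoint_strain < self.failure_strain:
            raise ValueError("require 0 < breakpoint_strain < failure_strain")
        if self.modulus1_true <= 0 or self.modulus2_true <= 0:
            raise ValueError("moduli must be positive")
        if self.n_points < 10:
            raise ValueError("n_points must be >= 10 to support a two-segment fit")


@dataclass
class StressStrainData:
    strain: np.ndarray
    stress: np.ndarray


def generate_stress_strain(spec: SyntheticCurveSpec) -> tuple[StressStrainData, SyntheticCurveSpec]:
    rng = np.random.default_rng(spec.seed)
    eps = np.linspace(0.0, spec.failure_strain, spec.n_points)
    b = spec.breakpoint_strain
    bilinear = spec.modulus1_true * np.minimum(eps, b) + spec.modulus2_true * np.maximum(
        eps - b, 0.0
    )
    if spec.peak_stress_drop_fraction > 0:
        drop_start = spec.failure_strain * (1.0 - spec.drop_tail_fraction)
        peak = spec.modulus1_true * b + spec.modulus2_true * (drop_start - b)
        tail = peak - peak * spec.peak_stress_drop_fraction * (
            (eps - drop_start) / (spec.failure_strain - drop_start)
        )
        stress = np.where(eps <= drop_start, bilinear, tail)
    else:
        stress = bilinear
    if spec.noise_sd > 0:
        stress = stress + rng.normal(0.0, spec.noise_sd, size=stress.shape)
    return StressStrainData(strain=eps, stress=stress), spec


def moduli_from_porosity(porosity: float) -> tuple[float, float]:
    """Stiffness-porosity link used by the synthetic study.

    Linear decline calibrated to shaft cortex: modulus 1 falls from 15 MPa
    at 5% void fraction to 5 MPa at 40%; modulus 2 from 1.4 MPa to 0.7 MPa
    over the same range (clipped to stay positive at extreme porosity).
    """
    m1 = 15.0 - (10.0 / 0.35) * (porosity - 0.05)
    m2 = 1.4 - (0.7 / 0.35) * (porosity - 0.05)
    return max(m1, 0.5), max(m2, 0.05)
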