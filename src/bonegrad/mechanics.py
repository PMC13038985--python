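"""Compressive mechanics of transverse bone slices.

Force-displacement records from uniaxial compression of thin (nominally
2.0 mm) transverse slices are converted to engineering stress-strain and
reduced to three parameters: modulus 1 (slope of the first linear region),
modulus 2 (slope of the second linear region) and maximum compressive
strength (peak stress before failure).  The two linear regions are
delimited by a continuous two-segment piecewise-linear least-squares fit
with an exhaustive breakpoint search over the pre-peak samples — a
deterministic, auditable stand-in for drawing the two slopes by eye.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CompressionRecord",
    "StressStrainCurve",
    "BilinearFit",
    "to_stress_strain",
    "fit_bilinear",
]


@dataclass
class CompressionRecord:
    """Raw force-displacement series plus the specimen geometry.

    ``slice_thickness`` in mm (nominal 2.0 ± 0.05 unless overridden),
    ``load_area`` in mm², ``position`` in mm from the distal end,
    ``rate`` in mm/min (metadata only).
    """

    displacement: np.ndarray
    force: np.ndarray
    slice_thickness: float = 2.0
    load_area: float = 1.0
    position: float = float("nan")
    rate: float = 1.0
    thickness_tolerance: float = 0.05
    allow_thickness_override: bool = False

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.displacement.shape != self.force.shape:
            raise ValueError("displacement and force must have equal length")
        if not self.allow_thickness_override and abs(self.slice_thickness - 2.0) > self.thickness_tolerance:
            raise ValueError(
                f"slice thickness {self.slice_thickness} mm outside 2.0 ± "
                f"{self.thickness_tolerance} mm (set allow_thickness_override to accept)"
            )


@dataclass
class StressStrainCurve:
    """Engineering strain (displacement / thickness) and stress (MPa)."""

    strain: np.ndarray
    stress: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class BilinearFit:
    modulus1: float
    modulus2: float
    breakpoint_strain: float
    max_strength: float
    sse: float
    n_points_used: int


def to_stress_strain(rec: CompressionRecord, monotone_tol: float = 1e-9) -> StressStrainCurve:
    """Convert a compression record to stress-strain.

    Strain = displacement / slice_thickness, stress = force / load_area,
    origin-shifted so the first sample is (0, 0).  Displacement must be
    non-decreasing up to ``monotone_tol``; offenders are listed.
    """
    if rec.load_area <= 0 or rec.slice_thickness <= 0:
        raise ValueError("load_area and slice_thickness must be positive")
    d = rec.displacement
    steps = np.diff(d)
    bad = np.flatnonzero(steps < -monotone_tol)
    if bad.size:
        raise ValueError(f"displacement decreases at indices {(bad + 1).tolist()[:20]}")
    strain = (d - d[0]) / rec.slice_thickness
    stress = (rec.force - rec.force[0]) / rec.load_area
    return StressStrainCurve(
        strain=strain,
        stress=stress,
        meta={"position_mm": rec.position, "thickness_mm": rec.slice_thickness,
              "area_mm2": rec.load_area},
    )


def fit_bilinear(
    curve: StressStrainCurve, min_points: int = 10, edge_fraction: float = 0.10
) -> BilinearFit:
    """Continuous two-segment least-squares fit of the pre-peak curve.

    Candidate breakpoints are the sample strains on an interior grid (the
    first and last ``edge_fraction`` of pre-peak points are excluded so both
    segments have support).  For each candidate the model
    ``a + m1*min(e, b) + m2*relu(e - b)`` is fit by linear least
    squares; the breakpoint minimising total squared error wins, ties going
    to the smaller breakpoint strain.  ``max_strength`` is the sample
    maximum of stress over the full record.  Deterministic.
    """
    eps = np.asarray(curve.strain, dtype=float)
    sig = np.asarray(curve.stress, dtype=float)
    if eps.size != sig.size or eps.size < min_points:
        raise ValueError(f"need at least {min_points} samples")
    if np.ptp(sig) == 0:
        raise ValueError("degenerate record: stress has zero variance")
    peak_idx = int(np.argmax(sig))
    e = eps[: peak_idx + 1]
    s = sig[: peak_idx + 1]
    n = e.size
    if n < min_points:
        raise ValueError(f"only {n} points at or before the stress peak; need {min_points}")

    lo = max(1, int(np.ceil(edge_fraction * n)))
    hi = min(n - 2, int(np.floor((1.0 - edge_fraction) * n)))
    if hi < lo:
        raise ValueError("too few interior points for a breakpoint search")

    best: tuple[float, float, float, float] | None = None  # (sse, b, m1, m2)
    ones = np.ones(n)
    for j in range(lo, hi + 1):
        b = e[j]
        x1 = np.minimum(e, b)
        x2 = np.maximum(e - b, 0.0)
        X = np.column_stack([ones, x1, x2])
        coef, _, _, _ = np.linalg.lstsq(X, s, rcond=None)
        resid = s - X @ coef
        sse = float(resid @ resid)
        if best is None or sse < best[0] - 1e-15 * (1 + best[0]):
            best = (sse, float(b), float(coef[1]), float(coef[2]))
    assert best is not None
    sse, b, m1, m2 = best
    return BilinearFit(
        modulus1=m1,
        modulus2=m2,
        breakpoint_strain=b,
        max_strength=float(sig.max()),
        sse=sse,
        n_points_used=n,
    )
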