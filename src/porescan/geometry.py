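"""Superposition, RMSD and distance series, and the ideal B-form strand.

All coordinates are Å, times ns.  Superposition is least-squares rigid-body
fitting (Kabsch); the proper-rotation branch is always taken, so a
reflection can never be returned.  The ideal B-form strand provides the
~7 Å adjacent phosphate spacing used as the one-nucleotide translocation
yardstick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, WindowError
from .trajio import TimeSeries, Trajectory

__all__ = [
    "RigidTransform",
    "SeriesStat",
    "BFormParams",
    "kabsch_superpose",
    "rmsd",
    "rmsd_series",
    "distance_series",
    "build_bform_strand",
    "bform_pp_spacing",
    "series_stat",
]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation (det = +1) plus translation, acting as R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        det = float(np.linalg.det(self.rotation))
        if abs(det - 1.0) > 1e-6:
            raise DegenerateGeometryError(
                f"rotation determinant {det:.8f} != +1; reflections forbidden"
            )

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


@dataclass(frozen=True)
class SeriesStat:
    """Windowed ensemble statistics, presented as mean ± per-frame SD."""

    mean: float
    sd: float
    window: tuple[float, float]
    n_frames: int

    def __post_init__(self):
        if self.n_frames < 2:
            raise WindowError("a series statistic needs at least 2 frames")
        if self.sd < 0:
            raise WindowError("standard deviation must be non-negative")


@dataclass(frozen=True)
class BFormParams:
    """Helical parameters of the ideal B-form reference strand.

    The default phosphate radius is calibrated so the adjacent intrastrand
    P-P spacing (the translocation step length) is 7.00 Å with the
    canonical 36 deg twist and 3.38 Å rise:
    r = sqrt(7^2 - rise^2) / (2 sin(twist/2)).
    """

    twist: float = 36.0      # degrees per step
    rise: float = 3.38       # Å per step
    p_radius: float = 9.9184  # Å, radial P displacement from the helix axis

    def __post_init__(self):
        # twist = 0 is admitted as the degenerate straight-stack limit,
        # where the P-P spacing collapses to the rise exactly
        if not (0 <= self.twist < 360):
            raise ValueError("twist must be in [0, 360) degrees")
        if self.rise <= 0 or self.p_radius <= 0:
            raise ValueError("rise and p_radius must be positive")


def bform_pp_spacing(params: BFormParams) -> float:
    """Closed-form adjacent P-P distance: chord of one helical step.

    sqrt((2 r sin(twist/2))^2 + rise^2).
    """
    half = np.deg2rad(params.twist) / 2.0
    return float(np.hypot(2.0 * params.p_radius * np.sin(half), params.rise))


def helix_points(
    n: int,
    twist: float,
    rise: float,
    radius: float,
    phase_deg: float = 0.0,
    origin=(0.0, 0.0, 0.0),
    axis_z_sign: float = 1.0,
) -> np.ndarray:
    """Points k on a circular helix about the z axis through ``origin``."""
    k = np.arange(n)
    ang = np.deg2rad(phase_deg + k * twist)
    pts = np.column_stack([
        radius * np.cos(ang),
        radius * np.sin(ang),
        axis_z_sign * k * rise,
    ])
    return pts + np.asarray(origin, dtype=float)


def build_bform_strand(
    n: int,
    params: BFormParams | None = None,
    origin=(0.0, 0.0, 0.0),
) -> np.ndarray:
    """Phosphate pseudo-atom coordinates of an ideal B-form strand.

    P atom k sits at angle k*twist, height k*rise, radius ``p_radius``; the
    adjacent P-P distance therefore equals the closed-form chord
    :func:`bform_pp_spacing`.
    """
    if n < 2:
        raise ValueError("a strand needs at least 2 nucleotides")
    params = params or BFormParams()
    return helix_points(n, params.twist, params.rise, params.p_radius,
                        origin=origin)


# ---------------------------------------------------------------------------
# superposition and series
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_atoms: np.ndarray | None = None,
) -> tuple[RigidTransform, np.ndarray]:
    """Least-squares superpose ``mobile`` onto ``reference``.

    The transform minimising the fit-atom RMSD is computed on ``fit_atoms``
    (all atoms when omitted) and applied to every atom of the mobile frame.
    Fewer than 3 fit atoms, or a collinear fit set, is an error.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit_atoms is None:
        fit_atoms = np.arange(len(mobile))
    fit_atoms = np.asarray(fit_atoms, dtype=int)
    mob_fit = mobile[fit_atoms]
    ref_fit = reference[fit_atoms]
    if len(mob_fit) < 3:
        raise DegenerateGeometryError("need at least 3 fit atoms")
    mob_c = mob_fit.mean(axis=0)
    ref_c = ref_fit.mean(axis=0)
    a = mob_fit - mob_c
    sv = np.linalg.svd(a, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise DegenerateGeometryError("fit atoms are collinear or coincident")
    rot, _ = Rotation.align_vectors(ref_fit - ref_c, a)
    rmat = rot.as_matrix()
    transform = RigidTransform(rmat, ref_c - rmat @ mob_c)
    return transform, transform.apply(mobile)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (unfitted) RMSD between two matching coordinate sets."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def fitted_rmsd(a: np.ndarray, b: np.ndarray, fit_atoms=None) -> float:
    """RMSD after mutual least-squares fit on ``fit_atoms``; symmetric."""
    if fit_atoms is None:
        fit_atoms = np.arange(len(a))
    _, fitted = kabsch_superpose(np.asarray(a), np.asarray(b), fit_atoms)
    return rmsd(fitted[fit_atoms], np.asarray(b)[fit_atoms])


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray,
    fit_atoms: np.ndarray,
    measure_atoms: np.ndarray,
    name: str = "rmsd",
) -> TimeSeries:
    """Per-frame RMSD over ``measure_atoms`` after superposing each frame
    onto the reference on ``fit_atoms``.

    With a single measure atom this reduces to its plain displacement
    distance from the reference position.
    """
    measure_atoms = np.asarray(measure_atoms, dtype=int)
    ref_measure = reference[measure_atoms]
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        _, fitted = kabsch_superpose(traj.coords[i], reference, fit_atoms)
        values[i] = rmsd(fitted[measure_atoms], ref_measure)
    return TimeSeries(traj.times.copy(), values, name=name, units="Å")


def distance_series(
    traj: Trajectory,
    group_a: np.ndarray,
    group_b: np.ndarray,
    mode: str = "ca_pair",
    name: str = "distance",
) -> TimeSeries:
    """Per-frame scalar distance between two atom groups.

    ``ca_pair`` requires exactly one atom per group; ``min_heavy`` is the
    minimum over all heavy-atom cross pairs; ``centroid`` is the distance
    between unweighted group centroids.  Distances are raw (no fitting) as
    they are internal to the complex.
    """
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if mode == "ca_pair":
        if len(group_a) != 1 or len(group_b) != 1:
            raise ValueError(
                f"ca_pair mode needs exactly one atom per group, got "
                f"{len(group_a)} and {len(group_b)}"
            )
        d = traj.coords[:, group_a[0]] - traj.coords[:, group_b[0]]
        values = np.linalg.norm(d, axis=1)
    elif mode == "min_heavy":
        heavy = traj.topology.heavy_mask()
        ga = group_a[heavy[group_a]]
        gb = group_b[heavy[group_b]]
        if ga.size == 0 or gb.size == 0:
            raise ValueError("min_heavy mode needs heavy atoms in both groups")
        values = np.array([
            cdist(traj.coords[i, ga], traj.coords[i, gb]).min()
            for i in range(traj.n_frames)
        ])
    elif mode == "centroid":
        ca = traj.coords[:, group_a].mean(axis=1)
        cb = traj.coords[:, group_b].mean(axis=1)
        values = np.linalg.norm(ca - cb, axis=1)
    else:
        raise ValueError(f"unknown distance mode {mode!r}")
    return TimeSeries(traj.times.copy(), values, name=name, units="Å")


def series_stat(series: TimeSeries, window: tuple[float, float]) -> SeriesStat:
    """Mean and per-frame SD over frames with t_start <= t <= t_end."""
    t0, t1 = window
    mask = (series.times >= t0) & (series.times <= t1)
    n = int(mask.sum())
    if n < 2:
        raise WindowError(
            f"window ({t0}, {t1}) ns intersects the series in {n} frame(s); "
            "need at least 2"
        )
    vals = series.values[mask]
    return SeriesStat(
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=0)),
        window=(float(t0), float(t1)),
        n_frames=n,
    )
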