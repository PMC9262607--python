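"""Pore geometry, displacement tracks, stage segmentation and replica
classification for helicase entry-pore translocation analysis.

The observables follow the entry-pore analysis of XPD-type 5'->3' helicases:
the pore width is proxied by the Cα(H135)-Cα(L220) distance, the Arch /
ATPase-lobe-1 gap by Cα(R380)-Cα(L220) and by the shortest heavy-atom
distance between the R380 side chain and the lobe-1 helix (residues
215-221).  A tracked nucleotide is followed, after superposing the pore Cα
set, through its phosphate displacement and heavy-atom RMSD from a
reference frame; the one-nucleotide translocation criterion compares the
equilibrated phosphate displacement against the ~7 Å B-form adjacent P-P
spacing.  Replicas are labelled backbone_translocation, base_translocation
(base flipped into the pore with the backbone in place) or blocked
(entrapment by the FeS pocket or lobe-1 helix sensors).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.spatial.distance import cdist

from .errors import WindowError
from .geometry import kabsch_superpose, rmsd, fitted_rmsd, distance_series, series_stat, SeriesStat
from .interactions import HBondCriterion, assign_roles, detect_hbonds
from .trajio import TimeSeries, Topology, Trajectory, resolve_selection

__all__ = [
    "PoreConfig",
    "NucleotideTrack",
    "StageSegmentation",
    "BehaviorLabel",
    "TranslocationReport",
    "pore_geometry_series",
    "equilibration_window",
    "nucleotide_track",
    "classify_behavior",
    "segment_stages",
    "representative_frame",
    "bend_series",
    "is_bent",
    "replica_summary",
    "analyze_replica",
]

BEHAVIOR_LABELS = ("backbone_translocation", "base_translocation", "blocked")


@dataclass(frozen=True)
class PoreConfig:
    """Residue identities and thresholds defining the entry-pore metrics.

    Defaults use the 6RO4 numbering: pore width Cα(H135)-Cα(L220), gap
    Cα(R380)-Cα(L220), minimum gap between the R380 side chain and the
    lobe-1 helix 215-221, with the FeS pocket and lobe-1 helix as the two
    base-sensor pockets.  ``bdna_spacing`` is the B-form adjacent P-P
    distance used as the one-nucleotide translocation yardstick; a replica
    is called backbone-translocated when the equilibrated phosphate
    displacement reaches ``backbone_frac`` of it.
    """

    width_pair: tuple[int, int] = (135, 220)
    gap_pair: tuple[int, int] = (380, 220)
    gap_residue: int = 380
    gap_group: tuple[int, int] = (215, 221)
    fit_selection: str = "domain FeS Arch ATPase1 and name CA"
    sensor_pockets: dict = field(default_factory=lambda: {
        "fes_pocket": (135, 139, 140, 141, 158, 161, 192, 193, 384),
        "lobe1_helix": tuple(range(215, 222)),
    })
    anchors: dict = field(default_factory=lambda: {
        "FeS": (128, 138),
        "Arch": (377, 384),
        "ATPase1": (215, 221),
    })
    bdna_spacing: float = 7.0
    backbone_frac: float = 0.8
    base_rmsd_cutoff: float = 5.0
    prism_half_depth: float = 6.0
    smooth_frac: float = 0.05
    min_dwell_frac: float = 0.05

    def __post_init__(self):
        if self.bdna_spacing <= 0:
            raise ValueError("bdna_spacing must be positive")


@dataclass
class NucleotideTrack:
    """Per-frame displacement metrics of one nucleotide after pore fit."""

    nucleotide: int
    p_displacement: TimeSeries | None
    heavy_rmsd: TimeSeries
    base_centroid_path: np.ndarray

    def windowed(self, window: tuple[float, float]) -> dict:
        out = {}
        if self.p_displacement is not None:
            out["p_displacement"] = series_stat(self.p_displacement, window)
        out["heavy_rmsd"] = series_stat(self.heavy_rmsd, window)
        return out


@dataclass
class StageSegmentation:
    """Contact-fingerprint stages: boundary times plus per-stage fingerprints."""

    boundaries: list[float]
    fingerprints: list[tuple[int, ...]]
    pairs: list[tuple[int, int]]
    min_dwell_ns: float

    def __post_init__(self):
        if any(b2 <= b1 for b1, b2 in zip(self.boundaries, self.boundaries[1:])):
            raise ValueError("stage boundaries must be strictly increasing")
        for f1, f2 in zip(self.fingerprints, self.fingerprints[1:]):
            if f1 == f2:
                raise ValueError("adjacent stages must differ in fingerprint")

    @property
    def n_stages(self) -> int:
        return len(self.fingerprints)


@dataclass
class BehaviorLabel:
    """Replica behavior label plus the windowed metrics that triggered it."""

    label: str
    evidence: dict

    def __post_init__(self):
        if self.label not in BEHAVIOR_LABELS:
            raise ValueError(f"unknown behavior label {self.label!r}")


# ---------------------------------------------------------------------------
# pore geometry
# ---------------------------------------------------------------------------

def _ca_index(top: Topology, resid: int) -> np.ndarray:
    return resolve_selection(top, f"name CA and resid {resid}")


def pore_geometry_series(
    traj: Trajectory, config: PoreConfig | None = None
) -> tuple[TimeSeries, TimeSeries, TimeSeries]:
    """Pore width, Arch/lobe-1 Cα gap and minimum side-chain gap series.

    All are raw internal distances; no superposition is involved.
    """
    config = config or PoreConfig()
    top = traj.topology
    width = distance_series(
        traj, _ca_index(top, config.width_pair[0]),
        _ca_index(top, config.width_pair[1]), mode="ca_pair",
        name="pore_width")
    gap = distance_series(
        traj, _ca_index(top, config.gap_pair[0]),
        _ca_index(top, config.gap_pair[1]), mode="ca_pair",
        name="arch_lobe1_gap")
    side = resolve_selection(
        top,
        f"resid {config.gap_residue} and not name N CA C O CM",
    )
    lo, hi = config.gap_group
    helix = resolve_selection(top, f"resid {lo}-{hi}")
    min_gap = distance_series(traj, side, helix, mode="min_heavy",
                              name="min_sidechain_gap")
    return width, gap, min_gap


# ---------------------------------------------------------------------------
# equilibration window
# ---------------------------------------------------------------------------

def equilibration_window(
    series_list: list[TimeSeries],
    override: tuple[float, float] | None = None,
    slope_tol: float = 0.1,          # Å per 100 ns
    window_frac: float = 0.1,
) -> tuple[float, float]:
    """Detect the equilibrated trailing window shared by several series.

    Returns the earliest t_start after which every series has an absolute
    linear slope below ``slope_tol`` (Å per 100 ns) in every sliding window
    of ``window_frac`` of the trajectory length; t_end is the final time.
    A user-supplied ``override`` is returned verbatim.  When no plateau is
    found the final 40% of frames is used, with a warning.
    """
    if override is not None:
        return (float(override[0]), float(override[1]))
    if len(series_list) < 2:
        raise WindowError("need at least 2 series to detect equilibration")
    times = series_list[0].times
    for s in series_list[1:]:
        if len(s.times) != len(times) or not np.allclose(s.times, times):
            raise WindowError("series must share a common time base")
    n = len(times)
    w = max(2, int(round(window_frac * n)))
    n_windows = n - w + 1
    ok = np.ones(n_windows, dtype=bool)
    for s in series_list:
        for i in range(n_windows):
            t = times[i:i + w]
            v = s.values[i:i + w]
            slope = np.polyfit(t, v, 1)[0] * 100.0  # Å per 100 ns
            if abs(slope) >= slope_tol:
                ok[i] = False
    # earliest start index such that every later window is flat
    bad = np.flatnonzero(~ok)
    if bad.size == 0:
        start = 0
    elif bad[-1] + 1 < n_windows:
        start = int(bad[-1] + 1)
    else:
        import warnings

        warnings.warn(
            "no plateau found; falling back to the final 40% of frames",
            stacklevel=2,
        )
        start = int(np.ceil(0.6 * n))
    return (float(times[start]), float(times[-1]))


# ---------------------------------------------------------------------------
# nucleotide track and classification
# ---------------------------------------------------------------------------

def nucleotide_track(
    traj: Trajectory,
    reference: np.ndarray,
    nucleotide: int,
    config: PoreConfig | None = None,
) -> NucleotideTrack:
    """Phosphate displacement, heavy-atom RMSD and base-centroid path of one
    nucleotide, each frame superposed on the pore fit selection first.

    A 5'-terminal nucleotide without a phosphate yields a heavy-only track
    with a warning.
    """
    config = config or PoreConfig()
    top = traj.topology
    fit_idx = resolve_selection(top, config.fit_selection)
    res_atoms = top.residue_atoms(nucleotide)
    heavy = top.heavy_mask()
    res_heavy = res_atoms[heavy[res_atoms]]
    p_idx = top.p_atom(nucleotide)
    if p_idx is None:
        import warnings

        warnings.warn(
            f"nucleotide {nucleotide} has no P atom (5' terminus); "
            "tracking heavy atoms only",
            stacklevel=2,
        )
    base_idx = resolve_selection(top, f"resid {nucleotide} and base")

    n = traj.n_frames
    p_disp = np.empty(n) if p_idx is not None else None
    heavy_vals = np.empty(n)
    centroids = np.empty((n, 3))
    ref_heavy = reference[res_heavy]
    for f in range(n):
        _, fitted = kabsch_superpose(traj.coords[f], reference, fit_idx)
        if p_idx is not None:
            p_disp[f] = float(np.linalg.norm(fitted[p_idx] - reference[p_idx]))
        heavy_vals[f] = rmsd(fitted[res_heavy], ref_heavy)
        centroids[f] = fitted[base_idx].mean(axis=0)
    times = traj.times.copy()
    return NucleotideTrack(
        nucleotide=int(nucleotide),
        p_displacement=(
            TimeSeries(times, p_disp, name=f"P_displacement_res{nucleotide}",
                       units="Å") if p_idx is not None else None
        ),
        heavy_rmsd=TimeSeries(times.copy(), heavy_vals,
                              name=f"heavy_rmsd_res{nucleotide}", units="Å"),
        base_centroid_path=centroids,
    )


def _anchor_centroids(top: Topology, reference: np.ndarray,
                      config: PoreConfig) -> np.ndarray:
    pts = []
    for tag in ("FeS", "Arch", "ATPase1"):
        lo, hi = config.anchors[tag]
        idx = resolve_selection(top, f"name CA and resid {lo}-{hi}")
        pts.append(reference[idx].mean(axis=0))
    return np.array(pts)


def point_in_pore_prism(
    point: np.ndarray,
    anchors: np.ndarray,
    half_depth: float = 6.0,
) -> bool:
    """Whether a point lies inside the triangular prism spanned by the three
    domain-anchor centroids, extruded ``half_depth`` Å along the normal."""
    a, b, c = anchors
    normal = np.cross(b - a, c - a)
    norm = np.linalg.norm(normal)
    if norm == 0:
        return False
    normal = normal / norm
    depth = float(np.dot(point - a, normal))
    if abs(depth) > half_depth:
        return False
    p = point - depth * normal  # project into the triangle plane
    # barycentric test
    v0, v1, v2 = c - a, b - a, p - a
    d00, d01 = np.dot(v0, v0), np.dot(v0, v1)
    d11 = np.dot(v1, v1)
    d20, d21 = np.dot(v2, v0), np.dot(v2, v1)
    denom = d00 * d11 - d01 * d01
    if denom == 0:
        return False
    u = (d11 * d20 - d01 * d21) / denom
    v = (d00 * d21 - d01 * d20) / denom
    eps = 1e-9
    return u >= -eps and v >= -eps and u + v <= 1 + eps


def classify_behavior(
    track: NucleotideTrack,
    window: tuple[float, float],
    config: PoreConfig,
    topology: Topology,
    reference: np.ndarray,
) -> BehaviorLabel:
    """Label one replica from its equilibrated nucleotide track.

    backbone_translocation: windowed mean P displacement reaches
    ``backbone_frac`` x the B-form P-P spacing (default 0.8 x 7.0 = 5.6 Å,
    separating translocated ~6.6 Å from non-translocated <= 3.6 Å).
    base_translocation: backbone in place but the base swung far (heavy
    RMSD >= cutoff) and its mean centroid lies inside the pore prism.
    blocked: everything else (entrapment by the sensor pockets).
    """
    # JSON-native types only, so reports round-trip losslessly
    evidence: dict = {"window": [float(window[0]), float(window[1])]}
    threshold = config.backbone_frac * config.bdna_spacing
    evidence["backbone_threshold"] = threshold

    if track.p_displacement is not None:
        p_stat = series_stat(track.p_displacement, window)
        evidence["p_displacement_mean"] = p_stat.mean
        evidence["p_displacement_sd"] = p_stat.sd
        if p_stat.mean >= threshold:
            return BehaviorLabel("backbone_translocation", evidence)

    h_stat = series_stat(track.heavy_rmsd, window)
    evidence["heavy_rmsd_mean"] = h_stat.mean
    evidence["heavy_rmsd_sd"] = h_stat.sd

    mask = ((track.heavy_rmsd.times >= window[0])
            & (track.heavy_rmsd.times <= window[1]))
    centroid = track.base_centroid_path[mask].mean(axis=0)
    anchors = _anchor_centroids(topology, reference, config)
    inside = point_in_pore_prism(centroid, anchors, config.prism_half_depth)
    evidence["base_centroid_mean"] = centroid.tolist()
    evidence["base_in_pore"] = bool(inside)
    if h_stat.mean >= config.base_rmsd_cutoff and inside:
        return BehaviorLabel("base_translocation", evidence)
    return BehaviorLabel("blocked", evidence)


# ---------------------------------------------------------------------------
# stage segmentation
# ---------------------------------------------------------------------------

def _contact_matrix(
    traj: Trajectory,
    pairs: list[tuple[int, int]],
    contact_cutoff: float = 4.0,
    criterion: HBondCriterion | None = None,
) -> np.ndarray:
    """frames x pairs boolean contact matrix.

    A residue-nucleotide pair is in contact when any heavy-atom cross
    distance is <= ``contact_cutoff`` or any donor-acceptor pair satisfies
    the H-bond criterion (the latter only adds contacts when its distance
    cutoff exceeds ``contact_cutoff``).
    """
    criterion = criterion or HBondCriterion()
    top = traj.topology
    heavy = top.heavy_mask()
    groups = []
    for res, nuc in pairs:
        ga = top.residue_atoms(res)
        gb = top.residue_atoms(nuc)
        groups.append((ga[heavy[ga]], gb[heavy[gb]]))
    need_hb = criterion.da_cutoff > contact_cutoff
    out = np.zeros((traj.n_frames, len(pairs)), dtype=bool)
    for f in range(traj.n_frames):
        for j, (ga, gb) in enumerate(groups):
            dmin = cdist(traj.coords[f, ga], traj.coords[f, gb]).min()
            hit = dmin <= contact_cutoff
            if not hit and need_hb:
                don_a, acc_a = assign_roles(top, ga)
                don_b, acc_b = assign_roles(top, gb)
                hit = bool(
                    detect_hbonds(top, traj.coords[f], don_a, acc_b, criterion)
                    or detect_hbonds(top, traj.coords[f], don_b, acc_a,
                                     criterion)
                )
            out[f, j] = hit
    return out


def segment_stages(
    traj: Trajectory,
    pairs: list[tuple[int, int]],
    config: PoreConfig | None = None,
    min_dwell_ns: float | None = None,
    contact_cutoff: float = 4.0,
) -> StageSegmentation:
    """Segment the trajectory into stages of constant contact fingerprint.

    The per-frame binary fingerprint over the key residue-nucleotide pairs
    is smoothed with a majority filter (width ``smooth_frac`` of the frame
    count); a boundary is emitted where the smoothed fingerprint changes
    and the new fingerprint persists for at least the minimum dwell
    (default ``min_dwell_frac`` of the trajectory length).
    """
    if not pairs:
        raise ValueError("need at least one key contact pair")
    config = config or PoreConfig()
    contacts = _contact_matrix(traj, pairs, contact_cutoff)
    n = traj.n_frames
    w = max(1, int(round(config.smooth_frac * n)))
    if w % 2 == 0:
        w += 1
    smoothed = np.column_stack([
        median_filter(contacts[:, j].astype(np.uint8), size=w, mode="nearest")
        for j in range(contacts.shape[1])
    ]).astype(bool)

    if min_dwell_ns is None:
        span = traj.times[-1] - traj.times[0]
        min_dwell_ns = config.min_dwell_frac * span
    dt = np.median(np.diff(traj.times)) if n > 1 else 1.0
    dwell_frames = max(1, int(round(min_dwell_ns / dt)))

    fingerprints = [tuple(int(x) for x in smoothed[0])]
    boundaries: list[float] = []
    f = 1
    while f < n:
        fp = tuple(int(x) for x in smoothed[f])
        if fp != fingerprints[-1]:
            # persists at least dwell_frames?
            end = min(n, f + dwell_frames)
            run = all(
                tuple(int(x) for x in smoothed[g]) == fp
                for g in range(f, end)
            )
            if run:  # persists for the dwell (or to the trajectory end)
                boundaries.append(float(traj.times[f]))
                fingerprints.append(fp)
                f = end
                continue
        f += 1
    return StageSegmentation(
        boundaries=boundaries,
        fingerprints=fingerprints,
        pairs=list(pairs),
        min_dwell_ns=float(min_dwell_ns),
    )


# ---------------------------------------------------------------------------
# representative frame, bend, populations
# ---------------------------------------------------------------------------

def representative_frame(
    traj: Trajectory,
    selection: np.ndarray,
    window: tuple[float, float],
) -> int:
    """Index of the window's medoid frame.

    The medoid minimises the summed pairwise RMSD (after mutual fit on the
    selection) to all other window frames; ties break to the earliest time.
    """
    frames = traj.window_indices(window)
    if frames.size < 2:
        raise WindowError("representative frame needs a window of >= 2 frames")
    selection = np.asarray(selection, dtype=int)
    k = frames.size
    dm = np.zeros((k, k))
    for i in range(k):
        ci = traj.coords[frames[i], selection]
        for j in range(i + 1, k):
            d = fitted_rmsd(ci, traj.coords[frames[j], selection])
            dm[i, j] = dm[j, i] = d
    sums = dm.sum(axis=1)
    return int(frames[int(np.argmin(sums))])  # argmin takes first minimum


def bend_series(
    traj: Trajectory,
    p_atoms: tuple[int, int, int],
    name: str = "bend_outer_pp",
) -> TimeSeries:
    """Cross-loop P-P distance: outer phosphate pair of three consecutive
    backbone phosphates (i-1, i, i+1)."""
    if len(p_atoms) != 3:
        raise ValueError("bend metric needs three consecutive P atoms")
    a, _, c = p_atoms
    d = traj.coords[:, a] - traj.coords[:, c]
    return TimeSeries(traj.times.copy(), np.linalg.norm(d, axis=1),
                      name=name, units="Å")


def is_bent(
    series: TimeSeries,
    window: tuple[float, float],
    bdna_spacing: float = 7.0,
    factor: float = 1.3,
) -> bool:
    """Bend predicate: windowed mean outer P-P within ``factor`` x the
    adjacent spacing (<= 9.1 Å at the 7 Å default), as for the ~8 Å
    phosphodiester distance across a retained backbone loop."""
    stat = series_stat(series, window)
    return stat.mean <= factor * bdna_spacing


def replica_summary(reports: list["TranslocationReport"]) -> pd.DataFrame:
    """Population table over replica labels.

    Deterministic row order backbone / base / blocked; percentages are
    rounded to the nearest integer percent.
    """
    if not reports:
        raise ValueError("need at least one report")
    counts = {label: 0 for label in BEHAVIOR_LABELS}
    for r in reports:
        counts[r.behavior.label] += 1
    total = sum(counts.values())
    return pd.DataFrame({
        "label": list(BEHAVIOR_LABELS),
        "count": [counts[l] for l in BEHAVIOR_LABELS],
        "percent": [int(round(100.0 * counts[l] / total))
                    for l in BEHAVIOR_LABELS],
    })


# ---------------------------------------------------------------------------
# report container and the replica pipeline
# ---------------------------------------------------------------------------

def _stat_dict(stat: SeriesStat) -> dict:
    return {"mean": stat.mean, "sd": stat.sd, "window": list(stat.window),
            "n_frames": stat.n_frames}


@dataclass
class TranslocationReport:
    """All per-replica observables, JSON-serializable losslessly."""

    replica_id: str
    window: tuple[float, float]
    pore_width: dict
    arch_lobe1_gap: dict
    min_sidechain_gap: dict
    tracks: dict
    stages: StageSegmentation | None
    behavior: BehaviorLabel
    representative_frame: int | None
    bend: dict | None
    schema_version: int = 1

    def to_dict(self) -> dict:
        d = {
            "schema_version": self.schema_version,
            "replica_id": self.replica_id,
            "window": list(self.window),
            "pore_width": self.pore_width,
            "arch_lobe1_gap": self.arch_lobe1_gap,
            "min_sidechain_gap": self.min_sidechain_gap,
            "tracks": self.tracks,
            "stages": None,
            "behavior": {"label": self.behavior.label,
                         "evidence": self.behavior.evidence},
            "representative_frame": self.representative_frame,
            "bend": self.bend,
        }
        if self.stages is not None:
            d["stages"] = {
                "boundaries": self.stages.boundaries,
                "fingerprints": [list(fp) for fp in self.stages.fingerprints],
                "pairs": [list(p) for p in self.stages.pairs],
                "min_dwell_ns": self.stages.min_dwell_ns,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TranslocationReport":
        stages = None
        if d.get("stages") is not None:
            s = d["stages"]
            stages = StageSegmentation(
                boundaries=list(s["boundaries"]),
                fingerprints=[tuple(fp) for fp in s["fingerprints"]],
                pairs=[tuple(p) for p in s["pairs"]],
                min_dwell_ns=s["min_dwell_ns"],
            )
        return cls(
            replica_id=d["replica_id"],
            window=tuple(d["window"]),
            pore_width=d["pore_width"],
            arch_lobe1_gap=d["arch_lobe1_gap"],
            min_sidechain_gap=d["min_sidechain_gap"],
            tracks=d["tracks"],
            stages=stages,
            behavior=BehaviorLabel(d["behavior"]["label"],
                                   d["behavior"]["evidence"]),
            representative_frame=d["representative_frame"],
            bend=d["bend"],
            schema_version=d.get("schema_version", 1),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "TranslocationReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def analyze_replica(
    traj: Trajectory,
    reference: np.ndarray,
    nucleotides: list[int],
    config: PoreConfig | None = None,
    replica_id: str = "replica",
    window: tuple[float, float] | None = None,
    stage_pairs: list[tuple[int, int]] | None = None,
    bend_resids: tuple[int, int, int] | None = None,
    with_representative: bool = True,
) -> TranslocationReport:
    """Run the full per-replica pipeline and assemble the report.

    The classification window is detected from the pore Cα RMSD plus the
    tracked nucleotides' heavy RMSD unless overridden.  The first tracked
    nucleotide provides the behavior label.
    """
    from .geometry import rmsd_series

    config = config or PoreConfig()
    top = traj.topology
    fit_idx = resolve_selection(top, config.fit_selection)

    width, gap, min_gap = pore_geometry_series(traj, config)
    pore_rmsd = rmsd_series(traj, reference, fit_idx, fit_idx,
                            name="pore_ca_rmsd")
    tracks = {nuc: nucleotide_track(traj, reference, nuc, config)
              for nuc in nucleotides}

    eq_series = [pore_rmsd] + [t.heavy_rmsd for t in tracks.values()]
    win = equilibration_window(eq_series, override=window)

    track_dicts = {}
    for nuc, t in tracks.items():
        stats = t.windowed(win)
        track_dicts[str(nuc)] = {
            name: _stat_dict(stat) for name, stat in stats.items()
        }

    behavior = classify_behavior(tracks[nucleotides[0]], win, config, top,
                                 reference)

    stages = None
    if stage_pairs:
        stages = segment_stages(traj, stage_pairs, config)

    rep = None
    if with_representative:
        sel = resolve_selection(top, config.fit_selection)
        rep = representative_frame(traj, sel, win)

    bend = None
    if bend_resids is not None:
        p_idx = [top.p_atom(r) for r in bend_resids]
        if all(p is not None for p in p_idx):
            bs = bend_series(traj, tuple(p_idx))
            stat = series_stat(bs, win)
            bend = {
                "outer_pp": _stat_dict(stat),
                "bent": bool(is_bent(bs, win, config.bdna_spacing)),
            }

    return TranslocationReport(
        replica_id=replica_id,
        window=win,
        pore_width=_stat_dict(series_stat(width, win)),
        arch_lobe1_gap=_stat_dict(series_stat(gap, win)),
        min_sidechain_gap=_stat_dict(series_stat(min_gap, win)),
        tracks=track_dicts,
        stages=stages,
        behavior=behavior,
        representative_frame=rep,
        bend=bend,
    )
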