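"""Quantification of pseudopod dynamics and chemotactic steering.

A pseudopod is read out as a local activator peak on the perimeter.  This
module finds those peaks frame by frame, links them into tracks, detects
one-into-two splitting (bifurcation) events, classifies pseudopod fates,
and computes the steering statistics: the chemotaxis index, the split-angle
relation between the attractant bearing alpha and the daughter angle gamma,
fate-by-direction histograms, and polar kymographs of the travelling
activator waves.

Angles are degrees CCW from +x; arc positions are fractions of the
perimeter in [0, 1).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import linregress

from .boundary import PerimeterMesh, polygon_area_centroid

logger = logging.getLogger("chemopod")


def wrap_angle(deg):
    """Wrap angle(s) to the interval (-180, 180]."""
    out = -np.mod(-np.asarray(deg, dtype=float) + 180.0, 360.0) + 180.0
    return float(out) if out.ndim == 0 else out


def circular_distance(u, v):
    """Shortest distance between arc fractions on the unit circle."""
    d = np.abs(np.asarray(u) - np.asarray(v)) % 1.0
    return np.minimum(d, 1.0 - d)


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Peak:
    arc_fraction: float   # position along the perimeter, in [0, 1)
    height: float
    direction: float      # degrees, centroid-to-peak


def pseudopod_direction(arc_position: float, mesh: PerimeterMesh,
                        centroid: np.ndarray) -> float:
    """Bearing of a perimeter point from the centroid, degrees CCW from +x."""
    p = mesh.point_at_arc(arc_position)
    d = np.asarray(p, dtype=float).ravel() - np.asarray(centroid, dtype=float)
    r = float(np.hypot(*d))
    if r < 1e-9:
        raise ValueError("peak coincides with centroid; direction undefined")
    return math.degrees(math.atan2(d[1], d[0]))


def detect_pseudopods(a: np.ndarray, mesh: PerimeterMesh, min_height: float,
                      min_prominence: float, min_separation: float) -> List[Peak]:
    """Local activator maxima on the periodic perimeter profile.

    ``min_separation`` is an arc length (same units as the mesh).  Peaks
    passing the height and prominence thresholds are suppressed greedily
    within ``min_separation`` of a higher peak; exact ties keep the lower
    arc position.
    """
    a = np.asarray(a, dtype=float)
    n = mesh.n_nodes
    if len(a) != n:
        raise ValueError("activator array does not match mesh nodes")
    if np.ptp(a) == 0.0:
        return []
    ext = np.concatenate([a, a, a])
    idx, props = find_peaks(ext, height=min_height, prominence=min_prominence)
    keep = (idx >= n) & (idx < 2 * n)
    idx = idx[keep] - n
    heights = props["peak_heights"][keep]
    if len(idx) == 0:
        return []
    # greedy suppression: highest first, ties at lower arc position first
    order = np.lexsort((idx, -heights))
    L = mesh.perimeter
    arcs = mesh.arc_positions
    chosen: List[int] = []
    for k in order:
        s_k = arcs[idx[k]]
        ok = all(min(abs(s_k - arcs[j]) % L, L - abs(s_k - arcs[j]) % L) >= min_separation
                 for j in (idx[c] for c in chosen))
        if ok:
            chosen.append(k)
    chosen.sort(key=lambda k: idx[k])
    _, centroid = polygon_area_centroid(mesh)
    peaks = []
    for k in chosen:
        s = arcs[idx[k]]
        peaks.append(Peak(arc_fraction=float(s / L), height=float(heights[k]),
                          direction=pseudopod_direction(s, mesh, centroid)))
    return peaks


# ---------------------------------------------------------------------------
# Tracking
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PseudopodTrack:
    id: int
    birth_frame: int
    frames: List[int] = dataclasses.field(default_factory=list)
    arc_fractions: List[float] = dataclasses.field(default_factory=list)
    directions: List[float] = dataclasses.field(default_factory=list)
    heights: List[float] = dataclasses.field(default_factory=list)
    parent_id: Optional[int] = None
    fate: str = "censored"   # split | retracted | censored

    @property
    def death_frame(self) -> int:
        return self.frames[-1]

    @property
    def lifetime(self) -> int:
        return self.death_frame - self.birth_frame + 1

    @property
    def birth_direction(self) -> float:
        return self.directions[0]


@dataclasses.dataclass
class BifurcationEvent:
    parent_id: int
    frame: int
    daughter_ids: Tuple[int, int]
    parent_direction: float          # parent peak bearing just before the split
    dominant_id: Optional[int] = None
    dominant_direction: Optional[float] = None

    def alpha(self, gradient_direction: float) -> float:
        """Attractant bearing relative to the parent pseudopod."""
        return wrap_angle(gradient_direction - self.parent_direction)

    def gamma(self) -> float:
        """Dominant daughter bearing relative to the parent pseudopod."""
        return wrap_angle(self.dominant_direction - self.parent_direction)


def track_pseudopods(peak_lists: Sequence[List[Peak]], matching_radius: float = 0.08,
                     min_lifetime: int = 5, split_radius_factor: float = 3.0,
                     gap_frames: int = 3):
    """Link per-frame peak lists into tracks and bifurcation events.

    Frame-to-frame matching is greedy nearest-neighbour on circular arc
    distance (fractions of the perimeter) within ``matching_radius``.  A
    peak that appears within ``split_radius_factor * matching_radius`` of a
    surviving track is recorded as a bifurcation: the parent track ends
    with ``fate='split'`` and two fresh daughter tracks begin.  Unmatched
    track ends become ``retracted`` (``censored`` at the final frame), and
    tracks shorter than ``min_lifetime`` frames are pruned as detection
    noise (events whose members are pruned are dropped; their parents
    revert to ``retracted``).

    ``gap_frames`` enables gap closing: a peak with no live match revives a
    track that ended at most that many frames ago within ``matching_radius``
    of its last position (peaks flicker around the detection threshold, and
    treating every flicker as a retraction + a de novo birth would corrupt
    the fate statistics).
    """
    tracks: Dict[int, PseudopodTrack] = {}
    events: List[BifurcationEvent] = []
    active: List[int] = []
    limbo: Dict[int, int] = {}   # track id -> frame it was last seen
    next_id = 0
    n_frames = len(peak_lists)

    def new_track(frame: int, peak: Peak, parent: Optional[int] = None) -> int:
        nonlocal next_id
        tr = PseudopodTrack(id=next_id, birth_frame=frame, parent_id=parent)
        tracks[next_id] = tr
        _append(tr, frame, peak)
        next_id += 1
        return tr.id

    def _append(tr: PseudopodTrack, frame: int, peak: Peak) -> None:
        tr.frames.append(frame)
        tr.arc_fractions.append(peak.arc_fraction)
        tr.directions.append(peak.direction)
        tr.heights.append(peak.height)

    for frame, peaks in enumerate(peak_lists):
        if frame == 0:
            active = [new_track(0, p) for p in peaks]
            continue
        prev_pos = np.array([tracks[i].arc_fractions[-1] for i in active])
        cur_pos = np.array([p.arc_fraction for p in peaks])
        matches: Dict[int, int] = {}   # peak index -> track id
        if len(prev_pos) and len(cur_pos):
            D = circular_distance(prev_pos[:, None], cur_pos[None, :])
            pairs = sorted(((D[i, j], i, j) for i in range(len(active))
                            for j in range(len(peaks))), key=lambda t: t[0])
            used_tr, used_pk = set(), set()
            for d, i, j in pairs:
                if d > matching_radius:
                    break
                if i in used_tr or j in used_pk:
                    continue
                used_tr.add(i)
                used_pk.add(j)
                matches[j] = active[i]
        # gap closing: revive recently-ended tracks for still-unmatched peaks
        for j, p in enumerate(peaks):
            if j in matches or not limbo:
                continue
            cands = [(circular_distance(tracks[tid].arc_fractions[-1], p.arc_fraction), tid)
                     for tid, last in limbo.items() if frame - last <= gap_frames]
            cands = [c for c in cands if c[0] <= matching_radius]
            if cands:
                _, tid = min(cands)
                limbo.pop(tid)
                tracks[tid].fate = "censored"
                matches[j] = tid
        survivors: List[int] = []
        consumed = set()
        # bifurcations: an unmatched peak next to a matched track's previous
        # position means the parent split into (continuation, new peak)
        for j, p in enumerate(peaks):
            if j in matches:
                continue
            best = None
            for jj, tid in matches.items():
                if tid in consumed:
                    continue
                d = circular_distance(tracks[tid].arc_fractions[-1], p.arc_fraction)
                if d <= split_radius_factor * matching_radius and (best is None or d < best[0]):
                    best = (d, jj, tid)
            if best is not None:
                _, jj, tid = best
                consumed.add(tid)
                parent = tracks[tid]
                parent.fate = "split"
                d1 = new_track(frame, peaks[jj], parent=tid)
                d2 = new_track(frame, p, parent=tid)
                events.append(BifurcationEvent(
                    parent_id=tid, frame=frame, daughter_ids=(d1, d2),
                    parent_direction=parent.directions[-1]))
                matches.pop(jj)
                survivors += [d1, d2]
            else:
                survivors.append(new_track(frame, p))  # de novo pseudopod
        for j, tid in matches.items():
            _append(tracks[tid], frame, peaks[j])
            survivors.append(tid)
        for tid in active:
            if tid not in survivors and tid not in consumed:
                tracks[tid].fate = "retracted"
                limbo[tid] = frame - 1
        for tid in [t for t, last in limbo.items() if frame - last > gap_frames]:
            limbo.pop(tid)
        active = survivors
    for tid in active:
        tracks[tid].fate = "censored"

    # prune sub-minimum-lifetime tracks
    pruned = {tid for tid, tr in tracks.items() if tr.lifetime < min_lifetime}
    kept_events = []
    for ev in events:
        if ev.parent_id in pruned or any(d in pruned for d in ev.daughter_ids):
            if ev.parent_id not in pruned:
                tracks[ev.parent_id].fate = "retracted"
            for d in ev.daughter_ids:
                if d not in pruned:
                    tracks[d].parent_id = None
            continue
        kept_events.append(ev)
    track_list = [tr for tid, tr in sorted(tracks.items()) if tid not in pruned]
    for tr in track_list:
        if tr.parent_id in pruned:
            tr.parent_id = None

    # resolve dominant daughters: the survivor, else the longer-lived, else
    # the higher mean peak
    for ev in kept_events:
        da, db = (tracks[d] for d in ev.daughter_ids)
        key = lambda tr: (tr.death_frame, tr.lifetime, float(np.mean(tr.heights)))
        dom = max((da, db), key=key)
        ev.dominant_id = dom.id
        ev.dominant_direction = dom.birth_direction
    return track_list, kept_events


def bifurcation_fraction(tracks: Sequence[PseudopodTrack]) -> float:
    """Fraction of pseudopods born after frame 0 that arise from a split."""
    born = [tr for tr in tracks if tr.birth_frame > 0]
    if not born:
        return float("nan")
    return sum(tr.parent_id is not None for tr in born) / len(born)


def tracks_to_frame(tracks: Sequence[PseudopodTrack]) -> pd.DataFrame:
    return pd.DataFrame([{
        "id": tr.id, "birth_frame": tr.birth_frame, "death_frame": tr.death_frame,
        "lifetime": tr.lifetime, "parent_id": tr.parent_id, "fate": tr.fate,
        "birth_direction": tr.birth_direction,
    } for tr in tracks])


# ---------------------------------------------------------------------------
# Split-angle statistics (alpha / gamma)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SplitAngleStats:
    """Per-event alpha/gamma table plus summary fits.

    ``table`` columns: alpha, gamma (signed), abs_alpha, abs_gamma,
    clockwise.  ``slope``/``intercept`` fit |gamma| against |alpha|;
    ``signed_slope``/``signed_intercept`` fit signed gamma against alpha
    after reflecting every event so the attractant lies at alpha >= 0.
    """

    table: pd.DataFrame
    slope: float = float("nan")
    intercept: float = float("nan")
    slope_stderr: float = float("nan")
    signed_slope: float = float("nan")
    signed_intercept: float = float("nan")
    binned: Optional[pd.DataFrame] = None

    def zero_bias_crossing(self, unbiased_mean: float) -> float:
        """Attractant angle at which the fitted split angle equals the
        no-stimulus mean (the gradient neither tightens nor widens splits)."""
        if self.slope == 0 or math.isnan(self.slope):
            return float("nan")
        return (unbiased_mean - self.intercept) / self.slope


def split_angle_statistics(events: Sequence[BifurcationEvent],
                           gradient_direction: float,
                           bin_width: float = 30.0) -> SplitAngleStats:
    """Alpha/gamma table, binned means and linear fits for split events."""
    rows = []
    for ev in events:
        if ev.dominant_direction is None:
            continue
        alpha = ev.alpha(gradient_direction)
        gamma = ev.gamma()
        rows.append({"frame": ev.frame, "parent_id": ev.parent_id,
                     "alpha": alpha, "gamma": gamma,
                     "abs_alpha": abs(alpha), "abs_gamma": abs(gamma),
                     "clockwise": gamma < 0})
    table = pd.DataFrame(rows)
    stats = SplitAngleStats(table=table)
    if len(table) == 0:
        return stats
    if len(table) >= 3 and table["abs_alpha"].nunique() > 1:
        fit = linregress(table["abs_alpha"], table["abs_gamma"])
        stats.slope = float(fit.slope)
        stats.intercept = float(fit.intercept)
        stats.slope_stderr = float(fit.stderr)
        # reflection convention: mirror events so the attractant is at +alpha
        refl = np.where(table["alpha"] >= 0, 1.0, -1.0)
        sfit = linregress(table["alpha"] * refl, table["gamma"] * refl)
        stats.signed_slope = float(sfit.slope)
        stats.signed_intercept = float(sfit.intercept)
    edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    grp = table.groupby(pd.cut(table["abs_alpha"], edges), observed=False)
    stats.binned = grp["abs_gamma"].agg(["mean", "std", "count"]).reset_index()
    return stats


# ---------------------------------------------------------------------------
# Trajectory and field summaries
# ---------------------------------------------------------------------------

def chemotaxis_index(trajectory: np.ndarray, gradient_direction: float) -> float:
    """Net displacement along the gradient divided by total path length."""
    xy = np.asarray(trajectory, dtype=float)
    if xy.ndim != 2 or len(xy) < 2:
        raise ValueError("trajectory needs at least 2 frames of (x, y)")
    steps = np.diff(xy, axis=0)
    path = float(np.linalg.norm(steps, axis=1).sum())
    if path == 0.0:
        logger.warning("zero path length; chemotaxis index undefined")
        return float("nan")
    th = math.radians(gradient_direction)
    u = np.array([math.cos(th), math.sin(th)])
    return float((xy[-1] - xy[0]) @ u / path)


def kymograph(meshes: Sequence[PerimeterMesh], activator: Sequence[np.ndarray],
              n_bins: int = 90) -> np.ndarray:
    """Polar unwrap of the perimeter activator: (n_frames, n_bins) matrix.

    Each frame's activator is resampled onto equal angular sectors around
    the centroid, anchored at laboratory angle 0 (east).  Frames whose
    perimeter is not star-shaped about the centroid fall back to an
    arc-length unwrap anchored at the node nearest to lab angle 0 (logged).
    """
    out = np.empty((len(meshes), n_bins))
    centers = (np.arange(n_bins) + 0.5) * 360.0 / n_bins
    for f, (mesh, a) in enumerate(zip(meshes, activator)):
        _, cen = polygon_area_centroid(mesh)
        rel = mesh.nodes - cen
        th = np.degrees(np.arctan2(rel[:, 1], rel[:, 0])) % 360.0
        dth = wrap_angle(np.diff(np.concatenate([th, th[:1]])))
        star = np.all(dth > 0) or np.all(dth < 0)
        if star:
            order = np.argsort(th)
            th_s = th[order]
            a_s = np.asarray(a)[order]
            th_ext = np.concatenate([th_s - 360.0, th_s, th_s + 360.0])
            a_ext = np.concatenate([a_s, a_s, a_s])
            out[f] = np.interp(centers, th_ext, a_ext)
        else:
            logger.debug("frame %d not star-shaped; arc-length unwrap", f)
            anchor = int(np.argmin(np.minimum(th, 360.0 - th)))
            a_roll = np.roll(np.asarray(a), -anchor)
            s = np.linspace(0.0, 360.0, mesh.n_nodes, endpoint=False)
            s_ext = np.concatenate([s - 360.0, s, s + 360.0])
            a_ext = np.concatenate([a_roll] * 3)
            out[f] = np.interp(centers, s_ext, a_ext)
    return out


@dataclasses.dataclass
class CircularSummary:
    mean: float
    sd: float
    resultant_length: float
    reliable: bool


def circular_mean_sd(angles_deg: Sequence[float]) -> CircularSummary:
    """Circular mean, SD and mean resultant length of angles in degrees.

    The mean is flagged unreliable when the resultant length falls below
    0.05 (angles nearly uniform on the circle).
    """
    th = np.radians(np.asarray(angles_deg, dtype=float))
    if th.size == 0:
        raise ValueError("need at least one angle")
    z = np.exp(1j * th).mean()
    R = float(np.abs(z))
    mean = math.degrees(math.atan2(z.imag, z.real))
    sd = math.degrees(math.sqrt(max(-2.0 * math.log(R), 0.0))) if R > 0 else float("inf")
    if R < 0.05:
        logger.warning("resultant length %.3f < 0.05; circular mean unreliable", R)
    return CircularSummary(mean=wrap_angle(mean), sd=sd, resultant_length=R,
                           reliable=R >= 0.05)


def fate_by_direction_histogram(tracks: Sequence[PseudopodTrack],
                                gradient_direction: float,
                                bin_width: float = 30.0) -> pd.DataFrame:
    """Histogram of birth directions relative to the gradient, split by fate.

    Censored tracks are excluded.  Bins cover (-180, 180] in ``bin_width``
    steps; returns columns ``bin_left``, ``total``, ``split``, ``retracted``.
    """
    edges = np.arange(-180.0, 180.0 + bin_width, bin_width)
    counts = {k: np.zeros(len(edges) - 1, dtype=int) for k in ("total", "split", "retracted")}
    for tr in tracks:
        if tr.fate == "censored":
            continue
        rel = wrap_angle(tr.birth_direction - gradient_direction)
        i = min(np.searchsorted(edges, rel, side="right") - 1, len(edges) - 2)
        i = max(i, 0)
        counts["total"][i] += 1
        counts[tr.fate][i] += 1
    return pd.DataFrame({"bin_left": edges[:-1], **counts})


# ---------------------------------------------------------------------------
# End-to-end run analysis
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PeakThresholds:
    """Peak-detection thresholds relative to the run-maximum activator."""

    height_fraction: float = 0.12
    prominence_fraction: float = 0.02
    separation_fraction: float = 0.04
    matching_radius: float = 0.08
    min_lifetime: int = 5


def analyze_run(output, gradient_direction: float = 0.0,
                thresholds: Optional[PeakThresholds] = None,
                skip_frames: int = 0) -> Dict:
    """Detect, track and summarise pseudopods for a simulation output.

    Returns a dict with tracks, events, split-angle statistics, the
    chemotaxis index and the bifurcation fraction.  ``skip_frames`` drops
    the initial transient before detection.
    """
    th = thresholds or PeakThresholds()
    run_max = float(output.a[skip_frames:].max())
    peak_lists = []
    for f in range(skip_frames, output.n_frames):
        mesh = output.mesh(f)
        L = mesh.perimeter
        peak_lists.append(detect_pseudopods(
            output.a[f], mesh,
            min_height=th.height_fraction * run_max,
            min_prominence=th.prominence_fraction * run_max,
            min_separation=th.separation_fraction * L))
    tracks, events = track_pseudopods(peak_lists, matching_radius=th.matching_radius,
                                      min_lifetime=th.min_lifetime)
    for tr in tracks:
        tr.birth_frame += skip_frames
        tr.frames = [f + skip_frames for f in tr.frames]
    for ev in events:
        ev.frame += skip_frames
    stats = split_angle_statistics(events, gradient_direction)
    return {
        "tracks": tracks,
        "events": events,
        "split_stats": stats,
        "chemotaxis_index": chemotaxis_index(output.centroid, gradient_direction),
        "bifurcation_fraction": bifurcation_fraction(tracks),
        "fate_histogram": fate_by_direction_histogram(tracks, gradient_direction),
    }
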