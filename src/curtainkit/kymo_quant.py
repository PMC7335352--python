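"""Kymograph quantification: tracking, segmentation and event tables.

The raw observable is a kymograph — a time x position intensity array
for one DNA molecule.  This module turns kymographs (or pre-tracked
trajectories) into per-molecule compaction-event tables:

* free-end tracking with sub-pixel refinement,
* piecewise-linear change-point segmentation of the trajectory,
* grouping of segments into processive compaction runs, with velocity,
  processivity, right-censoring flags, lag times,
* termination taxonomy (reversal / release / stall / complete),
* single-frame release detection, and
* nucleosome-collision outcome scoring.

Sign conventions: position 0 is the chromium barrier (tether point) and
positions increase toward the free DNA end.  Compaction moves the free
end toward the barrier, i.e. the raw trajectory slope is negative; the
reported compaction velocities are the corresponding positive rates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._changepoint import mad_sigma, piecewise_linear_breakpoints
from .units import CurtainGeometry, um_to_bp


class CensorReason(str, enum.Enum):
    DISSOCIATION = "dissociation"
    DNA_BREAKAGE = "dna_breakage"
    BARRIER_1PX = "barrier_1px"
    END_OF_RECORD = "end_of_record"
    NONE = "none"


class Termination(str, enum.Enum):
    REVERSAL = "reversal"
    RELEASE = "release"
    STALL = "stall"
    COMPLETE = "complete"


class CollisionOutcome(str, enum.Enum):
    BYPASS_NO_PAUSE = "bypass_no_pause"
    BYPASS_WITH_PAUSE = "bypass_with_pause"
    STALL = "stall"
    RELEASE = "release"
    REVERSAL = "reversal"


@dataclass
class Kymograph:
    """Time x position intensity array for one molecule.

    ``image`` has shape (n_frames, n_pixels), pixel 0 at the barrier.
    ``channel2`` optionally carries a second color (labeled nucleosomes
    or labeled condensin).
    """

    image: np.ndarray
    geometry: CurtainGeometry
    channel2: Optional[np.ndarray] = None
    molecule_id: int = 0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("kymograph image must be 2-D (frames x pixels)")
        if self.channel2 is not None:
            self.channel2 = np.asarray(self.channel2, dtype=float)
            if self.channel2.shape != self.image.shape:
                raise ValueError("channel2 shape must match the DNA channel")

    @property
    def n_frames(self) -> int:
        return self.image.shape[0]


@dataclass
class Trajectory:
    """Per-frame free-end (or punctum) position in μm."""

    molecule_id: int
    t_s: np.ndarray
    pos_um: np.ndarray
    geometry: CurtainGeometry

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.pos_um = np.asarray(self.pos_um, dtype=float)
        if self.t_s.shape != self.pos_um.shape or self.t_s.ndim != 1:
            raise ValueError("t_s and pos_um must be 1-D and aligned")
        if len(self.t_s) >= 2:
            dt = np.diff(self.t_s)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("t_s must be strictly increasing with constant spacing")

    @property
    def n_frames(self) -> int:
        return len(self.t_s)

    @property
    def dt(self) -> float:
        return float(self.t_s[1] - self.t_s[0]) if len(self.t_s) > 1 else self.geometry.frame_interval_s


@dataclass
class Segment:
    """One fitted line segment of a trajectory; frame range is [i0, i1)."""

    i0: int
    i1: int
    t_start: float
    t_end: float
    slope_um_s: float
    displacement_um: float

    def kind(self, v_min: float) -> str:
        if self.slope_um_s < -v_min:
            return "toward"
        if self.slope_um_s > v_min:
            return "away"
        return "stall"


@dataclass
class Run:
    """A maximal group of toward-barrier (plus interleaved stall) segments."""

    segments: list[Segment]
    i_start: int          # first frame of the first toward segment
    i_end: int            # last frame of the run (inclusive)
    next_away: Optional[Segment] = None


@dataclass
class CompactionEvent:
    molecule_id: int
    run_id: int
    velocities_um_s: list[float]
    processivity_um: float
    censored: bool
    censor_reason: CensorReason
    termination: Termination
    lag_s: Optional[float]
    t_start_s: float = 0.0
    t_end_s: float = 0.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.velocities_um_s):
            raise ValueError("compaction velocities must be positive by definition")
        if self.censored and self.censor_reason == CensorReason.NONE:
            raise ValueError("censored event must carry a censor reason")

    @property
    def median_velocity_um_s(self) -> float:
        return float(np.median(self.velocities_um_s))


@dataclass
class CollisionRecord:
    molecule_id: int
    run_id: int
    nucleosome_pos_um: float
    outcome: CollisionOutcome
    pause_frames: int = 0


def default_v_min(geometry: CurtainGeometry) -> float:
    """Stall threshold: half a pixel per frame, the tracking noise floor."""
    return 0.5 * geometry.pixel_size_um / geometry.frame_interval_s


# ---------------------------------------------------------------------------
# tracking

def track_free_end(kymo: Kymograph, n_sigma: float = 3.0, bg_margin_px: int = 5,
                   max_gap: int = 2) -> Trajectory:
    """Track the DNA free end through a single-channel kymograph.

    Per frame, the free end is first localized as the farthest-from-
    barrier pixel whose intensity exceeds background + ``n_sigma`` x
    (MAD-based sigma), then refined to sub-pixel:

    * a half-plateau crossing of the DNA line profile when no compacted
      punctum is present,
    * an iterative coverage-subtracted local centroid of the punctum
      residual when one is, and
    * a three-point log-parabola on the residual when the punctum
      dominates the DNA plateau (exact for a Gaussian spot, immune to
      window truncation at the barrier).

    Background and its noise come from the distal margin of the field
    (beyond the DNA); the DNA plateau intensity is estimated globally
    from the early frames.  Gaps of at most ``max_gap`` frames are
    linearly interpolated.
    """
    img = kymo.image
    n_frames, n_px = img.shape
    if n_frames < 5:
        raise ValueError("kymograph must have at least 5 frames")
    # background from the distal margin, which lies beyond the DNA
    bg_region = img[:, n_px - bg_margin_px:]
    bg = float(np.median(bg_region))
    sigma = 1.4826 * float(np.median(np.abs(bg_region - bg)))
    sigma = max(sigma, 1e-6 * max(float(img.max()) - bg, 1.0))
    thr = bg + n_sigma * sigma
    # DNA plateau level from above-threshold pixels of the early frames
    early = img[: min(5, n_frames)]
    lit = early[early > thr]
    plateau = float(np.median(lit) - bg) if lit.size else 0.0
    if plateau > 0:
        thr = max(thr, bg + 0.3 * plateau)

    centers = np.arange(n_px, dtype=float) + 0.5
    pix = np.arange(n_px, dtype=float)
    pos_px = np.full(n_frames, np.nan)
    for f in range(n_frames):
        row = img[f]
        above = np.nonzero(row > thr)[0]
        if above.size == 0:
            continue
        # the DNA is contiguous from the barrier: stop at the first gap of
        # more than 2 px so isolated bright noise pixels cannot pull the end
        gaps = np.nonzero(np.diff(above) > 3)[0]
        idx = int(above[gaps[0]] if gaps.size else above[-1])
        if plateau <= 0:
            pos_px[f] = idx + 0.5
            continue
        # initial estimate: half-plateau crossing, interpolated (restricted
        # to the contiguous DNA region so stray bright pixels are ignored)
        half = bg + 0.5 * plateau
        ge = np.nonzero(row[:idx + 2] >= half)[0]
        k = int(ge[-1]) if ge.size else idx
        if k + 1 < n_px and row[k] > row[k + 1]:
            e = centers[k] + float((row[k] - half) / (row[k] - row[k + 1]))
        else:
            e = centers[k]
        lo = max(0, idx - 6)
        peak = lo + int(np.argmax(row[lo:idx + 1]))
        peak_excess = float(row[peak] - bg - plateau)
        if peak_excess > 2.0 * plateau and 1 <= peak < n_px - 1:
            # bright punctum: log-parabola on the plateau-subtracted residual
            resid = row - bg - plateau * np.clip(e - pix, 0.0, 1.0)
            w = np.clip(resid[peak - 1:peak + 2], 1e-9, None)
            lw = np.log(w)
            den = lw[0] - 2.0 * lw[1] + lw[2]
            pos_px[f] = (centers[peak] + 0.5 * (lw[0] - lw[2]) / den
                         if den < 0 else centers[peak])
            continue
        # faint/absent punctum: iterative coverage-subtracted centroid
        for _ in range(4):
            resid = row - bg - plateau * np.clip(e - pix, 0.0, 1.0)
            c = int(round(e - 0.5))
            w0, w1 = max(0, c - 3), min(n_px, c + 4)
            wts = np.clip(resid[w0:w1], 0.0, None)
            tot = float(wts.sum())
            if tot < 0.2 * plateau:
                break   # no appreciable punctum: keep the edge estimate
            e_new = float((centers[w0:w1] * wts).sum() / tot)
            if abs(e_new - e) < 1e-3:
                e = e_new
                break
            e = e_new
        pos_px[f] = e

    if np.all(np.isnan(pos_px)):
        raise ValueError("empty kymograph: no frame exceeds the detection threshold")

    pos_px = _fill_short_gaps(pos_px, max_gap)
    t = np.arange(n_frames) * kymo.geometry.frame_interval_s
    return Trajectory(kymo.molecule_id, t, pos_px * kymo.geometry.pixel_size_um,
                      kymo.geometry)


def _fill_short_gaps(y: np.ndarray, max_gap: int) -> np.ndarray:
    y = y.copy()
    isnan = np.isnan(y)
    if not isnan.any():
        return y
    idx = np.arange(len(y))
    # find nan runs and interpolate only the short interior ones
    run_start = None
    for i in range(len(y) + 1):
        if i < len(y) and isnan[i]:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            run_len = i - run_start
            if run_len <= max_gap and run_start > 0 and i < len(y):
                y[run_start:i] = np.interp(idx[run_start:i],
                                           [run_start - 1, i], [y[run_start - 1], y[i]])
            run_start = None
    return y


# ---------------------------------------------------------------------------
# segmentation

def segment_trajectory(traj: Trajectory, min_size: int = 3,
                       penalty_scale: float = 3.0,
                       sigma: float | None = None) -> list[Segment]:
    """Piecewise-linear change-point decomposition of a trajectory.

    Breakpoints come from an exact penalized least-squares partition
    (BIC-style penalty, noise estimated from first-difference MAD);
    each segment is then refit by OLS.
    """
    if traj.n_frames < min_size:
        raise ValueError(f"trajectory must have at least {min_size} frames")
    t, y = traj.t_s, traj.pos_um
    bkps = piecewise_linear_breakpoints(t, y, min_size=min_size,
                                        penalty_scale=penalty_scale, sigma=sigma)
    bounds = [int(b) for b in (0, *bkps, traj.n_frames)]
    segments = []
    for i0, i1 in zip(bounds[:-1], bounds[1:]):
        # the breakpoint's flanking sample lies on both adjoining lines of a
        # continuous piecewise-linear signal: share it, and count the
        # interval entering the segment toward the segment's displacement
        j0 = max(i0 - 1, 0)
        tt, yy = t[j0:i1], y[j0:i1]
        if i1 - j0 >= 2:
            slope, _ = np.polyfit(tt, yy, 1)
        else:
            slope = 0.0
        segments.append(Segment(i0=i0, i1=i1, t_start=float(t[i0]), t_end=float(t[i1 - 1]),
                                slope_um_s=float(slope),
                                displacement_um=float(slope * (t[i1 - 1] - t[j0]))))
    return segments


# ---------------------------------------------------------------------------
# event extraction

def _group_runs(segments: Sequence[Segment], v_min: float) -> list[Run]:
    runs: list[Run] = []
    group: list[Segment] = []

    def close(next_away: Optional[Segment]) -> None:
        nonlocal group
        toward = [s for s in group if s.kind(v_min) == "toward"]
        if toward:
            runs.append(Run(segments=list(group), i_start=toward[0].i0,
                            i_end=group[-1].i1 - 1, next_away=next_away))
        group = []

    for s in segments:
        if s.kind(v_min) == "away":
            close(s)
        else:
            group.append(s)
    close(None)
    return runs


def detect_release(traj: Trajectory, run: Run, recovery_frac: float = 0.8,
                   extension_tol: float = 0.1) -> bool:
    """Single-step release: within one frame after the run the free end
    recovers at least ``recovery_frac`` of the compacted distance and
    lands within ``extension_tol`` of the pre-compaction extension."""
    e = run.i_end
    if e + 1 >= traj.n_frames:
        return False
    pre_ext = float(traj.pos_um[run.i_start])
    compacted = pre_ext - float(traj.pos_um[e])
    if compacted <= 0:
        return False
    jump = float(traj.pos_um[e + 1]) - float(traj.pos_um[e])
    return (jump >= recovery_frac * compacted
            and abs(float(traj.pos_um[e + 1]) - pre_ext) <= extension_tol * pre_ext)


def classify_termination(run: Run, traj: Trajectory, v_min: Optional[float] = None,
                         barrier_pos_um: float = 0.0) -> Termination:
    """Assign the single termination label of a compaction run.

    Precedence: complete > release > reversal > stall.  A run whose free
    end comes within one pixel of the barrier is complete regardless of
    what follows; a run cut off by the end of the record defaults to
    stall (and is always censored, so the label carries no weight).
    """
    if v_min is None:
        v_min = default_v_min(traj.geometry)
    px = traj.geometry.pixel_size_um
    run_pos = traj.pos_um[run.i_start:run.i_end + 1]
    if float(np.min(run_pos)) <= barrier_pos_um + px:
        return Termination.COMPLETE
    if detect_release(traj, run):
        return Termination.RELEASE
    if run.next_away is not None and (run.next_away.i1 - run.next_away.i0) >= 2:
        return Termination.REVERSAL
    return Termination.STALL


def extract_events(segments: Sequence[Segment], traj: Trajectory,
                   arrival_t: float = 0.0, v_min: Optional[float] = None,
                   barrier_pos_um: float = 0.0,
                   annotations: Optional[dict[int, CensorReason]] = None,
                   release_is_dissociation: bool = True) -> list[CompactionEvent]:
    """Group segments into compaction events with censoring and lag.

    A compaction run is a maximal group of toward-barrier segments
    (interleaved stalls do not break a run) delimited by away-from-
    barrier segments or the record boundaries.  Processivity is the
    summed positive displacement of the run's toward segments.  Events
    are right-censored when the run reaches within 1 px of the barrier,
    touches either record boundary, or carries an explicit annotation
    (protein dissociation / DNA breakage); a single-step release is
    attributed to protein dissociation by default.

    ``annotations`` optionally maps run index -> CensorReason for
    externally known dissociation/breakage calls.
    """
    if v_min is None:
        v_min = default_v_min(traj.geometry)
    if arrival_t > traj.t_s[-1]:
        raise ValueError("arrival_t is after the end of the record")
    runs = _group_runs(segments, v_min)
    events: list[CompactionEvent] = []
    for k, run in enumerate(runs):
        toward = [s for s in run.segments if s.kind(v_min) == "toward"]
        velocities = [-s.slope_um_s for s in toward]
        processivity = float(sum(-s.displacement_um for s in toward))
        termination = classify_termination(run, traj, v_min, barrier_pos_um)

        censor = CensorReason.NONE
        still_moving_at_end = (run.segments[-1].kind(v_min) == "toward"
                               and run.i_end >= traj.n_frames - 1)
        if annotations and k in annotations:
            censor = CensorReason(annotations[k])
        elif termination == Termination.COMPLETE:
            censor = CensorReason.BARRIER_1PX
        elif still_moving_at_end or run.i_start == 0:
            censor = CensorReason.END_OF_RECORD
        elif termination == Termination.RELEASE and release_is_dissociation:
            censor = CensorReason.DISSOCIATION

        lag = float(traj.t_s[run.i_start] - arrival_t) if k == 0 else None
        events.append(CompactionEvent(
            molecule_id=traj.molecule_id, run_id=k,
            velocities_um_s=velocities, processivity_um=processivity,
            censored=censor != CensorReason.NONE, censor_reason=censor,
            termination=termination, lag_s=lag,
            t_start_s=float(traj.t_s[run.i_start]),
            t_end_s=float(traj.t_s[run.i_end])))
    return events


# ---------------------------------------------------------------------------
# nucleosome collisions

def score_collisions(traj: Trajectory, nuc_positions_um: Sequence[float],
                     segments: Optional[Sequence[Segment]] = None,
                     v_min: Optional[float] = None,
                     window_px: float = 2.0,
                     smooth: bool = True) -> list[CollisionRecord]:
    """Score the outcome of each condensin-nucleosome encounter.

    For every nucleosome that the compacting free end reaches during a
    run: ``bypass_no_pause`` if it is traversed with no frame of
    sub-``v_min`` speed inside a +/-``window_px`` window around the
    nucleosome; ``bypass_with_pause`` if at least one such frame
    precedes traversal; otherwise the run's own termination label
    (stall / release / reversal) when the run ends inside the window.
    """
    if v_min is None:
        v_min = default_v_min(traj.geometry)
    if segments is None:
        segments = segment_trajectory(traj)
    w = window_px * traj.geometry.pixel_size_um
    span = float(np.nanmax(traj.pos_um))
    for p in nuc_positions_um:
        if not (0.0 <= p <= span):
            raise ValueError(f"nucleosome position {p} outside the DNA span")
    pos = traj.pos_um
    if smooth and traj.n_frames >= 3:
        pos = _median3(pos)
    dt = traj.dt
    runs = _group_runs(segments, v_min)
    records: list[CollisionRecord] = []
    for k, run in enumerate(runs):
        rpos = pos[run.i_start:run.i_end + 1]
        start_pos, min_pos = float(rpos[0]), float(np.min(rpos))
        termination = classify_termination(run, traj, v_min)
        for nuc in sorted(nuc_positions_um, reverse=True):
            if nuc >= start_pos:
                continue
            crossed = min_pos < nuc - w
            in_window = np.nonzero(np.abs(rpos - nuc) <= w)[0]
            if crossed:
                pause = 0
                for i in in_window:
                    j = run.i_start + i
                    if j + 1 < traj.n_frames and abs(pos[j + 1] - pos[j]) / dt < v_min:
                        pause += 1
                records.append(CollisionRecord(
                    traj.molecule_id, k, float(nuc),
                    CollisionOutcome.BYPASS_WITH_PAUSE if pause else CollisionOutcome.BYPASS_NO_PAUSE,
                    pause_frames=pause))
            elif abs(float(rpos[-1]) - nuc) <= w:
                outcome = {Termination.STALL: CollisionOutcome.STALL,
                           Termination.RELEASE: CollisionOutcome.RELEASE,
                           Termination.REVERSAL: CollisionOutcome.REVERSAL}.get(termination)
                if outcome is not None:
                    records.append(CollisionRecord(traj.molecule_id, k, float(nuc), outcome))
    return records


def _median3(y: np.ndarray) -> np.ndarray:
    out = y.copy()
    out[1:-1] = np.median(np.column_stack([y[:-2], y[1:-1], y[2:]]), axis=1)
    return out


# ---------------------------------------------------------------------------
# tabular I/O

def events_to_dataframe(events: Sequence[CompactionEvent],
                        geometry: CurtainGeometry) -> pd.DataFrame:
    rows = []
    for e in events:
        for v in e.velocities_um_s:
            rows.append({
                "molecule_id": e.molecule_id, "run_id": e.run_id,
                "velocity_um_s": v, "velocity_bp_s": um_to_bp(v, geometry),
                "processivity_um": e.processivity_um,
                "processivity_kbp": um_to_bp(e.processivity_um, geometry) / 1e3,
                "censored": e.censored, "censor_reason": e.censor_reason.value,
                "termination": e.termination.value, "lag_s": e.lag_s,
            })
    return pd.DataFrame(rows)


def collisions_to_dataframe(records: Sequence[CollisionRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "molecule_id": r.molecule_id, "run_id": r.run_id,
        "nucleosome_pos_um": r.nucleosome_pos_um,
        "outcome": r.outcome.value, "pause_frames": r.pause_frames,
    } for r in records])


def trajectory_to_dataframe(traj: Trajectory) -> pd.DataFrame:
    return pd.DataFrame({"molecule_id": traj.molecule_id,
                         "frame": np.arange(traj.n_frames),
                         "t_s": traj.t_s, "pos_um": np.round(traj.pos_um, 4)})


def trajectories_from_dataframe(df: pd.DataFrame,
                                geometry: CurtainGeometry) -> list[Trajectory]:
    out = []
    for mol, g in df.groupby("molecule_id"):
        g = g.sort_values("t_s")
        out.append(Trajectory(int(mol), g["t_s"].to_numpy(),
                              g["pos_um"].to_numpy(), geometry))
    return out
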