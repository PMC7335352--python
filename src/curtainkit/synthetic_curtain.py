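"""Seeded synthetic single-molecule data with known ground truth.

No raw single-molecule data accompanies the study this pipeline targets,
so every stage is exercised against simulations that emulate the
phenomenology of condensin DNA-curtain experiments:

* stochastic compaction initiation at free DNA ends over a ~20 min
  observation window, with exponentially distributed lag times,
* piecewise-linear free-end motion: processive compaction runs with
  lognormal velocities and exponential (memoryless) processivities,
  interrupted by stalls, gradual reversals and single-frame releases,
* two-sided (symmetric) vs one-sided (asymmetric) U-loop growth,
* nucleosome decoration (~3-4 per DNA) with bypass / pause / stall /
  release / reversal collision outcomes,
* stepwise fluorophore photobleaching traces, and
* fluorescence-polarization titrations and ATPase time courses drawn
  from the same binding / kinetic models the fitting stage assumes.

Determinism: a single integer seed drives everything; per-molecule
substreams are spawned from a SeedSequence so any subset of molecules
is reproducible on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .kymo_quant import Kymograph, Trajectory
from .symmetry import LoopEvent
from .units import CurtainGeometry, TetherMode, EXTENSION_U_SHAPED_UM

LN2 = math.log(2.0)

#: observation window emulating the ~20 min acquisitions, s
DEFAULT_WINDOW_S = 1200.0


@dataclass(frozen=True)
class SimParams:
    """Ground-truth parameters of the synthetic curtain.

    Defaults are the condensin I naked-DNA study conditions: median
    compaction velocity 0.201 μm/s with IQR 0.216 μm/s, processivity
    half-life 5.2 μm, ~31.5% single-step releases, lag times spread
    over the 20-min window, and 3-4 nucleosomes per DNA with ~80%
    unimpeded bypass of which ~90% show no resolvable pause.
    """

    seed: int = 0
    n_molecules: int = 50
    # lag model: time from condensin arrival to compaction onset
    lag_distribution: str = "exponential"   # or "uniform"
    lag_scale_s: float = 400.0
    # velocity model (lognormal, parameterized by median and IQR)
    velocity_median_um_s: float = 0.201
    velocity_iqr_um_s: float = 0.216
    # processivity model (exponential run length)
    processivity_half_life_um: float = 5.2
    # event-termination mixture for runs that end before the barrier
    p_release_per_event: float = 0.315
    p_reversal: float = 0.5
    stall_rate: float = 0.01          # probability per frame of a pause frame
    # imaging noise
    noise_sd_px: float = 0.5
    punctum_psf_sd_px: float = 1.0
    background: float = 100.0
    dna_intensity: float = 100.0
    # nucleosome decoration and collision outcomes
    nucleosome_count_range: tuple[int, int] = (3, 4)
    p_bypass: float = 0.8
    p_pause_given_bypass: float = 0.1
    pause_duration_frames: int = 2
    duration_s: float = DEFAULT_WINDOW_S
    reversal_frames: int = 4
    geometry: CurtainGeometry = field(default_factory=CurtainGeometry)

    def __post_init__(self) -> None:
        for name in ("p_release_per_event", "p_reversal", "stall_rate",
                     "p_bypass", "p_pause_given_bypass"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.processivity_half_life_um <= 0:
            raise ValueError("processivity_half_life_um must be > 0")
        if self.velocity_iqr_um_s < 0:
            raise ValueError("velocity_iqr_um_s must be >= 0")
        if self.geometry.extension_um <= 2 * self.geometry.pixel_size_um:
            raise ValueError("degenerate geometry: extension smaller than 2 px")

    def molecule_rng(self, molecule_id: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, molecule_id)))


@dataclass
class EventTruth:
    velocity_um_s: float          # drawn instantaneous compaction velocity
    processivity_um: float        # observed positive displacement of the run
    lag_s: float
    termination: str
    censored: bool                # True when the true run length exceeds observed
    t_move_start_s: float = 0.0
    t_move_end_s: float = 0.0

    @property
    def realized_velocity_um_s(self) -> float:
        """Mean speed over the run's moving phase (pauses included)."""
        dt = self.t_move_end_s - self.t_move_start_s
        return self.processivity_um / dt if dt > 0 else 0.0


@dataclass
class CollisionTruth:
    nucleosome_pos_um: float
    outcome: str
    pause_frames: int


@dataclass
class GroundTruth:
    molecule_id: int
    events: list[EventTruth] = field(default_factory=list)
    nucleosome_pos_um: list[float] = field(default_factory=list)
    collisions: list[CollisionTruth] = field(default_factory=list)
    n_fluors: int = 0
    symmetric: Optional[bool] = None
    rates_um_s: Optional[tuple[float, float]] = None
    pos_um_clean: Optional[np.ndarray] = None   # noiseless free-end positions

    @property
    def lag_s(self) -> Optional[float]:
        return self.events[0].lag_s if self.events else None


def lognormal_from_median_iqr(median: float, iqr: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given median and IQR.

    mu = ln(median); sigma solves median*(e^(z.75 s) - e^(-z.75 s)) = IQR
    with z.75 the 75th normal quantile, i.e. 2 median sinh(z.75 s) = IQR.
    """
    if median <= 0:
        raise ValueError("median must be > 0")
    mu = math.log(median)
    if iqr == 0:
        return mu, 0.0
    z75 = 0.6744897501960817
    sigma = math.asinh(iqr / (2.0 * median)) / z75
    return mu, sigma


def _draw_velocity(rng: np.random.Generator, p: SimParams) -> float:
    mu, sigma = lognormal_from_median_iqr(p.velocity_median_um_s, p.velocity_iqr_um_s)
    return float(rng.lognormal(mu, sigma))


def _draw_lag(rng: np.random.Generator, p: SimParams) -> float:
    if p.lag_distribution == "uniform":
        return float(rng.uniform(0.0, p.duration_s))
    # exponential, not truncated: a lag beyond the window simply means
    # the molecule never initiates within the record
    return float(rng.exponential(p.lag_scale_s))


def simulate_compaction_trajectory(
    p: SimParams, molecule_id: int = 0, with_nucleosomes: bool = False,
) -> tuple[Trajectory, GroundTruth]:
    """Simulate one molecule's free-end trajectory over the window.

    The free end starts at full extension; after a stochastic lag a
    compaction run proceeds at a drawn velocity until the drawn
    processivity is exhausted or the barrier (1 px) is reached, with
    stall frames inserted at ``stall_rate``.  A finished run terminates
    by single-frame release, gradual reversal, or stall; after release
    or reversal a new lag and run may follow within the record.  With
    nucleosomes, each crossing draws a bypass / pause / terminal
    outcome that overrides the run at the collision point.
    """
    g = p.geometry
    rng = p.molecule_rng(molecule_id)
    dt = g.frame_interval_s
    n_frames = int(round(p.duration_s / dt))
    px = g.pixel_size_um
    full_ext = g.extension_um
    barrier = px  # within 1 px of the barrier counts as complete

    truth = GroundTruth(molecule_id=molecule_id)
    if with_nucleosomes:
        lo, hi = p.nucleosome_count_range
        n_nuc = int(rng.integers(lo, hi + 1))
        truth.nucleosome_pos_um = sorted(
            rng.uniform(1.0, full_ext - 1.0, size=n_nuc).tolist(), reverse=True)

    pos = np.empty(n_frames)
    f = 0
    cur = full_ext
    t_clock = 0.0
    while f < n_frames:
        lag = _draw_lag(rng, p)
        start_f = f + int(math.ceil(lag / dt))
        pos[f:min(start_f, n_frames)] = cur
        if start_f >= n_frames:
            f = n_frames
            break
        f = start_f
        v = _draw_velocity(rng, p)
        proc_budget = float(rng.exponential(p.processivity_half_life_um / LN2))
        # single-step release competes with run-length exhaustion as an
        # independent exponential distance (so releases genuinely censor)
        if p.p_release_per_event > 0:
            release_scale = (p.processivity_half_life_um / LN2
                             * (1 - p.p_release_per_event) / p.p_release_per_event)
            release_dist = float(rng.exponential(release_scale))
        else:
            release_dist = math.inf
        stop_dist = min(proc_budget, release_dist)
        moved = 0.0
        lag_record = f * dt - t_clock
        t_move_start = max(f - 1, 0) * dt
        nuc_ahead = [n for n in truth.nucleosome_pos_um if n < cur - px]
        outcome: Optional[str] = None
        pause_left = 0
        while f < n_frames:
            if pause_left > 0:
                pause_left -= 1
                pos[f] = cur
                f += 1
                continue
            if p.stall_rate > 0 and rng.random() < p.stall_rate:
                pos[f] = cur
                f += 1
                continue
            step = v * dt
            if nuc_ahead and cur - step <= nuc_ahead[0]:
                nuc = nuc_ahead.pop(0)
                if rng.random() < p.p_bypass:
                    if rng.random() < p.p_pause_given_bypass:
                        truth.collisions.append(CollisionTruth(
                            nuc, "bypass_with_pause", p.pause_duration_frames))
                        moved += cur - nuc
                        cur = nuc
                        pos[f] = cur
                        f += 1
                        pause_left = p.pause_duration_frames - 1
                        continue
                    truth.collisions.append(CollisionTruth(nuc, "bypass_no_pause", 0))
                else:
                    outcome = str(rng.choice(["stall", "release", "reversal"]))
                    truth.collisions.append(CollisionTruth(nuc, outcome, 0))
                    moved += cur - nuc
                    cur = nuc
                    pos[f] = cur
                    f += 1
                    break
            if moved + step >= stop_dist:
                # exhaust the run (or hit the release point) mid-flight
                cur -= stop_dist - moved
                moved = stop_dist
                pos[f] = cur
                f += 1
                break
            if cur - step <= barrier:
                # clamp the final step at the barrier
                moved += cur
                cur = 0.0
                pos[f] = cur
                f += 1
                break
            cur -= step
            moved += step
            pos[f] = cur
            f += 1

        t_move_end = max(f - 1, 0) * dt
        censored = False
        if cur <= barrier:
            term = "complete"
            censored = True       # true run length exceeds the DNA left
            pos[f:] = cur
            f = n_frames
        elif f >= n_frames:
            term = "stall"        # still moving at the record end
            censored = True
        elif outcome is not None:
            term = outcome
        elif release_dist < proc_budget:
            term = "release"
            censored = True       # run truncated by condensin dissociation
        elif rng.random() < p.p_reversal:
            term = "reversal"
        else:
            term = "stall"

        if term == "release" and f < n_frames:
            cur = full_ext
            pos[f] = cur
            f += 1
            t_clock = f * dt
        elif term == "reversal" and f < n_frames:
            rev_v = v * float(rng.uniform(0.3, 0.8))
            for _ in range(p.reversal_frames):
                if f >= n_frames:
                    break
                cur = min(cur + rev_v * dt, full_ext)
                pos[f] = cur
                f += 1
            t_clock = f * dt
        elif term == "stall" and f < n_frames:
            pos[f:] = cur
            f = n_frames

        truth.events.append(EventTruth(
            velocity_um_s=v, processivity_um=moved, lag_s=lag_record,
            termination=term, censored=censored,
            t_move_start_s=t_move_start, t_move_end_s=t_move_end))
        if term not in ("release", "reversal"):
            break
    if f < n_frames:
        pos[f:] = cur

    truth.pos_um_clean = pos.copy()
    noisy = pos + rng.normal(0.0, p.noise_sd_px * px, size=n_frames)
    noisy = np.clip(noisy, 0.0, None)
    t = np.arange(n_frames) * dt
    return Trajectory(molecule_id, t, noisy, g), truth


def simulate_dataset(p: SimParams, with_nucleosomes: bool = False,
                     ) -> tuple[list[Trajectory], list[GroundTruth]]:
    """Simulate ``p.n_molecules`` molecules; every trajectory has a
    matching ground-truth record keyed by molecule id."""
    trajs, truths = [], []
    for m in range(p.n_molecules):
        tr, gt = simulate_compaction_trajectory(p, m, with_nucleosomes)
        trajs.append(tr)
        truths.append(gt)
    return trajs, truths


# ---------------------------------------------------------------------------
# kymograph rendering

def render_kymograph(traj: Trajectory, p: SimParams,
                     truth: Optional[GroundTruth] = None,
                     noise: bool = True) -> Kymograph:
    """Render a trajectory as a kymograph image.

    The DNA is drawn as a uniform-intensity line from the barrier to
    the free end (fractional coverage in the edge pixel); the compacted
    DNA forms a Gaussian punctum at the free end whose integrated
    intensity is proportional to the compacted length.  Nucleosome
    spots, if present in the ground truth, are rendered into a second
    channel; they travel with the punctum once collected and return to
    their original position after a release.  Poisson noise emulates
    shot noise when ``noise`` is on.
    """
    g = traj.geometry
    px = g.pixel_size_um
    n_px = int(math.ceil(g.extension_um / px)) + 8
    n_frames = traj.n_frames
    rng = p.molecule_rng(traj.molecule_id + 10_000_000)

    centers = np.arange(n_px) + 0.5
    img = np.full((n_frames, n_px), p.background, dtype=float)
    full_ext_px = g.extension_um / px
    for f in range(n_frames):
        e = traj.pos_um[f] / px
        cov = np.clip(e - np.arange(n_px), 0.0, 1.0)
        img[f] += p.dna_intensity * cov
        compacted_px = max(full_ext_px - e, 0.0)
        amp = p.dna_intensity * compacted_px
        if amp > 0:
            s = p.punctum_psf_sd_px
            img[f] += amp / (s * math.sqrt(2 * math.pi)) * np.exp(
                -0.5 * ((centers - e) / s) ** 2)

    ch2 = None
    if truth is not None and truth.nucleosome_pos_um:
        ch2 = np.full((n_frames, n_px), p.background, dtype=float)
        s = p.punctum_psf_sd_px
        for nuc in truth.nucleosome_pos_um:
            nuc_track = np.minimum(nuc, traj.pos_um) / px
            for f in range(n_frames):
                ch2[f] += 8 * p.dna_intensity / (s * math.sqrt(2 * math.pi)) * np.exp(
                    -0.5 * ((centers - nuc_track[f]) / s) ** 2)

    if noise:
        img = rng.poisson(img).astype(float)
        if ch2 is not None:
            ch2 = rng.poisson(ch2).astype(float)
    return Kymograph(image=img, geometry=g, channel2=ch2,
                     molecule_id=traj.molecule_id)


# ---------------------------------------------------------------------------
# U-shaped loop events

def simulate_u_loop_event(symmetric: bool, rates_um_s: tuple[float, float],
                          p: SimParams, molecule_id: int = 0,
                          n_frames: int = 60,
                          min_side_um: float = 1.0) -> tuple[LoopEvent, GroundTruth]:
    """Simulate per-frame side lengths of a U-shaped DNA during loop
    extrusion: both sides shrink at the given rates (equal when
    symmetric) until a side drops to ``min_side_um`` (side lengths are
    not measurable closer to the tether points) or the record ends."""
    if any(r < 0 for r in rates_um_s):
        raise ValueError("rates must be >= 0")
    if symmetric and rates_um_s[0] != rates_um_s[1]:
        raise ValueError("symmetric events must have equal side rates")
    geom = p.geometry
    if geom.tether_mode != TetherMode.U_SHAPED:
        geom = replace(geom, extension_um=EXTENSION_U_SHAPED_UM,
                       tether_mode=TetherMode.U_SHAPED)
    rng = p.molecule_rng(molecule_id + 20_000_000)
    dt = geom.frame_interval_s
    l0 = geom.extension_um / 2.0
    t = np.arange(n_frames) * dt
    left = l0 - rates_um_s[0] * t
    right = l0 - rates_um_s[1] * t
    keep = (left > min_side_um) & (right > min_side_um)
    if keep.sum() >= 5:
        left, right, t = left[keep], right[keep], t[keep]
    sd = p.noise_sd_px * geom.pixel_size_um
    if sd > 0:
        left = np.clip(left + rng.normal(0, sd, size=left.size), 0.01, None)
        right = np.clip(right + rng.normal(0, sd, size=right.size), 0.01, None)
    ev = LoopEvent(molecule_id=molecule_id, t_s=t, left_len_um=left,
                   right_len_um=right, geometry=geom)
    gt = GroundTruth(molecule_id=molecule_id, symmetric=symmetric,
                     rates_um_s=tuple(rates_um_s))
    return ev, gt


def simulate_u_loop_set(p: SimParams, n_events: int = 100,
                        frac_symmetric: float = 0.8,
                        rate_um_s: float = 0.1,
                        n_frames: int = 60) -> tuple[list[LoopEvent], list[GroundTruth]]:
    """A mixed set of symmetric/asymmetric loop events (80/20 for CI)."""
    rng = np.random.default_rng(np.random.SeedSequence((p.seed, 30_000_000)))
    events, truths = [], []
    for m in range(n_events):
        sym = bool(rng.random() < frac_symmetric)
        scale = float(rng.uniform(0.5, 1.5))
        if sym:
            rates = (rate_um_s * scale / 2, rate_um_s * scale / 2)
        else:
            one_sided_rate = rate_um_s * scale
            rates = (one_sided_rate, 0.0) if rng.random() < 0.5 else (0.0, one_sided_rate)
        ev, gt = simulate_u_loop_event(sym, rates, p, molecule_id=m, n_frames=n_frames)
        events.append(ev)
        truths.append(gt)
    return events, truths


# ---------------------------------------------------------------------------
# photobleaching traces

def simulate_bleach_trace(n_fluors: int, bleach_rate: float = 0.02,
                          step_height: float = 100.0, noise_sd: float = 10.0,
                          duration_s: float = 300.0, frame_interval_s: float = 1.0,
                          seed: int = 0) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Staircase intensity trace: ``n_fluors`` downward steps at
    exponential times plus Gaussian noise.  Returns (t, intensity, truth)."""
    if n_fluors < 0:
        raise ValueError("n_fluors must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 40_000_000)))
    t = np.arange(0.0, duration_s, frame_interval_s)
    bleach_times = np.sort(rng.exponential(1.0 / bleach_rate, size=n_fluors))
    alive = (t[:, None] < bleach_times[None, :]).sum(axis=1) if n_fluors else np.zeros_like(t)
    intensity = step_height * alive + rng.normal(0.0, noise_sd, size=t.size)
    gt = GroundTruth(molecule_id=seed, n_fluors=n_fluors)
    return t, intensity, gt


# ---------------------------------------------------------------------------
# biochemistry

def default_conc_grid_um(n: int = 11, lo: float = 0.05, hi: float = 20.0) -> np.ndarray:
    """Log-spaced titration grid spanning both reported Kd values."""
    return np.geomspace(lo, hi, n)


def simulate_fp_titration(kd_um: float, fp_max_mp: float = 100.0,
                          dna_conc_um: float = 0.05,
                          conc_grid_um: Optional[Sequence[float]] = None,
                          noise_sd_mp: Optional[float] = None,
                          n_reps: int = 3, seed: int = 0) -> pd.DataFrame:
    """Synthetic FP titration from the quadratic ligand-depletion model,
    three replicates per concentration by default; noise defaults to 2%
    of FP_max."""
    from .biochem_fits import FPModel, fp_predict
    if conc_grid_um is None:
        conc_grid_um = default_conc_grid_um()
    if noise_sd_mp is None:
        noise_sd_mp = 0.02 * fp_max_mp
    rng = np.random.default_rng(np.random.SeedSequence((seed, 50_000_000)))
    model = FPModel(kd_um=kd_um, fp_max_mp=fp_max_mp, dna_conc_um=dna_conc_um)
    rows = []
    for c in conc_grid_um:
        mu = fp_predict(c, model)
        for rep in range(n_reps):
            rows.append({"conc_uM": float(c), "rep": rep,
                         "fp_mP": float(mu + rng.normal(0.0, noise_sd_mp))})
    return pd.DataFrame(rows)


def simulate_atpase_timecourse(rate_per_s: float, enzyme_um: float = 0.2,
                               atp_um: float = 2000.0,
                               timepoints_s: Optional[Sequence[float]] = None,
                               noise_sd: float = 0.005,
                               n_reps: int = 3,
                               seed: int = 0) -> pd.DataFrame:
    """Synthetic ADP/(ADP+ATP) time course, three replicates per
    timepoint by default.

    The hydrolyzed fraction grows as k t with k = rate * [E] / [ATP]
    while the reaction is in its linear range, rolling over smoothly
    (C1 exponential knee above a hydrolyzed fraction of 0.25) toward
    full conversion at long times.
    """
    if timepoints_s is None:
        timepoints_s = np.linspace(75.0, 600.0, 8)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 60_000_000)))
    k = rate_per_s * enzyme_um / atp_um
    t = np.asarray(timepoints_s, dtype=float)
    x = k * t
    knee = 0.25
    clean = np.where(x <= knee, x,
                     1.0 - (1.0 - knee) * np.exp(-(x - knee) / (1.0 - knee)))
    rows = []
    for rep in range(n_reps):
        frac = clean + rng.normal(0.0, noise_sd, size=t.size)
        for ti, fi in zip(t, np.clip(frac, 0.0, 1.0)):
            rows.append({"t_s": float(ti), "rep": rep, "adp_fraction": float(fi)})
    return pd.DataFrame(rows)


def simulate_binding_times(half_life_s: float, n: int,
                           censor_time_s: float = 1200.0,
                           seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Exponential DNA-binding dwell times right-censored at the end of
    the record; returns (observed_times, event_observed_flags)."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 70_000_000)))
    true = rng.exponential(half_life_s / LN2, size=n)
    observed = np.minimum(true, censor_time_s)
    event_observed = true <= censor_time_s
    return observed, event_observed
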