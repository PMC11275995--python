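"""Synthetic FRAP movies and Hi-C contact matrices with known ground truth.

The generators emulate the acquisition protocol the analysis assumes — a
two-phase confocal time series (fast frames around the bleach, slower frames
through the recovery), a 1 um circular bleach spot inside a drifting
elliptical nucleus, exponential acquisition photobleaching, additive
background and Gaussian pixel noise — and contact matrices with power-law
distance decay, TAD blocks and focal loops. Every generator is deterministic
given its seed, and every output carries its ground truth so downstream
estimates can be checked against the values that produced the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hic import ContactMatrix
from .preprocess import FrapTrace, NormalizedTrace


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Frame times of a two-phase FRAP acquisition.

    ``bleach_after`` is the number of prebleach frames: frames
    ``0 .. bleach_after-1`` precede the bleach and frame ``bleach_after`` is
    the first post-bleach frame. ``phase_boundary`` is the index of the first
    phase-2 frame (equal to ``n_frames`` for a single-phase schedule).
    """

    frame_times: np.ndarray
    bleach_after: int
    phase_boundary: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "frame_times", np.asarray(self.frame_times, dtype=float))
        if self.frame_times.ndim != 1 or self.frame_times.size < 2:
            raise ValueError("schedule needs at least two frames")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if not (1 <= self.bleach_after < self.frame_times.size):
            raise ValueError("bleach_after must satisfy 1 <= bleach_after < n_frames")

    @property
    def n_frames(self) -> int:
        return self.frame_times.size

    @property
    def post_bleach_times_s(self) -> np.ndarray:
        """Times of post-bleach frames with t = 0 at the first post-bleach frame."""
        b = self.bleach_after
        return self.frame_times[b:] - self.frame_times[b]


class InvalidScheduleError(ValueError):
    pass


def make_acquisition_schedule(
    phase1_n: int,
    phase1_dt: float,
    phase2_n: int,
    phase2_dt: float,
    bleach_after: int,
) -> AcquisitionSchedule:
    """Build a contiguous two-phase schedule.

    Phase 1 frames sit at ``0, dt1, ..., (n1-1)*dt1``; phase 2 continues from
    the last phase-1 frame at spacing ``dt2`` with no dead time between
    phases. The bleach must fall inside phase 1.
    """
    if phase1_n < 0 or phase2_n < 0 or phase1_n + phase2_n < 2:
        raise InvalidScheduleError("need at least two frames across the phases")
    if (phase1_n > 0 and phase1_dt <= 0) or (phase2_n > 0 and phase2_dt <= 0):
        raise InvalidScheduleError("frame spacing must be positive")
    if not (1 <= bleach_after <= phase1_n):
        raise InvalidScheduleError("bleach_after must lie within phase 1")
    t1 = np.arange(phase1_n) * phase1_dt
    t_last = t1[-1] if phase1_n else -phase2_dt
    t2 = t_last + phase2_dt * np.arange(1, phase2_n + 1)
    return AcquisitionSchedule(
        frame_times=np.concatenate([t1, t2]),
        bleach_after=bleach_after,
        phase_boundary=phase1_n,
    )


def reference_schedule() -> AcquisitionSchedule:
    """The reference acquisition: 25 frames at 0.5 s then 160 at 4 s, bleach after frame 8."""
    return make_acquisition_schedule(25, 0.5, 160, 4.0, bleach_after=8)


@dataclass(frozen=True)
class TwoStateKinetics:
    """Parameters of the two-state reaction-dominant recovery model.

    ``FRAP(t) = 1 - c_eq_fast * exp(-k_off_fast * t) - c_eq_slow * exp(-k_off_slow * t)``

    with rates in 1/min and ``k_off_slow < k_off_fast``. The slow amplitude is
    the specific (chromatin) bound fraction and ``1/k_off_slow`` the specific
    residence time; the fast component captures transient, non-specific
    binding. ``1 - c_eq_fast - c_eq_slow`` is the free fraction, the recovery
    level immediately after the bleach.
    """

    c_eq_fast: float
    c_eq_slow: float
    k_off_fast: float
    k_off_slow: float

    def __post_init__(self) -> None:
        if min(self.c_eq_fast, self.c_eq_slow, self.k_off_fast, self.k_off_slow) < 0:
            raise ValueError("all kinetic parameters must be non-negative")
        if self.c_eq_fast + self.c_eq_slow > 1 + 1e-12:
            raise ValueError("amplitudes must sum to at most 1")
        if not self.k_off_slow < self.k_off_fast:
            raise ValueError("k_off_slow must be smaller than k_off_fast")

    def recovery(self, t_seconds) -> np.ndarray:
        """Model recovery at times ``t_seconds`` after the bleach."""
        t_min = np.asarray(t_seconds, dtype=float) / 60.0
        return (
            1.0
            - self.c_eq_fast * np.exp(-self.k_off_fast * t_min)
            - self.c_eq_slow * np.exp(-self.k_off_slow * t_min)
        )


def two_state_recovery(t_seconds, kinetics: TwoStateKinetics) -> np.ndarray:
    return kinetics.recovery(t_seconds)


@dataclass(frozen=True)
class MovieGroundTruth:
    """Generative parameters of one synthetic FRAP movie."""

    kinetics: TwoStateKinetics
    photobleach_rate: float = 1e-3  # 1/s, acquisition photobleaching
    background_level: float = 10.0
    prebleach_intensity: float = 100.0  # nuclear signal above background
    bleach_depth: float = 1.0  # fraction of spot signal destroyed at the bleach
    drift_velocity: tuple[float, float] = (0.0, 0.0)  # px/frame
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.bleach_depth <= 1.0:
            raise ValueError("bleach_depth must be in [0, 1]")
        if self.noise_sd < 0 or self.photobleach_rate < 0:
            raise ValueError("noise_sd and photobleach_rate must be non-negative")


@dataclass
class FrapMovie:
    """A rendered FRAP movie plus the metadata the analysis needs."""

    frames: np.ndarray  # (n_frames, h, w)
    schedule: AcquisitionSchedule
    roi_diameter_um: float
    pixel_size_um: float
    roi_anchors: dict[int, tuple[float, float]]
    truth: MovieGroundTruth | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, h, w) stack")
        if self.frames.shape[0] != self.schedule.n_frames:
            raise ValueError("frame count does not match the schedule")
        if self.roi_diameter_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("roi_diameter_um and pixel_size_um must be positive")
        n = self.frames.shape[0]
        if any(not 0 <= f < n for f in self.roi_anchors):
            raise ValueError("roi_anchors contain out-of-range frame indices")


def simulate_normalized_recovery(
    kinetics: TwoStateKinetics,
    schedule: AcquisitionSchedule,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> NormalizedTrace:
    """Two-state recovery sampled on the post-bleach grid plus Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    t = schedule.post_bleach_times_s
    values = kinetics.recovery(t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=t.size)
    return NormalizedTrace(
        time_post_bleach_s=t, value=values, prebleach_value=np.ones(schedule.bleach_after)
    )


def simulate_frap_movie(
    truth: MovieGroundTruth,
    schedule: AcquisitionSchedule,
    shape: tuple[int, int] = (72, 72),
    nucleus_center: tuple[float, float] = (36.0, 36.0),
    nucleus_axes: tuple[float, float] = (26.0, 20.0),
    spot_center: tuple[float, float] = (44.0, 36.0),
    roi_diameter_um: float = 1.0,
    pixel_size_um: float = 0.1,
    anchor_every: int = 20,
) -> tuple[FrapMovie, FrapTrace]:
    """Render a drifting-nucleus FRAP movie and its exact ground-truth trace.

    Each frame is ``background + I0 * exp(-photobleach_rate * t)`` inside the
    nucleus ellipse; inside the bleach spot the nuclear signal is additionally
    multiplied by ``1 - bleach_depth * (1 - recovery(t))`` after the bleach
    frame, where ``recovery`` is the two-state model with t = 0 at the first
    post-bleach frame. Gaussian pixel noise of sd ``truth.noise_sd`` is added.

    Returns the movie (with ROI anchors tracking the drifted spot and the
    truth attached) and the noiseless ground-truth :class:`FrapTrace` computed
    in closed form.
    """
    h, w = shape
    n = schedule.n_frames
    times = schedule.frame_times
    vx, vy = truth.drift_velocity
    ax, ay = nucleus_axes
    radius_px = roi_diameter_um / 2.0 / pixel_size_um

    # spot must start inside the nucleus (drift moves both together)
    sx0 = spot_center[0] - nucleus_center[0]
    sy0 = spot_center[1] - nucleus_center[1]
    if ((abs(sx0) + radius_px) / ax) ** 2 + ((abs(sy0) + radius_px) / ay) ** 2 > 1.0:
        raise ValueError("bleach spot does not fit inside the nucleus")

    # nucleus must stay inside the frame at every drifted position
    for f in range(n):
        cx = nucleus_center[0] + vx * f
        cy = nucleus_center[1] + vy * f
        if cx - ax < 0 or cx + ax > w - 1 or cy - ay < 0 or cy + ay > h - 1:
            raise ValueError(f"nucleus drifts out of the frame at frame {f}")

    b = schedule.bleach_after
    t0 = times[b]
    decay = np.exp(-truth.photobleach_rate * times)
    spot_factor = np.ones(n)
    rec = truth.kinetics.recovery(times[b:] - t0)
    spot_factor[b:] = 1.0 - truth.bleach_depth * (1.0 - rec)

    rng = np.random.default_rng(truth.seed)
    yy, xx = np.mgrid[0:h, 0:w]
    frames = np.empty((n, h, w))
    anchors: dict[int, tuple[float, float]] = {}
    for f in range(n):
        cx = nucleus_center[0] + vx * f
        cy = nucleus_center[1] + vy * f
        px = spot_center[0] + vx * f
        py = spot_center[1] + vy * f
        nuc = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
        disc = (xx - px) ** 2 + (yy - py) ** 2 <= radius_px**2
        img = np.full((h, w), truth.background_level)
        sig = truth.prebleach_intensity * decay[f]
        img[nuc] += sig
        img[disc & nuc] += sig * (spot_factor[f] - 1.0)
        if truth.noise_sd > 0:
            img = img + rng.normal(0.0, truth.noise_sd, size=(h, w))
        frames[f] = img
        if f % anchor_every == 0 or f == n - 1:
            anchors[f] = (px, py)

    movie = FrapMovie(
        frames=frames,
        schedule=schedule,
        roi_diameter_um=roi_diameter_um,
        pixel_size_um=pixel_size_um,
        roi_anchors=anchors,
        truth=truth,
    )
    truth_trace = FrapTrace(
        time_s=times,
        i_bleach=truth.background_level + truth.prebleach_intensity * decay * spot_factor,
        i_nonbleach=truth.background_level + truth.prebleach_intensity * decay,
        i_background=np.full(n, truth.background_level),
        bleach_after=b,
        trace_id="ground-truth",
    )
    return movie, truth_trace


def simulate_contact_matrix(
    n_bins: int,
    resolution_bp: int,
    decay_exponent: float = -1.0,
    tads: list[tuple[int, int, float]] = (),
    loops: list[tuple[int, int, float, float]] = (),
    depth: float = 1e6,
    seed: int = 0,
    sample: bool = True,
    chrom: str = "chrS",
) -> ContactMatrix:
    """Simulate a binned contact matrix with decay, TADs and loops.

    The expected count at bin distance ``d`` is proportional to
    ``max(d, 1) ** decay_exponent``. Each TAD ``(start, end, enrichment)``
    multiplies within-domain contacts by ``enrichment`` and divides contacts
    with exactly one end inside the domain by the same factor (domains both
    self-associate and insulate across their boundary). Each loop
    ``(bin1, bin2, strength, spread)`` multiplies the expected matrix by
    ``1 + strength * G`` where G is a unit-height 2-D Gaussian of sd ``spread``
    bins at the anchor pair (and its mirror). The expected matrix is scaled to
    ``depth`` total counts and, with ``sample=True``, Poisson-sampled
    symmetrically; ``sample=False`` returns the expected matrix itself.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    if decay_exponent >= 0:
        raise ValueError("decay_exponent must be negative")
    if depth <= 0:
        raise ValueError("depth must be positive")

    idx = np.arange(n_bins)
    d = np.abs(idx[:, None] - idx[None, :])
    E = np.maximum(d, 1).astype(float) ** decay_exponent

    spans = sorted((int(a), int(b)) for a, b, _ in tads)
    for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
        if a2 < b1:
            raise ValueError("TAD intervals overlap")
    for a, b, enr in tads:
        if not (0 <= a < b <= n_bins):
            raise ValueError(f"TAD interval [{a}, {b}) outside [0, {n_bins})")
        if enr <= 0:
            raise ValueError("TAD enrichment must be positive")
        inside = (idx >= a) & (idx < b)
        within = np.outer(inside, inside)
        crossing = np.outer(inside, ~inside) | np.outer(~inside, inside)
        E[within] *= enr
        E[crossing] /= enr

    for i, j, strength, spread in loops:
        if not (0 <= i < n_bins and 0 <= j < n_bins):
            raise ValueError("loop anchors outside the matrix")
        if strength < 0 or spread <= 0:
            raise ValueError("loop strength must be >= 0 and spread > 0")
        g = np.exp(
            -((idx[:, None] - i) ** 2 + (idx[None, :] - j) ** 2) / (2.0 * spread**2)
        )
        E *= 1.0 + strength * (g + g.T)

    E = (E + E.T) / 2.0
    E *= depth / E.sum()

    if sample:
        rng = np.random.default_rng(seed)
        iu = np.triu_indices(n_bins)
        counts = np.zeros_like(E)
        counts[iu] = rng.poisson(E[iu]).astype(float)
        counts = counts + counts.T - np.diag(np.diag(counts))
    else:
        counts = E
    return ContactMatrix(counts, resolution_bp, chrom=chrom)
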