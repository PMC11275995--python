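"""FRAP movie preprocessing: ROI tracking, intensity extraction, photobleaching
correction and prebleach normalization.

The pipeline turns a raw movie into a normalized recovery curve in four steps:

1. :func:`interpolate_roi_track` — piecewise-linear interpolation of sparse
   manual ROI anchor positions to a per-frame track of the bleach spot.
2. :func:`extract_intensities` — per-frame mean intensities of the bleach ROI
   (``I_bleach``), the rest of the bleached nucleus (``I_nonbleach``) and the
   extra-nuclear background (``I_background``).
3. :func:`correct_photobleaching` — a correction-factor series
   ``C(t) = smooth(I_nonbleach - I_background) / <same>_prebleach`` tracking the
   loss of total nuclear signal to acquisition photobleaching.
4. :func:`normalize_trace` — double normalization: the background-subtracted
   bleach signal is divided by ``C(t)`` and scaled so its prebleach mean is 1.

The result is dimensionless, equals 1 before the bleach, drops at the bleach
and recovers toward 1 as unbleached molecules exchange into the spot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu


class DegenerateTraceError(ValueError):
    """The trace cannot support photobleaching correction (non-positive net signal)."""


@dataclass
class FrapTrace:
    """The three intensity series extracted from one FRAP movie.

    Attributes
    ----------
    time_s : array
        Acquisition time of each frame, seconds.
    i_bleach : array
        Mean intensity inside the bleach ROI per frame.
    i_nonbleach : array
        Mean intensity of the bleached nucleus excluding the ROI per frame.
    i_background : array
        Mean extra-nuclear background intensity per frame.
    bleach_after : int
        Number of prebleach frames; frame ``bleach_after`` is the first
        post-bleach frame (0-based).
    excessive_drift : bool
        Set when the tracked ROI moved more than the drift ceiling over any
        10-frame span (such movies were excluded in the source protocol).
    """

    time_s: np.ndarray
    i_bleach: np.ndarray
    i_nonbleach: np.ndarray
    i_background: np.ndarray
    bleach_after: int
    excessive_drift: bool = False
    trace_id: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.i_bleach = np.asarray(self.i_bleach, dtype=float)
        self.i_nonbleach = np.asarray(self.i_nonbleach, dtype=float)
        self.i_background = np.asarray(self.i_background, dtype=float)
        n = self.time_s.size
        for name in ("i_bleach", "i_nonbleach", "i_background"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length != time_s length")
        if not (1 <= self.bleach_after < n):
            raise ValueError("bleach_after must satisfy 1 <= bleach_after < n_frames")
        pre = slice(0, self.bleach_after)
        if np.any(self.i_nonbleach[pre] < self.i_background[pre]):
            raise ValueError("prebleach nuclear intensity below background")

    @property
    def n_frames(self) -> int:
        return self.time_s.size


@dataclass
class CorrectionSeries:
    """Per-frame photobleaching correction factors C(t).

    ``c`` is the smoothed, background-subtracted nuclear intensity divided by
    its prebleach mean, so its prebleach mean is 1 by construction and it decays
    below 1 as acquisition photobleaching removes fluorophores.
    """

    c: np.ndarray
    smooth_window: int

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        if np.any(self.c <= 0):
            raise DegenerateTraceError("correction factors must be positive")


@dataclass
class NormalizedTrace:
    """Background-subtracted, photobleaching-corrected, prebleach-normalized signal.

    ``time_post_bleach_s`` starts at 0 at the first post-bleach frame; the
    prebleach portion of the normalized series is kept in ``prebleach_value``
    (mean 1 by construction) for diagnostics.
    """

    time_post_bleach_s: np.ndarray
    value: np.ndarray
    prebleach_value: np.ndarray = field(default_factory=lambda: np.empty(0))
    provenance: str = ""

    def __post_init__(self) -> None:
        self.time_post_bleach_s = np.asarray(self.time_post_bleach_s, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        self.prebleach_value = np.asarray(self.prebleach_value, dtype=float)
        if self.time_post_bleach_s.size != self.value.size:
            raise ValueError("time and value length mismatch")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("normalized values must be finite")


def interpolate_roi_track(anchors: dict[int, tuple[float, float]], n_frames: int) -> np.ndarray:
    """Linearly interpolate sparse ROI anchors to a per-frame (x, y) track.

    Constant extrapolation before the first and after the last anchor.
    """
    if not anchors:
        raise ValueError("at least one ROI anchor is required")
    frames = np.array(sorted(anchors), dtype=float)
    if frames[0] < 0 or frames[-1] >= n_frames:
        raise ValueError("anchor frame index outside movie range")
    pts = np.array([anchors[int(f)] for f in frames], dtype=float)
    grid = np.arange(n_frames, dtype=float)
    x = np.interp(grid, frames, pts[:, 0])
    y = np.interp(grid, frames, pts[:, 1])
    return np.column_stack([x, y])


def roi_disc_mask(shape: tuple[int, int], center: tuple[float, float], radius_px: float) -> np.ndarray:
    """Boolean mask of pixels whose centers lie within ``radius_px`` (inclusive) of center.

    ``center`` is (x, y) in pixel coordinates; arrays are indexed [y, x].
    """
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius_px**2


def extract_intensities(
    movie,
    track: np.ndarray | None = None,
    nucleus_mask: np.ndarray | None = None,
    background_mask: np.ndarray | None = None,
    drift_ceiling: float = 0.2,
) -> FrapTrace:
    """Extract I_bleach / I_nonbleach / I_background series from a movie.

    Parameters
    ----------
    movie : FrapMovie
    track : (n_frames, 2) array, optional
        Per-frame ROI centers (x, y); defaults to interpolating the movie's
        ``roi_anchors``.
    nucleus_mask : bool array, optional
        Static nucleus mask. By default the nucleus is segmented by Otsu's
        threshold computed on the first frame and re-applied per frame so the
        mask follows nuclear drift.
    background_mask : bool array, optional
        Static background region; defaults to the per-frame complement of the
        nucleus segmentation.
    drift_ceiling : float
        Fraction of the nucleus equivalent diameter the tracked ROI may move
        over any 10-frame span before the trace is flagged.
    """
    frames = movie.frames
    n_frames, h, w = frames.shape
    if track is None:
        track = interpolate_roi_track(movie.roi_anchors, n_frames)
    track = np.asarray(track, dtype=float)
    radius = movie.roi_diameter_um / 2.0 / movie.pixel_size_um

    thr = threshold_otsu(frames[0])
    nuc0 = frames[0] >= thr if nucleus_mask is None else nucleus_mask.astype(bool)
    if not nuc0.any():
        raise ValueError("empty nucleus mask")

    i_b = np.empty(n_frames)
    i_n = np.empty(n_frames)
    i_g = np.empty(n_frames)
    for f in range(n_frames):
        cx, cy = track[f]
        if cx - radius < 0 or cy - radius < 0 or cx + radius > w - 1 or cy + radius > h - 1:
            raise ValueError(f"ROI disc extends outside the frame at frame {f}")
        if nucleus_mask is None:
            nuc = frames[f] >= thr
            if not nuc.any():
                nuc = nuc0
        else:
            nuc = nuc0
        disc = roi_disc_mask((h, w), (cx, cy), radius)
        # the bleached spot can fall below the segmentation threshold, so the
        # background is everything outside both the nucleus and the ROI disc
        bg = ~(nuc | disc) if background_mask is None else background_mask.astype(bool)
        if not bg.any():
            raise ValueError("empty background region")
        nuc_excl = nuc & ~disc
        if not nuc_excl.any():
            raise ValueError(f"nucleus mask empty after ROI exclusion at frame {f}")
        i_b[f] = frames[f][disc].mean()
        i_n[f] = frames[f][nuc_excl].mean()
        i_g[f] = frames[f][bg].mean()

    # drift check against the nucleus equivalent diameter
    diam = 2.0 * np.sqrt(nuc0.sum() / np.pi)
    drift_flag = False
    if n_frames > 10:
        disp = np.linalg.norm(track[10:] - track[:-10], axis=1)
        drift_flag = bool(np.max(disp) > drift_ceiling * diam)
        if drift_flag:
            warnings.warn("excessive drift: ROI track exceeds the drift ceiling", stacklevel=2)

    return FrapTrace(
        time_s=movie.schedule.frame_times,
        i_bleach=i_b,
        i_nonbleach=i_n,
        i_background=i_g,
        bleach_after=movie.schedule.bleach_after,
        excessive_drift=drift_flag,
    )


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks symmetrically at the edges."""
    if window == 1:
        return x.astype(float).copy()
    half = window // 2
    n = x.size
    cs = np.concatenate([[0.0], np.cumsum(x, dtype=float)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def correct_photobleaching(
    trace: FrapTrace, smooth_window: int = 5, smooth_background: bool = False
) -> CorrectionSeries:
    """Compute the photobleaching correction series C(t).

    ``C(t) = net_smooth(t) / <net_smooth>_prebleach`` where
    ``net_smooth = moving_average(i_nonbleach) - i_background``. The prebleach
    mean of C is exactly 1. ``smooth_window`` must be odd; width 1 disables
    smoothing (appropriate for noiseless data).
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be an odd integer >= 1")
    nb = _moving_average(trace.i_nonbleach, smooth_window)
    bg = (
        _moving_average(trace.i_background, smooth_window)
        if smooth_background
        else trace.i_background
    )
    net = nb - bg
    if np.any(net <= 0):
        raise DegenerateTraceError("non-positive smoothed net nuclear signal")
    denom = net[: trace.bleach_after].mean()
    if denom <= 0:
        raise DegenerateTraceError("non-positive prebleach net nuclear signal")
    return CorrectionSeries(c=net / denom, smooth_window=smooth_window)


def normalize_trace(trace: FrapTrace, correction: CorrectionSeries) -> NormalizedTrace:
    """Double-normalize a FRAP trace.

    The background-subtracted bleach signal is divided by C(t) (removing the
    shared acquisition-photobleaching decay) and scaled by its prebleach mean,
    so the prebleach level is 1. Only post-bleach frames are returned, with
    t = 0 at the first post-bleach frame.
    """
    if correction.c.size != trace.n_frames:
        raise ValueError("correction series not aligned with trace")
    corrected = (trace.i_bleach - trace.i_background) / correction.c
    denom = corrected[: trace.bleach_after].mean()
    if denom == 0:
        raise ValueError("zero prebleach normalization denominator")
    norm = corrected / denom
    b = trace.bleach_after
    return NormalizedTrace(
        time_post_bleach_s=trace.time_s[b:] - trace.time_s[b],
        value=norm[b:],
        prebleach_value=norm[:b],
        provenance=trace.trace_id,
    )


def process_movie(movie, smooth_window: int = 5, **extract_kwargs) -> NormalizedTrace:
    """Full pipeline: extract, correct and normalize a movie in one call."""
    trace = extract_intensities(movie, **extract_kwargs)
    corr = correct_photobleaching(trace, smooth_window=smooth_window)
    return normalize_trace(trace, corr)
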