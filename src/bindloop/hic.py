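"""Hi-C contact-matrix summary statistics.

Operates on single-chromosome binned contact matrices:

- :func:`ice_balance` — iterative correction (ICE) matrix balancing.
- :func:`contact_probability_curve` — distance-decay / relative contact
  probability P(s) on log-spaced (or per-diagonal) distance bins.
- :func:`estimate_pmax` — location of the local maximum of d log10 P / d log10 s
  after Loess smoothing; a proxy for the average extruded loop length.
- :func:`insulation_track` — diamond-window insulation score with boundary calls.
- :func:`aggregate_around_anchors` — pileups over anchor pairs (matrices) or
  mean profiles over sites (insulation tracks).
- :func:`downsample_matrix` — binomial thinning to a target depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess


@dataclass
class ContactMatrix:
    """A symmetric, non-negative binned contact matrix for one chromosome.

    Bins are 0-based and half-open: bin ``i`` covers
    ``[start + i*resolution_bp, start + (i+1)*resolution_bp)``.
    """

    counts: np.ndarray
    resolution_bp: int
    chrom: str = "chrS"
    start: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts, self.counts.T, rtol=0, atol=1e-8 * max(1.0, self.counts.max(initial=1.0))):
            raise ValueError("counts must be symmetric")
        if self.resolution_bp <= 0:
            raise ValueError("resolution_bp must be positive")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def span_bp(self) -> int:
        return self.n_bins * self.resolution_bp

    def bin_of(self, pos_bp: float) -> int:
        return int((pos_bp - self.start) // self.resolution_bp)


@dataclass
class RcpCurve:
    """Relative contact probability vs genomic separation.

    ``probability`` is normalized to sum to 1 over the retained bins;
    ``mean_count`` holds the unnormalized per-bin mean contact frequency.
    """

    distance_bp: np.ndarray
    probability: np.ndarray
    n_pairs: np.ndarray
    mean_count: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.distance_bp = np.asarray(self.distance_bp, dtype=float)
        self.probability = np.asarray(self.probability, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs)
        if np.any(np.diff(self.distance_bp) <= 0):
            raise ValueError("distance grid must be strictly increasing")
        if np.any(self.probability < 0):
            raise ValueError("probabilities must be non-negative")


@dataclass
class PmaxEstimate:
    """Location of the maximum of the log-log P(s) derivative (average loop size)."""

    pmax_distance_bp: float
    derivative_value: float
    search_range_bp: tuple[float, float]
    loess_span: float
    no_peak: bool = False


@dataclass
class InsulationTrack:
    """Per-bin diamond insulation score (log2 ratio to the mean diamond)."""

    score: np.ndarray
    valid: np.ndarray
    window_bp: int
    resolution_bp: int
    boundaries: list[int] = field(default_factory=list)
    chrom: str = "chrS"
    start: int = 0

    @property
    def n_bins(self) -> int:
        return self.score.size


def ice_balance(
    matrix: ContactMatrix, tol: float = 1e-9, max_iter: int = 1000
) -> tuple[ContactMatrix, np.ndarray]:
    """Balance a contact matrix by iterative correction (ICE).

    Rows/columns are repeatedly divided by their (mean-normalized) marginal
    sums until the coefficient of variation of the non-masked row sums falls
    below ``tol``. All-zero rows are masked and left untouched (bias 1).

    Returns the balanced matrix and the bias vector ``b`` with
    ``raw[i, j] = b[i] * b[j] * balanced[i, j]``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    M = matrix.counts.copy()
    mask = M.sum(axis=1) > 0
    if not mask.any():
        raise ValueError("all rows are zero; cannot balance")
    bias = np.ones(matrix.n_bins)
    for _ in range(max_iter):
        s = M.sum(axis=1)
        sv = s[mask]
        cv = sv.std() / sv.mean()
        if cv < tol:
            break
        f = s / sv.mean()
        f[~mask] = 1.0
        M /= np.outer(f, f)
        bias *= f
    M = (M + M.T) / 2.0  # guard against accumulated asymmetry
    return ContactMatrix(M, matrix.resolution_bp, matrix.chrom, matrix.start), bias


def _diagonal_means(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = counts.shape[0]
    d = np.arange(1, n)
    means = np.array([counts.diagonal(k).mean() for k in d])
    pairs = n - d
    return means, pairs


def contact_probability_curve(
    matrix: ContactMatrix, log_bins_per_decade: int | None = 10
) -> RcpCurve:
    """Mean contact frequency per distance bin, normalized to sum to 1.

    Distances are ``|i - j| * resolution_bp`` with the main diagonal (d = 0)
    excluded. With ``log_bins_per_decade=None`` every integer bin-distance is
    its own bin (exact per-diagonal means); otherwise diagonals are aggregated
    into log-spaced distance bins (pair-weighted means), and the representative
    distance of a bin is the pair-weighted geometric mean of its members.
    """
    n = matrix.n_bins
    if n < 10:
        raise ValueError("matrix too small for a contact probability curve")
    means, pairs = _diagonal_means(matrix.counts)
    dist = np.arange(1, n) * float(matrix.resolution_bp)

    if log_bins_per_decade is None:
        keep = pairs > 0
        mean_count = means[keep]
        out_dist, out_pairs = dist[keep], pairs[keep]
    else:
        if log_bins_per_decade < 1:
            raise ValueError("log_bins_per_decade must be >= 1")
        lo, hi = np.log10(dist[0]), np.log10(dist[-1])
        n_edges = int(np.ceil((hi - lo) * log_bins_per_decade)) + 1
        if n_edges < 2:
            raise ValueError("matrix too small for the requested log binning")
        edges = np.logspace(lo, hi, n_edges + 1)
        idx = np.clip(np.searchsorted(edges, dist, side="right") - 1, 0, n_edges - 1)
        mean_count, out_dist, out_pairs = [], [], []
        for b in range(n_edges):
            sel = idx == b
            if not sel.any():
                continue
            w = pairs[sel]
            mean_count.append(np.average(means[sel], weights=w))
            out_dist.append(10 ** np.average(np.log10(dist[sel]), weights=w))
            out_pairs.append(w.sum())
        mean_count = np.array(mean_count)
        out_dist = np.array(out_dist)
        out_pairs = np.array(out_pairs)

    total = mean_count.sum()
    if total <= 0:
        raise ValueError("matrix has no off-diagonal signal")
    return RcpCurve(
        distance_bp=out_dist,
        probability=mean_count / total,
        n_pairs=out_pairs,
        mean_count=mean_count,
    )


def estimate_pmax(
    rcp: RcpCurve,
    loess_span: float = 0.3,
    search_range_bp: tuple[float, float] = (50_000.0, 2_000_000.0),
    min_prominence: float = 0.01,
) -> PmaxEstimate:
    """Estimate the average loop length from the log-log P(s) derivative.

    log10 P is Loess-smoothed (local linear regression, tricube weights) on the
    log10 distance grid; the first derivative is taken by centered finite
    differences; the estimate is the interior local maximum of the derivative
    within ``search_range_bp``. A monotone/flat derivative (range below
    ``min_prominence``) yields ``no_peak=True`` rather than a fabricated
    location.
    """
    keep = rcp.probability > 0
    x = np.log10(rcp.distance_bp[keep])
    y = np.log10(rcp.probability[keep])
    if x.size < 10:
        raise ValueError("need at least 10 positive distance bins")
    smooth = lowess(y, x, frac=loess_span, it=0, return_sorted=False)
    deriv = np.gradient(smooth, x)

    lo, hi = search_range_bp
    dist = 10**x
    in_range = (dist >= lo) & (dist <= hi)
    # interior points only: a maximum at the grid edge is not a peak
    in_range[0] = in_range[-1] = False
    if not in_range.any():
        raise ValueError("search range contains no distance bins")

    cand = [
        i
        for i in np.flatnonzero(in_range)
        if deriv[i] > deriv[i - 1] and deriv[i] > deriv[i + 1]
    ]
    d_range = deriv[in_range]
    if not cand or (d_range.max() - d_range.min()) < min_prominence:
        return PmaxEstimate(
            pmax_distance_bp=float("nan"),
            derivative_value=float("nan"),
            search_range_bp=(lo, hi),
            loess_span=loess_span,
            no_peak=True,
        )
    best = max(cand, key=lambda i: deriv[i])
    return PmaxEstimate(
        pmax_distance_bp=float(dist[best]),
        derivative_value=float(deriv[best]),
        search_range_bp=(lo, hi),
        loess_span=loess_span,
    )


def insulation_track(
    matrix: ContactMatrix, window_bp: int, boundary_threshold: float = -0.5
) -> InsulationTrack:
    """Diamond-window insulation score with boundary calls.

    For each bin ``i`` the diamond is the ``w x w`` submatrix of contacts
    between the ``w`` bins upstream and the ``w`` bins starting at ``i``
    (all pairs crossing the left edge of bin i), ``w = window_bp /
    resolution_bp``. The score is ``log2(diamond mean / mean of all valid
    diamond means)``. Boundaries are strict local minima below
    ``boundary_threshold``, at least ``w`` bins apart (deepest first).
    """
    res = matrix.resolution_bp
    if window_bp % res != 0:
        raise ValueError("window_bp must be a multiple of resolution_bp")
    w = window_bp // res
    n = matrix.n_bins
    if w < 1 or w > n // 4:
        raise ValueError("window too large (must be at most a quarter of the matrix span)")

    dm = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in range(w, n - w + 1):
        dm[i] = matrix.counts[i - w : i, i : i + w].mean()
        valid[i] = True
    finite = valid & np.isfinite(dm) & (dm > 0)
    mean_dm = dm[finite].mean()
    score = np.full(n, np.nan)
    score[finite] = np.log2(dm[finite] / mean_dm)
    valid = finite

    minima = [
        i
        for i in range(1, n - 1)
        if valid[i]
        and valid[i - 1]
        and valid[i + 1]
        and score[i] < score[i - 1]
        and score[i] < score[i + 1]
        and score[i] < boundary_threshold
    ]
    boundaries: list[int] = []
    for i in sorted(minima, key=lambda i: score[i]):
        if all(abs(i - b) >= w for b in boundaries):
            boundaries.append(i)
    boundaries.sort()

    return InsulationTrack(
        score=score,
        valid=valid,
        window_bp=window_bp,
        resolution_bp=res,
        boundaries=boundaries,
        chrom=matrix.chrom,
        start=matrix.start,
    )


def aggregate_around_anchors(signal, anchors, flank_bp: int):
    """Average the signal in centered windows around anchors.

    For a :class:`ContactMatrix`, ``anchors`` are (pos1_bp, pos2_bp) pairs and
    the result is a 2-D pileup of shape ``(2f+1, 2f+1)`` with
    ``f = flank_bp / resolution_bp``. For an :class:`InsulationTrack`,
    ``anchors`` are bp positions and the result is a 1-D mean profile of length
    ``2f+1`` (invalid track bins are ignored via nanmean). Anchors whose window
    exceeds the matrix/track are excluded; the usable count is returned.

    Returns ``(aggregate, n_usable)``.
    """
    res = signal.resolution_bp
    if flank_bp % res != 0:
        raise ValueError("flank_bp must be a multiple of resolution_bp")
    f = flank_bp // res

    if isinstance(signal, ContactMatrix):
        n = signal.n_bins
        windows = []
        for a in anchors:
            b1 = signal.bin_of(a[0])
            b2 = signal.bin_of(a[1])
            if b1 - f < 0 or b2 - f < 0 or b1 + f >= n or b2 + f >= n:
                continue
            windows.append(signal.counts[b1 - f : b1 + f + 1, b2 - f : b2 + f + 1])
        if not windows:
            raise ValueError("no usable anchors (all windows exceed the matrix)")
        return np.mean(windows, axis=0), len(windows)

    if isinstance(signal, InsulationTrack):
        n = signal.n_bins
        score = np.where(signal.valid, signal.score, np.nan)
        windows = []
        for pos in anchors:
            b = int((pos - signal.start) // res)
            if b - f < 0 or b + f >= n:
                continue
            windows.append(score[b - f : b + f + 1])
        if not windows:
            raise ValueError("no usable anchors (all windows exceed the track)")
        with np.errstate(invalid="ignore"):
            profile = np.nanmean(np.array(windows), axis=0)
        return profile, len(windows)

    raise TypeError("signal must be a ContactMatrix or InsulationTrack")


def downsample_matrix(
    matrix: ContactMatrix, target_total: float, seed: int = 0
) -> ContactMatrix:
    """Binomially thin counts to an expected total of ``target_total``.

    Mirrors depth equalization across samples: each upper-triangle count is
    replaced by a Binomial(count, p) draw with ``p = target_total / total``.
    """
    total = matrix.counts.sum()
    if not 0 < target_total <= total:
        raise ValueError("target_total must be in (0, current total]")
    p = target_total / total
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(matrix.n_bins)
    vals = matrix.counts[iu]
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("downsampling requires integer counts")
    thinned = rng.binomial(vals.astype(np.int64), p).astype(float)
    out = np.zeros_like(matrix.counts)
    out[iu] = thinned
    out = out + out.T - np.diag(np.diag(out))
    return ContactMatrix(out, matrix.resolution_bp, matrix.chrom, matrix.start)
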