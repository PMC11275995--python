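"""Kinetics-to-genome association fits.

Ordinary least-squares regression of a per-condition genomic summary (percent
cohesin overlap, interaction count, mean insulation score, loop-length
estimate, ...) on a kinetic parameter (specific bound fraction or residence
time) across conditions, reporting slope, R^2 and a p-value. A permutation
p-value is available for the very small n typical of per-condition panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

_P_FLOOR = 1e-300


@dataclass
class AssociationFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    exact_fit: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def fit_linear_association(x, y, permutation: bool = False, seed: int = 0) -> AssociationFit:
    """OLS fit of y on x with R^2 and the slope F-test p-value.

    For simple regression the slope F-test equals the slope t-test, which is
    what :func:`scipy.stats.linregress` reports. A constant response gives
    R^2 = 0 and p = 1; an exact linear fit is flagged and its p-value floored
    rather than reported as 0. With ``permutation=True`` the p-value is the
    two-sided permutation p (exact enumeration for n <= 8, otherwise 10000
    seeded draws).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in x or y")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: slope is not identified")

    res = stats.linregress(x, y)
    if np.ptp(y) == 0:
        return AssociationFit(slope=0.0, intercept=float(y[0]), r_squared=0.0, p_value=1.0, n=n)

    r2 = float(res.rvalue**2)
    sse_frac = 1.0 - r2
    exact = sse_frac < 1e-12
    p = float(res.pvalue)

    if permutation:
        obs = abs(res.rvalue)

        def corr(yp):
            return abs(np.corrcoef(x, yp)[0, 1])

        if n <= 8:
            hits = sum(corr(np.array(p_)) >= obs - 1e-12 for p_ in permutations(y))
            p = hits / factorial(n)
        else:
            rng = np.random.default_rng(seed)
            n_perm = 10_000
            hits = sum(corr(rng.permutation(y)) >= obs - 1e-12 for _ in range(n_perm))
            p = (hits + 1) / (n_perm + 1)

    p = max(p, _P_FLOOR)
    return AssociationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        p_value=p,
        n=n,
        exact_fit=exact,
    )


def fit_association_table(
    table: pd.DataFrame, x: str, y: str, **kwargs
) -> AssociationFit:
    """Run :func:`fit_linear_association` on two columns of a condition table."""
    sub = table[[x, y]].dropna()
    return fit_linear_association(sub[x].to_numpy(), sub[y].to_numpy(), **kwargs)


def overlap_fraction(bed_a: pd.DataFrame, bed_b: pd.DataFrame) -> float:
    """Fraction of intervals in A overlapping any interval in B by >= 1 bp.

    Both frames use half-open BED coordinates with columns
    ``chrom, start, end``.
    """
    for df in (bed_a, bed_b):
        if not {"chrom", "start", "end"}.issubset(df.columns):
            raise ValueError("BED frames need chrom/start/end columns")
    if len(bed_a) == 0:
        raise ValueError("empty query interval set")
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in bed_b.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(grp["start"], grp["end"]) if e > s
        )
    hits = 0
    for chrom, s, e in zip(bed_a["chrom"], bed_a["start"], bed_a["end"]):
        tree = trees.get(chrom)
        if tree is not None and tree.overlap(int(s), int(e)):
            hits += 1
    return hits / len(bed_a)
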