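"""Somite-size statistics for drug-treated embryo boundary series.

Boundaries b_j are axial positions indexed from the posterior-most
boundary at experiment end (j = 0) anteriorly; somite j lies between
boundaries j-1 and j, so j = 1 is the last-formed (+1) somite.  The
statistics are: somite lengths S_j = |b_j - b_{j-1}|, successive-length
ratios r_j = S_j / S_{j+1}, their log2 fold changes, per-index group mean
+/- SEM, a Kolmogorov-Smirnov normality check, and two-sided paired
t-tests of treatment vs control at each somite position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "BoundarySeries",
    "SomiteStats",
    "somite_lengths",
    "log2_ratios",
    "group_compare",
    "load_boundary_table",
]


@dataclass
class BoundarySeries:
    """Ordered somite boundary positions for one embryo sample.

    positions[j] is boundary j; j = 0 is the posterior-most boundary and j
    increases anteriorly.  Positions must be strictly monotonic (either
    direction); anterior-decreasing coordinate systems are normalised on
    construction so stored positions always increase with j.
    """

    sample_id: str
    treatment: str
    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.size < 2:
            raise ValueError("need at least 2 boundaries")
        d = np.diff(pos)
        if (d > 0).all():
            pass
        elif (d < 0).all():
            pos = -pos  # normalise to increasing; lengths are unsigned anyway
        else:
            j = int(np.flatnonzero(~(d > 0) if d[0] > 0 else ~(d < 0))[0]) + 1
            raise ValueError(f"boundary positions not strictly monotonic at index {j}")
        self.positions = pos


@dataclass
class SomiteStats:
    """Group comparison at one somite position: mean log2fc, SEM, paired t."""

    index: int
    treatment: str
    control: str
    n: int
    mean_treated: float
    sem_treated: float
    mean_control: float
    sem_control: float
    t_statistic: float | None
    p_value: float | None
    indeterminate: bool
    normal: bool
    normality_p: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def somite_lengths(b: BoundarySeries) -> np.ndarray:
    """Somite lengths S_j = |b_j - b_{j-1}| for j = 1, 2, ... (all > 0)."""
    return np.abs(np.diff(b.positions))


def log2_ratios(S) -> np.ndarray:
    """log2(S_j / S_{j+1}) for j = 1 .. len(S)-1.

    Element 0 compares the last-formed (+1) somite with the penultimate
    (+2) one; a positive value means the more recent somite is larger.
    """
    S = np.asarray(S, dtype=float)
    if S.size < 2:
        raise ValueError("need at least 2 somite lengths")
    if (S <= 0).any():
        raise ValueError("somite lengths must be > 0")
    return np.log2(S[:-1] / S[1:])


def _log2fc_at(series: BoundarySeries, index: int) -> float:
    ratios = log2_ratios(somite_lengths(series))
    j = index - 1  # position +1 is the first ratio
    if not 0 <= j < ratios.size:
        raise ValueError(
            f"sample {series.sample_id}: somite position +{index} needs "
            f">= {index + 2} boundaries, have {series.positions.size}"
        )
    return float(ratios[j])


def group_compare(
    treated: list[BoundarySeries],
    control: list[BoundarySeries],
    index: int = 1,
    alpha: float = 0.05,
    normality: str = "lilliefors",
) -> SomiteStats:
    """Paired comparison of log2 fold changes at one somite position.

    Samples are paired by list order (e.g. contralateral halves or matched
    embryos).  Reports group mean +/- SEM of the per-sample log2(r_index),
    a two-sided paired t-test p-value, and a normality check on the paired
    differences: Lilliefors by default (normal with estimated mean/sd), or
    ``normality="ks"`` for the fixed-parameter Kolmogorov-Smirnov test.
    Zero-variance differences give an indeterminate p (flagged), not a
    number.
    """
    if len(treated) != len(control) or len(treated) < 2:
        raise ValueError("treated and control must be paired lists of equal length >= 2")
    x = np.array([_log2fc_at(s, index) for s in treated])
    y = np.array([_log2fc_at(s, index) for s in control])
    diffs = x - y
    n = len(diffs)

    degenerate = np.allclose(diffs.std(ddof=1), 0.0)
    if degenerate:
        norm_p = np.nan  # normality undefined for constant differences
    elif normality == "lilliefors":
        _, norm_p = lilliefors(diffs, dist="norm")
    elif normality == "ks":
        _, norm_p = stats.kstest(diffs, "norm", args=(diffs.mean(), diffs.std(ddof=1)))
    else:
        raise ValueError("normality must be 'lilliefors' or 'ks'")

    if degenerate:
        t_stat, p_val, indet = None, None, True
    else:
        t_stat, p_val = stats.ttest_rel(x, y)
        t_stat, p_val, indet = float(t_stat), float(p_val), False

    def _sem(v):
        return float(v.std(ddof=1) / np.sqrt(n))

    return SomiteStats(
        index=index,
        treatment=treated[0].treatment,
        control=control[0].treatment,
        n=n,
        mean_treated=float(x.mean()),
        sem_treated=_sem(x),
        mean_control=float(y.mean()),
        sem_control=_sem(y),
        t_statistic=t_stat,
        p_value=p_val,
        indeterminate=indet,
        normal=bool(norm_p > alpha),
        normality_p=float(norm_p),
    )


def load_boundary_table(df: pd.DataFrame) -> dict[str, list[BoundarySeries]]:
    """Group a tidy table (sample_id, treatment, boundary_index, position)
    into per-treatment lists of BoundarySeries, ordered by sample_id."""
    required = {"sample_id", "treatment", "boundary_index", "position"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out: dict[str, list[BoundarySeries]] = {}
    for (treatment, sample_id), g in sorted(
        df.groupby(["treatment", "sample_id"]), key=lambda kv: kv[0]
    ):
        g = g.sort_values("boundary_index")
        out.setdefault(str(treatment), []).append(
            BoundarySeries(str(sample_id), str(treatment), g["position"].to_numpy())
        )
    return out
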