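"""Cell-cycle position, phase classification and CDK activity windows.

A cell's position on the cycle is a clock coordinate ``theta`` in hours on
``[0, t_cycle)``, advancing at unit speed and wrapping at division.  The four
canonical phases G1, S, G2 and M partition the cycle into consecutive
half-open intervals.  CDK2 (CyclinE/A) and CDK1 (CyclinB) activity are
modelled as indicator windows on the cycle: CDK2 high around the G1/S
transition and through S, CDK1 high in late G2 and M.  Populations are
collections of cells sharing one parameter set; a double-thymidine-arrested
population sits tightly at a release point in late G1, an asynchronous
culture is spread uniformly over the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

PHASES = ("G1", "S", "G2", "M")

__all__ = [
    "PHASES",
    "CellCycleParams",
    "CellState",
    "Population",
    "phase_of",
    "cdk_activity",
    "advance",
    "make_synchronized_population",
    "make_asynchronous_population",
    "phase_fractions",
    "modal_phase",
]


@dataclass(frozen=True)
class CellCycleParams:
    """Phase durations (hours) and CDK activity windows on the cycle.

    Defaults give a 16 h cycle (G1 7 h, S 5 h, G2 3 h, M 1 h) with the CDK2
    window spanning the G1/S boundary through most of S ([7, 11)) and the
    CDK1 window rising in late G2 and switching off at mitotic exit
    ([13.5, 15.5) — CyclinB/CDK1 activates before nuclear envelope
    breakdown and is destroyed at anaphase).  A double-thymidine
    block arrests cells just before G1/S (release_point 6.5 h) with a small
    positional spread (dispersion 0.5 h, truncated at +/- 2 sd).

    ``ramp_width`` > 0 replaces the boxcar windows by logistic ramps of that
    width (hours); 0 keeps sharp windows.
    """

    d_g1: float = 7.0
    d_s: float = 5.0
    d_g2: float = 3.0
    d_m: float = 1.0
    w2: tuple[float, float] = (7.0, 11.0)
    w1: tuple[float, float] = (13.5, 15.5)
    release_point: float = 6.5
    dispersion: float = 0.5
    ramp_width: float = 0.0

    def __post_init__(self) -> None:
        for name in ("d_g1", "d_s", "d_g2", "d_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        t = self.t_cycle
        for name, (lo, hi) in (("w2", self.w2), ("w1", self.w1)):
            if not (0 <= lo < hi <= t):
                raise ValueError(f"{name}=[{lo},{hi}) must satisfy 0 <= lo < hi <= t_cycle={t}")
        if not 0 <= self.release_point < t:
            raise ValueError(f"release_point must lie in [0, {t})")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.ramp_width < 0:
            raise ValueError("ramp_width must be >= 0")

    @property
    def t_cycle(self) -> float:
        return self.d_g1 + self.d_s + self.d_g2 + self.d_m

    @property
    def phase_edges(self) -> np.ndarray:
        """Cumulative phase boundaries [0, d_g1, d_g1+d_s, ..., t_cycle]."""
        return np.cumsum([0.0, self.d_g1, self.d_s, self.d_g2, self.d_m])

    def replace(self, **kwargs) -> "CellCycleParams":
        return replace(self, **kwargs)


@dataclass
class CellState:
    """One cell: cycle position theta (h) plus NICD and pNICD amounts (au)."""

    theta: float
    n: float
    p: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.theta, self.n, self.p]).all():
            raise ValueError("CellState fields must be finite")
        if self.n < 0 or self.p < 0:
            raise ValueError("NICD amounts must be non-negative")


@dataclass
class Population:
    """A non-empty collection of cells sharing one cell-cycle parameter set.

    State is held in arrays (theta, n, p) for efficient population-level
    integration; ``cells`` materialises CellState views on demand.
    """

    theta: np.ndarray
    n: np.ndarray
    p: np.ndarray
    params: CellCycleParams = field(default_factory=CellCycleParams)

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.n = np.atleast_1d(np.asarray(self.n, dtype=float))
        self.p = np.atleast_1d(np.asarray(self.p, dtype=float))
        if self.theta.size == 0:
            raise ValueError("Population must contain at least one cell")
        if not (self.theta.shape == self.n.shape == self.p.shape):
            raise ValueError("theta, n, p must have identical shapes")
        t = self.params.t_cycle
        if ((self.theta < 0) | (self.theta >= t)).any():
            raise ValueError(f"cycle positions must lie in [0, {t})")

    def __len__(self) -> int:
        return self.theta.size

    @property
    def cells(self) -> list[CellState]:
        return [CellState(t, n, p) for t, n, p in zip(self.theta, self.n, self.p)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": np.arange(len(self)),
                "theta": self.theta,
                "n": self.n,
                "p": self.p,
            }
        )

    def copy(self) -> "Population":
        return Population(self.theta.copy(), self.n.copy(), self.p.copy(), self.params)


def _check_theta(theta, t_cycle: float) -> np.ndarray:
    th = np.asarray(theta, dtype=float)
    if ((th < 0) | (th >= t_cycle)).any():
        raise ValueError(f"theta must lie in [0, {t_cycle}), got {theta}")
    return th


def phase_of(theta, params: CellCycleParams):
    """Classify cycle position(s) into G1/S/G2/M.

    Intervals are half-open and ordered G1 [0, d_g1), S, G2, M [.., t_cycle).
    Scalar in, scalar out; array in, array of labels out.
    """
    th = _check_theta(theta, params.t_cycle)
    idx = np.searchsorted(params.phase_edges[1:-1], th, side="right")
    labels = np.asarray(PHASES)[idx]
    return labels if np.ndim(theta) else str(labels)


def _window_activity(theta: np.ndarray, lo: float, hi: float, ramp: float) -> np.ndarray:
    if ramp == 0.0:
        return ((theta >= lo) & (theta < hi)).astype(float)
    # Logistic ramps of width `ramp` centred on each edge; product of an
    # opening and a closing sigmoid.
    s = ramp / 4.0  # logistic scale so the 2%-98% rise spans ~`ramp` hours
    up = 1.0 / (1.0 + np.exp(-(theta - lo) / s))
    down = 1.0 / (1.0 + np.exp((theta - hi) / s))
    return up * down


def cdk_activity(theta, params: CellCycleParams):
    """CDK2 and CDK1 activity (a2, a1) at cycle position(s) theta.

    Boxcar by default: 1 inside the window, 0 outside; with ramp_width > 0
    the edges become logistic ramps and activities lie in [0, 1].
    """
    th = _check_theta(theta, params.t_cycle)
    a2 = _window_activity(th, *params.w2, params.ramp_width)
    a1 = _window_activity(th, *params.w1, params.ramp_width)
    if np.ndim(theta):
        return a2, a1
    return float(a2[()]), float(a1[()])


def advance(theta, dt, params: CellCycleParams):
    """Advance cycle position(s) by dt hours, wrapping modulo t_cycle."""
    if np.any(np.asarray(dt) < 0):
        raise ValueError("dt must be >= 0")
    th = _check_theta(theta, params.t_cycle)
    out = np.mod(th + dt, params.t_cycle)
    return out if np.ndim(theta) else float(out[()])


def make_synchronized_population(
    n_cells: int, params: CellCycleParams | None = None, seed: int | None = 0
) -> Population:
    """Population released from a double-thymidine block.

    Positions are drawn from a normal centred at ``release_point`` with sd
    ``dispersion``, truncated at +/- 2 sd, then wrapped into the cycle.  At
    the defaults (release point 6.5 h, late G1) the modal phase at t = 0 is
    G1.  NICD amounts are zero-initialised; experiment drivers overwrite
    them with arrest steady states.
    """
    params = params or CellCycleParams()
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    if params.dispersion == 0:
        theta = np.full(n_cells, params.release_point)
    else:
        z = rng.standard_normal(n_cells)
        # resample outside +/- 2 sd (truncation)
        while True:
            bad = np.abs(z) > 2.0
            if not bad.any():
                break
            z[bad] = rng.standard_normal(bad.sum())
        theta = np.mod(params.release_point + params.dispersion * z, params.t_cycle)
    return Population(theta, np.zeros(n_cells), np.zeros(n_cells), params)


def make_asynchronous_population(
    n_cells: int, params: CellCycleParams | None = None, seed: int | None = 0
) -> Population:
    """Asynchronously cycling population: positions uniform on [0, t_cycle)."""
    params = params or CellCycleParams()
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, params.t_cycle, n_cells)
    return Population(theta, np.zeros(n_cells), np.zeros(n_cells), params)


def phase_fractions(pop: Population) -> dict[str, float]:
    """Fraction of cells in each phase; keys ordered G1, S, G2, M."""
    if len(pop) == 0:
        raise ValueError("empty population")
    labels = phase_of(pop.theta, pop.params)
    n = len(pop)
    return {ph: float(np.count_nonzero(labels == ph)) / n for ph in PHASES}


def modal_phase(pop_or_fractions) -> str:
    """Most populated phase; ties broken in the fixed order G1 < S < G2 < M."""
    fr = pop_or_fractions if isinstance(pop_or_fractions, dict) else phase_fractions(pop_or_fractions)
    best = max(PHASES, key=lambda ph: (fr[ph], -PHASES.index(ph)))
    return best
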