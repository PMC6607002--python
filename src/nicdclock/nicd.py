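"""NICD production, cell-cycle-dependent phosphorylation and turnover.

Two species per cell: unphosphorylated NICD (n) and PEST-phosphorylated
NICD (p).  NICD is produced at a constant rate alpha, phosphorylated at a
rate that is high only while CDK2 or CDK1 is active (two windows on the
cell cycle), and degraded — the phosphorylated form much faster, standing
in for SCF(FBXW7)-mediated proteolysis:

    dn/dt = alpha - (k_base + k2*a2(theta) + k1*a1(theta)) * n - delta_n * n
    dp/dt = (k_base + k2*a2 + k1*a1) * n - delta_p * p

with a2, a1 the CDK2/CDK1 window indicators at cycle position theta, which
advances at unit speed.  Because the system is linear with piecewise-
constant coefficients under boxcar windows, trajectories are propagated
exactly segment by segment (closed form per constant-kinase stretch); the
optional smooth-window variant falls back to an adaptive stiff solver.

Drug treatments act as parameter modifications: a gamma-secretase inhibitor
zeroes production, a NEDDylation inhibitor removes the extra phospho-driven
degradation, CDK inhibitors scale the corresponding window rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .cell_cycle import CellCycleParams, CellState, Population, cdk_activity

__all__ = [
    "NicdParams",
    "TreatmentSpec",
    "DRUGS",
    "nicd_rhs",
    "steady_state_constant_kinase",
    "apply_treatment",
    "simulate_cell",
    "propagate_population",
    "steady_state_at_theta",
]

#: Known drug labels and their mechanism class.
DRUGS = {
    "DMSO": "vehicle",
    "LY411575": "gamma_secretase",  # blocks Notch1 S3 cleavage -> no NICD production
    "MLN4924": "neddylation",  # blocks SCF activity -> pNICD loses its fast route
    "Roscovitine": "cdk2",
    "PurvalanolB": "cdk2",
    "GSK650394A": "cdk2",
    "RO3306": "cdk1",
    "DRB": "cdk2",  # CDK7/9 inhibitor; mapped onto the CDK2 channel (see docs)
    "LambdaPhosphatase": "readout",  # lysate treatment: collapses bands, no kinetics
}


@dataclass(frozen=True)
class NicdParams:
    """Kinetic rates for the two-species NICD model.

    alpha    NICD production (au/h)
    delta_n  degradation of unphosphorylated NICD (/h); default 0.35 gives
             the ~2 h half-life of the unphosphorylated form
    delta_p  degradation of phosphorylated NICD (/h); must be >= delta_n —
             faster pNICD turnover is the model premise
    k1, k2   phosphorylation rates inside the CDK1 / CDK2 windows (/h)
    k_base   window-independent (basal) phosphorylation (/h)
    """

    alpha: float = 1.0
    delta_n: float = 0.35
    delta_p: float = 5.0
    k1: float = 4.0
    k2: float = 4.0
    k_base: float = 0.2

    def __post_init__(self) -> None:
        vals = [self.alpha, self.delta_n, self.delta_p, self.k1, self.k2, self.k_base]
        if not np.isfinite(vals).all():
            raise ValueError("all rates must be finite")
        if self.alpha < 0 or self.k1 < 0 or self.k2 < 0 or self.k_base < 0:
            raise ValueError("alpha and phosphorylation rates must be >= 0")
        if self.delta_n <= 0 or self.delta_p <= 0:
            raise ValueError("degradation rates must be > 0")
        if self.delta_p < self.delta_n:
            raise ValueError("delta_p must be >= delta_n (pNICD degrades faster)")

    def replace(self, **kw) -> "NicdParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class TreatmentSpec:
    """A drug treatment: label, inhibition fraction, duration, optional combo."""

    drug: str = "DMSO"
    inhibition: float = 0.95
    duration: float = 3.0
    combination: str | None = None

    def __post_init__(self) -> None:
        for d in filter(None, (self.drug, self.combination)):
            if d not in DRUGS:
                raise KeyError(f"unknown drug {d!r}; known: {sorted(DRUGS)}")
        if not 0.0 <= self.inhibition <= 1.0:
            raise ValueError("inhibition must be in [0, 1]")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


def nicd_rhs(state: CellState, params: NicdParams, cc: CellCycleParams) -> tuple[float, float]:
    """Instantaneous (dn/dt, dp/dt) for one cell at its cycle position."""
    a2, a1 = cdk_activity(state.theta, cc)
    k = params.k_base + params.k2 * a2 + params.k1 * a1
    dn = params.alpha - (k + params.delta_n) * state.n
    dp = k * state.n - params.delta_p * state.p
    return dn, dp


def steady_state_constant_kinase(params: NicdParams, k: float) -> tuple[float, float]:
    """Closed-form fixed point (n*, p*) at a constant phosphorylation rate k.

    n* = alpha / (delta_n + k),  p* = k n* / delta_p.
    """
    if params.delta_n + k <= 0 or params.delta_p <= 0:
        raise ValueError("need delta_n + k > 0 and delta_p > 0")
    n = params.alpha / (params.delta_n + k)
    return n, k * n / params.delta_p


def _effective_k(theta, params: NicdParams, cc: CellCycleParams):
    a2, a1 = cdk_activity(theta, cc)
    return params.k_base + params.k2 * np.asarray(a2) + params.k1 * np.asarray(a1)


def steady_state_at_theta(theta, params: NicdParams, cc: CellCycleParams):
    """(n*, p*) for cells frozen at position(s) theta (vectorised)."""
    k = _effective_k(theta, params, cc)
    n = params.alpha / (params.delta_n + k)
    p = k * n / params.delta_p
    return n, p


def _apply_one(params: NicdParams, drug: str, inhibition: float) -> tuple[NicdParams, bool]:
    mech = DRUGS[drug]
    if mech == "vehicle":
        return params, False
    if mech == "gamma_secretase":
        return params.replace(alpha=0.0), False
    if mech == "neddylation":
        # SCF route removed; residual FBXW7-independent turnover keeps
        # pNICD decaying at the basal NICD rate.
        return params.replace(delta_p=params.delta_n), False
    if mech == "cdk2":
        return params.replace(k2=(1.0 - inhibition) * params.k2), False
    if mech == "cdk1":
        return params.replace(k1=(1.0 - inhibition) * params.k1), False
    if mech == "readout":
        return params, True
    raise KeyError(drug)


def apply_treatment(
    params: NicdParams, cc: CellCycleParams, treatment: TreatmentSpec
) -> tuple[NicdParams, dict]:
    """Map a drug treatment onto modified kinetic parameters.

    Returns the modified parameters and readout flags (currently only
    ``lambda_phosphatase``: the lysate phosphatase collapses the phospho
    band into the unphosphorylated band at measurement time; it never
    changes kinetics).  Combinations compose on the affected rates.
    """
    flags = {"lambda_phosphatase": False}
    out, flag = _apply_one(params, treatment.drug, treatment.inhibition)
    flags["lambda_phosphatase"] |= flag
    if treatment.combination:
        out, flag = _apply_one(out, treatment.combination, treatment.inhibition)
        flags["lambda_phosphatase"] |= flag
    return out, flags


# ---------------------------------------------------------------------------
# Exact piecewise propagation (boxcar windows)
# ---------------------------------------------------------------------------

def _propagate_constant(n0, p0, k, dt, params: NicdParams):
    """Advance (n, p) by dt under a constant phosphorylation rate k.

    Closed-form solution of the linear system; vectorised over cells.
    Handles the degenerate resonance delta_p == delta_n + k.
    """
    lam = params.delta_n + k  # decay rate of n
    n_inf = np.where(lam > 0, params.alpha / np.where(lam > 0, lam, 1.0), 0.0)
    en = np.exp(-lam * dt)
    n1 = n_inf + (n0 - n_inf) * en

    dp = params.delta_p
    ep = np.exp(-dp * dt)
    p_inf = k * n_inf / dp
    gap = dp - lam
    reg = np.abs(gap) > 1e-10
    safe_gap = np.where(reg, gap, 1.0)
    b = k * (n0 - n_inf) / safe_gap  # coefficient of the e^{-lam t} mode
    p_reg = p_inf + (p0 - p_inf - b) * ep + b * en
    # limit dp -> lam: the forcing mode degenerates to t * e^{-lam t}
    p_res = p_inf + (p0 - p_inf) * ep + k * (n0 - n_inf) * dt * en
    p1 = np.where(reg, p_reg, p_res)
    return n1, np.maximum(p1, 0.0)


def _window_edges(cc: CellCycleParams) -> np.ndarray:
    """Sorted unique cycle positions at which the effective kinase rate jumps."""
    edges = {0.0, cc.t_cycle, *cc.w2, *cc.w1}
    return np.array(sorted(edges))


def propagate_population(
    theta0: np.ndarray,
    n0: np.ndarray,
    p0: np.ndarray,
    params: NicdParams,
    cc: CellCycleParams,
    dt: float,
):
    """Advance every cell by dt hours, exactly, under boxcar windows.

    Cells advance on the cycle at unit speed; between consecutive window
    crossings the kinetics are linear with constant coefficients and are
    propagated in closed form.  Vectorised event loop: each iteration moves
    every cell to its own next crossing (or to dt).
    """
    if cc.ramp_width != 0.0:
        raise ValueError("exact propagation requires boxcar windows (ramp_width=0)")
    edges = _window_edges(cc)
    T = cc.t_cycle
    theta = np.asarray(theta0, dtype=float).copy()
    n = np.asarray(n0, dtype=float).copy()
    p = np.asarray(p0, dtype=float).copy()
    remaining = np.full(theta.shape, float(dt))
    eps = 1e-12
    while True:
        active = remaining > eps
        if not active.any():
            break
        th = theta[active]
        # time to the next kinase-rate discontinuity for each active cell
        idx = np.searchsorted(edges, th + eps, side="right")
        next_edge = edges[np.minimum(idx, len(edges) - 1)]
        t_to_edge = next_edge - th
        step = np.minimum(t_to_edge, remaining[active])
        k = _effective_k(th, params, cc)
        n1, p1 = _propagate_constant(n[active], p[active], k, step, params)
        n[active] = n1
        p[active] = p1
        theta[active] = np.mod(th + step, T)
        remaining[active] -= step
    return theta, n, p


def simulate_cell(
    initial: CellState,
    params: NicdParams,
    cc: CellCycleParams,
    treatment: TreatmentSpec | None,
    t_grid: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> list[CellState]:
    """Integrate one cell's (theta, n, p) along an increasing time grid.

    With boxcar windows the exact piecewise propagator is used; with smooth
    (logistic-ramp) windows an adaptive stiff-capable solver (LSODA) at the
    stated tolerances.  The treatment, if given, modifies the kinetic
    parameters for the whole simulated span.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size == 0 or t[0] != 0 or (np.diff(t) <= 0).any():
        raise ValueError("t_grid must be increasing and start at 0")
    if treatment is not None:
        params, _ = apply_treatment(params, cc, treatment)

    out = [CellState(initial.theta, initial.n, initial.p)]
    if cc.ramp_width == 0.0:
        th = np.array([initial.theta])
        n = np.array([initial.n])
        p = np.array([initial.p])
        for dt in np.diff(t):
            th, n, p = propagate_population(th, n, p, params, cc, float(dt))
            out.append(CellState(float(th[0]), float(n[0]), float(p[0])))
        return out

    def rhs(time, y):
        theta = (initial.theta + time) % cc.t_cycle
        k = float(_effective_k(theta, params, cc))
        nn, pp = y
        return [params.alpha - (k + params.delta_n) * nn, k * nn - params.delta_p * pp]

    sol = solve_ivp(
        rhs, (0.0, float(t[-1])), [initial.n, initial.p], t_eval=t[1:] if t.size > 1 else [],
        method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    for time, (nn, pp) in zip(sol.t, sol.y.T):
        out.append(CellState((initial.theta + time) % cc.t_cycle, max(nn, 0.0), max(pp, 0.0)))
    return out
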