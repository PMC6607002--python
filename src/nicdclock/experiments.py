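"""Virtual population experiments and measurement models.

Drivers reproduce the bench protocols in silico: release of a
double-thymidine-synchronized population followed by time-course sampling
of population-mean NICD (what a Western blot lane measures), and 3 h drug
treatments on asynchronous cultures read out as fold changes against a
paired DMSO control.  Measurement models add the blot's multiplicative
lane/band noise with loading-control normalization, and a propidium-iodide
FACS readout (DNA content histogram with G1/S/G2M gating).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell_cycle import (
    PHASES,
    CellCycleParams,
    Population,
    make_asynchronous_population,
    make_synchronized_population,
    phase_fractions,
)
from .nicd import (
    NicdParams,
    TreatmentSpec,
    apply_treatment,
    propagate_population,
    steady_state_at_theta,
)

__all__ = [
    "TimeCourse",
    "FoldChangeResult",
    "run_release_experiment",
    "run_treatment_experiment",
    "westernblot_readout",
    "facs_readout",
]


@dataclass
class TimeCourse:
    """Population-averaged trajectory of the NICD species.

    mean_total is identically mean_n + mean_p; phase_fractions holds one
    G1/S/G2/M fraction mapping per sampled time.
    """

    times: np.ndarray
    mean_n: np.ndarray
    mean_p: np.ndarray
    phase_fractions: list[dict[str, float]]
    metadata: dict = field(default_factory=dict)

    @property
    def mean_total(self) -> np.ndarray:
        return self.mean_n + self.mean_p

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time": self.times,
                "mean_n": self.mean_n,
                "mean_p": self.mean_p,
                "mean_total": self.mean_total,
            }
        )
        for ph in PHASES:
            df[f"frac_{ph}"] = [fr[ph] for fr in self.phase_fractions]
        return df


@dataclass
class FoldChangeResult:
    """Treatment-vs-control fold changes of population NICD readouts.

    fold_total: treated mean total NICD / control; fold_p_share: treated
    phospho share p/(n+p) relative to control.  When replicate (noisy)
    readouts are requested, per-replicate fold changes and their SEM are
    attached.
    """

    treatment: str
    fold_total: float
    fold_p_share: float
    replicates: np.ndarray | None = None
    sem: float | None = None


def _arrest_population(n_cells: int, cc: CellCycleParams, params: NicdParams, seed) -> Population:
    """Synchronized population whose cells start at their arrest steady state.

    Cells were held at the block for much longer than the NICD turnover
    time, so each starts at the constant-kinase fixed point for its own
    position.
    """
    pop = make_synchronized_population(n_cells, cc, seed)
    pop.n, pop.p = steady_state_at_theta(pop.theta, params, cc)
    return pop


def _sample_population(
    pop: Population, params: NicdParams, t_grid: np.ndarray
) -> TimeCourse:
    theta, n, p = pop.theta.copy(), pop.n.copy(), pop.p.copy()
    mean_n, mean_p, fracs = [], [], []
    prev = 0.0
    for t in t_grid:
        if t > prev:
            theta, n, p = propagate_population(theta, n, p, params, pop.params, t - prev)
            prev = t
        mean_n.append(n.mean())
        mean_p.append(p.mean())
        fracs.append(phase_fractions(Population(theta, n, p, pop.params)))
    return TimeCourse(np.asarray(t_grid, float), np.array(mean_n), np.array(mean_p), fracs)


def run_release_experiment(
    n_cells: int = 1000,
    cc: CellCycleParams | None = None,
    params: NicdParams | None = None,
    t_grid=None,
    seed: int | None = 0,
    synchronized: bool = True,
) -> TimeCourse:
    """Double-thymidine release time course of population-mean NICD.

    Initialises a synchronized population at its arrest steady state (or an
    asynchronous control with ``synchronized=False``), integrates every
    cell, and returns population means plus phase fractions at each grid
    time (default 0..12 h, step 2 h).
    """
    cc = cc or CellCycleParams()
    params = params or NicdParams()
    t = np.arange(0.0, 12.0 + 1e-9, 2.0) if t_grid is None else np.asarray(t_grid, float)
    if t.size == 0 or (np.diff(t) <= 0).any() or t[0] < 0:
        raise ValueError("t_grid must be increasing and non-negative")
    if synchronized:
        pop = _arrest_population(n_cells, cc, params, seed)
    else:
        # cycling cells sit on the periodic orbit, not the frozen fixed
        # point: burn in for a few cycles so t = 0 is stationary
        pop = make_asynchronous_population(n_cells, cc, seed)
        pop.n, pop.p = steady_state_at_theta(pop.theta, params, cc)
        pop.theta, pop.n, pop.p = propagate_population(
            pop.theta, pop.n, pop.p, params, cc, 3.0 * cc.t_cycle
        )
    tc = _sample_population(pop, params, t)
    tc.metadata = {"seed": seed, "n_cells": n_cells, "synchronized": synchronized}
    return tc


def run_treatment_experiment(
    n_cells: int = 1000,
    cc: CellCycleParams | None = None,
    params: NicdParams | None = None,
    treatment: TreatmentSpec | str = "DMSO",
    seed: int | None = 0,
) -> FoldChangeResult:
    """Drug treatment on an asynchronous culture vs a paired DMSO control.

    Control and treated arms share the same seed (identical populations),
    isolating the treatment effect.  Both arms start at the untreated
    steady state and are integrated for the treatment duration (default
    3 h); fold changes compare population mean total NICD and the phospho
    share p/(n+p).
    """
    cc = cc or CellCycleParams()
    params = params or NicdParams()
    if isinstance(treatment, str):
        treatment = TreatmentSpec(drug=treatment)
    treated_params, _flags = apply_treatment(params, cc, treatment)

    def _endpoint(kin: NicdParams):
        pop = make_asynchronous_population(n_cells, cc, seed)
        # untreated culture on its periodic orbit at the moment of dosing
        pop.n, pop.p = steady_state_at_theta(pop.theta, params, cc)
        theta, n, p = propagate_population(
            pop.theta, pop.n, pop.p, params, cc, 3.0 * cc.t_cycle
        )
        theta, n, p = propagate_population(theta, n, p, kin, cc, treatment.duration)
        return n.mean(), p.mean()

    n_c, p_c = _endpoint(params)
    n_t, p_t = _endpoint(treated_params)
    fold_total = (n_t + p_t) / (n_c + p_c)
    share_c = p_c / (n_c + p_c)
    share_t = p_t / (n_t + p_t)
    label = treatment.drug + (f"+{treatment.combination}" if treatment.combination else "")
    return FoldChangeResult(label, float(fold_total), float(share_t / share_c))


def westernblot_readout(
    true_means,
    noise_cv: float = 0.0,
    loading_noise_cv: float = 0.0,
    lambda_phosphatase: bool = False,
    seed: int | None = 0,
):
    """Simulate blot band intensities for lanes with true (n, p) means.

    Each lane gets a shared lognormal loading factor (pipetting/transfer),
    each band an independent lognormal error, and intensities are divided
    by a simulated loading-control band carrying the same lane factor and
    its own band noise — the standard densitometry normalization.  Lambda
    phosphatase collapses the phospho band into the unphosphorylated band
    before noise (a lysate treatment, not a kinetic one).

    Parameters
    ----------
    true_means : array-like of shape (n_lanes, 2)
        True (n, p) per lane.
    """
    if noise_cv < 0 or loading_noise_cv < 0:
        raise ValueError("noise CVs must be >= 0")
    bands = np.atleast_2d(np.asarray(true_means, dtype=float)).copy()
    if lambda_phosphatase:
        bands = np.column_stack([bands.sum(axis=1), np.zeros(len(bands))])
    rng = np.random.default_rng(seed)

    def _lognorm(cv, size):
        if cv == 0:
            return np.ones(size)
        sigma = np.sqrt(np.log1p(cv**2))
        return rng.lognormal(-(sigma**2) / 2.0, sigma, size)

    lane = _lognorm(loading_noise_cv, len(bands))[:, None]
    band_noise = _lognorm(noise_cv, bands.shape)
    control = lane[:, 0] * _lognorm(noise_cv, len(bands))
    measured = bands * lane * band_noise / control[:, None]
    return measured


def facs_readout(
    pop: Population,
    cv: float = 0.05,
    n_bins: int = 100,
    seed: int | None = 0,
):
    """Propidium-iodide flow-cytometry readout: DNA content and gating.

    True DNA content is 1.0 in G1, rises linearly 1 -> 2 across S, and is
    2.0 in G2/M; measured content carries lognormal stain/instrument noise
    of the given CV.  Fixed gates at 1.25 and 1.75 classify G1 / S / G2M.

    Returns (hist_counts, bin_edges, gated_fractions).
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    cc = pop.params
    th = pop.theta
    s_frac = np.clip((th - cc.d_g1) / cc.d_s, 0.0, 1.0)
    content = 1.0 + s_frac
    rng = np.random.default_rng(seed)
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        content = content * rng.lognormal(-(sigma**2) / 2.0, sigma, content.shape)
    hist, edges = np.histogram(content, bins=n_bins, range=(0.5, 2.5))
    gated = {
        "G1": float(np.mean(content < 1.25)),
        "S": float(np.mean((content >= 1.25) & (content < 1.75))),
        "G2M": float(np.mean(content >= 1.75)),
    }
    return hist, edges, gated
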