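"""Synthetic-data generators with known ground truth.

Replaces the study's wet-lab inputs: clock-and-wavefront somite boundary
series with a treatment-induced period change, noisy virtual-blot release
time courses for calibration tests, and drug-panel fold-change tables.
Every generator is a pure function of (parameters, seed); noisy outputs
always come with a ground-truth record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell_cycle import CellCycleParams
from .experiments import run_release_experiment, run_treatment_experiment, westernblot_readout
from .nicd import NicdParams, TreatmentSpec
from .somites import BoundarySeries

__all__ = [
    "ClockWavefrontParams",
    "generate_boundary_series",
    "generate_release_dataset",
    "generate_treatment_panel",
]


@dataclass(frozen=True)
class ClockWavefrontParams:
    """Clock-and-wavefront rule for somite sizes under a period change.

    Somite length = clock period x wavefront regression speed.  A drug
    applied at ``treatment_onset`` (somite formation index) multiplies the
    period by ``period_factor`` (>= 1 is a delay -> bigger somites), but
    only from the (onset + commitment_lag)-th somite on: the next
    ``commitment_lag`` boundaries are already specified in the anterior
    PSM when the drug arrives (default 3 — positions +1, +2, +3 specified,
    +4 not, at treatment time).
    """

    base_period: float = 90.0  # min; chick segmentation clock scale
    wavefront_speed: float = 1.0  # length units / min
    treatment_onset: int = 0
    commitment_lag: int = 3
    period_factor: float = 1.0
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_period <= 0 or self.wavefront_speed <= 0:
            raise ValueError("base_period and wavefront_speed must be > 0")
        if self.period_factor <= 0:
            raise ValueError("period_factor must be > 0")
        if self.commitment_lag < 0 or int(self.commitment_lag) != self.commitment_lag:
            raise ValueError("commitment_lag must be a non-negative integer")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def generate_boundary_series(
    p: ClockWavefrontParams,
    n_somites: int,
    sample_id: str = "synthetic",
    treatment: str = "synthetic",
) -> tuple[BoundarySeries, pd.DataFrame]:
    """One embryo's boundary series plus its ground-truth length table.

    Somites form in order 0..n_somites-1; the last formed becomes somite
    +1 of the output series (boundary index 0 = posterior-most).  Expected
    lengths follow the clock-and-wavefront rule with the committed-somite
    lag; realised lengths carry lognormal noise of CV ``noise_cv``.
    """
    if n_somites < 2:
        raise ValueError("n_somites must be >= 2")
    form_idx = np.arange(n_somites)
    affected = (form_idx >= p.treatment_onset + p.commitment_lag) & (p.period_factor != 1.0)
    expected = p.base_period * p.wavefront_speed * np.where(affected, p.period_factor, 1.0)
    rng = np.random.default_rng(p.seed)
    if p.noise_cv > 0:
        sigma = np.sqrt(np.log1p(p.noise_cv**2))
        lengths = expected * rng.lognormal(-(sigma**2) / 2.0, sigma, n_somites)
    else:
        lengths = expected.copy()
    # boundaries in formation order (anterior -> posterior), then re-index
    # so that j=0 is the posterior-most boundary and j increases anteriorly
    boundaries = np.concatenate([[0.0], np.cumsum(lengths)])
    positions = boundaries[::-1]  # decreasing: BoundarySeries normalises
    series = BoundarySeries(sample_id, treatment, positions)
    truth = pd.DataFrame(
        {
            "formation_index": form_idx,
            "somite_position": n_somites - form_idx,  # +1 = last formed
            "expected_length": expected,
            "length": lengths,
            "affected": affected,
        }
    )
    return series, truth


def generate_release_dataset(
    cc: CellCycleParams | None = None,
    params: NicdParams | None = None,
    t_grid=None,
    n_cells: int = 200,
    noise_cv: float = 0.0,
    loading_noise_cv: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Noisy release time-course replicates plus a ground-truth record.

    Wraps the release driver and the blot measurement model: each
    replicate is the deterministic population time course with independent
    per-lane blot noise.  Returns a tidy table (replicate, time,
    mean_total, mean_p) and a sidecar dict with the generating rates,
    population size and seeds.
    """
    cc = cc or CellCycleParams()
    params = params or NicdParams()
    tc = run_release_experiment(n_cells=n_cells, cc=cc, params=params, t_grid=t_grid, seed=seed)
    rows = []
    for rep in range(n_replicates):
        lanes = np.column_stack([tc.mean_n, tc.mean_p])
        measured = westernblot_readout(
            lanes, noise_cv=noise_cv, loading_noise_cv=loading_noise_cv,
            seed=np.random.SeedSequence([seed, 1 + rep]).generate_state(1)[0] % (2**31),
        )
        for t, (band_n, band_p) in zip(tc.times, measured):
            rows.append(
                {"replicate": rep, "time": t, "mean_total": band_n + band_p, "mean_p": band_p}
            )
    truth = {
        "params": {k: getattr(params, k) for k in
                   ("alpha", "delta_n", "delta_p", "k1", "k2", "k_base")},
        "n_cells": n_cells,
        "seed": seed,
        "noise_cv": noise_cv,
        "loading_noise_cv": loading_noise_cv,
        "n_replicates": n_replicates,
    }
    return pd.DataFrame(rows), truth


def generate_treatment_panel(
    cc: CellCycleParams | None = None,
    params: NicdParams | None = None,
    drugs=("DMSO", "LY411575", "MLN4924", "Roscovitine", "PurvalanolB", "RO3306"),
    noise_cv: float = 0.1,
    n_replicates: int = 3,
    n_cells: int = 200,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fold-change panel emulating the 3 h drug-treatment blot figures.

    For each drug, the deterministic paired fold change (same-seed control)
    is perturbed by replicate blot noise on the treated and control lanes.
    Returns (replicate table, ground-truth noiseless folds).
    """
    cc = cc or CellCycleParams()
    params = params or NicdParams()
    rows, truth_rows = [], []
    for d, drug in enumerate(drugs):
        res = run_treatment_experiment(
            n_cells=n_cells, cc=cc, params=params, treatment=TreatmentSpec(drug=drug), seed=seed
        )
        truth_rows.append(
            {"drug": drug, "fold_total": res.fold_total, "fold_p_share": res.fold_p_share}
        )
        for rep in range(n_replicates):
            rng_seed = np.random.SeedSequence([seed, 7 + d, rep]).generate_state(1)[0] % (2**31)
            rng = np.random.default_rng(rng_seed)
            if noise_cv > 0:
                sigma = np.sqrt(np.log1p(noise_cv**2))
                # treated and control lanes each carry independent blot noise
                noise = rng.lognormal(-(sigma**2) / 2.0, sigma, 2)
                fold = res.fold_total * noise[0] / noise[1]
            else:
                fold = res.fold_total
            rows.append({"drug": drug, "replicate": rep, "fold_total": fold})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
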