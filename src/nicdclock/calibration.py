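"""Calibration of the NICD kinetic rates to population time-course data.

`NicdTimeCourseModel` is a statsmodels-style modelling object: it is built
from observed mean-total-NICD time courses (optionally also the phospho
mean), and its `fit()` runs multi-start bounded least squares in
log-rate space, returning an `NicdFitResults` carrying estimates, standard
errors from the Gauss-Newton approximation, the per-start table, and an
unidentifiability diagnostic.  The function `fit_nicd_params` is a thin
convenience wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .cell_cycle import CellCycleParams
from .experiments import run_release_experiment
from .nicd import NicdParams

__all__ = ["NicdTimeCourseModel", "NicdFitResults", "fit_nicd_params"]

_RATE_NAMES = ("alpha", "delta_n", "delta_p", "k1", "k2", "k_base")

#: Default box bounds (per hour / au per hour) for the free rates.
DEFAULT_BOUNDS = {
    "alpha": (0.05, 20.0),
    "delta_n": (0.02, 5.0),
    "delta_p": (0.1, 50.0),
    "k1": (0.01, 40.0),
    "k2": (0.01, 40.0),
    "k_base": (0.001, 5.0),
}


class NicdTimeCourseModel:
    """Least-squares model for release-experiment NICD time courses.

    Parameters
    ----------
    times : array-like
        Sampling times (h), shared by all replicate curves.
    total : array-like, shape (n_times,) or (n_reps, n_times)
        Observed population-mean total NICD per replicate.
    cc : CellCycleParams
        Known cell-cycle calibration (phase durations, CDK windows).
    phospho : optional, same shape as total
        Observed mean phosphorylated NICD, fitted jointly when given.
    free : sequence of rate names to estimate; the rest are fixed at
        ``base`` values.
    n_cells, sim_seed : size and seed of the simulated population used to
        evaluate the model — fixed across the fit so the objective is
        deterministic.
    """

    def __init__(
        self,
        times,
        total,
        cc: CellCycleParams | None = None,
        phospho=None,
        free=("alpha", "delta_n", "delta_p", "k1", "k2"),
        base: NicdParams | None = None,
        bounds: dict | None = None,
        n_cells: int = 200,
        sim_seed: int = 0,
    ):
        self.times = np.asarray(times, dtype=float)
        self.total = np.atleast_2d(np.asarray(total, dtype=float))
        if self.total.shape[1] != self.times.size:
            raise ValueError("total must have one column per time point")
        self.phospho = None if phospho is None else np.atleast_2d(np.asarray(phospho, float))
        unknown = set(free) - set(_RATE_NAMES)
        if unknown:
            raise ValueError(f"unknown free parameters: {sorted(unknown)}")
        self.free = tuple(free)
        if len(self.free) > self.times.size * self.total.shape[0]:
            raise ValueError("fewer informative points than free parameters")
        self.cc = cc or CellCycleParams()
        self.base = base or NicdParams()
        self.bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
        self.n_cells = n_cells
        self.sim_seed = sim_seed

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, cc: CellCycleParams | None = None, **kw):
        """Build from a tidy table with columns time, mean_total
        (optionally mean_p and replicate)."""
        if "replicate" in df.columns:
            wide = df.pivot_table(index="replicate", columns="time", values="mean_total")
            times = wide.columns.to_numpy(float)
            total = wide.to_numpy()
            phospho = None
            if "mean_p" in df.columns:
                phospho = df.pivot_table(index="replicate", columns="time", values="mean_p").to_numpy()
        else:
            d = df.sort_values("time")
            times = d["time"].to_numpy(float)
            total = d["mean_total"].to_numpy(float)
            phospho = d["mean_p"].to_numpy(float) if "mean_p" in d.columns else None
        return cls(times, total, cc=cc, phospho=phospho, **kw)

    # -- objective ---------------------------------------------------------

    def _params_from_logx(self, logx: np.ndarray) -> NicdParams:
        kw = dict(zip(self.free, np.exp(logx)))
        # keep the model premise delta_p >= delta_n feasible during search
        dn = kw.get("delta_n", self.base.delta_n)
        if "delta_p" in kw:
            kw["delta_p"] = max(kw["delta_p"], dn)
        elif self.base.delta_p < dn:
            kw["delta_p"] = dn
        return self.base.replace(**kw)

    def predict(self, params: NicdParams):
        tc = run_release_experiment(
            n_cells=self.n_cells, cc=self.cc, params=params,
            t_grid=self.times, seed=self.sim_seed,
        )
        return tc.mean_total, tc.mean_p

    def _residuals(self, logx: np.ndarray) -> np.ndarray:
        total_hat, p_hat = self.predict(self._params_from_logx(logx))
        res = (self.total - total_hat[None, :]).ravel()
        if self.phospho is not None:
            res = np.concatenate([res, (self.phospho - p_hat[None, :]).ravel()])
        return res

    # -- fitting -----------------------------------------------------------

    def fit(self, n_starts: int = 16, seed: int = 0, init: dict | None = None) -> "NicdFitResults":
        """Multi-start bounded least squares in log-rate space.

        Starts are Latin-hypercube samples of the log-bounds box; an
        explicit ``init`` (rate name -> value) is prepended as the first
        start.  Raises if no start converges.
        """
        lo = np.log([self.bounds[f][0] for f in self.free])
        hi = np.log([self.bounds[f][1] for f in self.free])
        starts = []
        if init:
            starts.append(np.clip(np.log([init[f] for f in self.free]), lo, hi))
        n_lhs = max(n_starts - len(starts), 0)
        if n_lhs:
            sampler = qmc.LatinHypercube(d=len(self.free), seed=seed)
            starts.extend(lo + sampler.random(n_lhs) * (hi - lo))

        rows = []
        best = None
        for i, x0 in enumerate(starts):
            try:
                sol = least_squares(self._residuals, x0, bounds=(lo, hi), method="trf")
            except Exception as exc:  # pragma: no cover - integrator failure path
                rows.append({"start": i, "success": False, "rss": np.inf, "message": str(exc)})
                continue
            rss = float(2.0 * sol.cost)
            rows.append(
                {"start": i, "success": bool(sol.success), "rss": rss,
                 **{f: float(v) for f, v in zip(self.free, np.exp(sol.x))}}
            )
            if sol.success and (best is None or rss < float(2.0 * best.cost)):
                best = sol
        starts_table = pd.DataFrame(rows)
        if best is None:
            raise RuntimeError(
                "no least-squares start converged; start table:\n" + starts_table.to_string()
            )

        estimates = dict(zip(self.free, np.exp(best.x)))
        rss = float(2.0 * best.cost)

        # Gauss-Newton covariance in log space -> delta-method SEs on rates
        m = best.fun.size
        dof = max(m - len(self.free), 1)
        s2 = rss / dof
        J = best.jac
        try:
            cov_log = s2 * np.linalg.pinv(J.T @ J)
            se_log = np.sqrt(np.maximum(np.diag(cov_log), 0.0))
        except np.linalg.LinAlgError:  # pragma: no cover
            se_log = np.full(len(self.free), np.nan)
        bse = {f: estimates[f] * se for f, se in zip(self.free, se_log)}

        ok = starts_table[starts_table["success"] == True]  # noqa: E712
        flat = False
        if len(ok) >= 2:
            rss_spread = ok["rss"].max() - ok["rss"].min()
            est_cols = ok[list(self.free)].to_numpy()
            with np.errstate(divide="ignore", invalid="ignore"):
                rel_spread = np.nanmax(est_cols.max(0) / np.maximum(est_cols.min(0), 1e-300))
            flat = bool(rss_spread < 1e-6 * (1.0 + ok["rss"].min()) and rel_spread > 1.5)

        return NicdFitResults(
            model=self,
            params=estimates,
            bse=bse,
            rss=rss,
            nobs=int(self.total.size + (0 if self.phospho is None else self.phospho.size)),
            starts=starts_table,
            unidentifiable=flat,
        )


@dataclass
class NicdFitResults:
    """Fit output: rate estimates, SEs, RSS, per-start table, diagnostics."""

    model: NicdTimeCourseModel
    params: dict
    bse: dict
    rss: float
    nobs: int
    starts: pd.DataFrame
    unidentifiable: bool = False

    @property
    def fitted_params(self) -> NicdParams:
        return self.model._params_from_logx(np.log([self.params[f] for f in self.model.free]))

    def predict(self):
        """Model-implied (mean_total, mean_p) at the data's time grid."""
        return self.model.predict(self.fitted_params)

    def summary(self) -> str:
        lines = [
            "NICD time-course calibration (multi-start least squares)",
            f"  observations: {self.nobs}   free rates: {len(self.model.free)}",
            f"  RSS: {self.rss:.6g}   starts converged: "
            f"{int((self.starts['success'] == True).sum())}/{len(self.starts)}",  # noqa: E712
            f"  unidentifiability flag: {self.unidentifiable}",
            "",
            f"  {'rate':<9}{'estimate':>12}{'std err':>12}",
        ]
        for f in self.model.free:
            lines.append(f"  {f:<9}{self.params[f]:>12.5g}{self.bse[f]:>12.3g}")
        return "\n".join(lines)


def fit_nicd_params(
    timecourse,
    cc: CellCycleParams | None = None,
    free=("alpha", "delta_n", "delta_p", "k1", "k2"),
    init: dict | None = None,
    bounds: dict | None = None,
    n_starts: int = 16,
    seed: int = 0,
    **model_kw,
) -> NicdFitResults:
    """Fit NICD rates to a TimeCourse or tidy DataFrame (convenience wrapper)."""
    if isinstance(timecourse, pd.DataFrame):
        model = NicdTimeCourseModel.from_dataframe(
            timecourse, cc=cc, free=free, bounds=bounds, **model_kw
        )
    else:
        model = NicdTimeCourseModel(
            timecourse.times, timecourse.mean_total, cc=cc, free=free,
            bounds=bounds, **model_kw
        )
    return model.fit(n_starts=n_starts, seed=seed, init=init)
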