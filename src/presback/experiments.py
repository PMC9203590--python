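"""Simulation-study engine: replicated benchmarks of LK vs (refined) CLK.

Each experiment simulates presence-background data repeatedly from one
catalogued probability function, fits the requested methods, and
summarises fitted-probability RMSE against the truth on an evaluation
grid, along with nonconvergence rates.  The design mirrors the three
function categories, the small/large sample ladders, the full/scaled
logistic pair, erroneous local certainty, and the +/-10% local
knowledge mis-specification sensitivity.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import ClassifierConfig
from .likelihood import (FitFamily, FitResult, fit_clk, fit_lk,
                         fit_refined_clk)
from .prevalence import LocalKnowledge
from .rspf import FunctionCatalog, RSPFModel, catalog
from .simulate import simulate_pb, true_prevalence

METHODS = ("lk", "clk_known_pi", "refined_clk")
_SEED_MOD = 2**31


@dataclass(frozen=True)
class ExperimentConfig:
    """One replicated simulation experiment on one function."""

    name: str
    function: str                       # catalogue key
    n1: int = 5000
    n0: int = 50_000
    reps: int = 1000
    methods: tuple[str, ...] = ("lk", "refined_clk")
    lk_family: tuple[str, int] = ("logistic", 1)     # (link, degree)
    clk_family: tuple[str, int] = ("logistic", 1)
    q: float = 1.0                      # local knowledge at the top sites
    percentile: float = 10.0
    aggregator: str = "mean"
    misspec_factor: float = 1.0         # multiplies q (0.9 / 1.0 / 1.1)
    classifier: str = "neural_net"
    hidden_units: int = 8
    alpha: float = 1e-2
    classifier_max_iter: int = 500
    n_starts: int = 5
    seed: int = 0
    grid_size: int = 1001
    heavy: bool = False

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if self.misspec_factor <= 0:
            raise ValueError("misspec_factor must be > 0")
        bad = set(self.methods) - set(METHODS)
        if bad:
            raise ValueError(f"unknown methods {sorted(bad)}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentConfig":
        d = json.loads(text)
        for k in ("methods", "lk_family", "clk_family"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class ReplicationReport:
    config: ExperimentConfig
    records: pd.DataFrame          # one row per (replicate, method)
    grid: np.ndarray
    truth: np.ndarray
    mean_curves: dict              # method -> mean fitted curve (converged only)
    summary: pd.DataFrame          # method-level summary block

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(outdir / "records.csv", index=False,
                            float_format="%.17g")
        self.summary.to_csv(outdir / "summary.csv", index=False,
                            float_format="%.17g")
        curves = pd.DataFrame({"x": self.grid[:, 0], "truth": self.truth})
        for m, c in self.mean_curves.items():
            curves[f"mean_{m}"] = c
        curves.to_csv(outdir / "mean_curves.csv", index=False,
                      float_format="%.17g")
        (outdir / "config.json").write_text(self.config.to_json())


def evaluation_grid(model: RSPFModel, grid_size: int = 1001) -> np.ndarray:
    """Equally spaced tensor grid over the model's domain."""
    per_axis = grid_size if model.n_covariates == 1 else min(grid_size, 101)
    axes = [np.linspace(lo, hi, per_axis) for lo, hi in model.domain]
    if model.n_covariates == 1:
        return axes[0][:, None]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([m.ravel() for m in mesh])


def rmse_curve(fitted: FitResult, truth: RSPFModel,
               grid_size: int = 1001) -> float:
    """RMSE of fitted vs true probabilities on the evaluation grid."""
    grid = evaluation_grid(truth, grid_size)
    pf = fitted.predict(grid)
    if not np.all(np.isfinite(pf)):
        raise ValueError("non-finite fitted probabilities on the grid")
    pt = truth.probability(grid)
    return float(np.sqrt(np.mean((pf - pt) ** 2)))


def _fit_one(method: str, data, config: ExperimentConfig,
             model: RSPFModel, rep_seed: int):
    """Run one method on one replicate; returns (FitResult, pi_hat)."""
    if method == "lk":
        fam = FitFamily(link=config.lk_family[0], degree=config.lk_family[1],
                        n_covariates=model.n_covariates)
        return fit_lk(data, fam, config.n_starts, rep_seed), None
    fam = FitFamily(link=config.clk_family[0], degree=config.clk_family[1],
                    n_covariates=model.n_covariates)
    if method == "clk_known_pi":
        pi0 = true_prevalence(model)
        return fit_clk(data, fam, pi0, config.n_starts, rep_seed), pi0
    lkn = LocalKnowledge(q=min(config.q * config.misspec_factor, 1.0),
                         percentile=config.percentile,
                         aggregator=config.aggregator)
    cfg = ClassifierConfig(kind=config.classifier,
                           hidden_units=config.hidden_units,
                           alpha=config.alpha,
                           max_iter=config.classifier_max_iter,
                           seed=rep_seed)
    rep = fit_refined_clk(data, fam, lkn, cfg,
                          n_starts=config.n_starts, seed=rep_seed)
    return rep.fit, rep.prevalence.pi_hat


def run_experiment(config: ExperimentConfig,
                   reps: Optional[int] = None,
                   cat: Optional[FunctionCatalog] = None) -> ReplicationReport:
    """Run all replicates of one experiment.

    Deterministic given the master seed.  ``reps`` overrides the
    configured replicate count (the full-scale run is long; scaled-down
    runs are routine).  A replicate whose fit raises is recorded as
    failed, never dropped.  Mean curves average converged replicates
    only; nonconvergence is reported separately.
    """
    cat = cat or catalog()
    model = cat.model(config.function)
    reps = config.reps if reps is None else reps
    grid = evaluation_grid(model, config.grid_size)
    truth_curve = model.probability(grid)

    rows = []
    curves: dict[str, list[np.ndarray]] = {m: [] for m in config.methods}
    for rep in range(reps):
        rep_seed = (config.seed + 1009 * rep) % _SEED_MOD
        data = simulate_pb(model, config.n1, config.n0, seed=rep_seed,
                           model_id=config.function)
        for method in config.methods:
            row = {"experiment": config.name, "function": config.function,
                   "method": method, "rep": rep, "seed": rep_seed}
            try:
                fit, pi_hat = _fit_one(method, data, config, model, rep_seed)
                pf = fit.predict(grid)
                rmse = float(np.sqrt(np.mean((pf - truth_curve) ** 2)))
                row.update(converged=bool(fit.converged),
                           loglik=fit.loglik, rmse=rmse, pi_hat=pi_hat,
                           constraint_residual=fit.constraint_residual,
                           beta_hat=json.dumps(np.asarray(fit.beta_hat).tolist()))
                if fit.converged:
                    curves[method].append(pf)
            except Exception as exc:  # record the failure, keep going
                row.update(converged=False, loglik=np.nan, rmse=np.nan,
                           pi_hat=None, constraint_residual=None,
                           beta_hat=None, error=str(exc))
            rows.append(row)

    records = pd.DataFrame(rows)
    mean_curves = {}
    summary_rows = []
    for m in config.methods:
        sub = records[records["method"] == m]
        conv = sub[sub["converged"] == True]  # noqa: E712
        mean_curves[m] = (np.mean(curves[m], axis=0) if curves[m]
                          else np.full(len(grid), np.nan))
        rm = conv["rmse"].astype(float)
        summary_rows.append({
            "experiment": config.name, "function": config.function,
            "method": m, "reps": reps,
            "n_converged": len(conv),
            "nonconvergence_rate": 1.0 - len(conv) / reps,
            "rmse_mean": rm.mean() if len(conv) else np.nan,
            "rmse_median": rm.median() if len(conv) else np.nan,
            "rmse_q10": rm.quantile(0.1) if len(conv) else np.nan,
            "rmse_q90": rm.quantile(0.9) if len(conv) else np.nan,
        })
    return ReplicationReport(config=config, records=records, grid=grid,
                             truth=truth_curve, mean_curves=mean_curves,
                             summary=pd.DataFrame(summary_rows))


def summarize(reports: Sequence[ReplicationReport]) -> pd.DataFrame:
    """Long-format comparison table across experiments and methods.

    Columns: experiment, function, method, reps, n_converged,
    nonconvergence_rate, rmse_mean, rmse_median, rmse_q10, rmse_q90.
    """
    if not reports:
        raise ValueError("no reports to summarise")
    return pd.concat([r.summary for r in reports], ignore_index=True)


# ---------------------------------------------------------------------------
# The benchmark suite

# local knowledge values: the maximal probabilities of the generating
# functions, rounded as conventionally quoted
_CAT3_Q = {"cat3_linear": 0.83, "cat3_quadratic": 0.8, "cat3_cubic": 0.75}
_HF_Q = {"hf_full": 0.8, "hf_scaled": 0.4}


def paper_suite() -> list[ExperimentConfig]:
    """Fully specified configurations of the benchmark study.

    Replicate counts default to 1000; pass ``reps=...`` to
    :func:`run_experiment` for scaled-down runs.  The very-large
    sample configurations are flagged heavy.
    """
    cfgs: list[ExperimentConfig] = []
    cat1 = ["cat1_linear", "cat1_quadratic", "cat1_cubic"]
    cat2 = ["cat2_scaled_logistic", "cat2_gaussian", "cat2_exponential"]
    cat3 = ["cat3_linear", "cat3_quadratic", "cat3_cubic"]
    deg = {"linear": 1, "quadratic": 2, "cubic": 3,
           "scaled": 1, "gaussian": 2, "exponential": 3}

    def d_of(fn):
        return deg[fn.split("_")[1]]

    for fn in cat1:
        cfgs.append(ExperimentConfig(
            name=f"cat1_main/{fn}", function=fn, n1=5000, n0=50_000,
            lk_family=("logistic", d_of(fn)), clk_family=("logistic", d_of(fn)),
            q=1.0))
        cfgs.append(ExperimentConfig(
            name=f"cat1_small/{fn}", function=fn, n1=250, n0=5000,
            lk_family=("logistic", d_of(fn)), clk_family=("logistic", d_of(fn)),
            q=1.0))
    for fn in cat2:
        # LK fits a logistic family; CLK an exponential family
        cfgs.append(ExperimentConfig(
            name=f"cat2_main/{fn}", function=fn, n1=5000, n0=50_000,
            lk_family=("logistic", d_of(fn)),
            clk_family=("exponential", d_of(fn)), q=1.0))
    for fn in cat3:
        base = dict(function=fn, n1=5000, n0=50_000,
                    lk_family=("logistic", d_of(fn)),
                    clk_family=("logistic", d_of(fn)), q=_CAT3_Q[fn])
        cfgs.append(ExperimentConfig(name=f"cat3_lkn/{fn}", **base))
        for f in (0.9, 1.1):
            cfgs.append(ExperimentConfig(
                name=f"cat3_lkn_misspec/{fn}/{f}", misspec_factor=f, **base))
        cfgs.append(ExperimentConfig(
            name=f"cat3_erroneous_lc/{fn}", **{**base, "q": 1.0}))
        cfgs.append(ExperimentConfig(
            name=f"cat_verylarge/{fn}", heavy=True,
            **{**base, "n1": 50_000, "n0": 500_000}))
    cfgs.append(ExperimentConfig(
        name="cat3_erroneous_lc/hf_scaled", function="hf_scaled",
        n1=5000, n0=50_000, lk_family=("logistic", 1),
        clk_family=("logistic", 1), q=1.0))
    for fn, qv in _HF_Q.items():
        for (n1, n0) in ((50, 5000), (500, 5000), (5000, 50_000)):
            cfgs.append(ExperimentConfig(
                name=f"hf_suite/{fn}/{n1}_{n0}", function=fn,
                n1=n1, n0=n0, lk_family=("logistic", 1),
                clk_family=("logistic", 1), q=qv))
    return cfgs
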