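"""Presence-background likelihoods and the LK / CLK / refined-CLK fits.

The relative (LK) log-likelihood of a candidate probability function
p(x; beta) given presences P and background B is

    L(beta) = sum_{x in P} ln p(x; beta)
              - n1 * ln( (1/n0) sum_{x in B} p(x; beta) ),

the background mean standing in for the population prevalence.  L is
exactly invariant to multiplying the family by a constant — the source
of the well-known scale non-identifiability of presence-background
maximum likelihood.  The constrained (CLK) fit maximises the same
objective subject to

    (1/n0) sum_{x in B} p(x; beta) = pi0

for a predetermined prevalence pi0, which pins down the scale.  The
constraint is enforced by profiling the intercept: the background mean
is strictly monotone in beta0 for every supported link, so for each
setting of the remaining coefficients there is a unique feasible
intercept, found by bracketing and root-finding.  On the constraint
surface the objective reduces to sum_P ln p - n1 * ln(pi0).

The refined CLK pipeline estimates pi0 from the data itself: train a
membership classifier on the pooled rows, read the labelling frequency
off the top-ranked scores under local certainty or local knowledge,
convert it to a prevalence estimate, and run the constrained fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import expit
from sklearn.base import BaseEstimator

from .classify import (ClassifierConfig, SMembershipClassifier,
                       SMembershipScores, fit_s_classifier, score_pb)
from .prevalence import (LocalKnowledge, PrevalenceEstimate,
                         estimate_prevalence_from_scores)
from .simulate import PBDataset

_P_FLOOR = 1e-300
_GRAD_TOL = 1e-3       # relative gradient norm for declared convergence
_BETA_BOUND = 50.0     # |beta|_inf above this flags a runaway fit
_CONSTRAINT_TOL = 1e-8
_EXP_PENALTY = 1e4     # smooth penalty keeping exp-link probabilities <= 1


# ---------------------------------------------------------------------------
# Fit family: link + per-covariate polynomial ladder (no cross terms)

@dataclass(frozen=True)
class FitFamily:
    """An unscaled parametric family to fit.

    ``degree`` is the polynomial degree of the inner function in each
    covariate (an int applies to all covariates).  Terms are the pure
    powers x_j, x_j^2, ..., x_j^degree_j; the free parameters are the
    intercept plus one coefficient per term.
    """

    link: str = "logistic"
    degree: int | tuple[int, ...] = 1
    n_covariates: int = 1

    def __post_init__(self) -> None:
        if self.link not in ("logistic", "exponential", "cloglog"):
            raise ValueError(f"unsupported link {self.link!r}")
        degs = self.degrees
        if any(d < 1 for d in degs):
            raise ValueError("degree must be >= 1")

    @property
    def degrees(self) -> tuple[int, ...]:
        if isinstance(self.degree, int):
            return (self.degree,) * self.n_covariates
        if len(self.degree) != self.n_covariates:
            raise ValueError("one degree per covariate required")
        return tuple(self.degree)

    @property
    def n_params(self) -> int:
        return 1 + sum(self.degrees)

    def design(self, X: np.ndarray) -> np.ndarray:
        """Non-intercept term matrix T with g = beta0 + T @ beta_rest."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        cols = []
        for j, dg in enumerate(self.degrees):
            for e in range(1, dg + 1):
                cols.append(X[:, j] ** e)
        return np.column_stack(cols)

    # link evaluations on the inner polynomial g -------------------------
    def p_of_g(self, g: np.ndarray) -> np.ndarray:
        if self.link == "logistic":
            return expit(-g)
        if self.link == "exponential":
            return np.exp(np.minimum(g, 300.0))
        return -np.expm1(-np.exp(np.minimum(g, 300.0)))

    def dp_dg(self, g: np.ndarray, p: np.ndarray) -> np.ndarray:
        if self.link == "logistic":
            return -p * (1.0 - p)
        if self.link == "exponential":
            return p
        eg = np.exp(np.minimum(g, 300.0))
        return eg * np.exp(-eg)

    def logp_of_g(self, g: np.ndarray) -> np.ndarray:
        if self.link == "logistic":
            return -np.logaddexp(0.0, g)
        if self.link == "exponential":
            return np.minimum(g, 300.0)
        return np.log(np.maximum(self.p_of_g(g), _P_FLOOR))

    def dlogp_dg(self, g: np.ndarray, p: np.ndarray) -> np.ndarray:
        if self.link == "logistic":
            return -(1.0 - p)
        if self.link == "exponential":
            return np.ones_like(g)
        return self.dp_dg(g, p) / np.maximum(p, _P_FLOOR)

    def probability(self, beta: np.ndarray, X: np.ndarray) -> np.ndarray:
        beta = np.asarray(beta, dtype=float)
        g = beta[0] + self.design(X) @ beta[1:]
        return self.p_of_g(g)


@dataclass
class FitResult:
    beta_hat: np.ndarray
    loglik: float
    converged: bool
    family: FitFamily
    n_starts_used: int = 1
    grad_norm: float = float("nan")
    constraint_residual: Optional[float] = None
    pi_constraint: Optional[float] = None
    diagnostics: list = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Fitted Pr(y=1|x) over the rows of X."""
        return self.family.probability(self.beta_hat, X)

    def to_dict(self) -> dict:
        return {
            "beta_hat": np.asarray(self.beta_hat).tolist(),
            "loglik": self.loglik, "converged": self.converged,
            "link": self.family.link, "degree": self.family.degree,
            "n_covariates": self.family.n_covariates,
            "n_starts_used": self.n_starts_used, "grad_norm": self.grad_norm,
            "constraint_residual": self.constraint_residual,
            "pi_constraint": self.pi_constraint,
        }


# ---------------------------------------------------------------------------
# LK log-likelihood

def _loglik_terms(beta: np.ndarray, family: FitFamily,
                  TP: np.ndarray, TB: np.ndarray):
    beta = np.asarray(beta, dtype=float)
    gP = beta[0] + TP @ beta[1:]
    gB = beta[0] + TB @ beta[1:]
    pP = family.p_of_g(gP)
    pB = family.p_of_g(gB)
    return gP, gB, pP, pB


def lk_loglik(beta: Sequence[float], family: FitFamily, data: PBDataset) -> float:
    """The relative log-likelihood L(beta) defined in the module docstring."""
    TP, TB = family.design(data.P), family.design(data.B)
    gP, _, pP, pB = _loglik_terms(beta, family, TP, TB)
    mean_b = pB.mean()
    if not np.isfinite(mean_b) or mean_b <= _P_FLOOR:
        return -np.inf
    return float(np.sum(family.logp_of_g(gP)) - data.n1 * np.log(mean_b))


def _lk_value_grad(beta, family, TP, TB, n1):
    """(-L, -dL/dbeta) with the exp-link validity penalty included."""
    gP, gB, pP, pB = _loglik_terms(beta, family, TP, TB)
    mean_b = pB.mean()
    if not np.isfinite(mean_b) or mean_b <= _P_FLOOR:
        return np.inf, np.zeros_like(np.asarray(beta, float))
    L = np.sum(family.logp_of_g(gP)) - n1 * np.log(mean_b)
    # gradient: chain rule through g; design incl. intercept column
    dlP = family.dlogp_dg(gP, pP)
    dpB = family.dp_dg(gB, pB)
    grad = np.empty_like(np.asarray(beta, float))
    grad[0] = dlP.sum() - n1 * dpB.sum() / (pB.size * mean_b)
    grad[1:] = TP.T @ dlP - n1 * (TB.T @ dpB) / (pB.size * mean_b)
    if family.link == "exponential":
        # keep p <= 1 on all data points: quadratic penalty on g > 0
        vP, vB = np.maximum(gP, 0.0), np.maximum(gB, 0.0)
        L -= _EXP_PENALTY * (np.sum(vP**2) + np.sum(vB**2))
        grad[0] -= _EXP_PENALTY * 2 * (vP.sum() + vB.sum())
        grad[1:] -= _EXP_PENALTY * 2 * (TP.T @ vP + TB.T @ vB)
    if not np.isfinite(L):
        return np.inf, np.zeros_like(grad)
    return -L, -grad


def _starts(n_params: int, n_starts: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    starts = [np.zeros(n_params)]
    for _ in range(n_starts - 1):
        starts.append(rng.standard_normal(n_params))
    return np.array(starts)


def _design_full_rank(family: FitFamily, data: PBDataset) -> bool:
    T = family.design(np.vstack([data.P, data.B]))
    A = np.column_stack([np.ones(T.shape[0]), T])
    return np.linalg.matrix_rank(A) == A.shape[1]


def fit_lk(data: PBDataset, family: FitFamily, n_starts: int = 5,
           seed: int = 0) -> FitResult:
    """Multi-start quasi-Newton maximisation of the LK log-likelihood.

    Convergence requires optimiser success, a finite objective,
    relative gradient norm <= 1e-3 and |beta|_inf <= 50; the runaway
    bound flags the drifting solutions typical when the family is not
    identifiable from relative selection.
    """
    TP, TB = family.design(data.P), family.design(data.B)
    diagnostics = []
    if not _design_full_rank(family, data):
        return FitResult(beta_hat=np.zeros(family.n_params), loglik=float("nan"),
                         converged=False, family=family,
                         diagnostics=[{"error": "rank-deficient design"}])
    best = None
    for i, x0 in enumerate(_starts(family.n_params, n_starts, seed)):
        res = minimize(_lk_value_grad, x0, args=(family, TP, TB, data.n1),
                       jac=True, method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7})
        L = -res.fun
        gnorm = float(np.max(np.abs(res.jac))) / max(1.0, abs(L))
        ok = (res.success and np.isfinite(L) and gnorm <= _GRAD_TOL
              and np.max(np.abs(res.x)) <= _BETA_BOUND)
        diagnostics.append({"start": i, "status": int(res.status),
                            "loglik": float(L), "grad_norm": gnorm,
                            "converged": bool(ok), "nit": int(res.nit)})
        cand = (ok, L, -i, res.x, gnorm)
        if best is None or cand[:3] > best[:3]:
            best = cand
    ok, L, negi, x, gnorm = best
    return FitResult(beta_hat=x, loglik=float(L), converged=bool(ok),
                     family=family, n_starts_used=n_starts,
                     grad_norm=gnorm, diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# Intercept profiling and the constrained fit

def profile_intercept(beta_rest: Sequence[float], family: FitFamily,
                      B: np.ndarray, pi0: float,
                      TB: Optional[np.ndarray] = None) -> float:
    """The unique intercept making the background mean equal pi0.

    Exploits strict monotonicity of the background mean probability in
    beta0 for all supported links.  Raises if pi0 is unattainable
    (reporting the attainable interval).
    """
    if not (0 < pi0 < 1):
        raise ValueError("pi0 must lie in (0, 1)")
    beta_rest = np.asarray(beta_rest, dtype=float)
    if TB is None:
        TB = family.design(B)
    h = TB @ beta_rest

    if family.link == "exponential":
        # mean(exp(b0 + h)) = pi0 has the closed form below
        return float(np.log(pi0) - (np.log(np.mean(np.exp(h - h.max()))) + h.max()))

    def mean_minus(b0: float) -> float:
        return float(family.p_of_g(b0 + h).mean() - pi0)

    lo, hi = -_BETA_BOUND, _BETA_BOUND
    flo, fhi = mean_minus(lo), mean_minus(hi)
    # widen the bracket geometrically if needed
    for _ in range(8):
        if flo * fhi <= 0:
            break
        lo, hi = lo * 2, hi * 2
        flo, fhi = mean_minus(lo), mean_minus(hi)
    if flo * fhi > 0:
        a, b = sorted([flo + pi0, fhi + pi0])
        raise ValueError(
            f"pi0={pi0} unattainable for these coefficients; background "
            f"mean ranges over [{a:.3g}, {b:.3g}]")
    b0 = brentq(mean_minus, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    return float(b0)


def _clk_objective(beta_rest, family, TP, TB, n1, pi0):
    """Negative constrained objective over the profiled surface."""
    try:
        b0 = profile_intercept(beta_rest, family, None, pi0, TB=TB)
    except ValueError:
        return 1e12
    beta = np.concatenate([[b0], beta_rest])
    gP = b0 + TP @ beta[1:]
    val = np.sum(family.logp_of_g(gP)) - n1 * np.log(pi0)
    if family.link == "exponential":
        gB = b0 + TB @ beta[1:]
        val -= _EXP_PENALTY * (np.sum(np.maximum(gP, 0.0) ** 2)
                               + np.sum(np.maximum(gB, 0.0) ** 2))
    if not np.isfinite(val):
        return 1e12
    return -val


def fit_clk(data: PBDataset, family: FitFamily, pi0: float,
            n_starts: int = 5, seed: int = 0) -> FitResult:
    """Constrained maximisation with the background mean pinned at pi0.

    Optimises over the non-intercept coefficients with the intercept
    profiled at every evaluation, so every iterate is exactly feasible.
    """
    if not (0 < pi0 < 1):
        raise ValueError("pi0 must lie in (0, 1)")
    TP, TB = family.design(data.P), family.design(data.B)
    m = family.n_params - 1
    diagnostics = []
    if not _design_full_rank(family, data):
        return FitResult(beta_hat=np.zeros(family.n_params), loglik=float("nan"),
                         converged=False, family=family, pi_constraint=pi0,
                         diagnostics=[{"error": "rank-deficient design"}])
    best = None
    for i, r0 in enumerate(_starts(m, n_starts, seed)):
        res = minimize(_clk_objective, r0, args=(family, TP, TB, data.n1, pi0),
                       method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7})
        L = -res.fun
        feasible = L > -1e11
        if feasible:
            try:
                b0 = profile_intercept(res.x, family, None, pi0, TB=TB)
            except ValueError:
                feasible = False
        if not feasible:
            diagnostics.append({"start": i, "status": int(res.status),
                                "converged": False, "error": "infeasible"})
            cand = (False, -np.inf, -i, np.concatenate([[0.0], res.x]),
                    np.inf, np.inf)
            if best is None:
                best = cand
            continue
        beta = np.concatenate([[b0], res.x])
        resid = abs(float(family.p_of_g(b0 + TB @ res.x).mean()) - pi0)
        gnorm = float(np.max(np.abs(res.jac))) / max(1.0, abs(L))
        ok = (res.success and np.isfinite(L) and gnorm <= _GRAD_TOL
              and np.max(np.abs(beta)) <= _BETA_BOUND
              and resid <= _CONSTRAINT_TOL)
        diagnostics.append({"start": i, "status": int(res.status),
                            "loglik": float(L), "grad_norm": gnorm,
                            "constraint_residual": resid,
                            "converged": bool(ok), "nit": int(res.nit)})
        cand = (ok, L, -i, beta, gnorm, resid)
        if best is None or cand[:3] > best[:3]:
            best = cand
    ok, L, negi, beta, gnorm, resid = best
    return FitResult(beta_hat=beta, loglik=float(L), converged=bool(ok),
                     family=family, n_starts_used=n_starts, grad_norm=gnorm,
                     constraint_residual=float(resid), pi_constraint=pi0,
                     diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# Refined CLK: classifier -> prevalence -> constrained fit

@dataclass
class RefinedFitReport:
    scores: SMembershipScores
    prevalence: PrevalenceEstimate
    fit: FitResult
    suspicious: bool = False
    provenance: dict = field(default_factory=dict)


def fit_refined_clk(data: PBDataset, family: FitFamily,
                    lkn: Optional[LocalKnowledge] = None,
                    classifier_config: Optional[ClassifierConfig] = None,
                    n_starts: int = 5, seed: int = 0) -> RefinedFitReport:
    """The full data-driven pipeline.

    Step 1: train the membership classifier on pooled P and B and score
    every row.  Step 2: rank the scores, estimate the labelling
    frequency from the top share, convert it to a prevalence estimate
    under local knowledge q.  Step 3: run the constrained fit with the
    estimated prevalence.  A capped prevalence estimate still proceeds
    but marks the report suspicious.
    """
    lkn = lkn or LocalKnowledge()
    cfg = classifier_config or ClassifierConfig(seed=seed)
    scorer = fit_s_classifier(data, cfg)
    scores = score_pb(scorer, data)
    prev = estimate_prevalence_from_scores(scores, lkn, clip_eps=cfg.clip_eps)
    pi0 = min(max(prev.pi_hat, 1e-6), 1 - 1e-9)
    fit = fit_clk(data, family, pi0, n_starts=n_starts, seed=seed)
    return RefinedFitReport(
        scores=scores, prevalence=prev, fit=fit,
        suspicious=prev.capped,
        provenance={"seed": seed, "classifier": cfg.kind,
                    "q": lkn.q, "percentile": lkn.percentile,
                    "aggregator": lkn.aggregator, "pi0": pi0},
    )


# ---------------------------------------------------------------------------
# Scikit-learn estimator facade

class _PBFitMixin:
    @staticmethod
    def _split(X: np.ndarray, s: np.ndarray) -> PBDataset:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        s = np.asarray(s)
        if set(np.unique(s)) - {0, 1}:
            raise ValueError("s must be binary (1 = presence sample)")
        if X.shape[0] != s.shape[0]:
            raise ValueError("X and s length mismatch")
        return PBDataset(P=X[s == 1], B=X[s == 0])

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Fitted Pr(y=1|x) over the rows of X."""
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")
        return self.result_.predict(X)


class LKEstimator(BaseEstimator, _PBFitMixin):
    """Unconstrained presence-background maximum likelihood.

    ``fit(X, s)`` takes pooled covariates and the membership flag
    (s=1 presence sample, s=0 background); ``predict(X)`` returns the
    fitted probability of presence.
    """

    def __init__(self, link: str = "logistic", degree: int = 1,
                 n_starts: int = 5, random_state: int = 0):
        self.link = link
        self.degree = degree
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, X, s):
        data = self._split(X, s)
        family = FitFamily(link=self.link, degree=self.degree,
                           n_covariates=data.n_covariates)
        self.result_ = fit_lk(data, family, self.n_starts, self.random_state)
        self.coef_ = self.result_.beta_hat
        self.loglik_ = self.result_.loglik
        self.converged_ = self.result_.converged
        self.n_features_in_ = data.n_covariates
        return self


class CLKEstimator(BaseEstimator, _PBFitMixin):
    """Constrained presence-background maximum likelihood.

    Requires ``pi0``, the prevalence at which the background mean of
    the fitted probabilities is pinned.
    """

    def __init__(self, pi0: float = 0.5, link: str = "logistic",
                 degree: int = 1, n_starts: int = 5, random_state: int = 0):
        self.pi0 = pi0
        self.link = link
        self.degree = degree
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, X, s):
        data = self._split(X, s)
        family = FitFamily(link=self.link, degree=self.degree,
                           n_covariates=data.n_covariates)
        self.result_ = fit_clk(data, family, self.pi0,
                               self.n_starts, self.random_state)
        self.coef_ = self.result_.beta_hat
        self.loglik_ = self.result_.loglik
        self.converged_ = self.result_.converged
        self.constraint_residual_ = self.result_.constraint_residual
        self.n_features_in_ = data.n_covariates
        return self


class RefinedCLKEstimator(BaseEstimator, _PBFitMixin):
    """Constrained fit with the prevalence estimated from the data.

    Composes the membership classifier, the top-percentile labelling
    frequency estimate under local knowledge q, and the constrained
    likelihood fit.
    """

    def __init__(self, link: str = "logistic", degree: int = 1,
                 q: float = 1.0, percentile: float = 10.0,
                 aggregator: str = "mean", classifier: str = "neural_net",
                 hidden_units: int = 8, alpha: float = 1e-2,
                 classifier_max_iter: int = 500, n_starts: int = 5,
                 random_state: int = 0,
                 oracle_model=None, oracle_c=None):
        self.link = link
        self.degree = degree
        self.q = q
        self.percentile = percentile
        self.aggregator = aggregator
        self.classifier = classifier
        self.hidden_units = hidden_units
        self.alpha = alpha
        self.classifier_max_iter = classifier_max_iter
        self.n_starts = n_starts
        self.random_state = random_state
        self.oracle_model = oracle_model
        self.oracle_c = oracle_c

    def fit(self, X, s):
        data = self._split(X, s)
        family = FitFamily(link=self.link, degree=self.degree,
                           n_covariates=data.n_covariates)
        lkn = LocalKnowledge(q=self.q, percentile=self.percentile,
                             aggregator=self.aggregator)
        cfg = ClassifierConfig(kind=self.classifier,
                               hidden_units=self.hidden_units,
                               alpha=self.alpha,
                               max_iter=self.classifier_max_iter,
                               seed=self.random_state,
                               oracle_model=self.oracle_model,
                               oracle_c=self.oracle_c)
        rep = fit_refined_clk(data, family, lkn, cfg,
                              n_starts=self.n_starts, seed=self.random_state)
        self.report_ = rep
        self.result_ = rep.fit
        self.coef_ = rep.fit.beta_hat
        self.loglik_ = rep.fit.loglik
        self.converged_ = rep.fit.converged
        self.c_hat_ = rep.prevalence.c_hat
        self.pi_hat_ = rep.prevalence.pi_hat
        self.constraint_residual_ = rep.fit.constraint_residual
        self.n_features_in_ = data.n_covariates
        return self
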