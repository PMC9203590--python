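"""Parametric resource selection probability functions (RSPFs).

An RSPF is the absolute conditional probability of presence,
``Pr(y=1|x)``, as a function of environmental covariates x.  Models are
parameterised by a link function applied to an inner polynomial

    g(x) = beta0 + sum_j beta_j * b_j(x),

optionally multiplied by a positive scale ``k``:

* ``logistic``:     p(x) = k / (1 + exp(g(x)))
* ``exponential``:  p(x) = k * exp(g(x))
* ``cloglog``:      p(x) = k * (1 - exp(-exp(g(x))))

The sign convention for the logistic link keeps the polynomial exactly
as it appears inside ``exp(.)``, so a positive slope coefficient makes
the probability *decrease* in that covariate.

The module ships a catalogue of thirteen named simulated species whose
probability functions span three qualitative regimes: functions whose
maximum reaches (essentially) one while the log-probability is
nonlinear, functions that reach one but are not identifiable from
relative selection alone (scaled logistic, Gaussian, exponential), and
logistic functions whose maximum stays well below one.  The catalogue
also carries the full/half scaled pair of one-dimensional logistic
functions used to illustrate the scale non-identifiability of
presence-background likelihoods, and a two-covariate full/scaled pair.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit

LINKS = ("logistic", "exponential", "cloglog")


def _apply_link(link: str, g: np.ndarray) -> np.ndarray:
    if link == "logistic":
        # 1/(1+exp(g)) == expit(-g), overflow-safe
        return expit(-g)
    if link == "exponential":
        return np.exp(g)
    if link == "cloglog":
        return -np.expm1(-np.exp(g))
    raise ValueError(f"unknown link {link!r}; expected one of {LINKS}")


@dataclass(frozen=True)
class RSPFModel:
    """A parametric probability-of-presence function.

    Parameters
    ----------
    link : {"logistic", "exponential", "cloglog"}
    coefficients : sequence of float
        ``(beta0, beta1, ..., beta_m)`` — intercept followed by one
        coefficient per polynomial term.
    powers : sequence of int tuples
        Exponent vector of each non-intercept term, shape (m, d).
        A univariate cubic is ``((1,), (2,), (3,))``.
    scale : float
        Positive multiplier k applied to the link output (default 1).
    domain : sequence of (low, high)
        Closed covariate bounds, one pair per covariate.
    """

    link: str
    coefficients: tuple[float, ...]
    powers: tuple[tuple[int, ...], ...]
    scale: float = 1.0
    domain: tuple[tuple[float, float], ...] = ((-1.0, 1.0),)

    def __post_init__(self) -> None:
        if self.link not in LINKS:
            raise ValueError(f"unknown link {self.link!r}")
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))
        object.__setattr__(self, "powers", tuple(tuple(int(p) for p in row) for row in self.powers))
        object.__setattr__(self, "domain", tuple((float(a), float(b)) for a, b in self.domain))
        if not all(math.isfinite(c) for c in self.coefficients):
            raise ValueError("non-finite coefficient")
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise ValueError("scale must be positive and finite")
        if len(self.coefficients) != len(self.powers) + 1:
            raise ValueError("need exactly one coefficient per term plus an intercept")
        d = self.n_covariates
        if any(len(row) != d for row in self.powers):
            raise ValueError("inconsistent covariate dimension in powers")
        if any(a > b for a, b in self.domain):
            raise ValueError("domain lower bound exceeds upper bound")

    @property
    def n_covariates(self) -> int:
        return len(self.domain)

    def inner(self, X: np.ndarray) -> np.ndarray:
        """Evaluate the inner polynomial g at each row of X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        g = np.full(X.shape[0], self.coefficients[0])
        for beta, pw in zip(self.coefficients[1:], self.powers):
            term = np.ones(X.shape[0])
            for j, e in enumerate(pw):
                if e:
                    term = term * X[:, j] ** e
            g += beta * term
        return g

    def probability(self, X: np.ndarray, *, extrapolate: bool = False) -> np.ndarray:
        """Pr(y=1|x) for each row of X.  Raises outside the domain
        unless ``extrapolate`` is set (diagnostics only)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_covariates:
            raise ValueError(f"expected {self.n_covariates} covariates, got {X.shape[1]}")
        if not extrapolate:
            for j, (lo, hi) in enumerate(self.domain):
                col = X[:, j]
                if col.size and (col.min() < lo - 1e-12 or col.max() > hi + 1e-12):
                    raise ValueError(f"covariate {j} outside domain [{lo}, {hi}]")
        return self.scale * _apply_link(self.link, self.inner(X))

    def with_scale(self, scale: float) -> "RSPFModel":
        return dataclasses.replace(self, scale=scale)

    def to_dict(self) -> dict:
        return {
            "link": self.link,
            "coefficients": list(self.coefficients),
            "powers": [list(p) for p in self.powers],
            "scale": self.scale,
            "domain": [list(b) for b in self.domain],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RSPFModel":
        return cls(
            link=d["link"],
            coefficients=tuple(d["coefficients"]),
            powers=tuple(tuple(p) for p in d["powers"]),
            scale=d.get("scale", 1.0),
            domain=tuple(tuple(b) for b in d["domain"]),
        )


def evaluate_probability(model: RSPFModel, points: np.ndarray, *, extrapolate: bool = False) -> np.ndarray:
    """Vectorised Pr(y=1|x) over the rows of ``points``."""
    return model.probability(points, extrapolate=extrapolate)


def _grid(model: RSPFModel, grid_size: int) -> np.ndarray:
    axes = []
    per_axis = grid_size if model.n_covariates == 1 else min(grid_size, 501)
    for lo, hi in model.domain:
        axes.append(np.linspace(lo, hi, per_axis) if hi > lo else np.array([lo]))
    if model.n_covariates == 1:
        return axes[0][:, None]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([m.ravel() for m in mesh])


def max_probability(model: RSPFModel, grid_size: int = 100_001) -> tuple[np.ndarray, float]:
    """Maximum probability over the domain and the point attaining it.

    Dense grid search refined by bounded local optimisation; domain
    endpoints/corners are always candidates so boundary maxima are
    exact.  Deterministic for fixed ``grid_size``.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    if all(lo == hi for lo, hi in model.domain):
        x = np.array([lo for lo, _ in model.domain])
        return x, float(model.probability(x[None, :])[0])
    pts = _grid(model, grid_size)
    vals = model.probability(pts)
    best = pts[int(np.argmax(vals))]

    if model.n_covariates == 1:
        lo, hi = model.domain[0]
        h = (hi - lo) / (grid_size - 1)
        a, b = max(lo, best[0] - h), min(hi, best[0] + h)
        res = minimize_scalar(
            lambda x: -model.probability(np.array([[x]]))[0],
            bounds=(a, b), method="bounded", options={"xatol": 1e-12},
        )
        cand = [np.array([res.x]), np.array([lo]), np.array([hi]), best]
    else:
        res = minimize(
            lambda x: -model.probability(x[None, :])[0],
            best, method="L-BFGS-B", bounds=list(model.domain),
        )
        corners = _grid(dataclasses.replace(model), 2)
        cand = [res.x, best] + list(corners)
    cand = np.array(cand)
    cv = model.probability(cand)
    i = int(np.argmax(cv))
    return cand[i], float(cv[i])


@dataclass(frozen=True)
class ValidationReport:
    valid: bool
    min_probability: float
    max_probability: float
    n_violations: int
    grid_size: int


def validate_model(model: RSPFModel, grid_size: int = 10_001) -> ValidationReport:
    """Check that k * link(g) stays inside [0, 1] on a dense grid.

    Scaled links can exceed one on part of the domain (the scale is
    then not a valid probability there); this reports rather than
    raises so that candidate models can be screened.
    """
    pts = _grid(model, grid_size)
    vals = model.probability(pts)
    bad = int(np.sum((vals < -1e-12) | (vals > 1 + 1e-12)))
    return ValidationReport(
        valid=bad == 0,
        min_probability=float(vals.min()),
        max_probability=float(vals.max()),
        n_violations=bad,
        grid_size=len(pts),
    )


# --------------------------------------------------------------------------
# Catalogue of simulated species


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    model: RSPFModel
    category: str            # "1", "2", "3" or "hf" / "fig2"
    function_type: str       # linear / quadratic / cubic / gaussian / ...
    argmax: tuple[float, ...]
    true_max: float = field(default=0.0)
    printed_form: str = ""

    def to_dict(self) -> dict:
        d = {"name": self.name, "category": self.category,
             "function_type": self.function_type,
             "argmax": list(self.argmax), "true_max": self.true_max,
             "printed_form": self.printed_form}
        d.update(self.model.to_dict())
        return d


class FunctionCatalog(Mapping):
    """Immutable name -> CatalogEntry mapping of the built-in species."""

    def __init__(self, entries: Sequence[CatalogEntry]):
        self._entries = {e.name: e for e in entries}

    def __getitem__(self, name: str) -> CatalogEntry:
        return self._entries[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def model(self, name: str) -> RSPFModel:
        return self._entries[name].model

    def to_json(self) -> str:
        return json.dumps([e.to_dict() for e in self._entries.values()], indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FunctionCatalog":
        entries = []
        for d in json.loads(text):
            entries.append(CatalogEntry(
                name=d["name"], model=RSPFModel.from_dict(d),
                category=d["category"], function_type=d["function_type"],
                argmax=tuple(d["argmax"]), true_max=d["true_max"],
                printed_form=d.get("printed_form", ""),
            ))
        return cls(entries)


def _entry(name, category, ftype, link, coefs, powers, domain, argmax,
           scale=1.0, printed=""):
    model = RSPFModel(link=link, coefficients=coefs, powers=powers,
                      scale=scale, domain=domain)
    true_max = float(model.probability(np.atleast_2d(argmax))[0])
    return CatalogEntry(name=name, model=model, category=category,
                        function_type=ftype, argmax=tuple(argmax),
                        true_max=true_max, printed_form=printed)


_U1 = ((1,), (2,), (3,))  # univariate power ladder


def catalog() -> FunctionCatalog:
    """The thirteen built-in simulated species.

    Category 1: logistic, maximum essentially 1 (separable presences).
    Category 2: scaled logistic / Gaussian / cubic exponential, maximum
    reaches (essentially) 1 but the family is only identified up to
    scale by the relative likelihood.  Category 3: logistic with
    maximum well below 1.  ``hf_full``/``hf_scaled`` are the
    one-covariate full and half-scaled logistic pair on [-2.5, 2.5];
    ``fig2_full``/``fig2_scaled`` the two-covariate analogue.
    """
    D11 = ((-1.0, 1.0),)
    D01 = ((0.0, 1.0),)
    Dhf = ((-2.5, 2.5),)
    D2 = ((-1.0, 1.0), (-1.0, 1.0))
    # Gaussian 0.99*exp(-(4x-2)^2) rewritten on the exponential link:
    # -(4x-2)^2 = -4 + 16x - 16x^2, the 0.99 multiplier is the scale.
    entries = [
        _entry("cat1_linear", "1", "linear", "logistic",
               (-0.606, 3.64), _U1[:1], D11, (-1.0,),
               printed="1/(1+exp(-0.606+3.64x))"),
        _entry("cat1_quadratic", "1", "quadratic", "logistic",
               (-0.606, 3.64, -1.26), _U1[:2], D11, (-1.0,),
               printed="1/(1+exp(-0.606+3.64x-1.26x^2))"),
        _entry("cat1_cubic", "1", "cubic", "logistic",
               (0.284, 2.298, 0.232, -7.269), _U1, D11, (1.0,),
               printed="1/(1+exp(0.284+2.298x+0.232x^2-7.269x^3))"),
        _entry("cat2_scaled_logistic", "2", "scaled logistic", "logistic",
               (4.0, -2.0), _U1[:1], D01, (1.0,), scale=8.3,
               printed="8.3/(1+exp(4-2x))"),
        _entry("cat2_gaussian", "2", "gaussian", "exponential",
               (-4.0, 16.0, -16.0), _U1[:2], D01, (0.5,), scale=0.99,
               printed="0.99*exp(-(4x-2)^2)"),
        _entry("cat2_exponential", "2", "cubic exponential", "exponential",
               (-0.5, 0.5, -0.9, 0.9), _U1, D01, (1.0,),
               printed="exp(-0.5+0.5x-0.9x^2+0.9x^3)"),
        _entry("cat3_linear", "3", "linear", "logistic",
               (-0.5855, -1.064), _U1[:1], D11, (1.0,),
               printed="1/(1+exp(-0.5855-1.064x))"),
        _entry("cat3_quadratic", "3", "quadratic", "logistic",
               (-0.5855, -1.064, 0.218), _U1[:2], D11, (1.0,),
               printed="1/(1+exp(-0.5855-1.064x+0.218x^2))"),
        _entry("cat3_cubic", "3", "cubic", "logistic",
               (-0.5855, -1.064, 0.218, 1.81), _U1, D11, (-1.0,),
               printed="1/(1+exp(-0.5855-1.064x+0.218x^2+1.81x^3))"),
        _entry("hf_full", "hf", "linear", "logistic",
               (1.0, -1.0), _U1[:1], Dhf, (2.5,),
               printed="1/(1+exp(1-x))"),
        _entry("hf_scaled", "hf", "scaled linear", "logistic",
               (1.0, -1.0), _U1[:1], Dhf, (2.5,), scale=0.5,
               printed="0.5/(1+exp(1-x))"),
        _entry("fig2_full", "fig2", "linear 2-covariate", "logistic",
               (-0.606, 3.64, -1.26), ((1, 0), (0, 1)), D2, (-1.0, 1.0),
               printed="1/(1+exp(-0.606+3.64x1-1.26x2))"),
        _entry("fig2_scaled", "fig2", "scaled linear 2-covariate", "logistic",
               (-0.606, 3.64, -1.26), ((1, 0), (0, 1)), D2, (-1.0, 1.0),
               scale=0.5, printed="0.5/(1+exp(-0.606+3.64x1-1.26x2))"),
    ]
    return FunctionCatalog(entries)
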