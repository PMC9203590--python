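"""Presence-background data simulation.

The sampling scheme is the case-control / use-availability design: a
presence sample P of size n1 drawn from the presence points (each
landscape point x carries presence probability p(x) = Pr(y=1|x)), and
a background sample B of size n0 drawn iid from the landscape with no
presence information.  Covariates are Uniform on the model's domain.

Presences are generated by rejection: draw x uniform on the domain and
r uniform on [0,1]; accept when r <= p(x).  Acceptance depends only on
x, so labelled presences are selected completely at random (SCAR) —
there is no covariate-dependent sampling effort.

For simulated data the latent presence label y of each background site
is retained, along with p2 (the count of true presences hidden in the
background) and the implied labelling frequency c = n1/(n1+p2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.polynomial.legendre import leggauss

from .rspf import RSPFModel

# fixed offsets deriving component sub-seeds from the master seed, so
# presence, background and latent labels are independently reproducible
_PRESENCE_OFFSET = 101
_BACKGROUND_OFFSET = 211
_LABEL_OFFSET = 307
_SEED_MOD = 2**31


@dataclass
class Landscape:
    """A finite sample of landscape covariates."""

    covariates: np.ndarray
    domain: tuple[tuple[float, float], ...]
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] < 1:
            raise ValueError("landscape needs at least one site")
        for j, (lo, hi) in enumerate(self.domain):
            col = self.covariates[:, j]
            if col.min() < lo or col.max() > hi:
                raise ValueError(f"covariate {j} outside bounds")


@dataclass
class PBDataset:
    """Presence covariates P, background covariates B, and (for
    simulated data) the latent truth of the background sample."""

    P: np.ndarray
    B: np.ndarray
    y_latent: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.P = np.atleast_2d(np.asarray(self.P, dtype=float))
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        if self.P.shape[0] < 1 or self.B.shape[0] < 1:
            raise ValueError("need at least one presence and one background row")
        if self.P.shape[1] != self.B.shape[1]:
            raise ValueError("presence/background covariate dimension mismatch")
        if self.y_latent is not None:
            self.y_latent = np.asarray(self.y_latent, dtype=int)
            if self.y_latent.shape[0] != self.B.shape[0]:
                raise ValueError("y_latent must align with background rows")

    @property
    def n1(self) -> int:
        return self.P.shape[0]

    @property
    def n0(self) -> int:
        return self.B.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.P.shape[1]

    @property
    def p2(self) -> Optional[int]:
        """Number of true presences hidden in the background sample."""
        return int(self.y_latent.sum()) if self.y_latent is not None else None

    @property
    def implied_c(self) -> Optional[float]:
        """Labelling frequency c = n1/(n1+p2) (simulation-only)."""
        p2 = self.p2
        return self.n1 / (self.n1 + p2) if p2 is not None else None

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """Stacked covariates (P then B) and the membership flag s."""
        X = np.vstack([self.P, self.B])
        s = np.concatenate([np.ones(self.n1, dtype=int), np.zeros(self.n0, dtype=int)])
        return X, s


def _check_bounds(domain) -> None:
    for lo, hi in domain:
        if not (lo < hi):
            raise ValueError(f"invalid bounds [{lo}, {hi}]")


def draw_background(n0: int, domain, seed: int) -> np.ndarray:
    """n0 iid uniform draws from the landscape."""
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    _check_bounds(domain)
    rng = np.random.default_rng(seed)
    lo = np.array([a for a, _ in domain])
    hi = np.array([b for _, b in domain])
    return lo + (hi - lo) * rng.random((n0, len(domain)))


def draw_presence(n1: int, model: RSPFModel, seed: int) -> np.ndarray:
    """n1 draws from x | y=1 by rejection sampling against p(x)."""
    if n1 < 1:
        raise ValueError("n1 must be >= 1")
    _check_bounds(model.domain)
    rng = np.random.default_rng(seed)
    lo = np.array([a for a, _ in model.domain])
    hi = np.array([b for _, b in model.domain])
    d = model.n_covariates

    # pilot acceptance estimate guards against (near-)zero functions
    pilot = lo + (hi - lo) * rng.random((2048, d))
    mean_p = float(model.probability(pilot).mean())
    if mean_p < 1e-6:
        raise RuntimeError(
            f"rejection sampling infeasible: mean probability {mean_p:.2e} "
            "over a pilot sample is below 1e-6"
        )

    out = np.empty((n1, d))
    filled = 0
    batch = max(1024, int(1.5 * n1 / mean_p))
    while filled < n1:
        x = lo + (hi - lo) * rng.random((batch, d))
        r = rng.random(batch)
        acc = x[r <= model.probability(x)]
        take = min(n1 - filled, acc.shape[0])
        out[filled:filled + take] = acc[:take]
        filled += take
    return out


def simulate_pb(model: RSPFModel, n1: int = 5000, n0: int = 50_000,
                seed: int = 0, model_id: str = "") -> PBDataset:
    """Simulate one presence-background dataset with latent truth."""
    s_p = (seed + _PRESENCE_OFFSET) % _SEED_MOD
    s_b = (seed + _BACKGROUND_OFFSET) % _SEED_MOD
    s_y = (seed + _LABEL_OFFSET) % _SEED_MOD
    P = draw_presence(n1, model, s_p)
    B = draw_background(n0, model.domain, s_b)
    rng = np.random.default_rng(s_y)
    y = (rng.random(n0) <= model.probability(B)).astype(int)
    ds = PBDataset(P=P, B=B, y_latent=y,
                   provenance={"model_id": model_id, "seed": seed,
                               "presence_seed": s_p, "background_seed": s_b,
                               "label_seed": s_y})
    ds.provenance["implied_c"] = ds.implied_c
    return ds


def true_prevalence(model: RSPFModel, n_nodes: int = 256) -> float:
    """Population prevalence pi = E[p(x)] under uniform covariates.

    Tensor Gauss-Legendre quadrature over the domain; the catalogue
    functions are smooth, so a few hundred nodes per axis give well
    below 1e-6 error.
    """
    x, w = leggauss(n_nodes)
    axes, weights = [], []
    for lo, hi in model.domain:
        axes.append(lo + (hi - lo) * (x + 1) / 2)
        weights.append(w / 2)  # normalised: uniform density on [lo, hi]
    if model.n_covariates == 1:
        pts = axes[0][:, None]
        return float(np.sum(weights[0] * model.probability(pts)))
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    wmesh = np.meshgrid(*weights, indexing="ij")
    wt = np.prod(np.column_stack([wm.ravel() for wm in wmesh]), axis=1)
    return float(np.sum(wt * model.probability(pts)))
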