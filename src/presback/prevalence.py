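"""Labelling-frequency and prevalence estimation from membership scores.

Under case-control sampling with labelling frequency c = p1/(p1+p2)
(p1 labelled presences, p2 true presences hidden among the n0
background rows), the membership probability at a site where presence
is certain equals c.  Ranking the predicted Pr(s=1|x) over all pooled
rows and reading off the top share therefore estimates c — the
local-certainty (LC) / prototypical-presence-location route.  When the
probability of presence at the top sites is known to be some q <= 1
rather than exactly 1 (the local-knowledge condition, LKN), the
prevalence estimate scales linearly by q:

    pi_hat = q * (p1/n0) * (1 - c_hat) / c_hat .

With q=1 and c_hat equal to the exact labelling frequency this reduces
to the identity pi_hat = p2/n0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .classify import SMembershipScores

AGGREGATORS = ("mean", "max", "ratio")
_EPS = 1e-12


@dataclass(frozen=True)
class LocalKnowledge:
    """What is known about the top-ranked sites.

    q : probability of presence at the selected sites; q=1 encodes
        local certainty (PPL).
    percentile : top share of pooled scores used (default 10).
    aggregator : how the c estimate summarises the top scores.
    """

    q: float = 1.0
    percentile: float = 10.0
    aggregator: str = "mean"

    def __post_init__(self) -> None:
        if not (0 < self.q <= 1):
            raise ValueError("q must lie in (0, 1]")
        if not (0 < self.percentile <= 100):
            raise ValueError("percentile must lie in (0, 100]")
        if self.aggregator not in AGGREGATORS:
            raise ValueError(f"aggregator must be one of {AGGREGATORS}")


@dataclass
class PrevalenceEstimate:
    c_hat: float
    pi_hat: float
    n_top: int
    q: float
    percentile: float
    aggregator: str
    capped: bool = False
    suspicious: bool = False
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("c_hat", "pi_hat", "n_top", "q", "percentile",
                 "aggregator", "capped", "suspicious", "provenance")}


def select_top_sites(scores: SMembershipScores | np.ndarray,
                     percentile: float = 10.0) -> np.ndarray:
    """Indices of the top ``percentile`` percent of pooled scores.

    k = ceil(percentile/100 * n); ties broken by descending score then
    ascending index (stable).
    """
    vec = scores.scores if isinstance(scores, SMembershipScores) else np.asarray(scores, float)
    if vec.size == 0:
        raise ValueError("empty score vector")
    if not (0 < percentile <= 100):
        raise ValueError("percentile must lie in (0, 100]")
    k = math.ceil(percentile / 100.0 * vec.size)
    order = np.argsort(-vec, kind="stable")
    return order[:k]


def estimate_c(scores: SMembershipScores, top: np.ndarray,
               aggregator: str = "mean", clip_eps: float = 1e-6) -> float:
    """Labelling-frequency estimate from the scores on the top set."""
    if len(top) == 0:
        raise ValueError("empty top set")
    if aggregator not in AGGREGATORS:
        raise ValueError(f"aggregator must be one of {AGGREGATORS}")
    vals = scores.scores[np.asarray(top, dtype=int)]
    if aggregator == "mean":
        c = float(vals.mean())
    elif aggregator == "max":
        c = float(vals.max())
    else:  # ratio of the top-set sum to the background-row sum
        denom = float(scores.background_scores.sum())
        if denom <= _EPS:
            raise ZeroDivisionError("background score sum is zero")
        c = float(vals.sum() / denom)
    return float(np.clip(c, clip_eps, 1.0 - clip_eps))


def estimate_prevalence(c_hat: float, p1: int, n0: int, q: float = 1.0,
                        **meta) -> PrevalenceEstimate:
    """Prevalence from the labelling frequency under local knowledge q.

    pi_hat = q * (p1/n0) * (1-c_hat)/c_hat; values above 1 are capped
    at 1 and flagged (downstream constrained fitting needs pi in (0,1)).
    """
    if not (0 < c_hat < 1):
        raise ValueError("c_hat must lie strictly inside (0, 1)")
    if p1 < 1 or n0 < 1:
        raise ValueError("p1 and n0 must be >= 1")
    if not (0 < q <= 1):
        raise ValueError("q must lie in (0, 1]")
    raw = q * (p1 / n0) * (1.0 - c_hat) / c_hat
    capped = raw > 1.0
    return PrevalenceEstimate(
        c_hat=float(c_hat), pi_hat=float(min(raw, 1.0)),
        n_top=int(meta.pop("n_top", 0)), q=float(q),
        percentile=float(meta.pop("percentile", float("nan"))),
        aggregator=str(meta.pop("aggregator", "")),
        capped=bool(capped), suspicious=bool(capped),
        provenance=meta.pop("provenance", {}),
    )


def estimate_prevalence_from_scores(scores: SMembershipScores,
                                    lkn: Optional[LocalKnowledge] = None,
                                    clip_eps: float = 1e-6) -> PrevalenceEstimate:
    """Full chain: rank pooled scores, estimate c, convert to pi_hat."""
    lkn = lkn or LocalKnowledge()
    top = select_top_sites(scores, lkn.percentile)
    c_hat = estimate_c(scores, top, lkn.aggregator, clip_eps)
    return estimate_prevalence(
        c_hat, scores.n1, scores.n0, lkn.q,
        n_top=len(top), percentile=lkn.percentile, aggregator=lkn.aggregator,
    )
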