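"""Estimating the observation-stratum probability Pr(s=1|x).

Pooling the presence rows (s=1) with the background rows (s=0) turns
the presence-background problem into ordinary binary classification of
the *membership* flag s.  Under case-control sampling the membership
probability relates to the presence probability p(x) = Pr(y=1|x)
through the labelling frequency c:

    Pr(s=1|x) = c p(x) / (c p(x) + 1 - c),

which is strictly increasing in p(x).  A classifier trained on the
pooled data with a proper log loss and *no* class rebalancing
therefore estimates a quantity whose top-ranked sites are the sites of
highest presence probability — the basis of the prevalence estimator.

Rebalancing (class weights, over/undersampling) would destroy the
calibration to the actual n1:n0 design and is deliberately not
offered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .rspf import RSPFModel
from .simulate import PBDataset

DEFAULT_CLIP = 1e-6


@dataclass
class ClassifierConfig:
    """Configuration of the membership classifier.

    kind: "neural_net" (single hidden layer, the default), a
    "logistic_main_effects" baseline, or "oracle" (requires the true
    model and c; testing only).
    """

    kind: str = "neural_net"
    hidden_units: int = 8
    alpha: float = 1e-2          # L2 weight decay
    max_iter: int = 500
    clip_eps: float = DEFAULT_CLIP
    seed: int = 0
    oracle_model: Optional[RSPFModel] = None
    oracle_c: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 < self.clip_eps <= 0.01):
            raise ValueError("clip_eps must lie in (0, 0.01]")
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")


@dataclass
class SMembershipScores:
    """Predicted Pr(s=1|x) aligned to the pooled rows, P first then B."""

    scores: np.ndarray
    n1: int
    n0: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape[0] != self.n1 + self.n0:
            raise ValueError("scores must have length n1 + n0")

    @property
    def background_scores(self) -> np.ndarray:
        return self.scores[self.n1:]


def oracle_scores(model: RSPFModel, c: float, points: np.ndarray,
                  clip_eps: float = DEFAULT_CLIP) -> np.ndarray:
    """Exact Pr(s=1|x) from the true model and labelling frequency c.

    Computed as c*p/(c*p + 1 - c), the algebraically stable form of
    1/(1 + ((1-c)/c)/p); p(x)=0 maps to 0 before clipping.
    """
    if not (0 < c < 1):
        raise ValueError("c must lie in (0, 1)")
    p = model.probability(np.atleast_2d(points), extrapolate=True)
    s = c * p / (c * p + (1.0 - c))
    return np.clip(s, clip_eps, 1.0 - clip_eps)


class SMembershipClassifier(BaseEstimator):
    """Scikit-learn style estimator of the membership probability.

    ``fit(X, s)`` trains on pooled covariates with the binary
    membership flag; ``predict_s(X)`` returns clipped Pr(s=1|x).
    Covariates are standardised internally; the estimator never
    rebalances classes.

    Parameters
    ----------
    kind : {"neural_net", "logistic_main_effects", "oracle"}
    hidden_units : int, hidden layer width of the neural net.
    alpha : float, L2 weight decay.
    max_iter : int, optimiser iteration cap.
    clip_eps : float, scores are clipped into [eps, 1-eps].
    random_state : int, seeds weight initialisation.
    oracle_model, oracle_c : the true RSPF and labelling frequency,
        used only by the oracle kind.
    """

    def __init__(self, kind: str = "neural_net", hidden_units: int = 8,
                 alpha: float = 1e-2, max_iter: int = 500,
                 clip_eps: float = DEFAULT_CLIP, random_state: int = 0,
                 oracle_model: Optional[RSPFModel] = None,
                 oracle_c: Optional[float] = None):
        self.kind = kind
        self.hidden_units = hidden_units
        self.alpha = alpha
        self.max_iter = max_iter
        self.clip_eps = clip_eps
        self.random_state = random_state
        self.oracle_model = oracle_model
        self.oracle_c = oracle_c

    def fit(self, X: np.ndarray, s: np.ndarray) -> "SMembershipClassifier":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        s = np.asarray(s, dtype=int)
        if not (0 < self.clip_eps <= 0.01):
            raise ValueError("clip_eps must lie in (0, 0.01]")
        if self.kind == "oracle":
            if self.oracle_model is None or self.oracle_c is None:
                raise ValueError("oracle kind requires oracle_model and oracle_c")
            self.n_features_in_ = X.shape[1]
            self._inner = None
            return self
        if np.sum(s == 1) < 10 or np.sum(s == 0) < 10:
            raise ValueError("need at least 10 presence and 10 background rows")
        self.scaler_ = StandardScaler().fit(X)
        Z = self.scaler_.transform(X)
        if self.kind == "neural_net":
            inner = None
            for attempt in range(3):
                cand = MLPClassifier(
                    hidden_layer_sizes=(self.hidden_units,),
                    alpha=self.alpha, max_iter=self.max_iter,
                    solver="lbfgs", activation="logistic",
                    random_state=self.random_state + attempt,
                )
                cand.fit(Z, s)
                if np.isfinite(cand.loss_):
                    inner = cand
                    break
            if inner is None:
                raise RuntimeError("neural-net training diverged on every attempt")
        elif self.kind == "logistic_main_effects":
            inner = LogisticRegression(penalty=None, max_iter=self.max_iter)
            inner.fit(Z, s)
        else:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        self._inner = inner
        self.n_features_in_ = X.shape[1]
        return self

    def predict_s(self, X: np.ndarray) -> np.ndarray:
        """Clipped Pr(s=1|x) for each row of X."""
        check_is_fitted(self, "n_features_in_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 0:
            return np.empty(0)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("covariate dimension mismatch with training data")
        if self.kind == "oracle":
            return oracle_scores(self.oracle_model, self.oracle_c, X, self.clip_eps)
        proba = self._inner.predict_proba(self.scaler_.transform(X))[:, 1]
        return np.clip(proba, self.clip_eps, 1.0 - self.clip_eps)

    # JSON round trip (neural net / logistic only) -----------------------
    def to_json(self) -> str:
        check_is_fitted(self, "n_features_in_")
        if self.kind == "oracle":
            raise ValueError("oracle scorer is not serialisable")
        doc = {"kind": self.kind, "clip_eps": self.clip_eps,
               "n_features": self.n_features_in_,
               "scaler_mean": self.scaler_.mean_.tolist(),
               "scaler_scale": self.scaler_.scale_.tolist()}
        if self.kind == "neural_net":
            doc["coefs"] = [c.tolist() for c in self._inner.coefs_]
            doc["intercepts"] = [b.tolist() for b in self._inner.intercepts_]
        else:
            doc["coef"] = self._inner.coef_.tolist()
            doc["intercept"] = self._inner.intercept_.tolist()
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "SMembershipClassifier":
        doc = json.loads(text)
        est = cls(kind=doc["kind"], clip_eps=doc["clip_eps"])
        est.n_features_in_ = doc["n_features"]
        est.scaler_ = StandardScaler()
        est.scaler_.mean_ = np.array(doc["scaler_mean"])
        est.scaler_.scale_ = np.array(doc["scaler_scale"])
        est.scaler_.var_ = est.scaler_.scale_ ** 2
        est.scaler_.n_features_in_ = doc["n_features"]
        if doc["kind"] == "neural_net":
            inner = MLPClassifier(hidden_layer_sizes=(len(doc["intercepts"][0]),),
                                  activation="logistic")
            inner.coefs_ = [np.array(c) for c in doc["coefs"]]
            inner.intercepts_ = [np.array(b) for b in doc["intercepts"]]
            inner.n_layers_ = len(inner.coefs_) + 1
            inner.n_outputs_ = 1
            inner.out_activation_ = "logistic"
            inner.classes_ = np.array([0, 1])
            inner._label_binarizer = None
            est._inner = _RawMLPScorer(inner)
        else:
            inner = LogisticRegression()
            inner.coef_ = np.array(doc["coef"])
            inner.intercept_ = np.array(doc["intercept"])
            inner.classes_ = np.array([0, 1])
            est._inner = inner
        return est


class _RawMLPScorer:
    """Forward pass through restored MLP weights (logistic activations)."""

    def __init__(self, mlp: MLPClassifier):
        self._mlp = mlp

    def predict_proba(self, Z: np.ndarray) -> np.ndarray:
        a = Z
        n = len(self._mlp.coefs_)
        for i, (W, b) in enumerate(zip(self._mlp.coefs_, self._mlp.intercepts_)):
            a = a @ W + b
            a = 1.0 / (1.0 + np.exp(-a))  # logistic hidden and output
        p1 = a.ravel()
        return np.column_stack([1 - p1, p1])


# Thin functional surface over the estimator ----------------------------

def fit_s_classifier(data: PBDataset, config: ClassifierConfig) -> SMembershipClassifier:
    """Train the membership classifier on the pooled P and B rows."""
    X, s = data.pooled()
    est = SMembershipClassifier(
        kind=config.kind, hidden_units=config.hidden_units,
        alpha=config.alpha, max_iter=config.max_iter,
        clip_eps=config.clip_eps, random_state=config.seed,
        oracle_model=config.oracle_model, oracle_c=config.oracle_c,
    )
    return est.fit(X, s)


def score(scorer: SMembershipClassifier, points: np.ndarray) -> np.ndarray:
    """Clipped Pr(s=1|x) over the rows of ``points``."""
    return scorer.predict_s(points)


def score_pb(scorer: SMembershipClassifier, data: PBDataset) -> SMembershipScores:
    """Score the pooled dataset, keeping the P-then-B alignment."""
    X, _ = data.pooled()
    return SMembershipScores(scores=scorer.predict_s(X), n1=data.n1, n0=data.n0)
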