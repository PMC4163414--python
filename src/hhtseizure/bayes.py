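"""Bayesian-network classification of discretized feature vectors.

The network B over X = {X_1..X_n, C} factorizes the joint distribution as
P_B(X, C) = P(C) * prod_i P(X_i | par(X_i)), and classification returns
the class c maximizing the posterior P_B(c | x_1..x_n).  Attributes are
discretized with the same supervised MDL procedure the feature-selection
stage uses (cuts learned on training data only); conditional probability
tables are estimated from counts with additive smoothing alpha = 0.5.

Two structures are available: "naive" (every attribute's only parent is
the class — the robust default) and "k2-1parent", a K2-style greedy search
that may give each attribute one extra attribute parent, in attribute
order, when the Bayesian (BDeu-like) score improves.  Class imbalance is
handled by honest priors; no resampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cfs import apply_cuts, mdl_discretize

__all__ = ["BayesNetModel", "fit", "predict_proba"]

POSITIVE_CLASS = "preictal"


@dataclass
class BayesNetModel:
    """Fitted discrete Bayesian-network classifier.

    cpts[i] has shape (n_parent_states, n_bins_i, n_classes): the
    distribution of attribute i's bin given its extra parent's bin (axis 0
    is singleton for class-only parents) and the class.  Every
    (parent, class) row sums to 1.
    """

    classes: list[str]
    log_prior: np.ndarray
    cuts: list[list[float]]
    parent: list[int | None]  # extra (non-class) parent index per attribute
    cpts: list[np.ndarray]
    attr_names: list[str] = field(default_factory=list)

    @property
    def n_attrs(self) -> int:
        return len(self.cuts)

    def to_json(self) -> str:
        return json.dumps(
            {
                "classes": self.classes,
                "log_prior": self.log_prior.tolist(),
                "cuts": self.cuts,
                "parent": self.parent,
                "cpts": [c.tolist() for c in self.cpts],
                "attr_names": self.attr_names,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "BayesNetModel":
        d = json.loads(s)
        return cls(
            classes=d["classes"],
            log_prior=np.asarray(d["log_prior"]),
            cuts=[list(c) for c in d["cuts"]],
            parent=[p if p is None else int(p) for p in d["parent"]],
            cpts=[np.asarray(c) for c in d["cpts"]],
            attr_names=d["attr_names"],
        )


def _cpt_class_only(xb: np.ndarray, yi: np.ndarray, n_bins: int, n_classes: int,
                    alpha: float) -> np.ndarray:
    counts = np.zeros((1, n_bins, n_classes))
    np.add.at(counts, (0, xb, yi), 1.0)
    counts += alpha
    return counts / counts.sum(axis=1, keepdims=True)


def _cpt_with_parent(xb: np.ndarray, pb: np.ndarray, yi: np.ndarray,
                     n_bins: int, n_parent: int, n_classes: int,
                     alpha: float) -> np.ndarray:
    counts = np.zeros((n_parent, n_bins, n_classes))
    np.add.at(counts, (pb, xb, yi), 1.0)
    counts += alpha
    return counts / counts.sum(axis=1, keepdims=True)


def _log_score(xb, pb, yi, n_bins, n_parent, n_classes, alpha) -> float:
    """Smoothed log-likelihood of attribute xb given (parent, class)."""
    counts = np.zeros((n_parent, n_bins, n_classes))
    np.add.at(counts, (pb, xb, yi), 1.0)
    sm = counts + alpha
    probs = sm / sm.sum(axis=1, keepdims=True)
    # penalize free parameters (BIC-style) so extra parents must earn keep
    n = len(xb)
    k = n_parent * (n_bins - 1) * n_classes
    return float((counts * np.log(probs)).sum() - 0.5 * k * np.log(max(n, 2)))


def fit(
    feature_matrix: np.ndarray,
    labels,
    structure: str = "naive",
    alpha: float = 0.5,
    attr_names: list[str] | None = None,
) -> BayesNetModel:
    """Fit the classifier on (already selected) continuous features.

    Discretization cuts, priors and CPTs are all estimated from this
    training data only.  Raises ValueError on a single-class training set.
    """
    X = np.atleast_2d(np.asarray(feature_matrix, dtype=np.float64))
    y = np.asarray(labels)
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("training set must contain both classes")
    if structure not in ("naive", "k2-1parent"):
        raise ValueError(f"unknown structure {structure!r}")
    yi = np.searchsorted(classes, y)
    n, p = X.shape
    n_classes = len(classes)
    if attr_names is None:
        attr_names = [f"x{i}" for i in range(p)]

    prior = np.bincount(yi, minlength=n_classes).astype(float) + alpha
    log_prior = np.log(prior / prior.sum())

    cuts = [mdl_discretize(X[:, i], y) for i in range(p)]
    binned = [apply_cuts(X[:, i], cuts[i]) for i in range(p)]
    n_bins = [len(c) + 1 for c in cuts]

    parent: list[int | None] = [None] * p
    cpts: list[np.ndarray] = []
    for i in range(p):
        if structure == "k2-1parent" and i > 0:
            base = _log_score(binned[i], np.zeros(n, dtype=int), yi,
                              n_bins[i], 1, n_classes, alpha)
            best_j, best_s = None, base
            for j in range(i):
                s = _log_score(binned[i], binned[j], yi,
                               n_bins[i], n_bins[j], n_classes, alpha)
                if s > best_s + 1e-12:
                    best_j, best_s = j, s
            parent[i] = best_j
        if parent[i] is None:
            cpts.append(
                _cpt_class_only(binned[i], yi, n_bins[i], n_classes, alpha)
            )
        else:
            j = parent[i]
            cpts.append(
                _cpt_with_parent(binned[i], binned[j], yi,
                                 n_bins[i], n_bins[j], n_classes, alpha)
            )
    return BayesNetModel(
        classes=classes,
        log_prior=log_prior,
        cuts=cuts,
        parent=parent,
        cpts=cpts,
        attr_names=attr_names,
    )


def _log_posterior(model: BayesNetModel, X: np.ndarray) -> np.ndarray:
    n, p = X.shape
    if p != model.n_attrs:
        raise ValueError(
            f"feature vector covers {p} attributes, model has {model.n_attrs}"
        )
    binned = [apply_cuts(X[:, i], model.cuts[i]) for i in range(p)]
    logp = np.tile(model.log_prior, (n, 1))
    for i in range(p):
        par = model.parent[i]
        pb = binned[par] if par is not None else np.zeros(n, dtype=int)
        logp += np.log(model.cpts[i][pb, binned[i], :])
    return logp


def predict_proba(model: BayesNetModel, feature_vectors: np.ndarray) -> np.ndarray:
    """Posterior probability of the preictal class for each row.

    Accepts a single vector or a matrix; returns a scalar-per-row array of
    normalized posteriors P(preictal | x).  Values binned outside the
    training range fall in the boundary bins, whose smoothed CPT entries
    are never zero.
    """
    X = np.atleast_2d(np.asarray(feature_vectors, dtype=np.float64))
    logp = _log_posterior(model, X)
    logp -= logp.max(axis=1, keepdims=True)
    post = np.exp(logp)
    post /= post.sum(axis=1, keepdims=True)
    pos = model.classes.index(POSITIVE_CLASS) if POSITIVE_CLASS in model.classes \
        else len(model.classes) - 1
    return post[:, pos]


def predict(model: BayesNetModel, feature_vectors: np.ndarray) -> list[str]:
    """MAP class label per row."""
    X = np.atleast_2d(np.asarray(feature_vectors, dtype=np.float64))
    logp = _log_posterior(model, X)
    return [model.classes[i] for i in np.argmax(logp, axis=1)]
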