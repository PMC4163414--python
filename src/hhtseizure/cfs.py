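"""Correlation-based feature selection (CFS) with best-first search.

CFS scores a feature subset S by the merit

    merit(S) = k * r_cf / sqrt(k + k (k-1) * r_ff),

where k = |S|, r_cf is the mean feature-class correlation and r_ff the
mean feature-feature correlation over S.  A good subset is strongly
correlated with the class but internally redundant-free.  Correlation is
measured by symmetrical uncertainty SU = 2 I(a;b) / (H(a) + H(b)) on
features discretized by the entropy-minimizing MDL procedure (recursive
binary cuts accepted under the minimum-description-length criterion).

The subset space is explored by forward best-first search from the empty
set, expanding the best unexpanded subset by single-feature additions and
stopping after five consecutive expansions that fail to improve the best
merit seen.  Ties in merit break toward the lower feature index, so
selection is deterministic and seed-free.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SelectionResult",
    "mdl_discretize",
    "apply_cuts",
    "symmetrical_uncertainty",
    "merit",
    "best_first_select",
]


@dataclass
class SelectionResult:
    selected: list[str]
    selected_idx: list[int]
    merit: float
    search_trace: list[tuple[tuple[int, ...], float]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "selected": self.selected,
                "merit": self.merit,
                "trace_length": len(self.search_trace),
            }
        )


# ---------------------------------------------------------------------------
# supervised MDL discretization (entropy minimization with the MDL stop rule)


def _entropy_counts(counts: np.ndarray) -> float:
    tot = counts.sum()
    if tot == 0:
        return 0.0
    p = counts[counts > 0] / tot
    return float(-(p * np.log2(p)).sum())


def _class_counts(y: np.ndarray, n_classes: int) -> np.ndarray:
    return np.bincount(y, minlength=n_classes).astype(float)


def _best_cut(x: np.ndarray, y: np.ndarray, n_classes: int):
    """Best boundary cut of sorted (x, y) by class-entropy minimization.

    Returns (cut_value, left_count, gain stats) or None if no valid cut.
    Candidate cuts are midpoints between adjacent distinct x values
    (boundary points suffice for entropy minimization, but scanning all
    adjacent distinct pairs is simple and correct).
    """
    n = len(x)
    total_counts = _class_counts(y, n_classes)
    ent_all = _entropy_counts(total_counts)
    left = np.zeros(n_classes)
    best = None
    best_ent = np.inf
    for i in range(n - 1):
        left[y[i]] += 1
        if x[i + 1] == x[i]:
            continue
        right = total_counts - left
        nl, nr = i + 1, n - i - 1
        ent = (nl * _entropy_counts(left) + nr * _entropy_counts(right)) / n
        if ent < best_ent - 1e-15:
            best_ent = ent
            best = (
                0.5 * (x[i] + x[i + 1]),
                i + 1,
                ent,
                _entropy_counts(left),
                _entropy_counts(right),
                int((left > 0).sum()),
                int((right > 0).sum()),
            )
    if best is None:
        return None
    return best, ent_all


def _mdl_accept(n, ent_all, ent_split, ent_l, ent_r, k, kl, kr) -> bool:
    gain = ent_all - ent_split
    delta = np.log2(3.0**k - 2.0) - (k * ent_all - kl * ent_l - kr * ent_r)
    return gain > (np.log2(n - 1) + delta) / n


def _mdl_recurse(x: np.ndarray, y: np.ndarray, n_classes: int, cuts: list[float]):
    n = len(x)
    if n < 2:
        return
    res = _best_cut(x, y, n_classes)
    if res is None:
        return
    (cut, nl, ent_split, ent_l, ent_r, kl, kr), ent_all = res
    k = int(len(np.unique(y)))
    if not _mdl_accept(n, ent_all, ent_split, ent_l, ent_r, k, kl, kr):
        return
    cuts.append(cut)
    _mdl_recurse(x[:nl], y[:nl], n_classes, cuts)
    _mdl_recurse(x[nl:], y[nl:], n_classes, cuts)


def mdl_discretize(feature_column: np.ndarray, labels: np.ndarray) -> list[float]:
    """Entropy/MDL cut points for one continuous feature.

    Returns the sorted list of accepted cut values; an empty list means the
    feature collapses to a single bin and is uninformative for the class.
    Raises ValueError when only one class is present.
    """
    x = np.asarray(feature_column, dtype=np.float64)
    y = np.asarray(labels)
    classes, y_enc = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 class labels to discretize")
    order = np.argsort(x, kind="stable")
    cuts: list[float] = []
    _mdl_recurse(x[order], y_enc[order], len(classes), cuts)
    return sorted(cuts)


def apply_cuts(x: np.ndarray, cuts: list[float]) -> np.ndarray:
    """Map continuous values to bin indices 0..len(cuts) (half-open bins)."""
    return np.searchsorted(np.asarray(cuts, dtype=float), np.asarray(x), side="right")


# ---------------------------------------------------------------------------
# symmetrical uncertainty and the CFS merit


def symmetrical_uncertainty(a: np.ndarray, b: np.ndarray) -> float:
    """SU(a, b) = 2 I(a;b) / (H(a) + H(b)) on discrete series; in [0, 1].

    Defined as 0 when both series are constant (H(a) + H(b) = 0).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    na, nb = ai.max() + 1, bi.max() + 1
    joint = np.zeros((na, nb))
    np.add.at(joint, (ai, bi), 1.0)
    ha = _entropy_counts(joint.sum(axis=1))
    hb = _entropy_counts(joint.sum(axis=0))
    hab = _entropy_counts(joint.ravel())
    if ha + hb == 0.0:
        return 0.0
    mi = ha + hb - hab
    return float(max(0.0, min(1.0, 2.0 * mi / (ha + hb))))


def merit(
    subset,
    feature_class_su: np.ndarray,
    feature_feature_su,
) -> float:
    """CFS merit of a subset given precomputed SU tables.

    feature_class_su: vector of SU(f, class); feature_feature_su: callable
    (i, j) -> SU(f_i, f_j) or a full symmetric matrix.  Empty subset has
    merit 0 by convention.
    """
    idx = list(subset)
    k = len(idx)
    if k == 0:
        return 0.0
    r_cf = float(np.mean([feature_class_su[i] for i in idx]))
    if k == 1:
        return r_cf
    if callable(feature_feature_su):
        ff = [
            feature_feature_su(idx[i], idx[j])
            for i in range(k)
            for j in range(i + 1, k)
        ]
    else:
        ff = [
            feature_feature_su[idx[i], idx[j]]
            for i in range(k)
            for j in range(i + 1, k)
        ]
    r_ff = float(np.mean(ff))
    denom = np.sqrt(k + k * (k - 1) * r_ff)
    return float(k * r_cf / denom) if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# best-first search


def best_first_select(
    feature_matrix: np.ndarray,
    labels: np.ndarray,
    feature_names: list[str] | None = None,
    patience: int = 5,
    precomputed_cuts: list[list[float]] | None = None,
) -> SelectionResult:
    """Forward best-first CFS over the columns of feature_matrix.

    Features are MDL-discretized against the labels (a feature with no
    accepted cut gets SU(f, class) = 0).  Search starts from the empty set;
    the open list is a max-heap on merit with ties broken toward the
    lexicographically smaller index tuple.  Stops after ``patience``
    consecutive expansions that do not improve the best merit seen and
    returns the best subset.  All-uninformative input yields an empty
    selection.
    """
    X = np.asarray(feature_matrix, dtype=np.float64)
    y = np.asarray(labels)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(p)]
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for selection")

    if precomputed_cuts is None:
        precomputed_cuts = [mdl_discretize(X[:, i], y) for i in range(p)]
    disc = [apply_cuts(X[:, i], precomputed_cuts[i]) for i in range(p)]
    su_cf = np.array(
        [
            symmetrical_uncertainty(disc[i], y) if precomputed_cuts[i] else 0.0
            for i in range(p)
        ]
    )

    ff_cache: dict[tuple[int, int], float] = {}

    def su_ff(i: int, j: int) -> float:
        key = (i, j) if i < j else (j, i)
        if key not in ff_cache:
            ff_cache[key] = symmetrical_uncertainty(disc[key[0]], disc[key[1]])
        return ff_cache[key]

    trace: list[tuple[tuple[int, ...], float]] = []
    best_subset: tuple[int, ...] = ()
    best_merit = 0.0
    # heap entries: (-merit, subset) — tuple comparison breaks merit ties
    # toward the lexicographically smaller subset, i.e. lower indices first
    open_heap: list[tuple[float, tuple[int, ...]]] = [(0.0, ())]
    closed: set[tuple[int, ...]] = set()
    stall = 0

    while open_heap and stall < patience:
        neg_m, subset = heapq.heappop(open_heap)
        if subset in closed:
            continue
        closed.add(subset)
        improved = False
        for f in range(p):
            if f in subset:
                continue
            child = tuple(sorted(subset + (f,)))
            if child in closed:
                continue
            m = merit(child, su_cf, su_ff)
            trace.append((child, m))
            heapq.heappush(open_heap, (-m, child))
            if m > best_merit + 1e-12:
                best_merit = m
                best_subset = child
                improved = True
        stall = 0 if improved else stall + 1

    sel = list(best_subset)
    return SelectionResult(
        selected=[feature_names[i] for i in sel],
        selected_idx=sel,
        merit=best_merit,
        search_trace=trace,
    )
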