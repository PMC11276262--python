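"""Independent brute-force oracles used to freeze expected values in tests.

These deliberately avoid the library code paths they check: levels come from
exhaustive enumeration of all upward paths, AUC from exhaustive pair
ordering, and the SVM reference from a direct QP solve of the dual.
"""

from __future__ import annotations

import numpy as np

from ppilearn.ontology import OntologyGraph, OntologyTerm


def random_dag_graph(rng: np.random.Generator, n_terms: int, max_parents: int = 2) -> OntologyGraph:
    """Random single-root DAG: term i draws 1..max_parents parents among 0..i-1."""
    terms = {"T000": OntologyTerm(id="T000", namespace="biological_process")}
    for i in range(1, n_terms):
        tid = f"T{i:03d}"
        k = int(rng.integers(1, min(max_parents, i) + 1))
        parents = rng.choice(i, size=k, replace=False)
        relations = ("is_a", "part_of", "regulates")
        terms[tid] = OntologyTerm(
            id=tid,
            namespace="biological_process",
            parents={(f"T{p:03d}", relations[int(rng.integers(3))]) for p in parents},
        )
    return OntologyGraph(terms)


def _upward_paths(graph: OntologyGraph, tid: str):
    """Yield every path (as list of ids, term first) from tid up to a root."""
    term = graph.terms[tid]
    if not term.parents:
        yield [tid]
        return
    for pid, _rel in sorted(term.parents):
        for sub in _upward_paths(graph, pid):
            yield [tid] + sub


def bf_level(graph: OntologyGraph, tid: str) -> int:
    """Level by exhaustive enumeration of all upward paths (root = level 1)."""
    return min(len(path) for path in _upward_paths(graph, tid))


def bf_ancestors_or_self(graph: OntologyGraph, tid: str) -> set[str]:
    out: set[str] = set()
    for path in _upward_paths(graph, tid):
        out.update(path)
    return out


def bf_ancestors_at_level(graph: OntologyGraph, tid: str, L: int, shallow: str = "keep") -> set[str]:
    """Mirror of the backtracking contract, driven entirely by path enumeration."""
    if bf_level(graph, tid) < L:
        return {tid} if shallow == "keep" else set()
    return {a for a in bf_ancestors_or_self(graph, tid) if bf_level(graph, a) == L}


def bf_auc(labels, scores) -> float:
    """Fraction of (positive, negative) score pairs ordered correctly; ties 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def svm_dual_qp(X, y_signed, C: float, gamma: float):
    """Exact soft-margin RBF dual solved with SLSQP; returns decision values.

    Only suitable for a handful of points; serves as the independent check
    on the fitted SVM.
    """
    from scipy.optimize import minimize

    X = np.asarray(X, dtype=float)
    y = np.asarray(y_signed, dtype=float)
    n = len(y)
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    K = np.exp(-gamma * d2)
    Q = (y[:, None] * y[None, :]) * K

    res = minimize(
        lambda a: -(a.sum() - 0.5 * a @ Q @ a),
        np.full(n, min(C, 1.0) / 2),
        jac=lambda a: -(np.ones(n) - Q @ a),
        bounds=[(0.0, C)] * n,
        constraints={"type": "eq", "fun": lambda a: a @ y},
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-12},
    )
    alpha = res.x
    f_wo_b = (alpha * y) @ K
    free = (alpha > 1e-6) & (alpha < C - 1e-6)
    b = float(np.mean(y[free] - f_wo_b[free])) if free.any() else 0.0
    return f_wo_b + b
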