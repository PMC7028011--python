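"""Joint revision of PWM columns over similarity graphs.

Two solvers revise all cores' columns at one binding-site position
simultaneously, balancing fidelity to the initial estimates ``S`` against
consistency across similar cores with a single parameter ``0 < alpha <= 1``
(``alpha = 1`` means no information sharing and returns the input exactly).

**Quadratic program (QP).**  Minimize

    alpha * sum_a ||S_a - X_a||^2
    + (1 - alpha) * sum_{a,a'} w_j(a, a') * ||X_a - X_{a'}||^2

subject to each revised column ``X_a`` lying on the probability simplex.
Writing ``L = D_out + D_in - W - W^T`` for the Laplacian of the
symmetrized weights, the stationarity system for each base is

    (alpha I + (1 - alpha) L) x_b = alpha s_b.

Because ``L`` annihilates constant vectors, the solutions automatically
satisfy ``sum_b x_b = 1``; and because the system matrix is a strictly
diagonally dominant M-matrix its inverse is entrywise nonnegative, so the
box constraints are never active.  The constrained QP therefore reduces to
one sparse symmetric positive-definite solve per base, which is how it is
implemented here (tests check this against a general-purpose constrained
minimizer).

**Label propagation / adsorption (LPA).**  The anchored variant iterates

    X^(t) = alpha * S + (1 - alpha) * W X^(t-1)

from ``X^(0) = S`` until the maximum entry change drops below ``tol``; for
``alpha > 0`` the map is a contraction (spectral radius of
``(1 - alpha) W`` at most ``1 - alpha``), so convergence is guaranteed and
the fixed point is ``alpha (I - (1 - alpha) W)^{-1} S`` -- the absorption
probabilities of a random walk that stops at its start with probability
``alpha``.  A *literal* variant ``X^(t) = alpha X^(t-1) + (1-alpha) W X^(t-1)``
is available for finite-iteration experiments; it has no anchor and drifts
toward per-component consensus, so it is not the default.  With
``max_iter = 1`` both variants coincide with a weighted nearest-neighbour
blend ``alpha S_a + (1 - alpha) sum w(a, a') S_{a'}``.

Both solvers leave isolated nodes (no outgoing edges) unchanged and preserve
the probability simplex exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as sparse_linalg

from .pwm_io import PWM, PWMDataset
from .similarity_graph import SimilarityGraph


class SolverError(RuntimeError):
    """QP/LPA failure, carrying solver status in the message."""


@dataclass(frozen=True)
class InferenceConfig:
    """Settings for :func:`joint_infer`.

    ``positions`` selects the binding-site positions (0-based) to revise;
    ``None`` means all.  Columns at unselected positions are copied through
    unchanged, which supports protocols that smooth only a subset of
    positions.
    """

    alpha: float
    method: str = "qp"
    lpa_tol: float = 1e-8
    lpa_max_iter: int = 1000
    lpa_variant: str = "anchored"
    qp_feasibility_tol: float = 1e-9
    positions: tuple[int, ...] | None = None

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if self.method not in ("qp", "lpa"):
            raise ValueError(f"method must be 'qp' or 'lpa', got {self.method!r}")
        if self.lpa_variant not in ("anchored", "literal"):
            raise ValueError(f"lpa_variant must be 'anchored' or 'literal'")
        if self.lpa_max_iter < 1:
            raise ValueError("lpa_max_iter must be >= 1")


@dataclass
class InferenceResult:
    revised: PWMDataset
    diagnostics: dict[int, dict] = field(default_factory=dict)
    config: InferenceConfig | None = None


def _column_matrix(S_cols: Mapping[str, np.ndarray], order: Sequence[str]) -> np.ndarray:
    S = np.array([np.asarray(S_cols[a], dtype=float) for a in order])
    if S.ndim != 2 or S.shape[1] != 4:
        raise ValueError("columns must be 4-vectors")
    if np.any(S < -1e-9) or np.any(np.abs(S.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("columns must be probability 4-vectors")
    return S


def qp_infer_column(
    S_cols: Mapping[str, np.ndarray],
    graph: SimilarityGraph,
    alpha: float,
    feasibility_tol: float = 1e-9,
) -> dict[str, np.ndarray]:
    """Simplex-constrained quadratic-programming revision of one position.

    Returns the global minimizer of the QP described in the module
    docstring.  Nodes untouched by any edge are returned unchanged.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    missing = {a for e in graph.edges for a in e} - set(S_cols)
    if missing:
        raise SolverError(f"graph references cores without columns: {sorted(missing)}")
    result = {a: np.asarray(col, dtype=float).copy() for a, col in S_cols.items()}
    if alpha == 1.0 or not graph.edges:
        return result

    involved = sorted({a for e in graph.edges for a in e})
    S = _column_matrix(S_cols, involved)
    W = graph.to_sparse(involved)
    d_out = np.asarray(W.sum(axis=1)).ravel()
    d_in = np.asarray(W.sum(axis=0)).ravel()
    lap = sparse.diags(d_out + d_in) - W - W.T
    A = (alpha * sparse.identity(len(involved)) + (1 - alpha) * lap).tocsc()
    try:
        solve = sparse_linalg.factorized(A)
    except RuntimeError as exc:  # pragma: no cover - A is SPD by construction
        raise SolverError(f"QP linear solve failed: {exc}") from exc
    X = np.column_stack([solve(alpha * S[:, b]) for b in range(4)])

    # numerical hygiene: roundoff can leave tiny negatives / drift in sums
    if np.any(X < -feasibility_tol) or np.any(
        np.abs(X.sum(axis=1) - 1.0) > 1e4 * feasibility_tol
    ):
        raise SolverError(
            "QP solution violates simplex feasibility beyond tolerance "
            f"(min entry {X.min():.3g}, worst column sum {X.sum(axis=1).max():.12g})"
        )
    X = np.clip(X, 0.0, None)
    X /= X.sum(axis=1, keepdims=True)
    for i, a in enumerate(involved):
        result[a] = X[i]
    return result


def lpa_infer_column(
    S_cols: Mapping[str, np.ndarray],
    graph: SimilarityGraph,
    alpha: float,
    tol: float = 1e-8,
    max_iter: int = 1000,
    variant: str = "anchored",
) -> dict[str, np.ndarray]:
    cols, _info = lpa_infer_column_with_info(S_cols, graph, alpha, tol, max_iter, variant)
    return cols


def lpa_infer_column_with_info(
    S_cols: Mapping[str, np.ndarray],
    graph: SimilarityGraph,
    alpha: float,
    tol: float = 1e-8,
    max_iter: int = 1000,
    variant: str = "anchored",
) -> tuple[dict[str, np.ndarray], dict]:
    """Label-propagation revision of one position, with iteration diagnostics.

    See the module docstring for the anchored and literal updates.  Nodes
    with no outgoing edges keep their initial column.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    if variant not in ("anchored", "literal"):
        raise ValueError(f"unknown LPA variant {variant!r}")
    result = {a: np.asarray(col, dtype=float).copy() for a, col in S_cols.items()}
    info = {"iterations": 0, "converged": True, "max_change": 0.0}
    if alpha == 1.0 or not graph.edges:
        return result, info

    order = sorted(S_cols)
    S = _column_matrix(S_cols, order)
    W = graph.to_sparse(order)
    has_out = np.asarray(W.sum(axis=1)).ravel() > 0

    X = S.copy()
    converged = False
    change = 0.0
    for it in range(1, max_iter + 1):
        prop = W @ X
        if variant == "anchored":
            X_new = alpha * S + (1 - alpha) * prop
        else:
            X_new = alpha * X + (1 - alpha) * prop
        X_new[~has_out] = S[~has_out]
        change = float(np.max(np.abs(X_new - X)))
        X = X_new
        if change < tol:
            converged = True
            break
    info.update(iterations=it, converged=converged, max_change=change)
    if not converged:
        info["warning"] = (
            f"LPA did not reach tol={tol:g} within {max_iter} iterations "
            f"(last max change {change:.3g}); returning last iterate"
        )
    for i, a in enumerate(order):
        result[a] = X[i]
    return result, info


def joint_infer(
    dataset: PWMDataset,
    graphs: Sequence[SimilarityGraph],
    config: InferenceConfig,
) -> InferenceResult:
    """Revise every PWM in *dataset* position-by-position.

    Each binding-site position in ``config.positions`` is solved
    independently with the configured method over the matching similarity
    graph; other positions pass through unchanged.
    """
    k = dataset.k
    by_j = {g.j: g for g in graphs}
    if any(j < 0 or j >= k for j in by_j):
        raise ValueError(f"graph positions must lie in 0..{k - 1}")
    positions = tuple(range(k)) if config.positions is None else tuple(config.positions)
    if any(j < 0 or j >= k for j in positions):
        raise ValueError(f"config.positions must lie in 0..{k - 1}")

    cores = dataset.cores
    revised = {a: dataset[a].values.copy() for a in cores}
    diagnostics: dict[int, dict] = {}
    for j in positions:
        graph = by_j.get(j)
        if graph is None or not graph.edges:
            diagnostics[j] = {"status": "no-graph", "n_edges": 0}
            continue
        S_cols = {a: dataset[a].values[:, j] for a in cores}
        try:
            if config.method == "qp":
                out = qp_infer_column(
                    S_cols, graph, config.alpha, config.qp_feasibility_tol
                )
                diagnostics[j] = {"status": "optimal", "n_edges": len(graph.edges)}
            else:
                out, info = lpa_infer_column_with_info(
                    S_cols,
                    graph,
                    config.alpha,
                    config.lpa_tol,
                    config.lpa_max_iter,
                    config.lpa_variant,
                )
                diagnostics[j] = {"status": "ok", "n_edges": len(graph.edges), **info}
        except SolverError as exc:
            raise SolverError(f"position {j}: {exc}") from exc
        for a in cores:
            revised[a][:, j] = out[a]

    entries = {a: PWM(revised[a]) for a in cores}
    out_ds = PWMDataset(entries, k=k, label=dataset.label)
    return InferenceResult(revised=out_ds, diagnostics=diagnostics, config=config)
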