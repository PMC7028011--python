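"""Independent reference minimizer for the per-position QP.

Solves the simplex-constrained quadratic objective with a general-purpose
constrained optimizer (scipy SLSQP) over the full 4n-dimensional variable,
sharing no code with the package's linear-solve implementation.
"""

import numpy as np
from scipy import optimize

from jointpwm.similarity_graph import SimilarityGraph


def qp_objective(X, S, pairs, alpha):
    """alpha * ||S - X||^2 + (1-alpha) * sum w (X_a - X_a')^2 (summed over bases)."""
    fid = alpha * np.sum((S - X) ** 2)
    coup = 0.0
    for ia, ib, w in pairs:
        coup += w * np.sum((X[ia] - X[ib]) ** 2)
    return fid + (1.0 - alpha) * coup


def slsqp_qp_solve(
    S_cols: dict[str, np.ndarray], graph: SimilarityGraph, alpha: float
) -> dict[str, np.ndarray]:
    order = sorted(S_cols)
    index = {a: i for i, a in enumerate(order)}
    S = np.array([S_cols[a] for a in order], dtype=float)
    pairs = [(index[a], index[b], w) for (a, b), w in graph.edges.items()]
    n = len(order)

    def fun(x):
        return qp_objective(x.reshape(n, 4), S, pairs, alpha)

    constraints = [
        {"type": "eq", "fun": (lambda x, i=i: x.reshape(n, 4)[i].sum() - 1.0)}
        for i in range(n)
    ]
    res = optimize.minimize(
        fun,
        S.ravel().copy(),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * (4 * n),
        constraints=constraints,
        options={"maxiter": 500, "ftol": 1e-14},
    )
    assert res.success, res.message
    X = res.x.reshape(n, 4)
    return {a: X[index[a]] for a in order}
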