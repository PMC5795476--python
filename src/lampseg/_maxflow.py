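"""Binary energy minimization by s/t min-cut on a sparse graph.

Solves min over x in {0,1}^n of

    sum_p theta_p(x_p) + sum_{(p,q)} E_pq(x_p, x_q)

for submodular pairwise terms (E00 + E11 <= E01 + E10).  The energy is
reparameterized into terminal and edge capacities (the standard
graph construction for submodular binary energies) and solved with
``scipy.sparse.csgraph.maximum_flow``, which takes integer capacities;
float capacities are scaled adaptively so that the rounding granularity is
as fine as the int32 range allows for the given instance.  Label 0 is the
source side of the cut.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

_INT32_MAX = 2**31 - 1


def solve_binary(
    theta0: np.ndarray,
    theta1: np.ndarray,
    pairs: np.ndarray,
    pair_costs: np.ndarray,
) -> np.ndarray:
    """Minimize a submodular binary pairwise energy exactly.

    Parameters
    ----------
    theta0, theta1
        Unary costs of labels 0 and 1, shape (n,).
    pairs
        (E, 2) int array of node index pairs (p, q).
    pair_costs
        (E, 4) array of [E00, E01, E10, E11] per pair.  Non-submodular
        residuals (numerical noise) are clipped to zero.

    Returns
    -------
    labels : (n,) uint8 array.
    """
    theta0 = np.asarray(theta0, dtype=np.float64)
    theta1 = np.asarray(theta1, dtype=np.float64).copy()
    n = theta0.size
    if pairs.size:
        a = pair_costs[:, 0]  # E(0,0)
        b = pair_costs[:, 1]  # E(0,1)
        c = pair_costs[:, 2]  # E(1,0)
        d = pair_costs[:, 3]  # E(1,1)
        # E = A + (C-A) x_p + (D-C) x_q + (B+C-A-D)(1-x_p) x_q
        np.add.at(theta1, pairs[:, 0], c - a)
        np.add.at(theta1, pairs[:, 1], d - c)
        edge_cap = np.clip(b + c - a - d, 0.0, None)
    else:
        edge_cap = np.zeros(0)

    base = np.minimum(theta0, theta1)
    cap_s = theta1 - base  # cut when p is on the sink side (label 1)
    cap_t = theta0 - base  # cut when p is on the source side (label 0)

    # Adaptive integer scaling: keep every capacity and the max-flow value
    # within int32.  The flow is bounded by the smaller terminal-side total.
    flow_bound = min(cap_s.sum(), cap_t.sum() + edge_cap.sum())
    biggest = max(
        float(cap_s.max(initial=0.0)),
        float(cap_t.max(initial=0.0)),
        float(edge_cap.max(initial=0.0)),
        flow_bound,
        1e-12,
    )
    scale = (_INT32_MAX - 1) / (biggest * (1.0 + 1e-9))

    src, snk = n, n + 1
    rows = [np.full(n, src), np.arange(n)]
    cols = [np.arange(n), np.full(n, snk)]
    caps = [cap_s, cap_t]
    if pairs.size:
        rows.append(pairs[:, 0])
        cols.append(pairs[:, 1])
        caps.append(edge_cap)
    row = np.concatenate(rows)
    col = np.concatenate(cols)
    cap = np.rint(np.concatenate(caps) * scale).astype(np.int64)
    keep = cap > 0
    graph = csr_matrix(
        (cap[keep].astype(np.int32), (row[keep], col[keep])), shape=(n + 2, n + 2)
    )
    result = maximum_flow(graph, src, snk)

    residual = graph - result.flow
    residual.data = (residual.data > 0).astype(np.int32)
    residual.eliminate_zeros()
    reachable = breadth_first_order(residual, src, directed=True, return_predecessors=False)
    labels = np.ones(n, dtype=np.uint8)
    reachable = reachable[reachable < n]
    labels[reachable] = 0
    return labels


def grid_pairs(h: int, w: int) -> np.ndarray:
    """Unordered 4-connected neighbor pairs of an h x w grid, as flat indices."""
    idx = np.arange(h * w).reshape(h, w)
    horiz = np.stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()], axis=1)
    vert = np.stack([idx[:-1, :].ravel(), idx[1:, :].ravel()], axis=1)
    return np.concatenate([horiz, vert], axis=0)
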