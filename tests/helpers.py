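"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: population partial
correlations come from a direct linear-Gaussian parameterization of a DAG,
balance from an exhaustive cycle-basis sign product, partial correlations
from regression residuals, and ROC AUC from pairwise concordance.
"""

from __future__ import annotations

import networkx as nx
import numpy as np


def population_covariance(dag, weights: dict, noise_var: dict | float = 1.0) -> tuple[list, np.ndarray]:
    """Covariance of the linear-Gaussian SEM X = A X + e on a DAG.

    ``weights`` maps directed edges (u, v) to coefficients; noise variances
    per node (or one scalar).  Sigma = (I - A)^-1 D (I - A)^-T with
    A[child, parent] = w.
    """
    nodes = sorted(dag.g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for (u, v), w in weights.items():
        A[idx[v], idx[u]] = w
    if np.isscalar(noise_var):
        D = np.eye(n) * noise_var
    else:
        D = np.diag([noise_var[m] for m in nodes])
    Minv = np.linalg.inv(np.eye(n) - A)
    return nodes, Minv @ D @ Minv.T


def population_partial_corr(nodes, Sigma, x, y, C) -> float:
    """Partial correlation from a covariance matrix by direct inversion."""
    idx = {n: i for i, n in enumerate(nodes)}
    sel = [idx[x], idx[y]] + [idx[c] for c in C]
    K = np.linalg.inv(Sigma[np.ix_(sel, sel)])
    return float(-K[0, 1] / np.sqrt(K[0, 0] * K[1, 1]))


def generic_weights(dag, rng: np.random.Generator) -> dict:
    """Random nonzero weights for every directed edge (generic parameterization)."""
    return {
        e: float(rng.uniform(0.5, 1.5) * rng.choice([-1, 1]))
        for e in sorted(dag.g.edges)
    }


def cycle_sign_oracle(signs: np.ndarray) -> bool:
    """Balanced iff every cycle of a cycle basis has positive sign product.

    The cycle sign is a homomorphism on the GF(2) cycle space, so checking a
    basis is exhaustive.
    """
    g = nx.Graph()
    n = signs.shape[0]
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if signs[i, j] != 0:
                g.add_edge(i, j, sign=int(signs[i, j]))
    for cycle in nx.cycle_basis(g):
        prod = 1
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            prod *= g.edges[a, b]["sign"]
        if prod < 0:
            return False
    return True


def regression_partial_corr(X: np.ndarray, ix: int, iy: int, iC: list[int]) -> float:
    """Sample partial correlation via least-squares residuals."""
    if not iC:
        return float(np.corrcoef(X[:, ix], X[:, iy])[0, 1])
    Z = np.column_stack([X[:, iC], np.ones(len(X))])
    rx = X[:, ix] - Z @ np.linalg.lstsq(Z, X[:, ix], rcond=None)[0]
    ry = X[:, iy] - Z @ np.linalg.lstsq(Z, X[:, iy], rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])


def concordance_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Rank-sum AUC: P(score_pos < score_neg), ties counted half.

    'Positive' here means the truth label whose low scores should be
    accepted (verified), matching the ROC construction under test.
    """
    pos = scores[positive]
    neg = scores[~positive]
    less = (pos[:, None] < neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((less + 0.5 * ties) / (len(pos) * len(neg)))


def random_signed_mtp2_correlation(rng: np.random.Generator, n: int) -> np.ndarray:
    """Correlation matrix whose concentration gauges to an M-matrix."""
    B = rng.uniform(0, 1, (n, n)) * (rng.random((n, n)) < 0.7)
    B = (B + B.T) / 2
    np.fill_diagonal(B, 0)
    s = np.abs(np.linalg.eigvalsh(B)).max() + rng.uniform(0.05, 1.0)
    K = s * np.eye(n) - B
    d = rng.choice([-1.0, 1.0], n)
    Sigma = np.linalg.inv(np.outer(d, d) * K)
    dn = np.sqrt(np.diag(Sigma))
    return Sigma / np.outer(dn, dn)


def random_correlation(rng: np.random.Generator, n: int) -> np.ndarray:
    """Generic positive-definite correlation matrix."""
    A = rng.normal(size=(n, n + 2))
    S = A @ A.T + 0.1 * np.eye(n)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)
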