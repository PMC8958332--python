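"""Structural balance and inverse balance of sample correlation graphs.

A signed graph is *balanced* (frustration-free) when every cycle carries an
even number of negative edges; equivalently there is a gauge d in {+-1}^n
with sign(R_ij) = d_i d_j on every present edge, so D R D is entrywise
nonnegative.  Balance of the signed graph of the partial-correlation matrix
P = 2I - H (H the diagonal-normalized concentration matrix) is *inverse
balance*, equivalent to the concentration matrix becoming an M-matrix after
the gauge (signed MTP2).  Inverse balance implies balance, never the
converse, and forces the contraction |R_xy.C| <= |R_xy| upon conditioning;
under plain balance the contraction is typical but not guaranteed.

Balance of the motif formed by a Markov condition's variables is used as a
cheap consistency screen predicting whether the condition will verify.
"""

from __future__ import annotations

from collections import deque
from typing import Sequence

import numpy as np
import pandas as pd

from .citest import IllConditionedError, COND_TOL
from .dyncorr import DynCorrResult

__all__ = [
    "sign_graph",
    "is_balanced",
    "partial_correlation_matrix",
    "is_inverse_balanced",
    "classify_condition_motifs",
    "contraction_stats",
    "threshold_roc",
]

ZERO_TOL = 1e-8  # |R_ij| below this counts as an absent edge


def sign_graph(R: np.ndarray, tol: float = ZERO_TOL) -> np.ndarray:
    """Off-diagonal sign pattern (+1/-1, 0 = absent edge) of a symmetric matrix."""
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("R must be symmetric")
    s = np.sign(R) * (np.abs(R) >= tol)
    np.fill_diagonal(s, 0)
    return s.astype(int)


def is_balanced(signs: np.ndarray) -> tuple[bool, np.ndarray | list[int]]:
    """Gauge test by breadth-first spin assignment with conflict detection.

    Returns ``(True, gauge)`` with a +-1 signature vector satisfying
    sign(R_ij) = d_i d_j on every present edge, or ``(False, cycle)`` with
    the node indices of a violating (odd-sign) cycle.
    """
    s = np.asarray(signs)
    n = s.shape[0]
    gauge = np.zeros(n, dtype=int)
    parent = {i: None for i in range(n)}
    for root in range(n):
        if gauge[root]:
            continue
        gauge[root] = 1
        queue = deque([root])
        while queue:
            u = queue.popleft()
            for v in np.flatnonzero(s[u]):
                want = gauge[u] * s[u, v]
                if gauge[v] == 0:
                    gauge[v] = want
                    parent[v] = u
                    queue.append(v)
                elif gauge[v] != want:
                    # reconstruct the violating cycle through the BFS tree
                    def path_to_root(w):
                        out = [w]
                        while parent[out[-1]] is not None:
                            out.append(parent[out[-1]])
                        return out
                    pu, pv = path_to_root(u), path_to_root(v)
                    common = set(pu) & set(pv)
                    cu = next(i for i, w in enumerate(pu) if w in common)
                    cv = next(i for i, w in enumerate(pv) if w in common)
                    cycle = pu[: cu + 1] + pv[:cv][::-1]
                    return False, cycle
    return True, gauge


def partial_correlation_matrix(R: np.ndarray) -> np.ndarray:
    """P = 2I - H with H the diagonal-normalized inverse of R."""
    R = np.asarray(R, dtype=float)
    cond = np.linalg.cond(R)
    if not np.isfinite(cond) or cond > COND_TOL:
        raise IllConditionedError(f"singular correlation matrix (cond {cond:.2e})")
    K = np.linalg.inv(R)
    d = np.sqrt(np.diag(K))
    H = K / np.outer(d, d)
    return 2 * np.eye(R.shape[0]) - H


def is_inverse_balanced(R: np.ndarray) -> tuple[bool, np.ndarray | None]:
    """Balance of G(P); equivalently K gauges to an M-matrix (signed MTP2)."""
    P = partial_correlation_matrix(R)
    ok, witness = is_balanced(sign_graph(P))
    return (ok, witness if ok else None)


def classify_condition_motifs(
    records: pd.DataFrame, dc: DynCorrResult
) -> pd.DataFrame:
    """Label each condition's motif balanced / unbalanced (both notions).

    The motif is the complete signed subgraph of G(R) on {x, y} U C
    (including the x-y edge itself); conditions with C = {} have no cycle
    and are balanced by convention.  Adds ``balance_label`` and
    ``inverse_balance_label`` columns ('balanced' / 'unbalanced'; inverse
    label is NaN when the restricted matrix is singular).
    """
    out = records.copy()
    bal, inv = [], []
    for row in out.itertuples():
        names = [row.x, row.y] + ([] if not row.C else row.C.split("|"))
        if len(names) == 2:
            bal.append("balanced")
            inv.append("balanced")
            continue
        sub = dc.submatrix(names)
        ok, _ = is_balanced(sign_graph(sub))
        bal.append("balanced" if ok else "unbalanced")
        try:
            ok_inv, _ = is_inverse_balanced(sub)
            inv.append("balanced" if ok_inv else "unbalanced")
        except IllConditionedError:
            inv.append(np.nan)
    out["balance_label"] = bal
    out["inverse_balance_label"] = inv
    return out


def contraction_stats(records: pd.DataFrame) -> pd.DataFrame:
    """Fraction of |R_xy.C| <= |R_xy| stratified by the balance labels."""
    ok = records[~records.skipped]
    rows = []
    for col in ("balance_label", "inverse_balance_label"):
        if col not in ok.columns:
            continue
        for label, grp in ok.dropna(subset=[col]).groupby(col):
            rows.append(
                {
                    "criterion": col.replace("_label", ""),
                    "label": label,
                    "n": len(grp),
                    "contraction_fraction": float(grp.contraction.mean()),
                }
            )
    return pd.DataFrame(rows)


def threshold_roc(
    records: pd.DataFrame,
    truth_label: str = "balance",
    n_grid: int = 1001,
) -> dict:
    """ROC and precision-recall curves sweeping the acceptance threshold.

    Balance (or inverse balance) is the truth; "verified at threshold
    theta", i.e. |R_xy.C| < theta, is the prediction.  TP = balanced and
    verified, FP = unbalanced and verified.  AUCs by trapezoid on a uniform
    theta grid over [0, 1].
    """
    col = {"balance": "balance_label", "inverse_balance": "inverse_balance_label"}.get(
        truth_label
    )
    if col is None:
        raise ValueError("truth_label must be 'balance' or 'inverse_balance'")
    ok = records[~records.skipped].dropna(subset=[col, "r_xy_C"])
    truth = (ok[col] == "balanced").to_numpy()
    if truth.all() or not truth.any():
        raise ValueError("single-class truth: AUC undefined")
    score = np.abs(ok.r_xy_C.to_numpy())
    thetas = np.linspace(0, 1, n_grid)
    pred = score[None, :] < thetas[:, None]
    tp = (pred & truth).sum(axis=1)
    fp = (pred & ~truth).sum(axis=1)
    fn = (~pred & truth).sum(axis=1)
    tn = (~pred & ~truth).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = tp / (tp + fn)
        fpr = fp / (fp + tn)
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 1.0)
    roc_auc = float(np.trapezoid(tpr, fpr))
    pr_auc = float(np.trapezoid(precision, tpr))
    return {
        "theta": thetas,
        "tpr": tpr,
        "fpr": fpr,
        "precision": precision,
        "recall": tpr,
        "roc_auc": roc_auc,
        "pr_auc": pr_auc,
    }
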