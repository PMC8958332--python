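"""Empirical verification of Markov conditions via partial correlations.

A condition x _|_ y | C is *verified* when the sample partial correlation
satisfies |R_xy.C| < theta, with theta the largest magnitude not rejecting
independence in a Fisher z-test:

    theta = tanh( Phi^{-1}(1 - alpha/2) / sqrt(N - |C| - 3) )

For the study design (49 interpolated time points x 3 replicates, N = 147,
alpha = 0.05) this gives theta ~ 0.16.  N counts interpolated points, which
overstates the information content of six native samples; it is exposed in
:class:`TestConfig` and the caveat is discussed in the methods notes.

The module also infers dominant splice variants (the isoform s_i rendering
every sibling s_j conditionally independent of the protein), runs the two
null models used to benchmark verification rates, and provides the subset /
annotation comparisons (Fisher exact and two-sample t tests).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dyncorr import DynCorrResult
from .graphs import ProteinCodingUnitDAG, appris_rank
from .markov import MarkovCondition

__all__ = [
    "TestConfig",
    "IllConditionedError",
    "fisher_threshold",
    "partial_correlation",
    "verify_conditions",
    "aggregate_by_node",
    "aggregate_by_dag",
    "klass_table",
    "dominant_splice",
    "dominant_splice_population",
    "null_model_benchmark",
    "subset_enrichment",
    "covariate_comparison",
    "annotation_agreement",
    "load_gene_list",
]

COND_TOL = 1e10  # condition-number cutoff for partial-correlation submatrices


class IllConditionedError(ValueError):
    """Submatrix too ill-conditioned for a trustworthy partial correlation."""


@dataclass
class TestConfig:
    """Verification settings.

    ``n_samples`` is the effective sample size fed to the Fisher z test
    (default 147 = 49 interpolated points x 3 replicates); ``theta_mode``
    selects |C|-specific degrees of freedom ("per-card", default) or one
    global threshold at |C| = 0 ("global").
    """

    alpha: float = 0.05
    n_samples: int = 147
    theta_mode: str = "per-card"
    null_reps: int = 1
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.theta_mode not in ("per-card", "global"):
            raise ValueError("theta_mode must be 'per-card' or 'global'")
        if self.n_samples - 3 <= 0:
            raise ValueError("n_samples too small for the Fisher z test")

    def theta(self, card_c: int) -> float:
        card = card_c if self.theta_mode == "per-card" else 0
        return fisher_threshold(self.n_samples, card, self.alpha)


def fisher_threshold(n: int, card_c: int, alpha: float = 0.05) -> float:
    """Largest |partial correlation| not rejecting independence at ``alpha``.

    Inverts sqrt(N - |C| - 3) * |z(R)| < Phi^{-1}(1 - alpha/2) with
    z the Fisher transform atanh, giving tanh(Phi^{-1}(1-alpha/2)/sqrt(dof)).
    """
    dof = n - card_c - 3
    if dof <= 0:
        raise ValueError(f"non-positive degrees of freedom: N={n}, |C|={card_c}")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    return float(np.tanh(stats.norm.ppf(1 - alpha / 2) / np.sqrt(dof)))


def partial_correlation(
    R: np.ndarray, ids: Sequence[str], x: str, y: str, C: Sequence[str]
) -> float:
    """R_xy.C via inversion of the restriction of R to {x, y} U C.

    R_xy.C = -[K]_xy / sqrt([K]_xx [K]_yy) with K the inverse of the
    restricted matrix; C = {} returns R_xy unchanged.  Raises
    :class:`IllConditionedError` when the submatrix condition number exceeds
    1e10 (a silent pseudo-inverse would distort the result).
    """
    index = {v: i for i, v in enumerate(ids)}
    try:
        sel = [index[v] for v in (x, y, *C)]
    except KeyError as e:
        raise KeyError(f"variable {e.args[0]!r} not in correlation matrix") from None
    if len(set(sel)) != len(sel):
        raise ValueError("x, y and C must be distinct variables")
    if not C:
        return float(R[sel[0], sel[1]])
    sub = R[np.ix_(sel, sel)]
    cond = np.linalg.cond(sub)
    if not np.isfinite(cond) or cond > COND_TOL:
        raise IllConditionedError(
            f"submatrix for ({x},{y}|{','.join(C)}) has condition number {cond:.2e}"
        )
    K = np.linalg.inv(sub)
    return float(-K[0, 1] / np.sqrt(K[0, 0] * K[1, 1]))


def verify_conditions(
    conditions: Iterable[MarkovCondition],
    dc: DynCorrResult,
    config: TestConfig | None = None,
) -> pd.DataFrame:
    """One verification record per condition.

    Columns: dag_id, x, y, klass, C (pipe-joined), card_C, r_xy, r_xy_C,
    theta, verified, contraction (|r_xy_C| <= |r_xy|), skipped (ill-
    conditioned submatrix; such rows carry NaN partials and verified=False).
    """
    config = config or TestConfig()
    config.validate()
    rows = []
    for c in conditions:
        r_xy = dc.r(c.x, c.y)
        theta = config.theta(len(c.C))
        try:
            r_c = partial_correlation(dc.R, dc.ids, c.x, c.y, c.C)
            skipped = False
        except IllConditionedError:
            r_c = np.nan
            skipped = True
        rows.append(
            {
                "dag_id": c.dag_id,
                "x": c.x,
                "y": c.y,
                "klass": c.klass,
                "C": "|".join(c.C),
                "card_C": len(c.C),
                "r_xy": r_xy,
                "r_xy_C": r_c,
                "theta": theta,
                "verified": bool(not skipped and abs(r_c) < theta),
                "contraction": bool(not skipped and abs(r_c) <= abs(r_xy)),
                "skipped": skipped,
            }
        )
    return pd.DataFrame(rows)


def _ratio_frame(records: pd.DataFrame, key_cols: list[str]) -> pd.DataFrame:
    ok = records[~records.skipped]
    grp = ok.groupby(key_cols, sort=True)
    out = grp.agg(predicted=("verified", "size"), verified=("verified", "sum"))
    out["ratio"] = out.verified / out.predicted
    return out.reset_index()


def aggregate_by_node(records: pd.DataFrame) -> pd.DataFrame:
    """Verified/predicted ratio per node (a node appears as x or y)."""
    ok = records[~records.skipped]
    long = pd.concat(
        [
            ok[["dag_id", "x", "verified"]].rename(columns={"x": "node"}),
            ok[["dag_id", "y", "verified"]].rename(columns={"y": "node"}),
        ]
    )
    grp = long.groupby(["dag_id", "node"], sort=True)
    out = grp.agg(predicted=("verified", "size"), verified=("verified", "sum"))
    out["ratio"] = out.verified / out.predicted
    return out.reset_index()


def aggregate_by_dag(records: pd.DataFrame) -> pd.DataFrame:
    """Verified/predicted ratio per DAG."""
    return _ratio_frame(records, ["dag_id"])


def klass_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-class totals: predicted, verified, non-verified, rate."""
    ok = records[~records.skipped]
    grp = ok.groupby("klass", sort=True)
    out = grp.agg(total=("verified", "size"), verified=("verified", "sum"))
    out["non_verified"] = out.total - out.verified
    out["rate"] = out.verified / out.total
    return out.reset_index()


# ---------------------------------------------------------------------------
# dominant splice variant
# ---------------------------------------------------------------------------

@dataclass
class DominantResult:
    dag_id: str
    dominant: str | None
    explained_fraction: float
    n_splices: int
    single_dominant: bool


def dominant_splice(
    dag: ProteinCodingUnitDAG,
    dc: DynCorrResult,
    config: TestConfig | None = None,
) -> DominantResult:
    """Search for the isoform s_i with s_j _|_ p | s_i for every sibling s_j.

    The dominant candidate maximizes the number of siblings with
    |R_{s_j p . s_i}| < theta; ties break toward the candidate with the
    smallest maximum residual |R|.  Single-splice DAGs are rejected.
    """
    config = config or TestConfig()
    config.validate()
    splices = dag.splices
    if len(splices) < 2:
        raise ValueError(f"{dag.dag_id}: dominant splice needs >= 2 splice variants")
    (protein,) = dag.proteins
    theta = config.theta(1)
    best: tuple[int, float, str] | None = None
    for si in splices:
        resid = []
        for sj in splices:
            if sj == si:
                continue
            try:
                resid.append(abs(partial_correlation(dc.R, dc.ids, sj, protein, (si,))))
            except IllConditionedError:
                resid.append(np.inf)
        count = sum(r < theta for r in resid)
        worst = max(resid)
        if best is None or count > best[0] or (count == best[0] and worst < best[1]):
            best = (count, worst, si)
    count, _, dom = best
    frac = count / (len(splices) - 1)
    return DominantResult(dag.dag_id, dom, frac, len(splices), frac == 1.0)


def dominant_splice_population(
    dags: Iterable[ProteinCodingUnitDAG],
    dc: DynCorrResult,
    config: TestConfig | None = None,
) -> pd.DataFrame:
    """Dominant-splice summary over all multi-splice DAGs."""
    rows = []
    for d in dags:
        if len(d.splices) < 2:
            continue
        r = dominant_splice(d, dc, config)
        rows.append(vars(r))
    return pd.DataFrame(
        rows,
        columns=["dag_id", "dominant", "explained_fraction", "n_splices", "single_dominant"],
    )


# ---------------------------------------------------------------------------
# null models
# ---------------------------------------------------------------------------

def null_model_benchmark(
    conditions: Sequence[MarkovCondition],
    dc: DynCorrResult,
    config: TestConfig | None = None,
    rng: np.random.Generator | None = None,
) -> dict:
    """Per-node success distributions: true vs two randomized null models.

    Null 1 replaces y with a node y_r drawn uniformly from all variables
    (any DAG); null 2 additionally replaces C with a random set C_r of the
    same cardinality.  Returns the three per-node success-rate arrays and
    two-sample t statistics between them.
    """
    config = config or TestConfig()
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    pool = np.array(dc.ids)
    if pool.size < 4:
        raise ValueError("too few variables to sample null models")

    def success(x, y, C):
        theta = config.theta(len(C))
        try:
            return abs(partial_correlation(dc.R, dc.ids, x, y, C)) < theta
        except IllConditionedError:
            return np.nan

    per_node: dict[str, dict[str, list]] = {}
    for c in conditions:
        rec = per_node.setdefault(c.x, {"true": [], "null_y": [], "null_yC": []})
        rec["true"].append(success(c.x, c.y, c.C))
        for _ in range(config.null_reps):
            banned = {c.x, *c.C}
            yr = rng.choice(pool)
            while yr in banned:
                yr = rng.choice(pool)
            rec["null_y"].append(success(c.x, yr, c.C))
            yr2 = rng.choice(pool)
            while yr2 == c.x:
                yr2 = rng.choice(pool)
            others = pool[(pool != c.x) & (pool != yr2)]
            Cr = tuple(rng.choice(others, size=len(c.C), replace=False))
            assert len(Cr) == len(c.C)
            rec["null_yC"].append(success(c.x, yr2, Cr))

    def rates(key):
        vals = []
        for rec in per_node.values():
            arr = np.array(rec[key], dtype=float)
            arr = arr[~np.isnan(arr)]
            if arr.size:
                vals.append(arr.mean())
        return np.array(vals)

    out = {k: rates(k) for k in ("true", "null_y", "null_yC")}
    out["t_true_vs_null_y"] = stats.ttest_ind(out["true"], out["null_y"], equal_var=False)
    out["t_null_y_vs_null_yC"] = stats.ttest_ind(out["null_y"], out["null_yC"], equal_var=False)
    return out


# ---------------------------------------------------------------------------
# subset and annotation comparisons
# ---------------------------------------------------------------------------

def subset_enrichment(
    records: pd.DataFrame, subset: Iterable[str]
) -> tuple[np.ndarray, float]:
    """Fisher exact test: verification vs membership of the DAG subset.

    Contingency rows are (verified, non-verified), columns (in subset,
    outside).  An empty margin yields p = 1 with a warning.
    """
    import warnings

    subset = set(subset)
    if not subset:
        raise ValueError("subset must be nonempty")
    ok = records[~records.skipped]
    inside = ok.dag_id.isin(subset)
    table = np.array(
        [
            [int((ok.verified & inside).sum()), int((ok.verified & ~inside).sum())],
            [int((~ok.verified & inside).sum()), int((~ok.verified & ~inside).sum())],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate contingency margin; p set to 1")
        return table, 1.0
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(p)


def covariate_comparison(
    records: pd.DataFrame, covariate: dict[str, float], on: str = "x"
) -> dict:
    """Two-sample t test of a numeric covariate (e.g. TF counts) between
    verified and non-verified conditions, the covariate keyed by node id."""
    ok = records[~records.skipped].copy()
    ok["cov"] = ok[on].map(covariate)
    ok = ok.dropna(subset=["cov"])
    a = ok.loc[ok.verified, "cov"].to_numpy()
    b = ok.loc[~ok.verified, "cov"].to_numpy()
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 covariate values per group")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "mean_verified": float(a.mean()),
        "mean_non_verified": float(b.mean()),
        "t": float(t),
        "p": float(p),
    }


def annotation_agreement(
    dominant: pd.DataFrame,
    annotation: dict[str, str],
    dags: Iterable[ProteinCodingUnitDAG],
    rng: np.random.Generator | None = None,
) -> dict:
    """Compare dominant splices with annotation ranks (lower rank = better).

    Reports the fraction of dominant splices carrying the top rank of their
    DAG, the same fraction for a random in-DAG choice, and a Fisher exact
    p value between the two.  Missing annotations count as ABSENT.
    """
    import warnings

    rng = rng or np.random.default_rng(0)
    by_id = {d.dag_id: d for d in dags}
    if not annotation:
        warnings.warn("empty annotation table; all splices rank as ABSENT")
    hits_dom = hits_rand = total = 0
    for row in dominant.itertuples():
        d = by_id.get(row.dag_id)
        if d is None or row.dominant is None:
            continue
        ranks = {s: appris_rank(annotation.get(s, "ABSENT")) for s in d.splices}
        best = min(ranks.values())
        total += 1
        hits_dom += ranks[row.dominant] == best
        hits_rand += ranks[rng.choice(d.splices)] == best
    if total == 0:
        raise ValueError("no dominant results to compare")
    table = np.array(
        [[hits_dom, total - hits_dom], [hits_rand, total - hits_rand]]
    )
    if (table.sum(axis=0) == 0).any():
        p = 1.0
    else:
        _, p = stats.fisher_exact(table)
    return {
        "n": total,
        "frac_dominant_top_rank": hits_dom / total,
        "frac_random_top_rank": hits_rand / total,
        "fisher_p": float(p),
    }


def load_gene_list(name: str) -> list[str]:
    """Packaged gene lists: 'th1' or 'tcell' (T-cell differentiation panels)."""
    fname = {"th1": "th1_genes.txt", "tcell": "tcell_genes.txt"}.get(name)
    if fname is None:
        raise ValueError("name must be 'th1' or 'tcell'")
    text = resources.files("pcunits.data").joinpath(fname).read_text()
    return [g.strip() for g in text.split() if g.strip()]
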