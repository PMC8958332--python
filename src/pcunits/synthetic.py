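"""Synthetic protein-coding units and replicated multi-omics time series.

No public generative model exists for the joint ATAC/RNA/protein time
courses this package analyzes, so the generator is an explicit stand-in: it
draws three-layer DAGs and propagates smooth latent signals through
instantaneous linear-Gaussian structural equations consistent with the DAG
factorization P(a,...,s,...,p) = prod P(node | parents).

Per unit each root peak receives a smooth latent trajectory (random
coefficients on cubic B-spline bumps over [0, 24] h); each splice is the
signed weighted sum of its peak parents plus optional hidden-confounder
loadings and its own smooth noise; the protein is the signed weighted sum of
its splices plus smooth noise.  Signals are sampled on the native layer
grids (peaks and splices at [0, 0.5, 1, 2, 6, 24] h, protein at
[0, 1, 2, 6, 24] h) and each of the 3 replicates adds independent Gaussian
observation noise at the sampled points.  Replicates share the latent
trajectory, mimicking biological replicates of one differentiation response.

Planted violations (direct a->s edges bypassing the assumed DAG, and hidden
smooth confounders loading on several splices) enter the generating
equations but are deliberately left out of the "assumed" DAGs, so that
downstream conditional-independence tests can be benchmarked against a known
truth ledger.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.interpolate import BSpline

from .dyncorr import ReplicatedTimeSeries
from .graphs import ProteinCodingUnitDAG

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_dag_population",
    "plant_violations",
    "simulate_unit_timeseries",
    "smooth_random_function",
]

GRID_AS = (0.0, 0.5, 1.0, 2.0, 6.0, 24.0)
GRID_P = (0.0, 1.0, 2.0, 6.0, 24.0)


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the experimental design the analysis assumes: 3
    biological replicates, peak/splice grids [0, 0.5, 1, 2, 6, 24] h and a
    protein grid [0, 1, 2, 6, 24] h (no 0.5 h protein sample; the late
    120 h point is disregarded).  Edge weights are drawn uniform in
    [0.5, 1.5] x ``edge_weight_magnitude`` -- bounded away from zero so true
    edges are detectable -- with sign flipped with probability
    ``negative_edge_prob``.
    """

    n_units: int = 20
    peaks_per_unit: tuple[int, int] = (1, 3)
    splices_per_unit: tuple[int, int] = (1, 5)
    edge_weight_magnitude: float = 1.0
    negative_edge_prob: float = 0.2
    noise_sd: float = 0.15
    replicate_sd: float = 0.25
    n_replicates: int = 3
    grid_a: tuple[float, ...] = GRID_AS
    grid_s: tuple[float, ...] = GRID_AS
    grid_p: tuple[float, ...] = GRID_P
    n_basis: int = 6
    extra_parent_prob: float = 0.25
    planted_extra_edge_rate: float = 0.0
    confounder_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("negative_edge_prob", "extra_parent_prob",
                     "planted_extra_edge_rate", "confounder_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("noise_sd", "replicate_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        for name in ("peaks_per_unit", "splices_per_unit"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name}: need 1 <= min <= max, got ({lo},{hi})")
        for name in ("grid_a", "grid_s", "grid_p"):
            g = np.asarray(getattr(self, name), dtype=float)
            if g[0] != 0 or np.any(np.diff(g) <= 0):
                raise ValueError(f"{name} must start at 0 and increase strictly")
        if self.n_basis < 4:
            raise ValueError("n_basis must be >= 4 (cubic B-splines)")
        if self.edge_weight_magnitude <= 0:
            raise ValueError("edge_weight_magnitude must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})
        cfg.validate()
        return cfg


@dataclass
class GroundTruth:
    """Truth ledger: assumed DAGs plus whatever violates them."""

    true_dags: list[ProteinCodingUnitDAG]
    weights: dict[tuple[str, str], float]
    planted_edges: list[tuple[str, str]] = field(default_factory=list)
    confounders: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    planted_weights: dict[tuple[str, str], float] = field(default_factory=dict)
    confounder_weights: dict[tuple[str, str], float] = field(default_factory=dict)

    def validate(self) -> None:
        by_id = {d.dag_id: d for d in self.true_dags}
        for a, s in self.planted_edges:
            for d in by_id.values():
                if a in d.g and s in d.g and d.g.has_edge(a, s):
                    raise ValueError(f"planted edge ({a},{s}) present in true DAG")

    def to_json(self) -> str:
        payload = {
            "units": [
                {
                    "dag_id": d.dag_id,
                    "nodes": [
                        {"id": n, "layer": d.layer(n), "unit": d.unit(n)}
                        for n in sorted(d.g.nodes)
                    ],
                    "edges": sorted(map(list, d.g.edges)),
                }
                for d in self.true_dags
            ],
            "weights": {f"{u}->{v}": w for (u, v), w in sorted(self.weights.items())},
            "planted_edges": sorted(map(list, self.planted_edges)),
            "planted_weights": {
                f"{u}->{v}": w for (u, v), w in sorted(self.planted_weights.items())
            },
            "confounders": [
                {"factor": f, "splices": sorted(ss)} for f, ss in self.confounders
            ],
            "confounder_weights": {
                f"{f}->{s}": w for (f, s), w in sorted(self.confounder_weights.items())
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _draw_weight(rng: np.random.Generator, cfg: SimulationConfig) -> float:
    w = rng.uniform(0.5, 1.5) * cfg.edge_weight_magnitude
    if rng.random() < cfg.negative_edge_prob:
        w = -w
    return float(w)


def generate_dag_population(config: SimulationConfig) -> GroundTruth:
    """Draw a population of single-unit DAGs with signed edge weights.

    Each unit has >= 1 peak, >= 1 splice and exactly one protein; every
    splice gets one primary peak parent (plus extras with probability
    ``extra_parent_prob``), orphan peaks are attached to a random splice, and
    every splice feeds the protein.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    dags = []
    weights: dict[tuple[str, str], float] = {}
    width = len(str(config.n_units))
    for u in range(config.n_units):
        uid = f"U{u + 1:0{width}d}"
        n_a = int(rng.integers(config.peaks_per_unit[0], config.peaks_per_unit[1] + 1))
        n_s = int(rng.integers(config.splices_per_unit[0], config.splices_per_unit[1] + 1))
        d = ProteinCodingUnitDAG(uid)
        prot = f"{uid}_p"
        d.add_node(prot, "p", uid)
        peaks = [f"{uid}_a{i + 1}" for i in range(n_a)]
        splices = [f"{uid}_s{j + 1}" for j in range(n_s)]
        for a in peaks:
            d.add_node(a, "a", uid)
        for s in splices:
            d.add_node(s, "s", uid)
        for s in splices:
            primary = peaks[int(rng.integers(n_a))]
            par = {primary}
            for a in peaks:
                if a != primary and rng.random() < config.extra_parent_prob:
                    par.add(a)
            for a in sorted(par):
                d.add_edge(a, s)
        for a in peaks:
            if not d.children(a):
                d.add_edge(a, splices[int(rng.integers(n_s))])
        for s in splices:
            d.add_edge(s, prot)
        d.validate()
        for e in sorted(d.g.edges):
            weights[e] = _draw_weight(rng, config)
        dags.append(d)
    return GroundTruth(true_dags=dags, weights=weights)


def plant_violations(truth: GroundTruth, config: SimulationConfig) -> GroundTruth:
    """Add hidden a->s edges and confounders to the generating equations.

    The assumed DAGs are left untouched; planted structure is recorded in
    the ledger so recovery tests know what to look for.  Units with no
    non-adjacent a-s pair (or < 2 splices, for confounders) are skipped
    with a warning.
    """
    import warnings

    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    out = GroundTruth(
        true_dags=truth.true_dags,
        weights=dict(truth.weights),
        planted_edges=list(truth.planted_edges),
        confounders=list(truth.confounders),
        planted_weights=dict(truth.planted_weights),
        confounder_weights=dict(truth.confounder_weights),
    )
    for d in truth.true_dags:
        if config.planted_extra_edge_rate > 0 and rng.random() < config.planted_extra_edge_rate:
            pairs = [
                (a, s)
                for a in d.peaks
                for s in d.splices
                if not d.g.has_edge(a, s)
            ]
            if not pairs:
                warnings.warn(f"{d.dag_id}: no non-adjacent a-s pair, planting skipped")
            else:
                a, s = pairs[int(rng.integers(len(pairs)))]
                out.planted_edges.append((a, s))
                out.planted_weights[(a, s)] = _draw_weight(rng, config)
        if config.confounder_rate > 0 and rng.random() < config.confounder_rate:
            if len(d.splices) < 2:
                warnings.warn(f"{d.dag_id}: < 2 splices, confounder skipped")
            else:
                k = 2 if len(d.splices) == 2 else int(rng.integers(2, len(d.splices) + 1))
                loaded = tuple(sorted(rng.choice(d.splices, size=k, replace=False)))
                fid = f"{d.dag_id}_h{sum(1 for f, _ in out.confounders if f.startswith(d.dag_id)) + 1}"
                out.confounders.append((fid, loaded))
                for s in loaded:
                    out.confounder_weights[(fid, s)] = _draw_weight(rng, config)
    out.validate()
    return out


def smooth_random_function(
    rng: np.random.Generator, n_basis: int, sd: float, span: tuple[float, float] = (0.0, 24.0)
):
    """Random smooth function: cubic B-spline bumps with N(0, sd^2) coefficients."""
    k = 3
    lo, hi = span
    knots = np.concatenate([[lo] * k, np.linspace(lo, hi, n_basis - k + 1), [hi] * k])
    coef = rng.normal(scale=sd, size=n_basis)
    return BSpline(knots, coef, k)


def simulate_unit_timeseries(
    truth: GroundTruth, config: SimulationConfig
) -> list[ReplicatedTimeSeries]:
    """Sample replicated series for every node of every unit.

    Deterministic given the config seed.  Root latents have unit coefficient
    scale; splice and protein equations add smooth noise with scale
    ``noise_sd``; each replicate adds iid N(0, replicate_sd^2) observation
    noise at its native sampling times.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
    grids = {
        "a": np.asarray(config.grid_a, dtype=float),
        "s": np.asarray(config.grid_s, dtype=float),
        "p": np.asarray(config.grid_p, dtype=float),
    }
    planted_by_s: dict[str, list[tuple[str, float]]] = {}
    for (a, s), w in truth.planted_weights.items():
        planted_by_s.setdefault(s, []).append((a, w))
    conf_by_s: dict[str, list[tuple[str, float]]] = {}
    for (f, s), w in truth.confounder_weights.items():
        conf_by_s.setdefault(s, []).append((f, w))

    out: list[ReplicatedTimeSeries] = []
    for d in sorted(truth.true_dags, key=lambda d: d.dag_id):
        funcs: dict[str, object] = {}
        for a in d.peaks:
            funcs[a] = smooth_random_function(rng, config.n_basis, 1.0)
        factor_funcs = {
            f: smooth_random_function(rng, config.n_basis, 1.0)
            for f, _ in truth.confounders
            if f.startswith(d.dag_id + "_h")
        }

        def mix(terms, noise_scale):
            parts = list(terms)
            eps = smooth_random_function(rng, config.n_basis, noise_scale) if noise_scale > 0 else None

            def f(t, parts=parts, eps=eps):
                v = np.zeros_like(np.asarray(t, dtype=float))
                for w, g in parts:
                    v = v + w * g(t)
                if eps is not None:
                    v = v + eps(t)
                return v

            return f

        for s in d.splices:
            terms = [(truth.weights[(a, s)], funcs[a]) for a in sorted(d.parents(s))]
            terms += [(w, funcs[a]) for a, w in sorted(planted_by_s.get(s, []))]
            terms += [
                (w, factor_funcs[f])
                for f, w in sorted(conf_by_s.get(s, []))
                if f in factor_funcs
            ]
            funcs[s] = mix(terms, config.noise_sd)
        for p in d.proteins:
            terms = [(truth.weights[(s, p)], funcs[s]) for s in sorted(d.parents(p))]
            funcs[p] = mix(terms, config.noise_sd)

        for n in sorted(d.g.nodes):
            layer = d.layer(n)
            grid = grids[layer]
            base = np.asarray(funcs[n](grid), dtype=float)
            vals = np.tile(base, (config.n_replicates, 1))
            if config.replicate_sd > 0:
                vals = vals + rng.normal(scale=config.replicate_sd, size=vals.shape)
            out.append(ReplicatedTimeSeries(n, grid, vals, layer))
    return out
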