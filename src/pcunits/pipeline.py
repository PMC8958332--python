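"""End-to-end orchestration: simulate/build -> enumerate -> correlate ->
verify -> balance -> optional stages, with seeded determinism and a run
manifest.

Outputs are data tables (TSV) plus a JSON manifest; plotting is left to the
caller.  In simulate mode the synthetic generator supplies both the assumed
DAGs and the series; in table mode the DAGs are built from association
tables and the series read from a long-format TSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .balance import classify_condition_motifs, contraction_stats, threshold_roc
from .citest import (
    TestConfig,
    aggregate_by_dag,
    aggregate_by_node,
    dominant_splice_population,
    klass_table,
    null_model_benchmark,
    subset_enrichment,
    verify_conditions,
)
from .dyncorr import detrended_normality_test, dynamical_correlation, interpolate_to_grid
from .graphs import ProteinCodingUnitDAG, add_complex_edges, build_unit_dags, merge_shared_peak_units
from .io import read_series_tsv, read_table, write_matrix_tsv, write_series_tsv, write_table
from .markov import enumerate_markov_conditions
from .synthetic import GroundTruth, SimulationConfig, generate_dag_population, plant_violations, simulate_unit_timeseries

log = logging.getLogger("pcunits")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Run settings: exactly one of simulate mode or table inputs."""

    outdir: str = "pcu_out"
    simulation: SimulationConfig | None = None
    test: TestConfig = field(default_factory=TestConfig)
    series_path: str | None = None
    peak_transcript_path: str | None = None
    transcript_protein_path: str | None = None
    complex_pairs_path: str | None = None
    subset_paths: dict[str, str] = field(default_factory=dict)
    merge_shared_peaks: bool = False
    run_null_models: bool = False
    run_balance: bool = True
    run_roc: bool = False
    run_dominant: bool = True
    run_normality: bool = True
    interp_step: float = 0.5
    interp_span: tuple[float, float] = (0.0, 24.0)
    log_level: str = "INFO"

    def validate(self) -> None:
        simulate = self.simulation is not None
        tables = self.series_path is not None
        if simulate == tables:
            raise ValueError(
                "exactly one of simulate mode (simulation config) and table "
                "mode (series/association paths) must be active"
            )
        if tables and (
            self.peak_transcript_path is None or self.transcript_protein_path is None
        ):
            raise ValueError("table mode needs peak_transcript and transcript_protein tables")
        self.test.validate()
        if simulate:
            self.simulation.validate()

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", None)
        test = d.pop("test", None)
        cfg = cls(**d)
        if sim is not None:
            cfg.simulation = SimulationConfig.from_dict(sim)
        if test is not None:
            cfg.test = TestConfig(**test)
        if isinstance(cfg.interp_span, list):
            cfg.interp_span = tuple(cfg.interp_span)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"missing config file: {path}")
        with open(path) as fh:
            payload = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        return cls.from_dict(payload)


def _config_hash(cfg: PipelineConfig) -> str:
    def default(o):
        if hasattr(o, "to_dict"):
            return o.to_dict()
        if hasattr(o, "__dict__"):
            return vars(o)
        return str(o)

    blob = json.dumps(vars(cfg), default=default, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the in-memory result bundle."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    # --- stage: inputs ------------------------------------------------
    if config.simulation is not None:
        truth = generate_dag_population(config.simulation)
        truth = plant_violations(truth, config.simulation)
        series = simulate_unit_timeseries(truth, config.simulation)
        dags: list[ProteinCodingUnitDAG] = [d.copy() for d in truth.true_dags]
        (out / "ground_truth.json").write_text(truth.to_json())
        write_series_tsv(out / "series.tsv", series)
        bundle["truth"] = truth
    else:
        series = read_series_tsv(config.series_path)
        pt = read_table(config.peak_transcript_path, {"peak_id": str, "transcript_id": str})
        tp = read_table(config.transcript_protein_path, {"transcript_id": str, "protein_id": str})
        idx = {s.variable for s in series}
        dags = build_unit_dags(pt, tp, series_index=idx)
    log.info("stage build: %d units, %d series", len(dags), len(series))

    if config.merge_shared_peaks:
        dags = merge_shared_peak_units(dags)
        log.info("stage merge: %d graphs after shared-peak merging", len(dags))
    if config.complex_pairs_path is not None:
        pairs = read_table(config.complex_pairs_path, {"protein_1": str, "protein_2": str})
        dags = add_complex_edges(dags, pairs)
    bundle["dags"] = dags

    # --- stage: enumerate --------------------------------------------
    conditions = [c for d in dags for c in enumerate_markov_conditions(d)]
    log.info("stage enumerate: %d Markov conditions", len(conditions))
    write_table(
        out / "conditions.tsv",
        pd.DataFrame(
            [
                {"dag_id": c.dag_id, "x": c.x, "y": c.y, "C": "|".join(c.C), "klass": c.klass}
                for c in conditions
            ]
        ),
    )
    bundle["conditions"] = conditions

    # --- stage: correlate --------------------------------------------
    if config.run_normality:
        norm = detrended_normality_test(series)
        write_table(out / "normality.tsv", norm)
        bundle["normality"] = norm
    interp = [
        interpolate_to_grid(s, config.interp_step, config.interp_span) for s in series
    ]
    dc = dynamical_correlation(interp)
    write_matrix_tsv(out / "R.tsv", dc.ids, dc.R)
    bundle["dyncorr"] = dc
    log.info("stage correlate: %d x %d correlation matrix", *dc.R.shape)

    # --- stage: verify -----------------------------------------------
    records = verify_conditions(conditions, dc, config.test)
    if config.run_balance:
        records = classify_condition_motifs(records, dc)
        write_table(out / "balance_crosstab.tsv", _balance_crosstab(records))
        write_table(out / "contraction.tsv", contraction_stats(records))
    write_table(out / "records.tsv", records)
    write_table(out / "node_ratios.tsv", aggregate_by_node(records))
    write_table(out / "dag_ratios.tsv", aggregate_by_dag(records))
    write_table(out / "klass_table.tsv", klass_table(records))
    bundle["records"] = records
    log.info(
        "stage verify: %d/%d conditions verified (%d skipped)",
        int(records.verified.sum()), len(records), int(records.skipped.sum()),
    )

    # --- optional stages ---------------------------------------------
    if config.run_dominant:
        dom = dominant_splice_population(dags, dc, config.test)
        write_table(out / "dominant.tsv", dom)
        bundle["dominant"] = dom
    if config.run_null_models:
        rng = np.random.default_rng(config.test.seed)
        nm = null_model_benchmark(conditions, dc, config.test, rng)
        write_table(
            out / "nullmodel.tsv",
            pd.DataFrame(
                {
                    "model": ["true", "null_y", "null_yC"],
                    "mean_success": [nm[k].mean() for k in ("true", "null_y", "null_yC")],
                    "n_nodes": [len(nm[k]) for k in ("true", "null_y", "null_yC")],
                }
            ),
        )
        bundle["nullmodel"] = nm
    if config.run_roc and config.run_balance:
        roc = {}
        for label in ("balance", "inverse_balance"):
            try:
                r = threshold_roc(records, label)
            except ValueError:
                continue
            roc[label] = r
            write_table(
                out / f"roc_{label}.tsv",
                pd.DataFrame(
                    {k: r[k] for k in ("theta", "fpr", "tpr", "precision", "recall")}
                ),
            )
        bundle["roc"] = roc
    subsets = {}
    for name, path in config.subset_paths.items():
        ids = [l.strip() for l in Path(path).read_text().split() if l.strip()]
        table, p = subset_enrichment(records, ids)
        subsets[name] = {"table": table.tolist(), "fisher_p": p}
    if subsets:
        (out / "subsets.json").write_text(json.dumps(subsets, indent=1))
        bundle["subsets"] = subsets

    manifest = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "n_dags": len(dags),
        "n_conditions": len(conditions),
        "n_verified": int(records.verified.sum()),
        "stages": sorted(bundle),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    bundle["manifest"] = manifest
    return bundle


def _balance_crosstab(records: pd.DataFrame) -> pd.DataFrame:
    """Verified x balanced cross-tabulation for both balance notions."""
    ok = records[~records.skipped]
    rows = []
    for col in ("balance_label", "inverse_balance_label"):
        sub = ok.dropna(subset=[col])
        for verified in (True, False):
            grp = sub[sub.verified == verified]
            rows.append(
                {
                    "criterion": col.replace("_label", ""),
                    "verified": verified,
                    "balanced": int((grp[col] == "balanced").sum()),
                    "unbalanced": int((grp[col] == "unbalanced").sum()),
                }
            )
    return pd.DataFrame(rows)
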