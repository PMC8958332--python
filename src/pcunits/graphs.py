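"""Protein-coding-unit DAGs.

A protein-coding unit gathers, for one gene, the chromatin-accessibility
peaks (layer 'a'), the transcript isoforms (layer 's') and the protein
(layer 'p'), with directed edges a->s (a peak sits in the promoter of the
transcript) and s->p (every coding isoform feeds the gene's protein).  All
directed paths have length at most two, so each unit is a three-layer DAG.

Units can be coupled: ~3-8% of peaks sit in promoters of transcripts of
different genes (shared peaks), and proteins can be bound in complexes,
modeled as an undirected p-p edge (the graph is then mixed, no longer a
pure Bayesian network).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "Node",
    "ProteinCodingUnitDAG",
    "APPRIS_RANKS",
    "appris_rank",
    "demo_unit",
    "assign_peaks_to_transcripts",
    "build_unit_dags",
    "merge_shared_peak_units",
    "add_complex_edges",
]

LAYERS = ("a", "s", "p")

#: Numeric rank for APPRIS-style isoform labels, 1 = most important.
APPRIS_RANKS = {
    "PRINCIPAL:1": 1,
    "PRINCIPAL:2": 2,
    "PRINCIPAL:3": 3,
    "PRINCIPAL:4": 4,
    "PRINCIPAL:5": 5,
    "ALTERNATIVE:1": 6,
    "ALTERNATIVE:2": 7,
    "MINOR": 8,
    "NON-CODING": 9,
    "ABSENT": 10,
}


def appris_rank(label: str) -> int:
    """Numeric rank of an annotation label; unknown labels count as ABSENT."""
    return APPRIS_RANKS.get(label, APPRIS_RANKS["ABSENT"])


@dataclass(frozen=True)
class Node:
    id: str
    layer: str
    unit: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")


class ProteinCodingUnitDAG:
    """Typed 3-layer DAG for one protein, or a merged joint graph.

    Thin wrapper around a :class:`networkx.DiGraph` whose nodes carry
    ``layer`` and ``unit`` attributes, plus an optional set of undirected
    p-p edges for protein-complex couplings.
    """

    def __init__(self, dag_id: str, provenance: str = "single-unit"):
        self.dag_id = dag_id
        self.provenance = provenance
        self.g = nx.DiGraph()
        self.undirected_pp: set[frozenset[str]] = set()

    # -- construction -------------------------------------------------
    def add_node(self, node_id: str, layer: str, unit: str) -> None:
        if layer not in LAYERS:
            raise ValueError(f"bad layer {layer!r} for node {node_id}")
        if node_id in self.g and self.g.nodes[node_id]["layer"] != layer:
            raise ValueError(f"node {node_id} already present with another layer")
        self.g.add_node(node_id, layer=layer, unit=unit)

    def add_edge(self, u: str, v: str) -> None:
        lu, lv = self.layer(u), self.layer(v)
        if (lu, lv) not in (("a", "s"), ("s", "p")):
            raise ValueError(f"edges must be a->s or s->p, got {lu}->{lv}")
        self.g.add_edge(u, v)

    def add_pp_edge(self, p1: str, p2: str) -> None:
        if self.layer(p1) != "p" or self.layer(p2) != "p":
            raise ValueError("undirected edges are protein-protein only")
        self.undirected_pp.add(frozenset((p1, p2)))

    # -- accessors ----------------------------------------------------
    def layer(self, node_id: str) -> str:
        try:
            return self.g.nodes[node_id]["layer"]
        except KeyError:
            raise KeyError(f"unknown node {node_id!r} in DAG {self.dag_id}") from None

    def unit(self, node_id: str) -> str:
        return self.g.nodes[node_id]["unit"]

    def nodes_in_layer(self, layer: str) -> list[str]:
        return sorted(n for n, d in self.g.nodes(data=True) if d["layer"] == layer)

    @property
    def peaks(self) -> list[str]:
        return self.nodes_in_layer("a")

    @property
    def splices(self) -> list[str]:
        return self.nodes_in_layer("s")

    @property
    def proteins(self) -> list[str]:
        return self.nodes_in_layer("p")

    @property
    def units(self) -> list[str]:
        return sorted({d["unit"] for _, d in self.g.nodes(data=True)})

    def parents(self, n: str) -> set[str]:
        return set(self.g.predecessors(n))

    def children(self, n: str) -> set[str]:
        return set(self.g.successors(n))

    def is_adjacent(self, x: str, y: str) -> bool:
        return (
            self.g.has_edge(x, y)
            or self.g.has_edge(y, x)
            or frozenset((x, y)) in self.undirected_pp
        )

    def copy(self) -> "ProteinCodingUnitDAG":
        out = ProteinCodingUnitDAG(self.dag_id, self.provenance)
        out.g = self.g.copy()
        out.undirected_pp = set(self.undirected_pp)
        return out

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        """Structural contract: acyclic, typed edges, connected layers."""
        if not nx.is_directed_acyclic_graph(self.g):
            raise ValueError(f"DAG {self.dag_id} is cyclic")
        for u, v in self.g.edges:
            lu, lv = self.layer(u), self.layer(v)
            if (lu, lv) not in (("a", "s"), ("s", "p")):
                raise ValueError(f"DAG {self.dag_id}: illegal edge {lu}->{lv}")
        for s in self.splices:
            if not any(self.layer(q) == "a" for q in self.parents(s)):
                raise ValueError(f"DAG {self.dag_id}: splice {s} has no peak parent")
            if not self.children(s):
                raise ValueError(f"DAG {self.dag_id}: splice {s} has no protein child")
        for a in self.peaks:
            if not self.children(a):
                raise ValueError(f"DAG {self.dag_id}: peak {a} has no splice child")
        if self.undirected_pp and self.provenance == "single-unit":
            raise ValueError("undirected p-p edges only on joint graphs")

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<ProteinCodingUnitDAG {self.dag_id} ({self.provenance}): "
            f"{len(self.peaks)}a/{len(self.splices)}s/{len(self.proteins)}p>"
        )


def demo_unit(dag_id: str = "DEMO") -> ProteinCodingUnitDAG:
    """The two-peak, three-splice unit used throughout the documentation.

    Edges: a1->s1, a2->s2, a2->s3, s1->p, s2->p, s3->p.
    """
    d = ProteinCodingUnitDAG(dag_id)
    for a in ("a1", "a2"):
        d.add_node(a, "a", dag_id)
    for s in ("s1", "s2", "s3"):
        d.add_node(s, "s", dag_id)
    d.add_node("p", "p", dag_id)
    for u, v in [("a1", "s1"), ("a2", "s2"), ("a2", "s3")]:
        d.add_edge(u, v)
    for s in ("s1", "s2", "s3"):
        d.add_edge(s, "p")
    return d


# ---------------------------------------------------------------------------
# genomic peak -> promoter assignment
# ---------------------------------------------------------------------------

def _read_bed(path) -> pd.DataFrame:
    """Minimal BED reader (half-open, 0-based): chrom, start, end[, name]."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line has < 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-integer BED coordinates") from None
            if start < 0 or end < start:
                raise ValueError(f"{path}:{ln}: bad BED interval [{start},{end})")
            name = parts[3] if len(parts) > 3 else f"peak_{ln}"
            rows.append((parts[0], start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_id"])


def _read_gtf_transcripts(path) -> pd.DataFrame:
    """Transcript records from a GTF (closed, 1-based -> half-open 0-based)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{ln}: GTF line has < 9 fields")
            if parts[2] != "transcript":
                continue
            try:
                start = int(parts[3]) - 1  # to half-open 0-based
                end = int(parts[4])
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-integer GTF coordinates") from None
            strand = parts[6]
            if strand not in "+-":
                raise ValueError(f"{path}:{ln}: transcript without strand")
            attrs = dict(
                (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                for kv in parts[8].rstrip(";").split(";")
                if kv.strip()
            )
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ValueError(f"{path}:{ln}: transcript record lacks transcript_id")
            rows.append((parts[0], start, end, strand, tid))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "transcript_id"]
    )


def assign_peaks_to_transcripts(
    peaks_bed,
    transcripts_gtf,
    promoter_halfwidth: int = 3000,
    flank: int = 5000,
) -> pd.DataFrame:
    """Associate peaks with transcripts through promoter-window overlap.

    The promoter is the window [TSS - halfwidth, TSS + halfwidth] around the
    strand-aware transcription start site; a peak and a transcript are
    associated iff the peak interval (half-open) overlaps that window.  The
    ``flank`` distance acts as a pre-filter on candidate transcripts: peaks
    farther than ``flank`` bp from the transcript body are never considered.
    Accepts file paths (BED / GTF) or pre-parsed DataFrames with the columns
    produced by the internal readers.

    Returns a two-column association table (peak_id, transcript_id); one peak
    may map to many transcripts and vice versa.
    """
    peaks = peaks_bed if isinstance(peaks_bed, pd.DataFrame) else _read_bed(peaks_bed)
    txs = (
        transcripts_gtf
        if isinstance(transcripts_gtf, pd.DataFrame)
        else _read_gtf_transcripts(transcripts_gtf)
    )
    out = []
    for tx in txs.itertuples():
        tss = tx.start if tx.strand == "+" else tx.end - 1
        win_lo, win_hi = max(0, tss - promoter_halfwidth), tss + promoter_halfwidth + 1
        body_lo, body_hi = max(0, tx.start - flank), tx.end + flank
        cand = peaks[
            (peaks.chrom == tx.chrom)
            & (peaks.end > body_lo)
            & (peaks.start < body_hi)
        ]
        hit = cand[(cand.end > win_lo) & (cand.start < win_hi)]
        out.extend((pid, tx.transcript_id) for pid in hit.peak_id)
    return pd.DataFrame(sorted(set(out)), columns=["peak_id", "transcript_id"])


# ---------------------------------------------------------------------------
# building units from association tables
# ---------------------------------------------------------------------------

def build_unit_dags(
    peak_transcript: pd.DataFrame,
    transcript_protein: pd.DataFrame,
    series_index: set[str] | None = None,
    coding_flags: dict[str, bool] | None = None,
) -> list[ProteinCodingUnitDAG]:
    """One DAG per protein with >= 1 surviving splice and >= 1 peak.

    Splices are dropped when flagged non-coding, missing from
    ``series_index`` (when given), or left without any peak; peaks are
    dropped when all their splices drop.  Units losing every splice are
    omitted with a warning.  The result is sorted by unit id.
    """
    for col in ("peak_id", "transcript_id"):
        if col not in peak_transcript.columns:
            raise ValueError(f"peak_transcript table lacks column {col!r}")
    for col in ("transcript_id", "protein_id"):
        if col not in transcript_protein.columns:
            raise ValueError(f"transcript_protein table lacks column {col!r}")

    tx_peaks: dict[str, set[str]] = {}
    for row in peak_transcript.itertuples():
        tx_peaks.setdefault(row.transcript_id, set()).add(row.peak_id)

    dags = []
    for protein, grp in sorted(transcript_protein.groupby("protein_id")):
        keep = []
        for tx in sorted(set(grp.transcript_id)):
            if coding_flags is not None and not coding_flags.get(tx, True):
                continue
            if series_index is not None and tx not in series_index:
                continue
            peaks = tx_peaks.get(tx, set())
            if series_index is not None:
                peaks = {a for a in peaks if a in series_index}
            if not peaks:
                continue
            keep.append((tx, peaks))
        if not keep:
            warnings.warn(f"unit {protein}: no surviving splice, omitted")
            continue
        if series_index is not None and protein not in series_index:
            warnings.warn(f"unit {protein}: protein series missing, omitted")
            continue
        d = ProteinCodingUnitDAG(str(protein))
        d.add_node(str(protein), "p", str(protein))
        for tx, peaks in keep:
            d.add_node(tx, "s", str(protein))
            for a in sorted(peaks):
                d.add_node(a, "a", str(protein))
                d.add_edge(a, tx)
            d.add_edge(tx, str(protein))
        d.validate()
        dags.append(d)
    return dags


def merge_shared_peak_units(
    dags: list[ProteinCodingUnitDAG],
) -> list[ProteinCodingUnitDAG]:
    """Merge units sharing >= 1 peak (transitive closure of sharing).

    Shared peaks appear once in the joint DAG with children in every member
    unit.  Units sharing nothing pass through unchanged.  Idempotent and
    order-independent.
    """
    parent = {i: i for i in range(len(dags))}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    peak_owner: dict[str, int] = {}
    for i, d in enumerate(dags):
        for a in d.peaks:
            if a in peak_owner:
                union(i, peak_owner[a])
            else:
                peak_owner[a] = i

    groups: dict[int, list[int]] = {}
    for i in range(len(dags)):
        groups.setdefault(find(i), []).append(i)

    out = []
    for members in groups.values():
        members = sorted(members, key=lambda i: dags[i].dag_id)
        if len(members) == 1:
            out.append(dags[members[0]].copy())
            continue
        joint = ProteinCodingUnitDAG(
            "+".join(dags[i].dag_id for i in members), provenance="shared-peak-joint"
        )
        for i in members:
            d = dags[i]
            for n, data in d.g.nodes(data=True):
                joint.add_node(n, data["layer"], data["unit"])
            for u, v in d.g.edges:
                joint.add_edge(u, v)
        joint.validate()
        out.append(joint)
    return sorted(out, key=lambda d: d.dag_id)


def add_complex_edges(
    dags: list[ProteinCodingUnitDAG],
    complex_pairs: pd.DataFrame,
) -> list[ProteinCodingUnitDAG]:
    """Couple units whose proteins form a complex with an undirected p-p edge.

    ``complex_pairs`` has columns protein_1, protein_2.  For each pair whose
    proteins live in the current DAG set, the involved DAGs are merged into a
    joint mixed graph carrying the undirected edge; if both proteins already
    share a joint DAG the edge is added there.  Pairs referencing unknown
    proteins are skipped with a warning.
    """
    for col in ("protein_1", "protein_2"):
        if col not in complex_pairs.columns:
            raise ValueError(f"complex pair table lacks column {col!r}")
    out = [d.copy() for d in dags]
    where = {p: i for i, d in enumerate(out) for p in d.proteins}
    for row in complex_pairs.itertuples():
        p1, p2 = str(row.protein_1), str(row.protein_2)
        if p1 not in where or p2 not in where:
            warnings.warn(f"complex pair ({p1},{p2}) references unknown protein, skipped")
            continue
        i, j = where[p1], where[p2]
        if i == j:
            target = out[i]
        else:
            a, b = out[min(i, j)], out[max(i, j)]
            target = ProteinCodingUnitDAG(
                "+".join(sorted((a.dag_id, b.dag_id))), provenance="complex-joint"
            )
            for src in (a, b):
                for n, data in src.g.nodes(data=True):
                    target.add_node(n, data["layer"], data["unit"])
                for u, v in src.g.edges:
                    target.add_edge(u, v)
                target.undirected_pp |= src.undirected_pp
            lo, hi = min(i, j), max(i, j)
            out[lo] = target
            out.pop(hi)
            where = {p: k for k, d in enumerate(out) for p in d.proteins}
            target = out[lo]
        if target.provenance == "single-unit":
            target.provenance = "complex-joint"
        target.add_pp_edge(p1, p2)
    return sorted(out, key=lambda d: d.dag_id)
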