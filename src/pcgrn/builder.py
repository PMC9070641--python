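"""Bottom-up assembly of the multi-layer hierarchical GRN, plus summaries,
recovery scoring against a planted truth, and graph serialization.

Construction proceeds from the structural genes upward.  Co-expressed pairs
are enumerated within the current bottom layer; every candidate regulator
that breaks at least ``min_pairs_broken`` of those pairs (partial
correlation below threshold) is assigned to the next layer up and receives
directed edges to both members of each pair it broke.  The freshly
assigned regulators then serve as the bottom for the next round, with
already-placed regulators removed from the candidate pool — layers are
disjoint by construction.  The process stops after ``n_layers − 1`` rounds
or as soon as a round assigns nobody.

Only adjacent-layer, downward edges are represented.  Within-layer and
layer-skipping regulation is deliberately out of the model: the layered
picture trades that completeness for an interpretable hierarchy.

All iteration is in lexicographic gene-id order, so identical inputs give
identical networks on any platform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .datamodel import ExpressionMatrix, GeneCatalog, ProcessMap, ROLE_REGULATOR
from .correlation import (
    CoexpressedPair,
    ThresholdConfig,
    _break_decision,
    _correlation_submatrix,
    _p_from_cc,
    _pair_passes,
)

__all__ = [
    "Edge",
    "HierarchicalGRN",
    "GrnSummary",
    "RecoveryReport",
    "infer_layer",
    "build_hierarchical_grn",
    "summarize_grn",
    "score_recovery",
    "write_edge_tsv",
    "read_edge_tsv",
    "write_layers_tsv",
    "read_layers_tsv",
    "write_sif",
    "read_sif",
    "write_graphml",
    "read_graphml",
    "read_grn",
]


@dataclass(frozen=True)
class Edge:
    """Directed regulator → target edge with its supporting evidence:
    the co-expressed pairs the regulator broke that involve the target,
    each with the achieved partial correlation."""

    regulator: str
    target: str
    evidence: Tuple[Tuple[CoexpressedPair, float], ...] = ()

    @property
    def key(self) -> Tuple[str, str]:
        return (self.regulator, self.target)

    @property
    def n_supporting_pairs(self) -> int:
        return len(self.evidence)

    @property
    def min_abs_pcc(self) -> Optional[float]:
        if not self.evidence:
            return None
        return min(abs(p) for _, p in self.evidence)


@dataclass
class HierarchicalGRN:
    """Ordered disjoint layers (index 0 = top) plus adjacent-layer edges.

    ``unplaced_regulators`` holds catalog regulators that were candidates
    but never assigned to any layer.
    """

    layers: List[Set[str]]
    edges: List[Edge]
    unplaced_regulators: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def bottom_layer(self) -> Set[str]:
        return self.layers[-1] if self.layers else set()

    def layer_of(self) -> Dict[str, int]:
        """gene id → 1-based layer index (1 = top)."""
        out: Dict[str, int] = {}
        for i, layer in enumerate(self.layers, start=1):
            for g in layer:
                out[g] = i
        return out

    def edge_keys(self) -> Set[Tuple[str, str]]:
        return {e.key for e in self.edges}

    def validate(self) -> None:
        seen: Set[str] = set()
        for i, layer in enumerate(self.layers):
            overlap = seen & set(layer)
            if overlap:
                raise ValueError(f"layers not disjoint: {sorted(overlap)}")
            seen |= set(layer)
        idx = self.layer_of()
        keys: Set[Tuple[str, str]] = set()
        for e in self.edges:
            if e.key in keys:
                raise ValueError(f"duplicate edge {e.key}")
            keys.add(e.key)
            if e.regulator not in idx or e.target not in idx:
                raise ValueError(f"edge {e.key} references an unplaced gene")
            if idx[e.target] != idx[e.regulator] + 1:
                raise ValueError(
                    f"edge {e.key} does not connect adjacent layers downward"
                )
        sources = {e.regulator for e in self.edges}
        for layer in self.layers[:-1]:
            dangling = set(layer) - sources
            if dangling:
                raise ValueError(
                    f"non-bottom genes without outgoing edges: {sorted(dangling)}"
                )
        if self.unplaced_regulators & seen:
            raise ValueError("unplaced regulators overlap placed layers")


def infer_layer(
    bottom: Iterable[str],
    candidates: Iterable[str],
    matrix: ExpressionMatrix,
    config: Optional[ThresholdConfig] = None,
    min_pairs_broken: int = 1,
) -> Tuple[Set[str], List[Edge]]:
    """One inference round: which candidates regulate the bottom genes?

    Enumerates co-expressed pairs within ``bottom``, tests every candidate
    against every pair, and assigns each candidate that breaks at least
    ``min_pairs_broken`` pairs.  Edges run from the assigned candidate to
    both members of each broken pair, deduplicated, with the pair evidence
    retained.
    """
    config = config or ThresholdConfig()
    bottom_list = sorted(set(bottom))
    cand_list = sorted(set(candidates))
    clash = set(bottom_list) & set(cand_list)
    if clash:
        raise ValueError(f"candidates overlap bottom layer: {sorted(clash)}")
    if len(bottom_list) < 2:
        warnings.warn("bottom layer has < 2 genes; no pairs exist", stacklevel=2)
        return set(), []
    if not cand_list:
        return set(), []

    genes = bottom_list + cand_list
    R = _correlation_submatrix(matrix, genes)
    n = matrix.n_samples
    pos = {g: i for i, g in enumerate(genes)}

    pairs: List[CoexpressedPair] = []
    for i in range(len(bottom_list)):
        for j in range(i + 1, len(bottom_list)):
            cc = float(R[i, j])
            p = _p_from_cc(cc, n)
            if _pair_passes(cc, p, config):
                pairs.append(
                    CoexpressedPair.make(bottom_list[i], bottom_list[j], cc, p)
                )

    broken: Dict[str, List[Tuple[CoexpressedPair, float]]] = {c: [] for c in cand_list}
    for pair in pairs:
        ia, ib = pos[pair.gene_a], pos[pair.gene_b]
        for c in cand_list:
            ic = pos[c]
            pcc, breaks = _break_decision(
                pair.cc, float(R[ia, ic]), float(R[ib, ic]), config
            )
            if breaks:
                broken[c].append((pair, pcc))

    assigned = {c for c in cand_list if len(broken[c]) >= min_pairs_broken}
    evidence: Dict[Tuple[str, str], List[Tuple[CoexpressedPair, float]]] = {}
    for c in sorted(assigned):
        for pair, pcc in broken[c]:
            for target in pair.members:
                evidence.setdefault((c, target), []).append((pair, pcc))
    edges = [
        Edge(regulator=r, target=t, evidence=tuple(ev))
        for (r, t), ev in sorted(evidence.items())
    ]
    return assigned, edges


def build_hierarchical_grn(
    matrix: ExpressionMatrix,
    catalog: GeneCatalog,
    bottom_genes: Iterable[str],
    n_layers: int = 3,
    config: Optional[ThresholdConfig] = None,
    min_pairs_broken: int = 1,
) -> HierarchicalGRN:
    """Build the full hierarchy from the structural bottom layer upward.

    ``bottom_genes`` must all carry the structural role.  The candidate pool
    is every catalog regulator present in the matrix; once assigned, a
    regulator leaves the pool (layers are exclusive).  Stops early, without
    error, when a round assigns no regulator.
    """
    if n_layers < 2:
        raise ValueError("n_layers must be >= 2")
    config = config or ThresholdConfig()
    bottom_list = sorted(set(bottom_genes))
    for g in bottom_list:
        if catalog.role_by_gene.get(g) == ROLE_REGULATOR:
            raise ValueError(f"bottom gene {g!r} has regulator role")
    matrix_genes = set(matrix.gene_ids)
    missing = [g for g in bottom_list if g not in matrix_genes]
    if missing:
        raise KeyError(f"bottom genes not in matrix: {missing}")
    pool = sorted(set(catalog.regulators) & matrix_genes)

    layers_bottom_up: List[Set[str]] = [set(bottom_list)]
    edges_bottom_up: List[List[Edge]] = []
    current = bottom_list
    remaining = list(pool)
    for _ in range(n_layers - 1):
        if len(current) < 2 or not remaining:
            break
        assigned, edges = infer_layer(
            current, remaining, matrix, config, min_pairs_broken=min_pairs_broken
        )
        if not assigned:
            break
        layers_bottom_up.append(assigned)
        edges_bottom_up.append(edges)
        remaining = [r for r in remaining if r not in assigned]
        current = sorted(assigned)

    layers = list(reversed(layers_bottom_up))
    edges: List[Edge] = []
    for round_edges in edges_bottom_up:
        edges.extend(round_edges)
    edges.sort(key=lambda e: e.key)
    return HierarchicalGRN(
        layers=layers, edges=edges, unplaced_regulators=set(remaining)
    )


# -- summaries -------------------------------------------------------------


@dataclass
class GrnSummary:
    """Composition report: layer sizes, edge counts per interface, regulator
    out-degrees, bottom genes reachable from each top regulator through one
    intermediary, and per-process regulated/total tallies."""

    per_layer_counts: List[int]
    edge_count_total: int
    edge_counts_between_layers: List[int]
    out_degree_by_regulator: Dict[str, int]
    regulated_targets_by_top_regulator: Dict[str, Set[str]]
    per_process_counts: Dict[str, Tuple[int, int]]

    def to_dict(self) -> dict:
        return {
            "per_layer_counts": list(self.per_layer_counts),
            "edge_count_total": self.edge_count_total,
            "edge_counts_between_layers": list(self.edge_counts_between_layers),
            "out_degree_by_regulator": dict(sorted(self.out_degree_by_regulator.items())),
            "regulated_targets_by_top_regulator": {
                k: sorted(v)
                for k, v in sorted(self.regulated_targets_by_top_regulator.items())
            },
            "per_process_counts": {
                k: {"regulated": v[0], "total": v[1]}
                for k, v in sorted(self.per_process_counts.items())
            },
        }


def summarize_grn(
    grn: HierarchicalGRN, processes: Optional[ProcessMap] = None
) -> GrnSummary:
    """Count layers, edges and per-process regulated bottom genes."""
    idx = grn.layer_of()
    per_layer = [len(layer) for layer in grn.layers]
    counts_between = [0] * max(grn.n_layers - 1, 0)
    out_deg: Dict[str, int] = {}
    for e in grn.edges:
        counts_between[idx[e.regulator] - 1] += 1
        out_deg[e.regulator] = out_deg.get(e.regulator, 0) + 1

    two_hop: Dict[str, Set[str]] = {}
    if grn.n_layers >= 1 and grn.layers:
        children: Dict[str, Set[str]] = {}
        for e in grn.edges:
            children.setdefault(e.regulator, set()).add(e.target)
        for g in sorted(grn.layers[0]):
            reach: Set[str] = set()
            for mid in children.get(g, ()):  # one intermediary
                reach |= children.get(mid, set())
            two_hop[g] = reach

    per_process: Dict[str, Tuple[int, int]] = {}
    if processes is not None:
        bottom = grn.bottom_layer
        with_parent = {e.target for e in grn.edges} & bottom
        for name, members in processes.sets.items():
            in_bottom = members & bottom
            per_process[name] = (len(in_bottom & with_parent), len(in_bottom))

    return GrnSummary(
        per_layer_counts=per_layer,
        edge_count_total=len(grn.edges),
        edge_counts_between_layers=counts_between,
        out_degree_by_regulator=out_deg,
        regulated_targets_by_top_regulator=two_hop,
        per_process_counts=per_process,
    )


# -- recovery scoring ------------------------------------------------------


def _prf(pred: Set, truth: Set) -> Tuple[Optional[float], Optional[float]]:
    precision = len(pred & truth) / len(pred) if pred else None
    recall = len(pred & truth) / len(truth) if truth else None
    return precision, recall


@dataclass
class RecoveryReport:
    """How well an inferred hierarchy matches a planted ground truth.

    Layers are aligned from the bottom (offset 0 = bottom layer), since the
    bottom is given and both objects grow upward from it.  ``layer_metrics``
    and ``edge_metrics`` are keyed by that bottom offset; edge interface k
    connects offset k+1 regulators to offset k targets.  Precision is None
    (undefined) where nothing was predicted.
    """

    layer_metrics: List[dict]
    edge_metrics: List[dict]
    edge_precision: Optional[float]
    edge_recall: Optional[float]
    membership_accuracy: float
    exact_layers: bool
    exact_edges: bool

    def to_dict(self) -> dict:
        return {
            "layer_metrics": self.layer_metrics,
            "edge_metrics": self.edge_metrics,
            "edge_precision": self.edge_precision,
            "edge_recall": self.edge_recall,
            "membership_accuracy": self.membership_accuracy,
            "exact_layers": self.exact_layers,
            "exact_edges": self.exact_edges,
        }


def score_recovery(inferred: HierarchicalGRN, truth) -> RecoveryReport:
    """Score layer membership and edge recovery against a planted network.

    ``truth`` needs ``layers`` (ordered top-first) and an iterable ``edges``
    whose items expose ``regulator``/``target`` attributes or are
    (regulator, target, ...) tuples — both :class:`HierarchicalGRN` and the
    simulator's planted networks qualify.
    """
    truth_layers: List[Set[str]] = [set(l) for l in truth.layers]
    truth_edges: Set[Tuple[str, str]] = set()
    for e in truth.edges:
        if hasattr(e, "regulator"):
            truth_edges.add((e.regulator, e.target))
        else:
            truth_edges.add((e[0], e[1]))
    inf_layers = [set(l) for l in inferred.layers]
    inf_edges = inferred.edge_keys()

    def from_bottom(layers: List[Set[str]], offset: int) -> Set[str]:
        k = len(layers) - 1 - offset
        return layers[k] if 0 <= k < len(layers) else set()

    n_off = max(len(truth_layers), len(inf_layers))
    layer_metrics: List[dict] = []
    correct = 0
    universe = 0
    for off in range(n_off):
        t = from_bottom(truth_layers, off)
        p = from_bottom(inf_layers, off)
        precision, recall = _prf(p, t)
        layer_metrics.append(
            {
                "offset_from_bottom": off,
                "truth_size": len(t),
                "inferred_size": len(p),
                "precision": precision,
                "recall": recall,
                "exact": p == t,
            }
        )
        correct += len(p & t)
        universe += len(t)
    membership_accuracy = correct / universe if universe else 1.0

    # per-interface edge metrics, keyed by the truth layer of the target
    t_off = {}
    for off in range(len(truth_layers)):
        for g in from_bottom(truth_layers, off):
            t_off[g] = off
    i_off = {}
    for off in range(len(inf_layers)):
        for g in from_bottom(inf_layers, off):
            i_off[g] = off
    edge_metrics: List[dict] = []
    for off in range(n_off - 1):
        t_edges = {e for e in truth_edges if t_off.get(e[1]) == off}
        p_edges = {e for e in inf_edges if i_off.get(e[1]) == off}
        precision = len(p_edges & truth_edges) / len(p_edges) if p_edges else None
        recall = len(t_edges & inf_edges) / len(t_edges) if t_edges else None
        edge_metrics.append(
            {
                "target_offset_from_bottom": off,
                "truth_edges": len(t_edges),
                "inferred_edges": len(p_edges),
                "precision": precision,
                "recall": recall,
            }
        )
    precision, recall = _prf(inf_edges, truth_edges)
    return RecoveryReport(
        layer_metrics=layer_metrics,
        edge_metrics=edge_metrics,
        edge_precision=precision,
        edge_recall=recall,
        membership_accuracy=membership_accuracy,
        exact_layers=[set(l) for l in inf_layers] == [set(l) for l in truth_layers],
        exact_edges=inf_edges == truth_edges,
    )


# -- serialization ---------------------------------------------------------


def write_edge_tsv(grn: HierarchicalGRN, path, float_fmt: str = "%.6g") -> None:
    idx = grn.layer_of()
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(
            "regulator\ttarget\tlayer_from\tlayer_to\tn_supporting_pairs\tmin_abs_pcc\n"
        )
        for e in sorted(grn.edges, key=lambda e: e.key):
            mp = e.min_abs_pcc
            fh.write(
                f"{e.regulator}\t{e.target}\t{idx[e.regulator]}\t{idx[e.target]}\t"
                f"{e.n_supporting_pairs}\t{'NA' if mp is None else float_fmt % mp}\n"
            )


def read_edge_tsv(path) -> List[Tuple[str, str, int, int]]:
    """Read an edge-list TSV; returns (regulator, target, layer_from, layer_to)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        need = ("regulator", "target", "layer_from", "layer_to")
        if not all(c in header for c in need):
            raise ValueError(f"edge table must have columns {need}")
        col = {c: header.index(c) for c in need}
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            out.append(
                (
                    parts[col["regulator"]],
                    parts[col["target"]],
                    int(parts[col["layer_from"]]),
                    int(parts[col["layer_to"]]),
                )
            )
    return out


def write_layers_tsv(grn: HierarchicalGRN, path) -> None:
    """gene → 1-based layer index; unplaced regulators get layer 0."""
    idx = grn.layer_of()
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene_id\tlayer\n")
        for g in sorted(idx):
            fh.write(f"{g}\t{idx[g]}\n")
        for g in sorted(grn.unplaced_regulators):
            fh.write(f"{g}\t0\n")


def read_layers_tsv(path) -> Tuple[List[Set[str]], Set[str]]:
    by_layer: Dict[int, Set[str]] = {}
    unplaced: Set[str] = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            g, k = line.rstrip("\n").split("\t")[:2]
            k = int(k)
            if k == 0:
                unplaced.add(g)
            else:
                by_layer.setdefault(k, set()).add(g)
    if not by_layer:
        return [], unplaced
    layers = [by_layer.get(k, set()) for k in range(1, max(by_layer) + 1)]
    return layers, unplaced


def read_grn(edges_path, layers_path) -> HierarchicalGRN:
    """Rebuild a HierarchicalGRN (without pair evidence) from its TSVs."""
    layers, unplaced = read_layers_tsv(layers_path)
    edges = [
        Edge(regulator=r, target=t)
        for r, t, _, _ in read_edge_tsv(edges_path)
    ]
    return HierarchicalGRN(layers=layers, edges=edges, unplaced_regulators=unplaced)


def write_sif(grn: HierarchicalGRN, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for e in sorted(grn.edges, key=lambda e: e.key):
            fh.write(f"{e.regulator}\tregulates\t{e.target}\n")


def read_sif(path) -> Set[Tuple[str, str]]:
    out: Set[Tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3 or parts[1] != "regulates":
                raise ValueError(f"malformed SIF line: {line!r}")
            out.add((parts[0], parts[2]))
    return out


def write_graphml(grn: HierarchicalGRN, path) -> None:
    g = nx.DiGraph()
    idx = grn.layer_of()
    for gene in sorted(idx):
        g.add_node(gene, layer=idx[gene])
    for e in sorted(grn.edges, key=lambda e: e.key):
        mp = e.min_abs_pcc
        attrs = {"n_supporting_pairs": e.n_supporting_pairs}
        if mp is not None:
            attrs["min_abs_pcc"] = float(mp)
        g.add_edge(e.regulator, e.target, **attrs)
    nx.write_graphml(g, str(path))


def read_graphml(path) -> HierarchicalGRN:
    g = nx.read_graphml(str(path))
    by_layer: Dict[int, Set[str]] = {}
    for node, data in g.nodes(data=True):
        by_layer.setdefault(int(data["layer"]), set()).add(node)
    layers = [by_layer.get(k, set()) for k in range(1, max(by_layer, default=0) + 1)]
    edges = [Edge(regulator=u, target=v) for u, v in sorted(g.edges())]
    return HierarchicalGRN(layers=layers, edges=edges)
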