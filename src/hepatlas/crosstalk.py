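"""Hierarchical ligand→receptor→TF→target crosstalk network construction.

The model connects nonparenchymal sender cells to a parenchymal receiver
(hepatocytes in the liver): ligands that are enhanced in — or secreted by — a
sender are paired with receptors detected in the receiver; receptors are
linked to transcription factors through *active* signaling pathways
(hypergeometric enrichment of enhanced constituent proteins at raw p < 0.05
AND every pathway node detected in the proteomic or transcriptomic profile);
the simplified network keeps ligand→receptor edges, direct receptor→TF edges
annotated with the originating pathway and the shortest directed path length
(in edges), and TF→target edges from a TF-target table.

Path lengths of edges ending at cell-specific TFs can then be compared with
those of all TFs with a Mann-Whitney U test.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import numpy as np

from .differential import MWUResult, hypergeom_pvalue, mann_whitney_u
from .errors import ValidationError
from .io_formats import (
    AbundanceMatrix,
    LigandReceptorDB,
    OrthologyMap,
    PathwayGraph,
    TFTargetMap,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Candidate ligand-receptor interactions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidateInteraction:
    """A ligand-receptor pair between one sender cell type and the receiver."""

    ligand: str
    sender: str
    receptor: str
    receiver: str
    evidence: str  # "enhanced" | "secreted" | "both"


def detected_in_receiver(
    matrix: AbundanceMatrix,
    receiver_cell: str,
    transcriptome: AbundanceMatrix | None = None,
    fpkm_threshold: float = 1.0,
) -> set[str]:
    """Genes detected in the receiver: FOT > 0 in any replicate, or FPKM
    strictly above threshold when a transcriptome is supplied."""
    detected = matrix.detected(receiver_cell)
    if transcriptome is not None:
        sub = transcriptome.data[transcriptome.columns_for(receiver_cell)]
        detected |= set(sub.index[(sub.to_numpy() > fpkm_threshold).any(axis=1)])
    return detected


def select_candidates(
    lr_db: LigandReceptorDB,
    matrix: AbundanceMatrix,
    secretome_sets: dict,
    sender_cells,
    receiver_cell: str,
    enhanced_calls: dict,
    transcriptome: AbundanceMatrix | None = None,
    fpkm_threshold: float = 1.0,
) -> list[CandidateInteraction]:
    """Retrieve potential crosstalk components: ligands enhanced in or
    secreted by a sender, paired with receptors expressed in the receiver.

    ``enhanced_calls`` maps sender cell type to its
    :class:`~hepatlas.differential.EnhancedCallSet`. One candidate is
    produced per (pair, sender); the output is sorted by
    (ligand, receptor, sender).
    """
    if receiver_cell not in matrix.cell_types:
        raise ValidationError(f"receiver cell {receiver_cell!r} not in matrix")
    for sender in sender_cells:
        if sender not in enhanced_calls:
            raise ValidationError(f"no enhanced call set for sender {sender!r}")
    receiver_detected = detected_in_receiver(
        matrix, receiver_cell, transcriptome, fpkm_threshold
    )
    out = []
    for ligand, receptor, _src in lr_db.pairs:
        if receptor not in receiver_detected:
            continue
        for sender in sender_cells:
            enhanced = ligand in enhanced_calls[sender].genes
            secreted = ligand in secretome_sets.get(sender, frozenset())
            if not (enhanced or secreted):
                continue
            evidence = "both" if (enhanced and secreted) else (
                "enhanced" if enhanced else "secreted"
            )
            out.append(
                CandidateInteraction(ligand, sender, receptor, receiver_cell, evidence)
            )
    out.sort(key=lambda c: (c.ligand, c.receptor, c.sender))
    return out


# ---------------------------------------------------------------------------
# Active pathways
# ---------------------------------------------------------------------------


@dataclass
class ActivePathwayCall:
    """Pathway activity: enriched enhanced constituents AND all nodes detected."""

    name: str
    p: float
    k: int
    m: int
    all_detected: bool
    active: bool


def call_active_pathways(
    pathways,
    enhanced_union,
    detected_union,
    universe,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> list[ActivePathwayCall]:
    """Call each pathway active when its node set is enriched in enhanced
    proteins (hypergeometric, raw p < ``alpha``) and every node is detected.

    ``universe`` should be all detected genes (proteome ∪ expressed
    transcriptome). The activity rule uses the raw p by default;
    ``bonferroni=True`` multiplies by the number of pathways with nodes in
    the universe for a stricter call.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    enhanced = set(enhanced_union) & universe
    detected = set(detected_union)
    N, q = len(universe), len(enhanced)
    prelim = []
    n_tested = 0
    for pw in pathways:
        nodes = set(pw.node_set)
        members = nodes & universe
        m = len(members)
        if m == 0:
            prelim.append((pw.name, 1.0, 0, 0, False))
            continue
        n_tested += 1
        k = len(enhanced & members)
        p = hypergeom_pvalue(k, N, m, q) if q > 0 else 1.0
        prelim.append((pw.name, p, k, m, nodes <= detected))
    factor = max(n_tested, 1) if bonferroni else 1
    out = []
    for name, p, k, m, flag in prelim:
        p_eff = min(1.0, p * factor)
        out.append(
            ActivePathwayCall(
                name=name, p=p_eff, k=k, m=m, all_detected=flag,
                active=(p_eff < alpha) and flag,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Shortest paths (in-package BFS with a lexicographic witness)
# ---------------------------------------------------------------------------


def _bfs_distances(adj: dict, source: str) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj.get(u, ()):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def shortest_path_lex(graph, source: str, target: str) -> list[str] | None:
    """Shortest directed path from source to target; among equally short
    paths, the lexicographically smallest node sequence. None if unreachable."""
    radj: dict = {}
    for u, v in graph.edges:
        radj.setdefault(v, []).append(u)
    dist_to_target = _bfs_distances(radj, target)
    if source not in dist_to_target:
        return None
    adj: dict = {}
    for u, v in graph.edges:
        adj.setdefault(u, []).append(v)
    for u in adj:
        adj[u].sort()
    path = [source]
    current = source
    while current != target:
        step = dist_to_target[current]
        for v in adj.get(current, ()):  # sorted: first admissible is lex-smallest
            if dist_to_target.get(v, -1) == step - 1:
                path.append(v)
                current = v
                break
        else:  # pragma: no cover - unreachable given dist bookkeeping
            return None
    return path


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReceptorTFEdge:
    """A simplified receptor→TF link with pathway provenance."""

    receptor: str
    tf: str
    pathway: str
    length: int  # edges on the shortest directed receptor→TF path
    path: tuple  # witness node sequence (lexicographically smallest)
    tf_specific: bool


@dataclass
class CrosstalkNetwork:
    """Layered crosstalk network: ligand→receptor, receptor→TF, TF→target."""

    candidates: tuple  # retained CandidateInteraction entries
    receptor_tf_edges: tuple  # ReceptorTFEdge entries
    tf_targets: dict  # tf -> frozenset of attached target genes

    @property
    def receptors(self) -> set[str]:
        return {e.receptor for e in self.receptor_tf_edges}

    @property
    def tfs(self) -> set[str]:
        return {e.tf for e in self.receptor_tf_edges}

    def is_empty(self) -> bool:
        return not self.receptor_tf_edges


def build_network(
    candidates,
    active_calls,
    pathways,
    specific_tfs,
    tf_targets: TFTargetMap,
    receiver_detected=None,
) -> CrosstalkNetwork:
    """Combine active pathways into the simplified crosstalk network.

    For every candidate receptor and every TF node reachable from it inside
    an active pathway graph, one receptor→TF edge is recorded with the
    overall shortest path length; ties between pathways break on pathway
    name, then on the lexicographic witness path. Candidates whose receptor
    reaches no TF are dropped. TF target sets are restricted to
    ``receiver_detected`` when given. An empty network is valid output.
    """
    specific_tfs = set(specific_tfs)
    active_names = {c.name for c in active_calls if c.active}
    by_name = {pw.name: pw for pw in pathways}
    unknown = active_names - set(by_name)
    if unknown:
        raise ValidationError(f"active pathways without graphs: {sorted(unknown)}")

    best: dict = {}  # (receptor, tf) -> (length, pathway, path)
    receptors = sorted({c.receptor for c in candidates})
    for name in sorted(active_names):
        graph = by_name[name].graph
        tf_nodes = by_name[name].nodes_with_role("tf")
        adj: dict = {}
        for u, v in graph.edges:
            adj.setdefault(u, []).append(v)
        for rec in receptors:
            if rec not in graph:
                continue
            dist = _bfs_distances(adj, rec)
            for tf in sorted(tf_nodes):
                if tf == rec or tf not in dist:
                    continue
                key = (rec, tf)
                cand = (dist[tf], name)
                if key not in best or cand < (best[key][0], best[key][1]):
                    path = shortest_path_lex(graph, rec, tf)
                    best[key] = (dist[tf], name, tuple(path))

    edges = tuple(
        ReceptorTFEdge(
            receptor=rec, tf=tf, pathway=name, length=length, path=path,
            tf_specific=tf in specific_tfs,
        )
        for (rec, tf), (length, name, path) in sorted(best.items())
    )
    linked_receptors = {e.receptor for e in edges}
    kept = tuple(c for c in candidates if c.receptor in linked_receptors)
    attached: dict = {}
    for tf in sorted({e.tf for e in edges}):
        targets = set(tf_targets.get(tf))
        if receiver_detected is not None:
            targets &= set(receiver_detected)
        if targets:
            attached[tf] = frozenset(targets)
    return CrosstalkNetwork(candidates=kept, receptor_tf_edges=edges, tf_targets=attached)


# ---------------------------------------------------------------------------
# Path-length comparison
# ---------------------------------------------------------------------------


@dataclass
class PathLengthComparison:
    """Shortest-path lengths for specific-TF edges vs a reference group."""

    lengths_specific: np.ndarray
    lengths_reference: np.ndarray
    mean_specific: float
    mean_reference: float
    mwu: MWUResult
    mode: str  # "all" (reference = every TF) or "nonspecific"


def compare_path_lengths(
    network: CrosstalkNetwork, specific_tfs, mode: str = "all"
) -> PathLengthComparison:
    """Compare receptor→TF path lengths ending at specific TFs against all
    TFs (``mode="all"``, overlapping groups) or against nonspecific TFs only
    (``mode="nonspecific"``)."""
    if mode not in ("all", "nonspecific"):
        raise ValidationError(f"unknown mode {mode!r}")
    if network.is_empty():
        raise ValidationError("empty crosstalk network")
    specific_tfs = set(specific_tfs)
    spec = [e.length for e in network.receptor_tf_edges if e.tf in specific_tfs]
    if mode == "all":
        ref = [e.length for e in network.receptor_tf_edges]
    else:
        ref = [e.length for e in network.receptor_tf_edges if e.tf not in specific_tfs]
    if not spec:
        raise ValidationError("no path ends at a specific TF")
    if not ref:
        raise ValidationError("reference path group is empty")
    spec_arr = np.asarray(spec, dtype=float)
    ref_arr = np.asarray(ref, dtype=float)
    return PathLengthComparison(
        lengths_specific=spec_arr,
        lengths_reference=ref_arr,
        mean_specific=float(spec_arr.mean()),
        mean_reference=float(ref_arr.mean()),
        mwu=mann_whitney_u(spec_arr, ref_arr),
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Orthology application
# ---------------------------------------------------------------------------


def apply_orthology(tf_targets: TFTargetMap, orthology: OrthologyMap) -> TFTargetMap:
    """Map a TF-target table through an orthology map (e.g. mouse→human).

    Unmapped TFs or targets are dropped (count logged); many-to-one TF
    collisions are resolved by the union of their target sets.
    """
    mapping = orthology.mapping
    out: dict = {}
    dropped_tfs = dropped_targets = 0
    for tf, targets in tf_targets.targets.items():
        if tf not in mapping:
            dropped_tfs += 1
            continue
        mapped = set()
        for t in targets:
            if t in mapping:
                mapped.add(mapping[t])
            else:
                dropped_targets += 1
        if mapped:
            out.setdefault(mapping[tf], set()).update(mapped)
    if dropped_tfs or dropped_targets:
        log.info(
            "orthology mapping dropped %d TFs and %d target entries",
            dropped_tfs, dropped_targets,
        )
    return TFTargetMap({tf: frozenset(v) for tf, v in out.items()})
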