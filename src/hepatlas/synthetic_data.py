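"""Seeded synthetic four-cell-type cohorts with a machine-readable record of
every planted feature.

The generator emulates the study design the analysis pipeline targets: four
liver cell types (hepatocytes plus three nonparenchymal sender types), three
biological replicates, log-normal abundance with multiplicative log10 noise,
FOT-normalized proteome columns, a matched FPKM transcriptome, GO/KEGG-like
annotation sets, ligand-receptor pairs, layered signaling-pathway DAGs,
TF→target tables, secretome sets and a drifting cultured-hepatocyte time
course.

Planted structure
-----------------
* *Enhanced proteins* are detected only in their focal cell type, at
  ``enhanced_fold`` times the local baseline — mirroring the
  "not detected elsewhere" pattern of strongly cell-enhanced proteins — so
  their ratio to the four-cell average is the maximum (the number of cell
  types) and calling is robust to replicate noise.
* *Specific TFs* are expressed everywhere but ``specific_tf_fold`` higher in
  the focal cell, putting their geometric-mean ratio well above the 10x
  calling threshold. (A 20:1:1:1 profile also exceeds the 2-fold enhanced
  rule, so planted specific TFs are included in the enhanced truth.)
* *Crosstalk chains* ligand→receptor→intermediates→TF are planted inside
  per-pathway DAGs; chains of "specific" pathways end at receiver-specific
  TFs and are ``nonspecific_path_gap`` edges shorter than chains of
  "nonspecific" pathways. Inactive pathways carry one undetected node per
  chain, which vetoes the all-nodes-detected activity rule.
* Hepatocytes run a distinct program: a configurable fraction of (low
  abundance) genes is silenced there, which also makes them the clustering
  outgroup.

Unplanted genes carry bounded per-cell log10 effects (uniform within
``cell_effect_bound``) chosen small enough that, after FOT renormalization,
no unplanted gene can reach the 2x enhanced or 10x specific-TF threshold in
the noiseless expectation — every :func:`generate_cohort` call verifies this
by running the full calling pipeline against the planted truth and raising
:class:`~hepatlas.errors.GenerationError` on any mismatch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import crosstalk, differential
from .errors import GenerationError
from .io_formats import (
    AbundanceMatrix,
    AnnotationDB,
    LigandReceptorDB,
    PathwayGraph,
    SampleInfo,
    TFTargetMap,
    write_abundance_table,
    write_gmt,
    write_ligand_receptor_table,
    write_pathway_table,
    write_tf_target_table,
)

import networkx as nx

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults follow the emulated design: 4 cell types x 3 replicates,
    replicate noise sd 0.2 on log10 abundance, 4x planted enhanced folds
    against a 2x calling threshold, 20x planted specific-TF folds against a
    10x threshold, and a cultured-hepatocyte time course at days 1, 3, 6
    and 10.
    """

    seed: int = 0
    n_genes: int = 1500
    cell_types: tuple = ("HC", "HSC", "KC", "LSEC")
    receiver_cell: str = "HC"
    n_replicates: int = 3
    noise_sd: float = 0.2  # log10, per replicate
    baseline_log10_mean: float = -4.0
    baseline_log10_sd: float = 1.0
    planted_log10_sd: float = 0.4  # narrower spread for planted genes (mass control)
    cell_effect_bound: float = 0.04  # uniform log10 per gene per cell
    receiver_effect_bound: float = 0.24  # distinct receiver program, uniform log10
    sender_program_genes: int = 270  # genes shifted per sender cell type
    sender_program_shift: float = 0.26  # log10 magnitude of the shift (sign random)
    hc_silenced_fraction: float = 0.25
    n_enhanced: int = 8
    enhanced_fold: float = 4.0
    enhanced_threshold: float = 2.0
    n_specific_tfs: int = 8
    specific_tf_fold: float = 20.0
    specific_tf_threshold: float = 10.0
    n_free_tfs: int = 16
    n_specific_pathways: int = 8
    n_nonspecific_pathways: int = 8
    n_inactive_pathways: int = 4
    chains_per_pathway: int = 4
    inactive_chains_per_pathway: int = 2
    specific_path_length_range: tuple = (3, 5)
    nonspecific_path_gap: int = 2
    n_enhanced_intermediates_per_chain: int = 2
    secreted_ligand_period: int = 4  # every k-th chain ligand secreted, not enhanced
    both_ligand_period: int = 8  # every k-th chain ligand enhanced AND secreted
    n_decoy_pairs: int = 10
    secretome_extra: int = 10
    n_targets_per_tf: int = 8
    target_pool_size: int = 150
    n_categories: int = 30
    pathway_alpha: float = 0.05
    fpkm_log10_offset: float = 5.0
    fpkm_noise_sd: float = 1.3
    timecourse_days: tuple = (1.0, 3.0, 6.0, 10.0)
    drift_rate: float = 0.12  # log10 per day
    n_drift_extra: int = 150

    @property
    def senders(self) -> tuple:
        return tuple(c for c in self.cell_types if c != self.receiver_cell)

    def validate(self) -> None:
        counts = dict(
            n_genes=self.n_genes, n_replicates=self.n_replicates,
            n_enhanced=self.n_enhanced, n_specific_tfs=self.n_specific_tfs,
            n_free_tfs=self.n_free_tfs, chains_per_pathway=self.chains_per_pathway,
            n_targets_per_tf=self.n_targets_per_tf,
            target_pool_size=self.target_pool_size, n_categories=self.n_categories,
        )
        for name, v in counts.items():
            if v <= 0:
                raise GenerationError(f"{name} must be positive, got {v}")
        if self.receiver_cell not in self.cell_types:
            raise GenerationError(f"receiver {self.receiver_cell!r} not in cell_types")
        if len(self.cell_types) < 2:
            raise GenerationError("need at least 2 cell types")
        if self.noise_sd < 0:
            raise GenerationError("noise_sd must be >= 0")
        lo, hi = self.specific_path_length_range
        if not (1 <= lo <= hi):
            raise GenerationError("invalid specific_path_length_range")
        if hi + self.nonspecific_path_gap + 2 > self.n_genes:
            raise GenerationError("pathway depth exceeds gene budget")
        if self.n_enhanced_intermediates_per_chain > lo - 1:
            raise GenerationError(
                "n_enhanced_intermediates_per_chain exceeds shortest chain interior"
            )
        if self.n_specific_pathways > self.n_specific_tfs:
            raise GenerationError("more specific pathways than receiver-specific TFs")
        if self.n_free_tfs < self.n_nonspecific_pathways + self.n_inactive_pathways:
            raise GenerationError("n_free_tfs too small for nonspecific+inactive pathways")
        # planted folds must clear the calling thresholds with margin
        max_ratio = float(len(self.cell_types))  # exclusive expression attains this
        if max_ratio < 1.5 * self.enhanced_threshold:
            raise GenerationError(
                f"enhanced calling ratio {max_ratio} (exclusive planting) does not "
                f"exceed threshold {self.enhanced_threshold} by a 1.5x margin"
            )
        if self.specific_tf_fold < 1.5 * self.specific_tf_threshold:
            raise GenerationError(
                f"specific_tf_fold {self.specific_tf_fold} does not exceed threshold "
                f"{self.specific_tf_threshold} by a 1.5x margin"
            )
        if self.enhanced_fold <= 1:
            raise GenerationError("enhanced_fold must exceed 1")


# ---------------------------------------------------------------------------
# Truth records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedChain:
    """One planted ligand→receptor→...→TF crosstalk chain."""

    ligand: str
    sender: str
    receptor: str
    tf: str
    pathway: str
    length: int  # receptor→TF edges
    evidence: str  # "enhanced" | "secreted" | "both"


@dataclass
class TimecourseTruth:
    """Planted monotone drift of the cultured-receiver time course."""

    days: tuple
    down_genes: frozenset
    up_genes: frozenset
    is_tf_target: dict  # down gene -> bool (target of a receiver-specific TF)


@dataclass
class SyntheticTruth:
    """Record of every planted feature, for recovery testing."""

    enhanced: dict  # cell -> frozenset
    specific_tfs: dict  # cell -> frozenset
    secretomes: dict  # cell -> frozenset
    active_pathways: frozenset
    inactive_pathways: frozenset
    chains: tuple  # PlantedChain
    specific_path_lengths: tuple
    nonspecific_path_lengths: tuple
    undetected_genes: frozenset
    silenced_in_receiver: frozenset
    timecourse: TimecourseTruth | None = None

    def to_json_dict(self) -> dict:
        def _s(x):
            return sorted(x)

        out = {
            "enhanced": {c: _s(v) for c, v in self.enhanced.items()},
            "specific_tfs": {c: _s(v) for c, v in self.specific_tfs.items()},
            "secretomes": {c: _s(v) for c, v in self.secretomes.items()},
            "active_pathways": _s(self.active_pathways),
            "inactive_pathways": _s(self.inactive_pathways),
            "chains": [asdict(ch) for ch in self.chains],
            "specific_path_lengths": list(self.specific_path_lengths),
            "nonspecific_path_lengths": list(self.nonspecific_path_lengths),
            "undetected_genes": _s(self.undetected_genes),
            "silenced_in_receiver": _s(self.silenced_in_receiver),
        }
        if self.timecourse is not None:
            out["timecourse"] = {
                "days": list(self.timecourse.days),
                "down_genes": _s(self.timecourse.down_genes),
                "up_genes": _s(self.timecourse.up_genes),
                "is_tf_target": dict(sorted(self.timecourse.is_tf_target.items())),
            }
        return out


@dataclass
class SyntheticCohort:
    """Everything :func:`generate_cohort` produces."""

    config: GeneratorConfig
    proteome: AbundanceMatrix  # FOT
    transcriptome: AbundanceMatrix  # FPKM, one column per cell type
    annotation: AnnotationDB
    lr_db: LigandReceptorDB
    pathways: list
    tf_targets: TFTargetMap
    secretomes: dict
    truth: SyntheticTruth
    tf_list: list
    expectation: pd.DataFrame  # genes x cell types, noiseless FOT

    def expectation_matrix(self) -> AbundanceMatrix:
        """Noiseless expectation as a one-replicate-per-cell FOT matrix."""
        samples = [SampleInfo(ct, 1) for ct in self.expectation.columns]
        return AbundanceMatrix(self.expectation, samples, unit="fot")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _draw_baseline(rng, n, mean, sd, clip=None):
    z = rng.standard_normal(n)
    if clip is not None:
        z = np.clip(z, -clip, clip)
    return 10.0 ** (mean + sd * z)


def generate_cohort(config: GeneratorConfig = GeneratorConfig(), self_check: bool = True) -> SyntheticCohort:
    """Generate a complete synthetic cohort, fully deterministic from
    ``config.seed``.

    With ``self_check=True`` (default) the noiseless expectation matrix is
    pushed through the full calling pipeline (enhanced → specific TF →
    candidates → active pathways → network) and compared against the planted
    truth; any mismatch raises :class:`GenerationError`.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    cells = list(cfg.cell_types)
    n_cells = len(cells)
    receiver = cfg.receiver_cell
    senders = list(cfg.senders)

    gene_rows: list[str] = []

    def _new_genes(prefix, count):
        start = len(gene_rows)
        names = [f"{prefix}{start + i:04d}" for i in range(count)]
        gene_rows.extend(names)
        return names

    # --- structural gene allocation -------------------------------------
    markers = {c: _new_genes(f"ENH{c}_", cfg.n_enhanced) for c in cells}
    spec_tfs = {c: _new_genes(f"TF{c}_", cfg.n_specific_tfs) for c in cells}
    free_tfs = _new_genes("TFN_", cfg.n_free_tfs)
    tf_list = [tf for c in cells for tf in spec_tfs[c]] + free_tfs

    lo, hi = cfg.specific_path_length_range
    chain_counter = 0
    chains: list[PlantedChain] = []
    pathway_specs = []  # (name, kind, tf, list of chain dicts)
    undetected: list[str] = []
    exclusive: dict = {c: set(markers[c]) for c in cells}  # cell -> exclusive genes
    secre_ligands: dict = {c: set() for c in cells}

    def _build_chains(pw_name, kind, tf, n_chains, length_offset):
        nonlocal chain_counter
        chain_list = []
        for _ in range(n_chains):
            sender = senders[chain_counter % len(senders)]
            L = int(rng.integers(lo, hi + 1)) + length_offset
            lig = _new_genes(f"LIG_{pw_name}_", 1)[0]
            rec = _new_genes(f"REC_{pw_name}_", 1)[0]
            inter = _new_genes(f"INT_{pw_name}_", L - 1)
            if kind == "inactive":
                evidence = "enhanced"
                undetected.append(inter[0])
                enhanced_inter: list = []
            else:
                if chain_counter % cfg.both_ligand_period == 0:
                    evidence = "both"
                elif chain_counter % cfg.secreted_ligand_period == 0:
                    evidence = "secreted"
                else:
                    evidence = "enhanced"
                enhanced_inter = inter[: cfg.n_enhanced_intermediates_per_chain]
            if evidence in ("enhanced", "both"):
                exclusive[sender].add(lig)
            if evidence in ("secreted", "both"):
                secre_ligands[sender].add(lig)
            for g in enhanced_inter:
                exclusive[sender].add(g)
            chain_list.append(dict(ligand=lig, receptor=rec, inter=inter,
                                   sender=sender, evidence=evidence, length=L))
            chains.append(PlantedChain(lig, sender, rec, tf, pw_name, L, evidence))
            chain_counter += 1
        pathway_specs.append((pw_name, kind, tf, chain_list))

    for i in range(cfg.n_specific_pathways):
        _build_chains(f"PW_SPEC{i:02d}", "specific", spec_tfs[receiver][i],
                      cfg.chains_per_pathway, 0)
    for i in range(cfg.n_nonspecific_pathways):
        _build_chains(f"PW_NONSP{i:02d}", "nonspecific", free_tfs[i],
                      cfg.chains_per_pathway, cfg.nonspecific_path_gap)
    for i in range(cfg.n_inactive_pathways):
        _build_chains(f"PW_INACT{i:02d}", "inactive",
                      free_tfs[cfg.n_nonspecific_pathways + i],
                      cfg.inactive_chains_per_pathway, 0)

    target_pool = _new_genes("TG_", cfg.target_pool_size)
    decoy_lig = _new_genes("DLIG_", cfg.n_decoy_pairs)
    decoy_rec = _new_genes("DREC_", cfg.n_decoy_pairs)

    n_structural = len(gene_rows)
    n_filler = cfg.n_genes - n_structural
    n_silenced = int(round(cfg.hc_silenced_fraction * cfg.n_genes))
    if n_filler < n_silenced + 2 * cfg.n_drift_extra + 50:
        raise GenerationError(
            f"n_genes={cfg.n_genes} leaves only {n_filler} filler genes for "
            f"{n_silenced} silenced + {2 * cfg.n_drift_extra} drifting genes"
        )
    filler = _new_genes("GENE_", n_filler)
    genes = list(gene_rows)
    gene_index = {g: i for i, g in enumerate(genes)}
    planted_set = set().union(*exclusive.values()) | {tf for c in cells for tf in spec_tfs[c]}

    # --- expectation matrix ----------------------------------------------
    base = _draw_baseline(rng, cfg.n_genes, cfg.baseline_log10_mean, cfg.baseline_log10_sd)
    # cell-exclusive genes sit a decade below the bulk so that their absence
    # in other cells perturbs sample ranks only mildly; calling ratios are
    # scale-free, so this does not affect recovery
    planted_base = _draw_baseline(
        rng, cfg.n_genes, cfg.baseline_log10_mean - 1.0, cfg.planted_log10_sd, clip=2.0
    )
    effects = 10.0 ** rng.uniform(
        -cfg.cell_effect_bound, cfg.cell_effect_bound, size=(cfg.n_genes, n_cells)
    )
    # the top-mass tier keeps only the small cell effects: FOT column sums are
    # dominated by these genes, and large per-cell factors there would skew
    # whole columns after renormalization
    heavy = np.zeros(cfg.n_genes, dtype=bool)
    heavy[np.argsort(base, kind="stable")[-max(1, cfg.n_genes // 10):]] = True
    effects[heavy, :] = 1.0
    # distinct receiver program: bounded +- shifts (bimodal maximizes the
    # correlation signature for a given worst-case calling-ratio corner)
    receiver_effect = 10.0 ** (
        rng.choice([-1.0, 1.0], size=cfg.n_genes) * cfg.receiver_effect_bound
    )
    ri0 = cells.index(receiver)
    effects[~heavy, ri0] = receiver_effect[~heavy]
    E = base[:, None] * effects
    for ci, c in enumerate(cells):
        for g in exclusive[c]:
            gi = gene_index[g]
            E[gi, :] = 0.0
            E[gi, ci] = cfg.enhanced_fold * planted_base[gi]
        for g in spec_tfs[c]:
            gi = gene_index[g]
            # mass-capped baseline: a 20-fold focal level on an unbounded
            # draw could dominate a whole FOT column
            E[gi, :] = planted_base[gi]
            E[gi, ci] = cfg.specific_tf_fold * planted_base[gi]
    for g in undetected:
        E[gene_index[g], :] = 0.0

    # receiver-silenced program: mid-abundance filler genes zeroed in the
    # receiver — rank-disruptive against the senders, yet only a small mass
    # fraction, so FOT renormalization cannot push unplanted genes past the
    # enhanced threshold
    filler_idx = np.array([gene_index[g] for g in filler])
    order = filler_idx[np.argsort(base[filler_idx], kind="stable")]
    band = order[int(0.2 * len(order)) : int(0.8 * len(order))]
    silenced_idx = rng.choice(band, size=min(n_silenced, len(band)), replace=False)
    ri = cells.index(receiver)
    E[silenced_idx, ri] = 0.0
    silenced = frozenset(genes[i] for i in silenced_idx)

    # per-sender expression programs: moderate shifts on dedicated gene sets,
    # disjoint across cells and from planted/silenced/undetected genes; the
    # shift magnitude keeps every unplanted enhanced ratio below threshold
    excluded = set(silenced_idx) | {gene_index[g] for g in undetected}
    excluded |= {gene_index[g] for g in planted_set}
    excluded |= set(np.flatnonzero(heavy))
    program_pool = np.array([i for i in range(cfg.n_genes) if i not in excluded])
    n_prog = min(cfg.sender_program_genes * len(senders), len(program_pool))
    prog_idx = rng.choice(program_pool, size=n_prog, replace=False)
    for k, c in enumerate(senders):
        block = prog_idx[k::len(senders)]
        signs = rng.choice([-1.0, 1.0], size=len(block))
        E[block, cells.index(c)] *= 10.0 ** (signs * cfg.sender_program_shift)

    # --- emitted proteome (replicate noise, FOT columns) ------------------
    samples = [SampleInfo(c, r + 1) for c in cells for r in range(cfg.n_replicates)]
    cols = {}
    for si, s in enumerate(samples):
        col = E[:, cells.index(s.cell_type)].copy()
        if cfg.noise_sd > 0:
            col = col * 10.0 ** (cfg.noise_sd * rng.standard_normal(cfg.n_genes))
        cols[s.label] = col / col.sum()
    proteome = AbundanceMatrix(
        pd.DataFrame(cols, index=genes), samples, unit="fot"
    )

    # --- transcriptome (FPKM, one column per cell type) -------------------
    fpkm = np.zeros_like(E)
    pos = E > 0
    noise = cfg.fpkm_noise_sd * rng.standard_normal(E.shape)
    fpkm[pos] = 10.0 ** (np.log10(E[pos]) + cfg.fpkm_log10_offset + noise[pos])
    transcriptome = AbundanceMatrix(
        pd.DataFrame(fpkm, index=genes, columns=[f"{c}_1" for c in cells]),
        [SampleInfo(c, 1) for c in cells],
        unit="fpkm",
    )

    # --- annotation -------------------------------------------------------
    cat_ids = [f"CAT{i:02d}" for i in range(cfg.n_categories)]
    primary = rng.integers(0, cfg.n_categories, size=cfg.n_genes)
    extra = rng.integers(0, cfg.n_categories, size=cfg.n_genes)
    has_extra = rng.random(cfg.n_genes) < 0.5
    cat_sets: dict = {cid: set() for cid in cat_ids}
    for gi, g in enumerate(genes):
        cat_sets[cat_ids[primary[gi]]].add(g)
        if has_extra[gi]:
            cat_sets[cat_ids[extra[gi]]].add(g)
    annotation = AnnotationDB(
        {cid: frozenset(v) for cid, v in cat_sets.items() if v},
        {cid: f"synthetic category {cid}" for cid in cat_ids},
        ontology="other",
    )

    # --- network side tables ----------------------------------------------
    pair_rows = [(ch.ligand, ch.receptor, ch.pathway) for ch in chains]
    pair_rows += [(dl, dr, "decoy") for dl, dr in zip(decoy_lig, decoy_rec)]
    lr_db = LigandReceptorDB(tuple(pair_rows))

    pathways = []
    for name, kind, tf, chain_list in pathway_specs:
        g = nx.DiGraph()
        g.add_node(tf, role="tf")
        for ch in chain_list:
            g.add_node(ch["ligand"], role="ligand")
            g.add_node(ch["receptor"], role="receptor")
            for node in ch["inter"]:
                g.add_node(node, role="intermediate")
            seq = [ch["ligand"], ch["receptor"], *ch["inter"], tf]
            for u, v in zip(seq, seq[1:]):
                g.add_edge(u, v)
        pathways.append(PathwayGraph(name, g))

    tft = TFTargetMap(
        {
            tf: frozenset(rng.choice(target_pool, size=cfg.n_targets_per_tf, replace=False))
            for tf in tf_list
        }
    )

    nonsilenced_filler = [g for g in filler if g not in silenced]
    secretomes = {}
    for c in cells:
        extra_sec = rng.choice(nonsilenced_filler, size=cfg.secretome_extra, replace=False)
        secretomes[c] = frozenset(secre_ligands[c] | set(extra_sec))

    # --- truth -------------------------------------------------------------
    enhanced_truth = {
        c: frozenset(exclusive[c] | set(spec_tfs[c])) for c in cells
    }
    truth = SyntheticTruth(
        enhanced=enhanced_truth,
        specific_tfs={c: frozenset(spec_tfs[c]) for c in cells},
        secretomes=secretomes,
        active_pathways=frozenset(
            name for name, kind, _, _ in pathway_specs if kind != "inactive"
        ),
        inactive_pathways=frozenset(
            name for name, kind, _, _ in pathway_specs if kind == "inactive"
        ),
        chains=tuple(chains),
        specific_path_lengths=tuple(
            ch.length for ch in chains if ch.pathway.startswith("PW_SPEC")
        ),
        nonspecific_path_lengths=tuple(
            ch.length for ch in chains if ch.pathway.startswith("PW_NONSP")
        ),
        undetected_genes=frozenset(undetected),
        silenced_in_receiver=silenced,
    )

    expectation = pd.DataFrame(E / E.sum(axis=0), index=genes, columns=cells)
    cohort = SyntheticCohort(
        config=cfg, proteome=proteome, transcriptome=transcriptome,
        annotation=annotation, lr_db=lr_db, pathways=pathways, tf_targets=tft,
        secretomes=secretomes, truth=truth, tf_list=tf_list, expectation=expectation,
    )
    if self_check:
        _verify_planted_truth(cohort)
    return cohort


def _verify_planted_truth(cohort: SyntheticCohort) -> None:
    """Run the calling pipeline on the noiseless expectation and compare with
    the planted truth; raise GenerationError on any mismatch."""
    cfg = cohort.config
    truth = cohort.truth
    m0 = cohort.expectation_matrix()
    enhanced_calls = {}
    for c in cfg.cell_types:
        call = differential.call_enhanced(m0, c, threshold=cfg.enhanced_threshold)
        enhanced_calls[c] = call
        if call.genes != truth.enhanced[c]:
            extra = sorted(call.genes - truth.enhanced[c])[:5]
            miss = sorted(truth.enhanced[c] - call.genes)[:5]
            raise GenerationError(
                f"noiseless enhanced recovery mismatch for {c}: "
                f"spurious={extra} missed={miss}"
            )
        tf_call = differential.call_specific_tf(
            m0, cohort.tf_list, c, threshold=cfg.specific_tf_threshold
        )
        if tf_call.genes != truth.specific_tfs[c]:
            raise GenerationError(f"noiseless specific-TF recovery mismatch for {c}")

    receiver = cfg.receiver_cell
    candidates = crosstalk.select_candidates(
        cohort.lr_db, m0, cohort.secretomes, cfg.senders, receiver, enhanced_calls
    )
    detected_union = m0.detected()
    enhanced_union = set().union(*(truth.enhanced[c] for c in cfg.cell_types))
    calls = crosstalk.call_active_pathways(
        cohort.pathways, enhanced_union, detected_union, detected_union,
        alpha=cfg.pathway_alpha,
    )
    active = {c.name for c in calls if c.active}
    if active != set(truth.active_pathways):
        raise GenerationError(
            f"active-pathway mismatch: called {sorted(active)} vs "
            f"planted {sorted(truth.active_pathways)}"
        )
    network = crosstalk.build_network(
        candidates, calls, cohort.pathways, truth.specific_tfs[receiver],
        cohort.tf_targets, receiver_detected=m0.detected(receiver),
    )
    edges = {(e.receptor, e.tf): e for e in network.receptor_tf_edges}
    for ch in truth.chains:
        if ch.pathway in truth.active_pathways:
            e = edges.get((ch.receptor, ch.tf))
            if e is None:
                raise GenerationError(f"planted chain lost: {ch}")
            if e.length != ch.length or e.pathway != ch.pathway:
                raise GenerationError(f"chain attribution mismatch: {ch} vs {e}")
        else:
            if (ch.receptor, ch.tf) in edges:
                raise GenerationError(f"edge through inactive pathway: {ch}")
    n_active_chains = sum(1 for ch in truth.chains if ch.pathway in truth.active_pathways)
    if len(edges) != n_active_chains:
        raise GenerationError(
            f"{len(edges)} receptor-TF edges for {n_active_chains} active chains"
        )


# ---------------------------------------------------------------------------
# Time course
# ---------------------------------------------------------------------------


def generate_timecourse(
    cohort: SyntheticCohort, config: GeneratorConfig | None = None
) -> tuple:
    """Cultured-receiver time course: day 0 equals the receiver's noiseless
    mean profile; targets of receiver-specific TFs (plus extra planted genes)
    drift down, planted trigger-like genes drift up, at ``drift_rate`` log10
    units per day, with replicate noise on every column.

    Returns ``(AbundanceMatrix[fot] with timepoints, TimecourseTruth)``; the
    truth extension is also attached to ``cohort.truth.timecourse``.
    """
    cfg = config or cohort.config
    if cfg.drift_rate <= 0:
        raise GenerationError("drift_rate must be > 0")
    rng = np.random.default_rng([cfg.seed, 7919])
    receiver = cfg.receiver_cell
    genes = cohort.proteome.gene_ids
    base = cohort.expectation[receiver].to_numpy().copy()

    tf_targets_receiver = set()
    for tf in cohort.truth.specific_tfs[receiver]:
        tf_targets_receiver |= set(cohort.tf_targets.get(tf))
    candidates_pool = [
        g for g in genes
        if g.startswith("GENE_")
        and g not in cohort.truth.silenced_in_receiver
        and base[genes.index(g)] > 0
    ]
    picked = rng.choice(candidates_pool, size=2 * cfg.n_drift_extra, replace=False)
    extra_down = set(picked[: cfg.n_drift_extra])
    up_genes = frozenset(picked[cfg.n_drift_extra :])
    down_genes = frozenset(tf_targets_receiver | extra_down)

    gene_pos = {g: i for i, g in enumerate(genes)}
    direction = np.zeros(len(genes))
    for g in down_genes:
        direction[gene_pos[g]] = -1.0
    for g in up_genes:
        direction[gene_pos[g]] = +1.0

    days = (0.0, *cfg.timecourse_days)
    cols = {}
    samples = []
    for day in days:
        col = base.copy()
        pos = col > 0
        # expectation at day 0 is exactly the receiver mean; every emitted
        # column (day 0 included) carries replicate noise
        shift = direction[pos] * cfg.drift_rate * day
        noise = cfg.noise_sd * rng.standard_normal(pos.sum()) if cfg.noise_sd > 0 else 0.0
        col[pos] = 10.0 ** (np.log10(col[pos]) + shift + noise)
        info = SampleInfo(receiver, 1, timepoint=day)
        samples.append(info)
        cols[info.label] = col / col.sum()
    matrix = AbundanceMatrix(pd.DataFrame(cols, index=genes), samples, unit="fot")
    tc_truth = TimecourseTruth(
        days=days,
        down_genes=down_genes,
        up_genes=up_genes,
        is_tf_target={g: (g in tf_targets_receiver) for g in sorted(down_genes)},
    )
    cohort.truth.timecourse = tc_truth
    return matrix, tc_truth


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write every input format plus ``truth.json`` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_abundance_table(cohort.proteome, outdir / "proteome_fot.tsv")
    write_abundance_table(cohort.transcriptome, outdir / "transcriptome_fpkm.tsv")
    write_gmt(cohort.annotation, outdir / "annotation.gmt")
    write_ligand_receptor_table(cohort.lr_db, outdir / "ligand_receptor_pairs.tsv")
    pw_dir = outdir / "pathways"
    pw_dir.mkdir(exist_ok=True)
    for pw in cohort.pathways:
        write_pathway_table(pw, pw_dir / f"{pw.name}.tsv")
    write_tf_target_table(cohort.tf_targets, outdir / "tf_targets.tsv")
    for cell, genes in cohort.secretomes.items():
        with open(outdir / f"secretome_{cell}.txt", "w", encoding="utf-8") as fh:
            fh.write("\n".join(sorted(genes)) + "\n")
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(cohort.truth.to_json_dict(), fh, indent=1, sort_keys=True)
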