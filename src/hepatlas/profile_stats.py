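"""Per-cell-type proteome feature statistics.

Covers the descriptive layer of the pipeline: functional-category Shannon
entropy and its random-sampling null, coefficients of variation and dynamic
range, replicate correlation, average-linkage hierarchical clustering on
Spearman distances, gene-complexity over-representation and
proteome/transcriptome overlap partitions.

Entropy is computed in natural log by default (only the base rescales,
comparisons are within one base). All correlation-based steps share one
transform: Spearman rank correlation on log10(x + pseudocount), which is
robust to the multi-decade dynamic range of FOT values.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .differential import hypergeom_pvalue
from .errors import ValidationError
from .io_formats import AbundanceMatrix, AnnotationDB

log = logging.getLogger(__name__)

#: pseudocount added before log10 in correlation / clustering transforms
LOG_PSEUDOCOUNT = 1e-8


# ---------------------------------------------------------------------------
# Functional-category entropy
# ---------------------------------------------------------------------------


@dataclass
class EntropyResult:
    """Shannon entropy of a gene set's annotation-category frequencies.

    ``counts`` holds T_i = |set ∩ category_i| over categories with T_i > 0;
    ``frequencies`` holds F_i = T_i / ΣT_i. A gene belonging to several
    categories counts once in each, so ΣT_i may exceed the set size.
    """

    label: str
    entropy: float
    frequencies: pd.Series
    counts: pd.Series
    n_categories: int
    base: float | None = None  # None = natural log


class NoAnnotatedGenesError(ValidationError):
    """Raised when no gene of the query set is annotated; distinct from the
    legitimate entropy-0 case of a single-category set."""


def functional_entropy(
    gene_set, annotation: AnnotationDB, label: str = "", base: float | None = None
) -> EntropyResult:
    """Entropy −Σ F_i log F_i of ``gene_set`` over annotation categories."""
    gene_set = set(gene_set)
    if not gene_set:
        raise ValidationError("empty gene set")
    counts = {}
    for cat, members in annotation.categories.items():
        t = len(gene_set & members)
        if t > 0:
            counts[cat] = t
    if not counts:
        raise NoAnnotatedGenesError(
            f"no gene of set {label or '<unnamed>'} is annotated in any category"
        )
    t = pd.Series(counts, dtype=float).sort_index()
    f = t / t.sum()
    logf = np.log(f.to_numpy())
    if base is not None:
        logf = logf / math.log(base)
    entropy = float(-(f.to_numpy() * logf).sum())
    return EntropyResult(
        label=label,
        entropy=max(entropy, 0.0),
        frequencies=f,
        counts=t,
        n_categories=len(t),
        base=base,
    )


@dataclass
class NullDistribution:
    """Entropy null from random gene sets of fixed size."""

    set_size: int
    draws: int
    mean: float
    sd: float
    values: np.ndarray
    seed: int | None


def entropy_null(
    set_size: int,
    annotation: AnnotationDB,
    universe,
    draws: int = 100,
    seed: int | None = None,
    base: float | None = None,
) -> NullDistribution:
    """Entropy of ``draws`` random subsets of ``universe`` (without
    replacement within each draw), fully reproducible from ``seed``."""
    universe = sorted(set(universe))
    if set_size > len(universe):
        raise ValidationError(
            f"set_size {set_size} exceeds universe size {len(universe)}"
        )
    if draws < 1:
        raise ValidationError("draws must be >= 1")
    rng = np.random.default_rng(seed)
    values = np.empty(draws)
    arr = np.asarray(universe, dtype=object)
    for i in range(draws):
        subset = rng.choice(arr, size=set_size, replace=False)
        values[i] = functional_entropy(subset, annotation, base=base).entropy
    return NullDistribution(
        set_size=set_size,
        draws=draws,
        mean=float(values.mean()),
        sd=float(values.std(ddof=0)),
        values=values,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# CV and dynamic range
# ---------------------------------------------------------------------------


def cv_and_dynamic_range(matrix: AbundanceMatrix) -> tuple[pd.Series, pd.Series]:
    """Per-gene CV across cell-type means and per-sample dynamic range.

    CV = population sd / mean over the per-cell-type means, for genes with a
    positive mean. Dynamic range = log10(max / min positive abundance) per
    sample column.
    """
    means = matrix.cell_means()
    if means.shape[1] < 2:
        raise ValidationError("need at least 2 cell types for CV")
    mu = means.mean(axis=1)
    keep = mu > 0
    cv = (means[keep].std(axis=1, ddof=0) / mu[keep]).rename("cv")
    dr = {}
    for col in matrix.data.columns:
        vals = matrix.data[col].to_numpy()
        pos = vals[vals > 0]
        dr[col] = float(np.log10(pos.max() / pos.min())) if pos.size else float("nan")
    return cv, pd.Series(dr, name="dynamic_range")


# ---------------------------------------------------------------------------
# Correlation and clustering
# ---------------------------------------------------------------------------


def _log_transform(values: np.ndarray, pseudocount: float = LOG_PSEUDOCOUNT) -> np.ndarray:
    return np.log10(values + pseudocount)


def replicate_correlation(
    matrix: AbundanceMatrix, pseudocount: float = LOG_PSEUDOCOUNT, min_shared: int = 3
) -> pd.DataFrame:
    """Pairwise Spearman correlations on log10(x + pseudocount).

    Correlation is computed over genes detected (value > 0) in both columns
    and labeled ``within`` / ``between`` cell type. Pairs sharing fewer than
    ``min_shared`` genes get rho = NaN.
    """
    cols = list(matrix.data.columns)
    if len(cols) < 2:
        raise ValidationError("need at least 2 samples")
    rows = []
    for (i, ca), (j, cb) in itertools.combinations(enumerate(cols), 2):
        va = matrix.data[ca].to_numpy(dtype=float)
        vb = matrix.data[cb].to_numpy(dtype=float)
        shared = (va > 0) & (vb > 0)
        n = int(shared.sum())
        if n < min_shared:
            rho = float("nan")
        else:
            rho = float(
                spearmanr(_log_transform(va[shared], pseudocount),
                          _log_transform(vb[shared], pseudocount)).statistic
            )
        kind = (
            "within"
            if matrix.samples[i].cell_type == matrix.samples[j].cell_type
            else "between"
        )
        rows.append(
            (ca, cb, matrix.samples[i].cell_type, matrix.samples[j].cell_type, kind, rho, n)
        )
    return pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "cell_a", "cell_b", "kind", "rho", "n_shared"]
    )


@dataclass
class ClusterResult:
    """Average-linkage tree over samples on 1 − Spearman distances."""

    linkage: np.ndarray
    labels: list[str]  # label order used for the linkage (sorted)
    leaf_order: list[str]
    distances: pd.DataFrame


def hierarchical_cluster(
    matrix: AbundanceMatrix, pseudocount: float = LOG_PSEUDOCOUNT
) -> ClusterResult:
    """Cluster samples with average linkage on 1 − Spearman correlation of
    log10-transformed abundances.

    Columns are processed in sorted label order, which makes the tree
    invariant to the input column permutation and breaks ties
    deterministically. A rank-constant column is a hard error.
    """
    if matrix.n_samples < 3:
        raise ValidationError("need at least 3 samples to cluster")
    labels = sorted(matrix.data.columns)
    X = _log_transform(matrix.data[labels].to_numpy(dtype=float), pseudocount)
    for idx, lab in enumerate(labels):
        if np.ptp(X[:, idx]) == 0:
            raise ValidationError(f"sample {lab} is constant; correlation undefined")
    rho = spearmanr(X).statistic
    if np.isscalar(rho):  # two columns; unreachable given n >= 3 guard
        rho = np.array([[1.0, rho], [rho, 1.0]])
    D = 1.0 - np.asarray(rho)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    condensed = squareform(D, checks=False)
    # optimal leaf ordering: minimizes adjacent distances so that leaves of
    # a gradient (e.g. a culture time course) come out in gradient order
    Z = hierarchy.linkage(condensed, method="average", optimal_ordering=True)
    order = hierarchy.leaves_list(Z)
    return ClusterResult(
        linkage=Z,
        labels=labels,
        leaf_order=[labels[i] for i in order],
        distances=pd.DataFrame(D, index=labels, columns=labels),
    )


def clades_at_root(result: ClusterResult) -> tuple[frozenset, frozenset]:
    """The two sample sets joined by the final (root) merge."""
    n = len(result.labels)
    members: dict[int, frozenset] = {i: frozenset([result.labels[i]]) for i in range(n)}
    for step, (a, b, _, _) in enumerate(result.linkage):
        members[n + step] = members[int(a)] | members[int(b)]
    a, b = int(result.linkage[-1, 0]), int(result.linkage[-1, 1])
    return members[a], members[b]


# ---------------------------------------------------------------------------
# Gene-complexity over-representation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComplexityClass:
    """One complexity predicate: gene attribute compared against a threshold."""

    values: pd.Series  # per-gene numeric attribute
    threshold: float
    strict: bool = True  # True: value > threshold; False: value >= threshold

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValidationError("complexity threshold must be strictly positive")

    def members(self) -> frozenset:
        if self.strict:
            hit = self.values > self.threshold
        else:
            hit = self.values >= self.threshold
        return frozenset(self.values.index[hit])


@dataclass
class ComplexityClasses:
    """Named complexity predicates. :func:`default_classes` builds the four
    canonical ones: long genes (GL > 28,256 bp), genes with >= 5
    cis-regulatory modules (CRMN), long proteins (PL > 512 aa) and
    multi-domain repeat proteins (DNIR > 2 domains)."""

    classes: dict[str, ComplexityClass]


def default_classes(attributes: pd.DataFrame) -> ComplexityClasses:
    """Build GL / CRMN / PL / DNIR from a per-gene attribute table with
    columns ``gene_length``, ``crm_count``, ``protein_length``,
    ``domain_repeat_count``."""
    needed = ["gene_length", "crm_count", "protein_length", "domain_repeat_count"]
    missing = [c for c in needed if c not in attributes.columns]
    if missing:
        raise ValidationError(f"attribute table missing columns {missing}")
    return ComplexityClasses(
        {
            "GL": ComplexityClass(attributes["gene_length"], 28256.0, strict=True),
            "CRMN": ComplexityClass(attributes["crm_count"], 5.0, strict=False),
            "PL": ComplexityClass(attributes["protein_length"], 512.0, strict=True),
            "DNIR": ComplexityClass(attributes["domain_repeat_count"], 2.0, strict=True),
        }
    )


def complexity_overrepresentation(
    cell_gene_set, universe, classes: ComplexityClasses
) -> pd.DataFrame:
    """Fold over-representation and hypergeometric p of each complexity class
    in ``cell_gene_set`` relative to ``universe``.

    fold = (fraction of the cell set in the class) / (fraction of the
    universe in the class); a class with no member in the universe is a hard
    error.
    """
    universe = set(universe)
    cell = set(cell_gene_set) & universe
    if not cell:
        raise ValidationError("cell gene set has no overlap with universe")
    N, q = len(universe), len(cell)
    rows = []
    for name, cc in classes.classes.items():
        members = cc.members() & universe
        m = len(members)
        if m == 0:
            raise ValidationError(f"complexity class {name!r} absent from universe")
        k = len(cell & members)
        fold = (k / q) / (m / N)
        rows.append((name, k, q, m, N, fold, hypergeom_pvalue(k, N, m, q)))
    return pd.DataFrame(rows, columns=["class", "k", "q", "m", "N", "fold", "p"])


# ---------------------------------------------------------------------------
# Proteome / transcriptome overlap
# ---------------------------------------------------------------------------


@dataclass
class OverlapPartition:
    """Venn partition of the proteome against the expressed transcriptome."""

    proteome_only: frozenset
    transcriptome_only: frozenset
    both: frozenset
    expressed_transcriptome: frozenset


def omics_overlap(
    proteome_set,
    transcriptome: AbundanceMatrix,
    secretome_set=None,
    fpkm_threshold: float = 1.0,
    cell_type: str | None = None,
) -> OverlapPartition:
    """Partition identified proteins against genes expressed at the mRNA
    level (FPKM strictly greater than ``fpkm_threshold``).

    ``secretome_set`` is merged into the proteome side when given, which is
    how secreted-but-not-resident proteins attenuate the extracellular-space
    bias of proteome-vs-transcriptome comparisons. Each partition piece is a
    valid enrichment query set.
    """
    prot = set(proteome_set)
    if secretome_set is not None:
        prot |= set(secretome_set)
    sub = transcriptome.data
    if cell_type is not None:
        sub = sub[transcriptome.columns_for(cell_type)]
    expressed = set(sub.index[(sub.to_numpy() > fpkm_threshold).any(axis=1)])
    return OverlapPartition(
        proteome_only=frozenset(prot - expressed),
        transcriptome_only=frozenset(expressed - prot),
        both=frozenset(prot & expressed),
        expressed_transcriptome=frozenset(expressed),
    )
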