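"""Shared statistical core: cell-enhanced protein calling, cell-specific TF
calling, hypergeometric enrichment with Bonferroni, and the Mann-Whitney U
test.

Calling rules
-------------
* *Cell-enhanced protein*: the ratio of the focal cell-type mean to the
  arithmetic mean over all cell types (focal included) is at least a
  threshold, 2-fold by default. ``include_focal=False`` switches the
  denominator to the mean over the other cell types only.
* *Cell-specific TF*: the focal cell-type mean is at least ``threshold``
  (10 by default) times the geometric mean over the *other* cell types,
  zeros replaced by a pseudocount (half the smallest positive matrix value
  unless given).

Enrichment uses the upper-tail hypergeometric probability P(X >= k) with a
Bonferroni correction over the categories that intersect the universe. The
correction controls the family-wise error rate; output columns label it
``p_bonferroni``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io_formats import AbundanceMatrix, AnnotationDB

log = logging.getLogger(__name__)

#: combined sample size at or below which the Mann-Whitney p is exact
EXACT_MWU_LIMIT = 12


# ---------------------------------------------------------------------------
# Enhanced proteins
# ---------------------------------------------------------------------------


@dataclass
class EnhancedCallSet:
    """Result of :func:`call_enhanced` for one cell type."""

    cell_type: str
    ratios: pd.Series  # gene -> focal mean / all-cell average
    threshold: float
    genes: frozenset

    def __len__(self) -> int:
        return len(self.genes)


def call_enhanced(
    matrix: AbundanceMatrix,
    cell_type: str,
    threshold: float = 2.0,
    include_focal: bool = True,
) -> EnhancedCallSet:
    """Call proteins enhanced in ``cell_type``.

    Replicates are averaged per cell type first; genes whose all-cell mean is
    0 are skipped. Deterministic.
    """
    means = matrix.cell_means()
    if cell_type not in means.columns:
        raise ValidationError(f"unknown cell type {cell_type!r}")
    if means.shape[1] < 2:
        raise ValidationError("need at least 2 cell types to call enhanced proteins")
    if include_focal:
        denom = means.mean(axis=1)
    else:
        denom = means.drop(columns=[cell_type]).mean(axis=1)
    keep = denom > 0
    ratios = (means.loc[keep, cell_type] / denom[keep]).astype(float)
    called = frozenset(ratios.index[ratios >= threshold])
    return EnhancedCallSet(cell_type, ratios, threshold, called)


# ---------------------------------------------------------------------------
# Specific TFs
# ---------------------------------------------------------------------------


@dataclass
class SpecificTFSet:
    """Result of :func:`call_specific_tf` for one cell type."""

    cell_type: str
    ratios: pd.Series  # TF -> focal mean / geometric mean of other cells
    threshold: float
    pseudocount: float
    genes: frozenset

    def __len__(self) -> int:
        return len(self.genes)


def call_specific_tf(
    matrix: AbundanceMatrix,
    tf_list,
    cell_type: str,
    threshold: float = 10.0,
    pseudocount: float | None = None,
) -> SpecificTFSet:
    """Call TFs specific to ``cell_type``: focal mean at least ``threshold``
    times the geometric mean of the other cell-type means.

    TFs absent from the matrix are logged and skipped; an empty ``tf_list``
    is a hard error. Zeros are replaced by ``pseudocount`` (default: half the
    smallest positive value in the matrix) before the geometric mean.
    """
    tf_list = list(tf_list)
    if not tf_list:
        raise ValidationError("empty TF list")
    means = matrix.cell_means()
    if cell_type not in means.columns:
        raise ValidationError(f"unknown cell type {cell_type!r}")
    if means.shape[1] < 2:
        raise ValidationError("need at least 2 cell types to call specific TFs")
    present = [tf for tf in tf_list if tf in means.index]
    missing = sorted(set(tf_list) - set(present))
    if missing:
        log.warning("%d TFs absent from matrix, skipped: %s ...", len(missing), missing[:5])
    if pseudocount is None:
        vals = matrix.data.to_numpy()
        positive = vals[vals > 0]
        if positive.size == 0:
            raise ValidationError("matrix has no positive values")
        pseudocount = float(positive.min()) * 0.5
    sub = means.loc[present].clip(lower=pseudocount)
    others = sub.drop(columns=[cell_type])
    gm = np.exp(np.log(others).mean(axis=1))
    ratios = (sub[cell_type] / gm).astype(float)
    called = frozenset(ratios.index[ratios >= threshold])
    return SpecificTFSet(cell_type, ratios, threshold, float(pseudocount), called)


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------


def hypergeom_pvalue(k: int, N: int, m: int, q: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, m, q)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, m, q))


def hypergeom_enrich(query_set, annotation: AnnotationDB, universe) -> pd.DataFrame:
    """Over-representation of ``query_set`` in each annotation category.

    Query genes outside the universe are trimmed with a warning (empty query
    after trimming is a hard error). Only categories intersecting the
    universe are tested; the Bonferroni factor is the number of tested
    categories. Returns a DataFrame sorted by raw p then category id with
    columns ``category, name, k, q, m, N, fold, p, p_bonferroni``.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    query = set(query_set)
    outside = query - universe
    if outside:
        log.warning("%d query genes outside universe trimmed", len(outside))
        query &= universe
    if not query:
        raise ValidationError("query set empty after trimming to universe")
    N, q = len(universe), len(query)
    rows = []
    for cat, genes in annotation.categories.items():
        members = genes & universe
        m = len(members)
        if m == 0:
            continue
        k = len(query & members)
        p = hypergeom_pvalue(k, N, m, q)
        fold = (k / q) / (m / N)
        rows.append((cat, annotation.names.get(cat, ""), k, q, m, N, fold, p))
    if not rows:
        return pd.DataFrame(
            columns=["category", "name", "k", "q", "m", "N", "fold", "p", "p_bonferroni"]
        )
    df = pd.DataFrame(
        rows, columns=["category", "name", "k", "q", "m", "N", "fold", "p"]
    )
    df["p_bonferroni"] = np.minimum(1.0, df["p"] * len(df))
    return df.sort_values(["p", "category"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


@dataclass
class MWUResult:
    """Mann-Whitney U statistic for the first group, with a two-sided p."""

    u: float
    p: float
    method: str  # "exact" or "normal-approximation"
    n1: int
    n2: int


def mann_whitney_u(a, b) -> MWUResult:
    """Two-sided Mann-Whitney U test with midrank ties.

    The p value is exact (full null enumeration) when the combined sample
    size is at most ``EXACT_MWU_LIMIT`` and there are no ties; otherwise a
    normal approximation with tie and continuity corrections is used. Two
    identical groups give p = 1 rather than an error.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if np.ptp(pooled) == 0:
        # all observations identical: U is central and the null is certain
        return MWUResult(u=n1 * n2 / 2.0, p=1.0, method="normal-approximation", n1=n1, n2=n2)
    if n1 + n2 <= EXACT_MWU_LIMIT and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return MWUResult(u=float(res.statistic), p=float(min(res.pvalue, 1.0)),
                         method="exact", n1=n1, n2=n2)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return MWUResult(u=float(res.statistic), p=float(min(res.pvalue, 1.0)),
                     method="normal-approximation", n1=n1, n2=n2)
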