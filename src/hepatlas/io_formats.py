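"""Readers, writers and validated containers for every external format.

The pipeline consumes plain tab-separated tables (UTF-8, ``.`` decimal):

* abundance matrices  — ``gene<TAB><CELL>_<rep>[_d<day>]...`` headers,
  nonnegative numeric body; units are tagged ``ibaq``, ``fot`` or ``fpkm``;
* gene sets           — standard GMT (``category<TAB>description<TAB>genes...``);
* ligand-receptor pairs — two or three columns (ligand, receptor[, source]);
* pathway graphs      — per-pathway edge lists with role tags
  (``src<TAB>dst<TAB>role_src<TAB>role_dst``);
* TF→target tables    — two columns;
* orthology maps      — two columns (source gene, destination gene).

Gene identifiers are opaque, case-sensitive strings. Missing values are not
permitted in abundance tables; "not detected" must be encoded as ``0``.
Every reader enforces the container invariants and fails hard, naming the
offending record.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

VALID_UNITS = ("ibaq", "fot", "fpkm")
PATHWAY_ROLES = ("ligand", "receptor", "intermediate", "tf")

#: tolerance on per-column sums of a FOT matrix
FOT_SUM_TOL = 1e-9

_HEADER_RE = re.compile(
    r"^(?P<cell>[A-Za-z][A-Za-z0-9\-]*)_(?P<rep>\d+)(?:_d(?P<day>\d+(?:\.\d+)?))?$"
)


# ---------------------------------------------------------------------------
# Abundance matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleInfo:
    """Per-column metadata of an abundance matrix.

    Attributes
    ----------
    cell_type : cell-type label (e.g. ``HC``).
    replicate : biological replicate index, >= 1.
    timepoint : optional culture timepoint in days (``None`` for primary cells).
    """

    cell_type: str
    replicate: int
    timepoint: float | None = None

    @property
    def label(self) -> str:
        base = f"{self.cell_type}_{self.replicate}"
        if self.timepoint is not None:
            base += f"_d{self.timepoint:g}"
        return base

    @property
    def key(self) -> tuple:
        return (self.cell_type, self.replicate, self.timepoint)

    @classmethod
    def from_label(cls, label: str) -> "SampleInfo":
        m = _HEADER_RE.match(label)
        if m is None:
            raise FormatError(
                f"malformed sample header {label!r}: expected CELL_rep or CELL_rep_dDAY"
            )
        day = m.group("day")
        return cls(
            cell_type=m.group("cell"),
            replicate=int(m.group("rep")),
            timepoint=float(day) if day is not None else None,
        )


class AbundanceMatrix:
    """A gene x sample grid of nonnegative abundances.

    Parameters
    ----------
    data : DataFrame indexed by gene id, one column per sample.
    samples : per-column :class:`SampleInfo`, aligned with ``data.columns``.
    unit : one of ``ibaq``, ``fot``, ``fpkm``. FOT columns must each sum
        to 1 within ``FOT_SUM_TOL``.
    """

    def __init__(self, data: pd.DataFrame, samples: Sequence[SampleInfo], unit: str):
        if unit not in VALID_UNITS:
            raise ValidationError(f"unknown unit tag {unit!r}; expected one of {VALID_UNITS}")
        if len(samples) != data.shape[1]:
            raise ValidationError(
                f"{len(samples)} sample records for {data.shape[1]} columns"
            )
        dup = data.index[data.index.duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate gene id {dup[0]!r}")
        keys = [s.key for s in samples]
        if len(set(keys)) != len(keys):
            seen: set = set()
            for k in keys:
                if k in seen:
                    raise ValidationError(f"duplicate sample (cell, replicate, day) = {k}")
                seen.add(k)
        for s in samples:
            if s.replicate < 1:
                raise ValidationError(f"replicate index must be >= 1 in sample {s.label}")
        values = data.to_numpy(dtype=float)
        bad = ~np.isfinite(values)
        if bad.any():
            g, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite value for gene {data.index[g]!r}, sample {samples[c].label}"
            )
        neg = values < 0
        if neg.any():
            g, c = np.argwhere(neg)[0]
            raise ValidationError(
                f"negative abundance for gene {data.index[g]!r}, sample {samples[c].label}"
            )
        if unit == "fot" and data.shape[0] > 0:
            sums = values.sum(axis=0)
            off = np.abs(sums - 1.0) > FOT_SUM_TOL
            if off.any():
                c = int(np.argmax(off))
                raise ValidationError(
                    f"FOT column {samples[c].label} sums to {sums[c]!r}, not 1"
                )
        df = pd.DataFrame(values, index=data.index.astype(str), columns=[s.label for s in samples])
        self.data = df
        self.samples = tuple(samples)
        self.unit = unit

    # -- basic introspection -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def cell_types(self) -> list[str]:
        """Cell-type labels in first-appearance column order."""
        seen: list[str] = []
        for s in self.samples:
            if s.cell_type not in seen:
                seen.append(s.cell_type)
        return seen

    def columns_for(self, cell_type: str) -> list[str]:
        cols = [s.label for s in self.samples if s.cell_type == cell_type]
        if not cols:
            raise ValidationError(f"unknown cell type {cell_type!r}")
        return cols

    def cell_means(self) -> pd.DataFrame:
        """Arithmetic mean over replicates, one column per cell type."""
        return pd.DataFrame(
            {ct: self.data[self.columns_for(ct)].mean(axis=1) for ct in self.cell_types}
        )

    def detected(self, cell_type: str | None = None) -> set[str]:
        """Genes with abundance > 0 in at least one (matching) column."""
        sub = self.data if cell_type is None else self.data[self.columns_for(cell_type)]
        mask = (sub.to_numpy() > 0).any(axis=1)
        return set(sub.index[mask])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"AbundanceMatrix({self.n_genes} genes x {self.n_samples} samples, "
            f"unit={self.unit!r}, cells={self.cell_types})"
        )


def read_abundance_table(path: str | Path, unit: str) -> AbundanceMatrix:
    """Parse a TSV abundance table; the header grammar is ``CELL_rep[_dDAY]``."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    if raw.index.name is None or raw.index.name.strip() == "":
        raise FormatError(f"{path}: first header field must name the gene column")
    samples = [SampleInfo.from_label(str(c)) for c in raw.columns]
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate gene id {dup[0]!r}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        g, c = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: non-numeric or missing value {raw.iat[g, c]!r} "
            f"for gene {raw.index[g]!r}, column {raw.columns[c]!r}"
        )
    neg = (numeric.to_numpy() < 0)
    if neg.any():
        g, c = np.argwhere(neg)[0]
        raise ValidationError(
            f"{path}: negative value for gene {raw.index[g]!r}, column {raw.columns[c]!r}"
        )
    return AbundanceMatrix(numeric, samples, unit)


def write_abundance_table(matrix: AbundanceMatrix, path: str | Path) -> None:
    df = matrix.data.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Annotation gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class AnnotationDB:
    """Flat category -> gene-set map (GO-biological-process / KEGG style).

    ``categories`` maps category id to a frozen gene set; ``names`` carries the
    human-readable description from the GMT second field. No ontology
    traversal is performed: categories are plain sets.
    """

    categories: dict[str, frozenset]
    names: dict[str, str] = field(default_factory=dict)
    ontology: str = "other"

    def __post_init__(self):
        for cat, genes in self.categories.items():
            if not genes:
                raise ValidationError(f"category {cat!r} is empty")
            for g in genes:
                if not isinstance(g, str) or g == "" or any(ch.isspace() for ch in g):
                    raise ValidationError(
                        f"category {cat!r} contains invalid gene id {g!r}"
                    )

    def __len__(self) -> int:
        return len(self.categories)

    def annotated_genes(self) -> set[str]:
        out: set = set()
        for genes in self.categories.values():
            out |= genes
        return out


def read_gmt(path: str | Path, ontology: str = "other") -> AnnotationDB:
    """Read a GMT file. Duplicate genes within a line are deduplicated;
    duplicate category ids and lines with fewer than 3 fields are hard errors.
    An empty file yields an empty AnnotationDB."""
    path = Path(path)
    categories: dict[str, frozenset] = {}
    names: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line == "":
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            cat, desc, *genes = fields
            if cat in categories:
                raise FormatError(f"{path}:{lineno}: duplicate category id {cat!r}")
            genes = [g for g in genes if g != ""]
            categories[cat] = frozenset(genes)
            names[cat] = desc
    return AnnotationDB(categories, names, ontology)


def write_gmt(db: AnnotationDB, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cat in db.categories:
            genes = sorted(db.categories[cat])
            desc = db.names.get(cat, "")
            fh.write("\t".join([cat, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Ligand-receptor pairs
# ---------------------------------------------------------------------------


@dataclass
class LigandReceptorDB:
    """Set of directed (ligand, receptor) pairs with a provenance label."""

    pairs: tuple  # of (ligand, receptor, source)

    def __post_init__(self):
        seen: set = set()
        clean = []
        for lig, rec, src in self.pairs:
            if lig == rec:
                raise ValidationError(f"ligand-receptor pair with identical genes: {lig!r}")
            if (lig, rec) in seen:
                raise ValidationError(f"duplicate ligand-receptor pair ({lig!r}, {rec!r})")
            seen.add((lig, rec))
            clean.append((lig, rec, src))
        object.__setattr__(self, "pairs", tuple(clean))

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def ligands(self) -> set[str]:
        return {lig for lig, _, _ in self.pairs}

    @property
    def receptors(self) -> set[str]:
        return {rec for _, rec, _ in self.pairs}


def read_ligand_receptor_table(path: str | Path) -> LigandReceptorDB:
    """Read a 2-3 column TSV of ligand-receptor pairs.

    Duplicate pairs are deduplicated with a logged warning; a pair whose two
    genes are identical is a hard error.
    """
    path = Path(path)
    rows: list[tuple] = []
    seen: set = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line == "" or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: need at least 2 columns")
            lig, rec = fields[0], fields[1]
            src = fields[2] if len(fields) > 2 else ""
            if lig == rec:
                raise ValidationError(
                    f"{path}:{lineno}: self-pair {lig!r} (ligand == receptor)"
                )
            if (lig, rec) in seen:
                log.warning("%s:%d: duplicate pair (%s, %s) ignored", path, lineno, lig, rec)
                continue
            seen.add((lig, rec))
            rows.append((lig, rec, src))
    return LigandReceptorDB(tuple(rows))


def write_ligand_receptor_table(db: LigandReceptorDB, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for lig, rec, src in db.pairs:
            fh.write(f"{lig}\t{rec}\t{src}\n")


# ---------------------------------------------------------------------------
# Pathway graphs
# ---------------------------------------------------------------------------


@dataclass
class PathwayGraph:
    """A named directed signaling graph whose nodes carry role tags
    (``ligand``/``receptor``/``intermediate``/``tf``)."""

    name: str
    graph: nx.DiGraph

    def __post_init__(self):
        for u, v in self.graph.edges:
            if u == v:
                raise ValidationError(f"pathway {self.name!r}: self-loop on node {u!r}")
        for n, data in self.graph.nodes(data=True):
            role = data.get("role")
            if role not in PATHWAY_ROLES:
                raise ValidationError(
                    f"pathway {self.name!r}: node {n!r} has unknown role {role!r}"
                )
        # every receptor must be a source or fed by at least one ligand
        ligands = self.nodes_with_role("ligand")
        reachable_from_ligand: set = set()
        for lig in ligands:
            reachable_from_ligand |= nx.descendants(self.graph, lig)
        for rec in self.nodes_with_role("receptor"):
            if self.graph.in_degree(rec) > 0 and rec not in reachable_from_ligand:
                raise ValidationError(
                    f"pathway {self.name!r}: receptor {rec!r} is fed only by "
                    "non-ligand nodes and is not a source"
                )

    def nodes_with_role(self, role: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("role") == role}

    @property
    def node_set(self) -> frozenset:
        return frozenset(self.graph.nodes)


def read_pathway_table(path: str | Path, name: str | None = None) -> PathwayGraph:
    """Read a per-pathway edge list ``src<TAB>dst<TAB>role_src<TAB>role_dst``.

    Conflicting role tags for the same node and unknown role tags are hard
    errors, as are self-loop edges.
    """
    path = Path(path)
    if name is None:
        name = path.stem
    g = nx.DiGraph(name=name)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line == "" or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: need 4 columns, got {len(fields)}")
            src, dst, role_src, role_dst = fields
            if src == dst:
                raise ValidationError(f"{path}:{lineno}: self-loop edge on {src!r}")
            for node, role in ((src, role_src), (dst, role_dst)):
                if role not in PATHWAY_ROLES:
                    raise ValidationError(
                        f"{path}:{lineno}: unknown role tag {role!r} for node {node!r}"
                    )
                prev = g.nodes[node].get("role") if node in g else None
                if prev is not None and prev != role:
                    raise ValidationError(
                        f"{path}:{lineno}: node {node!r} tagged both {prev!r} and {role!r}"
                    )
                g.add_node(node, role=role)
            g.add_edge(src, dst)
    return PathwayGraph(name, g)


def write_pathway_table(pathway: PathwayGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in pathway.graph.edges:
            fh.write(
                f"{u}\t{v}\t{pathway.graph.nodes[u]['role']}\t{pathway.graph.nodes[v]['role']}\n"
            )


# ---------------------------------------------------------------------------
# TF -> target map and orthology
# ---------------------------------------------------------------------------


@dataclass
class TFTargetMap:
    """Map from transcription factor to its (nonempty) target gene set."""

    targets: dict[str, frozenset]

    def __post_init__(self):
        for tf, genes in self.targets.items():
            if not genes:
                raise ValidationError(f"TF {tf!r} has an empty target set")

    def __len__(self) -> int:
        return len(self.targets)

    def get(self, tf: str) -> frozenset:
        return self.targets.get(tf, frozenset())


def read_tf_target_table(path: str | Path) -> TFTargetMap:
    path = Path(path)
    acc: dict[str, set] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line == "" or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: need 2 columns, got {len(fields)}")
            tf, target = fields
            acc.setdefault(tf, set()).add(target)
    return TFTargetMap({tf: frozenset(v) for tf, v in acc.items()})


def write_tf_target_table(tft: TFTargetMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tf in sorted(tft.targets):
            for target in sorted(tft.targets[tf]):
                fh.write(f"{tf}\t{target}\n")


@dataclass
class OrthologyMap:
    """Many-to-one source gene -> destination gene map (e.g. mouse -> human)."""

    mapping: dict[str, str]

    def __post_init__(self):
        for src, dst in self.mapping.items():
            if not src or not dst:
                raise ValidationError(f"empty orthology mapping entry {src!r} -> {dst!r}")

    def __len__(self) -> int:
        return len(self.mapping)


def read_orthology_table(path: str | Path) -> OrthologyMap:
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line == "" or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: need 2 columns, got {len(fields)}")
            src, dst = fields
            if src in mapping and mapping[src] != dst:
                raise ValidationError(
                    f"{path}:{lineno}: conflicting orthology for {src!r}"
                )
            mapping[src] = dst
    return OrthologyMap(mapping)


def write_orthology_table(orth: OrthologyMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for src in sorted(orth.mapping):
            fh.write(f"{src}\t{orth.mapping[src]}\n")


def read_network_tables(
    pairs_path: str | Path,
    graph_paths: Iterable[str | Path],
    tf_targets_path: str | Path,
    orthology_path: str | Path | None = None,
):
    """Read all crosstalk-network inputs in one call.

    Returns ``(LigandReceptorDB, list[PathwayGraph], TFTargetMap, OrthologyMap | None)``.
    Orthology is read but *not* applied: mapping is the caller's explicit step.
    """
    lr = read_ligand_receptor_table(pairs_path)
    pathways = [read_pathway_table(p) for p in graph_paths]
    names = [p.name for p in pathways]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate pathway names among graph files")
    tft = read_tf_target_table(tf_targets_path)
    orth = read_orthology_table(orthology_path) if orthology_path is not None else None
    return lr, pathways, tft, orth
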