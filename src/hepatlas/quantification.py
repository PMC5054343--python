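"""iBAQ computation from peptide intensities and FOT normalization.

iBAQ (intensity-based absolute quantification) divides the summed peptide
intensity of a protein by the number of its theoretically observable tryptic
peptides. The digest uses the conventional trypsin rule — cleave C-terminal
of K or R, but not when the next residue is P — and an observable length
window of 6-30 residues with 0 missed cleavages by default; both are
configurable through :class:`DigestParams`.

FOT (fraction of total) divides each iBAQ value by its sample's total iBAQ,
so every sample column sums to 1. FOT is kept as a raw fraction; scaling to
ppm is a display concern only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ValidationError
from .io_formats import AbundanceMatrix, SampleInfo

log = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class DigestParams:
    """In-silico tryptic digest settings.

    ``missed_cleavages`` = 0 counts fully cleaved peptides only (the
    theoretical-peptide denominator of iBAQ); the observable window
    ``[min_len, max_len]`` is in residues.
    """

    missed_cleavages: int = 0
    min_len: int = 6
    max_len: int = 30

    def __post_init__(self):
        if self.missed_cleavages < 0:
            raise ValidationError("missed_cleavages must be >= 0")
        if not (0 <= self.min_len <= self.max_len):
            raise ValidationError("need 0 <= min_len <= max_len")


def digest_protein(sequence: str, params: DigestParams = DigestParams()) -> list[str]:
    """Cleave ``sequence`` after K/R (not before P).

    With 0 missed cleavages the returned peptides tile the sequence exactly;
    with ``m`` missed cleavages all concatenations of up to ``m + 1`` adjacent
    fragments are returned, ordered by start position then length.
    """
    if not sequence:
        raise ValidationError("empty protein sequence")
    for pos, ch in enumerate(sequence):
        if ch not in AMINO_ACIDS:
            raise ValidationError(
                f"illegal amino-acid character {ch!r} at position {pos + 1}"
            )
    fragments: list[str] = []
    start = 0
    for i, ch in enumerate(sequence):
        if ch in "KR" and (i + 1 == len(sequence) or sequence[i + 1] != "P"):
            fragments.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        fragments.append(sequence[start:])
    if params.missed_cleavages == 0:
        return fragments
    peptides = []
    for i in range(len(fragments)):
        for j in range(i, min(i + params.missed_cleavages + 1, len(fragments))):
            peptides.append("".join(fragments[i : j + 1]))
    return peptides


def observable_peptide_count(sequence: str, params: DigestParams = DigestParams()) -> int:
    """Number of digest peptides inside the observable length window —
    the iBAQ denominator."""
    return sum(
        1
        for pep in digest_protein(sequence, params)
        if params.min_len <= len(pep) <= params.max_len
    )


def read_peptide_intensity_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV peptide table ``protein<TAB>peptide<TAB>sample1...``.

    Peptide sequences must be uppercase amino-acid strings; intensities must
    be finite and nonnegative.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValidationError("peptide table needs protein, peptide and >= 1 sample column")
    df = df.rename(columns={df.columns[0]: "protein", df.columns[1]: "peptide"})
    _validate_peptide_table(df)
    return df


def _validate_peptide_table(table: pd.DataFrame) -> None:
    if "protein" not in table.columns or "peptide" not in table.columns:
        raise ValidationError("peptide table must have 'protein' and 'peptide' columns")
    for pep in table["peptide"]:
        if not pep or any(ch not in AMINO_ACIDS for ch in str(pep)):
            raise ValidationError(f"invalid peptide sequence {pep!r}")
    sample_cols = [c for c in table.columns if c not in ("protein", "peptide")]
    vals = table[sample_cols].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValidationError("peptide intensities must be finite")
    if (vals < 0).any():
        raise ValidationError("peptide intensities must be >= 0")


def compute_ibaq(
    table: pd.DataFrame,
    fasta_path: str | Path,
    params: DigestParams = DigestParams(),
) -> AbundanceMatrix:
    """Per protein and sample: iBAQ = summed peptide intensity / number of
    theoretically observable peptides.

    Proteins whose theoretical-peptide count is 0 are dropped with a logged
    warning; a protein missing from the FASTA is a hard error. Sample column
    headers must follow the ``CELL_rep[_dDAY]`` grammar.
    """
    _validate_peptide_table(table)
    sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    sample_cols = [c for c in table.columns if c not in ("protein", "peptide")]
    samples = [SampleInfo.from_label(str(c)) for c in sample_cols]

    summed = table.groupby("protein", sort=True)[sample_cols].sum()
    rows = {}
    for protein, intensities in summed.iterrows():
        if protein not in sequences:
            raise ValidationError(f"protein {protein!r} missing from FASTA {fasta_path}")
        denom = observable_peptide_count(sequences[protein], params)
        if denom == 0:
            log.warning(
                "protein %s has no observable theoretical peptides; dropped", protein
            )
            continue
        rows[protein] = intensities.to_numpy(dtype=float) / denom
    data = pd.DataFrame.from_dict(rows, orient="index", columns=sample_cols)
    return AbundanceMatrix(data, samples, unit="ibaq")


def normalize_fot(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Divide each column by its sum so that every sample sums to 1.

    Idempotent and scale-invariant; an all-zero column is a hard error.
    """
    values = matrix.data.to_numpy(dtype=float)
    sums = values.sum(axis=0)
    zero = sums <= 0
    if zero.any():
        c = int(np.argmax(zero))
        raise ValidationError(
            f"cannot FOT-normalize all-zero sample {matrix.samples[c].label}"
        )
    out = pd.DataFrame(values / sums, index=matrix.data.index, columns=matrix.data.columns)
    return AbundanceMatrix(out, matrix.samples, unit="fot")
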