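"""Sequence and alignment I/O, dereplication, and score-table serialization.

Protein sequences use the 20 standard amino-acid letters plus ``X`` for
anything unresolved; non-standard residue codes (B, J, O, U, Z, ...) are
mapped to ``X`` on input so that every downstream bit score stays defined.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentShapeError,
    DuplicateIdError,
    EmptyInputError,
    ParameterError,
)

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")
GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence.

    Attributes
    ----------
    id : str
        Unique identifier without whitespace.
    residues : str
        Non-empty string over the 20 amino-acid letters plus ``X``.
    description : str
        Optional free-text description.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise ParameterError(f"sequence id {self.id!r} is empty or contains whitespace")
        if not self.residues:
            raise EmptyInputError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ParameterError(
                f"sequence {self.id!r} contains invalid residues {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MultipleAlignment:
    """An ungapped-consistent multiple alignment (rows of equal length)."""

    ids: tuple
    rows: tuple

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise AlignmentShapeError("ids and rows differ in length")
        if len(self.rows) < 2:
            raise AlignmentShapeError("alignment needs at least 2 rows")
        if len(set(self.ids)) != len(self.ids):
            raise DuplicateIdError("alignment ids are not unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            detail = ", ".join(
                f"{i}={len(r)}" for i, r in zip(self.ids, self.rows)
            )
            raise AlignmentShapeError(f"ragged alignment rows: {detail}")
        if self.n_columns < 1:
            raise AlignmentShapeError("alignment has zero columns")
        for sid, row in zip(self.ids, self.rows):
            ungapped = "".join(c for c in row if c not in GAP_CHARS)
            # Raises if the ungapped row is empty or off-alphabet.
            ProteinSequence(id=sid, residues=ungapped)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


def _clean_residues(raw: str, seq_id: str) -> str:
    s = raw.upper().replace("*", "").replace("-", "").replace(".", "")
    cleaned = []
    mapped = set()
    for c in s:
        if c in VALID_RESIDUES:
            cleaned.append(c)
        else:
            cleaned.append("X")
            mapped.add(c)
    if mapped:
        logger.warning(
            "sequence %s: mapped non-standard residues %s to 'X'",
            seq_id,
            sorted(mapped),
        )
    return "".join(cleaned)


def read_fasta(stream) -> list[ProteinSequence]:
    """Read protein FASTA into a list of :class:`ProteinSequence`.

    Residues are uppercased, ``*`` stop marks stripped, and characters
    outside the alphabet mapped to ``X`` with a logged warning.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records = list(SeqIO.parse(stream, "fasta"))
    if not records:
        raise EmptyInputError("no FASTA records in stream")
    out, seen = [], set()
    for rec in records:
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = _clean_residues(str(rec.seq), rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        out.append(ProteinSequence(id=rec.id, residues=residues, description=desc))
    return out


def write_fasta(seqs, stream, width: int = 60) -> None:
    """Write sequences as FASTA, wrapping at ``width`` columns."""
    if width < 1:
        raise ParameterError("width must be a positive integer")
    for s in seqs:
        header = f">{s.id}" + (f" {s.description}" if s.description else "")
        stream.write(header + "\n")
        for i in range(0, len(s.residues), width):
            stream.write(s.residues[i : i + width] + "\n")


def _read_minimal_stockholm(text: str) -> list[tuple[str, str]]:
    """Single-block Stockholm: ``id  seq`` lines, '#' annotations ignored."""
    pairs = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line == "//":
            continue
        parts = line.split()
        if len(parts) != 2:
            raise AlignmentShapeError(f"unparseable Stockholm line: {line!r}")
        pairs.append((parts[0], parts[1]))
    return pairs


def read_alignment(stream, format: str = "afa") -> MultipleAlignment:
    """Read an aligned FASTA ("afa") or minimal Stockholm alignment.

    Rows are uppercased and Stockholm ``.`` gaps converted to ``-``.
    Ragged rows raise :class:`AlignmentShapeError` naming the offenders.
    """
    if isinstance(stream, str):
        text = stream
    else:
        text = stream.read()
    if format == "afa":
        recs = list(SeqIO.parse(io.StringIO(text), "fasta"))
        if not recs:
            raise EmptyInputError("no alignment records in stream")
        pairs = [(r.id, str(r.seq)) for r in recs]
    elif format == "stockholm":
        pairs = _read_minimal_stockholm(text)
        if not pairs:
            raise EmptyInputError("no alignment records in stream")
    else:
        raise ParameterError(f"unknown alignment format {format!r}")
    ids = tuple(p[0] for p in pairs)
    rows = []
    for sid, row in pairs:
        row = row.upper().replace(".", "-")
        rows.append("".join(c if c in VALID_RESIDUES or c == "-" else "X" for c in row))
    return MultipleAlignment(ids=ids, rows=tuple(rows))


def write_alignment(msa: MultipleAlignment, stream, format: str = "afa") -> None:
    if format != "afa":
        raise ParameterError("only 'afa' output is supported")
    for sid, row in zip(msa.ids, msa.rows):
        stream.write(f">{sid}\n{row}\n")


def dereplicate(seqs) -> list[ProteinSequence]:
    """Remove sequences equal to, or contained in, another sequence.

    Within a redundant group the longest sequence survives, ties broken by
    lexicographically smallest id; output preserves the input order of the
    survivors. Membership of the result is permutation-invariant.
    """
    # Longest first so every potential container is kept before its substrings.
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i].residues), seqs[i].id))
    kept_idx: list[int] = []
    kept_residues: list[str] = []
    for i in order:
        r = seqs[i].residues
        if any(r in other for other in kept_residues):
            continue
        kept_idx.append(i)
        kept_residues.append(r)
    kept_idx.sort()
    return [seqs[i] for i in kept_idx]


def write_scores_tsv(matrix: pd.DataFrame, stream, header_comment: str | None = None) -> None:
    """Write a sequences x HMMs bit-score matrix as TSV (1 decimal place).

    The layout follows tabular homology-search output: a ``seq_id`` column
    followed by one column per profile; missing scores print as 0.0.
    """
    if header_comment:
        for line in header_comment.splitlines():
            stream.write(f"# {line}\n")
    cols = list(matrix.columns)
    stream.write("\t".join(["seq_id"] + [str(c) for c in cols]) + "\n")
    for sid, row in matrix.iterrows():
        vals = ["0.0" if pd.isna(v) else f"{v:.1f}" for v in row.to_numpy()]
        stream.write("\t".join([str(sid)] + vals) + "\n")


def read_scores_tsv(stream) -> pd.DataFrame:
    """Paired reader for :func:`write_scores_tsv`."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    df = pd.read_csv(stream, sep="\t", comment="#")
    if "seq_id" not in df.columns:
        raise ParameterError("score table lacks a seq_id column")
    return df.set_index("seq_id")
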