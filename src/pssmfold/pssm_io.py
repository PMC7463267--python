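"""Reading and writing PSI-BLAST ASCII PSSM profiles and labeled FASTA sets.

A profile is the L x 20 block of position-specific log-odds substitution
scores emitted by ``psiblast -out_ascii_pssm``.  Only that first block is
retained: the weighted-percentage block and the trailing per-position
statistics are parsed past and discarded.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from scipy.special import expit

#: Column order used internally, identical to the order PSI-BLAST prints.
PSIBLAST_COLUMNS: tuple[str, ...] = tuple("ARNDCQEGHILKMFPSTWYV")

NORMALIZATION_MODES = ("raw", "sigmoid")


class PSSMParseError(ValueError):
    """Raised when an ASCII PSSM file does not follow the expected layout."""


@dataclass
class PSSMProfile:
    """One protein's evolutionary profile: sequence plus L x 20 score matrix.

    Scores are held as floats; PSI-BLAST prints integers but downstream
    normalization may map them into (0, 1).  ``column_order`` records the
    amino-acid letter of each score column and is always the canonical
    PSI-BLAST ordering after parsing.
    """

    protein_id: str
    sequence: str
    scores: np.ndarray
    column_order: tuple[str, ...] = PSIBLAST_COLUMNS

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"profile {self.protein_id!r}: scores must be L x 20, "
                f"got shape {self.scores.shape}"
            )
        if len(self.sequence) == 0:
            raise ValueError(f"profile {self.protein_id!r}: empty sequence")
        if self.scores.shape[0] != len(self.sequence):
            raise ValueError(
                f"profile {self.protein_id!r}: {self.scores.shape[0]} score rows "
                f"but sequence length {len(self.sequence)}"
            )
        if len(self.column_order) != 20:
            raise ValueError("column_order must list exactly 20 amino acids")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError(f"profile {self.protein_id!r}: non-finite score entries")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass
class LabeledSequenceSet:
    """Sequences with fold labels; label order follows first appearance."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)
    fold_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate protein ids: {dupes}")
        known = set(self.fold_labels)
        for pid, _, lab in self.entries:
            if lab not in known:
                raise ValueError(f"entry {pid!r} has unknown fold label {lab!r}")


def _is_header_line(tokens: list[str]) -> bool:
    return len(tokens) >= 20 and all(len(t) == 1 and t.isalpha() for t in tokens[:20])


def parse_pssm(text: str, protein_id: str = "") -> PSSMProfile:
    """Parse PSI-BLAST ``-out_ascii_pssm`` output into a :class:`PSSMProfile`.

    The 20-letter column order is read from the header line rather than
    assumed, then scores are reordered to :data:`PSIBLAST_COLUMNS`.  Only the
    log-odds block (first 20 numeric columns of each residue row) is kept.
    """
    lines = text.splitlines()
    header_order: list[str] | None = None
    seq_letters: list[str] = []
    rows: list[list[float]] = []
    expected_pos = 0

    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if not tokens:
            continue
        if header_order is None:
            if _is_header_line(tokens):
                header_order = tokens[:20]
                if sorted(header_order) != sorted(PSIBLAST_COLUMNS):
                    raise PSSMParseError(
                        f"line {lineno}: header does not list the 20 standard "
                        f"amino acids: {header_order}"
                    )
            continue
        # Residue rows: position index, residue letter, >= 20 numeric scores.
        if not tokens[0].isdigit():
            if rows:
                break  # footer statistics reached
            continue
        pos = int(tokens[0])
        if pos != expected_pos + 1:
            raise PSSMParseError(
                f"line {lineno}: expected position {expected_pos + 1}, got {pos}"
            )
        if len(tokens) < 2 or not (len(tokens[1]) == 1 and tokens[1].isalpha()):
            raise PSSMParseError(f"line {lineno}: missing residue letter")
        numeric = tokens[2:]
        if len(numeric) < 20:
            raise PSSMParseError(
                f"line {lineno}: expected at least 20 score columns, "
                f"got {len(numeric)}"
            )
        try:
            row = [float(v) for v in numeric[:20]]
        except ValueError as exc:
            raise PSSMParseError(f"line {lineno}: non-numeric score: {exc}") from None
        seq_letters.append(tokens[1])
        rows.append(row)
        expected_pos = pos

    if header_order is None:
        raise PSSMParseError("no amino-acid header line found")
    if not rows:
        raise PSSMParseError("no residue rows found (empty matrix)")

    scores = np.asarray(rows, dtype=float)
    order = [header_order.index(aa) for aa in PSIBLAST_COLUMNS]
    scores = scores[:, order]
    return PSSMProfile(
        protein_id=protein_id,
        sequence="".join(seq_letters),
        scores=scores,
    )


def serialize_pssm(profile: PSSMProfile) -> str:
    """Render a profile in the PSI-BLAST ASCII dialect ``parse_pssm`` reads.

    Integer-valued scores print as integers so round-trips are exact for
    PSI-BLAST-style matrices.  The percentage block is filled with zeros.
    """
    buf = io.StringIO()
    buf.write(
        "\nLast position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts\n"
    )
    letters = "   ".join(profile.column_order)
    buf.write(f"            {letters}   {letters}\n")
    for j, (aa, row) in enumerate(zip(profile.sequence, profile.scores), start=1):
        cells = " ".join(
            f"{int(v):3d}" if float(v).is_integer() else f"{v:7.3f}" for v in row
        )
        pct = " ".join("  0" for _ in range(20))
        buf.write(f"{j:5d} {aa}  {cells}  {pct}  0.00 0.00\n")
    buf.write("\n                      K         Lambda\n")
    buf.write("Standard Ungapped    0.1347     0.3179\n")
    return buf.getvalue()


def read_labeled_fasta(fasta: str, labels: str) -> LabeledSequenceSet:
    """Join FASTA records with a two-column ``id<TAB>fold`` label table.

    Entries keep FASTA order; distinct fold labels are collected in order of
    first appearance.
    """
    label_map: dict[str, str] = {}
    for lineno, line in enumerate(labels.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(
                f"label table line {lineno}: expected 2 tab-separated columns"
            )
        label_map[parts[0]] = parts[1]

    records = list(SeqIO.parse(io.StringIO(fasta), "fasta"))
    if not records:
        raise ValueError("empty FASTA input")

    seen: set[str] = set()
    missing: list[str] = []
    entries: list[tuple[str, str, str]] = []
    fold_order: list[str] = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        if rec.id not in label_map:
            missing.append(rec.id)
            continue
        lab = label_map[rec.id]
        if lab not in fold_order:
            fold_order.append(lab)
        entries.append((rec.id, str(rec.seq), lab))
    if missing:
        raise ValueError(f"FASTA ids missing from label table: {missing}")
    return LabeledSequenceSet(entries=entries, fold_labels=tuple(fold_order))


def normalize_profile(p: PSSMProfile, mode: str = "raw") -> PSSMProfile:
    """Return a profile with scores transformed per ``mode``.

    ``raw`` is the identity; ``sigmoid`` maps each score x to 1/(1+e^-x),
    squashing log-odds into (0, 1).
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(
            f"unknown normalization mode {mode!r}; expected one of "
            f"{NORMALIZATION_MODES}"
        )
    if mode == "raw":
        scores = p.scores.copy()
    else:
        scores = expit(p.scores)
    return PSSMProfile(
        protein_id=p.protein_id,
        sequence=p.sequence,
        scores=scores,
        column_order=p.column_order,
    )
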