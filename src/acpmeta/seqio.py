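"""Peptide FASTA input/output, validation and redundancy filtering.

Dataset-mode validation enforces the benchmark construction rules: standard
20-residue alphabet and length between 5 and 50 residues.  Redundancy
filtering is a documented greedy approximation of CD-HIT-style clustering at
an identity threshold; it is not bit-compatible with CD-HIT.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tables import AA_ORDER

VALID_RESIDUES = frozenset(AA_ORDER)

MIN_LENGTH = 5
MAX_LENGTH = 50

POSITIVE_LABEL = "ACP"
NEGATIVE_LABEL = "non-ACP"


class FastaError(ValueError):
    """Raised for unreadable or empty FASTA input."""


class ValidationError(ValueError):
    """Raised in strict mode when a record fails validation."""


@dataclass(frozen=True)
class Peptide:
    """A validated peptide record: identifier, residues and optional class tag."""

    id: str
    sequence: str
    label: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Rejection:
    """Machine-readable reason a record was excluded from a set."""

    id: str
    reason: str


@dataclass
class PeptideSet:
    """Ordered collection of peptides with unique ids and provenance."""

    records: list[Peptide] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)
    rejections: list[Rejection] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate peptide ids: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.records)

    def __getitem__(self, i: int) -> Peptide:
        return self.records[i]

    def ids(self) -> list[str]:
        return [p.id for p in self.records]

    def sequences(self) -> list[str]:
        return [p.sequence for p in self.records]

    def labels(self) -> list[str | None]:
        return [p.label for p in self.records]


def normalize_sequence(raw: str) -> str:
    """Uppercase, strip whitespace and a trailing stop character."""
    seq = "".join(raw.split()).upper()
    return seq.rstrip("*")


def validate_sequence(seq: str, enforce_length: bool = True) -> str | None:
    """Return a rejection reason, or None if the sequence is valid.

    ``enforce_length`` switches on the dataset rule 5 <= L <= 50.
    """
    if not seq:
        return "empty sequence"
    bad = sorted(set(seq) - VALID_RESIDUES)
    if bad:
        return f"non-standard residues: {','.join(bad)}"
    if enforce_length:
        if len(seq) < MIN_LENGTH:
            return f"length {len(seq)} < {MIN_LENGTH}"
        if len(seq) > MAX_LENGTH:
            return f"length {len(seq)} > {MAX_LENGTH}"
    return None


def read_fasta(
    path: str | Path,
    enforce_length: bool = True,
    strict: bool = False,
    label: str | None = None,
) -> PeptideSet:
    """Read a peptide FASTA file into a validated :class:`PeptideSet`.

    Sequences are case-normalized; invalid records are skipped with a recorded
    :class:`Rejection` in lenient mode (default) or raise
    :class:`ValidationError` in strict mode.  ``label`` tags every accepted
    record with a class (e.g. when reading a positive training file).
    """
    path = Path(path)
    if not path.exists():
        raise FastaError(f"no such file: {path}")
    try:
        raw = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # pragma: no cover - biopython wraps I/O oddly
        raise FastaError(f"could not parse {path}: {exc}") from exc
    if not raw:
        raise FastaError(f"no FASTA records in {path}")

    records: list[Peptide] = []
    rejections: list[Rejection] = []
    seen: set[str] = set()
    for rec in raw:
        seq = normalize_sequence(str(rec.seq))
        reason = validate_sequence(seq, enforce_length=enforce_length)
        if reason is None and rec.id in seen:
            reason = "duplicate id"
        if reason is not None:
            if strict:
                raise ValidationError(f"record {rec.id!r}: {reason}")
            rejections.append(Rejection(rec.id, reason))
            continue
        seen.add(rec.id)
        records.append(Peptide(rec.id, seq, label))
    return PeptideSet(records, provenance=[str(path)], rejections=rejections)


def write_fasta(pset: PeptideSet | Iterable[Peptide], path: str | Path) -> None:
    """Write peptides as unwrapped multi-record FASTA."""
    recs = [SeqRecord(Seq(p.sequence), id=p.id, description="") for p in pset]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta-2line")


def write_rejections(pset: PeptideSet, path: str | Path) -> None:
    """Write the rejection report as TSV (id, reason)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "reason"])
        for r in pset.rejections:
            w.writerow([r.id, r.reason])


def _aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(a: str, b: str, aligner: PairwiseAligner | None = None) -> float:
    """Global-alignment identity: matched positions / length of the shorter sequence.

    The shorter-sequence denominator follows the CD-HIT convention.
    """
    if aligner is None:
        aligner = _aligner()
    aln = aligner.align(a, b)[0]
    return aln.counts().identities / min(len(a), len(b))


def redundancy_filter(pset: PeptideSet, identity_threshold: float) -> PeptideSet:
    """Greedy longest-first redundancy reduction at an identity threshold.

    Peptides are visited from longest to shortest (ties keep input order); a
    peptide is absorbed by the first existing representative to which its
    global-alignment identity reaches the threshold, otherwise it becomes a new
    representative.  Approximates CD-HIT clustering without its word-filter
    heuristics.  Returned representatives keep the original input order.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError(f"identity_threshold must be in (0, 1], got {identity_threshold}")
    if len(pset) == 0:
        raise ValueError("cannot filter an empty peptide set")

    aligner = _aligner()
    order = sorted(range(len(pset)), key=lambda i: -len(pset[i]))
    reps: list[int] = []
    for i in order:
        p = pset[i]
        for j in reps:
            if pairwise_identity(p.sequence, pset[j].sequence, aligner) >= identity_threshold:
                break
        else:
            reps.append(i)
    keep = sorted(reps)
    return PeptideSet(
        [pset[i] for i in keep],
        provenance=list(pset.provenance),
    )


def labels_to_y(pset: PeptideSet) -> "list[int]":
    """Map class tags to 1 (positive) / 0 (negative); unknown tags raise."""
    y = []
    for p in pset:
        if p.label == POSITIVE_LABEL:
            y.append(1)
        elif p.label == NEGATIVE_LABEL:
            y.append(0)
        else:
            raise ValueError(f"peptide {p.id!r} has no binary class label ({p.label!r})")
    return y


def concat(a: PeptideSet, b: PeptideSet) -> PeptideSet:
    """Concatenate two sets (ids must stay unique)."""
    return PeptideSet(
        list(a.records) + list(b.records),
        provenance=list(a.provenance) + list(b.provenance),
    )
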