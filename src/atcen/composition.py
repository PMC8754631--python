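"""Composition analytics on DNA sequences.

The centromeres of many eukaryotes are enriched for A and T nucleotides
relative to the genome average, and in fission yeast an A+T fraction above
roughly 0.75 over a few kilobases is sufficient for a sequence to acquire
centromere function when placed next to a native centromere.  This module
provides the elementary measurements that the rest of the package is built
on: bulk and windowed A+T fraction, detection of A/T homopolymer runs (the
structural unit of A/T tract organisation), and a simple rule-based
classifier that maps (A+T fraction, length) onto an expected centromere
competence class.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AnnotatedSequence",
    "CompositionProfile",
    "HomopolymerRun",
    "CompetenceThresholds",
    "CompetenceCall",
    "at_fraction",
    "gc_fraction",
    "windowed_at",
    "find_at_runs",
    "classify_competence",
    "read_fasta",
    "write_fasta",
]

_VALID = frozenset("ACGT")
# IUPAC ambiguity codes that denote a non-A/T-only base set; under the
# permissive mode they are counted as G/C-equivalent.
_AMBIGUOUS = frozenset("RYSWKMBDHVN")


@dataclass(frozen=True)
class HomopolymerRun:
    """A maximal run of a single base (or of mixed A/T, if requested)."""

    start: int
    end: int
    base: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedSequence:
    """A named DNA string with optional interval features.

    Residues are normalised to upper case on construction.  In strict mode
    (the default) any residue outside {A, C, G, T} raises ``ValueError``
    naming the offending position; with ``strict=False`` IUPAC ambiguity
    codes are retained and treated as G/C-equivalent by the composition
    operations.

    Features are ``(start, end, kind)`` triples in 0-based half-open
    coordinates.
    """

    id: str
    residues: str
    features: list[tuple[int, int, str]] = field(default_factory=list)
    strict: bool = True

    def __post_init__(self) -> None:
        seq = self.residues.upper()
        if len(seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        allowed = _VALID if self.strict else (_VALID | _AMBIGUOUS)
        for pos, ch in enumerate(seq):
            if ch not in allowed:
                raise ValueError(
                    f"sequence {self.id!r}: invalid residue {ch!r} at position {pos}"
                )
        object.__setattr__(self, "residues", seq)
        for (s, e, kind) in self.features:
            if not (0 <= s < e <= len(seq)):
                raise ValueError(
                    f"sequence {self.id!r}: feature {kind!r} interval "
                    f"[{s},{e}) out of bounds for length {len(seq)}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int, new_id: str | None = None) -> "AnnotatedSequence":
        """Subsequence [start, end); features are dropped."""
        return AnnotatedSequence(
            id=new_id or f"{self.id}:{start}-{end}",
            residues=self.residues[start:end],
            strict=self.strict,
        )

    def at_indicator(self) -> np.ndarray:
        """Per-base 0/1 array marking A/T residues."""
        arr = np.frombuffer(self.residues.encode("ascii"), dtype=np.uint8)
        return ((arr == ord("A")) | (arr == ord("T"))).astype(np.int64)


def at_fraction(seq: AnnotatedSequence) -> float:
    """Fraction (A+T)/length of a sequence.

    The count and length are exact integers; a single division produces the
    returned float.
    """
    n_at = seq.residues.count("A") + seq.residues.count("T")
    return n_at / len(seq)


def gc_fraction(seq: AnnotatedSequence) -> float:
    """Complement of :func:`at_fraction` (ambiguity codes count as G/C)."""
    return 1.0 - at_fraction(seq)


@dataclass
class CompositionProfile:
    """Windowed A+T fractions over a sequence (tiled or sliding)."""

    window: int
    step: int
    starts: np.ndarray
    values: np.ndarray
    sequence_id: str = ""

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.starts.shape != self.values.shape:
            raise ValueError("starts and values must have equal length")

    def to_bedgraph(self, path: str | Path, chrom: str | None = None) -> None:
        chrom = chrom or self.sequence_id or "seq"
        with open(path, "w") as fh:
            for s, v in zip(self.starts, self.values):
                fh.write(f"{chrom}\t{s}\t{s + self.window}\t{v:.6g}\n")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("start\tend\tat_fraction\n")
            for s, v in zip(self.starts, self.values):
                fh.write(f"{s}\t{s + self.window}\t{v:.6g}\n")


def windowed_at(seq: AnnotatedSequence, window: int, step: int = 0) -> CompositionProfile:
    """A+T fraction in windows of ``window`` bp every ``step`` bp.

    ``step`` defaults to ``window`` (tiled, non-overlapping windows).  A
    trailing window that would extend past the end of the sequence is
    dropped.
    """
    if step == 0:
        step = window
    n = len(seq)
    if not (1 <= window <= n):
        raise ValueError(f"window {window} must be in [1, {n}]")
    if step < 1:
        raise ValueError("step must be >= 1")
    ind = seq.at_indicator()
    csum = np.concatenate([[0], np.cumsum(ind)])
    starts = np.arange(0, n - window + 1, step, dtype=np.int64)
    values = (csum[starts + window] - csum[starts]) / window
    return CompositionProfile(window=window, step=step, starts=starts,
                              values=values, sequence_id=seq.id)


def find_at_runs(seq: AnnotatedSequence, min_len: int = 3,
                 mixed: bool = False) -> list[HomopolymerRun]:
    """Maximal A or T homopolymer runs of length >= ``min_len``.

    With ``mixed=True`` maximal tracts of mixed A/T (e.g. ``ATAT``) are
    reported instead, with ``base == "AT"`` — a sensitivity-analysis mode;
    the default treats an A-run and an adjacent T-run as distinct runs.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if mixed:
        pattern = re.compile(r"[AT]{%d,}" % min_len)
        return [HomopolymerRun(m.start(), m.end(), "AT")
                for m in pattern.finditer(seq.residues)]
    pattern = re.compile(r"A{%d,}|T{%d,}" % (min_len, min_len))
    return [HomopolymerRun(m.start(), m.end(), seq.residues[m.start()])
            for m in pattern.finditer(seq.residues)]


@dataclass(frozen=True)
class CompetenceThresholds:
    """Thresholds of the centromere-competence rule.

    ``active_at`` is the lowest A+T fraction observed to give stable
    centromere function (0.747 for the bacterial test sequences);
    ``unstable_at`` the composition at which centromeres form but are lost
    on propagation (0.71); ``min_length_bp`` the approximate minimum length
    for stable function (between the 4.17 kb stable and 3.59 kb unstable
    experimental constructs; 4000 bp by default).
    """

    min_length_bp: int = 4000
    unstable_at: float = 0.71
    active_at: float = 0.747

    def __post_init__(self) -> None:
        if self.min_length_bp < 1:
            raise ValueError("min_length_bp must be >= 1")
        if not (0.0 < self.unstable_at < self.active_at <= 1.0):
            raise ValueError(
                "thresholds must satisfy 0 < unstable_at < active_at <= 1"
            )


@dataclass(frozen=True)
class CompetenceCall:
    label: str  # one of {active, unstable, inactive, too_short}
    at_fraction: float
    length_bp: int


def classify_competence(at: float, length_bp: int,
                        thresholds: CompetenceThresholds | None = None) -> CompetenceCall:
    """Classify a candidate sequence by the empirical competence rule.

    A sequence shorter than the minimum length is ``too_short`` regardless
    of composition; otherwise the A+T fraction decides between ``active``
    (>= active threshold), ``unstable`` (in the threshold band) and
    ``inactive`` (below it).
    """
    if not (0.0 <= at <= 1.0):
        raise ValueError("at must be in [0, 1]")
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    t = thresholds or CompetenceThresholds()
    if length_bp < t.min_length_bp:
        label = "too_short"
    elif at >= t.active_at:
        label = "active"
    elif at >= t.unstable_at:
        label = "unstable"
    else:
        label = "inactive"
    return CompetenceCall(label=label, at_fraction=at, length_bp=length_bp)


def read_fasta(path: str | Path, strict: bool = True) -> list[AnnotatedSequence]:
    """Read a multi-record FASTA file into AnnotatedSequences."""
    return [
        AnnotatedSequence(id=rec.id, residues=str(rec.seq), strict=strict)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Iterable[AnnotatedSequence], path: str | Path) -> None:
    """Write sequences as FASTA, wrapped at 60 columns."""
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")
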