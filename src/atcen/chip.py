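"""CENP-A ChIP coverage quantitation over engineered centromere candidates.

An engineered candidate placed next to the native centromere is nearly
identical to the native locus, so reads must be attributed using the small
deletion markers introduced at design time: a read that spans a deletion
junction carries a junction word unique to the experimental copy, while a
read over the corresponding undeleted native bases carries the native word.
Reads touching no marker are structurally ambiguous.

Coverage is computed from read placements (alignment itself is external;
this module consumes a plain placement table or a text SAM file), and
enrichment is normalised to the average read count over two reference
centromeres so that independent immunoprecipitations are comparable.
The 180 bp-segment regression asks whether local A+T composition predicts
local CENP-A occupancy along a candidate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import stats

from .composition import AnnotatedSequence, windowed_at
from .design import MarkerSet

__all__ = [
    "ReadPlacement",
    "CoverageTrack",
    "MarkerIndex",
    "ReadPartition",
    "RegressionResult",
    "coverage",
    "normalize_to_reference",
    "assign_reads",
    "binding_at_regression",
    "read_placements_tsv",
    "write_placements_tsv",
    "read_placements_sam",
]


@dataclass(frozen=True)
class ReadPlacement:
    """One read placed on a named reference; sequence is optional and only
    needed for marker-based discrimination."""

    reference: str
    start: int
    end: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"placement [{self.start},{self.end}) is empty")
        if self.start < 0:
            raise ValueError("placement start must be >= 0")


@dataclass
class CoverageTrack:
    """Per-base depth over one reference, with a normalisation factor.

    ``depth`` holds raw counts; ``normalized()`` returns depth divided by
    ``norm_factor`` (1.0 until :func:`normalize_to_reference` is applied).
    """

    reference: str
    depth: np.ndarray
    norm_factor: float = 1.0

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.float64)
        if self.norm_factor <= 0:
            raise ValueError("norm_factor must be positive")
        if (self.depth < 0).any():
            raise ValueError("depth values must be non-negative")

    def normalized(self) -> np.ndarray:
        return self.depth / self.norm_factor

    def to_bedgraph(self, path: str | Path, normalized: bool = True) -> None:
        vals = self.normalized() if normalized else self.depth
        with open(path, "w") as fh:
            i = 0
            n = len(vals)
            while i < n:  # run-length encode constant stretches
                j = i + 1
                while j < n and vals[j] == vals[i]:
                    j += 1
                fh.write(f"{self.reference}\t{i}\t{j}\t{vals[i]:.6g}\n")
                i = j


def coverage(placements: Iterable[ReadPlacement], reference_length: int,
             reference: str | None = None) -> CoverageTrack:
    """Per-base depth: depth[i] = number of placements covering base i."""
    placements = list(placements)
    if reference is None:
        refs = {p.reference for p in placements}
        if len(refs) > 1:
            raise ValueError(f"placements span multiple references {sorted(refs)}; "
                             "pass reference= explicitly")
        reference = refs.pop() if refs else "ref"
    else:
        placements = [p for p in placements if p.reference == reference]
    offenders = [p for p in placements if p.end > reference_length]
    if offenders:
        raise ValueError(
            f"{len(offenders)} placement(s) extend beyond reference length "
            f"{reference_length}; first: {offenders[0]}"
        )
    delta = np.zeros(reference_length + 1, dtype=np.int64)
    for p in placements:
        delta[p.start] += 1
        delta[p.end] -= 1
    return CoverageTrack(reference=reference, depth=np.cumsum(delta[:-1]))


def normalize_to_reference(track: CoverageTrack,
                           ref_read_counts: tuple[float, float]) -> CoverageTrack:
    """Normalise to the mean read count over two reference centromeres.

    The norm factor is (count_cen1 + count_cen3)/2; normalised values are
    depth divided by that factor, making tracks from libraries of
    different depth comparable.
    """
    c1, c3 = ref_read_counts
    if c1 <= 0 or c3 <= 0:
        raise ValueError("reference read counts must be positive")
    return CoverageTrack(reference=track.reference, depth=track.depth.copy(),
                         norm_factor=(c1 + c3) / 2.0)


@dataclass
class MarkerIndex:
    """Junction words discriminating experimental from native reads.

    For each deletion marker, the experimental word is the fixed-length
    substring of the marked sequence spanning the deletion junction
    (``flank`` bases each side); the native word is the corresponding
    undeleted stretch of the original sequence (flank + deleted bases +
    flank).  The two word sets must not collide.
    """

    experimental_words: list[str]
    native_words: list[str]
    flank: int

    def __post_init__(self) -> None:
        if set(self.experimental_words) & set(self.native_words):
            raise ValueError("experimental and native junction words collide; "
                             "increase flank or re-seed the markers")
        for e, n in zip(self.experimental_words, self.native_words):
            if e == n:
                raise ValueError("marker has identical experimental and native word")

    @property
    def min_read_length(self) -> int:
        """Shortest read that could possibly contain a junction word."""
        return max(len(w) for w in self.experimental_words + self.native_words)

    @classmethod
    def build(cls, original: AnnotatedSequence, markers: MarkerSet,
              flank: int = 10) -> "MarkerIndex":
        if not markers.deletions:
            raise ValueError("marker set is empty")
        marked = markers.apply(original)
        exp_words, nat_words = [], []
        removed_so_far = 0
        for d in markers.deletions:
            nat = original.residues[max(0, d.position - flank):
                                    d.position + d.length + flank]
            pos_marked = d.position - removed_so_far
            exp = marked.residues[max(0, pos_marked - flank): pos_marked + flank]
            removed_so_far += d.length
            exp_words.append(exp)
            nat_words.append(nat)
        # a junction word is only discriminating if it is absent from the
        # other variant (repetitive sequence can defeat this)
        for w in exp_words:
            if w in original.residues:
                raise ValueError(
                    f"experimental junction word {w!r} collides: it also "
                    "occurs in the native sequence; increase flank or "
                    "re-seed the markers")
        for w in nat_words:
            if w in marked.residues:
                raise ValueError(
                    f"native junction word {w!r} collides: it also occurs "
                    "in the marked sequence")
        return cls(experimental_words=exp_words, native_words=nat_words, flank=flank)


@dataclass
class ReadPartition:
    """Exhaustive, disjoint partition of reads by marker evidence."""

    experimental: list[ReadPlacement] = field(default_factory=list)
    native: list[ReadPlacement] = field(default_factory=list)
    ambiguous: list[ReadPlacement] = field(default_factory=list)
    ambiguous_reasons: list[str] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {"experimental": len(self.experimental),
                "native": len(self.native),
                "ambiguous": len(self.ambiguous)}


def assign_reads(placements: Iterable[ReadPlacement],
                 index: MarkerIndex) -> ReadPartition:
    """Partition reads into experimental / native / ambiguous.

    A read containing at least one experimental junction word and no native
    word is experimental; the converse is native; reads with neither kind
    of evidence, with both (conflicting), or too short to contain any word
    are ambiguous, with a reason code recorded.
    """
    part = ReadPartition()
    for p in placements:
        if p.sequence is None:
            raise ValueError("assign_reads requires placements with sequences")
        seq = p.sequence.upper()
        if len(seq) < min(len(w) for w in index.experimental_words):
            part.ambiguous.append(p)
            part.ambiguous_reasons.append("read_shorter_than_junction_word")
            continue
        has_exp = any(w in seq for w in index.experimental_words)
        has_nat = any(w in seq for w in index.native_words)
        if has_exp and not has_nat:
            part.experimental.append(p)
        elif has_nat and not has_exp:
            part.native.append(p)
        else:
            part.ambiguous.append(p)
            part.ambiguous_reasons.append(
                "conflicting_words" if has_exp else "no_marker_overlap")
    return part


@dataclass(frozen=True)
class RegressionResult:
    """OLS of per-segment CENP-A occupancy on per-segment A+T fraction."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_segments: int
    segment: int
    response: str  # "mean_depth" or "read_count"-style label
    normalized: bool

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def binding_at_regression(track: CoverageTrack, seq: AnnotatedSequence,
                          segment: int = 180, normalized: bool = True,
                          response: str = "mean_depth") -> RegressionResult:
    """Regress per-segment CENP-A signal on per-segment A+T fraction.

    The sequence is tiled into non-overlapping ``segment`` bp segments
    (trailing partial segment dropped).  The predictor is each segment's
    A+T fraction; the response is its mean (normalised) depth, or the
    per-segment total if ``response="sum_depth"``.  Ordinary least squares
    with a two-sided slope test.
    """
    if len(track.depth) != len(seq):
        raise ValueError("track and sequence must have the same length")
    n_seg = len(seq) // segment
    if n_seg < 3:
        raise ValueError(f"only {n_seg} segments of {segment} bp; need >= 3")
    profile = windowed_at(seq, segment, segment)
    x = profile.values[:n_seg]
    vals = track.normalized() if normalized else track.depth
    y = vals[: n_seg * segment].reshape(n_seg, segment)
    y = y.sum(axis=1) if response == "sum_depth" else y.mean(axis=1)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in segment A+T; regression undefined")
    if np.ptp(y) == 0:
        return RegressionResult(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                                p_value=1.0, n_segments=n_seg, segment=segment,
                                response=response, normalized=normalized)
    fit = stats.linregress(x, y)
    return RegressionResult(slope=float(fit.slope), intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue ** 2),
                            p_value=float(fit.pvalue), n_segments=n_seg,
                            segment=segment, response=response,
                            normalized=normalized)


# ---------------------------------------------------------------------------
# I/O: placement TSV (the canonical light-weight format) and text SAM.

def read_placements_tsv(path: str | Path) -> list[ReadPlacement]:
    """Read the placement dialect: reference, start, end[, sequence]."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip() or line.startswith("#"):
            continue
        if i == 0 and line.startswith("reference\t"):
            continue  # optional header
        parts = line.split("\t")
        ref, start, end = parts[0], int(parts[1]), int(parts[2])
        seqstr = parts[3] if len(parts) > 3 and parts[3] else None
        out.append(ReadPlacement(ref, start, end, seqstr))
    return out


def write_placements_tsv(placements: Iterable[ReadPlacement],
                         path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("reference\tstart\tend\tsequence\n")
        for p in placements:
            fh.write(f"{p.reference}\t{p.start}\t{p.end}\t{p.sequence or ''}\n")


def read_placements_sam(path: str | Path) -> list[ReadPlacement]:
    """Read placements from a text SAM file.

    Only primary, mapped records are used; the placement interval is the
    reference span of the alignment and the read sequence is carried along
    when present.
    """
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            out.append(ReadPlacement(
                reference=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                sequence=rec.query_sequence,
            ))
    return out
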