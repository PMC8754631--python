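"""Construction and mutagenesis of candidate centromere sequences.

Engineered centromere candidates fall into a few recurring shapes:

* tandem concatemers of a short active unit (e.g. pentamers/heptamers of an
  889 bp central-core fragment, giving 4.4 and 6.2 kb arrays);
* interleaved designs alternating short A+T-rich segments with gene-derived
  backbone segments (CDEII-like 20-mers at ~0.94 A+T woven into 0.55 A+T
  gene sequence, ~0.74 A+T overall);
* marked variants carrying small deletions every ~1 kb so that short
  sequencing reads can be attributed to the engineered copy rather than the
  near-identical native locus;
* mutant series that either break all A/T homopolymer runs or lower bulk
  A+T while leaving the runs intact, separating the contribution of run
  structure from overall composition.

All stochastic operations take an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .composition import AnnotatedSequence, at_fraction, find_at_runs, windowed_at

__all__ = [
    "Deletion",
    "MarkerSet",
    "DesignSpec",
    "concatemerize",
    "build_interleaved",
    "introduce_markers",
    "disrupt_runs",
    "reduce_at_preserving_runs",
    "select_at_windows",
]


@dataclass(frozen=True)
class Deletion:
    """One deletion marker, addressed in the UNMODIFIED coordinate system."""

    position: int
    length: int
    removed: str


@dataclass
class MarkerSet:
    """A set of small deletions distinguishing an engineered sequence.

    Positions refer to the unmodified sequence; deletions are sorted and
    non-overlapping, and applying then reverting them reconstructs the
    original sequence byte-for-byte.
    """

    deletions: list[Deletion] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.deletions = sorted(self.deletions, key=lambda d: d.position)
        prev_end = -1
        for d in self.deletions:
            if d.position < 0 or d.length != len(d.removed):
                raise ValueError(f"malformed deletion {d}")
            if d.position < prev_end:
                raise ValueError("deletions overlap")
            prev_end = d.position + d.length

    def apply(self, seq: AnnotatedSequence) -> AnnotatedSequence:
        """Remove the marked bases, returning the experimental sequence."""
        out = []
        cursor = 0
        for d in self.deletions:
            if seq.residues[d.position:d.position + d.length] != d.removed:
                raise ValueError(
                    f"deletion at {d.position} does not match sequence "
                    f"(expected {d.removed!r})"
                )
            out.append(seq.residues[cursor:d.position])
            cursor = d.position + d.length
        out.append(seq.residues[cursor:])
        return AnnotatedSequence(id=f"{seq.id}|marked", residues="".join(out),
                                 strict=seq.strict)

    def revert(self, marked: AnnotatedSequence) -> AnnotatedSequence:
        """Re-insert the deleted bases, reconstructing the original."""
        out = []
        cursor = 0  # cursor in marked (experimental) coordinates
        removed_so_far = 0
        for d in self.deletions:
            pos_marked = d.position - removed_so_far
            out.append(marked.residues[cursor:pos_marked])
            out.append(d.removed)
            cursor = pos_marked
            removed_so_far += d.length
        out.append(marked.residues[cursor:])
        ident = marked.id[:-7] if marked.id.endswith("|marked") else marked.id
        return AnnotatedSequence(id=ident, residues="".join(out), strict=marked.strict)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tlength\tremoved\n")
            for d in self.deletions:
                fh.write(f"{d.position}\t{d.length}\t{d.removed}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MarkerSet":
        dels = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("position"):
                raise ValueError("marker TSV must have a position/length/removed header")
            for line in fh:
                if not line.strip():
                    continue
                pos, length, removed = line.rstrip("\n").split("\t")
                dels.append(Deletion(int(pos), int(length), removed))
        return cls(dels)

    def to_bed(self, path: str | Path, chrom: str) -> None:
        """BED intervals of the deletions over the unmodified coordinates."""
        with open(path, "w") as fh:
            for i, d in enumerate(self.deletions):
                fh.write(f"{chrom}\t{d.position}\t{d.position + d.length}\tdel{i}\n")


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of an interleaved two-component concatemer design."""

    unit_length: int
    segment_a_at: float
    segment_b_at: float
    total_length: int
    seed: int

    def __post_init__(self) -> None:
        if self.total_length < self.unit_length:
            raise ValueError("total_length must be >= unit_length")
        for f in (self.segment_a_at, self.segment_b_at):
            if not (0.0 <= f <= 1.0):
                raise ValueError("segment compositions must be in [0, 1]")


def concatemerize(unit: AnnotatedSequence, n: int) -> AnnotatedSequence:
    """Tandem array of ``n`` copies of a unit, no linker bases.

    Each copy is annotated as a ``unit`` feature on the product.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    L = len(unit)
    features = [(i * L, (i + 1) * L, "unit") for i in range(n)]
    return AnnotatedSequence(id=f"{unit.id}x{n}", residues=unit.residues * n,
                             features=features, strict=unit.strict)


def build_interleaved(spec: DesignSpec, segment_pool_a: list[str],
                      segment_pool_b: list[str]) -> AnnotatedSequence:
    """Alternate A,B,A,B… segments drawn from two pools to a target length.

    The output is truncated at the last whole segment so that per-segment
    composition stays exact; its overall A+T is therefore exactly the mean
    A+T of the segments that were emitted.
    """
    if not segment_pool_a or not segment_pool_b:
        raise ValueError("segment pools must be non-empty")
    for pool, name in ((segment_pool_a, "A"), (segment_pool_b, "B")):
        for s in pool:
            if len(s) != spec.unit_length:
                raise ValueError(
                    f"pool {name} segment of length {len(s)} != unit_length "
                    f"{spec.unit_length}"
                )
    rng = np.random.default_rng(spec.seed)
    n_segments = spec.total_length // spec.unit_length
    parts: list[str] = []
    features = []
    for i in range(n_segments):
        pool, kind = (segment_pool_a, "segment_a") if i % 2 == 0 else (segment_pool_b, "segment_b")
        parts.append(pool[rng.integers(len(pool))])
        features.append((i * spec.unit_length, (i + 1) * spec.unit_length, kind))
    return AnnotatedSequence(id="interleaved", residues="".join(parts),
                             features=features)


def introduce_markers(seq: AnnotatedSequence, del_len: int = 4,
                      spacing: int = 1000, jitter: int | None = None,
                      seed: int = 0) -> tuple[AnnotatedSequence, MarkerSet]:
    """Mark a sequence with one small deletion per ``spacing`` bp block.

    Each full block of ``spacing`` bp receives one deletion of ``del_len``
    bp placed uniformly within ``jitter`` bp of the block centre (default
    jitter spacing/4).  Deletions are kept clear of the sequence ends by at
    least ``del_len`` bp and can never overlap.  Returns the marked
    (shortened) sequence and the reversible MarkerSet.
    """
    if del_len < 0:
        raise ValueError("del_len must be >= 0")
    if del_len == 0:
        return AnnotatedSequence(id=f"{seq.id}|marked", residues=seq.residues,
                                 strict=seq.strict), MarkerSet([])
    if spacing <= del_len:
        raise ValueError("spacing must exceed del_len")
    if len(seq) < spacing:
        raise ValueError("sequence shorter than one spacing block")
    if jitter is None:
        jitter = spacing // 4
    # non-overlap requires the jittered window to stay inside the block
    if jitter > (spacing - del_len) // 2 - 1:
        raise ValueError(
            f"jitter {jitter} too large for spacing {spacing} and del_len "
            f"{del_len}: deletions could overlap"
        )
    rng = np.random.default_rng(seed)
    n_blocks = len(seq) // spacing
    deletions = []
    for b in range(n_blocks):
        centre = b * spacing + spacing // 2
        pos = int(rng.integers(centre - jitter, centre + jitter + 1))
        pos = max(del_len, min(pos, len(seq) - 2 * del_len))
        deletions.append(Deletion(pos, del_len, seq.residues[pos:pos + del_len]))
    markers = MarkerSet(deletions)
    return markers.apply(seq), markers


def _substitute_gc(rng: np.random.Generator) -> str:
    return "G" if rng.integers(2) == 0 else "C"


def disrupt_runs(seq: AnnotatedSequence, max_run: int = 2, seed: int = 0) -> AnnotatedSequence:
    """Break every A/T homopolymer run longer than ``max_run``.

    Greedy left-to-right: within each qualifying run, every
    ``(max_run+1)``-th position is substituted by G or C (choice random,
    seeded), which is the minimal number of substitutions that leaves no
    run longer than ``max_run``.  Length is unchanged and A+T never
    increases.
    """
    if max_run < 1:
        raise ValueError("max_run must be >= 1")
    rng = np.random.default_rng(seed)
    residues = list(seq.residues)
    for run in find_at_runs(seq, min_len=max_run + 1):
        # substitute offsets max_run, 2*max_run+1, ... within the run
        for off in range(max_run, run.length, max_run + 1):
            residues[run.start + off] = _substitute_gc(rng)
    return AnnotatedSequence(id=f"{seq.id}|runs_disrupted",
                             residues="".join(residues), strict=seq.strict)


def reduce_at_preserving_runs(seq: AnnotatedSequence, target_at: float,
                              max_run: int = 2, seed: int = 0) -> AnnotatedSequence:
    """Lower bulk A+T by mutating only OUTSIDE preserved homopolymer runs.

    All A/T runs longer than ``max_run`` are kept byte-identical; A/T
    residues outside them are substituted by G or C (seeded) until the
    composition is within 1/length of ``target_at``.  Raises if the target
    is below the composition contributed by the preserved runs alone, or
    above the current composition (substitution can only lower A+T).
    """
    n = len(seq)
    current = at_fraction(seq)
    runs = find_at_runs(seq, min_len=max_run + 1)
    protected = np.zeros(n, dtype=bool)
    for r in runs:
        protected[r.start:r.end] = True
    candidates = [i for i in range(n)
                  if seq.residues[i] in "AT" and not protected[i]]
    min_achievable = (int(protected.sum())) / n
    if target_at < min_achievable - 0.5 / n:
        raise ValueError(
            f"target_at {target_at} unachievable; minimum achievable A+T is "
            f"{min_achievable:.4f} (residues inside preserved runs)"
        )
    k = round((current - target_at) * n)
    if k < 0:
        raise ValueError(
            f"target_at {target_at} exceeds current A+T {current:.4f}; "
            "substitution can only reduce composition"
        )
    if k == 0:
        return AnnotatedSequence(id=seq.id, residues=seq.residues, strict=seq.strict)
    if k > len(candidates):
        raise ValueError(
            f"target_at {target_at} unachievable; minimum achievable A+T is "
            f"{min_achievable:.4f}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=k, replace=False)
    residues = list(seq.residues)
    for idx in chosen:
        residues[candidates[idx]] = _substitute_gc(rng)
    return AnnotatedSequence(id=f"{seq.id}|at_reduced",
                             residues="".join(residues), strict=seq.strict)


def select_at_windows(genome: AnnotatedSequence, window: int,
                      min_at: float) -> list[tuple[int, int, float]]:
    """Tiled windows with A+T >= ``min_at``, ranked by A+T descending.

    Mirrors how A+T-rich candidate stretches are picked from a donor
    genome.  Ties are broken by window start (ascending).
    """
    profile = windowed_at(genome, window, window)
    hits = [(int(s), int(s) + window, float(v))
            for s, v in zip(profile.starts, profile.values) if v >= min_at]
    hits.sort(key=lambda t: (-t[2], t[0]))
    return hits
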