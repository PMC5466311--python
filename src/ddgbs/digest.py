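"""In silico single- and double-enzyme digestion of a genome.

Coordinates are 0-based, half-open.  A *cut position* ``p`` is a
between-base index: the backbone is severed between base ``p-1`` and base
``p``.  Fragments from one digestion tile each sequence without gaps or
overlaps, so fragment lengths always sum to the sequence length.

Double digestion classifies each fragment by its two ends:

* ``AB`` — one end cut by each enzyme.  This is the sequenceable class:
  the barcode adapter ligates only to enzyme-A overhangs and the common
  adapter only to enzyme-B overhangs.
* ``AA`` / ``BB`` — both ends cut by the same enzyme.
* ``terminal`` — the fragment touches a sequence boundary and lacks one
  ligatable overhang; it is excluded from library simulation.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio import SeqIO

from .enzymes import RestrictionEnzyme, motif_regex, reverse_complement

CHROM_START = "chrom_start"
CHROM_END = "chrom_end"


@dataclass
class Genome:
    """An ordered collection of named, uppercase DNA sequences."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        self.sequences = {name: seq.upper() for name, seq in self.sequences.items()}

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate sequence name {rec.id!r} in {path}")
            seqs[rec.id] = str(rec.seq)
        if not seqs:
            raise ValueError(f"no FASTA records found in {path}")
        return cls(seqs)

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


@dataclass(frozen=True)
class Fragment:
    """A genomic interval bounded by cut sites (or sequence ends)."""

    seq_name: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    left_end: str   # enzyme name, or "chrom_start"
    right_end: str  # enzyme name, or "chrom_end"

    @property
    def length(self) -> int:
        return self.end - self.start

    def classify(self, enzA: str, enzB: str) -> str:
        ends = (self.left_end, self.right_end)
        if CHROM_START in ends or CHROM_END in ends:
            return "terminal"
        if set(ends) == {enzA, enzB}:
            return "AB"
        if ends == (enzA, enzA):
            return "AA"
        if ends == (enzB, enzB):
            return "BB"
        raise ValueError(f"unclassifiable fragment ends {ends!r}")


@dataclass
class DigestResult:
    """Fragments from one digestion plus class counts and a size histogram."""

    fragments: list[Fragment]
    enzyme_a: str
    enzyme_b: str
    bin_width: int = 10
    class_counts: Counter = field(default_factory=Counter)
    size_histogram: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if not self.class_counts and not self.size_histogram:
            self.recount()

    def recount(self) -> None:
        self.class_counts = Counter(
            frag.classify(self.enzyme_a, self.enzyme_b) for frag in self.fragments
        )
        for cls in ("AB", "AA", "BB", "terminal"):
            self.class_counts.setdefault(cls, 0)
        self.size_histogram = Counter(
            (frag.length // self.bin_width) * self.bin_width
            for frag in self.fragments
        )

    def fragments_of_class(self, cls: str) -> list[Fragment]:
        return [
            f for f in self.fragments
            if f.classify(self.enzyme_a, self.enzyme_b) == cls
        ]

    def to_bed(self, path) -> None:
        """Write fragments as BED: chrom, start, end, name=class, score=length."""
        with open(path, "w") as fh:
            for frag in self.fragments:
                cls = frag.classify(self.enzyme_a, self.enzyme_b)
                fh.write(
                    f"{frag.seq_name}\t{frag.start}\t{frag.end}\t{cls}\t{frag.length}\n"
                )

    def histogram_to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# fragment size histogram, bin width {self.bin_width} bp\n")
            fh.write("bin_start\tcount\n")
            for start in sorted(self.size_histogram):
                fh.write(f"{start}\t{self.size_histogram[start]}\n")


def find_cut_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """All top-strand cut positions of *enzyme* in *sequence*.

    The motif is matched on both strands (with overlapping matches allowed);
    for a reverse-strand match the mirrored top-strand cut coordinate is
    reported.  All registry enzymes are reverse-complement palindromes, so
    for them the forward scan alone is exhaustive.  Positions are sorted,
    deduplicated, and restricted to the open interval (0, len): a cut flush
    with a sequence boundary severs nothing.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = sequence.upper()
    motif = enzyme.recognition
    length = len(motif)
    cuts: set[int] = set()
    for m in motif_regex(motif).finditer(seq):
        cuts.add(m.start() + enzyme.cut_offset)
    rc = reverse_complement(motif)
    if rc != motif:
        for m in motif_regex(rc).finditer(seq):
            cuts.add(m.start() + (length - enzyme.cut_offset))
    return sorted(p for p in cuts if 0 < p < len(seq))


def digest_sequence(
    seq_name: str,
    sequence: str,
    enzA: RestrictionEnzyme,
    enzB: RestrictionEnzyme,
) -> list[Fragment]:
    """Fragments of one sequence under a double digestion (enzA has precedence
    when both enzymes cut at the same coordinate)."""
    cuts_a = set(find_cut_sites(sequence, enzA)) if sequence else set()
    cuts_b = set(find_cut_sites(sequence, enzB)) if sequence else set()
    label = {p: enzB.name for p in cuts_b}
    label.update({p: enzA.name for p in cuts_a})  # enzA wins coincident cuts
    bounds = [0] + sorted(label) + [len(sequence)]
    frags = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        frags.append(
            Fragment(
                seq_name=seq_name,
                start=lo,
                end=hi,
                left_end=label.get(lo, CHROM_START),
                right_end=label.get(hi, CHROM_END),
            )
        )
    return frags


def double_digest(
    genome: Genome | Mapping[str, str],
    enzA: RestrictionEnzyme,
    enzB: RestrictionEnzyme,
    bin_width: int = 10,
) -> DigestResult:
    """Digest every sequence of *genome* with both enzymes."""
    if enzA.name == enzB.name:
        raise ValueError("double digestion requires two distinct enzymes")
    sequences = genome.sequences if isinstance(genome, Genome) else genome
    fragments: list[Fragment] = []
    for name, seq in sequences.items():
        fragments.extend(digest_sequence(name, seq, enzA, enzB))
    return DigestResult(fragments, enzA.name, enzB.name, bin_width=bin_width)


def size_select(
    result: DigestResult,
    min_len: int,
    max_len: int,
    classes: Iterable[str] = ("AB",),
) -> DigestResult:
    """Restrict a digest to fragments with min_len <= length <= max_len.

    By default only the sequenceable AB class is retained, mimicking the
    hard size window applied before sequencing (bead-selection soft tails
    are a simulation option, not a digest property).
    """
    if not (0 < min_len <= max_len):
        raise ValueError("require 0 < min_len <= max_len")
    keep = set(classes)
    selected = [
        f for f in result.fragments
        if min_len <= f.length <= max_len
        and f.classify(result.enzyme_a, result.enzyme_b) in keep
    ]
    if not selected:
        warnings.warn(
            f"size selection [{min_len}, {max_len}] bp retained no fragments",
            stacklevel=2,
        )
    return DigestResult(
        selected, result.enzyme_a, result.enzyme_b, bin_width=result.bin_width
    )
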