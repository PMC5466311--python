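"""Barcode design, adapter molar-ratio arithmetic, and demultiplexing.

Barcodes follow the design constraints used for variable-length GBS
barcode sets: lengths staggered between 6 and 9 bases (so restriction-site
positions vary across the flow cell), no barcode starting with ``GG``
(NextSeq two-channel chemistry reads GG as a dark cycle), a minimum
pairwise Hamming distance over the shared prefix, and no barcode that —
once followed by the enzyme-A overhang remnant — recreates either
enzyme's recognition site.

Demultiplexing is exact-prefix ("good barcode read") matching: a read is
assigned only on a perfect prefix match, nested barcodes resolve longest
match first, and the barcode is trimmed off.  The residual enzyme
overhang is kept on the read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from Bio import SeqIO

from .enzymes import RestrictionEnzyme, motif_regex

_BASES = "ACGT"


@dataclass
class BarcodeSet:
    """Ordered (sample_id, barcode) pairs."""

    entries: list[tuple[str, str]]

    @property
    def barcodes(self) -> list[str]:
        return [bc for _, bc in self.entries]

    @property
    def samples(self) -> list[str]:
        return [sid for sid, _ in self.entries]

    def as_dict(self) -> dict[str, str]:
        return dict(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for sid, bc in self.entries:
                fh.write(f"{sid}\t{bc}\n")

    @classmethod
    def from_tsv(cls, path) -> "BarcodeSet":
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                sid, bc = line.split("\t")[:2]
                entries.append((sid, bc.upper()))
        return cls(entries)


def hamming_prefix(a: str, b: str) -> int:
    """Hamming distance over the shared prefix (shorter barcode's length).

    This is the distance that matters for prefix-based demultiplexing.
    """
    n = min(len(a), len(b))
    return sum(x != y for x, y in zip(a[:n], b[:n]))


def _violations(
    candidate: str,
    accepted: list[str],
    min_distance: int,
    forbidden: list,
    remnant: str,
) -> str | None:
    """Name of the first violated constraint, or None if acceptable."""
    if candidate.startswith("GG"):
        return "GG_start"
    for motif in forbidden:
        if motif.search(candidate + remnant):
            return "recreates_restriction_site"
    for other in accepted:
        if hamming_prefix(candidate, other) < min_distance:
            return "min_distance"
    return None


def generate_barcodes(
    n: int,
    length_range: tuple[int, int] = (6, 9),
    min_distance: int = 3,
    seed: int = 0,
    enzymes: tuple[RestrictionEnzyme, RestrictionEnzyme] | None = None,
    remnant: str | None = None,
    max_consecutive_failures: int = 5000,
) -> BarcodeSet:
    """Draw *n* barcodes satisfying all design constraints (deterministic).

    Candidate barcodes are sampled uniformly over the length range by
    rejection; generation fails with an explicit error naming the binding
    constraint when the space is exhausted.  When *enzymes* is given, the
    enzyme-A overhang remnant (or an explicit *remnant*) is appended before
    checking that no recognition site is recreated at the read start.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if not (6 <= lo <= hi <= 9):
        raise ValueError("barcode lengths must lie within [6, 9]")
    if remnant is None:
        remnant = enzymes[0].remnant if enzymes else ""
    forbidden = (
        [motif_regex(e.recognition) for e in enzymes] if enzymes else []
    )
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    failures: dict[str, int] = {}
    streak = 0
    while len(accepted) < n:
        length = int(rng.integers(lo, hi + 1))
        candidate = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
        why = _violations(candidate, accepted, min_distance, forbidden, remnant)
        if why is None:
            accepted.append(candidate)
            streak = 0
        else:
            failures[why] = failures.get(why, 0) + 1
            streak += 1
            if streak >= max_consecutive_failures:
                binding = max(failures, key=failures.get)
                raise RuntimeError(
                    f"barcode space exhausted after {len(accepted)} of {n} "
                    f"barcodes; binding constraint: {binding}"
                )
    entries = [(f"S{i + 1:03d}", bc) for i, bc in enumerate(accepted)]
    return BarcodeSet(entries)


@dataclass(frozen=True)
class AdapterRatio:
    """Molar parts of barcode adapter vs common adapter."""

    barcode_adapter_parts: float
    common_adapter_parts: float

    def __str__(self) -> str:
        return f"{self.barcode_adapter_parts}:{self.common_adapter_parts}"


def compute_adapter_ratio(
    enzA_cut_count: int, enzB_cut_count: int, total_parts: float
) -> AdapterRatio:
    """Adapter parts proportional to predicted cut-end counts.

    The two enzymes' predicted cut counts from the in silico digestion set
    the molar mix of barcode adapters (ligating to enzyme-A overhangs) and
    common adapters (enzyme-B overhangs).  Parts are scaled to sum to
    *total_parts* and rounded half-up to one decimal place.
    """
    if enzA_cut_count <= 0 or enzB_cut_count <= 0:
        raise ValueError("cut counts must be positive")
    if total_parts <= 0:
        raise ValueError("total_parts must be positive")
    total = enzA_cut_count + enzB_cut_count

    def part(count: int) -> float:
        raw = total_parts * count / total
        return float(Decimal(repr(raw)).quantize(Decimal("0.1"), ROUND_HALF_UP))

    return AdapterRatio(part(enzA_cut_count), part(enzB_cut_count))


@dataclass
class DemuxResult:
    """Per-sample good-barcode reads (barcode-trimmed) plus accounting."""

    reads_by_sample: dict[str, list[tuple[str, str, str]]]
    counts: dict[str, int]
    unassigned: int
    total: int = field(default=0)

    def __post_init__(self) -> None:
        if not self.total:
            self.total = sum(self.counts.values()) + self.unassigned


def demultiplex(reads, barcode_set: BarcodeSet) -> DemuxResult:
    """Assign reads to samples by perfect barcode-prefix match.

    *reads* is an iterable of ``(read_id, sequence, quality)`` tuples (the
    quality string may be empty).  Nested barcodes resolve longest match
    first; anything without a perfect match is counted as unassigned.
    """
    by_barcode = {bc: sid for sid, bc in barcode_set.entries}
    if len(by_barcode) != len(barcode_set):
        raise ValueError("barcodes are not unique")
    lengths = sorted({len(bc) for bc in by_barcode}, reverse=True)
    reads_by_sample: dict[str, list[tuple[str, str, str]]] = {
        sid: [] for sid in barcode_set.samples
    }
    counts = {sid: 0 for sid in barcode_set.samples}
    unassigned = 0
    total = 0
    for read_id, seq, qual in reads:
        total += 1
        for length in lengths:
            sid = by_barcode.get(seq[:length])
            if sid is not None:
                reads_by_sample[sid].append((read_id, seq[length:], qual[length:]))
                counts[sid] += 1
                break
        else:
            unassigned += 1
    return DemuxResult(reads_by_sample, counts, unassigned, total)


def demultiplex_fastq(path, barcode_set: BarcodeSet) -> DemuxResult:
    """Demultiplex a FASTQ file (gzip-compressed if the path ends in .gz)."""
    import gzip

    def records(handle):
        for rec in SeqIO.parse(handle, "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            yield rec.id, str(rec.seq).upper(), qual

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as handle:
        return demultiplex(records(handle), barcode_set)


def write_demux_report(result: DemuxResult, barcode_set: BarcodeSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tbarcode\tgood_barcode_reads\n")
        for sid, bc in barcode_set.entries:
            fh.write(f"{sid}\t{bc}\t{result.counts.get(sid, 0)}\n")
        fh.write(f"#unassigned\t-\t{result.unassigned}\n")
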