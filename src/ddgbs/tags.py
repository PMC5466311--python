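"""Tag tables: per-sample counts of unique trimmed read sequences.

A *tag* is a unique read sequence after barcode trimming; identical reads
collapse to one tag with a count.  Each tag is assigned to the *fragment*
(genomic locus) its reads originate from, which makes the tag table the
common input to depth metrics and saturation analysis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Mapping

import numpy as np


@dataclass
class TagTable:
    """Per-sample tag counts plus a tag -> fragment assignment."""

    counts: dict[str, dict[str, int]]        # sample -> tag -> count
    tag_fragment: dict[str, Hashable]        # tag -> fragment identifier

    def __post_init__(self) -> None:
        for sample, tags in self.counts.items():
            if any(c < 1 for c in tags.values()):
                raise ValueError(f"tag counts must be >= 1 (sample {sample})")

    @property
    def samples(self) -> list[str]:
        return list(self.counts)

    @property
    def good_barcode_reads(self) -> dict[str, int]:
        """Reads per sample; equals the sum of that sample's tag counts."""
        return {s: sum(tags.values()) for s, tags in self.counts.items()}

    def pooled_counts(self) -> dict[str, int]:
        pooled: Counter = Counter()
        for tags in self.counts.values():
            pooled.update(tags)
        return dict(pooled)

    def fragment_depth_matrix(self, fragment_ids=None):
        """Reads per fragment per sample.

        Returns ``(fragment_ids, matrix)`` where the matrix has one row per
        fragment and one column per sample (column order = :attr:`samples`).
        *fragment_ids* may list fragments explicitly (e.g. to include
        fragments that received no reads); defaults to the fragments that
        appear in the tag assignment.
        """
        if fragment_ids is None:
            fragment_ids = sorted(set(self.tag_fragment.values()), key=str)
        index = {f: i for i, f in enumerate(fragment_ids)}
        samples = self.samples
        mat = np.zeros((len(fragment_ids), len(samples)), dtype=float)
        for j, sample in enumerate(samples):
            for tag, count in self.counts[sample].items():
                frag = self.tag_fragment.get(tag)
                if frag in index:
                    mat[index[frag], j] += count
        return list(fragment_ids), mat

    @classmethod
    def from_reads(
        cls,
        reads_by_sample: Mapping[str, list[tuple[str, str]]],
        read_fragment: Mapping[str, Hashable],
    ) -> "TagTable":
        """Build a table from trimmed reads with known fragments of origin.

        *reads_by_sample* maps sample -> list of ``(read_id, sequence)``;
        *read_fragment* maps read_id -> fragment.  A tag is assigned to the
        majority fragment among its reads (ties break on the smaller id).
        """
        counts: dict[str, dict[str, int]] = {}
        votes: dict[str, Counter] = {}
        for sample, reads in reads_by_sample.items():
            tally: Counter = Counter()
            for read_id, seq in reads:
                tally[seq] += 1
                frag = read_fragment.get(read_id)
                if frag is not None:
                    votes.setdefault(seq, Counter())[frag] += 1
            counts[sample] = dict(tally)
        tag_fragment = {
            tag: min(
                (f for f, c in tally.items() if c == max(tally.values())),
                key=str,
            )
            for tag, tally in votes.items()
        }
        return cls(counts=counts, tag_fragment=tag_fragment)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\ttag\tfragment\tcount\n")
            for sample, tags in self.counts.items():
                for tag, count in tags.items():
                    frag = self.tag_fragment.get(tag, "")
                    fh.write(f"{sample}\t{tag}\t{frag}\t{count}\n")

    @classmethod
    def from_tsv(cls, path) -> "TagTable":
        counts: dict[str, dict[str, int]] = {}
        tag_fragment: dict[str, Hashable] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("sample\t"):
                raise ValueError("tag TSV must start with a sample/tag header")
            for line in fh:
                sample, tag, frag, count = line.rstrip("\n").split("\t")
                counts.setdefault(sample, {})[tag] = int(count)
                if frag:
                    tag_fragment[tag] = frag
        return cls(counts=counts, tag_fragment=tag_fragment)
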