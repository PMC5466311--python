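"""Synthetic ddGBS data: genome, barcoded reads, planted SNPs, chip calls.

The simulator emulates a double-digest GBS library at desk scale so every
analysis step is testable without downloads:

* a random genome at a target GC fraction;
* in silico double digestion, hard size selection, and single-end reads
  taken from the barcoded (enzyme-A) end of each AB fragment;
* a heavy-tailed per-fragment abundance: each fragment x sample draws a
  lognormal weight with unit mean and scale ``abundance_sigma``, so the
  across-sample depth CV of a fragment approaches the closed form
  ``sqrt(exp(sigma^2) - 1)`` at high depth — which makes the depth-CV
  statistics recoverable by construction;
* biallelic SNPs planted inside the read-covered fragment ends, with true
  genotypes drawn per sample under Hardy-Weinberg at a site-specific
  allele frequency;
* an emulated genotyping-array matrix that equals the truth except for
  independent errors at a configurable rate.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import qc
from .digest import Fragment, Genome, double_digest, size_select
from .enzymes import get_enzyme, reverse_complement
from .library import BarcodeSet, DemuxResult, generate_barcodes
from .tags import TagTable

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """All knobs of one simulated ddGBS experiment (seed mandatory)."""

    seed: int
    genome_length: int = 3_000_000
    gc_fraction: float = 0.42        # avian genome-wide GC
    n_chromosomes: int = 1
    n_samples: int = 3
    enzyme_a: str = "EcoRI"
    enzyme_b: str = "MseI"
    size_window: tuple[int, int] = (300, 650)
    mean_depth: float = 30.0         # reads per fragment per sample
    abundance_sigma: float = 0.8     # lognormal scale of fragment abundance
    read_length: int = 91            # trimmed single-end read length
    base_error_rate: float = 0.001
    n_snps: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    chip_error_rate: float = 0.0
    barcode_min_distance: int = 3

    def __post_init__(self) -> None:
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be >= 10 kb")
        for name in ("gc_fraction", "base_error_rate", "chip_error_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.abundance_sigma < 0 or self.mean_depth <= 0:
            raise ValueError("abundance_sigma >= 0 and mean_depth > 0 required")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=list)


@dataclass
class TruthSet:
    """Ground truth emitted alongside simulated reads."""

    sites: pd.DataFrame              # chrom, pos, ref, alt, maf, fragment_index
    genotypes: np.ndarray            # int8 sites x samples (0/1/2)
    samples: list[str]
    fragments: list[Fragment]        # size-selected AB fragments
    abundance: np.ndarray            # fragments x samples lognormal weights
    read_fragment: dict[str, int]    # read id -> fragment index
    barcodes: BarcodeSet = field(default=None)

    def to_snp_matrix(self) -> qc.SnpMatrix:
        sites = self.sites[["chrom", "pos", "ref"]].copy()
        sites["alt"] = [(a,) for a in self.sites["alt"]]
        return qc.SnpMatrix(
            sites=sites,
            genotypes=self.genotypes.copy(),
            samples=list(self.samples),
        )

    def to_vcf(self, path) -> None:
        self.to_snp_matrix().to_vcf(path)

    def sites_to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# planted SNP truth\n")
            out = self.sites.copy()
            for j, s in enumerate(self.samples):
                out[s] = self.genotypes[:, j]
            out.to_csv(fh, sep="\t", index=False)


def simulate_genome(cfg: SimConfig) -> Genome:
    """Random genome at the target GC fraction (deterministic given seed)."""
    rng = np.random.default_rng(cfg.seed)
    gc = cfg.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    per_chrom = cfg.genome_length // cfg.n_chromosomes
    seqs = {}
    for i in range(cfg.n_chromosomes):
        arr = rng.choice(_BASE_ARR, size=per_chrom, p=probs)
        seqs[f"chr{i + 1}"] = arr.tobytes().decode("ascii")
    return Genome(seqs)


def _covered_span(frag: Fragment, enzA_name: str, read_length: int):
    """Genomic interval a single-end read covers, and its orientation.

    Reads start at the barcoded (enzyme-A) end: forward from the left end
    when that end is the A cut, else reverse-complemented from the right.
    """
    span = min(frag.length, read_length)
    if frag.left_end == enzA_name:
        return frag.start, frag.start + span, "+"
    return frag.end - span, frag.end, "-"


def plant_snps(
    genome: Genome,
    fragments: Sequence[Fragment],
    cfg: SimConfig,
    rng: np.random.Generator,
):
    """Plant biallelic SNPs in read-covered fragment ends with HWE genotypes.

    Returns ``(sites, genotypes)``; positions are 1-based and the alternate
    allele frequency is drawn uniformly from ``cfg.maf_range`` per site.
    """
    enzA = get_enzyme(cfg.enzyme_a)
    candidates = []  # (fragment_index, genomic 0-based pos)
    for fi, frag in enumerate(fragments):
        lo, hi, _ = _covered_span(frag, enzA.name, cfg.read_length)
        # keep clear of the overhang remnant so motifs stay intact
        margin = len(enzA.recognition)
        for p in range(lo + margin, hi - margin):
            candidates.append((fi, p))
    if len(candidates) < cfg.n_snps:
        raise ValueError(
            f"only {len(candidates)} plantable positions for {cfg.n_snps} SNPs;"
            " enlarge the genome or widen the size window"
        )
    picks = rng.choice(len(candidates), size=cfg.n_snps, replace=False)
    rows, genos = [], []
    for k in sorted(picks):
        fi, pos0 = candidates[k]
        frag = fragments[fi]
        ref = genome.sequences[frag.seq_name][pos0]
        alt = "ACGT".replace(ref, "")[rng.integers(0, 3)]
        maf = float(rng.uniform(*cfg.maf_range))
        rows.append(
            {
                "chrom": frag.seq_name,
                "pos": pos0 + 1,
                "ref": ref,
                "alt": alt,
                "maf": maf,
                "fragment_index": fi,
            }
        )
        genos.append(rng.binomial(2, maf, size=cfg.n_samples))
    sites = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "maf", "fragment_index"]
    )
    return sites, np.array(genos, dtype=np.int8)


def _mutate(seq: list, n_errors: int, rng: np.random.Generator) -> None:
    for p in rng.choice(len(seq), size=n_errors, replace=False):
        seq[p] = "ACGT".replace(seq[p], "")[rng.integers(0, 3)]


def simulate_reads(
    genome: Genome, cfg: SimConfig, barcodes: BarcodeSet | None = None
):
    """Simulate barcoded single-end reads from the size-selected AB fragments.

    Returns ``(reads, truth)`` where *reads* is a list of
    ``(read_id, sequence, quality)`` tuples (barcode already prepended) and
    *truth* is the :class:`TruthSet`.  Per fragment x sample, the read
    count is Poisson with mean ``mean_depth * w`` for a unit-mean lognormal
    weight ``w``; substitution errors are applied at ``base_error_rate``.
    """
    enzA, enzB = get_enzyme(cfg.enzyme_a), get_enzyme(cfg.enzyme_b)
    digest = double_digest(genome, enzA, enzB)
    selected = size_select(digest, *cfg.size_window)
    fragments = selected.fragments
    if not fragments:
        raise ValueError(
            "digestion produced no AB fragments in the size window; "
            "enlarge the genome or widen the window"
        )
    rng = np.random.default_rng(cfg.seed + 1)
    if barcodes is None:
        barcodes = generate_barcodes(
            cfg.n_samples,
            min_distance=cfg.barcode_min_distance,
            seed=cfg.seed + 2,
            enzymes=(enzA, enzB),
        )
    if len(barcodes) < cfg.n_samples:
        raise ValueError("need one barcode per sample")

    sites, genotypes = plant_snps(genome, fragments, cfg, rng)
    snps_by_frag: dict[int, list[int]] = {}
    for si, fi in enumerate(sites["fragment_index"]):
        snps_by_frag.setdefault(int(fi), []).append(si)

    sigma = cfg.abundance_sigma
    if sigma > 0:
        abundance = rng.lognormal(
            -sigma * sigma / 2, sigma, size=(len(fragments), cfg.n_samples)
        )
    else:
        abundance = np.ones((len(fragments), cfg.n_samples))

    reads: list[tuple[str, str, str]] = []
    read_fragment: dict[str, int] = {}
    samples = barcodes.samples[: cfg.n_samples]
    for j, sample in enumerate(samples):
        barcode = barcodes.as_dict()[sample]
        for fi, frag in enumerate(fragments):
            n_reads = rng.poisson(cfg.mean_depth * abundance[fi, j])
            if n_reads == 0:
                continue
            lo, hi, strand = _covered_span(frag, enzA.name, cfg.read_length)
            template = list(genome.sequences[frag.seq_name][lo:hi])
            het_offsets = []
            for si in snps_by_frag.get(fi, []):
                off = int(sites["pos"].iloc[si]) - 1 - lo
                if not (0 <= off < len(template)):
                    continue
                g = int(genotypes[si, j])
                if g == 2:
                    template[off] = sites["alt"].iloc[si]
                elif g == 1:
                    het_offsets.append((off, sites["alt"].iloc[si],
                                        sites["ref"].iloc[si]))
            for r in range(n_reads):
                seq = list(template)
                for off, alt, ref in het_offsets:
                    seq[off] = alt if rng.random() < 0.5 else ref
                if cfg.base_error_rate > 0:
                    n_err = rng.binomial(len(seq), cfg.base_error_rate)
                    if n_err:
                        _mutate(seq, n_err, rng)
                insert = "".join(seq)
                if strand == "-":
                    insert = reverse_complement(insert)
                read_id = f"{sample}:f{fi}:r{r}"
                full = barcode + insert
                reads.append((read_id, full, "I" * len(full)))
                read_fragment[read_id] = fi

    truth = TruthSet(
        sites=sites,
        genotypes=genotypes,
        samples=list(samples),
        fragments=fragments,
        abundance=abundance,
        read_fragment=read_fragment,
        barcodes=barcodes,
    )
    return reads, truth


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def tag_table_from_demux(demux: DemuxResult, truth: TruthSet) -> TagTable:
    """Collapse demultiplexed (trimmed) reads into a fragment-labelled
    tag table using the simulator's read-of-origin labels."""
    reads_by_sample = {
        sample: [(rid, seq) for rid, seq, _ in recs]
        for sample, recs in demux.reads_by_sample.items()
    }
    return TagTable.from_reads(reads_by_sample, truth.read_fragment)


def simulate_chip(
    truth: TruthSet, chip_error_rate: float | None = None, seed: int = 0
) -> qc.SnpMatrix:
    """Array-style genotypes: the truth plus independent genotyping errors.

    With probability *chip_error_rate* a call is replaced by one of the two
    other genotype codes, uniformly.  Deterministic given *seed*.
    """
    rate = chip_error_rate if chip_error_rate is not None else 0.0
    rng = np.random.default_rng(seed)
    matrix = truth.to_snp_matrix()
    if rate > 0:
        gt = matrix.genotypes
        err = rng.random(gt.shape) < rate
        shift = rng.integers(1, 3, size=gt.shape)
        gt[err] = ((gt[err] + shift[err]) % 3).astype(np.int8)
    return matrix


def simulate_gbs_genotypes(
    truth: TruthSet,
    mean_depth: float = 20.0,
    seed: int = 0,
    allele_sampling: bool = True,
    het_to_hom_error: float = 0.0,
    gq: int = 99,
) -> qc.SnpMatrix:
    """Sequencing-style genotype calls derived from the truth.

    Per call, depth is Poisson(*mean_depth*); zero depth is missing.  With
    *allele_sampling*, a true heterozygote yields binomially sampled
    alleles (error-free base calls): it is called homozygous when only one
    allele is observed.  *het_to_hom_error* additionally converts called
    heterozygotes to a random homozygote at the given rate — a planted
    error whose recovery is directly checkable via the concordance report.
    """
    rng = np.random.default_rng(seed)
    matrix = truth.to_snp_matrix()
    gt = matrix.genotypes
    depth = rng.poisson(mean_depth, size=gt.shape).astype(np.int32)
    if allele_sampling:
        het = gt == 1
        alt_reads = rng.binomial(depth, 0.5)
        gt_new = gt.copy()
        gt_new[het & (alt_reads == 0)] = 0
        gt_new[het & (alt_reads == depth)] = 2
        gt = gt_new
    if het_to_hom_error > 0:
        flip = (gt == 1) & (rng.random(gt.shape) < het_to_hom_error)
        gt[flip] = np.where(rng.random(gt.shape)[flip] < 0.5, 0, 2)
    gt = np.where(depth == 0, qc.MISSING, gt).astype(np.int8)
    matrix.genotypes = gt
    matrix.depth = depth
    matrix.gq = np.full(gt.shape, gq, dtype=np.int32)
    return matrix
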