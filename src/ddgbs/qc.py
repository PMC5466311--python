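"""SNP filtering, chip-vs-GBS concordance, missing rates, and LD decay.

Genotypes are stored as small integer codes over a sites x samples matrix:
0 = homozygous reference, 1 = heterozygous, 2 = homozygous alternate,
-1 = missing.  Positions are 1-based internally for VCF fidelity.

Filtering follows the order: genotype-level depth/quality masking first,
then site-level filters (biallelic, minor allele frequency computed from
the non-missing calls that remain, site call rate), then the sample
call-rate filter.  Concordance against array genotypes is stratified by a
minimum GBS call depth, with REF/ALT orientation harmonized and
strand-ambiguous (A/T, C/G) sites dropped.  LD is summarized as the
squared Pearson correlation of allele-dosage vectors, binned by pairwise
distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1
_GT_CODES = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SnpMatrix:
    """Sites x samples genotype calls with optional per-call depth/quality."""

    sites: pd.DataFrame            # chrom, pos (1-based), ref, alt (tuple)
    genotypes: np.ndarray          # int8, codes above
    samples: list[str]
    depth: np.ndarray | None = None
    gq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError("genotype matrix shape mismatch")
        for arr_name in ("depth", "gq"):
            arr = getattr(self, arr_name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != self.genotypes.shape:
                    raise ValueError(f"{arr_name} matrix shape mismatch")
                setattr(self, arr_name, arr)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def take_sites(self, mask_or_idx) -> "SnpMatrix":
        idx = np.arange(self.n_sites)[mask_or_idx]
        return SnpMatrix(
            sites=self.sites.iloc[idx],
            genotypes=self.genotypes[idx],
            samples=list(self.samples),
            depth=None if self.depth is None else self.depth[idx],
            gq=None if self.gq is None else self.gq[idx],
        )

    def take_samples(self, idx: Sequence[int]) -> "SnpMatrix":
        idx = list(idx)
        return SnpMatrix(
            sites=self.sites,
            genotypes=self.genotypes[:, idx],
            samples=[self.samples[i] for i in idx],
            depth=None if self.depth is None else self.depth[:, idx],
            gq=None if self.gq is None else self.gq[:, idx],
        )

    def copy(self) -> "SnpMatrix":
        return SnpMatrix(
            sites=self.sites.copy(),
            genotypes=self.genotypes.copy(),
            samples=list(self.samples),
            depth=None if self.depth is None else self.depth.copy(),
            gq=None if self.gq is None else self.gq.copy(),
        )

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_vcf(cls, path) -> "SnpMatrix":
        """Read a VCF (v4.x) with GT and, when present, DP and GQ."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows, gts, dps, gqs = [], [], [], []
        have_dp = have_gq = True
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        remap = np.array([0, 1, MISSING, 2], dtype=np.int8)
        for var in vcf:
            rows.append(
                {
                    "chrom": var.CHROM,
                    "pos": var.POS,
                    "ref": var.REF,
                    "alt": tuple(var.ALT),
                }
            )
            gts.append(remap[var.gt_types])
            dp = var.format("DP")
            gq = var.format("GQ")
            if dp is None:
                have_dp = False
            else:
                dps.append(np.where(dp.ravel() < 0, 0, dp.ravel()))
            if gq is None:
                have_gq = False
            else:
                gqs.append(np.where(gq.ravel() < 0, 0, gq.ravel()))
        sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
        return cls(
            sites=sites,
            genotypes=np.array(gts, dtype=np.int8).reshape(len(rows), len(samples)),
            samples=samples,
            depth=np.array(dps, dtype=np.int32) if have_dp and dps else None,
            gq=np.array(gqs, dtype=np.int32) if have_gq and gqs else None,
        )

    def to_vcf(self, path) -> None:
        """Write a minimal VCF with GT plus DP/GQ when available."""
        fmt = ["GT"]
        if self.depth is not None:
            fmt.append("DP")
        if self.gq is not None:
            fmt.append("GQ")
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for chrom in dict.fromkeys(self.sites["chrom"]):
                sub = self.sites[self.sites["chrom"] == chrom]
                fh.write(
                    f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1000}>\n"
                )
            fh.write(
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            )
            if self.depth is not None:
                fh.write(
                    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
                )
            if self.gq is not None:
                fh.write(
                    '##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                    'Description="Genotype quality">\n'
                )
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples)
                + "\n"
            )
            for i in range(self.n_sites):
                row = self.sites.iloc[i]
                alt = ",".join(row["alt"]) if row["alt"] else "."
                cells = []
                for j in range(self.n_samples):
                    parts = [_GT_CODES[int(self.genotypes[i, j])]]
                    if self.depth is not None:
                        parts.append(str(int(self.depth[i, j])))
                    if self.gq is not None:
                        parts.append(str(int(self.gq[i, j])))
                    cells.append(":".join(parts))
                fh.write(
                    f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{alt}\t.\t"
                    f"PASS\t.\t{':'.join(fmt)}\t" + "\t".join(cells) + "\n"
                )

    @classmethod
    def from_chip_tsv(cls, path) -> "SnpMatrix":
        """Read array genotypes: chrom, pos, ref, alt, then one ACGT-pair
        column per sample ('AG'; 'NN' or '--' = missing)."""
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        meta = ["chrom", "pos", "ref", "alt"]
        samples = [c for c in df.columns if c not in meta]
        sites = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "pos": df["pos"].astype(int),
                "ref": df["ref"].str.upper(),
                "alt": [tuple(a.upper().split(",")) for a in df["alt"]],
            }
        )
        gts = np.full((len(df), len(samples)), MISSING, dtype=np.int8)
        for i in range(len(df)):
            ref = sites["ref"].iloc[i]
            alt = sites["alt"].iloc[i][0]
            for j, sample in enumerate(samples):
                pair = str(df[sample].iloc[i]).upper()
                if len(pair) != 2 or not set(pair) <= {"A", "C", "G", "T"}:
                    continue
                n_alt = sum(b == alt for b in pair)
                n_ref = sum(b == ref for b in pair)
                if n_alt + n_ref == 2:
                    gts[i, j] = n_alt if n_alt != 1 else 1
        return cls(sites=sites, genotypes=gts, samples=samples)

    def to_chip_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\t" + "\t".join(self.samples) + "\n")
            for i in range(self.n_sites):
                row = self.sites.iloc[i]
                ref, alt = row["ref"], row["alt"][0]
                pairs = {0: ref + ref, 1: ref + alt, 2: alt + alt, MISSING: "NN"}
                cells = [pairs[int(g)] for g in self.genotypes[i]]
                fh.write(
                    f"{row['chrom']}\t{row['pos']}\t{ref}\t"
                    + ",".join(row["alt"])
                    + "\t"
                    + "\t".join(cells)
                    + "\n"
                )


@dataclass
class FilterConfig:
    """Thresholds for genotype- and site-level SNP filtering."""

    maf_min: float = 0.05
    gq_min: int = 98
    dp_min: int = 5
    biallelic_only: bool = True
    site_call_rate_min: float = 0.6
    sample_call_rate_min: float = 0.01

    def __post_init__(self) -> None:
        if not (0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must lie in [0, 0.5]")
        for name in ("site_call_rate_min", "sample_call_rate_min"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.gq_min < 0 or self.dp_min < 0:
            raise ValueError("gq_min and dp_min must be non-negative")


def filter_snps(matrix: SnpMatrix, cfg: FilterConfig | None = None) -> SnpMatrix:
    """Apply genotype-level masking then site- and sample-level filters.

    Order (fixed): (1) calls with DP < dp_min or GQ < gq_min become
    missing; (2) sites failing the biallelic, MAF (>= maf_min, computed
    from non-missing calls), or call-rate thresholds are dropped; (3)
    samples below the sample call-rate threshold are dropped.
    """
    cfg = cfg or FilterConfig()
    out = matrix.copy()
    if out.depth is not None:
        out.genotypes[out.depth < cfg.dp_min] = MISSING
    if out.gq is not None:
        out.genotypes[out.gq < cfg.gq_min] = MISSING

    called = out.genotypes != MISSING
    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(
            n_called > 0,
            np.where(called, out.genotypes, 0).sum(axis=1) / (2 * n_called),
            0.0,
        )
    maf = np.minimum(alt_freq, 1 - alt_freq)
    keep = (maf >= cfg.maf_min) & (
        n_called / max(out.n_samples, 1) >= cfg.site_call_rate_min
    )
    if cfg.biallelic_only:
        keep &= np.array([len(a) == 1 for a in out.sites["alt"]])
    out = out.take_sites(keep)

    if out.n_sites:
        sample_rate = (out.genotypes != MISSING).mean(axis=0)
        out = out.take_samples(
            np.nonzero(sample_rate >= cfg.sample_call_rate_min)[0]
        )
    else:
        warnings.warn("all sites removed by filtering", stacklevel=2)
    return out


# --------------------------------------------------------------- concordance


@dataclass
class ConcordanceReport:
    """Depth-stratified agreement between GBS and array genotypes."""

    table: pd.DataFrame  # depth_threshold, n_compared, homo/het/total pct
    n_sites_matched: int
    n_ambiguous_dropped: int
    n_incompatible_dropped: int

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# chip-vs-GBS concordance; matched={self.n_sites_matched} "
                f"strand_ambiguous_dropped={self.n_ambiguous_dropped} "
                f"allele_incompatible_dropped={self.n_incompatible_dropped}\n"
            )
            self.table.to_csv(fh, sep="\t", index=False)


def _harmonize(gref, galt, cref, calt):
    """Return 'same', 'swap', or None for a chip site vs the GBS alleles.

    Tries direct, REF/ALT-swapped, and opposite-strand (complemented)
    orientations.  Strand-ambiguous pairs must be excluded beforehand.
    """
    if (cref, calt) == (gref, galt):
        return "same"
    if (cref, calt) == (galt, gref):
        return "swap"
    comp = (_COMP.get(cref), _COMP.get(calt))
    if comp == (gref, galt):
        return "same"
    if comp == (galt, gref):
        return "swap"
    return None


def concordance(
    gbs: SnpMatrix,
    chip: SnpMatrix,
    depth_thresholds: Sequence[int] = tuple(range(2, 13)),
) -> ConcordanceReport:
    """Depth-stratified genotype agreement on shared samples and sites.

    At each threshold *d*, only GBS calls with depth >= d (and both calls
    non-missing) are compared.  Homozygous consistency is computed over
    chip-homozygous calls, heterozygous over chip-heterozygous calls, and
    the total is the call-weighted combination of the two.
    """
    shared = [s for s in gbs.samples if s in chip.samples]
    if not shared:
        raise ValueError("no shared samples between GBS and chip matrices")
    g = gbs.take_samples([gbs.samples.index(s) for s in shared])
    c = chip.take_samples([chip.samples.index(s) for s in shared])

    gkey = g.sites.assign(idx_g=np.arange(g.n_sites))
    ckey = c.sites.assign(idx_c=np.arange(c.n_sites))
    merged = gkey.merge(
        ckey, on=["chrom", "pos"], suffixes=("_g", "_c"), how="inner"
    )
    if merged.empty:
        raise ValueError("no overlapping sites between GBS and chip matrices")

    keep_g, keep_c, flip = [], [], []
    n_ambiguous = n_incompatible = 0
    for row in merged.itertuples(index=False):
        gref, galt = row.ref_g, row.alt_g[0]
        if {gref, galt} in ({"A", "T"}, {"C", "G"}):
            n_ambiguous += 1
            continue
        orient = _harmonize(gref, galt, row.ref_c, row.alt_c[0])
        if orient is None:
            n_incompatible += 1
            continue
        keep_g.append(row.idx_g)
        keep_c.append(row.idx_c)
        flip.append(orient == "swap")

    if not keep_g:
        raise ValueError("no comparable sites after allele harmonization")
    gt_g = g.genotypes[keep_g]
    gt_c = c.genotypes[keep_c].copy()
    flip = np.asarray(flip)
    missing_c = gt_c[flip] == MISSING
    gt_c[flip] = 2 - gt_c[flip]
    gt_c[flip] = np.where(missing_c, MISSING, gt_c[flip])
    depth_g = (
        g.depth[keep_g]
        if g.depth is not None
        else np.full(gt_g.shape, np.iinfo(np.int32).max)
    )

    rows = []
    for d in depth_thresholds:
        compared = (gt_g != MISSING) & (gt_c != MISSING) & (depth_g >= d)
        match = gt_g == gt_c
        homo = compared & ((gt_c == 0) | (gt_c == 2))
        het = compared & (gt_c == 1)

        def pct(mask):
            n = int(mask.sum())
            return 100.0 * match[mask].sum() / n if n else float("nan")

        rows.append(
            {
                "depth_threshold": d,
                "n_compared": int(compared.sum()),
                "homozygous_pct": pct(homo),
                "heterozygous_pct": pct(het),
                "total_pct": pct(compared),
            }
        )
    return ConcordanceReport(
        table=pd.DataFrame(rows),
        n_sites_matched=len(keep_g),
        n_ambiguous_dropped=n_ambiguous,
        n_incompatible_dropped=n_incompatible,
    )


# ------------------------------------------------------------- missing rates


@dataclass
class MissingRates:
    """Per-site and per-sample missing fractions, before/after depth masking."""

    per_site_before: np.ndarray
    per_site_after: np.ndarray
    per_sample_before: np.ndarray
    per_sample_after: np.ndarray
    dp_min: int


def missing_rates(matrix: SnpMatrix, dp_min: int = 0) -> MissingRates:
    """Missing-call fractions before and after masking calls below *dp_min*."""
    missing = matrix.genotypes == MISSING
    if matrix.depth is not None and dp_min > 0:
        masked = missing | (matrix.depth < dp_min)
    else:
        masked = missing
    return MissingRates(
        per_site_before=missing.mean(axis=1),
        per_site_after=masked.mean(axis=1),
        per_sample_before=missing.mean(axis=0),
        per_sample_after=masked.mean(axis=0),
        dp_min=dp_min,
    )


# ----------------------------------------------------------------- LD decay


@dataclass
class LdDecay:
    """Mean r-squared per distance bin and the decay distance."""

    bin_centers: np.ndarray
    mean_r2: np.ndarray
    pair_counts: np.ndarray
    decay_distance: float | None
    threshold: float
    n_pairs_excluded: int

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# LD decay; threshold={self.threshold} "
                f"decay_distance={self.decay_distance} "
                f"monomorphic_pairs_excluded={self.n_pairs_excluded}\n"
            )
            fh.write("bin_center_bp\tmean_r2\tn_pairs\n")
            for ctr, r2, n in zip(
                self.bin_centers, self.mean_r2, self.pair_counts
            ):
                fh.write(f"{ctr:.1f}\t{r2:.6f}\t{int(n)}\n")


def pairwise_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float | None:
    """Squared Pearson correlation of two dosage vectors (NaN = missing).

    Returns None when fewer than two complete observations remain or
    either site is monomorphic among them.
    """
    both = ~(np.isnan(dosage_a) | np.isnan(dosage_b))
    if both.sum() < 2:
        return None
    a, b = dosage_a[both], dosage_b[both]
    if a.std() == 0 or b.std() == 0:
        return None
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_decay(
    matrix: SnpMatrix,
    max_distance: int,
    bins: int = 20,
    threshold: float = 0.1,
) -> LdDecay:
    """Genotype-based (dosage-correlation) LD decay with distance.

    All same-chromosome site pairs within *max_distance* contribute one
    r-squared; bin means are reported and the decay distance is the first
    bin center whose mean drops to or below *threshold*.  Monomorphic
    pairs are excluded and counted.
    """
    if matrix.n_sites < 2:
        raise ValueError("LD decay needs at least two sites")
    dosage = matrix.genotypes.astype(float)
    dosage[matrix.genotypes == MISSING] = np.nan
    edges = np.linspace(0, max_distance, bins + 1)
    sums = np.zeros(bins)
    counts = np.zeros(bins, dtype=int)
    n_excluded = 0
    for chrom, sub in matrix.sites.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos)
        idx, pos = idx[order], pos[order]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                dist = pos[b] - pos[a]
                if dist > max_distance:
                    break
                r2 = pairwise_r2(dosage[idx[a]], dosage[idx[b]])
                if r2 is None:
                    n_excluded += 1
                    continue
                k = min(int(np.searchsorted(edges, dist, side="right")) - 1,
                        bins - 1)
                sums[k] += r2
                counts[k] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (edges[:-1] + edges[1:]) / 2
    decay = None
    for ctr, m, n in zip(centers, means, counts):
        if n > 0 and m <= threshold:
            decay = float(ctr)
            break
    return LdDecay(
        bin_centers=centers,
        mean_r2=means,
        pair_counts=counts,
        decay_distance=decay,
        threshold=threshold,
        n_pairs_excluded=n_excluded,
    )
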