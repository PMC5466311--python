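"""Evaluation statistics for double-digest GBS enzyme combinations.

The statistics compare enzyme combinations on four axes:

* **FCI** (fragment consistency index): mean per-sample fragment count
  divided by the pooled multi-sample fragment count.  Values near 1 mean
  the same loci are recovered in every sample, i.e. little missing data.
* **Depth**: good barcode reads divided by fragment count — reads per
  sequenced locus.
* **CV of per-fragment depth across samples** (``cv_depth_distribution``):
  one coefficient of variation per fragment; a tight distribution means
  uniform locus representation across individuals.
* **SNP density per chromosome** and its CV across chromosomes: how evenly
  the discovered markers cover the genome.

All report rounding is half-up decimal rounding.  CVs use the sample
standard deviation (n-1 denominator); at the two decimals reported the
choice of denominator is immaterial for realistic inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, ROUND_HALF_UP))


def compute_fci(
    per_sample_fragment_counts: Sequence[int],
    pooled_fragment_count: int,
    ndigits: int = 4,
) -> float:
    """Fragment consistency index: mean per-sample count / pooled count."""
    counts = list(per_sample_fragment_counts)
    if not counts:
        raise ValueError("need at least one per-sample fragment count")
    if pooled_fragment_count <= 0:
        raise ValueError("pooled fragment count must be positive")
    if any(c <= 0 for c in counts):
        raise ValueError("per-sample fragment counts must be positive")
    if pooled_fragment_count < max(counts):
        warnings.warn(
            "pooled fragment count is smaller than a per-sample count; "
            "FCI may exceed 1",
            stacklevel=2,
        )
    return round_half_up(float(np.mean(counts)) / pooled_fragment_count, ndigits)


def compute_depth(
    good_barcode_reads: int, fragment_count: int, ndigits: int = 2
) -> float:
    """Sequencing depth: good barcode reads per fragment, rounded for report."""
    if fragment_count <= 0:
        raise ValueError("fragment count must be positive")
    if good_barcode_reads < 0:
        raise ValueError("read count must be non-negative")
    return round_half_up(good_barcode_reads / fragment_count, ndigits)


def cv(values: Sequence[float], ddof: int = 1) -> float:
    """Coefficient of variation: sample SD / mean (scale-invariant)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(arr.std(ddof=ddof) / mean)


@dataclass
class CvDepthDistribution:
    """Per-fragment depth CVs across samples, with a mean +/- SD summary."""

    cvs: np.ndarray
    mean_cv: float
    sd_cv: float
    n_fragments: int
    n_excluded_zero: int

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# per-fragment depth CV across samples; "
                f"mean={self.mean_cv:.4f} sd={self.sd_cv:.4f} "
                f"excluded_all_zero={self.n_excluded_zero}\n"
            )
            fh.write("cv_depth\n")
            for v in self.cvs:
                fh.write(f"{v:.6f}\n")


def cv_depth_distribution(per_fragment_depths) -> CvDepthDistribution:
    """One depth CV per fragment, computed across samples.

    *per_fragment_depths* is a fragments x samples matrix.  Fragments with
    zero depth in every sample are excluded from the distribution and
    counted separately.
    """
    mat = np.asarray(per_fragment_depths, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("need a fragments x samples matrix with >= 2 samples")
    nonzero = mat.sum(axis=1) > 0
    n_excluded = int((~nonzero).sum())
    mat = mat[nonzero]
    means = mat.mean(axis=1)
    sds = mat.std(axis=1, ddof=1)
    cvs = sds / means
    return CvDepthDistribution(
        cvs=cvs,
        mean_cv=float(cvs.mean()) if cvs.size else float("nan"),
        sd_cv=float(cvs.std(ddof=1)) if cvs.size > 1 else float("nan"),
        n_fragments=int(cvs.size),
        n_excluded_zero=n_excluded,
    )


@dataclass
class DensityTable:
    """Per-chromosome SNP density (SNPs/Mb) with mean and CV."""

    table: pd.DataFrame  # chrom, snp_count, length_bp, density, density_rounded
    mean_density: float
    cv_density: float
    rounded_mode: bool

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# SNP density per chromosome; mean={self.mean_density} "
                f"cv={self.cv_density:.4f} rounded_mode={self.rounded_mode}\n"
            )
            self.table.to_csv(fh, sep="\t", index=False)


def snp_density_table(
    snp_counts: Mapping[str, int],
    chrom_lengths: Mapping[str, int],
    use_rounded: bool = True,
) -> DensityTable:
    """SNPs per megabase for each chromosome, plus mean and CV.

    Published summaries print densities as integers per Mb and compute the
    mean/CV from those rounded values, so ``use_rounded=True`` (the default)
    reproduces table-style output; ``use_rounded=False`` keeps full
    precision throughout.
    """
    rows = []
    for chrom, count in snp_counts.items():
        if chrom not in chrom_lengths:
            raise ValueError(f"chromosome {chrom!r} has SNPs but no length")
        length = chrom_lengths[chrom]
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length")
        density = count / (length / 1e6)
        rows.append(
            {
                "chrom": chrom,
                "snp_count": int(count),
                "length_bp": int(length),
                "density": density,
                "density_rounded": int(round_half_up(density, 0)),
            }
        )
    if not rows:
        raise ValueError("no chromosomes given")
    table = pd.DataFrame(rows)
    col = table["density_rounded"] if use_rounded else table["density"]
    mean = float(col.mean())
    # CV across chromosomes is undefined for a single chromosome
    cv_val = cv(col.to_numpy()) if len(table) >= 2 and mean != 0 else float("nan")
    return DensityTable(
        table=table,
        mean_density=round_half_up(mean, 0) if use_rounded else mean,
        cv_density=cv_val,
        rounded_mode=use_rounded,
    )


@dataclass
class RegionSummary:
    """SNP counts and percentages by genomic region category."""

    table: pd.DataFrame          # category, count, percent (of total)
    exonic_table: pd.DataFrame   # subcategory, count, percent (of exonic)
    total: int

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# SNPs by region; total={self.total}\n")
            self.table.to_csv(fh, sep="\t", index=False)
            if not self.exonic_table.empty:
                fh.write("# exonic subcategories (% of exonic)\n")
                self.exonic_table.to_csv(fh, sep="\t", index=False)


def summarize_regions(
    category_counts: Mapping[str, int],
    exonic_subcounts: Mapping[str, int] | None = None,
    exonic_category: str = "EXONIC",
) -> RegionSummary:
    """Percent of SNPs per region category; exonic subcategories as % of exonic.

    Region labels come from an external annotation engine; this only
    summarizes the counts.  Category percents are reported at 3 decimals,
    exonic subcategory percents at 2 decimals.
    """
    if any(c < 0 for c in category_counts.values()):
        raise ValueError("counts must be non-negative")
    total = sum(category_counts.values())
    if total == 0:
        raise ValueError("no SNPs to summarize")
    table = pd.DataFrame(
        {
            "category": list(category_counts),
            "count": [int(c) for c in category_counts.values()],
        }
    )
    table["percent"] = [
        round_half_up(100 * c / total, 3) for c in table["count"]
    ]
    exonic_rows = []
    if exonic_subcounts:
        exonic_total = category_counts.get(exonic_category, 0)
        sub_sum = sum(exonic_subcounts.values())
        if sub_sum > exonic_total:
            raise ValueError(
                f"exonic subcounts ({sub_sum}) exceed the "
                f"{exonic_category} count ({exonic_total})"
            )
        for sub, count in exonic_subcounts.items():
            exonic_rows.append(
                {
                    "subcategory": sub,
                    "count": int(count),
                    "percent_of_exonic": round_half_up(
                        100 * count / exonic_total, 2
                    ),
                }
            )
    exonic_table = pd.DataFrame(
        exonic_rows, columns=["subcategory", "count", "percent_of_exonic"]
    )
    return RegionSummary(table=table, exonic_table=exonic_table, total=total)
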