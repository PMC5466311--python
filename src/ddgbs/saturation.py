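"""Read-subsampling saturation analysis and sequencing-volume optimization.

Reads are subsampled *nested* (each smaller proportion is a subset of each
larger one), drawn without replacement, so fragment counts are guaranteed
non-decreasing along the curve.  A fragment is counted at a point when at
least one of its tags occurs >= ``c`` times in the subsample — the same
minimum-tag-count rule used by GBS tag-counting pipelines (default c=3).

Two summary points locate the economical sequencing volume:

* **ORP** (optimal read-count point): the read volume minimizing the unit
  sequencing cost per discovered fragment.  Reported on the observed grid
  (no interpolation); if the minimum sits on the grid boundary the point
  is flagged as not (interior-)reached.
* **SRP** (saturated read-count point): the smallest read volume at which
  fragment discovery has plateaued — the first point whose incoming
  fragment-count slope is <= ``slope_tol`` and stays there.  Absent when
  the curve is still rising at full volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .tags import TagTable

DEFAULT_PROPORTIONS = (0.1, 0.2, 0.5, 0.8, 1.0)
#: One new fragment per 1e5 additional reads.
DEFAULT_SLOPE_TOL = 1e-5


@dataclass
class SaturationCurve:
    """Ordered (reads, fragments, depth, unit_cost) points from subsampling."""

    points: pd.DataFrame
    proportions: tuple
    min_tag_count: int
    seed: int
    cost_per_read: float

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# saturation curve; c={self.min_tag_count} "
                f"proportions={','.join(map(str, self.proportions))} "
                f"seed={self.seed} cost_per_read={self.cost_per_read}\n"
            )
            self.points.to_csv(fh, sep="\t", index=False)


@dataclass
class OrpSrpResult:
    """ORP/SRP location on a saturation curve (either part may be absent)."""

    orp_reads: int | None = None
    orp_unit_cost: float | None = None
    orp_boundary: bool | None = None  # True: minimum sat on the grid edge
    srp_reads: int | None = None
    slope_tolerance: float | None = None


def build_saturation_curve(
    tags: TagTable,
    proportions: Sequence[float] = DEFAULT_PROPORTIONS,
    c: int = 3,
    seed: int = 0,
    cost_per_read: float = 1.0,
) -> SaturationCurve:
    """Subsample pooled reads at nested proportions and count fragments.

    Tag counts are pooled across samples before subsampling (the multi-plex
    pool is what gets sequenced).  Deterministic given *seed*.
    """
    props = list(proportions)
    if any(p <= 0 or p > 1 for p in props):
        raise ValueError("proportions must lie in (0, 1]")
    if props != sorted(props):
        raise ValueError("proportions must be sorted ascending")
    if props[-1] != 1.0:
        raise ValueError("the last proportion must be 1.0")
    if c < 1:
        raise ValueError("minimum tag count c must be >= 1")

    pooled = tags.pooled_counts()
    tag_list = list(pooled)
    tag_counts = np.array([pooled[t] for t in tag_list], dtype=np.int64)
    # tags without a fragment assignment count as their own singleton locus
    frag_of_tag = [tags.tag_fragment.get(t, ("__tag__", t)) for t in tag_list]
    frag_ids = {f: i for i, f in enumerate(dict.fromkeys(frag_of_tag))}
    frag_idx = np.array([frag_ids[f] for f in frag_of_tag], dtype=np.int64)

    read_tags = np.repeat(np.arange(len(tag_list)), tag_counts)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(read_tags)
    n_total = len(perm)

    rows = []
    for p in props:
        n = int(round(p * n_total))
        sub_counts = np.bincount(perm[:n], minlength=len(tag_list))
        passing = sub_counts >= c
        fragments = int(np.unique(frag_idx[passing]).size)
        depth = n / fragments if fragments else float("inf")
        rows.append(
            {
                "proportion": p,
                "reads": n,
                "fragments": fragments,
                "depth": depth,
                "unit_cost": cost_per_read * n / fragments
                if fragments
                else float("inf"),
            }
        )
    return SaturationCurve(
        points=pd.DataFrame(rows),
        proportions=tuple(props),
        min_tag_count=c,
        seed=seed,
        cost_per_read=cost_per_read,
    )


def find_orp(curve: SaturationCurve) -> OrpSrpResult:
    """Locate the unit-cost minimum on the observed grid."""
    pts = curve.points
    if len(pts) < 2:
        raise ValueError("ORP needs at least two curve points")
    i = int(pts["unit_cost"].to_numpy().argmin())
    boundary = i == 0 or i == len(pts) - 1
    return OrpSrpResult(
        orp_reads=int(pts["reads"].iloc[i]),
        orp_unit_cost=float(pts["unit_cost"].iloc[i]),
        orp_boundary=boundary,
    )


def find_srp(
    curve: SaturationCurve, slope_tol: float = DEFAULT_SLOPE_TOL
) -> OrpSrpResult:
    """Locate the fragment-count plateau, if reached.

    Finite-difference slopes between consecutive points are scanned; the
    SRP is the first point whose incoming slope is <= *slope_tol* with all
    later slopes also <= *slope_tol*.  Returns ``srp_reads=None`` when the
    curve never flattens.
    """
    pts = curve.points
    if len(pts) < 3:
        raise ValueError("SRP needs at least three curve points")
    reads = pts["reads"].to_numpy(dtype=float)
    frags = pts["fragments"].to_numpy(dtype=float)
    slopes = np.diff(frags) / np.diff(reads)
    if (slopes < 0).any():
        raise ValueError(
            "fragment counts decreased along the curve; nested subsampling "
            "was violated"
        )
    srp_reads = None
    ok = slopes <= slope_tol
    for j in range(len(slopes)):
        if ok[j:].all():
            srp_reads = int(pts["reads"].iloc[j + 1])
            break
    return OrpSrpResult(srp_reads=srp_reads, slope_tolerance=slope_tol)


def optimize(
    curve: SaturationCurve, slope_tol: float = DEFAULT_SLOPE_TOL
) -> OrpSrpResult:
    """Combined ORP + SRP summary of one saturation curve."""
    orp = find_orp(curve)
    srp = find_srp(curve, slope_tol)
    return OrpSrpResult(
        orp_reads=orp.orp_reads,
        orp_unit_cost=orp.orp_unit_cost,
        orp_boundary=orp.orp_boundary,
        srp_reads=srp.srp_reads,
        slope_tolerance=srp.slope_tolerance,
    )
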