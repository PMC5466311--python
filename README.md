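# ddgbs

A design and evaluation toolkit for **double-digest genotyping by
sequencing (ddGBS)** experiments: in silico restriction digestion and
library design, the statistics used to score enzyme combinations,
read-subsampling saturation analysis for choosing a sequencing volume,
and depth-stratified genotype quality control against array genotypes.
A built-in simulator generates complete synthetic experiments (genome,
barcoded reads, planted SNPs with truth genotypes, emulated chip data),
so every step can be exercised and validated at desk scale.

It is aimed at groups planning reduced-representation sequencing for a
new species or population — typically before committing a large panel
(hundreds of individuals) to one enzyme combination and one lane budget.

## The statistics

For a library digested with enzymes A and B, only **AB fragments** (one
end cut by each enzyme) receive both adapters and are sequenced. With
per-sample fragment counts *f₁ … fₙ* and the pooled multi-sample count
*f_pool*, the toolkit computes:

- **Fragment consistency index**: FCI = (1/n Σ fᵢ) / f_pool — near 1
  when every sample recovers the same loci (little missing data).
- **Depth**: good-barcode reads / fragment count (reads per locus).
- **CV_depth**: per fragment, the coefficient of variation
  SD(depth)/mean(depth) across samples; its distribution measures how
  uniformly loci are represented across individuals.
- **SNP density** per chromosome (SNPs/Mb) and its CV across
  chromosomes (marker-distribution uniformity).
- **Saturation curve**: nested read subsampling at increasing
  proportions, counting fragments whose tag support reaches the minimum
  tag count c (default 3). The **ORP** (optimal read-count point)
  minimizes the unit sequencing cost per discovered fragment; the
  **SRP** (saturated read-count point) is the smallest read volume at
  which fragment discovery plateaus.
- **Concordance**: depth-stratified agreement of sequencing genotypes
  with array genotypes, split into homozygous / heterozygous /
  call-weighted total consistency.
- **LD decay**: mean dosage-correlation r² per distance bin, and the
  distance at which it falls below a threshold (default 0.1).

## Worked example

A complete synthetic EcoRI–MseI experiment (3 Mb genome, 3 samples,
mean depth 30×, lognormal fragment-abundance dispersion σ = 0.8):

```python
from ddgbs import *
from ddgbs.simulate import tag_table_from_demux

cfg = SimConfig(seed=7, genome_length=3_000_000, n_samples=3)
genome = simulate_genome(cfg)

res = double_digest(genome, get_enzyme("EcoRI"), get_enzyme("MseI"))
sel = size_select(res, 300, 650)
# res: 22097 fragments {'BB': 20342, 'AB': 1720, 'AA': 33, 'terminal': 2}
# sel: 173 AB fragments in the 300-650 bp window

reads, truth = simulate_reads(genome, cfg)
dm = demultiplex(reads, truth.barcodes)
# per-sample good barcode reads: {'S001': 5516, 'S002': 5546, 'S003': 5751}
# unassigned: 0

tags = tag_table_from_demux(dm, truth)
curve = build_saturation_curve(
    tags, [0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 0.8, 1.0], c=3, seed=0
)
print(optimize(curve, slope_tol=1e-3))
```

The saturation curve this prints:

```
proportion  reads  fragments  depth  unit_cost
      0.01    168          5  33.60      33.60
      0.02    336         21  16.00      16.00
      0.05    841         77  10.92      10.92
      0.10   1681        130  12.93      12.93
      0.20   3363        166  20.26      20.26
      0.50   8406        173  48.59      48.59
      0.80  13450        173  77.75      77.75
      1.00  16813        173  97.18      97.18
```

The unit cost is U-shaped: at tiny read volumes almost no fragment
reaches the minimum tag count (expensive per fragment); at large
volumes fragment discovery has saturated while reads keep accumulating.
The interior minimum — the ORP — sits at 841 reads, where each
discovered fragment costs 10.9 read-units and the depth is ≈ 11× per
fragment, i.e. the ~10× economic operating regime. Fragment counts
plateau at 173, reached (slope ≤ 10⁻³ fragments/read) by 13 450 reads
(the SRP). The realized per-fragment depth dispersion,
`cv_depth_distribution`, reports mean CV_depth 0.68 ± 0.33 over the 173
fragments for this 3-plex library.

Published 3-plex library statistics are reproduced directly from their
read/fragment counts, e.g.:

```python
>>> compute_fci([974736, 976575, 978805], 1247742)
0.7828
>>> compute_depth(95649069, 1247742)
76.66
```

## Command line

Every analysis is also exposed as a subcommand of `ddgbs`:

```
ddgbs digest   --fasta G.fa --enzyme-a EcoRI --enzyme-b MseI \
               --min-len 300 --max-len 650 --out-bed frags.bed
ddgbs barcodes --n 96 --min-distance 3 --seed 1 --out bc.tsv
ddgbs demux    --fastq run.fq --barcodes bc.tsv --report demux.tsv
ddgbs saturate --tags tags.tsv --c 3 --proportions 0.1,0.2,0.5,0.8,1.0
ddgbs qc filter  --vcf calls.vcf --dp-min 5 --gq-min 98
ddgbs qc concord --gbs-vcf calls.vcf --chip-tsv chip.tsv
ddgbs simulate --seed 1 --out-dir run/
```

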