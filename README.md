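# sdscape

Genome-wide detection and characterisation of **segmental duplications
(SDs)** — genomic segments ≥ 1 kb present at two or more locations with
≥ 90% sequence identity. SDs drive copy-number variation and gene-family
expansion, and they are also where genome assemblies break: a high-identity
"duplication" in an assembly may equally be a mis-assembly artifact. This
package is aimed at people analysing assemblies of non-model
(e.g. livestock) genomes who want a reproducible SD map with absolute copy
numbers and downstream association statistics, and at methods developers
who need a fully instrumented synthetic test bed for SD callers.

## What it computes

Two independent detectors are combined:

* **WGAC** (whole-genome assembly comparison): after excising known common
  repeats, the assembly is compared against itself with a seed–chain–extend
  local aligner; pairwise alignments with length ≥ 1 kb and identity ≥ 0.90
  are reported. Duplicon families with ≥ 50 copies or spanning ≥ 3
  chromosomes are removed as high-copy artifacts.
* **WSSD** (whole-genome shotgun sequence detection): 36 bp reads are
  placed at every locus within 2 mismatches, depth split equally among
  equal-best loci; runs of sliding windows (5 kb window, 1 kb slide) whose
  depth exceeds the trimmed background mean by > 3 SD are refined to
  base-level boundaries and reported when ≥ 10 kb, with absolute copy
  number

  ```
  CN = 2 × mean depth / background depth      (diploid scale)
  ```

The final SD map applies the artifact-removal rule: WGAC alignments with
identity < 94% enter the map directly; alignments ≥ 94% — the range where
assembly artifacts concentrate — are kept only when WSSD intervals cover at
least half of one of their loci. Permutation tests (length- and
count-based overlap statistics, 10,000 random non-overlapping re-placements,
add-one empirical p-values) quantify SD enrichment in pericentromeric and
subtelomeric regions (2 Mb flanks; 300 kb for designated short
chromosomes), CNV regions and gene families, and gene annotations are
intersected with the map to produce per-gene copy numbers, copy-number bin
tables and cross-species common-gene sets.

A first-class synthetic-data module generates reference genomes with
planted duplications (controlled length, identity, copy number, tandem /
dispersed / interchromosomal), high-copy repeat families, and uniform
coverage reads from a donor genome that carries extra copies absent from
the reference — with complete ground truth, so every stage is testable
end to end without any external data.

## Worked example

```python
import json, pandas as pd
from sdscape import RunConfig, run_all
from sdscape.pipeline import build_fixture
from sdscape import intervals as iv

fx = build_fixture("standard", seed=1)     # 5 Mb, 30 planted duplications
cfg = RunConfig(outdir="std_run", seed=1, n_replicates=1000)
manifest = run_all(cfg, fixture=fx)
print(manifest["determinism"]["counts"])

sd_map = pd.read_csv("std_run/sd_map.bed", sep="\t", header=None,
                     names=["chrom", "start", "end", "support",
                            "max_identity", "copy_number"])
truth = fx.scored_truth_intervals()
rec = iv.overlap_bases(sd_map[["chrom", "start", "end"]], truth) \
    / iv.total_length(truth)
summary = json.load(open("std_run/sd_summary.json"))
print(round(rec, 4), round(summary["sd_content"], 4))
```

prints (about a minute on one CPU)

```
{'wgac_initial': 1803, 'wgac_cleaned': 30, 'reads_unmapped': 4801,
 'wssd_intervals': 28, 'wgac_low': 16, 'wgac_high': 14,
 'wgac_high_validated': 12, 'sd_regions': 56, 'enrichment_tests': 2,
 'genes_in_sd': 69}
0.9427 0.2437
```

Reading the counts: self-comparison found 1,803 initial pairwise
alignments; high-copy cleaning collapsed the planted 60-copy and
3-chromosome artifact families, leaving the 30 genuine alignments. Of
those, 16 fall below 94% identity and enter the map directly; 12 of the 14
at ≥ 94% are validated by the 28 read-depth intervals (the two dropped
ones are short events below the 10 kb depth floor). The final 56-region
map covers 94.3% of the planted duplicated bases — none of its bases fall
outside the planted intervals ± 1 kb — and 24.4% of this
duplication-dense synthetic genome is SD.

The same pipeline is available from the shell:

```bash
sdscape make-fixture --scale small --seed 1 --outdir fx/
sdscape run-all --outdir run/ --scale standard --seed 1
sdscape wgac --genome fx/reference.fa --repeats fx/repeats.bed --out aln.tsv
```

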