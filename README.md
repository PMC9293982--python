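# desertsweep

Selection-sweep scans, population structure and genome×transcriptome
association for SNP panels, with a synthetic-data generator that provides
ground truth for every stage.

The pipeline covers:

* **Marker QC** — call rate, minor-allele frequency and an exact
  Hardy–Weinberg test (strict `<` thresholds: 0.90 / 0.05 / 1e-6).
* **Population structure** — PCA (Patterson scaling), p-distance matrices,
  Saitou–Nei neighbor joining with Newick output, pairwise r² (haplotype
  and composite modes), sliding-window LD pruning (50 SNPs / step 10 /
  r² > 0.1, keeping the higher-MAF SNP of each offending pair), and LD-decay
  curves.
* **Selection statistics** — per-SNP Weir–Cockerham FST (with a
  ratio-of-sums genome average), EHH → iHH → iHS (standardized within
  derived-allele-frequency bins), and site-EHH → iES → xp-EHH / Rsb between
  populations (genome-wide standardization). Integration is over physical
  distance with a configurable EHH cutoff (default 0.05).
* **Candidate gene sets** — top 1% / 5% score tails, SNP→gene annotation
  with a flank (default 50 kb), UpSet-style exclusive intersections, and
  CGS construction by union or intersection.
* **Expression arm** — FPKM (`10⁶·C / (N·L/10³)`), a least-squares
  focal-stage t-statistic (MSE divided by N, exactly as specified), top-7%
  stage-specific gene sets (SEGS), CGS∩SEGS association with per-stage
  contribution fractions, and 2^−ΔΔCt arithmetic.
* **Synthetic data** — mosaic-of-founders haplotypes with decaying LD and
  tunable between-population FST, implanted hard sweeps, planted QC
  violations, tiled toy gene annotations and stage-structured expression
  matrices; all byte-stable under a fixed seed.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence against independent brute-force implementations, sweep-recovery
power over 20 simulated replicates, NJ exactness on additive matrices,
planted-violation QC, SEGS recovery and the pruning contract). The sweep
recovery class takes several minutes; everything else finishes in seconds.

## CLI

```sh
# generate a synthetic fixture bundle (VCF, PLINK, GFF3, expression TSVs)
desert-sweep simulate --config sim.yaml --seed 1 --out bundle/

# marker QC
desert-sweep qc --vcf bundle/genotypes.vcf --pop-map bundle/pop_map.tsv \
    --min-call-rate 0.9 --min-maf 0.05 --hwe 1e-6 --out-dir qc/

# one statistic at a time
desert-sweep scan --vcf ... --pop-map ... --stat ihs   --pops pop0 --out ihs.tsv
desert-sweep scan --vcf ... --pop-map ... --stat xpehh --pops pop0:pop1 --out xpehh.tsv

# the full workflow
desert-sweep run --config pipeline.yaml --out results/
```

A minimal `pipeline.yaml`:

```yaml
vcf: bundle/genotypes.vcf
pop_map: bundle/pop_map.tsv
gff: bundle/genes.gff3
ihs_pops: [pop0]
comparisons:
  - name: a
    pop_a: [pop0]
    pop_b: [pop1]
expression:
  fpkm: bundle/expression_fpkm.tsv
  stages: bundle/sample_stages.tsv
```

`run` writes plain TSV/JSON artifacts per stage plus `manifest.json`, which
records every resolved default and is itself a valid config (feeding it
back reproduces the outputs). Exit codes: 0 ok, 2 config error, 3 data
error.

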