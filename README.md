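# ploidyscan

Single-embryo ploidy and chromosome-dosage inference from whole-genome
read depth, plus everything needed to exercise it without external
data: a synthetic miniature genome and depth simulator, an embryo-fate
cohort simulator, and the cohort-level statistics battery.

The pipeline starts from per-position depth-of-coverage tracks
(bedGraph) and marker-gene annotations (BED). For each embryo it
computes **percent depth** per gene — 100 × mean depth across the gene
/ mean depth across the genome — classifies each gene into a dosage
band (absent / hemizygous / disomic / amplified, anchored at nominal
0 / 50 / 100 / 150 %), majority-votes five marker genes per chromosome
arm, tests the paternally transmitted `egfp` transgene for meaningful,
evenly distributed coverage, and combines everything into an
embryo-level verdict: **diploid**, **haploid** (maternal-only; absent
paternal markers, self-normalized 100 % dosage elsewhere),
**segmental aneuploid**, or ambiguous, with inferred sex.

Cohort statistics cover blastulation-vs-hatch comparisons (chi-squared,
with a Yates variant), stage-wise abnormality frequencies (two-sided
Fisher exact, including exact 2×C tables by enumeration), rank tests
(Mann–Whitney with exact small-sample enumeration, Kruskal–Wallis),
paired t with Shapiro–Wilk pre-checks, and egg-to-adult attrition.

## Layout

| module | contents |
| --- | --- |
| `ploidyscan.synthetic_data` | miniature genome layout, karyotype presets, Poisson depth simulator, embryo-fate cohort simulator, FASTA/BED/TSV writers |
| `ploidyscan.depth_quant` | bedGraph/BED ingestion, mean genome depth, per-gene percent depth, mitochondrially normalized depth |
| `ploidyscan.ploidy_caller` | dosage banding, arm majority vote, transgene presence, sex and ploidy calls |
| `ploidyscan.cohort_stats` | contingency/rank/paired-t tests, lethal-phase and defect-rate reports |
| `ploidyscan.printed_counts` | published count tables used as fixtures and worked examples |
| `ploidyscan.cli_pipeline` | `ploidyscan` CLI and the end-to-end demo run |

## CLI

```sh
# miniature reference: FASTA + gene BED + sequence manifest
ploidyscan simulate genome --arm-length 100000 --gene-length 1000 --seed 0 --out-dir genome/

# one embryo's depth track (preset or explicit copy numbers)
ploidyscan simulate embryo --karyotype haploid_maternal --coverage 50 --seed 3 --out-dir depth/
ploidyscan simulate embryo --karyotype "X=1,Y=1,2L=2,2R=2,3L=2,3R=2,4=2,egfp=1" --out-dir depth/

# per-embryo verdict (JSON + optional gene x percent-depth matrix)
ploidyscan call-ploidy --depth depth/haploid_maternal.bedgraph \
    --genes genome/genes.bed --layout genome/manifest.tsv \
    --paternal-markers egfp,Y --out call.json --matrix-out matrix.tsv

# four-cross fate cohort and its statistics
ploidyscan simulate cohort --n 2000 --seed 1 --out cohort.tsv
ploidyscan cohort-stats --input cohort.tsv --out stats.json

# everything end to end, deterministic per seed
ploidyscan demo --seed 1 --out-dir demo/
```

`simulate cohort --params` and `demo --config` accept plain key/value
files (`CI.p_hatch_given_diploid = 0.5`, `coverage = 30`, ...). All
caller thresholds (band edges, transgene percent/evenness cuts, arm
majority) are config-exposed.

## Notes on conventions

- Coordinates are 0-based half-open throughout; bedGraph/BED native
  conventions are preserved at I/O; strand is ignored.
- The mean-genome-depth denominator is the length-weighted mean over
  the *autosomal* arms (overridable); see `depth_quant.denominator_sequences`.
- All simulators draw from named `numpy.random.SeedSequence`
  sub-streams, so per-embryo results are independent of cohort size.
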