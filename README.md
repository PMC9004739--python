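# seedtox

Predicted 6mer-seed-toxicity analysis of small RNA sequencing data.

Any small RNA loaded into the RISC acts through its 6mer seed (read
positions 2–7 from the 5' end). `seedtox` takes trimmed or untrimmed
small-RNA reads (FASTQ/FASTA, one file per sample) — or a pre-built
unique-read count table — and produces a set of keyed output tables
describing the sample's sRNA pool by predicted seed toxicity (% viability
from an all-4096-seeds screen resource), plus the statistics comparing
toxicity and positional seed composition between groups.

## Pipeline

1. **Preprocess** — 5' adapter/UMI stripping, exact-substring 3' adapter
   removal (default `TCCGACGATC`), and mode-dependent length filtering
   (`risc`: > 6 nt; `total`: 18–25 nt).
2. **Count** — unique-read × sample count table, counts-per-million
   normalization, and the rare-read filter (total normalized count < n
   removed, n = number of samples; the unfiltered table is kept as
   `Int_allReads.txt`).
3. **Annotate** — each read is assigned a mature-miRNA identity (≥ 18 nt
   exact ungapped identity) and an RNA-world catalog identity (≥ 95%
   ungapped identity over the read); reads whose catalog hit names an
   artificial sequence (spike-ins, markers, adapters) are purged. Every
   row gains its seed and species-averaged % viability.
4. **Differential** (optional) — per-read negative-binomial exact test
   between two sample groups (common dispersion by conditional maximum
   likelihood), BH adjustment, selection at adjusted p < 0.05 and
   |logFC| > 0.585, delta normalized counts split into Up/Down groups.
5. **Outputs** — the keyed families, per analysis
   (`totalCounts`/`differential`) and branch (`sRNA`/`miRNA`):
   - `A_rawCounts` / `A_normCounts` / `A_diff_*` — annotated count tables
   - `B_collapsed` (+ `Int_seedKeyed`) — collapsed by (seed, assigned name)
   - `C_binned` — counts in 1% viability bins (Seed Tox graph input)
   - `D_toxAnalysis` — one row per rescaled seed instance (count/1000),
     holding the viability value (boxplot / rank-test input)
   - `E_seedAnalysis` — same expansion holding the seed string (logo input)
   - `F_seedExpand` — 6 rows per instance (position 1–6, one nucleotide
     each); seeds with counts < 1000 omitted; exactly 6N rows
6. **Statistics** — Wilcoxon rank-sum / Kruskal–Wallis on D; a
   baseline-category multinomial mixed-effects logit on F (fixed effects:
   group, position, group × position; random per-instance intercept per
   non-reference nucleotide, A as the reference), fitted by marginal
   maximum likelihood with Gauss–Hermite quadrature. Group differences are
   reported as odds ratios with Wald intervals and Tukey-adjusted p-values
   over all pairwise group contrasts.

## Command line

```sh
# generate a synthetic dataset with known ground truth
seedtox simulate --seed 1 --out demo/

# print the ordered stage plan without executing
seedtox plan --fastq demo/fastq/control_1.fastq ... --out demo/out \
    --viability demo/viability.tsv --mirna demo/mirna.fasta --rnaworld demo/rnaworld.fasta

# execute (writes the totalCounts/differential x sRNA/miRNA hierarchy)
seedtox run --fastq demo/fastq/control_1.fastq ... --out demo/out \
    --viability demo/viability.tsv --mirna demo/mirna.fasta --rnaworld demo/rnaworld.fasta \
    --group control_1=control --group disease_1=disease \
    --analysis totalCounts --analysis differential --comparisons comparisons.csv

# fit the seed-composition model on an F table
seedtox stats --f-table demo/out/totalCounts/sRNA/F_seedExpand_avg.txt --out ors.tsv
```

Input resources: the seed-viability table is a TSV
(`seed<TAB>cellline1<TAB>...`, all 4096 seeds); references are plain
FASTA. `seedtox simulate` produces structurally faithful stand-ins for all
of them.

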