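# mirswim

A small RNA-seq miRNA profiling pipeline for two-library (treatment vs
control) deep-sequencing studies, of the kind used to catalogue known and
novel brain miRNAs responding to exercise in the rat.  It takes two raw
FASTQ libraries, a genome, an annotation and a mature-miRNA reference, and
produces the full ladder of study tables: filtering statistics, annotation
categories, known-miRNA expression, novel hairpin candidates, and
differentially expressed miRNAs — plus a synthetic-data generator that
plants ground truth so the entire pipeline is testable without any external
data.

## What it computes

**Cleaning and profiling.** Reads are filtered (quality, adapter
contaminants, polyA, length), 3'-adapter-trimmed, and collapsed to unique
18–30 nt tags with per-library counts.  Tags map to the genome by perfect
match on both strands and receive one annotation class by fixed priority
(rRNA > scRNA > … > repeat > exon > intron); unannotated tags are matched
to a miRBase-style mature reference with a ≤2 nt terminal-shift (isomiR)
tolerance and grouped into families.

**Novel miRNA discovery.** Remaining mapped tags seed candidate precursor
windows that are folded with a single-hairpin nearest-neighbour MFE model
(Watson–Crick + G·U stacking, loop penalties; dynamic programming validated
against exhaustive enumeration).  A candidate is called a novel miRNA iff
it passes six criteria: MFE ≤ −25 kcal/mol and MFEI ≥ 0.85, where

    MFEI = (−MFE · 100 / L) / GC%,

mature on one arm; a mature/miRNA* duplex with 2-nt 3' overhangs; ≤ 4
duplex mismatches; at most one bulge/internal loop of ≤ 1 nt; and ≥ 5
supporting reads.  Identical matures at multiple loci merge into one miRNA
listing every locus.

**Differential expression.** Counts are normalized to transcripts per
million (TPM = count/total·10⁶) of each library's clean reads; fold change
is log₂ of the TPM ratio with a 0.01 floor (so condition-specific miRNAs
stay finite); significance uses the Audic–Claverie exact test — the count
in one library conditional on the other is negative binomial,
NB(x+1, N₁/(N₁+N₂)) — two-sided, symmetrized, with the gate
p < 0.05 and |log₂FC| > 1.  A 2^−ΔΔCT helper supports qPCR validation, and
a 2-of-3 consensus combiner post-processes external target predictions.

## Worked example

Generate a synthetic two-library study and run the whole pipeline:

```bash
mirswim synth --seed 11 --out demo/synth --deterministic
cat > demo/run.yaml <<EOF
fastq:
  HIST: demo/synth/HIST.fastq
  NC: demo/synth/NC.fastq
genome: demo/synth/genome.fa
annotation: demo/synth/annotation.bed
reference: demo/synth/mature_reference.fa
families: demo/synth/families.tsv
adapter3: TCGTATGCCGTCTTCTGCTTG
adapter5: GTTCAGAGTTCTACAGTCCGACGATC
output_dir: demo/out
seed: 11
EOF
mirswim run-all --config demo/run.yaml
```

which prints:

```
INFO mirswim: HIST: 17429 raw -> 14962 clean reads, 80 unique tags
INFO mirswim: NC: 17626 raw -> 15162 clean reads, 82 unique tags
INFO mirswim: mapped 99.9% of reads
INFO mirswim: known miRNAs: 12
INFO mirswim: novel miRNAs: 9 (21 candidate loci evaluated)
INFO mirswim: significant: 8 (4 up, 4 down)
```

Reading the output: the filter cascade removed the ~14% planted
contaminants; every planted known miRNA was re-identified; the nine novel
calls are exactly the planted criteria-passing hairpins (the planted weak,
high-mismatch and low-count decoys are rejected); and the eight significant
miRNAs are exactly the loci planted with |log₂FC| ≈ 2 or
condition-specific expression.  The novel table
(`demo/out/table4_novel.tsv`) reports, per miRNA, its mature sequence,
per-library counts, precursor locus, MFE and MFEI:

```
name             sequence                 length  HIST  NC   precursor_loci      MFE    MFEI
rno-miR-n001_5p  CACCTGTACTGCTACCCTCACG   22      124   495  chr1:584:644:+      -39.9  1.38
rno-miR-n002_3p  CCTCAGCTGTCGGGTGTTGTACT  23      280   280  chr1:844:906:+      -37.8  1.45
```

and the expression table (`demo/out/table5_diffexpr.tsv`) the normalized
values, fold change and significance call:

```
name           tpm_HIST   tpm_NC     log2fc  p_value  sig  direction
rno-let-7f     258053.74  63645.96   2.02    0.0      **   up
rno-miR-200b   63494.19   250692.52  -1.98   0.0      **   down
```

Stage-by-stage commands (`mirswim preprocess`, `mirswim diffexpr`,
`mirswim targets`) expose the same steps individually; the library API
(`mirswim.preprocess`, `.annotate`, `.known`, `.novel`, `.diffexpr`,
`.targets`, `.synth`, `.pipeline`) is what the test suite exercises.

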