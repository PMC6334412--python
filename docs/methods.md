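# Methods

`mirswim` re-implements a two-library small-RNA-seq miRNA analysis as a
tested, reusable pipeline: read cleaning, perfect-match genome annotation,
known-miRNA profiling, hairpin-based novel-miRNA discovery, and exact-test
differential expression, together with a synthetic-study generator that
makes every stage verifiable against planted ground truth.  This note
documents the models, the parameters that matter, and the choices made where
the design was genuinely open.

## Read filtering and tag collapsing

Raw reads are insert + 3' adapter.  The cascade drops, in fixed order:

1. **low-quality** — more than 20% of bases below Q10 (Phred+33), or any N.
   The simulator uses the same definition, so filter and generator share one
   notion of "low quality".
2. **5'-adapter contaminants** — read begins with the first 10 nt of the 5'
   adapter (adapter-adapter ligation products).
3. **no 3' adapter** — no acceptable adapter match: at least 6 nt of exact
   adapter prefix, one mismatch tolerated for matches of 10 nt or more,
   leftmost match wins.
4. **no insert** — adapter match at position 0.
5. **polyA** — trimmed insert with ≥ 90% A.
6. **length** — insert outside 18–30 nt.

Every run asserts `raw = clean + Σ dropped`.  Filtering is idempotent:
re-adaptered clean tags pass unchanged.  Collapsing produces unique tags
with per-library counts, sorted by count then sequence so output is
byte-stable.

## Mapping and annotation

Tags map to the genome by exact substring search on both strands (12-mer
seed index, full verification; only perfect alignments are used anywhere).
All loci of a multi-mapping tag are kept.  Each tag receives exactly one
annotation class — the highest-priority class over all features overlapping
any of its hits:

```
rRNA > scRNA > snRNA > snoRNA > srpRNA > tRNA > repeat >
exon_sense > exon_antisense > intron_sense > intron_antisense
```

Exon/intron split into sense/antisense by strand agreement between hit and
feature.  Tags overlapping nothing are *unannotated* and feed miRNA
identification.  The priority order is configurable; the default mirrors the
row set of classic small-RNA annotation reports.  Class assignment is
computed across all hits at once, so it is independent of hit order.

## Known-miRNA identification

Unannotated tags are matched to a multi-species mature reference
(miRBase-style headers, `spe-miR-name`).  A tag matches an entry when the
overlapping region is identical and each terminus differs by at most 2 nt
(isomiR shifts/extensions; no internal mismatches).  Ties break
deterministically: native-species (`rno`) entries first, then fewest
terminal shifts, then name.  Each tag is assigned to at most one entry, so
read counts are conserved: known + unmatched = input.  Families come from an
explicit metadata table when available, otherwise from the name stem
(`let-7c → let-7`, `rno-miR-200a-5p → mir-200`).

## Secondary-structure model

Novel-miRNA discovery needs the minimum free energy (MFE) of stem-loop
structures.  Animal pre-miRNAs are single hairpins, so folding is restricted
to that topology: one nested chain of base pairs closed by a terminal loop
of ≥ 3 nt, no multibranch loops.  The energy model is a Turner-style
nearest-neighbour set authored for this package:

- stacking energies over the six pair types (Watson–Crick + G·U wobble),
  roughly −0.5 to −3.4 kcal/mol;
- hairpin-loop, bulge and internal-loop initiation penalties by size, with
  logarithmic extrapolation (1.08·ln(n/n₀) kcal/mol) beyond the tabulated
  sizes; single-nucleotide bulges preserve helix stacking;
- an asymmetry penalty of 0.5 kcal/mol per unpaired-nucleotide difference
  (capped at 3.0) for internal loops;
- a 0.5 kcal/mol terminal penalty for AU/GU-closed helices;
- bulge and internal-loop gaps capped at 10 nt per strand.

The DP is O(n²·g²) with g the gap cap, implemented in numba, and is
validated two ways: against a full enumeration of every legal structure on
tiny sequences, and against an independent memoized top-down search on
sequences up to 30 nt (1000+ randomized cases).  Because the parameter set
is this package's own, MFE values are comparable *within* the pipeline
(thresholds, rankings) but are not expected to equal other folding engines'
numbers; no test compares absolute MFEs across programs.

## Novel-miRNA discovery

For each perfectly mapped unmatched tag, candidate precursors are excised
around every hit.  The tag may sit on either arm, so windows leave 20 nt on
the loop-proximal side and a ladder of 50–160 nt on the loop-distal side, in
both orientations.  The ladder exists for a structural reason: the MFE of a
~200 nt window of background sequence (≈ −45 kcal/mol under this model) can
exceed that of a genuine ~60 nt hairpin inside it, while the loop-gap cap
prevents the DP from attaching flank pairing to the hairpin stem — so at
least one bounded window must isolate the hairpin.  Each window is folded,
trimmed to the outermost pair that spans ≤ 120 nt and contains the tag
(plus 2 nt of context for the star overhang), and refolded so the reported
MFE/MFEI describe the trimmed precursor.  Per hit, the best window is kept:
criteria-accepted first, then lower MFE, ties to the 5p orientation.

The mature/star duplex is read off the structure with the canonical Dicer
geometry: the star spans the pairing partners of the outermost paired mature
bases, extended 2 nt at its 3' end (2-nt 3' overhangs).  Mismatches are
unpaired mature bases within the duplex span (the mature's own 2-nt 3'
overhang excluded); 1×1 gaps count as mismatches, anything larger is an
internal-loop/bulge feature with per-strand size.

A candidate is accepted iff all six criteria hold:

| # | criterion | threshold |
|---|-----------|-----------|
| 1 | stable stem-loop | MFE ≤ −25.0 kcal/mol **and** MFEI ≥ 0.85 |
| 2 | mature on one arm | never spans the terminal loop |
| 3 | duplex with 2-nt 3' overhangs | star fits inside the precursor |
| 4 | duplex mismatches | ≤ 4 |
| 5 | internal loops/bulges in duplex | ≤ 1, each ≤ 1 nt per strand |
| 6 | supporting reads | ≥ 5 (merged mature, both libraries) |

MFEI = AMFE / GC% with AMFE = −MFE·100/length — the classic index that
separates miRNA hairpins (typically ≳ 0.85) from tRNA/rRNA/mRNA structure
(≈ 0.6).  All thresholds are inclusive and configurable.  Identical matures
at several loci merge into one miRNA listing every locus; counts come from
the tag once, never per locus.  Names are assigned in order of total
abundance (`rno-miR-n001_5p`, …).

## Differential expression

Counts are normalized to TPM of each library's clean reads (unrounded
internally, 2 decimals in reports).  Fold change is
`log2(max(TPM_A, 0.01) / max(TPM_B, 0.01))`; the 0.01 floor makes
library-specific miRNAs finite and reproduces the conventional reporting of
a 1.51-TPM / absent pair as +7.24.  Significance uses the Audic–Claverie
exact test: conditional on one library's count x, the other's count is
negative-binomial with x+1 successes and success probability N₁/(N₁+N₂)
(library totals N₁, N₂).  The two-sided p-value doubles the smaller
*inclusive* tail (capped at 1) and averages the two conditioning directions,
which makes the statistic exactly symmetric under library exchange; the
doubled-tail definition alone differs between directions by one pmf term.
Computation is in log-space via `scipy.stats.nbinom`, and equals exact
rational tail summation to 1e-9 relative error for counts up to 50.

A miRNA is significant when p < 0.05 **and** |log2FC| > 1, both on unrounded
values (a row printed as −1.00 can pass because its unrounded value is
−1.003); `*`/`**` mark p < 0.05 / p < 0.01; direction follows the sign.
The study design pools RNA (one library per condition), so no replicate
dispersion is modelled, and no multiple-testing correction is applied by
default (a Benjamini–Hochberg flag exists, default off) — single-tag exact
testing is reported as-is, as is conventional for this design.  Calibration
on planted counts: type-I error ≤ 5% + 3·SE under the null, ≥ 95% power at
|log2FC| = 2 with ≥ 50 reads per library.

The qPCR helper computes relative expression as 2^−ΔΔCT from target and
reference-gene cycle thresholds in two conditions.

## Target consensus

External predictions are consumed as per-tool vote lists; a (miRNA, gene)
pair supported by ≥ 2 of 3 distinct tools becomes a putative target
(gene-level agreement — "same site" agreement is not required, since site
coordinates are not comparable across tools).  Descriptions come from an
NCBI-dialect gene_info table by left join; missing genes are flagged, never
dropped.  A built-in seed scanner (7mer-m8 / 7mer-A1 / 8mer exact
complements of miRNA positions 2–8) serves as a self-contained stand-in
predictor for generating test votes; it is not a replacement for the
external tools' full scoring.

## Synthetic study generator

The generator emulates the study design end to end on a desk-scale genome
(120 kb over 4 chromosomes by default):

- **known miRNA loci** (10 + 2 planted cross-species-only matures) embedded
  in designed hairpins, with a multi-species reference containing ortholog
  duplicates and decoy entries, and 10% isomiR reads (one templated 3'
  extension);
- **novel hairpin loci** (8) designed to pass all six criteria, with 0–2
  planted duplex mismatches or one 1-nt bulge, on either arm and strand;
- an **11-copy cluster** sharing one mature sequence, copies spaced beyond
  the candidate-window span;
- **designed failures**: AU-only weak stems (criterion 1), 6-mismatch
  duplexes (criterion 4), and a 4-read mature (criterion 6);
- **annotation features** of every class (rRNA … repeat, exon/intron with
  antisense fragments) with planted fragment reads;
- **contaminants** of every filter class at configured fractions
  (2%/3%/1%/1%/1% by default);
- **fold changes**: three up and three down known miRNAs at |log2FC| ≈ 2,
  one down-regulated and one condition-specific (absent-in-control) novel
  miRNA, everything else flat.

Designed stems have exact GC content (0.58 by default; mismatch designs
0.62–0.66 — under this energy model each 1×1 mismatch costs ≈ 6 kcal/mol),
A-rich loops (A/C cannot pair, and a near-GC-free loop does not deflate
MFEI's GC denominator), two G·U wobbles (so the star arm is not the exact
reverse complement of the mature, which would make the tag map onto the
star's strand as well), and 12-nt A/C buffer flanks whose stem-adjacent
base cannot pair the stem terminus — together these guarantee the genomic
context neither extends nor reregisters the designed fold.  Each planted
hairpin's truth record stores the six-criteria verdict obtained by folding
its designed precursor with the pipeline's own engine, so truth labels and
pipeline evaluation can never drift apart; a separate test asserts that the
verdicts match the design intent (pass-designs pass, each failure design
trips its intended criterion).

Per-locus abundances are log-uniform (known 100–3000, novel 20–300 reads) —
the real study reports no abundance distribution, so this is a free choice
covering the dynamic range the tables display.  Counts are emitted exactly
in deterministic mode; in stochastic mode, locus counts are one multinomial
draw around the expectations (clean total conserved) and contaminant counts
are binomial.  Reads are insert + 3' adapter truncated to 36 nt, Phred+33,
Q40 for clean reads.

What the generator does **not** emulate: sequencing substitution errors,
quality-score gradients along the read, abundance biases of ligation and
PCR, degradation products of long RNAs beyond the planted class fragments,
and genome-scale repeat structure.  Passing recovery tests therefore shows
the pipeline logic is correct on clean data at desk scale, not that it is
robust to platform noise at survey scale.

## Numerical and reporting conventions

- Sequences are stored in DNA alphabet (U→T) everywhere; folding treats T
  as U.
- Internal coordinates are 0-based half-open; all user-facing loci are
  1-based inclusive `chrom:start:end:strand`.
- TPM and log2FC are computed unrounded and rounded only in written tables;
  significance gates always use unrounded values.
- All randomness flows from one integer seed (`numpy.random.default_rng`);
  identical configuration and seed give byte-identical FASTA/FASTQ/TSV
  output, asserted by tests.
- Desk-scale defaults (120 kb genome, ~30k reads/library, 500–600 tags for
  calibration) keep a full synthetic study under ~10 s; all sizes are
  configuration fields.

## Known limitations

- The energy parameter set is plausible but not fitted to thermodynamic
  data; only structure *rankings* within this model should be interpreted.
- Hairpin-only folding cannot represent multibranch or pseudoknotted
  alternatives, and loops larger than 10 nt per strand are not bridged.
- Known-miRNA matching has no internal-mismatch tolerance, so cross-species
  matches with point substitutions are not found.
- The exact count test assumes Poisson sampling within each pooled library;
  biological replicate variance is out of scope by design.
- Target consensus never executes the external predictors; it post-processes
  their outputs.
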