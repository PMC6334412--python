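"""End-to-end orchestration: preprocess -> annotate -> known -> novel ->
diffexpr (-> targets), with report tables and a global read-count ledger.

Every intermediate is written as TSV under the output directory; the run is
reproducible byte-for-byte given the same inputs.  The ledger asserts, per
library, that raw reads = dropped + every annotation class (unannotated
included), and that unannotated reads = known + novel + unassigned.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

from . import annotate as ann_mod
from . import diffexpr, known as known_mod, novel as novel_mod
from . import preprocess as pre
from .novel import CriteriaThresholds

log = logging.getLogger("mirswim")

LIB_A = "HIST"
LIB_B = "NC"


@dataclass
class RunConfig:
    fastq: dict[str, str]            # library name -> FASTQ path
    genome: str
    annotation: str                  # BED6 or GFF3
    reference: str                   # mature miRNA FASTA
    adapter3: str
    adapter5: str
    output_dir: str
    families: str | None = None
    gene_info: str | None = None
    target_votes: str | None = None
    alpha: float = 0.05
    lfc: float = 1.0
    floor: float = 0.01
    thresholds: CriteriaThresholds = field(default_factory=CriteriaThresholds)
    seed: int = 0

    def validate(self) -> None:
        for path in [*self.fastq.values(), self.genome, self.annotation,
                     self.reference]:
            if not os.path.exists(path):
                raise FileNotFoundError(path)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.lfc < 0 or self.floor <= 0:
            raise ValueError("lfc must be >= 0 and floor > 0")


@dataclass
class RunResult:
    reports: dict[str, pre.FilterReport]
    tags: list[pre.CleanTag]
    classes: dict[str, str]
    category_table: pd.DataFrame
    known: list[known_mod.KnownMiRNA]
    novel: list[novel_mod.NovelMiRNA]
    unassigned: list[pre.CleanTag]
    expression: pd.DataFrame
    de_summary: dict[str, int]
    ledger: dict[str, dict[str, int]]


def _load_genome(path) -> dict[str, str]:
    chroms = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    names = [n for n, _ in chroms]
    if len(names) != len(set(names)):
        raise ValueError("duplicate chromosome names in genome FASTA")
    return dict(chroms)


def _load_annotation(path) -> list[ann_mod.AnnotationRecord]:
    if str(path).endswith((".gff", ".gff3")):
        return ann_mod.read_gff3(path)
    return ann_mod.read_bed6(path)


def run_all(cfg: RunConfig) -> RunResult:
    """Execute all stages in order; writes report tables to cfg.output_dir."""
    cfg.validate()
    os.makedirs(cfg.output_dir, exist_ok=True)
    libs = sorted(cfg.fastq)

    def out(name):
        return os.path.join(cfg.output_dir, name)

    # --- stage 1: preprocess ------------------------------------------------
    try:
        reports: dict[str, pre.FilterReport] = {}
        per_lib_tags = []
        for lib in libs:
            inserts, report = pre.filter_and_trim(
                pre.read_fastq(cfg.fastq[lib]), cfg.adapter3, cfg.adapter5)
            reports[lib] = report
            per_lib_tags.append(pre.collapse(inserts, lib))
            log.info("%s: %d raw -> %d clean reads, %d unique tags", lib,
                     report.raw_reads, report.clean_reads, report.unique_tags)
            for reason, n in report.dropped.items():
                log.debug("%s: dropped %d (%s)", lib, n, reason)
        tags = pre.merge_libraries(*per_lib_tags)
    except Exception as exc:
        raise RuntimeError(f"stage preprocess failed: {exc}") from exc

    summary_rows = []
    for lib in libs:
        r = reports[lib]
        summary_rows.append({
            "library": lib, "raw_reads": r.raw_reads,
            **{f"dropped_{k}": v for k, v in r.dropped.items()},
            "clean_reads": r.clean_reads, "unique_tags": r.unique_tags,
        })
    pd.DataFrame(summary_rows).to_csv(out("table1_summary.tsv"), sep="\t", index=False)
    with open(out("filter_reports.json"), "w") as fh:
        json.dump({lib: vars(r) for lib, r in reports.items()}, fh, indent=2)

    dist_rows = []
    for lib in libs:
        for ln, (c, f) in pre.length_distribution(tags, lib).items():
            dist_rows.append({"library": lib, "length": ln, "count": c, "fraction": f})
    pd.DataFrame(dist_rows).to_csv(out("fig1_length_distribution.tsv"),
                                   sep="\t", index=False)
    if len(libs) == 2:
        a_tags = [t for t in tags if t.counts.get(libs[0], 0) > 0]
        b_tags = [t for t in tags if t.counts.get(libs[1], 0) > 0]
        comp = pre.compare_libraries(
            [pre.CleanTag(t.seq, {libs[0]: t.counts[libs[0]]}) for t in a_tags],
            [pre.CleanTag(t.seq, {libs[1]: t.counts[libs[1]]}) for t in b_tags])
        pd.DataFrame(comp).T.to_csv(out("fig2_common_specific.tsv"), sep="\t")

    # --- stage 2: map + annotate -------------------------------------------
    try:
        genome = _load_genome(cfg.genome)
        index = ann_mod.build_index(genome.items())
        hits_by_seq, map_summary = ann_mod.map_tags(tags, index)
        ann_index = ann_mod.AnnotationIndex(_load_annotation(cfg.annotation))
        classes = ann_mod.classify_all(tags, hits_by_seq, ann_index)
        category = ann_mod.category_summary(tags, classes, libs)
    except Exception as exc:
        raise RuntimeError(f"stage annotate failed: {exc}") from exc
    category.to_csv(out("table2_categories.tsv"), sep="\t", index=False)
    with open(out("mapping_summary.json"), "w") as fh:
        json.dump(map_summary, fh, indent=2)
    log.info("mapped %.1f%% of reads", 100 * map_summary["read_fraction"])

    # --- stage 3: known miRNAs ---------------------------------------------
    try:
        unannotated = [t for t in tags if classes[t.seq] == ann_mod.UNANNOTATED]
        reference = known_mod.load_mature_fasta(cfg.reference)
        fam_map = known_mod.load_family_tsv(cfg.families) if cfg.families else None
        known_list, unmatched = known_mod.match_known(unannotated, reference, fam_map)
    except Exception as exc:
        raise RuntimeError(f"stage known failed: {exc}") from exc
    with open(out("table3_known.tsv"), "w") as fh:
        fh.write("name\tsequence\tlength\t" + "\t".join(f"count_{l}" for l in libs)
                 + "\tfamily\torthologs\n")
        for k in known_list:
            fh.write(f"{k.name}\t{k.mature_seq}\t{len(k.mature_seq)}\t"
                     + "\t".join(str(k.counts.get(l, 0)) for l in libs)
                     + f"\t{k.family}\t{','.join(k.orthologs)}\n")
    log.info("known miRNAs: %d", len(known_list))

    # --- stage 4: novel miRNAs ---------------------------------------------
    try:
        mapped_unmatched = [t for t in unmatched if t.seq in hits_by_seq]
        novel_list, candidates, unassigned_mapped = novel_mod.discover_novel(
            mapped_unmatched, hits_by_seq, genome, cfg.thresholds)
        novel_matures = {n.mature_seq for n in novel_list}
        unassigned = [t for t in unmatched if t.seq not in novel_matures]
    except Exception as exc:
        raise RuntimeError(f"stage novel failed: {exc}") from exc
    with open(out("table4_novel.tsv"), "w") as fh:
        fh.write("name\tsequence\tlength\t" + "\t".join(f"count_{l}" for l in libs)
                 + "\tprecursor_loci\tMFE\tMFEI\n")
        for n in novel_list:
            loci = ";".join(c.locus for c in n.loci)
            mfes = ";".join(f"{c.mfe:.1f}" for c in n.loci)
            mfeis = ";".join(f"{c.mfei:.2f}" for c in n.loci)
            fh.write(f"{n.name}\t{n.mature_seq}\t{len(n.mature_seq)}\t"
                     + "\t".join(str(n.counts.get(l, 0)) for l in libs)
                     + f"\t{loci}\t{mfes}\t{mfeis}\n")
    with open(out("novel_precursors.fa"), "w") as fh:
        for n in novel_list:
            for i, c in enumerate(n.loci):
                fh.write(f">{n.name}|locus{i + 1}|{c.locus}\n{c.precursor_seq}\n")
    with open(out("novel_structures.txt"), "w") as fh:
        for n in novel_list:
            for i, c in enumerate(n.loci):
                fh.write(f"{n.name}|locus{i + 1}\t{c.precursor_seq}\t"
                         f"{c.fold.structure}\t{c.mfe:.1f}\n")
    log.info("novel miRNAs: %d (%d candidate loci evaluated)",
             len(novel_list), len(candidates))

    # --- stage 5: differential expression ----------------------------------
    try:
        totals = {lib: reports[lib].clean_reads for lib in libs}
        names, ca, cb = [], [], []
        for k in known_list:
            names.append(k.name)
            ca.append(k.counts.get(LIB_A, 0))
            cb.append(k.counts.get(LIB_B, 0))
        for n in novel_list:
            names.append(n.name)
            ca.append(n.counts.get(LIB_A, 0))
            cb.append(n.counts.get(LIB_B, 0))
        expression = diffexpr.build_expression_table(
            names, ca, cb, totals[LIB_A], totals[LIB_B],
            lib_a=LIB_A, lib_b=LIB_B, floor=cfg.floor)
        expression, de_summary = diffexpr.classify(expression, cfg.alpha, cfg.lfc)
    except Exception as exc:
        raise RuntimeError(f"stage diffexpr failed: {exc}") from exc
    report = expression.copy()
    for col in (f"tpm_{LIB_A}", f"tpm_{LIB_B}"):
        report[col] = report[col].round(2)
    report["log2fc"] = report["log2fc"].round(2)
    report.to_csv(out("table5_diffexpr.tsv"), sep="\t", index=False)
    expression[["name", f"tpm_{LIB_A}", f"tpm_{LIB_B}", "significance"]].to_csv(
        out("fig4_scatter.tsv"), sep="\t", index=False)
    log.info("significant: %d (%d up, %d down)", de_summary["n_sig"],
             de_summary["n_up"], de_summary["n_down"])

    # --- stage 6 (optional): target consensus -------------------------------
    if cfg.target_votes and cfg.gene_info:
        from . import targets as tgt
        votes = tgt.read_votes_tsv(cfg.target_votes)
        calls = tgt.consensus(votes)
        calls, missing = tgt.annotate_genes(calls, tgt.load_gene_info(cfg.gene_info))
        if missing:
            log.warning("gene_info missing %d gene ids", len(set(missing)))
        tgt.write_calls_tsv(calls, out("table6_targets.tsv"))

    # --- global read-count ledger -------------------------------------------
    ledger = {}
    for lib in libs:
        clean = reports[lib].clean_reads
        by_class = {}
        for t in tags:
            by_class[classes[t.seq]] = by_class.get(classes[t.seq], 0) + t.counts.get(lib, 0)
        known_reads = sum(k.counts.get(lib, 0) for k in known_list)
        novel_reads = sum(n.counts.get(lib, 0) for n in novel_list)
        unassigned_reads = sum(t.counts.get(lib, 0) for t in unassigned)
        entry = {
            "raw": reports[lib].raw_reads,
            "dropped": sum(reports[lib].dropped.values()),
            "clean": clean,
            "annotated_non_mirna": clean - by_class.get(ann_mod.UNANNOTATED, 0),
            "unannotated": by_class.get(ann_mod.UNANNOTATED, 0),
            "known": known_reads,
            "novel": novel_reads,
            "unassigned": unassigned_reads,
        }
        assert entry["raw"] == entry["dropped"] + entry["clean"], \
            f"{lib}: raw != dropped + clean"
        assert sum(by_class.values()) == clean, f"{lib}: classes do not partition clean"
        assert entry["unannotated"] == known_reads + novel_reads + unassigned_reads, \
            f"{lib}: unannotated != known + novel + unassigned"
        ledger[lib] = entry
    with open(out("ledger.json"), "w") as fh:
        json.dump(ledger, fh, indent=2)

    return RunResult(
        reports=reports, tags=tags, classes=classes, category_table=category,
        known=known_list, novel=novel_list, unassigned=unassigned,
        expression=expression, de_summary=de_summary, ledger=ledger,
    )
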