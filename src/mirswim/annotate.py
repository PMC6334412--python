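"""Perfect-match genome mapping and priority-based tag annotation.

Tags are mapped to the genome requiring exact matches on either strand
(multi-locus hits are all reported).  Each tag is then assigned exactly one
annotation class — the highest-priority class among all features overlapping
any of its hits — so a tag overlapping both an rRNA and a repeat is counted
as rRNA.  Exon and intron features split into sense/antisense by strand
agreement between the hit and the feature.  Tags overlapping nothing are
"unannotated" and feed miRNA identification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from intervaltree import IntervalTree

from .preprocess import CleanTag

__all__ = [
    "AnnotationRecord", "GenomeHit", "GenomeIndex", "AnnotationIndex",
    "build_index", "map_tags", "assign_class", "category_summary",
    "DEFAULT_PRIORITY", "FEATURE_CLASSES",
]

# feature classes accepted in annotation inputs
FEATURE_CLASSES = ("rRNA", "tRNA", "scRNA", "snRNA", "snoRNA", "srpRNA",
                   "exon", "intron", "repeat")

# assignment priority, highest first; exon/intron appear stranded
DEFAULT_PRIORITY = (
    "rRNA", "scRNA", "snRNA", "snoRNA", "srpRNA", "tRNA", "repeat",
    "exon_sense", "exon_antisense", "intron_sense", "intron_antisense",
)

UNANNOTATED = "unannotated"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AnnotationRecord:
    """One genomic feature; coordinates 0-based half-open."""

    cls: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.cls not in FEATURE_CLASSES:
            raise ValueError(f"unknown annotation class {self.cls!r}")
        if not self.start < self.end:
            raise ValueError("feature start must be < end")


@dataclass(frozen=True)
class GenomeHit:
    """A perfect alignment of a tag; coordinates 0-based half-open.

    For minus-strand hits the genome substring reverse-complemented equals
    the tag sequence.
    """

    tag_seq: str
    chrom: str
    start: int
    end: int
    strand: str


class GenomeIndex:
    """Exact-substring index over a genome, seeded on 12-mers."""

    SEED = 12

    def __init__(self, chroms: list[tuple[str, str]]):
        names = [n for n, _ in chroms]
        if len(names) != len(set(names)):
            raise ValueError("duplicate chromosome names in genome")
        self.chroms = {n: s.upper() for n, s in chroms}
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        k = self.SEED
        for name, seq in self.chroms.items():
            for i in range(len(seq) - k + 1):
                self._seeds.setdefault(seq[i:i + k], []).append((name, i))

    def _find_exact(self, query: str) -> list[tuple[str, int]]:
        k = self.SEED
        if len(query) < k:
            raise ValueError(f"query shorter than seed length {k}")
        out = []
        for name, i in self._seeds.get(query[:k], []):
            if self.chroms[name][i:i + len(query)] == query:
                out.append((name, i))
        return out

    def search(self, query: str) -> list[GenomeHit]:
        """All perfect hits of ``query`` on both strands."""
        query = query.upper()
        hits = [GenomeHit(query, c, i, i + len(query), "+")
                for c, i in self._find_exact(query)]
        rc = revcomp(query)
        hits += [GenomeHit(query, c, i, i + len(query), "-")
                 for c, i in self._find_exact(rc)]
        hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
        return hits


def build_index(chroms: Iterable[tuple[str, str]]) -> GenomeIndex:
    return GenomeIndex(list(chroms))


def map_tags(
    tags: list[CleanTag], index: GenomeIndex
) -> tuple[dict[str, list[GenomeHit]], dict[str, float]]:
    """Map tags to the genome; returns hits per tag plus mapping summary."""
    hits_by_seq: dict[str, list[GenomeHit]] = {}
    mapped_tags = 0
    mapped_reads = 0
    total_reads = 0
    for t in tags:
        h = index.search(t.seq)
        total_reads += t.total()
        if h:
            hits_by_seq[t.seq] = h
            mapped_tags += 1
            mapped_reads += t.total()
    summary = {
        "total_tags": len(tags),
        "mapped_tags": mapped_tags,
        "total_reads": total_reads,
        "mapped_reads": mapped_reads,
        "tag_fraction": mapped_tags / len(tags) if tags else 0.0,
        "read_fraction": mapped_reads / total_reads if total_reads else 0.0,
    }
    return hits_by_seq, summary


class AnnotationIndex:
    """Interval index over annotation features, per chromosome."""

    def __init__(self, records: Iterable[AnnotationRecord]):
        self._trees: dict[str, IntervalTree] = {}
        for rec in records:
            self._trees.setdefault(rec.chrom, IntervalTree())[rec.start:rec.end] = rec

    def overlapping(self, chrom: str, start: int, end: int) -> list[AnnotationRecord]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


def assign_class(
    hits: list[GenomeHit],
    ann: AnnotationIndex,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> str:
    """Single class for a tag: best priority over all its hits' overlaps."""
    rank = {c: i for i, c in enumerate(priority)}
    best: str | None = None
    for hit in hits:
        for rec in ann.overlapping(hit.chrom, hit.start, hit.end):
            cls = rec.cls
            if cls in ("exon", "intron"):
                cls += "_sense" if rec.strand == hit.strand else "_antisense"
            if cls not in rank:
                raise ValueError(f"class {cls!r} missing from priority order")
            if best is None or rank[cls] < rank[best]:
                best = cls
    return best if best is not None else UNANNOTATED


def classify_all(
    tags: list[CleanTag],
    hits_by_seq: dict[str, list[GenomeHit]],
    ann: AnnotationIndex,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> dict[str, str]:
    """Class per tag sequence; unmapped tags are unannotated."""
    return {
        t.seq: assign_class(hits_by_seq.get(t.seq, []), ann, priority)
        for t in tags
    }


def category_summary(
    tags: list[CleanTag],
    classes: dict[str, str],
    libraries: list[str],
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> pd.DataFrame:
    """Per-class unique/redundant counts and percentages, one pair of
    columns per library, plus a Total row.  Counts partition the totals
    exactly."""
    order = list(priority) + [UNANNOTATED]
    rows = {c: {f"{lib}_{k}": 0 for lib in libraries for k in ("unique", "redundant")}
            for c in order}
    totals = {f"{lib}_{k}": 0 for lib in libraries for k in ("unique", "redundant")}
    for t in tags:
        cls = classes[t.seq]
        for lib in libraries:
            c = t.counts.get(lib, 0)
            if c > 0:
                rows[cls][f"{lib}_unique"] += 1
                rows[cls][f"{lib}_redundant"] += c
                totals[f"{lib}_unique"] += 1
                totals[f"{lib}_redundant"] += c
    records = []
    for cls in order:
        rec: dict[str, object] = {"category": cls}
        for lib in libraries:
            for kind in ("unique", "redundant"):
                n = rows[cls][f"{lib}_{kind}"]
                tot = totals[f"{lib}_{kind}"]
                rec[f"{lib}_{kind}"] = n
                rec[f"{lib}_{kind}_pct"] = 100.0 * n / tot if tot else 0.0
        records.append(rec)
    total_rec: dict[str, object] = {"category": "Total"}
    for lib in libraries:
        for kind in ("unique", "redundant"):
            total_rec[f"{lib}_{kind}"] = totals[f"{lib}_{kind}"]
            total_rec[f"{lib}_{kind}_pct"] = 100.0
    records.append(total_rec)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# BED6 / GFF3 I/O (annotation exchange formats)

def read_bed6(path) -> list[AnnotationRecord]:
    recs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: BED6 needs 6 columns")
            chrom, start, end, name, _score, strand = parts[:6]
            recs.append(AnnotationRecord(name, chrom, int(start), int(end), strand))
    return recs


def write_bed6(records: Iterable[AnnotationRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.cls}\t0\t{r.strand}\n")


def read_gff3(path) -> list[AnnotationRecord]:
    recs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, _src, ftype, start, end, _score, strand = parts[:7]
            recs.append(AnnotationRecord(ftype, chrom, int(start) - 1, int(end), strand))
    return recs


def write_gff3(records: Iterable[AnnotationRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            fh.write(f"{r.chrom}\tmirswim\t{r.cls}\t{r.start + 1}\t{r.end}\t.\t"
                     f"{r.strand}\t.\tID={r.cls}:{r.chrom}:{r.start + 1}\n")


def write_hits_bed6(hits: Iterable[GenomeHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\t{h.tag_seq}\t0\t{h.strand}\n")
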