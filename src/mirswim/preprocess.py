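"""Raw-read filtering, 3' adapter trimming, and unique-tag collapsing.

Small-RNA libraries are sequenced as insert + 3' adapter; the filtering
cascade removes, in order: low-quality reads, 5'-adapter contaminants, reads
whose 3' adapter cannot be located, adapter-only reads (no insert), polyA
inserts, and inserts outside the 18-30 nt band.  Surviving inserts are
collapsed to unique tags with per-library read counts — the atoms of every
downstream stage.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "RawRead", "CleanTag", "FilterReport", "FILTER_REASONS",
    "read_fastq", "filter_and_trim", "collapse", "merge_libraries",
    "length_distribution", "compare_libraries",
]

FILTER_REASONS = (
    "low_quality",
    "adapter5_contaminant",
    "no_3adapter",
    "no_insert",
    "polyA",
    "too_short",
)

MIN_INSERT = 18
MAX_INSERT = 30

# low-quality definition shared with the simulator: >20% of bases below Q10,
# or any uncalled base
LOW_QUAL_PHRED = 10
LOW_QUAL_FRACTION = 0.20
POLYA_FRACTION = 0.90

# 3' adapter search: >=6 nt exact prefix; 1 mismatch tolerated for >=10 nt
ADAPTER_MIN_OVERLAP = 6
ADAPTER_MM_OVERLAP = 10


@dataclass
class RawRead:
    id: str
    seq: str
    qual: str  # Phred+33 encoded, same length as seq


@dataclass
class CleanTag:
    """A unique 18-30 nt insert with read counts per library."""

    seq: str
    counts: dict[str, int] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class FilterReport:
    raw_reads: int
    dropped: dict[str, int]
    clean_reads: int
    unique_tags: int

    def conserves(self) -> bool:
        return self.raw_reads == self.clean_reads + sum(self.dropped.values())


def read_fastq(path) -> Iterator[RawRead]:
    """Stream a FASTQ file (plain or .gz) as RawRead records."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        try:
            for rid, seq, qual in FastqGeneralIterator(fh):
                yield RawRead(rid, seq.upper().replace("U", "T"), qual)
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ in {path}: {exc}") from exc


def _is_low_quality(seq: str, qual: str) -> bool:
    if "N" in seq:
        return True
    low = sum(1 for c in qual if ord(c) - 33 < LOW_QUAL_PHRED)
    return low > LOW_QUAL_FRACTION * len(qual)


def find_adapter3(seq: str, adapter3: str) -> int | None:
    """Leftmost position where a prefix of the 3' adapter starts in ``seq``.

    Requires at least 6 matching nt; one mismatch is tolerated when the
    overlap is 10 nt or longer.  Returns None when no acceptable match.
    """
    n = len(seq)
    for i in range(0, n - ADAPTER_MIN_OVERLAP + 1):
        overlap = min(len(adapter3), n - i)
        if overlap < ADAPTER_MIN_OVERLAP:
            break
        mm = sum(1 for a, b in zip(seq[i:i + overlap], adapter3[:overlap]) if a != b)
        allowed = 1 if overlap >= ADAPTER_MM_OVERLAP else 0
        if mm <= allowed:
            return i
    return None


def _starts_with_adapter5(seq: str, adapter5: str) -> bool:
    k = min(len(adapter5), 10)
    return seq[:k] == adapter5[:k]


def filter_and_trim(
    reads: Iterable[RawRead],
    adapter3: str,
    adapter5: str,
) -> tuple[list[str], FilterReport]:
    """Run the filtering cascade over one library's raw reads.

    Returns the surviving inserts (in input order, one entry per read) and a
    FilterReport whose drop reasons partition the input exactly.
    """
    if not adapter3 or not adapter5:
        raise ValueError("adapters must be non-empty")
    dropped = {reason: 0 for reason in FILTER_REASONS}
    inserts: list[str] = []
    raw = 0
    for read in reads:
        raw += 1
        seq, qual = read.seq, read.qual
        if len(seq) != len(qual):
            raise ValueError(f"malformed FASTQ record {read.id!r}: seq/qual length mismatch")
        if _is_low_quality(seq, qual):
            dropped["low_quality"] += 1
            continue
        if _starts_with_adapter5(seq, adapter5):
            dropped["adapter5_contaminant"] += 1
            continue
        pos = find_adapter3(seq, adapter3)
        if pos is None:
            dropped["no_3adapter"] += 1
            continue
        if pos == 0:
            dropped["no_insert"] += 1
            continue
        insert = seq[:pos]
        if insert.count("A") >= POLYA_FRACTION * len(insert):
            dropped["polyA"] += 1
            continue
        if not MIN_INSERT <= len(insert) <= MAX_INSERT:
            dropped["too_short"] += 1
            continue
        inserts.append(insert)
    report = FilterReport(
        raw_reads=raw,
        dropped=dropped,
        clean_reads=len(inserts),
        unique_tags=len(set(inserts)),
    )
    assert report.conserves(), "filter report does not conserve read counts"
    return inserts, report


def collapse(inserts: Iterable[str], library: str) -> list[CleanTag]:
    """Collapse one library's inserts to unique tags with counts.

    Output is sorted by count (descending), then sequence, so repeated runs
    are byte-identical.
    """
    counter = Counter(inserts)
    tags = [CleanTag(seq=s, counts={library: c}) for s, c in counter.items()]
    tags.sort(key=lambda t: (-t.counts[library], t.seq))
    return tags


def merge_libraries(*tag_lists: list[CleanTag]) -> list[CleanTag]:
    """Merge per-library tag lists into one list with per-library counts."""
    merged: dict[str, CleanTag] = {}
    for tags in tag_lists:
        for t in tags:
            if t.seq not in merged:
                merged[t.seq] = CleanTag(seq=t.seq, counts={})
            for lib, c in t.counts.items():
                merged[t.seq].counts[lib] = merged[t.seq].counts.get(lib, 0) + c
    out = list(merged.values())
    out.sort(key=lambda t: (-t.total(), t.seq))
    return out


def length_distribution(
    tags: list[CleanTag], library: str | None = None
) -> dict[int, tuple[int, float]]:
    """Read-count-weighted length distribution: length -> (count, fraction)."""
    counts: Counter[int] = Counter()
    for t in tags:
        c = t.counts.get(library, 0) if library else t.total()
        if c:
            counts[len(t.seq)] += c
    total = sum(counts.values())
    if total == 0:
        return {}
    return {ln: (c, c / total) for ln, c in sorted(counts.items())}


def compare_libraries(
    tags_a: list[CleanTag], tags_b: list[CleanTag]
) -> dict[str, dict[str, float]]:
    """Partition the tag union into common / A-specific / B-specific.

    Unique fractions are over the union of unique tags; read fractions over
    the two libraries' summed read counts.
    """
    a = {t.seq: t.total() for t in tags_a}
    b = {t.seq: t.total() for t in tags_b}
    union = set(a) | set(b)
    n_union = len(union)
    reads_total = sum(a.values()) + sum(b.values())
    parts = {
        "common": [s for s in union if s in a and s in b],
        "A_specific": [s for s in union if s in a and s not in b],
        "B_specific": [s for s in union if s not in a and s in b],
    }
    out = {}
    for name, seqs in parts.items():
        reads = sum(a.get(s, 0) + b.get(s, 0) for s in seqs)
        out[name] = {
            "unique_tags": len(seqs),
            "unique_fraction": len(seqs) / n_union if n_union else 0.0,
            "read_count": reads,
            "read_fraction": reads / reads_total if reads_total else 0.0,
        }
    return out


def write_tags_tsv(tags: list[CleanTag], path, libraries: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("seq\t" + "\t".join(libraries) + "\n")
        for t in tags:
            fh.write(t.seq + "\t" + "\t".join(str(t.counts.get(l, 0)) for l in libraries) + "\n")


def read_tags_tsv(path) -> list[CleanTag]:
    tags = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        libs = header[1:]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            counts = {l: int(c) for l, c in zip(libs, parts[1:]) if int(c) > 0}
            tags.append(CleanTag(seq=parts[0], counts=counts))
    return tags
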