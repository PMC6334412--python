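"""Known-miRNA identification against a mature-miRNA reference.

Unannotated tags are matched against a miRBase-style multi-species mature
reference.  A tag matches a reference mature when the overlapping region is
identical and each terminus differs by at most 2 nt (isomiR tolerance:
shifts/extensions, no internal mismatches).  Same-species entries take
precedence for naming; ties break on fewest terminal shifts, then name.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import SeqIO

from .preprocess import CleanTag

__all__ = [
    "KnownMiRNA", "load_mature_fasta", "load_family_tsv", "match_known",
    "family_rollup", "shared_specific", "family_from_name",
]

MAX_TERMINAL_SHIFT = 2


@dataclass
class ReferenceEntry:
    name: str        # e.g. rno-miR-182
    species: str     # 3-letter code parsed from the name
    mature_seq: str  # DNA alphabet


@dataclass
class KnownMiRNA:
    name: str
    family: str
    species: str
    mature_seq: str
    counts: dict[str, int] = field(default_factory=dict)
    orthologs: list[str] = field(default_factory=list)
    matched_tags: list[str] = field(default_factory=list)

    def total(self) -> int:
        return sum(self.counts.values())


def load_mature_fasta(path) -> list[ReferenceEntry]:
    """Parse a mature reference FASTA with `>spe-miR-name` headers."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        species = name.split("-", 1)[0] if "-" in name else ""
        seq = str(rec.seq).upper().replace("U", "T")
        entries.append(ReferenceEntry(name=name, species=species, mature_seq=seq))
    if not entries:
        raise ValueError(f"empty mature reference: {path}")
    return entries


def load_family_tsv(path) -> dict[str, str]:
    fam = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            name, family = line.rstrip("\n").split("\t")[:2]
            fam[name] = family
    return fam


def _terminal_shift(tag: str, mature: str) -> int | None:
    """Smallest |5' shift| + |3' shift| aligning tag on mature, or None.

    The tag start may sit up to 2 nt before/after the mature start, the tag
    end up to 2 nt before/after the mature end, and every overlapping
    position must be identical.
    """
    best: int | None = None
    for a in range(-MAX_TERMINAL_SHIFT, MAX_TERMINAL_SHIFT + 1):
        end_diff = (a + len(tag)) - len(mature)
        if abs(end_diff) > MAX_TERMINAL_SHIFT:
            continue
        t0 = max(0, -a)           # first tag index overlapping the mature
        m0 = max(0, a)            # corresponding mature index
        ov = min(len(tag) - t0, len(mature) - m0)
        if ov <= 0:
            continue
        if tag[t0:t0 + ov] == mature[m0:m0 + ov]:
            score = abs(a) + abs(end_diff)
            if best is None or score < best:
                best = score
    return best


def match_known(
    tags: list[CleanTag],
    reference: list[ReferenceEntry],
    family_map: dict[str, str] | None = None,
    native_species: str = "rno",
) -> tuple[list[KnownMiRNA], list[CleanTag]]:
    """Assign unannotated tags to known miRNAs; return (known, unmatched).

    Each tag goes to at most one reference entry (native species first, then
    fewest terminal shifts, then lexicographic name); counts of all matching
    tags accumulate on that entry.  Read counts are conserved: known +
    unmatched totals equal the input totals.
    """
    if not reference:
        raise ValueError("empty mature reference")
    by_mature: dict[str, list[ReferenceEntry]] = {}
    for e in reference:
        by_mature.setdefault(e.mature_seq, []).append(e)

    known: dict[str, KnownMiRNA] = {}
    unmatched: list[CleanTag] = []
    for tag in tags:
        candidates: list[tuple[int, int, str, ReferenceEntry]] = []
        for entry in reference:
            shift = _terminal_shift(tag.seq, entry.mature_seq)
            if shift is not None:
                foreign = 0 if entry.species == native_species else 1
                candidates.append((foreign, shift, entry.name, entry))
        if not candidates:
            unmatched.append(tag)
            continue
        candidates.sort(key=lambda c: c[:3])
        entry = candidates[0][3]
        if entry.name not in known:
            fam = (family_map or {}).get(entry.name) or family_from_name(entry.name)
            orthologs = sorted({e.species for e in by_mature.get(entry.mature_seq, [])
                                if e.species != entry.species})
            known[entry.name] = KnownMiRNA(
                name=entry.name, family=fam, species=entry.species,
                mature_seq=entry.mature_seq, orthologs=orthologs,
            )
        rec = known[entry.name]
        rec.matched_tags.append(tag.seq)
        for lib, c in tag.counts.items():
            rec.counts[lib] = rec.counts.get(lib, 0) + c
    out = sorted(known.values(), key=lambda k: (-k.total(), k.name))
    return out, unmatched


_FAMILY_RE = re.compile(
    r"^(?:[a-z]{3,4}-)?(let|lin|mir|miR)-?(\d+)", re.IGNORECASE
)


def family_from_name(name: str) -> str:
    """Fallback family: strip species prefix, arm suffix and letter variants.

    let-7c -> let-7; rno-miR-200a-5p -> mir-200; unparseable names are their
    own family.
    """
    m = _FAMILY_RE.match(name)
    if not m:
        return name
    return f"{m.group(1).lower()}-{m.group(2)}"


def family_rollup(known: list[KnownMiRNA]) -> dict[str, dict[str, object]]:
    """family -> member count and summed expression (totals conserved)."""
    out: dict[str, dict[str, object]] = {}
    for k in known:
        fam = out.setdefault(k.family, {"members": 0, "total_reads": 0, "names": []})
        fam["members"] += 1
        fam["total_reads"] += k.total()
        fam["names"].append(k.name)
    return out


def shared_specific(
    known: list[KnownMiRNA], lib_a: str, lib_b: str, native_species: str = "rno"
) -> dict[str, int]:
    """Venn counts of co-expressed / library-specific known miRNAs, with the
    native-species (e.g. rno-matched) subsets."""
    co = a_only = b_only = 0
    co_native = a_native = b_native = 0
    for k in known:
        in_a = k.counts.get(lib_a, 0) > 0
        in_b = k.counts.get(lib_b, 0) > 0
        native = k.species == native_species
        if in_a and in_b:
            co += 1
            co_native += native
        elif in_a:
            a_only += 1
            a_native += native
        elif in_b:
            b_only += 1
            b_native += native
    return {
        "co_expressed": co, f"{lib_a}_only": a_only, f"{lib_b}_only": b_only,
        "co_expressed_native": co_native,
        f"{lib_a}_only_native": a_native, f"{lib_b}_only_native": b_native,
    }
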