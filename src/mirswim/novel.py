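"""Novel miRNA prediction from unassigned tags.

Each perfectly mapped tag seeds two candidate precursor windows (the tag may
sit on the 5' or the 3' arm of its hairpin).  Windows are folded with the
single-hairpin MFE model, trimmed to the folded stem, refolded, and the
mature/star duplex geometry is read off the structure with the canonical
2-nt 3' overhang convention.  A candidate becomes a novel miRNA when it
passes all six acceptance criteria:

  c1  stable stem-loop: MFE <= -25.0 kcal/mol and MFEI >= 0.85
  c2  the mature lies entirely on one arm of the hairpin
  c3  the mature/star duplex forms with 2-nt 3' overhangs inside the precursor
  c4  at most 4 mismatched mature bases within the duplex
  c5  at most one internal loop or bulge in the duplex, no larger than 1 nt
  c6  at least 5 reads supporting the mature (over the merged mature)

where MFEI = (-MFE * 100 / precursor_length) / (GC% ), the adjusted MFE per
GC percentage that separates miRNA hairpins from other structured RNAs.
Identical matures predicted at several loci merge into one miRNA listing all
loci; read counts are counted once per library, never per locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotate import GenomeHit, revcomp
from .fold import FoldResult, fold_hairpin
from .preprocess import CleanTag

__all__ = [
    "DuplexGeometry", "HairpinCandidate", "NovelMiRNA", "CriteriaThresholds",
    "extract_candidates", "locate_duplex", "compute_mfei",
    "evaluate_criteria", "merge_multilocus", "discover_novel",
]

DEFAULT_L_UP = 20
DEFAULT_L_DOWN = 160

# longest stem-loop reported as a precursor; windows fold as a whole, then
# the candidate is trimmed to a bounded hairpin subunit containing the tag
MAX_PRECURSOR_SPAN = 120


@dataclass(frozen=True)
class CriteriaThresholds:
    mfe_max: float = -25.0       # kcal/mol, pass when mfe <= this
    mfei_min: float = 0.85
    max_mismatches: int = 4
    max_loop_features: int = 1   # internal loops + bulges in the duplex
    max_loop_size: int = 1       # nt per feature ("less than 2 bases")
    min_count: int = 5


@dataclass
class DuplexGeometry:
    star_start: int          # precursor coords, 0-based inclusive
    star_end: int            # 0-based inclusive
    mature_arm: str          # 5p | 3p
    mismatches: int
    n_loop_features: int
    max_loop_size: int
    reject_reason: str | None = None


@dataclass
class PrecursorWindow:
    """A genomic window in precursor orientation (strand applied)."""

    chrom: str
    start: int               # genome coords, 0-based half-open
    end: int
    strand: str
    seq: str                 # oriented 5'->3' on `strand`
    mature_offset: int       # tag start within `seq`
    mature_len: int
    arm_guess: str           # which arm the window design puts the tag on


@dataclass
class HairpinCandidate:
    precursor_seq: str
    chrom: str
    start: int               # genome coords, 1-based inclusive
    end: int
    strand: str
    fold: FoldResult
    mature_seq: str
    star_seq: str
    mature_arm: str
    mfe: float
    mfei: float
    gc_fraction: float
    read_count: int
    criteria: dict[str, bool] = field(default_factory=dict)

    @property
    def accepted(self) -> bool:
        return bool(self.criteria) and all(self.criteria.values())

    @property
    def locus(self) -> str:
        return f"{self.chrom}:{self.start}:{self.end}:{self.strand}"


@dataclass
class NovelMiRNA:
    name: str
    mature_seq: str
    loci: list[HairpinCandidate]
    counts: dict[str, int] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.counts.values())


# flank extents tried on the loop-distal side of the tag; the largest equals
# the full flanking window, the shorter ones keep a compact hairpin's fold
# from being swamped by spurious structure in long random flanks
FLANK_LADDER = (50, 70, 90, 110, 130, DEFAULT_L_DOWN)


def extract_candidates(
    hit: GenomeHit,
    chrom_seq: str,
    l_up: int = DEFAULT_L_UP,
    l_down: int = DEFAULT_L_DOWN,
) -> list[PrecursorWindow]:
    """Candidate precursor windows around one genomic hit.

    The tag may sit on either arm of its hairpin, so windows leave l_up nt
    on the loop-proximal side and up to l_down nt on the loop-distal side
    (in precursor orientation), in both orientations.  A ladder of distal
    extents is tried because the minimum-energy structure of a long window
    is typically dominated by diffuse pairing of the flanks rather than by
    a compact stem-loop.  Windows are clipped at chromosome ends and
    deduplicated.
    """
    n = len(chrom_seq)
    if hit.start < 0 or hit.end > n:
        raise ValueError(f"hit {hit} beyond chromosome bounds (len {n})")
    ladder = [d for d in FLANK_LADDER if d <= l_down] or [l_down]
    if ladder[-1] != l_down:
        ladder.append(l_down)
    windows = []
    seen = set()
    for arm in ("5p", "3p"):
        for down in ladder:
            up = l_up
            if arm == "3p":
                up, down = down, up
            if hit.strand == "+":
                ws = max(0, hit.start - up)
                we = min(n, hit.end + down)
                seq = chrom_seq[ws:we]
                offset = hit.start - ws
            else:
                # upstream in precursor orientation = downstream in genome
                ws = max(0, hit.start - down)
                we = min(n, hit.end + up)
                seq = revcomp(chrom_seq[ws:we])
                offset = we - hit.end
            if (ws, we) in seen:
                continue
            seen.add((ws, we))
            windows.append(PrecursorWindow(
                chrom=hit.chrom, start=ws, end=we, strand=hit.strand,
                seq=seq, mature_offset=offset, mature_len=hit.end - hit.start,
                arm_guess=arm,
            ))
    return windows


def locate_duplex(fold: FoldResult, mat_a: int, mat_b: int) -> DuplexGeometry:
    """Duplex geometry of a mature spanning precursor positions [mat_a, mat_b].

    The star is the strand pairing the mature, shifted to leave 2-nt 3'
    overhangs on both strands.  Mismatches are unpaired mature bases within
    the duplex span (the 2-nt mature 3' overhang excluded); loop features
    are gaps between consecutive paired mature bases, with 1x1 gaps counted
    as mismatches rather than loops.
    """
    partner = fold.partner
    paired = [i for i in range(mat_a, mat_b + 1) if i in partner]
    if len(paired) < 2:
        return DuplexGeometry(-1, -1, "", 0, 0, 0, reject_reason="mature unpaired")
    partners = [partner[i] for i in paired]
    if all(p > mat_b for p in partners):
        arm = "5p"
    elif all(p < mat_a for p in partners):
        arm = "3p"
    else:
        return DuplexGeometry(-1, -1, "", 0, 0, 0,
                              reject_reason="mature spans the terminal loop")
    first = paired[0]                     # 5'-most paired mature base
    anchors = [i for i in paired if i <= mat_b - 2]
    if not anchors:
        return DuplexGeometry(-1, -1, "", 0, 0, 0,
                              reject_reason="mature 3' end unpaired beyond overhang")
    last = anchors[-1]                    # 3'-most paired base within duplex span

    # star span from the 2-nt 3' overhang convention, anchored on the
    # outermost paired mature bases (unpaired termini are not extrapolated
    # across: they have no defined pairing partner)
    ends = (partner[last], partner[first] + 2)
    star_lo, star_hi = min(ends), max(ends)

    mismatches = sum(1 for i in range(mat_a, mat_b - 1) if i not in partner)

    n_features = 0
    max_size = 0
    for i, j in zip(paired, paired[1:]):
        if j > mat_b - 2 and i >= mat_b - 2:
            continue
        m_gap = j - i - 1
        s_gap = abs(partner[i] - partner[j]) - 1
        if m_gap == 0 and s_gap == 0:
            continue
        if m_gap == s_gap == 1:
            continue  # 1x1 mismatch, already counted above
        n_features += 1
        size = max(m_gap, s_gap)
        if m_gap == s_gap:
            size = m_gap  # symmetric internal loop: per-strand size
        max_size = max(max_size, size)

    return DuplexGeometry(
        star_start=star_lo, star_end=star_hi, mature_arm=arm,
        mismatches=mismatches, n_loop_features=n_features, max_loop_size=max_size,
    )


def compute_mfei(mfe: float, length: int, gc_fraction: float) -> float:
    """MFEI = AMFE / GC% where AMFE = -MFE * 100 / length."""
    if length <= 0:
        raise ValueError("length must be positive")
    if mfe > 0:
        raise ValueError("mfe must be <= 0")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be strictly between 0 and 1")
    amfe = -mfe * 100.0 / length
    return amfe / (gc_fraction * 100.0)


def evaluate_criteria(
    cand: HairpinCandidate,
    geometry: DuplexGeometry,
    thresholds: CriteriaThresholds = CriteriaThresholds(),
) -> dict[str, bool]:
    """Six pass/fail verdicts; the candidate is accepted iff all pass."""
    th = thresholds
    ok_duplex = geometry.reject_reason is None
    on_one_arm = ok_duplex and geometry.mature_arm in ("5p", "3p")
    star_inside = ok_duplex and geometry.star_start >= 0 and \
        geometry.star_end < len(cand.precursor_seq)
    return {
        "c1_stable_hairpin": cand.mfe <= th.mfe_max and cand.mfei >= th.mfei_min,
        "c2_mature_on_one_arm": on_one_arm,
        "c3_duplex_2nt_overhang": star_inside,
        "c4_mismatches": ok_duplex and geometry.mismatches <= th.max_mismatches,
        "c5_loops": ok_duplex
        and geometry.n_loop_features <= th.max_loop_features
        and geometry.max_loop_size <= th.max_loop_size,
        "c6_read_count": cand.read_count >= th.min_count,
    }


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def build_candidate(
    window: PrecursorWindow,
    read_count: int,
    thresholds: CriteriaThresholds = CriteriaThresholds(),
) -> HairpinCandidate | None:
    """Fold a window, trim to the stem, and evaluate the six criteria.

    Returns None when the window does not fold at all.
    """
    fold0 = fold_hairpin(window.seq)
    mat_a = window.mature_offset
    mat_b = mat_a + window.mature_len - 1
    if not fold0.pairs:
        return None
    # trim to a bounded stem-loop subunit: the outermost pair of the fold
    # chain that still contains the mature and spans at most
    # MAX_PRECURSOR_SPAN nt (long-range pairing across the window would
    # otherwise dilute the precursor), plus 2 nt of context for the star's
    # 3' overhang; refold so MFE/MFEI refer to the reported precursor
    oi, oj = fold0.pairs[0]
    for i, j in fold0.pairs:
        if i <= mat_a and j >= mat_b and (j - i + 1) <= MAX_PRECURSOR_SPAN:
            oi, oj = i, j
            break
    lo = max(0, min(oi, mat_a) - 2)
    hi = min(len(window.seq) - 1, max(oj, mat_b) + 2)
    pre = window.seq[lo:hi + 1]
    if len(pre) < 8:
        return None
    fold = fold_hairpin(pre)
    pm_a, pm_b = mat_a - lo, mat_b - lo
    geometry = locate_duplex(fold, pm_a, pm_b)
    gc = _gc_fraction(pre)
    mfe = fold.mfe
    mfei = compute_mfei(mfe, len(pre), gc) if 0 < gc < 1 and mfe <= 0 else 0.0
    # genome coordinates of the trimmed precursor, 1-based inclusive
    if window.strand == "+":
        g_start = window.start + lo + 1
        g_end = window.start + hi + 1
    else:
        g_start = window.end - hi
        g_end = window.end - lo
    mature = pre[pm_a:pm_b + 1]
    star = ""
    if geometry.reject_reason is None:
        s0 = max(0, geometry.star_start)
        s1 = min(len(pre) - 1, geometry.star_end)
        star = pre[s0:s1 + 1]
    cand = HairpinCandidate(
        precursor_seq=pre, chrom=window.chrom, start=g_start, end=g_end,
        strand=window.strand, fold=fold, mature_seq=mature, star_seq=star,
        mature_arm=geometry.mature_arm or window.arm_guess,
        mfe=mfe, mfei=mfei, gc_fraction=gc, read_count=read_count,
    )
    cand.criteria = evaluate_criteria(cand, geometry, thresholds)
    return cand


def best_candidate_for_hit(
    hit: GenomeHit,
    chrom_seq: str,
    read_count: int,
    thresholds: CriteriaThresholds = CriteriaThresholds(),
    l_up: int = DEFAULT_L_UP,
    l_down: int = DEFAULT_L_DOWN,
) -> HairpinCandidate | None:
    """The better of the two windows for one hit: accepted beats rejected,
    then lower MFE; exact ties keep the 5p window."""
    best = None
    for window in extract_candidates(hit, chrom_seq, l_up, l_down):
        cand = build_candidate(window, read_count, thresholds)
        if cand is None:
            continue
        if best is None:
            best = cand
        elif (cand.accepted, -cand.mfe) > (best.accepted, -best.mfe):
            best = cand
    return best


def merge_multilocus(accepted: list[HairpinCandidate],
                     counts_by_seq: dict[str, dict[str, int]]) -> list[NovelMiRNA]:
    """Merge accepted candidates sharing a mature sequence into one miRNA.

    Loci are listed per candidate; per-library counts come from the tag once
    (never multiplied by locus number).  Names follow discovery order after
    sorting by total count descending: rno-miR-nNNN_5p/3p.
    """
    by_mature: dict[str, list[HairpinCandidate]] = {}
    for c in accepted:
        by_mature.setdefault(c.mature_seq, []).append(c)
    merged = []
    for mature, cands in by_mature.items():
        cands.sort(key=lambda c: (c.chrom, c.start, c.strand))
        counts = dict(counts_by_seq.get(mature, {}))
        merged.append((mature, cands, counts))
    merged.sort(key=lambda m: (-sum(m[2].values()), m[0]))
    out = []
    for idx, (mature, cands, counts) in enumerate(merged, start=1):
        arm = cands[0].mature_arm or "5p"
        out.append(NovelMiRNA(
            name=f"rno-miR-n{idx:03d}_{arm}",
            mature_seq=mature, loci=cands, counts=counts,
        ))
    return out


def discover_novel(
    tags: list[CleanTag],
    hits_by_seq: dict[str, list[GenomeHit]],
    chroms: dict[str, str],
    thresholds: CriteriaThresholds = CriteriaThresholds(),
    l_up: int = DEFAULT_L_UP,
    l_down: int = DEFAULT_L_DOWN,
) -> tuple[list[NovelMiRNA], list[HairpinCandidate], list[CleanTag]]:
    """Full novel-miRNA stage over the tags left after known matching.

    Count criterion (c6) is applied on the merged mature's total count, so a
    mature spread over multiple loci is judged once.  Returns (novel,
    all candidates, unassigned tags).
    """
    candidates: list[HairpinCandidate] = []
    for tag in tags:
        for hit in hits_by_seq.get(tag.seq, []):
            cand = best_candidate_for_hit(
                hit, chroms[hit.chrom], tag.total(), thresholds, l_up, l_down)
            if cand is not None:
                candidates.append(cand)
    accepted = [c for c in candidates if c.accepted]
    counts_by_seq = {t.seq: t.counts for t in tags}
    novel = merge_multilocus(accepted, counts_by_seq)
    assigned = {n.mature_seq for n in novel}
    unassigned = [t for t in tags if t.seq not in assigned]
    return novel, candidates, unassigned
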