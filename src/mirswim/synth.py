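"""Synthetic two-library small-RNA study generator.

Builds a synthetic genome with planted miRNA hairpin loci (known and novel,
including an 11-copy clustered mature), non-miRNA annotation features for
every classification category, a miRBase-style multi-species mature
reference, and two FASTQ libraries ("HIST" and "NC") with planted
per-condition abundances, fold changes (including condition-specific
expression) and contaminant reads of every filter class.  Every planted
hairpin is labelled with the six-criteria verdict obtained by folding its
designed precursor with the package's own hairpin engine, so recovery tests
can compare pipeline output against ground truth exactly.

Hairpin loci are flanked by 12-nt A/C-only buffer sequence.  A and C cannot
pair with each other, and the folding model bridges loops of at most 10 nt
per strand, so the buffers guarantee that the folded stem of an extracted
candidate window is exactly the designed precursor — planted geometry is
never perturbed by random flanking sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .annotate import AnnotationRecord, revcomp
from .fold import fold_hairpin
from .known import family_from_name
from .novel import (CriteriaThresholds, HairpinCandidate, compute_mfei,
                    evaluate_criteria, locate_duplex)

__all__ = [
    "SyntheticConfig", "PlantedTruth", "SyntheticBundle",
    "build_genome", "simulate_library", "write_bundle", "sample_counts",
]

LIB_A = "HIST"
LIB_B = "NC"

BUFFER_LEN = 12  # A/C-only inert flank around planted hairpins

# Solexa-era small-RNA adapters
DEFAULT_ADAPTER3 = "TCGTATGCCGTCTTCTGCTTG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"


@dataclass
class SyntheticConfig:
    genome_length: int = 120_000
    n_chromosomes: int = 4
    n_known_mirna_loci: int = 10
    n_novel_hairpin_loci: int = 8
    n_fail_hairpin_loci: int = 4
    n_multicopy_loci: int = 11
    ncrna_class_counts: dict[str, int] = field(default_factory=lambda: {
        "rRNA": 2, "tRNA": 2, "scRNA": 1, "snRNA": 1, "snoRNA": 1,
        "srpRNA": 1, "exon": 2, "intron": 2, "repeat": 2,
    })
    reads_per_library: int = 30_000
    read_length: int = 36
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    contaminant_fractions: dict[str, float] = field(default_factory=lambda: {
        "low_quality": 0.02, "no_3adapter": 0.03, "adapter_dimer": 0.01,
        "polyA": 0.01, "short_insert": 0.01,
    })
    # locus_id -> (base_abundance, log2fc, condition_specific); None = built in
    fold_change_map: dict[str, tuple[float, float, bool]] | None = None
    conditions: tuple[str, str] = (LIB_A, LIB_B)
    deterministic_counts: bool = False
    isomir_fraction: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if sum(self.contaminant_fractions.values()) >= 1.0:
            raise ValueError("contaminant fractions must sum to < 1")
        if self.genome_length < 2_000 * self.n_chromosomes:
            raise ValueError("genome too short for requested chromosome count")


@dataclass
class PlantedTruth:
    """Ground truth for one planted locus (coordinates 1-based inclusive)."""

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    mature_seq: str
    star_seq: str
    is_known: bool
    expected_counts: dict[str, int]
    expected_log2fc: float
    kind: str                      # known | novel | novel_fail | ncrna:<cls>
    criteria_pass: bool | None = None
    criteria: dict[str, bool] = field(default_factory=dict)
    n_mismatches: int = 0
    n_bulges: int = 0
    name: str = ""                 # reference name for known loci
    condition_specific: bool = False
    iso_ext_seq: str = ""          # mature + 1 genomic 3' nt (isomiR reads)


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    genome: dict[str, str]
    truth: list[PlantedTruth]
    annotation: list[AnnotationRecord]
    reference: list[tuple[str, str]]       # (name, mature DNA seq)
    family_map: dict[str, str]


# ---------------------------------------------------------------------------
# hairpin design

def _random_seq(rng, n: int, gc: float = 0.42) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _exact_gc_seq(rng, n: int, gc: float) -> str:
    """Random sequence with exactly round(gc*n) G/C bases (shuffled).

    Planted stems need a tight GC band: too AU-rich misses the MFE
    threshold, too GC-rich deflates MFEI (GC% is its denominator).
    """
    n_gc = int(round(gc * n))
    bases = [str(rng.choice(["G", "C"])) for _ in range(n_gc)]
    bases += [str(rng.choice(["A", "T"])) for _ in range(n - n_gc)]
    rng.shuffle(bases)
    return "".join(bases)


def _design_hairpin(
    rng,
    stem_len: int = 22,
    loop_len: int = 13,
    gc: float = 0.58,
    n_mismatches: int = 0,
    n_bulges: int = 0,
    mature_arm: str = "5p",
    mature: str | None = None,
    weak: bool = False,
) -> tuple[str, str, int]:
    """Design one hairpin core; returns (core_seq, mature_seq, mature_offset).

    The core is mature + loop + modified reverse complement (or its 3p
    mirror) plus 2 nt of designed 3'-side context so the star's 2-nt
    overhang is well defined.  Mismatches replace the pairing partner with
    the identical base (which cannot pair, wobble included); a bulge inserts
    one extra nt into the star arm.  ``weak`` designs an AU-only short stem
    that cannot reach the MFE threshold.
    """
    if mature is None:
        if weak:
            mature = "".join(rng.choice(["A", "T"], size=stem_len, p=[0.5, 0.5]))
            while mature.count("A") >= 0.8 * len(mature):
                mature = "".join(rng.choice(["A", "T"], size=stem_len))
        else:
            mature = _exact_gc_seq(rng, stem_len, gc)
            while mature.count("A") >= 0.8 * len(mature):
                mature = _exact_gc_seq(rng, stem_len, gc)
    stem_len = len(mature)
    star = list(revcomp(mature))
    modified: set[int] = set()  # mature-side positions already perturbed

    def far_from_modified(i: int, dist: int = 3) -> bool:
        return all(abs(i - m) >= dist for m in modified)

    if n_mismatches:
        # maximally separated 1x1 mismatches: nearby ones let the duplex
        # refold into larger loops or slid registers and change the
        # designed geometry
        if n_mismatches <= 3:
            positions = np.linspace(4, stem_len - 6, n_mismatches).round()
        else:
            positions = np.array(list(range(4, stem_len - 5, 2))[:n_mismatches])
        for i in positions:
            star[stem_len - 1 - int(i)] = mature[int(i)]
            modified.add(int(i))
    # plant two G.U wobbles: they pair (so the duplex still has the designed
    # mismatch count) but break the exact reverse-complement identity, so
    # the mature tag cannot spuriously map onto the star arm's strand
    wobbled = 0
    for i in rng.permutation(np.arange(3, stem_len - 3)):
        if wobbled >= 2:
            break
        i = int(i)
        if not far_from_modified(i):
            continue
        j = stem_len - 1 - i
        if mature[i] == "T" and star[j] == "A":
            star[j] = "G"
        elif mature[i] == "G" and star[j] == "C":
            star[j] = "T"
        else:
            continue
        modified.add(i)
        wobbled += 1
    if n_bulges:
        for _ in range(n_bulges):
            for k in rng.permutation(np.arange(5, stem_len - 5)):
                if far_from_modified(stem_len - 1 - int(k)):
                    star.insert(int(k), str(rng.choice(list("ACGT"))))
                    modified.add(stem_len - 1 - int(k))
                    break
    star_arm = "".join(star)
    # A-rich loop: inert (A/C cannot pair) and nearly GC-free, so the loop
    # neither extends the stem nor inflates MFEI's GC denominator
    loop = "".join(rng.choice(["A", "C"], size=loop_len, p=[0.95, 0.05]))
    if mature_arm == "5p":
        core = mature + loop + star_arm
        offset = 0
    else:
        core = star_arm + loop + mature
        offset = len(star_arm) + loop_len
    return core, mature, offset


def _label_hairpin(core: str, mature_offset: int, mature_len: int,
                   read_count: int,
                   thresholds: CriteriaThresholds = CriteriaThresholds(),
                   ) -> tuple[dict[str, bool], str]:
    """Six-criteria verdict and star sequence for a designed precursor."""
    fold = fold_hairpin(core)
    a, b = mature_offset, mature_offset + mature_len - 1
    geom = locate_duplex(fold, a, b)
    gc = (core.count("G") + core.count("C")) / len(core)
    mfei = compute_mfei(fold.mfe, len(core), gc) if 0 < gc < 1 else 0.0
    cand = HairpinCandidate(
        precursor_seq=core, chrom="", start=0, end=0, strand="+",
        fold=fold, mature_seq=core[a:b + 1], star_seq="",
        mature_arm=geom.mature_arm, mfe=fold.mfe, mfei=mfei,
        gc_fraction=gc, read_count=read_count,
    )
    criteria = evaluate_criteria(cand, geom, thresholds)
    star = ""
    if geom.reject_reason is None:
        s0 = max(0, geom.star_start)
        s1 = min(len(core) - 1, geom.star_end)
        star = core[s0:s1 + 1]
    return criteria, star


# ---------------------------------------------------------------------------
# genome assembly

class _Placer:
    """Sequential non-overlapping placement of loci on chromosomes."""

    def __init__(self, rng, chrom_names: list[str], chrom_len: int):
        self.rng = rng
        self.chroms = {n: [] for n in chrom_names}  # (pos, seq) inserts
        self.cursor = {n: 150 for n in chrom_names}
        self.chrom_len = chrom_len
        self.names = chrom_names

    def place(self, seq: str, chrom: str | None = None,
              min_gap: int = 80, max_gap: int = 240) -> tuple[str, int]:
        order = [chrom] if chrom else list(self.rng.permutation(self.names))
        for name in order:
            gap = int(self.rng.integers(min_gap, max_gap))
            pos = self.cursor[name] + gap
            if pos + len(seq) + 150 <= self.chrom_len:
                self.chroms[name].append((pos, seq))
                self.cursor[name] = pos + len(seq)
                return name, pos
        raise ValueError("genome too short to place requested loci")

    def render(self, rng) -> dict[str, str]:
        genome = {}
        for name in self.names:
            backbone = list(_random_seq(rng, self.chrom_len))
            for pos, seq in self.chroms[name]:
                backbone[pos:pos + len(seq)] = list(seq)
            genome[name] = "".join(backbone)
        return genome


def _context_buffers(rng, core: str) -> tuple[str, str]:
    """A/C buffers whose stem-adjacent bases cannot pair the stem termini.

    A pairs only U, C pairs only G, so within the buffer nothing pairs; the
    base touching each end of the designed stem is additionally chosen so it
    cannot pair the terminal stem base either — otherwise the fold can shift
    its register one step into the buffer.
    """
    buf_l = list(rng.choice(["A", "C"], size=BUFFER_LEN))
    buf_r = list(rng.choice(["A", "C"], size=BUFFER_LEN))
    buf_r[0] = "C" if core[0] == "T" else "A"
    buf_l[-1] = "C" if core[-1] == "T" else "A"
    return "".join(buf_l), "".join(buf_r)


_KNOWN_NAMES = [
    "rno-let-7c", "rno-let-7f", "rno-miR-9a-5p", "rno-miR-200a",
    "rno-miR-200b", "rno-miR-141", "rno-miR-182", "rno-miR-96",
    "rno-miR-127", "rno-miR-34c", "rno-miR-379", "rno-miR-26a",
]
_CROSS_SPECIES_NAMES = ["hsa-miR-501", "hsa-miR-502"]


def _abundance(rng, low: float, high: float) -> float:
    return float(np.exp(rng.uniform(math.log(low), math.log(high))))


def _expected_counts(base: float, lfc: float, specific: bool) -> dict[str, int]:
    a = int(round(base * 2 ** (lfc / 2)))
    b = 0 if specific else int(round(base * 2 ** (-lfc / 2)))
    return {LIB_A: a, LIB_B: b}


def build_genome(cfg: SyntheticConfig) -> SyntheticBundle:
    """Assemble genome, truth, annotation and reference from a config.

    Deterministic given cfg.seed: the same config produces byte-identical
    sequence output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chrom_len = cfg.genome_length // cfg.n_chromosomes
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    placer = _Placer(rng, chrom_names, chrom_len)

    truth: list[PlantedTruth] = []
    annotation: list[AnnotationRecord] = []
    reference: list[tuple[str, str]] = []
    family_map: dict[str, str] = {}
    seen_matures: set[str] = set()
    fc_map = cfg.fold_change_map or {}

    def unique_hairpin(**kw):
        for _ in range(20):
            core, mature, off = _design_hairpin(rng, **kw)
            if mature not in seen_matures:
                seen_matures.add(mature)
                return core, mature, off
        raise RuntimeError("could not design a unique mature sequence")

    def plant(locus_id, core, mature, off, *, is_known, kind, base, lfc,
              specific, name="", n_mm=0, n_bulge=0, chrom=None, strand=None):
        if strand is None:
            strand = "+" if rng.random() < 0.67 else "-"
        buf_l, buf_r = _context_buffers(rng, core)
        insert = buf_l + core + buf_r
        if strand == "-":
            insert = revcomp(insert)
        ch, pos = placer.place(insert, chrom)
        core_start0 = pos + BUFFER_LEN if strand == "+" else \
            pos + len(insert) - BUFFER_LEN - len(core)
        counts = _expected_counts(base, lfc, specific)
        # label exactly the precursor the pipeline will trim to: the folded
        # stem plus 2 nt of context on each side (room for the 3' overhang)
        labeled = buf_l[-2:] + core + buf_r[:2]
        criteria, star = _label_hairpin(labeled, off + 2, len(mature),
                                        sum(counts.values()))
        truth.append(PlantedTruth(
            locus_id=locus_id, chrom=ch,
            start=core_start0 - 1, end=core_start0 + len(core) + 2,
            strand=strand, mature_seq=mature, star_seq=star,
            is_known=is_known, expected_counts=counts,
            expected_log2fc=lfc, kind=kind,
            criteria_pass=all(criteria.values()), criteria=criteria,
            n_mismatches=n_mm, n_bulges=n_bulge, name=name,
            condition_specific=specific,
        ))
        return truth[-1]

    # --- known miRNA loci (plus multi-species reference entries) -----------
    n_known = cfg.n_known_mirna_loci
    known_names = _KNOWN_NAMES[:n_known]
    if n_known > len(_KNOWN_NAMES):
        known_names += [f"rno-miR-9{i:02d}" for i in range(n_known - len(_KNOWN_NAMES))]
    # three planted fold-change slots up, three down, the rest flat
    known_lfc = [2.0, 2.0, 2.2, -2.0, -2.0, -2.2] + [0.0] * max(0, n_known - 6)
    for i, name in enumerate(known_names):
        stem = int(rng.choice([20, 21, 22, 22, 22, 23, 24]))
        arm = "5p" if i % 2 == 0 else "3p"
        core, mature, off = unique_hairpin(stem_len=stem, mature_arm=arm)
        base, lfc, specific = fc_map.get(
            f"known:{name}", (_abundance(rng, 100, 3000), known_lfc[i], False))
        rec = plant(f"known:{name}", core, mature, off, is_known=True,
                    kind="known", base=base, lfc=lfc, specific=specific,
                    name=name)
        reference.append((name, mature))
        family_map[name] = None  # filled below
        if i < 2:  # ortholog entries in other species, same mature
            for sp in ("hsa", "mmu"):
                reference.append((f"{sp}-{name.split('-', 1)[1]}", mature))
    # family metadata for half the entries; the rest exercise the fallback
    for j, name in enumerate(list(family_map)):
        if j % 2 == 0:
            family_map[name] = family_from_name(name)
        else:
            family_map.pop(name)
    # cross-species-only entries, planted so tags match hsa references
    for name in _CROSS_SPECIES_NAMES:
        core, mature, off = unique_hairpin(stem_len=22)
        plant(f"known:{name}", core, mature, off, is_known=True, kind="known",
              base=_abundance(rng, 50, 400), lfc=0.0, specific=False, name=name)
        reference.append((name, mature))
    # decoy reference entries never planted
    for i in range(3):
        decoy = _random_seq(rng, 22, gc=0.5)
        reference.append((f"rno-miR-7{i:02d}", decoy))

    # --- novel hairpin loci (criteria-passing designs) ----------------------
    novel_specs = []
    for i in range(cfg.n_novel_hairpin_loci):
        # up to 2 designed mismatches: in this energy model each 1x1
        # mismatch costs several kcal/mol, and deeper-mismatch duplexes do
        # not fold reproducibly into the designed register
        n_mm = [0, 0, 1, 2, 0, 2, 0, 1][i % 8]
        n_bulge = 1 if i % 8 == 4 else 0
        novel_specs.append((n_mm, n_bulge))
    novel_lfc = [0.0, -2.0, 0.0, 0.0] + [0.0] * max(0, cfg.n_novel_hairpin_loci - 4)
    for i, (n_mm, n_bulge) in enumerate(novel_specs):
        # each 1x1 mismatch costs several kcal/mol: multi-mismatch designs
        # get longer, GC-richer stems so they still clear the MFE threshold
        stem = 24 if n_mm >= 2 else int(rng.choice([21, 22, 22, 23]))
        arm = "5p" if i % 3 else "3p"
        core, mature, off = unique_hairpin(
            stem_len=stem, mature_arm=arm, n_mismatches=n_mm, n_bulges=n_bulge,
            gc=0.66 if n_mm >= 2 else (0.62 if n_mm else 0.58))
        specific = i == 2  # one HIST-only novel mature
        base, lfc, spec_flag = fc_map.get(
            f"novel:p{i:02d}",
            (_abundance(rng, 20, 300), 0.0 if specific else novel_lfc[i], specific))
        plant(f"novel:p{i:02d}", core, mature, off, is_known=False,
              kind="novel", base=base, lfc=lfc, specific=spec_flag,
              n_mm=n_mm, n_bulge=n_bulge)

    # --- multicopy cluster: one mature, many near-identical loci ------------
    if cfg.n_multicopy_loci:
        core, mature, off = unique_hairpin(stem_len=22, mature_arm="5p")
        base, lfc, specific = fc_map.get("multicopy", (150.0, 0.0, False))
        cluster_chrom = chrom_names[-1]
        counts = _expected_counts(base, lfc, specific)
        for c in range(cfg.n_multicopy_loci):
            strand = "+" if c == 0 else "-"
            buf_l, buf_r = _context_buffers(rng, core)
            insert = buf_l + core + buf_r
            if strand == "-":
                insert = revcomp(insert)
            # keep copies farther apart than a candidate window (20+160 nt
            # flanks) so near-identical neighbours cannot pair across copies
            ch, pos = placer.place(insert, cluster_chrom,
                                   min_gap=280, max_gap=420)
            core_start0 = pos + BUFFER_LEN
            labeled = buf_l[-2:] + core + buf_r[:2]
            criteria, star = _label_hairpin(labeled, off + 2, len(mature),
                                            sum(counts.values()))
            truth.append(PlantedTruth(
                locus_id=f"multicopy:c{c:02d}", chrom=ch,
                start=core_start0 - 1, end=core_start0 + len(core) + 2,
                strand=strand, mature_seq=mature, star_seq=star,
                is_known=False,
                # counts live on the mature once: attached to copy 0 only
                expected_counts=counts if c == 0 else {LIB_A: 0, LIB_B: 0},
                expected_log2fc=lfc, kind="novel_multicopy",
                criteria_pass=all(criteria.values()), criteria=criteria,
            ))

    # --- designed criteria failures -----------------------------------------
    fail_kinds = ["weak_stem", "many_mismatches", "low_count", "weak_stem"]
    for i in range(cfg.n_fail_hairpin_loci):
        fk = fail_kinds[i % len(fail_kinds)]
        if fk == "weak_stem":
            core, mature, off = unique_hairpin(stem_len=14, loop_len=9, weak=True)
            base = 40.0
        elif fk == "many_mismatches":
            core, mature, off = unique_hairpin(stem_len=22, n_mismatches=6)
            base = 40.0
        else:  # low_count: a fine hairpin below the read-count threshold
            core, mature, off = unique_hairpin(stem_len=22)
            base = 2.0  # 2 reads per library: 4 total, under the 5-read rule
        plant(f"novel_fail:{fk}:{i:02d}", core, mature, off, is_known=False,
              kind=f"novel_fail:{fk}", base=base, lfc=0.0, specific=False)

    # --- non-miRNA annotation features with planted fragment reads ----------
    frag_serial = 0
    for cls, n_feat in cfg.ncrna_class_counts.items():
        for f in range(n_feat):
            feat_len = int(rng.integers(150, 400))
            feat_seq = _random_seq(rng, feat_len, gc=0.45)
            strand = "+" if rng.random() < 0.5 else "-"
            embedded = feat_seq if strand == "+" else revcomp(feat_seq)
            ch, pos = placer.place(embedded)
            annotation.append(AnnotationRecord(cls, ch, pos, pos + feat_len, strand))
            n_frags = 2 + (1 if cls in ("exon", "intron") else 0)
            for k in range(n_frags):
                flen = int(rng.integers(18, 29))
                foff = int(rng.integers(0, feat_len - flen))
                frag = feat_seq[foff:foff + flen]
                antisense = k == 2  # third fragment reads the opposite strand
                read_seq = revcomp(frag) if antisense else frag
                read_strand = strand if not antisense else ("-" if strand == "+" else "+")
                if strand == "+":
                    g0 = pos + foff
                else:
                    g0 = pos + feat_len - foff - flen
                base = _abundance(rng, 30, 250)
                truth.append(PlantedTruth(
                    locus_id=f"ncrna:{cls}:{frag_serial:03d}", chrom=ch,
                    start=g0 + 1, end=g0 + flen,
                    strand=read_strand,
                    mature_seq=read_seq, star_seq="", is_known=False,
                    expected_counts=_expected_counts(base, 0.0, False),
                    expected_log2fc=0.0, kind=f"ncrna:{cls}",
                ))
                frag_serial += 1

    genome = placer.render(rng)

    # fill isomiR extension (mature + next genomic base, 3' side)
    for t in truth:
        if t.kind == "known":
            seq = genome[t.chrom]
            if t.strand == "+":
                mstart = seq.find(t.mature_seq, t.start - 1, t.end + 40)
                if mstart >= 0 and mstart + len(t.mature_seq) < len(seq):
                    t.iso_ext_seq = seq[mstart:mstart + len(t.mature_seq) + 1]
            else:
                rc = revcomp(t.mature_seq)
                mstart = seq.find(rc, max(0, t.start - 40), t.end + 40)
                if mstart > 0:
                    t.iso_ext_seq = revcomp(seq[mstart - 1:mstart + len(rc)])

    # the genome must contain each planted mature on its stated strand
    for t in truth:
        locus = genome[t.chrom][t.start - 1:t.end]
        oriented = locus if t.strand == "+" else revcomp(locus)
        assert t.mature_seq in oriented, f"planting failed for {t.locus_id}"

    return SyntheticBundle(
        config=cfg, genome=genome, truth=truth, annotation=annotation,
        reference=reference, family_map=family_map,
    )


# ---------------------------------------------------------------------------
# read simulation

def _clean_read(insert: str, cfg: SyntheticConfig) -> str:
    read = insert + cfg.adapter3
    if len(read) < cfg.read_length:
        read += "A" * (cfg.read_length - len(read))
    return read[:cfg.read_length]


def _contaminant_read(kind: str, rng, cfg: SyntheticConfig) -> tuple[str, str]:
    L = cfg.read_length
    hi_q = "I" * L
    if kind == "low_quality":
        seq = _clean_read(_random_seq(rng, 22, gc=0.5), cfg)
        qual = list(hi_q)
        bad = rng.choice(L, size=int(0.3 * L), replace=False)
        for b in bad:
            qual[int(b)] = "#"  # Q2
        return seq, "".join(qual)
    if kind == "adapter_dimer":
        seq = (cfg.adapter5 + cfg.adapter3 + "A" * L)[:L]
        return seq, hi_q
    if kind == "no_3adapter":
        from .preprocess import find_adapter3
        while True:
            seq = _random_seq(rng, L, gc=0.5)
            if find_adapter3(seq, cfg.adapter3) is None:
                return seq, hi_q
    if kind == "polyA":
        n = int(rng.integers(20, 25))
        insert = "".join("A" if rng.random() < 0.96 else "G" for _ in range(n))
        return _clean_read(insert, cfg), hi_q
    if kind == "short_insert":
        insert = _random_seq(rng, int(rng.integers(10, 15)), gc=0.5)
        return _clean_read(insert, cfg), hi_q
    raise ValueError(f"unknown contaminant class {kind!r}")


def simulate_library(
    cfg: SyntheticConfig,
    truth: list[PlantedTruth],
    condition: str,
) -> list[tuple[str, str, str]]:
    """One library's FASTQ records as (id, seq, qual) tuples.

    Deterministic mode emits exactly the truth's expected counts per locus
    plus round(fraction x reads_per_library) contaminants of each class.
    Stochastic mode draws a single multinomial of size reads_per_library
    over contaminant classes and loci (loci weighted by expected counts).
    """
    if not truth:
        raise ValueError("truth must be non-empty")
    if condition not in cfg.conditions:
        raise ValueError(f"unknown condition {condition!r}; "
                         f"expected one of {cfg.conditions}")
    rng = np.random.default_rng([cfg.seed, list(cfg.conditions).index(condition)])
    emitters: list[tuple[str, PlantedTruth | str]] = []
    weights: list[float] = []
    for t in truth:
        c = t.expected_counts.get(condition, 0)
        if c > 0:
            emitters.append(("locus", t))
            weights.append(float(c))
    contam = list(cfg.contaminant_fractions.items())

    reads: list[tuple[str, str, str]] = []
    serial = 0

    def emit_locus(t: PlantedTruth, n: int):
        nonlocal serial
        n_iso = 0
        if t.kind == "known" and t.iso_ext_seq:
            n_iso = int(round(cfg.isomir_fraction * n))
        for i in range(n):
            insert = t.iso_ext_seq if i < n_iso else t.mature_seq
            seq = _clean_read(insert, cfg)
            reads.append((f"{condition}.{serial}", seq, "I" * len(seq)))
            serial += 1

    def emit_contaminant(kind: str, n: int):
        nonlocal serial
        for _ in range(n):
            seq, qual = _contaminant_read(kind, rng, cfg)
            reads.append((f"{condition}.{serial}", seq, qual))
            serial += 1

    if cfg.deterministic_counts:
        for _, t in emitters:
            emit_locus(t, t.expected_counts[condition])
        for kind, frac in contam:
            emit_contaminant(kind, int(round(frac * cfg.reads_per_library)))
    else:
        # multinomial around the planted expectations: total clean reads are
        # conserved at the truth's sum, each locus has mean expected_counts
        w = np.array(weights, dtype=float)
        draws = rng.multinomial(int(w.sum()), w / w.sum())
        for (_, t), n in zip(emitters, draws):
            emit_locus(t, int(n))
        for kind, frac in contam:
            emit_contaminant(kind, int(rng.binomial(cfg.reads_per_library, frac)))
        order = rng.permutation(len(reads))
        reads = [reads[i] for i in order]
    return reads


def sample_counts(
    rng,
    n_tags: int,
    lfc: float = 0.0,
    base_low: float = 20.0,
    base_high: float = 500.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson count pairs for n_tags with a shared planted log2 fold change.

    Used for calibration studies of the two-library test (type-I error under
    lfc=0, power under |lfc|>0) without building a genome.
    """
    base = np.exp(rng.uniform(math.log(base_low), math.log(base_high), size=n_tags))
    a = rng.poisson(base * 2.0 ** (lfc / 2))
    b = rng.poisson(base * 2.0 ** (-lfc / 2))
    return a, b


# ---------------------------------------------------------------------------
# writers

def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, str]:
    """Write genome FASTA, annotation BED/GFF3, reference FASTA, family TSV,
    truth TSV and both FASTQ libraries; returns the path map."""
    import os

    from .annotate import write_bed6, write_gff3

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    p = os.path.join(outdir, "genome.fa")
    with open(p, "w") as fh:
        for name, seq in bundle.genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    paths["genome"] = p

    p = os.path.join(outdir, "annotation.bed")
    write_bed6(bundle.annotation, p)
    paths["annotation_bed"] = p
    p = os.path.join(outdir, "annotation.gff3")
    write_gff3(bundle.annotation, p)
    paths["annotation_gff3"] = p

    p = os.path.join(outdir, "mature_reference.fa")
    with open(p, "w") as fh:
        for name, seq in bundle.reference:
            fh.write(f">{name}\n{seq}\n")
    paths["reference"] = p

    p = os.path.join(outdir, "families.tsv")
    with open(p, "w") as fh:
        for name, fam in sorted(bundle.family_map.items()):
            fh.write(f"{name}\t{fam}\n")
    paths["families"] = p

    p = os.path.join(outdir, "truth.tsv")
    with open(p, "w") as fh:
        fh.write("locus_id\tchrom\tstart\tend\tstrand\tmature_seq\tstar_seq\t"
                 "is_known\tkind\tcriteria_pass\texpected_HIST\texpected_NC\t"
                 "expected_log2fc\n")
        for t in bundle.truth:
            fh.write(f"{t.locus_id}\t{t.chrom}\t{t.start}\t{t.end}\t{t.strand}\t"
                     f"{t.mature_seq}\t{t.star_seq}\t{int(t.is_known)}\t{t.kind}\t"
                     f"{'' if t.criteria_pass is None else int(t.criteria_pass)}\t"
                     f"{t.expected_counts.get(LIB_A, 0)}\t"
                     f"{t.expected_counts.get(LIB_B, 0)}\t{t.expected_log2fc}\n")
    paths["truth"] = p

    for condition in bundle.config.conditions:
        reads = simulate_library(bundle.config, bundle.truth, condition)
        p = os.path.join(outdir, f"{condition}.fastq")
        with open(p, "w") as fh:
            for rid, seq, qual in reads:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
        paths[f"fastq_{condition}"] = p
    return paths
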