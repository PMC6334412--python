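"""Precursor extraction, duplex geometry, MFEI and the six-criteria engine."""

import numpy as np
import pytest

from mirswim.annotate import GenomeHit, revcomp
from mirswim.fold import fold_hairpin
from mirswim.novel import (CriteriaThresholds, HairpinCandidate,
                           best_candidate_for_hit, compute_mfei,
                           evaluate_criteria, extract_candidates,
                           locate_duplex, merge_multilocus, DuplexGeometry)


def perfect_hairpin(mature="TGAGGTAGTAGGTTGTATGGTT", loop="AACAACAACAACA"):
    return mature + loop + revcomp(mature), mature


class TestExtractCandidates:
    def test_windows_contain_tag(self):
        rng = np.random.default_rng(0)
        chrom = "".join(rng.choice(list("ACGT"), size=2000))
        hit = GenomeHit(chrom[1000:1022], "c", 1000, 1022, "+")
        windows = extract_candidates(hit, chrom)
        assert len(windows) >= 2
        for w in windows:
            assert w.seq[w.mature_offset:w.mature_offset + 22] == hit.tag_seq

    def test_minus_strand_orientation(self):
        rng = np.random.default_rng(1)
        chrom = "".join(rng.choice(list("ACGT"), size=2000))
        tag = revcomp(chrom[1000:1022])
        hit = GenomeHit(tag, "c", 1000, 1022, "-")
        for w in extract_candidates(hit, chrom):
            assert w.seq[w.mature_offset:w.mature_offset + 22] == tag

    def test_clipped_at_chromosome_start(self):
        rng = np.random.default_rng(2)
        chrom = "".join(rng.choice(list("ACGT"), size=400))
        hit = GenomeHit(chrom[5:27], "c", 5, 27, "+")
        windows = extract_candidates(hit, chrom)
        assert all(w.start >= 0 and w.end <= 400 for w in windows)
        assert any(w.mature_offset == 5 for w in windows)

    def test_out_of_bounds_hit_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            extract_candidates(GenomeHit("A" * 22, "c", 390, 412, "+"), "A" * 400)


class TestLocateDuplex:
    def test_perfect_arms_zero_mismatches_with_overhang(self):
        pre, mature = perfect_hairpin()
        fold = fold_hairpin(pre + "CA")  # 2 nt of 3' context
        geom = locate_duplex(fold, 0, len(mature) - 1)
        assert geom.reject_reason is None
        assert geom.mature_arm == "5p"
        assert geom.mismatches == 0
        assert geom.n_loop_features == 0
        # star 3' end overhangs the mature 5' end's partner by 2
        assert geom.star_end == fold.partner[0] + 2

    def test_mature_spanning_loop_rejected(self):
        pre, mature = perfect_hairpin()
        # a "mature" centered on the terminal loop
        mid = len(pre) // 2
        geom = locate_duplex(fold_hairpin(pre), mid - 10, mid + 10)
        assert geom.reject_reason is not None

    def test_constructed_five_mismatches_counted(self):
        mature = "TGAGGTAGTAGGTTGTATGGTTAG"
        star = list(revcomp(mature))
        for i in (4, 8, 12, 16, 20):  # five separated 1x1 mismatches
            star[len(mature) - 1 - i] = mature[i]
        pre = mature + "AACAACAACAACA" + "".join(star) + "CA"
        geom = locate_duplex(fold_hairpin(pre), 0, len(mature) - 1)
        assert geom.reject_reason is None
        assert geom.mismatches == 5

    def test_single_bulge_feature(self):
        mature = "TGAGGTAGTAGGTTGTATGGTT"
        star = list(revcomp(mature))
        star.insert(11, "A")  # 1-nt bulge on the star strand
        pre = mature + "AACAACAACAACA" + "".join(star) + "CA"
        geom = locate_duplex(fold_hairpin(pre), 0, len(mature) - 1)
        assert geom.n_loop_features == 1
        assert geom.max_loop_size == 1
        assert geom.mismatches == 0


class TestMFEI:
    def test_arithmetic(self):
        assert compute_mfei(-40.0, 80, 0.50) == pytest.approx(1.0)

    def test_published_locus_inversion(self):
        """A published precursor (80 nt, MFE -48.2, MFEI 1.24) implies
        GC ~ 0.486; the formula inverted reproduces the printed index."""
        implied_gc = (48.2 * 100 / 80) / (1.24 * 100)
        assert implied_gc == pytest.approx(0.486, abs=0.001)
        assert compute_mfei(-48.2, 80, implied_gc) == pytest.approx(1.24, abs=1e-9)

    def test_zero_mfe(self):
        assert compute_mfei(0.0, 80, 0.5) == 0.0

    def test_degenerate_gc_rejected(self):
        with pytest.raises(ValueError):
            compute_mfei(-10.0, 80, 0.0)


def make_candidate(mfe=-40.0, mfei=1.2, read_count=100, pre_len=80):
    return HairpinCandidate(
        precursor_seq="A" * pre_len, chrom="c", start=1, end=pre_len,
        strand="+", fold=fold_hairpin("GGGGGGAAAACCCCCC"), mature_seq="A" * 22,
        star_seq="", mature_arm="5p", mfe=mfe, mfei=mfei, gc_fraction=0.5,
        read_count=read_count)


def clean_geometry(**kw):
    base = dict(star_start=30, star_end=60, mature_arm="5p", mismatches=0,
                n_loop_features=0, max_loop_size=0)
    base.update(kw)
    return DuplexGeometry(**base)


class TestCriteriaBoundaries:
    def test_all_pass_at_exact_thresholds(self):
        """MFE exactly -25.0, MFEI exactly 0.85, 4 mismatches, count 5:
        inclusive boundaries all pass."""
        cand = make_candidate(mfe=-25.0, mfei=0.85, read_count=5)
        crit = evaluate_criteria(cand, clean_geometry(mismatches=4))
        assert all(crit.values()), crit

    @pytest.mark.parametrize("cand_kw,geom_kw,failing", [
        ({"mfe": -24.9}, {}, "c1_stable_hairpin"),
        ({"mfe": -20.0}, {}, "c1_stable_hairpin"),
        ({"mfei": 0.849}, {}, "c1_stable_hairpin"),
        ({}, {"mismatches": 5}, "c4_mismatches"),
        ({}, {"n_loop_features": 2, "max_loop_size": 1}, "c5_loops"),
        ({}, {"n_loop_features": 1, "max_loop_size": 2}, "c5_loops"),
        ({"read_count": 4}, {}, "c6_read_count"),
        ({}, {"star_end": 90}, "c3_duplex_2nt_overhang"),
    ])
    def test_single_violation_fails_only_that_criterion(self, cand_kw, geom_kw,
                                                        failing):
        cand = make_candidate(**cand_kw)
        crit = evaluate_criteria(cand, clean_geometry(**geom_kw))
        assert crit[failing] is False
        others = {k: v for k, v in crit.items() if k != failing}
        assert all(others.values()), others

    def test_mfei_identity_holds_for_accepted(self, pipeline_result):
        result, _ = pipeline_result
        for n in result.novel:
            for c in n.loci:
                amfe = -c.mfe * 100 / len(c.precursor_seq)
                assert c.mfei == pytest.approx(amfe / (c.gc_fraction * 100),
                                               abs=1e-9)

    def test_mfei_threshold_monotonicity(self, det_bundle):
        """Raising the MFEI threshold never grows the accepted set."""
        from mirswim.annotate import build_index
        from mirswim.novel import build_candidate, extract_candidates
        idx = build_index(det_bundle.genome.items())
        truth = [t for t in det_bundle.truth if t.kind.startswith("novel")][:6]
        accepted_at = {}
        for thr in (0.85, 1.0, 1.2, 1.4):
            th = CriteriaThresholds(mfei_min=thr)
            acc = set()
            for t in truth:
                for h in idx.search(t.mature_seq):
                    c = best_candidate_for_hit(h, det_bundle.genome[h.chrom],
                                               100, th)
                    if c is not None and c.accepted:
                        acc.add(c.locus)
            accepted_at[thr] = acc
        assert accepted_at[0.85] >= accepted_at[1.0] >= accepted_at[1.2] \
            >= accepted_at[1.4]


class TestMergeMultilocus:
    def _cand(self, mature, chrom="c", start=1):
        c = make_candidate()
        c.mature_seq = mature
        c.chrom, c.start, c.end = chrom, start, start + 79
        return c

    def test_same_mature_merges_loci_counts_once(self):
        cands = [self._cand("A" * 22, start=s) for s in range(1, 1101, 100)]
        counts = {"A" * 22: {"HIST": 40, "NC": 10}}
        merged = merge_multilocus(cands, counts)
        assert len(merged) == 1
        assert len(merged[0].loci) == 11
        assert merged[0].counts == {"HIST": 40, "NC": 10}

    def test_distinct_matures_stay_separate_named_by_abundance(self):
        cands = [self._cand("A" * 22), self._cand("C" * 22, start=500)]
        counts = {"A" * 22: {"HIST": 5}, "C" * 22: {"HIST": 50}}
        merged = merge_multilocus(cands, counts)
        assert [m.mature_seq for m in merged] == ["C" * 22, "A" * 22]
        assert merged[0].name.startswith("rno-miR-n001")
        assert merged[1].name.startswith("rno-miR-n002")
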