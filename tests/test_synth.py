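"""Synthetic study generator: determinism, conservation, planted truth."""

import numpy as np
import pytest

from mirswim.annotate import revcomp
from mirswim.preprocess import FILTER_REASONS
from mirswim.synth import (LIB_A, LIB_B, SyntheticConfig, build_genome,
                           simulate_library, write_bundle)


class TestBuildGenome:
    def test_deterministic_given_seed(self, tmp_path):
        cfg = SyntheticConfig(seed=5)
        p1 = write_bundle(build_genome(cfg), tmp_path / "a")
        p2 = write_bundle(build_genome(SyntheticConfig(seed=5)), tmp_path / "b")
        for key in p1:
            assert open(p1[key]).read() == open(p2[key]).read(), key

    def test_different_seed_different_genome(self):
        g1 = build_genome(SyntheticConfig(seed=1)).genome
        g2 = build_genome(SyntheticConfig(seed=2)).genome
        assert g1 != g2

    def test_multicopy_cluster_shares_one_mature(self, det_bundle):
        copies = [t for t in det_bundle.truth if t.kind == "novel_multicopy"]
        assert len(copies) == 11
        assert len({t.mature_seq for t in copies}) == 1
        assert len({t.chrom for t in copies}) == 1  # clustered

    def test_mature_and_star_are_locus_substrings(self, det_bundle):
        for t in det_bundle.truth:
            locus = det_bundle.genome[t.chrom][t.start - 1:t.end]
            oriented = locus if t.strand == "+" else revcomp(locus)
            assert t.mature_seq in oriented, t.locus_id
            if t.star_seq:
                assert t.star_seq in oriented, t.locus_id

    def test_annotation_covers_every_class(self, det_bundle):
        classes = {a.cls for a in det_bundle.annotation}
        assert classes == {"rRNA", "tRNA", "scRNA", "snRNA", "snoRNA",
                           "srpRNA", "exon", "intron", "repeat"}

    def test_criteria_labels_match_design_intent(self, det_bundle):
        """Hairpins designed to pass do pass, designed failures fail, and
        each failure mode trips the intended criterion."""
        for t in det_bundle.truth:
            if t.criteria_pass is None:
                continue
            if t.kind.startswith("novel_fail"):
                assert t.criteria_pass is False, t.locus_id
                if "weak_stem" in t.kind:
                    assert not t.criteria["c1_stable_hairpin"]
                elif "many_mismatches" in t.kind:
                    assert not t.criteria["c4_mismatches"]
                elif "low_count" in t.kind:
                    assert not t.criteria["c6_read_count"]
            else:
                assert t.criteria_pass is True, (t.locus_id, t.criteria)

    def test_perfect_hairpin_truth_has_clean_duplex(self, det_bundle):
        perfect = [t for t in det_bundle.truth
                   if t.kind == "novel" and t.n_mismatches == 0 and t.n_bulges == 0]
        assert perfect
        for t in perfect:
            assert t.criteria["c4_mismatches"] and t.criteria["c5_loops"]

    def test_condition_specific_locus_exists(self, det_bundle):
        specific = [t for t in det_bundle.truth if t.condition_specific]
        assert specific
        for t in specific:
            assert t.expected_counts[LIB_B] == 0
            assert t.expected_counts[LIB_A] > 0

    def test_contaminant_fractions_validated(self):
        cfg = SyntheticConfig(contaminant_fractions={"polyA": 0.6, "low_quality": 0.5})
        with pytest.raises(ValueError, match="sum"):
            cfg.validate()

    def test_genome_too_short_raises(self):
        with pytest.raises(ValueError):
            build_genome(SyntheticConfig(genome_length=9000, n_chromosomes=4))


class TestSimulateLibrary:
    def test_deterministic_counts_exact(self, det_bundle):
        reads = simulate_library(det_bundle.config, det_bundle.truth, LIB_A)
        by_insert = {}
        for _, seq, _ in reads:
            by_insert[seq] = by_insert.get(seq, 0) + 1
        cfg = det_bundle.config
        # one clean locus check: every planted read present at exact count
        t = next(t for t in det_bundle.truth if t.kind == "novel"
                 and not t.iso_ext_seq)
        expected = t.expected_counts[LIB_A]
        read_seq = (t.mature_seq + cfg.adapter3 + "A" * 36)[:36]
        assert by_insert.get(read_seq) == expected

    def test_total_read_conservation_deterministic(self, det_bundle):
        cfg = det_bundle.config
        reads = simulate_library(cfg, det_bundle.truth, LIB_A)
        planted = sum(t.expected_counts[LIB_A] for t in det_bundle.truth)
        contaminants = sum(int(round(f * cfg.reads_per_library))
                           for f in cfg.contaminant_fractions.values())
        assert len(reads) == planted + contaminants

    def test_condition_specific_zero_in_control(self, det_bundle):
        reads = simulate_library(det_bundle.config, det_bundle.truth, LIB_B)
        specific = [t for t in det_bundle.truth if t.condition_specific]
        for t in specific:
            assert not any(seq.startswith(t.mature_seq) for _, seq, _ in reads)

    def test_polya_fraction_within_binomial_noise(self):
        cfg = SyntheticConfig(
            seed=13, reads_per_library=1000,
            contaminant_fractions={"polyA": 0.1})
        bundle = build_genome(cfg)
        reads = simulate_library(cfg, bundle.truth, LIB_A)
        n_polya = 0
        for _, seq, _ in reads:
            from mirswim.preprocess import find_adapter3
            pos = find_adapter3(seq, cfg.adapter3)
            insert = seq[:pos] if pos else seq
            if insert and insert.count("A") >= 0.9 * len(insert):
                n_polya += 1
        # Binomial(1000, 0.1): mean 100, sd ~9.5
        assert 60 <= n_polya <= 140

    def test_unknown_condition_rejected(self, det_bundle):
        with pytest.raises(ValueError, match="condition"):
            simulate_library(det_bundle.config, det_bundle.truth, "EXOTIC")

    def test_contaminants_cover_all_filter_reasons_but_no_insert(self, det_bundle):
        """Each simulated contaminant class is dropped under its intended
        filter reason."""
        from mirswim.preprocess import filter_and_trim, RawRead
        cfg = det_bundle.config
        reads = [RawRead(r, s, q)
                 for r, s, q in simulate_library(cfg, det_bundle.truth, LIB_A)]
        _, report = filter_and_trim(reads, cfg.adapter3, cfg.adapter5)
        for reason in FILTER_REASONS:
            if reason == "no_insert":
                continue  # exercised with constructed reads, not simulated
            assert report.dropped[reason] > 0, reason

    def test_stochastic_mode_mean_matches_expectation(self):
        cfg = SyntheticConfig(seed=3)
        bundle = build_genome(cfg)
        reads = simulate_library(cfg, bundle.truth, LIB_A)
        planted = sum(t.expected_counts[LIB_A] for t in bundle.truth)
        # multinomial over loci conserves the planted clean total exactly
        n_clean_like = sum(1 for _, s, _ in reads
                           if any(s.startswith(t.mature_seq[:18])
                                  for t in bundle.truth))
        assert abs(len(reads) - planted) / planted < 0.2  # plus contaminants
        assert n_clean_like >= 0.8 * planted
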