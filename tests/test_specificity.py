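import numpy as np
import pytest

from _oracles import build_variants_oracle, oracle_accepted_loci
from methylannot.core import PROBE_LENGTH, compute_probe_intervals, reverse_complement
from methylannot.specificity import (
    AlignmentHit,
    SearchParams,
    SeedIndex,
    best_anchored_extent,
    bisulfite_convert,
    build_variants,
    count_repetitive_bp,
    cross_hyb_table,
    distinct_loci,
    expand_degenerate,
    filter_hits,
    find_candidate_hits,
    repetitive_flags,
    run_specificity_screen,
    summarize_specificity,
)


class TestBisulfiteConvert:
    def test_unmeth_all_c_to_t(self):
        assert bisulfite_convert({"c": "ACGT"}, "unmeth_fwd")["c"] == "ATGT"

    def test_meth_keeps_cpg(self):
        assert bisulfite_convert({"c": "ACGT"}, "meth_fwd")["c"] == "ACGT"

    def test_meth_converts_non_cpg(self):
        assert bisulfite_convert({"c": "ACCT"}, "meth_fwd")["c"] == "ATTT"

    def test_case_preserved(self):
        assert bisulfite_convert({"c": "acGT"}, "unmeth_fwd")["c"] == "atGT"
        assert bisulfite_convert({"c": "acgt"}, "meth_fwd")["c"] == "acgt"

    def test_rev_variant_is_conversion_of_revcomp(self):
        genome = {"c": "AACGTTGCA"}
        rev = bisulfite_convert(genome, "unmeth_rev")["c"]
        manual = reverse_complement(genome["c"]).translate(str.maketrans("Cc", "Tt"))
        assert rev == manual

    def test_idempotent(self):
        genome = {"c": "ACGTCCGGACGCT"}
        for variant in ("unmeth_fwd", "meth_fwd"):
            once = bisulfite_convert(genome, variant)
            twice = bisulfite_convert(once, variant.replace("_rev", "_fwd"))
            assert twice == once

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            bisulfite_convert({"c": "ACGT"}, "bogus")

    def test_matches_independent_oracle(self, default_fixture):
        ours = build_variants(default_fixture.genome)
        oracle = build_variants_oracle(default_fixture.genome)
        assert ours == oracle

    def test_unmeth_variants_have_no_c(self, default_fixture):
        for variant in ("unmeth_fwd", "unmeth_rev"):
            for seq in bisulfite_convert(default_fixture.genome, variant).values():
                assert "C" not in seq and "c" not in seq


class TestExpandDegenerate:
    def test_single_r(self):
        assert set(expand_degenerate("AARTT")) == {"AAATT", "AAGTT"}

    def test_no_r(self):
        assert expand_degenerate("AATTT") == ["AATTT"]

    def test_joint_substitution(self):
        assert set(expand_degenerate("RRA")) == {"AAA", "GGA"}
        assert len(expand_degenerate("RRA")) == 2

    def test_type_i_rejected(self):
        with pytest.raises(ValueError):
            expand_degenerate("AARTT", assay_type="I")


def hit(matches, aligned, gaps=0, pos50=True):
    return AlignmentHit(
        probe_id="cg1", allele="A", degenerate_version="none",
        variant="unmeth_fwd", chrom="chr1", start=0, orientation="+",
        matches=matches, aligned_length=aligned, gaps=gaps,
        pos50_aligned=pos50, genomic_start=0, genomic_end=50,
        is_intended_target=False,
    )


class TestFilterHits:
    def test_perfect_accepted(self):
        assert filter_hits([hit(50, 50)]) == [hit(50, 50)]

    def test_below_40_matches_rejected(self):
        assert filter_hits([hit(39, 40)]) == []

    def test_gap_rejected(self):
        assert filter_hits([hit(45, 50, gaps=1)]) == []

    def test_unaligned_pos50_rejected(self):
        assert filter_hits([hit(44, 48, pos50=False)]) == []

    def test_identity_boundary(self):
        assert filter_hits([hit(45, 50)]) == [hit(45, 50)]  # exactly 90%
        assert filter_hits([hit(44, 50)]) == []  # 88%

    def test_forty_of_forty_accepted(self):
        assert filter_hits([hit(40, 40)]) == [hit(40, 40)]


class TestBestAnchoredExtent:
    def test_all_match(self):
        assert best_anchored_extent([True] * 50) == (50, 50)

    def test_clustered_5prime_mismatches_trimmed(self):
        flags = [False] * 8 + [True] * 42
        assert best_anchored_extent(flags) == (42, 42)

    def test_scattered_mismatches_kept_in_extent(self):
        flags = [True] * 50
        for i in (5, 20, 35):
            flags[i] = False
        assert best_anchored_extent(flags) == (47, 50)

    def test_tie_prefers_longer_extent(self):
        # extents [0..3] and [2..3] both score 2; the longer one wins
        flags = [True, False, True, True]
        matches, aligned = best_anchored_extent(flags)
        assert (matches, aligned) == (3, 4)


class TestSearch:
    def test_verbatim_copy_found_at_both_loci(self):
        rng = np.random.default_rng(0)
        bg = "".join(rng.choice(list("ACGT"), size=3000, p=[0.3, 0.2, 0.2, 0.3]))
        site = 1000
        seq = bg[: site - 1] + "CG" + bg[site + 1 :]
        # plant an exact copy of the footprint elsewhere
        from methylannot.core import ProbeRecord, expected_probe_sequences

        probe_a, probe_b = expected_probe_sequences(seq, "II", "F", site + 1)
        fp_seq = seq[site - PROBE_LENGTH : site]
        seq = seq[:2500] + fp_seq + seq[2550:]
        genome = {"chr1": seq}
        probe = ProbeRecord("cg0000001", "II", "F", "chr1", site + 1, probe_a)
        variants = build_variants(genome)
        index = SeedIndex(variants, 12)
        hits, _ = find_candidate_hits(probe, index)
        accepted = filter_hits(hits)
        loci = distinct_loci(accepted)
        assert ("chr1", site - PROBE_LENGTH, site) in loci
        assert ("chr1", 2500, 2550) in loci

    def test_intended_target_scores_50(self, default_fixture, probe_by_id):
        probe = probe_by_id["cg2000000"]
        variants = build_variants(default_fixture.genome)
        index = SeedIndex(variants, 12)
        hits, _ = find_candidate_hits(probe, index)
        intended = [h for h in hits if h.is_intended_target and h.allele == "A"]
        assert max(h.matches for h in intended) == PROBE_LENGTH

    def test_decoy_42_makes_non_specific(self, default_fixture, probe_by_id):
        summaries = run_specificity_screen(
            [probe_by_id["cg4000001"], probe_by_id["cg4000002"]],
            default_fixture.genome,
        )
        assert summaries["cg4000001"].non_specific
        assert not summaries["cg4000002"].non_specific  # degraded to 39/50

    def test_r_versions_collapse_to_one_locus(self, default_fixture, probe_by_id):
        probe = probe_by_id["cg4000004"]
        assert "R" in probe.probe_seq_A
        variants = build_variants(default_fixture.genome)
        index = SeedIndex(variants, 12)
        hits, _ = find_candidate_hits(probe, index)
        accepted = filter_hits(hits)
        versions = {h.degenerate_version for h in accepted}
        assert versions == {"R->A", "R->G"}
        assert len(distinct_loci(accepted)) == 1

    def test_r_design_found_only_via_rev_variants(self, default_fixture):
        probe = next(
            p for p in default_fixture.probes
            if p.design_strand == "R" and p.assay_type == "I"
        )
        variants = build_variants(default_fixture.genome)
        index = SeedIndex(variants, 12)
        accepted = filter_hits(find_candidate_hits(probe, index)[0])
        assert accepted
        assert all(h.variant.endswith("_rev") for h in accepted)

    def test_f_design_found_only_via_fwd_variants(self, default_fixture):
        probe = next(
            p for p in default_fixture.probes
            if p.design_strand == "F" and p.assay_type == "I"
        )
        variants = build_variants(default_fixture.genome)
        index = SeedIndex(variants, 12)
        accepted = filter_hits(find_candidate_hits(probe, index)[0])
        assert accepted
        assert all(h.variant.endswith("_fwd") for h in accepted)

    def test_oracle_equivalence_small(self, default_fixture):
        variants = build_variants(default_fixture.genome)
        index = SeedIndex(variants, 12)
        for pid in ("cg4000001", "cg4000003", "cg4000004"):
            probe = next(p for p in default_fixture.probes if p.probe_id == pid)
            accepted = filter_hits(find_candidate_hits(probe, index)[0])
            assert set(distinct_loci(accepted)) == oracle_accepted_loci(
                probe, variants
            )


class TestSummaries:
    def test_single_locus_specific(self, default_fixture, probe_by_id):
        s = run_specificity_screen(
            [probe_by_id["cg2000000"]], default_fixture.genome
        )["cg2000000"]
        assert s.n_loci == 1 and not s.non_specific and not s.no_hit
        assert s.allele_a_hits == 1

    def test_cross_hyb_auto_to_sex(self, default_fixture, probe_by_id):
        s = run_specificity_screen(
            [probe_by_id["cg4000003"]], default_fixture.genome
        )["cg4000003"]
        assert s.intended_chrom_class == "auto"
        assert s.cross_hyb_sex and not s.cross_hyb_auto
        assert s.xy_hits == 1 and s.autosomal_hits == 1

    def test_cross_hyb_sex_to_auto(self, default_fixture, probe_by_id):
        s = run_specificity_screen(
            [probe_by_id["cg4100001"]], default_fixture.genome
        )["cg4100001"]
        assert s.intended_chrom_class == "sex"
        assert s.cross_hyb_auto and not s.cross_hyb_sex

    def test_cross_hyb_table_cells(self, default_fixture):
        summaries = run_specificity_screen(
            default_fixture.probes, default_fixture.genome
        )
        table = cross_hyb_table(summaries.values())
        assert table["intended_auto_cross_sex_only"] == 1
        assert table["intended_sex_cross_auto_only"] == 1
        assert table["intended_auto_cross_auto_only"] == 1

    def test_no_hit_flag(self, default_fixture):
        from methylannot.core import ProbeRecord

        foreign = ProbeRecord(
            "cg9999999", "II", "F", "chr1", 40_500,
            "ACGT" * 12 + "AC",  # not derived from the genome
        )
        s = run_specificity_screen([foreign], default_fixture.genome)["cg9999999"]
        assert s.no_hit and s.n_loci == 0

    def test_xy_plus_auto_cover_all_loci(self, default_fixture):
        summaries = run_specificity_screen(
            default_fixture.probes, default_fixture.genome
        )
        for s in summaries.values():
            assert s.xy_hits + s.autosomal_hits == s.n_loci


class TestRepetitive:
    def test_counts(self, default_fixture, probe_by_id):
        genome = default_fixture.genome
        fp_full = compute_probe_intervals(probe_by_id["cg5000001"]).footprint
        fp_half = compute_probe_intervals(probe_by_id["cg5000002"]).footprint
        fp_none = compute_probe_intervals(probe_by_id["cg2000000"]).footprint
        assert count_repetitive_bp(fp_full, genome) == 50
        assert count_repetitive_bp(fp_half, genome) == 30
        assert count_repetitive_bp(fp_none, genome) == 0

    def test_flags(self):
        assert repetitive_flags(0, False) == (False, False)
        assert repetitive_flags(25, False) == (False, False)
        assert repetitive_flags(26, False) == (True, False)
        assert repetitive_flags(50, False) == (True, True)
        assert repetitive_flags(50, True) == (True, False)

    def test_specific_repetitive_class(self, default_fixture, probe_by_id):
        probe = probe_by_id["cg5000001"]
        s = run_specificity_screen([probe], default_fixture.genome)[probe.probe_id]
        fp = compute_probe_intervals(probe).footprint
        n = count_repetitive_bp(fp, default_fixture.genome)
        assert repetitive_flags(n, s.non_specific) == (True, True)
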