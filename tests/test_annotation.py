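"""Compatibility rules, isoform-altered modifiability, mapping and filters."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptmsurf.annotation import (
    COMPATIBILITY,
    binding_site_overlap,
    conservation_of_sites,
    detect_altered_capability,
    map_ptm_to_structure,
    modification_compatibility,
    multi_modification_sites,
    reliability_filter,
)
from ptmsurf.datamodel import MOD_TYPES, PTMRecord, PTMTable, VariantSite
from ptmsurf.synthetic import generate_alignment, generate_globule


class TestCompatibility:
    @pytest.mark.parametrize(
        "aa,mod,expected",
        [
            ("S", "phosphorylation", True),
            ("T", "phosphorylation", True),
            ("Y", "phosphorylation", True),
            ("A", "phosphorylation", False),  # no hydroxyl
            ("K", "acetylation", True),
            ("R", "acetylation", False),
            ("K", "methylation", True),
            ("R", "methylation", True),
            ("K", "ubiquitination", True),
            ("C", "S-nitrosylation", True),
            ("T", "S-nitrosylation", False),
            ("C", "S-glutathionylation", True),
            ("S", "O-glucosylation", True),  # the S53 glucosylation chemistry
            ("T", "O-glucosylation", False),
            ("E", "ethanolamination", True),  # the E301 chemistry
            ("D", "ethanolamination", False),
            ("P", "carbonylation", True),
        ],
    )
    def test_ruleset(self, aa, mod, expected):
        assert modification_compatibility(aa, mod) is expected

    @given(
        aa=st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
        mod=st.sampled_from(MOD_TYPES),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_total_function_over_vocabulary(self, aa, mod):
        assert modification_compatibility(aa, mod) in (True, False)

    def test_unknown_modification_rejected(self):
        with pytest.raises(ValueError, match="unknown modification"):
            modification_compatibility("S", "sumoylation")


class TestAlteredCapability:
    def test_threonine_to_alanine_loses_phosphorylation(self, small_table):
        variants = [VariantSite(176, "T", "A")]
        out = detect_altered_capability(variants, small_table)
        assert len(out) == 1
        assert out[0].mods_only_A1 == {"phosphorylation"}
        assert out[0].mods_only_A2 == frozenset()

    def test_cysteine_threonine_swap_is_bidirectional(self, small_table):
        # C234T: nitrosylation possible only with C; at the same position the
        # observed S-nitrosylation record implies phospho-capability checks on T
        table = PTMTable(
            records=list(small_table.records)
            + [PTMRecord("eEF1A2", 234, "T", "phosphorylation", 2)]
        )
        out = detect_altered_capability([VariantSite(234, "C", "T")], table)
        assert out[0].mods_only_A1 == {"S-nitrosylation"}
        assert out[0].mods_only_A2 == {"phosphorylation"}

    def test_lysine_arginine_keeps_methylation(self, small_table):
        out = detect_altered_capability([VariantSite(273, "K", "R")], small_table)
        assert out[0].mods_only_A1 == {"acetylation", "ubiquitination"}
        # methylation targets both K and R, so it is differential for neither
        assert "methylation" not in out[0].mods_only_A1
        assert out[0].mods_only_A2 == frozenset()

    def test_variant_without_observed_ptms_omitted(self, small_table):
        out = detect_altered_capability([VariantSite(999, "S", "A")], small_table)
        assert out == []

    def test_symmetric_under_isoform_swap(self, small_table):
        variants = [VariantSite(176, "T", "A"), VariantSite(273, "K", "R")]
        swapped = [VariantSite(v.position, v.aa_A2, v.aa_A1) for v in variants]
        fwd = {a.variant.position: a for a in detect_altered_capability(variants, small_table)}
        rev = {a.variant.position: a for a in detect_altered_capability(swapped, small_table)}
        assert set(fwd) == set(rev)
        for pos in fwd:
            assert fwd[pos].mods_only_A1 == rev[pos].mods_only_A2
            assert fwd[pos].mods_only_A2 == rev[pos].mods_only_A1


class TestMapping:
    def test_empty_table(self, globule64):
        model, _ = globule64
        sites = map_ptm_to_structure(PTMTable(records=[]), model)
        assert sites.mapped == [] and sites.unmapped_tail == []

    def test_planted_tail_split(self, globule64):
        model, _ = globule64
        boundary = 56
        recs = [
            PTMRecord("eEF1A1", p, "S", "phosphorylation", 1) for p in (3, 10, 20, 30, 40, 50, 55, 56)
        ] + [PTMRecord("eEF1A1", p, "K", "acetylation", 1) for p in (60, 64)]
        sites = map_ptm_to_structure(PTMTable(records=recs), model, c_terminal_boundary=boundary)
        assert len(sites.mapped) == 8
        assert sites.unmapped_tail == [60, 64]
        assert sites.n_total == len({r.position for r in recs})

    def test_boundary_defaults_to_last_resolved(self, globule64):
        model, _ = globule64
        recs = [PTMRecord("eEF1A1", 64, "S", "phosphorylation", 1)]
        sites = map_ptm_to_structure(PTMTable(records=recs), model)
        assert sites.mapped == [64]

    def test_position_beyond_sequence_is_error(self, globule64):
        model, _ = globule64
        recs = [PTMRecord("eEF1A1", 99, "S", "phosphorylation", 1)]
        with pytest.raises(ValueError, match="99"):
            map_ptm_to_structure(PTMTable(records=recs), model, sequence_length=80)

    def test_mods_merged_across_species_and_isoforms(self, small_table):
        model, _ = generate_globule(400, seed=0)
        sites = map_ptm_to_structure(small_table, model)
        assert sites.mods_by_position[234] == {"S-nitrosylation"}
        assert sites.isoforms_by_position[234] == {"eEF1A1", "eEF1A2"}
        assert sites.mods_by_position[273] == {"acetylation", "ubiquitination", "methylation"}

    def test_mapped_plus_tail_equals_distinct_positions(self, bundle150):
        model, _, _, table, _ = bundle150
        sites = map_ptm_to_structure(table, model, c_terminal_boundary=120)
        assert sites.n_total == len(table.positions())
        assert set(sites.mapped) | set(sites.unmapped_tail) == set(table.positions())
        assert not set(sites.mapped) & set(sites.unmapped_tail)


class TestMultiModification:
    def test_empty(self):
        assert multi_modification_sites(PTMTable(records=[])) == {}

    def test_planted_double_sites(self):
        recs = []
        for p in (5, 10, 15, 20, 25):  # 5 positions with two mod types
            recs.append(PTMRecord("eEF1A1", p, "K", "acetylation", 1))
            recs.append(PTMRecord("eEF1A1", p, "K", "ubiquitination", 1))
        for p in (30, 35):
            recs.append(PTMRecord("eEF1A1", p, "S", "phosphorylation", 1))
        multi = multi_modification_sites(PTMTable(records=recs))
        assert sorted(multi) == [5, 10, 15, 20, 25]
        assert multi[5] == {"acetylation", "ubiquitination"}

    def test_invariant_to_order_and_species_duplication(self):
        base = [
            PTMRecord("eEF1A1", 7, "K", "acetylation", 1, species=("human",)),
            PTMRecord("eEF1A1", 7, "K", "methylation", 1, species=("human",)),
        ]
        dup = base + [PTMRecord("eEF1A2", 7, "K", "acetylation", 2, species=("mouse",))]
        assert multi_modification_sites(PTMTable(records=list(reversed(dup)))) == \
            multi_modification_sites(PTMTable(records=base))


class TestReliabilityFilter:
    def test_zero_threshold_passes_all(self, small_table):
        subset, counts = reliability_filter(small_table, min_citations=0)
        assert len(subset) == len(small_table)

    def test_pass_plus_fail_equals_total_per_type(self, small_table):
        _, counts = reliability_filter(small_table, min_citations=5)
        for mod, (npass, total) in counts.items():
            expected_total = sum(1 for r in small_table.records if r.mod_type == mod)
            assert total == expected_total
            assert 0 <= npass <= total

    def test_site_specific_passes_despite_low_citations(self, small_table):
        subset, _ = reliability_filter(small_table, min_citations=5)
        assert any(r.position == 53 for r in subset.records)  # 1 citation, targeted experiment

    def test_planted_mixture_recovered_exactly(self):
        recs = [PTMRecord("eEF1A1", p, "S", "phosphorylation", 10) for p in range(1, 13)]
        recs += [PTMRecord("eEF1A1", p, "S", "phosphorylation", 1) for p in range(13, 21)]
        subset, counts = reliability_filter(PTMTable(records=recs), min_citations=5)
        assert counts["phosphorylation"] == (12, 20)
        assert len(subset) == 12

    def test_negative_threshold_rejected(self, small_table):
        with pytest.raises(ValueError):
            reliability_filter(small_table, min_citations=-1)


class TestConservation:
    def test_identical_comparison_all_conserved(self, small_table):
        ref = "A" * 310
        aln = generate_alignment(ref, n_orthologs=2, divergence=0.0, seed=0)
        flags, n_non = conservation_of_sites(aln, small_table, "reference", "distant")
        assert n_non == 0 and all(flags.values())

    def test_planted_substitutions_flagged(self):
        ref = "ACDEFGHIKLMNPQRSTVWY" * 3
        table = PTMTable(
            records=[PTMRecord("eEF1A1", p, "S", "phosphorylation", 1) for p in (5, 12, 30, 44, 51)]
        )
        aln = generate_alignment(ref, n_orthologs=3, divergence=0.0,
                                 planted_site_substitutions=[5, 30, 44, 51], seed=1)
        flags, n_non = conservation_of_sites(aln, table, "reference", "distant")
        assert n_non == 4
        assert [p for p, ok in flags.items() if not ok] == [5, 30, 44, 51]

    def test_gap_counts_as_non_conserved(self):
        from ptmsurf.datamodel import AlignmentMap

        aln = AlignmentMap(
            sequences={"ref": "MKSAY", "cmp": "MK-AY"},
            column_to_position={
                "ref": {0: 1, 1: 2, 2: 3, 3: 4, 4: 5},
                "cmp": {0: 1, 1: 2, 3: 3, 4: 4},
            },
            conservation=["strict", "strict", "variable", "strict", "strict"],
        )
        table = PTMTable(records=[PTMRecord("eEF1A1", 3, "S", "phosphorylation", 1)])
        flags, n_non = conservation_of_sites(aln, table, "ref", "cmp")
        assert n_non == 1 and flags[3] is False

    def test_missing_row_is_error(self, small_table):
        aln = generate_alignment("A" * 310, n_orthologs=1, divergence=0.0, seed=0)
        with pytest.raises(ValueError, match="yeast"):
            conservation_of_sites(aln, small_table, "reference", "yeast")


class TestBindingSiteOverlap:
    def test_empty_list(self, small_table):
        assert binding_site_overlap(small_table, {"empty": set()}) == {"empty": {}}

    def test_named_lists_with_mod_types(self, small_table):
        lists = {"GTP_GDP": {21, 22, 154, 157}, "patch": {273, 300, 301}}
        out = binding_site_overlap(small_table, lists)
        assert out["GTP_GDP"] == {}
        assert sorted(out["patch"]) == [273, 300, 301]
        assert out["patch"][300] == {"phosphorylation"}
        assert out["patch"][273] == {"acetylation", "ubiquitination", "methylation"}
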