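"""Folding engine, position classification, insertion design, and fusions."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_best_score
from rtdna.structure import (
    DnaSequence,
    FoldResult,
    InsertionSite,
    StemAnnotation,
    build_fusion,
    classify_positions,
    fold_mfe,
    fold_preservation,
    pairs_to_dotbracket,
    parse_dotbracket,
    propose_insertion_sites,
    truncate_stem,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=18)


class TestFoldMfe:
    def test_toy_hairpin(self, hairpin):
        fold = fold_mfe(hairpin)
        assert fold.dotbracket == "(((...)))"
        assert fold.score == 9.0

    def test_no_legal_pair(self):
        fold = fold_mfe(DnaSequence("a", "AAAA"))
        assert fold.dotbracket == "...."
        assert fold.score == 0.0

    def test_mask_forbids_pairing(self, hairpin):
        masked = DnaSequence(hairpin.id, hairpin.residues, mask=(0, 2))
        fold = fold_mfe(masked)
        assert all(i >= 3 and j >= 3 for i, j in fold.pairs)
        assert fold.score < 9.0
        assert fold.score == brute_force_best_score(masked)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            DnaSequence("x", "GGXCC")
        with pytest.raises(ValueError):
            fold_mfe(DnaSequence("x", "GGGAAACCC"), min_loop=-1)

    def test_deterministic(self):
        seq = DnaSequence("d", "GCGCAAAGCGCAAAGCGC")
        assert fold_mfe(seq).pairs == fold_mfe(seq).pairs

    @given(dna)
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force_oracle(self, residues):
        """DP score equals exhaustive enumeration on every short sequence."""
        seq = DnaSequence("h", residues)
        assert fold_mfe(seq).score == pytest.approx(brute_force_best_score(seq))

    @given(dna.filter(lambda s: len(s) >= 2), st.data())
    @settings(max_examples=100, deadline=None)
    def test_random_masks_never_pair_masked_indices(self, residues, data):
        lo = data.draw(st.integers(0, len(residues) - 1))
        hi = data.draw(st.integers(lo, len(residues) - 1))
        seq = DnaSequence("m", residues, mask=(lo, hi))
        fold = fold_mfe(seq)
        for i, j in fold.pairs:
            assert not seq.masked(i) and not seq.masked(j)
        assert fold.score == pytest.approx(brute_force_best_score(seq))


class TestDotBracket:
    @pytest.mark.parametrize(
        "s,expected",
        [
            ("(((...)))", {(0, 8), (1, 7), (2, 6)}),
            (".........", set()),
            ("((..((...))..))", {(0, 14), (1, 13), (4, 10), (5, 9)}),
        ],
    )
    def test_parse(self, s, expected):
        assert parse_dotbracket(s) == frozenset(expected)

    @pytest.mark.parametrize("bad", ["(()", "())", "(x)"])
    def test_parse_errors(self, bad):
        with pytest.raises(ValueError):
            parse_dotbracket(bad)

    @given(dna)
    @settings(max_examples=100, deadline=None)
    def test_round_trip_through_predicted_structures(self, residues):
        fold = fold_mfe(DnaSequence("r", residues))
        assert parse_dotbracket(fold.dotbracket) == fold.pairs

    def test_serialization_round_trip(self):
        pairs = parse_dotbracket("((..((...))..))")
        assert parse_dotbracket(pairs_to_dotbracket(pairs, 15)) == pairs


class TestClassifyPositions:
    def test_hairpin_loop_vs_stem(self, hairpin):
        annos = classify_positions(fold_mfe(hairpin))
        assert [a.cls for a in annos[3:6]] == ["hairpin_loop"] * 3
        assert all(annos[i].cls == "paired" for i in (0, 1, 2, 6, 7, 8))

    def test_all_exterior(self):
        annos = classify_positions(fold_mfe(DnaSequence("e", "AAAAAAAAA")))
        assert {a.cls for a in annos} == {"exterior"}

    def test_internal_loop_detection(self):
        seq = DnaSequence("i", "A" * 15)
        fold = FoldResult(seq, parse_dotbracket("((..((...))..))"), 0.0)
        cls = {a.index: a.cls for a in classify_positions(fold)}
        assert all(cls[i] == "internal_or_bulge" for i in (2, 3, 11, 12))
        assert all(cls[i] == "hairpin_loop" for i in (6, 7, 8))

    @given(dna)
    @settings(max_examples=100, deadline=None)
    def test_classes_partition_sequence(self, residues):
        fold = fold_mfe(DnaSequence("p", residues))
        annos = classify_positions(fold)
        assert len(annos) == len(residues)
        n_paired = sum(a.cls == "paired" for a in annos)
        assert n_paired == 2 * len(fold.pairs)


class TestInsertionSites:
    def test_single_loop_midpoint(self, hairpin):
        sites = propose_insertion_sites(fold_mfe(hairpin), min_run=3)
        assert len(sites) == 1
        assert sites[0].position in (4, 5)
        assert sites[0].cls == "hairpin_loop"

    def test_exterior_run(self):
        sites = propose_insertion_sites(fold_mfe(DnaSequence("e", "AAAA")), min_run=3)
        assert len(sites) == 1
        assert sites[0].cls == "exterior"
        assert sites[0].position == 2

    def test_longer_run_ranks_first(self):
        # two hairpins: loop of 3 then loop of 5
        seq = DnaSequence("two", "GGGAAACCC" + "AA" + "GGGAAAAACCC")
        fold = fold_mfe(seq)
        sites = propose_insertion_sites(fold, min_run=3)
        loops = [s for s in sites if s.cls == "hairpin_loop"]
        assert loops[0].run_length == 5 and loops[0].rank < loops[-1].rank

    def test_no_qualifying_run_is_empty(self, hairpin):
        assert propose_insertion_sites(fold_mfe(hairpin), min_run=4) == []

    def test_ranks_are_permutation(self):
        seq = DnaSequence("x", "AAGGGAAACCCAAAAGGGAAACCCAA")
        sites = propose_insertion_sites(fold_mfe(seq), min_run=2)
        assert sorted(s.rank for s in sites) == list(range(1, len(sites) + 1))


class TestFusion:
    @pytest.mark.parametrize(
        "pos,expected", [(2, "AAGGAA"), (0, "GGAAAA"), (4, "AAAAGG")]
    )
    def test_insertion_positions(self, pos, expected):
        site = InsertionSite(position=pos, run_length=4, cls="exterior", rank=1)
        fusion = build_fusion(DnaSequence("s", "AAAA"), DnaSequence("c", "GG"), site)
        assert fusion.residues == expected

    def test_out_of_range(self):
        site = InsertionSite(position=5, run_length=4, cls="exterior", rank=1)
        with pytest.raises(IndexError):
            build_fusion(DnaSequence("s", "AAAA"), DnaSequence("c", "GG"), site)

    def test_length_additivity_67nt_scale(self):
        """A 67-nt scaffold plus 67-nt cargo yields a 134-nt fusion."""
        scaffold = DnaSequence("msd", ("GGGAAACCCAT" * 7)[:67])
        cargo = DnaSequence("aptamer", ("GCTA" * 17)[:67])
        site = InsertionSite(position=30, run_length=5, cls="hairpin_loop", rank=1)
        fusion = build_fusion(scaffold, cargo, site)
        assert len(fusion.residues) == 134
        assert fusion.residues[:30] == scaffold.residues[:30]
        assert fusion.residues[30:97] == cargo.residues


class TestFoldPreservation:
    def test_loop_insertion_preserves_stem(self, hairpin):
        scaffold_fold = fold_mfe(hairpin)
        site = propose_insertion_sites(scaffold_fold, min_run=3)[0]
        cargo = DnaSequence("c", "AAAA")  # inert cargo: cannot pair
        fusion = build_fusion(hairpin, cargo, site)
        fusion_fold = fold_mfe(DnaSequence("f", fusion.residues))
        assert fold_preservation(scaffold_fold, fusion_fold, site) == 1.0

    def test_empty_cargo_is_identity(self, hairpin):
        scaffold_fold = fold_mfe(hairpin)
        site = InsertionSite(position=4, run_length=3, cls="hairpin_loop", rank=1)
        assert fold_preservation(scaffold_fold, scaffold_fold, site) == 1.0

    def test_no_pairs_retained(self, hairpin):
        scaffold_fold = fold_mfe(hairpin)
        site = InsertionSite(position=4, run_length=3, cls="hairpin_loop", rank=1)
        bare = FoldResult(DnaSequence("f", "A" * 13), frozenset(), 0.0)
        assert fold_preservation(scaffold_fold, bare, site) == 0.0

    def test_pairless_scaffold_vacuously_preserved(self):
        empty = FoldResult(DnaSequence("s", "AAAA"), frozenset(), 0.0)
        fused = FoldResult(DnaSequence("f", "AAAAAA"), frozenset(), 0.0)
        site = InsertionSite(position=2, run_length=4, cls="exterior", rank=1)
        assert fold_preservation(empty, fused, site) == 1.0


class TestTruncateStem:
    def _stem(self, n_pairs, length):
        return StemAnnotation(tuple((i, length - 1 - i) for i in range(n_pairs)))

    def test_keep_all_is_identity(self):
        seq = DnaSequence("s", "G" * 11 + "AAAA" + "C" * 11)
        stem = self._stem(11, len(seq))
        assert truncate_stem(seq, stem, keep=11).residues == seq.residues

    def test_keep_one_of_two(self):
        seq = DnaSequence("s", "GGAAAAAACC")
        stem = StemAnnotation(((0, 9), (1, 8)))
        out = truncate_stem(seq, stem, keep=1)
        assert out.residues == "GAAAAAAC"

    def test_full_to_four_pair_series(self):
        """Trimming an 11-pair terminal stem to 4 removes 2*(11-4) residues."""
        seq = DnaSequence("s", "G" * 11 + "AAAA" + "C" * 11)
        stem = self._stem(11, len(seq))
        out = truncate_stem(seq, stem, keep=4)
        assert len(out.residues) == len(seq.residues) - 14
        assert "AAAA" in out.residues

    def test_keep_out_of_range(self):
        seq = DnaSequence("s", "GGAAAAAACC")
        stem = StemAnnotation(((0, 9), (1, 8)))
        with pytest.raises(ValueError):
            truncate_stem(seq, stem, keep=3)
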