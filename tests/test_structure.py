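"""Folding DP, stem annotation, variant design and chimera assembly."""

import itertools
import random

import pytest

from aptakit.structure import (
    DEFAULT_FOLD_PARAMS,
    FoldParams,
    FoldResult,
    annotate_stems,
    assemble_chimera,
    design_corrected_variants,
    design_truncations,
    fold_mfe,
    fold_suboptimal,
)


def enumerate_structures(seq, params):
    """Yield every nested pairing of seq as a frozenset of pairs.

    Exhaustive recursion over position sets — deliberately independent
    of the DP (no interval table, no memoization)."""

    def rec(positions):
        if not positions:
            yield frozenset()
            return
        i, rest = positions[0], positions[1:]
        yield from rec(rest)  # i unpaired
        for k in rest:
            if k - i <= params.min_loop or params.score(seq[i], seq[k]) <= 0:
                continue
            inside = tuple(p for p in rest if i < p < k)
            outside = tuple(p for p in rest if p > k)
            for sin in rec(inside):
                for sout in rec(outside):
                    yield frozenset({(i, k)}) | sin | sout

    yield from rec(tuple(range(len(seq))))


def brute_force_best_score(seq, params=DEFAULT_FOLD_PARAMS):
    return max(
        sum(params.score(seq[i], seq[j]) for i, j in s)
        for s in enumerate_structures(seq, params)
    )


def pairs_from_dot_bracket(db):
    stack, pairs = [], set()
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            pairs.add((stack.pop(), i))
    return frozenset(pairs)


def assert_nested(pairs):
    for (i, j), (k, l) in itertools.combinations(pairs, 2):
        # disjoint or strictly nested, never crossing
        assert j < k or l < i or (i < k and l < j) or (k < i and j < l)


class TestFoldMfe:
    def test_no_complementary_pairs(self):
        fold = fold_mfe("AAAAAA")
        assert fold.dot_bracket == "......" and fold.score == 0

    def test_gc_hairpin(self):
        fold = fold_mfe("GGGAAAACCC")
        assert fold.dot_bracket == "(((....)))"
        assert fold.score == 9
        assert fold.score == brute_force_best_score("GGGAAAACCC")

    def test_invalid_alphabet(self):
        with pytest.raises(ValueError):
            fold_mfe("ACGU")

    def test_matches_exhaustive_enumeration(self):
        rng = random.Random(2024)
        for _ in range(60):
            seq = "".join(rng.choices("ACGT", k=rng.randint(1, 10)))
            assert fold_mfe(seq).score == brute_force_best_score(seq)

    def test_pairs_are_nested_and_respect_min_loop(self):
        rng = random.Random(7)
        for _ in range(25):
            seq = "".join(rng.choices("ACGT", k=40))
            fold = fold_mfe(seq)
            assert_nested(fold.pairs)
            assert all(j - i > DEFAULT_FOLD_PARAMS.min_loop for i, j in fold.pairs)
            assert fold.score == sum(
                DEFAULT_FOLD_PARAMS.score(seq[i], seq[j]) for i, j in fold.pairs
            )

    def test_custom_min_loop(self):
        params = FoldParams(min_loop=0)
        assert fold_mfe("GC", params).pairs == frozenset({(0, 1)})

    def test_suboptimal_are_distinct_and_ranked(self):
        subs = fold_suboptimal("GGGAAAACCC", n_structures=3, margin=3)
        assert subs[0].score == 9
        scores = [s.score for s in subs]
        assert scores == sorted(scores, reverse=True)
        assert len({s.pairs for s in subs}) == len(subs)


class TestAnnotateStems:
    def test_perfect_hairpin_one_stem_no_mismatch(self):
        fold = fold_mfe("GGGGAAAACCCC")
        ann = annotate_stems(fold)
        assert len(ann.stems) == 1 and ann.mismatches == ()

    def test_interior_defect_merges_runs(self):
        db = "((.((...)).))"
        seq = "GGAGGAAACCACC"
        fold = FoldResult(seq, pairs_from_dot_bracket(db), score=0)
        ann = annotate_stems(fold, max_defect=2)
        assert len(ann.stems) == 1
        stem = ann.stems[0]
        assert len(stem.pairs) == 4
        assert stem.mismatches == (2, 10)

    def test_defect_larger_than_max_splits_stems(self):
        db = "((...((...))...))"
        seq = "GGAAAGGAAACCAAACC"
        fold = FoldResult(seq, pairs_from_dot_bracket(db), score=0)
        ann = annotate_stems(fold, max_defect=2)
        assert len(ann.stems) == 2
        assert ann.mismatches == ()

    def test_unpaired_structure(self):
        ann = annotate_stems(fold_mfe("AAAAAA"))
        assert ann.stems == () and ann.mismatches == ()


class TestCorrectedVariants:
    def test_single_defect_refolds_to_strictly_better_stem(self):
        # A at 2 opposes G at 10 inside a G-C stem; closing the defect
        # (G -> T so the A-T pair forms) must strictly raise the score
        db = "((.((...)).))"
        seq = "GGAGGAAACCGCC"
        fold = FoldResult(seq, pairs_from_dot_bracket(db), score=0)
        (variant,) = design_corrected_variants(seq, fold, annotate_stems(fold))
        assert len(variant.sequence) == len(seq)
        assert fold_mfe(variant.sequence).score > fold_mfe(seq).score

    def test_opposed_mismatch_replaced_by_complement(self):
        # helix (0-3 with 10-13) interrupted: position 2 (A) opposes 11 (G)
        db = "((.((...)).))"
        seq = "GGAGGAAACCGCC"
        fold = FoldResult(seq, pairs_from_dot_bracket(db), score=0)
        ann = annotate_stems(fold)
        (variant,) = design_corrected_variants(seq, fold, ann)
        # 5' side base A at index 2 kept; 3' side base G at index 10 -> T
        assert variant.sequence[2] == "A"
        assert variant.sequence[10] == "T"
        assert variant.substitutions == ((10, "G", "T"),)

    def test_no_mismatch_gives_empty_set(self):
        seq = "GGGGAAAACCCC"
        fold = fold_mfe(seq)
        variants = design_corrected_variants(seq, fold, annotate_stems(fold))
        assert variants == ()

    def test_two_defective_stems_give_two_variants(self):
        db = "((.((...)).))....((.((...)).))"
        seq = "GGAGGAAACCGCCTTTTGGAGGAAACCGCC"
        fold = FoldResult(seq, pairs_from_dot_bracket(db), score=0)
        variants = design_corrected_variants(seq, fold, annotate_stems(fold))
        assert len(variants) == 2
        assert variants[0].stem_span == (0, 12)
        assert variants[1].stem_span == (17, 29)

    def test_correction_never_lowers_score_random(self):
        rng = random.Random(11)
        for _ in range(20):
            seq = "".join(rng.choices("ACGT", k=36))
            fold = fold_mfe(seq)
            ann = annotate_stems(fold)
            for v in design_corrected_variants(seq, fold, ann):
                assert fold_mfe(v.sequence).score >= fold.score


class TestTruncations:
    def test_single_hairpin_span(self):
        seq = "TT" + "GGGAAAACCC" + "TT"
        fold = fold_mfe(seq)
        truncs = design_truncations(seq, fold, include_full=False)
        spans = {t.span for t in truncs}
        assert (2, 11) in spans
        assert all(t.sequence == seq[t.span[0]: t.span[1] + 1] for t in truncs)

    def test_unpaired_sequence_yields_nothing(self):
        seq = "AAAAAA"
        assert design_truncations(seq, fold_mfe(seq)) == ()

    def test_two_hairpins_give_four_variants(self):
        db = ".(((....)))....(((....)))."
        seq = "AGGGTTTTCCCAAAAGGGTTTTCCCA"
        fold = FoldResult(seq, pairs_from_dot_bracket(db), score=0)
        truncs = design_truncations(seq, fold)
        spans = [t.span for t in truncs]
        # single elements, both + spacer, and the full parent
        assert spans == [(1, 10), (15, 24), (1, 24), (0, 25)]
        assert len(truncs) == 4

    def test_truncation_retains_parent_pairs(self):
        seq = "TT" + "GGGAAAACCC" + "TTTT" + "GGGGTTTTCCCC"
        fold = fold_mfe(seq)
        for t in design_truncations(seq, fold, include_full=False):
            i0 = t.span[0]
            parent_pairs = {
                (i - i0, j - i0)
                for i, j in fold.pairs
                if t.span[0] <= i and j <= t.span[1]
            }
            refold = fold_mfe(t.sequence)
            restricted_score = sum(
                DEFAULT_FOLD_PARAMS.score(t.sequence[i], t.sequence[j])
                for i, j in parent_pairs
            )
            assert refold.score >= restricted_score
            if len(t.elements) == 1:
                assert parent_pairs <= refold.pairs or refold.score == restricted_score


class TestChimera:
    def test_assembly_rule(self):
        design = assemble_chimera("ACGTACGT", "GGCC", "GGCC")
        assert design.assembled_sense_strand == "ACGTACGT" + "UU" + "GGCC" + "TT"
        assert len(design.assembled_sense_strand) == 8 + 2 + 4 + 2
        assert design.assembled_antisense_strand == "GGCC" + "TT"
        assert design.sense_alphabet == "D" * 8 + "R" * 6 + "D" * 2

    def test_empty_aptamer_rejected(self):
        with pytest.raises(ValueError):
            assemble_chimera("", "GGCC", "GGCC")

    def test_duplex_mismatch_rejected(self):
        with pytest.raises(ValueError, match="reverse complement"):
            assemble_chimera("ACGT", "GGCC", "GGGG")

    def test_rna_duplex_uses_au_pairing(self):
        design = assemble_chimera("ACGTACGT", "AUGC", "GCAU")
        assert design.antisense == "GCAU"
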