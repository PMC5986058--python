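"""Column profiles, conservation, mutual information, permutation test,
classification."""

import numpy as np
import pytest

from conftest import mi_bruteforce, random_profile_counts
from fspscan import (
    AlignmentError,
    FamilyAnnotation,
    MultipleAlignment,
    ReferenceNumbering,
    ScanConfig,
    classify_positions,
    column_profile,
    conservation_score,
    mutual_information,
    permutation_significance,
)
from fspscan.stats import ColumnProfile, consensus_residue, observed_mi


def profile_from_counts(per_family: dict[str, dict[str, int]]) -> ColumnProfile:
    counts: dict[str, int] = {}
    for cs in per_family.values():
        for r, c in cs.items():
            counts[r] = counts.get(r, 0) + c
    n = sum(counts.values())
    return ColumnProfile(
        column=1, counts=counts, per_family_counts=per_family,
        gap_fraction=0.0, n_effective=n,
    )


def diagnostic_alignment(n_per_family: int = 10) -> tuple[MultipleAlignment, FamilyAnnotation]:
    """One column: family A all histidine, family B all phenylalanine."""
    ids = [f"a{i}" for i in range(n_per_family)] + [
        f"b{i}" for i in range(n_per_family)
    ]
    rows = ["H"] * n_per_family + ["F"] * n_per_family
    ann = FamilyAnnotation(
        {**{f"a{i}": "famA" for i in range(n_per_family)},
         **{f"b{i}": "famB" for i in range(n_per_family)}}
    )
    return MultipleAlignment(ids, rows), ann


class TestColumnProfile:
    def test_invariant_column(self, toy_alignment, toy_annotation):
        pr = column_profile(toy_alignment, toy_annotation, 2)
        assert pr.counts == {"K": 4}
        assert pr.gap_fraction == 0.0
        assert pr.n_effective == 4

    def test_per_family_split(self, toy_alignment, toy_annotation):
        pr = column_profile(toy_alignment, toy_annotation, 3)
        assert pr.per_family_counts == {"famA": {"H": 2}, "famB": {"F": 2}}

    def test_gaps_and_ambiguity_are_missing(self):
        aln = MultipleAlignment(["a", "b", "c", "d"], ["K", "-", "X", "K"])
        ann = FamilyAnnotation({"a": "f1", "b": "f1", "c": "f2", "d": "f2"})
        pr = column_profile(aln, ann, 1)
        assert pr.counts == {"K": 2}
        assert pr.gap_fraction == 0.5
        assert pr.n_effective == 2


class TestConservation:
    def test_invariant_column_scores_one(self):
        pr = profile_from_counts({"f1": {"K": 2}, "f2": {"K": 2}})
        assert conservation_score(pr) == 1.0

    def test_single_exception_ratio(self):
        # 14 arginines and one deviant: 14/15
        pr = profile_from_counts({"f1": {"R": 14}, "f2": {"V": 1}})
        assert conservation_score(pr) == pytest.approx(14 / 15)

    def test_tie_broken_alphabetically(self):
        pr = profile_from_counts({"f1": {"H": 2}, "f2": {"F": 2}})
        assert conservation_score(pr) == 0.5
        assert consensus_residue(pr.counts) == "F"

    def test_empty_column_is_undefined(self):
        pr = ColumnProfile(1, {}, {"f1": {}, "f2": {}}, 1.0, 0)
        with pytest.raises(AlignmentError, match="masked"):
            conservation_score(pr)


class TestMutualInformation:
    def test_invariant_column_has_zero_mi(self):
        pr = profile_from_counts({"f1": {"K": 5}, "f2": {"K": 5}})
        mi, nmi = mutual_information(pr)
        assert mi == 0.0 and nmi == 0.0

    def test_disjoint_equal_families_give_one_bit(self):
        pr = profile_from_counts({"f1": {"H": 10}, "f2": {"F": 10}})
        mi, nmi = mutual_information(pr)
        assert mi == pytest.approx(1.0)
        assert nmi == pytest.approx(1.0)

    def test_single_family_rejected(self):
        pr = profile_from_counts({"f1": {"H": 4}})
        with pytest.raises(AlignmentError, match="2 families"):
            mutual_information(pr)

    def test_matches_bruteforce_double_summation(self):
        per_fam = {"famA": {"H": 8, "Y": 2}, "famB": {"F": 9, "L": 1}}
        mi, _ = mutual_information(profile_from_counts(per_fam))
        assert mi == pytest.approx(mi_bruteforce(per_fam), abs=1e-12)

    def test_bruteforce_agreement_on_random_profiles(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            per_fam = random_profile_counts(rng)
            mi, nmi = mutual_information(profile_from_counts(per_fam))
            assert mi == pytest.approx(mi_bruteforce(per_fam), abs=1e-12)
            assert 0.0 <= nmi <= 1.0 + 1e-12

    def test_mi_bounded_by_entropies(self):
        from scipy.stats import entropy

        rng = np.random.default_rng(7)
        for _ in range(100):
            per_fam = random_profile_counts(rng)
            pr = profile_from_counts(per_fam)
            mi, _ = mutual_information(pr)
            res_counts = np.array(list(pr.counts.values()), dtype=float)
            fam_counts = np.array(
                [sum(cs.values()) for cs in per_fam.values()], dtype=float
            )
            if res_counts.sum() == 0:
                continue
            h_res = entropy(res_counts / res_counts.sum(), base=2)
            h_fam = entropy(fam_counts / fam_counts.sum(), base=2)
            assert mi <= min(h_res, h_fam) + 1e-9
            assert mi >= -1e-12

    def test_vectorized_columns_match_scalar(self, toy_alignment, toy_annotation):
        mis = observed_mi(toy_alignment, toy_annotation)
        for c in range(1, toy_alignment.n_columns + 1):
            pr = column_profile(toy_alignment, toy_annotation, c)
            assert mis[c - 1] == pytest.approx(mutual_information(pr)[0], abs=1e-12)


class TestPermutationSignificance:
    def test_diagnostic_column_hits_p_floor(self):
        aln, ann = diagnostic_alignment(10)
        cfg = ScanConfig(n_permutations=999, seed=123)
        res = permutation_significance(aln, ann, cfg)
        assert res.p_values[0] == pytest.approx(1 / 1000)
        assert res.z_scores[0] > 3

    def test_invariant_column_has_p_one(self):
        ids = [f"s{i}" for i in range(8)]
        aln = MultipleAlignment(ids, ["K"] * 8)
        ann = FamilyAnnotation(
            {s: ("f1" if i < 4 else "f2") for i, s in enumerate(ids)}
        )
        cfg = ScanConfig(n_permutations=99, seed=0)
        res = permutation_significance(aln, ann, cfg)
        assert res.p_values[0] == 1.0
        assert res.z_scores[0] == 0.0

    def test_deterministic_given_seed(self, toy_alignment, toy_annotation):
        cfg = ScanConfig(n_permutations=200, seed=9)
        r1 = permutation_significance(toy_alignment, toy_annotation, cfg)
        r2 = permutation_significance(toy_alignment, toy_annotation, cfg)
        assert np.array_equal(r1.p_values, r2.p_values)
        assert np.array_equal(r1.z_scores, r2.z_scores)

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError, match="99"):
            ScanConfig(n_permutations=50)


class TestClassifyPositions:
    def make_alignment(self, columns: list[list[str]], families: dict[str, list[int]]):
        """columns: per column, one residue per sequence."""
        n_seq = len(columns[0])
        ids = [f"s{i}" for i in range(n_seq)]
        rows = ["".join(col[i] for col in columns) for i in range(n_seq)]
        labels = {}
        for fam, idxs in families.items():
            for i in idxs:
                labels[ids[i]] = fam
        return MultipleAlignment(ids, rows), FamilyAnnotation(labels)

    def test_every_column_gets_exactly_one_class(self):
        rng = np.random.default_rng(5)
        cols = [[rng.choice(list("ACDK-")) for _ in range(12)] for _ in range(20)]
        aln, ann = self.make_alignment(
            cols, {"f1": range(0, 4), "f2": range(4, 8), "f3": range(8, 12)}
        )
        cls = classify_positions(aln, ann, None, ScanConfig(n_permutations=99, seed=1))
        assert len(cls) == 20
        legal = {"conserved", "conserved_with_exceptions", "fsp", "variable", "masked"}
        assert all(pc.category in legal for pc in cls)

    def test_invariant_column_is_conserved(self):
        aln, ann = self.make_alignment(
            [["K"] * 12, ["A"] * 12],
            {"f1": range(0, 4), "f2": range(4, 8), "f3": range(8, 12)},
        )
        cls = classify_positions(aln, ann, None, ScanConfig(n_permutations=99, seed=0))
        assert [pc.category for pc in cls] == ["conserved", "conserved"]
        assert cls[0].conservation == 1.0

    def test_single_family_deviation_is_conserved_with_exceptions(self):
        # arginine in all families but one, which carries valine
        col = ["R"] * 8 + ["V"] * 4
        aln, ann = self.make_alignment(
            [col, ["A"] * 12],
            {"f1": range(0, 4), "f2": range(4, 8), "f3": range(8, 12)},
        )
        cls = classify_positions(aln, ann, None, ScanConfig(n_permutations=99, seed=0))
        assert cls[0].category == "conserved_with_exceptions"
        assert cls[0].exception_families == ["f3"]

    def test_heavily_gapped_column_is_masked(self):
        col = ["-"] * 7 + ["K"] * 5
        aln, ann = self.make_alignment(
            [col, ["A"] * 12],
            {"f1": range(0, 4), "f2": range(4, 8), "f3": range(8, 12)},
        )
        cls = classify_positions(aln, ann, None, ScanConfig(n_permutations=99, seed=0))
        assert cls[0].category == "masked"
        assert np.isnan(cls[0].p_value) and np.isnan(cls[0].q_value)

    def test_q_values_dominate_p_values(self):
        rng = np.random.default_rng(3)
        cols = [[rng.choice(list("ACDK")) for _ in range(12)] for _ in range(15)]
        aln, ann = self.make_alignment(
            cols, {"f1": range(0, 4), "f2": range(4, 8), "f3": range(8, 12)}
        )
        cls = classify_positions(aln, ann, None, ScanConfig(n_permutations=99, seed=2))
        for pc in cls:
            if not np.isnan(pc.q_value):
                assert pc.q_value >= pc.p_value - 1e-12

    def test_ref_labels_attached_per_family(self):
        col1 = ["K"] * 8
        col2 = ["H"] * 4 + ["F"] * 4
        aln, ann = self.make_alignment(
            [col1, col2], {"f1": range(0, 4), "f2": range(4, 8)}
        )
        numberings = {
            "f1": ReferenceNumbering("s0", 100),
            "f2": ReferenceNumbering("s4", 200),
        }
        cls = classify_positions(
            aln, ann, numberings, ScanConfig(n_permutations=99, seed=0)
        )
        assert cls[0].ref_labels == {"f1": "K100", "f2": "K200"}
        assert cls[1].ref_labels == {"f1": "H101", "f2": "F201"}
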