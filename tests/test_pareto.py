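"""Dominance, non-dominated filtering, the molecule archive, and metrics."""

import numpy as np
import pytest

from pmcts.pareto import (
    FingerprintSet,
    ParetoArchive,
    SuccessCriterion,
    diversity,
    dominates,
    hypervolume,
    hypervolume_mc,
    metrics_report,
    non_dominated_filter,
    success_rate,
)


from tests.helpers import brute_force_front


class TestDominates:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((1, 1), (0, 0), True),
            ((0.5, 0.5), (0.5, 0.5), False),  # equality is not dominance
            ((0.9, 0.1), (0.1, 0.9), False),  # trade-off
            ((0.1, 0.9), (0.9, 0.1), False),
            ((1, 0.5), (1, 0.4), True),  # weak dominance with one strict gain
        ],
    )
    def test_examples(self, a, b, expected):
        assert dominates(a, b) is expected

    def test_dimension_mismatch_names_both_lengths(self):
        with pytest.raises(ValueError, match="2.*3|3.*2"):
            dominates((1, 2), (1, 2, 3))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            dominates((np.nan, 1), (0, 0))

    def test_irreflexive_antisymmetric_transitive(self):
        rng = np.random.default_rng(42)
        vecs = rng.random((40, 4))
        for v in vecs:
            assert not dominates(v, v)
        for a in vecs[:15]:
            for b in vecs[:15]:
                assert not (dominates(a, b) and dominates(b, a))
        # transitivity on randomly found chains
        for a in vecs:
            for b in vecs:
                if not dominates(a, b):
                    continue
                for c in vecs:
                    if dominates(b, c):
                        assert dominates(a, c)


class TestNonDominatedFilter:
    def test_example_front(self):
        vecs = [(1, 0), (0, 1), (0.5, 0.5), (0.2, 0.2)]
        assert non_dominated_filter(vecs) == [0, 1, 2]

    def test_single_vector(self):
        assert non_dominated_filter([(0.3, 0.7)]) == [0]

    def test_all_identical_all_kept(self):
        assert non_dominated_filter([(0.5, 0.5)] * 4) == [0, 1, 2, 3]

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            non_dominated_filter([])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            n = int(rng.integers(1, 65))
            d = int(rng.integers(1, 9))
            mat = rng.random((n, d)).round(2)  # rounding creates ties
            assert non_dominated_filter(mat) == brute_force_front(mat)


class TestParetoArchive:
    def test_insert_mutually_nondominated(self):
        archive = ParetoArchive()
        archive.insert("a", (1, 0))
        archive.insert("b", (0, 1))
        change = archive.insert("c", (0.5, 0.5))
        assert change.accepted and change.removed == []
        assert len(archive) == 3

    def test_global_dominator_sweeps_archive(self):
        archive = ParetoArchive()
        for smi, vec in [("a", (1, 0)), ("b", (0, 1)), ("c", (0.5, 0.5))]:
            archive.insert(smi, vec)
        change = archive.insert("d", (1, 1))
        assert change.accepted
        assert sorted(change.removed) == ["a", "b", "c"]
        assert archive.smiles() == ["d"]

    def test_dominated_candidate_rejected(self):
        archive = ParetoArchive()
        archive.insert("a", (0.5, 0.5))
        change = archive.insert("b", (0.1, 0.1))
        assert not change.accepted
        assert archive.smiles() == ["a"]

    def test_reinsert_identical_is_noop(self):
        archive = ParetoArchive()
        archive.insert("a", (0.5, 0.5))
        change = archive.insert("a", (0.5, 0.5))
        assert change.accepted and change.removed == []
        assert len(archive) == 1

    def test_dimension_mismatch(self):
        archive = ParetoArchive()
        archive.insert("a", (0.5, 0.5))
        with pytest.raises(ValueError, match="dimension"):
            archive.insert("b", (0.5, 0.5, 0.5))

    def test_pairwise_nondomination_after_random_insertions(self):
        rng = np.random.default_rng(11)
        archive = ParetoArchive()
        for i in range(2000):
            archive.insert(f"m{i}", rng.random(3).round(2))
        mat = archive.vectors()
        assert brute_force_front(mat) == list(range(len(mat)))

    def test_insertion_order_invariance(self):
        rng = np.random.default_rng(3)
        candidates = [(f"m{i}", tuple(rng.random(3).round(2))) for i in range(120)]
        reference = None
        for shuffle_seed in range(5):
            order = np.random.default_rng(shuffle_seed).permutation(len(candidates))
            archive = ParetoArchive()
            for idx in order:
                smi, vec = candidates[idx]
                archive.insert(smi, vec)
            content = {smi: tuple(vec) for smi, (vec, _) in archive}
            if reference is None:
                reference = content
            assert content == reference

    def test_csv_round_trip(self, tmp_path):
        archive = ParetoArchive()
        archive.insert("CCO", (0.123456789012, 0.9), raw={"qed": 0.55})
        archive.insert("c1ccccc1", (0.9, 0.123456789012), raw={"qed": 0.44})
        path = tmp_path / "archive.csv"
        archive.to_csv(path, objective_names=["o1", "o2"])
        loaded = ParetoArchive.from_csv(path)
        assert set(loaded.smiles()) == {"CCO", "c1ccccc1"}
        for smi in archive.smiles():
            np.testing.assert_allclose(
                loaded.entries[smi][0], archive.entries[smi][0], rtol=1e-11
            )
            assert loaded.entries[smi][1] == pytest.approx(archive.entries[smi][1])


class TestHypervolume:
    def test_single_point_box(self):
        assert hypervolume([(0.5, 0.5)]) == pytest.approx(0.25)
        assert hypervolume([(0.2, 0.3, 0.5)]) == pytest.approx(0.03)

    def test_two_point_inclusion_exclusion(self):
        assert hypervolume([(1, 0.5), (0.5, 1)]) == pytest.approx(0.75)

    def test_dominated_points_do_not_change_result(self):
        base = hypervolume([(1, 0.5), (0.5, 1)])
        with_dominated = hypervolume([(1, 0.5), (0.5, 1), (0.4, 0.4), (0.2, 0.9)])
        assert with_dominated == pytest.approx(base)

    def test_monotone_in_added_points(self):
        rng = np.random.default_rng(5)
        pts = rng.random((12, 4))
        hv = hypervolume(pts)
        for _ in range(5):
            pts = np.vstack([pts, rng.random(4)])
            hv_new = hypervolume(pts)
            assert hv_new >= hv - 1e-12
            hv = hv_new

    def test_point_below_reference_errors(self):
        with pytest.raises(ValueError, match="reference"):
            hypervolume([(0.5, -0.1)], ref=(0, 0))

    def test_empty_front_is_zero(self):
        assert hypervolume([], ref=(0, 0)) == 0.0

    def test_nonzero_reference_point(self):
        # box [0.2, 0.6] x [0.1, 0.5]
        assert hypervolume([(0.6, 0.5)], ref=(0.2, 0.1)) == pytest.approx(0.16)

    @pytest.mark.parametrize("d", [2, 3, 4, 5, 6, 7])
    def test_exact_matches_monte_carlo(self, d):
        rng = np.random.default_rng(d)
        pts = rng.random((12, d)) ** 0.5
        exact = hypervolume(pts, method="exact")
        n = 200_000
        mc = hypervolume_mc(pts, n_samples=n, seed=99)
        upper = np.max(np.asarray(pts)[non_dominated_filter(pts)], axis=0)
        box = float(np.prod(upper))
        p = exact / box
        se = box * np.sqrt(max(p * (1 - p), 1e-12) / n)
        assert abs(exact - mc) <= 3 * se + 1e-9


class TestHypervolumeMC:
    def test_full_cube(self):
        assert hypervolume_mc([(1, 1, 1)], n_samples=1000, seed=0) == pytest.approx(1.0)

    def test_empty_front(self):
        assert hypervolume_mc([], ref=(0, 0), n_samples=10) == 0.0

    def test_bad_sample_count(self):
        with pytest.raises(ValueError):
            hypervolume_mc([(0.5, 0.5)], n_samples=0)

    def test_deterministic_given_seed(self):
        pts = np.random.default_rng(1).random((10, 3))
        a = hypervolume_mc(pts, n_samples=50_000, seed=5)
        b = hypervolume_mc(pts, n_samples=50_000, seed=5)
        assert a == b


class TestSuccessRate:
    CRITERIA = [
        SuccessCriterion("act", 5.5, "gt"),
        SuccessCriterion("tox", 3.0, "lt"),
    ]

    def test_all_pass(self):
        records = [{"act": 6.0, "tox": 2.0}, {"act": 7.0, "tox": 1.0}]
        assert success_rate(records, self.CRITERIA) == 1.0

    def test_one_record_fails_one_criterion(self):
        records = [{"act": 6.0, "tox": 2.0}] * 4 + [{"act": 6.0, "tox": 3.5}]
        assert success_rate(records, self.CRITERIA) == pytest.approx(4 / 5)

    def test_strict_comparison_at_threshold(self):
        assert success_rate([{"act": 5.5, "tox": 2.0}], self.CRITERIA) == 0.0

    def test_empty_records_error(self):
        with pytest.raises(ValueError):
            success_rate([], self.CRITERIA)

    def test_missing_property_names_record_and_property(self):
        with pytest.raises(KeyError, match="tox"):
            success_rate([{"act": 6.0}], self.CRITERIA)

    def test_bad_sense_rejected(self):
        with pytest.raises(ValueError):
            SuccessCriterion("x", 1.0, "ge")


class TestDiversity:
    def test_identical_fingerprints_zero(self):
        fps = FingerprintSet.from_smiles(["CCO", "CCO"])
        assert diversity(fps) == pytest.approx(0.0)

    def test_disjoint_fingerprints_one(self):
        from rdkit import DataStructs

        a = DataStructs.ExplicitBitVect(64)
        b = DataStructs.ExplicitBitVect(64)
        a.SetBit(1), a.SetBit(2)
        b.SetBit(10), b.SetBit(11)
        assert diversity(FingerprintSet([a, b])) == pytest.approx(1.0)

    def test_requires_two_molecules(self):
        with pytest.raises(ValueError):
            diversity(FingerprintSet.from_smiles(["CCO"]))

    def test_matches_double_loop_oracle(self, corpus):
        from rdkit import DataStructs

        smiles = corpus[:10]
        fps = FingerprintSet.from_smiles(smiles)
        total, n = 0.0, len(smiles)
        for i in range(n):
            for j in range(i + 1, n):
                total += 1 - DataStructs.TanimotoSimilarity(
                    fps.bitvectors[i], fps.bitvectors[j]
                )
        assert diversity(fps) == pytest.approx(total / (n * (n - 1) / 2))

    def test_permutation_invariant(self, corpus):
        smiles = corpus[:8]
        d1 = diversity(FingerprintSet.from_smiles(smiles))
        d2 = diversity(FingerprintSet.from_smiles(smiles[::-1]))
        assert d1 == pytest.approx(d2)
        assert 0.0 <= d1 <= 1.0


def test_metrics_report_fields(corpus):
    rng = np.random.default_rng(0)
    smiles = corpus[:6]
    vectors = rng.random((6, 3))
    report = metrics_report(
        smiles,
        vectors,
        raw_records=[{"x": 1.0}] * 6,
        criteria=[SuccessCriterion("x", 0.5, "gt")],
    )
    assert set(report) == {"hv", "sr", "div", "n_molecules", "n_objectives", "hv_method"}
    assert report["sr"] == 1.0
    assert report["n_molecules"] == 6
    assert report["hv"] > 0
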