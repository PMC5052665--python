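"""Unit tests for coarse-graining, overlap statistics, and the stimulation map."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_point_brain
from respnet.exceptions import EmptyResultError, InvalidArgumentError
from respnet.rsn_matching import (
    RSN_NAMES,
    MatchResult,
    RSNMask,
    bhattacharyya_coefficient,
    build_stimulation_map,
    candidate_patterns,
    coarse_grain,
    cortical_subcortical_tests,
    generate_synthetic_masks,
    graph_metrics,
    holm_correct,
    match_candidates,
    permutation_test,
    read_masks,
    select_optimal_parameters,
    write_masks,
)
from respnet.synthetic_brain import HeterogeneousSC


@pytest.fixture(scope="module")
def point_parc():
    _, parc, _, _ = make_point_brain(4, np.zeros((4, 4)), np.zeros((4, 4)))
    return parc


class TestCoarseGrain:
    def test_one_node_per_area_squares(self, point_parc):
        v = np.array([0.5, 0.5, 0.5, 0.5])
        out = coarse_grain(v, point_parc, "square")
        np.testing.assert_allclose(out, 0.25)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_hand_arithmetic(self):
        _, parc, _, _ = make_point_brain(2, np.zeros((2, 2)), np.zeros((2, 2)))
        out = coarse_grain(np.array([0.6, 0.8]), parc, "square")
        np.testing.assert_allclose(out, [0.36, 0.64], atol=1e-12)

    def test_all_mass_one_area(self, point_parc):
        v = np.array([0.0, 1.0, 0.0, 0.0])
        out = coarse_grain(v, point_parc, "square")
        np.testing.assert_allclose(out, [0, 1, 0, 0], atol=1e-12)

    def test_absolute_metric(self, point_parc):
        v = np.array([-0.5, 0.5, 0.5, 0.5])
        out = coarse_grain(v, point_parc, "absolute")
        np.testing.assert_allclose(out, 0.25)

    def test_unknown_metric(self, point_parc):
        with pytest.raises(InvalidArgumentError):
            coarse_grain(np.ones(4), point_parc, "cubic")

    def test_aggregates_within_area(self, tiny_bundle):
        parc = tiny_bundle.parcellation
        n = tiny_bundle.geometry.n_nodes
        v = np.zeros(n)
        mem = parc.members(0)
        v[mem[:2]] = [0.6, 0.8]
        out = coarse_grain(v, parc, "square")
        assert out[0] == pytest.approx(1.0, abs=1e-12)


class TestCandidatePatterns:
    def test_three_identical_vectors(self, point_parc):
        v = np.full((4, 3), 0.5)
        cands = candidate_patterns(v, point_parc, "square")
        assert len(cands) == 7
        for c in cands:
            np.testing.assert_allclose(c, cands[0], atol=1e-12)

    def test_two_vectors_three_candidates(self, point_parc):
        v = np.zeros((4, 2))
        v[0, 0] = 1.0
        v[1, 1] = 1.0
        cands = candidate_patterns(v, point_parc, "square")
        assert len(cands) == 3
        np.testing.assert_allclose(cands[2], [0.5, 0.5, 0, 0], atol=1e-12)

    def test_all_sum_to_one(self, point_parc):
        rng = np.random.default_rng(0)
        v, _ = np.linalg.qr(rng.standard_normal((4, 3)))
        for c in candidate_patterns(v, point_parc, "square"):
            assert c.sum() == pytest.approx(1.0, abs=1e-12)


class TestBhattacharyya:
    def test_identical(self):
        p = np.array([0.2, 0.3, 0.5])
        assert bhattacharyya_coefficient(p, p) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint(self):
        assert bhattacharyya_coefficient(
            np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_closed_form(self):
        bc = bhattacharyya_coefficient(np.array([0.5, 0.5]), np.array([1.0, 0.0]))
        assert bc == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(InvalidArgumentError):
            bhattacharyya_coefficient(np.array([-0.1, 1.1]), np.array([0.5, 0.5]))

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8))
    def test_symmetric_and_bounded(self, raw):
        p = np.array(raw) / np.sum(raw)
        rng = np.random.default_rng(0)
        q = rng.dirichlet(np.ones(len(p)))
        a = bhattacharyya_coefficient(p, q)
        b = bhattacharyya_coefficient(q, p)
        assert a == pytest.approx(b, abs=1e-12)
        assert 0.0 <= a <= 1.0 + 1e-12


class TestPermutationTest:
    def test_p_formula(self):
        mask = RSNMask("visual", np.array([0, 1, 2, 0, 1]))
        r = permutation_test(np.array([0.2] * 5), mask, N=99, seed=0)
        # uniform candidate: every permutation gives the same BC, none greater
        assert r.n_exceed == 0
        assert r.p == pytest.approx(0.01)

    def test_identical_candidate(self):
        mask = RSNMask("visual", np.array([0, 1, 2, 0]))
        r = permutation_test(mask.weights, mask, N=999, seed=1)
        assert r.bc == pytest.approx(1.0, abs=1e-12)
        assert r.n_exceed == 0
        assert r.p == pytest.approx(1 / 1000)

    def test_reproducible(self):
        rng = np.random.default_rng(2)
        cand = rng.dirichlet(np.ones(10))
        mask = RSNMask("memory", rng.integers(0, 3, 10) + (rng.random(10) < 0.1))
        r1 = permutation_test(cand, mask, N=500, seed=7)
        r2 = permutation_test(cand, mask, N=500, seed=7)
        assert r1.n_exceed == r2.n_exceed and r1.p == r2.p

    def test_invalid_n(self):
        mask = RSNMask("visual", np.array([0, 1]))
        with pytest.raises(InvalidArgumentError):
            permutation_test(np.array([0.5, 0.5]), mask, N=0)


class TestHolm:
    def test_formula_arithmetic(self):
        np.testing.assert_allclose(holm_correct([0.01, 0.04], m=2), [0.02, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_correct([0.03], m=1), [0.03])

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(0)
        p = rng.random(20)
        adj = holm_correct(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_larger_family(self):
        np.testing.assert_allclose(holm_correct([0.001], m=24), [0.024])

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            holm_correct([0.5, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_adjusted_at_least_raw(self, ps):
        adj = holm_correct(ps)
        assert (adj >= np.asarray(ps) - 1e-15).all()
        assert (adj <= 1.0 + 1e-15).all()


class TestSelectOptimal:
    def make_table(self, rows):
        return pd.DataFrame(rows)

    def test_single_triple_single_rsn(self):
        t = self.make_table([dict(metric="square", alpha=0.6, sigma=10.0,
                                  rsn="visual", bc=0.9, significant=True,
                                  group="cortical")])
        out = select_optimal_parameters(t)
        assert out["cortical"][:3] == ("square", 0.6, 10.0)

    def test_known_argmax_recovered(self):
        # oracle: exhaustive scan of a small hand-built table
        rows = []
        for alpha, base in [(0.2, 0.5), (0.6, 0.8), (1.0, 0.6)]:
            for rsn in RSN_NAMES[:3]:
                rows.append(dict(metric="square", alpha=alpha, sigma=10.0,
                                 rsn=rsn, bc=base, significant=True, group="all"))
        out = select_optimal_parameters(self.make_table(rows), group_column=None)
        assert out["all"][:3] == ("square", 0.6, 10.0)
        assert out["all"][3] == pytest.approx(3 * 0.8 / len(RSN_NAMES))

    def test_nonsignificant_high_bc_ignored(self):
        rows = [
            dict(metric="square", alpha=0.2, sigma=10.0, rsn="visual", bc=0.5,
                 significant=True, group="all"),
            dict(metric="square", alpha=0.8, sigma=10.0, rsn="visual", bc=0.99,
                 significant=False, group="all"),
        ]
        out = select_optimal_parameters(self.make_table(rows), group_column=None)
        assert out["all"][1] == 0.2

    def test_no_significant_anywhere(self):
        t = self.make_table([dict(metric="square", alpha=0.2, sigma=10.0,
                                  rsn="visual", bc=0.9, significant=False,
                                  group="all")])
        with pytest.raises(EmptyResultError):
            select_optimal_parameters(t)


class TestGraphMetrics:
    def test_mutual_triangle_clustering_one(self):
        w = 1.0 - np.eye(3)
        het = HeterogeneousSC(weights=w / w.sum(1).max(),
                              tract_lengths=np.ones((3, 3)) - np.eye(3))
        m = graph_metrics(het, normalize=False)
        np.testing.assert_allclose(m["clustering"], 1.0, atol=1e-12)

    def test_star_centre_clustering_zero(self):
        w = np.zeros((4, 4))
        w[1:, 0] = 1.0  # hub 0 -> leaves, no leaf-leaf edges
        het = HeterogeneousSC(weights=w / w.sum(1).max(), tract_lengths=w * 0)
        m = graph_metrics(het, normalize=False)
        assert m["clustering"][0] == 0.0

    def test_degrees_hand_example(self):
        # edges A->B and C->B (target-row convention: row B gets both)
        w = np.zeros((3, 3))
        w[1, 0] = 1.0
        w[1, 2] = 1.0
        het = HeterogeneousSC(weights=w / 2.0, tract_lengths=w * 0)
        m = graph_metrics(het, normalize=False)
        assert m["in_degree"][1] == 2 and m["out_degree"][1] == 0
        assert m["total_degree"][1] == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_adjacency_loop_oracle(self, seed):
        # independent oracle: explicit loops over the adjacency
        rng = np.random.default_rng(seed)
        n = 10
        mask = rng.random((n, n)) < 0.3
        np.fill_diagonal(mask, False)
        w = np.where(mask, rng.uniform(0.1, 1.0, (n, n)), 0.0)
        het = HeterogeneousSC(weights=w / w.sum(1).max(), tract_lengths=w * 0)
        m = graph_metrics(het, normalize=False)
        wn = het.weights
        for i in range(n):
            in_d = sum(1 for j in range(n) if wn[i, j] > 0)
            out_d = sum(1 for j in range(n) if wn[j, i] > 0)
            assert m["in_degree"][i] == in_d
            assert m["out_degree"][i] == out_d
            assert m["in_strength"][i] == pytest.approx(sum(wn[i]))
            assert m["out_strength"][i] == pytest.approx(sum(wn[:, i]))
        # clustering oracle: explicit Fagiolo sum over directed triangles
        wh = np.cbrt(wn.T / wn.max())
        a = (wn.T > 0).astype(float)
        for i in range(n):
            num = sum((wh[i, j] + wh[j, i]) * (wh[i, k] + wh[k, i])
                      * (wh[j, k] + wh[k, j])
                      for j in range(n) for k in range(n)) / 2.0
            d_tot = a[i].sum() + a[:, i].sum()
            d_bi = sum(a[i, j] * a[j, i] for j in range(n))
            denom = d_tot * (d_tot - 1) - 2 * d_bi
            expected = num / denom if denom > 0 else 0.0
            assert m["clustering"][i] == pytest.approx(expected, abs=1e-12)


class TestCorticalSubcorticalTests:
    def test_identical_distributions(self, tiny_bundle):
        parc = tiny_bundle.parcellation
        w = np.full(parc.n_areas, 1.0 / parc.n_areas)
        out = cortical_subcortical_tests(w, parc)
        assert out["ks_p"] > 0.5 and out["ranksum_p"] > 0.5
        assert not out["ks_significant"] and not out["ranksum_significant"]

    def test_separated_supports(self):
        # oracle: constructed fixture with >= 20 areas per group
        from respnet.synthetic_brain import generate_parcellation, generate_sphere_mesh

        geom = generate_sphere_mesh(300, 100.0, seed=3, n_subcortical=25)
        parc = generate_parcellation(geom, 25, 25, seed=3)
        w = np.zeros(parc.n_areas)
        w[parc.cortical_area_ids()] = 1.0
        w[parc.subcortical_area_ids()] = 10.0
        w /= w.sum()
        out = cortical_subcortical_tests(w, parc)
        assert out["ks_p"] < 0.01 and out["ranksum_p"] < 0.01

    def test_within_group_permutation_invariance(self, tiny_bundle):
        parc = tiny_bundle.parcellation
        rng = np.random.default_rng(0)
        w = rng.dirichlet(np.ones(parc.n_areas))
        out1 = cortical_subcortical_tests(w, parc)
        w2 = w.copy()
        sub = parc.subcortical_area_ids()
        w2[sub] = w2[rng.permutation(sub)]
        out2 = cortical_subcortical_tests(w2, parc)
        assert out1 == out2

    def test_degenerate_group_rejected(self, point_parc):
        with pytest.raises(InvalidArgumentError):
            cortical_subcortical_tests(np.ones(4) / 4, point_parc)


class TestStimulationMap:
    def test_empty(self):
        df = build_stimulation_map([])
        assert df.empty

    def test_single_row(self):
        r = MatchResult(rsn="visual", candidate=0, bc=0.8, n_exceed=3,
                        n_perm=100, p=0.04, p_corrected=0.04, significant=True,
                        extra=dict(site=5, alpha=0.6, sigma=10.0, group="cortical"))
        df = build_stimulation_map([r])
        assert len(df) == 1
        assert df.iloc[0]["bc"] == 0.8 and df.iloc[0]["site"] == 5

    def test_tie_break_lowest_candidate(self):
        rows = []
        for cand in (2, 0, 1):
            rows.append(MatchResult(rsn="visual", candidate=cand, bc=0.8,
                                    n_exceed=0, n_perm=100, p=0.01,
                                    p_corrected=0.01, significant=True,
                                    extra=dict(site=1, alpha=0.6, sigma=10.0)))
        df = build_stimulation_map(rows)
        assert len(df) == 1
        assert df.iloc[0]["eigenvector"] == 0

    def test_only_significant_rows(self):
        rows = [
            MatchResult(rsn="visual", candidate=0, bc=0.9, n_exceed=50,
                        n_perm=100, p=0.5, p_corrected=1.0, significant=False,
                        extra=dict(site=1)),
        ]
        assert build_stimulation_map(rows).empty


class TestMasksIO:
    def test_round_trip(self, tiny_bundle, tmp_path):
        parc = tiny_bundle.parcellation
        masks = generate_synthetic_masks(parc, seed=5)
        assert len(masks) == len(RSN_NAMES)
        write_masks(masks, parc, tmp_path / "masks.tsv")
        loaded = read_masks(tmp_path / "masks.tsv", parc)
        assert [m.name for m in loaded] == [m.name for m in masks]
        for a, b in zip(masks, loaded):
            np.testing.assert_array_equal(a.levels, b.levels)

    def test_mask_validation(self):
        with pytest.raises(InvalidArgumentError):
            RSNMask("visual", np.zeros(5, dtype=int))
        with pytest.raises(InvalidArgumentError):
            RSNMask("visual", np.array([0, 3]))

    def test_weights_sum_to_one(self, tiny_bundle):
        masks = generate_synthetic_masks(tiny_bundle.parcellation, seed=1)
        for m in masks:
            assert m.weights.sum() == pytest.approx(1.0, abs=1e-12)


def test_match_candidates_family_correction(tiny_bundle):
    parc = tiny_bundle.parcellation
    masks = generate_synthetic_masks(parc, seed=2)
    rng = np.random.default_rng(0)
    basis, _ = np.linalg.qr(rng.standard_normal((tiny_bundle.geometry.n_nodes, 3)))
    results = match_candidates(basis[:, :3], parc, masks, N=200, seed=0)
    assert len(results) == 7 * len(masks)
    for r in results:
        assert r.p_corrected >= r.p - 1e-15
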