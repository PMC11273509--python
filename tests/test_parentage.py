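"""Likelihood, Mendelian-transmission and exclusion engines, plus consensus."""

import itertools

import numpy as np
import pytest

from crosskin import parentage, synth
from crosskin.containers import MISSING, GenotypeMatrix, SNPPanel
from crosskin.parentage import (LikelihoodSimulationParams, assign_apis,
                                assign_exclusion, assign_likelihood, consensus,
                                locus_likelihood_ratio, simulate_delta_criticals)


def _matrix(ids, genos):
    genos = np.asarray(genos, dtype=np.int8)
    return GenotypeMatrix(list(ids), [f"L{j}" for j in range(genos.shape[1])], genos)


def _panel(freqs):
    freqs = np.asarray(freqs, dtype=float)
    return SNPPanel([f"L{j}" for j in range(freqs.size)], "parentage", ref_freq=freqs)


class TestLocusLikelihoodRatio:
    def test_het_offspring_homalt_candidate_balanced_freq_is_neutral(self):
        # Transmission prob p equals the unrelated HWE prob 2pq at p=q=0.5.
        assert locus_likelihood_ratio(1, 2, None, 0.5, 0.0) == pytest.approx(1.0)

    def test_impossible_transmission_zero_at_zero_error(self):
        assert locus_likelihood_ratio(0, 2, None, 0.5, 0.0) == 0.0

    @pytest.mark.parametrize("go, gc", list(itertools.product(range(3), range(3))))
    def test_full_error_rate_is_uninformative(self, go, gc):
        assert locus_likelihood_ratio(go, gc, None, 0.3, 1.0) == pytest.approx(1.0)

    def test_missing_genotype_neutral(self):
        assert locus_likelihood_ratio(MISSING, 2, None, 0.5) == 1.0
        assert locus_likelihood_ratio(1, MISSING, None, 0.5) == 1.0

    def test_known_dam_sharpens_the_ratio(self):
        # Offspring het, candidate hom-alt, dam hom-ref: transmission is
        # certain given the pair, vs p given the dam alone.
        r = locus_likelihood_ratio(1, 2, 0, 0.5, 0.0)
        assert r == pytest.approx(1.0 / 0.5)


def _oracle_ranking(g_off, g_cands, freqs, error_rate):
    """Brute-force candidate ranking by the joint likelihood ratio product.

    Fresh per-locus probability formulas, independent of the package's
    lookup-table path.
    """
    def hwe(g, p):
        q = 1 - p
        return [p * p, 2 * p * q, q * q][g]

    def t1(go, gp, p):
        a = gp / 2.0
        q = 1 - p
        return [(1 - a) * p, (1 - a) * q + a * p, a * q][go]

    scores = []
    for gc in g_cands:
        prod = 1.0
        for l, p in enumerate(freqs):
            if g_off[l] == MISSING or gc[l] == MISSING:
                continue
            num = (1 - error_rate) * t1(g_off[l], gc[l], p) + error_rate * hwe(g_off[l], p)
            den = hwe(g_off[l], p)
            ratio = num / den
            prod *= max(ratio, np.exp(parentage.LOG_RATIO_FLOOR))
        scores.append(prod)
    return list(np.argsort(-np.asarray(scores), kind="stable"))


class TestLikelihoodRankingOracle:
    def test_exhaustive_two_locus_three_candidates(self):
        # All genotype configurations at 2 loci x 3 candidates: the summed
        # log-ratio ranking must equal the joint-product oracle ranking.
        freqs = np.array([0.4, 0.7])
        e = 0.01
        for g_off in itertools.product(range(3), repeat=2):
            for flat in itertools.product(range(3), repeat=6):
                cands = [flat[:2], flat[2:4], flat[4:]]
                ids = ["kid", "c0", "c1", "c2"]
                m = _matrix(ids, [g_off] + cands)
                scores = assign_likelihood(
                    m, _panel(freqs), ["kid"], ["c0", "c1", "c2"],
                    LikelihoodSimulationParams(min_typed_loci=1,
                                               genotyping_error_rate=e),
                    criticals=(0.0, 0.0))
                oracle_best = _oracle_ranking(list(g_off), cands, freqs, e)[0]
                assert scores[0].sire_id == f"c{oracle_best}"

    def test_random_five_locus_four_candidates(self, rng):
        freqs = rng.uniform(0.2, 0.8, 5)
        e = 0.01
        for _ in range(200):
            g_off = rng.integers(0, 3, 5)
            cands = rng.integers(0, 3, (4, 5))
            m = _matrix(["kid"] + [f"c{i}" for i in range(4)],
                        np.vstack([g_off, cands]))
            scores = assign_likelihood(
                m, _panel(freqs), ["kid"], [f"c{i}" for i in range(4)],
                LikelihoodSimulationParams(min_typed_loci=1, genotyping_error_rate=e),
                criticals=(0.0, 0.0))
            oracle_best = _oracle_ranking(g_off, cands, freqs, e)[0]
            assert scores[0].sire_id == f"c{oracle_best}"


class TestDeltaCriticals:
    def test_easy_limit_gives_zero_threshold(self):
        # Every father sampled, no error, many loci: every best candidate is
        # the father, so the strict threshold collapses to 0.
        params = LikelihoodSimulationParams(
            prop_loci_typed=1.0, genotyping_error_rate=0.0,
            n_simulated_offspring=150, n_candidate_fathers=10,
            prop_fathers_sampled=1.0, min_typed_loci=5)
        freqs = np.full(120, 0.5)
        strict, relaxed = simulate_delta_criticals(freqs, params, seed=4)
        assert strict == 0.0 and relaxed == 0.0

    def test_noisier_data_needs_larger_threshold(self):
        freqs = np.random.default_rng(8).uniform(0.3, 0.7, 10)
        base = dict(prop_loci_typed=1.0, n_simulated_offspring=300,
                    n_candidate_fathers=20, prop_fathers_sampled=0.7,
                    min_typed_loci=2)
        lo, _ = simulate_delta_criticals(
            freqs, LikelihoodSimulationParams(genotyping_error_rate=0.01, **base), seed=5)
        hi, _ = simulate_delta_criticals(
            freqs, LikelihoodSimulationParams(genotyping_error_rate=0.5, **base), seed=5)
        assert hi >= lo

    def test_deterministic_under_seed(self):
        params = LikelihoodSimulationParams(n_simulated_offspring=100,
                                            n_candidate_fathers=5, min_typed_loci=2)
        freqs = np.full(30, 0.4)
        assert (simulate_delta_criticals(freqs, params, seed=9)
                == simulate_delta_criticals(freqs, params, seed=9))

    def test_degenerate_frequencies_rejected(self):
        with pytest.raises(ValueError):
            simulate_delta_criticals(np.array([0.0, 0.5]),
                                     LikelihoodSimulationParams(), seed=1)


@pytest.fixture(scope="module")
def parentage_sim():
    """50 sire-offspring truths on a 500-locus panel with 1% genotype noise."""
    rng = np.random.default_rng(100)
    n_loci, n_sires, n_dams, n_off = 500, 25, 25, 50
    freqs = rng.uniform(0.25, 0.75, n_loci)
    sires = rng.binomial(2, 1 - freqs, (n_sires, n_loci)).astype(np.int8)
    dams = rng.binomial(2, 1 - freqs, (n_dams, n_loci)).astype(np.int8)
    true_s = rng.integers(0, n_sires, n_off)
    true_d = rng.integers(0, n_dams, n_off)
    kids = np.array([
        (rng.random(n_loci) < sires[true_s[k]] / 2.0).astype(np.int8)
        + (rng.random(n_loci) < dams[true_d[k]] / 2.0).astype(np.int8)
        for k in range(n_off)])
    # 1% genotyping error: replace with a random HWE genotype.
    err = rng.random(kids.shape) < 0.01
    kids = np.where(err, rng.binomial(2, 1 - freqs[None, :], kids.shape), kids).astype(np.int8)
    ids = ([f"sire{i}" for i in range(n_sires)] + [f"dam{i}" for i in range(n_dams)]
           + [f"kid{i}" for i in range(n_off)])
    matrix = GenotypeMatrix(ids, [f"L{j}" for j in range(n_loci)],
                            np.vstack([sires, dams, kids]))
    truth = {f"kid{k}": (f"sire{true_s[k]}", f"dam{true_d[k]}") for k in range(n_off)}
    return matrix, _panel(freqs), truth


class TestAssignLikelihood:
    def test_true_sire_recovered_at_rank_one(self, parentage_sim):
        matrix, panel, truth = parentage_sim
        kids = sorted(truth)
        sires = [f"sire{i}" for i in range(25)]
        scores = assign_likelihood(
            matrix, panel, kids, sires,
            LikelihoodSimulationParams(n_simulated_offspring=200,
                                       n_candidate_fathers=25,
                                       genotyping_error_rate=0.01), seed=2)
        correct = np.mean([s.sire_id == truth[s.offspring_id][0] for s in scores])
        assert correct >= 0.95

    def test_single_candidate_delta_equals_lod(self):
        m = _matrix(["kid", "sire"], [[1, 1, 2], [2, 2, 2]])
        s = assign_likelihood(m, _panel([0.5, 0.5, 0.5]), ["kid"], ["sire"],
                              LikelihoodSimulationParams(min_typed_loci=1),
                              criticals=(0.0, 0.0))[0]
        assert s.delta == s.lod
        assert s.lod > 0

    def test_fully_missing_offspring_unassigned(self):
        m = _matrix(["kid", "sire"], [[MISSING] * 3, [2, 2, 2]])
        s = assign_likelihood(m, _panel([0.5] * 3), ["kid"], ["sire"],
                              LikelihoodSimulationParams(min_typed_loci=1),
                              criticals=(0.0, 0.0))[0]
        assert s.confidence == "unassigned" and s.sire_id is None


class TestAssignApis:
    def test_certain_transmission_scores_one(self):
        m = _matrix(["kid", "s", "d"], [[1] * 4, [2] * 4, [0] * 4])
        a = assign_apis(m, _panel([0.5] * 4), ["kid"], ["s"], ["d"])[0]
        assert a.mendel1 == 1.0 and a.best_pair == ("s", "d")

    def test_half_probability_transmission(self):
        # Offspring hom-alt from hom-alt x het: per-locus probability 0.5.
        m = _matrix(["kid", "s", "d"], [[2] * 4, [2] * 4, [1] * 4])
        a = assign_apis(m, _panel([0.5] * 4), ["kid"], ["s"], ["d"])[0]
        assert a.mendel1 == pytest.approx(0.5)

    def test_true_pair_ranks_first_on_clean_data(self, parentage_sim):
        matrix, panel, truth = parentage_sim
        kids = sorted(truth)
        sires = [f"sire{i}" for i in range(25)]
        dams = [f"dam{i}" for i in range(25)]
        res = assign_apis(matrix, panel, kids, sires, dams)
        correct = np.mean([r.best_pair[0] == truth[r.offspring_id][0] for r in res])
        assert correct >= 0.95

    def test_scores_in_unit_interval_and_ranked(self, parentage_sim):
        matrix, panel, truth = parentage_sim
        res = assign_apis(matrix, panel, sorted(truth)[:10],
                          [f"sire{i}" for i in range(25)],
                          [f"dam{i}" for i in range(25)])
        for r in res:
            assert 0 <= r.mendel3 <= r.mendel2 <= r.mendel1 <= 1
            assert r.delta1 >= 0 and r.delta2 >= 0

    def test_ordering_invariant_under_locus_permutation(self, rng, parentage_sim):
        matrix, panel, truth = parentage_sim
        perm = rng.permutation(panel.n_loci)
        panel_p = SNPPanel([panel.locus_ids[i] for i in perm], "parentage",
                           ref_freq=panel.ref_freq[perm])
        kids = sorted(truth)[:10]
        sires = [f"sire{i}" for i in range(25)]
        dams = [f"dam{i}" for i in range(25)]
        a = assign_apis(matrix, panel, kids, sires, dams)
        b = assign_apis(matrix, panel_p, kids, sires, dams)
        assert [r.best_pair for r in a] == [r.best_pair for r in b]

    def test_acceptance_rate_tracks_alpha(self, parentage_sim):
        matrix, panel, truth = parentage_sim
        res = assign_apis(matrix, panel, sorted(truth),
                          [f"sire{i}" for i in range(25)],
                          [f"dam{i}" for i in range(25)], accepted_error_rate=0.10)
        frac = np.mean([r.accepted for r in res])
        assert frac == pytest.approx(0.90, abs=0.05)


class TestAssignExclusion:
    def test_opposing_homozygotes_incompatible(self):
        m = _matrix(["kid", "s"], [[2, 2], [0, 2]])
        r = assign_exclusion(m, _panel([0.5, 0.5]), ["kid"], ["s"], dam_ids=None)[0]
        assert int(r.best["mismatches"]) == 1

    def test_true_parents_have_zero_mismatches_without_noise(self):
        cfg = synth.SimulationConfig(n_sires=5, n_dams=5, n_f1=10,
                                     n_f2_backcross=0, n_f2_intercross=0,
                                     n_loci=200, frac_fixed_divergent=0.2,
                                     genotype_error_rate=0.0, missing_rate=0.0, seed=31)
        sim = synth.simulate_population(cfg)
        ped = sim.pedigree
        panel = _panel(np.full(200, 0.5))
        panel.locus_ids = sim.truth.locus_ids
        res = assign_exclusion(sim.truth, panel, ped.offspring_ids,
                               ped.sire_ids, ped.dam_ids)
        for r in res:
            sire, dam = ped.parents_of(r.offspring_id)
            row = r.table.query("sire_id == @sire and dam_id == @dam")
            assert int(row["mismatches"].iloc[0]) == 0

    def test_mismatch_count_matches_binomial_flip_oracle(self, rng):
        # Both parents hom-ref, offspring truly hom-ref; flipping the
        # offspring call to hom-alt with probability e makes exactly the
        # flipped loci incompatible, so counts are Binomial(L, e).
        L, e, n_off = 400, 0.05, 200
        flips = rng.random((n_off, L)) < e
        kids = np.where(flips, 2, 0).astype(np.int8)
        ids = ["s", "d"] + [f"k{i}" for i in range(n_off)]
        m = GenotypeMatrix(ids, [f"L{j}" for j in range(L)],
                           np.vstack([np.zeros((2, L), dtype=np.int8), kids]))
        res = assign_exclusion(m, _panel(np.full(L, 0.5)),
                               [f"k{i}" for i in range(n_off)], ["s"], ["d"])
        counts = np.array([int(r.best["mismatches"]) for r in res])
        assert (counts == flips.sum(axis=1)).all()
        mean, sd = L * e, np.sqrt(L * e * (1 - e) / n_off)
        assert abs(counts.mean() - mean) < 4 * sd
        # P(zero mismatches) = (1-e)^L, tiny at this scale.
        p0 = (1 - e) ** L
        assert abs((counts == 0).mean() - p0) < 4 * np.sqrt(p0 * (1 - p0) / n_off) + 1e-9


class TestConsensus:
    def test_identical_inputs_fully_agree(self):
        a = {"k1": "s1", "k2": "s2"}
        agreed, report = consensus(a, dict(a))
        assert agreed == a and report["n_disagree"] == 0

    def test_disjoint_inputs_empty(self):
        agreed, report = consensus({"k1": "s1"}, {"k1": "s2"})
        assert agreed == {} and report["n_disagree"] == 1

    def test_intersection_at_least_as_accurate_as_either_engine(self, parentage_sim):
        matrix, panel, truth = parentage_sim
        kids = sorted(truth)
        sires = [f"sire{i}" for i in range(25)]
        dams = [f"dam{i}" for i in range(25)]
        lik = assign_likelihood(matrix, panel, kids, sires,
                                LikelihoodSimulationParams(n_simulated_offspring=200,
                                                           n_candidate_fathers=25,
                                                           genotyping_error_rate=0.01),
                                seed=2)
        apis = assign_apis(matrix, panel, kids, sires, dams)
        agreed, _ = consensus(lik, apis)

        def acc(mapping):
            return np.mean([truth[k][0] == s for k, s in mapping.items()])

        acc_l = np.mean([s.sire_id == truth[s.offspring_id][0] for s in lik])
        acc_a = np.mean([a.best_pair[0] == truth[a.offspring_id][0] for a in apis])
        assert acc(agreed) >= max(acc_l, acc_a)

    def test_venn_counts_three_methods(self):
        v = parentage.venn_counts({
            "a": {"k1": "s1", "k2": "s2"},
            "b": {"k1": "s1", "k2": "s9"},
            "c": {"k1": "s1"},
        })
        assert v["a&b"] == 1 and v["a&b&c"] == 1 and v["a"] == 2


class TestAccuracyMonotoneInPanelSize:
    def test_more_loci_never_hurt(self, rng):
        # Same simulated families scored on nested panels of 100/500/1000
        # loci: rank-1 sire accuracy must be non-decreasing.
        n_loci, n_sires, n_off = 1000, 30, 60
        freqs = rng.uniform(0.3, 0.7, n_loci)
        sires = rng.binomial(2, 1 - freqs, (n_sires, n_loci)).astype(np.int8)
        dams = rng.binomial(2, 1 - freqs, (n_off, n_loci)).astype(np.int8)
        true_s = rng.integers(0, n_sires, n_off)
        kids = np.array([
            (rng.random(n_loci) < sires[true_s[k]] / 2.0).astype(np.int8)
            + (rng.random(n_loci) < dams[k] / 2.0).astype(np.int8)
            for k in range(n_off)])
        err = rng.random(kids.shape) < 0.05
        kids = np.where(err, rng.integers(0, 3, kids.shape), kids).astype(np.int8)
        ids = ([f"s{i}" for i in range(n_sires)] + [f"k{i}" for i in range(n_off)])
        m = GenotypeMatrix(ids, [f"L{j}" for j in range(n_loci)],
                           np.vstack([sires, kids]))
        accs = []
        for n in (100, 500, 1000):
            panel = SNPPanel([f"L{j}" for j in range(n)], "parentage",
                             ref_freq=freqs[:n])
            scores = assign_likelihood(
                m, panel, [f"k{i}" for i in range(n_off)],
                [f"s{i}" for i in range(n_sires)],
                LikelihoodSimulationParams(min_typed_loci=5,
                                           genotyping_error_rate=0.05),
                criticals=(0.0, 0.0))
            accs.append(np.mean([s.sire_id == f"s{true_s[int(s.offspring_id[1:])]}"
                                 for s in scores]))
        assert accs[0] <= accs[1] <= accs[2]
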