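"""Generator correctness: ascertainment, transmission, pedigree dependence."""

import numpy as np
import pytest

import haplasso as hp
from haplasso.core import PairSpace
from haplasso.errors import DataError, SimulationError


def pair_freq(records, space, idx, which="true_pair"):
    pairs = np.array([space.pair_index(r.__dict__[which].first,
                                       r.__dict__[which].second) for r in records])
    return np.mean(pairs == idx)


class TestCaseControl:
    def test_null_cases_follow_hwe(self, small_pool):
        hl, fv = small_pool
        reg = hp.RegressionParams(alpha=-1.0, beta=np.zeros(3))
        spec = hp.SimulationSpec(haplotypes=hl, freqs=fv, regression=reg,
                                 n_cases=2000, n_controls=0, seed=4)
        cases = hp.simulate_case_control(spec)
        space = PairSpace(hl)
        pp = space.pair_probs(fv)
        for i in range(space.n_pairs):
            assert pair_freq(cases, space, i) == pytest.approx(pp[i], abs=0.02)

    def test_case_enrichment_matches_retrospective_form(self):
        hl = hp.HaplotypeList.from_strings(["0", "1"])
        fv = hp.FrequencyVector(np.array([0.5, 0.5]))
        reg = hp.RegressionParams(alpha=0.0, beta=np.array([np.log(3.0)]))
        spec = hp.SimulationSpec(haplotypes=hl, freqs=fv, regression=reg,
                                 n_cases=4000, n_controls=4000, seed=8)
        subjects = hp.simulate_case_control(spec)
        space = PairSpace(hl)
        i11 = space.pair_index(1, 1)
        cases = [s for s in subjects if s.phenotype == 1]
        ctrls = [s for s in subjects if s.phenotype == 0]
        params = hp.ParameterVector(regression=reg, freqs=fv)
        z = hp.HaplotypePair(1, 1)
        expected_case = hp.retro_prob(z, 1, params)
        expected_ctrl = hp.retro_prob(z, 0, params)
        assert pair_freq(cases, space, i11) == pytest.approx(expected_case, abs=0.03)
        assert pair_freq(ctrls, space, i11) == pytest.approx(expected_ctrl, abs=0.03)

    def test_zero_case_quota(self, small_pool):
        hl, fv = small_pool
        reg = hp.RegressionParams(alpha=-1.0, beta=np.zeros(3))
        spec = hp.SimulationSpec(haplotypes=hl, freqs=fv, regression=reg,
                                 n_cases=0, n_controls=50, seed=1)
        subjects = hp.simulate_case_control(spec)
        assert len(subjects) == 50
        assert all(s.phenotype == 0 for s in subjects)

    def test_infeasible_penetrance_raises(self, small_pool):
        hl, fv = small_pool
        reg = hp.RegressionParams(alpha=-40.0, beta=np.zeros(3))
        spec = hp.SimulationSpec(haplotypes=hl, freqs=fv, regression=reg,
                                 n_cases=10, n_controls=0, seed=1,
                                 max_rejection_draws=20000)
        with pytest.raises(SimulationError):
            hp.simulate_case_control(spec)

    def test_fixed_seed_bitwise_identical(self, small_pool):
        hl, fv = small_pool
        reg = hp.RegressionParams(alpha=-1.0, beta=np.zeros(3))
        spec = hp.SimulationSpec(haplotypes=hl, freqs=fv, regression=reg,
                                 n_cases=30, n_controls=30, n_trios=5, seed=77)
        a = hp.simulate_case_control(spec)
        b = hp.simulate_case_control(spec)
        assert all(np.array_equal(x.genotype, y.genotype) and x.phenotype == y.phenotype
                   for x, y in zip(a, b))
        ta = hp.simulate_trios(spec)
        tb = hp.simulate_trios(spec)
        assert all(np.array_equal(x.g_child, y.g_child) for x, y in zip(ta, tb))


class TestTrios:
    def test_null_no_transmission_distortion(self, small_pool):
        hl, fv = small_pool
        reg = hp.RegressionParams(alpha=-1.0, beta=np.zeros(3))
        spec = hp.SimulationSpec(haplotypes=hl, freqs=fv, regression=reg,
                                 n_trios=2000, seed=6)
        trios = hp.simulate_trios(spec)
        K1 = len(hl)
        trans = np.zeros(K1)
        untrans = np.zeros(K1)
        for t in trios:
            for h in (t.true_child_pair.first, t.true_child_pair.second):
                trans[h] += 1
            for h in (t.true_untransmitted_pair.first, t.true_untransmitted_pair.second):
                untrans[h] += 1
        trans /= trans.sum()
        untrans /= untrans.sum()
        np.testing.assert_allclose(trans, untrans, atol=0.02)

    def test_risk_haplotype_overtransmitted(self, small_pool):
        hl, fv = small_pool
        beta = np.array([0.0, 0.0, np.log(4.0)])  # haplotype '111', f=0.1
        reg = hp.RegressionParams(alpha=-1.0, beta=beta)
        spec = hp.SimulationSpec(haplotypes=hl, freqs=fv, regression=reg,
                                 n_trios=1500, seed=6)
        trios = hp.simulate_trios(spec)
        risk = 3
        t_count = sum((t.true_child_pair.first == risk)
                      + (t.true_child_pair.second == risk) for t in trios)
        u_count = sum((t.true_untransmitted_pair.first == risk)
                      + (t.true_untransmitted_pair.second == risk) for t in trios)
        assert t_count > u_count

    def test_mendelian_consistent_by_construction(self, small_pool):
        hl, fv = small_pool
        reg = hp.RegressionParams(alpha=-1.0, beta=np.zeros(3))
        spec = hp.SimulationSpec(haplotypes=hl, freqs=fv, regression=reg,
                                 n_trios=200, seed=2)
        for t in hp.simulate_trios(spec):  # TrioRecord validates on init
            assert t.mendelian_violations().size == 0


class TestPedigrees:
    def test_requires_template(self, small_pool):
        hl, fv = small_pool
        reg = hp.RegressionParams(alpha=-1.0, beta=np.zeros(3))
        spec = hp.SimulationSpec(haplotypes=hl, freqs=fv, regression=reg,
                                 n_cases=5, n_controls=5, seed=1)
        with pytest.raises(DataError):
            hp.simulate_pedigrees(spec)

    def test_singleton_template_reduces_to_case_control(self, small_pool):
        hl, fv = small_pool
        reg = hp.RegressionParams(alpha=-1.0, beta=np.zeros(3))
        space = PairSpace(hl)
        pp = space.pair_probs(fv)
        spec = hp.SimulationSpec(
            haplotypes=hl, freqs=fv, regression=reg, n_cases=1000,
            n_controls=1000, n_trios=0,
            pedigree_template=hp.simulate.singleton_template(), seed=13)
        cc, trios = hp.simulate_pedigrees(spec)
        assert trios == []
        assert len(cc) == 2000
        for i in range(space.n_pairs):
            assert pair_freq(cc, space, i) == pytest.approx(pp[i], abs=0.03)

    def test_sibling_dosages_correlate_within_family_only(self, small_pool):
        hl, fv = small_pool
        reg = hp.RegressionParams(alpha=0.0, beta=np.zeros(3))  # everyone phenotyped
        template = hp.PedigreeTemplate((
            ("f", None, None), ("m", None, None),
            ("s1", "f", "m"), ("s2", "f", "m"),
        ))
        spec = hp.SimulationSpec(haplotypes=hl, freqs=fv, regression=reg,
                                 n_cases=4000, n_controls=4000,
                                 pedigree_template=template, seed=3)
        cc, _ = hp.simulate_pedigrees(spec)
        by_member: dict = {}
        for s in cc:
            fam, member = s.subject_id.split(":")
            by_member.setdefault(member, {})[fam] = s.genotype[0]
        fams = sorted(set(by_member["s1"]) & set(by_member["s2"]))
        x = np.array([by_member["s1"][f] for f in fams], dtype=float)
        y = np.array([by_member["s2"][f] for f in fams], dtype=float)
        within = np.corrcoef(x, y)[0, 1]
        between = np.corrcoef(x[:-1], y[1:])[0, 1]  # different families
        assert within > 0.2
        assert between == pytest.approx(0.0, abs=0.05)

    def test_gene_drop_marginals_are_hwe(self):
        # every member - founder or not - has the HWE diplotype marginal
        hl, fv = hp.block_pool()
        reg = hp.RegressionParams(alpha=0.0, beta=np.zeros(5))
        spec = hp.SimulationSpec(haplotypes=hl, freqs=fv, regression=reg,
                                 n_cases=5000, n_controls=5000,
                                 pedigree_template=hp.default_template(), seed=10)
        cc, _ = hp.simulate_pedigrees(spec)
        space = PairSpace(hl)
        pp = space.pair_probs(fv)
        grandchildren = [s for s in cc if s.subject_id.endswith(":gc")]
        assert len(grandchildren) > 1000
        for i in np.argsort(pp)[-4:]:  # the four most probable diplotypes
            assert pair_freq(grandchildren, space, i) == pytest.approx(pp[i], abs=0.02)

    def test_pool_gamete_frequencies_match(self):
        # 2000 gametes from the 7-SNP pool reproduce the generating
        # frequencies, including the 0.1663 entry
        hl, fv = hp.block_pool()
        reg = hp.RegressionParams(alpha=-1.0, beta=np.zeros(5))
        spec = hp.SimulationSpec(haplotypes=hl, freqs=fv, regression=reg,
                                 n_cases=0, n_controls=1000, seed=14)
        subjects = hp.simulate_case_control(spec)
        counts = np.zeros(len(hl))
        for s in subjects:
            counts[s.true_pair.first] += 1
            counts[s.true_pair.second] += 1
        realized = counts / counts.sum()
        np.testing.assert_allclose(realized, fv.f, atol=0.02)
        assert fv.f[hl.index_of("0101010")] == 0.1663


class TestTypeIErrorHarness:
    def test_zero_replicates_empty_table(self, small_pool):
        hl, fv = small_pool
        reg = hp.RegressionParams(alpha=-1.0, beta=np.zeros(3))
        spec = hp.SimulationSpec(haplotypes=hl, freqs=fv, regression=reg,
                                 n_cases=10, n_controls=10, seed=1)
        cfg = hp.MCMCConfig(n_iter=120, n_burn=20, n_chains=1)
        res = hp.type_I_error_study(spec, 0, cfg)
        assert res.n_replicates == 0
        assert res.table["n_tests"].sum() == 0

    def test_rejects_non_null_spec(self, small_pool):
        hl, fv = small_pool
        reg = hp.RegressionParams(alpha=-1.0, beta=np.array([0.0, 0.0, 0.5]))
        spec = hp.SimulationSpec(haplotypes=hl, freqs=fv, regression=reg,
                                 n_cases=10, n_controls=10, seed=1)
        with pytest.raises(DataError):
            hp.type_I_error_study(spec, 2, hp.MCMCConfig(n_iter=120, n_burn=20))

    def test_small_run_counts_and_determinism(self, small_pool):
        hl, fv = small_pool
        reg = hp.RegressionParams(alpha=-1.0, beta=np.zeros(3))
        spec = hp.SimulationSpec(haplotypes=hl, freqs=fv, regression=reg,
                                 n_cases=40, n_controls=40, n_trios=5, seed=21)
        cfg = hp.MCMCConfig(n_iter=150, n_burn=50, n_chains=1,
                            pool_threshold=0.02, k_update_every=50)
        r1 = hp.type_I_error_study(spec, 3, cfg, seed=5)
        r2 = hp.type_I_error_study(spec, 3, cfg, seed=5)
        assert r1.table.equals(r2.table)
        assert r1.n_failed == 0
        assert r1.table["n_tests"].sum() >= 3 * 3  # >= K rows per replicate
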