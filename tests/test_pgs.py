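import numpy as np
import pandas as pd
import pytest
from scipy import stats

from amlink import (
    GenotypeMatrix,
    MISSING,
    SimConfig,
    odd_even_theta,
    ptdt,
    score,
    sd_filter,
    simulate_dataset,
    theta_from_scores,
)
from amlink.pgs import PgsError, PgsResult

from conftest import make_variants, quartet_pedigree


class TestSdFilter:
    def test_printed_formula_evaluation(self):
        """se=0.02, n_case=n_control=10000, AF=0.5: n_eff=20000 and
        SD_ss = SD_test = 0.7071 -> kept."""
        t = pd.DataFrame({"se": [0.02], "n_case": [10_000], "n_control": [10_000]})
        n_eff = 4 / (1 / 10_000 + 1 / 10_000)
        assert n_eff == 20_000
        sd_ss = 2 / (0.02 * np.sqrt(n_eff))
        assert sd_ss == pytest.approx(0.7071, abs=1e-4)
        assert sd_filter(t, np.array([0.5]))[0]

    def test_rare_allele_removed_by_sd_test_floor(self):
        t = pd.DataFrame({"se": [0.02], "n_case": [10_000], "n_control": [10_000]})
        af = np.array([0.0005])
        assert np.sqrt(2 * af[0] * (1 - af[0])) == pytest.approx(0.0316, abs=1e-4)
        assert not sd_filter(t, af)[0]

    def test_huge_se_removed_by_sd_ss_floor(self):
        # SD_ss = 2/(se*sqrt(n_eff)) = 0.05 < 0.1
        t = pd.DataFrame({"se": [2 / (0.05 * np.sqrt(20_000))],
                          "n_case": [10_000], "n_control": [10_000]})
        assert not sd_filter(t, np.array([0.5]))[0]

    def test_quantitative_branch(self):
        t = pd.DataFrame({"se": [1 / (0.7 * np.sqrt(50_000))], "n": [50_000]})
        assert sd_filter(t, np.array([0.5]), binary=False)[0]


class TestScore:
    def _matrix(self, dosages):
        d = np.asarray(dosages, dtype=np.int8)
        return GenotypeMatrix([f"i{k}" for k in range(d.shape[0])],
                              make_variants(d.shape[1]), d)

    def _weights(self, betas):
        return pd.DataFrame({"variant_index": range(len(betas)), "beta": betas,
                             "id": [f"snp{i}" for i in range(len(betas))]})

    def test_zero_weights_zero_scores(self):
        G = self._matrix([[0, 1], [2, 1], [1, 0]])
        res = score(G, self._weights([0.0, 0.0]), G.samples)
        assert (res.scores["raw"] == 0).all()

    def test_single_variant_is_dosage(self):
        G = self._matrix([[0], [1], [2]])
        res = score(G, self._weights([1.0]), G.samples)
        np.testing.assert_allclose(res.scores["raw"], [0, 1, 2])

    def test_missing_dosage_mean_imputed(self):
        # founder mean dosage of the variant is (2+1+0+2+1)/5 = 1.2
        G = self._matrix([[2], [1], [0], [2], [1], [MISSING]])
        res = score(G, self._weights([1.0]), G.samples[:5])
        assert res.scores["raw"].iloc[5] == pytest.approx(1.2)

    def test_founder_standardization(self):
        rng = np.random.default_rng(0)
        G = self._matrix(rng.integers(0, 3, (50, 10)))
        res = score(G, self._weights(rng.normal(size=10)), G.samples[:30])
        s = res.scores.loc[G.samples[:30], "standardized"]
        assert abs(s.mean()) < 1e-10
        assert s.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_no_overlap_is_error(self):
        G = self._matrix([[0], [1]])
        with pytest.raises(PgsError):
            score(G, self._weights([])[0:0], G.samples)


def _pgs_from_values(values: dict) -> PgsResult:
    df = pd.DataFrame({"raw": pd.Series(values)})
    df["standardized"] = df["raw"]
    return PgsResult(df, n_variants_used=1, founder_ids=list(values))


class TestPtdt:
    def test_children_at_midparent_give_zero(self):
        ped = quartet_pedigree(3)
        values = {}
        for i, fam in enumerate(ped):
            values[fam.father_id] = float(i)
            values[fam.mother_id] = float(i + 1)
            values[fam.proband_id] = float(i) + 0.5
        res = ptdt(_pgs_from_values(values), ped)
        assert res.mean_deviation == 0.0
        assert res.t == 0.0

    def test_hand_computed_deviations(self):
        """Midparent scores (0,1,2) and children (1,2,4): deviations
        (1,1,2), mean 4/3, t = 4.0."""
        ped = quartet_pedigree(3)
        values = {}
        for fam, (mid, child) in zip(ped, [(0, 1), (1, 2), (2, 4)]):
            values[fam.father_id] = float(mid)
            values[fam.mother_id] = float(mid)
            values[fam.proband_id] = float(child)
        res = ptdt(_pgs_from_values(values), ped)
        assert res.mean_deviation == pytest.approx(4 / 3)
        assert res.t == pytest.approx(4.0, abs=1e-10)
        assert res.ci_low <= res.mean_deviation <= res.ci_high

    def test_degenerate_midparent_sd_is_error(self):
        ped = quartet_pedigree(3)
        values = {}
        for fam in ped:
            values[fam.father_id] = 1.0
            values[fam.mother_id] = 1.0
            values[fam.proband_id] = 2.0
        with pytest.raises(PgsError):
            ptdt(_pgs_from_values(values), ped)

    def test_ascertained_probands_overtransmitted_siblings_null(self, quartet_sim):
        """Liability-threshold ascertainment drives proband scores above the
        midparent; unaffected siblings stay consistent with it."""
        sim = quartet_sim
        weights = pd.DataFrame({
            "variant_index": sim.causal_index,
            "beta": sim.causal_beta,
            "id": sim.genotypes.variants["id"].iloc[sim.causal_index]})
        res = score(sim.genotypes, weights, sim.pedigree.founder_ids())
        pro = ptdt(res, sim.pedigree, child_role="proband")
        sib = ptdt(res, sim.pedigree, child_role="sibling")
        assert pro.mean_deviation > 0 and pro.p < 0.05
        assert abs(sib.mean_deviation) < 0.15


class TestTheta:
    def test_identical_scores_give_theta_one(self):
        rng = np.random.default_rng(0)
        s = rng.standard_normal(500)
        pcs = rng.standard_normal((500, 5))
        res = theta_from_scores(s, s.copy(), pcs, pcs)
        assert res.theta_odd_on_even == pytest.approx(1.0, abs=1e-10)
        assert res.theta_combined == pytest.approx(1.0, abs=1e-10)

    def test_independent_scores_give_null_theta(self):
        rng = np.random.default_rng(1)
        n_reps = 100
        hits = 0
        for _ in range(n_reps):
            s_o = rng.standard_normal(2000)
            s_e = rng.standard_normal(2000)
            pcs = rng.standard_normal((2000, 20))
            res = theta_from_scores(s_o, s_e, pcs, pcs)
            if abs(res.theta_combined) < 0.08 and res.p_odd_on_even > 0.05:
                hits += 1
        assert hits >= 0.9 * n_reps

    def test_score_matched_spouses_induce_positive_theta(self):
        """One generation of direct assortment on the score makes the
        offspring's odd- and even-chromosome scores positively correlated."""
        sim = simulate_dataset(SimConfig(
            n_snps=600, n_causal=300, n_families=1000, h2=1.0,
            rho_ancestry=0.0, rho_trait=0.4, fst=0.0,
            ascertain_simplex=False, seed=61))
        weights = pd.DataFrame({
            "variant_index": sim.causal_index,
            "beta": sim.causal_beta,
            "id": sim.genotypes.variants["id"].iloc[sim.causal_index]})
        children = sim.pedigree.child_ids()
        res = odd_even_theta(sim.genotypes, weights, children, k=20)
        assert res.theta_combined > 0
        assert min(res.p_odd_on_even, res.p_even_on_odd) < 0.05

    def test_ancestry_only_assortment_leaves_theta_null(self):
        """Ancestry-related AM with ancestry-independent weights: after PC
        adjustment the odd/even score correlation is consistent with zero."""
        sim = simulate_dataset(SimConfig(
            n_snps=600, n_causal=300, n_families=1000, h2=0.5,
            rho_ancestry=0.5, rho_trait=0.0, fst=0.01,
            ascertain_simplex=False, seed=67))
        rng = np.random.default_rng(5)
        weights = pd.DataFrame({
            "variant_index": np.arange(sim.genotypes.n_variants),
            "beta": rng.standard_normal(sim.genotypes.n_variants) * 0.05,
            "id": sim.genotypes.variants["id"]})
        children = sim.pedigree.child_ids()
        res = odd_even_theta(sim.genotypes, weights, children, k=20)
        assert abs(res.theta_combined) < 0.1
        assert res.p_odd_on_even > 0.05
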