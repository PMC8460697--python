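"""Candidate-CpG association scan, technical residualization, and the
clump-and-threshold polygenic score."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from artgrowth.measures import bonferroni_threshold
from artgrowth.methylation import (candidate_cpg_scan, clump, clump_and_score,
                                   residualize_technical)
from artgrowth.synthetic import simulate_genotypes


class TestResidualize:
    def _matrix(self, n=120, k=4, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(size=(n, k)),
                            columns=[f"cg{i:07d}" for i in range(k)])

    def test_constant_covariates_give_centered_input(self):
        B = self._matrix()
        tech = pd.DataFrame({"batch": ["A"] * len(B)})
        R = residualize_technical(B, tech)
        expected = B - B.mean()
        assert np.allclose(R.to_numpy(), expected.to_numpy(), atol=1e-12)

    def test_pure_batch_shift_removed_exactly(self):
        B = self._matrix(seed=1)
        batch = np.array(["A", "B"] * (len(B) // 2))
        B2 = B.add(pd.Series((batch == "B") * 0.2, index=B.index), axis=0)
        R = residualize_technical(B2, pd.DataFrame({"batch": batch}))
        diff = R[batch == "B"].mean() - R[batch == "A"].mean()
        assert np.max(np.abs(diff.to_numpy())) < 1e-10

    def test_residuals_orthogonal_to_technical_columns(self):
        rng = np.random.default_rng(2)
        B = self._matrix(seed=3)
        tech = pd.DataFrame({"chip_pos": rng.choice(list("xyz"), len(B)),
                             "extraction": rng.normal(size=len(B))})
        R = residualize_technical(B, tech)
        X = pd.get_dummies(tech, drop_first=True, dtype=float)
        for col in X:
            for cg in R:
                r = np.corrcoef(R[cg], X[col])[0, 1]
                assert abs(r) < 1e-10

    def test_rank_deficient_design_names_aliased(self):
        B = self._matrix(seed=4)
        dup = np.tile(["A", "B"], len(B) // 2)
        tech = pd.DataFrame({"b1": dup, "b2": dup})  # aliased duplicate
        with pytest.raises(ValueError, match="aliased"):
            residualize_technical(B, tech)


class TestCpgScan:
    def test_printed_bonferroni_bounds(self):
        assert f"{bonferroni_threshold(0.05, 187):.1e}" == "2.7e-04"
        assert f"{bonferroni_threshold(0.05, 281):.1e}" == "1.8e-04"

    def test_absent_columns_skipped_not_fatal(self, frame72):
        assoc, skipped = candidate_cpg_scan(frame72,
                                            ["cpg_cg03904042", "cpg_none"])
        assert skipped == ["cpg_none"]
        assert len(assoc) == 1
        assert assoc[0].n > 0

    def test_detects_planted_signal(self, frame72):
        """The default generator plants a strong negative treatment
        effect on the fetal CpG; the scan should flag it."""
        assoc, _ = candidate_cpg_scan(frame72, ["cpg_cg03904042"])
        assert assoc[0].beta < 0
        assert assoc[0].p < 0.05

    def test_power_matches_noncentral_t_oracle(self):
        """ART effect -0.1 SD, n about 1200, noise SD 1: empirical
        detection power at alpha 0.05 matches the closed-form normal
        approximation within 5 points."""
        n, n1 = 1177, 83
        effect = -0.1
        alpha = 0.05
        rng = np.random.default_rng(0)
        art = np.zeros(n)
        art[:n1] = 1.0
        se_truth = np.sqrt(1 / n1 + 1 / (n - n1))
        ncp = effect / se_truth
        zcrit = stats.norm.ppf(1 - alpha / 2)
        power_theory = (stats.norm.cdf(-zcrit - ncp)
                        + stats.norm.sf(zcrit - ncp))
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            y = effect * art + rng.normal(0, 1, n)
            df = pd.DataFrame({"art": art, "cpg_x": y})
            assoc, _ = candidate_cpg_scan(df, ["cpg_x"], covariates=())
            hits += assoc[0].p < alpha
        assert abs(hits / n_rep - power_theory) < 0.05

    def test_null_p_values_uniform(self):
        """Global null: two-sided p-values across 200 null CpGs are
        consistent with uniformity (KS p > 0.01)."""
        rng = np.random.default_rng(5)
        n = 1000
        art = (rng.random(n) < 0.07).astype(float)
        cols = {f"cpg_{i:03d}": rng.normal(size=n) for i in range(200)}
        df = pd.DataFrame({"art": art, **cols})
        assoc, _ = candidate_cpg_scan(df, list(cols), covariates=())
        ps = [a.p for a in assoc]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestClumping:
    def _mini(self):
        """3 SNPs within 250 kb, pairwise correlated beyond 0.5."""
        rng = np.random.default_rng(1)
        base = rng.integers(0, 3, 300).astype(float)
        noisy = lambda: np.clip(base + (rng.random(300) < 0.05), 0, 2)
        geno = pd.DataFrame({"subject_id": [f"S{i}" for i in range(300)],
                             "rs1": base, "rs2": noisy(), "rs3": noisy()})
        meta = pd.DataFrame({
            "snp_id": ["rs1", "rs2", "rs3"],
            "chromosome": [1, 1, 1],
            "position": [100_000, 150_000, 200_000],
            "gwas_beta": [0.1, 0.2, 0.3],
            "gwas_p": [1e-8, 1e-6, 1e-3],
        })
        return geno, meta

    def test_most_significant_index_survives(self):
        geno, meta = self._mini()
        kept = clump(geno, meta, 250_000, 0.5)
        assert kept == ["rs1"]

    def test_order_invariance(self):
        geno, meta = self._mini()
        shuffled = meta.iloc[[2, 0, 1]].reset_index(drop=True)
        assert clump(geno, shuffled, 250_000, 0.5) == clump(geno, meta, 250_000, 0.5)

    def test_uncorrelated_snps_all_kept(self):
        rng = np.random.default_rng(2)
        geno = pd.DataFrame({"subject_id": [f"S{i}" for i in range(500)],
                             "rsA": rng.integers(0, 3, 500).astype(float),
                             "rsB": rng.integers(0, 3, 500).astype(float)})
        meta = pd.DataFrame({"snp_id": ["rsA", "rsB"], "chromosome": [1, 1],
                             "position": [1, 2], "gwas_beta": [0.1, -0.2],
                             "gwas_p": [1e-4, 1e-3]})
        assert set(clump(geno, meta, 250_000, 0.5)) == {"rsA", "rsB"}

    def test_weighted_sum_arithmetic(self):
        geno = pd.DataFrame({"subject_id": ["S0"], "rsA": [2.0], "rsB": [1.0]})
        meta = pd.DataFrame({"snp_id": ["rsA", "rsB"], "chromosome": [1, 2],
                             "position": [1, 1], "gwas_beta": [0.1, -0.2],
                             "gwas_p": [1e-9, 1e-9]})
        eth = pd.Series(["chinese"])
        res = clump_and_score(geno, meta, eth)
        assert res.scores["raw"].iloc[0] == pytest.approx(0.1 * 2 - 0.2 * 1)


class TestPrs:
    def test_standardized_within_ethnicity(self):
        geno, meta = simulate_genotypes(400, 40, seed=3)
        rng = np.random.default_rng(4)
        eth = pd.Series(rng.choice(["chinese", "malay", "indian"], 400))
        anchors = pd.DataFrame({"birth_weight": rng.normal(3.2, 0.4, 400),
                                "bmi": rng.normal(16, 2, 400)})
        res = clump_and_score(geno, meta, eth, anchors)
        for group, grp in res.scores.groupby("ethnicity"):
            assert abs(grp["standardized"].mean()) < 1e-8
            assert grp["standardized"].var(ddof=0) == pytest.approx(1.0, abs=1e-6)
        assert set(res.chosen_thresholds) == set(eth.unique())

    def test_anchor_correlation_selects_informative_threshold(self):
        """When the anchors are literally generated from the large-effect
        SNPs, a threshold retaining them should win over one retaining
        nothing relevant."""
        geno, meta = simulate_genotypes(500, 30, seed=6)
        meta = meta.copy()
        # make the 3 most significant SNPs causal for the anchor
        top = meta.nsmallest(3, "gwas_p")["snp_id"].tolist()
        signal = geno[top].to_numpy() @ np.array([0.5, 0.4, 0.3])
        rng = np.random.default_rng(7)
        anchors = pd.DataFrame({"birth_weight": signal + rng.normal(0, 0.3, 500)})
        meta.loc[meta.snp_id.isin(top), "gwas_beta"] = [0.5, 0.4, 0.3]
        eth = pd.Series(["chinese"] * 500)
        res = clump_and_score(geno, meta, eth, anchors)
        thresh = res.chosen_thresholds["chinese"]
        assert max(meta.loc[meta.snp_id.isin(top), "gwas_p"]) <= thresh
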