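"""Spirometry QC, variant QC, association scan, clumping, and selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import pulmo_mr as pm
from pulmo_mr.containers import BlowSeries
from pulmo_mr.gwas import qc_blow
from tests.conftest import make_panel


class TestBlowQC:
    @pytest.mark.parametrize(
        "blows, expect_pass, expect_best",
        [
            ([2.0], False, 2.0),                # single blow: reproducibility unknown
            ([2.0, 2.1, 2.2], True, 2.2),       # 2.1 within 0.15 L of best
            ([1.5, 1.8], False, 1.8),           # 0.3 L apart: non-reproducible
            ([2.0, 2.14], True, 2.14),          # just inside the 0.15 L rule
            ([2.0, 2.16], False, 2.16),         # just outside
        ],
    )
    def test_reproducibility_rule(self, blows, expect_pass, expect_best):
        ok, best = qc_blow(np.array(blows))
        assert ok is expect_pass
        assert best == pytest.approx(expect_best)

    def test_both_measures_must_pass(self):
        s = BlowSeries("x", fev1=[2.0, 2.1], fvc=[3.0, 3.5])
        qc = pm.qc_spirometry([s])
        assert not qc["qc_pass"].iloc[0]

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            pm.qc_spirometry([])


class TestPhenotypes:
    def _qc_frame(self, fev1, fvc):
        return pd.DataFrame(
            {
                "individual_id": [f"i{k}" for k in range(len(fev1))],
                "qc_pass": True,
                "best_fev1": fev1,
                "best_fvc": fvc,
            }
        )

    def test_copd_flag_at_ratio_below_0_70(self):
        ph = pm.derive_phenotypes(self._qc_frame([2.0, 3.0], [4.0, 4.1]))
        assert ph.ratio[0] == pytest.approx(0.5)
        assert ph.copd[0] and not ph.copd[1]

    def test_zscore_normalization_identity(self):
        rng = np.random.default_rng(1)
        ph = pm.derive_phenotypes(
            self._qc_frame(rng.uniform(1, 4, 500), rng.uniform(2, 6, 500))
        )
        assert abs(ph.fev1_z.mean()) < 1e-10
        assert abs(ph.fev1_z.std() - 1) < 1e-10

    def test_constant_phenotype_rejected(self):
        with pytest.raises(ValueError):
            pm.derive_phenotypes(self._qc_frame([2.0] * 5, [3.0, 3.1, 3.2, 3.3, 3.4]))


class TestHweExact:
    def test_perfect_hwe_proportions(self):
        assert pm.hwe_exact_test(50, 25, 25) == pytest.approx(1.0)

    def test_extreme_departure(self):
        assert pm.hwe_exact_test(0, 50, 50) < 1e-5

    def test_matches_enumeration_oracle(self):
        # independent oracle: exact probabilities by integer arithmetic
        from fractions import Fraction
        from math import comb

        def oracle(het, hom_min, hom_maj):
            n = het + hom_min + hom_maj
            na = 2 * hom_min + het
            if na > n:
                na = 2 * n - na
            probs = {}
            total = Fraction(0)
            start = na % 2
            for h in range(start, na + 1, 2):
                hmin = (na - h) // 2
                hmaj = n - h - hmin
                if hmaj < 0:
                    continue
                ways = Fraction(2**h) * comb(n, h) * comb(n - h, hmin)
                probs[h] = ways
                total += ways
            p_obs = probs[het] / total
            return float(sum(p for p in (w / total for w in probs.values()) if p <= p_obs))

        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(10, 200))
            het = int(rng.integers(0, n + 1))
            hom_min = int(rng.integers(0, n - het + 1))
            hom_maj = n - het - hom_min
            expected = oracle(het, hom_min, hom_maj)
            assert pm.hwe_exact_test(het, hom_min, hom_maj) == pytest.approx(
                expected, rel=1e-9, abs=1e-12
            )


class TestVariantQC:
    def test_hwe_failure_removed(self):
        # 50 AA / 0 Aa / 50 aa: gross heterozygote deficit
        col_bad = np.array([0.0] * 50 + [2.0] * 50)
        col_good = np.array([0.0] * 25 + [1.0] * 50 + [2.0] * 25)
        panel = make_panel(np.column_stack([col_bad, col_good]))
        qc = pm.variant_qc(panel)
        assert bool(qc["fail_hwe"][0]) and not bool(qc["fail_hwe"][1])
        assert not bool(qc["retained"][0]) and bool(qc["retained"][1])

    def test_low_maf_removed(self):
        rare = np.zeros(1000)
        rare[0] = 1.0  # MAF 0.0005 < 0.005
        common = np.array([0, 1, 2] * 333 + [1], dtype=float)
        panel = make_panel(np.column_stack([rare, common]))
        qc = pm.variant_qc(panel)
        assert bool(qc["fail_maf"][0]) and not bool(qc["fail_maf"][1])

    def test_poor_call_rate_removed(self):
        # dosages far from integers count as missing at the 0.1 hard-call rule
        fuzzy = np.full(100, 0.5)
        fuzzy[:4] = 1.0
        clean = np.array([0, 1, 2, 1] * 25, dtype=float)
        panel = make_panel(np.column_stack([fuzzy, clean]))
        qc = pm.variant_qc(panel)
        assert bool(qc["fail_call_rate"][0]) and not bool(qc["fail_call_rate"][1])
        assert (qc["info_filter"] == "skipped").all()


class TestRunGwas:
    def test_noiseless_single_variant(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, 200).astype(float)
        panel = make_panel(g[:, None])
        y = 0.5 * g + 1e-9 * rng.standard_normal(200)
        out = pm.run_gwas(panel, y)
        assert out["BETA"][0] == pytest.approx(0.5, abs=1e-6)

    def test_null_lambda_gc_near_one(self):
        panel = pm.simulate_genotype_panel(800, 500, block_size=1, seed=2)
        y = np.random.default_rng(3).standard_normal(800)
        out = pm.run_gwas(panel, y)
        assert 0.8 <= out.attrs["lambda_gc"] <= 1.2

    def test_permuted_phenotype_gives_uniform_p(self):
        panel = pm.simulate_genotype_panel(500, 1000, block_size=1, seed=4)
        rng = np.random.default_rng(5)
        y = rng.permutation(rng.standard_normal(500))
        out = pm.run_gwas(panel, y)
        ks = stats.kstest(out["P"], "uniform")
        assert ks.pvalue > 0.01

    def test_collinear_covariates_rejected(self):
        panel = pm.simulate_genotype_panel(50, 3, seed=6)
        y = np.random.default_rng(7).standard_normal(50)
        dup = np.ones((50, 2))
        with pytest.raises(ValueError):
            pm.run_gwas(panel, y, covariates=dup)

    def test_covariate_adjustment_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        panel = pm.simulate_genotype_panel(300, 4, block_size=1, seed=9)
        cov = rng.standard_normal((300, 2))
        y = panel.dosages[:, 0] * 0.3 + cov @ [0.5, -0.2] + rng.standard_normal(300)
        out = pm.run_gwas(panel, y, covariates=cov)
        X = sm.add_constant(np.column_stack([panel.dosages[:, 0], cov]))
        ref = sm.OLS(y, X).fit()
        assert out["BETA"][0] == pytest.approx(ref.params[1], rel=1e-10)
        assert out["SE"][0] == pytest.approx(ref.bse[1], rel=1e-10)

    def test_causal_variant_sensitivity(self):
        # variants explaining >= 0.1% of variance each are found at 5e-8
        n, j = 50_000, 25
        panel = pm.simulate_genotype_panel(n, 50, block_size=1, seed=10)
        rng = np.random.default_rng(11)
        g = panel.dosages[:, :j]
        g = (g - g.mean(0)) / g.std(0)
        per_sd = np.sqrt(0.0012)  # per-variant r^2 slightly above 0.001
        y = g @ np.full(j, per_sd) + rng.standard_normal(n) * np.sqrt(1 - j * 0.0012)
        out = pm.run_gwas(panel, y)
        sens = (out["P"][:j] < 5e-8).mean()
        assert sens >= 0.9


class TestClump:
    def _correlated_panel(self):
        rng = np.random.default_rng(1)
        base = rng.integers(0, 3, 2000).astype(float)
        noise = rng.integers(0, 3, 2000).astype(float)
        v2 = np.where(rng.uniform(size=2000) < 0.9, base, noise)  # r2 ~ 0.8 with base
        indep = rng.integers(0, 3, 2000).astype(float)
        return make_panel(
            np.column_stack([base, v2, indep]), pos=[1000, 2000, 3000]
        )

    def test_hand_traced_greedy_pass(self):
        panel = self._correlated_panel()
        stats_table = pd.DataFrame(
            {"SNP": ["rs0", "rs1", "rs2"], "CHR": 1, "POS": [1000, 2000, 3000],
             "P": [1e-10, 1e-9, 1e-8]}
        )
        kept = pm.clump(stats_table, panel)
        assert kept == ["rs0", "rs2"]

    def test_independent_variants_all_kept(self):
        panel = make_panel(
            np.random.default_rng(2).integers(0, 3, (2000, 5)).astype(float)
        )
        stats_table = pd.DataFrame(
            {"SNP": panel.variant_ids, "CHR": 1, "POS": panel.pos,
             "P": [1e-9] * 5}
        )
        assert len(pm.clump(stats_table, panel)) == 5

    def test_duplicate_variants_tie_keeps_one(self):
        g = np.random.default_rng(3).integers(0, 3, 500).astype(float)
        panel = make_panel(np.column_stack([g, g]), pos=[1000, 2000])
        stats_table = pd.DataFrame(
            {"SNP": ["rs0", "rs1"], "CHR": 1, "POS": [1000, 2000], "P": [1e-9, 1e-9]}
        )
        kept = pm.clump(stats_table, panel)
        assert kept == ["rs0"]  # tie broken by position

    def test_row_order_invariance_and_bruteforce_oracle(self):
        panel = pm.simulate_genotype_panel(1500, 40, block_size=4, rho=0.95, seed=4)
        rng = np.random.default_rng(5)
        stats_table = pd.DataFrame(
            {"SNP": panel.variant_ids, "CHR": panel.chrom, "POS": panel.pos,
             "P": rng.uniform(1e-12, 1e-6, 40)}
        )
        kept = pm.clump(stats_table, panel)
        shuffled = stats_table.sample(frac=1, random_state=6).reset_index(drop=True)
        assert pm.clump(shuffled, panel) == kept

        # oracle: verify the greedy postconditions directly from all pairs
        kept_idx = [panel.index_of(s) for s in kept]
        p_lookup = stats_table.set_index("SNP")["P"]
        for a_pos, a in enumerate(kept_idx):
            for b in kept_idx[a_pos + 1:]:
                if panel.chrom[a] == panel.chrom[b] and abs(
                    int(panel.pos[a]) - int(panel.pos[b])
                ) <= 10_000_000:
                    assert panel.ld_r2(a, b) < 0.05
        for snp in stats_table["SNP"]:
            if snp in kept:
                continue
            j = panel.index_of(snp)
            partners = [
                a for a in kept_idx
                if panel.chrom[a] == panel.chrom[j]
                and abs(int(panel.pos[a]) - int(panel.pos[j])) <= 10_000_000
                and panel.ld_r2(a, j) >= 0.05
                and p_lookup[panel.variant_ids[a]] <= p_lookup[snp]
            ]
            assert partners, f"{snp} discarded without a retained index partner"

    def test_missing_variant_rejected(self):
        panel = make_panel(np.zeros((10, 1)) + 1.0)
        stats_table = pd.DataFrame(
            {"SNP": ["rs_unknown"], "CHR": 1, "POS": [1], "P": [1e-9]}
        )
        with pytest.raises(KeyError):
            pm.clump(stats_table, panel)


class TestSelectInstruments:
    def _tables(self, p_disc, p_repl, sign=1.0):
        g = np.random.default_rng(1).integers(0, 3, (500, 1)).astype(float)
        panel = make_panel(g)
        disc = pd.DataFrame(
            {"SNP": ["rs0"], "CHR": 1, "POS": [1000], "A1": "A", "A2": "G",
             "EAF": 0.3, "BETA": [0.1], "SE": [0.01], "P": [p_disc], "N": 1000}
        )
        repl = pd.DataFrame(
            {"SNP": ["rs0"], "CHR": 1, "POS": [1000], "A1": "A", "A2": "G",
             "EAF": 0.3, "BETA": [0.08 * sign], "SE": [0.02], "P": [p_repl], "N": 400}
        )
        return disc, repl, panel

    def test_two_stage_thresholds(self):
        disc, repl, panel = self._tables(1e-9, 0.01)
        assert pm.select_instruments(disc, repl, panel).n_instruments == 1

    def test_opposite_sign_rejected(self):
        disc, repl, panel = self._tables(1e-9, 0.01, sign=-1.0)
        assert pm.select_instruments(disc, repl, panel).n_instruments == 0

    def test_subthreshold_discovery_rejected(self):
        disc, repl, panel = self._tables(1e-7, 0.01)
        assert pm.select_instruments(disc, repl, panel).n_instruments == 0

    def test_selection_monotone_in_thresholds(self):
        panel = pm.simulate_genotype_panel(4000, 30, block_size=1, seed=2)
        rng = np.random.default_rng(3)
        y = panel.dosages[:, :10] @ rng.normal(0.1, 0.02, 10) + rng.standard_normal(4000)
        from pulmo_mr.synthetic import split_panel

        pd_, pr_ = split_panel(panel, 2800)
        disc = pm.run_gwas(pd_, y[:2800])
        repl = pm.run_gwas(pr_, y[2800:])
        loose = pm.select_instruments(disc, repl, pd_, discovery_p=5e-6,
                                      replication_p=0.10)
        tight_d = pm.select_instruments(disc, repl, pd_, discovery_p=5e-8,
                                        replication_p=0.10)
        tight_r = pm.select_instruments(disc, repl, pd_, discovery_p=5e-6,
                                        replication_p=0.05)
        assert set(tight_d.variant_ids) <= set(loose.variant_ids)
        assert set(tight_r.variant_ids) <= set(loose.variant_ids)


class TestInstrumentStrength:
    def test_single_strong_variant_closed_form(self):
        r2, f = pm.instrument_strength(np.array([10.0]), 10_000)
        assert r2 == pytest.approx(100 / 10_098, rel=1e-12)
        # F = r2 (n-1-J) / ((1-r2) J) with J=1 reduces to z^2 exactly
        assert f == pytest.approx(100.0, rel=1e-9)

    def test_null_variant(self):
        r2, f = pm.instrument_strength(np.array([0.0]), 10_000)
        assert r2 == 0.0 and f == 0.0

    def test_two_variants_formula(self):
        # per-variant r2 = 0.01 needs z^2 = 0.01 * (n - 2) / 0.99
        z = np.sqrt(0.01 * 9998 / 0.99)
        r2, f = pm.instrument_strength(np.array([z, z]), 10_000)
        assert r2 == pytest.approx(0.02, rel=1e-12)
        assert f == pytest.approx(0.02 * 9997 / (0.98 * 2), rel=1e-12)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            pm.instrument_strength(np.array([1.0, 2.0]), 3)


@settings(deadline=None, max_examples=25)
@given(
    z=st.floats(0.0, 50.0),
    n=st.integers(100, 1_000_000),
)
def test_per_variant_r2_stays_in_unit_interval(z, n):
    r2, f = pm.instrument_strength(np.array([z]), n)
    assert 0.0 <= r2 < 1.0
    assert f >= 0.0
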