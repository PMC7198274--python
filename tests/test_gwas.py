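import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybridgp.architecture import fit_gblup
from hybridgp.genotypes import additive_kinship, dominance_kinship
from hybridgp.gwas import (
    bh_fdr,
    emmax_scan,
    select_high_confidence,
    snp_max_wpip,
    wpip,
)
from hybridgp.reml import fit_reml, wald_test
from hybridgp.simulate import SimulationConfig, simulate_study


class TestBhFdr:
    def test_hand_computed_step_up(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.5]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_single_p(self):
        assert bh_fdr(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_all_equal(self):
        q = bh_fdr(np.full(7, 0.3))
        assert np.allclose(q, 0.3)

    def test_matches_reference_implementation(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(rng.integers(5, 200))
            q = bh_fdr(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(q, ref)

    def test_nan_handling(self):
        q = bh_fdr(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], bh_fdr(np.array([0.01, 0.5])))


class TestWpip:
    def test_single_snp_example(self):
        out = wpip(np.array([0.6]), np.array(["1"]), np.array([100_000]))
        w0 = out[(out["start"] == 0)]["wpip"].iloc[0]
        assert w0 == pytest.approx(0.6)
        # a window starting past the SNP would score 0, but the last window
        # anchored at or before the SNP is the one at 0 here
        assert out["wpip"].sum() == pytest.approx(0.6)

    def test_two_snps_one_window(self):
        out = wpip(np.array([0.3, 0.3]), np.array(["1", "1"]), np.array([10_000, 20_000]))
        assert out[out["start"] == 0]["wpip"].iloc[0] == pytest.approx(0.6)

    def test_matches_bruteforce_double_loop(self, rng):
        m = 1000
        chrom = rng.choice(["1", "2"], size=m)
        pos = rng.integers(0, 5_000_000, size=m)
        pips = rng.random(m)
        out = wpip(pips, chrom, pos)
        for row in out.sample(min(100, len(out)), random_state=1).itertuples(index=False):
            inside = (chrom == row.chrom) & (pos >= row.start) & (pos < row.start + 500_000)
            assert row.wpip == pytest.approx(pips[inside].sum(), abs=1e-12)

    def test_even_windows_partition_total_pip(self, rng):
        m = 500
        chrom = np.full(m, "1")
        pos = rng.integers(0, 3_000_000, size=m)
        pips = rng.random(m)
        out = wpip(pips, chrom, pos)
        even = out[out["start"] % 500_000 == 0]
        assert even["wpip"].sum() == pytest.approx(pips.sum())


class TestSelectHighConfidence:
    def _windows(self, chrom, pos, pips):
        return wpip(pips, chrom, pos)

    def test_no_fdr_pass_gives_empty(self):
        tab = pd.DataFrame(
            {"snp_id": ["a"], "chrom": ["1"], "pos": [100], "p_beta": [0.9]}
        )
        windows = self._windows(tab["chrom"].to_numpy(), tab["pos"].to_numpy(), np.array([1.0]))
        out = select_high_confidence(tab, windows)
        assert len(out) == 0

    def test_pruning_within_one_mb(self):
        tab = pd.DataFrame(
            {
                "snp_id": ["a", "b"],
                "chrom": ["1", "1"],
                "pos": [100_000, 1_000_000],  # 0.9 Mb apart
                "p_beta": [1e-8, 1e-6],
            }
        )
        windows = self._windows(
            tab["chrom"].to_numpy(), tab["pos"].to_numpy(), np.array([0.9, 0.9])
        )
        out = select_high_confidence(tab, windows)
        assert out["snp_id"].tolist() == ["a"]

    def test_matches_exhaustive_pruning_oracle(self, rng):
        m = 300
        tab = pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(m)],
                "chrom": rng.choice(["1", "2"], size=m),
                "pos": rng.integers(0, 8_000_000, size=m),
                "p_beta": rng.random(m) ** 4,
            }
        )
        pips = rng.random(m)
        windows = self._windows(tab["chrom"].to_numpy(), tab["pos"].to_numpy(), pips)
        out = select_high_confidence(tab, windows)

        # oracle: recompute candidacy and greedy pruning from scratch
        q = bh_fdr(tab["p_beta"].to_numpy())
        maxw = np.zeros(m)
        for i in range(m):
            cw = windows[windows["chrom"] == tab["chrom"][i]]
            cover = cw[(cw["start"] <= tab["pos"][i]) & (tab["pos"][i] < cw["start"] + 500_000)]
            maxw[i] = cover["wpip"].max() if len(cover) else 0.0
        cand = [
            i for i in range(m) if q[i] <= 0.05 and maxw[i] >= 0.5
        ]
        cand.sort(key=lambda i: (tab["p_beta"][i], tab["chrom"][i], tab["pos"][i]))
        kept = []
        for i in cand:
            if all(
                tab["chrom"][i] != tab["chrom"][j]
                or abs(int(tab["pos"][i]) - int(tab["pos"][j])) > 1_000_000
                for j in kept
            ):
                kept.append(i)
        assert out["snp_id"].tolist() == [f"s{i}" for i in kept]


@pytest.fixture(scope="module")
def gwas_study():
    cfg = SimulationConfig(
        seed=21,
        n_founders=100,
        m_snps=800,
        variance_spec={"additive": 1.0, "dominance": 0.3, "structure": 0.3, "residual": 0.5},
    )
    return simulate_study(cfg, panels=("ames",))


class TestEmmaxScan:
    def test_collinear_snp_flagged_na(self, gwas_study):
        ms, pa = gwas_study.markers["ames"], gwas_study.panels["ames"]
        Q = np.column_stack([pa.q_design(), ms.X[:, 0].astype(float)])
        res = emmax_scan(pa.g, Q, ms, [additive_kinship(ms.X)])
        assert np.isnan(res.table["p_beta"].iloc[0])

    def test_matches_exact_per_snp_reml(self, gwas_study):
        """EMMAX p-values track exact per-SNP REML refits (Spearman > 0.99)."""
        ms, pa = gwas_study.markers["ames"], gwas_study.panels["ames"]
        idx = np.arange(0, ms.m, ms.m // 50)[:50]
        G = additive_kinship(ms.X)
        res = emmax_scan(pa.g, pa.q_design(), ms, [G])
        exact = []
        for j in idx:
            W = np.column_stack([pa.q_design(), ms.X[:, j].astype(float)])
            if np.linalg.matrix_rank(W) < W.shape[1]:
                exact.append(np.nan)
                continue
            fit = fit_reml(pa.g, W, [G])
            exact.append(wald_test(fit, [W.shape[1] - 1])[1])
        approx = res.table["p_beta"].to_numpy()[idx]
        ok = ~np.isnan(exact) & ~np.isnan(approx)
        rho = stats.spearmanr(np.asarray(exact)[ok], approx[ok]).statistic
        assert rho > 0.99

    def test_dominance_scan_reports_both_effects(self, gwas_study):
        ms, pa = gwas_study.markers["ames"], gwas_study.panels["ames"]
        res = emmax_scan(
            pa.g,
            pa.q_design(),
            ms,
            [additive_kinship(ms.X), dominance_kinship(ms.Z)],
            include_dominance=True,
        )
        assert {"beta", "theta", "p_beta", "p_theta"} <= set(res.table.columns)
        # theta is estimable only where all three genotype classes occur;
        # two-class SNPs have z collinear with [1, x] and fall back to the
        # additive-only test
        n_classes = np.array([len(np.unique(ms.X[:, j])) for j in range(ms.m)])
        p_theta = res.table["p_theta"].to_numpy()
        assert np.all(np.isnan(p_theta[n_classes < 3]))
        three = p_theta[n_classes == 3]
        assert np.mean(~np.isnan(three)) > 0.95
        ok = three[~np.isnan(three)]
        assert ((ok >= 0) & (ok <= 1)).all()

    def test_top_snp_localizes_large_causal_effect(self):
        """With one strong causal SNP, the scan's top hit lands within 250 kb
        in most replicates."""
        hits = 0
        n_rep = 10
        for r in range(n_rep):
            cfg = SimulationConfig(
                seed=300 + r,
                n_founders=252,
                m_snps=1500,
                variance_spec={"additive": 0.4, "dominance": 0.0, "structure": 0.2, "residual": 0.9},
            )
            st = simulate_study(cfg, panels=("ames",))
            ms, pa = st.markers["ames"], st.panels["ames"]
            rng = np.random.default_rng(900 + r)
            j = rng.integers(ms.m)
            x = ms.X[:, j].astype(float)
            xc = x - x.mean()
            beta = np.sqrt(0.1 * pa.g.var() / xc.var())
            g = pa.g + beta * xc
            res = emmax_scan(g, pa.q_design(), ms, [additive_kinship(ms.X)])
            top = res.table.loc[res.table["p_beta"].idxmin()]
            same = top["chrom"] == ms.snps["chrom"].iloc[j]
            close = abs(int(top["pos"]) - int(ms.snps["pos"].iloc[j])) <= 250_000
            hits += int(same and close)
        assert hits >= 0.8 * n_rep
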