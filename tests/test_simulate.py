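import numpy as np
import pandas as pd
import pytest

from hybridgp.simulate import (
    SimulationConfig,
    simulate_annotations,
    simulate_founders,
    simulate_genetic_map,
    simulate_phenotypes,
    simulate_pips,
    simulate_plot_data,
    simulate_ril_population,
    simulate_study,
)


def _cfg(**kw):
    base = dict(seed=1, n_founders=40, m_snps=400, n_ril_populations=3, rils_per_population=20)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    def test_divergence_out_of_range(self):
        with pytest.raises(ValueError, match="divergence"):
            _cfg(divergence=1.0)

    def test_too_few_snps_per_chromosome(self):
        with pytest.raises(ValueError, match="10 SNPs"):
            _cfg(m_snps=50, n_chromosomes=10)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            _cfg(variance_spec={"additive": -1.0, "dominance": 0, "residual": 1})


class TestFounders:
    def test_fully_homozygous(self):
        f = simulate_founders(_cfg())
        assert set(np.unique(f.counts)) <= {0, 2}

    def test_determinism(self):
        f1 = simulate_founders(_cfg(seed=9))
        f2 = simulate_founders(_cfg(seed=9))
        assert np.array_equal(f1.counts, f2.counts)
        pd.testing.assert_frame_equal(f1.snps, f2.snps)

    def test_no_divergence_limit(self):
        """divergence=0: subpopulation frequency difference ~ 0 on average."""
        f = simulate_founders(
            _cfg(seed=3, n_founders=200, m_snps=2000, n_subpops=2, divergence=0.0,
                 family_divergence=0.0)
        )
        f1 = f.counts[f.subpop == 0].mean(axis=0) / 2
        f2 = f.counts[f.subpop == 1].mean(axis=0) / 2
        assert abs((f1 - f2).mean()) < 0.01

    def test_hudson_fst_matches_generative_target(self):
        """Balding-Nichols divergence 0.2 yields Hudson Fst ~ 0.2."""
        f = simulate_founders(
            _cfg(seed=5, n_founders=300, m_snps=5000, n_subpops=2, divergence=0.2,
                 family_divergence=0.0)
        )
        # haploid founder allele frequencies per subpopulation
        p1 = f.counts[f.subpop == 0].mean(axis=0) / 2
        p2 = f.counts[f.subpop == 1].mean(axis=0) / 2
        n1 = (f.subpop == 0).sum()
        n2 = (f.subpop == 1).sum()
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        keep = den > 0
        fst = num[keep].sum() / den[keep].sum()
        assert abs(fst - 0.2) < 0.05

    def test_reference_frequencies_polymorphic(self):
        f = simulate_founders(_cfg())
        assert np.all((f.ref_freqs > 0) & (f.ref_freqs <= 0.5))


class TestRils:
    def _setup(self, cfg):
        f = simulate_founders(cfg)
        gmap = simulate_genetic_map(cfg)
        return f, gmap

    def test_identical_parents_give_identical_rils(self, rng):
        cfg = _cfg()
        f, gmap = self._setup(cfg)
        p = f.counts[0]
        rils = simulate_ril_population(p, p, 5, gmap, f.snps, rng)
        assert np.all(rils == p)

    def test_zero_length_map_gives_whole_chromosome_blocks(self, rng):
        cfg = _cfg()
        f, gmap = self._setup(cfg)
        flat = gmap.assign(cm=0.0)
        a, b = f.counts[0], f.counts[1]
        rils = simulate_ril_population(a, b, 20, flat, f.snps, rng)
        chrom = f.snps["chrom"].to_numpy()
        for r in rils:
            for c in np.unique(chrom):
                sel = (chrom == c) & (a != b)  # origin only observable where parents differ
                if sel.sum() < 2:
                    continue
                origins = np.where(r[sel] == a[sel], 0, 1)
                assert len(np.unique(origins)) == 1

    def test_mean_crossovers_match_map_length(self, rng):
        """1 Morgan of map per chromosome: ~1 crossover per transmitted gamete."""
        cfg = _cfg(m_snps=2000, n_chromosomes=2, chrom_length_bp=100_000_000,
                   recomb_rate_cm_per_mb=1.0)
        f = simulate_founders(cfg)
        bp = np.array([1, 100_000_000])
        gmap = pd.concat(
            [pd.DataFrame({"chrom": c, "pos": bp, "cm": [0.0, 100.0]}) for c in ("1", "2")]
        )
        a = np.zeros(f.snps.shape[0], dtype=np.int8)
        b = np.full(f.snps.shape[0], 2, dtype=np.int8)  # parents differ everywhere
        rils = simulate_ril_population(a, b, 1000, gmap, f.snps, rng)
        chrom = f.snps["chrom"].to_numpy()
        switches = []
        for c in ("1", "2"):
            sub = rils[:, chrom == c] // 2
            switches.append(np.abs(np.diff(sub, axis=1)).sum(axis=1))
        mean_cx = np.mean(switches)
        assert abs(mean_cx - 1.0) < 0.15

    def test_rils_carry_only_parental_alleles(self, rng):
        cfg = _cfg()
        f, gmap = self._setup(cfg)
        a, b = f.counts[2], f.counts[3]
        rils = simulate_ril_population(a, b, 10, gmap, f.snps, rng)
        for r in rils:
            assert np.all((r == a) | (r == b))

    def test_heterozygous_parent_rejected(self, rng):
        cfg = _cfg()
        f, gmap = self._setup(cfg)
        bad = f.counts[0].copy()
        bad[0] = 1
        with pytest.raises(ValueError, match="homozygous"):
            simulate_ril_population(bad, f.counts[1], 2, gmap, f.snps, rng)


class TestAnnotationsSim:
    def test_zero_gene_density_all_distal(self):
        cfg = _cfg(gene_proximal_fraction=0.0, mnase_open_fraction=0.0)
        f = simulate_founders(cfg)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, annoset = simulate_annotations(f.snps, cfg)
        assert np.all(annoset.bins["gene"] == "distal")

    def test_determinism(self):
        cfg = _cfg(seed=8)
        f = simulate_founders(cfg)
        i1, a1 = simulate_annotations(f.snps, cfg)
        i2, a2 = simulate_annotations(f.snps, cfg)
        pd.testing.assert_frame_equal(i1.genes, i2.genes)
        pd.testing.assert_frame_equal(a1.features, a2.features)

    def test_no_association_matches_random_overlap(self):
        """With association 0, the fraction of open SNPs near genes matches
        the overall open fraction (hypergeometric/random expectation)."""
        cfg = _cfg(seed=13, m_snps=4000, n_founders=60, mnase_gene_association=0.0,
                   mnase_open_fraction=0.2, gene_proximal_fraction=0.3)
        f = simulate_founders(cfg)
        _, annoset = simulate_annotations(f.snps, cfg)
        open_all = (annoset.bins["mnase"] == "open").mean()
        prox = annoset.bins["gene"] == "proximal"
        open_prox = (annoset.bins["mnase"][prox] == "open").mean()
        assert abs(open_prox - open_all) < 0.05

    def test_positive_association_enriches_open_near_genes(self):
        cfg = _cfg(seed=13, m_snps=4000, n_founders=60, mnase_gene_association=0.9,
                   mnase_open_fraction=0.15, gene_proximal_fraction=0.3)
        f = simulate_founders(cfg)
        _, annoset = simulate_annotations(f.snps, cfg)
        prox = annoset.bins["gene"] == "proximal"
        open_prox = (annoset.bins["mnase"][prox] == "open").mean()
        open_dist = (annoset.bins["mnase"][~prox] == "open").mean()
        assert open_prox > open_dist


class TestPhenotypes:
    def test_all_zero_variances_give_fixed_part_only(self):
        cfg = _cfg(variance_spec={"additive": 0.0, "dominance": 0.0, "structure": 0.0,
                                  "panel": 0.0, "residual": 0.0})
        st = simulate_study(cfg, panels=("ames",))
        assert np.allclose(st.panels["ames"].g, 0.0)

    def test_missing_component_rejected(self):
        cfg = _cfg()
        st = simulate_study(cfg, panels=("ames",))
        bad = _cfg(variance_spec={"additive": 1.0})
        with pytest.raises(ValueError, match="missing"):
            simulate_phenotypes(st.panels["ames"], st.markers["ames"], bad)

    def test_dominance_variance_hits_target(self):
        cfg = _cfg(n_founders=252, m_snps=1000,
                   variance_spec={"additive": 0.0, "dominance": 0.5, "structure": 0.0,
                                  "residual": 0.0})
        st = simulate_study(cfg, panels=("ames",))
        w = st.truth.components["dominance"]
        assert st.truth.realized_variances["dominance"] == pytest.approx(0.5, rel=1e-9)
        assert np.var(w) == pytest.approx(0.5, rel=0.15)  # plain sample variance

    def test_realized_variances_match_targets(self):
        cfg = _cfg(n_founders=252, m_snps=1000)
        st = simulate_study(cfg, panels=("ames",))
        for name, target in st.truth.true_variances.items():
            if target == 0 or name == "residual":
                continue
            if name == "structure":
                continue  # unnormalized, absorbed by the fixed design
            assert st.truth.realized_variances[name] == pytest.approx(target, rel=0.15)

    def test_enrichment_fold_realized(self):
        cfg = _cfg(n_founders=100, m_snps=2000, enrichment_spec={"hot": 10.0})
        st = simulate_study(cfg, panels=("ames",))
        ms, pa = st.markers["ames"], st.panels["ames"]
        rng = np.random.default_rng(0)
        bins = np.where(rng.random(ms.m) < 0.5, "hot", "cold")
        _, truth = simulate_phenotypes(pa, ms, cfg, bins=bins)
        ratio = truth.true_bin_enrichments["hot"] / truth.true_bin_enrichments["cold"]
        assert ratio == pytest.approx(10.0, rel=0.35)

    def test_study_determinism_bytewise(self):
        s1 = simulate_study(_cfg(seed=17))
        s2 = simulate_study(_cfg(seed=17))
        assert s1.panels["all"].g.tobytes() == s2.panels["all"].g.tobytes()
        assert s1.markers["all"].X.tobytes() == s2.markers["all"].X.tobytes()

    def test_hybrid_counts_in_range(self, small_study):
        X, Z = small_study.markers["all"].X, small_study.markers["all"].Z
        assert set(np.unique(X)) <= {0, 1, 2}
        assert set(np.unique(Z)) <= {0, 1}
        assert np.all((Z == 1) == (X == 1))


class TestPlotsAndPips:
    def test_zero_variance_plots_equal_genotype_values(self):
        g = np.array([1.0, 2.0, 3.0])
        plots = simulate_plot_data(g, 2, 0.0, 0.0, seed=1)
        for e in plots["env"].unique():
            assert np.allclose(plots[plots["env"] == e]["y"], g)

    def test_single_environment_rejected(self):
        with pytest.raises(ValueError):
            simulate_plot_data(np.zeros(3), 1, 0.1, 0.1, seed=1)

    def test_same_seed_identical(self):
        g = np.arange(5.0)
        p1 = simulate_plot_data(g, 3, 0.2, 0.4, seed=6)
        p2 = simulate_plot_data(g, 3, 0.2, 0.4, seed=6)
        pd.testing.assert_frame_equal(p1, p2)

    def test_pips_concentrated_on_largest_effects(self, rng):
        effects = np.zeros(100)
        effects[[3, 50, 97]] = (2.0, -3.0, 1.5)
        pips = simulate_pips(effects, seed=2, n_top=3)
        assert np.all((pips >= 0) & (pips <= 1))
        assert pips[[3, 50, 97]].min() > pips[np.delete(np.arange(100), [3, 50, 97])].max()


class TestStudyAssembly:
    def test_two_testers_in_diversity_panel(self, small_study):
        assert small_study.panels["ames"].n_testers == 2
        assert small_study.panels["nam"].n_testers == 1

    def test_panels_share_check_hybrids(self, small_study):
        ames = set(small_study.panels["ames"].table["hybrid_id"])
        nam = set(small_study.panels["nam"].table["hybrid_id"])
        assert len(ames & nam) >= 3

    def test_population_labels_partition_nam(self, small_study):
        tab = small_study.panels["nam"].table
        assert tab["population"].nunique() == 3
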