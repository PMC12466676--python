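import numpy as np
import pandas as pd
import pytest

from hetvar.animal_model import (ChainConfig, Design, build_design,
                                 gibbs_bivariate, gibbs_single_trait,
                                 mme_solve)
from hetvar.pedigree import a_inverse
from hetvar.posterior import batch_means_variance, derived_parameters
from hetvar.preprocess import HIGH, LOW, prepare
from hetvar.synthetic_data import SimulationConfig, simulate


class TestChainConfig:
    def test_study_scale_bookkeeping(self):
        chain = ChainConfig(cycles=600_000, burnin=60_000, thin=20)
        assert chain.n_retained == 27_000

    @pytest.mark.parametrize("cycles,burnin,thin,retained", [
        (100, 0, 1, 100), (100, 10, 1, 90), (105, 10, 20, 4),
    ])
    def test_retained_count(self, cycles, burnin, thin, retained):
        assert ChainConfig(cycles, burnin, thin).n_retained == retained

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ChainConfig(cycles=100, burnin=100)
        with pytest.raises(ValueError):
            ChainConfig(cycles=100, burnin=0, thin=0)


@pytest.fixture(scope="module")
def prepared(small_dataset):
    records, ped, truth = small_dataset
    return prepare(records), a_inverse(ped)


class TestBuildDesign:
    def test_columns_are_groups_plus_covariates(self, prepared):
        prep, st = prepared
        design = build_design(prep, st, "ALL")
        ncg = prep.retained["cg_id"].nunique()
        assert design.X.shape == (len(prep.retained), ncg + 2)
        assert design.fixed_names[-2:] == ["htz", "age"]
        # age column is centered
        assert design.X.toarray()[:, -1].mean() == pytest.approx(0, abs=1e-9)

    def test_parents_without_records_have_bv_slots(self, prepared,
                                                   small_dataset):
        prep, st = prepared
        _, ped, _ = small_dataset
        design = build_design(prep, st, "ALL")
        assert design.Z.shape[1] == len(ped)
        recorded = set(design.record_animals)
        assert any(a not in recorded for a in design.animal_order)
        # each record row maps to exactly one animal
        assert (design.Z.sum(axis=1) == 1).all()

    def test_class_subsets_partition_groups(self, prepared):
        prep, st = prepared
        d_all = build_design(prep, st, "ALL")
        d_low = build_design(prep, st, LOW)
        d_high = build_design(prep, st, HIGH)
        assert d_low.n_fixed + d_high.n_fixed == d_all.n_fixed + 2
        low_cgs = {n for n in d_low.fixed_names if n.startswith("cg:")}
        high_cgs = {n for n in d_high.fixed_names if n.startswith("cg:")}
        assert not low_cgs & high_cgs

    def test_unknown_subset_rejected(self, prepared):
        prep, st = prepared
        with pytest.raises(ValueError):
            build_design(prep, st, "MEDIUM")


from conftest import toy_design as _toy_design  # noqa: E402


class TestMmeSolve:
    def test_infinite_shrinkage_zeroes_breeding_values(self, trio_pedigree):
        design = _toy_design()
        st = a_inverse(trio_pedigree)
        _, a = mme_solve(design, st.Ainv, sigma2_a=1e-9, sigma2_e=1e3)
        np.testing.assert_allclose(a, 0.0, atol=1e-4)

    def test_matches_dense_gls(self, trio_pedigree):
        """BLUP from the sparse equations equals the dense GLS computation."""
        from hetvar.pedigree import relationship_matrix
        design = _toy_design()
        st = a_inverse(trio_pedigree)
        s2a, s2e = 400.0, 900.0
        beta, a = mme_solve(design, st.Ainv, s2a, s2e)
        A = relationship_matrix(trio_pedigree).A
        X, Z = design.X.toarray(), design.Z.toarray()
        V = Z @ A @ Z.T * s2a + np.eye(5) * s2e
        Vi = np.linalg.inv(V)
        beta_gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ design.y)
        a_gls = s2a * A @ Z.T @ Vi @ (design.y - X @ beta_gls)
        np.testing.assert_allclose(beta, beta_gls, atol=1e-8)
        np.testing.assert_allclose(a, a_gls, atol=1e-8)

    def test_singular_fixed_block_reported(self, trio_pedigree):
        from scipy import sparse
        design = _toy_design()
        X = design.X.toarray()
        X[:, 1] = 2 * X[:, 0]  # collinear with the group column
        bad = Design(X=sparse.csr_matrix(X), Z=design.Z, y=design.y,
                     fixed_names=design.fixed_names,
                     animal_order=design.animal_order,
                     record_animals=design.record_animals, subset="ALL")
        st = a_inverse(trio_pedigree)
        with pytest.raises(np.linalg.LinAlgError, match="contemporary-group"):
            mme_solve(bad, st.Ainv, 400.0, 900.0)


class TestGibbsSingleTrait:
    def test_seeded_determinism(self, trio_pedigree):
        design = _toy_design()
        st = a_inverse(trio_pedigree)
        chain = ChainConfig(cycles=500, burnin=100, thin=4, seed=42)
        d1 = gibbs_single_trait(design, st.Ainv, chain)
        d2 = gibbs_single_trait(design, st.Ainv, chain)
        pd.testing.assert_frame_equal(d1.draws, d2.draws)
        np.testing.assert_array_equal(d1.a_mean["general"],
                                      d2.a_mean["general"])

    def test_retained_count_and_positive_draws(self, trio_pedigree):
        design = _toy_design()
        st = a_inverse(trio_pedigree)
        chain = ChainConfig(cycles=1000, burnin=100, thin=3, seed=1)
        d = gibbs_single_trait(design, st.Ainv, chain)
        assert len(d.draws) == chain.n_retained
        assert (d.draws > 0).all().all()

    def test_location_means_match_mme_with_frozen_variances(
            self, trio_pedigree):
        """With variances fixed, the Gibbs means of (beta, a) converge on
        the mixed-model-equation solution (within 3 Monte-Carlo SEs)."""
        design = _toy_design()
        st = a_inverse(trio_pedigree)
        s2a, s2e = 400.0, 900.0
        beta, a = mme_solve(design, st.Ainv, s2a, s2e)
        chain = ChainConfig(cycles=60_000, burnin=2_000, thin=2, seed=9,
                            start_sigma2_a=s2a, start_sigma2_e=s2e)
        d = gibbs_single_trait(design, st.Ainv, chain,
                               update_variances=False,
                               keep_location_draws=True)
        target = np.concatenate([beta, a])
        means = d.location_draws.mean(axis=0)
        for j in range(len(target)):
            mcse = np.sqrt(batch_means_variance(d.location_draws[:, j]))
            assert abs(means[j] - target[j]) < max(3 * mcse, 1e-6), (
                f"coordinate {j}: {means[j]} vs {target[j]}")

    def test_null_genetic_variance_detected(self):
        """Data simulated without genetic signal: posterior h2 stays small."""
        cfg = SimulationConfig(seed=31, n_records=2000, n_sires=60,
                               n_dams=800, n_herds=8,
                               sigma2_a_low=1e-6, sigma2_a_high=1e-6,
                               rg=0.0, sigma2_e_low=1800.0,
                               sigma2_e_high=1800.0)
        records, ped, _ = simulate(cfg)
        prep = prepare(records)
        st = a_inverse(ped)
        design = build_design(prep, st, "ALL")
        chain = ChainConfig(cycles=12_000, burnin=2_000, thin=10, seed=3)
        d = gibbs_single_trait(design, st.Ainv, chain)
        h2 = derived_parameters(d.draws)["h2"].mean()
        assert h2 < 0.05


class TestGibbsBivariate:
    def test_animal_in_both_classes_rejected(self, prepared):
        prep, st = prepared
        d_low = build_design(prep, st, LOW)
        with pytest.raises(ValueError, match="both SD classes"):
            gibbs_bivariate(d_low, d_low, st.Ainv,
                            ChainConfig(cycles=10, burnin=0, thin=1))

    def test_retained_count_and_pd_draws(self, prepared):
        prep, st = prepared
        d_low = build_design(prep, st, LOW)
        d_high = build_design(prep, st, HIGH)
        chain = ChainConfig(cycles=2_000, burnin=500, thin=5, seed=17)
        d = gibbs_bivariate(d_low, d_high, st.Ainv, chain)
        assert len(d.draws) == chain.n_retained
        det = (d.draws["sigma2_a_low"] * d.draws["sigma2_a_high"]
               - d.draws["sigma_a_lh"] ** 2)
        assert (det > 0).all()
        assert (d.draws[["sigma2_a_low", "sigma2_a_high",
                         "sigma2_e_low", "sigma2_e_high"]] > 0).all().all()

    def test_seeded_determinism(self, prepared):
        prep, st = prepared
        d_low = build_design(prep, st, LOW)
        d_high = build_design(prep, st, HIGH)
        chain = ChainConfig(cycles=400, burnin=100, thin=2, seed=5)
        d1 = gibbs_bivariate(d_low, d_high, st.Ainv, chain)
        d2 = gibbs_bivariate(d_low, d_high, st.Ainv, chain)
        pd.testing.assert_frame_equal(d1.draws, d2.draws)

    def test_independent_traits_recovered(self):
        """True cross-class correlation 0: the posterior mean correlation
        stays near 0 (median over replicate datasets; a single dataset of
        this size identifies the correlation only to within ~0.2)."""
        means = []
        for seed in (23, 24, 25, 26, 27):
            cfg = SimulationConfig(seed=seed, n_records=1600, n_sires=50,
                                   n_dams=500, n_herds=6, rg=0.0,
                                   sigma2_a_low=800.0, sigma2_a_high=800.0,
                                   sigma2_e_low=800.0, sigma2_e_high=800.0)
            records, ped, truth = simulate(cfg)
            prep = prepare(records)
            st = a_inverse(ped)
            chain = ChainConfig(cycles=20_000, burnin=4_000, thin=10, seed=2)
            d = gibbs_bivariate(build_design(prep, st, LOW),
                                build_design(prep, st, HIGH), st.Ainv, chain)
            means.append(derived_parameters(d.draws)["rg"].mean())
        assert abs(np.median(means)) < 0.25

    def test_same_trait_degenerate_case(self):
        """Near-perfect cross-class correlation and equal variances: the
        posterior correlation must be strongly positive."""
        cfg = SimulationConfig(seed=29, n_records=1400, n_sires=50,
                               n_dams=500, n_herds=6, rg=0.98,
                               sigma2_a_low=600.0, sigma2_a_high=600.0,
                               sigma2_e_low=900.0, sigma2_e_high=900.0)
        records, ped, truth = simulate(cfg)
        prep = prepare(records)
        st = a_inverse(ped)
        chain = ChainConfig(cycles=24_000, burnin=4_000, thin=10, seed=4)
        d = gibbs_bivariate(build_design(prep, st, LOW),
                            build_design(prep, st, HIGH), st.Ainv, chain)
        rg = derived_parameters(d.draws)["rg"].mean()
        assert rg > 0.6


def test_credible_interval_coverage_over_replicates():
    """95% intervals for the four main variance components should cover the
    simulation truth in most replicate datasets."""
    truth_vals = {"sigma2_a_low": 353.51, "sigma2_a_high": 1134.22,
                  "sigma2_e_low": 1480.62, "sigma2_e_high": 2180.15}
    covered = total = 0
    for rep in range(10):
        cfg = SimulationConfig(seed=100 + rep, n_records=1200, n_sires=60,
                               n_dams=500, n_herds=8)
        records, ped, _ = simulate(cfg)
        prep = prepare(records)
        st = a_inverse(ped)
        chain = ChainConfig(cycles=16_000, burnin=3_000, thin=10,
                            seed=500 + rep)
        d = gibbs_bivariate(build_design(prep, st, LOW),
                            build_design(prep, st, HIGH), st.Ainv, chain)
        for par, tv in truth_vals.items():
            lo, hi = np.quantile(d.draws[par], [0.025, 0.975])
            covered += lo <= tv <= hi
            total += 1
    assert covered / total >= 0.8
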