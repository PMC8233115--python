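"""HPDI computation and hemisphere/atom/region/covariate summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lesionatoms.atoms import AtomBasis
from lesionatoms.errors import DomainError
from lesionatoms.model import PosteriorSamples
from lesionatoms.relevance import (
    atom_lateralization,
    build_relevance_report,
    covariate_effects,
    hemisphere_relevance,
    hpdi,
    region_relevance,
)


def brute_force_hpdi(draws, prob=0.94):
    """Exhaustive narrowest-window search over the sorted draws (oracle)."""
    values = np.sort(np.asarray(draws, dtype=float))
    n = len(values)
    m = int(np.ceil(prob * n))
    best = None
    for i in range(n - m + 1):
        lo, hi = values[i], values[i + m - 1]
        if best is None or (hi - lo) < (best[1] - best[0]) - 0:
            best = (lo, hi)
    return best


def _samples(k=2, p=2, draws=100, beta=None, gamma=None, sigma_l=None, sigma_r=None):
    """Hand-built PosteriorSamples with one chain of given draws."""
    shape = (1, draws)
    zeros = np.zeros(shape)
    return PosteriorSamples(
        alpha=zeros.copy(),
        beta=np.zeros((1, draws, 2 * k)) if beta is None else beta,
        gamma=np.zeros((1, draws, p)) if gamma is None else gamma,
        tau=zeros.copy() + 0.1,
        sigma_left=zeros.copy() if sigma_l is None else sigma_l,
        sigma_right=zeros.copy() if sigma_r is None else sigma_r,
        sigma_eps=zeros.copy() + 1.0,
        atom_names=[f"{h}_atom{a + 1:02d}" for h in ("L", "R") for a in range(k)],
        covariate_names=["education", "iqcode"][:p],
    )


class TestHPDI:
    def test_point_mass_gives_degenerate_interval(self):
        interval = hpdi(np.full(50, 3.25))
        assert interval.lower == interval.upper == 3.25

    def test_fewer_than_two_draws_rejected(self):
        with pytest.raises(DomainError):
            hpdi(np.array([1.0]))

    def test_standard_normal_interval_matches_symmetric_quantiles(self):
        # for a symmetric unimodal density the 94% HPDI is the central
        # interval at +/- z_{0.97} = 1.881
        rng = np.random.default_rng(0)
        interval = hpdi(rng.standard_normal(1_000_000))
        assert interval.lower == pytest.approx(-1.881, abs=0.02)
        assert interval.upper == pytest.approx(1.881, abs=0.02)

    def test_exponential_interval_starts_at_mode(self):
        # mode at 0; upper bound at -ln(0.06) = 2.813
        rng = np.random.default_rng(1)
        interval = hpdi(rng.exponential(1.0, 1_000_000))
        assert interval.lower == pytest.approx(0.0, abs=0.001)
        assert interval.upper == pytest.approx(2.813, abs=0.02)

    @settings(max_examples=60, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=200),
        st.floats(0.5, 0.99),
    )
    def test_matches_brute_force_oracle(self, values, prob):
        draws = np.asarray(values)
        interval = hpdi(draws, prob)
        lo, hi = brute_force_hpdi(draws, prob)
        assert interval.upper - interval.lower == pytest.approx(hi - lo, abs=1e-12)

    def test_skewed_draws_prefer_dense_side(self):
        # two clusters: 95 draws near 0, 5 near 10 -> 94% window hugs the cluster
        draws = np.concatenate([np.linspace(0, 0.1, 95), np.full(5, 10.0)])
        interval = hpdi(draws, 0.94)
        assert interval.upper < 1.0


class TestHemisphereRelevance:
    def test_identical_dispersions_are_balanced(self):
        rng = np.random.default_rng(2)
        sig = np.abs(rng.normal(0.1, 0.02, (1, 300)))
        rows = hemisphere_relevance(_samples(sigma_l=sig.copy(), sigma_r=sig.copy()))
        assert (rows["dominance"] == "balanced").all()
        left, right = rows.iloc[0], rows.iloc[1]
        assert left["mean"] == right["mean"]
        assert left["hpdi_lower"] == right["hpdi_lower"]

    def test_zero_dispersion_reported_as_point(self):
        rows = hemisphere_relevance(_samples())
        left = rows[rows["hemisphere"] == "left"].iloc[0]
        assert left["mean"] == 0.0
        assert left["hpdi_lower"] == left["hpdi_upper"] == 0.0

    def test_dominance_follows_larger_posterior_mean(self):
        sig_l = np.full((1, 100), 0.3)
        sig_r = np.full((1, 100), 0.05)
        rows = hemisphere_relevance(_samples(sigma_l=sig_l, sigma_r=sig_r))
        assert (rows["dominance"] == "left").all()


class TestAtomLateralization:
    def test_equal_sides_not_lateralized(self):
        rng = np.random.default_rng(3)
        k, draws = 2, 400
        beta = np.zeros((1, draws, 2 * k))
        common = rng.normal(0, 0.2, (draws, k))
        beta[0, :, :k] = common
        beta[0, :, k:] = common
        rows = atom_lateralization(_samples(k=k, beta=beta))
        assert not rows["lateralized"].any()
        assert (rows["delta_mean"] == 0).all()

    def test_constant_offset_lateralized_toward_left(self):
        k, draws = 2, 100
        beta = np.zeros((1, draws, 2 * k))
        beta[0, :, 0] = -0.5  # left atom 1
        rows = atom_lateralization(_samples(k=k, beta=beta))
        atom1 = rows.iloc[0]
        assert atom1["delta_mean"] == pytest.approx(-0.5)
        assert atom1["delta_hpdi_lower"] == atom1["delta_hpdi_upper"] == -0.5
        assert atom1["lateralized"]
        assert atom1["direction"] == "left"
        assert not rows.iloc[1]["lateralized"]

    def test_flag_equals_hpdi_zero_exclusion_exactly(self):
        rng = np.random.default_rng(4)
        k, draws = 5, 500
        beta = rng.normal(0, 0.1, (1, draws, 2 * k))
        rows = atom_lateralization(_samples(k=k, beta=beta))
        for _, row in rows.iterrows():
            excluded = row["delta_hpdi_lower"] > 0 or row["delta_hpdi_upper"] < 0
            assert row["lateralized"] == excluded

    def test_independent_draws_fire_near_nominal_rate(self):
        # calibration: when the posterior of the difference is N(c, 1) and the
        # experiment-to-experiment spread of c is also standard normal (the
        # matched Bayesian-frequentist case), a 94% HPDI excludes zero in
        # about 6% of repetitions
        rng = np.random.default_rng(5)
        fired = total = 0
        for _ in range(400):
            centers = rng.standard_normal(2)
            delta_draws = centers + rng.standard_normal((1, 300, 2))
            beta = np.concatenate([delta_draws, np.zeros((1, 300, 2))], axis=2)
            rows = atom_lateralization(_samples(k=2, beta=beta, draws=300))
            fired += int(rows["lateralized"].sum())
            total += len(rows)
        assert 0.02 <= fired / total <= 0.12


class TestRegionRelevance:
    def test_identity_basis_reproduces_atom_summaries(self):
        rng = np.random.default_rng(6)
        k, draws = 3, 400
        beta = rng.normal(0, 0.3, (1, draws, 2 * k))
        samples = _samples(k=k, beta=beta, draws=draws)
        basis = AtomBasis(
            W=pd.DataFrame(np.eye(k), index=[f"r{i}" for i in range(k)])
        )
        regions = region_relevance(samples, basis)
        atoms = atom_lateralization(samples)
        left = regions[regions["hemisphere"] == "left"]
        np.testing.assert_allclose(
            left["mean"].to_numpy(), atoms["mean_left"].to_numpy(), atol=1e-12
        )

    def test_zero_coefficients_give_zero_relevance(self):
        basis = AtomBasis(W=pd.DataFrame(np.ones((4, 2)), index=list("abcd")))
        regions = region_relevance(_samples(k=2), basis)
        assert (regions["mean"] == 0).all()

    def test_single_entry_basis_scales_linearly(self):
        k, draws = 1, 200
        rng = np.random.default_rng(7)
        beta = rng.normal(0, 0.2, (1, draws, 2))
        W = np.zeros((3, 1))
        W[1, 0] = 0.7
        basis = AtomBasis(W=pd.DataFrame(W, index=list("abc")))
        samples = _samples(k=k, beta=beta, draws=draws)
        regions = region_relevance(samples, basis)
        row = regions[(regions["region"] == "b") & (regions["hemisphere"] == "left")]
        assert row["mean"].iloc[0] == pytest.approx(0.7 * beta[0, :, 0].mean())

    def test_shape_mismatch_rejected(self):
        basis = AtomBasis(W=pd.DataFrame(np.ones((4, 3))))
        with pytest.raises(DomainError):
            region_relevance(_samples(k=2), basis)

    def test_linearity_under_convex_combination(self):
        rng = np.random.default_rng(8)
        k, draws = 2, 100
        beta_a = rng.normal(0, 1, (1, draws, 2 * k))
        beta_b = rng.normal(0, 1, (1, draws, 2 * k))
        basis = AtomBasis(W=pd.DataFrame(rng.uniform(0, 1, (5, k))))
        lam = 0.3
        mixed = region_relevance(
            _samples(k=k, beta=lam * beta_a + (1 - lam) * beta_b), basis
        )
        a = region_relevance(_samples(k=k, beta=beta_a), basis)
        b = region_relevance(_samples(k=k, beta=beta_b), basis)
        np.testing.assert_allclose(
            mixed["mean"], lam * a["mean"] + (1 - lam) * b["mean"], atol=1e-12
        )


class TestCovariateEffects:
    def test_zero_education_effect_reported_as_point_zero(self):
        rows = covariate_effects(_samples(p=2))
        edu = rows[rows["covariate"] == "education"].iloc[0]
        assert edu["mean"] == 0.0
        assert edu["hpdi_lower"] == edu["hpdi_upper"] == 0.0

    def test_negative_effect_keeps_sign(self):
        gamma = np.full((1, 100, 2), 0.0)
        gamma[0, :, 1] = -0.4
        rows = covariate_effects(_samples(p=2, gamma=gamma))
        assert rows[rows["covariate"] == "iqcode"]["mean"].iloc[0] < 0


def test_report_bundle_roundtrip(tmp_path, fitted_small_model):
    from lesionatoms.model import posterior_predictive_r2

    samples = fitted_small_model["samples"]
    r2 = posterior_predictive_r2(samples, fitted_small_model["data"])
    report = build_relevance_report(
        samples, fitted_small_model["basis"], r2=r2, outcome_name="outcome"
    )
    paths = report.write(tmp_path)
    assert all(path.exists() for path in paths.values())
    import json

    payload = json.loads(paths["json"].read_text())
    assert {"hemisphere", "atoms", "regions", "covariates", "r2"} <= set(payload)
    assert len(payload["regions"]) == 2 * fitted_small_model["basis"].n_regions
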