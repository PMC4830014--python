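import numpy as np
import pytest

from tiltsplay.fitting import (
    Histogram,
    PmfCurve,
    build_histogram,
    combine_splay_moduli,
    combine_tilt_moduli,
    extract_splay_modulus,
    extract_tilt_and_splay_moduli,
    extract_tilt_modulus,
    fit_gaussian,
    fit_pmf_quadratic,
    modulus_from_fits,
    splay_pmf,
    tilt_pmf,
)
from tiltsplay.synthetic import sample_splays, sample_tilt_angles


class TestHistogram:
    def test_single_value_single_bin(self):
        hist = build_histogram(np.full(100, 3.7), n_bins=10)
        assert (hist.probabilities > 0).sum() == 1
        assert hist.probabilities.max() == pytest.approx(1.0)

    def test_uniform_probabilities(self):
        rng = np.random.default_rng(2)
        hist = build_histogram(rng.random(200_000), 10, value_range=(0, 1))
        # 3-sigma multinomial tolerance around 0.1
        sigma = np.sqrt(0.1 * 0.9 / 200_000)
        assert np.all(np.abs(hist.probabilities - 0.1) < 3.5 * sigma)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(3)
        hist = build_histogram(rng.normal(size=5000), 37)
        assert hist.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_histogram(np.empty(0), 10)


class TestFitGaussian:
    def test_exact_gaussian_recovered(self):
        x = np.linspace(-4, 4, 81)
        p = np.exp(-((x - 0.5) ** 2) / (2 * 1.2**2))
        hist = Histogram(centers=x, counts=np.ones_like(x), probabilities=p / p.sum())
        # counts > 0 everywhere so all bins used
        mu, sigma = fit_gaussian(hist)
        assert mu == pytest.approx(0.5, abs=0.01)
        assert sigma == pytest.approx(1.2, abs=0.012)

    def test_sampled_standard_normal(self):
        rng = np.random.default_rng(4)
        hist = build_histogram(rng.normal(size=100_000), 100)
        mu, sigma = fit_gaussian(hist)
        assert -0.02 < mu < 0.02
        assert 0.98 < sigma < 1.02

    def test_too_few_bins_rejected(self):
        hist = Histogram(
            centers=np.array([0.0, 1, 2]),
            counts=np.array([0, 5, 0]),
            probabilities=np.array([0.0, 1.0, 0.0]),
        )
        with pytest.raises(ValueError):
            fit_gaussian(hist)


class TestPmfs:
    def test_sine_distribution_gives_flat_tilt_pmf(self):
        theta = np.linspace(0.01, np.pi / 2, 90)
        p = np.sin(theta)
        hist = Histogram(theta, np.ones_like(theta), p / p.sum())
        pmf = tilt_pmf(hist)
        assert np.allclose(pmf.f, 0.0, atol=1e-9)

    def test_quadratic_tilt_pmf_inversion(self):
        """P ~ sin(theta) exp(-5 theta^2) has PMF exactly 5 theta^2 + const."""
        theta = np.linspace(0.01, np.pi / 2, 90)
        p = np.sin(theta) * np.exp(-5.0 * theta**2)
        hist = Histogram(theta, np.ones_like(theta), p / p.sum())
        pmf = tilt_pmf(hist)
        fits = fit_pmf_quadratic(pmf, mu=0.3, sigma=0.15)
        assert all(f.b == pytest.approx(5.0, abs=1e-9) for f in fits)

    def test_scaling_counts_leaves_pmf_unchanged(self):
        theta = np.linspace(0.01, np.pi / 2, 50)
        counts = np.rint(1000 * np.sin(theta)).astype(int) + 1
        h1 = Histogram(theta, counts, counts / counts.sum())
        h2 = Histogram(theta, 2 * counts, counts / counts.sum())
        assert np.allclose(tilt_pmf(h1).f, tilt_pmf(h2).f)

    def test_gaussian_splay_pmf_coefficient(self):
        """P from the splay model with K_c A_L = 600 has PMF coefficient 300."""
        s = np.linspace(-0.2, 0.2, 101)
        p = np.exp(-300.0 * s**2)
        hist = Histogram(s, np.ones_like(s), p / p.sum())
        pmf = splay_pmf(hist)
        fits = fit_pmf_quadratic(pmf, mu=0.0, sigma=np.sqrt(1 / 600.0))
        assert all(f.b == pytest.approx(300.0, abs=1e-9) for f in fits)

    def test_symmetric_histogram_symmetric_pmf(self):
        s = np.linspace(-1, 1, 41)
        p = np.exp(-(s**2))
        hist = Histogram(s, np.ones_like(s), p / p.sum())
        pmf = splay_pmf(hist)
        assert np.allclose(pmf.f, pmf.f[::-1], atol=1e-12)


class TestQuadraticFit:
    def test_exact_polynomial_recovery(self):
        x = np.linspace(0, 1, 60)
        pmf = PmfCurve(x=x, f=2.0 + 3.0 * x**2, source="tilt")
        fits = fit_pmf_quadratic(pmf, mu=0.5, sigma=0.25)
        assert len(fits) == 5
        assert all(f.b == pytest.approx(3.0, abs=1e-10) for f in fits)
        value, unc = modulus_from_fits(fits, scale=2.0)
        assert value == pytest.approx(6.0, abs=1e-9)
        assert unc < 1e-9

    def test_constant_shift_changes_only_a(self):
        x = np.linspace(0, 1, 60)
        f1 = fit_pmf_quadratic(PmfCurve(x, 3.0 * x**2, "tilt"), 0.5, 0.25)
        f2 = fit_pmf_quadratic(PmfCurve(x, 7.0 + 3.0 * x**2, "tilt"), 0.5, 0.25)
        for a, b in zip(f1, f2):
            assert b.a - a.a == pytest.approx(7.0, abs=1e-9)
            assert b.b == pytest.approx(a.b, abs=1e-9)

    def test_quartic_contamination_grows_with_range(self):
        """Direct least-squares oracle: fitted b increases with c for 3x^2 + x^4."""
        x = np.linspace(-1, 1, 201)
        pmf = PmfCurve(x, 3.0 * x**2 + x**4, "splay")
        fits = fit_pmf_quadratic(pmf, mu=0.0, sigma=0.4)
        bs = [f.b for f in sorted(fits, key=lambda f: f.c)]
        assert all(b2 > b1 for b1, b2 in zip(bs, bs[1:]))
        # cross-check the narrowest range against an independent lstsq
        sel = np.abs(x) <= 0.4
        oracle = np.linalg.lstsq(
            np.column_stack([np.ones(sel.sum()), x[sel] ** 2]), pmf.f[sel], rcond=None
        )[0][1]
        assert bs[0] == pytest.approx(oracle, rel=1e-12)

    def test_centered_variant(self):
        x = np.linspace(0, 2, 100)
        pmf = PmfCurve(x, 4.0 * (x - 1.0) ** 2, "splay")
        fits = fit_pmf_quadratic(pmf, mu=1.0, sigma=0.3, centered=True)
        assert all(f.b == pytest.approx(4.0, abs=1e-9) for f in fits)


class TestModulusRecovery:
    def test_tilt_generative_recovery(self):
        est = extract_tilt_modulus(sample_tilt_angles(12.0, 50_000, seed=21))
        assert est.value == pytest.approx(12.0, rel=0.05)

    def test_splay_generative_recovery(self):
        est = extract_splay_modulus(sample_splays(10.0, 60.0, 50_000, seed=22), 60.0)
        assert est.value == pytest.approx(10.0, rel=0.05)

    def test_doubling_area_halves_kc(self):
        samples = sample_splays(10.0, 60.0, 30_000, seed=23)
        a = extract_splay_modulus(samples, 60.0)
        b = extract_splay_modulus(samples, 120.0)
        assert b.value == pytest.approx(a.value / 2.0, rel=1e-9)

    def test_degenerate_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            extract_splay_modulus(np.zeros(1000), 60.0)

    def test_estimator_consistency(self):
        """Median recovery error decreases as the sample count grows."""
        sizes = [10_000, 100_000, 200_000]
        med_errors = []
        for n in sizes:
            errs = [
                abs(extract_splay_modulus(
                    sample_splays(10.0, 60.0, n, seed=1000 + s), 60.0
                ).value - 10.0)
                for s in range(5)
            ]
            med_errors.append(np.median(errs))
        assert med_errors[2] < med_errors[0]


class TestCombination:
    def test_harmonic_hand_values(self):
        assert combine_splay_moduli(
            {"aa": 20.0, "ab": 30.0, "bb": 60.0}, {"aa": 1, "ab": 1, "bb": 1}
        ) == pytest.approx(30.0, abs=1e-12)
        assert combine_tilt_moduli({"a": 10.0, "b": 20.0}, {"a": 5, "b": 5}) == \
            pytest.approx(40.0 / 3.0, abs=1e-12)

    def test_single_component_collapse(self):
        assert combine_splay_moduli({"aa": 17.3}, {"aa": 9}) == 17.3
        assert combine_tilt_moduli({"a": 8.1}, {"a": 4}) == 8.1

    def test_equal_components_weight_independent(self):
        assert combine_splay_moduli(
            {"aa": 12.0, "ab": 12.0}, {"aa": 3, "ab": 97}
        ) == pytest.approx(12.0)

    def test_harmonic_fixed_point(self):
        """Adding a species at the current combined value leaves it unchanged."""
        base = combine_tilt_moduli({"a": 10.0, "b": 20.0}, {"a": 5, "b": 5})
        extended = combine_tilt_moduli(
            {"a": 10.0, "b": 20.0, "c": base}, {"a": 5, "b": 5, "c": 7}
        )
        assert extended == pytest.approx(base, abs=1e-12)

    def test_bounded_by_components(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            chi = {i: rng.uniform(5, 50) for i in range(4)}
            phi = {i: rng.integers(1, 100) for i in range(4)}
            combined = combine_splay_moduli(chi, phi)
            assert min(chi.values()) <= combined <= max(chi.values())

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            combine_splay_moduli({"aa": -1.0}, {"aa": 5})
        with pytest.raises(ValueError):
            combine_tilt_moduli({"a": 10.0}, {"a": 0})


class TestFullChain:
    def test_single_species_collapse_and_outputs(self, tmp_path):
        tilts = {"LIP": sample_tilt_angles(12.0, 30_000, seed=31)}
        splays = {("LIP", "LIP"): sample_splays(10.0, 60.0, 30_000, seed=32)}
        res = extract_tilt_and_splay_moduli(tilts, splays, 60.0, outdir=tmp_path)
        assert res.kappa_t == pytest.approx(res.tilt["LIP"].value)
        assert res.K_c == pytest.approx(res.splay[("LIP", "LIP")].value)
        for name in (
            "tilt_LIP_distribution.csv", "tilt_LIP.png",
            "splay_LIP-LIP_distribution.csv", "splay_LIP-LIP.png",
            "moduli_summary.json", "moduli_summary.txt",
        ):
            assert (tmp_path / name).exists()

    def test_two_species_internal_consistency(self):
        tilts = {
            "A": sample_tilt_angles(10.0, 30_000, seed=41),
            "B": sample_tilt_angles(20.0, 30_000, seed=42),
        }
        splays = {
            ("A", "A"): sample_splays(8.0, 60.0, 30_000, seed=43),
            ("A", "B"): sample_splays(12.0, 60.0, 30_000, seed=44),
            ("B", "B"): sample_splays(20.0, 60.0, 30_000, seed=45),
        }
        res = extract_tilt_and_splay_moduli(tilts, splays, 60.0)
        expect_t = combine_tilt_moduli(
            {sp: res.tilt[sp].value for sp in tilts},
            {sp: 30_000 for sp in tilts},
        )
        expect_s = combine_splay_moduli(
            {p: res.splay[p].value for p in splays},
            {p: 30_000 for p in splays},
        )
        assert res.kappa_t == pytest.approx(expect_t, abs=1e-9)
        assert res.K_c == pytest.approx(expect_s, abs=1e-9)
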