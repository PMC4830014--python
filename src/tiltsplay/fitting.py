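"""Distributions, PMFs, quadratic fits and elastic moduli.

The tilt modulus of a lipid species is extracted from the distribution of
its tilt angles: with P(theta) ~ sin(theta) exp(-kappa theta^2 / 2 kBT), the
potential of mean force -kBT ln(P/sin theta) is quadratic, a + b theta^2,
and kappa_t = 2 b.  The bending rigidity comes from pairwise splays: with
P(S) ~ exp(-K_c A_L S^2 / 2 kBT) the PMF -kBT ln P(S) gives A_L K_c = 2 b.

Fitting protocol: a Gaussian is first fitted to the distribution to locate
its mean mu and width sigma; the PMF is then fitted with a + b x^2 over five
ranges [mu - c sigma, mu + c sigma], c in {1, 1.25, 1.5, 1.75, 2}.  The
modulus is the one from c = 1 and the uncertainty is the (population)
standard deviation of the <= 5 moduli.  All moduli are per monolayer, in
units of kBT; temperature only relabels the energy unit because the samples
themselves are dimensionless angles and inverse lengths.

For lipid mixtures, per-species tilt moduli chi_i and per-pair splay moduli
chi_ij are combined into monolayer moduli by count-weighted harmonic means:

    1/K_c    = (1/phi_tot) sum_ij phi_ij / chi_ij
    1/kappa_t = (1/N_L)    sum_i  N_i   / chi_i
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DEFAULT_C_VALUES",
    "Histogram",
    "PmfCurve",
    "FitResult",
    "ModulusEstimate",
    "ModuliResult",
    "build_histogram",
    "fit_gaussian",
    "tilt_pmf",
    "splay_pmf",
    "fit_pmf_quadratic",
    "modulus_from_fits",
    "extract_tilt_modulus",
    "extract_splay_modulus",
    "combine_tilt_moduli",
    "combine_splay_moduli",
    "extract_tilt_and_splay_moduli",
]

DEFAULT_C_VALUES: tuple[float, ...] = (1.0, 1.25, 1.5, 1.75, 2.0)


@dataclass
class Histogram:
    centers: np.ndarray
    counts: np.ndarray
    probabilities: np.ndarray

    @property
    def bin_width(self) -> float:
        return float(self.centers[1] - self.centers[0]) if len(self.centers) > 1 else 0.0


@dataclass
class PmfCurve:
    """PMF in kBT units on the non-empty histogram bins, minimum shifted to 0."""

    x: np.ndarray
    f: np.ndarray
    source: str  # "tilt" | "splay"


@dataclass
class FitResult:
    a: float
    b: float
    mu: float
    sigma: float
    c: float
    fit_range: tuple[float, float]
    n_points: int


@dataclass
class ModulusEstimate:
    value: float
    uncertainty: float
    mu: float
    sigma: float
    fits: list[FitResult]
    histogram: Histogram
    pmf: PmfCurve
    n_samples: int


@dataclass
class ModuliResult:
    """Per-species / per-pair moduli plus mixture-combined monolayer values."""

    tilt: dict[str, ModulusEstimate]
    splay: dict[tuple[str, str], ModulusEstimate]
    kappa_t: float
    K_c: float
    area_per_lipid: float
    temperature: float
    tilt_counts: dict[str, int] = field(default_factory=dict)
    splay_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def summary_dict(self) -> dict:
        return {
            "temperature_K": self.temperature,
            "area_per_lipid_A2": self.area_per_lipid,
            "kappa_t_kBT": self.kappa_t,
            "K_c_kBT": self.K_c,
            "tilt_per_species": {
                sp: {
                    "kappa_t_kBT": est.value,
                    "uncertainty_kBT": est.uncertainty,
                    "n_samples": est.n_samples,
                }
                for sp, est in self.tilt.items()
            },
            "splay_per_pair": {
                "-".join(pair): {
                    "K_c_kBT": est.value,
                    "uncertainty_kBT": est.uncertainty,
                    "n_samples": est.n_samples,
                }
                for pair, est in self.splay.items()
            },
        }


# ---------------------------------------------------------------------------
# histograms and PMFs
# ---------------------------------------------------------------------------


def build_histogram(
    samples: np.ndarray,
    n_bins: int,
    value_range: tuple[float, float] | None = None,
) -> Histogram:
    """Equal-width histogram with probabilities = counts / total."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("cannot histogram an empty sample set")
    if samples.size < 100:
        warnings.warn(f"only {samples.size} samples; distribution will be noisy")
    lo, hi = value_range if value_range is not None else (samples.min(), samples.max())
    if hi <= lo:
        hi = lo + 1e-12
    counts, edges = np.histogram(samples, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Histogram(centers=centers, counts=counts, probabilities=counts / counts.sum())


def fit_gaussian(hist: Histogram) -> tuple[float, float]:
    """Least-squares Gaussian fit of the distribution; returns (mu, sigma).

    Initialized at the histogram mean/std; falls back to those moments with
    a warning if the fit does not converge.
    """
    used = hist.counts > 0
    if used.sum() < 3:
        raise ValueError("need at least 3 non-empty bins for a Gaussian fit")
    x = hist.centers[used]
    p = hist.probabilities[used]
    mu0 = float(np.sum(x * p) / p.sum())
    sigma0 = float(np.sqrt(np.sum(p * (x - mu0) ** 2) / p.sum()))
    sigma0 = max(sigma0, 1e-12)

    def gauss(xx, amp, mu, sigma):
        return amp * np.exp(-((xx - mu) ** 2) / (2.0 * sigma**2))

    try:
        popt, _ = curve_fit(
            gauss, x, p, p0=[p.max(), mu0, sigma0], maxfev=10000
        )
        mu, sigma = float(popt[1]), abs(float(popt[2]))
        if not np.isfinite(mu) or not np.isfinite(sigma) or sigma <= 0:
            raise RuntimeError("non-finite Gaussian parameters")
    except (RuntimeError, ValueError):
        warnings.warn("Gaussian fit did not converge; using sample moments")
        mu, sigma = mu0, sigma0
    return mu, sigma


def tilt_pmf(hist: Histogram, temperature: float = 300.0) -> PmfCurve:
    """Tilt PMF in kBT: -ln(P(theta)/sin theta) on non-empty bins, shifted to 0."""
    used = (hist.counts > 0) & (np.sin(hist.centers) > 0)
    if not np.any(used):
        raise ValueError("all histogram bins are empty")
    x = hist.centers[used]
    f = -np.log(hist.probabilities[used] / np.sin(x))
    return PmfCurve(x=x, f=f - f.min(), source="tilt")


def splay_pmf(hist: Histogram, temperature: float = 300.0) -> PmfCurve:
    """Splay PMF in kBT: -ln(P(S)) on non-empty bins, shifted to 0."""
    used = hist.counts > 0
    if not np.any(used):
        raise ValueError("all histogram bins are empty")
    x = hist.centers[used]
    f = -np.log(hist.probabilities[used])
    return PmfCurve(x=x, f=f - f.min(), source="splay")


def fit_pmf_quadratic(
    pmf: PmfCurve,
    mu: float,
    sigma: float,
    c_values: tuple[float, ...] = DEFAULT_C_VALUES,
    centered: bool = False,
) -> list[FitResult]:
    """Unweighted least-squares fits of a + b x^2 over ranges [mu - c sigma, mu + c sigma].

    With ``centered=True`` the model becomes a + b (x - mu)^2, which is the
    variant for distributions with nonzero spontaneous splay.  Ranges with
    fewer than 3 PMF points are skipped with a warning.
    """
    results: list[FitResult] = []
    for c in c_values:
        lo, hi = mu - c * sigma, mu + c * sigma
        sel = (pmf.x >= lo) & (pmf.x <= hi)
        if sel.sum() < 3:
            warnings.warn(f"fit range c={c} contains {int(sel.sum())} points; skipped")
            continue
        x = pmf.x[sel] - (mu if centered else 0.0)
        A = np.column_stack([np.ones_like(x), x**2])
        coef, *_ = np.linalg.lstsq(A, pmf.f[sel], rcond=None)
        results.append(
            FitResult(
                a=float(coef[0]),
                b=float(coef[1]),
                mu=mu,
                sigma=sigma,
                c=float(c),
                fit_range=(lo, hi),
                n_points=int(sel.sum()),
            )
        )
    if not results:
        raise ValueError("no fitting range contained at least 3 PMF points")
    return results


def modulus_from_fits(fits: list[FitResult], scale: float) -> tuple[float, float]:
    """Modulus = scale * b from the c = 1 fit; uncertainty = population std over fits."""
    by_c = {f.c: f for f in fits}
    primary = by_c.get(1.0, fits[0])
    values = np.array([scale * f.b for f in fits])
    return float(scale * primary.b), float(values.std())


# ---------------------------------------------------------------------------
# per-species / per-pair moduli
# ---------------------------------------------------------------------------


def extract_tilt_modulus(
    samples: np.ndarray,
    temperature: float = 300.0,
    n_bins: int = 90,
    c_values: tuple[float, ...] = DEFAULT_C_VALUES,
) -> ModulusEstimate:
    """Tilt modulus kappa_t (kBT, per monolayer) from tilt-angle samples.

    Chain: histogram over [0, pi/2] (1 degree bins by default) -> Gaussian
    fit for (mu, sigma) -> PMF -> quadratic fits -> kappa_t = 2 b(c=1).
    """
    samples = np.asarray(samples, dtype=float)
    hist = build_histogram(samples, n_bins, value_range=(0.0, np.pi / 2))
    mu, sigma = fit_gaussian(hist)
    pmf = tilt_pmf(hist, temperature)
    fits = fit_pmf_quadratic(pmf, mu, sigma, c_values)
    value, unc = modulus_from_fits(fits, scale=2.0)
    return ModulusEstimate(
        value=value, uncertainty=unc, mu=mu, sigma=sigma, fits=fits,
        histogram=hist, pmf=pmf, n_samples=samples.size,
    )


def extract_splay_modulus(
    samples: np.ndarray,
    area_per_lipid: float,
    temperature: float = 300.0,
    n_bins: int = 100,
    c_values: tuple[float, ...] = DEFAULT_C_VALUES,
    centered: bool = False,
) -> ModulusEstimate:
    """Bending rigidity K_c (kBT, per monolayer) from splay samples.

    K_c = 2 b(c=1) / A_L, where b carries Å² and A_L is the area per lipid.
    """
    if area_per_lipid <= 0:
        raise ValueError("area per lipid must be > 0")
    samples = np.asarray(samples, dtype=float)
    if samples.size and float(np.std(samples)) < 1e-12:
        raise ValueError("degenerate splay samples (zero variance)")
    hist = build_histogram(samples, n_bins)
    mu, sigma = fit_gaussian(hist)
    pmf = splay_pmf(hist, temperature)
    fits = fit_pmf_quadratic(pmf, mu, sigma, c_values, centered=centered)
    value, unc = modulus_from_fits(fits, scale=2.0 / area_per_lipid)
    return ModulusEstimate(
        value=value, uncertainty=unc, mu=mu, sigma=sigma, fits=fits,
        histogram=hist, pmf=pmf, n_samples=samples.size,
    )


# ---------------------------------------------------------------------------
# mixture combination
# ---------------------------------------------------------------------------


def combine_splay_moduli(
    chi_pairs: dict, phi_pairs: dict
) -> float:
    """Splay-count-weighted harmonic combination of per-pair splay moduli."""
    keys = list(chi_pairs)
    if not keys:
        raise ValueError("no splay moduli to combine")
    for k in keys:
        if chi_pairs[k] <= 0:
            raise ValueError(f"non-positive splay modulus for pair {k}")
        if phi_pairs.get(k, 0) <= 0:
            raise ValueError(f"non-positive splay count for pair {k}")
    phi_tot = float(sum(phi_pairs[k] for k in keys))
    inv = sum(phi_pairs[k] / chi_pairs[k] for k in keys) / phi_tot
    return float(1.0 / inv)


def combine_tilt_moduli(
    chi_species: dict, n_species: dict
) -> float:
    """Lipid-count-weighted harmonic combination of per-species tilt moduli."""
    keys = list(chi_species)
    if not keys:
        raise ValueError("no tilt moduli to combine")
    for k in keys:
        if chi_species[k] <= 0:
            raise ValueError(f"non-positive tilt modulus for species {k}")
        if n_species.get(k, 0) <= 0:
            raise ValueError(f"non-positive lipid count for species {k}")
    n_tot = float(sum(n_species[k] for k in keys))
    inv = sum(n_species[k] / chi_species[k] for k in keys) / n_tot
    return float(1.0 / inv)


# ---------------------------------------------------------------------------
# full chain with file/figure output
# ---------------------------------------------------------------------------


def _plot_estimate(est: ModulusEstimate, title: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.6))
    x, p = est.histogram.centers, est.histogram.probabilities
    ax1.plot(x, p, "k.", ms=3, label="P")
    amp = p.max() if p.size else 1.0
    xx = np.linspace(x.min(), x.max(), 300)
    ax1.plot(xx, amp * np.exp(-((xx - est.mu) ** 2) / (2 * est.sigma**2)),
             "g-", lw=1, label=r"$G(\mu,\sigma)$")
    ax1.axvline(est.mu, color="r", ls="--", lw=1)
    for s in (-1, 1):
        ax1.axvline(est.mu + s * est.sigma, color="b", ls="--", lw=0.8)
    ax1.set_xlabel("value")
    ax1.set_ylabel("probability")
    ax1.legend(fontsize=8)

    ax2.plot(est.pmf.x, est.pmf.f, "k.", ms=3, label="PMF")
    primary = next((f for f in est.fits if f.c == 1.0), est.fits[0])
    xx = np.linspace(primary.fit_range[0], primary.fit_range[1], 200)
    ax2.plot(xx, primary.a + primary.b * xx**2, "r--", lw=1,
             label=f"fit: b={primary.b:.3g}")
    ax2.set_xlabel("value")
    ax2.set_ylabel(r"PMF [$k_BT$]")
    ax2.legend(fontsize=8)
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _write_estimate_csv(est: ModulusEstimate, path: Path) -> None:
    import pandas as pd

    pmf_map = dict(zip(est.pmf.x, est.pmf.f))
    pd.DataFrame(
        {
            "bin_center": est.histogram.centers,
            "count": est.histogram.counts,
            "probability": est.histogram.probabilities,
            "pmf_kBT": [pmf_map.get(c, np.nan) for c in est.histogram.centers],
        }
    ).to_csv(path, index=False)


def extract_tilt_and_splay_moduli(
    tilt_samples: dict,
    splay_samples: dict,
    area_per_lipid: float,
    temperature: float = 300.0,
    outdir=None,
    n_bins_tilt: int = 90,
    n_bins_splay: int = 100,
    c_values: tuple[float, ...] = DEFAULT_C_VALUES,
    centered_splay_fit: bool = False,
) -> ModuliResult:
    """Full chain: distributions -> PMFs -> fits -> moduli -> mixture combination.

    ``tilt_samples`` maps species to tilt-angle arrays (or objects with a
    ``theta`` attribute); ``splay_samples`` maps unordered species pairs to
    splay arrays (or objects with a ``splay`` attribute).  When ``outdir`` is
    given, per-observable CSVs, figures, and a moduli summary (JSON + text)
    are written there.
    """

    def _tilt_array(v):
        return np.asarray(getattr(v, "theta", v), dtype=float)

    def _splay_array(v):
        return np.asarray(getattr(v, "splay", v), dtype=float)

    tilt_est: dict[str, ModulusEstimate] = {}
    tilt_counts: dict[str, int] = {}
    for sp, v in tilt_samples.items():
        arr = _tilt_array(v)
        tilt_est[sp] = extract_tilt_modulus(arr, temperature, n_bins_tilt, c_values)
        tilt_counts[sp] = arr.size

    splay_est: dict[tuple[str, str], ModulusEstimate] = {}
    splay_counts: dict[tuple[str, str], int] = {}
    for pair, v in splay_samples.items():
        arr = _splay_array(v)
        splay_est[pair] = extract_splay_modulus(
            arr, area_per_lipid, temperature, n_bins_splay, c_values,
            centered=centered_splay_fit,
        )
        splay_counts[pair] = arr.size

    kappa_t = combine_tilt_moduli(
        {sp: est.value for sp, est in tilt_est.items()}, tilt_counts
    )
    K_c = combine_splay_moduli(
        {pair: est.value for pair, est in splay_est.items()}, splay_counts
    )
    result = ModuliResult(
        tilt=tilt_est, splay=splay_est, kappa_t=kappa_t, K_c=K_c,
        area_per_lipid=area_per_lipid, temperature=temperature,
        tilt_counts=tilt_counts, splay_counts=splay_counts,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sp, est in tilt_est.items():
            _write_estimate_csv(est, outdir / f"tilt_{sp}_distribution.csv")
            _plot_estimate(est, f"tilt {sp}", outdir / f"tilt_{sp}.png")
        for pair, est in splay_est.items():
            tag = "-".join(pair)
            _write_estimate_csv(est, outdir / f"splay_{tag}_distribution.csv")
            _plot_estimate(est, f"splay {tag}", outdir / f"splay_{tag}.png")
        summary = result.summary_dict()
        (outdir / "moduli_summary.json").write_text(json.dumps(summary, indent=2))
        lines = [
            f"temperature: {temperature} K",
            f"area per lipid: {area_per_lipid} A^2",
            f"monolayer tilt modulus kappa_t: {kappa_t:.4g} kBT",
            f"monolayer bending rigidity K_c: {K_c:.4g} kBT",
        ]
        for sp, est in tilt_est.items():
            lines.append(
                f"  tilt {sp}: {est.value:.4g} +/- {est.uncertainty:.2g} kBT"
                f" (n={est.n_samples})"
            )
        for pair, est in splay_est.items():
            lines.append(
                f"  splay {'-'.join(pair)}: {est.value:.4g} +/- {est.uncertainty:.2g}"
                f" kBT (n={est.n_samples})"
            )
        (outdir / "moduli_summary.txt").write_text("\n".join(lines) + "\n")
    return result
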