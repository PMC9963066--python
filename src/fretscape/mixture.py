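"""Decomposition of transfer-efficiency histograms into conformational populations.

The histogram of burst efficiencies for a mixture of K conformational states
is modelled as a sum of K Gaussian peaks.  Each peak's width is bounded
below by the shot-noise width sqrt(E(1-E)/n̄) for the mean burst size n̄ —
a static state cannot be narrower than binomial counting statistics allows —
and any excess width (conformational heterogeneity, residual dynamics) is a
free parameter.  Peak areas give the population fractions, which sum to one
by construction.

The entry points follow the statsmodels idiom: build an
:class:`EfficiencyMixtureModel` from a histogram, call :meth:`fit`, and read
estimates, uncertainties and diagnostics off the returned
:class:`MixtureResults`; :func:`fit_mixture` is the functional shorthand.
Condition-linked fits (shared peak positions across denaturant conditions,
free fractions per condition) are provided by :func:`fit_mixture_shared`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.stats import norm

from .bursts import EfficiencyHistogram

__all__ = [
    "EfficiencyMixtureModel",
    "MixtureResults",
    "fit_mixture",
    "fit_mixture_shared",
]

DEFAULT_MEAN_BURST_SIZE = 80.0


def shot_noise_width(e: float, mean_burst_size: float) -> float:
    """Binomial shot-noise standard deviation of burst E at mean size n̄."""
    return float(np.sqrt(max(e * (1.0 - e), 1e-6) / mean_burst_size))


def _peak_bin_mass(edges: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Probability mass of a Gaussian peak in each histogram bin."""
    cdf = norm.cdf(edges, loc=mu, scale=sigma)
    return np.diff(cdf)


def _fraction_errors(minres, amps: np.ndarray, k: int) -> np.ndarray:
    """Delta-method standard errors of fractions f_i = a_i / Σa.

    Uses the covariance of the free amplitudes (a_0 is pinned); gradient
    ∂f_i/∂a_j = (δ_ij Σ − a_i)/Σ².
    """
    covar = getattr(minres, "covar", None)
    var_names = list(getattr(minres, "var_names", []))
    if covar is None:
        return np.full(k, np.nan)
    free = [f"amp{i}" for i in range(1, k)]
    try:
        idx = [var_names.index(n) for n in free]
    except ValueError:
        return np.full(k, np.nan)
    sub = covar[np.ix_(idx, idx)]
    total = amps.sum()
    errs = np.empty(k)
    for i in range(k):
        grad = np.array(
            [((1.0 if i == j else 0.0) * total - amps[i]) / total**2 for j in range(1, k)]
        )
        errs[i] = np.sqrt(max(grad @ sub @ grad, 0.0))
    return errs


class EfficiencyMixtureModel:
    """K-component Gaussian-peak model of an efficiency histogram.

    Parameters
    ----------
    histogram : EfficiencyHistogram
        Binned burst efficiencies (must be non-empty).
    k : int
        Number of components, >= 1.
    mean_burst_size : float, optional
        Mean number of donor-excitation photons per burst; sets the
        shot-noise floor on peak widths.  Default 80.
    fixed_means : sequence of float, optional
        Pin some or all component means (None entries stay free), e.g. to
        share a value determined at another condition.
    """

    def __init__(
        self,
        histogram: EfficiencyHistogram,
        k: int,
        mean_burst_size: float = DEFAULT_MEAN_BURST_SIZE,
        fixed_means=None,
    ) -> None:
        if histogram.is_empty:
            raise ValueError("cannot fit a mixture to an empty histogram")
        if k < 1:
            raise ValueError("number of components must be >= 1")
        if fixed_means is not None and len(fixed_means) != k:
            raise ValueError("fixed_means must have one entry per component")
        self.histogram = histogram
        self.k = k
        self.mean_burst_size = float(mean_burst_size)
        self.fixed_means = fixed_means

    # ------------------------------------------------------------------ fit

    def _initial_means(self) -> np.ndarray:
        """Spread starting means over the occupied part of the histogram."""
        h = self.histogram
        mass = h.normalized()
        cum = np.cumsum(mass)
        qs = (np.arange(self.k) + 0.5) / self.k
        idx = np.searchsorted(cum, qs)
        return h.centers[np.clip(idx, 0, len(mass) - 1)]

    def _make_params(self, start_means=None) -> lmfit.Parameters:
        means = np.asarray(start_means if start_means is not None else self._initial_means(), float)
        params = lmfit.Parameters()
        for i in range(self.k):
            fixed = self.fixed_means[i] if self.fixed_means is not None else None
            mu = fixed if fixed is not None else means[i]
            params.add(f"mu{i}", value=mu, min=-0.1, max=1.1, vary=fixed is None)
            # width = sqrt(shot^2 + excess^2): floor enforced by construction
            params.add(f"excess{i}", value=0.02, min=0.0, max=0.5)
            # amp0 pinned to 1: only amplitude ratios matter for the fractions
            params.add(f"amp{i}", value=1.0, min=0.0, vary=i > 0)
        return params

    def _component_masses(self, params: lmfit.Parameters, edges: np.ndarray) -> np.ndarray:
        out = np.empty((self.k, len(edges) - 1))
        for i in range(self.k):
            mu = params[f"mu{i}"].value
            sigma = np.hypot(shot_noise_width(np.clip(mu, 0.02, 0.98), self.mean_burst_size),
                             params[f"excess{i}"].value)
            out[i] = _peak_bin_mass(edges, mu, sigma)
        return out

    def _residual(self, params: lmfit.Parameters) -> np.ndarray:
        h = self.histogram
        comp = self._component_masses(params, h.bin_edges)
        amps = np.array([params[f"amp{i}"].value for i in range(self.k)])
        total = amps.sum()
        if total <= 0:
            return np.full(len(h.counts), 1e6)
        fracs = amps / total
        model = h.n_bursts * fracs @ comp
        # Pearson residuals: Poisson bin counts
        return (model - h.counts) / np.sqrt(np.maximum(model, 1.0))

    def fit(self, start_means=None, max_nfev: int = 5000) -> "MixtureResults":
        """Fit by Levenberg–Marquardt on Pearson residuals.

        Raises
        ------
        RuntimeError
            On optimizer failure, with the lmfit diagnostics attached.
        """
        params = self._make_params(start_means)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            minres = lmfit.minimize(self._residual, params, max_nfev=max_nfev)
        if not minres.success:
            raise RuntimeError(f"mixture fit did not converge: {minres.message}")
        return MixtureResults._from_minimizer(self, minres)


@dataclass
class MixtureResults:
    """Estimates from a histogram mixture fit, components sorted by mean E."""

    k: int
    means: np.ndarray
    widths: np.ndarray
    fractions: np.ndarray
    mean_errors: np.ndarray
    fraction_errors: np.ndarray
    redchi: float
    degenerate: bool
    flags: list[str]
    model: EfficiencyMixtureModel = field(repr=False)
    minimizer_result: lmfit.minimizer.MinimizerResult = field(repr=False)

    @classmethod
    def _from_minimizer(cls, model: EfficiencyMixtureModel, minres) -> "MixtureResults":
        p = minres.params
        k = model.k
        mus = np.array([p[f"mu{i}"].value for i in range(k)])
        amps = np.array([p[f"amp{i}"].value for i in range(k)])
        total = amps.sum()
        fracs = amps / total
        sigmas = np.array(
            [
                np.hypot(
                    shot_noise_width(np.clip(mus[i], 0.02, 0.98), model.mean_burst_size),
                    p[f"excess{i}"].value,
                )
                for i in range(k)
            ]
        )
        mu_err = np.array(
            [p[f"mu{i}"].stderr if p[f"mu{i}"].stderr else np.nan for i in range(k)]
        )
        frac_err = _fraction_errors(minres, amps, k)

        order = np.argsort(mus)
        mus, sigmas, fracs = mus[order], sigmas[order], fracs[order]
        mu_err, frac_err = mu_err[order], frac_err[order]

        flags = []
        if np.any(fracs < 1e-3):
            flags.append("vanishing component fraction")
        for i in range(k - 1):
            if mus[i + 1] - mus[i] < max(sigmas[i], sigmas[i + 1]):
                flags.append(f"components {i} and {i + 1} closer than one peak width")
        return cls(
            k=k,
            means=mus,
            widths=sigmas,
            fractions=fracs,
            mean_errors=mu_err,
            fraction_errors=frac_err,
            redchi=float(minres.redchi),
            degenerate=bool(flags),
            flags=flags,
            model=model,
            minimizer_result=minres,
        )

    def predicted_counts(self) -> np.ndarray:
        """Model-implied bin counts at the fitted parameters."""
        return self.model.histogram.n_bursts * self.fractions @ np.array(
            [
                _peak_bin_mass(self.model.histogram.bin_edges, self.means[i], self.widths[i])
                for i in range(self.k)
            ]
        )

    def summary(self) -> str:
        lines = [
            "Efficiency mixture fit",
            f"  components: {self.k}   bursts: {self.model.histogram.n_bursts}"
            f"   reduced chi2: {self.redchi:.3f}",
            "  comp    mean E      width    fraction",
        ]
        for i in range(self.k):
            me = f"{self.mean_errors[i]:.3f}" if np.isfinite(self.mean_errors[i]) else "--"
            fe = (
                f"{self.fraction_errors[i]:.3f}"
                if np.isfinite(self.fraction_errors[i])
                else "--"
            )
            lines.append(
                f"  {i:>4}  {self.means[i]:.3f}±{me}   {self.widths[i]:.3f}"
                f"   {self.fractions[i]:.3f}±{fe}"
            )
        for fl in self.flags:
            lines.append(f"  warning: {fl}")
        return "\n".join(lines)


def fit_mixture(
    histogram: EfficiencyHistogram,
    k: int,
    mean_burst_size: float = DEFAULT_MEAN_BURST_SIZE,
    fixed_means=None,
    start_means=None,
) -> MixtureResults:
    """Fit a K-component peak mixture to a histogram (functional shorthand)."""
    return EfficiencyMixtureModel(
        histogram, k, mean_burst_size=mean_burst_size, fixed_means=fixed_means
    ).fit(start_means=start_means)


def fit_mixture_shared(
    histograms: list[EfficiencyHistogram],
    k: int,
    mean_burst_size: float = DEFAULT_MEAN_BURST_SIZE,
    start_means=None,
) -> list[MixtureResults]:
    """Global fit of several histograms with shared component means.

    Peak positions are common to all conditions; widths and fractions are
    free per condition.  Returns per-condition results (components sorted by
    the shared means).
    """
    if not histograms:
        raise ValueError("need at least one histogram")
    models = [EfficiencyMixtureModel(h, k, mean_burst_size) for h in histograms]

    params = lmfit.Parameters()
    base = models[0]._make_params(start_means)
    for i in range(k):
        params.add(f"mu{i}", value=base[f"mu{i}"].value, min=-0.1, max=1.1)
    for c, m in enumerate(models):
        for i in range(k):
            params.add(f"excess{c}_{i}", value=0.02, min=0.0, max=0.5)
            params.add(f"amp{c}_{i}", value=1.0, min=0.0, vary=i > 0)

    def residual(p):
        res = []
        for c, m in enumerate(models):
            local = lmfit.Parameters()
            for i in range(k):
                local.add(f"mu{i}", value=p[f"mu{i}"].value)
                local.add(f"excess{i}", value=p[f"excess{c}_{i}"].value)
                local.add(f"amp{i}", value=p[f"amp{c}_{i}"].value)
            res.append(m._residual(local))
        return np.concatenate(res)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        minres = lmfit.minimize(residual, params, max_nfev=20000)
    if not minres.success:
        raise RuntimeError(f"shared mixture fit did not converge: {minres.message}")

    out = []
    for c, m in enumerate(models):
        local = lmfit.Parameters()
        for i in range(k):
            mu = minres.params[f"mu{i}"]
            local.add(f"mu{i}", value=mu.value)
            local[f"mu{i}"].stderr = mu.stderr
            ex = minres.params[f"excess{c}_{i}"]
            local.add(f"excess{i}", value=ex.value)
            local[f"excess{i}"].stderr = ex.stderr
            amp = minres.params[f"amp{c}_{i}"]
            local.add(f"amp{i}", value=amp.value)
            local[f"amp{i}"].stderr = amp.stderr

        class _Shim:
            params = local
            success = True
            redchi = minres.redchi
            message = minres.message

        out.append(MixtureResults._from_minimizer(m, _Shim()))
    return out
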