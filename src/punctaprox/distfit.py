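"""Two-component localisation-error distance-distribution model.

The distance between two fluorophores, each localised with isotropic 2-D
Gaussian error, follows a Rician-type density characterised by the true
separation µ and the combined localisation error σ:

    DD(r) = A · (r/σ²) · exp(−(µ² + r²)/(2σ²)) · I₀(rµ/σ²)

where I₀ is the modified Bessel function of integer order zero
(Churchman-style single-molecule distance analysis).  Super-resolution
nearest-neighbour histograms of two junctional proteins are modelled as
the sum of two such components — a frequent short-distance mode and an
occasional longer mode — fitted by non-linear least squares, with 95%
confidence intervals propagated from the covariance matrix and a
degeneracy rule (uncertainty larger than the estimate) that marks
uninformative fits, as happens for unpaired point patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, signal
from scipy.ndimage import gaussian_filter1d
from scipy.special import i0e

__all__ = [
    "RicianMixtureParams",
    "FitResult",
    "FitQualityReport",
    "dd_density",
    "fit_distance_model",
    "confidence_intervals",
    "assess_fit",
]

#: Parameter order used in arrays and covariance matrices.
PARAM_NAMES = ("a1", "mu1", "sigma1", "a2", "mu2", "sigma2")

_SIGMA_FLOOR = 1e-4  # µm; lower bound keeping the density finite


@dataclass
class RicianMixtureParams:
    """Parameters of the (up to) two-component distance density.

    ``a1, a2`` are dimensionless component amplitudes (each component
    integrates to its amplitude); ``mu1, mu2`` are the characteristic
    separations in µm; ``sigma1, sigma2`` the combined two-channel
    localisation errors in µm.  Setting ``a2 = 0`` selects the
    single-component model.
    """

    a1: float
    mu1: float
    sigma1: float
    a2: float = 0.0
    mu2: float = 0.0
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a1", "a2", "mu1", "mu2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.a1 > 0 and self.sigma1 <= 0:
            raise ValueError("sigma1 must be > 0 for an active component")
        if self.a2 > 0 and self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0 for an active component")

    @property
    def n_components(self) -> int:
        return 2 if self.a2 > 0 else 1

    def as_array(self) -> np.ndarray:
        return np.array([self.a1, self.mu1, self.sigma1, self.a2, self.mu2, self.sigma2])

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "RicianMixtureParams":
        a1, mu1, s1, a2, mu2, s2 = np.asarray(theta, dtype=float)
        return cls(a1=a1, mu1=mu1, sigma1=s1, a2=a2, mu2=mu2, sigma2=s2)

    def normalised_weights(self) -> tuple[float, float]:
        """Component proportions normalised to sum to 1."""
        total = self.a1 + self.a2
        if total <= 0:
            raise ValueError("total amplitude must be positive")
        return self.a1 / total, self.a2 / total

    def sorted_by_mu(self) -> "RicianMixtureParams":
        """Components reordered so mu1 <= mu2 (identity if single-component)."""
        if self.n_components == 2 and self.mu2 < self.mu1:
            return RicianMixtureParams(a1=self.a2, mu1=self.mu2, sigma1=self.sigma2,
                                       a2=self.a1, mu2=self.mu1, sigma2=self.sigma1)
        return self


def _component_density(r: np.ndarray, a: float, mu: float, sigma: float) -> np.ndarray:
    # a·(r/σ²)·exp(−(µ²+r²)/(2σ²))·I0(rµ/σ²), computed with the
    # exponentially scaled Bessel: exp(−(r−µ)²/(2σ²))·i0e(rµ/σ²),
    # which never overflows for large rµ/σ².
    if a == 0:
        return np.zeros_like(r)
    s2 = sigma * sigma
    return a * (r / s2) * np.exp(-((r - mu) ** 2) / (2.0 * s2)) * i0e(r * mu / s2)


def dd_density(r, params: RicianMixtureParams) -> np.ndarray:
    """Evaluate the mixture distance density (per µm) at distances ``r``.

    Raises on negative ``r``; each component integrates over [0, ∞) to its
    amplitude, so the full density integrates to ``a1 + a2``.
    """
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    if np.any(r < 0):
        raise ValueError("distances r must be >= 0")
    out = _component_density(r, params.a1, params.mu1, params.sigma1)
    out = out + _component_density(r, params.a2, params.mu2, params.sigma2)
    return float(out[0]) if scalar else out


@dataclass
class FitResult:
    """Least-squares fit of the distance density to a histogram.

    ``covariance`` and ``ci95`` follow the parameter order
    ``(a1, mu1, sigma1, a2, mu2, sigma2)`` (first three only for a
    single-component fit).  ``ci95`` are half-widths, 1.96·SE.
    """

    params: RicianMixtureParams
    covariance: np.ndarray
    ci95: np.ndarray
    residual_ss: float
    converged: bool
    degenerate: bool
    n_components: int = 2
    n: int = 0
    bin_width: float = float("nan")

    def param_array(self) -> np.ndarray:
        full = self.params.as_array()
        return full[:3] if self.n_components == 1 else full

    def param_names(self) -> tuple[str, ...]:
        return PARAM_NAMES[:3] if self.n_components == 1 else PARAM_NAMES

    def to_dict(self) -> dict:
        return {
            "params": dict(zip(PARAM_NAMES, self.params.as_array().tolist())),
            "ci95": dict(zip(self.param_names(), np.asarray(self.ci95).tolist())),
            "residual_ss": float(self.residual_ss),
            "converged": bool(self.converged),
            "degenerate": bool(self.degenerate),
            "n_components": int(self.n_components),
            "n": int(self.n),
            "bin_width": float(self.bin_width),
        }


def _model_2c(r, a1, mu1, s1, a2, mu2, s2):
    p = RicianMixtureParams(a1=a1, mu1=mu1, sigma1=max(s1, _SIGMA_FLOOR),
                            a2=a2, mu2=mu2, sigma2=max(s2, _SIGMA_FLOOR))
    return dd_density(r, p)


def _model_1c(r, a1, mu1, s1):
    p = RicianMixtureParams(a1=a1, mu1=mu1, sigma1=max(s1, _SIGMA_FLOOR))
    return dd_density(r, p)


def amplitudes_nnls(centres: np.ndarray, density: np.ndarray,
                    mus: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Solve for nonnegative component amplitudes given fixed (µ, σ).

    The density is linear in the amplitudes, so this is a nonnegative
    linear least-squares problem — used for initialisation and by the
    grid-search cross-check.
    """
    basis = np.column_stack([
        _component_density(centres, 1.0, mu, sigma)
        for mu, sigma in zip(mus, sigmas)
    ])
    amps, _ = optimize.nnls(basis, density)
    return amps


def _initial_guess(centres: np.ndarray, density: np.ndarray, bin_width: float,
                   n_components: int) -> np.ndarray:
    """Data-driven starting point: peak positions of a lightly smoothed
    histogram for µ, 2·bin_width for σ, NNLS for the amplitudes."""
    smoothed = gaussian_filter1d(density, sigma=1.0)
    peaks, props = signal.find_peaks(smoothed, prominence=0.0)
    if len(peaks) > 0:
        order = np.argsort(props["prominences"])[::-1]
        peak_pos = centres[peaks[order]]
    else:
        peak_pos = np.array([centres[int(np.argmax(smoothed))]])
    mode = float(peak_pos[0]) if peak_pos[0] > 0 else float(centres[len(centres) // 2])
    if n_components == 1:
        mus = np.array([mode])
    elif len(peak_pos) >= 2:
        mus = np.sort(peak_pos[:2])
    else:
        mus = np.array([mode, 3.0 * mode])
    sigmas = np.full(n_components, max(2.0 * bin_width, _SIGMA_FLOOR))
    amps = amplitudes_nnls(centres, density, mus, sigmas)
    amps = np.where(amps > 0, amps, 0.05)
    theta = np.empty(3 * n_components)
    theta[0::3] = amps
    theta[1::3] = mus
    theta[2::3] = sigmas
    return theta


def fit_distance_model(hist, n_components: int = 2,
                       init: RicianMixtureParams | None = None,
                       weighted: bool = True,
                       max_restarts: int = 5) -> FitResult:
    """Fit the distance density to a binned nearest-neighbour histogram.

    Parameters
    ----------
    hist : DistanceHistogram
        Density-normalised histogram (see :mod:`punctaprox.proximity`).
    n_components : {1, 2}
        Number of Rician components.
    init : RicianMixtureParams, optional
        Explicit starting point; otherwise a data-driven guess is used.
    weighted : bool
        If True (default), weight each bin by its Poisson counting error
        (SD of the density estimate, sqrt(count)/(n·bin_width)) and treat
        those errors as absolute when propagating the covariance — bin
        counts are Poisson, so this yields calibrated confidence
        intervals.  ``weighted=False`` gives plain unweighted least
        squares with residual-scaled covariance.
    max_restarts : int
        Perturbed restarts attempted on non-convergence.

    Returns
    -------
    FitResult
        With components sorted by µ ascending, covariance from the
        least-squares solution, 95% CIs and the degeneracy flag set.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    centres = hist.bin_centres()
    density = np.asarray(hist.density, dtype=float)
    k_free = 3 * n_components
    if np.count_nonzero(density) < k_free:
        raise ValueError(
            f"histogram has {np.count_nonzero(density)} nonzero bins; "
            f"need at least {k_free} to fit {k_free} parameters"
        )
    bin_width = float(np.diff(hist.bin_edges)[0])

    if init is not None:
        theta0_full = init.as_array()
        theta0 = theta0_full[:k_free]
    else:
        theta0 = _initial_guess(centres, density, bin_width, n_components)

    model = _model_1c if n_components == 1 else _model_2c
    lower = np.tile([0.0, 0.0, _SIGMA_FLOOR], n_components)
    upper = np.full(k_free, np.inf)
    theta0 = np.clip(theta0, lower + 1e-12, None)

    sigma_w = None
    if weighted:
        # per-bin SD of the density estimate from Poisson counts; empty
        # bins get the one-count floor so they keep a finite weight
        counts = np.maximum(density * hist.n * bin_width, 1.0)
        sigma_w = np.sqrt(counts) / (hist.n * bin_width)

    rng = np.random.default_rng(0)  # deterministic restart perturbations
    best = None
    attempt_theta = theta0.copy()
    for attempt in range(max_restarts + 1):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, pcov = optimize.curve_fit(
                    model, centres, density, p0=attempt_theta,
                    sigma=sigma_w, absolute_sigma=weighted,
                    bounds=(lower, upper), maxfev=20000,
                )
            resid = density - model(centres, *popt)
            rss = float(resid @ resid)
            ok = np.all(np.isfinite(popt))
            if best is None or (ok and rss < best[2]):
                best = (popt, pcov, rss, ok)
            if ok and np.all(np.isfinite(pcov)):
                break
        except (RuntimeError, ValueError):
            pass
        attempt_theta = np.clip(
            theta0 * rng.uniform(0.5, 1.5, size=k_free), lower + 1e-12, None)

    if best is None:
        popt = theta0
        pcov = np.full((k_free, k_free), np.inf)
        rss = float(np.sum((density - model(centres, *theta0)) ** 2))
        converged = False
    else:
        popt, pcov, rss, converged = best

    # assemble full parameter vector, sort components by mu, permute cov
    if n_components == 1:
        full = np.array([popt[0], popt[1], max(popt[2], _SIGMA_FLOOR), 0.0, 0.0, 1.0])
        perm = np.arange(3)
    else:
        full = popt.copy()
        full[2] = max(full[2], _SIGMA_FLOOR)
        full[5] = max(full[5], _SIGMA_FLOOR)
        if full[4] < full[1]:
            perm = np.array([3, 4, 5, 0, 1, 2])
            full = full[perm]
        else:
            perm = np.arange(6)
    pcov = np.asarray(pcov)[np.ix_(perm, perm)]

    params = RicianMixtureParams.from_array(
        full if n_components == 2 else np.array([full[0], full[1], full[2], 0.0, 0.0, 1.0]))
    result = FitResult(params=params, covariance=pcov,
                       ci95=np.full(k_free, np.nan), residual_ss=rss,
                       converged=bool(converged), degenerate=False,
                       n_components=n_components, n=hist.n, bin_width=bin_width)
    result = confidence_intervals(result)
    result.degenerate = assess_fit(result).degenerate
    return result


def confidence_intervals(fit: FitResult) -> FitResult:
    """Attach 95% CI half-widths (1.96·√diag(cov)) to a fit.

    Non-finite covariance entries produce infinite half-widths and force
    the degenerate flag.
    """
    diag = np.diag(np.asarray(fit.covariance, dtype=float)).copy()
    bad = ~np.isfinite(diag) | (diag < 0)
    diag[bad] = np.inf
    ci95 = 1.96 * np.sqrt(diag)
    degenerate = fit.degenerate or bool(np.any(~np.isfinite(ci95)))
    return replace(fit, ci95=ci95, degenerate=degenerate)


@dataclass
class FitQualityReport:
    """Outcome of the degeneracy rule: a fit is uninformative when any
    active parameter's 95% CI half-width exceeds the estimate itself."""

    degenerate: bool
    offending: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"degenerate": self.degenerate, "offending": list(self.offending)}


def assess_fit(fit: FitResult) -> FitQualityReport:
    """Apply the degenerate-fit criterion to every active parameter."""
    names = fit.param_names()
    estimates = fit.param_array()
    offending = [
        name for name, est, hw in zip(names, estimates, fit.ci95)
        if not np.isfinite(hw) or hw > abs(est)
    ]
    return FitQualityReport(degenerate=bool(offending), offending=offending)
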