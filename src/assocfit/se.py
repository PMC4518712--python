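"""Sedimentation-equilibrium forward model and global self-association fit.

At equilibrium in the centrifuge, each species of oligomer size ``n``
distributes radially as an exponential in r²,

    c_n(r) = c_n(r0) · exp( n·σ1·(r² − r0²)/2 ),

where σ1 = M(1−v̄ρ)ω²/(RT) is the reduced buoyant molar mass of the monomer
(cm⁻²).  The observed absorbance is the per-monomer-unit signal summed over
species plus a per-channel baseline.  Mass-action coupling ties the reference
concentrations of all species to the free monomer through the
:class:`~assocfit.equilibria.AssociationScheme`, and mass conservation over
the sector-shaped channel,

    loading = 2 ∫_m^b c(r)·r dr / (b² − m²),

is imposed as a hard constraint: the reference free-monomer level of every
channel is eliminated by solving this equation at the known loading, so the
only global fit parameters are the log10 dissociation constants (plus one
bounded baseline per channel, solved linearly).

The fit is performed by :class:`SEGlobalFitter`, an estimator in the
scikit-learn style; Monte Carlo confidence intervals come from a parametric
bootstrap that re-adds Gaussian noise at the fitted residual level and
refits.  :func:`correct_s20w` applies the standard-condition (water, 20 °C)
correction for sedimentation coefficients.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate, optimize
from sklearn.base import BaseEstimator

from .equilibria import AssociationScheme, solve_species

__all__ = [
    "SolutionProperties",
    "SEChannel",
    "SEExperiment",
    "SEFitResult",
    "SvCorrectionInput",
    "reduced_buoyant_sigma",
    "se_profile",
    "conserve_mass",
    "SEGlobalFitter",
    "fit_se_global",
    "monte_carlo_ci",
    "correct_s20w",
    "DegenerateBuoyancyError",
    "ModelRangeError",
    "SEFitError",
]

#: Gas constant in cgs units, erg/(mol K)
R_CGS = 8.314e7
#: Viscosity of water at 20 °C, cP
ETA_WATER_20 = 1.002
#: Density of water at 20 °C, g/ml
RHO_WATER_20 = 0.99823

_MAX_EXPONENT = 700.0


class DegenerateBuoyancyError(ValueError):
    """v̄·ρ = 1: the particle neither sediments nor floats."""


class ModelRangeError(ValueError):
    """The exponential model overflows for the requested parameters."""


class SEFitError(RuntimeError):
    """All optimization starts failed; ``args[1]`` holds per-start info."""


@dataclass(frozen=True)
class SolutionProperties:
    """Solvent and optical properties shared by all channels of a run.

    molar_signal converts molar monomer-unit concentration times the optical
    pathlength (cm) into absorbance; for 280 nm data a useful default is a
    mass extinction of ~0.75 AU·ml/(mg·cm), i.e. ``0.75 * monomer_mass``.
    """

    monomer_mass: float  # g/mol
    vbar: float = 0.73  # ml/g
    density: float = 1.005  # g/ml
    viscosity: float = 1.002  # cP
    molar_signal: float | None = None  # AU cm^-1 M^-1
    pathlength: float = 1.2  # cm
    temperature: float = 293.15  # K

    def __post_init__(self):
        if self.molar_signal is None:
            object.__setattr__(self, "molar_signal", 0.75 * self.monomer_mass)
        for name in (
            "monomer_mass",
            "vbar",
            "density",
            "viscosity",
            "molar_signal",
            "pathlength",
            "temperature",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def signal_per_molar(self) -> float:
        """Absorbance produced by 1 M of monomer units in this cell."""
        return self.molar_signal * self.pathlength


@dataclass(frozen=True)
class SEChannel:
    """One radial absorbance scan with its channel metadata."""

    radii: np.ndarray  # cm, strictly increasing
    signal: np.ndarray  # AU
    rotor_speed: float  # rpm
    loading_signal: float  # AU (known loading in signal units)
    meniscus: float = 6.95  # cm
    bottom: float = 7.25  # cm
    noise_sigma: float | None = None  # AU

    def __post_init__(self):
        radii = np.asarray(self.radii, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "signal", signal)
        if radii.size < 20:
            raise ValueError("a channel needs at least 20 radial points")
        if radii.size != signal.size:
            raise ValueError("radii and signal must have equal length")
        if np.any(np.diff(radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        if not (self.meniscus < radii[0] and radii[-1] < self.bottom):
            raise ValueError("radii must lie strictly inside (meniscus, bottom)")
        if self.rotor_speed <= 0:
            raise ValueError("rotor_speed must be positive")


@dataclass(frozen=True)
class SEExperiment:
    """A multi-channel SE dataset fitted globally with one scheme."""

    channels: tuple[SEChannel, ...]
    properties: SolutionProperties
    scheme: AssociationScheme

    def __post_init__(self):
        object.__setattr__(self, "channels", tuple(self.channels))
        if not self.channels:
            raise ValueError("an experiment needs at least one channel")


@dataclass(frozen=True)
class SEFitResult:
    """Global-fit output: constants, per-channel nuisances, fit statistics."""

    kd_estimates: tuple[float, ...]  # molar-scale overall constants
    per_channel_baseline: tuple[float, ...]  # AU
    per_channel_reference_conc: tuple[float, ...]  # molar free monomer at meniscus
    reduced_chi2: float
    rmsd_per_channel: tuple[float, ...]  # AU
    kd_ci: tuple[tuple[float, float], ...] | None = None
    n_monte_carlo: int = 0
    ci_level: float | None = None
    at_boundary: bool = False
    objective: float = 0.0

    def __post_init__(self):
        if self.reduced_chi2 < 0:
            raise ValueError("reduced chi-square must be >= 0")
        if self.kd_ci is not None:
            for est, (lo, hi) in zip(self.kd_estimates, self.kd_ci):
                if not (lo <= est <= hi):
                    raise ValueError("CI must bracket the estimate")


@dataclass(frozen=True)
class SvCorrectionInput:
    """Inputs for the s20,w standard-condition correction."""

    s_observed: float  # svedberg
    buffer_density: float  # g/ml
    buffer_viscosity: float  # cP
    vbar: float  # ml/g
    temperature: float = 293.15  # K

    def __post_init__(self):
        for name in ("s_observed", "buffer_density", "buffer_viscosity", "vbar"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def reduced_buoyant_sigma(properties: SolutionProperties, rotor_speed: float) -> float:
    """Reduced buoyant molar mass σ = M(1−v̄ρ)ω²/(RT) of the monomer, cm⁻².

    ``rotor_speed`` in rpm; consistent cgs units internally.
    """
    if rotor_speed <= 0:
        raise ValueError("rotor_speed must be positive")
    buoyancy = 1.0 - properties.vbar * properties.density
    if abs(buoyancy) < 1e-12:
        raise DegenerateBuoyancyError("v̄·ρ = 1; buoyant mass vanishes")
    omega = 2.0 * math.pi * rotor_speed / 60.0
    return (
        properties.monomer_mass
        * buoyancy
        * omega**2
        / (R_CGS * properties.temperature)
    )


def _species_exponents(scheme: AssociationScheme, sigma1: float) -> np.ndarray:
    return sigma1 * np.asarray(scheme.stoichiometries, dtype=float)


def se_profile(
    scheme: AssociationScheme,
    sigma1: float,
    ref_radius: float,
    ref_free_monomer: float,
    radii: np.ndarray,
    baseline: float,
    properties: SolutionProperties,
) -> np.ndarray:
    """Model absorbance at each radius for a mass-action species mixture.

    signal(r) = baseline + ε·l · Σ_i n_i · c_i(r0) · exp(n_i σ1 (r²−r0²)/2)
    with c_i(r0) following mass action from the reference free monomer.
    """
    radii = np.asarray(radii, dtype=float)
    n = np.asarray(scheme.stoichiometries, dtype=float)
    c_ref = scheme.species_conc(ref_free_monomer)
    expo = np.outer(n * sigma1 * 0.5, radii**2 - ref_radius**2)
    if np.any(expo > _MAX_EXPONENT):
        raise ModelRangeError("exponent exceeds overflow guard (700)")
    conc_units = (n * c_ref) @ np.exp(expo)  # monomer units, molar
    return baseline + properties.signal_per_molar * conc_units


def _sector_average_factor(a: float, ref_radius: float, meniscus: float, bottom: float) -> float:
    """Sector average of exp(a·(r²−r0²)/2) over [meniscus, bottom].

    Closed form: 2·[exp(a(b²−r0²)/2) − exp(a(m²−r0²)/2)] / (a·(b²−m²)).
    """
    if abs(a) < 1e-14:
        return 1.0
    hi = a * (bottom**2 - ref_radius**2) / 2.0
    lo = a * (meniscus**2 - ref_radius**2) / 2.0
    if max(hi, lo) > _MAX_EXPONENT:
        raise ModelRangeError("exponent exceeds overflow guard (700)")
    return 2.0 * (math.exp(hi) - math.exp(lo)) / (a * (bottom**2 - meniscus**2))


def _implied_loading(
    scheme: AssociationScheme,
    sigma1: float,
    ref_radius: float,
    ref_free_monomer: float,
    meniscus: float,
    bottom: float,
) -> float:
    """Sector-average loading (molar monomer units), closed form.

    Scalar-math hot path: called inside the per-channel root solve of every
    objective evaluation.
    """
    m0 = ref_free_monomer
    total = m0 * _sector_average_factor(sigma1, ref_radius, meniscus, bottom)
    for n, kd in zip(scheme.stoichiometries[1:], scheme.kd_steps):
        if math.isinf(kd) or m0 == 0.0:
            continue
        ci = m0**n / kd
        total += n * ci * _sector_average_factor(n * sigma1, ref_radius, meniscus, bottom)
    return total


def conserve_mass(
    channel: SEChannel,
    scheme: AssociationScheme,
    sigma1: float,
    ref_radius: float,
    ref_free_monomer: float,
    rtol: float = 1e-10,
) -> float:
    """Sector-average loading implied by the model, molar monomer units.

    loading = 2 ∫_m^b c(r)·r dr / (b²−m²), by adaptive quadrature.  Used to
    re-parameterize the reference free monomer from the known loading (hard
    constraint); the fitter uses the equivalent closed form internally.
    """
    n = np.asarray(scheme.stoichiometries, dtype=float)
    c_ref = scheme.species_conc(ref_free_monomer)

    def conc(r: float) -> float:
        return float(
            np.dot(n * c_ref, np.exp(n * sigma1 * (r**2 - ref_radius**2) / 2.0))
        )

    val, err = integrate.quad(
        lambda r: conc(r) * r, channel.meniscus, channel.bottom,
        epsrel=rtol, epsabs=0.0, limit=200,
    )
    if val != 0 and err > 100 * rtol * abs(val):
        raise RuntimeError("mass-conservation integral did not converge")
    return 2.0 * val / (channel.bottom**2 - channel.meniscus**2)


def _ref_monomer_for_loading(
    scheme: AssociationScheme,
    sigma1: float,
    loading_molar: float,
    meniscus: float,
    bottom: float,
) -> float:
    """Solve the reference (meniscus) free monomer from the known loading.

    With the reference at the meniscus every species' sector-average factor
    is >= 1, so the implied loading at m0 = loading already overshoots and
    [0, loading] brackets the root.
    """
    if loading_molar <= 0:
        return 0.0

    def g(m0: float) -> float:
        return _implied_loading(scheme, sigma1, meniscus, m0, meniscus, bottom) - loading_molar

    return optimize.brentq(
        g, 0.0, loading_molar, xtol=1e-30, rtol=8.9e-16, maxiter=300
    )


def correct_s20w(inp: SvCorrectionInput) -> float:
    """Correct an observed sedimentation coefficient to water at 20 °C.

    s20,w = s_obs · (η_buffer/η_20,w) · (1 − v̄ρ)_20,w / (1 − v̄ρ)_buffer.
    """
    b_buffer = 1.0 - inp.vbar * inp.buffer_density
    if abs(b_buffer) < 1e-12:
        raise DegenerateBuoyancyError("(1 − v̄ρ)_buffer = 0")
    b_water = 1.0 - inp.vbar * RHO_WATER_20
    return (
        inp.s_observed
        * (inp.buffer_viscosity / ETA_WATER_20)
        * (b_water / b_buffer)
    )


class SEGlobalFitter(BaseEstimator):
    """Global sedimentation-equilibrium fit of self-association constants.

    The log10 dissociation constants are shared across all channels; each
    channel's reference free monomer is eliminated through the hard
    mass-conservation constraint at its known loading, and its baseline is
    the (bounded) weighted-mean residual, solved in closed form.  Five
    log-spaced initializations spanning 0.01–100× a slope-based guess guard
    against local optima.

    Parameters
    ----------
    n_starts : number of multistart initializations.
    log10_kd_bounds : bounds on each log10 constant (molar scale).
    baseline_bound : per-channel baseline bound, AU.

    Attributes (after :meth:`fit`)
    ------------------------------
    kd_ : tuple of fitted overall dissociation constants (M^(n-1)).
    log10_kd_ : their log10s.
    baselines_, ref_monomer_, reduced_chi2_, rmsd_per_channel_ : nuisances
        and fit statistics; ``result_`` bundles everything as
        :class:`SEFitResult`.
    """

    def __init__(
        self,
        n_starts: int = 5,
        log10_kd_bounds: tuple[float, float] = (-9.0, -1.0),
        baseline_bound: float = 0.1,
        xatol: float = 1e-7,
    ):
        self.n_starts = n_starts
        self.log10_kd_bounds = log10_kd_bounds
        self.baseline_bound = baseline_bound
        self.xatol = xatol

    # -- internals ---------------------------------------------------------

    def _channel_stats(self, experiment: SEExperiment):
        props = experiment.properties
        stats = []
        for ch in experiment.channels:
            sigma1 = reduced_buoyant_sigma(props, ch.rotor_speed)
            loading_molar = ch.loading_signal / props.signal_per_molar
            w = 1.0 if not ch.noise_sigma else 1.0 / ch.noise_sigma**2
            stats.append((ch, sigma1, loading_molar, w))
        return stats

    def _eval(self, log10_kds: np.ndarray, experiment: SEExperiment, stats):
        """Weighted SSR plus per-channel nuisances for given constants."""
        props = experiment.properties
        scheme = AssociationScheme(
            experiment.scheme.stoichiometries, tuple(10.0**k for k in log10_kds)
        )
        ssr = 0.0
        baselines, refs, rmsds = [], [], []
        for ch, sigma1, loading_molar, w in stats:
            m0 = _ref_monomer_for_loading(
                scheme, sigma1, loading_molar, ch.meniscus, ch.bottom
            )
            model = se_profile(
                scheme, sigma1, ch.meniscus, m0, ch.radii, 0.0, props
            )
            resid = ch.signal - model
            b = float(np.clip(np.mean(resid), -self.baseline_bound, self.baseline_bound))
            resid = resid - b
            ssr += w * float(resid @ resid)
            baselines.append(b)
            refs.append(m0)
            rmsds.append(float(np.sqrt(np.mean(resid**2))))
        return ssr, baselines, refs, rmsds

    def _guess_log10_kd(self, experiment: SEExperiment, stats) -> float:
        """Slope-based guess: apparent weight-average mass vs monomer mass."""
        props = experiment.properties
        ratios, loads = [], []
        for ch, sigma1, loading_molar, _ in stats:
            y = ch.signal - np.min(ch.signal) + 1e-4
            slope = np.polyfit(ch.radii**2, np.log(y), 1)[0]
            ratios.append(np.clip(2.0 * slope / sigma1, 1.0, 2.0))
            loads.append(loading_molar)
        q = float(np.median(ratios))  # apparent mass ratio in [1, 2]
        c = float(np.median(loads))
        f = np.clip(q - 1.0, 0.05, 0.95)  # crude fraction of units in dimer
        kd = 2.0 * c * (1.0 - f) ** 2 / f
        lo, hi = self.log10_kd_bounds
        return float(np.clip(np.log10(kd), lo, hi))

    # -- estimator API -----------------------------------------------------

    def fit(self, X: SEExperiment, y=None):
        """Fit the experiment; ``X`` is an :class:`SEExperiment`."""
        if not isinstance(X, SEExperiment):
            raise TypeError("X must be an SEExperiment")
        experiment = X
        stats = self._channel_stats(experiment)
        lo, hi = self.log10_kd_bounds
        oligomers = experiment.scheme.stoichiometries[1:]
        n_steps = len(oligomers)
        # overall constants K_n = [M]^n/[M_n] scale as the (n-1)-th power of
        # a molar constant, so bounds and starts stretch accordingly
        scale = np.array([n - 1 for n in oligomers], dtype=float)
        step_bounds = [(lo * s, hi * s) for s in scale]
        center = self._guess_log10_kd(experiment, stats)

        override = getattr(self, "_x0_override", None)
        if override is not None:
            starts = [np.asarray(override, dtype=float)]
        else:
            if self.n_starts == 1:
                offsets = np.array([0.0])
            else:
                offsets = np.linspace(-2.0, 2.0, self.n_starts)
            starts = [
                np.clip(
                    center * scale + off,
                    [b[0] + 0.05 for b in step_bounds],
                    [b[1] - 0.05 for b in step_bounds],
                )
                for off in offsets
            ]

        best = None
        failures = []
        for x0 in starts:
            try:
                res = optimize.minimize(
                    lambda th: self._eval(th, experiment, stats)[0],
                    x0,
                    method="Nelder-Mead",
                    bounds=step_bounds,
                    options={"xatol": self.xatol, "fatol": 1e-12, "maxiter": 400 * n_steps},
                )
            except (ModelRangeError, RuntimeError) as exc:  # pragma: no cover
                failures.append((float(x0[0]), repr(exc)))
                continue
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise SEFitError("all optimization starts failed", failures)

        theta = np.asarray(best.x, dtype=float)
        ssr, baselines, refs, rmsds = self._eval(theta, experiment, stats)
        n_points = sum(ch.radii.size for ch in experiment.channels)
        n_free = n_steps + len(experiment.channels)
        at_boundary = bool(
            any(
                min(t - b[0], b[1] - t) < 1e-3
                for t, b in zip(theta, step_bounds)
            )
        )
        if at_boundary:
            warnings.warn("a fitted constant sits at its bound", RuntimeWarning)

        self.log10_kd_ = tuple(float(t) for t in theta)
        self.kd_ = tuple(10.0**t for t in theta)
        self.baselines_ = tuple(baselines)
        self.ref_monomer_ = tuple(refs)
        self.rmsd_per_channel_ = tuple(rmsds)
        self.reduced_chi2_ = ssr / (n_points - n_free)
        self.result_ = SEFitResult(
            kd_estimates=self.kd_,
            per_channel_baseline=self.baselines_,
            per_channel_reference_conc=self.ref_monomer_,
            reduced_chi2=self.reduced_chi2_,
            rmsd_per_channel=self.rmsd_per_channel_,
            at_boundary=at_boundary,
            objective=float(ssr),
        )
        self._experiment = experiment
        return self

    def predict(self, X: SEExperiment | None = None) -> list[np.ndarray]:
        """Best-fit model signal for every channel of the experiment."""
        if not hasattr(self, "kd_"):
            raise RuntimeError("call fit first")
        experiment = X if X is not None else self._experiment
        props = experiment.properties
        scheme = AssociationScheme(experiment.scheme.stoichiometries, self.kd_)
        out = []
        for ch, b in zip(experiment.channels, self.baselines_):
            sigma1 = reduced_buoyant_sigma(props, ch.rotor_speed)
            loading_molar = ch.loading_signal / props.signal_per_molar
            m0 = _ref_monomer_for_loading(
                scheme, sigma1, loading_molar, ch.meniscus, ch.bottom
            )
            out.append(se_profile(scheme, sigma1, ch.meniscus, m0, ch.radii, b, props))
        return out

    def monte_carlo_ci(
        self,
        n_iter: int = 500,
        level: float = 0.95,
        seed: int | None = None,
        method: str = "parametric",
    ) -> SEFitResult:
        """Parametric-bootstrap confidence intervals on the constants.

        Fresh Gaussian noise at the fitted per-channel residual σ is added to
        the best-fit model and the fit repeated (single start at the current
        optimum); the CI is the percentile interval at ``level``.  With
        ``method='residual'`` the channel residuals are resampled instead.
        """
        if not hasattr(self, "kd_"):
            raise RuntimeError("call fit first")
        if n_iter == 0:
            return self.result_
        rng = np.random.default_rng(seed)
        experiment = self._experiment
        models = self.predict()
        draws = []
        failures = 0
        refit = SEGlobalFitter(
            n_starts=1,
            log10_kd_bounds=self.log10_kd_bounds,
            baseline_bound=self.baseline_bound,
            xatol=self.xatol,
        )
        for _ in range(n_iter):
            chans = []
            for ch, model, sig in zip(
                experiment.channels, models, self.rmsd_per_channel_
            ):
                if method == "parametric":
                    noise = rng.normal(0.0, sig, size=model.size)
                elif method == "residual":
                    resid = ch.signal - model
                    noise = rng.choice(resid, size=model.size, replace=True)
                else:
                    raise ValueError(f"unknown bootstrap method {method!r}")
                chans.append(replace(ch, signal=model + noise))
            sim = SEExperiment(tuple(chans), experiment.properties, experiment.scheme)
            try:
                refit._x0_override = np.asarray(self.log10_kd_)
                refit.fit(sim)
                draws.append(refit.log10_kd_)
            except (SEFitError, RuntimeError):
                failures += 1
        if failures > 0.2 * n_iter:
            raise SEFitError(
                f"{failures}/{n_iter} Monte Carlo refits failed; CI unreliable", []
            )
        draws = np.asarray(draws)
        alpha = (1.0 - level) / 2.0
        cis = []
        for j, est in enumerate(self.log10_kd_):
            lo_q, hi_q = np.quantile(draws[:, j], [alpha, 1.0 - alpha])
            lo_q, hi_q = min(lo_q, est), max(hi_q, est)
            cis.append((10.0**lo_q, 10.0**hi_q))
        self.kd_ci_ = tuple(cis)
        self.result_ = replace(
            self.result_, kd_ci=self.kd_ci_, n_monte_carlo=n_iter, ci_level=level
        )
        return self.result_


def fit_se_global(
    experiment: SEExperiment,
    n_starts: int = 5,
    log10_kd_bounds: tuple[float, float] = (-9.0, -1.0),
    baseline_bound: float = 0.1,
) -> SEFitResult:
    """Functional wrapper over :class:`SEGlobalFitter`."""
    fitter = SEGlobalFitter(
        n_starts=n_starts,
        log10_kd_bounds=log10_kd_bounds,
        baseline_bound=baseline_bound,
    )
    return fitter.fit(experiment).result_


def monte_carlo_ci(
    experiment: SEExperiment,
    n_iter: int = 500,
    level: float = 0.95,
    seed: int | None = None,
    method: str = "parametric",
    **fit_kwargs,
) -> SEFitResult:
    """Fit then attach Monte Carlo CIs (functional wrapper)."""
    fitter = SEGlobalFitter(**fit_kwargs)
    fitter.fit(experiment)
    return fitter.monte_carlo_ci(n_iter=n_iter, level=level, seed=seed, method=method)
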