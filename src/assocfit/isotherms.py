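"""MST dose–response and ITC injection-heat models with fitting.

Two microscale-thermophoresis isotherms are provided:

* ``one_to_one`` — the exact quadratic bound fraction of a labeled species
  titrated with a distinct partner.
* ``self_association`` — a trace-labeled protein titrated with the *same*
  unlabeled protein.  The unlabeled free monomer follows the dimerization
  quadratic ``u + 2u²/Kd = U_total``; the labeled bound fraction is then
  ``u/(kd_het + u)`` with the statistical heterodimer constant
  ``kd_het = Kd_dim/2`` by default (the label·unlabeled pair carries twice
  the combinatoric weight of a homo-pair; a toggle is provided because
  instrument 1:1 fits lack this factor).

The ITC forward model is the standard one-site injection-heat series with a
perfusion-cell dilution factor ``(1 − v/V)`` per injection; fitting yields a
:class:`~assocfit.equilibria.ThermoResult` (Kd, ΔG, ΔH, TΔS, N) at the
experiment temperature.  Heats are reported in µcal (1 cal = 4.184 J).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .equilibria import ThermoResult

__all__ = [
    "MSTSeries",
    "MSTFit",
    "ITCExperiment",
    "ITCFit",
    "fraction_bound_1to1",
    "fraction_bound_self",
    "dilution_series",
    "itc_heats",
    "MSTFitter",
    "ITCFitter",
    "fit_mst",
    "fit_itc",
    "UnidentifiableAmplitudeError",
]

J_PER_CAL = 4.184


class UnidentifiableAmplitudeError(RuntimeError):
    """Fitted MST amplitude indistinguishable from noise."""


@dataclass(frozen=True)
class MSTSeries:
    """A thermophoresis dose–response series (concentrations in nM)."""

    titrant_total: np.ndarray  # nM, strictly decreasing
    labeled_total: float  # nM
    fnorm: np.ndarray  # per mil

    def __post_init__(self):
        t = np.asarray(self.titrant_total, dtype=float)
        f = np.asarray(self.fnorm, dtype=float)
        object.__setattr__(self, "titrant_total", t)
        object.__setattr__(self, "fnorm", f)
        if t.size < 8:
            raise ValueError("an MST series needs at least 8 points")
        if t.size != f.size:
            raise ValueError("titrant and fnorm must have equal length")
        if np.any(np.diff(t) >= 0):
            raise ValueError("titrant series must be strictly decreasing")
        if self.labeled_total <= 0:
            raise ValueError("labeled_total must be positive")


@dataclass(frozen=True)
class MSTFit:
    """Fitted MST parameters; concentrations molar, fnorm per mil."""

    kd: float
    f_free: float
    f_bound: float
    model_tag: str
    kd_ci: tuple[float, float] | None = None
    residual_rms: float = 0.0

    def __post_init__(self):
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if self.f_free == self.f_bound:
            raise ValueError("f_free must differ from f_bound")


@dataclass(frozen=True)
class ITCExperiment:
    """An ITC titration design with integrated per-injection heats."""

    cell_volume: float  # µl
    cell_conc: float  # µM
    syringe_conc: float  # µM
    injection_volumes: np.ndarray  # µl
    heats: np.ndarray  # µcal
    temperature: float = 298.15  # K

    def __post_init__(self):
        v = np.asarray(self.injection_volumes, dtype=float)
        q = np.asarray(self.heats, dtype=float)
        object.__setattr__(self, "injection_volumes", v)
        object.__setattr__(self, "heats", q)
        if self.cell_volume <= 0 or self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if np.any(v <= 0):
            raise ValueError("injection volumes must be positive")
        if v.size != q.size:
            raise ValueError("heats and injection_volumes must have equal length")


@dataclass(frozen=True)
class ITCFit:
    """One-site ITC fit: thermodynamics plus nuisance heat of dilution."""

    thermo: ThermoResult
    q_dilution: float  # µcal per injection
    residual_rms: float  # µcal
    c_value: float = 0.0
    c_value_warning: bool = False


def fraction_bound_1to1(labeled_total: float, titrant_total: float, kd: float) -> float:
    """Exact bound fraction of the labeled species for 1:1 binding.

    All concentrations molar.  Solves the standard quadratic for the complex
    concentration; the result is in [0, 1].
    """
    L, T = float(labeled_total), float(titrant_total)
    if L < 0 or T < 0 or kd <= 0:
        raise ValueError("concentrations must be >= 0 and kd > 0")
    if L == 0:
        return 0.0
    s = L + T + kd
    c = (s - math.sqrt(s * s - 4.0 * L * T)) / 2.0
    return min(max(c / L, 0.0), 1.0)


def fraction_bound_self(
    labeled_total: float,
    unlabeled_total: float,
    kd_dim: float,
    statistical_factor: bool = True,
) -> float:
    """Bound fraction of a trace-labeled protein titrated with itself.

    The unlabeled free monomer ``u`` is taken from the dimerization
    quadratic (the trace label does not perturb it); the label partitions as
    a 1:1 ligand with ``kd_het = kd_dim/2`` when the statistical factor is
    on (default) else ``kd_dim``.
    """
    U = float(unlabeled_total)
    if U < 0 or kd_dim <= 0:
        raise ValueError("concentrations must be >= 0 and kd_dim > 0")
    if U == 0 or math.isinf(kd_dim):
        return 0.0
    # u + 2u²/kd = U  =>  u = (−kd + sqrt(kd² + 8·kd·U))/4
    u = (-kd_dim + math.sqrt(kd_dim * kd_dim + 8.0 * kd_dim * U)) / 4.0
    kd_het = kd_dim / 2.0 if statistical_factor else kd_dim
    return u / (kd_het + u)


def _fb_1to1_vec(L: float, T: np.ndarray, kd: float) -> np.ndarray:
    """Vectorized 1:1 bound fraction (hot path of the MST fitter)."""
    s = L + T + kd
    c = (s - np.sqrt(s * s - 4.0 * L * T)) / 2.0
    return np.clip(c / L, 0.0, 1.0)


def _fb_self_vec(
    U: np.ndarray, kd_dim: float, statistical_factor: bool
) -> np.ndarray:
    """Vectorized trace-label self-association bound fraction."""
    u = (-kd_dim + np.sqrt(kd_dim * kd_dim + 8.0 * kd_dim * U)) / 4.0
    kd_het = kd_dim / 2.0 if statistical_factor else kd_dim
    return u / (kd_het + u)


def dilution_series(top: float, ratio: float = 0.5, n_points: int = 16) -> np.ndarray:
    """Geometric serial-dilution series ``top·ratio^k``, k = 0 … n−1."""
    if n_points < 2:
        raise ValueError("a dilution series needs at least 2 points")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    return top * ratio ** np.arange(n_points)


def _bound_complex(M: float, X: float, kd: float, n: float) -> float:
    """One-site complex concentration with stoichiometry n (per cell M)."""
    sites = n * M
    s = sites + X + kd
    disc = max(s * s - 4.0 * sites * X, 0.0)
    return (s - math.sqrt(disc)) / 2.0


def itc_heats(
    exp: ITCExperiment,
    kd: float,
    dH: float,
    n_stoich: float = 1.0,
    q_dil: float = 0.0,
) -> np.ndarray:
    """Model per-injection heats (µcal) for a one-site binding isotherm.

    ``kd`` molar, ``dH`` kJ/mol.  Cell and titrant totals are updated with
    the perfusion dilution factor (1 − v/V) at each injection; the heat of
    injection i is ΔH·V·(B_i − B_{i−1}·(1 − v_i/V)) + q_dil.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    V = exp.cell_volume * 1e-6  # l
    M = exp.cell_conc * 1e-6  # molar in cell
    Xs = exp.syringe_conc * 1e-6
    if np.sum(exp.injection_volumes) > 0.5 * exp.cell_volume:
        warnings.warn(
            "cumulative injected volume exceeds half the cell volume",
            RuntimeWarning,
        )
    X = 0.0
    b_prev = 0.0
    heats = np.empty(exp.injection_volumes.size)
    for i, v_ul in enumerate(exp.injection_volumes):
        d = 1.0 - (v_ul * 1e-6) / V
        M *= d
        X = X * d + Xs * (v_ul * 1e-6) / V
        b = _bound_complex(M, X, kd, n_stoich)
        dq_J = dH * 1000.0 * V * (b - b_prev * d)
        heats[i] = dq_J / J_PER_CAL * 1e6 + q_dil
        b_prev = b
    return heats


class MSTFitter(BaseEstimator):
    """Least-squares fit of an MST isotherm (kd, f_free, f_bound).

    ``model`` selects the isotherm: ``"self_association"`` (trace-labeled
    protein titrated with itself; kd is the dimerization constant) or
    ``"one_to_one"``.  The constant is optimized in log10 space with five
    log-spaced starts.  After :meth:`fit` the instance exposes ``kd_``,
    ``f_free_``, ``f_bound_``, ``residual_rms_`` and ``result_``.
    """

    def __init__(
        self,
        model: str = "self_association",
        statistical_factor: bool = True,
        n_starts: int = 5,
        log10_kd_bounds: tuple[float, float] = (-9.0, -2.0),
    ):
        self.model = model
        self.statistical_factor = statistical_factor
        self.n_starts = n_starts
        self.log10_kd_bounds = log10_kd_bounds

    def _bound_fraction(self, titrant_molar: np.ndarray, label_molar: float, kd: float):
        if self.model == "self_association":
            return _fb_self_vec(titrant_molar, kd, self.statistical_factor)
        if self.model == "one_to_one":
            return _fb_1to1_vec(label_molar, titrant_molar, kd)
        raise ValueError(f"unknown model {self.model!r}")

    def fit(self, X: MSTSeries, y=None):
        if not isinstance(X, MSTSeries):
            raise TypeError("X must be an MSTSeries")
        series = X
        t_molar = series.titrant_total * 1e-9
        l_molar = series.labeled_total * 1e-9
        f = series.fnorm
        lo, hi = self.log10_kd_bounds

        def amplitudes(kd: float):
            """Closed-form linear solve of (f_free, f_bound) given kd."""
            fb = self._bound_fraction(t_molar, l_molar, kd)
            A = np.column_stack([1.0 - fb, fb])
            coef, *_ = np.linalg.lstsq(A, f, rcond=None)
            return coef, fb

        def sse(log10_kd: float) -> float:
            (a_free, a_bound), fb = amplitudes(10.0**log10_kd)
            resid = f - (a_free * (1.0 - fb) + a_bound * fb)
            return float(resid @ resid)

        starts = np.linspace(lo + 0.5, hi - 0.5, self.n_starts)
        best_x, best_v = None, np.inf
        for x0 in starts:
            res = optimize.minimize_scalar(
                sse,
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-10},
            ) if self.n_starts == 1 else optimize.minimize(
                lambda th: sse(th[0]),
                np.array([x0]),
                method="Nelder-Mead",
                bounds=[(lo, hi)],
                options={"xatol": 1e-9, "fatol": 1e-14},
            )
            val = res.fun if np.isscalar(res.fun) else float(res.fun)
            x = res.x if np.isscalar(res.x) else float(np.atleast_1d(res.x)[0])
            if val < best_v:
                best_v, best_x = val, float(x)

        kd = 10.0**best_x
        (f_free, f_bound), fb = amplitudes(kd)
        resid = f - (f_free * (1.0 - fb) + f_bound * fb)
        rms = float(np.sqrt(np.mean(resid**2)))
        # realized signal span over the titration, not the extrapolated
        # plateau difference: a near-flat isotherm segment is unidentifiable
        # no matter how large the extrapolated amplitude
        span = abs(f_bound - f_free) * float(np.ptp(fb))
        if span < 3.0 * rms:
            raise UnidentifiableAmplitudeError(
                f"fitted signal span {span:.3g} below 3x residual rms {rms:.3g}"
            )
        self.kd_ = kd
        self.f_free_ = float(f_free)
        self.f_bound_ = float(f_bound)
        self.residual_rms_ = rms
        # unbiased noise level: 3 fitted parameters absorb variance
        dof = max(f.size - 3, 1)
        self.noise_sigma_ = rms * math.sqrt(f.size / dof)
        self.result_ = MSTFit(
            kd=kd,
            f_free=self.f_free_,
            f_bound=self.f_bound_,
            model_tag=self.model,
            residual_rms=rms,
        )
        self._series = series
        return self

    def predict(self, X: MSTSeries | None = None) -> np.ndarray:
        if not hasattr(self, "kd_"):
            raise RuntimeError("call fit first")
        series = X if X is not None else self._series
        fb = self._bound_fraction(
            series.titrant_total * 1e-9, series.labeled_total * 1e-9, self.kd_
        )
        return self.f_free_ * (1.0 - fb) + self.f_bound_ * fb

    def monte_carlo_ci(
        self, n_iter: int = 500, level: float = 0.95, seed: int | None = None
    ) -> MSTFit:
        """Parametric-bootstrap CI on kd, as in the SE fitter."""
        if n_iter == 0:
            return self.result_
        rng = np.random.default_rng(seed)
        model = self.predict()
        draws = []
        sub = MSTFitter(
            model=self.model,
            statistical_factor=self.statistical_factor,
            n_starts=1,
            log10_kd_bounds=self.log10_kd_bounds,
        )
        for _ in range(n_iter):
            sim = replace(
                self._series,
                fnorm=model + rng.normal(0.0, self.noise_sigma_, model.size),
            )
            try:
                sub.fit(sim)
                draws.append(math.log10(sub.kd_))
            except (UnidentifiableAmplitudeError, ValueError):
                continue
        if len(draws) < 0.8 * n_iter:
            raise RuntimeError("too many Monte Carlo refits failed; CI unreliable")
        alpha = (1.0 - level) / 2.0
        lo_q, hi_q = np.quantile(draws, [alpha, 1.0 - alpha])
        est = math.log10(self.kd_)
        ci = (10.0 ** min(lo_q, est), 10.0 ** max(hi_q, est))
        self.kd_ci_ = ci
        self.result_ = replace(self.result_, kd_ci=ci)
        return self.result_


class ITCFitter(BaseEstimator):
    """One-site ITC fit over (log10 Kd, ΔH, N, q_dil).

    Multistart least squares on the injection heats; the fitted constant is
    turned into a full thermodynamic record (ΔG = RT·ln Kd, TΔS = ΔH − ΔG)
    at the experiment temperature.  A Wiseman c-value (N·[cell]/Kd) outside
    [0.05, 5000] flags the result as unreliable rather than failing.
    """

    def __init__(
        self,
        n_starts: int = 5,
        log10_kd_bounds: tuple[float, float] = (-9.0, -2.0),
        discard_first: bool = False,
    ):
        self.n_starts = n_starts
        self.log10_kd_bounds = log10_kd_bounds
        self.discard_first = discard_first

    def fit(self, X: ITCExperiment, y=None):
        if not isinstance(X, ITCExperiment):
            raise TypeError("X must be an ITCExperiment")
        exp = X
        if exp.heats.size < 8:
            raise ValueError("need at least 8 injections to fit")
        mask = np.ones(exp.heats.size, dtype=bool)
        if self.discard_first:
            mask[0] = False
        lo, hi = self.log10_kd_bounds

        total_q = float(np.sum(exp.heats[mask]))
        cell_mol = exp.cell_conc * 1e-6 * exp.cell_volume * 1e-6
        # enthalpy-conservation guess: sum of heats ~ dH·N·(cell moles)
        dh_guess = (total_q * 1e-6 * J_PER_CAL) / cell_mol / 1000.0  # kJ/mol
        if dh_guess == 0.0:
            dh_guess = -1.0

        def residuals(theta):
            log_kd, dh, n, qd = theta
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                model = itc_heats(exp, 10.0**log_kd, dh, n, qd)
            return (exp.heats - model)[mask]

        starts = np.linspace(lo + 0.5, hi - 0.5, self.n_starts)
        best = None
        for x0 in starts:
            res = optimize.least_squares(
                residuals,
                x0=np.array([x0, dh_guess, 1.0, 0.0]),
                bounds=(
                    [lo, -1e4, 0.05, -1e3],
                    [hi, 1e4, 20.0, 1e3],
                ),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            if best is None or res.cost < best.cost:
                best = res
        log_kd, dh, n, qd = best.x
        kd = 10.0**log_kd
        rms = float(np.sqrt(np.mean(best.fun**2)))
        c_value = n * exp.cell_conc * 1e-6 / kd
        c_warn = not (0.05 <= c_value <= 5000.0)
        if c_warn:
            warnings.warn(
                f"c-value {c_value:.3g} outside [0.05, 5000]; Kd unreliable",
                RuntimeWarning,
            )
        thermo = ThermoResult.from_kd_dh(kd, dh, exp.temperature, n_stoich=n)
        self.kd_ = kd
        self.dH_ = float(dh)
        self.n_stoich_ = float(n)
        self.q_dilution_ = float(qd)
        self.thermo_ = thermo
        self.residual_rms_ = rms
        self.result_ = ITCFit(
            thermo=thermo,
            q_dilution=self.q_dilution_,
            residual_rms=rms,
            c_value=float(c_value),
            c_value_warning=c_warn,
        )
        self._experiment = exp
        return self

    def predict(self, X: ITCExperiment | None = None) -> np.ndarray:
        if not hasattr(self, "kd_"):
            raise RuntimeError("call fit first")
        exp = X if X is not None else self._experiment
        return itc_heats(exp, self.kd_, self.dH_, self.n_stoich_, self.q_dilution_)


def fit_mst(series: MSTSeries, model: str = "self_association", seed=None, **kwargs) -> MSTFit:
    """Functional wrapper over :class:`MSTFitter` (seed reserved for CIs)."""
    return MSTFitter(model=model, **kwargs).fit(series).result_


def fit_itc(exp: ITCExperiment, seed=None, **kwargs) -> ITCFit:
    """Functional wrapper over :class:`ITCFitter`."""
    return ITCFitter(**kwargs).fit(exp).result_
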