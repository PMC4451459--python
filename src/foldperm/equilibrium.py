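"""Two-state equilibrium denaturation analysis.

Fits the six-parameter Santoro-Bolen model (two-state unfolding with
linear folded and unfolded baselines) to signal-vs-denaturant data and
derives stability differences between variants.

The observed signal at denaturant concentration ``D`` is the population-
weighted average of the two baselines::

    Y(D) = [(a_N + b_N D) + (a_D + b_D D) K(D)] / [1 + K(D)]
    K(D) = exp(m (D - D50) / RT),   D50 = dG_H2O / m

where ``dG_H2O`` is the unfolding free energy in water and ``m`` its
linear denaturant dependence (the equilibrium m-value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .constants import RT_DEFAULT, T_DEFAULT, rt


class FitFailureError(RuntimeError):
    """A nonlinear fit failed to converge to a physically sensible optimum."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals


@dataclass(frozen=True)
class EquilibriumParams:
    """Ground-truth / fitted parameters of a two-state denaturation curve.

    dG_h2o     unfolding free energy in water, kcal/mol
    m_eq       equilibrium m-value, kcal mol^-1 M^-1 (must be > 0)
    alpha_N/beta_N  folded-baseline intercept and slope
    alpha_D/beta_D  unfolded-baseline intercept and slope
    """

    dG_h2o: float
    m_eq: float
    alpha_N: float = 1.0
    beta_N: float = 0.0
    alpha_D: float = 0.0
    beta_D: float = 0.0
    temperature_K: float = T_DEFAULT

    def __post_init__(self):
        if self.m_eq <= 0:
            raise ValueError(f"m_eq must be positive, got {self.m_eq}")
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be positive")
        if not np.isfinite(self.dG_h2o / self.m_eq):
            raise ValueError("midpoint dG_h2o/m_eq must be finite")

    @property
    def d50(self) -> float:
        """Denaturation midpoint [D]50 in M."""
        return self.dG_h2o / self.m_eq


@dataclass
class DenaturationCurve:
    """Equilibrium signal vs denaturant concentration for one variant."""

    variant_id: str
    urea: np.ndarray
    signal: np.ndarray
    signal_kind: str = "average emission wavelength (nm)"

    def __post_init__(self):
        self.urea = np.asarray(self.urea, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.urea.shape != self.signal.shape:
            raise ValueError("urea and signal must have the same length")
        if np.any(self.urea < 0):
            raise ValueError("urea concentrations must be non-negative")

    def __len__(self) -> int:
        return self.urea.size


@dataclass
class TwoStateEqFit:
    """Result of fitting the two-state model to one denaturation curve."""

    variant_id: str
    params: EquilibriumParams
    se: dict[str, float]
    residual_rms: float
    covariance: np.ndarray = field(repr=False, default=None)

    @property
    def d50(self) -> float:
        return self.params.d50

    @property
    def d50_se(self) -> float:
        """SE of the midpoint by first-order propagation of (dG, m)."""
        g, m = self.params.dG_h2o, self.params.m_eq
        if self.covariance is None:
            return float("nan")
        # gradient of g/m w.r.t. (g, m)
        grad = np.array([1.0 / m, -g / m**2])
        var = grad @ self.covariance[:2, :2] @ grad
        return float(np.sqrt(max(var, 0.0)))


@dataclass(frozen=True)
class DeltaDeltaG:
    """Stability change of a variant relative to a reference (wild type).

    Positive values mean the variant is destabilised.
    """

    value: float
    se: float
    wt_id: str
    mut_id: str

    def __post_init__(self):
        if self.se < 0:
            raise ValueError("se must be non-negative")


def average_emission_wavelength(wavelengths, intensities) -> float:
    """Intensity-weighted mean emission wavelength, <lambda> = sum(l F)/sum(F).

    Collapses a fluorescence emission spectrum to a single number that
    tracks the folded/unfolded red shift of tryptophan emission.
    """
    lam = np.asarray(wavelengths, dtype=float)
    f = np.asarray(intensities, dtype=float)
    if lam.size < 2:
        raise ValueError("need at least 2 wavelengths")
    if lam.shape != f.shape:
        raise ValueError("wavelength and intensity grids must match")
    total = f.sum()
    if total <= 0:
        raise ValueError("total intensity must be positive")
    return float((lam * f).sum() / total)


def signal_model(params: EquilibriumParams, urea) -> np.ndarray:
    """Two-state Santoro-Bolen signal at the given urea concentration(s)."""
    d = np.asarray(urea, dtype=float)
    rt_val = rt(params.temperature_K)
    # exponent written around D50 for numerical symmetry
    x = params.m_eq * (d - params.d50) / rt_val
    # logistic unfolded fraction, stable for large |x|
    fu = 0.5 * (1.0 + np.tanh(x / 2.0))
    folded = params.alpha_N + params.beta_N * d
    unfolded = params.alpha_D + params.beta_D * d
    out = folded * (1.0 - fu) + unfolded * fu
    return out if out.ndim else float(out)


def _initial_guess(urea: np.ndarray, signal: np.ndarray) -> np.ndarray:
    """Data-driven starting point: baselines from the outer 15% of the
    urea range, D50 from the half-signal crossing, m from a logistic slope."""
    lo, hi = urea.min(), urea.max()
    span = hi - lo
    left = urea <= lo + 0.15 * span
    right = urea >= hi - 0.15 * span
    if left.sum() >= 2:
        b_n, a_n = np.polyfit(urea[left], signal[left], 1)
    else:
        a_n, b_n = signal[left].mean(), 0.0
    if right.sum() >= 2:
        b_d, a_d = np.polyfit(urea[right], signal[right], 1)
    else:
        a_d, b_d = signal[right].mean(), 0.0
    mid_signal = 0.5 * (a_n + a_d) + 0.5 * (b_n + b_d) * urea.mean()
    # half-crossing of the baseline-detrended signal
    crossing = np.argmin(np.abs(signal - mid_signal))
    d50 = float(np.clip(urea[crossing], lo + 1e-3, hi - 1e-3))
    # logistic pre-fit for the steepness: use the central finite difference
    # of unfolded fraction around the midpoint as d f_u/dD = m/(4 RT)
    amp = (a_d + b_d * d50) - (a_n + b_n * d50)
    m0 = 1.5
    if abs(amp) > 0:
        grad = np.gradient(signal, urea)
        slope_mid = grad[crossing] - 0.5 * (b_n + b_d)
        m_est = abs(4.0 * RT_DEFAULT * slope_mid / amp)
        if np.isfinite(m_est) and 0.05 < m_est < 20:
            m0 = m_est
    return np.array([m0 * d50, m0, a_n, b_n, a_d, b_d])


_PARAM_NAMES = ("dG_h2o", "m_eq", "alpha_N", "beta_N", "alpha_D", "beta_D")


def fit_equilibrium(
    curve: DenaturationCurve,
    init: EquilibriumParams | None = None,
    temperature_K: float = T_DEFAULT,
) -> TwoStateEqFit:
    """Nonlinear least-squares fit of the six-parameter two-state model.

    Parameters are initialised from the data (baselines from the outer
    15% of the urea range, midpoint from the half-signal crossing) unless
    an explicit starting point is supplied.  A fit that lands on a
    negative m-value is retried with the signal sign flipped; if the
    m-value is still negative the fit is reported as failed.
    """
    if len(curve) < 8:
        raise ValueError(
            f"need >= 8 points to fit 6 parameters, got {len(curve)}"
        )
    urea, signal = curve.urea, curve.signal

    rt_val = rt(temperature_K)

    def model(d, g, m, a_n, b_n, a_d, b_d):
        # raw form of signal_model that tolerates non-physical m during
        # optimisation; exponent around (mD - g) for stability
        x = (m * d - g) / rt_val
        fu = 0.5 * (1.0 + np.tanh(x / 2.0))
        return (a_n + b_n * d) * (1.0 - fu) + (a_d + b_d * d) * fu

    if init is not None:
        p0 = np.array([init.dG_h2o, init.m_eq, init.alpha_N, init.beta_N,
                       init.alpha_D, init.beta_D])
    else:
        p0 = _initial_guess(urea, signal)

    def attempt(y, p0_):
        popt, pcov = curve_fit(model, urea, y, p0=p0_, maxfev=20000)
        return popt, pcov

    try:
        popt, pcov = attempt(signal, p0)
    except RuntimeError as exc:
        raise FitFailureError(f"equilibrium fit did not converge: {exc}")

    if popt[1] <= 0:
        # sign-flipped retry: refit -signal, then un-flip the baselines
        p0f = _initial_guess(urea, -signal)
        try:
            popt_f, pcov_f = attempt(-signal, p0f)
        except RuntimeError as exc:
            raise FitFailureError(f"sign-flipped refit failed: {exc}")
        if popt_f[1] <= 0:
            resid = signal - model(urea, *popt)
            raise FitFailureError(
                "fitted m-value negative in both signal orientations",
                residuals=resid,
            )
        popt = np.array([popt_f[0], popt_f[1], -popt_f[2], -popt_f[3],
                         -popt_f[4], -popt_f[5]])
        pcov = pcov_f

    params = EquilibriumParams(*popt, temperature_K=temperature_K)
    resid = signal - signal_model(params, urea)
    se = dict(zip(_PARAM_NAMES, np.sqrt(np.clip(np.diag(pcov), 0, None))))
    return TwoStateEqFit(
        variant_id=curve.variant_id,
        params=params,
        se=se,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        covariance=pcov,
    )


def delta_delta_g(
    wt: TwoStateEqFit,
    mut: TwoStateEqFit,
    convention: str = "direct",
) -> DeltaDeltaG:
    """Stability loss of a variant: ddG = dG_H2O(wt) - dG_H2O(mut).

    ``convention="mean_m"`` uses the alternative <m>*(D50_wt - D50_mut)
    form, which is less sensitive to m-value fitting noise.
    The SE combines both fit errors in quadrature.
    """
    if convention == "direct":
        value = wt.params.dG_h2o - mut.params.dG_h2o
        se = float(np.hypot(wt.se["dG_h2o"], mut.se["dG_h2o"]))
    elif convention == "mean_m":
        m_mean = 0.5 * (wt.params.m_eq + mut.params.m_eq)
        value = m_mean * (wt.d50 - mut.d50)
        se = float(m_mean * np.hypot(wt.d50_se, mut.d50_se))
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return DeltaDeltaG(value=value, se=se, wt_id=wt.variant_id,
                       mut_id=mut.variant_id)
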