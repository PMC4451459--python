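"""Chevron analysis: two-state folding kinetics vs denaturant.

For a two-state folder the observed relaxation rate constant is the sum
of the folding and unfolding rate constants, each exponential in
denaturant concentration::

    k_obs(D) = kf_H2O exp(-m_kf D) + ku_H2O exp(+m_ku D)

so ln k_obs vs D is the familiar V-shaped chevron with linear limbs.
Fitting is performed in ln k space (stopped-flow errors are roughly
fractional) with the rate constants parameterised logarithmically to
enforce positivity.

Phi-values compare the kinetic effect of a mutation (or permutation,
"treating it as a mutant") with its equilibrium destabilisation:
Phi = ddG_kin / ddG_eq with ddG_kin = RT ln(kf_ref/kf_mut) evaluated at
a reference denaturant concentration on the refolding limb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import RT_DEFAULT
from .equilibrium import DeltaDeltaG, FitFailureError, TwoStateEqFit

#: |ddG_eq| below which a phi-value is flagged unreliable, kcal/mol
PHI_RELIABILITY_FLOOR = 0.6

#: default urea concentration at which refolding rates are compared, M
PHI_REFERENCE_UREA = 2.0


@dataclass(frozen=True)
class ChevronParams:
    """Two-state chevron parameters.

    kf_h2o, ku_h2o  folding/unfolding rate constants in water, s^-1
    m_kf, m_ku      denaturant dependences of ln k (positive magnitudes), M^-1
    """

    kf_h2o: float
    m_kf: float
    ku_h2o: float
    m_ku: float

    def __post_init__(self):
        if self.kf_h2o <= 0 or self.ku_h2o <= 0:
            raise ValueError("rate constants must be positive")
        if self.m_kf < 0 or self.m_ku < 0:
            raise ValueError("kinetic m-values must be non-negative")


@dataclass
class ChevronDataset:
    """Observed rate constants vs urea concentration for one variant."""

    variant_id: str
    urea: np.ndarray
    k_obs: np.ndarray

    def __post_init__(self):
        self.urea = np.asarray(self.urea, dtype=float)
        self.k_obs = np.asarray(self.k_obs, dtype=float)
        if self.urea.shape != self.k_obs.shape:
            raise ValueError("urea and k_obs must have the same length")
        if np.any(self.k_obs <= 0):
            raise ValueError("k_obs must be strictly positive")

    def __len__(self) -> int:
        return self.urea.size


@dataclass
class ChevronFit:
    """Fitted chevron parameters with standard errors (ln k residuals)."""

    variant_id: str
    params: ChevronParams
    se: dict[str, float]
    residual_rms: float
    covariance: np.ndarray = field(repr=False, default=None)  # (lnkf,mkf,lnku,mku)


@dataclass
class PhiValue:
    """Phi-value of a variant relative to a reference variant."""

    phi: float
    se: float
    reference_urea: float
    ddg_kinetic: float
    ddg_equilibrium: float
    wt_id: str = ""
    mut_id: str = ""
    reliable: bool = True


def chevron_model(params: ChevronParams, urea) -> np.ndarray:
    """ln k_obs(D) for the two-state chevron, computed in log space."""
    d = np.asarray(urea, dtype=float)
    lnf = np.log(params.kf_h2o) - params.m_kf * d
    lnu = np.log(params.ku_h2o) + params.m_ku * d
    out = np.logaddexp(lnf, lnu)
    return out if out.ndim else float(out)


def _ln_chevron(theta, d):
    lnkf, mkf, lnku, mku = theta
    return np.logaddexp(lnkf - mkf * d, lnku + mku * d)


def _initial_guess(d: np.ndarray, lnk: np.ndarray) -> np.ndarray:
    """Slopes/intercepts of straight lines through the outer thirds of the
    urea range, which approximate the two limbs."""
    order = np.argsort(d)
    d, lnk = d[order], lnk[order]
    n = d.size
    third = max(n // 3, 2)
    sf, if_ = np.polyfit(d[:third], lnk[:third], 1)
    su, iu = np.polyfit(d[-third:], lnk[-third:], 1)
    return np.array([if_, max(-sf, 0.05), iu, max(su, 0.05)])


def fit_chevron(
    data: ChevronDataset, init: ChevronParams | None = None
) -> ChevronFit:
    """Least-squares fit of the chevron in ln k_obs space.

    Raises :class:`FitFailureError` when the data cover only one limb
    (the diagnostic names the missing limb) or the optimiser fails.
    """
    if len(data) < 6:
        raise ValueError(f"need >= 6 points for a chevron fit, got {len(data)}")
    d, lnk = data.urea, np.log(data.k_obs)

    if init is not None:
        theta0 = np.array([np.log(init.kf_h2o), init.m_kf,
                           np.log(init.ku_h2o), init.m_ku])
    else:
        theta0 = _initial_guess(d, lnk)

    res = least_squares(
        lambda t: _ln_chevron(t, d) - lnk,
        theta0,
        bounds=([-np.inf, 0, -np.inf, 0], np.inf),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not res.success:
        raise FitFailureError(f"chevron fit did not converge: {res.message}",
                              residuals=res.fun)

    lnkf, mkf, lnku, mku = res.x
    # one-limb diagnostics: a limb is covered only if its rate contributes
    # appreciably somewhere in the data range
    frac_f = np.exp(lnkf - mkf * d - _ln_chevron(res.x, d))
    frac_u = np.exp(lnku + mku * d - _ln_chevron(res.x, d))
    if frac_u.max() < 0.05:
        raise FitFailureError(
            "unfolding limb not covered by the data "
            "(k_u never contributes > 5% of k_obs)", residuals=res.fun)
    if frac_f.max() < 0.05:
        raise FitFailureError(
            "folding limb not covered by the data "
            "(k_f never contributes > 5% of k_obs)", residuals=res.fun)

    # covariance of (lnkf, mkf, lnku, mku) from the jacobian
    m_pts, n_par = res.jac.shape
    dof = max(m_pts - n_par, 1)
    s2 = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(jtj)
    se_diag = np.sqrt(np.clip(np.diag(cov), 0, None))

    params = ChevronParams(np.exp(lnkf), mkf, np.exp(lnku), mku)
    se = {
        "kf_h2o": params.kf_h2o * se_diag[0],  # delta method from ln k
        "m_kf": se_diag[1],
        "ku_h2o": params.ku_h2o * se_diag[2],
        "m_ku": se_diag[3],
    }
    resid = _ln_chevron(res.x, d) - lnk
    return ChevronFit(
        variant_id=data.variant_id,
        params=params,
        se=se,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        covariance=cov,
    )


def rate_at(fit: ChevronFit, urea: float, limb: str) -> float:
    """Extrapolated single-limb rate constant at the given urea, s^-1."""
    p = fit.params
    if limb == "folding":
        return float(p.kf_h2o * np.exp(-p.m_kf * urea))
    if limb == "unfolding":
        return float(p.ku_h2o * np.exp(p.m_ku * urea))
    raise ValueError(f"limb must be 'folding' or 'unfolding', got {limb!r}")


def _ln_rate_var(fit: ChevronFit, urea: float, limb: str) -> float:
    """Variance of ln k(limb) at the given urea from the fit covariance."""
    if fit.covariance is None:
        return float("nan")
    if limb == "folding":
        grad = np.array([1.0, -urea, 0.0, 0.0])
    else:
        grad = np.array([0.0, 0.0, 1.0, urea])
    return float(grad @ fit.covariance @ grad)


def phi_value(
    wt: ChevronFit,
    mut: ChevronFit,
    ddg_eq: DeltaDeltaG,
    reference_urea: float = PHI_REFERENCE_UREA,
    reliability_floor: float = PHI_RELIABILITY_FLOOR,
    use_unfolding: bool = False,
) -> PhiValue:
    """Phi-value from refolding-rate ratios at the reference urea.

    ddG_kin = RT ln(kf_wt(Dref)/kf_mut(Dref)); Phi = ddG_kin / ddG_eq.
    With ``use_unfolding=True`` the unfolding-limb form
    Phi = 1 - RT ln(ku_mut/ku_wt)/ddG_eq is returned as a cross-check.
    A |ddG_eq| below ``reliability_floor`` flags the result unreliable
    (warning, not an exception).
    """
    reliable = bool(abs(ddg_eq.value) >= reliability_floor)
    if not reliable:
        warnings.warn(
            f"|ddG_eq| = {abs(ddg_eq.value):.2f} kcal/mol is below the "
            f"{reliability_floor} kcal/mol reliability floor; "
            "phi-value flagged unreliable", stacklevel=2)
    if ddg_eq.value == 0:
        raise ZeroDivisionError("ddG_eq is exactly zero; phi undefined")

    if use_unfolding:
        ku_wt = rate_at(wt, reference_urea, "unfolding")
        ku_mut = rate_at(mut, reference_urea, "unfolding")
        ddg_kin_u = RT_DEFAULT * np.log(ku_mut / ku_wt)
        phi = 1.0 - ddg_kin_u / ddg_eq.value
        ddg_kin = ddg_eq.value - ddg_kin_u
        var_ln = (_ln_rate_var(wt, reference_urea, "unfolding")
                  + _ln_rate_var(mut, reference_urea, "unfolding"))
        se_kin = RT_DEFAULT * np.sqrt(max(var_ln, 0.0))
    else:
        kf_wt = rate_at(wt, reference_urea, "folding")
        kf_mut = rate_at(mut, reference_urea, "folding")
        ddg_kin = RT_DEFAULT * np.log(kf_wt / kf_mut)
        phi = ddg_kin / ddg_eq.value
        var_ln = (_ln_rate_var(wt, reference_urea, "folding")
                  + _ln_rate_var(mut, reference_urea, "folding"))
        se_kin = RT_DEFAULT * np.sqrt(max(var_ln, 0.0))

    # first-order propagation of the two ddG errors through the ratio
    g = ddg_eq.value
    se = np.sqrt((se_kin / g) ** 2 + (ddg_kin * ddg_eq.se / g**2) ** 2)
    return PhiValue(
        phi=float(phi), se=float(se), reference_urea=reference_urea,
        ddg_kinetic=float(ddg_kin), ddg_equilibrium=float(g),
        wt_id=wt.variant_id, mut_id=mut.variant_id, reliable=reliable,
    )


def tanford_beta(fit: ChevronFit) -> float:
    """Tanford beta_T = m_kf / (m_kf + m_ku), in [0, 1].

    Measures the relative compaction (solvent exposure) of the
    transition state between unfolded (0) and native (1).
    """
    p = fit.params
    total = p.m_kf + p.m_ku
    if total == 0:
        raise ValueError("m_kf + m_ku is zero; beta_T undefined")
    return float(p.m_kf / total)


@dataclass
class MValueConsistency:
    """Comparison of the kinetic m-value sum with the equilibrium m-value."""

    variant_id: str
    m_kinetic: float   # RT (m_kf + m_ku), kcal mol^-1 M^-1
    m_equilibrium: float
    relative_discrepancy: float
    flagged: bool


def kinetic_mvalue_check(
    fit: ChevronFit, eq: TwoStateEqFit, flag_threshold: float = 0.20
) -> MValueConsistency:
    """Two-state self-consistency: RT (m_kf + m_ku) should match m_eq.

    Deviations beyond ``flag_threshold`` (relative) are flagged; for a
    genuine two-state system the kinetic and equilibrium denaturant
    dependences must agree.
    """
    m_kin = RT_DEFAULT * (fit.params.m_kf + fit.params.m_ku)
    m_eq = eq.params.m_eq
    rel = abs(m_kin - m_eq) / m_eq
    return MValueConsistency(
        variant_id=fit.variant_id,
        m_kinetic=float(m_kin),
        m_equilibrium=float(m_eq),
        relative_discrepancy=float(rel),
        flagged=bool(rel > flag_threshold),
    )
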