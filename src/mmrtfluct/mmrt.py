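"""Macromolecular rate theory (MMRT) fitting of enzyme temperature–rate profiles.

MMRT extends transition state theory by letting the activation enthalpy and
entropy vary with temperature through a constant activation heat capacity
change ΔCp‡::

    ln k = ln(kB·T/h) - [ΔH‡(T0) + ΔCp‡·(T - T0)] / (R·T)
                      + [ΔS‡(T0) + ΔCp‡·ln(T/T0)] / R

A negative ΔCp‡ produces the curvature seen in Eyring plots of many enzymes
and an intrinsic temperature optimum (Topt) in the absence of denaturation.
The reference temperature T0 follows the convention T0 = Topt − 4 K, applied
self-consistently: the fit is repeated, resetting T0 from the fitted optimum,
until T0 is stationary.

The fit itself is exposed both as a scikit-learn style estimator
(:class:`MMRTRegressor`) and as the thin functional wrapper :func:`fit_mmrt`
operating on :class:`RateProfile`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .constants import KB, H_PLANCK, R_KJ

__all__ = [
    "MMRTParams",
    "RateProfile",
    "FitResult",
    "mmrt_lnk",
    "topt_closed_form",
    "shift_reference",
    "MMRTRegressor",
    "fit_mmrt",
]


@dataclass(frozen=True)
class MMRTParams:
    """Activation parameters of the MMRT rate law.

    Parameters
    ----------
    dH_T0 : float
        Activation enthalpy at the reference temperature, kJ mol⁻¹.
    dS_T0 : float
        Activation entropy at the reference temperature, kJ mol⁻¹ K⁻¹.
    dCp : float
        Activation heat capacity change ΔCp‡, kJ mol⁻¹ K⁻¹ (assumed
        temperature-independent over the fitted range).
    T0 : float
        Reference temperature, K.
    kappa : float
        Transmission coefficient; fixed at 1.
    """

    dH_T0: float
    dS_T0: float
    dCp: float
    T0: float
    kappa: float = 1.0

    def __post_init__(self) -> None:
        if self.T0 <= 0:
            raise ValueError(f"reference temperature must be positive, got {self.T0}")
        if self.kappa != 1.0:
            raise ValueError("the transmission coefficient is fixed at 1")


@dataclass
class RateProfile:
    """Temperature–rate measurements for one enzyme.

    Rates may be supplied on the linear scale (s⁻¹) or already as natural
    logs; the ``log_scale`` flag is explicit and never auto-detected.
    """

    temperatures: np.ndarray
    rates: np.ndarray
    log_scale: bool = False
    replicate_sd: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.temperatures.shape != self.rates.shape:
            raise ValueError("temperatures and rates must have equal length")
        if np.any(self.temperatures <= 0):
            raise ValueError("temperatures must be strictly positive")
        if np.unique(self.temperatures).size < 5:
            raise ValueError("at least 5 distinct temperatures are required")
        if not self.log_scale and np.any(self.rates <= 0):
            raise ValueError("linear-scale rates must be strictly positive")
        if self.replicate_sd is not None:
            self.replicate_sd = np.asarray(self.replicate_sd, dtype=float)
            if self.replicate_sd.shape != self.temperatures.shape:
                raise ValueError("replicate_sd must align with temperatures")

    @property
    def ln_rates(self) -> np.ndarray:
        return self.rates if self.log_scale else np.log(self.rates)


@dataclass
class FitResult:
    """Converged MMRT fit: parameters, uncertainties and derived quantities."""

    params: MMRTParams
    param_sd: dict[str, float]
    covariance: np.ndarray
    residual_sd: float
    topt: Optional[float]
    n_iter_T0: int
    n_points: int = 0

    def to_dict(self) -> dict:
        return {
            "params": dataclasses.asdict(self.params),
            "param_sd": dict(self.param_sd),
            "covariance": np.asarray(self.covariance).tolist(),
            "residual_sd": float(self.residual_sd),
            "topt": None if self.topt is None else float(self.topt),
            "n_iter_T0": int(self.n_iter_T0),
            "n_points": int(self.n_points),
        }


def mmrt_lnk(params: MMRTParams, T) -> np.ndarray | float:
    """Evaluate ln k(T) under MMRT.

    Raises
    ------
    ValueError
        If any temperature is non-positive.
    """
    T_arr = np.asarray(T, dtype=float)
    if np.any(T_arr <= 0):
        raise ValueError("temperature must be strictly positive")
    lnk = (
        np.log(KB * T_arr / H_PLANCK)
        - (params.dH_T0 + params.dCp * (T_arr - params.T0)) / (R_KJ * T_arr)
        + (params.dS_T0 + params.dCp * np.log(T_arr / params.T0)) / R_KJ
    )
    return float(lnk) if np.isscalar(T) else lnk


def topt_closed_form(params: MMRTParams) -> Optional[float]:
    """Closed-form temperature optimum of the MMRT curve.

    Setting d(ln k)/dT = 1/T + [ΔH‡ + ΔCp‡(T − T0)]/(R·T²) to zero gives

        Topt = (ΔCp‡·T0 − ΔH‡_T0) / (ΔCp‡ + R).

    A finite maximum exists only when ΔCp‡ < −R (otherwise ln k is monotonic
    increasing); returns ``None`` in that case or if the stationary point is
    non-positive.
    """
    if params.dCp >= -R_KJ:
        return None
    topt = (params.dCp * params.T0 - params.dH_T0) / (params.dCp + R_KJ)
    return topt if topt > 0 else None


def shift_reference(params: MMRTParams, T0_new: float) -> MMRTParams:
    """Re-express MMRT parameters at a different reference temperature.

    ΔCp‡ is reference-independent; ΔH‡ and ΔS‡ transform as
    ΔH‡(T0') = ΔH‡(T0) + ΔCp‡(T0' − T0) and
    ΔS‡(T0') = ΔS‡(T0) + ΔCp‡·ln(T0'/T0).
    """
    return MMRTParams(
        dH_T0=params.dH_T0 + params.dCp * (T0_new - params.T0),
        dS_T0=params.dS_T0 + params.dCp * np.log(T0_new / params.T0),
        dCp=params.dCp,
        T0=T0_new,
    )


class InsufficientDataError(ValueError):
    """Raised when too few points remain to fit the three MMRT parameters."""


class ConvergenceError(RuntimeError):
    """Raised when the T0 self-consistency loop fails to converge.

    Carries the last iterate on the ``last_result`` attribute.
    """

    def __init__(self, message: str, last_result: Optional[FitResult] = None):
        super().__init__(message)
        self.last_result = last_result


def _initial_guess(T: np.ndarray, lnk: np.ndarray) -> tuple[MMRTParams, float]:
    """Seed-free derivative-based initial guesses from a quadratic smooth.

    A parabola a + b·T + c·T² fit to ln k gives ΔCp from the curvature
    (dominant term of d²lnk/dT² is ΔCp/(R·T²)), ΔH from the local slope at
    T0 and ΔS from intercept matching; the initial T0 is set 4 K below the
    parabola's vertex (or 4 K below the hottest point if no vertex exists).
    """
    c, b, a = np.polyfit(T, lnk, 2)
    Tbar = float(np.mean(T))
    if c < 0:
        t_vertex = -b / (2 * c)
        # keep the initial reference near the data even for flat curvature
        t_vertex = float(np.clip(t_vertex, T.min() - 50.0, T.max() + 50.0))
    else:
        t_vertex = float(T.max())
    T0 = t_vertex - 4.0
    dCp0 = 2.0 * c * R_KJ * Tbar**2
    slope_T0 = b + 2 * c * T0
    dH0 = (slope_T0 - 1.0 / T0) * R_KJ * T0**2
    lnk_T0 = a + b * T0 + c * T0**2
    dS0 = R_KJ * (lnk_T0 - np.log(KB * T0 / H_PLANCK)) + dH0 / T0
    return MMRTParams(dH_T0=dH0, dS_T0=dS0, dCp=dCp0, T0=T0), T0


class MMRTRegressor(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares MMRT fit of ln(rate) against temperature.

    The three free parameters are ΔH‡_T0, ΔS‡_T0 and ΔCp‡ (κ fixed at 1).
    Unless ``T0`` is supplied, the reference temperature follows the
    T0 = Topt − 4 K convention, enforced by refitting until T0 moves by less
    than ``tol_T0``.

    Parameters
    ----------
    T0 : float, optional
        Fixed reference temperature in K. Default ``None`` activates the
        self-consistent Topt − 4 K convention.
    tol_T0 : float
        Convergence threshold on successive T0 values, K.
    max_refits : int
        Maximum number of T0 refit iterations.
    init : MMRTParams, optional
        Explicit initial parameters; default derives them from a quadratic
        smooth of the data.

    Attributes
    ----------
    dH_, dS_, dCp_ : float
        Fitted activation parameters (kJ mol⁻¹, kJ mol⁻¹ K⁻¹, kJ mol⁻¹ K⁻¹).
    T0_ : float
        Converged reference temperature, K.
    params_ : MMRTParams
    covariance_ : (3, 3) ndarray
        Covariance of (dH, dS, dCp) from the converged fit.
    param_sd_ : dict
        Standard errors keyed ``dH_T0``, ``dS_T0``, ``dCp``.
    residual_sd_ : float
        Root-mean-square residual in ln-rate units (ddof = 3).
    topt_ : float or None
        Closed-form temperature optimum of the fitted curve.
    n_iter_T0_ : int
        Number of reference-temperature refits performed.

    Examples
    --------
    >>> import numpy as np
    >>> from mmrtfluct.mmrt import MMRTRegressor, MMRTParams, mmrt_lnk
    >>> truth = MMRTParams(dH_T0=50.0, dS_T0=-0.05, dCp=-11.6, T0=316.0)
    >>> T = np.arange(280.0, 331.0, 2.0)
    >>> reg = MMRTRegressor().fit(T, mmrt_lnk(truth, T))
    >>> round(reg.dCp_, 6)
    -11.6
    """

    def __init__(
        self,
        T0: Optional[float] = None,
        tol_T0: float = 0.01,
        max_refits: int = 20,
        init: Optional[MMRTParams] = None,
    ):
        self.T0 = T0
        self.tol_T0 = tol_T0
        self.max_refits = max_refits
        self.init = init

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _model(T0):
        def f(T, dH, dS, dCp):
            return mmrt_lnk(MMRTParams(dH_T0=dH, dS_T0=dS, dCp=dCp, T0=T0), T)

        return f

    def _single_fit(self, T, lnk, sigma, T0, p0):
        popt, pcov = curve_fit(
            self._model(T0),
            T,
            lnk,
            p0=p0,
            sigma=sigma,
            absolute_sigma=False,
            maxfev=20000,
        )
        return popt, pcov

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y, sample_weight=None):
        """Fit ln(rate) = MMRT(T).

        Parameters
        ----------
        X : array-like
            Temperatures in K, shape (n,) or (n, 1).
        y : array-like
            Natural log of the rate constant at each temperature.
        sample_weight : array-like, optional
            Per-point standard deviations of ln(rate); used as
            inverse-variance weights (``sigma`` of the least squares).
        """
        T = np.asarray(X, dtype=float)
        if T.ndim == 2:
            if T.shape[1] != 1:
                raise ValueError("X must be temperatures of shape (n,) or (n, 1)")
            T = T[:, 0]
        lnk = np.asarray(y, dtype=float)
        if T.shape != lnk.shape:
            raise ValueError("X and y must have equal length")
        if np.any(T <= 0):
            raise ValueError("temperatures must be strictly positive")
        if T.size < 4:
            raise InsufficientDataError(
                f"need at least 4 points to fit 3 parameters, got {T.size}"
            )
        sigma = None
        if sample_weight is not None:
            sigma = np.asarray(sample_weight, dtype=float)
            if np.any(sigma <= 0):
                # points with no replicate spread carry unit weight
                sigma = np.where(sigma > 0, sigma, np.nanmin(sigma[sigma > 0]))

        if self.init is not None:
            guess = self.init
            T0 = self.T0 if self.T0 is not None else guess.T0
        else:
            guess, T0_auto = _initial_guess(T, lnk)
            T0 = self.T0 if self.T0 is not None else T0_auto
            guess = shift_reference(guess, T0)

        p0 = [guess.dH_T0, guess.dS_T0, guess.dCp]
        n_iter = 0
        last = None
        while True:
            popt, pcov = self._single_fit(T, lnk, sigma, T0, p0)
            n_iter += 1
            params = MMRTParams(dH_T0=popt[0], dS_T0=popt[1], dCp=popt[2], T0=T0)
            last = (params, pcov)
            if self.T0 is not None:
                break
            topt = topt_closed_form(params)
            if topt is None:
                break  # monotonic curve: no optimum, T0 convention vacuous
            T0_new = topt - 4.0
            if abs(T0_new - T0) < self.tol_T0:
                break
            if n_iter >= self.max_refits:
                self._store(T, lnk, params, pcov, n_iter)
                raise ConvergenceError(
                    f"T0 self-consistency loop did not converge in "
                    f"{self.max_refits} refits (last T0={T0:.3f} K)",
                    last_result=self._as_result(),
                )
            p0 = list(
                dataclasses.astuple(shift_reference(params, T0_new))[:3]
            )
            T0 = T0_new

        params, pcov = last
        self._store(T, lnk, params, pcov, n_iter)
        return self

    def _store(self, T, lnk, params: MMRTParams, pcov, n_iter: int) -> None:
        resid = lnk - mmrt_lnk(params, T)
        dof = max(T.size - 3, 1)
        self.params_ = params
        self.dH_ = params.dH_T0
        self.dS_ = params.dS_T0
        self.dCp_ = params.dCp
        self.T0_ = params.T0
        self.covariance_ = np.asarray(pcov)
        sd = np.sqrt(np.diag(self.covariance_))
        self.param_sd_ = {"dH_T0": sd[0], "dS_T0": sd[1], "dCp": sd[2]}
        self.residual_sd_ = float(np.sqrt(np.sum(resid**2) / dof))
        self.topt_ = topt_closed_form(params)
        self.n_iter_T0_ = n_iter
        self.n_features_in_ = 1
        self.n_points_ = int(T.size)

    def predict(self, X):
        """Predicted ln(rate) at temperatures ``X`` (shape (n,) or (n, 1))."""
        check_is_fitted(self, "params_")
        T = np.asarray(X, dtype=float)
        if T.ndim == 2:
            T = T[:, 0]
        return mmrt_lnk(self.params_, T)

    def _as_result(self) -> FitResult:
        return FitResult(
            params=self.params_,
            param_sd=self.param_sd_,
            covariance=self.covariance_,
            residual_sd=self.residual_sd_,
            topt=self.topt_,
            n_iter_T0=self.n_iter_T0_,
            n_points=self.n_points_,
        )


def fit_mmrt(profile: RateProfile, init: Optional[MMRTParams] = None) -> FitResult:
    """Fit MMRT to a :class:`RateProfile` (thin wrapper over MMRTRegressor).

    Weighting follows the profile: if ``replicate_sd`` is present the fit is
    inverse-variance weighted, otherwise unweighted.
    """
    reg = MMRTRegressor(init=init)
    reg.fit(
        profile.temperatures,
        profile.ln_rates,
        sample_weight=profile.replicate_sd,
    )
    return reg._as_result()
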