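"""Nonlinear least-squares fitting of the kinetic models.

Each model is exposed as a scikit-learn style estimator (``fit`` /
``predict``, ``get_params`` / ``set_params``, fitted attributes with a
trailing underscore) so the fitters compose with sklearn tooling.  The
engine is unweighted least squares by default (matching the convention
under which fitted standard errors are reported as "fitting errors"),
with per-model initial-guess heuristics and a deterministic restart
ladder on non-convergence.

Also here: nested (extra-sum-of-squares F-test) and non-nested (AICc)
model comparison, ratio error propagation in quadrature for
heavy-enzyme kinetic isotope effects (HE-KIE), and the Welch t-test used
to flag significant kcat differences.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import models

__all__ = [
    "FitResult",
    "ModelComparison",
    "ValueWithError",
    "TTestResult",
    "KineticCurveFitter",
    "MeltCurveModel",
    "MichaelisMentenModel",
    "TitrationModel",
    "DoseResponseModel",
    "TwoStepBurstModel",
    "ViscosityLineModel",
    "EyringModel",
    "MMRTModel",
    "SingleExponentialModel",
    "MODEL_REGISTRY",
    "make_estimator",
    "fit",
    "initial_guess",
    "compare_models",
    "propagate_ratio",
    "t_test_kcat",
]

# Deterministic multiplicative perturbation ladder applied to the initial
# guess when an attempt fails to converge (no random seeds in the fit path).
_RESTART_SCALES = (1.0, 0.5, 2.0, 0.25, 4.0)


@dataclasses.dataclass(frozen=True)
class ValueWithError:
    """A point estimate with its standard error (and optional dof)."""

    value: float
    se: float
    dof: float | None = None


@dataclasses.dataclass
class FitResult:
    """Least-squares estimates with standard errors and diagnostics.

    Standard errors are sqrt of the covariance diagonal with the
    covariance scaled by the residual variance RSS/dof.
    """

    model_id: str
    param_names: tuple[str, ...]
    estimates: dict[str, float]
    standard_errors: dict[str, float]
    covariance: np.ndarray
    rss: float
    n_points: int
    dof: int
    converged: bool
    n_iterations: int
    message: str = ""
    x: np.ndarray | None = None
    y: np.ndarray | None = None

    def aicc(self) -> float:
        """Small-sample corrected Akaike criterion for LS fits."""
        n = self.n_points
        k = len(self.param_names) + 1  # + residual variance
        aic = n * math.log(max(self.rss, 1e-300) / n) + 2 * k
        if n - k - 1 <= 0:
            return math.inf
        return aic + 2 * k * (k + 1) / (n - k - 1)

    def value(self, name: str) -> ValueWithError:
        return ValueWithError(self.estimates[name], self.standard_errors[name], self.dof)


@dataclasses.dataclass
class ModelComparison:
    """Outcome of comparing candidate fits on the same data."""

    candidate_ids: tuple[str, ...]
    criterion_values: dict[str, float]
    selected_id: str
    nested: bool
    f_statistic: float | None = None
    p_value: float | None = None
    alpha: float = 0.05


@dataclasses.dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float

    def significant(self, alpha: float = 0.01) -> bool:
        return self.p < alpha


def _as_1d(arr) -> np.ndarray:
    out = np.asarray(arr, dtype=float)
    if out.ndim == 2 and out.shape[1] == 1:
        out = out[:, 0]
    if out.ndim != 1:
        raise ValueError(f"expected a 1-D abscissa/ordinate, got shape {out.shape}")
    return out


class KineticCurveFitter(RegressorMixin, BaseEstimator):
    """Base class for single-abscissa nonlinear curve fits.

    Subclasses define the parameter names, the model function and an
    initial-guess heuristic.  ``fit`` accepts a 1-D array or an (n, 1)
    column as X.  Fitted attributes: ``params_`` (dict), ``se_`` (dict),
    ``cov_``, ``result_`` (:class:`FitResult`), ``converged_``,
    ``n_iter_``.
    """

    model_id: str = ""
    _param_names: tuple[str, ...] = ()

    def __init__(self, init: Mapping[str, float] | None = None,
                 bounds: Mapping[str, tuple[float, float]] | None = None,
                 max_restarts: int = 5):
        self.init = init
        self.bounds = bounds
        self.max_restarts = max_restarts

    # --- subclass API -----------------------------------------------------
    def _model(self, x: np.ndarray, theta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _default_init(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _default_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        k = len(self._param_names)
        return np.full(k, -np.inf), np.full(k, np.inf)

    # ----------------------------------------------------------------------
    def _resolved_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self._default_bounds()
        lo, hi = lo.copy(), hi.copy()
        if self.bounds:
            for name, (a, b) in self.bounds.items():
                idx = self._param_names.index(name)
                lo[idx], hi[idx] = a, b
        return lo, hi

    def _resolved_init(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        theta0 = self._default_init(x, y)
        if self.init:
            theta0 = theta0.copy()
            for name, value in self.init.items():
                theta0[self._param_names.index(name)] = value
        return np.asarray(theta0, dtype=float)

    def fit(self, X, y, sample_weight=None):
        x = _as_1d(X)
        y = _as_1d(y)
        if x.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("X and y must be finite")
        k = len(self._param_names)
        if x.size <= k:
            raise ValueError(
                f"need more than {k} points to fit {k} parameters, got {x.size}"
            )
        if np.ptp(y) == 0:
            raise ValueError("degenerate data: ordinate is constant")
        w = None
        if sample_weight is not None:
            w = np.sqrt(_as_1d(sample_weight))
            if w.shape != y.shape or np.any(w < 0):
                raise ValueError("invalid sample_weight")

        lo, hi = self._resolved_bounds()
        theta0 = np.clip(self._resolved_init(x, y), lo + 0.0, hi)
        # keep strictly inside the box for the trust-region solver
        span = np.where(np.isfinite(hi - lo), hi - lo, 1.0)
        theta0 = np.clip(theta0, lo + 1e-12 * np.abs(span), hi - 1e-12 * np.abs(span))

        def residuals(theta):
            r = self._model(x, theta) - y
            return r if w is None else w * r

        best = None
        last = None
        n_attempts = 0
        for scale in _RESTART_SCALES[: max(1, self.max_restarts)]:
            start = np.clip(theta0 * scale, lo, hi)
            start = np.where(np.isfinite(start), start, theta0)
            try:
                res = optimize.least_squares(
                    residuals, start, bounds=(lo, hi), method="trf",
                    xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000,
                )
            except Exception:  # singular start, overflow, ...
                n_attempts += 1
                continue
            n_attempts += 1
            last = res
            if res.success:
                best = res
                break
        converged = best is not None
        if best is None:
            best = last  # flagged, never silent: diagnostics survive below
        if best is None:  # pragma: no cover - every attempt raised
            raise RuntimeError("all fit attempts failed to evaluate")

        theta = best.x
        rss = float(2.0 * best.cost)
        dof = x.size - k
        cov, singular = self._covariance(best.jac, rss, dof)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

        self.params_ = dict(zip(self._param_names, theta.tolist()))
        self.se_ = dict(zip(self._param_names, se.tolist()))
        self.cov_ = cov
        self.converged_ = bool(converged and not singular)
        self.n_iter_ = int(best.nfev)
        self.result_ = FitResult(
            model_id=self.model_id,
            param_names=self._param_names,
            estimates=dict(self.params_),
            standard_errors=dict(self.se_),
            covariance=cov,
            rss=rss,
            n_points=int(x.size),
            dof=int(dof),
            converged=self.converged_,
            n_iterations=self.n_iter_,
            message=("singular Jacobian" if singular else str(best.message))
            + ("" if converged else f" [no convergence in {n_attempts} attempts]"),
            x=x.copy(),
            y=y.copy(),
        )
        return self

    @staticmethod
    def _covariance(jac: np.ndarray, rss: float, dof: int) -> tuple[np.ndarray, bool]:
        _, s, vt = np.linalg.svd(jac, full_matrices=False)
        threshold = np.finfo(float).eps * max(jac.shape) * (s[0] if s.size else 0.0)
        singular = bool(np.any(s <= threshold)) or s.size == 0
        s_inv = np.where(s > threshold, 1.0 / np.where(s > 0, s, 1.0), 0.0)
        cov_unscaled = (vt.T * s_inv**2) @ vt
        sigma2 = rss / dof if dof >= 1 else np.nan
        return cov_unscaled * sigma2, singular

    def predict(self, X):
        check_is_fitted(self, "params_")
        x = _as_1d(X)
        return self._model(x, np.array([self.params_[p] for p in self._param_names]))

    # convenience for subclasses exposing named fitted values
    def _fitted(self, name: str) -> float:
        check_is_fitted(self, "params_")
        return self.params_[name]


class MeltCurveModel(KineticCurveFitter):
    """DSF thermal-unfolding sigmoid: fluorescence vs temperature (deg C)."""

    model_id = "melt"
    _param_names = ("ll", "ul", "tm", "c")

    def _model(self, x, theta):
        ll, ul, tm, c = theta
        arg = np.clip((tm - x) / c, -700.0, 700.0)  # avoid exp overflow
        return ll + (ul - ll) / (1.0 + np.exp(arg))

    def _default_init(self, x, y):
        ll0 = float(np.percentile(y, 2))
        ul0 = float(np.percentile(y, 98))
        mid = 0.5 * (ll0 + ul0)
        tm0 = float(x[np.argmin(np.abs(y - mid))])
        c0 = max(np.ptp(x) / 20.0, 1e-3)
        return np.array([ll0, ul0, tm0, c0])

    def _default_bounds(self):
        lo = np.array([-np.inf, -np.inf, -np.inf, 1e-9])
        hi = np.array([np.inf, np.inf, np.inf, np.inf])
        return lo, hi

    @property
    def tm_(self):
        return self._fitted("tm")


class MichaelisMentenModel(KineticCurveFitter):
    """Michaelis–Menten saturation: v/E_T (1/s) vs substrate (mM)."""

    model_id = "michaelis"
    _param_names = ("kcat", "km")

    def _model(self, x, theta):
        kcat, km = theta
        return kcat * x / (km + x)

    def _default_init(self, x, y):
        kcat0 = float(np.max(y))
        half = kcat0 / 2.0
        km0 = float(x[np.argmin(np.abs(y - half))])
        return np.array([max(kcat0, 1e-9), max(km0, 1e-6)])

    def _default_bounds(self):
        return np.array([1e-12, 1e-12]), np.array([np.inf, np.inf])

    @property
    def kcat_(self):
        return self._fitted("kcat")

    @property
    def km_(self):
        return self._fitted("km")

    def catalytic_efficiency_(self) -> float:
        """Fitted kcat/Km in 1/(M*s)."""
        return models.catalytic_efficiency(self.kcat_, self.km_)


class TitrationModel(KineticCurveFitter):
    """Tight-binding quadratic titration: rate vs HisZ (uM) at fixed HisG_S.

    Parameters
    ----------
    g_conc : float
        Fixed catalytic-subunit concentration G in uM (not fitted).
    """

    model_id = "titration"
    _param_names = ("vmax", "kd_app")

    def __init__(self, g_conc: float = 1.0, init=None, bounds=None, max_restarts=5):
        super().__init__(init=init, bounds=bounds, max_restarts=max_restarts)
        self.g_conc = g_conc

    def _model(self, x, theta):
        vmax, kd = theta
        return vmax * models.holoenzyme_conc(self.g_conc, x, max(kd, 0.0)) / self.g_conc

    def _default_init(self, x, y):
        vmax0 = float(np.max(y))
        half_z = float(x[np.argmin(np.abs(y - vmax0 / 2.0))])
        kd0 = max(half_z - self.g_conc, 0.01 * self.g_conc)
        return np.array([max(vmax0, 1e-9), kd0])

    def _default_bounds(self):
        return np.array([1e-12, 0.0]), np.array([np.inf, np.inf])

    @property
    def vmax_(self):
        return self._fitted("vmax")

    @property
    def kd_app_(self):
        return self._fitted("kd_app")


class DoseResponseModel(KineticCurveFitter):
    """Hill inhibition curve: fractional activity vs inhibitor (uM)."""

    model_id = "dose_response"
    _param_names = ("ic50", "hill_n")

    def _model(self, x, theta):
        ic50, n = theta
        with np.errstate(divide="ignore"):
            ratio = np.where(x > 0, x / ic50, 0.0)
            return 1.0 / (1.0 + ratio**n)

    def _default_init(self, x, y):
        ic50_0 = float(x[np.argmin(np.abs(y - 0.5))])
        if ic50_0 <= 0:
            positive = x[x > 0]
            ic50_0 = float(np.median(positive)) if positive.size else 1.0
        return np.array([max(ic50_0, 1e-6), 1.0])

    def _default_bounds(self):
        return np.array([1e-12, 1e-6]), np.array([np.inf, 100.0])

    @property
    def ic50_(self):
        return self._fitted("ic50")

    @property
    def hill_n_(self):
        return self._fitted("hill_n")


class TwoStepBurstModel(KineticCurveFitter):
    """Lagged product formation through two consecutive irreversible steps.

    Fits P(t) in uM vs time in s.  ``fix_amplitude`` constrains ES to a
    known enzyme/substrate concentration instead of floating it.
    """

    model_id = "two_step"
    _param_names = ("es", "k2", "k3")

    def __init__(self, fix_amplitude: float | None = None, init=None, bounds=None,
                 max_restarts=5):
        super().__init__(init=init, bounds=bounds, max_restarts=max_restarts)
        self.fix_amplitude = fix_amplitude

    def _model(self, x, theta):
        es, k2, k3 = theta
        if self.fix_amplitude is not None:
            es = self.fix_amplitude
        return models.two_step_product(x, es, k2, k3)

    def _default_init(self, x, y):
        es0 = self.fix_amplitude if self.fix_amplitude is not None else float(np.max(y))
        es0 = max(es0, 1e-9)
        k_slow = _tail_rate_guess(x, y, es0)
        return np.array([es0, 4.0 * k_slow, k_slow])

    def _default_bounds(self):
        return np.array([1e-12, 1e-9, 1e-9]), np.array([np.inf] * 3)

    def fit(self, X, y, sample_weight=None):
        super().fit(X, y, sample_weight=sample_weight)
        if self.fix_amplitude is not None:
            # ES was pinned: report it without uncertainty
            self.params_["es"] = float(self.fix_amplitude)
            self.se_["es"] = 0.0
            self.result_.estimates["es"] = float(self.fix_amplitude)
            self.result_.standard_errors["es"] = 0.0
        return self

    def rates_(self) -> tuple[float, float]:
        """(k2, k3) ordered fast-first; the model is exchange-symmetric."""
        k2, k3 = self._fitted("k2"), self._fitted("k3")
        return (k2, k3) if k2 >= k3 else (k3, k2)


def _tail_rate_guess(x: np.ndarray, y: np.ndarray, es0: float) -> float:
    """Log-linear regression on the approach to the plateau.

    The window 50–90% of the amplitude avoids both the lag (where the
    fast step still matters) and the plateau (where es0 - y is noise);
    its log-gap slope estimates the slower rate constant.
    """
    order = np.argsort(x)
    x, y = x[order], y[order]
    window = (y >= 0.5 * es0) & (y <= 0.9 * es0)
    if window.sum() < 3:
        window = y <= 0.9 * es0
    gap = np.clip(es0 - y[window], es0 * 1e-6, None)
    xt = x[window]
    if xt.size < 2 or np.ptp(xt) == 0:
        return 1.0
    slope = np.polyfit(xt, np.log(gap), 1)[0]
    return max(-slope, 1e-3)


class ViscosityLineModel(KineticCurveFitter):
    """kcat(0)/kcat(eta) vs relative viscosity; intercept fixed at 1."""

    model_id = "viscosity"
    _param_names = ("m",)

    def _model(self, x, theta):
        (m,) = theta
        return m * (x - 1.0) + 1.0

    def _default_init(self, x, y):
        dx = x - 1.0
        denom = float(np.dot(dx, dx))
        m0 = float(np.dot(dx, y - 1.0)) / denom if denom > 0 else 0.0
        return np.array([m0])

    @property
    def slope_(self):
        return self._fitted("m")

    def slope_ci_(self, level: float = 0.95) -> tuple[float, float]:
        check_is_fitted(self, "result_")
        half = stats.t.ppf(0.5 + level / 2.0, self.result_.dof) * self.se_["m"]
        return self.slope_ - half, self.slope_ + half


class EyringModel(KineticCurveFitter):
    """Linear Eyring fit of ln(kcat/T) vs T (K); the dCp = 0 reduction."""

    model_id = "eyring"
    _param_names = ("dh", "ds")

    def _model(self, x, theta):
        dh, ds = theta
        return models.eyring_log_rate(x, dh, ds)

    def _default_init(self, x, y):
        # ln(k/T) = [ln(kB/h) + dS/R] - (dH/R)(1/T): seed from the line in 1/T
        slope, intercept = np.polyfit(1.0 / x, y, 1)
        dh0 = -slope * models.CODATA.r
        ds0 = (intercept - math.log(models.CODATA.kb_over_h)) * models.CODATA.r
        return np.array([dh0, ds0])


class MMRTModel(KineticCurveFitter):
    """Curved Eyring fit with activation heat capacity, T0 fixed (never fitted)."""

    model_id = "mmrt"
    _param_names = ("dh_t0", "ds_t0", "dcp")

    def __init__(self, t0: float = 298.0, init=None, bounds=None, max_restarts=5):
        super().__init__(init=init, bounds=bounds, max_restarts=max_restarts)
        self.t0 = t0

    def _model(self, x, theta):
        dh, ds, dcp = theta
        return models.mmrt_log_rate(x, dh, ds, dcp, t0=self.t0)

    def _default_init(self, x, y):
        lin = EyringModel()._default_init(x, y)
        return np.array([lin[0], lin[1], 0.0])

    @property
    def dcp_(self):
        return self._fitted("dcp")


class SingleExponentialModel(KineticCurveFitter):
    """Exponential product rise A*(1-exp(-k_STO*t)); P(t) in uM vs s."""

    model_id = "single_exp"
    _param_names = ("a", "k_sto")

    def _model(self, x, theta):
        a, k = theta
        return a * (1.0 - np.exp(-k * x))

    def _default_init(self, x, y):
        a0 = max(float(np.max(y)), 1e-9)
        target = 0.632 * a0
        t63 = float(x[np.argmin(np.abs(y - target))])
        k0 = 1.0 / t63 if t63 > 0 else 1.0
        return np.array([a0, k0])

    def _default_bounds(self):
        return np.array([1e-12, 1e-9]), np.array([np.inf, np.inf])

    @property
    def k_sto_(self):
        return self._fitted("k_sto")


MODEL_REGISTRY: dict[str, type[KineticCurveFitter]] = {
    cls.model_id: cls
    for cls in (
        MeltCurveModel,
        MichaelisMentenModel,
        TitrationModel,
        DoseResponseModel,
        TwoStepBurstModel,
        ViscosityLineModel,
        EyringModel,
        MMRTModel,
        SingleExponentialModel,
    )
}


def make_estimator(model_id: str, **kwargs) -> KineticCurveFitter:
    try:
        cls = MODEL_REGISTRY[model_id]
    except KeyError:
        raise ValueError(
            f"unknown model {model_id!r}; known: {sorted(MODEL_REGISTRY)}"
        ) from None
    return cls(**kwargs)


def fit(model_id: str, x, y, init: Mapping[str, float] | None = None,
        bounds: Mapping[str, tuple[float, float]] | None = None,
        weights=None, **estimator_kwargs) -> FitResult:
    """Functional front end: fit one of the registered models and return
    the :class:`FitResult`."""
    est = make_estimator(model_id, init=init, bounds=bounds, **estimator_kwargs)
    est.fit(x, y, sample_weight=weights)
    return est.result_


def initial_guess(model_id: str, x, y, **estimator_kwargs) -> dict[str, float]:
    """Per-model starting-value heuristics (documented on each estimator)."""
    est = make_estimator(model_id, **estimator_kwargs)
    x, y = _as_1d(x), _as_1d(y)
    if x.size == 0:
        raise ValueError("dataset is empty")
    if np.ptp(y) == 0:
        raise ValueError("degenerate data: ordinate is constant")
    theta0 = est._default_init(x, y)
    return dict(zip(est._param_names, np.asarray(theta0, dtype=float).tolist()))


def _same_data(a: FitResult, b: FitResult) -> bool:
    return (
        a.x is not None and b.x is not None
        and np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)
    )


def compare_models(fits: Sequence[FitResult], nested: bool = False,
                   alpha: float = 0.05) -> ModelComparison:
    """Select among candidate fits of the same data.

    Non-nested candidates (e.g. lag vs single-exponential single-turnover
    models) are ranked by AICc.  Nested pairs (e.g. linear Eyring inside
    MMRT) use the extra-sum-of-squares F-test at ``alpha``: the richer
    model is selected only if it significantly reduces the RSS.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    for other in fits[1:]:
        if not _same_data(fits[0], other):
            raise ValueError("model comparison requires fits on identical data")
    ids = tuple(f.model_id for f in fits)
    criteria = {f.model_id: f.aicc() for f in fits}

    if not nested:
        selected = min(fits, key=lambda f: f.aicc()).model_id
        return ModelComparison(ids, criteria, selected, nested=False, alpha=alpha)

    if len(fits) != 2:
        raise ValueError("nested comparison takes exactly two fits")
    restricted, full = sorted(fits, key=lambda f: len(f.param_names))
    if len(full.param_names) <= len(restricted.param_names):
        raise ValueError("nested comparison needs models of different size")
    df_extra = len(full.param_names) - len(restricted.param_names)
    if full.dof < 1:
        raise ValueError("full model has no residual degrees of freedom")
    num = max(restricted.rss - full.rss, 0.0) / df_extra
    den = full.rss / full.dof
    f_stat = num / den if den > 0 else math.inf
    p = float(stats.f.sf(f_stat, df_extra, full.dof))
    selected = full.model_id if p < alpha else restricted.model_id
    return ModelComparison(ids, criteria, selected, nested=True,
                           f_statistic=float(f_stat), p_value=p, alpha=alpha)


def propagate_ratio(numerator: ValueWithError | tuple[float, float],
                    denominator: ValueWithError | tuple[float, float]) -> ValueWithError:
    """Ratio a/b with standard error propagated in quadrature.

    SE_r = r * sqrt((SE_a/a)^2 + (SE_b/b)^2), assuming independent errors.
    This is how the unlabelled/heavy kcat ratio (HE-KIE) uncertainty is
    reported.
    """
    a = numerator if isinstance(numerator, ValueWithError) else ValueWithError(*numerator)
    b = denominator if isinstance(denominator, ValueWithError) else ValueWithError(*denominator)
    if b.value <= 0:
        raise ValueError("denominator must be positive")
    if a.value == 0:
        return ValueWithError(0.0, a.se / b.value)
    r = a.value / b.value
    se = abs(r) * math.sqrt((a.se / a.value) ** 2 + (b.se / b.value) ** 2)
    return ValueWithError(r, se)


def t_test_kcat(a: ValueWithError | tuple, b: ValueWithError | tuple) -> TTestResult:
    """Two-sided Welch t-test between two fitted estimates.

    t = (a-b)/sqrt(SE_a^2 + SE_b^2); degrees of freedom by
    Welch–Satterthwaite from each fit's residual dof.
    """
    a = a if isinstance(a, ValueWithError) else ValueWithError(*a)
    b = b if isinstance(b, ValueWithError) else ValueWithError(*b)
    if a.se <= 0 or b.se <= 0:
        raise ValueError("both standard errors must be positive")
    if a.dof is None or b.dof is None or a.dof < 1 or b.dof < 1:
        raise ValueError("both estimates need dof >= 1")
    var = a.se**2 + b.se**2
    t = (a.value - b.value) / math.sqrt(var)
    df = var**2 / (a.se**4 / a.dof + b.se**4 / b.dof)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=float(df), p=min(p, 1.0))
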