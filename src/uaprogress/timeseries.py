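"""Two-segment ARIMA analysis of the adjusted weekly score series.

The adjusted score for week ``i`` (group score divided by the number of
patients tested) forms a 52-point weekly time series.  Because the
protocol's testing demand changes when patients stabilize — on average
about six months in — the series is split at week 27 and each segment is
modelled separately:

1. augmented Dickey-Fuller (ADF) unit-root test for stationarity,
2. ARIMA(p, d, q) fit with either caller-fixed orders or an AIC grid
   search in which ``d`` is the smallest differencing order whose
   differenced series rejects a unit root,
3. Box-Pierce portmanteau test on the residuals (Ljung-Box available as
   an option; it dominates in small samples),
4. out-of-sample forecasting with confidence intervals.

Estimation and testing are delegated to statsmodels; this module owns the
segmentation logic, order-selection procedure, validation, and the
machine-readable report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from statsmodels.stats.diagnostic import acorr_ljungbox
from statsmodels.tsa.arima.model import ARIMA
from statsmodels.tsa.stattools import adfuller

from .scoring import WeeklyGroupScore, fill_missing_adjusted

__all__ = [
    "ArimaOrder",
    "ArimaFit",
    "StationarityResult",
    "PortmanteauResult",
    "ForecastResult",
    "AnalysisConfig",
    "SegmentReport",
    "DegenerateSeriesError",
    "FitError",
    "OrderSelectionError",
    "difference",
    "undifference",
    "adf_test",
    "fit_arima",
    "select_order",
    "box_pierce",
    "split_phases",
    "forecast",
    "run_two_phase_analysis",
]


class DegenerateSeriesError(ValueError):
    """Series is constant or otherwise unusable for the requested analysis."""


class FitError(RuntimeError):
    """ARIMA estimation failed; carries optimizer diagnostics."""


class OrderSelectionError(RuntimeError):
    """No admissible (p, d, q) candidate could be selected."""


@dataclass(frozen=True)
class ArimaOrder:
    """ARIMA order: p autoregressive lags, d differences, q moving-average lags."""

    p: int
    d: int
    q: int

    def __post_init__(self) -> None:
        if min(self.p, self.d, self.q) < 0:
            raise ValueError("ARIMA orders must be non-negative")

    @property
    def n_params(self) -> int:
        """Number of fitted lag coefficients (p + q), used for portmanteau df."""
        return self.p + self.q

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.p, self.d, self.q)


@dataclass
class ArimaFit:
    """A fitted ARIMA model plus the statsmodels results object for forecasting."""

    order: ArimaOrder
    ar_coefficients: np.ndarray
    ma_coefficients: np.ndarray
    intercept: float
    residuals: np.ndarray
    aic: float
    loglik: float
    converged: bool
    _results: object = field(repr=False, default=None)


@dataclass(frozen=True)
class StationarityResult:
    """ADF unit-root test outcome; rejection indicates stationarity."""

    statistic: float
    p_value: float
    lags_used: int
    alpha: float
    reject_unit_root: bool


@dataclass(frozen=True)
class PortmanteauResult:
    """Portmanteau (Box-Pierce or Ljung-Box) residual-autocorrelation test."""

    q_statistic: float
    df: int
    p_value: float
    n_lags: int
    method: str = "box-pierce"


@dataclass(frozen=True)
class ForecastResult:
    horizon: int
    level: float
    point_forecasts: np.ndarray
    lower: np.ndarray
    upper: np.ndarray


def difference(series: Sequence[float], d: int) -> np.ndarray:
    """Apply the first-difference operator ``d`` times (length shrinks by d)."""
    x = np.asarray(series, dtype=float)
    if d < 0:
        raise ValueError("d must be >= 0")
    if len(x) <= d:
        raise ValueError(f"series of length {len(x)} too short for d={d}")
    return np.diff(x, n=d) if d > 0 else x.copy()


def undifference(diffed: Sequence[float], initial: Sequence[float]) -> np.ndarray:
    """Invert :func:`difference` given the ``d`` dropped leading values.

    ``initial`` must hold the first value of each intermediate difference
    level, innermost last, i.e. ``initial[k]`` is the first element of the
    series differenced ``k`` times.
    """
    x = np.asarray(diffed, dtype=float)
    for k in range(len(initial) - 1, -1, -1):
        x = np.concatenate([[initial[k]], x]).cumsum()
    return x


def adf_test(
    series: Sequence[float],
    lags: int | Literal["auto"] = "auto",
    alpha: float = 0.05,
) -> StationarityResult:
    """Augmented Dickey-Fuller unit-root test (constant-only regression).

    ``lags='auto'`` uses floor((T-1)^(1/3)) lagged differences.  Rejection
    of the unit-root null at ``alpha`` is reported as stationarity.
    """
    x = np.asarray(series, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("ADF regression is degenerate on a constant series")
    n_lags = int(np.floor((len(x) - 1) ** (1 / 3))) if lags == "auto" else int(lags)
    if len(x) < n_lags + 10:
        raise ValueError(
            f"series of length {len(x)} too short for ADF with {n_lags} lags"
        )
    stat, p_value, used_lags, *_ = adfuller(x, maxlag=n_lags, regression="c", autolag=None)
    return StationarityResult(
        statistic=float(stat),
        p_value=float(p_value),
        lags_used=int(used_lags),
        alpha=alpha,
        reject_unit_root=bool(p_value < alpha),
    )


def fit_arima(series: Sequence[float], order: ArimaOrder) -> ArimaFit:
    """Maximum-likelihood ARIMA fit.

    An intercept (constant trend) is included for d = 0 models, matching
    the usual convention that differencing absorbs the level.  Residuals
    exclude the first ``d`` diffuse values, so their length is
    ``len(series) - d``.  Raises :class:`FitError` if the optimizer does
    not converge.
    """
    x = np.asarray(series, dtype=float)
    if len(x) - order.d <= order.p + order.q + 1:
        raise ValueError(
            f"series of length {len(x)} insufficient for order {order.as_tuple()}"
        )
    trend = "c" if order.d == 0 else "n"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ARIMA(x, order=order.as_tuple(), trend=trend)
        try:
            results = model.fit(method_kwargs={"maxiter": 200})
        except Exception as exc:  # noqa: BLE001 - surface as a domain error
            raise FitError(f"ARIMA{order.as_tuple()} estimation failed: {exc}") from exc
    retvals = getattr(results, "mle_retvals", {}) or {}
    converged = bool(retvals.get("converged", True))
    if not converged:
        raise FitError(
            f"ARIMA{order.as_tuple()} did not converge; optimizer diagnostics: {retvals}"
        )
    params = results.params
    intercept = float(params[0]) if trend == "c" else 0.0
    return ArimaFit(
        order=order,
        ar_coefficients=np.asarray(results.arparams, dtype=float),
        ma_coefficients=np.asarray(results.maparams, dtype=float),
        intercept=intercept,
        residuals=np.asarray(results.resid, dtype=float)[order.d :],
        aic=float(results.aic),
        loglik=float(results.llf),
        converged=converged,
        _results=results,
    )


def select_order(
    series: Sequence[float],
    max_p: int = 5,
    max_d: int = 2,
    max_q: int = 5,
    alpha: float = 0.05,
) -> ArimaOrder:
    """Grid order selection: ADF-driven d, then AIC over (p, q).

    ``d`` is the smallest value in 0..max_d whose d-times differenced
    series rejects a unit root at ``alpha``; then every (p, q) on the grid
    is fitted and the AIC-minimizing pair wins, ties broken by smaller
    p + q, then smaller p.
    """
    x = np.asarray(series, dtype=float)
    if min(max_p, max_d, max_q) < 0:
        raise ValueError("grid bounds must be >= 0")

    chosen_d: int | None = None
    for d in range(max_d + 1):
        try:
            if adf_test(difference(x, d), alpha=alpha).reject_unit_root:
                chosen_d = d
                break
        except (DegenerateSeriesError, ValueError):
            continue
    if chosen_d is None:
        raise OrderSelectionError(
            f"no d in 0..{max_d} yields a stationary differenced series at alpha={alpha}"
        )

    best: tuple[float, int, int, ArimaOrder] | None = None
    for p in range(max_p + 1):
        for q in range(max_q + 1):
            order = ArimaOrder(p, chosen_d, q)
            try:
                fit = fit_arima(x, order)
            except (FitError, ValueError):
                continue
            key = (fit.aic, p + q, p)
            if best is None or key < (best[0], best[1], best[2]):
                best = (fit.aic, p + q, p, order)
    if best is None:
        raise OrderSelectionError("no (p, q) candidate on the grid converged")
    return best[3]


def box_pierce(
    residuals: Sequence[float], n_lags: int, n_fitted_params: int = 0,
    method: Literal["box-pierce", "ljung-box"] = "box-pierce",
) -> PortmanteauResult:
    """Portmanteau test for residual autocorrelation.

    Box-Pierce statistic Q = T * sum_{k=1..n_lags} rho_k^2, referred to a
    chi-square with ``n_lags - n_fitted_params`` degrees of freedom.
    """
    x = np.asarray(residuals, dtype=float)
    if n_lags <= n_fitted_params:
        raise ValueError(
            f"n_lags ({n_lags}) must exceed n_fitted_params ({n_fitted_params})"
        )
    if len(x) <= n_lags:
        raise ValueError(f"need more than {n_lags} residuals, got {len(x)}")
    table = acorr_ljungbox(
        x, lags=[n_lags], boxpierce=True, model_df=n_fitted_params
    )
    if method == "box-pierce":
        q_stat = float(table["bp_stat"].iloc[0])
        p_value = float(table["bp_pvalue"].iloc[0])
    elif method == "ljung-box":
        q_stat = float(table["lb_stat"].iloc[0])
        p_value = float(table["lb_pvalue"].iloc[0])
    else:
        raise ValueError(f"unknown portmanteau method {method!r}")
    return PortmanteauResult(
        q_statistic=q_stat,
        df=n_lags - n_fitted_params,
        p_value=p_value,
        n_lags=n_lags,
        method=method,
    )


def split_phases(
    series: Sequence[float], split_week: int = 27
) -> tuple[np.ndarray, np.ndarray]:
    """Split a weekly series into pre- and post-transition segments.

    Week indexing is 1-based: the first segment covers weeks
    1..split_week-1, the second split_week..end.  A 52-point series split
    at 27 yields two 26-point halves.
    """
    x = np.asarray(series, dtype=float)
    if not 1 < split_week <= len(x):
        raise ValueError(f"split_week must be in (1, {len(x)}], got {split_week}")
    return x[: split_week - 1], x[split_week - 1 :]


def forecast(fit: ArimaFit, horizon: int, level: float = 0.95) -> ForecastResult:
    """Point forecasts with symmetric confidence intervals at ``level``."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    pred = fit._results.get_forecast(steps=horizon)
    ci = pred.conf_int(alpha=1 - level)
    ci = np.asarray(ci, dtype=float)
    return ForecastResult(
        horizon=horizon,
        level=level,
        point_forecasts=np.asarray(pred.predicted_mean, dtype=float),
        lower=ci[:, 0],
        upper=ci[:, 1],
    )


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for the two-phase analysis pipeline."""

    split_week: int = 27
    fill_policy: Literal["zero", "interpolate"] = "zero"
    orders: tuple[ArimaOrder, ArimaOrder] | None = None
    max_p: int = 5
    max_d: int = 2
    max_q: int = 5
    alpha: float = 0.05
    forecast_horizon: int = 8
    forecast_level: float = 0.95
    portmanteau: Literal["box-pierce", "ljung-box"] = "box-pierce"


@dataclass
class SegmentReport:
    """All statistics for one analysed segment."""

    name: str
    n_points: int
    adf: StationarityResult
    order: ArimaOrder
    fit: ArimaFit
    portmanteau: PortmanteauResult
    forecast: ForecastResult
    small_sample_warning: bool

    def to_dict(self) -> dict:
        return {
            "segment": self.name,
            "n_points": self.n_points,
            "adf": {
                "statistic": self.adf.statistic,
                "p_value": self.adf.p_value,
                "lags_used": self.adf.lags_used,
                "reject_unit_root": self.adf.reject_unit_root,
            },
            "order": {"p": self.order.p, "d": self.order.d, "q": self.order.q},
            "ar_coefficients": self.fit.ar_coefficients.tolist(),
            "ma_coefficients": self.fit.ma_coefficients.tolist(),
            "intercept": self.fit.intercept,
            "aic": self.fit.aic,
            "loglik": self.fit.loglik,
            "portmanteau": {
                "method": self.portmanteau.method,
                "q_statistic": self.portmanteau.q_statistic,
                "df": self.portmanteau.df,
                "p_value": self.portmanteau.p_value,
                "n_lags": self.portmanteau.n_lags,
            },
            "forecast": {
                "horizon": self.forecast.horizon,
                "level": self.forecast.level,
                "point": self.forecast.point_forecasts.tolist(),
                "lower": self.forecast.lower.tolist(),
                "upper": self.forecast.upper.tolist(),
            },
            "small_sample_warning": self.small_sample_warning,
        }


def _analyse_segment(name: str, segment: np.ndarray, config: AnalysisConfig,
                     fixed_order: ArimaOrder | None) -> SegmentReport:
    if np.ptp(segment) == 0:
        raise DegenerateSeriesError(
            f"{name} segment is constant; ARIMA analysis is undefined"
        )
    adf = adf_test(segment, alpha=config.alpha)
    if fixed_order is not None:
        order = fixed_order
    else:
        order = select_order(
            segment, max_p=config.max_p, max_d=config.max_d, max_q=config.max_q,
            alpha=config.alpha,
        )
    small_sample = len(segment) - order.d < 3 * (order.n_params + 1)
    if small_sample:
        warnings.warn(
            f"{name}: order {order.as_tuple()} leaves only "
            f"{len(segment) - order.d} effective points for "
            f"{order.n_params} lag coefficients; estimates are fragile",
            UserWarning,
            stacklevel=2,
        )
    fit = fit_arima(segment, order)
    # Default portmanteau lag rule min(10, T//5), but the df must be
    # positive: with heavily parameterized orders the lag count is raised
    # to n_params + 1 so a p-value exists.
    n_lags = max(min(10, len(segment) // 5), order.n_params + 1)
    if len(fit.residuals) <= n_lags:
        n_lags = len(fit.residuals) - 1
    if n_lags <= order.n_params:
        raise FitError(
            f"{name}: too few residuals ({len(fit.residuals)}) for a portmanteau "
            f"test of a model with {order.n_params} lag coefficients"
        )
    pm = box_pierce(fit.residuals, n_lags, order.n_params, method=config.portmanteau)
    fc = forecast(fit, config.forecast_horizon, config.forecast_level)
    return SegmentReport(
        name=name,
        n_points=len(segment),
        adf=adf,
        order=order,
        fit=fit,
        portmanteau=pm,
        forecast=fc,
        small_sample_warning=small_sample,
    )


def run_two_phase_analysis(
    weekly: Sequence[WeeklyGroupScore], config: AnalysisConfig | None = None
) -> dict:
    """Full two-segment analysis of a weekly adjusted-score series.

    Fills missing weeks per the configured policy, splits at the phase
    cut-off week, and per segment runs ADF, order selection (or fixed
    orders), ARIMA fit, portmanteau diagnostics and forecasting.  Returns
    a machine-readable report; stage errors propagate with the failing
    segment named.
    """
    config = config or AnalysisConfig()
    filled = fill_missing_adjusted(weekly, policy=config.fill_policy)
    n_filled = sum(1 for w in weekly if w.adjusted_score is None)
    first, second = split_phases(filled, config.split_week)

    fixed_first = config.orders[0] if config.orders else None
    fixed_second = config.orders[1] if config.orders else None
    try:
        first_report = _analyse_segment("high_demand", first, config, fixed_first)
    except Exception as exc:
        raise type(exc)(f"[segment high_demand, weeks 1-{config.split_week - 1}] {exc}") from exc
    try:
        second_report = _analyse_segment("low_demand", second, config, fixed_second)
    except Exception as exc:
        raise type(exc)(f"[segment low_demand, weeks {config.split_week}-{len(filled)}] {exc}") from exc

    return {
        "n_weeks": len(filled),
        "split_week": config.split_week,
        "fill_policy": config.fill_policy,
        "n_weeks_filled": n_filled,
        "alpha": config.alpha,
        "segments": [first_report.to_dict(), second_report.to_dict()],
    }
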