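"""Per-subject ARIMA modelling of trend-model residuals.

Each subject's residual series gets its own ARIMA(p, d, q): the differencing
order d comes from repeated KPSS tests (with a configurable floor, default
d >= 1 because trends typically survive the trend-model stage), and (p, q)
from a stepwise AICc neighbourhood search in the style of the
Hyndman–Khandakar auto-ARIMA algorithm.  Likelihood fitting of each candidate
is delegated to :class:`statsmodels.tsa.arima.model.ARIMA` (exact state-space
Gaussian ML).  Fitted values are in-sample one-step-ahead predictions, so the
whitened residual is r_t = eps_t - epshat_t and epshat + r reconstructs the
input exactly.

Seasonal orders (P, D, Q, S) are carried on :class:`ARIMAOrder` for interface
completeness but the reference pipeline never fits them (S = 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.tsa.arima.model import ARIMA
from statsmodels.tsa import stattools

from .diagnostics import WhitenessReport, whiteness_report
from .errors import FitError, SelectionError, SeriesLengthError
from .lmm import LMMFit


@dataclass(frozen=True)
class ARIMAOrder:
    p: int
    d: int
    q: int
    seasonal: tuple[int, int, int, int] = (0, 0, 0, 0)  # (P, D, Q, S)
    trend: str = "n"  # 'n' none, 'c' constant (d=0), 't' drift (d=1)

    def __post_init__(self) -> None:
        if min(self.p, self.d, self.q) < 0 or self.d > 2:
            raise ValueError(f"invalid order {(self.p, self.d, self.q)}")
        P, D, Q, S = self.seasonal
        if S <= 1 and (P, D, Q) != (0, 0, 0):
            raise ValueError("seasonal terms require a seasonal period S > 1")
        if self.trend not in ("n", "c", "t"):
            raise ValueError(f"unknown trend {self.trend!r}")

    @property
    def pdq(self) -> tuple[int, int, int]:
        return (self.p, self.d, self.q)

    def __str__(self) -> str:  # ARIMA(1,1,0) style
        s = f"ARIMA({self.p},{self.d},{self.q})"
        if self.seasonal[3] > 1:
            s += f"x{self.seasonal[:3]}[{self.seasonal[3]}]"
        if self.trend != "n":
            s += " with " + ("constant" if self.trend == "c" else "drift")
        return s


@dataclass
class ARIMAFit:
    """One subject's fitted residual model."""

    order: ARIMAOrder
    ar_coeffs: np.ndarray
    ma_coeffs: np.ndarray
    intercept: float  # constant/drift coefficient, 0.0 when trend='n'
    sigma2: float
    loglik: float
    aic: float
    aicc: float
    bic: float
    fitted: np.ndarray  # one-step in-sample predictions epshat_t
    residuals: np.ndarray  # input - fitted (whitened residuals r_t)
    method: str = "statespace-ML"


@dataclass(frozen=True)
class ARIMASettings:
    """Knobs of the per-subject residual-modelling stage."""

    min_d: int = 1  # floor on differencing; trends usually persist
    max_d: int = 2
    p_max: int = 5
    q_max: int = 5
    ic: str = "aicc"  # selection criterion: aicc | aic | bic
    kpss_alpha: float = 0.05
    drift: bool = True  # consider constant/drift candidates when d <= 1

    def __post_init__(self) -> None:
        if not 0 <= self.min_d <= self.max_d <= 2:
            raise ValueError("need 0 <= min_d <= max_d <= 2")
        if self.ic not in ("aicc", "aic", "bic"):
            raise ValueError(f"unknown information criterion {self.ic!r}")


def choose_d(series, min_d: int = 1, *, max_d: int = 2, alpha: float = 0.05) -> int:
    """Differencing order: start at ``min_d``, difference until KPSS accepts.

    The min_d-times differenced series is tested for level stationarity;
    while the test rejects at ``alpha`` (and d < max_d), d is incremented.
    """
    y = np.asarray(series, dtype=float)
    if len(y) < 20:
        raise SeriesLengthError(f"need >= 20 points to choose d, got {len(y)}")
    if not 0 <= min_d <= max_d <= 2:
        raise ValueError("need 0 <= min_d <= max_d <= 2")
    d = min_d
    x = np.diff(y, n=min_d) if min_d else y
    while d < max_d:
        if len(x) < 12:
            raise SeriesLengthError("series too short after differencing")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, pvalue, *_ = stattools.kpss(x, regression="c", nlags="auto")
        if pvalue >= alpha:
            break
        d += 1
        x = np.diff(x)
    return d


def _candidate_trends(d: int, drift: bool) -> list[str]:
    if not drift:
        return ["n"]
    if d == 0:
        return ["c", "n"]
    if d == 1:
        return ["t", "n"]
    return ["n"]


def fit_arima(series, order: ARIMAOrder) -> ARIMAFit:
    """Exact-ML fit of one ARIMA model; raises :class:`FitError` on failure.

    Stationarity/invertibility are enforced during optimization, so the
    fitted AR and MA polynomials have roots outside the unit circle.
    """
    y = np.asarray(series, dtype=float)
    if len(y) <= order.p + order.d + order.q + 1:
        raise SeriesLengthError(
            f"series of length {len(y)} too short for {order}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = ARIMA(
                y,
                order=order.pdq,
                trend=order.trend if order.trend != "n" else None,
                enforce_stationarity=True,
                enforce_invertibility=True,
            )
            res = model.fit()
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise FitError(f"{order} fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise FitError(f"{order} fit produced non-finite parameters")
    fitted = np.asarray(res.fittedvalues, dtype=float)
    resid = y - fitted
    names = list(res.param_names)
    params = pd.Series(np.asarray(res.params, dtype=float), index=names)
    ar = params[[n for n in names if n.startswith("ar.")]].to_numpy()
    ma = params[[n for n in names if n.startswith("ma.")]].to_numpy()
    const = 0.0
    for cname in ("const", "x1", "trend.1", "drift"):
        if cname in params.index:
            const = float(params[cname])
            break
    return ARIMAFit(
        order=order,
        ar_coeffs=ar,
        ma_coeffs=ma,
        intercept=const,
        sigma2=float(params.get("sigma2", np.nan)),
        loglik=float(res.llf),
        aic=float(res.aic),
        aicc=float(res.aicc),
        bic=float(res.bic),
        fitted=fitted,
        residuals=resid,
    )


def _criterion(fit: ARIMAFit, ic: str) -> float:
    return getattr(fit, ic)


def _near_unit_roots(fit: ARIMAFit, tol: float = 1e-2) -> bool:
    """True when an AR or MA polynomial root sits on/near the unit circle.

    Such candidates are numerically fragile (near-cancelling or marginally
    stationary/invertible) and are skipped during order selection, as in the
    reference auto-selection algorithm.
    """
    # AR: phi(z) = 1 - phi1 z - ...; MA: theta(z) = 1 + theta1 z + ...
    for coeffs, sign in ((fit.ar_coeffs, -1.0), (fit.ma_coeffs, 1.0)):
        if len(coeffs):
            roots = np.roots(np.r_[sign * coeffs[::-1], 1.0])
            if len(roots) and np.abs(roots).min() < 1.0 + tol:
                return True
    return False


def stepwise_select(
    series,
    d: int,
    *,
    p_max: int = 5,
    q_max: int = 5,
    ic: str = "aicc",
    drift: bool = True,
    return_fit: bool = False,
):
    """Stepwise Hyndman–Khandakar-style search for the (p, q) order.

    Starts from {(0,d,0), (1,d,0), (0,d,1), (2,d,2)} (with and without a
    constant/drift term when d <= 1) and repeatedly moves to the best-IC
    neighbour obtained by stepping p and/or q by +-1 or toggling the trend
    term, until no neighbour improves.  Ties break toward smaller p+q, then
    smaller p.  Returns the selected :class:`ARIMAOrder` (and its fit when
    ``return_fit``).
    """
    y = np.asarray(series, dtype=float)
    cache: dict[tuple[int, int, str], tuple[float, ARIMAFit | None]] = {}
    failures: list[str] = []

    def evaluate(p: int, q: int, trend: str) -> float:
        key = (p, q, trend)
        if key in cache:
            return cache[key][0]
        if not (0 <= p <= p_max and 0 <= q <= q_max):
            cache[key] = (np.inf, None)
            return np.inf
        try:
            fit = fit_arima(y, ARIMAOrder(p, d, q, trend=trend))
            # near-unit roots signal a fragile overfit when no differencing
            # was applied; with d >= 1 a unit MA root is the legitimate
            # signature of (possibly forced) overdifferencing, so keep it
            if d == 0 and (p or q) and _near_unit_roots(fit):
                fit, crit = None, np.inf
            else:
                crit = _criterion(fit, ic)
        except (FitError, SeriesLengthError) as exc:
            failures.append(str(exc))
            fit, crit = None, np.inf
        cache[key] = (crit, fit)
        return crit

    def rank(key: tuple[int, int, str]):
        p, q, _ = key
        return (cache[key][0], p + q, p)

    if p_max == 0 and q_max == 0:
        trends = _candidate_trends(d, drift)
        for tr in trends:
            evaluate(0, 0, tr)
        best = min(cache, key=rank)
    else:
        # starts use the richer trend variant; the toggle is explored as a move
        start_trend = _candidate_trends(d, drift)[0]
        for p, q in [(0, 0), (1, 0), (0, 1), (2, 2)]:
            evaluate(p, q, start_trend)
        finite = [k for k in cache if np.isfinite(cache[k][0])]
        if not finite:
            raise SelectionError(
                "every starting candidate failed to fit: " + "; ".join(failures[:4])
            )
        best = min(cache, key=rank)
        while True:
            p, q, tr = best
            neighbours = [
                (p + 1, q, tr), (p - 1, q, tr),
                (p, q + 1, tr), (p, q - 1, tr),
                (p + 1, q + 1, tr), (p - 1, q - 1, tr),
            ]
            for alt in _candidate_trends(d, drift):
                if alt != tr:
                    neighbours.append((p, q, alt))
            for np_, nq, ntr in neighbours:
                if np_ >= 0 and nq >= 0:
                    evaluate(np_, nq, ntr)
            new_best = min(cache, key=rank)
            if rank(new_best) >= rank(best):
                break
            best = new_best

    crit, fit = cache[best]
    if not np.isfinite(crit):
        raise SelectionError(
            "no candidate ARIMA model could be fitted: " + "; ".join(failures[:4])
        )
    order = ARIMAOrder(best[0], d, best[1], trend=best[2])
    if return_fit:
        return order, fit
    return order


def exhaustive_select(
    series, d: int, *, p_max: int = 3, q_max: int = 3, ic: str = "aicc", drift: bool = True
) -> tuple[ARIMAOrder, float]:
    """Brute-force search over the full (p, q) grid; the stepwise oracle."""
    y = np.asarray(series, dtype=float)
    best_key: tuple[float, int, int] | None = None
    best_order: ARIMAOrder | None = None
    for p in range(p_max + 1):
        for q in range(q_max + 1):
            for tr in _candidate_trends(d, drift):
                try:
                    fit = fit_arima(y, ARIMAOrder(p, d, q, trend=tr))
                except (FitError, SeriesLengthError):
                    continue
                if d == 0 and (p or q) and _near_unit_roots(fit):
                    continue
                key = (_criterion(fit, ic), p + q, p)
                if best_key is None or key < best_key:
                    best_key, best_order = key, ARIMAOrder(p, d, q, trend=tr)
    if best_order is None or best_key is None:
        raise SelectionError("no model in the grid could be fitted")
    return best_order, best_key[0]


@dataclass
class ResidualModelSet:
    """ARIMA fits for every subject's residual series, plus diagnostics."""

    fits: dict[str, ARIMAFit]
    whiteness: WhitenessReport
    settings: ARIMASettings

    def orders_frame(self) -> pd.DataFrame:
        """Per-subject model listing (subject, order, coefficients, AICc)."""
        rows = []
        for subj, fit in self.fits.items():
            rows.append(
                {
                    "subject": subj,
                    "model": str(fit.order),
                    "p": fit.order.p,
                    "d": fit.order.d,
                    "q": fit.order.q,
                    "ar_coeffs": ";".join(f"{c:.6g}" for c in fit.ar_coeffs),
                    "ma_coeffs": ";".join(f"{c:.6g}" for c in fit.ma_coeffs),
                    "intercept": fit.intercept,
                    "sigma2": fit.sigma2,
                    "aicc": fit.aicc,
                }
            )
        return pd.DataFrame(rows)


def fit_all_residuals(
    lmm_fit: LMMFit, settings: ARIMASettings | None = None
) -> ResidualModelSet:
    """Select and fit one ARIMA model per subject's trend-model residuals.

    For each subject: d via :func:`choose_d` (respecting ``settings.min_d``),
    order via :func:`stepwise_select`, then the final fit.  Returns all fits
    plus a whiteness report on the whitened residuals r.  If any subject
    fails, a :class:`FitError` naming it is raised with the partial results
    attached as ``exc.partial``.
    """
    settings = settings or ARIMASettings()
    residuals = lmm_fit.residual_series()
    if not residuals:
        raise FitError("no residual series to fit")
    fits: dict[str, ARIMAFit] = {}
    errors: dict[str, str] = {}
    for subj, series in residuals.items():
        try:
            d = choose_d(
                series, settings.min_d, max_d=settings.max_d, alpha=settings.kpss_alpha
            )
            _, fit = stepwise_select(
                series,
                d,
                p_max=settings.p_max,
                q_max=settings.q_max,
                ic=settings.ic,
                drift=settings.drift,
                return_fit=True,
            )
            fits[subj] = fit
        except (FitError, SeriesLengthError) as exc:
            errors[subj] = str(exc)
    if errors:
        err = FitError(
            f"ARIMA stage failed for subject(s) {sorted(errors)}: "
            + "; ".join(list(errors.values())[:3])
        )
        err.partial = fits  # type: ignore[attr-defined]
        raise err
    white = whiteness_report({s: f.residuals for s, f in fits.items()})
    return ResidualModelSet(fits=fits, whiteness=white, settings=settings)
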