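"""Residual diagnostics: autocorrelation functions, white-noise bands, trend screens.

The 95% white-noise band for an ACF estimated from n points is +-1.96/sqrt(n);
lags whose estimated autocorrelation falls outside it are flagged significant.
A residual panel "passes" when no subject has more than a small fraction of
significant lags — the operational version of "the correlogram is flat".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.tsa import stattools

from .errors import DegenerateSeriesError, SeriesLengthError

WHITENESS_THRESHOLD = 0.10  # max fraction of significant lags for a pass


def default_max_lag(n: int) -> int:
    """Common correlogram depth: min(10*log10(n), n-1), rounded."""
    return int(min(round(10 * np.log10(n)), n - 1))


@dataclass
class ACFResult:
    """Estimated autocorrelation function with its white-noise band."""

    lags: np.ndarray  # 0..L
    values: np.ndarray  # acf per lag; values[0] == 1
    n: int
    band: float  # 1.96 / sqrt(n)

    @property
    def significant_lags(self) -> set[int]:
        """Lags (excluding 0) outside the 95% band."""
        out = np.flatnonzero(np.abs(self.values) > self.band)
        return {int(k) for k in out if k != 0}

    @property
    def significant_fraction(self) -> float:
        """Fraction of tested lags (1..L) that are significant."""
        n_tested = len(self.lags) - 1
        return len(self.significant_lags) / n_tested if n_tested else 0.0

    def to_frame(self) -> pd.DataFrame:
        sig = self.significant_lags
        return pd.DataFrame(
            {
                "lag": self.lags,
                "acf": self.values,
                "band": self.band,
                "significant": [int(k) in sig for k in self.lags],
            }
        )


def acf(series, max_lag: int | None = None) -> ACFResult:
    """Sample ACF with the standard biased (1/n) denominator.

    rho(k) = sum_{t=1}^{n-k} (y_t - ybar)(y_{t+k} - ybar) / sum (y_t - ybar)^2.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    if n < 3:
        raise SeriesLengthError(f"need >= 3 points for an ACF, got {n}")
    if np.ptp(y) == 0 or np.allclose(y, y[0], rtol=0, atol=1e-300):
        raise DegenerateSeriesError("constant series has no autocorrelation")
    if max_lag is None:
        max_lag = default_max_lag(n)
    if not 0 < max_lag < n:
        raise SeriesLengthError(f"max_lag must be in 1..{n - 1}, got {max_lag}")
    vals = stattools.acf(y, nlags=max_lag, adjusted=False, fft=True)
    return ACFResult(
        lags=np.arange(max_lag + 1),
        values=np.asarray(vals, dtype=float),
        n=n,
        band=1.96 / np.sqrt(n),
    )


@dataclass
class WhitenessReport:
    """Per-subject ACF diagnostics plus an overall verdict."""

    acfs: dict[str, ACFResult]
    fractions: pd.Series  # significant-lag fraction per subject
    threshold: float
    max_lag: int

    @property
    def subject_pass(self) -> pd.Series:
        return self.fractions <= self.threshold

    @property
    def overall_pass(self) -> bool:
        return bool(self.subject_pass.all())

    @property
    def mean_fraction(self) -> float:
        """Significant-lag fraction pooled (averaged) over subjects."""
        return float(self.fractions.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "significant_fraction": self.fractions,
                "passes": self.subject_pass,
            }
        )


def whiteness_report(
    residuals_by_subject: dict[str, np.ndarray],
    max_lag: int | None = None,
    threshold: float = WHITENESS_THRESHOLD,
) -> WhitenessReport:
    """ACF every subject's residual series and compare against the 95% band."""
    if not residuals_by_subject:
        raise DegenerateSeriesError("no residual series supplied")
    acfs: dict[str, ACFResult] = {}
    fracs = {}
    resolved_lag = None
    for subj, series in residuals_by_subject.items():
        res = acf(series, max_lag)
        acfs[str(subj)] = res
        fracs[str(subj)] = res.significant_fraction
        resolved_lag = len(res.lags) - 1
    return WhitenessReport(
        acfs=acfs,
        fractions=pd.Series(fracs, name="significant_fraction"),
        threshold=threshold,
        max_lag=int(resolved_lag),
    )


def trend_flag(series, alpha: float = 0.05) -> tuple[bool, float, float]:
    """KPSS level-stationarity screen: returns (trend_present, stat, p).

    Rejecting level stationarity at ``alpha`` is read as "a trend (or other
    nonstationarity) remains".  KPSS p-values are table-interpolated and
    clipped to [0.01, 0.10].
    """
    y = np.asarray(series, dtype=float)
    if len(y) < 10:
        raise SeriesLengthError(f"need >= 10 points for a trend screen, got {len(y)}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, pvalue, *_ = stattools.kpss(y, regression="c", nlags="auto")
    return bool(pvalue < alpha), float(stat), float(pvalue)
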