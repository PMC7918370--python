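"""Linear mixed model for the common trend of a panel of time series.

The population trend is quadratic in the time index with dummy-coded group
offsets; each subject additionally gets a random intercept, slope and
curvature drawn from an unstructured 3x3 covariance:

    y_ij = b0 + b1*t + b2*t^2 + sum_g b_g * 1[group(j)=g]
           + u0_j + u1_j*t + u2_j*t^2 + eps_ij

Estimation is maximum likelihood by default so candidate mean structures
(e.g. quadratic vs cubic) are comparable by AIC; REML is available behind a
flag.  Fitting is delegated to :class:`statsmodels.regression.mixed_linear_model.MixedLM`.

The time covariates are internally rescaled (t/T, (t/T)^2) before
optimization — on the raw index scale (t up to 121, t^2 up to ~1.5e4) the
likelihood surface is so badly conditioned that gradient optimizers stall —
and all estimates, standard errors, covariances and BLUPs are transformed
back to the index scale exactly (the rescaling is a linear reparametrization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ComparabilityError, ConfigurationError, FitError
from .panel import Panel

RANDOM_TERMS = ("intercept", "time", "time2")


@dataclass(frozen=True)
class LMMSpec:
    """Mean/covariance structure of the trend model.

    ``include_cubic`` adds a fixed Time^3 term (an alternative mean structure
    that AIC comparison can reject); the random part is always the
    (intercept, time, time2) triple with unstructured covariance unless
    ``random_terms`` trims it.
    """

    estimation: str = "ML"  # "ML" or "REML"
    include_cubic: bool = False
    random_terms: tuple[str, ...] = RANDOM_TERMS
    maxiter: int = 500

    def __post_init__(self) -> None:
        if self.estimation not in ("ML", "REML"):
            raise ConfigurationError("estimation must be 'ML' or 'REML'")
        bad = set(self.random_terms) - set(RANDOM_TERMS)
        if bad:
            raise ConfigurationError(f"unknown random terms: {sorted(bad)}")


@dataclass
class Design:
    """Design matrices on the raw index scale."""

    X: pd.DataFrame  # fixed: const, time, time2 [, time3], dummies
    Z: pd.DataFrame  # random: subset of const, time, time2
    y: pd.Series
    groups: pd.Series  # subject id per row
    fixed_names: list[str]
    random_names: list[str]


@dataclass
class LMMFit:
    """Fitted trend model.

    All quantities are on the time-index scale.  ``fixed`` has one row per
    fixed coefficient (estimate, se, z, p); ``random_cov`` is the estimated
    covariance of the subject random effects; ``blups`` one row per subject.
    """

    spec: LMMSpec
    fixed: pd.DataFrame
    random_cov: pd.DataFrame
    random_sd: pd.Series
    random_corr: pd.DataFrame
    blups: pd.DataFrame  # index: subject; columns: random terms
    sigma2: float
    loglik: float
    aic: float
    bic: float
    n_obs: int
    n_subjects: int
    k_params: int
    fitted: pd.Series  # fixed + random prediction per observation
    residuals: pd.Series  # observed - fitted
    data: pd.DataFrame  # panel rows the fit aligns to
    converged: bool
    ridged: bool = False  # singular covariance fallback applied

    @property
    def fixed_estimates(self) -> pd.Series:
        return self.fixed["estimate"]

    def residual_series(self) -> dict[str, np.ndarray]:
        """Per-subject residual series ordered by time index."""
        out: dict[str, np.ndarray] = {}
        frame = self.data.assign(resid=self.residuals.to_numpy())
        for subj, sub in frame.groupby("subject", sort=True):
            out[str(subj)] = sub.sort_values("time")["resid"].to_numpy()
        return out

    def summary_frame(self) -> pd.DataFrame:
        """Fixed-effect block in a publication-style layout."""
        out = self.fixed.copy()
        out.index.name = "coefficient"
        return out


def build_design(panel: Panel, spec: LMMSpec | None = None) -> Design:
    """Construct fixed (X) and random (Z) design matrices and the response.

    X columns: intercept, time, time^2 [, time^3], then one dummy per
    non-reference group in sorted label order; the reference group is the
    all-zero row.  Z columns: intercept, time, time^2 (per ``spec``).
    """
    spec = spec or LMMSpec()
    df = panel.data
    if panel.reference_group not in set(df["group"]):
        raise ConfigurationError(
            f"reference group {panel.reference_group!r} absent from panel"
        )
    t = df["time"].astype(float)
    X = pd.DataFrame({"const": 1.0, "time": t, "time2": t**2})
    if spec.include_cubic:
        X["time3"] = t**3
    for g in panel.groups[1:]:
        X[f"group[{g}]"] = (df["group"] == g).astype(float)
    zcols = {"intercept": np.ones(len(df)), "time": t.to_numpy(), "time2": (t**2).to_numpy()}
    Z = pd.DataFrame({name: zcols[name] for name in spec.random_terms})
    return Design(
        X=X,
        Z=Z,
        y=df["value"].astype(float),
        groups=df["subject"],
        fixed_names=list(X.columns),
        random_names=list(Z.columns),
    )


def _time_scale_vector(names: list[str], T: float) -> np.ndarray:
    """Per-column divisor used to rescale time covariates to O(1)."""
    power = {"const": 0, "intercept": 0, "time": 1, "time2": 2, "time3": 3}
    return np.array([T ** power.get(n, 0) for n in names])


def fit_lmm(design: Design, spec: LMMSpec | None = None, panel: Panel | None = None) -> LMMFit:
    """Fit the mixed model by ML (default) or REML.

    AIC/BIC count k = (#fixed) + (#free covariance parameters) + 1 for the
    residual variance; e.g. 5 + 6 + 1 = 12 for the three-group quadratic
    model with a full 3x3 random covariance.
    """
    spec = spec or LMMSpec()
    X, Z, y = design.X, design.Z, design.y
    if len(y) <= X.shape[1]:
        raise FitError("fewer observations than fixed parameters")

    T = float(np.max(X["time"])) if "time" in X else 1.0
    sx = _time_scale_vector(design.fixed_names, T)
    sz = _time_scale_vector(design.random_names, T)
    Xs = X / sx
    Zs = Z / sz

    model = sm.MixedLM(
        endog=np.asarray(y, dtype=float),
        exog=np.asarray(Xs, dtype=float),
        groups=np.asarray(design.groups.astype(str)),
        exog_re=np.asarray(Zs, dtype=float),
    )
    reml = spec.estimation == "REML"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=reml, maxiter=spec.maxiter, method=["lbfgs", "bfgs", "cg"])
            if not res.converged:
                # boundary-adjacent optima often stall lbfgs; restart other
                # optimizers from the stalled parameters before giving up
                stalled = res.params
                for retry_method in ("bfgs", "cg", "powell"):
                    cand = model.fit(
                        reml=reml,
                        maxiter=max(2000, spec.maxiter),
                        method=retry_method,
                        start_params=stalled,
                    )
                    if retry_method == "powell" and not cand.converged:
                        # powell ignores gradients; polish with lbfgs
                        cand = model.fit(
                            reml=reml, maxiter=2000, method="lbfgs",
                            start_params=cand.params,
                        )
                    if cand.converged:
                        res = cand
                        break
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
            raise FitError(f"mixed-model optimization failed: {exc}") from exc
    if not res.converged:
        raise FitError(
            f"mixed-model optimizer did not converge after retries "
            f"(k={len(res.params)} parameters, n={len(y)} observations)"
        )

    ridged = False
    cov_re_s = np.asarray(res.cov_re, dtype=float)
    eig = np.linalg.eigvalsh(cov_re_s)
    if eig.min() < -1e-10 * max(eig.max(), 1e-30):
        # near-singular boundary optimum: nudge to PSD, record it
        cov_re_s = cov_re_s + (1e-12 - eig.min()) * np.eye(cov_re_s.shape[0])
        ridged = True

    q = len(design.random_names)
    k_fixed = len(design.fixed_names)
    k = k_fixed + q * (q + 1) // 2 + 1
    llf = float(res.llf)
    n = len(y)
    aic = -2 * llf + 2 * k
    bic = -2 * llf + np.log(n) * k

    # back-transform to the index scale
    fe = np.asarray(res.fe_params, dtype=float)[:k_fixed] / sx
    with warnings.catch_warnings():
        # boundary optima can give a non-PD Hessian -> NaN standard errors
        warnings.simplefilter("ignore")
        se = np.asarray(res.bse_fe, dtype=float)[:k_fixed] / sx
    zval = np.divide(fe, se, out=np.full_like(fe, np.nan), where=se > 0)
    pval = 2 * stats.norm.sf(np.abs(zval))
    fixed = pd.DataFrame(
        {"estimate": fe, "se": se, "z": zval, "p": pval}, index=design.fixed_names
    )

    Dz = np.diag(1.0 / sz)
    cov_re = Dz @ cov_re_s @ Dz
    sd = np.sqrt(np.clip(np.diag(cov_re), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov_re / np.outer(sd, sd)
    random_cov = pd.DataFrame(cov_re, index=design.random_names, columns=design.random_names)
    random_corr = pd.DataFrame(corr, index=design.random_names, columns=design.random_names)
    random_sd = pd.Series(sd, index=design.random_names)

    re = res.random_effects
    order = sorted(re.keys())
    blups = pd.DataFrame(
        np.vstack([np.asarray(re[kk], dtype=float) / sz for kk in order]),
        index=pd.Index(order, name="subject"),
        columns=design.random_names,
    )

    fitted = np.asarray(res.fittedvalues, dtype=float)
    resid = np.asarray(y, dtype=float) - fitted

    if panel is not None:
        frame = panel.data
    else:
        frame = pd.DataFrame({"subject": design.groups.astype(str).to_numpy(),
                              "time": np.asarray(X["time"], dtype=int),
                              "value": np.asarray(y, dtype=float)})
        frame["group"] = ""

    return LMMFit(
        spec=spec,
        fixed=fixed,
        random_cov=random_cov,
        random_sd=random_sd,
        random_corr=random_corr,
        blups=blups,
        sigma2=float(res.scale),
        loglik=llf,
        aic=float(aic),
        bic=float(bic),
        n_obs=n,
        n_subjects=len(order),
        k_params=k,
        fitted=pd.Series(fitted, index=frame.index),
        residuals=pd.Series(resid, index=frame.index),
        data=frame.reset_index(drop=True),
        converged=bool(res.converged),
        ridged=ridged,
    )


def fit_trend(panel: Panel, spec: LMMSpec | None = None) -> LMMFit:
    """Convenience wrapper: build the design from a panel and fit."""
    spec = spec or LMMSpec()
    return fit_lmm(build_design(panel, spec), spec, panel=panel)


def compare_by_aic(fits: list[LMMFit]) -> tuple[LMMFit, pd.DataFrame]:
    """Pick the fit with minimal AIC; ties go to the fewer-parameter model.

    All fits must be ML fits on the same response: AIC is meaningless for
    REML fits, and comparisons across different data are not comparisons.
    """
    if not fits:
        raise ComparabilityError("no fits to compare")
    if any(f.spec.estimation != "ML" for f in fits):
        raise ComparabilityError("AIC comparison requires ML fits (not REML)")
    if len(fits) > 1:
        y0 = fits[0].data["value"].to_numpy()
        for f in fits[1:]:
            yk = f.data["value"].to_numpy()
            if len(yk) != len(y0) or not np.allclose(np.sort(yk), np.sort(y0)):
                raise ComparabilityError("fits are not on identical response data")
    ranking = pd.DataFrame(
        {
            "aic": [f.aic for f in fits],
            "k": [f.k_params for f in fits],
            "loglik": [f.loglik for f in fits],
        }
    ).sort_values(["aic", "k"], kind="mergesort")
    best = fits[int(ranking.index[0])]
    return best, ranking
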