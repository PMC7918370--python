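"""Synthetic panels with the exact structure the two-stage pipeline assumes.

Each subject j in group g gets

    y_jt = b0 + b1*t + b2*t^2 + offset_g
           + u0_j + u1_j*t + u2_j*t^2 + delta_g(t) + e_jt

with (u0, u1, u2) ~ MVN(0, random_cov) (unstructured covariance), e_jt IID,
AR(1) or ARMA(1,1) noise generated independently per subject, and
delta_g(t) an optional localized offset on a minute window (the known
"difference window" the inference stage should recover).

Defaults mirror the chlorophyll de-etiolation study design this pipeline
was built around: 3 groups x 3 experiments x 3 replicas (27 subjects),
121 timepoints at 2-minute intervals, quadratic trend coefficients and
random-effect covariance at the scale of that study's fitted model, and
AR(1) residual noise (phi = 0.8) whose stationary SD matches the fitted
residual SD (~0.036).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .panel import Panel, TimeAxis, scale_to_baseline

#: random-effect SDs (intercept, slope, curvature) at the reference study's scale
DEFAULT_RANDOM_SD = (0.0625, 4.385e-3, 2.937e-5)
#: correlations (u0,u1), (u0,u2), (u1,u2)
DEFAULT_RANDOM_CORR = (-0.65, 0.58, -0.97)


def default_random_cov() -> np.ndarray:
    sd = np.asarray(DEFAULT_RANDOM_SD)
    r01, r02, r12 = DEFAULT_RANDOM_CORR
    corr = np.array([[1.0, r01, r02], [r01, 1.0, r12], [r02, r12, 1.0]])
    return np.outer(sd, sd) * corr


@dataclass(frozen=True)
class NoiseSpec:
    """Within-subject noise: iid, ar1 (phi) or arma (phi, theta).

    ``sd`` is the innovation SD.  The default AR(1) with phi = 0.8 and
    innovation SD 0.0218 has stationary SD 0.0218/sqrt(1-0.64) ~ 0.036.
    """

    kind: str = "ar1"  # iid | ar1 | arma
    phi: float = 0.8
    theta: float = 0.0
    sd: float = 0.0218

    def __post_init__(self) -> None:
        if self.kind not in ("iid", "ar1", "arma"):
            raise ConfigurationError(f"unknown noise kind {self.kind!r}")
        if self.kind in ("ar1", "arma") and abs(self.phi) >= 1:
            raise ConfigurationError("AR coefficient must satisfy |phi| < 1")
        if self.sd < 0:
            raise ConfigurationError("innovation SD must be >= 0")


@dataclass(frozen=True)
class LocalizedEffect:
    """Extra mean offset for one group on a closed minute window."""

    group: str
    start_minutes: float
    end_minutes: float
    magnitude: float


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic study."""

    n_groups: int = 3
    n_experiments: int = 3
    replicas_per_experiment: int = 3
    n_timepoints: int = 121
    interval_minutes: float = 2.0
    fixed_effects: tuple[float, float, float] = (0.09175, 0.04297, -1.961e-4)
    group_offsets: tuple[float, ...] | None = (0.0, -0.1914, 0.1083)
    random_cov: np.ndarray = field(default_factory=default_random_cov)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    localized_effect: LocalizedEffect | None = None
    scale_baseline: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 10:
            raise ConfigurationError("n_timepoints must be >= 10")
        cov = np.asarray(self.random_cov, dtype=float)
        if cov.shape != (3, 3):
            raise ConfigurationError("random_cov must be 3x3")
        if not np.allclose(cov, cov.T):
            raise ConfigurationError("random_cov must be symmetric")
        if np.any(np.diag(cov) > 0) and np.linalg.eigvalsh(cov).min() < -1e-12:
            raise ConfigurationError("random_cov must be positive semi-definite")
        offs = self.group_offsets
        if offs is not None and len(offs) != self.n_groups:
            raise ConfigurationError(
                f"group_offsets has {len(offs)} entries for {self.n_groups} groups"
            )

    @property
    def group_labels(self) -> list[str]:
        return [f"G{i + 1}" for i in range(self.n_groups)]

    @property
    def n_subjects(self) -> int:
        return self.n_groups * self.n_experiments * self.replicas_per_experiment

    @property
    def offsets(self) -> np.ndarray:
        if self.group_offsets is None:
            return np.zeros(self.n_groups)
        return np.asarray(self.group_offsets, dtype=float)


@dataclass
class GroundTruth:
    """Everything the generator drew, for recovery checks."""

    config: SimConfig
    group_curves: pd.DataFrame  # index: time 1..T; columns: group labels (pre-scaling)
    scaled_group_curves: pd.DataFrame | None  # mean of scaled series per group
    random_effects: pd.DataFrame  # index: subject; columns: u0, u1, u2
    effect_indices: dict[str, np.ndarray]  # group -> indices with localized offset


def _simulate_noise(rng: np.random.Generator, spec: NoiseSpec, n: int) -> np.ndarray:
    if spec.sd == 0:
        return np.zeros(n)
    if spec.kind == "iid":
        return rng.normal(0.0, spec.sd, n)
    burn = 200
    innov = rng.normal(0.0, spec.sd, n + burn)
    if spec.kind == "arma":
        x = np.empty(n + burn)
        x[0] = innov[0]
        for t in range(1, n + burn):
            x[t] = spec.phi * x[t - 1] + innov[t] + spec.theta * innov[t - 1]
    else:  # ar1, stationary start
        x = np.empty(n + burn)
        x[0] = innov[0] / np.sqrt(1 - spec.phi**2)
        for t in range(1, n + burn):
            x[t] = spec.phi * x[t - 1] + innov[t]
    return x[burn:]


def generate_panel(config: SimConfig) -> tuple[Panel, GroundTruth]:
    """Draw one panel plus its ground truth; identical seed, identical panel."""
    rng = np.random.default_rng(config.seed)
    T = config.n_timepoints
    t = np.arange(1, T + 1, dtype=float)
    minutes = config.interval_minutes * (t - 1)
    b0, b1, b2 = config.fixed_effects
    base_curve = b0 + b1 * t + b2 * t**2

    effect_indices: dict[str, np.ndarray] = {}
    deltas: dict[str, np.ndarray] = {}
    for g in config.group_labels:
        delta = np.zeros(T)
        if config.localized_effect is not None and config.localized_effect.group == g:
            eff = config.localized_effect
            mask = (minutes >= eff.start_minutes) & (minutes <= eff.end_minutes)
            delta[mask] = eff.magnitude
            effect_indices[g] = np.flatnonzero(mask) + 1  # 1-based indices
        deltas[g] = delta

    curves = {
        g: base_curve + off + deltas[g]
        for g, off in zip(config.group_labels, config.offsets)
    }

    rows = []
    u_rows = {}
    cov = np.asarray(config.random_cov, dtype=float)
    for gi, g in enumerate(config.group_labels):
        for exp in range(1, config.n_experiments + 1):
            for rep in range(1, config.replicas_per_experiment + 1):
                subject = f"{g}:r{rep}:e{exp}"
                u = rng.multivariate_normal(np.zeros(3), cov, method="cholesky") \
                    if np.any(np.diag(cov) > 0) else np.zeros(3)
                e = _simulate_noise(rng, config.noise, T)
                y = curves[g] + u[0] + u[1] * t + u[2] * t**2 + e
                u_rows[subject] = u
                rows.append(
                    pd.DataFrame(
                        {
                            "subject": subject,
                            "group": g,
                            "replicate": rep,
                            "experiment": exp,
                            "time": t.astype(int),
                            "value": y,
                        }
                    )
                )
    df = pd.concat(rows, ignore_index=True)
    panel = Panel.from_frame(
        df,
        interval_minutes=config.interval_minutes,
        reference_group=config.group_labels[0],
    )
    scaled_curves = None
    if config.scale_baseline:
        panel = scale_to_baseline(panel)
        scaled_curves = (
            panel.data.groupby(["group", "time"])["value"].mean().unstack("group")
        )
    truth = GroundTruth(
        config=config,
        group_curves=pd.DataFrame(curves, index=pd.Index(t.astype(int), name="time")),
        scaled_group_curves=scaled_curves,
        random_effects=pd.DataFrame.from_dict(
            u_rows, orient="index", columns=["u0", "u1", "u2"]
        ).rename_axis("subject"),
        effect_indices=effect_indices,
    )
    return panel, truth


def true_difference_set(
    truth: GroundTruth, pair: tuple[str, str], tol: float = 0.0
) -> set[int]:
    """Time indices where the pair's true (pre-scaling) mean curves differ."""
    curves = truth.group_curves
    for g in pair:
        if g not in curves.columns:
            raise KeyError(f"unknown group {g!r}")
    diff = (curves[pair[0]] - curves[pair[1]]).abs()
    return {int(i) for i in diff.index[diff > tol]}


@dataclass
class OperatingCharacteristics:
    """Per-replicate and aggregate pipeline performance on known truth."""

    rejections: pd.DataFrame  # rep, mode, pair, rates & window endpoints
    estimates: pd.DataFrame  # rep, term, estimate, truth

    def summary(self) -> pd.DataFrame:
        agg = (
            self.rejections.groupby(["mode", "pair"])
            .agg(
                type1_rate=("null_reject_rate", "mean"),
                power=("true_reject_rate", "mean"),
            )
            .reset_index()
        )
        return agg

    def estimate_summary(self) -> pd.DataFrame:
        g = self.estimates.groupby("term")
        out = g.agg(
            mean_estimate=("estimate", "mean"),
            sd_estimate=("estimate", "std"),
            truth=("truth", "first"),
            n=("estimate", "size"),
        )
        out["bias"] = out["mean_estimate"] - out["truth"]
        out["mc_se"] = out["sd_estimate"] / np.sqrt(out["n"])
        out["rmse"] = np.sqrt(
            ((self.estimates["estimate"] - self.estimates["truth"]) ** 2)
            .groupby(self.estimates["term"])
            .mean()
        )
        return out


def run_operating_characteristics(
    config: SimConfig,
    n_reps: int,
    *,
    alpha: float = 0.05,
    arima_settings=None,
    modes: tuple[str, ...] = ("corrected", "naive"),
) -> OperatingCharacteristics:
    """Repeat generate -> pipeline -> score against truth.

    Each replicate uses seed ``config.seed + rep`` so the study is
    reproducible rep by rep.  Scores per (mode, pair): rejection rate at
    truly-null timepoints, rejection rate at truly-different timepoints,
    and the endpoints of the detected window best overlapping the true one.
    Fixed-effect estimates are recorded once per replicate.
    """
    from .arima import ARIMASettings
    from .inference import combine, fit_all_residuals, pairwise_windows
    from .lmm import fit_trend

    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    arima_settings = arima_settings or ARIMASettings()
    rej_rows, est_rows = [], []
    b_truth = dict(
        zip(
            ["const", "time", "time2"]
            + [f"group[{g}]" for g in config.group_labels[1:]],
            list(config.fixed_effects) + list(config.offsets[1:]),
        )
    )
    for rep in range(n_reps):
        cfg = replace(config, seed=int(config.seed) + rep)
        panel, truth = generate_panel(cfg)
        lmm_fit = fit_trend(panel)
        for term, est in lmm_fit.fixed["estimate"].items():
            est_rows.append(
                {
                    "rep": rep,
                    "term": term,
                    "estimate": float(est),
                    "truth": b_truth.get(term, np.nan),
                }
            )
        residual_models = (
            fit_all_residuals(lmm_fit, arima_settings) if "corrected" in modes else None
        )
        for mode in modes:
            report = pairwise_windows(
                combine(
                    lmm_fit, residual_models if mode == "corrected" else None, mode
                ),
                alpha,
            )
            for (ga, gb), sub in report.results.groupby(["group_a", "group_b"]):
                true_idx = true_difference_set(truth, (ga, gb))
                is_true = sub["time"].isin(true_idx)
                n_null = int((~is_true).sum())
                n_true = int(is_true.sum())
                row = {
                    "rep": rep,
                    "mode": mode,
                    "pair": f"{ga}-{gb}",
                    "n_null": n_null,
                    "n_true": n_true,
                    "null_reject_rate": float(sub.loc[~is_true, "significant"].mean())
                    if n_null
                    else np.nan,
                    "true_reject_rate": float(sub.loc[is_true, "significant"].mean())
                    if n_true
                    else np.nan,
                    "window_start_minutes": np.nan,
                    "window_end_minutes": np.nan,
                }
                if n_true:
                    best = _best_overlap_window(report, (ga, gb), true_idx)
                    if best is not None:
                        row["window_start_minutes"] = best.start_minutes
                        row["window_end_minutes"] = best.end_minutes
                rej_rows.append(row)
    return OperatingCharacteristics(
        rejections=pd.DataFrame(rej_rows), estimates=pd.DataFrame(est_rows)
    )


def _best_overlap_window(report, pair, true_idx: set[int]):
    """Detected window with maximal overlap with the true index set."""
    best, best_ov = None, 0
    for w in report.windows_for(pair):
        ov = len(true_idx & set(range(w.start_index, w.end_index + 1)))
        if ov > best_ov:
            best, best_ov = w, ov
    return best
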