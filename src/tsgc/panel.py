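"""Panels of grouped time series: reading, validation and baseline scaling.

A *panel* is a long-format collection of time series measured on a common,
complete grid of integer time indices 1..T.  Each series belongs to one
subject (e.g. one seedling), each subject to one group (e.g. genotype), and
carries replicate / experiment bookkeeping.  The time index is the modelling
variable; conversion to minutes is a reporting convention owned by
:class:`TimeAxis` (index 1 is 0 min, index 2 is ``interval`` min, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    DegenerateBaselineError,
    IntegrityError,
    ParseError,
    SchemaError,
)

#: canonical column order of the in-memory panel frame
PANEL_COLUMNS = ["subject", "group", "replicate", "experiment", "time", "value"]

#: default CSV header -> canonical name mapping (identity)
DEFAULT_SCHEMA = {c: c for c in PANEL_COLUMNS}


@dataclass(frozen=True)
class TimeAxis:
    """Grid of T equally spaced timepoints, index 1..T.

    minutes(i) = interval * (i - 1), so the first timepoint is minute 0.
    """

    n_timepoints: int
    interval_minutes: float = 2.0

    def __post_init__(self) -> None:
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")
        if self.interval_minutes <= 0:
            raise ValueError("interval_minutes must be positive")

    def minutes_of(self, index: int) -> float:
        if not 1 <= index <= self.n_timepoints:
            raise IndexError(
                f"time index {index} outside grid 1..{self.n_timepoints}"
            )
        return self.interval_minutes * (index - 1)

    def minutes(self) -> np.ndarray:
        """Minutes for every index on the grid, in order."""
        return self.interval_minutes * (np.arange(self.n_timepoints))


def minutes_of(index: int, axis: TimeAxis) -> float:
    """Minutes elapsed at ``index`` (1-based) on ``axis``."""
    return axis.minutes_of(index)


@dataclass
class Panel:
    """Validated long-format panel of time series.

    ``data`` holds one row per (subject, time) with canonical columns
    ``subject, group, replicate, experiment, time, value``, sorted by
    (subject, time).  Construct via :meth:`from_frame` or :func:`read_panel`
    so the invariants (complete grid, unique keys, >= 2 groups when asked)
    are checked.
    """

    data: pd.DataFrame
    axis: TimeAxis
    reference_group: str
    scaled: bool = False
    log_transformed: bool = False

    # -- construction -----------------------------------------------------
    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        *,
        interval_minutes: float = 2.0,
        reference_group: str | None = None,
        scaled: bool = False,
        require_groups: int = 1,
    ) -> "Panel":
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"panel frame missing columns: {missing}")
        df = df.loc[:, PANEL_COLUMNS].copy()
        try:
            df["time"] = pd.to_numeric(df["time"], errors="raise")
            df["value"] = pd.to_numeric(df["value"], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ParseError(f"non-numeric time/value cell: {exc}") from exc
        if df["value"].isna().any():
            bad = df.index[df["value"].isna()][:5].tolist()
            raise ParseError(f"missing/non-numeric value in rows {bad}")
        if not np.allclose(df["time"] % 1, 0):
            raise ParseError("time indices must be integers")
        df["time"] = df["time"].astype(int)
        df["subject"] = df["subject"].astype(str)
        df["group"] = df["group"].astype(str)

        dup = df.duplicated(subset=["subject", "time"])
        if dup.any():
            pairs = df.loc[dup, ["subject", "time"]].head(5).to_records(index=False)
            raise IntegrityError(f"duplicate (subject, time) pairs: {list(pairs)}")

        tmin, tmax = int(df["time"].min()), int(df["time"].max())
        if tmin != 1:
            raise IntegrityError(f"time indices must start at 1 (found {tmin})")
        full = set(range(1, tmax + 1))
        for subj, sub in df.groupby("subject", sort=False):
            have = set(sub["time"])
            gaps = sorted(full - have)
            if gaps:
                raise IntegrityError(
                    f"subject {subj!r} missing time indices {gaps[:10]}"
                    f"{'...' if len(gaps) > 10 else ''} (grid is 1..{tmax})"
                )

        groups = sorted(df["group"].unique())
        if len(groups) < require_groups:
            raise IntegrityError(
                f"panel has {len(groups)} group(s); {require_groups} required"
            )
        if reference_group is None:
            reference_group = groups[0]
        elif reference_group not in groups:
            raise IntegrityError(
                f"reference group {reference_group!r} not among groups {groups}"
            )

        df = df.sort_values(["subject", "time"], kind="mergesort").reset_index(
            drop=True
        )
        axis = TimeAxis(n_timepoints=tmax, interval_minutes=interval_minutes)
        panel = cls(
            data=df, axis=axis, reference_group=str(reference_group), scaled=scaled
        )
        if scaled:
            firsts = df.loc[df["time"] == 1, "value"].to_numpy()
            if not np.allclose(firsts, 1.0, atol=1e-12):
                raise IntegrityError(
                    "panel flagged as scaled but some series do not start at 1"
                )
        return panel

    # -- views ------------------------------------------------------------
    @property
    def subjects(self) -> list[str]:
        return sorted(self.data["subject"].unique())

    @property
    def groups(self) -> list[str]:
        """Group labels with the reference first, rest sorted."""
        labels = sorted(self.data["group"].unique())
        labels.remove(self.reference_group)
        return [self.reference_group] + labels

    @property
    def n_subjects(self) -> int:
        return self.data["subject"].nunique()

    @property
    def n_observations(self) -> int:
        return len(self.data)

    def group_of(self) -> pd.Series:
        """Group label per subject (index: subject id)."""
        return self.data.groupby("subject")["group"].first()

    def series(self, subject: str) -> np.ndarray:
        """One subject's values ordered by time index."""
        sub = self.data[self.data["subject"] == subject]
        if sub.empty:
            raise KeyError(f"unknown subject {subject!r}")
        return sub.sort_values("time")["value"].to_numpy()


def read_panel(
    path,
    schema: dict[str, str] | None = None,
    *,
    interval_minutes: float = 2.0,
    reference_group: str | None = None,
    scaled: bool = False,
) -> Panel:
    """Read a long-format CSV into a validated :class:`Panel`.

    ``schema`` maps canonical names (``subject``, ``group``, ``replicate``,
    ``experiment``, ``time``, ``value``) to the CSV's column names; omitted
    entries default to the canonical name itself.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path)
    missing = [src for src in schema.values() if src not in df.columns]
    if missing:
        raise SchemaError(
            f"CSV {path} missing columns {missing}; present: {list(df.columns)}"
        )
    df = df.rename(columns={src: dst for dst, src in schema.items()})
    return Panel.from_frame(
        df,
        interval_minutes=interval_minutes,
        reference_group=reference_group,
        scaled=scaled,
    )


def write_panel(panel: Panel, path) -> None:
    """Write a panel in the canonical CSV dialect (full float precision)."""
    panel.data.to_csv(path, index=False, float_format="%.17g")


def scale_to_baseline(panel: Panel) -> Panel:
    """Divide every series by its own first value so each starts at 1.

    Idempotent: a panel already flagged ``scaled`` is returned unchanged.
    """
    if panel.scaled:
        return panel
    df = panel.data
    firsts = df.loc[df["time"] == 1].set_index("subject")["value"]
    bad = firsts[firsts <= 0]
    if not bad.empty:
        raise DegenerateBaselineError(
            f"zero/negative baseline for subject(s): {list(bad.index)}"
        )
    out = df.copy()
    out["value"] = out["value"] / firsts.loc[out["subject"]].to_numpy()
    return replace(panel, data=out, scaled=True)


def log_transform(panel: Panel) -> Panel:
    """Natural-log transform of all values (optional; requires positivity)."""
    if panel.log_transformed:
        return panel
    if (panel.data["value"] <= 0).any():
        raise DegenerateBaselineError("log transform requires positive values")
    out = panel.data.copy()
    out["value"] = np.log(out["value"])
    return replace(panel, data=out, log_transformed=True, scaled=False)
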