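"""Cytokine panel I/O and the preprocessing chain.

A panel holds plasma concentrations (pg/ml) of the 16-cytokine exercise
panel for each subject at 8 labelled blood draws (T0 rest, T0+3 early
exercise, T1 peak effort, then T1+10/20/30/60 and T2 at 4 h).  The time
axis is anchored at peak effort: ``minutes_from_T1`` = 0 at T1, negative
before.  Preprocessing follows the study chain: non-detect replacement by
the cohort-wide minimum detected level per cytokine, piecewise-linear
interpolation to a uniform ~3-min grid, normalisation to fold change
relative to the healthy-control resting (T0) geometric mean, and slicing
to the 4-h recovery window [0, 240] min.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CYTOKINES: tuple[str, ...] = (
    "IL-1a", "IL-1b", "IL-2", "IL-4", "IL-5", "IL-6", "IL-8", "IL-10",
    "IL-12", "IL-13", "IL-15", "IL-17", "IL-23", "IFNg", "TNFa", "TNFb",
)

TIMEPOINT_LABELS: tuple[str, ...] = (
    "T0", "T0+3", "T1", "T1+10", "T1+20", "T1+30", "T1+60", "T2",
)

#: Nominal minutes from peak effort for each label (T0 ~12 min before peak
#: under the default synthetic protocol; real panels carry their own minutes).
NOMINAL_MINUTES: dict[str, float] = {
    "T0": -12.0, "T0+3": -9.0, "T1": 0.0, "T1+10": 10.0,
    "T1+20": 20.0, "T1+30": 30.0, "T1+60": 60.0, "T2": 240.0,
}

GROUPS = ("HC", "GWI")

PANEL_COLUMNS = (
    "subject_id", "group", "cytokine", "timepoint_label",
    "minutes_from_T1", "concentration",
)

RECOVERY_WINDOW = (0.0, 240.0)


class PanelSchemaError(ValueError):
    """Header/enum violation in a panel file."""


class PanelValidationError(ValueError):
    """Record-level violation (duplicates, negative values, ...)."""


@dataclass
class CytokinePanel:
    """Long-format cytokine concentration records plus a units flag."""

    data: pd.DataFrame
    units: str = "pg_ml"  # or "fold_change"

    def __post_init__(self) -> None:
        validate_panel(self)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.data["subject_id"].unique())

    def subjects_in(self, group: str) -> list[str]:
        mask = self.data["group"] == group
        return sorted(self.data.loc[mask, "subject_id"].unique())

    def group_of(self, subject_id: str) -> str:
        rows = self.data[self.data["subject_id"] == subject_id]
        return rows["group"].iloc[0]

    def exclude_subjects(self, subject_ids: Iterable[str]) -> "CytokinePanel":
        """Drop listed subjects (explicit outlier exclusion)."""
        drop = set(subject_ids)
        kept = self.data[~self.data["subject_id"].isin(drop)].reset_index(
            drop=True
        )
        return CytokinePanel(kept, units=self.units)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CytokinePanel):
            return NotImplemented
        a = self.data.sort_values(list(PANEL_COLUMNS)).reset_index(drop=True)
        b = other.data.sort_values(list(PANEL_COLUMNS)).reset_index(drop=True)
        return self.units == other.units and a.equals(b)


def validate_panel(panel: CytokinePanel) -> None:
    df = panel.data
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelSchemaError(f"missing column(s): {', '.join(missing)}")
    if panel.units not in ("pg_ml", "fold_change"):
        raise PanelSchemaError(f"unknown units flag {panel.units!r}")
    unknown = set(df["cytokine"]) - set(CYTOKINES)
    if unknown:
        raise PanelSchemaError(f"unknown cytokine name(s): {sorted(unknown)}")
    unknown_groups = set(df["group"]) - set(GROUPS)
    if unknown_groups:
        raise PanelSchemaError(f"unknown group(s): {sorted(unknown_groups)}")
    if len(df):
        neg = df.index[df["concentration"] < 0]
        if len(neg):
            raise PanelValidationError(
                f"negative concentration at record index {neg[0]}"
            )
        if panel.units == "fold_change" and (df["concentration"] <= 0).any():
            raise PanelValidationError(
                "fold-change panels must have strictly positive values"
            )
        dup = df.duplicated(["subject_id", "cytokine", "timepoint_label"])
        if dup.any():
            first = df[dup].iloc[0]
            raise PanelValidationError(
                "duplicate record for "
                f"({first['subject_id']}, {first['cytokine']}, "
                f"{first['timepoint_label']})"
            )
        # minutes strictly increasing within each subject x cytokine series
        for (subj, cyt), grp in df.groupby(["subject_id", "cytokine"]):
            m = grp.sort_values("timepoint_label", key=_label_order)[
                "minutes_from_T1"
            ].to_numpy()
            if np.any(np.diff(np.sort(m)) <= 0):
                raise PanelValidationError(
                    f"non-increasing minutes for ({subj}, {cyt})"
                )


def _label_order(labels: pd.Series) -> pd.Series:
    order = {lab: i for i, lab in enumerate(TIMEPOINT_LABELS)}
    return labels.map(order)


# ---------------------------------------------------------------------------
# I/O

def read_panel(path, dialect: str = "tsv") -> CytokinePanel:
    """Read a panel TSV/CSV written by :func:`write_panel`.

    The file may carry a ``# units=...`` comment header; without one the
    panel is taken to be raw pg/ml.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    units = "pg_ml"
    with open(path, "r", encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            stripped = line[1:].strip()
            if stripped.startswith("units="):
                units = stripped.split("=", 1)[1].strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep=sep)
    df = df.astype(
        {"subject_id": str, "group": str, "cytokine": str,
         "timepoint_label": str}
    ) if len(df) else df
    panel = CytokinePanel(df, units=units)
    logger.info("read %d panel records from %s", len(df), path)
    return panel


def write_panel(panel: CytokinePanel, path) -> str:
    """Write a panel with a ``# units=`` comment header; returns the path."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# units={panel.units}\n")
        panel.data.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    logger.info("wrote %d panel records to %s", len(panel.data), path)
    return str(path)


# ---------------------------------------------------------------------------
# Preprocessing chain

class UnresolvableFloorError(ValueError):
    """A cytokine is zero for every subject, so no detection floor exists."""


def replace_nondetects(panel: CytokinePanel) -> CytokinePanel:
    """Replace zero (below-detection) readings by the cytokine's cohort floor.

    The floor is the minimum strictly positive concentration of that
    cytokine observed across all subjects in both groups.  Idempotent.
    """
    if panel.units != "pg_ml":
        raise ValueError("non-detect replacement applies to pg/ml panels")
    df = panel.data.copy()
    n_replaced = 0
    for cyt, grp in df.groupby("cytokine"):
        vals = grp["concentration"]
        zeros = vals == 0.0
        if not zeros.any():
            continue
        positive = vals[vals > 0.0]
        if positive.empty:
            raise UnresolvableFloorError(
                f"cytokine {cyt} is zero for all subjects; no detection floor"
            )
        df.loc[grp.index[zeros], "concentration"] = positive.min()
        n_replaced += int(zeros.sum())
    logger.info("replaced %d non-detect values", n_replaced)
    return CytokinePanel(df, units=panel.units)


@dataclass
class UniformSeries:
    """One subject x cytokine trajectory on a uniform time grid (minutes)."""

    subject_id: str
    cytokine: str
    t0_minutes: float
    step_minutes: float
    values: np.ndarray
    group: str = ""
    units: str = "pg_ml"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.step_minutes <= 0:
            raise ValueError("step_minutes must be positive")
        if self.values.size < 2:
            raise ValueError("a uniform series needs at least 2 points")

    @property
    def times(self) -> np.ndarray:
        return self.t0_minutes + self.step_minutes * np.arange(
            self.values.size
        )


class InsufficientPointsError(ValueError):
    pass


def interpolate_uniform(
    panel: CytokinePanel, step_minutes: float = 3.0
) -> list[UniformSeries]:
    """Linearly interpolate each subject x cytokine series to a uniform grid.

    The grid runs from the first to the last observed minute of that series
    (no extrapolation); observed points are reproduced exactly when the grid
    lands on them.
    """
    out: list[UniformSeries] = []
    for (subj, cyt), grp in panel.data.groupby(
        ["subject_id", "cytokine"], sort=True
    ):
        grp = grp.sort_values("minutes_from_T1")
        t = grp["minutes_from_T1"].to_numpy(dtype=float)
        y = grp["concentration"].to_numpy(dtype=float)
        if t.size < 2:
            raise InsufficientPointsError(
                f"({subj}, {cyt}) has {t.size} observation(s); need >= 2"
            )
        n_steps = int(np.floor((t[-1] - t[0]) / step_minutes + 1e-9))
        grid = t[0] + step_minutes * np.arange(n_steps + 1)
        vals = np.interp(grid, t, y)
        out.append(
            UniformSeries(
                subject_id=subj, cytokine=cyt, t0_minutes=float(t[0]),
                step_minutes=float(step_minutes), values=vals,
                group=grp["group"].iloc[0], units=panel.units,
            )
        )
    logger.info("interpolated %d series (step %.3g min)", len(out), step_minutes)
    return out


class BaselineUndefinedError(ValueError):
    pass


def hc_resting_baseline(panel: CytokinePanel) -> dict[str, float]:
    """Mean log2 concentration at T0 over healthy-control subjects, per cytokine."""
    hc_t0 = panel.data[
        (panel.data["group"] == "HC") & (panel.data["timepoint_label"] == "T0")
    ]
    if hc_t0.empty:
        raise BaselineUndefinedError("no HC T0 records to define the baseline")
    if (hc_t0["concentration"] <= 0).any():
        raise ValueError("baseline requires positive concentrations; run "
                         "replace_nondetects first")
    return {
        cyt: float(np.mean(np.log2(grp["concentration"])))
        for cyt, grp in hc_t0.groupby("cytokine")
    }


def to_fold_change(
    series: Sequence[UniformSeries], panel_meta: CytokinePanel
) -> list[UniformSeries]:
    """Normalise to fold change over the HC resting geometric mean.

    Each value becomes ``2^(log2(v) - mean_HC(log2 T0))`` for its cytokine,
    i.e. the value divided by the geometric mean of healthy resting levels.
    Baselines are taken from the raw T0 observations in ``panel_meta``.
    """
    baseline = hc_resting_baseline(panel_meta)
    out = []
    for s in series:
        if np.any(s.values <= 0):
            raise ValueError(
                f"({s.subject_id}, {s.cytokine}) has non-positive values; "
                "run replace_nondetects first"
            )
        vals = 2.0 ** (np.log2(s.values) - baseline[s.cytokine])
        out.append(replace(s, values=vals, units="fold_change"))
    return out


def slice_recovery(series: Sequence[UniformSeries]) -> list[UniformSeries]:
    """Clip each series to the 4-h recovery window [0, 240] min from peak."""
    lo, hi = RECOVERY_WINDOW
    out = []
    for s in series:
        t = s.times
        keep = (t >= lo - 1e-9) & (t <= hi + 1e-9)
        if keep.sum() < 2:
            raise ValueError(
                f"({s.subject_id}, {s.cytokine}) has no recovery window"
            )
        if t[-1] < hi - 1e-9:
            logger.warning(
                "series (%s, %s) ends at %.1f min; partial recovery window",
                s.subject_id, s.cytokine, t[-1],
            )
        out.append(
            replace(s, t0_minutes=float(t[keep][0]), values=s.values[keep])
        )
    return out


def preprocess(
    panel: CytokinePanel,
    step_minutes: float = 3.0,
    exclude: Iterable[str] = (),
) -> list[UniformSeries]:
    """Full chain: exclusion -> non-detect floor -> interpolation ->
    fold-change normalisation -> recovery-window slice."""
    panel = panel.exclude_subjects(exclude)
    panel = replace_nondetects(panel)
    series = interpolate_uniform(panel, step_minutes=step_minutes)
    series = to_fold_change(series, panel)
    return slice_recovery(series)
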