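"""Per-fragment G_0 time series, completion detection and RG% normalization.

A fragment's standardized grays ``G_0(t)`` fall as the coral pales.  Two
baselines anchor the trajectory: ``G_0^normal``, the mean of the first 5
points recorded during 27 °C acclimation, and ``G_0^bleach``, the mean of
the last 5 points once no further paling is observed.  The relative
grayscale is then::

    RG% = 100 * (G_0 - G_0^bleach) / (G_0^normal - G_0^bleach)

so every fragment starts at 100% and ends at 0% regardless of its
pigmentation, and only the fragment's own record enters the scaling.
RG% is never clamped: values above 100% occur when expelled symbionts
transiently darken the tissue surface, and they carry signal.

Imaging is considered complete when a run of consecutive points shows no
decrease in G_0 (default: 6 points).  Series may be irregular (failed
photographs leave gaps); no imputation is performed, the downstream curve
fit consumes raw (t, RG%) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StandardizedSeries",
    "Baselines",
    "RGSeries",
    "InsufficientDataError",
    "DegenerateTrajectoryError",
    "NOT_COMPLETE",
    "detect_completion",
    "baselines",
    "relative_grayscale",
    "to_rg_series",
    "series_from_measurements",
    "series_from_long_csv",
    "rg_long_table",
]

BASELINE_POINTS = 5  # points averaged into each baseline
DEFAULT_WINDOW = 6  # consecutive non-decreasing points = completion

#: Sentinel returned by detect_completion when the series never plateaus.
NOT_COMPLETE = -1


class InsufficientDataError(ValueError):
    """Series too short for the requested computation."""


class DegenerateTrajectoryError(ValueError):
    """Normal and bleached baselines coincide; the fragment never changed."""


@dataclass(frozen=True)
class StandardizedSeries:
    """A fragment's G_0 record, with times in days since heating onset.

    Twice-daily photographs (6 AM / 6 PM) map to +0.0 / +0.5 day offsets;
    acclimation points carry negative times.
    """

    fragment_id: str
    species: str
    colony: str
    regime: str  # "FHP" | "SHP"
    times: np.ndarray
    g0_values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        g = np.asarray(self.g0_values, dtype=float)
        if t.shape != g.shape or t.ndim != 1:
            raise ValueError("times and g0_values must be equal-length 1-D")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "g0_values", g)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class Baselines:
    """Normal (acclimated) and bleached G_0 anchors for one fragment."""

    g0_normal: float
    g0_bleach: float


@dataclass(frozen=True)
class RGSeries:
    """Relative-grayscale trajectory in percent; the fitting substrate."""

    fragment_id: str
    times: np.ndarray
    rg_values: np.ndarray
    species: str = ""
    colony: str = ""
    regime: str = ""
    baselines_used: Baselines | None = field(default=None, compare=False)

    def __len__(self) -> int:
        return len(self.times)


def detect_completion(
    series: StandardizedSeries,
    window: int = DEFAULT_WINDOW,
    tol: float = 0.0,
) -> int:
    """Find the earliest plateau of ``window`` consecutive points.

    A plateau is a run in which every successive difference satisfies
    ``g0[i+1] - g0[i] >= -tol``; its presence marks bleaching completion.
    ``tol`` (in G_0 units) relaxes the strict no-decrease reading for
    noisy plateaus.

    Returns the index of the run's last point, or :data:`NOT_COMPLETE`.
    """
    if len(series) < window + 1:
        raise InsufficientDataError(
            f"need at least {window + 1} points, got {len(series)}"
        )
    nondecreasing = np.diff(series.g0_values) >= -tol
    run = 0
    for i, ok in enumerate(nondecreasing):
        run = run + 1 if ok else 0
        if run >= window - 1:  # window points span window-1 differences
            return i + 1
    return NOT_COMPLETE


def baselines(
    series: StandardizedSeries,
    completion_index: int | None = None,
    epsilon: float = 1e-6,
) -> Baselines:
    """Compute the normal and bleached G_0 baselines.

    ``g0_normal`` averages the first 5 points; ``g0_bleach`` averages the
    last 5 points up to ``completion_index`` (defaults to the end of the
    record when imaging stopped at completion).
    """
    n = len(series)
    if n < 2 * BASELINE_POINTS:
        raise InsufficientDataError(
            f"need at least {2 * BASELINE_POINTS} points, got {n}"
        )
    end = n - 1 if completion_index is None else completion_index
    if end < BASELINE_POINTS:
        raise InsufficientDataError("completion index before 5th point")
    g0_normal = float(series.g0_values[:BASELINE_POINTS].mean())
    g0_bleach = float(
        series.g0_values[end - BASELINE_POINTS + 1 : end + 1].mean()
    )
    if abs(g0_normal - g0_bleach) <= epsilon:
        raise DegenerateTrajectoryError(
            f"baselines coincide ({g0_normal:.6f} vs {g0_bleach:.6f}); "
            "fragment never bleached or never had color"
        )
    return Baselines(g0_normal=g0_normal, g0_bleach=g0_bleach)


def relative_grayscale(
    g0: float | np.ndarray, b: Baselines
) -> float | np.ndarray:
    """Map G_0 onto the fragment's own 0–100% bleaching scale (unclamped)."""
    return 100.0 * (g0 - b.g0_bleach) / (b.g0_normal - b.g0_bleach)


def to_rg_series(
    series: StandardizedSeries,
    completion_index: int | None = None,
    epsilon: float = 1e-6,
) -> RGSeries:
    """Convert a standardized series to RG% using its own baselines."""
    b = baselines(series, completion_index, epsilon)
    rg = relative_grayscale(series.g0_values, b)
    return RGSeries(
        fragment_id=series.fragment_id,
        times=series.times.copy(),
        rg_values=np.asarray(rg, dtype=float),
        species=series.species,
        colony=series.colony,
        regime=series.regime,
        baselines_used=b,
    )


# ---------------------------------------------------------------------------
# I/O: assembling series from the measurement table or long-format CSVs


def _day_offsets(timestamps: pd.Series) -> np.ndarray:
    """Days since the first photograph, 6 AM/6 PM -> +0.0/+0.5."""
    ts = pd.to_datetime(timestamps)
    delta = ts - ts.iloc[0].normalize()
    return (delta.dt.total_seconds() / 86400.0).to_numpy()


def series_from_measurements(
    measurements: pd.DataFrame,
    t0: pd.Timestamp | str | None = None,
) -> list[StandardizedSeries]:
    """Group the imaging measurement table into per-fragment series.

    ``t0`` fixes day 0 (first heating step, 6 AM); by default the earliest
    timestamp in the table is used.
    """
    df = measurements.copy()
    df["ts"] = pd.to_datetime(df["timestamp_iso"])
    origin = pd.to_datetime(t0) if t0 is not None else df["ts"].min()
    df["day"] = (df["ts"] - origin).dt.total_seconds() / 86400.0
    out = []
    for frag, grp in df.groupby("fragment_id", sort=True):
        grp = grp.sort_values("day")
        out.append(
            StandardizedSeries(
                fragment_id=str(frag),
                species=str(grp["species"].iloc[0]),
                colony=str(grp["colony"].iloc[0]),
                regime=str(grp["regime"].iloc[0]),
                times=grp["day"].to_numpy(),
                g0_values=grp["g0"].to_numpy(),
            )
        )
    return out


def series_from_long_csv(
    table: pd.DataFrame | str,
    value_type: str = "g0",
) -> list[StandardizedSeries] | list[RGSeries]:
    """Read a long-format CSV of per-fragment trajectories.

    Columns: fragment_id, species, colony, regime, day, value.  With
    ``value_type="g0"`` returns :class:`StandardizedSeries`; with
    ``value_type="rg_percent"`` (the dialect of published
    relative-grayscale tables) returns :class:`RGSeries` directly.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    required = {"fragment_id", "species", "colony", "regime", "day", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"long-format CSV missing columns: {sorted(missing)}")
    if value_type not in ("g0", "rg_percent"):
        raise ValueError(f"unknown value_type {value_type!r}")
    out: list = []
    for frag, grp in table.groupby("fragment_id", sort=True):
        grp = grp.sort_values("day")
        meta = dict(
            species=str(grp["species"].iloc[0]),
            colony=str(grp["colony"].iloc[0]),
            regime=str(grp["regime"].iloc[0]),
        )
        if value_type == "g0":
            out.append(
                StandardizedSeries(
                    fragment_id=str(frag),
                    times=grp["day"].to_numpy(),
                    g0_values=grp["value"].to_numpy(),
                    **meta,
                )
            )
        else:
            out.append(
                RGSeries(
                    fragment_id=str(frag),
                    times=grp["day"].to_numpy(dtype=float),
                    rg_values=grp["value"].to_numpy(dtype=float),
                    **meta,
                )
            )
    return out


def rg_long_table(series_list: list[RGSeries]) -> pd.DataFrame:
    """Serialize RG% series to long format with baseline metadata."""
    rows = []
    for s in series_list:
        for t, v in zip(s.times, s.rg_values):
            rows.append(
                {
                    "fragment_id": s.fragment_id,
                    "species": s.species,
                    "colony": s.colony,
                    "regime": s.regime,
                    "day": t,
                    "value": v,
                    "value_type": "rg_percent",
                    "g0_normal": (
                        s.baselines_used.g0_normal
                        if s.baselines_used
                        else np.nan
                    ),
                    "g0_bleach": (
                        s.baselines_used.g0_bleach
                        if s.baselines_used
                        else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)
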