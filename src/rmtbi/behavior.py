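"""Open-field zone metrics and novel-object-recognition analysis.

Open field: an animal explores a rectangular arena; anxiety-like behaviour
is read out as time spent in the 8 cm peripheral band versus the central
zone, plus total distance travelled.  Novel object recognition (NOR): the
investigation ratio IR = novel-object contact time / total contact time is
compared to chance (0.5) with a single-sample two-tailed t-test; IR > 0.5
indicates intact recognition memory.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["ArenaConfig", "open_field_metrics", "nor_investigation"]


@dataclass(frozen=True)
class ArenaConfig:
    """Open-field arena geometry (cm).

    The peripheral zone is the band within ``border_cm`` of the walls; the
    central zone is the interior rectangle.  The geometric central-area
    fraction depends on the arena size, so it is computed and reported
    rather than assumed.
    """

    width_cm: float
    height_cm: float
    border_cm: float = 8.0

    def __post_init__(self) -> None:
        if self.width_cm <= 0 or self.height_cm <= 0:
            raise ValueError("arena dimensions must be positive")
        if not 0 <= self.border_cm < min(self.width_cm, self.height_cm) / 2:
            raise ValueError(
                "border must be non-negative and less than half the smaller side"
            )

    @property
    def central_fraction(self) -> float:
        """Area fraction of the central zone (e.g. 44^2/60^2 = 0.538 for a
        60 x 60 arena with an 8 cm border)."""
        cw = self.width_cm - 2 * self.border_cm
        ch = self.height_cm - 2 * self.border_cm
        return (cw * ch) / (self.width_cm * self.height_cm)

    def in_center(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        b = self.border_cm
        return (
            (x >= b)
            & (x <= self.width_cm - b)
            & (y >= b)
            & (y <= self.height_cm - b)
        )


def open_field_metrics(
    track: pd.DataFrame | np.ndarray, arena: ArenaConfig
) -> dict[str, float]:
    """Distance travelled and center/periphery times from an (t, x, y) track.

    Zone times use sample-and-hold: each sample's zone membership counts
    for the following inter-sample interval (the last sample holds the
    final interval), so center + periphery time equals the track duration
    exactly.
    """
    if isinstance(track, pd.DataFrame):
        t = track["t"].to_numpy(dtype=float)
        x = track["x"].to_numpy(dtype=float)
        y = track["y"].to_numpy(dtype=float)
    else:
        arr = np.asarray(track, dtype=float)
        t, x, y = arr[:, 0], arr[:, 1], arr[:, 2]
    if t.size < 2:
        raise ValueError("track needs >= 2 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("track times must be strictly increasing")
    outside = (x < 0) | (x > arena.width_cm) | (y < 0) | (y > arena.height_cm)
    if outside.any():
        raise ValueError(
            f"track points outside the arena at indices {np.nonzero(outside)[0].tolist()}"
        )
    steps = np.sqrt(np.diff(x) ** 2 + np.diff(y) ** 2)
    distance = float(steps.sum())
    dt = np.diff(t)
    intervals = np.append(dt, dt[-1] if dt.size else 0.0)
    duration = float(intervals.sum())
    in_center = arena.in_center(x, y)
    time_center = float(intervals[in_center].sum())
    time_periphery = duration - time_center
    logger.debug(
        "arena central fraction %.3f (geometry-derived)", arena.central_fraction
    )
    return {
        "distance_cm": distance,
        "time_center_s": time_center,
        "time_periphery_s": time_periphery,
        "duration_s": duration,
        "central_fraction": arena.central_fraction,
    }


def nor_investigation(
    contacts: pd.DataFrame, chance: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Investigation ratios and the chance-level test per group.

    ``contacts`` columns: subject_id, group, novel_s, familiar_s.  Subjects
    with zero total contact are excluded with a warning.  Per group a
    single-sample two-tailed t-test compares mean IR to 0.5; when exactly
    two groups are present a two-sample t-test compares them.
    """
    needed = {"subject_id", "group", "novel_s", "familiar_s"}
    missing = needed - set(contacts.columns)
    if missing:
        raise ValueError(f"contact table missing columns {sorted(missing)}")
    df = contacts.copy()
    total = df["novel_s"] + df["familiar_s"]
    if np.any(df[["novel_s", "familiar_s"]].to_numpy() < 0):
        raise ValueError("contact times must be non-negative")
    zero = total <= 0
    if zero.any():
        warnings.warn(
            f"subjects with zero contact excluded: "
            f"{df.loc[zero, 'subject_id'].tolist()}",
            stacklevel=2,
        )
        df = df.loc[~zero]
        total = total.loc[~zero]
    df = df.assign(ir=df["novel_s"] / total)
    rows = []
    for group, sub in df.groupby("group"):
        ir = sub["ir"].to_numpy()
        if ir.size >= 2 and np.ptp(ir) > 0:
            t_stat, p = stats.ttest_1samp(ir, chance)
        else:
            t_stat, p = np.nan, np.nan
        rows.append(
            {
                "group": group,
                "n": ir.size,
                "mean_ir": float(ir.mean()),
                "t_vs_chance": float(t_stat),
                "p_vs_chance": float(p),
            }
        )
    group_stats = pd.DataFrame(rows)
    groups = list(df["group"].unique())
    if len(groups) == 2:
        a = df.loc[df["group"] == groups[0], "ir"]
        b = df.loc[df["group"] == groups[1], "ir"]
        t2, p2 = stats.ttest_ind(a, b, equal_var=True)
        group_stats.attrs["between_groups"] = {
            "t": float(t2),
            "p": float(p2),
            "groups": groups,
        }
    return df[["subject_id", "group", "ir"]], group_stats
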