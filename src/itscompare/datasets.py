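"""Interrupted time series datasets and their plain-text file format.

A dataset is one evenly indexed series of outcome measurements with a
single interruption: ``n_pre`` points before it, ``n_post`` points from
the interruption onwards, and optionally a transition window in between
that is modelled as its own segment but ignored when effects are
computed.  Time is the observation index, 1..N.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

__all__ = ["TimeSeriesDataset", "DatasetError", "read_series_file", "write_series_file"]


class DatasetError(ValueError):
    """Raised when a series violates the eligibility or format rules."""


MIN_SEGMENT_POINTS = 3  # eligibility: at least three points in each segment


@dataclass(frozen=True)
class TimeSeriesDataset:
    """One interrupted time series.

    Parameters
    ----------
    series_id : str
        Label used in reports and exclusion ledgers.
    y : ndarray
        Outcome values, one per time point; no missing values.
    t : ndarray
        Integer time index 1..N, strictly incrementing by 1.
    interruption_time : int
        Time index ``T_I`` of the *first post-interruption observation*;
        the level-change indicator switches on at ``t == T_I``.
    transition : (int, int), optional
        First and last time index of a transition period lying strictly
        between the pre segment and ``T_I``.
    """

    series_id: str
    y: np.ndarray
    t: np.ndarray
    interruption_time: int
    transition: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        t = np.asarray(self.t, dtype=int)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "t", t)
        if y.ndim != 1 or t.ndim != 1 or len(y) != len(t):
            raise DatasetError(f"{self.series_id}: y and t must be 1-d of equal length")
        n = len(t)
        if n == 0 or t[0] != 1 or not np.array_equal(t, np.arange(1, n + 1)):
            raise DatasetError(
                f"{self.series_id}: time index must be 1..N incrementing by 1"
            )
        if not np.all(np.isfinite(y)):
            raise DatasetError(f"{self.series_id}: missing/non-finite outcome values")
        ti = int(self.interruption_time)
        if not (1 <= ti <= n):
            raise DatasetError(f"{self.series_id}: interruption_time {ti} outside 1..{n}")
        if self.transition is not None:
            a, b = (int(self.transition[0]), int(self.transition[1]))
            object.__setattr__(self, "transition", (a, b))
            if not (a <= b):
                raise DatasetError(f"{self.series_id}: empty transition window ({a},{b})")
            if not (a >= 2 and b <= ti - 1):
                raise DatasetError(
                    f"{self.series_id}: transition ({a},{b}) must lie strictly "
                    f"between the pre segment and T_I={ti}"
                )
        if self.n_pre < MIN_SEGMENT_POINTS or self.n_post < MIN_SEGMENT_POINTS:
            raise DatasetError(
                f"{self.series_id}: need >= {MIN_SEGMENT_POINTS} points in each of the "
                f"pre and post segments (got {self.n_pre} pre, {self.n_post} post)"
            )

    # -- derived counts ------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def n_pre(self) -> int:
        """Points strictly before the transition window (or before T_I)."""
        first_non_pre = self.transition[0] if self.transition else self.interruption_time
        return int(first_non_pre - 1)

    @property
    def n_post(self) -> int:
        """Points from T_I to the end of the series."""
        return int(self.n - self.interruption_time + 1)


# ---------------------------------------------------------------------------
# File format: CSV body `time,outcome` preceded by `# key: value` front matter.

_META_KEYS = {"series_id", "interruption_time", "transition_start", "transition_end",
              "second_interruption_time"}


def read_series_file(path: str | Path) -> TimeSeriesDataset:
    """Read one series file.

    The format is delimited text with a ``time,outcome`` header, preceded
    by ``# key: value`` front-matter lines carrying ``interruption_time``
    and, optionally, ``transition_start``/``transition_end`` and
    ``second_interruption_time``.  When a second interruption is declared,
    the series is truncated just before it so only the first interruption
    and its adjacent segments are modelled.

    Malformed rows raise :class:`DatasetError` naming the line number.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[int, float]] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            if not header_seen:
                cols = [c.strip().lower() for c in line.split(",")]
                if cols[:2] != ["time", "outcome"]:
                    raise DatasetError(
                        f"{path}:{lineno}: expected header 'time,outcome', got {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) < 2:
                raise DatasetError(f"{path}:{lineno}: expected 'time,outcome' row")
            try:
                t_val = int(float(parts[0]))
                y_val = float(parts[1])
            except ValueError as exc:
                raise DatasetError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
            if not np.isfinite(y_val):
                raise DatasetError(f"{path}:{lineno}: missing outcome value")
            rows.append((t_val, y_val))
    if "interruption_time" not in meta:
        raise DatasetError(f"{path}: missing 'interruption_time' metadata")
    if not rows:
        raise DatasetError(f"{path}: no data rows")

    t = np.array([r[0] for r in rows], dtype=int)
    y = np.array([r[1] for r in rows], dtype=float)

    if "second_interruption_time" in meta:
        cut = int(meta["second_interruption_time"])
        keep = t < cut
        t, y = t[keep], y[keep]

    transition = None
    if "transition_start" in meta or "transition_end" in meta:
        if not ("transition_start" in meta and "transition_end" in meta):
            raise DatasetError(f"{path}: transition_start/transition_end must both be set")
        transition = (int(meta["transition_start"]), int(meta["transition_end"]))

    return TimeSeriesDataset(
        series_id=meta.get("series_id", path.stem),
        y=y,
        t=t,
        interruption_time=int(meta["interruption_time"]),
        transition=transition,
    )


def write_series_file(dataset: TimeSeriesDataset, path: str | Path) -> None:
    """Write a series in the front-matter CSV format (full float precision)."""
    buf = io.StringIO()
    buf.write(f"# series_id: {dataset.series_id}\n")
    buf.write(f"# interruption_time: {dataset.interruption_time}\n")
    if dataset.transition is not None:
        buf.write(f"# transition_start: {dataset.transition[0]}\n")
        buf.write(f"# transition_end: {dataset.transition[1]}\n")
    buf.write("time,outcome\n")
    for t_val, y_val in zip(dataset.t, dataset.y):
        buf.write(f"{int(t_val)},{float(y_val)!r}\n")
    Path(path).write_text(buf.getvalue())
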