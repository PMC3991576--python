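"""Reading, validating, filtering and segmenting RR-interval series.

RR series are stored as plain text, one interval per line, with an optional
second whitespace-separated token carrying the beat annotation (``N`` for a
normal sinus beat).  Lines starting with ``#`` are comments.  Intervals are
held internally in milliseconds; files written in seconds (the PhysioNet RR
export convention) are detected by magnitude and converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "RRSeries",
    "read_rr_file",
    "write_rr_file",
    "extract_segment",
    "filter_normal_beats",
]


@dataclass(frozen=True)
class RRSeries:
    """A sequence of beat-to-beat (RR) intervals with beat annotations.

    Parameters
    ----------
    intervals
        Positive interval durations in milliseconds.
    beat_labels
        One annotation symbol per interval; ``'N'`` marks a normal sinus
        beat.  Defaults to all-normal.
    t0_offset
        Start time of this segment, in seconds, within its source record.
    source_id
        Opaque identifier of the source record.
    """

    intervals: np.ndarray
    beat_labels: np.ndarray = field(default=None)  # type: ignore[assignment]
    t0_offset: float = 0.0
    source_id: str = ""

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float)
        if iv.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if iv.size and np.min(iv) <= 0:
            raise ValueError("all RR intervals must be positive")
        labels = self.beat_labels
        if labels is None:
            labels = np.full(iv.size, "N", dtype="<U4")
        else:
            labels = np.asarray(labels, dtype="<U4")
        if labels.shape != iv.shape:
            raise ValueError("beat_labels must have the same length as intervals")
        object.__setattr__(self, "intervals", iv)
        object.__setattr__(self, "beat_labels", labels)

    def __len__(self) -> int:
        return self.intervals.size

    @property
    def duration_s(self) -> float:
        """Total span of the series in seconds."""
        return float(self.intervals.sum()) / 1000.0

    def start_times_s(self) -> np.ndarray:
        """Cumulative start time of each interval, in seconds from t0."""
        return np.concatenate(([0.0], np.cumsum(self.intervals)[:-1])) / 1000.0

    def end_times_s(self) -> np.ndarray:
        """Cumulative end time of each interval, in seconds from t0."""
        return np.cumsum(self.intervals) / 1000.0


def read_rr_file(path, units_hint: str = "auto") -> RRSeries:
    """Read an RR-interval series from a plain-text file.

    One numeric value per line, optionally followed by a whitespace-separated
    beat label; ``#`` comment lines and blank lines are ignored.  With
    ``units_hint='auto'`` a file whose median value is below 10 is taken to
    be in seconds and converted to milliseconds.
    """
    if units_hint not in ("auto", "ms", "s"):
        raise ValueError(f"units_hint must be 'auto', 'ms' or 's', got {units_hint!r}")
    path = Path(path)
    values: list[float] = []
    labels: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            try:
                v = float(tokens[0])
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: expected a numeric RR interval, got {tokens[0]!r}"
                ) from None
            if v <= 0:
                raise ValueError(f"{path}: line {lineno}: nonpositive RR interval {v}")
            values.append(v)
            labels.append(tokens[1] if len(tokens) > 1 else "N")
    if not values:
        raise ValueError(f"{path}: file contains no RR intervals")
    iv = np.asarray(values, dtype=float)
    if units_hint == "s" or (units_hint == "auto" and np.median(iv) < 10.0):
        iv = iv * 1000.0
    return RRSeries(intervals=iv, beat_labels=np.asarray(labels), source_id=path.stem)


def write_rr_file(rr: RRSeries, path, units: str = "ms") -> None:
    """Write an RR series as plain text (inverse of :func:`read_rr_file`)."""
    if units not in ("ms", "s"):
        raise ValueError("units must be 'ms' or 's'")
    scale = 1.0 if units == "ms" else 1e-3
    with open(path, "w") as fh:
        fh.write("# hrvscreen:rr-series:v1\n")
        for v, lab in zip(rr.intervals, rr.beat_labels):
            fh.write(f"{v * scale:.10g} {lab}\n")


def extract_segment(rr: RRSeries, start_s: float = 0.0, duration_s: float = 300.0) -> RRSeries:
    """Extract the run of intervals whose start times lie in a time window.

    The window is ``[start_s, start_s + duration_s)`` in cumulative record
    time.  Raises if the window extends past the end of the record.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    total = rr.duration_s
    if start_s + duration_s > total + 1e-9:
        raise ValueError(
            f"requested window [{start_s}, {start_s + duration_s}) s exceeds the "
            f"record span of {total:.3f} s"
        )
    starts = rr.start_times_s()
    mask = (starts >= start_s) & (starts < start_s + duration_s)
    idx = np.flatnonzero(mask)
    return RRSeries(
        intervals=rr.intervals[idx],
        beat_labels=rr.beat_labels[idx],
        t0_offset=rr.t0_offset + start_s,
        source_id=rr.source_id,
    )


def filter_normal_beats(rr: RRSeries, policy: str = "off") -> RRSeries:
    """Restrict a series to normal-to-normal (NN) intervals.

    ``policy='strict'`` drops every interval not labelled ``'N'`` and also
    the interval immediately following a dropped one, since that interval is
    not bounded by two normal beats.  ``policy='off'`` returns the input
    unchanged.
    """
    if policy == "off":
        return rr
    if policy != "strict":
        raise ValueError(f"policy must be 'strict' or 'off', got {policy!r}")
    keep = rr.beat_labels == "N"
    dropped = ~keep
    # an interval after a dropped beat is not normal-to-normal
    keep[1:] &= ~dropped[:-1]
    if len(rr) and (1 - keep.mean()) > 0.20:
        warnings.warn(
            f"{rr.source_id or 'RR series'}: more than 20% of intervals removed "
            "by NN filtering",
            stacklevel=2,
        )
    idx = np.flatnonzero(keep)
    return replace(rr, intervals=rr.intervals[idx], beat_labels=rr.beat_labels[idx])
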