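"""Locomotion-event detection, epoching, baseline normalization, and response metrics.

The analysis treats each locomotion onset as a trial: locomotion and
hemodynamic traces are cut from 5 s before to 20 s after the onset, each
epoch is normalized to its own pre-onset baseline,

    ΔTrace = (Trace − Trace0) / |Trace0|        (×100 for hemodynamic traces),

and per-event response metrics are computed over the 0-5 s post-onset window:
trapezoidal area under the curve, maximum peak and minimum (each averaged
over ±0.25 s around the extremum to suppress noise spikes), times to reach
them, and a normalized speed metric |peak| / time-to-peak (%/s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LocomotionTrace",
    "EventEpochs",
    "detect_events",
    "epoch",
    "normalize",
    "metrics",
    "rank_and_split",
    "grand_average",
]

#: Epoch window relative to onset, seconds (half-open).
WINDOW_S = (-5.0, 20.0)
#: Metrics window after onset, seconds (closed).
METRIC_WINDOW_S = (0.0, 5.0)

KEY_COLUMNS = ("animal_id", "session_id", "event_id", "vessel", "genotype")


@dataclass(frozen=True)
class LocomotionTrace:
    """A locomotion speed trace in arbitrary units: zero when stationary."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if np.any(self.samples < 0):
            raise ValueError("locomotion samples must be >= 0")


@dataclass
class EventEpochs:
    """Per-event trace matrix on the −5…+20 s window.

    ``data`` is (n_events, n_samples) with the onset at column
    ``onset_index = 5 s × rate``. ``keys`` carries one row of identifying
    labels per event (animal, session, event, vessel, genotype).
    ``flags`` marks rows whose baseline fell below the normalization epsilon.
    """

    data: np.ndarray
    rate: float
    window: tuple[float, float] = WINDOW_S
    normalized: bool = False
    units: str = "a.u."
    keys: pd.DataFrame = field(default_factory=pd.DataFrame)
    flags: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        expected = int(round((self.window[1] - self.window[0]) * self.rate))
        if self.data.shape[1] != expected:
            raise ValueError(
                f"epoch length {self.data.shape[1]} != window × rate = {expected}"
            )
        if len(self.keys) == 0:
            self.keys = pd.DataFrame(
                {c: [None] * self.n_events for c in KEY_COLUMNS}
            )
        if len(self.keys) != self.n_events:
            raise ValueError("keys must have one row per event")
        if self.flags.size == 0:
            self.flags = np.zeros(self.n_events, dtype=bool)

    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    @property
    def onset_index(self) -> int:
        return int(round(-self.window[0] * self.rate))

    def times(self) -> np.ndarray:
        """Time axis in seconds relative to onset."""
        return self.window[0] + np.arange(self.data.shape[1]) / self.rate


def detect_events(
    trace: LocomotionTrace,
    min_quiescence_s: float = 1.0,
    min_duration_s: float = 0.5,
    min_separation_s: float = 0.0,
) -> np.ndarray:
    """Detect locomotion onsets from a continuous trace.

    An onset is the first supra-zero sample of a movement run lasting at least
    ``min_duration_s``, preceded by at least ``min_quiescence_s`` of zeros.
    Onsets closer than ``min_separation_s`` to an accepted predecessor are
    dropped, as are onsets whose full −5/+20 s epoch exceeds the recording
    (logged). Replaces the manual event marking of the original workflow.
    """
    x = trace.samples
    rate = trace.rate
    n = x.size
    moving = x > 0
    # run-length encode the movement mask
    edges = np.flatnonzero(np.diff(moving.astype(np.int8)))
    starts = edges[~moving[edges]] + 1 if edges.size else np.array([], dtype=int)
    if moving.size and moving[0]:
        starts = np.concatenate([[0], starts])
    onsets = []
    min_dur = int(round(min_duration_s * rate))
    min_quiet = int(round(min_quiescence_s * rate))
    min_sep = min_separation_s * rate
    pre = int(round(-WINDOW_S[0] * rate))
    post = int(round(WINDOW_S[1] * rate))
    dropped_bounds = 0
    for s in starts:
        e = s
        while e < n and moving[e]:
            e += 1
        if e - s < min_dur:
            continue
        if s < min_quiet or moving[s - min_quiet : s].any():
            continue
        if onsets and s - onsets[-1] < min_sep:
            continue
        if s - pre < 0 or s + post > n:
            dropped_bounds += 1
            continue
        onsets.append(s)
    if dropped_bounds:
        logger.warning("detect_events: dropped %d onset(s) without a full epoch", dropped_bounds)
    return np.asarray(onsets, dtype=int)


def epoch(
    trace: np.ndarray,
    onsets,
    rate: float,
    units: str = "a.u.",
    keys: "dict | None" = None,
) -> EventEpochs:
    """Cut per-event rows [onset − 5 s, onset + 20 s) from a continuous trace.

    Onsets that do not admit the full window are dropped with a warning.
    ``keys`` values are broadcast across events; ``event_id`` is enumerated
    if not supplied.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    trace = np.asarray(trace, dtype=float)
    pre = int(round(-WINDOW_S[0] * rate))
    post = int(round(WINDOW_S[1] * rate))
    rows, kept = [], []
    for i, o in enumerate(onsets):
        o = int(o)
        if o - pre < 0 or o + post > trace.size:
            logger.warning("epoch: dropped onset %d (incomplete window)", o)
            continue
        rows.append(trace[o - pre : o + post])
        kept.append(i)
    data = np.asarray(rows) if rows else np.empty((0, pre + post))
    keydict = dict(keys or {})
    keydict.setdefault("event_id", kept)
    frame = {}
    for c in KEY_COLUMNS:
        v = keydict.get(c)
        frame[c] = [v] * len(kept) if (v is None or np.isscalar(v)) else list(v)
    return EventEpochs(data=data, rate=rate, units=units, keys=pd.DataFrame(frame))


def normalize(epochs: EventEpochs, epsilon: float = 1e-6) -> EventEpochs:
    """Normalize each epoch to its own 5-s pre-onset baseline.

    ``out = (Trace − Trace0) / |Trace0|`` with ``Trace0`` the arithmetic mean
    of the pre-onset samples; hemodynamic traces (units ``'um'``) are further
    multiplied by 100 to read in % change. Rows with ``|Trace0| < epsilon``
    (e.g. locomotion epochs, whose baseline is all zeros) fall back to plain
    baseline subtraction and are flagged. Normalizing twice is rejected.
    """
    if epochs.normalized:
        raise ValueError("epochs are already normalized")
    base = epochs.data[:, : epochs.onset_index].mean(axis=1)
    small = np.abs(base) < epsilon
    denom = np.where(small, 1.0, np.abs(base))
    out = (epochs.data - base[:, None]) / denom[:, None]
    units = epochs.units
    if units == "um":
        out = out * 100.0
        units = "%"
    if small.any():
        logger.info("normalize: %d row(s) had |baseline| < epsilon; subtraction only", small.sum())
    return EventEpochs(
        data=out,
        rate=epochs.rate,
        window=epochs.window,
        normalized=True,
        units=units,
        keys=epochs.keys.copy(),
        flags=small,
    )


def metrics(
    epochs: EventEpochs,
    window_s: tuple[float, float] = METRIC_WINDOW_S,
    peak_halfwidth_s: float = 0.25,
    locomotion_auc: "np.ndarray | None" = None,
) -> pd.DataFrame:
    """Per-event response metrics over the post-onset window (default 0-5 s).

    Columns: ``auc`` (trapezoidal integral, %·s), ``max_peak`` / ``min_peak``
    (mean over ±0.25 s around the raw extremum, clipped to the window),
    ``time_to_max`` / ``time_to_min`` (s from onset), ``norm_speed_max`` /
    ``norm_speed_min`` (|peak| / time-to-peak, time floored at one sample
    period), plus the event keys and, if given, each event's locomotion AUC.
    """
    if not epochs.normalized:
        raise ValueError("metrics require normalized epochs")
    rate = epochs.rate
    a = int(round((window_s[0] - epochs.window[0]) * rate))
    b = int(round((window_s[1] - epochs.window[0]) * rate))  # inclusive endpoint
    if a < 0 or b >= epochs.data.shape[1]:
        raise ValueError("metrics window lies outside the epoch")
    hw = int(round(peak_halfwidth_s * rate))
    dt = 1.0 / rate
    rows = []
    for row in epochs.data:
        seg = row[a : b + 1]
        auc = np.trapezoid(seg, dx=dt)
        imax = int(np.argmax(seg))
        imin = int(np.argmin(seg))
        max_peak = seg[max(imax - hw, 0) : min(imax + hw, len(seg) - 1) + 1].mean()
        min_peak = seg[max(imin - hw, 0) : min(imin + hw, len(seg) - 1) + 1].mean()
        t_max = imax * dt
        t_min = imin * dt
        rows.append(
            dict(
                auc=auc,
                max_peak=max_peak,
                time_to_max=t_max,
                min_peak=min_peak,
                time_to_min=t_min,
                norm_speed_max=abs(max_peak) / max(t_max, dt),
                norm_speed_min=abs(min_peak) / max(t_min, dt),
            )
        )
    table = pd.concat([epochs.keys.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
    if locomotion_auc is not None:
        locomotion_auc = np.asarray(locomotion_auc, dtype=float)
        if locomotion_auc.size != len(table):
            raise ValueError("locomotion_auc must have one value per event")
        table["locomotion_auc"] = locomotion_auc
    return table


def rank_and_split(
    table: pd.DataFrame,
    by: str = "locomotion_auc",
    q: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ascending stable sort by one metric; return the bottom and top q fractions.

    With N events, each subset holds ``floor(q·N)`` rows (e.g. 234 of 2343 at
    q = 0.10). Ties at a boundary are resolved by original event order.
    """
    if not 0 < q < 0.5:
        raise ValueError("q must be in (0, 0.5)")
    n = len(table)
    k = int(np.floor(q * n))
    if k < 1:
        raise ValueError(f"q·N = {q * n:.2f} < 1: not enough events to split")
    ordered = table.sort_values(by, kind="stable")
    return ordered.iloc[:k].copy(), ordered.iloc[n - k :].copy()


def grand_average(epochs_or_data) -> tuple[np.ndarray, np.ndarray, int]:
    """Pointwise mean and SEM (SD/√n, ddof 1) across event rows.

    Accepts an :class:`EventEpochs` or a raw (events × time) array. With a
    single row the SEM is zero by convention (logged).
    """
    data = getattr(epochs_or_data, "data", epochs_or_data)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[0]
    if n < 1:
        raise ValueError("need at least one event row")
    mean = data.mean(axis=0)
    if n == 1:
        logger.info("grand_average: single row, SEM set to 0 by convention")
        sem = np.zeros_like(mean)
    else:
        sem = data.std(axis=0, ddof=1) / np.sqrt(n)
    return mean, sem, n
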