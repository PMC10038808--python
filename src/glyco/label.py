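"""Four-class event labels from diary channels.

Every grid sample is assigned one of four classes encoding
(meal?, exercise?): C00 neither, C01 exercise only, C10 meal only,
C11 both.  An activity entry of duration AD(k) milliseconds at sample k
covers T(k) = ceil(AD(k) / 3e5) samples (3e5 ms = one 5-minute sample);
samples inside any activity span are exercise, and the span is a C11
span when a carbohydrate entry falls in samples k+1 .. k+T(k) (the
window as defined, shifted one sample past the span start; a config
toggle includes sample k as well).  Outside activity spans a sample is
C10 when it carries a carbohydrate entry, else C00.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io_grid import GriddedSeries

log = logging.getLogger("glyco")

C00, C01, C10, C11 = 0, 1, 2, 3
CLASS_NAMES = ("C00", "C01", "C10", "C11")
MS_PER_SAMPLE = 3e5


@dataclass
class EventLabels:
    """Per-sample class codes and activity durations in samples."""

    classes: np.ndarray  # int8, one of C00..C11
    T: np.ndarray        # int, activity length in samples at each start

    @property
    def n(self) -> int:
        return len(self.classes)

    def counts(self) -> dict[str, int]:
        return {name: int(np.sum(self.classes == c))
                for c, name in enumerate(CLASS_NAMES)}


def label_events(series: GriddedSeries,
                 include_span_start_carb: bool = False) -> EventLabels:
    """Assign the four-class labels from activity-duration and
    carbohydrate channels (NaN treated as no entry)."""
    ad = np.nan_to_num(series.channels["activity_duration"], nan=0.0)
    cho = np.nan_to_num(series.channels["carbohydrate"], nan=0.0)
    n = series.n
    T = np.array([math.ceil(a / MS_PER_SAMPLE) for a in ad], dtype=int)

    exercise = np.zeros(n, dtype=bool)
    with_meal = np.zeros(n, dtype=bool)  # samples of C11 spans
    for k in np.flatnonzero(T):
        stop = k + T[k]  # span is [k, k+T-1]
        if stop > n:
            log.warning("label_events: activity span at %d exceeds series end; truncated", k)
            stop = n
        exercise[k:stop] = True
        lo = k if include_span_start_carb else k + 1
        hi = min(k + T[k] + 1, n)
        if lo < hi and np.any(cho[lo:hi] != 0):
            with_meal[k:stop] = True

    classes = np.full(n, C00, dtype=np.int8)
    classes[(~exercise) & (cho != 0)] = C10
    classes[exercise & ~with_meal] = C01
    classes[exercise & with_meal] = C11
    return EventLabels(classes=classes, T=T)


def event_probability_profile(series: GriddedSeries, labels: EventLabels,
                              bin_minutes: int = 60) -> np.ndarray:
    """Empirical class frequencies per time-of-day bin (rows sum to 1)."""
    if labels.n * series.step < 7 * 86400:
        raise ValueError("need at least 7 labeled days for a daily profile")
    sod = series.seconds_of_day()
    bins = (sod // (bin_minutes * 60)).astype(int)
    n_bins = int(np.ceil(86400 / (bin_minutes * 60)))
    prof = np.zeros((n_bins, 4))
    for b in range(n_bins):
        sel = bins == b
        if sel.any():
            for c in range(4):
                prof[b, c] = np.mean(labels.classes[sel] == c)
    return prof
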