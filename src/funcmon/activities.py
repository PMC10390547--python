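"""Component 1 — ICF category Activities and Participation.

Predicts mobility assessment scores from wearable IMU windows and flags
qualifier changes between consecutive monthly periods:

* d450 Walking        <- TUG category, predicted per 1-s window
* d460 Moving around  <- SPPB points,  predicted per 1-s window

Per-window magnitudes (Euclidean norm of the three axes) of the
low-range accelerometer, wide-range accelerometer, gyroscope and
magnetometer are reduced to summary features; a pluggable
:class:`ScorePredictor` turns feature sequences into per-window scores,
which a majority vote aggregates to one score per interval. The
reference study used deep networks for this prediction step; here the
contract is filled by :class:`AmplitudeThresholdPredictor`, a
transparent heuristic whose thresholds are the midpoints of the gait
amplitude ladder used by the bundled household simulator.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Protocol, Sequence

import numpy as np

from .core import ComponentOutput, Direction, ImuWindow, IMU_MODALITIES
from .icf import IcfLinkTable, icf_change, sppb_to_icf, tug_category_to_icf


def imu_magnitude(window: ImuWindow) -> "dict[str, np.ndarray]":
    """Per-modality magnitude series: sqrt(x^2 + y^2 + z^2) per sample."""
    return {
        mod: np.linalg.norm(window.samples[mod], axis=1) for mod in IMU_MODALITIES
    }


@dataclass(frozen=True)
class ImuFeatureVector:
    """Summary statistics of the magnitude series of one window.

    Per modality: mean, standard deviation, peak, and a dominant-frequency
    proxy (mean-crossing rate of the centred magnitude, in Hz).
    """

    mean: "dict[str, float]"
    std: "dict[str, float]"
    peak: "dict[str, float]"
    freq_hz: "dict[str, float]"

    def __post_init__(self) -> None:
        for d in (self.mean, self.std, self.peak, self.freq_hz):
            for mod, v in d.items():
                if not np.isfinite(v):
                    raise ValueError(f"non-finite feature for {mod!r}")


def extract_features(window: ImuWindow) -> ImuFeatureVector:
    """Reduce one IMU window to its magnitude feature vector."""
    mags = imu_magnitude(window)
    mean, std, peak, freq = {}, {}, {}, {}
    for mod, m in mags.items():
        mean[mod] = float(np.mean(m))
        std[mod] = float(np.std(m))
        peak[mod] = float(np.max(m))
        centred = m - np.mean(m)
        crossings = int(np.count_nonzero(np.diff(np.signbit(centred))))
        # two mean-crossings per oscillation cycle
        freq[mod] = crossings / (2.0 * window.duration)
    return ImuFeatureVector(mean=mean, std=std, peak=peak, freq_hz=freq)


class ScorePredictor(Protocol):
    """Contract for per-window assessment-score prediction.

    Implementations must be deterministic given the features and their
    own fixed internal state, and must keep outputs in range (SPPB
    0-12, TUG category 1-4).
    """

    def predict_sppb(self, features: Sequence[ImuFeatureVector]) -> np.ndarray: ...

    def predict_tug_category(self, features: Sequence[ImuFeatureVector]) -> np.ndarray: ...


#: Gait-oscillation amplitude (g) of the low-range accelerometer magnitude
#: at TUG categories 1..4 in the simulator; brisker walkers swing harder.
TUG_AMPLITUDE_LADDER = {1: 0.80, 2: 0.55, 3: 0.35, 4: 0.15}

#: Wide-range accelerometer amplitude encodes SPPB: base + step * points.
SPPB_AMPLITUDE_BASE = 0.10
SPPB_AMPLITUDE_STEP = 0.05

_SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class AmplitudeThresholdPredictor:
    """Heuristic :class:`ScorePredictor` thresholding gait amplitude.

    A sinusoidal oscillation of amplitude A superposed on gravity gives a
    magnitude standard deviation of ~A/sqrt(2); the decision thresholds
    are midpoints between the amplitude ladder rungs. ``tug_thresholds``
    are descending std cut-points for categories 1|2|3|4.
    """

    tug_thresholds: tuple = tuple(
        (TUG_AMPLITUDE_LADDER[c] + TUG_AMPLITUDE_LADDER[c + 1]) / 2.0 / _SQRT2
        for c in (1, 2, 3)
    )

    def predict_tug_category(self, features: Sequence[ImuFeatureVector]) -> np.ndarray:
        stds = np.array([f.std["acc_low"] for f in features])
        cats = np.full(len(stds), len(self.tug_thresholds) + 1, dtype=int)
        for i, thr in enumerate(self.tug_thresholds, start=1):
            cats[(cats == len(self.tug_thresholds) + 1) & (stds >= thr)] = i
        return cats

    def predict_sppb(self, features: Sequence[ImuFeatureVector]) -> np.ndarray:
        stds = np.array([f.std["acc_wide"] for f in features])
        pts = np.rint((stds * _SQRT2 - SPPB_AMPLITUDE_BASE) / SPPB_AMPLITUDE_STEP)
        return np.clip(pts, 0, 12).astype(int)


def aggregate_interval(
    predictions: Sequence[int],
    interval_len: int,
    *,
    worse: Callable[[Iterable[int]], int] = max,
) -> "list[int]":
    """Majority-vote per-window scores down to one score per interval.

    Ties break toward the more impaired score (``worse``); for TUG
    categories that is :func:`max`, for SPPB pass ``worse=min``. The last
    interval may be shorter than ``interval_len``.
    """
    if interval_len < 1:
        raise ValueError("interval_len must be >= 1")
    preds = list(predictions)
    if not preds:
        raise ValueError("predictions must be non-empty")
    out = []
    for i in range(0, len(preds), interval_len):
        chunk = preds[i : i + interval_len]
        counts = Counter(chunk)
        top = max(counts.values())
        out.append(worse(s for s, c in counts.items() if c == top))
    return out


@dataclass(frozen=True)
class PeriodScores:
    """Aggregated assessment scores for one monitoring period.

    Either field may be ``None`` when neither IMU windows nor an
    assessment fallback value exist for the period.
    """

    sppb: Optional[int] = None
    tug_category: Optional[int] = None


def detect_change_c1(
    prev: PeriodScores,
    curr: PeriodScores,
    link: Optional[IcfLinkTable] = None,
    *,
    period: tuple = (0, 1),
) -> ComponentOutput:
    """Flag an ICF qualifier change in d450 (TUG) or d460 (SPPB).

    The flag is 1 iff either score's qualifier differs between the two
    periods; changed items are attributed. When both items change in
    opposite directions the reported direction is deterioration (the
    component errs toward sensitivity). A modality missing in either
    period is skipped; with both modalities missing the output is marked
    unavailable.
    """
    link = link or IcfLinkTable()
    items: set = set()
    directions: list = []
    evaluated = False

    if prev.tug_category is not None and curr.tug_category is not None:
        evaluated = True
        changed, direction = icf_change(
            tug_category_to_icf(prev.tug_category, link),
            tug_category_to_icf(curr.tug_category, link),
        )
        if changed:
            items.add("d450")
            directions.append(direction)
    if prev.sppb is not None and curr.sppb is not None:
        evaluated = True
        changed, direction = icf_change(
            sppb_to_icf(prev.sppb, link), sppb_to_icf(curr.sppb, link)
        )
        if changed:
            items.add("d460")
            directions.append(direction)

    if not evaluated:
        return ComponentOutput(component=1, flag=0, period=period, available=False)

    if not items:
        return ComponentOutput(component=1, flag=0, period=period)
    direction = (
        Direction.DETERIORATION
        if Direction.DETERIORATION in directions
        else Direction.IMPROVEMENT
    )
    return ComponentOutput(
        component=1, flag=1, icf_items=frozenset(items), direction=direction, period=period
    )
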