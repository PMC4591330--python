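"""Driving-simulator outcome measures.

A four-minute simulated drive on a winding country road yields two kinds of
raw data per visit:

* telemetry — uniformly sampled road curvature ``k_road`` and driven vehicle
  path curvature ``k_own`` (1/m), from which the central-task performance
  metric *curve coherence* is computed: the maximum over delay shifts of the
  normalized cross-correlation between the two curvature signals (1 = the
  driver tracked the road perfectly, after allowing for their reaction lag);
* a stimulus/response event log — peripheral divided-attention stimuli at two
  Michelson contrast levels with button-press latencies, from which mean
  reaction times per contrast, the corrected (low minus high) reaction time
  and a false-positive rate are computed.

All metrics are per-visit scalars suitable for use as time-dependent
covariates in a survival model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "TelemetryTrace",
    "StimulusEvent",
    "StimulusEventLog",
    "SimulatorMetrics",
    "DegenerateSignalError",
    "curve_coherence",
    "coherence_profile",
    "mean_reaction_time",
    "corrected_reaction_time",
    "false_positive_rate",
    "miss_rate",
    "michelson_contrast",
    "solve_background_intensity",
    "assign_button_presses",
    "compute_metrics",
]

LOW = "low"
HIGH = "high"


class DegenerateSignalError(ValueError):
    """Raised when a coherence computation meets a constant (zero-SD) signal."""


@dataclass(frozen=True)
class TelemetryTrace:
    """Uniformly sampled road and vehicle-path curvature for one drive.

    Parameters
    ----------
    sample_times : array of float
        Sample times in seconds, uniformly spaced.
    k_road, k_own : array of float
        Road curvature and driven path curvature (1/m) at each sample.
    """

    sample_times: np.ndarray
    k_road: np.ndarray
    k_own: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.sample_times, dtype=float)
        kr = np.asarray(self.k_road, dtype=float)
        ko = np.asarray(self.k_own, dtype=float)
        if not (len(t) == len(kr) == len(ko)):
            raise ValueError("sample_times, k_road and k_own must have equal length")
        if len(t) < 2:
            raise ValueError("telemetry needs at least two samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("telemetry must be uniformly sampled")
        object.__setattr__(self, "sample_times", t)
        object.__setattr__(self, "k_road", kr)
        object.__setattr__(self, "k_own", ko)

    @property
    def dt(self) -> float:
        return float(self.sample_times[1] - self.sample_times[0])

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.dt

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.sample_times, "k_road": self.k_road, "k_own": self.k_own}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TelemetryTrace":
        return cls(
            sample_times=df["time_s"].to_numpy(),
            k_road=df["k_road"].to_numpy(),
            k_own=df["k_own"].to_numpy(),
        )


@dataclass(frozen=True)
class StimulusEvent:
    """One peripheral stimulus presentation.

    ``response_latency`` is seconds from onset to button press, or ``None``
    for a miss (no press before the maximum display time elapsed).
    """

    onset: float
    contrast: str
    display_max: float
    response_latency: float | None

    def __post_init__(self):
        if self.contrast not in (LOW, HIGH):
            raise ValueError(f"contrast must be {LOW!r} or {HIGH!r}")
        if self.response_latency is not None and not self.response_latency > 0:
            raise ValueError("response_latency must be positive when present")

    @property
    def responded(self) -> bool:
        return self.response_latency is not None

    @property
    def offset(self) -> float:
        """Time the stimulus left the screen (response or timeout)."""
        if self.responded:
            return self.onset + min(self.response_latency, self.display_max)
        return self.onset + self.display_max


@dataclass(frozen=True)
class StimulusEventLog:
    """Stimulus presentations plus button presses not tied to any stimulus."""

    events: tuple[StimulusEvent, ...]
    spurious_presses: tuple[float, ...] = ()

    def __post_init__(self):
        events = tuple(self.events)
        onsets = [e.onset for e in events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("stimulus onsets must be strictly increasing")
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "spurious_presses", tuple(self.spurious_presses))

    @property
    def n_presented(self) -> int:
        return len(self.events)

    def at_contrast(self, contrast: str) -> tuple[StimulusEvent, ...]:
        return tuple(e for e in self.events if e.contrast == contrast)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "onset_s": e.onset,
                "contrast": e.contrast,
                "display_max_s": e.display_max,
                "response_s": e.response_latency if e.responded else np.nan,
                "is_spurious": False,
            }
            for e in self.events
        ]
        rows += [
            {
                "onset_s": t,
                "contrast": "",
                "display_max_s": np.nan,
                "response_s": np.nan,
                "is_spurious": True,
            }
            for t in self.spurious_presses
        ]
        return pd.DataFrame(
            rows,
            columns=["onset_s", "contrast", "display_max_s", "response_s", "is_spurious"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StimulusEventLog":
        stim = df[~df["is_spurious"].astype(bool)].sort_values("onset_s")
        events = tuple(
            StimulusEvent(
                onset=float(r.onset_s),
                contrast=str(r.contrast),
                display_max=float(r.display_max_s),
                response_latency=None if pd.isna(r.response_s) else float(r.response_s),
            )
            for r in stim.itertuples()
        )
        spurious = tuple(
            float(t) for t in df.loc[df["is_spurious"].astype(bool), "onset_s"]
        )
        return cls(events=events, spurious_presses=spurious)


@dataclass(frozen=True)
class SimulatorMetrics:
    """Per-visit scalar outcome measures from one simulated drive."""

    rt_low: float
    rt_high: float
    rt_corrected: float
    curve_coherence: float
    false_positive_rate: float
    miss_rate_low: float
    miss_rate_high: float

    def as_dict(self) -> dict[str, float]:
        return {
            "rt_low": self.rt_low,
            "rt_high": self.rt_high,
            "rt_corrected": self.rt_corrected,
            "curve_coherence": self.curve_coherence,
            "false_positive_rate": self.false_positive_rate,
            "miss_rate_low": self.miss_rate_low,
            "miss_rate_high": self.miss_rate_high,
        }


def _window_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson-type correlation with population (1/n) normalization.

    Means and SDs are recomputed on the supplied window so that an exact
    match always scores 1 regardless of the shift applied upstream.
    """
    a = a - a.mean()
    b = b - b.mean()
    sa = np.sqrt(np.mean(a * a))
    sb = np.sqrt(np.mean(b * b))
    if sa == 0.0 or sb == 0.0:
        return -np.inf  # window carries no signal; cannot contribute a max
    return float(np.mean(a * b) / (sa * sb))


def coherence_profile(trace: TelemetryTrace, max_delay: int) -> np.ndarray:
    """Normalized cross-correlation at each delay shift d = 0 .. max_delay.

    At delay ``d`` the driven path ``k_own[d:]`` is compared with the road
    ``k_road[:-d]``: the driver is modelled as lagging the road, so only
    non-negative shifts are searched.  Statistics use the overlapping window.
    """
    n = len(trace.k_road)
    if not max_delay >= 0:
        raise ValueError("max_delay must be non-negative")
    if max_delay >= n / 2:
        raise ValueError(f"max_delay={max_delay} too large for signal length {n}")
    if np.std(trace.k_road) == 0.0 or np.std(trace.k_own) == 0.0:
        raise DegenerateSignalError("coherence undefined for constant signal")
    out = np.empty(max_delay + 1)
    for d in range(max_delay + 1):
        own = trace.k_own[d:]
        road = trace.k_road[: n - d]
        out[d] = _window_corr(own, road)
    return out


def curve_coherence(trace: TelemetryTrace, max_delay: int | None = None) -> float:
    """Maximum over delay shifts of the normalized cross-correlation
    between road curvature and driven path curvature.

    A value of 1 means the two curvature signals are an exact match after
    shifting; a driver who neglects the central curve-negotiation task scores
    lower.  The default search window is 5 seconds of samples.

    Returns a value in [-1, 1].
    """
    if max_delay is None:
        max_delay = int(round(5.0 * trace.sample_rate))
        max_delay = min(max_delay, (len(trace.k_road) - 1) // 2)
    prof = coherence_profile(trace, max_delay)
    return float(np.max(prof))


def mean_reaction_time(log: StimulusEventLog, contrast: str) -> float:
    """Arithmetic mean button-press latency at one contrast level.

    Misses are excluded from the mean (they are tallied by
    :func:`miss_rate`).  Returns NaN when no presentation at this contrast
    was responded to, so the undefined metric propagates as a missing value.
    """
    lat = [e.response_latency for e in log.at_contrast(contrast) if e.responded]
    if not lat:
        return float("nan")
    return float(np.mean(lat))


def corrected_reaction_time(rt_low: float, rt_high: float) -> float:
    """Low-contrast minus high-contrast mean reaction time (seconds).

    Subtracting the two isolates the visual-processing component: the motor
    act of pressing the button contributes equally at both contrasts.
    """
    return rt_low - rt_high


def miss_rate(log: StimulusEventLog, contrast: str) -> float:
    events = log.at_contrast(contrast)
    if not events:
        return float("nan")
    return sum(not e.responded for e in events) / len(events)


def false_positive_rate(log: StimulusEventLog) -> float:
    """Button presses with no stimulus on screen, per stimulus presented.

    The denominator is the number of stimuli, not the number of press
    opportunities, so the rate can exceed 1.
    """
    if log.n_presented == 0:
        raise ValueError("false-positive rate undefined with no stimuli presented")
    return len(log.spurious_presses) / log.n_presented


def assign_button_presses(
    stimuli: Sequence[tuple[float, float]], press_times: Iterable[float]
) -> tuple[dict[int, float], list[float]]:
    """Attribute raw button presses to stimuli.

    Each press is attributed to the earliest still-unanswered stimulus that is
    on screen at press time (``onset <= t < onset + display_max``); presses
    matching no such stimulus are spurious.

    Parameters
    ----------
    stimuli : sequence of (onset, display_max)
    press_times : iterable of press times, any order

    Returns
    -------
    responses : dict mapping stimulus index -> response latency (s)
    spurious : list of unattributed press times
    """
    responses: dict[int, float] = {}
    spurious: list[float] = []
    for t in sorted(press_times):
        for i, (onset, display_max) in enumerate(stimuli):
            if i in responses:
                continue
            if onset <= t < onset + display_max:
                responses[i] = t - onset
                break
        else:
            spurious.append(t)
    return responses, spurious


def michelson_contrast(
    symbol_alpha: float, symbol_intensity: float, background_intensity: float
) -> float:
    """Michelson contrast of an alpha-blended stimulus against its background.

    The displayed luminance is ``alpha * symbol + (1 - alpha) * background``
    (alpha-blending: at transparency 0.9 the driver perceives 90% of the
    symbol intensity and 10% of the background).  Contrast is
    ``|displayed - background| / (displayed + background)``.
    """
    for name, v in (
        ("symbol_alpha", symbol_alpha),
        ("symbol_intensity", symbol_intensity),
        ("background_intensity", background_intensity),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    displayed = symbol_alpha * symbol_intensity + (1.0 - symbol_alpha) * background_intensity
    denom = displayed + background_intensity
    if denom == 0.0:
        raise ValueError("Michelson contrast undefined: zero total luminance")
    return abs(displayed - background_intensity) / denom


def solve_background_intensity(
    symbol_alpha: float, target_contrast: float, symbol_intensity: float = 1.0
) -> float:
    """Background luminance at which the given alpha-blend has the target
    Michelson contrast (root-solved on [1e-9, 1])."""

    def f(b: float) -> float:
        return michelson_contrast(symbol_alpha, symbol_intensity, b) - target_contrast

    return float(brentq(f, 1e-9, 1.0 - 1e-12))


def compute_metrics(
    trace: TelemetryTrace, log: StimulusEventLog, max_delay: int | None = None
) -> SimulatorMetrics:
    """All per-visit simulator metrics from one drive's telemetry + event log."""
    rt_low = mean_reaction_time(log, LOW)
    rt_high = mean_reaction_time(log, HIGH)
    return SimulatorMetrics(
        rt_low=rt_low,
        rt_high=rt_high,
        rt_corrected=corrected_reaction_time(rt_low, rt_high),
        curve_coherence=curve_coherence(trace, max_delay=max_delay),
        false_positive_rate=false_positive_rate(log),
        miss_rate_low=miss_rate(log, LOW),
        miss_rate_high=miss_rate(log, HIGH),
    )
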