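"""Ratiometric (fura-2) calcium trace processing and responder calling.

Traces carry two fluorescence channels sampled every few seconds: emission
under 340 nm excitation (calcium-bound dye) and under 380 nm (calcium-free).
The ratio R = F340/F380 tracks intracellular calcium independently of dye
loading; a response is the peak fractional rise of R over its pre-stimulus
baseline, dR/R0 x 100, expressed as a percent.

A trace is a responder when its peak response reaches the threshold and its
onset falls within `max_latency` of stimulus onset.  The baseline defaults
to the mean ratio over all pre-stimulus samples for noise robustness;
`r0_at_t0` restores the literal single-sample definition R0 = R(t=0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

RESPONDER_THRESHOLD_DEFAULT = 20.0  # % dR/R0
MAX_LATENCY_DEFAULT = 30.0          # s after stimulus onset


@dataclass
class CalciumTrace:
    trace_id: str
    time: np.ndarray   # seconds
    f340: np.ndarray
    f380: np.ndarray
    stimulus_window: tuple[float, float]  # (t_on, t_off) seconds

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.f340 = np.asarray(self.f340, dtype=float)
        self.f380 = np.asarray(self.f380, dtype=float)
        if not (len(self.time) == len(self.f340) == len(self.f380)):
            raise ValueError("time and channel arrays must have equal length")
        if np.any(self.f380 <= 0):
            raise ValueError("f380 must be > 0 everywhere")
        t_on, t_off = self.stimulus_window
        if not (self.time[0] <= t_on < t_off <= self.time[-1]):
            raise ValueError("stimulus window must satisfy t_on < t_off inside the recording")


@dataclass
class ResponseCall:
    trace_id: str
    r0: float
    peak_percent: float     # peak dR/R0 x 100 after stimulus onset
    responder: bool
    onset_latency: float    # s from t_on to threshold crossing (nan if none)
    duration: float         # s above half-peak (0 if no response)


def ratio_trace(trace: CalciumTrace) -> np.ndarray:
    """R(t) = F340(t) / F380(t)."""
    return trace.f340 / trace.f380


def baseline(ratio: np.ndarray, time: np.ndarray, t_on: float,
             r0_at_t0: bool = False) -> float:
    """Baseline ratio R0 over the pre-stimulus window.

    Default: mean of all samples strictly before t_on; with `r0_at_t0`, the
    single sample at the start of the recording.
    """
    if r0_at_t0:
        return float(ratio[0])
    pre = ratio[time < t_on]
    if pre.size == 0:
        return float(ratio[0])
    return float(pre.mean())


def response_percent(ratio: np.ndarray, r0: float, time: np.ndarray,
                     t_on: float) -> float:
    """Peak dR/R0 x 100 over the post-stimulus-onset window."""
    if r0 <= 0:
        raise ValueError("baseline ratio must be > 0")
    post = ratio[time >= t_on]
    if post.size == 0:
        raise ValueError("no samples at or after stimulus onset")
    return float((post.max() - r0) / r0 * 100.0)


def call_response(
    trace: CalciumTrace,
    threshold: float = RESPONDER_THRESHOLD_DEFAULT,
    max_latency: float = MAX_LATENCY_DEFAULT,
    r0_at_t0: bool = False,
) -> ResponseCall:
    """Compute baseline, peak response, onset latency and duration for one trace."""
    t_on, _ = trace.stimulus_window
    r = ratio_trace(trace)
    r0 = baseline(r, trace.time, t_on, r0_at_t0=r0_at_t0)
    pct = (r - r0) / r0 * 100.0
    post = trace.time >= t_on
    peak = float(pct[post].max())

    crossing = post & (pct >= threshold)
    if crossing.any():
        onset_t = float(trace.time[crossing][0])
        latency = onset_t - t_on
    else:
        latency = float("nan")

    responder = peak >= threshold and np.isfinite(latency) and latency <= max_latency

    # duration: time spent above half the peak response, after onset
    duration = 0.0
    if peak > 0:
        above = post & (pct >= peak / 2.0)
        if above.sum() >= 2:
            t_above = trace.time[above]
            duration = float(t_above[-1] - t_above[0])
        elif above.any():
            duration = 0.0
    return ResponseCall(trace.trace_id, r0, peak, bool(responder), latency, duration)


def classify_responder(call: ResponseCall, threshold: float = RESPONDER_THRESHOLD_DEFAULT,
                       max_latency: float = MAX_LATENCY_DEFAULT) -> bool:
    """Responder iff the peak reaches threshold with onset inside the latency window."""
    return (
        call.peak_percent >= threshold
        and np.isfinite(call.onset_latency)
        and call.onset_latency <= max_latency
    )


def summarize_population(calls: list[ResponseCall]) -> dict[str, float]:
    """Responder fraction (%, one decimal) and amplitude mean +/- SD over responders."""
    if not calls:
        raise ValueError("empty population")
    responders = [c for c in calls if c.responder]
    frac = round(len(responders) / len(calls) * 100.0, 1)
    if responders:
        amps = np.array([c.peak_percent for c in responders])
        mean_amp = float(amps.mean())
        sd_amp = float(amps.std(ddof=1)) if len(amps) > 1 else 0.0
    else:
        mean_amp, sd_amp = float("nan"), float("nan")
    return {
        "n_total": len(calls),
        "n_responders": len(responders),
        "responder_percent": frac,
        "mean_amplitude": mean_amp,
        "sd_amplitude": sd_amp,
    }
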