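"""Amplitude-envelope rise-time analysis of synthesized syllables.

The analysis unit is the pitch period.  The waveform is segmented into
glottal cycles (either from the known F0 contour or by local
autocorrelation), an RMS value is computed per period, the syllable's
amplitude peak is located, and the peak RMS is taken over the five periods
centered on it.  Scanning the periods from syllable onset, the first one
whose RMS reaches 80 % of that peak value marks the end of the amplitude
rise; the rise time is the interval from the syllable's onset (t = 0) to
the end of that period.

The VOT continuum (/ga/-/ka/) is excluded from this analysis by
construction: its envelope is the VOT manipulation itself, so a rise-time
summary would merely restate the stimulus dimension.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .continua import ContinuumSpec
from .synthesis import ParameterError, Waveform, make_f0_contour, synthesize

__all__ = [
    "PitchPeriodSegmentation",
    "RiseTimeResult",
    "segment_pitch_periods",
    "period_rms",
    "rms_window_at_peak",
    "rise_time",
    "continuum_rise_times",
    "AnalysisError",
]

RISE_FRACTION = 0.80
PEAK_WINDOW_PERIODS = 5

ENVELOPE_CONTINUA = ("ba_da", "ba_wa")


class AnalysisError(RuntimeError):
    pass


@dataclass(frozen=True)
class PitchPeriodSegmentation:
    """Sample indices delimiting consecutive pitch periods."""

    boundaries: tuple[int, ...]  # len = n_periods + 1, strictly increasing
    method: str  # "from_known_f0" | "autocorrelation"
    sample_rate_hz: int

    @property
    def n_periods(self) -> int:
        return len(self.boundaries) - 1

    def period_slice(self, i: int) -> slice:
        return slice(self.boundaries[i], self.boundaries[i + 1])

    def period_end_s(self, i: int) -> float:
        return self.boundaries[i + 1] / self.sample_rate_hz


@dataclass(frozen=True)
class RiseTimeResult:
    peak_period_index: int
    peak_rms: float
    rise_end_period_index: int
    rise_time_s: float
    truncated_window: bool  # peak within 2 periods of an edge
    no_pre_peak_crossing: bool  # no period before the peak reached 80 %


def _boundaries_from_f0(
    f0_per_sample: np.ndarray, fs: float, start: int, end: int
) -> list[int]:
    # integrate instantaneous frequency; a boundary at each whole cycle
    bounds = [start]
    phase = 0.0
    for i in range(start, end):
        phase += f0_per_sample[i] / fs
        if phase >= 1.0 - 1e-9:  # tolerance for accumulated float error
            bounds.append(i + 1)
            phase -= 1.0
    return bounds


def _boundaries_by_autocorr(
    x: np.ndarray, fs: float, start: int, end: int
) -> list[int]:
    # local period tracking: at each boundary, pick the lag maximizing the
    # normalized autocorrelation of a two-period window around the
    # previous period estimate
    from .synthesis import estimate_f0

    # seed the tracker from a short quasi-stationary window at the center
    # of the voiced region; a whole-syllable window smears the pitch peak
    # of the declining contour and can lock onto first-formant ringing
    mid = (start + end) // 2
    half_w = int(0.025 * fs)
    center = x[max(start, mid - half_w) : min(end, mid + half_w)]
    f0_global = estimate_f0(center, fs, fmin=60.0, fmax=250.0)
    period = fs / f0_global
    bounds = [start]
    pos = start
    while pos + 1.5 * period < end:
        win = x[pos : min(pos + int(2.5 * period), end)]
        lo = max(int(0.7 * period), 2)
        hi = min(int(1.4 * period), len(win) - 1)
        if hi <= lo:
            break
        w = win - np.mean(win)
        r = np.correlate(w, w, mode="full")[len(w) - 1 :]
        if r[0] <= 0:
            break
        lag = lo + int(np.argmax(r[lo:hi] / r[0]))
        pos += lag
        period = 0.7 * period + 0.3 * lag  # smooth the local estimate
        bounds.append(pos)
    return bounds


def segment_pitch_periods(
    w: Waveform,
    f0_track: np.ndarray | None = None,
    method: str = "from_known_f0",
    voicing_onset_s: float = 0.0,
) -> PitchPeriodSegmentation:
    """Delimit the glottal cycles of the voiced portion.

    ``from_known_f0`` integrates the supplied per-sample F0 track (cycle
    boundaries at whole-phase crossings); ``autocorrelation`` tracks the
    local period directly from the waveform and needs no track.
    """
    fs = w.sample_rate_hz
    start = int(round(voicing_onset_s * fs))
    end = len(w.samples)
    if end - start < fs * 0.005:
        raise AnalysisError("no voiced portion to segment")
    if method == "from_known_f0":
        if f0_track is None:
            raise ParameterError("from_known_f0 requires an f0_track")
        bounds = _boundaries_from_f0(np.asarray(f0_track, float), fs, start, end)
    elif method == "autocorrelation":
        bounds = _boundaries_by_autocorr(np.asarray(w.samples, float), fs, start, end)
    else:
        raise ParameterError(f"unknown segmentation method {method!r}")
    if len(bounds) < 3:
        raise AnalysisError("could not segment at least two pitch periods")
    return PitchPeriodSegmentation(
        boundaries=tuple(bounds), method=method, sample_rate_hz=fs
    )


def period_rms(w: Waveform, seg: PitchPeriodSegmentation) -> np.ndarray:
    """RMS amplitude of each pitch period."""
    x = np.asarray(w.samples, float)
    return np.array(
        [np.sqrt(np.mean(x[seg.period_slice(i)] ** 2)) for i in range(seg.n_periods)]
    )


def rms_window_at_peak(
    w: Waveform, seg: PitchPeriodSegmentation
) -> tuple[int, float, bool]:
    """Locate the period holding the amplitude peak; RMS over 5 periods.

    Returns ``(peak_period_index, peak_rms, truncated)`` where ``peak_rms``
    is the RMS over the peak period and its two neighbours on each side
    (fewer near an edge, flagged via ``truncated``).
    """
    if seg.n_periods < PEAK_WINDOW_PERIODS:
        raise AnalysisError(
            f"need at least {PEAK_WINDOW_PERIODS} pitch periods, "
            f"got {seg.n_periods}"
        )
    x = np.asarray(w.samples, float)
    lo_b, hi_b = seg.boundaries[0], seg.boundaries[-1]
    peak_sample = lo_b + int(np.argmax(np.abs(x[lo_b:hi_b])))
    bounds = np.asarray(seg.boundaries)
    peak_idx = int(np.searchsorted(bounds, peak_sample, side="right") - 1)
    peak_idx = min(max(peak_idx, 0), seg.n_periods - 1)

    half = PEAK_WINDOW_PERIODS // 2
    first = max(peak_idx - half, 0)
    last = min(peak_idx + half, seg.n_periods - 1)
    truncated = (last - first + 1) < PEAK_WINDOW_PERIODS
    window = x[seg.boundaries[first] : seg.boundaries[last + 1]]
    return peak_idx, float(np.sqrt(np.mean(window**2))), truncated


def rise_time(w: Waveform, seg: PitchPeriodSegmentation) -> RiseTimeResult:
    """Amplitude rise time per the per-period 80 %-of-peak-RMS criterion."""
    peak_idx, peak, truncated = rms_window_at_peak(w, seg)
    rms = period_rms(w, seg)
    rise_end = peak_idx
    no_crossing = True
    for i in range(peak_idx + 1):
        if rms[i] >= RISE_FRACTION * peak:
            rise_end = i
            no_crossing = False
            break
    return RiseTimeResult(
        peak_period_index=peak_idx,
        peak_rms=peak,
        rise_end_period_index=rise_end,
        rise_time_s=seg.period_end_s(rise_end),
        truncated_window=truncated,
        no_pre_peak_crossing=no_crossing,
    )


def continuum_rise_times(
    continuum: ContinuumSpec,
    method: str = "from_known_f0",
    seed: int = 0,
    csv_path: str | Path | None = None,
):
    """Rise-time report for every step of an envelope-analysed continuum.

    Returns a list of dicts (step, dimension value, rise_time_ms,
    peak_rms, n_periods); optionally written as CSV.  Only the /ba/-/da/
    and /ba/-/wa/ continua are accepted (see module notes on /ga/-/ka/).
    """
    if continuum.name not in ENVELOPE_CONTINUA:
        raise ParameterError(
            f"envelope analysis is defined for {ENVELOPE_CONTINUA}, "
            f"not {continuum.name!r}"
        )
    rows = []
    for k, spec in enumerate(continuum.syllables):
        w = synthesize(spec, seed=seed + k)
        f0_track = make_f0_contour(spec) if method == "from_known_f0" else None
        seg = segment_pitch_periods(
            w, f0_track=f0_track, method=method, voicing_onset_s=spec.vot_s
        )
        rt = rise_time(w, seg)
        rows.append(
            dict(
                step=k,
                value=continuum.value_at(k),
                unit=continuum.unit,
                rise_time_ms=rt.rise_time_s * 1000.0,
                peak_rms=rt.peak_rms,
                n_periods=seg.n_periods,
            )
        )
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            wtr = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            wtr.writeheader()
            wtr.writerows(rows)
    return rows
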