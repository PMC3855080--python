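"""Cascade formant synthesis of consonant-vowel syllables.

The voiced source is an impulse train whose instantaneous rate follows a
linearly declining fundamental-frequency contour.  The train is shaped by a
critically damped glottal low-pass (a zero-frequency resonator), driven
through a cascade of five time-varying second-order formant resonators, and
differentiated once at the output to model lip radiation.  Voice onset time
is realised by replacing the periodic source with low-level aspiration
noise for the initial interval; voicing offset is a linear amplitude ramp
over the final portion of the syllable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "F0Contour",
    "FormantTrack",
    "SyllableSpec",
    "Waveform",
    "make_f0_contour",
    "synthesize",
    "apply_voicing_ramp",
    "write_wav",
    "read_wav",
    "estimate_f0",
    "estimate_f0_endpoints",
    "periodicity_strength",
    "estimate_formants",
    "export_spectrogram",
]

DEFAULT_SAMPLE_RATE = 16_000
#: aspiration level relative to the shaped voiced source, in dB
ASPIRATION_REL_DB = -20.0
#: glottal low-pass bandwidth (Hz); two cascaded zero-frequency resonator
#: poles give roughly -12 dB/oct source tilt, +6 dB/oct radiation nets -6
GLOTTAL_BW_HZ = 100.0


class ParameterError(ValueError):
    """Raised when a synthesis spec violates its invariants."""


@dataclass(frozen=True)
class F0Contour:
    """Linear fundamental-frequency decline over the syllable."""

    onset_hz: float = 120.0
    offset_hz: float = 90.0
    duration_s: float = 0.200

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ParameterError("F0 contour duration must be positive")
        if self.onset_hz <= 0 or self.offset_hz <= 0:
            raise ParameterError("F0 values must be positive")


@dataclass(frozen=True)
class FormantTrack:
    """Piecewise-linear trajectory of one formant.

    The frequency moves linearly from ``onset_hz`` to ``target_hz`` over
    ``[0, transition_end_s]``, stays at the target until ``late_change_s``,
    then (if ``late_target_hz`` is set) moves linearly to the late target
    by the end of the syllable.  Bandwidth is constant.
    """

    onset_hz: float
    target_hz: float
    bandwidth_hz: float
    transition_end_s: float
    late_target_hz: float | None = None
    late_change_s: float = 0.180

    def __post_init__(self) -> None:
        if min(self.onset_hz, self.target_hz, self.bandwidth_hz) <= 0:
            raise ParameterError("formant frequencies and bandwidth must be positive")
        if not 0 < self.transition_end_s < self.late_change_s:
            raise ParameterError("need 0 < transition_end_s < late_change_s")

    def frequency_at(self, t: np.ndarray, duration_s: float) -> np.ndarray:
        f = np.full_like(t, self.target_hz, dtype=float)
        early = t < self.transition_end_s
        f[early] = self.onset_hz + (self.target_hz - self.onset_hz) * (
            t[early] / self.transition_end_s
        )
        if self.late_target_hz is not None:
            late = t >= self.late_change_s
            span = max(duration_s - self.late_change_s, 1e-9)
            f[late] = self.target_hz + (self.late_target_hz - self.target_hz) * (
                (t[late] - self.late_change_s) / span
            )
        return f


@dataclass(frozen=True)
class SyllableSpec:
    """Complete parametric recipe for one synthetic syllable."""

    label: str
    formants: tuple[FormantTrack, ...]
    f0: F0Contour = field(default_factory=F0Contour)
    duration_s: float = 0.200
    vot_s: float = 0.0
    voicing_ramp_s: float = 0.020
    sample_rate_hz: int = DEFAULT_SAMPLE_RATE
    vot_aspiration: bool = True

    def __post_init__(self) -> None:
        if len(self.formants) != 5:
            raise ParameterError("exactly five formant tracks are required")
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ParameterError("duration and sample rate must be positive")
        if self.vot_s < 0 or self.vot_s >= self.duration_s:
            raise ParameterError("VOT must lie within the syllable")
        if self.voicing_ramp_s < 0 or self.voicing_ramp_s > self.duration_s:
            raise ParameterError("voicing ramp must fit in the syllable")
        nyquist = self.sample_rate_hz / 2
        for tr in self.formants:
            for f in (tr.onset_hz, tr.target_hz, tr.late_target_hz or tr.target_hz):
                if f >= nyquist:
                    raise ParameterError(
                        f"formant frequency {f} Hz at or above Nyquist ({nyquist} Hz)"
                    )

    @property
    def n_samples(self) -> int:
        return round(self.duration_s * self.sample_rate_hz)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyllableSpec":
        d = json.loads(text)
        d["formants"] = tuple(FormantTrack(**ft) for ft in d["formants"])
        d["f0"] = F0Contour(**d["f0"])
        return cls(**d)


@dataclass(frozen=True)
class Waveform:
    """Peak-normalized mono audio samples."""

    samples: np.ndarray
    sample_rate_hz: int

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    def segment(self, start_s: float, end_s: float) -> np.ndarray:
        i0 = max(int(round(start_s * self.sample_rate_hz)), 0)
        i1 = min(int(round(end_s * self.sample_rate_hz)), len(self.samples))
        return self.samples[i0:i1]


def make_f0_contour(spec: SyllableSpec) -> np.ndarray:
    """Per-sample fundamental-frequency track (Hz).

    The decline is linear from onset to offset over the *voiced* span
    (from the end of the VOT interval to the end of the syllable), so the
    first glottal cycle is at the onset frequency regardless of VOT.
    Samples inside the VOT interval hold the onset value; they drive no
    periodic source.
    """
    n = spec.n_samples
    if n <= 0:
        raise ParameterError("empty syllable")
    vot_n = int(round(spec.vot_s * spec.sample_rate_hz))
    track = np.full(n, spec.f0.onset_hz)
    track[vot_n:] = np.linspace(spec.f0.onset_hz, spec.f0.offset_hz, n - vot_n)
    return track


def apply_voicing_ramp(
    samples: np.ndarray, ramp_s: float, sample_rate_hz: float
) -> np.ndarray:
    """Multiply the final ``ramp_s`` seconds by a linear 1 -> 0 gain."""
    if ramp_s < 0:
        raise ParameterError("ramp must be non-negative")
    n_ramp = int(round(ramp_s * sample_rate_hz))
    if n_ramp > len(samples):
        raise ParameterError("ramp longer than signal")
    if n_ramp == 0:
        return np.asarray(samples, dtype=float).copy()
    out = np.asarray(samples, dtype=float).copy()
    out[-n_ramp:] *= np.linspace(1.0, 0.0, n_ramp)
    return out


def _resonator_coeffs(
    f_hz: np.ndarray, bw_hz: float, fs: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # Klatt second-order resonator, unity gain at DC
    T = 1.0 / fs
    C = -np.exp(-2.0 * np.pi * bw_hz * T) * np.ones_like(f_hz)
    B = 2.0 * np.exp(-np.pi * bw_hz * T) * np.cos(2.0 * np.pi * f_hz * T)
    A = 1.0 - B - C
    return A, B, C


def _filter_time_varying(
    x: np.ndarray, A: np.ndarray, B: np.ndarray, C: np.ndarray
) -> np.ndarray:
    y = np.empty_like(x)
    y1 = 0.0
    y2 = 0.0
    for i in range(len(x)):
        v = A[i] * x[i] + B[i] * y1 + C[i] * y2
        y[i] = v
        y2 = y1
        y1 = v
    return y


def _glottal_lowpass(x: np.ndarray, fs: float) -> np.ndarray:
    A, B, C = _resonator_coeffs(
        np.zeros(1), GLOTTAL_BW_HZ, fs
    )
    a, b, c = float(A[0]), float(B[0]), float(C[0])
    y = np.empty_like(x)
    y1 = y2 = 0.0
    for i in range(len(x)):
        v = a * x[i] + b * y1 + c * y2
        y[i] = v
        y2 = y1
        y1 = v
    return y


def synthesize(spec: SyllableSpec, seed: int | None = 0) -> Waveform:
    """Render a syllable spec to audio.

    ``seed`` feeds the aspiration-noise generator only; voiced portions are
    deterministic.  The output is peak-normalized to 0.9 full scale.
    """
    fs = spec.sample_rate_hz
    n = spec.n_samples
    t = np.arange(n) / fs
    f0 = make_f0_contour(spec)

    vot_n = int(round(spec.vot_s * fs))

    # impulse train from voicing onset, phase-accumulated against the
    # instantaneous F0 so the declining contour is honoured exactly
    pulses = np.zeros(n)
    phase = 1.0  # emit a pulse on the first voiced sample
    for i in range(vot_n, n):
        phase += f0[i] / fs
        if phase >= 1.0 - 1e-9:  # tolerance for accumulated float error
            pulses[i] = 1.0
            phase -= 1.0

    voiced = _glottal_lowpass(pulses, fs)

    source = voiced
    if vot_n > 0 and spec.vot_aspiration:
        rng = np.random.default_rng(seed)
        v_rms = float(np.sqrt(np.mean(voiced[vot_n:] ** 2))) or 1.0
        sigma = v_rms * 10.0 ** (ASPIRATION_REL_DB / 20.0)
        source = source.copy()
        source[:vot_n] += rng.normal(0.0, sigma, vot_n)

    y = source
    for tr in spec.formants:
        A, B, C = _resonator_coeffs(tr.frequency_at(t, spec.duration_s), tr.bandwidth_hz, fs)
        y = _filter_time_varying(y, A, B, C)

    # lip radiation: first difference (+6 dB/oct)
    y = np.diff(y, prepend=0.0)

    y = apply_voicing_ramp(y, spec.voicing_ramp_s, fs)

    peak = np.max(np.abs(y))
    if peak > 0:
        y = y * (0.9 / peak)
    return Waveform(samples=y, sample_rate_hz=fs)


def write_wav(w: Waveform, path: str | Path) -> Path:
    """Write 16-bit PCM WAV."""
    if len(w.samples) == 0:
        raise ParameterError("refusing to write an empty waveform")
    path = Path(path)
    data = np.clip(w.samples, -1.0, 1.0)
    wavfile.write(path, w.sample_rate_hz, (data * 32767.0).astype(np.int16))
    return path


def read_wav(path: str | Path) -> Waveform:
    fs, data = wavfile.read(path)
    return Waveform(samples=data.astype(float) / 32767.0, sample_rate_hz=fs)


# ---------------------------------------------------------------------------
# measurement utilities (used as oracles on the generated audio)


def _norm_autocorr(x: np.ndarray) -> np.ndarray:
    x = x - np.mean(x)
    r = np.correlate(x, x, mode="full")[len(x) - 1 :]
    if r[0] <= 0:
        return np.zeros_like(r)
    return r / r[0]


def estimate_f0(
    samples: np.ndarray, fs: float, fmin: float = 60.0, fmax: float = 400.0
) -> float:
    """Autocorrelation pitch estimate with parabolic lag interpolation."""
    r = _norm_autocorr(np.asarray(samples, dtype=float))
    lo = max(int(fs / fmax), 2)
    hi = min(int(fs / fmin) + 1, len(r) - 1)
    if hi <= lo:
        raise ParameterError("window too short for the pitch search range")
    lag = lo + int(np.argmax(r[lo:hi]))
    if 0 < lag < len(r) - 1:
        y0, y1, y2 = r[lag - 1], r[lag], r[lag + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            lag = lag + 0.5 * (y0 - y2) / denom
    return fs / lag


def estimate_f0_endpoints(
    w: Waveform,
    ramp_s: float = 0.020,
    window_s: float = 0.025,
    vot_s: float = 0.0,
) -> tuple[float, float]:
    """Estimated F0 at the onset and offset of the voiced portion.

    The onset is a plain autocorrelation estimate over the first 30 ms of
    voicing.  The offset needs more care: an autocorrelation window
    reports the *mean* period inside it, so near the end of the glide any
    single window is biased above the target; the offset is therefore
    estimated from two adjacent ``window_s`` windows and the implied
    linear trend is extrapolated half a window outward to the boundary
    (exact in expectation for a linear glide).  The same trick is not used
    at the onset because the rapid formant transitions there distort
    short-window period estimates more than the glide does.  The known
    linear voicing ramp is divided out of the final window first —
    otherwise it down-weights the last, slowest pitch periods; gains
    below 0.05 are not inverted, to avoid amplifying quantization noise.
    """
    fs = w.sample_rate_hz
    T = len(w.samples) / fs

    onset = estimate_f0(w.segment(vot_s, vot_s + 0.030), fs)

    tail = w.samples[-int(round(window_s * fs)) :].copy()
    n_ramp = min(int(round(ramp_s * fs)), len(tail))
    if n_ramp > 0:
        gain = np.linspace(1.0, 0.0, n_ramp)
        inv = np.ones(len(tail))
        inv[-n_ramp:] = 1.0 / np.maximum(gain, 0.05)
        inv[-n_ramp:][gain < 0.05] = 0.0
        tail = tail * inv
    fb2 = estimate_f0(tail, fs)
    fa2 = estimate_f0(w.segment(T - 2 * window_s, T - window_s), fs)
    offset = 1.5 * fb2 - 0.5 * fa2
    return onset, offset


def periodicity_strength(
    samples: np.ndarray, fs: float, fmin: float = 60.0, fmax: float = 400.0
) -> float:
    """Peak normalized autocorrelation in the pitch lag range (0..1)."""
    r = _norm_autocorr(np.asarray(samples, dtype=float))
    lo = max(int(fs / fmax), 2)
    hi = min(int(fs / fmin) + 1, len(r) - 1)
    if hi <= lo:
        return 0.0
    return float(np.max(r[lo:hi]))


def estimate_formants(
    samples: np.ndarray, fs: float, n_formants: int = 5, order: int | None = None
) -> list[tuple[float, float]]:
    """LPC-based formant estimates as (frequency_hz, bandwidth_hz) pairs.

    Autocorrelation-method linear prediction with 0.97 pre-emphasis; formants
    are taken from the complex pole angles, narrowest bandwidths first by
    frequency order.
    """
    from scipy.linalg import solve_toeplitz

    x = np.asarray(samples, dtype=float)
    x = np.append(x[0], x[1:] - 0.97 * x[:-1])
    x = x * np.hamming(len(x))
    order = order or (2 * n_formants + 2)
    r = np.correlate(x, x, mode="full")[len(x) - 1 : len(x) + order]
    a = solve_toeplitz(r[:-1], r[1:])
    poly = np.concatenate(([1.0], -a))
    roots = np.roots(poly)
    roots = roots[np.imag(roots) > 0.01]
    freqs = np.angle(roots) * fs / (2 * np.pi)
    bws = -np.log(np.abs(roots)) * fs / np.pi
    keep = (freqs > 80) & (freqs < fs / 2 - 80) & (bws < 800)
    pairs = sorted(zip(freqs[keep], bws[keep]))
    return [(float(f), float(b)) for f, b in pairs[:n_formants]]


def export_spectrogram(
    w: Waveform, csv_path: str | Path | None = None, png_path: str | Path | None = None
) -> np.ndarray:
    """Spectrogram matrix (dB) of a waveform; optional CSV / PNG export."""
    from scipy.signal import spectrogram as _spectrogram

    nperseg = min(256, len(w.samples))
    f, tt, S = _spectrogram(w.samples, fs=w.sample_rate_hz, nperseg=nperseg, noverlap=nperseg * 3 // 4)
    S_db = 10.0 * np.log10(S + 1e-12)
    if csv_path is not None:
        np.savetxt(csv_path, S_db, delimiter=",")
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 3))
        ax.pcolormesh(tt, f, S_db, shading="auto", cmap="magma")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("frequency (Hz)")
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
    return S_db
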