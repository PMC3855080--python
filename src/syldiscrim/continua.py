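"""The three syllable continua and the step/limen bookkeeping.

Each continuum fixes a reference syllable (step 0) and varies exactly one
acoustic dimension in uniform steps toward the opposite phonetic endpoint:

=========  ==========================  ===================  ==========
name       varying dimension           range                syllables
=========  ==========================  ===================  ==========
``ba_da``  F2 onset frequency          800 -> 1600 Hz        21
``ba_wa``  formant transition duration 25 -> 100 ms          16
``ga_ka``  voice onset time            0 -> 50 ms            11
=========  ==========================  ===================  ==========

The discrimination limen of a (reference, test) pair is the absolute
difference on that dimension; the first pair of a staircase run uses the
far endpoint, so its limen equals the full range (800 Hz / 75 ms / 50 ms).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .synthesis import (
    F0Contour,
    FormantTrack,
    ParameterError,
    SyllableSpec,
    synthesize,
    write_wav,
)

__all__ = ["ContinuumSpec", "PairLimen", "build_continuum", "limen_of_pair",
           "export_continuum", "CONTINUUM_NAMES"]

CONTINUUM_NAMES = ("ba_da", "ba_wa", "ga_ka")

# F3 onset for /ba/-/da/: the printed 500 Hz onset is inconsistent with the
# 2500 Hz vowel target; a mid transition onset is used by default and is
# overridable (see build_continuum).
DEFAULT_BA_DA_F3_ONSET = 2000.0

_BA_BW = (90.0, 110.0, 90.0, 400.0, 500.0)
_GA_BW = (90.0, 90.0, 130.0, 400.0, 500.0)


@dataclass(frozen=True)
class ContinuumSpec:
    name: str
    dimension: str
    unit: str
    reference_value: float
    far_value: float
    step_size: float
    syllables: tuple[SyllableSpec, ...]

    @property
    def n_steps(self) -> int:
        return len(self.syllables)

    @property
    def range(self) -> float:
        return abs(self.far_value - self.reference_value)

    def value_at(self, step: int) -> float:
        if not 0 <= step < self.n_steps:
            raise ParameterError(f"step {step} outside 0..{self.n_steps - 1}")
        return self.reference_value + step * self.step_size


@dataclass(frozen=True)
class PairLimen:
    continuum: str
    test_step: int
    limen: float
    unit: str


def _ba_formants(transition_s: float, f2_onset: float, f3_onset: float) -> tuple[FormantTrack, ...]:
    onsets = (420.0, f2_onset, f3_onset, 3250.0, 3700.0)
    targets = (800.0, 1200.0, 2500.0, 3250.0, 3700.0)
    late = (750.0, None, None, None, None)
    return tuple(
        FormantTrack(
            onset_hz=o,
            target_hz=tg,
            bandwidth_hz=bw,
            transition_end_s=transition_s,
            late_target_hz=lt,
        )
        for o, tg, bw, lt in zip(onsets, targets, _BA_BW, late)
    )


def _ga_formants(transition_s: float) -> tuple[FormantTrack, ...]:
    onsets = (420.0, 1625.0, 2125.0, 3250.0, 3700.0)
    targets = (700.0, 1200.0, 2600.0, 3250.0, 3700.0)
    late = (750.0, 1000.0, 2300.0, None, None)
    return tuple(
        FormantTrack(
            onset_hz=o,
            target_hz=tg,
            bandwidth_hz=bw,
            transition_end_s=transition_s,
            late_target_hz=lt,
        )
        for o, tg, bw, lt in zip(onsets, targets, _GA_BW, late)
    )


def build_continuum(
    name: str,
    sample_rate_hz: int = 16_000,
    ba_da_f3_onset_hz: float = DEFAULT_BA_DA_F3_ONSET,
    ga_ka_transition_s: float = 0.040,
    vot_aspiration: bool = True,
) -> ContinuumSpec:
    """Construct one of the three named continua.

    Parameters
    ----------
    name:
        ``"ba_da"``, ``"ba_wa"`` or ``"ga_ka"``.
    ba_da_f3_onset_hz:
        F3 transition onset for the /ba/-/da/ family (see module notes).
    ga_ka_transition_s:
        Formant transition duration for /ga/-/ka/ (not printed in the
        source description; defaults to the 40 ms used by /ba/-/da/).
    vot_aspiration:
        If True the VOT interval of /ga/-/ka/ syllables carries low-level
        aspiration noise; if False it is silent.
    """
    if name == "ba_da":
        f2_onsets = [800.0 + 40.0 * k for k in range(21)]
        syllables = tuple(
            SyllableSpec(
                label=f"ba_da_{k:02d}",
                formants=_ba_formants(0.040, f2, ba_da_f3_onset_hz),
                sample_rate_hz=sample_rate_hz,
            )
            for k, f2 in enumerate(f2_onsets)
        )
        return ContinuumSpec(
            name=name, dimension="F2 onset", unit="Hz",
            reference_value=800.0, far_value=1600.0, step_size=40.0,
            syllables=syllables,
        )
    if name == "ba_wa":
        durations_ms = [25.0 + 5.0 * k for k in range(16)]
        syllables = tuple(
            SyllableSpec(
                label=f"ba_wa_{k:02d}",
                formants=_ba_formants(d / 1000.0, 800.0, DEFAULT_BA_DA_F3_ONSET),
                sample_rate_hz=sample_rate_hz,
            )
            for k, d in enumerate(durations_ms)
        )
        return ContinuumSpec(
            name=name, dimension="transition duration", unit="ms",
            reference_value=25.0, far_value=100.0, step_size=5.0,
            syllables=syllables,
        )
    if name == "ga_ka":
        vots_ms = [5.0 * k for k in range(11)]
        syllables = tuple(
            SyllableSpec(
                label=f"ga_ka_{k:02d}",
                formants=_ga_formants(ga_ka_transition_s),
                vot_s=v / 1000.0,
                vot_aspiration=vot_aspiration,
                sample_rate_hz=sample_rate_hz,
            )
            for k, v in enumerate(vots_ms)
        )
        return ContinuumSpec(
            name=name, dimension="VOT", unit="ms",
            reference_value=0.0, far_value=50.0, step_size=5.0,
            syllables=syllables,
        )
    raise ParameterError(f"unknown continuum {name!r}; expected one of {CONTINUUM_NAMES}")


def limen_of_pair(continuum: ContinuumSpec, test_step: int) -> PairLimen:
    """Acoustic difference between the test syllable and the reference."""
    value = continuum.value_at(test_step)
    return PairLimen(
        continuum=continuum.name,
        test_step=test_step,
        limen=abs(value - continuum.reference_value),
        unit=continuum.unit,
    )


def export_continuum(
    continuum: ContinuumSpec, outdir: str | Path, seed: int = 0, write_audio: bool = True
) -> Path:
    """Write all WAVs plus a manifest CSV; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / f"{continuum.name}_manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["step", "dimension", "unit", "value", "limen", "wav"])
        for k, spec in enumerate(continuum.syllables):
            wav_name = f"{continuum.name}_{k:02d}.wav"
            if write_audio:
                write_wav(synthesize(spec, seed=seed + k), outdir / wav_name)
            w.writerow(
                [k, continuum.dimension, continuum.unit,
                 continuum.value_at(k), limen_of_pair(continuum, k).limen, wav_name]
            )
    return manifest
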