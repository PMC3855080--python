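"""Three-down one-up adaptive same/different staircase.

The run starts at the most easily discriminable pair (the far endpoint of
the continuum).  Three consecutive correct responses move the test syllable
``step_down`` steps toward the reference (harder); each incorrect response
moves it ``step_up`` steps toward the far endpoint (easier), clamped at the
endpoints.  Catch trials (identical pairs) are interleaved every 5-10
trials and do not touch the staircase state.  The run terminates after a
fixed number of reversals — trials at which the prescribed direction of
movement flips — or after five consecutive errors on the easiest pair; the
threshold is the arithmetic mean of the limens at the last four reversals.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .continua import ContinuumSpec, limen_of_pair
from .observers import Observer, p_correct
from .synthesis import ParameterError

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "TrialRecord",
    "StaircaseResult",
    "run_staircase",
    "update_state",
    "estimate_threshold",
    "EstimationError",
]


class EstimationError(RuntimeError):
    """Raised when a threshold is requested from too few reversals."""

    def __init__(self, message: str, partial: float | None = None):
        super().__init__(message)
        self.partial = partial


@dataclass(frozen=True)
class StaircaseConfig:
    down_rule: int = 3
    step_down: int = 2
    step_up: int = 1
    reversal_stop: int = 7
    reversals_for_threshold: int = 4
    #: descent size once the measurement phase has begun (after the first
    #: reversal).  The two-step descents of ``step_down`` are read as the
    #: coarse initial approach from the easiest pair; symmetric one-step
    #: moves thereafter give the rule its standard 79.4 % convergence
    #: point (with 2:1 steps throughout the equilibrium sits near the
    #: p^3 = 1/3, ~69 % point instead — set this to ``step_down`` for that
    #: reading).
    step_down_fine: int = 1
    catch_min: int = 5
    catch_max: int = 10
    max_consecutive_incorrect_at_easiest: int = 5
    isi_ms: float = 750.0  # metadata only; no audio is presented
    max_trials: int = 400  # safety stop for degenerate responders

    def __post_init__(self) -> None:
        if min(self.down_rule, self.step_down, self.step_up,
               self.reversal_stop, self.reversals_for_threshold) <= 0:
            raise ParameterError("staircase counts must be positive")
        if self.reversals_for_threshold > self.reversal_stop:
            raise ParameterError("cannot average more reversals than are collected")
        if not 0 < self.catch_min <= self.catch_max:
            raise ParameterError("need 0 < catch_min <= catch_max")


@dataclass
class StaircaseState:
    """Mutable counters of the 3-down/1-up rule."""

    step: int  # current test-syllable index
    easiest: int  # maximal step index (far endpoint)
    hardest: int = 1  # step adjacent to the reference
    run_correct: int = 0
    consecutive_incorrect_at_easiest: int = 0
    last_direction: int | None = None  # -1 harder, +1 easier
    n_reversals: int = 0
    moved: bool = field(default=False, init=False)
    reversed: bool = field(default=False, init=False)


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    test_step: int
    limen: float
    is_catch: bool
    presentation_order: str  # "reference_first" | "test_first"
    response: str  # "same" | "different"
    correct: bool


@dataclass(frozen=True)
class StaircaseResult:
    continuum: str
    unit: str
    trials: tuple[TrialRecord, ...]
    reversal_limens: tuple[float, ...]
    threshold: float
    terminated_by: str  # "reversals" | "failure_at_easiest" | "max_trials"
    threshold_is_partial: bool
    n_catch: int
    n_catch_correct: int

    def to_json(self, config: StaircaseConfig | None = None) -> str:
        d = {
            "continuum": self.continuum,
            "unit": self.unit,
            "reversal_limens": list(self.reversal_limens),
            "threshold": self.threshold,
            "terminated_by": self.terminated_by,
            "threshold_is_partial": self.threshold_is_partial,
            "n_catch": self.n_catch,
            "n_catch_correct": self.n_catch_correct,
        }
        if config is not None:
            d["config"] = asdict(config)
        return json.dumps(d, indent=2)

    def trials_to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["trial_index", "test_step", "limen", "is_catch",
                 "presentation_order", "response", "correct"]
            )
            for t in self.trials:
                w.writerow(
                    [t.trial_index, t.test_step, t.limen, int(t.is_catch),
                     t.presentation_order, t.response, int(t.correct)]
                )
        return path


def update_state(
    state: StaircaseState, correct: bool, config: StaircaseConfig | None = None
) -> StaircaseState:
    """Apply one non-catch response to the 3-down/1-up counters.

    Mutates and returns ``state``; sets ``state.moved`` / ``state.reversed``
    for the trial just applied.  Movement direction is the *prescribed*
    one, so a clamped move at an endpoint still counts for reversal
    bookkeeping.
    """
    cfg = config or StaircaseConfig()
    state.moved = False
    state.reversed = False
    if correct:
        if state.step == state.easiest:
            state.consecutive_incorrect_at_easiest = 0
        state.run_correct += 1
        if state.run_correct >= cfg.down_rule:
            state.run_correct = 0
            direction = -1
            down = cfg.step_down if state.n_reversals == 0 else cfg.step_down_fine
            state.step = max(state.step - down, state.hardest)
            state.moved = True
            if state.last_direction is not None and direction != state.last_direction:
                state.reversed = True
                state.n_reversals += 1
            state.last_direction = direction
    else:
        state.run_correct = 0
        if state.step == state.easiest:
            state.consecutive_incorrect_at_easiest += 1
        else:
            state.consecutive_incorrect_at_easiest = 0
        direction = +1
        state.step = min(state.step + cfg.step_up, state.easiest)
        state.moved = True
        if state.last_direction is not None and direction != state.last_direction:
            state.reversed = True
            state.n_reversals += 1
        state.last_direction = direction
    return state


def estimate_threshold(reversal_limens, k: int) -> float:
    """Arithmetic mean of the last ``k`` reversal limens, native units."""
    limens = list(reversal_limens)
    if k <= 0:
        raise ParameterError("k must be positive")
    if len(limens) < k:
        partial = float(np.mean(limens)) if limens else None
        raise EstimationError(
            f"only {len(limens)} reversals available, {k} requested", partial=partial
        )
    return float(np.mean(limens[-k:]))


def run_staircase(
    continuum: ContinuumSpec,
    observer: Observer,
    config: StaircaseConfig | None = None,
    seed: int = 0,
) -> StaircaseResult:
    """Run one adaptive track of an observer on a continuum.

    All randomness — catch-trial spacing, presentation order, and the
    observer's Bernoulli responses — is drawn from a single generator
    seeded with ``seed``, so a run is exactly reproducible.
    """
    cfg = config or StaircaseConfig()
    rng = np.random.default_rng(seed)
    state = StaircaseState(step=continuum.n_steps - 1, easiest=continuum.n_steps - 1)

    trials: list[TrialRecord] = []
    reversal_limens: list[float] = []
    visited_limens: set[float] = set()
    n_catch = n_catch_correct = 0
    trials_since_catch = 0
    next_catch_gap = int(rng.integers(cfg.catch_min, cfg.catch_max + 1))
    terminated_by = "max_trials"

    while len(trials) < cfg.max_trials:
        is_catch = trials_since_catch >= next_catch_gap
        order = "reference_first" if rng.random() < 0.5 else "test_first"
        if is_catch:
            limen = 0.0
            test_step = 0
        else:
            pair = limen_of_pair(continuum, state.step)
            limen, test_step = pair.limen, state.step
            visited_limens.add(limen)

        correct_draw = rng.random() < p_correct(observer, limen)
        if is_catch:
            response = "same" if correct_draw else "different"
            correct = response == "same"
        else:
            response = "different" if correct_draw else "same"
            correct = response == "different"

        trials.append(
            TrialRecord(
                trial_index=len(trials),
                test_step=test_step,
                limen=limen,
                is_catch=is_catch,
                presentation_order=order,
                response=response,
                correct=correct,
            )
        )

        if is_catch:
            n_catch += 1
            n_catch_correct += int(correct)
            trials_since_catch = 0
            next_catch_gap = int(rng.integers(cfg.catch_min, cfg.catch_max + 1))
            continue
        trials_since_catch += 1

        update_state(state, correct, cfg)
        if state.reversed:
            reversal_limens.append(limen)
            if len(reversal_limens) >= cfg.reversal_stop:
                terminated_by = "reversals"
                break
        if (
            state.consecutive_incorrect_at_easiest
            >= cfg.max_consecutive_incorrect_at_easiest
        ):
            terminated_by = "failure_at_easiest"
            break

    partial = False
    try:
        threshold = estimate_threshold(reversal_limens, cfg.reversals_for_threshold)
    except EstimationError as err:
        partial = True
        if err.partial is not None:
            threshold = err.partial
        else:
            # no reversals at all (e.g. an error-free responder): fall back
            # to the hardest limens actually reached near the reference
            k = cfg.reversals_for_threshold
            hardest = sorted(visited_limens)[:k]
            threshold = float(np.mean(hardest)) if hardest else float("nan")

    return StaircaseResult(
        continuum=continuum.name,
        unit=continuum.unit,
        trials=tuple(trials),
        reversal_limens=tuple(reversal_limens),
        threshold=threshold,
        terminated_by=terminated_by,
        threshold_is_partial=partial,
        n_catch=n_catch,
        n_catch_correct=n_catch_correct,
    )
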