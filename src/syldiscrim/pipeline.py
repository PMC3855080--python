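"""End-to-end experiment orchestration.

A run draws a simulated cohort, puts every participant through one
adaptive staircase per selected continuum (continuum order counterbalanced
across participants), transforms the estimated thresholds to relative
threshold indices, runs the group statistics, and — for the two
envelope-analysed continua — writes the rise-time report.  Everything is
driven by one master seed; per-participant and per-stage seeds are spawned
deterministically from it, so a bundle is byte-for-byte reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .continua import CONTINUUM_NAMES, build_continuum, export_continuum
from .envelope import ENVELOPE_CONTINUA, continuum_rise_times
from .observers import CohortSpec, sample_cohort
from .staircase import StaircaseConfig, run_staircase
from .stats import cohort_analysis, compute_rti
from .synthesis import ParameterError

__all__ = ["RunConfig", "run_experiment", "simulate_rti_table"]

log = logging.getLogger("syldiscrim")


@dataclass(frozen=True)
class RunConfig:
    continua: tuple[str, ...] = CONTINUUM_NAMES
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    master_seed: int = 0
    outdir: str = "results"
    export_audio: bool = False
    envelope_method: str = "from_known_f0"
    fdr_q: float = 0.05

    def __post_init__(self) -> None:
        if not self.continua:
            raise ParameterError("select at least one continuum")
        unknown = set(self.continua) - set(CONTINUUM_NAMES)
        if unknown:
            raise ParameterError(f"unknown continua: {sorted(unknown)}")

    def config_hash(self) -> str:
        # hash of the scientific content; the output location is excluded
        d = asdict(self)
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        if "staircase" in d:
            d["staircase"] = StaircaseConfig(**d["staircase"])
        if "cohort" in d:
            from .observers import GroupEffects

            c = d["cohort"]
            if "group_effects" in c:
                c["group_effects"] = GroupEffects(**c["group_effects"])
            d["cohort"] = CohortSpec(**c)
        if "continua" in d:
            d["continua"] = tuple(d["continua"])
        return cls(**d)


def simulate_rti_table(config: RunConfig) -> pd.DataFrame:
    """Cohort -> staircases -> RTI, as a tidy DataFrame (no file output).

    One row per participant x continuum with the estimated threshold, its
    RTI, the generating (true) values, and trial/catch counts.
    """
    continua = {name: build_continuum(name) for name in config.continua}
    cohort = sample_cohort(config.cohort, continua, seed=config.master_seed)
    ss = np.random.SeedSequence(config.master_seed)
    # one independent child seed per participant x continuum staircase
    participants = list(dict.fromkeys(cohort["participant_id"]))
    children = ss.spawn(len(participants))
    order_rng = np.random.default_rng(ss.spawn(1)[0])

    rows = []
    for p_idx, pid in enumerate(participants):
        sub = cohort[cohort["participant_id"] == pid]
        # counterbalance: independent random continuum order per participant
        order = order_rng.permutation(list(config.continua))
        run_seeds = children[p_idx].generate_state(len(order))
        for c_idx, cname in enumerate(order):
            row = sub[sub["continuum"] == cname].iloc[0]
            cont = continua[cname]
            res = run_staircase(
                cont, row["observer"], config.staircase,
                seed=int(run_seeds[c_idx] % (2**31 - 1)),
            )
            # the staircase estimates a limen (difference from the
            # reference); the RTI formula wants the absolute value on the
            # continuum's dimension
            raw = cont.reference_value + res.threshold
            rows.append(
                dict(
                    participant_id=pid,
                    group=row["group"],
                    years=row["years"],
                    hours=row["hours"],
                    continuum=cname,
                    presentation_position=c_idx,
                    threshold_limen=res.threshold,
                    raw_threshold=raw,
                    rti=compute_rti(cont, raw),
                    true_threshold=row["true_threshold"],
                    true_rti=row["true_rti"],
                    n_trials=len(res.trials),
                    n_reversals=len(res.reversal_limens),
                    terminated_by=res.terminated_by,
                    n_catch=res.n_catch,
                    n_catch_correct=res.n_catch_correct,
                )
            )
    table = pd.DataFrame(rows)
    return table.sort_values(["participant_id", "continuum"]).reset_index(drop=True)


def run_experiment(config: RunConfig) -> dict:
    """Execute the full pipeline and write the output bundle.

    Writes manifest.json (config + hash + seeds), rti_table.csv, the stats
    JSON and summary, a rise-time CSV per envelope-analysed continuum, and
    optionally all WAVs.  Returns a dict of the in-memory artifacts.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log.info("run %s: seed=%d outdir=%s", chash, config.master_seed, outdir)

    bundle: dict = {"config_hash": chash}
    stage = "synthesis"
    try:
        if config.export_audio:
            for name in config.continua:
                export_continuum(
                    build_continuum(name), outdir / "audio",
                    seed=config.master_seed,
                )
            log.info("stage synthesis: audio exported")

        stage = "staircases"
        table = simulate_rti_table(config)
        table.to_csv(outdir / "rti_table.csv", index=False)
        bundle["rti_table"] = table
        log.info("stage staircases: %d runs", len(table))

        stage = "envelope"
        env_rows = {}
        for name in config.continua:
            if name in ENVELOPE_CONTINUA:
                env_rows[name] = continuum_rise_times(
                    build_continuum(name), method=config.envelope_method,
                    seed=config.master_seed,
                    csv_path=outdir / f"rise_times_{name}.csv",
                )
        bundle["rise_times"] = env_rows
        log.info("stage envelope: %s", sorted(env_rows))

        stage = "stats"
        if len(config.continua) > 1:
            report = cohort_analysis(table, q=config.fdr_q)
            report.to_json(outdir / "stats.json")
            (outdir / "stats_summary.txt").write_text(report.summary() + "\n")
            bundle["stats"] = report
            log.info("stage stats: done")
    except Exception as err:  # pragma: no cover - logged and re-raised
        log.error("stage %s failed: %s", stage, err)
        raise RuntimeError(f"pipeline stage {stage!r} failed") from err

    manifest = dict(
        config=asdict(config), config_hash=chash, master_seed=config.master_seed,
        outputs=sorted(p.name for p in outdir.iterdir() if p.is_file()),
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    bundle["manifest"] = manifest
    return bundle
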