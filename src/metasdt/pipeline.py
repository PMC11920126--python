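"""End-to-end analysis runs: exclusions -> behavioral stats -> hierarchical fits.

A :class:`RunConfig` fully determines a run; the output directory receives
an exclusion report, participant summaries, the frequentist/Bayesian test
table, per-phase posterior effect summaries, and a machine-readable manifest
sufficient to re-execute the run bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavioral import (
    apply_exclusions,
    levene_holm,
    mixed_anova,
    paired_t_with_bf,
    post_by_pre_level,
    summarize_participants,
)
from .counts import RatingCounts
from .hierarchical import (
    CellAssignment,
    effects_frame,
    fit_hierarchical_mratio,
    summarize_effects,
)
from .io import read_trials, write_trials
from .sdt import compute_type1_sdt
from .simulator import SimulationConfig, simulate_dataset

log = logging.getLogger("metasdt")

PHASE_K = {"pre": 2, "post": 5}


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run."""

    seed: int
    trials_path: str | None = None
    simulate: bool = False
    simulation: SimulationConfig | None = None
    phases: tuple[str, ...] = ("pre", "post")
    chains: int = 3
    iterations: int = 10_000
    burnin: int = 1_000
    alpha: float = 0.05
    hdi_mass: float = 0.95
    pd_threshold: float = 0.95
    out_dir: str = "metasdt_out"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phases"] = list(self.phases)
        if self.simulation is not None:
            d["simulation"]["post_thresholds"] = list(self.simulation.post_thresholds)
        return d


def cells_from_trials(trials: pd.DataFrame, phase: str) -> list[CellAssignment]:
    """Build per-(participant, difficulty) rating-count cells for one phase.

    Rows with missing or too-fast responses are dropped (participant-level
    exclusions are the caller's responsibility; see ``apply_exclusions``).
    """
    from .behavioral import trial_validity

    trials = trials[trial_validity(trials)]
    rating_col = "pre_rating" if phase == "pre" else "post_rating"
    k = PHASE_K[phase]
    cells = []
    for (pid, instr, diff), sub in trials.groupby(
        ["participant_id", "instruction", "difficulty"], sort=True
    ):
        counts = RatingCounts.from_trials(
            sub["stimulus"].to_numpy(),
            sub["type1_response"].to_numpy(),
            sub[rating_col].to_numpy(dtype=np.int64),
            k=k,
        )
        t1 = compute_type1_sdt(counts)
        cells.append(CellAssignment(
            participant_id=pid, instruction=instr, difficulty=diff,
            counts=counts, d_prime=t1.d_prime, criterion=t1.criterion,
        ))
    return cells


def behavioral_tests(participants: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """The battery of behavioral tests, one row per test."""
    rows = []
    for dv in ("accuracy", "d_prime", "total_score",
               "mean_pre_rating", "mean_post_rating"):
        aov = mixed_anova(
            participants.rename(columns={dv: "value"}), dv="value")
        for _, r in aov.iterrows():
            rows.append({
                "name": f"anova_{dv}_{r['effect']}", "statistic": r["F"],
                "df1": r["df1"], "df2": r["df2"], "p": r["p"],
                "effect_size": r["eta_g"], "bf10": np.nan, "adjusted_p": np.nan,
            })
    lev = levene_holm(
        participants.rename(columns={"mean_pre_rating": "value"}), dv="value")
    for _, r in lev.iterrows():
        rows.append({
            "name": f"levene_pre_rating_{r['difficulty']}", "statistic": r["W"],
            "df1": r["df1"], "df2": r["df2"], "p": r["p"],
            "effect_size": np.nan, "bf10": np.nan, "adjusted_p": r["adjusted_p"],
        })
    try:
        pairs = post_by_pre_level(trials)
        t_res = paired_t_with_bf(
            pairs["post_low"].to_numpy(), pairs["post_high"].to_numpy())
        rows.append({
            "name": "paired_t_post_by_pre", "statistic": t_res["t"],
            "df1": t_res["df"], "df2": np.nan, "p": t_res["p"],
            "effect_size": t_res["cohen_d"], "bf10": t_res["bf10"],
            "adjusted_p": np.nan,
        })
    except ValueError as err:
        log.warning("skipping post-by-pre paired t-test: %s", err)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full analysis run and write the report bundle.

    Returns a dict with the in-memory results (kept trials, summaries,
    test table, per-phase effect summaries, manifest).
    """
    if not config.simulate and config.trials_path is None:
        raise ValueError("RunConfig needs either trials_path or simulate=True")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed_root = np.random.SeedSequence(config.seed)
    sim_seed, pre_seed, post_seed = (
        int(s.generate_state(1)[0] % 2**31) for s in seed_root.spawn(3))
    fit_seeds = {"pre": pre_seed, "post": post_seed}

    if config.simulate:
        sim_cfg = config.simulation or SimulationConfig(seed=sim_seed)
        log.info("simulating cohort (seed %d)", sim_cfg.seed)
        trials, truth = simulate_dataset(sim_cfg)
        write_trials(trials, out / "trials.csv")
        truth.to_json(out / "ground_truth.json")
    elif config.trials_path is not None:
        log.info("reading trials from %s", config.trials_path)
        trials = read_trials(config.trials_path)
    else:
        raise ValueError("RunConfig needs either trials_path or simulate=True")

    kept, report = apply_exclusions(trials)
    report.to_csv(out / "exclusion_report.csv", index=False)
    log.info("kept %d/%d participants after exclusions",
             int((~report["excluded"]).sum()), len(report))

    participants = summarize_participants(kept)
    participants.to_csv(out / "participants.csv", index=False)

    tests = behavioral_tests(participants, kept)
    tests.to_csv(out / "tests.csv", index=False)

    effect_frames = []
    effect_summaries = {}
    for phase in config.phases:
        cells = cells_from_trials(kept, phase)
        log.info("fitting %s-phase hierarchical model (%d cells)", phase, len(cells))
        samples = fit_hierarchical_mratio(
            cells, phase=phase, chains=config.chains,
            iterations=config.iterations, burnin=config.burnin,
            seed=fit_seeds[phase],
        )
        summaries = summarize_effects(
            samples, hdi_mass=config.hdi_mass, pd_threshold=config.pd_threshold)
        effect_summaries[phase] = summaries
        effect_frames.append(effects_frame(summaries, phase))
        for s in summaries:
            if not s.converged:
                log.warning("%s-phase effect %s flagged non-converged (R-hat %.4f)",
                            phase, s.effect, s.rhat)
    effects = (pd.concat(effect_frames, ignore_index=True)
               if effect_frames else pd.DataFrame())
    effects.to_csv(out / "effects.csv", index=False)
    effects.to_json(out / "effects.json", orient="records", indent=1)

    manifest = {
        "package": "metasdt",
        "version": __version__,
        "config": config.to_dict(),
        "stage_seeds": {"simulate": sim_seed, **fit_seeds},
        "n_participants_kept": int((~report["excluded"]).sum()),
        "n_trials_kept": int(len(kept)),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return {
        "trials": kept,
        "exclusion_report": report,
        "participants": participants,
        "tests": tests,
        "effects": effects,
        "effect_summaries": effect_summaries,
        "manifest": manifest,
    }
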