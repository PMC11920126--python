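import warnings

import numpy as np
import pandas as pd
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from metasdt import SimulationConfig, PhaseEffects, simulate_dataset  # noqa: E402


def make_trials(participants: dict) -> pd.DataFrame:
    """Build a trial table from {pid: (instruction, row dicts)} shorthand."""
    rows = []
    for pid, (instr, trial_rows) in participants.items():
        for r in trial_rows:
            base = {
                "participant_id": pid, "instruction": instr,
                "difficulty": "easy", "session": 1, "trial": 1,
                "stimulus": "match", "pre_rating": 1, "type1_response": "match",
                "post_rating": 3, "rt_pre": 500.0, "rt_answer": 700.0,
                "rt_post": 600.0,
            }
            base.update(r)
            rows.append(base)
    return pd.DataFrame(rows)


def clean_participant_rows(n_easy: int = 36, n_hard: int = 36, alternate_pre=True):
    """Valid trials alternating stimuli/pre-ratings so no exclusion fires."""
    rows = []
    for diff, n in (("easy", n_easy), ("hard", n_hard)):
        for i in range(n):
            rows.append({
                "difficulty": diff,
                "session": 1 + i // 12 + (0 if diff == "easy" else 3),
                "trial": 1 + i % 12,
                "stimulus": "match" if i % 2 == 0 else "nonmatch",
                "type1_response": "match" if i % 3 != 0 else "nonmatch",
                "pre_rating": (1 + i % 2) if alternate_pre else 2,
                "post_rating": 1 + i % 5,
            })
    return rows


@pytest.fixture(scope="session")
def small_cohort():
    """A compact simulated cohort reused by several read-only tests."""
    cfg = SimulationConfig(
        seed=424241, n_bet=8, n_confidence=8,
        pre_effects=PhaseEffects(mean=0.75, instruction=-0.3,
                                 difficulty=0.0, interaction=0.0),
    )
    trials, truth = simulate_dataset(cfg)
    return cfg, trials, truth
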