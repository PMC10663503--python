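"""Temporal-wagering task structure generator.

A session is a sequence of trials organized into uncued blocks.  The first
block is always mixed; thereafter high and low blocks alternate with a mixed
block between each (mixed-high-mixed-low-... or mixed-low-mixed-high-...).
Blocks advance after a fixed number of successfully completed trials
(default 40); premature fixation breaks (violation trials) do not count and
the same reward offer is repeated on the following trial.  Reward offers are
drawn uniformly from the block's volume set ({5,10,20} μL in low blocks,
{20,40,80} in high, all five in mixed); a fraction of completed trials are
catch trials on which reward is withheld; reward delays are exponential with
mean 2.5 s.

The trial table schema (one row per trial) is:

rat_id, session_id, trial_index, block, trial_in_block, reward_offer,
is_catch, is_violation, reward_delay, opted_out, rewarded, wait_time,
trial_initiation_time

Task generation fills everything except the behavioral fields (opted_out,
rewarded, wait_time, trial_initiation_time), which are produced by
:func:`tempwager.agents.generate_behavior`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import BLOCK_REWARDS, REWARDS

#: catch trials terminate (censor the wait) after this many seconds
CATCH_TIMEOUT = 100.0

#: reduced volumes used for female rats, relabeled as the male set
FEMALE_REWARDS = (4.0, 8.0, 16.0, 32.0, 64.0)

TRIAL_COLUMNS = (
    "rat_id",
    "session_id",
    "trial_index",
    "block",
    "trial_in_block",
    "reward_offer",
    "is_catch",
    "is_violation",
    "reward_delay",
    "opted_out",
    "rewarded",
    "wait_time",
    "trial_initiation_time",
)


@dataclass
class SessionConfig:
    """Task parameters for one simulated session."""

    reward_set: tuple = REWARDS
    block_length_completed: int = 40
    n_blocks: int = 9
    catch_prob: float = 0.20
    violation_prob: float = 0.20
    mean_delay: float = 2.5
    first_block: str = "mixed"
    female_scaling: bool = False
    cue_before_initiation: bool = False
    rng_seed: int | None = None

    def __post_init__(self):
        rs = tuple(float(r) for r in self.reward_set)
        if len(rs) != 5 or any(b <= a for a, b in zip(rs, rs[1:])):
            raise ValueError("reward_set must be 5 strictly increasing volumes")
        self.reward_set = rs
        if not 0.0 <= self.catch_prob < 1.0:
            raise ValueError("catch_prob must lie in [0, 1)")
        if not 0.0 <= self.violation_prob < 1.0:
            raise ValueError("violation_prob must lie in [0, 1)")
        if self.mean_delay <= 0:
            raise ValueError("mean_delay must be positive")
        if self.block_length_completed < 1:
            raise ValueError("block_length_completed must be positive")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be at least 1")
        if self.first_block != "mixed":
            raise ValueError("sessions start with a mixed block")


def generate_block_sequence(n_blocks: int, rng: np.random.Generator) -> list[str]:
    """Block labels for a session: mixed first, then alternating high/low
    separated by mixed blocks; whether high or low comes first is a coin flip.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be at least 1")
    first_adapt = "high" if rng.random() < 0.5 else "low"
    other = {"high": "low", "low": "high"}[first_adapt]
    seq = []
    adapt = first_adapt
    for i in range(n_blocks):
        if i % 2 == 0:
            seq.append("mixed")
        else:
            seq.append(adapt)
            adapt = other if adapt == first_adapt else first_adapt
    return seq


def draw_reward_delay(mean_delay: float, rng: np.random.Generator, size=None):
    """Exponential reward delay(s) with the given mean (seconds)."""
    if mean_delay <= 0:
        raise ValueError("mean_delay must be positive")
    return rng.exponential(mean_delay, size=size)


def generate_session(
    config: SessionConfig,
    rng: np.random.Generator | None = None,
    rat_id: str = "rat0",
    session_id: str = "s0",
) -> pd.DataFrame:
    """Generate the task side of one session as a trial table.

    Behavioral columns are present but empty (NaN / False).  Per-trial RNG
    draw order is fixed (block coin up front; then per trial: violation flag,
    catch flag, reward draw, delay) so a seed pins the whole table.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    volumes = FEMALE_REWARDS if config.female_scaling else config.reward_set
    # stored labels always use the canonical (male) set
    label_of = dict(zip(volumes, config.reward_set))

    blocks = generate_block_sequence(config.n_blocks, rng)
    rows: list[dict] = []
    trial_index = 0
    prev_offer: float | None = None  # carried across a violation
    for block in blocks:
        block_set = [v for v, lab in label_of.items() if lab in BLOCK_REWARDS[block]]
        completed = 0
        while completed < config.block_length_completed:
            trial_index += 1
            is_violation = rng.random() < config.violation_prob
            u_catch = rng.random()
            if prev_offer is not None and prev_offer in block_set:
                offer = prev_offer
                rng.random()  # keep draw order fixed whether or not we redraw
            else:
                offer = block_set[int(rng.random() * len(block_set))]
            delay = draw_reward_delay(config.mean_delay, rng)
            is_catch = (not is_violation) and (u_catch < config.catch_prob)
            if not is_violation:
                completed += 1
            rows.append(
                {
                    "rat_id": rat_id,
                    "session_id": session_id,
                    "trial_index": trial_index,
                    "block": block,
                    "trial_in_block": completed if not is_violation else completed + 1,
                    "reward_offer": label_of[offer],
                    "is_catch": is_catch,
                    "is_violation": is_violation,
                    "reward_delay": delay,
                    "opted_out": False,
                    "rewarded": False,
                    "wait_time": np.nan,
                    "trial_initiation_time": np.nan,
                }
            )
            prev_offer = offer if is_violation else None
    df = pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
    return df
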