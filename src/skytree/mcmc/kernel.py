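"""Metropolis-Hastings chain over (tree, parameters) with logging.

Acceptance uses ``alpha = min(1, exp(log posterior ratio + log adjustment))``
where the adjustment is the operator's combined Hastings ratio and
Jacobian.  Runs are bit-reproducible for a fixed seed: a single
``numpy.random.Generator`` drives operator choice, proposals, and
acceptance draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from ..trees import TimeTree
from .operators import Operator
from .state import McmcState, Target

__all__ = ["OperatorSchedule", "TraceLog", "McmcResult", "run_mcmc"]


class OperatorSchedule:
    """Weighted operator mix with acceptance bookkeeping and optional
    auto-tuning of scale windows during an initial tuning phase."""

    def __init__(self, operators: Sequence[Operator], tune_for: int = 0):
        if not operators:
            raise ValueError("schedule needs at least one operator")
        self.operators = list(operators)
        weights = np.array([op.weight for op in self.operators], dtype=float)
        self.probs = weights / weights.sum()
        self.tune_for = tune_for

    def choose(self, rng: np.random.Generator) -> Operator:
        return self.operators[rng.choice(len(self.operators), p=self.probs)]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "operator": [op.name for op in self.operators],
                "weight": [op.weight for op in self.operators],
                "proposed": [op.n_proposed for op in self.operators],
                "accepted": [op.n_accepted for op in self.operators],
                "acceptance_rate": [op.acceptance_rate for op in self.operators],
            }
        )


@dataclass
class TraceLog:
    """Tab-separated-compatible parameter trace; first column "Sample"."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.columns[0] != "Sample":
            raise ValueError('first trace column must be "Sample"')

    def __getitem__(self, key: str) -> np.ndarray:
        return self.table[key].to_numpy()

    def __len__(self) -> int:
        return len(self.table)

    def burned(self, burn_in: float = 0.1) -> "TraceLog":
        n = len(self.table)
        return TraceLog(self.table.iloc[int(burn_in * n):].reset_index(drop=True))

    def write_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str) -> "TraceLog":
        return cls(pd.read_csv(path, sep="\t", comment="#"))


@dataclass
class McmcResult:
    trace: TraceLog
    trees: list[TimeTree]
    final_state: McmcState
    schedule: OperatorSchedule


Logger = tuple[str, Callable[[McmcState], object]]


def _default_loggers(state: McmcState) -> list[Logger]:
    loggers: list[Logger] = []
    if state.tree is not None:
        loggers.append(("root_height", lambda s: s.tree.root.height))
        loggers.append(("tree_length", lambda s: s.tree.tree_length))
        loggers.append(
            ("n_sampled_ancestors", lambda s: len(s.tree.sampled_ancestors))
        )
    if state.site is not None:
        loggers.append(("model_code", lambda s: s.site.code))
        loggers.append(("freqs_equal", lambda s: int(s.site.freqs_equal)))
        loggers.append(("use_gamma", lambda s: int(s.site.use_gamma)))
        loggers.append(("use_inv", lambda s: int(s.site.use_inv)))
    for key in state.params:
        loggers.append((key, lambda s, k=key: s.params[k]))
    return loggers


def run_mcmc(
    state0: McmcState,
    target: Target,
    schedule: OperatorSchedule,
    chain_length: int,
    log_every: int = 100,
    seed: int = 1,
    loggers: Optional[list[Logger]] = None,
    log_trees: bool = False,
    validate_every: int = 1000,
    check_target_every: int = 1000,
) -> McmcResult:
    """Run the chain and return trace, sampled trees and final state.

    ``validate_every``/``check_target_every`` spot-check the tree
    invariants and the stored log posterior against fresh recomputation.
    """
    rng = np.random.default_rng(seed)
    state = state0
    logp = target(state)
    if not math.isfinite(logp):
        raise ValueError(
            "initial state has non-finite posterior; choose a starting "
            "state inside the prior's support"
        )
    if loggers is None:
        loggers = _default_loggers(state0)
    rows: list[list] = []
    trees: list[TimeTree] = []

    def record(sample: int) -> None:
        rows.append([sample, logp] + [fn(state) for _, fn in loggers])
        if log_trees and state.tree is not None:
            trees.append(state.tree.copy())

    record(0)
    for step in range(1, chain_length + 1):
        op = schedule.choose(rng)
        op.n_proposed += 1
        proposal = op.propose(state, rng)
        accepted = False
        if proposal is not None:
            new_state, log_adj = proposal
            new_logp = target(new_state)
            if math.isnan(new_logp):
                raise FloatingPointError(
                    f"non-finite posterior proposed by {op.name} at step {step}"
                )
            if math.log(rng.random()) < new_logp - logp + log_adj:
                state, logp = new_state, new_logp
                accepted = True
                op.n_accepted += 1
        if op.tunable and step <= schedule.tune_for:
            op.tune(accepted, step)
        if validate_every and step % validate_every == 0 and state.tree is not None:
            state.tree.validate()
        if check_target_every and step % check_target_every == 0:
            fresh = target(state)
            if abs(fresh - logp) > 1e-8 * max(1.0, abs(fresh)):
                raise FloatingPointError(
                    f"cached posterior {logp} drifted from recomputation {fresh}"
                )
        if step % log_every == 0:
            record(step)

    columns = ["Sample", "posterior"] + [name for name, _ in loggers]
    trace = TraceLog(pd.DataFrame(rows, columns=columns))
    return McmcResult(trace, trees, state, schedule)
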