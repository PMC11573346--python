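"""Yield statistics, binomial connection analytics, and replicate comparisons.

Bookkeeping conventions follow standard paired-recording practice: a *paired
recording* is two cells simultaneously in whole-cell configuration; *probed
connections* is twice the number of paired recordings (each pair is tested in
both directions); the whole-cell *success rate* is successes over attempts.

The binomial helper answers power-style questions such as "with a 16.9%
per-pair connection probability, what is the chance of finding at least 3
connections in 29 paired recordings?" (about 89%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import ExperimentConfig
from .efficiency import ProbeMatrix
from .scheduler import ScheduleResult, run_patch_walk, run_traditional
from .slice_synth import (
    CellSite,
    ConnectionModel,
    SliceSpec,
    distance_matrix,
    generate_slice,
    sample_ground_truth,
)

__all__ = [
    "ExperimentSummary",
    "ReplicateSet",
    "ComparisonResult",
    "prob_at_least_k",
    "summarize",
    "compare_strategies",
    "expected_connections",
    "binomial_ci",
]


@dataclass(frozen=True)
class ExperimentSummary:
    """Headline numbers of one simulated (or real) patching session."""

    attempts: int
    whole_cell_successes: int
    success_rate_percent: Optional[float]  # None when there were no attempts
    paired_recordings: int
    probed_connections: int  # directed; always 2 x paired_recordings
    connections_found: int
    mean_time_to_pair_min: Optional[float]
    mean_intersomatic_distance_um: Optional[float]

    def to_dict(self) -> dict:
        return {
            "attempts": self.attempts,
            "whole_cell_successes": self.whole_cell_successes,
            "success_rate_percent": self.success_rate_percent,
            "paired_recordings": self.paired_recordings,
            "probed_connections": self.probed_connections,
            "connections_found": self.connections_found,
            "mean_time_to_pair_min": self.mean_time_to_pair_min,
            "mean_intersomatic_distance_um": self.mean_intersomatic_distance_um,
        }


def prob_at_least_k(m: int, p: float, k: int) -> float:
    """P(X >= k) for X ~ Binomial(m, p), via the stable survival function."""
    if not (0 <= p <= 1):
        raise ValueError("p must be a probability")
    if not (0 <= k <= m):
        raise ValueError("need 0 <= k <= m")
    if k == 0:
        return 1.0
    return float(sps.binom.sf(k - 1, m, p))


def summarize(result: ScheduleResult) -> ExperimentSummary:
    """Reduce a session to its summary counts and means (pure; no side effects).

    Time-to-pair is measured pair to pair: the first pair from experiment
    start, each later pair from the completion of the previous one.
    """
    attempts = len(result.attempts)
    successes = result.n_whole_cell
    rate = round(100.0 * successes / attempts, 1) if attempts else None
    pairs = result.pairs
    if pairs:
        ends = [pr.t_end for pr in pairs]
        gaps = np.diff([0.0] + ends)
        mean_ttp = float(np.mean(gaps)) / 60.0
        mean_dist = float(np.mean([pr.distance_um for pr in pairs]))
    else:
        mean_ttp = None
        mean_dist = None
    return ExperimentSummary(
        attempts=attempts,
        whole_cell_successes=successes,
        success_rate_percent=rate,
        paired_recordings=len(pairs),
        probed_connections=2 * len(pairs),
        connections_found=sum(pr.connections_found for pr in pairs),
        mean_time_to_pair_min=mean_ttp,
        mean_intersomatic_distance_um=mean_dist,
    )


def binomial_ci(
    successes: int, trials: int, level: float = 0.95, exact: bool = False
) -> tuple[float, float]:
    """Binomial proportion CI: normal approximation, or Clopper-Pearson if exact."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    phat = successes / trials
    if exact:
        alpha = 1 - level
        lo = sps.beta.ppf(alpha / 2, successes, trials - successes + 1) if successes > 0 else 0.0
        hi = (
            sps.beta.ppf(1 - alpha / 2, successes + 1, trials - successes)
            if successes < trials
            else 1.0
        )
        return float(lo), float(hi)
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(phat * (1 - phat) / trials)
    return max(0.0, phat - half), min(1.0, phat + half)


def expected_connections(
    cells: Sequence[CellSite], model: ConnectionModel, probe_matrix: ProbeMatrix
) -> float:
    """Analytic expectation: sum of p(d(i, j)) over probed directed pairs."""
    if probe_matrix.size != len(cells):
        raise ValueError(
            f"probe matrix size {probe_matrix.size} does not match {len(cells)} cells"
        )
    if probe_matrix.size == 0 or probe_matrix.directed_count == 0:
        return 0.0
    d = distance_matrix(cells)
    p = model.probability(d)
    return float(p[probe_matrix.probed].sum())


@dataclass
class ReplicateSet:
    """Per-replicate summaries of one strategy plus aggregate statistics."""

    strategy: str
    seeds: list[int]
    summaries: list[ExperimentSummary]

    def mean(self, attr: str) -> float:
        vals = [getattr(s, attr) for s in self.summaries if getattr(s, attr) is not None]
        return float(np.mean(vals)) if vals else float("nan")

    def ci(self, attr: str, level: float = 0.95) -> tuple[float, float]:
        """Normal-approximation CI on the replicate mean."""
        vals = np.array(
            [getattr(s, attr) for s in self.summaries if getattr(s, attr) is not None],
            dtype=float,
        )
        if len(vals) < 2:
            m = float(vals.mean()) if len(vals) else float("nan")
            return (m, m)
        z = sps.norm.ppf(0.975 if level == 0.95 else 0.5 + level / 2)
        half = z * vals.std(ddof=1) / math.sqrt(len(vals))
        return float(vals.mean() - half), float(vals.mean() + half)


@dataclass
class ComparisonResult:
    """Paired patch-walk vs traditional replicates on identical slices."""

    patchwalk: ReplicateSet
    traditional: ReplicateSet
    table: pd.DataFrame = field(repr=False)

    @property
    def improvement_percent(self) -> float:
        """Empirical improvement in probed connections, patch-walk over traditional."""
        trad = self.traditional.mean("probed_connections")
        if trad == 0:
            raise ZeroDivisionError("traditional strategy probed no connections")
        return 100.0 * (self.patchwalk.mean("probed_connections") - trad) / trad

    def aggregate(self) -> dict:
        out = {"improvement_percent": self.improvement_percent}
        for rs in (self.patchwalk, self.traditional):
            for attr in ("paired_recordings", "probed_connections", "connections_found"):
                lo, hi = rs.ci(attr)
                out[f"{rs.strategy}_mean_{attr}"] = rs.mean(attr)
                out[f"{rs.strategy}_ci95_{attr}"] = [lo, hi]
        return out


def compare_strategies(
    slice_spec: SliceSpec,
    config: ExperimentConfig | None = None,
    n_replicates: int = 100,
    seed: int = 0,
    common_random_numbers: bool = True,
) -> ComparisonResult:
    """Run paired replicates of both strategies and tabulate their yields.

    Each replicate draws a fresh slice and ground truth; with
    ``common_random_numbers`` (default) both strategies run on the *same*
    slice, truth, and engine seed, which removes between-slice variance from
    the comparison.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    config = config or ExperimentConfig()
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) for s in ss.generate_state(3 * n_replicates) % (2**31)]

    rows = []
    pw_sums, tr_sums, seeds_used = [], [], []
    for i in range(n_replicates):
        s_slice, s_pw, s_tr = child_seeds[3 * i : 3 * i + 3]
        if common_random_numbers:
            s_tr = s_pw
        spec = slice_spec.model_copy(update={"seed": s_slice})
        cells = generate_slice(spec)
        truth = sample_ground_truth(cells, ConnectionModel.default(), seed=s_slice)
        res_pw = run_patch_walk(cells, truth, config, seed=s_pw)
        res_tr = run_traditional(cells, truth, config, seed=s_tr)
        sum_pw, sum_tr = summarize(res_pw), summarize(res_tr)
        pw_sums.append(sum_pw)
        tr_sums.append(sum_tr)
        seeds_used.append(s_pw)
        for strat, sm in (("patchwalk", sum_pw), ("traditional", sum_tr)):
            rows.append({"replicate": i, "strategy": strat, **sm.to_dict()})

    table = pd.DataFrame(rows)
    return ComparisonResult(
        patchwalk=ReplicateSet("patchwalk", seeds_used, pw_sums),
        traditional=ReplicateSet("traditional", seeds_used, tr_sums),
        table=table,
    )
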