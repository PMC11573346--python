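"""Coordinated patch-walking scheduler and the traditional-strategy baseline.

Two pipettes share one brain slice, one cell queue, and one microscope.  Each
pipette repeatedly takes the unattempted cell nearest its calibrated home
position and walks through the patching pipeline:

    pipette finding -> neuron hunting -> gigaseal -> break-in -> whole cell

The stage/camera is an exclusive resource: only one pipette may be in the
finding/hunting phases at a time (the other works in parallel on the later,
camera-free stages, or waits).  A failed attempt routes the pipette through
cleaning and back to the queue.  When both pipettes hold whole-cell
recordings, the pair is tested for synaptic connectivity in both directions;
afterwards the strategies diverge:

* **patch-walk** — only the pipette that has held its cell the *longest* is
  released, cleaned, and re-used, so the freshly patched cell is probed
  against a still-held one and the rig "walks" across the slice;
* **traditional** — both pipettes are retracted and cleaned, and a new
  disjoint pair is patched.

The simulation is a seeded discrete-event loop over simulated seconds; the
same seed and configuration replay to an identical event log (JSON-lines:
one ``{t, pipette, event, cell, detail}`` object per line).
"""

from __future__ import annotations

import heapq
import json
import math
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigError, ExperimentConfig, StageDuration
from .rig_model import measure_connection
from .slice_synth import CellSite, GroundTruth, intersomatic_distance

__all__ = [
    "PipetteState",
    "PipetteAgent",
    "CellQueue",
    "MicroscopeToken",
    "AttemptRecord",
    "PairRecording",
    "ScheduleResult",
    "StateError",
    "assign_next_cell",
    "held_release_choice",
    "run_patch_walk",
    "run_traditional",
]


class StateError(RuntimeError):
    """An operation was applied to a pipette in an incompatible lifecycle state."""


class PipetteState(str, Enum):
    IDLE = "IDLE"
    PIPETTE_FINDING = "PIPETTE_FINDING"
    NEURON_HUNTING = "NEURON_HUNTING"
    GIGASEAL = "GIGASEAL"
    BREAK_IN = "BREAK_IN"
    WHOLE_CELL_HOLD = "WHOLE_CELL_HOLD"
    CONNECTIVITY_TEST = "CONNECTIVITY_TEST"
    CLEANING = "CLEANING"
    RETRACTED = "RETRACTED"


#: states in which a pipette has a cell assigned
_ACTIVE_STATES = frozenset(
    {
        PipetteState.PIPETTE_FINDING,
        PipetteState.NEURON_HUNTING,
        PipetteState.GIGASEAL,
        PipetteState.BREAK_IN,
        PipetteState.WHOLE_CELL_HOLD,
        PipetteState.CONNECTIVITY_TEST,
    }
)


@dataclass
class PipetteAgent:
    """One pipette: home position, lifecycle state, and (maybe) a held cell."""

    pipette_id: str
    home: np.ndarray
    state: PipetteState = PipetteState.IDLE
    assigned_cell: Optional[CellSite] = None
    whole_cell_since: Optional[float] = None
    label: Optional[str] = None  # "n.p" name once whole cell is achieved

    def is_holding(self) -> bool:
        return self.state in (PipetteState.WHOLE_CELL_HOLD, PipetteState.CONNECTIVITY_TEST)


class CellQueue:
    """Unattempted cells; a cell leaves the queue exactly once, never returns."""

    def __init__(self, cells: Sequence[CellSite]):
        self._cells: list[CellSite] = list(cells)

    def __len__(self) -> int:
        return len(self._cells)

    def peek_all(self) -> list[CellSite]:
        return list(self._cells)

    def pop_nearest(
        self,
        home: np.ndarray,
        partner_site: Optional[CellSite] = None,
        d_min: float = 0.0,
        d_max: Optional[float] = None,
    ) -> Optional[CellSite]:
        """Remove and return the queue cell nearest ``home`` (ties: lowest cell_id).

        If a partner cell and a distance window are given, candidates are first
        restricted to cells within [d_min, d_max] of the partner's soma so the
        eventual pair stays probe-worthy; if no cell qualifies, fall back to
        the unconstrained nearest.
        """
        if not self._cells:
            return None
        pool = self._cells
        if partner_site is not None and (d_min > 0 or d_max is not None):
            hi = math.inf if d_max is None else d_max
            constrained = [
                c
                for c in self._cells
                if d_min <= intersomatic_distance(c, partner_site) <= hi
            ]
            if constrained:
                pool = constrained
        best = min(pool, key=lambda c: (float(np.linalg.norm(c.xyz - home)), c.cell_id))
        self._cells.remove(best)
        return best


def assign_next_cell(
    pipette: PipetteAgent,
    queue: CellQueue,
    partner_site: Optional[CellSite] = None,
    d_min: float = 0.0,
    d_max: Optional[float] = None,
) -> Optional[CellSite]:
    """Pop the nearest-to-home cell and assign it to an available pipette."""
    if pipette.state in _ACTIVE_STATES:
        raise StateError(
            f"pipette {pipette.pipette_id} is {pipette.state.value}; cannot take a new cell"
        )
    site = queue.pop_nearest(pipette.home, partner_site=partner_site, d_min=d_min, d_max=d_max)
    if site is not None:
        pipette.assigned_cell = site
    return site


class MicroscopeToken:
    """Exclusive stage/camera ownership with a FIFO wait list."""

    def __init__(self) -> None:
        self.holder: Optional[str] = None
        self._waiting: deque[tuple[str, Callable[[], None]]] = deque()

    def request(self, pipette_id: str, granted: Callable[[], None]) -> bool:
        """Grant immediately if free (callback runs now), else queue the request."""
        if self.holder is None:
            self.holder = pipette_id
            granted()
            return True
        self._waiting.append((pipette_id, granted))
        return False

    def release(self, pipette_id: str) -> None:
        if self.holder != pipette_id:
            raise StateError(f"pipette {pipette_id} does not hold the microscope")
        self.holder = None
        if self._waiting:
            nxt_id, cb = self._waiting.popleft()
            self.holder = nxt_id
            cb()


@dataclass
class AttemptRecord:
    """One patch attempt on one cell: stage outcomes and timing."""

    cell_id: int
    pipette_id: str
    t_start: float
    t_end: Optional[float] = None
    stages: dict = field(default_factory=dict)  # stage name -> bool
    success: bool = False
    label: Optional[str] = None


@dataclass
class PairRecording:
    """Two cells held simultaneously in whole-cell, probed in both directions."""

    cell_a: int
    cell_b: int
    label_a: str
    label_b: str
    t_start: float
    t_end: float
    distance_um: float
    found_a_to_b: bool
    found_b_to_a: bool
    qc_pass: bool = True

    @property
    def probed_directed(self) -> int:
        return 2

    @property
    def connections_found(self) -> int:
        return int(self.found_a_to_b) + int(self.found_b_to_a)


@dataclass
class ScheduleResult:
    """Full outcome of one simulated session: attempts, pairs, and event log."""

    strategy: str
    seed: int
    config: ExperimentConfig
    cells: list[CellSite]
    attempts: list[AttemptRecord]
    pairs: list[PairRecording]
    events: list[dict]
    duration_s: float

    @property
    def n_whole_cell(self) -> int:
        return sum(a.success for a in self.attempts)

    def connectivity_frame(self) -> pd.DataFrame:
        """Directed connectivity matrix over recorded cells, "n.p"-style labels.

        1 = probed and connected, 0 = probed and not connected, NaN = never
        probed (the two cells were not held simultaneously).
        """
        labels = [a.label for a in self.attempts if a.success]
        frame = pd.DataFrame(np.nan, index=labels, columns=labels)
        for pr in self.pairs:
            frame.loc[pr.label_a, pr.label_b] = int(pr.found_a_to_b)
            frame.loc[pr.label_b, pr.label_a] = int(pr.found_b_to_a)
        return frame

    def write_events_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for ev in self.events:
                fh.write(json.dumps(ev) + "\n")


def held_release_choice(pipettes: Sequence[PipetteAgent]) -> str:
    """Which pipette walks on: the one whose whole-cell hold started first.

    Ties break toward the lexicographically lower pipette id.
    """
    holding = [p for p in pipettes if p.is_holding() and p.whole_cell_since is not None]
    if len(holding) < 2:
        raise StateError("need two simultaneously held pipettes to choose a release")
    return min(holding, key=lambda p: (p.whole_cell_since, p.pipette_id)).pipette_id


class _EventLoop:
    """Minimal discrete-event kernel: a time-ordered callback queue."""

    def __init__(self) -> None:
        self.now = 0.0
        self._seq = 0
        self._queue: list[tuple[float, int, Callable[[], None]]] = []

    def schedule(self, delay: float, fn: Callable[[], None]) -> None:
        heapq.heappush(self._queue, (self.now + delay, self._seq, fn))
        self._seq += 1

    def run(self, until: float = math.inf) -> None:
        while self._queue:
            t, _, fn = heapq.heappop(self._queue)
            if t > until:
                self.now = until
                return
            self.now = t
            fn()


class _Engine:
    """Shared two-pipette session machinery; strategies differ in release policy."""

    def __init__(
        self,
        cells: Sequence[CellSite],
        ground_truth: Optional[GroundTruth],
        config: ExperimentConfig,
        seed: int,
        release_policy: str,
    ) -> None:
        if config.n_pipettes != 2:
            raise ConfigError(
                "only two-pipette rigs are supported; collision-safe scheduling "
                "for >2 pipettes requires route planning beyond this engine"
            )
        if not cells:
            raise ValueError("need at least one cell")
        self.cells = list(cells)
        self.truth = ground_truth
        self.config = config
        self.seed = seed
        self.release_policy = release_policy
        self.rng = np.random.default_rng(seed)
        self.loop = _EventLoop()
        self.queue = CellQueue(self.cells)
        self.token = MicroscopeToken()
        homes = config.pipette_homes
        self.pipettes = {
            "a": PipetteAgent("a", np.asarray(homes[0], dtype=float)),
            "b": PipetteAgent("b", np.asarray(homes[1], dtype=float)),
        }
        self.events: list[dict] = []
        self.attempts: list[AttemptRecord] = []
        self.pairs: list[PairRecording] = []
        self._open_attempt: dict[str, AttemptRecord] = {}
        self._next_cell_number = 1
        self._pair_t_start: Optional[float] = None

    # -- logging ---------------------------------------------------------

    def _log(self, pipette: Optional[str], event: str, cell: Optional[int] = None, **detail):
        self.events.append(
            {
                "t": round(self.loop.now, 6),
                "pipette": pipette,
                "event": event,
                "cell": cell,
                "detail": detail or {},
            }
        )

    # -- sampling --------------------------------------------------------

    def _duration(self, spec: StageDuration) -> float:
        if spec.sd_s == 0:
            return spec.mean_s
        a = (0.0 - spec.mean_s) / spec.sd_s
        return float(
            stats.truncnorm.rvs(a, np.inf, loc=spec.mean_s, scale=spec.sd_s, random_state=self.rng)
        )

    def _stage_outcome(self, stage: str) -> bool:
        cfg = self.config
        if cfg.whole_cell_success is not None:
            # shortcut mode: a single end-to-end Bernoulli, applied at break-in
            p = cfg.whole_cell_success if stage == "break_in" else 1.0
        else:
            p = {
                "neuron_hunting": cfg.hunt_success,
                "gigaseal": cfg.seal_success,
                "break_in": cfg.breakin_success,
            }[stage]
        if p >= 1.0:
            return True
        if p <= 0.0:
            return False
        return bool(self.rng.random() < p)

    # -- lifecycle -------------------------------------------------------

    def run(self) -> ScheduleResult:
        for pip in self.pipettes.values():
            self._start_next(pip)
        self.loop.run(until=self.config.max_duration_s)
        for pip in self.pipettes.values():
            if pip.state == PipetteState.WHOLE_CELL_HOLD:
                self._log(pip.pipette_id, "held_unpaired", cell=pip.assigned_cell.cell_id)
        self._log(None, "experiment_end")
        return ScheduleResult(
            strategy=self.release_policy,
            seed=self.seed,
            config=self.config,
            cells=self.cells,
            attempts=self.attempts,
            pairs=self.pairs,
            events=self.events,
            duration_s=self.loop.now,
        )

    def _partner(self, pip: PipetteAgent) -> PipetteAgent:
        return self.pipettes["b" if pip.pipette_id == "a" else "a"]

    def _start_next(self, pip: PipetteAgent) -> None:
        partner = self._partner(pip)
        partner_site = partner.assigned_cell if partner.is_holding() else None
        site = assign_next_cell(
            pip,
            self.queue,
            partner_site=partner_site,
            d_min=self.config.pair_distance_min_um,
            d_max=self.config.pair_distance_max_um,
        )
        if site is None:
            pip.state = PipetteState.RETRACTED
            self._log(pip.pipette_id, "retracted", reason="queue_empty")
            return
        pip.state = PipetteState.PIPETTE_FINDING
        rec = AttemptRecord(cell_id=site.cell_id, pipette_id=pip.pipette_id, t_start=self.loop.now)
        self._open_attempt[pip.pipette_id] = rec
        self.attempts.append(rec)
        self._log(pip.pipette_id, "cell_assigned", cell=site.cell_id)
        self.token.request(pip.pipette_id, lambda: self._on_microscope(pip))

    def _on_microscope(self, pip: PipetteAgent) -> None:
        self._log(pip.pipette_id, "microscope_granted", cell=pip.assigned_cell.cell_id)
        self.loop.schedule(
            self._duration(self.config.durations.pipette_finding),
            lambda: self._after_finding(pip),
        )

    def _after_finding(self, pip: PipetteAgent) -> None:
        pip.state = PipetteState.NEURON_HUNTING
        self._log(pip.pipette_id, "neuron_hunting_start", cell=pip.assigned_cell.cell_id)
        self.loop.schedule(
            self._duration(self.config.durations.neuron_hunting),
            lambda: self._after_hunting(pip),
        )

    def _after_hunting(self, pip: PipetteAgent) -> None:
        ok = self._stage_outcome("neuron_hunting")
        self._open_attempt[pip.pipette_id].stages["neuron_hunting"] = ok
        # camera/stage freed as soon as hunting concludes, either way
        self.token.release(pip.pipette_id)
        self._log(pip.pipette_id, "microscope_released", cell=pip.assigned_cell.cell_id)
        if not ok:
            self._log(pip.pipette_id, "neuron_hunting_failed", cell=pip.assigned_cell.cell_id)
            self._fail_attempt(pip)
            return
        self._log(pip.pipette_id, "neuron_detected", cell=pip.assigned_cell.cell_id)
        pip.state = PipetteState.GIGASEAL
        dur = self._duration(self.config.durations.gigaseal) + self.config.thresholds.gigaseal_wait_s
        self.loop.schedule(dur, lambda: self._after_gigaseal(pip))

    def _after_gigaseal(self, pip: PipetteAgent) -> None:
        ok = self._stage_outcome("gigaseal")
        self._open_attempt[pip.pipette_id].stages["gigaseal"] = ok
        if not ok:
            self._log(pip.pipette_id, "gigaseal_failed", cell=pip.assigned_cell.cell_id)
            self._fail_attempt(pip)
            return
        self._log(pip.pipette_id, "gigaseal_formed", cell=pip.assigned_cell.cell_id)
        pip.state = PipetteState.BREAK_IN
        self.loop.schedule(
            self._duration(self.config.durations.break_in),
            lambda: self._after_breakin(pip),
        )

    def _after_breakin(self, pip: PipetteAgent) -> None:
        ok = self._stage_outcome("break_in")
        rec = self._open_attempt[pip.pipette_id]
        rec.stages["break_in"] = ok
        if not ok:
            self._log(pip.pipette_id, "breakin_failed", cell=pip.assigned_cell.cell_id)
            self._fail_attempt(pip)
            return
        pip.state = PipetteState.WHOLE_CELL_HOLD
        pip.whole_cell_since = self.loop.now
        pip.label = f"{self._next_cell_number}.{pip.pipette_id}"
        self._next_cell_number += 1
        rec.success = True
        rec.t_end = self.loop.now
        rec.label = pip.label
        self._log(pip.pipette_id, "whole_cell", cell=pip.assigned_cell.cell_id, label=pip.label)
        self._maybe_pair()

    def _fail_attempt(self, pip: PipetteAgent) -> None:
        rec = self._open_attempt.pop(pip.pipette_id)
        rec.t_end = self.loop.now
        rec.success = False
        self._to_cleaning(pip)

    def _to_cleaning(self, pip: PipetteAgent) -> None:
        pip.assigned_cell = None
        pip.whole_cell_since = None
        pip.label = None
        pip.state = PipetteState.CLEANING
        self._log(pip.pipette_id, "cleaning_start")
        self.loop.schedule(
            self._duration(self.config.durations.cleaning),
            lambda: self._after_cleaning(pip),
        )

    def _after_cleaning(self, pip: PipetteAgent) -> None:
        pip.state = PipetteState.IDLE
        self._log(pip.pipette_id, "cleaning_done")
        self._start_next(pip)

    # -- pairing ---------------------------------------------------------

    def _maybe_pair(self) -> None:
        a, b = self.pipettes["a"], self.pipettes["b"]
        if a.state == PipetteState.WHOLE_CELL_HOLD and b.state == PipetteState.WHOLE_CELL_HOLD:
            a.state = b.state = PipetteState.CONNECTIVITY_TEST
            self._pair_t_start = self.loop.now
            self._log(
                None,
                "connectivity_test_start",
                pair=[a.assigned_cell.cell_id, b.assigned_cell.cell_id],
            )
            self.loop.schedule(
                self._duration(self.config.durations.connectivity_test), self._after_pair_test
            )

    def _after_pair_test(self) -> None:
        a, b = self.pipettes["a"], self.pipettes["b"]
        ca, cb = a.assigned_cell, b.assigned_cell
        ia, ib = ca.cell_id - 1, cb.cell_id - 1  # ground-truth indices are 0-based
        if self.truth is not None:
            found_ab = measure_connection(ia, ib, self.truth, self.config.detect_prob, self.rng)
            found_ba = measure_connection(ib, ia, self.truth, self.config.detect_prob, self.rng)
        else:
            found_ab = found_ba = False
        pr = PairRecording(
            cell_a=ca.cell_id,
            cell_b=cb.cell_id,
            label_a=a.label,
            label_b=b.label,
            t_start=self._pair_t_start,
            t_end=self.loop.now,
            distance_um=intersomatic_distance(ca, cb),
            found_a_to_b=found_ab,
            found_b_to_a=found_ba,
        )
        self.pairs.append(pr)
        self._log(
            None,
            "pair_recorded",
            pair=[ca.cell_id, cb.cell_id],
            labels=[a.label, b.label],
            found=[found_ab, found_ba],
            distance_um=round(pr.distance_um, 3),
        )
        a.state = b.state = PipetteState.WHOLE_CELL_HOLD
        if self.release_policy == "traditional":
            for pip in (a, b):
                self._log(pip.pipette_id, "released", cell=pip.assigned_cell.cell_id)
                self._to_cleaning(pip)
        else:
            rid = held_release_choice([a, b])
            pip = self.pipettes[rid]
            self._log(rid, "released", cell=pip.assigned_cell.cell_id, rule="earliest_whole_cell")
            self._to_cleaning(pip)


def run_patch_walk(
    cells: Sequence[CellSite],
    ground_truth: Optional[GroundTruth],
    config: ExperimentConfig | None = None,
    seed: int = 0,
) -> ScheduleResult:
    """Simulate one patch-walking session on a slice.

    After each paired connectivity test only the longer-held pipette is
    cleaned and re-used, so successive whole-cell recordings chain across the
    slice; with perfectly reliable stages, n cells yield n - 1 pairs.
    """
    eng = _Engine(cells, ground_truth, config or ExperimentConfig(), seed, "patchwalk")
    return eng.run()


def run_traditional(
    cells: Sequence[CellSite],
    ground_truth: Optional[GroundTruth],
    config: ExperimentConfig | None = None,
    seed: int = 0,
) -> ScheduleResult:
    """Simulate the traditional baseline: patch a pair, probe it, retract both.

    With perfectly reliable stages, n cells yield floor(n / 2) pairs.
    """
    eng = _Engine(cells, ground_truth, config or ExperimentConfig(), seed, "traditional")
    return eng.run()
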