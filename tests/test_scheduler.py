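"""Cell assignment, microscope arbitration, and the two coordination strategies."""

import numpy as np
import pytest

from patchwalk.config import ConfigError, ExperimentConfig
from patchwalk.efficiency import patchwalk_possible, traditional_possible
from patchwalk.scheduler import (
    CellQueue,
    MicroscopeToken,
    PipetteAgent,
    PipetteState,
    StateError,
    assign_next_cell,
    held_release_choice,
    run_patch_walk,
    run_traditional,
)
from patchwalk.slice_synth import (
    CellSite,
    ConnectionModel,
    SliceSpec,
    generate_slice,
    sample_ground_truth,
)


def microscope_intervals(events):
    """(pipette, t_granted, t_released) triples from the event log."""
    open_at = {}
    out = []
    for ev in events:
        if ev["event"] == "microscope_granted":
            open_at[ev["pipette"]] = ev["t"]
        elif ev["event"] == "microscope_released":
            out.append((ev["pipette"], open_at.pop(ev["pipette"]), ev["t"]))
    return out


def hold_intervals(events, end_time):
    """label -> (t_whole_cell, t_released_or_end) from the event log."""
    spans = {}
    open_label = {}
    for ev in events:
        if ev["event"] == "whole_cell":
            open_label[ev["pipette"]] = (ev["detail"]["label"], ev["t"])
        elif ev["event"] == "released":
            label, t0 = open_label.pop(ev["pipette"])
            spans[label] = (t0, ev["t"])
    for label, t0 in open_label.values():
        spans[label] = (t0, end_time)
    return spans


class TestAssignment:
    def _pipette(self, home=(0.0, 0.0, 0.0)):
        return PipetteAgent("a", np.array(home))

    def test_nearest_cell_chosen_and_removed(self):
        q = CellQueue([CellSite(1, 50, 0, 50), CellSite(2, 80, 0, 50)])
        pip = self._pipette()
        got = assign_next_cell(pip, q)
        assert got.cell_id == 1 and len(q) == 1
        assert pip.assigned_cell is got

    def test_equidistant_tie_breaks_to_lower_id(self):
        q = CellQueue([CellSite(7, 0, 60, 50), CellSite(3, 60, 0, 50)])
        assert assign_next_cell(self._pipette(), q).cell_id == 3

    def test_constrained_mode_filters_then_takes_nearest(self):
        # partner holds a cell far from everything except cell 9
        partner_cell = CellSite(99, 1000, 1000, 50)
        q = CellQueue(
            [
                CellSite(1, 10, 0, 50),  # nearest to home but 1400 um from partner
                CellSite(9, 900, 950, 50),  # 111 um from partner
            ]
        )
        got = assign_next_cell(self._pipette(), q, partner_site=partner_cell, d_max=200.0)
        assert got.cell_id == 9

    def test_constrained_mode_falls_back_when_empty(self):
        partner_cell = CellSite(99, 5000, 5000, 50)
        q = CellQueue([CellSite(1, 10, 0, 50), CellSite(2, 20, 0, 50)])
        got = assign_next_cell(self._pipette(), q, partner_site=partner_cell, d_max=200.0)
        assert got.cell_id == 1

    def test_empty_queue_returns_none(self):
        assert assign_next_cell(self._pipette(), CellQueue([])) is None

    def test_active_pipette_cannot_take_cell(self):
        pip = self._pipette()
        pip.state = PipetteState.NEURON_HUNTING
        with pytest.raises(StateError):
            assign_next_cell(pip, CellQueue([CellSite(1, 0, 0, 50)]))


class TestMicroscopeToken:
    def test_mutual_exclusion_and_fifo_handoff(self):
        token = MicroscopeToken()
        order = []
        assert token.request("a", lambda: order.append("a")) is True
        assert token.request("b", lambda: order.append("b")) is False
        assert order == ["a"]
        token.release("a")
        assert order == ["a", "b"] and token.holder == "b"

    def test_release_by_non_holder_rejected(self):
        token = MicroscopeToken()
        token.request("a", lambda: None)
        with pytest.raises(StateError):
            token.release("b")


class TestReleaseChoice:
    def _held(self, pid, t):
        pip = PipetteAgent(pid, np.zeros(3), state=PipetteState.WHOLE_CELL_HOLD)
        pip.whole_cell_since = t
        pip.assigned_cell = CellSite(1, 0, 0, 50)
        return pip

    def test_earlier_hold_released(self):
        assert held_release_choice([self._held("a", 100.0), self._held("b", 400.0)]) == "a"

    def test_tie_breaks_to_lower_id(self):
        assert held_release_choice([self._held("b", 100.0), self._held("a", 100.0)]) == "a"

    def test_single_holder_is_an_error(self):
        lone = self._held("a", 100.0)
        idle = PipetteAgent("b", np.zeros(3))
        with pytest.raises(StateError):
            held_release_choice([lone, idle])


@pytest.fixture()
def lossy_config(perfect_config):
    return perfect_config.model_copy(
        update={"hunt_success": 0.7, "seal_success": 0.85, "breakin_success": 0.85}
    )


class TestEngines:
    @pytest.mark.parametrize("n", [2, 3, 7, 12, 20])
    def test_perfect_walk_chains_all_cells(self, n, perfect_config):
        cells = generate_slice(SliceSpec(n_cells=n, seed=n))
        res = run_patch_walk(cells, None, perfect_config, seed=0)
        assert len(res.pairs) == n - 1
        assert 2 * len(res.pairs) == patchwalk_possible(n, 2)
        assert len(res.attempts) == n and all(a.success for a in res.attempts)

    @pytest.mark.parametrize("n", [2, 5, 6, 11, 20])
    def test_perfect_traditional_patches_disjoint_pairs(self, n, perfect_config):
        cells = generate_slice(SliceSpec(n_cells=n, seed=n))
        res = run_traditional(cells, None, perfect_config, seed=0)
        assert len(res.pairs) == n // 2
        assert 2 * len(res.pairs) == traditional_possible(n, 2)
        assert len(res.attempts) == n

    def test_single_cell_yields_no_pairs(self, perfect_config):
        res = run_patch_walk([CellSite(1, 100, 100, 50)], None, perfect_config, seed=0)
        assert len(res.pairs) == 0 and len(res.attempts) == 1

    def test_hopeless_rig_consumes_queue_without_pairs(self, perfect_config):
        cfg = perfect_config.model_copy(update={"whole_cell_success": 0.0})
        cells = generate_slice(SliceSpec(n_cells=9, seed=1))
        res = run_patch_walk(cells, None, cfg, seed=0)
        assert len(res.pairs) == 0
        assert len(res.attempts) == 9 and not any(a.success for a in res.attempts)

    def test_each_cell_attempted_at_most_once(self, lossy_config):
        cells = generate_slice(SliceSpec(n_cells=10, seed=2))
        res = run_patch_walk(cells, None, lossy_config, seed=3)
        attempted = [a.cell_id for a in res.attempts]
        assert len(attempted) == len(set(attempted))
        assert len(attempted) <= len(cells)

    @pytest.mark.parametrize("seed", range(5))
    def test_microscope_never_shared(self, seed, lossy_config):
        cells = generate_slice(SliceSpec(n_cells=10, seed=seed))
        res = run_patch_walk(cells, None, lossy_config, seed=seed)
        ivs = sorted(microscope_intervals(res.events), key=lambda iv: iv[1])
        for (p1, _, end1), (p2, start2, _) in zip(ivs, ivs[1:]):
            assert end1 <= start2, f"{p1} and {p2} held the microscope concurrently"

    def test_pairs_recorded_while_both_cells_held(self, lossy_config, default_model):
        cells = generate_slice(SliceSpec(n_cells=10, seed=4))
        truth = sample_ground_truth(cells, default_model, seed=4)
        res = run_patch_walk(cells, truth, lossy_config, seed=5)
        spans = hold_intervals(res.events, res.duration_s)
        assert res.pairs, "expected at least one pair in this seeded run"
        for pr in res.pairs:
            for label in (pr.label_a, pr.label_b):
                t0, t1 = spans[label]
                assert t0 <= pr.t_start and pr.t_end <= t1

    def test_released_pipette_is_the_longest_held(self, lossy_config):
        cells = generate_slice(SliceSpec(n_cells=12, seed=6))
        res = run_patch_walk(cells, None, lossy_config, seed=7)
        since = {}
        for ev in res.events:
            if ev["event"] == "whole_cell":
                since[ev["pipette"]] = ev["t"]
            elif ev["event"] == "released" and ev["detail"].get("rule"):
                other = "b" if ev["pipette"] == "a" else "a"
                assert since[ev["pipette"]] <= since[other]

    def test_deterministic_replay(self, lossy_config, default_model):
        cells = generate_slice(SliceSpec(n_cells=10, seed=8))
        truth = sample_ground_truth(cells, default_model, seed=8)
        a = run_patch_walk(cells, truth, lossy_config, seed=9)
        b = run_patch_walk(cells, truth, lossy_config, seed=9)
        assert a.events == b.events

    def test_different_seed_changes_stochastic_run(self, lossy_config):
        cells = generate_slice(SliceSpec(n_cells=10, seed=8))
        a = run_patch_walk(cells, None, lossy_config, seed=1)
        b = run_patch_walk(cells, None, lossy_config, seed=2)
        assert a.events != b.events

    def test_more_than_two_pipettes_unsupported(self, perfect_config):
        cfg = perfect_config.model_copy(update={"n_pipettes": 3})
        with pytest.raises(ConfigError):
            run_patch_walk([CellSite(1, 0, 0, 50)], None, cfg, seed=0)

    def test_empty_slice_rejected(self, perfect_config):
        with pytest.raises(ValueError):
            run_patch_walk([], None, perfect_config, seed=0)

    def test_max_duration_truncates_session(self, perfect_config):
        cfg = perfect_config.model_copy(update={"max_duration_s": 200.0})
        cells = generate_slice(SliceSpec(n_cells=10, seed=10))
        res = run_patch_walk(cells, None, cfg, seed=0)
        assert res.duration_s <= 200.0
        assert len(res.pairs) == 0  # first pair takes longer than 200 s

    def test_connectivity_frame_labels_and_values(self, perfect_config, default_model):
        cells = generate_slice(SliceSpec(n_cells=5, seed=11))
        truth = sample_ground_truth(cells, default_model, seed=11)
        res = run_patch_walk(cells, truth, perfect_config, seed=0)
        frame = res.connectivity_frame()
        assert list(frame.index) == [a.label for a in res.attempts if a.success]
        assert all(lbl.split(".")[1] in ("a", "b") for lbl in frame.index)
        # 4 pairs probed bidirectionally -> 8 directed entries filled
        assert frame.notna().to_numpy().sum() == 8

    def test_events_jsonl_roundtrip(self, perfect_config, tmp_path):
        import json

        cells = generate_slice(SliceSpec(n_cells=4, seed=12))
        res = run_patch_walk(cells, None, perfect_config, seed=0)
        path = tmp_path / "events.jsonl"
        res.write_events_jsonl(path)
        back = [json.loads(line) for line in path.read_text().splitlines()]
        assert back == res.events
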