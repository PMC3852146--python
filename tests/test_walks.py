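"""Energy-bounded probabilistic walks: replay, counting, calibration."""

import math

import numpy as np
import pytest

from plw import SimilarityModel, WalkConfig, replay_walk, run_walks
from plw.walks import ENERGY_EPS


class TestReplayWalk:
    def test_single_step_energy(self, walk_example_model):
        trace = replay_walk(walk_example_model, ["1", "2"], alpha=2.0)
        assert trace == pytest.approx([2.0, 1.89])

    def test_full_worked_trace(self, walk_example_model):
        path = ["1", "2", "3", "4", "2", "3", "4", "2", "3", "4", "7"]
        trace = replay_walk(walk_example_model, path, alpha=2.0)
        expected = [2.00, 1.89, 1.69, 1.49, 1.29, 1.09,
                    0.89, 0.69, 0.49, 0.29, -0.26]
        assert trace == pytest.approx(expected)
        # step-10 penalty is 1 - 0.45 = 0.55
        assert trace[-2] - trace[-1] == pytest.approx(0.55)

    def test_empty_and_single_vertex_paths(self, walk_example_model):
        assert replay_walk(walk_example_model, [], alpha=2.0) == [2.0]
        assert replay_walk(walk_example_model, ["1"], alpha=2.0) == [2.0]

    def test_non_adjacent_step_names_offender(self, walk_example_model):
        with pytest.raises(ValueError, match="step 2"):
            replay_walk(walk_example_model, ["1", "2", "7"], alpha=2.0)


class TestRunWalks:
    def test_uniform_similarity_walk_length(self):
        # all penalties 0.20 from energy 2.00: after 10 steps energy is
        # exactly 0.00 (still >= 0), the 11th step drives it to -0.20.
        # Each walk therefore takes 11 steps and counts 10 arrivals.
        m = SimilarityModel.from_similarities(
            [("a", "b", 0.8), ("b", "c", 0.8), ("c", "a", 0.8)]
        )
        cfg = WalkConfig(alpha=2.0, w=50, rng_seed=5)
        vc = run_walks(m, ["a"], cfg)
        assert vc.n_walks == 50
        assert vc.total_steps == 50 * 11
        # ten arrivals per walk are countable; returns to the seed are not
        assert 0 < vc.seed_total("a") <= 50 * 10

    def test_similarity_one_edge_terminates_via_gamma_floor(self):
        m = SimilarityModel.from_similarities([("s", "t", 1.0)])
        cfg = WalkConfig(alpha=2.0, w=3, rng_seed=0)
        vc = run_walks(m, ["s"], cfg)
        # penalty clamped at 0.01: 201 steps, alternating s<->t, t counted
        # on ~half the arrivals, and the walk is finite
        assert vc.total_steps == 3 * 201
        assert vc.counts["s"]["t"] == 3 * 100

    def test_seed_never_counted(self, walk_example_model):
        vc = run_walks(walk_example_model, ["2"], WalkConfig(w=200, rng_seed=1))
        assert "2" not in vc.counts["2"]

    def test_walk_length_hard_cap(self, walk_example_model):
        cfg = WalkConfig(alpha=2.0, w=100, rng_seed=2)
        vc = run_walks(walk_example_model, ["1", "2", "4"], cfg)
        assert vc.total_steps <= vc.n_walks * cfg.max_steps

    def test_determinism_under_fixed_rng_seed(self, walk_example_model):
        cfg = WalkConfig(w=30, rng_seed=77)
        a = run_walks(walk_example_model, ["1", "4"], cfg)
        b = run_walks(walk_example_model, ["1", "4"], cfg)
        assert a.counts == b.counts
        assert a.total_steps == b.total_steps

    def test_empty_seed_set_gives_empty_counts(self, walk_example_model):
        vc = run_walks(walk_example_model, [], WalkConfig())
        assert len(vc) == 0 and vc.n_walks == 0

    def test_degree_zero_seed_skipped_with_warning(self):
        import networkx as nx

        G = nx.Graph([("a", "b")])
        G.add_node("loner")
        m = SimilarityModel.from_network(G)
        with pytest.warns(UserWarning, match="loner"):
            vc = run_walks(m, ["loner", "a"], WalkConfig(w=5, rng_seed=0))
        assert "loner" not in vc.counts and "a" in vc.counts

    def test_unknown_seed_rejected(self, walk_example_model):
        with pytest.raises(ValueError):
            run_walks(walk_example_model, ["nope"], WalkConfig())

    def test_first_step_frequencies_match_transition_probabilities(self):
        # walker at s must choose a, b, c proportionally to similarity.
        # Penalties are 0.45/0.70/0.85; with alpha = 0.87 every first step
        # survives (energy stays >= 0) while the forced return to s always
        # exhausts the budget, so each walk counts exactly its first step.
        m = SimilarityModel.from_similarities(
            [("s", "a", 0.55), ("s", "b", 0.30), ("s", "c", 0.15)]
        )
        n = 10_000
        vc = run_walks(m, ["s"], WalkConfig(alpha=0.87, w=n, rng_seed=9))
        probs = {"a": 0.55, "b": 0.30, "c": 0.15}
        for v, p in probs.items():
            se = math.sqrt(p * (1 - p) / n)
            assert abs(vc.counts["s"].get(v, 0) / n - p) <= 3 * se

    def test_mirrored_loop_oracle_reproduces_counts_and_energies(self):
        # Re-run the exact walk loop in-test with the same RNG stream,
        # recording per-walk energy traces; counts must match run_walks
        # and every prefix of every walk must respect energy >= 0.
        m = SimilarityModel.from_similarities(
            [("s", "a", 0.9), ("a", "b", 0.7), ("s", "b", 0.5), ("b", "c", 0.3)]
        )
        cfg = WalkConfig(alpha=2.0, w=40, rng_seed=123)
        vc = run_walks(m, ["s"], cfg)

        rng = np.random.default_rng(cfg.rng_seed)
        counts: dict[str, int] = {}
        for _ in range(cfg.w):
            v, energy = "s", cfg.alpha
            while True:
                if v != "s":
                    counts[v] = counts.get(v, 0) + 1
                    assert energy >= -ENERGY_EPS  # counted within the budget
                u = m.sample_neighbour(v, rng)
                energy -= max(1 - m.similarity(v, u), cfg.gamma_floor)
                v = u
                if energy < -ENERGY_EPS:
                    break
        assert counts == vc.counts["s"]


class TestWalkConfig:
    @pytest.mark.parametrize(
        "kwargs", [{"alpha": 0}, {"w": 0}, {"gamma_floor": 0}, {"gamma_floor": 2}]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            WalkConfig(**kwargs)

    def test_max_steps_cap(self):
        assert WalkConfig(alpha=2.0, gamma_floor=0.01).max_steps == 201
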