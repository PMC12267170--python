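"""Protocol pieces and degenerate-protocol guarantees."""

import dataclasses

import numpy as np
import pytest

from slsim.classifier import TrainConfig, init_model, train_local
from slsim.errors import ProtocolError, TrainingError
from slsim.swarm import (
    SwarmConfig,
    SwarmModel,
    elect_leader,
    fedavg,
    run_centralized,
    screen_updates,
)
from slsim.synth import CLASSES, generate_cohort


class TestElectLeader:
    def test_single_node(self):
        assert elect_leader("0" * 64, 0, [7]) == 7

    def test_deterministic(self):
        ids = [1, 2, 3]
        assert elect_leader("ab" * 32, 5, ids) == elect_leader("ab" * 32, 5, ids)

    def test_order_independent(self):
        assert elect_leader("cd" * 32, 2, [3, 1, 2]) == elect_leader(
            "cd" * 32, 2, [1, 2, 3]
        )

    def test_empty_rejected(self):
        with pytest.raises(ProtocolError):
            elect_leader("0" * 64, 0, [])

    def test_varies_with_head_hash(self):
        leaders = {elect_leader(f"{i:064x}", 0, [1, 2, 3]) for i in range(50)}
        assert leaders == {1, 2, 3}


class TestFedAvg:
    def test_weighted_example(self):
        out = fedavg([(np.array([2.0]), 1), (np.array([4.0]), 3)])
        assert out[0] == pytest.approx(3.5)

    def test_idempotent_on_identical_vectors(self, rng):
        v = rng.normal(size=10)
        out = fedavg([(v, 1), (v, 5), (v, 2)])
        assert np.allclose(out, v, rtol=1e-15, atol=0)

    def test_equal_weights_is_mean(self, rng):
        vs = [rng.normal(size=6) for _ in range(4)]
        out = fedavg([(v, 3) for v in vs])
        assert np.allclose(out, np.mean(vs, axis=0), rtol=1e-12)

    def test_convex_combination(self, rng):
        vs = [rng.normal(size=8) for _ in range(3)]
        out = fedavg([(v, int(n)) for v, n in zip(vs, [1, 7, 2])])
        stack = np.stack(vs)
        assert (out >= stack.min(axis=0) - 1e-12).all()
        assert (out <= stack.max(axis=0) + 1e-12).all()

    def test_errors(self):
        with pytest.raises(TrainingError):
            fedavg([])
        with pytest.raises(TrainingError):
            fedavg([(np.zeros(3), 1), (np.zeros(4), 1)])
        with pytest.raises(TrainingError):
            fedavg([(np.zeros(3), 0)])


class TestScreening:
    def test_all_equal_none_rejected(self):
        v = np.ones(5)
        kept, rejected = screen_updates([v, v, v, v])
        assert rejected == []

    def test_scaled_outlier_rejected(self, rng):
        honest = [rng.normal(size=20) * 0.1 + 1.0 for _ in range(3)]
        poisoned = honest[0] * 1000
        kept, rejected = screen_updates(honest + [poisoned], screening_factor=5)
        assert rejected == [3]
        assert kept == [0, 1, 2]

    def test_two_updates_never_rejected(self, rng):
        kept, rejected = screen_updates([rng.normal(size=5), rng.normal(size=5) * 99])
        assert rejected == []

    def test_empty_rejected(self):
        with pytest.raises(TrainingError):
            screen_updates([])


@pytest.fixture(scope="module")
def tiny_data():
    train = generate_cohort({c: 10 for c in CLASSES}, cohort="train", seed=31)
    val = generate_cohort({c: 4 for c in CLASSES}, cohort="val", seed=32)
    return train, val


class TestProtocolCollapse:
    """One node, masking off: the swarm degenerates to plain local
    training and to centralized training, bit for bit."""

    def test_swarm_equals_chained_local(self, tiny_data, model_spec):
        train, val = tiny_data
        tcfg = TrainConfig(seed=5)
        scfg = SwarmConfig(
            n_rounds=5, min_participation=1, masking=False, fixed_point=False, seed=5
        )
        res = SwarmModel([train], val, model_spec, tcfg, scfg).fit()

        params = init_model(model_spec, seed=5)
        for r in range(5):
            params, _ = train_local(
                params, train, tcfg, model_spec, epoch_offset=r, node_salt=1
            )
        assert np.array_equal(res.final_params.values, params.values)

    def test_swarm_equals_centralized(self, tiny_data, model_spec):
        train, val = tiny_data
        tcfg = TrainConfig(seed=5)
        scfg = SwarmConfig(
            n_rounds=5, min_participation=1, masking=False, fixed_point=False, seed=5
        )
        swarm = SwarmModel([train], val, model_spec, tcfg, scfg).fit()
        central = run_centralized(train, val, model_spec, tcfg, epochs=5, node_salt=1)
        assert np.array_equal(swarm.best_params.values, central.best_params.values)
        assert swarm.best_round == central.best_epoch


class TestMaskingTransparency:
    def test_fixed_point_masked_equals_unmasked(self, tiny_data, model_spec):
        """Pair masks cancel exactly: fixed-point trajectories are
        identical with masking on or off, every round."""
        train, val = tiny_data
        from slsim.partition import PartitionSpec, make_node_shards

        shards = make_node_shards(train, PartitionSpec(seed=1))
        tcfg = TrainConfig(seed=2)
        base = SwarmConfig(n_rounds=4, seed=2, fixed_point=True)
        on = SwarmModel(
            shards, val, model_spec, tcfg, dataclasses.replace(base, masking=True)
        ).fit()
        off = SwarmModel(
            shards, val, model_spec, tcfg, dataclasses.replace(base, masking=False)
        ).fit()
        for a, b in zip(on.history, off.history):
            assert np.array_equal(a.params.values, b.params.values)


class TestRunSwarm:
    def test_history_and_ledger(self, tiny_data, model_spec):
        train, val = tiny_data
        from slsim.partition import PartitionSpec, make_node_shards

        shards = make_node_shards(train, PartitionSpec(seed=1))
        res = SwarmModel(
            shards, val, model_spec, TrainConfig(seed=0), SwarmConfig(n_rounds=6, seed=0)
        ).fit()
        assert len(res.history) == 6
        assert res.verify_ledger()
        assert len(res.ledger) == 6
        # leaders recomputable from the chain
        for h in res.history:
            assert h.leader_id in (1, 2, 3)
        assert 0 <= res.best_round < 6
        assert "Swarm learning run" in res.summary()

    def test_below_min_participation_rejected(self, tiny_data, model_spec):
        train, val = tiny_data
        with pytest.raises(ProtocolError):
            SwarmModel([train, train], val, model_spec, config=SwarmConfig())

    def test_screening_abort_when_minimum_violated(self, tiny_data, model_spec):
        """3 nodes, one poisoned and rejected, minimum participation 3:
        the round must abort."""
        train, val = tiny_data
        from slsim.partition import PartitionSpec, make_node_shards

        shards = make_node_shards(train, PartitionSpec(seed=1))
        model = SwarmModel(
            shards,
            val,
            model_spec,
            TrainConfig(seed=0),
            SwarmConfig(n_rounds=2, min_participation=3, seed=0),
            adversaries={3: 1000.0},
        )
        with pytest.raises(ProtocolError, match="below minimum"):
            model.fit()

    def test_adversary_screened_with_four_nodes(self, tiny_data, model_spec):
        train, val = tiny_data
        from slsim.partition import PartitionSpec, make_node_shards

        shards = make_node_shards(
            train, PartitionSpec(seed=1, node_ratios=(1, 1, 1, 1))
        )
        res = SwarmModel(
            shards,
            val,
            model_spec,
            TrainConfig(seed=0),
            SwarmConfig(n_rounds=3, seed=0),
            adversaries={4: 1000.0},
        ).fit()
        for h in res.history:
            assert h.rejected == [4]
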