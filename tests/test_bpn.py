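"""Back-propagation network: gradients, encoding, splitting, training."""

import numpy as np
import pytest

from hemoqc.bpn import (
    HIDDEN_UNIT_PRESETS,
    Network,
    NetworkConfig,
    TrainingRecord,
    encode_records,
    gradient_check,
    split_data,
    train,
)
from hemoqc.errors import ConfigurationError, EncodingError, StructuralError
from hemoqc.pipeline import _reconstruct_runs


@pytest.fixture(scope="module")
def reference_runs(plan, reference_results):
    return _reconstruct_runs(reference_results, plan)


@pytest.fixture(scope="module")
def proportion_records(reference_runs, plan):
    return encode_records(reference_runs, plan, encoding="proportion")


XOR = [
    TrainingRecord((0.0, 0.0), 0.0, 1),
    TrainingRecord((0.0, 1.0), 1.0, 1),
    TrainingRecord((1.0, 0.0), 1.0, 1),
    TrainingRecord((1.0, 1.0), 0.0, 1),
]


class TestGradientCheck:
    """Central finite differences are the module's correctness oracle."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_analytic_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        net = Network(4, 5, 1, rng=rng)
        x = rng.random(4)
        assert gradient_check(net, x, target=0.3, epsilon=1e-5) < 1e-6

    def test_zero_weights_zero_input_well_defined(self):
        net = Network(4, 5, 1, rng=np.random.default_rng(0))
        for arr in (net.w1, net.b1, net.w2, net.b2):
            arr[...] = 0.0
        dev = gradient_check(net, np.zeros(4), target=1.0)
        assert np.isfinite(dev)

    def test_corrupted_gradient_detected(self):
        """A sign flip in the backward pass must blow up the deviation."""
        rng = np.random.default_rng(3)
        net = Network(4, 5, 1, rng=rng)
        original = net.gradients

        def corrupted(x, t):
            gw1, gb1, gw2, gb2 = original(x, t)
            return -gw1, gb1, gw2, gb2

        net.gradients = corrupted
        assert gradient_check(net, rng.random(4), target=0.3) > 0.5

    def test_bad_epsilon_rejected(self):
        net = Network(4, 5, 1, rng=np.random.default_rng(0))
        with pytest.raises(ConfigurationError):
            gradient_check(net, np.zeros(4), 0.0, epsilon=0.0)


class TestEncoding:
    def test_min_max_scaling_endpoints_and_midpoint(self, plan):
        import pandas as pd

        # A=500 (min), B=300 (max), C=2.5 (mid), D=autologous (level 2)
        runs = pd.DataFrame(
            {"run_id": [1], "condition": [3], "A": [1], "B": [3], "C": [2],
             "D": [2], "outcome": ["good"]}
        )
        # condition column only anchors the target; use binary to avoid rates
        rec = encode_records(runs, plan, encoding="binary")[0]
        assert rec.inputs == (0.0, 1.0, 0.5, pytest.approx(2 / 3))
        assert rec.target == 0.0

    def test_binary_targets(self, reference_runs, plan):
        records = encode_records(reference_runs, plan, encoding="binary")
        defective = [r.target for r in records if r.target == 1.0]
        assert len(defective) == 86

    def test_proportion_targets_are_condition_rates(self, proportion_records):
        cond1 = [r for r in proportion_records if r.condition_id == 1]
        assert all(r.target == pytest.approx(7 / 30) for r in cond1)

    def test_onehot_widens_inputs(self, reference_runs, plan):
        records = encode_records(reference_runs, plan, access_encoding="onehot")
        assert len(records[0].inputs) == 6
        assert sum(records[0].inputs[3:]) == 1.0

    def test_unknown_level_rejected(self, plan):
        import pandas as pd

        runs = pd.DataFrame(
            {"run_id": [1], "condition": [1], "A": [4], "B": [1], "C": [1],
             "D": [1], "outcome": ["good"]}
        )
        with pytest.raises(EncodingError):
            encode_records(runs, plan, encoding="binary")


class TestSplit:
    def test_reference_split_sizes(self, proportion_records):
        tr, va, te = split_data(proportion_records, seed=0)
        assert (len(tr), len(va), len(te)) == (216, 27, 27)

    def test_floor_allocation_small(self):
        records = [TrainingRecord((0.5,), 0.5, i % 2 + 1) for i in range(10)]
        tr, va, te = split_data(records, seed=0)
        assert (len(tr), len(va), len(te)) == (8, 1, 1)

    def test_same_seed_identical_partition(self, proportion_records):
        a = split_data(proportion_records, seed=42)
        b = split_data(proportion_records, seed=42)
        assert a == b

    def test_every_condition_in_train(self, proportion_records):
        for seed in range(5):
            tr, _, _ = split_data(proportion_records, seed=seed)
            assert {r.condition_id for r in tr} == set(range(1, 10))

    def test_too_few_records_rejected(self):
        with pytest.raises(StructuralError):
            split_data([TrainingRecord((0.5,), 0.5, 1)] * 9)


class TestTraining:
    def test_xor_sanity_oracle(self):
        """The classic XOR problem is learned by a 2-2-1 net."""
        cfg = NetworkConfig(
            n_inputs=2, hidden_units=2, learning_rate=0.5, momentum=0.9,
            epochs=5000, seed=0, split=(1.0, 0.0, 0.0),
        )
        _, report = train(cfg, XOR)
        assert report.final_train_mse < 0.01

    def test_single_epoch_report_length(self, proportion_records):
        cfg = NetworkConfig(epochs=1, seed=0)
        tr, va, te = split_data(proportion_records, seed=0)
        _, report = train(cfg, tr, va, te)
        assert report.epochs == 1
        assert len(report.val_mse) == 1 and len(report.test_mse) == 1

    def test_bit_reproducible(self, proportion_records):
        cfg = NetworkConfig(epochs=20, seed=5)
        tr, va, te = split_data(proportion_records, seed=5)
        net_a, rep_a = train(cfg, tr, va, te)
        net_b, rep_b = train(cfg, tr, va, te)
        assert rep_a.train_mse == rep_b.train_mse
        assert (net_a.w1 == net_b.w1).all() and (net_a.w2 == net_b.w2).all()

    def test_first_order_consistency(self):
        """With momentum 0 and tiny lr, one epoch's step ~ summed gradient."""
        records = XOR
        eta = 1e-5
        cfg = NetworkConfig(
            n_inputs=2, hidden_units=2, learning_rate=eta, momentum=0.0,
            epochs=1, seed=0, split=(1.0, 0.0, 0.0),
        )
        rng = np.random.default_rng(cfg.seed)
        ref = Network(2, 2, 1, rng=rng)
        summed = [np.zeros_like(ref.w1), np.zeros_like(ref.b1),
                  np.zeros_like(ref.w2), np.zeros_like(ref.b2)]
        for r in records:
            for acc, g in zip(summed, ref.gradients(np.array(r.inputs), r.target)):
                acc += g
        net, _ = train(cfg, records)
        # at lr -> 0 the online updates approach the batch gradient step
        assert np.allclose(net.w1 - ref.w1, -eta * summed[0], atol=1e-8)
        assert np.allclose(net.w2 - ref.w2, -eta * summed[2], atol=1e-8)

    def test_convergence_report_on_reference_data(self, proportion_records):
        cfg = NetworkConfig(seed=1)
        tr, va, te = split_data(proportion_records, seed=1)
        _, report = train(cfg, tr, va, te)
        assert report.converged
        assert report.convergence_epoch is not None
        assert report.convergence_epoch <= cfg.epochs
        assert all(m >= 0 for m in report.train_mse)

    def test_hidden_unit_presets(self):
        assert HIDDEN_UNIT_PRESETS == {"average": 3, "summation": 5, "doubling": 10}

    def test_serialization_round_trip(self, tmp_path, proportion_records):
        cfg = NetworkConfig(epochs=5, seed=2)
        tr, va, te = split_data(proportion_records, seed=2)
        net, report = train(cfg, tr, va, te)
        net.to_json(tmp_path / "net.json", cfg)
        loaded = Network.from_json(tmp_path / "net.json")
        X = np.array([r.inputs for r in tr[:5]])
        assert np.allclose(net.predict(X), loaded.predict(X))
        report.to_csv(tmp_path / "curve.csv")
        assert (tmp_path / "curve.csv").read_text().splitlines()[0] == \
            "epoch,train_mse,val_mse,test_mse"

    def test_more_hidden_units_reach_lower_mse_on_average(self, proportion_records):
        """Average final MSE decreases with capacity (1 vs 10 hidden units)."""
        tr, va, te = split_data(proportion_records, seed=0)
        means = {}
        for h in (1, 10):
            finals = []
            for seed in range(3):
                cfg = NetworkConfig(hidden_units=h, epochs=60, seed=seed)
                _, rep = train(cfg, tr, va, te)
                finals.append(rep.final_train_mse)
            means[h] = np.mean(finals)
        assert means[10] <= means[1]
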