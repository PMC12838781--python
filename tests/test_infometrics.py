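"""Plugin entropy / mutual-information / transfer-entropy estimators and scans."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recres.connectivity import condition_spec
from recres.infometrics import (ScanResult, SymbolSeries, entropy, find_peak,
                                mutual_information, noise_scan,
                                per_trial_values, shuffle_surrogate,
                                subsystem_series, temporal_mi,
                                transfer_entropy)

# ---------------------------------------------------------------------------
# direct-summation oracles: literal transcriptions of the defining formulas


def oracle_entropy(x):
    out = 0.0
    for v in set(x.tolist()):
        p = np.mean(x == v)
        out -= p * np.log2(p)
    return out


def oracle_mi(x, y):
    out = 0.0
    for a in set(x.tolist()):
        for b in set(y.tolist()):
            pxy = np.mean((x == a) & (y == b))
            if pxy > 0:
                out += pxy * np.log2(pxy / (np.mean(x == a) * np.mean(y == b)))
    return out


def oracle_te(src, tgt):
    b1, b0, a0 = tgt[1:], tgt[:-1], src[:-1]
    out = 0.0
    for bn in set(b1.tolist()):
        for b in set(b0.tolist()):
            for a in set(a0.tolist()):
                p_full = np.mean((b1 == bn) & (b0 == b) & (a0 == a))
                if p_full == 0:
                    continue
                p_cond_ba = p_full / np.mean((b0 == b) & (a0 == a))
                p_cond_b = np.mean((b1 == bn) & (b0 == b)) / np.mean(b0 == b)
                out += p_full * np.log2(p_cond_ba / p_cond_b)
    return out


class TestEntropy:
    def test_constant_series_has_zero_entropy(self):
        assert entropy(np.zeros(100, dtype=int)) == 0.0

    def test_exactly_uniform_32_symbols_gives_five_bits(self):
        assert entropy(np.repeat(np.arange(32), 4)) == pytest.approx(5.0, abs=1e-12)

    def test_three_one_split(self):
        # −(¾ log2 ¾ + ¼ log2 ¼)
        assert entropy(np.array([0, 0, 0, 1])) == pytest.approx(0.811278124459, abs=1e-10)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            entropy(np.array([], dtype=int))

    def test_bounded_by_alphabet_bits(self, rng):
        s = SymbolSeries(rng.integers(0, 32, 500), m=5)
        assert 0 <= entropy(s) <= 5


class TestMutualInformation:
    def test_identical_uniform_series(self):
        x = np.repeat(np.arange(4), 25)
        assert mutual_information(x, x) == pytest.approx(2.0, abs=1e-12)

    def test_constructed_independent_series_is_zero(self):
        # exact product empirical distribution → MI exactly 0
        x = np.repeat([0, 1], 50)
        y = np.tile([0, 1], 50)
        assert mutual_information(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mutual_information(np.arange(5), np.arange(6))

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_matches_direct_summation_oracle(self, data):
        n = data.draw(st.integers(10, 60))
        kx = data.draw(st.integers(1, 4))
        ky = data.draw(st.integers(1, 4))
        x = np.array(data.draw(st.lists(st.integers(0, kx - 1), min_size=n, max_size=n)))
        y = np.array(data.draw(st.lists(st.integers(0, ky - 1), min_size=n, max_size=n)))
        assert mutual_information(x, y) == pytest.approx(oracle_mi(x, y), abs=1e-10)
        assert entropy(x) == pytest.approx(oracle_entropy(x), abs=1e-10)

    def test_nonnegative_and_bounded_by_marginals(self, rng):
        for _ in range(20):
            x = rng.integers(0, 8, 200)
            y = rng.integers(0, 8, 200)
            mi = mutual_information(x, y)
            assert mi >= -1e-12
            assert mi <= min(entropy(x), entropy(y)) + 1e-9


class TestTemporalMI:
    def test_two_cycle_is_one_bit(self):
        # T−1 transition pairs leave the marginals a hair off-uniform
        assert temporal_mi(np.tile([0, 1], 100)) == pytest.approx(1.0, abs=1e-3)

    def test_period_four_cycle_is_two_bits(self):
        assert temporal_mi(np.tile([0, 1, 2, 3], 100)) == pytest.approx(2.0, abs=1e-3)

    def test_too_short(self):
        with pytest.raises(ValueError):
            temporal_mi(np.array([3]))

    def test_iid_uniform_approaches_plugin_bias(self, rng):
        """For i.i.d. symbols the estimate equals bias, as a shuffled surrogate shows."""
        x = rng.integers(0, 16, 5000)
        mi = temporal_mi(x)
        surrogate = temporal_mi(rng.permutation(x))
        assert mi == pytest.approx(surrogate, abs=0.02)
        assert 0 < mi < 0.2


class TestTransferEntropy:
    def test_copy_channel_is_one_bit(self, rng):
        src = rng.integers(0, 2, 20_000)
        tgt = np.concatenate([[0], src[:-1]])  # target_{t+1} = source_t
        assert transfer_entropy(src, tgt) == pytest.approx(1.0, abs=0.01)

    def test_constant_source_transfers_nothing(self, rng):
        tgt = rng.integers(0, 4, 500)
        assert transfer_entropy(np.zeros(500, dtype=int), tgt) == pytest.approx(0.0, abs=1e-12)

    def test_hand_built_table_matches_oracle(self):
        src = np.array([0, 1, 1, 0, 1, 0, 0, 1, 1, 1, 0, 1])
        tgt = np.array([1, 0, 1, 1, 0, 0, 1, 0, 1, 0, 0, 1])
        assert transfer_entropy(src, tgt) == pytest.approx(oracle_te(src, tgt), abs=1e-10)

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_matches_oracle_on_random_small_tables(self, data):
        n = data.draw(st.integers(5, 40))
        ka = data.draw(st.integers(1, 4))
        kb = data.draw(st.integers(1, 4))
        src = np.array(data.draw(st.lists(st.integers(0, ka - 1), min_size=n, max_size=n)))
        tgt = np.array(data.draw(st.lists(st.integers(0, kb - 1), min_size=n, max_size=n)))
        te = transfer_entropy(src, tgt)
        assert te == pytest.approx(oracle_te(src, tgt), abs=1e-10)
        assert te >= -1e-12

    def test_shuffled_source_gives_positive_bias_not_zero(self, rng):
        src = rng.integers(0, 32, 20_000)
        tgt = rng.integers(0, 32, 20_000)
        bias = shuffle_surrogate(src, tgt, rng)
        assert bias > 0.05  # plugin bias floor, far from exact zero

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            transfer_entropy(np.arange(4), np.arange(5))


def test_subsystem_series_projects_bit_ranges():
    z = np.array([0b1010110011])
    assert subsystem_series(z, (0, 5)).symbols[0] == 0b10011
    assert subsystem_series(z, (5, 10)).symbols[0] == 0b10101
    assert subsystem_series(z, (0, 5)).m == 5


class TestNoiseScan:
    def test_identical_seeds_identical_results(self):
        spec = condition_spec("five_ql_excitatory")
        a = noise_scan(spec, 1.0, [0.0, 1.0], trials=3, steps=400, seed=6)
        b = noise_scan(spec, 1.0, [0.0, 1.0], trials=3, steps=400, seed=6)
        assert a.data.equals(b.data)

    def test_single_trial_zero_noise_entropy(self):
        spec = condition_spec("five_ql_excitatory")
        scan = noise_scan(spec, 1.0, [0.0], trials=1, steps=400, seed=3)
        h = scan.data[scan.data.observable == "entropy"].value.iloc[0]
        assert h >= 0  # deterministic run: entropy of the settled orbit
        assert scan.summary()["sd"].iloc[0] == 0.0

    def test_all_requested_observables_present(self):
        spec = condition_spec("ten_ql")
        obs = ("entropy", "mi", "entropy_A", "mi_B", "te_AB")
        scan = noise_scan(spec, 1.0, [1.0], trials=2, steps=300, observables=obs, seed=1)
        assert set(scan.data.observable) == set(obs)

    def test_trials_must_be_positive(self):
        with pytest.raises(ValueError):
            noise_scan(condition_spec("five_ql_excitatory"), 1.0, [0.0], trials=0, steps=10)


class TestFindPeak:
    def _scan(self, values, grid):
        import pandas as pd

        rows = [("c", 1.0, float(r), 0, "mi", v) for r, v in zip(grid, values)]
        data = pd.DataFrame(rows, columns=["condition", "W", "r", "trial", "observable", "value"])
        return ScanResult("c", 1.0, tuple(float(g) for g in grid), 1, 10, data)

    def test_interior_maximum(self):
        r, v, sd = find_peak(self._scan([0.1, 0.9, 0.4], [0, 1, 2]))
        assert (r, v) == (1.0, 0.9)

    def test_flat_curve_ties_to_smallest_r(self):
        r, _, _ = find_peak(self._scan([0.5, 0.5, 0.5], [0, 1, 2]))
        assert r == 0.0

    def test_unknown_observable(self):
        with pytest.raises(ValueError):
            find_peak(self._scan([1.0], [0]), "te_AB")

    def test_per_trial_values_sorted_by_trial(self):
        scan = self._scan([0.1, 0.9, 0.4], [0, 1, 2])
        assert per_trial_values(scan, "mi", 1.0).tolist() == [0.9]
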