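import numpy as np
import pytest

from phaselock.connectivity import (
    PLVMatrix,
    plv_matrix,
    plv_pair,
    plv_rows,
    rsn_fc,
    seed_fc,
    seed_fc_from_phases,
)
from phaselock.preprocessing import DEFAULT_BANDS, PhaseSet
from phaselock.simulate import expected_plv_vonmises, kappa_for_plv
from phaselock.source_space import SeedROI, build_rsn


def _phase_set(data, band=DEFAULT_BANDS[2]):
    return PhaseSet(subject_id="s", band=band, data=np.asarray(data), fs=1000.0, epoch_len=4.0)


class TestPlvPair:
    def test_constant_lag_gives_exactly_one(self, rng):
        pk = rng.uniform(-np.pi, np.pi, (3, 100))
        assert plv_pair(pk, pk + 0.7) == pytest.approx(1.0, abs=1e-12)

    def test_iid_uniform_null_matches_rayleigh_mean(self, rng):
        # E[PLV] for independent uniform phases at T samples is ~ sqrt(pi)/(2 sqrt(T))
        T = 4000
        vals = [
            plv_pair(rng.uniform(-np.pi, np.pi, (1, T)), rng.uniform(-np.pi, np.pi, (1, T)))
            for _ in range(200)
        ]
        expected = np.sqrt(np.pi) / (2 * np.sqrt(T))
        assert np.mean(vals) == pytest.approx(expected, abs=0.002)

    @pytest.mark.parametrize("kappa", [0.5, 1.1595, 4.0])
    def test_von_mises_jitter_recovers_bessel_ratio(self, rng, kappa):
        pk = rng.uniform(-np.pi, np.pi, (80, 4000))
        pl = pk + rng.vonmises(0, kappa, (80, 4000))
        assert plv_pair(pk, pl) == pytest.approx(expected_plv_vonmises(kappa), abs=0.02)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="identical shapes"):
            plv_pair(np.zeros((2, 10)), np.zeros((3, 10)))

    def test_invariant_to_constant_shift_and_swap(self, rng):
        pk = rng.uniform(-np.pi, np.pi, (4, 500))
        pl = pk + rng.vonmises(0, 2.0, (4, 500))
        base = plv_pair(pk, pl)
        assert plv_pair(pk + 1.234, pl) == pytest.approx(base, abs=1e-12)
        assert plv_pair(pl, pk) == pytest.approx(base, abs=1e-12)

    def test_invariant_to_wrapping_branch(self, rng):
        pk = rng.uniform(-np.pi, np.pi, (2, 300))
        pl = pk + rng.vonmises(0, 1.0, (2, 300))
        wrapped = np.angle(np.exp(1j * pl))
        assert plv_pair(pk, pl) == pytest.approx(plv_pair(pk, wrapped), abs=1e-12)

    def test_monotone_in_von_mises_concentration(self, rng):
        """Higher concentration (less jitter) must give higher mean PLV."""
        k1, k2 = 3.0, 1.0
        diffs = []
        for _ in range(100):
            pk = rng.uniform(-np.pi, np.pi, (1, 400))
            a = plv_pair(pk, pk + rng.vonmises(0, k1, (1, 400)))
            b = plv_pair(pk, pk + rng.vonmises(0, k2, (1, 400)))
            diffs.append(a - b)
        assert np.mean(diffs) > 0
        assert np.mean(np.array(diffs) > 0) > 0.95

    def test_narrowband_null_exceeds_iid_value(self, rng):
        """Autocorrelation of band-limited noise inflates the null PLV above
        the i.i.d. value (~0.014) but it stays well below 0.3."""
        from phaselock.preprocessing import bandpass_epochs, instantaneous_phase

        vals = []
        for _ in range(30):
            x = rng.normal(0, 1, (2, 8000))
            ep = bandpass_epochs(x, 1000.0, DEFAULT_BANDS[2])
            ph = instantaneous_phase(ep)
            vals.append(plv_pair(ph.data[0, 1:2], ph.data[1, 1:2]))
        null_mean = np.mean(vals)
        assert 0.014 < null_mean < 0.3


class TestPlvMatrix:
    def test_identical_sources_give_all_ones(self, rng):
        row = rng.uniform(-np.pi, np.pi, (2, 200))
        ph = _phase_set(np.stack([row, row, row]))
        m = plv_matrix(ph)
        np.testing.assert_allclose(m.values, 1.0, atol=1e-12)

    def test_matches_naive_pair_loop(self, rng):
        data = rng.uniform(-np.pi, np.pi, (6, 3, 150))
        m = plv_matrix(_phase_set(data))
        for i in range(6):
            for j in range(6):
                want = 1.0 if i == j else plv_pair(data[i], data[j])
                assert m.values[i, j] == pytest.approx(want, abs=1e-10)

    def test_bitwise_symmetric_with_unit_diagonal(self, rng):
        data = rng.uniform(-np.pi, np.pi, (8, 2, 100))
        m = plv_matrix(_phase_set(data))
        assert np.max(np.abs(m.values - m.values.T)) == 0.0
        np.testing.assert_array_equal(np.diag(m.values), 1.0)
        assert np.all((m.values >= 0) & (m.values <= 1))

    def test_blocked_equals_unblocked(self, rng):
        data = rng.uniform(-np.pi, np.pi, (7, 2, 120))
        a = plv_matrix(_phase_set(data), block_size=3)
        b = plv_matrix(_phase_set(data), block_size=256)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_global_offset_only_touches_own_row_and_column(self, rng):
        data = rng.uniform(-np.pi, np.pi, (5, 2, 100))
        m0 = plv_matrix(_phase_set(data)).values
        data2 = data.copy()
        data2[2] += 0.9
        m1 = plv_matrix(_phase_set(data2)).values
        others = [i for i in range(5) if i != 2]
        np.testing.assert_array_equal(m0[np.ix_(others, others)], m1[np.ix_(others, others)])

    def test_plv_rows_agrees_with_matrix(self, rng):
        data = rng.uniform(-np.pi, np.pi, (6, 2, 100))
        ph = _phase_set(data)
        rows = plv_rows(ph, [1, 4])
        m = plv_matrix(ph).values
        np.testing.assert_allclose(rows, m[[1, 4]], atol=1e-10)


class TestSeedFC:
    def _matrix(self, values):
        return PLVMatrix(subject_id="s", band="upper_beta", values=values)

    def test_single_source_seed_is_its_row(self, rng):
        v = rng.uniform(0, 1, (5, 5))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        seed = SeedROI("s0", "left", np.array([2]))
        out = seed_fc(self._matrix(v), seed)
        np.testing.assert_allclose(out.values, v[2, [0, 1, 3, 4]])
        assert list(out.source_indices) == [0, 1, 3, 4]

    def test_all_ones_matrix_gives_all_ones_vector(self):
        v = np.ones((6, 6))
        seed = SeedROI("s", "bilateral", np.array([0, 3]))
        out = seed_fc(self._matrix(v), seed)
        np.testing.assert_array_equal(out.values, 1.0)

    def test_matches_brute_force_double_loop(self, rng):
        v = rng.uniform(0, 1, (20, 20))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        seed_idx = np.array([2, 5, 11, 17])
        out = seed_fc(self._matrix(v), SeedROI("s", "right", seed_idx))
        for pos, s in enumerate(out.source_indices):
            want = np.mean([v[m, s] for m in seed_idx])
            assert out.values[pos] == pytest.approx(want, abs=1e-12)
        assert not set(seed_idx) & set(out.source_indices)

    def test_seed_covering_grid_raises(self):
        v = np.ones((3, 3))
        with pytest.raises(ValueError, match="no distant sources"):
            seed_fc(self._matrix(v), SeedROI("all", "bilateral", np.arange(3)))

    def test_from_phases_fast_path_agrees(self, rng):
        data = rng.uniform(-np.pi, np.pi, (8, 2, 120))
        ph = _phase_set(data)
        seed = SeedROI("s", "left", np.array([1, 6]))
        fast = seed_fc_from_phases(ph, seed)
        slow = seed_fc(plv_matrix(ph), seed)
        np.testing.assert_allclose(fast.values, slow.values, atol=1e-10)
        np.testing.assert_array_equal(fast.source_indices, slow.source_indices)


class TestRSNFC:
    def _matrix(self, rng, n):
        v = rng.uniform(0, 1, (n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        return PLVMatrix(subject_id="s", band="alpha_mu", values=v)

    def test_two_source_rsn_is_single_entry(self, rng, grid333):
        m = self._matrix(rng, 27)
        rsn = build_rsn(grid333, "pair", [grid333.positions[0]], radius=10)
        assert len(rsn.source_indices) == 4  # corner + 3 face neighbors
        # restrict to exactly two sources via a tighter sphere
        rsn2 = build_rsn(grid333, "pair", [(grid333.positions[0] + grid333.positions[1]) / 2], radius=5)
        i, j = rsn2.source_indices
        out = rsn_fc(m, rsn2, "all_pairs")
        assert out.value == pytest.approx(m.values[i, j], abs=1e-12)
        assert out.n_pairs == 1

    def test_all_ones_matrix_gives_one_under_both_policies(self, grid333):
        v = np.ones((27, 27))
        m = PLVMatrix("s", "b", v)
        rsn = build_rsn(
            grid333, "net", [grid333.positions[0], grid333.positions[26]], radius=12
        )
        for policy in ("all_pairs", "between_spheres"):
            assert rsn_fc(m, rsn, policy).value == pytest.approx(1.0)

    def test_policies_match_brute_force_enumeration(self, rng, grid333):
        m = self._matrix(rng, 27)
        centers = [grid333.positions[4], grid333.positions[13], grid333.positions[22]]
        rsn = build_rsn(grid333, "net3", centers, radius=12)
        idx = rsn.source_indices
        # all_pairs oracle
        want_all = np.mean(
            [m.values[a, b] for k, a in enumerate(idx) for b in idx[k + 1:]]
        )
        assert rsn_fc(m, rsn, "all_pairs").value == pytest.approx(want_all, abs=1e-12)
        # between_spheres oracle
        pairs = set()
        for a in range(3):
            for b in range(a + 1, 3):
                for i in rsn.center_membership[a]:
                    for j in rsn.center_membership[b]:
                        if i != j:
                            pairs.add((min(i, j), max(i, j)))
        want_between = np.mean([m.values[i, j] for i, j in pairs])
        assert rsn_fc(m, rsn, "between_spheres").value == pytest.approx(
            want_between, abs=1e-12
        )

    def test_unknown_policy_raises(self, rng, grid333):
        m = self._matrix(rng, 27)
        rsn = build_rsn(grid333, "n", [grid333.positions[13]], radius=10)
        with pytest.raises(ValueError, match="pair_policy"):
            rsn_fc(m, rsn, "bogus")
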