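"""Mechanism-specific injection invariants."""

import numpy as np
import pytest

from lfqimpute import (MissingnessSpec, ValidationError, inject,
                       introduce_mar, introduce_mcar, introduce_mixture,
                       introduce_mnar, stratify_protein_missingness)
from lfqimpute.missingness import protein_stratum

from conftest import make_matrix


def complete(rng, p=20, n=15):
    return make_matrix(rng.normal(20, 1, size=(p, n)))


class TestMCAR:
    def test_exact_count(self, rng):
        m = make_matrix(rng.normal(size=(10, 10)))
        r = introduce_mcar(m, 0.1, np.random.default_rng(0))
        assert len(r.deleted_cells) == 10
        assert r.masked_matrix.n_missing == 10

    def test_zero_rate_noop(self, rng):
        m = complete(rng)
        r = introduce_mcar(m, 0.0, np.random.default_rng(0))
        assert r.masked_matrix == m and not r.deleted_cells

    def test_invalid_rate(self, rng):
        with pytest.raises(ValidationError):
            introduce_mcar(complete(rng), 1.0, np.random.default_rng(0))

    def test_removal_frequency_uniform(self, rng):
        m = make_matrix(rng.normal(size=(8, 8)))
        counts = np.zeros((8, 8))
        n_rep, rate = 300, 0.1
        for s in range(n_rep):
            r = introduce_mcar(m, rate, np.random.default_rng(s))
            for c in r.deleted_cells:
                counts[c.protein, c.sample] += 1
        # each cell ~ Bin(n_rep, ~rate): 3-sigma band around 6/64 per draw
        p_cell = round(rate * 64) / 64
        sd = np.sqrt(n_rep * p_cell * (1 - p_cell))
        assert (np.abs(counts - n_rep * p_cell) < 3.5 * sd).all()


class TestMAR:
    def test_requires_two_proteins(self, rng):
        m = make_matrix(rng.normal(size=(1, 10)))
        with pytest.raises(ValidationError, match="2 proteins"):
            introduce_mar(m, 0.1, 1, np.random.default_rng(0))

    def test_zero_rate_noop(self, rng):
        m = complete(rng)
        r = introduce_mar(m, 0.0, 1, np.random.default_rng(0))
        assert r.masked_matrix == m

    def test_realized_rate_at_most_one_pair_over(self, rng):
        m = make_matrix(rng.normal(20, 1, size=(100, 45)))
        r = introduce_mar(m, 0.1, 1, np.random.default_rng(11))
        total = m.values.size
        assert 0.1 <= r.realized_global_rate + 1e-12
        assert r.realized_global_rate <= 0.1 + 45 / total  # one victim's worth


class TestMNAR:
    def test_bottom_k_order_statistics(self, rng):
        m = complete(rng, p=30, n=20)
        r = introduce_mnar(m, 0.2, 1, np.random.default_rng(5))
        for i in range(30):
            gone = [c.sample for c in r.deleted_cells if c.protein == i]
            if not gone:
                continue
            k = len(gone)
            order = np.argsort(m.values[i])
            assert set(gone) == set(order[:k].tolist())

    def test_removed_below_survivors(self, rng):
        m = complete(rng)
        r = introduce_mnar(m, 0.15, 1, np.random.default_rng(2))
        removed = r.truth_values()
        surviving = r.masked_matrix.values[r.masked_matrix.mask]
        assert removed.mean() < surviving.mean()

    def test_zero_rate_noop(self, rng):
        m = complete(rng)
        assert introduce_mnar(m, 0.0, 1, np.random.default_rng(0)).masked_matrix == m


class TestMixture:
    def test_equal_thirds_and_partition(self, rng):
        m = make_matrix(rng.normal(20, 1, size=(60, 45)))
        r = introduce_mixture(m, 0.3, 1, np.random.default_rng(7))
        total = len(r.deleted_cells)
        by_mech = {k: sum(1 for c in r.deleted_cells if c.mechanism == k)
                   for k in ("MCAR", "MAR", "MNAR")}
        assert sum(by_mech.values()) == total
        for count in by_mech.values():
            assert abs(count - total / 3) <= 0.05 * total + 45
        # disjoint: every deleted cell appears exactly once
        cells = [(c.protein, c.sample) for c in r.deleted_cells]
        assert len(set(cells)) == len(cells)

    def test_zero_rate_noop(self, rng):
        m = complete(rng)
        assert introduce_mixture(m, 0.0, 1, np.random.default_rng(0)).masked_matrix == m


class TestCommonInvariants:
    @pytest.mark.parametrize("mechanism", ["MCAR", "MAR", "MNAR", "MIX"])
    def test_deleted_were_observed_and_unique(self, rng, mechanism):
        m = complete(rng, p=25, n=20)
        r = inject(m, MissingnessSpec(mechanism, 0.2, seed=3))
        cells = [(c.protein, c.sample) for c in r.deleted_cells]
        assert len(set(cells)) == len(cells)
        for c in r.deleted_cells:
            assert c.true_value == m.values[c.protein, c.sample]
            assert np.isnan(r.masked_matrix.values[c.protein, c.sample])
        assert r.realized_global_rate == len(cells) / m.values.size

    @pytest.mark.parametrize("mechanism", ["MCAR", "MAR", "MNAR", "MIX"])
    def test_deterministic_and_rate_monotone(self, rng, mechanism):
        m = complete(rng, p=25, n=20)
        r1 = inject(m, MissingnessSpec(mechanism, 0.1, seed=9))
        r1b = inject(m, MissingnessSpec(mechanism, 0.1, seed=9))
        r2 = inject(m, MissingnessSpec(mechanism, 0.25, seed=9))
        assert r1.masked_matrix == r1b.masked_matrix
        assert r2.realized_global_rate >= r1.realized_global_rate

    def test_spec_validation(self):
        with pytest.raises(ValidationError):
            MissingnessSpec("MCAR", 0.8)
        with pytest.raises(ValidationError):
            MissingnessSpec("bogus", 0.1)


class TestStratification:
    def test_bin_assignment_half_open(self):
        assert protein_stratum(2 / 45) == "[0%,5%)"      # 4.4%
        assert protein_stratum(0.07) == "[5%,10%)"
        assert protein_stratum(0.15) == "[10%,20%)"

    def test_exact_boundary_falls_right(self):
        # 9/45 = 20% exactly -> [20%, 30%) under the half-open convention
        assert protein_stratum(9 / 45) == "[20%,30%)"
        assert protein_stratum(0.30) == ">=30%"

    def test_untouched_proteins_excluded(self, rng):
        m = complete(rng, p=10, n=10)
        r = introduce_mcar(m, 0.1, np.random.default_rng(1))
        strata = stratify_protein_missingness(r)
        binned = [i for members in strata.values() for i in members]
        assert set(binned) == {c.protein for c in r.deleted_cells}

    def test_unsorted_bins_rejected(self, rng):
        m = complete(rng, p=5, n=5)
        r = introduce_mcar(m, 0.2, np.random.default_rng(1))
        with pytest.raises(ValidationError, match="sorted"):
            stratify_protein_missingness(r, bins=[0.1, 0.05])
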