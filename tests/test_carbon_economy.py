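import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pipsim.carbon_economy import (
    AllometryParams,
    TreeState,
    allocate,
    capacities,
    dbh_from_stem,
    defoliate,
    lai_of_stand,
    phloem_export,
    stem_biomass,
    turnover_step,
)

P = AllometryParams()


def make_tree(dbh=10.0, leaf=None, root=None, store=None, p=P):
    caps = capacities(dbh, p)
    return TreeState(
        dbh=dbh,
        b_leaf=caps.leaf if leaf is None else leaf,
        b_root=caps.root if root is None else root,
        b_stem=stem_biomass(dbh, p),
        b_store=caps.store if store is None else store,
    )


class TestAllometry:
    def test_round_trip_identity(self):
        b = stem_biomass(10.0, P)
        assert dbh_from_stem(b, P) == pytest.approx(10.0, abs=1e-10)

    def test_power_law_closed_form(self):
        p = AllometryParams(stem_a=0.08, stem_b=2.5)
        assert stem_biomass(10.0, p) == pytest.approx(0.08 * 10.0 ** 2.5, rel=1e-12)

    def test_monotone_in_dbh(self):
        assert stem_biomass(12.0, P) > stem_biomass(10.0, P)

    def test_capacity_ratios_hold(self):
        p = AllometryParams(q_root=0.8, q_store=0.4)
        caps = capacities(13.7, p)
        assert caps.root == pytest.approx(0.8 * caps.leaf, rel=1e-12)
        assert caps.store == pytest.approx(0.4 * caps.leaf, rel=1e-12)

    def test_capacity_closed_form(self):
        caps = capacities(10.0, P)
        assert caps.leaf == pytest.approx(P.leaf_a * 10.0 ** P.leaf_b, rel=1e-12)


class TestPhloemExport:
    def test_no_tax_passes_net(self):
        assert phloem_export(5.0, 1.0, 0.0) == (4.0, 0.0)

    def test_half_tax_splits_evenly(self):
        to_store, intercepted = phloem_export(3.0, 1.0, 0.5)
        assert to_store == pytest.approx(1.0) and intercepted == pytest.approx(1.0)

    def test_deficit_never_taxed(self):
        to_store, intercepted = phloem_export(0.5, 1.5, 0.9)
        assert to_store == pytest.approx(-1.0) and intercepted == 0.0


class TestTurnover:
    def test_baseline_multiplier_one(self):
        tree = make_tree()
        _, leaf_l, root_l = turnover_step(tree, P, root_multiplier=1.0)
        assert leaf_l == pytest.approx(tree.b_leaf * P.turnover_leaf / 365.0)
        assert root_l == pytest.approx(tree.b_root * P.turnover_root / 365.0)

    def test_multiplier_scales_root_litter_only(self):
        tree = make_tree()
        _, leaf1, root1 = turnover_step(tree, P, root_multiplier=1.0)
        _, leaf3, root3 = turnover_step(tree, P, root_multiplier=3.0)
        assert root3 == pytest.approx(3 * root1, rel=1e-12)
        assert leaf3 == leaf1

    def test_one_year_daily_compounding(self):
        # a year of unreplaced turnover at 1/3 yr-1 leaves (1 - r/365)^365,
        # the daily-compounded analogue of exp(-1/3)
        tree = make_tree()
        b0 = tree.b_leaf
        for _ in range(365):
            tree, _, _ = turnover_step(tree, P)
        expected = b0 * (1.0 - P.turnover_leaf / 365.0) ** 365
        assert tree.b_leaf == pytest.approx(expected, rel=1e-9)
        assert tree.b_leaf == pytest.approx(b0 * math.exp(-P.turnover_leaf), rel=2e-4)

    def test_rejects_multiplier_below_one(self):
        with pytest.raises(ValueError):
            turnover_step(make_tree(), P, root_multiplier=0.5)


class TestDefoliation:
    @pytest.mark.parametrize("fraction", [0.0, 0.5, 1.0])
    def test_fraction_removed_exactly(self, fraction):
        tree = make_tree()
        new, removed = defoliate(tree, fraction)
        assert new.b_leaf == pytest.approx(tree.b_leaf * (1 - fraction))
        assert removed == pytest.approx(tree.b_leaf * fraction)


class TestAllocation:
    def test_empty_storage_is_identity(self):
        tree = make_tree(store=0.0)
        new, repro, gr = allocate(tree, capacities(tree.dbh, P), 0.05, P)
        assert new == tree and repro == 0.0 and gr == 0.0

    def test_reserve_has_priority_over_depleted_pools(self):
        # storage below the K-day reserve: nothing moves even with pools low
        maint = 0.05
        tree = make_tree(leaf=0.1, root=0.1, store=0.5 * P.k_days * maint)
        new, repro, gr = allocate(tree, capacities(tree.dbh, P), maint, P)
        assert new == tree and repro == 0.0 and gr == 0.0

    def test_surplus_split_arithmetic(self):
        # pools at capacity, storage 1 kgC above capacity:
        # repro = 0.1, stem = 0.9*(1-0.25) = 0.675, growth resp = 0.225
        caps = capacities(10.0, P)
        tree = make_tree(store=caps.store + 1.0)
        new, repro, gr = allocate(tree, caps, 0.0, P)
        assert repro == pytest.approx(0.1, rel=1e-12)
        assert new.b_stem - tree.b_stem == pytest.approx(0.675, rel=1e-12)
        assert gr == pytest.approx(0.225, rel=1e-12)
        assert new.b_store == pytest.approx(caps.store)
        assert new.dbh > tree.dbh

    def test_minima_restored_before_stem_growth(self):
        caps = capacities(10.0, P)
        tree = make_tree(leaf=0.2 * caps.leaf, root=0.2 * caps.root, store=caps.store)
        new, repro, _ = allocate(tree, caps, 0.01, P)
        assert new.b_leaf >= 0.5 * caps.leaf - 1e-12
        assert new.b_root >= 0.5 * caps.root - 1e-12
        assert new.b_stem == tree.b_stem and repro == 0.0  # no surplus left the store

    def test_idempotent_at_capacity(self):
        caps = capacities(10.0, P)
        tree = make_tree()
        new, repro, gr = allocate(tree, caps, 0.02, P)
        assert new == tree and repro == 0.0 and gr == 0.0

    def test_dbh_never_decreases(self):
        tree = make_tree(store=capacities(10.0, P).store + 5.0)
        new, _, _ = allocate(tree, capacities(10.0, P), 0.0, P)
        assert new.dbh >= tree.dbh


@settings(max_examples=200, deadline=None)
@given(
    leaf_frac=st.floats(0.0, 1.2), root_frac=st.floats(0.0, 1.2),
    store=st.floats(0.0, 12.0), maint=st.floats(0.0, 0.2),
)
def test_allocation_conserves_carbon(leaf_frac, root_frac, store, maint):
    caps = capacities(10.0, P)
    tree = make_tree(leaf=leaf_frac * caps.leaf, root=root_frac * caps.root, store=store)
    new, repro, gr = allocate(tree, caps, maint, P)
    before = tree.b_leaf + tree.b_root + tree.b_stem + tree.b_store
    after = new.b_leaf + new.b_root + new.b_stem + new.b_store
    assert after + repro + gr == pytest.approx(before, abs=1e-12)
    assert new.b_store >= -1e-12


class TestLai:
    def test_zero_leaf_zero_lai(self):
        assert lai_of_stand(0.0, 700.0, 6.0) == 0.0

    def test_linear_in_density(self):
        assert lai_of_stand(3.0, 1400.0, 6.0) == pytest.approx(2 * lai_of_stand(3.0, 700.0, 6.0))

    def test_arithmetic_oracle(self):
        assert lai_of_stand(3.0, 700.0, 6.0) == pytest.approx(1.26, rel=1e-12)
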