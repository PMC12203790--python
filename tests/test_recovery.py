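import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import staplecycle as sc
from staplecycle.recovery import original_volumes


def make_pool(fl, tr, species="s1", cycle=0):
    amounts = pd.DataFrame(
        {"full_length": [fl], "truncated": [tr]},
        index=pd.Index([species], name="species_id"),
    )
    return sc.PoolState(amounts=amounts, volume_ul=100.0, cycle_index=cycle)


class TestReplenishVolume:
    @pytest.mark.parametrize(
        "recovery_yield, excess, expected_factor",
        [
            (0.0, 5.0, 1.0),    # total loss -> full replacement
            (1.0, 5.0, 0.2),    # perfect recovery -> only the consumed equivalent
            (0.9, 10.0, 0.19),  # printed equation: 1 - 0.9 + 0.9/10
            (0.5, 2.0, 0.75),
        ],
    )
    def test_printed_equation(self, recovery_yield, excess, expected_factor):
        assert sc.replenish_volume(10.0, recovery_yield, excess) == pytest.approx(
            10.0 * expected_factor, rel=1e-12
        )

    def test_invalid_excess(self):
        with pytest.raises(ValueError):
            sc.replenish_volume(10.0, 0.5, 0.0)

    @given(
        v=st.floats(min_value=0.0, max_value=1e3),
        y=st.floats(min_value=0.0, max_value=1.0),
        e=st.floats(min_value=1.0, max_value=50.0),
    )
    def test_linear_in_volume_and_bounded(self, v, y, e):
        out = sc.replenish_volume(v, y, e)
        assert out == pytest.approx(v * sc.replenish_volume(1.0, y, e), rel=1e-9, abs=1e-12)
        # between the consumed-equivalent floor and full replacement
        assert v / e - 1e-9 <= out <= v + 1e-9

    @given(e=st.floats(min_value=1.01, max_value=50.0))
    def test_decreasing_in_recovery_yield(self, e):
        vols = [sc.replenish_volume(1.0, y, e) for y in np.linspace(0, 1, 11)]
        assert all(a >= b - 1e-12 for a, b in zip(vols, vols[1:]))
        assert vols[-1] == pytest.approx(1.0 / e, rel=1e-12)


class TestApplyRecovery:
    def test_unit_yield_is_identity(self):
        pool = make_pool(6e-12, 4e-12)
        out = sc.apply_recovery(pool, 1.0)
        pd.testing.assert_frame_equal(out.amounts, pool.amounts)

    def test_neutral_scaling_preserves_purity(self):
        pool = make_pool(6e-12, 4e-12)
        out = sc.apply_recovery(pool, 0.5)
        assert out.total("s1") == pytest.approx(5e-12, rel=1e-12)
        assert out.purity("s1") == pytest.approx(0.6, rel=1e-12)

    def test_elementwise_scale(self):
        pool = make_pool(10e-12, 5e-12)
        out = sc.apply_recovery(pool, 0.8)
        assert out.amounts.loc["s1", "full_length"] == pytest.approx(8e-12)
        assert out.amounts.loc["s1", "truncated"] == pytest.approx(4e-12)

    def test_invalid_yield_rejected(self):
        with pytest.raises(ValueError):
            sc.RecoveryConfig(recovery_yield=1.2)

    def test_per_cycle_yields(self):
        cfg = sc.RecoveryConfig(recovery_yield=[0.9, 0.8])
        assert cfg.yield_at(0) == 0.9
        assert cfg.yield_at(1) == 0.8
        assert cfg.yield_at(5) == 0.8  # last value persists


class TestQC:
    @pytest.mark.parametrize(
        "ratio, expected",
        [
            (2.0, sc.QCResult.PASS),
            (3.0, sc.QCResult.REPEAT_PRECIPITATION),
            (2.2, sc.QCResult.PASS),  # boundary: rule triggers only above
        ],
    )
    def test_threshold_rule(self, ratio, expected):
        assert sc.qc_260_230(ratio) is expected

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            sc.qc_260_230(0.0)


class TestReplenish:
    def setup_pool(self, design, consume_eq=1.0):
        """Fresh pool minus `consume_eq` unbiased equivalents."""
        pool = sc.init_pool(design)
        scaffold = 50e-9 * 100e-6
        for sid in pool.amounts.index:
            p = pool.purity(sid)
            pool.amounts.loc[sid, "full_length"] -= consume_eq * scaffold * p
            pool.amounts.loc[sid, "truncated"] -= consume_eq * scaffold * (1 - p)
        return pool, scaffold

    def test_none_policy_is_identity(self, mixed_design):
        pool, _ = self.setup_pool(mixed_design)
        out = sc.replenish(
            pool,
            sc.ReplenishmentPolicy(kind="none"),
            mixed_design,
            original_volumes(mixed_design, 50e-9 * 100e-6),
        )
        pd.testing.assert_frame_equal(out.amounts, pool.amounts)

    def test_typical_perfect_recovery_restores_equivalents(self, uniform_design):
        pool, scaffold = self.setup_pool(uniform_design)
        policy = sc.ReplenishmentPolicy(
            kind="typical", fresh_purity_source=sc.SynthesisModel(1.0)
        )
        out = sc.replenish(
            pool, policy, uniform_design,
            original_volumes(uniform_design, scaffold), recovery_yield=1.0,
        )
        assert out.total("f1") == pytest.approx(10.0 * scaffold, rel=1e-10)

    def test_typical_accounts_for_recovery_loss(self, uniform_design):
        pool, scaffold = self.setup_pool(uniform_design)
        pool = sc.apply_recovery(pool, 0.9)
        policy = sc.ReplenishmentPolicy(
            kind="typical", fresh_purity_source=sc.SynthesisModel(1.0)
        )
        out = sc.replenish(
            pool, policy, uniform_design,
            original_volumes(uniform_design, scaffold), recovery_yield=0.9,
        )
        # recovered y*(E-1) eq plus fresh E*(1-y+y/E) = E eq exactly:
        # the printed equation replaces both the consumed equivalent and
        # the recovery loss
        assert out.total("f1") / scaffold == pytest.approx(10.0, rel=1e-9)

    def test_label_override_adds_fixed_fraction(self, mixed_design):
        pool, scaffold = self.setup_pool(mixed_design)
        before = pool.total("cy5")
        policy = sc.ReplenishmentPolicy(
            kind="typical", fresh_purity_source=sc.SynthesisModel(1.0)
        )
        out = sc.replenish(
            pool, policy, mixed_design,
            original_volumes(mixed_design, scaffold), recovery_yield=1.0,
        )
        added = out.total("cy5") - before
        # one-fifth of the amount initially used (5 eq * 0.2)
        assert added / scaffold == pytest.approx(0.2 * 5.0, rel=1e-9)

    def test_replenishment_never_decreases_purity(self, uniform_design):
        pool, scaffold = self.setup_pool(uniform_design)
        p_before = pool.purity("f1")
        policy = sc.ReplenishmentPolicy(
            kind="typical", fresh_purity_source=sc.SynthesisModel(0.99)
        )
        out = sc.replenish(
            pool, policy, uniform_design,
            original_volumes(uniform_design, scaffold), recovery_yield=1.0,
        )
        assert out.purity("f1") >= p_before - 1e-12

    def test_alternative_restores_total_in_original_proportions(self, mixed_design):
        pool, scaffold = self.setup_pool(mixed_design)
        policy = sc.ReplenishmentPolicy(
            kind="alternative", fresh_purity_source=sc.SynthesisModel(1.0)
        )
        out = sc.replenish(
            pool, policy, mixed_design, original_volumes(mixed_design, scaffold)
        )
        orig_total = sum(s.fold_excess for s in mixed_design) * scaffold
        total = out.amounts[["full_length", "truncated"]].to_numpy().sum()
        assert total == pytest.approx(orig_total, rel=1e-10)

    def test_missing_species_in_design_errors(self, uniform_design):
        pool, scaffold = self.setup_pool(uniform_design)
        other = [sc.StapleSpecies("other", 42)]
        with pytest.raises(KeyError, match="f1"):
            sc.replenish(
                pool,
                sc.ReplenishmentPolicy(kind="typical"),
                other,
                {"other": 1.0},
            )
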