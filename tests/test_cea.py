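"""Cost-effectiveness statistics: dominance, CEAC, EVPI, EVPPI metamodels."""

import numpy as np
import pandas as pd
import pytest

from copdcea.cea import (
    ce_plane,
    ceac,
    ceac_at,
    evpi,
    evppi_by_group,
    evppi_metamodel,
    icer,
    logistic_ce_explorer,
    net_benefit,
    parameter_groups,
)
from copdcea.psa import PSASample


def make_sample(cost_uc, qaly_uc, cost_idm, qaly_idm, draws=None):
    data = pd.DataFrame(
        {
            "cost_UC": cost_uc, "qaly_UC": qaly_uc, "ly_UC": qaly_uc,
            "cost_IDM": cost_idm, "qaly_IDM": qaly_idm, "ly_IDM": qaly_idm,
        }
    )
    data["dcost"] = data["cost_IDM"] - data["cost_UC"]
    data["dqaly"] = data["qaly_IDM"] - data["qaly_UC"]
    data["dly"] = data["ly_IDM"] - data["ly_UC"]
    if draws is None:
        draws = pd.DataFrame(index=data.index)
    return PSASample(data=data, draws=draws, meta={"seed": 0, "n_reps": len(data)})


class TestIcer:
    def test_published_increments_are_dominant(self):
        assert icer(-267.0, 0.102) == "dominant"

    def test_ratio_and_dominated(self):
        assert icer(500.0, 0.05) == pytest.approx(10000.0)
        assert icer(100.0, -0.1) == "dominated"
        assert icer(-100.0, -0.1) == pytest.approx(1000.0)
        assert icer(100.0, 0.0) == "undefined"

    def test_agrees_with_sign_logic_on_random_pairs(self, rng):
        dc = rng.normal(0, 300, 100_000)
        dq = rng.normal(0, 0.1, 100_000)
        for c, q in zip(dc[:2000], dq[:2000]):
            label = icer(c, q)
            if c < 0 and q > 0:
                assert label == "dominant"
            elif c > 0 and q < 0:
                assert label == "dominated"
            elif q != 0:
                assert label == pytest.approx(c / q)


class TestNetBenefit:
    def test_arithmetic_identity(self):
        assert net_benefit(0.102, -267.0, 50000.0) == pytest.approx(5367.0)
        assert net_benefit(1.732, -3973.0, 50000.0) == pytest.approx(90573.0)
        assert net_benefit(0.0, 0.0, 12345.0) == 0.0

    def test_negative_wtp_rejected(self):
        with pytest.raises(ValueError):
            net_benefit(0.1, 0.0, -1.0)


class TestCeac:
    def test_three_replication_brute_force(self):
        # (dqaly, dcost): (0.1, -100), (0.1, 100), (-0.1, -100)
        s = make_sample(
            cost_uc=[0, 0, 0], qaly_uc=[0, 0, 0],
            cost_idm=[-100, 100, -100], qaly_idm=[0.1, 0.1, -0.1],
        )
        assert ceac_at(s, 50000.0) == pytest.approx(2 / 3)

    def test_all_dominant_is_one_everywhere(self):
        s = make_sample([0] * 4, [0] * 4, [-50] * 4, [0.2] * 4)
        curve = ceac(s, [0, 1000, 50000])
        assert (curve["probability"] == 1.0).all()

    def test_wtp_zero_is_cost_only_criterion(self):
        s = make_sample([0, 0, 0], [0, 0, 0], [-1, 2, -3], [1, 1, 1])
        assert ceac_at(s, 0.0) == pytest.approx(2 / 3)

    def test_ties_count_as_not_cost_effective(self):
        s = make_sample([0, 0], [0, 0], [0, 0], [0, 0])
        assert ceac_at(s, 50000.0) == 0.0

    def test_monotone_when_all_dq_nonnegative(self, trial_run):
        sub = trial_run.sample.data
        mask = sub["dqaly"] >= 0
        s = make_sample(
            sub.loc[mask, "cost_UC"].to_numpy(),
            sub.loc[mask, "qaly_UC"].to_numpy(),
            sub.loc[mask, "cost_IDM"].to_numpy(),
            sub.loc[mask, "qaly_IDM"].to_numpy(),
        )
        probs = ceac(s)["probability"].to_numpy()
        assert np.all(np.diff(probs) >= -1e-12)


class TestEvpi:
    def test_no_decision_uncertainty(self):
        s = make_sample([0, 0], [0, 0], [-10, -20], [0.1, 0.2])
        assert evpi(s, 50000.0) == 0.0

    def test_two_replication_enumeration(self):
        # per-arm NBs: rep1 (UC 0, IDM 1), rep2 (UC 2, IDM 0)
        s = make_sample(cost_uc=[0, -2], qaly_uc=[0, 0],
                        cost_idm=[-1, 0], qaly_idm=[0, 0])
        assert evpi(s, 50000.0) == pytest.approx(0.5, abs=1e-12)

    def test_matches_brute_force_on_random_samples(self, rng):
        for _ in range(20):
            n = rng.integers(2, 30)
            s = make_sample(
                rng.normal(900, 100, n), rng.uniform(0.5, 0.9, n),
                rng.normal(700, 100, n), rng.uniform(0.5, 0.9, n),
            )
            wtp = float(rng.uniform(0, 100000))
            nb_uc = s.data["qaly_UC"] * wtp - s.data["cost_UC"]
            nb_idm = s.data["qaly_IDM"] * wtp - s.data["cost_IDM"]
            brute = np.mean(np.maximum(nb_uc, nb_idm)) - max(
                nb_uc.mean(), nb_idm.mean()
            )
            assert evpi(s, wtp) == pytest.approx(brute, abs=1e-10)
            assert evpi(s, wtp) >= -1e-12

    def test_homogeneity_in_scale(self):
        s = make_sample([0, -2, 3], [0, 0, 0], [-1, 0, 1], [0, 0, 0])
        base = evpi(s, 1000.0)
        scaled = make_sample([0, -20, 30], [0, 0, 0], [-10, 0, 10], [0, 0, 0])
        assert evpi(scaled, 1000.0) == pytest.approx(10 * base, rel=1e-12)


class TestEvppi:
    def test_uninformative_subset_is_zero(self, rng):
        n = 500
        draws = pd.DataFrame({"noise": rng.normal(size=n)})
        s = make_sample(
            rng.normal(900, 50, n), rng.uniform(0.6, 0.8, n),
            rng.normal(700, 50, n), rng.uniform(0.6, 0.8, n), draws=draws,
        )
        # noise is independent of outcomes: fitted slope ~ 0, EVPPI ~ 0
        res = evppi_metamodel(s, ["noise"], 50000.0)
        assert res.value == pytest.approx(0.0, abs=50.0)
        assert res.r_squared < 0.02

    def test_saturated_fit_recovers_evpi_on_linear_toy(self, rng):
        # dNB is exactly linear in three retained parameters and UC NB is 0,
        # so the saturated linear metamodel reproduces EVPI
        n = 4000
        x = rng.normal(size=(n, 3))
        dnb = 200.0 * x[:, 0] - 120.0 * x[:, 1] + 60.0 * x[:, 2] + 100.0
        draws = pd.DataFrame(x, columns=["a", "b", "c"])
        s = make_sample(
            cost_uc=np.zeros(n), qaly_uc=np.zeros(n),
            cost_idm=-dnb, qaly_idm=np.zeros(n), draws=draws,
        )
        full = evppi_metamodel(s, ["a", "b", "c"], wtp=0.0)
        assert full.r_squared > 0.999
        assert full.value == pytest.approx(evpi(s, 0.0), rel=0.01)
        # single-parameter subsets approach EVPI from below
        single = evppi_metamodel(s, ["a"], wtp=0.0)
        assert 0.0 <= single.value <= evpi(s, 0.0) + 1e-9

    def test_evppi_bounded_by_evpi_for_all_groups(self, trial_run):
        wtp = 50000.0
        total = evpi(trial_run.sample, wtp)
        for name, value in evppi_by_group(trial_run.sample, wtp).items():
            assert -1e-9 <= value <= total * 1.05 + 1e-9, name

    def test_missing_column_rejected(self, trial_run):
        with pytest.raises(KeyError):
            evppi_metamodel(trial_run.sample, ["not.a.column"], 50000.0)

    def test_utility_group_dominates_single_subsets(self, trial_run):
        values = evppi_by_group(trial_run.sample, 50000.0)
        assert max(values, key=values.get) == "utilities"

    def test_logistic_explorer_flags_utilities(self, trial_run):
        groups = parameter_groups(trial_run.sample)
        cols = groups["utilities"] + groups["intervention_costs"]
        fit = logistic_ce_explorer(trial_run.sample, 50000.0, columns=cols)
        coefs = fit.params.drop("const").abs()
        assert coefs.idxmax() in groups["utilities"]


class TestCePlane:
    def test_dominant_only_sample(self):
        s = make_sample([0, 0], [0, 0], [-10, -20], [0.1, 0.2])
        plane = ce_plane(s, 50000.0)
        assert plane.quadrant_counts["SE"] == 2
        assert sum(plane.quadrant_counts.values()) == 2

    def test_sustainability_fraction_equals_ceac(self, trial_run):
        plane = ce_plane(trial_run.sample, 50000.0)
        assert plane.sustainability_fraction == pytest.approx(
            ceac_at(trial_run.sample, 50000.0), abs=1e-12
        )

    def test_quadrant_counts_partition_sample(self, trial_run):
        plane = ce_plane(trial_run.sample, 50000.0)
        assert sum(plane.quadrant_counts.values()) == trial_run.sample.n_reps
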