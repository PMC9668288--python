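import math

import numpy as np
import pandas as pd
import pytest

from rvburden.collapsing import build_carrier_matrix, fisher_burden
from rvburden.exwas import variant_binary_tests
from rvburden.followup import (
    JointModelSpec,
    conditional_joint_regression,
    dominant_snp_model,
    ld_from_genotypes,
    ld_from_haplotypes,
    leave_out_collapsing,
    stratified_effect_modification,
)
from rvburden.meta import heterogeneity_test


def _logistic_cohort(rng, n, effects, prevalence=0.3):
    """Simple direct logistic draw for follow-up unit tests."""
    data = pd.DataFrame({
        "age": rng.integers(40, 70, size=n).astype(float),
        "sex": rng.choice([0.0, 1.0], size=n),
    })
    eta = np.zeros(n)
    for name, (freq, log_or) in effects.items():
        data[name] = (rng.random(n) < freq).astype(float)
        eta += log_or * data[name]
    c = math.log(prevalence / (1 - prevalence))
    data["outcome"] = (rng.random(n) < 1 / (1 + np.exp(-(c + eta)))).astype(float)
    return data


class TestConditionalJointRegression:
    def test_orthogonal_indicators_match_marginals(self):
        rng = np.random.default_rng(0)
        data = _logistic_cohort(rng, 30_000, {"v1": (0.02, -0.8), "v2": (0.02, 0.6)})
        # force zero overlap
        data.loc[(data.v1 > 0) & (data.v2 > 0), "v2"] = 0.0
        joint = conditional_joint_regression(
            JointModelSpec("outcome", ("v1", "v2"), ()), data
        ).set_index("term")
        m1 = conditional_joint_regression(JointModelSpec("outcome", ("v1",), ()), data)
        m2 = conditional_joint_regression(JointModelSpec("outcome", ("v2",), ()), data)
        assert joint.loc["v1", "estimate"] == pytest.approx(m1.iloc[0]["estimate"], abs=0.02)
        assert joint.loc["v2", "estimate"] == pytest.approx(m2.iloc[0]["estimate"], abs=0.02)

    def test_single_indicator_equals_marginal_exactly(self):
        rng = np.random.default_rng(1)
        data = _logistic_cohort(rng, 5000, {"v1": (0.05, -0.5)})
        a = conditional_joint_regression(JointModelSpec("outcome", ("v1",), ("age", "sex")), data)
        b = conditional_joint_regression(JointModelSpec("outcome", ("v1",), ("age", "sex")), data)
        assert a.iloc[0]["estimate"] == b.iloc[0]["estimate"]

    def test_collinear_indicators_flagged(self):
        rng = np.random.default_rng(2)
        data = _logistic_cohort(rng, 1000, {"v1": (0.1, 0.0)})
        data["v2"] = data["v1"]
        with pytest.raises(ValueError, match="collinear"):
            conditional_joint_regression(JointModelSpec("outcome", ("v1", "v2"), ()), data)

    def test_duplicate_indicator_names_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            JointModelSpec("outcome", ("v1", "v1"), ())

    def test_separation_flagged(self):
        data = pd.DataFrame({
            "outcome": [1.0] * 10 + [0.0] * 10,
            "v1": [1.0] * 10 + [0.0] * 10,
        })
        out = conditional_joint_regression(JointModelSpec("outcome", ("v1",), ()), data)
        assert out.iloc[0]["flag"].startswith("separation")

    def test_two_ptv_recovery(self):
        # regime: two hemizygous PTVs with protective ORs 0.30 and 0.68
        rng = np.random.default_rng(3)
        ests1, ests2 = [], []
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            data = _logistic_cohort(
                rng, 40_000,
                {"ptv1": (0.002, math.log(0.30)), "ptv2": (0.007, math.log(0.68))},
                prevalence=0.1,
            )
            fit = conditional_joint_regression(
                JointModelSpec("outcome", ("ptv1", "ptv2"), ("age", "sex")), data
            ).set_index("term")
            ests1.append(fit.loc["ptv1", "estimate"])
            ests2.append(fit.loc["ptv2", "estimate"])
        for ests, target in ((ests1, math.log(0.30)), (ests2, math.log(0.68))):
            sem = np.std(ests, ddof=1) / math.sqrt(len(ests))
            assert abs(np.mean(ests) - target) < 4 * sem + 0.02


class TestLeaveOut:
    @staticmethod
    def _setup(rng):
        n, m = 2000, 5
        dosage = rng.choice([0, 1], size=(n, m), p=[0.97, 0.03]).astype(np.int8)
        positions = np.arange(100, 100 + 10 * m, 10)
        outcome = rng.random(n) < 0.3
        return dosage, np.arange(m), positions, outcome

    def test_exclude_nothing_identity(self):
        rng = np.random.default_rng(4)
        dosage, qv, pos, outcome = self._setup(rng)
        base_cm = build_carrier_matrix(dosage, qv, "dominant", positions=pos)
        base = fisher_burden(base_cm.carrier, outcome)
        left = leave_out_collapsing(dosage, qv, [], "dominant", outcome, positions=pos)
        assert left.p == base.p
        assert left.n_case_carrier == base.n_case_carrier

    def test_all_but_one_equals_single_variant_test(self):
        rng = np.random.default_rng(5)
        dosage, qv, pos, outcome = self._setup(rng)
        left = leave_out_collapsing(dosage, qv, [0, 1, 2, 3], "dominant", outcome, positions=pos)
        single = {r.genetic_model: r
                  for r in variant_binary_tests(dosage[:, 4], outcome)}["dominant"]
        assert left.p == pytest.approx(single.p, abs=1e-12)
        assert (left.n_case_carrier, left.n_ctrl_carrier) == (single.table[0], single.table[2])

    def test_carrier_drop_is_exact_set_arithmetic(self):
        rng = np.random.default_rng(6)
        dosage, qv, pos, outcome = self._setup(rng)
        full = build_carrier_matrix(dosage, qv, "dominant", positions=pos).carrier
        reduced_idx = np.array([2, 3, 4])
        reduced = build_carrier_matrix(dosage, reduced_idx, "dominant", positions=pos).carrier
        left = leave_out_collapsing(dosage, qv, [0, 1], "dominant", outcome, positions=pos)
        assert left.n_carrier == int(reduced.sum())
        assert ((full & ~reduced) == ((dosage[:, :2] > 0).any(axis=1) & ~reduced)).all()

    def test_exclusions_validated(self):
        rng = np.random.default_rng(7)
        dosage, qv, pos, outcome = self._setup(rng)
        with pytest.raises(ValueError, match="not in the QV set"):
            leave_out_collapsing(dosage, qv, [99], "dominant", outcome, positions=pos)
        empty = leave_out_collapsing(dosage, qv, list(qv), "dominant", outcome, positions=pos)
        assert "empty_qv_set" in empty.flags and math.isnan(empty.p)


class TestDominantSnpModel:
    def test_large_sample_agrees_with_table_or(self):
        rng = np.random.default_rng(8)
        data = _logistic_cohort(rng, 60_000, {"tag": (0.51, math.log(1.37))}, prevalence=0.2)
        dosage = data["tag"].to_numpy().astype(int)
        res = dominant_snp_model(dosage, data["outcome"].to_numpy())
        carrier = dosage >= 1
        case = data["outcome"].to_numpy() > 0
        a = (carrier & case).sum(); b = (~carrier & case).sum()
        c = (carrier & ~case).sum(); d = (~carrier & ~case).sum()
        table_or = (a * d) / (b * c)
        assert res["or"] == pytest.approx(table_or, abs=0.005)
        assert res["ci_low"] < 1.37 < res["ci_high"]

    def test_monomorphic_flagged(self):
        res = dominant_snp_model(np.zeros(100, dtype=int), np.random.default_rng(0).random(100) < 0.5)
        assert res["flag"] == "monomorphic"

    def test_call_rate_guard(self):
        dosage = np.full(100, -1); dosage[:5] = 1
        with pytest.raises(ValueError, match="call rate"):
            dominant_snp_model(dosage, np.zeros(100))


class TestStratifiedEffectModification:
    def test_identical_effects_q_small(self):
        rng = np.random.default_rng(9)
        data = _logistic_cohort(rng, 40_000, {"g": (0.02, -0.6)})
        modifier = rng.random(len(data)) < 0.5
        res = stratified_effect_modification(
            data["g"].to_numpy() > 0, modifier, data["outcome"].to_numpy(),
            pd.DataFrame({"age": data["age"], "sex": data["sex"]}),
        )
        assert res.q is not None and res.q < 6.0
        assert res.q_p == heterogeneity_test(res.estimates[0], res.ses[0],
                                             res.estimates[1], res.ses[1])[2]

    def test_label_swap_symmetric(self):
        rng = np.random.default_rng(10)
        data = _logistic_cohort(rng, 20_000, {"g": (0.03, -0.8)})
        modifier = rng.random(len(data)) < 0.5
        carrier = data["g"].to_numpy() > 0
        outcome = data["outcome"].to_numpy()
        r1 = stratified_effect_modification(carrier, modifier, outcome)
        r2 = stratified_effect_modification(carrier, ~modifier, outcome)
        assert r1.estimates == (r2.estimates[1], r2.estimates[0])
        assert r1.q == pytest.approx(r2.q, rel=1e-12)

    def test_zero_carrier_stratum_skips_q(self):
        rng = np.random.default_rng(11)
        carrier = rng.random(500) < 0.05
        modifier = rng.random(500) < 0.5
        carrier[modifier] = False
        outcome = (rng.random(500) < 0.3).astype(float)
        res = stratified_effect_modification(carrier, modifier, outcome)
        assert res.q is None and "zero_carriers" in res.flags

    def test_empty_stratum_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            stratified_effect_modification(
                np.ones(10, bool), np.ones(10, bool), np.zeros(10)
            )


class TestLD:
    def test_fixed_haplotype_counts(self):
        # AB=40, Ab=10, aB=10, ab=40 -> D = 0.4 - 0.25 = 0.15,
        # D' = 0.15/0.25 = 0.6, r2 = 0.15^2/0.0625 = 0.36
        h1 = np.repeat([1, 1, 0, 0], [40, 10, 10, 40])
        h2 = np.repeat([1, 0, 1, 0], [40, 10, 10, 40])
        res = ld_from_haplotypes(h1, h2)
        assert res.d == pytest.approx(0.15, abs=1e-12)
        assert res.d_prime == pytest.approx(0.6, abs=1e-12)
        assert res.r2 == pytest.approx(0.36, abs=1e-12)
        assert res.haplotype_freqs["AB"] == pytest.approx(0.4)

    def test_complete_ld(self):
        h1 = np.repeat([1, 0], [30, 70])
        res = ld_from_haplotypes(h1, h1.copy())
        assert res.d_prime == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_independent_variants_near_zero(self):
        rng = np.random.default_rng(12)
        r2s = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            h1 = (rng.random(20_000) < 0.3).astype(int)
            h2 = (rng.random(20_000) < 0.4).astype(int)
            r2s.append(ld_from_haplotypes(h1, h2).r2)
        assert np.mean(r2s) < 0.001

    def test_em_agrees_with_phased_truth(self):
        rng = np.random.default_rng(13)
        n = 10_000
        # build correlated haplotypes, then scramble phase into genotypes
        hap_pool = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
        probs = np.array([0.25, 0.15, 0.1, 0.5])
        pick1 = rng.choice(4, size=n, p=probs)
        pick2 = rng.choice(4, size=n, p=probs)
        h1a, h1b = hap_pool[pick1, 0], hap_pool[pick2, 0]
        h2a, h2b = hap_pool[pick1, 1], hap_pool[pick2, 1]
        phased = ld_from_haplotypes(
            np.concatenate([h1a, h1b]), np.concatenate([h2a, h2b])
        )
        em = ld_from_genotypes(h1a + h1b, h2a + h2b)
        assert em.method == "em"
        assert em.d_prime == pytest.approx(phased.d_prime, abs=0.01)
        assert em.r2 == pytest.approx(phased.r2, abs=0.01)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="polymorphic"):
            ld_from_genotypes(np.zeros(100, int), np.ones(100, int))
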