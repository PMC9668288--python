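import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rvburden import qvmodels
from rvburden.collapsing import (
    PhenotypeSpec,
    build_carrier_matrix,
    compute_qv_sets,
    fisher_burden,
    int_transform,
    quantitative_burden,
    run_collapsing,
    sex_match_controls,
)
from rvburden.exact import fisher_exact_2x2

from conftest import fisher_oracle, recessive_scan_oracle


class TestCarrierMatrix:
    def test_compound_het_female(self):
        dosage = np.array([[1, 1, 0]])
        cm = build_carrier_matrix(dosage, np.array([0, 1, 2]), "recessive",
                                  is_male=np.array([False]),
                                  positions=np.array([100, 110, 120]))
        assert cm.carrier[0] and cm.basis[0] == "compound_het"

    def test_hemizygous_male(self):
        dosage = np.array([[2, 0]])
        cm = build_carrier_matrix(dosage, np.array([0, 1]), "recessive",
                                  is_male=np.array([True]),
                                  positions=np.array([100, 110]))
        assert cm.carrier[0] and cm.basis[0] == "hemizygous"

    def test_single_het_is_dominant_only(self):
        dosage = np.array([[0, 1, 0]])
        idx = np.array([0, 1, 2])
        pos = np.array([100, 110, 120])
        rec = build_carrier_matrix(dosage, idx, "recessive", positions=pos)
        dom = build_carrier_matrix(dosage, idx, "dominant", positions=pos)
        assert not rec.carrier[0] and dom.carrier[0]

    def test_same_position_counted_once(self):
        # two het alts at one position cannot be compound het
        dosage = np.array([[1, 1]])
        cm = build_carrier_matrix(dosage, np.array([0, 1]), "recessive",
                                  positions=np.array([100, 100]))
        assert not cm.carrier[0]

    def test_missing_contributes_nothing(self):
        dosage = np.array([[-1, 1]])
        cm = build_carrier_matrix(dosage, np.array([0, 1]), "recessive",
                                  positions=np.array([100, 110]))
        assert not cm.carrier[0]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n, m = 150, 7
            dosage = rng.choice([-1, 0, 0, 0, 1, 1, 2], size=(n, m)).astype(np.int8)
            positions = rng.choice([100, 110, 120, 130], size=m)
            qv_idx = np.sort(rng.choice(m, size=4, replace=False))
            cm = build_carrier_matrix(dosage, qv_idx, "recessive", positions=positions)
            oracle = recessive_scan_oracle(dosage, qv_idx, None, None, positions)
            np.testing.assert_array_equal(cm.carrier, oracle)

    def test_dominant_count_identity(self):
        rng = np.random.default_rng(6)
        dosage = rng.choice([-1, 0, 1, 2], size=(200, 5)).astype(np.int8)
        idx = np.arange(5)
        cm = build_carrier_matrix(dosage, idx, "dominant")
        assert cm.carrier.sum() == ((dosage[:, idx] > 0).any(axis=1)).sum()


class TestSexMatching:
    def test_equal_fractions_unchanged(self):
        keep = sex_match_controls(np.repeat([True, False], 50),
                                  np.repeat([True, False], 50), seed=1)
        assert keep.all()

    def test_matching_triggered(self):
        case_f = np.repeat([True, False], [40, 60])
        ctrl_f = np.repeat([True, False], [60, 40])
        assert fisher_oracle(40, 60, 60, 40) < 0.05
        keep = sex_match_controls(case_f, ctrl_f, seed=3)
        kept = ctrl_f[keep]
        assert abs(kept.mean() - 0.40) <= 1.5 / kept.size
        a, b = int(kept.sum()), int((~kept).sum())
        assert fisher_exact_2x2(40, 60, a, b) >= 0.05

    def test_deterministic(self):
        case_f = np.repeat([True, False], [40, 60])
        ctrl_f = np.repeat([True, False], [60, 40])
        k1 = sex_match_controls(case_f, ctrl_f, seed=11)
        k2 = sex_match_controls(case_f, ctrl_f, seed=11)
        np.testing.assert_array_equal(k1, k2)

    def test_single_sex_warns(self):
        with pytest.warns(UserWarning, match="single-sex"):
            keep = sex_match_controls(np.ones(10, bool), np.ones(10, bool), seed=0)
        assert keep.all()


class TestFisherBurden:
    def test_counts_and_frequencies_echoed(self):
        carrier = np.array([True] * 5 + [False] * 95 + [True] * 9 + [False] * 491)
        case = np.array([True] * 100 + [False] * 500)
        res = fisher_burden(carrier, case)
        assert (res.n_case_carrier, res.n_case_noncarrier) == (5, 95)
        assert (res.n_ctrl_carrier, res.n_ctrl_noncarrier) == (9, 491)
        assert res.f_case == pytest.approx(0.05)
        assert res.f_ctrl == pytest.approx(9 / 500)
        assert res.p == pytest.approx(fisher_oracle(5, 95, 9, 491), abs=1e-12)
        assert res.ci_low < res.estimate < res.ci_high

    def test_no_carriers_flag(self):
        res = fisher_burden(np.zeros(20, bool), np.arange(20) < 10)
        assert res.p == 1.0 and "or_undefined" in res.flags

    def test_requires_cases_and_controls(self):
        with pytest.raises(ValueError):
            fisher_burden(np.zeros(5, bool), np.ones(5, bool))


class TestIntTransform:
    def test_three_values(self):
        out = int_transform([1.0, 2.0, 3.0])
        expected = stats.norm.ppf((np.array([1, 2, 3]) - 0.375) / 3.25)
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert out[1] == pytest.approx(0.0, abs=1e-12)
        assert out[2] == pytest.approx(0.8694, abs=1e-4)

    def test_mean_and_symmetry(self):
        rng = np.random.default_rng(2)
        x = rng.exponential(size=501)
        out = int_transform(x)
        assert abs(out.mean()) < 1e-6 * x.size
        assert abs(stats.skew(out)) < 1e-6 * x.size

    def test_monotone_and_missing_preserved(self):
        x = np.array([5.0, np.nan, 1.0, 3.0])
        out = int_transform(x)
        assert np.isnan(out[1])
        assert out[2] < out[3] < out[0]

    def test_ties_share_rank(self):
        out = int_transform([1.0, 2.0, 2.0, 3.0])
        assert out[1] == out[2]

    def test_constant_raises(self):
        with pytest.raises(ValueError, match="constant"):
            int_transform([2.0, 2.0, 2.0])


class TestQuantitativeBurden:
    def test_orthogonal_covariate_leaves_beta(self):
        rng = np.random.default_rng(3)
        n = 2000
        carrier = rng.random(n) < 0.05
        y = -0.3 * carrier + rng.normal(size=n)
        base = quantitative_burden(carrier, y, None)
        # residualise an arbitrary covariate against the carrier column so
        # it is exactly orthogonal (Frisch-Waugh check)
        z = rng.normal(size=n)
        X = np.column_stack([np.ones(n), carrier.astype(float)])
        z_orth = z - X @ np.linalg.lstsq(X, z, rcond=None)[0]
        with_cov = quantitative_burden(carrier, y, pd.DataFrame({"z": z_orth}))
        assert with_cov.estimate == pytest.approx(base.estimate, abs=1e-8)

    def test_null_beta_near_zero(self):
        rng = np.random.default_rng(4)
        carrier = rng.random(3000) < 0.05
        y = rng.normal(size=3000)
        res = quantitative_burden(carrier, y, None)
        assert abs(res.estimate) < 0.2
        assert res.n_carrier + res.n_noncarrier == 3000

    def test_collinear_raises_with_names(self):
        n = 100
        carrier = np.arange(n) < 10
        cov = pd.DataFrame({"dup": carrier.astype(float)})
        with pytest.raises(ValueError, match="collinear"):
            quantitative_burden(carrier, np.random.default_rng(0).normal(size=n), cov)

    def test_zero_carriers_flagged(self):
        res = quantitative_burden(np.zeros(50, bool), np.random.default_rng(1).normal(size=50))
        assert "no_carriers" in res.flags and math.isnan(res.estimate)


class TestRunCollapsing(object):
    def test_end_to_end_on_demo_cohort(self, demo_cohort):
        sim = demo_cohort
        registry = {name: qvmodels.DEFAULT_REGISTRY[name] for name in ("rec", "ptv", "syn")}
        phenos = [
            PhenotypeSpec("diabetes", "binary", sex_match=False),
            PhenotypeSpec("hba1c", "quantitative"),
        ]
        table, lambdas = run_collapsing(
            sim.samples, sim.variants, sim.genotypes.dosage, phenos, registry, seed=1
        )
        assert set(table["model"]) <= {"rec", "ptv", "syn"}
        rec_x = table[(table.gene == "GENE_X") & (table.model == "rec")
                      & (table.phenotype == "diabetes")]
        assert len(rec_x) == 1
        row = rec_x.iloc[0]
        total = (row.n_case_carrier + row.n_case_noncarrier
                 + row.n_ctrl_carrier + row.n_ctrl_noncarrier)
        assert total == len(sim.samples)
        syn_rows = table[table.model == "syn"]
        assert all("negative_control" in f for f in syn_rows["flags"])
        assert set(lambdas) <= {"rec", "ptv", "syn"}

    def test_deterministic_ordering(self, demo_cohort):
        sim = demo_cohort
        registry = {"rec": qvmodels.DEFAULT_REGISTRY["rec"]}
        phenos = [PhenotypeSpec("diabetes", "binary", sex_match=False)]
        t1, _ = run_collapsing(sim.samples, sim.variants, sim.genotypes.dosage,
                               phenos, registry, seed=1)
        t2, _ = run_collapsing(sim.samples, sim.variants, sim.genotypes.dosage,
                               phenos, registry, seed=1)
        pd.testing.assert_frame_equal(t1, t2)
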