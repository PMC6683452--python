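"""Case-control statistics: HWE, genotype χ², model tables, odds ratios,
adjusted logistic regression, and power."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regsnp_screen.association import (
    AssociationResult,
    Contingency2x2,
    GeneticModel,
    GenotypeCounts,
    PowerSpec,
    adjusted_logistic,
    build_model_tables,
    genotype_chisq,
    genotype_counts_from_subjects,
    hwe_test,
    odds_ratio,
    power_genetic,
)
from regsnp_screen.synthetic_data import simulate_genotype_counts

from conftest import RS9395890_CASE, RS9395890_CONTROL

COUNTS = GenotypeCounts("rs9395890", control=RS9395890_CONTROL, case=RS9395890_CASE)


class TestHwe:
    def test_published_control_counts_in_equilibrium(self):
        chi2, p = hwe_test(RS9395890_CONTROL)
        assert p > 0.05
        # frozen from the hand computation: p̂(G)=725/1692, χ²=0.1067
        assert chi2 == pytest.approx(0.1067, abs=5e-4)
        assert p == pytest.approx(0.7439, abs=5e-4)

    def test_exact_hwe_counts(self):
        chi2, p = hwe_test((25, 50, 25))
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_extreme_disequilibrium(self):
        # all homozygotes: χ² equals n, p vanishingly small
        chi2, p = hwe_test((100, 0, 100))
        assert chi2 == pytest.approx(200.0) and p < 1e-6

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            hwe_test((0, 0, 0))


class TestGenotypeChisq:
    def test_published_counts_reproduce_p(self):
        assert genotype_chisq(COUNTS) == pytest.approx(0.031, abs=5e-4)

    def test_identical_rows_p_one(self):
        c = GenotypeCounts("x", (10, 20, 30), (10, 20, 30))
        assert genotype_chisq(c) == pytest.approx(1.0)

    def test_empty_column_reduces_df_with_warning(self):
        c = GenotypeCounts("x", (10, 20, 0), (12, 18, 0))
        with pytest.warns(UserWarning, match="df reduced"):
            p = genotype_chisq(c)
        assert 0 <= p <= 1

    def test_agrees_with_permutation_oracle(self, rng):
        """Monte-Carlo permutation p on a small table brackets the χ² p."""
        control, case = (9, 14, 7), (4, 10, 16)
        c = GenotypeCounts("small", control, case)
        p_chi = genotype_chisq(c)
        labels = np.repeat([0, 1], [sum(control), sum(case)])
        genos = np.concatenate([
            np.repeat([0, 1, 2], control), np.repeat([0, 1, 2], case)
        ])

        def stat(lab):
            t = np.zeros((2, 3))
            for g_row in (0, 1):
                for g_col in (0, 1, 2):
                    t[g_row, g_col] = np.sum((lab == g_row) & (genos == g_col))
            e = t.sum(1, keepdims=True) @ t.sum(0, keepdims=True) / t.sum()
            return ((t - e) ** 2 / e).sum()

        observed = stat(labels)
        n_shuffles = 100_000
        perm = labels.copy()
        count = 0
        for _ in range(n_shuffles):
            rng.shuffle(perm)
            if stat(perm) >= observed - 1e-12:
                count += 1
        p_perm = count / n_shuffles
        # 4 MC standard errors
        assert abs(p_perm - p_chi) < 4 * math.sqrt(p_chi * (1 - p_chi) / n_shuffles) + 0.01


class TestModelTables:
    def test_published_allele_collapse(self):
        t = build_model_tables(COUNTS)[GeneticModel.ALLELE]
        # control alleles: G = 725, T = 967; case: G = 655, T = 1027
        assert (t.c, t.d) == (967, 725)
        assert (t.a, t.b) == (1027, 655)

    def test_published_recessive_collapse(self):
        t = build_model_tables(COUNTS)[GeneticModel.RECESSIVE]
        assert (t.a, t.b, t.c, t.d) == (324, 517, 274, 572)

    def test_published_dominant_collapse(self):
        t = build_model_tables(COUNTS)[GeneticModel.DOMINANT]
        assert (t.a, t.b, t.c, t.d) == (703, 138, 693, 153)

    def test_all_zero_counts(self):
        tables = build_model_tables(GenotypeCounts("z", (0, 0, 0), (0, 0, 0)))
        for t in tables.values():
            assert (t.a, t.b, t.c, t.d) == (0, 0, 0, 0)


class TestOddsRatio:
    def test_recessive_published_row(self):
        r = odds_ratio(Contingency2x2(324, 517, 274, 572))
        assert round(r.or_estimate, 2) == 1.31
        assert (round(r.ci95[0], 2), round(r.ci95[1], 2)) == (1.07, 1.60)
        assert round(r.p_value, 3) == 0.008

    def test_dominant_published_row(self):
        r = odds_ratio(Contingency2x2(703, 138, 693, 153))
        assert round(r.or_estimate, 2) == 1.12
        assert (round(r.ci95[0], 2), round(r.ci95[1], 2)) == (0.87, 1.45)

    @pytest.mark.parametrize(
        "cells,expect_or,expect_ci",
        [
            ((141, 288, 122, 304), 1.22, (0.91, 1.63)),  # rs11826681 GG vs CC
            ((18, 582, 23, 611), 0.82, (0.44, 1.54)),    # rs7284245 TT vs GG
            ((2, 753, 4, 745), 0.49, (0.09, 2.71)),      # rs59118205 TT vs CC
            ((8, 696, 4, 697), 2.00, (0.60, 6.68)),      # rs78229468 GG vs AA
        ],
    )
    def test_published_genotype_level_rows(self, cells, expect_or, expect_ci):
        r = odds_ratio(Contingency2x2(*cells))
        assert round(r.or_estimate, 2) == expect_or
        assert (round(r.ci95[0], 2), round(r.ci95[1], 2)) == expect_ci

    def test_balanced_table(self):
        r = odds_ratio(Contingency2x2(10, 10, 10, 10))
        assert r.or_estimate == pytest.approx(1.0)
        assert math.log(r.ci95[0]) == pytest.approx(-math.log(r.ci95[1]))

    def test_zero_case_exposed_cell(self):
        # mirrors a published "0.00 (0.00 - inf)" row: no 0.5 correction
        r = odds_ratio(Contingency2x2(0, 665, 1, 846))
        assert r.or_estimate == 0.0 and r.ci95 == (0.0, math.inf)

    def test_zero_denominator_cell(self):
        r = odds_ratio(Contingency2x2(5, 0, 3, 10))
        assert math.isinf(r.or_estimate)

    cells = st.integers(1, 500)

    @settings(max_examples=100, derandomize=True)
    @given(cells, cells, cells, cells)
    def test_antisymmetry_and_ci_contains_estimate(self, a, b, c, d):
        r = odds_ratio(Contingency2x2(a, b, c, d))
        swapped = odds_ratio(Contingency2x2(b, a, d, c))
        assert swapped.or_estimate == pytest.approx(1 / r.or_estimate)
        assert swapped.ci95[0] == pytest.approx(1 / r.ci95[1])
        assert r.ci95[0] <= r.or_estimate <= r.ci95[1]

    @settings(max_examples=50, derandomize=True)
    @given(cells, cells, cells, cells, st.integers(2, 5))
    def test_or_invariant_under_row_scaling(self, a, b, c, d, k):
        r1 = odds_ratio(Contingency2x2(a, b, c, d))
        r2 = odds_ratio(Contingency2x2(a, b, k * c, k * d))
        assert r2.or_estimate == pytest.approx(r1.or_estimate)


class TestAdjustedLogistic:
    @staticmethod
    def _subjects_from_counts(counts: GenotypeCounts) -> pd.DataFrame:
        rows = []
        for group, triplet in ((0, counts.control), (1, counts.case)):
            for dosage, n in enumerate(triplet):
                rows += [{"group": group, "genotype": dosage}] * n
        return pd.DataFrame(rows)

    def test_unadjusted_fit_matches_cross_product(self):
        """A covariate-free logistic fit on the 2x2 dichotomy is saturated,
        so exp(beta) equals the cross-product odds ratio."""
        df = self._subjects_from_counts(COUNTS)
        fit = adjusted_logistic(df, "genotype", GeneticModel.RECESSIVE, covariates=())
        crude = odds_ratio(build_model_tables(COUNTS)[GeneticModel.RECESSIVE])
        assert fit.or_estimate == pytest.approx(crude.or_estimate, rel=1e-6)

    def test_all_case_input_rejected(self):
        df = pd.DataFrame({"group": [1, 1, 1], "genotype": [0, 1, 2]})
        with pytest.raises(ValueError, match="case and one control"):
            adjusted_logistic(df, "genotype", covariates=())

    def test_missing_genotypes_dropped(self):
        df = self._subjects_from_counts(COUNTS)
        df.loc[:10, "genotype"] = np.nan
        fit = adjusted_logistic(df, "genotype", GeneticModel.RECESSIVE, covariates=())
        assert math.isfinite(fit.or_estimate)

    def test_perfect_separation_flagged_not_raised(self):
        df = pd.DataFrame(
            {"group": [0] * 20 + [1] * 20,
             "genotype": [0] * 20 + [2] * 20}
        )
        fit = adjusted_logistic(df, "genotype", GeneticModel.RECESSIVE, covariates=())
        assert fit.separation

    def test_confounder_adjustment_removes_bias(self, rng):
        """With a covariate that drives both genotype and outcome, the
        adjusted OR recovers the planted conditional OR over replicates while
        the crude OR is biased upward."""
        true_or = 1.5
        n = 1200
        reps = 120
        log_adj, log_crude = [], []
        for _ in range(reps):
            z = rng.normal(size=n)
            g = (rng.random(n) < 1 / (1 + np.exp(-z))).astype(float) * 2
            logit = -0.8 + math.log(true_or) * (g == 2) + 1.2 * z
            y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
            df = pd.DataFrame({"group": y, "genotype": g, "z": z})
            adj = adjusted_logistic(df, "genotype", GeneticModel.RECESSIVE, covariates=("z",))
            crude = adjusted_logistic(df, "genotype", GeneticModel.RECESSIVE, covariates=())
            log_adj.append(math.log(adj.or_estimate))
            log_crude.append(math.log(crude.or_estimate))
        se_adj = np.std(log_adj, ddof=1) / math.sqrt(reps)
        assert abs(np.mean(log_adj) - math.log(true_or)) < 3 * se_adj
        se_crude = np.std(log_crude, ddof=1) / math.sqrt(reps)
        assert np.mean(log_crude) - math.log(true_or) > 3 * se_crude


class TestPower:
    FREQS = (0.181, 0.495, 0.324)

    def test_null_or_gives_alpha(self):
        spec = PowerSpec(n_case=841, n_control=846, target_or=1.0, alpha=0.05)
        assert power_genetic(spec, self.FREQS) == pytest.approx(0.05, abs=1e-9)

    def test_recessive_power_exceeds_half_at_published_design(self):
        spec = PowerSpec(n_case=841, n_control=846, target_or=1.5, alpha=0.05)
        assert power_genetic(spec, self.FREQS) > 0.50

    def test_monotone_in_n_and_effect(self):
        grid_n = [100, 300, 900]
        p_by_n = [
            power_genetic(PowerSpec(n, n, 1.5), self.FREQS) for n in grid_n
        ]
        assert p_by_n == sorted(p_by_n)
        grid_or = [1.1, 1.3, 1.6, 2.2]
        p_by_or = [
            power_genetic(PowerSpec(500, 500, o), self.FREQS) for o in grid_or
        ]
        assert p_by_or == sorted(p_by_or)
        # symmetric in ln OR
        up = power_genetic(PowerSpec(500, 500, 1.5), self.FREQS)
        down = power_genetic(PowerSpec(500, 500, 1 / 1.5), self.FREQS)
        assert up == pytest.approx(down, rel=0.15)

    def test_analytic_power_matches_simulation(self, rng):
        """Noncentral-χ² approximation agrees with a 2000-replicate
        simulation of the recessive test."""
        from scipy.stats import chi2_contingency

        spec = PowerSpec(n_case=400, n_control=400, target_or=1.5)
        analytic = power_genetic(spec, self.FREQS)
        reps = 2000
        hits = 0
        for _ in range(reps):
            counts = simulate_genotype_counts(400, 400, self.FREQS, 1.5, rng)
            t = build_model_tables(counts)[GeneticModel.RECESSIVE]
            table = np.array([[t.a, t.b], [t.c, t.d]])
            if table.min() >= 0 and (table.sum(0) > 0).all():
                _, p, _, _ = chi2_contingency(table, correction=False)
                hits += p < 0.05
        sim = hits / reps
        assert abs(sim - analytic) < 4 * math.sqrt(analytic * (1 - analytic) / reps)

    def test_degenerate_frequencies_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            power_genetic(PowerSpec(100, 100, 1.5), (0.5, 0.5, 0.0))

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            PowerSpec(100, 100, 1.5, alpha=1.5)


class TestGenotypeCountsFromSubjects:
    def test_round_trip_through_subject_table(self):
        df = TestAdjustedLogistic._subjects_from_counts(COUNTS)
        back = genotype_counts_from_subjects(df, "genotype", "rs9395890")
        assert back.control == RS9395890_CONTROL and back.case == RS9395890_CASE

    def test_empty_case_group_rejected(self):
        df = pd.DataFrame({"group": [0, 0], "genotype": [0, 1]})
        with pytest.raises(ValueError, match="empty case group"):
            genotype_counts_from_subjects(df, "genotype")
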