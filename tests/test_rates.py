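"""Rate estimation and treatment statistics against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from tema import (
    PeakCall,
    PresenceMatrix,
    SimulationConfig,
    ancova_rates,
    compare_treatments,
    expected_vs_observed_high_loss,
    germline_gain_rate,
    loss_rate_per_lineage,
    regress_somatic_vs_copy_number,
    run_experiment,
    somatic_gain_rate,
    somatic_rates_per_lineage,
    summarize_rates,
)
from conftest import score_cohort


def make_matrix(presence_rows, treatments):
    lineages = list(treatments)
    cols = list(range(100, 100 + len(presence_rows[0])))
    presence = pd.DataFrame(presence_rows, index=lineages, columns=cols, dtype=bool)
    return PresenceMatrix(presence=presence,
                          treatments=pd.Series(treatments))


class TestPerLineageRates:
    @pytest.mark.parametrize(
        "losses, gens, copies, expected",
        [(2, 40, 25, 0.002), (0, 40, 25, 0.0), (1, 40, 1, 0.025)],
    )
    def test_loss_rate(self, losses, gens, copies, expected):
        assert loss_rate_per_lineage(losses, gens, copies) == pytest.approx(expected)

    def test_loss_rate_zero_denominators_rejected(self):
        with pytest.raises(ValueError):
            loss_rate_per_lineage(1, 0, 25)
        with pytest.raises(ValueError):
            loss_rate_per_lineage(1, 40, 0)

    @pytest.mark.parametrize(
        "gains, copies, line_gens, expected",
        [(1, 3, 94 * 40, 1 / (3 * 94 * 40)), (0, 5, 100, 0.0), (2, 1, 100, 0.02)],
    )
    def test_germline_gain_rate(self, gains, copies, line_gens, expected):
        assert germline_gain_rate(gains, copies, line_gens) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "somatic, ancestral, expected", [(5, 25, 0.2), (0, 25, 0.0), (25, 25, 1.0)]
    )
    def test_somatic_gain_rate(self, somatic, ancestral, expected):
        assert somatic_gain_rate(somatic, ancestral) == pytest.approx(expected)

    def test_somatic_gain_rate_rejects_zero_ancestral(self):
        with pytest.raises(ValueError):
            somatic_gain_rate(1, 0)


class TestSummarizeRates:
    def test_hand_built_matrix_matches_spreadsheet_arithmetic(self):
        # 4 lineages x 5 loci; losses: S1=2, S2=0, A1=1, A2=1
        m = make_matrix(
            [
                [False, False, True, True, True],
                [True, True, True, True, True],
                [True, False, True, True, True],
                [True, True, True, False, True],
            ],
            {"S1": "sexual", "S2": "sexual", "A1": "asexual", "A2": "asexual"},
        )
        gens = {"S1": 10, "S2": 20, "A1": 10, "A2": 20}
        out = summarize_rates(m, gens, family_id="toy")
        r_s = [2 / (10 * 5), 0 / (20 * 5)]
        r_a = [1 / (10 * 5), 1 / (20 * 5)]
        assert out["sexual"].per_lineage_rates == pytest.approx(r_s)
        assert out["asexual"].per_lineage_rates == pytest.approx(r_a)
        assert out["sexual"].mean_rate == pytest.approx(np.mean(r_s))
        assert out["sexual"].se_rate == pytest.approx(np.std(r_s, ddof=1) / np.sqrt(2))
        assert out["asexual"].n_high_loss_loci == 0

    def test_all_present_matrix_gives_zero_rates(self):
        m = make_matrix(
            [[True] * 3] * 4,
            {"S1": "sexual", "S2": "sexual", "A1": "asexual", "A2": "asexual"},
        )
        out = summarize_rates(m, dict.fromkeys(m.presence.index, 40))
        for s in out.values():
            assert s.mean_rate == 0.0 and s.se_rate == 0.0

    def test_missing_treatment_is_an_error(self):
        m = make_matrix([[True], [True]], {"S1": "sexual", "S2": "sexual"})
        with pytest.raises(ValueError, match="asexual"):
            summarize_rates(m, {"S1": 40, "S2": 40})


class TestCompareTreatments:
    def test_identical_samples(self):
        res = compare_treatments([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res.t_statistic == 0.0
        assert res.p_value == pytest.approx(0.5)
        assert res.direction == "none"

    def test_pooled_one_tailed_matches_closed_form(self):
        sexual, asexual = [0.2, 0.3, 0.4], [0.0, 0.1, 0.2]
        res = compare_treatments(sexual, asexual)
        # Closed-form pooled-variance oracle.
        n1, n2 = 3, 3
        v1, v2 = np.var(sexual, ddof=1), np.var(asexual, ddof=1)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        t = (np.mean(sexual) - np.mean(asexual)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p = sps.t.sf(t, n1 + n2 - 2)
        assert res.t_statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        assert res.df == n1 + n2 - 2
        assert res.direction == "sexual_greater"

    def test_welch_two_tailed_matches_closed_form(self):
        a, b = [0.5, 0.7, 0.9, 1.1], [0.1, 0.2]
        res = compare_treatments(a, b, variant="welch", tails=2)
        v1, v2 = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
        t = (np.mean(a) - np.mean(b)) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (len(a) - 1) + v2**2 / (len(b) - 1))
        p = 2 * sps.t.sf(abs(t), df)
        assert res.t_statistic == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_short_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_treatments([0.1], [0.1, 0.2])

    def test_sexual_excess_detected_across_cohorts(self):
        """With segregation as the only loss mechanism, the one-tailed test
        flags sexual > asexual in every replicate cohort at default sizes."""
        significant = 0
        for rep in range(20):
            cfg = SimulationConfig(generations_mean=4, n_ancestral_loci=10,
                                   fraction_heterozygous=0.3, excision_rate=0,
                                   germline_transposition_rate=0, somatic_rate=0,
                                   seed=3000 + rep)
            lines = run_experiment(cfg)
            m = score_cohort(lines, cfg)
            out = summarize_rates(m, {l.lineage_id: l.generations for l in lines})
            res = compare_treatments(out["sexual"].per_lineage_rates,
                                     out["asexual"].per_lineage_rates)
            significant += (res.p_value < 0.05 and res.direction == "sexual_greater")
        assert significant == 20


class TestRegression:
    def test_collinear_points(self):
        pts = [(10, 1.0), (20, 2.0), (30, 3.0)]
        res = regress_somatic_vs_copy_number(pts)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(0.1)

    def test_constant_response(self):
        res = regress_somatic_vs_copy_number([(10, 0.5), (20, 0.5), (30, 0.5)])
        assert res.r_squared == 0.0 and res.slope == 0.0
        assert res.f_statistic == 0.0 and res.p_value == 1.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        x = np.array([3.0, 7.0, 25.0, 60.0, 130.0, 340.0])
        y = 0.9 - 0.002 * x + rng.normal(0, 0.05, size=6)
        res = regress_somatic_vs_copy_number(list(zip(x, y)))
        X = np.column_stack([np.ones(6), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        ss_res = resid @ resid
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1 - ss_res / ss_tot
        f = (ss_tot - ss_res) / 1 / (ss_res / 4)
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        assert res.slope == pytest.approx(beta[1], abs=1e-10)
        assert res.r_squared == pytest.approx(r2, abs=1e-10)
        assert res.f_statistic == pytest.approx(f, abs=1e-10)
        assert res.p_value == pytest.approx(sps.f.sf(f, 1, 4), abs=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            regress_somatic_vs_copy_number([(1, 0.1), (2, 0.2)])


def toy_ancova_table():
    rng = np.random.default_rng(11)
    rows = []
    for family, cn in [("f1", 5), ("f2", 50), ("f3", 200)]:
        for treatment, shift in [("sexual", 5e-4), ("asexual", 0.0)]:
            for _ in range(2):
                rows.append(
                    {
                        "family": family,
                        "treatment": treatment,
                        "copy_number": cn,
                        "rate": shift + 1e-6 * cn + rng.normal(0, 1e-4),
                    }
                )
    return pd.DataFrame(rows)


class TestAncova:
    def test_matches_general_linear_model_oracle(self):
        data = toy_ancova_table()
        out = ancova_rates(data)

        y = data["rate"].to_numpy()
        t = (data["treatment"] == "sexual").astype(float).to_numpy()
        c = data["copy_number"].to_numpy(dtype=float)
        ones = np.ones(len(y))

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return r @ r

        full = np.column_stack([ones, t, c])
        rss_full = rss(full)
        df_resid = len(y) - 3
        for term, reduced in [
            ("C(treatment)", np.column_stack([ones, c])),
            ("copy_number", np.column_stack([ones, t])),
        ]:
            f = (rss(reduced) - rss_full) / (rss_full / df_resid)
            assert out.loc[term, "F"] == pytest.approx(f, abs=1e-10)
            assert out.loc[term, "p"] == pytest.approx(
                sps.f.sf(f, 1, df_resid), abs=1e-10
            )

    def test_constant_rates_yield_null_effects(self):
        data = toy_ancova_table()
        data["rate"] = 1e-4
        out = ancova_rates(data)
        assert (out["F"] == 0.0).all() and (out["p"] == 1.0).all()

    def test_single_treatment_is_rank_deficient(self):
        data = toy_ancova_table()
        data = data[data["treatment"] == "sexual"]
        with pytest.raises(ValueError, match="rank-deficient"):
            ancova_rates(data)

    def test_treatment_effect_detected_in_simulated_cohorts(self):
        """A segregation-driven treatment effect across three families is
        picked up by the ANCOVA treatment term in nearly every cohort."""
        hits = 0
        n_cohorts = 10
        for rep in range(n_cohorts):
            rows = []
            for fam, (n_loci, cn) in {"f1": (8, 8), "f2": (15, 15), "f3": (25, 25)}.items():
                cfg = SimulationConfig(
                    n_sexual=20, n_asexual=20, generations_mean=4,
                    n_ancestral_loci=n_loci, fraction_heterozygous=0.3,
                    excision_rate=0, germline_transposition_rate=0,
                    somatic_rate=0, seed=rep * 100 + cn,
                )
                lines = run_experiment(cfg)
                m = score_cohort(lines, cfg)
                losses = m.losses_per_lineage()
                for line in lines:
                    rows.append({
                        "family": fam,
                        "treatment": line.treatment,
                        "copy_number": cn,
                        "rate": losses[line.lineage_id] / (line.generations * n_loci),
                    })
            out = ancova_rates(pd.DataFrame(rows))
            hits += out.loc["C(treatment)", "p"] < 0.05
        assert hits >= int(0.9 * n_cohorts)


class TestExpectedVsObserved:
    def test_expected_counts(self):
        presence = [[True, False]] * 5 + [[False, True]] * 40 + [[True, True]] * 4
        treatments = {f"S{i}": "sexual" for i in range(45)}
        treatments.update({f"A{i}": "asexual" for i in range(4)})
        m = make_matrix(presence, treatments)
        out = expected_vs_observed_high_loss(m, n_selfing_bouts=1)
        out = out.set_index("locus")
        # 45 sexual lines, one bout: 11.25 expected at each high-loss locus.
        assert out["expected"].tolist() == pytest.approx([11.25, 11.25])
        assert out.loc[100, "observed"] == 40 and out.loc[100, "excess"]
        assert out.loc[101, "observed"] == 5 and not out.loc[101, "excess"]

    def test_no_sexual_lineages_gives_zero_expectation(self):
        m = make_matrix([[False, True]] * 4, {f"A{i}": "asexual" for i in range(4)})
        out = expected_vs_observed_high_loss(m, high_loss_loci={100})
        assert out["expected"].tolist() == [0.0]

    def test_two_bout_expectation_uses_chain(self):
        m = make_matrix([[False]] * 8, {f"S{i}": "sexual" for i in range(8)})
        out = expected_vs_observed_high_loss(m, high_loss_loci={100}, n_selfing_bouts=2)
        assert out["expected"].tolist() == pytest.approx([8 * 0.375])


def test_somatic_rates_per_lineage():
    m = make_matrix([[True, True], [True, False]], {"L1": "sexual", "L2": "asexual"})
    m.new_calls = [
        PeakCall("L1", 500, "somatic", 1),
        PeakCall("L1", 510, "somatic", 2),
        PeakCall("L2", 600, "germline_gain", 3),
    ]
    rates = somatic_rates_per_lineage(m)
    assert rates["L1"] == pytest.approx(2 / 2)
    assert rates["L2"] == pytest.approx(0 / 1)
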