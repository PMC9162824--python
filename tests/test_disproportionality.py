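"""The four disproportionality algorithms, their criteria and the screen."""

import math

import numpy as np
import pytest
import scipy.stats
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal.case_selection import enumerate_pairs
from pvsignal.datasets import TOP10_SIGNAL_ROWS
from pvsignal.disproportionality import (
    ContingencyTable,
    SignalCriteria,
    SignalStatistics,
    build_contingency,
    compute_ebgm,
    compute_ic,
    compute_prr_chi2,
    compute_ror,
    compute_statistics,
    evaluate_criteria,
    format_estimate,
    screen_all_pairs,
)

T_REF = ContingencyTable(20, 80, 100, 9800)
T_NULL = ContingencyTable(10, 10, 10, 10)


class TestPointEstimates:
    def test_ror_closed_form(self):
        ror, lo, hi = compute_ror(T_REF)
        assert ror == pytest.approx(24.5)
        assert lo == pytest.approx(14.45, abs=0.01)
        assert hi == pytest.approx(41.55, abs=0.01)

    def test_ror_independent_oracle(self):
        """statsmodels' 2x2 odds-ratio routine agrees with our ROR and CI."""
        table = sm.stats.Table2x2(
            np.array([[T_REF.a, T_REF.b], [T_REF.c, T_REF.d]]), shift_zeros=False
        )
        ror, lo, hi = compute_ror(T_REF)
        assert ror == pytest.approx(table.oddsratio, rel=1e-12)
        # we use the conventional z = 1.96; statsmodels uses norm.ppf(0.975)
        sm_lo, sm_hi = table.oddsratio_confint(0.05)
        assert lo == pytest.approx(sm_lo, rel=1e-4)
        assert hi == pytest.approx(sm_hi, rel=1e-4)

    def test_prr_and_four_cell_chi2(self):
        prr, _lo, _hi, chi2 = compute_prr_chi2(T_REF)
        assert prr == pytest.approx(19.8)
        oracle_chi2 = scipy.stats.chi2_contingency(
            [[T_REF.a, T_REF.b], [T_REF.c, T_REF.d]], correction=False
        ).statistic
        assert chi2 == pytest.approx(oracle_chi2, rel=1e-12)
        assert chi2 == pytest.approx(301.1, abs=0.1)

    def test_ic_closed_form(self):
        ic, ic_low = compute_ic(T_REF)
        assert ic == pytest.approx(math.log2(20 * 10000 / (120 * 100)), rel=1e-12)
        assert ic == pytest.approx(4.059, abs=1e-3)
        sd = math.sqrt(1 / 20 + 1 / 80 + 1 / 100 + 1 / 9800) / math.log(2)
        assert ic_low == pytest.approx(ic - 2 * sd, rel=1e-12)
        assert ic_low == pytest.approx(3.281, abs=1e-3)

    def test_ebgm_closed_form(self):
        ebgm, ebgm05 = compute_ebgm(T_REF)
        assert ebgm == pytest.approx(16.667, abs=1e-3)
        se = math.sqrt(1 / 20 + 1 / 80 + 1 / 100 + 1 / 9800)
        assert ebgm05 == pytest.approx(math.exp(math.log(ebgm) - 1.645 * se), rel=1e-12)
        assert ebgm05 == pytest.approx(10.70, abs=0.01)

    def test_independence_table_is_exactly_null(self):
        assert compute_ror(T_NULL)[0] == 1.0
        prr, _l, _h, chi2 = compute_prr_chi2(T_NULL)
        assert prr == 1.0 and chi2 == 0.0
        assert compute_ic(T_NULL)[0] == 0.0
        assert compute_ebgm(T_NULL)[0] == 1.0
        # ad = bc in a non-symmetric table too
        t = ContingencyTable(5, 10, 50, 100)
        assert compute_ic(t)[0] == 0.0

    def test_zero_cell_marks_statistics_undefined(self):
        stats = compute_statistics(ContingencyTable(5, 0, 3, 7))
        assert stats.undefined_reason == "zero cell"
        assert stats.ror is None
        assert evaluate_criteria(stats).flag_ror is False

    def test_haldane_correction_restores_estimates(self):
        stats = compute_statistics(ContingencyTable(5, 0, 3, 7), use_haldane=True)
        assert stats.ror is not None and stats.undefined_reason is None


class TestProperties:
    @settings(max_examples=200, derandomize=True)
    @given(st.tuples(*[st.integers(min_value=1, max_value=50)] * 4))
    def test_independence_identity(self, quad):
        """ad = bc forces ror = prr = ebgm = 1 and ic = 0 exactly."""
        i, j, k, l = quad
        t = ContingencyTable(i * j, i * k, l * j, l * k)  # ad = bc by construction
        assert compute_ror(t)[0] == pytest.approx(1.0, abs=1e-12)
        assert compute_prr_chi2(t)[0] == pytest.approx(1.0, abs=1e-12)
        assert compute_ic(t)[0] == pytest.approx(0.0, abs=1e-12)
        assert compute_ebgm(t)[0] == pytest.approx(1.0, abs=1e-12)

    def test_ordering_ror_ge_prr_ge_ebgm(self):
        """On 1000 random tables with ad >= bc: ror >= prr >= ebgm."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 1000:
            a, b, c, d = rng.integers(1, 500, size=4)
            if a * d < b * c:
                b, c = c, b  # mirror into the ad >= bc half
                if a * d < b * c:
                    continue
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            ror = compute_ror(t)[0]
            prr = compute_prr_chi2(t)[0]
            ebgm = compute_ebgm(t)[0]
            assert ror >= prr - 1e-12 >= ebgm - 2e-12
            if a * d > b * c:
                assert ror > prr > ebgm
            checked += 1

    def test_ebgm_equals_two_to_the_ic(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a, b, c, d = rng.integers(1, 300, size=4)
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            assert compute_ebgm(t)[0] == pytest.approx(2 ** compute_ic(t)[0], rel=1e-12)

    def test_ror_monotonicity(self):
        base = ContingencyTable(10, 20, 30, 40)
        ror = compute_ror(base)[0]
        assert compute_ror(ContingencyTable(11, 20, 30, 40))[0] > ror
        assert compute_ror(ContingencyTable(10, 20, 30, 41))[0] > ror
        assert compute_ror(ContingencyTable(10, 21, 30, 40))[0] < ror
        assert compute_ror(ContingencyTable(10, 20, 31, 40))[0] < ror

    def test_all_statistics_match_brute_force_oracle(self):
        """1e-9 relative agreement with independent formulas on 1000 tables."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            a, b, c, d = (int(x) for x in rng.integers(1, 200, size=4))
            t = ContingencyTable(a, b, c, d)
            n = a + b + c + d
            se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            assert compute_ror(t)[0] == pytest.approx(a * d / (b * c), rel=1e-9)
            prr, lo, hi, chi2 = compute_prr_chi2(t)
            assert prr == pytest.approx(a * (c + d) / (c * (a + b)), rel=1e-9)
            exp_chi2 = sum(
                (o - e) ** 2 / e
                for o, e in [
                    (a, (a + b) * (a + c) / n),
                    (b, (a + b) * (b + d) / n),
                    (c, (c + d) * (a + c) / n),
                    (d, (c + d) * (b + d) / n),
                ]
            )
            assert chi2 == pytest.approx(exp_chi2, rel=1e-9)
            ic, ic_low = compute_ic(t)
            assert ic == pytest.approx(math.log2(a * n / ((a + c) * (a + b))), rel=1e-9, abs=1e-9)
            assert ic_low == pytest.approx(ic - 2 * se / math.log(2), rel=1e-9, abs=1e-9)
            ebgm, ebgm05 = compute_ebgm(t)
            assert ebgm == pytest.approx(a * n / ((a + b) * (a + c)), rel=1e-9)
            assert ebgm05 == pytest.approx(math.exp(math.log(ebgm) - 1.645 * se), rel=1e-9)

    def test_ror_ci_null_coverage(self):
        """95% CI covers the true OR=1 in 90-99% of 400 null replicates."""
        rng = np.random.default_rng(2024)
        covered = trials = 0
        while trials < 400:
            a = rng.binomial(500, 0.1)
            c = rng.binomial(5000, 0.1)
            t = ContingencyTable(a, 500 - a, c, 5000 - c)
            if min(t.a, t.b, t.c, t.d) == 0:
                continue
            _ror, lo, hi = compute_ror(t)
            covered += lo <= 1.0 <= hi
            trials += 1
        assert 0.90 <= covered / trials <= 0.99

    def test_prr_criterion_false_positive_rate_under_null(self):
        """The PRR flag fires on <= 5% of truly null pairs."""
        rng = np.random.default_rng(99)
        flagged = 0
        n_pairs = 400
        for _ in range(n_pairs):
            a = rng.binomial(500, 0.05)
            c = rng.binomial(5000, 0.05)
            t = ContingencyTable(a, 500 - a, c, 5000 - c)
            stats = evaluate_criteria(compute_statistics(t), t)
            flagged += stats.flag_prr
        assert flagged / n_pairs <= 0.05


class TestCriteria:
    def _stats(self, ror, ci_low, prr, chi2, ic_low, ebgm05, a):
        return SignalStatistics(
            ror=ror, ror_ci_low=ci_low, ror_ci_high=ci_low * 3,
            prr=prr, chi2=chi2, ic=ic_low + 0.5, ic_low=ic_low,
            ebgm=ebgm05 * 1.3, ebgm05=ebgm05, a=a,
        )

    def test_ror_and_bcpnn_flag_without_prr_or_mgps(self):
        # published "Dyspnoea at rest" row: PRR misses chi2>=4, MGPS misses 2
        s = evaluate_criteria(
            self._stats(ror=1.78, ci_low=1.03, prr=1.78, chi2=3.69,
                        ic_low=0.69, ebgm05=1.32, a=13)
        )
        assert (s.flag_ror, s.flag_prr, s.flag_bcpnn, s.flag_mgps) == (
            True, False, True, False,
        )
        assert s.signal

    def test_prr_fails_on_magnitude_despite_chi2(self):
        # published "Duodenal ulcer" (thrombosis) row: prr < 2 but chi2 >= 4
        s = evaluate_criteria(
            self._stats(ror=1.48, ci_low=1.04, prr=1.48, chi2=4.26,
                        ic_low=0.5, ebgm05=1.18, a=31)
        )
        assert s.flag_ror and not s.flag_prr and s.signal

    def test_minimum_case_count_gate(self):
        strong = dict(ror=5.0, ci_low=0.9, prr=5.0, chi2=25.0, ic_low=-0.1, ebgm05=1.0)
        assert evaluate_criteria(self._stats(**strong, a=3)).flag_prr
        assert not evaluate_criteria(self._stats(**strong, a=2)).flag_prr

    def test_all_null_statistics_do_not_signal(self):
        s = evaluate_criteria(
            self._stats(ror=1.0, ci_low=0.8, prr=1.0, chi2=0.0,
                        ic_low=-0.1, ebgm05=1.0, a=50)
        )
        assert not s.signal

    def test_every_published_top10_row_signals(self):
        for row in TOP10_SIGNAL_ROWS:
            (_pt, _ind, n, ror, lo, hi, prr, plo, phi, chi2, ic, ic_low,
             ebgm, ebgm05) = row
            s = SignalStatistics(
                ror=ror, ror_ci_low=lo, ror_ci_high=hi, prr=prr,
                prr_ci_low=plo, prr_ci_high=phi, chi2=chi2, ic=ic,
                ic_low=ic_low, ebgm=ebgm, ebgm05=ebgm05, a=n,
            )
            assert evaluate_criteria(s).signal, row[0]


class TestScreen:
    def test_contingency_cells_match_brute_force(self, small_cohort, small_clean):
        reactions_by_case = {}
        for r in small_clean.db.reactions:
            reactions_by_case.setdefault(r.primary_id, set()).add(r.preferred_term)
        all_cases = small_clean.case_ids
        for indication, pt, a in enumerate_pairs(small_cohort):
            t = build_contingency((indication, pt), small_cohort, small_clean)
            stratum = small_cohort.stratum_cases(indication)
            brute_a = sum(1 for pid in stratum if pt in reactions_by_case.get(pid, ()))
            brute_c = sum(
                1
                for pid in all_cases - stratum
                if pt in reactions_by_case.get(pid, ())
            )
            assert (t.a, t.c) == (brute_a, brute_c)
            assert t.n == small_clean.n_cases
            assert t.a + t.b == len(stratum)

    def test_pair_not_in_cohort_is_rejected(self, small_cohort, small_clean):
        with pytest.raises(ValueError):
            build_contingency(("Prophylaxis (NEC)", "No Such PT"), small_cohort, small_clean)

    def test_empty_cohort_gives_empty_table(self, small_clean):
        from pvsignal.case_selection import Cohort

        empty = Cohort(target_drug="aspirin", db=small_clean, strata={})
        frame = screen_all_pairs(empty, small_clean)
        assert len(frame) == 0

    def test_rounding_formatter(self):
        assert format_estimate(1.5499, 1.284, 1.889) == "1.55 (1.28, 1.89)"

    def test_screen_ranks_by_n_with_alphabetical_ties(self, small_cohort, small_clean):
        frame = screen_all_pairs(small_cohort, small_clean, signals_only=False)
        n = frame["n"].to_numpy()
        assert (n[:-1] >= n[1:]).all()
        for _value, group in frame.groupby("n"):
            assert list(group["reaction"]) == sorted(group["reaction"])

    def test_injected_signal_recovered_and_null_fpr_controlled(self):
        """One lambda=5 pair in 20k reports is flagged; PRR flags <= 5% of nulls."""
        import dataclasses

        from pvsignal.case_selection import select_cohort
        from pvsignal.cleaning import deduplicate
        from pvsignal.synthetic import default_paper_config, generate_database

        base = default_paper_config(seed=7, n_reports=20_000)
        vocab = [("Melaena", "Gastrointestinal disorders", 0.01)] + [
            e for e in base.event_vocabulary if e[0] != "Melaena"
        ]
        cfg = dataclasses.replace(
            base,
            event_vocabulary=vocab,
            injected_signals=[("Prophylaxis (NEC)", "Melaena", 5.0)],
        )
        db, _truth = generate_database(cfg)
        clean = deduplicate(db)
        cohort = select_cohort(clean, "aspirin")
        frame = screen_all_pairs(cohort, clean, signals_only=False)
        hit = frame[
            (frame["reaction"] == "Melaena")
            & (frame["indication"] == "Prophylaxis (NEC)")
        ]
        assert len(hit) == 1 and bool(hit["signal"].iloc[0])
        nulls = frame[
            ~((frame["reaction"] == "Melaena") & (frame["indication"] == "Prophylaxis (NEC)"))
        ]
        assert len(nulls) >= 200
        assert nulls["flag_prr"].mean() <= 0.05
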