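"""NCA and the fold-error / GMFE qualification arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import doxpbpk as d
from doxpbpk.errors import EvaluationError, NCAError
from doxpbpk.evaluation import (
    evaluation_table,
    format_evaluation_table,
    round_half_up,
)


def _profile(times, conc, name="x"):
    return d.ConcentrationTimeProfile(name, np.asarray(times), np.asarray(conc))


class TestNCA:
    def test_monoexponential_auc_matches_c0_over_k(self):
        t = np.arange(0.0, 48.25, 0.25)
        c0, k = 100.0, 0.2
        m = d.nca(_profile(t, c0 * np.exp(-k * t)))
        assert m.auc_inf == pytest.approx(c0 / k, rel=0.01)
        assert m.lambda_z == pytest.approx(k, rel=0.01)
        assert m.cmax == c0 and m.tmax == 0.0

    def test_bateman_auc_matches_dose_over_clearance(self):
        """For first-order absorption with complete bioavailability,
        AUC_inf = Dose / CL regardless of ka."""
        dose, vol, cl, ka = 1.0e5, 50.0, 0.6 * 50.0, 3.0  # CL in L/h
        ke = cl / vol
        t = np.arange(0.1, 36.1, 0.1)
        conc = dose * ka / (vol * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))
        m = d.nca(_profile(t, conc))
        assert m.auc_inf == pytest.approx(dose / cl, rel=0.01)

    def test_too_few_points_rejected(self):
        with pytest.raises(NCAError):
            d.nca(_profile([0.0, 1.0], [1.0, 0.5]))

    def test_all_zero_profile_rejected(self):
        with pytest.raises(NCAError):
            d.nca(_profile([0.0, 1.0, 2.0], [0.0, 0.0, 0.0]))

    def test_high_extrapolation_is_flagged(self):
        t = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
        m = d.nca(_profile(t, 100.0 * np.exp(-0.05 * t)))
        assert m.extrapolated_fraction > 0.2
        assert "high-extrapolation" in m.flags


class TestFoldError:
    @pytest.mark.parametrize(
        "predicted, observed, printed",
        [(709.02, 692.47, 1.02), (4640.32, 1820.00, 2.55)],
    )
    def test_printed_rows(self, predicted, observed, printed):
        assert round_half_up(d.fold_error(predicted, observed), 2) == printed

    def test_identity(self):
        assert d.fold_error(3.7, 3.7) == 1.0

    @given(a=st.floats(0.01, 100), x=st.floats(0.01, 1e4))
    @settings(max_examples=40, derandomize=True)
    def test_multiplicative(self, a, x):
        assert d.fold_error(a * x, x) == pytest.approx(a, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(EvaluationError):
            d.fold_error(0.0, 1.0)


class TestGMFE:
    @staticmethod
    def _pairs(values):
        return [
            d.EvaluationPair("s", "c", "g", "AUC", observed=o, predicted=p)
            for o, p in values
        ]

    def test_genotyped_parent_auc_pairs_give_1_13(self):
        frame = d.load_observed_predicted()
        sel = frame[
            (frame.compound == "doxepin")
            & (frame.metric == "AUC")
            & (frame.cyp2d6 != "non-genotyped")
        ]
        assert len(sel) == 4
        assert round_half_up(d.gmfe(d.pairs_from_frame(sel)), 2) == 1.13

    def test_perfect_predictions_give_unity(self):
        assert d.gmfe(self._pairs([(1.0, 1.0), (5.0, 5.0)])) == 1.0

    def test_symmetric_twofold_errors_give_two(self):
        assert d.gmfe(self._pairs([(1.0, 2.0), (2.0, 1.0)])) == pytest.approx(2.0)

    def test_empty_rejected(self):
        with pytest.raises(EvaluationError):
            d.gmfe([])

    @given(
        st.lists(
            st.tuples(st.floats(0.1, 100), st.floats(0.1, 100)), min_size=1, max_size=8
        )
    )
    @settings(max_examples=40, derandomize=True)
    def test_gmfe_at_least_one_and_swap_invariant(self, values):
        pairs = self._pairs(values)
        swapped = self._pairs([(p, o) for o, p in values])
        g = d.gmfe(pairs)
        assert g >= 1.0
        assert g == pytest.approx(d.gmfe(swapped), rel=1e-12)


class TestCoverage:
    def test_direct_count(self):
        assert d.coverage_fraction([1.0, 1.2, 3.0], 2.0) == pytest.approx(2 / 3)

    def test_huge_bound_covers_everything(self):
        assert d.coverage_fraction([0.1, 1.0, 9.0], 1e9) == 1.0

    def test_genotyped_parent_auc_within_twofold(self):
        assert d.coverage_fraction([1.27, 1.11, 1.01, 1.15], 2.0) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(EvaluationError):
            d.coverage_fraction([], 2.0)


#: every printed fold-error cell: (compound, group, metric) -> value
PRINTED_FOLD_ERRORS = {
    ("doxepin", "non-genotyped", "AUC"): 1.02,
    ("doxepin", "non-genotyped", "Cmax"): 0.98,
    ("doxepin", "non-genotyped", "Tmax"): 0.71,
    ("doxepin", "NM", "AUC"): 1.27,
    ("doxepin", "NM", "Cmax"): 1.26,
    ("doxepin", "IM", "AUC"): 1.11,
    ("doxepin", "IM", "Cmax"): 0.97,
    ("doxepin", "PM", "AUC"): 1.01,
    ("doxepin", "PM", "Cmax"): 0.79,
    ("doxepin", "UM", "AUC"): 1.15,
    ("doxepin", "UM", "Cmax"): 1.39,
    ("nordoxepin", "non-genotyped", "AUC"): 0.85,
    ("nordoxepin", "non-genotyped", "Cmax"): 1.02,
    ("nordoxepin", "non-genotyped", "Tmax"): 1.23,
    ("nordoxepin", "NM", "AUC"): 1.12,
    ("nordoxepin", "NM", "Cmax"): 0.77,
    ("nordoxepin", "IM", "AUC"): 1.31,
    ("nordoxepin", "IM", "Cmax"): 1.02,
    ("nordoxepin", "PM", "AUC"): 2.55,
    ("nordoxepin", "PM", "Cmax"): 1.18,
    ("nordoxepin", "UM", "AUC"): 1.71,
    ("nordoxepin", "UM", "Cmax"): 0.84,
}


def test_full_reference_table_fold_errors_reproduced():
    """Recomputing predicted/observed for every bundled row reproduces the
    printed fold error at two decimals (half-up)."""
    frame = d.load_observed_predicted()
    assert len(frame) == len(PRINTED_FOLD_ERRORS)
    for row in frame.itertuples(index=False):
        fe = round_half_up(d.fold_error(row.predicted, row.observed), 2)
        assert fe == PRINTED_FOLD_ERRORS[(row.compound, row.cyp2d6, row.metric)], row


class TestEvaluationTable:
    def test_reference_fixture_table(self):
        table = evaluation_table(d.pairs_from_frame(d.load_observed_predicted()))
        data_rows = table[table.label != "GMFE"]
        assert len(data_rows) == 22
        for row in data_rows.itertuples(index=False):
            key = (row.compound, row.genotype, row.metric)
            assert row.fold_error == PRINTED_FOLD_ERRORS[key]
        gmfe_rows = table[table.label == "GMFE"]
        assert set(gmfe_rows.metric) == {"AUC", "Cmax", "Tmax"}

    def test_empty_input_gives_header_only(self):
        table = evaluation_table([])
        assert table.empty and "fold_error" in table.columns
        assert format_evaluation_table(table).startswith("label")

    def test_single_metric_single_section(self):
        pairs = [d.EvaluationPair("s", "doxepin", "NM", "AUC", 2.0, 2.2)]
        table = evaluation_table(pairs)
        assert len(table) == 2  # one data row + one GMFE row
        assert format_evaluation_table(table)
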