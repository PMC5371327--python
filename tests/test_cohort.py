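"""Cohort table I/O, record validation, grader reconciliation, and ICC."""

import numpy as np
import pandas as pd
import pytest

import stargardt_endpoint as se
from stargardt_endpoint.cohort import (
    COHORT_COLUMNS,
    CohortValidationError,
    EyeVisitRecord,
    GraderPair,
)

HEADER = ",".join(COHORT_COLUMNS)


def _write(tmp_path, text, name="cohort.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadCohort:
    def test_snellen_and_areas_parse(self, tmp_path):
        p = _write(
            tmp_path,
            HEADER + "\nP9,OD,0.0,20/100,1.37,0.33,2.24,1.75\n",
        )
        table = se.read_cohort(p)
        rec = table.records[0]
        assert rec.bcva == pytest.approx(0.2)
        assert rec.qdaf_area == pytest.approx(1.37)
        assert rec.eye == "OD"

    def test_missing_cells_preserved(self, tmp_path):
        p = _write(tmp_path, HEADER + "\nP1,OS,0.0,0.5,,,,\n")
        rec = se.read_cohort(p).records[0]
        assert rec.bcva == 0.5
        assert rec.qdaf_area is None and rec.elm_loss is None

    def test_empty_file_rejected(self, tmp_path):
        p = _write(tmp_path, HEADER + "\n")
        with pytest.raises(CohortValidationError, match="no records"):
            se.read_cohort(p)

    def test_malformed_rows_reported_with_numbers(self, tmp_path):
        p = _write(
            tmp_path,
            HEADER
            + "\nP1,OD,0.0,0.5,1.0,,,\nP1,OD,1.0,counting fingers,1.2,,,\nP2,OX,0.0,0.5,,,,1.0\n",
        )
        with pytest.raises(CohortValidationError) as exc:
            se.read_cohort(p)
        assert "row 3" in str(exc.value) and "row 4" in str(exc.value)

    def test_duplicate_visit_rejected(self, tmp_path):
        p = _write(
            tmp_path,
            HEADER + "\nP1,OD,0.0,0.5,1.0,,,\nP1,OD,0.0,0.4,1.1,,,\n",
        )
        with pytest.raises(CohortValidationError, match="duplicate"):
            se.read_cohort(p)

    def test_eye_without_baseline_rejected(self, tmp_path):
        p = _write(tmp_path, HEADER + "\nP1,OD,1.5,0.5,1.0,,,\n")
        with pytest.raises(CohortValidationError, match="baseline"):
            se.read_cohort(p)

    def test_baseline_only_table_reads_but_cannot_fit(self, tmp_path):
        p = _write(
            tmp_path,
            HEADER + "\nP1,OD,0.0,0.5,1.0,,,\nP2,OD,0.0,0.4,2.0,,,\n",
        )
        table = se.read_cohort(p)
        ecc = se.standardize_cohort(table.to_frame())
        deltas = se.deltas_from_baseline(ecc)
        deltas["delta_c"] = se.composite_column(deltas, se.OPTIMAL_WEIGHTS)
        with pytest.raises(ValueError):
            se.fit_progression(deltas)

    def test_xlsx_with_column_map(self, tmp_path, dev_cohort):
        frame = dev_cohort.to_frame().rename(columns={"patient_id": "ID", "bcva": "VA"})
        p = tmp_path / "cohort.xlsx"
        frame.to_excel(p, index=False)
        table = se.read_cohort(p, column_map={"ID": "patient_id", "VA": "bcva"})
        assert len(table) == len(dev_cohort)


def test_round_trip_write_read_identity(tmp_path, dev_cohort):
    p = tmp_path / "out.csv"
    se.write_cohort(dev_cohort, p)
    back = se.read_cohort(p, cohort_label=dev_cohort.cohort_label)
    a, b = dev_cohort.to_frame(), back.to_frame()
    assert list(a["patient_id"]) == list(b["patient_id"])
    assert list(a["eye"]) == list(b["eye"])
    num = a.columns[2:]
    assert np.allclose(
        a[num].to_numpy(dtype=float), b[num].to_numpy(dtype=float),
        atol=1e-9, equal_nan=True,
    )


class TestRecordInvariants:
    def test_no_measurements_rejected(self):
        with pytest.raises(CohortValidationError, match="no measurements"):
            EyeVisitRecord("P1", "OD", 0.0)

    def test_negative_time_rejected(self):
        with pytest.raises(CohortValidationError):
            EyeVisitRecord("P1", "OD", -1.0, bcva=0.5)

    def test_nonpositive_acuity_rejected(self):
        with pytest.raises(CohortValidationError):
            EyeVisitRecord("P1", "OD", 0.0, bcva=0.0)


class TestReconcileGraders:
    def test_below_threshold_unflagged(self):
        means, flags = se.reconcile_graders([GraderPair("QDAF", 4.0, 4.2)])
        assert means[0] == pytest.approx(4.1)
        assert not flags[0]

    def test_above_threshold_flagged(self):
        means, flags = se.reconcile_graders([GraderPair("DDAF", 4.0, 5.5)])
        assert means[0] == pytest.approx(4.75)
        assert flags[0]

    def test_identity_and_symmetry(self):
        m1, _ = se.reconcile_graders([GraderPair("EZ", 3.3, 3.3)])
        assert m1[0] == 3.3
        ma, _ = se.reconcile_graders([GraderPair("ELM", 2.0, 5.0)])
        mb, _ = se.reconcile_graders([GraderPair("ELM", 5.0, 2.0)])
        assert ma[0] == mb[0]

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            GraderPair("QDAF", -1.0, 2.0)


def _icc2_anova(a, b):
    """Two-way absolute-agreement single-rater ICC by explicit ANOVA sums
    of squares (the independent oracle)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n, k = a.size, 2
    data = np.column_stack([a, b])
    grand = data.mean()
    msr = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sst = ((data - grand) ** 2).sum()
    sse = sst - (msr * (n - 1) + msc * (k - 1))
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


FIXTURE_A = [1.2, 3.4, 2.2, 5.1, 4.0]
FIXTURE_B = [1.5, 3.1, 2.6, 4.7, 4.4]


class TestAgreementStats:
    def _pairs(self, a, b):
        return [GraderPair("QDAF", x, y) for x, y in zip(a, b)]

    def test_perfect_agreement(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        res = se.agreement_stats(self._pairs(vals, vals))
        assert res.mean_abs_diff == 0.0
        assert res.icc == pytest.approx(1.0, abs=1e-9)

    def test_icc_matches_manual_anova_on_fixture(self):
        res = se.agreement_stats(self._pairs(FIXTURE_A, FIXTURE_B))
        assert res.icc == pytest.approx(_icc2_anova(FIXTURE_A, FIXTURE_B), abs=1e-9)
        diffs = np.abs(np.array(FIXTURE_A) - np.array(FIXTURE_B))
        assert res.mean_abs_diff == pytest.approx(diffs.mean())
        assert res.sd_abs_diff == pytest.approx(diffs.std(ddof=1))

    def test_shuffled_grader_near_zero_icc(self):
        rng = np.random.default_rng(42)
        a = rng.uniform(0, 10, size=10)
        b = rng.permutation(rng.uniform(0, 10, size=10))
        res = se.agreement_stats([GraderPair("ELM", x, y) for x, y in zip(a, b)])
        assert res.icc == pytest.approx(_icc2_anova(a, b), abs=1e-9)
        assert abs(res.icc) < 0.5

    def test_shift_invariance_and_bounds(self):
        base = se.agreement_stats(self._pairs(FIXTURE_A, FIXTURE_B))
        shifted = se.agreement_stats(
            self._pairs([x + 7 for x in FIXTURE_A], [x + 7 for x in FIXTURE_B])
        )
        assert shifted.icc == pytest.approx(base.icc, abs=1e-9)
        assert -1.0 <= base.icc <= 1.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            se.agreement_stats(self._pairs([1, 2], [1, 2]))

    def test_zero_variance_signalled(self):
        with pytest.raises(ValueError, match="zero total variance"):
            se.agreement_stats(self._pairs([2.0] * 4, [2.0] * 4))

    def test_consistency_form_differs_when_raters_biased(self):
        biased_b = [x + 0.5 for x in FIXTURE_A]
        abs_res = se.agreement_stats(self._pairs(FIXTURE_A, biased_b))
        con_res = se.agreement_stats(self._pairs(FIXTURE_A, biased_b), form="consistency")
        assert con_res.icc > abs_res.icc  # constant offset penalized only by absolute form


def test_read_grader_pairs(tmp_path):
    p = tmp_path / "graders.csv"
    p.write_text("label,value_a_deg,value_b_deg\nQDAF,4.0,4.2\nELM,2.0,2.1\n")
    pairs = se.read_grader_pairs(p)
    assert len(pairs) == 2 and pairs[0].label == "QDAF"
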