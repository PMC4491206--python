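"""PPV cells, exact binomial intervals, agreement and Cohen's kappa."""

import random

import numpy as np
import pytest
from scipy import stats

from pedopitox.adjudication_engine import GROUP1, GROUP2, GROUP3, AdjudicationResult
from pedopitox.case_screening import PotentialCase, RiskWindow
from pedopitox.validation_stats import (
    ValidationError,
    build_report,
    cohens_kappa,
    kappa_from_agreement,
    ppv,
)
from datetime import date, timedelta


@pytest.mark.parametrize(
    "confirmed,total,expected",
    [(85, 168, 50.6), (15, 30, 50.0), (25, 31, 80.6), (33, 58, 56.9),
     (12, 47, 25.5), (0, 2, 0.0), (9, 32, 28.1), (3, 15, 20.0),
     (69, 121, 57.0), (16, 47, 34.0), (5, 5, 100.0)],
)
def test_ppv_point_estimates(confirmed, total, expected):
    cell = ppv(confirmed, total)
    assert cell.ppv_percent == pytest.approx(expected, abs=0.05)


def test_ppv_boundaries_and_exact_interval():
    cell = ppv(5, 5)
    assert cell.ppv_percent == 100.0
    assert cell.ci95[1] == 100.0
    zero = ppv(0, 2)
    assert zero.ci95[0] == 0.0


def test_clopper_pearson_matches_beta_quantiles():
    """Independent closed form: CP bounds are beta-distribution quantiles."""
    for k, n in [(85, 168), (1, 10), (9, 32), (0, 7), (7, 7)]:
        cell = ppv(k, n)
        lo = 0.0 if k == 0 else stats.beta.ppf(0.025, k, n - k + 1)
        hi = 1.0 if k == n else stats.beta.ppf(0.975, k + 1, n - k)
        assert cell.ci95[0] == pytest.approx(100 * lo, abs=1e-9)
        assert cell.ci95[1] == pytest.approx(100 * hi, abs=1e-9)


def test_empty_stratum_is_undefined_not_zero():
    cell = ppv(0, 0)
    assert cell.ppv_percent is None and cell.ci95 is None


def test_invalid_counts_rejected():
    with pytest.raises(ValidationError):
        ppv(3, 2)


def test_kappa_from_agreement_reference_value():
    """po 91.7%, pe 50.6% -> kappa 0.832 (rounds to 0.83)."""
    assert kappa_from_agreement(0.917, 0.506) == pytest.approx(0.832, abs=5e-4)


@pytest.mark.parametrize("po", [0.0, 0.3, 1.0])
def test_kappa_zero_expected_agreement_identity(po):
    assert kappa_from_agreement(po, 0.0) == po


def test_kappa_at_chance_level_is_zero():
    assert kappa_from_agreement(0.4, 0.4) == 0.0


def test_kappa_expected_agreement_one_rejected():
    with pytest.raises(ValidationError):
        kappa_from_agreement(0.9, 1.0)


def test_cohens_kappa_perfect_agreement():
    labels = [GROUP1, GROUP2, GROUP3, GROUP2] * 5
    rel = cohens_kappa(labels, labels)
    assert rel.observed_agreement == 1.0
    assert rel.kappa == 1.0


def test_cohens_kappa_undefined_for_identical_constant_raters():
    rel = cohens_kappa([GROUP1] * 10, [GROUP1] * 10)
    assert rel.kappa is None


def test_cohens_kappa_matches_sklearn():
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    rng = random.Random(7)
    a = [rng.choice([GROUP1, GROUP2, GROUP3]) for _ in range(500)]
    b = [x if rng.random() < 0.8 else rng.choice([GROUP1, GROUP2, GROUP3]) for x in a]
    rel = cohens_kappa(a, b)
    assert rel.kappa == pytest.approx(sklearn_metrics.cohen_kappa_score(a, b), abs=1e-12)


def test_cohens_kappa_internally_consistent():
    rng = random.Random(3)
    a = [rng.choice([GROUP1, GROUP2, GROUP3]) for _ in range(200)]
    b = [rng.choice([GROUP1, GROUP2, GROUP3]) for _ in range(200)]
    rel = cohens_kappa(a, b)
    assert rel.kappa == pytest.approx(
        kappa_from_agreement(rel.observed_agreement, rel.expected_agreement)
    )
    assert rel.kappa <= 1.0


def test_independent_raters_have_near_zero_kappa():
    rng = np.random.default_rng(11)
    a = rng.choice([GROUP1, GROUP2, GROUP3], size=10_000)
    b = rng.choice([GROUP1, GROUP2, GROUP3], size=10_000)
    rel = cohens_kappa(list(a), list(b))
    assert abs(rel.kappa) < 0.03  # ~3 sigma Monte-Carlo bound


# --- report assembly --------------------------------------------------------


def _case(i, category, stratum, subtype=None):
    fill = date(2005, 3, 1)
    window = RiskWindow("k%d" % i, fill, fill + timedelta(days=4),
                        fill + timedelta(days=11), fill + timedelta(days=18))
    event = fill + (timedelta(days=2) if stratum == "early" else timedelta(days=15))
    return PotentialCase(child_id=f"k{i}", event_date=event, category=category,
                         window=window, time_stratum=stratum,
                         encounter_id=None if category == "death_any_cause" else f"e{i}",
                         symptom_subtype=subtype)


def _result(case, group):
    if group == GROUP3:
        return AdjudicationResult(case.case_id, group)
    return AdjudicationResult(case.case_id, group, "intermediate", "therapeutic",
                              "own_prescription")


def test_report_additivity_and_permutation_invariance():
    cases, finals = [], {}
    layout = [("intentional_overdose", "early", 4, 2),
              ("symptom_only", "late", 3, 1),
              ("adverse_effect_therapeutic", "early", 5, 4)]
    i = 0
    for category, stratum, total, confirmed in layout:
        for j in range(total):
            sub = "cns" if category == "symptom_only" else None
            case = _case(i, category, stratum, sub)
            cases.append(case)
            finals[case.case_id] = _result(case, GROUP2 if j < confirmed else GROUP3)
            i += 1
    report = build_report(cases, finals)
    assert report.overall.n_total == 12 and report.overall.n_confirmed == 7
    assert sum(c.n_total for c in report.by_category.values()) == 12
    assert sum(c.n_total for c in report.by_time_stratum.values()) == 12
    shuffled = random.Random(0).sample(cases, len(cases))
    assert build_report(shuffled, finals).overall == report.overall


def test_report_excludes_unavailable_records_from_denominators():
    cases = [_case(i, "adverse_effect_therapeutic", "early") for i in range(10)]
    finals = {c.case_id: _result(c, GROUP1) for c in cases[:7]}
    availability = {c.case_id: "not_found" for c in cases[7:9]}
    availability[cases[9].case_id] = "no_information"
    report = build_report(cases, finals, availability=availability)
    assert report.availability.n_screened == 10
    assert report.availability.n_adjudicable == 7
    assert report.overall.n_total == 7


def test_report_requires_final_group_for_adjudicable_cases():
    case = _case(0, "symptom_only", "early", "cns")
    with pytest.raises(ValidationError, match="no final adjudication"):
        build_report([case], {})


def test_empty_case_list_yields_undefined_cells():
    report = build_report([], {})
    assert report.overall.ppv_percent is None
    assert report.availability.n_screened == 0
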