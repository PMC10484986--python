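"""Synthetic registry generation and planted-label recovery."""

import numpy as np
import pandas as pd
import pytest

from hncmeta import (
    SynthParams,
    derive_labels,
    generate_registry,
    recovery_report,
    select_cohort,
    study_table,
    tag_cohort,
)
from hncmeta.mention_tagging import match_terms
from hncmeta.lexicons import Lexicon, MatchMode, sg_lexicon


def run_pipeline(bundle):
    report = select_cohort(bundle)
    tags = tag_cohort(bundle, report.included_ids)
    return report, derive_labels(bundle, tags, report.included_ids)


def test_determinism_same_seed_same_registry():
    params = SynthParams(n_studies=60, seed=11)
    b1, t1 = generate_registry(params)
    b2, t2 = generate_registry(SynthParams(n_studies=60, seed=11))
    pd.testing.assert_frame_equal(t1, t2)
    pd.testing.assert_frame_equal(study_table(b1), study_table(b2))
    b3, _ = generate_registry(SynthParams(n_studies=60, seed=12))
    assert not study_table(b3).equals(study_table(b1))


def test_no_sg_injection_yields_all_no_mention():
    params = SynthParams(
        n_studies=50, seed=5, decoy_rate=0.0,
        sg_section_probs={k: 0.0 for k in SynthParams().sg_section_probs},
    )
    bundle, truth = generate_registry(params)
    _, labels = run_pipeline(bundle)
    assert (labels["sg_category"] == "NO_MENTION").all()
    assert (truth["sg_category"] == "NO_MENTION").all()


def test_hpv_probability_one_marks_every_study():
    bundle, truth = generate_registry(SynthParams(n_studies=40, seed=9, p_hpv=1.0))
    _, labels = run_pipeline(bundle)
    assert labels["hpv_mention"].all()


def test_invalid_probability_rejected():
    with pytest.raises(ValueError):
        generate_registry(SynthParams(n_studies=5, p_hpv=1.5))
    with pytest.raises(ValueError):
        generate_registry(SynthParams(n_studies=5, sg_section_probs={"bogus": 0.1}))


def test_cohort_gates_recover_planted_inclusion_exactly():
    bundle, truth = generate_registry(SynthParams(n_studies=800, seed=21))
    report = select_cohort(bundle)
    planted = set(truth.loc[truth["included"], "nct_id"])
    assert set(report.included_ids) == planted
    assert report.n_hnc_unique == (truth["excluded_reason"] != "non_hnc").sum()
    assert report.n_excluded_status == (truth["excluded_reason"] == "status").sum()
    assert report.n_excluded_single_sex == (truth["excluded_reason"] == "single_sex").sum()


def test_end_to_end_label_recovery_with_decoys():
    """Whole-word matching recovers every planted label despite decoys."""
    bundle, truth = generate_registry(
        SynthParams(n_studies=600, seed=33, decoy_rate=0.5)
    )
    report, labels = run_pipeline(bundle)
    included_truth = truth[truth["included"]].reset_index(drop=True)
    result = recovery_report(included_truth, labels)
    assert all(entry["agreement"] == 1.0 for entry in result.values())


def test_substring_misconfiguration_breaks_recovery():
    """A deliberately substring-matched S/G lexicon fires on decoys; the
    asymmetry against whole-word matching is the boundary-rule regression."""
    bad_lexicon = Lexicon(
        "sg_substring",
        tuple((term, MatchMode.SUBSTRING) for term, _ in sg_lexicon().entries),
    )
    bundle, truth = generate_registry(
        SynthParams(n_studies=300, seed=44, decoy_rate=1.0)
    )
    report = select_cohort(bundle)
    tags = tag_cohort(bundle, report.included_ids, sg_lex=bad_lexicon)
    truth_cat = truth.set_index("nct_id").loc[report.included_ids, "sg_category"]
    predicted = tags.set_index("nct_id")["sg_category"]
    # decoys ("human", "treatment", ...) embed "man"/"men" and get tagged
    assert (predicted != truth_cat).any()


def test_recovery_report_counts_single_flip():
    truth = pd.DataFrame({"nct_id": ["a", "b", "c", "d"], "x": ["1", "1", "2", "2"]})
    predicted = truth.copy()
    assert recovery_report(truth, predicted)["x"]["agreement"] == 1.0
    predicted.loc[0, "x"] = "2"
    entry = recovery_report(truth, predicted)["x"]
    assert entry["agreement"] == pytest.approx(3 / 4)
    assert entry["confusion"].loc["1", "2"] == 1


def test_recovery_report_id_mismatch_is_error():
    truth = pd.DataFrame({"nct_id": ["a", "b"], "x": ["1", "1"]})
    predicted = pd.DataFrame({"nct_id": ["a", "c"], "x": ["1", "1"]})
    with pytest.raises(ValueError, match="symmetric difference"):
        recovery_report(truth, predicted)


def test_marginal_frequencies_converge_to_parameters():
    """Realized label frequencies sit within binomial tolerance of the
    generator parameters at n = 5000."""
    params = SynthParams(n_studies=5000, seed=77)
    bundle, truth = generate_registry(params)

    def within(observed_p, p, n):
        # 4-sigma binomial band
        return abs(observed_p - p) <= 4 * np.sqrt(p * (1 - p) / n) + 1e-9

    n = params.n_studies
    assert within((truth["study_type"] == "INTERVENTIONAL").mean(),
                  params.p_interventional, n)
    assert within(truth["hpv_mention"].mean(), params.p_hpv, n)
    # "non_hnc" covers both fully non-HNC and mixed-condition studies
    non_hnc_rate = (truth["excluded_reason"] == "non_hnc").mean()
    assert within(non_hnc_rate, params.p_non_hnc + params.p_partial_hnc, n)
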