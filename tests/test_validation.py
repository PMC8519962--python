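"""Report-level scoring, stratification and error-reason classification."""

import pandas as pd
import pytest

from vetptr import synth, pipeline, validation
from vetptr.validation import TumourHierarchy, classify_error, score_corpus


def gold_frame(rows):
    """rows: (ref, assay, [types], [locations], text)"""
    out = []
    for ref, assay, types, locs, text in rows:
        if not types:
            out.append({"ReportRef": ref, "Histo_Cyto": assay,
                        "Primary_tumour": "", "Location": "",
                        "ReportText": text})
        for t, l in zip(types, locs):
            out.append({"ReportRef": ref, "Histo_Cyto": assay,
                        "Primary_tumour": t, "Location": l,
                        "ReportText": text})
    return pd.DataFrame(out)


def pred_frame(rows):
    """rows: (ref, [types], [locations])"""
    out = []
    for ref, types, locs in rows:
        for i, (t, l) in enumerate(zip(types, locs), start=1):
            out.append({"ReportRef": ref, "TumourRef": f"{ref}-T.{i}",
                        "Primary_tumour": t, "Location": l})
    return pd.DataFrame(out)


class TestScoreCorpus:
    def test_perfect_agreement_is_all_hundred(self):
        gold = gold_frame([("R.1", "Histology", ["Lipoma"], ["Skin"], "t"),
                           ("R.2", "Cytology", ["Lymphoma"], [""], "t"),
                           ("R.3", "Histology", ["Lipoma", "Lipoma"],
                            ["Skin", "Neck"], "t")])
        pred = pred_frame([("R.1", ["Lipoma"], ["Skin"]),
                           ("R.2", ["Lymphoma"], [""]),
                           ("R.3", ["Lipoma", "Lipoma"], ["Skin", "Neck"])])
        res = score_corpus(pred, gold)
        assert res.strata["overall"].accuracy == 1.0
        assert res.errors == []
        assert res.per_lesion_f1 == 1.0

    def test_single_group_accuracy_arithmetic(self):
        # 6 single-tumour reports, 2 missed: 4/6
        rows, preds = [], []
        for i in range(6):
            rows.append((f"R.{i}", "Histology", ["Lipoma"], [""], "t"))
            preds.append((f"R.{i}", ["Lipoma" if i < 4 else "Melanoma"], [""]))
        res = score_corpus(pred_frame(preds), gold_frame(rows))
        s = res.strata["single"]
        assert (s.total, s.matched) == (6, 4)
        assert s.accuracy == pytest.approx(4 / 6)
        assert s.ci_low < s.accuracy < s.ci_high

    def test_partial_multiset_recovery_is_a_failure(self):
        gold = gold_frame([("R.1", "Histology", ["Seminoma", "Seminoma"],
                            ["", ""], "Seminoma in both testicles")])
        pred = pred_frame([("R.1", ["Seminoma"], [""])])
        res = score_corpus(pred, gold)
        assert res.strata["multiple"].matched == 0
        assert res.errors[0].reason == 2

    def test_non_tumour_gold_with_prediction_is_single_stratum_error(self):
        gold = gold_frame([("R.1", "Cytology", [], [], "Lymphoma not excluded")])
        pred = pred_frame([("R.1", ["Lymphoma"], [""])])
        res = score_corpus(pred, gold)
        assert res.strata["single_cytology"].total == 1
        assert res.strata["single_cytology"].matched == 0

    def test_reordering_reports_does_not_change_result(self):
        gold = gold_frame([("R.1", "Histology", ["Lipoma"], [""], "t"),
                           ("R.2", "Cytology", ["Melanoma"], [""], "t")])
        pred = pred_frame([("R.1", ["Lipoma"], [""]),
                           ("R.2", ["Lipoma"], [""])])
        a = score_corpus(pred, gold)
        b = score_corpus(pred.iloc[::-1], gold.iloc[::-1])
        assert a.to_dict() == b.to_dict()

    def test_predicted_report_missing_from_gold_is_hard_error(self):
        gold = gold_frame([("R.1", "Histology", ["Lipoma"], [""], "t")])
        pred = pred_frame([("R.404", ["Lipoma"], [""])])
        with pytest.raises(ValueError, match="R.404"):
            score_corpus(pred, gold)


@pytest.fixture(scope="module")
def hierarchy():
    return TumourHierarchy()


class TestClassifyError:
    def test_unnamed_lipoma_is_reason_1(self, hierarchy):
        assert classify_error([], [("Lipoma", "")],
                              "Consistent with aspiration of adipose tissue",
                              hierarchy) == 1

    def test_missing_delimiters_is_reason_2(self, hierarchy):
        assert classify_error([("Lipoma", "")],
                              [("Lipoma", "")] * 3,
                              "All three sites: Lipoma", hierarchy) == 2

    def test_provisional_phrase_is_reason_3(self, hierarchy):
        assert classify_error([("Lymphoma", "")], [],
                              "Lymphoma not excluded", hierarchy) == 3

    def test_location_driven_type_error_is_reason_4(self, hierarchy):
        assert classify_error([("Carcinoma_others", "Perianal")],
                              [("Anal sac carcinoma", "Anal sac")],
                              "Carcinoma, perianal region", hierarchy) == 4

    def test_generic_for_specific_is_reason_5(self, hierarchy):
        assert classify_error([("Mesenchymal_neoplasias_others", "Hindlimb")],
                              [("Soft tissue sarcoma", "Hindlimb")],
                              "Mesenchymal neoplasia, hindlimb", hierarchy) == 5

    def test_unrelated_mismatch_is_unclassified(self, hierarchy):
        assert classify_error([("Melanoma", "")], [("Lymphoma", "")],
                              "plain text", hierarchy) is None

    def test_numbered_report_with_missing_tumour_is_not_reason_2(self,
                                                                 hierarchy):
        # delimiters were used, so the count error is not the delimiter mode
        got = classify_error([("Lipoma", "")], [("Lipoma", ""), ("Melanoma", "")],
                             "1. Lipoma 2. something odd", hierarchy)
        assert got != 2


class TestHierarchy:
    def test_ancestors_climb_to_root(self):
        h = TumourHierarchy()
        assert "Mesenchymal neoplasia" in h.ancestors("Soft tissue sarcoma")
        assert "Neoplasia" in h.ancestors("Soft tissue sarcoma")
        assert "Epithelial tumour" in h.ancestors("Thyroid carcinoma")

    def test_catch_all_aliases_dealias(self):
        h = TumourHierarchy()
        assert h.is_generic_of("Epithelial tumour_others", "Thyroid carcinoma")
        assert not h.is_generic_of("Lipoma", "Thyroid carcinoma")

    def test_base_family(self):
        h = TumourHierarchy()
        assert h.base_family("Anal sac carcinoma") == "Epithelial tumour"
        assert h.base_family("Carcinoma_others") == "Epithelial tumour"
        assert h.base_family("Soft tissue sarcoma") == "Mesenchymal neoplasia"


class TestParameterRecovery:
    def test_accuracy_recovers_one_minus_injected_rate(self, context):
        rates = synth.reference_failure_rates()
        accs = []
        for seed in range(8):
            spec = synth.CorpusSpec(n_reports=400, seed=seed,
                                    failure_rates=rates)
            reports = synth.generate_corpus(spec)
            reg = pipeline.registry_from_records(
                synth.corpus_records(reports), context)
            res = score_corpus(reg, synth.gold_frame(reports))
            accs.append(res.strata["overall"].accuracy)
        mean = sum(accs) / len(accs)
        assert abs(mean - (1 - 23 / 400)) < 0.02

    def test_single_reason_corpus_errors_all_classified_to_it(self, context):
        for reason in range(1, 6):
            rates = {r: (0.3 if r == reason else 0.0) for r in range(1, 6)}
            spec = synth.CorpusSpec(n_reports=60, seed=reason,
                                    failure_rates=rates)
            reports = synth.generate_corpus(spec)
            reg = pipeline.registry_from_records(
                synth.corpus_records(reports), context)
            res = score_corpus(reg, synth.gold_frame(reports))
            assert res.errors, f"reason {reason} corpus produced no errors"
            assert {e.reason for e in res.errors} == {reason}
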