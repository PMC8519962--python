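"""The synthetic corpus generator: determinism, round trips, failure modes."""

import logging

import numpy as np
import pytest

from vetptr import pipeline, synth
from vetptr.synth import CorpusSpec


class TestDeterminism:
    def test_same_spec_twice_is_identical(self):
        spec = CorpusSpec(n_reports=40, seed=42,
                          failure_rates=synth.reference_failure_rates())
        a = synth.generate_corpus(spec)
        b = synth.generate_corpus(spec)
        assert a == b

    def test_report_regenerable_in_isolation(self):
        spec = CorpusSpec(n_reports=40, seed=42)
        corpus = synth.generate_corpus(spec)
        assert synth.generate_report(spec, 17) == corpus[17]

    def test_different_seeds_differ(self):
        a = synth.generate_corpus(CorpusSpec(n_reports=20, seed=1))
        b = synth.generate_corpus(CorpusSpec(n_reports=20, seed=2))
        assert a != b


class TestSpecValidation:
    def test_bad_probability_vector_rejected(self):
        with pytest.raises(ValueError):
            CorpusSpec(n_reports=10, lesion_count_probs=(0.5, 0.2, 0.1,
                                                         0.1, 0.05, 0.0)
                       ).validate()

    def test_failure_rates_must_not_exceed_one(self):
        with pytest.raises(ValueError):
            CorpusSpec(n_reports=10,
                       failure_rates={1: 0.6, 2: 0.6, 3: 0, 4: 0, 5: 0}
                       ).validate()


class TestCleanRoundTrip:
    """The generator's core guarantee: on a clean corpus the pipeline
    recovers the gold annotation on every field."""

    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_every_field_matches_gold(self, context, seed):
        reports = synth.generate_corpus(CorpusSpec(n_reports=80, seed=seed))
        reg = pipeline.registry_from_records(
            synth.corpus_records(reports), context)
        gold = synth.gold_frame(reports)
        gold_tumours = gold[gold["Primary_tumour"] != ""]
        assert len(reg) == len(gold_tumours)
        merged = reg.merge(
            gold_tumours, left_on=["ReportRef", "TumourRef"],
            right_on=["ReportRef",
                      gold_tumours["ReportRef"] + "-T." +
                      gold_tumours["Ordinal"].astype(str)],
            suffixes=("_pred", "_gold"))
        assert len(merged) == len(reg)
        for col in ["Species", "Breed", "Gender", "Primary_tumour",
                    "Grade_2_tier", "Grade_3_tier", "Differentiation",
                    "Location", "Uncertainty_terms", "ResultDate"]:
            mism = merged[merged[f"{col}_pred"] != merged[f"{col}_gold"]]
            assert mism.empty, f"{col}: {mism.head()}"

    def test_export_csv_path_equals_direct_records_path(self, context,
                                                        tmp_path):
        reports = synth.generate_corpus(CorpusSpec(n_reports=40, seed=5))
        export_path, _ = synth.write_corpus(reports, tmp_path)
        via_csv = pipeline.registry_from_export(export_path, "default", context)
        direct = pipeline.registry_from_records(
            synth.corpus_records(reports), context)
        assert via_csv.equals(direct)

    def test_generator_output_ingests_without_warnings(self, context, tmp_path,
                                                       caplog):
        reports = synth.generate_corpus(CorpusSpec(n_reports=40, seed=9))
        export_path, _ = synth.write_corpus(reports, tmp_path)
        with caplog.at_level(logging.WARNING, logger="vetptr.ingest"):
            records = pipeline.records_from_export(export_path, "default",
                                                   context["dialects"])
        assert caplog.records == []
        assert len(records) == 40

    def test_alt_dialect_reports_also_round_trip(self, context):
        spec = CorpusSpec(n_reports=40, seed=3,
                          dialect_mix={"default": 0.5, "alt": 0.5})
        reports = synth.generate_corpus(spec)
        assert {r.dialect for r in reports} == {"default", "alt"}
        reg = pipeline.registry_from_records(
            synth.corpus_records(reports), context)
        gold = synth.gold_frame(reports)
        assert len(reg) == (gold["Primary_tumour"] != "").sum()


class TestInjectFailure:
    def clean_report(self, **kw):
        spec = CorpusSpec(n_reports=200, seed=1)
        for i in range(200):
            r = synth.generate_report(spec, i)
            if all(getattr(r, k) == v for k, v in kw.items()):
                return r
        raise AssertionError(f"no clean report with {kw}")

    def test_reason2_needs_multiple_lesions(self):
        single = self.clean_report(delimiter_style="none")
        with pytest.raises(ValueError, match="two lesions"):
            synth.inject_failure(single, 2)

    def test_reason1_needs_cytology(self):
        histo = self.clean_report(assay_type="histology")
        with pytest.raises(ValueError, match="cytology"):
            synth.inject_failure(histo, 1)

    def test_reason1_text_never_names_the_lipoma(self):
        cyto = self.clean_report(assay_type="cytology")
        for s in range(5):
            out = synth.inject_failure(cyto, 1, seed=s)
            assert "lipoma" not in out.report_text.lower()
            assert [g.primary for g in out.gold_lesions] == ["Lipoma"]

    def test_reason2_removes_delimiters_but_keeps_gold_count(self, context):
        spec = CorpusSpec(n_reports=300, seed=2,
                          failure_rates={1: 0, 2: 1.0, 3: 0, 4: 0, 5: 0})
        reports = synth.generate_corpus(spec)[:30]
        reg = pipeline.registry_from_records(
            synth.corpus_records(reports), context)
        for r in reports:
            assert len(r.gold_lesions) >= 2
            predicted = reg[reg["ReportRef"] == r.lab_no]
            assert len(predicted) == 1  # the pipeline sees a single tumour

    def test_reason3_gold_is_non_tumour_but_pipeline_registers_one(self,
                                                                   context):
        spec = CorpusSpec(n_reports=30, seed=3,
                          failure_rates={1: 0, 2: 0, 3: 1.0, 4: 0, 5: 0})
        reports = synth.generate_corpus(spec)
        reg = pipeline.registry_from_records(
            synth.corpus_records(reports), context)
        assert all(len(r.gold_lesions) == 0 for r in reports)
        assert len(reg) == len(reports)

    def test_unknown_reason_rejected(self):
        r = self.clean_report()
        with pytest.raises(ValueError):
            synth.inject_failure(r, 7)


class TestCorpusComposition:
    def test_lesion_count_median_is_one(self):
        reports = synth.generate_corpus(CorpusSpec(n_reports=1500, seed=4))
        counts = [len(r.gold_lesions) for r in reports]
        assert float(np.median(counts)) == 1.0
        assert max(counts) <= 6

    def test_error_count_matches_rates_in_expectation(self):
        spec = CorpusSpec(n_reports=400, seed=0,
                          failure_rates=synth.reference_failure_rates())
        n_injected = [sum(1 for r in synth.generate_corpus(
            CorpusSpec(n_reports=400, seed=s,
                       failure_rates=synth.reference_failure_rates()))
            if r.injected_reason) for s in range(15)]
        mean = float(np.mean(n_injected))
        # 23 expected; allow ~4 standard errors of the mean
        assert abs(mean - 23.0) < 5.0
        spec.validate()
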