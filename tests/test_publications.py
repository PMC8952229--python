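"""Evidence filtering, primacy resolution and binding-sequence classes."""

from __future__ import annotations

import random
from collections import Counter
from datetime import date

import pytest

from annodrift import (
    BINDING_TERM_ID,
    BindingSequenceClass,
    EvidenceRecord,
    SequencingScenarioConfig,
    class_histogram,
    classify_binding_sequence,
    extract_evidence_records,
    filter_positive_experimental,
    generate_sequencing_fixture,
    publication_stats,
    resolve_primacy,
)

from conftest import ann, entry, ev, pub, release

W0, W1 = date(2016, 1, 1), date(2021, 12, 31)


def rec(
    acc="P1",
    category="go-molecular-function",
    term="GO:1",
    kind="direct-assay",
    neg=False,
    pid="PMID:1",
    iso="2018-05-01",
    year_only=False,
):
    d = None if iso is None else (date(int(iso), 1, 1) if year_only else date.fromisoformat(iso))
    return EvidenceRecord(
        accession=acc,
        category=category,
        term_id=term,
        term_label=term,
        evidence_kind=kind,
        is_negative=neg,
        pub_id=pid,
        pub_date=d,
        year_only=year_only,
    )


class TestFilter:
    def test_all_negative_input_gives_empty(self):
        records = [rec(pid=f"PMID:{i}", neg=True) for i in range(5)]
        assert filter_positive_experimental(records, W0, W1) == []

    def test_exactly_negatives_and_nonexperimental_removed(self):
        keep = [rec(pid=f"PMID:{i}") for i in range(6)]
        negs = [rec(pid=f"PMID:n{i}", neg=True) for i in range(3)]
        nonexp = [
            rec(pid="PMID:s1", kind="sequence-similarity"),
            rec(pid="PMID:c1", kind="curator-inference"),
            rec(pid="PMID:a1", kind="author-statement"),
        ]
        out = filter_positive_experimental(keep + negs + nonexp, W0, W1)
        assert len(out) == len(keep)
        assert set(out) == set(keep)

    def test_sequence_similarity_inside_window_is_dropped(self):
        out = filter_positive_experimental([rec(kind="sequence-similarity")], W0, W1)
        assert out == []

    @pytest.mark.parametrize(
        "iso, year_only, kept",
        [
            ("2018-05-01", False, True),
            ("2015-12-31", False, False),
            ("2022-01-01", False, False),
            ("2016", True, True),  # year intersects window
            ("2021", True, True),
            ("2015", True, False),
            ("2022", True, False),
        ],
    )
    def test_window_logic_with_granularity(self, iso, year_only, kept):
        out = filter_positive_experimental([rec(iso=iso, year_only=year_only)], W0, W1)
        assert (len(out) == 1) is kept

    def test_record_without_publication_is_dropped(self):
        r = rec()
        bare = EvidenceRecord(
            accession="P1",
            category="pathway",
            term_id=None,
            term_label=None,
            evidence_kind="direct-assay",
            is_negative=False,
            pub_id=None,
            pub_date=None,
        )
        assert filter_positive_experimental([r, bare], W0, W1) == [r]


class TestPrimacy:
    def test_single_record_is_identity(self):
        out = resolve_primacy([rec()])
        assert len(out) == 1
        assert out[0].first_pub_id == "PMID:1"
        assert out[0].first_pub_date == date(2018, 5, 1)

    def test_oldest_publication_wins(self):
        records = [rec(pid="PMID:new", iso="2019-01-01"), rec(pid="PMID:old", iso="2017-06-01")]
        out = resolve_primacy(records)
        assert len(out) == 1
        assert out[0].first_pub_id == "PMID:old"

    def test_date_tie_broken_by_smallest_pub_id(self):
        records = [rec(pid="PMID:9", iso="2018-01-01"), rec(pid="PMID:1", iso="2018-01-01")]
        out = resolve_primacy(records)
        assert out[0].first_pub_id == "PMID:1"

    def test_each_function_key_keeps_its_own_first(self):
        records = [
            rec(term="GO:1", pid="PMID:1", iso="2017-01-01"),
            rec(term="GO:2", pid="PMID:2", iso="2019-01-01"),
        ]
        out = resolve_primacy(records)
        assert {(r.term_id, r.first_pub_id) for r in out} == {
            ("GO:1", "PMID:1"),
            ("GO:2", "PMID:2"),
        }

    def test_permutation_invariance(self):
        rng = random.Random(0)
        records = [
            rec(
                acc=f"P{i % 7}",
                term=f"GO:{i % 5}",
                pid=f"PMID:{rng.randrange(40)}",
                iso=f"20{16 + i % 6}-0{1 + i % 9}-15",
            )
            for i in range(60)
        ]
        baseline = resolve_primacy(records)
        for _ in range(20):
            rng.shuffle(records)
            assert resolve_primacy(records) == baseline

    def test_idempotence_on_own_output(self):
        records = [
            rec(acc=f"P{i % 4}", term=f"GO:{i % 3}", pid=f"PMID:{i}", iso=f"201{6 + i % 4}-03-0{1 + i % 9}")
            for i in range(30)
        ]
        first = resolve_primacy(records)
        as_records = [
            rec(acc=p.accession, category=p.category, term=p.term_id,
                pid=p.first_pub_id, iso=p.first_pub_date.isoformat())
            for p in first
        ]
        assert resolve_primacy(as_records) == first

    def test_missing_date_excluded_with_warning(self, caplog):
        bare = EvidenceRecord(
            accession="P1", category="pathway", term_id="GO:1", term_label="x",
            evidence_kind="direct-assay", is_negative=False, pub_id=None, pub_date=None,
        )
        import logging

        with caplog.at_level(logging.WARNING):
            out = resolve_primacy([bare, rec()])
        assert len(out) == 1
        assert any("without publication date" in r.message for r in caplog.records)


class TestClassifier:
    def _primacy(self, records):
        return resolve_primacy(records)

    def test_binding_before_other_is_binding_first(self):
        prim = self._primacy([
            rec(term=BINDING_TERM_ID, pid="PMID:1", iso="2017-02-01"),
            rec(term="GO:0016301", pid="PMID:2", iso="2019-06-01"),
        ])
        assert classify_binding_sequence(prim)["P1"] == BindingSequenceClass.BINDING_FIRST

    def test_shared_publication_is_same_publication(self):
        prim = self._primacy([
            rec(term=BINDING_TERM_ID, pid="PMID:7", iso="2018-01-01"),
            rec(term="GO:0016301", pid="PMID:7", iso="2018-01-01"),
        ])
        assert classify_binding_sequence(prim)["P1"] == BindingSequenceClass.SAME_PUBLICATION

    def test_other_before_binding_is_binding_after(self):
        prim = self._primacy([
            rec(term=BINDING_TERM_ID, pid="PMID:2", iso="2020-01-01"),
            rec(term="GO:0016301", pid="PMID:1", iso="2016-03-01"),
        ])
        assert classify_binding_sequence(prim)["P1"] == BindingSequenceClass.BINDING_AFTER

    def test_only_binding_and_only_other(self):
        prim = self._primacy([
            rec(acc="A", term=BINDING_TERM_ID, pid="PMID:1"),
            rec(acc="B", term="GO:0016301", pid="PMID:2"),
        ])
        classes = classify_binding_sequence(prim)
        assert classes["A"] == BindingSequenceClass.BINDING_ONLY
        assert classes["B"] == BindingSequenceClass.OTHER_ONLY

    def test_equal_dates_different_publications_is_binding_first(self):
        prim = self._primacy([
            rec(term=BINDING_TERM_ID, pid="PMID:2", iso="2018-01-01"),
            rec(term="GO:0016301", pid="PMID:1", iso="2018-01-01"),
        ])
        assert classify_binding_sequence(prim)["P1"] == BindingSequenceClass.BINDING_FIRST

    def test_year_only_same_year_counts_as_equal(self):
        prim = self._primacy([
            rec(term=BINDING_TERM_ID, pid="PMID:2", iso="2018", year_only=True),
            rec(term="GO:0016301", pid="PMID:1", iso="2018-06-01"),
        ])
        # equal at year granularity, different publications -> BINDING_FIRST
        assert classify_binding_sequence(prim)["P1"] == BindingSequenceClass.BINDING_FIRST

    def test_uncontrolled_record_counts_as_other_function(self):
        prim = self._primacy([
            rec(term=BINDING_TERM_ID, pid="PMID:1", iso="2017-01-01"),
            rec(category="function-info", term=None, pid="PMID:2", iso="2019-01-01"),
        ])
        assert classify_binding_sequence(prim)["P1"] == BindingSequenceClass.BINDING_FIRST

    def test_totality_every_protein_gets_one_class(self):
        cfg = SequencingScenarioConfig(
            multiplicities={
                "SAME_PUBLICATION": 5, "BINDING_FIRST": 5, "BINDING_AFTER": 5,
                "OTHER_ONLY": 5, "BINDING_ONLY": 5,
            },
            year_only_fraction=0.3,
        )
        rel, _ = generate_sequencing_fixture(cfg, seed=3)
        prim = resolve_primacy(filter_positive_experimental(extract_evidence_records(rel), W0, W1))
        classes = classify_binding_sequence(prim)
        assert set(classes) == {r.accession for r in prim}
        hist = class_histogram(classes)
        assert sum(hist.values()) == len(classes)
        assert list(hist) == list(BindingSequenceClass.ALL)

    def test_fixture_classes_recovered_exactly(self):
        cfg = SequencingScenarioConfig(
            multiplicities={
                "SAME_PUBLICATION": 4, "BINDING_FIRST": 7, "BINDING_AFTER": 3,
                "OTHER_ONLY": 6, "BINDING_ONLY": 9,
            },
            date_spacing=14,
        )
        rel, log = generate_sequencing_fixture(cfg, seed=21)
        prim = resolve_primacy(filter_positive_experimental(extract_evidence_records(rel), W0, W1))
        classes = classify_binding_sequence(prim)
        assert classes == log.true_classes


class TestPublicationStats:
    def test_two_proteins_one_publication_each(self):
        prim = resolve_primacy([
            rec(acc="A", pid="PMID:1"), rec(acc="B", pid="PMID:2"),
        ])
        stats = publication_stats(prim)
        assert stats.mean_publications_per_protein == 1.0
        assert stats.n_single_publication_proteins == 2

    def test_one_publication_covering_four_proteins(self):
        prim = resolve_primacy([rec(acc=f"P{i}", pid="PMID:1") for i in range(4)])
        stats = publication_stats(prim)
        assert stats.mean_proteins_per_publication == 4.0
        assert stats.n_single_protein_publications == 0

    def test_binding_fractions(self):
        prim = resolve_primacy([
            rec(acc="A", term=BINDING_TERM_ID, pid="PMID:1"),
            rec(acc="A", term="GO:0016301", pid="PMID:2"),
            rec(acc="B", term="GO:0016301", pid="PMID:3"),
        ])
        stats = publication_stats(prim)
        assert stats.binding_fraction == pytest.approx(0.5)
        assert stats.binding_record_fraction == pytest.approx(1 / 3)

    def test_generator_fixture_matches_independent_tally(self):
        cfg = SequencingScenarioConfig(
            multiplicities={
                "SAME_PUBLICATION": 3, "BINDING_FIRST": 2, "BINDING_AFTER": 2,
                "OTHER_ONLY": 4, "BINDING_ONLY": 5,
            }
        )
        rel, _ = generate_sequencing_fixture(cfg, seed=8)
        prim = resolve_primacy(filter_positive_experimental(extract_evidence_records(rel), W0, W1))
        stats = publication_stats(prim)
        # brute-force recount straight from the release object
        pairs = set()
        binding_prots = set()
        prots = set()
        pubs = set()
        for e in rel.entries:
            prots.add(e.accession)
            for a in e.annotations:
                p = a.evidences[0].publication
                pairs.add((e.accession, p.pub_id))
                pubs.add(p.pub_id)
                if a.term_id == BINDING_TERM_ID:
                    binding_prots.add(e.accession)
        assert stats.n_proteins == len(prots)
        assert stats.n_publications == len(pubs)
        assert stats.mean_proteins_per_publication == pytest.approx(len(pairs) / len(pubs))
        assert stats.mean_publications_per_protein == pytest.approx(len(pairs) / len(prots))
        assert stats.binding_fraction == pytest.approx(len(binding_prots) / len(prots))

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            publication_stats([])
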