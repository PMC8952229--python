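"""Evidence filtering, publication primacy and binding-sequence classes.

This stage asks, per protein, *in what order* its functions entered the
literature. It admits only positive experimental evidence (direct assay
or physical interaction used in manual assertion) whose publication falls
in an analysis window, resolves per (protein, function) the oldest
publication, and then classifies each protein by when generic
protein binding was first shown relative to any other function:

- SAME_PUBLICATION: binding and another function share the earliest paper;
- BINDING_FIRST: binding was published strictly earlier (equal dates from
  different papers also land here — at year precision primacy cannot be
  decided, and the deterministic rule is logged per protein);
- BINDING_AFTER: another function was published strictly earlier;
- OTHER_ONLY: binding was never shown;
- BINDING_ONLY: only binding was ever shown.

Uncontrolled function records (term-less, e.g. free-text function-info)
participate in primacy and statistics but can never be the binding term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date

from .model import (
    BINDING_TERM_ID,
    EXPERIMENTAL_KINDS,
    BindingSequenceClass,
    PublicationRef,
    Release,
    compare_pub_dates,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvidenceRecord:
    """Flattened (annotation, evidence) pair from a release."""

    accession: str
    category: str
    term_id: str | None
    term_label: str | None
    evidence_kind: str
    is_negative: bool
    pub_id: str | None
    pub_date: date | None
    year_only: bool = False

    def publication(self) -> PublicationRef | None:
        if self.pub_id is None or self.pub_date is None:
            return None
        return PublicationRef(self.pub_id, self.pub_date, self.year_only)

    def function_key(self) -> tuple[str, str | None]:
        return (self.category, self.term_id)


@dataclass(frozen=True)
class PrimacyRecord:
    """Oldest-publication record for one (protein, function) pair."""

    accession: str
    category: str
    term_id: str | None
    first_pub_id: str
    first_pub_date: date
    year_only: bool = False

    def publication(self) -> PublicationRef:
        return PublicationRef(self.first_pub_id, self.first_pub_date, self.year_only)


@dataclass(frozen=True)
class PublicationStats:
    n_proteins: int
    n_publications: int
    mean_proteins_per_publication: float
    n_single_protein_publications: int
    mean_publications_per_protein: float
    n_single_publication_proteins: int
    binding_fraction: float  # proteins whose function set includes binding
    binding_record_fraction: float  # primacy records that are the binding term

    def to_json_dict(self) -> dict:
        return {
            "n_proteins": self.n_proteins,
            "n_publications": self.n_publications,
            "mean_proteins_per_publication": self.mean_proteins_per_publication,
            "n_single_protein_publications": self.n_single_protein_publications,
            "mean_publications_per_protein": self.mean_publications_per_protein,
            "n_single_publication_proteins": self.n_single_publication_proteins,
            "binding_fraction": self.binding_fraction,
            "binding_record_fraction": self.binding_record_fraction,
        }


def extract_evidence_records(release: Release) -> list[EvidenceRecord]:
    """Flatten a release into one row per (annotation, evidence) pair."""
    rows: list[EvidenceRecord] = []
    for entry in release.entries:
        for ann in entry.annotations:
            for ev in ann.evidences:
                pub = ev.publication
                rows.append(
                    EvidenceRecord(
                        accession=entry.accession,
                        category=ann.category,
                        term_id=ann.term_id,
                        term_label=ann.term_label,
                        evidence_kind=ev.kind,
                        is_negative=ev.is_negative,
                        pub_id=pub.pub_id if pub else None,
                        pub_date=pub.pub_date if pub else None,
                        year_only=pub.year_only if pub else False,
                    )
                )
    return rows


def filter_positive_experimental(
    records: list[EvidenceRecord], window_start: date, window_end: date
) -> list[EvidenceRecord]:
    """Keep positive experimental evidence published inside the window.

    Drops negative evidence, non-experimental kinds (sequence similarity,
    curator inference, author statement), records without a publication
    date, and publications outside [window_start, window_end]. A year-only
    date is kept when its year intersects the window.
    """
    kept: list[EvidenceRecord] = []
    for rec in records:
        if rec.is_negative or rec.evidence_kind not in EXPERIMENTAL_KINDS:
            continue
        if rec.pub_date is None:
            continue
        if rec.year_only:
            if not (window_start.year <= rec.pub_date.year <= window_end.year):
                continue
        elif not (window_start <= rec.pub_date <= window_end):
            continue
        kept.append(rec)
    return kept


def _pub_sort_key(rec: EvidenceRecord) -> tuple:
    pub = rec.publication()
    assert pub is not None
    return (*pub.sort_key(), rec.accession, rec.pub_id)


def resolve_primacy(records: list[EvidenceRecord]) -> list[PrimacyRecord]:
    """Per (protein, function key) keep the oldest publication.

    Records are sorted by (publication date, accession, publication id);
    for each (accession, category, term_id) the first record in that order
    wins — i.e. the oldest date, with ties broken by smallest publication
    id (year-only dates sort before full dates of the same year). Records
    lacking a publication date are excluded with a logged warning. Because
    every function key keeps its own oldest record, functions established
    by the protein's first publication are retained alongside the rest.
    Output order is deterministic and input-permutation invariant.
    """
    dated: list[EvidenceRecord] = []
    for rec in records:
        if rec.pub_id is None or rec.pub_date is None:
            logger.warning(
                "primacy: dropping record %s/%s/%s without publication date",
                rec.accession,
                rec.category,
                rec.term_id,
            )
            continue
        dated.append(rec)
    dated.sort(key=_pub_sort_key)

    winners: dict[tuple[str, str, str | None], PrimacyRecord] = {}
    for rec in dated:
        key = (rec.accession, rec.category, rec.term_id)
        if key not in winners:
            winners[key] = PrimacyRecord(
                accession=rec.accession,
                category=rec.category,
                term_id=rec.term_id,
                first_pub_id=rec.pub_id,
                first_pub_date=rec.pub_date,
                year_only=rec.year_only,
            )
    out = list(winners.values())
    out.sort(
        key=lambda p: (
            *p.publication().sort_key(),
            p.accession,
            p.first_pub_id,
            p.category,
            p.term_id or "",
        )
    )
    return out


def classify_binding_sequence(
    primacy: list[PrimacyRecord], binding_term: str = BINDING_TERM_ID
) -> dict[str, str]:
    """Assign every protein one of the five temporal-order classes.

    Every accession with at least one primacy record receives exactly one
    class. Equal earliest dates (including year-only dates compared at
    year granularity) from *different* publications yield BINDING_FIRST;
    the ambiguity is logged per protein.
    """
    by_acc: dict[str, list[PrimacyRecord]] = {}
    for rec in primacy:
        by_acc.setdefault(rec.accession, []).append(rec)

    classes: dict[str, str] = {}
    for acc, recs in by_acc.items():
        binding = [r for r in recs if r.term_id == binding_term]
        others = [r for r in recs if r.term_id != binding_term]
        if not binding:
            classes[acc] = BindingSequenceClass.OTHER_ONLY
            continue
        if not others:
            classes[acc] = BindingSequenceClass.BINDING_ONLY
            continue
        eb = min(binding, key=lambda r: (*r.publication().sort_key(), r.first_pub_id))
        eo = min(others, key=lambda r: (*r.publication().sort_key(), r.first_pub_id))
        if eb.first_pub_id == eo.first_pub_id:
            classes[acc] = BindingSequenceClass.SAME_PUBLICATION
            continue
        cmp = compare_pub_dates(eb.publication(), eo.publication())
        if cmp < 0:
            classes[acc] = BindingSequenceClass.BINDING_FIRST
        elif cmp > 0:
            classes[acc] = BindingSequenceClass.BINDING_AFTER
        else:
            logger.info(
                "classify: %s earliest binding (%s) and other (%s) dates coincide; "
                "assigning BINDING_FIRST by rule",
                acc,
                eb.first_pub_id,
                eo.first_pub_id,
            )
            classes[acc] = BindingSequenceClass.BINDING_FIRST
    return classes


def class_histogram(classes: dict[str, str]) -> dict[str, int]:
    """Count proteins per class, in canonical five-row order."""
    hist = {name: 0 for name in BindingSequenceClass.ALL}
    for cls_name in classes.values():
        hist[cls_name] += 1
    return hist


def publication_stats(
    primacy: list[PrimacyRecord], binding_term: str = BINDING_TERM_ID
) -> PublicationStats:
    """Exact ratios over the protein-publication bipartite graph.

    ``binding_fraction`` is over proteins (share whose surviving function
    set includes the binding term); ``binding_record_fraction`` is over
    primacy records — the underlying quantity is ambiguous between the
    two readings, so both are reported.
    """
    if not primacy:
        raise ValueError("publication statistics need at least one record")
    pairs = {(r.accession, r.first_pub_id) for r in primacy}
    proteins = {r.accession for r in primacy}
    pubs = {r.first_pub_id for r in primacy}
    pubs_per_protein: dict[str, set[str]] = {}
    proteins_per_pub: dict[str, set[str]] = {}
    for acc, pid in pairs:
        pubs_per_protein.setdefault(acc, set()).add(pid)
        proteins_per_pub.setdefault(pid, set()).add(acc)
    binding_proteins = {r.accession for r in primacy if r.term_id == binding_term}
    n_binding_records = sum(1 for r in primacy if r.term_id == binding_term)
    return PublicationStats(
        n_proteins=len(proteins),
        n_publications=len(pubs),
        mean_proteins_per_publication=len(pairs) / len(pubs),
        n_single_protein_publications=sum(
            1 for accs in proteins_per_pub.values() if len(accs) == 1
        ),
        mean_publications_per_protein=len(pairs) / len(proteins),
        n_single_publication_proteins=sum(
            1 for pids in pubs_per_protein.values() if len(pids) == 1
        ),
        binding_fraction=len(binding_proteins) / len(proteins),
        binding_record_fraction=n_binding_records / len(primacy),
    )
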