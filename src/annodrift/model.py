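"""Domain model for versioned protein-knowledgebase releases.

A *release* is one dated snapshot of a curated protein knowledgebase
(modeled on document-oriented dumps such as neXtProt's): protein entries
carry an accession, a chromosome assignment, a protein-existence level
(PE1 = existence confirmed at protein level ... PE5 = dubious), and a list
of function annotations. Each annotation belongs to one of six curation
categories, optionally bears a controlled-vocabulary term (GO-like), and
is backed by evidence records; evidence has a kind (two of the five kinds
are experimental), a negative flag (the evidence asserts the *absence* of
the function), and usually a publication reference whose date may be known
only to the year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date


# -- controlled value sets ---------------------------------------------------

PE_LEVELS = ("PE1", "PE2", "PE3", "PE4", "PE5")

CATEGORIES = (
    "catalytic-activity",
    "function-info",
    "go-biological-process",
    "go-molecular-function",
    "pathway",
    "transport-activity",
)

EVIDENCE_KINDS = (
    "direct-assay",
    "physical-interaction",
    "sequence-similarity",
    "curator-inference",
    "author-statement",
)

#: Evidence kinds that reflect a wet-lab experiment (used in manual assertion);
#: only these are admitted to the publication-primacy analysis.
EXPERIMENTAL_KINDS = frozenset({"direct-assay", "physical-interaction"})

CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT", "unknown")

#: Default controlled term for the generic protein-binding function.
BINDING_TERM_ID = "GO:0005515"
BINDING_TERM_LABEL = "protein binding"


class BindingSequenceClass:
    """Five temporal-order categories for when protein binding was first
    shown relative to any other function of the same protein."""

    SAME_PUBLICATION = "SAME_PUBLICATION"
    BINDING_FIRST = "BINDING_FIRST"
    BINDING_AFTER = "BINDING_AFTER"
    OTHER_ONLY = "OTHER_ONLY"
    BINDING_ONLY = "BINDING_ONLY"

    #: Canonical report order (same-publication, binding-first, binding-after,
    #: other-only, binding-only).
    ALL = (SAME_PUBLICATION, BINDING_FIRST, BINDING_AFTER, OTHER_ONLY, BINDING_ONLY)


# -- records -----------------------------------------------------------------


@dataclass(frozen=True)
class PublicationRef:
    """A literature reference. ``year_only`` marks dates whose precision is
    one year; such a date is stored as January 1 of that year and must be
    compared at year granularity (see :func:`compare_pub_dates`)."""

    pub_id: str
    pub_date: date
    year_only: bool = False

    def __post_init__(self) -> None:
        # canonical form: a year-only date is stored as January 1, so the
        # in-memory value carries no more precision than its serialization
        if self.year_only and (self.pub_date.month != 1 or self.pub_date.day != 1):
            object.__setattr__(self, "pub_date", date(self.pub_date.year, 1, 1))

    def sort_key(self) -> tuple:
        """Deterministic total order on publication dates.

        Year-only dates sort before any full date of the same year, so
        selection among records whose dates are *equal* at year granularity
        is stable and reproducible.
        """
        d = self.pub_date
        if self.year_only:
            return (d.year, 0, 0, 0)
        return (d.year, 1, d.month, d.day)


def compare_pub_dates(a: PublicationRef, b: PublicationRef) -> int:
    """Three-way comparison honouring date granularity.

    If either side is year-only, only the years are compared; a year-only
    date neither precedes nor follows a full date in the same year (0).
    Returns -1, 0 or 1.
    """
    if a.year_only or b.year_only:
        x, y = a.pub_date.year, b.pub_date.year
    else:
        x, y = a.pub_date, b.pub_date
    return (x > y) - (x < y)


@dataclass
class Evidence:
    """One piece of evidence backing a function annotation."""

    kind: str
    is_negative: bool = False
    publication: PublicationRef | None = None


@dataclass
class FunctionAnnotation:
    """A function record in one of the six curation categories.

    Annotations without a ``term_id`` are *uncontrolled*: they carry free
    text only and cannot participate in term-frequency analyses.
    """

    category: str
    term_id: str | None = None
    term_label: str | None = None
    evidences: list[Evidence] = field(default_factory=list)

    @property
    def is_controlled(self) -> bool:
        return self.term_id is not None

    def key(self) -> tuple[str, str | None]:
        """Function key used for diffing and primacy: (category, term_id)."""
        return (self.category, self.term_id)


@dataclass
class ProteinEntry:
    accession: str
    chromosome: str = "unknown"
    existence_level: str = "PE1"
    annotations: list[FunctionAnnotation] = field(default_factory=list)


@dataclass(frozen=True)
class ReleaseMeta:
    release_id: str
    release_date: date


@dataclass
class Release:
    """One dated snapshot of the knowledgebase."""

    meta: ReleaseMeta
    entries: list[ProteinEntry] = field(default_factory=list)

    def entry_map(self) -> dict[str, ProteinEntry]:
        return {e.accession: e for e in self.entries}


# -- validation --------------------------------------------------------------


def validate_release(release: Release) -> list[str]:
    """Check every model invariant; return human-readable violations.

    An empty list means the release is valid. Each message names the
    offending entry accession (where there is one) and the violated rule.
    Negative evidence is legal and produces no violation.
    """
    violations: list[str] = []
    if not release.meta.release_id:
        violations.append("release: release_id must be nonempty")
    if not isinstance(release.meta.release_date, date):
        violations.append("release: release_date must be a calendar date")

    seen: set[str] = set()
    for i, entry in enumerate(release.entries):
        label = entry.accession or f"<entry #{i}>"
        if not entry.accession:
            violations.append(f"{label}: accession must be nonempty")
        elif entry.accession in seen:
            violations.append(f"{label}: duplicate accession in release")
        seen.add(entry.accession)
        if entry.chromosome not in CHROMOSOMES:
            violations.append(f"{label}: unknown chromosome {entry.chromosome!r}")
        if entry.existence_level not in PE_LEVELS:
            violations.append(
                f"{label}: existence_level {entry.existence_level!r} "
                f"is not one of {', '.join(PE_LEVELS)}"
            )
        for ann in entry.annotations:
            if ann.category not in CATEGORIES:
                violations.append(
                    f"{label}: annotation category {ann.category!r} "
                    f"is not one of the six curation categories"
                )
            for ev in ann.evidences:
                if ev.kind not in EVIDENCE_KINDS:
                    violations.append(
                        f"{label}: evidence kind {ev.kind!r} is not recognised"
                    )
                if ev.publication is not None and not ev.publication.pub_id:
                    violations.append(f"{label}: publication pub_id must be nonempty")
    return violations
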