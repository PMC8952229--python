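"""Seeded synthetic release series with recorded ground truth.

The generator emulates the observable structure of a curated protein
knowledgebase evolving across yearly releases: a mostly stable set of
protein entries, per-category accrual of function annotations, occasional
removal of previously published annotations (curation drift), a mixture of
experimental and inferential evidence, a small amount of negative
evidence, and publications whose dates are sometimes known only to the
year.

Every annotation, evidence record and removal the generator emits is
recorded in an :class:`EmissionLog`, which downstream tests use as ground
truth for parameter recovery. A second entry point builds single-release
fixtures realizing each of the five binding-sequence temporal classes with
configurable multiplicities, so that the primacy classifier can be checked
for exact recovery.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .model import (
    BINDING_TERM_ID,
    BINDING_TERM_LABEL,
    CATEGORIES,
    BindingSequenceClass,
    Evidence,
    FunctionAnnotation,
    ProteinEntry,
    PublicationRef,
    Release,
    ReleaseMeta,
)

logger = logging.getLogger(__name__)

#: Flat GO-like vocabulary (no DAG structure). The literal label
#: "protein binding" is always present so term analyses can exercise its
#: named exclusion rule.
VOCABULARY: tuple[tuple[str, str], ...] = (
    (BINDING_TERM_ID, BINDING_TERM_LABEL),
    ("GO:0005524", "ATP binding"),
    ("GO:0003677", "DNA binding"),
    ("GO:0003723", "RNA binding"),
    ("GO:0003823", "antigen binding"),
    ("GO:0034987", "immunoglobulin receptor binding"),
    ("GO:0005509", "calcium ion binding"),
    ("GO:0008270", "zinc ion binding"),
    ("GO:0016301", "kinase activity"),
    ("GO:0004674", "protein serine/threonine kinase activity"),
    ("GO:0003700", "DNA-binding transcription factor activity"),
    ("GO:0003924", "GTPase activity"),
    ("GO:0061630", "ubiquitin protein ligase activity"),
    ("GO:0003824", "catalytic activity"),
    ("GO:0005215", "transporter activity"),
    ("GO:0006355", "regulation of transcription, DNA-templated"),
    ("GO:0006357", "regulation of transcription by RNA polymerase II"),
    ("GO:0055114", "oxidation-reduction process"),
    ("GO:0006955", "immune response"),
    ("GO:0002250", "adaptive immune response"),
    ("GO:0045087", "innate immune response"),
    ("GO:0002377", "immunoglobulin production"),
    ("GO:0006910", "phagocytosis, recognition"),
    ("GO:0006911", "phagocytosis, engulfment"),
    ("GO:0050853", "B cell receptor signaling pathway"),
    ("GO:0006958", "complement activation, classical pathway"),
    ("GO:0042742", "defense response to bacterium"),
    ("GO:0050871", "positive regulation of B cell activation"),
    ("GO:0007165", "signal transduction"),
    ("GO:0006915", "apoptotic process"),
    ("GO:0007155", "cell adhesion"),
    ("GO:0006508", "proteolysis"),
    ("GO:0006629", "lipid metabolic process"),
    ("GO:0006811", "ion transport"),
    ("GO:0015031", "protein transport"),
    ("GO:0006338", "chromatin remodeling"),
    ("GO:0030154", "cell differentiation"),
    ("GO:0006412", "translation"),
    ("GO:0000398", "mRNA splicing, via spliceosome"),
    ("GO:0006468", "protein phosphorylation"),
)

_NON_EXPERIMENTAL = ("sequence-similarity", "curator-inference", "author-statement")


class ConfigError(ValueError):
    """An impossible or inconsistent generator configuration."""


# -- configs -----------------------------------------------------------------


class SeriesConfig(BaseModel):
    """Parameters of a synthetic release series.

    Defaults sketch a desk-scale analogue of a decade of yearly releases:
    a few hundred proteins, mostly PE1, category accrual dominated by
    GO biological-process and molecular-function records, a predominantly
    experimental evidence mixture, a handful of removals and a few negative
    evidence records.
    """

    n_proteins: int = Field(default=200, ge=0)
    n_releases: int = Field(default=10, ge=1)
    release_dates: list[date] = Field(
        default_factory=lambda: [date(2011 + i, 1, 15) for i in range(10)]
    )
    pe1_fraction: float = Field(default=0.85, ge=0.0, le=1.0)
    per_category_rates: dict[str, float] = Field(
        default_factory=lambda: {
            "catalytic-activity": 1.0,
            "function-info": 12.0,
            "go-biological-process": 40.0,
            "go-molecular-function": 24.0,
            "pathway": 20.0,
            "transport-activity": 1.5,
        }
    )
    removal_count: int = Field(default=5, ge=0)
    negative_evidence_count: int = Field(default=3, ge=0)
    experimental_fraction: float = Field(default=0.4, ge=0.0, le=1.0)
    term_vocabulary_size: int = Field(default=30, ge=1, le=len(VOCABULARY))
    year_only_fraction: float = Field(default=0.1, ge=0.0, le=1.0)
    seed: int = 0

    @field_validator("per_category_rates")
    @classmethod
    def _rates_valid(cls, v: dict[str, float]) -> dict[str, float]:
        for cat, rate in v.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown annotation category {cat!r}")
            if rate < 0:
                raise ValueError(f"rate for {cat} must be >= 0")
        return v

    @model_validator(mode="after")
    def _dates_match(self) -> "SeriesConfig":
        if len(self.release_dates) != self.n_releases:
            raise ValueError(
                f"len(release_dates)={len(self.release_dates)} != n_releases={self.n_releases}"
            )
        for a, b in zip(self.release_dates, self.release_dates[1:]):
            if b <= a:
                raise ValueError("release_dates must strictly increase")
        return self


class SequencingScenarioConfig(BaseModel):
    """Shape of a binding-sequence classification fixture.

    ``multiplicities`` gives the number of proteins to realize per temporal
    class; ``date_spacing`` is the gap in days between the earlier and the
    later publication in the two-date classes; ``year_only_fraction`` makes
    that fraction of publication dates year-precision only (deliberately
    introducing primacy ambiguity).
    """

    multiplicities: dict[str, int]
    date_spacing: int = Field(default=30, ge=0)
    year_only_fraction: float = Field(default=0.0, ge=0.0, le=1.0)

    @field_validator("multiplicities")
    @classmethod
    def _exactly_five(cls, v: dict[str, int]) -> dict[str, int]:
        if set(v) != set(BindingSequenceClass.ALL):
            raise ValueError(
                "multiplicities must have exactly the five binding-sequence classes as keys"
            )
        for cls_name, count in v.items():
            if count < 0:
                raise ValueError(f"multiplicity for {cls_name} must be >= 0")
        return v


# -- emission log ------------------------------------------------------------


@dataclass(frozen=True)
class EvidenceEmission:
    kind: str
    is_negative: bool
    pub_id: str | None
    pub_date: str | None  # ISO date, or "YYYY" when year-only
    year_only: bool


@dataclass(frozen=True)
class AnnotationEmission:
    release_id: str
    accession: str
    category: str
    term_id: str | None
    term_label: str | None
    evidences: tuple[EvidenceEmission, ...]


@dataclass(frozen=True)
class RemovalEmission:
    accession: str
    category: str
    term_id: str | None
    release_present: str  # last release still containing the annotation
    release_absent: str  # first release it is missing from


@dataclass
class EmissionLog:
    """Ground truth of everything a generator run emitted."""

    additions: list[AnnotationEmission] = field(default_factory=list)
    removals: list[RemovalEmission] = field(default_factory=list)
    true_classes: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        doc = {
            "additions": [asdict(a) for a in self.additions],
            "removals": [asdict(r) for r in self.removals],
            "true_classes": dict(sorted(self.true_classes.items())),
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    def category_totals(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for a in self.additions:
            totals[a.category] = totals.get(a.category, 0) + 1
        return totals


# -- series generation -------------------------------------------------------


def _accession(i: int) -> str:
    return f"NX_P{i:05d}"


def _pub_date_near(rng: np.random.Generator, release_date: date) -> date:
    # publications precede the release that curates them by 1-24 months
    return release_date - timedelta(days=int(rng.integers(30, 720)))


def generate_series(config: SeriesConfig) -> tuple[list[Release], EmissionLog]:
    """Generate a deterministic series of releases plus its ground truth.

    Annotation counts per release and category are Poisson draws from
    ``per_category_rates``; exactly ``removal_count`` annotations created
    before the final release are removed in a later release (so each
    removal is observable as presence-then-absence); exactly
    ``negative_evidence_count`` evidence records carry the negative flag.
    """
    rng = np.random.default_rng(config.seed)
    n_rel = config.n_releases
    vocab = VOCABULARY[: config.term_vocabulary_size]
    chromosomes = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")

    proteins = []
    for i in range(config.n_proteins):
        pe = "PE1" if rng.random() < config.pe1_fraction else f"PE{int(rng.integers(2, 6))}"
        proteins.append(
            ProteinEntry(
                accession=_accession(i),
                chromosome=str(rng.choice(chromosomes)),
                existence_level=pe,
            )
        )

    # plan annotation creations: (release_idx, accession, category, term_id, label)
    pub_counter = 0
    creations: list[dict] = []
    existing_keys: set[tuple[str, str, str | None]] = set()
    all_evidences: list[Evidence] = []
    release_ids = [f"rel-{d.isoformat()}" for d in config.release_dates]

    for r in range(n_rel):
        for category in CATEGORIES:
            rate = config.per_category_rates.get(category, 0.0)
            if rate <= 0 or config.n_proteins == 0:
                continue
            k = int(rng.poisson(rate))
            for _ in range(k):
                acc = _accession(int(rng.integers(config.n_proteins)))
                if category == "function-info" or rng.random() < 0.15:
                    term_id, label = None, None  # uncontrolled record
                else:
                    term_id, label = vocab[int(rng.integers(len(vocab)))]
                if (acc, category, term_id) in existing_keys:
                    continue  # keep (accession, category, term) unique
                existing_keys.add((acc, category, term_id))

                evidences = []
                for _ in range(1 + int(rng.integers(0, 2))):
                    if rng.random() < config.experimental_fraction:
                        kind = ("direct-assay", "physical-interaction")[int(rng.integers(2))]
                    else:
                        kind = _NON_EXPERIMENTAL[int(rng.integers(3))]
                    if rng.random() < 0.9:
                        pub_counter += 1
                        year_only = bool(rng.random() < config.year_only_fraction)
                        publication = PublicationRef(
                            pub_id=f"PMID:{100000 + pub_counter}",
                            pub_date=_pub_date_near(rng, config.release_dates[r]),
                            year_only=year_only,
                        )
                    else:
                        publication = None
                    ev = Evidence(kind=kind, is_negative=False, publication=publication)
                    evidences.append(ev)
                    all_evidences.append(ev)
                creations.append(
                    dict(
                        release_idx=r,
                        accession=acc,
                        category=category,
                        term_id=term_id,
                        term_label=label,
                        evidences=evidences,
                        removed_at=None,
                    )
                )

    # negative flags on exactly negative_evidence_count evidence records
    if config.negative_evidence_count > len(all_evidences):
        raise ConfigError(
            f"negative_evidence_count={config.negative_evidence_count} exceeds the "
            f"{len(all_evidences)} evidence records generated"
        )
    if config.negative_evidence_count:
        for idx in rng.choice(
            len(all_evidences), size=config.negative_evidence_count, replace=False
        ):
            all_evidences[int(idx)].is_negative = True

    # removals: only annotations created before the final release are eligible,
    # so every removal is observable as presence followed by absence
    eligible = [i for i, c in enumerate(creations) if c["release_idx"] < n_rel - 1]
    if config.removal_count > len(eligible):
        raise ConfigError(
            f"removal_count={config.removal_count} exceeds the {len(eligible)} "
            f"annotations created before the final release"
        )
    log = EmissionLog()
    if config.removal_count:
        chosen = rng.choice(len(eligible), size=config.removal_count, replace=False)
        for idx in sorted(int(i) for i in chosen):
            c = creations[eligible[idx]]
            j = int(rng.integers(c["release_idx"] + 1, n_rel))
            c["removed_at"] = j
            log.removals.append(
                RemovalEmission(
                    accession=c["accession"],
                    category=c["category"],
                    term_id=c["term_id"],
                    release_present=release_ids[j - 1],
                    release_absent=release_ids[j],
                )
            )

    for c in creations:
        log.additions.append(
            AnnotationEmission(
                release_id=release_ids[c["release_idx"]],
                accession=c["accession"],
                category=c["category"],
                term_id=c["term_id"],
                term_label=c["term_label"],
                evidences=tuple(
                    EvidenceEmission(
                        kind=ev.kind,
                        is_negative=ev.is_negative,
                        pub_id=ev.publication.pub_id if ev.publication else None,
                        pub_date=(
                            None
                            if ev.publication is None
                            else str(ev.publication.pub_date.year)
                            if ev.publication.year_only
                            else ev.publication.pub_date.isoformat()
                        ),
                        year_only=bool(ev.publication and ev.publication.year_only),
                    )
                    for ev in c["evidences"]
                ),
            )
        )

    releases: list[Release] = []
    for r in range(n_rel):
        entries = []
        for p in proteins:
            anns = [
                FunctionAnnotation(
                    category=c["category"],
                    term_id=c["term_id"],
                    term_label=c["term_label"],
                    evidences=c["evidences"],
                )
                for c in creations
                if c["accession"] == p.accession
                and c["release_idx"] <= r
                and (c["removed_at"] is None or r < c["removed_at"])
            ]
            entries.append(
                ProteinEntry(
                    accession=p.accession,
                    chromosome=p.chromosome,
                    existence_level=p.existence_level,
                    annotations=anns,
                )
            )
        releases.append(
            Release(
                meta=ReleaseMeta(
                    release_id=release_ids[r], release_date=config.release_dates[r]
                ),
                entries=entries,
            )
        )
    return releases, log


# -- binding-sequence fixtures ----------------------------------------------

_OTHER_TERMS = tuple(
    (tid, label) for tid, label in VOCABULARY if tid != BINDING_TERM_ID
)


def generate_sequencing_fixture(
    config: SequencingScenarioConfig, seed: int
) -> tuple[Release, EmissionLog]:
    """Build a single release realizing each temporal class exactly
    ``multiplicities[class]`` times, with ground-truth classes recorded.

    Publication-date patterns per class (d = a per-protein base date,
    s = ``date_spacing`` days):

    - SAME_PUBLICATION: binding and one other function cite one shared
      publication dated d.
    - BINDING_FIRST: binding published at d, the other function at d + s.
    - BINDING_AFTER: the other function at d, binding at d + s.
    - OTHER_ONLY: a single non-binding function at d.
    - BINDING_ONLY: a single binding annotation at d.

    With full-precision dates and s >= 1 the classifier must recover the
    multiplicities exactly. Year-only dates with s smaller than a year (in
    particular ``date_spacing=0``) make the two-date patterns ambiguous on
    purpose; a warning is emitted, not an error.
    """
    rng = np.random.default_rng(seed)
    if config.year_only_fraction > 0 and config.date_spacing == 0:
        msg = "date_spacing=0 with year-only dates: temporal classes will be ambiguous"
        logger.warning(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)

    entries: list[ProteinEntry] = []
    log = EmissionLog()
    release_id = "seqfix"
    pub_counter = 0
    protein_counter = 0
    spacing = timedelta(days=config.date_spacing)

    def next_pub(d: date) -> PublicationRef:
        nonlocal pub_counter
        pub_counter += 1
        year_only = bool(rng.random() < config.year_only_fraction)
        return PublicationRef(f"PMID:{500000 + pub_counter}", d, year_only=year_only)

    def binding_annotation(pub: PublicationRef) -> FunctionAnnotation:
        return FunctionAnnotation(
            category="go-molecular-function",
            term_id=BINDING_TERM_ID,
            term_label=BINDING_TERM_LABEL,
            evidences=[Evidence("physical-interaction", publication=pub)],
        )

    def other_annotation(pub: PublicationRef) -> FunctionAnnotation:
        tid, label = _OTHER_TERMS[int(rng.integers(len(_OTHER_TERMS)))]
        return FunctionAnnotation(
            category="go-molecular-function",
            term_id=tid,
            term_label=label,
            evidences=[Evidence("direct-assay", publication=pub)],
        )

    for cls_name in BindingSequenceClass.ALL:
        for _ in range(config.multiplicities[cls_name]):
            # spread base dates so proteins do not share publication dates
            base = date(2016, 1, 1) + timedelta(days=int(rng.integers(0, 1400)))
            anns: list[FunctionAnnotation]
            if cls_name == BindingSequenceClass.SAME_PUBLICATION:
                shared = next_pub(base)
                anns = [binding_annotation(shared), other_annotation(shared)]
            elif cls_name == BindingSequenceClass.BINDING_FIRST:
                anns = [
                    binding_annotation(next_pub(base)),
                    other_annotation(next_pub(base + spacing)),
                ]
            elif cls_name == BindingSequenceClass.BINDING_AFTER:
                anns = [
                    other_annotation(next_pub(base)),
                    binding_annotation(next_pub(base + spacing)),
                ]
            elif cls_name == BindingSequenceClass.OTHER_ONLY:
                anns = [other_annotation(next_pub(base))]
            else:  # BINDING_ONLY
                anns = [binding_annotation(next_pub(base))]

            acc = _accession(90000 + protein_counter)
            protein_counter += 1
            entries.append(
                ProteinEntry(
                    accession=acc,
                    chromosome=str(int(rng.integers(1, 23))),
                    existence_level="PE1",
                    annotations=anns,
                )
            )
            log.true_classes[acc] = cls_name
            for ann in anns:
                pub = ann.evidences[0].publication
                log.additions.append(
                    AnnotationEmission(
                        release_id=release_id,
                        accession=acc,
                        category=ann.category,
                        term_id=ann.term_id,
                        term_label=ann.term_label,
                        evidences=(
                            EvidenceEmission(
                                kind=ann.evidences[0].kind,
                                is_negative=False,
                                pub_id=pub.pub_id,
                                pub_date=str(pub.pub_date.year)
                                if pub.year_only
                                else pub.pub_date.isoformat(),
                                year_only=pub.year_only,
                            ),
                        ),
                    )
                )

    release = Release(
        meta=ReleaseMeta(release_id=release_id, release_date=date(2021, 1, 15)),
        entries=entries,
    )
    return release, log
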