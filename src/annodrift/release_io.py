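"""Reading and writing the versioned-release XML dialect.

The dialect is defined by this package (the real knowledgebase XSD is out
of scope); it is documented in ``schemas/release.xsd`` and looks like::

    <release id="2017-01" date="2017-01-15">
      <entry accession="NX_P00001" chromosome="7" existence-level="PE1">
        <annotation category="go-molecular-function"
                    term-id="GO:0005515" term-label="protein binding">
          <evidence kind="direct-assay" negative="false">
            <publication id="PMID:100" date="2016-03-04" granularity="day"/>
          </evidence>
        </annotation>
      </entry>
    </release>

Year-only publication dates serialize as ``date="2016"`` with
``granularity="year"`` so downstream primacy analysis knows the precision.
Unknown elements are ignored with a warning; unknown evidence kinds are
mapped to ``curator-inference`` with a warning (fixtures stay forward
compatible). The parser never silently drops an entry: a schema violation
raises instead.
"""

from __future__ import annotations

import logging
from datetime import date
from importlib import resources
from pathlib import Path

from lxml import etree

from .model import (
    CATEGORIES,
    EVIDENCE_KINDS,
    Evidence,
    FunctionAnnotation,
    ProteinEntry,
    PublicationRef,
    Release,
    ReleaseMeta,
    validate_release,
)

logger = logging.getLogger(__name__)

_KNOWN_CHILDREN = {
    "release": {"entry"},
    "entry": {"annotation"},
    "annotation": {"evidence"},
    "evidence": {"publication"},
}


class ReleaseParseError(ValueError):
    """Malformed XML or structurally unreadable release file."""


class ReleaseValidationError(ValueError):
    """Well-formed XML that violates a model invariant."""


def _warn_unknown(elem: etree._Element) -> None:
    known = _KNOWN_CHILDREN.get(elem.tag, set())
    for child in elem:
        if not isinstance(child.tag, str):  # comments / PIs
            continue
        if child.tag not in known:
            logger.warning("ignoring unknown element <%s> under <%s>", child.tag, elem.tag)


def _parse_publication(elem: etree._Element, context: str) -> PublicationRef:
    pub_id = elem.get("id")
    raw = elem.get("date")
    gran = elem.get("granularity", "day")
    if pub_id is None or raw is None:
        raise ReleaseValidationError(f"{context}: publication needs id and date")
    if gran == "year":
        pub_date = date(int(raw), 1, 1)
        year_only = True
    else:
        pub_date = date.fromisoformat(raw)
        year_only = False
    return PublicationRef(pub_id=pub_id, pub_date=pub_date, year_only=year_only)


def _parse_evidence(elem: etree._Element, context: str) -> Evidence:
    kind = elem.get("kind", "curator-inference")
    if kind not in EVIDENCE_KINDS:
        logger.warning(
            "%s: unknown evidence kind %r mapped to curator-inference", context, kind
        )
        kind = "curator-inference"
    negative = elem.get("negative", "false").lower() == "true"
    _warn_unknown(elem)
    pub_elem = elem.find("publication")
    publication = _parse_publication(pub_elem, context) if pub_elem is not None else None
    return Evidence(kind=kind, is_negative=negative, publication=publication)


def _parse_annotation(elem: etree._Element, context: str) -> FunctionAnnotation:
    category = elem.get("category")
    if category not in CATEGORIES:
        raise ReleaseValidationError(
            f"{context}: annotation category {category!r} is not one of the "
            f"six curation categories"
        )
    _warn_unknown(elem)
    return FunctionAnnotation(
        category=category,
        term_id=elem.get("term-id"),
        term_label=elem.get("term-label"),
        evidences=[_parse_evidence(ev, context) for ev in elem.findall("evidence")],
    )


def read_release(path: str | Path) -> Release:
    """Parse one release file into a :class:`Release`.

    Raises :class:`ReleaseParseError` (naming the line) on malformed XML and
    :class:`ReleaseValidationError` (naming the entry) on schema violations
    such as a missing accession, a duplicate accession, or a bad category.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ReleaseParseError(f"{path}: malformed XML at line {exc.lineno}: {exc.msg}") from exc

    root = tree.getroot()
    if root.tag != "release":
        raise ReleaseParseError(f"{path}: root element is <{root.tag}>, expected <release>")
    release_id = root.get("id")
    raw_date = root.get("date")
    if not release_id or not raw_date:
        raise ReleaseValidationError(f"{path}: <release> needs nonempty id and date")
    _warn_unknown(root)

    entries: list[ProteinEntry] = []
    seen: set[str] = set()
    for i, elem in enumerate(root.findall("entry")):
        accession = elem.get("accession")
        if not accession:
            raise ReleaseValidationError(f"{path}: entry #{i} is missing an accession")
        if accession in seen:
            raise ReleaseValidationError(f"{path}: duplicate accession {accession}")
        seen.add(accession)
        _warn_unknown(elem)
        entries.append(
            ProteinEntry(
                accession=accession,
                chromosome=elem.get("chromosome", "unknown"),
                existence_level=elem.get("existence-level", "PE1"),
                annotations=[
                    _parse_annotation(a, accession) for a in elem.findall("annotation")
                ],
            )
        )
    return Release(
        meta=ReleaseMeta(release_id=release_id, release_date=date.fromisoformat(raw_date)),
        entries=entries,
    )


def release_to_bytes(release: Release) -> bytes:
    """Serialize a release to UTF-8 XML bytes (deterministic)."""
    violations = validate_release(release)
    if violations:
        raise ReleaseValidationError(
            "refusing to write invalid release: " + "; ".join(violations)
        )
    root = etree.Element(
        "release",
        id=release.meta.release_id,
        date=release.meta.release_date.isoformat(),
    )
    for entry in release.entries:
        e = etree.SubElement(
            root,
            "entry",
            accession=entry.accession,
            chromosome=entry.chromosome,
        )
        e.set("existence-level", entry.existence_level)
        for ann in entry.annotations:
            a = etree.SubElement(e, "annotation", category=ann.category)
            if ann.term_id is not None:
                a.set("term-id", ann.term_id)
            if ann.term_label is not None:
                a.set("term-label", ann.term_label)
            for ev in ann.evidences:
                v = etree.SubElement(a, "evidence", kind=ev.kind)
                v.set("negative", "true" if ev.is_negative else "false")
                if ev.publication is not None:
                    pub = ev.publication
                    p = etree.SubElement(v, "publication", id=pub.pub_id)
                    if pub.year_only:
                        p.set("date", str(pub.pub_date.year))
                        p.set("granularity", "year")
                    else:
                        p.set("date", pub.pub_date.isoformat())
                        p.set("granularity", "day")
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def write_release(release: Release, path: str | Path) -> None:
    """Write a release; refuses (raises) if any model invariant is violated.

    ``read_release(write_release(r))`` reproduces ``r`` field-for-field.
    """
    Path(path).write_bytes(release_to_bytes(release))


def schema_path() -> Path:
    """Filesystem path of the bundled XSD for the release dialect."""
    return Path(str(resources.files("annodrift") / "schemas" / "release.xsd"))


def validate_against_schema(path: str | Path) -> None:
    """Validate a release file against the bundled XSD; raises on failure."""
    schema = etree.XMLSchema(etree.parse(str(schema_path())))
    doc = etree.parse(str(path))
    schema.assertValid(doc)
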