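"""Shared fixtures and handmade-release builders."""

from __future__ import annotations

from datetime import date

import pytest
from hypothesis import settings

from annodrift import (
    Evidence,
    FunctionAnnotation,
    ProteinEntry,
    PublicationRef,
    Release,
    ReleaseMeta,
    SeriesConfig,
    generate_series,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def pub(pid: str, iso: str, year_only: bool = False) -> PublicationRef:
    if year_only:
        return PublicationRef(pid, date(int(iso), 1, 1), year_only=True)
    return PublicationRef(pid, date.fromisoformat(iso))


def ev(kind: str = "direct-assay", neg: bool = False, publication=None) -> Evidence:
    return Evidence(kind=kind, is_negative=neg, publication=publication)


def ann(
    category: str = "go-molecular-function",
    term_id: str | None = None,
    term_label: str | None = None,
    evidences=(),
) -> FunctionAnnotation:
    return FunctionAnnotation(
        category=category,
        term_id=term_id,
        term_label=term_label,
        evidences=list(evidences),
    )


def entry(acc: str, annotations=(), pe: str = "PE1", chrom: str = "1") -> ProteinEntry:
    return ProteinEntry(
        accession=acc,
        chromosome=chrom,
        existence_level=pe,
        annotations=list(annotations),
    )


def release(release_id: str, iso_date: str, entries=()) -> Release:
    return Release(
        meta=ReleaseMeta(release_id=release_id, release_date=date.fromisoformat(iso_date)),
        entries=list(entries),
    )


@pytest.fixture(scope="session")
def default_series():
    """A 10-release synthetic series with removals and negative evidence."""
    return generate_series(SeriesConfig(seed=11))


@pytest.fixture(scope="session")
def tiny_series():
    """A small fast series for I/O-heavy tests."""
    config = SeriesConfig(
        n_proteins=40,
        n_releases=4,
        release_dates=[date(2016 + i, 1, 15) for i in range(4)],
        removal_count=3,
        negative_evidence_count=2,
        seed=5,
    )
    return generate_series(config)
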