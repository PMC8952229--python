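"""Cross-release comparison of a knowledgebase series.

All counting here follows the version-comparison stage of the analysis:
only PE1 entries (protein existence confirmed at protein level) are
counted, and a protein counts as *annotated* as soon as it carries at
least one function record of any category — the evidence base behind the
record is deliberately not examined at this stage. A *removal case* is a
(accession, category, term_id) triple present in an earlier release and
absent from a later one; re-additions after a removal still count as one
case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

from .model import Release

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RemovedFunctionCase:
    accession: str
    category: str
    term_id: str | None
    release_present: str  # last release the annotation was still in
    release_absent: str  # first release it is missing from


@dataclass
class DiffReport:
    per_release_pe1_counts: dict[str, int] = field(default_factory=dict)
    per_release_annotated_counts: dict[str, int] = field(default_factory=dict)
    per_chromosome_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    removed_function_cases: list[RemovedFunctionCase] = field(default_factory=list)
    never_annotated: set[str] = field(default_factory=set)
    unmapped_accessions: dict[str, set[str]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "per_release_pe1_counts": self.per_release_pe1_counts,
            "per_release_annotated_counts": self.per_release_annotated_counts,
            "per_chromosome_counts": {
                f"{rid}/{chrom}": n
                for (rid, chrom), n in sorted(self.per_chromosome_counts.items())
            },
            "removed_function_cases": [
                {
                    "accession": c.accession,
                    "category": c.category,
                    "term_id": c.term_id,
                    "release_present": c.release_present,
                    "release_absent": c.release_absent,
                }
                for c in self.removed_function_cases
            ],
            "never_annotated": sorted(self.never_annotated),
            "unmapped_accessions": {
                rid: sorted(accs) for rid, accs in sorted(self.unmapped_accessions.items())
            },
        }


def _sorted_series(series: list[Release]) -> list[Release]:
    if not series:
        raise ValueError("release series is empty")
    return sorted(series, key=lambda r: r.meta.release_date)


def map_to_reference(
    series: list[Release], reference: Release | None = None
) -> tuple[dict[str, str], set[str]]:
    """Map accessions of every release onto the reference (latest) release.

    Mapping is the identity on shared accessions; accessions that occur in
    some release but not in the reference form the unmapped set (proteins
    retired before the reference snapshot, reported separately).
    """
    series = _sorted_series(series)
    if reference is None:
        reference = series[-1]
    ref_accs = {e.accession for e in reference.entries}
    mapping: dict[str, str] = {}
    unmapped: set[str] = set()
    for release in series:
        for entry in release.entries:
            if entry.accession in ref_accs:
                mapping[entry.accession] = entry.accession
            else:
                unmapped.add(entry.accession)
    return mapping, unmapped


def count_functional_status(series: list[Release]) -> DiffReport:
    """Per-release PE1 / annotated-PE1 counts with a chromosome breakdown.

    ``per_chromosome_counts[(release_id, chromosome)]`` counts PE1 entries.
    Chromosome labels are taken from each release verbatim; if one
    accession carries conflicting labels across releases the latest
    release wins for the reference-level sets (logged).
    """
    series = _sorted_series(series)
    report = DiffReport()
    for release in series:
        rid = release.meta.release_id
        pe1 = [e for e in release.entries if e.existence_level == "PE1"]
        report.per_release_pe1_counts[rid] = len(pe1)
        report.per_release_annotated_counts[rid] = sum(
            1 for e in pe1 if len(e.annotations) > 0
        )
        for e in pe1:
            key = (rid, e.chromosome)
            report.per_chromosome_counts[key] = report.per_chromosome_counts.get(key, 0) + 1

    # reference-level sets
    reference = series[-1]
    ever_annotated: set[str] = set()
    for release in series:
        for e in release.entries:
            if e.annotations:
                ever_annotated.add(e.accession)
    report.never_annotated = {
        e.accession
        for e in reference.entries
        if e.existence_level == "PE1" and e.accession not in ever_annotated
    }
    ref_accs = {e.accession for e in reference.entries}
    for release in series[:-1]:
        missing = {e.accession for e in release.entries} - ref_accs
        if missing:
            report.unmapped_accessions[release.meta.release_id] = missing
    return report


def detect_removed_functions(series: list[Release]) -> list[RemovedFunctionCase]:
    """Find annotations present in an earlier release and absent later.

    One case is reported per (accession, category, term_id), at the
    *earliest* release where the annotation is first missing; later
    re-additions (and re-removals) do not create further cases. Requires
    at least two releases.
    """
    series = _sorted_series(series)
    if len(series) < 2:
        raise ValueError("removed-function detection needs at least two releases")

    last_present: dict[tuple[str, str, str | None], str] = {}
    reported: set[tuple[str, str, str | None]] = set()
    cases: list[RemovedFunctionCase] = []
    for release in series:
        rid = release.meta.release_id
        current: set[tuple[str, str, str | None]] = set()
        for entry in release.entries:
            for ann in entry.annotations:
                current.add((entry.accession, ann.category, ann.term_id))
        for key, present_rid in list(last_present.items()):
            if key not in current and key not in reported:
                cases.append(
                    RemovedFunctionCase(
                        accession=key[0],
                        category=key[1],
                        term_id=key[2],
                        release_present=present_rid,
                        release_absent=rid,
                    )
                )
                reported.add(key)
        for key in current:
            last_present[key] = rid
    cases.sort(key=lambda c: (c.accession, c.category, c.term_id or ""))
    return cases


def newly_annotated(
    series: list[Release], window_start: date, window_end: date
) -> set[str]:
    """Accessions whose function annotation *arrived* during the window.

    A protein qualifies if the first release in which it carries any
    function annotation falls inside [window_start, window_end], or if all
    its annotations had been removed before the window and it was
    re-annotated within it. Proteins already annotated in the baseline
    (earliest) release were "previously known" and never qualify through
    the first path, whatever the window.
    """
    series = _sorted_series(series)
    span = (series[0].meta.release_date, series[-1].meta.release_date)
    if window_start > window_end:
        raise ValueError("window_start must not exceed window_end")
    if window_end < span[0] or window_start > span[1]:
        raise ValueError(
            f"window [{window_start}, {window_end}] lies outside the series span "
            f"[{span[0]}, {span[1]}]"
        )

    result: set[str] = set()
    # state per accession: None = never annotated; True = currently annotated;
    # (False, zero_date) = annotated once, currently bare
    state: dict[str, object] = {}
    baseline_date = series[0].meta.release_date
    for release in series:
        d = release.meta.release_date
        baseline = d == baseline_date
        for entry in release.entries:
            acc = entry.accession
            annotated = len(entry.annotations) > 0
            prev = state.get(acc)
            if annotated:
                if prev is None:
                    if not baseline and window_start <= d <= window_end:
                        result.add(acc)
                elif isinstance(prev, tuple):
                    zero_date = prev[1]
                    if zero_date < window_start and window_start <= d <= window_end:
                        result.add(acc)
                state[acc] = True
            elif prev is True:
                state[acc] = (False, d)
    return result


def build_diff_report(series: list[Release]) -> DiffReport:
    """Full cross-release report: counts, removal cases, unmapped sets."""
    report = count_functional_status(series)
    if len(series) >= 2:
        report.removed_function_cases = detect_removed_functions(series)
    return report
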