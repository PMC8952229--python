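"""Term-frequency accounting, trend partition and tag-cloud scaling.

Frequencies count distinct proteins, not annotation records: a term's
*lifetime count* is the number of proteins whose first release carrying
that controlled term falls anywhere in the series, and its *window count*
restricts those first appearances to an analysis window. Uncontrolled
records (no term id) are ignored throughout.

For tag-cloud export raw frequencies x are squashed onto [1, 20] by the
min-max affine map

    x' = 1 + 19 * (x - xmin) / (xmax - xmin)

computed after dropping excluded labels (by default the over-represented,
uninformative "protein binding"). When every term has the same frequency
the map is undefined and every score is set to 1, the bottom of the range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

from .model import Release

DEFAULT_EXCLUDE = frozenset({"protein binding"})


@dataclass(frozen=True)
class TermRow:
    term_id: str
    term_label: str
    lifetime_count: int
    window_count: int
    lifetime_rate: float  # first appearances per year over the series span
    window_rate: float  # first appearances per year inside the window


@dataclass
class TermFrequencyTable:
    rows: list[TermRow] = field(default_factory=list)
    span_years: float = 0.0
    window_years: float = 0.0

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class TrendPartition:
    more_frequent: set[str] = field(default_factory=set)
    less_frequent: set[str] = field(default_factory=set)
    stable: set[str] = field(default_factory=set)
    thresholds: tuple[float, float, int] = (1.5, 0.67, 5)


def term_frequencies(
    series: list[Release], window_start: date, window_end: date
) -> TermFrequencyTable:
    """Tabulate per-term protein counts over the series and a window.

    The first appearance of a (accession, term_id) pair is the date of the
    earliest release in which that protein carries that term; the pair
    contributes to the window count iff that date lies inside
    [window_start, window_end].
    """
    if not series:
        raise ValueError("release series is empty")
    series = sorted(series, key=lambda r: r.meta.release_date)
    if window_start > window_end:
        raise ValueError("window_start must not exceed window_end")

    first_seen: dict[tuple[str, str], date] = {}
    labels: dict[str, str] = {}
    for release in series:
        d = release.meta.release_date
        for entry in release.entries:
            for ann in entry.annotations:
                if ann.term_id is None:
                    continue
                key = (entry.accession, ann.term_id)
                if key not in first_seen:
                    first_seen[key] = d
                if ann.term_label is not None:
                    labels.setdefault(ann.term_id, ann.term_label)

    span_years = (series[-1].meta.release_date - series[0].meta.release_date).days / 365.25
    window_years = (window_end - window_start).days / 365.25

    lifetime: dict[str, int] = {}
    window: dict[str, int] = {}
    for (acc, term_id), d in first_seen.items():
        lifetime[term_id] = lifetime.get(term_id, 0) + 1
        if window_start <= d <= window_end:
            window[term_id] = window.get(term_id, 0) + 1

    rows = [
        TermRow(
            term_id=tid,
            term_label=labels.get(tid, tid),
            lifetime_count=life,
            window_count=window.get(tid, 0),
            lifetime_rate=life / span_years if span_years > 0 else 0.0,
            window_rate=window.get(tid, 0) / window_years if window_years > 0 else 0.0,
        )
        for tid, life in sorted(lifetime.items())
    ]
    return TermFrequencyTable(rows=rows, span_years=span_years, window_years=window_years)


def scale_for_cloud(
    table: TermFrequencyTable,
    exclude_labels: frozenset[str] | set[str] = DEFAULT_EXCLUDE,
    count: str = "window",
) -> list[tuple[str, float]]:
    """Min-max scale term frequencies onto [1, 20] for tag-cloud export.

    ``count`` selects the frequency column ("window" or "lifetime").
    Excluded labels are dropped *before* xmin/xmax are computed, so the
    remaining scores use the full [1, 20] range. Raises if nothing is left
    after exclusion.
    """
    if count not in ("window", "lifetime"):
        raise ValueError("count must be 'window' or 'lifetime'")
    kept = [r for r in table.rows if r.term_label not in exclude_labels]
    if not kept:
        raise ValueError("no terms left after exclusion; cannot scale")
    xs = [
        (r.window_count if count == "window" else r.lifetime_count) for r in kept
    ]
    xmin, xmax = min(xs), max(xs)
    if xmax == xmin:
        return [(r.term_label, 1.0) for r in kept]
    return [
        (r.term_label, 1.0 + 19.0 * (x - xmin) / (xmax - xmin))
        for r, x in zip(kept, xs)
    ]


def trend_partition(
    table: TermFrequencyTable,
    r_hi: float = 1.5,
    r_lo: float = 0.67,
    min_count: int = 5,
) -> TrendPartition:
    """Partition terms into more-/less-frequently-detected and stable.

    Only terms with lifetime_count >= min_count are classified. A term is
    more_frequent when window_rate / lifetime_rate >= r_hi, less_frequent
    when the ratio <= r_lo, stable otherwise (both boundaries inclusive).
    Terms with zero lifetime rate (a degenerate single-date series) count
    as more_frequent iff their window count reaches min_count.
    """
    if not (r_hi > 1.0 > r_lo > 0.0):
        raise ValueError("thresholds must satisfy r_hi > 1 > r_lo > 0")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    part = TrendPartition(thresholds=(r_hi, r_lo, min_count))
    for row in table.rows:
        if row.lifetime_count < min_count:
            continue
        if row.lifetime_rate == 0.0:
            if row.window_count >= min_count:
                part.more_frequent.add(row.term_id)
            else:
                part.stable.add(row.term_id)
            continue
        ratio = row.window_rate / row.lifetime_rate
        if ratio >= r_hi:
            part.more_frequent.add(row.term_id)
        elif ratio <= r_lo:
            part.less_frequent.add(row.term_id)
        else:
            part.stable.add(row.term_id)
    return part
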