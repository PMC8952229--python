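"""End-to-end pipeline: generate/load releases, diff, trends, primacy.

A single declarative config drives the whole run; rerunning with the same
config and seed reproduces every artifact byte for byte. The run manifest
records the package version, the seed and a hash of the resolved config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import date
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .diff import build_diff_report, newly_annotated
from .model import BINDING_TERM_ID, BindingSequenceClass, Release
from .publications import (
    class_histogram,
    classify_binding_sequence,
    extract_evidence_records,
    filter_positive_experimental,
    publication_stats,
    resolve_primacy,
)
from .release_io import read_release, write_release
from .synthetic import SeriesConfig, generate_series
from .trends import DEFAULT_EXCLUDE, scale_for_cloud, term_frequencies, trend_partition

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class PipelineConfig(BaseModel):
    """Declarative description of one analysis run."""

    releases: list[str] | None = None  # paths to release XML files
    generator: SeriesConfig | None = None  # or generate the series
    window_start: date = date(2016, 1, 1)
    window_end: date = date(2021, 1, 15)
    r_hi: float = 1.5
    r_lo: float = 0.67
    min_count: int = 5
    exclude: list[str] = Field(default_factory=lambda: sorted(DEFAULT_EXCLUDE))
    binding_term: str = BINDING_TERM_ID
    out_dir: str = "annodrift-out"
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if self.window_start >= self.window_end:
            raise ValueError("window_start must precede window_end")
        if self.releases is None and self.generator is None:
            raise ValueError("config needs either 'releases' paths or a 'generator' block")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        canonical = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def _write_json(path: Path, doc: dict) -> None:
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _write_tsv(path: Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def _load_series(config: PipelineConfig, out_dir: Path) -> list[Release]:
    if config.generator is not None:
        gen_cfg = config.generator.model_copy(update={"seed": config.seed})
        series, log = generate_series(gen_cfg)
        release_dir = out_dir / "releases"
        release_dir.mkdir(parents=True, exist_ok=True)
        for release in series:
            write_release(release, release_dir / f"{release.meta.release_id}.xml")
        log.write(out_dir / "emission_log.json")
        return series
    assert config.releases is not None
    return [read_release(p) for p in config.releases]


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run generate/load -> diff -> trends -> primacy; return artifact paths.

    Raises :class:`PipelineError` naming the failing stage. The emitted
    bundle: diff_report.json, release_counts.tsv, removal_cases.tsv,
    term_trends.tsv, cloud.tsv, class_histogram.tsv, primacy.tsv,
    publication_stats.json, manifest.json.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    try:
        series = _load_series(config, out_dir)
    except Exception as exc:
        raise PipelineError(f"stage 'load-releases' failed: {exc}") from exc
    series = sorted(series, key=lambda r: r.meta.release_date)
    span = (series[0].meta.release_date, series[-1].meta.release_date)
    if config.window_end < span[0] or config.window_start > span[1]:
        raise PipelineError(
            f"stage 'window-check' failed: window [{config.window_start}, "
            f"{config.window_end}] lies outside the series span [{span[0]}, {span[1]}]"
        )

    try:
        report = build_diff_report(series)
        newly = newly_annotated(series, config.window_start, config.window_end)
        doc = report.to_json_dict()
        doc["newly_annotated_in_window"] = sorted(newly)
        _write_json(out_dir / "diff_report.json", doc)
        counts = pd.DataFrame(
            {
                "release_id": list(report.per_release_pe1_counts),
                "pe1_count": list(report.per_release_pe1_counts.values()),
                "annotated_count": list(report.per_release_annotated_counts.values()),
            }
        )
        _write_tsv(out_dir / "release_counts.tsv", counts)
        removals = pd.DataFrame(
            [
                {
                    "accession": c.accession,
                    "category": c.category,
                    "term_id": c.term_id or "",
                    "release_present": c.release_present,
                    "release_absent": c.release_absent,
                }
                for c in report.removed_function_cases
            ],
            columns=["accession", "category", "term_id", "release_present", "release_absent"],
        )
        _write_tsv(out_dir / "removal_cases.tsv", removals)
        artifacts["diff_report"] = out_dir / "diff_report.json"
        artifacts["release_counts"] = out_dir / "release_counts.tsv"
        artifacts["removal_cases"] = out_dir / "removal_cases.tsv"
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'diff' failed: {exc}") from exc

    try:
        table = term_frequencies(series, config.window_start, config.window_end)
        partition = trend_partition(table, config.r_hi, config.r_lo, config.min_count)

        def trend_class(term_id: str) -> str:
            if term_id in partition.more_frequent:
                return "more_frequent"
            if term_id in partition.less_frequent:
                return "less_frequent"
            if term_id in partition.stable:
                return "stable"
            return "below_min_count"

        trends_frame = pd.DataFrame(
            [
                {
                    "term_id": r.term_id,
                    "term_label": r.term_label,
                    "lifetime_count": r.lifetime_count,
                    "window_count": r.window_count,
                    "rate_ratio": (
                        r.window_rate / r.lifetime_rate if r.lifetime_rate > 0 else float("nan")
                    ),
                    "trend": trend_class(r.term_id),
                }
                for r in table.rows
            ],
            columns=[
                "term_id",
                "term_label",
                "lifetime_count",
                "window_count",
                "rate_ratio",
                "trend",
            ],
        )
        _write_tsv(out_dir / "term_trends.tsv", trends_frame)
        exclude = set(config.exclude)
        kept = [r for r in table.rows if r.term_label not in exclude]
        if kept:
            cloud = scale_for_cloud(table, exclude_labels=exclude)
        else:
            logger.warning("trends: no terms left for the cloud after exclusion")
            cloud = []
        cloud_frame = pd.DataFrame(cloud, columns=["term_label", "scaled_score"])
        _write_tsv(out_dir / "cloud.tsv", cloud_frame)
        artifacts["term_trends"] = out_dir / "term_trends.tsv"
        artifacts["cloud"] = out_dir / "cloud.tsv"
    except Exception as exc:
        raise PipelineError(f"stage 'trends' failed: {exc}") from exc

    try:
        reference = series[-1]
        records = extract_evidence_records(reference)
        filtered = filter_positive_experimental(
            records, config.window_start, config.window_end
        )
        primacy = resolve_primacy(filtered)
        classes = classify_binding_sequence(primacy, config.binding_term)
        hist = class_histogram(classes)
        hist_frame = pd.DataFrame(
            [{"class": name, "n_proteins": hist[name]} for name in BindingSequenceClass.ALL]
        )
        _write_tsv(out_dir / "class_histogram.tsv", hist_frame)
        primacy_frame = pd.DataFrame(
            [
                {
                    "accession": p.accession,
                    "category": p.category,
                    "term_id": p.term_id or "",
                    "first_pub_id": p.first_pub_id,
                    "first_pub_date": (
                        str(p.first_pub_date.year) if p.year_only else p.first_pub_date.isoformat()
                    ),
                    "year_only": p.year_only,
                }
                for p in primacy
            ],
            columns=[
                "accession",
                "category",
                "term_id",
                "first_pub_id",
                "first_pub_date",
                "year_only",
            ],
        )
        _write_tsv(out_dir / "primacy.tsv", primacy_frame)
        stats_doc: dict = {
            "n_eligible_proteins": len({r.accession for r in filtered}),
            "n_classified_proteins": len(classes),
        }
        if primacy:
            stats_doc.update(publication_stats(primacy, config.binding_term).to_json_dict())
        _write_json(out_dir / "publication_stats.json", stats_doc)
        artifacts["class_histogram"] = out_dir / "class_histogram.tsv"
        artifacts["primacy"] = out_dir / "primacy.tsv"
        artifacts["publication_stats"] = out_dir / "publication_stats.json"
    except Exception as exc:
        raise PipelineError(f"stage 'primacy' failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": config.config_hash(),
        "artifacts": sorted(p.name for p in artifacts.values()),
    }
    _write_json(out_dir / "manifest.json", manifest)
    artifacts["manifest"] = out_dir / "manifest.json"
    return artifacts
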