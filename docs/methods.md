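# Methods

## The release model and its dialect

The unit of analysis is a *release*: one dated snapshot of a curated
protein knowledgebase. The package defines its own document-oriented XML
dialect for releases (schema in `src/annodrift/schemas/release.xsd`) rather
than parsing any production dump format: entries carry an accession, a
chromosome label (1–22, X, Y, MT, or unknown), a protein-existence level
(PE1–PE5) and function annotations; annotations carry one of six curation
categories, an optional controlled term (id + label), and evidence records;
evidence carries one of five kinds (two experimental: direct assay and
physical interaction; three inferential: sequence similarity, curator
inference, author statement), a negative flag, and usually a publication
reference. A multi-gigabyte production dump differs from this dialect only
in volume and incidental structure; everything the cross-release analysis
consumes is represented.

Two representational choices matter downstream:

- **Year-only publication dates** are first-class: they serialize as
  `date="2017" granularity="year"` and are canonicalized in memory to
  January 1 of their year, so serialization is lossless and the in-memory
  value never carries spurious precision. Comparison is granularity-aware:
  if either side is year-only, only years compare, and a year-only date
  neither precedes nor follows a full date of the same year.
- **Annotation removal is encoded as absence** in a later release, not as a
  tombstone record. A removal is therefore only *observable* by diffing,
  which mirrors how it would be observed in a real resource, and the
  generator guarantees every injected removal is observable (it never
  targets an annotation created in the final release).

Parsing is strict about identity and category (missing/duplicate accession
and unknown categories raise, naming the entry) and lenient about
extensions (unknown elements are ignored with a warning; unknown evidence
kinds map to curator-inference with a warning), so fixtures stay forward
compatible without ever silently dropping an entry.

## Diffing

Counting follows the version-comparison convention: only PE1 entries are
counted, and a protein is *annotated* as soon as it has ≥ 1 function record
of any category — evidence quality is deliberately ignored at this stage
(it enters only in the primacy analysis). Removal cases are keyed by
(accession, category, term_id) — term-less annotations form their own key —
so the unit is a *case*, not a protein; one case is reported per key at its
earliest absence, and later re-additions do not create new cases.
`newly_annotated` treats the earliest release as a baseline: proteins
annotated there were "previously known" and never qualify, whatever the
window; proteins qualify by first annotation inside the window, or by
re-annotation inside the window after complete removal before it. With
these conventions {baseline-annotated} ∪ {newly annotated} ∪
{never annotated} exactly partitions the reference's PE1 accessions, which
the suite asserts. Accession mapping onto the reference release is the
identity on shared accessions; merges, splits and secondary accessions are
out of scope, and retired accessions are reported per release.

## Term trends and cloud scaling

Frequencies count *distinct proteins*, not annotation records: a protein
contributes once to a term at the date of the earliest release in which it
carries that term. Only controlled (term-bearing) records participate.
Lifetime and window counts are converted to per-year rates using the series
span and the window length (in Julian years, 365.25 days); the trend
partition compares the two rates. Both thresholds are inclusive
(ratio ≥ r_hi → more frequent; ≤ r_lo → less frequent), terms below
`min_count` lifetime proteins are not classified, and the defaults
(r_hi = 1.5, r_lo = 0.67, min_count = 5) are deliberately explicit,
CLI-configurable parameters: the more/less-frequent distinction is
qualitative in origin, and reproducible behaviour requires pinning it.

Cloud scaling is the affine min-max map x' = 1 + 19·(x − xmin)/(xmax −
xmin), computed *after* removing excluded labels so the surviving terms use
the full [1, 20] range. The default exclusion is the label
"protein binding": it dominates raw frequencies while carrying almost no
information about specific function. When xmax = xmin the map is undefined;
all scores are set to 1, the conservative bottom of the range. The map is
invariant under scaling all frequencies by a constant and strictly
monotone in x otherwise — both are asserted as properties.

## Evidence filtering and publication primacy

The primacy stage admits only rows that are (a) positive, (b) of an
experimental kind (direct assay or physical interaction), and (c) published
inside the analysis window, where year-only dates match if their year
intersects the window. Rows without a publication date cannot be ordered
and are excluded with a warning.

Primacy resolution sorts rows by (publication date, accession, publication
id) and keeps, per (accession, category, term_id), the first row — the
oldest date, ties broken by smallest publication id. In the deterministic
total order, year-only dates sort before full dates of the same year, so
selection among year-equal candidates is stable. Because every function key
retains its own oldest record, the functions established by a protein's
first publication are retained alongside all later firsts; a separate
"re-attach by shared protein + publication" pass is implied by this per-key
selection and is therefore not a distinct step. The resolution is
input-permutation invariant and idempotent, both asserted by tests.

The five-way classification per protein: BINDING_ONLY if only the binding
term survives, OTHER_ONLY if binding is absent; otherwise the earliest
binding record is compared with the earliest non-binding record —
SAME_PUBLICATION if they share a publication id, BINDING_FIRST /
BINDING_AFTER by strict granularity-aware date order. Dates equal under
that comparison (including year-only ties) but from different publications
classify as BINDING_FIRST: at that precision primacy is genuinely
undecidable, a deterministic rule is mandatory, and the choice is logged
per protein. "Binding" is a single configurable controlled term (default
GO:0005515, "protein binding"); terms affiliated with binding are *not*
folded in — the analysis ignores the term hierarchy throughout, so binding
primacy is, if anything, underestimated. Term-less records participate in
primacy and statistics but can never be the binding term.

Publication statistics are exact ratios over the bipartite
protein–publication graph of surviving primacy records. Because "fraction
of functions that are binding" is ambiguous between proteins and records,
both fractions are reported, and the stats artifact also reports both the
eligible-set size (proteins with any window-eligible evidence) and the
classified-set size.

## The synthetic generator

`generate_series` emulates: a stable protein set (accession, chromosome,
PE level with a configurable PE1 fraction, default 0.85); per-release,
per-category annotation accrual as Poisson draws from configurable rates
whose defaults follow the observed category profile of curated function
records (biological-process ≫ molecular-function ≈ pathway ≫ free-text
function-info ≫ transport ≈ catalytic); controlled terms drawn from a flat
bundled GO-like vocabulary (including the literal "protein binding");
free-text function-info records always term-less and a 15% term-less
fraction elsewhere; 1–2 evidence records per annotation with a configurable
experimental fraction (default 0.4, reflecting that inferential evidence is
common); publications dated 1–24 months before their release, 10%
year-only; exactly `removal_count` removals and exactly
`negative_evidence_count` negative flags. Everything is driven by one
`numpy` generator seeded from the config, and two runs with the same config
are byte-identical.

It does **not** emulate: term-hierarchy (DAG) structure, accession merges
and splits, proteoforms and isoforms, curation latency between publication
and release, or correlated term co-occurrence. Passing tests therefore
demonstrate the *accounting* is exact on structurally faithful data, not
that scientific conclusions transfer to any real resource.

`generate_sequencing_fixture` realizes each temporal class as a concrete
publication-date pattern (shared publication; binding earlier by
`date_spacing` days; binding later; one function only) and records the true
class per protein. With full-precision dates and spacing ≥ 1 day the
classifier recovers the configured class counts exactly — the pipeline's
central acceptance property, checked over 20 random configurations.
`date_spacing=0` combined with year-only dates is an intentional-ambiguity
fixture and warns instead of raising.

## Numerical and scale choices

Problem sizes in tests and examples are desk-scale by design — hundreds of
proteins, ≤ 10 releases, multiplicities ≤ 50 per class — large enough to
exercise every code path and exhaust every oracle comparison, small enough
that the whole suite runs in seconds. The removal-detection oracle is an
independent exhaustive presence-matrix recomputation; the incremental
detector must agree with it exactly on 50 random series. All report
artifacts (JSON with sorted keys, TSV with fixed column order) are
byte-deterministic under a fixed config and seed; the run manifest records
the package version, seed and a SHA-256 of the resolved config.

## Known limitations

- No adapter for real production dumps or their XSD; the dialect is
  synthetic-first.
- Flat vocabulary: no propagation of counts along a term hierarchy, hence
  term frequencies and binding primacy are approximations in the same
  direction a hierarchy-blind analysis of a real resource would be.
- Accession mapping is identity-only.
- Chromosome labels are taken per release verbatim; conflicts across
  releases for one accession resolve to the latest release (logged).
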