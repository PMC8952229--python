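# Demo pipeline config: generate a synthetic decade of yearly releases and
# run the full diff -> trends -> primacy analysis on it.
generator:
  n_proteins: 200
  n_releases: 10
  release_dates:
    - 2011-01-15
    - 2012-01-15
    - 2013-01-15
    - 2014-01-15
    - 2015-01-15
    - 2016-01-15
    - 2017-01-15
    - 2018-01-15
    - 2019-01-15
    - 2020-01-15
  pe1_fraction: 0.85
  removal_count: 5
  negative_evidence_count: 3
  experimental_fraction: 0.4
  term_vocabulary_size: 30
window_start: 2016-01-01
window_end: 2020-01-15
r_hi: 1.5
r_lo: 0.67
min_count: 5
exclude:
  - protein binding
binding_term: GO:0005515
out_dir: annodrift-out
seed: 7
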