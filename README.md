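# cohortcat

A library + CLI for cataloguing cohort-study metadata and exploring data
harmonization potential:

- **metadata model** — typed Study → Population → DataCollectionEvent
  hierarchy with Datasets/Variables/Categories attached to collection
  events; invariant validation that reports (never throws), with warnings
  for incomplete-but-acceptable metadata.
- **taxonomy** — a packaged 18-domain / 135-term variable classification
  plus annotation and validation machinery (YAML-loadable custom taxonomies
  supported).
- **dictionary I/O** — data-dictionary import/export as CSV variable +
  category tables in three dialects (`plain_csv`, `spss_export`,
  `sas_export` — CSV emulations of those tools' export conventions), and a
  minimal "ddi-lite" XML codebook export
  (see `src/cohortcat/data/ddi_lite_schema.md`).
- **search** — deterministic inverted-index search over studies (property
  filters) and variables (conjunctive token text search with `*` prefixes,
  taxonomy-term filters, scope restriction) plus facet counts; results are
  provably equivalent to a brute-force scan (property-tested).
- **compare** — harmonization-potential tables: variable counts per
  (study, population, collection event) × taxonomy term, rendered as CSV or
  grouped markdown.
- **classifier** — a transparent multinomial naive-Bayes suggester of
  taxonomy terms from variable text, with JSON model serialization.
- **synthgen** — seeded, fully deterministic generators: random catalogues
  for property tests, a packaged two-birth-cohort comparison fixture, and
  labelled variables with controllable vocabulary overlap.

## CLI

```bash
cohortcat fixture table3 -o demo/            # write the packaged fixture
cohortcat validate demo/                     # exit 1 on any validation error
cohortcat taxonomy show --domain Diseases
cohortcat search variables -C demo/ --text "tobacco trimester" --format json
cohortcat search variables -C demo/ --term "Lifestyle and behaviours/Tobacco" \
    --study APrON --population mothers --dce tri1
cohortcat search studies -C demo/ --start-year 2009 2010
cohortcat compare -C demo/ \
    --term "Lifestyle and behaviours/Tobacco" \
    --term "Lifestyle and behaviours/Alcohol" \
    --study AOBF --study APrON --format markdown
cohortcat import src_dir/ --dialect spss_export -o imported/
cohortcat export-ddi AOBF_mothers_gest24w -C demo/ -o codebook.xml
cohortcat generate --seed 7 -o synth/
cohortcat classify train --in labelled.csv --model model.json
cohortcat classify suggest APrON_mothers_tri1 -C demo/ --model model.json --k 3
```

Exit codes: 0 success, 1 validation/content error, 2 usage error.

A catalogue directory contains `studies/<id>.yaml`, one
`datasets/<id>/{dataset.yaml,variables.csv,categories.csv}` per dataset, and
an optional `taxonomy.yaml` (the packaged taxonomy is used when absent).

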