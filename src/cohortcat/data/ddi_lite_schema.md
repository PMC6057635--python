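# ddi-lite codebook export — element vocabulary

A deliberately minimal, DDI-flavoured XML codebook. This is **not** a
conformant DDI Codebook document; it is a fixed small subset intended to be
trivially mappable onto one.

```
codebook                      root; attributes: dataset (dataset id), name
  variable                    one per variable, in dataset order
    name                      variable name (token)
    label                     display label
    units                     measurement unit (omitted when absent)
    question                  question text (omitted when absent)
    category                  one per category, in declared order
                              attributes: code, missing ("true"/"false")
      label                   category label
```

All text is UTF-8; the document carries an XML declaration.
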