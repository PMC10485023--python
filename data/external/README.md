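# External datasets (not shipped)

The headline-number acceptance tests
(`tests/test_acceptance.py::TestHeadlineNumbers`) need published datasets
that cannot be redistributed here. Place them in this directory to enable
those tests; they skip otherwise.

Scored datasets — TSV with columns `sequence` (28-nt window: 20-nt
protospacer + NGG PAM + 5 downstream nt, uppercase) and `target`
(standardized activity score):

- `guo_espcas9_scored.tsv` — Guo et al. eSpCas9 depletion dataset (n≈45,010)
- `tevspcas9_scored.tsv`   — TevSpCas9 enrichment dataset (n=279)
- `spcas9_scored.tsv`      — SpCas9 enrichment dataset (n≈303)
- `guo_spcas9_zscores.tsv` — Guo et al. SpCas9 dataset with original Z-scores

Count tables — guide × sample TSV (first column `guide`) plus a YAML sidecar
`<name>.tsv.yaml` with per-sample `condition` and `replicate` lists:

- `tevspcas9_counts.tsv`   — 10 induced + 10 repressed replicates
- `guo_spcas9_counts.tsv`, `guo_espcas9_counts.tsv`
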