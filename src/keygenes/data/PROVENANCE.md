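# meta_hub_studies.tsv

A long-format (study_id, gene_symbol) table of hub genes reported by 52
published hepatocellular-carcinoma gene-identification studies
(2019–2022 bioinformatics literature), transcribed verbatim from the curated
summary table those studies were collected into.

Transcription policy: symbols are kept exactly as printed, including probable
typographical variants (e.g. `SULTIA3` for SULT1A3, `KCCNB2`, `GF1` for IGF1,
`CXL12` for CXCL12, `RACGAP` for RACGAP1, `PPTG1` for PTTG1, `CDK1A`, `TK`);
no silent symbol corrections or alias merging are applied.  Case and
whitespace normalization happen at read time, and duplicate (study, gene)
pairs — a few studies list the same gene twice — collapse to a single record.

Known internal inconsistencies of the source table, preserved rather than
repaired:

* several rows' stated hub-gene count disagrees with the genes actually
  listed (S03 states 16 but lists 15; S18 states 8 but lists 9; S43 states 9
  but lists 9 of which two are the same symbol; S51 states 10 but lists 15);
* the running-text description of the studies disagrees with the table for a
  few rows (e.g. the text credits one study with 9 hub genes where the table
  lists 4).

Because of these inconsistencies the union of this transcription contains
212 distinct gene symbols, with 45 genes appearing in >= 3 studies (36 in
> 3), whereas the source's own prose reports a union of 214 and 52
"significant" genes.  The six-gene consensus the table feeds into is
insensitive to the discrepancy: TOP2A (31 studies), CDC20 (19), ASPM (13),
PRC1 (12), UBE2C (7) and NUSAP1 (6) clear either frequency threshold by a
wide margin, and PNPLA7 and MT1E appear in no study row at all.
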