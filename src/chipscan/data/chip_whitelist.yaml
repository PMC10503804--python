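# Driver-gene whitelist for CHIP annotation.
#
# Default list covers the common myeloid drivers; a fuller curated list
# (e.g. the 74-gene panel used for biobank exome calling) can be dropped in
# with the same schema.  Per-gene `classes` restricts qualifying variant
# classes; `any` accepts every reported variant in the gene.
version: 1
vaf_min: 0.02
large_clone_vaf: 0.10
genes:
  DNMT3A: {classes: any}
  TET2: {classes: any}
  ASXL1: {classes: any}
  JAK2: {classes: any}
  SRSF2: {classes: any}
  SF3B1: {classes: any}
  TP53: {classes: any}
  PPM1D: {classes: any}
  OTHER: {classes: any}
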