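# Default CD/WDEIA epitope catalog for wheat gliadins.
#
# Native 9-mer cores for the DQ2.5/DQ8-restricted celiac-disease epitopes
# and 7-mer cores for the omega-5 gliadin WDEIA epitopes.  Deamidated cores
# are the tissue-transglutaminase products (Q->E at the positions relevant
# for HLA binding).  Entries with `verified: false` carry cores taken from
# the standard published epitope nomenclature rather than being fixed by
# in-package primary data; they are configuration and may be replaced.
epitopes:
  - name: DQ2.5-glia-α1a
    core_native: PFPQPQLPY
    core_deamidated: PFPQPELPY
    disease: CD
    source_family: alpha
    verified: true
  - name: DQ2.5-glia-α1b
    core_native: PYPQPQLPY
    core_deamidated: PYPQPELPY
    disease: CD
    source_family: alpha
    verified: false
  - name: DQ2.5-glia-α2
    core_native: PQPQLPYPQ
    core_deamidated: PQPELPYPQ
    disease: CD
    source_family: alpha
    verified: true
  - name: DQ2.5-glia-α3
    core_native: FRPQQPYPQ
    core_deamidated: FRPEQPYPQ
    disease: CD
    source_family: alpha
    verified: false
  - name: DQ8-glia-α1
    core_native: QGSFQPSQQ
    core_deamidated: EGSFQPSQE
    disease: CD
    source_family: alpha
    verified: false
  - name: DQ2.5-glia-γ1
    core_native: PQQSFPQQQ
    core_deamidated: PQQSFPEQQ
    disease: CD
    source_family: gamma
    verified: false
  - name: DQ2.5-glia-γ2
    core_native: IQPQQPAQL
    core_deamidated: IQPEQPAQL
    disease: CD
    source_family: gamma
    verified: false
  - name: DQ2.5-glia-γ3
    core_native: QQPQQPYPQ
    core_deamidated: QQPEQPYPQ
    disease: CD
    source_family: gamma
    verified: false
  - name: DQ2.5-glia-γ4a
    core_native: SQPQQQFPQ
    core_deamidated: SQPEQEFPQ
    disease: CD
    source_family: gamma
    verified: false
  - name: DQ2.5-glia-γ4b
    core_native: PQPQQQFPQ
    core_deamidated: PQPEQEFPQ
    disease: CD
    source_family: gamma
    verified: false
  - name: DQ2.5-glia-γ4c
    core_native: QQPQQPFPQ
    core_deamidated: QQPEQPFPQ
    disease: CD
    source_family: gamma
    verified: false
  - name: DQ2.5-glia-γ4d
    core_native: PQPQQPFPQ
    core_deamidated: PQPEQPFPQ
    disease: CD
    source_family: gamma
    verified: false
  - name: DQ2.5-glia-γ5
    core_native: QQPFPQQPQ
    core_deamidated: QQPFPEQPQ
    disease: CD
    source_family: gamma
    verified: false
  - name: DQ2.5-glia-ω1
    core_native: PFPQPQQPF
    core_deamidated: PFPQPEQPF
    disease: CD
    source_family: omega
    verified: false
  - name: DQ2.5-glia-ω2
    core_native: PQPQQPFPW
    core_deamidated: PQPEQPFPW
    disease: CD
    source_family: omega
    verified: false
  - name: WD-1
    core_native: QQIPQQQ
    disease: WDEIA
    source_family: omega
    verified: true
  - name: WD-2
    core_native: QQFPQQQ
    disease: WDEIA
    source_family: omega
    verified: true
  - name: WD-3
    core_native: QQSPQQQ
    disease: WDEIA
    source_family: omega
    verified: false
  - name: WD-4
    core_native: QQYPQQQ
    disease: WDEIA
    source_family: omega
    verified: false
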