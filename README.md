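# fusiontriage

Triage of RNA-seq fusion-transcript candidates in leukemia cohorts:
normalize caller outputs, apply a removal cascade, check each surviving
chimera against the sample's banded karyotype, and prioritize it into
three tiers, with functional annotation at the junction.

## What it does

- **Input normalization** (`fusion_io`): fusion tables in two TSV dialects
  (ChimeraScan-like and deFuse-like), GTF gene models (exons + CDS),
  UCSC-dialect cytoband tables, ISCN karyotype tables, healthy-panel and
  tumor-suppressor gene lists, copy-number segments. All internal
  coordinates are 1-based inclusive on the forward strand.
- **ISCN parsing** (`iscn`): karyotype strings → clones and structural
  events (translocations, inversions, deletions, derivatives with embedded
  translocations, gains/losses, markers); unrecognized tokens are kept
  verbatim, never dropped.
- **Filter cascade** (`filters`): flags instead of deletions —
  `no_split_reads`, `unannotated_partner`, `healthy_panel`,
  `unreliable_structure`, `promiscuous_gene`, `readthrough`,
  `cohort_recurrent`. Caller outputs are merged first (10 bp breakpoint
  tolerance, max read support, driver-score conflict warning).
- **Cytogenetic concordance** (`concordance`): band-level matching of a
  fusion to translocation-like karyotype events, on major-band numbers of
  the same arm with a configurable tolerance (default 1).
- **Junction consequences** (`consequence`): reading frame from CDS
  arithmetic (`c5 ≡ s3 mod 3`), partner orientation (conserved/inverted),
  exon-skipping isoform enumeration, fusion-protein residue extents, and
  junction microhomology with a brute-force-verified sliding definition.
- **Copy-number inference** (`cn_inference`): interstitial deletion implied
  by a colinear intrachromosomal flanking-gene fusion, encompassed genes,
  and support/contradiction against SNP-array segments.
- **Tiering** (`tiering`): tier 1 = karyotype-concordant; tier 2 = driver
  score ≥ 0.7; tier 3 = out-of-frame fusion rescued by a tumor-suppressor
  partner; otherwise rejected with machine-readable reasons. Also cohort
  summary statistics (median age, per-gene alteration fractions, FLT3-ITD
  VAF classes).
- **Synthetic cohorts** (`synthetic_data`): deterministic bundles (mini
  genome, GTF, cytobands, karyotypes, caller tables, panels, CN segments,
  cohort CSV) with planted ground truth for every pipeline branch, plus a
  fixed fixture bundle encoding the published worked examples.

## CLI

```
fusiontriage simulate --seed 1 --samples 4 --out cohort/
fusiontriage run --config cohort/config.yaml --out results/
fusiontriage run --config cohort/config.yaml --dry-run
fusiontriage paper-fixture --out fixture/
fusiontriage show-config
fusiontriage validate --config cohort/config.yaml
```

`run` writes `report.tsv` (one row per candidate with tier, flags,
frame, isoform count, microhomology, inferred deletion and reasons), a
`report.bedpe` companion of surviving fusions, and a `manifest.json` with
input checksums. Identical inputs and config produce byte-identical
outputs.

## Tests

```
python -m pytest -q tests/
```

The suite includes property tests (hypothesis) and independent oracles:
translate-and-scan for reading frames, junction-sliding for
microhomology, linear scans for interval and band lookups, and
full-pipeline planted-truth recovery across seeds.

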