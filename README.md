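# ervkit

Analysis toolkit for retroelement-family silencing studies in mouse ES
cells, exercised end-to-end on synthetic data. It covers four analyses:

1. **Repeat expression deregulation** — RPKM per repeat family and per
   individual full-length element, with a pairwise Poisson Z-score
   `z = (RPKM_A − RPKM_B) / sqrt(RPKM_A + r_AB·RPKM_B)` (`r_AB = N_A/N_B`)
   and pseudocounted fold changes (`repeat_expression`).
2. **ChIP flank metaprofiles** — duplicate-collapsed, mapQ ≥ 10,
   300 bp directionally-extended coverage; peak-height ≥ 10 thresholding;
   mean density in 50 bp bins over ±6 kb strand-oriented flanks of intact
   LTR–internal–LTR elements, as aggregate profiles and per-element
   heatmaps (`chip_flank_profiler`).
3. **Chimeric LTR–gene transcripts** — mate pairs more than one SD from
   the mean fragment size with one mate in an ERV upstream of a gene's
   first exon and the other in a genic exon; transcripts with > 5 unique
   supporting pairs scored valid, with a per-family breakdown
   (`chimeric_transcripts`).
4. **2C-specific genes** — stage RPKM = RPM / transcript length; genes
   ≥ 4-fold higher at the 2C stage than oocyte and 8C; overlap with
   KO-upregulated sets; hypergeometric enrichment of TSSs within 5 kb of
   MT2/MT2A/MT2C LTRs (`stage_specificity`).

`genome_model` supplies the domain types (BED6/RepeatMasker repeats,
GTF/BED12 gene models, intact-element assembly, flank-bin geometry,
TSS-to-LTR distances; all coordinates 0-based half-open internally).
`synthetic_data` generates deterministic toy genomes, SAM/TSV alignments
(Poisson counts, Normal fragment sizes, planted chimeras, planted
2C-specific genes) together with ground truth for recovery tests.

## Command line

One subcommand per stage, sharing a run directory:

```sh
ervkit simulate --seed 7 --out run/           # toy genome + alignments + truth
ervkit quantify --run run --sample ko         # expression_ko.tsv
ervkit compare  --run run -a ko -b wt         # Z-score + fold-change table
ervkit profile  --run run --antibody chip     # WIG tracks, profiles, heatmaps
ervkit chimera  --run run --sample ko         # chimera calls + family breakdown
ervkit twocell  --run run                     # 2C gene set + MT2 enrichment
ervkit all --seed 7 --out run/                # everything, in dependency order
```

All thresholds default to the standard values (mapQ 10, extension 300,
peak height 10, 50 bp bins over ±6 kb, 1 SD discordance, support > 5,
4-fold stage/KO thresholds, 5 kb proximity); overrides are echoed into
`pipeline_manifest.json`, which also records output digests so a rerun
with the same seed can be verified byte-for-byte.

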