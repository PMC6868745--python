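# reosig

Rank-based, single-sample gene-pair signatures for calling lung tumor
samples **ADC** (adenocarcinoma) or **SCC** (squamous cell carcinoma) from
bulk expression profiles.

The method relies on *within-sample relative expression orderings* (REOs):
whether gene *a*'s expression exceeds gene *b*'s inside one sample. REO
rules need no normalization or reference cohort, and are invariant to any
per-sample monotone transform of expression. The package ships the frozen
published rule — **SCC iff KRT5 > AGR2, otherwise ADC** — and implements the
full discovery pipeline that produces such rules:

1. **Direction calls** (`subtype_opposite`) — per-gene tumor-vs-normal
   dysregulation directions for each subtype (Wilcoxon rank-sum + BH FDR;
   the DE engine is pluggable).
2. **Subtype-opposite genes** — genes significant in both subtypes with
   opposite directions; multi-cohort sets are integrated with a
   cross-cohort direction-consistency filter.
3. **Pair screening** (`pair_screen`) — all n·(n−1)/2 pairs, oriented so
   `Ea > Eb` marks SCC, one-sided Fisher exact enrichment with BH FDR,
   apparent accuracy (C/M), and a rank-difference spread statistic.
4. **Signature selection** (`signature_select`) — forward selection from the
   top-50 seed pairs under strict-majority voting, ties broken by fewest
   pairs, then largest median rank difference.
5. **Classification** (`classifier`) — per-sample calls, cohort accuracy /
   sensitivity / specificity, and reclassification bookkeeping.
6. **Validation statistics** (`validation`) — proliferation scores, the
   16-point IHC staining index (low <5, medium 5–10, high 11–16), crosstab
   percentages with Fisher tests, and rank-based marker contrasts.
7. **Synthetic data** (`synth`) — labeled two-subtype datasets with planted
   subtype-opposite genes, a dominant planted pair with tunable per-sample
   REO flip rate, and end-to-end recovery experiments.

## CLI

```sh
# generate a synthetic labeled dataset
reosig simulate --spec spec.yaml --out matrix.tsv --labels-out labels.tsv --truth truth.json

# discover a signature from one or more training cohorts
reosig discover --matrix m1.tsv --labels l1.tsv [--matrix m2.tsv --labels l2.tsv] \
    --alpha 0.05 --fdr 0.05 --n-seeds 50 --out-dir out/

# classify a cohort (defaults to the built-in KRT5/AGR2 rule)
reosig classify --matrix cohort.tsv --labels labels.tsv --out calls.tsv

# supporting statistics
reosig validate ihc --intensity 2 --extent 3
reosig validate crosstab --high-a 63 --total-a 96 --high-b 43 --total-b 80
reosig validate proliferation --matrix m.tsv --gene-list panel.txt --out scores.tsv
reosig validate markers --matrix m.tsv --group-a reclassified.txt --group-b confirmed.txt
```

Formats: expression matrices are TSV (gene rows × sample columns; GCT v1.2
is accepted read-only), labels are two-column TSV (`sample_id`, one of
`ADC/SCC/NORMAL/UNKNOWN`), probe maps are two-column TSV (probes mapping to
zero or multiple genes are dropped; probes sharing a gene are averaged),
signatures are JSON (`{"pairs": [{"scc_high": "KRT5", "scc_low": "AGR2"}],
"rule": "strict_majority"}`).

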