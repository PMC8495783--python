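# branchsel

Batch selection-regime analysis (dN/dS, ω) over phylogenies, built to
include **nonubiquitous genes** — single-copy orthologs that are missing
from some of the sampled species and are therefore usually dropped from
comparative genomics selection scans, even though they commonly outnumber
the ubiquitous ones.

The workflow has two independent stages:

* **analyze** — per gene: screen the codon alignment for stop codons,
  prune the species tree to the gene's taxon set (or use a per-gene
  tree), place user-defined foreground labels (`#k` branch / `$k` clade,
  CodeML tree dialect), fit two nested codon models with replicate random
  ω starts, and compare them by a likelihood-ratio test

      LRT = 2(lnL_general − lnL_alternative)  ~  χ²(Δnp)

  with Benjamini–Hochberg FDR correction across the gene batch (the
  *general* model is the parameter-rich one; the *alternative* is the
  restricted model nested within it).
* **extract** — across genes: identify "the same" branch or clade by its
  species set even when taxa are missing, and tabulate dN/dS, dN and dS
  from each gene's best-fit model. Mode A requires every clade species to
  be present; mode B admits genes missing clade species down to a
  threshold — a proportion (e.g. 0.8 ⇒ at least 80% of the clade's
  species, rounded up) or an absolute count.

Model fitting runs through an external `codeml` binary when available, or
through the built-in Goldman–Yang engine (M0 and branch models, equal
codon frequencies), which also provides an alignment simulator and a
CodeML-output emulator so the entire pipeline is reproducible and
verifiable without external software. See `docs/methods.md` for the model,
assumptions and numerical choices.

## Worked example

Generate a 10-gene toy dataset (8 species, some genes missing 1–2 of
them), run both stages, and read the results:

```sh
branchsel simulate-fixtures --out demo --genes 10 --taxa 8 --codons 300 --seed 7
branchsel analyze --alignments demo/alignments --species-tree demo/species_tree.nwk \
    --general-ctl demo/general.ctl --alternative-ctl demo/alternative.ctl \
    --labels demo/labels.tsv --replicates 2 --seed 11 --out demo/out
branchsel extract --analysis demo/out --definitions demo/labels.tsv \
    --mode B --threshold 0.8 --out demo/tables
```

`demo/out/summary.tsv` then holds one LRT row per analyzed gene, e.g.

```
gene_id  lnl_general   lnl_alternative  stat      df  pvalue    qvalue    best_model   negative_stat_flag
gene001  -3820.990069  -3823.219344     4.458550  1   0.034727  0.173635  alternative  False
gene002  -3907.581747  -3907.866737     0.569980  1   0.450267  0.831963  alternative  False
```

Here `stat` is 2ΔlnL, `df` the parameter-count difference between the two
models, and `best_model` says whether the FDR-adjusted test (`qvalue`)
rejected the restricted model at α = 0.05 — gene001 would be nominally
significant on its raw p value, but after FDR correction across the batch
the restricted single-ω model is rightly kept for these null-simulated
genes. `demo/tables/focal.tsv` lists, for every gene in which the focal
clade could be matched, one row per clade branch with its dN/dS, dN and
dS (plus a clearly marked mean row):

```
gene_id  branch               dnds      dn        ds        derived
gene001  sp3                  0.205386  0.115136  0.560585  False
gene001  sp3,sp4,sp5,sp6,sp8  0.205386  0.015681  0.076347  False
```

and `demo/tables/coverage.tsv` states for every unmatched gene *why* it
was excluded (below-threshold, not-monophyletic, …).

The stages are independent: `branchsel extract --mlc some_folder` works
directly on CodeML main-output files produced by any other means.

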