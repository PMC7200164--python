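# fourcat

Quantitative analysis of 4C-seq contact profiles around engineered CTCF
insulators.

4C-seq (circular chromosome conformation capture sequencing) measures how
often one chosen restriction fragment — the *viewpoint*, typically a gene
promoter — touches every other fragment of its locus. When an array of
CTCF-binding sites is inserted between a gene and its enhancer, the contact
profile beyond the insertion drops, and the gene's expression drops with it,
far more steeply than the contacts do. `fourcat` is a toolkit for making
those statements quantitative across an allelic series:

* **Fragment maps** — in silico digestion of a locus (NlaIII/CATG primary,
  DpnII/GATC secondary cutter by default), fixed-width bin grids, BED I/O.
* **Contact profiles** — replicate pooling, reads-per-million normalization,
  7-fragment running-mean smoothing for browser tracks, and viewpoint-excluded
  **contact-frequency ratios**: reads in a region over reads in the locus,
  dropping the viewpoint fragment ± 10 kb where self-ligation artifacts live.
* **Folding directionality** — `(R − L)/(R + L)` of raw reads in windows of
  100 kb / 500 kb / 1 Mb flanking the viewpoint; positive means rightward
  folding.
* **Contact-profile PCA** — 30 kb bin ratios across samples, column-centred
  PCA, and per-bin **component loadings** `v_jk·√λ_k` plotted along the
  genome; the changepoint of the loading track localizes the insulator
  without supervision.
* **Power-law scaling** — OLS on log-log axes of expression against enhancer
  contact (exponent γ), or of one region's contact against another's
  (exponent > 1 ⇒ preferential, super-linear escalation), plus Spearman's ρ.
* **Synthetic allelic series** — a distance-decay + barrier-permeability +
  enhancer-affinity generator with multinomial read sampling and a power-law
  expression link, so the whole pipeline runs and is tested with known
  ground truth.

## Worked example

Run the full pipeline on the default nine-allele synthetic panel
(permeabilities β from 1.0 for the open alleles down to 0.25 for the full
divergent CTCF array):

```sh
fourcat run --seed 1 --out demo
```

```
INFO fourcat: PC1 loading changepoint at 1530000 (truth 1530000)
INFO fourcat: scaling exponents: expression~contact 4.030, enhancer~neutral 1.217
run complete: 27 files in demo (config a4869ec10c50)
```

The bundle contains, among others, `scaling_fits.tsv`:

```
fit                             exponent      intercept_log10  spearman_rho  n
expression_vs_enhancer_contact  4.030093703   7.055316861      0.9833333333  9
enhancer_vs_neutral_contact     1.216601306   0.6413143316     0.9833333333  9
```

The first row recovers the generator's expression exponent (γ = 4): a ~2×
drop in enhancer contact produces a ~16× drop in expression. The second row
is the enhancer-vs-neutral contact exponent: above 1, meaning insulation
suppresses gene–enhancer contact preferentially over neutral cross-barrier
contact. `pca_changepoint.txt` reports the PC1 loading step at 1,530,000 bp —
exactly the simulated barrier position — and `directionality.tsv` shows the
open allele folding symmetrically (value ≈ 0) while the insulated allele
folds away from the barrier (value ≈ −0.25 at 100 kb).

Individual stages are available as subcommands (`digest`, `simulate panel`,
`profile`, `directionality`, `pca`, `scaling fit`) and as plain library
functions (`fourcat.contact_frequency`, `fourcat.run_pca`, ...).

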