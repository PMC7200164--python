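# Methods

## Contact-frequency quantification

All counting happens on restriction fragments: the intervals between
consecutive occurrences of the primary cutter motif (NlaIII, CATG) in the
locus sequence, with a flag per fragment recording whether it contains the
secondary cutter (DpnII, GATC). Cuts are placed at the motif start offset;
every statistic downstream is invariant to this constant ≤ 4 bp convention,
so it is documented rather than configurable. N bases never match a motif.
Coordinates are 0-based half-open throughout, including emitted BED/BedGraph.

Raw per-fragment read counts from replicate libraries of the same viewpoint
are pooled by summation before any ratio is formed. Two derived signals
serve visualization only: reads per million (`counts · 10⁶ / Σcounts`) and a
centred running mean over w = 7 fragments, truncated (never zero-padded) at
the locus edges so no artificial decay is fabricated there. The running mean
is computed by direct convolution rather than a sliding sum, so roundoff
does not accumulate along the locus. The window statistic defaults to the
mean and can be switched to a median.

The contact frequency of a region is a ratio of **raw** counts: reads on
fragments whose midpoint falls in the region, over reads on all fragments of
the locus, in both cases excluding fragments whose midpoint lies in the
*exclusion zone* — the viewpoint fragment extended by 10 kb on **each** side
(configurable). Self-ligation and undigested templates contaminate both
flanks, hence the symmetric default; the flank is a parameter because the
convention is not universal. Midpoint membership makes ratios of disjoint
regions exactly additive and assigns each straddling fragment to exactly one
region. Smoothed signal is never used in ratios, because smoothing leaks
reads across region boundaries.

## Folding directionality

For a window distance d (defaults 100 kb, 500 kb, 1 Mb), L and R are the raw
reads in `[vp_start − d, vp_start)` and `[vp_end, vp_end + d)` with
exclusion-zone fragments dropped; the statistic is `(R − L)/(R + L)`,
positive for rightward folding. Windows abut the viewpoint fragment (not the
exclusion zone) and are clipped at the locus edges with a warning — a 1 Mb
window from a viewpoint near the locus end is still meaningful, just
asymmetric. The statistic is exactly antisymmetric under mirror-flipping the
locus and exactly invariant to rescaling all counts.

## Binned PCA and loading tracks

Per sample, reads are summed into fixed-width bins (30 kb default) by
fragment midpoint; bins whose midpoint lies in the exclusion zone are
removed, bins empty in every sample are dropped with a warning, and each
row is divided by its total, giving within-region ratios that sum to one.
Region presets (whole locus, or sub-regions with re-normalized ratios) are
expressed by passing the bin grid of the sub-region.

PCA column-centres the matrix but does **not** scale columns to unit
variance: ratio bins already share a scale, and scaling would inflate noise
from near-empty bins. Eigenvalues use the n − 1 covariance divisor. The
decomposition is computed by SVD of the centred matrix (equivalent to
eigendecomposition of the covariance, and verified against it in the tests);
eigenvector sign is fixed by making each component's largest-magnitude entry
positive, since the sign is mathematically indeterminate and reproducible
tracks require a convention.

The loading of bin j on component k is `v_jk √λ_k`. On columns standardized
to unit variance this equals the Pearson correlation between the bin and the
component scores; on centred-but-unscaled data it does not, so the product
formula is what is implemented and the correlation identity is asserted only
on standardized input. The loading changepoint is the inter-bin boundary
maximizing |mean(left) − mean(right)|, ties broken leftmost; a constant
track has no changepoint and raises.

## Power-law scaling

Expression E and contact f are fitted by ordinary least squares on
log10–log10 axes; the slope is the scaling exponent (base-invariant), the
intercept is reported in log10. No weighting or robust loss is applied, and
zero contact values are rejected rather than pseudo-counted — a pseudo-count
would silently change the model being fitted. Spearman's ρ is the Pearson
correlation of average ranks; it errors on a constant vector, except inside
a power-law fit, where a constant response still has a well-defined zero
slope and ρ degrades to NaN.

## Synthetic allelic series

The generator emulates an engineered, locally haploid 3 Mb locus: 3,000
uniform 1 kb fragments (uniform by design, to decouple tests from
fragment-length confounds), viewpoint at 1.5 Mb, a barrier at +30 kb, an
enhancer region at +330 to +440 kb, and a neutral comparison region of the
same width at +630 to +740 kb. Expected contact probabilities are

    p_i ∝ d_i^(−α) · w_i,   w_i = 1 (viewpoint side), β (cross-barrier),
                            β^δ (cross-barrier, enhancer region)

with distance decay α = 1, permeability β ∈ (0, 1] per allele, and enhancer
affinity δ = 1.15 by default (δ ≥ 1). The viewpoint fragment gets
probability zero. Reads are one multinomial draw per allele; expression is
`E = c · f^γ · exp(ε)` with γ = 4, lognormal noise σ = 0.05, and f the
*expected* viewpoint-excluded enhancer contact frequency — the noise-free
value of the statistic the pipeline measures, so the generative exponent is
exactly γ. The scale c = 10⁷ only sets relative units and cancels from every
exponent. Default depth is 10⁶ reads per allele.

The default nine-allele panel spans β = 1.0 (no bound CTCF) down to 0.25
(full divergent array, and its whole-cassette inversion, which insulates
equally); intermediate values follow the ordering "more directly bound CTCF
sites ⇒ lower permeability". These β are documented constants satisfying
that ordering, not estimates of any real allele.

### What the generator does and does not capture

It reproduces the features the statistics consume: distance decay, a
one-sided barrier with graded permeability, preferential enhancer
escalation, multinomial counting noise, and a power-law expression link. It
deliberately omits polymer/loop-extrusion dynamics, fragment-length and
mappability biases, PCR duplicates, ligation artifacts beyond the excluded
zone, and diploid mixtures. Passing tests therefore demonstrate the
correctness and sensitivity of the *analysis*, not biological realism of the
locus model.

### A known bias, quantified

Because enhancer and neutral contact frequencies share one denominator that
itself depends on β, the enhancer-vs-neutral log-log slope is
`(δ − z)/(1 − z)` with `z = ∂log D/∂log β` ≈ 0.1–0.25 at this geometry,
not exactly δ: the measured exponent for δ = 1.2 is ≈ 1.27 (and ≈ 1.22 for
the default δ = 1.15). The *ratio* form of the preferential-escalation
property is exact, however: `f_enh(β₂)/f_enh(β₁)` exceeds
`f_neu(β₂)/f_neu(β₁)` by exactly `(β₂/β₁)^(δ−1)`, and the tests assert both
the exact ratio identity and the ±0.1 band on the fitted exponent.

## Problem sizes and determinism

Simulation-based checks use 20–100 seeded replicates at depths 10⁵–10⁶
reads, sizes at which every rate tested (segregation, changepoint
localization, exponent recovery) is stable across seeds. All randomness
flows through `numpy.random.default_rng` seeded explicitly; the pipeline
writes a manifest with a config hash and per-file SHA-256 checksums, and
identical config + seed reproduces byte-identical output bundles.

## Degenerate inputs

Empty profiles (zero total reads), regions with no informative reads,
constant loading tracks, constant vectors in rank correlation, non-positive
values on log axes, even smoothing windows, and mismatched fragment maps all
raise typed errors (`DataValidationError` → CLI exit 3, `NumericError` →
exit 4) naming the offending sample or row rather than propagating NaNs.
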