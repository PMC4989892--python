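# Methods

This note records the model, the numerical conventions and the genuinely
open design choices behind `pcafe`, in the spirit of a statistical
software methods appendix.

## Feature-embedding PCA

The decomposition operates on the features-by-samples matrix `X` (I
probes × J samples) after subtracting each sample column's mean over
probes: `Xc[i,j] = x_ij − mean_i(x_ij)`. Nothing else is done to the
data — no per-probe centring, no variance scaling, no log transform —
because the selection statistic is the raw directional extremity of a
probe and any per-probe normalisation would change which probes are
outliers. The loadings `c_jk` are the right singular vectors of `Xc`
(computed with `numpy.linalg.svd` on the economy decomposition; at
I ≈ 10⁴–10⁵ and J = 24 this is far cheaper and better conditioned than
forming an I × I covariance), and the scores are `x_ik = Xc · c_k`.

**Sign convention.** PCA determines each component only up to sign. Each
loading column is flipped, if necessary, so that its largest-magnitude
element is positive. The convention matters for a *single* directional
top-N set ("larger" vs "smaller" swap under a flip) but not for the union
over both directions, nor for any |ρ|-based quantity; the tests pin this
down.

**Degenerate inputs.** A matrix whose per-sample-centred form is
identically zero (e.g. every probe constant within each sample) has no
principal axes and is rejected rather than silently returning noise.

## Cross-modality PC pairing

Loadings are z-scored over samples with the population (divisor J)
standard deviation, matching the mean-over-samples definition of the
correlation `ρ_kk′ = ⟨Δc_jk Δc_jk′⟩_j`. Using the J−1 divisor would
change nothing downstream (ρ is scale-invariant); a test documents this.

UPGMA is run on the joint 2K-label set under the distance `−|ρ_kk′|`.
The agglomeration is implemented directly (size-weighted running update
of cluster distances) because the pairing rule needs label-level sibling
queries and a fixed deterministic tie-break — ties are broken by the
lexicographically smallest (min-label, max-label) pair — guarantees the
tree is a pure function of ρ. The implementation is cross-checked in the
tests against brute-force agglomeration (recomputing every cluster
distance as the mean over all inter-cluster leaf pairs) and against
SciPy's average-linkage on tie-free matrices.

"Clustered together" is operationalised as *sibling leaves*: a merge of
two singleton clusters, one per modality. Pairs are reported in order of
merge height (largest |ρ| first) and the first pair is the selected one.
A mutual-nearest-neighbour rule (each member the other's best |ρ| match
across modalities) is available as a sensitivity check; on clean
structure the two rules agree.

K = 5 components per modality enter the clustering by default, matching
the five-PC relabelling convention of the stability analysis; K is
configurable.

## Leave-one-out stability

For each left-out sample (removed from both modalities), decompositions
are recomputed on J−1 samples and each reduced PC is matched to a
full-sample PC by greedy maximum-|correlation| assignment between
z-scored loadings restricted to the shared samples, each full label used
once. Greedy (rather than optimal bipartite) assignment is a deliberate
simplicity choice: in practice the correlation matrix of matched PCs is
strongly diagonal after one sample is removed, and the assignment is a
bijection by construction, which a test asserts. The UPGMA tree is then
rebuilt under the relabelled names and a subset counts as conserved when
every target pair is again a cross-modality sibling pair. Whether "every"
or "any" target pair is required is configurable
(`stability_require_all`); the default requires all. The pipeline's
default target is the top pair only (`stability_max_pairs: 1`): with a
single planted factor the second carried pair is a chance pairing among
noise PCs, and requiring its conservation measures nothing — a study
design with two genuine pairs would set it to 2.

## Categorical regression

Each probe is fit with a single categorical predictor (cell-line
identity). The reported P-value is the overall model F-test — the
between-category over within-category mean-square ratio on (L−1, J−L)
degrees of freedom — which for a lone categorical predictor is exactly
the one-way ANOVA F and exactly what a standard linear-model summary
prints. The fit is vectorised across probes via group-indicator matrix
products. No multiple-testing adjustment is applied: selection keeps the
N smallest P-values, and any monotone adjustment preserves that ranking.

Degenerate probes: a completely constant probe carries no information
(P = 1 by convention); a probe with zero within-category variance but
nonzero between-category variance is perfectly separated (P = 0) and
flagged, since its F statistic is formally infinite.

The calibration tests compare the analytic P-values to a 10⁵-draw
Monte-Carlo simulation of the null F distribution (fresh Gaussian
datasets under H₀, for which the F-test is exact), within three binomial
standard errors per probe. A label-permutation null conditional on one
observed dataset is *not* used as the oracle: at J = 24 its distribution
deviates from F by O(1/J) (measured up to |ΔP| ≈ 0.02), which is real
behaviour of permutation tests, not an implementation error.

## Per-gene correlation and group comparison

Per-gene expression–methylation correlation uses the exact t transform
`t = r√(J−2)/√(1−r²)` with J−2 df, two-sided; the
negative-significance flag is `r < 0 ∧ P < 0.05` on raw P-values. The
probe universes of the two platforms differ, so for a gene with several
probes every expression probe is paired with every methylation probe and
the smallest-P pair reported (`best_pair`); averaging probe values first
(`mean`) is available, because the original per-gene reduction rule is
not documented and the two can disagree. The same minimum-P reduction,
flagged, applies to multi-probe genes in the two-group comparison stage,
whose default test is Welch's t (the variance assumption behind the
original P-values being unstated, the pooled flavour is also provided).

## Synthetic data generator

The generator emulates exactly the structure the pairing analysis needs:

| parameter | default | meaning |
|---|---|---|
| `n_probes` | 5,000 | probes per modality |
| categories × replicates | 8 × 3 | the study panel layout (J = 24) |
| `nuisance_variances` | (9.0, 4.0) | loading variances of two modality-private factors |
| `shared_factor_variance` | 1.0 | background loading variance on the shared factor |
| `n_planted` | 50 | probes loading strongly on the shared factor |
| `planted_loading` | 5.0 | |w| of planted probes (vs N(0,1) background) |
| `planted_sign_mix` | 0.5 | fraction with opposite signs across modalities |
| `noise_sd` | 1.0 | residual Gaussian noise |
| `category_effect_sd` | 0.5 | per-cell-line mean offsets (independent per modality) |
| `baseline` | 100.0 | array-intensity offset |

All units are arbitrary array-intensity units. The variance ordering
(9 > 4 > 1) puts the shared factor near PC3 — below two leading private
components, as observed in the study data — and `planted_loading = 5`
places planted probes far outside the N(0,1) background loading tail
(≈ 0.3 background probes beyond |4| are expected among 5,000), so the
planted set is recoverable but not trivially separated once noise is
added. Factor scores are centred and, within each modality, Gram-Schmidt
orthogonalised (shared factor first, identical across modalities): with
only 24 samples, raw Gaussian scores carry chance correlations of order
1/√J that would rotate the shared axis differently per modality and make
the planted ground truth ill-defined. Gaussian factors and noise are an
analyzability choice of the test harness; the pipeline itself makes no
distributional assumption.

**What passing tests do and do not show.** The generator produces clean
low-rank-plus-noise Gaussian structure with exchangeable probes. It does
not emulate array-specific effects — intensity-dependent variance,
beta-value compression of methylation arrays, probe GC effects, batch
structure — so recovery results here demonstrate correctness of the
machinery under its stated model, not performance on any particular
array platform.

## Problem sizes and tolerances

Module tests run on scaled-down instances (hundreds to ~1,500 probes);
the acceptance script and acceptance tests use the full default
conditions (5,000 probes, 24 samples, 20 generator seeds). Orthonormality
and oracle agreements are asserted at 1e-8, z-scoring at 1e-10, UPGMA
height agreement at 1e-12. Probe-id tie-breaks make every ranking and
every tree deterministic; all stochastic tests fix their seeds in the
source.

## Known limitations

- The selection-N (300) trade-off is taken as given, not optimised; the
  package deliberately offers no automatic choice of N.
- Cross-modality probe intersection assumes either a shared probe
  universe (synthetic data) or a probe→gene annotation to intersect at
  gene level; without either, the PCA intersection stage cannot run.
- The leave-one-out analysis relabels only the first K PCs; a component
  that drifts out of the top K after sample removal counts against
  conservation rather than being tracked further down the spectrum.
- `find_coincident_pairs` reports sibling pairs only; a shared factor
  split across two PCs of one modality (factor degeneracy) would be
  missed by the default rule, though it is usually visible in the ρ
  matrix output.
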