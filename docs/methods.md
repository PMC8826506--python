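# Methods

This note records the models behind each stage, the defaults and why
they were chosen, and what the synthetic generators do and do not
emulate. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Plate-assay generative model

A transfected well's luminescence is modelled as

    response = U0 + s_b · ( B + Σ_ligand E_max · c^h / (EC50^h + c^h)
                              + γ · min(occ_a, occ_s) ) + ε,

where `U0` is the receptor-independent plate background (default 20
response units) shared with untransfected control wells, `s_b` a
lognormal transfection-efficiency factor per batch (log-sd
`batch_scale_sd`, default 0.15 — batch-to-batch swings of roughly
±15%), `B` a receptor constitutive signal (default 0), `ε` Gaussian
homoscedastic noise (`noise_sd`, default 5), and occupancies
`occ = c^h/(EC50^h + c^h)`. Untransfected wells read `U0 + ε`, plus a
small receptor-independent artifact (fixed at 10% of the panel's
maximal E_max) for histidine and for two-ligand mixes whose summed
concentration exceeds 175 mM — the two situations where control cells
respond in this assay type.

Two modelling choices matter downstream:

- **The plate background enters transfected wells additively, outside
  the batch factor.** Only the receptor-driven signal scales with
  transfection efficiency; the signalling-machinery background is
  common to all wells. This is what makes sucralose normalization of
  background-subtracted means cancel the batch factor *exactly* in a
  batch-balanced design (a property the tests verify at near-zero
  noise).
- **Synergy is generated as `γ · min(occ_a, occ_s)`,** with the amino
  acid's occupancy computed from its own EC50 even at concentrations
  far below its activation threshold. A potentiator bound at 25%
  occupancy can therefore boost the sugar response even when its solo
  response (E_max · occ) is invisible against noise — the mechanism
  that produces "synergy at sub-activating concentrations" in
  simulation. γ is in response units; 0 means no interaction.

Default design: 6 replicates spread over 3 transfection batches
(replicate *r* in batch *r* mod 3), matching the 4–6 replicates from
2–3 transfections typical of this assay. Fewer than 2 replicates is
rejected because every downstream test needs a variance.

What the generator does *not* emulate: plate-position effects,
receptor-specific noise heteroscedasticity, cross-desensitization
between sequential ligand applications, and any kinetics (responses
are single endpoint values). Passing tests therefore certify the
statistics pipeline, not robustness to those real-data artifacts.

## Agonist calling and normalization

Per (receptor, mix) group: mean and SE = SD/√n (ddof = 1). Calls use
Welch's unequal-variance *t*-test with Satterthwaite degrees of
freedom, alternative "transfected > untransfected", against the
untransfected group that received the same mix; mixes without a
dedicated control fall back to the no-ligand control for background
subtraction but are skipped for testing. The multiple-testing family
is all mixes tested for one receptor in one experiment, adjusted by
Holm step-down (running max of min(1, (m−j+1)·p₍ⱼ₎)); α defaults to
0.05 and is configurable.

Normalized profiles divide each ligand's background-subtracted mean by
the background-subtracted sucralose mean (sucralose being the one
ligand all receptors in this family answer strongly); the value at the
reference is exactly 1 and negative numerators are preserved — they
are only clipped later, inside the response index. Normalization
refuses to proceed when the reference does not exceed its background,
naming the receptor.

Hill fits are bounded multi-start least squares over
(B, E_max, log EC50, h) with h ∈ [0.5, 10], starts from response
quantiles × EC50 quantiles × h ∈ {0.8, 1.5, 3}, best RSS wins.
Requires ≥ 4 distinct concentrations; flat series converge honestly to
E_max ≈ 0.

## Synergy against the additive proxy

The additive estimate for a mix is `mean_a + mean_s − background`,
background counted once so the proxy lives on the raw single-well
scale. For testing, an additive *pseudo-sample* is built replicate-wise
(`a_i + s_i − mean(bg)`), pairing within transfection batch and then by
sorted replicate index, so the batch factor common to the two
single-ligand wells propagates into each pseudo-replicate; unequal
counts truncate to the shorter side with a logged warning. Observed
mix wells are compared with the pseudo-sample by Welch's two-tailed
*t*-test; the synergistic flag additionally requires positive excess,
because a two-tailed p alone cannot distinguish enhancement from
sub-additivity. α defaults: 0.01 for panel screens, 0.05 for dose
ladders; both configurable.

A caveat the exactness property makes visible: if a receptor has
nonzero constitutive signal `B`, the proxy counts `B` twice (once per
single-ligand well) and the comparison acquires a conservative,
sub-additive bias of `s̄·B`. The proxy is unbiased exactly for
receptors whose baseline above the untransfected background is
negligible, which is the regime the assay design assumes.

Dose profiling walks an ascending amino-acid ladder (≥ 3 levels) at a
fixed sugar concentration, emitting one synergy call per level plus a
solo-agonist call for the amino acid alone at that level (one-tailed
Welch vs matched controls, Holm across the ladder) — so "synergistic
but not solo-active" is a directly queryable outcome.

## Trait index and phylogenetics

The relative response index is I = (S − A)/(S + A), with S and A the
sums of sucralose-normalized, background-subtracted values over the
sugar and amino-acid sets, negatives clipped to 0 before summation.
Clipping keeps I within [−1, 1] and prevents a slightly negative
(noise-driven) entry from pushing the index outside its range;
normalized inputs keep receptors comparable despite transfection
differences. The sugar set contains carbohydrates only; sucralose, as
the normalization reference (constant 1 by construction), belongs to
neither sum — including it would compress the index toward +1 by a
constant. Both set memberships are caller-configurable. S + A = 0
raises rather than returning a silent NaN.

Trees are rooted `dendropy.Tree` objects; the seed node is the root.
Under Brownian motion, `C[i, j]` is the branch length shared by the
root-to-tip paths of tips i and j. Ancestral states are the standard
ML point estimates: the state at internal node v is the GLS mean
`(1ᵀC_v⁻¹1)⁻¹ 1ᵀC_v⁻¹ x` with the tree re-rooted at v. Re-rooting is
done without tree surgery: the shared path length from v between tips
i, j equals `(d(v,i) + d(v,j) − d(i,j))/2` in the unrooted metric, and
the test suite checks this construction against an explicit
clone-and-reroot GLS solve to 1e−8. The rate estimate is the ML
`σ² = (x − 1â)ᵀC⁻¹(x − 1â)/n` (biased low by factor (n−1)/n, as usual
for ML). Zero-length branches are lifted to 1e−9 before any inversion;
solves use Cholesky factorization. States are invariant to uniform
branch-length rescaling; σ² scales inversely.

Edge painting is linear interpolation between the parent and child
states at n equally spaced positions (fractions from the parent) — the
simplest rule whose endpoints agree with the node states.

Phylogenetic PCA follows the GLS formulation: phylogenetic mean
`a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹X`, evolutionary covariance
`R = (X − 1aᵀ)ᵀC⁻¹(X − 1aᵀ)/(n − 1)` (rescaled to unit diagonal in
correlation mode), eigendecomposition of R with descending
eigenvalues, and scores as ordinary projections `(X − 1aᵀ)V`. Sign
indeterminacy is resolved deterministically: each loading column's
largest-magnitude entry is made positive. On a star tree with equal
branch lengths (C ∝ I) the whole construction collapses to ordinary
PCA, which the tests verify.

Branch lengths are taken as given in the Newick input (for receptor
work, per-branch synonymous rates dS from a free-ratio codon model);
estimating them is out of scope here.

## Chimera screen

Columns where the two ancestral sequences differ are candidates; a
candidate passes when (a) the substitution is radical, (b) BLOSUM62
≤ 0, and (c) every extant sequence carries the second ancestor's
residue. "Radical" has no single field-wide definition; the default
partition is {hydrophobic AVLIMFWY | polar STNQ | positive KRH |
negative DE | special GCP}, and the class map is a plain argument so
Grantham-style alternatives can be swapped in. Columns with an
ancestral gap are skipped (an indel column cannot be a point-mutation
target); extant gaps fail conservation. Domain assignment (VFT / CRD /
TMD) comes from user-supplied 1-based inclusive ranges — receptor
domain boundaries are construct-specific and are not guessed.

## Bout analysis

Visits are (start_frame, end_frame) events at a known frame rate
(60 fps by default); duration = Δframes / fps, each visit one sample.
The two-sample KS statistic is the supremum ECDF difference evaluated
at pooled unique values, which handles the heavy ties that frame
quantization produces. The p-value is exact whenever n·m ≤ 100 — every
one of the C(n+m, n) assignments of the pooled multiset to the two
groups is enumerated (vectorized over an indicator matrix) — and
otherwise uses the asymptotic Kolmogorov distribution at
D·√(nm/(n+m)). The exact p is conservative under ties and discrete
data, which the type-I tests allow for. Pooling across species, sexes
or seasons is never done implicitly.

The bout generator draws from a two-component lognormal mixture:
brief sampling visits (mode ≈ 0.2 s) and appetitive drinking bouts
(mode ≈ 1.5 s, log-sd 0.35), the per-stimulus mixture weight being the
probability of a long bout; durations are quantized to 1/fps with a
one-frame minimum. It does not model individual birds, repeated
visits by the same animal, or temporal autocorrelation — real feeder
data violate independence in ways this generator cannot expose.

## Pipeline sizes and numerical choices

The bundled demo uses 6 receptors × 8 ligands × 6 replicates across 3
batches, a 6-tip tree, a 60-column alignment and 150 bouts per
stimulus — small enough that a full run takes seconds while every
stage has enough replication to test. Simulation-based checks in the
test suite use 100–2,000 replicates per property, chosen so that
binomial noise on the checked rates is well inside the asserted bands.
Determinism: every generator consumes a `numpy` Generator seeded from
explicit arguments; identical configs reproduce byte-identical
pipeline outputs, and the output manifest records the config hash and
seed.

## Known limitations

- Ancestral-state uncertainty (CIs on node states) is not computed;
  only ML point estimates are mapped.
- The additive-proxy bias under nonzero constitutive baseline (above)
  is documented but not corrected; receptors with strong constitutive
  signal need a different null.
- The Holm family is per receptor per experiment; studies that test
  many receptors jointly may want a broader family.
- The asymptotic KS p is used above n·m = 100 without small-sample
  continuity corrections; near the boundary the exact and asymptotic
  p can differ by a few percent.
- phyloPCA assumes a single Brownian rate regime; rate shifts across
  the tree would distort both the phylogenetic mean and R.
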