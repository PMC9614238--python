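# Methods

## Model and scaling

The phenotype model is y = Xb + Z Σᵢ uᵢ + e with uᵢ ~ N(0, σᵢ²Sᵢ) and
e ~ N(0, σₑ²I_N). Each effect type i has a coded model matrix Wᵢ
(individuals × effect levels) and a scaling constant kᵢ = tr(WᵢWᵢ′)/n, the
average diagonal of the numerator WᵢWᵢ′. The relationship matrix is
Sᵢ = WᵢWᵢ′/kᵢ, equivalently Sᵢ = TᵢTᵢ′ with Tᵢ = Wᵢ/√kᵢ; effects on the
normalized scale are τᵢ = √kᵢ·τᵢᵒ and variances σᵢ² = kᵢσᵢᵒ². Only this
scaling makes the normalized effects, model matrices, and variances mutually
consistent, and it gives σᵢ² the interpretation of the average
per-individual genetic variance of effect type i — which is what lets
hᵢ² = σᵢ²/σ_y² (σ_y² = Σσᵢ² + σₑ²) be read as a genomic heritability and
H² = Σhᵢ² as the total. Because kᵢ-normalization absorbs any global
rescaling of Wᵢ, all downstream results are invariant to the overall scale
of the codings.

Codings (counted-allele frequency p, q = 1 − p), chosen from the standard
genetic-partition lineage:

* additive: allele count g → g − 2p (zero column mean when p is the sample
  frequency);
* dominance: counts 2/1/0 → (−2q², 2pq, −2p²) (zero mean under
  Hardy–Weinberg proportions);
* haplotype additive: one column per (block, haplotype allele h), diplotype
  count of h minus 2p_h. All alleles of a block are kept (no reference
  allele is dropped); the resulting column-space redundancy is harmless
  because the kᵢ-normalized relationship matrix, not Wᵢ itself, enters the
  model. Alleles rarer than `rare_min` (default 0.01) are pooled into one
  "rare" pseudo-allele per block to avoid near-zero-frequency columns
  destabilizing kᵢ;
* epistasis: elementwise products of parent columns over distinct loci —
  unordered pairs/triples, except A×D which stacks the ordered αδ block
  (additive at the smaller index) before the δα block, 2·C(m,2) columns.

Missing genotypes are kept as missing in the raw data and contribute 0 on
the centered scale at coding time (mean imputation), the common GRM
practice. Input filters follow the usual defaults: SNPs with minor allele
frequency ≤ 0.001 (including monomorphic SNPs) or missingness > 0.10 are
removed at read time; both thresholds are arguments.

## Epistasis relationship matrices

Two constructions of the epistasis numerators avoid the explicit epistasis
model matrices:

**Hadamard (approximate).** Entrywise products of the additive and dominance
numerators N_A = W_aW_a′ and N_D = W_dW_d′: N_A∘N_A for A×A, N_A∘N_D for
A×D, ..., N_D∘N_D∘N_D for D×D×D. Products are taken on the unnormalized
numerators and the result is rescaled by its own mean diagonal; this equals
normalizing first and rescaling afterwards (proportionality — unit-tested).
The Hadamard numerator sums locus products over all index tuples, so it
contains same-locus terms that the underlying genetic model excludes.

**Exact (distinct-locus).** Writing xᵢ = w_a,jᵢ·w_a,kᵢ and yᵢ = w_d,jᵢ·w_d,kᵢ
for one entry (j,k), the distinct-locus sums are elementary symmetric
polynomials reduced to power sums p_ab = Σᵢ xᵢᵃyᵢᵇ (each p_ab is one n×n
cross-product of elementwise powers of W_a and W_d, so the whole
construction is O(n²m)):

| type | numerator entry |
|------|-----------------|
| A×A  | (s_x² − p₂₀)/2 |
| D×D  | (s_y² − p₀₂)/2 |
| A×D  | s_x·s_y − p₁₁ (ordered distinct pairs) |
| A×A×A| (s_x³ − 3s_x·p₂₀ + 2p₃₀)/6 |
| D×D×D| (s_y³ − 3s_y·p₀₂ + 2p₀₃)/6 |
| A×A×D| e₂(x)·s_y − s_x·p₁₁ + p₂₁ |
| A×D×D| e₂(y)·s_x − s_y·p₁₁ + p₁₂ |

with s_x = p₁₀, s_y = p₀₁, e₂(x) = (s_x² − p₂₀)/2. Every formula is
validated against the brute-force explicit-model-matrix cross-product on
random fixtures before use (the test suite treats this oracle as the
module's gate), and the Hadamard construction is checked to exceed the
distinct-locus one by exactly the brute-force repeated-index contribution.

**Intra-/inter-chromosome partition** (pairwise types only): the intra
numerator is the sum of per-chromosome numerators; the inter numerator is
the whole-genome numerator minus the intra numerator; each part is
normalized by its own mean diagonal. The partition works identically for
both constructions. Third-order intra/inter splits are deliberately not
provided — the 13-type model replaces only the pairwise types.

The 10-type model orders effect types as A, D, H, A×A, A×D, D×D, A×A×A,
A×A×D, A×D×D, D×D×D; the 13-type model replaces entries 4–6 with intra-A×A,
intra-A×D, intra-D×D followed by inter-A×A, inter-A×D, inter-D×D.

## REML

Estimation runs on the conditional-expectation side: V = Z(Σσᵢ²Sᵢ)Z′ + σₑ²I
(size N, never the mixed-model equations whose coefficient matrix grows with
the number of effects), P = V⁻¹ − V⁻¹X(X′V⁻¹X)⁻X′V⁻¹ via dense Cholesky of
V and a pseudoinverse for the fixed-effect block (rank-deficient X is
allowed; only estimable functions are reported).

Each iteration first attempts the AI-REML update θ ← θ + AI⁻¹Δ with
Δᵢ = −½tr(PAᵢ) + ½y′PAᵢPy and AIᵢₖ = ½y′PAᵢPAₖPy (Aᵢ = ZSᵢZ′, A_{f+1} = I),
and falls back to the EM-REML multiplicative update
σᵢ² ← σᵢ²·[y′PAᵢPy/tr(PAᵢ)], σₑ² ← σₑ²·[y′PPy/tr(P)] whenever the AI system
is singular (condition number above 1e12), produces a non-finite step, or
drives a component negative beyond the floor. Both iterations share the REML
score equation Δ = 0 as fixed point; at convergence the EM update factor of
every retained component is 1.

Numerical choices, all exposed as arguments:

* starting values: σₑ² = ½·var(y), the other half split equally across
  genetic components (symmetric start, no effect type prejudged);
* convergence: max|θ_new − θ_old|/σ_y² < 1e-8, max 1000 iterations (EM can
  be slow on many-component models; the run trace records the algorithm used
  per iteration and the final change);
* zero floor: genetic components below 1e-6·σ_y² are clamped to 0; the EM
  update is multiplicative, so clamped components stay at 0 (this mirrors
  removing zero-variance effect types so the AI step can converge); an
  option records them as dropped;
* the likelihood is available for diagnostics but convergence is
  parameter-based, since both iterations live in parameter space.

## GBLUP, BLUE, reliability

For phenotyped individuals û_i1 = σᵢ²S_i11Z₁′Py₁, ĝ₁ = Σû_i1, and the
total-genetic-value reliability of individual j is
R²₁ⱼ = [G₁₁(Z₁′PZ₁)G₁₁]ⱼⱼ/G₁₁ⱼⱼ with G₁₁ = Σσᵢ²S_i11 (the per-effect-type
version restricts numerator and denominator to one term; the default keeps
the full-model V and P, with the refit-per-subset reading available by
rebuilding the context on the subset). For unphenotyped individuals the
two-set form û_i0 = σᵢ²S_i01Z₁′Py₁ is used: it needs neither S₁₁⁻¹ (so
singular training blocks are harmless) nor any of S₀₀ beyond its diagonal,
which is what R²₀ⱼ = [G₀₁(Z₁′PZ₁)G₁₀]ⱼⱼ/G₀₀ⱼⱼ consumes. The regression form
û_i0 = G_i01G_i11⁻¹û_i1 is implemented for cross-checking where S₁₁ is
invertible. An individual whose fitted genomic variance G_jj is zero gets
reliability 0 with a warning (the quantity is otherwise undefined).
Zeroing the X and Z rows of unphenotyped individuals in a one-step system
reproduces the two-set results exactly; both routes are tested against each
other.

A block Gauss–Seidel mixed-model-equations solver over effect types — each
type solved against phenotypes adjusted for the fixed effects and all other
types — serves as a small-scale oracle; its solutions agree with the
conditional-expectation path to 1e-8 on fixtures where every G_i is
nonsingular. (The residual-variance scaling (Z′Z + σₑ²G_i⁻¹) is required for
that identity.) The overall mean is always absorbed as the intercept column
of X.

## Effect back-solving

τ̂ᵢ = σᵢ²Tᵢ′Z′Py reconstructs the GBLUP exactly (Tᵢτ̂ᵢ = ûᵢ) and equals
Tᵢ′Sᵢ⁻¹ûᵢ when Sᵢ is invertible. Per-effect heritabilities are squared-effect
shares of the type heritability, ĥᵢⱼ² = (τ̂ᵢⱼ²/τ̂ᵢ′τ̂ᵢ)·ĥᵢ², summing exactly
to ĥᵢ². Pairwise epistasis back-solving streams the product columns one
anchor SNP at a time (never materializing the C(m,2)-column matrix) and
refuses requests beyond a `max_pairs` guard (default 5×10⁷ columns);
third-order types are refused outright — their effect-level estimation is
computationally unfeasible. A mixed-model-equations construction of the
per-effect variances from the coefficient-matrix inverse exists purely as a
tiny-fixture oracle for the proportionality behind the heritability shares.
When the relationship matrix being back-solved was built by the Hadamard
construction, its own normalizer must be passed so the reconstruction stays
consistent with the fitted Sᵢ.

## Synthetic data

The generator draws two gametes per individual per SNP at a
uniform-on-[0.05, 0.95] allele frequency (Hardy–Weinberg equilibrium,
independent SNPs, no linkage disequilibrium, unrelated individuals), stores
them phased, and tiles haplotype blocks of fixed length along each
chromosome. Phenotypes are y = μ + Σᵢuᵢ + e. Additive, dominance, and
haplotype effects are drawn per column on the normalized Tᵢ scale, so the
requested variance fraction is the effect-type heritability; epistasis
genetic values are drawn from N(0, σᵢ²Sᵢ) via an eigendecomposition of the
exact relationship matrix — distributionally identical to drawing
per-column epistasis effects, without materializing the pair/triple model
matrix. Every uᵢ and the residual are then rescaled to their exact target
sample variances, so the realized variance composition of each dataset
equals the nominal one; with that convention, replicate-to-replicate spread
in REML estimates reflects estimation error only, not generator noise.

What the generator does not emulate — and what passing tests therefore do
not certify for real data: linkage disequilibrium, family or population
structure, Hardy–Weinberg disequilibrium, selection, genotyping error, and
correlated effect types. In particular, with independent SNPs and unrelated
individuals the pairwise-epistasis relationship matrix at large SNP counts
is numerically close to the identity (off-diagonals shrink as 1/m), making
the epistasis variance weakly identifiable against the residual: at n=500
individuals and m=1000 SNPs the expected-information standard deviation of
the A×A variance is ≈0.7 on the heritability scale, with correlation ≈−0.99
to the residual component. Estimates on such designs wander along a nearly
flat likelihood ridge (this is a property of the design, not of the
estimator — the test suite verifies the optimizer reaches higher likelihood
than the truth on such data). Real livestock populations identify epistasis
variance primarily through family relatedness, which this generator
deliberately omits. The small-m recovery tests, where the information
exists, show the estimator tracking the simulated composition.

## Problem sizes used in tests

Oracle-equivalence and identity tests run on fixtures of 6–20 individuals
and 6–40 SNPs, where the brute-force explicit matrices are cheap. Recovery
tests use n=200–500 individuals and m=60–1000 SNPs; the full pipeline demo
runs at n=300, m=600 with a 60-individual validation split. Some equivalence
fixtures compute codings from externally supplied allele frequencies rather
than sample frequencies: sample-frequency centering makes every numerator
exactly singular (the vector of ones is a null vector), while the
mixed-model-equations oracle requires nonsingular relationship matrices.

## Known limitations

* Fourth-order epistasis and third-order intra/inter partitions are out of
  scope (negligible variance contribution at prohibitive cost).
* No standard errors on variance components or heritabilities.
* Single-trait, one observation per individual by default (repeated records
  enter through an explicit incidence matrix Z).
* Dense O(N³) REML iterations: intended for tens of thousands of
  individuals at most, not biobank scale.
* Phasing and imputation (beyond mean imputation at coding) are assumed done
  upstream.
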