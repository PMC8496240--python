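# Methods

This note documents the statistical model behind `gamrel`, the
numerical choices made in implementing it, what the synthetic-data
generator does and does not emulate, and known limitations.

## Model

### Gametic effects and their collapse

Under Mendelian inheritance each individual i carries two gametic
effects g_i1 (paternal gamete) and g_i2 (maternal gamete); their
covariances over a pedigree of t individuals form the classical
gametic relationship matrix G (2t × 2t): every gamete has unit
variance, a gamete from parent p is in expectation the average of p's
two gametes, and an individual's own two gametes covary by its
inbreeding coefficient F_i. For imprinting analysis every effect
exists in two correlated versions — *as sire* (expressed when
transmitted paternally) and *as dam* — with the 2 × 2 covariance
Σ = [[σ²ₛ, σₛd], [σₛd, σ²_d]], so the full effect covariance is Σ ⊗ G.

Individuals that carry no phenotype do not need per-gamete resolution:
their pair can be averaged into a transmitting ability
a_i = (g_i1 + g_i2)/2. The matrix K′ (m × 2t, m = u + 2v for u
collapsed and v uncollapsed individuals) has a (½, ½) row per
transmitting ability and a unit row per retained gametic effect;

    Ḡ = K′ G K

is the covariance of the mixed vector. Special cases: Ḡ = G (nothing
collapsed) and Ḡ = ½A (everything collapsed, A the numerator
relationship matrix). Diagonals are ½(1 + F_i) for a transmitting
ability and 1 for a gametic effect.

### Direct sparse inversion

Ḡ⁻¹ = (T′)⁻¹D⁻¹T⁻¹ with T lower-triangular, so the inverse is the sum
of one rank-1 contribution u_i u_i′ δ_i per effect. The coefficient
pattern of u_i depends only on the *case*: which kind the effect is
(transmitting ability `a` / gametic `g`) and how each relevant parent
is represented (unknown `0`, transmitting ability `a`, gametic pair
`gg`) — 12 cases in total. Parental coefficients are −½ per
transmitting-ability parent slot of an `a` effect, −¼ per gametic
parent slot of an `a` effect, −1 / −½ −½ for a `g` effect from a
transmitting-ability / gametic parent, and +1 on the effect's own slot.

The inverse Mendelian-sampling variances fall into five classes
(F = inbreeding coefficient of the named parent):

| class | cases | δ |
|---|---|---|
| founder TA | a-00 | 2 |
| one known parent | a-0a, a-a0, a-0gg, a-gg0 | 8 / (3 − F_known) |
| two known parents | a-aa, a-agg, a-gga, a-gggg | 8 / (2 − F_sire − F_dam) |
| gamete, known parent | g-a, g-gg | 2 / (1 − F_parent) |
| founder gamete | g-0 | 1 |

Two of these closed forms are easy to mis-derive from the sampling
variance expressions (a one-known-parent transmitting ability has an
extra founder-gamete half in its sampling variance, giving 8/(3 − F)
rather than 2/(1 − F); a gamete gives 2/(1 − F), not 4/(1 − F)). Each
form equals δ_i = (Ḡ_ii − q_i′ Ḡ q_i)⁻¹ with q_i the negated parental
coefficients, and the test suite pins all five against dense inversion
of Ḡ on constructed pedigrees — that generic identity, not any printed
rendering, is the contract.

Unknown parents are treated as unrelated, non-inbred base founders;
they contribute no coefficient and no F term. The accumulation order
over effects is immaterial. Output is a 1-based lower-triangle triplet
file ("GIV" layout) with a comment header mapping slot index →
(individual, slot kind).

### Genomic counterpart

With all individuals phased into 2t haplotypes over p biallelic
markers, the 0/1 indicator matrix C is column-centered at allele
frequencies p_j and

    G_g = CC′/s,   s = Σ_j p_j (1 − p_j).

Frequencies default to sample column means; base-population
frequencies can be supplied (the reference population is a user
choice — the theory does not fix it). Individuals whose haplotypes
cannot be assigned a parental origin enter through the average of
their two centered rows, which is order-invariant; this is exactly the
K′ collapse, so Ḡ_g = K′G_gK and the pedigree and genomic matrices are
conformable. Monomorphic panels (s = 0) are rejected; markers with
missing calls are dropped, not imputed.

### Mixed model, weights, REML

Observations enter as gametic rows (coefficient 1 on the individual's
own paternal slot in the as-vector and maternal slot in the ad-vector;
residual variance σ²ₑ) or reduced rows (phenotype regressed on the
parents' effects, with the parents' Mendelian-sampling contributions
folded into the residual). A reduced residual has variance
½(1 − F_s)σ²ₛ + ½(1 − F_d)σ²_d + σ²ₑ, encoded as the precision weight

    w_i = σ²ₑ / (½(1 − F_s)σ²ₛ + ½(1 − F_d)σ²_d + σ²ₑ),

with Var(ε_i) = σ²ₑ/w_i and diag(w) entering the mixed-model equations
as the precision multiplier. (Stating the residual covariance this way
— weights as inverse variance *ratios*, variance as σ²ₑ/w — is the one
internally consistent reading of the weighted model, and it reproduces
the weighted normal-equation blocks exactly.) The same weight applies
when the two parents are represented differently (one transmitting
ability, one gametic pair); gametic rows have w = 1 identically.

The coefficient matrix couples the as/ad blocks through
[[α₁, α₂], [α₂, α₃]] = σ²ₑ Σ⁻¹ applied to Ḡ⁻¹. An optional i.i.d.
group (litter) effect with variance σ²_c adds an identity block. The
restricted log-likelihood is evaluated through the standard
mixed-model-equation identity

    −2 logL = (n − p) log 2π + log|R| + log|G| + log|C| + y′Py,

with all log-determinants taken from sparse LU factorizations
(symmetric-mode SuperLU; log|Ḡ| is computed once per design from Ḡ⁻¹).

REML maximizes logL by Nelder–Mead on the transformed parameters
(log σ²ₛ, log σ²_d, atanh r, log σ²ₑ[, log σ²_c]), which enforces
positive variances and |r| ≤ 1, hence σ²ᵢ ≥ 0, by construction. The
search is restricted to |log σ²| ≤ 30 and |atanh r| ≤ 8: outside this
region the 2 × 2 determinant under- or overflows and the likelihood is
numerically meaningless. Inner tolerance is 1e-8 on logL. When reduced
rows are present the weights depend on the unknown components, so an
outer loop starts from equal weights, maximizes, recomputes the
weights from the estimates and repeats until |ΔlogL| < 1e-6 (at most
50 rounds); a non-converged search returns the best point with a
warning. Note the reweighted profile need not reach the exact
all-gametic maximum in highly inbred pedigrees — the two variants are
equivalent only at correctly specified weights.

The Mendelian null is σ²ₛ = σ²_d = σₛd (one additive gametic
variance). Since Σ is then singular, the null is fitted as a
single-vector model with Z = Zs + Zd and covariance Ḡσ²ₐ, which is the
equivalent representation. The imprinting test is an approximate RLRT:
2ΔlogL against χ² with 2 df by default (configurable; no
boundary-mixture correction is applied, so the test is conservative
for the variance-boundary part of the null). Derived parameters use
σ²_p = σ²ₛ + σ²_d + σ²_c + σ²ₑ, h² = (σ²ₛ + σ²_d)/σ²_p,
i² = σ²ᵢ/(σ²ₛ + σ²_d), c² = σ²_c/σ²_p, r = σₛd/(σₛσ_d); these
denominators were chosen for internal consistency (they make the
reported (r, i²) pairs mutually consistent) since several conventions
exist. Standard errors, when requested, come from the numerical
Hessian of logL in the untransformed components (central differences,
relative step 1e-3).

### Model equivalences as tests

Three exact equivalences are exploited as oracles in the test suite:
(1) the generalized model and the classical all-gametic model are the
same marginal model for y — identical restricted likelihood and fixed
effects, with transmitting abilities equal to the average of the
corresponding gametic pair; (2) reduced rows with weights computed at
the true components reproduce the gametic-row likelihood exactly
(final progeny have no descendants, so their Mendelian-sampling terms
appear in no other observation); (3) the dense inverse of Ḡ equals the
rule-built sparse inverse. None of these checks shares code with the
path it validates beyond the pedigree parser.

## Algorithms and numerics

* Inbreeding: tabular recursion (dense ½A) up to t = 2000, an
  ancestor-path (Meuwissen–Luo-style) algorithm above; both are exact
  and cross-checked. Dense matrix construction refuses t > 2000 by
  default — the sparse inverse is the production path.
* Topological ordering: depth = 1 + max(parent depth), stable on input
  order, so founders keep file order; cycles and duplicate ids are
  errors; parents that never appear as rows are auto-inserted as
  founders with a warning; id 0 is reserved for "unknown".
* The worked-example matrix is reproduced in exact arithmetic (all
  entries are quarters; tests compare 4Ḡ as integers). Everything else
  uses double precision with oracle tolerances of 1e-9 (inverse
  equivalence), 1e-10 (genomic identity), 1e-6 (likelihood
  equivalences).
* Triplet output sums duplicate entries, keeps the lower triangle
  sorted by (row, column) and prints 12 significant digits.

## Synthetic data

`SimulationConfig` describes a closed random-mating population:
n_founders founders, n_generations discrete generations, n_matings
random sire × dam pairs per generation (sib-avoidance optional),
Poisson litter sizes. Records are carried by final progeny —
non-founders that never reproduce — matching the structure of real
parent-of-origin data sets, where most phenotyped individuals are
non-parents; phenotyped individuals are represented by gametic pairs,
all others by transmitting abilities. Gene dropping gives every gamete
a bivariate (as-sire, as-dam) effect: founder gametes ~ N(0, Σ),
transmitted gametes = parental average + N(0, ½(1 − F_parent)Σ), so
the realized covariance is Σ ⊗ G exactly in expectation. Phenotypes
are y = μ + generation effect + g_pat(as sire) + g_mat(as dam) +
litter + e. Marker haplotypes gene-drop 0/1 alleles with per-marker
independent transmission.

Defaults (Σ = [[1, .5], [.5, 1]], σ²ₑ = 1, five generations, ~40
matings of mean litter 5 → t ≈ 1000 with ~700 records) give a
moderately inbred multi-generation population at a size where a full
REML fit takes seconds; the recovery harness runs 50 replicates at
this size rather than fewer replicates of a larger population, which
bounds Monte-Carlo error on the bias check without exceeding a desk
runtime. What the generator does **not** emulate: selection (matings
are random), linkage (markers segregate independently), non-normal
effects, maternal genetic effects, missing or erroneous pedigree
links. Passing tests therefore demonstrate correctness of the
machinery under the stated model, not robustness to model violations
in real data.

## Known limitations

* Maternal genetic effects are out of scope (they are confounded with
  imprinting variance in reduced-equation analyses).
* No single-step blending of Ḡ and Ḡ_g into one matrix.
* The RLRT reference distribution is plain χ²; boundary corrections
  and simulation-based nulls are left to the user.
* Haplotype phasing itself is assumed done upstream; unphased
  genotypes of origin-ordered individuals are rejected, not phased.
* Standard errors are numerical-Hessian approximations; no
  average-information REML machinery is provided.
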