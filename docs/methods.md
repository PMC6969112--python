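# Methods

## Genetic model

Every drive locus carries alleles from the closed set {W, T, R, B}: wild
type, transgene, in-frame (function-preserving) resistant, out-of-frame
(loss-of-function) resistant.  Architectures are described by their loci
(one `fused_site` for full drives; a `cas9_site` plus a `grna_site` for
split drives), chromosome type (autosome or X), and a recombination fraction
between the two loci of a split drive (0 for the linked variants, 0.5 for
the freely recombining `tGDc`/`tGDXc`).  Males of X-linked architectures are
hemizygous: a single haplotype plus a drive-free Y.

Offspring distributions are composed from three exact probabilistic
transforms, expanded symbolically in double precision (row sums of the
inheritance cube emerge exactly from construction; no renormalization is
ever applied):

1. **Germline conversion.**  A wild-type allele is *drive-competent* when
   the genotype carries at least one Cas9 source and one gRNA source and the
   homologous chromosome carries the transgene at that locus (the repair
   template).  Each competent allele independently: cleaved with probability
   `q[locus, parental sex]`; given cleavage, converted to `T` with
   probability `c[locus, sex]`; otherwise end-joined to `R` with probability
   `rho`, else `B`.  Conversion events at the two loci of a split drive are
   treated as independent given competence — there are no joint data to
   constrain a correlation, and the independence assumption is the simplest
   one consistent with the single-locus rates.  Hemizygous males have no
   homolog and therefore never convert.
2. **Segregation.**  Mendelian, with recombinant haplotypes formed at the
   architecture's recombination fraction; hemizygous males transmit X or Y
   with probability 1/2.
3. **Maternal deposition.**  Active only when the mother's own genotype
   carries both components.  Each zygotic `W` allele at a drive locus is
   cleaved with probability `d[locus]` and repaired by end joining only
   (`R` with probability `rho`, else `B`).  Deposition never performs HDR:
   double-carrier-maternal crosses show ~50% transmission and a single
   early clonal indel, which is incompatible with embryonic conversion.
   Deposition depends on the mother's genotype only — no grand-maternal
   carryover of ribonucleoprotein is modeled.

Defaults (`q = 1`, `c = 1`, `d = 0`, `rho = 1`, all fitness multipliers 1)
encode the exploratory parameterization used for the population modeling:
complete cleavage, cost-free in-frame resistant alleles, no fitness costs.
Somatic mosaicism from leaky promoter expression carries no fitness or
phenotype consequence in the model.

Genotype ordering is deterministic: haplotypes sort lexicographically by
per-locus state code (W < T < R < B), unordered pairs are canonicalized with
hap1 ≤ hap2, and the single canonical string code (e.g. `TA-WB/WA-TB|F`,
`T/Y|M`) is used across all file formats.

## Cross-outcome model

One vial = one scored F1 individual outcrossed to wild type.  Cleavage in
the F1 has two phases:

* **Zygotic phase** (probability `z` per target W allele), active only when
  the F0 mother deposited both components.  A cleaved allele fixes a single
  indel identity clonally across the entire germline — hence exactly one
  distinct resistant allele per vial and Mendelian marker transmission when
  `z` is high.
* **Germline phase**: each of `k` primordial germline precursor cells
  (default `k = 3`, the approximate number of pole-cell precursors set aside
  at the 128-cell stage of the fly embryo) independently resolves each
  remaining competent W allele once, with per-cell cleavage `q_late` and
  conversion `c_late`.  Each F2 offspring samples a precursor cell
  uniformly, then a gamete.  The clonal structure bounds the number of
  distinct indels per vial by `k` per locus; observed ranges up to 4 with
  ~3 pole cells would require `k > 3` or residual post-pole-cell editing,
  which we leave as a configurable parameter rather than a mechanism.

Indel identities are categorical: a small set of recurrent labels with fixed
probabilities plus an "infinite tail" of always-novel singleton identities
(defaults: three recurrent labels per locus with tail mass 0.07 at the
*white*-style locus and 0.19 at the *yellow*-style locus, matching the
observed singleton fractions).  Labels are namespaced by a per-locus tag
(`wA`, `wx7`, `yB`, ...), and sequencing-style records report labels on male
offspring only, since hemizygous males expose the maternally derived X.

Phenotype mapping: DsRed tracks the Cas9 transgene, GFP the gRNA transgene;
body/eye phenotypes derive purely from functional-allele content (W and R
functional, T and B not); mosaicism is not scored.

Schemes in which a single F0 parent contributes both elements are modeled
through the coupled double-homozygous line only; a trans-heterozygous single
F0 carrier (requiring segregation plus recombination in the F0 germline) is
out of scope.

## Inference

`fit_conversion` with the `germline_only` model maximizes a binomial
likelihood with common marker probability p = 1/2 + (q·c)/2 across vials;
the MLE is the pooled positive fraction mapped through that line, with a
percentile bootstrap over vials (default 2000 resamples) for the CI.
Boundary estimates are flagged, and the raw (unclamped) value is reported
alongside.  The `zygotic_mixture` model fits the two-component per-vial
mixture implied by the timing model — a fraction `z` of germlines fixed at
p = 1/2 by zygotic cleavage, the remainder at 1/2 + (q_late·c_late)/2 — by
L-BFGS-B from multiple starts.  The mixture likelihood treats each vial as
a plain binomial within its component, ignoring the extra-binomial variance
contributed by the finite pole-cell number; it is a quasi-likelihood in that
respect.

Randomization tests permute pooled observations uniformly and use the
add-one convention p = (1 + #extreme) / (n_perm + 1) (never exactly 0,
conservative); both tests are two-sided, with 5000 permutations by default.
The pooled vector is sorted before permuting so that exchanging equal-sized
groups gives bit-identical p-values.

## Population dynamics

Single patch, daily time step, no spatial structure, seasonality, or
multiple mating.  State: egg/larva/pupa cohorts indexed by (age-in-stage,
genotype-and-sex), adult males by genotype, adult females by (own genotype,
stored mate genotype).  Daily order: oviposition → survival → stage
advancement and emergence → mating of newly emerged females → releases.
Females mate once upon emergence, sampling a mate proportional to adult male
counts weighted by fitness; females emerging with no males present remain
unmated permanently and lay nothing (logged, not an error).

Calibration.  Juvenile daily mortality μ_J is identical across juvenile
stages and solves the daily Euler–Lotka identity of the density-free
linearized dynamics,

    1 = (β/2) (1−μ_J)^τ r^(−τ) / (r − (1−μ_M)),    τ = T_E + T_L + T_P,

by bracketed root finding (tolerance 1e-10); `r` is interpreted as the daily
multiplicative growth factor of the full lifecycle linearization.  Density
dependence acts on larvae as the daily survival multiplier
(α/(α+L_total))^(1/T_L) — the standard Deredec-style form used by the cited
framework family; the exact expression is not printed in the source
framework's description, so equivalence is claimed at the level of
equilibrium and growth rate, not bit-for-bit.  α follows in closed form from
the adult balance at equilibrium (f*^T_L = 2 μ_M / (β (1−μ_J)^τ)) and the
equilibrium larval cohort recursion; by construction the deterministic model
then holds N adults exactly, which the tests verify over a year.  `N` is the
total adult population (females plus males, N/2 each at equilibrium).

Stochastic mode draws Poisson egg counts (mean β per female per day — the
count distribution is otherwise unspecified, and Poisson is the maximum-
entropy default), multinomial offspring genotypes from the cube row,
binomial survival, and multinomial mate choice; deterministic mode
propagates the exact expectations of the same step.  Equilibrium cohorts are
integerized by the largest-remainder method.  Replicate RNG streams are
spawned from the master seed via `numpy.random.SeedSequence`.

Releases default to the studied program: 5 weekly releases of 100 adult
males homozygous for the drive, starting after a 50-day burn-in (the burn-in
length is not specified by the study conditions; it is configurable and only
sets the time origin).

## Scenario metrics

*Carrier fraction*: adults with ≥1 `T` allele over total adults (0 when the
population is empty).  *Allele counts*: per-day copy counts per (locus,
state); X-linked loci contribute 2 copies per female and 1 per male.
*Time to steady state*: first day from which every subsequent 30-day window
of the carrier series has range < 0.001 (the windowed-range definition
alone would fire during the flat pre-spread phase, so experiments use the
"settled from here on" scan).  *Crash*: adult-female extinction, measured
relative to the first release day (1.5 years = 548 days).  *Rebound*: a
post-release minimum of total adults below 0.95 N (a genuine suppression
transient — equilibrium noise is of order √N ≈ 1% of N) followed by
recovery to ≥ 0.5 N.  All metrics are pure functions of trajectories.

In suppression mode the gRNA (or fused) locus sits in a gene required in at
least one copy for female fertility: females with zero functional alleles
(W or R) there are sterile.  In-frame resistant alleles are the rescue
channel — at conversion 1.0 none form and every replicate crashes; at 0.99
they arise, restore fertility, and the population rebounds.

## Synthetic data

The fixture generator is the ground-truth source for parameter-recovery
tests: every fixture embeds its generating parameters in a JSON manifest and
regenerates byte-identically from its seed.  Defaults mirror the scored
experiments' shape: 11 vials × 50 flies per vial, k = 3 precursor cells,
three recurrent indels per locus with singleton tails of 0.07/0.19.  The
generator emulates the statistical structure of per-vial scoring data —
marker counts, phenotypes, labeled male records — not vial-by-vial values of
any real dataset; real data add features the generator omits (variable vial
sizes, locus-specific deposition asymmetries, genetic background effects),
so passing recovery tests demonstrates correctness of the inference under
the model, not robustness to those effects.

## Problem sizes used in tests

The suppression and rebound checks run 10 stochastic replicates at
N = 10,000 for 3 simulated years; parameter recovery uses 100 tables of
20 vials × 50 flies per conversion value; cube-oracle equivalence uses 20
random parameter vectors (exhaustive over parental pairs for the one-locus
drive, sampled pairs for the two-locus drive, tolerance 1e-12); replacement
orderings are asserted on deterministic trajectories at N = 2,000.  These
sizes were chosen as the smallest that make the assertions statistically
meaningful.

## Known limitations

* Indels are categorical labels; no nucleotide-level cut-site or gRNA
  efficiency modeling (impaired-homology biology enters only as alternative
  per-construct conversion values).
* Per-locus deposition probabilities can differ, but the observed
  asymmetry between co-deposited elements (e.g. 67% vs 53% marker
  inheritance from a double-carrier mother) is not reproduced by any
  symmetric `d`; locus-specific deposition values capture it only
  partially and are not separately identifiable from marker means alone.
* Single patch; no migration, seasonality, temperature dependence, adult
  age structure beyond constant mortality, or remating.
* Whether a "crash" in the modeled sense means strict extinction or a
  threshold is a definition choice; strict adult-female extinction is used,
  with the threshold configurable.
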