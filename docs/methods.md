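# Methods

## The problem

Commercial SNP arrays report unordered genotypes. In breeding
populations the typical material is a large half-sib family: one
genotyped sire, tens of progeny, and ungenotyped dams drawn from a
population whose gametes carry linkage disequilibrium (LD). Phasing the
sire and the progeny from this material requires knowing, for every
pair of consecutive SNPs, whether the sire's meioses recombined between
them — but with a single genotyped parent the recombination fraction
`c` and the dam-population LD `δ` both shape the offspring genotype
distribution and must be estimated jointly.

## Transmission model

For two biallelic SNPs `T/t` and `M/m`, a double-heterozygous sire in
coupling phase (`TM/tm`) transmits the parental gametes `TM` and `tm`
with probability `(1−c)/2` each and the recombinants `Tm` and `tM` with
probability `c/2` each (repulsion swaps the roles of `c` and `1−c`).
The maternal gamete is an independent draw from the dam haplotype
frequencies `f_TM, f_Tm, f_tM, f_tm`, with

    f_TM = δ + f_T f_M,   f_Tm = −δ + f_T f_m,
    f_tM = −δ + f_t f_M,  f_tm = δ + f_t f_m,
    δ = f_TM f_tm − f_Tm f_tM,

`δ` bounded by `max(−f_T f_M, −f_t f_m) ≤ δ ≤ min(f_T f_m, f_t f_M)`.
Offspring fall into nine unordered two-locus genotype classes whose
probabilities are sums over the 4×4 (sire gamete × dam gamete) table;
the observed-data likelihood is multinomial in the nine class counts
(the multinomial coefficient is dropped — it cancels in maximisation
and in the phase posterior).

## EM estimators

The complete data augment each offspring with its sire-gamete and
dam-gamete identity. The E-step distributes each class count over the
compatible cells of the gamete table in proportion to current cell
probabilities; the M-step sets the dam haplotype frequencies to the
normalised expected gamete counts and `c` to the expected recombinant
fraction, clamped to `[0, 0.5]` (phase symmetry makes `c > 0.5`
unidentifiable from phase). The same machinery covers every sire
genotype through its gamete-mix vectors: a sire homozygous at a locus
contributes dam-gamete information but its expected recombinant
fraction is identically `c` (no linkage information), and a double
heterozygote of unknown phase is a two-component mixture with the phase
posterior recomputed each iteration. The multi-family estimator pools
expected gamete and recombinant counts across families weighted by
family size, re-deriving `f_T = f_TM + f_Tm` and `f_M = f_TM + f_tM`
every iteration; `c` is reported as NaN when no family has a
double-heterozygous sire.

The phase posterior for a SNP pair is formed from the two separately
maximised (profile) likelihoods, `L_c / (L_c + L_r)`, evaluated with
log-sum-exp.

Convergence is declared when the largest absolute change in
`(f_TM, f_Tm, f_tM, f_tm, c)` drops below `1e-8` (cap 10,000
iterations, flagged if hit). The default estimator adds five seeded
random restarts to the deterministic start (linkage-equilibrium
frequencies from observed allele counts, `c = 0.25`) and keeps the
best-likelihood solution, because the surface can be multimodal when
`c` and `δ` are confounded.

### The reference Monte-Carlo estimator

The table-replication harness (`sim.replicate_experiment`,
`sim.table_experiment`, `scripts/acceptance.py`) deliberately uses the
single deterministic start and conditions on the sire's known simulated
phase. Two measured facts drove this choice:

* At intermediate allele frequencies the model is *exactly*
  non-identifiable across phases for negative LD at the boundary:
  coupling with `(c=0, δ=−0.1)` induces the same offspring distribution
  as repulsion with `(c=0.3, f_Tm=f_tM=0)`. Free phase selection
  therefore scrambles the negative-δ reference rows; the reference
  designs fix a known-phase double heterozygote.
* Where `c` and `δ` are jointly positive the likelihood has a long,
  nearly flat ridge (see the surfaces below). Restart selection then
  reports an essentially arbitrary ridge point: at
  `(c=0.2, δ=0.2, N=2000)` best-of-restarts averages `ĉ ≈ 0.137` while
  the deterministic-start EM averages `ĉ ≈ 0.107` — numerically higher
  likelihood (verified against the grid oracle), but a less
  reproducible point estimate. The deterministic start is kept for all
  tabulated comparisons; restart selection remains the default for
  phasing, where only the phase call and the zero/nonzero character of
  `ĉ` matter.

### LE-constrained baseline

The classical single-parent linkage estimator forces
`δ = 0` (haplotype frequencies = allele-frequency products). It is
implemented as the same EM with the constrained M-step and serves only
to quantify the bias incurred by ignoring dam-population LD: with
`δ = 0.2` truth it attenuates `c = 0.10` to ≈ 0.012.

### Grid oracle

An independent brute-force maximiser guards the EM: exhaustive lattice
over `(c, f_T, f_M)` at step 0.01 with `δ` profiled out inside its
admissible interval — the likelihood is concave in `δ` for fixed
`(c, f_T, f_M)` because class probabilities are affine in `δ`, so a
17-point screen plus golden-section search is exact — followed by six
shrinking local-refinement rounds (factor 10 per round) so that
boundary maxima (allele frequencies approaching 0 or 1, `c` at 0) are
approached closely. EM and oracle agree in log-likelihood to better
than `1e-3` on hundreds of random instances; this, not the printed
update formulas (typographically corrupted in the source material), is
the correctness certificate for the EM.

### Identifiability surfaces

Replacing counts by their expectations under true parameters gives the
infinite-sample likelihood surface over `(c, δ)` with allele
frequencies held at truth. On a 0.05 lattice the maximum sits at the
truth whenever `c = 0` or `δ = 0`, and at `(0.10, 0.15)` when the truth
is `(0.20, 0.20)`: with a single genotyped parent the two parameters
are confounded unless one of them vanishes — which is exactly why
fragment boundaries (where `ĉ > 0`) are trustworthy while interior
`ĉ = 0` calls are what phasing relies on.

## Monte-Carlo generators

* **Single family** — offspring classes drawn by cumulative-probability
  inversion of uniforms over the nine class probabilities. Per-replicate
  generators come from `SeedSequence` spawning, so replicate `r` is
  reproducible independently of how many replicates run.
* **Multi-family** — each sire's two haplotypes are drawn from the dam
  haplotype frequencies (so sires may be double/homo-heterozygous or
  homozygous); progeny are simulated by sire meiosis (parental gamete
  with prob. `(1−c)/2` each, recombinant `c/2` each) plus a dam gamete.
  Family sizes default to the six-family design (94, 77, 106, 81, 79,
  100).
* **Phased chromosome** — the sire is heterozygous at every simulated
  SNP (homozygous SNPs are phase-trivial); the paternal gamete carries
  0–3 crossovers with probabilities 0.511494 / 0.398467 / 0.081418 /
  0.00862 at positions uniform on the physical map (both meiotic
  products switch at every crossover; one is transmitted at random);
  the maternal haplotype is a first-order Markov chain driven by
  per-adjacent-pair haplotype frequencies. The helper
  `markov_pair_freqs` emulates dense-array short-range LD: allele
  frequencies uniform in (0.15, 0.85) (arrays are pre-filtered for
  extreme MAF) and per-pair `δ` a random 30–60% of its admissible
  maximum. What this does **not** emulate: genotyping errors, map
  errors/mis-assembled markers, crossover interference, varying marker
  density, or the long-range LD structure of any real chromosome — so
  passing accuracy figures certify the machinery under clean Markov LD,
  not performance on any particular real array.

## The fragmentation phasing strategy

1. **QC** — keep SNPs called in at least `ceil(2/3 · n_progeny)`
   progeny (the 24-of-36 rule; with hard genotype calls the 0.80
   per-call confidence acts upstream) and with MAF ≥ 0.10 over called
   sire + progeny alleles; drop SNPs with a missing sire genotype; then
   drop any SNP with a sire–progeny Mendelian inconsistency (one bad
   calf discards the SNP family-wide; the violation list doubles as the
   genotyping-error report).
2. **Scan** — joint `(ĉ, δ̂, phase posterior)` for every pair of
   consecutive sire-het SNPs (the right SNP of one pair is the left of
   the next) within 50 Mb; larger gaps are skipped and force a
   boundary. All pairs of a chromosome run as one batched EM.
3. **Fragmentation** — `ĉ > 1e-4` (configurable; the EM returns tiny
   positive values from finite tolerance, so "greater than 0" needs a
   numeric floor) closes a fragment at the pair's left SNP and opens
   the next at its right SNP. Degenerate pairs and exactly ambiguous
   phase posteriors (0.5) also split, the latter with a warning.
   Sire-homozygous SNPs ride along with the preceding het SNP's
   fragment.
4. **Sire phasing** — chain the pairwise phase calls (posterior > 0.5 ⇒
   allele1-with-allele1) left to right into two complementary strings;
   hom SNPs appear on both. Fragment labelling is arbitrary up to swap.
5. **Progeny phasing** — any progeny-homozygous/sire-het SNP in a
   fragment votes for the transmitted sire haplotype; agreeing votes
   fix the fragment origin, and then the paternal allele is the sire
   haplotype allele at *every* SNP of the span (this is where
   sire-het/progeny-het sites — uninformative in isolation — become
   informative), the maternal allele the genotype's other allele.
   Conflicting votes flag the span (within-fragment recombination or
   genotyping error) and leave origin-dependent calls unset; missing
   genotypes get an imputed paternal allele and no maternal call.
6. **Linkage between fragments** — adjacent fragments' labels are
   aligned to minimise origin switches (ties flagged unresolved, which
   breaks the alignment chain); the boundary recombination estimate is
   switches/informative. Recombination events are then read from each
   calf's genome-ordered *vote sequence*: every label change — across a
   boundary or inside a conflicted fragment — is an event bounded by
   the two flanking vote sites and assigned to the interval midpoint.
   The within-fragment part matters: with 36 progeny a single
   recombinant is often absorbed into `δ̂` (the confounding above), so
   no boundary forms there, yet the calf's inherited configuration
   still switches; walking votes rather than boundaries raises
   crossover recovery from roughly 85% to above 99% in the chromosome
   simulation.
7. **Genome-wide fragment scan** — the super-allele estimate
   `min(s, n−s)/n` between a query fragment and every other fragment
   flags mis-assembled markers (unlinked to neighbours, tightly linked
   somewhere else).
8. **ROIs** — maximal runs (≥ 20 SNPs) of identical, jointly known
   same-origin alleles between two individuals; the reported proportion
   is shared SNPs over jointly phased SNPs (identity is defined on SNP
   alleles; a bp-based denominator is available via `basis="bp"`).
   Unknown calls break runs.

Event matching against simulation truth is greedy one-to-one nearest
matching within 3 Mb, per calf and chromosome.

## Numerical and design notes

* Genotypes are stored as sorted integer code pairs (0/1, −1 missing);
  a half-missing genotype is treated as missing.
* Monomorphic-in-progeny markers are refused by the estimators with an
  explicit error rather than returning silently degenerate values; the
  scan records such pairs as `degenerate` (they neither split nor phase
  anything on their own — they split fragments because the phase chain
  cannot cross them).
* Coordinates: SNP row indices are 0-based with inclusive spans; bp
  positions are 1-based as in map files; event positions are interval
  midpoints.
* Replicate summaries report mean and population SD; a single replicate
  has SD 0 by convention. Estimator failures (NaN) are counted and
  excluded.

## Problem sizes used by the shipped checks

Chosen as the package's standard verification scale: single-family
designs run 2,000–10,000 replicates depending on family size; the
six-family design runs 5,000–10,000 replicates; the chromosome
simulation uses 751 sire-het SNPs on a 158 Mb map with 36 progeny and
100 replicates (the density at which a ~50k array covers a large
autosome). Re-running with more replicates only narrows Monte-Carlo
error.

## Known limitations

* With one genotyped parent, `(c, δ)` are jointly identifiable only
  when one of them is zero; interior estimates on the confounded ridge
  are start-dependent and should be read qualitatively.
* For negative `δ` at intermediate allele frequencies the sire phase
  itself is not identifiable at `c = 0` (an exact distribution-level
  equivalence, not a finite-sample effect). The phasing pipeline is
  unaffected when consecutive-pair LD is positive in the sire-phase
  allele orientation, but phase calls at strongly negative-LD pairs
  carry little information.
* Crossovers beyond a calf's outermost origin-informative site, and
  even numbers of crossovers between two consecutive informative sites,
  are undetectable in principle; they bound event recovery below 100%.
* No modelling of genotyping error inside fragments beyond surfacing
  conflicts; distinguishing error from true double recombination is
  left to the genome-wide fragment scan and the user.
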