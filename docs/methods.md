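# Methods

## Transmission model

The simulator is a forward-time, individual-based model of *C. elegans*
inheritance at chromosome resolution.

**Karyotype and sex.** Six chromosomes; hermaphrodites are XX and males
X0. Hermaphrodite gametes always carry an X; male sperm carry the X or
no X with probability 1/2 each, which yields the 1:1 sex ratio of
cross-progeny. Self broods additionally produce spontaneous males by X
nondisjunction at rate `male_rate` (default 0.002 — the literature-range
spontaneous rate; the source procedures give no number). The exact
enumeration oracle ignores `male_rate`: it is the Mendelian limit, and
at the brood sizes used the bias it removes is far inside the sampling
bands the tests assert.

**Segregation.** Each autosome assorts independently; there is no
recombination map. Linkage is therefore binary at chromosome scale: two
loci on the same chromosome always co-segregate within a haplotype. This
is the right granularity for balancer-based mapping, which asks only
"which chromosome", not "where on it". A `epsilon` knob (default 0)
allows breakthrough recombination between a balancer and its normal
homolog per meiosis, as a robustness lever for the sampling path; the
enumeration oracle requires `epsilon = 0` and raises otherwise.

**Balancers.** Reciprocal translocations balance two chromosomes, and
their two halves segregate together (alternate segregation): a gamete
receives either both halves or both normal homologs, each with
probability 1/2. Unbalanced (adjacent) products would be aneuploid and
inviable; by default they are folded into the redraw of inviable
conceptions, so a brood of size *n* means *n* scorable animals — which
is how plates are actually screened. The `emit_unbalanced` switch
(probability `unbalanced_prob = 0.5` of independent assortment per
meiosis) exposes them for brood-viability studies. Balancer homozygote
fates are configuration per balancer: hT2[qIs48] lethal, nT1[qIs51]
lethal, eT1 viable with an Unc phenotype, mIn1[mIs14] viable. These
follow the standard descriptions of the elements; the mapping statistic
(Red among nonGreen) conditions on nonGreen animals and is insensitive
to the choice.

**Phenotype.** Dominant alleles, balancer markers and array tags express
with one copy; recessive alleles require every haplotype of their slot
(so hemizygous males express X-linked recessives). Penetrance defaults
to 1.0, with a per-tag knob for robustness experiments. Array tags are
always dominant; recessive array expression is not modeled.

**Arrays.** Extrachromosomal arrays transmit per conception with their
`transmission_prob` (default 0.65), making the carrier count in a brood
Binomial(n, p) regardless of parental zygosity at chromosomal loci. A
per-gamete variant (`per_gamete=True`) transmits through each carrier
gamete independently; with p = 0.5 this reproduces the segregation of a
free duplication, i.e. an element unlinked to every chromosome. Note the
single-gamete marginal and the per-conception rule differ for selfing
(1 − (1 − p)² vs p); the brood-level operations use the per-conception
rule because the 65%-transmission figure is a per-progeny observation.

## Enumeration oracle

`enumerate_offspring` computes the exact offspring distribution as the
product of the two parental gamete-class distributions (segregation
units × X transmission × array carry/no-carry branches), canonicalizes
genotypes so homolog order is irrelevant, and reports both the
unconditional and the viable-conditioned distributions. Probabilities
sum to 1 within 1e−12 (asserted at construction). Every printed
expectation in the pipelines — 3/16 doubly marked F2, 75%/100% Green in
the cross stages, the 1.0/0.75 and 0.0/0.5 linkage anchors — is
cross-validated against this oracle, and the sampling path is checked
against it class-by-class at n = 10,000 within 3 binomial SD.

## Linkage pipeline

Each autosomal test simulates the full protocol: balancer-strain Green
male × Red hermaphrodite, selection of a Red-Green F1 hermaphrodite
(retried over up to 10 broods, then a protocol failure), selfing, and
scoring. `n_scored` counts *informative* animals — nonGreen F2 for the
autosomal tests, F2 males for the X test — so every test has the same
binomial precision on p_obs; screening continues over additional broods
until the quota is met. Males are excluded from autosomal scoring by
default (hermaphrodite X-segregation would otherwise distort the
Red-among-nonGreen fraction when the transgene is X-linked).

The Linkage Index is the affine normalization of p_obs between the
unlinked (LI = 0) and fully linked (LI = 1) expectations, clipped to
[−1, 1]. A test is called linked when LI ≥ 0.5 (half-way between the
anchors); an exact two-sided binomial test against p_unlinked is
reported alongside because the index itself has no sampling theory.
Chromosome inference is set algebra over the coverage table
(hT2→{I,III}, eT1→{III,V}, nT1→{IV,V}, mIn1→{II}, X-test→{X}): a
chromosome is implicated iff it is covered by every linked test and by
no unlinked test; an inconsistent pattern returns the empty set. With
n_scored = 200 the unlinked anchor sits ~4 binomial SD below the call
threshold, which is why recovery across all placements is essentially
certain at that size (verified over 20 seeds per placement).

The unplaced control places the Red element on a free-duplication-like
carrier (per-gamete p = 0.5), which reads unlinked in all five tests —
the only configuration that can, since the five coverage sets together
span all six chromosomes.

## Protocol engine

Bench actions are Bernoulli draws from a single seeded generator:
pick-up and put-down each succeed with 0.90 by default (success of a
transfer is their product), picked animals survive with 0.97, worms
escape with 0.01 on a failed attempt, screens misclassify each animal
independently with `phenotype_error` (default 0), and plates are
contaminated at creation with `contamination_prob_per_plate` (default 0;
a manual-bench preset uses 0.034). These rates are *inputs* describing a
bench — the package does not claim to reproduce the measurements behind
them, nor hardware figures like sorting throughput. Scripts form a
three-level hierarchy (high → mid → low, enforced at construction), and
execution is depth-first with per-action logging; identical seed and
configuration give byte-identical logs.

The cross driver follows the published pick counts (17 + 4 for male
generation, 6 + 2 for P0, 2 F1 / 3 F2 / 11 F4 singled, F5 screened at
40 per line) and calls a line homozygous iff 100% of its screened
progeny are Green. Broods are sampled (default) or enumeration-backed:
the exact mode apportions class counts by largest remainder and
interleaves classes, and singling then picks evenly spaced candidates,
so a run with perfect rates is fully deterministic and its stage
fractions equal the enumerated expectations. The observed ~10% doubly
marked F2 reported for the real experiment is below the Mendelian 3/16
and unexplained by this model; the driver logs the fraction but does not
test against the observed value. The N2 plate used for male generation
is a male-enriched mating stock (`n2_stock_male_fraction = 0.35`);
ordinary N2 stocks default to the spontaneous male rate.

The integration screen models mutagenesis only through `p_integration`:
each F1 line is heterozygous for a genomic insertion (random autosome)
with that probability, otherwise it keeps the array. Singled F2 lines
are screened over `generations` generations (default 2, i.e. F3 and F4)
of `screen_n = 30` progeny; a line is called an integrant iff every
screened animal carries the marker in every generation, and called lines
are re-screened over `confirm_generations` more. Closed forms anchor the
tests: a non-integrated line false-positives with probability
0.65^(30×2) ≈ 6e−12, and a heterozygous integrant passes one generation
with probability 0.75^30 ≈ 1.8e−4 (the mechanism is additionally checked
at screen_n = 5, where the pass rate 0.75⁵ is measurable). The package
deliberately does not claim to reproduce the published line counts,
since the per-line integration probability is not reported.

## Synthetic data

All tests and pipelines consume populations from the strains module: the
wild type, the Dumpy mutant, the Green and Red integrated-transgene
strains, the four Green balancer heterozygote stocks, the helper-array
strain, the 65%-transmission array strain, and a mixed sorting stock
(carrier fraction 0.5, an assumption). Balancer stocks are balanced
heterozygotes so Green males can be picked. Fixtures emulate brood
structure, sex ratios, dominance, balancer segregation with inviable
aneuploids, array transmission and stochastic handling — they do not
emulate brood-size biology over the reproductive span, mating-efficiency
kinetics, crossover interference, mosaicism, or real strain provenance,
so green tests certify the transmission model and the protocol logic,
not those aspects of real husbandry.

## Numerical and design choices

* Single `numpy` generator per run, injected at protocol start; identical
  seed ⇒ identical artifacts. Stochastic assertions use 3-binomial-SD
  bands at stated sample sizes.
* Inviable conceptions are redrawn (cap 10,000) so brood sizes count
  scorable animals; a flag returns them as dead records instead.
* Genotype classes are keyed canonically (sorted haplotype pairs), so
  homolog order never splits a class.
* Problem sizes in the test suite — 10,000-offspring equivalence broods,
  200 informative animals per linkage test over 20 seeds per placement,
  50 seeded cross runs — were chosen to keep each stochastic check at
  3-SD resolution while the full suite runs in well under a minute.
* Chromosome placements used by fixtures (dpy-5 on I, vsIs28 on II,
  vsIs33 on V) are configuration facts, not model outputs; the true
  placement in a mapping scenario is whatever the caller requests.

## Known limitations

No centimorgan-scale mapping (interval or SNP mapping is out of scope),
no recombination within balanced regions beyond the ε knob, no sperm
depletion or brood-size dynamics, no hardware modeling (motion, optics,
sterilization). The Linkage Index convention adopted here — affine
normalization with clipping — reproduces all of its stated properties
(range [−1, 1], 1 strongest, 0 weakest, anchors at the two
expectations); other normalizations satisfying the same constraints
would differ only between the anchors.
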