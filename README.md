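# wormbench

A seeded virtual bench for *C. elegans* transmission genetics.

Automated worm-handling robots can run multi-generation genetic
procedures — crossing strains, mapping a transgene to a chromosome,
screening for genomic integration of a transgenic array — but every step
of those procedures rests on Mendelian expectations that should be
reproducible *without* hardware. `wormbench` implements the genetics and
the protocols as a forward-time simulator plus a protocol engine, so
that every segregation ratio, linkage call, and screening decision can
be recomputed, tested, and rerun deterministically from a seed.

It is written for *C. elegans* geneticists and for developers of
automated husbandry systems who need a digital twin of the bench:
virtual barcoded plates, stochastic picking/screening with configurable
success rates, and high-level drivers for three standard procedures.

## The model

**Transmission.** Hermaphrodites (XX) are diploid for all six
chromosomes (I–V, X); males (X0) are haploid for X and sire ~50% male
cross-progeny via nullo-X sperm. Each autosome assorts independently
(linkage is binary at chromosome scale; there is no centimorgan map).
Dominant alleles express with one copy; recessive alleles require all
haplotypes of their slot, so hemizygous males express X-linked
recessives.

**Balancers.** Reciprocal translocations (hT2 (I;III), eT1 (III;V),
nT1 (IV;V)) and the inversion mIn1 (II) carry dominant *myo-2::GFP*
markers. Translocation halves segregate together (alternate
segregation), so a heterozygote emits balanced gametes only; unbalanced
aneuploid products are folded into the redraw of inviable conceptions
(or exposed with `emit_unbalanced`). Balancer homozygotes die or show a
configured phenotype per balancer.

**Arrays.** Extrachromosomal arrays are transmitted per conception with
probability *p* (default 0.65), so the carrier count in a brood of *n*
is Binomial(*n*, *p*), independent of chromosomal loci.

**Linkage mapping.** In the balancer scheme, a doubly fluorescent F1
(balancer / normal homolog carrying the Red transgene in cis) selfs.
Among nonGreen F2, the expected fraction of Red animals is **1.0 if the
transgene lies on a balanced chromosome and 0.75 otherwise**; the X
scheme scores Red among F2 males, with expectations **0.0 (X-linked) vs
0.5 (autosomal)**. The Linkage Index normalizes an observed fraction
between these anchors:

    LI = (p_obs − p_unlinked) / (p_linked − p_unlinked),  clipped to [−1, 1]

so LI = 1 at the fully linked expectation and LI = 0 at the unlinked
one. Chromosome assignment intersects the coverage sets of the linked
tests and subtracts those of the unlinked tests.

An exhaustive enumeration oracle (`enumerate_offspring`) computes exact
offspring distributions for any self or cross and cross-validates every
expectation the simulator samples.

## Worked example

Map a Red transgene that the scenario integrates on chromosome V:

```sh
$ wormbench map --true-chromosome V --n-scored 200 --seed 5 --out run_map
inferred chromosome(s): V
   hT2: p_obs=0.740 LI=-0.040 (n=200)
   eT1: p_obs=1.000 LI=+1.000 (n=200)
   nT1: p_obs=1.000 LI=+1.000 (n=200)
  mIn1: p_obs=0.745 LI=-0.020 (n=200)
     X: p_obs=0.520 LI=-0.040 (n=200)
```

Both translocations covering chromosome V (eT1, nT1) read 100% Red among
nonGreen F2 (LI = 1); the remaining tests sit at their unlinked
expectations (LI ≈ 0), so the intersection of the linked coverage sets
minus the unlinked ones is exactly {V}. `run_map/` holds the manifest,
the tests × chromosomes LI matrix (TSV) and a JSON summary.

The exact Mendelian table behind a cross stage:

```sh
$ wormbench enumerate --hom e61 --het vsIs28 --out run_enum
phenotype fractions among viable offspring:
             Dpy+Green: 0.7500
                   Dpy: 0.2500
```

i.e. the self-progeny of a *dpy-5*-homozygous, *vsIs28*-heterozygous
hermaphrodite are 100% Dumpy and 75% Green — the signature used to
recognize a line that is homozygous for the mutation but still
heterozygous for the transgene. Other subcommands: `cross` (the full
multi-generation hybridization), `integrate` (array-integration screen),
`fixtures` (materialize synthetic populations), `report`.

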