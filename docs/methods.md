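# Methods

This note records the models, defaults, numerical choices and limitations
behind `ham`. Nothing here states an empirical result that the test suite
does not itself compute.

## Crossing-design simulator

**Design.** A balanced 2^k-founder funnel: inbred founders are crossed in
fixed pairs to two-way hybrids, hybrids to four-way recombinants, and (for
eight founders) four-ways to eight-way recombinants; the pairing of the
four two-way hybrids rotates round-robin through the three perfect
matchings across families so founder combinations vary. Each terminal
recombinant founds a family of lines advanced by single-seed descent
(SSD): one selfed offspring per generation. Defaults: 8 founders, 100
families, 4 lines per family, 4 selfing generations — i.e. ~400 F5 lines,
with residual per-locus heterozygosity ≈ (1/2)^4, matching the generation
at which such panels are usually genotyped.

**Meiosis.** Haldane model, no interference: crossover count per
chromosome ~ Poisson(length_cM/100), positions uniform in cM, mapped to bp
through the genetic map (linear within a chromosome; default 4 cM/Mb, a
typical rice genome-wide average). Segments are half-open bp intervals;
boundary ties resolve to the left segment. A 12-chromosome rice-like
genome (`GeneticMap.rice_like()`) is built in.

**Genotypes.** Line calls are projected from the true mosaic onto a
homozygous founder panel (random panels are polymorphic at every SNP; two
founders share an allele at ~half the SNPs). Genotyping error flips calls
at a per-call rate (default used in tests: 0.2–1%), missingness masks them
(2–3%); both mimic GBS data after variant calling.

**Phenotypes.** One causal locus with founder classes: the line's value is
the mean class effect of its two homologs at the locus, plus an optional
polygenic term (sum of random founder effects at 50 random background
loci, standardized) and Gaussian noise. Components are standardized so the
locus explains fraction `h2` of the variance and the polygenic term
`h2_poly`; alternatively `noise_sd` adds unstandardized noise when class
separation must be controlled in residual-SD units. Binary traits are
recessive: a line scores 1 only when both homologs carry a carrier-class
founder — so an allele private to one of eight founders appears in ~1/8 of
fully inbred lines.

**What the simulator does not model**, hence what a green test cannot
establish: shared founder ancestry (real founder panels are kin, which
distorts local founder proportions and makes haplotypes locally
indistinguishable), selection and mortality during SSD, crossover
interference, and segregation distortion. Local founder proportions still
drift substantially in finite populations (25 families leave some founders
nearly absent at individual loci), which usefully reproduces the
"unclassifiable rare founder" situation.

## Founder HMM

Hidden state = single founder per position (near-inbred lines; residual
heterozygous calls are treated as uninformative rather than modelled as
founder pairs). Emission: P(obs | founder) = 1 − ε on an allele match, ε
on a mismatch; uniform when the observation is heterozygous or missing;
0.5 when the founder's own call is missing or heterozygous. Transition
between adjacent SNPs at map distance d Morgans: stay with exp(−d·ρ),
remaining mass split equally among the other founders; uniform stationary
prior at the first SNP of each chromosome; chromosomes independent.

Defaults: ε = 0.01 (GBS-like); ρ = 1.75 junctions/Morgan. ρ is a modelling
choice, not an estimated quantity — the posterior is dominated by
emissions wherever founders are locally distinguishable, so moderate
misspecification of ρ mainly affects behaviour in uninformative stretches.

Numerics: forward–backward with per-position rescaling (not log-space;
rescaling is exact and vectorizes over lines), Viterbi in log space with
ties broken toward the lower founder index. An observation impossible
under every founder (only possible at ε = 0) raises rather than silently
renormalizing. Exactness is checked against full path enumeration on a
3-SNP toy (1e-12).

## Mixed-model GWAS

K is a realized-relationship matrix from centered dosages, scaled to mean
diagonal 1 and shifted by the smallest ε·I needed for positive
semidefiniteness (logged). Q is an intercept plus top principal components
of the centered dosage matrix (default 2). Variance components are fitted
once on the null model by REML, profiling the ratio δ = σ²_e/σ²_g on the
spectral decomposition of K (coarse log-grid then bounded refinement);
markers are then tested by GLS in the whitened space — the standard
two-stage approximation ("population parameters previously determined").
Exact per-marker REML is deliberately not implemented; the two-stage
approximation is the field's default at this scale.

Reference distributions (a documented choice): SNP mode refers the 1-df
Wald statistic to chi-square(1); haplotype mode tests the founder
posterior design (alphabetically last founder dropped for
identifiability; numerically empty columns dropped and recorded) with an F
statistic on (df_founders, n − rank(Q) − df_founders). The chi-square
reference is mildly anticonservative in the far tail at small n relative
to the matching F — visible in permutation experiments at n ≈ 100 — and
calibrated at conventional α for the sample sizes the tests use. On a
two-founder design where the posterior matrix is collinear with the
dosage, the two modes produce identical statistics; their P-values differ
only through the reference distribution (asserted in tests).

Locus regions use the ×10³ rule: threshold = min(P) × 10³ (capped at 1),
members = the maximal contiguous run of sub-threshold SNPs containing the
peak; real regions reported with this rule are contiguous runs, and a
contiguous definition keeps the region interpretable as an interval.
Ties at the minimum resolve to the lowest genome coordinate.

## Classification and candidate narrowing

Mann–Whitney U (convention: U counts x > y pairs plus half-ties, so U = 0
when every x precedes every y). Exact two-sided P for pooled n ≤ 25 via a
tie-aware subset-sum recursion over doubled mid-ranks, returning the
symmetric tail Pr(|U − mn/2| ≥ |u − mn/2|); larger samples use the normal
approximation with tie correction and no continuity correction (identical
samples therefore give exactly P = 1).

Founder classes: all pairwise tests among founders with ≥ `min_n` lines
(default 2) at the peak, Holm step-down over the pair family at α = 0.01
(Bonferroni by flag), classes = connected components of the
"not-significantly-different" graph, labelled A, B, … by ascending class
median. Pairwise non-significance is not transitive; components are the
documented resolution, with the consequence that one small, noisy —
but still eligible — group can chain otherwise-distinct classes together.
Raising `min_n` (the worked example uses 5) trades coverage for class
sharpness. Founders below `min_n` are reported unclassified with the
reason.

Gene allele types: per gene, founders with fewer than two recorded
variants against the reference are always Cluster 1; other founders share
a cluster iff their variant-id signatures are identical; clusters are
numbered 2, 3, … by ascending severity score (HIGH=4, MODERATE=3, LOW=2,
MODIFIER=1 — a fixed convention for ordering, not a biological claim;
ties break lexicographically on the signature). Ward clustering of
founders runs on one-hot encoded per-gene labels (scipy linkage,
deterministic).

Candidate narrowing: a gene is class-discordant when founders from
different phenotypic classes carry different allele-type labels; among
discordant genes, survivors additionally carry ≥ 1 HIGH-impact variant in
a founder of a class involved in such a label difference. Removing a
HIGH-impact record can only remove survivors (monotone).

Segregation chi-square: 1-df goodness-of-fit against the expected carrier
fraction, no continuity correction — with Yates' correction the canonical
57/358-vs-1/8 example would not give P = 0.0503.

## LD

Inbred lines are treated as single haplotype draws (heterozygotes and
missing pairwise-deleted), so haplotype frequencies come directly from
counts without EM phasing. D = p(AB) − p(A)p(B); D′ = |D|/Dmax with the
sign-dependent Dmax; r² = D²/(p(A)p(a)p(B)p(b)) ≡ squared Pearson
correlation of allele indicators. Monomorphic columns give undefined LD,
flagged rather than zeroed; D′ is defined as 0 at D = 0. Decay summaries
bin all within-window pairs (default 5 Mb) per chromosome, with seeded SNP
subsampling to bound the quadratic pair count.

## Scale of the shipped tests

Simulation-backed checks are scaled to desk size: populations of 96–400
lines, 1–12 chromosomes, 50–250 SNPs per chromosome; replicate counts
follow the stated designs (200 null phenotype replicates, 50 power /
classification replicates). The whole suite runs in about a minute on one
CPU. Consequences of the scale: local founder-proportion drift is large
(see above), and genome-wide significance behaviour at n ≈ 100 reflects
the chi-square-vs-F tail issue noted under GWAS.
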