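# Methods

This package re-implements, as tested reusable code over synthetic data, the
bespoke computational core of a hadal-trench sediment virome analysis: the
null-model partition of viral community assembly, multi-evidence virus–host
linkage prediction, auxiliary-metabolic-gene (AMG) curation and lifestyle
rules, and viral microdiversity metrics (SNVs/kb, gene-level pN/pS). Because
every stage is driven by seeded generators with planted ground truth, each
claim the pipeline makes can be checked against what was planted.

## Community assembly partition (`hadalvirome.assembly`)

Assembly of each pair of communities is attributed to one of five processes
from two null models.

**βMNTD / βNTI.** The between-community mean nearest taxon distance is

    βMNTD(k, m) = ½ [ Σ_{i∈k} f_ik · min_{j∈m} D(i, j)
                    + Σ_{j∈m} f_jm · min_{i∈k} D(i, j) ]

with `D` the patristic distance on the vOTU phylogeny and `f` the
within-sample relative abundance (abundance-weighted mode, the default,
because the abundance tables are RPKM; an unweighted 1/richness mode is kept
for sensitivity checks). A taxon shared by both communities contributes its
own zero distance. The null shuffles taxon labels across all tips of the
tree — one global shuffle per randomization shared by every pair, i.e. a
regional-pool-scale randomization, the most common reading of the
framework. βNTI is the z-score of the observed βMNTD against 999 sampled
shuffles (sample standard deviation); an `exhaustive` mode enumerates every
tip permutation for small instances and then uses the population standard
deviation, since the null is complete. Pairs whose null has zero spread
(e.g. identical communities) get NaN, are excluded from process fractions
and tallied separately — silently counting them as drift would inflate it.

**RC_Bray.** Abundances are first discretized by scaling each sample to a
fixed total (default 1000 quanta) and rounding, with any positive abundance
rounding up to at least 1 so richness is preserved; the Raup–Crick null
draws discrete individuals and the source analysis does not say how RPKM
was discretized, so the rule is explicit and configurable. Each of 999
replicates reassembles both communities from the regional pool: species are
drawn without replacement with probability proportional to occupancy until
the observed richness is reached (each drawn species seeded with one
individual), then the remaining quanta are assigned multinomially with
probability proportional to pool relative abundance. With
`RC_raw = (#{null<obs} + ½·#{null=obs})/n_null`, `RC_Bray = 2(RC_raw − ½)`.
Occupancy and pool abundance default to the empirical pool of the input
table; both can be passed explicitly, which makes data generated by the
same null process exactly exchangeable with the replicates (used by the
self-consistency checks).

**Classification.** βNTI > 2 → heterogeneous selection; βNTI < −2 →
homogeneous selection; otherwise RC_Bray > 0.95 → dispersal limitation,
RC_Bray < −0.95 → homogenizing dispersal, |RC_Bray| < 0.95 → drift. The
inequalities are strict exactly as stated; boundary values fall through to
the next rule, so (βNTI = 2, RC = 0) is drift. Per-group process fractions
are computed over classified within-group pairs and sum to one.

## Community statistics (`hadalvirome.ecology`)

Shannon uses the natural log and Simpson is 1 − Σp², matching the vegan
conventions behind the original analysis. Bray–Curtis comes from
scipy's pairwise distance machinery. ANOSIM uses Clarke's statistic
R = (r̄_between − r̄_within)/(n(n−1)/4) with mid-ranks, and the add-one
permutation estimator p = (1 + #{R_perm ≥ R_obs})/(1 + n_perm); with small
groups, permutations reproducing the observed partition tie with R_obs, so
the attainable minimum p is above 1/(1+n_perm). The Wilcoxon rank-sum test
uses mid-ranks; for samples of at most 20 observations each, p comes from
the exact permutation distribution of the rank sum (computed by dynamic
programming over doubled mid-ranks, equivalent to full subset enumeration
and tolerant of ties), otherwise from the normal approximation with tie and
continuity corrections. Geographic distances are haversine on a sphere of
radius 6371.0088 km; the geodesic-vs-sphere difference (<0.5%) is far below
any tolerance used here. Distance–decay regresses Bray–Curtis
*dissimilarity* on the pairwise predictor by OLS over unordered pairs; the
original figures report positive slopes alongside "negative distance-decay
relationships", so the orientation is stated here explicitly rather than
guessed — users wanting similarity-decay can regress `1 − BC`.

## Virus–host linkage (`hadalvirome.virus_host`)

Four evidence channels, each with the retention thresholds used in the
source analysis:

* homology — precomputed nucleotide alignment rows kept when query coverage
  ≥ 75% of the viral sequence, identity ≥ 70%, length ≥ 1500 bp, bit score
  ≥ 50 and e-value ≤ 1e-3, all jointly. Alignment engines are upstream of
  this pipeline; hits arrive as BLAST-outfmt-6-like tables plus a query
  length column.
* tRNA — exact full-length identity between a viral and a host tRNA.
* CRISPR — a host spacer matching a full-length window of a viral genome
  with ≤ 1 mismatch, identity ≥ 95% and coverage ≥ 95% jointly; the
  identity floor means a single mismatch already disqualifies spacers
  shorter than 20 nt. Spacers shorter than 15 nt are refused as a sanity
  floor.
* ONF — d2* ≤ 0.2. d2* counts k-mers (default k=6) over both strands,
  centers them by the expectation under the sequence's own order-2 Markov
  model (transitions from (r+1)-mer counts, stationary law from r-mer
  counts), and is ½(1 − S) for the normalized centered inner product S.
  k-mers with zero expectation in either sequence are excluded and tallied.
  Sequences must be at least 10·4^order long for the model to be estimable.

Spacer and tRNA matching scan both strands: the orientation of a spacer or
tRNA relative to the assembled contig strand is arbitrary.

Integration per virus: a single candidate is kept outright; otherwise
candidates supported by the maximal number of *distinct methods* survive
(method count, not hit count — multiple hits of one method are one vote);
if the survivors still span more than one phylum, only those with CRISPR or
tRNA support are kept; if none has such support, all are dropped — the
original rule names no selection criterion for that case, so the
conservative choice is made and logged. The procedure is idempotent and
invariant to evidence order.

`linkage_stats` reports the virus-to-host ratio VHR = viral RPKM / host
RPKM per linked pair and sample (host-absent pair-samples excluded and
tallied), Spearman correlations of host abundance against virus abundance
and against VHR overall and per lifestyle class, and the per-sample
lytic:temperate abundance ratio.

## AMG curation and lifestyle (`hadalvirome.annotation`)

A candidate AMG is retained iff: DRAM-v-style bit score ≥ 60 and auxiliary
score ≤ 3; its function is not on the denylist (nucleotide metabolism,
DNA-related reactions, modification of viral components, ribosomal
proteins, transcriptional/translational regulators, viral invasion); at
least two viral-like genes occur among its two nearest neighbours per side,
counted jointly across both sides (the flanking rule names no window, so
the window is explicit and configurable); and it is not within 5000 bp of a
contig end while adjacent to a tRNA gene or an annotated repeat — the
classic signature of mis-attached host sequence at provirus boundaries. The
5000 bp end window is a package default (unstated in the source) and a
parameter. Lifestyle: temperate if any lysogeny marker (integrase,
recombinase, transposase, excisionase, CI/Cro repressors, parAB) is present
or the contig is a provirus; else the upstream lytic call; else unknown.
AMG abundance of function f in sample s sums the RPKM of vOTUs carrying at
least one retained AMG of f, each vOTU counted once per function regardless
of copy number.

## Evolutionary metrics (`hadalvirome.evolution`)

SNVs are called per non-reference allele at positions with coverage ≥ 5
when the allele has count ≥ 2 and frequency ≥ 0.05 — the documented
defaults of the population-genomics tool the source analysis ran with
default parameters; all three are exposed as flags. SNVs/kb is 1000 ×
(distinct SNV positions)/(positions with coverage ≥ 5). Expected sites use
Nei–Gojobori-style counting under the standard genetic code with equal
mutation rates (no transition/transversion weighting): each codon position
contributes the synonymous fraction of its three single-base alternatives,
so N_sites + S_sites = 3 × #codons exactly; mutations to stop codons count
as nonsynonymous. pN/pS = (N_obs/N_sites)/(S_obs/S_sites), with
multi-allelic positions contributing one observation per alternate allele;
genes with S_obs = 0 are undefined and excluded (not imputed), with counts
reported. Minus-strand genes are evaluated on the reverse complement.
Group comparisons use the two-sided Wilcoxon rank-sum test without
multiplicity adjustment, matching the original single-contrast usage.

## Synthetic data (`hadalvirome.synthetic`)

All randomness flows from one root seed through `numpy.random.SeedSequence`
spawning with named child streams, so identical (seed, config) reproduce
byte-identical outputs while stages remain statistically independent.

**Communities.** The phylogeny is pure-birth (Yule, rate 1.0) — the
simplest process with positive branch lengths, which is all βNTI needs.
Scenario defaults (12–30 samples, 100–200 taxa, 1000 abundance quanta per
sample, lognormal(0,1) species pool) are chosen to emulate sparse RPKM
tables at desk scale; the original study's process-fraction magnitudes
depend on its 40 real metagenomes and are not value targets here, so the
calibration checks are property-based. Regimes: *well_mixed* draws each
sample multinomially from one pool (null calibration); *selection_gradient*
gives taxa a Brownian trait on the tree and filters the pool through a
Gaussian niche around each sample's optimum (niche breadth = trait
sd/strength, default strength 4 — strong but not degenerate selection);
*dispersal_limited_islands* partitions taxa into per-island pools with an
optional shared fraction; *rc_null_process* builds every sample with
exactly the Raup–Crick null assembly routine (fixed richness n_taxa/3,
fixed total), so RC_Bray conditioned on the same pool is uniform by
construction. Sample metadata (two trench labels, coordinates, depths) is
invented plumbing for the grouping and distance–decay interfaces and
carries no geochemical realism.

**Genomes.** Hosts and viruses are order-2 Markov sequences with
genome-specific Dirichlet(0.6) transition rows — distinctive enough that
unrelated pairs sit well above the d2* threshold. Homology planting copies
a 2000 bp viral segment into the host with substitutions at 20% of
positions: 80% identity sits above the 70% retention floor with margin
while keeping oracle alignment (blastn in the test suite) trivial, and the
alignment-hit row is emitted from the planting bookkeeping together with
decoy rows that each fail exactly one threshold. tRNA planting inserts one
identical 75-nt sequence in both genomes; CRISPR planting copies a 25–40 nt
spacer exactly or with exactly one mismatch (alternating); ONF planting
emits the viral genome from the host's own Markov model.

**Pileups.** Coding contigs are built codon-wise from the 61 sense codons
(no internal stops, strands alternating); variants are planted at distinct
uniform positions with uniform alternate bases, so all nine mutation types
are equally likely and the planted pool is neutral in expectation — the
recorded synonymy comes from the gene models and the standard code.
Site coverage is Poisson around the mean; base counts are multinomial over
(reference, planted alternates at their true frequencies, uniform errors).
Default planted frequencies span 0.2–0.8: far enough from the 0.05 calling
floor that, at coverage 100, recovery failures would signal a caller
defect rather than binomial bad luck (the tail probability of a planted
allele falling under the thresholds is <1e-6 per site). No read-level
artefacts (indels, mapping bias, strand bias) are modelled, so passing
tests show the metric layer is correct given counts, not that upstream
mapping is.

## Verification scales and known limitations

The acceptance checks run at desk scale: 30 samples × 200 taxa with 999
randomizations for βNTI calibration, 21 samples (210 pairs) for RC_Bray
uniformity, ten seeded replicates per regime for process recovery, 20
viruses × 10 hosts for linkage recall, 100 random 50-kb instances for the
spacer oracle, and 50 genes for the neutral pN/pS calibration. These sizes
make every stage verifiable in minutes while leaving the statistical
properties intact; they are package choices, not claims about the original
study's power. Known limitations: the null-model randomization scale,
βMNTD weighting and RPKM discretization are configurable defaults because
the source analysis does not state them; the generator plants no
compositional ambiguity (e.g. shared prophages between hosts), so linkage
precision on real data will be lower than on these fixtures; and drift here
is the undominated remainder class, not a positive diagnosis.
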