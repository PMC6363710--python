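# Methods

`picoevo` re-implements, at desk scale, the inference chain used to study
the evolution of picocyanobacteria and their phycobilisome pigment
clusters: assembly-graph contig triage, contour-based ortholog
delimitation, Bayesian constrained-topology testing of gene duplication
versus lateral gene transfer (LGT) by stepping-stone Bayes factors,
relaxed-clock divergence dating with soft fossil calibrations, and
pigment-cluster typing with Dollo loss/LGT reconstruction.  Every stage
is exercisable on synthetic data generated in-package with known ground
truth; nothing in the test loop downloads or depends on external
genomes.

## Substitution models and likelihood

All sequence likelihoods use reversible models Q_ij = s_ij * pi_j scaled
to one expected substitution per site, with a proportion `p_inv` of
invariant sites and discrete-gamma rate variation (four
equal-probability categories represented by their conditional means,
mean rate 1).  Amino-acid analyses use the published LG, WAG and JTT
exchangeability matrices (packaged as JSON in PAML `dat` ordering); a
uniform prior over this fixed set with a Metropolised indicator move
plays the role of a "mixed" amino-acid model.  Site-heterogeneous
profile-mixture models are deliberately out of scope: the topology,
hypothesis-testing and clock machinery is agnostic to the
site-homogeneous replacement model, and GTR+G (nucleotide) or
empirical-matrix+I+G (protein) keep every analysis tractable on one
CPU.

The likelihood is the standard postorder pruning recursion over an
unrooted tree, pattern-compressed, with per-pattern rescaling only when
partial likelihoods drift toward underflow, and exact agreement with a
brute-force sum over internal-state assignments to 1e-10 relative error
(tested for up to 5 taxa on nucleotide, binary and LG models).
Partitioned matrices scale each partition's branch lengths by a
mean-one rate multiplier.

## Topology MCMC and diagnostics

The sampler is plain Metropolis-Hastings over topology (NNI plus SPR
with a branch-length split whose Jacobian enters the acceptance ratio),
branch lengths (multiplier proposals, Exp(mean 0.1) prior), gamma shape
(Exp(1)), `p_inv` (uniform), frequencies and partition multipliers
(Dirichlet-style proposals), and the amino-acid model indicator.
Monophyly constraints are enforced by rejecting proposals whose
topology violates any clause; constraint sets must be laminar and a
satisfying starting tree is constructed before sampling starts (or the
run is refused).  Desk-scale defaults are 50,000 generations, thinning
50, 25% burn-in and two runs; production-scale runs of tens of millions of
generations are a configuration value, not a default.

Convergence across runs is summarised by the average standard deviation
of split frequencies (ASDSF; splits qualify at frequency >= 0.1 in at
least one run, standard deviations use the n-1 denominator).  Posterior
topologies are summarised by a majority-rule-extended consensus whose
split posterior probabilities are exactly the sample frequencies;
splits below PP 0.75 are collapsed into polytomies, the conventional
reporting threshold this package adopts throughout.  Rooting places the root on the
branch inducing a requested bipartition (for the phycoerythrin trees,
the branch separating the alpha from the beta subunits), and fails
loudly, naming the nearest compatible split, if the bipartition is
absent.

## Duplication-vs-LGT hypothesis testing

The three hypotheses for the origin of phycoerythrin-II (mpeBA) from
phycoerythrin-I (cpeBA) are encoded as monophyly constraint sets on the
four-gene tree (tips = species x {cpeA, cpeB, mpeA, mpeB}):

- **A** (duplication/transfer before the cyanobacterial ancestor):
  cpeA and cpeB each monophyletic, excluding the mpe sequences.
- **B** (duplication on the stem of the picocyanobacteria plus their
  sponge-symbiont sister): mpeA, mpeB, the picocyanobacterial cpeA and
  cpeB clades, and each mpe + cpe(pico) pairing monophyletic.
- **C** (transfer from a crown-group cyanobacterium): only mpeA and
  mpeB monophyly.  C's clauses are implied by B's, so the C space
  strictly contains the B space and hypothesis C pays the Occam penalty
  of its breadth in the marginal likelihood.

Marginal likelihoods come from stepping-stone sampling along powers
beta_k = (k/K)^(1/0.4) (quantiles of Beta(0.4, 1); K = 32 stones and
5,000 generations per stone by default, desk-scaled in the test-suite
experiments).  The ladder is run hot-to-cold with warm starts: the
high-power basin is located once (the first chain is doubled) and each
cooler stone relaxes from the previous state.  Hot chains are seeded
with a neighbor-joining guide topology built from Poisson-corrected
p-distances; when a hypothesis's clauses reject the data's own NJ tree,
within-clause distances are shrunk four-fold before joining so the
guide lands inside the constrained space.  The guide only chooses a
starting point - the estimator itself is untouched - and a guide that
still violates a clause is discarded in favour of a random
constraint-satisfying tree.  Per-stone contributions are
log-mean importance weights; the Monte-Carlo standard error uses batch
means (10 blocks) so chain autocorrelation is reflected, and stones
whose importance weights collapse (effective sample size < 10) are
flagged rather than silently accepted.  Log Bayes factors are
differences of log marginal likelihoods, banded by the conventional
evidence scale (<1 weak, 1-3 positive, 3-5 strong, >5 very strong, on
the natural-log scale).

The synthetic recovery experiment generates two-subunit gene
superfamilies: a species tree (birth-death conditioned on 4 taxa with a
2-taxon picocyanobacteria-analogue clade), the focal cpe/mpe scenario
(B: duplication on the clade stem; C: transfer of the gene from an
outgroup donor onto that stem), and one subunit-level duplication above
the root mirroring the ancient alpha/beta split - 12 tips and 300 sites
per replicate, evolved under the 20-state equal-exchangeability model
at 5e-4 substitutions/site/Myr.  Twenty states rather than four, and a
rate low enough to avoid saturation, are what keep the deep
attachment signal recoverable at 300 sites; the planted events are
required to be temporally resolvable (clade stems at least 15% of the
root age; transfers from deeply nested donors with at least 20% of the
root age of shared donor lineage above the attachment), because a
transfer grafted next to the root is *in principle* indistinguishable
from an ancient origin - the same ambiguity the A-versus-C comparison
confronts on real gene families.  With those conditions the suite names the
generating hypothesis in 20/20 replicates (10 duplication + 10
transfer) in the shipped experiment.

## Relaxed-clock dating

Node ages (Myr) are sampled on a fixed rooted topology.  The age prior
factorises as a root-age prior times the birth-death density of the
non-root internal ages conditioned on the root age (complete sampling;
the i.i.d. kernel lambda r^2 e^{-rt} / (lambda - mu e^{-rt})^2
normalised on (0, T), which reduces to the classic Yule form for
mu = 0 and to lambda/(1+lambda t)^2 at the critical limit).  Soft
calibration densities multiply in at their MRCA nodes: a uniform core
on [min, max] with exponential tails continuous at the bounds carrying
5% total mass (2.5% per side when both bounds exist, all 5% on the
bounded side otherwise; the upper tail of a minimum-only calibration
decays with scale equal to the bound, a deliberately diffuse choice).
The packaged calibration set mirrors the seven used for the
picocyanobacterial chronology: the Great Oxygenation Event window
(2,320-2,700 Myr) on the root, minimum ages of 1,900 (Oscillatoria-type
filaments), 1,700 (Pleurocapsales multiple fission), 1,600 (Nostocales
akinetes), 110 and 100 Myr (Hemiaulus and Braarudosphaera host
fossils), and a 713 Myr maximum for the sponge-symbiont stem (the identity of the sponge host is not pinned down by the fossil
record used here; the calibration attaches to the S. spongiarum stem
and is flagged as such).

The root prior is a Gamma distribution fitted so that its equal-tail
central 95% interval is exactly [2,320, 2,700] Myr (CDF residuals below
1e-8; the two-parameter fit reduces to a one-dimensional bracketed root
find on the shape via the quantile ratio).  Branch rates follow the
uncorrelated-gamma relaxed clock: i.i.d. Gamma multipliers with mean 1
and free variance times a global rate with a log-normal prior
(median 5e-4 substitutions/site/Myr, log-sd 0.5); variance 0 is the
strict clock.  Expected substitutions on a branch are duration x
multiplier x rate.  Moves: single-node age slides within the legal
window, a root-offset multiplier, a global age scaling, a rate
multiplier, a joint rate-up/ages-down ridge move (essential for
mixing along the rate-age confounding), and per-branch multiplier
updates.  Summaries are per-node posterior medians with 95% HPD
intervals (shortest interval containing ceil(0.95 n) samples);
convergence uses across-run relative mean differences (threshold 0.3)
and autocorrelation-time effective sample sizes (threshold 50),
following the customary cutoffs of trace-comparison tools.

Calibration of the machinery is checked by simulation: drawing root
ages from the fitted prior, trees from the conditioned birth-death
process, rates from their prior and strict-clock sequences (12 taxa,
500 sites), the 95% HPD intervals cover the true node ages at the
nominal rate; and a prior-only run with the GOE calibration leaves
5% (+-1.5%) of sampled root ages outside the bounds.

## Contig triage

Four rules in fixed order: flag nodes with core-gene hits at e-value
<= 1e-10; provisionally retain connected components containing flagged
nodes, keeping nodes within 2-fold of the component's flagged-node
median depth ("similar read depth" has no canonical definition;
this package operationalises it as a fold-tolerance around a robust
location estimate, exposed as a knob); remove every node below half
the unweighted mean depth of the provisionally retained connected
portion (strict inequality; a length-weighted mean is available);
finally drop contigs under 200 bp.  Unconnected nodes with exactly one
line of evidence (a hit but discordant depth, or concordant depth but
no hit) correspond to nodes that real workflows screen manually
against an external database; they are labelled `ambiguous` and stay
out of the retained set unless explicitly kept.

## Ortholog delimitation by contours

BLAST hits are scored by identical residues as a fraction of query
length (identity x alignment length / query length; uncapped, since
gapped alignments can exceed 1, and capped at 1 only for contour
binning).  Candidates are placed on a neighbor-joining tree (hand-rolled
Q-criterion agglomeration: exact on additive matrices, lexicographic
tie-breaks, negative branch estimates clamped to zero with the deficit
moved to the sibling).  The NJ input distance is a free choice;
p-distance over shared ungapped columns is the default with a
Poisson correction available.  A contour at level L collects the
maximal clades whose tips all score >= L; groups are laminar within and
nested across levels.  The candidate ortholog clade is the smallest
clade containing the query that, at some level, holds at most a 10%
fraction of below-level tips (the "mostly monophyletic" allowance) and
whose internal minimum score exceeds the maximum score outside by at
least 0.2 (the "well-defined contour profile").  Intruders and outside
tips within the gap of the internal minimum sit on the group boundary
and are called uncertain; a genome with an uncertain alpha-subunit call
has its beta-subunit excluded as well (symmetric by default; the
source states the alpha-to-beta direction).  All three thresholds make explicit what is
usually judged visually on annotated trees, and are configurable.

## Pigment typing and event reconstruction

Types are called from rod-cluster gene content: III = cpeBA plus mpeBA
(mpeC/mpeU recorded as support); II = cpeBA plus the full cpeS/cpeT/cpeR
lyase set without mpeBA; IIB = cpeBA plus cpeT only (cpcBA upstream of
aplA and a ferrochelatase on the opposite strand recorded as
arrangement support, promotable to hard requirements in strict mode);
I = cpcBA without cpeBA.  Whether mpeC/mpeU absence should disqualify
Type III is unsettled (strains with phycoerythrin-II but no detectable
PUB-binding linker exist); mpeBA alone triggers III here.
Taxa with fewer than 3 of the 16 panel genes are excluded from
cluster-level phylogenetics.  Gene histories use Dollo parsimony - one
gain at the MRCA of the present taxa, losses on the stems of the
maximal all-absent subtrees below it, which is the unique minimum-loss
single-gain history (verified against exhaustive search on 8-tip
trees); the single-origin assumption matches the narrative that pigment
types arose by repeated losses.  Transfers are flagged where a taxon's
gene-tree sister group and species-tree sister group (restricted to
shared taxa, walking rootward past empty sisters) are disjoint - a
sister-group conflict test, deliberately lighter than full
duplication-transfer-loss reconciliation.  Genome GC content excludes
ambiguity codes from numerator and denominator; genome size counts all
residues.  The Kruskal-Wallis H (tie-corrected, df = groups-1,
chi-square tail) backs the clade comparisons.

## Synthetic data

The generators define the study conditions: birth-death species trees
conditioned on tip count and root (MRCA) age by bounded rejection of
forward simulations (10,000 attempts; node-age marginals verified
against a negative-binomial bridge-intensity quadrature oracle by
Kolmogorov-Smirnov at 1,000 replicates); i.i.d. mean-one Gamma branch
multipliers; sequences evolved site-by-site under the declared +I+Gamma
mixture with per-site categories recorded; gene families with one
duplication, lineage-consistent losses and replacement transfers whose
event times must lie within both branches' durations; pigment
inventories propagated from a Type III ancestral cluster under loss
events (mpe set; cpeS/cpeR+rpc set; all phycoerythrin genes), with
truth labels derived from the event composition rather than from the
classifier; and assembly graphs with one connected target component
(depths ~Normal around the target coverage, cv 8%), contaminant
components at a distinct coverage, log-normal contig lengths straddling
200 bp, and core-gene hits placed only on target nodes.  All
randomness flows from one integer seed through named
`numpy.random.Generator` instances; equal seeds give byte-identical
outputs.

What the generators do *not* emulate - assembly chimeras and repeats,
indels and alignment error, codon structure, heterotachy, lineage
sorting, partial genome sampling - bounds what green tests show about
real data: they demonstrate the correctness and calibration of the
machinery under its own assumptions, not robustness to violations of
them.

## Problem sizes and numerics

Suite experiments run at 12-tip/300-site (hypothesis testing),
12-taxon/500-site (clock coverage) and 8-25-node (triage/pigment)
scales, chosen so each experiment carries enough signal to decide its
question while the whole suite stays desk-sized.  Tolerances: oracle
equivalences at 1e-10 relative; stochastic checks at 3 standard errors
(with batch means or conservative effective sample sizes where chains
are autocorrelated); distributional checks by Kolmogorov-Smirnov or
chi-square at conventional levels.  Ties and degeneracies are fixed by
contract: lexicographic NJ joins, strict inequalities at the triage
boundaries (depth < half-mean and length < 200 removed), consensus
tie-breaks by frequency then mean branch length then label order.

## Known limitations

Single-threaded, pure-numpy likelihoods cap practical problem sizes at
tens of taxa.  Stepping-stone estimates at desk-scale ladders carry
Monte-Carlo error of order 1-3 log units; log Bayes factors inside that
band are not interpretable.  The NJ-guided hot starts remove a search
failure mode but cannot guarantee global basin discovery on
pathological data.  The birth-death node-age prior assumes complete
sampling; no fossilised birth-death or sampling-fraction variants are
provided.  The pipeline's CLI orchestrates the synthetic walkthrough
and single-stage runs; it is a convenience layer, not a workflow
engine.
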