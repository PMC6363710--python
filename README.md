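# picoevo

Desk-scale phylogenomics of picocyanobacterial evolution: from raw
assembly-graph triage to dated phylogenies and pigment-cluster
histories.

Marine and freshwater picocyanobacteria (*Synechococcus*,
*Prochlorococcus*, *Cyanobium* and the sponge symbiont
*S. spongiarum*) differ strikingly in the phycobilisome gene clusters
that set their light-harvesting phenotype (pigment Types I, II, IIB and
III).  Reconstructing how those clusters evolved requires a chain of
inferences: cleaning non-axenic assemblies down to the cyanobacterial
contigs, deciding which BLAST hits of the phycoerythrin genes
(*cpeBA*, *mpeBA*) are true orthologs, testing whether *mpeBA* arose by
gene duplication or lateral gene transfer (LGT), dating the divergences
against the fossil and geochemical record, and mapping gene losses and
transfers onto the species tree.  `picoevo` implements that chain as a
tested Python library with a synthetic-data generator for every input,
so each stage can be validated against known ground truth.

## The core machinery

- **Contig triage** — nodes of a GFA assembly graph are kept when they
  sit in a connected component with core-cyanobacterial BLAST hits
  (e-value <= 1e-10) at similar read depth; nodes below half the mean
  depth of that component and contigs under 200 bp are removed.
- **Ortholog contours** — BLAST candidates are scored by identical
  residues over query length, placed on a neighbor-joining tree, and
  grouped by similarity contours; true orthologs form a (mostly)
  monophyletic clade around the query whose scores separate cleanly
  from everything outside, boundary sequences are marked uncertain, and
  a genome with an uncertain alpha subunit loses its beta subunit too.
- **Bayesian phylogenetics** — pruning likelihood under GTR-family
  models with invariant sites and discrete-gamma rates (+ the published
  LG/WAG/JTT matrices for proteins), Metropolis-Hastings over topology
  and parameters, ASDSF convergence across runs, and majority-rule
  consensus trees with posterior probabilities below 0.75 collapsed.
- **Duplication vs LGT** — the competing hypotheses are monophyly
  constraint sets; each constrained marginal likelihood is estimated by
  stepping-stone sampling along a power-posterior ladder, and evidence
  is reported as log Bayes factors `log BF = log ML_i − log ML_j`.
- **Relaxed-clock dating** — node ages under a birth-death prior
  conditioned on the root age, a Gamma root prior holding 95% of its
  mass in the Great Oxygenation Event window (2,320–2,700 Myr), seven
  soft-bounded fossil calibrations (5% prior mass outside each
  interval), uncorrelated-gamma branch rates, and 95% HPD summaries
  with trace-comparison convergence checks.
- **Pigment clusters** — content rules call Types I/II/IIB/III from the
  rod-cluster gene inventory, Dollo parsimony places the minimal loss
  events on the species tree, and sister-group conflicts between gene
  and species trees flag transfers.

## Worked example

The whole pipeline runs end-to-end on synthetic data:

```
picoevo demo --seed 7 --out demo/
```

which simulates a species tree, sequences, an assembly graph with
contaminants, a two-subunit phycoerythrin-like gene family and pigment
inventories, then triages, delimits, infers, tests and dates.  With
seed 7 the hypothesis-test stage prints (`demo/hypothesis_test.tsv`):

```
hypothesis  log_ml      mc_se   log_bf_vs_winner  winner
A           -5269.5812  1.8028  120.592           False
B           -5148.9892  1.1736  0.0               True
C           -5182.2395  1.235   33.2503           False
```

The generating scenario was a duplication on the picocyanobacterial
stem (hypothesis B), and B wins with log Bayes factors of ~121 against
an ancient duplication (A) and ~33 against a transfer (C) — "very
strong" evidence on the conventional scale, mirroring how the real
analysis discriminated the same three hypotheses.  The triage stage
retains exactly the target component above the depth threshold
(`demo/triage_report.tsv`), every pigment inventory is classified back
to its generating type (`demo/pigment_types.tsv`), and the clock stage
writes per-node median ages with 95% HPD intervals next to the true
simulated ages (`demo/node_ages.tsv`).

As a library:

```python
from picoevo.relaxed_clock import fit_root_prior

prior = fit_root_prior(2320.0, 2700.0, 0.95)
print(round(prior.shape, 1), round(prior.rate, 4))
print(100 * (prior.cdf(2700) - prior.cdf(2320)))
```

prints `668.3 0.2666` and `95.0`: the fitted Gamma root prior places
exactly 95% of its mass between 2.32 and 2.70 Gyr.

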