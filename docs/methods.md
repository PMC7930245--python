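# Methods

`somaclone` reconstructs the clonal relationship between a tumour and
multiple normal tissues of one patient from multi-sample variant read
counts. The pipeline has four inference stages — germline/somatic
classification, per-sample presence calling, Dirichlet-process clustering,
and pigeonhole tree reconciliation — plus a synthetic-data generator that
produces read-count tables with exactly the statistical structure the
inference assumes, so every stage can be validated against a known truth.

## Model overview

A patient is sequenced in `N` samples (one or more tumour biopsies and
several normal tissues) at roughly 30–40× whole-genome coverage. For each
candidate single-nucleotide variant we observe, per sample `s`, an alt
read count `a_s` and a total depth `d_s`. Three latent layers generate
these counts:

1. **Clones.** Somatic mutations arise on the branches of a rooted clone
   tree. Node `k` has a cellular prevalence `phi_{k,s} ∈ [0,1]` in each
   sample — the fraction of cells carrying every mutation on the branch
   above `k`. Because a daughter clone's cells are a subset of its
   parent's, prevalences obey the pigeonhole constraint: in every sample,
   the daughters of a node can never sum to more than the node itself.
   The root is the ubiquitous embryonic lineage, `phi = 1` everywhere.
2. **Reads.** For a heterozygous diploid somatic mutation the expected
   variant allele fraction (VAF) is `phi/2`, and
   `a_s ~ Binomial(d_s, phi_{k,s}/2)`. Germline heterozygous variants have
   expected VAF 0.5 in every sample.
3. **Noise.** Sequencing miscalls add a small site-specific error rate,
   possibly overdispersed across samples (beta-binomial).

## Stage 1 — germline vs somatic

Under the germline null a variant is heterozygous in every cell of every
tissue, so alt counts aggregated over the patient's matched tissue samples
should sit at VAF 0.5. Each site gets a one-sided exact binomial test,
`p = P(X ≤ Σa | Σd, 0.5)`: a significantly *low* aggregated VAF is
evidence the variant is somatic (absent or subclonal in most tissue).
P values are Benjamini–Hochberg corrected across the testable sites and
thresholded at `q < 1e-5`; sites with zero aggregated depth are
unclassifiable. By default the aggregation runs over all of the patient's
samples (germline variants are everywhere, so aggregation maximises
power); `matched_only` restricts it to designated reference samples.

Before testing, sites in regions of consistently aberrant depth are
removed: depth `< 15×` in **every** sample, or `> 50×` in every sample.
For X/Y sites of a male patient both thresholds are halved (one copy).
Removal happens before BH correction so the multiplicity count includes
only testable sites. The literal every-sample reading of "consistently" is
the default; a mean-depth variant is exposed as `consistency="mean"`.

A structural consequence worth stating: mutations of the *ubiquitous
embryonic* clone have VAF ≈ 0.5 in every tissue and are therefore
indistinguishable from germline variants by this test. The pipeline drops
them, and the reconstructed tree regains its root as a synthetic unit
root. Recovery scoring accounts for this (the recovered root stands in
for the true root).

## Stage 2 — presence vs sequencing noise

A somatic site may show a few alt reads in a sample that does not truly
carry the variant. Each site gets a beta-binomial noise model with rate
`mu` and overdispersion `rho` (`alpha = mu(1-rho)/rho`,
`beta = (1-mu)(1-rho)/rho`), fitted by maximum likelihood over a 25-point
logarithmic grid for `rho` on `[1e-6, 0.89]`, with `mu` profiled at each
grid point as the precision-weighted mean of `a/d`
(weights `d / (1 + (d-1) rho)`). The lowest grid point is evaluated as the
exact `rho → 0` binomial limit; pushing shape parameters of order `1e6`
through the beta-binomial loses more than the 1e-6 agreement we require
of the limit.

Fitting uses candidate non-carrier samples only (naive VAF < 0.1,
configurable) and is **leave-one-out**: sample `s` is tested against a
model fitted without `s`, so a borderline carrier cannot absorb its own
reads into the noise estimate. Three numerical guards keep the
small-sample fit sane, all adopted after power/calibration simulations
showed the unguarded ML estimate is pathological with < 10 fitted
samples:

- `mu` is floored at the measurement resolution, half a read over the
  summed fitted depth (an all-zero background cannot certify a rate below
  what one read would produce);
- `rho` stays at the binomial floor unless at least two fitted samples
  carry variant reads — with fewer, across-sample rate variability is not
  identifiable and the likelihood drifts along the degenerate
  `(mu → 0, rho → max)` ridge;
- `rho` leaves the floor only when it gains ≥ 2.0 log-likelihood units
  (a boundary likelihood-ratio test at roughly the 2–3% level), so one
  stray read pair cannot inflate the tail.

The presence p-value is the upper tail `P(X ≥ a)` under the fitted model
(`p = 1` when `a = 0` or `d = 0`); calls use a fixed threshold (default
`1e-3`, no multiplicity correction — exposed in config). Sites where
fewer than two low-VAF samples remain fall back to a pooled model fitted
across all low-VAF cells of the table and are flagged. Shared-mutation
counts between tissues are the sites called present in both members of a
pair.

Under a pure-noise simulation (`mu = 0.002`, depth 40, 1e5 site-sample
pairs) the measured call rate at threshold 1e-3 is ~1e-3, and a clone at
prevalence 0.4 shared by two tissues at depth 40 is detected in both in
≥ 95% of replicates (the irreducible miss is a carrier drawing ≤ 2 alt
reads, probability ~0.8% per tissue at these conditions).

## Stage 3 — Dirichlet-process clustering

Somatic mutations are clustered on their joint count profile across all
`N` samples: `a_{m,s} ~ Binomial(d_{m,s}, theta_{k,s})` for mutation `m`
in cluster `k`, `theta_{k,s} ~ Beta(1,1)`, and a Chinese-restaurant-
process prior with concentration `alpha ~ Gamma(1,1)`. Working on raw
counts weighs samples by their coverage and avoids hard VAF cut-offs.

Inference is collapsed Gibbs sampling (theta integrated out of assignment
moves via the beta-binomial predictive; `alpha` resampled with the
Escobar–West auxiliary step), implemented as a numba kernel; a single
integer seed makes runs bit-reproducible. Defaults: 2000 sweeps, 500
burn-in — on the benchmarks used here the chain reaches its plateau
within ~100 sweeps, and the defaults leave an order-of-magnitude margin
while keeping a full run in seconds. Presence calls do not enter the
likelihood (the mixture model handles noise itself); they are used for
reporting only.

The point estimate is the retained state of maximal posterior density
(deterministic given the trace). Clusters below `min_cluster_size`
(default 5) are dissolved and their members reassigned to the
highest-likelihood surviving cluster; cluster VAFs are conditional
posterior means `(1 + Σa) / (2 + Σd)` under the final membership. The
co-assignment matrix over (a thinned subsample of) retained states is
available for diagnostics.

Known limitation: single-site Gibbs moves split overlapping clusters
slowly. When two clones are separated by less than ~0.1 VAF in every
sample, an occasional replicate keeps them merged through the default
sweep budget (observed in roughly 1 of 20 end-to-end benchmark runs);
split-merge moves would address this but are not implemented.

## Stage 4 — clone tree reconciliation

Cluster VAFs map to prevalences by the diploid rule
`phi = min(1, 2 theta)` (the cap absorbs noise above VAF 0.5). Clusters
are placed greedily in descending mean-prevalence order: the first
becomes the root if it is clonal everywhere (`phi ≥ 1 - epsilon`),
otherwise a synthetic unit root is inserted; each remaining cluster
attaches to the *deepest* node satisfying, in every sample, containment
(`phi_parent ≥ phi_child - epsilon`) and spare capacity
(`phi_parent - Σ phi_existing-children ≥ phi_child - epsilon`), with ties
broken by minimal total slack. A cluster admitting no parent raises an
incompatibility error naming the violating samples rather than being
placed silently. `epsilon` defaults to 0.05 on the prevalence scale,
sized to absorb binomial sampling noise at 30–40× depth
(SE of `2 theta_hat` for a 150-mutation cluster is well below 0.01, so
0.05 also covers moderate assignment error).

Note the deepest-admissible rule nests a cluster under any candidate that
dominates it in every sample — profiles related by containment are
reconstructed as chains even if the truth had siblings; only crossing
profiles force siblings. This is the inherent ambiguity of the constraint,
not a solver choice.

Per node the tree reports: prevalence per sample, the private clone size
(prevalence minus children's sum, the fraction of cells in that clone and
no descendant), and the mutation burden of the branch. An independent
`check_pigeonhole` verifier re-checks every node/sample constraint on any
tree. Exports: JSON, newick (branch lengths = burdens), Graphviz dot.

No copy-number adjustment is performed anywhere (diploid heterozygous
assumption); sites in user-supplied CNV regions can be masked with a BED
exclusion file (0-based half-open, converted on read).

## Synthetic data

The generator draws a random topology (each node's parent uniform among
earlier nodes), then per-sample prevalences by recursive stick-breaking
from the root down. Every internal node reserves a recursive minimum
(its 0.02 dominance margin plus its descendants' needs) before the
remaining stick is split by a Dirichlet draw, so the strict pigeonhole
margin holds by construction in every sample. Draws are rejected until
clone profiles are *well separated*: every pair of non-nested clones
crosses by ≥ 0.10 in some sample, every parent–child edge opens a gap of
≥ 0.15 somewhere, every clone reaches prevalence ≥ 0.15 in some sample,
and no non-root clone exceeds a mean prevalence of 0.60 (a quasi-
ubiquitous clone would be swallowed by the germline filter). These
thresholds define the study conditions for the recovery benchmarks: they
make the true tree the unique reconciliation of the true prevalences
while leaving the noisy-recovery problem non-trivial. If no separated
draw is found (degenerate configurations), the last margin-valid draw is
kept and flagged `well_separated=False`.

Counts follow the read model above: depth per site and sample i.i.d.
Poisson(depth_mean) clamped to ≥ 1, alt binomial with a symmetric
per-read miscall rate (default 1e-3). Germline variants are injected at
VAF 0.5 in every sample and recorded in the truth object. Optionally,
male chrX somatic sites are simulated haploid (half depth, VAF = phi);
default off. Defaults — 5 samples, 4 clones, 150–300 mutations per
branch, depth 40, 500 germline sites — mirror a small multi-tissue WGS
cohort.

What the generator does **not** emulate, hence what passing benchmarks do
not certify on real data: copy-number aberrations and LOH (which distort
VAF→prevalence mapping), mapping artefacts and strand bias (handled by
upstream callers), correlated depth along the genome, indels and
structural variants, tumour-in-normal contamination beyond what clone
sharing itself produces.

## Problem sizes used in validation

The acceptance suite and `scripts/acceptance.py` run: exhaustive
exact-test checks to depth 200; a 12-site depth-filter toy; presence
calibration on 1e5 site-sample pairs and 200 power replicates; the
two-cluster VAF benchmark (200 mutations, 5 seeds); twenty end-to-end
simulations at the default cohort conditions; and a double pipeline run
compared byte-for-byte. These sizes keep the full suite under a few
minutes on one CPU while leaving each check statistically meaningful.
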