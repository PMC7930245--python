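# somaclone

Somatic-mutation lineage tracing across tumour and normal tissues.

Every cell division leaves behind somatic mutations, so the mutations
shared between a tumour and the normal tissues of the same patient record
their common developmental ancestry. Given per-sample variant read counts
(alt count, depth) for one patient across a tumour and several normal
tissues, `somaclone` reconstructs that record: it separates germline from
somatic variants, decides in which tissues each somatic variant is truly
present versus supported only by sequencing noise, clusters mutations into
clones by their joint VAF profile, and reconciles the clones into a rooted
tree with per-tissue clone sizes and per-branch mutation burdens. A
synthetic-data generator produces ground-truth cohorts with the same
statistical structure, so the whole pipeline is testable without access to
patient data.

Intended users: researchers doing phylogenetic analyses of tumours and
surrounding normal tissue from multi-sample (bulk WGS) variant calls.

## The model in brief

For a mutation on clone `k` with cellular prevalence `φ_{k,s}` in sample
`s`, the alt count at a diploid heterozygous site is

    a_s ~ Binomial(d_s, φ_{k,s} / 2)

Four inferences are stacked on this read model:

- **Germline vs somatic** — one-sided exact binomial test of the counts
  aggregated over the patient's matched tissues against the germline null
  VAF 0.5, Benjamini–Hochberg corrected, somatic iff `q < 1e-5`. Sites
  with consistently low (<15×) or high (>50×) depth across all samples are
  removed first (thresholds halved on X/Y for a male patient).
- **Presence vs noise** — per site, a beta-binomial error model
  `(μ, ρ)` is fitted on non-carrier samples (leave-one-out, 25-point
  log-grid in ρ); a sample carries the variant if the upper-tail
  probability of its alt count falls below 1e-3.
- **Clustering** — a Dirichlet-process mixture of per-sample binomials
  over all N samples, fitted by collapsed Gibbs sampling (numba kernel,
  seeded and bit-reproducible); the point estimate is the
  maximum-posterior retained state.
- **Tree** — cluster VAFs map to prevalences (`φ = min(1, 2θ)`) and
  clusters are reconciled under the pigeonhole principle: in every sample
  the daughter clones of a node can never sum to more than the node.
  Reported per node: prevalence, private clone size (percent of cells in
  that clone and no descendant), and mutation burden.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate a five-tissue patient (tumour + four normals, four clones,
depth ~40×) and run the full pipeline:

```sh
somaclone simulate --n-samples 5 --n-clones 4 --seed 11 --outdir sim
# wrote 1426 sites x 5 samples to sim
somaclone run --variants sim/variants.tsv --samples sim/samples.tsv \
    --seed 11 --outdir out
```

The run prints the report (abridged):

```json
{
 "clone_tree_nodes": 4,
 "n_clusters": 3,
 "n_input_sites": 1426,
 "n_somatic": 730,
 "shared_mutation_counts": {
  "S0": {"S0": 209, "S1": 3, "S2": 1, "S3": 3, "S4": 120},
  ...
 }
}
```

Reading it: of 1426 input sites, 730 are classified somatic (the rest are
germline, including the ubiquitous embryonic mutations that sit at VAF 0.5
in every tissue and are therefore indistinguishable from germline — the
tree regains its root as a synthetic unit root). The tumour `S0` shares
120 presence-called mutations with tissue `S4` but only 1–3 with `S1`–`S3`:
`S4` is the tumour's closest developmental relative in this simulated
patient. The clusters are reconciled into `out/tree.json` / `out/tree.nwk`:

```
(c0:233,c1:298,c2:199)root:0;
```

with per-node annotations such as

```json
{"id": 0, "parent": -1, "burden": 233,
 "clone_size_pct": {"S0": 55.93, "S1": 11.47, "S2": 8.55, "S3": 11.78, "S4": 40.05}}
```

i.e. clone `c0` carries 233 mutations on its branch and privately makes up
~56% of the tumour and ~40% of tissue `S4` — the shared-clone signature
behind the 120 shared mutations. Every run writes a `manifest.json` with
the config hash and seed; identical config + seed reproduce the bundle
byte for byte.

The same stages are available as library functions
(`somaclone.classify_germline_somatic`, `call_presence`, `gibbs_run`,
`point_estimate`, `build_tree`, ...) operating on a `VariantTable`
(multi-sample VCF with AD/DP, or the TSV dialect written by `simulate`).

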