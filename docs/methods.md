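# Methods

This note describes the statistical model implemented by `phosphodyn`, the
parameter choices it exposes, what the synthetic-data generator does and does
not emulate, and the numerical conventions used throughout.

## 1. The dynamics-based network model

The unit of analysis is a **phosphopeptide profile**: a short vector of
abundance measurements for one phosphopeptide in one subcellular fraction
across an ordered series of stimulation time points (by default five points:
0, 1, 5, 10 and 20 minutes). A network node is the pair
*(peptide ID, fraction)* — the same peptide observed in the cytoplasmic and
the nucleic fraction contributes two distinct nodes, because its dynamics may
differ between compartments.

Two nodes are connected by an undirected edge when the Pearson correlation
of their profiles is **strictly greater** than a threshold *R* (default
0.99; 0.98 and 0.97 are the standard sensitivity settings). Design
consequences of this rule:

- Only peptides with a **complete profile** (no missing time points) enter
  the network; correlation over an inconsistent subset of time points would
  not be comparable across pairs.
- A profile with **zero variance** has no defined correlation with anything
  and therefore forms no edges.
- Anti-correlated profiles never form edges; the model captures co-regulation,
  not opposite regulation.
- After thresholding, nodes with no edges are dropped: the network contains
  only peptides that share dynamics with at least one other peptide.

Because the edge rule is a pure threshold on one statistic, edge sets are
**nested across thresholds**: every R > 0.99 edge is also an R > 0.98 edge,
and so on. The sensitivity analysis exploits this.

## 2. Graph summaries

- **Density** is reported in percent: `100 · E / (N·(N−1)/2)`.
- **Cumulative degree distributions** report `P(degree ≥ k)` either for the
  whole network (grouped by node fraction) or for the two induced fraction
  subnetworks.
- **Protein-level degree** maps each node to its protein via the ID mapping
  and reports, per protein, the mean degree over that protein's peptide
  nodes. Nodes without a protein assignment are counted and skipped.
- **Shortest path lengths** are unweighted breadth-first-search distances.

## 3. Motif census

Motifs are counted by **node-label composition**, where the label is the
subcellular fraction (cytoplasmic "C" or nucleic "N"):

- **Binary** (edges): 3 classes — C–C, mixed, N–N (`B2:0`, `B1:1`, `B0:2`).
- **Triangles**: 4 classes by the number of C nodes (`T3:0` … `T0:3`).
- **Squares**: induced chordless 4-cycles by default. Under the symmetry of
  the 4-cycle there are 6 classes: all-C, three-C, two-C adjacent, two-C
  opposite, one-C, all-N. The adjacent/opposite distinction matters: with
  2 C and 2 N nodes the cycle either alternates labels or not. A collapsed
  5-class mode (merging adjacent/opposite) is available.

Each motif instance is counted exactly once by canonical enumeration
(ordered node indices for edges and triangles; a minimum-node diagonal
representation for 4-cycles). The census reports raw counts and proportions
in percent of the total for that motif size.

The **localization score** of a network is the summed proportion of the two
pure triangle classes, `T3:0 + T0:3` — the fraction of triangles whose
members all share a compartment.

## 4. Null model and enrichment

The null model is **random edge rewiring**: repeatedly pick two edges
(a,b), (c,d) uniformly at random and replace them with (a,d), (c,b) (with a
random orientation), rejecting any swap that would create a self-loop or a
duplicate edge. This preserves every node's degree exactly while destroying
higher-order structure. Rewiring stops when no original edge remains or
after `100 · E` attempts, whichever comes first; **rejected attempts count
toward the cap**, so the procedure always terminates, and the attempt
budget (not full memorylessness) is the effective guarantee on dense,
clustered graphs. The replicate records how many original edges remained.

Enrichment of a motif class compares the observed proportion with its
distribution over `n` independent rewired replicates (default 1,000):

- **O/E** is observed / null mean.
- The **empirical p-value** is one-sided with ties counted:
  `p = (#replicates at least as extreme + 1 is not used; ties count) / n`,
  reported as `< 1/n` when no replicate reaches the observed value. The
  side is chosen per class from the sign of the observed deviation from the
  null mean; for calibration experiments a *fixed* side should be used,
  since choosing the side after seeing the deviation doubles the nominal
  type-I rate (see §7).
- Stars: `*` p < 0.05, `**` p < 0.01, `***` p < 0.001.

Replicate seeds are spawned from a single master seed via
`numpy.random.SeedSequence`, so any replicate can be reproduced in
isolation.

## 5. Pathway comparison

A **pathway network** is built from curated kinase→substrate reactions:
only phosphorylation reactions are used (dephosphorylation events are
excluded), direction is discarded, duplicates and self-reactions collapse.
Subsets can be taken by pathway tag, by excluding a tag, or by restricting
both endpoints to a kinase list.

For every protein pair present in both the pathway network and the dynamics
network, the **dynamics-side distance** is the mean (optionally minimum)
shortest path length over all reachable peptide-node pairs belonging to the
two proteins. Pairs are binned by their integer pathway shortest path
length; an "All" bin additionally pools every shared-protein pair, including
those unreachable in the pathway network. Concordance is the Pearson
correlation between the numeric bin values and the per-bin mean dynamics
distances (optionally weighted by bin size); the "All" bin is excluded from
the correlation.

## 6. Synthetic-data generator

The generator produces a quantification table, a reaction table, an ID map,
and a ground-truth record, for end-to-end testing and power analysis. Its
model:

- Peptides belong to one of `n_modules` **co-regulation modules**. Each
  module has a pulse-shaped template
  `exp(−0.5·((log1p(t) − log1p(peak))/width)²)` with peaks log-spaced over
  the time range — an early transient for low peaks, a late ramp for high
  ones.
- Within a module, proteins form a **kinase cascade chain**; each step down
  the chain shifts the template peak by `cascade_delay` minutes and emits a
  planted kinase→substrate reaction. Depth is recorded as ground truth.
- `fraction_purity` sets the probability that a peptide adopts its module's
  majority compartment; 0.5 removes any compartment signal, values near 1
  plant a strong localization signal.
- Observed abundances are the template scaled by a per-peptide log-normal
  factor plus additive Gaussian noise (multiplicative noise behind a flag),
  with values clipped to be positive and time points dropped independently
  at `missing_rate`.
- ID structure deliberately exercises the mapping code: raw quant and
  reaction accessions differ and map many-to-one onto standard IDs, and one
  dephosphorylation reaction per module is emitted so that reaction
  filtering is observable.

**What the generator does not emulate:** instrument-specific intensity
distributions, missingness that depends on abundance, shared-peptide
ambiguity between proteins, cross-fraction contamination, or feedback loops
in the cascade (chains only). Conclusions about those phenomena cannot be
drawn from it.

### Canonical study configurations

The test suite and the acceptance script use two fixed configurations:

- **Purity study**: 200 peptides, 8 modules, additive noise SD 0.08, no
  cascade delay, purity 0.95 (planted arm) or 0.5 (null arm), threshold
  0.99. The module count and noise level keep the R > 0.99 network sparse
  enough that 1,000 rewiring replicates run in seconds per hundred.
- **Cascade study**: 120 peptides, 4 modules, noise SD 0.02, cascade delay
  1 minute, 1–2 peptides per protein, threshold **0.95**. The threshold
  comes from the template geometry: a one-step peak shift of 1 minute
  lowers within-chain correlation to roughly 0.97 and a two-step shift to
  roughly 0.90, so 0.95 keeps adjacent cascade steps connected while
  separating distant ones.

## 7. Numerical conventions and caveats

- Correlations are computed in double precision. An exactly self-consistent
  construction (dynamics distances equal to pathway distances by design)
  yields a Pearson R of 1 only up to floating-point round-off
  (≈ 1 − 10⁻¹⁶); tests assert `|R − 1| < 10⁻¹²` rather than equality.
- Empirical p-values are discrete with resolution `1/n_reps`; `p = 0` is
  never reported, only `< 1/n`.
- The per-class *adaptive* side choice in enrichment reports is a
  descriptive convention. Under the null it yields about twice the nominal
  significance rate; calibration checks therefore use a fixed side.
- Thresholding uses a strict `>` comparison; profiles correlating exactly
  at the threshold are excluded. With continuous noise this is a
  measure-zero event, but byte-identical duplicated profiles correlate at
  exactly 1.0 and are connected at any threshold below 1.
- All randomness flows from explicit integer seeds below 2³¹; the same
  seed reproduces tables, networks and replicate sets byte-for-byte on the
  same dependency versions.

## 8. Limitations

- Pearson correlation on five points is a coarse similarity; profiles with
  different shapes can correlate highly by chance, which is why the strict
  0.99 default and the rewiring null are both part of the method.
- The rewiring null preserves degrees only; it does not preserve, e.g., the
  fraction-wise degree sequences, so label-related enrichment is tested
  against a fully label-agnostic rewiring.
- Protein-level summaries inherit whatever ambiguity the ID mapping has;
  many-to-one mappings pool peptides from distinct raw accessions.
- The pathway comparison conditions on proteins present in both networks;
  selection effects from detection bias are not modeled.
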