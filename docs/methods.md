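# Methods

## Model and assumptions

The package treats synaptic sign as a deterministic function of gene
expression. Three assumptions carry all of it:

1. **Cation ⇒ excitatory, anion ⇒ inhibitory.** Channel ion selectivity is
   taken as a proxy for the sign of the postsynaptic effect. Real currents
   also depend on ion gradients and membrane potential; none of that is
   modelled.
2. **Genetic permissibility, not functional receptors.** A neuron "has" a
   receptor class if it expresses at least one gene of that class. Subunit
   assembly, trafficking and subcellular localization are ignored, which
   is why a substantial *complex* category appears: many neurons express
   both cation- and anion-channel genes, often for the same ligand.
3. **One label per connection.** The reconstruction reports synapse counts
   per ordered neuron pair with no per-synapse molecular detail, so a
   connection's label is computed once and weighted by its synapse count
   for synapse-level statistics.

Sign prediction covers the three fast ionotropic transmitter systems
(glutamate, acetylcholine, GABA). Monoamines, neuropeptides, metabotropic
receptors and gap junctions are out of scope: gap-junction edges are
parsed and filterable but never labeled.

### The three rule sets

For an edge `pre → post`, with NT(pre) the transmitter set and R(post) the
receptor-class set:

* **NT+R** (headline): matched channels
  `M = {channel : (ligand, channel) ∈ R(post), ligand ∈ NT(pre)}`;
  {cation} → excitatory, {anion} → inhibitory, both → complex, ∅ →
  `unpredicted_no_match`; NT(pre) = ∅ → `unpredicted_no_nt`. The two
  unpredicted flavours collapse to one category in headline statistics
  but stay distinguishable in prediction tables.
* **NT-only**: ACh and/or Glu → excitatory; GABA → inhibitory; an
  excitatory transmitter together with GABA → complex.
* **R-only**: channel types of R(post) regardless of ligand, same
  {cation}/{anion}/both/∅ mapping. R-only can never return
  `unpredicted_no_nt`.

A presynaptic neuron expressing two transmitters matches with the union
over both (one label per edge); the per-transmitter breakdown instead
credits such an edge to *each* expressed transmitter's row and flags the
double counting, since its rows are conditional distributions, not a
partition.

### Receptor classification table

62 genes in six (ligand × channel) classes: Glu-cation 10, ACh-cation 30,
GABA-cation 2, Glu-anion 6, ACh-anion 6, GABA-anion 8; the 14 genes in the
last three-plus-one unconventional classes (Glu-anion, ACh-anion,
GABA-cation) invert the classical transmitter sign. *acc-4* and *lgc-46*
(ACh-gated anion channels with presynaptic localization evidence) ride in
the table flagged `excluded`: known, reported, never matched. The table is
a CSV (`gene,ligand,channel,excluded`) so users can swap in their own
classification.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| binarization threshold | 0 | a quantitative expression value scores positive iff strictly greater; always recorded, never implicit |
| `include_rnaseq` | true | OR-combine the RNA-seq-derived layer with bulk-curated calls; off re-runs everything on bulk evidence only |
| E:I level | synapse | counts weighted by synapse number; `connection` counts each ordered pair once |
| min-weight filter | k = 2 in the stock "weak links deleted" variant | single-synapse connections are the reconstruction's least reproducible |
| pharyngeal roster | packaged 20-neuron list | override-able per dataset |

E:I ratios exclude complex and unpredicted connections from both numerator
and denominator; raw counts are always reported alongside. A zero
inhibitory count makes the ratio *undefined* (`None`), never an infinity.
The "nearest simple ratio" rendering (3.52 → "7:2 (approx.)") is display
only.

## Synthetic data generator

The generator exists to test the pipeline's statistics, not to model the
worm. Per neuron it draws a transmitter category and six independent
receptor-class indicators; per ordered neuron pair an independent
(Erdős–Rényi) directed chemical edge with a geometric synapse count.
Defaults are fixed at worm-scale conditions:

* 300 neurons; transmitter categories at the empirical worm marginals
  (single 256/302, double 12/302, none 34/302), with the single mass split
  ACh 0.60 / Glu 0.30 / GABA 0.10 reflecting the worm's ACh-heavy
  transmitter usage (only the totals are published; the split is this
  package's choice). Double-transmitter neurons draw ACh+Glu with
  probability ½, Glu+GABA and ACh+GABA ¼ each (composition is not
  published; configurable).
* Class expression probabilities (0.45/0.55/0.15 cation, 0.25/0.20/0.35
  anion for Glu/ACh/GABA) chosen once so the cation-only / anion-only /
  mixed / none neuron mix lands near the curated data's shape.
* Expected out-degree 12 and geometric synapse counts with mean ≈ 5.7
  (≈ 3,638 connections, ≈ 20,600 synapses at 300 neurons).

Receptor classes are realized as one canonical gene per class (glr-1,
acr-16, exp-1, glc-3, acc-1, unc-49) so synthetic data exercises the real
gene→class machinery. Consequences a user should know:

* the generator cannot reproduce gene-count statistics of the real data
  (e.g. mean receptor genes per neuron saturates at 6, realized ≈ 2);
* degree structure is Poisson-like, not the heavy-tailed empirical one,
  and there is no spatial, ganglion or modality-correlated wiring —
  modalities are drawn independently of connectivity;
* passing tests on synthetic data certify the *computations* (rule
  engines, tallies, filters, comparisons), not any biological claim.

Because pre- and post-profiles are independent, the NT+R label
distribution of a random edge has an exact closed form, computed by
enumerating every transmitter set against all 2⁶ receptor-class subsets
with product probabilities. Monte-Carlo validation uses a dedicated
sampler that draws each edge with its own fresh endpoint pair
(`sample_independent_edges`) — in an Erdős–Rényi graph edges share neurons
and their labels are correlated, so binomial standard errors would be
invalid there.

## Numerical and design choices

* Duplicate `(pre, post, kind)` rows are summed on load with a warning;
  loading is row-order insensitive. Weights must be integers ≥ 1.
* Neuron names are canonicalized to upper case, genes to lower-case
  hyphenated; transmitter column aliases (`gaba`, `ACh`, …) are
  canonicalized inside `ExpressionDB`, and unknown transmitter columns are
  an error rather than silently dropped.
* Edge endpoints missing from the expression database are treated as
  expressing nothing (→ unpredicted, with a warning), so such synapses
  stay in every denominator; unknown receptor genes are carried but never
  contribute to a class.
* Curation edits apply in listed order; group names expand over the
  database by the positional-suffix convention (AIY → AIYL/AIYR, VA →
  VA1…), explicit neuron lists override, and every flipped cell lands in
  an audit log. Applying an edit and its inverse restores the matrix
  exactly.
* Consistency comparisons run over the intersection of connections with a
  definite label on both sides; `+`/`−` reference vocabularies are
  normalized; complex agrees only with complex; group-level references
  are broadcast to member pairs first. Experimental validation verdicts:
  *validated* / *opposed* on definite agreement/contradiction,
  *partially validated* when either side is complex or uncertain,
  *uncomparable* when the prediction table lacks the connection.
* Polymodal neurons are their own modality category in balance matrices,
  which therefore partition the network exactly.
* The modality balance matrix is computed at synapse level by default
  with a connection-level switch, and both E:I levels are always
  available, since either convention is defensible.

## Problem sizes used by the test and acceptance runs

The default suite runs entirely on generated data: a shared 120-neuron
instance for oracle/tally checks, 1,000 independent 12-neuron instances
for partition conservation, and 10⁵ independent edges for the Monte-Carlo
vs closed-form comparison (3 standard errors per label, seeds fixed).
`scripts/acceptance.py` re-runs the worked example, one 300-neuron study
with the stock perturbation suite, and the 10⁵-edge comparison, all
seeded from `--seed`.

## Known limitations

Beyond the generator caveats above: the full-connectome reproduction
requires user-supplied source files (the public reconstruction and curated
expression matrices are not redistributable here), group-to-member
broadcasting of group-level references is a convention the original
reference sets only define implicitly, and the package deliberately makes
no attempt to resolve *complex* labels into per-synapse signs — that needs
subcellular receptor localization or dynamic expression data that does not
exist worm-wide.
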