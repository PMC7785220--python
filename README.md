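# synsign

Gene-expression-based prediction of chemical-synapse polarity in the
*Caenorhabditis elegans* ionotropic connectome, and analysis of the
resulting excitatory:inhibitory (E:I) sign balance.

## The problem

The worm's chemical-synapse network is fully reconstructed and directed,
but almost none of its connections have a known *sign*. Classically a
connection's sign is read off the presynaptic transmitter — glutamate and
acetylcholine excite, GABA inhibits — but that ignores the receptor side:
glutamate- and acetylcholine-gated **anion** channels and GABA-gated
**cation** channels exist and invert the textbook sign. The same
cholinergic neuron can therefore excite one target and inhibit another,
depending on which receptor genes each target expresses.

`synsign` labels every chemical connection `pre → post` by matching the
presynaptic transmitter set NT(pre) ⊆ {Glu, ACh, GABA} against the
postsynaptic receptor classes R(post) ⊆ {Glu, ACh, GABA} × {cation,
anion}, where a neuron holds a class if it expresses ≥ 1 gene of that
class. With the matched channel set

M = { channel : (ligand, channel) ∈ R(post), ligand ∈ NT(pre) },

the **NT+R** rule labels the connection *excitatory* if M = {cation},
*inhibitory* if M = {anion}, *complex* if both, and *unpredicted* if
M = ∅ (distinguishing "no transmitter known" from "no matching
receptor"). Two reference rules are included for comparison: **NT-only**
(transmitter identity alone) and **R-only** (postsynaptic channel types
alone, ligand ignored). The packaged classification table sorts the 62
ionotropic receptor genes into the six (ligand, channel) classes — 14 of
them sign-inverting ("unconventional") — and excludes the two
presynaptically acting genes *acc-4* and *lgc-46* from matching.

From the labeled network the package computes E:I ratios (excitatory over
inhibitory counts, at synapse or connection level; complex and unpredicted
excluded from the quotient), per-transmitter breakdowns, modality-group
balance matrices, perturbation robustness (weak-link deletion, pharyngeal
removal, unweighting, alternative reconstructions, expression-source
exclusion), and per-connection consistency against reference polarity
sets. A seeded synthetic-data generator with a closed-form label
distribution makes every stage testable without any download.

## Worked example

```sh
python analysis/01_worked_example.py
```

```
pre post  method      label
AIY  RIB    NT+R excitatory
AIY  AIZ    NT+R inhibitory
AIY  RIB NT-only excitatory
AIY  AIZ NT-only excitatory
AIY  RIB  R-only excitatory
AIY  AIZ  R-only inhibitory

NT+R splits AIY's two cholinergic outputs: AIY->RIB excitatory, AIY->AIZ
inhibitory — receptor expression, not transmitter identity, sets the sign.
```

AIY is cholinergic; RIB expresses only an ACh-gated cation channel
(*acr-16*) and AIZ only an ACh-gated anion channel (*acc-1*). Judging by
transmitter alone (NT-only) calls both connections excitatory and misses
the inhibition entirely.

The remaining drivers run the full synthetic study —
`analysis/02_simulate.py` (worm-scale dataset: 300 neurons, ~3,600
connections, ~20,000 synapses), `03_predict.py` (all three rule sets),
`04_balance.py` (per-transmitter and modality-pair balances),
`05_robustness.py` (perturbation suite, closed-form cross-check, NT+R vs
NT-only consistency) — writing tables under `results/`.

Real data flows through the same functions: a `pre,post,kind,weight` edge
list, binary neuron × gene matrices (CSV/TSV/XLSX), optional quantitative
matrices via `binarize_expression` with an explicit threshold, curation
edits via `apply_curation_edits`, and the `synsign` CLI
(`predict`, `stats`, `robustness`, `compare`, `simulate`, `summary`).

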