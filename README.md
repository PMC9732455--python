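# molforge

A desk-scale toolkit for AI-assisted hit-to-lead design, written for
computational chemists who want the *machinery* of such a campaign — reverse
target fishing, generative SMILES modeling with transfer learning, synthetic
feasibility scoring, lead-like triage, kinase-panel selectivity, and
alchemical free-energy estimation — as one tested, configuration-driven
Python library with a CLI, runnable end to end on synthetic fixtures with no
external databases, docking engines or MD codes.

## What it computes

**Reverse target prediction.** A query compound is scored against every
ligand of a bipartite protein–ligand network under 6 fingerprint families ×
6 similarity measures (Tanimoto, Dice, Cosine, Sokal, Kulczynski,
McConnaughey). The most similar ligands propagate scores to their proteins;
within each fingerprint, proteins are ranked and receive normalized rank
scores `rank score = rank value / Σ rank values`, and the per-protein total
R over fingerprints is rescaled to the modified total rank score
`R̃ = R / Rmax ∈ (0, 1]` — the final target ranking.

**De novo generation.** A character-level LSTM SMILES language model
(implemented in NumPy, fully seeded and reproducible) is pretrained on a
corpus, fine-tuned by transfer learning on a focused analog series, sampled
at a temperature, and evaluated MOSES-style (validity, uniqueness, novelty,
internal diversity, scaffold overlap).

**RAFSF synthetic feasibility.** Compounds are cleaved at BRICS bonds and
each fragment/bond is looked up in a frequency space harvested from a
reference corpus; the score `1 + 9·max_f [1 − log10(1+c_f)/log10(1+Cmax)]`
runs from 1 (every piece common) to 10 (some piece never seen).

**Lead-like funnel.** Property windows, PAINS structural alerts, novelty
versus known actives, RAFSF cutoff, and pluggable toxicity predicates, with
per-compound verdicts and reasons.

**Selectivity.** Kinase-panel docking scores are min–max rescaled per
compound and the selectivity score is `S = |{k : rescaled_k < 0.5}| / N`
(strict inequality; lower S = more selective).

**BAR free energies.** The Bennett acceptance ratio self-consistency
equation `⟨1/(1+e^{β(ΔU−ΔG)})⟩_i = ⟨1/(1+e^{β(−ΔU+ΔG)})⟩_j` is solved per
λ-window over tabulated energy-difference samples, chained into decoupling
legs (default 21-λ-state schedule) and combined as
`ΔG_bind = ΔG_water − ΔG_complex`, with bootstrap uncertainties.

See `docs/methods.md` for models, assumptions, defaults and limitations.

## Worked example

```python
from molforge import fixtures, targetnet, bar

# a synthetic 10-protein network with one planted target for a query compound
table, planted, query = fixtures.generate_network(fixtures.FixtureSpec(seed=7))
net = targetnet.build_network(table)
ranked = targetnet.predict_targets(query, net, top_k=10)
print(ranked.totals.head(3))

samples, truth = fixtures.generate_work_samples(delta_g=1.0, sigma2=1.0,
                                                n=100_000, seed=7)
dg = bar.bar_solve(samples)
se = bar.bar_uncertainty(samples, n_bootstrap=200, seed=7)
print(f"BAR: {dg:.3f} +/- {se:.3f} kcal/mol (truth {truth})")
```

prints

```
             R   R_tilde  rank
P000  1.714286  1.000000     1
P007  1.428571  0.833333     2
P006  0.952381  0.555556     3
BAR: 0.998 +/- 0.002 kcal/mol (truth 1.0)
```

`P000` is the planted target: it tops every per-fingerprint ranking, so its
six rank scores are maximal and `R̃ = R/Rmax = 1`, while decoy proteins
collect strictly less rank mass. The BAR solve recovers the planted
free-energy difference of the Crooks-consistent Gaussian work samples to
within its bootstrap standard error.

The same functionality is scriptable from the shell:

```bash
molforge run --out-dir myrun              # corpus -> train -> sample -> funnel
molforge target score --network net.csv --query 'CC(C)c1ccc(NC(=O)c2ccc(Cl)cc2)cc1'
molforge rafsf build-space corpus.smi -o space.tsv
molforge rafsf score hits.smi --space space.tsv
molforge selectivity panel.csv
molforge bar --windows windows/ --beta 1.688
```

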