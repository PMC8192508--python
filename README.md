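# ageflow

Signal-flow analysis of how age-associated DNA-methylation changes drive
transcriptomic aging, and where in the regulatory network that drive can be
reversed.

`ageflow` is for systems-biology researchers who have paired methylation
and expression profiles from an aging cohort plus a canonical
transcription-factor (TF) → target regulatory network, and who want to:

1. call **DMPs** (CpG positions whose beta value correlates with age) and
   **DEGs** (genes with a per-year expression trend),
2. link DMPs to nearby TF genes (TSS or gene body within 5 kb) through
   methylation–expression correlation,
3. carve out the aging subnetwork and assign each edge a **mode of action**
   (+1 activation / −1 inhibition) from partial correlations,
4. propagate per-sample methylation-derived input signals through the
   signed network, classify each output DEG by whether its predicted
   **direction of activity change (DAC)** matches its measured trend,
5. rank intermediate nodes as **reverse-aging targets** by in-silico ±1
   perturbation, and
6. screen drug perturbation (modZ) profiles for reversal of the aging
   signature.

A first-class synthetic-data module generates cohorts, methylation and
count matrices, ground-truth signed networks and perturbation profiles
with the statistical structure the analysis assumes, so the entire
pipeline is testable end to end without restricted human data.

## The model

Activities on the signed network follow a damped linear fixed point

```
x = α W x + (1 − α) b,      W[i, j] = s(j→i) / d_in(i),
```

where `s(j→i) ∈ {−1, +1}` is the edge mode of action, `d_in(i)` the
in-degree of node *i*, `α ∈ [0, 1)` (default 0.5) balances upstream signal
flow against basal activity, and `b` carries the inputs. In-degree
normalization makes `‖αW‖∞ ≤ α < 1`, so

```
x = (1 − α)(I − α W)⁻¹ b
```

exists, is unique, and is linear in `b` — per-input contributions are exact
superposition. Inputs are built per sample: each representative DMP's beta
value is Z-scored across the cohort, scaled to [−1, 1] by the cohort
maximum |Z|, signed by its methylation–expression correlation, and placed
on its linked TF node.

Marker statistics use Pearson correlation with the exact t transform
(DMPs; raw P, no multiplicity correction), a negative-binomial GLM with
design `intercept + age + sex` and library-size offset with
Benjamini–Hochberg adjustment (DEGs), and the upper-tail hypergeometric
test for marker-panel overlaps.

## Worked example

```bash
ageflow all --seed 7 --out demo/
```

simulates a 100-sample cohort (ages 20–74), a 300-gene ground-truth
network, runs every stage, and writes `dmp.tsv`, `deg.tsv`, `links.tsv`,
`network.tsv`, `activities.tsv`, `dac.tsv`, `targets.tsv`, `screen.tsv`
and `summary.json`. A typical `summary.json`:

```json
{
 "n_candidate_drugs": 3,
 "n_candidate_targets": 1,
 "n_dac_consistent": 45,
 "n_deg": 75,
 "n_dmp": 216,
 "n_links": 145,
 "n_network_edges": 118,
 "n_network_nodes": 69,
 "n_variance_dropped": 4,
 "seed": 7
}
```

Reading the run: 216 positions pass the raw P < 0.05 DMP test (150 are
planted, the rest are the expected ~5% false positives among 1,350 nulls);
75 genes survive BH adjustment (45 planted DEGs plus the on-path TFs that
genuinely inherit the aging signal); 145 DMP–TF links fall within the 5 kb
window; the reconstructed subnetwork keeps 118 signed edges over 69 nodes;
45 output DEGs have a DAC consistent with their measured trend; one
intermediate node (the top 5% of intermediates) is a candidate target, and
three drugs reverse more than half of the signature.

`targets.tsv` ranks each intermediate node by the number of validated DEGs
its best ±1 perturbation drives opposite to aging; the top 5% are candidate
targets. `screen.tsv` reports, per drug, the dose/time condition reversing
the most signature DEGs and flags drugs reversing more than half.

The same objects are available in Python:

```python
from ageflow.simulate import SimulationConfig, simulate_all
from ageflow.pipeline import run_analysis

study = simulate_all(SimulationConfig(seed=7))
result = run_analysis(study.methylation, study.expression, study.cohort,
                      study.truth.annotation,
                      study.network.edge_table()[["source", "target"]],
                      study.profiles)
print(result.ranked_targets.head())
```

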