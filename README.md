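# omu-synergy

Prioritizing synergistic two-drug combinations from **single-drug** data.

Testing all pairwise combinations of a drug panel in multi-dose matrix
experiments is quadratically expensive: 57 drugs already mean 1,596 pairs,
each needing a 6×6 dose–response matrix.  `omu-synergy` implements a
network-based ranking that uses only what is routinely measured per single
drug — a transcriptomic response profile and a dose–response phenotype — to
nominate the small fraction of pairs worth testing in the lab.  It is aimed
at computational biologists and drug-screening groups working with
LINCS-style perturbation profiles and growth-rate inhibition assays.

## Method

1. **Condition-specific regulatory networks.**  For the untreated control
   and each drug a weighted bipartite TF→gene network is inferred by
   message passing that integrates a regulatory prior, TF–TF protein
   interactions and gene co-expression; edge weights are z-scores.
2. **Differential modules.**  Each treated network is compared with the
   control: the differential modularity D[tf, gene] measures how much an
   edge exceeds its expectation under the control network's community
   structure; positive mass is aggregated into drug-specific differential
   gene modules, each edge carrying its D score.
3. **OMU system.**  Modules recurring across drugs (Jaccard similarity of
   edge sets ≥ 0.25, greedy merge from most similar pair down) form
   *operational module units* (OMUs).  Each OMU stores its shared-edge
   structure, its member modules, and a mean GRmax
   `mean GRmax = Σᵢ GRᵢ·Xᵢ / Σⱼ Yⱼ` — member-module weights Xᵢ weighted by
   their sample's GRmax relative to the sample's total module weight Yⱼ.
   Every drug becomes a sparse non-negative activity vector over the OMU
   system.
4. **Balance regression.**  OMUs are clustered hierarchically by mean
   GRmax.  At an internal node the isometric log-ratio (ILR) balance

   b = √(|iL|·|iR| / (|iL|+|iR|)) · ln( g(iL) / g(iR) )

   contrasts the geometric means g(·) of the left (death-associated) and
   right subtree components.  The node whose balances best correlate with
   GRmax across drugs is selected and GRmax is regressed on b by ordinary
   least squares.
5. **DGIS ranking.**  Two-drug vectors take the component-wise maximum of
   the single-drug vectors (renormalized).  The model predicts each pair's
   growth impact score (GIS); the differential growth impact score (DGIS)
   compares it with the pair's two self-combinations: below both → negative
   (predicted super-additive inhibition), between → 0, above both →
   positive.  Pairs are ranked ascending by DGIS.
6. **Validation and enrichment.**  6×6 combination matrices are scored with
   a ZIP-style delta (observed inhibition minus the independence
   expectation y₁+y₂−y₁y₂ of the monotherapy margins, in percentage points;
   > 5 is called synergistic), and a joint-binomial maximum-likelihood
   statistic compares the hit rate of the top-k list against a random
   sample of pairs.

A seeded synthetic-study generator (`omu_synergy.simulate`) emulates every
input — block-structured priors, single-profile expression with planted
module perturbations tied to GRmax, and Hill-curve dose–response matrices
with planted interactions — so the full pipeline runs and is tested without
any external download.

## Worked example

```python
from omu_synergy import StudyConfig, SynergyModel, generate_study
from omu_synergy.model import PipelineOptions

study = generate_study(StudyConfig(n_drugs=20, seed=1))
results = SynergyModel.from_study(study, options=PipelineOptions(seed=1)).fit()
print(results.summary())
```

```
Two-drug synergy prioritization
===============================================
conditions (drugs):                    20
differential modules:                 118  (per drug 5..6)
OMUs in system:                        41
balance point (node id):               80
  centroid mean GRmax:             -0.012
ILR ~ GRmax Pearson r:             -0.817
R-squared:                          0.667
slope / intercept:            -0.617 / -0.102
scored pairs:                         190
top candidates reported:               30
```

The negative correlation (r = −0.817) says drugs whose differential modules
load on the low-mean-GRmax (cell-death) side of the balance kill cells more
strongly; the fitted line converts any combined vector's balance into a
predicted growth impact.  `results.top` holds the candidate list:

```
 rank drug_1 drug_2       gis      dgis
    1 drug05 drug12 -1.012005 -0.134830
    2 drug14 drug20 -0.263560 -0.114247
    3 drug08 drug12 -0.986432 -0.109257
```

A DGIS of −0.135 means the pair's predicted growth impact is 0.135 GRmax
units below the better of its two single drugs — a super-additive
prediction.  `results.plot_fit()` and `results.plot_dgis_distribution()`
visualize the regression and the (zero-mode) DGIS distribution.

The same workflow is scriptable:

```bash
omu-synergy run --config run.yaml --out-dir out/
```

which writes every intermediate artifact (networks, modules, OMU system,
vectors, model, ranking, ZIP scores, enrichment) plus a checksummed
manifest; each stage is also available as its own subcommand
(`simulate`, `grn`, `diffnet`, `omu`, `fit`, `score`, `zip`, `gr`,
`enrich`).

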