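# panelnet

Two-wave symptom-network analysis for treatment studies: regularized
partial-correlation networks, cross-lagged panel networks, expected-influence
centrality, resampling-based stability, permutation network comparison, and
centrality-to-outcome linkage with likelihood-based missing-data handling —
plus a synthetic-data generator with known ground truth so every stage can be
verified without access to clinical records.

## Who this is for

Researchers analyzing pre/post treatment panels of ordinal symptom ratings —
the motivating case is a cohort of youth assessed on the 20 DSM-5 PTSD
symptoms (0–4 frequency ratings) before and after trauma-focused CBT, with a
parent-rated psychosocial-difficulties total (0–40) that is partly missing.
The package reproduces that study design end to end on any conforming panel
CSV, and ships a generator that emulates its statistical shape (n ≈ 652,
skewed 5-point items, pre→post improvement around *d* ≈ 1, ~50% outcome
missingness) for simulation work and method checks.

## The models

**Cross-sectional networks.** Each wave's 20×20 item correlation matrix *S*
is fit by the graphical lasso,

&nbsp;&nbsp;&nbsp;&nbsp;min<sub>Θ≻0</sub> −log det Θ + tr(SΘ) + λ‖Θ‖<sub>1,off</sub>,

over a 100-point log-spaced λ path, with the penalty selected by the extended
BIC, EBIC(λ) = −2ℓ(Θ̂) + E log n + 4γE log p (γ = 0.5, E = number of edges).
By default the EBIC of each candidate support is evaluated on the unpenalized
maximum likelihood restricted to that support, and the refit edge weights
w<sub>ij</sub> = −θ<sub>ij</sub>/√(θ<sub>ii</sub>θ<sub>jj</sub>) are returned
(`refit=False` gives the penalized variant). The inner solver is a
numba-compiled block coordinate descent, fast enough for full re-estimation
inside every bootstrap draw and permutation.

**Centrality.** Expected influence EI<sub>i</sub> = Σ<sub>j</sub>
w<sub>ij</sub> (signed one-step sum); for directed networks, out-EI and in-EI
sum a node's outgoing and incoming off-diagonal effects. Nodes with EI
z-scores above 1 are flagged central.

**Stability.** Subject bootstrap for edge-weight percentile CIs and
difference tests; case-dropping bootstrap for the CS-coefficient — the
largest case-drop proportion at which 95% of subsets still correlate ≥ 0.7
with full-sample centrality.

**Network comparison.** Permutation tests of structure invariance
(M = max |w<sup>(1)</sup><sub>ij</sub> − w<sup>(2)</sup><sub>ij</sub>|) and
global strength (S = |Σ|w<sup>(1)</sup>| − Σ|w<sup>(2)</sup>||), paired
(within-subject wave swaps) or independent (group-label permutation), with
networks re-estimated inside every permutation.

**Cross-lagged panel network.** Node-wise LASSO of each standardized wave-2
symptom on all standardized wave-1 symptoms (10-fold cross-validated
penalty); b[i, j] is the standardized lagged effect of symptom i on symptom
j, the diagonal holding autoregressive effects. Optional covariate
adjustment (age, sex, race, maltreatment index trauma) keeps covariates out
of the network.

**Clinical linkage.** Per-symptom importance (correlation of a symptom's
change score with the summed change of the other 19), regressions of
importance on centrality controlling baseline severity, and a
core-vs-peripheral regression of the post outcome on mean change in central
vs peripheral symptoms plus covariates. Missing outcomes are handled by EM
for the multivariate-normal mean/covariance (coefficients from the converged
moments, bootstrap SEs), which equals complete-data OLS exactly when nothing
is missing; Little's χ² test diagnoses the MCAR hypothesis.

## Worked example

```python
import panelnet as pn

truth = pn.make_ground_truth(edge_density=0.2, seed=1)   # known structure
panel = pn.simulate_panel(truth, n=652, seed=1)          # two-wave panel

net = pn.estimate_network(panel, "pre")                  # EBIC-glasso GGM
ei  = pn.expected_influence(net)
res = pn.nct_paired(panel, None, n_perm=200, seed=4)     # paired comparison
clpn = pn.fit_clpn(panel, k_folds=10, seed=5)            # lagged network
c = pn.autoregressive_contrast(clpn)
```

Printed by the example scripts (`python examples/02_cross_sectional_network.py`
and friends):

```
edges retained: 23 of 190 pairs
central symptoms (EI z > 1): ['D4', 'E2']
structure  M = 0.365, p = 0.005
strength   S = 0.053, p = 0.905
mean autoregressive coefficient: 0.093 (sd 0.057)
mean cross-lagged coefficient:   0.002 (sd 0.016)
paired t(19) = 7.12, p = 9e-07
```

Reading these numbers: the EBIC keeps 23 of 190 possible edges (sparse
conditional-dependence structure); two symptoms are central by the z > 1
rule; the paired test finds the wave-2 wiring differs (the generator draws
wave-2 innovations from their own network) while global connectivity does
not; and symptom persistence (mean autoregressive 0.09) dominates
symptom-to-symptom influence (0.002) with t(19) = 7.1 — the classic
strong-diagonal signature of two-wave treatment data.

The same analyses run from the shell on a panel CSV:

```bash
panelnet simulate --n 652 --seed 1 --out panel.csv
panelnet run panel.csv --seed 7 --out report/
panelnet subgroup panel.csv --split sex --out subgroups/
```

`panelnet run` writes a bundle of CSV/JSON artifacts (networks, centrality,
bootstraps, stability profiles, comparison and regression results) that is
byte-identical across re-runs with the same config and master seed.

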