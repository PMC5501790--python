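# fcscaffold

Percolation and maximum-spanning scaffold analysis of resting-state
functional connectivity networks.

## The problem

A resting-state fMRI cohort yields, per subject, a T × N matrix of ROI time
series. Pairwise Pearson correlation turns each into an N × N functional
connectivity matrix. The usual next step — picking a threshold to binarise
the group matrix — is arbitrary. This package implements a threshold-free
alternative: track the connected components of the weighted network while
links are removed one at a time in increasing weight order (*percolation*),
read off the stable configurations (*plateaux*) where many removals change
nothing, benchmark their lengths against random correlation matrices with
the same eigenvalue spectrum, and extract the network's basal scaffold with
the Maximum Spanning Forest (each node keeps only its strongest link) and
the Maximum Spanning Tree. The degree profile of the scaffold distinguishes
chain-like organisation (nearly all degrees ≤ 2) from the star-like hubs
that random matrices produce.

It is written for network-neuroscience practitioners, but the pipeline is
agnostic to N and to where the time series came from.

## The method in brief

- **Group matrix** — subject matrices are Fisher-transformed
  (z = atanh r), averaged across subjects, and back-transformed; analysis
  weights are w_ij = r_ij², which discards the sign of a correlation while
  keeping the ranking of its magnitude.
- **Percolation** — rank all weights increasingly; remove links one at a
  time; record the component count after every removal. The plateau ending
  at the birth of component n+1 has length equal to the weight increment
  since the previous birth.
- **Null ensemble** — random correlation matrices with exactly the observed
  spectrum: A₀ = Q diag(λ) Qᵀ with Q Haar-orthogonal, then ≤ N−1 Givens
  rotations restore the unit diagonal. Symmetric, PSD and unit-diagonal by
  construction.
- **Threshold selection** — a real plateau is significant when its length
  exceeds the null ensemble's mean + 4 SD at the same component-count
  transition; selected start-of-plateau weights are reported on both the w
  and the √w (correlation) scales.
- **Scaffold** — the directed MSF keeps arc i → argmax_j w_ij for every
  node; completing it with the heaviest inter-component links (union-find)
  yields the MST, verified against classical maximum-spanning-tree oracles.

## Worked example

The bundled synthetic cohort plants 8 chain modules across N = 116 ROIs
(40 subjects, T = 240, within-chain r = 0.6, background 0.1, subject noise
SD 0.1 on the z scale). Running the analysis scripts in order:

```
python analysis/01_simulate_cohort.py     # writes scratch/cohort/
python analysis/02_group_correlation.py
python analysis/03_percolation_nulls.py
python analysis/04_spanning_scaffold.py
```

prints (seed 1):

```
across-subject SD in [0.056, 0.128]; 6669/6670 edges retained by FDR
jackknife similarity in [0.999492, 0.999551] -> no single subject drives the group average
real percolation: 115 plateaus, longest 0.1512
null ensemble (100 members): longest plateau 0.0435, pooled mean 0.00091 +- 0.00231
2 significant thresholds selected (w scale: [0.1694, 0.0181]; r scale: [0.4115, 0.1346])
MSF: 36 components, 36 reciprocated pairs, 47% of in-degrees equal to 1 (chain-like)
null MSF max in-degree 7.0 on average (range 4-13) vs real 2 -> star-like nulls, chain-like brain
MST: total weight 21.418, chain score 0.90, degree histogram {1: 14, 2: 90, 3: 12}
```

Reading this: the real network resists disaggregation — its longest plateau
(0.151) dwarfs anything in the null ensemble (max 0.043), and the selected
thresholds bracket the planted within/between-module weight gap. The MSF
splits into 36 modules whose in-degrees stay at 1–2 (chains), while every
spectrum-matched random matrix collapses into star-like components around
in-degree hubs. Tables land under `results/`, bulky intermediates under
`scratch/`.

The same pipeline runs on real data from a manifest of time-series files:

```
fcscaffold run --config config.yaml          # or stage-by-stage:
fcscaffold simulate/correlate/variability/nulls/percolate/thresholds/msf/mst/report
```

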