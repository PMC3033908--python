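# gpcrmi — chemogenomic mutual information for GPCRs and their ligands

`gpcrmi` asks a chemogenomics question: *which amino-acid positions of
family A G-protein-coupled receptors statistically co-vary with the
chemical properties of the ligands that act on them?* It links two spaces
that are usually analysed separately — the aligned receptor sequences
(positions in Ballesteros–Weinstein numbering, with the `Lp2.x` extension
for the second extracellular loop) and a matrix of discrete molecular
descriptors of the ligands (element counts, H-bond donor/acceptor counts,
ring counts, plus two continuous surface areas). The analysis is run
separately for agonists and antagonists, and for receptors grouped by
their Gs/Gi/Gq coupling preference, so that positions can be classified
as selective for a ligand effect or for a signalling pathway.

The package is aimed at computational chemists and receptor biologists
who have (or can emulate) a receptor–ligand pair table and an annotated
alignment, and want a tested, reproducible implementation of the method
rather than a one-off script.

## The statistic

Each receptor–ligand pair contributes one observation of
(X = residue at a position, Y = a discretized descriptor of the ligand).
With relative frequencies from the joint histogram over K pairs:

    H(X)   = − Σ_i p_i log₂ p_i
    I(X,Y) = H(X) + H(Y) − H(X,Y)

The plug-in estimate is positively biased at finite K; the leading-order
systematic error depends only on the occupied-bin counts, and the
corrected estimate is

    I_corr = I − (B_XY − B_X − B_Y + 1) / (2 K ln 2)     [bits]

Significance is assessed with 100 permutation surrogates (the y values
permuted against fixed x, preserving both marginals exactly):

    S = (I_corr − mean_surrogate) / sd_surrogate

and the null hypothesis of independence is rejected one-sided at
α = 0.005, i.e. S > 2.63 (the t quantile with 99 degrees of freedom).
A Lilliefors test audits the normality assumption on every surrogate
ensemble. Per analysis subset, the top 0.5% of MI values that also pass
the S threshold are the *hotspots*; hotspot positions are then classified
as agonist-/antagonist-selective (or both) and by single / pair / triple
G-protein selectivity.

## Worked example

The analysis is driven by the numbered scripts under `analysis/`, which
exercise the library in `src/gpcrmi/` end to end on a synthetic dataset
with known ground truth:

```sh
python analysis/01_simulate.py         # write dataset to results/synthetic/
python analysis/02_scan.py             # scan all five subsets, write reports
python analysis/03_surrogate_diagnostics.py
python analysis/04_recovery.py
```

`01_simulate.py` (seed 0) prints:

```
receptors: 100  pairs: 1742
pairs by ligand type: {'full_agonist': 784, 'partial_agonist': 188, 'antagonist': 770}
pairs by G protein:   {'Gs': 1116, 'Gi': 1026, 'Gq': 1067}
```

— the study-scale shape: ~100 receptors, ~1700 pairs split into full
agonists, partial agonists and antagonists, with overlapping G-protein
annotations because many receptors couple promiscuously.

`02_scan.py` then computes 1800 (position, descriptor) tests per subset:

```
agonist      pairs=972   tests=1800  top=9   hotspots=2
antagonist   pairs=770   tests=1800  top=9   hotspots=1
Gi           pairs=1026  tests=1800  top=9   hotspots=3
Gs           pairs=1116  tests=1800  top=9   hotspots=3
Gq           pairs=1067  tests=1800  top=9   hotspots=1
```

`top` is the ceil(0.005 × 1800) = 9 highest corrected-MI entries per
subset, and `hotspots` the few of those that also exceed S = 2.63. This
default dataset plants *no* true associations, so the handful of
survivors is exactly the false-positive level the thresholds are designed
to deliver; `03_surrogate_diagnostics.py` confirms the null calibration:

```
"s_mean": -0.0513, "s_sd": 1.0218,
"frac_s_above_threshold": 0.00989, "threshold": 2.6264
```

With associations actually planted, `04_recovery.py` plants 5 strong
residue–descriptor dependencies among 2100 candidate pairs and recovers
them through the full filter chain in 84 of 100 cases over 20 seeds
(`overall recovery: 84/100 = 0.84`).

Reports land in `results/reports/`: `scan.csv` (every test with entropies,
raw/corrected MI, bias, S, and both selection filters flagged),
`hotspots.csv`, `position_classes.csv`, `descriptor_frequencies.csv`, a
JSON run summary, and an optional per-position attribute file for
molecular-viewer coloring. Identical inputs, config and seed give
byte-identical outputs.

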