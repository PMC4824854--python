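# calpcleave

Quantitative structure–activity (QSAR) analysis of calpain proteolysis.

Calpain-1 and calpain-2 are Ca²⁺-dependent intracellular cysteine
proteases that regulate their substrates by *limited* proteolysis —
cutting a few specific bonds — yet the sequences they cut look almost
arbitrary. `calpcleave` is a toolkit for working on that problem
quantitatively. It is aimed at protease biochemists and computational
biologists who have cleavage-site tables (and, ideally, measured
catalytic efficiencies) and want to featurize sites, build and apply
predictive models, estimate efficiencies from multiplexed digestion
data, and run the standard specificity statistics.

## What it computes

Every cleavage is described by its P10–P10′ window: residues
P10…P1 N-terminal and P1′…P10′ C-terminal of the scissile bond
(cleaved between P1 and P1′). On top of per-position amino-acid
descriptors (AAindex scales, molecular-property tables,
secondary-structure probabilities) the package provides:

* **Binary-QSAR cleavability classifier** — Bayes' rule over principal
  components of the descriptors with binned, smoothed class-conditional
  densities: P(cleaved | x) ∝ P(cleaved) ∏ⱼ P(binⱼ(x) | cleaved).
  With leave-one-out cross-validated accuracy (XA), greedy backward
  feature elimination (smallest set with XA > 0.7), confusion-matrix
  metrics, reversed-sequence negatives, whole-protein scanning, and a
  P2×P1 cooperativity count table.
* **PLS efficiency regression** — NIPALS partial least squares of
  k_cat/K_m (M⁻¹s⁻¹) on position-specific descriptors, components
  chosen by LOO-cross-validated r² (Xr²), outlier exclusion at
  |standardized residual| > 2.5, backward elimination (Xr² > 0.6),
  per-position Δk_cat/K_m contribution profiles, and additive
  subsequence scoring.
* **Kinetics estimation** — under [S] ≪ K_m, v = (k_cat/K_m)·[E]·[S];
  initial velocities come from isobaric-reporter intensities
  (full-length decay or fragment appearance against reference/standard
  channels) and k_cat/K_m = 1/(b·[E]ₜ) from the Lineweaver–Burk slope
  b of 1/v₀ on 1/[S]₀, with an optional exact first-order depletion
  correction and an Eadie–Hofstee comparison estimator.
* **Specificity statistics** — background-standardized log-ratio
  frequency profiles (sequence-logo input), profile correlations with
  the t-test for a correlation coefficient, one- and two-proportion
  Z-tests, binomial absence probabilities, Welch t-tests, paired
  enzyme–enzyme k_cat/K_m correlation, and cleavage-position bias
  against the uniform 1/(L−1) null.
* **I/O and synthetic data** — TSV site/intensity tables, AAindex1 flat
  files, FASTA, decoy-database construction (4-mer-block-filtered
  C-terminal proteome tails), control-peptide scrambling, and a seeded
  synthetic library generator so everything is testable offline.

## Worked example

Generate a synthetic 89-peptide library whose cleavability is driven by
P2 hydrophobicity, fit the classifier, and estimate an efficiency from
simulated digestion intensities:

```python
import numpy as np
from calpcleave import (DescriptorTable, SyntheticConfig, featurize,
                        fit_binary, generate_synthetic_library,
                        loo_accuracy, predict_probability)
from calpcleave.kinetics import (ChannelDesign, estimate_kcat_km,
                                 simulate_digestion)

hydro = DescriptorTable(id="HYDRO", values={
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2})

cfg = SyntheticConfig(n_peptides=89, seed=0,
                      planted_features=[(("P2",), "HYDRO")],
                      planted_coefficients=[60.0],
                      planted_intercept=150.0, noise_cv=0.3,
                      cleavage_threshold=150.0)
lib = generate_synthetic_library(cfg, {"HYDRO": hydro})
fm = featurize(lib["windows"], [hydro], ["P2", "P1"],
               labels=lib["labels"])
model = fit_binary(fm, tables={"HYDRO": hydro})

print(f"windows: {len(lib['windows'])}, cleaved: {int(lib['labels'].sum())}")
print(f"LOO accuracy (XA): {loo_accuracy(fm):.3f}")
w = lib["windows"][0]
print("window", w.id, "P2 =", w.residues["P2"],
      "P(cleaved) =", round(predict_probability(model, w), 3))

design = ChannelDesign()   # 6 enzyme channels, [E]t = 2.5 uM, 900 s
rec = simulate_digestion(200.0, design, noise_cv=0.1, seed=1)
est = estimate_kcat_km(rec, design, method="auto", correct_depletion=True)
print(f"kcat/Km = {est.value:.1f} +/- {est.standard_error:.1f} "
      f"M^-1 s^-1 ({est.n_points} points)")
```

Output:

```
windows: 801, cleaved: 353
LOO accuracy (XA): 0.933
window SYN0001@6 P2 = S P(cleaved) = 0.28
kcat/Km = 220.4 +/- 12.4 M^-1 s^-1 (6 points)
```

The 89 20-mers yield 801 windows complete over P6–P6′ (9 per 20-mer);
the classifier cross-validates at XA ≈ 0.93 because the planted rule is
one clean hydrophobicity feature. The first window has serine at P2
(mildly hydrophilic), hence a low cleavage probability. The simulated
digestion at a true k_cat/K_m of 200 M⁻¹s⁻¹ with 10% reporter noise is
recovered at 220 ± 12 M⁻¹s⁻¹ from the six-channel dilution series.

A CLI mirrors the library for shell use — `calpcleave simulate`,
`featurize`, `fit-binary`, `fit-pls`, `predict`, `scan`, `kinetics`,
`stats`, `decoydb`; see `calpcleave --help` and `docs/formats.md` for
the file schemas.

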