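# bilemix

Physicochemical analysis of bile-salt micellization, solubilization and
in-vitro lipolysis.

Bile salts (BS) are the rigid, planar steroid surfactants that emulsify
dietary fat and carry lipolysis products out of the intestinal lumen. Gut
bacteria carrying bile salt hydrolase deconjugate them — cleaving the
glycine/taurine residue — and that single chemical change shifts every
surface property that feeds into the rate of fat digestion: the critical
micelle concentration (CMC), the mixing behaviour of BS pairs, the
aggregation number, and the molar solubilization ratio (MSR). `bilemix`
provides the statistical and physicochemical toolchain for studying those
links from literature-collated tables and bench titrations: it is aimed at
colloid and digestion scientists who need reproducible, scriptable versions
of the calculations that usually live in spreadsheets.

## What it computes

**Mixed-micelle regular-solution theory** (`bilemix.micelle_rst`). For a
binary mixture with bulk mole fraction α of component 1, measured mixed CMC
C₁₂ and pure CMCs C₁, C₂, the micellar mole fraction x₁ solves

```
x₁² ln(αC₁₂ / x₁C₁) = (1−x₁)² ln((1−α)C₁₂ / (1−x₁)C₂)
```

and the interaction parameter is β = ln(αC₁₂ / x₁C₁) / (1−x₁)², with
activity coefficients f₁ = exp(β(1−x₁)²), f₂ = exp(βx₁²). β < 0 means
synergism (mixed CMC below the ideal Clint value 1/C₁₂ = α/C₁ + (1−α)/C₂),
β > 0 antagonism. A forward model predicts C₁₂ from β, which both powers
the synthetic generator and disambiguates the multi-rooted strong-antagonism
regime.

**Conductometric CMC detection** (`bilemix.cmc_phillips`). The Phillips
criterion locates the CMC at the extremum of d²κ/dC² (equivalently the zero
of the third derivative) of a conductivity titration, computed by moving
local-polynomial regression; a classical two-line segmented fit provides an
independent cross-check, and the post/pre-CMC slope ratio estimates the
micellar degree of counter-ion ionization.

**Molar solubilization ratio** (`bilemix.solubilization`). MSR is the OLS
slope of dissolved solubilizate vs surfactant concentration above the CMC;
Pearson correlation (with t-transform p-value) links MSR to solubilizate
descriptors such as logK_ow and molecular volume.

**PLS/VIP meta-regression** (`bilemix.meta_pls`). Grouped summaries,
full one-hot encoding of the four BS classes (primary/secondary ×
conjugated/unconjugated; mixture systems set two indicators), NIPALS
partial-least-squares regression on autoscaled data, Variable Importance in
Projection scores (ΣVIP² = p), and one-tailed Welch t-tests.

**pH-stat lipolysis** (`bilemix.lipolysis`). Cumulative NaOH titration
volumes convert to %FFA via the sn-1,3 stoichiometry
%FFA = 100 · V·c_NaOH·M_lipid / (2·m_lipid); release curves are summarised
by Φ(t) = Φ_max(1 − e^(−kt)) and conditions compared at a common time
point.

**Synthetic data** (`bilemix.synthetic`). Seeded generators emulate every
input class with planted ground truth, so each estimator ships with
parameter-recovery tests and no external data are needed.

## Worked example

```python
from bilemix import (gen_mixture_cmc_dataset, analyze_mixtures, clint_cmc,
                     gen_conductivity, phillips_cmc, segmented_cmc)

# binary BS mixtures with a planted antagonistic interaction (beta = +1.3)
ds = gen_mixture_cmc_dataset(c1=13.0, c2=6.0, beta=1.3, pair_label="PU:PC")
print(analyze_mixtures(ds.data))
print(clint_cmc(0.2, 13.0, 6.0))

# conductivity titration with the CMC planted at 4.16 mM, 0.5% noise
curve = gen_conductivity(cmc=4.16, noise=0.005, seed=0)
print(phillips_cmc(curve).cmc, segmented_cmc(curve).cmc)
```

prints (abridged):

```
pair_label  alpha  cmc_mix_mM   beta     x1        label
     PU:PC 0.2000      7.2618 1.3000 0.0331 antagonistic
     PU:PC 0.4000      9.1371 1.3000 0.0975 antagonistic
     PU:PC 0.6000     11.9429 1.3000 0.2820 antagonistic
     PU:PC 0.8000     13.7125 1.3000 0.8019 antagonistic
6.7241
4.091  4.170
```

Reading: an unconjugated/conjugated pair with pure CMCs 13 and 6 mM and
β = +1.3 mixes antagonistically — every measured mixed CMC (7.26 mM at
α = 0.2, …) sits above the ideal Clint prediction (6.72 mM), and the
micelle is enriched in the lower-CMC component (x₁ ≪ α). The Phillips and
segmented estimates bracket the planted 4.16 mM breakpoint to within about
2% despite 0.5% conductivity noise.

A `bilemix` console script exposes the same stages
(`simulate`, `cmc-detect`, `beta`, `msr`, `meta-pls`, `lipolysis`,
`pipeline --config config.yaml`).

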