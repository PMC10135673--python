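# traitseg

Trait-based biomonitoring of stream macroinvertebrate communities: from
taxon counts to functional trait abundances, trait-diversity profiles,
trait–environment response curves, and ecological tipping points along
gradients of flow velocity (m/s), turbidity (NTU) and elevation (m a.s.l.).

It is written for freshwater ecologists and biomonitoring practitioners who
have (1) site-by-taxon count tables from a field survey, (2) a fuzzy-coded
trait affinity table linking each taxon to traits within grouping features
(feeding style, respiration mode, locomotion mode, reproduction mode, body
size), and (3) per-site environmental measurements — and who want
quantitative, threshold-aware trait–environment relationships rather than
taxonomic indices alone.

## What it computes

**Fuzzy-coded trait allocation.** Each taxon carries integer affinity
scores 0–5 per trait within a grouping feature. Scores are normalised to
coefficients `c_t = a_t / Σ a_t`; a taxon counted `n` times contributes
`round(n · c_t)` individuals to trait `t` (ties round away from zero), and
contributions are summed over taxa per site. Taxa without fuzzy coding for
a feature split their count equally over the traits they possess.

**Functional diversity.** Per site, from trait proportions `p_i`:
Shannon–Weaver `H = −Σ p_i ln p_i`, Simpson `D₁ = 1 − Σ p_i²`, inverse
Simpson `D₂ = 1/Σ p_i²`, trait richness `S`, and Pielou evenness
`J = H / ln S`.

**Response curves.** Trait counts are modelled with negative-binomial
GLMs (log link, variance `µ + µ²/k`); diversity metrics with Gaussian
linear models. Predictors are centred; backward elimination picks
quadratic, linear or intercept-only forms via likelihood-ratio tests at
α = 0.05.

**Tipping points.** A segmented (broken-line) model

```
y = α + β₁x                      x < ψ
y = (α − β₂ψ) + (β₁ + β₂)x       x > ψ
```

is estimated by iterative linearisation (hinge term `(x − ψ)⁺` plus its
indicator correction, with a profile-likelihood polish), with the delta-method
standard error for ψ. Breakpoint *existence* is tested by maximising a
statistic over candidate breakpoints with a Davies-bound p-value: a Wald t
statistic for Gaussian responses (Davies test) and a Rao score statistic
for count responses (score test). Among multi-start segmented fits, the
converged estimate closest to the test's best candidate is reported.

A synthetic-survey module generates 80-site communities with known
coefficients, dispersion and breakpoints, so every stage is verifiable
without field data.

## Worked example

```python
import pandas as pd
from traitseg import TraitAffinityTable, build_trait_abundance_matrix

cols = pd.MultiIndex.from_tuples(
    [("feeding_style", "deposit_feeder"), ("feeding_style", "scraper")],
    names=["feature", "trait"])
affinity = TraitAffinityTable(scores=pd.DataFrame(
    [[1, 3]], index=pd.Index(["Baetidae"], name="taxon"), columns=cols))
taxa = pd.DataFrame({"site_id": ["US17"], "taxon": ["Baetidae"], "count": [8]})
print(affinity.coefficients("Baetidae", "feeding_style"))
print(build_trait_abundance_matrix(taxa, affinity).data)
```

prints

```
[0.25 0.75]
feature  feeding_style
trait   deposit_feeder scraper
site_id
US17                 2       6
```

i.e. affinities 1 and 3 become coefficients 0.25 and 0.75, and the 8
counted mayflies are allocated as 2 deposit-feeder and 6 scraper
individuals.

Running the tipping-point stage on the bundled synthetic survey
(`python examples/04_tipping_points.py`) prints

```
score test: statistic -3.66, p = 2.21e-03, best candidate 4.77 NTU
tipping point psi = 5.03 +/- 0.43 NTU (truth: 5.0)
left slope 0.425, slope change -0.759 (right slope -0.334) on the log-mean scale
significant at 5%: True
```

— the planted 5 NTU turbidity breakpoint in the piercer trait is detected
and located within one standard error.

The `examples/` directory holds one short script per capability
(allocation, diversity, response curves, tipping points, full pipeline);
each builds or simulates a small input, runs the method, and explains the
numbers it prints. A thin CLI mirrors the stages:
`traitseg simulate | allocate | diversity | curves | tipping | run-all`.

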