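# pulsentropy

Multiscale entropy analysis of wrist-pulse recordings: does the complexity
of the radial-artery pressure pulse differ between two groups of subjects?

Single-channel pressure-pulse recordings (10 s at 200 Hz is the typical
acquisition) are cleaned, their irregularity is quantified with four
complementary entropy measures across time scales, and the per-scale values
are compared between groups (e.g. male vs female, recorded separately for
each hand) with standard two-sample statistics. The package is aimed at
researchers in physiological signal analysis and computational pulse
diagnosis who need a tested, reproducible version of this pipeline, plus a
synthetic pulse-cohort generator for validating it end to end.

## The measures

For a series `x(1..N)`, embedding dimension `m = 3`, tolerance
`r = 0.15·SD(x)`:

- **Sample entropy (SaEn)** — `-ln(A/B)` where `B` counts template pairs of
  length `m` within Chebyshev distance `r` (self-matches excluded) and `A`
  counts the same pairs still matching at length `m+1`. Undefined when no
  pairs match.
- **Fuzzy entropy (FuEn)** — the same ratio with each crisp match replaced
  by the graded membership `exp(-(d/r)^n)`, `n = 2`; continuous in `r` and
  always finite.
- **Permutation entropy (PeEn)** — Shannon entropy of the ordinal-pattern
  distribution of length-`m` windows, normalized by `ln(m!)` to `[0, 1]`.
- **Dispersion entropy (DiEn)** — Shannon entropy of patterns of amplitude
  classes obtained by mapping samples through the normal CDF into `c = 6`
  classes, normalized by `ln(c^m)`.

**Refined composite multiscale versions** (RC_MSE, RC_MFE, RC_MPE, RC_MDE):
at scale `τ` there are `τ` offset coarse-grained series (non-overlapping
window means of width `τ`). The refined composite estimate pools the
template-match counts — or averages the pattern distributions — over all
`τ` offset series before taking the entropy, which greatly reduces
undefined or unstable estimates on short records. The tolerance `r` (and
the dispersion class mapping) is frozen at the full-resolution series'
moments across all scales.

## Worked example

```python
import numpy as np
from pulsentropy import (SyntheticCohortSpec, generate_cohort, run_study,
                         significant_fraction, Measure, Hand)

spec = SyntheticCohortSpec(n_per_group=30, duration_s=10.0, effect=0.0, seed=1)
manifest, records = generate_cohort(spec)
result = run_study(manifest, records, tau_max=10, out_dir="results/")

rows = result.tables[(Measure.RC_MFE, Hand.LEFT)]
for r in rows[:3]:
    print(f"tau={r.tau}  male {r.male_mean:.4f}±{r.male_sd:.4f}  "
          f"female {r.female_mean:.4f}±{r.female_sd:.4f}  p={r.p_value:.4f}")
print("fraction of significant cells:", round(significant_fraction(result), 3))
```

Output:

```
tau=1  male 0.2605±0.0135  female 0.2657±0.0168  p=0.1911
tau=2  male 0.3732±0.0317  female 0.3847±0.0304  p=0.1550
tau=3  male 0.4097±0.0585  female 0.4294±0.0514  p=0.1696
fraction of significant cells: 0.0
```

Each row is one time scale of the refined composite multiscale fuzzy
entropy: group means ± SD of the per-subject entropy values and the
pooled-variance two-sample t-test p-value. Here the two groups were
generated with identical parameters (`effect=0`), and accordingly no
(measure, scale) cell reaches p < 0.05 — the expected null outcome. The
written CSV tables (one per measure and hand) mirror this layout and add a
Holm-corrected column.

The same pipeline is scriptable from the shell:

```bash
pulsentropy simulate --n-per-group 30 --effect 0 --seed 1 --out-dir data/
pulsentropy compare --manifest data/manifest.csv --out-dir results/
```

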