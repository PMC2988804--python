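# cellascribe

Ascribe differential gene expression in **bulk tumor** samples to
**tumor-epithelial** or **stromal** cells, using nothing more than the
histopathological area fractions that routinely accompany tissue sections.

Bulk expression profiles mix mRNA from every tissue component in the
specimen — carcinoma cells, tumor stroma, entrapped adipocytes. When two
outcome groups (say, patients who later developed distant metastasis, *DM*,
versus those who did not, *NoDM*) are compared probe by probe, a
differentially expressed gene-probe (DEG) may reflect a change in the
carcinoma cells, in the stroma, or in both. `cellascribe` implements an
*in silico* ascription strategy for this question: weight each sample's
contribution to the two-sample statistic by its cell-type area fractions,
repeat the analysis under a grid of assumptions about per-compartment
transcription efficiency, and categorize genes by which focus finds them
consistently.

## The statistic

For each gene, the weighted group mean is `m = Σᵢ wᵢ xᵢ / Σᵢ wᵢ` with
per-sample weights `w`. With normalized weights `ŵ = w/Σw`, the effective
sample size is `n_eff = 1/Σŵ²` (Kish), the weighted variance is
`Σŵ(x−m)² / (1−Σŵ²)`, and the two groups are compared with the pooled
statistic

    T = (m₁ − m₂) / √( s_p² (1/n₁ + 1/n₂) ),
    s_p² = ((n₁−1)v₁ + (n₂−1)v₂) / (n₁ + n₂ − 2),

which reduces *exactly* to the classical equal-variance two-sample t when
all weights are 1 (the un-weighted analysis, *UWA*). Significance comes
from a label-permutation test (weights stay attached to samples) with
Benjamini–Hochberg control of the FDR at 5%.

The weights derive from the section area percentages of tumor epithelium
(*t*), stroma (*s*) and adipocytes (*a*), averaged over two sections per
sample, under two assumption parameters:

* adipocyte efficiency `c ∈ [0,1]`:  `t′ = t/(t+s+ac)`, `s′ = s/(t+s+ac)`;
* stroma efficiency `d ∈ (0,1]` (applied at `c = 0`):
  `t″ = t′/(t′+s′d)`, `s″ = (t′+s′) − t″`.

A *tumor-focused analysis* (TFA) uses `t″` as each sample's weight, a
*stroma-focused analysis* (SFA) uses `s″`. Running both foci over
`d ∈ {0.2, 0.4, 0.6, 0.8, 1}` yields five DEG lists per focus; their
direction-concordant intersections are the consensus lists **TACsev** and
**SACsev**, and every DEG is categorized:

| category | rule |
|---|---|
| `tumor_ascribed` | in TACsev, in *no* stroma-focused list at any *d* |
| `tumor_associated` | in TACsev, not in SACsev, in ≥1 stroma-focused list |
| `stroma_associated` | in SACsev but not in TACsev |
| `shared_robust` | in both consensus lists |

The package also ships the surrounding machinery: raw-signal preprocessing
(flag/S-N filtering, missingness filtering, missing-aware quantile
normalization, KNN imputation, per-array rescale + log2), cohort
statistics (chi-square/Fisher contingency tests, two-sample
Kolmogorov–Smirnov on fraction distributions, paired weight comparison
across histopathology procedures, extreme-group marker tests, per-gene
fraction correlations, cross-platform probe matching by gene symbol), and
a synthetic-cohort generator with known compartment-level ground truth.

## Worked example

```python
import cellascribe as ca

cfg = ca.SimulationConfig(n_dm=40, n_nodm=40, n_genes=1000,
                          n_de_tumor=30, n_de_stroma=30, n_de_shared=20, seed=7)
matrix, annotations, truth = ca.generate_cohort(cfg)

model = ca.WeightedDifferentialExpression(matrix, annotations, focus="tumor")
print(model.fit(B=999, seed=1).summary(top=5))
```

```
Weighted differential expression (DM vs NoDM)
==============================================
focus: tumor   c=0   d=1
samples: 40 DM / 40 NoDM   probes: 1000
permutations: 999   FDR level: 0.05
significant probes: 57

top 5 probes by |T|:
probe_id  mean_DM  mean_NoDM      T     p       q  direction
   G0077     5.63      7.786 -9.733 0.001 0.01818 up_in_NoDM
   G0075     9.16       7.01  9.724 0.001 0.01818   up_in_DM
   G0066     10.8      8.505  8.976 0.001 0.01818   up_in_DM
   G0063    5.538      7.729  -8.82 0.001 0.01818 up_in_NoDM
   G0013    8.559      6.675  8.816 0.001 0.01818   up_in_DM
```

57 probes pass the 5% FDR in this tumor-focused analysis; each row shows
the weighted group means (log2), the weighted statistic, its permutation
p-value (floor 1/(B+1) = 0.001) and BH q-value, and the direction of the
difference. The full ascription grid then intersects such lists across
the `d` assumptions:

```python
results = ca.AscriptionAnalysis(matrix, annotations).fit(B=999, seed=2)
print(results.summary())          # per-cell list sizes, consensus sizes,
                                  # category counts, overlap with the UWA
ev = ca.truth_evaluation(results.report, truth)
```

On this cohort the grid finds a TACsev of 60 and SACsev of 51 probes, of
which 50 are `shared_robust` — planted effects of 2 log2 units are strong
enough that both foci detect most of them, exactly the behavior expected
of the method on extreme effect sizes (see `docs/methods.md`).

The same steps are available from a shell via the `cellascribe` console
script (`simulate`, `preprocess`, `weights`, `test`, `ascribe`, `table`).

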