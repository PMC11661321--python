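# tgvis

Multivariable TWAS fine-mapping of **causal gene–tissue pairs**, **direct
causal variants**, and **infinitesimal (polygenic) effects** from GWAS and
xQTL summary statistics at a single locus.

A genome-wide significant locus typically harbors dozens of genes, each
with expression or splicing measured in many tissues, plus thousands of
variants — hundreds of highly correlated candidate causes for one
association signal.  Standard TWAS tests each candidate marginally and is
confounded by shared xQTLs and local polygenicity.  `tgvis` is for
statistical geneticists who want to jointly fine-map *which gene, in which
tissue, and which variants* drive a GWAS signal, while modeling the
polygenic background that otherwise inflates false discoveries.

## Model

With GWAS z-scores $\hat a$ over $M$ locus variants, LD matrix $R$, and a
sparse matrix $\hat B$ of fine-mapped cis-effects for $J\times T$
gene–tissue pairs,

$$\hat a \sim \mathcal N\big(R(\hat B\theta + \gamma + \upsilon),\
\sigma_\alpha^2 R\big),\qquad \upsilon \sim \mathcal N(0,
\sigma_\upsilon^2 I).$$

Estimation alternates sum-of-single-effects (SuSiE) selection of the
sparse pair effects $\theta$ and direct variant effects $\gamma$ with a
penalized-quasi-likelihood/REML update of the infinitesimal BLUPs
$\upsilon$; the number of single effects is chosen by a summary-data BIC,
and a variance-component score test decides once whether the infinitesimal
component is used at all.  Results are reported as 95% credible sets with
posterior inclusion probabilities and **Pratt indices** ($V = \beta \times
\mathrm{cor}(X, y)$, additive shares of local $R^2$); sets with cumulative
CS-Pratt > 0.15 are prioritized as causal.  cTWAS-style (no infinitesimal
component) and TGFM-style (posterior-resampling) baselines, and a
benchmark simulator, are included.  See `docs/methods.md` for the full
account.

## Worked example

Simulate a locus in the "both" scenario (two causal pairs with effects
+1/−1, two direct causal variants, infinitesimal background) and fit it:

```python
import numpy as np
from tgvis import SimConfig, simulate_locus, fit_tgvis

locus, truth = simulate_locus(SimConfig(scenario="both", seed=19))
fit = fit_tgvis(locus)

print("L selected:", fit.L_selected)
print("infinitesimal active:", fit.infinitesimal_active,
      " p =", f"{fit.score_test.p_value:.2e}")
for i, cs in enumerate(fit.credible_sets):
    names = [fit.stacked_index(m) for m in cs.members]
    print(f"set {i}: members {names}  CS-Pratt {fit.cs_pratt[i]:.3f}")
print("pairs called:", sorted(fit.called_pairs()),
      "| true causal:", [0, 99])
print("variants called:", sorted(fit.called_variants()),
      "| true direct:", [int(v) for v in truth.gamma.nonzero()[0]])
print("cor(upsilon_hat, upsilon):",
      round(float(np.corrcoef(fit.upsilon, truth.upsilon)[0, 1]), 3))
```

Output (stacked member indices: pairs are < 100, variant v appears as
100 + v):

```
L selected: 8
infinitesimal active: True  p = 3.92e-41
set 0: members [483]  CS-Pratt 0.121
set 1: members [99]  CS-Pratt 0.114
set 2: members [198]  CS-Pratt 0.131
set 3: members [3]  CS-Pratt 0.063
pairs called: [3, 99] | true causal: [0, 99]
variants called: [98, 383] | true direct: [98, 383]
cor(upsilon_hat, upsilon): 0.64
```

Reading it: both true direct causal variants (98 and 383, stacked members
198 and 483) and causal pair 99 are each isolated in their own credible
set.  Gene 1's signal landed on a sibling tissue (pair 3 instead of pair
0) — tissues sharing cis-xQTLs are statistically near-indistinguishable,
which is exactly why inference is set-based; notably that set carries the
lowest CS-Pratt (0.063).  The score test firmly rejects
$\sigma_\upsilon^2 = 0$ and the estimated polygenic background correlates
0.64 with the generating one instead of being forced into spurious
variant calls.

The same pipeline runs from files:

```sh
tgvis simulate --out locus_dir --scenario both --seed 7
tgvis run --gwas locus_dir/gwas.tsv --xqtl-dir locus_dir/xqtl \
          --ld locus_dir/ld.tsv --out results/
tgvis benchmark --out bench/ --methods tgvis,ctwas,tgfm --n-reps 20
```

`run` writes `credible_sets.tsv` (members, PIPs, estimates, per-variable
Pratt, CS-Pratt, purity), `direct_variants.tsv`, `infinitesimal.tsv`
(per-variant BLUPs) and `run_info.tsv`.

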