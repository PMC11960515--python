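# enrange

Analysis toolkit for asking whether genes controlled by **distal enhancers
are more sensitive to perturbation of transcription machinery** than genes
controlled by proximal enhancers.

Enhancer–promoter (E-P) links predicted by an activity-by-contact-style
model (ENCODE-rE2G) score every candidate element–gene pair in [0, 1].
`enrange` turns such a link table into distance-based gene classes, joins
them with differential-expression (DE) readouts after factor depletion,
and quantifies which classes respond. It also scores dual-gate (FACS
high/low) CRISPRi reporter screens and normalizes 4C-seq contact
profiles, and ships a seeded synthetic-data generator that plants known
structure so the whole pipeline is verifiable end to end without any
external downloads.

## The model

Expressed genes (DESeq2 `baseMean ≥ 50` by default) are classified from
their E2G links with score cutoffs τ_low = 0.3, τ_high = 0.8:

| category | rule |
|---|---|
| `no_enhancer` | no link > 2 kb with score ≥ τ_low |
| `short` | ≥ 1 link at 2–10 kb with score ≥ τ_high, and no link > 10 kb with score ≥ τ_low |
| `mid` | ≥ 1 link at 10–40 kb with score ≥ τ_high, and no link > 40 kb with score ≥ τ_low |
| `long` | ≥ 1 link at 50–500 kb with score ≥ τ_high |
| `ambiguous` | anything else |

Each enhancer class carries a *representative* link (maximal score within
its window). A gene is *inside CCD* when a qualifying link has both its
element and the TSS inside one CTCF contact domain.

Class responses are compared with the one-sided two-sample
Kolmogorov–Smirnov statistic

D = sup_t [F_class(t) − F_reference(t)],  p ≈ exp(−2 D² n₁n₂/(n₁+n₂)),

where F are empirical CDFs of log₂ fold changes (positive D ⇔ the class
is shifted toward downregulation), and with two-sided Wilcoxon rank-sum
tests (exact for small untied samples). Screen scores are
β_low − β_high per target, normalized to the reporter-promoter anchor
guide; distance specificity is Δ = score(E0) − mean(distal scores).
4C profiles are rescaled so non-blind fragment counts, excluding the two
highest, sum to 10⁶, then smoothed with a centered 21-fragment running
mean.

## Worked example

```sh
enrange demo --seed 3 --out demo/
```

simulates a cohort at the published scale (2,790 promoter-autonomous,
285 short-, 209 mid-, 474 long-range genes) with cohesin-like planted
effects (long-range genes downregulated, short-range slightly up),
classifies it, compares classes, and scores a synthetic screen. Output:

```
wrote synthetic cohesin inputs for 3758 genes to demo/sim
classified 3758 genes: {'no_enhancer': 2790, 'long': 474, 'short': 285, 'mid': 209}
perturbation group_a     group_b statistic_kind  statistic      p_value  n_a  n_b
          de    long no_enhancer   ks_one_sided   0.218053 1.849940e-17  474 2790
          de    long       short   ks_one_sided   0.411970 5.784370e-27  474  285
ranked 3825 targets; 24 selected
demo complete
```

The KS D ≈ 0.22 against no-enhancer genes (p ≈ 10⁻¹⁷) says long-range
genes are strongly overrepresented among downregulated genes, and the
even larger D against short-range genes reflects the planted opposite
(positive) short-range response. The screen table ranks targets by
Δ = score(E0) − avg(distal); `selected` marks factors with a normalized
score ≤ −0.1 in ≥ 1 distal line.

Library use mirrors the CLI:

```python
from enrange.synthdata import SimConfig, gen_links, gen_de
from enrange.classify import classify_table
from enrange.sensitivity import compare_categories

cfg = SimConfig(seed=3)
links, truth, ccds = gen_links(cfg)
de = gen_de(links, truth, cfg, preset="cohesin")
classes = classify_table(links, de, min_base_mean=50)
comps, joined = compare_categories(classes, de, [("long", "no_enhancer")])
```

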