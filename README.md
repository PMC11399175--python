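# ibrtools

From raw microplate reads to a single stress score per exposure group.

`ibrtools` is a Python library for grouped multi-biomarker exposure
studies in aquatic ecotoxicology — the classic design where fish (or
another test organism) are held in a control tank and several dilution
tanks of a contaminant (here, metal-rich e-waste leachate), and a battery
of biochemical biomarkers is measured per animal: acetylcholinesterase
(AChE), metallothionein (MT), superoxide dismutase (SOD), catalase (CAT),
reduced glutathione (GSH), glutathione S-transferase (GST),
malondialdehyde (MDA), protein carbonyls (PC), and the cellular energy
allocation components (protein/glucose/lipid reserves and
electron-transport-system activity).

It covers the full computational path:

1. **Assay endpoint extraction** (`ibrtools.assay`) — kinetic microplate
   traces are reduced to ordinary-least-squares slopes (OD/min), endpoint
   reads kept as-is; procedural blanks are subtracted, triplicates
   averaged with a CV quality flag, and endpoints standardised to sample
   protein content.
2. **Cellular energy allocation** (`ibrtools.energy`) —
   `Ea = E_protein + E_glucose + E_lipid`, `CEA = Ea − Ec`.
3. **Group comparisons** (`ibrtools.stats`) — an assumption-driven
   decision tree: per-group Shapiro–Wilk normality with a
   square-root-then-natural-log transform cascade; Levene's test; then
   one-way ANOVA + Tukey HSD (assumptions met), Welch's ANOVA +
   Games–Howell (heteroscedastic), or Kruskal–Wallis + Dunn–Bonferroni
   (non-normal). Effect sizes: ω² = df₁(F−1)/(df₁(F−1)+N) for the
   F-family, ε² = H/(n−1) for the rank family; negative values (statistic
   below its null expectation) are reported as computed.
4. **IBRv2 scoring** (`ibrtools.ibr`) — per biomarker,
   Yᵢ = ln(Xᵢ / mean X_ref), Zᵢ = (Yᵢ − Ȳ)/s_Y pooled over all animals,
   deviation index A(g) = Z̄(g) − Z̄(ref), and per group
   **IBRv2 = Σ_biomarkers |A|**; radar-plot data and figures included.
5. **Synthetic studies** (`ibrtools.synthetic`) — reproducible lognormal
   (or normal) four-group dilution designs with configurable effect sizes
   and directions, synthetic plates, and a recovery report scoring the
   pipeline against known truth.
6. **Orchestration** (`ibrtools.pipeline`, `ibrtools.cli`) — one config →
   CSV bundle + markdown report, also exposed as the `ibrtools` command
   (`simulate`, `process-plates`, `all`, `leachate`, …).

## Worked example

```python
from ibrtools import compare_groups, compute_ibr, default_design, generate_study

table = generate_study(default_design(seed=42))   # 80 animals, 12 biomarkers
r = compare_groups(table, "AChE")
print(r.trail.branch, f"F({r.df1:.0f}, {r.df2:.0f}) = {r.statistic:.3g}",
      f"p = {r.p:.3g}", f"omega2 = {r.effect_size:.3f}")

scores = compute_ibr(table).scores
print(scores.round(2).to_dict())
```

prints

```
anova_tukey F(3, 76) = 15.4 p = 6.6e-08 omega2 = 0.350
{'A1': 0.0, 'A2': 4.21, 'A3': 6.11, 'A4': 10.67}
```

AChE differs strongly between groups (a large effect: exposure explains
~35% of the variance), and the IBRv2 stress score rises with leachate
dose; the control group's score is 0 by construction. The `examples/`
directory has one narrative script per capability (assay processing, IBR
scoring, the statistics engine, the full pipeline), each printing the
numbers it computes and a line on what they mean.

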