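# valveoptics

Label-free optical biomarker quantification for early calcific aortic valve
disease (CAVD), for researchers analyzing multiphoton and polarized-light
imaging of valve tissue sections alongside histology, echocardiography and
immunohistochemistry.

Early CAVD is marked by collagen remodeling and incipient mineralization at
the valve commissures before overt calcification appears. This package
implements the quantitative pipeline used to track that progression without
labels:

* **TPEF autofluorescence ratios.** Four two-photon channels A_ex/em
  (A_755/460, A_860/525, A_810/460, A_810/525) combine per pixel into

  - TPEF 755–860 ratio = A_860/525 / (A_755/460 + A_860/525)
  - TPEF Col–Cal ratio = A_810/525 / (A_810/460 + A_810/525)

  Both live in [0, 1]; the 755–860 ratio generalizes the optical redox ratio
  FAD/(FAD + NADH) to tissue where collagen, lipid and mineral also
  fluoresce, and falls with calcific progression.

* **QPLI collagen metrics.** A rotating polarizer with circular analyzer
  gives per-pixel intensity I(θ) = B·(1 + sin δ · sin 2(θ − φ)). A
  closed-form harmonic fit recovers retardation δ (∝ collagen thickness) and
  axial fiber orientation φ; the local directional variance
  V = 1 − |⟨e^{2iφ}⟩| ∈ [0, 1] measures fiber disorganization, and
  collagen-positive pixel density the collagen footprint.

* **Histology.** Picrosirius-red fiber-thickness composition by hue binning
  (thick/red, thick-intermediate/orange, thin-intermediate/yellow,
  thin/green) and Alizarin-red-S percent calcified area by constant-threshold
  particle analysis.

* **Echo formulas.** Teichholz volumes V(D) = 7.0·D³/(2.4 + D), EF and
  cardiac output from M-mode LV diameters; ordinal IHC score grading
  (0/1/2 rater scores → −/+/++/+++ by exact-rational mean cut points).

* **Statistics.** Normality-gated two-way ANOVA (Type-II) with Tukey HSD over
  diet × week cells, Kruskal–Wallis with Dunn-style rank contrasts as the
  non-parametric fallback, and Pearson/Spearman correlation with an automatic
  gate.

Everything is exercisable on a **synthetic valve-phantom generator**
(`valveoptics.phantom`) that produces all pipeline inputs with known ground
truth: linearly mixed fluorophore channels with shot-like noise, sinusoidal
polarizer stacks with known δ/φ, hue-structured PSR images, disk-shaped ARS
deposits of exact area fraction, and diet × week study tables with a tunable
pro-calcific effect.

## Worked example

```python
import valveoptics as vo

cfg = vo.PhantomConfig(image_size=(64, 64), effect_size=3.0, seed=7)
study = vo.generate_study(cfg, n_per_group=4, weeks=(4, 16))
report = vo.analyze_study(study)

m = report["metrics"]
sub = m[(m.metric == "ratio_755_860") & (m.region == "commissure")]
print(sub.groupby(["diet", "week"]).value.mean())
```

```
diet          week
control       4       0.485230
              16      0.483827
pro_calcific  4       0.485915
              16      0.460520
Name: value, dtype: float64
```

The commissure 755–860 ratio is stable in controls (~0.485) and depressed in
the pro-calcific group at week 16 (~0.461): the calcium-like source loads on
460-nm emission, pushing the denominator up as mineral accumulates. The same
report correlates that ratio against the generator's truth calcium burden
(commissures: r = −0.78, p = 0.0004 in this run) and

```python
print(vo.headline_signs(report))
# {'ratio_lower': True, 'contrast_significant': True,
#  'negative_correlation': True, 'ars_increases': True}
```

summarizes the qualitative structure: lower week-16 pro-calcific ratio with a
significant Tukey contrast, negative correlation with calcium burden, rising
ARS percent area.

From a shell, the same flow is:

```bash
valve-optics simulate --seed 7 --n-per-group 4 --weeks 4,16 --out study/
valve-optics run --in study/ --out report/
```

which writes `region_metrics.csv`, `comparisons.csv`, `correlations.csv`,
`echo_derived.csv`, `scores_graded.csv`, per-animal ratio/fiber maps and a
provenance log.

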