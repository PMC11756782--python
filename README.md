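# lamella

Plan-quality evaluation for linac-based stereotactic radiosurgery (SRS) of
brain metastases, built around the *equivalent isodose volume* family of
metrics and the *concentric lamellarity* view of dose conformity — with a
synthetic dose-phantom generator for controlled methodological experiments
and a paired nonparametric comparison stack for factor studies.

## Who this is for

Medical physicists and planning researchers who want to compare treatment
plans (or planning-system calculation settings, such as Monte-Carlo grid
spacing and statistical uncertainty) using near-minimum / near-maximum dose
metrics rather than classical conformity or gradient indices, and who need
the whole analysis — margins, DVHs, metric panel, statistics — reproducible
from code.

## The metrics

Let `V` be the gross tumor volume (GTV) in cc. The prescribed dose PD is
assigned to the GTV **D**<sub>V−0.01cc</sub> — the minimum dose covering the
GTV minus 0.01 cc (a 3 mm-diameter allowance), i.e. D<sub>&gt;95%</sub> for
V &gt; 0.20 cc, or to D<sub>95%</sub> for V ≤ 0.20 cc. The implied GTV
coverage is `100·(V − 0.01)/V` (e.g. 99.90% at V = 9.81 cc). Every plan is
first rescaled so this metric equals PD; the multiplicative factor is the
*rescaling ratio*.

On an evaluation region (GTV + 10–30 mm, default 20 mm):

* **IIV(d)** — irradiated isodose volume: total volume receiving ≥ d.
* **Spillage** at 100/75/50% of PD — volume outside the GTV at or above the
  threshold: conformity (100%) and dose-falloff steepness (75/50%).
* **D<sub>eIIV</sub>(S)** for a reference structure S — the minimum dose
  whose IIV equals S's volume. Equals PD exactly for a perfectly conformal
  plan; reported as % of PD.
* **Coverage of S by its D<sub>eIIV</sub>** — 100% iff the isodose surface
  wraps S concentrically ("concentric lamellarity"); evaluated for the GTV
  and its +2 / −2 / −4 mm shells (interior shells only for GTV ≥ 0.72 cc and
  ≥ 2.20 cc respectively).
* **Dose inhomogeneity** — D<sub>V−0.01cc</sub> as % of the near-maximum
  dose D<sub>0.01cc</sub>.

Group comparisons use Friedman's test, a Scheffé-type post hoc on rank sums
(with conditional Wilcoxon signed-rank re-tests for non-significant pairs
with p &lt; 0.9), the Jonckheere–Terpstra trend test over the ordered
calculation settings, and strict significance tiers 0.05/0.01/0.001.

## Worked example

```python
import lamella as lm

# ideal spherical plan: r = 10 mm target, concentric dose, no noise
ph = lm.generate_phantom(lm.PhantomSpec(shape="sphere", target_size=10.0))
pm = lm.evaluate_plan(ph.dose, ph.gtv, lm.EvalConfig(pd_gy=43.0))
print(pm.to_row())
```

prints (1 mm grid):

```
{'gtv_cc': 4.18, 'pd_gy': 43.0, 'coverage_pct': 99.76,
 'rescaling_ratio': 1.0, 'piv_spillage_cc': 0.0,
 'piv75_spillage_cc': 3.99, 'piv50_spillage_cc': 12.96,
 'inhomogeneity_pct': 81.7,
 'gtv_d_eiiv_pct': 100.0, 'gtv_coverage_pct': 100.0,
 'gtv_plus_2_d_eiiv_pct': 78.7, 'gtv_plus_2_coverage_pct': 99.3,
 'gtv_minus_2_d_eiiv_pct': 108.0, 'gtv_minus_2_coverage_pct': 99.1,
 'gtv_minus_4_d_eiiv_pct': 114.6, 'gtv_minus_4_coverage_pct': 99.3}
```

Read: the plan needs no rescaling (ratio 1.000); nothing outside the GTV
reaches PD (PIV spillage 0.00 cc); the GTV's D<sub>eIIV</sub> equals PD
(100.0% — perfect conformity); every shell is ~100% covered by its own
D<sub>eIIV</sub> (perfect lamellarity); dose 2 mm outside the target has
fallen to 78.7% of PD and 4 mm inside it has risen to 114.6%. Setting
`anisotropy=2.0` in the `PhantomSpec` deforms the dose cloud away from the target
and every lamellarity coverage drops into the 80s while the panel's other
values barely move — exactly the degradation these metrics exist to expose.

The factor experiment (paired cohort across calculation-setting groups
G2U3 … G1U1) runs from the shell:

```sh
lamella run --out results/ --seed 1 --subjects 12
```

writing `per_plan.csv` (one metric panel per lesion × setting),
`comparisons.csv` (Friedman / post hoc [conditional Wilcoxon] / trend per
metric), and `bwp_summary.json` (box-whisker summaries). `lamella phantom`,
`lamella evaluate` (NIfTI or DICOM RT Dose + RT Structure Set) and
`lamella compare` expose the individual stages.

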