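# cfes — CT histogram-based fat estimation and quasi-segmentation

`cfes` quantifies and segments adipose tissue in abdominal CT slices
from the grey-value histogram alone.  It is aimed at quantitative
imaging and forensic-modelling workflows (e.g. building body models for
temperature-based post-mortem interval estimation) where fat content
and localisation must be extracted fully automatically, without manual
contouring or a trained segmentation model.

## The model

The soft-tissue pixels of a slice are treated as independent draws from
a two-component Gaussian mixture over Hounsfield units,

```
f(g) = z · φ(g; E_F, S_F) + (1 − z) · φ(g; E_M, S_M),      E_F < E_M,
```

with fat (F) darker than muscle/organ tissue (M) and `z` the fat pixel
proportion — the primary quantification target (`Q_F = z·Q`).  The
parameter vector `Θ = (E_F, E_M, S_F, S_M, z)` is estimated by
minimising the weighted least-squares distance between the empirical
8-bit histogram `x_n(Y)` and the model-expected histogram `x_n(Θ)`,

```
S_α = Σ_{n∈G₀} (x_n(Y) − x_n(Θ))² · x_n(Y)^α ,
```

with weight exponent `α` (default 1).  A threshold `t_FM` minimising
the expected misclassified pixel count under the fitted mixture then
labels every body pixel fat or muscle ("quasi-segmentation").

Around the core the package provides:

* **quality measures** — the Welch-like separability
  `τ = √Q·(E_M−E_F)/√(S_F²/z + S_M²/(1−z))`, the per-slice verdict
  `d` with scan/sample rates `D`/`F`, and the fat-ratio error
  `RE_z = |z*−z⁺|/z⁺`;
* **a seeded phantom generator** — concentric-disk two-material slices
  with exact fat fraction and known ground truth;
* **Monte-Carlo experiment drivers** — the τ*–ln S_α "umbrella" sweep
  and boundary-line/regression analyses;
* **a delta-method sensitivity analysis** — analytic Jacobian,
  histogram covariance and sandwich covariance of `Θ*`, giving the
  z-estimator standard deviation `S(z*)` as a function of component
  overlap.

The fitting core is a scikit-learn-style estimator (`CFES`) with
`fit`/`predict` and fitted attributes (`theta_`, `z_`, `t_fm_`,
`ln_s_alpha_`, …).

## Worked example

Generate a 512×512 phantom (fat ratio 0.3, component SD 15 HU), fit it,
and inspect the fat quantification:

```
$ cfes simulate --z 0.3 --s 15 --size 512 --seed 7 --outdir demo --stem ph
wrote demo/ph.tif (Q=166740)

$ cfes fit --image demo/ph.tif --alpha 1
{
  "e_f": -80.08606906291931,
  "e_m": 49.96157535014492,
  "s_f": 15.00930627049069,
  "s_m": 14.96280543025731,
  "z": 0.3001544152277546,
  "s_alpha": 769367187.0091742,
  "ln_s_alpha": 20.461078899867417,
  "t_fm": 63,
  "q_f": 50047.747195075804,
  "q_m": 116692.2528049242
}
```

The fitted mixture recovers the generating parameters (means −80/+50 HU,
SDs 15 HU) and the fat ratio to 0.05 %: of the 166,740 body pixels,
`q_f ≈ 50,048` are attributed to fat.  `t_fm = 63` is the threshold
grey bin (−16 HU with the default binning): pixels in darker bins are
labelled fat by `cfes segment`.  With 1 mm² pixels and 0.625 mm slice
spacing this slice contributes `50048 · 1 · 0.625 ≈ 31,280 mm³` of fat
(`cfes.fat_volume`).

How reliably can `z` be estimated as the fat and muscle peaks merge?
The delta-method curve:

```
$ cfes sensitivity --s-grid 20:90:10
s_hu,z_std
20.0,0.0011612584306644328
...
60.0,0.012915274350880407
...
90.0,0.09158536740077183
```

`S(z*)` grows by two orders of magnitude between S = 20 HU and
S = 90 HU at a fixed peak distance of 130 HU — fat-ratio estimation
degrades exponentially with component overlap, which is the method's
principal constraint.

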