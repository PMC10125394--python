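# fixir

Label-free MID-IR fixation metrology as a tested Python pipeline.

Formalin fixation deforms the protein amide bands of a tissue's mid-infrared
absorbance spectrum. `fixir` simulates differential-fixation studies of such
spectra, preprocesses them (atmospheric correction, concave rubber-band
baseline removal, amplitude normalization, spatial averaging), extracts
Amide I derivative peak/FWHM and Amide A magnitude features, trains a NIPALS
partial-least-squares regression model that predicts fixation time of
held-out samples, maps fixation spatially over whole-organ spectral rasters,
and quantifies IHC percent positivity as an orthogonal validation signal.

No real spectra are bundled: the `synth` module generates studies with the
statistical structure the analysis assumes (saturating band deformation,
scattering baselines, atmospheric lines, diffusion-limited fixation
gradients, brightfield-like IHC tiles with ground-truth masks), so every
stage is testable offline.

## Package layout

| module | contents |
| --- | --- |
| `fixir.core` | wavenumber grid, spectrum, saturating band model, study config |
| `fixir.synth` | study / whole-organ-grid / IHC-image generators, positivity curves |
| `fixir.preprocess` | absorbance, atmospheric correction, rubber-band baseline, normalization, averaging |
| `fixir.features` | Savitzky-Golay derivative, Amide I peak/FWHM, Amide A magnitude |
| `fixir.plsr` | stratified holdout split, NIPALS PLS1, twofold-CV component selection, evaluation, coefficient spectrum |
| `fixir.spatial` | per-pixel metric maps, under-fixed region flagging, false-color rendering |
| `fixir.ihc` | tissue segmentation, DAB stain unmixing, percent positivity, hot-spot maps, rank-sum test |
| `fixir.pipeline` | end-to-end orchestration with manifests and reports |
| `fixir.io` | two-column CSV spectra, study and grid directory layouts |

## CLI

```sh
fixir simulate  --out study/ --seed 7                       # synthetic study (CSV spectra + JSON sidecars)
fixir preprocess --in study/ --out pre/ --baseline-points 64 --baseline-iters 9
fixir features  --in study/ --out features.csv
fixir train     --features study/ --holdout 0.25 --folds 2 --max-components 15 --seed 7 --model model.json
fixir predict   --model model.json --in study/ --out predictions.csv
fixir map       --in grid/ --metric amide1_deriv_peak --out maps/
fixir ihc       --in images/ --marker bcl2 --out positivity.csv
fixir run       --config run.toml                           # full pipeline
```

`fixir run` accepts a TOML/JSON config with `[study]`, `[preprocess]` and
`[model]` sections; all defaults mirror the study design (7 fixation times
x 15 tissues x 2 replicate slides, ~100 regions per slide, 64 baseline
points, 9 iterations, 25% stratified holdout, twofold CV).

## Notes

- The rubber-band baseline is a from-scratch implementation (interval
  minima, lower convex hull, iterated with accumulation); the vendor
  algorithm it stands in for is proprietary.
- The PLSR is hand-written NIPALS PLS1; tests check it against an
  independent SVD-based oracle, ordinary least squares at full rank, and
  scikit-learn.
- Generator band parameters are configurable defaults chosen to reproduce
  the qualitative deformation behavior (Amide I shifts up and broadens,
  amplitude drops, Amide A grows); they are not claims about real
  chemistry.
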