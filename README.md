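# cect — quantitative contrast-enhanced microCT analysis

`cect` is a Python package for the quantitative image analysis used in ex
vivo contrast-enhanced computed tomography (CECT) studies of soft tissue,
where a specimen (typically a murine brain hemisphere) is immersed in a
contrast-enhancing staining agent (CESA) and imaged by microCT as the
stain diffuses inward. It is aimed at researchers running CESA screening
or white-matter pathology studies who need reproducible, scriptable
versions of the measurements usually done interactively in commercial
tools.

## What it computes

**Staining kinetics.** The specimen is approximated as a sphere from its
measured entire and unstained volumes,

```
R_e = (3 V_e / 4π)^(1/3),   r_u = (3 V_u / 4π)^(1/3),   r_p = R_e − r_u,
```

and the penetration-front depth over time is fitted with the saturating
exponential `r_p(t) = R_e (1 − e^(−kt))` by bounded nonlinear least
squares, giving the asymptote `R_e` and rate `k` per staining agent.
Total-volume tracking quantifies staining-induced swelling or shrinkage.

**Contrast-to-noise ratio.** Between two regions (e.g. corpus callosum vs
cerebral cortex): `CNR = |μ₁ − μ₂| / ((σ₁ + σ₂)/2)`, with Otsu
binarization as the ease-of-segmentation readout.

**Gray-value normalization.** Dimensionless gray values anchored to
in-scene reference materials, `g = (G − G_E) / (G_B − G_E)` with `G_E`
the sample-tube gray and `G_B` the ceramic-bead gray; plus automatic
percentile histogram windowing for 16-bit → 8-bit export and
reference-matched rescaling across datasets.

**White-matter microstructure.** A DTI-like fractional anisotropy from
image-gradient structure tensors (Gaussian smoothing scales 0.5 / 0.5 / 5
voxels), fiber volume fraction at a fixed normalized threshold, cylinder-
correlation fiber-bundle detection with marker-based watershed labeling,
and inscribed-sphere (local) thickness per bundle.

**Phantoms.** Because microCT volumes of this kind are rarely shareable,
`cect.phantom` generates synthetic scenes — a stained half-ellipsoid
hemisphere with tube/bead/air references, and parallel-fiber phantoms
with controllable contrast polarity and demyelination — whose manifests
carry the exact ground truth for every metric. All tests validate the
pipeline against these.

## Worked example

Run the staining-kinetics study on a phantom time series (1, 2, 4, 9
days of staining, 128³ grid, 30 µm voxels):

```
$ cat kinetics.yaml
spec:
  seed: 42
times_days: [1, 2, 4, 9]

$ cect kinetics --config kinetics.yaml --out out/
decay fit: R_e = 1.035 mm, k = 0.536 /day
```

`out/kinetics_per_timepoint.csv` holds the per-time-point sphere
approximation:

```
t_days  v_entire_mm3  v_unstained_mm3  penetration_depth_mm
1.0     5.228         1.228            0.412
2.0     5.312         0.265            0.684
4.0     5.400         0.015            0.934
9.0     5.443         0.002            1.015
```

Reading: after one day the front has advanced 0.41 mm into a specimen of
sphere-equivalent radius ≈ 1.08 mm; by day 9 the specimen is essentially
fully stained (`r_p → R_e`). The fitted `(R_e, k)` = (1.035 mm,
0.536/day) recover the generative values (≈1.08 mm, 0.5/day) to within
5 %, and the reported relative volume change (+4.1 % at day 9 vs day 1)
reflects the phantom's built-in staining-coupled swelling. The same verb
works on real slice stacks via the library API (`cect.volume.read_volume`
plus the functions in `cect.kinetics`).

Other verbs: `cect phantom` (write a synthetic scene as a 16-bit TIFF
stack), `cect contrast` (CNR comparison across agents), `cect cuprizone`
(paired healthy/demyelinated white-matter comparison).

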