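# collafiber

Automated quantification of collagen fiber morphology in second-harmonic
generation (SHG) microscopy images, with a two-group statistical
comparison. Written for tissue-optics and tumor-microenvironment work
where the question is whether the collagen architecture around a lesion
— e.g. a gastrointestinal stromal tumor versus the normal muscularis it
arose from — differs in measurable, reproducible ways.

The pipeline: vesselness (multiscale Hessian) ridge enhancement →
Gaussian-mixture segmentation → mask refinement (closing, hole filling,
removal of segments < 5 px) → skeleton-graph fiber tracing with
collinearity-based branch pairing → eight collagen morphometrics →
per-feature Student's t-test between groups.

## The measurements

For a quantification ROI (default 1500×1500 px) with pixel size known in
µm, `collafiber` reports, per sample:

| feature | definition | units |
|---|---|---|
| area | foreground fraction of the ROI | a.u. |
| density | fiber count / ROI area | per mm² |
| length | mean fiber arc length | µm |
| width | 2 × mean distance-transform radius along the centerline | µm |
| orientation | \|Σ exp(2iθ_f)\| / N over fiber chord angles | a.u. (0–1) |
| straightness | mean chord/arc ratio | a.u. (0–1] |
| cross-link space | mean along-fiber distance between consecutive cross-links | µm |
| cross-link density | cross-links per 100 µm of fiber | a.u. |

A cross-link is a vertex shared by two or more fibers' ordered vertex
sequences. Orientation uses doubled angles because fiber orientations are
axial (θ and θ+π are the same fiber). Undefined values (e.g. cross-link
space when no fiber carries two cross-links) are reported as missing and
excluded pairwise from group statistics.

## Worked example

No SHG images ship with the package; the built-in phantom generator
stands in (bright curvilinear fibers over a dim noisy background, with
vector ground truth). Simulate a two-group study and run it:

```bash
collafiber simulate --preset nm   --n 15 --seed 1 --out study/nm
collafiber simulate --preset gist --n 15 --seed 1 --out study/gist
# merge the two manifests, then:
python - <<'EOF'
import pandas as pd
m = pd.concat([pd.read_csv("study/nm/manifest.csv"),
               pd.read_csv("study/gist/manifest.csv")])
m.to_csv("study/manifest.csv", index=False)
EOF
collafiber run-study study/manifest.csv --pixel-size 0.5 --roi 512 512 --out study/out
```

The comparison table printed at the end (also written to
`study/out/comparison.csv`) looks like:

```
          feature  n1       mean1        sd1  n2      mean2      sd2          t   df            p  significant
             area  15    0.155292   0.015890  15   0.010802 0.001169  35.122262 28.0 1.062839e-24         True
          density  15 1459.757487 101.160571  15 119.018555 8.554259  51.148320 28.0 3.348474e-29         True
           length  15   48.096885   2.326420  15  33.460035 5.311888   9.775529 28.0 1.584927e-10         True
            width  15    2.114407   0.120926  15   2.663506 0.112804 -12.859794 28.0 2.861935e-13         True
      orientation  15    0.853246   0.039634  15   0.362078 0.186583   9.972849 28.0 1.021984e-10         True
     straightness  15    0.980241   0.005415  15   0.964879 0.013691   4.041126 28.0 3.762978e-04         True
  crosslink_space  15   35.241129   7.585554   0        NaN      NaN        NaN  NaN          NaN        False
crosslink_density  15    0.688346   0.104552  15   0.147967 0.188439   9.711714 28.0 1.828552e-10         True
```

Reading it: the dense, aligned normal-muscularis-like phantoms ("nm",
group 1) carry ~14× the collagen area fraction, ~12× the fiber density
and ~5× the cross-link density of the sparse, disordered stroma-like
phantoms ("gist", group 2), and each difference is significant at
α = 0.05 by a pooled-variance Student's t-test (df = n1 + n2 − 2). The
cross-link *space* row has no test: no stroma-like sample had a fiber
carrying two cross-links, so that feature is missing for the whole group
and the row is emitted without test fields. On
real images the same command applies with the manifest pointing at your
TIFFs and `--pixel-size` set to your calibration; fiber area, density and
cross-link density are the features that this class of analysis flags as
discriminating tumor stroma from normal muscle.

Single images work too:

```bash
collafiber run-sample study/nm/nm_000.tif --pixel-size 0.5 --roi 512 512
```

which prints the eight-feature JSON for that sample.

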