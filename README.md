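# ctradial

Radial positioning analysis of chromosome territories (CTs) in FISH images.

Interphase chromosomes occupy discrete territories whose radial position in
the nucleus — interior, intermediate or peripheral — is a basic feature of
nuclear organisation and can change, for example after DNA damage.  The
standard readout is *shell-erosion analysis* of 2D-FISH images: each
DAPI-segmented nucleus is divided into `k` concentric shells (shell 1
innermost), the chromosome-paint signal and the DAPI signal are tabulated
per shell, and the probe signal in shell *x* is normalised by local DNA
content:

    n_x = (p_x / d_x) / (Σ p / Σ d)

where `p_x` is the percentage of total probe signal and `d_x` the
percentage of total DAPI signal in shell *x*.  A probe distributed like
bulk DNA gives `n_x = 1` in every shell; interior CTs peak in shell 1,
peripheral CTs in shell `k`.  `ctradial` implements this analysis for both
the classic **equal-area** scheme and the **equal-volume** scheme, in which
projected shell areas follow

    f_i = (i^(2/3) − (i−1)^(2/3)) / k^(2/3)

so that the concentric *spherical* shells of a sphere-modelled nucleus hold
equal volume (for k = 5: 34, 20, 17, 15 and 14 percent of the area,
innermost to outermost; a `paper_1` preset reproduces the historically used
integer proportions 34:20:17:16:13).  Equal-area shells concentrate 28.5%
of the spherical volume in the outermost shell, biasing profiles toward
the periphery — the equal-volume scheme removes that bias.

The package also covers the 3D-FISH side (geometric centres of nucleus and
CT masks in μm from anisotropic confocal stacks, CT-to-centre distance
distributions, pairwise distances between territory groups with quartile
box summaries, region volumes) and ships a synthetic FISH-image generator
(elliptical/ellipsoidal nuclei, Gaussian-blob territories with controllable
radial placement ρ, PSF blur, Poisson + Gaussian noise) so the entire
pipeline is testable without microscopy data.

Intended users: image-analysis and nuclear-organisation researchers who
need a scriptable, deterministic shell-erosion pipeline with explicit
geometry and statistics.

## Worked example

Simulate an interior-placed and a peripheral-placed population (25 nuclei
each), run the full 2D pipeline, and classify each condition:

```python
from ctradial import ConditionSpec, RunConfig, run_2d_pipeline

config = RunConfig(
    seed=6,
    conditions=[
        ConditionSpec("ctrl",    n=25, cts=[{"name": "A", "rho": "interior"}]),
        ConditionSpec("damaged", n=25, cts=[{"name": "A", "rho": "peripheral"}]),
    ],
)
report = run_2d_pipeline(config)
for label, info in report.summary["conditions"].items():
    print(label, info)
```

prints

```
ctrl {'n_nuclei': 25, 'm': 1.5298621280912454, 'category': 'interior'}
damaged {'n_nuclei': 25, 'm': 3.696537443395545, 'category': 'peripheral'}
```

`m` is the signal-weighted mean shell index `Σ i·n_i / Σ n_i` (1 =
innermost shell, 5 = outermost); a uniform profile gives m = 3, and the
default category cuts are m ≤ 2.6 → interior, m ≥ 3.4 → peripheral.  The
interior population (ρ drawn with mean 0.3) lands at m ≈ 1.5, the
peripheral one (mean ρ 0.8) at m ≈ 3.7.  `report.comparisons` holds
per-shell Welch t-tests between the conditions and `report.frequency` the
interior/intermediate/peripheral tally of per-nucleus calls with chi-square
homogeneity tests.  With `out_dir` set, every table is written as CSV along
with profile plots and a summary JSON.  The same templates are available
from the shell: `ctradial simulate | profile | dist3d | series`.

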