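# creasemap

Quantification of tissue shape and reporter expression at the boundaries of
the shoot apical meristem (SAM), from 3D confocal stacks.

When a plant meristem initiates a lateral organ, the tissue between the dome
and the young organ folds into a saddle-shaped crease. `creasemap` measures
that geometry and relates it to gene-reporter signal:

1. **Surface detection** — the outer tissue surface is found in the
   membrane-stained channel (e.g. FM4-64) by a level-set method: a first
   guess from intensity thresholding is evolved, as an implicit
   signed-distance field, until its zero level set settles on the crest of
   the bright membrane shell.
2. **Curvature mapping** — the zero level set is triangulated (marching
   cubes, anisotropy-aware) and per-vertex Gaussian curvature `K` (μm⁻²) is
   estimated by a local quadric fit over 15 μm geodesic neighbourhoods:
   `K = (4ac − b²)/(1 + d² + e²)²` from `z = ax² + bxy + cy² + dx + ey + f`
   in the tangent frame.  Domes give `K > 0`, boundary creases `K < 0`.
3. **Signal projection** — the nuclear reporter channel is blurred (Gaussian,
   10 μm) and sampled along the inward surface normal over a 10 μm depth,
   attaching a `projected_intensity` to every vertex; individual nuclei can
   also be detected and integrated inside a fitted disc on their brightest
   z-slice.
4. **Statistics** — after the standard exclusions (mesh extremities, organs
   past the analysed stage), cell-scale units are binned by curvature
   (equal-count bins) with Student confidence intervals (α = 0.05), and the
   association is summarised by Pearson r, Spearman ρ, the regression slope,
   and a bilateral Student test between the extreme curvature bins.
5. **Section measures** — longitudinal optical sections through the middle of
   each boundary (thin maximal projections) yield the folding angle of the
   crease (180° = flat), the organ area in top view (shoelace formula), and
   the area of reporter expression on the section.

A fully analytic **synthetic-data generator** produces meristem-like
two-channel stacks (dome + primordia as a smooth union of spheres, bright
membrane shell, L1 nuclei whose reporter intensity increases with negative
curvature) with exact ground truth for surface position, curvature, folding
angles and organ areas — so every stage of the pipeline is testable without
any microscopy data.  A delayed-folding variant emulates katanin-mutant-like
meristems whose boundaries stay shallow at a given organ size.

## Worked example

```python
from creasemap.pipeline import run_pipeline
from creasemap.presets import small_config

report = run_pipeline(small_config(seed=7), outdir="results/demo")
print(f"n = {report['n_used']} cell patches, "
      f"r = {report['pearson_r']:+.3f} (p = {report['pearson_p']:.2g}), "
      f"slope = {report['slope']:.3g} a.u. per um^-2, "
      f"extreme-bin p = {report['extreme_bin_p']:.2g}")
```

prints, for the bundled two-primordium demo scene:

```
n = 170 cell patches, r = -0.167 (p = 0.03), slope = -281 a.u. per um^-2, extreme-bin p = 0.068
```

meaning: across 170 cell-scale surface patches of the dome and its
boundaries, reporter intensity falls significantly with Gaussian curvature
(boundary creases, K < 0, carry the strongest signal); the extreme-bin
Student contrast points the same way at this single-meristem sample size.
Across repeated scenes the correlation is recovered in essentially every
seed (see the acceptance script below).  The output
directory receives the mesh (`surface_mesh.ply` with per-vertex curvature and
intensity), the binned table and per-unit table (CSV with a units row), the
config snapshot and the report JSON.

The same pipeline runs on real data from the command line:

```sh
creasemap run --config cfg.json --input stack.tif --out results/
creasemap synth --config cfg.json --seed 17 --out phantom.tif   # synthetic stack
```

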