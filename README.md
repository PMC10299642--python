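# kinoquant

Quantitative analysis of protein localization and length morphometry in the
kinocilia of sensory hair cells, built around live confocal imaging of
zebrafish lateral-crista hair bundles.

Hair cells carry a single microtubule-based kinocilium alongside their
actin-based stereocilia. Fluorescently tagged ciliary proteins (tubulin,
Ankef1a, Odf3l2a, Saxo2) occupy distinct territories along this filament —
uniform, middle-proximal, distal-enriched, or distal with a bulbed tip —
and overexpression of microtubule stabilizers can bend or truncate it.
`kinoquant` turns those observations into numbers:

- **Synthetic imaging** — ground-truthed confocal Z-stacks of curved,
  pattern-bearing filaments (0.064 µm lateral pitch, 0.65 µm optical
  sections, Gaussian PSF, Gaussian/Poisson noise), so the whole pipeline is
  testable without microscope data.
- **Filament tracing** — seeded minimum-cost (Dijkstra) paths through the
  26-connected voxel graph, with edge cost = physical step length × mean of
  (I_max − I + 1) at the endpoints.
- **Length morphometry** — base-to-tip Euclidean chord
  `sqrt((Δx·s_xy)² + (Δy·s_xy)² + (Δz·s_z)²)` (the default) and smoothed
  polyline arc length; per-larva summaries as the mean of the five tallest
  measurable kinocilia.
- **Intensity profiling** — line profiles on the maximum Z-projection every
  0.064 µm with a 2-pixel line width, a 32 µm minimum-length filter,
  registration of all profiles at the distal tip over a 32 µm window
  (501 samples), position-wise averaging, min–max rescaling to 0–100,
  log2(1 + x), and a Loess smooth; a centroid-based regionalization index
  classifies profiles as proximal / uniform / distal.
- **Group statistics** — two-tailed Welch *t* with Welch–Satterthwaite df,
  one-way ANOVA (F = MS_between/MS_within), Tukey–Kramer HSD or Holm-adjusted
  pairwise comparisons, and a type-I-error self-check.
- **Locus mapping** — placement of candidate genes against marker-defined
  deafness critical regions (GRCh38), with inside/overlapping/outside calls
  and gap distances in bp and MB.

## Worked example

Render one distally enriched kinocilium, trace it, and profile it:

```python
import numpy as np
import kinoquant as kq
from kinoquant.synthetic import SceneManifest, GroundTruthCurve, render_stack

curve = kq.generate_curve(34.0, curvature_amp=1.5, rng_seed=11, pattern="distal")
pts = curve.control_points.copy()
pts[:, 1] += 4.5   # place the filament inside the grid (µm)
pts[:, 2] += 3.0
manifest = SceneManifest([GroundTruthCurve(pts, pattern="distal", amplitude=3000)],
                         gaussian_sd=60.0, seed=11)
stack = render_stack(manifest, (12, 160, 540))

(base, tip), = manifest.tracer_seeds(stack.spacing_xy, stack.spacing_z)
path = kq.trace(stack, base, tip)
result = kq.measure(path)
print(f"chord = {result.euclidean_um:.2f} um, arc = {result.path_um:.2f} um")

averaged, ensemble = kq.profile_stack(stack, [path])
s_bar, label = kq.regionalization_index(averaged.rescaled)
print(f"ensemble shape = {ensemble.matrix.shape}, centroid = {s_bar:.3f} ({label})")
```

prints

```
chord = 33.86 um, arc = 34.00 um
ensemble shape = (1, 501), centroid = 0.753 (distal)
```

The traced chord is within one voxel of the 33.90 µm ground-truth chord, the
arc length recovers the generated 34 µm filament, the registered window
holds 501 samples (32 µm at 0.064 µm steps), and the intensity centroid
(0.753 of the window, well past the 0.55 threshold) classifies the profile
as distally enriched.

Candidate-gene placement against deafness loci uses the bundled GRCh38
fixture:

```python
print(kq.candidacy_table().to_string(index=False))
```

```
  gene  locus  status  gap_bp  gap_mb
ANKEF1    n/a     n/a       0     0.0
ODF3L2 DFNB72 outside 4474521     4.5
ODF3L2 DFNA57 outside 7331882     7.3
 SAXO2 DFNA30 outside 4768993     4.8
```

ODF3L2 sits 4,474,521 bp (≥ 4.4 MB) from the DFNB72 critical region and
SAXO2 sits 4,768,993 bp (4.8 MB) from DFNA30 — both genes fall outside
their proposed deafness loci.

The same operations are available from the shell: `kinoquant simulate
scene|lengths`, `kinoquant trace`, `kinoquant profile`, `kinoquant stats`,
and `kinoquant loci` (see `kinoquant --help`).

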