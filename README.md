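# spcold

Single-particle cryogenic light microscopy (spCryo-LM) analysis:
polarization-resolved single-molecule localization, blinking
photophysics, projection-geometry inference, and class-based 3D
reconstruction of rigid oligomers — plus a synthetic two-channel
cryo-microscope so that every stage can be validated against known
ground truth.

## The problem

A fluorophore frozen in vitreous ice keeps a fixed transition dipole and
blinks spontaneously, spending far longer dark than emitting (off-on
dwell ratio ≈ 30).  Splitting its emission between two orthogonal
polarization channels gives each molecule a fingerprint — the
polarization angle θ = arctan √(Iy/Ix) ∈ [0°, 90°] — which is stable
within a blink and jumps between the different fluorophores decorating
one particle.  Segmenting a spot's intensity-pair time trace into
polarization states, and localizing each state's frames separately
(precision ≈ σ_PSF /√N per frame, improving as 1/√n over n events),
resolves several fluorophores within a single diffraction-limited spot
at nanometer–ångström precision.  Each resolved particle is a 2D
projection of a rigid 3D arrangement at an unknown orientation; pooling
many projections supports distance-distribution fits
(f(r) = r / (d√(d²−r²)) for true separation d), supervised labeling-class
assignment, and class-wise 3D reconstruction with Fourier-shell-correlation
resolution assessment against the half-bit threshold.

The package is aimed at microscopists and method developers who want a
tested, scriptable reference implementation of this analysis chain.

## Worked example

Recover the separation of a 30 nm two-fluorophore ruler from 53 noisy
2D projections at random 3D orientations:

```python
import numpy as np
from spcold.simkit import build_nanoruler_model, sample_orientation
from spcold.projgeom import fit_projection_distance

rng = np.random.default_rng(7)
ruler = build_nanoruler_model(30.0)
projected = []
for _ in range(53):
    R = sample_orientation(rng)
    pts = (R @ ruler.labels.T).T[:, :2] + rng.normal(0, 0.7, (2, 2))
    projected.append(np.linalg.norm(pts[0] - pts[1]))

fit = fit_projection_distance(projected)
print(f"d = {fit.d_nm:.1f} nm  (95% CI {fit.d_ci_nm[0]:.1f}–{fit.d_ci_nm[1]:.1f})")
```

```
d = 30.6 nm  (95% CI 29.8–31.3)
```

Projections only ever shorten distances, so the histogram of the 53
measured lengths has a long left tail — the maximum-likelihood fit of
the projection model still recovers the true 30 nm separation to within
a nanometer.

Enumerate the labeling classes of a 3-of-7 labeled heptamer (the
situation for sparsely labeled alpha-hemolysin):

```sh
$ spcold classes
class 0: gaps (1, 1, 5) multiplicity 7 sides [3.5, 3.5, 6.31] nm
class 1: gaps (1, 2, 4) multiplicity 14 sides [3.5, 6.31, 7.86] nm
class 2: gaps (1, 3, 3) multiplicity 7 sides [3.5, 7.86, 7.86] nm
class 3: gaps (2, 2, 3) multiplicity 7 sides [6.31, 6.31, 7.86] nm
```

The 35 ways of choosing 3 of 7 ring subunits collapse into 4 triangle
classes under ring symmetry; their side lengths are the chords of the
3.5 nm-spaced heptagon.

The full image-level pipeline (simulate → detect → segment → localize →
fit) runs from a config or the CLI:

```sh
spcold run --seed 1 --out demo_run       # nanoruler end-to-end
spcold simulate --model heptamer --preset 8K --n-frames 2000 --out sim
```

See `docs/methods.md` for the models, estimators, and their
assumptions.

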