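# afcomp — multiscale structure-based model of the annulus fibrosus

`afcomp` is a computational biomechanics package for the annulus fibrosus
(AF), the fiber-reinforced ring of the intervertebral disk.  It implements a
structure-based composite model in which collagen fiber bundles and the
extrafibrillar matrix are distinct materials occupying separate volumes
(the **SEP** description), alongside the conventional homogenized
description (**HOM**) in which every material point blends both ±30° fiber
families.  The package is for researchers who want to run *virtual
mechanical tests* on multi-lamellar AF specimens — uniaxial and biaxial
tension, simple shear, different gripping conditions — and to study how
sub-tissue properties and specimen geometry shape bulk tissue mechanics.

## The model

* Matrix: compressible neo-Hookean,
  `W = mu/2 (I1−3) − mu ln J + lam/2 (ln J)^2`, E = 0.22 MPa, nu = 0.3.
* Fiber-bundle ground substance: Holmes–Mow, `W = c/2 (e^Q − 1)`, beta = 1.
* Fibers: tension-only power-linear family — toe energy
  `xi (λ²−1)^gamma` up to the transition stretch λ0, then a linear region
  with tangent modulus E_lin (0.58 GPa SEP / 0.53 GPa HOM), with stress
  continuity at λ0.
* Swelling: ideal Donnan equilibrium, fixed charge density −100 mmol/L in
  the matrix (0 in fibers), osmotic coefficient 0.927, 0.15 M bath; the
  strain-dependent Holmes–Mow permeability k(J) is exposed (transient
  transport is out of scope).
* Microstructure: 0.2 mm lamellae, bundle radius 0.06 mm, in-plane pitch
  0.22 mm, alternating ±30° fiber angles (bundle volume fraction ≈ 0.257).

Specimens are solved either as finite-strain angle-ply laminates or as
voxel finite element models (total-Lagrangian hexahedra, Newton iteration,
free-swelling pre-step, gripped / vertebrae-attached / parallel-plate
boundary conditions).  A sub-tissue calibration loop fits single-lamella
region moduli; a validation harness compares multi-lamellar predictions
with pooled literature data via the within-one-standard-deviation rule; a
geometry study sweeps specimen length × width and decomposes the relative
importance of length, width, and aspect ratio (LMG).

See `docs/methods.md` for the full model description, numerical choices,
and known limitations.

## Worked example

Uniaxial tension of a three-lamella SEP specimen (10 × 2.5 mm, gripped,
20% strain after free swelling), on the voxel FE path:

```python
from afcomp.microstructure import LamellaSpec, SpecimenSpec
from afcomp.protocols import LoadCase, extract_moduli, run_experiment
from afcomp.solvers.fe import BoundaryCondition

spec = SpecimenSpec(length=10.0, width=2.5, n_lamellae=3,
                    orientation="circumferential", model_family="SEP")
case = LoadCase(modality="uniaxial", bc=BoundaryCondition("gripped"))
curve = run_experiment(spec, LamellaSpec(), case, solver_path="fe",
                       resolution=0.2, increments=20)
rep = extract_moduli(curve["strain_x"], curve["stress_x"])
print(f"toe {rep.toe_modulus:.2f} MPa, linear {rep.linear_modulus:.1f} MPa,"
      f" {rep.linearity}")
```

prints

```
toe 1.11 MPa, linear 33.9 MPa, NL
```

— a nonlinear (NL) stress–strain response whose toe and linear-region
moduli both fall inside the pooled experimental one-standard-deviation
bands for circumferential AF tension (2.52 ± 2.08 and 21.10 ± 15.80 MPa).
The same specimen solved with the homogenized description returns a
linear-region modulus of ≈ 56 MPa, overestimating the experimental band —
the structural separation of fibers and matrix, not the constituent laws,
carries the difference.

The command-line interface wraps the same library:

```bash
afcomp simulate run.yaml        # stress-strain curve + moduli report
afcomp calibrate --family SEP   # sub-tissue calibration loop
afcomp validate --predictions preds.json   # 13-case literature check
afcomp sweep --lengths 6,9,12,15 --widths 2,2.5,3
afcomp regress --sweep-csv results/sweep.csv
```

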