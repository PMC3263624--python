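# brainshift-xfem

Serial update of intraoperative brain MR images across surgery with a
linear-elastic tetrahedral biomechanical model and XFEM resection
modeling.

During image-guided tumor surgery the brain deforms repeatedly: it shifts
when the skull and dura are opened, then changes shape again after every
resection. Navigation based on the pre-surgical images degrades with each
step. This package implements a nonrigid registration pipeline for a
time-ordered series of intraoperative volumes I_1 … I_n that compensates
those deformations: it is written for researchers in medical image
computing and computational biomechanics who need a complete, testable
reference implementation of the surface-landmark-driven FEM/XFEM update
strategy.

## The model

A tetrahedral mesh of the whole-brain region (healthy brain ∪ tumor) is
built once from I_1 and assigned an isotropic linear-elastic law
(E = 3000 Pa, ν = 0.45; with pure displacement boundary conditions the
solution is independent of E). For each image pair (I_k, I_{k+1}), region
boundary surfaces — the whole-brain boundary, and, once resection starts,
the healthy-brain boundary only — are tracked with distance-map active
surfaces (plus local rigid ICP along the internal tumor boundary), and the
smoothed surface displacements drive a Dirichlet solve

u(x) = Σ_{i∈I} φ_i(x) u_i  +  Σ_{j∈J} φ_j(x) g(x) a_j

where the second (XFEM) term is active from the second resection on: J is
the set of nodes whose support is fully intersected by the prior cavity's
boundary, each carrying three extra DOFs a_j, and g is the Heaviside
function H(x) = ±1 or the hole function V(x) ∈ {1, 0} across the
discontinuity — so the removed tissue stops influencing the remaining
tissue without any remeshing. Because the formulation is linear,
increments are solved on the initial mesh and superpose:
ε^{n+1} = Σ_k Δε_k^{k+1}.

Warped images are produced by overlap-weighted forward splatting of the
volume displacement field, and registration quality is measured with the
modified Hausdorff distance between Canny edge maps,
H(A,B) = max(h(A,B), h(B,A)), h(A,B) = (1/N_a) Σ_a min_b ‖a−b‖.

No patient data ships with the repository; a synthetic five-time-point
phantom (brain ball, off-center tumor, 5 mm apex shift, three progressive
resections with known analytic displacement fields) exercises every stage
end-to-end. See `docs/methods.md` for assumptions, parameters and
limitations.

## Worked example

`examples/04_full_serial_pipeline.py` runs the full serial update on the
reference phantom (64³ voxels at 2 mm, ~2 minutes on one CPU) and prints:

```
model: 11239 nodes, 57006 tets, 33717 FEM DOFs
brain_shift: FEM, 3534 BC nodes, max increment 3.85 mm
1st_resection: FEM, 3534 BC nodes, max increment 2.23 mm
2nd_resection: XFEM, 3534 BC nodes, max increment 4.21 mm
3rd_resection: XFEM, 3534 BC nodes, max increment 2.51 mm

per-interval ground-truth recovery near the tracked boundary:
  interval 1: mean 0.323 mm, max 1.74 mm
  interval 2: mean 0.279 mm, max 1.44 mm
  interval 3: mean 0.259 mm, max 2.03 mm
  interval 4: mean 0.248 mm, max 1.98 mm

pairwise modified Hausdorff (whole-brain mask), rigid -> nonrigid:
  brain_shift    0.148 -> 0.109 mm
  1st_resection  0.171 -> 0.083 mm
  2nd_resection  0.195 -> 0.079 mm
  3rd_resection  0.081 -> 0.072 mm
```

Reading: the shift interval is modeled with FEM, the first resection with
FEM plus background assignment (no discontinuity yet), the later
resections with XFEM (the cavity from the previous image enriches the
model). The recovered displacement fields agree with the phantom's ground
truth to ~0.3 mm mean — well below the voxel size — in the neighborhood of
the tracked surfaces, and the nonrigid warp reduces the edge-map distance
on every interval. The other examples cover phantom generation, the
analytic XFEM split-bar problem, the Hausdorff metric, and the case-file
CLI (`brainshift-xfem phantom | run | validate`).

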