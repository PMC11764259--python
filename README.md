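# cyclereg

Unsupervised deformable registration of structural and functional MRI
with a cycle-consistent bidirectional network and a 3D shifted-window
attention encoder — implemented in pure scientific Python (numpy-based
autodiff, no deep-learning framework required).

## The problem

Group analysis of fMRI requires spatially normalising every subject to a
common space.  Registration driven purely by structural MRI aligns
anatomy but not necessarily function; registration driven purely by
functional features discards the anatomical detail that structural
images provide.  `cyclereg` implements a framework that registers the
structural images with a deformable network and injects functional
information during training, so the learned deformations improve both
structural and functional consistency.

Two networks are trained jointly on image pairs (A, B): G_A(A, B) → φ_AB
and G_B(B, A) → φ_BA, where φ(p) = p + u(p) is a dense displacement
field applied by differentiable trilinear warping.  The loss is

    L = L_mri + α·L_fmri + β·L_cycle + γ·L_identity,

with MSE + smoothness terms in both directions (L_mri), functional MSE +
local-functional-connectivity (LFC) feature distance on the
1/3-downsampled fields (L_fmri), an L1 cycle term that demands a warp
followed by the reverse warp return the original image, and an identity
term that demands no deformation when moving == fixed.  Defaults:
α = 0.2, β = 0.1, γ = 0.5, λ = 0.02.  The encoder computes multi-head
self-attention softmax(QKᵀ/√d + B)V inside (shifted) 6×6×6 windows with
learnable relative-position bias, block depths {2, 2, 4, 2}.  The LFC
feature of a voxel is a Gaussian KDE (bandwidth 0.1) of the Pearson
correlations between its time course and its 26 neighbours, evaluated at
64 points on [−1, 1].  See `docs/methods.md` for the full model account.

## Worked example

Generate a synthetic pair with a known smooth ground-truth deformation
(peak 2 voxels) and fit the registration model:

```python
from cyclereg import CycleRegistration, RegistrationConfig
from cyclereg.synthetic_data import make_structural_pair

pair = make_structural_pair(shape=(24, 24, 24), amplitude=2.0, seed=11)
model = CycleRegistration.from_pair(pair, config=RegistrationConfig(seed=1).tiny())
res = model.fit(max_iterations=60, learning_rate=5e-3, seed=1)
print(res.summary())
```

prints (about a minute on one CPU):

```
Cycle-consistent bidirectional registration results
====================================================
iterations run:        60
grid:                  (24, 24, 24)
total loss:            0.067966 -> 0.021971
  structural term:     0.015635
  functional term:     0.000000
  cycle term:          0.053416
  identity term:       0.001989
mean |u| (voxels):     0.2034
% negative Jacobian:   0.00000
mean Dice:             0.9757 -> 0.9816
```

The total loss falls as the forward/backward fields align the pair; the
Dice line shows the anatomical overlap of the warped labels against the
fixed labels improving over the unregistered baseline, and the Jacobian
line confirms the deformation is fold-free.  Training to the full
desk-scale protocol (300 iterations) reduces the mean endpoint error
against the known truth field to well under half of the zero-field
baseline — `res.endpoint_error(pair.truth_field, mask=...)` measures it
directly.

A thin CLI mirrors the library: `cyclereg simulate`, `cyclereg
extract-lfc`, `cyclereg train`, `cyclereg register`, `cyclereg
evaluate {dice,jacobian,tmap,table}`.

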