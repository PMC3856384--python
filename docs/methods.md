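# Methods

`wscalp` segments the brain in a T1-weighted head MRI without an atlas, a
template, or any registration step.  The approach treats skull stripping as a
two-stage *marker-based watershed* problem: instead of deciding for each voxel
whether it is brain, the method places a small number of spatially safe
markers — some certainly inside the brain, some certainly outside — and lets a
watershed transform grow them against each other over a control surface whose
ridges coincide with the tissue boundaries of interest.  Large-kernel
morphological filters, sized in millimetres rather than voxels, do the work
that atlases do in other pipelines: they encode coarse prior knowledge about
head geometry (the brain is a large, compact, bright object near the top of
the head) while remaining invariant to orientation conventions, voxel size,
and global intensity scaling.

All operations run in a canonical RAS orientation derived from the NIfTI
affine and results are mapped back to the input grid, so the method is
equivariant under grid re-orderings.  All sizes below are millimetres;
kernels are either metric balls (realised exactly via a squared Euclidean
distance transform) or axis-aligned boxes.

## Preprocessing

**Neck cropping.**  The field of view of a head scan may extend far down the
neck, where bright fat and muscle confuse background detection.  The volume
is thresholded (Otsu), the largest connected foreground component is found,
and every axial slice more than 180 mm (human; 80 mm macaque) below the top
of that component is set to zero.  If the field of view is already short the
step is a no-op.  The centre of mass of the top 20 mm slab of the head
(`COM_top`) anchors all subsequent geometric constructions.

**Flat-field bias correction (macaque).**  Small-animal coils produce strong
receive-field inhomogeneity.  A simple flat-field estimate — the 30 mm box
mean of the image — is divided out and the global mean level restored.  This
removes smooth multiplicative shading at scales larger than the kernel; it
does not preserve absolute intensities and is applied only where the
downstream steps are quantile- or median-based and therefore scale-free.

## Stage 1: gross brain/background separation

Stage 1 finds an initial brain mask that errs on the side of *including* all
brain (high sensitivity), leaving over-inclusion to be corrected by stage 2.

*Brain marker* `M_A` (human): within a 40 mm box centred 50 mm below
`COM_top`, the median intensity `T1_med` is computed; voxels in the band
`[T1_med, 1.25·T1_med]` — white matter and bright grey matter — are opened
with a 2 mm ball to remove thin bridges, and the components touching the box
are kept.  The construction is safe because the box lies deep inside the
brain for any plausible adult head.

*Background marker* `N_F` (human): the Otsu-dark voxels are eroded 5 mm (so
the marker cannot touch the scalp), restricted to the image border
neighbourhood, and augmented with markers in dark interior cavities (eyes,
sinuses) found as dark voxels well below the head median that survive a
volume filter.

*Watershed.*  Both markers are combined into one label image and a watershed
from markers is run on the *inverted* intensity (`max − v`), so that bright
tissue is low terrain and the dark CSF/skull shell forms the ridge at which
the brain and background floods meet.  The watershed is a priority-flood with
a deterministic, documented tie rule, so repeated runs are bit-identical.

Macaque stage 1 differs only in marker construction: the background marker is
the whole grid except a blanked 70×90×65 mm box around the expected brain
position, reinforced by dark anterior regions (orbits) found by quantile
thresholds on a box-closed image; the brain marker is a small box at the box
centre.

## Stage 2: scalp/marrow refinement

Stage 1 leaks wherever bright tissue touches the brain through a thin or
bright skull — most prominently into scalp via bright marrow in cancellous
bone.  Stage 2 re-runs the watershed inside the stage-1 mask with a control
surface built to place ridges at the *inner* skull boundary:

- the image is clipped at the 50 % quantile of the stage-1 region, so all
  brain tissue is flat terrain;
- a border-excess term penalises voxels near the stage-1 boundary that are
  brighter than their local masked mean (marrow, scalp);
- a smoothed masked gradient adds ridges at genuine tissue edges.

The stage-2 brain marker is the bright core of the stage-1 region away from
its boundary; background markers are dark border-zone voxels (CSF rim) and,
when present, bright marrow voxels high above the skull base.  The final
mask is the stage-2 brain region, dilated 1 mm to recover the partial-volume
rim, minus the bright markers.

**Smoothing.**  An optional morphological regularisation (5 mm opening +
6.5 mm closing after stage 1; 6.5 mm closing after stage 2) removes
voxel-scale spikes and closes narrow slits; it is idempotent and nearly a
no-op on already-smooth masks.

## Synthetic phantom and validation

Because the method is atlas-free and geometric, it can be validated on a
synthetic head phantom with voxel-exact ground truth: a brain ellipsoid
(grey shell over white core with CSF ventricle), wrapped in constant-thickness
CSF, skull, muscle and scalp shells built by distance transforms, with a neck
cylinder, brainstem sheathed in CSF and vertebral bone, eyes, optional bright
marrow patches inside the skull, smooth multiplicative bias (sum of signed
Gaussian bumps), and additive Gaussian noise.  Truth masks are derived from
the pre-noise tissue labels.  Accuracy is reported as Dice/Jaccard overlap
and sensitivity against the truth brain; the package's acceptance suite
checks stage-1 sensitivity ≥ 0.99 and stage-2 smoothed Dice ≥ 0.95 over ten
human phantoms, Dice ≥ 0.93 over five strongly biased macaque phantoms, and
bit-identical determinism.

## Why it works

The watershed from markers is exactly equivalent to (i) imposing regional
minima at the markers on the control surface and (ii) assigning each voxel to
the marker whose flooded basin reaches it first.  Errors can therefore only
occur where a *ridge* of the control surface is misplaced — not where
intensities are merely noisy — and marker placement only needs to be *safe*,
not accurate.  This is what makes the method robust to bias fields and
intensity non-standardisation: every threshold in the pipeline is relative
(Otsu, medians, quantiles, local means), and every size is metric.
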