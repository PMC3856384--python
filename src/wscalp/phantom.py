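"""Synthetic head phantoms with voxel-exact ground truth.

The phantom emulates the anatomy the extraction pipelines assume: a bright
brain (gray shell, brighter white core, a dark ventricle), a dark CSF gap and
skull, bright scalp/muscle shells, a neck extension and a brainstem bridge
that keeps the head one connected bright component, optional bright marrow
patches inside the skull (the classic false-positive source), dark eyes for
the macaque, a smooth multiplicative bias field and additive Gaussian noise.

Shells are built at constant millimetre thickness via a Euclidean distance
transform from the brain ellipsoid, so parameters like "CSF gap 3 mm" are
exact in every direction.  Truth masks are the pre-noise tissue labels.

Everything is deterministic given the spec (including its seed); the factory
functions jitter geometry per seed so a multi-seed suite explores slightly
different heads.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .grid import GridError, Mask, Volume
from .morphology import squared_edt

# tissue label codes used while painting
_AIR, _CSF, _BONE, _MUSCLE, _SCALP, _GRAY, _WHITE, _MARROW, _EYE, _VENT = range(10)


@dataclass(frozen=True)
class TissueIntensities:
    """Pre-bias tissue intensities (arbitrary T1-like units)."""

    air: float = 25.0
    csf: float = 150.0
    bone: float = 90.0
    muscle: float = 600.0
    scalp: float = 700.0
    gray: float = 850.0
    white: float = 1000.0
    marrow: float = 1350.0
    eye: float = 50.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom instance."""

    species: str
    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float]
    center_mm: Tuple[float, float, float]
    brain_semi_mm: Tuple[float, float, float]
    white_scale: float = 0.55
    csf_mm: float = 3.0
    skull_mm: float = 6.0
    muscle_mm: float = 0.0
    scalp_mm: float = 6.0
    ventricle_semi_mm: Optional[Tuple[float, float, float]] = None
    neck_len_mm: float = 0.0
    neck_radius_mm: float = 0.0
    stem_radius_mm: float = 0.0
    stem_bottom_mm: float = 0.0
    stem_csf_mm: float = 0.0
    stem_bone_mm: float = 0.0
    marrow_patches: int = 0
    marrow_radius_mm: float = 4.5
    eye_radius_mm: float = 0.0
    eye_offset_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensities: TissueIntensities = TissueIntensities()
    bias_amp: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    @property
    def shell_offsets(self) -> Tuple[float, float, float, float]:
        o1 = self.csf_mm
        o2 = o1 + self.skull_mm
        o3 = o2 + self.muscle_mm
        o4 = o3 + self.scalp_mm
        return o1, o2, o3, o4


def _axis_mm(spec: PhantomSpec, ax: int) -> np.ndarray:
    return np.arange(spec.shape[ax]) * spec.spacing[ax]


def _grids(spec: PhantomSpec):
    x = _axis_mm(spec, 0)[:, None, None]
    y = _axis_mm(spec, 1)[None, :, None]
    z = _axis_mm(spec, 2)[None, None, :]
    return x, y, z


def _ellipsoid(spec: PhantomSpec, center, semi) -> np.ndarray:
    x, y, z = _grids(spec)
    return (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _sphere(spec: PhantomSpec, center, radius) -> np.ndarray:
    x, y, z = _grids(spec)
    return ((x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2) <= radius**2


def _cylinder_z(spec: PhantomSpec, cx, cy, radius, z_lo, z_hi) -> np.ndarray:
    x, y, z = _grids(spec)
    return (((x - cx) ** 2 + (y - cy) ** 2) <= radius**2) & (z >= z_lo) & (z <= z_hi)


def _validate(spec: PhantomSpec) -> None:
    if spec.species not in ("human", "macaque"):
        raise GridError(f"unknown species {spec.species!r}")
    o4 = spec.shell_offsets[3]
    extents = [(n - 1) * s for n, s in zip(spec.shape, spec.spacing)]
    for ax in range(3):
        lo = spec.center_mm[ax] - spec.brain_semi_mm[ax] - o4
        hi = spec.center_mm[ax] + spec.brain_semi_mm[ax] + o4
        if lo < 0 or hi > extents[ax]:
            raise GridError(
                f"phantom geometry violates nesting: head exceeds grid on axis {ax}"
            )
    if spec.ventricle_semi_mm is not None:
        for v, b in zip(spec.ventricle_semi_mm, spec.brain_semi_mm):
            if v >= spec.white_scale * b:
                raise GridError("phantom geometry violates nesting: ventricle exceeds white core")
    if not 0 < spec.white_scale < 1:
        raise GridError("white_scale must be in (0, 1)")
    for name in ("air", "csf", "bone", "muscle", "scalp", "gray", "white", "marrow", "eye"):
        if getattr(spec.intensities, name) < 0:
            raise GridError(f"intensity {name} must be >= 0")


def make_phantom(spec: PhantomSpec) -> Tuple[Volume, Dict[str, Mask]]:
    """Render the phantom; returns the noisy biased volume and truth masks.

    Truth keys: brain (ellipsoid + ventricle + brainstem down to the outer
    skull table — what a skull stripper should keep), white, gray, csf,
    bone, muscle, scalp, marrow, eyes, head, air.
    """
    _validate(spec)
    rng = np.random.default_rng(spec.seed)
    c = spec.center_mm
    o1, o2, o3, o4 = spec.shell_offsets

    lab = np.full(spec.shape, _AIR, dtype=np.uint8)

    if spec.neck_len_mm > 0 and spec.neck_radius_mm > 0:
        lab[_cylinder_z(spec, c[0], c[1], spec.neck_radius_mm, 0.0, spec.neck_len_mm)] = _MUSCLE

    brain_ell = _ellipsoid(spec, c, spec.brain_semi_mm)
    d2 = squared_edt(brain_ell, spec.spacing)
    lab[(d2 > o3**2) & (d2 <= o4**2)] = _SCALP
    if spec.muscle_mm > 0:
        lab[(d2 > o2**2) & (d2 <= o3**2)] = _MUSCLE
    lab[(d2 > o1**2) & (d2 <= o2**2)] = _BONE
    lab[(d2 <= o1**2) & ~brain_ell] = _CSF

    # marrow patches: carved through the skull down to the CSF boundary but
    # leaving a 1 mm outer bone table, placed near the top of the head
    if spec.marrow_patches > 0:
        zone = (d2 > max(o1 - 1.0, 0.0) ** 2) & (d2 <= (o2 - 1.0) ** 2)
        semi = np.array(spec.brain_semi_mm)
        mid = o1 + spec.skull_mm / 2.0
        for _ in range(spec.marrow_patches):
            theta = np.deg2rad(rng.uniform(5.0, 30.0))
            phi = rng.uniform(0.0, 2 * np.pi)
            u = np.array(
                [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
            )
            r_dir = 1.0 / np.sqrt(((u / semi) ** 2).sum())
            pc = np.array(c) + (r_dir + mid) * u
            blob = _sphere(spec, pc, spec.marrow_radius_mm) & zone
            lab[blob] = _MARROW

    if spec.stem_radius_mm > 0:
        # the cord is sheathed in CSF and vertebral bone, as at the foramen
        # magnum; without this collar the bright cord would fuse with neck
        # muscle and grossly overstate the inferior leak
        zlo, zhi = spec.stem_bottom_mm, c[2]
        if spec.stem_bone_mm > 0:
            r_bone = spec.stem_radius_mm + spec.stem_csf_mm + spec.stem_bone_mm
            lab[_cylinder_z(spec, c[0], c[1], r_bone, zlo, zhi)] = _BONE
        if spec.stem_csf_mm > 0:
            r_csf = spec.stem_radius_mm + spec.stem_csf_mm
            lab[_cylinder_z(spec, c[0], c[1], r_csf, zlo, zhi)] = _CSF
        stem = _cylinder_z(spec, c[0], c[1], spec.stem_radius_mm, zlo, zhi)
        lab[stem] = _GRAY
    else:
        stem = np.zeros(spec.shape, dtype=bool)

    lab[brain_ell] = _GRAY
    white = _ellipsoid(spec, c, tuple(spec.white_scale * s for s in spec.brain_semi_mm))
    lab[white] = _WHITE
    if spec.ventricle_semi_mm is not None:
        lab[_ellipsoid(spec, c, spec.ventricle_semi_mm)] = _VENT

    if spec.eye_radius_mm > 0:
        dx, dy, dz = spec.eye_offset_mm
        for sx in (+1.0, -1.0):
            ec = (c[0] + sx * dx, c[1] + dy, c[2] + dz)
            skin = _sphere(spec, ec, spec.eye_radius_mm + spec.scalp_mm)
            lab[skin & (lab == _AIR)] = _SCALP
            lab[_sphere(spec, ec, spec.eye_radius_mm)] = _EYE

    it = spec.intensities
    lut = np.array(
        [it.air, it.csf, it.bone, it.muscle, it.scalp, it.gray, it.white, it.marrow, it.eye, it.csf],
        dtype=np.float64,
    )
    vol = lut[lab]

    if spec.bias_amp > 0:
        x, y, z = _grids(spec)
        extents = [(n - 1) * s for n, s in zip(spec.shape, spec.spacing)]
        sig_lo, sig_hi = (40.0, 80.0) if spec.species == "human" else (20.0, 40.0)
        raw = np.zeros(spec.shape, dtype=np.float64)
        for _ in range(4):
            bc = [rng.uniform(0, e) for e in extents]
            sig = rng.uniform(sig_lo, sig_hi)
            w = rng.uniform(-1.0, 1.0)
            raw += w * np.exp(
                -((x - bc[0]) ** 2 + (y - bc[1]) ** 2 + (z - bc[2]) ** 2) / (2 * sig**2)
            )
        peak = np.abs(raw).max()
        if peak > 0:
            vol = vol * (1.0 + spec.bias_amp * raw / peak)

    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, spec.shape)
    vol = np.clip(vol, 0.0, None).astype(np.float32)

    def mk(m: np.ndarray) -> Mask:
        return Mask(m, spec.spacing)

    truth = {
        "brain": mk(brain_ell | (stem & (d2 <= o2**2))),
        "white": mk(lab == _WHITE),
        "gray": mk(lab == _GRAY),
        "csf": mk((lab == _CSF) | (lab == _VENT)),
        "bone": mk(lab == _BONE),
        "muscle": mk(lab == _MUSCLE),
        "scalp": mk(lab == _SCALP),
        "marrow": mk(lab == _MARROW),
        "eyes": mk(lab == _EYE),
        "head": mk(lab != _AIR),
        "air": mk(lab == _AIR),
    }
    return Volume(vol, spec.spacing), truth


# ---------------------------------------------------------------------------
# Factory specs (per-seed geometry jitter)


def human_phantom_spec(seed: int, *, marrow: bool = False, short_fov: bool = False) -> PhantomSpec:
    """Default 1 mm human head phantom.

    The default field of view includes enough neck that the 180 mm crop path
    executes; ``short_fov`` produces a head-only volume on which neck
    cropping is a no-op.  ``marrow`` adds bright cancellous-bone patches to
    the superior skull.
    """
    rng = np.random.default_rng(seed)
    semi = tuple(b * rng.uniform(0.97, 1.03) for b in (55.0, 66.0, 58.0))
    cz = (106.5 if not short_fov else 90.0) + rng.uniform(-1.5, 1.5)
    center = (82.0 + rng.uniform(-1.5, 1.5), 94.0 + rng.uniform(-1.5, 1.5), cz)
    nz = 194 if not short_fov else 178
    # the bright outer shell (muscle + scalp, 12 mm) must be thicker than the
    # worst-case span of the pipeline's 5 mm box opening (5*sqrt(3) ~ 8.7 mm on
    # oblique surfaces), as it is on real heads, or the opening deletes it
    return PhantomSpec(
        species="human",
        shape=(166, 190, nz),
        spacing=(1.0, 1.0, 1.0),
        center_mm=center,
        brain_semi_mm=semi,  # type: ignore[arg-type]
        white_scale=0.55,
        csf_mm=3.0,
        skull_mm=6.0,
        muscle_mm=5.0,
        scalp_mm=7.0,
        ventricle_semi_mm=(8.0, 18.0, 10.0),
        neck_len_mm=60.0,
        neck_radius_mm=42.0,
        stem_radius_mm=6.0,
        stem_bottom_mm=30.0,
        stem_csf_mm=1.5,
        stem_bone_mm=4.0,
        marrow_patches=6 if marrow else 0,
        marrow_radius_mm=4.5,
        bias_amp=0.1,
        noise_sd=20.0,
        seed=seed,
    )


def macaque_phantom_spec(seed: int, *, bias_amp: float = 0.5) -> PhantomSpec:
    """Default 0.75 mm macaque head phantom with strong bias by default."""
    rng = np.random.default_rng(seed)
    semi = tuple(b * rng.uniform(0.97, 1.03) for b in (24.0, 30.0, 20.0))
    center = (
        47.6 + rng.uniform(-1.0, 1.0),
        56.0 + rng.uniform(-1.0, 1.0),
        69.5 + rng.uniform(-1.0, 1.0),
    )
    return PhantomSpec(
        species="macaque",
        shape=(128, 160, 146),
        spacing=(0.75, 0.75, 0.75),
        center_mm=center,
        brain_semi_mm=semi,  # type: ignore[arg-type]
        white_scale=0.55,
        csf_mm=2.0,
        skull_mm=3.0,
        muscle_mm=8.0,
        scalp_mm=3.0,
        ventricle_semi_mm=None,
        neck_len_mm=45.0,
        neck_radius_mm=30.0,
        stem_radius_mm=4.5,
        stem_bottom_mm=25.0,
        stem_csf_mm=1.2,
        stem_bone_mm=2.5,
        eye_radius_mm=9.0,
        eye_offset_mm=(15.0, 36.0, -20.0),
        bias_amp=bias_amp,
        noise_sd=20.0,
        seed=seed,
    )
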