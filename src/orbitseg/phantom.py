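"""Synthetic orbital CT phantom generator.

Produces 2D slices that structurally emulate the three clinically selected
views of an orbital CT study, each with paired ground-truth masks:

* ``axial1`` — the eye-level axial slice: two orbits, each with an eyeball
  (sclera ring around a vitreous interior), an optic nerve running
  posteriorly, and the medial/lateral rectus muscle bands; a bony nasal
  septum sits between the orbits.
* ``axial2`` — a superior axial slice where the lacrimal gland appears as a
  crescent supero-temporal to the eyeball (lacrimal gland is the only
  annotated tissue in this view).
* ``coronal`` — a retrobulbar coronal cut: the optic nerve as a central
  disc with the four rectus muscle bands at compass positions inside a
  bony orbital ring.

Geometry is deliberately schematic (circles, bands, crescents): the purpose
is to exercise a segmentation pipeline, not anatomical realism.  Attenuation
values are drawn from standard radiology ranges (orbital fat ~ -80 HU,
muscle ~ +50 HU, bone ~ +1000 HU) and per-pixel Gaussian noise emulates CT
quantum noise.  The ``enlargement_factor`` multiplies muscle-band thickness
to mimic the extraocular-muscle enlargement seen in Graves' orbitopathy.
Pixel values are integers clipped to the CT range [-1024, 3071].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as oio

__all__ = [
    "TISSUES", "PLANES", "PLANE_TISSUES", "HU_RANGE",
    "UnknownPlaneError", "PhantomSpec", "CTSlice", "TissueMaskSet",
    "render_slice", "generate_dataset",
]

TISSUES = (
    "eyeball", "optic_nerve", "MRM", "LRM", "SRM", "IRM", "lacrimal_gland",
)
PLANES = ("axial1", "axial2", "coronal")
PLANE_TISSUES = {
    "axial1": ("eyeball", "optic_nerve", "MRM", "LRM"),
    "axial2": ("lacrimal_gland",),
    "coronal": ("optic_nerve", "MRM", "LRM", "SRM", "IRM"),
}
HU_RANGE = (-1024, 3071)

_DEFAULT_HU = {
    "fat": -80.0,
    "eyeball": 5.0,       # vitreous interior
    "sclera": 60.0,
    "muscle": 50.0,
    "optic_nerve": 35.0,
    "lacrimal_gland": 40.0,
    "bone": 1000.0,
}


class UnknownPlaneError(ValueError):
    """Raised for a plane tag outside {axial1, axial2, coronal}."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic slice generator.

    Geometry fields are fractions of ``image_size``; ``jitter`` is the
    relative range of per-item random variation of the geometry (positions,
    radii, thicknesses), so a generated dataset is not a single repeated
    image.  ``enlargement_factor >= 1`` scales muscle-band thickness.
    """

    image_size: int = 512
    hu_means: dict = field(default_factory=lambda: dict(_DEFAULT_HU))
    noise_sd: float = 8.0
    eyeball_radius_frac: float = 0.14
    sclera_thickness_frac: float = 0.02
    nerve_width_frac: float = 0.035
    muscle_thickness_frac: float = 0.04
    lacrimal_size_frac: float = 0.06
    enlargement_factor: float = 1.0
    jitter: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 64 or self.image_size % 32:
            raise ValueError("image_size must be >= 64 and divisible by 32")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.enlargement_factor < 1.0:
            raise ValueError("enlargement_factor must be >= 1")
        if not 0.0 <= self.jitter < 0.5:
            raise ValueError("jitter must lie in [0, 0.5)")


@dataclass(frozen=True)
class CTSlice:
    """An integer Hounsfield-unit image with its plane tag."""

    pixels: np.ndarray  # int16, (H, W)
    plane: str
    pixel_spacing_mm: float = 0.4


class TissueMaskSet:
    """Pairwise-disjoint boolean masks keyed by tissue name."""

    def __init__(self, masks: dict[str, np.ndarray]):
        for name in masks:
            if name not in TISSUES:
                raise ValueError(f"unknown tissue {name!r}")
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in masks.items()}

    def __getitem__(self, tissue: str) -> np.ndarray:
        return self.masks[tissue]

    def __contains__(self, tissue: str) -> bool:
        return tissue in self.masks

    def __len__(self) -> int:
        return len(self.masks)

    def tissues(self) -> tuple[str, ...]:
        return tuple(self.masks)

    def coverage(self) -> np.ndarray:
        """Per-pixel count of covering masks (disjoint sets stay <= 1)."""
        total = None
        for m in self.masks.values():
            total = m.astype(np.uint8) if total is None else total + m
        return total


def _disc(yy, xx, cy, cx, r):
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _vband(yy, xx, xc, half_w, y0, y1):
    return (np.abs(xx - xc) <= half_w) & (yy >= y0) & (yy <= y1)


def _hband(yy, xx, yc, half_w, x0, x1):
    return (np.abs(yy - yc) <= half_w) & (xx >= x0) & (xx <= x1)


def _jitter(rng: np.random.Generator, value: float, frac: float) -> float:
    return value * (1.0 + rng.uniform(-frac, frac))


def render_slice(spec: PhantomSpec, plane: str, seed: int | None = None
                 ) -> tuple[CTSlice, TissueMaskSet]:
    """Render one slice and its ground-truth masks; fully seeded."""
    if plane not in PLANES:
        raise UnknownPlaneError(f"unknown plane {plane!r}; expected one of {PLANES}")
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    s = float(spec.image_size)
    yy, xx = np.mgrid[0:spec.image_size, 0:spec.image_size].astype(np.float32)
    hu = spec.hu_means
    j = spec.jitter

    img = np.full(yy.shape, hu["fat"], dtype=np.float32)
    masks: dict[str, np.ndarray] = {}
    t_muscle = 0.5 * spec.muscle_thickness_frac * s * spec.enlargement_factor

    if plane in ("axial1", "axial2"):
        r_eye = _jitter(rng, spec.eyeball_radius_frac * s, j)
        if plane == "axial2":
            r_eye *= 0.8  # superior cut crosses the globe off-equator
        sclera = spec.sclera_thickness_frac * s
        eye_mask = np.zeros(yy.shape, bool)
        nerve_mask = np.zeros(yy.shape, bool)
        mrm_mask = np.zeros(yy.shape, bool)
        lrm_mask = np.zeros(yy.shape, bool)
        lac_mask = np.zeros(yy.shape, bool)
        for cx0, lateral_sign in ((0.27, -1.0), (0.73, +1.0)):
            cx = _jitter(rng, cx0 * s, 0.3 * j)
            cy = _jitter(rng, 0.35 * s, 0.3 * j)
            outer = _disc(yy, xx, cy, cx, r_eye)
            inner = _disc(yy, xx, cy, cx, r_eye - sclera)
            img[outer & ~inner] = hu["sclera"]
            img[inner] = hu["eyeball"]
            if plane == "axial1":
                eye_mask |= inner
                half_n = 0.5 * _jitter(rng, spec.nerve_width_frac * s, j)
                nerve = _vband(yy, xx, cx, half_n, cy + r_eye, 0.88 * s) & ~outer
                nerve_mask |= nerve
                off = r_eye + 0.05 * s
                half_m = _jitter(rng, t_muscle, 0.5 * j)
                for sign, store in ((-lateral_sign, mrm_mask), (lateral_sign, lrm_mask)):
                    band = _vband(yy, xx, cx + sign * off, half_m, cy, 0.85 * s)
                    store |= band & ~outer
            else:
                r_lac = _jitter(rng, spec.lacrimal_size_frac * s, j)
                lac_c = (cy - 0.75 * r_eye, cx + lateral_sign * 0.75 * r_eye)
                lac = _disc(yy, xx, lac_c[0], lac_c[1], r_lac) & ~outer
                lac_mask |= lac
        # bony nasal septum and posterior skull base
        bone = _vband(yy, xx, 0.5 * s, 0.015 * s, 0.22 * s, s)
        bone |= yy >= 0.94 * s
        img[bone] = hu["bone"]
        if plane == "axial1":
            masks["eyeball"] = eye_mask
            masks["optic_nerve"] = nerve_mask & ~eye_mask & ~bone
            masks["MRM"] = mrm_mask & ~masks["optic_nerve"] & ~eye_mask
            masks["LRM"] = lrm_mask & ~masks["MRM"] & ~masks["optic_nerve"] & ~eye_mask
        else:
            masks["lacrimal_gland"] = lac_mask & ~bone
    else:  # coronal
        cy = cx = 0.5 * s
        ring_r = _jitter(rng, 0.38 * s, 0.3 * j)
        ring = _disc(yy, xx, cy, cx, ring_r) & ~_disc(yy, xx, cy, cx, ring_r - 0.03 * s)
        img[ring] = hu["bone"]
        r_nerve = _jitter(rng, spec.nerve_width_frac * s, j)
        nerve = _disc(yy, xx, cy, cx, r_nerve)
        d = 0.22 * s
        half_m = _jitter(rng, t_muscle, 0.5 * j)
        length = 0.09 * s
        srm = _hband(yy, xx, cy - d, half_m, cx - length, cx + length)
        irm = _hband(yy, xx, cy + d, half_m, cx - length, cx + length)
        mrm = _vband(yy, xx, cx - d, half_m, cy - length, cy + length)
        lrm = _vband(yy, xx, cx + d, half_m, cy - length, cy + length)
        masks["optic_nerve"] = nerve
        masks["MRM"] = mrm & ~nerve
        masks["LRM"] = lrm & ~nerve & ~mrm
        masks["SRM"] = srm & ~nerve & ~mrm & ~lrm
        masks["IRM"] = irm & ~nerve & ~mrm & ~lrm & ~srm

    for tissue, mask in masks.items():
        key = tissue if tissue in hu else ("muscle" if tissue.endswith("RM") else tissue)
        img[mask] = hu.get(key, hu["muscle"])

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), HU_RANGE[0], HU_RANGE[1]).astype(np.int16)
    return CTSlice(pixels=pixels, plane=plane), TissueMaskSet(masks)


def generate_dataset(n: int, spec: PhantomSpec, plane: str, out_dir,
                     seed: int | None = None) -> "pd.DataFrame":
    """Write ``n`` slice/mask-set pairs plus a manifest CSV.

    Item ``i`` is rendered with seed ``seed + i`` so every item is
    independently reproducible.  Returns the manifest as a DataFrame; it is
    also written to ``out_dir/manifest.csv``.
    """
    import pandas as pd  # noqa: F401  (re-exported type in docstring)

    if n < 1:
        raise ValueError("n must be >= 1")
    if seed is None:
        seed = spec.seed
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n):
        item_seed = seed + i
        item_id = f"{plane}_{i:04d}"
        ct, masks = render_slice(spec, plane, seed=item_seed)
        image_path = out_dir / f"{item_id}.png"
        oio.write_image_png(image_path, ct.pixels)
        for tissue in masks.tissues():
            mask_path = out_dir / f"{item_id}_{tissue}.png"
            oio.write_mask_png(mask_path, masks[tissue])
            rows.append({
                "id": item_id, "plane": plane,
                "image_path": image_path.name, "tissue": tissue,
                "mask_path": mask_path.name, "seed": item_seed,
            })
    return oio.write_manifest(rows, out_dir / "manifest.csv")
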