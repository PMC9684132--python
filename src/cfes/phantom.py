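"""Seeded synthetic two-material CT slice phantoms.

The generator emulates the Monte-Carlo study design: a concentric-disk
abdomen stand-in on an air background, with a muscle disk and an
interior fat ring whose pixel count realises the requested fat ratio
``z`` exactly.  Each fat pixel draws its HU value from
``Normal(E_F, S_F)``, each muscle pixel from ``Normal(E_M, S_M)``,
independently; air pixels carry the sentinel value -1000 HU and are
masked out.  HU values are stored as continuous floats — binning to
8-bit grey values happens only at histogram extraction, keeping the
generator independent of binning conventions.

Reproducibility: every phantom of a series derives its own
``numpy.random.SeedSequence`` from the base seed and the item's
``(S, z, replicate)`` coordinates, so any sub-experiment can be
regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .model import MixtureParams

__all__ = [
    "FAT",
    "MUSCLE",
    "EXCLUDED",
    "AIR_HU",
    "PhantomSpec",
    "SliceImage",
    "LabelMap",
    "generate_phantom",
    "phantom_series",
    "STUDY_S_GRID",
]

# label codes of the quasi-segmentation / ground-truth rasters
FAT = 1
MUSCLE = 2
EXCLUDED = 0

AIR_HU = -1000.0

#: the component-SD grid of the Monte-Carlo image series (HU)
STUDY_S_GRID: tuple = (
    10, 12, 14, 15, 17, 20, 25, 30, 35, 40, 45, 55,
    60, 70, 80, 90, 100, 150, 200, 250,
)


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of one synthetic slice.

    ``geometry`` describes the concentric-disk family: the muscle disk
    radius and the centre radius of the fat ring, both as fractions of
    the image side length.  The fat ring's width is solved so that the
    fat pixel count equals ``round(z * Q_FM)`` exactly.
    """

    theta_true: MixtureParams
    size: int = 512
    geometry: dict = field(
        default_factory=lambda: {"disk_radius": 0.45, "fat_ring_center": 0.28}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ValueError("phantom size must be at least 64 pixels")


@dataclass
class SliceImage:
    """HU-valued pixel raster with a body (fat-or-muscle) mask."""

    pixels: np.ndarray
    mask: np.ndarray
    provenance: PhantomSpec | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.shape != self.mask.shape:
            raise ValueError("pixels and mask must have identical shape")

    @property
    def q_total(self) -> int:
        """Number of masked-in (body) pixels Q."""
        return int(self.mask.sum())


@dataclass
class LabelMap:
    """Per-pixel FAT / MUSCLE / EXCLUDED labels."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)

    @property
    def q_fat(self) -> int:
        return int(np.count_nonzero(self.labels == FAT))

    @property
    def q_muscle(self) -> int:
        return int(np.count_nonzero(self.labels == MUSCLE))


def _disk_layout(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth body mask and fat submask of the concentric phantom.

    The fat region is the set of body pixels whose radius is closest to
    the fat ring's centre radius, taken in deterministic order until the
    exact target count is reached — so the realised fat fraction matches
    ``z`` to within a single pixel.
    """
    n = spec.size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - c, xx - c)
    body = r <= spec.geometry["disk_radius"] * n
    q_fm = int(body.sum())
    n_fat = int(round(spec.theta_true.z * q_fm))
    if n_fat > q_fm:
        raise ValueError("geometry cannot realise the requested fat fraction")
    ring_r = spec.geometry["fat_ring_center"] * n
    # rank body pixels by distance from the ring radius; ties broken by
    # flat pixel index so the layout is deterministic
    flat = np.flatnonzero(body.ravel())
    key = np.abs(r.ravel()[flat] - ring_r)
    order = np.lexsort((flat, key))
    fat_flat = flat[order[:n_fat]]
    fat = np.zeros(n * n, dtype=bool)
    fat[fat_flat] = True
    return body, fat.reshape(n, n)


def generate_phantom(spec: PhantomSpec) -> tuple[SliceImage, LabelMap]:
    """Draw one seeded phantom slice and its ground-truth label map."""
    body, fat = _disk_layout(spec)
    th = spec.theta_true
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    pixels = np.full(body.shape, AIR_HU, dtype=float)
    muscle = body & ~fat
    pixels[fat] = rng.normal(th.e_f, th.s_f, int(fat.sum()))
    pixels[muscle] = rng.normal(th.e_m, th.s_m, int(muscle.sum()))
    labels = np.full(body.shape, EXCLUDED, dtype=np.uint8)
    labels[fat] = FAT
    labels[muscle] = MUSCLE
    image = SliceImage(pixels=pixels, mask=body, provenance=spec)
    return image, LabelMap(labels=labels)


def item_seed(base_seed: int, s_hu: float, z: float, replicate: int) -> np.random.SeedSequence:
    """Splittable per-item seed: base seed keyed by (S, z, replicate).

    S and z enter in fixed-point milli-units so float grid values hash
    reproducibly across platforms.
    """
    return np.random.SeedSequence(
        entropy=int(base_seed),
        spawn_key=(int(round(1000 * s_hu)), int(round(1000 * z)), int(replicate)),
    )


def phantom_series(
    z_value: float,
    s_grid: Sequence[float],
    replicates: int,
    base_seed: int,
    *,
    e_f: float = -80.0,
    e_m: float = 50.0,
    size: int = 512,
) -> list[tuple[SliceImage, LabelMap, PhantomSpec]]:
    """Generate one phantom per (S, replicate) over an SD grid.

    Component means default to the study values E_F = -80 HU and
    E_M = +50 HU.
    """
    if replicates < 1:
        raise ValueError("replicates must be at least 1")
    s_grid = list(s_grid)
    if not s_grid:
        raise ValueError("s_grid must not be empty")
    out = []
    for s in s_grid:
        for r in range(replicates):
            ss = item_seed(base_seed, s, z_value, r)
            # derive a plain integer seed so the spec is self-describing
            seed = int(ss.generate_state(1, dtype=np.uint32)[0])
            spec = PhantomSpec(
                theta_true=MixtureParams(e_f=e_f, e_m=e_m, s_f=float(s), s_m=float(s), z=z_value),
                size=size,
                seed=seed,
            )
            image, truth = generate_phantom(spec)
            out.append((image, truth, spec))
    return out
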