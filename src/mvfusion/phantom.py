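"""Synthetic multi-view volumetric phantoms with cross-view planted signal.

Each case consists of ``n_views`` independent noise volumes (a smooth
low-frequency background field plus white Gaussian noise).  In a positive
case one ellipsoidal "lesion" with a smooth radial profile is planted at a
randomly drawn centre, but every view renders only a *sector* of the
lesion: view ``v`` sees the part of the lesion whose in-plane angle around
the lesion centre falls inside an arc of width
``view_informativeness[v] * 2*pi`` centred at ``2*pi*v / n_views``.  With
the default informativeness of 0.2 for each of 4 views, any single view
renders only a fifth of the lesion, while the rotated disjoint sectors of
all views together render most of it — the structural reason a multi-view
model can beat the best single-view model on this data.

Generation is a pure function of the spec (which includes the seed):
identical specs yield bitwise-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import Case, DatasetSplit, ViewVolume

__all__ = ["PhantomSpec", "generate_case", "generate_dataset"]

#: standard deviation of the smooth low-frequency background field
_BACKGROUND_SD = 0.5
#: Gaussian smoothing sigma (depth, height, width) for the background field
_BACKGROUND_SIGMA = (1.5, 3.0, 3.0)
#: lesion radii as fractions of each volume extent, drawn uniformly
_RADIUS_FRACTION = (0.28, 0.40)
#: lesion centre jitter, as a fraction of each extent around the middle
#: (the emulated structure sits in a consistent central region, like the
#: cruciate ligaments within a knee acquisition)
_CENTER_JITTER = 0.125
#: angular feather (radians) softening the sector edges
_FEATHER = 0.35


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one phantom dataset.

    Defaults describe the standard benchmark: 100 cases, 4 views of
    16x32x32 voxels, balanced classes, lesion amplitude 10 against unit
    white noise, and each view rendering a 0.2 fraction of the lesion's
    angular extent (rotated non-overlapping sectors, so any one view sees
    only a fifth of the lesion while the four views together render most
    of it).
    """

    n_views: int = 4
    shape: tuple[int, int, int] = (16, 32, 32)
    n_cases: int = 100
    positive_fraction: float = 0.5
    signal_amplitude: float = 10.0
    noise_sd: float = 1.0
    view_informativeness: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2)
    lesion_radius_fraction: tuple[float, float] = _RADIUS_FRACTION
    seed: int = 0

    def __post_init__(self):
        if self.n_views < 1:
            raise ValueError("n_views must be >= 1")
        if len(self.view_informativeness) != self.n_views:
            raise ValueError(
                "view_informativeness must have one entry per view "
                f"({len(self.view_informativeness)} != {self.n_views})"
            )
        if not all(0.0 <= f <= 1.0 for f in self.view_informativeness):
            raise ValueError("view_informativeness entries must lie in [0, 1]")
        if all(f >= 1.0 for f in self.view_informativeness):
            raise ValueError(
                "at least one view_informativeness entry must be < 1 "
                "(no single view may render the full lesion)"
            )
        if not (0.0 < self.positive_fraction < 1.0):
            raise ValueError("positive_fraction must lie in (0, 1)")
        if self.signal_amplitude < 0:
            raise ValueError("signal_amplitude must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        lo, hi = self.lesion_radius_fraction
        if not (0.0 < lo <= hi):
            raise ValueError(
                f"lesion_radius_fraction must be 0 < lo <= hi, got {(lo, hi)}"
            )
        if len(self.shape) != 3 or min(self.shape) < 4:
            raise ValueError(f"shape must be 3 extents >= 4, got {self.shape}")


def _background(shape, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency field plus white Gaussian noise."""
    low = ndimage.gaussian_filter(
        rng.normal(size=shape), sigma=_BACKGROUND_SIGMA, mode="wrap"
    )
    sd = low.std()
    if sd > 0:
        low *= _BACKGROUND_SD / sd
    return (low + rng.normal(0.0, noise_sd, size=shape)).astype(np.float32)


def _lesion_geometry(spec: PhantomSpec, rng: np.random.Generator):
    """Draw a lesion centre and radii; shared by all views of one case."""
    shape = np.asarray(spec.shape, dtype=float)
    radii = rng.uniform(*spec.lesion_radius_fraction, size=3) * shape
    if np.any(2 * radii > shape):
        raise ValueError(
            f"lesion diameter {2 * radii} exceeds volume extent {spec.shape}"
        )
    lo = np.maximum(radii, (0.5 - _CENTER_JITTER) * shape)
    hi = np.minimum(shape - radii, (0.5 + _CENTER_JITTER) * shape)
    center = rng.uniform(np.minimum(lo, hi), np.maximum(lo, hi))
    return center, radii


def _render_lesion_sector(
    shape,
    center: np.ndarray,
    radii: np.ndarray,
    amplitude: float,
    arc_center: float,
    arc_fraction: float,
) -> np.ndarray:
    """Smooth ellipsoid profile masked to one angular sector (softened edges)."""
    if arc_fraction <= 0:
        return np.zeros(shape, dtype=np.float32)
    zz, yy, xx = np.meshgrid(
        *(np.arange(s, dtype=float) for s in shape), indexing="ij"
    )
    rho2 = (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    )
    profile = np.exp(-3.0 * rho2)
    profile[rho2 > 2.0] = 0.0
    if arc_fraction >= 1.0:
        mask = 1.0
    else:
        theta = np.arctan2(xx - center[2], yy - center[1])
        # wrapped angular distance from the view's arc centre
        dist = np.abs(np.angle(np.exp(1j * (theta - arc_center))))
        half_width = arc_fraction * np.pi
        mask = np.clip((half_width - dist) / _FEATHER + 0.5, 0.0, 1.0)
    return (amplitude * profile * mask).astype(np.float32)


def generate_case(
    spec: PhantomSpec, label: int, rng: np.random.Generator, case_id: str = "case"
) -> Case:
    """Generate one phantom case; positive cases carry the sectored lesion."""
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label!r}")
    center = radii = None
    if label == 1:
        center, radii = _lesion_geometry(spec, rng)
    views = []
    for v in range(spec.n_views):
        vol = _background(spec.shape, spec.noise_sd, rng)
        if label == 1 and spec.signal_amplitude > 0:
            vol = vol + _render_lesion_sector(
                spec.shape,
                center,
                radii,
                spec.signal_amplitude,
                arc_center=2.0 * np.pi * v / spec.n_views,
                arc_fraction=spec.view_informativeness[v],
            )
        views.append(ViewVolume(view_id=f"view{v}", data=vol))
    return Case(case_id=case_id, views=views, label=label)


def _partition_sizes(n_cases: int) -> tuple[int, int, int]:
    sizes = [round(0.7 * n_cases), round(0.1 * n_cases), 0]
    sizes[2] = n_cases - sizes[0] - sizes[1]
    # every partition needs room for both classes; take from the largest
    for i in range(3):
        while sizes[i] < 2:
            sizes[int(np.argmax(sizes))] -= 1
            sizes[i] += 1
    return tuple(sizes)


def _positive_count(size: int, fraction: float) -> int:
    # both classes must be representable in every partition
    k = round(fraction * size)
    if size >= 2:
        k = min(max(k, 1), size - 1)
    if k < 1 or k >= size:
        raise ValueError(
            f"partition of size {size} cannot contain both classes"
        )
    return k


def generate_dataset(spec: PhantomSpec) -> DatasetSplit:
    """Generate a seeded, stratified 70/10/20 phantom dataset.

    Each partition receives ``round(positive_fraction * size)`` positive
    cases (clamped so both classes are always present).  Within a
    partition, case order is shuffled.
    """
    if spec.n_cases < 10:
        raise ValueError(f"n_cases must be >= 10, got {spec.n_cases}")
    rng = np.random.default_rng(spec.seed)
    sizes = _partition_sizes(spec.n_cases)
    partitions: list[list[Case]] = []
    counter = 0
    for size in sizes:
        n_pos = _positive_count(size, spec.positive_fraction)
        labels = np.array([1] * n_pos + [0] * (size - n_pos))
        rng.shuffle(labels)
        cases = []
        for lab in labels:
            cases.append(
                generate_case(spec, int(lab), rng, case_id=f"case{counter:04d}")
            )
            counter += 1
        partitions.append(cases)
    return DatasetSplit(train=partitions[0], validation=partitions[1], test=partitions[2])
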