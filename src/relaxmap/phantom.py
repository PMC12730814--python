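"""Digital tissue phantoms and noisy multi-contrast series simulation.

Replaces undeposited scanner data with synthetic magnitude-image series that
carry the statistical structure the downstream analysis assumes: piecewise-
constant tissue regions with known ground-truth T1/T2, forward-simulated
through the shared signal models and corrupted with Rician noise (the
magnitude-reconstruction statistics of a clinical scanner).

Tissue ground truths default to the ex vivo bladder reference values of the
three study groups (healthy margin tissue, untreated non-muscle-invasive
bladder cancer, and the same tumours after 5-ALA photodynamic therapy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .models import (
    AcquisitionGrid,
    SeriesMode,
    T1ModelParams,
    T2ModelParams,
    t1_signal,
    t2_signal,
)

__all__ = [
    "GROUPS",
    "BLADDER_TISSUE_VALUES",
    "PhantomRegion",
    "PhantomSpec",
    "AcquisitionSeries",
    "make_three_tissue_phantom",
    "simulate_series",
    "sample_cohort",
    "rician_corrupt",
]

GROUPS = ("healthy", "NMIBC", "NMIBC_PDT")

#: Per-group ex vivo relaxation reference values, ms:
#: group -> (T1 mean, T1 SD, T2 mean, T2 SD).
BLADDER_TISSUE_VALUES: dict[str, tuple[float, float, float, float]] = {
    "healthy": (1351.7, 271.1, 93.5, 20.3),
    "NMIBC": (727.7, 145.0, 78.5, 20.4),
    "NMIBC_PDT": (368.9, 65.2, 55.7, 6.1),
}

DEFAULT_PROTON_DENSITY = 1000.0
#: Default Rician scale; SNR 50 at the default proton density.
DEFAULT_NOISE_SIGMA = 20.0


@dataclass
class PhantomRegion:
    """One piecewise-constant tissue region of a phantom."""

    label: str
    mask: np.ndarray
    t1_ms: float
    t2_ms: float
    proton_density: float = DEFAULT_PROTON_DENSITY
    baseline: float = 0.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.proton_density > 0 and (self.t1_ms <= 0 or self.t2_ms <= 0):
            raise ValueError(
                f"region {self.label!r}: t1_ms and t2_ms must be > 0"
            )
        if self.proton_density < 0 or self.baseline < 0:
            raise ValueError("proton_density and baseline must be >= 0")


@dataclass
class PhantomSpec:
    """Region layout + noise level + seed; drives the simulator."""

    shape: tuple[int, int]
    regions: list[PhantomRegion]
    noise_sigma: float = 0.0
    seed: int = 0
    sample_id: str = "phantom"
    group: str | None = None

    def __post_init__(self) -> None:
        self.shape = (int(self.shape[0]), int(self.shape[1]))
        if self.shape[0] <= 0 or self.shape[1] <= 0:
            raise ValueError(f"shape must be positive, got {self.shape}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        occupancy = np.zeros(self.shape, dtype=int)
        for r in self.regions:
            if r.mask.shape != self.shape:
                raise ValueError(
                    f"region {r.label!r} mask shape {r.mask.shape} "
                    f"does not fit phantom shape {self.shape}"
                )
            occupancy += r.mask
        if np.any(occupancy > 1):
            raise ValueError("region masks must be disjoint")

    def region(self, label: str) -> PhantomRegion:
        for r in self.regions:
            if r.label == label:
                return r
        raise KeyError(f"no region labelled {label!r}")


@dataclass
class AcquisitionSeries:
    """Ordered stack of same-shape 2-D magnitude images with (TR, TE) tags."""

    images: np.ndarray  # (n_images, rows, cols)
    tags: list[tuple[float, float]]
    grid: AcquisitionGrid
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n, rows, cols) stack")
        if len(self.tags) != self.images.shape[0] or len(self.grid) != len(self.tags):
            raise ValueError("images, tags and grid must have equal length")
        if np.any(self.images < 0):
            raise ValueError("magnitude images must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]

    def __len__(self) -> int:
        return self.images.shape[0]


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def make_three_tissue_phantom(
    shape: tuple[int, int] = (64, 64),
    values: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    proton_density: float = DEFAULT_PROTON_DENSITY,
    noise_sigma: float = 0.0,
) -> PhantomSpec:
    """Three disjoint disc-shaped tissue regions plus zero-signal background.

    Parameters
    ----------
    shape
        Phantom matrix size, at least 16 x 16.
    values
        Optional ``{label: (t1_ms, t2_ms)}`` overriding the per-group
        reference ground truths in :data:`BLADDER_TISSUE_VALUES`.
    """
    if shape[0] < 16 or shape[1] < 16:
        raise ValueError(
            f"shape {shape} too small to place three disjoint regions "
            "(minimum 16 x 16)"
        )
    if values is None:
        values = {g: (BLADDER_TISSUE_VALUES[g][0], BLADDER_TISSUE_VALUES[g][2]) for g in GROUPS}
    labels = list(values)
    if len(labels) != 3:
        raise ValueError("exactly three tissue value pairs expected")
    # one disc per tissue along the diagonal; radius scaled to the matrix
    radius = min(shape) / 8.0
    centers = [
        (shape[0] * 0.25, shape[1] * 0.25),
        (shape[0] * 0.50, shape[1] * 0.72),
        (shape[0] * 0.75, shape[1] * 0.30),
    ]
    regions = []
    for label, center in zip(labels, centers):
        t1_ms, t2_ms = values[label]
        regions.append(
            PhantomRegion(
                label=label,
                mask=_disc_mask(shape, center, radius),
                t1_ms=t1_ms,
                t2_ms=t2_ms,
                proton_density=proton_density,
            )
        )
    return PhantomSpec(shape=shape, regions=regions, noise_sigma=noise_sigma, seed=seed)


def rician_corrupt(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of ``signal`` with complex Gaussian noise of scale ``sigma``.

    ``out = sqrt((S + g1*sigma)^2 + (g2*sigma)^2)`` with independent standard
    normal ``g1, g2``; at zero signal this is Rayleigh with mean
    ``sigma * sqrt(pi/2)``.
    """
    if sigma == 0:
        return np.asarray(signal, dtype=float)
    g1 = rng.standard_normal(np.shape(signal))
    g2 = rng.standard_normal(np.shape(signal))
    return np.sqrt((signal + g1 * sigma) ** 2 + (g2 * sigma) ** 2)


def _noiseless_image(spec: PhantomSpec, tr_ms: float, te_ms: float, mode: SeriesMode) -> np.ndarray:
    img = np.zeros(spec.shape, dtype=float)
    for r in spec.regions:
        if r.proton_density == 0:
            continue
        if mode is SeriesMode.T1_SERIES:
            val = t1_signal(
                tr_ms, T1ModelParams(r.proton_density, 1.0, r.t1_ms)
            )
        else:
            val = t2_signal(
                te_ms, T2ModelParams(r.proton_density, r.t2_ms, r.baseline)
            )
        img[r.mask] = val
    return img


def simulate_series(spec: PhantomSpec, grid: AcquisitionGrid) -> AcquisitionSeries:
    """Forward-simulate a magnitude-image series for one phantom.

    Each pixel carries the noiseless model signal of its region (background
    is identically zero); with ``spec.noise_sigma > 0`` every pixel of every
    image is independently Rician-corrupted. Deterministic given
    ``(spec.seed, grid)``.
    """
    rng = np.random.default_rng(spec.seed)
    images = np.stack(
        [_noiseless_image(spec, tr, te, grid.mode) for tr, te in grid.tags]
    )
    if spec.noise_sigma > 0:
        images = rician_corrupt(images, spec.noise_sigma, rng)
    return AcquisitionSeries(
        images=images,
        tags=grid.tags,
        grid=grid,
        provenance={
            "sample_id": spec.sample_id,
            "group": spec.group,
            "seed": spec.seed,
            "source": "synthetic",
        },
    )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) truncated at zero by rejection (means are many SDs
    above zero for all tissue groups, so rejection is cheap)."""
    if sd == 0:
        return float(mean)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)
    raise RuntimeError("truncated-normal rejection failed; check mean/sd")


def sample_cohort(
    n_per_group: int,
    group_params: Mapping[str, tuple[float, float, float, float]] | None = None,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    proton_density: float = DEFAULT_PROTON_DENSITY,
) -> list[PhantomSpec]:
    """Draw a three-group cohort of single-tissue phantom specs.

    Each sample's ground-truth (T1, T2) is drawn from a truncated-at-zero
    normal with its group's mean/SD (default: the per-group reference
    moments). The tumour groups are paired: spec ``i`` of ``NMIBC`` and of
    ``NMIBC_PDT`` share a sample_id, modelling the same physical specimen
    measured before and after photodynamic therapy.

    Seeding: per-sample sub-seeds are spawned from one master
    ``numpy.random.SeedSequence(seed)`` so cohorts are reproducible
    element-wise regardless of evaluation order.
    """
    if n_per_group < 2:
        raise ValueError(f"n_per_group must be >= 2, got {n_per_group}")
    if group_params is None:
        group_params = BLADDER_TISSUE_VALUES
    for g, (_, t1_sd, _, t2_sd) in group_params.items():
        if t1_sd < 0 or t2_sd < 0:
            raise ValueError(f"group {g!r}: SDs must be >= 0")

    root = np.random.SeedSequence(seed)
    children = root.spawn(len(group_params) * n_per_group)
    radius = min(shape) / 5.0
    center = (shape[0] / 2.0, shape[1] / 2.0)
    tissue_mask = _disc_mask(shape, center, radius)

    specs: list[PhantomSpec] = []
    k = 0
    for group in group_params:
        t1_mean, t1_sd, t2_mean, t2_sd = group_params[group]
        for i in range(n_per_group):
            child = children[k]
            k += 1
            sub_seed = int(child.generate_state(1)[0] % 2**31)
            rng = np.random.default_rng(child)
            t1 = _truncated_normal(rng, t1_mean, t1_sd)
            t2 = _truncated_normal(rng, t2_mean, t2_sd)
            # tumour specimens keep one identity across pre-/post-PDT scans
            if group in ("NMIBC", "NMIBC_PDT"):
                sample_id = f"T{i:03d}"
            else:
                sample_id = f"H{i:03d}"
            specs.append(
                PhantomSpec(
                    shape=shape,
                    regions=[
                        PhantomRegion(
                            label="tissue",
                            mask=tissue_mask.copy(),
                            t1_ms=t1,
                            t2_ms=t2,
                            proton_density=proton_density,
                        )
                    ],
                    noise_sigma=noise_sigma,
                    seed=sub_seed,
                    sample_id=sample_id,
                    group=group,
                )
            )
    return specs
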