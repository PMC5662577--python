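"""Synthetic sonogram phantoms and synthetic cohorts.

The clinical images and per-nodule measurements behind the method are
not publicly deposited, so this module provides ground-truth-bearing
stand-ins for both pipeline stages:

* :func:`generate_phantom` draws a blob-shaped "nodule" (low-harmonic
  radial perturbation of a disc) filled with grey speckle on a grey
  speckle background, paints Doppler-like color pixels at controlled
  Bernoulli densities in the peripheral and central zones of a known
  distance-mode partition, and traces the annotation outline around it.
  Every piece of ground truth (interior mask, partition, exact painted
  color counts) is returned, so image I/O, offsetting and VI computation
  can each be checked pixel-for-pixel.

* :func:`generate_cohort` samples per-nodule VI records and GSU
  features whose *marginal* group distributions follow configurable
  per-offset means/SDs and prevalences (defaulting to the originating
  study's summaries).  Regional VIs share a per-nodule latent factor so
  a hypervascular nodule is hypervascular across offsets — the joint
  distribution in real nodules is unknown, so only the marginals (and
  this one physiologically necessary correlation) are emulated.

These phantoms contain no transducer physics: no point-spread function,
no attenuation, no aliasing, and exactly one nodule per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi

from . import study
from .cohort import GroupSummary, GSUFeatures, NoduleRecord, RegionalGroupSummaries
from .errors import ValidationError
from .geometry import RegionPartition, inward_offset
from .image_io import DEFAULT_ANNOTATION_COLOR, AnnotatedImage, ROIMask

#: Doppler-like flow colors (reds for one flow direction, blues for the
#: other).  Every entry has channel spread >= 60 so it is classified as
#: color at any tau <= 60, and none equals the annotation color.
DOPPLER_PALETTE: tuple[tuple[int, int, int], ...] = (
    (200, 30, 30),
    (230, 70, 40),
    (160, 20, 60),
    (40, 80, 220),
    (60, 140, 235),
    (20, 40, 180),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic annotated sonogram.

    The blob radius is ``mean_radius * (1 + sum_k a_k cos(k theta + phi_k))``
    with the harmonic amplitudes ``a_k`` starting at k = 2 (k = 1 would
    only translate the blob).  Amplitudes around 0.1 give the gently
    lobed outlines typical of hand-drawn nodule contours.
    """

    height: int = 256
    width: int = 256
    mean_radius: float = 60.0
    harmonic_amplitudes: tuple[float, ...] = (0.10, 0.06)
    rotation: float = 0.0
    offset_pct: float = float(study.OPTIMUM_OFFSET)
    target_peripheral_vi: float = 30.0
    target_central_vi: float = 10.0
    speckle_mean_background: float = 25.0
    speckle_mean_interior: float = 55.0
    annotation_color: tuple[int, int, int] = DEFAULT_ANNOTATION_COLOR
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("target_peripheral_vi", "target_central_vi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"{name} must be in [0, 100], got {v}")
        margin = 3.0  # outline ring + one safety pixel
        max_r = self.mean_radius * (1.0 + sum(abs(a) for a in self.harmonic_amplitudes))
        if 2 * (max_r + margin) >= min(self.height, self.width):
            raise ValidationError(
                "blob does not fit in the image with the outline margin"
            )


@dataclass(frozen=True)
class PhantomResult:
    image: AnnotatedImage
    roi: ROIMask
    partition: RegionPartition
    color_count_peripheral: int
    color_count_central: int

    @property
    def color_count_total(self) -> int:
        return self.color_count_peripheral + self.color_count_central


def _blob_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    cy, cx = (spec.height - 1) / 2.0, (spec.width - 1) / 2.0
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    rho = np.hypot(dy, dx)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(spec.harmonic_amplitudes))
    r = np.full_like(theta, spec.mean_radius)
    for k, (amp, phi) in enumerate(zip(spec.harmonic_amplitudes, phases), start=2):
        r = r + spec.mean_radius * amp * np.cos(k * (theta + spec.rotation) + phi)
    return rho <= r


def _speckle(shape, mean: float, rng: np.random.Generator) -> np.ndarray:
    # Rayleigh-like envelope magnitude; mean of Rayleigh(scale) is
    # scale * sqrt(pi/2), so divide out to hit the requested mean grey.
    scale = mean / np.sqrt(np.pi / 2.0)
    return np.clip(rng.rayleigh(scale, size=shape), 0, 235).astype(np.uint8)


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Render one annotated phantom with full ground truth."""
    rng = np.random.default_rng(spec.seed)

    interior = _blob_mask(spec, rng)
    roi = ROIMask(interior).validate_nodule()
    partition = inward_offset(roi, spec.offset_pct, mode="distance")

    # grey speckle everywhere (R = G = B, so spread = 0: never "color")
    grey = _speckle((spec.height, spec.width), spec.speckle_mean_background, rng)
    grey_in = _speckle((spec.height, spec.width), spec.speckle_mean_interior, rng)
    grey = np.where(interior, grey_in, grey)
    pixels = np.repeat(grey[:, :, None], 3, axis=2)

    counts = {}
    for name, region, target in (
        ("peripheral", partition.peripheral, spec.target_peripheral_vi),
        ("central", partition.central, spec.target_central_vi),
    ):
        if target > 0.0 and region.is_empty():
            raise ValidationError(
                f"target {name} VI {target}% infeasible: region is empty at "
                f"offset {spec.offset_pct}%"
            )
        idx = np.argwhere(region.grid)
        chosen = idx[rng.random(len(idx)) < target / 100.0]
        palette = np.array(DOPPLER_PALETTE, dtype=np.uint8)
        colors = palette[rng.integers(0, len(palette), size=len(chosen))]
        pixels[chosen[:, 0], chosen[:, 1]] = colors
        counts[name] = len(chosen)

    ring = ndi.binary_dilation(interior, structure=np.ones((3, 3), bool)) & ~interior
    pixels[ring] = spec.annotation_color

    image = AnnotatedImage(
        pixels.astype(np.uint8),
        annotation_color=spec.annotation_color,
        image_id=f"phantom_{spec.seed}",
    )
    return PhantomResult(
        image=image,
        roi=roi,
        partition=partition,
        color_count_peripheral=counts["peripheral"],
        color_count_central=counts["central"],
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Statistical recipe for a synthetic cohort.

    Defaults reproduce the originating study's conditions: 84 benign and
    27 malignant nodules, regional VI marginals per offset from its
    summary table, overall-VI marginals, and its GSU feature
    prevalences.  VI values are drawn from normals truncated to
    [0, 100] *by resampling* (clipping would pile mass at 0 and drag the
    realised means); GSU features are independent Bernoullis within a
    group, since only marginal prevalences are known.

    ``rho`` is the correlation induced by a shared per-nodule latent
    factor across all of a nodule's VI values; 0.7 by default so that a
    nodule hypervascular at one offset tends to be hypervascular at all
    of them (independent values would be physiologically absurd and
    would break representative-image logic).
    """

    n_benign: int = study.N_BENIGN
    n_malignant: int = study.N_MALIGNANT
    regional_summaries: Mapping[float, RegionalGroupSummaries] = field(
        default_factory=lambda: dict(study.REGIONAL_VI_SUMMARIES)
    )
    overall_benign: GroupSummary = study.OVERALL_VI_BENIGN
    overall_malignant: GroupSummary = study.OVERALL_VI_MALIGNANT
    gsu_prevalence_benign: Mapping[str, float] = field(
        default_factory=lambda: dict(study.GSU_PREVALENCE_BENIGN)
    )
    gsu_prevalence_malignant: Mapping[str, float] = field(
        default_factory=lambda: dict(study.GSU_PREVALENCE_MALIGNANT)
    )
    rho: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_benign < 2 or self.n_malignant < 2:
            raise ValidationError("group sizes must be >= 2")
        if not 0.0 <= self.rho <= 1.0:
            raise ValidationError(f"rho must be in [0, 1], got {self.rho}")
        for prev in (self.gsu_prevalence_benign, self.gsu_prevalence_malignant):
            for k, v in prev.items():
                if not 0.0 <= v <= 1.0:
                    raise ValidationError(f"prevalence {k}={v} outside [0, 1]")


def _truncated_normal(
    mean: float,
    sd: float,
    latent: np.ndarray,
    rho: float,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> np.ndarray:
    """value = mean + sd * (rho * z + sqrt(1 - rho^2) * eps), eps resampled
    until the value lands in [0, 100] (z, the nodule's latent factor, is
    held fixed so the cross-offset correlation survives truncation)."""
    w = np.sqrt(1.0 - rho * rho)
    vals = mean + sd * (rho * latent + w * rng.standard_normal(latent.shape))
    if sd == 0.0:
        return np.clip(vals, 0.0, 100.0)
    for _ in range(max_tries):
        bad = (vals < 0.0) | (vals > 100.0)
        if not bad.any():
            return vals
        vals[bad] = mean + sd * (
            rho * latent[bad] + w * rng.standard_normal(int(bad.sum()))
        )
    return np.clip(vals, 0.0, 100.0)  # pathological spec; keep it legal


def generate_cohort(spec: CohortSpec) -> list[NoduleRecord]:
    """Sample a cohort of :class:`NoduleRecord`; reproducible under seed."""
    rng = np.random.default_rng(spec.seed)
    offsets = sorted(spec.regional_summaries)
    records: list[NoduleRecord] = []
    for malignant, n, prefix, overall, prevalence in (
        (False, spec.n_benign, "B", spec.overall_benign, spec.gsu_prevalence_benign),
        (True, spec.n_malignant, "M", spec.overall_malignant, spec.gsu_prevalence_malignant),
    ):
        latent = rng.standard_normal(n)
        overall_vi = _truncated_normal(overall.mean, overall.sd, latent, spec.rho, rng)
        regional: dict[float, tuple[np.ndarray, np.ndarray]] = {}
        for pct in offsets:
            s = spec.regional_summaries[pct]
            per_s = s.peripheral_malignant if malignant else s.peripheral_benign
            cen_s = s.central_malignant if malignant else s.central_benign
            regional[pct] = (
                _truncated_normal(per_s.mean, per_s.sd, latent, spec.rho, rng),
                _truncated_normal(cen_s.mean, cen_s.sd, latent, spec.rho, rng),
            )
        gsu_draws = {
            feat: rng.random(n) < prevalence.get(feat, 0.0)
            for feat in spec.gsu_prevalence_benign
        }
        for i in range(n):
            records.append(
                NoduleRecord(
                    nodule_id=f"{prefix}{i + 1:03d}",
                    malignant=malignant,
                    overall_vi=float(overall_vi[i]),
                    vi_by_offset={
                        pct: (float(regional[pct][0][i]), float(regional[pct][1][i]))
                        for pct in offsets
                    },
                    gsu=GSUFeatures(**{f: bool(gsu_draws[f][i]) for f in gsu_draws}),
                )
            )
    return records
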