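"""Synthetic cervical-cell crop generator with known ground truth.

Each crop contains one cell: an elliptical nucleus on a cytoplasm disc over
a white background, mimicking the factors a latent-variable model of stained
cell images must learn — nucleus size, shape and chromatin density, cytoplasm
hue, and global brightness. The abnormal phenotype follows the cytological
signature of high-grade lesions: enlarged, more eccentric, hyperchromatic
(darker) nuclei.

Ground truth (phenotype parameters and class labels) is returned alongside
the images, so segmentation-, scoring- and clustering-stages can all be
validated without external data.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CellPhenotype",
    "PopulationSpec",
    "LatentPosterior",
    "generate_cell_image",
    "generate_population",
    "generate_latent_fixture",
    "NORMAL_PHENOTYPE_RANGES",
    "ABNORMAL_PHENOTYPE_RANGES",
]


@dataclass(frozen=True)
class CellPhenotype:
    """Rendering parameters for one synthetic cell.

    nucleus_radius : effective radius in pixels (the ellipse has area
        pi * r^2 regardless of eccentricity).
    nucleus_eccentricity : in [0, 1); 0 is a circle.
    nucleus_intensity : HSV value of the nucleus color in [0, 1]; lower is
        darker (hyperchromatic).
    cytoplasm_hue : hue in degrees [0, 360).
    brightness : multiplicative factor applied to the whole image (> 0).
    noise_sd : standard deviation of additive Gaussian pixel noise.
    """

    nucleus_radius: float
    nucleus_eccentricity: float = 0.0
    nucleus_intensity: float = 0.45
    cytoplasm_hue: float = 35.0
    brightness: float = 1.0
    noise_sd: float = 0.0
    is_abnormal: bool = False

    def validate(self, image_size: int) -> None:
        if not (1.0 <= self.nucleus_radius < image_size / 2):
            raise ValueError(
                f"nucleus_radius must be in [1, {image_size / 2}), got {self.nucleus_radius}"
            )
        if not (0.0 <= self.nucleus_eccentricity < 1.0):
            raise ValueError(
                f"nucleus_eccentricity must be in [0, 1), got {self.nucleus_eccentricity}"
            )
        if not (0.0 <= self.cytoplasm_hue < 360.0):
            raise ValueError(f"cytoplasm_hue must be in [0, 360), got {self.cytoplasm_hue}")
        if not self.brightness > 0:
            raise ValueError(f"brightness must be > 0, got {self.brightness}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not (0.0 <= self.nucleus_intensity <= 1.0):
            raise ValueError(
                f"nucleus_intensity must be in [0, 1], got {self.nucleus_intensity}"
            )


# Sampling ranges for the two classes: each entry is (low, high) for a uniform
# draw. Abnormal nuclei are 1.5x larger, 0.2 darker and 0.2 more eccentric
# than normal — the hyperchromatic enlarged-nucleus signal of high-grade
# squamous lesions.
NORMAL_PHENOTYPE_RANGES: dict[str, tuple[float, float]] = {
    "nucleus_radius": (13.0, 19.0),
    "nucleus_eccentricity": (0.0, 0.35),
    "nucleus_intensity": (0.40, 0.55),
    "cytoplasm_hue": (25.0, 45.0),
    "brightness": (0.9, 1.1),
    "noise_sd": (0.02, 0.03),
}
ABNORMAL_PHENOTYPE_RANGES: dict[str, tuple[float, float]] = {
    "nucleus_radius": (13.0 * 1.5, 19.0 * 1.5),
    "nucleus_eccentricity": (0.2, 0.55),
    "nucleus_intensity": (0.20, 0.35),
    "cytoplasm_hue": (25.0, 45.0),
    "brightness": (0.9, 1.1),
    "noise_sd": (0.02, 0.03),
}


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of a two-class synthetic cell population."""

    n_normal: int
    n_abnormal: int
    image_size: int = 256
    seed: int = 0
    normal_ranges: dict = field(default_factory=lambda: dict(NORMAL_PHENOTYPE_RANGES))
    abnormal_ranges: dict = field(default_factory=lambda: dict(ABNORMAL_PHENOTYPE_RANGES))
    center_jitter: float = 6.0  # max |offset| of the cell center from image center, px

    def validate(self) -> None:
        if self.n_normal < 0 or self.n_abnormal < 0:
            raise ValueError("class counts must be non-negative")
        if self.image_size < 8:
            raise ValueError("image_size too small")


def _hsv_rgb(h_deg: float, s: float, v: float) -> np.ndarray:
    return np.array(colorsys.hsv_to_rgb((h_deg % 360.0) / 360.0, s, v))


def _ellipse_mask(size, center, a, b, angle):
    """Anti-aliased coverage in [0,1] for an ellipse with semi-axes a, b."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dx, dy = xx - center[0], yy - center[1]
    c, s = np.cos(angle), np.sin(angle)
    u = (c * dx + s * dy) / a
    v = (-s * dx + c * dy) / b
    # signed distance (approximate, in px) from the boundary; 1-px soft edge
    q = np.sqrt(u**2 + v**2)
    dist = (q - 1.0) * min(a, b)
    return np.clip(0.5 - dist, 0.0, 1.0)


def generate_cell_image(
    phenotype: CellPhenotype,
    image_size: int = 256,
    seed: int = 0,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Render one RGB cell crop in [0, 1], deterministically for a seed.

    The nucleus is an anti-aliased filled ellipse of area pi * r^2 (semi-axes
    a = r / (1-e^2)^(1/4), b = r * (1-e^2)^(1/4)) drawn at `center` (default:
    image center) at a seed-determined orientation, on a cytoplasm disc of
    the requested hue; the whole image is scaled by `brightness` and Gaussian
    noise of sd `noise_sd` is added before clipping to [0, 1].
    """
    phenotype.validate(image_size)
    rng = np.random.default_rng(seed)
    if center is None:
        center = (image_size / 2.0, image_size / 2.0)

    e = phenotype.nucleus_eccentricity
    ratio = (1.0 - e**2) ** 0.25
    a = phenotype.nucleus_radius / ratio
    b = phenotype.nucleus_radius * ratio
    angle = rng.uniform(0.0, np.pi)

    cyto_radius = rng.uniform(0.32, 0.42) * image_size
    cyto_color = _hsv_rgb(phenotype.cytoplasm_hue, 0.35, 0.88)
    nuc_color = _hsv_rgb(phenotype.cytoplasm_hue, 0.55, phenotype.nucleus_intensity)

    img = np.ones((image_size, image_size, 3), dtype=np.float64)
    cyto = _ellipse_mask(image_size, center, cyto_radius, cyto_radius, 0.0)
    img = img * (1 - cyto[..., None]) + cyto[..., None] * cyto_color
    nuc = _ellipse_mask(image_size, center, a, b, angle)
    img = img * (1 - nuc[..., None]) + nuc[..., None] * nuc_color

    img = img * phenotype.brightness
    if phenotype.noise_sd > 0:
        img = img + rng.normal(0.0, phenotype.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


def _sample_phenotype(rng: np.random.Generator, ranges: dict, abnormal: bool) -> CellPhenotype:
    draw = {k: rng.uniform(lo, hi) for k, (lo, hi) in ranges.items()}
    return CellPhenotype(is_abnormal=abnormal, **draw)


def generate_population(
    spec: PopulationSpec,
) -> tuple[dict[str, np.ndarray], pd.DataFrame, list[CellPhenotype]]:
    """Generate a labelled cell population and its annotation table.

    Returns (images, annotations, phenotypes). `images` maps image_id to an
    RGB array; the annotation table has columns image_id, center_x, center_y,
    class with classes "NILM" (normal) and "ABNORMAL". Deterministic for a
    given spec (including seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    images: dict[str, np.ndarray] = {}
    rows = []
    phenotypes: list[CellPhenotype] = []
    labels = ["NILM"] * spec.n_normal + ["ABNORMAL"] * spec.n_abnormal
    for i, label in enumerate(labels):
        abnormal = label == "ABNORMAL"
        ranges = spec.abnormal_ranges if abnormal else spec.normal_ranges
        ph = _sample_phenotype(rng, ranges, abnormal)
        jitter = rng.uniform(-spec.center_jitter, spec.center_jitter, size=2)
        cx = spec.image_size / 2.0 + jitter[0]
        cy = spec.image_size / 2.0 + jitter[1]
        img_seed = int(rng.integers(0, 2**31 - 1))
        image_id = f"cell_{i:05d}"
        images[image_id] = generate_cell_image(
            ph, image_size=spec.image_size, seed=img_seed, center=(cx, cy)
        )
        rows.append(
            {
                "image_id": image_id,
                "center_x": int(round(cx)),
                "center_y": int(round(cy)),
                "class": label,
            }
        )
        phenotypes.append(ph)
    annotations = pd.DataFrame(rows, columns=["image_id", "center_x", "center_y", "class"])
    return images, annotations, phenotypes


@dataclass(frozen=True)
class LatentPosterior:
    """Diagonal-Gaussian posterior q(z|x): a mean and per-dimension stddev."""

    mean: np.ndarray
    stddev: np.ndarray

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=np.float64)
        stddev = np.asarray(self.stddev, dtype=np.float64)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "stddev", stddev)
        if mean.shape != stddev.shape or mean.ndim != 1:
            raise ValueError("mean and stddev must be 1-D vectors of equal length")
        if not np.all(np.isfinite(mean)):
            raise ValueError("posterior mean must be finite")
        if not np.all(stddev > 0):
            raise ValueError("posterior stddev must be strictly positive")

    @property
    def dim(self) -> int:
        return self.mean.shape[0]


def generate_latent_fixture(
    n: int,
    dim: int,
    component_means: list,
    component_stddevs: list,
    assignment,
    seed: int = 0,
) -> tuple[list[LatentPosterior], np.ndarray]:
    """Draw latent posteriors from a Gaussian mixture with known labels.

    Posterior i has mean ~ N(component_means[k], diag(component_stddevs[k]^2))
    and stddev = component_stddevs[k], where k = assignment[i]. Returns the
    posteriors and the label array.
    """
    means = [np.broadcast_to(np.asarray(m, float), (dim,)) for m in component_means]
    stds = [np.broadcast_to(np.asarray(s, float), (dim,)) for s in component_stddevs]
    if len(means) != len(stds):
        raise ValueError("component_means and component_stddevs length mismatch")
    for s in stds:
        if not np.all(s > 0):
            raise ValueError("component stddevs must be strictly positive")
    assignment = np.asarray(assignment, dtype=int)
    if assignment.shape != (n,):
        raise ValueError(f"assignment must have shape ({n},)")
    rng = np.random.default_rng(seed)
    posteriors = []
    for k in assignment:
        mu = rng.normal(means[k], stds[k])
        posteriors.append(LatentPosterior(mean=mu, stddev=stds[k].copy()))
    return posteriors, assignment
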