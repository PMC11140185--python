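"""Single-channel experimental-pattern workflow (CDIMA chemistry).

Experimental Turing patterns -- e.g. the chlorine dioxide-iodine-malonic
acid (CDIMA) reaction imaged through emitted light -- come as one grayscale
image with an unknown concentration scale, while the Lengyel-Epstein model
describes two concentrations u (activator, iodide) and v (inhibitor,
chlorite).  The workflow here:

1. rescales the observed image to a free-scale variable W in [0, 1];
2. posits linear maps u = kappa_u*W + gamma_u, v = kappa_v*W + gamma_v
   (patterns in phase for kappa > 0, antiphase for kappa < 0);
3. trains two RBF subnetworks that each approximate W, maps them through
   the scale/shift parameters inside the PDE loss of the chosen
   Lengyel-Epstein variant, and co-optimizes model parameters (and
   optionally the scale parameters, which makes the problem
   underdetermined -- hence the default protocol fixes them or starts near
   a published set);
4. tries both variants (diffusion ratio on the u- or the v-Laplacian) and
   keeps the one yielding physically admissible (non-negative) constants,
   which simultaneously identifies whether the observed channel is the
   activator or the inhibitor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .rbf_pinn import RBFNet, TrainConfig, _training_loop
from .metrics import dominant_wavelength
from .models import get_model
from .simulate import Pattern

__all__ = [
    "ScaleMap",
    "FreeScalePattern",
    "ChemInit",
    "load_pattern_image",
    "free_scale",
    "apply_scale",
    "best_scale_map",
    "infer_from_single_channel",
    "select_variant",
    "DegenerateRangeError",
    "InvalidScaleError",
    "ImageFormatError",
]


class DegenerateRangeError(ValueError):
    """The image or grid has zero range and cannot be rescaled to [0, 1]."""


class InvalidScaleError(ValueError):
    """A zero scale parameter collapses the linear map."""


class ImageFormatError(ValueError):
    """Unsupported image format (e.g. color without conversion)."""


@dataclass
class ScaleMap:
    """Per-species scale and shift of the free-scale variable."""

    kappa_u: float
    gamma_u: float
    kappa_v: float
    gamma_v: float

    def as_array(self) -> np.ndarray:
        return np.array([self.kappa_u, self.gamma_u,
                         self.kappa_v, self.gamma_v], float)

    @classmethod
    def from_array(cls, a) -> "ScaleMap":
        return cls(*(float(x) for x in a))

    def validate(self):
        if self.kappa_u == 0 or self.kappa_v == 0:
            raise InvalidScaleError("scale parameters kappa must be nonzero")


@dataclass
class FreeScalePattern:
    """An observed pattern rescaled to [0, 1]."""

    W: np.ndarray
    source: str = "synthetic"
    crop: tuple[int, int, int] | None = None

    def __post_init__(self):
        self.W = np.asarray(self.W, float)
        if not np.all(np.isfinite(self.W)):
            raise ValueError("W contains non-finite values")
        if not (np.isclose(self.W.min(), 0.0, atol=1e-12)
                and np.isclose(self.W.max(), 1.0, atol=1e-12)):
            raise ValueError("W must span [0, 1]; use free_scale() first")


def free_scale(grid, source: str = "synthetic",
               crop: tuple[int, int, int] | None = None) -> FreeScalePattern:
    """Rescale any grid to the [0, 1] free-scale variable W."""
    grid = np.asarray(grid, float)
    lo, hi = float(grid.min()), float(grid.max())
    if hi == lo:
        raise DegenerateRangeError("grid has zero range; cannot rescale")
    return FreeScalePattern(W=(grid - lo) / (hi - lo), source=source, crop=crop)


def load_pattern_image(path, crop: tuple[int, int, int] | None = None,
                       resize: int | None = None,
                       convert_color: bool = False) -> FreeScalePattern:
    """Load a grayscale 8/16-bit image as a free-scale pattern.

    ``crop`` is a square pixel box (row0, col0, size) applied before
    rescaling; ``resize`` resamples to resize x resize by area averaging,
    which preserves local mean intensity.
    """
    from PIL import Image

    img = Image.open(path)
    if img.mode not in ("L", "I", "I;16", "F"):
        if not convert_color:
            raise ImageFormatError(
                f"image mode '{img.mode}' is not single-channel grayscale; "
                "pass convert_color=True to convert")
        img = img.convert("L")
    arr = np.asarray(img, dtype=float)
    if crop is not None:
        r0, c0, size = (int(x) for x in crop)
        if r0 < 0 or c0 < 0 or r0 + size > arr.shape[0] or c0 + size > arr.shape[1]:
            raise IndexError(f"crop {crop} outside image {arr.shape}")
        arr = arr[r0:r0 + size, c0:c0 + size]
    if resize is not None:
        img2 = Image.fromarray(arr)
        arr = np.asarray(img2.resize((resize, resize), Image.BOX), dtype=float)
    return free_scale(arr, source=str(path), crop=crop)


def apply_scale(W, scale_map: ScaleMap) -> tuple[np.ndarray, np.ndarray]:
    """Map the free-scale variable to model concentrations (u, v)."""
    scale_map.validate()
    W = np.asarray(W, float)
    return (W * scale_map.kappa_u + scale_map.gamma_u,
            W * scale_map.kappa_v + scale_map.gamma_v)


def best_scale_map(W, u, v) -> ScaleMap:
    """Least-squares linear maps W -> u and W -> v (ground-truth scales for
    synthetic closed-loop experiments)."""
    W = np.asarray(W, float).ravel()
    A = np.column_stack([W, np.ones_like(W)])
    ku, gu = np.linalg.lstsq(A, np.asarray(u, float).ravel(), rcond=None)[0]
    kv, gv = np.linalg.lstsq(A, np.asarray(v, float).ravel(), rcond=None)[0]
    return ScaleMap(float(ku), float(gu), float(kv), float(gv))


@dataclass
class ChemInit:
    """Starting point for single-channel inference.

    With free scale parameters the problem is underdetermined (shift
    parameters trade off against basal production rates), so the default
    protocol fixes the scale map; alternatively ``fix_scales=False`` trains
    kappa/gamma too, with ``fix_gamma_u`` pinning the one shift that feeds
    straight into the constant production term.
    """

    theta0: np.ndarray = field(default_factory=lambda: np.ones(3))
    scale: ScaleMap = field(default_factory=lambda: ScaleMap(1.0, 0.0, -1.0, 1.0))
    fix_scales: bool = True
    fix_gamma_u: bool = True


def infer_from_single_channel(fsp: FreeScalePattern, le_variant: str = "a",
                              init: ChemInit | None = None,
                              config: TrainConfig | None = None,
                              dx: float = 0.2, bc: str = "noflux"):
    """Joint inference of Lengyel-Epstein parameters (and scale map) from W.

    Returns ``(history, InferenceResult)``; the result's ``extra`` carries
    the final :class:`ScaleMap` and the two trained subnetworks.
    """
    init = init or ChemInit()
    config = config or TrainConfig()
    init.scale.validate()
    if le_variant not in ("a", "b"):
        raise ValueError("le_variant must be 'a' or 'b'")
    model = get_model(f"lengyel_epstein_{le_variant}")
    carrier = Pattern(u=fsp.W, v=fsp.W, dx=dx, bc=bc,
                      meta={"model": model.name, "source": fsp.source})
    carrier.single_channel = True
    rng = np.random.default_rng(config.seed)
    span = (carrier.n - 1) * dx
    sigma0 = dominant_wavelength(fsp.W, dx) / 4.0
    net_u = RBFNet.init(config.nodes, span, sigma0, rng)
    net_v = RBFNet.init(config.nodes, span, sigma0, rng)
    if init.fix_scales:
        train_scales = (False, False, False, False)
    else:
        train_scales = (True, not init.fix_gamma_u, True, True)
    history, result = _training_loop(
        net_u, net_v, carrier, model, config,
        scale=init.scale.as_array(), train_scales=train_scales,
        theta0=np.asarray(init.theta0, float))
    result.method = f"rbf_pinn_chem_{le_variant}"
    result.extra["scale_map"] = ScaleMap.from_array(result.extra["scale"])
    result.extra["variant"] = le_variant
    return history, result


def select_variant(fsp: FreeScalePattern, init: ChemInit | None = None,
                   config: TrainConfig | None = None, dx: float = 0.2,
                   bc: str = "noflux") -> dict:
    """Train both Lengyel-Epstein variants and keep the physical one.

    A variant is admissible when every inferred constant is non-negative.
    Variant ``a`` (ratio on the u-Laplacian) winning implies the observed
    channel is the activator species (iodide in the CDIMA system); variant
    ``b`` implies the inhibitor.  Returns a dict with the chosen variant,
    the species identification, and both inference results.
    """
    results = {}
    for variant in ("a", "b"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            _, res = infer_from_single_channel(
                fsp, le_variant=variant, init=init, config=config, dx=dx, bc=bc)
        results[variant] = res
    admissible = {v: bool(np.all(results[v].beta_hat >= 0)) for v in results}
    chosen = None
    if admissible["a"] and not admissible["b"]:
        chosen = "a"
    elif admissible["b"] and not admissible["a"]:
        chosen = "b"
    elif admissible["a"] and admissible["b"]:
        # both physical: prefer the one with the smaller PDE residual
        chosen = min(results, key=lambda v: results[v].residual_norm)
    identification = {None: "undetermined", "a": "activator",
                      "b": "inhibitor"}[chosen]
    return {"variant": chosen, "identification": identification,
            "admissible": admissible, "results": results}
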