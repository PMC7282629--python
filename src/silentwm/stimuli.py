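"""Synthesis of the visual stimuli driving the model.

All stimuli are 128x128 grey-scale images on a mid-grey background,
restricted to a circular aperture of diameter 128.  Luminance follows the
8-bit convention with the background (RGB 128) mapped to 0 and the full
range to [-1, 1].  Memory items and probes are sine-wave gratings with a
spatial frequency of 0.034 cycles per pixel; the impulse stimulus is a
bull's-eye (a radial sinusoid at the same spatial frequency) at twice the
grating contrast, or a uniform white disc.

Orientations are canonicalized to (-90, 90] degrees *before* the phase is
applied along the canonical axis, so that a grating at theta and one at
theta+180 are pixel-identical for every phase -- the physical
indistinguishability the rest of the model relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

IMAGE_SIZE = 128
SPATIAL_FREQ = 0.034  # cycles per pixel
GRATING_AMPLITUDE = 0.5  # peak luminance deviation of a contrast-1 grating
IMPULSE_CONTRAST = 2.0  # bull's-eye contrast relative to the gratings
GREY60_SCALE = 0.6  # ring amplitude of the grey bull's-eye vs the black one
CANONICAL_PHASE = np.pi / 2  # cosine phase: even-symmetric about the centre

#: signed angular differences (deg) between item and probe per design
DESIGN_DELTAS = {
    "exp1": (3, 7, 12, 18, 25, 33, 42),
    "exp2": (5, 10, 16, 24, 32, 40),
    "exp3": (16,),
}


@dataclass
class StimulusImage:
    """A 128x128 luminance image plus the parameters that generated it."""

    pixels: np.ndarray
    kind: str  # grating | bullseye | uniform | blank
    orientation: Optional[float] = None  # degrees in (-90, 90]
    phase: Optional[float] = None  # radians
    contrast: float = 1.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (IMAGE_SIZE, IMAGE_SIZE):
            raise ValueError(f"expected {IMAGE_SIZE}x{IMAGE_SIZE} pixels")

    def to_uint8(self) -> np.ndarray:
        """Map [-1, 1] luminance back to 8-bit grey levels (background 128)."""
        return np.clip(np.round(128 + 127 * self.pixels), 0, 255).astype(np.uint8)


def _grid():
    c = (IMAGE_SIZE - 1) / 2.0
    y, x = np.mgrid[0:IMAGE_SIZE, 0:IMAGE_SIZE]
    return x - c, y - c


def aperture_mask() -> np.ndarray:
    """Boolean mask of the circular aperture (diameter = image size)."""
    x, y = _grid()
    return x**2 + y**2 <= (IMAGE_SIZE / 2.0) ** 2


def wrap_orientation(theta_deg: float) -> float:
    """Wrap an orientation in degrees into the canonical range (-90, 90].

    The result is quantized to a nano-degree grid so that theta and
    theta + 180 map to the bit-identical canonical value (adding 180 in
    floating point perturbs the low bits); gratings built from the two are
    then pixel-identical, as the physics demands.
    """
    wrapped = (float(theta_deg) + 90.0) % 180.0 - 90.0
    wrapped = round(wrapped * 1e9) / 1e9
    if wrapped <= -90.0:
        wrapped += 180.0
    return wrapped


def make_grating(orientation_deg: float, phase: float = CANONICAL_PHASE,
                 contrast: float = 1.0) -> StimulusImage:
    """Sine-wave grating inside the aperture on a zero (grey) background.

    ``contrast`` multiplies the standard grating amplitude; the default of 1
    yields peak luminance +-0.5 so that the double-contrast impulse spans the
    full luminance range.
    """
    if not np.isfinite(orientation_deg):
        raise ValueError("orientation must be finite")
    if contrast < 0:
        raise ValueError("contrast must be >= 0")
    theta = wrap_orientation(orientation_deg)
    rad = np.deg2rad(theta)
    x, y = _grid()
    # coordinate along the canonical axis (perpendicular to the stripes)
    u = x * np.cos(rad) + y * np.sin(rad)
    pix = GRATING_AMPLITUDE * contrast * np.sin(2 * np.pi * SPATIAL_FREQ * u + phase)
    pix[~aperture_mask()] = 0.0
    return StimulusImage(pix, "grating", orientation=theta, phase=float(phase),
                         contrast=float(contrast))


def make_impulse(style: str = "bullseye-black", phase: float = -np.pi / 2) -> StimulusImage:
    """Impulse stimulus: a bull's-eye or a uniform white disc.

    The bull's-eye is a radial sinusoid at the grating spatial frequency and
    twice the grating contrast; the default radial phase makes its centre
    dark.  ``bullseye-grey60`` scales the ring amplitude to 60% of the black
    variant.  ``uniform-white`` is a flat disc at full luminance.
    """
    mask = aperture_mask()
    if style == "uniform-white":
        pix = np.where(mask, 1.0, 0.0)
        return StimulusImage(pix, "uniform", contrast=1.0)
    if style not in ("bullseye-black", "bullseye-grey60"):
        raise ValueError(f"unknown impulse style: {style!r}")
    x, y = _grid()
    r = np.hypot(x, y)
    amp = GRATING_AMPLITUDE * IMPULSE_CONTRAST
    if style == "bullseye-grey60":
        amp *= GREY60_SCALE
    pix = amp * np.sin(2 * np.pi * SPATIAL_FREQ * r + phase)
    pix[~mask] = 0.0
    return StimulusImage(pix, "bullseye", phase=float(phase),
                         contrast=IMPULSE_CONTRAST * (GREY60_SCALE if style.endswith("grey60") else 1.0))


def make_blank() -> StimulusImage:
    """Uniform background image (all zeros)."""
    return StimulusImage(np.zeros((IMAGE_SIZE, IMAGE_SIZE)), "blank", contrast=0.0)


@dataclass
class TrialStimuli:
    """Orientations/phases for one trial: one item and probe per module."""

    item_deg: np.ndarray  # per-module item orientation
    probe_deg: np.ndarray  # per-module probe orientation
    delta_deg: np.ndarray  # signed probe-minus-item difference per module
    item_phase: np.ndarray
    probe_phase: np.ndarray
    impulse_phase: float = -np.pi / 2


def sample_trial_orientations(design: str, rng: np.random.Generator,
                              n_modules: int = 2,
                              constant_phase: Optional[float] = None) -> TrialStimuli:
    """Draw item/probe orientations and phases for one trial.

    The item orientation is uniform over (-90, 90]; the probe differs by a
    signed angular difference drawn uniformly from the design's difference
    set, clockwise and counter-clockwise balanced by the uniform sign draw.
    Phases are independent uniform draws per stimulus unless
    ``constant_phase`` pins them (used by the representation analyses).
    """
    if design not in DESIGN_DELTAS:
        raise ValueError(f"unknown design: {design!r}")
    deltas = DESIGN_DELTAS[design]
    items = np.array([wrap_orientation(rng.uniform(-90.0, 90.0))
                      for _ in range(n_modules)])
    mags = rng.choice(deltas, size=n_modules)
    signs = rng.choice([-1.0, 1.0], size=n_modules)
    delta = mags * signs
    probes = np.array([wrap_orientation(t + d) for t, d in zip(items, delta)])
    if constant_phase is None:
        item_phase = rng.uniform(0, 2 * np.pi, size=n_modules)
        probe_phase = rng.uniform(0, 2 * np.pi, size=n_modules)
    else:
        item_phase = np.full(n_modules, float(constant_phase))
        probe_phase = np.full(n_modules, float(constant_phase))
    return TrialStimuli(items, probes, delta, item_phase, probe_phase)


def save_png(image: StimulusImage, path) -> None:
    """Write the image as an 8-bit grey-scale PNG (for inspection only)."""
    from PIL import Image

    Image.fromarray(image.to_uint8(), mode="L").save(path)
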