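"""Gabor encoder bank and the SVD-derived low-dimensional image basis.

The sensory populations see the world through a bank of randomly
parameterized two-dimensional Gabor filters (sinusoidal plane wave times a
Gaussian envelope), the classic model of simple-cell receptive fields.  To
obtain a compact vector code, a matrix T is assembled whose rows are both
the task stimuli and the Gabor filters; its top-D right-singular directions
W (D = 24 by default) form an orthonormal pixel-space basis.  Images are
encoded as v = scale * W' @ pixels; neuron encoders are E = G W (rows
renormalized); and the "ideal vectors" R are the encodings of canonical
gratings at 1-degree steps, the reference points for all cosine-similarity
analyses.

The overall ``scale`` is chosen so a full-contrast canonical grating has
unit norm, putting stimulus vectors on the natural radius-1 scale of the
neural populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.utils.extmath import randomized_svd

from .stimuli import (CANONICAL_PHASE, IMAGE_SIZE, SPATIAL_FREQ, aperture_mask,
                      make_grating, make_impulse)

D_DEFAULT = 24
N_GABORS_DEFAULT = 1000


def generate_gabor_bank(n_filters: int, image_size: int = IMAGE_SIZE,
                        rng: np.random.Generator | None = None,
                        d: int = D_DEFAULT) -> np.ndarray:
    """Random Gabor filters as an (n_filters, image_size**2) matrix.

    Centres are uniform in the aperture, orientation uniform over [0, pi),
    phase uniform over [0, 2*pi), spatial frequency log-uniform within a
    factor of two of the stimulus frequency, and the Gaussian envelope sigma
    uniform in [8, 32] pixels.  Rows are normalized to unit length.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_filters < d:
        raise ValueError(f"need at least D={d} filters, got {n_filters}")
    c = (image_size - 1) / 2.0
    y, x = np.mgrid[0:image_size, 0:image_size]
    x = (x - c).ravel()
    y = (y - c).ravel()
    radius = image_size / 2.0

    # rejection-free uniform draws in the disc; independent per-filter params
    rr = radius * np.sqrt(rng.uniform(size=n_filters))
    ang = rng.uniform(0, 2 * np.pi, size=n_filters)
    cx, cy = rr * np.cos(ang), rr * np.sin(ang)
    theta = rng.uniform(0, np.pi, size=n_filters)
    phase = rng.uniform(0, 2 * np.pi, size=n_filters)
    freq = SPATIAL_FREQ * np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=n_filters))
    sigma = rng.uniform(8.0, 32.0, size=n_filters)

    dx = x[None, :] - cx[:, None]
    dy = y[None, :] - cy[:, None]
    ct, st = np.cos(theta)[:, None], np.sin(theta)[:, None]
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    G = (np.exp(-(u**2 + v**2) / (2 * sigma[:, None] ** 2))
         * np.sin(2 * np.pi * freq[:, None] * u + phase[:, None]))
    G /= np.linalg.norm(G, axis=1, keepdims=True)
    return G


def _canonical_gratings(step_deg: float = 1.0, phases=(0.0, np.pi / 2)) -> np.ndarray:
    thetas = np.arange(-89.0, 90.0 + 1e-9, step_deg)
    imgs = [make_grating(t, ph).pixels.ravel() for t in thetas for ph in phases]
    return np.array(imgs)


@dataclass
class VisualBasis:
    """Image <-> vector codec shared by one module's populations."""

    G: np.ndarray  # (n_gabors, n_pixels) unit-norm Gabor filters
    W: np.ndarray  # (n_pixels, D) orthonormal pixel-space basis
    E: np.ndarray  # (n_gabors, D) unit-norm neuron encoders
    R: np.ndarray  # (180, D) ideal vectors for theta = -89..90 deg
    R_theta: np.ndarray  # orientations (deg) of the rows of R
    singular_values: np.ndarray
    scale: float  # image-vector scaling: unit norm for a canonical grating
    D: int = D_DEFAULT
    seed: int | None = None

    def encode_image(self, image) -> np.ndarray:
        """Project an image (StimulusImage or pixel array) to a D-vector."""
        pix = getattr(image, "pixels", image)
        pix = np.asarray(pix, dtype=float)
        if pix.shape != (IMAGE_SIZE, IMAGE_SIZE):
            raise ValueError("image size does not match basis")
        return self.scale * (pix.ravel() @ self.W)

    def ideal_vector(self, theta_deg: float, phase: float = CANONICAL_PHASE) -> np.ndarray:
        """Encoding of a full-contrast grating at the given orientation/phase."""
        return self.encode_image(make_grating(theta_deg, phase))


def build_basis(G: np.ndarray, d: int = D_DEFAULT,
                extra_images: np.ndarray | None = None,
                step_deg: float = 1.0,
                random_state: int = 0,
                seed: int | None = None) -> VisualBasis:
    """Assemble T from stimuli + Gabors, take its top-D SVD, derive E and R.

    The stimulus block contains the task's memoranda -- gratings at
    ``step_deg`` orientation steps in two quadrature phases (which together
    span every phase at each orientation); ``extra_images`` rows may be
    appended.  The task-neutral impulse stimuli are deliberately not part
    of T: the basis is built for what must be remembered, and the impulse
    is only represented through its overlap with that code.  The
    right-singular directions of T live in pixel space and form W.
    """
    stim = _canonical_gratings(step_deg=step_deg)
    blocks = [stim, G]
    if extra_images is not None:
        blocks.append(np.atleast_2d(extra_images))
    T = np.vstack(blocks)
    # normalize rows so images and unit-norm Gabor filters weigh in equally
    T = T / np.linalg.norm(T, axis=1, keepdims=True)
    if min(T.shape) < d:
        raise ValueError(f"rank of T cannot reach D={d}")
    # top-d singular directions; T rows are samples, columns pixels
    _, S, Vt = randomized_svd(T, n_components=d, n_iter=7,
                              random_state=random_state)
    if S[d - 1] <= 1e-12 * S[0]:
        raise ValueError(f"T is rank-deficient below D={d}")
    W = Vt.T  # (n_pixels, d), orthonormal columns

    E = G @ W
    norms = np.linalg.norm(E, axis=1, keepdims=True)
    E = E / np.maximum(norms, 1e-300)

    thetas = np.arange(-89.0, 91.0, 1.0)
    R_raw = np.array([make_grating(t, CANONICAL_PHASE).pixels.ravel() @ W
                      for t in thetas])
    scale = 1.0 / np.mean(np.linalg.norm(R_raw, axis=1))
    R = scale * R_raw
    return VisualBasis(G=G, W=W, E=E, R=R, R_theta=thetas,
                       singular_values=S, scale=float(scale), D=d, seed=seed)


def make_basis(n_gabors: int = N_GABORS_DEFAULT, d: int = D_DEFAULT,
               rng: np.random.Generator | int | None = None,
               step_deg: float = 1.0) -> VisualBasis:
    """Convenience constructor: draw a Gabor bank and build its basis."""
    seed = None
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    elif rng is None:
        rng = np.random.default_rng()
    G = generate_gabor_bank(n_gabors, rng=rng, d=d)
    svd_state = int(rng.integers(2**31 - 1))
    return build_basis(G, d=d, step_deg=step_deg, random_state=svd_state, seed=seed)


def save_basis(basis: VisualBasis, path) -> None:
    """Persist the basis (G, W, E, R, spectrum, seed) to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        for name in ("G", "W", "E", "R", "R_theta", "singular_values"):
            f.create_dataset(name, data=getattr(basis, name))
        f.attrs["scale"] = basis.scale
        f.attrs["D"] = basis.D
        if basis.seed is not None:
            f.attrs["seed"] = basis.seed


def load_basis(path) -> VisualBasis:
    import h5py

    with h5py.File(path, "r") as f:
        data = {name: f[name][()] for name in
                ("G", "W", "E", "R", "R_theta", "singular_values")}
        return VisualBasis(scale=float(f.attrs["scale"]), D=int(f.attrs["D"]),
                           seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
                           **data)
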