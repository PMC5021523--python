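"""Image-based surround/attention simulation.

A model neuron sits on every pixel of a grayscale image.  Each neuron
pools local contrast under a narrow excitatory Gaussian (sigma 8 px) and a
wide suppressive Gaussian (sigma 40 px) and responds with the ratio
E / (S + semisaturation).  The classical receptive field (cRF) is the disc
of radius 16 px (two excitatory s.d.); neurons "without a surround" keep
the identical suppressive weights inside the cRF but receive no
suppression from beyond it.  Spatial attention is a Gaussian gain field
(sigma 5 px, amplitude 6) that multiplies the contrast input at each pixel
before both poolings — the image analogue of the attention gain beta
multiplying both L and alpha in the spiking model.  The attention
modulation of each neuron is (Ratt - R)/(Ratt + R).

The simulation illustrates why a suppressive surround amplifies attention:
with a wide surround, the attention field boosts excitation at the locus
much more than the broadly-pooled suppression, so the ratio moves; without
a surround both pools are boosted almost equally and the modulation is
weak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve


@dataclass
class ImageModelConfig:
    """Spatial scales (pixels) and gains of the image model.

    Defaults follow the illustration parameters: excitatory sigma 8,
    suppressive sigma 40, cRF radius 16 (two excitatory s.d.), attention
    kernel sigma 5 with amplitude 6.  ``contrast_sigma`` is the fine scale
    at which pixelwise local contrast is measured before pooling;
    ``semisaturation`` prevents division by zero on blank regions.
    """

    sigma_exc: float = 8.0
    sigma_sup: float = 40.0
    crf_radius: float = 16.0
    attention_sigma: float = 5.0
    attention_amplitude: float = 6.0
    surround_enabled: bool = True
    semisaturation: float = 1e-3
    contrast_sigma: float = 2.0
    kernel_truncate: float = 3.0

    def __post_init__(self) -> None:
        for name in ("sigma_exc", "sigma_sup", "crf_radius", "attention_sigma",
                     "contrast_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.attention_amplitude < 0 or self.semisaturation <= 0:
            raise ValueError("amplitude must be >= 0 and semisaturation > 0")


def as_grayscale(image: np.ndarray) -> np.ndarray:
    """Coerce an image to float grayscale in [0, 1] (warns on color input)."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        warnings.warn("color image converted to grayscale by channel mean")
        img = img.mean(axis=2)
    if img.ndim != 2:
        raise ValueError("image must be 2-d (or 3-d color)")
    if img.max() > 1.0:
        img = img / 255.0
    return np.clip(img, 0.0, 1.0)


def gaussian_kernel(sigma: float, truncate: float = 3.0,
                    crf_radius: float | None = None) -> np.ndarray:
    """Normalized 2-d Gaussian kernel, optionally zeroed beyond a cRF radius.

    When ``crf_radius`` is given the weights outside the radius are set to
    zero without renormalizing, so the within-cRF suppression is unchanged.
    """
    r = int(np.ceil(truncate * sigma))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    k = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    k /= k.sum()
    if crf_radius is not None:
        k = np.where(np.sqrt(xx**2 + yy**2) <= crf_radius, k, 0.0)
    return k


def _pool(field: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return fftconvolve(field, kernel, mode="same")


def local_contrast(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-weighted RMS contrast per pixel.

    sqrt of the Gaussian-weighted local luminance variance, normalized by
    the local mean luminance (Weber-style); uniform regions score 0.
    """
    img = as_grayscale(image)
    k = gaussian_kernel(sigma)
    # normalized convolution: image borders keep unit effective kernel mass
    mass = np.maximum(_pool(np.ones_like(img), k), 1e-12)
    mean = _pool(img, k) / mass
    var = np.maximum(_pool(img**2, k) / mass - mean**2, 0.0)
    var[var < 1e-12] = 0.0  # numerical floor: uniform regions are exactly flat
    return np.sqrt(var) / np.maximum(mean, 1e-6)


def attention_gain(shape: tuple[int, int], locus: tuple[int, int],
                   sigma: float, amplitude: float) -> np.ndarray:
    """Multiplicative gain field 1 + A*exp(-d^2 / 2 sigma^2) around a locus."""
    r, c = locus
    if not (0 <= r < shape[0] and 0 <= c < shape[1]):
        raise ValueError(f"attention locus {locus} outside image {shape}")
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    d2 = (yy - r) ** 2 + (xx - c) ** 2
    return 1.0 + amplitude * np.exp(-d2 / (2.0 * sigma**2))


def respond(
    image: np.ndarray,
    config: ImageModelConfig | None = None,
    attention_locus: tuple[int, int] | None = None,
) -> np.ndarray:
    """Per-pixel model-neuron responses E / (S + semisaturation).

    E and S pool the (attention-weighted) local-contrast field under the
    excitatory and suppressive Gaussians; with ``surround_enabled=False``
    the suppressive pool is restricted to the cRF disc.
    """
    config = config or ImageModelConfig()
    contrast = local_contrast(image, config.contrast_sigma)
    if attention_locus is not None:
        contrast = contrast * attention_gain(
            contrast.shape, attention_locus,
            config.attention_sigma, config.attention_amplitude,
        )
    k_exc = gaussian_kernel(config.sigma_exc, config.kernel_truncate)
    k_sup = gaussian_kernel(
        config.sigma_sup, config.kernel_truncate,
        crf_radius=None if config.surround_enabled else config.crf_radius,
    )
    E = _pool(contrast, k_exc)
    S = _pool(contrast, k_sup)
    return np.maximum(E, 0.0) / (np.maximum(S, 0.0) + config.semisaturation)


def attention_modulation_map(resp_att: np.ndarray, resp: np.ndarray) -> np.ndarray:
    """Elementwise (Ratt - R)/(Ratt + R); 0/0 pixels map to 0."""
    resp_att = np.asarray(resp_att, dtype=float)
    resp = np.asarray(resp, dtype=float)
    if resp_att.shape != resp.shape:
        raise ValueError("response maps must have the same shape")
    if np.any(resp_att < 0) or np.any(resp < 0):
        raise ValueError("responses must be nonnegative")
    den = resp_att + resp
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, (resp_att - resp) / np.maximum(den, 1e-300), 0.0)
    return out


def attended_image(image: np.ndarray, response_map: np.ndarray) -> np.ndarray:
    """Original image rescaled by the (max-normalized) response map."""
    img = as_grayscale(image)
    r = np.asarray(response_map, dtype=float)
    return img * (r / max(r.max(), 1e-12))


def make_test_image(
    size: int = 128, seed: int = 0, n_blobs: int = 4
) -> np.ndarray:
    """Synthetic grayscale test scene with natural-like 1/f statistics.

    Pink noise (amplitude spectrum ~ 1/f) plus a few Gaussian luminance
    blobs providing localized high-contrast structure; values in [0, 1].
    This is a synthetic stand-in for a photograph.
    """
    rng = np.random.default_rng(seed)
    f = np.fft.fftfreq(size)
    fr = np.sqrt(f[:, None] ** 2 + f[None, :] ** 2)
    amp = np.where(fr > 0, 1.0 / np.maximum(fr, 1e-6), 0.0)
    phase = np.exp(2j * np.pi * rng.random((size, size)))
    noise = np.real(np.fft.ifft2(amp * phase))
    noise = (noise - noise.mean()) / (noise.std() + 1e-12)
    img = 0.5 + 0.12 * noise
    yy, xx = np.mgrid[:size, :size]
    for _ in range(n_blobs):
        cy, cx = rng.integers(size // 6, 5 * size // 6, size=2)
        s = rng.uniform(size / 24, size / 10)
        a = rng.uniform(0.25, 0.45) * rng.choice([-1.0, 1.0])
        img = img + a * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2))
    return np.clip(img, 0.0, 1.0)


def run_image_simulation(
    image: np.ndarray,
    locus: tuple[int, int],
    config: ImageModelConfig | None = None,
) -> dict[str, np.ndarray]:
    """Response and modulation maps with and without the surround.

    Returns a dict of maps: ``response``/``response_att``/``modulation``
    for the surround model and ``*_nosurround`` counterparts.
    """
    cfg = config or ImageModelConfig()
    out = {}
    for tag, surround in (("", True), ("_nosurround", False)):
        c = ImageModelConfig(**{**cfg.__dict__, "surround_enabled": surround})
        r = respond(image, c)
        ra = respond(image, c, attention_locus=locus)
        out[f"response{tag}"] = r
        out[f"response_att{tag}"] = ra
        out[f"modulation{tag}"] = attention_modulation_map(ra, r)
    return out
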