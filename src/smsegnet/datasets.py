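"""Seed-deterministic brain-like phantoms.

A phantom volume stacks per-slice nested ellipses — a white-matter core
inside a gray-matter annulus inside a CSF rim inside background — whose axes
shrink towards the first and last slices, mimicking the non-informative edge
slices of a real acquisition.  Intensities are the per-class means plus
Gaussian noise, optionally modulated by a smooth multiplicative bias field
(a low-order polynomial surface per slice emulating scanner intensity
non-uniformity), and clipped to [0, 1].  Labels are exact by construction,
so the phantoms provide pixel-perfect ground truth for every pipeline stage
without any external data.

The phantoms make no attempt at anatomical realism (no gyri or sulci, no MR
physics); they exist to exercise code paths and metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import Volume, LabelMap

__all__ = ["PhantomSpec", "make_phantom", "make_phantom_dataset"]


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one phantom subject.

    ``class_means`` are the noiseless intensities (arbitrary units in [0, 1])
    of background, CSF, GM and WM and must be strictly increasing in that
    order; ``noise_sigma`` is the additive Gaussian sigma; ``bias_amplitude``
    scales the multiplicative bias field (0 disables it); ``jitter`` is the
    fractional per-subject/per-slice ellipse-axis perturbation.
    """

    dims: tuple[int, int, int] = (176, 208, 176)
    class_means: tuple[float, float, float, float] = (0.05, 0.25, 0.55, 0.80)
    noise_sigma: float = 0.05
    bias_amplitude: float = 0.0
    jitter: float = 0.05
    seed: int = 0

    #: Semi-axis fractions of (H, W) for the CSF, GM and WM ellipses.
    RADII = ((0.42, 0.42), (0.34, 0.34), (0.21, 0.21))

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must be positive")
        m = self.class_means
        if not (m[0] < m[1] < m[2] < m[3]):
            raise ValueError("class means must be strictly ordered "
                             "background < CSF < GM < WM")
        if self.noise_sigma < 0 or self.bias_amplitude < 0 or self.jitter < 0:
            raise ValueError("noise, bias amplitude and jitter must be >= 0")
        if max(r for pair in self.RADII for r in pair) * (1 + self.jitter) >= 0.5:
            raise ValueError("ellipse geometry exceeds the volume bounds")


def _slice_profile(n_slices: int) -> np.ndarray:
    """Axis scale factor per slice: ~1 centrally, shrinking to the ends."""
    z = (np.arange(n_slices) - (n_slices - 1) / 2) / (0.62 * max(n_slices, 2))
    return np.sqrt(np.clip(1.0 - z ** 2, 0.0, None))


def make_phantom(spec: PhantomSpec | None = None, **kwargs):
    """Generate one (Volume, LabelMap) phantom pair.

    Identical specs (including the seed) produce bit-identical outputs.
    """
    if spec is None:
        spec = PhantomSpec(**kwargs)
    elif kwargs:
        raise TypeError("pass either a PhantomSpec or keyword arguments")
    h, w, s = spec.dims
    rng = np.random.default_rng(spec.seed)

    labels = np.zeros((h, w, s), dtype=np.int16)
    rows = (np.arange(h) - (h - 1) / 2)[:, None]
    cols = (np.arange(w) - (w - 1) / 2)[None, :]
    profile = _slice_profile(s)
    # one jitter draw per slice, shared by the three nested ellipses so the
    # nesting WM c GM c CSF can never break
    slice_jitter = 1.0 + spec.jitter * rng.uniform(-1.0, 1.0, size=s)
    for k in range(s):
        scale = profile[k] * slice_jitter[k]
        for cls, (ra, rb) in zip((1, 2, 3), spec.RADII):
            a, b = ra * h * scale, rb * w * scale
            if a < 0.5 or b < 0.5:
                continue
            inside = (rows / a) ** 2 + (cols / b) ** 2 <= 1.0
            labels[:, :, k][inside] = cls

    means = np.asarray(spec.class_means, dtype=np.float32)
    vol = means[labels]
    if spec.noise_sigma > 0:
        vol = vol + rng.normal(0.0, spec.noise_sigma,
                               size=vol.shape).astype(np.float32)
    if spec.bias_amplitude > 0:
        y = np.linspace(-1, 1, h)[:, None]
        x = np.linspace(-1, 1, w)[None, :]
        coeffs = rng.uniform(-1.0, 1.0, size=(s, 5))
        for k in range(s):
            c0, c1, c2, c3, c4 = coeffs[k]
            surf = c0 * y + c1 * x + c2 * y * x + c3 * y ** 2 + c4 * x ** 2
            surf /= max(1e-9, np.abs(surf).max())
            vol[:, :, k] *= 1.0 + spec.bias_amplitude * surf
    vol = np.clip(vol, 0.0, 1.0).astype(np.float32)
    return Volume(data=vol), LabelMap(data=labels)


def make_phantom_dataset(n_subjects: int, spec: PhantomSpec | None = None,
                         base_seed: int = 0, **kwargs):
    """Generate a deterministic list of phantom subjects.

    Subject ``i`` is generated with seed ``base_seed + i``, so subjects
    differ in geometry jitter and noise while sharing the class structure,
    and the whole dataset is reproducible from ``base_seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if spec is None:
        spec = PhantomSpec(**kwargs)
    elif kwargs:
        raise TypeError("pass either a PhantomSpec or keyword arguments")
    out = []
    for i in range(n_subjects):
        subject = PhantomSpec(
            dims=spec.dims, class_means=spec.class_means,
            noise_sigma=spec.noise_sigma, bias_amplitude=spec.bias_amplitude,
            jitter=spec.jitter, seed=base_seed + i)
        out.append(make_phantom(subject))
    return out
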