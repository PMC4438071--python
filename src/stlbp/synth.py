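"""Seeded generators of synthetic dynamic-texture videos and labeled corpora.

Real micro-expression corpora are access-restricted, so tests and examples
run on synthetic stand-ins that reproduce the statistical structure the
descriptors assume: a static per-subject texture (the identity confound that
makes subject-disjoint evaluation necessary), a subtle class-specific
localized motion pattern, and sensor noise.

Each video is

    frame_t = subject_texture
              + motion_amplitude * envelope * cos(spatial_phase - omega_k t)
              + sensor noise

where the envelope is a Gaussian patch (jittered location per video), the
spatial carrier orientation and the temporal angular frequency ``omega_k``
depend on the class — a small traveling wave whose direction and speed are
the class signal, invisible as mean intensity but present in local ordering,
exactly what LBP codes pick up.  Intensities are clipped to [0, 255] and
rounded to whole numbers, emulating an 8-bit sensor and making lossless
image round-trips exact.

Determinism: every stream is keyed by (seed, subject, class, index) through
``numpy.random.SeedSequence``, so the same call always yields the same
voxels and corpora are reproducible at every granularity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .evaluate import Corpus, Sample

__all__ = ["SynthSpec", "make_video", "make_corpus"]


@dataclass(frozen=True)
class SynthSpec:
    """Generator settings for one synthetic corpus.

    ``motion_amplitude`` is the peak intensity excursion (8-bit units) of the
    class-specific moving patch; subtle relative to the texture contrast.
    ``noise_sd`` is the per-voxel Gaussian sensor noise sigma.
    """

    n_subjects: int = 16
    videos_per_subject: int = 3
    n_classes: int = 3
    shape: tuple[int, int, int] = (48, 48, 10)  # (height, width, length)
    motion_amplitude: float = 6.0
    noise_sd: float = 2.0
    seed: int = 0
    spatial_class_cue: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.videos_per_subject < 1:
            raise ValueError("need at least one subject and one video per subject")
        if self.n_classes < 2:
            raise ValueError("corpus generation needs n_classes >= 2")
        if min(self.shape) < 8:
            raise ValueError(f"all dims must be >= 8, got {self.shape}")
        if self.motion_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise must be non-negative")


def _texture(spec: SynthSpec, subject_id: int) -> np.ndarray:
    """Band-limited per-subject base texture, mean 128, sd ~20."""
    h, w, _ = spec.shape
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7, subject_id]))
    tex = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=2.0)
    tex = tex / max(tex.std(), 1e-12)
    return 128.0 + 20.0 * tex


def make_video(
    class_id: int, subject_id: int, spec: SynthSpec, index: int = 0
) -> np.ndarray:
    """One synthetic (h, w, l) video for the given class and subject.

    Deterministic under (spec.seed, subject_id, class_id, index).
    """
    if not (0 <= class_id < spec.n_classes):
        raise ValueError(f"class_id {class_id} outside [0, {spec.n_classes})")
    h, w, l = spec.shape
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, 11, subject_id, class_id, index])
    )
    base = _texture(spec, subject_id)

    # localized traveling wave; direction and temporal frequency carry the class
    cy = h / 2 + rng.uniform(-h / 8, h / 8)
    cx = w / 2 + rng.uniform(-w / 8, w / 8)
    yy, xx = np.mgrid[0:h, 0:w]
    sigma = h / 5.0
    envelope = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)))
    # with spatial_class_cue off, all classes share one carrier orientation and
    # differ only in temporal frequency — the class signal then lives purely in
    # the temporal ordering of intensities
    phi = np.pi * class_id / spec.n_classes if spec.spatial_class_cue else 0.0
    freq = 0.20  # cycles per pixel of the spatial carrier
    spatial_phase = 2 * np.pi * freq * (xx * np.cos(phi) + yy * np.sin(phi))
    omega = 2 * np.pi * (class_id + 1) / l

    video = np.empty((h, w, l), dtype=float)
    for t in range(l):
        wave = spec.motion_amplitude * envelope * np.cos(spatial_phase - omega * t)
        video[:, :, t] = base + wave
    if spec.noise_sd > 0:
        video += spec.noise_sd * rng.standard_normal(video.shape)
    return np.clip(np.round(video), 0.0, 255.0)


def make_corpus(spec: SynthSpec) -> Corpus:
    """A labeled multi-subject corpus with raw videos attached.

    ``n_subjects * videos_per_subject`` samples; class labels assigned
    round-robin over the global sample index, so class counts differ by at
    most one and (when videos_per_subject >= n_classes is not required)
    every training fold of a reasonable split sees every class.
    """
    samples: list[Sample] = []
    g = 0
    for subj in range(spec.n_subjects):
        for vid in range(spec.videos_per_subject):
            class_id = g % spec.n_classes
            video = make_video(class_id, subj, spec, index=vid)
            samples.append(
                Sample(
                    sample_id=f"s{subj:03d}_v{vid:02d}",
                    subject_id=f"subj{subj:03d}",
                    label=f"c{class_id}",
                    video=video,
                )
            )
            g += 1
    return Corpus(samples)
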