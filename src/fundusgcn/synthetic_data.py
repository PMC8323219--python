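"""Synthetic correlated-label fundus-style dataset generator.

Real multi-lesion fundus datasets are rarely shareable, so this module
provides a fully synthetic stand-in with two properties the rest of the
package needs:

* **Known label dependence.**  Annotations are drawn from a mixture of
  "patient profiles": a profile k is chosen with weight w_k, then each of
  the N lesion labels is an independent Bernoulli(q_k[i]) within that
  profile.  Because labels are conditionally independent given the profile,
  every pairwise conditional probability has a closed form,

      P(L_i | L_j) = sum_k w_k q_ki q_kj / sum_k w_k q_kj   (i != j),

  which serves as the exact oracle for graph-construction recovery tests.

* **Label-encoding images.**  Each active label draws a visually distinct
  primitive on a circular fundus-like background — tiny red dots for
  microaneurysms, bright yellow blobs for hard exudates, dark blotches for
  hemorrhages, pale fuzzy patches for soft exudates, a pale dot-ring for
  laser scars, yellow specks for drusen, an enlarged bright inner disc for
  a large cup-disc ratio, thickened dark vessel strokes for
  arteriosclerosis.  Rendering is a pure function of (labels, spec, seed).

The default mixture has three profiles over the eight lesion labels, shaped
so the marginal prevalences roughly track a hospital screening population
(hemorrhages and arteriosclerosis common, laser scars and soft exudates
rare).  The images are deliberately cartoon-like: high-contrast primitives
on a clean background, so a small classifier can learn them — they test the
pipeline, not photorealism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "ProfileMixture",
    "RenderSpec",
    "DEFAULT_LABELS",
    "default_mixture",
    "two_profile_mixture",
    "sample_labels",
    "true_conditional_probabilities",
    "render_image",
    "generate_dataset",
]

logger = logging.getLogger(__name__)

DEFAULT_LABELS = [
    "laser scars",
    "drusen",
    "cup disc ratio",
    "hemorrhages",
    "retinal arteriosclerosis",
    "microaneurysms",
    "hard exudates",
    "soft exudates",
]


@dataclass
class ProfileMixture:
    """Mixture of per-profile independent Bernoulli label distributions."""

    weights: np.ndarray
    probs: np.ndarray  # K x N
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.weights.ndim != 1 or self.probs.ndim != 2 or \
                self.weights.size != self.probs.shape[0]:
            raise ValueError("weights must be length-K, probs K x N")
        if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")
        if np.any((self.probs < 0) | (self.probs > 1)):
            raise ValueError("profile probabilities must lie in [0, 1]")
        if not self.labels:
            self.labels = [f"label_{i}" for i in range(self.probs.shape[1])]
        if len(self.labels) != self.probs.shape[1]:
            raise ValueError("label count must match probs columns")

    @property
    def n_labels(self) -> int:
        return self.probs.shape[1]

    @property
    def marginals(self) -> np.ndarray:
        return self.weights @ self.probs


def default_mixture() -> ProfileMixture:
    """Three profiles over the eight lesion labels.

    A mostly-healthy background profile, a proliferative-retinopathy profile
    (hemorrhages, microaneurysms, exudates), and a vascular-aging profile
    (arteriosclerosis, drusen, optic-disc cupping).  Mixture marginals land
    near a screening population: arteriosclerosis ~0.37, hemorrhages ~0.28,
    hard exudates ~0.25, microaneurysms ~0.14, laser scars ~0.04.
    """
    return ProfileMixture(
        weights=[0.45, 0.30, 0.25],
        probs=[
            # scars drusen  cup   hem   arter  micro  hardx  softx
            [0.01, 0.02, 0.03, 0.08, 0.15, 0.03, 0.05, 0.01],
            [0.08, 0.05, 0.08, 0.70, 0.45, 0.35, 0.60, 0.18],
            [0.03, 0.22, 0.18, 0.15, 0.65, 0.10, 0.18, 0.06],
        ],
        labels=list(DEFAULT_LABELS),
    )


def two_profile_mixture(labels: list[str] | None = None) -> ProfileMixture:
    """A strongly correlated two-profile mixture over four labels.

    Used by the scaled-down end-to-end experiment: profile one favours the
    first two labels, profile two the last two, giving the label graph clear
    co-occurrence structure.
    """
    if labels is None:
        labels = ["hard exudates", "hemorrhages", "soft exudates",
                  "laser scars"]
    if len(labels) != 4:
        raise ValueError("two_profile_mixture defines four labels")
    return ProfileMixture(
        weights=[0.5, 0.5],
        probs=[
            [0.85, 0.75, 0.10, 0.05],
            [0.10, 0.15, 0.80, 0.70],
        ],
        labels=list(labels),
    )


def sample_labels(n: int, mix: ProfileMixture, seed: int) -> np.ndarray:
    """Draw an n x N binary label matrix from the mixture, reproducibly."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    profiles = rng.choice(mix.weights.size, size=n, p=mix.weights)
    u = rng.random((n, mix.n_labels))
    return (u < mix.probs[profiles]).astype(np.int64)


def true_conditional_probabilities(mix: ProfileMixture) -> np.ndarray:
    """Closed-form P(L_i | L_j) implied by the mixture.

    Within a profile labels are independent, so the joint is
    sum_k w_k q_ki q_kj and the marginal sum_k w_k q_kj.  The diagonal is 1
    by definition.  Errors if any label has zero marginal probability.
    """
    marg = mix.marginals
    zero = np.flatnonzero(marg <= 0)
    if zero.size:
        names = [mix.labels[i] for i in zero]
        raise ValueError(f"labels with zero marginal probability: {names}")
    joint = (mix.probs.T * mix.weights) @ mix.probs  # N x N: sum_k w q_i q_j
    P = joint / marg[np.newaxis, :]
    np.fill_diagonal(P, 1.0)
    return P


# --------------------------------------------------------------------------
# Rendering


@dataclass
class RenderSpec:
    """How labels are drawn.

    size      : square image side in pixels (minimum 32).
    noise     : std-dev of additive Gaussian pixel noise, in [0, 1] units.
    contrast  : scales primitive intensity against the background.
    anchored  : if True, each label's primitives cluster around its own
                angular sector of the fundus disc, making labels spatially
                as well as chromatically distinct.
    primitives: one primitive kind per label; auto-assigned from the label
                name when possible, cycling through the palette otherwise.
    """

    size: int = 64
    noise: float = 0.02
    contrast: float = 1.0
    anchored: bool = True
    primitives: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValueError("image size must be at least 32 pixels")
        if self.noise < 0:
            raise ValueError("noise must be non-negative")


_NAME_TO_PRIMITIVE = {
    "microaneurysm": "red_dots",
    "hard exudate": "yellow_blobs",
    "hemorrhage": "dark_blotches",
    "haemorrhage": "dark_blotches",
    "soft exudate": "pale_patches",
    "laser scar": "dot_ring",
    "drusen": "yellow_specks",
    "cup disc": "bright_disc",
    "arterioscler": "vessel_strokes",
}

_PRIMITIVE_CYCLE = ("yellow_blobs", "dark_blotches", "pale_patches",
                    "dot_ring", "red_dots", "yellow_specks", "bright_disc",
                    "vessel_strokes")


def assign_primitives(labels: list[str],
                      spec: RenderSpec) -> tuple[str, ...]:
    if spec.primitives:
        if len(spec.primitives) != len(labels):
            raise ValueError("primitives must match label count")
        return spec.primitives
    out = []
    for idx, label in enumerate(labels):
        low = label.lower()
        for key, prim in _NAME_TO_PRIMITIVE.items():
            if key in low:
                out.append(prim)
                break
        else:
            out.append(_PRIMITIVE_CYCLE[idx % len(_PRIMITIVE_CYCLE)])
    return tuple(out)


def _disc(img: np.ndarray, cx: float, cy: float, r: float,
          color, alpha: float = 1.0, soft: float = 0.0) -> None:
    size = img.shape[0]
    yy, xx = np.ogrid[:size, :size]
    dist = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    if soft > 0:
        w = np.clip(1.0 - (dist - r) / soft, 0.0, 1.0)
    else:
        w = (dist <= r).astype(float)
    w = (w * alpha)[:, :, None]
    img[...] = img * (1 - w) + np.asarray(color) * w


def _sector_center(idx: int, n: int, size: int,
                   rng: np.random.Generator) -> tuple[float, float]:
    angle = 2 * np.pi * idx / max(n, 1) + rng.uniform(-0.3, 0.3)
    rad = size * rng.uniform(0.18, 0.30)
    return size / 2 + rad * np.cos(angle), size / 2 + rad * np.sin(angle)


def _draw_primitive(img: np.ndarray, kind: str, idx: int, n_labels: int,
                    spec: RenderSpec, rng: np.random.Generator) -> None:
    size = img.shape[0]
    c = spec.contrast

    def center():
        if spec.anchored:
            return _sector_center(idx, n_labels, size, rng)
        rad = size * rng.uniform(0.05, 0.32)
        ang = rng.uniform(0, 2 * np.pi)
        return size / 2 + rad * np.cos(ang), size / 2 + rad * np.sin(ang)

    if kind == "red_dots":
        for _ in range(rng.integers(6, 12)):
            cx, cy = center()
            cx += rng.uniform(-4, 4)
            cy += rng.uniform(-4, 4)
            _disc(img, cx, cy, size * 0.012 + 0.7, (0.45 * c, 0.02, 0.02))
    elif kind == "yellow_blobs":
        for _ in range(rng.integers(2, 4)):
            cx, cy = center()
            _disc(img, cx, cy, size * rng.uniform(0.05, 0.09),
                  (0.98 * c, 0.92 * c, 0.15), soft=2.0)
    elif kind == "dark_blotches":
        for _ in range(rng.integers(2, 4)):
            cx, cy = center()
            _disc(img, cx, cy, size * rng.uniform(0.05, 0.10),
                  (0.16, 0.01, 0.01), soft=1.5)
    elif kind == "pale_patches":
        for _ in range(rng.integers(1, 3)):
            cx, cy = center()
            _disc(img, cx, cy, size * rng.uniform(0.06, 0.10),
                  (0.95 * c, 0.95 * c, 0.88 * c), alpha=0.85, soft=3.0)
    elif kind == "dot_ring":
        cx, cy = center()
        ring_r = size * 0.10
        for t in range(10):
            ang = 2 * np.pi * t / 10 + rng.uniform(-0.1, 0.1)
            _disc(img, cx + ring_r * np.cos(ang), cy + ring_r * np.sin(ang),
                  size * 0.018, (0.75 * c, 0.85 * c, 0.55))
    elif kind == "yellow_specks":
        for _ in range(rng.integers(8, 16)):
            cx, cy = center()
            cx += rng.uniform(-5, 5)
            cy += rng.uniform(-5, 5)
            _disc(img, cx, cy, size * 0.010 + 0.6, (0.92 * c, 0.78 * c, 0.25))
    elif kind == "bright_disc":
        # Enlarged bright cup inside the optic disc, fixed nasal position.
        cx, cy = size * 0.72, size * 0.42
        _disc(img, cx, cy, size * 0.10, (0.95 * c, 0.75 * c, 0.40), soft=1.5)
        _disc(img, cx, cy, size * 0.065, (1.0 * c, 0.95 * c, 0.75), soft=1.0)
    elif kind == "vessel_strokes":
        for _ in range(3):
            cx, cy = center()
            ang = rng.uniform(0, np.pi)
            length = size * 0.28
            for t in np.linspace(-0.5, 0.5, int(length)):
                _disc(img, cx + t * length * np.cos(ang),
                      cy + t * length * np.sin(ang),
                      size * 0.020, (0.30, 0.06, 0.04))
    else:
        raise ValueError(f"unknown primitive kind {kind!r}")


def render_image(labels, spec: RenderSpec, seed) -> np.ndarray:
    """Render one RGB image (H x W x 3 uint8) encoding the active labels.

    Pure function of (labels, spec, seed): every label draws from its own
    sub-stream, so toggling one label never perturbs the appearance of the
    others.  ``seed`` may be an int or a tuple of ints.
    """
    labels = np.asarray(labels).astype(int)
    n_labels = labels.size
    seed_tuple = tuple(np.atleast_1d(seed).astype(np.int64).tolist()) \
        if not isinstance(seed, tuple) else seed
    size = spec.size
    bg_rng = np.random.default_rng((*seed_tuple, 10_000))

    img = np.zeros((size, size, 3), dtype=float)
    # Fundus disc: warm radial gradient on black.
    yy, xx = np.ogrid[:size, :size]
    dist = np.sqrt((xx - size / 2) ** 2 + (yy - size / 2) ** 2)
    disc = np.clip(1.0 - dist / (size * 0.48), 0.0, 1.0)
    base = np.array([0.58, 0.26, 0.09])
    img += disc[:, :, None] * base * (0.75 + 0.25 * disc[:, :, None])

    if spec.primitives:
        if len(spec.primitives) != n_labels:
            raise ValueError("primitives must match label count")
        prims = spec.primitives
    else:
        prims = tuple(_PRIMITIVE_CYCLE[i % len(_PRIMITIVE_CYCLE)]
                      for i in range(n_labels))

    for i in range(n_labels):
        if labels[i]:
            rng_i = np.random.default_rng((*seed_tuple, i))
            _draw_primitive(img, prims[i], i, n_labels, spec, rng_i)

    mask = (dist <= size * 0.49)[:, :, None]
    img *= mask
    if spec.noise > 0:
        img += bg_rng.normal(0.0, spec.noise, img.shape) * mask
    return (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)


def render_for_labels(labels_row, label_names: list[str], spec: RenderSpec,
                      seed) -> np.ndarray:
    """Render with primitives resolved from real label names."""
    spec_resolved = RenderSpec(
        size=spec.size, noise=spec.noise, contrast=spec.contrast,
        anchored=spec.anchored,
        primitives=assign_primitives(label_names, spec))
    return render_image(labels_row, spec_resolved, seed)


def generate_dataset(n: int, mix: ProfileMixture, spec: RenderSpec,
                     out_dir, seed: int) -> pd.DataFrame:
    """Write n rendered images plus a manifest CSV; returns the manifest.

    Manifest schema: ``image_path,patient_id,eye,<label_1>,...,<label_N>``
    with image paths relative to the manifest's directory.  Consecutive
    images pair into patients (left then right eye) so patient-level
    splitting is exercisable.  Fully reproducible from the seed.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    Y = sample_labels(n, mix, seed)
    prims = assign_primitives(mix.labels, spec)
    spec_resolved = RenderSpec(size=spec.size, noise=spec.noise,
                               contrast=spec.contrast, anchored=spec.anchored,
                               primitives=prims)
    rows = []
    for idx in range(n):
        img = render_image(Y[idx], spec_resolved, (int(seed), idx))
        rel = f"images/img_{idx:05d}.png"
        Image.fromarray(img).save(out_dir / rel)
        rows.append({
            "image_path": rel,
            "patient_id": f"patient_{idx // 2:04d}",
            "eye": "OD" if idx % 2 == 0 else "OS",
            **{lab: int(Y[idx, j]) for j, lab in enumerate(mix.labels)},
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    marg = Y.mean(axis=0)
    logger.info("generated %d images under %s; label marginals: %s", n,
                out_dir, {lab: round(float(m), 3)
                          for lab, m in zip(mix.labels, marg)})
    return manifest
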