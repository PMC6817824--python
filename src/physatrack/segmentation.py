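"""Chromatic segmentation and history-based trinarization.

Each frame is reduced to the a*b* chromaticity plane (CIELAB without the
lightness channel, which mostly carries illumination) and split into
slime / not-slime by two-cluster k-means over the in-arena pixels.  The
cluster whose centroid lies nearer to a reference color — the mean a*b* of
the known initial plasmodium disc in frame 0 — is taken as slime, which
makes the output invariant to k-means label permutation and to the seed.

The not-slime class is then refined from pixel history: a pixel that was
ever slime and is slime no longer is mucus (the extracellular trace);
otherwise it is unexplored substrate.  A visited pixel can never return to
the unexplored state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage import color as skcolor
from skimage import morphology
from sklearn.cluster import KMeans

from .frames_io import ArenaMask
from .labels import Label

__all__ = [
    "TrinarizedFrame",
    "to_ab",
    "reference_color",
    "kmeans_binarize",
    "trinarize_sequence",
]

#: Default minimum blob/hole size for mask cleanup, as a fraction of arena area.
DEFAULT_MIN_BLOB_FRAC = 1e-4


@dataclass
class TrinarizedFrame:
    """Per-pixel labels over the arena for one frame.

    ``labels`` holds codes from :class:`~physatrack.labels.Label`; pixels
    outside the arena are 0 and carry no meaning.
    """

    labels: np.ndarray
    frame_index: int
    arena: ArenaMask

    def class_mask(self, label: Label) -> np.ndarray:
        return (self.labels == label) & self.arena.mask

    @property
    def slime(self) -> np.ndarray:
        return self.class_mask(Label.SLIME)

    @property
    def mucus(self) -> np.ndarray:
        return self.class_mask(Label.MUCUS)

    @property
    def unexplored(self) -> np.ndarray:
        return self.class_mask(Label.UNEXPLORED)

    @property
    def explored(self) -> np.ndarray:
        """Pixels visited at least once (slime or mucus)."""
        return self.slime | self.mucus


def to_ab(frame: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB frame to the a*b* chromaticity plane.

    Standard sRGB -> CIELAB (D65) conversion with the L* channel dropped.
    Returns an (H, W, 2) float array.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB frame")
    if frame.dtype != np.uint8:
        raise ValueError("expected 8-bit RGB input")
    lab = skcolor.rgb2lab(frame)
    return lab[..., 1:3]


def reference_color(
    ab_frame: np.ndarray, center_px: tuple[float, float], radius_px: float
) -> np.ndarray:
    """Mean a*b* inside a circle — used on frame 0 over the initial slime disc."""
    h, w = ab_frame.shape[:2]
    rows, cols = np.ogrid[:h, :w]
    disc = (rows - center_px[0]) ** 2 + (cols - center_px[1]) ** 2 <= radius_px**2
    if not disc.any():
        raise ValueError("reference disc contains no pixels")
    return ab_frame[disc].mean(axis=0)


def kmeans_binarize(
    ab_frame: np.ndarray,
    arena: ArenaMask,
    ref_color: np.ndarray,
    seed: int = 0,
    min_blob_frac: float = DEFAULT_MIN_BLOB_FRAC,
    min_blob_px: int | None = None,
) -> np.ndarray:
    """Two-cluster k-means slime/not-slime binarization of one frame.

    The k-means is fit independently per frame on the in-arena a*b* values
    (10 restarts, tolerance 1e-4).  The cluster whose centroid is nearer
    (Euclidean, in a*b*) to ``ref_color`` becomes slime.  The raw mask is
    cleaned by removing 8-connected components no larger than the blob
    threshold and filling holes up to the same threshold.

    Raises
    ------
    ValueError
        ``"no chromatic contrast"`` when all in-arena pixels are chromatically
        identical — the frame cannot be segmented.
    """
    vals = ab_frame[arena.mask]
    if np.ptp(vals, axis=0).max() < 1e-6:
        raise ValueError("no chromatic contrast: all in-arena pixels identical")

    if min_blob_px is None:
        min_blob_px = max(1, int(round(min_blob_frac * arena.n_px)))

    km = KMeans(n_clusters=2, n_init=10, tol=1e-4, random_state=seed)
    assign = km.fit_predict(vals)
    d = np.linalg.norm(km.cluster_centers_ - np.asarray(ref_color)[None, :], axis=1)
    slime_cluster = int(np.argmin(d))

    mask = np.zeros(arena.mask.shape, dtype=bool)
    mask[arena.mask] = assign == slime_cluster

    # speckle cleanup: drop blobs and close holes of at most the threshold size
    if min_blob_px >= 1:
        mask = morphology.remove_small_objects(mask, max_size=min_blob_px, connectivity=2)
        mask = morphology.remove_small_holes(mask, max_size=min_blob_px, connectivity=2)
        mask &= arena.mask
    return mask


def trinarize_sequence(
    slime_masks: Sequence[np.ndarray], arena: ArenaMask
) -> list[TrinarizedFrame]:
    """Fold a sequence of binary slime masks into three-class label frames.

    Frame 0 is slime/unexplored.  For t > 0 a non-slime pixel is mucus if it
    was ever slime (or mucus) before, else unexplored; hence explored area
    never shrinks and no pixel returns to the unexplored state.
    """
    if len(slime_masks) == 0:
        raise ValueError("empty mask sequence")
    ever = np.zeros(arena.mask.shape, dtype=bool)
    out: list[TrinarizedFrame] = []
    for t, m in enumerate(slime_masks):
        m = np.asarray(m, dtype=bool) & arena.mask
        labels = np.zeros(arena.mask.shape, dtype=np.uint8)
        labels[m] = Label.SLIME
        labels[~m & ever & arena.mask] = Label.MUCUS
        ever |= m
        out.append(TrinarizedFrame(labels, t, arena))
    return out
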