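"""FLU-to-VIS co-registration of pre-segmented plant masks.

The two camera frames differ by chamber geometry and magnification, so a
similarity transform (scale + rotation + translation) is estimated by
maximizing the Dice overlap between the transformed FLU pre-segmentation
and the VIS pre-segmentation.  Binary masks rather than raw intensities
are registered because FLU and VIS intensities are not comparable across
modalities.  The search is a coarse-to-fine hill climb on a factor-2
image pyramid.

Non-uniform leaf motion is deliberately not modelled: the residual
misalignment it leaves behind ("marginal background") is what the
downstream color classification step removes.

Coordinate convention: points are ``(col, row)``; the transform maps FLU
pixel coordinates into the VIS frame as ``p_vis = s R(theta) (p - c) + c + t``
with rotation center ``c`` in the FLU frame.  The serialized form is the
3x3 homogeneous matrix acting on ``(col, row, 1)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.measure import block_reduce

from .errors import RegistrationError, ValidationError
from .io import BinaryMask


@dataclass
class SimilarityTransform:
    """Scale/rotation/translation mapping FLU coordinates to the VIS frame."""

    scale: float = 1.0
    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)  # (dx cols, dy rows)
    center: tuple[float, float] = (0.0, 0.0)  # (cx cols, cy rows), FLU frame

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValidationError("scale must be positive")
        self.translation = (float(self.translation[0]), float(self.translation[1]))
        self.center = (float(self.center[0]), float(self.center[1]))

    def matrix(self) -> np.ndarray:
        """Homogeneous 3x3 matrix acting on ``(col, row, 1)`` column vectors."""
        th = math.radians(self.rotation_deg)
        a = self.scale * np.array(
            [[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]]
        )
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        m = np.eye(3)
        m[:2, :2] = a
        m[:2, 2] = c + t - a @ c
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an ``(n, 2)`` array of (col, row) FLU points to VIS coordinates."""
        pts = np.asarray(points, dtype=np.float64)
        m = self.matrix()
        return pts @ m[:2, :2].T + m[:2, 2]

    def rescaled(self, factor: float) -> "SimilarityTransform":
        """The same transform expressed on a grid downsampled by ``factor``."""
        return SimilarityTransform(
            scale=self.scale,
            rotation_deg=self.rotation_deg,
            translation=(self.translation[0] / factor, self.translation[1] / factor),
            center=(self.center[0] / factor, self.center[1] / factor),
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "convention": "vis = M @ (col, row, 1) of flu",
            "scale": self.scale,
            "rotation_deg": self.rotation_deg,
            "translation": list(self.translation),
            "center": list(self.center),
            "matrix": self.matrix().tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimilarityTransform":
        payload = json.loads(Path(path).read_text())
        return cls(
            scale=payload["scale"],
            rotation_deg=payload["rotation_deg"],
            translation=tuple(payload["translation"]),
            center=tuple(payload["center"]),
        )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient between two boolean arrays (both empty -> 1)."""
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / (na + nb)


def transfer_mask(
    flu_mask: BinaryMask, transform: SimilarityTransform, vis_shape: tuple[int, int]
) -> BinaryMask:
    """Resample a FLU mask into the VIS frame by inverse nearest-neighbour mapping.

    VIS pixels whose pre-image falls outside the FLU frame are background.
    """
    h, w = vis_shape
    minv = np.linalg.inv(transform.matrix())
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    src_c = minv[0, 0] * cols + minv[0, 1] * rows + minv[0, 2]
    src_r = minv[1, 0] * cols + minv[1, 1] * rows + minv[1, 2]
    ic = np.rint(src_c).astype(np.intp)
    ir = np.rint(src_r).astype(np.intp)
    fh, fw = flu_mask.shape
    valid = (ir >= 0) & (ir < fh) & (ic >= 0) & (ic < fw)
    out = np.zeros((h, w), dtype=bool)
    out[valid] = flu_mask.pixels[ir[valid], ic[valid]]
    return BinaryMask(out, frame="VIS")


def _mask_moments(mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Centroid (col, row) and root-mean-squared radius of a boolean mask."""
    rows, cols = np.nonzero(mask)
    centroid = np.array([cols.mean(), rows.mean()])
    r2 = (cols - centroid[0]) ** 2 + (rows - centroid[1]) ** 2
    return centroid, math.sqrt(float(r2.mean()))


def _downsample(mask: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return mask
    return block_reduce(mask, (factor, factor), np.max).astype(bool)


def _level_dice(
    params: tuple[float, float, float, float],
    center: tuple[float, float],
    flu_level: BinaryMask,
    vis_level: np.ndarray,
    factor: int,
) -> float:
    s, rot, dx, dy = params
    t = SimilarityTransform(s, rot, (dx, dy), center).rescaled(factor)
    warped = transfer_mask(flu_level, t, vis_level.shape)
    return dice(warped.pixels, vis_level)


def estimate_similarity_transform(
    flu_preseg: BinaryMask,
    vis_preseg: BinaryMask,
    max_iter: int = 50,
    min_level_dim: int = 64,
) -> SimilarityTransform:
    """Estimate the FLU-to-VIS similarity transform from two pre-segmentations.

    Initialization: translation from the centroid difference, scale from
    the ratio of root-mean-squared mask radii, rotation zero.  The four
    parameters are then refined by a hill climb that maximizes Dice
    overlap, coarse-to-fine over a factor-2 pyramid, accepting a step only
    when it improves Dice by more than 1e-4 and halving the step sizes
    otherwise.
    """
    if flu_preseg.count() == 0 or vis_preseg.count() == 0:
        raise RegistrationError(
            "cannot register: a pre-segmentation mask is empty (no plant found)"
        )
    c_flu, r_flu = _mask_moments(flu_preseg.pixels)
    c_vis, r_vis = _mask_moments(vis_preseg.pixels)
    scale0 = r_vis / max(r_flu, 1e-9)
    center = (float(c_flu[0]), float(c_flu[1]))
    params = [scale0, 0.0, float(c_vis[0] - c_flu[0]), float(c_vis[1] - c_flu[1])]

    min_dim = min(*flu_preseg.shape, *vis_preseg.shape)
    factor = 1
    while min_dim // (factor * 2) >= min_level_dim:
        factor *= 2
    factors = []
    while factor >= 1:
        factors.append(factor)
        factor //= 2

    # Step sizes: (scale, rotation deg, dx px, dy px); minimums set the
    # final parameter resolution at full image scale.
    min_steps = np.array([0.002, 0.05, 0.25, 0.25])
    for f in factors:
        flu_level = BinaryMask(_downsample(flu_preseg.pixels, f))
        vis_level = _downsample(vis_preseg.pixels, f)
        steps = np.maximum(np.array([0.04, 2.0, 3.0 * f, 3.0 * f]), min_steps)
        level_min = np.maximum(min_steps, [0.002, 0.05, 0.25 * f, 0.25 * f])
        best = _level_dice(tuple(params), center, flu_level, vis_level, f)
        for _ in range(max_iter):
            improved = False
            best_cand, best_cand_score = None, best
            for i in range(4):
                for sign in (+1.0, -1.0):
                    cand = list(params)
                    cand[i] += sign * steps[i]
                    if cand[0] <= 0:
                        continue
                    score = _level_dice(tuple(cand), center, flu_level, vis_level, f)
                    if score > best_cand_score + 1e-4:
                        best_cand, best_cand_score = cand, score
            if best_cand is not None:
                params, best = best_cand, best_cand_score
                improved = True
            if not improved:
                if np.all(steps <= level_min):
                    break
                steps = np.maximum(steps / 2.0, level_min)
    return SimilarityTransform(
        scale=params[0],
        rotation_deg=params[1],
        translation=(params[2], params[3]),
        center=center,
    )
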