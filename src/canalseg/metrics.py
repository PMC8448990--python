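"""Segmentation loss and evaluation metrics.

Training uses the soft Dice loss

    L(G, P) = 1 - (2 * sum_i p_i g_i + s) / (sum_i p_i + sum_i g_i + s)

with a small smoothing constant ``s`` so all-background patches do not
produce 0/0.  Evaluation uses three standard volumetric metrics between a
predicted mask P and ground truth G:

* **DSC** (Dice similarity coefficient) ``2|P∩G| / (|P| + |G|)``;
* **AVD** (average Hausdorff distance, mm) — the maximum of the two
  directed mean nearest-neighbour distances between the voxel sets;
* **ASD** (average symmetric surface distance, mm) — the mean
  nearest-surface distance pooled over both masks' surface voxels, where a
  surface voxel is a foreground voxel with at least one face-adjacent
  (6-connectivity) background or out-of-grid neighbour.

Distances are Euclidean in physical millimetres (voxel offsets scaled by
the per-axis spacing).  Nearest-neighbour queries go through a KD-tree,
which is exact, so results coincide with brute-force enumeration.

Empty masks are a hard error rather than a sentinel value: silently
returning 0 or infinity would corrupt per-case averages.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .nn import Tensor, sigmoid

__all__ = [
    "EmptyMaskError", "dice_loss", "soft_dice_loss",
    "dsc", "avd", "surface_voxels", "asd", "evaluate_masks",
]

DEFAULT_SMOOTH = 1e-5


class EmptyMaskError(ValueError):
    """A metric was asked to evaluate an empty voxel or surface set."""


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def _as_bool(mask) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype != bool:
        vals = np.unique(arr)
        bad = [v for v in vals if v not in (0, 1)]
        if bad:
            raise ValueError(f"binary mask contains non-binary values: {bad}")
        arr = arr.astype(bool)
    return arr


def dice_loss(p, g, smooth: float = DEFAULT_SMOOTH) -> float:
    """Soft Dice loss between a probability map ``p`` and binary labels ``g``."""
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    _check_shapes(p, g)
    if smooth < 0:
        raise ValueError("smooth must be >= 0")
    inter = float((p * g).sum())
    denom = float(p.sum() + g.sum())
    return 1.0 - (2.0 * inter + smooth) / (denom + smooth)


def soft_dice_loss(logits: Tensor, target: np.ndarray,
                   smooth: float = DEFAULT_SMOOTH) -> Tensor:
    """Differentiable Dice loss on network logits (autograd tensor)."""
    t = np.asarray(target, dtype=np.float32)
    if logits.shape != t.shape:
        raise ValueError(f"shape mismatch: logits {logits.shape} vs target {t.shape}")
    p = sigmoid(logits)
    g = Tensor(t)
    inter = (p * g).sum()
    return 1.0 - (2.0 * inter + smooth) / (p.sum() + float(t.sum()) + smooth)


def dsc(P, G) -> float:
    """Dice similarity coefficient between two binary masks (in [0, 1])."""
    P = _as_bool(P)
    G = _as_bool(G)
    _check_shapes(P, G)
    np_, ng = int(P.sum()), int(G.sum())
    if np_ == 0 and ng == 0:
        raise EmptyMaskError("DSC is undefined: both masks are empty")
    return 2.0 * int((P & G).sum()) / (np_ + ng)


def _coords_mm(mask: np.ndarray, spacing) -> np.ndarray:
    spacing = np.asarray(spacing, dtype=np.float64)
    return np.argwhere(mask) * spacing


def avd(P, G, spacing=(1.0, 1.0, 1.0)) -> float:
    """Average Hausdorff distance (mm): max of the two directed mean
    nearest-neighbour distances between the foreground voxel sets."""
    P = _as_bool(P)
    G = _as_bool(G)
    _check_shapes(P, G)
    if not P.any() or not G.any():
        raise EmptyMaskError("AVD requires both masks to be non-empty")
    cp = _coords_mm(P, spacing)
    cg = _coords_mm(G, spacing)
    d_pg = cKDTree(cg).query(cp)[0].mean()
    d_gp = cKDTree(cp).query(cg)[0].mean()
    return float(max(d_pg, d_gp))


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


def surface_voxels(R) -> np.ndarray:
    """Boolean mask of surface voxels of ``R``: foreground voxels with a
    face-adjacent (6-connectivity) background or out-of-grid neighbour."""
    R = _as_bool(R)
    if not R.any():
        return np.zeros_like(R)
    interior = ndimage.binary_erosion(R, structure=_FACE_STRUCT, border_value=0)
    return R & ~interior


def asd(R, G, spacing=(1.0, 1.0, 1.0)) -> float:
    """Average symmetric surface distance (mm) between two binary masks."""
    sr = surface_voxels(R)
    sg = surface_voxels(G)
    if not sr.any() or not sg.any():
        raise EmptyMaskError("ASD requires both masks to have a non-empty surface")
    cr = _coords_mm(sr, spacing)
    cg = _coords_mm(sg, spacing)
    d_rg = cKDTree(cg).query(cr)[0]
    d_gr = cKDTree(cr).query(cg)[0]
    return float((d_rg.sum() + d_gr.sum()) / (len(cr) + len(cg)))


def evaluate_masks(P, G, spacing=(1.0, 1.0, 1.0)) -> dict:
    """All three metrics for one prediction/ground-truth pair."""
    return {"dsc": dsc(P, G), "avd_mm": avd(P, G, spacing), "asd_mm": asd(P, G, spacing)}
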