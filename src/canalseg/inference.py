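"""Overlap-averaged sliding-window whole-volume prediction.

Large CT volumes are evaluated as overlapping fixed-size patches.  Raw
network logits are accumulated additively into a sum grid while a count
matrix records how many windows covered each voxel; the averaged logits
pass through a sigmoid and a threshold to give the binary mask.  (A flag
switches to averaging post-sigmoid probabilities instead.)

Internally everything is depth-first ``(D, H, W)``; the study's stated
geometry — 64x64x32 patches swept with steps 28/28/8 along X/Y/Z over a
512x512x64 volume, i.e. 17*17*5 = 1445 window evaluations — corresponds to
``patch_size=(32, 64, 64)`` and ``steps=(8, 28, 28)`` here.  The X/Y/Z
ordering is converted at the CLI boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import EmptyMaskError, asd, avd, dsc
from .nn import Tensor, no_grad
from .phantoms import LabeledVolume

__all__ = ["SlidingSpec", "window_starts", "predict_volume",
           "evaluate_cases", "normalize_intensities"]


@dataclass(frozen=True)
class SlidingSpec:
    """Patch geometry for sliding-window inference, in (D, H, W) order."""

    patch_size: tuple = (32, 64, 64)
    steps: tuple = (8, 28, 28)
    threshold: float = 0.5
    accumulate: str = "logits"          # or "probs"

    def __post_init__(self):
        object.__setattr__(self, "patch_size", tuple(int(p) for p in self.patch_size))
        object.__setattr__(self, "steps", tuple(int(s) for s in self.steps))
        for p, s in zip(self.patch_size, self.steps):
            if not (0 < s <= p):
                raise ValueError(
                    f"steps must satisfy 0 < step <= patch size; got step {s} "
                    f"for patch {p}")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if self.accumulate not in ("logits", "probs"):
            raise ValueError("accumulate must be 'logits' or 'probs'")


def window_starts(extent: int, patch: int, step: int) -> list[int]:
    """Start indices 0, step, 2*step, ... plus a final clamped start at
    ``extent - patch`` if the regular grid does not already end there, so
    the windows jointly cover [0, extent)."""
    if patch > extent:
        raise ValueError(f"patch size {patch} exceeds extent {extent}")
    if step <= 0:
        raise ValueError("step must be positive")
    starts = list(range(0, extent - patch + 1, step))
    if starts[-1] != extent - patch:
        starts.append(extent - patch)
    return starts


def normalize_intensities(grid: np.ndarray) -> np.ndarray:
    """Per-volume z-score normalisation applied before the network."""
    grid = np.asarray(grid, dtype=np.float32)
    std = float(grid.std())
    return (grid - float(grid.mean())) / (std if std > 0 else 1.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def predict_volume(model, vol, spec: SlidingSpec = SlidingSpec(),
                   normalize: bool = True):
    """Sweep ``model`` over the volume and return
    ``(probability_map, count_matrix, binary_mask)``.

    ``vol`` may be a :class:`LabeledVolume` or a plain 3D intensity array.
    ``model`` is called on ``(1, 1, pd, ph, pw)`` tensors and must return
    same-shaped logits.
    """
    grid = vol.intensities if isinstance(vol, LabeledVolume) else np.asarray(vol)
    for ax, (dim, p) in enumerate(zip(grid.shape, spec.patch_size)):
        if dim < p:
            raise ValueError(
                f"volume axis {ax} (size {dim}) is smaller than the patch "
                f"size {p} on that axis")
    if normalize:
        grid = normalize_intensities(grid)
    grid = grid.astype(np.float32, copy=False)

    starts = [window_starts(e, p, s)
              for e, p, s in zip(grid.shape, spec.patch_size, spec.steps)]
    acc = np.zeros(grid.shape, dtype=np.float64)
    counts = np.zeros(grid.shape, dtype=np.int32)
    pd_, ph, pw = spec.patch_size
    if hasattr(model, "eval"):
        model.eval()
    with no_grad():
        for sd in starts[0]:
            for sh in starts[1]:
                for sw in starts[2]:
                    patch = grid[sd:sd + pd_, sh:sh + ph, sw:sw + pw]
                    out = model(Tensor(patch[None, None]))
                    logits = out.data[0, 0] if isinstance(out, Tensor) else np.asarray(out)[0, 0]
                    if spec.accumulate == "probs":
                        acc[sd:sd + pd_, sh:sh + ph, sw:sw + pw] += _sigmoid(logits)
                    else:
                        acc[sd:sd + pd_, sh:sh + ph, sw:sw + pw] += logits
                    counts[sd:sd + pd_, sh:sh + ph, sw:sw + pw] += 1
    mean = acc / counts
    probs = mean if spec.accumulate == "probs" else _sigmoid(mean)
    mask = probs > spec.threshold
    return probs.astype(np.float32), counts, mask


def evaluate_cases(model, cases: list, spec: SlidingSpec = SlidingSpec(),
                   normalize: bool = True, case_ids: list | None = None
                   ) -> pd.DataFrame:
    """Per-case DSC/AVD/ASD rows plus a mean row (the standard report
    layout).  Metric errors (e.g. an empty prediction) are surfaced per
    case as NaN metrics with a note; remaining cases still evaluate."""
    if case_ids is None:
        case_ids = [f"Sample {i + 1}" for i in range(len(cases))]
    rows = []
    for cid, case in zip(case_ids, cases):
        _, _, mask = predict_volume(model, case, spec, normalize=normalize)
        row = {"case": cid, "dsc": np.nan, "avd_mm": np.nan,
               "asd_mm": np.nan, "note": ""}
        try:
            row["dsc"] = dsc(mask, case.labels)
            row["avd_mm"] = avd(mask, case.labels, case.spacing_mm)
            row["asd_mm"] = asd(mask, case.labels, case.spacing_mm)
        except EmptyMaskError as exc:
            row["note"] = str(exc)
        rows.append(row)
    df = pd.DataFrame(rows)
    mean_row = {"case": "Mean",
                "dsc": df["dsc"].mean(), "avd_mm": df["avd_mm"].mean(),
                "asd_mm": df["asd_mm"].mean(), "note": ""}
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
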