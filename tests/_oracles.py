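"""Independent brute-force oracles for the evaluation metrics.

Deliberately naive: voxel sets as python sets / explicit all-pairs distance
matrices, surface detection by enumerating the six face neighbours.  These
never share code with the package implementations they check.
"""

import numpy as np


def voxel_set(mask):
    return {tuple(idx) for idx in np.argwhere(np.asarray(mask, dtype=bool))}


def brute_dsc(P, G):
    sp, sg = voxel_set(P), voxel_set(G)
    return 2.0 * len(sp & sg) / (len(sp) + len(sg))


def _pair_dists(A, B, spacing):
    A = np.asarray(sorted(A), dtype=float) * spacing
    B = np.asarray(sorted(B), dtype=float) * spacing
    return np.sqrt(((A[:, None, :] - B[None, :, :]) ** 2).sum(-1))


def brute_avd(P, G, spacing=(1.0, 1.0, 1.0)):
    sp, sg = voxel_set(P), voxel_set(G)
    d = _pair_dists(sp, sg, np.asarray(spacing))
    return max(d.min(axis=1).mean(), d.min(axis=0).mean())


def brute_surface(mask):
    mask = np.asarray(mask, dtype=bool)
    out = set()
    for v in voxel_set(mask):
        for ax in range(3):
            for dlt in (-1, 1):
                n = list(v)
                n[ax] += dlt
                if not (0 <= n[ax] < mask.shape[ax]) or not mask[tuple(n)]:
                    out.add(v)
    return out


def brute_asd(R, G, spacing=(1.0, 1.0, 1.0)):
    sr, sg = brute_surface(R), brute_surface(G)
    d = _pair_dists(sr, sg, np.asarray(spacing))
    return (d.min(axis=1).sum() + d.min(axis=0).sum()) / (len(sr) + len(sg))


def random_mask_pair(rng, shape=(8, 8, 8), p=0.08):
    """Two random non-empty masks (re-drawn until non-empty)."""
    while True:
        P = rng.random(shape) < p
        G = rng.random(shape) < p
        if P.any() and G.any():
            return P, G
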