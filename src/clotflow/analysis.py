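"""Post-processing helpers: thrombus centroids, interface shear, and
embolus (detached-fragment) detection."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .fields import Grid, deriv

__all__ = ["thrombus_centroid", "clot_surface_shear", "detect_emboli"]


def thrombus_centroid(phi: np.ndarray, grid: Grid, mask=None) -> np.ndarray:
    """Thrombus-weighted centroid, weight (1 - phi); sub-grid resolution."""
    w = 1.0 - phi
    if mask is not None:
        w = w * mask
    Xs = grid.meshgrid()
    tot = w.sum()
    if tot <= 0:
        raise ValueError("no thrombus in the (masked) domain")
    return np.array([float((X * w).sum() / tot) for X in Xs])


def clot_surface_shear(state, eta_field: np.ndarray,
                       band=(0.25, 0.75)) -> float:
    """Maximum viscous shear magnitude eta |du_x/dy| over the interfacial
    band ``band[0] < phi < band[1]`` (a surrogate for the shear stress acting
    on the clot surface)."""
    grid = state.grid
    dudy = deriv(state.u[0], grid, 1, bc="extrap")
    sel = (state.phi > band[0]) & (state.phi < band[1])
    if not sel.any():
        return 0.0
    return float(np.max(np.abs(eta_field * dudy)[sel]))


def detect_emboli(phi: np.ndarray, grid: Grid, threshold: float = 0.5,
                  lumen_mask=None, min_nodes: int = 2) -> dict:
    """Label connected thrombus components (1 - phi > 1 - threshold) and
    classify all but the largest as detached fragments (emboli).

    Returns component count, embolus count, and per-component node counts.
    Periodic axes are handled by joining labels across the wrap.
    """
    solid = phi < threshold
    if lumen_mask is not None:
        solid = solid & lumen_mask
    labels, n = ndimage.label(solid)
    # merge labels across periodic wraps
    for a in range(grid.ndim):
        if not grid.periodic[a]:
            continue
        lo = np.take(labels, 0, axis=a)
        hi = np.take(labels, -1, axis=a)
        for la, lb in zip(lo.ravel(), hi.ravel()):
            if la > 0 and lb > 0 and la != lb:
                labels[labels == lb] = la
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = counts >= min_nodes
    ids, counts = ids[keep], counts[keep]
    n_comp = len(ids)
    return {"n_components": int(n_comp),
            "n_emboli": int(max(0, n_comp - 1)),
            "component_sizes": sorted((int(c) for c in counts),
                                      reverse=True)}
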