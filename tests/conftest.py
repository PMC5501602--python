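"""Shared fixtures: canonical flow solutions (expensive, session-scoped)
and independent brute-force oracles used to cross-check the package."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from osteoflow.flow_solver import PorousProps, refine_until_converged, solve_flow
from osteoflow.geometry import FlowBoundaryCondition, build_geometry, rasterize

V_LOW = 1e-3  # m/s
V_HIGH = 0.061  # m/s
Q_LOW = 0.2e-6 / 60.0  # m^3/s (0.2 ml/min)


@pytest.fixture(scope="session")
def canonical_geometry():
    return build_geometry()


@pytest.fixture(scope="session")
def vlow_converged(canonical_geometry):
    """Mesh-refinement sweep at the low operating point (inertia on)."""
    sol, report = refine_until_converged(
        canonical_geometry, None, PorousProps(), FlowBoundaryCondition(V_LOW),
        initial_spacing=205e-6, criterion=0.02, tol=1e-6,
    )
    return sol, report


@pytest.fixture(scope="session")
def vhigh_solution(canonical_geometry, vlow_converged):
    """High operating point solved on the spacing the sweep converged at."""
    _, report = vlow_converged
    grid = rasterize(canonical_geometry, report.spacings[-1])
    return solve_flow(grid, None, PorousProps(), FlowBoundaryCondition(V_HIGH),
                      include_inertia=True, tol=1e-5, max_iter=80)


# ----------------------------------------------------------------------
# independent oracles
# ----------------------------------------------------------------------


def auc_mann_whitney(tau: np.ndarray, labels: np.ndarray) -> float:
    """Double-loop Mann-Whitney statistic Pr(tau_pos > tau_neg) + Pr(tie)/2."""
    pos = tau[labels.astype(bool)]
    neg = tau[~labels.astype(bool)]
    total = 0.0
    for tp in pos:
        for tn in neg:
            if tp > tn:
                total += 1.0
            elif tp == tn:
                total += 0.5
    return total / (len(pos) * len(neg))


def roc_by_enumeration(tau: np.ndarray, labels: np.ndarray):
    """Exhaustive threshold enumeration with the rule 'positive if tau >= t'.

    Returns (thresholds, tpr, fpr) over +inf and every unique tau value.
    """
    labels = labels.astype(bool)
    P = labels.sum()
    N = len(labels) - P
    thresholds = [np.inf] + sorted(np.unique(tau), reverse=True)
    tpr, fpr = [], []
    for t in thresholds:
        pred = tau >= t
        tpr.append((pred & labels).sum() / P)
        fpr.append((pred & ~labels).sum() / N)
    return np.array(thresholds), np.array(tpr), np.array(fpr)


_OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
_OFFSETS_6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def flood_fill_label(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Brute-force BFS flood-fill component labeling (independent of scipy)."""
    offsets = _OFFSETS_26 if connectivity == 26 else _OFFSETS_6
    nx, ny, nz = mask.shape
    labels = np.zeros(mask.shape, dtype=np.int32)
    current = 0
    for sx, sy, sz in zip(*np.nonzero(mask)):
        if labels[sx, sy, sz]:
            continue
        current += 1
        queue = deque([(sx, sy, sz)])
        labels[sx, sy, sz] = current
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in offsets:
                u, v, w = x + dx, y + dy, z + dz
                if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz \
                        and mask[u, v, w] and not labels[u, v, w]:
                    labels[u, v, w] = current
                    queue.append((u, v, w))
    return labels


def brute_force_gaussian_kernel(sigma: float, support: int) -> np.ndarray:
    """Directly constructed truncated/renormalized 3-D Gaussian kernel."""
    ax = np.arange(-support, support + 1, dtype=float)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    k = np.exp(-(X**2 + Y**2 + Z**2) / (2 * sigma**2))
    return k / k.sum()
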