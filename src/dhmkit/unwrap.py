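"""2D phase unwrapping by reliability sorting (noncontinuous path).

Pixels are scored by a reliability derived from wrapped second differences;
edges between 4-connected neighbours are then processed in order of
decreasing summed reliability, merging pixel groups and adding integer
multiples of 2π to the smaller group so that the two pixels joined by the
edge differ by less than π.  The most reliable regions are therefore
unwrapped first and noisy regions last, without following any continuous
spatial path.

The merge loop is JIT-compiled with numba when available; a pure-Python
fallback keeps the module dependency-light.
"""
from __future__ import annotations

import numpy as np

from .optics import PhaseMap

__all__ = ["ReliabilityMap", "reliability_map", "unwrap_phase"]

try:  # optional acceleration
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is normally present
    _njit = None

TWO_PI = 2.0 * np.pi


class ReliabilityMap:
    """Per-pixel nonnegative reliability scores (border pixels lowest)."""

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("reliability map must be 2D")
        if not np.isfinite(values).all():
            raise ValueError("reliability scores must be finite")
        if (values < 0).any():
            raise ValueError("reliability scores must be nonnegative")
        self.values = values


def _wrap_diff(d: np.ndarray) -> np.ndarray:
    """Wrap differences into [-pi, pi)."""
    return np.mod(d + np.pi, TWO_PI) - np.pi


def reliability_map(wrapped: PhaseMap) -> ReliabilityMap:
    """Reliability = 1 / D, with D the root-sum-square of the wrapped second
    differences over the horizontal, vertical and two diagonal neighbour
    triples.  Border pixels, where the triples are undefined, get score 0 so
    they are merged last.
    """
    if not wrapped.wrapped:
        raise ValueError("reliability_map expects a wrapped phase")
    p = wrapped.values
    if p.shape[0] < 3 or p.shape[1] < 3:
        raise ValueError("image must be at least 3x3 to score reliability")

    c = p[1:-1, 1:-1]
    h = _wrap_diff(p[1:-1, :-2] - c) - _wrap_diff(c - p[1:-1, 2:])
    v = _wrap_diff(p[:-2, 1:-1] - c) - _wrap_diff(c - p[2:, 1:-1])
    d1 = _wrap_diff(p[:-2, :-2] - c) - _wrap_diff(c - p[2:, 2:])
    d2 = _wrap_diff(p[:-2, 2:] - c) - _wrap_diff(c - p[2:, :-2])
    second_diff = np.sqrt(h * h + v * v + d1 * d1 + d2 * d2)

    rel = np.zeros_like(p)
    with np.errstate(divide="ignore"):
        interior = 1.0 / np.maximum(second_diff, np.finfo(float).tiny)
    rel[1:-1, 1:-1] = np.minimum(interior, np.finfo(float).max)
    return ReliabilityMap(rel)


def _merge_edges_py(w, m, ea, eb, label, head, nxt, last, size):
    for idx in range(ea.shape[0]):
        a, b = ea[idx], eb[idx]
        ra, rb = label[a], label[b]
        if ra == rb:
            continue
        step = int(np.rint(((w[a] + TWO_PI * m[a])
                            - (w[b] + TWO_PI * m[b])) / TWO_PI))
        if size[ra] < size[rb]:
            ra, rb = rb, ra
            step = -step
        # shift rb's members by +step so b aligns with a, then splice lists
        q = head[rb]
        while q != -1:
            m[q] += step
            label[q] = ra
            q = nxt[q]
        nxt[last[ra]] = head[rb]
        last[ra] = last[rb]
        size[ra] += size[rb]


if _njit is not None:
    _merge_edges = _njit(cache=False)(_merge_edges_py)
else:  # pragma: no cover
    _merge_edges = _merge_edges_py


def unwrap_phase(wrapped: PhaseMap) -> PhaseMap:
    """Unwrap a 2D phase map by descending-reliability edge merging.

    The output differs from the input by an integer multiple of 2π at every
    pixel; no global offset is fixed here (downstream ring background
    subtraction owns the zero level).  The procedure is deterministic: edges
    are sorted with a stable sort and ties resolved by row-major edge index
    (horizontal edges before vertical).
    """
    rel = reliability_map(wrapped).values
    p = wrapped.values
    ny, nx = p.shape
    n = ny * nx

    # edge endpoints (flat indices), horizontal then vertical, row-major
    ii, jj = np.meshgrid(np.arange(ny), np.arange(nx - 1), indexing="ij")
    ha = (ii * nx + jj).ravel()
    hb = ha + 1
    ii, jj = np.meshgrid(np.arange(ny - 1), np.arange(nx), indexing="ij")
    va = (ii * nx + jj).ravel()
    vb = va + nx

    ea = np.concatenate([ha, va])
    eb = np.concatenate([hb, vb])
    flat_rel = rel.ravel()
    edge_rel = flat_rel[ea] + flat_rel[eb]
    order = np.argsort(-edge_rel, kind="stable")
    ea, eb = ea[order], eb[order]

    w = p.ravel().astype(np.float64)
    m = np.zeros(n, dtype=np.int64)
    label = np.arange(n, dtype=np.int64)
    head = np.arange(n, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    last = np.arange(n, dtype=np.int64)
    size = np.ones(n, dtype=np.int64)

    _merge_edges(w, m, ea.astype(np.int64), eb.astype(np.int64),
                 label, head, nxt, last, size)

    out = (w + TWO_PI * m.astype(np.float64)).reshape(ny, nx)
    return PhaseMap(out, wrapped=False)
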