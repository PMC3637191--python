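r"""Zero-crossing finger-print maps and contour tracing.

For each layer of the scale-space image the second derivative is
approximated by the second-order difference and its zero-crossings are
marked: ``z[i,k] = +1`` where the curvature crosses from minus to plus
(left edge of a concave-up trough), ``-1`` where it crosses from plus to
minus. The collection of crossings over all layers is the finger-print map;
its contours bound concave-up/concave-down intervals of the signal and can
only close upward (disappear) as the scale grows.

Because Gaussian smoothing displaces inflection points outward, a boundary
detected at a coarse layer is localised by tracing its contour down the
layer stack to layer 0, greedily re-matching the nearest same-sign crossing
within a search radius at each step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .scale_space import ScaleSpaceImage

__all__ = [
    "FingerPrintMap",
    "second_difference",
    "zero_crossing_signal",
    "build_fingerprint_map",
    "trace_boundary",
    "write_fingerprint_tsv",
]


def second_difference(layer: np.ndarray) -> np.ndarray:
    """Second-order difference ``x[i+1] - 2 x[i] + x[i-1]``; end samples 0."""
    layer = np.asarray(layer, dtype=float)
    if layer.size < 3:
        raise ValueError("need at least 3 samples")
    out = np.zeros_like(layer)
    out[1:-1] = layer[2:] - 2.0 * layer[1:-1] + layer[:-2]
    return out


def zero_crossing_signal(second_diff: np.ndarray, atol: float = 0.0) -> np.ndarray:
    """Mark sign changes of the curvature.

    ``z[i] = +1`` iff ``d[i+1] > 0`` and ``d[i-1] < 0``; ``z[i] = -1`` for the
    opposite signs; 0 elsewhere (the value at ``i`` itself is not consulted).
    End samples are 0 by convention. Values with ``|d| <= atol`` count as
    zero; a small ``atol`` suppresses sign flips that sit below the floating
    point resolution of the layer the differences came from.
    """
    d = np.asarray(second_diff, dtype=float)
    if d.size < 3:
        raise ValueError("need at least 3 samples")
    z = np.zeros(d.size, dtype=np.int8)
    up = (d[2:] > atol) & (d[:-2] < -atol)
    dn = (d[2:] < -atol) & (d[:-2] > atol)
    z[1:-1][up] = 1
    z[1:-1][dn] = -1
    return z


@dataclass
class FingerPrintMap:
    """Dense map of zero-crossing signals: ``z[i, k]`` in {-1, 0, +1}."""

    z: np.ndarray  # shape (n, layers), int8
    sigmas: np.ndarray

    @property
    def n(self) -> int:
        return self.z.shape[0]

    @property
    def layers(self) -> int:
        return self.z.shape[1]

    @property
    def nonzero_counts(self) -> np.ndarray:
        return np.count_nonzero(self.z, axis=0)

    def crossings(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Positions and signs of the non-zero entries of layer ``k``."""
        pos = np.flatnonzero(self.z[:, k])
        return pos, self.z[pos, k].astype(int)


def build_fingerprint_map(image: ScaleSpaceImage) -> FingerPrintMap:
    """Zero-crossing signal of the second difference of every layer.

    Second differences within round-off of the layer values (1e-12 of the
    layer's peak magnitude) are treated as zero, so an exactly flat layer
    computed through the FFT route yields an empty map.
    """
    z = np.zeros(image.values.shape, dtype=np.int8)
    for k in range(image.layers):
        layer = image.layer(k)
        atol = 1e-12 * float(np.max(np.abs(layer))) if layer.size else 0.0
        z[:, k] = zero_crossing_signal(second_difference(layer), atol=atol)
    return FingerPrintMap(z=z, sigmas=np.asarray(image.sigmas))


# ---------------------------------------------------------------------------
# Contour tracing
# ---------------------------------------------------------------------------

def _nearest_same_sign(positions: np.ndarray, pos: int, radius: int) -> int | None:
    """Nearest element of a sorted position array within ``radius`` of ``pos``.

    Ties between equidistant candidates resolve toward the smaller index.
    """
    if positions.size == 0:
        return None
    idx = np.searchsorted(positions, pos)
    best = None
    best_d = radius + 1
    if idx > 0:
        d = pos - positions[idx - 1]
        if d < best_d:
            best, best_d = int(positions[idx - 1]), int(d)
    if idx < positions.size:
        d = positions[idx] - pos
        if d < best_d:  # strict: left (smaller index) wins ties
            best, best_d = int(positions[idx]), int(d)
    return best


def trace_contour(
    crossing_positions: list[tuple[np.ndarray, np.ndarray]],
    sigmas: np.ndarray,
    pos: int,
    layer: int,
    sign: int,
) -> int:
    """Trace a crossing down to layer 0 over per-layer crossing position lists.

    ``crossing_positions[k]`` is a pair ``(plus_positions, minus_positions)``
    of sorted arrays. At each step from layer ``k`` to ``k-1`` the trace moves
    to the nearest same-sign crossing within ``ceil(3 * sigma_k)``; when no
    candidate exists (the contour was annihilated below), the current
    position is retained.
    """
    cur = int(pos)
    for k in range(layer, 0, -1):
        radius = math.ceil(3.0 * float(sigmas[k]))
        plus, minus = crossing_positions[k - 1]
        cand = _nearest_same_sign(plus if sign > 0 else minus, cur, radius)
        if cand is not None:
            cur = cand
    return cur


def crossing_lists(fpmap: FingerPrintMap) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-layer ``(plus_positions, minus_positions)`` sorted arrays."""
    out = []
    for k in range(fpmap.layers):
        pos, signs = fpmap.crossings(k)
        out.append((pos[signs > 0], pos[signs < 0]))
    return out


def trace_boundary(fpmap: FingerPrintMap, pos: int, layer: int, sign: int) -> int:
    """Trace the crossing at ``(pos, layer)`` down to its layer-0 position."""
    if fpmap.z[pos, layer] != sign:
        raise ValueError(f"no crossing of sign {sign} at position {pos}, layer {layer}")
    return trace_contour(crossing_lists(fpmap), fpmap.sigmas, pos, layer, sign)


def write_fingerprint_tsv(fpmap: FingerPrintMap, path) -> None:
    """Export ``(layer, sigma, position, sign)`` rows for plotting."""
    with open(path, "w") as fh:
        fh.write("layer\tsigma\tposition\tsign\n")
        for k in range(fpmap.layers):
            pos, signs = fpmap.crossings(k)
            for p, s in zip(pos, signs):
                fh.write(f"{k}\t{fpmap.sigmas[k]:.6g}\t{p}\t{s:+d}\n")
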