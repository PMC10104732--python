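"""Clustering-threshold segmentation and live-wire boundary extraction.

The threshold selector partitions voxels at a test threshold t into a
bright foreground B1 (intensity >= t, the contrast-filled lumen) and a
dark background B2 (intensity < t), computes the class means

    a1 = (1/M1) sum_{p in B1} p,    a2 = (1/M2) sum_{p in B2} p,

and scores the partition by the total within-class sum of squared
deviations

    G(t) = sum_{p in B1} (p - a1)^2 + sum_{p in B2} (p - a2)^2 .

Scanning every candidate t and taking the argmin of G is the two-class
clustering (Otsu / 2-means) criterion: minimizing within-class scatter
is equivalent to maximizing between-class variance.  Ties are broken
toward the smallest t; an empty class contributes zero scatter.

The live-wire extractor finds a minimum-cost 8-connected path between
two user points on a slice, with a local cost favouring strong
gradients and Laplacian zero crossings — the classic interactive
boundary-tracing formulation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .volume import CTVolume

__all__ = [
    "ThresholdResult",
    "PixelPath",
    "class_stats",
    "objective_G",
    "optimal_threshold",
    "apply_threshold",
    "largest_component",
    "live_wire",
]


def _values(volume) -> np.ndarray:
    data = volume.data if isinstance(volume, CTVolume) else np.asarray(volume)
    return data.reshape(-1).astype(float)


@dataclass
class ThresholdResult:
    """Optimal clustering threshold with its objective curve and class stats."""

    threshold: float                 # t*, argmin of G over the scanned grid
    thresholds: np.ndarray           # scanned t values
    objective: np.ndarray            # G(t) for each scanned t
    foreground_mean: float           # a1 at t*
    background_mean: float           # a2 at t*
    foreground_count: int            # M1 at t*
    background_count: int            # M2 at t*
    overall_mean: float              # count-weighted mean of a1, a2

    def to_json(self, path=None) -> str:
        payload = {
            "threshold": self.threshold,
            "foreground_mean": self.foreground_mean,
            "background_mean": self.background_mean,
            "foreground_count": self.foreground_count,
            "background_count": self.background_count,
            "overall_mean": self.overall_mean,
            "thresholds": np.asarray(self.thresholds).tolist(),
            "objective": np.asarray(self.objective).tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def class_stats(volume, t: float):
    """Class means and counts for the partition at threshold t.

    Returns ``(a1, a2, M1, M2, abar)`` with foreground = intensity >= t.
    An empty class has count 0 and mean NaN (flagged); ``abar`` is
    always the overall mean.
    """
    p = _values(volume)
    fg = p >= t
    m1 = int(fg.sum())
    m2 = p.size - m1
    a1 = float(p[fg].mean()) if m1 else float("nan")
    a2 = float(p[~fg].mean()) if m2 else float("nan")
    return a1, a2, m1, m2, float(p.mean())


def objective_G(volume, t: float) -> float:
    """Within-class sum of squared deviations at threshold t.

    An empty class contributes zero scatter, so G is defined for every t.
    """
    p = _values(volume)
    fg = p >= t
    g = 0.0
    for cls in (p[fg], p[~fg]):
        if cls.size:
            g += float(np.sum((cls - cls.mean()) ** 2))
    return g


def _scan_objective(p: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """G(t) over a grid of thresholds via sorted cumulative sums."""
    x = np.sort(p)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x**2)])
    n = x.size
    # background = values < t
    m2 = np.searchsorted(x, ts, side="left")
    s2, q2 = cs[m2], cs2[m2]
    s1, q1 = cs[n] - s2, cs2[n] - q2
    m1 = n - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        g = (q1 - np.where(m1 > 0, s1**2 / np.maximum(m1, 1), 0.0)) + (
            q2 - np.where(m2 > 0, s2**2 / np.maximum(m2, 1), 0.0)
        )
    return g


def optimal_threshold(
    volume,
    t_min: float | None = None,
    t_max: float | None = None,
    step: float = 1.0,
) -> ThresholdResult:
    """Scan thresholds on a grid and return the argmin of G.

    Defaults scan every integer intensity between the volume's min
    (exclusive) and max (inclusive), so both classes can be non-empty.
    Ties in G are broken toward the smallest t.
    """
    if step <= 0:
        raise ValidationError("step must be positive")
    p = _values(volume)
    if t_min is None:
        t_min = np.floor(p.min()) + 1.0
    if t_max is None:
        t_max = np.ceil(p.max())
    if t_min > t_max:
        raise ValidationError(f"empty scan range [{t_min}, {t_max}]")
    ts = np.arange(t_min, t_max + 0.5 * step, step)
    g = _scan_objective(p, ts)
    best = int(np.argmin(g))  # argmin returns the first minimum: smallest t
    t_star = float(ts[best])
    a1, a2, m1, m2, abar = class_stats(p, t_star)
    return ThresholdResult(
        threshold=t_star,
        thresholds=ts,
        objective=g,
        foreground_mean=a1,
        background_mean=a2,
        foreground_count=m1,
        background_count=m2,
        overall_mean=abar,
    )


def apply_threshold(volume, t: float):
    """Binary mask, true where intensity >= t.

    Returns a bool :class:`CTVolume` when given one (metadata kept),
    else a bool array.
    """
    if isinstance(volume, CTVolume):
        return CTVolume(volume.data >= t, spacing=volume.spacing, origin=volume.origin)
    return np.asarray(volume) >= t


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def largest_component(mask, connectivity: int = 26):
    """Keep only the largest connected true-component of a 3-D mask.

    ``connectivity`` counts the neighbours sharing a face / edge /
    corner: 6, 18 or 26.  Size ties are broken toward the component
    containing the lowest linear (C-order) index.  An all-false mask is
    returned unchanged with a warning.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValidationError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    vol = mask if isinstance(mask, CTVolume) else None
    data = np.asarray(mask.data if vol is not None else mask).astype(bool)
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndimage.label(data, structure=structure)
    if n == 0:
        warnings.warn("largest_component: mask is empty", stacklevel=2)
        out = data
    else:
        sizes = np.bincount(labels.reshape(-1))[1:]
        biggest = sizes.max()
        candidates = np.flatnonzero(sizes == biggest) + 1
        if candidates.size == 1:
            keep = candidates[0]
        else:  # tie: earliest first-occurrence in linear order wins
            flat = labels.reshape(-1)
            firsts = {int(lab): int(np.argmax(flat == lab)) for lab in candidates}
            keep = min(firsts, key=firsts.get)
        out = labels == keep
    if vol is not None:
        return CTVolume(out, spacing=vol.spacing, origin=vol.origin)
    return out


@dataclass
class PixelPath:
    """An ordered 8-connected pixel path with its accumulated cost."""

    points: list[tuple[int, int]]
    cost: float


def _local_cost(image: np.ndarray, w_gradient: float, w_zerocross: float) -> np.ndarray:
    """Per-pixel live-wire cost in [0, w_g + w_z]: low on strong edges."""
    img = np.asarray(image, dtype=float)
    gy = ndimage.sobel(img, axis=0, mode="nearest")
    gx = ndimage.sobel(img, axis=1, mode="nearest")
    grad = np.hypot(gy, gx)
    gmax = grad.max()
    gnorm = grad / gmax if gmax > 0 else np.zeros_like(grad)
    lap = ndimage.laplace(img, mode="nearest")
    zc = np.zeros(img.shape, dtype=bool)
    zc |= lap == 0
    for axis in (0, 1):
        a = lap
        b = np.roll(lap, -1, axis=axis)
        flip = (a * b < 0)
        flip[tuple(slice(None) if ax != axis else slice(-1, None) for ax in (0, 1))] = False
        # mark the pixel of the pair closer to the zero level
        zc |= flip & (np.abs(a) <= np.abs(b))
        zc |= np.roll(flip & (np.abs(b) < np.abs(a)), 1, axis=axis)
    return w_gradient * (1.0 - gnorm) + w_zerocross * (1.0 - zc.astype(float))


_STEPS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def live_wire(
    image_slice,
    seed_point: tuple[int, int],
    target_point: tuple[int, int],
    w_gradient: float = 0.8,
    w_zerocross: float = 0.2,
) -> PixelPath:
    """Minimum-cost 8-connected path between two points on a 2-D slice.

    The cost of stepping onto pixel q is
    ``cost(q) * (sqrt(2) if diagonal else 1)`` with
    ``cost = w_g (1 - |grad I| / max|grad I|) + w_z (1 - zc)``, where zc
    indicates a Laplacian zero crossing.  Dijkstra search; deterministic.
    """
    img = np.asarray(image_slice, dtype=float)
    if img.ndim != 2:
        raise ValidationError("live_wire operates on a 2-D slice")
    for name, pt in (("seed", seed_point), ("target", target_point)):
        if not (0 <= pt[0] < img.shape[0] and 0 <= pt[1] < img.shape[1]):
            raise ValidationError(f"{name} point {pt} outside the slice")
    seed = (int(seed_point[0]), int(seed_point[1]))
    target = (int(target_point[0]), int(target_point[1]))
    if seed == target:
        return PixelPath(points=[seed], cost=0.0)

    cost = _local_cost(img, w_gradient, w_zerocross)
    import heapq

    dist = np.full(img.shape, np.inf)
    dist[seed] = 0.0
    prev: dict[tuple[int, int], tuple[int, int]] = {}
    heap = [(0.0, seed)]
    while heap:
        d, (i, j) = heapq.heappop(heap)
        if d > dist[i, j]:
            continue
        if (i, j) == target:
            break
        for di, dj in _STEPS:
            ni, nj = i + di, j + dj
            if not (0 <= ni < img.shape[0] and 0 <= nj < img.shape[1]):
                continue
            scale = np.sqrt(2.0) if di and dj else 1.0
            nd = d + cost[ni, nj] * scale
            if nd < dist[ni, nj]:
                dist[ni, nj] = nd
                prev[(ni, nj)] = (i, j)
                heapq.heappush(heap, (nd, (ni, nj)))
    path = [target]
    while path[-1] != seed:
        path.append(prev[path[-1]])
    path.reverse()
    return PixelPath(points=path, cost=float(dist[target]))
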