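"""Partition a wound mask into parameter-homogeneous segments.

The segmenter merges 4-connected regions greedily, starting from single
pixels, always taking the adjacent pair whose merged within-region spread is
smallest (ties broken by pixel index), and stopping once no merge keeps the
spread below the homogeneity threshold tau. The spread of a region is the
maximum over the eight parameter channels of the within-region standard
deviation. Because the merge sequence for a smaller tau is a prefix of the
sequence for a larger one, the number of segments is non-increasing in tau.
Regions below the minimum area are absorbed into the adjacent region with
the closest channel mean. The procedure has no random step: identical
inputs give identical partitions.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .secondary import PARAM_CHANNELS

__all__ = [
    "Segment",
    "homogeneity",
    "segment_wound",
    "single_class_check",
]


@dataclass(frozen=True)
class Segment:
    """A connected, parameter-homogeneous pixel set."""

    id: int
    pixels: np.ndarray  # (N, 2) row/col indices, row-major sorted
    area_cm2: float
    mean: dict
    sd: dict
    homogeneity_score: float


def _stats_sd(n, s, q):
    var = np.maximum(q / n - (s / n) ** 2, 0.0)
    return np.sqrt(var)


def homogeneity(pixels: np.ndarray, param_maps: np.ndarray) -> float:
    """Max-over-channels within-set SD (population); 0 for constant maps."""
    pixels = np.asarray(pixels)
    if pixels.ndim == 2 and pixels.shape[1] == 2:
        vals = param_maps[pixels[:, 0], pixels[:, 1], :]
    else:  # boolean mask
        vals = param_maps[pixels.astype(bool)]
    if vals.shape[0] == 0:
        raise ValueError("empty pixel set")
    # shift by the first row so constant regions score exactly 0
    return float(np.max(np.std(vals - vals[0], axis=0)))


class _Regions:
    """Union-find with per-region channel statistics and adjacency."""

    def __init__(self, maps, mask):
        h, w, c = maps.shape
        flat_ids = np.flatnonzero(mask.ravel())
        self.parent = {int(i): int(i) for i in flat_ids}
        self.version = {int(i): 0 for i in flat_ids}
        vals = maps.reshape(-1, c)
        self.n = {int(i): 1 for i in flat_ids}
        self.s = {int(i): vals[i].astype(float).copy() for i in flat_ids}
        self.q = {int(i): (vals[i].astype(float) ** 2).copy() for i in flat_ids}
        self.members = {int(i): [int(i)] for i in flat_ids}
        self.adj = {int(i): set() for i in flat_ids}
        mask = mask.astype(bool)
        for r in range(h):
            for col in range(w):
                if not mask[r, col]:
                    continue
                i = r * w + col
                if col + 1 < w and mask[r, col + 1]:
                    self.adj[i].add(i + 1)
                    self.adj[i + 1].add(i)
                if r + 1 < h and mask[r + 1, col]:
                    self.adj[i].add(i + w)
                    self.adj[i + w].add(i)

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def merged_score(self, a, b):
        n = self.n[a] + self.n[b]
        s = self.s[a] + self.s[b]
        q = self.q[a] + self.q[b]
        return float(np.max(_stats_sd(n, s, q)))

    def merge(self, a, b):
        """Merge b into a (a must be the smaller representative)."""
        self.parent[b] = a
        self.n[a] += self.n[b]
        self.s[a] = self.s[a] + self.s[b]
        self.q[a] = self.q[a] + self.q[b]
        self.members[a].extend(self.members[b])
        newadj = (self.adj[a] | self.adj[b]) - {a, b}
        self.adj[a] = newadj
        for c in newadj:
            self.adj[c].discard(b)
            self.adj[c].add(a)
        self.version[a] += 1
        del self.s[b], self.q[b], self.members[b], self.adj[b], self.version[b]
        return a

    def roots(self):
        return sorted({self.find(i) for i in self.parent})


def _push_candidates(reg, heap, root):
    for nb in sorted(reg.adj[root]):
        a, b = (root, nb) if root < nb else (nb, root)
        heapq.heappush(
            heap,
            (reg.merged_score(a, b), a, b, reg.version[a], reg.version[b]),
        )


def segment_wound(
    param_maps: np.ndarray,
    mask: np.ndarray,
    tau: float = 0.05,
    min_area: int = 4,
    pixel_pitch_mm: float = 0.5,
    channel_names=None,
) -> tuple[np.ndarray, list[Segment]]:
    """Segment the masked area into parameter-homogeneous regions.

    ``param_maps`` is H x W x C (the eight secondary-parameter channels),
    ``mask`` the wound mask. Returns an integer label image (0 = background,
    labels in row-major order of each segment's first pixel) and the segment
    list. Every masked pixel belongs to exactly one segment.
    """
    maps = np.asarray(param_maps, float)
    mask = np.asarray(mask, bool)
    if maps.shape[:2] != mask.shape:
        raise ValueError("param_maps and mask shapes differ")
    if not mask.any():
        raise ValueError("empty mask")
    h, w, c = maps.shape
    if channel_names is None:
        channel_names = (
            PARAM_CHANNELS if c == len(PARAM_CHANNELS)
            else tuple(f"ch{i}" for i in range(c))
        )

    reg = _Regions(maps, mask)
    heap: list = []
    for i in sorted(reg.adj):
        for j in sorted(reg.adj[i]):
            if i < j:
                heapq.heappush(heap, (reg.merged_score(i, j), i, j, 0, 0))

    while heap:
        score, a, b, va, vb = heapq.heappop(heap)
        if score > tau:
            break
        if reg.parent.get(a) != a or reg.parent.get(b) != b:
            continue
        if reg.version[a] != va or reg.version[b] != vb:
            continue
        root = reg.merge(a, b)
        _push_candidates(reg, heap, root)

    # absorb undersized regions into the most similar adjacent region
    while True:
        roots = reg.roots()
        if len(roots) <= 1:
            break
        small = sorted(
            (r for r in roots if reg.n[r] < min_area),
            key=lambda r: (reg.n[r], r),
        )
        if not small:
            break
        r = small[0]
        neighbors = sorted(reg.adj[r])
        if not neighbors:
            break
        mean_r = reg.s[r] / reg.n[r]
        dist = [
            (float(np.linalg.norm(reg.s[nb] / reg.n[nb] - mean_r)), nb)
            for nb in neighbors
        ]
        _, target = min(dist)
        a, b = (target, r) if target < r else (r, target)
        reg.merge(a, b)

    labels = np.zeros((h, w), np.int32)
    segments = []
    pitch_cm = pixel_pitch_mm / 10.0
    for new_id, root in enumerate(sorted(reg.roots()), start=1):
        flat = np.array(sorted(reg.members[root]))
        rows, cols = np.unravel_index(flat, (h, w))
        labels[rows, cols] = new_id
        vals = maps[rows, cols, :]
        mean = vals.mean(axis=0)
        sd = (vals - vals[0]).std(axis=0)
        segments.append(
            Segment(
                id=new_id,
                pixels=np.column_stack([rows, cols]),
                area_cm2=float(flat.size) * pitch_cm**2,
                mean=dict(zip(channel_names, mean.tolist())),
                sd=dict(zip(channel_names, sd.tolist())),
                homogeneity_score=float(sd.max()),
            )
        )
    return labels, segments


def single_class_check(
    segment: Segment, labels_map: np.ndarray, tolerance: float = 0.95
) -> bool:
    """True iff at least ``tolerance`` of the segment's pixels share one label."""
    vals = labels_map[segment.pixels[:, 0], segment.pixels[:, 1]]
    _, counts = np.unique(vals, return_counts=True)
    return bool(counts.max() / vals.size >= tolerance)
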