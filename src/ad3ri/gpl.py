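"""Gradient Path Labelling segmentation.

Drusen are regional intensity maxima: in the gradient field, ascending paths
from the surrounding pixels converge on them.  GPL segments an image by
assigning every pixel to the maximum its gradient path reaches:

1. per pixel, quantize the Sobel gradient azimuth to one of the 8 compass
   neighbours (the ascending direction);
2. scan top-left to bottom-right; each unvisited pixel starts a new label
   which is propagated along successive ascent directions until the path
   leaves the mask, reaches a flat pixel, or steps onto an already-labelled
   pixel — in which case the two labels are recorded as equivalent;
3. resolve equivalences (union-find) and replace every label group by its
   smallest member;
4. repair the over-segmentation caused by flat hills/valleys by merging
   adjacent regions whose separating border is shallow: on a region adjacency
   graph whose nodes carry the regional maximum intensity and whose links
   carry the minimum border intensity, any pair with
   min(node_i, node_j) - link < delta_a is merged, iterated to a fixed point.

A brute-force steepest-ascent basin reference (:func:`steepest_ascent_basins`)
is provided for validation; on plateau-free images it must produce the same
partition as the scan-order labelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "LabelMap",
    "AdjacencyGraph",
    "gradient_azimuth",
    "label_paths",
    "build_graph",
    "merge_regions",
    "segment",
    "steepest_ascent_basins",
]

#: Compass offsets (row, col), index k at azimuth k*45 deg, 0 = east,
#: positive azimuth toward increasing row (south) so index 2 = south.
OFFSETS = np.array(
    [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)],
    dtype=int,
)
NO_DIRECTION = -1


@dataclass
class LabelMap:
    """Integer label grid (0 = outside mask) plus per-label maxima.

    ``maxima`` maps each label to the (row, col, amplitude) of its
    maximum-intensity pixel.
    """

    labels: np.ndarray
    maxima: dict[int, tuple[int, int, float]] = field(default_factory=dict)

    @property
    def n_labels(self) -> int:
        return len(self.maxima)


@dataclass
class AdjacencyGraph:
    """Region adjacency graph: node = regional max, link = border saddle.

    The link value of an adjacent pair is the saddle of their shared border:
    the highest crossing point, i.e. the maximum over facing 8-connected
    border pixel pairs of the lower of the two intensities.  For a border of
    a single pixel pair this is simply the smaller of the two border values.
    """

    nodes: dict[int, float]
    links: dict[tuple[int, int], float]


def gradient_azimuth(img: np.ndarray) -> np.ndarray:
    """Quantized ascending direction per pixel.

    Returns an int grid of compass indices 0-7 into ``OFFSETS``, or -1
    where both 3x3 Sobel responses vanish (flat neighbourhood).  Exact
    22.5-degree sector boundaries round toward the smaller compass index.
    """
    img = np.asarray(img, dtype=float)
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("image must be at least 3x3 for the Sobel operator")
    gr = ndimage.sobel(img, axis=0, mode="reflect")
    gc = ndimage.sobel(img, axis=1, mode="reflect")
    ang = np.degrees(np.arctan2(gr, gc))  # (-180, 180], 0 = east, 90 = south
    k = np.ceil(ang / 45.0 - 0.5).astype(int) % 8  # half-sector rounds down
    k[(gr == 0) & (gc == 0)] = NO_DIRECTION
    return k


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[int, int] = {}

    def add(self, x: int) -> None:
        self.parent.setdefault(x, x)

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return ra
        lo, hi = (ra, rb) if ra < rb else (rb, ra)
        self.parent[hi] = lo  # groups keep their smallest member
        return lo


def _compute_maxima(img: np.ndarray, labels: np.ndarray) -> dict[int, tuple[int, int, float]]:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return {}
    pos = ndimage.maximum_position(img, labels=labels, index=ids)
    return {
        int(l): (int(r), int(c), float(img[r, c])) for l, (r, c) in zip(ids, pos)
    }


def label_paths(img: np.ndarray, mask: np.ndarray | None = None) -> LabelMap:
    """Pre-merge gradient-path labelling of ``img`` within ``mask``.

    Pixels with no direction (flat 3x3 neighbourhood) adopt the label of
    their first already-labelled 8-neighbour in scan order; isolated flat
    pixels become their own region, left for the merging stage.
    """
    img = np.asarray(img, dtype=float)
    dirs = gradient_azimuth(img)
    rows, cols = img.shape
    if mask is None:
        mask = np.ones(img.shape, dtype=bool)
    labels = np.zeros(img.shape, dtype=np.int32)
    uf = _UnionFind()
    next_label = 1
    offs = [tuple(o) for o in OFFSETS]

    for r in range(rows):
        for c in range(cols):
            if not mask[r, c] or labels[r, c] != 0:
                continue
            if dirs[r, c] == NO_DIRECTION:
                adopted = 0
                for nr, nc in (
                    (r - 1, c - 1), (r - 1, c), (r - 1, c + 1), (r, c - 1),
                    (r, c + 1), (r + 1, c - 1), (r + 1, c), (r + 1, c + 1),
                ):
                    if 0 <= nr < rows and 0 <= nc < cols and labels[nr, nc] != 0:
                        adopted = labels[nr, nc]
                        break
                if adopted:
                    labels[r, c] = adopted
                    continue
                lab = next_label
                next_label += 1
                uf.add(lab)
                labels[r, c] = lab
                continue
            lab = next_label
            next_label += 1
            uf.add(lab)
            cr, cc = r, c
            while True:
                labels[cr, cc] = lab
                d = dirs[cr, cc]
                if d == NO_DIRECTION:
                    break  # path terminates on a flat attractor
                dr, dc = offs[d]
                nr, nc = cr + dr, cc + dc
                if not (0 <= nr < rows and 0 <= nc < cols) or not mask[nr, nc]:
                    break  # ascent leaves the mask
                if img[nr, nc] < img[cr, cc]:
                    break  # discrete summit: the quantized azimuth points
                    # at a lower pixel, so there is no ascending step left
                nlab = labels[nr, nc]
                if nlab != 0:
                    if nlab != lab:
                        uf.union(nlab, lab)  # two paths to the same maximum
                    break  # own label again: equal-valued plateau cycle
                cr, cc = nr, nc

    if next_label > 1:
        # apply equivalences: every group replaced by its smallest member
        lut = np.zeros(next_label, dtype=np.int32)
        for lab in range(1, next_label):
            lut[lab] = uf.find(lab)
        labels = lut[labels]
    return LabelMap(labels=labels, maxima=_compute_maxima(img, labels))


def build_graph(img: np.ndarray, labels: LabelMap | np.ndarray) -> AdjacencyGraph:
    """Region adjacency graph over 8-connected label borders.

    Node value: maximum image intensity within the region.  Link value: the
    saddle intensity of the shared border (see :class:`AdjacencyGraph`) —
    two basins carved out of one smooth bump by direction quantization share
    a border reaching up to the summit, and it is the border's highest
    point, not its lowest, that decides whether the split is an artefact.
    """
    img = np.asarray(img, dtype=float)
    lab = labels.labels if isinstance(labels, LabelMap) else np.asarray(labels)
    maxima = labels.maxima if isinstance(labels, LabelMap) else {}
    if not maxima:
        maxima = _compute_maxima(img, lab)
    nodes = {l: amp for l, (_, _, amp) in maxima.items()}

    links: dict[tuple[int, int], float] = {}
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r0, r1 = max(0, -dr), lab.shape[0] - max(0, dr)
        c0, c1 = max(0, -dc), lab.shape[1] - max(0, dc)
        a = lab[r0:r1, c0:c1]
        b = lab[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        va = img[r0:r1, c0:c1]
        vb = img[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        sel = (a > 0) & (b > 0) & (a != b)
        if not sel.any():
            continue
        pa, pb = a[sel], b[sel]
        lo = np.minimum(pa, pb)
        hi = np.maximum(pa, pb)
        border_val = np.minimum(va[sel], vb[sel])
        order = np.lexsort((hi, lo))
        lo, hi, border_val = lo[order], hi[order], border_val[order]
        boundaries = np.r_[0, np.nonzero(np.diff(lo) | np.diff(hi))[0] + 1]
        saddles = np.maximum.reduceat(border_val, boundaries)
        for i, m in zip(boundaries, saddles):
            key = (int(lo[i]), int(hi[i]))
            if key not in links or m > links[key]:
                links[key] = float(m)
    return AdjacencyGraph(nodes=nodes, links=links)


def merge_regions(
    img: np.ndarray,
    labels: LabelMap,
    graph: AdjacencyGraph | None = None,
    delta_a: float = 3.0,
) -> LabelMap:
    """Merge adjacent regions separated by a shallow border, to fixed point.

    A region is merged away when its prominence — its peak minus its highest
    saddle (the largest link it carries) — is below ``delta_a``; it is
    absorbed into the neighbour across that highest saddle.  Equivalently,
    the qualifying pair (i, j) satisfies min(node_i, node_j) - link_ij <
    delta_a with j the best-connected neighbour of the weaker region.
    Restricting each region to its best link keeps two prominent peaks from
    being chained together through a flat, prominence-free region (such as
    the background) that happens to border both.  The merged node takes the
    larger peak; links of a merged group combine by maximum (the union
    border's saddle).  delta_a controls the detail of the analysis (default
    3 intensity levels on the normalized scale).

    Merging proceeds in simultaneous rounds to a fixed point, each round
    evaluated against the start-of-round state, so the result is independent
    of link enumeration order.
    """
    if delta_a < 0:
        raise ValueError("delta_a must be >= 0")
    img = np.asarray(img, dtype=float)
    if graph is None:
        graph = build_graph(img, labels)
    node_val = dict(graph.nodes)
    links = dict(graph.links)
    uf = _UnionFind()
    for l in node_val:
        uf.add(l)

    while links:
        # per region: best (highest) saddle and the neighbour across it;
        # ties break toward the smaller neighbour label for determinism
        best: dict[int, tuple[float, int]] = {}
        for (a, b), lv in links.items():
            for i, j in ((a, b), (b, a)):
                cur = best.get(i)
                if cur is None or lv > cur[0] or (lv == cur[0] and j < cur[1]):
                    best[i] = (lv, j)
        to_merge = [
            (i, j)
            for i, (saddle, j) in best.items()
            if node_val[i] - saddle < delta_a
        ]
        if not to_merge:
            break
        for i, j in to_merge:
            ri, rj = uf.find(i), uf.find(j)
            if ri == rj:
                continue
            root = uf.union(ri, rj)
            other = rj if root == ri else ri
            node_val[root] = max(node_val[root], node_val[other])
        merged: dict[tuple[int, int], float] = {}
        for (a, b), lv in links.items():
            ra, rb = uf.find(a), uf.find(b)
            if ra == rb:
                continue
            key = (ra, rb) if ra < rb else (rb, ra)
            if key not in merged or lv > merged[key]:
                merged[key] = lv
        links = merged
        node_val = {r: node_val[r] for r in {uf.find(l) for l in node_val}}

    lab = labels.labels
    maxlab = int(lab.max(initial=0))
    lut = np.zeros(maxlab + 1, dtype=np.int32)
    for l in graph.nodes:
        lut[l] = uf.find(l)
    out = lut[lab]
    return LabelMap(labels=out, maxima=_compute_maxima(img, out))


def segment(
    img: np.ndarray, mask: np.ndarray | None = None, delta_a: float = 3.0
) -> LabelMap:
    """Full GPL segmentation: label propagation, equivalences, merging."""
    pre = label_paths(img, mask)
    graph = build_graph(img, pre)
    return merge_regions(img, pre, graph, delta_a=delta_a)


def steepest_ascent_basins(
    img: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Brute-force basin assignment by per-pixel gradient-path walking.

    From every mask pixel, follow the quantized ascent direction until the
    walk leaves the mask (attractor = exit pixel), reaches a flat pixel, or
    revisits a pixel of the current walk (attractor = smallest cycle pixel).
    Returns an int grid where pixels sharing an attractor share a label
    (labels numbered by first occurrence in scan order).  Quadratic-time
    reference used to validate :func:`label_paths` on plateau-free images.
    """
    img = np.asarray(img, dtype=float)
    dirs = gradient_azimuth(img)
    rows, cols = img.shape
    if mask is None:
        mask = np.ones(img.shape, dtype=bool)
    offs = [tuple(o) for o in OFFSETS]
    attractor_label: dict[tuple[int, int], int] = {}
    out = np.zeros(img.shape, dtype=np.int32)
    next_label = 1
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            walk: list[tuple[int, int]] = []
            seen: dict[tuple[int, int], int] = {}
            cr, cc = r, c
            while True:
                if (cr, cc) in seen:  # entered a cycle
                    cycle = walk[seen[(cr, cc)] :]
                    key = min(cycle)
                    break
                seen[(cr, cc)] = len(walk)
                walk.append((cr, cc))
                d = dirs[cr, cc]
                if d == NO_DIRECTION:
                    key = (cr, cc)
                    break
                dr, dc = offs[d]
                nr, nc = cr + dr, cc + dc
                if not (0 <= nr < rows and 0 <= nc < cols) or not mask[nr, nc]:
                    key = (cr, cc)  # exit pixel
                    break
                if img[nr, nc] < img[cr, cc]:
                    key = (cr, cc)  # discrete summit
                    break
                cr, cc = nr, nc
            if key not in attractor_label:
                attractor_label[key] = next_label
                next_label += 1
            out[r, c] = attractor_label[key]
    return out
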