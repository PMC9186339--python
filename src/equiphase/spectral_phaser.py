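"""Window-based spectral phasing.

The chromosome's het sites are cut into sliding windows (default 200
variants, 20-variant overlap).  Inside a window every variant ``v``
contributes two graph nodes, ``(v,0)`` = "haplotype A carries REF at v"
and ``(v,1)`` = "haplotype A carries ALT at v".  Each fragment that
co-observes two variants adds weight between the consistent node pair
and, symmetrically, between the two complementary nodes.  The
unnormalized Laplacian ``L = D - W`` of this graph is formed and, per
connected component, the Fiedler vector (eigenvector of the
second-smallest eigenvalue) bipartitions the nodes: a variant is phased
when its two nodes fall on opposite sides of the cut, and haplotype A
receives the allele whose node lies on the positive side.  Adjacent
windows are stitched by a majority vote over their overlap; ties and
empty overlaps break the block.

The output is invariant under a global haplotype flip (A and B swap);
comparisons against truth must be flip-aware.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from equiphase.iohap import Fragment, HaplotypeBlock, PhasedVariant, VariantSite

logger = logging.getLogger(__name__)


@dataclass
class PhaserConfig:
    window_size: int = 200  # variants per sliding window
    window_overlap: int = 20  # variants shared by adjacent windows
    fiedler_tol: float = 1e-6  # minimum |Fiedler entry| to call a phase
    quality_weighting: bool = True  # weight edges by base-call confidence

    def __post_init__(self) -> None:
        if not 0 < self.window_overlap < self.window_size:
            raise ValueError("need 0 < window_overlap < window_size")
        if self.fiedler_tol <= 0:
            raise ValueError("fiedler_tol must be positive")


@dataclass
class LinkageWindow:
    """Linkage graph over a window of het-site ordinals ``[start, start+k)``.

    ``adjacency`` is a symmetric non-negative ``(2k, 2k)`` matrix with zero
    diagonal; node ``2*(v-start) + a`` is allele ``a`` of variant ``v`` on
    haplotype A.  No edge ever joins a variant's own two nodes.
    """

    start: int
    k: int
    adjacency: np.ndarray

    def node(self, v: int, allele: int) -> int:
        return 2 * (v - self.start) + allele


def build_linkage_graph(
    frags: list[Fragment], window: tuple[int, int], cfg: PhaserConfig | None = None
) -> LinkageWindow:
    """Accumulate fragment co-observations into a window's linkage graph.

    For each fragment and each pair of its observations ``(u, a_u, q_u)``,
    ``(v, a_v, q_v)`` inside the window, weight ``w`` is added to the edge
    ``(u,a_u)-(v,a_v)`` and to the mirrored edge ``(u,1-a_u)-(v,1-a_v)``,
    with ``w = (1 - 10^(-q_u/10)) * (1 - 10^(-q_v/10))`` under quality
    weighting, else 1.
    """
    cfg = cfg or PhaserConfig()
    lo, hi = window
    k = hi - lo
    W = np.zeros((2 * k, 2 * k))
    for f in frags:
        obs = [(i, a, q) for i, a, q in f.observations if lo <= i < hi]
        for x in range(len(obs)):
            u, a_u, q_u = obs[x]
            for y in range(x + 1, len(obs)):
                v, a_v, q_v = obs[y]
                if cfg.quality_weighting:
                    w = (1.0 - 10.0 ** (-q_u / 10.0)) * (1.0 - 10.0 ** (-q_v / 10.0))
                else:
                    w = 1.0
                i0, j0 = 2 * (u - lo) + a_u, 2 * (v - lo) + a_v
                i1, j1 = 2 * (u - lo) + (1 - a_u), 2 * (v - lo) + (1 - a_v)
                W[i0, j0] += w
                W[j0, i0] += w
                W[i1, j1] += w
                W[j1, i1] += w
    return LinkageWindow(lo, k, W)


@dataclass
class WindowPhasing:
    """Per-window phasing result.

    ``alleles[v]`` is haplotype A's allele at local variant ``v`` (-1 =
    unphased); ``components[v]`` labels the linkage component a phased
    variant belongs to (variants in different components are never
    co-phased, so component boundaries are block cuts).
    """

    start: int
    alleles: np.ndarray  # int, -1 unphased
    components: np.ndarray  # int, -1 unphased

    @property
    def haplotype_strings(self) -> tuple[str, str]:
        a = "".join("-" if x < 0 else str(x) for x in self.alleles)
        b = "".join("-" if x < 0 else str(1 - x) for x in self.alleles)
        return a, b

    @property
    def cuts(self) -> list[int]:
        """Local indices where a new block starts (component change or gap)."""
        out = []
        prev = None
        for v, c in enumerate(self.components):
            if c >= 0 and c != prev:
                out.append(v)
            prev = c if c >= 0 else None
        return out


def _fiedler_reduced(cis: np.ndarray, trans: np.ndarray) -> np.ndarray:
    """Fiedler vector of the component, in the phase-consistent sector.

    Edge weights are added in mirror pairs, so the node graph is invariant
    under swapping every variant's two nodes and the Laplacian's
    eigenvectors split into a symmetric sector (``f[(v,0)] = f[(v,1)]``,
    containing the all-ones vector) and an antisymmetric one
    (``f[(v,0)] = -f[(v,1)]``).  Only antisymmetric eigenvectors can pass
    the opposite-sign phasing test, so the Fiedler vector is taken as the
    lowest eigenvector of the antisymmetric sector — computed economically
    as the smallest eigenvector of the k-by-k signed Laplacian
    ``H[u,v] = -(w_cis - w_trans)``, ``H[u,u] = total degree of u's nodes``.
    Returns ``g`` with ``f[(v,0)] = g[v]``, ``f[(v,1)] = -g[v]``.
    """
    H = -(cis - trans)
    np.fill_diagonal(H, 0.0)
    np.fill_diagonal(H, (cis + trans).sum(axis=1))
    _, vec = scipy.linalg.eigh(H, subset_by_index=[0, 0])
    return vec[:, 0]


def _refine_bipartition(S: np.ndarray, x: np.ndarray, max_rounds: int | None = None) -> np.ndarray:
    """Greedy single-variant flips maximizing signed agreement ``x' S x``.

    Standard local rounding cleanup for a spectral bipartition; the
    objective is the linkage graph's own cis-minus-trans weight, so the
    step stays within the spectral model (no external scoring).
    """
    x = x.copy()
    limit = max_rounds if max_rounds is not None else 4 * len(x) + 8
    for _ in range(limit):
        gain = -2.0 * x * (S @ x)
        i = int(np.argmax(gain))
        if gain[i] <= 1e-12:
            break
        x[i] = -x[i]
    return x


def phase_window(window: LinkageWindow, cfg: PhaserConfig | None = None) -> WindowPhasing:
    """Fiedler-vector bipartition of one window.

    Per connected component (of the variant-level graph) with at least two
    variants, the Laplacian restricted to the component's nodes is formed
    and its Fiedler vector computed; variant ``v`` is phased iff its two
    node entries have opposite signs and the larger magnitude reaches
    ``fiedler_tol``.  The sign pattern then seeds a greedy signed-cut
    refinement (:func:`_refine_bipartition`) that cleans up rounding of
    the spectral relaxation.  Variants failing the magnitude test, and
    singleton components, stay unphased.
    """
    cfg = cfg or PhaserConfig()
    k = window.k
    W = window.adjacency
    alleles = np.full(k, -1, dtype=int)
    comps = np.full(k, -1, dtype=int)
    if k == 0:
        return WindowPhasing(window.start, alleles, comps)

    # variant-level connectivity: u ~ v if any of their node pairs is linked
    blocked = W.reshape(k, 2, k, 2).sum(axis=(1, 3))
    np.fill_diagonal(blocked, 0.0)
    n_comp, labels = connected_components(coo_matrix(blocked > 0), directed=False)

    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        if len(members) < 2:
            continue
        nodes0, nodes1 = 2 * members, 2 * members + 1
        cis = W[np.ix_(nodes0, nodes0)]  # mirror symmetry: equals the (1,1) sub-block
        trans = W[np.ix_(nodes0, nodes1)]
        try:
            g = _fiedler_reduced(cis, trans)
        except scipy.linalg.LinAlgError:  # pragma: no cover - dense eigh rarely fails
            logger.warning("eigen-solver failure in window at %d; component unphased", window.start)
            continue
        # sign test on the expanded vector: f[(v,0)] = g[v], f[(v,1)] = -g[v]
        phaseable = np.abs(g) >= cfg.fiedler_tol
        x = np.where(g > 0, 1.0, -1.0)
        x = _refine_bipartition(cis - trans, x)
        for j, v in enumerate(members):
            if phaseable[j]:
                alleles[v] = 0 if x[j] > 0 else 1
                comps[v] = c
    return WindowPhasing(window.start, alleles, comps)


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[int, int] = {}

    def find(self, x: int) -> int:
        p = self.parent.setdefault(x, x)
        while p != self.parent[p]:
            self.parent[p] = self.parent[self.parent[p]]
            p = self.parent[p]
        self.parent[x] = p
        return p

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _window_starts(n: int, cfg: PhaserConfig) -> list[int]:
    step = cfg.window_size - cfg.window_overlap
    starts = [0]
    while starts[-1] + cfg.window_size < n:
        starts.append(starts[-1] + step)
    return starts


def phase_chromosome(
    sites: list[VariantSite], frags: list[Fragment], cfg: PhaserConfig | None = None
) -> list[HaplotypeBlock]:
    """Phase one chromosome's het sites from pooled fragments.

    Windows advance by ``window_size - window_overlap``; the orientation of
    each new window relative to the accumulated phasing is fixed by a
    majority vote over the overlap's co-phased variants (agreements minus
    disagreements; zero margin or empty overlap cuts the block at the
    boundary).  Returns haplotype blocks with ``phase_set`` = position of
    each block's first variant.
    """
    cfg = cfg or PhaserConfig()
    het = sorted((s for s in sites if s.is_het), key=lambda s: s.pos)
    chroms = {s.chrom for s in het}
    if len(chroms) > 1:
        raise ValueError(f"phase_chromosome expects one chromosome, got {sorted(chroms)}")
    n = len(het)
    if n == 0 or not frags:
        return []

    assignment: dict[int, int] = {}  # ordinal -> haplotype A allele
    uf = _UnionFind()

    for s0 in _window_starts(n, cfg):
        e0 = min(s0 + cfg.window_size, n)
        wp = phase_window(build_linkage_graph(frags, (s0, e0), cfg), cfg)

        agree = disagree = 0
        for v_loc in range(e0 - s0):
            a = wp.alleles[v_loc]
            v = s0 + v_loc
            if a < 0 or v not in assignment:
                continue
            if assignment[v] == a:
                agree += 1
            else:
                disagree += 1
        if s0 == 0 or agree + disagree == 0:
            flip, stitched = 0, s0 == 0
        elif agree != disagree:
            flip, stitched = int(disagree > agree), True
        else:
            flip, stitched = 0, False  # tie: cut at the boundary
        if not stitched and s0 > 0:
            logger.debug("window at %d: boundary cut (agree=%d disagree=%d)", s0, agree, disagree)

        by_comp: dict[int, list[int]] = {}
        for v_loc in range(e0 - s0):
            c = wp.components[v_loc]
            if c >= 0:
                by_comp.setdefault(int(c), []).append(s0 + v_loc)
        for members in by_comp.values():
            new = [v for v in members if v not in assignment]
            old = [v for v in members if v in assignment]
            for v in new:
                assignment[v] = int(wp.alleles[v - s0]) ^ flip
            if stitched and old:
                for v in members[1:]:
                    uf.union(members[0], v)
            elif new:
                for v in new[1:]:
                    uf.union(new[0], v)

    # group phased ordinals into blocks
    groups: dict[int, list[int]] = {}
    for v in assignment:
        groups.setdefault(uf.find(v), []).append(v)
    het_pos = [s.pos for s in het]
    blocks: list[HaplotypeBlock] = []
    for ordinals in groups.values():
        ordinals.sort()
        first_pos = het[ordinals[0]].pos
        variants = [
            PhasedVariant(het[v], assignment[v], 1 - assignment[v], first_pos) for v in ordinals
        ]
        lo = bisect_left(het_pos, variants[0].site.pos)
        hi = bisect_right(het_pos, variants[-1].site.pos)
        blocks.append(HaplotypeBlock(het[0].chrom, variants, n_het_in_range=hi - lo))
    blocks.sort(key=lambda b: b.start)
    return blocks
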