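"""Priority-graph merging of two phased variant sets.

Two phased inputs of different priority — typically read-based phase
blocks (primary) and a panel-based phasing (secondary) — are merged via
a block-level connection graph.  Nodes are haplotype blocks labelled
primary or secondary; an edge joins a primary and a secondary block when
they share strictly more than ``N`` phased SNVs and their relative
orientation is unambiguous (majority of shared sites agrees or
disagrees; exact ties are conflicts and excluded).

Two situations drive the merge: a secondary block connected to several
primary blocks re-orients and joins those primaries into one phase set;
a secondary block of degree one extends its primary with the variants
only the secondary phases.  Primary alleles always win where both phase
a variant, and primaries untouched by any accepted edge pass through
unchanged.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path

from equiphase.iohap import (
    HaplotypeBlock,
    PhasedVariant,
    VariantSite,
    VcfVariants,
    read_vcf,
    write_phased_vcf,
)

logger = logging.getLogger(__name__)


@dataclass
class MergeConfig:
    min_shared: int = 2  # edge requires shared phased SNVs > min_shared (strict)

    def __post_init__(self) -> None:
        if self.min_shared < 0:
            raise ValueError("min_shared must be >= 0")


@dataclass(frozen=True)
class MergeEdge:
    primary: int  # index into the primary block list
    secondary: int  # index into the secondary block list
    shared: int
    agree: int
    disagree: int

    @property
    def orientation(self) -> str:
        if self.agree > self.disagree:
            return "same"
        if self.disagree > self.agree:
            return "flip"
        return "conflict"


@dataclass
class MergeGraph:
    primary: list[HaplotypeBlock]
    secondary: list[HaplotypeBlock]
    edges: list[MergeEdge]
    conflicts: list[MergeEdge] = field(default_factory=list)


def relative_orientation(a: HaplotypeBlock, b: HaplotypeBlock) -> tuple[int, int, int, str]:
    """(shared, agree, disagree, orientation) over variants phased in both."""
    if a.chrom != b.chrom:
        raise ValueError("blocks must lie on one chromosome")
    b_alleles = {v.site.pos: v.hapA for v in b.variants}
    agree = disagree = 0
    for v in a.variants:
        other = b_alleles.get(v.site.pos)
        if other is None:
            continue
        if v.hapA == other:
            agree += 1
        else:
            disagree += 1
    shared = agree + disagree
    if agree > disagree:
        orient = "same"
    elif disagree > agree:
        orient = "flip"
    else:
        orient = "conflict"
    return shared, agree, disagree, orient


def build_merge_graph(
    primary: list[HaplotypeBlock],
    secondary: list[HaplotypeBlock],
    cfg: MergeConfig | None = None,
) -> MergeGraph:
    """Connect opposite-priority blocks sharing > ``min_shared`` phased SNVs.

    Orientation conflicts (equal agree/disagree) are logged and excluded.
    """
    cfg = cfg or MergeConfig()
    edges: list[MergeEdge] = []
    conflicts: list[MergeEdge] = []
    for pi, p in enumerate(primary):
        for si, s in enumerate(secondary):
            if p.chrom != s.chrom:
                continue
            shared, agree, disagree, orient = relative_orientation(p, s)
            if shared <= cfg.min_shared:
                continue
            e = MergeEdge(pi, si, shared, agree, disagree)
            if orient == "conflict":
                logger.info("conflicting orientation between P%d and S%d (%d/%d)", pi, si, agree, disagree)
                conflicts.append(e)
            else:
                edges.append(e)
    return MergeGraph(primary, secondary, edges, conflicts)


_Node = tuple[str, int]


def _orient_component(
    comp_nodes: list[_Node],
    adj: dict[_Node, list[MergeEdge]],
) -> tuple[dict[_Node, int], MergeEdge | None, dict[_Node, tuple[_Node, MergeEdge] | None]]:
    """BFS 2-coloring of flips.

    Returns (flips, inconsistent edge or None, BFS parent pointers for
    cycle recovery).
    """
    flips: dict[_Node, int] = {}
    parent: dict[_Node, tuple[_Node, MergeEdge] | None] = {}
    root = comp_nodes[0]
    flips[root] = 0
    parent[root] = None
    queue = [root]
    while queue:
        node = queue.pop(0)
        for e in adj[node]:
            parity = 0 if e.orientation == "same" else 1
            other: _Node = ("S", e.secondary) if node[0] == "P" else ("P", e.primary)
            want = flips[node] ^ parity
            if other not in flips:
                flips[other] = want
                parent[other] = (node, e)
                queue.append(other)
            elif flips[other] != want:
                return flips, e, parent
    return flips, None, parent


def _cycle_edges(
    bad: MergeEdge, parent: dict[_Node, tuple[_Node, MergeEdge] | None]
) -> list[MergeEdge]:
    """Edges of the cycle closed by ``bad``: the BFS tree path between its
    endpoints plus ``bad`` itself."""
    u: _Node = ("P", bad.primary)
    v: _Node = ("S", bad.secondary)
    path_u: dict[_Node, list[MergeEdge]] = {}
    acc: list[MergeEdge] = []
    node = u
    while node is not None:
        path_u[node] = list(acc)
        up = parent.get(node)
        if up is None:
            break
        acc.append(up[1])
        node = up[0]
    acc_v: list[MergeEdge] = []
    node = v
    while node not in path_u:
        up = parent[node]
        acc_v.append(up[1])
        node = up[0]
    return path_u[node] + acc_v + [bad]


def merge_blocks(
    graph: MergeGraph, cfg: MergeConfig | None = None, all_het_sites: list[VariantSite] | None = None
) -> list[HaplotypeBlock]:
    """Unite primaries through shared secondaries and extend from secondaries.

    Connected components over accepted edges are oriented into a common
    frame by BFS; an inconsistently-oriented cycle drops its lowest-shared
    edge and retries.  Within a component the merged block takes the
    primary allele wherever any primary phases a variant and the
    secondary allele elsewhere; phase sets are reassigned to each merged
    block's first position.  Secondary-only components are not emitted.
    """
    cfg = cfg or MergeConfig()
    edges = list(graph.edges)

    while True:
        adj: dict[tuple[str, int], list[MergeEdge]] = {}
        for e in edges:
            adj.setdefault(("P", e.primary), []).append(e)
            adj.setdefault(("S", e.secondary), []).append(e)
        for pi in range(len(graph.primary)):
            adj.setdefault(("P", pi), [])

        # connected components over the current edge set
        seen: set[tuple[str, int]] = set()
        components: list[list[tuple[str, int]]] = []
        for start in adj:
            if start in seen:
                continue
            comp = []
            stack = [start]
            seen.add(start)
            while stack:
                node = stack.pop()
                comp.append(node)
                for e in adj[node]:
                    other = ("S", e.secondary) if node[0] == "P" else ("P", e.primary)
                    if other not in seen:
                        seen.add(other)
                        stack.append(other)
            components.append(comp)

        bad_edge = None
        bad_parent: dict[_Node, tuple[_Node, MergeEdge] | None] = {}
        oriented: list[tuple[list[_Node], dict[_Node, int]]] = []
        for comp in components:
            flips, bad, parent = _orient_component(comp, adj)
            if bad is not None:
                bad_edge, bad_parent = bad, parent
                break
            oriented.append((comp, flips))
        if bad_edge is None:
            break
        # odd cycle: drop the lowest-shared edge of the cycle and retry
        drop = min(_cycle_edges(bad_edge, bad_parent), key=lambda e: e.shared)
        logger.info(
            "dropping inconsistently oriented edge P%d-S%d (shared=%d)",
            drop.primary, drop.secondary, drop.shared,
        )
        edges = [e for e in edges if e is not drop]

    # variants phased by ANY primary stay with their primary's block: a
    # secondary may only append positions no primary phases at all
    primary_phased = {(b.chrom, v.site.pos) for b in graph.primary for v in b.variants}

    merged: list[HaplotypeBlock] = []
    for comp, flips in oriented:
        primaries = [i for kind, i in comp if kind == "P"]
        if not primaries:
            continue  # secondary-only component: nothing to extend
        chrom = graph.primary[primaries[0]].chrom
        alleles: dict[int, tuple[int, bool]] = {}  # pos -> (hapA allele, from_primary)
        for kind, i in comp:
            block = graph.primary[i] if kind == "P" else graph.secondary[i]
            flip = flips[(kind, i)]
            for v in block.variants:
                a = v.hapA ^ flip
                if kind == "P":
                    alleles[v.site.pos] = (a, True)
                elif (chrom, v.site.pos) not in primary_phased and (
                    v.site.pos not in alleles or not alleles[v.site.pos][1]
                ):
                    alleles[v.site.pos] = (a, False)
        sites_by_pos: dict[int, VariantSite] = {}
        for kind, i in comp:
            block = graph.primary[i] if kind == "P" else graph.secondary[i]
            for v in block.variants:
                # primary sites win so site_index provenance follows alleles
                if kind == "P" or v.site.pos not in sites_by_pos:
                    sites_by_pos[v.site.pos] = v.site
        positions = sorted(alleles)
        ps = positions[0]
        variants = [
            PhasedVariant(sites_by_pos[p], alleles[p][0], 1 - alleles[p][0], ps) for p in positions
        ]
        merged.append(_make_block(chrom, variants, all_het_sites))
    merged.sort(key=lambda b: (b.chrom, b.start))
    return merged


def _make_block(
    chrom: str, variants: list[PhasedVariant], all_het_sites: list[VariantSite] | None
) -> HaplotypeBlock:
    if all_het_sites is None:
        return HaplotypeBlock(chrom, variants)
    pos = sorted(s.pos for s in all_het_sites if s.is_het and s.chrom == chrom)
    lo = bisect_left(pos, variants[0].site.pos)
    hi = bisect_right(pos, variants[-1].site.pos)
    return HaplotypeBlock(chrom, variants, n_het_in_range=max(hi - lo, len(variants)))


def blocks_from_phased(phased: list[PhasedVariant], all_het_sites: list[VariantSite] | None = None) -> list[HaplotypeBlock]:
    """Group phased variants by (chrom, phase_set) into haplotype blocks."""
    groups: dict[tuple[str, int], list[PhasedVariant]] = {}
    for v in phased:
        groups.setdefault((v.site.chrom, v.phase_set), []).append(v)
    blocks = []
    for (chrom, _ps), vs in groups.items():
        vs.sort(key=lambda v: v.site.pos)
        blocks.append(_make_block(chrom, vs, all_het_sites))
    blocks.sort(key=lambda b: (b.chrom, b.start))
    return blocks


def merge_phased(
    primary: list[PhasedVariant],
    secondary: list[PhasedVariant],
    cfg: MergeConfig | None = None,
    all_het_sites: list[VariantSite] | None = None,
) -> list[HaplotypeBlock]:
    """End-to-end merge of two phased variant lists (primary wins)."""
    cfg = cfg or MergeConfig()
    p_blocks = blocks_from_phased(primary, all_het_sites)
    s_blocks = blocks_from_phased(secondary, all_het_sites)
    graph = build_merge_graph(p_blocks, s_blocks, cfg)
    return merge_blocks(graph, cfg, all_het_sites)


def merge_vcf(
    read_based: str | Path,
    panel_based: str | Path,
    out: str | Path,
    cfg: MergeConfig | None = None,
) -> list[HaplotypeBlock]:
    """Merge a read-based phased VCF (primary) with a panel-based one
    (secondary) and write the merged phased VCF.

    Both inputs must cover the same variant universe; the merged output
    phases at least as many SNVs as the primary input.
    """
    cfg = cfg or MergeConfig()
    prim = read_vcf(read_based)
    seco = read_vcf(panel_based)
    prim_keys = [(s.chrom, s.pos) for s in prim.sites]
    seco_keys = [(s.chrom, s.pos) for s in seco.sites]
    if prim_keys != seco_keys:
        diff = next(iter(set(prim_keys) ^ set(seco_keys)))
        raise ValueError(f"variant universes differ; first discrepancy at {diff[0]}:{diff[1]}")

    merged_blocks = merge_phased(prim.phased, seco.phased, cfg, all_het_sites=prim.sites)
    phased_pos = {(b.chrom, v.site.pos): v for b in merged_blocks for v in b.variants}
    out_records: list[PhasedVariant | VariantSite] = []
    for s in prim.sites:
        out_records.append(phased_pos.get((s.chrom, s.pos), s))
    write_phased_vcf(out_records, out)
    return merged_blocks
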