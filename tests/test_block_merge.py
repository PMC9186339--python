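"""Priority-graph block merging: orientation voting, edge thresholds,
the two merge cases, and end-to-end VCF merging."""

import numpy as np
import pytest

from equiphase.block_merge import (
    MergeConfig,
    blocks_from_phased,
    build_merge_graph,
    merge_blocks,
    merge_phased,
    merge_vcf,
    relative_orientation,
)
from equiphase.hapmetrics import phase_rate, switch_error
from equiphase.haplosim import SimConfig, corrupt_phasing, simulate_truth
from equiphase.iohap import Genotype, HaplotypeBlock, PhasedVariant, VariantSite, read_vcf, write_phased_vcf


def block(positions, alleles, ps=None, chrom="chr1"):
    ps = ps if ps is not None else positions[0]
    variants = [
        PhasedVariant(VariantSite(chrom, p, "A", "G", Genotype.HET, i), a, 1 - a, ps)
        for i, (p, a) in enumerate(zip(positions, alleles))
    ]
    return HaplotypeBlock(chrom, variants)


class TestRelativeOrientation:
    def test_identical_blocks(self):
        b = block([10, 20, 30, 40, 50], [0, 1, 0, 0, 1])
        assert relative_orientation(b, b) == (5, 5, 0, "same")

    def test_global_flip(self):
        a = block([10, 20, 30, 40, 50], [0, 1, 0, 0, 1])
        b = block([10, 20, 30, 40, 50], [1, 0, 1, 1, 0])
        assert relative_orientation(a, b) == (5, 0, 5, "flip")

    def test_tie_is_conflict(self):
        a = block([10, 20, 30, 40], [0, 0, 0, 0])
        b = block([10, 20, 30, 40], [0, 0, 1, 1])
        assert relative_orientation(a, b)[3] == "conflict"


class TestBuildMergeGraph:
    def test_shared_equal_n_gives_no_edge(self):
        p = block([10, 20], [0, 1])
        s = block([10, 20, 30], [0, 1, 0])
        g = build_merge_graph([p], [s], MergeConfig(min_shared=2))
        assert g.edges == []

    def test_shared_above_n_gives_edge(self):
        p = block([10, 20, 30], [0, 1, 0])
        s = block([10, 20, 30, 40], [0, 1, 0, 1])
        g = build_merge_graph([p], [s], MergeConfig(min_shared=2))
        (e,) = g.edges
        assert (e.shared, e.orientation) == (3, "same")

    def test_disjoint_blocks_no_edges(self):
        p = block([10, 20, 30], [0, 1, 0])
        s = block([100, 200, 300], [0, 1, 0])
        assert build_merge_graph([p], [s], MergeConfig()).edges == []

    def test_conflicts_excluded_and_logged(self):
        p = block([10, 20, 30, 40], [0, 0, 0, 0])
        s = block([10, 20, 30, 40], [0, 0, 1, 1])
        g = build_merge_graph([p], [s], MergeConfig(min_shared=2))
        assert g.edges == [] and len(g.conflicts) == 1


class TestMergeBlocks:
    def test_two_primaries_united_through_secondary(self):
        # 12-variant universe: P1 on first 4, P2 on last 4, secondary spans all
        p1 = block([10, 20, 30, 40], [0, 1, 0, 1])
        p2 = block([90, 100, 110, 120], [1, 1, 0, 0])
        sec = block(
            [10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 110, 120],
            [1, 0, 1, 0, 1, 1, 0, 0, 1, 1, 0, 0],  # flip of P1's frame, same as P2's
        )
        merged = merge_blocks(build_merge_graph([p1, p2], [sec], MergeConfig(2)), MergeConfig(2))
        (m,) = merged
        assert m.n_phased == 12
        # in the common frame the merged haplotype equals the secondary's
        # (P1 is its exact flip, P2 its exact copy), up to one global flip
        from conftest import hap_agrees_flipaware

        by_pos = {v.site.pos: v.hapA for v in m.variants}
        sec_alleles = [v.hapA for v in sec.variants]
        assert hap_agrees_flipaware([by_pos[v.site.pos] for v in sec.variants], sec_alleles)

    def test_degree_one_secondary_extends_primary(self):
        p = block([10, 20, 30], [0, 1, 0])
        s = block([10, 20, 30, 40, 50, 60, 70], [0, 1, 0, 1, 1, 0, 0])
        (m,) = merge_blocks(build_merge_graph([p], [s], MergeConfig(2)), MergeConfig(2))
        assert m.n_phased == 7
        by_pos = {v.site.pos: v.hapA for v in m.variants}
        assert [by_pos[p_] for p_ in [40, 50, 60, 70]] == [1, 1, 0, 0]

    def test_no_edges_passes_primaries_through(self):
        p1 = block([10, 20, 30], [0, 1, 0])
        p2 = block([100, 200, 300], [1, 0, 1])
        merged = merge_blocks(build_merge_graph([p1, p2], [], MergeConfig(2)), MergeConfig(2))
        assert sorted(m.start for m in merged) == [10, 100]
        assert all(m.n_phased == 3 for m in merged)

    def test_primary_alleles_win_on_disagreement(self):
        p = block([10, 20, 30, 40], [0, 1, 0, 1])
        s = block([10, 20, 30, 40, 50], [0, 1, 1, 1, 0])  # disagrees at 30, majority same
        (m,) = merge_blocks(build_merge_graph([p], [s], MergeConfig(2)), MergeConfig(2))
        by_pos = {v.site.pos: v.hapA for v in m.variants}
        assert by_pos[30] == 0  # primary's call

    def test_odd_cycle_drops_lowest_shared_edge(self):
        # cycle P1-S1-P2-S2-P1 with one inconsistent orientation
        p1 = block([10, 20, 30, 40, 50, 60], [0, 1, 0, 1, 0, 1])
        p2 = block([200, 210, 220, 230, 240, 250], [0, 0, 1, 1, 0, 0])
        # S1 agrees with both primaries; S2 agrees with P1 but flips P2
        s1 = block([10, 20, 30, 200, 210, 220], [0, 1, 0, 0, 0, 1], ps=1)
        s2 = block([40, 50, 60, 230, 240, 250], [1, 0, 1, 0, 1, 1], ps=2)
        graph = build_merge_graph([p1, p2], [s1, s2], MergeConfig(2))
        assert len(graph.edges) == 4
        merged = merge_blocks(graph, MergeConfig(2))
        # every primary variant survives exactly once after dropping an edge
        pos = sorted(v.site.pos for m in merged for v in m.variants)
        assert pos == [10, 20, 30, 40, 50, 60, 200, 210, 220, 230, 240, 250]
        # primary alleles conserved per merged block up to a global flip
        from conftest import hap_agrees_flipaware

        for m in merged:
            by_pos = {v.site.pos: v.hapA for v in m.variants}
            for p in (p1, p2):
                shared = [v for v in p.variants if v.site.pos in by_pos]
                if shared:
                    assert hap_agrees_flipaware(
                        [by_pos[v.site.pos] for v in shared], [v.hapA for v in shared]
                    )


class TestMergeVcf:
    def _write(self, path, records):
        write_phased_vcf(records, path)
        return str(path)

    def test_panel_bridges_read_blocks_to_single_phase_set(self, tmp_path):
        cfg = SimConfig(seed=31, chrom_length=60_000, n_het=90)
        truth = simulate_truth(cfg)
        prim = []
        for start in range(0, 90, 31):  # blocks of 29 with 2-site gaps
            blk = truth.variants[start : start + 29]
            ps = blk[0].site.pos
            prim += [PhasedVariant(v.site, v.hapA, v.hapB, ps) for v in blk]
        by_pos = {v.site.pos: v for v in prim}
        records = [by_pos.get(v.site.pos, v.site) for v in truth.variants]
        primary_vcf = self._write(tmp_path / "p.vcf", records)
        panel = corrupt_phasing(truth, 0.02, seed=32)
        panel_vcf = self._write(tmp_path / "s.vcf", panel)
        out = tmp_path / "m.vcf"
        blocks = merge_vcf(primary_vcf, panel_vcf, out)
        assert len(blocks) == 1
        merged = read_vcf(str(out))
        assert len({v.phase_set for v in merged.phased}) == 1
        assert len(merged.phased) >= len(prim)

    def test_empty_secondary_output_equals_primary(self, tmp_path):
        cfg = SimConfig(seed=33, chrom_length=30_000, n_het=40)
        truth = simulate_truth(cfg)
        primary_vcf = self._write(tmp_path / "p.vcf", truth.variants)
        panel_vcf = self._write(tmp_path / "s.vcf", [v.site for v in truth.variants])
        out = tmp_path / "m.vcf"
        merge_vcf(primary_vcf, panel_vcf, out)
        merged = read_vcf(str(out))
        assert [(v.site.pos, v.hapA) for v in merged.phased] == [
            (v.site.pos, v.hapA) for v in truth.variants
        ]

    def test_identical_secondary_idempotent(self, tmp_path):
        cfg = SimConfig(seed=34, chrom_length=30_000, n_het=40)
        truth = simulate_truth(cfg)
        primary_vcf = self._write(tmp_path / "p.vcf", truth.variants)
        out = tmp_path / "m.vcf"
        merge_vcf(primary_vcf, primary_vcf, out)
        merged = read_vcf(str(out))
        assert [(v.site.pos, v.hapA) for v in merged.phased] == [
            (v.site.pos, v.hapA) for v in truth.variants
        ]

    def test_mismatched_universes_rejected(self, tmp_path):
        cfg = SimConfig(seed=35, chrom_length=30_000, n_het=40)
        truth = simulate_truth(cfg)
        primary_vcf = self._write(tmp_path / "p.vcf", truth.variants)
        panel_vcf = self._write(tmp_path / "s.vcf", truth.variants[1:])
        with pytest.raises(ValueError, match="discrepancy"):
            merge_vcf(primary_vcf, panel_vcf, tmp_path / "m.vcf")


class TestMergeProperties:
    def test_switch_error_not_worse_than_secondary_pooled(self):
        """Pooled over 50 simulations, merging truth-faithful primary blocks
        with a 2%-switch panel never degrades accuracy below the panel's."""
        merged_sw = []
        panel_sw = []
        for rep in range(50):
            cfg = SimConfig(seed=900 + rep, chrom_length=100_000, n_het=200)
            truth = simulate_truth(cfg)
            prim = []
            for start in range(0, 200, 31):
                blk = truth.variants[start : start + 29]
                if not blk:
                    continue
                ps = blk[0].site.pos
                prim += [PhasedVariant(v.site, v.hapA, v.hapB, ps) for v in blk]
            panel = corrupt_phasing(truth, 0.02, seed=901 + rep)
            merged = merge_phased(prim, panel, MergeConfig(2), all_het_sites=truth.sites)
            merged_sw.append(switch_error(merged, truth.variants)[0])
            panel_sw.append(switch_error(blocks_from_phased(panel), truth.variants)[0])
        assert np.mean(merged_sw) <= np.mean(panel_sw)

    def test_phase_rate_monotone(self):
        for rep in range(10):
            cfg = SimConfig(seed=950 + rep, chrom_length=60_000, n_het=100)
            truth = simulate_truth(cfg)
            rng = np.random.default_rng(rep)
            prim = []
            for start in range(0, 100, 17):
                blk = truth.variants[start : start + 13]
                if not blk:
                    continue
                ps = blk[0].site.pos
                flip = int(rng.integers(0, 2))
                prim += [PhasedVariant(v.site, v.hapA ^ flip, 1 - (v.hapA ^ flip), ps) for v in blk]
            panel = corrupt_phasing(truth, 0.02, seed=951 + rep)
            merged = merge_phased(prim, panel, MergeConfig(2), all_het_sites=truth.sites)
            assert phase_rate(merged, 100) >= phase_rate(blocks_from_phased(prim), 100)
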