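"""VCF and fragment I/O: field mapping, het ordinals, dialect decoding,
and lossless round trips."""

import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from equiphase.iohap import (
    Fragment,
    Genotype,
    PhasedVariant,
    Protocol,
    VariantSite,
    read_fragments,
    read_vcf,
    write_fragments,
    write_phased_vcf,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n'
    "##contig=<ID=chr1>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
)


def write_lines(path, *records):
    path.write_text(VCF_HEADER + "".join(r + "\n" for r in records))
    return str(path)


class TestReadVcf:
    def test_unphased_het_record(self, tmp_path):
        p = write_lines(tmp_path / "a.vcf", "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1")
        data = read_vcf(p)
        (site,) = data.sites
        assert site.genotype is Genotype.HET
        assert (site.chrom, site.pos, site.ref, site.alt) == ("chr1", 100, "A", "G")
        assert data.phased == []

    def test_phased_record_with_ps(self, tmp_path):
        p = write_lines(tmp_path / "a.vcf", "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:PS\t1|0:100")
        (pv,) = read_vcf(p).phased
        assert (pv.hapA, pv.hapB, pv.phase_set) == (1, 0, 100)

    def test_het_ordinals_skip_hom_sites(self, tmp_path):
        p = write_lines(
            tmp_path / "a.vcf",
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1",
            "chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t1/1",
            "chr1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t0/1",
        )
        het = read_vcf(p).het_sites()
        assert [(s.pos, s.site_index) for s in het] == [(100, 0), (300, 1)]

    def test_multiallelic_skipped_with_warning(self, tmp_path):
        p = write_lines(
            tmp_path / "a.vcf",
            "chr1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t1/2",
            "chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0/1",
        )
        with pytest.warns(UserWarning, match="skipped 1"):
            data = read_vcf(p)
        assert data.n_skipped == 1
        assert len(data.sites) == 1

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text(VCF_HEADER + "chr1\t100\tbroken\n")
        with pytest.raises(ValueError, match="line 6"):
            read_vcf(str(path))

    def test_ps_absent_uses_block_start_pos(self, tmp_path):
        p = write_lines(
            tmp_path / "a.vcf",
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0|1",
            "chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t1|0",
            "chr1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t0/1",
            "chr1\t400\t.\tT\tC\t.\tPASS\t.\tGT\t0|1",
        )
        phased = read_vcf(p).phased
        assert [v.phase_set for v in phased] == [100, 100, 400]


class TestWritePhasedVcf:
    def test_phased_field_format(self, tmp_path):
        site = VariantSite("chr1", 50, "A", "C", Genotype.HET, 0)
        out = tmp_path / "o.vcf"
        write_phased_vcf([PhasedVariant(site, 0, 1, 50)], out)
        assert "GT:PS\t0|1:50" in out.read_text()

    def test_empty_list_gives_header_only(self, tmp_path):
        out = tmp_path / "o.vcf"
        write_phased_vcf([], out)
        assert all(line.startswith("#") for line in out.read_text().splitlines())

    def test_unsorted_input_rejected(self, tmp_path):
        a = PhasedVariant(VariantSite("chr1", 200, "A", "C", Genotype.HET, 1), 0, 1, 100)
        b = PhasedVariant(VariantSite("chr1", 100, "A", "C", Genotype.HET, 0), 0, 1, 100)
        with pytest.raises(ValueError, match="sorted"):
            write_phased_vcf([a, b], tmp_path / "o.vcf")

    @given(st.data())
    @settings(max_examples=25, deadline=None)
    def test_round_trip_reproduces_phases(self, data):
        import tempfile
        from pathlib import Path

        n = data.draw(st.integers(2, 12))
        positions = sorted(data.draw(st.sets(st.integers(1, 10_000), min_size=n, max_size=n)))
        hapA = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        ps = positions[0]
        variants = [
            PhasedVariant(VariantSite("chr1", pos, "A", "G", Genotype.HET, i), a, 1 - a, ps)
            for i, (pos, a) in enumerate(zip(positions, hapA))
        ]
        with tempfile.TemporaryDirectory() as d:
            out = Path(d) / "rt.vcf"
            write_phased_vcf(variants, out)
            back = read_vcf(str(out)).phased
        assert [(v.site.pos, v.hapA, v.phase_set) for v in back] == [
            (v.site.pos, v.hapA, v.phase_set) for v in variants
        ]


class TestFragmentDialect:
    def test_hand_decoded_line(self, tmp_path):
        path = tmp_path / "f.frag"
        path.write_text("2 frag1 0 0 0 01 5 1 II2\n")
        (f,) = read_fragments(str(path))
        assert f.id == "frag1" and f.protocol is Protocol.NGS
        assert f.observations == [(0, 0, 40), (1, 1, 40), (5, 1, 17)]

    def test_empty_file(self, tmp_path):
        path = tmp_path / "f.frag"
        path.write_text("")
        assert read_fragments(str(path)) == []

    def test_single_observation_flagged_uninformative(self, tmp_path):
        path = tmp_path / "f.frag"
        path.write_text("1 lone 2 0 3 1 I\n")
        (f,) = read_fragments(str(path))
        assert not f.is_informative

    def test_out_of_range_index_rejected(self, tmp_path):
        path = tmp_path / "f.frag"
        path.write_text("1 far 0 0 8 11 II\n")
        with pytest.raises(ValueError, match="far"):
            read_fragments(str(path), n_sites=9)

    def test_quality_length_mismatch_rejected(self, tmp_path):
        path = tmp_path / "f.frag"
        path.write_text("1 f1 0 0 0 011 II\n")
        with pytest.raises(ValueError, match="quality string length"):
            read_fragments(str(path))

    def test_non_monotone_indices_name_fragment(self):
        with pytest.raises(ValueError, match="fragX"):
            Fragment("fragX", Protocol.NGS, [(3, 0, 30), (3, 1, 30)])

    @given(st.data())
    @settings(max_examples=25, deadline=None)
    def test_round_trip_lossless(self, data):
        import tempfile
        from pathlib import Path

        n_frags = data.draw(st.integers(1, 6))
        frags = []
        for k in range(n_frags):
            n_obs = data.draw(st.integers(1, 8))
            idx = sorted(data.draw(st.sets(st.integers(0, 50), min_size=n_obs, max_size=n_obs)))
            obs = [
                (i, data.draw(st.integers(0, 1)), data.draw(st.integers(0, 60))) for i in idx
            ]
            proto = data.draw(st.sampled_from(list(Protocol)))
            frags.append(Fragment(f"f{k}", proto, obs, data.draw(st.integers(0, 10_000))))
        with tempfile.TemporaryDirectory() as d:
            path = Path(d) / "x.frag"
            write_fragments(frags, path)
            back = read_fragments(str(path))
        assert [(f.id, f.protocol, f.observations, f.insert_span) for f in back] == [
            (f.id, f.protocol, f.observations, f.insert_span) for f in frags
        ]


def test_block_invariants():
    sites = [VariantSite("chr1", p, "A", "G", Genotype.HET, i) for i, p in enumerate([10, 40, 90])]
    from equiphase.iohap import HaplotypeBlock

    block = HaplotypeBlock("chr1", [PhasedVariant(s, 0, 1, 10) for s in sites], n_het_in_range=6)
    assert block.span == 81
    assert block.n_phased == 3
    assert block.adjusted_span == pytest.approx(81 * 3 / 6)
    with pytest.raises(ValueError):
        HaplotypeBlock("chr1", [PhasedVariant(s, 0, 1, 10) for s in sites], n_het_in_range=2)
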