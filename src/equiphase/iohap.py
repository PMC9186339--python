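"""Core data model and readers/writers for VCF, fragment files, FASTA and FASTQ.

All coordinate and format conventions live here:

* VCF positions are 1-based (VCF 4.2).  Phased genotypes are written
  ``a|b`` with a ``PS`` (phase set) FORMAT tag; unphased het genotypes are
  ``a/b``.
* Internally, phasing addresses het sites by a 0-based ``site_index``
  assigned per chromosome over biallelic SNV het sites sorted by position
  — the ordinal space haplotype fragments are indexed against.
* The fragment file is a one-fragment-per-line whitespace-separated
  dialect (see :func:`read_fragments`).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from cyvcf2 import VCF


class Genotype(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


class Protocol(str, enum.Enum):
    """Sequencing protocol a fragment derives from."""

    NGS = "NGS"
    HIC = "HIC"
    LONGREAD = "LONGREAD"
    LINKED = "LINKED"


#: fragment-file protocol codes (column 3 of the dialect)
PROTOCOL_CODES = {Protocol.NGS: 0, Protocol.HIC: 1, Protocol.LONGREAD: 2, Protocol.LINKED: 3}
CODE_TO_PROTOCOL = {v: k for k, v in PROTOCOL_CODES.items()}


@dataclass(frozen=True)
class VariantSite:
    """A genotyped biallelic SNV locus.

    ``site_index`` is the 0-based ordinal of this site among het sites of
    its chromosome sorted by position; ``None`` for non-het sites.
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    genotype: Genotype
    site_index: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")

    @property
    def is_het(self) -> bool:
        return self.genotype is Genotype.HET


@dataclass(frozen=True)
class PhasedVariant:
    """A het site with its allele assignment to the two haplotypes.

    ``hapA``/``hapB`` are allele codes (0 = REF, 1 = ALT); for a het site
    they are complementary.  ``phase_set`` identifies the haplotype block
    (convention: position of the block's first variant).
    """

    site: VariantSite
    hapA: int
    hapB: int
    phase_set: int

    def __post_init__(self) -> None:
        if self.site.is_het and {self.hapA, self.hapB} != {0, 1}:
            raise ValueError(
                f"het site at {self.site.chrom}:{self.site.pos} needs complementary "
                f"alleles, got {self.hapA}|{self.hapB}"
            )

    def flipped(self) -> "PhasedVariant":
        return PhasedVariant(self.site, self.hapB, self.hapA, self.phase_set)


@dataclass
class Fragment:
    """One read (or pair / Hi-C pair) reduced to allele observations.

    ``observations`` is an ordered list of ``(site_index, allele, base_quality)``
    over het-site ordinals; ``insert_span`` is the bp distance between the
    outermost observed variant positions.
    """

    id: str
    protocol: Protocol
    observations: list[tuple[int, int, int]]
    insert_span: int = 0

    def __post_init__(self) -> None:
        idx = [o[0] for o in self.observations]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"fragment {self.id}: site indices must strictly increase")
        if any(q < 0 for _, _, q in self.observations):
            raise ValueError(f"fragment {self.id}: negative base quality")
        if self.insert_span < 0:
            raise ValueError(f"fragment {self.id}: negative insert_span")

    @property
    def is_informative(self) -> bool:
        """A fragment carries linkage only if it observes >= 2 sites."""
        return len(self.observations) >= 2

    @property
    def site_indices(self) -> list[int]:
        return [o[0] for o in self.observations]


@dataclass
class HaplotypeBlock:
    """A contiguous set of co-phased variants on one chromosome.

    ``n_het_in_range`` counts all het sites whose position falls inside
    the block's genomic range ``[first, last]``; the adjusted span scales
    the physical span by the fraction of those sites the block phases.
    """

    chrom: str
    variants: list[PhasedVariant]
    n_het_in_range: int | None = None

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("a haplotype block needs at least one variant")
        pos = [v.site.pos for v in self.variants]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("block variants must be sorted by position")
        if self.n_het_in_range is None:
            self.n_het_in_range = len(self.variants)
        if self.n_het_in_range < len(self.variants):
            raise ValueError("n_het_in_range cannot be below the number of phased variants")

    @property
    def start(self) -> int:
        return self.variants[0].site.pos

    @property
    def end(self) -> int:
        return self.variants[-1].site.pos

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def n_phased(self) -> int:
        return len(self.variants)

    @property
    def adjusted_span(self) -> float:
        return self.span * (self.n_phased / self.n_het_in_range)

    @property
    def phase_set(self) -> int:
        return self.variants[0].phase_set


@dataclass
class VcfVariants:
    """Result of :func:`read_vcf`: the genotyped sites plus phasing, if any."""

    sites: list[VariantSite]
    phased: list[PhasedVariant]
    n_skipped: int = 0  # multiallelic / non-SNV records

    def het_sites(self, chrom: str | None = None) -> list[VariantSite]:
        return [s for s in self.sites if s.is_het and (chrom is None or s.chrom == chrom)]


_SNV_BASES = frozenset("ACGT")


def _structural_prescan(path: str | Path) -> None:
    """Cheap per-line column check so malformed records fail with a line number."""
    n_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##") or not line.strip():
                continue
            if line.startswith("#CHROM"):
                n_cols = len(line.rstrip("\n").split("\t"))
                continue
            ncol = len(line.rstrip("\n").split("\t"))
            if ncol < 8 or (n_cols is not None and ncol != n_cols):
                raise ValueError(f"{path}: malformed VCF record at line {lineno} ({ncol} columns)")


def read_vcf(path: str | Path, het_only: bool = False) -> VcfVariants:
    """Read a VCF with GT (and optional PS) into the internal data model.

    Biallelic SNV records are kept; multiallelic and non-SNV records are
    skipped with a warning count.  ``site_index`` is assigned per
    chromosome over het sites in position order.  Phased genotypes
    (``a|b``) produce :class:`PhasedVariant` entries; when PS is absent,
    consecutive phased het records uninterrupted by an unphased het on
    the same chromosome form one block identified by its first position.
    """
    path = str(path)
    _structural_prescan(path)
    # (site, hapA or None, PS or None); phase info travels with the site
    records: list[tuple[VariantSite, int | None, int | None]] = []
    n_skipped = 0
    vcf = VCF(path)
    try:
        for rec in vcf:
            if len(rec.ALT) != 1:
                n_skipped += 1
                continue
            ref, alt = rec.REF.upper(), rec.ALT[0].upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in _SNV_BASES or alt not in _SNV_BASES:
                n_skipped += 1
                continue
            g = rec.genotypes[0]  # [a, b, phased_flag]
            a, b, phased_flag = g[0], g[1], bool(g[2])
            if a < 0 or b < 0:
                gt = Genotype.MISSING
            elif a == b == 0:
                gt = Genotype.HOM_REF
            elif a == b:
                gt = Genotype.HOM_ALT
            else:
                gt = Genotype.HET
            site = VariantSite(rec.CHROM, rec.POS, ref, alt, gt)
            hapA = ps = None
            if gt is Genotype.HET and phased_flag:
                hapA = int(a)
                try:
                    ps_arr = rec.format("PS")
                    if ps_arr is not None:
                        ps = int(ps_arr[0][0])
                except KeyError:
                    ps = None
            records.append((site, hapA, ps))
    finally:
        vcf.close()
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} multiallelic/non-SNV records")

    records.sort(key=lambda r: (r[0].chrom, r[0].pos))

    # assign het ordinals per chromosome; resolve PS-less phased runs
    sites: list[VariantSite] = []
    phased: list[PhasedVariant] = []
    counters: dict[str, int] = {}
    block_start: int | None = None
    prev_chrom: str | None = None
    for s, hapA, ps in records:
        if s.chrom != prev_chrom:
            block_start = None
            prev_chrom = s.chrom
        if s.is_het:
            k = counters.get(s.chrom, 0)
            s = VariantSite(s.chrom, s.pos, s.ref, s.alt, s.genotype, k)
            counters[s.chrom] = k + 1
            if hapA is not None:
                if ps is None:
                    if block_start is None:
                        block_start = s.pos
                    ps = block_start
                phased.append(PhasedVariant(s, hapA, 1 - hapA, ps))
            else:
                block_start = None  # an unphased het interrupts a PS-less block
        sites.append(s)
    if het_only:
        sites = [s for s in sites if s.is_het]
    return VcfVariants(sites=sites, phased=phased, n_skipped=n_skipped)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set identifier">
"""


def write_phased_vcf(
    variants: Sequence[PhasedVariant | VariantSite],
    path: str | Path,
    sample: str = "SAMPLE",
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write phased (and optionally unphased pass-through) variants as VCF 4.2.

    Phased entries get ``GT:PS`` ``a|b:<ps>``; plain :class:`VariantSite`
    entries are written unphased.  Input must be position-sorted per
    chromosome.  Round-trips losslessly through :func:`read_vcf`.
    """

    def key(v):
        s = v.site if isinstance(v, PhasedVariant) else v
        return (s.chrom, s.pos)

    keys = [key(v) for v in variants]
    if any(b <= a for a, b in zip(keys, keys[1:]) if a[0] == b[0]):
        raise ValueError("variants must be sorted by (chrom, pos)")

    chroms: list[str] = []
    for c, _ in keys:
        if c not in chroms:
            chroms.append(c)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in chroms:
            length = (contig_lengths or {}).get(c)
            fh.write(f"##contig=<ID={c}" + (f",length={length}" if length else "") + ">\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n")
        for v in variants:
            if isinstance(v, PhasedVariant):
                s = v.site
                fh.write(
                    f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT:PS\t"
                    f"{v.hapA}|{v.hapB}:{v.phase_set}\n"
                )
            else:
                gt = {
                    Genotype.HOM_REF: "0/0",
                    Genotype.HET: "0/1",
                    Genotype.HOM_ALT: "1/1",
                    Genotype.MISSING: "./.",
                }[v.genotype]
                fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gt}\n")


# ---------------------------------------------------------------------------
# fragment file dialect
# ---------------------------------------------------------------------------

def read_fragments(path: str | Path, n_sites: int | None = None) -> list[Fragment]:
    """Parse the fragment dialect.

    One fragment per line, whitespace-separated::

        n_segments  id  protocol_code  insert_span_bp \
            (start_site_index allele_string){n_segments}  quality_string

    ``protocol_code``: 0=NGS, 1=HIC, 2=LONGREAD, 3=LINKED.  The quality
    string is Phred+33, one character per observed allele across all
    segments.  ``n_sites``, when given, bounds valid site indices.
    """
    frags: list[Fragment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            try:
                n_seg = int(tok[0])
                frag_id = tok[1]
                protocol = CODE_TO_PROTOCOL[int(tok[2])]
                span = int(tok[3])
                obs: list[tuple[int, int]] = []
                p = 4
                for _ in range(n_seg):
                    start = int(tok[p])
                    alleles = tok[p + 1]
                    if set(alleles) - {"0", "1"}:
                        raise ValueError(f"bad allele string {alleles!r}")
                    obs.extend((start + k, int(a)) for k, a in enumerate(alleles))
                    p += 2
                quals = tok[p]
            except (IndexError, ValueError, KeyError) as exc:
                raise ValueError(f"{path}: malformed fragment at line {lineno}: {exc}") from exc
            if len(quals) != len(obs):
                raise ValueError(
                    f"{path}: fragment {frag_id} (line {lineno}): quality string length "
                    f"{len(quals)} != {len(obs)} observed alleles"
                )
            observations = [(i, a, ord(q) - 33) for (i, a), q in zip(obs, quals)]
            if n_sites is not None and observations and observations[-1][0] >= n_sites:
                raise ValueError(
                    f"{path}: fragment {frag_id}: site index {observations[-1][0]} outside "
                    f"het range [0, {n_sites})"
                )
            try:
                frags.append(Fragment(frag_id, protocol, observations, span))
            except ValueError as exc:
                raise ValueError(f"{path}: fragment {frag_id}: {exc}") from exc
    return frags


def write_fragments(frags: Iterable[Fragment], path: str | Path) -> None:
    """Inverse of :func:`read_fragments` (lossless for the dialect's fields)."""
    with open(path, "w") as fh:
        for f in frags:
            segs: list[tuple[int, str]] = []
            quals: list[str] = []
            for i, a, q in f.observations:
                if segs and i == segs[-1][0] + len(segs[-1][1]):
                    segs[-1] = (segs[-1][0], segs[-1][1] + str(a))
                else:
                    segs.append((i, str(a)))
                quals.append(chr(min(q, 93) + 33))
            parts = [str(len(segs)), f.id, str(PROTOCOL_CODES[f.protocol]), str(f.insert_span)]
            for start, alleles in segs:
                parts += [str(start), alleles]
            parts.append("".join(quals))
            fh.write(" ".join(parts) + "\n")


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq_pairs(r1: str | Path, r2: str | Path):
    """Yield (id, seq1, qual1, seq2, qual2) from two synchronized FASTQ files."""
    from Bio import SeqIO

    for rec1, rec2 in zip(SeqIO.parse(str(r1), "fastq"), SeqIO.parse(str(r2), "fastq")):
        yield (
            rec1.id,
            str(rec1.seq),
            rec1.letter_annotations["phred_quality"],
            str(rec2.seq),
            rec2.letter_annotations["phred_quality"],
        )
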