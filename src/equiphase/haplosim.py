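"""Seed-deterministic synthetic data for every pipeline stage.

Emulates a diploid individual and its sequencing: a reference chromosome
with het SNVs and a known phase, short-insert paired observations,
error-prone long reads spanning many variants, Hi-C pairs with
heavy-tailed insert sizes plus trans-homolog noise, a panel-style phased
VCF corrupted by switch errors, and a mosaic-of-founders cohort with
tunable LD decay.

The Hi-C model ties the trans-interaction error mode to apparent insert
size: a trans contact reports the opposite homolog's allele at its
second anchor and its apparent separation is drawn uniformly over the
chromosome, so trans noise concentrates in oversize fragments — the
error mode the Hi-C insert-size filter targets.

The cohort generator copies each sample haplotype as a mosaic of founder
haplotypes with exponentially distributed segment lengths; shorter
segments mean more historical recombination and faster LD decay.  It is
a stand-in with tunable LD structure, not a demographic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from equiphase.iohap import Fragment, Genotype, PhasedVariant, Protocol, VariantSite
from equiphase.popstats import CohortHaplotypes

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class NGSParams:
    coverage: float = 30.0
    read_length: int = 150
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    allele_error: float = 0.0


@dataclass
class LongReadParams:
    coverage: float = 20.0
    length_mean: float = 20_000.0  # SMRT-style long-insert library
    allele_error: float = 0.05
    baseq_sd: float = 8.0


@dataclass
class HiCParams:
    n_pairs: int = 10_000
    anchor_length: int = 150
    insert_scale: float = 20_000.0  # cis contact distance scale
    tail_exponent: float = 1.0  # Pareto tail: heavier for smaller values
    trans_noise_rate: float = 0.05
    # apparent separation range of trans contacts; defaults to
    # [chrom_length/10, chrom_length) — far beyond typical cis inserts
    trans_gap_min: int | None = None
    trans_gap_max: int | None = None


@dataclass
class CohortParams:
    n_samples: int = 156
    # two founders give full LD at zero distance (r^2 -> 1), decaying on the
    # segment-length scale; more founders cap attainable r^2 near 1/n_founders
    n_founders: int = 2
    segment_mean: float = 10_000.0  # bp; mosaic segment length (LD scale)
    mutation_density: float = 0.005  # het sites per bp in the cohort


@dataclass
class SimConfig:
    seed: int = 0
    chrom: str = "chr1"
    chrom_length: int = 1_000_000
    n_het: int = 2_000
    ngs: NGSParams = field(default_factory=NGSParams)
    longread: LongReadParams = field(default_factory=LongReadParams)
    hic: HiCParams = field(default_factory=HiCParams)
    panel_switch_rate: float = 0.02
    cohort: CohortParams = field(default_factory=CohortParams)

    def __post_init__(self) -> None:
        for r in (self.ngs.allele_error, self.longread.allele_error, self.hic.trans_noise_rate, self.panel_switch_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_het > self.chrom_length:
            raise ValueError("cannot place more het sites than base pairs")

    def rng(self, stream: int) -> np.random.Generator:
        # independent deterministic stream per generator stage
        return np.random.default_rng([self.seed, stream])


@dataclass
class TruthSet:
    """Ground truth: reference sequence plus the phased het variants."""

    chrom: str
    reference: str
    variants: list[PhasedVariant]

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.site.pos for v in self.variants], dtype=np.int64)

    @property
    def hapA(self) -> np.ndarray:
        return np.array([v.hapA for v in self.variants], dtype=np.int8)

    @property
    def sites(self) -> list[VariantSite]:
        return [v.site for v in self.variants]


def _phred(error: float) -> int:
    if error <= 0:
        return 40
    return int(round(-10.0 * np.log10(error)))


def simulate_truth(cfg: SimConfig) -> TruthSet:
    """Reference sequence with uniformly placed het SNVs of known phase."""
    rng = cfg.rng(1)
    ref_codes = rng.integers(0, 4, size=cfg.chrom_length)
    reference = bytes(_BASES[ref_codes]).decode()
    positions = np.sort(rng.choice(cfg.chrom_length, size=cfg.n_het, replace=False)) + 1
    variants: list[PhasedVariant] = []
    ps = int(positions[0]) if cfg.n_het else 0
    for idx, pos in enumerate(positions):
        ref_base = reference[pos - 1]
        alt_base = "ACGT"[(int(ref_codes[pos - 1]) + int(rng.integers(1, 4))) % 4]
        hapA = int(rng.integers(0, 2))
        site = VariantSite(cfg.chrom, int(pos), ref_base, alt_base, Genotype.HET, site_index=idx)
        variants.append(PhasedVariant(site, hapA, 1 - hapA, ps))
    return TruthSet(cfg.chrom, reference, variants)


def _observe(
    positions: np.ndarray,
    hap_alleles: np.ndarray,
    lo: float,
    hi: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Het ordinals and alleles covered by the genomic interval [lo, hi)."""
    a = int(np.searchsorted(positions, lo, side="left"))
    b = int(np.searchsorted(positions, hi, side="left"))
    idx = np.arange(a, b)
    return idx, hap_alleles[idx]


def simulate_fragments(truth: TruthSet, cfg: SimConfig, protocol: Protocol) -> list[Fragment]:
    """Fragments for one sequencing protocol, indexed to het-site ordinals."""
    if protocol is Protocol.NGS:
        return _simulate_ngs(truth, cfg)
    if protocol is Protocol.LONGREAD:
        return _simulate_longread(truth, cfg)
    if protocol is Protocol.HIC:
        return _simulate_hic(truth, cfg)
    raise ValueError(f"no generator for protocol {protocol}")


def _frag(
    fid: str,
    protocol: Protocol,
    idx: np.ndarray,
    alleles: np.ndarray,
    quals: np.ndarray,
    positions: np.ndarray,
) -> Fragment | None:
    if len(idx) == 0:
        return None
    span = int(positions[idx[-1]] - positions[idx[0]]) if len(idx) > 1 else 0
    obs = [(int(i), int(a), int(q)) for i, a, q in zip(idx, alleles, quals)]
    return Fragment(fid, protocol, obs, span)


def _simulate_ngs(truth: TruthSet, cfg: SimConfig) -> list[Fragment]:
    p = cfg.ngs
    rng = cfg.rng(2)
    L = cfg.chrom_length
    positions, hapA = truth.positions, truth.hapA
    haps = np.stack([hapA, 1 - hapA])
    n_pairs = int(np.ceil(p.coverage * L / (2 * p.read_length)))
    q = _phred(p.allele_error)
    frags: list[Fragment] = []
    for k in range(n_pairs):
        insert = max(int(rng.normal(p.insert_mean, p.insert_sd)), 2 * p.read_length)
        start = int(rng.integers(0, max(L - insert, 1)))
        h = int(rng.integers(0, 2))
        i1, a1 = _observe(positions, haps[h], start + 1, start + p.read_length + 1)
        i2, a2 = _observe(positions, haps[h], start + insert - p.read_length + 1, start + insert + 1)
        keep = ~np.isin(i2, i1)
        idx = np.concatenate([i1, i2[keep]])
        alleles = np.concatenate([a1, a2[keep]])
        if p.allele_error > 0 and len(idx):
            flip = rng.random(len(idx)) < p.allele_error
            alleles = np.where(flip, 1 - alleles, alleles)
        f = _frag(f"ngs{k}", Protocol.NGS, idx, alleles, np.full(len(idx), q), positions)
        if f is not None:
            frags.append(f)
    return frags


def _simulate_longread(truth: TruthSet, cfg: SimConfig) -> list[Fragment]:
    p = cfg.longread
    rng = cfg.rng(3)
    L = cfg.chrom_length
    positions, hapA = truth.positions, truth.hapA
    haps = np.stack([hapA, 1 - hapA])
    n_reads = int(np.ceil(p.coverage * L / p.length_mean))
    q_mean = _phred(p.allele_error)
    frags: list[Fragment] = []
    for k in range(n_reads):
        length = max(int(rng.exponential(p.length_mean)), 1)
        start = int(rng.integers(0, L))
        h = int(rng.integers(0, 2))
        idx, alleles = _observe(positions, haps[h], start + 1, start + length + 1)
        if len(idx) == 0:
            continue
        if p.allele_error > 0:
            flip = rng.random(len(idx)) < p.allele_error
            alleles = np.where(flip, 1 - alleles, alleles)
        quals = np.clip(np.rint(rng.normal(q_mean, p.baseq_sd, size=len(idx))), 2, 60).astype(int)
        f = _frag(f"lr{k}", Protocol.LONGREAD, idx, alleles, quals, positions)
        if f is not None:
            frags.append(f)
    return frags


def _simulate_hic(truth: TruthSet, cfg: SimConfig) -> list[Fragment]:
    p = cfg.hic
    rng = cfg.rng(4)
    L = cfg.chrom_length
    positions, hapA = truth.positions, truth.hapA
    haps = np.stack([hapA, 1 - hapA])
    frags: list[Fragment] = []
    for k in range(p.n_pairs):
        h = int(rng.integers(0, 2))
        start1 = int(rng.integers(0, max(L - p.anchor_length, 1)))
        is_trans = rng.random() < p.trans_noise_rate
        if is_trans:
            # trans contact: arbitrary apparent separation, opposite homolog
            lo = p.trans_gap_min if p.trans_gap_min is not None else L // 10
            hi = p.trans_gap_max if p.trans_gap_max is not None else L
            gap = int(rng.integers(lo, hi))
        else:
            gap = int((rng.pareto(p.tail_exponent) + 1.0) * p.insert_scale)
        start2 = min(start1 + gap, L - p.anchor_length)
        i1, a1 = _observe(positions, haps[h], start1 + 1, start1 + p.anchor_length + 1)
        h2 = 1 - h if is_trans else h
        i2, a2 = _observe(positions, haps[h2], start2 + 1, start2 + p.anchor_length + 1)
        keep = ~np.isin(i2, i1)
        idx = np.concatenate([i1, i2[keep]])
        alleles = np.concatenate([a1, a2[keep]])
        f = _frag(f"hic{k}", Protocol.HIC, idx, alleles, np.full(len(idx), 40), positions)
        if f is not None:
            frags.append(f)
    return frags


def corrupt_phasing(truth: TruthSet, switch_rate: float, seed: int = 0) -> list[PhasedVariant]:
    """Panel-style phasing of the truth with random switch errors.

    Walks sites left to right toggling orientation with ``switch_rate``
    per inter-site step; the result is one chromosome-wide phase set, the
    shape of a statistically phased panel output.
    """
    rng = np.random.default_rng([seed, 5])
    flipped = 0
    ps = truth.variants[0].site.pos if truth.variants else 0
    out: list[PhasedVariant] = []
    for i, v in enumerate(truth.variants):
        if i > 0 and rng.random() < switch_rate:
            flipped ^= 1
        hapA = v.hapA ^ flipped
        out.append(PhasedVariant(v.site, hapA, 1 - hapA, ps))
    return out


def simulate_cohort(cfg: SimConfig) -> CohortHaplotypes:
    """Mosaic-of-founders cohort haplotypes with tunable LD decay.

    Founder haplotypes carry independent alleles per site; each sample
    haplotype copies founders in segments of exponential length
    (``segment_mean``).  Longer segments preserve founder LD further.
    """
    c = cfg.cohort
    if c.n_samples < 2:
        raise ValueError("cohort needs at least two samples")
    rng = cfg.rng(6)
    n_sites = max(int(round(c.mutation_density * cfg.chrom_length)), 2)
    positions = np.sort(rng.choice(cfg.chrom_length, size=n_sites, replace=False)) + 1
    p_alt = rng.uniform(0.1, 0.9, size=n_sites)
    founders = (rng.random((c.n_founders, n_sites)) < p_alt).astype(np.int8)

    gaps = np.diff(positions).astype(float)
    p_switch = 1.0 - np.exp(-gaps / c.segment_mean)
    n_hap = 2 * c.n_samples
    matrix = np.empty((n_hap, n_sites), dtype=np.int8)
    for hap_i in range(n_hap):
        switches = rng.random(n_sites - 1) < p_switch
        founder_ids = rng.integers(0, c.n_founders, size=int(switches.sum()) + 1)
        segment = np.concatenate([[0], np.cumsum(switches)])
        matrix[hap_i] = founders[founder_ids[segment], np.arange(n_sites)]
    samples = [f"s{i}" for i in range(c.n_samples)]
    return CohortHaplotypes(cfg.chrom, positions, matrix, samples)


def qc_boundary_cases(adapter: str = "AGATCGGAAGAGCACACGTC"):
    """A 60-row table of read pairs probing every QC rule's boundary.

    Returns ``(pairs, expected, adapter)`` where ``expected`` maps pair id
    to the reason the composite filter should report (``pass`` or a drop
    reason).  Rows cross each threshold from both sides: N-fraction
    (strictly more than 2%), low quality (at least 40% of bases at Q<=7),
    adapter contamination (ungapped overlap strictly over 10 bp with at
    most 3 mismatches), mate overlap (>=10 bp at <=10% mismatches) or
    implied insert under 30 bp, and exact duplicates.
    """
    from equiphase.read_qc import ReadPair, reverse_complement

    rng = np.random.default_rng(20240)
    bases = "ACGT"

    def rand_seq(n):
        return "".join(bases[i] for i in rng.integers(0, 4, n))

    def clean_pair(pid, len1=100, len2=100):
        # unrelated random mates; re-draw in the unlikely event of a chance
        # overlap or adapter hit so non-target rules stay silent
        from equiphase.read_qc import QCConfig, classify_pair

        for _ in range(50):
            p = ReadPair(pid, rand_seq(len1), rand_seq(len2), [40] * len1, [40] * len2)
            if classify_pair(p, QCConfig(adapter=adapter)).keep:
                return p
        raise RuntimeError("could not draw a clean pair")  # pragma: no cover

    pairs: list = []
    expected: dict[str, str] = {}

    def add(pair, reason):
        pairs.append(pair)
        expected[pair.id] = reason

    # --- N fraction: drop iff N proportion strictly exceeds 2% (12 rows)
    for k, (length, n_n, mate, keep) in enumerate(
        [(100, 0, 1, True), (100, 1, 1, True), (100, 2, 1, True), (100, 3, 1, False),
         (100, 5, 1, False), (100, 3, 2, False), (50, 0, 1, True), (50, 1, 1, True),
         (50, 2, 1, False), (50, 3, 1, False), (50, 2, 2, False), (50, 1, 2, True)]
    ):
        base = clean_pair(f"nf{k}", length, length)
        seq = "N" * n_n + (base.seq1 if mate == 1 else base.seq2)[n_n:]
        s1, s2 = (seq, base.seq2) if mate == 1 else (base.seq1, seq)
        add(ReadPair(f"nf{k}", s1, s2, [40] * length, [40] * length),
            "pass" if keep else "n_fraction")

    # --- low quality: drop iff >=40% of bases at Q<=7 (12 rows)
    for k, (length, n_low, q, mate, keep) in enumerate(
        [(100, 0, 7, 1, True), (100, 39, 7, 1, True), (100, 40, 7, 1, False),
         (100, 45, 7, 1, False), (100, 100, 7, 1, False), (100, 100, 8, 1, True),
         (50, 19, 7, 1, True), (50, 20, 7, 1, False), (50, 25, 7, 1, False),
         (100, 39, 7, 2, True), (100, 40, 7, 2, False), (100, 50, 0, 2, False)]
    ):
        base = clean_pair(f"lq{k}", length, length)
        quals = [q] * n_low + [40] * (length - n_low)
        q1, q2 = (quals, [40] * length) if mate == 1 else ([40] * length, quals)
        add(ReadPair(f"lq{k}", base.seq1, base.seq2, q1, q2),
            "pass" if keep else "low_quality")

    # --- adapter: drop iff some placement overlaps >10 bp with <=3 mismatches
    def with_adapter_tail(pid, n_over, mismatch_at=()):
        base = clean_pair(pid)
        tail = list(adapter[:n_over])
        for i in mismatch_at:
            tail[i] = bases[(bases.index(tail[i]) + 1) % 4]
        seq1 = base.seq1[: 100 - n_over] + "".join(tail)
        return ReadPair(pid, seq1, base.seq2, [40] * 100, [40] * 100)

    for k, (n_over, mm, keep) in enumerate(
        [(8, (), True), (9, (), True), (10, (), True), (11, (), False), (12, (), False),
         (13, (), False), (11, (0, 4, 8), False), (11, (0, 3, 6, 9), True),
         (12, (1, 5, 9), False), (12, (0, 3, 6, 9), True), (20, (), False), (20, (2, 8, 14), False)]
    ):
        add(with_adapter_tail(f"ad{k}", n_over, mm), "pass" if keep else "adapter")

    # --- abnormal insert: drop iff mate overlap >=10 bp at <=10% mismatches,
    #     or implied insert below 30 bp (12 rows)
    def overlapping_pair(pid, len1, len2, n_over, mismatch_at=()):
        template = rand_seq(len1 + len2 - n_over)
        m1 = template[:len1]
        tail = list(template[len1 - n_over :])
        for i in mismatch_at:
            tail[i] = bases[(bases.index(tail[i]) + 1) % 4]
        m2 = reverse_complement("".join(tail))
        return ReadPair(pid, m1, m2, [40] * len1, [40] * len2)

    for k, (len1, len2, n_over, mm, keep) in enumerate(
        [(100, 100, 60, (), False), (100, 100, 10, (), False), (100, 100, 9, (), True),
         (100, 100, 20, (0, 7, 14), True), (100, 100, 20, (3, 11), False),
         (100, 100, 10, (4,), False), (100, 100, 10, (2, 7), True),
         (100, 100, 100, (), False), (20, 20, 12, (), False), (20, 20, 11, (), False),
         (20, 20, 9, (), True), (15, 15, 5, (), True)]
    ):
        add(overlapping_pair(f"ai{k}", len1, len2, n_over, mm),
            "pass" if keep else "abnormal_insert")

    # --- duplicates: all but the first of identical (seq1, seq2) (12 rows)
    dup_a = clean_pair("du0")
    add(dup_a, "pass")
    for k in range(1, 5):
        add(ReadPair(f"du{k}", dup_a.seq1, dup_a.seq2, dup_a.qual1, dup_a.qual2), "duplicate")
    dup_b = clean_pair("du5")
    add(dup_b, "pass")
    add(ReadPair("du6", dup_b.seq1, dup_b.seq2, dup_b.qual1, dup_b.qual2), "duplicate")
    for k in range(7, 12):
        add(clean_pair(f"du{k}"), "pass")

    assert len(pairs) == 60
    return pairs, expected, adapter


def simulate_read_pairs(
    reference: str,
    n_pairs: int,
    read_length: int = 100,
    insert_mean: float = 300.0,
    insert_sd: float = 30.0,
    seed: int = 0,
):
    """Minimal clean FASTQ-level pair generator (for read-QC testing).

    Pairs are drawn from the reference with normal insert sizes, no N
    bases beyond the reference's own, Q40 everywhere, mate2
    reverse-complemented — all pairs pass the QC rules when the insert
    stays comfortably above the overlap regime.
    """
    from equiphase.read_qc import ReadPair, reverse_complement

    rng = np.random.default_rng([seed, 7])
    L = len(reference)
    pairs = []
    for k in range(n_pairs):
        insert = max(int(rng.normal(insert_mean, insert_sd)), 2 * read_length)
        start = int(rng.integers(0, max(L - insert, 1)))
        seq1 = reference[start : start + read_length]
        seq2 = reverse_complement(reference[start + insert - read_length : start + insert])
        pairs.append(ReadPair(f"rp{k}", seq1, seq2, [40] * len(seq1), [40] * len(seq2)))
    return pairs
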