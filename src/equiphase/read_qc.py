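"""Read-pair quality filtering for short-insert and mate-pair libraries.

Four rules, applied to each read pair:

1. *N fraction* — drop if the proportion of N bases in either mate
   strictly exceeds 2%.
2. *Low quality* — drop if at least 40% of bases in either mate have
   Phred quality <= 7.
3. *Adapter contamination* — drop if the adapter sequence aligns to
   either mate (ungapped, any offset including 3' partial overlaps) with
   more than 10 bp overlap and at most 3 mismatches.
4. *Abnormal insert* — drop if the mates themselves overlap by >= 10 bp
   (mismatch fraction <= 10%) or the implied insert size is < 30 bp.

Plus exact-duplicate marking: pairs with byte-identical (seq1, seq2) keep
only their first occurrence.  The composite filter drops a pair iff any
rule drops it; individual rules are order-independent on the keep/drop
outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadPair:
    id: str
    seq1: str
    seq2: str
    qual1: Sequence[int]
    qual2: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"pair {self.id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class QCDecision:
    keep: bool
    reason: str  # pass | n_fraction | low_quality | adapter | abnormal_insert | duplicate

    def __post_init__(self) -> None:
        if (self.reason == "pass") != self.keep:
            raise ValueError("reason must be 'pass' iff keep")


_PASS = QCDecision(True, "pass")


def filter_n_fraction(pair: ReadPair, threshold: float = 0.02) -> QCDecision:
    """Drop iff the N fraction of either mate strictly exceeds ``threshold``."""
    for seq in (pair.seq1, pair.seq2):
        if seq and seq.upper().count("N") / len(seq) > threshold:
            return QCDecision(False, "n_fraction")
    return _PASS


def filter_low_quality(pair: ReadPair, q_cut: int = 7, frac: float = 0.40) -> QCDecision:
    """Drop iff >= ``frac`` of either mate's bases have quality <= ``q_cut``."""
    for qual in (pair.qual1, pair.qual2):
        if qual and sum(q <= q_cut for q in qual) / len(qual) >= frac:
            return QCDecision(False, "low_quality")
    return _PASS


def detect_adapter(read: str, adapter: str, min_overlap: int = 10, max_mismatch: int = 3) -> bool:
    """Ungapped adapter scan over all offsets, including 3' partial overlaps.

    True iff some placement overlaps the read by more than ``min_overlap``
    bases with at most ``max_mismatch`` mismatches.
    """
    if not adapter:
        raise ValueError("adapter sequence must be non-empty")
    read = read.upper()
    adapter = adapter.upper()
    n, m = len(read), len(adapter)
    for offset in range(-(m - 1), n):
        r0 = max(offset, 0)
        r1 = min(offset + m, n)
        overlap = r1 - r0
        if overlap <= min_overlap:
            continue
        mism = sum(read[r] != adapter[r - offset] for r in range(r0, r1))
        if mism <= max_mismatch:
            return True
    return False


def filter_abnormal_insert(
    pair: ReadPair,
    min_insert: int = 30,
    min_overlap: int = 10,
    mismatch_rate: float = 0.10,
) -> QCDecision:
    """Drop iff the mates credibly overlap, or the implied insert is short.

    Mates are oriented toward each other, so after reverse-complementing
    mate2 an overlapping pair shares a suffix of mate1 with a prefix of
    mate2-rc.  An overlap is credible when it reaches ``min_overlap``
    bases at a mismatch fraction within ``mismatch_rate``; any credible
    overlap marks the insert abnormal, as does the insert it implies
    (len1 + len2 - overlap) falling below ``min_insert``.  Overlaps below
    ``min_overlap`` carry too little evidence to imply an insert.
    """
    seq1 = pair.seq1.upper()
    seq2_rc = reverse_complement(pair.seq2).upper()
    n1, n2 = len(seq1), len(seq2_rc)
    for ov in range(min_overlap, min(n1, n2) + 1):
        mism = sum(a != b for a, b in zip(seq1[n1 - ov :], seq2_rc[:ov]))
        if mism <= mismatch_rate * ov:
            return QCDecision(False, "abnormal_insert")
    return _PASS


def mark_duplicates(pairs: Iterable[ReadPair]) -> set[str]:
    """Ids of pairs whose (seq1, seq2) was already seen — all but first kept."""
    seen: set[tuple[str, str]] = set()
    dups: set[str] = set()
    for p in pairs:
        key = (p.seq1, p.seq2)
        if key in seen:
            dups.add(p.id)
        else:
            seen.add(key)
    return dups


@dataclass
class QCConfig:
    adapter: str | None = None
    n_threshold: float = 0.02
    q_cut: int = 7
    q_frac: float = 0.40
    adapter_min_overlap: int = 10
    adapter_max_mismatch: int = 3
    min_insert: int = 30
    overlap_min: int = 10
    overlap_mismatch_rate: float = 0.10


def classify_pair(pair: ReadPair, cfg: QCConfig, is_duplicate: bool = False) -> QCDecision:
    """Composite filter: first failing rule (fixed report order) names the reason."""
    d = filter_n_fraction(pair, cfg.n_threshold)
    if not d.keep:
        return d
    d = filter_low_quality(pair, cfg.q_cut, cfg.q_frac)
    if not d.keep:
        return d
    if cfg.adapter:
        if detect_adapter(pair.seq1, cfg.adapter, cfg.adapter_min_overlap, cfg.adapter_max_mismatch) or detect_adapter(
            pair.seq2, cfg.adapter, cfg.adapter_min_overlap, cfg.adapter_max_mismatch
        ):
            return QCDecision(False, "adapter")
    d = filter_abnormal_insert(pair, cfg.min_insert, cfg.overlap_min, cfg.overlap_mismatch_rate)
    if not d.keep:
        return d
    if is_duplicate:
        return QCDecision(False, "duplicate")
    return _PASS


def run_qc(pairs: Sequence[ReadPair], cfg: QCConfig) -> tuple[list[ReadPair], dict[str, int]]:
    """Filter a collection of pairs; returns kept pairs and per-reason counts."""
    dups = mark_duplicates(pairs)
    kept: list[ReadPair] = []
    counts = {"pass": 0, "n_fraction": 0, "low_quality": 0, "adapter": 0, "abnormal_insert": 0, "duplicate": 0}
    for p in pairs:
        d = classify_pair(p, cfg, is_duplicate=p.id in dups)
        counts[d.reason] += 1
        if d.keep:
            kept.append(p)
    return kept, counts
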