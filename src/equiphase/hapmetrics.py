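"""Haplotype continuity and accuracy statistics.

Continuity: N50 over block spans, AN50 over adjusted spans (span scaled
by the fraction of in-range het sites phased), total phased SNVs, phase
rate, and the MVP block (the block phasing the most het variants).

Accuracy against a known truth: switch error rate (orientation flips
between consecutive co-phased variants, after per-block optimal global
orientation) and hamming rate (min-mismatch fraction), both pooled over
blocks.

Also provides minimum-error-correction (MEC) scoring: the fewest allele
flips needed to make all fragments consistent with a candidate phasing,
and its exhaustive optimum for small variant counts — the brute-force
oracle for validating the spectral solver.
"""

from __future__ import annotations

from itertools import product
from typing import Sequence

import numpy as np

from equiphase.iohap import Fragment, HaplotypeBlock, PhasedVariant


def phase_rate(blocks: Sequence[HaplotypeBlock], n_het_total: int) -> float:
    """Fraction of het sites phased: sum of block sizes over total het count."""
    total = sum(b.n_phased for b in blocks)
    if total > n_het_total:
        raise ValueError(f"phased count {total} exceeds het total {n_het_total}")
    return total / n_het_total if n_het_total else 0.0


def n50(values: Sequence[float]) -> float:
    """Largest v whose cumulative (descending) sum first reaches half the total."""
    if not values:
        raise ValueError("n50 of an empty collection is undefined")
    if any(v <= 0 for v in values):
        raise ValueError("n50 requires positive values")
    ordered = sorted(values, reverse=True)
    half = sum(ordered) / 2.0
    acc = 0.0
    for v in ordered:
        acc += v
        if acc >= half:
            return v
    return ordered[-1]  # pragma: no cover - loop always reaches half


def an50(blocks: Sequence[HaplotypeBlock]) -> float:
    """N50 of adjusted spans (span x proportion of in-range het SNVs phased)."""
    return n50([b.adjusted_span for b in blocks])


def mvp_block(blocks: Sequence[HaplotypeBlock]) -> HaplotypeBlock:
    """Block with the most phased het variants; ties by larger span, then
    smaller start position."""
    if not blocks:
        raise ValueError("mvp_block needs at least one block")
    return max(blocks, key=lambda b: (b.n_phased, b.span, -b.start))


def switch_error(
    pred: Sequence[HaplotypeBlock], truth: Sequence[PhasedVariant]
) -> tuple[float, float]:
    """(switch rate, hamming rate) of predicted blocks against truth.

    Per block, the global orientation minimizing mismatches is chosen
    (flip-aware); switch rate counts orientation changes between
    consecutive co-phased variants over comparable adjacent pairs, and
    hamming rate the minimized mismatch fraction.  Both are pooled over
    blocks.  Truth must phase every predicted variant.
    """
    truth_by_key = {(t.site.chrom, t.site.pos): t.hapA for t in truth}
    switches = pairs = mismatches = compared = 0
    for b in pred:
        mism = []
        for v in b.variants:
            key = (v.site.chrom, v.site.pos)
            if key not in truth_by_key:
                raise ValueError(f"truth does not phase predicted variant {key[0]}:{key[1]}")
            mism.append(int(v.hapA != truth_by_key[key]))
        n_mis = sum(mism)
        mismatches += min(n_mis, len(mism) - n_mis)
        compared += len(mism)
        # adjacent orientation changes are invariant under a global flip
        switches += sum(a != b_ for a, b_ in zip(mism, mism[1:]))
        pairs += max(len(mism) - 1, 0)
    return (
        switches / pairs if pairs else 0.0,
        mismatches / compared if compared else 0.0,
    )


# ---------------------------------------------------------------------------
# MEC scoring
# ---------------------------------------------------------------------------

def mec_score(frags: Sequence[Fragment], hap: Sequence[int]) -> int:
    """Minimum error correction of a phasing: for each fragment, the fewer
    of its mismatches against the haplotype or its complement, summed.

    ``hap`` gives haplotype A's allele per het-site ordinal; entries < 0
    mark unphased sites, which are skipped in the comparison.
    """
    total = 0
    for f in frags:
        same = diff = 0
        for i, a, _q in f.observations:
            h = hap[i]
            if h < 0:
                continue
            if a == h:
                same += 1
            else:
                diff += 1
        total += min(same, diff)
    return total


def exhaustive_mec(frags: Sequence[Fragment], n_sites: int) -> tuple[int, tuple[int, ...]]:
    """Global MEC optimum by enumerating all 2^(n-1) phasings (small n only).

    Returns (optimal score, one optimal haplotype); the first site is fixed
    to allele 0 since MEC is invariant under a global flip.
    """
    if n_sites > 20:
        raise ValueError("exhaustive MEC is exponential; use n_sites <= 20")
    if n_sites == 0:
        return 0, ()
    best = None
    best_hap: tuple[int, ...] = ()
    for rest in product((0, 1), repeat=n_sites - 1):
        hap = (0,) + rest
        s = mec_score(frags, hap)
        if best is None or s < best:
            best, best_hap = s, hap
    return int(best), best_hap
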