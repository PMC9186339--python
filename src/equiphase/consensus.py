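"""Pseudodiploid consensus: substitute phased alleles into a reference
sequence to produce the two haplotype sequences of a chromosome.

SNV-only: output lengths equal the reference length.  Unphased het sites
are handled per policy — the default leaves the reference base on both
haplotypes and records the masked site in a sidecar BED (0-based
half-open).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Sequence

from equiphase.iohap import Genotype, PhasedVariant, VariantSite


def apply_haplotypes(
    reference: str,
    phased: Sequence[PhasedVariant],
    unphased: Sequence[VariantSite] = (),
    unphased_policy: Literal["ref", "exclude"] = "ref",
) -> tuple[str, str, list[tuple[int, int]]]:
    """Build (hapA, hapB, masked_intervals) from a reference sequence.

    ``phased`` substitutes hapA/hapB alleles at het sites and the ALT
    base on both haplotypes at hom-alt sites (pass hom-alt sites as
    PhasedVariant with hapA == hapB == 1).  ``unphased`` het sites keep
    the reference base on both haplotypes under the default policy and
    are reported as masked 0-based half-open intervals; the ``exclude``
    policy skips them silently.

    Raises when a REF allele disagrees with the reference base or two
    records overlap a position.
    """
    hapA = list(reference)
    hapB = list(reference)
    seen: set[int] = set()
    masked: list[tuple[int, int]] = []

    for v in phased:
        s = v.site
        _check_site(reference, s, seen)
        i = s.pos - 1
        hapA[i] = s.alt if v.hapA == 1 else s.ref
        hapB[i] = s.alt if v.hapB == 1 else s.ref

    for s in unphased:
        _check_site(reference, s, seen)
        if s.genotype is Genotype.HOM_ALT:
            hapA[s.pos - 1] = hapB[s.pos - 1] = s.alt
        elif s.genotype is Genotype.HET and unphased_policy == "ref":
            masked.append((s.pos - 1, s.pos))

    return "".join(hapA), "".join(hapB), masked


def _check_site(reference: str, s: VariantSite, seen: set[int]) -> None:
    if not 1 <= s.pos <= len(reference):
        raise ValueError(f"variant position {s.pos} outside reference (length {len(reference)})")
    if len(s.ref) != 1 or len(s.alt) != 1:
        raise ValueError(f"non-SNV record at {s.chrom}:{s.pos} — consensus is SNV-only")
    if reference[s.pos - 1].upper() != s.ref.upper():
        raise ValueError(
            f"REF mismatch at {s.chrom}:{s.pos}: VCF says {s.ref}, reference has {reference[s.pos - 1]}"
        )
    if s.pos in seen:
        raise ValueError(f"overlapping records at {s.chrom}:{s.pos}")
    seen.add(s.pos)


def write_bed(intervals: Sequence[tuple[int, int]], chrom: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        for start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
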