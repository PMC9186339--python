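"""Cohort haplotype statistics: MAF, heterozygosity, inter-SNP distances,
haplotype-based LD r-squared and the LD-decay curve.

LD is computed from phased haplotype counts directly: for sites u, v with
ALT frequencies p_u, p_v and joint ALT-ALT haplotype frequency p_uv,

    r^2 = (p_uv - p_u p_v)^2 / (p_u (1 - p_u) p_v (1 - p_v))

The decay distance is where the binned mean r^2 first drops below a
threshold (0.5 by default), linearly interpolated between the straddling
bin midpoints.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from equiphase.iohap import Genotype, PhasedVariant, VariantSite


@dataclass
class CohortHaplotypes:
    """Phased haplotype-allele matrix: 2 rows per sample, one column per site."""

    chrom: str
    positions: np.ndarray  # 1-based bp, strictly increasing
    matrix: np.ndarray  # (2*n_samples, n_sites) of {0,1}
    samples: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape[0] != 2 * len(self.samples):
            raise ValueError("matrix must have two haplotype rows per sample")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.matrix.shape[1] != len(self.positions):
            raise ValueError("matrix columns must match positions")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("alleles must be binary")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.positions)


def site_maf(cohort: CohortHaplotypes, site: int) -> float:
    """Minor allele frequency over haplotypes at one site."""
    p = float(cohort.matrix[:, site].mean())
    return min(p, 1.0 - p)


def site_heterozygosity(cohort: CohortHaplotypes, site: int) -> float:
    """Fraction of samples whose two haplotype alleles differ at the site."""
    col = cohort.matrix[:, site]
    return float((col[0::2] != col[1::2]).mean())


def inter_snp_distances(positions: Sequence[int]) -> np.ndarray:
    """Consecutive distances between sorted SNP positions (bp)."""
    pos = np.asarray(positions, dtype=np.int64)
    if len(pos) < 2:
        return np.empty(0, dtype=np.int64)
    return np.diff(pos)


def fraction_over(distances: Sequence[int], cutoff: int = 1000) -> float:
    """Fraction of inter-SNP distances exceeding ``cutoff`` (default 1 kb)."""
    d = np.asarray(distances)
    return float((d > cutoff).mean()) if len(d) else 0.0


def haplotype_r2(cohort: CohortHaplotypes, site_u: int, site_v: int) -> float:
    """Squared Pearson correlation between two sites from haplotype counts.

    Symmetric in its sites, invariant to REF/ALT relabeling, bounded
    [0, 1].  Raises on a monomorphic site (r^2 undefined).
    """
    u = cohort.matrix[:, site_u].astype(float)
    v = cohort.matrix[:, site_v].astype(float)
    p_u, p_v = u.mean(), v.mean()
    if p_u in (0.0, 1.0) or p_v in (0.0, 1.0):
        raise ValueError(f"monomorphic site: r^2 undefined for sites {site_u},{site_v}")
    p_uv = (u * v).mean()
    num = (p_uv - p_u * p_v) ** 2
    den = p_u * (1 - p_u) * p_v * (1 - p_v)
    return float(num / den)


def ld_decay(
    cohort: CohortHaplotypes,
    bin_width: int = 1000,
    max_dist: int = 500_000,
    r2_threshold: float = 0.5,
) -> tuple[pd.DataFrame, float]:
    """Binned mean r^2 versus distance, and the decay distance.

    All polymorphic site pairs within ``max_dist`` contribute; pairs with
    a monomorphic member are excluded with a warning.  The decay distance
    is where the mean-r^2 curve first crosses below ``r2_threshold``,
    linearly interpolated between straddling bin midpoints (the first
    bin's midpoint if it is already below).  ``math.inf`` is returned
    when no bin falls below the threshold (decay distance > max_dist).

    Returns (curve, decay_distance); curve columns: bin_start, bin_end,
    mid, mean_r2, n_pairs.
    """
    freqs = cohort.matrix.mean(axis=0)
    poly = np.flatnonzero((freqs > 0) & (freqs < 1))
    n_mono = cohort.n_sites - len(poly)
    if n_mono:
        warnings.warn(f"excluding {n_mono} monomorphic sites from LD decay")
    if len(poly) < 2:
        raise ValueError("LD decay needs at least two polymorphic sites")

    pos = cohort.positions[poly]
    X = cohort.matrix[:, poly].astype(np.float64)
    n_bins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    p = X.mean(axis=0)
    var = p * (1 - p)
    n_hap = X.shape[0]
    for i in range(len(poly) - 1):
        j_hi = int(np.searchsorted(pos, pos[i] + max_dist, side="right"))
        if j_hi <= i + 1:
            continue
        cols = slice(i + 1, j_hi)
        p_uv = (X[:, i][:, None] * X[:, cols]).sum(axis=0) / n_hap
        r2 = (p_uv - p[i] * p[cols]) ** 2 / (var[i] * var[cols])
        bins = ((pos[cols] - pos[i]) // bin_width).astype(int)
        bins = np.minimum(bins, n_bins - 1)
        np.add.at(sums, bins, r2)
        np.add.at(counts, bins, 1)

    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    edges = np.arange(n_bins + 1) * bin_width
    curve = pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "mid": (edges[:-1] + edges[1:]) / 2.0,
            "mean_r2": means,
            "n_pairs": counts,
        }
    )
    decay = decay_distance_from_curve(curve, r2_threshold)
    return curve, decay


def decay_distance_from_curve(curve: pd.DataFrame, threshold: float = 0.5) -> float:
    """Distance at which the binned mean-r^2 curve crosses below the
    threshold, linearly interpolated between straddling bin midpoints."""
    obs = curve[curve["n_pairs"] > 0].reset_index(drop=True)
    prev_mid = prev_r2 = None
    for _, row in obs.iterrows():
        if row["mean_r2"] < threshold:
            if prev_mid is None:
                return float(row["mid"])
            # interpolate the crossing between the straddling bin midpoints
            t = (prev_r2 - threshold) / (prev_r2 - row["mean_r2"])
            return float(prev_mid + t * (row["mid"] - prev_mid))
        prev_mid, prev_r2 = row["mid"], row["mean_r2"]
    return math.inf


def cohort_from_vcf(path: str | Path) -> list[CohortHaplotypes]:
    """Load a multi-sample phased VCF into per-chromosome haplotype matrices."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    data: dict[str, tuple[list[int], list[list[int]]]] = {}
    try:
        for rec in vcf:
            if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
                continue
            alleles: list[int] = []
            ok = True
            for g in rec.genotypes:
                a, b = g[0], g[1]
                if a < 0 or b < 0:
                    ok = False
                    break
                alleles += [int(a), int(b)]
            if not ok:
                continue
            positions, rows = data.setdefault(rec.CHROM, ([], []))
            positions.append(rec.POS)
            rows.append(alleles)
    finally:
        vcf.close()
    out = []
    for chrom, (positions, rows) in data.items():
        out.append(CohortHaplotypes(chrom, np.array(positions), np.array(rows).T, samples))
    return out


def write_cohort_vcf(cohort: CohortHaplotypes, path: str | Path) -> None:
    """Write the haplotype matrix as a phased multi-sample VCF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={cohort.chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cohort.samples) + "\n")
        for j, pos in enumerate(cohort.positions):
            gts = "\t".join(
                f"{cohort.matrix[2*i, j]}|{cohort.matrix[2*i+1, j]}" for i in range(cohort.n_samples)
            )
            fh.write(f"{cohort.chrom}\t{pos}\t.\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def summarize_cohort(cohort: CohortHaplotypes) -> pd.DataFrame:
    """Per-site MAF and heterozygosity table."""
    p = cohort.matrix.mean(axis=0)
    maf = np.minimum(p, 1 - p)
    het = (cohort.matrix[0::2] != cohort.matrix[1::2]).mean(axis=0)
    return pd.DataFrame({"pos": cohort.positions, "maf": maf, "heterozygosity": het})
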