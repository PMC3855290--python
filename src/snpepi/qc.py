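"""Marker and individual quality control, plus the composite-LD r².

Filter conventions follow the emulated genotyping protocol literally:
markers with MAF *below* 5% or monomorphic are removed (MAF exactly 0.05
is retained), individuals with 5% *or more* missing genotypes are removed
(exactly 5% is removed).  Marker filtering runs before individual
filtering; MAF is not recomputed after individual removal unless asked.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .containers import GenotypeMatrix


class EmptyPanelError(ValueError):
    """All markers (or all individuals) were removed by a filter."""


@dataclass
class QcReport:
    n_snps_in: int = 0
    n_snps_removed_maf: int = 0
    n_snps_removed_monomorphic: int = 0
    n_individuals_in: int = 0
    n_individuals_removed_missing: int = 0
    n_snps_out: int = 0
    n_individuals_out: int = 0

    def __post_init__(self):
        for k, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"negative count {k}={v}")

    def to_text(self) -> str:
        d = asdict(self)
        width = max(len(k) for k in d)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in d.items())

    def to_dict(self) -> dict:
        return asdict(self)


def filter_markers(genotypes: GenotypeMatrix, maf_floor: float = 0.05
                   ) -> tuple[GenotypeMatrix, QcReport]:
    """Remove monomorphic markers and markers with MAF below the floor.

    MAF is computed on non-missing calls; a marker needs at least two
    observed genotype classes to survive.  The floor is inclusive: MAF
    exactly equal to ``maf_floor`` is retained.
    """
    maf = genotypes.maf()
    n_classes = genotypes.n_genotype_classes()
    mono = n_classes < 2
    # a marker with all calls missing counts as monomorphic here
    mono |= np.isnan(maf)
    low = ~mono & (maf < maf_floor)
    keep = ~(mono | low)
    report = QcReport(
        n_snps_in=genotypes.n_snps,
        n_snps_removed_monomorphic=int(mono.sum()),
        n_snps_removed_maf=int(low.sum()),
        n_individuals_in=genotypes.n_individuals,
        n_snps_out=int(keep.sum()),
        n_individuals_out=genotypes.n_individuals,
    )
    if report.n_snps_out == 0:
        raise EmptyPanelError("marker filter removed every SNP")
    return genotypes.subset_snps(np.flatnonzero(keep)), report


def filter_individuals(genotypes: GenotypeMatrix, max_missing: float = 0.05
                       ) -> tuple[GenotypeMatrix, QcReport]:
    """Remove individuals whose missing-call fraction is >= ``max_missing``."""
    miss = genotypes.missing_rate_individuals()
    keep = miss < max_missing
    report = QcReport(
        n_snps_in=genotypes.n_snps,
        n_snps_out=genotypes.n_snps,
        n_individuals_in=genotypes.n_individuals,
        n_individuals_removed_missing=int((~keep).sum()),
        n_individuals_out=int(keep.sum()),
    )
    if report.n_individuals_out == 0:
        raise EmptyPanelError("individual filter removed every individual")
    return genotypes.subset_individuals(np.flatnonzero(keep)), report


def run_qc(genotypes: GenotypeMatrix, maf_floor: float = 0.05,
           max_missing: float = 0.05,
           refilter_markers: bool = False) -> tuple[GenotypeMatrix, QcReport]:
    """Markers first, then individuals (optionally re-check MAF after)."""
    gm, rep_m = filter_markers(genotypes, maf_floor)
    gm, rep_i = filter_individuals(gm, max_missing)
    if refilter_markers:
        gm, rep_m2 = filter_markers(gm, maf_floor)
        rep_m.n_snps_removed_maf += rep_m2.n_snps_removed_maf
        rep_m.n_snps_removed_monomorphic += rep_m2.n_snps_removed_monomorphic
    report = QcReport(
        n_snps_in=genotypes.n_snps,
        n_snps_removed_maf=rep_m.n_snps_removed_maf,
        n_snps_removed_monomorphic=rep_m.n_snps_removed_monomorphic,
        n_individuals_in=genotypes.n_individuals,
        n_individuals_removed_missing=rep_i.n_individuals_removed_missing,
        n_snps_out=gm.n_snps,
        n_individuals_out=gm.n_individuals,
    )
    return gm, report


class UndefinedLdError(ValueError):
    """r² undefined: a locus is monomorphic among complete cases."""


def pairwise_r2(snp_a: np.ndarray, snp_b: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of genotype codes.

    Computed on individuals with complete calls at both loci.  Phase is not
    required; this is the dosage-correlation convention.  Raises
    :class:`UndefinedLdError` when either locus is monomorphic among the
    complete cases (the statistic is undefined, not zero).
    """
    a = np.asarray(snp_a, dtype=float)
    b = np.asarray(snp_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("genotype vectors differ in length")
    mask = ~(np.isnan(a) | np.isnan(b))
    if mask.sum() < 2:
        raise UndefinedLdError("need at least two complete observations")
    a, b = a[mask], b[mask]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedLdError("monomorphic locus among complete cases")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def mean_r2_within(genotypes: GenotypeMatrix, max_distance_bp: int
                   ) -> float:
    """Mean pairwise r² between same-chromosome SNPs within a distance.

    Supports the choice of annotation window size: a window is defensible
    when the mean r² within it is high (the emulated protocol used ~0.2 Mb
    at mean r² > 0.8).
    """
    chroms = genotypes.markers.chroms
    pos = genotypes.markers.positions
    vals = []
    for i in range(genotypes.n_snps - 1):
        for j in range(i + 1, genotypes.n_snps):
            if chroms[i] != chroms[j]:
                continue
            if abs(int(pos[i]) - int(pos[j])) > max_distance_bp:
                continue
            try:
                vals.append(pairwise_r2(genotypes.codes[:, i],
                                        genotypes.codes[:, j]))
            except UndefinedLdError:
                continue
    return float(np.mean(vals)) if vals else np.nan
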