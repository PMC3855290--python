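"""Synthetic cohorts with family structure and planted epistasis.

Emulates the design of a two-line divergently selected broiler population:
a few hundred individuals in a handful of families, a dense biallelic SNP
panel with a minor-allele-frequency floor, optional Hardy-Weinberg
disequilibrium and block LD, and a quantitative trait (abdominal fat
weight) generated as

    y = mu + additive/dominance main effects + planted epistatic products
           + family draw + Gaussian error.

Planted epistatic effects multiply the same frequency-orthogonal contrast
products the scan estimates, so generative effect sizes and estimated
effects live on one scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MarkerMap
from .scan import EFFECT_TYPES, locus_contrasts

#: mean gap between adjacent markers, bp (dense 60K-chip scale)
_MEAN_GAP_BP = 16_000


@dataclass
class PlantedEpistasis:
    """One planted two-locus effect.

    ``effect_size`` multiplies the corresponding orthogonal contrast
    product (trait units per contrast-product unit).  Optional per-locus
    additive/dominance main-effect sizes ride along.
    """

    snp_i: str
    snp_j: str
    effect_type: str
    effect_size: float
    main_additive: tuple[float, float] = (0.0, 0.0)
    main_dominance: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.snp_i == self.snp_j:
            raise ValueError("planted pair must involve two distinct SNPs")
        if self.effect_type not in EFFECT_TYPES:
            raise ValueError(f"effect_type must be one of {EFFECT_TYPES}")


@dataclass
class SimulationConfig:
    """Full parameterization of a synthetic cohort.

    Defaults mirror the emulated study: 475 individuals in 2 lines with
    family substructure, SNPs surviving a 5% MAF floor, and a quantitative
    trait with family and residual variance components.  ``maf_law`` is
    either a fixed frequency, a (low, high) uniform range within
    (0, 0.5], or a callable ``f(rng, n) -> frequencies``.
    """

    n_individuals: int = 475
    n_families: int = 10
    n_lines: int = 2
    family_variance: float = 0.25
    residual_variance: float = 1.0
    grand_mean: float = 0.0
    n_snps: int = 500
    n_chromosomes: int = 5
    maf_law: float | tuple[float, float] | Callable = (0.05, 0.5)
    hwd_coefficient: float = 0.0
    ld_blocks: Sequence[tuple[int, float]] | None = None
    missing_rate: float = 0.0
    planted_effects: list[PlantedEpistasis] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 2 * self.n_families:
            raise ValueError("need at least two individuals per family")
        if self.family_variance < 0 or self.residual_variance < 0:
            raise ValueError("variances must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if isinstance(self.maf_law, (int, float)):
            if not 0 < self.maf_law <= 0.5:
                raise ValueError("fixed MAF must lie in (0, 0.5]")
        elif isinstance(self.maf_law, tuple):
            lo, hi = self.maf_law
            if not (0 < lo <= hi <= 0.5):
                raise ValueError("MAF range must satisfy 0 < low <= high <= 0.5")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _draw_mafs(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    law = config.maf_law
    if callable(law):
        maf = np.asarray(law(rng, config.n_snps), dtype=float)
    elif isinstance(law, tuple):
        maf = rng.uniform(law[0], law[1], size=config.n_snps)
    else:
        maf = np.full(config.n_snps, float(law))
    if maf.shape != (config.n_snps,):
        raise ValueError("maf_law produced the wrong number of frequencies")
    return maf


def _hwd_genotype_probs(q: float, D: float) -> np.ndarray:
    """Genotype probabilities (q=minor freq) with HWD coefficient D.

    P(hom major) = p^2 + D, P(het) = 2pq - 2D, P(hom minor) = q^2 + D.
    """
    p = 1.0 - q
    probs = np.array([p * p + D, 2 * p * q - 2 * D, q * q + D])
    if (probs < -1e-12).any():
        raise ValueError(
            f"hwd_coefficient D={D} is infeasible at MAF {q:.3f}: "
            f"genotype frequency would be negative (feasible range "
            f"[{-q*q:.4f}, {p*q:.4f}])"
        )
    return np.clip(probs, 0.0, None) / probs.sum()


def _ld_block_genotypes(rng, n_ind: int, block_size: int, r2: float,
                        q: float) -> np.ndarray:
    """Block of correlated genotypes via haplotype copying.

    Two haplotypes per individual; the anchor site draws alleles
    Bernoulli(q) and every other site copies the anchor allele with
    probability t = sqrt(r2), else redraws Bernoulli(q).  Allelic
    correlation between any site and the anchor is then t, giving pairwise
    genotype r^2 of about r2 against the anchor.
    """
    if not 0 <= r2 <= 1:
        raise ValueError("target r2 must lie in [0, 1]")
    t = np.sqrt(r2)
    anchor = rng.random((n_ind, 2)) < q          # alleles on 2 haplotypes
    geno = np.empty((n_ind, block_size))
    geno[:, 0] = anchor.sum(axis=1)
    for s in range(1, block_size):
        copy = rng.random((n_ind, 2)) < t
        fresh = rng.random((n_ind, 2)) < q
        hap = np.where(copy, anchor, fresh)
        geno[:, s] = hap.sum(axis=1)
    return geno


def generate_genotypes(config: SimulationConfig,
                       rng: np.random.Generator | None = None
                       ) -> GenotypeMatrix:
    """Draw the genotype panel and its marker map.

    Returns a :class:`GenotypeMatrix` whose ``markers`` map has strictly
    increasing positions per chromosome.  LD blocks, when configured,
    occupy the leading SNPs in order; the remaining SNPs are independent
    draws from the (possibly HWD-perturbed) genotype distribution.
    """
    rng = config.rng() if rng is None else rng
    n, m = config.n_individuals, config.n_snps
    maf = _draw_mafs(config, rng)
    codes = np.empty((n, m))

    pointer = 0
    block_of = np.full(m, -1)
    if config.ld_blocks:
        for b, (size, r2) in enumerate(config.ld_blocks):
            if pointer + size > m:
                raise ValueError("ld_blocks exceed the SNP panel")
            q = maf[pointer]
            maf[pointer:pointer + size] = q  # one frequency per block
            codes[:, pointer:pointer + size] = _ld_block_genotypes(
                rng, n, size, r2, q)
            block_of[pointer:pointer + size] = b
            pointer += size

    for k in range(pointer, m):
        probs = _hwd_genotype_probs(maf[k], config.hwd_coefficient)
        codes[:, k] = rng.choice(3, size=n, p=probs)

    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        codes[mask] = np.nan

    # marker map: SNPs split evenly over chromosomes, random gaps around
    # the dense-chip mean spacing; LD blocks stay contiguous by layout
    chrom_sizes = np.full(config.n_chromosomes, m // config.n_chromosomes)
    chrom_sizes[: m % config.n_chromosomes] += 1
    rows = []
    k = 0
    for c, size in enumerate(chrom_sizes, start=1):
        pos = np.cumsum(rng.integers(1, 2 * _MEAN_GAP_BP, size=size))
        for jj in range(size):
            rows.append((f"snp{k+1:05d}", str(c), int(pos[jj])))
            k += 1
    markers = MarkerMap(pd.DataFrame(rows, columns=["snp", "chrom", "pos"]))
    return GenotypeMatrix(codes, markers)


def _contrast_or_zero(g: np.ndarray, what: str, snp: str):
    """Contrast vector on the cohort, zeros where undefined or missing."""
    mask = ~np.isnan(g)
    out = np.zeros(g.size)
    try:
        a, d = locus_contrasts(g[mask])
    except ValueError:
        warnings.warn(
            f"planted SNP {snp} is monomorphic in the realized sample; "
            "its effect contributes nothing", stacklevel=3)
        return out
    if what == "a":
        out[mask] = a
    elif d is not None:
        out[mask] = d
    else:
        warnings.warn(
            f"planted SNP {snp} shows only two genotype classes; its "
            "dominance contrast is undefined and contributes nothing",
            stacklevel=3)
    return out


def generate_phenotypes(genotypes: GenotypeMatrix, config: SimulationConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the quantitative trait over a genotype panel.

    Returns ``(phenotypes, planted_report)``: a table with columns
    ``id``, ``family``, ``line``, ``afw`` and a per-planted-pair report of
    the realized contribution (%) of each planted epistatic term, i.e. its
    corrected sum of squares over the phenotype's corrected total sum of
    squares.
    """
    if rng is None:
        # offset keeps the phenotype stream decoupled from the genotype
        # stream so the same panel can carry many phenotype replicates
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = genotypes.n_individuals

    # equal-sized families assigned at random, families nested in lines
    fam = np.repeat(np.arange(config.n_families),
                    -(-n // config.n_families))[:n]
    rng.shuffle(fam)
    line = fam % config.n_lines
    fam_effects = rng.normal(0.0, np.sqrt(config.family_variance),
                             size=config.n_families)

    y = np.full(n, config.grand_mean, dtype=float)
    y += fam_effects[fam]

    planted_terms = []
    for pe in config.planted_effects:
        for snp in (pe.snp_i, pe.snp_j):
            if snp not in genotypes.markers:
                raise ValueError(f"planted SNP {snp} not in the genotype panel")
        gi = genotypes.column(pe.snp_i)
        gj = genotypes.column(pe.snp_j)
        ci = _contrast_or_zero(gi, "a" if pe.effect_type[0] == "A" else "d",
                               pe.snp_i)
        cj = _contrast_or_zero(gj, "a" if pe.effect_type[1] == "A" else "d",
                               pe.snp_j)
        term = pe.effect_size * ci * cj
        # main effects, additive and dominance per locus
        for snp, g, adds, doms in (
            (pe.snp_i, gi, pe.main_additive[0], pe.main_dominance[0]),
            (pe.snp_j, gj, pe.main_additive[1], pe.main_dominance[1]),
        ):
            if adds:
                y += adds * _contrast_or_zero(g, "a", snp)
            if doms:
                y += doms * _contrast_or_zero(g, "d", snp)
        y += term
        planted_terms.append((pe, term))

    y += rng.normal(0.0, np.sqrt(config.residual_variance), size=n)

    tss = float(((y - y.mean()) ** 2).sum())
    report_rows = []
    for pe, term in planted_terms:
        ss = float(((term - term.mean()) ** 2).sum())
        report_rows.append({
            "snp_i": pe.snp_i, "snp_j": pe.snp_j,
            "effect_type": pe.effect_type,
            "effect_size": pe.effect_size,
            "realized_ss": ss,
            "realized_contribution": 100.0 * ss / tss if tss > 0 else np.nan,
        })

    pheno = pd.DataFrame({
        "id": genotypes.individuals,
        "family": [f"fam{f+1}" for f in fam],
        "line": [f"line{v+1}" for v in line],
        "afw": y,
    })
    report = pd.DataFrame(
        report_rows, columns=["snp_i", "snp_j", "effect_type", "effect_size",
                              "realized_ss", "realized_contribution"])
    return pheno, report


def simulate_cohort(config: SimulationConfig):
    """Genotypes and phenotypes in one call (shared seed stream)."""
    genotypes = generate_genotypes(config)
    pheno, report = generate_phenotypes(genotypes, config)
    return genotypes, pheno, report
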