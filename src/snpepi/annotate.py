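"""Genomic-window annotation of significant SNPs.

Significant SNPs are expanded into fixed-width fragments (0.4 Mb centered
on the SNP), overlapping or touching fragments on one chromosome are
merged into union regions, genes overlapping a region are assigned to it,
SNPs are intersected with QTL intervals, and genes are tallied into
pathways from a local gene-to-pathway mapping.  All coordinates are
1-based inclusive; BED input (0-based half-open) is converted at the
reader boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: half-width of a single-SNP fragment, bp (0.2 Mb each side -> 0.4 Mb)
DEFAULT_HALF_WIDTH = 200_000


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """1-based inclusive chromosome span."""

    chrom: str
    start: int
    end: int
    kind: str = field(default="fragment", compare=False)
    id: str = field(default="", compare=False)
    members: tuple = field(default=(), compare=False)

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError("coordinates are 1-based; start must be >= 1")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start <= other.end and other.start <= self.end)

    def touches_or_overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start <= other.end + 1
                and other.start <= self.end + 1)

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


class UnmappedSnpError(ValueError):
    """SNP lacks a usable map position (unplaced / 'UN' chromosome)."""


UNPLACED_LABELS = {"UN", "0", "", "NA"}


def snp_fragment(snp: str, chrom: str, pos: int,
                 half_width: int = DEFAULT_HALF_WIDTH) -> GenomicInterval:
    """Fragment of width 2*half_width centered on a mapped SNP.

    The left edge clips at 1.  SNPs on unplaced pseudo-chromosomes are
    rejected (they cannot enter region building).
    """
    if str(chrom).upper() in UNPLACED_LABELS:
        raise UnmappedSnpError(f"SNP {snp} is unplaced (chrom={chrom!r})")
    if pos < 1:
        raise ValueError(f"SNP {snp} has a non-positive position")
    return GenomicInterval(
        chrom=str(chrom), start=max(1, pos - half_width),
        end=pos + half_width, kind="fragment", id=snp, members=(snp,),
    )


def fragments_for_snps(markers, snps, half_width: int = DEFAULT_HALF_WIDTH
                       ) -> tuple[list[GenomicInterval], list[str]]:
    """Fragments for every mappable SNP; unplaced SNPs returned separately."""
    frags, unplaced = [], []
    for snp in snps:
        chrom, pos = markers.locus(snp)
        try:
            frags.append(snp_fragment(snp, chrom, pos, half_width))
        except UnmappedSnpError:
            logger.warning("SNP %s is unplaced; excluded from regions", snp)
            unplaced.append(snp)
    return frags, unplaced


def merge_fragments(fragments: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union-merge overlapping or touching fragments per chromosome.

    Returns regions sorted by (chromosome, start); each region's
    ``members`` is the union of its fragments' member SNPs.  Intervals that
    touch (end + 1 == start) merge, per the union-set convention.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for f in fragments:
        by_chrom.setdefault(f.chrom, []).append(f)
    regions = []
    for chrom in sorted(by_chrom):
        frags = sorted(by_chrom[chrom], key=lambda f: (f.start, f.end))
        cur_start, cur_end = frags[0].start, frags[0].end
        cur_members = set(frags[0].members)
        for f in frags[1:]:
            if f.start <= cur_end + 1:
                cur_end = max(cur_end, f.end)
                cur_members |= set(f.members)
            else:
                regions.append(GenomicInterval(
                    chrom, cur_start, cur_end, kind="region",
                    members=tuple(sorted(cur_members))))
                cur_start, cur_end, cur_members = f.start, f.end, set(f.members)
        regions.append(GenomicInterval(
            chrom, cur_start, cur_end, kind="region",
            members=tuple(sorted(cur_members))))
    return sorted(regions)


def map_to_qtls(markers, snps, qtl_intervals: list[GenomicInterval]
                ) -> pd.DataFrame:
    """Intersect SNP positions with QTL intervals (inclusive ends).

    Many-to-many: a SNP may hit several QTLs and a QTL several SNPs.
    Chromosome-label mismatches produce no hits and are logged once.
    """
    qtl_chroms = {q.chrom for q in qtl_intervals}
    rows = []
    seen_mismatch = set()
    for snp in snps:
        chrom, pos = markers.locus(snp)
        if chrom not in qtl_chroms and chrom not in seen_mismatch:
            logger.info("no QTL intervals on chromosome %r (SNP %s)",
                        chrom, snp)
            seen_mismatch.add(chrom)
        for q in qtl_intervals:
            if q.contains_point(chrom, pos):
                rows.append({"snp": snp, "chrom": chrom, "pos": pos,
                             "qtl": q.id, "qtl_start": q.start,
                             "qtl_end": q.end})
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "qtl",
                                       "qtl_start", "qtl_end"])


def genes_in_regions(regions: list[GenomicInterval],
                     gene_intervals: list[GenomicInterval]) -> pd.DataFrame:
    """Assign genes to regions by any-overlap.

    ``gene_intervals`` carry ``kind`` "gene" or "noncoding_gene"; output
    rows record the region, gene, and a coding flag so coding and
    non-coding genes can be reported separately.
    """
    rows = []
    for ri, region in enumerate(regions):
        for gene in gene_intervals:
            if region.overlaps(gene):
                rows.append({
                    "region_chrom": region.chrom,
                    "region_start": region.start,
                    "region_end": region.end,
                    "region_snps": ",".join(region.members),
                    "gene": gene.id,
                    "coding": gene.kind != "noncoding_gene",
                })
    return pd.DataFrame(rows, columns=["region_chrom", "region_start",
                                       "region_end", "region_snps", "gene",
                                       "coding"])


def pathway_tally(gene_sets: dict[str, list[str]],
                  gene_to_pathway: pd.DataFrame
                  ) -> tuple[pd.DataFrame, list[str]]:
    """Tally pathway membership for per-subnet gene sets.

    ``gene_to_pathway`` has columns ``gene`` and ``pathway`` (one row per
    assignment).  Returns (tally, unmapped): the tally has one row per
    (subnet, pathway) with the contributing genes; genes absent from the
    mapping are listed in ``unmapped`` rather than dropped silently.
    """
    required = {"gene", "pathway"}
    if not required <= set(gene_to_pathway.columns):
        raise ValueError("mapping needs columns 'gene' and 'pathway'")
    lookup: dict[str, list[str]] = {}
    for row in gene_to_pathway.itertuples(index=False):
        lookup.setdefault(str(row.gene), []).append(str(row.pathway))
    rows = []
    unmapped = []
    for subnet, genes in gene_sets.items():
        per_pathway: dict[str, list[str]] = {}
        for gene in genes:
            if gene not in lookup:
                unmapped.append(gene)
                continue
            for pw in lookup[gene]:
                per_pathway.setdefault(pw, []).append(gene)
        for pw in sorted(per_pathway):
            genes_pw = sorted(set(per_pathway[pw]))
            rows.append({"subnet": subnet, "pathway": pw,
                         "n_genes": len(genes_pw),
                         "genes": ",".join(genes_pw)})
    tally = pd.DataFrame(rows, columns=["subnet", "pathway", "n_genes",
                                        "genes"])
    return tally, sorted(set(unmapped))


def genes_near_snps(markers, snps,
                    gene_intervals: list[GenomicInterval],
                    max_distance: int = DEFAULT_HALF_WIDTH) -> pd.DataFrame:
    """Alternative per-SNP rule: genes within ``max_distance`` of the SNP.

    Distance is 0 when the SNP falls inside the gene, otherwise the gap to
    the nearest gene edge.  Offered alongside the region-overlap rule.
    """
    rows = []
    for snp in snps:
        chrom, pos = markers.locus(snp)
        for gene in gene_intervals:
            if gene.chrom != chrom:
                continue
            if gene.start <= pos <= gene.end:
                dist = 0
            else:
                dist = min(abs(pos - gene.start), abs(pos - gene.end))
            if dist < max_distance:
                rows.append({"snp": snp, "gene": gene.id, "distance": dist,
                             "coding": gene.kind != "noncoding_gene"})
    return pd.DataFrame(rows, columns=["snp", "gene", "distance", "coding"])


def region_report(regions: list[GenomicInterval],
                  gene_assignments: pd.DataFrame) -> pd.DataFrame:
    """Region table: chromosome, span, member SNPs, coding and non-coding
    gene sets (mirrors the usual published region-report layout)."""
    rows = []
    for region in regions:
        sel = gene_assignments[
            (gene_assignments["region_chrom"] == region.chrom)
            & (gene_assignments["region_start"] == region.start)
            & (gene_assignments["region_end"] == region.end)
        ]
        coding = sorted(sel.loc[sel["coding"], "gene"])
        noncoding = sorted(sel.loc[~sel["coding"], "gene"])
        rows.append({
            "chrom": region.chrom, "start": region.start, "end": region.end,
            "snp_set": ",".join(region.members),
            "gene_set": ",".join(coding) if coding else "Blank",
            "noncoding_gene_set": ",".join(noncoding) if noncoding else "Blank",
        })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "snp_set",
                                       "gene_set", "noncoding_gene_set"])
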