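"""Readers and writers: genotype matrices, PED/MAP, VCF, pair tables, BED.

Genotype codes are minor-allele counts in {0, 1, 2} with NaN for missing.
Pair tables follow the published significant-pair schema (first chromosome,
SNP1, second chromosome, SNP2, epistatic effect type, P-value,
contribution %); the P-value parser accepts both plain scientific notation
("2.54e-14") and typeset notation ("2.54×10^−14", Unicode multiplication
sign and minus).  BED intervals (0-based half-open) are converted to the
package's 1-based inclusive convention at the reader boundary.
"""

from __future__ import annotations

import importlib.resources as resources
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MarkerMap
from .annotate import GenomicInterval

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"


# ---------------------------------------------------------------------------
# plain matrix + map

def write_matrix(genotypes: GenotypeMatrix, prefix) -> tuple[Path, Path]:
    """Write codes as a TSV (rows = individuals) plus a map TSV."""
    prefix = Path(prefix)
    geno_path = prefix.with_suffix(".geno.tsv")
    map_path = prefix.with_suffix(".markers.tsv")
    df = pd.DataFrame(genotypes.codes, columns=genotypes.markers.snps,
                      index=genotypes.individuals)
    df.index.name = "id"
    with np.errstate(invalid="ignore"):
        out = df.map(lambda v: MISSING_TOKEN if np.isnan(v) else str(int(v)))
    out.to_csv(geno_path, sep="\t")
    genotypes.markers.table.to_csv(map_path, sep="\t", index=False)
    logger.info("wrote genotype matrix to %s and map to %s",
                geno_path, map_path)
    return geno_path, map_path


def read_matrix(geno_path, map_path) -> GenotypeMatrix:
    df = pd.read_csv(geno_path, sep="\t", index_col=0,
                     na_values=[MISSING_TOKEN])
    df = df.astype(float)
    markers = MarkerMap(pd.read_csv(map_path, sep="\t",
                                    dtype={"chrom": str}))
    if list(df.columns) != list(markers.snps):
        raise ValueError("genotype columns do not match the marker map")
    return GenotypeMatrix(df.to_numpy(), markers,
                          [str(i) for i in df.index])


def write_phenotypes(pheno: pd.DataFrame, path) -> Path:
    """Two-column (id, afw) table plus the family column."""
    path = Path(path)
    cols = [c for c in ("id", "afw", "family", "line") if c in pheno.columns]
    pheno.loc[:, cols].to_csv(path, sep="\t", index=False)
    logger.info("wrote phenotypes to %s", path)
    return path


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns or "afw" not in df.columns:
        raise ValueError("phenotype file needs 'id' and 'afw' columns")
    return df


# ---------------------------------------------------------------------------
# PED/MAP (PLINK-style text)

#: allele letters: 'A' = major, 'B' = minor.  At MAF exactly 0.5 the
#: alphabetically later letter is taken as minor, so round-trips are stable.
_PED_ALLELES = {0.0: "A A", 1.0: "A B", 2.0: "B B"}


def write_ped(genotypes: GenotypeMatrix, pheno: pd.DataFrame | None,
              prefix) -> tuple[Path, Path]:
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for row in genotypes.markers.table.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp}\t0\t{row.pos}\n")
    fam = {}
    trait = {}
    if pheno is not None:
        fam = dict(zip(pheno["id"], pheno.get("family", "0")))
        if "afw" in pheno.columns:
            trait = dict(zip(pheno["id"], pheno["afw"]))
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(genotypes.individuals):
            lead = [str(fam.get(ind, "0")), ind, "0", "0", "0",
                    str(trait.get(ind, -9))]
            alleles = [
                "0 0" if np.isnan(v) else _PED_ALLELES[v]
                for v in genotypes.codes[i]
            ]
            fh.write("\t".join(lead + alleles) + "\n")
    logger.info("wrote PED/MAP to %s / %s", ped_path, map_path)
    return ped_path, map_path


def read_ped(ped_path, map_path) -> GenotypeMatrix:
    """Read PED/MAP, coding genotypes as per-site minor-allele counts."""
    markers = []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"malformed map line: {line!r}")
            markers.append((parts[1], parts[0], int(parts[3])))
    mmap = MarkerMap(pd.DataFrame(markers, columns=["snp", "chrom", "pos"]))
    n_snps = len(mmap)
    ids, fams, rows = [], [], []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(
                    f"PED line has {len(parts)} fields; map implies "
                    f"{6 + 2 * n_snps}")
            fams.append(parts[0])
            ids.append(parts[1])
            rows.append(parts[6:])
    alleles = np.array(rows).reshape(len(ids), n_snps, 2)
    codes = np.empty((len(ids), n_snps))
    for k in range(n_snps):
        site = alleles[:, k, :]
        called = site[site != "0"]
        if called.size == 0:
            codes[:, k] = np.nan
            continue
        uniq, counts = np.unique(called, return_counts=True)
        if uniq.size > 2:
            raise ValueError(f"site {mmap.snps[k]} has >2 alleles")
        order = np.lexsort((uniq, counts))  # least frequent first,
        minor = uniq[order][0]              # ties -> alphabetically later
        if uniq.size == 2 and counts[0] == counts[1]:
            minor = max(uniq)
        miss = (site == "0").any(axis=1)
        codes[:, k] = (site == minor).sum(axis=1).astype(float)
        codes[miss, k] = np.nan
    return GenotypeMatrix(codes, mmap, ids)


# ---------------------------------------------------------------------------
# VCF

def write_vcf(genotypes: GenotypeMatrix, path) -> Path:
    """Minimal uncompressed VCF; ALT is the minor allele (REF 'A', ALT 'B')."""
    path = Path(path)
    gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.individuals) + "\n")
        for k, row in enumerate(genotypes.markers.table.itertuples(index=False)):
            calls = [
                "./." if np.isnan(v) else gt[v]
                for v in genotypes.codes[:, k]
            ]
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp}\tA\tB\t.\t.\t.\tGT\t"
                     + "\t".join(calls) + "\n")
    logger.info("wrote VCF to %s", path)
    return path


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic sites from a VCF via cyvcf2, coding minor-allele counts.

    Sites with more than one ALT allele are skipped (counted in the log).
    When the ALT allele is the major one, codes flip so they always count
    the minor allele; at an exact 50/50 tie the ALT allele counts.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    markers, cols = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        # gt_types: 0 hom-ref, 1 het, 3 hom-alt, 2 unknown
        gt = np.asarray(var.gt_types, dtype=float)
        col = np.where(gt == 3, 2.0, gt)
        col[gt == 2] = np.nan
        obs = col[~np.isnan(col)]
        if obs.size and obs.mean() / 2.0 > 0.5:
            col = 2.0 - col
        markers.append((var.ID or f"{var.CHROM}:{var.POS}",
                        str(var.CHROM), int(var.POS)))
        cols.append(col)
    if n_skipped:
        logger.warning("skipped %d non-biallelic VCF records", n_skipped)
    if not markers:
        raise ValueError(f"no usable biallelic records in {path}")
    mmap = MarkerMap(pd.DataFrame(markers, columns=["snp", "chrom", "pos"]))
    return GenotypeMatrix(np.column_stack(cols), mmap, ids)


def read_genotypes(path, format: str | None = None,
                   map_path=None) -> GenotypeMatrix:
    """Dispatch on format: 'matrix', 'ped' or 'vcf' (guessed from suffix)."""
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".vcf": "vcf", ".ped": "ped"}.get(suffix, "matrix")
    if format == "vcf":
        return read_vcf(path)
    if format == "ped":
        if map_path is None:
            map_path = path.with_suffix(".map")
        return read_ped(path, map_path)
    if format == "matrix":
        if map_path is None:
            map_path = path.with_name(
                path.name.replace(".geno.tsv", ".markers.tsv"))
        return read_matrix(path, map_path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# significant-pair tables

PAIR_TABLE_COLUMNS = ["chrom1", "snp1", "chrom2", "snp2", "effect", "P", "c"]

_HEADER_ALIASES = {
    "gga f": "chrom1", "gga_f": "chrom1", "ggaf": "chrom1", "chrom1": "chrom1",
    "snp1 name": "snp1", "snp_1_ name": "snp1", "snp1": "snp1",
    "gga s": "chrom2", "gga_s": "chrom2", "ggas": "chrom2", "chrom2": "chrom2",
    "snp2 name": "snp2", "snp_2_ name": "snp2", "snp2": "snp2",
    "epistatic effect type": "effect", "epistatic_effect_type": "effect",
    "effect type": "effect", "effect": "effect",
    "p-value": "P", "p_value": "P", "p": "P",
    "c (%)": "c", "c(%)": "c", "c": "c", "c_percent": "c",
}

_TYPESET_SCI = re.compile(r"^\s*([0-9.]+)\s*[×x]\s*10\s*\^?\s*([+\-−–]?\s*\d+)\s*$")


def parse_p_value(text) -> float:
    """Parse '2.54e-14' or '2.54×10^−14' (typeset ×, superscript minus)."""
    if isinstance(text, (int, float)):
        return float(text)
    s = str(text).strip().replace("−", "-").replace("–", "-")
    m = _TYPESET_SCI.match(s)
    if m:
        mantissa, exponent = m.groups()
        return float(mantissa) * 10.0 ** int(exponent.replace(" ", ""))
    return float(s)


def load_pair_table(path) -> pd.DataFrame:
    """Load a significant-pair table in the published schema.

    Returns columns ``chrom1, snp1, chrom2, snp2, effect, P, c`` with P as
    float and c as percent.  Raises with the offending row number on
    malformed rows.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    renames = {}
    for col in raw.columns:
        key = col.strip().lower()
        if key in _HEADER_ALIASES:
            renames[col] = _HEADER_ALIASES[key]
    df = raw.rename(columns=renames)
    missing = set(PAIR_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"pair table {path} missing columns {sorted(missing)}; "
            f"header was {list(raw.columns)}")
    out_rows = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            out_rows.append({
                "chrom1": str(row.chrom1).strip(),
                "snp1": str(row.snp1).strip(),
                "chrom2": str(row.chrom2).strip(),
                "snp2": str(row.snp2).strip(),
                "effect": str(row.effect).strip().upper(),
                "P": parse_p_value(row.P),
                "c": float(str(row.c).rstrip("%")),
            })
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path} line {i}: unparseable row") from exc
    return pd.DataFrame(out_rows, columns=PAIR_TABLE_COLUMNS)


def write_pair_table(pairs: pd.DataFrame, path) -> Path:
    """Write significant pairs in the published column layout."""
    path = Path(path)
    out = pairs.rename(columns={
        "chrom1": "GGA_F", "snp1": "SNP1", "chrom2": "GGA_S", "snp2": "SNP2",
        "effect": "Epistatic_effect_type", "P": "P_value", "c": "c_percent",
    })
    cols = ["GGA_F", "SNP1", "GGA_S", "SNP2", "Epistatic_effect_type",
            "P_value", "c_percent"]
    out.loc[:, [c for c in cols if c in out.columns]].to_csv(
        path, sep="\t", index=False)
    logger.info("wrote pair table to %s", path)
    return path


# ---------------------------------------------------------------------------
# intervals and mappings

def read_bed(path, kind: str = "QTL") -> list[GenomicInterval]:
    """BED (0-based half-open) -> 1-based inclusive intervals.

    Column 4, when present, is the interval id; column 5 may carry a
    coding/non-coding flag for gene files ('coding' / 'noncoding').
    """
    intervals = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path} line {ln}: need >=3 BED columns")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            iid = parts[3] if len(parts) > 3 else f"{kind}_{ln}"
            k = kind
            if len(parts) > 4 and parts[4].lower().startswith("noncod"):
                k = "noncoding_gene"
            elif kind == "gene":
                k = "gene"
            intervals.append(GenomicInterval(
                chrom=str(chrom), start=start0 + 1, end=end0, kind=k, id=iid))
    return intervals


def read_gene_pathways(path) -> pd.DataFrame:
    """Tab-separated gene -> pathway mapping (one assignment per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "pathway"} <= set(df.columns):
        raise ValueError(f"{path}: need columns 'gene' and 'pathway'")
    return df


# ---------------------------------------------------------------------------
# packaged fixtures

def fixture_path(name: str) -> Path:
    """Path to a packaged data fixture (e.g. the 52-pair AFW table)."""
    return Path(resources.files("snpepi").joinpath("data", name))


def load_afw_pairs() -> pd.DataFrame:
    """The 52 published genome-wide significant AFW epistatic SNP pairs."""
    return load_pair_table(fixture_path("afw_pairs.tsv"))
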