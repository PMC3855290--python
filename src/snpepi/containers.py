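"""In-memory containers for genotype panels and marker maps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sort key for chicken chromosome labels: autosomes numerically, then
#: linkage groups (LGE/LEG*), then Z/W, then unplaced ("UN") and "0".
def chrom_sort_key(label: str) -> tuple:
    s = str(label)
    if s.isdigit() and s != "0":
        return (0, int(s), "")
    if s.upper().startswith(("LGE", "LEG")):
        return (1, 0, s)
    if s.upper() in ("Z", "W"):
        return (2, 0, s)
    return (3, 0, s)


class MarkerMap:
    """SNP id -> (chromosome, bp position) map.

    Thin wrapper over a DataFrame with columns ``snp``, ``chrom``, ``pos``;
    positions are 1-based.  Chromosome labels are opaque strings ("1".."28",
    "Z", linkage groups like "LEG22", "UN"/"0" for unplaced).
    """

    COLUMNS = ("snp", "chrom", "pos")

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"marker map missing columns: {sorted(missing)}")
        df = table.loc[:, list(self.COLUMNS)].copy()
        df["snp"] = df["snp"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        if df["snp"].duplicated().any():
            dupes = df.loc[df["snp"].duplicated(), "snp"].tolist()
            raise ValueError(f"duplicate SNP ids in marker map: {dupes[:5]}")
        self.table = df.reset_index(drop=True)
        self._index = {s: i for i, s in enumerate(self.table["snp"])}

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, snp: str) -> bool:
        return snp in self._index

    @property
    def snps(self) -> np.ndarray:
        return self.table["snp"].to_numpy()

    @property
    def chroms(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    def index_of(self, snp: str) -> int:
        return self._index[snp]

    def locus(self, snp: str) -> tuple[str, int]:
        i = self._index[snp]
        return self.table.at[i, "chrom"], int(self.table.at[i, "pos"])

    def subset(self, idx) -> "MarkerMap":
        return MarkerMap(self.table.iloc[np.asarray(idx)].reset_index(drop=True))

    def check_sorted(self) -> bool:
        """True when positions strictly increase within every chromosome."""
        for _, grp in self.table.groupby("chrom", sort=False):
            p = grp["pos"].to_numpy()
            if np.any(np.diff(p) <= 0):
                return False
        return True


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs minor-allele-count codes with missing values.

    ``codes`` is a float array with entries in {0, 1, 2} and NaN for missing
    calls; rows are individuals (ids in ``individuals``), columns follow
    ``markers``.
    """

    codes: np.ndarray
    markers: MarkerMap
    individuals: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2:
            raise ValueError("genotype codes must be a 2-D array")
        if self.codes.shape[1] != len(self.markers):
            raise ValueError(
                f"{self.codes.shape[1]} genotype columns but "
                f"{len(self.markers)} markers in the map"
            )
        if not self.individuals:
            self.individuals = [f"ind{i+1}" for i in range(self.codes.shape[0])]
        if len(self.individuals) != self.codes.shape[0]:
            raise ValueError("individual ids do not match row count")
        obs = self.codes[~np.isnan(self.codes)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotype codes must be 0, 1, 2 or missing")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def column(self, snp: str) -> np.ndarray:
        return self.codes[:, self.markers.index_of(snp)]

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency over non-missing calls.

        Codes count the minor allele, so the frequency is folded back below
        0.5 in case missingness pushed the realized count frequency above it.
        """
        with np.errstate(invalid="ignore"):
            f = np.nanmean(self.codes, axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def missing_rate_individuals(self) -> np.ndarray:
        return np.isnan(self.codes).mean(axis=1)

    def n_genotype_classes(self) -> np.ndarray:
        """Number of distinct observed genotype codes per SNP."""
        out = np.zeros(self.n_snps, dtype=int)
        for k, code in enumerate((0.0, 1.0, 2.0)):
            out += np.nansum(self.codes == code, axis=0) > 0
        return out

    def subset_snps(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.codes[:, idx], self.markers.subset(idx), list(self.individuals))

    def subset_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.codes[idx], self.markers, [self.individuals[i] for i in idx]
        )
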