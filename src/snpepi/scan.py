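"""Two-locus epistasis testing with a frequency-orthogonal effect partition.

The model fitted for every SNP pair is

    y = mu + family + a1 + d1 + a2 + d2
           + (a1*a2) + (a1*d2) + (d1*a2) + (d1*d2) + e

where ``a`` is the additive contrast (minor-allele count centered by its
observed mean) and ``d`` the dominance contrast (heterozygosity indicator
orthogonalized against the constant and additive columns under the observed
genotype frequencies).  Because the contrasts are orthogonalized under the
*observed* frequencies rather than assumed Hardy-Weinberg ones, the
partition of the 4-df interaction into AA, AD, DA and DD one-degree-of-
freedom effects remains meaningful under Hardy-Weinberg disequilibrium and
linkage disequilibrium.  Each effect is tested by an F-test on its marginal
(type-III) sum of squares; the overall interaction is a model-comparison
F-test against the main-effects model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

EFFECT_TYPES = ("AA", "AD", "DA", "DD")

#: residual-norm fraction below which a design column is treated as
#: collinear with the rest of the design (and its effect untestable)
_COLLINEARITY_TOL = 1e-8


class MonomorphicLocusError(ValueError):
    """Raised when a locus has fewer than two observed genotype classes."""


def locus_contrasts(g: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
    """Additive and dominance contrasts for one locus.

    Parameters
    ----------
    g : array of genotype codes in {0, 1, 2}, no missing values.

    Returns
    -------
    (a, d) where ``a`` is the centered allele count and ``d`` the
    heterozygosity indicator orthogonalized (Gram-Schmidt under the observed
    genotype frequencies, i.e. ordinary least squares on this sample)
    against the constant and additive columns.  ``d`` is None when only two
    genotype classes are observed: the dominance contrast is then collinear
    with the additive one and the corresponding effects are untestable.
    """
    g = np.asarray(g, dtype=float)
    classes = np.unique(g)
    if classes.size < 2:
        raise MonomorphicLocusError("locus is monomorphic in the analyzed sample")
    a = g - g.mean()
    if classes.size == 2:
        return a, None
    h = (g == 1.0).astype(float)
    # residual of h on [1, a]; a is already centered so the projections split
    d = h - h.mean() - (h @ a) / (a @ a) * a
    if np.linalg.norm(d) < _COLLINEARITY_TOL * np.sqrt(g.size):
        return a, None
    return a, d


@dataclass
class PairDesign:
    """Design pieces for one SNP pair on its complete-case individuals."""

    snp1: str
    snp2: str
    mask: np.ndarray              # complete-case mask into the cohort
    family: np.ndarray            # family labels on complete cases
    g1: np.ndarray
    g2: np.ndarray
    a1: np.ndarray = field(repr=False, default=None)
    d1: np.ndarray | None = field(repr=False, default=None)
    a2: np.ndarray = field(repr=False, default=None)
    d2: np.ndarray | None = field(repr=False, default=None)

    @property
    def n_used(self) -> int:
        return int(self.mask.sum())

    def interaction_columns(self) -> dict[str, np.ndarray | None]:
        return {
            "AA": self.a1 * self.a2,
            "AD": None if self.d2 is None else self.a1 * self.d2,
            "DA": None if self.d1 is None else self.d1 * self.a2,
            "DD": None if (self.d1 is None or self.d2 is None)
            else self.d1 * self.d2,
        }

    def orthogonality_residuals(self) -> dict[str, float]:
        """Per-locus weighted inner products that the contrasts must zero.

        Under no LD these are exactly the quantities the Gram-Schmidt step
        annihilates; under LD the *cross-locus* non-orthogonality is real
        and reported by ``TwoLocusResults.decomposition_gap`` instead.
        """
        out = {"a1.const": float(self.a1.sum()), "a2.const": float(self.a2.sum())}
        if self.d1 is not None:
            out["d1.const"] = float(self.d1.sum())
            out["d1.a1"] = float(self.d1 @ self.a1)
        if self.d2 is not None:
            out["d2.const"] = float(self.d2.sum())
            out["d2.a2"] = float(self.d2 @ self.a2)
        return out


def build_pair_design(
    g1: np.ndarray,
    g2: np.ndarray,
    family: np.ndarray | None = None,
    snp1: str = "snp1",
    snp2: str = "snp2",
) -> PairDesign:
    """Assemble the frequency-orthogonal design for one SNP pair.

    Missing genotypes at either locus drop the individual (complete-case
    within the pair).  Raises :class:`MonomorphicLocusError` when either
    locus has fewer than two genotype classes among complete cases.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("genotype vectors differ in length")
    mask = ~(np.isnan(g1) | np.isnan(g2))
    if family is None:
        family = np.zeros(g1.size, dtype=int)
    family = np.asarray(family)[mask]
    g1c, g2c = g1[mask], g2[mask]
    a1, d1 = locus_contrasts(g1c)
    a2, d2 = locus_contrasts(g2c)
    return PairDesign(
        snp1=snp1, snp2=snp2, mask=mask, family=family,
        g1=g1c, g2=g2c, a1=a1, d1=d1, a2=a2, d2=d2,
    )


# ---------------------------------------------------------------------------
# least-squares machinery

def _family_dummies(family: np.ndarray) -> np.ndarray:
    """Intercept plus k-1 family indicator columns."""
    levels = pd.unique(family)
    cols = [np.ones(family.size)]
    for lev in levels[1:]:
        cols.append((family == lev).astype(float))
    return np.column_stack(cols)


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of an OLS fit."""
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        return float(res[0]), int(rank)
    r = y - X @ beta
    return float(r @ r), int(rank)


def _is_collinear(col: np.ndarray, others: np.ndarray) -> bool:
    """Whether ``col`` lies (numerically) in the span of ``others``."""
    beta, *_ = np.linalg.lstsq(others, col, rcond=None)
    resid = col - others @ beta
    denom = np.linalg.norm(col)
    if denom == 0:
        return True
    return np.linalg.norm(resid) / denom < _COLLINEARITY_TOL


# ---------------------------------------------------------------------------
# model / results objects

class TwoLocusModel:
    """Linear model for one SNP pair: main effects, family, 4-way epistasis.

    Parameters
    ----------
    endog : phenotype vector for the full cohort.
    design : a :class:`PairDesign` (see :func:`build_pair_design`).
    family_mode : "fixed" absorbs family as indicator covariates (default);
        "random" fits a one-way random intercept by REML first and runs the
        same contrasts on family-adjusted phenotypes.
    """

    def __init__(self, endog: np.ndarray, design: PairDesign,
                 family_mode: str = "fixed"):
        if family_mode not in ("fixed", "random"):
            raise ValueError("family_mode must be 'fixed' or 'random'")
        self.design = design
        self.family_mode = family_mode
        y = np.asarray(endog, dtype=float)
        if y.size == design.mask.size:
            y = y[design.mask]
        elif y.size != design.n_used:
            raise ValueError("phenotype length matches neither cohort nor design")
        self.endog = y

    @classmethod
    def from_genotypes(cls, endog, g1, g2, family=None,
                       snp1="snp1", snp2="snp2", family_mode="fixed"):
        design = build_pair_design(g1, g2, family, snp1=snp1, snp2=snp2)
        return cls(endog, design, family_mode=family_mode)

    def _adjusted_response_and_base(self) -> tuple[np.ndarray, np.ndarray]:
        """Response and base (non-interaction) columns per family mode."""
        d = self.design
        if self.family_mode == "fixed":
            return self.endog, _family_dummies(d.family)
        from statsmodels.regression.mixed_linear_model import MixedLM

        groups = pd.Series(d.family).astype(str).to_numpy()
        if pd.unique(groups).size < 2:
            return self.endog, np.ones((d.n_used, 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mm = MixedLM(self.endog, np.ones((d.n_used, 1)), groups=groups)
            fit = mm.fit(reml=True)
        blup = np.zeros(d.n_used)
        for lev, re in fit.random_effects.items():
            blup[groups == lev] = float(np.asarray(re)[0])
        return self.endog - blup, np.ones((d.n_used, 1))

    def fit(self) -> "TwoLocusResults":
        d = self.design
        y, base = self._adjusted_response_and_base()

        main_cols, main_names = [d.a1], ["a1"]
        if d.d1 is not None:
            main_cols.append(d.d1); main_names.append("d1")
        main_cols.append(d.a2); main_names.append("a2")
        if d.d2 is not None:
            main_cols.append(d.d2); main_names.append("d2")

        inter = d.interaction_columns()
        inter_names = [e for e in EFFECT_TYPES if inter[e] is not None]

        X_main = np.column_stack([base] + main_cols)
        untestable: dict[str, str] = {
            e: "dominance contrast undefined (two genotype classes)"
            for e in EFFECT_TYPES if inter[e] is None
        }
        # keep a maximal estimable subset of interaction columns (an empty
        # genotype cell makes one linear combination unidentifiable);
        # greedy in AA, AD, DA, DD order, so the highest-order effect is
        # the one flagged untestable, never silently dropped
        estimable = []
        for e in inter_names:
            others = np.column_stack(
                [X_main] + [inter[f] for f in estimable]
            )
            if _is_collinear(inter[e], others):
                untestable[e] = (
                    "not estimable: column collinear with the design "
                    "(absent genotype cell or exact LD)"
                )
            else:
                estimable.append(e)

        X_full = np.column_stack([X_main] + [inter[e] for e in estimable]) \
            if estimable else X_main
        n = d.n_used
        rss_full, rank_full = _rss(X_full, y)
        df_resid = n - rank_full
        rss_main, _ = _rss(X_main, y)

        tss = float(((y - y.mean()) ** 2).sum())
        df_int = len(estimable)

        if df_resid <= 0:
            raise ValueError("saturated design: no residual degrees of freedom")
        # a numerically perfect fit leaves only rounding noise in the RSS;
        # treat it as exact so SS ratios do not amplify that noise
        noise_floor = 1e-12 * max(tss, 1.0)
        if rss_full < noise_floor:
            rss_full = 0.0
        if rss_main < noise_floor:
            rss_main = 0.0
        mse = rss_full / df_resid

        ss_overall = max(rss_main - rss_full, 0.0)
        if df_int > 0 and mse > 0:
            f_overall = (ss_overall / df_int) / mse
            p_overall = float(stats.f.sf(f_overall, df_int, df_resid))
        elif df_int > 0:
            # perfect fit: any interaction signal is infinitely significant
            f_overall = np.inf if ss_overall > 0 else 0.0
            p_overall = 0.0 if ss_overall > 0 else 1.0
        else:
            f_overall, p_overall = np.nan, np.nan

        per_effect = {}
        for e in EFFECT_TYPES:
            if e in untestable:
                per_effect[e] = dict(ss=np.nan, F=np.nan, p=np.nan,
                                     testable=False, reason=untestable[e])
                continue
            keep = [f for f in estimable if f != e]
            X_red = np.column_stack([X_main] + [inter[f] for f in keep]) \
                if keep else X_main
            rss_red, _ = _rss(X_red, y)
            if rss_red < noise_floor:
                rss_red = 0.0
            ss = max(rss_red - rss_full, 0.0)
            if mse > 0:
                F = ss / mse
                p = float(stats.f.sf(F, 1, df_resid))
            else:
                F = np.inf if ss > 0 else 0.0
                p = 0.0 if ss > 0 else 1.0
            per_effect[e] = dict(ss=ss, F=F, p=p, testable=True, reason="")

        return TwoLocusResults(
            model=self,
            n_used=n,
            df_int=df_int,
            df_resid=df_resid,
            rss_full=rss_full,
            rss_main=rss_main,
            tss=tss,
            f_overall=f_overall,
            p_overall=p_overall,
            ss_overall=ss_overall,
            per_effect=per_effect,
        )


@dataclass
class TwoLocusResults:
    """Fit results for one SNP pair.

    ``per_effect`` maps each of AA/AD/DA/DD to its marginal (type-III) sum
    of squares, 1-df F statistic, P-value and a testability flag.
    Contribution rates (percent of the corrected total sum of squares of the
    phenotype) are exposed through :meth:`contribution`.
    """

    model: TwoLocusModel
    n_used: int
    df_int: int
    df_resid: int
    rss_full: float
    rss_main: float
    tss: float
    f_overall: float
    p_overall: float
    ss_overall: float
    per_effect: dict

    @property
    def snp1(self) -> str:
        return self.model.design.snp1

    @property
    def snp2(self) -> str:
        return self.model.design.snp2

    def contribution(self, effect: str) -> float:
        """Contribution rate (%) of one epistatic effect."""
        info = self.per_effect[effect]
        if not info["testable"]:
            return np.nan
        return contribution_rate_from_ss(info["ss"], self.tss)

    def decomposition_gap(self) -> float:
        """Sum of the four 1-df SS minus the overall interaction SS.

        Zero (to numerical tolerance) when the interaction columns are
        mutually orthogonal after adjustment for the main effects - the
        no-LD, Hardy-Weinberg, balanced-family case.  Under LD the partial
        sums of squares need not add up; the gap quantifies the
        non-orthogonality instead of hiding it.
        """
        ss = sum(v["ss"] for v in self.per_effect.values() if v["testable"])
        return float(ss - self.ss_overall)

    def to_record(self) -> dict:
        rec = {
            "snp1": self.snp1, "snp2": self.snp2, "n_used": self.n_used,
            "F_overall": self.f_overall, "df_int": self.df_int,
            "df_resid": self.df_resid, "P_overall": self.p_overall,
            "SS_overall": self.ss_overall, "TSS": self.tss,
        }
        for e in EFFECT_TYPES:
            info = self.per_effect[e]
            rec[f"SS_{e}"] = info["ss"]
            rec[f"F_{e}"] = info["F"]
            rec[f"P_{e}"] = info["p"]
            rec[f"c_{e}"] = self.contribution(e)
            rec[f"testable_{e}"] = info["testable"]
        return rec

    def summary(self) -> str:
        lines = [
            f"Two-locus epistasis model: {self.snp1} x {self.snp2}",
            f"  n = {self.n_used}, family mode = {self.model.family_mode}",
            f"  overall interaction: F({self.df_int}, {self.df_resid}) = "
            f"{self.f_overall:.4g}, P = {self.p_overall:.3g}",
            f"  {'effect':<8}{'SS':>12}{'F':>12}{'P':>12}{'c (%)':>9}",
        ]
        for e in EFFECT_TYPES:
            info = self.per_effect[e]
            if info["testable"]:
                lines.append(
                    f"  {e:<8}{info['ss']:>12.5g}{info['F']:>12.5g}"
                    f"{info['p']:>12.3g}{self.contribution(e):>9.3f}"
                )
            else:
                lines.append(f"  {e:<8}{'untestable: ' + info['reason']:>45}")
        return "\n".join(lines)


def test_pair(design: PairDesign, phenotype: np.ndarray,
              family_mode: str = "fixed") -> TwoLocusResults:
    """Functional wrapper: fit the two-locus model for one pair."""
    return TwoLocusModel(phenotype, design, family_mode=family_mode).fit()


# ---------------------------------------------------------------------------
# thresholds and contribution rates

def bonferroni(n_snps: int, alpha: float = 0.05,
               tests_per_pair: int = 4) -> tuple[int, float]:
    """Bonferroni test count and per-test threshold for a pairwise scan.

    ``n_tests = tests_per_pair * C(n_snps, 2)``; four tests per pair because
    each pair contributes four 1-df effect tests.
    """
    if n_snps < 2:
        raise ValueError("need at least two SNPs for a pairwise scan")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    n_tests = tests_per_pair * (n_snps * (n_snps - 1)) // 2
    return n_tests, alpha / n_tests


def contribution_rate_from_ss(effect_ss: float, total_ss: float) -> float:
    """Contribution rate c (%) = 100 * effect SS / corrected total SS."""
    if total_ss <= 0:
        raise ValueError("zero phenotypic variance: contribution undefined")
    if effect_ss < 0:
        raise ValueError("negative sum of squares")
    return 100.0 * effect_ss / total_ss


def contribution_rate(effect_ss: float, phenotype: np.ndarray) -> float:
    """Contribution rate (%) of a 1-df effect against a phenotype vector."""
    y = np.asarray(phenotype, dtype=float)
    if y.size < 2:
        raise ValueError("phenotype must have at least two values")
    tss = float(((y - y.mean()) ** 2).sum())
    return contribution_rate_from_ss(effect_ss, tss)


# ---------------------------------------------------------------------------
# scans

SCAN_COLUMNS = ["chrom1", "snp1", "chrom2", "snp2", "effect", "P", "c"]


def _pair_indices(n_snps: int, markers, chrom_pairs=None, max_pairs=None):
    pairs = []
    chroms = markers.chroms if markers is not None else None
    for i in range(n_snps - 1):
        for j in range(i + 1, n_snps):
            if chrom_pairs is not None:
                key = frozenset((chroms[i], chroms[j]))
                if key not in chrom_pairs:
                    continue
            pairs.append((i, j))
            if max_pairs is not None and len(pairs) >= max_pairs:
                return pairs
    return pairs


def run_scan(
    genotypes,
    phenotype: np.ndarray,
    family: np.ndarray | None = None,
    threshold: float | None = None,
    alpha: float = 0.05,
    tests_per_pair: int = 4,
    family_mode: str = "fixed",
    chrom_pairs=None,
    max_pairs: int | None = None,
    log=None,
) -> pd.DataFrame:
    """Exhaustive pairwise epistasis scan.

    Tests every SNP pair (optionally restricted to chromosome pairs or a
    pair-count cap), compares each of the four per-effect P-values to the
    threshold (strict <) and returns one row per significant effect with the
    pair's chromosomes, SNP ids, effect type, P-value and contribution rate
    (%).  Rows are ordered deterministically by (chrom1, pos1, chrom2, pos2,
    effect type).  Pairs skipped for degeneracy are recorded through ``log``
    (a callable) and never abort the scan.

    ``threshold`` defaults to the Bonferroni threshold for the panel.
    """
    gm = genotypes
    if gm.n_snps == 0 or gm.n_individuals == 0:
        raise ValueError("empty genotype set")
    y = np.asarray(phenotype, dtype=float)
    if y.size != gm.n_individuals:
        raise ValueError("phenotype length does not match genotype rows")
    if threshold is None:
        _, threshold = bonferroni(gm.n_snps, alpha=alpha,
                                  tests_per_pair=tests_per_pair)
    if chrom_pairs is not None:
        chrom_pairs = {frozenset(map(str, cp)) for cp in chrom_pairs}

    markers = gm.markers
    snps, chroms, pos = markers.snps, markers.chroms, markers.positions
    records = []
    for i, j in _pair_indices(gm.n_snps, markers, chrom_pairs, max_pairs):
        try:
            design = build_pair_design(
                gm.codes[:, i], gm.codes[:, j], family,
                snp1=snps[i], snp2=snps[j],
            )
            res = test_pair(design, y, family_mode=family_mode)
        except (MonomorphicLocusError, ValueError) as exc:
            if log is not None:
                log(f"pair ({snps[i]}, {snps[j]}) skipped: {exc}")
            continue
        for e in EFFECT_TYPES:
            info = res.per_effect[e]
            if info["testable"] and info["p"] < threshold:
                records.append({
                    "chrom1": chroms[i], "snp1": snps[i],
                    "chrom2": chroms[j], "snp2": snps[j],
                    "pos1": pos[i], "pos2": pos[j],
                    "effect": e, "P": info["p"],
                    "c": res.contribution(e), "n_used": res.n_used,
                })
    df = pd.DataFrame(
        records,
        columns=["chrom1", "snp1", "chrom2", "snp2", "pos1", "pos2",
                 "effect", "P", "c", "n_used"],
    )
    if len(df):
        df = df.sort_values(
            ["chrom1", "pos1", "chrom2", "pos2", "effect"],
            key=lambda s: s.map(_chrom_key) if s.name in ("chrom1", "chrom2") else s,
        ).reset_index(drop=True)
    return df


def _chrom_key(label):
    from .containers import chrom_sort_key
    return chrom_sort_key(label)


def single_locus_scan(
    genotypes,
    phenotype: np.ndarray,
    family: np.ndarray | None = None,
    family_mode: str = "fixed",
    log=None,
) -> pd.DataFrame:
    """Per-SNP association scan under the one-locus version of the model.

    Fits ``y = mu + family + a + d + e`` per SNP, tests the joint genotypic
    effect (a, d) by a model-comparison F-test and reports the genotypic
    sum of squares as a contribution rate (%).
    """
    gm = genotypes
    y_all = np.asarray(phenotype, dtype=float)
    if y_all.size != gm.n_individuals:
        raise ValueError("phenotype length does not match genotype rows")
    if family is None:
        family = np.zeros(gm.n_individuals, dtype=int)
    family = np.asarray(family)

    records = []
    for k in range(gm.n_snps):
        g = gm.codes[:, k]
        mask = ~np.isnan(g)
        try:
            a, d = locus_contrasts(g[mask])
        except MonomorphicLocusError:
            if log is not None:
                log(f"SNP {gm.markers.snps[k]} skipped: monomorphic")
            continue
        y = y_all[mask]
        fam = family[mask]
        if family_mode == "random":
            design = PairDesign(
                snp1=gm.markers.snps[k], snp2=gm.markers.snps[k],
                mask=mask, family=fam, g1=g[mask], g2=g[mask],
                a1=a, d1=d, a2=a, d2=d,
            )
            mdl = TwoLocusModel(y, design, family_mode="random")
            y, base = mdl._adjusted_response_and_base()
        else:
            base = _family_dummies(fam)
        cols = [a] if d is None else [a, d]
        X_full = np.column_stack([base] + cols)
        rss_full, rank_full = _rss(X_full, y)
        rss_base, _ = _rss(base, y)
        df_num = len(cols)
        df_resid = y.size - rank_full
        if df_resid <= 0:
            continue
        ss = max(rss_base - rss_full, 0.0)
        mse = rss_full / df_resid
        F = (ss / df_num) / mse if mse > 0 else np.inf
        p = float(stats.f.sf(F, df_num, df_resid)) if np.isfinite(F) else 0.0
        tss = float(((y - y.mean()) ** 2).sum())
        records.append({
            "chrom": gm.markers.chroms[k], "snp": gm.markers.snps[k],
            "pos": gm.markers.positions[k], "n_used": int(mask.sum()),
            "F": F, "df": df_num, "P": p,
            "c": contribution_rate_from_ss(ss, tss) if tss > 0 else np.nan,
        })
    return pd.DataFrame(
        records, columns=["chrom", "snp", "pos", "n_used", "F", "df", "P", "c"]
    )
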