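"""Two-factorial ANOVA, variance components, broad-sense heritability,
trait summaries and the z-score correlation matrix.

The experimental design is fully crossed and balanced: genotype (G) x
phosphorus environment (E in {HP, LP}) x replication (R), one plant per
cell.  Because the second replication was grown months after the first
it is treated like a "year" effect rather than pooled into an error
term, so the model has no residual stratum: the three-way interaction
G x E x R is the bottom stratum and serves as the error term for the
F-tests of E, G and G x E.

Variance components are method-of-moments solutions of the expected
mean squares of the all-random balanced model:

    E[MS_GER] = s2_ger
    E[MS_GE]  = s2_ger + nR * s2_ge
    E[MS_GR]  = s2_ger + nE * s2_gr
    E[MS_G]   = s2_ger + nR * s2_ge + nE * s2_gr + nE * nR * s2_g

Broad-sense heritability follows the two-environment, two-replication
formula h2 = s2_g / (s2_g + s2_ge/2 + s2_gr/2 + s2_ger/4).  With no
residual stratum the components omit within-cell error, so these
heritabilities are comparative, not absolute — they may overestimate
the repeatable fraction and should only be compared within a study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaTable",
    "VarComponents",
    "anova_ge",
    "anova_cube",
    "variance_components",
    "heritability",
    "heritability_general",
    "trait_summary",
    "correlation_matrix",
    "CorrMatrix",
    "significance_stars",
]

EFFECTS = ("E", "G", "R", "G:E", "G:R", "E:R", "G:E:R")


@dataclass
class AnovaTable:
    """Balanced three-way ANOVA decomposition for one trait."""

    table: pd.DataFrame          # index EFFECTS; columns df, ss, ms, F, p
    n_G: int
    n_E: int
    n_R: int
    trait: str = ""

    def __getitem__(self, effect: str) -> pd.Series:
        return self.table.loc[effect]


@dataclass
class VarComponents:
    """Method-of-moments variance components (trait units squared)."""

    sigma_g: float
    sigma_ge: float
    sigma_gr: float
    sigma_ger: float
    truncated: tuple[str, ...] = ()


def _cube_from_table(table: pd.DataFrame, trait: str | None) -> tuple[np.ndarray, dict]:
    """Pivot a long table into a (G, E, R) cube, checking balance."""
    df = table
    if trait is not None:
        df = df[df["trait"] == trait]
    elif "trait" in df.columns:
        names = df["trait"].unique()
        if len(names) > 1:
            raise ValueError(f"table holds several traits {list(names)}; pass trait=")
    if df.empty:
        raise ValueError(f"no observations for trait {trait!r}")

    genotypes = sorted(df["genotype"].unique())
    envs = sorted(df["environment"].unique())
    reps = sorted(df["replication"].unique())
    pivot = df.pivot_table(index="genotype", columns=["environment", "replication"],
                           values="value", aggfunc="count")
    expected = pd.MultiIndex.from_product([envs, reps])
    missing = []
    counts = pivot.reindex(index=genotypes, columns=expected)
    bad = counts.isna() | (counts != 1)
    if bad.to_numpy().any():
        for g in genotypes:
            for e, r in expected:
                if bad.loc[g, (e, r)]:
                    missing.append((g, e, r))
        raise ValueError(
            f"unbalanced design: {len(missing)} cells missing or duplicated, "
            f"first few: {missing[:5]}"
        )
    vals = df.pivot_table(index="genotype", columns=["environment", "replication"],
                          values="value")
    vals = vals.reindex(index=genotypes, columns=expected)
    cube = vals.to_numpy().reshape(len(genotypes), len(envs), len(reps))
    return cube, {"genotypes": genotypes, "environments": envs, "replications": reps}


def anova_cube(y: np.ndarray) -> pd.DataFrame:
    """Balanced three-way ANOVA on a (G, E, R) data cube.

    Closed-form sums of squares from marginal means; F statistics for
    E, G and G:E use MS(G:E:R) as denominator.
    """
    y = np.asarray(y, dtype=float)
    n_g, n_e, n_r = y.shape
    grand = y.mean()
    mg = y.mean(axis=(1, 2))
    me = y.mean(axis=(0, 2))
    mr = y.mean(axis=(0, 1))
    mge = y.mean(axis=2)
    mgr = y.mean(axis=1)
    mer = y.mean(axis=0)

    ss = {
        "G": n_e * n_r * ((mg - grand) ** 2).sum(),
        "E": n_g * n_r * ((me - grand) ** 2).sum(),
        "R": n_g * n_e * ((mr - grand) ** 2).sum(),
        "G:E": n_r * ((mge - mg[:, None] - me[None, :] + grand) ** 2).sum(),
        "G:R": n_e * ((mgr - mg[:, None] - mr[None, :] + grand) ** 2).sum(),
        "E:R": n_g * ((mer - me[:, None] - mr[None, :] + grand) ** 2).sum(),
    }
    resid = (y - mge[:, :, None] - mgr[:, None, :] - mer[None, :, :]
             + mg[:, None, None] + me[None, :, None] + mr[None, None, :] - grand)
    ss["G:E:R"] = (resid ** 2).sum()

    dof = {
        "G": n_g - 1, "E": n_e - 1, "R": n_r - 1,
        "G:E": (n_g - 1) * (n_e - 1), "G:R": (n_g - 1) * (n_r - 1),
        "E:R": (n_e - 1) * (n_r - 1),
        "G:E:R": (n_g - 1) * (n_e - 1) * (n_r - 1),
    }
    rows = []
    ms_err = ss["G:E:R"] / dof["G:E:R"] if dof["G:E:R"] > 0 else math.nan
    for eff in EFFECTS:
        msq = ss[eff] / dof[eff] if dof[eff] > 0 else math.nan
        if eff in ("E", "G", "G:E") and dof["G:E:R"] > 0 and ms_err > 0:
            F = msq / ms_err
            p = float(sps.f.sf(F, dof[eff], dof["G:E:R"]))
        else:
            F = p = math.nan
        rows.append((eff, dof[eff], ss[eff], msq, F, p))
    return pd.DataFrame(rows, columns=["effect", "df", "ss", "ms", "F", "p"]
                        ).set_index("effect")


def anova_ge(table: pd.DataFrame, trait: str | None = None) -> AnovaTable:
    """Two-factorial (G x E, with replication as a crossed third factor)
    ANOVA for one trait of a balanced long-format observation table.

    The table needs columns genotype, environment, replication, value
    (and trait, if it holds several traits).  Unbalanced designs raise
    an error listing the missing cells.
    """
    cube, levels = _cube_from_table(table, trait)
    if cube.shape[1] < 2 or cube.shape[2] < 2:
        raise ValueError(
            f"need >=2 environments and >=2 replications, got "
            f"{cube.shape[1]} x {cube.shape[2]}"
        )
    df = anova_cube(cube)
    return AnovaTable(table=df, n_G=cube.shape[0], n_E=cube.shape[1],
                      n_R=cube.shape[2], trait=trait or "")


def variance_components(anova: AnovaTable) -> VarComponents:
    """Method-of-moments variance components from a balanced ANOVA.

    Negative solutions of the expected-mean-square equations are
    truncated to zero and flagged.
    """
    t = anova.table
    for eff in ("G", "G:E", "G:R", "G:E:R"):
        if t.loc[eff, "df"] <= 0:
            raise ValueError(f"zero degrees of freedom for {eff}")
    ms_g = t.loc["G", "ms"]
    ms_ge = t.loc["G:E", "ms"]
    ms_gr = t.loc["G:R", "ms"]
    ms_ger = t.loc["G:E:R", "ms"]
    n_e, n_r = anova.n_E, anova.n_R

    raw = {
        "sigma_ger": ms_ger,
        "sigma_ge": (ms_ge - ms_ger) / n_r,
        "sigma_gr": (ms_gr - ms_ger) / n_e,
        "sigma_g": (ms_g - ms_ge - ms_gr + ms_ger) / (n_e * n_r),
    }
    truncated = tuple(k for k, v in raw.items() if v < 0)
    vals = {k: max(0.0, float(v)) for k, v in raw.items()}
    return VarComponents(truncated=truncated, **vals)


def heritability(vc: VarComponents) -> float:
    """Broad-sense heritability h2 = s2_g / (s2_g + s2_ge/2 + s2_gr/2 +
    s2_ger/4), divisors fixed for the two-environment two-replication
    design.  All-zero components yield NaN (undefined)."""
    denom = vc.sigma_g + vc.sigma_ge / 2.0 + vc.sigma_gr / 2.0 + vc.sigma_ger / 4.0
    if denom <= 0:
        return math.nan
    return vc.sigma_g / denom


def heritability_general(vc: VarComponents, n_E: int, n_R: int) -> float:
    """Design-aware variant: interaction variances divided by the number
    of environments / replications they average over."""
    denom = (vc.sigma_g + vc.sigma_ge / n_E + vc.sigma_gr / n_R
             + vc.sigma_ger / (n_E * n_R))
    if denom <= 0:
        return math.nan
    return vc.sigma_g / denom


def trait_summary(table: pd.DataFrame,
                  environments: tuple[str, ...] = ("HP", "LP")) -> pd.DataFrame:
    """Per-trait, per-environment mean and sample s.d. (over genotypes
    and replications).  Environments absent from the table are reported
    as NaN (missing) columns."""
    if table.empty:
        raise ValueError("empty observation table")
    envs = sorted(set(environments) | set(table["environment"].unique()))
    grouped = table.groupby(["trait", "environment"])["value"]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1)).reset_index()
    wide = out.pivot(index="trait", columns="environment")
    wide = wide.reindex(columns=pd.MultiIndex.from_product([["mean", "sd"], envs]))
    wide.columns = [f"{env}_{stat}" for stat, env in wide.columns]
    return wide.sort_index(axis=1)


def significance_stars(p: float) -> str:
    """Significance coding: *, **, *** at 0.05 / 0.01 / 0.001, NS above."""
    if not np.isfinite(p):
        return "NA"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


@dataclass
class CorrMatrix:
    """Pairwise Pearson correlations of trait-environment columns."""

    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: int
    dropped: tuple[str, ...] = ()

    def to_long(self) -> pd.DataFrame:
        rows = []
        cols = list(self.r.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                rows.append((a, b, self.r.loc[a, b], self.p.loc[a, b],
                             self.stars.loc[a, b]))
        return pd.DataFrame(rows, columns=["trait_a", "trait_b", "r", "p", "stars"])


def correlation_matrix(table: pd.DataFrame) -> CorrMatrix:
    """Pearson correlations among z-score standardized genotype trait
    means, HP and LP blocks jointly.

    Genotype means (over replications) are formed per trait and
    environment; each resulting column is standardized and correlated
    with every other.  Constant columns are kept but flagged NA.
    """
    means = (table.groupby(["genotype", "environment", "trait"])["value"]
             .mean().unstack(["trait", "environment"]))
    means.columns = [f"{t}_{e}" for t, e in means.columns]
    means = means.sort_index(axis=1)
    n = means.shape[0]
    if n < 3:
        raise ValueError("need at least 3 genotypes for correlations")

    cols = list(means.columns)
    constant = tuple(c for c in cols if means[c].std(ddof=1) == 0
                     or means[c].isna().any())
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            if cols[i] in constant or cols[j] in constant:
                continue
            if i == j:
                r[i, j] = 1.0
                p[i, j] = 0.0
                continue
            res = sps.pearsonr(means[cols[i]], means[cols[j]])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    stars = p_df.map(significance_stars)
    for c in constant:
        stars.loc[c, :] = "NA"
        stars.loc[:, c] = "NA"
    return CorrMatrix(r=r_df, p=p_df, stars=stars, n=n, dropped=constant)
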