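"""Sexual-dimorphism statistics for standardized muscle-size ratios.

For each species the ratios F_A/F_B are grouped by (sex, segment); the
battery compares female-A5 vs male-A5 (the dimorphism contrast) and male-A4
vs male-A5 (the segment-specificity control).  When every group is
consistent with a Gaussian (raw or log scale) the omnibus is the
Brown-Forsythe and Welch ANOVA with Games-Howell pairwise comparisons;
otherwise a tie-corrected Kruskal-Wallis omnibus with Dunn z tests,
Bonferroni-adjusted over the two comparisons of interest, is used.

A species is called sexually dimorphic ("+") iff the male-A5 mean ratio
exceeds the female-A5 mean AND the adjusted pairwise p is strictly below
0.001; an adjusted p equal to 0.001 yields "−".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "DimorphismCall",
    "summarize_group",
    "gaussian_fit_check",
    "welch_anova",
    "brown_forsythe_anova",
    "games_howell",
    "kruskal_wallis_dunn",
    "call_dimorphism",
    "confidence_band",
    "stars",
    "analyze_species",
]

CALL_ALPHA = 0.001
DEFAULT_SEED = 20210727


def stars(p: float) -> str:
    """Significance code: * p<0.05, ** p<0.01, *** p<0.001, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GroupSummary:
    """Per-(species, sex, segment) summary of F_A/F_B ratios.

    ``n`` counts hemisegments (the statistical unit: left/right sides are
    independent data points), ``N`` counts individual flies.
    """

    species: str
    sex: str
    segment: str
    n: int
    N: int
    mean: float
    SEM: float
    SD: float
    min: float
    max: float

    def __post_init__(self) -> None:
        # tolerance absorbs float rounding when the mean is accumulated
        if not (self.min - 1e-9 <= self.mean <= self.max + 1e-9):
            raise ValueError(
                f"{self.species} {self.sex}-{self.segment}: "
                "min <= mean <= max violated"
            )

    @property
    def reconstructed_sd(self) -> float:
        """SD recovered from a published SEM as SEM * sqrt(n)."""
        return self.SEM * math.sqrt(self.n)


@dataclass(frozen=True)
class ComparisonResult:
    test_family: str  # "welch_anova" | "kruskal_wallis"
    omnibus_stat: float
    omnibus_p: float
    pair: tuple[str, str]
    statistic: float
    adjusted_p: float

    @property
    def significant_at(self) -> str:
        return stars(self.adjusted_p)


@dataclass(frozen=True)
class DimorphismCall:
    species: str
    call: str  # "+" | "−"
    basis: ComparisonResult | None
    male_mean: float
    female_mean: float


def summarize_group(
    ratios: Sequence[float],
    N: int,
    *,
    species: str = "",
    sex: str = "",
    segment: str = "",
) -> GroupSummary:
    x = np.asarray(ratios, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty group")
    n = int(x.size)
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    return GroupSummary(
        species=species,
        sex=sex,
        segment=segment,
        n=n,
        N=int(N),
        mean=float(x.mean()),
        SEM=sd / math.sqrt(n),
        SD=sd,
        min=float(x.min()),
        max=float(x.max()),
    )


def gaussian_fit_check(
    groups: Iterable[Sequence[float]],
    allow_log: bool = True,
    alpha: float = 0.05,
    min_n: int = 8,
) -> dict:
    """Decide whether all groups are adequately Gaussian on a common scale.

    Mechanized surrogate for a visual Gaussian histogram fit: D'Agostino's
    omnibus skewness/kurtosis normality test per group at ``alpha``, first on
    raw values, then (if allowed and all values positive) on logs.  Groups
    smaller than ``min_n`` make normality not assessable and the caller
    should fall back to the nonparametric branch.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < min_n for g in gs):
        return {"gaussian_ok": False, "use_log": False, "assessable": False}

    def _all_pass(samples: list[np.ndarray]) -> bool:
        return all(stats.normaltest(s).pvalue >= alpha for s in samples)

    if _all_pass(gs):
        return {"gaussian_ok": True, "use_log": False, "assessable": True}
    if allow_log and all((g > 0).all() for g in gs) and _all_pass(
        [np.log(g) for g in gs]
    ):
        return {"gaussian_ok": True, "use_log": True, "assessable": True}
    return {"gaussian_ok": False, "use_log": False, "assessable": True}


def _group_moments(groups: Sequence[np.ndarray]):
    n = np.array([g.size for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    return n, m, v


def welch_anova(groups: Sequence[Sequence[float]]) -> dict:
    """Welch's heteroscedastic one-way ANOVA (F* with Welch-Satterthwaite df).

    Returns statistic, df1, df2 and p.  All-equal constant groups return the
    p = 1 convention.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("each group needs n >= 2")
    n, m, v = _group_moments(gs)
    if np.all(v == 0):
        if np.all(m == m[0]):
            return {"statistic": 0.0, "df1": len(gs) - 1.0, "df2": float("inf"), "p": 1.0}
        return {"statistic": float("inf"), "df1": len(gs) - 1.0, "df2": float("inf"), "p": 0.0}
    k = len(gs)
    w = n / v
    mw = (w * m).sum() / w.sum()
    a = (w * (m - mw) ** 2).sum() / (k - 1)
    lam = ((1 - w / w.sum()) ** 2 / (n - 1)).sum()
    b = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    f = a / b
    df1 = k - 1.0
    df2 = (k**2 - 1) / (3 * lam)
    return {"statistic": float(f), "df1": df1, "df2": float(df2),
            "p": float(stats.f.sf(f, df1, df2))}


def brown_forsythe_anova(groups: Sequence[Sequence[float]]) -> dict:
    """Brown-Forsythe F* test for equality of means under heteroscedasticity.

    F* = SS_between / sum_i (1 - n_i/N) s_i^2 with Satterthwaite denominator
    df.  (This is the means test, not the Levene-type spread test.)
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    n, m, v = _group_moments(gs)
    N = n.sum()
    grand = np.concatenate(gs).mean()
    num = (n * (m - grand) ** 2).sum()
    ci = (1 - n / N) * v
    denom = ci.sum()
    if denom == 0:
        return {"statistic": 0.0 if num == 0 else float("inf"),
                "df1": len(gs) - 1.0, "df2": float("inf"),
                "p": 1.0 if num == 0 else 0.0}
    f = num / denom
    df1 = len(gs) - 1.0
    df2 = denom**2 / ((ci**2 / (n - 1)).sum())
    return {"statistic": float(f), "df1": df1, "df2": float(df2),
            "p": float(stats.f.sf(f, df1, df2))}


def _welch_t_df(gi: np.ndarray, gj: np.ndarray) -> tuple[float, float, float]:
    ni, nj = gi.size, gj.size
    vi, vj = gi.var(ddof=1), gj.var(ddof=1)
    se2 = vi / ni + vj / nj
    if se2 == 0:
        t = 0.0 if gi.mean() == gj.mean() else math.inf
        return t, math.inf, 0.0
    t = (gi.mean() - gj.mean()) / math.sqrt(se2)
    df = se2**2 / ((vi / ni) ** 2 / (ni - 1) + (vj / nj) ** 2 / (nj - 1))
    return float(t), float(df), float(se2)


def games_howell(
    groups: dict[str, Sequence[float]],
    pairs_of_interest: Sequence[tuple[str, str]] | None = None,
    omnibus: dict | None = None,
) -> list[ComparisonResult]:
    """Games-Howell pairwise comparisons.

    Per pair: Welch t statistic and Welch-Satterthwaite df; the adjusted p
    comes from the studentized-range distribution with k = total number of
    groups, q = |t| * sqrt(2).
    """
    names = list(groups)
    gs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    k = len(names)
    if k < 2:
        raise ValueError("need at least 2 groups")
    pairs = list(pairs_of_interest) if pairs_of_interest else list(
        combinations(names, 2)
    )
    if omnibus is None:
        omnibus = welch_anova([gs[n] for n in names])
    out = []
    for a, b in pairs:
        t, df, se2 = _welch_t_df(gs[a], gs[b])
        if not math.isfinite(t):
            p = 0.0
        elif se2 == 0:
            p = 1.0
        else:
            p = float(stats.studentized_range.sf(abs(t) * math.sqrt(2), k, df))
        out.append(
            ComparisonResult(
                test_family="welch_anova",
                omnibus_stat=omnibus["statistic"],
                omnibus_p=omnibus["p"],
                pair=(a, b),
                statistic=t,
                adjusted_p=min(1.0, p),
            )
        )
    return out


def kruskal_wallis_dunn(
    groups: dict[str, Sequence[float]],
    pairs_of_interest: Sequence[tuple[str, str]] | None = None,
) -> list[ComparisonResult]:
    """Tie-corrected Kruskal-Wallis omnibus plus Dunn pairwise z tests.

    Dunn z uses the pooled-rank variance with the tie correction; adjusted p
    is the two-sided normal p multiplied by the number of comparisons of
    interest (Bonferroni restricted to ``pairs_of_interest``), clipped at 1.
    All-identical observations yield H = 0, p = 1.
    """
    names = list(groups)
    gs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate([gs[n] for n in names])
    if np.all(pooled == pooled[0]):
        h, hp = 0.0, 1.0
    else:
        h, hp = stats.kruskal(*[gs[n] for n in names])
    pairs = list(pairs_of_interest) if pairs_of_interest else list(
        combinations(names, 2)
    )
    # pooled ranks for Dunn
    ranks = stats.rankdata(pooled)
    idx = np.cumsum([0] + [gs[n].size for n in names])
    rbar = {
        n: ranks[idx[i]: idx[i + 1]].mean() for i, n in enumerate(names)
    }
    N = pooled.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (N - 1)) if N > 1 else 0.0
    m = len(pairs)
    out = []
    for a, b in pairs:
        var = (N * (N + 1) / 12 - tie_term) * (1 / gs[a].size + 1 / gs[b].size)
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = (rbar[a] - rbar[b]) / math.sqrt(var)
            p = 2 * stats.norm.sf(abs(z))
        out.append(
            ComparisonResult(
                test_family="kruskal_wallis",
                omnibus_stat=float(h),
                omnibus_p=float(hp),
                pair=(a, b),
                statistic=float(z),
                adjusted_p=min(1.0, m * p),
            )
        )
    return out


def call_dimorphism(
    female_A5: GroupSummary,
    male_A5: GroupSummary,
    male_A4: GroupSummary | None = None,
    adjusted_p_f5_m5: float = 1.0,
    basis: ComparisonResult | None = None,
    alpha: float = CALL_ALPHA,
) -> DimorphismCall:
    """Dimorphism verdict: "+" iff male A5 mean > female A5 mean and the
    adjusted female-A5 vs male-A5 p is strictly < ``alpha`` (0.001).

    The boundary is strict: adjusted p exactly equal to 0.001 gives "−".
    The male-A4 comparison is contextual only and never enters the call.
    """
    plus = male_A5.mean > female_A5.mean and adjusted_p_f5_m5 < alpha
    return DimorphismCall(
        species=male_A5.species or female_A5.species,
        call="+" if plus else "−",
        basis=basis,
        male_mean=male_A5.mean,
        female_mean=female_A5.mean,
    )


def confidence_band(ratios: Sequence[float]) -> tuple[float, float]:
    """Mean ± 3·SD band (the conventional 99% envelope for these ratios)."""
    x = np.asarray(ratios, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2")
    m, sd = x.mean(), x.std(ddof=1)
    return float(m - 3 * sd), float(m + 3 * sd)


PAIR_F5_M5 = ("female_A5", "male_A5")
PAIR_M4_M5 = ("male_A4", "male_A5")


def analyze_species(
    female_A5: Sequence[float],
    male_A4: Sequence[float],
    male_A5: Sequence[float],
    *,
    species: str = "",
    N: dict[str, int] | None = None,
    alpha_call: float = CALL_ALPHA,
) -> dict:
    """Run the full per-species battery on raw hemisegment ratios.

    Chooses the parametric (Brown-Forsythe/Welch ANOVA + Games-Howell) or
    nonparametric (Kruskal-Wallis + Dunn) branch from the Gaussian check and
    returns summaries, both comparisons of interest, and the dimorphism call.
    """
    N = N or {}
    groups = {
        "female_A5": np.asarray(female_A5, float),
        "male_A4": np.asarray(male_A4, float),
        "male_A5": np.asarray(male_A5, float),
    }
    summaries = {
        key: summarize_group(
            vals,
            N.get(key, 0),
            species=species,
            sex=key.split("_")[0],
            segment=key.split("_")[1],
        )
        for key, vals in groups.items()
    }
    fit = gaussian_fit_check(groups.values())
    pairs = [PAIR_F5_M5, PAIR_M4_M5]
    if fit["gaussian_ok"]:
        work = (
            {k: np.log(v) for k, v in groups.items()} if fit["use_log"] else groups
        )
        comps = games_howell(work, pairs)
        test_family = "welch_anova"
        bf = brown_forsythe_anova(list(work.values()))
    else:
        comps = kruskal_wallis_dunn(groups, pairs)
        test_family = "kruskal_wallis"
        bf = None
    by_pair = {c.pair: c for c in comps}
    basis = by_pair[PAIR_F5_M5]
    call = call_dimorphism(
        summaries["female_A5"],
        summaries["male_A5"],
        summaries["male_A4"],
        adjusted_p_f5_m5=basis.adjusted_p,
        basis=basis,
        alpha=alpha_call,
    )
    return {
        "species": species,
        "summaries": summaries,
        "gaussian": fit,
        "test_family": test_family,
        "comparisons": by_pair,
        "brown_forsythe": bf,
        "call": call,
    }


def calls_table(results: Iterable[dict]) -> pd.DataFrame:
    """Tabulate analyze_species results as the calls CSV schema."""
    rows = []
    for r in results:
        rows.append(
            {
                "species": r["species"],
                "call": r["call"].call,
                "test_family": r["test_family"],
                "adjusted_p_f5_m5": r["comparisons"][PAIR_F5_M5].adjusted_p,
                "adjusted_p_m4_m5": r["comparisons"][PAIR_M4_M5].adjusted_p,
                "male_mean": r["call"].male_mean,
                "female_mean": r["call"].female_mean,
            }
        )
    return pd.DataFrame(rows)
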