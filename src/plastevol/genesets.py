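"""Parallel gene-set calling and the genetic-assimilation accounting.

Two gene sets capture parallelism across the replicate mine/coast pairs:

CEC (constitutive evolutionary change)
    differentially expressed between tolerant and sensitive populations in
    the *control* treatment in both pairs, with the same direction.
DP (derived plasticity)
    zinc-responsive in both tolerant populations in the same direction, and
    differentially expressed between ecotypes (control or zinc) in both
    pairs.

Canalization and genetic assimilation are then read off the CEC set: a CEC
gene that is no longer zinc-responsive in either tolerant population but had
substantial ancestral plasticity has been canalized; it counts as
assimilated when that ancestral plasticity pointed at (or beyond) the new
optimum — no substantial residual EC, or a reinforcement/overshooting
category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cond_odds_ratio

from .de import DEResult, bh_adjust
from .io import PlastevolError
from .plasticity import OVERSHOOTING, REINFORCEMENT, UNCLASSIFIED

__all__ = [
    "call_cec",
    "call_dp",
    "fisher_overlap",
    "binomial_proportion_test",
    "fc_similarity",
    "compare_similarity",
    "call_assimilation",
    "assimilation_accounting",
    "OverlapStat",
    "SimilarityStat",
]


def _check_universe(*tables: DEResult) -> pd.Index:
    universe = tables[0].gene_ids
    for t in tables[1:]:
        if not universe.equals(t.gene_ids):
            raise PlastevolError(
                f"gene universes differ between contrasts "
                f"{tables[0].contrast!r} and {t.contrast!r}"
            )
    return universe


def _sig_same_direction(a: DEResult, b: DEResult) -> pd.Series:
    both = a.significant & b.significant
    same = a.direction == b.direction
    return (both & same & a.direction.notna() & b.direction.notna()).astype(bool)


def call_cec(de_pair1_control: DEResult, de_pair2_control: DEResult) -> pd.Series:
    """Boolean CEC membership: ecotype-DE in control in both pairs, same direction."""
    _check_universe(de_pair1_control, de_pair2_control)
    out = _sig_same_direction(de_pair1_control, de_pair2_control)
    out.name = "is_cec"
    return out


def call_dp(
    de_cvz_t1: DEResult,
    de_cvz_t2: DEResult,
    eco_pair1_control: DEResult,
    eco_pair1_zinc: DEResult,
    eco_pair2_control: DEResult,
    eco_pair2_zinc: DEResult,
) -> pd.Series:
    """Boolean DP membership.

    Zinc-responsive in both tolerant populations with the same direction,
    and ecotype-DE in the control or zinc treatment (or both) in *each*
    pair.  Direction consistency is not required of the ecotype component.
    """
    _check_universe(
        de_cvz_t1, de_cvz_t2, eco_pair1_control, eco_pair1_zinc,
        eco_pair2_control, eco_pair2_zinc,
    )
    responsive = _sig_same_direction(de_cvz_t1, de_cvz_t2)
    eco1 = eco_pair1_control.significant | eco_pair1_zinc.significant
    eco2 = eco_pair2_control.significant | eco_pair2_zinc.significant
    out = (responsive & eco1 & eco2).astype(bool)
    out.name = "is_dp"
    return out


@dataclass
class OverlapStat:
    """2x2 overlap of two gene sets within a common universe."""

    a: int  # shared
    b: int  # set1 only
    c: int  # set2 only
    d: int  # neither
    odds_ratio: float  # conditional MLE
    sample_odds_ratio: float
    p_one_sided: float

    def asdict(self) -> dict:
        return {
            "a_shared": self.a,
            "b_set1_only": self.b,
            "c_set2_only": self.c,
            "d_neither": self.d,
            "odds_ratio": self.odds_ratio,
            "sample_odds_ratio": self.sample_odds_ratio,
            "p_one_sided": self.p_one_sided,
        }


def fisher_overlap(n_shared: int, n_set1: int, n_set2: int, universe: int) -> OverlapStat:
    """One-sided (enrichment) Fisher's exact test for a gene-set overlap.

    The p-value is the hypergeometric upper tail P(X >= n_shared); the odds
    ratio is the conditional maximum-likelihood estimate, with the sample
    odds ratio a*d/(b*c) reported alongside.
    """
    a = n_shared
    b = n_set1 - a
    c = n_set2 - a
    d = universe - a - b - c
    if min(a, b, c, d) < 0:
        raise PlastevolError(
            f"inconsistent overlap counts: a={a}, b={b}, c={c}, d={d}"
        )
    table = np.array([[a, b], [c, d]])
    res = _cond_odds_ratio(table, kind="conditional")
    with np.errstate(divide="ignore", invalid="ignore"):
        sample_or = (a * d) / (b * c) if b * c > 0 else np.inf
    # upper tail of Hypergeometric(N=universe, K=n_set1, n=n_set2) at a
    p = float(stats.hypergeom.sf(a - 1, universe, n_set1, n_set2))
    return OverlapStat(
        a=a,
        b=b,
        c=c,
        d=d,
        odds_ratio=float(res.statistic),
        sample_odds_ratio=float(sample_or),
        p_one_sided=p,
    )


def binomial_proportion_test(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial test of k/n against a reference proportion.

    Two-sidedness by the minimum-likelihood rule: sum of the probabilities of
    all outcomes no more likely than the observed one.
    """
    if not 0 < p0 < 1:
        raise PlastevolError("reference proportion must lie strictly in (0, 1)")
    if not 0 <= k <= n:
        raise PlastevolError("need 0 <= k <= n")
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)


@dataclass
class SimilarityStat:
    """|FC| values (absolute shrunken log2 fold change) for a gene set."""

    label: str
    comparison: str
    values: pd.Series = field(repr=False)
    median: float = 0.0

    def __post_init__(self) -> None:
        self.median = float(self.values.median())


def fc_similarity(de: DEResult, genes: pd.Index | list[str], label: str = "") -> SimilarityStat:
    """Per-gene |shrunken FC| over a gene set, summarized by the median.

    The median (not the mean) summarizes |FC| because its distribution is
    strongly right-skewed.
    """
    genes = pd.Index(genes)
    if len(genes) == 0:
        raise PlastevolError("empty gene set")
    missing = genes.difference(de.gene_ids)
    if len(missing):
        raise PlastevolError(f"genes absent from DE table: {list(missing[:5])}")
    vals = de.lfc_shrunk.loc[genes].abs()
    vals.name = "abs_fc"
    return SimilarityStat(label=label or de.contrast, comparison=de.contrast, values=vals)


def compare_similarity(
    a: SimilarityStat, b: SimilarityStat, paired: bool = True
) -> dict:
    """Two-sided Wilcoxon signed-rank (paired) or rank-sum comparison of |FC|.

    Returns statistic and p; BH across a family of such comparisons is the
    caller's job (see ``bh_adjust``).
    """
    if paired:
        x = a.values
        y = b.values.reindex(x.index)
        if y.isna().any():
            raise PlastevolError("paired comparison needs identical gene sets")
        diffs = x.to_numpy() - y.to_numpy()
        if np.all(diffs == 0):
            return {"statistic": 0.0, "pvalue": 1.0}
        res = stats.wilcoxon(x.to_numpy(), y.to_numpy(), alternative="two-sided")
    else:
        res = stats.mannwhitneyu(a.values, b.values, alternative="two-sided")
    return {"statistic": float(res.statistic), "pvalue": float(res.pvalue)}


def adjust_family(pvalues: dict[str, float]) -> dict[str, float]:
    """BH-adjust a named family of comparison p-values."""
    keys = list(pvalues)
    adj = bh_adjust(pd.Series([pvalues[k] for k in keys], index=keys))
    return {k: float(adj[k]) for k in keys}


# ---------------------------------------------------------------------------
# genetic assimilation
# ---------------------------------------------------------------------------

def assimilation_accounting(
    n_cec: int, n_canalized: int, n_no_ec: int, n_beneficial: int, universe: int | None = None
) -> dict:
    """Summary arithmetic of the assimilation call.

    Assimilated = canalized genes without substantial residual EC plus
    canalized genes whose (substantial) ancestral plasticity pointed toward
    the new optimum (reinforcement or overshooting).
    """
    if n_no_ec + n_beneficial > n_canalized:
        raise PlastevolError("assimilated subcounts exceed the canalized count")
    if n_canalized > n_cec:
        raise PlastevolError("canalized genes must be a subset of CEC genes")
    n_assim = n_no_ec + n_beneficial
    out = {
        "n_cec": int(n_cec),
        "n_canalized": int(n_canalized),
        "n_no_EC": int(n_no_ec),
        "n_beneficial": int(n_beneficial),
        "n_assimilated": int(n_assim),
        "pct_of_cec": 100.0 * n_assim / n_cec if n_cec else 0.0,
    }
    if universe:
        out["pct_of_universe"] = 100.0 * n_assim / universe
    return out


def call_assimilation(
    gene_sets: pd.DataFrame,
    de_cvz_t1: DEResult,
    de_cvz_t2: DEResult,
    profiles: pd.DataFrame,
    calls: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Flag canalized and assimilated genes; return (table, summary).

    canalized   = CEC and not zinc-responsive in either tolerant population
                  and substantial ancestral PC
    assimilated = canalized and (no substantial EC, or category in
                  {reinforcement, overshooting})

    The chain assimilated <= canalized <= CEC holds by construction.
    """
    if "is_cec" not in gene_sets.columns:
        raise PlastevolError("gene_sets table must carry an is_cec column")
    idx = gene_sets.index
    for name, other in (
        ("profiles", profiles),
        ("calls", calls),
    ):
        if not idx.isin(other.index).all():
            raise PlastevolError(f"gene(s) missing from {name} table")
    cec = gene_sets["is_cec"].astype(bool)

    def _flag(series: pd.Series) -> pd.Series:
        return pd.Series(idx.isin(series.index[series.astype(bool)]), index=idx)

    responsive = _flag(de_cvz_t1.significant) | _flag(de_cvz_t2.significant)
    sub_pc = _flag(profiles["substantial_PC"])
    sub_ec = _flag(profiles["substantial_EC"])
    category = calls["category"].reindex(idx).fillna(UNCLASSIFIED)

    canalized = cec & ~responsive & sub_pc
    no_ec = canalized & ~sub_ec
    beneficial = canalized & sub_ec & category.isin([REINFORCEMENT, OVERSHOOTING])
    assimilated = no_ec | beneficial

    out = gene_sets.copy()
    out["canalized"] = canalized
    out["assimilated"] = assimilated
    summary = assimilation_accounting(
        n_cec=int(cec.sum()),
        n_canalized=int(canalized.sum()),
        n_no_ec=int(no_ec.sum()),
        n_beneficial=int(beneficial.sum()),
        universe=len(idx),
    )
    return out, summary


def build_gene_set_table(
    de: dict[str, DEResult],
) -> pd.DataFrame:
    """Per-gene membership flags from the named DE tables.

    Needs contrasts T1vS1_C, T2vS2_C, T1vS1_Z, T2vS2_Z, CvZ_S1, CvZ_S2,
    CvZ_T1 and CvZ_T2.  ``ancestrally_plastic`` = zinc-responsive in both
    sensitive populations (no direction requirement).
    """
    required = [
        "T1vS1_C", "T2vS2_C", "T1vS1_Z", "T2vS2_Z",
        "CvZ_S1", "CvZ_S2", "CvZ_T1", "CvZ_T2",
    ]
    missing = [k for k in required if k not in de]
    if missing:
        raise PlastevolError(f"missing DE tables: {missing}")
    universe = _check_universe(*(de[k] for k in required))
    table = pd.DataFrame(index=universe)
    table["is_cec"] = call_cec(de["T1vS1_C"], de["T2vS2_C"])
    table["is_dp"] = call_dp(
        de["CvZ_T1"], de["CvZ_T2"],
        de["T1vS1_C"], de["T1vS1_Z"], de["T2vS2_C"], de["T2vS2_Z"],
    )
    table["ancestrally_plastic"] = (
        de["CvZ_S1"].significant & de["CvZ_S2"].significant
    ).astype(bool)
    for name in required:
        table[f"sig_{name}"] = de[name].significant.astype(bool)
        table[f"dir_{name}"] = de[name].direction
    return table
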