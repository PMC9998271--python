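"""Per-gene evolutionary responses to ancestral expression plasticity.

For each gene three mean expression levels are computed on the
variance-stabilized (log2-like) scale:

``L_o``  sensitive populations, control      (ancestor at home)
``L_p``  sensitive populations, zinc         (ancestor's plastic response)
``L_a``  tolerant populations, zinc          (adapted populations in zinc)

The plastic change is PC = L_p - L_o and the evolutionary change is
EC = L_a - L_p (so PC + EC = L_a - L_o identically).  Genes whose PC and EC
are both "substantial" (significant in the designated pooled DE contrasts)
are assigned one of three categories:

* reinforcement:  EC x PC > 0
* overshooting:   EC x PC < 0 and |EC| <  r |PC|
* reversion:      EC x PC < 0 and |EC| >  r |PC|

with r = 0.5 by default.  Exact boundaries (EC x PC = 0, |EC| = r |PC|) are
resolved by configurable tie rules: the product-zero case carries no
directional information and is left unclassified; the ratio boundary goes
to reversion (the dominant class) unless configured otherwise.

Because L_p enters PC and EC with opposite signs, measurement error in L_p
makes PC and EC spuriously anti-correlated, inflating apparent reversion.
The parametric bootstrap therefore draws TWO independent realizations of
the sensitive-zinc group mean per replicate — one used in PC*, one in EC* —
breaking the shared-error correlation before re-classifying.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import DEResult, NormalizedMatrix
from .io import PlastevolError, SampleDesign

__all__ = [
    "REVERSION",
    "REINFORCEMENT",
    "OVERSHOOTING",
    "UNCLASSIFIED",
    "compute_levels",
    "set_substantiality",
    "classify",
    "classify_raw",
    "bootstrap_classify",
    "bootstrap_profiles",
    "classify_set",
    "BootstrapResult",
]

log = logging.getLogger(__name__)

REVERSION = "reversion"
REINFORCEMENT = "reinforcement"
OVERSHOOTING = "overshooting"
UNCLASSIFIED = "unclassified"
CATEGORIES = (REVERSION, REINFORCEMENT, OVERSHOOTING)

_SCOPES = {
    "combined": ("S1", "S2", "T1", "T2"),
    "pair1": ("S1", "T1"),
    "pair2": ("S2", "T2"),
}


def compute_levels(
    nm: NormalizedMatrix, design: SampleDesign, scope: str = "combined"
) -> pd.DataFrame:
    """Per-gene L_o, L_p, L_a, PC and EC on the VST scale.

    ``scope`` restricts the averages to one geographic pair ("pair1" =
    T1/S1, "pair2" = T2/S2) or uses all four populations ("combined").
    """
    if scope not in _SCOPES:
        raise PlastevolError(f"unknown scope {scope!r}; expected {sorted(_SCOPES)}")
    pops = _SCOPES[scope]
    vals = nm.vst_values

    def group_mean(ecotype: str, treatment: str) -> pd.Series:
        samples = [
            s
            for s in design.samples_for(ecotype=ecotype, treatment=treatment)
            if design.table.set_index("sample").loc[s, "population"] in pops
        ]
        if not samples:
            raise PlastevolError(
                f"no samples for ecotype={ecotype}, treatment={treatment}, scope={scope}"
            )
        return vals[samples].mean(axis=1)

    L_o = group_mean("S", "C")
    L_p = group_mean("S", "Z")
    L_a = group_mean("T", "Z")
    out = pd.DataFrame(
        {
            "L_o": L_o,
            "L_p": L_p,
            "L_a": L_a,
            "PC": L_p - L_o,
            "EC": L_a - L_p,
        }
    )
    out["scope"] = scope
    return out


def set_substantiality(
    profiles: pd.DataFrame, de_pooled_pc: DEResult, de_pooled_ec: DEResult
) -> pd.DataFrame:
    """Attach substantial_PC / substantial_EC flags from the pooled contrasts.

    PC substantiality comes from the pooled sensitive control-vs-zinc
    contrast, EC substantiality from the pooled tolerant-vs-sensitive
    contrast in zinc.  Genes missing from a DE table get False (logged).
    """
    out = profiles.copy()
    for col, de in (("substantial_PC", de_pooled_pc), ("substantial_EC", de_pooled_ec)):
        n_missing = int((~out.index.isin(de.gene_ids)).sum())
        if n_missing:
            log.warning(
                "%d gene(s) absent from DE table %s; substantiality set to False",
                n_missing,
                de.contrast,
            )
        sig = de.significant
        out[col] = out.index.isin(sig.index[sig])
    return out


def classify_raw(
    pc: np.ndarray | float,
    ec: np.ndarray | float,
    ratio: float = 0.5,
    boundary_tie: str = "reversion",
) -> np.ndarray:
    """Ungated three-way classification of (PC, EC) arrays.

    Returns an object array over {reversion, reinforcement, overshooting,
    unclassified}; "unclassified" marks the degenerate EC x PC = 0 case.
    Symmetric under joint sign flip of (PC, EC).
    """
    pc = np.atleast_1d(np.asarray(pc, dtype=float))
    ec = np.atleast_1d(np.asarray(ec, dtype=float))
    out = np.full(pc.shape, UNCLASSIFIED, dtype=object)
    prod = pc * ec
    out[prod > 0] = REINFORCEMENT
    opp = prod < 0
    ae, ap = np.abs(ec), ratio * np.abs(pc)
    out[opp & (ae > ap)] = REVERSION
    out[opp & (ae < ap)] = OVERSHOOTING
    tie = opp & (ae == ap)
    if boundary_tie == "reversion":
        out[tie] = REVERSION
    elif boundary_tie == "overshooting":
        out[tie] = OVERSHOOTING
    else:
        out[tie] = UNCLASSIFIED
    return out


def classify(
    profiles: pd.DataFrame,
    ratio: float = 0.5,
    boundary_tie: str = "reversion",
) -> pd.DataFrame:
    """Gated per-gene category calls.

    A gene is categorized only when substantial_PC and substantial_EC both
    hold; otherwise it is "unclassified".  If the substantiality columns are
    absent all genes are treated as gated-in (useful for noise-free data).
    """
    raw = classify_raw(
        profiles["PC"].to_numpy(), profiles["EC"].to_numpy(), ratio, boundary_tie
    )
    if {"substantial_PC", "substantial_EC"} <= set(profiles.columns):
        gated = (profiles["substantial_PC"] & profiles["substantial_EC"]).to_numpy()
    else:
        gated = np.ones(len(profiles), dtype=bool)
    cat = np.where(gated, raw, UNCLASSIFIED)
    return pd.DataFrame({"category": cat}, index=profiles.index)


# ---------------------------------------------------------------------------
# parametric bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Replicate-level category frequencies for one gene."""

    point_category: str
    support: float
    frequencies: dict[str, float]
    passes: bool


def _draw_category_freqs(
    means: np.ndarray,
    sems: np.ndarray,
    B: int,
    rng: np.random.Generator,
    ratio: float,
    boundary_tie: str,
    shared_lp: bool,
) -> np.ndarray:
    """(G x 4) category frequencies over B replicates.

    means/sems are (G x 3) arrays for the sensitive-control, sensitive-zinc
    and tolerant-zinc group means.  Column order of the result follows
    (reversion, reinforcement, overshooting, unclassified).
    """
    G = means.shape[0]
    lo = rng.normal(means[:, [0]], sems[:, [0]], size=(G, B))
    lp1 = rng.normal(means[:, [1]], sems[:, [1]], size=(G, B))
    lp2 = lp1 if shared_lp else rng.normal(means[:, [1]], sems[:, [1]], size=(G, B))
    la = rng.normal(means[:, [2]], sems[:, [2]], size=(G, B))
    cat = classify_raw(lp1 - lo, la - lp2, ratio, boundary_tie)
    freqs = np.empty((G, 4))
    for j, name in enumerate(CATEGORIES + (UNCLASSIFIED,)):
        freqs[:, j] = (cat == name).mean(axis=1)
    return freqs


def bootstrap_classify(
    means: tuple[float, float, float],
    sds: tuple[float, float, float],
    ns: tuple[int, int, int],
    B: int = 100,
    seed: int | np.random.Generator = 0,
    ratio: float = 0.5,
    boundary_tie: str = "reversion",
    support_threshold: float = 0.95,
    shared_lp: bool = False,
) -> BootstrapResult:
    """Parametric bootstrap of the category call for one gene.

    Group means are redrawn from normal(mean, SD/sqrt(n)) for the
    sensitive-control, sensitive-zinc and tolerant-zinc groups.  By default
    the sensitive-zinc mean is drawn twice independently (once for PC*, once
    for EC*) to remove the shared-L_p error correlation; ``shared_lp=True``
    reproduces the naive single-draw scheme.  Zero or negative SDs collapse
    to degenerate (noise-free) draws.
    """
    if B < 1:
        raise PlastevolError("bootstrap needs B >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    means_a = np.asarray(means, dtype=float)[None, :]
    sds_a = np.clip(np.asarray(sds, dtype=float), 0.0, None)
    ns_a = np.asarray(ns, dtype=float)
    if np.any(ns_a < 1):
        raise PlastevolError("group sizes must be >= 1")
    sems = (sds_a / np.sqrt(ns_a))[None, :]
    freqs = _draw_category_freqs(
        means_a, sems, B, rng, ratio, boundary_tie, shared_lp
    )[0]
    point = str(
        classify_raw(
            means_a[0, 1] - means_a[0, 0], means_a[0, 2] - means_a[0, 1], ratio, boundary_tie
        )[0]
    )
    names = CATEGORIES + (UNCLASSIFIED,)
    fdict = dict(zip(names, freqs))
    support = float(fdict[point])
    return BootstrapResult(
        point_category=point,
        support=support,
        frequencies={k: float(v) for k, v in fdict.items()},
        passes=support >= support_threshold,
    )


def bootstrap_profiles(
    nm: NormalizedMatrix,
    design: SampleDesign,
    profiles: pd.DataFrame,
    calls: pd.DataFrame,
    B: int = 100,
    seed: int | np.random.Generator = 0,
    ratio: float = 0.5,
    boundary_tie: str = "reversion",
    support_threshold: float = 0.95,
    shared_lp: bool = False,
    scope: str = "combined",
) -> pd.DataFrame:
    """Vectorized bootstrap over all genes; augments the category calls.

    Adds ``bootstrap_support`` (fraction of replicates agreeing with the
    ungated point classification; NaN for gated-out genes) and
    ``passes_bootstrap``.
    """
    pops = _SCOPES[scope]
    vals = nm.vst_values
    groups = []
    for eco, trt in (("S", "C"), ("S", "Z"), ("T", "Z")):
        samples = [
            s
            for s in design.samples_for(ecotype=eco, treatment=trt)
            if design.table.set_index("sample").loc[s, "population"] in pops
        ]
        groups.append(samples)
    means = np.column_stack([vals[g].mean(axis=1).to_numpy() for g in groups])
    sems = np.column_stack(
        [
            (vals[g].std(axis=1, ddof=1) / np.sqrt(len(g))).to_numpy()
            for g in groups
        ]
    )
    sems = np.nan_to_num(sems, nan=0.0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = _draw_category_freqs(means, sems, B, rng, ratio, boundary_tie, shared_lp)
    point_raw = classify_raw(
        profiles["PC"].to_numpy(), profiles["EC"].to_numpy(), ratio, boundary_tie
    )
    names = list(CATEGORIES + (UNCLASSIFIED,))
    idx = np.array([names.index(c) for c in point_raw])
    support = freqs[np.arange(len(idx)), idx]

    out = calls.copy()
    gated = (calls["category"] != UNCLASSIFIED).to_numpy()
    out["bootstrap_support"] = np.where(gated, support, np.nan)
    out["passes_bootstrap"] = gated & (support >= support_threshold)
    return out


def classify_set(calls: pd.DataFrame, genes: pd.Index | None = None) -> pd.DataFrame:
    """Counts and proportions of each category among classified genes.

    ``genes`` restricts the tally to a subset (e.g. the CEC or DP set).
    Proportions are over classified genes only and sum to 1; an empty
    tally returns an all-zero table (with a warning).
    """
    sub = calls if genes is None else calls.loc[calls.index.intersection(genes)]
    classified = sub[sub["category"] != UNCLASSIFIED]
    counts = {c: int((classified["category"] == c).sum()) for c in CATEGORIES}
    total = sum(counts.values())
    if total == 0:
        log.warning("no classified genes in set; returning empty category table")
    table = pd.DataFrame(
        {
            "count": pd.Series(counts),
            "proportion": pd.Series(
                {c: (counts[c] / total if total else 0.0) for c in CATEGORIES}
            ),
        }
    )
    table.index.name = "category"
    table.attrs["n_classified"] = total
    table.attrs["n_total"] = len(sub)
    return table
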