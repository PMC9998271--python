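"""Negative-binomial differential expression for the clone-pair design.

A deliberately compact NB engine: median-of-ratios size factors,
method-of-moments gene dispersions shrunk toward a fitted a0/mu + a1 trend,
a closed-form log2(x + c) variance-stabilizing transform, and per-gene NB
GLMs (log link, size-factor offsets) fitted by IRLS with the dispersion held
fixed, Wald tests against the standard normal, BH correction across genes,
and normal-prior shrinkage of log2 fold changes.

All per-gene fits are vectorized across genes: one design matrix is shared
by every gene, so the IRLS normal equations are solved as a batched
(genes x p x p) linear system.

Four model parameterizations cover every contrast the downstream logic
needs:

``group``
    one combined population+treatment factor (8 cells); between-population
    contrasts within a treatment.
``paired_population``
    population + population:individual + population:treatment; the
    within-population control-vs-zinc response with genotype pairing.
``paired_ecotype``
    ecotype + ecotype:individual + ecotype:treatment; the pooled sensitive
    (or tolerant) zinc response across both pairs.
``eco_cond``
    one combined ecotype+treatment factor (4 cells); the pooled
    tolerant-vs-sensitive contrast in zinc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, PlastevolError, SampleDesign

__all__ = [
    "DEResult",
    "DispersionFit",
    "NormalizedMatrix",
    "NBFit",
    "CONTRASTS",
    "size_factors",
    "fit_dispersion",
    "vst",
    "fit_model",
    "run_contrast",
    "bh_adjust",
    "NormalizationError",
    "ModelError",
]

_LN2 = np.log(2.0)
_MIN_DISP = 1e-8
_MIN_PRIOR_VAR = 1e-6


class NormalizationError(PlastevolError):
    pass


class ModelError(PlastevolError):
    pass


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    factor_s = median over genes g (with strictly positive counts in every
    sample) of counts[g, s] / geometric-mean_g.  Scale-equivariant:
    multiplying one sample's counts by c multiplies its factor by c.
    """
    arr = m.data.to_numpy(dtype=float)
    allpos = np.all(arr > 0, axis=1)
    if not allpos.any():
        raise NormalizationError(
            "no gene has nonzero counts in every sample; size factors undefined"
        )
    sub = arr[allpos]
    geomean = np.exp(np.mean(np.log(sub), axis=1))
    sf = np.median(sub / geomean[:, None], axis=0)
    return pd.Series(sf, index=m.sample_ids, name="size_factor")


@dataclass
class DispersionFit:
    """Per-gene raw, trend and final (shrunken) NB dispersions."""

    alpha_raw: pd.Series
    alpha_trend: pd.Series
    alpha_final: pd.Series
    trend_a0: float
    trend_a1: float
    base_mean: pd.Series


def _fit_trend(base_mean: np.ndarray, alpha_hat: np.ndarray) -> tuple[float, float]:
    """Fit alpha_tr(mu) = a0/mu + a1 by trimmed non-negative least squares."""
    ok = base_mean > 0
    mu, a = base_mean[ok], alpha_hat[ok]
    A = np.column_stack([1.0 / mu, np.ones_like(mu)])
    keep = np.ones(len(a), dtype=bool)
    coef = np.zeros(2)
    for _ in range(3):
        coef, _ = optimize.nnls(A[keep], a[keep])
        resid = a - A @ coef
        scale = np.std(resid[keep])
        if scale == 0:
            break
        new_keep = np.abs(resid) <= 3.0 * scale
        if new_keep.sum() < 10 or np.array_equal(new_keep, keep):
            keep = new_keep if new_keep.sum() >= 10 else keep
            break
        keep = new_keep
    return float(coef[0]), float(coef[1])


def fit_dispersion(
    m: CountMatrix,
    sf: pd.Series,
    design: SampleDesign,
    shrink_weight: float = 0.5,
) -> DispersionFit:
    """Method-of-moments dispersions with trend shrinkage.

    Raw dispersion per gene pools (variance - mean)/mean^2 moments over the
    population x treatment replicate groups, floored at zero.  A decreasing
    trend a0/mu + a1 is fitted over all genes; the final dispersion is a
    log-scale weighted average of raw and trend values.
    """
    df = design.table
    norm = m.data.to_numpy(dtype=float) / sf.loc[m.sample_ids].to_numpy()
    groups = [
        np.array([m.sample_ids.index(s) for s in sub["sample"]])
        for _, sub in df.groupby(["population", "treatment"])
    ]
    groups = [g for g in groups if len(g) >= 2]
    if not groups:
        raise ModelError("all replicate groups are singletons; cannot estimate dispersion")

    num = np.zeros(m.shape[0])
    den = np.zeros(m.shape[0])
    for idx in groups:
        sub = norm[:, idx]
        mu_j = sub.mean(axis=1)
        v_j = sub.var(axis=1, ddof=1)
        w = len(idx) - 1
        num += w * (v_j - mu_j)
        den += w * mu_j**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = np.where(den > 0, num / den, 0.0)
    alpha_hat = np.clip(alpha_hat, 0.0, None)

    base_mean = norm.mean(axis=1)
    a0, a1 = _fit_trend(base_mean, alpha_hat)
    with np.errstate(divide="ignore"):
        alpha_trend = np.where(base_mean > 0, a0 / base_mean + a1, a1)
    alpha_trend = np.clip(alpha_trend, _MIN_DISP, None)

    w = shrink_weight
    log_final = (1 - w) * np.log(np.clip(alpha_hat, _MIN_DISP, None)) + w * np.log(
        alpha_trend
    )
    alpha_final = np.exp(log_final)

    genes = m.data.index
    return DispersionFit(
        alpha_raw=pd.Series(alpha_hat, index=genes, name="alpha_raw"),
        alpha_trend=pd.Series(alpha_trend, index=genes, name="alpha_trend"),
        alpha_final=pd.Series(alpha_final, index=genes, name="alpha_final"),
        trend_a0=a0,
        trend_a1=a1,
        base_mean=pd.Series(base_mean, index=genes, name="base_mean"),
    )


@dataclass
class NormalizedMatrix:
    """Size factors plus variance-stabilized (log2-like) expression values."""

    size_factors: pd.Series
    vst_values: pd.DataFrame
    pseudocount: float


def vst(
    m: CountMatrix,
    sf: pd.Series,
    disp: DispersionFit | None = None,
    pseudocount: float | None = None,
) -> NormalizedMatrix:
    """log2(normalized count + c) with c tied to the dispersion asymptote.

    For an NB family the variance of log(x + c) becomes mean-independent for
    large means when c ~ 1/(4 * alpha); c = 1/(4 * a1) (trend asymptote a1),
    clipped to [0.5, 32].  Monotone in counts within a sample.
    """
    if pseudocount is None:
        a1 = disp.trend_a1 if disp is not None else 0.0
        c = 1.0 / (4.0 * a1) if a1 > 0 else 32.0
        pseudocount = float(np.clip(c, 0.5, 32.0))
    norm = m.data.to_numpy(dtype=float) / sf.loc[m.sample_ids].to_numpy()
    values = pd.DataFrame(
        np.log2(norm + pseudocount), index=m.data.index, columns=m.data.columns
    )
    return NormalizedMatrix(size_factors=sf, vst_values=values, pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# design matrices and contrasts
# ---------------------------------------------------------------------------

#: the named contrasts used by the pipeline: (model, contrast spec).
#: A tuple spec means "first group minus second group" on the log2 scale;
#: a string spec names a single design-matrix coefficient.
CONTRASTS: dict[str, tuple[str, object]] = {
    # between-population, within-treatment (combined factor model)
    "T1vS1_C": ("group", ("T1_C", "S1_C")),
    "T2vS2_C": ("group", ("T2_C", "S2_C")),
    "T1vS1_Z": ("group", ("T1_Z", "S1_Z")),
    "T2vS2_Z": ("group", ("T2_Z", "S2_Z")),
    # expression-similarity contrasts (same model)
    "S1vS2_C": ("group", ("S1_C", "S2_C")),
    "T1vT2_C": ("group", ("T1_C", "T2_C")),
    "S1vS2_Z": ("group", ("S1_Z", "S2_Z")),
    "T1vT2_Z": ("group", ("T1_Z", "T2_Z")),
    # within-population zinc response, genotype-paired
    "CvZ_S1": ("paired_population", "S1:Z"),
    "CvZ_S2": ("paired_population", "S2:Z"),
    "CvZ_T1": ("paired_population", "T1:Z"),
    "CvZ_T2": ("paired_population", "T2:Z"),
    # pooled contrasts gating "substantial" PC and EC
    "S_CvZ": ("paired_ecotype", "S:Z"),
    "T_CvZ": ("paired_ecotype", "T:Z"),
    "SZvTZ": ("eco_cond", ("T_Z", "S_Z")),
}


def _sum_to_zero(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero coding of a factor: k levels -> k-1 columns."""
    levels = sorted(labels.unique())
    k = len(levels)
    cols = np.zeros((len(labels), k - 1))
    for i, lab in enumerate(labels):
        j = levels.index(lab)
        if j < k - 1:
            cols[i, j] = 1.0
        else:
            cols[i, :] = -1.0
    return cols, [f"ind[{l}]" for l in levels[:-1]]


def _design_matrix(design: SampleDesign, model: str) -> tuple[np.ndarray, list[str]]:
    df = design.table
    n = len(df)
    blocks: list[np.ndarray] = []
    names: list[str] = []
    if model == "group":
        cells = sorted((df["population"] + "_" + df["treatment"]).unique())
        for cell in cells:
            blocks.append(
                ((df["population"] + "_" + df["treatment"]) == cell).to_numpy(float)[:, None]
            )
            names.append(cell)
    elif model == "eco_cond":
        cells = sorted((df["ecotype"] + "_" + df["treatment"]).unique())
        for cell in cells:
            blocks.append(
                ((df["ecotype"] + "_" + df["treatment"]) == cell).to_numpy(float)[:, None]
            )
            names.append(cell)
    elif model in ("paired_population", "paired_ecotype"):
        factor = "population" if model == "paired_population" else "ecotype"
        for lev in sorted(df[factor].unique()):
            in_lev = (df[factor] == lev).to_numpy(float)
            blocks.append(in_lev[:, None])
            names.append(lev)
            sub = df[factor] == lev
            ind_cols, ind_names = _sum_to_zero(df.loc[sub, "individual"])
            full = np.zeros((n, ind_cols.shape[1]))
            full[sub.to_numpy()] = ind_cols
            blocks.append(full)
            names.extend(f"{lev}:{nm}" for nm in ind_names)
            blocks.append((in_lev * (df["treatment"] == "Z").to_numpy(float))[:, None])
            names.append(f"{lev}:Z")
    else:
        raise ModelError(f"unknown model {model!r}")
    X = np.hstack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError(f"design matrix for model {model!r} is rank-deficient")
    return X, names


def _contrast_vector(names: list[str], spec: object) -> np.ndarray:
    c = np.zeros(len(names))
    if isinstance(spec, tuple):
        a, b = spec
        for lab, sign in ((a, 1.0), (b, -1.0)):
            if lab not in names:
                raise ModelError(f"contrast level {lab!r} not estimable (empty cell?)")
            c[names.index(lab)] = sign
    else:
        if spec not in names:
            raise ModelError(f"coefficient {spec!r} not in model")
        c[names.index(spec)] = 1.0
    return c


# ---------------------------------------------------------------------------
# NB GLM via batched IRLS
# ---------------------------------------------------------------------------

def _irls_nb(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    maxiter: int = 60,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit NB GLMs (log link, fixed per-gene dispersion) for all genes at once.

    Returns (beta [G x p], cov [G x p x p], converged [G]).
    """
    G, n = Y.shape
    p = X.shape[1]
    ridge = 1e-10 * np.eye(p)
    eta0 = np.log(Y + 0.5) - offset  # crude start on the link scale
    beta, *_ = np.linalg.lstsq(X, eta0.T, rcond=None)
    beta = beta.T  # G x p
    converged = np.zeros(G, dtype=bool)
    a = alpha[:, None]
    XtWX = None
    for _ in range(maxiter):
        eta = beta @ X.T + offset
        mu = np.clip(np.exp(eta), 1e-10, 1e12)
        W = mu / (1.0 + a * mu)
        z = (eta - offset) + (Y - mu) / mu
        XtWX = np.einsum("ni,gn,nj->gij", X, W, X) + ridge
        rhs = np.einsum("ni,gn->gi", X, W * z)
        new_beta = np.linalg.solve(XtWX, rhs[..., None])[..., 0]
        delta = np.max(np.abs(new_beta - beta), axis=1)
        beta = new_beta
        converged = delta < tol
        if converged.all():
            break
    cov = np.linalg.inv(XtWX)
    return beta, cov, converged


class DEResult:
    """Per-gene fold changes and significance for one contrast.

    ``table`` columns: lfc_raw, lfc_shrunk, se, pvalue, padj, significant,
    direction (all log2 scale; se is the SE of lfc_raw).
    """

    def __init__(self, contrast: str, table: pd.DataFrame, fdr_threshold: float):
        self.contrast = contrast
        self.table = table
        self.fdr_threshold = fdr_threshold

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def significant(self) -> pd.Series:
        return self.table["significant"]

    @property
    def direction(self) -> pd.Series:
        return self.table["direction"]

    @property
    def lfc_shrunk(self) -> pd.Series:
        return self.table["lfc_shrunk"]

    @property
    def padj(self) -> pd.Series:
        return self.table["padj"]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "contrast", self.contrast)
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_sig = int(self.significant.sum())
        return f"<DEResult {self.contrast}: {n_sig}/{len(self.table)} significant>"


class NBFit:
    """A fitted NB GLM (one model parameterization, all genes).

    Fit once, then extract any number of Wald contrasts from the shared
    coefficient/covariance arrays.
    """

    def __init__(
        self,
        m: CountMatrix,
        sf: pd.Series,
        disp: DispersionFit,
        design: SampleDesign,
        model: str,
    ):
        self.model = model
        self.genes = m.data.index
        order = design.sample_ids
        Y = m.data[order].to_numpy(dtype=float)
        X, names = _design_matrix(design, model)
        self.names = names
        offset = np.log(sf.loc[order].to_numpy())[None, :]
        alpha = disp.alpha_final.loc[self.genes].to_numpy()
        beta, cov, converged = _irls_nb(Y, X, offset, alpha)
        # genes with no information (all-zero rows) are flagged unfit
        converged = converged & (Y.sum(axis=1) > 0)
        self.beta, self.cov, self.converged = beta, cov, converged

    def contrast(self, spec: str | tuple, fdr_threshold: float = 0.05) -> DEResult:
        """Wald test for a named or explicit contrast; returns a DEResult."""
        if isinstance(spec, str) and spec in CONTRASTS:
            model, raw = CONTRASTS[spec]
            if model != self.model:
                raise ModelError(
                    f"contrast {spec!r} needs model {model!r}, this fit is {self.model!r}"
                )
            name = spec
        else:
            raw, name = spec, str(spec)
        c = _contrast_vector(self.names, raw)
        est = self.beta @ c
        var = np.einsum("gij,i,j->g", self.cov, c, c)
        se = np.sqrt(np.clip(var, 0, None))
        lfc = est / _LN2
        se2 = se / _LN2
        with np.errstate(divide="ignore", invalid="ignore"):
            z = lfc / se2
        pvalue = 2.0 * stats.norm.sf(np.abs(z))
        pvalue = np.where(self.converged & (se2 > 0), pvalue, np.nan)
        lfc = np.where(self.converged, lfc, np.nan)

        padj = bh_adjust(pd.Series(pvalue, index=self.genes)).to_numpy()
        ok = np.isfinite(lfc) & np.isfinite(se2)
        prior_var = max(
            float(np.var(lfc[ok]) - np.mean(se2[ok] ** 2)) if ok.any() else 0.0,
            _MIN_PRIOR_VAR,
        )
        shrink = prior_var / (prior_var + se2**2)
        lfc_shrunk = lfc * shrink
        direction = np.sign(lfc_shrunk)
        direction[~np.isfinite(lfc_shrunk) | (lfc_shrunk == 0)] = np.nan
        significant = pd.Series(padj, index=self.genes) <= fdr_threshold
        significant &= pd.Series(np.isfinite(padj), index=self.genes)
        table = pd.DataFrame(
            {
                "lfc_raw": lfc,
                "lfc_shrunk": lfc_shrunk,
                "se": se2,
                "pvalue": pvalue,
                "padj": padj,
                "significant": significant.to_numpy(),
                "direction": direction,
            },
            index=self.genes,
        )
        return DEResult(name, table, fdr_threshold)


def fit_model(
    m: CountMatrix,
    sf: pd.Series,
    disp: DispersionFit,
    design: SampleDesign,
    model: str,
) -> NBFit:
    return NBFit(m, sf, disp, design, model)


def run_contrast(
    m: CountMatrix,
    sf: pd.Series,
    disp: DispersionFit,
    design: SampleDesign,
    contrast: str | tuple,
    model: str | None = None,
    fdr_threshold: float = 0.05,
) -> DEResult:
    """Fit the model a contrast needs and return its DEResult."""
    if model is None:
        if not (isinstance(contrast, str) and contrast in CONTRASTS):
            raise ModelError("model must be given for non-registered contrasts")
        model = CONTRASTS[contrast][0]
    fit = fit_model(m, sf, disp, design, model)
    return fit.contrast(contrast, fdr_threshold=fdr_threshold)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p: pd.Series | np.ndarray) -> pd.Series:
    """Benjamini-Hochberg step-up adjustment; NaNs are excluded and kept NaN."""
    s = pd.Series(p).astype(float)
    vals = s.to_numpy()
    finite = np.isfinite(vals)
    if np.any((vals[finite] < 0) | (vals[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(len(s), np.nan)
    if finite.any():
        out[finite] = multipletests(vals[finite], method="fdr_bh")[1]
    return pd.Series(out, index=s.index, name="padj")
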