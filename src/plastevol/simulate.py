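"""Seeded synthetic RNA-seq generator with ground-truth gene categories.

Emulates the clone-pair study design: 4 populations (two mine/coast pairs),
2 treatments, ``n_individuals`` genotypes per population with clones of each
genotype present in both treatments (default 3, giving 24 samples).

Counts are negative binomial with

    mu[g, s] = depth_s * 2 ** (beta_g + effect(g, population_s, treatment_s)
                                + genotype_offset(g, individual_s))

and per-gene dispersion alpha_g ~ Gamma(shape, mean).  Four gene classes
set the effects:

``null``
    no effects; any DE call is a false positive.
``stress_reverted``
    a large zinc response (+/- lfc_scale) in the sensitive ecotype only;
    tolerant populations sit at baseline in both treatments.  These genes
    are truth-class reversion (EC = -PC) and emulate the dominant ancestral
    stress response that adapted plants have lost.
``cec``
    a constitutive ecotype shift (+/- lfc_scale in both treatments, same
    direction in both pairs).  A configurable fraction also receives
    beneficial ancestral plasticity (a half-sized sensitive zinc response in
    the same direction), making them truth-class reinforcement and feeding
    the canalization/assimilation paths.
``dp``
    a zinc response (+/- lfc_scale) in the tolerant populations, centred on
    the baseline (half below in control, half above in zinc) so the
    constitutive ecotype offset never stacks beyond one lfc_scale of
    displacement; most (83% by default) are also ancestrally plastic in the
    same direction, with a slightly larger (0.8 lfc_scale) sensitive
    response, so their truth class is overshooting.

Library depths are log-normal; genotype offsets are shared between a
clone's two treatment samples so the paired model has something to absorb.
Identical seeds give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, PlastevolError, SampleDesign
from .plasticity import classify_raw, UNCLASSIFIED

__all__ = ["SimParams", "simulate_experiment", "truth_class"]

CATEGORY_NULL = "null"
CATEGORY_STRESS = "stress_reverted"
CATEGORY_CEC = "cec"
CATEGORY_DP = "dp"


@dataclass
class SimParams:
    """Generator settings; defaults mirror the study conditions.

    ``frac_stress`` is the share of genes carrying the ancestral stress
    response (the dominant differentially-expressed fraction of a stressed
    transcriptome); ``frac_cec``/``frac_dp`` are the small parallel-adaptive
    fractions (hundreds of genes out of ~28k).  ``lfc_scale`` (log2) sets
    effect magnitudes, ``dispersion_mean``/``dispersion_shape`` the NB
    dispersion distribution, ``libsize_sigma`` the log-normal depth spread
    and ``genotype_sigma`` the per-genotype log2 offset spread.
    """

    n_genes: int = 5000
    n_individuals: int = 3
    frac_stress: float = 0.30
    frac_cec: float = 0.015
    frac_dp: float = 0.005
    lfc_scale: float = 2.0
    dispersion_shape: float = 2.0
    dispersion_mean: float = 0.05
    libsize_sigma: float = 0.15
    genotype_sigma: float = 0.1
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    cec_plastic_frac: float = 0.5
    dp_plastic_frac: float = 0.83
    rng_seed: int = 0

    def __post_init__(self) -> None:
        fractions = self.frac_stress + self.frac_cec + self.frac_dp
        if fractions > 1:
            raise PlastevolError(
                f"gene-class fractions sum to {fractions:.3f} > 1"
            )
        for name in ("lfc_scale",):
            if getattr(self, name) < 0:
                raise PlastevolError(f"{name} must be >= 0")
        for name in ("dispersion_shape", "dispersion_mean"):
            if getattr(self, name) <= 0:
                raise PlastevolError(f"{name} must be > 0")
        if self.n_genes < 1 or self.n_individuals < 2:
            raise PlastevolError("need n_genes >= 1 and n_individuals >= 2")


def truth_class(
    L_o: float, L_p: float, L_a: float, ratio: float = 0.5
) -> str:
    """Noise-free category for stated mean levels (none when EC*PC = 0)."""
    if ratio <= 0:
        raise PlastevolError("ratio must be positive")
    cat = classify_raw(L_p - L_o, L_a - L_p, ratio=ratio)[0]
    return "none" if cat == UNCLASSIFIED else str(cat)


def _build_design(p: SimParams) -> SampleDesign:
    rows = []
    for pop in ("S1", "T1", "S2", "T2"):
        for k in range(p.n_individuals):
            ind = f"{pop}_{chr(ord('a') + k)}"
            for trt in ("C", "Z"):
                rows.append(
                    {
                        "sample": f"{pop}_{trt}_{chr(ord('a') + k)}",
                        "population": pop,
                        "treatment": trt,
                        "individual": ind,
                    }
                )
    return SampleDesign(pd.DataFrame(rows))


def simulate_experiment(
    p: SimParams,
) -> tuple[CountMatrix, SampleDesign, pd.DataFrame]:
    """Generate (counts, design, truth) for one synthetic experiment.

    The truth table records, per gene: category, effect direction, the
    noise-free log2 levels L_o (sensitive control), L_p (sensitive zinc),
    L_a (tolerant zinc) and L_tc (tolerant control), and the implied
    plasticity-response class.
    """
    rng = np.random.default_rng(p.rng_seed)
    design = _build_design(p)
    G = p.n_genes

    n_stress = int(round(p.frac_stress * G))
    n_cec = int(round(p.frac_cec * G))
    n_dp = int(round(p.frac_dp * G))
    category = np.array(
        [CATEGORY_STRESS] * n_stress
        + [CATEGORY_CEC] * n_cec
        + [CATEGORY_DP] * n_dp
        + [CATEGORY_NULL] * (G - n_stress - n_cec - n_dp),
        dtype=object,
    )

    beta = rng.normal(p.baseline_log2_mean, p.baseline_log2_sd, size=G)
    beta = np.clip(beta, 1.0, 14.0)
    direction = rng.choice([-1.0, 1.0], size=G)
    d = direction * p.lfc_scale

    # noise-free log2 levels per (ecotype, treatment) cell
    L_o = beta.copy()          # sensitive control
    L_p = beta.copy()          # sensitive zinc
    L_tc = beta.copy()         # tolerant control
    L_a = beta.copy()          # tolerant zinc

    is_stress = category == CATEGORY_STRESS
    L_p[is_stress] += d[is_stress]

    is_cec = category == CATEGORY_CEC
    cec_plastic = is_cec & (rng.random(G) < p.cec_plastic_frac)
    L_tc[is_cec] += d[is_cec]
    L_a[is_cec] += d[is_cec]
    L_p[cec_plastic] += 0.5 * d[cec_plastic]

    is_dp = category == CATEGORY_DP
    dp_plastic = is_dp & (rng.random(G) < p.dp_plastic_frac)
    L_tc[is_dp] -= 0.5 * d[is_dp]
    L_a[is_dp] += 0.5 * d[is_dp]
    L_p[dp_plastic] += 0.8 * d[dp_plastic]

    # assemble the per-sample expected log2 levels
    table = design.table
    n_samples = len(table)
    level = np.empty((G, n_samples))
    cell_levels = {
        ("S", "C"): L_o,
        ("S", "Z"): L_p,
        ("T", "C"): L_tc,
        ("T", "Z"): L_a,
    }
    for j, row in table.iterrows():
        level[:, j] = cell_levels[(row["ecotype"], row["treatment"])]

    individuals = sorted(table["individual"].unique())
    geno = rng.normal(0.0, p.genotype_sigma, size=(G, len(individuals)))
    ind_idx = np.array([individuals.index(i) for i in table["individual"]])
    level = level + geno[:, ind_idx]

    depth = np.exp(rng.normal(0.0, p.libsize_sigma, size=n_samples))
    mu = depth[None, :] * np.exp2(level)

    alpha = rng.gamma(
        p.dispersion_shape, p.dispersion_mean / p.dispersion_shape, size=G
    )
    alpha = np.clip(alpha, 1e-8, None)
    # NB(r, q): r = 1/alpha, q = r / (r + mu)
    r = 1.0 / alpha
    q = r[:, None] / (r[:, None] + mu)
    counts = rng.negative_binomial(r[:, None], q)

    gene_ids = [f"g{i + 1:05d}" for i in range(G)]
    cm = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=table["sample"].tolist())
    )
    true_class = [
        truth_class(lo, lp, la) for lo, lp, la in zip(L_o, L_p, L_a)
    ]
    truth = pd.DataFrame(
        {
            "category": category,
            "direction": np.where(direction > 0, "up", "down"),
            "L_o": L_o,
            "L_p": L_p,
            "L_a": L_a,
            "L_tc": L_tc,
            "true_class": true_class,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return cm, design, truth
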