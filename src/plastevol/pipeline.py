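"""End-to-end orchestration: model object, results object, pipeline runner.

`PlasticityModel` holds validated counts + design + config; `fit()` runs
normalization, dispersion estimation, every named contrast, the PC/EC
profiles and category calls, the parametric bootstrap, the CEC/DP gene
sets, overlap and proportion statistics, and the genetic-assimilation
accounting, returning a `PlasticityResults`.

`run_pipeline` wraps the two objects for file-based use: it reads (or
simulates) the inputs, fits, and writes every stage output as TSV/JSON
into an output directory, together with a config snapshot and input
digests so a run is reproducible from its own records.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import de as de_mod
from . import genesets as gs_mod
from . import plasticity as pl_mod
from .io import AnalysisConfig, CountMatrix, PlastevolError, SampleDesign
from .simulate import SimParams, simulate_experiment

__all__ = [
    "PlasticityModel",
    "PlasticityResults",
    "PipelineRun",
    "run_pipeline",
    "pca_summary",
]

log = logging.getLogger(__name__)

#: contrasts fitted by default, grouped by model so each model is fitted once.
_MODEL_CONTRASTS: dict[str, list[str]] = {}
for _name, (_model, _) in de_mod.CONTRASTS.items():
    _MODEL_CONTRASTS.setdefault(_model, []).append(_name)


def pca_summary(
    nm: de_mod.NormalizedMatrix,
    samples: list[str] | None = None,
    genes: list[str] | pd.Index | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centred (unscaled) PCA of samples over VST values.

    Returns (coordinates, variance fractions).  Components are ordered by
    decreasing variance; signs are fixed so each component's largest-|value|
    coordinate is positive.
    """
    vals = nm.vst_values
    if samples is not None:
        vals = vals[list(samples)]
    if genes is not None:
        vals = vals.loc[list(genes)]
    X = vals.T.to_numpy(dtype=float)  # samples x genes
    n = X.shape[0]
    if n < 2:
        raise PlastevolError("PCA needs at least 2 samples")
    Xc = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    k = min(n - 1, len(S))
    coords = (U[:, :k] * S[:k])
    for j in range(k):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    var = S[:k] ** 2
    total = Xc.var(axis=0, ddof=0).sum() * n
    frac = var / total if total > 0 else np.zeros(k)
    out = pd.DataFrame(
        coords, index=vals.columns, columns=[f"PC{j + 1}" for j in range(k)]
    )
    out.index.name = "sample"
    return out, frac


class PlasticityModel:
    """The full analysis as a fittable model.

    Parameters
    ----------
    counts : CountMatrix or DataFrame
        Gene x sample integer counts (low-count genes are filtered here).
    design : SampleDesign or DataFrame
        Per-sample factors.
    config : AnalysisConfig, optional
    truth : DataFrame, optional
        Ground-truth table when the data came from the simulator.
    """

    def __init__(self, counts, design, config: AnalysisConfig | None = None, truth=None):
        if isinstance(counts, pd.DataFrame):
            counts = CountMatrix(counts)
        if isinstance(design, pd.DataFrame):
            design = SampleDesign(design)
        self.config = config or AnalysisConfig()
        missing = set(design.sample_ids) - set(counts.sample_ids)
        if missing:
            raise PlastevolError(f"design samples absent from counts: {sorted(missing)[:5]}")
        self.n_genes_input = counts.shape[0]
        counts = counts.filter_low_counts(self.config.low_count_min)
        if counts.shape[0] == 0:
            raise PlastevolError("all genes removed by the low-count filter")
        # keep only designed samples, in design order
        counts = CountMatrix(counts.data[design.sample_ids])
        self.counts = counts
        self.design = design
        self.truth = truth

    @classmethod
    def from_tsv(
        cls, counts_path, design_path, config: AnalysisConfig | None = None
    ) -> "PlasticityModel":
        return cls(
            CountMatrix.from_tsv(counts_path),
            SampleDesign.from_tsv(design_path),
            config=config,
        )

    @classmethod
    def from_simulation(
        cls, params: SimParams | None = None, config: AnalysisConfig | None = None
    ) -> "PlasticityModel":
        cm, design, truth = simulate_experiment(params or SimParams())
        return cls(cm, design, config=config, truth=truth)

    def fit(self, bootstrap: bool = True) -> "PlasticityResults":
        cfg = self.config
        log.info("normalizing %d genes x %d samples", *self.counts.shape)
        sf = de_mod.size_factors(self.counts)
        disp = de_mod.fit_dispersion(
            self.counts, sf, self.design, shrink_weight=cfg.dispersion_shrink_weight
        )
        nm = de_mod.vst(self.counts, sf, disp)

        de: dict[str, de_mod.DEResult] = {}
        for model, names in _MODEL_CONTRASTS.items():
            fit = de_mod.fit_model(self.counts, sf, disp, self.design, model)
            for name in names:
                de[name] = fit.contrast(name, fdr_threshold=cfg.fdr_threshold)
        for name, res in de.items():
            log.info("contrast %s: %d significant", name, int(res.significant.sum()))

        profiles = pl_mod.compute_levels(nm, self.design, scope="combined")
        profiles = pl_mod.set_substantiality(profiles, de["S_CvZ"], de["SZvTZ"])
        calls = pl_mod.classify(
            profiles, ratio=cfg.overshoot_ratio, boundary_tie=cfg.boundary_tie
        )
        if bootstrap:
            calls = pl_mod.bootstrap_profiles(
                nm,
                self.design,
                profiles,
                calls,
                B=cfg.bootstrap_reps,
                seed=np.random.default_rng(cfg.rng_seed),
                ratio=cfg.overshoot_ratio,
                boundary_tie=cfg.boundary_tie,
                support_threshold=cfg.bootstrap_support_threshold,
                shared_lp=cfg.shared_lp_bootstrap,
            )
        else:
            calls = calls.assign(bootstrap_support=np.nan, passes_bootstrap=False)

        gene_sets = gs_mod.build_gene_set_table(de)
        gene_sets, assimilation = gs_mod.call_assimilation(
            gene_sets, de["CvZ_T1"], de["CvZ_T2"], profiles, calls
        )
        return PlasticityResults(
            model=self,
            size_factors=sf,
            dispersion=disp,
            normalized=nm,
            de=de,
            profiles=profiles,
            calls=calls,
            gene_sets=gene_sets,
            assimilation=assimilation,
        )


@dataclass
class PlasticityResults:
    """Everything `PlasticityModel.fit` computes, plus reporting helpers."""

    model: PlasticityModel
    size_factors: pd.Series
    dispersion: de_mod.DispersionFit
    normalized: de_mod.NormalizedMatrix
    de: dict[str, de_mod.DEResult]
    profiles: pd.DataFrame
    calls: pd.DataFrame
    gene_sets: pd.DataFrame
    assimilation: dict

    # -- derived tables ----------------------------------------------------
    def category_table(self, genes: pd.Index | None = None) -> pd.DataFrame:
        return pl_mod.classify_set(self.calls, genes)

    @property
    def cec_genes(self) -> pd.Index:
        return self.gene_sets.index[self.gene_sets["is_cec"]]

    @property
    def dp_genes(self) -> pd.Index:
        return self.gene_sets.index[self.gene_sets["is_dp"]]

    def overlap_stats(self) -> dict[str, gs_mod.OverlapStat | None]:
        """Fisher overlap tests for the CEC and DP constructions.

        The shared count is the direction-consistent one, so when the
        per-pair sets nearly fill the universe the implied 2x2 table can
        become inconsistent (direction-discordant genes are double-counted
        in both margins); such degenerate tables yield None.
        """
        g = self.gene_sets
        universe = len(g)
        dp1 = g["sig_CvZ_T1"] & (g["sig_T1vS1_C"] | g["sig_T1vS1_Z"])
        dp2 = g["sig_CvZ_T2"] & (g["sig_T2vS2_C"] | g["sig_T2vS2_Z"])
        specs = {
            "cec": (
                int(g["is_cec"].sum()),
                int(g["sig_T1vS1_C"].sum()),
                int(g["sig_T2vS2_C"].sum()),
            ),
            "dp": (int(g["is_dp"].sum()), int(dp1.sum()), int(dp2.sum())),
        }
        out: dict[str, gs_mod.OverlapStat | None] = {}
        for key, (a, n1, n2) in specs.items():
            try:
                out[key] = gs_mod.fisher_overlap(a, n1, n2, universe)
            except PlastevolError:
                log.warning("degenerate %s overlap table; skipping Fisher test", key)
                out[key] = None
        return out

    def proportion_tests(self) -> dict[str, dict]:
        """Two-sided binomial tests comparing category proportions between sets."""
        out: dict[str, dict] = {}
        whole = self.category_table()
        comparisons = [
            ("overshooting_dp_vs_transcriptome", self.dp_genes, "overshooting", whole),
            ("reinforcement_cec_vs_transcriptome", self.cec_genes, "reinforcement", whole),
        ]
        dp_table = self.category_table(self.dp_genes)
        if dp_table.attrs["n_classified"] > 0:
            comparisons.append(
                ("reinforcement_cec_vs_dp", self.cec_genes, "reinforcement", dp_table)
            )
        for name, genes, category, ref in comparisons:
            sub = self.category_table(genes)
            n = sub.attrs["n_classified"]
            p0 = float(ref.loc[category, "proportion"])
            if n == 0 or not 0 < p0 < 1:
                continue
            k = int(sub.loc[category, "count"])
            out[name] = {
                "k": k,
                "n": n,
                "p0": p0,
                "pvalue": gs_mod.binomial_proportion_test(k, n, p0),
            }
        return out

    def similarity_stats(self) -> pd.DataFrame:
        """Median |FC| for the standard population comparisons and gene sets."""
        rows = []
        sets: list[tuple[str, pd.Index]] = [("all", self.gene_sets.index)]
        if len(self.cec_genes):
            sets.append(("cec", self.cec_genes))
        if len(self.dp_genes):
            sets.append(("dp", self.dp_genes))
        for label, genes in sets:
            for contrast in ("S1vS2_C", "T1vT2_C", "S1vS2_Z", "T1vT2_Z"):
                stat = gs_mod.fc_similarity(self.de[contrast], genes, label=label)
                rows.append(
                    {
                        "gene_set": label,
                        "comparison": contrast,
                        "n": len(stat.values),
                        "median_abs_fc": stat.median,
                    }
                )
        return pd.DataFrame(rows)

    def pca(self, treatment: str | None = None, genes=None):
        samples = (
            self.model.design.samples_for(treatment=treatment)
            if treatment
            else None
        )
        return pca_summary(self.normalized, samples=samples, genes=genes)

    # -- reporting ---------------------------------------------------------
    def summary_dict(self) -> dict:
        whole = self.category_table()
        cec_t = self.category_table(self.cec_genes)
        dp_t = self.category_table(self.dp_genes)

        def cat_block(t: pd.DataFrame) -> dict:
            return {
                "n_classified": t.attrs["n_classified"],
                "counts": {c: int(t.loc[c, "count"]) for c in t.index},
                "proportions": {c: float(t.loc[c, "proportion"]) for c in t.index},
            }

        return {
            "n_genes_input": self.model.n_genes_input,
            "n_genes_analyzed": len(self.gene_sets),
            "n_samples": len(self.model.design),
            "significant_per_contrast": {
                k: int(v.significant.sum()) for k, v in self.de.items()
            },
            "set_sizes": {
                "cec": int(len(self.cec_genes)),
                "dp": int(len(self.dp_genes)),
                "ancestrally_plastic": int(self.gene_sets["ancestrally_plastic"].sum()),
            },
            "categories": {
                "transcriptome": cat_block(whole),
                "cec": cat_block(cec_t),
                "dp": cat_block(dp_t),
            },
            "overlaps": {
                k: (v.asdict() if v is not None else None)
                for k, v in self.overlap_stats().items()
            },
            "proportion_tests": self.proportion_tests(),
            "assimilation": self.assimilation,
            "bootstrap": {
                "n_passing": int(self.calls["passes_bootstrap"].sum()),
                "support_threshold": self.model.config.bootstrap_support_threshold,
            },
        }

    def summary(self) -> str:
        s = self.summary_dict()
        cats = s["categories"]["transcriptome"]
        lines = [
            "Evolutionary responses to ancestral plasticity",
            "=" * 54,
            f"genes analyzed        {s['n_genes_analyzed']:>8d}  (of {s['n_genes_input']} input)",
            f"samples               {s['n_samples']:>8d}",
            f"classified genes      {cats['n_classified']:>8d}",
        ]
        for c in ("reversion", "reinforcement", "overshooting"):
            lines.append(
                f"  {c:<19s} {cats['counts'][c]:>8d}  ({100 * cats['proportions'][c]:5.1f}%)"
            )
        ss = s["set_sizes"]
        lines += [
            f"CEC genes             {ss['cec']:>8d}",
            f"DP genes              {ss['dp']:>8d}",
            f"ancestrally plastic   {ss['ancestrally_plastic']:>8d}",
        ]
        a = s["assimilation"]
        lines += [
            f"canalized             {a['n_canalized']:>8d}",
            f"assimilated           {a['n_assimilated']:>8d}"
            f"  ({a['pct_of_cec']:.1f}% of CEC)",
        ]
        ov = s["overlaps"]

        def _or(key):
            return f"{ov[key]['odds_ratio']:.2f}" if ov.get(key) else "n/a"

        lines.append(f"overlap OR (CEC/DP)   {_or('cec')} / {_or('dp')}")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def save(self, outdir: str | Path) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, str] = {}

        for name, res in self.de.items():
            p = outdir / f"de_{name}.tsv"
            res.to_tsv(p)
            paths[f"de_{name}"] = str(p)

        prof = self.profiles.join(self.calls)
        prof.index.name = "gene_id"
        prof = prof[
            [
                "scope", "L_o", "L_p", "L_a", "PC", "EC",
                "substantial_PC", "substantial_EC",
                "category", "bootstrap_support", "passes_bootstrap",
            ]
        ]
        p = outdir / "profiles.tsv"
        prof.to_csv(p, sep="\t")
        paths["profiles"] = str(p)

        p = outdir / "genesets.tsv"
        out = self.gene_sets.copy()
        out.index.name = "gene_id"
        out.to_csv(p, sep="\t")
        paths["genesets"] = str(p)

        p = outdir / "overlaps.json"
        p.write_text(json.dumps(
            {k: (v.asdict() if v is not None else None)
             for k, v in self.overlap_stats().items()},
            indent=2,
        ))
        paths["overlaps"] = str(p)

        p = outdir / "similarity.tsv"
        self.similarity_stats().to_csv(p, sep="\t", index=False)
        paths["similarity"] = str(p)

        p = outdir / "assimilation_summary.json"
        p.write_text(json.dumps(_jsonify(self.assimilation), indent=2))
        paths["assimilation"] = str(p)

        pca_specs = [("pca_control.tsv", "C", None), ("pca_all.tsv", None, None)]
        if len(self.dp_genes) >= 1:
            pca_specs.append(("pca_dp.tsv", None, self.dp_genes))
        for fname, trt, genes in pca_specs:
            coords, frac = self.pca(treatment=trt, genes=genes)
            coords = coords.copy()
            coords.attrs["variance_fraction"] = list(frac)
            p = outdir / fname
            with open(p, "w") as fh:
                fh.write("# variance_fraction\t" + "\t".join(f"{f:.6f}" for f in frac) + "\n")
                coords.to_csv(fh, sep="\t")
            paths[fname.removesuffix(".tsv")] = str(p)
        return paths


@dataclass
class PipelineRun:
    """Record of one end-to-end run: config, input digests, outputs, summary."""

    config: dict
    input_digests: dict[str, str]
    outputs: dict[str, str] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    results: PlasticityResults | None = field(default=None, repr=False)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(
    outdir: str | Path,
    config: AnalysisConfig | str | Path | None = None,
    counts_path: str | Path | None = None,
    design_path: str | Path | None = None,
    simulate: bool = False,
    sim_params: SimParams | None = None,
) -> PipelineRun:
    """Run filter -> normalize -> contrasts -> classification -> bootstrap ->
    gene sets -> assimilation -> report, writing all stage outputs.

    Either ``counts_path`` + ``design_path`` or ``simulate=True`` (with
    optional ``sim_params``) must be given.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("plastevol")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        if isinstance(config, (str, Path)):
            config = AnalysisConfig.from_yaml(config)
        config = config or AnalysisConfig()

        digests: dict[str, str] = {}
        if simulate:
            params = sim_params or SimParams()
            cm, design, truth = simulate_experiment(params)
            # persist the generated inputs so the run is self-contained
            cm.to_tsv(outdir / "counts.tsv")
            design.to_tsv(outdir / "design.tsv")
            truth.to_csv(outdir / "truth.tsv", sep="\t")
            model = PlasticityModel(cm, design, config=config, truth=truth)
            digests["sim_params"] = json.dumps(_jsonify(vars(params)), sort_keys=True)
        else:
            if counts_path is None or design_path is None:
                raise PlastevolError("need counts_path and design_path (or simulate=True)")
            model = PlasticityModel.from_tsv(counts_path, design_path, config=config)
            digests["counts"] = _sha256(counts_path)
            digests["design"] = _sha256(design_path)

        results = model.fit()
        outputs = results.save(outdir)
        summary = _jsonify(results.summary_dict())
        run = PipelineRun(
            config=config.asdict(),
            input_digests=digests,
            outputs=outputs,
            summary=summary,
            results=results,
        )
        snapshot = {
            "config": run.config,
            "input_digests": run.input_digests,
            "summary": run.summary,
        }
        (outdir / "summary.json").write_text(json.dumps(snapshot, indent=2))
        run.outputs["summary"] = str(outdir / "summary.json")
        return run
    finally:
        root.removeHandler(handler)
        handler.close()
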