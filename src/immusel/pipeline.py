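"""End-to-end orchestration: synthesize (or ingest) inputs, run alignment
QC, selection tests, pN/pS, expression covariates, merge, and the category
statistics, with a reproducibility manifest.

The run directory has a fixed layout::

    alignments/              one FASTA per gene
    trees/                   one newick per gene
    results/selection.tsv
    results/pnps.tsv
    results/expression.tsv
    results/covariates.tsv
    results/stats/           model summaries (TSV + JSON)
    manifest.json
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as iomod
from . import stats as st
from .alignment import filter_alignment_length, filter_min_taxa
from .constraint import classify_degeneracy, compute_pnps, maf_filter, site_filters
from .expression import summarize_expression
from .selection import FitSettings, bh_fdr, run_gene_tests
from .simulate import SimulationConfig, simulate_expression, simulate_variants, simulate_world

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "run"
    synthetic: dict = field(default_factory=dict)  # SimulationConfig overrides
    seed: int = 0
    fdr_q: float = 0.2
    length_fraction: float = 0.8
    min_taxa_per_clade: int = 7
    maf_species2: float = 0.0625
    maf_species1: float = 0.0
    run_selection: bool = True
    run_pnps: bool = True
    run_expression: bool = True
    run_stats: bool = True
    selection_variants: tuple = ("base", "S", "S_MH")
    fast_fits: bool = False
    include_global_omega: bool = True
    write_gene_files: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cls._check(cfg)
        return cfg

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["selection_variants"] = list(self.selection_variants)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @staticmethod
    def _check(cfg: "PipelineConfig") -> None:
        if not 0 < cfg.fdr_q <= 1:
            raise ValueError("fdr_q must lie in (0, 1]")
        if not 0 < cfg.length_fraction <= 1:
            raise ValueError("length_fraction must lie in (0, 1]")
        if cfg.min_taxa_per_clade < 1:
            raise ValueError("min_taxa_per_clade must be >= 1")

    def hash(self) -> str:
        data = dataclasses.asdict(self)
        data["selection_variants"] = list(self.selection_variants)
        return hashlib.sha256(
            json.dumps(data, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict
    attrition: dict = field(default_factory=dict)  # stage -> {"in": n, "out": m}
    checksums: dict = field(default_factory=dict)

    def record_attrition(self, stage: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError("attrition cannot increase gene counts")
        self.attrition[stage] = {
            "in": int(n_in), "out": int(n_out), "excluded": int(n_in - n_out)
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def merge_covariates(
    test_results: pd.DataFrame,
    pnps: pd.DataFrame | None,
    expression: pd.DataFrame | None,
    ppi_table: pd.DataFrame | None,
    lengths: pd.DataFrame,
    categories: pd.DataFrame,
    manifest: RunManifest | None = None,
) -> pd.DataFrame:
    """Join per-gene tables on gene_id into the covariate table used by
    the statistics stage. Selection results, lengths and categories are
    required (inner join); pN/pS, expression and PPI merge left so their
    attrition shows up as missing values (listwise deletion downstream)."""
    for name, t in (("test_results", test_results), ("lengths", lengths),
                    ("categories", categories)):
        if t["gene_id"].duplicated().any():
            raise ValueError(f"duplicate gene ids in {name}")
    out = categories.merge(test_results, on="gene_id", how="inner")
    out = out.merge(lengths, on="gene_id", how="inner")
    for t in (pnps, expression, ppi_table):
        if t is not None:
            if t["gene_id"].duplicated().any():
                raise ValueError("duplicate gene ids in merged table")
            out = out.merge(t, on="gene_id", how="left")
    if manifest is not None:
        manifest.record_attrition(
            "merge", len(categories), len(out)
        )
    if len(out) == 0:
        log.warning("covariate merge produced an empty table")
    return out


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all enabled stages in dependency order on a synthetic world.

    Stages: synthesize -> alignment QC -> selection tests -> pN/pS ->
    expression -> merge covariates -> comparative statistics. Rerunning
    with an identical config reproduces identical outputs.
    """
    PipelineConfig._check(config)
    outdir = Path(config.outdir)
    (outdir / "results" / "stats").mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.hash(), seeds={"master": config.seed})

    sim_kwargs = dict(config.synthetic)
    sim_kwargs.setdefault("seed", config.seed)
    sim_cfg = SimulationConfig(**sim_kwargs)
    genes = simulate_world(sim_cfg)
    manifest.record_attrition("simulated", len(genes), len(genes))

    # ---------------------------------------------------------- alignment QC
    clade_map = {
        t: ("cladeA" if t.startswith("A") else "cladeB")
        for t in genes[0].tree.taxon_names
    }
    kept = []
    for g in genes:
        L = g.alignment.n_codons
        if not filter_alignment_length(L, L):  # synthetic: untrimmed
            continue
        if not filter_min_taxa(g.alignment, clade_map,
                               min(config.min_taxa_per_clade,
                                   sim_cfg.n_taxa_per_clade)):
            continue
        kept.append(g)
    manifest.record_attrition("alignment_qc", len(genes), len(kept))
    genes = kept

    if config.write_gene_files:
        (outdir / "alignments").mkdir(exist_ok=True)
        (outdir / "trees").mkdir(exist_ok=True)
        for g in genes:
            g.alignment.to_fasta(outdir / "alignments" / f"{g.gene_id}.fasta")
            (outdir / "trees" / f"{g.gene_id}.nwk").write_text(
                g.tree.to_newick() + "\n"
            )

    categories = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes],
         "category": [g.category for g in genes]}
    )
    lengths = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes],
         "seq_length": [3 * g.alignment.n_codons for g in genes]}
    )

    # ------------------------------------------------------------- selection
    sel_df = None
    if config.run_selection:
        settings = FitSettings.fast() if config.fast_fits else FitSettings()
        rows = []
        for i, g in enumerate(genes):
            res = run_gene_tests(
                g.alignment, g.tree, variants=config.selection_variants,
                seed=config.seed + 1000 + i, settings=settings,
                include_m1a_m2a=not config.fast_fits,
                include_global_omega=config.include_global_omega,
            )
            rows.append(res.as_row())
        sel_df = pd.DataFrame(rows)
        q, flags = bh_fdr(sel_df["model_averaged_p"].fillna(1.0).values,
                          config.fdr_q)
        sel_df["q_value"] = q
        sel_df["positive_flag"] = flags
        sel_df.to_csv(outdir / "results" / "selection.tsv", sep="\t",
                      index=False)
        manifest.record_attrition("selection", len(genes), len(sel_df))

    # ----------------------------------------------------------------- pN/pS
    pnps_df = None
    if config.run_pnps:
        n1, n2 = sim_cfg.n_diploid_samples
        rows = []
        rng = np.random.default_rng(config.seed + 7)
        for g in genes:
            cds = g.alignment.sequences[0]
            prof = classify_degeneracy(cds)
            S, N = prof.S_sites, prof.N_sites
            vals = {}
            for species, (n_dip, maf) in {
                "sp1": (n1, config.maf_species1),
                "sp2": (n2, config.maf_species2),
            }.items():
                var = simulate_variants(
                    cds, g.pnps_target, n_dip, sim_cfg.theta,
                    int(rng.integers(2**31)),
                )
                var = site_filters(var)
                var = maf_filter(var, maf)
                n_syn = int((var["true_class"] == "synonymous").sum())
                n_non = int((var["true_class"] == "nonsynonymous").sum())
                vals[species] = compute_pnps(n_syn, n_non, S, N, g.gene_id)
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "pnps_sp1": vals["sp1"].pnps,
                    "pnps_sp2": vals["sp2"].pnps,
                    "pnps": (vals["sp1"].pnps + vals["sp2"].pnps) / 2.0,
                }
            )
        pnps_df = pd.DataFrame(rows)
        pnps_df.to_csv(outdir / "results" / "pnps.tsv", sep="\t", index=False)
        manifest.record_attrition("pnps", len(genes), len(pnps_df))

    # ------------------------------------------------------------ expression
    expr_df = None
    if config.run_expression:
        n_samples = 2 * sim_cfg.n_tissues
        lib = np.full(n_samples, 2e6)
        mat = simulate_expression(
            len(genes), sim_cfg.n_tissues,
            [g.tau_target for g in genes], lib, config.seed + 11,
        )
        mat.counts.index = [g.gene_id for g in genes]
        mat.effective_lengths.index = mat.counts.index
        summary = summarize_expression(mat)
        expr_df = summary[["mean_expression", "tau"]].reset_index(
            names="gene_id"
        )
        expr_df.to_csv(outdir / "results" / "expression.tsv", sep="\t",
                       index=False)
        manifest.record_attrition("expression", len(genes), len(expr_df))

    # ------------------------------------------------------------------ merge
    table = None
    if sel_df is not None:
        test_results = sel_df[["gene_id", "model_averaged_p", "q_value",
                               "positive_flag", "global_omega"]].rename(
            columns={"global_omega": "dnds", "positive_flag": "positive"}
        )
        rng = np.random.default_rng(config.seed + 13)
        ppi = pd.DataFrame(
            {"gene_id": [g.gene_id for g in genes],
             "ppi_count": rng.poisson(20, size=len(genes))}
        )
        if expr_df is None:
            log.warning("expression stage disabled: tau and mean expression "
                        "covariates unavailable to the statistics stage")
        table = merge_covariates(
            test_results, pnps_df, expr_df, ppi, lengths, categories, manifest
        )
        table = st.transform_covariates(table)
        table.to_csv(outdir / "results" / "covariates.tsv", sep="\t",
                     index=False)
    elif config.run_stats:
        log.warning("statistics stage skipped: selection results missing")

    # ------------------------------------------------------------------ stats
    if (config.run_stats and table is not None
            and table["category"].nunique() >= 2):
        stats_dir = outdir / "results" / "stats"
        out = {}
        glm0 = st.fit_binomial_glm(table, "positive ~ category")
        out["glm_category"] = _cr_json(glm0)
        if pnps_df is not None:
            glm1 = st.fit_binomial_glm(table, "positive ~ category + z_pnps")
            out["glm_category_pnps"] = _cr_json(glm1)
            dun = st.dunnett_vs_control(glm1.fitted, seed=config.seed + 17)
            out["dunnett_glm_pnps"] = dun.to_dict(orient="list")
            kw = st.kruskal_dunn(table["pnps"], table["category"])
            out["kruskal_pnps"] = _cr_json(kw)
        if table["dnds"].notna().any():
            lm = st.fit_linear_model(table, "sqrt_dnds ~ category")
            out["lm_dnds_category"] = _cr_json(lm)
        with open(stats_dir / "models.json", "w") as fh:
            json.dump(out, fh, indent=2, default=float)

    for p in sorted((outdir / "results").rglob("*.tsv")):
        manifest.checksums[str(p.relative_to(outdir))] = _checksum(p)
    config.to_yaml(outdir / "config.yaml")
    manifest.to_json(outdir / "manifest.json")
    return manifest


def replicate_world_inference(
    seed: int,
    outdir,
    n_per_category: int = 150,
) -> dict:
    """One end-to-end synthetic world probing the constraint-vs-function
    logic: cytokines carry both a genuine (function) excess of
    positive-selection targets and lower selective constraint (higher
    pN/pS), with a gene-level coupling between constraint and positive
    selection. Runs the full fast-mode pipeline and fits the category GLM
    with and without the pN/pS covariate.

    Returns the category chi-square without/with pN/pS, the Dunnett
    p-value for the cytokine contrast in the pN/pS-adjusted model, and the
    per-category positive rates.
    """
    cfg = PipelineConfig(
        outdir=str(outdir),
        seed=seed,
        fast_fits=True,
        selection_variants=("base",),
        include_global_omega=False,
        synthetic=dict(
            n_taxa_per_clade=2,
            tree_depth=0.8,
            n_codons=90,
            omega_positive=8.0,
            positive_weight=0.15,
            theta=0.2,
            n_genes_per_category={
                "control": n_per_category, "cytokines": n_per_category
            },
            fraction_positive={"control": 0.03, "cytokines": 0.25},
            pnps_targets={"control": 0.12, "cytokines": 0.32},
            tau_targets={"control": 0.45, "cytokines": 0.70},
            constraint_coupling=1.5,
            pnps_gene_sd=0.5,
        ),
    )
    run_pipeline(cfg)
    table = pd.read_csv(
        Path(cfg.outdir) / "results" / "covariates.tsv", sep="\t"
    )
    g0 = st.fit_binomial_glm(table, "positive ~ category")
    g1 = st.fit_binomial_glm(table, "positive ~ category + z_pnps")
    chi0 = float(
        g0.terms.loc[g0.terms.term.str.contains("category"), "statistic"].iloc[0]
    )
    chi1 = float(
        g1.terms.loc[g1.terms.term.str.contains("category"), "statistic"].iloc[0]
    )
    dun = st.dunnett_vs_control(g1.fitted, seed=seed + 1)
    cyto = dun.loc[dun["category"] == "cytokines"].iloc[0]
    rates = table.groupby("category")["positive"].mean()
    return {
        "chi2_category": chi0,
        "chi2_category_with_pnps": chi1,
        "attenuated": chi1 < chi0,
        "p_cytokines_adj": float(cyto["p_adjusted"]),
        "rate_control": float(rates.get("control", np.nan)),
        "rate_cytokines": float(rates.get("cytokines", np.nan)),
    }


def _cr_json(cr: st.ComparisonResult) -> dict:
    out = {"terms": cr.terms.to_dict(orient="list"), **cr.extra}
    if cr.contrasts is not None:
        out["contrasts"] = cr.contrasts.to_dict(orient="list")
    return out
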