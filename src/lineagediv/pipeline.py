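"""End-to-end orchestration: data -> signal -> LD -> model competition -> ranking.

Mirrors the study design: genus precipitation niches from occupied sites,
phylogenetic signal by Pagel's lambda, lineage diversity as sesPD under tip
shuffling, model competition (linear / quadratic / piecewise) with the break
point located on the pooled data and spatial GLS refit on each side, 99%
mean-prediction bands, and a ranking of the top unprotected sites.
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

from . import conservation, diversity, regression
from .phylo import PhyloTree, pagel_lambda, read_newick
from .simulate import SimulationConfig, SyntheticDataset, make_dataset, mask_genera
from .phylo import graft_missing

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]

DRY_THRESHOLD_MM = 1200.0
WET_THRESHOLD_MM = 1800.0


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; hashable for provenance."""

    # either a simulation preset ...
    preset: str | None = "ech"  # "ech" | "null" | None for file inputs
    n_tips: int = 300
    n_sites: int = 200
    # ... or file inputs
    tree_path: str | None = None
    matrix_path: str | None = None
    sites_path: str | None = None
    # analysis knobs
    n_null: int = 199
    n_reps: int = 0  # rarefaction repetitions (0 disables)
    n_imputation_seeds: int = 0  # grafting robustness (0 disables)
    imputation_fraction: float = 68.0 / 920.0
    fraction: float = 0.05
    dry_threshold: float = DRY_THRESHOLD_MM
    wet_threshold: float = WET_THRESHOLD_MM
    predictor: str = "map_mm"
    min_segment: int = 5
    ci_level: float = 0.99
    seed: int = 0
    outdir: str = "results/pipeline"

    def __post_init__(self) -> None:
        if self.dry_threshold >= self.wet_threshold:
            raise ValueError("dry_threshold must be below wet_threshold")
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")
        if self.preset is None and not (self.tree_path and self.matrix_path and self.sites_path):
            raise ValueError("either a preset or all three input paths are required")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    config: PipelineConfig
    lambda_fit: dict
    model_table: pd.DataFrame
    selected_kind: str
    break_point: float | None
    ld_table_path: Path
    niche_table_path: Path
    conservation_top: list[str]
    robustness: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "lambda_fit": self.lambda_fit,
            "selected_kind": self.selected_kind,
            "break_point": self.break_point,
            "model_table": self.model_table.to_dict(orient="records"),
            "conservation_top": self.conservation_top,
            "robustness": self.robustness,
            "provenance": self.provenance,
        }, indent=2, sort_keys=True, default=str)


def _load_inputs(config: PipelineConfig) -> SyntheticDataset:
    if config.preset is not None:
        sim = SimulationConfig(n_tips=config.n_tips, n_sites=config.n_sites,
                               seed=config.seed, preset=config.preset)
        return make_dataset(sim)
    tree = read_newick(Path(config.tree_path).read_text())
    matrix = pd.read_csv(config.matrix_path, index_col=0)
    sites = pd.read_csv(config.sites_path)
    return SyntheticDataset(tree=tree, niches={}, matrix=matrix, sites=sites,
                            truth={"source": "files"})


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run the full analysis and write all artifacts under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start (hash %s)", config.config_hash())

    data = _load_inputs(config)
    tree, matrix, sites = data.tree, data.matrix, data.sites

    # genus niches and phylogenetic signal
    niche_tab = diversity.genus_mean_map(matrix, sites)
    lam = pagel_lambda(tree, niche_tab["mean_map"].to_dict())
    niche_path = outdir / "niche_table.csv"
    niche_tab.to_csv(niche_path)

    # lineage diversity
    ld_tab = diversity.ses_pd(matrix, tree, n_null=config.n_null, seed=config.seed)
    ld_path = outdir / "ld_table.csv"
    ld_tab.to_csv(ld_path)

    robustness: dict = {}

    # rarefaction control on wet sites
    if config.n_reps > 0:
        wet_ids = sites.loc[sites["map_mm"] >= config.wet_threshold, "site_id"]
        wet = matrix.loc[matrix.index.intersection(wet_ids)]
        if len(wet):
            rich = wet.sum(axis=1)
            target = max(2, int(rich.max() // 4))
            rar = diversity.rarefy_ld(wet, tree, target_richness=target,
                                      n_reps=config.n_reps, n_null=config.n_null,
                                      seed=config.seed)
            rar.to_csv(outdir / "rarefied_ld.csv")
            joint = rar.join(ld_tab["ld"], how="inner").dropna()
            corr = float(joint["ld_mean"].corr(joint["ld"], method="spearman")) if len(joint) > 2 else None
            robustness["rarefaction"] = {"target_richness": target,
                                         "n_sites": len(rar),
                                         "spearman_vs_unrarefied": corr}

    # imputation robustness: mask, re-graft, compare LD with the full tree
    if config.n_imputation_seeds > 0:
        pruned, clade_map = mask_genera(matrix, tree, config.imputation_fraction,
                                        seed=config.seed)
        lds = []
        for i in range(config.n_imputation_seeds):
            grafted = graft_missing(pruned, clade_map, seed=config.seed + i)
            t = diversity.ses_pd(matrix, grafted, n_null=config.n_null,
                                 seed=config.seed + i)
            lds.append(t["ld"].to_numpy())
        mean_ld = np.nanmean(np.vstack(lds), axis=0)
        ok = ld_tab["flag"].to_numpy() == "ok"
        r = float(np.corrcoef(mean_ld[ok], ld_tab["ld"].to_numpy()[ok])[0, 1])
        robustness["imputation"] = {"n_masked": len(clade_map),
                                    "n_seeds": config.n_imputation_seeds,
                                    "pearson_vs_full_tree": r}

    # model competition on valid sites
    reg = (ld_tab[ld_tab["flag"] == "ok"].reset_index()
           .merge(sites, on="site_id", validate="1:1"))
    x = reg[config.predictor].to_numpy(dtype=float)
    y = reg["ld"].to_numpy(dtype=float)
    # synthetic presets carry a spatially autocorrelated residual field;
    # adding it to the response emulates the unmodelled, spatially
    # structured variation the GLS stage exists to absorb
    if config.preset is not None and "noise" in reg.columns:
        noise_sd = float(data.truth.get("noise_sd", 0.0))
        y = y + noise_sd * reg["noise"].to_numpy(dtype=float)
    coords = reg[["lon", "lat"]].to_numpy(dtype=float)

    fit_lin = regression.fit_polynomial(x, y, degree=1)
    fit_quad = regression.fit_polynomial(x, y, degree=2)
    fit_pw = regression.fit_piecewise(x, y, min_segment=config.min_segment)
    selected = regression.select_model([fit_lin, fit_quad, fit_pw])

    rows = [f.summary_row() for f in (fit_lin, fit_quad, fit_pw)]

    # spatial GLS on each side of the break point, four structures + none
    gls_rows = []
    bp = fit_pw.break_point
    for side, mask in (("before", x < bp), ("after", x >= bp)):
        xs, ys, cs = x[mask], y[mask], coords[mask]
        design = np.column_stack([np.ones_like(xs), xs])
        side_fits = []
        for st in regression.STRUCTURES:
            try:
                f = regression.gls_fit(design, ys, cs, st)
            except ValueError as exc:
                log.warning("GLS %s/%s failed: %s", side, st, exc)
                continue
            side_fits.append(f)
            row = f.summary_row()
            row["kind"] = f"gls_{side}"
            row["slope"] = float(f.coefficients[1])
            row["intercept"] = float(f.coefficients[0])
            gls_rows.append(row)
        best_side = min(side_fits, key=lambda f: f.aic)
        robustness.setdefault("gls", {})[side] = {
            "structure": best_side.spatial.structure,
            "range_km": best_side.spatial.range_km,
            "delta_aic_vs_null_spatial": best_side.delta_aic_vs_null_spatial,
            "r2": best_side.r2,
            "slope": float(best_side.coefficients[1]),
            "intercept": float(best_side.coefficients[0]),
        }

    model_table = pd.DataFrame(rows + gls_rows)
    model_table.to_csv(outdir / "model_comparison.csv", index=False)

    # 99% mean band for the selected model
    grid = np.linspace(x.min(), x.max(), 200)
    band = regression.mean_ci(selected, grid, level=config.ci_level)
    pd.DataFrame(band).to_csv(outdir / "mean_ci.csv", index=False)

    report_cons = conservation.top_unprotected(ld_tab, sites, config.fraction)
    report_cons.write(outdir)

    provenance = {"config_hash": config.config_hash(), "seed": config.seed,
                  "n_sites_regressed": int(len(x))}
    report = PipelineReport(
        config=config,
        lambda_fit={"lambda_hat": lam.lambda_hat, "p_value": lam.p_value,
                    "lrt_stat": lam.lrt_stat, "n_tips": lam.n_tips},
        model_table=model_table,
        selected_kind=selected.kind,
        break_point=fit_pw.break_point,
        ld_table_path=ld_path,
        niche_table_path=niche_path,
        conservation_top=report_cons.top_set,
        robustness=robustness,
        provenance=provenance,
    )
    (outdir / "report.json").write_text(report.to_json())
    log.info("pipeline done: selected %s, break point %s", selected.kind, fit_pw.break_point)
    return report
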