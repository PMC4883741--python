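"""Analysis orchestration: configuration, data preparation, and the full pipeline.

A run takes a tree sample, a site table and a RunConfig, and produces the
study-shaped report: a predictor table (RVI, averaged beta, 95% CI) averaged
across replicates, a dependence block (lambda', phi, gamma with LRT p-values),
best-subset R^2, phylogenetic-signal results per outcome, the spatial
variogram, a replicate log, and a machine-readable JSON of everything.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pglspatial.averaging import run_model_averaging
from pglspatial.covariance import build_covariance_set, empirical_variogram, haversine_matrix
from pglspatial.gls import pagel_lambda_signal
from pglspatial.replicates import ReplicateSpec, run_replicates
from pglspatial.tree_io import TreeSample, read_trees

__all__ = ["RunConfig", "PreparedData", "prepare_data", "run_analysis", "read_site_table"]


@dataclass
class RunConfig:
    """Resolved configuration of one analysis run.

    ``predictors`` is the candidate set entering all-subsets averaging;
    ``factors`` declares categorical columns with their baseline level;
    ``transforms`` maps columns to "log" (or "none"); ``drop_where`` removes
    rows matching column == value before anything else (e.g. treeless islands
    for a replacement run). ``dummy_mode`` "independent" lets each factor dummy
    enter models on its own; "joint" ties a factor's dummies together.
    """

    trees_path: str = ""
    sites_path: str = ""
    outcome: str = ""
    predictors: list[str] = field(default_factory=list)
    forced_in: list[str] = field(default_factory=list)
    transforms: dict[str, str] = field(default_factory=dict)
    factors: dict[str, dict] = field(default_factory=dict)
    ordinals: dict[str, dict] = field(default_factory=dict)  # col -> {level: numeric code}
    drop_where: dict[str, object] = field(default_factory=dict)
    averaging_mode: str = "conditional"
    dummy_mode: str = "independent"
    n_replicates: int = 100
    seed: int = 0
    n_variogram_bins: int = 10
    outdir: str = "results"
    # optional second stage: best ecological predictors + cultural predictors
    stage2_predictors: list[str] = field(default_factory=list)
    stage2_selection: str = "top_k"  # or "rvi_threshold"
    stage2_top_k: int = 5
    stage2_rvi_threshold: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_against(self, table: pd.DataFrame) -> None:
        cols = set(table.columns)
        missing = [c for c in [self.outcome, *self.predictors, *self.forced_in,
                               *self.transforms, *self.factors, *self.drop_where] if c not in cols
                   and c != "abs_latitude"]
        if missing:
            raise ValueError(f"config references missing columns: {sorted(set(missing))}")
        for col, spec in self.factors.items():
            base = spec.get("baseline")
            levels = set(table[col].dropna().unique())
            if base not in levels:
                raise ValueError(f"baseline {base!r} not among levels of factor {col}: {sorted(map(str, levels))}")


@dataclass
class PreparedData:
    """Model-ready data after filtering, transforms, dummy coding and listwise deletion."""

    design: pd.DataFrame            # expanded candidate columns, no intercept
    y: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    candidate_taxa: list[list[str]]
    site_ids: list[str]
    term_map: dict[str, list[str]]  # term -> design columns
    n_input: int
    n_used: int
    drop_report: dict[str, int]


def read_site_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if "candidate_taxa" in table.columns and table["candidate_taxa"].dtype == object:
        first = table["candidate_taxa"].iloc[0]
        if isinstance(first, str):
            table["candidate_taxa"] = table["candidate_taxa"].str.split(";")
    return table


def prepare_data(site_table: pd.DataFrame, config: RunConfig) -> PreparedData:
    """Apply row filters, transforms and dummy coding, then listwise deletion.

    Deletion runs once over the union of the outcome and every candidate
    predictor so that all candidate models are fit on the identical observation
    set — required for valid AICc comparison.
    """
    config.validate_against(site_table)
    table = site_table.copy()
    n_input = len(table)
    drop_report: dict[str, int] = {}

    for col, val in config.drop_where.items():
        mask = table[col] == val
        drop_report[f"filter[{col}=={val}]"] = int(mask.sum())
        table = table[~mask]

    if "abs_latitude" in (config.predictors + config.forced_in) and "abs_latitude" not in table.columns:
        table["abs_latitude"] = table["lat"].abs()

    for col, kind in config.transforms.items():
        if kind == "none":
            continue
        if kind != "log":
            raise ValueError(f"unknown transform {kind!r} for {col}")
        vals = table[col]
        bad = table.index[vals.notna() & (vals <= 0)]
        if len(bad):
            raise ValueError(f"log transform of nonpositive value in column {col}, rows {bad.tolist()[:5]}")
        table[col] = np.log(vals)

    all_terms = config.forced_in + [p for p in config.predictors if p not in config.forced_in]
    design_cols: dict[str, pd.Series] = {}
    term_map: dict[str, list[str]] = {}
    for term in all_terms:
        if term in config.ordinals:
            codes = {str(k): v for k, v in config.ordinals[term].items()}
            design_cols[term] = table[term].map(lambda v: codes.get(str(v), np.nan))
            term_map[term] = [term]
        elif term in config.factors:
            base = config.factors[term]["baseline"]
            levels = [l for l in pd.unique(table[term].dropna()) if l != base]
            levels = sorted(levels, key=str)
            dummies = []
            for lvl in levels:
                cname = f"{term}={lvl}"
                design_cols[cname] = pd.Series(
                    np.where(table[term].isna(), np.nan, (table[term] == lvl).astype(float)),
                    index=table.index,
                )
                dummies.append(cname)
            if config.dummy_mode == "independent":
                for c in dummies:
                    term_map[c] = [c]
            else:
                term_map[term] = dummies
        else:
            design_cols[term] = pd.to_numeric(table[term], errors="coerce")
            term_map[term] = [term]

    design = pd.DataFrame(design_cols, index=table.index)
    y = pd.to_numeric(table[config.outcome], errors="coerce")
    complete = y.notna() & design.notna().all(axis=1)
    drop_report["listwise_deletion"] = int((~complete).sum())
    table = table[complete]
    design = design[complete]
    if len(table) == 0:
        raise ValueError("no rows remain after filtering and listwise deletion")

    return PreparedData(
        design=design.reset_index(drop=True),
        y=y[complete].to_numpy(dtype=float),
        lat=table["lat"].to_numpy(dtype=float),
        lon=table["lon"].to_numpy(dtype=float),
        candidate_taxa=[list(c) for c in table["candidate_taxa"]],
        site_ids=[str(s) for s in table["site_id"]],
        term_map=term_map,
        n_input=n_input,
        n_used=len(table),
        drop_report=drop_report,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def _averaging_analysis(prepared: PreparedData, config: RunConfig, forced_terms: list[str]):
    """Build the per-replicate analysis callable over prepared data."""

    def analysis(site_table: pd.DataFrame, tree, rng) -> dict[str, float]:
        cov = build_covariance_set(tree, site_table["taxon"], prepared.lat, prepared.lon,
                                   labels=prepared.site_ids)
        result = run_model_averaging(
            prepared.design, prepared.y, cov,
            term_map=prepared.term_map, forced_in=forced_terms,
            averaging_mode=config.averaging_mode,
        )
        return result.to_flat_dict()

    return analysis


def _aggregate_tables(agg, prepared: PreparedData):
    """Reshape aggregate means into the predictor table and dependence block."""
    terms = sorted({k.split(".", 1)[1] for k in agg.means if k.startswith("rvi.")})
    rows = []
    for t in terms:
        rows.append(
            {
                "predictor": t,
                "rvi": agg.means.get(f"rvi.{t}", np.nan),
                "beta": agg.means.get(f"beta.{t}", np.nan),
                "ci_lo": agg.means.get(f"ci_lo.{t}", np.nan),
                "ci_hi": agg.means.get(f"ci_hi.{t}", np.nan),
            }
        )
    table = pd.DataFrame(rows).sort_values("rvi", ascending=False, kind="mergesort").reset_index(drop=True)
    dependence = {k.split(".", 1)[1]: v for k, v in agg.means.items() if k.startswith("dependence.")}
    dependence["r2_best"] = agg.means.get("r2_best", np.nan)
    return table, dependence


def _signal_analysis(prepared: PreparedData):
    def analysis(site_table: pd.DataFrame, tree, rng) -> dict[str, float]:
        from pglspatial.covariance import phylo_vcv

        order = list(site_table["taxon"])
        sigma, h = phylo_vcv(tree, taxon_order=None, normalize=True)
        pos = {lbl: i for i, lbl in enumerate(tree.tips)}
        idx = np.array([pos[t] for t in order])
        sig = sigma[np.ix_(idx, idx)]
        res = pagel_lambda_signal(prepared.y, sig, np.diag(sig))
        return {"lambda_hat": res.lam_hat, "p_value": res.p_value, "n": res.n}

    return analysis


def run_signal(trees: TreeSample, site_table: pd.DataFrame, config: RunConfig):
    """Pagel's-lambda phylogenetic signal for the configured outcome, replicated."""
    cfg = config
    prepared = prepare_data(site_table, cfg)
    spec = ReplicateSpec(tree_source=trees, site_table=_sites_frame(prepared),
                         n_replicates=cfg.n_replicates, seed=cfg.seed)
    agg = run_replicates(spec, _signal_analysis(prepared))
    return {
        "outcome": cfg.outcome,
        "lambda_hat": agg.means["lambda_hat"],
        "p_value": agg.means["p_value"],
        "n": prepared.n_used,
        "n_replicates_effective": agg.n_effective,
    }


def _sites_frame(prepared: PreparedData) -> pd.DataFrame:
    return pd.DataFrame(
        {"site_id": prepared.site_ids, "candidate_taxa": prepared.candidate_taxa}
    )


def run_analysis(config: RunConfig, trees: TreeSample | None = None,
                 site_table: pd.DataFrame | None = None, write: bool = True) -> dict:
    """Execute the full pipeline and (optionally) write the report bundle.

    Stage 1 averages over all subsets of the configured candidate predictors.
    If ``stage2_predictors`` is set, the best stage-1 predictors (top-k by
    aggregated RVI, or those above an RVI threshold) are combined with the
    stage-2 (cultural) candidates and the averaging is repeated.
    """
    if trees is None:
        trees = read_trees(config.trees_path, format="newick" if config.trees_path.endswith((".nwk", ".newick", ".tre")) else "nexus")
    if site_table is None:
        site_table = read_site_table(config.sites_path)

    prepared = prepare_data(site_table, config)
    rep_spec = ReplicateSpec(tree_source=trees, site_table=_sites_frame(prepared),
                             n_replicates=config.n_replicates, seed=config.seed)
    agg = run_replicates(rep_spec, _averaging_analysis(prepared, config, config.forced_in))
    table1, dependence = _aggregate_tables(agg, prepared)

    signal = run_signal(trees, site_table, config)

    dist = haversine_matrix(prepared.lat, prepared.lon, site_ids=prepared.site_ids)
    variogram = empirical_variogram(prepared.y, dist, n_bins=config.n_variogram_bins)

    report = {
        "config": asdict(config),
        "n_input": prepared.n_input,
        "n_used": prepared.n_used,
        "drop_report": prepared.drop_report,
        "predictor_table": table1,
        "dependence": dependence,
        "signal": signal,
        "variogram": variogram,
        "replicate_log": agg.replicate_log,
        "n_replicates_effective": agg.n_effective,
        "seed": config.seed,
    }

    if config.stage2_predictors:
        if config.stage2_selection == "top_k":
            keep = table1["predictor"].head(config.stage2_top_k).tolist()
        elif config.stage2_selection == "rvi_threshold":
            keep = table1.loc[table1["rvi"] > config.stage2_rvi_threshold, "predictor"].tolist()
        else:
            raise ValueError(f"unknown stage2_selection {config.stage2_selection!r}")
        # selection happened on expanded columns; map dummies back to source terms
        sources = []
        for k in keep:
            src = k.split("=", 1)[0] if "=" in k else k
            if src not in sources:
                sources.append(src)
        cfg2 = RunConfig(**{**asdict(config),
                            "predictors": sources + [p for p in config.stage2_predictors if p not in sources],
                            "stage2_predictors": []})
        prepared2 = prepare_data(site_table, cfg2)
        spec2 = ReplicateSpec(tree_source=trees, site_table=_sites_frame(prepared2),
                              n_replicates=cfg2.n_replicates, seed=cfg2.seed)
        agg2 = run_replicates(spec2, _averaging_analysis(prepared2, cfg2, cfg2.forced_in))
        table2, dependence2 = _aggregate_tables(agg2, prepared2)
        report["stage2"] = {
            "selected_stage1": keep,
            "predictor_table": table2,
            "dependence": dependence2,
            "n_used": prepared2.n_used,
        }

    if write:
        write_report(report, Path(config.outdir))
    return report


def write_report(report: dict, outdir: Path) -> None:
    """Write the TSV tables plus one JSON carrying every reported number."""
    outdir.mkdir(parents=True, exist_ok=True)
    report["predictor_table"].to_csv(outdir / "predictor_table.tsv", sep="\t", index=False)
    report["variogram"].to_csv(outdir / "variogram.tsv", sep="\t", index=False)
    report["replicate_log"].to_csv(outdir / "replicate_log.tsv", sep="\t", index=False)
    pd.DataFrame([report["dependence"]]).to_csv(outdir / "dependence.tsv", sep="\t", index=False)
    if "stage2" in report:
        report["stage2"]["predictor_table"].to_csv(outdir / "predictor_table_stage2.tsv", sep="\t", index=False)
    (outdir / "report.json").write_text(json.dumps(_jsonable(report), sort_keys=True, indent=2))
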