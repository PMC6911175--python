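"""End-to-end orchestration: simulate -> design -> stats -> features -> model -> snp.

Stages communicate only through files on disk (TSV/BED/JSON), so each stage
can be re-run or tested in isolation.  A run manifest records the resolved
parameters of every stage (including defaulted ones), the output files with
their SHA-256 hashes, and the package version; re-running with the same
config and seed reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Callable

import pandas as pd

from . import __version__, io
from .essentiality_model import (
    GAParams,
    cross_validate,
    error_analysis,
    fit_model,
    ga_svm_select,
    label_sites,
    predict_scores,
)
from .feature_association import (
    proximity_enrichment,
    rank_features,
    tad_anchor_analysis,
)
from .library_design import add_controls, build_site_library, summarize_library
from .screen_stats import run_screen_stats
from .snp_enrichment import assign_snp_enhancer, score_comparison, trait_enrichment
from .synthetic_screen import (
    CountParams,
    SimConfig,
    TrueEssentiality,
    assign_site_essentiality,
    default_truth_weights,
    simulate_counts,
    simulate_features,
    simulate_genome,
    simulate_snp_catalog,
)

STAGES = ("simulate", "design", "stats", "features", "model", "snp")
STAGE_DEPS = {
    "simulate": (),
    "design": ("simulate",),
    "stats": ("simulate", "design"),
    "features": ("simulate", "stats"),
    "model": ("simulate", "stats", "features"),
    "snp": ("simulate", "model"),
}

DEFAULT_CONFIG: dict = {
    "stages": list(STAGES),
    "simulate": {
        "n_chroms": 2,
        "chrom_length": 30_000_000,
        "n_genes": 300,
        "n_sites": {"FOXA1": 250, "CTCF": 250},
        "effect_spec": {"DNase": 1.0, "H3K27ac": 0.7, "FOXA1_signal": 0.0},
        "essential_fraction": 0.05,
        "weights": None,  # None -> default_truth_weights()
        "intercept": 0.2,
        "noise_sd": 0.1,
        "prevalence": 0.05,
    },
    "design": {
        "guides_per_site": 12,
        "n_control_genes": 20,
        "guides_per_gene": 5,
        "n_negative": 60,
    },
    "stats": {
        "depth": 500.0,
        "dispersion": 0.1,
        "replicates": 2,
        "generations": 10.0,
        "cnv_effect": -0.1,
        "permutations": 500,
        "rra_permutations": 100,
    },
    "features": {"top_frac": 0.05, "proximity_distance": 100_000},
    "model": {
        "rank_threshold": "auto",
        "folds": 5,
        "ga": {"enabled": False, "population": 16, "iterations": 10},
    },
    "snp": {
        "traits": {"trait_enriched": [300, 3.0], "trait_null": [300, 1.0]},
        "alpha": 0.2,
    },
}


# mapping-valued parameters that a user config replaces outright (merging a
# user trait table with the default one would silently add traits)
_ATOMIC_KEYS = {"traits", "n_sites", "effect_spec", "weights"}


def _merge(default: dict, override: dict | None) -> dict:
    out = {}
    for k, v in default.items():
        if isinstance(v, dict) and k not in _ATOMIC_KEYS:
            out[k] = _merge(v, (override or {}).get(k))
        else:
            out[k] = (override or {}).get(k, v)
    for k, v in (override or {}).items():
        out.setdefault(k, v)
    return out


def resolve_config(config: dict | None) -> dict:
    cfg = _merge(DEFAULT_CONFIG, config or {})
    unknown = set(cfg["stages"]) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    enabled = set(cfg["stages"])
    for stage in cfg["stages"]:
        missing = [d for d in STAGE_DEPS[stage] if d not in enabled]
        if missing:
            raise ValueError(
                f"stage {stage!r} requires disabled stage(s): {missing}"
            )
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _truth_from_tsv(path: Path) -> TrueEssentiality:
    df = io.read_tsv(path)
    return TrueEssentiality(
        beta_true=pd.Series(
            df["beta_true"].to_numpy(), index=df["site_id"].to_numpy()
        ),
        weights={},
        intercept=0.0,
    )


# ---------------------------------------------------------------------------
# stage implementations (each: (config, seed, outdir) -> list of output paths)


def _stage_simulate(cfg: dict, seed: int, out: Path) -> list[Path]:
    p = cfg["simulate"]
    sim = SimConfig(
        n_chroms=p["n_chroms"],
        chrom_length=p["chrom_length"],
        n_genes=p["n_genes"],
        n_sites=p["n_sites"],
    )
    fixture = simulate_genome(sim, seed)
    features, latent = simulate_features(
        fixture,
        p["effect_spec"],
        seed,
        essential_fraction=p["essential_fraction"],
    )
    weights = p["weights"] or default_truth_weights()
    truth = assign_site_essentiality(
        features,
        weights,
        intercept=p["intercept"],
        noise_sd=p["noise_sd"],
        prevalence=p["prevalence"],
        seed=seed,
    )
    trait_spec = {t: tuple(v) for t, v in cfg["snp"]["traits"].items()}
    snps = simulate_snp_catalog(fixture, truth, trait_spec, seed)

    paths = list(io.write_fixture(fixture, out / "fixture").values())
    ft = features.rename_axis("site_id").reset_index()
    paths.append(io.write_tsv(ft, out / "features.tsv"))
    truth_df = truth.beta_true.rename("beta_true").rename_axis("site_id").reset_index()
    truth_df["latent_essential"] = truth_df["site_id"].isin(latent)
    paths.append(io.write_tsv(truth_df, out / "truth.tsv"))
    paths.append(io.write_tsv(snps, out / "snps.tsv"))
    return paths


def _stage_design(cfg: dict, seed: int, out: Path) -> list[Path]:
    p = cfg["design"]
    fixture = io.read_fixture(out / "fixture")
    manifest = build_site_library(
        fixture.sites, seed, guides_per_site=p["guides_per_site"]
    )
    genes = fixture.genes.nsmallest(p["n_control_genes"], "beta_gene")
    manifest = add_controls(
        manifest,
        genes["gene_id"].tolist(),
        guides_per_gene=p["guides_per_gene"],
        n_negative=p["n_negative"],
    )
    paths = [io.write_tsv(manifest.guides, out / "library.tsv")]
    summary = summarize_library(manifest)
    paths.append(
        io.write_tsv(summary.rename_axis("quantity").reset_index(), out / "library_summary.tsv")
    )
    return paths


def _stage_stats(cfg: dict, seed: int, out: Path) -> list[Path]:
    p = cfg["stats"]
    fixture = io.read_fixture(out / "fixture")
    library = io.read_tsv(out / "library.tsv")
    truth = _truth_from_tsv(out / "truth.tsv")
    params = CountParams(
        depth=p["depth"],
        dispersion=p["dispersion"],
        n_replicates=p["replicates"],
        generations=p["generations"],
        cnv_effect=p["cnv_effect"],
    )
    counts = simulate_counts(library, truth, fixture, params, seed)
    results = run_screen_stats(
        counts,
        fixture.sites,
        fixture.copy_segments,
        generations=p["generations"],
        n_permutations=p["permutations"],
        rra_permutations=p["rra_permutations"],
        seed=seed,
    )
    return [
        io.write_tsv(counts, out / "counts.tsv"),
        io.write_tsv(results, out / "site_results.tsv"),
    ]


def _stage_features(cfg: dict, seed: int, out: Path) -> list[Path]:
    p = cfg["features"]
    fixture = io.read_fixture(out / "fixture")
    features = io.read_tsv(out / "features.tsv").set_index("site_id")
    results = io.read_tsv(out / "site_results.tsv")
    ranking = rank_features([features], [results], top_frac=p["top_frac"])
    prox = proximity_enrichment(
        fixture.sites, results, fixture.genes, distance=p["proximity_distance"]
    )
    tad = tad_anchor_analysis(
        results,
        fixture.sites,
        fixture.tad_boundaries,
        fixture.anchors,
        h3k27ac=features["H3K27ac"],
        strict=False,
    )
    report = {
        "proximity": {
            "pct_all_sites_near": prox.pct_all_sites_near,
            "pct_essential_sites_near": prox.pct_essential_sites_near,
            "odds_ratio": prox.odds_ratio,
            "fisher_p": prox.fisher_p,
        },
        "tad_anchor": {
            k: v for k, v in tad.items() if k in ("tad_boundary", "anchor")
        },
    }
    return [
        io.write_tsv(ranking, out / "feature_ranking.tsv"),
        io.write_json(report, out / "association_report.json"),
    ]


def _stage_model(cfg: dict, seed: int, out: Path) -> list[Path]:
    p = cfg["model"]
    features = io.read_tsv(out / "features.tsv").set_index("site_id")
    results = io.read_tsv(out / "site_results.tsv")
    labels = label_sites(results, rank_threshold=p["rank_threshold"], seed=seed)
    use = features
    trace: list[float] = []
    if p["ga"]["enabled"]:
        selected, trace = ga_svm_select(
            features,
            labels,
            GAParams(
                population=p["ga"]["population"], iterations=p["ga"]["iterations"]
            ),
            seed=seed,
        )
        use = features[selected]
    cv = cross_validate(use, labels, folds=p["folds"], seed=seed)
    model = fit_model(use, labels)
    scores = predict_scores(model, features)
    errors = error_analysis(cv.per_site_score, labels, use)
    report = {
        "selected_features": cv.selected_features,
        "cv_auc": cv.cv_auc,
        "cv_aupr": cv.cv_aupr,
        "single_feature_aucs": cv.single_feature_aucs,
        "ga_trace": trace,
        "error_analysis": {
            "threshold": errors["threshold"],
            "skipped": errors["skipped"],
        },
        "roc_points": cv.roc_points.tolist(),
        "pr_points": cv.pr_points.tolist(),
    }
    return [
        io.write_tsv(labels, out / "labels.tsv"),
        io.write_tsv(
            scores.rename_axis("site_id").reset_index(), out / "scores.tsv"
        ),
        io.write_json(report, out / "model_report.json"),
    ]


def _stage_snp(cfg: dict, seed: int, out: Path) -> list[Path]:
    p = cfg["snp"]
    fixture = io.read_fixture(out / "fixture")
    snps = io.read_tsv(out / "snps.tsv")
    scores = io.read_tsv(out / "scores.tsv").set_index("site_id")["score"]
    labels = io.read_tsv(out / "labels.tsv")
    peaks = fixture.sites[["site_id", "chrom", "start", "end"]]
    assignments = assign_snp_enhancer(snps, dnase_peaks=None, tf_peaks=peaks)
    # predicted-essential cutoff: match the screen-wide essential prevalence,
    # not the balanced training set's
    prevalence = (labels["label"] == "essential").sum() / len(scores)
    cut = scores.quantile(1.0 - prevalence)
    ess_ids = scores.index[scores >= cut]
    essential = peaks[peaks["site_id"].isin(ess_ids)]
    enrich = trait_enrichment(
        assignments, essential, peaks, alpha=p["alpha"]
    )
    comparison = score_comparison(assignments, scores)
    return [
        io.write_tsv(assignments, out / "snp_assignments.tsv"),
        io.write_tsv(enrich, out / "snp_enrichment.tsv"),
        io.write_tsv(comparison, out / "snp_score_comparison.tsv"),
    ]


_STAGE_FN: dict[str, Callable[[dict, int, Path], list[Path]]] = {
    "simulate": _stage_simulate,
    "design": _stage_design,
    "stats": _stage_stats,
    "features": _stage_features,
    "model": _stage_model,
    "snp": _stage_snp,
}


def run_pipeline(
    config: dict | None,
    outdir: str | Path,
    seed: int = 0,
    stages: list[str] | None = None,
) -> dict:
    """Run the enabled stages in dependency order; return the run manifest.

    ``stages`` restricts execution to a subset (their upstream outputs must
    already exist in ``outdir``).  Stage failure aborts downstream stages;
    the manifest records the failure point.
    """
    cfg = resolve_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    todo = [s for s in STAGES if s in (stages or cfg["stages"])]
    manifest: dict = {
        "version": __version__,
        "seed": int(seed),
        "config": cfg,
        "stages": {},
    }
    for stage in todo:
        try:
            paths = _STAGE_FN[stage](cfg, int(seed), out)
        except Exception as exc:  # record the failure point, then re-raise
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            io.write_json(manifest, out / "run_manifest.json")
            raise
        manifest["stages"][stage] = {
            "status": "ok",
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in paths},
        }
    io.write_json(manifest, out / "run_manifest.json")
    return manifest
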