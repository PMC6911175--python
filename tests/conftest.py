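"""Shared simulated-screen fixtures.

Everything is generated at test time from the package's own simulator; the
medium-size screen bundle is session-scoped because several modules test
against the same recovered results.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest

from cistrome_ess.library_design import LibraryManifest, add_controls, build_site_library
from cistrome_ess.screen_stats import run_screen_stats
from cistrome_ess.synthetic_screen import (
    CountParams,
    GenomeFixture,
    SimConfig,
    TrueEssentiality,
    assign_site_essentiality,
    default_truth_weights,
    simulate_counts,
    simulate_features,
    simulate_genome,
)

SEED = 20240917


@dataclass
class ScreenBundle:
    fixture: GenomeFixture
    features: pd.DataFrame
    truth: TrueEssentiality
    library: LibraryManifest
    counts: pd.DataFrame
    results: pd.DataFrame


def make_screen(
    seed: int,
    n_sites: int = 600,
    guides_per_site: int = 12,
    effect_spec: dict | None = None,
    weights: dict | None = None,
    noise_sd: float = 0.1,
    params: CountParams | None = None,
    n_permutations: int = 500,
    n_negative: int = 80,
) -> ScreenBundle:
    """Simulate and analyse one screen end to end."""
    cfg = SimConfig(
        n_sites={"FOXA1": n_sites // 2, "CTCF": n_sites - n_sites // 2},
        n_genes=250,
    )
    fixture = simulate_genome(cfg, seed)
    if effect_spec is None:
        effect_spec = {"DNase": 1.0, "H3K27ac": 0.7, "FOXA1_signal": 0.0}
    features, _ = simulate_features(fixture, effect_spec, seed)
    if weights is None:
        weights = {k: 2.2 * v for k, v in default_truth_weights().items()}
    truth = assign_site_essentiality(
        features, weights, noise_sd=noise_sd, prevalence=0.05, seed=seed
    )
    manifest = build_site_library(fixture.sites, seed, guides_per_site=guides_per_site)
    genes = fixture.genes.nsmallest(20, "beta_gene")["gene_id"].tolist()
    manifest = add_controls(manifest, genes, guides_per_gene=5, n_negative=n_negative)
    params = params or CountParams()
    counts = simulate_counts(manifest.guides, truth, fixture, params, seed)
    results = run_screen_stats(
        counts,
        fixture.sites,
        fixture.copy_segments,
        generations=params.generations,
        n_permutations=n_permutations,
        rra_permutations=100,
        seed=seed,
    )
    return ScreenBundle(fixture, features, truth, manifest, counts, results)


@pytest.fixture(scope="session")
def screen() -> ScreenBundle:
    """A medium screen with the default feature-effect structure."""
    return make_screen(SEED)


@pytest.fixture(scope="session")
def null_screen() -> ScreenBundle:
    """A screen with no selection signal at all (beta_true = 0 everywhere)."""
    return make_screen(
        SEED + 1,
        n_sites=400,
        effect_spec={},
        weights={},
        noise_sd=0.0,
        params=CountParams(cnv_effect=0.0),
        n_permutations=1000,
        n_negative=800,
    )
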