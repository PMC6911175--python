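"""Synthetic screen fixtures with known ground truth.

This module generates every input the downstream analysis consumes — a genome
annotation with genes, binding sites, TAD boundaries, CTCF loop anchors and
copy-number segments; per-site epigenomic feature tables; a continuous
ground-truth selection coefficient per site; negative-binomial guide count
tables under an exponential-growth selection model; and a trait-associated
SNP catalog with configurable enrichment in essential enhancers.

The generative model, briefly:

* Binding sites are drawn per selection class (strong-signal, proximal to
  essential genes, constitutive, cell-specific).  A configurable fraction is
  placed within 50 kb of genes in the lowest decile of the gene-level
  selection score, mirroring how proximity-selected sites enter a cistrome
  library.
* Signal features (DNase, H3K27ac, ...) are log-scale Gaussian around a
  common baseline; sites latently marked essential receive per-feature mean
  shifts.
* The true per-site selection coefficient ``beta_true`` is a linear function
  of the (standardised) features plus Gaussian noise, re-centred so that a
  requested prevalence of sites falls below zero (negative = depleting).
* Guide counts: day-0 counts are negative binomial around a lognormal
  library-representation mean; endpoint means are scaled by
  ``2**(beta_effective * generations)`` where ``beta_effective`` adds a
  copy-number confounder of ``cnv_effect`` per copy above diploid.
  Safe-harbor (AAVS1) control guides are neutral; essential-gene positive
  controls draw strongly negative coefficients.
* SNPs land inside binding-site ("enhancer") intervals with per-trait fold
  enrichment in essential (beta_true < 0) enhancers.

All operations are deterministic given the master seed; each draws from its
own stream (see :mod:`cistrome_ess._rng`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import stream

SIGNAL_FEATURES = (
    "DNase",
    "H3K27ac",
    "H3K4me2",
    "FOXA1_signal",
    "CTCF_signal",
    "ER_signal",
)

HISTONE_FEATURES = frozenset({"H3K27ac", "H3K4me2", "H3K4me1", "H3K4me3"})


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimConfig:
    """Parameters of the simulated genome annotation.

    ``n_sites`` maps factor name to site count; class proportions are per
    factor and must sum to 1.  ``prox_fraction``, when set, overrides the
    proportion of FOXA1 sites in the ``near_essential_gene`` class (the
    proximity-selected arm of the library).
    """

    n_chroms: int = 2
    chrom_length: int = 30_000_000
    n_genes: int = 300
    n_sites: Mapping[str, int] = field(
        default_factory=lambda: {"FOXA1": 150, "CTCF": 150}
    )
    class_proportions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "FOXA1": {"strong_signal": 0.817, "near_essential_gene": 0.183},
            "CTCF": {"constitutive": 0.6, "cell_specific": 0.4},
        }
    )
    prox_fraction: float | None = None
    prox_distance: int = 50_000
    site_width: tuple[int, int] = (200, 500)
    essential_gene_fraction: float = 0.10
    n_tads_per_chrom: int = 8
    boundary_width: int = 10_000
    n_anchors_per_chrom: int = 10
    anchor_width: int = 10_000
    head_to_head_fraction: float = 0.7
    n_copy_segments_per_chrom: int = 6
    copy_number_probs: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.10, 2: 0.60, 3: 0.20, 4: 0.10}
    )

    def resolved_class_proportions(self) -> dict[str, dict[str, float]]:
        props = {f: dict(p) for f, p in self.class_proportions.items()}
        if self.prox_fraction is not None:
            if not 0 <= self.prox_fraction <= 1:
                raise ValueError("prox_fraction must be in [0, 1]")
            if "FOXA1" in props:
                props["FOXA1"] = {
                    "strong_signal": 1.0 - self.prox_fraction,
                    "near_essential_gene": self.prox_fraction,
                }
        return props


@dataclass
class GenomeFixture:
    """A simulated annotation context: genes, sites, domains, copy number.

    Intervals are 0-based half-open throughout.  ``copy_segments`` tile each
    chromosome without gaps or overlap.
    """

    chrom_sizes: dict[str, int]
    genes: pd.DataFrame  # gene_id, chrom, tss, strand, beta_gene, expression
    sites: pd.DataFrame  # site_id, chrom, start, end, summit, factor, ...
    tad_boundaries: pd.DataFrame  # chrom, start, end
    anchors: pd.DataFrame  # chrom, start, end, head_to_head
    copy_segments: pd.DataFrame  # chrom, start, end, copy_number

    def site_copy_number(self) -> pd.Series:
        """Copy number of the segment containing each site summit."""
        out = np.full(len(self.sites), 2, dtype=int)
        for chrom, seg in self.copy_segments.groupby("chrom"):
            mask = (self.sites["chrom"] == chrom).to_numpy()
            if not mask.any():
                continue
            seg = seg.sort_values("start")
            idx = np.searchsorted(
                seg["start"].to_numpy(), self.sites.loc[mask, "summit"].to_numpy(),
                side="right",
            ) - 1
            out[mask] = seg["copy_number"].to_numpy()[idx.clip(0)]
        return pd.Series(out, index=self.sites["site_id"].to_numpy(), name="copy_number")

    def summary(self) -> pd.DataFrame:
        """Per-factor site counts plus a total column (library-table layout)."""
        counts = self.sites["factor"].value_counts().to_dict()
        row = {f: counts.get(f, 0) for f in sorted(counts)}
        row["total"] = int(sum(counts.values()))
        return pd.DataFrame([row], index=["binding_sites"])


@dataclass
class TrueEssentiality:
    """Ground-truth per-site selection with the generative weights recorded."""

    beta_true: pd.Series  # indexed by site_id; negative = depleting
    weights: dict[str, float]
    intercept: float

    @property
    def essential_ids(self) -> np.ndarray:
        return self.beta_true.index[self.beta_true.to_numpy() < 0].to_numpy()


@dataclass
class CountParams:
    """Negative-binomial screen count model parameters.

    depth
        mean day-0 reads per guide (library representation is lognormal
        around it, sigma ``rep_sigma``).
    dispersion
        NB dispersion alpha; variance = mu + alpha * mu**2.
    generations
        effective population doublings between day 0 and the endpoint, the
        scale linking selection to log2 fold change (LFC = beta * G).
    cnv_effect
        additive shift of beta per copy above diploid (multi-cut toxicity).
    """

    depth: float = 500.0
    dispersion: float = 0.1
    n_replicates: int = 2
    generations: float = 10.0
    rep_sigma: float = 0.25
    cnv_effect: float = -0.1
    pos_control_beta_mean: float = -0.5
    pos_control_beta_sd: float = 0.1


# ---------------------------------------------------------------------------
# helpers


def _largest_remainder(total: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Integer class counts summing to ``total``, each within 1 of exact."""
    keys = list(proportions)
    raw = np.array([proportions[k] for k in keys], dtype=float)
    if raw.sum() <= 0:
        raise ValueError("class proportions must sum to a positive value")
    raw = raw / raw.sum() * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return dict(zip(keys, base.tolist()))


def _check_config(config: SimConfig) -> None:
    wmin, wmax = config.site_width
    if wmin < 2 or wmax < wmin:
        raise ValueError("site_width must satisfy 2 <= min <= max")
    if wmax >= config.chrom_length // 10:
        raise ValueError(
            f"site width {wmax} does not fit chromosomes of length "
            f"{config.chrom_length}"
        )
    if config.n_chroms < 1 or config.n_genes < 10:
        raise ValueError("need at least 1 chromosome and 10 genes")
    total_sites = sum(config.n_sites.values())
    if total_sites * wmax > config.n_chroms * config.chrom_length:
        raise ValueError("requested sites cannot fit in the genome")
    probs = config.copy_number_probs
    if any(cn < 0 for cn in probs):
        raise ValueError("copy numbers must be >= 0")


# ---------------------------------------------------------------------------
# operations


def simulate_genome(config: SimConfig, seed: int) -> GenomeFixture:
    """Draw a genome annotation fixture.

    Class proportions are honoured to within one site per class (largest
    remainder apportionment); sites in the ``near_essential_gene`` class are
    placed with their summit within ``prox_distance`` of a TSS from the
    lowest decile of ``beta_gene``.
    """
    _check_config(config)
    rng = stream(seed, "simulate_genome")
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_sizes = {c: int(config.chrom_length) for c in chroms}

    # genes: a background population plus a strongly depleting minority so a
    # bottom decile with clear essential character exists
    n = config.n_genes
    gene_chrom = rng.choice(chroms, size=n)
    tss = rng.integers(10_000, config.chrom_length - 10_000, size=n)
    is_ess = rng.random(n) < config.essential_gene_fraction
    beta_gene = np.where(
        is_ess, rng.normal(-1.0, 0.3, size=n), rng.normal(0.0, 0.3, size=n)
    )
    genes = pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(n)],
            "chrom": gene_chrom,
            "tss": tss,
            "strand": rng.choice(["+", "-"], size=n),
            "beta_gene": beta_gene,
            "expression": rng.gamma(2.0, 1.5, size=n),
        }
    )

    decile_cut = genes["beta_gene"].quantile(0.10)
    bottom = genes[genes["beta_gene"] <= decile_cut]

    wmin, wmax = config.site_width
    props = config.resolved_class_proportions()
    rows = []
    for factor, n_sites in config.n_sites.items():
        if factor not in props:
            raise ValueError(f"no class proportions for factor {factor!r}")
        counts = _largest_remainder(int(n_sites), props[factor])
        i = 0
        for cls, k in counts.items():
            for _ in range(k):
                w = int(rng.integers(wmin, wmax + 1))
                if cls == "near_essential_gene" and len(bottom):
                    g = bottom.iloc[int(rng.integers(len(bottom)))]
                    chrom = g["chrom"]
                    lo = max(wmax, int(g["tss"]) - config.prox_distance)
                    hi = min(
                        chrom_sizes[chrom] - wmax,
                        int(g["tss"]) + config.prox_distance,
                    )
                    summit = int(rng.integers(lo, hi + 1))
                else:
                    chrom = chroms[int(rng.integers(len(chroms)))]
                    summit = int(rng.integers(wmax, chrom_sizes[chrom] - wmax))
                off = int(rng.integers(1, w))  # start <= summit < end
                rows.append(
                    {
                        "site_id": f"{factor}_P{i:05d}",
                        "chrom": chrom,
                        "start": summit - off,
                        "end": summit - off + w,
                        "summit": summit,
                        "factor": factor,
                        "cell_specificity": rng.choice(
                            ["cellA_specific", "cellB_specific", "shared"],
                            p=[0.3, 0.3, 0.4],
                        ),
                        "selection_class": cls,
                        "context": rng.choice(["intronic", "intergenic"]),
                    }
                )
                i += 1
    sites = pd.DataFrame(rows)

    # TAD boundaries and loop anchors
    tad_rows, anchor_rows = [], []
    half_b = config.boundary_width // 2
    for chrom in chroms:
        L = chrom_sizes[chrom]
        bpos = np.sort(
            rng.integers(half_b, L - half_b, size=config.n_tads_per_chrom)
        )
        for p in bpos:
            tad_rows.append({"chrom": chrom, "start": int(p) - half_b, "end": int(p) + half_b})
        astart = rng.integers(0, L - config.anchor_width, size=config.n_anchors_per_chrom)
        for s in astart:
            anchor_rows.append(
                {
                    "chrom": chrom,
                    "start": int(s),
                    "end": int(s) + config.anchor_width,
                    "head_to_head": bool(rng.random() < config.head_to_head_fraction),
                }
            )
    tad_boundaries = pd.DataFrame(tad_rows)
    anchors = pd.DataFrame(anchor_rows)

    # copy-number segments tiling each chromosome
    cns = np.array(sorted(config.copy_number_probs))
    cnp = np.array([config.copy_number_probs[c] for c in cns], dtype=float)
    cnp = cnp / cnp.sum()
    seg_rows = []
    for chrom in chroms:
        L = chrom_sizes[chrom]
        k = max(1, config.n_copy_segments_per_chrom)
        cuts = np.sort(rng.choice(np.arange(1, L), size=k - 1, replace=False)) if k > 1 else np.array([], dtype=int)
        bounds = np.concatenate(([0], cuts, [L]))
        for s, e in zip(bounds[:-1], bounds[1:]):
            seg_rows.append(
                {
                    "chrom": chrom,
                    "start": int(s),
                    "end": int(e),
                    "copy_number": int(rng.choice(cns, p=cnp)),
                }
            )
    copy_segments = pd.DataFrame(seg_rows)

    return GenomeFixture(
        chrom_sizes=chrom_sizes,
        genes=genes,
        sites=sites,
        tad_boundaries=tad_boundaries,
        anchors=anchors,
        copy_segments=copy_segments,
    )


def _nearest_gene(sites: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Nearest gene per site by |TSS - summit|; ties go to the lower TSS."""
    out = np.empty(len(sites), dtype=object)
    for chrom, g in genes.groupby("chrom"):
        mask = (sites["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        g = g.sort_values(["tss", "gene_id"], kind="mergesort")
        tss = g["tss"].to_numpy()
        summits = sites.loc[mask, "summit"].to_numpy()
        right = np.searchsorted(tss, summits)
        left = np.clip(right - 1, 0, len(tss) - 1)
        right = np.clip(right, 0, len(tss) - 1)
        dl = np.abs(summits - tss[left])
        dr = np.abs(summits - tss[right])
        # tie -> lower coordinate, i.e. the left neighbour
        pick = np.where(dl <= dr, left, right)
        out[mask] = g.index.to_numpy()[pick]
    if (out == None).any():  # noqa: E711 — chromosome with no genes
        raise ValueError("a chromosome carries sites but no genes")
    near = genes.loc[out.astype(int)].reset_index(drop=True)
    return pd.DataFrame(
        {
            "distance_to_tss": np.abs(
                sites["summit"].to_numpy() - near["tss"].to_numpy()
            ),
            "nearest_gene_expression": near["expression"].to_numpy(),
            "nearest_gene_beta": near["beta_gene"].to_numpy(),
            "nearest_gene_id": near["gene_id"].to_numpy(),
        },
        index=sites["site_id"].to_numpy(),
    )


def simulate_features(
    fixture: GenomeFixture,
    effect_spec: Mapping[str, float],
    seed: int,
    essential_ids: Sequence[str] | None = None,
    essential_fraction: float = 0.05,
    baseline_mean: float = 2.0,
    baseline_sd: float = 1.0,
    motif_rate: float = 0.7,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-site feature table with effect shifts on a latent essential set.

    Signal features are drawn from a shared log-scale Gaussian baseline
    N(``baseline_mean``, ``baseline_sd``); for sites in the latent essential
    set, each feature named in ``effect_spec`` is shifted by the given amount
    (features with shift 0 stay exchangeable between groups).  Annotation
    features (TSS distance, nearest-gene expression/essentiality, copy
    number, motif presence) are derived from the fixture; ``effect_spec`` may
    shift those additively too.

    Returns the table (indexed by site_id) and the latent essential ids.
    """
    rng = stream(seed, "simulate_features")
    sites = fixture.sites
    ids = sites["site_id"].to_numpy()
    if essential_ids is None:
        k = int(round(essential_fraction * len(ids)))
        essential_ids = rng.choice(ids, size=k, replace=False)
    essential_ids = np.asarray(essential_ids)
    unknown = set(essential_ids) - set(ids)
    if unknown:
        raise ValueError(f"essential ids not in fixture: {sorted(unknown)[:3]}")

    table = pd.DataFrame(
        {f: rng.normal(baseline_mean, baseline_sd, size=len(ids)) for f in SIGNAL_FEATURES},
        index=ids,
    )
    ann = _nearest_gene(sites, fixture.genes)
    table["distance_to_tss"] = ann["distance_to_tss"].astype(float)
    table["nearest_gene_expression"] = ann["nearest_gene_expression"]
    table["nearest_gene_beta"] = ann["nearest_gene_beta"]
    table["copy_number"] = fixture.site_copy_number().to_numpy().astype(float)
    table["motif_presence"] = (rng.random(len(ids)) < motif_rate).astype(float)

    ess_mask = np.isin(ids, essential_ids)
    for feat, shift in effect_spec.items():
        if feat not in table.columns:
            raise ValueError(f"unknown feature in effect_spec: {feat!r}")
        table.loc[ess_mask, feat] += shift
    return table, essential_ids


def assign_site_essentiality(
    features: pd.DataFrame,
    weights: Mapping[str, float],
    intercept: float = 0.0,
    noise_sd: float = 0.1,
    prevalence: float | None = 0.05,
    seed: int = 0,
    standardize: bool = True,
    positive_scale: float = 0.05,
) -> TrueEssentiality:
    """Ground-truth selection coefficients as a linear function of features.

    ``beta_true = intercept + sum_f w_f * x_f + N(0, noise_sd)``, then shifted
    by its ``prevalence`` quantile so that exactly that fraction of sites is
    negative (depleting).  With ``prevalence=None`` no shift is applied.

    The positive branch is compressed by ``positive_scale`` (a screen's
    non-essential background is near neutral, while the linear score would
    otherwise put most sites under strong positive selection).  The map
    stays strictly monotone, so rank-based recovery statistics are
    unaffected; set ``positive_scale=1`` for the uncompressed linear model.
    """
    for f, w in weights.items():
        if f not in features.columns:
            raise ValueError(f"weight refers to unknown feature {f!r}")
        if not np.isfinite(w):
            raise ValueError(f"non-finite weight for {f!r}")
    rng = stream(seed, "assign_site_essentiality")
    raw = np.full(len(features), float(intercept))
    for f, w in weights.items():
        x = features[f].to_numpy(dtype=float)
        if standardize:
            sd = x.std()
            x = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        raw = raw + w * x
    if noise_sd > 0:
        raw = raw + rng.normal(0.0, noise_sd, size=len(features))
    if prevalence is not None:
        raw = raw - np.quantile(raw, prevalence)
    raw = np.where(raw < 0, raw, raw * positive_scale)
    beta = pd.Series(raw, index=features.index, name="beta_true")
    return TrueEssentiality(beta_true=beta, weights=dict(weights), intercept=float(intercept))


def simulate_counts(
    library: pd.DataFrame,
    truth: TrueEssentiality,
    fixture: GenomeFixture,
    params: CountParams,
    seed: int,
) -> pd.DataFrame:
    """Negative-binomial guide counts for day 0 and endpoint replicates.

    ``library`` needs columns ``guide_id``, ``site_id``, ``class`` (class in
    {site, gene_targeting, AAVS1_negative}).  Endpoint means are
    ``day0_mean * 2**(beta_effective * generations)`` with
    ``beta_effective = beta_true + cnv_effect * (copy_number - 2)`` for
    site-targeting guides, a strongly negative per-gene draw for positive
    controls, and 0 for safe-harbor controls.
    """
    rng = stream(seed, "simulate_counts")
    lib = library.reset_index(drop=True)
    cn = fixture.site_copy_number()

    beta_eff = np.zeros(len(lib))
    cls = lib["class"].to_numpy()
    site_ids = lib["site_id"].to_numpy()

    site_mask = cls == "site"
    missing = set(site_ids[site_mask]) - set(truth.beta_true.index)
    if missing:
        raise ValueError(f"guides map to sites without truth: {sorted(missing)[:3]}")
    if site_mask.any():
        b = truth.beta_true.loc[site_ids[site_mask]].to_numpy()
        c = cn.reindex(site_ids[site_mask]).fillna(2).to_numpy()
        beta_eff[site_mask] = b + params.cnv_effect * (c - 2)

    gene_mask = cls == "gene_targeting"
    if gene_mask.any():
        genes = pd.unique(site_ids[gene_mask])
        per_gene = dict(
            zip(
                genes,
                rng.normal(
                    params.pos_control_beta_mean,
                    params.pos_control_beta_sd,
                    size=len(genes),
                ),
            )
        )
        beta_eff[gene_mask] = [per_gene[g] for g in site_ids[gene_mask]]

    known = {"site", "gene_targeting", "AAVS1_negative"}
    bad = set(cls) - known
    if bad:
        raise ValueError(f"unknown guide classes: {sorted(bad)}")

    day0_mean = params.depth * rng.lognormal(0.0, params.rep_sigma, size=len(lib))
    end_mean = day0_mean * np.power(2.0, beta_eff * params.generations)

    def nb(mu: np.ndarray) -> np.ndarray:
        if params.dispersion <= 0:
            return rng.poisson(mu)
        r = 1.0 / params.dispersion
        p = r / (r + mu)
        return rng.negative_binomial(r, p)

    out = lib[["guide_id", "site_id", "class"]].copy()
    out["day0"] = nb(day0_mean)
    for i in range(params.n_replicates):
        out[f"rep{i + 1}"] = nb(end_mean)
    return out


def simulate_snp_catalog(
    fixture: GenomeFixture,
    truth: TrueEssentiality,
    trait_spec: Mapping[str, tuple[int, float]],
    seed: int,
) -> pd.DataFrame:
    """Trait-associated SNPs placed in enhancer space with per-trait folds.

    ``trait_spec`` maps trait name to (n_snps, fold).  A fold-1 trait samples
    enhancers proportional to length; fold f multiplies the sampling weight
    of essential enhancers (``beta_true < 0``) by f.  Positions are emitted
    1-based (GWAS-catalog convention).
    """
    rng = stream(seed, "simulate_snp_catalog")
    sites = fixture.sites.reset_index(drop=True)
    lengths = (sites["end"] - sites["start"]).to_numpy(dtype=float)
    ess = truth.beta_true.reindex(sites["site_id"]).to_numpy() < 0
    rows = []
    for trait, (n_snps, fold) in trait_spec.items():
        if fold < 0:
            raise ValueError(f"negative enrichment fold for trait {trait!r}")
        w = lengths * np.where(ess, fold, 1.0)
        if w.sum() == 0:
            raise ValueError("all sampling weights zero")
        idx = rng.choice(len(sites), size=int(n_snps), p=w / w.sum())
        for j, i in enumerate(idx):
            s = sites.iloc[int(i)]
            pos0 = int(rng.integers(s["start"], s["end"]))
            rows.append(
                {
                    "snp_id": f"rs_{trait}_{j:05d}",
                    "chrom": s["chrom"],
                    "pos": pos0 + 1,
                    "trait": trait,
                }
            )
    return pd.DataFrame(rows)


def default_truth_weights() -> dict[str, float]:
    """Generative weights mirroring the observed association ordering:
    open chromatin strongest, then active-enhancer marks, with TF binding
    strength uninformative."""
    return {
        "DNase": -0.5,
        "H3K27ac": -0.3,
        "nearest_gene_beta": 0.25,
        "nearest_gene_expression": -0.15,
    }
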