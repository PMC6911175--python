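"""Association of genomic/epigenomic features with binding-site essentiality.

Implements the desk-side association analyses around a cistrome screen:
window-mean signal extraction (150 bp around the summit, 300 bp for histone
marks), a feature ranking that compares the most-depleted fraction of sites
against the rest with a two-sided Mann-Whitney U test and averages p-values
across cell lines, Fisher proximity enrichment of essential sites near
essential genes, Kolmogorov-Smirnov comparisons of beta-score distributions
between site classes, and TAD-boundary / CTCF-loop-anchor analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_screen import HISTONE_FEATURES


# ---------------------------------------------------------------------------
# signal extraction


def extract_window_signal(
    track: pd.DataFrame,
    chrom: str,
    summit: int,
    feature_class: str = "tf",
    chrom_size: int | None = None,
    window: int | None = None,
) -> float:
    """Mean track signal in a window centered on the summit.

    ``track`` is bedGraph-like (chrom, start, end, value); uncovered bases
    count as 0.  The window is 150 bp for TF/accessibility features and
    300 bp for histone modifications, clipped at chromosome ends (the mean
    divides by the clipped window length).
    """
    if window is None:
        window = 300 if feature_class == "histone_modification" else 150
    lo = summit - window // 2
    hi = lo + window
    lo = max(lo, 0)
    if chrom_size is not None:
        hi = min(hi, chrom_size)
    if hi <= lo:
        return 0.0
    rows = track[track["chrom"] == chrom]
    s = np.maximum(rows["start"].to_numpy(), lo)
    e = np.minimum(rows["end"].to_numpy(), hi)
    cover = np.maximum(e - s, 0)
    return float((cover * rows["value"].to_numpy()).sum() / (hi - lo))


def signal_features_from_tracks(
    tracks: Mapping[str, pd.DataFrame],
    sites: pd.DataFrame,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-site window means for each named track (feature table columns)."""
    out = {}
    for name, track in tracks.items():
        cls = "histone_modification" if name in HISTONE_FEATURES else "tf"
        out[name] = [
            extract_window_signal(
                track,
                row["chrom"],
                int(row["summit"]),
                feature_class=cls,
                chrom_size=None if chrom_sizes is None else chrom_sizes[row["chrom"]],
            )
            for _, row in sites.iterrows()
        ]
    return pd.DataFrame(out, index=sites["site_id"].to_numpy())


# ---------------------------------------------------------------------------
# feature ranking


def rank_features(
    feature_tables: Sequence[pd.DataFrame],
    site_results: Sequence[pd.DataFrame],
    top_frac: float = 0.05,
) -> pd.DataFrame:
    """Rank features by association with the most-depleted sites.

    Per cell line, sites in the lowest ``top_frac`` of the CNV-adjusted beta
    form the essential group; each feature is compared between groups with a
    two-sided Mann-Whitney U test.  The returned table carries per-cell-line
    p-values, their arithmetic mean ``p_avg`` (ascending sort key) and the
    direction of the median difference.  Constant features get p = 1 and a
    flagged direction.
    """
    if not 0 < top_frac <= 0.5:
        raise ValueError("top_frac must be in (0, 0.5]")
    if len(feature_tables) != len(site_results) or not feature_tables:
        raise ValueError("need matching, nonempty feature tables and results")
    features = list(feature_tables[0].columns)
    pmat = np.ones((len(features), len(feature_tables)))
    direction = {}
    for j, (table, res) in enumerate(zip(feature_tables, site_results)):
        beta_col = (
            "beta_cnv_adjusted"
            if "beta_cnv_adjusted" in res and res["beta_cnv_adjusted"].notna().all()
            else "beta"
        )
        res = res.set_index("site_id")
        beta = res.loc[table.index, beta_col]
        cut = beta.quantile(top_frac)
        ess = (beta <= cut).to_numpy()
        for i, f in enumerate(features):
            x = table[f].to_numpy(dtype=float)
            a, b = x[ess], x[~ess]
            if np.ptp(x) == 0:
                pmat[i, j] = 1.0
                direction[f] = "undefined"
                continue
            pmat[i, j] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
            d = np.median(a) - np.median(b)
            direction.setdefault(f, "higher_in_essential" if d > 0 else "lower_in_essential")
    out = pd.DataFrame(
        {
            "feature": features,
            **{f"p_cellline_{j + 1}": pmat[:, j] for j in range(pmat.shape[1])},
            "p_avg": pmat.mean(axis=1),
            "direction": [direction.get(f, "undefined") for f in features],
        }
    )
    return out.sort_values("p_avg", kind="mergesort", ignore_index=True)


# ---------------------------------------------------------------------------
# proximity enrichment


@dataclass
class ProximityEnrichment:
    pct_all_sites_near: float
    pct_essential_sites_near: float
    pct_all_genes_near: float
    pct_essential_genes_near: float
    odds_ratio: float
    fisher_p: float
    table: tuple[tuple[int, int], tuple[int, int]]


def proximity_enrichment(
    sites: pd.DataFrame,
    site_results: pd.DataFrame,
    genes: pd.DataFrame,
    distance: int = 100_000,
    essential_site_fdr: float = 0.25,
    essential_gene_decile: float = 0.10,
) -> ProximityEnrichment:
    """Are essential sites enriched within ``distance`` of essential genes?

    Essential genes are the lowest ``essential_gene_decile`` of the
    gene-level beta; essential sites are negatively selected at
    FDR < ``essential_site_fdr``.  The Fisher test compares near-gene rates
    between essential and non-essential sites.
    """
    res = site_results.set_index("site_id")
    beta_col = (
        "beta_cnv_adjusted"
        if "beta_cnv_adjusted" in res and res["beta_cnv_adjusted"].notna().all()
        else "beta"
    )
    ess_sites = set(
        res.index[(res["fdr"] < essential_site_fdr) & (res[beta_col] < 0)]
    )
    if not ess_sites:
        raise ValueError("no essential sites at the requested FDR")
    gcut = genes["beta_gene"].quantile(essential_gene_decile)
    ess_genes = genes[genes["beta_gene"] <= gcut]
    if ess_genes.empty:
        raise ValueError("no essential genes in the lowest decile")

    near = np.zeros(len(sites), dtype=bool)
    for chrom, g in ess_genes.groupby("chrom"):
        mask = (sites["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        tss = np.sort(g["tss"].to_numpy())
        summit = sites["summit"].to_numpy()[mask]
        pos = np.searchsorted(tss, summit)
        dl = np.abs(summit - tss[np.clip(pos - 1, 0, len(tss) - 1)])
        dr = np.abs(summit - tss[np.clip(pos, 0, len(tss) - 1)])
        near[mask] = np.minimum(dl, dr) <= distance
    is_ess = sites["site_id"].isin(ess_sites).to_numpy()

    a = int((near & is_ess).sum())  # essential sites near essential genes
    b = int((~near & is_ess).sum())
    c = int((near & ~is_ess).sum())
    d = int((~near & ~is_ess).sum())
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")

    # gene side: genes near essential sites
    ess_site_rows = sites[is_ess]
    gnear = np.zeros(len(genes), dtype=bool)
    for chrom, srows in ess_site_rows.groupby("chrom"):
        mask = (genes["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        summits = np.sort(srows["summit"].to_numpy())
        tss = genes["tss"].to_numpy()[mask]
        pos = np.searchsorted(summits, tss)
        dl = np.abs(tss - summits[np.clip(pos - 1, 0, len(summits) - 1)])
        dr = np.abs(tss - summits[np.clip(pos, 0, len(summits) - 1)])
        gnear[mask] = np.minimum(dl, dr) <= distance
    gene_is_ess = (genes["beta_gene"] <= gcut).to_numpy()

    return ProximityEnrichment(
        pct_all_sites_near=100.0 * near.mean(),
        pct_essential_sites_near=100.0 * near[is_ess].mean(),
        pct_all_genes_near=100.0 * gnear.mean(),
        pct_essential_genes_near=100.0 * gnear[gene_is_ess].mean()
        if gene_is_ess.any()
        else float("nan"),
        odds_ratio=float(odds),
        fisher_p=float(p),
        table=((a, b), (c, d)),
    )


# ---------------------------------------------------------------------------
# class comparisons


def compare_site_classes(
    site_results: pd.DataFrame,
    class_map: Mapping[str, str],
    value_col: str = "beta_cnv_adjusted",
) -> dict:
    """Two-sample KS statistics between every pair of site classes.

    Returns ECDF support points per class and, per class pair, the KS
    statistic and p-value.  Classes with fewer than 2 members are rejected.
    """
    res = site_results.set_index("site_id")
    if value_col not in res or res[value_col].isna().all():
        value_col = "beta"
    values: dict[str, np.ndarray] = {}
    cm = pd.Series(class_map)
    for cls, ids in cm.groupby(cm.values):
        members = [i for i in ids.index if i in res.index]
        if len(members) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        values[str(cls)] = np.sort(res.loc[members, value_col].to_numpy(dtype=float))
    pairs = {}
    names = sorted(values)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ks = stats.ks_2samp(values[a], values[b])
            pairs[(a, b)] = {"statistic": float(ks.statistic), "p_value": float(ks.pvalue)}
    ecdf = {
        c: {"x": v, "y": np.arange(1, len(v) + 1) / len(v)} for c, v in values.items()
    }
    return {"ecdf": ecdf, "ks": pairs}


def strongest_site_classes(
    signal: pd.Series, quantile: float = 0.9
) -> dict[str, str]:
    """Partition sites into strongest-signal (top quantile) vs others."""
    cut = signal.quantile(quantile)
    return {
        sid: ("strongest" if v >= cut else "other") for sid, v in signal.items()
    }


# ---------------------------------------------------------------------------
# TAD / anchor analyses


def tad_anchor_analysis(
    site_results: pd.DataFrame,
    sites: pd.DataFrame,
    tad_boundaries: pd.DataFrame,
    anchors: pd.DataFrame,
    h3k27ac: pd.Series | None = None,
    boundary_pad: int = 10_000,
    essential_fdr: float = 0.25,
    strict: bool = True,
) -> dict:
    """Beta comparisons for boundary/anchor membership, plus H3K27ac tiers.

    A site belongs to a TAD boundary when its summit lies within
    ``boundary_pad`` of a boundary midpoint, and to an anchor when its
    summit falls inside an anchor interval flagged head-to-head.  Group
    comparisons use a two-sided Mann-Whitney U test on the CNV-adjusted
    beta.  When an H3K27ac feature is supplied, essential sites inside
    anchors, essential sites outside anchors, and all sites are compared
    pairwise on that signal.
    """
    res = site_results.set_index("site_id")
    beta_col = (
        "beta_cnv_adjusted"
        if "beta_cnv_adjusted" in res and res["beta_cnv_adjusted"].notna().all()
        else "beta"
    )
    s = sites.set_index("site_id")
    common = [i for i in s.index if i in res.index]
    s = s.loc[common]
    beta = res.loc[common, beta_col]

    in_boundary = np.zeros(len(s), dtype=bool)
    for chrom, b in tad_boundaries.groupby("chrom"):
        mask = (s["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        mid = np.sort(((b["start"] + b["end"]) // 2).to_numpy())
        summit = s["summit"].to_numpy()[mask]
        pos = np.searchsorted(mid, summit)
        dl = np.abs(summit - mid[np.clip(pos - 1, 0, len(mid) - 1)])
        dr = np.abs(summit - mid[np.clip(pos, 0, len(mid) - 1)])
        in_boundary[mask] = np.minimum(dl, dr) <= boundary_pad

    in_anchor = np.zeros(len(s), dtype=bool)
    hh = anchors[anchors["head_to_head"]] if "head_to_head" in anchors else anchors
    for chrom, a in hh.groupby("chrom"):
        mask = (s["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        summit = s["summit"].to_numpy()[mask]
        hit = np.zeros(summit.shape, dtype=bool)
        for _, row in a.iterrows():
            hit |= (summit >= row["start"]) & (summit < row["end"])
        in_anchor[mask] |= hit

    def group_test(member: np.ndarray, name: str) -> dict:
        if not member.any() or member.all():
            if strict:
                raise ValueError(f"no sites in or out of group {name!r}")
            return {"n_in": int(member.sum()), "skipped": True}
        u = stats.mannwhitneyu(
            beta[member], beta[~member], alternative="two-sided"
        )
        return {
            "n_in": int(member.sum()),
            "median_in": float(np.median(beta[member])),
            "median_out": float(np.median(beta[~member])),
            "p_value": float(u.pvalue),
        }

    out = {
        "tad_boundary": group_test(in_boundary, "tad_boundary"),
        "anchor": group_test(in_anchor, "anchor"),
    }

    if h3k27ac is not None:
        ess = (res.loc[common, "fdr"] < essential_fdr).to_numpy() & (
            beta.to_numpy() < 0
        )
        sig = h3k27ac.reindex(common).to_numpy(dtype=float)
        groups = {
            "anchor_essential": sig[ess & in_anchor],
            "other_essential": sig[ess & ~in_anchor],
            "all_sites": sig,
        }
        tiers = {k: {"n": int(len(v)), "median": float(np.median(v)) if len(v) else float("nan")} for k, v in groups.items()}
        if len(groups["anchor_essential"]) >= 2 and len(groups["other_essential"]) >= 2:
            tiers["anchor_vs_other_essential_p"] = float(
                stats.mannwhitneyu(
                    groups["anchor_essential"],
                    groups["other_essential"],
                    alternative="two-sided",
                ).pvalue
            )
        out["h3k27ac"] = tiers
    return out
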