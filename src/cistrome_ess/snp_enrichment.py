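"""GWAS-SNP assignment to enhancers and per-trait enrichment testing.

Each trait-associated variant is assigned an enhancer by a fallback
hierarchy: the overlapping DNase peak if any, else an overlapping
transcription-factor peak, else a 150-bp window centered on the SNP.  When
several peaks of a tier overlap, the peak whose midpoint is nearest the SNP
wins, so assignments are independent of input peak order.  Per-trait
enrichment over predicted essential enhancers uses a chi-square test on the
2x2 table of trait SNPs in/out of the essential set against the background
enhancer composition, falling back to Fisher's exact test when an expected
cell drops below 1, with Benjamini-Hochberg adjustment across traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

TIERS = ("dnase", "tf_peak", "window150")


@dataclass
class EnrichmentResult:
    trait: str
    n_snps: int
    n_in_essential: int
    fold_enrichment: float
    chi2_p: float
    adjusted_p: float
    used_fisher: bool = False


def _build_trees(peaks: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in peaks.groupby("chrom"):
        t = IntervalTree()
        for idx, row in grp.iterrows():
            if row["end"] > row["start"]:
                t[int(row["start"]) : int(row["end"])] = idx
        trees[chrom] = t
    return trees


def _best_hit(tree: IntervalTree | None, pos0: int) -> int | None:
    """Index of the overlapping interval with midpoint nearest ``pos0``."""
    if tree is None:
        return None
    hits = tree[pos0]
    if not hits:
        return None
    best = min(
        hits,
        key=lambda iv: (abs((iv.begin + iv.end) / 2.0 - pos0), iv.begin, iv.end),
    )
    return best.data


def assign_snp_enhancer(
    snps: pd.DataFrame,
    dnase_peaks: pd.DataFrame | None,
    tf_peaks: pd.DataFrame | None,
    window: int = 150,
) -> pd.DataFrame:
    """Assign every SNP an enhancer interval via the fallback hierarchy.

    ``snps`` columns: snp_id, chrom, pos (1-based; converted to 0-based
    internally), trait.  Peak frames need chrom/start/end and may carry an
    id column (``site_id`` or ``peak_id``) echoed as ``enhancer_id``.
    """
    dtrees = _build_trees(dnase_peaks) if dnase_peaks is not None else {}
    ttrees = _build_trees(tf_peaks) if tf_peaks is not None else {}

    def peak_id(peaks: pd.DataFrame, idx) -> str | None:
        for col in ("site_id", "peak_id"):
            if col in peaks.columns:
                return str(peaks.loc[idx, col])
        return None

    rows = []
    half = window // 2
    for _, snp in snps.iterrows():
        pos0 = int(snp["pos"]) - 1
        chrom = snp["chrom"]
        hit = _best_hit(dtrees.get(chrom), pos0)
        if hit is not None:
            tier, src, idx = "dnase", dnase_peaks, hit
        else:
            hit = _best_hit(ttrees.get(chrom), pos0)
            if hit is not None:
                tier, src, idx = "tf_peak", tf_peaks, hit
            else:
                tier, src, idx = "window150", None, None
        if tier == "window150":
            start, end, eid = pos0 - half, pos0 - half + window, None
        else:
            start = int(src.loc[idx, "start"])
            end = int(src.loc[idx, "end"])
            eid = peak_id(src, idx)
        rows.append(
            {
                "snp_id": snp["snp_id"],
                "trait": snp["trait"],
                "chrom": chrom,
                "enh_start": start,
                "enh_end": end,
                "tier": tier,
                "enhancer_id": eid,
            }
        )
    return pd.DataFrame(rows)


def _overlaps_set(
    assignments: pd.DataFrame, intervals: pd.DataFrame
) -> np.ndarray:
    trees = _build_trees(intervals)
    out = np.zeros(len(assignments), dtype=bool)
    for i, (_, row) in enumerate(assignments.iterrows()):
        t = trees.get(row["chrom"])
        if t is not None and t.overlap(row["enh_start"], row["enh_end"]):
            out[i] = True
    return out


def trait_enrichment(
    assignments: pd.DataFrame,
    essential_enhancers: pd.DataFrame,
    background_enhancers: pd.DataFrame,
    alpha: float = 0.2,
    continuity_correction: bool = False,
) -> pd.DataFrame:
    """Per-trait enrichment of SNP-bearing enhancers in the essential set.

    The 2x2 table per trait is [[SNPs in essential, SNPs outside],
    [essential background enhancers, other background enhancers]].
    fold_enrichment = (in-essential SNP rate) / (essential background rate).
    ``significant`` marks adjusted_p < alpha with fold > 1.
    """
    n_bg = len(background_enhancers)
    n_ess_bg = len(essential_enhancers)
    if n_ess_bg == 0 or n_bg == 0 or n_ess_bg > n_bg:
        raise ValueError("essential set must be a nonempty subset of background")
    in_ess = pd.Series(
        _overlaps_set(assignments, essential_enhancers), index=assignments.index
    )
    rows = []
    for trait, grp in assignments.groupby("trait"):
        k = int(in_ess.loc[grp.index].sum())
        n = len(grp)
        table = np.array([[k, n - k], [n_ess_bg, n_bg - n_ess_bg]], dtype=float)
        expected = stats.contingency.expected_freq(table)
        used_fisher = (expected < 1).any()
        if used_fisher:
            p = float(stats.fisher_exact(table.astype(int))[1])
        else:
            p = float(
                stats.chi2_contingency(table, correction=continuity_correction)[1]
            )
        fold = (k / n) / (n_ess_bg / n_bg)
        rows.append(
            {
                "trait": trait,
                "n_snps": n,
                "n_in_essential": k,
                "fold_enrichment": fold,
                "chi2_p": p,
                "used_fisher": used_fisher,
            }
        )
    out = pd.DataFrame(rows)
    out["adjusted_p"] = multipletests(out["chi2_p"], method="fdr_bh")[1]
    out["significant"] = (out["adjusted_p"] < alpha) & (out["fold_enrichment"] > 1)
    return out.sort_values("adjusted_p", ignore_index=True)


def score_comparison(
    trait_assignments: pd.DataFrame,
    all_scores: pd.Series,
) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of predicted scores per trait.

    Scores of enhancers carrying a trait's variants (matched by
    ``enhancer_id``) are compared against the full score distribution with a
    two-sided rank-sum test; medians of both sets are reported.
    """
    rows = []
    for trait, grp in trait_assignments.groupby("trait"):
        ids = grp["enhancer_id"].dropna().unique()
        svals = all_scores.reindex(ids).dropna()
        if len(svals) < 2:
            raise ValueError(f"trait {trait!r} has fewer than 2 scored enhancers")
        stat = stats.ranksums(svals, all_scores.to_numpy())
        rows.append(
            {
                "trait": trait,
                "n_enhancers": int(len(svals)),
                "median_trait": float(np.median(svals)),
                "median_all": float(np.median(all_scores)),
                "p_value": float(stat.pvalue),
            }
        )
    return pd.DataFrame(rows)
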