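"""Per-site selection estimation from guide count tables.

The estimator chain mirrors MAGeCK-style screen analysis at the level of its
observable semantics:

1. median-of-ratios normalisation with a pseudocount;
2. per-guide log2 fold change (endpoint mean vs day-0 mean);
3. a per-site beta-score: the trimmed mean of guide LFCs divided by the
   effective number of population doublings G, so beta is on a
   per-generation selection scale (negative = depleted/essential);
4. a two-sided permutation p-value against a null built by resampling
   site-sized guide sets from the safe-harbor (AAVS1) control guides,
   with Benjamini-Hochberg FDR across sites;
5. an alpha-RRA rank-aggregation score: guides are ranked genome-wide by
   LFC (most depleted first), ranks are normalised to (0,1), and a site's
   score is the minimum over its alpha-passing guides j of
   P(U_(j) <= r_(j)) under the uniform order-statistic (Beta) distribution —
   smaller means stronger negative selection;
6. copy-number correction: a least-squares fit of beta on copy number over
   all sites is subtracted, re-centred at diploid, removing the multi-cut
   depletion trend that amplified loci induce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._rng import stream

RESULT_COLUMNS = [
    "site_id",
    "beta",
    "beta_cnv_adjusted",
    "lfc",
    "p_value",
    "fdr",
    "neg_rank",
    "n_guides",
]


@dataclass
class NormalizedCounts:
    matrix: pd.DataFrame  # guide x sample, normalized + pseudocount
    size_factors: pd.Series
    pseudocount: float
    guide_info: pd.DataFrame  # guide_id, site_id, class


def _sample_columns(counts: pd.DataFrame) -> list[str]:
    meta = {"guide_id", "site_id", "class"}
    return [c for c in counts.columns if c not in meta]


def normalize_counts(
    counts: pd.DataFrame,
    method: str = "median_ratio",
    pseudocount: float = 0.5,
    reference: str | None = None,
) -> NormalizedCounts:
    """Median-of-ratios normalisation, size factors anchored at the reference.

    Size factors are the per-sample median of count ratios to the per-guide
    geometric mean, computed over guides with nonzero counts in every
    sample, then rescaled so the reference sample (default: first column,
    normally day 0) has factor exactly 1.
    """
    samples = _sample_columns(counts)
    if len(samples) < 2:
        raise ValueError("need a reference and at least one endpoint sample")
    mat = counts[samples].to_numpy(dtype=float)
    if (mat.sum(axis=0) == 0).any():
        bad = [s for s, tot in zip(samples, mat.sum(axis=0)) if tot == 0]
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    if method == "median_ratio":
        nz = (mat > 0).all(axis=1)
        if not nz.any():
            raise ValueError("no guide has nonzero counts in all samples")
        logs = np.log(mat[nz])
        gm = logs.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logs - gm, axis=0))
    elif method == "total":
        tot = mat.sum(axis=0)
        sf = tot / tot.mean()
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    ref = reference or samples[0]
    sf = sf / sf[samples.index(ref)]
    norm = mat / sf + pseudocount
    return NormalizedCounts(
        matrix=pd.DataFrame(norm, columns=samples, index=counts["guide_id"].to_numpy()),
        size_factors=pd.Series(sf, index=samples, name="size_factor"),
        pseudocount=pseudocount,
        guide_info=counts[["guide_id", "site_id", "class"]].reset_index(drop=True),
    )


def guide_lfc(
    norm: NormalizedCounts,
    reference_cols: list[str] | None = None,
    endpoint_cols: list[str] | None = None,
) -> pd.Series:
    """Per-guide log2 fold change: log2(mean endpoint) - log2(mean day 0)."""
    samples = list(norm.matrix.columns)
    ref = reference_cols or [samples[0]]
    end = endpoint_cols or [s for s in samples if s not in ref]
    if not end:
        raise ValueError("no endpoint samples")
    lfc = np.log2(norm.matrix[end].mean(axis=1)) - np.log2(
        norm.matrix[ref].mean(axis=1)
    )
    lfc.name = "lfc"
    return lfc


def _trimmed_mean(x: np.ndarray, trim: float, axis: int = -1) -> np.ndarray:
    if trim <= 0:
        return np.mean(x, axis=axis)
    return stats.trim_mean(x, trim, axis=axis)


def control_null_pvalues(
    obs: pd.Series,
    sizes: pd.Series,
    ctl: np.ndarray,
    trim: float = 0.1,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Two-sided p per site vs a control-resampling null of matching size.

    ``obs`` maps site_id to its observed site-level LFC statistic; the null
    for a site with s guides is the trimmed mean of s draws (with
    replacement) from the control-guide LFC pool ``ctl``.
    """
    rng = stream(seed, "estimate_beta")
    pvals: dict = {}
    for s in np.unique(sizes.to_numpy()):
        draw = ctl[rng.integers(0, ctl.size, size=(n_permutations, int(s)))]
        null = _trimmed_mean(draw, trim, axis=1)
        anull = np.sort(np.abs(null))
        for sid in sizes.index[sizes.to_numpy() == s]:
            ge = anull.size - np.searchsorted(anull, abs(obs[sid]), side="left")
            pvals[sid] = (1.0 + ge) / (n_permutations + 1.0)
    return pvals


def estimate_beta(
    lfc: pd.Series,
    guide_map: pd.DataFrame,
    generations: float = 10.0,
    trim: float = 0.1,
    n_permutations: int = 1000,
    seed: int = 0,
    control_class: str = "AAVS1_negative",
) -> pd.DataFrame:
    """Per-site beta with control-resampling p-values and BH FDR.

    beta = trimmed mean (``trim`` per tail) of guide LFCs / ``generations``.
    The null for a site with s guides is the trimmed mean of s LFCs sampled
    with replacement from the control-guide pool; p is two-sided.
    ``neg_rank`` ranks sites by ascending beta (1 = most depleted).
    """
    gm = guide_map.set_index("guide_id")
    site_lfc = lfc.groupby(gm.loc[lfc.index, "site_id"].to_numpy())
    ctl_guides = gm.index[gm["class"] == control_class]
    ctl = lfc.reindex(ctl_guides).dropna().to_numpy()
    if ctl.size == 0:
        raise ValueError("no control guides for the permutation null")
    site_guides = gm[gm["class"] == "site"]
    sizes = site_guides.groupby("site_id").size()
    if (sizes == 0).any():
        raise ValueError("site with zero guides")
    if ctl.size < sizes.max():
        warnings.warn(
            "fewer control guides than the largest site; null resamples with "
            "replacement",
            stacklevel=2,
        )

    obs = {}
    for sid, grp in site_lfc:
        if sid in sizes.index:
            obs[sid] = float(_trimmed_mean(grp.to_numpy(), trim))
    pvals = control_null_pvalues(
        pd.Series(obs), sizes, ctl, trim=trim, n_permutations=n_permutations, seed=seed
    )
    ids = list(sizes.index)
    res = pd.DataFrame(
        {
            "site_id": ids,
            "beta": [obs[i] / generations for i in ids],
            "lfc": [obs[i] for i in ids],
            "p_value": [pvals[i] for i in ids],
            "n_guides": sizes.loc[ids].to_numpy(),
        }
    )
    res["fdr"] = multipletests(res["p_value"], method="fdr_bh")[1]
    res["beta_cnv_adjusted"] = np.nan
    res["neg_rank"] = res["beta"].rank(method="first").astype(int)
    return res[RESULT_COLUMNS]


# ---------------------------------------------------------------------------
# alpha-RRA


def _rho(sorted_ranks: np.ndarray, alpha: float) -> float:
    """min_j P(U_(j) <= r_(j)) over alpha-passing guides; 1.0 if none pass."""
    keep = sorted_ranks < alpha
    if not keep.any():
        return 1.0
    j = np.arange(1, len(sorted_ranks) + 1)[keep]
    r = sorted_ranks[keep]
    return float(np.min(stats.beta.cdf(r, j, len(sorted_ranks) - j + 1)))


def rra_score(
    lfc: pd.Series,
    guide_map: pd.DataFrame,
    alpha_cutoff: float = 0.25,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """alpha-RRA score per site plus a permutation p-value.

    Guides are ranked by LFC ascending (most depleted first) and ranks are
    normalised to (0, 1) by rank/(n+1).  The permutation null redraws guide
    sets of the same size uniformly from all guides.
    """
    if not 0 < alpha_cutoff <= 1:
        raise ValueError("alpha_cutoff must be in (0, 1]")
    gm = guide_map.set_index("guide_id")
    ranks = pd.Series(
        stats.rankdata(lfc.to_numpy()) / (len(lfc) + 1.0), index=lfc.index
    )
    site_guides = gm[gm["class"] == "site"]
    by_site = {
        sid: np.sort(ranks.reindex(grp.index).dropna().to_numpy())
        for sid, grp in site_guides.groupby("site_id")
    }
    scores = {sid: _rho(r, alpha_cutoff) for sid, r in by_site.items()}

    rng = stream(seed, "rra_score")
    all_ranks = ranks.to_numpy()
    pvals = {}
    sizes = {sid: len(r) for sid, r in by_site.items()}
    for s in sorted(set(sizes.values())):
        draw = all_ranks[rng.integers(0, all_ranks.size, size=(n_permutations, s))]
        draw.sort(axis=1)
        null = np.array([_rho(row, alpha_cutoff) for row in draw])
        snull = np.sort(null)
        for sid, sz in sizes.items():
            if sz == s:
                le = np.searchsorted(snull, scores[sid], side="right")
                pvals[sid] = (1.0 + le) / (n_permutations + 1.0)

    out = pd.DataFrame(
        {
            "site_id": list(scores),
            "rra_score": [scores[s] for s in scores],
            "permutation_p": [pvals[s] for s in scores],
        }
    )
    return out.sort_values("site_id", ignore_index=True)


# ---------------------------------------------------------------------------
# copy-number correction


def cnv_correct(
    results: pd.DataFrame,
    sites: pd.DataFrame,
    copy_segments: pd.DataFrame,
) -> pd.DataFrame:
    """Fill ``beta_cnv_adjusted`` by removing the linear beta-vs-copy trend.

    Each site takes the copy number of the segment containing its summit.
    A least-squares line beta ~ copy_number over all sites is subtracted and
    re-added at diploid, so diploid sites are unchanged.  With a single copy
    state the adjustment is the identity.  ``neg_rank`` is recomputed on the
    adjusted beta.
    """
    res = results.copy()
    pos = sites.set_index("site_id").loc[res["site_id"], ["chrom", "summit"]]
    cn = np.full(len(res), 2.0)
    for chrom, seg in copy_segments.groupby("chrom"):
        mask = (pos["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        seg = seg.sort_values("start")
        idx = (
            np.searchsorted(
                seg["start"].to_numpy(),
                pos["summit"].to_numpy()[mask],
                side="right",
            )
            - 1
        )
        cn[mask] = seg["copy_number"].to_numpy()[idx.clip(0)]

    beta = res["beta"].to_numpy(dtype=float)
    if np.unique(cn).size < 2:
        adj = beta.copy()
    else:
        slope, intercept = np.polyfit(cn, beta, 1)
        adj = beta - slope * (cn - 2.0)
    res["beta_cnv_adjusted"] = adj
    res["copy_number"] = cn.astype(int)
    res["neg_rank"] = res["beta_cnv_adjusted"].rank(method="first").astype(int)
    return res


def run_screen_stats(
    counts: pd.DataFrame,
    sites: pd.DataFrame,
    copy_segments: pd.DataFrame,
    generations: float = 10.0,
    n_permutations: int = 1000,
    seed: int = 0,
    alpha_cutoff: float = 0.25,
    rra_permutations: int = 200,
) -> pd.DataFrame:
    """Counts -> normalised -> LFC -> beta -> CNV-adjusted -> p/FDR (+RRA).

    Significance is assessed on the CNV-adjusted beta: the multi-cut
    depletion of amplified loci would otherwise flood the hit list, which is
    the artifact the correction exists to remove.
    """
    norm = normalize_counts(counts)
    lfc = guide_lfc(norm)
    res = estimate_beta(
        lfc,
        norm.guide_info,
        generations=generations,
        n_permutations=n_permutations,
        seed=seed,
    )
    res = cnv_correct(res, sites, copy_segments)
    # re-test the adjusted scores against the same control null
    gm = norm.guide_info.set_index("guide_id")
    ctl = lfc.reindex(gm.index[gm["class"] == "AAVS1_negative"]).dropna().to_numpy()
    sizes = res.set_index("site_id")["n_guides"]
    adj_lfc = pd.Series(
        (res["beta_cnv_adjusted"] * generations).to_numpy(), index=res["site_id"]
    )
    pvals = control_null_pvalues(
        adj_lfc, sizes, ctl, n_permutations=n_permutations, seed=seed
    )
    res["p_value"] = res["site_id"].map(pvals)
    res["fdr"] = multipletests(res["p_value"], method="fdr_bh")[1]
    rra = rra_score(
        lfc,
        norm.guide_info,
        alpha_cutoff=alpha_cutoff,
        n_permutations=rra_permutations,
        seed=seed,
    )
    return res.merge(rra, on="site_id", how="left")
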