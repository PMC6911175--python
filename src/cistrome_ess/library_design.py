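"""sgRNA and paired-guide library design against binding-site intervals.

Design follows the screening-library recipe for cistrome knockouts: scan all
candidate guides inside a binding-site interval (NGG protospacer-adjacent
motif on either strand in sequence mode, or an injected candidate pool in
synthetic mode), drop candidates with low predicted cutting efficiency or
specificity, then keep up to k guides closest to the ChIP-seq peak summit.
Paired guides (pgRNAs) are chosen from pools flanking the site, ranked by
total flanking distance so the smallest deletions that still remove the
whole site come first.  Control guides target the exons of known essential
genes (positive) and the AAVS1 safe-harbor locus (negative).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._rng import stream

GUIDE_COLUMNS = [
    "guide_id",
    "class",
    "site_id",
    "chrom",
    "cut",
    "strand",
    "efficiency",
    "specificity",
]


@dataclass(frozen=True)
class GuideCandidate:
    guide_id: str
    site_id: str
    cut_position: int
    strand: str
    efficiency: float
    specificity: float


@dataclass(frozen=True)
class PairedGuide:
    pair_id: str
    site_id: str
    left_cut: int
    right_cut: int


@dataclass
class LibraryManifest:
    """Guides plus control bookkeeping; ``guides`` uses :data:`GUIDE_COLUMNS`."""

    guides: pd.DataFrame
    controls: dict[str, int] = field(default_factory=dict)

    def per_site_counts(self) -> pd.Series:
        site = self.guides[self.guides["class"] == "site"]
        return site.groupby("site_id").size()


# ---------------------------------------------------------------------------
# guide scanning


def scan_guides(
    site,
    sequence: str | None = None,
    candidates: Sequence[GuideCandidate] | None = None,
) -> list[GuideCandidate]:
    """All candidate guides cutting within ``[site.start, site.end)``.

    Sequence mode scans both strands of ``sequence`` (assumed to start at
    ``site.start``) for NGG; the Cas9 blunt cut sits 3 bp 5' of the PAM.
    Synthetic mode filters an injected candidate pool to the site interval.
    Exactly one of ``sequence`` / ``candidates`` must be given.
    """
    start, end = int(site["start"]), int(site["end"])
    if end <= start:
        raise ValueError(f"empty site interval for {site['site_id']}")
    if (sequence is None) == (candidates is None):
        raise ValueError("provide exactly one of sequence or candidates")
    if candidates is not None:
        return [c for c in candidates if start <= c.cut_position < end]

    seq = sequence.upper()
    found: list[GuideCandidate] = []
    # + strand: PAM = NGG at [i, i+3); cut between i-4 and i-3 -> position i-3
    for m in re.finditer(r"(?=[ACGT]GG)", seq):
        i = m.start()
        cut = start + i - 3
        if start <= cut < end and i >= 3:
            found.append(
                GuideCandidate(
                    guide_id=f"{site['site_id']}_p{i}",
                    site_id=str(site["site_id"]),
                    cut_position=cut,
                    strand="+",
                    efficiency=1.0,
                    specificity=1.0,
                )
            )
    # - strand: PAM = CCN at [i, i+3) on the + sequence; cut 3 bp 5' of the
    # PAM on the - strand -> position i+3+3 in + coordinates
    for m in re.finditer(r"(?=CC[ACGT])", seq):
        i = m.start()
        cut = start + i + 6
        if start <= cut < end and i + 6 <= len(seq):
            found.append(
                GuideCandidate(
                    guide_id=f"{site['site_id']}_m{i}",
                    site_id=str(site["site_id"]),
                    cut_position=cut,
                    strand="-",
                    efficiency=1.0,
                    specificity=1.0,
                )
            )
    found.sort(key=lambda c: (c.cut_position, c.strand != "+"))
    return found


def synthetic_candidates(
    site, n: int, seed: int, min_score: float = 0.0
) -> list[GuideCandidate]:
    """An injected candidate pool for synthetic mode (no sequence needed)."""
    rng = stream(seed, f"candidates:{site['site_id']}")
    start, end = int(site["start"]), int(site["end"])
    cuts = rng.integers(start, end, size=n)
    effs = rng.uniform(min_score, 1.0, size=n)
    specs = rng.uniform(min_score, 1.0, size=n)
    strands = rng.choice(["+", "-"], size=n)
    return [
        GuideCandidate(
            guide_id=f"{site['site_id']}_c{i}",
            site_id=str(site["site_id"]),
            cut_position=int(cuts[i]),
            strand=str(strands[i]),
            efficiency=float(effs[i]),
            specificity=float(specs[i]),
        )
        for i in range(n)
    ]


def filter_guides(
    candidates: Iterable[GuideCandidate],
    min_efficiency: float = 0.0,
    min_specificity: float = 0.0,
) -> list[GuideCandidate]:
    """Drop candidates below the efficiency/specificity thresholds (order kept)."""
    for t in (min_efficiency, min_specificity):
        if not 0 <= t <= 1:
            raise ValueError("thresholds must lie in [0, 1]")
    return [
        c
        for c in candidates
        if c.efficiency >= min_efficiency and c.specificity >= min_specificity
    ]


def select_guides(
    candidates: Sequence[GuideCandidate], summit: int, k: int = 20
) -> list[GuideCandidate]:
    """Up to ``k`` candidates closest to the peak summit.

    Ties broken by lower cut coordinate, then + strand.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(
        candidates,
        key=lambda c: (abs(c.cut_position - summit), c.cut_position, c.strand != "+"),
    )
    return ordered[:k]


def design_pgRNAs(
    site,
    candidates_left: Sequence[GuideCandidate],
    candidates_right: Sequence[GuideCandidate],
    k: int = 25,
    flank_window: int = 1000,
) -> list[PairedGuide]:
    """Up to ``k`` guide pairs whose deletion interval contains the site.

    Pairs are ranked by total flanking distance (left gap + right gap,
    ascending) so the tightest deletions come first; duplicates by cut
    coordinates are removed.  Returns an empty list when no valid pair
    exists.
    """
    start, end = int(site["start"]), int(site["end"])
    pairs: list[tuple[int, int, int]] = []
    for lc in candidates_left:
        if not (start - flank_window <= lc.cut_position <= start):
            continue
        for rc in candidates_right:
            if not (end <= rc.cut_position <= end + flank_window):
                continue
            if lc.cut_position < rc.cut_position:
                pairs.append(
                    (
                        (start - lc.cut_position) + (rc.cut_position - end),
                        lc.cut_position,
                        rc.cut_position,
                    )
                )
    pairs = sorted(set(pairs))
    out = []
    for i, (_, lcut, rcut) in enumerate(pairs[:k]):
        out.append(
            PairedGuide(
                pair_id=f"{site['site_id']}_pg{i}",
                site_id=str(site["site_id"]),
                left_cut=lcut,
                right_cut=rcut,
            )
        )
    return out


# ---------------------------------------------------------------------------
# manifest assembly


def _distribute_guides(
    total: int, n_sites: int, lo: int, hi: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-site guide counts in [lo, hi] summing exactly to ``total``."""
    if not lo * n_sites <= total <= hi * n_sites:
        raise ValueError(
            f"cannot place {total} guides over {n_sites} sites with "
            f"{lo}-{hi} per site"
        )
    base = total // n_sites
    counts = np.full(n_sites, base)
    extra = total - base * n_sites
    if extra:
        counts[rng.choice(n_sites, size=extra, replace=False)] += 1
    return counts


def build_site_library(
    sites: pd.DataFrame,
    seed: int,
    guides_per_site: int = 16,
    k_max: int = 20,
    total_guides: int | None = None,
    candidate_pool: int = 30,
    min_efficiency: float = 0.2,
    min_specificity: float = 0.2,
) -> LibraryManifest:
    """Design the site-targeting arm of a library in synthetic mode.

    For each site a candidate pool is generated, filtered and summit-ranked.
    If ``total_guides`` is given, per-site counts are apportioned within
    [12, ``k_max``] so the library total is exact; otherwise
    ``guides_per_site`` is requested everywhere (capped at ``k_max``).
    """
    rng = stream(seed, "build_site_library")
    n = len(sites)
    if total_guides is not None:
        per_site = _distribute_guides(total_guides, n, 12, k_max, rng)
    else:
        per_site = np.full(n, min(guides_per_site, k_max))

    # vectorised candidate pools (one batch for the whole library)
    m = max(candidate_pool, int(per_site.max()) + 5)
    starts = sites["start"].to_numpy()
    ends = sites["end"].to_numpy()
    summits = sites["summit"].to_numpy()
    cuts = (starts[:, None] + rng.random((n, m)) * (ends - starts)[:, None]).astype(int)
    eff = rng.uniform(0.0, 1.0, size=(n, m))
    spc = rng.uniform(0.0, 1.0, size=(n, m))
    plus = rng.random((n, m)) < 0.5
    passing = (eff >= min_efficiency) & (spc >= min_specificity)

    row_site, row_col = [], []
    for i in range(n):
        want = int(per_site[i])
        idx = np.flatnonzero(passing[i])
        if idx.size < want:  # top up from the unfiltered pool
            idx = np.arange(m)
        d = np.abs(cuts[i, idx] - summits[i])
        order = np.lexsort((~plus[i, idx], cuts[i, idx], d))[:want]
        chosen = idx[order]
        row_site.append(np.full(chosen.size, i))
        row_col.append(chosen)
    ri = np.concatenate(row_site)
    ci = np.concatenate(row_col)
    site_ids = sites["site_id"].to_numpy()[ri]
    guides = pd.DataFrame(
        {
            "guide_id": [f"{s}_c{j}" for s, j in zip(site_ids, ci)],
            "class": "site",
            "site_id": site_ids,
            "chrom": sites["chrom"].to_numpy()[ri],
            "cut": cuts[ri, ci],
            "strand": np.where(plus[ri, ci], "+", "-"),
            "efficiency": eff[ri, ci],
            "specificity": spc[ri, ci],
        },
        columns=GUIDE_COLUMNS,
    )
    return LibraryManifest(guides=guides)


def add_controls(
    manifest: LibraryManifest,
    essential_gene_ids: Sequence[str],
    guides_per_gene: int = 5,
    n_negative: int = 267,
) -> LibraryManifest:
    """Append essential-gene positive controls and AAVS1 negative controls."""
    if guides_per_gene < 1:
        raise ValueError("guides_per_gene must be >= 1")
    if len(set(essential_gene_ids)) != len(list(essential_gene_ids)):
        raise ValueError("duplicate control gene ids")
    rows = []
    for g in essential_gene_ids:
        for i in range(guides_per_gene):
            rows.append(
                {
                    "guide_id": f"ctrl_{g}_{i}",
                    "class": "gene_targeting",
                    "site_id": g,
                    "chrom": ".",
                    "cut": -1,
                    "strand": ".",
                    "efficiency": 1.0,
                    "specificity": 1.0,
                }
            )
    for i in range(n_negative):
        rows.append(
            {
                "guide_id": f"ctrl_AAVS1_{i}",
                "class": "AAVS1_negative",
                "site_id": "AAVS1",
                "chrom": ".",
                "cut": -1,
                "strand": ".",
                "efficiency": 1.0,
                "specificity": 1.0,
            }
        )
    ctrl = pd.DataFrame(rows, columns=GUIDE_COLUMNS)
    guides = pd.concat([manifest.guides, ctrl], ignore_index=True)
    if guides["guide_id"].duplicated().any():
        raise ValueError("duplicate control guide ids after merge")
    controls = dict(manifest.controls)
    controls["gene_targeting"] = controls.get("gene_targeting", 0) + len(
        essential_gene_ids
    ) * guides_per_gene
    controls["AAVS1_negative"] = controls.get("AAVS1_negative", 0) + n_negative
    return LibraryManifest(guides=guides, controls=controls)


def summarize_library(
    manifests: dict[str, LibraryManifest] | LibraryManifest,
    sites: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Library-table summary: per-library site/guide/control counts + totals.

    Accepts a single manifest or a dict keyed by library name (e.g. factor).
    When ``sites`` is given, the site-count row uses the factor annotation.
    """
    if isinstance(manifests, LibraryManifest):
        manifests = {"library": manifests}
    cols = {}
    for name, man in manifests.items():
        site_guides = man.guides[man.guides["class"] == "site"]
        per_site = man.per_site_counts()
        cols[name] = {
            "binding_sites": int(site_guides["site_id"].nunique()),
            "sgRNAs": int(len(site_guides)),
            "gene_targeting_sgRNAs": int(
                (man.guides["class"] == "gene_targeting").sum()
            ),
            "AAVS1_sgRNAs": int((man.guides["class"] == "AAVS1_negative").sum()),
            "min_guides_per_site": int(per_site.min()) if len(per_site) else 0,
            "max_guides_per_site": int(per_site.max()) if len(per_site) else 0,
        }
    out = pd.DataFrame(cols)
    out["total"] = out.sum(axis=1)
    # min/max are not additive; report the extrema instead
    if len(out.columns) > 1:
        out.loc["min_guides_per_site", "total"] = out.loc[
            "min_guides_per_site", out.columns[:-1]
        ].min()
        out.loc["max_guides_per_site", "total"] = out.loc[
            "max_guides_per_site", out.columns[:-1]
        ].max()
    return out
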