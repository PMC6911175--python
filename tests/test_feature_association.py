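"""Window signal extraction, feature ranking, proximity/class/TAD analyses."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from cistrome_ess.feature_association import (
    compare_site_classes,
    extract_window_signal,
    proximity_enrichment,
    rank_features,
    strongest_site_classes,
    tad_anchor_analysis,
)


def _track(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


class TestWindowSignal:
    def test_constant_track(self):
        track = _track([("chr1", 0, 10_000, 2.0)])
        assert extract_window_signal(track, "chr1", 5000) == pytest.approx(2.0)
        assert extract_window_signal(
            track, "chr1", 5000, feature_class="histone_modification"
        ) == pytest.approx(2.0)

    def test_impulse_at_summit(self):
        track = _track([("chr1", 5000, 5001, 150.0)])
        assert extract_window_signal(track, "chr1", 5000) == pytest.approx(1.0)

    def test_matches_per_base_brute_force(self):
        rng = np.random.default_rng(2)
        edges = np.sort(rng.choice(np.arange(1, 3000), size=40, replace=False))
        rows = [
            ("chr1", int(s), int(e), float(rng.uniform(0, 5)))
            for s, e in zip(edges[:-1], edges[1:])
        ]
        track = _track(rows)
        for summit in (100, 1500, 2900):
            per_base = np.zeros(4000)
            for _, s, e, v in rows:
                per_base[s:e] = v
            lo, hi = summit - 75, summit + 75
            expect = per_base[max(lo, 0) : hi].sum() / (hi - max(lo, 0))
            got = extract_window_signal(track, "chr1", summit)
            assert got == pytest.approx(expect, abs=1e-12)

    def test_window_clipped_at_chromosome_end(self):
        track = _track([("chr1", 0, 100, 3.0)])
        got = extract_window_signal(track, "chr1", 10, chrom_size=100)
        # window [-65, 85) clips to [0, 85); fully covered at value 3
        assert got == pytest.approx(3.0)


def _ranking_inputs(seed, n=400, shifts=None):
    rng = np.random.default_rng(seed)
    shifts = shifts or {"DNase": 1.0, "H3K27ac": 0.5, "FOXA1_signal": 0.0}
    ess = np.zeros(n, dtype=bool)
    ess[: n // 10] = True
    table = pd.DataFrame(
        {f: rng.normal(0, 1, n) + shifts.get(f, 0) * ess for f in shifts},
        index=[f"S{i}" for i in range(n)],
    )
    beta = rng.normal(0, 0.05, n) - 0.5 * ess
    res = pd.DataFrame(
        {
            "site_id": table.index,
            "beta": beta,
            "beta_cnv_adjusted": beta,
            "fdr": np.where(ess, 0.01, 0.8),
        }
    )
    return table, res


class TestRankFeatures:
    def test_recovers_effect_order(self):
        table, res = _ranking_inputs(1)
        out = rank_features([table], [res], top_frac=0.10)
        assert out["feature"].tolist()[0] == "DNase"
        assert out["feature"].tolist()[-1] == "FOXA1_signal"
        assert out.loc[0, "direction"] == "higher_in_essential"

    def test_shuffled_labels_null(self):
        table, res = _ranking_inputs(2, shifts={"A": 0.0, "B": 0.0, "C": 0.0})
        out = rank_features([table], [res], top_frac=0.10)
        assert out["p_avg"].min() > 0.01

    def test_p_avg_is_arithmetic_mean(self):
        t1, r1 = _ranking_inputs(3)
        t2, r2 = _ranking_inputs(4)
        out = rank_features([t1, t2], [r1, r2], top_frac=0.10)
        expect = out[["p_cellline_1", "p_cellline_2"]].mean(axis=1)
        assert np.allclose(out["p_avg"], expect)

    def test_invariant_to_monotone_transform(self):
        table, res = _ranking_inputs(5)
        out1 = rank_features([table], [res], top_frac=0.10)
        out2 = rank_features([np.exp(table / 3)], [res], top_frac=0.10)
        merged = out1.merge(out2, on="feature", suffixes=("_raw", "_tr"))
        assert np.allclose(merged["p_avg_raw"], merged["p_avg_tr"])

    def test_constant_feature_flagged(self):
        table, res = _ranking_inputs(6)
        table["flat"] = 1.0
        out = rank_features([table], [res], top_frac=0.10).set_index("feature")
        assert out.loc["flat", "p_avg"] == 1.0
        assert out.loc["flat", "direction"] == "undefined"


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    def prob(x):
        return (
            comb(row1, x, exact=True)
            * comb(n - row1, col1 - x, exact=True)
            / comb(n, col1, exact=True)
        )
    p_obs = prob(a)
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestProximityEnrichment:
    def _fixture(self, a, b, c, d):
        """Genes/sites laid out so the 2x2 near-gene table is (a,b;c,d)."""
        genes = pd.DataFrame(
            {
                "gene_id": ["E0", "N1", "N2"],
                "chrom": "chr1",
                "tss": [1_000_000, 40_000_000, 45_000_000],
                "strand": "+",
                "beta_gene": [-2.0, 0.0, 0.1],
                "expression": 1.0,
            }
        )
        rows = []
        i = j = 0  # j counts near-gene sites so they all stay inside 100 kb
        for ess, near, cnt in [(1, 1, a), (1, 0, b), (0, 1, c), (0, 0, d)]:
            for _ in range(cnt):
                if near:
                    summit = 1_000_000 + 500 * j
                    j += 1
                else:
                    summit = 20_000_000 + 1000 * i
                rows.append(
                    {
                        "site_id": f"S{i}",
                        "chrom": "chr1",
                        "start": summit - 100,
                        "end": summit + 100,
                        "summit": summit,
                        "is_ess": ess,
                    }
                )
                i += 1
        sites = pd.DataFrame(rows)
        res = pd.DataFrame(
            {
                "site_id": sites["site_id"],
                "beta": np.where(sites["is_ess"], -0.5, 0.0),
                "beta_cnv_adjusted": np.where(sites["is_ess"], -0.5, 0.0),
                "fdr": np.where(sites["is_ess"], 0.01, 0.9),
            }
        )
        return sites, res, genes

    def test_two_by_two_matches_hypergeometric_oracle(self):
        sites, res, genes = self._fixture(20, 80, 5, 95)
        out = proximity_enrichment(sites, res, genes, distance=100_000)
        assert out.table == ((20, 80), (5, 95))
        assert out.odds_ratio == pytest.approx((20 / 80) / (5 / 95))
        assert out.fisher_p == pytest.approx(fisher_oracle(20, 80, 5, 95), rel=1e-9)

    def test_constructed_enrichment_significant(self):
        sites, res, genes = self._fixture(30, 0, 10, 90)
        out = proximity_enrichment(sites, res, genes)
        assert out.fisher_p < 0.001
        assert out.pct_essential_sites_near == pytest.approx(100.0)

    def test_random_placement_null(self):
        rng = np.random.default_rng(8)
        sites, res, genes = self._fixture(10, 30, 25, 75)  # same 25% near rate
        out = proximity_enrichment(sites, res, genes)
        assert out.fisher_p > 0.05

    def test_empty_essential_set_rejected(self):
        sites, res, genes = self._fixture(5, 5, 5, 5)
        res["fdr"] = 1.0
        with pytest.raises(ValueError, match="essential"):
            proximity_enrichment(sites, res, genes)


def ks_oracle(x, y):
    """Exact two-sample KS p by enumerating all label assignments (n <= 12)."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    def ks_stat(a, b):
        grid = np.sort(pooled)
        fa = np.searchsorted(np.sort(a), grid, side="right") / len(a)
        fb = np.searchsorted(np.sort(b), grid, side="right") / len(b)
        return np.max(np.abs(fa - fb))
    obs = ks_stat(x, y)
    count = total = 0
    for comb_idx in itertools.combinations(range(len(pooled)), nx):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(comb_idx)] = True
        if ks_stat(pooled[mask], pooled[~mask]) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


class TestCompareSiteClasses:
    def _results(self, values, classes):
        res = pd.DataFrame(
            {
                "site_id": [f"S{i}" for i in range(len(values))],
                "beta": values,
                "beta_cnv_adjusted": values,
                "fdr": 0.5,
            }
        )
        cmap = {f"S{i}": c for i, c in enumerate(classes)}
        return res, cmap

    def test_identical_distributions(self):
        vals = list(np.linspace(-1, 1, 10)) * 2
        res, cmap = self._results(vals, ["a"] * 10 + ["b"] * 10)
        out = compare_site_classes(res, cmap)
        assert out["ks"][("a", "b")]["statistic"] == pytest.approx(0.0)
        assert out["ks"][("a", "b")]["p_value"] == pytest.approx(1.0)

    def test_location_shift_detected(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(0, 1, 500), rng.normal(1, 1, 500)])
        res, cmap = self._results(vals, ["a"] * 500 + ["b"] * 500)
        out = compare_site_classes(res, cmap)
        assert out["ks"][("a", "b")]["p_value"] < 1e-10

    def test_matches_exact_enumeration_small_n(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=11)
        res, cmap = self._results(vals, ["a"] * 5 + ["b"] * 6)
        out = compare_site_classes(res, cmap)
        expect = ks_oracle(vals[:5], vals[5:])
        assert out["ks"][("a", "b")]["p_value"] == pytest.approx(expect, rel=1e-6)

    def test_small_class_rejected(self):
        res, cmap = self._results([0.0, 1.0, 2.0], ["a", "b", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_site_classes(res, cmap)

    def test_strongest_partition(self):
        sig = pd.Series(np.arange(10, dtype=float), index=[f"S{i}" for i in range(10)])
        cm = strongest_site_classes(sig, quantile=0.9)
        assert sum(v == "strongest" for v in cm.values()) == 1
        assert cm["S9"] == "strongest"


class TestTadAnchor:
    def _inputs(self, seed=0, boundary_effect=-0.4, anchor_k27_shift=0.0):
        rng = np.random.default_rng(seed)
        n = 300
        summits = rng.integers(50_000, 9_950_000, n)
        sites = pd.DataFrame(
            {
                "site_id": [f"S{i}" for i in range(n)],
                "chrom": "chr1",
                "start": summits - 100,
                "end": summits + 100,
                "summit": summits,
            }
        )
        boundaries = pd.DataFrame(
            {"chrom": "chr1", "start": [1_000_000, 5_000_000], "end": [1_020_000, 5_020_000]}
        )
        anchors = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [8_000_000],
                "end": [8_200_000],
                "head_to_head": [True],
            }
        )
        mid = (boundaries["start"] + boundaries["end"]) // 2
        in_b = np.zeros(n, dtype=bool)
        for m in mid:
            in_b |= np.abs(summits - m) <= 10_000
        # force some membership
        sites.loc[:19, "summit"] = mid[0] + rng.integers(-9000, 9000, 20)
        sites.loc[20:39, "summit"] = 8_100_000 + rng.integers(-50_000, 50_000, 20)
        summits = sites["summit"].to_numpy()
        in_b = np.abs(summits - mid[0]).astype(float) <= 10_000
        in_b |= np.abs(summits - mid[1]) <= 10_000
        in_a = (summits >= 8_000_000) & (summits < 8_200_000)
        beta = rng.normal(0, 0.1, n) + boundary_effect * in_b + boundary_effect * in_a
        res = pd.DataFrame(
            {
                "site_id": sites["site_id"],
                "beta": beta,
                "beta_cnv_adjusted": beta,
                "fdr": np.where(beta < -0.2, 0.05, 0.9),
            }
        )
        k27 = pd.Series(
            rng.normal(2, 0.3, n) + anchor_k27_shift * (~in_a) * (beta < -0.2),
            index=sites["site_id"],
        )
        return res, sites, boundaries, anchors, k27

    def test_boundary_depletion_detected(self):
        res, sites, b, a, k27 = self._inputs(boundary_effect=-0.4)
        out = tad_anchor_analysis(res, sites, b, a, h3k27ac=k27)
        assert out["tad_boundary"]["median_in"] < out["tad_boundary"]["median_out"]
        assert out["tad_boundary"]["p_value"] < 0.01
        assert out["anchor"]["p_value"] < 0.01

    def test_no_effect_is_null(self):
        pvals = []
        for seed in range(5):
            res, sites, b, a, k27 = self._inputs(seed=seed, boundary_effect=0.0)
            out = tad_anchor_analysis(res, sites, b, a)
            pvals += [out["tad_boundary"]["p_value"], out["anchor"]["p_value"]]
        assert min(pvals) > 0.005
        assert np.mean(pvals) > 0.2

    def test_anchor_essentials_have_weaker_k27(self):
        res, sites, b, a, k27 = self._inputs(anchor_k27_shift=1.0)
        out = tad_anchor_analysis(res, sites, b, a, h3k27ac=k27)
        tiers = out["h3k27ac"]
        assert tiers["anchor_essential"]["median"] < tiers["other_essential"]["median"]
        assert tiers["anchor_vs_other_essential_p"] < 0.01


def mwu_oracle(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration (n <= 12)."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    def u_stat(a, b):
        return sum((a_i > b_j) + 0.5 * (a_i == b_j) for a_i in a for b_j in b)
    obs = u_stat(x, y)
    mu = nx * len(y) / 2
    count = total = 0
    for comb_idx in itertools.combinations(range(len(pooled)), nx):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(comb_idx)] = True
        if abs(u_stat(pooled[mask], pooled[~mask]) - mu) >= abs(obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


def test_mann_whitney_matches_exhaustive_enumeration():
    """The ranking test's p-values equal the exact permutation distribution."""
    rng = np.random.default_rng(9)
    x = rng.normal(size=5)
    y = rng.normal(1.0, 1.0, size=6)
    table = pd.DataFrame({"f": np.concatenate([x, y])}, index=[f"S{i}" for i in range(11)])
    beta = np.concatenate([np.full(5, -1.0), np.zeros(6)])
    res = pd.DataFrame(
        {
            "site_id": table.index,
            "beta": beta,
            "beta_cnv_adjusted": beta,
            "fdr": 0.5,
        }
    )
    out = rank_features([table], [res], top_frac=5 / 11)
    assert out.loc[0, "p_avg"] == pytest.approx(mwu_oracle(x, y), rel=1e-9)
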