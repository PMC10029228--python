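"""Insulation score, TAD calling, conservation, size classes, proximity."""

import numpy as np
import pandas as pd
import pytest

from synteny3d import simdata, tads
from synteny3d.hicmat import ice_balance
from synteny3d.tracks import SignalTrack
from conftest import make_matrix


def _decay_matrix(n=120, depth=200.0, rng=None):
    i, j = np.indices((n, n))
    mu = depth / (np.abs(i - j) + 1.0)
    if rng is None:
        return mu
    V = rng.poisson(mu)
    return np.triu(V) + np.triu(V, 1).T


def _planted_tad_matrix(n=60, tad_bounds=((10, 30), (30, 50)), depth=200.0,
                        enrich=2.0, rng=None):
    i, j = np.indices((n, n))
    mu = depth / (np.abs(i - j) + 1.0)
    for a, b in tad_bounds:
        inside = (i >= a) & (i < b) & (j >= a) & (j < b)
        mu = np.where(inside, mu * enrich, mu)
    if rng is None:
        return mu
    V = rng.poisson(mu)
    return np.triu(V) + np.triu(V, 1).T


def test_insulation_flat_on_pure_decay():
    cm = make_matrix(_decay_matrix(rng=np.random.default_rng(0)),
                     resolution=5000)
    ins = tads.insulation_score(cm, window=50_000)
    sc = ins["score"].dropna()
    assert sc.std() < 0.05


def test_insulation_minimum_at_shared_tad_edge():
    cm = make_matrix(_planted_tad_matrix(), resolution=5000)
    ins = tads.insulation_score(cm, window=25_000)
    sc = ins["score"].to_numpy()
    # shared edge of the two adjacent TADs is bin 30; restrict to the TAD
    # region (the far background ties with the cross-edge level)
    region = np.arange(15, 46)
    argmin = region[np.argmin(sc[region])]
    assert abs(argmin - 30) <= 1


def test_insulation_scale_invariance_and_window_check():
    cm = make_matrix(_planted_tad_matrix(), resolution=5000)
    a = tads.insulation_score(cm, window=25_000)["score"]
    cm10 = make_matrix(10 * _planted_tad_matrix(), resolution=5000)
    b = tads.insulation_score(cm10, window=25_000)["score"]
    assert np.allclose(a.dropna(), b.dropna())
    with pytest.raises(ValueError):
        tads.insulation_score(cm, window=5000)


def test_call_tads_min_size_threshold():
    # one planted TAD of 50 kb (10 bins at 5 kb)
    rng = np.random.default_rng(1)
    V = _planted_tad_matrix(n=80, tad_bounds=((30, 40),), rng=rng)
    cm = make_matrix(V, resolution=5000)
    ins = tads.insulation_score(cm, window=25_000)
    small = tads.call_tads(ins, cm, min_size=60_000)
    kept = tads.call_tads(ins, cm, min_size=25_000)
    assert (small.domains["size"] < 60_000).sum() == 0
    assert len(kept.domains) >= len(small.domains)


def test_tiling_and_monotonicity_in_min_depth():
    g = simdata.simulate_ancestor(1, 200, 10_000, 50_000, seed=31,
                                  tad_gap_range=(10_000, 15_000))
    params = simdata.ContactModelParams(plaid_contrast=1.0)
    cm = simdata.simulate_contacts(g, g.architecture, 5_000, params, seed=32)
    bal, _ = ice_balance(cm)
    ins = tads.insulation_score(bal, 50_000)
    counts = []
    for depth in (0.1, 0.3, 0.6, 1.2):
        ts = tads.call_tads(ins, bal, min_depth=depth)
        counts.append(len(ts.boundaries))
    assert all(a >= b for a, b in zip(counts, counts[1:]))
    # tiling: domains, boundaries, intervals are disjoint and cover
    ts = tads.call_tads(ins, bal, min_depth=0.3)
    pieces = pd.concat([ts.domains[["chrom", "start", "end"]],
                        ts.boundaries[["chrom", "start", "end"]],
                        ts.intervals[["chrom", "start", "end"]]])
    pieces = pieces.sort_values(["chrom", "start"]).reset_index(drop=True)
    assert (pieces["start"].iloc[1:].to_numpy()
            == pieces["end"].iloc[:-1].to_numpy()).all()
    assert pieces["start"].iloc[0] == 0
    assert pieces["end"].iloc[-1] == g.chrom_length("chr01")


def test_no_minima_yields_empty_tadset():
    cm = make_matrix(np.ones((40, 40)) * 5, resolution=5000)
    ins = tads.insulation_score(cm, window=25_000)
    with pytest.warns(UserWarning, match="no insulation minima"):
        ts = tads.call_tads(ins, cm)
    assert len(ts.domains) == 0


# ----------------------------------------------------------------------
# conservation
# ----------------------------------------------------------------------

def _tadset(domains, res=5000):
    df = pd.DataFrame(domains, columns=["chrom", "start", "end"])
    df["size"] = df["end"] - df["start"]
    return tads.TADSet(df, pd.DataFrame(columns=["chrom", "start", "end",
                                                 "min_bin"]),
                       pd.DataFrame(columns=["chrom", "start", "end"]), res)


def _conservation_oracle(dom1, dom2, genes, min_syntenic=4, thr=0.5):
    """Brute-force conserved/rearranged labeling by direct counting."""
    out = {}
    for d1, (s1, e1) in enumerate(dom1):
        mine = [g for g in genes if s1 <= g[0] < e1]
        if len(mine) <= min_syntenic:
            out[d1] = "unassessed"
            continue
        counts = {}
        for _, p2 in mine:
            for d2, (s2, e2) in enumerate(dom2):
                if s2 <= p2 < e2:
                    counts[d2] = counts.get(d2, 0) + 1
        best = max(counts.values()) if counts else 0
        out[d1] = "conserved" if best / len(mine) > thr else "rearranged"
    return out


def test_mirrored_tads_all_conserved():
    doms = [("c", k * 100_000, k * 100_000 + 80_000) for k in range(5)]
    t1 = _tadset(doms)
    t2 = _tadset(doms)
    pos = np.arange(0, 500_000, 10_000) + 5_000
    pairs = pd.DataFrame({"chrom1": "c", "pos1": pos,
                          "chrom2": "c", "pos2": pos})
    res = tads.classify_conserved(t1, t2, pairs)
    assessable = res[res["status"] != "unassessed"]
    assert len(assessable) > 0
    assert (assessable["status"] == "conserved").all()


def test_domain_with_exactly_four_genes_unassessed():
    t1 = _tadset([("c", 0, 100_000)])
    t2 = _tadset([("c", 0, 100_000)])
    pos = np.array([10, 30, 50, 70]) * 1000
    pairs = pd.DataFrame({"chrom1": "c", "pos1": pos,
                          "chrom2": "c", "pos2": pos})
    res = tads.classify_conserved(t1, t2, pairs)
    assert res["status"].iloc[0] == "unassessed"


def test_six_four_split_is_conserved():
    t1 = _tadset([("c", 0, 100_000)])
    t2 = _tadset([("c", 0, 60_000), ("c", 60_000, 100_000)])
    pos1 = np.arange(10) * 10_000 + 5_000
    pairs = pd.DataFrame({"chrom1": "c", "pos1": pos1,
                          "chrom2": "c", "pos2": pos1})
    res = tads.classify_conserved(t1, t2, pairs)
    row = res.iloc[0]
    assert np.isclose(row["overlap_ratio"], 0.6)
    assert row["status"] == "conserved"
    assert row["best_target"] == 0


def test_conservation_matches_bruteforce_oracle():
    rng = np.random.default_rng(6)
    for trial in range(10):
        dom1 = [("c", s, s + 60_000)
                for s in range(0, 480_000, 120_000)]
        dom2 = [("c", s, s + rng.integers(40_000, 90_000))
                for s in range(0, 480_000, 100_000)]
        genes = [(int(p), int(p + rng.integers(-30_000, 30_000)))
                 for p in rng.integers(0, 480_000, 40)]
        pairs = pd.DataFrame({"chrom1": "c",
                              "pos1": [a for a, _ in genes],
                              "chrom2": "c",
                              "pos2": [b for _, b in genes]})
        res = tads.classify_conserved(_tadset(dom1), _tadset(dom2), pairs)
        oracle = _conservation_oracle(
            [(s, e) for _, s, e in dom1], [(s, e) for _, s, e in dom2],
            genes)
        for _, row in res.iterrows():
            assert row["status"] == oracle[row["domain"]], trial


# ----------------------------------------------------------------------
# size classes, boundary contrasts, proximity
# ----------------------------------------------------------------------

def test_group_by_size_threshold_semantics():
    ts = _tadset([("c", 0, 50_000), ("c", 100_000, 170_000)])
    dom = tads.group_by_size(ts, 60_000)
    assert list(dom["size_class"]) == ["small", "large"]
    with pytest.raises(ValueError):
        tads.group_by_size(ts, 0)


def test_boundary_feature_contrast_detects_planted_difference():
    doms, bnds = [], []
    rng = np.random.default_rng(7)
    vals = []
    for k in range(30):
        s = k * 200_000
        size = 40_000 if k < 15 else 120_000
        doms.append(("c", s + 30_000, s + 30_000 + size))
        bnds.append(("c", s + 5_000, s + 30_000, k))
        bnds.append(("c", s + 30_000 + size, s + 55_000 + size, k))
    ts = tads.TADSet(
        pd.DataFrame(doms, columns=["chrom", "start", "end"]).assign(
            size=lambda d: d["end"] - d["start"]),
        pd.DataFrame(bnds, columns=["chrom", "start", "end", "min_bin"]),
        pd.DataFrame(columns=["chrom", "start", "end"]), 5000)
    dom = tads.group_by_size(ts, 60_000)
    n_bins = 30 * 200_000 // 10_000
    track_bins = pd.DataFrame({
        "chrom": "c", "start": np.arange(n_bins) * 10_000,
        "end": (np.arange(n_bins) + 1) * 10_000})
    # mark elevated at boundaries of small TADs
    v = rng.normal(0, 0.05, n_bins)
    for _, d in dom.iterrows():
        bump = 1.0 if d["size_class"] == "small" else 0.0
        lo = d["start"] - 25_000
        hi = d["end"] + 25_000
        sel = (track_bins["start"] < hi) & (track_bins["end"] > lo)
        v[sel.to_numpy()] += bump
    track = SignalTrack(track_bins.assign(value=v), "mark")
    res = tads.boundary_feature_contrast(dom, ts, {"mark": track})
    assert res.iloc[0]["pvalue"] < 0.01
    assert res.iloc[0]["mean_small"] > res.iloc[0]["mean_large"]


def test_boundary_contrast_skips_empty_class():
    ts = _tadset([("c", 0, 50_000)])
    dom = tads.group_by_size(ts, 60_000)
    track = SignalTrack(pd.DataFrame({"chrom": "c", "start": [0],
                                      "end": [50_000], "value": [1.0]}), "m")
    with pytest.warns(UserWarning, match="skipped"):
        res = tads.boundary_feature_contrast(dom, ts, {"m": track})
    assert res.empty


def test_proximity_classification():
    ts = _tadset([("c", 100_000, 200_000), ("d", 0, 100_000)])
    inside = pd.DataFrame({"chrom": ["c"], "start": [150_000],
                           "end": [150_001]})
    assert list(tads.proximity_to_breaks(ts, inside, 0)["proximity"]) \
        == ["proximal", "distal"]
    other = pd.DataFrame({"chrom": ["e"], "start": [0], "end": [1]})
    assert list(tads.proximity_to_breaks(ts, other, 50_000)["proximity"]) \
        == ["distal", "distal"]


def test_proximity_planted_counts_recovered():
    doms = [("c", k * 300_000 + 50_000, k * 300_000 + 150_000)
            for k in range(100)]
    ts = _tadset(doms)
    # breaks right before the first 20 domains
    breaks = pd.DataFrame({"chrom": "c",
                           "start": [k * 300_000 + 30_000 for k in range(20)],
                           "end": [k * 300_000 + 30_001 for k in range(20)]})
    prox = tads.proximity_to_breaks(ts, breaks, window=10_000)
    assert (prox["proximity"] == "proximal").sum() == 20
    assert list(prox["proximity"][:20]) == ["proximal"] * 20
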