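"""Simulator: genomes, rearrangements, contacts, expression, tracks."""

import numpy as np
import pandas as pd
import pytest

from synteny3d import simdata
from synteny3d.simdata import (ContactModelParams, RearrangementEvent,
                               apply_rearrangements, simulate_ancestor,
                               simulate_contacts, simulate_expression,
                               simulate_tracks, MarkSpec)


# ----------------------------------------------------------------------
# ancestor
# ----------------------------------------------------------------------

def test_ancestor_identity_construction():
    g = simulate_ancestor(2, 100, 10_000, 50_000, seed=1)
    assert len(g.chromosomes) == 2
    assert len(g.genes) == 200
    seg = g.origin_segments
    assert (seg["chrom"] == seg["anc_chrom"]).all()
    assert (seg["orientation"] == "+").all()
    # genes sorted, within bounds, ancestral order preserved
    for chrom, grp in g.genes.groupby("chrom"):
        assert grp["start"].is_monotonic_increasing
        assert grp["end"].max() <= g.chrom_length(chrom)
        assert list(grp["ancestral_gene_id"]) == sorted(grp["ancestral_gene_id"])


def test_ancestor_seed_determinism():
    a = simulate_ancestor(2, 100, 10_000, 50_000, seed=1)
    b = simulate_ancestor(2, 100, 10_000, 50_000, seed=1)
    pd.testing.assert_frame_equal(a.genes, b.genes)
    assert all((a.architecture.compartment_truth[c]
                == b.architecture.compartment_truth[c]).all()
               for c, _ in a.chromosomes)


def test_ancestor_thirteen_chromosomes():
    g = simulate_ancestor(13, 50, 10_000, 50_000, seed=2)
    assert len(g.chromosomes) == 13
    assert len(g.genes) == 13 * 50


@pytest.mark.parametrize("kwargs", [
    dict(n_chrom=0, genes_per_chrom=10),
    dict(n_chrom=1, genes_per_chrom=1),
    dict(n_chrom=1, genes_per_chrom=10, gene_spacing=-5),
])
def test_ancestor_rejects_bad_sizes(kwargs):
    with pytest.raises(ValueError):
        simulate_ancestor(**{"gene_spacing": 10_000, "bin_size": 50_000,
                             **kwargs})


# ----------------------------------------------------------------------
# rearrangements: brute-force gene-order oracle
# ----------------------------------------------------------------------

def _order_oracle(genome, events):
    """Expected per-chromosome ancestral-id orders from plain list ops."""
    orders = {c: list(genome.genes[genome.genes["chrom"] == c]
                      .sort_values("start")["ancestral_gene_id"])
              for c, _ in genome.chromosomes}
    for ev in events:
        if ev.kind == "inversion":
            o = orders[ev.chrom]
            o[ev.start:ev.end] = o[ev.start:ev.end][::-1]
        elif ev.kind == "translocation":
            o = orders[ev.chrom]
            seg = o[ev.start:ev.end]
            del o[ev.start:ev.end]
            if ev.invert:
                seg = seg[::-1]
            d = orders[ev.dest_chrom]
            orders[ev.dest_chrom] = d[:ev.dest_index] + seg + d[ev.dest_index:]
        elif ev.kind == "fusion":
            other = orders.pop(ev.dest_chrom)
            if ev.invert:
                other = other[::-1]
            orders[f"{ev.chrom}-{ev.dest_chrom}"] = orders.pop(ev.chrom) + other
        elif ev.kind == "fission":
            o = orders.pop(ev.chrom)
            orders[f"{ev.chrom}a"] = o[:ev.start]
            orders[f"{ev.chrom}b"] = o[ev.start:]
    return orders


@pytest.mark.parametrize("events", [
    [],
    [RearrangementEvent("inversion", "chr01", 40, 60)],
    [RearrangementEvent("inversion", "chr01", 10, 25),
     RearrangementEvent("inversion", "chr02", 50, 90)],
    [RearrangementEvent("translocation", "chr01", 20, 55,
                        dest_chrom="chr02", dest_index=30)],
    [RearrangementEvent("translocation", "chr01", 20, 55,
                        dest_chrom="chr02", dest_index=30, invert=True)],
    [RearrangementEvent("fusion", "chr01", dest_chrom="chr02")],
    [RearrangementEvent("fusion", "chr01", dest_chrom="chr02", invert=True)],
])
def test_gene_order_matches_oracle(small_genome, events):
    derived, _ = apply_rearrangements(small_genome, events, species_id="d")
    expected = _order_oracle(small_genome, events)
    for chrom, _ in derived.chromosomes:
        got = list(derived.genes[derived.genes["chrom"] == chrom]
                   .sort_values("start")["ancestral_gene_id"])
        assert got == expected[chrom], chrom
    # gene count conserved
    assert len(derived.genes) == len(small_genome.genes)


def test_identity_rearrangement(small_genome):
    derived, truth = apply_rearrangements(small_genome, [], species_id="d")
    assert len(truth.planted_breakpoints) == 0
    assert (derived.genes[["chrom", "start", "end"]].to_numpy()
            == small_genome.genes[["chrom", "start", "end"]].to_numpy()).all()


def test_inversion_breakpoints_match_adjacency_disruptions(small_genome):
    ev = [RearrangementEvent("inversion", "chr01", 40, 60)]
    derived, truth = apply_rearrangements(small_genome, ev, species_id="d")
    assert len(truth.planted_breakpoints) == 2
    idx = [int(a.rsplit("g", 1)[1]) for a in
           derived.genes[derived.genes["chrom"] == "chr01"]
           .sort_values("start")["ancestral_gene_id"]]
    disruptions = sum(1 for a, b in zip(idx, idx[1:]) if abs(a - b) != 1)
    assert disruptions == 2


def test_fusion_then_fission_composes_provenance(toy_genome):
    # one chromosome of 30 genes: fission then refuse in a second round
    g2 = simulate_ancestor(2, 10, 10_000, 50_000, seed=3)
    fused, t1 = apply_rearrangements(
        g2, [RearrangementEvent("fusion", "chr01", dest_chrom="chr02")],
        species_id="f")
    assert len(fused.chromosomes) == 1
    assert len(t1.planted_breakpoints) == 1
    refis, t2 = apply_rearrangements(
        fused, [RearrangementEvent("fission", "chr01-chr02", start=10)],
        species_id="ff")
    assert len(refis.chromosomes) == 2
    # provenance composed back to the original ancestor chromosomes
    seg = refis.origin_segments
    assert set(seg["anc_chrom"]) == {"chr01", "chr02"}
    for _, row in seg.iterrows():
        assert 0 <= row["anc_start"] < row["anc_end"]


def test_breakpoints_equal_segment_junctions(small_genome):
    events = [RearrangementEvent("inversion", "chr01", 20, 45),
              RearrangementEvent("translocation", "chr02", 30, 70,
                                 dest_chrom="chr01", dest_index=80)]
    derived, truth = apply_rearrangements(small_genome, events,
                                          species_id="d")
    n_junctions = 0
    for chrom, _ in derived.chromosomes:
        seg = derived.origin_segments[
            derived.origin_segments["chrom"] == chrom]
        n_junctions += max(0, len(seg) - 1)
    assert len(truth.planted_breakpoints) == n_junctions


@pytest.mark.parametrize("events,err", [
    ([RearrangementEvent("inversion", "chr01", 10, 10)], "non-empty"),
    ([RearrangementEvent("translocation", "chr01", 5, 10,
                         dest_chrom="chr01", dest_index=50)], "distinct"),
    ([RearrangementEvent("inversion", "chr01", 10, 30),
      RearrangementEvent("inversion", "chr01", 20, 40)], "overlap"),
])
def test_invalid_events_rejected(small_genome, events, err):
    with pytest.raises(ValueError, match=err):
        apply_rearrangements(small_genome, events)


# ----------------------------------------------------------------------
# contacts
# ----------------------------------------------------------------------

def test_contact_mean_matches_closed_form():
    g = simulate_ancestor(1, 300, 10_000, 50_000, seed=4)
    params = ContactModelParams(plaid_contrast=1.0, tad_enrichment=1.0,
                                bias_sd=0.0, depth=50.0, alpha=1.0)
    cm = simulate_contacts(g, g.architecture, 50_000, params, seed=9)
    V = cm.matrix
    n = V.shape[0]
    for d in (2, 5, 10):
        vals = np.diagonal(V, d)
        expected = 50.0 * d ** -1.0
        se = np.sqrt(expected / vals.size)
        assert abs(vals.mean() - expected) < 3 * se


def test_contact_symmetry_and_zero_depth():
    g = simulate_ancestor(2, 60, 10_000, 50_000, seed=6)
    cm = simulate_contacts(g, g.architecture, 50_000,
                           ContactModelParams(trans_scale=0.01), seed=1)
    assert np.array_equal(cm.matrix, cm.matrix.T)
    cm0 = simulate_contacts(g, g.architecture, 50_000,
                            ContactModelParams(depth=0.0), seed=1)
    assert cm0.matrix.sum() == 0


def test_contact_rejects_bad_alpha(toy_genome):
    with pytest.raises(ValueError):
        simulate_contacts(toy_genome, toy_genome.architecture, 50_000,
                          ContactModelParams(alpha=0.0))


def test_ancestral_preserving_dampens_cross_origin():
    anc = simulate_ancestor(2, 150, 10_000, 50_000, seed=7)
    fused, truth = apply_rearrangements(
        anc, [RearrangementEvent("fusion", "chr01", dest_chrom="chr02")],
        species_id="f")
    params = ContactModelParams(mode="ancestral_preserving", dampening=0.2,
                                plaid_contrast=1.0, tad_enrichment=1.0,
                                bias_sd=0.0)
    cm = simulate_contacts(fused, truth, 5_000, params, seed=2)
    V = cm.matrix
    n = V.shape[0]
    half = n // 2
    for d in (5, 20, 80):
        same, diff = [], []
        for i in range(0, n - d):
            (same if (i < half) == (i + d < half) else diff).append(V[i, i + d])
        if same and diff:
            assert np.mean(same) > np.mean(diff)


# ----------------------------------------------------------------------
# expression
# ----------------------------------------------------------------------

def test_expression_determinism_and_errors():
    pairs = [(f"a{i}", f"b{i}") for i in range(20)]
    t1a, t2a = simulate_expression(pairs, seed=3)
    t1b, t2b = simulate_expression(pairs, seed=3)
    pd.testing.assert_frame_equal(t1a, t1b)
    pd.testing.assert_frame_equal(t2a, t2b)
    with pytest.raises(ValueError):
        simulate_expression(pairs, replicates=0)
    with pytest.raises(ValueError):
        simulate_expression(pairs, effect_map={"a0": -1.0})


def test_expression_null_pvalues_uniform():
    """With no planted effect the near/distal Wilcoxon p is uniform."""
    from scipy import stats
    from synteny3d.tracks import expression_divergence, group_compare
    ps = []
    for k in range(200):
        pairs = [(f"a{i}", f"b{i}") for i in range(60)]
        t1, t2 = simulate_expression(pairs, seed=1000 + k)
        div, _ = expression_divergence(t1, t2, pairs)
        d = div["divergence"].to_numpy()
        _, p = group_compare(d[:20], d[20:])
        ps.append(p)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_expression_effect_increases_divergence():
    pairs = [(f"a{i}", f"b{i}") for i in range(200)]
    eff = simdata.plant_expression_effects([f"a{i}" for i in range(100)], 4.0)
    from synteny3d.tracks import expression_divergence
    t1, t2 = simulate_expression(pairs, effect_map=eff, seed=5)
    div, _ = expression_divergence(t1, t2, pairs)
    d = div["divergence"].to_numpy()
    assert d[:100].mean() > d[100:].mean() + 0.3


# ----------------------------------------------------------------------
# tracks
# ----------------------------------------------------------------------

def test_tracks_null_and_bump_and_anticorrelation(small_genome):
    anchors = [("chr01", 200_000), ("chr01", 500_000), ("chr02", 300_000)]
    marks = [
        MarkSpec("flat", "ratio", 1.0, anchors, 0.0, noise_sd=0.01),
        MarkSpec("up", "ratio", 0.0, anchors, 1.0, width=10_000,
                 noise_sd=0.01),
        MarkSpec("down", "ratio", 0.0, anchors, -1.0, width=10_000,
                 noise_sd=0.01),
    ]
    tracks = simulate_tracks(small_genome, marks, 10_000, seed=8)
    flat = tracks["flat"].df["value"]
    assert abs(flat.mean() - 1.0) < 0.05
    assert flat.std() < 0.05
    up = tracks["up"].df["value"].to_numpy()
    down = tracks["down"].df["value"].to_numpy()
    assert np.corrcoef(up, down)[0, 1] < -0.8
    # bump height recovered at anchor bins
    bins = tracks["up"].df
    at = bins[(bins["chrom"] == "chr01") & (bins["start"] == 200_000)]
    assert abs(at["value"].iloc[0] - 1.0) < 0.2


def test_methylation_track_clipped_with_warning(small_genome):
    spec = MarkSpec("mCG", "fraction", 0.9, [("chr01", 100_000)], 0.5,
                    noise_sd=0.01)
    with pytest.warns(UserWarning, match="clipped"):
        tracks = simulate_tracks(small_genome, [spec], 10_000, seed=9)
    v = tracks["mCG"].df["value"]
    assert v.max() <= 1.0 and v.min() >= 0.0


def test_track_anchor_bounds_checked(small_genome):
    spec = MarkSpec("m", "ratio", 0.0, [("chr09", 1)], 1.0)
    with pytest.raises(ValueError):
        simulate_tracks(small_genome, [spec], 10_000)


# ----------------------------------------------------------------------
# switch planting and event snapping
# ----------------------------------------------------------------------

def test_plant_compartment_switches_only_flips_b_to_a(small_genome):
    derived, truth = apply_rearrangements(
        small_genome, [RearrangementEvent("inversion", "chr01", 30, 60)],
        species_id="d")
    flipped = simdata.plant_compartment_switches(
        truth, truth.planted_breakpoints, window=50_000, flip_prob=1.0,
        seed=1)
    for chrom in truth.compartment_truth:
        a = truth.compartment_truth[chrom]
        b = flipped.compartment_truth[chrom]
        changed = a != b
        assert (a[changed] == "B").all()
        assert (b[changed] == "A").all()


def test_snap_events_moves_cuts_toward_tad_gaps(small_genome):
    events = [RearrangementEvent("inversion", "chr01", 37, 61)]
    snapped = simdata.snap_events_to_boundaries(small_genome, events)
    tt = small_genome.architecture.tad_truth
    t = tt[tt["chrom"] == "chr01"].sort_values("start")
    centers = np.array([(a["end"] + b["start"]) / 2
                        for (_, a), (_, b) in zip(t.iterrows(),
                                                  t.iloc[1:].iterrows())])
    genes = small_genome.genes[small_genome.genes["chrom"] == "chr01"] \
        .sort_values("start").reset_index(drop=True)
    from synteny3d.simdata import _gene_cut_bp
    L = small_genome.chrom_length("chr01")
    for orig, new in ((37, snapped[0].start), (61, snapped[0].end)):
        assert abs(new - orig) <= 8
        d_orig = np.abs(centers - _gene_cut_bp(genes, L, orig)).min()
        d_new = np.abs(centers - _gene_cut_bp(genes, L, new)).min()
        assert d_new <= d_orig
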