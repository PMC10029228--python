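"""Recovery and calibration experiments on simulated data.

Each experiment regenerates its inputs from the forward simulator (or
small direct constructions), runs the corresponding pipeline stage, and
scores the result against planted truth: matrix-balancing agreement with
an independent Sinkhorn oracle, compartment label recovery, TAD boundary
F1 and null calibration, synteny-break recall/precision, co-localization
type-I error and power, switch-enrichment power, expression-contrast
power and direction, and the origin-stratified decay direction.  These
functions are the package's own reproducibility harness.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import coloc, compartments, hicmat, simdata, synteny, scoring
from . import tads as tadmod, tracks as trackmod

__all__ = [
    "sinkhorn_reference",
    "ice_oracle_agreement",
    "compartment_recovery",
    "tad_recovery",
    "synteny_recovery",
    "coloc_calibration",
    "coloc_power",
    "switch_enrichment_power",
    "expression_power",
    "expression_tad_contrasts",
    "origin_decay_direction",
    "origin_decay_null",
]


def _seed(seed, k):
    return (seed * 1_000_003 + k) % (2 ** 31)


# ----------------------------------------------------------------------
# ICE vs Sinkhorn oracle
# ----------------------------------------------------------------------

def sinkhorn_reference(M, tol=1e-14, max_iter=20_000):
    """Independent two-sided Sinkhorn scaling to doubly stochastic form.

    Alternates exact row and column normalization with separate scale
    vectors (a different algorithm from the symmetric ICE update) and
    returns diag(u) @ M @ diag(v).
    """
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    u = np.ones(n)
    v = np.ones(n)
    for _ in range(max_iter):
        u = 1.0 / (M @ v)
        v = 1.0 / (M.T @ u)
        B = M * np.outer(u, v)
        if max(np.abs(B.sum(1) - 1).max(), np.abs(B.sum(0) - 1).max()) < tol:
            break
    return M * np.outer(u, v)


def ice_oracle_agreement(n_matrices=100, n_bins=200, seed=0):
    """Balance random positive matrices; compare to the Sinkhorn oracle.

    Reports the worst post-balance row-sum CV and the worst relative
    entry-wise difference to the oracle (both matrices scaled to unit
    mean before comparison).
    """
    rng = np.random.default_rng(seed)
    bins = pd.DataFrame({"chrom": "chr1",
                         "start": np.arange(n_bins) * 1000,
                         "end": (np.arange(n_bins) + 1) * 1000})
    worst_cv, worst_diff = 0.0, 0.0
    for _ in range(n_matrices):
        A = rng.lognormal(0.0, 1.0, (n_bins, n_bins))
        A = (A + A.T) / 2
        cm = hicmat.ContactMatrix(bins, A, 1000)
        bal, _ = hicmat.ice_balance(cm, max_iter=5000, tol=1e-12,
                                    mask_low_pct=0.0)
        B = bal.matrix
        rs = B.sum(axis=1)
        worst_cv = max(worst_cv, rs.std() / rs.mean())
        O = sinkhorn_reference(A)
        B = B / B.mean()
        O = O / O.mean()
        worst_diff = max(worst_diff, np.abs(B - O).max() / O.max())
    return {"max_rowsum_cv": float(worst_cv),
            "max_rel_diff_vs_oracle": float(worst_diff),
            "n_matrices": n_matrices, "n_bins": n_bins}


# ----------------------------------------------------------------------
# Compartment recovery
# ----------------------------------------------------------------------

def compartment_recovery(n_sims=100, n_chrom=2, n_bins_per_chrom=160,
                         seed=0):
    """Label agreement with planted compartments at default forward model."""
    bin_size = 50_000
    genes = n_bins_per_chrom * bin_size // 10_000
    n_correct_orient = 0
    pooled_ok = pooled_n = 0
    per_sim = []
    for k in range(n_sims):
        g = simdata.simulate_ancestor(n_chrom, genes, 10_000, bin_size,
                                      seed=_seed(seed, 2 * k))
        cm = simdata.simulate_contacts(g, g.architecture, bin_size,
                                       seed=_seed(seed, 2 * k + 1))
        bal, _ = hicmat.ice_balance(cm)
        prof = compartments.call_compartments(bal, g.gene_density(bin_size))
        lab = prof.bins["label"].to_numpy()
        truth = np.concatenate([
            g.architecture.compartment_bins(c, bin_size,
                                            int((prof.bins["chrom"] == c).sum()))
            for c, _ in g.chromosomes])
        ok = lab != "NA"
        agree = (lab[ok] == truth[ok]).mean()
        per_sim.append(agree)
        pooled_ok += int((lab[ok] == truth[ok]).sum())
        pooled_n += int(ok.sum())
        # orientation correct on every chromosome: majority label agreement
        orient = True
        for c, _ in g.chromosomes:
            sel = (prof.bins["chrom"] == c).to_numpy() & ok
            if sel.any():
                orient &= (lab[sel] == truth[sel]).mean() > 0.5
        n_correct_orient += int(orient)
    return {"pooled_agreement": pooled_ok / pooled_n,
            "mean_agreement": float(np.mean(per_sim)),
            "min_agreement": float(np.min(per_sim)),
            "orientation_correct_frac": n_correct_orient / n_sims,
            "n_sims": n_sims}


# ----------------------------------------------------------------------
# TAD recovery
# ----------------------------------------------------------------------

def _tad_sim_chrom(seed, with_tads=True):
    g = simdata.simulate_ancestor(
        1, 180, 10_000, 50_000, seed=seed,
        tad_gap_range=(10_000, 15_000))
    params = simdata.ContactModelParams(
        plaid_contrast=1.0,
        tad_enrichment=2.0 if with_tads else 1.0)
    cm = simdata.simulate_contacts(g, g.architecture, 5_000, params,
                                   seed=_seed(seed, 1))
    bal, _ = hicmat.ice_balance(cm)
    ins = tadmod.insulation_score(bal, 50_000)
    ts = tadmod.call_tads(ins, bal)
    return g, ts


def tad_recovery(n_chroms=50, seed=0):
    """Boundary F1 (+/- 1 bin) on planted TADs; zero-call rate on nulls."""
    tps = fps = fns = 0
    for k in range(n_chroms):
        g, ts = _tad_sim_chrom(_seed(seed, 10 * k), with_tads=True)
        chrom = g.chromosomes[0][0]
        truth = scoring.boundary_truth_bins(g.architecture.tad_truth,
                                            chrom, 5_000)
        called = ts.boundaries["min_bin"].to_numpy()
        m = scoring.boundary_f1(called, truth, tol=1,
                                region=(truth.min() - 1, truth.max() + 1))
        tps += m["tp"]
        fps += m["fp"]
        fns += m["fn"]
    prec = tps / (tps + fps) if tps + fps else 1.0
    rec = tps / (tps + fns) if tps + fns else 1.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    n_zero = 0
    for k in range(n_chroms):
        _, ts = _tad_sim_chrom(_seed(seed, 10 * k + 5), with_tads=False)
        n_zero += int(len(ts.domains) == 0)
    return {"boundary_f1": float(f1), "precision": float(prec),
            "recall": float(rec), "null_zero_call_frac": n_zero / n_chroms,
            "n_chroms": n_chroms}


# ----------------------------------------------------------------------
# Synteny-break recovery
# ----------------------------------------------------------------------

def _random_events(rng):
    """Two inversions, one translocation, one fusion (segments sized above
    the chaining gap allowance so every junction is a detectable block
    end)."""
    ev = []
    s1 = int(rng.integers(20, 95))
    ev.append(simdata.RearrangementEvent("inversion", "chr01", s1,
                                         s1 + int(rng.integers(12, 50))))
    s2 = int(rng.integers(20, 110))
    ev.append(simdata.RearrangementEvent("inversion", "chr02", s2,
                                         s2 + int(rng.integers(12, 50))))
    # keep >= min_genes anchored genes on both flanks of the excision and
    # clear of the chr02 inversion and insertion site
    s3 = int(rng.integers(150, 180))
    ev.append(simdata.RearrangementEvent(
        "translocation", "chr01", s3, s3 + int(rng.integers(40, 56)),
        dest_chrom="chr02", dest_index=int(rng.integers(185, 235))))
    ev.append(simdata.RearrangementEvent("fusion", "chr03",
                                         dest_chrom="chr04",
                                         invert=bool(rng.integers(2))))
    return ev


def synteny_recovery(n_pairs=20, seed=0, min_genes=10, max_gap=30):
    """Recall/precision of planted breakpoints over simulated genome pairs.

    Each pair is an ancestor-like reference versus a derived genome with
    inversions, a translocation and one fusion; breaks are derived at
    min_genes=10, max_gap=30 and matched within one gene spacing of the
    planted junctions.  Threshold-sweep monotonicity is checked per pair.
    """
    recovered = total_truth = 0
    true_breaks = total_breaks = 0
    monotone = True
    for k in range(n_pairs):
        rng = np.random.default_rng(_seed(seed, 3 * k))
        anc = simdata.simulate_ancestor(4, 250, 10_000, 50_000,
                                        seed=_seed(seed, 3 * k + 1))
        ref, _ = simdata.apply_rearrangements(anc, [], species_id="ref")
        der, truth = simdata.apply_rearrangements(anc, _random_events(rng),
                                                  species_id="der")
        hits = synteny.filter_homologs(
            simdata.simulate_homolog_hits(der, ref,
                                          seed=_seed(seed, 3 * k + 2)))
        blocks = synteny.chain_collinear(der.genes, ref.genes, hits,
                                         max_gap=max_gap, min_genes=min_genes,
                                         n_perm=200, seed=_seed(seed, k))
        breaks = synteny.breaks_to_frame(
            synteny.derive_breaks(blocks, der.genes, ref.genes,
                                  min_genes=min_genes, max_gap=max_gap))
        truth_pos = [[(r["chrom"], r["position"])]
                     for _, r in truth.planted_breakpoints.iterrows()]
        m = scoring.match_breaks(breaks, truth_pos, tol=15_000)
        recovered += m["n_truth_recovered"]
        total_truth += m["n_truth"]
        true_breaks += int(round(m["precision"] * m["n_breaks"]))
        total_breaks += m["n_breaks"]
        sweep, _ = synteny.threshold_sweep(blocks, der.genes, ref.genes,
                                           max_gap=max_gap)
        monotone &= bool(np.all(np.diff(sweep["n_breaks"]) <= 0))
    return {"recall": recovered / total_truth,
            "precision": true_breaks / total_breaks,
            "sweep_monotone": monotone,
            "n_truth": total_truth, "n_breaks": total_breaks,
            "n_pairs": n_pairs}


# ----------------------------------------------------------------------
# Co-localization calibration and power
# ----------------------------------------------------------------------

_COLOC_SIZES = {f"c{i}": 5_000_000 for i in range(1, 4)}


def _random_intervals(rng, n, length, sizes):
    chroms = rng.choice(list(sizes), n)
    rows = []
    for c in chroms:
        s = int(rng.integers(0, sizes[c] - length))
        rows.append((c, s, s + length))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def coloc_calibration(n_null=500, n_perm=499, alphas=(0.05, 0.01), seed=0,
                      n_a=100, n_b=60):
    """Type-I error of the permutation p under independence.

    The overlap-count statistic is discrete, so ``n_a`` is kept large
    enough that null ties (which make the +1-corrected p conservative)
    stay a small fraction of the distribution.
    """
    rng = np.random.default_rng(seed)
    rej = {a: 0 for a in alphas}
    for k in range(n_null):
        A = coloc.IntervalSet(_random_intervals(rng, n_a, 1_000,
                                                _COLOC_SIZES), _COLOC_SIZES)
        B = coloc.IntervalSet(_random_intervals(rng, n_b, 20_000,
                                                _COLOC_SIZES), _COLOC_SIZES)
        r = coloc.empirical_enrichment(A, B, n_perm=n_perm,
                                       seed=_seed(seed, k))
        for a in alphas:
            rej[a] += int(r.p_empirical <= a)
    out = {"n_null": n_null, "alphas": {}}
    ok = True
    for a in alphas:
        rate = rej[a] / n_null
        half = 1.96 * np.sqrt(a * (1 - a) / n_null)
        within = bool(a - half <= rate <= a + half)
        ok &= within
        out["alphas"][a] = {"type1_rate": rate, "ci_low": a - half,
                            "ci_high": a + half, "within_ci": within}
    out["type1_rate"] = out["alphas"][alphas[0]]["type1_rate"]
    out["within_ci"] = ok
    return out


def _boundary_tiling(sizes, width=25_000, every=150_000):
    rows = []
    for c, L in sizes.items():
        for s in range(every, L - width, every):
            rows.append((c, s, s + width))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def coloc_power(n_sims=100, n_breaks=60, at_boundary_prob=0.4, seed=0):
    """Fisher power at p < 0.001 under planted ~3x break-at-boundary
    co-localization."""
    bdf = _boundary_tiling(_COLOC_SIZES)
    B = coloc.IntervalSet(bdf, _COLOC_SIZES)
    hitlist = 0
    for k in range(n_sims):
        rng = np.random.default_rng(_seed(seed, k))
        rows = []
        for _ in range(n_breaks):
            if rng.random() < at_boundary_prob:
                b = bdf.iloc[int(rng.integers(len(bdf)))]
                s = int(rng.integers(b["start"], b["end"] - 1_000))
                rows.append((b["chrom"], s, s + 1_000))
            else:
                c = rng.choice(list(_COLOC_SIZES))
                s = int(rng.integers(0, _COLOC_SIZES[c] - 1_000))
                rows.append((c, s, s + 1_000))
        A = coloc.IntervalSet(pd.DataFrame(rows,
                                           columns=["chrom", "start", "end"]),
                              _COLOC_SIZES)
        r = coloc.fisher_colocalization(A, B)
        hitlist += int(r.p_fisher < 1e-3)
    return {"power": hitlist / n_sims, "n_sims": n_sims}


# ----------------------------------------------------------------------
# Switch enrichment
# ----------------------------------------------------------------------

def _switch_sim(rng, n_genes=2500, n_breaks=60, base_btoa=0.06, mult=3.0,
                window=10_000):
    """Directly constructed switch calls with a planted B-to-A rate
    multiplier within +/- window of breaks."""
    sizes = {f"c{i}": 5_000_000 for i in range(1, 6)}
    per = n_genes // len(sizes)
    rows = []
    for c, L in sizes.items():
        pos = np.sort(rng.choice(L, per, replace=False))
        rows += [(c, int(p)) for p in pos]
    genes = pd.DataFrame(rows, columns=["chrom1", "pos1"])
    bidx = rng.choice(len(genes), n_breaks, replace=False)
    breaks = pd.DataFrame({
        "chrom": genes["chrom1"].to_numpy()[bidx],
        "start": genes["pos1"].to_numpy()[bidx],
        "end": genes["pos1"].to_numpy()[bidx] + 1})
    near = np.zeros(len(genes), dtype=bool)
    for _, b in breaks.iterrows():
        near |= ((genes["chrom1"] == b["chrom"])
                 & (genes["pos1"] >= b["start"] - window)
                 & (genes["pos1"] < b["end"] + window)).to_numpy()
    p_btoa = np.where(near, min(base_btoa * mult, 1.0), base_btoa)
    u = rng.random(len(genes))
    state = np.where(u < p_btoa, "BtoA",
                     np.where(u < p_btoa + 0.05, "AtoB",
                              np.where(u < 0.55, "stableA", "stableB")))
    genes = genes.copy()
    genes["state"] = state
    return genes, breaks


def switch_enrichment_power(n_sims=100, mult=3.0, seed=0):
    """Power at p < 0.001 for planted B-to-A enrichment near breaks."""
    hits = 0
    for k in range(n_sims):
        rng = np.random.default_rng(_seed(seed, k))
        switches, breaks = _switch_sim(rng, mult=mult)
        enr = compartments.break_adjacent_switch_enrichment(switches, breaks)
        p = enr[enr["state"] == "BtoA"]["pvalue"].iloc[0]
        hits += int(p < 1e-3)
    return {"power": hits / n_sims, "n_sims": n_sims}


def switch_enrichment_null(n_sims=200, alpha=0.05, seed=0):
    """Rejection rate without planted enrichment (Fisher is conservative)."""
    rej = 0
    for k in range(n_sims):
        rng = np.random.default_rng(_seed(seed, k))
        switches, breaks = _switch_sim(rng, mult=1.0)
        enr = compartments.break_adjacent_switch_enrichment(switches, breaks)
        p = enr[enr["state"] == "BtoA"]["pvalue"].iloc[0]
        rej += int(p <= alpha)
    return {"rejection_rate": rej / n_sims, "alpha": alpha, "n_sims": n_sims}


# ----------------------------------------------------------------------
# Expression contrasts
# ----------------------------------------------------------------------

def expression_power(n_sims=100, n_orthologs=500, n_affected=50,
                     effect=2.0, seed=0):
    """Wilcoxon one-sided power for near-break divergence at alpha=0.05."""
    hits = 0
    for k in range(n_sims):
        pairs = [(f"a{i}", f"b{i}") for i in range(n_orthologs)]
        effect_map = simdata.plant_expression_effects(
            [f"a{i}" for i in range(n_affected)], effect)
        t1, t2 = simdata.simulate_expression(pairs, effect_map=effect_map,
                                             seed=_seed(seed, k))
        div, _ = trackmod.expression_divergence(t1, t2, pairs)
        d = div["divergence"].to_numpy()
        _, p = trackmod.group_compare(d[:n_affected], d[n_affected:],
                                      alternative="greater")
        hits += int(p < 0.05)
    return {"power": hits / n_sims, "n_sims": n_sims}


def expression_tad_contrasts(seed=0, n_null_sims=11):
    """Conserved-vs-rearranged TAD divergence contrast and the
    proximal-vs-distal null, mirroring the directional pattern of the
    study's expression figures."""
    pairs = [(f"a{i}", f"b{i}") for i in range(400)]
    rearranged = [f"a{i}" for i in range(300, 400)]
    effect_map = simdata.plant_expression_effects(rearranged, 1.5)
    t1, t2 = simdata.simulate_expression(pairs, effect_map=effect_map,
                                         seed=_seed(seed, 0))
    div, _ = trackmod.expression_divergence(t1, t2, pairs)
    d = div["divergence"].to_numpy()
    cons, rear = d[:300], d[300:]
    _, p_cons = trackmod.group_compare(rear, cons, alternative="greater")
    null_ps = []
    for k in range(n_null_sims):
        t1, t2 = simdata.simulate_expression(pairs, seed=_seed(seed, 1 + k))
        div, _ = trackmod.expression_divergence(t1, t2, pairs)
        d = div["divergence"].to_numpy()
        _, p = trackmod.group_compare(d[:200], d[200:])
        null_ps.append(p)
    return {"p_conserved_vs_rearranged": float(p_cons),
            "direction_ok": bool(rear.mean() > cons.mean()),
            "proximal_distal_null_median_p": float(np.median(null_ps)),
            "n_null_sims": n_null_sims}


# ----------------------------------------------------------------------
# Origin-stratified decay
# ----------------------------------------------------------------------

def _fused_decay_tables(seed, mode, genes_per_chrom=300, plaid=1.6,
                        tad=2.0):
    anc = simdata.simulate_ancestor(2, genes_per_chrom, 10_000, 50_000,
                                    seed=_seed(seed, 0))
    fused, truth = simdata.apply_rearrangements(
        anc, [simdata.RearrangementEvent("fusion", "chr01",
                                         dest_chrom="chr02")],
        species_id="fused")
    cov = simdata.simulate_bin_covariates(fused.bin_table(5_000),
                                          seed=_seed(seed, 1))
    params = simdata.ContactModelParams(mode=mode, dampening=0.3,
                                        plaid_contrast=plaid,
                                        tad_enrichment=tad)
    cm = simdata.simulate_contacts(fused, truth, 5_000, params,
                                   seed=_seed(seed, 2), covariates=cov)
    bal, _ = hicmat.ice_balance(cm)
    norm = hicmat.hicnorm_lite(bal, max_fit_pairs=50_000,
                               seed=_seed(seed, 3))
    _, _, table = hicmat.cis_decay_by_origin(norm, fused.origin_segments)
    return table


def origin_decay_direction(seed=0, min_pairs=50):
    """Same-origin mean contact versus different-origin, per distance bin,
    under ancestral-preserving simulation (dampening 0.3)."""
    table = _fused_decay_tables(seed, "ancestral_preserving")
    t = table[(table["n_same"] >= min_pairs) & (table["n_diff"] >= min_pairs)]
    ok = bool((t["mean_same"] > t["mean_diff"]).all())
    return {"all_bins_same_gt_diff": ok, "n_bins": int(len(t)),
            "min_margin": float((t["mean_same"] / t["mean_diff"]).min())
            if len(t) else np.nan}


def origin_decay_null(n_sims=100, seed=0, genes_per_chrom=300):
    """With no origin effect the per-bin p-values are uniform.

    Each replicate simulates a chromosome under the full forward model in
    mixed mode (no dampening), assigns an arbitrary two-origin labeling
    with a uniformly drawn junction, and runs the origin-stratified decay
    test on the ICE+HiCNorm-normalized matrix.  The labeling carries no
    information about the contacts, so the per-bin p-values must be
    uniform.
    """
    ps = []
    for k in range(n_sims):
        sk = _seed(seed, 100 + k)
        rng = np.random.default_rng(sk)
        g = simdata.simulate_ancestor(1, genes_per_chrom, 10_000, 50_000,
                                      seed=_seed(sk, 0))
        cov = simdata.simulate_bin_covariates(g.bin_table(5_000),
                                              seed=_seed(sk, 1))
        cm = simdata.simulate_contacts(g, g.architecture, 5_000,
                                       simdata.ContactModelParams(),
                                       seed=_seed(sk, 2), covariates=cov)
        bal, _ = hicmat.ice_balance(cm)
        norm = hicmat.hicnorm_lite(bal, max_fit_pairs=50_000,
                                   seed=_seed(sk, 3))
        chrom, length = g.chromosomes[0]
        nbins = length // 5_000
        cut = int(rng.integers(1, nbins)) * 5_000
        segs = pd.DataFrame(
            [(chrom, 0, cut, "ancA", 0, cut, "+"),
             (chrom, cut, length, "ancB", 0, length - cut, "+")],
            columns=["chrom", "start", "end", "anc_chrom", "anc_start",
                     "anc_end", "orientation"])
        _, _, table = hicmat.cis_decay_by_origin(norm, segs,
                                                 seed=_seed(sk, 4))
        # one populated bin per replicate: the per-bin p-values within a
        # replicate share the junction and the null draws, so pooling
        # them would feed correlated samples to the KS test; sparsely
        # populated bins are excluded because their permutation p-grid is
        # too coarse to compare against a continuous uniform
        ok = (table["n_same"] >= 50) & (table["n_diff"] >= 50)
        cand = table.loc[ok, "pvalue"].dropna().to_numpy()
        if cand.size:
            ps.append(float(cand[rng.integers(cand.size)]))
    ks = stats.kstest(ps, "uniform")
    return {"ks_pvalue": float(ks.pvalue), "n_pvalues": len(ps),
            "n_sims": n_sims}
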