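"""End-to-end comparative pipeline: simulate -> normalize -> call ->
compare -> test.

``run_pipeline`` executes the full analysis on a simulated multi-species
system (the demo configuration mirrors the study design: a reference
genome plus relatives differing by inversions, translocations and a
chromosome fusion): contact-matrix simulation at compartment (50 kb) and
TAD (5 kb) resolutions, ICE + Poisson-regression normalization, A/B
compartment and TAD calling, collinear-block synteny and break
derivation, break/TAD-boundary co-localization with shuffle nulls and
Fisher tests, compartment-switch classification with break-adjacency
enrichment, conserved-TAD classification, ortholog expression divergence
contrasts, and origin-stratified cis decay on fused chromosomes.

``validate_report`` scores a run against the simulator's planted truth,
stage by stage.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, coloc, compartments, hicmat, simdata, synteny
from . import scoring, tads as tadmod, tracks as trackmod

__all__ = ["RunConfig", "RunReport", "run_pipeline", "validate_report",
           "demo_config"]


@dataclass
class RunConfig:
    """Pipeline configuration; defaults carry every study parameter."""
    seed: int = 0
    n_chrom: int = 4
    genes_per_chrom: int = 300
    gene_spacing: int = 10_000
    comp_resolution: int = 50_000
    tad_resolution: int = 5_000
    species: list = field(default_factory=list)   # {name, events, mode}
    # calling / comparison thresholds
    min_genes: int = 10
    max_gap: int = 30
    insulation_window: int = 50_000
    tad_min_depth: float = 0.3
    tad_min_size: int = 25_000
    tad_intra_flank_ratio: float = 1.2
    tad_size_threshold: int = 60_000
    overlap_threshold: float = 0.5
    min_syntenic: int = 4
    switch_window: int = 10_000
    profile_flank: int = 20_000
    n_perm: int = 200
    # forward model
    depth: float = 80.0
    plaid_contrast: float = 1.6
    tad_enrichment: float = 2.0
    bias_sd: float = 0.25
    dampening: float = 0.3
    trans_scale: float = 0.02
    # planted comparative effects
    snap_to_boundaries: bool = True
    switch_flip_prob: float = 1.0
    switch_flip_window: int = 10_000
    near_break_expr_factor: float = 2.0
    rearranged_tad_expr_factor: float = 1.5

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path):
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def validate(self):
        if self.comp_resolution % self.tad_resolution:
            raise ValueError("compartment resolution must be a multiple of "
                             "the matrix (TAD) resolution")
        for name in ("min_genes", "max_gap", "tad_min_size", "switch_window",
                     "n_perm", "comp_resolution", "tad_resolution"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def config_hash(self):
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Machine-readable summary plus in-memory stage artifacts."""
    summary: dict
    artifacts: dict

    def to_json(self, path):
        Path(path).write_text(json.dumps(self.summary, indent=2,
                                         default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(type(x))


def _stage_seed(seed, label):
    h = hashlib.blake2b(f"{seed}:{label}".encode(), digest_size=4).digest()
    return int.from_bytes(h, "big") % (2 ** 31)


def demo_config(seed=0) -> RunConfig:
    """Three-species demo mirroring the study design: a fused-karyotype
    reference ('kirk'-like) versus two relatives with inversions and a
    translocation each."""
    return RunConfig(
        seed=seed,
        species=[
            {"name": "kirk", "mode": "ancestral_preserving", "events": [
                {"kind": "inversion", "chrom": "chr01", "start": 40, "end": 75},
                {"kind": "inversion", "chrom": "chr02", "start": 60, "end": 105},
                {"kind": "inversion", "chrom": "chr04", "start": 30, "end": 70},
                {"kind": "translocation", "chrom": "chr01", "start": 150,
                 "end": 195, "dest_chrom": "chr02", "dest_index": 220},
                {"kind": "fusion", "chrom": "chr03", "dest_chrom": "chr04"},
            ]},
            {"name": "arbo", "mode": "mixed", "events": [
                {"kind": "inversion", "chrom": "chr01", "start": 100, "end": 135},
                {"kind": "inversion", "chrom": "chr03", "start": 50, "end": 95},
                {"kind": "inversion", "chrom": "chr04", "start": 170, "end": 215},
                {"kind": "inversion", "chrom": "chr02", "start": 200, "end": 240},
                {"kind": "translocation", "chrom": "chr02", "start": 30,
                 "end": 75, "dest_chrom": "chr03", "dest_index": 150},
            ]},
            {"name": "raim", "mode": "mixed", "events": [
                {"kind": "inversion", "chrom": "chr04", "start": 100, "end": 145},
                {"kind": "inversion", "chrom": "chr02", "start": 140, "end": 180},
                {"kind": "inversion", "chrom": "chr01", "start": 200, "end": 240},
                {"kind": "inversion", "chrom": "chr03", "start": 30, "end": 65},
                {"kind": "translocation", "chrom": "chr03", "start": 120,
                 "end": 165, "dest_chrom": "chr01", "dest_index": 40},
            ]},
        ])


def run_pipeline(config: RunConfig, outdir=None) -> RunReport:
    """Execute all stages; deterministic for a fixed (config, seed)."""
    config.validate()
    t0 = time.time()
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
    summary = {"version": __version__, "config_hash": config.config_hash(),
               "stages": {}, "timings": {}}
    art = {"config": config}

    def stage(name):
        summary["timings"][name] = time.time() - t0
        return _stage_seed(config.seed, name)

    # ------------------------------------------------ simulate genomes
    s = stage("simulate")
    ancestor = simdata.simulate_ancestor(
        config.n_chrom, config.genes_per_chrom, config.gene_spacing,
        config.comp_resolution, seed=s)
    genomes, truths, modes = {}, {}, {}
    for spec in config.species:
        events = [simdata.RearrangementEvent(**e) for e in spec["events"]]
        if config.snap_to_boundaries:
            events = simdata.snap_events_to_boundaries(ancestor, events)
        g, truth = simdata.apply_rearrangements(ancestor, events,
                                                species_id=spec["name"])
        truth = simdata.plant_compartment_switches(
            truth, truth.planted_breakpoints, window=config.switch_flip_window,
            flip_prob=config.switch_flip_prob,
            seed=_stage_seed(s, spec["name"]))
        g.architecture = truth
        genomes[spec["name"]] = g
        truths[spec["name"]] = truth
        modes[spec["name"]] = spec.get("mode", "mixed")
    art["genomes"], art["truths"] = genomes, truths
    names = [sp["name"] for sp in config.species]
    summary["stages"]["simulate"] = {
        n: {"n_chrom": len(genomes[n].chromosomes),
            "n_genes": len(genomes[n].genes),
            "n_planted_breakpoints": len(truths[n].planted_breakpoints)}
        for n in names}

    # ------------------------------------------------ contact matrices
    s = stage("contacts")
    comp_mats, tad_mats = {}, {}
    for n in names:
        params_c = simdata.ContactModelParams(
            depth=config.depth, plaid_contrast=config.plaid_contrast,
            tad_enrichment=config.tad_enrichment, bias_sd=config.bias_sd,
            trans_scale=config.trans_scale)
        comp_mats[n] = simdata.simulate_contacts(
            genomes[n], truths[n], config.comp_resolution, params_c,
            seed=_stage_seed(s, n + ":comp"))
        cov = simdata.simulate_bin_covariates(
            genomes[n].bin_table(config.tad_resolution),
            seed=_stage_seed(s, n + ":cov"))
        params_t = simdata.ContactModelParams(
            depth=config.depth, plaid_contrast=config.plaid_contrast,
            tad_enrichment=config.tad_enrichment, bias_sd=config.bias_sd,
            mode=modes[n], dampening=config.dampening)
        tad_mats[n] = simdata.simulate_contacts(
            genomes[n], truths[n], config.tad_resolution, params_t,
            seed=_stage_seed(s, n + ":tad"), covariates=cov)

    # ------------------------------------------------ normalization
    s = stage("normalize")
    comp_bal, tad_bal = {}, {}
    for n in names:
        comp_bal[n], _ = hicmat.ice_balance(comp_mats[n])
        iced, _ = hicmat.ice_balance(tad_mats[n])
        tad_bal[n] = hicmat.hicnorm_lite(iced, max_fit_pairs=50_000,
                                         seed=_stage_seed(s, n))
        if out:
            hicmat.write_matrix(comp_bal[n], out / f"{n}.comp.triples.tsv",
                                out / f"{n}.comp.bins.bed")
    art["comp_matrices"], art["tad_matrices"] = comp_bal, tad_bal
    summary["stages"]["normalize"] = {
        n: {"norm_comp": comp_bal[n].norm, "norm_tad": tad_bal[n].norm,
            "masked_bins_comp": int(comp_bal[n].mask.sum())}
        for n in names}

    # ------------------------------------------------ compartments
    stage("compartments")
    profiles, fractions = {}, {}
    for n in names:
        dens = genomes[n].gene_density(config.comp_resolution)
        profiles[n] = compartments.call_compartments(comp_bal[n], dens)
        fractions[n] = compartments.compartment_fractions(profiles[n])
    art["profiles"] = profiles
    summary["stages"]["compartments"] = {
        n: {"pct_A": fractions[n][0], "pct_B": fractions[n][1],
            "flagged": profiles[n].flagged,
            "orientation_r": profiles[n].orientation_r}
        for n in names}

    # ------------------------------------------------ TADs
    stage("tads")
    tadsets = {}
    for n in names:
        ins = tadmod.insulation_score(tad_bal[n], config.insulation_window)
        tadsets[n] = tadmod.call_tads(
            ins, tad_bal[n], min_depth=config.tad_min_depth,
            min_size=config.tad_min_size,
            intra_flank_ratio=config.tad_intra_flank_ratio)
        if out:
            tadsets[n].domains.to_csv(out / f"{n}.tads.bed", sep="\t",
                                      header=False, index=False)
    art["tadsets"] = tadsets
    summary["stages"]["tads"] = {
        n: {"n_tads": len(tadsets[n].domains),
            "mean_size_kb": float(tadsets[n].domains["size"].mean() / 1000)
            if len(tadsets[n].domains) else np.nan,
            "n_boundaries": len(tadsets[n].boundaries)}
        for n in names}

    # ------------------------------------------------ synteny + breaks
    s = stage("synteny")
    pairs_list = [(names[i], names[j]) for i in range(len(names))
                  for j in range(i + 1, len(names))]
    pair_data = {}
    for n1, n2 in pairs_list:
        g1, g2 = genomes[n1], genomes[n2]
        hits = simdata.simulate_homolog_hits(g1, g2,
                                             seed=_stage_seed(s, n1 + n2))
        filtered = synteny.filter_homologs(hits)
        blocks = synteny.chain_collinear(
            g1.genes, g2.genes, filtered, max_gap=config.max_gap,
            min_genes=config.min_genes, n_perm=200,
            seed=_stage_seed(s, n1 + n2 + ":p"))
        breaks = synteny.derive_breaks(blocks, g1.genes, g2.genes,
                                       min_genes=config.min_genes,
                                       max_gap=config.max_gap)
        bdf = synteny.breaks_to_frame(breaks)
        sweep, knee = synteny.threshold_sweep(blocks, g1.genes, g2.genes,
                                              max_gap=config.max_gap)
        pair_data[(n1, n2)] = {"blocks": blocks, "breaks": bdf,
                               "sweep": sweep, "knee": knee}
        if out:
            bdf.to_csv(out / f"{n1}_vs_{n2}.breaks.bed", sep="\t",
                       header=False, index=False)
    art["pairs"] = pair_data
    summary["stages"]["synteny"] = {
        f"{a}_vs_{b}": {"n_blocks": len(d["blocks"]),
                        "n_breaks": len(d["breaks"]),
                        "sweep": d["sweep"].to_dict("list"),
                        "knee": d["knee"]}
        for (a, b), d in pair_data.items()}

    # ------------------------------------------------ co-localization
    s = stage("coloc")
    coloc_res = {}
    for (n1, n2), d in pair_data.items():
        sizes = dict(genomes[n1].chromosomes)
        breaks_set = coloc.IntervalSet(d["breaks"][["chrom", "start", "end"]],
                                       sizes, "breaks")
        res_pair = {}
        for part, df in (("boundaries", tadsets[n1].boundaries),
                         ("bodies", tadsets[n1].domains),
                         ("intervals", tadsets[n1].intervals)):
            iset = coloc.IntervalSet(df[["chrom", "start", "end"]], sizes, part)
            r = coloc.empirical_enrichment(
                breaks_set, iset, n_perm=config.n_perm, mode="shuffle_A",
                seed=_stage_seed(s, f"{n1}{n2}{part}"))
            res_pair[part] = {"observed_fraction": r.observed_fraction,
                              "null_mean": r.null_mean,
                              "p_empirical": r.p_empirical,
                              "odds_ratio": r.odds_ratio,
                              "p_fisher": r.p_fisher}
        for mode in ("shuffle_B", "shuffle_both"):
            iset = coloc.IntervalSet(
                tadsets[n1].boundaries[["chrom", "start", "end"]], sizes)
            r = coloc.empirical_enrichment(
                breaks_set, iset, n_perm=config.n_perm, mode=mode,
                seed=_stage_seed(s, f"{n1}{n2}{mode}"))
            res_pair[f"boundaries_{mode}"] = {"p_empirical": r.p_empirical}
        coloc_res[(n1, n2)] = res_pair
    art["coloc"] = coloc_res
    summary["stages"]["coloc"] = {f"{a}_vs_{b}": v
                                  for (a, b), v in coloc_res.items()}

    # ------------------------------------------------ compartment switches
    stage("switches")
    switch_res = {}
    for (n1, n2), d in pair_data.items():
        op = simdata.ortholog_pairs(genomes[n1], genomes[n2])
        calls, counts = compartments.classify_switches(profiles[n1],
                                                       profiles[n2], op)
        enr = compartments.break_adjacent_switch_enrichment(
            calls, d["breaks"], window=config.switch_window)
        switch_res[(n1, n2)] = {"calls": calls, "counts": counts,
                                "enrichment": enr}
    art["switches"] = switch_res
    summary["stages"]["switches"] = {
        f"{a}_vs_{b}": {"counts": v["counts"],
                        "enrichment": v["enrichment"].drop(
                            columns=["adj_other", "bg_other"]).to_dict("records")}
        for (a, b), v in switch_res.items()}

    # ------------------------------------------------ conserved TADs
    stage("conservation")
    conservation = {}
    for (n1, n2), d in pair_data.items():
        op = simdata.ortholog_pairs(genomes[n1], genomes[n2])
        cons = tadmod.classify_conserved(
            tadsets[n1], tadsets[n2], op, min_syntenic=config.min_syntenic,
            overlap_threshold=config.overlap_threshold)
        prox = tadmod.proximity_to_breaks(tadsets[n1], d["breaks"],
                                          window=config.switch_window)
        conservation[(n1, n2)] = {"table": cons, "proximity": prox}
    art["conservation"] = conservation
    summary["stages"]["conservation"] = {
        f"{a}_vs_{b}": dict(v["table"]["status"].value_counts())
        for (a, b), v in conservation.items()}

    # ------------------------------------------------ expression divergence
    s = stage("expression")
    expr_res = {}
    for (n1, n2), d in pair_data.items():
        op = simdata.ortholog_pairs(genomes[n1], genomes[n2])
        near = _near_break_mask(op, d["breaks"], config.switch_window)
        cons = conservation[(n1, n2)]["table"]
        dom_of = tadmod._assign_domains(tadsets[n1].domains,
                                        op["chrom1"].to_numpy(),
                                        op["pos1"].to_numpy())
        status_by_dom = dict(zip(cons["domain"], cons["status"]))
        dom_status = np.array([status_by_dom.get(dv, "unassessed")
                               for dv in dom_of])
        effect = {}
        # conserved domains buffer rearrangement effects: genes inside a
        # conserved TAD keep ancestral-like expression even near a break
        conserved_mask = dom_status == "conserved"
        for gid in op["gene_id1"][near & ~conserved_mask]:
            effect[gid] = config.near_break_expr_factor
        for gid in op["gene_id1"][(dom_status == "rearranged") & ~near]:
            effect[gid] = config.rearranged_tad_expr_factor
        t1, t2 = simdata.simulate_expression(
            list(op[["gene_id1", "gene_id2"]].itertuples(index=False)),
            effect_map=effect, seed=_stage_seed(s, n1 + n2))
        div, _ = trackmod.expression_divergence(
            t1, t2, list(op[["gene_id1", "gene_id2"]].itertuples(index=False)))
        div = div.set_index("gene_id1")
        dv = div["divergence"]
        g_near = dv[op["gene_id1"][near]].to_numpy()
        g_far = dv[op["gene_id1"][~near]].to_numpy()
        _, p_near = trackmod.group_compare(g_near, g_far,
                                           alternative="greater")
        g_cons = dv[op["gene_id1"][dom_status == "conserved"]].to_numpy()
        g_rear = dv[op["gene_id1"][dom_status == "rearranged"]].to_numpy()
        _, p_cons = trackmod.group_compare(g_rear, g_cons,
                                           alternative="greater") \
            if g_cons.size and g_rear.size else (np.nan, np.nan)
        prox = conservation[(n1, n2)]["proximity"]
        cons_doms = set(cons[cons["status"] == "conserved"]["domain"])
        prox_doms = set(prox.index[prox["proximity"] == "proximal"]) \
            & cons_doms
        dist_doms = cons_doms - prox_doms
        g_prox = dv[op["gene_id1"][np.isin(dom_of, list(prox_doms))]].to_numpy()
        g_dist = dv[op["gene_id1"][np.isin(dom_of, list(dist_doms))]].to_numpy()
        if g_prox.size and g_dist.size:
            _, p_prox = trackmod.group_compare(g_prox, g_dist)
        else:
            p_prox = np.nan
        expr_res[(n1, n2)] = {
            "mean_div_near": float(g_near.mean()) if g_near.size else np.nan,
            "mean_div_distal": float(g_far.mean()),
            "p_near_vs_distal": p_near,
            "mean_div_conserved": float(g_cons.mean()) if g_cons.size else np.nan,
            "mean_div_rearranged": float(g_rear.mean()) if g_rear.size else np.nan,
            "p_conserved_vs_rearranged": p_cons,
            "p_proximal_vs_distal_conserved": p_prox,
        }
    art["expression"] = expr_res
    summary["stages"]["expression"] = {f"{a}_vs_{b}": v
                                       for (a, b), v in expr_res.items()}

    # ------------------------------------------------ origin-stratified decay
    stage("decay")
    decay_res = {}
    for n in names:
        if modes[n] != "ancestral_preserving":
            continue
        g = genomes[n]
        fused = [c for c, _ in g.chromosomes
                 if g.origin_segments[g.origin_segments["chrom"] == c]
                 ["anc_chrom"].nunique() > 1]
        if not fused:
            continue
        same, diff, table = hicmat.cis_decay_by_origin(
            tad_bal[n], g.origin_segments, chroms=fused)
        decay_res[n] = table
    art["decay"] = decay_res
    summary["stages"]["decay"] = {
        n: t.to_dict("list") for n, t in decay_res.items()}

    # ------------------------------------------------ trans enrichment
    stage("trans")
    trans_res = {}
    for n in names:
        try:
            trans_res[n] = hicmat.trans_enrichment(comp_bal[n])
        except ValueError:
            continue
    art["trans"] = trans_res
    summary["stages"]["trans"] = {
        n: {"max_abs_score": float(t["log2_ratio"].abs().max())}
        for n, t in trans_res.items()}

    summary["timings"]["total"] = time.time() - t0
    report = RunReport(summary, art)
    if out:
        report.to_json(out / "report.json")
    return report


def _near_break_mask(op: pd.DataFrame, breaks: pd.DataFrame, window):
    near = np.zeros(len(op), dtype=bool)
    for _, b in breaks.iterrows():
        near |= ((op["chrom1"] == b["chrom"])
                 & (op["pos1"] >= b["start"] - window)
                 & (op["pos1"] < b["end"] + window)).to_numpy()
    return near


# ----------------------------------------------------------------------
# Scorecard
# ----------------------------------------------------------------------

def validate_report(report: RunReport) -> dict:
    """Score a pipeline run against the simulator's planted truth.

    Returns a scorecard dict with one entry per stage: measured metrics
    plus a boolean ``ok`` flag, and an overall ``all_ok``.
    """
    art = report.artifacts
    config: RunConfig = art["config"]
    genomes, truths = art["genomes"], art["truths"]
    card = {}

    # ICE: balanced row sums uniform
    cvs = []
    for n, m in art["comp_matrices"].items():
        keep = ~m.mask
        rs = np.nansum(np.nan_to_num(m.matrix[np.ix_(keep, keep)]), axis=1)
        cvs.append(rs.std() / rs.mean())
    card["ice"] = {"max_rowsum_cv": float(max(cvs)),
                   "ok": max(cvs) < 1e-4}

    # compartments: label agreement with planted truth
    agrees, orient_ok = [], True
    for n, prof in art["profiles"].items():
        truth = truths[n]
        df = prof.bins
        lab = df["label"].to_numpy()
        true_lab = np.concatenate([
            truth.compartment_bins(c, config.comp_resolution,
                                   int((df["chrom"] == c).sum()))
            for c in dict(genomes[n].chromosomes)])
        ok = lab != "NA"
        agrees.append((lab[ok] == true_lab[ok]).mean())
        orient_ok &= all(r >= compartments.ORIENTATION_MIN_R
                         for r in prof.orientation_r.values())
    card["compartments"] = {"min_agreement": float(min(agrees)),
                            "orientation_ok": bool(orient_ok),
                            "ok": min(agrees) >= 0.95 and orient_ok}

    # TADs: boundary F1 against planted truth (any hit inside a true
    # inter-TAD gap recovers it; compartment transitions and rearrangement
    # junctions are genuine insulation features, not false positives)
    f1s = []
    for n, ts in art["tadsets"].items():
        truth = truths[n]
        res = config.tad_resolution
        for chrom, length in genomes[n].chromosomes:
            gaps = scoring.boundary_truth_regions(truth.tad_truth, chrom, res)
            if len(gaps) < 2:
                continue
            called = ts.boundaries[ts.boundaries["chrom"] == chrom][
                "min_bin"].to_numpy()
            extra = list(_label_transition_bins(truth, chrom, length, res))
            bps = truth.planted_breakpoints
            extra += [int(p // res) for p in
                      bps[bps["chrom"] == chrom]["position"]]
            m = scoring.boundary_region_f1(
                called, gaps, tol=1, extra_ok_bins=extra,
                region=(gaps[0][0] - 1, gaps[-1][1] + 1))
            f1s.append(m["f1"])
    card["tads"] = {"mean_boundary_f1": float(np.mean(f1s)),
                    "ok": float(np.mean(f1s)) >= 0.9}

    # synteny: break recall / precision vs planted junctions
    recs, precs = [], []
    for (n1, n2), d in art["pairs"].items():
        truth_pos = scoring.pair_break_truth(genomes[n1], genomes[n2])
        m = scoring.match_breaks(d["breaks"], truth_pos,
                                 tol=int(1.5 * config.gene_spacing))
        recs.append(m["recall"])
        precs.append(m["precision"])
    card["synteny"] = {"min_recall": float(min(recs)),
                       "min_precision": float(min(precs)),
                       "ok": min(recs) == 1.0 and min(precs) >= 0.95}

    # co-localization: breaks at TAD boundaries
    pf, pe = [], []
    for v in art["coloc"].values():
        pf.append(v["boundaries"]["p_fisher"])
        pe.append(max(v["boundaries"]["p_empirical"],
                      v["boundaries_shuffle_B"]["p_empirical"],
                      v["boundaries_shuffle_both"]["p_empirical"]))
    card["coloc"] = {"max_p_fisher": float(max(pf)),
                     "max_p_empirical": float(max(pe)),
                     "ok": max(pf) < 1e-3 and max(pe) < 0.05}

    # switches: B-to-A enrichment adjacent to breaks
    ps = []
    for v in art["switches"].values():
        enr = v["enrichment"]
        row = enr[enr["state"] == "BtoA"].iloc[0]
        ps.append(row["pvalue"])
    card["switches"] = {"max_p_BtoA": float(max(ps)),
                        "ok": max(ps) < 0.05}

    # expression contrasts (Fig. 4a-c directional pattern)
    pn, pc, pp = [], [], []
    direction_ok = True
    for v in art["expression"].values():
        pn.append(v["p_near_vs_distal"])
        if np.isfinite(v["p_conserved_vs_rearranged"]):
            pc.append(v["p_conserved_vs_rearranged"])
            direction_ok &= (v["mean_div_rearranged"]
                             > v["mean_div_conserved"])
        if np.isfinite(v["p_proximal_vs_distal_conserved"]):
            pp.append(v["p_proximal_vs_distal_conserved"])
    card["expression"] = {
        "max_p_near_vs_distal": float(max(pn)),
        "max_p_conserved_vs_rearranged": float(max(pc)) if pc else np.nan,
        "min_p_proximal_vs_distal": float(min(pp)) if pp else np.nan,
        "ok": (max(pn) < 0.05 and bool(pc) and max(pc) < 0.05
               and direction_ok and (not pp or min(pp) > 0.05)),
    }

    # origin decay: same-origin stronger in every populated bin
    decay_ok, n_bins_checked = True, 0
    for n, table in art["decay"].items():
        t = table[(table["n_same"] >= 50) & (table["n_diff"] >= 50)]
        n_bins_checked += len(t)
        decay_ok &= bool((t["mean_same"] > t["mean_diff"]).all())
    card["decay"] = {"n_distance_bins": n_bins_checked,
                     "ok": decay_ok and n_bins_checked > 0}

    card["all_ok"] = all(v["ok"] for k, v in card.items()
                         if isinstance(v, dict))
    return card


def _label_transition_bins(truth, chrom, length, resolution):
    """Bins (at matrix resolution) where the planted compartment label
    changes; the forward model creates genuine insulation there."""
    nb = int(np.ceil(length / resolution))
    labs = truth.compartment_bins(chrom, resolution, nb)
    return np.flatnonzero(labs[1:] != labs[:-1]) + 1
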