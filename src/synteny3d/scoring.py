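"""Helpers for scoring called structures against simulator ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "boundary_truth_bins",
    "boundary_f1",
    "match_breaks",
    "map_ancestral_position",
    "pair_break_truth",
]


def boundary_truth_bins(tad_truth: pd.DataFrame, chrom, resolution,
                        max_gap=30_000):
    """True boundary bin positions: centers of inter-TAD gaps.

    Consecutive true domains separated by at most ``max_gap`` bp define a
    boundary at the gap center (abutting domains share an edge).  Returns
    a sorted array of bin indices.
    """
    t = tad_truth[tad_truth["chrom"] == chrom].sort_values("start")
    out = []
    for (_, a), (_, b) in zip(t.iterrows(), t.iloc[1:].iterrows()):
        gap = b["start"] - a["end"]
        if 0 <= gap <= max_gap:
            out.append(int((a["end"] + b["start"]) // 2 // resolution))
    return np.array(sorted(set(out)), dtype=int)


def boundary_truth_regions(tad_truth: pd.DataFrame, chrom, resolution,
                           max_gap=30_000):
    """True boundary regions as (lo_bin, hi_bin) spans of inter-TAD gaps."""
    t = tad_truth[tad_truth["chrom"] == chrom].sort_values("start")
    out = []
    for (_, a), (_, b) in zip(t.iterrows(), t.iloc[1:].iterrows()):
        gap = b["start"] - a["end"]
        if 0 <= gap <= max_gap:
            out.append((int(a["end"] // resolution),
                        int(max(a["end"] // resolution,
                                (b["start"] - 1) // resolution))))
    return out


def boundary_region_f1(called_bins, gap_regions, tol=1, extra_ok_bins=(),
                       region=None):
    """F1 where any called bin inside a true inter-TAD gap (+/- tol bins)
    recovers that gap; called bins in no gap and not near
    ``extra_ok_bins`` are false positives."""
    called = np.asarray(sorted(set(called_bins)), dtype=int)
    if region is not None:
        called = called[(called >= region[0]) & (called <= region[1])]
    extra = np.asarray(sorted(extra_ok_bins), dtype=int)
    tp = 0
    matched = np.zeros(len(called), dtype=bool)
    for lo, hi in gap_regions:
        inb = (called >= lo - tol) & (called <= hi + tol)
        if inb.any():
            tp += 1
            matched |= inb
    fp = sum(1 for c, m in zip(called, matched)
             if not m and not (extra.size and np.min(np.abs(extra - c)) <= tol))
    fn = len(gap_regions) - tp
    prec = tp / (tp + fp) if tp + fp else 1.0
    rec = tp / (tp + fn) if tp + fn else 1.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return {"f1": f1, "precision": prec, "recall": rec,
            "tp": tp, "fp": fp, "fn": fn}


def boundary_f1(called_bins, truth_bins, tol=1, extra_ok_bins=(),
                region=None):
    """F1 of called boundary bins against truth at +/- ``tol`` bins.

    ``extra_ok_bins`` are positions that do not count as false positives
    (e.g. genuine insulation features outside the truth set);
    ``region=(lo, hi)`` restricts scoring to called bins inside it.
    Matching is greedy one-to-one in sorted order.
    """
    called = np.asarray(sorted(called_bins), dtype=int)
    truth = np.asarray(sorted(truth_bins), dtype=int)
    if region is not None:
        called = called[(called >= region[0]) & (called <= region[1])]
    used = np.zeros(truth.size, dtype=bool)
    tp = 0
    fp_cands = []
    for c in called:
        d = np.abs(truth - c) if truth.size else np.array([])
        ok = np.flatnonzero((d <= tol) & ~used)
        if ok.size:
            used[ok[np.argmin(d[ok])]] = True
            tp += 1
        else:
            fp_cands.append(c)
    extra = np.asarray(sorted(extra_ok_bins), dtype=int)
    fp = sum(1 for c in fp_cands
             if not (extra.size and np.min(np.abs(extra - c)) <= tol))
    fn = int((~used).sum())
    prec = tp / (tp + fp) if tp + fp else 1.0
    rec = tp / (tp + fn) if tp + fn else 1.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return {"f1": f1, "precision": prec, "recall": rec,
            "tp": tp, "fp": fp, "fn": fn}


def match_breaks(breaks: pd.DataFrame, truth_positions, tol=15_000):
    """Match called break intervals to truth junction positions.

    ``truth_positions`` is a list of junctions, each a list of candidate
    (chrom, pos) locations: a junction is recovered when any called break
    interval comes within ``tol`` bp of any of its candidates; a called
    break is true when it matches any junction.  Returns dict with
    recall/precision/counts.
    """
    n_truth = len(truth_positions)
    truth_hit = np.zeros(n_truth, dtype=bool)
    break_hit = np.zeros(len(breaks), dtype=bool)
    for bi, row in breaks.reset_index(drop=True).iterrows():
        for ti, cands in enumerate(truth_positions):
            for chrom, pos in cands:
                if chrom != row["chrom"]:
                    continue
                if row["start"] - tol <= pos <= row["end"] + tol:
                    truth_hit[ti] = True
                    break_hit[bi] = True
                    break
    recall = truth_hit.mean() if n_truth else 1.0
    precision = break_hit.mean() if len(breaks) else 1.0
    return {"recall": float(recall), "precision": float(precision),
            "n_truth": n_truth, "n_breaks": int(len(breaks)),
            "n_truth_recovered": int(truth_hit.sum())}


def map_ancestral_position(origin_segments: pd.DataFrame, anc_chrom, anc_pos):
    """Map an ancestral position into a genome via its origin segments.

    Returns (chrom, pos) or None when the locus was lost.
    """
    seg = origin_segments[
        (origin_segments["anc_chrom"] == anc_chrom)
        & (origin_segments["anc_start"] <= anc_pos)
        & (origin_segments["anc_end"] > anc_pos)]
    if seg.empty:
        return None
    s = seg.iloc[0]
    if s["orientation"] == "+":
        return s["chrom"], int(s["start"] + (anc_pos - s["anc_start"]))
    return s["chrom"], int(s["end"] - 1 - (anc_pos - s["anc_start"]))


def pair_break_truth(genome1, genome2, flank=1):
    """Truth junction positions for a species pair, on species-1 coordinates.

    Species-1 junctions contribute their own positions; species-2
    junctions contribute the species-1 images of their two ancestral
    flanks (a junction between provenance segments corresponds to two
    ancestral loci, either of which may host the resulting block end on
    the partner genome).
    """
    out = []
    segs1 = genome1.origin_segments
    for chrom in {c for c, _ in genome1.chromosomes}:
        seg = genome1.origin_segments[
            genome1.origin_segments["chrom"] == chrom].sort_values("start")
        for (_, a), (_, b) in zip(seg.iterrows(), seg.iloc[1:].iterrows()):
            out.append([(chrom, int(b["start"]))])
    for chrom in {c for c, _ in genome2.chromosomes}:
        seg = genome2.origin_segments[
            genome2.origin_segments["chrom"] == chrom].sort_values("start")
        for (_, a), (_, b) in zip(seg.iterrows(), seg.iloc[1:].iterrows()):
            cands = []
            for anc_chrom, anc_pos in (
                    (a["anc_chrom"], a["anc_end"] - 1 if a["orientation"] == "+"
                     else a["anc_start"]),
                    (b["anc_chrom"], b["anc_start"] if b["orientation"] == "+"
                     else b["anc_end"] - 1)):
                hit = map_ancestral_position(segs1, anc_chrom, anc_pos)
                if hit is not None:
                    cands.append((hit[0], hit[1]))
            if cands:
                out.append(cands)
    return out
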