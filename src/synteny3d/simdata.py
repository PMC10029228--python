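"""Forward simulator with known ground truth.

Generates related "species" genomes that differ by inversions,
translocations, fusions and fissions with known breakpoints; Hi-C contact
matrices with power-law distance decay, compartment plaid, TAD blocks and
bin biases; ortholog expression tables with planted divergence effects;
and binned epigenetic tracks with planted contrasts at anchors.  Every
downstream stage of the pipeline can therefore be scored against planted
truth.

Genomes are gene-centric: genes of fixed length are placed along
chromosomes with compartment-dependent density (A compartments are
gene-dense, mirroring the orientation convention used for compartment
calling).  Rearrangement events are specified in gene-index coordinates;
the genome is cut at midpoints between genes so that no gene ever
straddles a junction.  Provenance (``origin_segments``) is tracked exactly
and composes across successive rounds of rearrangement.

All coordinates are 0-based half-open.  Every operation takes an explicit
seed; there is no hidden global RNG state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hicmat import ContactMatrix

__all__ = [
    "ContactModelParams",
    "SimGenome",
    "SimTruth",
    "RearrangementEvent",
    "MarkSpec",
    "simulate_ancestor",
    "apply_rearrangements",
    "simulate_contacts",
    "simulate_bin_covariates",
    "simulate_expression",
    "simulate_tracks",
    "plant_expression_effects",
    "plant_compartment_switches",
    "ortholog_pairs",
    "simulate_homolog_hits",
]


@dataclass
class ContactModelParams:
    """Forward-model parameters for contact simulation.

    ``depth`` is the expected count at one-bin distance for unit biases.
    ``mode="ancestral_preserving"`` dampens cross-origin pairs within a
    fused/rearranged chromosome by ``dampening`` (< 1); ``mode="mixed"``
    applies no dampening.
    """
    alpha: float = 1.0
    plaid_contrast: float = 1.6
    tad_enrichment: float = 2.0
    bias_sd: float = 0.25
    depth: float = 80.0
    mode: str = "mixed"
    dampening: float = 0.3
    trans_scale: float = 0.0
    #: distance (bp) over which the plaid factor ramps to full strength;
    #: short-range contacts are decay-dominated and compartment-blind
    plaid_ramp_bp: float = 100_000.0


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator.

    ``compartment_truth`` maps chromosome name to an array of 'A'/'B'
    labels at ``comp_bin_size`` resolution covering the chromosome;
    ``tad_truth`` lists true domain intervals in bp;
    ``planted_breakpoints`` lists rearrangement junction positions;
    ``expression_effect`` maps ancestral gene ids to multiplicative
    ortholog-divergence factors (absent = 1.0).
    """
    species_id: str
    planted_breakpoints: pd.DataFrame
    comp_bin_size: int
    compartment_truth: dict
    tad_truth: pd.DataFrame
    expression_effect: dict = field(default_factory=dict)
    contact_params: ContactModelParams | None = None

    def compartment_label(self, chrom, pos):
        labels = self.compartment_truth[chrom]
        k = min(int(pos) // self.comp_bin_size, len(labels) - 1)
        return labels[k]

    def compartment_bins(self, chrom, bin_size, n_bins):
        """Resample truth labels at another bin size (midpoint rule)."""
        mids = np.arange(n_bins) * bin_size + bin_size // 2
        labels = self.compartment_truth[chrom]
        idx = np.minimum(mids // self.comp_bin_size, len(labels) - 1)
        return np.asarray(labels)[idx]


@dataclass
class SimGenome:
    """A simulated genome: chromosomes, genes, and provenance segments.

    ``genes`` columns: gene_id, chrom, start, end, strand,
    ancestral_gene_id (sorted by chrom then start).
    ``origin_segments`` columns: chrom, start, end, anc_chrom, anc_start,
    anc_end, orientation; segments tile each chromosome without overlap.
    ``architecture`` carries this genome's own chromatin ground truth.
    """
    species_id: str
    chromosomes: list
    genes: pd.DataFrame
    origin_segments: pd.DataFrame
    architecture: SimTruth | None = None

    def chrom_length(self, chrom):
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def bin_table(self, bin_size):
        rows = []
        for name, length in self.chromosomes:
            starts = np.arange(0, length, bin_size)
            for s in starts:
                rows.append((name, int(s), int(min(s + bin_size, length))))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def gene_density(self, bin_size):
        """Genes per bin (midpoint assignment), aligned to bin_table."""
        bins = self.bin_table(bin_size)
        counts = np.zeros(len(bins))
        offset = 0
        for name, length in self.chromosomes:
            nb = int(np.ceil(length / bin_size))
            g = self.genes[self.genes["chrom"] == name]
            mids = ((g["start"] + g["end"]) // 2).to_numpy()
            idx = np.minimum(mids // bin_size, nb - 1)
            np.add.at(counts, offset + idx, 1)
            offset += nb
        return counts


@dataclass
class RearrangementEvent:
    """A rearrangement in gene-index coordinates of the input genome.

    kind:
      - ``inversion``: reverse genes [start, end) of ``chrom``.
      - ``translocation``: move genes [start, end) of ``chrom`` to
        ``dest_chrom`` before gene ``dest_index`` (``invert`` flips it).
      - ``fusion``: append whole ``dest_chrom`` to whole ``chrom``
        (``invert`` flips the appended chromosome).
      - ``fission``: split ``chrom`` before gene ``start``.
    """
    kind: str
    chrom: str
    start: int | None = None
    end: int | None = None
    dest_chrom: str | None = None
    dest_index: int | None = None
    invert: bool = False


# ----------------------------------------------------------------------
# Ancestor simulation
# ----------------------------------------------------------------------

def simulate_ancestor(n_chrom, genes_per_chrom, gene_spacing=10_000,
                      bin_size=50_000, seed=0, *, species_id="ancestor",
                      gene_length=2_000, a_fraction=0.5, density_ratio=2.0,
                      comp_run_bins=(6, 14), tad_size_range=(80_000, 200_000),
                      tad_gap_range=(10_000, 20_000)) -> SimGenome:
    """Simulate an ancestral genome with planted chromatin architecture.

    Chromosome length is ``genes_per_chrom * gene_spacing`` rounded up to a
    multiple of ``bin_size``.  Compartments are planted as alternating A/B
    runs of ``comp_run_bins`` bins (run lengths skewed to hit
    ``a_fraction`` of the genome in A); genes are placed with density
    ratio ``density_ratio`` in A versus B so that gene density orients the
    compartment eigenvector.  TADs tile each chromosome with
    ``tad_size_range`` domains separated by ``tad_gap_range`` gaps (the
    non-side-by-side plant convention).
    """
    if n_chrom < 1 or genes_per_chrom < 2:
        raise ValueError("need n_chrom >= 1 and genes_per_chrom >= 2")
    if gene_spacing <= 0 or bin_size <= 0 or gene_length <= 0:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)
    chrom_len = int(np.ceil(genes_per_chrom * gene_spacing / bin_size)) * bin_size
    n_bins = chrom_len // bin_size
    chromosomes, gene_rows, seg_rows = [], [], []
    comp_truth, tad_rows = {}, []
    for c in range(n_chrom):
        name = f"chr{c + 1:02d}"
        chromosomes.append((name, chrom_len))
        # compartment runs
        labels = np.empty(n_bins, dtype="<U1")
        lab = rng.choice(["A", "B"])
        pos = 0
        lo, hi = comp_run_bins
        while pos < n_bins:
            base = rng.integers(lo, hi + 1)
            scale = 2 * a_fraction if lab == "A" else 2 * (1 - a_fraction)
            run = max(1, int(round(base * scale)))
            labels[pos:pos + run] = lab
            pos += run
            lab = "A" if lab == "B" else "B"
        comp_truth[name] = labels
        # gene placement: piecewise-constant density by compartment
        w = np.where(labels == "A", density_ratio, 1.0)
        cum = np.concatenate([[0.0], np.cumsum(w * bin_size)])
        total = cum[-1]
        n = genes_per_chrom
        targets = (np.arange(n) + 0.5) / n * total
        targets += rng.uniform(-0.2, 0.2, n) * total / n
        targets = np.clip(np.sort(targets), 0, total - 1e-9)
        idx = np.searchsorted(cum, targets, side="right") - 1
        mids = idx * bin_size + (targets - cum[idx]) / w[idx]
        # enforce separation so genes never overlap
        min_sep = gene_length + 200
        mids = np.maximum.accumulate(mids + np.arange(n) * 1e-9)
        for k in range(1, n):
            if mids[k] - mids[k - 1] < min_sep:
                mids[k] = mids[k - 1] + min_sep
        mids = np.clip(mids, gene_length, chrom_len - gene_length)
        strands = rng.choice(["+", "-"], n)
        for k in range(n):
            s = int(mids[k]) - gene_length // 2
            gid = f"{species_id}_{name}_g{k:05d}"
            gene_rows.append((gid, name, s, s + gene_length, strands[k], gid))
        seg_rows.append((name, 0, chrom_len, name, 0, chrom_len, "+"))
        # TAD tiling
        pos = 0
        while True:
            gap = int(rng.integers(*tad_gap_range))
            size = int(rng.integers(*tad_size_range))
            if pos + gap + size > chrom_len:
                break
            tad_rows.append((name, pos + gap, pos + gap + size))
            pos += gap + size
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end",
                                             "strand", "ancestral_gene_id"])
    segs = pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "anc_chrom",
                                           "anc_start", "anc_end", "orientation"])
    tads = pd.DataFrame(tad_rows, columns=["chrom", "start", "end"])
    truth = SimTruth(species_id, pd.DataFrame(columns=["chrom", "position"]),
                     bin_size, comp_truth, tads)
    return SimGenome(species_id, chromosomes, genes, segs, architecture=truth)


# ----------------------------------------------------------------------
# Rearrangements
# ----------------------------------------------------------------------

def _gene_cut_bp(genes_c: pd.DataFrame, chrom_len: int, k: int) -> int:
    """bp position of the cut before gene index k (midpoint between genes)."""
    n = len(genes_c)
    if k <= 0:
        return 0
    if k >= n:
        return chrom_len
    prev_end = int(genes_c.iloc[k - 1]["end"])
    nxt_start = int(genes_c.iloc[k]["start"])
    return (prev_end + nxt_start) // 2


def apply_rearrangements(genome: SimGenome, events, seed=0, species_id=None):
    """Apply rearrangement events; return (derived genome, ground truth).

    Provenance segments of the derived genome record ancestry exactly
    (composing with the input genome's own origin segments), and a planted
    breakpoint is emitted at every junction between segments of distinct
    ancestral provenance or flipped orientation.  Chromatin architecture
    (compartment labels, TAD intervals) is mapped through the
    rearrangement so the derived genome carries its own truth.
    """
    if species_id is None:
        species_id = genome.species_id + "_derived"
    events = list(events)
    # validate
    by_chrom = {}
    for ev in events:
        if ev.kind not in {"inversion", "translocation", "fusion", "fission"}:
            raise ValueError(f"unknown event kind {ev.kind!r}")
        if ev.kind in {"inversion", "translocation"}:
            if ev.start is None or ev.end is None or ev.start >= ev.end:
                raise ValueError("event interval must be non-empty")
            by_chrom.setdefault(ev.chrom, []).append((ev.start, ev.end))
        if ev.kind == "translocation":
            if ev.dest_chrom is None or ev.dest_chrom == ev.chrom:
                raise ValueError("translocation needs a distinct destination "
                                 "chromosome")
        if ev.kind == "fusion" and (ev.dest_chrom is None
                                    or ev.dest_chrom == ev.chrom):
            raise ValueError("fusion consumes two distinct whole chromosomes")
    for chrom, ivs in by_chrom.items():
        ivs = sorted(ivs)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping event intervals on {chrom}")

    genes_by_chrom = {c: genome.genes[genome.genes["chrom"] == c]
                      .sort_values("start").reset_index(drop=True)
                      for c, _ in genome.chromosomes}
    # collect cut positions (bp, input coordinates) per chromosome
    cuts = {c: {0, length} for c, length in genome.chromosomes}
    for ev in events:
        g = genes_by_chrom[ev.chrom]
        L = genome.chrom_length(ev.chrom)
        if ev.kind in {"inversion", "translocation"}:
            if ev.end > len(g):
                raise ValueError("event interval beyond gene count")
            cuts[ev.chrom].add(_gene_cut_bp(g, L, ev.start))
            cuts[ev.chrom].add(_gene_cut_bp(g, L, ev.end))
        if ev.kind == "translocation":
            gd = genes_by_chrom[ev.dest_chrom]
            Ld = genome.chrom_length(ev.dest_chrom)
            cuts[ev.dest_chrom].add(_gene_cut_bp(gd, Ld, ev.dest_index or 0))
        if ev.kind == "fission":
            cuts[ev.chrom].add(_gene_cut_bp(g, L, ev.start))

    # piece lists: (src_chrom, start, end, orient) in input coordinates
    layout = {}
    for c, _ in genome.chromosomes:
        edges = sorted(cuts[c])
        layout[c] = [[c, a, b, +1] for a, b in zip(edges, edges[1:]) if b > a]

    def find_span(pieces, src_chrom, lo, hi):
        first = last = None
        for k, p in enumerate(pieces):
            if p[0] == src_chrom and p[1] >= lo and p[2] <= hi:
                if first is None:
                    first = k
                last = k
        if first is None:
            raise ValueError("event interval not found (moved by a prior event?)")
        return first, last + 1

    order = [c for c, _ in genome.chromosomes]
    for ev in events:
        g = genes_by_chrom.get(ev.chrom)
        L = genome.chrom_length(ev.chrom) if ev.chrom in dict(genome.chromosomes) else None
        if ev.kind == "inversion":
            lo = _gene_cut_bp(g, L, ev.start)
            hi = _gene_cut_bp(g, L, ev.end)
            a, b = find_span(layout[ev.chrom], ev.chrom, lo, hi)
            seg = layout[ev.chrom][a:b][::-1]
            layout[ev.chrom][a:b] = [[p[0], p[1], p[2], -p[3]] for p in seg]
        elif ev.kind == "translocation":
            lo = _gene_cut_bp(g, L, ev.start)
            hi = _gene_cut_bp(g, L, ev.end)
            a, b = find_span(layout[ev.chrom], ev.chrom, lo, hi)
            seg = layout[ev.chrom][a:b]
            del layout[ev.chrom][a:b]
            if ev.invert:
                seg = [[p[0], p[1], p[2], -p[3]] for p in seg[::-1]]
            gd = genes_by_chrom[ev.dest_chrom]
            Ld = genome.chrom_length(ev.dest_chrom)
            cut = _gene_cut_bp(gd, Ld, ev.dest_index or 0)
            dest = layout[ev.dest_chrom]
            at = 0
            for k, p in enumerate(dest):
                if p[0] == ev.dest_chrom and p[1] >= cut:
                    at = k
                    break
            else:
                at = len(dest)
            layout[ev.dest_chrom] = dest[:at] + seg + dest[at:]
        elif ev.kind == "fusion":
            other = layout.pop(ev.dest_chrom)
            if ev.invert:
                other = [[p[0], p[1], p[2], -p[3]] for p in other[::-1]]
            new = f"{ev.chrom}-{ev.dest_chrom}"
            layout[new] = layout.pop(ev.chrom) + other
            order = [new if c == ev.chrom else c for c in order
                     if c != ev.dest_chrom]
        elif ev.kind == "fission":
            cut = _gene_cut_bp(g, L, ev.start)
            pieces = layout.pop(ev.chrom)
            split_at = len(pieces)
            for k, p in enumerate(pieces):
                if p[0] == ev.chrom and p[1] >= cut:
                    split_at = k
                    break
            left, right = pieces[:split_at], pieces[split_at:]
            la, lb = f"{ev.chrom}a", f"{ev.chrom}b"
            layout[la], layout[lb] = left, right
            idx = order.index(ev.chrom)
            order = order[:idx] + [la, lb] + order[idx + 1:]

    # ------------------------------------------------------------------
    # build the derived genome
    input_truth = genome.architecture
    in_segs = genome.origin_segments
    chromosomes, gene_rows, seg_rows, bp_rows = [], [], [], []
    comp_truth, tad_rows = {}, []
    gene_counter = 0
    for c in order:
        pieces = layout[c]
        length = sum(p[2] - p[1] for p in pieces)
        chromosomes.append((c, length))
        # derived genes + derived->input mapping
        offset = 0
        dmap = []  # (d_start, d_end, src_chrom, s_start, s_end, orient)
        for src, a, b, orient in pieces:
            dmap.append((offset, offset + (b - a), src, a, b, orient))
            g = genes_by_chrom[src]
            sel = g[(g["start"] >= a) & (g["end"] <= b)]
            for _, row in sel.iterrows():
                if orient > 0:
                    ns = offset + (row["start"] - a)
                    strand = row["strand"]
                else:
                    ns = offset + (b - row["end"])
                    strand = "-" if row["strand"] == "+" else "+"
                gene_rows.append([None, c, int(ns), int(ns) + (row["end"] - row["start"]),
                                  strand, row["ancestral_gene_id"]])
            offset += b - a
        # compose provenance with the input genome's origin segments
        comp_segs = []
        for d0, d1, src, a, b, orient in dmap:
            over = in_segs[(in_segs["chrom"] == src)
                           & (in_segs["end"] > a) & (in_segs["start"] < b)]
            for _, s in over.sort_values("start").iterrows():
                oa, ob = max(a, s["start"]), min(b, s["end"])
                if orient > 0:
                    ds, de = d0 + (oa - a), d0 + (ob - a)
                else:
                    ds, de = d0 + (b - ob), d0 + (b - oa)
                so = 1 if s["orientation"] == "+" else -1
                if so > 0:
                    aa = s["anc_start"] + (oa - s["start"])
                    ab = s["anc_start"] + (ob - s["start"])
                else:
                    aa = s["anc_end"] - (ob - s["start"])
                    ab = s["anc_end"] - (oa - s["start"])
                comp_segs.append([ds, de, s["anc_chrom"], int(aa), int(ab),
                                  orient * so, src, oa, ob, orient])
        comp_segs.sort(key=lambda r: r[0])
        # merge ancestrally contiguous neighbours
        merged = []
        for seg in comp_segs:
            if merged:
                m = merged[-1]
                if (m[2] == seg[2] and m[5] == seg[5] and m[1] == seg[0]
                        and ((m[5] > 0 and m[4] == seg[3])
                             or (m[5] < 0 and m[3] == seg[4]))):
                    m[1] = seg[1]
                    if m[5] > 0:
                        m[4] = seg[4]
                    else:
                        m[3] = seg[3]
                    continue
            merged.append(list(seg))
        for m in merged:
            seg_rows.append((c, m[0], m[1], m[2], m[3], m[4],
                             "+" if m[5] > 0 else "-"))
        for prev, nxt in zip(merged, merged[1:]):
            bp_rows.append((c, int(nxt[0])))
        # map chromatin architecture through the derived->input map
        if input_truth is not None:
            nb = int(np.ceil(length / input_truth.comp_bin_size))
            labels = np.empty(nb, dtype="<U1")
            mids = np.arange(nb) * input_truth.comp_bin_size \
                + input_truth.comp_bin_size // 2
            mids = np.minimum(mids, length - 1)
            for d0, d1, src, a, b, orient in dmap:
                sel = (mids >= d0) & (mids < d1)
                if not sel.any():
                    continue
                ip = (a + (mids[sel] - d0)) if orient > 0 else (b - 1 - (mids[sel] - d0))
                labels[sel] = [input_truth.compartment_label(src, p) for p in ip]
            comp_truth[c] = labels
            tt = input_truth.tad_truth
            for d0, d1, src, a, b, orient in dmap:
                over = tt[(tt["chrom"] == src) & (tt["end"] > a) & (tt["start"] < b)]
                for _, t in over.iterrows():
                    oa, ob = max(a, t["start"]), min(b, t["end"])
                    if orient > 0:
                        tad_rows.append((c, d0 + (oa - a), d0 + (ob - a)))
                    else:
                        tad_rows.append((c, d0 + (b - ob), d0 + (b - oa)))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end",
                                             "strand", "ancestral_gene_id"])
    genes = genes.sort_values(["chrom", "start"]).reset_index(drop=True)
    genes["gene_id"] = [f"{species_id}_g{k:06d}" for k in range(len(genes))]
    segs = pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "anc_chrom",
                                           "anc_start", "anc_end", "orientation"])
    bps = pd.DataFrame(bp_rows, columns=["chrom", "position"])
    tads = (pd.DataFrame(tad_rows, columns=["chrom", "start", "end"])
            .sort_values(["chrom", "start"]).reset_index(drop=True))
    truth = SimTruth(species_id, bps,
                     input_truth.comp_bin_size if input_truth else 0,
                     comp_truth, tads,
                     dict(input_truth.expression_effect) if input_truth else {})
    derived = SimGenome(species_id, chromosomes, genes, segs, architecture=truth)
    return derived, truth


# ----------------------------------------------------------------------
# Contact simulation
# ----------------------------------------------------------------------

def simulate_bin_covariates(bins: pd.DataFrame, seed=0) -> pd.DataFrame:
    """Per-bin effective length, GC and mappability covariates (positive)."""
    rng = np.random.default_rng(seed)
    n = len(bins)
    return pd.DataFrame({
        "eff_len": rng.lognormal(0.0, 0.2, n),
        "gc": np.clip(rng.normal(0.4, 0.05, n), 0.2, 0.7),
        "mappability": np.clip(rng.beta(8, 2, n), 0.2, 1.0),
    })


def simulate_contacts(genome: SimGenome, truth: SimTruth, bin_size,
                      params: ContactModelParams | None = None, seed=0,
                      covariates=None) -> ContactMatrix:
    """Draw a Poisson contact matrix from the planted architecture.

    Expected cis count for bins i, j of one chromosome:
    ``depth * d^(-alpha) * P_ij * T_ij * b_i * b_j`` with d the distance in
    bins (diagonal treated as distance 1), P the plaid factor
    (``plaid_contrast`` when both bins share a compartment label), T the
    TAD factor (``tad_enrichment`` when both bins lie in one true TAD) and
    b lognormal bin biases.  In ``ancestral_preserving`` mode, pairs whose
    bins derive from different ancestral chromosomes (within one derived
    chromosome) are additionally multiplied by ``dampening``.  Trans
    contacts (if ``trans_scale > 0``) are uniform at
    ``depth * trans_scale * b_i * b_j``.
    """
    params = params or ContactModelParams()
    if params.alpha <= 0:
        raise ValueError("alpha must be positive")
    rng = np.random.default_rng(seed)
    bins = genome.bin_table(bin_size)
    n = len(bins)
    bias = rng.lognormal(0.0, params.bias_sd, n)
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        for col, beta in (("eff_len", 1.0), ("gc", 0.7), ("mappability", 1.0)):
            x = cov[col].to_numpy()
            bias *= (x / np.exp(np.log(x).mean())) ** beta
    M = np.zeros((n, n))
    offset = 0
    for chrom, length in genome.chromosomes:
        nb = int(np.ceil(length / bin_size))
        mids = np.arange(nb) * bin_size + bin_size // 2
        labels = truth.compartment_bins(chrom, bin_size, nb) \
            if chrom in truth.compartment_truth else np.full(nb, "A")
        tt = truth.tad_truth[truth.tad_truth["chrom"] == chrom]
        tad_id = np.full(nb, -1)
        for t_i, (_, t) in enumerate(tt.iterrows()):
            tad_id[(mids >= t["start"]) & (mids < t["end"])] = t_i
        anc = _origin_lookup_arr(genome.origin_segments, chrom, mids)
        ii, jj = np.triu_indices(nb)
        d = np.maximum(jj - ii, 1).astype(float)
        mu = params.depth * d ** (-params.alpha)
        ramp = np.minimum(d * bin_size / max(params.plaid_ramp_bp, bin_size),
                          1.0)
        plaid = 1.0 + (params.plaid_contrast - 1.0) * ramp
        mu *= np.where(labels[ii] == labels[jj], plaid, 1.0)
        mu *= np.where((tad_id[ii] >= 0) & (tad_id[ii] == tad_id[jj]),
                       params.tad_enrichment, 1.0)
        if params.mode == "ancestral_preserving":
            mu *= np.where(anc[ii] != anc[jj], params.dampening, 1.0)
        b = bias[offset:offset + nb]
        mu *= b[ii] * b[jj]
        counts = rng.poisson(mu)
        block = np.zeros((nb, nb))
        block[ii, jj] = counts
        block[jj, ii] = block[ii, jj]
        M[offset:offset + nb, offset:offset + nb] = block
        offset += nb
    if params.trans_scale > 0:
        offs = np.cumsum([0] + [int(np.ceil(l / bin_size))
                                for _, l in genome.chromosomes])
        for a in range(len(genome.chromosomes)):
            for b_ in range(a + 1, len(genome.chromosomes)):
                sa = slice(offs[a], offs[a + 1])
                sb = slice(offs[b_], offs[b_ + 1])
                mu = params.depth * params.trans_scale * np.outer(
                    bias[sa], bias[sb])
                block = rng.poisson(mu)
                M[sa, sb] = block
                M[sb, sa] = block.T
    cm = ContactMatrix(bins, M, bin_size, norm="raw", bin_covariates=covariates)
    return cm


def _origin_lookup_arr(origin_segments, chrom, positions):
    seg = origin_segments[origin_segments["chrom"] == chrom].sort_values("start")
    starts = seg["start"].to_numpy()
    anc = seg["anc_chrom"].to_numpy()
    idx = np.clip(np.searchsorted(starts, positions, side="right") - 1,
                  0, len(starts) - 1)
    return anc[idx]


# ----------------------------------------------------------------------
# Expression and tracks
# ----------------------------------------------------------------------

def simulate_expression(pairs, base_log10_mean=1.0, base_sd=0.6,
                        effect_map=None, replicates=3, seed=0,
                        gene_length=2_000, count_scale=1.0):
    """Simulate replicate count tables for two species' orthologs.

    ``pairs`` is an iterable of (gene_id1, gene_id2).  Each ortholog gets a
    shared baseline log10 expression ``N(base_log10_mean, base_sd)``; a
    divergence factor ``f = effect_map[gene_id1]`` (default 1) splits the
    two species by ``log10(f)`` with random sign, so the expected
    |e1 - e2| increases with f.  Counts are Poisson around
    ``10^e * gene_length/1000 * count_scale`` with mild lognormal
    replicate depth factors.  Returns two DataFrames with columns
    gene_id, length, rep1..repN.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    effect_map = effect_map or {}
    pairs = list(pairs)
    for g1, _ in pairs:
        if effect_map.get(g1, 1.0) < 0:
            raise ValueError("negative effect factors are not allowed")
    rng = np.random.default_rng(seed)
    n = len(pairs)
    base = rng.normal(base_log10_mean, base_sd, n)
    f = np.array([effect_map.get(g1, 1.0) for g1, _ in pairs])
    sign = rng.choice([-1.0, 1.0], n)
    with np.errstate(divide="ignore"):
        shift = np.where(f > 0, np.log10(np.maximum(f, 1e-300)) / 2, 0.0)
    e1 = base - sign * shift
    e2 = base + sign * shift
    depth1 = rng.lognormal(0.0, 0.05, replicates)
    depth2 = rng.lognormal(0.0, 0.05, replicates)
    tables = []
    for e, depth, col in ((e1, depth1, 0), (e2, depth2, 1)):
        lam = (10.0 ** e)[:, None] * (gene_length / 1000.0) \
            * count_scale * depth[None, :]
        counts = rng.poisson(lam)
        df = pd.DataFrame({"gene_id": [p[col] for p in pairs],
                           "length": gene_length})
        for r in range(replicates):
            df[f"rep{r + 1}"] = counts[:, r]
        tables.append(df)
    return tables[0], tables[1]


def plant_expression_effects(affected_ids, factor):
    """Effect map assigning ``factor`` to each affected species-1 gene id."""
    if factor < 0:
        raise ValueError("negative effect factors are not allowed")
    return {g: float(factor) for g in affected_ids}


@dataclass
class MarkSpec:
    """One epigenetic mark to simulate: Gaussian-bump contrasts at anchors."""
    name: str
    kind: str = "ratio"            # ratio | fraction | density
    background: float = 0.0
    anchors: list = field(default_factory=list)   # (chrom, pos)
    contrast: float = 0.0
    width: float = 5_000.0         # Gaussian sigma, bp
    noise_sd: float = 0.02


def simulate_tracks(genome: SimGenome, mark_specs, bin_size, seed=0):
    """Binned signal tracks with planted contrasts centered on anchors.

    Fraction-kind marks (methylation-style) are clipped to [0, 1] with a
    warning if the contrast pushes them outside.  Returns a dict of mark
    name -> :class:`synteny3d.tracks.SignalTrack`.
    """
    from .tracks import SignalTrack

    rng = np.random.default_rng(seed)
    bins = genome.bin_table(bin_size)
    mids = (bins["start"] + bins["end"]).to_numpy() / 2.0
    out = {}
    for spec in mark_specs:
        for chrom, pos in spec.anchors:
            if chrom not in dict(genome.chromosomes):
                raise ValueError(f"anchor on unknown chromosome {chrom}")
            if not (0 <= pos <= genome.chrom_length(chrom)):
                raise ValueError("anchor outside chromosome bounds")
        vals = np.full(len(bins), float(spec.background))
        for chrom, pos in spec.anchors:
            sel = (bins["chrom"] == chrom).to_numpy()
            vals[sel] += spec.contrast * np.exp(
                -0.5 * ((mids[sel] - pos) / spec.width) ** 2)
        vals += rng.normal(0.0, spec.noise_sd, len(bins))
        if spec.kind == "fraction":
            if (vals < 0).any() or (vals > 1).any():
                warnings.warn(f"mark {spec.name}: values clipped to [0, 1]")
            vals = np.clip(vals, 0.0, 1.0)
        df = bins.copy()
        df["value"] = vals
        out[spec.name] = SignalTrack(df, name=spec.name, kind=spec.kind)
    return out


def snap_events_to_boundaries(genome: SimGenome, events, max_shift=8):
    """Shift event cut points to the nearest ancestral inter-TAD gap.

    Rearrangement breakpoints in real genomes arise preferentially in
    open chromatin at domain boundaries; snapping each gene-index cut of
    an event (by at most ``max_shift`` genes) to the closest gap between
    planted TADs reproduces that fragile-boundary bias in the forward
    model.  Fusions (whole-chromosome cuts) are left untouched.
    """
    truth = genome.architecture
    if truth is None:
        return list(events)
    gap_centers = {}
    for chrom, _ in genome.chromosomes:
        tt = truth.tad_truth[truth.tad_truth["chrom"] == chrom] \
            .sort_values("start")
        centers = [(a["end"] + b["start"]) / 2
                   for (_, a), (_, b) in zip(tt.iterrows(),
                                             tt.iloc[1:].iterrows())
                   if b["start"] >= a["end"]]
        gap_centers[chrom] = np.array(centers) if centers else np.array([0.0])
    genes_by_chrom = {c: genome.genes[genome.genes["chrom"] == c]
                      .sort_values("start").reset_index(drop=True)
                      for c, _ in genome.chromosomes}

    def snap(chrom, k):
        g = genes_by_chrom[chrom]
        L = genome.chrom_length(chrom)
        centers = gap_centers[chrom]
        best, bestd = k, np.inf
        for kk in range(max(1, k - max_shift),
                        min(len(g), k + max_shift) + 1):
            cut = _gene_cut_bp(g, L, kk)
            d = np.abs(centers - cut).min()
            if d < bestd:
                best, bestd = kk, d
        return best

    out = []
    for ev in events:
        ev = replace(ev)
        if ev.kind in {"inversion", "translocation"}:
            ev.start = snap(ev.chrom, ev.start)
            ev.end = snap(ev.chrom, ev.end)
        if ev.kind == "translocation" and ev.dest_index is not None:
            ev.dest_index = snap(ev.dest_chrom, ev.dest_index)
        if ev.kind == "fission":
            ev.start = snap(ev.chrom, ev.start)
        out.append(ev)
    return out


def plant_compartment_switches(truth: SimTruth, breakpoints: pd.DataFrame,
                               window=50_000, flip_prob=0.8, seed=0) -> SimTruth:
    """Flip B bins to A near breakpoints (planted B-to-A switch effect).

    Returns a new truth whose compartment labels within ``window`` bp of a
    planted breakpoint switch from B to A with probability ``flip_prob``.
    """
    rng = np.random.default_rng(seed)
    new_labels = {c: v.copy() for c, v in truth.compartment_truth.items()}
    for _, row in breakpoints.iterrows():
        chrom, pos = row["chrom"], row["position"]
        labels = new_labels.get(chrom)
        if labels is None:
            continue
        lo = max(0, int((pos - window) // truth.comp_bin_size))
        hi = min(len(labels) - 1, int((pos + window) // truth.comp_bin_size))
        for k in range(lo, hi + 1):
            if labels[k] == "B" and rng.random() < flip_prob:
                labels[k] = "A"
    return replace(truth, compartment_truth=new_labels)


# ----------------------------------------------------------------------
# Orthology helpers
# ----------------------------------------------------------------------

def ortholog_pairs(g1: SimGenome, g2: SimGenome) -> pd.DataFrame:
    """True ortholog pairs (shared ancestral gene id) with coordinates."""
    a = g1.genes.rename(columns={c: c + "1" for c in g1.genes.columns
                                 if c != "ancestral_gene_id"})
    b = g2.genes.rename(columns={c: c + "2" for c in g2.genes.columns
                                 if c != "ancestral_gene_id"})
    m = a.merge(b, on="ancestral_gene_id")
    m["pos1"] = (m["start1"] + m["end1"]) // 2
    m["pos2"] = (m["start2"] + m["end2"]) // 2
    return m[["ancestral_gene_id", "gene_id1", "chrom1", "pos1",
              "gene_id2", "chrom2", "pos2"]]


def simulate_homolog_hits(g1: SimGenome, g2: SimGenome, seed=0,
                          noise_rate=0.2) -> pd.DataFrame:
    """Raw homolog hit table: true orthologs plus random spurious hits.

    True pairs get high scores and tiny e-values; noise hits are random
    gene pairs with e-values spanning the filtering threshold.
    """
    rng = np.random.default_rng(seed)
    true = ortholog_pairs(g1, g2)
    rows = [(r.gene_id1, r.gene_id2,
             rng.uniform(400.0, 600.0), 10.0 ** -rng.uniform(30, 120))
            for r in true.itertuples()]
    n_noise = int(noise_rate * len(true))
    id1 = g1.genes["gene_id"].to_numpy()
    id2 = g2.genes["gene_id"].to_numpy()
    for _ in range(n_noise):
        rows.append((rng.choice(id1), rng.choice(id2),
                     rng.uniform(40.0, 120.0), 10.0 ** -rng.uniform(2, 20)))
    return pd.DataFrame(rows, columns=["gene1", "gene2", "score", "evalue"])
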