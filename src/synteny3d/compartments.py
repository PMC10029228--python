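"""A/B compartment calling and cross-species switch analysis.

Compartments are called per chromosome from the leading eigenvector of
the Pearson correlation matrix of observed/expected rows, with the sign
oriented so that the eigenvector correlates positively with gene density
(A = gene-dense, open chromatin).  Syntenic ortholog pairs are classified
into stable A / stable B / A-to-B / B-to-A states between two species,
and switch enrichment adjacent to synteny breaks is tested with Fisher's
exact test against the remaining syntenic genes as background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hicmat import ContactMatrix, observed_expected

__all__ = [
    "CompartmentProfile",
    "call_compartments",
    "compartment_fractions",
    "classify_switches",
    "break_adjacent_switch_enrichment",
    "SWITCH_STATES",
]

SWITCH_STATES = ("stableA", "stableB", "AtoB", "BtoA")

#: chromosomes with |orientation correlation| below this are flagged for
#: manual review rather than silently labeled
ORIENTATION_MIN_R = 0.3


@dataclass
class CompartmentProfile:
    """Per-bin PC1 loadings and A/B labels.

    ``bins`` has columns chrom, start, end, pc1, label ('A'/'B'/'NA');
    ``orientation_r`` maps chromosome to the correlation between PC1 and
    gene density used to orient the sign; ``flagged`` lists chromosomes
    whose orientation evidence was weak.
    """
    bins: pd.DataFrame
    resolution: int
    orientation_r: dict = field(default_factory=dict)
    flagged: list = field(default_factory=list)

    def label_at(self, chrom, pos):
        grp = self.bins[self.bins["chrom"] == chrom]
        if grp.empty:
            return "NA"
        starts = grp["start"].to_numpy()
        k = np.searchsorted(starts, pos, side="right") - 1
        if k < 0 or pos >= grp["end"].iloc[k]:
            return "NA"
        return grp["label"].iloc[k]

    def labels_for(self, chroms, positions):
        """Vectorized label lookup for (chrom, position) arrays."""
        out = np.full(len(positions), "NA", dtype=object)
        df = self.bins
        for chrom in pd.unique(np.asarray(chroms)):
            sel = np.asarray(chroms) == chrom
            grp = df[df["chrom"] == chrom]
            if grp.empty:
                continue
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            labs = grp["label"].to_numpy()
            pos = np.asarray(positions)[sel]
            k = np.clip(np.searchsorted(starts, pos, side="right") - 1,
                        0, len(starts) - 1)
            ok = (pos >= starts[k]) & (pos < ends[k])
            vals = np.where(ok, labs[k], "NA")
            out[sel] = vals
        return out


def call_compartments(matrix: ContactMatrix, gene_density,
                      min_bins=10) -> CompartmentProfile:
    """Call A/B compartments from a balanced matrix (default 50 kb).

    Per chromosome: the observed/expected matrix is correlated row-wise
    (Pearson), the leading eigenvector of the correlation matrix is
    extracted, its sign is oriented so that correlation with gene density
    is >= 0, and bins are labeled A (positive) or B (negative).  Masked
    bins and degenerate chromosomes are labeled NA.
    """
    gene_density = np.asarray(gene_density, dtype=float)
    if len(gene_density) != matrix.n_bins:
        raise ValueError("gene density must align with the bin table")
    oe = observed_expected(matrix)
    bins = matrix.bins.copy()
    pc1 = np.full(matrix.n_bins, np.nan)
    labels = np.full(matrix.n_bins, "NA", dtype=object)
    orientation_r, flagged = {}, []
    for chrom in matrix.chrom_names:
        sl = matrix.chrom_slice(chrom)
        E = oe.matrix[sl, sl]
        valid = np.flatnonzero(np.isfinite(E).sum(axis=1) >= 2)
        if valid.size < min_bins:
            warnings.warn(f"{chrom}: fewer than {min_bins} usable bins; "
                          "labels set to NA")
            continue
        sub = E[np.ix_(valid, valid)]
        sub = np.where(np.isfinite(sub), sub, 1.0)  # neutral O/E fill
        sd = sub.std(axis=1)
        if np.any(sd == 0):
            keep = sd > 0
            valid = valid[keep]
            sub = sub[np.ix_(keep, keep)]
            if valid.size < min_bins:
                warnings.warn(f"{chrom}: degenerate correlation matrix; NA")
                continue
        corr = np.corrcoef(sub)
        if not np.all(np.isfinite(corr)):
            warnings.warn(f"{chrom}: degenerate correlation matrix; NA")
            continue
        w, v = np.linalg.eigh(corr)
        vec = v[:, -1]
        dens = gene_density[sl][valid]
        if dens.std() > 0 and vec.std() > 0:
            r = float(np.corrcoef(vec, dens)[0, 1])
        else:
            r = 0.0
        if r < 0:
            vec = -vec
            r = -r
        orientation_r[chrom] = r
        if r < ORIENTATION_MIN_R:
            flagged.append(chrom)
            warnings.warn(f"{chrom}: weak orientation evidence (r={r:.2f}); "
                          "flagged for review")
        idx = np.arange(sl.start, sl.stop)[valid]
        pc1[idx] = vec
        labels[idx] = np.where(vec > 0, "A", "B")
    bins["pc1"] = pc1
    bins["label"] = labels
    return CompartmentProfile(bins, matrix.resolution, orientation_r, flagged)


def compartment_fractions(profile: CompartmentProfile):
    """(%A, %B) of the labeled genome by length; sums to 100."""
    df = profile.bins
    lengths = (df["end"] - df["start"]).to_numpy(dtype=float)
    a = lengths[df["label"] == "A"].sum()
    b = lengths[df["label"] == "B"].sum()
    tot = a + b
    if tot == 0:
        return (np.nan, np.nan)
    return (100.0 * a / tot, 100.0 * b / tot)


def classify_switches(profile1: CompartmentProfile,
                      profile2: CompartmentProfile,
                      pairs: pd.DataFrame):
    """Classify syntenic ortholog pairs into the four compartment states.

    ``pairs`` needs columns chrom1, pos1, chrom2, pos2 (gene midpoints in
    each species).  Genes falling in NA bins in either species are
    dropped and counted.  Returns (calls DataFrame with a ``state``
    column, state-count dict including ``dropped``).
    """
    l1 = profile1.labels_for(pairs["chrom1"].to_numpy(), pairs["pos1"].to_numpy())
    l2 = profile2.labels_for(pairs["chrom2"].to_numpy(), pairs["pos2"].to_numpy())
    calls = pairs.copy()
    state = np.full(len(pairs), "dropped", dtype=object)
    ok = (l1 != "NA") & (l2 != "NA")
    combo = np.char.add(l1.astype(str), l2.astype(str))
    mapping = {"AA": "stableA", "BB": "stableB", "AB": "AtoB", "BA": "BtoA"}
    for key, name in mapping.items():
        state[ok & (combo == key)] = name
    calls["state"] = state
    counts = {s: int((state == s).sum()) for s in SWITCH_STATES}
    counts["dropped"] = int((state == "dropped").sum())
    return calls[state != "dropped"].reset_index(drop=True), counts


def break_adjacent_switch_enrichment(switches: pd.DataFrame,
                                     breaks: pd.DataFrame,
                                     window=10_000) -> pd.DataFrame:
    """Per-state Fisher tests: break-adjacent versus background genes.

    A syntenic gene is break-adjacent when its species-1 midpoint lies
    within ``window`` bp of a break interval; all other syntenic genes
    form the background.  For each state a 2x2 table
    {adjacent, background} x {state, other} is tested with a two-tailed
    Fisher exact test; Benjamini-Hochberg q-values are added across the
    four states (raw p-values are also reported, as single tests).
    """
    if breaks.empty:
        raise ValueError("empty break set")
    adj = np.zeros(len(switches), dtype=bool)
    for chrom in breaks["chrom"].unique():
        b = breaks[breaks["chrom"] == chrom]
        lo = b["start"].to_numpy() - window
        hi = b["end"].to_numpy() + window
        sel = (switches["chrom1"] == chrom).to_numpy()
        pos = switches["pos1"].to_numpy()[sel]
        hit = np.zeros(pos.size, dtype=bool)
        for a, z in zip(lo, hi):
            hit |= (pos >= a) & (pos < z)
        adj[sel] = hit
    if not adj.any():
        raise ValueError("no syntenic genes adjacent to breaks")
    state = switches["state"].to_numpy()
    rows = []
    for s in SWITCH_STATES:
        n11 = int(((state == s) & adj).sum())
        n12 = int(((state != s) & adj).sum())
        n21 = int(((state == s) & ~adj).sum())
        n22 = int(((state != s) & ~adj).sum())
        odds, p = stats.fisher_exact([[n11, n12], [n21, n22]],
                                     alternative="two-sided")
        rows.append((s, n11, n12, n21, n22, odds, p))
    out = pd.DataFrame(rows, columns=["state", "adj_state", "adj_other",
                                      "bg_state", "bg_other",
                                      "odds_ratio", "pvalue"])
    from statsmodels.stats.multitest import multipletests
    out["qvalue"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out
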