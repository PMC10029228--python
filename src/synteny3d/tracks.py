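"""Signal-track utilities and expression statistics.

Histone scores (log2 ChIP/input), weighted methylation binning with a
>= 5-read coverage filter, meta-profiles of binned signal around anchor
sets, RPKM-based expression tables, the absolute ortholog expression
divergence |e1 - e2| on log10 RPKM, and rank-sum group comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SignalTrack",
    "histone_score",
    "methylation_binned",
    "meta_profile",
    "rpkm_table",
    "expression_divergence",
    "group_compare",
]

RPKM_PSEUDOCOUNT = 0.01
METH_MIN_COVERAGE = 5


class SignalTrack:
    """Binned signal: DataFrame (chrom, start, end, value) plus a kind.

    ``kind``: ``ratio`` (log-ratio style, unbounded), ``fraction``
    (values in [0, 1], methylation style) or ``density`` (>= 0).
    """

    def __init__(self, df, name="", kind="ratio"):
        df = pd.DataFrame(df).reset_index(drop=True)
        if not {"chrom", "start", "end", "value"}.issubset(df.columns):
            raise ValueError("track needs chrom/start/end/value columns")
        if kind == "fraction":
            v = df["value"].dropna()
            if ((v < 0) | (v > 1)).any():
                raise ValueError("fraction-kind values must lie in [0, 1]")
        self.df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
        self.name = name
        self.kind = kind

    def __len__(self):
        return len(self.df)

    def values_on(self, chrom):
        return self.df[self.df["chrom"] == chrom]

    def mean_over(self, chrom, start, end):
        g = self.df[(self.df["chrom"] == chrom)
                    & (self.df["end"] > start) & (self.df["start"] < end)]
        v = g["value"].dropna()
        return float(v.mean()) if len(v) else np.nan

    def write_bedgraph(self, path):
        self.df.to_csv(path, sep="\t", header=False, index=False,
                       columns=["chrom", "start", "end", "value"])

    @classmethod
    def read_bedgraph(cls, path, name="", kind="ratio"):
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "value"])
        return cls(df, name=name, kind=kind)


def histone_score(chip: SignalTrack, control: SignalTrack, pseudocount=1.0,
                  library_sizes=None) -> SignalTrack:
    """log2((chip + c) / (input + c)) per bin, optionally depth-scaled.

    When ``library_sizes=(chip_total, input_total)`` is given, counts are
    first converted to counts-per-million before the ratio.
    """
    a, b = chip.df, control.df
    if len(a) != len(b) or not (a[["chrom", "start", "end"]]
                                .equals(b[["chrom", "start", "end"]])):
        raise ValueError("chip and input tracks must share identical binning")
    x = a["value"].to_numpy(dtype=float)
    y = b["value"].to_numpy(dtype=float)
    if library_sizes is not None:
        x = x * 1e6 / library_sizes[0]
        y = y * 1e6 / library_sizes[1]
    out = a.copy()
    out["value"] = np.log2((x + pseudocount) / (y + pseudocount))
    return SignalTrack(out, name=f"{chip.name}_score", kind="ratio")


def methylation_binned(sites: pd.DataFrame, context, bin_size, chrom_sizes,
                       min_coverage=METH_MIN_COVERAGE) -> SignalTrack:
    """Weighted methylation per bin for one context (CG/CHG/CHH).

    ``sites`` columns: chrom, pos, context, meth, total.  Cytosines with
    fewer than ``min_coverage`` mapped reads are excluded; the bin value
    is sum(meth)/sum(total) over passing sites, NaN for empty bins.
    """
    s = sites[(sites["context"] == context)
              & (sites["total"] >= min_coverage)]
    rows = []
    for chrom, size in chrom_sizes.items():
        nb = int(np.ceil(size / bin_size))
        meth = np.zeros(nb)
        tot = np.zeros(nb)
        g = s[s["chrom"] == chrom]
        if len(g):
            idx = np.minimum(g["pos"].to_numpy() // bin_size, nb - 1)
            np.add.at(meth, idx, g["meth"].to_numpy())
            np.add.at(tot, idx, g["total"].to_numpy())
        with np.errstate(invalid="ignore", divide="ignore"):
            val = np.where(tot > 0, meth / np.maximum(tot, 1), np.nan)
        for k in range(nb):
            rows.append((chrom, k * bin_size, min((k + 1) * bin_size, size),
                         val[k]))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return SignalTrack(df, name=f"m{context}", kind="fraction")


def meta_profile(track: SignalTrack, anchors: pd.DataFrame, flank=20_000):
    """Aggregate signal in track-sized windows around anchors (+/- flank).

    ``anchors`` columns: chrom, pos, optional strand ('-' anchors are
    flipped).  Anchors whose window would leave the chromosome are
    trimmed and counted.  Returns a DataFrame (rel_pos, mean, se, n) and
    the number of trimmed anchors.
    """
    bs = int((track.df["end"] - track.df["start"]).mode().iloc[0])
    if flank % bs:
        raise ValueError("flank must be a multiple of the track bin size")
    w = flank // bs
    profiles = []
    trimmed = 0
    for chrom in anchors["chrom"].unique():
        g = track.values_on(chrom)
        if g.empty:
            trimmed += int((anchors["chrom"] == chrom).sum())
            continue
        vals = g["value"].to_numpy()
        starts = g["start"].to_numpy()
        n = vals.size
        for _, a in anchors[anchors["chrom"] == chrom].iterrows():
            k = int(np.searchsorted(starts, a["pos"], side="right") - 1)
            if k - w < 0 or k + w >= n:
                trimmed += 1
                continue
            row = vals[k - w:k + w + 1]
            if a.get("strand", "+") == "-":
                row = row[::-1]
            profiles.append(row)
    if not profiles:
        raise ValueError("no usable anchors")
    P = np.vstack(profiles)
    mean = np.nanmean(P, axis=0)
    counts = np.isfinite(P).sum(axis=0)
    se = np.nanstd(P, axis=0) / np.sqrt(np.maximum(counts, 1))
    rel = (np.arange(-w, w + 1)) * bs
    return pd.DataFrame({"rel_pos": rel, "mean": mean, "se": se,
                         "n": counts}), trimmed


# ----------------------------------------------------------------------
# Expression
# ----------------------------------------------------------------------

def rpkm_table(counts: pd.DataFrame, pseudocount=RPKM_PSEUDOCOUNT):
    """Add per-replicate RPKM and mean log10 RPKM (e) to a count table.

    ``counts`` columns: gene_id, length, rep1..repN.  RPKM =
    count * 1e9 / (length * library_size) with the library size taken as
    the replicate's total counts; e = log10(mean RPKM + pseudocount).
    """
    reps = [c for c in counts.columns if c.startswith("rep")]
    out = counts.copy()
    rp = []
    for r in reps:
        lib = counts[r].sum()
        rp.append(counts[r].to_numpy() * 1e9
                  / (counts["length"].to_numpy() * max(lib, 1)))
        out[f"rpkm_{r}"] = rp[-1]
    out["e"] = np.log10(np.mean(rp, axis=0) + pseudocount)
    return out


def expression_divergence(table1: pd.DataFrame, table2: pd.DataFrame,
                          pairs, pseudocount=RPKM_PSEUDOCOUNT):
    """Per-ortholog |e1 - e2| on mean log10 RPKM.

    ``pairs`` is an iterable of (gene_id1, gene_id2); pairs missing from
    either table are dropped (count returned).  Returns (DataFrame with
    e1, e2, divergence, n_dropped).
    """
    t1 = rpkm_table(table1, pseudocount).set_index("gene_id")["e"]
    t2 = rpkm_table(table2, pseudocount).set_index("gene_id")["e"]
    rows, dropped = [], 0
    for g1, g2 in pairs:
        if g1 in t1.index and g2 in t2.index:
            e1, e2 = float(t1[g1]), float(t2[g2])
            rows.append((g1, g2, e1, e2, abs(e1 - e2)))
        else:
            dropped += 1
    df = pd.DataFrame(rows, columns=["gene_id1", "gene_id2", "e1", "e2",
                                     "divergence"])
    return df, dropped


def group_compare(x, y, alternative="two-sided"):
    """Wilcoxon rank-sum comparison of two value groups.

    Exact null distribution for combined n <= 20 without ties, normal
    approximation with tie correction otherwise.  Constant pooled values
    give p = 1.  Returns (statistic, pvalue).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)
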