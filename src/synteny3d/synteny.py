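"""Collinear synteny blocks and synteny-break derivation.

Homolog hits are filtered (e-value <= 1e-5, top-5 matches per gene in
both directions), collinear blocks are chained by dynamic programming
over ortholog anchors in gene-rank coordinates (both orientations, gaps
of more than ``max_gap`` non-syntenic genes forbidden on either side),
block significance is estimated by a seeded Monte-Carlo permutation of
anchor positions, and breaks are emitted where consecutive retained
blocks along a species-1 chromosome are discontiguous on the species-2
side.  The ends of retained blocks define break borders; a sweep over
minimal block gene numbers {5, 8, 10, 20, 30} reports the knee of the
break-count curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntenyBlock",
    "SyntenyBreak",
    "filter_homologs",
    "chain_collinear",
    "block_pvalue",
    "derive_breaks",
    "threshold_sweep",
]

EVALUE_MAX = 1e-5
TOP_MATCHES = 5


@dataclass
class SyntenyBlock:
    """A chain of collinear ortholog anchors between two chromosomes."""
    block_id: int
    chrom1: str
    chrom2: str
    orientation: str                 # '+' or '-'
    anchors: pd.DataFrame            # rank1, rank2, gene1, gene2
    pvalue: float = np.nan
    meta: dict = field(default_factory=dict)

    @property
    def n_genes(self):
        return len(self.anchors)

    @property
    def rank1_range(self):
        r = self.anchors["rank1"]
        return int(r.min()), int(r.max())

    @property
    def rank2_range(self):
        r = self.anchors["rank2"]
        return int(r.min()), int(r.max())


@dataclass
class SyntenyBreak:
    """A junction between adjacent retained blocks evidencing rearrangement."""
    chrom1: str
    start1: int
    end1: int
    chrom2_left: str
    chrom2_right: str
    category: str                    # inversion | translocation | fusion/fission | unclassified
    left_block: int
    right_block: int


def filter_homologs(hits: pd.DataFrame) -> pd.DataFrame:
    """Apply the e-value and top-5 retention rule in both directions.

    Input columns: gene1, gene2, score, evalue (rows lacking an e-value
    are dropped).  A hit is retained when evalue <= 1e-5 and gene2 is
    among the top 5 matches of gene1 AND gene1 among the top 5 matches of
    gene2 (rank by score, descending).  Returns the table with a
    ``retained`` boolean column.
    """
    hits = hits.copy()
    missing = hits["evalue"].isna()
    if missing.any():
        hits = hits[~missing].reset_index(drop=True)
    if hits.empty:
        hits["retained"] = pd.Series(dtype=bool)
        return hits
    r1 = hits.groupby("gene1")["score"].rank(ascending=False, method="first")
    r2 = hits.groupby("gene2")["score"].rank(ascending=False, method="first")
    hits["retained"] = ((hits["evalue"] <= EVALUE_MAX)
                        & (r1 <= TOP_MATCHES) & (r2 <= TOP_MATCHES))
    return hits


def _gene_ranks(genes: pd.DataFrame):
    """gene_id -> (chrom, rank within chromosome by position)."""
    out = {}
    n_per_chrom = {}
    for chrom, grp in genes.sort_values(["chrom", "start"]).groupby("chrom",
                                                                    sort=False):
        for rank, gid in enumerate(grp["gene_id"]):
            out[gid] = (chrom, rank)
        n_per_chrom[chrom] = len(grp)
    return out, n_per_chrom


def _best_chain(r1, r2, sign, max_gap):
    """Longest chain monotone increasing in r1 and sign-monotone in r2,
    consecutive anchors separated by <= max_gap intervening genes on both
    sides.  Returns indices of chain members (anchor order by r1)."""
    n = r1.size
    if n == 0:
        return np.array([], dtype=int)
    order = np.lexsort((sign * r2, r1))
    a1 = r1[order]
    a2 = sign * r2[order]
    best = np.ones(n, dtype=int)
    prev = np.full(n, -1)
    for i in range(n):
        d1 = a1[i] - a1[:i]
        d2 = a2[i] - a2[:i]
        ok = (d1 > 0) & (d2 > 0) & (d1 <= max_gap + 1) & (d2 <= max_gap + 1)
        if ok.any():
            cand = np.flatnonzero(ok)
            j = cand[np.argmax(best[cand])]
            if best[j] + 1 > best[i]:
                best[i] = best[j] + 1
                prev[i] = j
    end = int(np.argmax(best))
    chain = []
    while end >= 0:
        chain.append(end)
        end = prev[end]
    return order[np.array(chain[::-1])]


def chain_collinear(genes1: pd.DataFrame, genes2: pd.DataFrame,
                    homologs: pd.DataFrame, max_gap=30, min_genes=10,
                    collapse_tandem=True, compute_pvalues=True,
                    pvalue_cutoff=0.05, n_perm=1000, seed=0):
    """Chain retained homolog anchors into maximal collinear blocks.

    Blocks are extracted greedily per chromosome pair and orientation:
    the best-scoring monotone chain (dynamic programming, gap beyond
    ``max_gap`` intervening genes forbidden on both sides) is removed and
    the search repeats until no chain of ``min_genes`` anchors remains.
    Each anchor joins at most one block.  Consecutive tandem duplicates
    hitting one target collapse to a single anchor beforehand.  When
    ``compute_pvalues`` is set, blocks with a Monte-Carlo collinearity
    p-value >= ``pvalue_cutoff`` are discarded.
    """
    hits = homologs[homologs["retained"]] if "retained" in homologs else homologs
    ranks1, n1_chrom = _gene_ranks(genes1)
    ranks2, n2_chrom = _gene_ranks(genes2)
    anchors = []
    for g1, g2 in hits[["gene1", "gene2"]].itertuples(index=False):
        if g1 in ranks1 and g2 in ranks2:
            c1, r1 = ranks1[g1]
            c2, r2 = ranks2[g2]
            anchors.append((c1, c2, r1, r2, g1, g2))
    df = pd.DataFrame(anchors, columns=["chrom1", "chrom2", "rank1", "rank2",
                                        "gene1", "gene2"])
    if collapse_tandem and not df.empty:
        df = df.sort_values(["chrom1", "chrom2", "rank1", "rank2"])
        same_prev = ((df["chrom1"] == df["chrom1"].shift())
                     & (df["chrom2"] == df["chrom2"].shift())
                     & ((df["gene2"] == df["gene2"].shift())
                        & (df["rank1"] - df["rank1"].shift() == 1)
                        | (df["gene1"] == df["gene1"].shift())
                        & (df["rank2"] - df["rank2"].shift() == 1)))
        df = df[~same_prev.fillna(False)]
    rng = np.random.default_rng(seed)
    blocks = []
    bid = 0
    for (c1, c2), grp in df.groupby(["chrom1", "chrom2"], sort=False):
        rem = grp.reset_index(drop=True)
        while len(rem) >= min_genes:
            best_chain, best_sign = None, None
            for sign in (+1, -1):
                chain = _best_chain(rem["rank1"].to_numpy(),
                                    rem["rank2"].to_numpy(), sign, max_gap)
                if best_chain is None or chain.size > best_chain.size:
                    best_chain, best_sign = chain, sign
            if best_chain is None or best_chain.size < min_genes:
                break
            sub = rem.iloc[best_chain].sort_values("rank1").reset_index(drop=True)
            blk = SyntenyBlock(bid, c1, c2, "+" if best_sign > 0 else "-",
                               sub[["rank1", "rank2", "gene1", "gene2"]])
            bid += 1
            if compute_pvalues:
                blk.pvalue = block_pvalue(
                    blk, n1_chrom[c1], n2_chrom[c2], len(grp),
                    n_perm=n_perm, seed=int(rng.integers(2 ** 31)))
                if blk.pvalue >= pvalue_cutoff:
                    rem = rem.drop(rem.index[best_chain]).reset_index(drop=True)
                    continue
            blocks.append(blk)
            rem = rem.drop(rem.index[best_chain]).reset_index(drop=True)
    # resolve genes claimed by multiple blocks (longest block wins)
    blocks.sort(key=lambda b: -b.n_genes)
    used1, used2 = set(), set()
    final = []
    for b in blocks:
        keep = [(g1 not in used1) and (g2 not in used2)
                for g1, g2 in b.anchors[["gene1", "gene2"]].itertuples(index=False)]
        b.anchors = b.anchors[keep].reset_index(drop=True)
        if b.n_genes >= min_genes:
            used1.update(b.anchors["gene1"])
            used2.update(b.anchors["gene2"])
            final.append(b)
    final = _rebuild_blocks_from_runs(final, min_genes, max_gap)
    final.sort(key=lambda b: (b.chrom1, b.rank1_range[0]))
    for k, b in enumerate(final):
        b.block_id = k
    return final


def _rebuild_blocks_from_runs(blocks, min_genes, max_gap, min_run=3):
    """Split blocks that bridge across a nested block into separate runs.

    A chain may legally jump across a nested rearranged segment (the gap
    rule allows it), leaving two blocks whose species-1 rank ranges
    overlap.  Anchors are re-decomposed into maximal single-block runs
    along species 1; runs shorter than ``min_run`` are dissolved and
    their anchors re-attached to a neighbouring run when collinearity
    and the gap allowance permit, otherwise dropped.  Each surviving run
    becomes its own block (inheriting orientation/chromosomes/p-value).
    """
    per_chrom = {}
    for b in blocks:
        for r1, r2, g1, g2 in b.anchors.itertuples(index=False):
            per_chrom.setdefault(b.chrom1, []).append((r1, r2, g1, g2, b))
    out = []
    for chrom1, anchors in per_chrom.items():
        anchors.sort(key=lambda t: t[0])
        runs = []
        for a in anchors:
            if runs and runs[-1][0] is a[4]:
                runs[-1][1].append(a)
            else:
                runs.append([a[4], [a]])
        orphans = [a for blk, ans in runs if len(ans) < min_run for a in ans]
        runs = [r for r in runs if len(r[1]) >= min_run]
        for a in orphans:
            r1, r2 = a[0], a[1]
            placed = False
            for blk, ans in runs:
                if blk.chrom2 != a[4].chrom2:
                    continue
                sign = 1 if blk.orientation == "+" else -1
                last = ans[-1]
                first = ans[0]
                if 0 < r1 - last[0] <= max_gap + 1 \
                        and 0 < sign * (r2 - last[1]) <= max_gap + 1:
                    ans.append(a)
                    placed = True
                elif 0 < first[0] - r1 <= max_gap + 1 \
                        and 0 < sign * (first[1] - r2) <= max_gap + 1:
                    ans.insert(0, a)
                    placed = True
                if placed:
                    break
        # merge adjacent same-block runs (contiguity restored after
        # orphan handling)
        runs.sort(key=lambda r: r[1][0][0])
        merged = []
        for blk, ans in runs:
            if merged and merged[-1][0] is blk:
                merged[-1][1].extend(ans)
            else:
                merged.append([blk, list(ans)])
        for blk, ans in merged:
            ans.sort(key=lambda t: t[0])
            sign = 1 if blk.orientation == "+" else -1
            ans = _drop_offdiagonal_anchors(ans, sign)
            # re-split where the gap allowance is violated (removal of a
            # bridging anchor exposes the underlying discontinuity)
            pieces = [[ans[0]]] if ans else []
            for prev, cur in zip(ans, ans[1:]):
                d1 = cur[0] - prev[0]
                d2 = sign * (cur[1] - prev[1])
                if d1 > max_gap + 1 or not (0 < d2 <= max_gap + 1):
                    pieces.append([cur])
                else:
                    pieces[-1].append(cur)
            for piece in pieces:
                if len(piece) < min_genes:
                    continue
                anchors_df = pd.DataFrame(
                    [(r1, r2, g1, g2) for r1, r2, g1, g2, _ in piece],
                    columns=["rank1", "rank2", "gene1", "gene2"])
                out.append(SyntenyBlock(0, blk.chrom1, blk.chrom2,
                                        blk.orientation, anchors_df,
                                        pvalue=blk.pvalue))
    return out


def _drop_offdiagonal_anchors(ans, sign, off_thresh=10):
    """Remove isolated anchors far off the block's local diagonal.

    A spurious homolog hit can bridge the gap left by an excised or
    inserted segment: it sits off the collinear diagonal, with both its
    incoming and outgoing steps skewed the same way (species-2 step much
    larger than species-1, or vice versa).  Genuine anchors flanking a
    plain unanchored stretch show symmetric steps and are kept.
    """
    if len(ans) < 3:
        return ans
    keep = [True] * len(ans)
    for k in range(1, len(ans) - 1):
        din1 = ans[k][0] - ans[k - 1][0]
        din2 = sign * (ans[k][1] - ans[k - 1][1])
        dout1 = ans[k + 1][0] - ans[k][0]
        dout2 = sign * (ans[k + 1][1] - ans[k][1])
        skew_in = din2 - din1
        skew_out = dout2 - dout1
        if (skew_in >= off_thresh and skew_out >= off_thresh) \
                or (skew_in <= -off_thresh and skew_out <= -off_thresh):
            keep[k] = False
    return [a for a, k in zip(ans, keep) if k]


def block_pvalue(block: SyntenyBlock, n_genes1, n_genes2, n_anchors_pair,
                 n_perm=1000, seed=0) -> float:
    """Monte-Carlo collinearity p-value for one block.

    Probability of observing >= k collinear anchors inside the block's
    rank windows when the chromosome pair's anchors are placed uniformly
    at random: anchors are permuted, those falling in the windows kept,
    and the longest increasing/decreasing subsequence compared to k.
    """
    k = block.n_genes
    if k < 2:
        return 1.0
    lo1, hi1 = block.rank1_range
    lo2, hi2 = block.rank2_range
    w1, w2 = hi1 - lo1 + 1, hi2 - lo2 + 1
    if w1 <= 0 or w2 <= 0 or n_genes1 <= 0 or n_genes2 <= 0:
        return 1.0
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        p1 = rng.integers(0, n_genes1, n_anchors_pair)
        p2 = rng.integers(0, n_genes2, n_anchors_pair)
        inw = (p1 >= lo1) & (p1 <= hi1) & (p2 >= lo2) & (p2 <= hi2)
        if inw.sum() < k:
            continue
        a1, a2 = p1[inw], p2[inw]
        order = np.lexsort((a2, a1))
        s = a2[order]
        if max(_lis_length(s), _lis_length(-s)) >= k:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def _lis_length(seq):
    """Longest strictly increasing subsequence length (patience sorting)."""
    tails = []
    for x in seq:
        import bisect
        i = bisect.bisect_left(tails, x)
        if i == len(tails):
            tails.append(x)
        else:
            tails[i] = x
    return len(tails)


def derive_breaks(blocks, genes1: pd.DataFrame, genes2: pd.DataFrame,
                  min_genes=10, max_gap=30, terminal_slack=5,
                  min_run=3):
    """Emit synteny breaks between adjacent retained block runs.

    Blocks with fewer than ``min_genes`` anchors (or failing the p-value
    filter upstream) are ignored.  Anchored genes along each species-1
    chromosome are decomposed into maximal runs of one block (a block may
    contribute several runs when another block is nested inside it, as
    for an inversion bridged by its flanks); runs shorter than
    ``min_run`` anchors are discarded and same-block neighbours merged.
    A break is emitted between adjacent runs whose species-2 sides are
    discontiguous: different chromosome (fusion/fission when both blocks
    reach within ``terminal_slack`` genes of their species-2 chromosome
    ends, translocation otherwise); same chromosome with flipped
    orientation (inversion); same chromosome out of order or with a
    species-2 anchor gap exceeding the species-1 gap by more than
    ``max_gap`` (unclassified; a plain unanchored stretch widens both
    gaps alike).  The break interval is the half-open bp gap between the
    flanking anchor genes on species 1 (1-bp point when empty).
    """
    _, n2_chrom = _gene_ranks(genes2)
    coords1 = {g: (s, e) for g, s, e in
               genes1[["gene_id", "start", "end"]].itertuples(index=False)}
    retained = {b.block_id: b for b in blocks
                if b.n_genes >= min_genes
                and (np.isnan(b.pvalue) or b.pvalue < 0.05)}
    # per chromosome: anchors of retained blocks ordered by rank1
    per_chrom = {}
    for b in retained.values():
        for r1, r2, g1, g2 in b.anchors.itertuples(index=False):
            per_chrom.setdefault(b.chrom1, []).append((r1, r2, g1, b.block_id))
    breaks = []
    for chrom1, anchors in per_chrom.items():
        anchors.sort()
        runs = []  # [block_id, list of (r1, r2, g1)]
        for r1, r2, g1, bid in anchors:
            if runs and runs[-1][0] == bid:
                runs[-1][1].append((r1, r2, g1))
            else:
                runs.append([bid, [(r1, r2, g1)]])
        runs = [r for r in runs if len(r[1]) >= min_run]
        merged = []
        for r in runs:
            if merged and merged[-1][0] == r[0]:
                merged[-1][1].extend(r[1])
            else:
                merged.append(r)
        for (lbid, lan), (rbid, ran) in zip(merged, merged[1:]):
            left, right = retained[lbid], retained[rbid]
            l_r1, l_r2, l_g1 = lan[-1]
            r_r1, r_r2, r_g1 = ran[0]
            category = None
            if left.chrom2 != right.chrom2:
                lterm = _is_terminal(left, n2_chrom[left.chrom2],
                                     terminal_slack)
                rterm = _is_terminal(right, n2_chrom[right.chrom2],
                                     terminal_slack)
                category = ("fusion/fission" if (lterm and rterm)
                            else "translocation")
            elif left.orientation != right.orientation:
                category = "inversion"
            else:
                gap1 = r_r1 - l_r1 - 1
                gap2 = (r_r2 - l_r2 - 1) if left.orientation == "+" \
                    else (l_r2 - r_r2 - 1)
                if gap2 < 0 or gap2 - gap1 > max_gap:
                    category = "unclassified"
            if category is None:
                continue
            s = coords1[l_g1][1]
            e = coords1[r_g1][0]
            if e <= s:
                e = s + 1
            breaks.append(SyntenyBreak(chrom1, int(s), int(e),
                                       left.chrom2, right.chrom2, category,
                                       left.block_id, right.block_id))
    return breaks


def _is_terminal(block, n2, slack):
    lo2, hi2 = block.rank2_range
    return lo2 <= slack or hi2 >= n2 - 1 - slack


def breaks_to_frame(breaks) -> pd.DataFrame:
    """Breaks as a BED-like DataFrame (chrom, start, end, category)."""
    return pd.DataFrame(
        [(b.chrom1, b.start1, b.end1, b.category, b.chrom2_left,
          b.chrom2_right) for b in breaks],
        columns=["chrom", "start", "end", "category",
                 "chrom2_left", "chrom2_right"])


def threshold_sweep(blocks, genes1, genes2, thresholds=(5, 8, 10, 20, 30),
                    max_gap=30):
    """Break counts per minimal-gene threshold, plus the curve's knee.

    The knee is located at the interior threshold maximizing the second
    difference of the count curve (reported, not applied).
    """
    counts = []
    for t in thresholds:
        counts.append(len(derive_breaks(blocks, genes1, genes2,
                                        min_genes=t, max_gap=max_gap)))
    counts = np.array(counts)
    knee = None
    if len(counts) >= 3:
        second = counts[:-2] - 2 * counts[1:-1] + counts[2:]
        knee = thresholds[1 + int(np.argmax(second))]
    return pd.DataFrame({"threshold": thresholds, "n_breaks": counts}), knee
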