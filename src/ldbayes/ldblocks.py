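"""Windowed LD-network clustering of SNPs into blocks.

Each chromosome is chunked into non-overlapping windows of at most ``w2``
consecutive SNPs.  Within a window SNPs are grouped bottom-up on the
pairwise r² matrix (average-linkage agglomeration on 1 − r²), and a group
is accepted as an LD block only when its minimum pairwise r² is at least
``r1`` and its median pairwise r² at least ``r2``.  SNPs satisfying
neither become singleton blocks.  The contract is compatible in spirit
with LD-network clustering (LDna's LDnClustering) but is not bit-identical
to that package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .genotypes import GenotypeMatrix


@dataclass
class LDBlockSet:
    """Partition of SNPs into LD blocks.

    ``blocks`` is an ordered list of (block_id, chrom, member SNP index
    array); ``snp_to_block`` maps every SNP index to its block id.  Block
    ids are consecutive integers in genome order, hence deterministic.
    """

    blocks: list
    snp_to_block: np.ndarray
    params: dict

    def __post_init__(self):
        covered = np.concatenate([m for _, _, m in self.blocks]) if self.blocks \
            else np.array([], dtype=int)
        if len(covered) != len(self.snp_to_block) or \
                len(np.unique(covered)) != len(covered):
            raise ValueError("blocks do not partition the SNP set")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def sizes(self) -> np.ndarray:
        return np.array([len(m) for _, _, m in self.blocks])

    def members(self, block_id: int) -> np.ndarray:
        return self.blocks[block_id][2]

    def block_interval(self, g: GenotypeMatrix, block_id: int):
        """(chrom, min pos, max pos) over member SNPs."""
        _, chrom, m = self.blocks[block_id]
        return chrom, int(g.pos[m].min()), int(g.pos[m].max())


def pairwise_r2(g: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation of two coded SNP columns (no missing)."""
    x = g.calls[:, i].astype(float)
    y = g.calls[:, j].astype(float)
    return _r2_pair(x, y)


def _r2_pair(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        warnings.warn("zero-variance SNP column in r^2; returning 0")
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def r2_matrix(calls: np.ndarray) -> np.ndarray:
    """All-pairs r² for a (lines × SNPs) call block; zero-variance columns
    correlate 0 with everything."""
    X = calls.astype(np.float64)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    ok = sd > 0
    Xn = np.zeros_like(X)
    Xn[:, ok] = X[:, ok] / sd[ok]
    R = (Xn.T @ Xn) / X.shape[0]
    out = R * R
    np.fill_diagonal(out, 1.0)
    return np.clip(out, 0.0, 1.0)


def _accept(r2: np.ndarray, members: np.ndarray, r1: float, r2_med: float) -> bool:
    if len(members) == 1:
        return True
    sub = r2[np.ix_(members, members)]
    iu = np.triu_indices(len(members), k=1)
    vals = sub[iu]
    return bool(vals.min() >= r1 and np.median(vals) >= r2_med)


def _cluster_window(r2: np.ndarray, r1: float, r2_med: float) -> list:
    """Top-down cut of an average-linkage tree: accept a node's leaf set as
    a block when both threshold conditions hold, otherwise descend."""
    n = r2.shape[0]
    if n == 1:
        return [np.array([0])]
    dist = squareform(1.0 - r2, checks=False)
    Z = linkage(dist, method="average")
    # leaves per internal node
    leaf_sets = {i: np.array([i]) for i in range(n)}
    for t, (a, b, _, _) in enumerate(Z):
        leaf_sets[n + t] = np.concatenate([leaf_sets[int(a)], leaf_sets[int(b)]])
    out = []

    def descend(node: int):
        members = np.sort(leaf_sets[node])
        if _accept(r2, members, r1, r2_med):
            out.append(members)
        else:
            a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
            descend(a)
            descend(b)

    descend(2 * n - 2)
    return out


def _window_bounds(n: int, w2: int, hot_breaks: np.ndarray | None) -> list:
    """Split [0, n) into chunks of at most w2 SNPs, roughly equal sized,
    optionally forcing boundaries at recombination-hotspot breakpoints."""
    segments = [(0, n)]
    if hot_breaks is not None and len(hot_breaks):
        segments = []
        start = 0
        for b in hot_breaks:
            if b > start:
                segments.append((start, b))
                start = b
        if start < n:
            segments.append((start, n))
    bounds = []
    for s, e in segments:
        k = int(np.ceil((e - s) / w2))
        cuts = np.linspace(s, e, k + 1).round().astype(int)
        bounds.extend((cuts[i], cuts[i + 1]) for i in range(k)
                      if cuts[i + 1] > cuts[i])
    return bounds


def cluster_ld_blocks(g: GenotypeMatrix, r1: float = 0.5, r2: float = 0.7,
                      w1: int = 10, w2: int = 100,
                      use_hotspots: bool = False) -> LDBlockSet:
    """Cluster SNPs into LD blocks per chromosome.

    Parameters
    ----------
    r1, r2 : float
        Minimum pairwise r² and minimum median r² within an accepted block.
    w1 : int
        Putative recombination-hotspot granularity: with ``use_hotspots``
        a window boundary is forced wherever ``w1`` consecutive adjacent
        SNP pairs all have r² below ``r1``.  Ignored otherwise.
    w2 : int
        Maximum window size in consecutive SNPs.
    """
    if w2 < 1:
        raise ValueError("w2 must be >= 1")
    if g.has_missing:
        raise ValueError("cluster_ld_blocks requires imputed genotypes")
    g = g.sort_snps()
    X = g.calls.astype(np.float64)
    blocks = []
    snp_to_block = np.full(g.n_snps, -1, dtype=int)
    next_id = 0
    for chrom in pd.unique(g.chrom):
        cidx = np.flatnonzero(g.chrom == chrom)
        hot = None
        if use_hotspots and len(cidx) > w1:
            adj = np.array([_r2_pair_silent(X[:, cidx[t]], X[:, cidx[t + 1]])
                            for t in range(len(cidx) - 1)])
            low = adj < r1
            hot = _hotspot_breaks(low, w1)
        for s, e in _window_bounds(len(cidx), w2, hot):
            widx = cidx[s:e]
            R2 = r2_matrix(X[:, widx])
            for members in _cluster_window(R2, r1, r2):
                snps = widx[members]
                blocks.append((next_id, str(chrom), snps))
                snp_to_block[snps] = next_id
                next_id += 1
    # stable genome order: by chromosome then first member position
    blocks.sort(key=lambda b: (b[1], int(g.pos[b[2]].min()), int(b[2][0])))
    blocks = [(i, c, m) for i, (_, c, m) in enumerate(blocks)]
    for i, _, m in blocks:
        snp_to_block[m] = i
    return LDBlockSet(blocks, snp_to_block,
                      {"r1": r1, "r2": r2, "w1": w1, "w2": w2})


def _r2_pair_silent(x, y):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _r2_pair(x, y)


def _hotspot_breaks(low_adjacent: np.ndarray, w1: int) -> np.ndarray:
    """Indices (into the chromosome's SNP run) where a window boundary is
    forced: the midpoint of every run of >= w1 consecutive low-LD pairs."""
    breaks = []
    run = 0
    for t, is_low in enumerate(low_adjacent):
        run = run + 1 if is_low else 0
        if run == w1:
            breaks.append(t - w1 // 2 + 1)
            run = 0
    return np.asarray(breaks, dtype=int)


def write_blocks(bs: LDBlockSet, g: GenotypeMatrix, path) -> None:
    """Persist block assignments as TSV (snp_id, chrom, block_id)."""
    rows = []
    for bid, chrom, members in bs.blocks:
        for s in members:
            rows.append((str(g.snp_ids[s]), chrom, bid))
    pd.DataFrame(rows, columns=["snp_id", "chrom", "block_id"]).to_csv(
        path, sep="\t", index=False)


def read_blocks(path, g: GenotypeMatrix) -> LDBlockSet:
    """Read a block-assignment TSV back against a genotype matrix."""
    df = pd.read_csv(path, sep="\t")
    lut = {str(s): i for i, s in enumerate(g.snp_ids)}
    snp_to_block = np.full(g.n_snps, -1, dtype=int)
    groups: dict = {}
    for sid, chrom, bid in zip(df["snp_id"], df["chrom"], df["block_id"]):
        j = lut[str(sid)]
        snp_to_block[j] = int(bid)
        groups.setdefault(int(bid), [str(chrom), []])[1].append(j)
    if (snp_to_block < 0).any():
        raise ValueError("block file does not cover every SNP")
    blocks = [(bid, groups[bid][0], np.array(sorted(groups[bid][1])))
              for bid in sorted(groups)]
    return LDBlockSet(blocks, snp_to_block, {})


def singleton_blocks(g: GenotypeMatrix) -> LDBlockSet:
    """Every SNP its own block (the no-LD-information limit)."""
    blocks = [(j, str(g.chrom[j]), np.array([j])) for j in range(g.n_snps)]
    return LDBlockSet(blocks, np.arange(g.n_snps), {})
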