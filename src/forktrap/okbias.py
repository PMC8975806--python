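"""Okazaki-fragment strand-bias (replication fork directionality) analysis.

Okazaki fragments are synthesized on the lagging strand, so the fraction of
sequenced fragments mapping to the Crick strand in a genomic bin equals the
fraction of replication forks moving left to right (%L2R) through that bin.
Efficient initiation near transcription start sites produces an upward step
in %L2R across the TSS; termination near transcription termination sites
relaxes it back.  This module bins stranded fragments at 1 kb, builds
%L2R meta-profiles around TSS/TTS anchors with genes stratified by
expression (FPKM) quartile or length, computes per-gene upstream/downstream
step statistics over fixed ranges (+1..+10 kb vs -50..-30 kb at the TSS;
+/-1-10 kb at the TTS), and compares conditions with the tie-corrected
Kruskal-Wallis H test plus rank effect sizes.

Coordinates are 0-based half-open internally; gene annotation TSVs are
declared 1-based and converted on read (see io module).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BIN_BP",
    "bin_fragments",
    "pct_l2r",
    "gene_offset_matrix",
    "meta_profile",
    "length_normalized_profile",
    "region_stat",
    "compare_groups",
    "GroupComparison",
]

BIN_BP = 1000

# step-statistic ranges, in kb relative to the anchor, inclusive
TSS_DOWN_KB = (1, 10)
TSS_UP_KB = (-50, -30)
TTS_DOWN_KB = (1, 10)
TTS_UP_KB = (-10, -1)


def bin_fragments(fragments: pd.DataFrame, genome_sizes: dict) -> pd.DataFrame:
    """Assign stranded fragments to 1 kb bins by midpoint.

    ``fragments`` needs columns chrom, start, end, strand ('+' Watson,
    '-' Crick).  Returns the full bin table (all bins of every chromosome,
    zero-filled) with watson_count / crick_count.
    """
    unknown = set(fragments["chrom"]) - set(genome_sizes)
    if unknown:
        raise ValueError(f"fragments on unknown chromosomes: {sorted(unknown)}")
    frames = []
    for chrom, size in genome_sizes.items():
        n_bins = int(np.ceil(size / BIN_BP))
        sub = fragments[fragments["chrom"] == chrom]
        mid = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(int)
        if np.any((mid < 0) | (mid >= size)):
            raise ValueError(f"fragment midpoints outside {chrom} bounds")
        idx = mid // BIN_BP
        is_crick = (sub["strand"] == "-").to_numpy()
        watson = np.bincount(idx[~is_crick], minlength=n_bins)
        crick = np.bincount(idx[is_crick], minlength=n_bins)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": np.arange(n_bins) * BIN_BP,
                    "watson_count": watson,
                    "crick_count": crick,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def pct_l2r(bins: pd.DataFrame) -> pd.Series:
    """Percent of forks moving left to right: 100 * crick / (crick + watson).

    Zero-coverage bins yield NaN (missing, excluded from downstream means).
    """
    total = bins["watson_count"] + bins["crick_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * bins["crick_count"] / total
    return pct.where(total > 0)


def _chrom_pct_arrays(bins: pd.DataFrame) -> dict:
    out = {}
    pct = pct_l2r(bins)
    for chrom, sub in bins.groupby("chrom", sort=False):
        arr = np.full(int(sub["start"].max()) // BIN_BP + 1, np.nan)
        arr[(sub["start"] // BIN_BP).to_numpy()] = pct[sub.index]
        out[chrom] = arr
    return out


def gene_offset_matrix(
    bins: pd.DataFrame, genes: pd.DataFrame, anchor: str = "TSS", window_kb: int = 25
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Per-gene %L2R vectors at 1 kb offsets around an anchor.

    Offsets run -window_kb..+window_kb in transcription direction; profiles
    of minus-strand genes are mirrored and complemented (100 - pct) so that
    transcription always reads left to right.  Returns (offsets_kb, matrix
    [genes x offsets, NaN where uncovered], genes actually used).
    """
    anchor = anchor.upper()
    if anchor not in ("TSS", "TTS"):
        raise ValueError("anchor must be TSS or TTS")
    arrays = _chrom_pct_arrays(bins)
    offsets = np.arange(-window_kb, window_kb + 1)
    mat = np.full((len(genes), len(offsets)), np.nan)
    used = np.zeros(len(genes), dtype=bool)
    for i, (_, g) in enumerate(genes.iterrows()):
        arr = arrays.get(g["chrom"])
        if arr is None:
            continue
        pos = int(g["tss"] if anchor == "TSS" else g["tts"])
        sign = 1 if g["strand"] == "+" else -1
        bin_idx = pos // BIN_BP + sign * offsets
        valid = (bin_idx >= 0) & (bin_idx < len(arr))
        vals = np.full(len(offsets), np.nan)
        vals[valid] = arr[bin_idx[valid]]
        if sign < 0:
            vals = 100.0 - vals
        if np.any(np.isfinite(vals)):
            mat[i] = vals
            used[i] = True
    return offsets, mat, genes[used].reset_index(drop=True)


@dataclass
class BiasProfile:
    offsets_kb: np.ndarray
    pct_l2r: np.ndarray
    group: str
    n_genes: int


def _grouping_labels(genes: pd.DataFrame, grouping: str) -> pd.Series:
    if grouping == "fpkm-quartile":
        return pd.Series(
            pd.qcut(genes["fpkm"].rank(method="first"), 4,
                    labels=["Q1", "Q2", "Q3", "Q4"]).astype(str),
            index=genes.index,
        )
    if grouping == "length-quartile":
        active = genes["fpkm"] > genes["fpkm"].median()
        labels = pd.Series("inactive", index=genes.index)
        labels[active] = pd.qcut(
            genes.loc[active, "length"].rank(method="first"), 4,
            labels=["L1", "L2", "L3", "L4"],
        ).astype(str)
        return labels
    if grouping == "length-class":
        labels = pd.Series("other", index=genes.index)
        labels[(genes["length"] >= 50_000) & (genes["length"] <= 100_000)] = "50-100kb"
        labels[genes["length"] > 100_000] = ">100kb"
        return labels
    if grouping == "all":
        return pd.Series("all", index=genes.index)
    raise ValueError(f"unknown grouping {grouping!r}")


def meta_profile(
    bins: pd.DataFrame,
    genes: pd.DataFrame,
    anchor: str = "TSS",
    window_kb: int = 25,
    grouping: str = "all",
) -> list[BiasProfile]:
    """Group-averaged %L2R meta-profiles around TSS or TTS.

    Each gene contributes its offset vector with equal weight; NaN offsets
    (no coverage) are excluded per offset.  Groupings: 'fpkm-quartile',
    'length-quartile' (among FPKM > median genes), 'length-class'
    (50-100 kb and >100 kb), or 'all'.
    """
    offsets, mat, used = gene_offset_matrix(bins, genes, anchor, window_kb)
    labels = _grouping_labels(used, grouping)
    profiles = []
    for grp in sorted(labels.unique()):
        if grp in ("inactive", "other"):
            continue
        sub = mat[(labels == grp).to_numpy()]
        with np.errstate(invalid="ignore"):
            avg = np.nanmean(sub, axis=0)
        profiles.append(
            BiasProfile(offsets_kb=offsets, pct_l2r=avg, group=grp, n_genes=len(sub))
        )
    return profiles


def length_normalized_profile(
    bins: pd.DataFrame, genes: pd.DataFrame, n_norm_bins: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """%L2R over the gene body rescaled to ``n_norm_bins`` positions.

    Each gene's TSS->TTS bin vector (transcription direction, minus-strand
    genes complemented) is linearly interpolated onto a common fractional
    grid; returns (fractional positions 0..1, per-position mean).
    """
    arrays = _chrom_pct_arrays(bins)
    grid = np.linspace(0.0, 1.0, n_norm_bins)
    rows = []
    for _, g in genes.iterrows():
        arr = arrays.get(g["chrom"])
        if arr is None:
            continue
        b0, b1 = int(g["tss"]) // BIN_BP, int(g["tts"]) // BIN_BP
        step = 1 if b1 >= b0 else -1
        idx = np.arange(b0, b1 + step, step)
        idx = idx[(idx >= 0) & (idx < len(arr))]
        vals = arr[idx]
        if g["strand"] == "-":
            vals = 100.0 - vals
        ok = np.isfinite(vals)
        if ok.sum() < 2:
            continue
        x = np.linspace(0.0, 1.0, len(vals))
        rows.append(np.interp(grid, x[ok], vals[ok]))
    if not rows:
        raise ValueError("no genes with usable coverage")
    return grid, np.mean(rows, axis=0)


def region_stat(
    bins: pd.DataFrame, genes: pd.DataFrame, anchor: str = "TSS"
) -> pd.DataFrame:
    """Per-gene downstream-minus-upstream %L2R difference at an anchor.

    TSS: mean over +1..+10 kb minus mean over -50..-30 kb.
    TTS: mean over +1..+10 kb minus mean over -10..-1 kb.
    Genes missing every offset of either range are excluded (reported via
    the returned frame's length vs the input).
    """
    anchor = anchor.upper()
    down_kb, up_kb = (TSS_DOWN_KB, TSS_UP_KB) if anchor == "TSS" else (TTS_DOWN_KB, TTS_UP_KB)
    window = max(abs(down_kb[1]), abs(up_kb[0]))
    offsets, mat, used = gene_offset_matrix(bins, genes, anchor, window_kb=window)
    down = (offsets >= down_kb[0]) & (offsets <= down_kb[1])
    up = (offsets >= up_kb[0]) & (offsets <= up_kb[1])
    rows = []
    for i in range(len(used)):
        with np.errstate(invalid="ignore"):
            d = np.nanmean(mat[i, down])
            u = np.nanmean(mat[i, up])
        if np.isfinite(d) and np.isfinite(u):
            rows.append((used["id"].iloc[i], d - u))
    return pd.DataFrame(rows, columns=["id", "stat"])


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def _partitions(indices: tuple, sizes: list):
    """All ways to split `indices` into ordered groups of the given sizes."""
    if len(sizes) == 1:
        yield (indices,)
        return
    for first in combinations(indices, sizes[0]):
        rest = tuple(i for i in indices if i not in first)
        for tail in _partitions(rest, sizes[1:]):
            yield (first,) + tail


def _kw_h(groups) -> float:
    """Tie-corrected Kruskal-Wallis H from first principles (oracle-friendly)."""
    all_vals = np.concatenate(groups)
    n = len(all_vals)
    ranks = stats.rankdata(all_vals)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(all_vals, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n) if n > 1 else 1.0
    return h / tie if tie > 0 else 0.0


@dataclass
class GroupComparison:
    h: float
    p_value: float
    epsilon_squared: float  # omnibus effect size H/(n-1)
    pairwise: pd.DataFrame  # group_a, group_b, rank_biserial
    n: int
    method: str

    def summary(self) -> str:
        lines = [
            "Kruskal-Wallis comparison",
            f"  H                : {self.h:10.4f}",
            f"  p ({self.method}) : {self.p_value:10.4g}",
            f"  epsilon^2        : {self.epsilon_squared:10.4f}",
            f"  n                : {self.n}",
        ]
        for _, row in self.pairwise.iterrows():
            lines.append(
                f"  rank-biserial {row['group_a']} vs {row['group_b']}: {row['rank_biserial']:+.4f}"
            )
        return "\n".join(lines)


def compare_groups(
    samples: dict, exact: bool = False, max_exact_n: int = 10
) -> GroupComparison:
    """Kruskal-Wallis H test across named groups of per-gene statistics.

    ``samples`` maps group label -> 1D array.  Reports tie-corrected H with
    the chi-squared p-value (or an exact permutation p when ``exact`` and
    total n <= ``max_exact_n``), the epsilon-squared omnibus effect size
    H/(n-1), and pairwise rank-biserial effect sizes of every group against
    the first (reference) group.
    """
    labels = list(samples)
    groups = [np.asarray(samples[k], dtype=float) for k in labels]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    n = sum(len(g) for g in groups)
    all_identical = len(np.unique(np.concatenate(groups))) == 1
    if all_identical:
        h, p, method = 0.0, 1.0, "degenerate"
    else:
        h, p = stats.kruskal(*groups)
        method = "chi-squared"
        if exact:
            if n > max_exact_n:
                raise ValueError(f"exact mode limited to n <= {max_exact_n}")
            sizes = [len(g) for g in groups]
            pooled = np.concatenate(groups)
            h_obs = _kw_h(groups)
            count = total = 0
            for assignment in _partitions(tuple(range(n)), sizes):
                parts = [pooled[list(idx)] for idx in assignment]
                if _kw_h(parts) >= h_obs - 1e-12:
                    count += 1
                total += 1
            p = count / total
            method = "exact-permutation"

    eps2 = h / (n - 1)
    pw = []
    ref = labels[0]
    for other in labels[1:]:
        a, b = np.asarray(samples[ref], float), np.asarray(samples[other], float)
        u = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
        pw.append((ref, other, 1.0 - 2.0 * u / (len(a) * len(b))))
    return GroupComparison(
        h=float(h),
        p_value=float(p),
        epsilon_squared=float(eps2),
        pairwise=pd.DataFrame(pw, columns=["group_a", "group_b", "rank_biserial"]),
        n=n,
        method=method,
    )
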