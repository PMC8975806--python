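"""DNA fiber assay statistics.

Fibers are dual-pulse labeled (IdU then CldU) nascent DNA tracts measured in
um; lengths convert to kb at 2.59 kb per um, so CldU tract length over the
pulse duration gives elongation speed.  Sister forks emanating from one
origin report fork symmetry through the ratio of their CldU tract lengths
(close to 1 for unperturbed, symmetric replication), and the share of
origin-class structures (bidirectional red-green-red tracts plus
second-label-only tracts) among all structures gives the origin-firing
percentage.  Conditions are compared with the two-sided Wilcoxon-Mann-
Whitney rank-sum test (exact enumeration for small samples, tie-corrected
normal approximation otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, log10

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KB_PER_UM",
    "tract_kb",
    "elongation_speed_kb_min",
    "fork_symmetry",
    "origin_fraction",
    "mann_whitney",
    "MannWhitneyResult",
    "population_doublings",
]

KB_PER_UM = 2.59

ORIGIN_CLASSES = ("origin_bidirectional", "origin_second_label_only")


def tract_kb(length_um):
    """Convert a tract length in um to kb (1 um = 2.59 kb)."""
    length_um = np.asarray(length_um, dtype=float)
    if np.any(length_um < 0):
        raise ValueError("tract lengths must be non-negative")
    out = KB_PER_UM * length_um
    return float(out) if out.ndim == 0 else out


def elongation_speed_kb_min(length_um, pulse_min: float):
    """Fork speed in kb/min from a CldU tract and the pulse duration."""
    if pulse_min <= 0:
        raise ValueError("pulse duration must be positive")
    return tract_kb(length_um) / pulse_min


def fork_symmetry(tracts: pd.DataFrame, directional: bool = True) -> pd.DataFrame:
    """Left/right CldU ratio per bidirectional origin.

    Pairs are rows sharing an ``origin_pair_id`` (exactly two members); the
    first member of each pair is taken as the leftward fork.  Ratios are
    directional (left/right) by default; ``directional=False`` returns
    min/max instead.  Zero-length members are excluded and counted in the
    frame's ``attrs['n_excluded']``.
    """
    pairs = tracts[tracts["class"] == "origin_bidirectional"]
    rows = []
    excluded = 0
    for pid, sub in pairs.groupby("origin_pair_id"):
        if len(sub) != 2:
            raise ValueError(f"origin pair {pid} has {len(sub)} members, expected 2")
        left, right = sub["cldu_um"].to_numpy(dtype=float)
        if left <= 0 or right <= 0:
            excluded += 1
            continue
        ratio = left / right if directional else min(left, right) / max(left, right)
        rows.append((pid, left, right, ratio))
    out = pd.DataFrame(rows, columns=["origin_pair_id", "left_um", "right_um", "ratio"])
    out.attrs["n_excluded"] = excluded
    return out


def origin_fraction(tracts: pd.DataFrame) -> float:
    """Percent of replication structures that are origin initiation events.

    A bidirectional pair counts as one structure; origin events are
    bidirectional origins plus second-label-only tracts.
    """
    if len(tracts) == 0:
        raise ValueError("no tracts supplied")
    if tracts["class"].isna().any():
        raise ValueError("every tract must carry a structure class")
    bidir = tracts[tracts["class"] == "origin_bidirectional"]
    n_bidir = bidir["origin_pair_id"].nunique()
    n_single = (~tracts["class"].isin(["origin_bidirectional"])).sum()
    n_origin_single = (tracts["class"] == "origin_second_label_only").sum()
    total = n_bidir + n_single
    return 100.0 * (n_bidir + n_origin_single) / total


@dataclass
class MannWhitneyResult:
    u: float
    p_value: float
    method: str  # 'exact' or 'asymptotic'
    n_a: int
    n_b: int

    def summary(self) -> str:
        return (
            f"Mann-Whitney U = {self.u:.1f} (n = {self.n_a}, {self.n_b}), "
            f"two-sided p = {self.p_value:.4g} [{self.method}]"
        )


def _u_statistic(ranks_a, n_a, n_b) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney(
    sample_a, sample_b, exact: bool | None = None
) -> MannWhitneyResult:
    """Two-sided Wilcoxon-Mann-Whitney rank-sum test.

    Exact enumeration over all group assignments (mid-ranks for ties) when
    min(n) <= 8 or ``exact=True``; otherwise the tie-corrected normal
    approximation with continuity correction (scipy).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    n_a, n_b = len(a), len(b)
    if exact is None:
        exact = min(n_a, n_b) <= 8
    if not exact:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return MannWhitneyResult(float(res.statistic), float(res.pvalue), "asymptotic", n_a, n_b)

    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n_a], n_a, n_b)
    n = n_a + n_b
    total = comb(n, n_a)
    le = ge = 0
    idx = np.arange(n)
    for pick in combinations(idx, n_a):
        u = _u_statistic(ranks[list(pick)], n_a, n_b)
        if u <= u_obs + 1e-9:
            le += 1
        if u >= u_obs - 1e-9:
            ge += 1
    p = min(1.0, 2.0 * min(le, ge) / total)
    return MannWhitneyResult(float(u_obs), float(p), "exact", n_a, n_b)


def population_doublings(ucy: float, inoculum: float, starting_level: float = 0.0) -> float:
    """Final population-doubling level: n = 3.32 (log10 UCY - log10 l) + X."""
    if ucy <= 0 or inoculum <= 0:
        raise ValueError("cell counts must be positive")
    return 3.32 * (log10(ucy) - log10(inoculum)) + starting_level
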