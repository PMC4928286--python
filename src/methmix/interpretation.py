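"""Scoring fitted methylomes against CpG annotation sets.

CpGs whose methylation varies most across the fitted cell-type methylomes
(row-variance above its 75th percentile) are the candidate cell-type
discriminators; their overlap with externally defined CpG sets (blood
leukocyte DMPs, Polycomb-group loci, or DMP sets derived here from a WGBS
pseudo-reference of whole tissues) is scored with an odds ratio and
Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .deconvolution import MethylomeMatrix
from .io import BetaMatrix

__all__ = [
    "RowVarianceResult",
    "CpGSet",
    "EnrichmentResult",
    "row_variances",
    "set_enrichment",
    "tissue_distances",
    "derive_pair_dmps",
]


@dataclass
class RowVarianceResult:
    cpg_ids: list[str]
    s2: np.ndarray
    threshold: float
    high_flags: np.ndarray


@dataclass
class CpGSet:
    """Named collection of CpG identifiers."""

    name: str
    cpg_ids: tuple

    def __post_init__(self) -> None:
        ids = tuple(str(c) for c in self.cpg_ids)
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate identifiers in CpG set {self.name!r}")
        self.cpg_ids = ids

    def __len__(self) -> int:
        return len(self.cpg_ids)


@dataclass
class EnrichmentResult:
    set_name: str
    a: int  # high variance, in set
    b: int  # high variance, out of set
    c: int  # low variance, in set
    d: int  # low variance, out of set
    odds_ratio: float
    p_value: float


def row_variances(M: MethylomeMatrix | np.ndarray) -> RowVarianceResult:
    """Per-CpG sample variance across the K methylome values.

    The cutoff is the 75th percentile (linear-interpolation quantile) and a
    CpG is flagged "high" on strict inequality, so roughly a quarter of
    CpGs are flagged (exactly, up to ties).  Requires K >= 2.
    """
    if isinstance(M, MethylomeMatrix):
        values, ids = M.values, list(M.cpg_ids)
    else:
        values = np.atleast_2d(np.asarray(M, dtype=float))
        ids = [f"cg{j}" for j in range(values.shape[0])]
    if values.shape[1] < 2:
        raise ValueError("row variances need K >= 2 cell types")
    s2 = values.var(axis=1, ddof=1)
    threshold = float(np.quantile(s2, 0.75))  # type-7 linear interpolation
    return RowVarianceResult(ids, s2, threshold, s2 > threshold)


def set_enrichment(rv: RowVarianceResult, cpg_set: CpGSet) -> EnrichmentResult:
    """Association of high row-variance with set membership.

    Builds the 2x2 table over the tested CpGs, reports the sample
    cross-product odds ratio (with Haldane's +0.5 correction if and only
    if any cell is zero) and the two-sided exact hypergeometric p-value on
    the uncorrected table.
    """
    members = set(cpg_set.cpg_ids) & set(rv.cpg_ids)
    if not members:
        raise ValueError(f"CpG set {cpg_set.name!r} does not intersect the tested CpGs")
    in_set = np.array([c in members for c in rv.cpg_ids])
    high = rv.high_flags
    a = int((high & in_set).sum())
    b = int((high & ~in_set).sum())
    c = int((~high & in_set).sum())
    d = int((~high & ~in_set).sum())
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return EnrichmentResult(cpg_set.name, a, b, c, d, float(odds), p)


def _top_variable(wgbs: BetaMatrix, top_n_variable: int, max_missing: int = 2):
    """Rows with at most ``max_missing`` missing tissues, restricted to the
    most variable ``top_n_variable`` of them."""
    Y = wgbs.values
    keep = np.isnan(Y).sum(axis=1) <= max_missing
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError("no CpGs with enough observed tissues")
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        variances = np.nanvar(Y[idx], axis=1)
    if idx.size > top_n_variable:
        top = np.argsort(-variances, kind="stable")[:top_n_variable]
        idx = idx[np.sort(top)]
    return idx


def tissue_distances(wgbs: BetaMatrix, top_n_variable: int = 15000) -> pd.DataFrame:
    """All pairwise tissue distances on the most variable CpGs.

    CpGs with three or more missing tissues are removed, the
    ``top_n_variable`` highest-variance CpGs are retained (all, if fewer),
    and each pair's Manhattan distance over pairwise-complete entries is
    rescaled by (#used CpGs / #complete CpGs for the pair).  Rows are
    sorted by ascending distance.
    """
    if wgbs.shape[1] < 2:
        raise ValueError("need at least two tissues")
    idx = _top_variable(wgbs, top_n_variable)
    Y = wgbs.values[idx]
    n_used = idx.size
    n = Y.shape[1]
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(Y[:, i]) & ~np.isnan(Y[:, j])
            n_complete = int(both.sum())
            if n_complete == 0:
                raise ValueError(
                    f"tissues {wgbs.specimen_ids[i]!r} and {wgbs.specimen_ids[j]!r} "
                    "share no complete CpGs")
            dist = float(np.abs(Y[both, i] - Y[both, j]).sum() * (n_used / n_complete))
            rows.append({"tissue_a": wgbs.specimen_ids[i],
                         "tissue_b": wgbs.specimen_ids[j],
                         "distance": dist, "n_complete": n_complete})
    out = pd.DataFrame(rows).sort_values("distance", kind="stable").reset_index(drop=True)
    return out


def derive_pair_dmps(wgbs: BetaMatrix, n_pairs: int = 25, delta_threshold: float = 0.70,
                     min_dmps: int = 11, top_n_variable: int = 15000) -> list[CpGSet]:
    """DMP sets from the closest tissue pairs of a WGBS pseudo-reference.

    For each of the ``n_pairs`` smallest-distance pairs, the DMPs are the
    top-variable CpGs observed in both tissues whose methylation fractions
    differ strictly by more than ``delta_threshold``; pairs with fewer than
    ``min_dmps`` DMPs (ten or fewer at the defaults) are dropped.  Each
    surviving pair becomes a named CpGSet, invariant to tissue column
    order.
    """
    dist = tissue_distances(wgbs, top_n_variable)
    if n_pairs > len(dist):
        raise ValueError(f"n_pairs={n_pairs} exceeds the {len(dist)} available pairs")
    idx = _top_variable(wgbs, top_n_variable)
    Y = wgbs.values[idx]
    ids = np.array(wgbs.cpg_ids, dtype=object)[idx]
    col = {s: k for k, s in enumerate(wgbs.specimen_ids)}
    sets: list[CpGSet] = []
    for _, row in dist.head(n_pairs).iterrows():
        i, j = col[row["tissue_a"]], col[row["tissue_b"]]
        both = ~np.isnan(Y[:, i]) & ~np.isnan(Y[:, j])
        dmp = both & (np.abs(Y[:, i] - Y[:, j]) > delta_threshold)
        if int(dmp.sum()) < min_dmps:
            continue
        a, b = sorted([row["tissue_a"], row["tissue_b"]])
        sets.append(CpGSet(f"{a}|{b}", tuple(ids[dmp])))
    return sets
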