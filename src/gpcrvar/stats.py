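"""Permutation enrichment tests and rank-sum comparisons.

Two permutation designs: a gene-set test (does a receptor set overlap a
target gene set more than same-size random draws from the universe?) and a
per-receptor site test (do variant sites fall in functional sites more often
than equally many random positions drawn within each receptor?).  Empirical
p-values use the plain tail-count estimator ``#{null >= observed} / n_iter``
and are reported as ``< 1/n_iter`` when no null draw reaches the observation;
a normal-tail p from the null mean and sd is emitted alongside.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "PermutationResult",
    "permutation_set_enrichment",
    "permutation_site_enrichment",
    "rank_sum_compare",
]


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of one permutation test."""

    observed: float
    null_mean: float
    null_sd: float
    z_score: float  # NaN when the null is degenerate (sd = 0)
    empirical_p: float
    p_label: str  # "0.0123" or "< 1e-05" when no null draw reached observed
    normal_p: float  # upper-tail p from the normal approximation to the null
    n_iterations: int
    seed: int

    def to_json(self) -> str:
        d = asdict(self)
        d["z_score"] = None if math.isnan(self.z_score) else self.z_score
        d["normal_p"] = None if math.isnan(self.normal_p) else self.normal_p
        return json.dumps(d)


def _summarize(observed: float, null: np.ndarray, seed: int) -> PermutationResult:
    n_iter = null.size
    mean = float(null.mean())
    sd = float(null.std(ddof=0))
    if sd > 0:
        z = (observed - mean) / sd
        normal_p = float(sps.norm.sf(z))
    else:
        z = float("nan")
        normal_p = float("nan")
    count = int((null >= observed).sum())
    p = count / n_iter
    label = f"< {1 / n_iter:g}" if count == 0 else f"{p:g}"
    return PermutationResult(
        observed=float(observed),
        null_mean=mean,
        null_sd=sd,
        z_score=z,
        empirical_p=p,
        p_label=label,
        normal_p=normal_p,
        n_iterations=n_iter,
        seed=seed,
    )


def _overlap_null(
    n_universe: int,
    n_draw: int,
    target_mask: np.ndarray,
    n_iter: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Overlap counts of ``n_iter`` uniform without-replacement draws of size
    ``n_draw`` with the masked target subset."""
    # vectorized when the uniform matrix is small; otherwise draw per iteration
    if n_iter * n_universe <= 50_000_000:
        order = rng.random((n_iter, n_universe)).argsort(axis=1)[:, :n_draw]
        return target_mask[order].sum(axis=1)
    out = np.empty(n_iter, dtype=np.int64)
    for i in range(n_iter):
        idx = rng.choice(n_universe, size=n_draw, replace=False)
        out[i] = int(target_mask[idx].sum())
    return out


def permutation_set_enrichment(
    query: Iterable,
    universe: Iterable,
    target: Iterable,
    n_iter: int = 100_000,
    seed: int = 0,
) -> PermutationResult:
    """Gene-set permutation test.

    Observed statistic is ``|query ∩ target|``; each null iteration replaces
    the query with a same-size uniform draw (without replacement) from the
    universe and counts its overlap with the target set.
    """
    universe_list = sorted(set(universe))
    query_set = set(query)
    target_set = set(target)
    if not query_set <= set(universe_list):
        raise ValueError("query must be a subset of the universe")
    if not target_set <= set(universe_list):
        raise ValueError("target must be a subset of the universe")
    observed = len(query_set & target_set)
    mask = np.array([u in target_set for u in universe_list], dtype=np.int64)
    rng = np.random.default_rng(seed)
    null = _overlap_null(len(universe_list), len(query_set), mask, n_iter, rng)
    return _summarize(observed, null, seed)


def permutation_site_enrichment(
    variant_sites: Mapping[str, Iterable[int]],
    functional_sites: Mapping[str, Iterable[int]],
    receptor_lengths: Mapping[str, int],
    n_iter: int = 100_000,
    seed: int = 0,
) -> PermutationResult:
    """Site-level permutation test across a receptor panel.

    Observed statistic: total number of variant sites falling in functional
    sites, summed over receptors.  Each null iteration redraws, per receptor,
    the same number of sites uniformly without replacement from that
    receptor's residue positions.
    """
    rng = np.random.default_rng(seed)
    observed = 0
    null = np.zeros(n_iter, dtype=np.int64)
    for receptor in sorted(variant_sites):
        length = receptor_lengths[receptor]
        v_sites = set(variant_sites[receptor])
        if len(v_sites) > length:
            raise ValueError(
                f"{receptor}: {len(v_sites)} variant sites exceed {length} positions"
            )
        if not v_sites:
            continue
        f_sites = set(functional_sites.get(receptor, ()))
        observed += len(v_sites & f_sites)
        mask = np.zeros(length, dtype=np.int64)
        mask[[p - 1 for p in f_sites]] = 1
        null += _overlap_null(length, len(v_sites), mask, n_iter, rng)
    return _summarize(observed, null, seed)


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact p for the rank-sum test by enumerating all group
    assignments; midranks handle ties."""
    from itertools import combinations

    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a = len(a)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    lo = hi = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        u = ranks[list(idx)].sum() - n_a * (n_a + 1) / 2
        total += 1
        if u <= u_obs + 1e-9:
            lo += 1
        if u >= u_obs - 1e-9:
            hi += 1
    p = min(1.0, 2.0 * min(lo, hi) / total)
    return float(u_obs), p


def rank_sum_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    exact_max_n: int = 12,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison.

    Exact enumeration of all group assignments for combined n up to
    ``exact_max_n``; normal approximation with tie correction and continuity
    correction otherwise.  Returns (U statistic of the first group,
    two-sided p).  Two identical groups give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2), 1.0
    if a.size + b.size <= exact_max_n:
        return _exact_rank_sum_p(a, b)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
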