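"""Unsupervised sample grouping and beta-binomial differential testing.

For each candidate region and sequence context, samples are summarised by
their pooled methylation rate (sum of methylated reads over sum of total
reads in the region).  An iterative k-means scan over k = 2..k_max groups
the samples; the smallest k whose adjacent cluster means are all separated
by at least the minimum methylation difference is accepted, otherwise the
region stays untested for that context (no biologically meaningful
grouping exists).  Accepted groupings are tested with a beta-binomial
likelihood-ratio test: a single beta-binomial fitted to all samples'
pooled counts (null) against independent per-cluster fits (alternative),
with per-sample pooled counts as the observational unit so that
between-sample biological variance is modelled rather than read-level
pseudo-replication.  P-values are referred to a chi-square with 2(k-1)
degrees of freedom and corrected across all tests actually performed.

A region is called a DMR in a context only if it passes both the FDR
threshold and the minimum between-cluster methylation difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .hmm_segmentation import BetaBinomialParams, DomainError, _bb_log_pmf_raw, _weighted_bb_mle
from .io_formats import CONTEXTS, SampleSheet, ValidationError
from .population_segments import CandidateRegion


class UntestableRegion(Exception):
    """Raised when a region/context cannot be tested (flagged, never a
    silent p-value)."""


@dataclass(frozen=True)
class TestConfig:
    """Thresholds of the DMR testing stage.

    ``min_meth_diff`` is the lower boundary for between-cluster mean
    methylation differences (both for accepting a k-means grouping and for
    the final DMR call); ``fdr_level`` the significance level applied to
    corrected p-values.
    """

    k_max: int = 3
    min_meth_diff: float = 0.20
    fdr_level: float = 0.05
    min_samples_per_cluster: int = 1
    min_cov_per_sample: int = 3
    correction: str = "BH"
    n_init: int = 10

    def __post_init__(self) -> None:
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")
        if not (0.0 <= self.min_meth_diff <= 1.0):
            raise ValueError("min_meth_diff must lie in [0, 1]")
        if not (0.0 < self.fdr_level < 1.0):
            raise ValueError("fdr_level must lie in (0, 1)")
        if self.min_samples_per_cluster < 1 or self.min_cov_per_sample < 1:
            raise ValueError("minimum counts must be >= 1")
        if self.correction not in ("BH", "bonferroni"):
            raise ValueError("correction must be 'BH' or 'bonferroni'")


@dataclass
class Grouping:
    """A per-region, per-context partition of the eligible samples.

    Cluster labels are 1-based and ordered by ascending cluster mean;
    ``k == 1`` marks a region left untested for the context.
    """

    context: str
    k: int
    assignment: dict[str, int]
    cluster_means: tuple[float, ...]

    @property
    def max_pairwise_diff(self) -> float:
        if self.k < 2:
            return 0.0
        return float(max(self.cluster_means) - min(self.cluster_means))

    def members(self, cluster: int) -> list[str]:
        return [s for s, c in self.assignment.items() if c == cluster]


@dataclass
class DMRResult:
    """One tested candidate region in one context."""

    region: CandidateRegion
    context: str
    grouping: Grouping
    lr_stat: float
    p_value: float
    q_value: float = float("nan")
    significant: bool = False

    @property
    def direction(self) -> str:
        """Sign pattern of cluster means around the pooled mean."""
        overall = float(np.mean(self.grouping.cluster_means))
        return "".join("+" if m >= overall else "-" for m in self.grouping.cluster_means)


def sample_region_rate(
    candidate: CandidateRegion, sample: str, context: str, min_cov_per_sample: int = 3
) -> float | None:
    """Pooled methylation rate of one sample in a region and context.

    sum(n_meth) / sum(n_total) over the sample's sites of that context;
    None (missing) if the pooled coverage is below ``min_cov_per_sample``
    or the context has no sites.
    """
    agg = candidate.aggregates.get(sample, {}).get(context)
    if agg is None:
        return None
    sum_meth, sum_total, n_sites = agg
    if n_sites == 0 or sum_total < min_cov_per_sample:
        return None
    return sum_meth / sum_total


def region_rates(
    candidate: CandidateRegion, context: str, sample_ids: Sequence[str],
    min_cov_per_sample: int = 3,
) -> dict[str, float]:
    """Eligible samples' pooled rates, in sample-sheet order."""
    out = {}
    for sid in sample_ids:
        r = sample_region_rate(candidate, sid, context, min_cov_per_sample)
        if r is not None:
            out[sid] = r
    return out


# ---------------------------------------------------------------------------
# grouping


def _quantile_centroids(x: np.ndarray, k: int) -> np.ndarray:
    return np.quantile(np.sort(x), (np.arange(k) + 0.5) / k)


def iterative_kmeans(
    rates: Mapping[str, float],
    k_max: int = 3,
    min_meth_diff: float = 0.20,
    seed: int = 0,
    n_init: int = 10,
    context: str = "CG",
) -> Grouping:
    """Group samples by region methylation rate with an iterative k-means.

    One-dimensional k-means is run for k = 2..min(k_max, n), each taking
    the best of ``n_init`` seeded initialisations (quantile centroids plus
    seeded jitter) by within-cluster sum of squares.  The chosen k is the
    smallest whose sorted cluster means are all separated by at least
    ``min_meth_diff``; if none qualifies the region is left untested
    (k = 1).  Deterministic given the seed and invariant to sample order.
    """
    samples = list(rates)
    if len(samples) < 2:
        raise UntestableRegion("fewer than 2 samples with a rate")
    x = np.array([rates[s] for s in samples], dtype=float)
    rng = np.random.default_rng(seed)
    span = max(x.max() - x.min(), 1e-3)
    for k in range(2, min(k_max, len(samples)) + 1):
        if len(np.unique(x)) < k:
            continue
        base = _quantile_centroids(x, k)
        inits = [base] + [
            np.sort(base + rng.normal(0.0, 0.05 * span, size=k)) for _ in range(n_init - 1)
        ]
        best = None
        for init in inits:
            km = KMeans(n_clusters=k, init=init.reshape(-1, 1), n_init=1, max_iter=300)
            km.fit(x.reshape(-1, 1))
            if best is None or km.inertia_ < best.inertia_ - 1e-12:
                best = km
        centers = best.cluster_centers_.ravel()
        order = np.argsort(centers)
        # recompute means from members (centers may drift from assignment)
        labels = best.labels_
        means = np.array([x[labels == c].mean() for c in order])
        if np.all(np.diff(means) >= min_meth_diff):
            relabel = {int(c): rank + 1 for rank, c in enumerate(order)}
            assignment = {s: relabel[int(l)] for s, l in zip(samples, labels)}
            return Grouping(context, k, assignment, tuple(float(m) for m in means))
    pooled = float(x.mean())
    return Grouping(context, 1, {s: 1 for s in samples}, (pooled,))


def supervised_grouping(
    candidate: CandidateRegion,
    context: str,
    sheet: SampleSheet,
    min_cov_per_sample: int = 3,
) -> Grouping:
    """Impose the sample sheet's shared group labels instead of k-means.

    Clusters are the user groups (ordered by ascending mean); downstream
    testing is identical to the unsupervised path.  A group with zero
    eligible samples in the region makes the region untestable there.
    """
    groups = sheet.groups
    if groups is None or len(set(groups.values())) < 2:
        raise ValueError("supervised grouping requires >= 2 group labels in the sheet")
    rates = region_rates(candidate, context, sheet.sample_ids, min_cov_per_sample)
    by_group: dict[str, list[str]] = {}
    for sid, r in rates.items():
        by_group.setdefault(groups[sid], []).append(sid)
    if len(by_group) < len(set(groups.values())):
        missing = sorted(set(groups.values()) - set(by_group))
        raise UntestableRegion(
            f"group(s) {missing} have no eligible samples in {candidate.region_id}"
        )
    means = {
        g: float(np.mean([rates[s] for s in members])) for g, members in by_group.items()
    }
    ordered = sorted(means, key=means.get)
    assignment = {}
    for rank, g in enumerate(ordered, start=1):
        for sid in by_group[g]:
            assignment[sid] = rank
    return Grouping(context, len(ordered), assignment, tuple(means[g] for g in ordered))


# ---------------------------------------------------------------------------
# beta-binomial fitting and likelihood-ratio test


def bb_fit_mle(counts: Sequence[tuple[int, int]]) -> tuple[BetaBinomialParams, float]:
    """Maximum-likelihood beta-binomial fit to (k, n) count pairs.

    Bounded quasi-Newton on (log alpha, log beta), started from the
    method-of-moments estimate; returns the parameters and the maximised
    log-likelihood.  With a single observation the fitted mean matches
    k/n while the dispersion runs to its lower bound (binomial limit).
    """
    counts = [(int(k), int(n)) for k, n in counts]
    if not counts or all(n == 0 for _, n in counts):
        raise DomainError("need at least one observation with n >= 1")
    if any(k < 0 or k > n for k, n in counts):
        raise DomainError("require 0 <= k <= n")
    ks = np.array([k for k, _ in counts], dtype=float)
    ns = np.array([n for _, n in counts], dtype=float)
    w = np.ones_like(ks)
    m = min(max(ks.sum() / ns.sum(), 1e-4), 1 - 1e-4)
    p = ks / np.maximum(ns, 1)
    var = float(np.var(p))
    rho = min(max(var / (m * (1 - m)) if m * (1 - m) > 0 else 1e-3, 1e-4), 0.95)
    mom = BetaBinomialParams.from_mean_dispersion(m, rho)
    near_binomial = BetaBinomialParams.from_mean_dispersion(m, 1e-5)
    params, ll = _weighted_bb_mle(ks, ns, w, mom, [near_binomial])
    return params, ll


def bb_lrt(
    counts_by_cluster: Mapping[int, Sequence[tuple[int, int]]],
    min_samples_per_cluster: int = 1,
) -> tuple[float, float, int]:
    """Beta-binomial likelihood-ratio test of equal cluster distributions.

    Null: one beta-binomial for all samples' pooled (k, n) region counts.
    Alternative: an independent beta-binomial per cluster.  Returns
    (lr_stat, p_value, df) with lr_stat = max(0, 2(ll_alt - ll_null)) and
    p from chi-square with 2(k-1) degrees of freedom.
    """
    k_clusters = len(counts_by_cluster)
    if k_clusters < 2:
        raise UntestableRegion("need >= 2 clusters to test")
    for c, counts in counts_by_cluster.items():
        if len(counts) < min_samples_per_cluster:
            raise UntestableRegion(f"cluster {c} has fewer than "
                                   f"{min_samples_per_cluster} samples with counts")
    all_counts = [kn for counts in counts_by_cluster.values() for kn in counts]
    try:
        _, ll_null = bb_fit_mle(all_counts)
        ll_alt = 0.0
        for counts in counts_by_cluster.values():
            _, ll_c = bb_fit_mle(counts)
            ll_alt += ll_c
    except DomainError as exc:
        raise UntestableRegion(f"degenerate optimisation: {exc}") from exc
    if not (np.isfinite(ll_null) and np.isfinite(ll_alt)):
        raise UntestableRegion("non-finite likelihood in optimisation")
    lr = max(0.0, 2.0 * (ll_alt - ll_null))
    df = 2 * (k_clusters - 1)
    p = float(chi2.sf(lr, df))
    return lr, p, df


# ---------------------------------------------------------------------------
# multiple testing


def bonferroni_threshold(m: int, level: float = 0.05) -> float:
    """Family-wise per-test significance threshold level/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return level / m


def correct_multiple_tests(
    p_values: Sequence[float], method: str = "BH", level: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Adjust p-values across the tested family.

    BH returns monotone step-up q-values; bonferroni returns
    min(1, p*m) with rejection at p <= level/m.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "BH":
        reject, q, _, _ = multipletests(p, alpha=level, method="fdr_bh")
        return q, reject
    if method == "bonferroni":
        q = np.minimum(p * p.size, 1.0)
        reject = p <= bonferroni_threshold(p.size, level)
        return q, reject
    raise ValueError("method must be 'BH' or 'bonferroni'")


# ---------------------------------------------------------------------------
# region scan and classification


def test_candidates(
    candidates: Iterable[CandidateRegion],
    sheet: SampleSheet,
    config: TestConfig = TestConfig(),
    seed: int = 0,
    supervised: bool = False,
) -> list[DMRResult]:
    """Group and test every candidate region in every context.

    Returns one :class:`DMRResult` per (region, context) actually tested;
    untestable combinations (too few eligible samples, no qualifying
    grouping, degenerate fits) are skipped and do not enter the
    multiple-testing family.  Call :func:`classify_dmrs` on the result to
    attach q-values and significance calls.
    """
    results: list[DMRResult] = []
    for candidate in candidates:
        for context in CONTEXTS:
            rates = region_rates(
                candidate, context, sheet.sample_ids, config.min_cov_per_sample
            )
            if len(rates) < 2:
                continue
            try:
                if supervised:
                    grouping = supervised_grouping(
                        candidate, context, sheet, config.min_cov_per_sample
                    )
                else:
                    grouping = iterative_kmeans(
                        rates,
                        k_max=config.k_max,
                        min_meth_diff=config.min_meth_diff,
                        seed=seed,
                        n_init=config.n_init,
                        context=context,
                    )
            except UntestableRegion:
                continue
            if grouping.k < 2:
                continue
            counts_by_cluster: dict[int, list[tuple[int, int]]] = {}
            for sid in grouping.assignment:
                agg = candidate.aggregates[sid][context]
                counts_by_cluster.setdefault(grouping.assignment[sid], []).append(
                    (agg[0], agg[1])
                )
            try:
                lr, p, _ = bb_lrt(counts_by_cluster, config.min_samples_per_cluster)
            except UntestableRegion:
                continue
            results.append(DMRResult(candidate, context, grouping, lr, p))
    return results


def classify_dmrs(
    results: Sequence[DMRResult], config: TestConfig = TestConfig()
) -> list[DMRResult]:
    """Attach q-values and the dual significance call; return DMRs only.

    The correction family is all tests actually performed, across regions
    and contexts.  A region is a context-specific DMR iff its corrected
    p-value passes ``fdr_level`` AND the maximum pairwise cluster-mean
    difference reaches ``min_meth_diff``.  A region may be a DMR in
    several contexts.
    """
    if not results:
        return []
    q, reject = correct_multiple_tests(
        [r.p_value for r in results], config.correction, config.fdr_level
    )
    dmrs = []
    for r, qi, rej in zip(results, q, reject):
        r.q_value = float(qi)
        r.significant = bool(rej) and r.grouping.max_pairwise_diff >= config.min_meth_diff
        if r.significant:
            dmrs.append(r)
    dmrs.sort(key=lambda r: (r.region.chrom, r.region.start, r.context))
    return dmrs


def export_dmr_matrix(
    dmrs: Sequence[DMRResult],
    sheet: SampleSheet,
    min_cov_per_sample: int = 3,
) -> pd.DataFrame:
    """DMR x sample matrix of pooled region methylation rates.

    Rows are DMRs (region:context), columns the samples in sheet order;
    entries are pooled region rates or NaN where a sample is ineligible.
    This matrix is the hand-off point for heatmaps and PCA.
    """
    rows = {}
    for r in dmrs:
        key = f"{r.region.region_id}:{r.context}"
        rows[key] = [
            sample_region_rate(r.region, sid, r.context, min_cov_per_sample)
            for sid in sheet.sample_ids
        ]
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=sheet.sample_ids)
    mat.index.name = "dmr"
    return mat.astype(float)
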