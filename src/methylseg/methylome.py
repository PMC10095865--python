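"""Per-sample methylome tracks: rates, coverage filters, rate distributions.

A :class:`SampleMethylome` wraps one sample's parsed cytosine table and
offers the per-cytosine methylation rate (n_meth / n_total), coverage
filtering, and the per-context methylation-rate distribution that the HMM
training step learns from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .io_formats import CONTEXTS, CytosineSite, ValidationError


class UndefinedRateError(ValueError):
    """Methylation rate requested for a zero-coverage site."""


def methylation_rate(site: CytosineSite) -> float:
    """Per-cytosine methylation rate n_meth / n_total.

    Zero-coverage sites carry no rate; they must have been filtered at
    parse time.
    """
    if site.n_total < 1:
        raise UndefinedRateError(f"site {site.chrom}:{site.pos} has zero coverage")
    return site.n_meth / site.n_total


@dataclass
class SampleMethylome:
    """One sample's cytosine sites, sorted by (chrom, pos, strand)."""

    sample_id: str
    sites: pd.DataFrame  # columns chrom, pos, strand, context, n_meth, n_total

    def __post_init__(self) -> None:
        df = self.sites
        if len(df):
            key = df[["chrom", "pos", "strand"]]
            if key.duplicated().any():
                raise ValidationError(
                    f"sample {self.sample_id}: duplicate (chrom, pos, strand) sites"
                )
            per_chrom = df.groupby("chrom", sort=False)["pos"]
            if not per_chrom.apply(lambda s: s.is_monotonic_increasing).all():
                self.sites = df.sort_values(
                    ["chrom", "pos", "strand"], kind="mergesort"
                ).reset_index(drop=True)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.sites["chrom"]))

    def per_chrom(self) -> Iterator[tuple[str, pd.DataFrame]]:
        for chrom, sub in self.sites.groupby("chrom", sort=False):
            yield chrom, sub.reset_index(drop=True)

    def global_stats(self) -> pd.DataFrame:
        """Per-context totals: covered sites, sum n_meth, sum n_total."""
        rows = []
        for ctx in CONTEXTS:
            sub = self.sites[self.sites["context"] == ctx]
            rows.append(
                {
                    "context": ctx,
                    "n_sites": int(len(sub)),
                    "sum_meth": int(sub["n_meth"].sum()),
                    "sum_total": int(sub["n_total"].sum()),
                }
            )
        return pd.DataFrame(rows).set_index("context")

    def iter_sites(self) -> Iterator[CytosineSite]:
        for row in self.sites.itertuples(index=False):
            yield CytosineSite(row.chrom, int(row.pos), row.strand, row.context,
                               int(row.n_meth), int(row.n_total))


def filter_by_coverage(methylome: SampleMethylome, min_cov: int) -> SampleMethylome:
    """Drop sites with fewer than ``min_cov`` total reads; order preserved."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    kept = methylome.sites[methylome.sites["n_total"] >= min_cov].reset_index(drop=True)
    return SampleMethylome(methylome.sample_id, kept)


@dataclass(frozen=True)
class RateDistribution:
    """Histogram and summary of per-site methylation rates in one context.

    ``fraction_gt0`` is the fraction of covered sites with any methylated
    read; ``mean_rate_gt0`` the mean rate among those sites (NaN if none).
    An empty context yields the ``n_sites == 0`` sentinel rather than an
    exception.
    """

    context: str
    n_sites: int
    hist: np.ndarray
    bin_edges: np.ndarray
    fraction_gt0: float
    mean_rate_gt0: float

    @property
    def empty(self) -> bool:
        return self.n_sites == 0


def context_rate_distribution(
    methylome: SampleMethylome, context: str, n_bins: int = 20
) -> RateDistribution:
    """Distribution of per-site methylation rates for one sequence context."""
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    sub = methylome.sites[methylome.sites["context"] == context]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    if len(sub) == 0:
        return RateDistribution(context, 0, np.zeros(n_bins, dtype=int), edges,
                                float("nan"), float("nan"))
    rates = (sub["n_meth"] / sub["n_total"]).to_numpy()
    hist, _ = np.histogram(rates, bins=edges)
    gt0 = rates > 0
    frac = float(gt0.mean())
    mean_gt0 = float(rates[gt0].mean()) if gt0.any() else float("nan")
    return RateDistribution(context, int(len(sub)), hist, edges, frac, mean_gt0)


def rate_distribution_table(methylome: SampleMethylome) -> pd.DataFrame:
    """Per-context rate histograms as a tidy frame (diagnostics dump)."""
    rows = []
    for ctx in CONTEXTS:
        dist = context_rate_distribution(methylome, ctx)
        for lo, hi, count in zip(dist.bin_edges[:-1], dist.bin_edges[1:], dist.hist):
            rows.append({"context": ctx, "bin_lo": lo, "bin_hi": hi, "count": int(count)})
    return pd.DataFrame(rows)


def apply_conversion_correction(
    methylome: SampleMethylome, failure_rate: float
) -> SampleMethylome:
    """Optional bisulfite non-conversion pre-correction hook.

    Subtracts the expected number of spuriously methylated-looking reads
    (``failure_rate`` x coverage) from n_meth, truncating at zero.  Off by
    default; no correction is applied unless explicitly requested.
    """
    if not (0.0 <= failure_rate < 1.0):
        raise ValueError("failure_rate must be in [0, 1)")
    df = methylome.sites.copy()
    adj = df["n_meth"] - np.rint(failure_rate * df["n_total"]).astype(int)
    df["n_meth"] = np.maximum(adj, 0)
    return SampleMethylome(methylome.sample_id, df)
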