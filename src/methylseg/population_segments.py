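"""Population-scale candidate regions from MR-frequency breakpoints.

All samples' methylated regions are projected onto the genome and counted
with an interval sweep, giving a piecewise-constant MR-frequency profile.
Breakpoints where the frequency jumps by at least a configurable fraction
of the cohort are retained; stretches between adjacent retained
breakpoints that are covered by at least one sample's MR throughout become
candidate regions for differential testing.  The frequency-change
threshold acts as a minimum epiallele-frequency filter: variants carried
by too few samples never reach the statistics stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np

from .hmm_segmentation import MethylatedRegion
from .io_formats import CONTEXTS, ValidationError
from .methylome import SampleMethylome


@dataclass
class FrequencyProfile:
    """Piecewise-constant count of samples whose MRs cover each interval.

    ``boundaries`` has length m+1 and ``counts`` length m; interval i is
    [boundaries[i], boundaries[i+1]) with constant count counts[i].
    Adjacent intervals always differ in count; the tiling spans the hull
    of all MR footprints (zero-count gaps inside the hull are kept as
    explicit intervals).
    """

    chrom: str
    boundaries: np.ndarray
    counts: np.ndarray
    n_samples: int

    def intervals(self) -> Iterator[tuple[int, int, int]]:
        for i in range(len(self.counts)):
            yield int(self.boundaries[i]), int(self.boundaries[i + 1]), int(self.counts[i])

    def count_at(self, pos: int) -> int:
        """Brute-force-comparable lookup of the frequency at one base."""
        i = np.searchsorted(self.boundaries, pos, side="right") - 1
        if i < 0 or i >= len(self.counts):
            return 0
        return int(self.counts[i])


def _validate_disjoint(mrs_by_sample: Mapping[str, Iterable[MethylatedRegion]]) -> None:
    for sid, mrs in mrs_by_sample.items():
        seen: dict[str, int] = {}
        for mr in sorted(mrs, key=lambda r: (r.chrom, r.start)):
            if mr.chrom in seen and mr.start < seen[mr.chrom]:
                raise ValidationError(f"overlapping MRs in sample {sid} on {mr.chrom}")
            seen[mr.chrom] = mr.end


def mr_frequency_profile(
    mrs_by_sample: Mapping[str, Iterable[MethylatedRegion]], n_samples: int | None = None
) -> dict[str, FrequencyProfile]:
    """Interval sweep over all samples' MRs: +1 at starts, -1 at ends.

    Equivalent to counting, at every base, the number of samples whose MR
    set covers it (the brute-force definition used as test oracle).
    """
    if n_samples is None:
        n_samples = len(mrs_by_sample)
    _validate_disjoint(mrs_by_sample)
    events: dict[str, list[tuple[int, int]]] = {}
    for mrs in mrs_by_sample.values():
        for mr in mrs:
            events.setdefault(mr.chrom, []).append((mr.start, 1))
            events[mr.chrom].append((mr.end, -1))
    profiles: dict[str, FrequencyProfile] = {}
    for chrom, evs in events.items():
        pos = np.array(sorted({p for p, _ in evs}), dtype=np.int64)
        delta = np.zeros(len(pos), dtype=np.int64)
        idx = {p: i for i, p in enumerate(pos)}
        for p, d in evs:
            delta[idx[p]] += d
        running = np.cumsum(delta)[:-1]  # count within [pos[i], pos[i+1])
        # merge adjacent intervals with equal counts
        keep = np.concatenate([[True], np.diff(running) != 0])
        boundaries = np.concatenate([pos[:-1][keep], [pos[-1]]])
        counts = running[keep]
        profiles[chrom] = FrequencyProfile(chrom, boundaries, counts, n_samples)
    return profiles


@dataclass
class CandidateRegion:
    """A population-level segment between retained MR-frequency breakpoints.

    ``aggregates[sample][context] = (sum_meth, sum_total, n_sites)`` over
    the sample's covered cytosines within [start, end); every sample
    contributes counts (absence of methylation is signal), while
    ``supporting_samples`` records only MR carriers.
    """

    chrom: str
    start: int
    end: int
    supporting_samples: tuple[str, ...]
    aggregates: dict[str, dict[str, tuple[int, int, int]]]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("candidate must have end > start")

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def _retained_breakpoints(profile: FrequencyProfile, threshold: int) -> np.ndarray:
    """Boundary positions where |count step| >= threshold (count is 0
    outside the profile hull)."""
    counts = np.concatenate([[0], profile.counts, [0]])
    deltas = np.abs(np.diff(counts))
    return profile.boundaries[deltas >= threshold]


def _split_long(
    start: int,
    end: int,
    profile: FrequencyProfile,
    retained: set[int],
    max_len: int,
) -> list[tuple[int, int]]:
    """Split over-long candidates at their largest internal (non-retained)
    frequency change; ties broken leftmost; recurse on both halves."""
    if end - start <= max_len:
        return [(start, end)]
    inner_idx = [
        i
        for i in range(1, len(profile.boundaries) - 1)
        if start < profile.boundaries[i] < end and int(profile.boundaries[i]) not in retained
    ]
    if not inner_idx:
        return [(start, end)]
    changes = [abs(int(profile.counts[i]) - int(profile.counts[i - 1])) for i in inner_idx]
    best = inner_idx[int(np.argmax(changes))]  # argmax is leftmost on ties
    mid = int(profile.boundaries[best])
    return _split_long(start, mid, profile, retained, max_len) + _split_long(
        mid, end, profile, retained, max_len
    )


def _aggregate(
    methylomes: Mapping[str, SampleMethylome], chrom: str, start: int, end: int
) -> tuple[dict, int]:
    aggregates: dict[str, dict[str, tuple[int, int, int]]] = {}
    covered_positions: set[int] = set()
    for sid, meth in methylomes.items():
        df = meth.sites
        sub = df[(df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] < end)]
        per_ctx = {}
        for ctx in CONTEXTS:
            csub = sub[sub["context"] == ctx]
            per_ctx[ctx] = (
                int(csub["n_meth"].sum()),
                int(csub["n_total"].sum()),
                int(len(csub)),
            )
        aggregates[sid] = per_ctx
        covered_positions.update(sub["pos"].tolist())
    return aggregates, len(covered_positions)


def segment_candidates(
    profiles: Mapping[str, FrequencyProfile],
    mrs_by_sample: Mapping[str, Iterable[MethylatedRegion]],
    methylomes: Mapping[str, SampleMethylome],
    min_freq_change: float = 0.20,
    max_segment_length: int = 10_000,
    min_sites_per_segment: int = 10,
) -> list[CandidateRegion]:
    """Construct candidate regions from the MR-frequency profile.

    A breakpoint is retained where the MR frequency changes by at least
    ``ceil(min_freq_change * n_samples)`` samples.  Each stretch between
    adjacent retained breakpoints whose profile count stays >= 1 becomes a
    candidate; candidates longer than ``max_segment_length`` are split at
    their largest internal frequency change, and candidates with fewer
    than ``min_sites_per_segment`` covered cytosines (union over samples)
    are dropped.
    """
    if not (0.0 < min_freq_change <= 1.0):
        raise ValueError("min_freq_change must lie in (0, 1]")
    candidates: list[CandidateRegion] = []
    for chrom in sorted(profiles):
        profile = profiles[chrom]
        threshold = max(1, math.ceil(min_freq_change * profile.n_samples))
        retained = _retained_breakpoints(profile, threshold)
        retained_set = {int(p) for p in retained}
        for left, right in zip(retained[:-1], retained[1:]):
            i0 = int(np.searchsorted(profile.boundaries, left))
            i1 = int(np.searchsorted(profile.boundaries, right))
            if i1 <= i0 or np.any(profile.counts[i0:i1] < 1):
                continue
            for start, end in _split_long(
                int(left), int(right), profile, retained_set, max_segment_length
            ):
                aggregates, n_covered = _aggregate(methylomes, chrom, start, end)
                if n_covered < min_sites_per_segment:
                    continue
                support = tuple(
                    sid
                    for sid in methylomes
                    if any(
                        mr.chrom == chrom and mr.start < end and mr.end > start
                        for mr in mrs_by_sample.get(sid, [])
                    )
                )
                if not support:
                    continue
                candidates.append(
                    CandidateRegion(chrom, start, end, support, aggregates)
                )
    candidates.sort(key=lambda c: (c.chrom, c.start))
    return candidates
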