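"""Ground-truthed multi-sample methylome simulation.

Generates three-context methylomes with block-structured high-methylation
regions, beta-distributed per-site methylation levels within state,
binomial read counts given Poisson coverage, and planted between-group
DMRs, so that every pipeline stage can be scored against known truth
without any external data.

The generative model mirrors the segmentation model: cytosine positions
are placed with context-specific densities and shared across samples (as
they are in a real reference genome); each site is latently LOW or HIGH
according to block membership; the per-site methylation level is drawn
from the state/context beta distribution; reads are binomial given the
level and an independent Poisson coverage.  Inside a planted DMR the
affected group's beta mean is replaced while the dispersion is kept, so
the differential signal is a mean shift on the natural count noise.

Simplifications (documented in the methods note): coverage has no
positional autocorrelation, and planted context-specific DMRs are
context-pure (the interval carries only the target context's cytosines).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hmm_segmentation import BetaBinomialParams, STATE_HIGH, STATE_LOW
from .io_formats import CONTEXTS, SampleSheet, SampleEntry, write_counts_tsv
from .methylome import SampleMethylome

DEFAULT_STATE_PARAMS = {
    # echoes plant methylation-rate profiles: CG near-binary, CHG ~ 0.5,
    # CHH ~ 0.3 among methylated cytosines; LOW states near zero
    (STATE_LOW, "CG"): BetaBinomialParams.from_mean_dispersion(0.02, 0.10),
    (STATE_LOW, "CHG"): BetaBinomialParams.from_mean_dispersion(0.02, 0.10),
    (STATE_LOW, "CHH"): BetaBinomialParams.from_mean_dispersion(0.03, 0.10),
    (STATE_HIGH, "CG"): BetaBinomialParams.from_mean_dispersion(0.85, 0.20),
    (STATE_HIGH, "CHG"): BetaBinomialParams.from_mean_dispersion(0.50, 0.20),
    (STATE_HIGH, "CHH"): BetaBinomialParams.from_mean_dispersion(0.30, 0.20),
}

# per-bp cytosine densities counting both strands, approximating
# A. thaliana base composition (GC ~ 36%): CHH dominates, CG and CHG similar
DEFAULT_DENSITIES = {"CG": 0.04, "CHG": 0.04, "CHH": 0.10}


@dataclass(frozen=True)
class PlantedDMR:
    """A planted group-specific differential interval in one context."""

    chrom: str
    start: int
    end: int
    context: str
    group_means: dict[str, float]

    def high_groups(self) -> set[str]:
        return {g for g, m in self.group_means.items() if m >= 0.5}


@dataclass
class SimulationConfig:
    genome: list[tuple[str, int]]
    n_samples: int
    groups: list[str]
    densities: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DENSITIES))
    mr_blocks: list[tuple[str, int, int]] = field(default_factory=list)
    planted_dmrs: list[PlantedDMR] = field(default_factory=list)
    coverage_mean: float = 10.0
    coverage_offset: int = 0
    state_params: dict = field(default_factory=lambda: dict(DEFAULT_STATE_PARAMS))
    seed: int = 0
    drop_zero_coverage: bool = True
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        lengths = dict(self.genome)
        if len(self.groups) != self.n_samples:
            raise ValueError("groups must have one label per sample")
        for ctx, d in self.densities.items():
            if ctx not in CONTEXTS or not (0 < d <= 1):
                raise ValueError(f"bad density for {ctx}: {d}")
        for chrom, start, end in self.mr_blocks:
            if chrom not in lengths or not (0 <= start < end <= lengths[chrom]):
                raise ValueError(f"MR block {chrom}:{start}-{end} outside genome")
        for dmr in self.planted_dmrs:
            if dmr.chrom not in lengths or not (0 <= dmr.start < dmr.end <= lengths[dmr.chrom]):
                raise ValueError(f"planted DMR {dmr.chrom}:{dmr.start}-{dmr.end} outside genome")
            if dmr.context not in CONTEXTS:
                raise ValueError(f"bad DMR context {dmr.context}")
            for g, m in dmr.group_means.items():
                if not (0 < m <= 1):
                    raise ValueError(f"DMR group mean for {g} must be in (0, 1]")
        if self.sample_ids is None:
            self.sample_ids = [f"sample{i + 1:02d}" for i in range(self.n_samples)]


@dataclass
class SimulationResult:
    config: SimulationConfig
    methylomes: dict[str, SampleMethylome]
    true_mrs: dict[str, list[tuple[str, int, int]]]  # per sample HIGH intervals
    true_dmrs: list[PlantedDMR]
    groups: dict[str, str]

    def write(self, outdir: str | os.PathLike) -> SampleSheet:
        """Write counts TSVs, a sample sheet, and truth BEDs; return sheet."""
        os.makedirs(outdir, exist_ok=True)
        entries = []
        for sid, meth in self.methylomes.items():
            path = os.path.join(os.fspath(outdir), f"{sid}.counts.tsv")
            write_counts_tsv(meth.sites, path)
            entries.append(SampleEntry(sid, path, self.groups[sid]))
        sheet = SampleSheet(entries)
        sheet.to_tsv(os.path.join(os.fspath(outdir), "samplesheet.tsv"))
        with open(os.path.join(os.fspath(outdir), "truth_mrs.bed"), "w") as fh:
            fh.write("#chrom\tstart\tend\tsample\n")
            for sid in self.config.sample_ids:
                for chrom, start, end in sorted(self.true_mrs[sid]):
                    fh.write(f"{chrom}\t{start}\t{end}\t{sid}\n")
        with open(os.path.join(os.fspath(outdir), "truth_dmrs.bed"), "w") as fh:
            fh.write("#chrom\tstart\tend\tcontext\tgroup_means\n")
            for dmr in sorted(self.true_dmrs, key=lambda d: (d.chrom, d.start)):
                means = ",".join(f"{g}={m:g}" for g, m in sorted(dmr.group_means.items()))
                fh.write(f"{dmr.chrom}\t{dmr.start}\t{dmr.end}\t{dmr.context}\t{means}\n")
        return sheet


def _in_intervals(pos: np.ndarray, intervals: list[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(len(pos), dtype=bool)
    for start, end in intervals:
        mask |= (pos >= start) & (pos < end)
    return mask


def simulate_methylomes(config: SimulationConfig) -> SimulationResult:
    """Draw a ground-truthed cohort from the generative model.

    Fully deterministic given ``config.seed``: positions and contexts are
    drawn once (shared across samples), then per-sample levels, coverage
    and counts in fixed sample order.
    """
    rng = np.random.default_rng(config.seed)
    groups = dict(zip(config.sample_ids, config.groups))

    # --- shared site skeleton
    skeleton: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    dens = np.array([config.densities.get(c, 0.0) for c in CONTEXTS])
    total_density = dens.sum()
    rel = dens / total_density
    for chrom, length in config.genome:
        pos = np.flatnonzero(rng.random(length) < total_density)
        ctx = rng.choice(3, size=len(pos), p=rel)
        strand = rng.choice(2, size=len(pos))
        # context-pure planted DMR intervals: drop other contexts inside
        keep = np.ones(len(pos), dtype=bool)
        for dmr in config.planted_dmrs:
            if dmr.chrom != chrom:
                continue
            ci = CONTEXTS.index(dmr.context)
            inside = (pos >= dmr.start) & (pos < dmr.end)
            keep &= ~inside | (ctx == ci)
        skeleton[chrom] = (pos[keep], ctx[keep], strand[keep])

    # --- per-site state/beta parameters, shared structure
    high_blocks: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in config.mr_blocks:
        high_blocks.setdefault(chrom, []).append((start, end))

    methylomes: dict[str, SampleMethylome] = {}
    true_mrs: dict[str, list[tuple[str, int, int]]] = {s: [] for s in config.sample_ids}

    for sid in config.sample_ids:
        frames = []
        group = groups[sid]
        for chrom, _length in config.genome:
            pos, ctx, strand = skeleton[chrom]
            if len(pos) == 0:
                continue
            a = np.empty(len(pos))
            b = np.empty(len(pos))
            high = _in_intervals(pos, high_blocks.get(chrom, []))
            for ci, cname in enumerate(CONTEXTS):
                for state, mask in ((STATE_LOW, ~high), (STATE_HIGH, high)):
                    m = mask & (ctx == ci)
                    params = config.state_params[(state, cname)]
                    a[m] = params.alpha
                    b[m] = params.beta
            # planted DMRs: replace the beta mean for this sample's group,
            # keeping the HIGH-state dispersion of the context
            for dmr in config.planted_dmrs:
                if dmr.chrom != chrom or group not in dmr.group_means:
                    continue
                ci = CONTEXTS.index(dmr.context)
                inside = (pos >= dmr.start) & (pos < dmr.end) & (ctx == ci)
                if not inside.any():
                    continue
                ref = config.state_params[(STATE_HIGH, dmr.context)]
                shifted = BetaBinomialParams.from_mean_dispersion(
                    min(max(dmr.group_means[group], 1e-3), 1 - 1e-3), ref.dispersion
                )
                a[inside] = shifted.alpha
                b[inside] = shifted.beta
            levels = rng.beta(a, b)
            coverage = rng.poisson(config.coverage_mean, size=len(pos)) + config.coverage_offset
            n_meth = rng.binomial(coverage, levels)
            keep = coverage > 0 if config.drop_zero_coverage else np.ones(len(pos), bool)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos[keep],
                        "strand": np.where(strand[keep] == 0, "+", "-"),
                        "context": np.array(CONTEXTS, dtype=object)[ctx[keep]],
                        "n_meth": n_meth[keep].astype(np.int64),
                        "n_total": coverage[keep].astype(np.int64),
                    }
                )
            )
        sites = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["chrom", "pos", "strand", "context", "n_meth", "n_total"])
        )
        methylomes[sid] = SampleMethylome(sid, sites)
        # truth: shared blocks plus planted intervals where this group is high
        intervals = [(chrom, s, e) for chrom, s, e in config.mr_blocks]
        for dmr in config.planted_dmrs:
            if group in dmr.high_groups():
                intervals.append((dmr.chrom, dmr.start, dmr.end))
        true_mrs[sid] = sorted(intervals)

    return SimulationResult(config, methylomes, true_mrs, list(config.planted_dmrs), groups)


# ---------------------------------------------------------------------------
# presets and cohort builders


def _tile_blocks(
    length: int, fraction: float, rng: np.random.Generator, mean_len: int = 2000
) -> list[tuple[int, int]]:
    """Place non-overlapping blocks covering ~fraction of [0, length)."""
    blocks = []
    covered = 0
    cursor = 0
    target = fraction * length
    while covered < target and cursor < length - mean_len:
        gap = int(rng.exponential(mean_len * (1 - fraction) / max(fraction, 1e-3)))
        blen = max(200, int(rng.normal(mean_len, mean_len / 4)))
        start = cursor + gap
        end = min(start + blen, length)
        if start >= length:
            break
        blocks.append((start, end))
        covered += end - start
        cursor = end + 1
    return blocks


def preset(name: str, n_samples: int = 4, seed: int = 0) -> SimulationConfig:
    """Named genome-composition presets.

    ``arabidopsis_like``: sparse methylation, ~20% of the genome in
    high-methylation blocks.  ``rice_like``: denser and more frequent
    methylation, ~33% in blocks.  Both keep the per-context mean ordering
    CG > CHG > CHH of the HIGH state.
    """
    rng = np.random.default_rng(seed)
    if name == "arabidopsis_like":
        genome = [("Chr1", 300_000)]
        fraction = 0.20
    elif name == "rice_like":
        genome = [("Chr1", 300_000)]
        fraction = 0.33
    else:
        raise ValueError(f"unknown preset {name!r}")
    blocks = []
    for chrom, length in genome:
        blocks += [(chrom, s, e) for s, e in _tile_blocks(length, fraction, rng)]
    return SimulationConfig(
        genome=genome,
        n_samples=n_samples,
        groups=["g1"] * n_samples,
        mr_blocks=blocks,
        seed=seed,
    )


def two_group_dmr_config(
    n_dmrs: int = 100,
    n_samples: int = 6,
    effect: float = 0.7,
    coverage_mean: float = 10.0,
    seed: int = 0,
    chrom_length: int | None = None,
    null: bool = False,
) -> SimulationConfig:
    """Cohort with planted two-group context-specific DMRs.

    Half the samples form each group; DMR intervals alternate contexts and
    shift the affected interval's mean from ``low = high - effect`` (group
    g2) to ``high = 0.8`` (group g1).  ``null=True`` builds the matched
    dataset with identical structure but no group effect (both groups get
    the high mean), for false-positive control experiments.
    """
    if not (0 < effect <= 0.8):
        raise ValueError("effect must lie in (0, 0.8]")
    rng = np.random.default_rng(seed)
    dmr_len = 600
    spacing = 2400
    shared_len = 1200
    n_shared = max(4, n_dmrs // 4)
    length = chrom_length or (n_dmrs + n_shared + 2) * (dmr_len + spacing)
    groups = ["g1"] * (n_samples // 2) + ["g2"] * (n_samples - n_samples // 2)

    blocks: list[tuple[str, int, int]] = []
    dmrs: list[PlantedDMR] = []
    cursor = spacing
    high, low = 0.8, 0.8 - effect
    slots = []
    for i in range(n_dmrs + n_shared):
        slots.append(cursor)
        cursor += dmr_len + spacing
    rng.shuffle(slots)
    for i in range(n_dmrs):
        start = slots[i]
        ctx = CONTEXTS[i % 3]
        means = {"g1": high, "g2": high if null else low}
        dmrs.append(PlantedDMR("Chr1", start, start + dmr_len, ctx, means))
    for i in range(n_dmrs, n_dmrs + n_shared):
        start = slots[i]
        blocks.append(("Chr1", start, start + shared_len))

    return SimulationConfig(
        genome=[("Chr1", length)],
        n_samples=n_samples,
        groups=groups,
        mr_blocks=blocks,
        planted_dmrs=dmrs,
        coverage_mean=coverage_mean,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# scoring helpers


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _total(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in intervals)


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total = 0
    j = 0
    for s, e in a:
        while j < len(b) and b[j][1] <= s:
            j += 1
        jj = j
        while jj < len(b) and b[jj][0] < e:
            total += min(e, b[jj][1]) - max(s, b[jj][0])
            jj += 1
    return total


def base_level_scores(
    called: list[tuple[str, int, int]], truth: list[tuple[str, int, int]]
) -> tuple[float, float, float]:
    """Base-level precision, recall and F1 of called intervals vs truth."""
    by_chrom_called: dict[str, list[tuple[int, int]]] = {}
    by_chrom_truth: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in called:
        by_chrom_called.setdefault(chrom, []).append((s, e))
    for chrom, s, e in truth:
        by_chrom_truth.setdefault(chrom, []).append((s, e))
    tp = 0
    called_bp = 0
    truth_bp = 0
    for chrom in set(by_chrom_called) | set(by_chrom_truth):
        c = _merge(by_chrom_called.get(chrom, []))
        t = _merge(by_chrom_truth.get(chrom, []))
        tp += _intersect(c, t)
        called_bp += _total(c)
        truth_bp += _total(t)
    precision = tp / called_bp if called_bp else 0.0
    recall = tp / truth_bp if truth_bp else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1
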