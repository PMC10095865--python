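"""Readers and writers for the tabular formats the pipeline touches.

Single-cytosine methylation tables come in several common dialects
(bismark coverage files, MethylDackel bedGraphs, and a generic counts TSV
used as the pipeline's interchange format).  All coordinates are converted
to 0-based half-open at the parse boundary and kept that way internally;
conversion back happens only when writing.

Output records (methylated regions, candidate regions, DMRs) are written as
BED6+ with deterministic formatting so identical runs produce identical
files.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")
SITE_COLUMNS = ("chrom", "pos", "strand", "context", "n_meth", "n_total")

DIALECTS = ("bismark_cov", "methyldackel_bedgraph", "counts_tsv")


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed data violates an invariant (e.g. n_meth > n_total)."""


@dataclass(frozen=True)
class CytosineSite:
    """One cytosine: coordinates, strand, sequence context and read counts.

    ``pos`` is the 0-based position of the cytosine itself.  ``n_meth`` is
    the number of reads supporting methylation (unconverted C), ``n_total``
    the total read count at the site.
    """

    chrom: str
    pos: int
    strand: str
    context: str | None
    n_meth: int
    n_total: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValidationError(f"negative position {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.context is not None and self.context not in CONTEXTS:
            raise ValidationError(f"unknown context {self.context!r}")
        if self.n_meth < 0 or self.n_total < self.n_meth:
            raise ValidationError(
                f"require 0 <= n_meth <= n_total, got {self.n_meth}/{self.n_total}"
            )


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    path: str
    group: str | None = None


@dataclass
class SampleSheet:
    """Ordered mapping of sample ids to per-sample methylation tables.

    Order is preserved and defines column order in every matrix the
    pipeline emits.  An optional group label per sample supports supervised
    (user-imposed) grouping during DMR testing.
    """

    entries: list[SampleEntry]

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if any(not i for i in ids):
            raise ValidationError("empty sample id in sample sheet")
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample ids: {', '.join(dupes)}")

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    @property
    def groups(self) -> dict[str, str] | None:
        """sample_id -> group label, or None if no labels are present."""
        if all(e.group is None for e in self.entries):
            return None
        return {e.sample_id: (e.group or e.sample_id) for e in self.entries}

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "SampleSheet":
        entries = []
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ParseError(
                        f"{path}: line {lineno}: expected at least 2 tab-separated "
                        f"columns (sample_id, path), got {len(parts)}"
                    )
                group = parts[2] if len(parts) > 2 and parts[2] else None
                entries.append(SampleEntry(parts[0], parts[1], group))
        return cls(entries)

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("#sample_id\tpath\tgroup\n")
            for e in self.entries:
                fh.write(f"{e.sample_id}\t{e.path}\t{e.group or ''}\n")


def _open_text(path):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_cytosine_table(path: str | os.PathLike, dialect: str) -> pd.DataFrame:
    """Parse a per-sample single-cytosine table into the internal frame.

    Parameters
    ----------
    path
        Input file (plain or gzipped text).
    dialect
        One of ``bismark_cov`` (1-based inclusive coordinates; columns
        chrom, start, end, %meth, count_methylated, count_unmethylated),
        ``methyldackel_bedgraph`` (0-based half-open; same trailing count
        columns) or ``counts_tsv`` (chrom, pos, strand, context, n_meth,
        n_total; 0-based).

    Returns
    -------
    pandas.DataFrame
        Columns ``chrom, pos, strand, context, n_meth, n_total`` sorted by
        (chrom, pos); zero-coverage sites are dropped.  ``df.attrs``
        carries ``unsorted_input`` (True if the file had to be re-sorted)
        and ``n_zero_coverage_dropped``.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")

    rows: list[tuple] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            try:
                if dialect == "bismark_cov":
                    chrom, start, _end, _pct, m, u = parts[:6]
                    rows.append((chrom, int(start) - 1, "+", None, int(m), int(m) + int(u)))
                elif dialect == "methyldackel_bedgraph":
                    chrom, start, _end, _pct, m, u = parts[:6]
                    rows.append((chrom, int(start), "+", None, int(m), int(m) + int(u)))
                else:  # counts_tsv
                    chrom, pos, strand, context, n_meth, n_total = parts[:6]
                    rows.append((chrom, int(pos), strand, context, int(n_meth), int(n_total)))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{os.fspath(path)}: line {lineno}: {exc}") from exc
            last = rows[-1]
            if last[4] > last[5]:
                raise ValidationError(
                    f"{os.fspath(path)}: line {lineno}: n_meth ({last[4]}) exceeds "
                    f"n_total ({last[5]})"
                )
            if last[2] not in ("+", "-"):
                raise ParseError(
                    f"{os.fspath(path)}: line {lineno}: bad strand {last[2]!r}"
                )
            if last[3] is not None and last[3] not in CONTEXTS:
                raise ParseError(
                    f"{os.fspath(path)}: line {lineno}: bad context {last[3]!r}"
                )

    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    if df.empty:
        df = pd.DataFrame(
            {
                "chrom": pd.Series(dtype=str),
                "pos": pd.Series(dtype=np.int64),
                "strand": pd.Series(dtype=str),
                "context": pd.Series(dtype=object),
                "n_meth": pd.Series(dtype=np.int64),
                "n_total": pd.Series(dtype=np.int64),
            }
        )
        df.attrs["unsorted_input"] = False
        df.attrs["n_zero_coverage_dropped"] = 0
        return df

    n_zero = int((df["n_total"] == 0).sum())
    if n_zero:
        df = df[df["n_total"] > 0].reset_index(drop=True)

    df2 = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    unsorted = not df2[["chrom", "pos"]].equals(df[["chrom", "pos"]].reset_index(drop=True))
    df = df2
    df.attrs["unsorted_input"] = unsorted
    df.attrs["n_zero_coverage_dropped"] = n_zero
    return df


def write_counts_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the internal site frame as the generic counts TSV dialect."""
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tstrand\tcontext\tn_meth\tn_total\n")
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.strand}\t{row.context}\t"
                f"{row.n_meth}\t{row.n_total}\n"
            )


# ---------------------------------------------------------------------------
# sequence-context assignment from a reference FASTA


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _classify(b1: str, b2: str) -> str | None:
    """Context from the two bases downstream of a cytosine on its strand."""
    if b1 not in _COMPLEMENT or b2 not in _COMPLEMENT:
        return None
    if b1 == "G":
        return "CG"
    if b2 == "G":
        return "CHG"
    return "CHH"


def read_context_table(fasta_path: str | os.PathLike) -> dict[tuple[str, int, str], str]:
    """Assign CG/CHG/CHH context to every cytosine in a reference FASTA.

    A C on the + strand is classified from the two bases following it; a G
    on the + strand is a cytosine on the - strand, classified from the
    reverse complement of the two bases preceding it.  Positions whose two
    downstream bases run off the chromosome end or contain N are omitted.
    """
    try:
        from pyfaidx import Fasta
    except ImportError as exc:  # pragma: no cover
        raise ImportError("pyfaidx is required for FASTA context assignment") from exc
    try:
        fasta = Fasta(os.fspath(fasta_path))
    except Exception as exc:
        raise IOError(f"cannot read FASTA {fasta_path}: {exc}") from exc

    table: dict[tuple[str, int, str], str] = {}
    for chrom in fasta.keys():
        seq = str(fasta[chrom][:]).upper()
        L = len(seq)
        for i, base in enumerate(seq):
            if base == "C" and i + 2 < L:
                ctx = _classify(seq[i + 1], seq[i + 2])
                if ctx is not None:
                    table[(chrom, i, "+")] = ctx
            elif base == "G" and i - 2 >= 0:
                ctx = _classify(_COMPLEMENT.get(seq[i - 1], "N"),
                                _COMPLEMENT.get(seq[i - 2], "N"))
                if ctx is not None:
                    table[(chrom, i, "-")] = ctx
    return table


def assign_contexts(df: pd.DataFrame, context_table: Mapping[tuple[str, int, str], str]) -> pd.DataFrame:
    """Fill the context column from a FASTA-derived table.

    An explicit context column (counts_tsv dialect) takes precedence; only
    missing contexts are looked up.  Sites absent from the table are
    dropped (they are not assignable cytosines); the count of dropped rows
    is recorded in ``df.attrs['n_context_unassigned']``.
    """
    df = df.copy()
    missing = df["context"].isna()
    if missing.any():
        keys = list(zip(df.loc[missing, "chrom"], df.loc[missing, "pos"], df.loc[missing, "strand"]))
        looked_up = [context_table.get(k) for k in keys]
        df.loc[missing, "context"] = looked_up
    unassigned = df["context"].isna()
    df.attrs["n_context_unassigned"] = int(unassigned.sum())
    return df[~unassigned].reset_index(drop=True)


# ---------------------------------------------------------------------------
# BED output


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def _check_sorted(intervals: list[tuple[str, int, int]]) -> None:
    if intervals != sorted(intervals, key=lambda r: (r[0], r[1], r[2])):
        raise ValidationError("records must be sorted by (chrom, start) before writing")


def write_mr_bed(mrs: Iterable, path: str | os.PathLike) -> None:
    """Write methylated regions of one or more samples as BED6+.

    Rows carry the sample id, the mean HIGH-state posterior, and per-context
    cytosine counts and pooled counts.  Overlapping regions within one
    sample are a contract violation (they must have been merged upstream).
    """
    mrs = list(mrs)
    _check_sorted([(m.chrom, m.start, m.end) for m in mrs])
    by_sample: dict[str, list] = {}
    for m in mrs:
        by_sample.setdefault(m.sample_id, []).append(m)
    for sid, sample_mrs in by_sample.items():
        prev_end = {}
        for m in sorted(sample_mrs, key=lambda r: (r.chrom, r.start)):
            if m.chrom in prev_end and m.start < prev_end[m.chrom]:
                raise ValidationError(f"overlapping MRs in sample {sid} on {m.chrom}")
            prev_end[m.chrom] = m.end
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tend\tsample\tmean_posterior\tstrand\t"
            + "\t".join(f"{c}_sites\t{c}_meth\t{c}_total" for c in CONTEXTS)
            + "\n"
        )
        for m in mrs:
            per_ctx = "\t".join(
                f"{m.n_sites.get(c, 0)}\t{m.sum_meth.get(c, 0)}\t{m.sum_total.get(c, 0)}"
                for c in CONTEXTS
            )
            fh.write(
                f"{m.chrom}\t{m.start}\t{m.end}\t{m.sample_id}\t"
                f"{_fmt(m.mean_posterior)}\t.\t{per_ctx}\n"
            )


def read_mr_bed(path: str | os.PathLike) -> list:
    from .hmm_segmentation import MethylatedRegion

    out = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            p = line.rstrip("\n").split("\t")
            n_sites, sum_meth, sum_total = {}, {}, {}
            for i, c in enumerate(CONTEXTS):
                n_sites[c] = int(p[6 + 3 * i])
                sum_meth[c] = int(p[7 + 3 * i])
                sum_total[c] = int(p[8 + 3 * i])
            out.append(
                MethylatedRegion(
                    sample_id=p[3], chrom=p[0], start=int(p[1]), end=int(p[2]),
                    n_sites=n_sites, sum_meth=sum_meth, sum_total=sum_total,
                    mean_posterior=float(p[4]),
                )
            )
    return out


def write_candidate_bed(candidates: Iterable, path: str | os.PathLike) -> None:
    """Candidate regions as BED4+ with the supporting-sample list and the
    per-sample per-context aggregated counts (sample:ctx:meth:total:sites)."""
    candidates = list(candidates)
    _check_sorted([(c.chrom, c.start, c.end) for c in candidates])
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tsupporting_samples\taggregates\n")
        for c in candidates:
            blobs = []
            for sid in sorted(c.aggregates):
                for ctx in CONTEXTS:
                    agg = c.aggregates[sid].get(ctx)
                    if agg is not None and agg[2] > 0:
                        blobs.append(f"{sid}:{ctx}:{agg[0]}:{agg[1]}:{agg[2]}")
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t"
                f"{','.join(c.supporting_samples) or '.'}\t{';'.join(blobs) or '.'}\n"
            )


def read_candidate_bed(path: str | os.PathLike) -> list:
    from .population_segments import CandidateRegion

    out = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            p = line.rstrip("\n").split("\t")
            aggregates: dict[str, dict[str, tuple[int, int, int]]] = {}
            if p[4] != ".":
                for blob in p[4].split(";"):
                    sid, ctx, m, t, s = blob.split(":")
                    aggregates.setdefault(sid, {})[ctx] = (int(m), int(t), int(s))
            out.append(
                CandidateRegion(
                    chrom=p[0], start=int(p[1]), end=int(p[2]),
                    supporting_samples=tuple(p[3].split(",")) if p[3] != "." else (),
                    aggregates=aggregates,
                )
            )
    return out


def write_dmr_bed(results: Iterable, path: str | os.PathLike, sample_ids: list[str]) -> None:
    """Tested candidate regions (one row per region x context) as BED6+.

    The assignment string lists each sample's cluster (1-based, clusters
    ordered by ascending mean) in sample-sheet order, '.' for samples
    ineligible in the region.
    """
    results = list(results)
    _check_sorted([(r.region.chrom, r.region.start, r.region.end) for r in results])
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tend\tcontext\tk\tassignment\tcluster_means\t"
            "max_diff\tlr_stat\tp_value\tq_value\tsignificant\n"
        )
        for r in results:
            g = r.grouping
            assign = ",".join(
                str(g.assignment[s]) if s in g.assignment else "." for s in sample_ids
            )
            means = ",".join(_fmt(m) for m in g.cluster_means)
            fh.write(
                f"{r.region.chrom}\t{r.region.start}\t{r.region.end}\t{r.context}\t"
                f"{g.k}\t{assign}\t{means}\t{_fmt(g.max_pairwise_diff)}\t"
                f"{_fmt(r.lr_stat)}\t{r.p_value:.6e}\t{r.q_value:.6e}\t"
                f"{int(r.significant)}\n"
            )


def write_frequency_bedgraph(profiles: Mapping[str, object], path: str | os.PathLike) -> None:
    """MR-frequency profile as bedGraph for genome-browser inspection."""
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="MR frequency"\n')
        for chrom in sorted(profiles):
            prof = profiles[chrom]
            for start, end, count in prof.intervals():
                fh.write(f"{chrom}\t{start}\t{end}\t{count}\n")
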