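"""End-to-end orchestration: methylomes -> models -> MRs -> candidates -> DMRs.

Each stage writes its output under the run directory in a plain-text
format that the next stage (and the user) can consume independently;
rerunning with identical inputs and configuration is byte-identical, and
every output header carries the configuration hash for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field, fields

import yaml

from . import hmm_segmentation as hmm
from . import io_formats as iof
from .dmr_testing import TestConfig, classify_dmrs, export_dmr_matrix, test_candidates
from .methylome import SampleMethylome, filter_by_coverage
from .population_segments import mr_frequency_profile, segment_candidates


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, validated at startup."""

    dialect: str = "counts_tsv"
    context_fasta: str | None = None
    min_cov: int = 1
    train_mode: str = "per_sample"
    reference_sample: str | None = None
    max_iter: int = 100
    tol: float = 1e-4
    posterior_cutoff: float = 0.5
    min_sites: int = 5
    desert_distance: int = 2000
    min_freq_change: float = 0.20
    max_segment_length: int = 10_000
    min_sites_per_segment: int = 10
    k_max: int = 3
    min_meth_diff: float = 0.20
    fdr_level: float = 0.05
    min_samples_per_cluster: int = 1
    min_cov_per_sample: int = 3
    correction: str = "BH"
    supervised: bool = False
    seed: int = 0
    explicitly_set: set = field(default_factory=set, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.dialect not in iof.DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if self.train_mode not in ("per_sample", "reference_sample"):
            raise ValueError(f"unknown train_mode {self.train_mode!r}")
        if self.min_cov < 1:
            raise ValueError("min_cov must be >= 1")
        if not (0.5 <= self.posterior_cutoff < 1.0):
            raise ValueError("posterior_cutoff must lie in [0.5, 1)")
        if not (0.0 < self.min_freq_change <= 1.0):
            raise ValueError("min_freq_change must lie in (0, 1]")
        # delegates the remaining range checks
        self.test_config()

    def test_config(self) -> TestConfig:
        return TestConfig(
            k_max=self.k_max,
            min_meth_diff=self.min_meth_diff,
            fdr_level=self.fdr_level,
            min_samples_per_cluster=self.min_samples_per_cluster,
            min_cov_per_sample=self.min_cov_per_sample,
            correction=self.correction,
        )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)} - {"explicitly_set"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        cfg = cls(**data)
        cfg.explicitly_set = set(data)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("explicitly_set", None)
        return d

    def param_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.md5(blob).hexdigest()[:12]


@dataclass
class ValidationIssue:
    severity: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue]

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def __str__(self) -> str:
        if not self.issues:
            return "validation passed"
        return "\n".join(f"[{i.severity}] {i.message}" for i in self.issues)


def validate_inputs(samplesheet_path, config: PipelineConfig) -> ValidationReport:
    """Pre-flight checks: files exist, first lines parse, ids unique,
    config ranges valid.  Issues are reported, never thrown."""
    issues: list[ValidationIssue] = []
    try:
        sheet = iof.SampleSheet.from_tsv(samplesheet_path)
    except (OSError, ValueError) as exc:
        return ValidationReport([ValidationIssue("error", f"sample sheet: {exc}")])
    if len(sheet.entries) < 2:
        issues.append(ValidationIssue("error", "need at least 2 samples for DMR calling"))
    for entry in sheet.entries:
        if not os.path.exists(entry.path):
            issues.append(ValidationIssue("error", f"{entry.sample_id}: missing file {entry.path}"))
            continue
        import itertools
        import tempfile

        tmp_path = None
        try:
            # parse only the first 100 data lines
            with iof._open_text(entry.path) as fh:
                head = "".join(itertools.islice(fh, 100))
            with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as tmp:
                tmp.write(head)
                tmp_path = tmp.name
            iof.read_cytosine_table(tmp_path, config.dialect)
        except (OSError, iof.ParseError, iof.ValidationError) as exc:
            msg = str(exc).replace(tmp_path or "", entry.path) if tmp_path else str(exc)
            issues.append(ValidationIssue("error", f"{entry.sample_id}: {msg}"))
        finally:
            if tmp_path is not None and os.path.exists(tmp_path):
                os.unlink(tmp_path)
    if config.train_mode == "reference_sample" and (
        config.reference_sample not in sheet.sample_ids
    ):
        issues.append(
            ValidationIssue(
                "error", f"reference sample {config.reference_sample!r} not in sheet"
            )
        )
    if config.supervised:
        groups = sheet.groups
        if groups is None or len(set(groups.values())) < 2:
            issues.append(
                ValidationIssue("error", "supervised testing needs >= 2 group labels")
            )
    return ValidationReport(issues)


def load_methylomes(sheet: iof.SampleSheet, config: PipelineConfig) -> dict[str, SampleMethylome]:
    context_table = None
    if config.context_fasta:
        context_table = iof.read_context_table(config.context_fasta)
    methylomes = {}
    for entry in sheet.entries:
        try:
            df = iof.read_cytosine_table(entry.path, config.dialect)
        except (iof.ParseError, iof.ValidationError) as exc:
            raise PipelineError(f"stage parse, sample {entry.sample_id}: {exc}") from exc
        if df["context"].isna().any():
            if context_table is None:
                raise PipelineError(
                    f"stage parse, sample {entry.sample_id}: dialect carries no "
                    f"context column and no context_fasta configured"
                )
            df = iof.assign_contexts(df, context_table)
        meth = SampleMethylome(entry.sample_id, df)
        if config.min_cov > 1:
            meth = filter_by_coverage(meth, config.min_cov)
        methylomes[entry.sample_id] = meth
    return methylomes


def run_pipeline(samplesheet_path, config: PipelineConfig, outdir) -> dict[str, str]:
    """Execute all stages; returns the paths of the stage outputs."""
    sheet = iof.SampleSheet.from_tsv(samplesheet_path)
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    for sub in ("models", "mrs"):
        os.makedirs(os.path.join(outdir, sub), exist_ok=True)
    phash = config.param_hash()

    methylomes = load_methylomes(sheet, config)

    # stage: training
    try:
        trained = hmm.train_models(
            methylomes,
            mode=config.train_mode,
            reference=config.reference_sample,
            desert_distance=config.desert_distance,
            max_iter=config.max_iter,
            tol=config.tol,
        )
    except (ValueError, iof.ValidationError) as exc:
        raise PipelineError(f"stage train: {exc}") from exc
    model_paths = {}
    for sid, result in trained.items():
        path = os.path.join(outdir, "models", f"{sid}.model.txt")
        result.model.to_text(path)
        model_paths[sid] = path

    # stage: segmentation
    mrs_by_sample = {}
    for sid, meth in methylomes.items():
        try:
            mrs = hmm.decode_regions(
                meth,
                trained[sid].model,
                posterior_cutoff=config.posterior_cutoff,
                min_sites=config.min_sites,
                desert_distance=config.desert_distance,
            )
        except iof.ValidationError as exc:
            raise PipelineError(f"stage segment, sample {sid}: {exc}") from exc
        mrs_by_sample[sid] = mrs
        iof.write_mr_bed(mrs, os.path.join(outdir, "mrs", f"{sid}.mr.bed"))

    # stage: candidates
    profiles = mr_frequency_profile(mrs_by_sample, n_samples=len(sheet.entries))
    candidates = segment_candidates(
        profiles,
        mrs_by_sample,
        methylomes,
        min_freq_change=config.min_freq_change,
        max_segment_length=config.max_segment_length,
        min_sites_per_segment=config.min_sites_per_segment,
    )
    cand_path = os.path.join(outdir, "candidates.bed")
    iof.write_candidate_bed(candidates, cand_path)
    iof.write_frequency_bedgraph(profiles, os.path.join(outdir, "mr_frequency.bedgraph"))

    # stage: testing
    tcfg = config.test_config()
    results = test_candidates(
        candidates, sheet, tcfg, seed=config.seed, supervised=config.supervised
    )
    dmrs = classify_dmrs(results, tcfg)
    dmr_path = os.path.join(outdir, "dmrs.bed")
    iof.write_dmr_bed(dmrs, dmr_path, sheet.sample_ids)
    matrix = export_dmr_matrix(dmrs, sheet, tcfg.min_cov_per_sample)
    matrix_path = os.path.join(outdir, "matrix.tsv")
    with open(matrix_path, "w") as fh:
        fh.write(f"# methylseg DMR x sample methylation-rate matrix (config {phash})\n")
        matrix.to_csv(fh, sep="\t", float_format="%.6g", na_rep="NA")

    # run log: full provenance, including defaults that were not set
    defaults_used = sorted(
        {f.name for f in fields(PipelineConfig)} - {"explicitly_set"} - config.explicitly_set
    )
    log_path = os.path.join(outdir, "run_log.txt")
    with open(log_path, "w") as fh:
        fh.write(f"config_hash\t{phash}\n")
        for key, value in sorted(config.to_dict().items()):
            fh.write(f"param\t{key}\t{value}\n")
        fh.write(f"defaults_not_explicitly_set\t{','.join(defaults_used)}\n")
        fh.write(f"n_samples\t{len(sheet.entries)}\n")
        for sid in sheet.sample_ids:
            fh.write(f"n_mrs\t{sid}\t{len(mrs_by_sample[sid])}\n")
        fh.write(f"n_candidates\t{len(candidates)}\n")
        fh.write(f"n_tests\t{len(results)}\n")
        fh.write(f"n_dmrs\t{len(dmrs)}\n")
        for ctx in iof.CONTEXTS:
            fh.write(f"n_dmrs_{ctx}\t{sum(1 for d in dmrs if d.context == ctx)}\n")

    return {
        "models": os.path.join(outdir, "models"),
        "mrs": os.path.join(outdir, "mrs"),
        "candidates": cand_path,
        "dmrs": dmr_path,
        "matrix": matrix_path,
        "run_log": log_path,
    }
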