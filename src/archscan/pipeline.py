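"""End-to-end orchestration: simulate/load -> align -> conserve -> segment ->
length statistics -> alanine-scan plan, with serialized configuration and a
machine-readable summary.

Every run is reproducible: all randomness flows from the single config seed,
the resolved configuration is written next to the outputs, and identical
config + seed produce byte-identical summaries.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .alignment import (
    MatchAlignment,
    build_reference_map,
    read_alignment,
    strip_insert_columns,
    write_alignment,
)
from .architecture import (
    ArchitectureTemplate,
    SegmentationParams,
    length_distribution,
    region_lengths,
    segment_regions,
)
from .conservation import (
    ConservationParams,
    call_conserved,
    conservation_profile,
    logo_matrix,
)
from .mutascan import correspondence_table, correspondence_to_frame, plan_alanine_scan, plan_to_frame
from .profiling import build_profile, paths_to_alignment
from .sequences import read_fasta
from .synthetic import (
    BlockLengths,
    ColumnClassLevel,
    LinkerJitterSampler,
    SyntheticFamilySpec,
    VariableLengthSampler,
    default_spec,
    sample_family,
)

log = logging.getLogger("archscan")


class ConfigError(ValueError):
    """Raised when a run configuration fails validation (names the key)."""


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run; every field has a default."""

    # inputs: either a synthetic spec, or an alignment, or FASTA + seed alignment
    synthetic: SyntheticFamilySpec | None = None
    input_alignment: str | None = None
    input_fasta: str | None = None
    seed_alignment: str | None = None
    align_mode: str = "auto"  # "truth" (synthetic), "profile", or "auto"

    # stage parameters
    conservation: ConservationParams = field(default_factory=ConservationParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    template: dict | None = None       # user-supplied {region: [start, end]}
    pseudocount_weight: float = 1.0
    gap_open: float = 4.0
    gap_extend: float = 0.25
    min_bits: float | None = None

    # reporting
    references: list = field(default_factory=list)  # [{"id":..., "offset":...}]
    scan_regions: tuple = ("alpha", "beta")
    variable_range: tuple = (40, 60)
    linker_range: tuple = (15, 25)
    outdir: str = "archscan_out"
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conservation"] = asdict(self.conservation)
        d["segmentation"] = asdict(self.segmentation)
        if self.synthetic is not None:
            d["synthetic"] = _spec_to_dict(self.synthetic)
        # YAML-safe containers
        d["scan_regions"] = list(self.scan_regions)
        d["variable_range"] = list(self.variable_range)
        d["linker_range"] = list(self.linker_range)
        if self.template is not None:
            d["template"] = {k: list(v) for k, v in self.template.items()}
        return d


def _spec_to_dict(spec: SyntheticFamilySpec) -> dict:
    return {
        "n_sequences": spec.n_sequences,
        "block_lengths": asdict(spec.block_lengths),
        "variable_length_sampler": asdict(spec.variable_length_sampler),
        "linker_jitter_sampler": asdict(spec.linker_jitter_sampler),
        "conservation_levels": {
            k: asdict(v) for k, v in spec.conservation_levels.items()
        },
        "invariant_sites": [
            {"column": s.column, "residue": s.residue, "identity": s.identity}
            for s in spec.invariant_sites
        ],
        "background": spec.background
        if isinstance(spec.background, str)
        else list(spec.background),
        "insert_placement": spec.insert_placement,
        "seed": spec.seed,
    }


def _spec_from_dict(d: dict) -> SyntheticFamilySpec:
    from .synthetic import InvariantSite

    kwargs = dict(d)
    if "block_lengths" in kwargs:
        kwargs["block_lengths"] = BlockLengths(**kwargs["block_lengths"])
    if "variable_length_sampler" in kwargs:
        kwargs["variable_length_sampler"] = VariableLengthSampler(
            **kwargs["variable_length_sampler"]
        )
    if "linker_jitter_sampler" in kwargs:
        kwargs["linker_jitter_sampler"] = LinkerJitterSampler(
            **kwargs["linker_jitter_sampler"]
        )
    if "conservation_levels" in kwargs:
        kwargs["conservation_levels"] = {
            k: ColumnClassLevel(**v) for k, v in kwargs["conservation_levels"].items()
        }
    if kwargs.get("invariant_sites") is not None:
        kwargs["invariant_sites"] = [InvariantSite(**s) for s in kwargs["invariant_sites"]]
    return SyntheticFamilySpec(**kwargs)


def validate_config(cfg: RunConfig | dict | None) -> RunConfig:
    """Fill defaults and range-check; idempotent on resolved configs."""
    if cfg is None:
        cfg = RunConfig()
    if isinstance(cfg, dict):
        cfg = _config_from_dict(cfg)
    try:
        cfg.conservation.validate()
    except ValueError as exc:
        raise ConfigError(f"conservation: {exc}") from exc
    try:
        cfg.segmentation.validate()
    except ValueError as exc:
        raise ConfigError(f"segmentation: {exc}") from exc
    if cfg.synthetic is not None:
        try:
            cfg.synthetic.validate()
        except ValueError as exc:
            raise ConfigError(f"synthetic: {exc}") from exc
    if cfg.align_mode not in ("auto", "truth", "profile"):
        raise ConfigError(f"align_mode: unknown mode {cfg.align_mode!r}")
    if cfg.pseudocount_weight <= 0:
        raise ConfigError("pseudocount_weight: must be positive")
    if cfg.gap_open < 0 or cfg.gap_extend < 0:
        raise ConfigError("gap_open/gap_extend: must be nonnegative")
    for rng_name in ("variable_range", "linker_range"):
        lo, hi = getattr(cfg, rng_name)
        if lo > hi or lo < 0:
            raise ConfigError(f"{rng_name}: invalid range [{lo}, {hi}]")
    if cfg.template is not None:
        spans = {k: tuple(v) for k, v in cfg.template.items()}
        try:
            ArchitectureTemplate.from_spans(spans)
        except ValueError as exc:
            raise ConfigError(f"template: {exc}") from exc
    if cfg.synthetic is None and cfg.input_alignment is None and cfg.input_fasta is None:
        # default run: synthetic family under the standard study conditions
        cfg.synthetic = default_spec(seed=cfg.seed)
    return cfg


def _config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if d.get("synthetic") is not None:
        d["synthetic"] = _spec_from_dict(d["synthetic"])
    if "conservation" in d and isinstance(d["conservation"], dict):
        d["conservation"] = ConservationParams(**d["conservation"])
    if "segmentation" in d and isinstance(d["segmentation"], dict):
        d["segmentation"] = SegmentationParams(**d["segmentation"])
    if "scan_regions" in d:
        d["scan_regions"] = tuple(d["scan_regions"])
    for key in ("variable_range", "linker_range"):
        if key in d:
            d[key] = tuple(d[key])
    return RunConfig(**d)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return validate_config(payload)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def run_pipeline(cfg: RunConfig | dict | None = None) -> dict:
    """Execute all stages and write outputs to ``cfg.outdir``.

    Returns the run summary (also written as ``summary.json``).  Outputs:
    aligned.sto, conservation.tsv, logo.tsv, architecture.tsv,
    lengths.tsv, distributions.json, scan.tsv, correspondence.tsv,
    resolved_config.yaml, summary.json.
    """
    cfg = validate_config(cfg)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(cfg, outdir / "resolved_config.yaml")
    summary: dict = {"seed": cfg.seed, "stages": []}

    def stage(name):
        log.info("stage %s", name)
        summary["stages"].append(name)
        return time.time()

    # -- obtain an alignment --------------------------------------------------
    truth = None
    if cfg.synthetic is not None:
        t0 = stage("simulate")
        spec = cfg.synthetic
        sequences, truth = sample_family(spec)
        log.info("simulated %d sequences in %.2fs", len(sequences), time.time() - t0)
        mode = "truth" if cfg.align_mode == "auto" else cfg.align_mode
        if mode == "truth":
            aln = truth.true_alignment
        else:
            t0 = stage("align")
            n_seed = min(50, len(sequences))
            seed_aln = MatchAlignment(
                truth.true_alignment.ids[:n_seed],
                truth.true_alignment.rows[:n_seed],
                truth.true_alignment.col_is_match,
            )
            profile = build_profile(
                seed_aln, cfg.pseudocount_weight, cfg.conservation.background,
                cfg.gap_open, cfg.gap_extend,
            )
            aln = paths_to_alignment(profile, sequences)
            log.info("aligned %d sequences in %.2fs", len(sequences), time.time() - t0)
    elif cfg.input_alignment is not None:
        stage("read_alignment")
        aln = read_alignment(cfg.input_alignment)
    else:
        t0 = stage("align")
        if cfg.seed_alignment is None:
            raise ConfigError("seed_alignment: required to align input_fasta")
        seed_aln = read_alignment(cfg.seed_alignment)
        profile = build_profile(
            seed_aln, cfg.pseudocount_weight, cfg.conservation.background,
            cfg.gap_open, cfg.gap_extend,
        )
        sequences = read_fasta(cfg.input_fasta)
        if cfg.min_bits is not None:
            from .profiling import score_filter

            retained = score_filter(profile, sequences, cfg.min_bits)
            summary["score_filter"] = {
                "input": len(sequences),
                "retained": len(retained),
                "min_bits": cfg.min_bits,
            }
            sequences = [r.sequence for r in retained]
            paths = [r.path for r in retained]
            aln = paths_to_alignment(profile, sequences, paths)
        else:
            aln = paths_to_alignment(profile, sequences)
        log.info("aligned %d sequences in %.2fs", len(sequences), time.time() - t0)

    write_alignment(aln, outdir / "aligned.sto")
    stripped = strip_insert_columns(aln)
    summary["n_sequences"] = aln.n_rows
    summary["n_match_columns"] = stripped.n_match_columns

    # -- conservation ----------------------------------------------------------
    stage("conserve")
    cp = conservation_profile(aln, cfg.conservation)
    cp.write_tsv(outdir / "conservation.tsv")
    logo_matrix(cp).to_csv(outdir / "logo.tsv", sep="\t", float_format="%.6g")

    # -- architecture ----------------------------------------------------------
    stage("segment")
    if cfg.template is not None:
        template = ArchitectureTemplate.from_spans(
            {k: tuple(v) for k, v in cfg.template.items()}
        )
        summary["template_provenance"] = "user-supplied"
    else:
        template = segment_regions(cp, cfg.segmentation)
        summary["template_provenance"] = "inferred"
    template.write_tsv(outdir / "architecture.tsv")
    summary["template"] = {r.name: [r.start, r.end] for r in template.regions}

    conserved = call_conserved(cp)
    dimer = set()
    for name in ("alpha", "linker", "beta"):
        dimer.update(template.columns_of(name))
    summary["conserved_columns"] = conserved
    summary["n_conserved"] = len(conserved)
    summary["n_conserved_dimerization"] = len([c for c in conserved if c in dimer])

    # -- length statistics -----------------------------------------------------
    stage("stats")
    records = region_lengths(stripped, template)
    records.to_csv(outdir / "lengths.tsv", sep="\t", index=False)
    dists = {}
    for region, rng in (("variable", cfg.variable_range), ("linker", cfg.linker_range)):
        dist, mass = length_distribution(records, region, range_of_interest=rng)
        dists[region] = {
            "edges": dist.edges.tolist(),
            "counts": dist.counts.tolist(),
            "percentages": dist.percentages.tolist(),
            "range": [mass.lo, mass.hi],
            "fraction_in_range": mass.fraction,
            "percent_in_range": mass.percent,
        }
        summary[f"{region}_percent_in_range"] = mass.percent
        summary[f"{region}_fraction_in_range"] = mass.fraction
    (outdir / "distributions.json").write_text(json.dumps(dists, indent=1, sort_keys=True))

    # -- scan plan & correspondence -------------------------------------------
    references = list(cfg.references)
    if not references and cfg.synthetic is not None:
        references = [{"id": stripped.ids[0], "offset": 1}]
    maps = []
    for ref in references:
        stage(f"reference_map:{ref['id']}")
        maps.append(
            build_reference_map(stripped, ref["id"], ref.get("offset", 1))
        )
    if maps:
        stage("scan")
        plan = plan_alanine_scan(
            cp, maps[0], template, tuple(cfg.scan_regions), cfg.conservation.bits_threshold
        )
        plan_to_frame(plan).to_csv(outdir / "scan.tsv", sep="\t", index=False)
        summary["scan_reference"] = maps[0].reference_id
        summary["scan_candidates"] = [c.residue_number for c in plan]
        summary["n_scan_candidates"] = len(plan)
        cols = sorted({c.column for c in plan})
        if cols:
            rows = correspondence_table(maps, cols)
            correspondence_to_frame(rows).to_csv(
                outdir / "correspondence.tsv", sep="\t", index=False
            )

    if truth is not None:
        summary["true_template"] = {
            r.name: [r.start, r.end] for r in truth.template.regions
        }

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
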