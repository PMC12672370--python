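"""End-to-end orchestration of the spatiotemporal analysis.

Runs decomposition -> temporal GAMs -> hormone associations -> mass-wise
TFCE inference on a set of session stacks with day-aligned hormone series,
writing all result tables and a run log.  Deterministic given the
configuration seed; rerunning with identical inputs and config reproduces
byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .association import associate_all
from .decomposition import SpatioTemporalSVD, threshold_spatial
from .gam import fdr_adjust, fit_gam
from .hormones import HormoneSeries
from .io import (
    StudyManifest,
    write_assoc_tsv,
    write_components_tsv,
    write_gam_tsv,
    write_scores_tsv,
    write_spatial_maps,
)
from .phantom import SessionStack
from .tfce import MasswiseGlmTfce

__all__ = ["RunConfig", "PipelineReport", "run_full_pipeline", "run_from_manifest"]


@dataclass
class RunConfig:
    """All pipeline defaults in one place (YAML round-trippable)."""

    centering: str = "per_individual"
    min_fraction: float = 0.095
    gam_k: int = 10
    fdr_alpha: float = 0.05
    gm_cutoff: float = 0.1
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    tfce_steps: int = 100
    n_perm: int = 1000
    fwe_alpha: float = 0.01
    seed: int = 0
    masswise_predictors: tuple[str, ...] = ("estradiol", "progesterone", "ratio")
    run_masswise: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if isinstance(cfg.masswise_predictors, list):
            cfg.masswise_predictors = tuple(cfg.masswise_predictors)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineReport:
    """In-memory bundle of everything the pipeline computed."""

    decomposition: SpatioTemporalSVD
    gam_fits: list
    associations: list
    masswise: dict = field(default_factory=dict)
    config: RunConfig = field(default_factory=RunConfig)


def _check_alignment(stacks, hormones) -> dict[str, HormoneSeries]:
    by_id = {h.individual_id: h for h in hormones}
    problems = []
    for s in stacks:
        if s.individual_id not in by_id:
            problems.append(f"no hormone series for {s.individual_id!r}")
            continue
        h = by_id[s.individual_id]
        if not np.array_equal(h.day, s.days):
            problems.append(
                f"individual {s.individual_id!r}: stack days "
                f"{s.days.tolist()} != hormone days {h.day.tolist()}"
            )
    if problems:
        raise ValueError("input validation failed:\n- " + "\n- ".join(problems))
    return by_id


def run_full_pipeline(
    stacks: list[SessionStack],
    hormones: list[HormoneSeries],
    config: RunConfig | None = None,
    out_dir: str | None = None,
    measure: str = "volume",
) -> PipelineReport:
    """Execute the full analysis on in-memory inputs.

    Validation failures abort before any computation, listing all problems.
    When ``out_dir`` is given, writes components / scores / GAM / association
    TSVs, spatial maps and a YAML run log with the config hash.
    """
    config = config or RunConfig()
    _check_alignment(stacks, hormones)

    svd = SpatioTemporalSVD(
        centering=config.centering, min_fraction=config.min_fraction
    ).fit(stacks)

    days_by_id = {s.individual_id: s.days for s in stacks}
    gam_fits = []
    for pattern in svd.retained_:
        for ind, sl in svd.blocks_:
            gam_fits.append(
                fit_gam(
                    days_by_id[ind],
                    pattern.temporal_std[sl],
                    k=config.gam_k,
                    individual_id=ind,
                    component=pattern.index,
                )
            )
    for p_adj, f in zip(fdr_adjust([f.p_value for f in gam_fits]), gam_fits):
        f.p_fdr = float(p_adj)

    scores = {
        ind: {
            p.index: p.temporal_std[sl] for p in svd.retained_
        }
        for ind, sl in svd.blocks_
    }
    associations = associate_all(scores, hormones, alpha=config.fdr_alpha)

    masswise = {}
    if config.run_masswise:
        for predictor in config.masswise_predictors:
            est = MasswiseGlmTfce(
                predictor=predictor,
                gm_cutoff=config.gm_cutoff if measure == "volume" else None,
                n_perm=config.n_perm,
                alpha=config.fwe_alpha,
                E=config.tfce_E,
                H=config.tfce_H,
                n_steps=config.tfce_steps,
                seed=config.seed,
            ).fit(stacks, hormones)
            masswise[predictor] = est

    report = PipelineReport(
        decomposition=svd,
        gam_fits=gam_fits,
        associations=associations,
        masswise=masswise,
        config=config,
    )
    if out_dir is not None:
        _write_outputs(report, stacks, days_by_id, out_dir, measure)
    return report


def _write_outputs(report, stacks, days_by_id, out_dir, measure) -> None:
    os.makedirs(out_dir, exist_ok=True)
    svd = report.decomposition
    write_components_tsv(svd.patterns_, os.path.join(out_dir, "components.tsv"))
    write_scores_tsv(
        svd.retained_, svd.blocks_, days_by_id, os.path.join(out_dir, "scores.tsv")
    )
    write_gam_tsv(
        report.gam_fits,
        os.path.join(out_dir, f"gam_{measure}.tsv"),
        alpha=report.config.fdr_alpha,
    )
    write_assoc_tsv(
        report.associations,
        os.path.join(out_dir, f"associations_{measure}.tsv"),
        measure=measure,
    )
    write_spatial_maps(
        svd.retained_,
        stacks[0].geometry,
        os.path.join(out_dir, "maps"),
        thresholder=threshold_spatial,
    )
    log = {
        "config": asdict(report.config),
        "config_hash": report.config.config_hash(),
        "individuals": [s.individual_id for s in stacks],
        "n_sessions": [int(s.n_sessions) for s in stacks],
        "n_retained": len(svd.retained_),
    }
    with open(os.path.join(out_dir, "run_log.yaml"), "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)


def run_from_manifest(
    manifest: StudyManifest | str,
    config: RunConfig | None = None,
    out_dir: str | None = None,
    exclusions: list[tuple[str, int]] | None = None,
) -> PipelineReport:
    """Load a study manifest, optionally exclude sessions, run the pipeline."""
    if not isinstance(manifest, StudyManifest):
        manifest = StudyManifest.load(manifest)
    if exclusions:
        manifest = manifest.exclude_sessions(exclusions)
    stacks, hormones = manifest.load_data()
    measure = "volume" if manifest.measure == "volume" else "thickness"
    return run_full_pipeline(stacks, hormones, config, out_dir, measure)
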