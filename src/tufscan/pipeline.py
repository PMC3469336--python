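"""End-to-end pipeline: simulate -> content -> correct -> detect ->
associate -> advise, with reproducible seeding and a run manifest.

One global seed is fanned out to per-stage sub-streams through
``numpy.random.SeedSequence(seed).spawn``, so a stage rerun in isolation with
its own sub-seed reproduces its output. All tabular outputs are TSV with a
provenance header comment; identical config + seed gives byte-identical
outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .content import RestrictionEnzyme, build_content_matrix
from .correction import (
    WaveCorrector,
    classify_extreme_samples,
    models_to_tsv,
    quantile_normalize,
    variance_report,
)
from .detection import (
    annotate_susceptibility,
    detect_weak_regions,
    estimate_nick_rate,
    infer_copy_number,
    suppression_profile,
    weak_regions_to_bed,
)
from .fragmentation import advise_digest, rank_treatments, sonication_verdict
from .intervals import GenomicInterval, write_bed
from .prt import table2_report, write_table2_tsv
from .simulate import SimulationConfig, simulate_study

__all__ = ["RunManifest", "run_pipeline", "PipelineError"]

log = logging.getLogger("tufscan")

#: Enzymes used for the demonstration digest advice on the synthetic genome.
DEFAULT_ENZYMES = (
    RestrictionEnzyme("NcoI", "CCATGG", 1),
    RestrictionEnzyme("EcoRI", "GAATTC", 1),
    RestrictionEnzyme("AluI", "AGCT", 2),
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seed, outputs, stage status."""

    config: dict
    seed: int
    version: str = __version__
    outputs: dict = field(default_factory=dict)
    status: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)

    def register(self, stage: str, paths) -> None:
        self.outputs[stage] = [str(p) for p in paths]
        self.status[stage] = "ok"
        for p in paths:
            self.checksums[str(p)] = hashlib.sha256(Path(p).read_bytes()).hexdigest()

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _provenance_header(stage: str, seed: int) -> str:
    return f"# tufscan {__version__} | stage={stage} | seed={seed}\n"


def _write_tsv(df: pd.DataFrame, path, stage: str, seed: int, index=True) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(stage, seed))
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(
    config, outdir, seed: Optional[int] = None
) -> RunManifest:
    """Execute every stage in dependency order; see module docstring.

    ``config`` is a :class:`SimulationConfig`, a mapping, or a YAML path.
    Association is skipped with a notice when fewer than 4 samples exist.
    On stage failure a FAILED marker naming the stage is left in ``outdir``
    and a :class:`PipelineError` is raised; earlier outputs are retained.
    """
    if isinstance(config, (str, Path)):
        config = SimulationConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = SimulationConfig.from_dict(config)
    if seed is None:
        seed = config.seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=int(seed))
    stage = "simulate"
    try:
        # -- simulate ----------------------------------------------------
        log.info("stage=simulate seed=%d", seed)
        study = simulate_study(config, seed=seed)
        truth = study["truth"]
        fa = outdir / "genome.fa"
        with open(fa, "w") as fh:
            fh.write(f">{config.chrom}\n")
            seq = study["sequence"]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
        man_tsv = outdir / "manifest.tsv"
        study["manifest"].to_tsv(man_tsv)
        el_bed = outdir / "elements.bed"
        write_bed(
            el_bed,
            [e.interval for e in study["elements"]],
            scores=[round(1000 * e.gc_fraction) for e in study["elements"]],
        )
        lrr_tsv = outdir / "intensity.tsv"
        study["intensity"].to_tsv(lrr_tsv)
        truth_tsv = outdir / "truth_samples.tsv"
        _write_tsv(truth.samples, truth_tsv, "simulate", seed, index=False)
        dist_tsv = outdir / "truth_distances.tsv"
        _write_tsv(truth.distances.to_frame(), dist_tsv, "simulate", seed)
        prt_tsv = outdir / "prt.tsv"
        _write_tsv(study["prt"], prt_tsv, "simulate", seed, index=False)
        manifest.register(
            "simulate", [fa, man_tsv, el_bed, lrr_tsv, truth_tsv, dist_tsv, prt_tsv]
        )

        # -- content -----------------------------------------------------
        stage = "content"
        log.info("stage=content windows=%s", list(config.window_sizes))
        content = study["content"]
        content_tsv = outdir / "content.tsv"
        content.to_tsv(content_tsv)
        manifest.register("content", [content_tsv])

        # -- correct -----------------------------------------------------
        stage = "correct"
        raw = study["intensity"].lrr
        # quantile normalization needs a cohort; a lone sample passes through
        lrr_qn = quantile_normalize(raw) if len(raw) >= 2 else raw
        corrector = WaveCorrector(
            content, strata=study["intensity"].strata, degree=2
        ).fit(lrr_qn)
        corrected = corrector.transform(lrr_qn)
        var_tsv = outdir / "variance_report.tsv"
        _write_tsv(variance_report(corrector.models_), var_tsv, "correct", seed, index=False)
        models_tsv = outdir / "models.tsv"
        models_to_tsv(corrector.models_, models_tsv)
        labels = classify_extreme_samples(corrector.models_)
        labels_tsv = outdir / "labels.tsv"
        _write_tsv(labels, labels_tsv, "correct", seed, index=False)
        corrected_tsv = outdir / "corrected_lrr.tsv"
        _write_tsv(corrected.T, corrected_tsv, "correct", seed)
        manifest.register("correct", [var_tsv, models_tsv, labels_tsv, corrected_tsv])

        # -- detect ------------------------------------------------------
        stage = "detect"
        calls = infer_copy_number(study["intensity"].lrr)
        affected = labels.loc[labels["label"] != "null", "sample_id"].tolist()
        regions = (
            detect_weak_regions(calls, study["manifest"], affected)
            if len(affected) >= 2
            else []
        )
        regions_bed = outdir / "weak_regions.bed"
        weak_regions_to_bed(regions, regions_bed)
        annotation = annotate_susceptibility(
            study["manifest"], study["elements"], config.d_max
        )
        ann_tsv = outdir / "susceptibility.tsv"
        _write_tsv(annotation, ann_tsv, "detect", seed)
        nick_rows = []
        for sid in corrected.index:
            prof = suppression_profile(corrected.loc[sid], annotation)
            try:
                fit = estimate_nick_rate(
                    prof["delta"], prof["distance"], d_max=config.d_max
                )
                nick_rows.append(
                    {
                        "sample_id": sid,
                        "amplitude": fit.amplitude,
                        "rate": fit.rate,
                        "amplitude_se": fit.amplitude_se,
                        "rate_se": fit.rate_se,
                    }
                )
            except (ValueError, RuntimeError) as err:
                nick_rows.append(
                    {"sample_id": sid, "amplitude": np.nan, "rate": np.nan,
                     "amplitude_se": np.nan, "rate_se": np.nan}
                )
                log.warning("nick-rate fit failed for %s: %s", sid, err)
        nick_tsv = outdir / "nick_rates.tsv"
        _write_tsv(pd.DataFrame(nick_rows), nick_tsv, "detect", seed, index=False)
        manifest.register("detect", [regions_bed, ann_tsv, nick_tsv])

        # -- associate ---------------------------------------------------
        stage = "associate"
        if config.n_samples < 4:
            log.warning("associate skipped: fewer than 4 samples")
            manifest.status["associate"] = "skipped: fewer than 4 samples"
        else:
            report = table2_report(corrector.models_, study["prt"])
            table2_tsv = outdir / "association.tsv"
            with open(table2_tsv, "w") as fh:
                fh.write(_provenance_header("associate", seed))
                flat = report.copy()
                flat.columns = [f"{m}_{t}" for m, t in flat.columns]
                flat.to_csv(fh, sep="\t")
            manifest.register("associate", [table2_tsv])

        # -- advise ------------------------------------------------------
        stage = "advise"
        el = study["elements"][0]
        # demonstration target: a short amplicon ~1 kb upstream of element 1
        t_end = el.interval.start - config.prt_distance
        t_start = max(1, t_end - 700)
        verdicts = []
        if t_end > t_start:
            target = GenomicInterval(config.chrom, t_start, t_end, "demo_target")
            verdicts = advise_digest(
                target,
                study["elements"],
                list(DEFAULT_ENZYMES),
                study["sequence"],
                amplitude=config.suppression_amplitude["positive"],
                nick_rate=config.nick_rate["positive"],
                r_eq=config.r_eq,
                d_max=config.d_max,
            )
            verdicts.append(
                sonication_verdict(
                    "sonication_500bp", 500.0, config.prt_distance,
                    amplitude=config.suppression_amplitude["positive"],
                    nick_rate=config.nick_rate["positive"],
                    r_eq=config.r_eq,
                )
            )
        advice_tsv = outdir / "advice.tsv"
        _write_tsv(
            rank_treatments(verdicts) if verdicts else pd.DataFrame(),
            advice_tsv, "advise", seed, index=False,
        )
        manifest.register("advise", [advice_tsv])
    except Exception as err:  # noqa: BLE001 - stage failure is surfaced
        (outdir / "FAILED").write_text(f"stage={stage}\nerror={err}\n")
        manifest.status[stage] = f"failed: {err}"
        manifest.to_json(outdir / "run_manifest.json")
        raise PipelineError(stage, err) from err

    manifest.to_json(outdir / "run_manifest.json")
    return manifest
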