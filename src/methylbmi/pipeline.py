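"""Reproducible pipeline orchestration.

``run_pipeline`` executes the stages simulate -> preprocess -> fit ->
predict -> deconv -> characterize -> scores in dependency order, writing
every output into a run directory and recording a manifest (per-stage
parameters, output files, sha256 checksums). One global seed is fanned out
to per-stage seeds by hashing the stage name, so each stage is individually
reproducible and a rerun with the same config yields identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .characterize import (correlate_features_with_score,
                           correlate_methylation_expression, records_to_frame,
                           summarize_predictor_distribution)
from .deconv import estimate_adipose_fraction, select_discriminating_probes
from .model import DMBMI, DMBMIModel
from .preprocess import adjust_batches, filter_probes, knn_impute
from .scores import associate_scores, build_score_table
from .synth import SynthConfig, simulate_cohort, simulate_reference_profiles, \
    write_cohort
from .transform import TraitTransform

ALL_STAGES = ("simulate", "preprocess", "fit", "predict", "deconv",
              "characterize", "scores")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Stage toggles, stage parameters, seed, and I/O paths."""

    outdir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # simulate
    n_samples: int = 221
    n_probes: int = 5000
    n_causal: int = 30
    n_discriminating: int = 50
    ref_delta: float = 0.75
    effect_scale: float = 0.2
    noise_sd: float = 0.02
    missing_rate: float = 0.02
    n_batches: int = 2
    batch_shift_sd: float = 0.01
    adipose_coupling: float = 0.8
    # stage parameters (pipeline defaults)
    missing_threshold: float = 0.5
    knn_k: int = 10
    cv_folds: int = 10
    deconv_threshold: float = 0.7
    flag_threshold: float = 0.3
    exome_mb: float = 38.0
    healthy_bmi: float = 25.0
    bmi_col: str = "bmi"
    batch_col: str = "batch"
    # external inputs (used when simulate is disabled)
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return zlib.crc32(f"{seed}:{stage}".encode()) & 0x7FFFFFFF


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = set(config.stages)
    manifest: dict = {"seed": config.seed, "stages": {}, "error": None}
    paths = dict(config.inputs)  # logical name -> path

    def record(stage: str, params: dict, outputs: dict[str, Path]) -> None:
        manifest["stages"][stage] = {
            "params": params,
            "outputs": {name: {"path": str(p), "sha256": _sha256(Path(p))}
                        for name, p in outputs.items()},
        }

    def require(stage: str, *names: str) -> list[Path]:
        got = []
        for name in names:
            if name not in paths or not Path(paths[name]).exists():
                raise PipelineError(stage, f"missing required input {name!r}")
            got.append(Path(paths[name]))
        return got

    try:
        if "simulate" in enabled:
            sseed = stage_seed(config.seed, "simulate")
            refs = simulate_reference_profiles(config.n_probes,
                                               config.n_discriminating,
                                               config.ref_delta, seed=sseed)
            cohort = simulate_cohort(SynthConfig(
                n_samples=config.n_samples, n_probes=config.n_probes,
                n_causal=config.n_causal, effect_scale=config.effect_scale,
                noise_sd=config.noise_sd, missing_rate=config.missing_rate,
                n_batches=config.n_batches,
                batch_shift_sd=config.batch_shift_sd,
                adipose_coupling=config.adipose_coupling, seed=sseed), refs)
            written = write_cohort(cohort, refs, outdir / "cohort")
            for name, p in written.items():
                paths[name.replace(".tsv", "").replace(".json", "")] = p
            record("simulate", {"seed": sseed,
                                "n_samples": config.n_samples,
                                "n_probes": config.n_probes,
                                "n_causal": config.n_causal}, written)

        if "preprocess" in enabled:
            bpath, apath, cpath = require("preprocess", "beta", "annotation",
                                          "clinical")
            beta = mio.read_beta_tsv(bpath)
            ann = mio.read_annotation_tsv(apath)
            clinical = mio.read_clinical_tsv(cpath).set_index("sample_id")
            beta = filter_probes(beta, ann, config.missing_threshold)
            beta = knn_impute(beta, k=config.knn_k)
            batches = clinical.loc[beta.sample_ids, config.batch_col].to_numpy()
            beta = adjust_batches(beta, batches)
            out = outdir / "beta_clean.tsv"
            mio.write_beta_tsv(beta, out)
            paths["beta_clean"] = out
            record("preprocess", {"missing_threshold": config.missing_threshold,
                                  "knn_k": config.knn_k},
                   {"beta_clean.tsv": out})

        if "fit" in enabled:
            bpath, cpath = require("fit", "beta_clean", "clinical")
            beta = mio.read_beta_tsv(bpath)
            clinical = mio.read_clinical_tsv(cpath)
            res = DMBMI.from_dataframe(
                beta.to_frame(), clinical, bmi_col=config.bmi_col,
                transform=TraitTransform(config.healthy_bmi),
            ).fit(cv_folds=config.cv_folds,
                  seed=stage_seed(config.seed, "fit"))
            out = outdir / "model.json"
            out.write_text(res.model.to_json())
            paths["model"] = out
            (outdir / "fit_summary.txt").write_text(res.summary())
            record("fit", {"cv_folds": config.cv_folds,
                           "healthy_bmi": config.healthy_bmi,
                           "seed": stage_seed(config.seed, "fit"),
                           "lambda_selected": res.model.lambda_selected,
                           "n_selected": len(res.model.coefficients)},
                   {"model.json": out,
                    "fit_summary.txt": outdir / "fit_summary.txt"})

        if "predict" in enabled:
            mpath, bpath = require("predict", "model", "beta_clean")
            model = DMBMIModel.from_json(Path(mpath).read_text())
            beta = mio.read_beta_tsv(bpath)
            pred = model.predict(beta)
            out = outdir / "dmbmi.tsv"
            pd.DataFrame({"sample_id": beta.sample_ids,
                          "dm_bmi": pred}).to_csv(out, sep="\t", index=False)
            paths["dmbmi"] = out
            record("predict", {}, {"dmbmi.tsv": out})

        if "deconv" in enabled:
            rpath, bpath = require("deconv", "references", "beta_clean")
            refs = mio.read_references_tsv(rpath)
            beta = mio.read_beta_tsv(bpath)
            basis = select_discriminating_probes(refs, config.deconv_threshold)
            basis = [p for p in basis if p in set(beta.probe_ids)]
            if not basis:
                raise PipelineError("deconv", "no basis probe survived QC")
            result = estimate_adipose_fraction(beta, refs, basis)
            out = outdir / "adipose_fraction.tsv"
            result.to_frame().to_csv(out, sep="\t", index=False)
            paths["adipose_fraction"] = out
            record("deconv", {"threshold": config.deconv_threshold,
                              "n_basis": len(basis)},
                   {"adipose_fraction.tsv": out})

        if "characterize" in enabled:
            mpath, apath, bpath, dpath, epath = require(
                "characterize", "model", "annotation", "beta_clean", "dmbmi",
                "expression")
            model = DMBMIModel.from_json(Path(mpath).read_text())
            ann = mio.read_annotation_tsv(apath)
            beta = mio.read_beta_tsv(bpath)
            dmbmi = mio.read_dmbmi_tsv(dpath).loc[beta.sample_ids]
            expr = mio.read_expression_tsv(epath)

            outputs = {}
            dist = summarize_predictor_distribution(model, ann)
            dist_path = outdir / "predictor_distribution.json"
            dist_path.write_text(json.dumps(
                {axis: dist[axis].to_dict(orient="records")
                 for axis in dist.tables}, indent=2))
            outputs["predictor_distribution.json"] = dist_path

            if model.support:
                sub = beta.subset_probes(model.support)
                corr = correlate_features_with_score(
                    sub.to_frame(), dmbmi.to_numpy(),
                    flag_threshold=config.flag_threshold)
                corr_path = outdir / "predictor_dmbmi_correlation.tsv"
                records_to_frame(corr).to_csv(corr_path, sep="\t", index=False)
                outputs["predictor_dmbmi_correlation.tsv"] = corr_path

                mapping = dict(zip(ann.table["probe_id"], ann.table["gene"]))
                mapping = {p: g for p, g in mapping.items() if g}
                me_records, skipped = correlate_methylation_expression(
                    sub, expr, mapping)
                me_path = outdir / "methylation_expression_correlation.tsv"
                records_to_frame(me_records).to_csv(me_path, sep="\t",
                                                    index=False)
                outputs["methylation_expression_correlation.tsv"] = me_path
            record("characterize", {"flag_threshold": config.flag_threshold},
                   outputs)

        if "scores" in enabled:
            epath, mpath, dpath = require("scores", "expression", "mutations",
                                          "dmbmi")
            expr = mio.read_expression_tsv(epath)
            mutations = mio.read_mutations_tsv(mpath)
            dmbmi = mio.read_dmbmi_tsv(dpath)
            external = None
            if "external" in paths and Path(paths["external"]).exists():
                external = mio.read_scores_tsv(paths["external"])
            table, meta = build_score_table(expr=expr, mutations=mutations,
                                            external=external,
                                            exome_mb=config.exome_mb)
            table_path = outdir / "score_table.tsv"
            table.to_csv(table_path, sep="\t")
            records = associate_scores(dmbmi, table)
            assoc_path = outdir / "score_associations.tsv"
            records_to_frame(records).to_csv(assoc_path, sep="\t", index=False)
            meta_path = outdir / "score_metadata.json"
            meta_path.write_text(json.dumps(meta, indent=2))
            record("scores", {"exome_mb": config.exome_mb},
                   {"score_table.tsv": table_path,
                    "score_associations.tsv": assoc_path,
                    "score_metadata.json": meta_path})

    except PipelineError as err:
        manifest["error"] = str(err)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         sort_keys=True))
        raise
    except Exception as err:  # annotate with the running stage
        stage = next((s for s in ALL_STAGES
                      if s in enabled and s not in manifest["stages"]), "?")
        manifest["error"] = f"stage {stage!r}: {err}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         sort_keys=True))
        raise PipelineError(stage, str(err)) from err

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
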