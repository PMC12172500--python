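"""Pipeline orchestration: simulate -> diversity -> age -> classify -> misch.

A run is driven by a plain config mapping (usually loaded from YAML) with
a master seed.  Every artifact is a TSV or JSON file stamped with the
master seed and a hash of the config, so any output can be re-derived
from the config alone; two runs with the same config and seed produce
byte-identical data files.  Timings live only in ``run_report.json``.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import replace
from pathlib import Path

import pandas as pd

from . import data_model as dm
from . import diversity as dv
from . import microbial_age as ma
from . import misch as mi
from . import stage_classifier as sc
from . import synthetic as syn
from ._seeds import child_int

__all__ = ["PipelineError", "run_pipeline", "config_hash", "DEFAULT_STAGES"]

DEFAULT_STAGES = ["simulate", "diversity", "age", "classify", "misch"]

_DEPENDENCIES = {
    "diversity": set(),
    "age": set(),
    "classify": set(),
    "misch": {"classify"},
}


class PipelineError(RuntimeError):
    """A stage failed or the config is invalid."""


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _validate(config: dict) -> list[str]:
    stages = list(config.get("stages", DEFAULT_STAGES))
    unknown = [s for s in stages if s not in DEFAULT_STAGES]
    if unknown:
        raise PipelineError(f"unknown stages: {unknown}")
    has_inputs = "inputs" in config
    has_sim = "simulate" in stages
    if has_inputs and has_sim:
        raise PipelineError("config must give either input paths or a simulate stage, not both")
    if not has_inputs and not has_sim:
        raise PipelineError("config needs input paths or a simulate stage")
    for stage in stages:
        missing = _DEPENDENCIES.get(stage, set()) - set(stages)
        if missing:
            raise PipelineError(
                f"stage {stage!r} requires {sorted(missing)} in the stage list"
            )
    return stages


def _write_tsv(df: pd.DataFrame, path: Path, stamp: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {stamp}\n")
        df.to_csv(fh, sep="\t", lineterminator="\n")


def _write_json(obj, path: Path, stamp_fields: dict) -> None:
    payload = {**stamp_fields, **obj} if isinstance(obj, dict) else obj
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the requested stages; returns the run report.

    Raises :class:`PipelineError` on invalid configs or stage failure.
    """
    stages = _validate(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed")
    chash = config_hash(config)
    stamp = f"misch-kit seed={seed} config={chash}"
    stamp_fields = {"seed": seed, "config_hash": chash}
    artifacts: list[str] = []
    timings: dict[str, float] = {}

    def record(path: Path):
        artifacts.append(str(path.name))

    try:
        # ---------------- cohort ----------------
        t0 = time.perf_counter()
        if "simulate" in stages:
            sim_opts = dict(config.get("simulate") or {})
            cfg = syn.default_config()
            if "n_subjects" in sim_opts:
                cfg = replace(cfg, n_subjects=dict(sim_opts["n_subjects"]))
            for key in ("rho", "concentration", "depth", "region_effect"):
                if key in sim_opts:
                    cfg = replace(cfg, **{key: sim_opts[key]})
            bact, fungi, meta = syn.simulate_cohort(cfg, seed=child_int(seed, "sim"))
            lineages = syn.default_lineages(cfg)
            dm.write_abundance_table(bact, outdir / "bacteria.tsv", header=stamp)
            dm.write_abundance_table(fungi, outdir / "fungi.tsv", header=stamp)
            dm.write_metadata(meta, outdir / "metadata.tsv", header=stamp)
            dm.write_lineages(lineages, outdir / "lineages.tsv")
            for name in ("bacteria.tsv", "fungi.tsv", "metadata.tsv", "lineages.tsv"):
                artifacts.append(name)
        else:
            paths = config["inputs"]
            bact = dm.read_abundance_table(paths["bacteria"], "bacteria")
            fungi = dm.read_abundance_table(paths["fungi"], "fungi")
            meta = dm.read_metadata(paths["metadata"])
        violations = dm.validate_cohort([bact, fungi], meta)
        if violations:
            raise PipelineError(f"cohort validation failed: {violations[:3]}")
        merged = dm.merge_kingdoms(bact, fungi)
        timings["cohort"] = time.perf_counter() - t0

        # ---------------- diversity ----------------
        if "diversity" in stages:
            t0 = time.perf_counter()
            opts = dict(config.get("diversity") or {})
            n_perm = int(opts.get("permutations", 999))
            factors = list(opts.get("factors", ["stage", "region", "age"]))
            alpha = pd.DataFrame(
                {
                    "shannon_bacteria": dv.alpha_diversity(bact, "shannon"),
                    "shannon_fungi": dv.alpha_diversity(fungi, "shannon"),
                    "simpson_bacteria": dv.alpha_diversity(bact, "simpson"),
                    "simpson_fungi": dv.alpha_diversity(fungi, "simpson"),
                }
            )
            _write_tsv(alpha, outdir / "alpha_diversity.tsv", stamp)
            record(outdir / "alpha_diversity.tsv")
            distance = dv.jsd_matrix(merged)
            _write_tsv(distance.to_frame(), outdir / "jsd_distance.tsv", stamp)
            record(outdir / "jsd_distance.tsv")
            ordination = dv.pcoa(distance, k=2)
            _write_tsv(ordination.coordinates, outdir / "pcoa.tsv", stamp)
            record(outdir / "pcoa.tsv")
            effects = dv.factor_effect_sizes(
                distance, meta, factors, n_perm, seed=child_int(seed, "permanova")
            )
            anova = dv.alpha_factor_anova(alpha["shannon_bacteria"], meta, factors)
            _write_json(
                {
                    "permanova": [r.as_dict() for r in effects],
                    "alpha_anova": anova.reset_index().to_dict("records"),
                },
                outdir / "effect_sizes.json",
                stamp_fields,
            )
            record(outdir / "effect_sizes.json")
            timings["diversity"] = time.perf_counter() - t0

        # ---------------- microbial age ----------------
        if "age" in stages:
            t0 = time.perf_counter()
            opts = dict(config.get("age") or {})
            healthy_ids = meta.samples_of_stage("Healthy")
            model = ma.train_age_model(
                merged.subset(healthy_ids),
                meta,
                n_iterations=int(opts.get("iterations", 10)),
                subsample=float(opts.get("subsample", 0.9)),
                folds=int(opts.get("folds", 10)),
                seed=child_int(seed, "age"),
                n_estimators=int(opts.get("n_estimators", ma.DEFAULT_TREES)),
                k_max=opts.get("k_max"),
            )
            predictions = ma.predict_microbial_age(model, merged)
            curve = ma.age_curve(predictions, meta)
            _write_tsv(predictions.to_frame(), outdir / "microbial_age.tsv", stamp)
            _write_tsv(curve.set_index("group"), outdir / "age_curve.tsv", stamp)
            _write_json(
                {
                    "selected_taxa": model.selected,
                    "cv_curve": model.cv_curve.to_dict("records"),
                    "slopes": ma.age_curve_slopes(curve),
                },
                outdir / "age_model.json",
                stamp_fields,
            )
            for name in ("microbial_age.tsv", "age_curve.tsv", "age_model.json"):
                artifacts.append(name)
            timings["age"] = time.perf_counter() - t0

        # ---------------- classifier ----------------
        params = None
        if "classify" in stages:
            t0 = time.perf_counter()
            opts = dict(config.get("classify") or {})
            params = opts.get("params")
            report = sc.repeated_evaluation(
                merged,
                meta,
                n_repeats=int(opts.get("repeats", 10)),
                train_fraction=float(opts.get("train_fraction", 0.7)),
                seed=child_int(seed, "classify"),
                params=params,
            )
            _write_json(
                {
                    "means": report.means,
                    "per_repeat": report.per_repeat.to_dict("records"),
                    "n_repeats": report.n_repeats,
                    "train_fraction": report.train_fraction,
                },
                outdir / "classifier_evaluation.json",
                stamp_fields,
            )
            record(outdir / "classifier_evaluation.json")
            timings["classify"] = time.perf_counter() - t0

        # ---------------- MiSCH ----------------
        if "misch" in stages:
            t0 = time.perf_counter()
            opts = dict(config.get("misch") or {})
            result = mi.compute_misch(
                merged,
                meta,
                n_repeats=int(opts.get("repeats", 20)),
                train_fraction=float(opts.get("train_fraction", 0.7)),
                seed=child_int(seed, "misch"),
                params=params,
                isotonic=bool(opts.get("isotonic", False)),
            )
            per_sample, _ = mi.flag_table(result.scores, meta)
            per_sample = pd.concat([result.probabilities, per_sample], axis=1)
            _write_tsv(per_sample, outdir / "misch_samples.tsv", stamp)
            subj = mi.subject_scores(result.scores, meta).to_frame()
            subj.index.name = "subject_id"
            _write_tsv(subj, outdir / "misch_subjects.tsv", stamp)
            _write_json(
                {
                    "distances": result.weights.distances.to_dict(),
                    "weights": result.weights.weights.to_dict(),
                    "n_probability_repeats": result.n_probability_repeats,
                },
                outdir / "misch_weights.json",
                stamp_fields,
            )
            f_stat, p = mi.score_association_anova(
                result.scores, meta.df["stage"]
            )
            flagged = [f.sample_id for f in result.flags if f.flag]
            _write_json(
                {
                    "anova_F": f_stat,
                    "anova_p": p,
                    "n_flagged": len(flagged),
                    "flagged": flagged,
                },
                outdir / "misch_report.json",
                stamp_fields,
            )
            for name in (
                "misch_samples.tsv",
                "misch_subjects.tsv",
                "misch_weights.json",
                "misch_report.json",
            ):
                artifacts.append(name)
            timings["misch"] = time.perf_counter() - t0
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive wrap
        raise PipelineError(f"stage failure: {exc}") from exc

    report = {
        "seed": seed,
        "config_hash": chash,
        "stages": stages,
        "artifacts": artifacts,
        "timings": timings,
    }
    _write_json(report, outdir / "run_report.json", {})
    return report
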