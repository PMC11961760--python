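"""End-to-end driver: simulate -> continuity correction -> longitudinal
mapping -> lattice geometry, with a machine-readable JSON report.

The global seed deterministically derives per-stage seeds, so identical
configurations yield byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np

from ciliaxis import core_model, lattice_geometry, longitudinal_mapping, synthetic_data
from ciliaxis import trajectory_ransac
from ciliaxis.core_model import RegionSpec, group_into_filaments, write_particle_table
from ciliaxis.synthetic_data import BarrelSpec, LatticeSpec, NoiseSpec, TransitionSpec
from ciliaxis.trajectory_ransac import RansacConfig

__all__ = ["PipelineConfig", "run_pipeline", "percentage_check"]

logger = logging.getLogger("ciliaxis")


def percentage_check(count_known: int, share_known: float, count_query: int) -> float:
    """Percentage of a dataset represented by ``count_query``, inferred from a
    sibling class's printed count and share.

    The dataset total is ``count_known / share_known``; the result is
    ``100 * count_query / total`` rounded to one decimal (matching typical
    reporting precision).
    """
    if not 0.0 < share_known <= 1.0:
        raise ValueError(f"share_known must be in (0, 1], got {share_known}")
    if count_known <= 0 or count_query < 0:
        raise ValueError("counts must be positive (known) / non-negative (query)")
    total = count_known / share_known
    return round(100.0 * count_query / total, 1)


@dataclass
class PipelineConfig:
    """All stage specs plus the global seed.

    ``regions`` and ``transitions`` are parallel lists: transition ``i`` is
    applied to records whose ground-truth position falls in region ``i``.
    Stage seeds are derived deterministically from ``seed``.
    """

    barrel: BarrelSpec = field(default_factory=BarrelSpec)
    noise: NoiseSpec = field(default_factory=lambda: NoiseSpec(
        pose_sigma_nm=1.0, outlier_fraction=0.1, outlier_min_offset_nm=15.0))
    ransac: RansacConfig = field(default_factory=RansacConfig)
    regions: list[RegionSpec] = field(default_factory=lambda: [
        RegionSpec.proximal(), RegionSpec.core()])
    transitions: list[TransitionSpec] = field(default_factory=lambda: [
        TransitionSpec("class1", "class2", center_nm=130.0),
        TransitionSpec("core_pre", "core_post", center_nm=170.0),
    ])
    lattice: LatticeSpec | None = field(
        default_factory=lambda: LatticeSpec.uniform_tube(13))
    occupancy_periods_nm: list[float] = field(default_factory=lambda: [8.0, 16.0, 48.0])
    occupancy_noise_p: float = 0.0
    step_nm: float = 12.0
    n_permutations: int = 199
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if len(self.regions) != len(self.transitions):
            raise ValueError("regions and transitions must pair up one-to-one")

    def stage_seeds(self) -> dict[str, int]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ["barrel", "noise", "labels", "ransac"]
        return {name: int(c.generate_state(1)[0]) for name, c in zip(names, children)}

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        kwargs: dict[str, Any] = {}
        if "barrel" in data:
            kwargs["barrel"] = BarrelSpec(**data["barrel"])
        if "noise" in data:
            kwargs["noise"] = NoiseSpec(**data["noise"])
        if "ransac" in data:
            kwargs["ransac"] = RansacConfig(**data["ransac"])
        if "regions" in data:
            kwargs["regions"] = [RegionSpec(**r) for r in data["regions"]]
        if "transitions" in data:
            kwargs["transitions"] = [TransitionSpec(**t) for t in data["transitions"]]
        if "lattice" in data:
            kwargs["lattice"] = LatticeSpec(**data["lattice"]) if data["lattice"] else None
        for key in ("occupancy_periods_nm", "occupancy_noise_p", "step_nm",
                    "n_permutations", "seed", "log_level"):
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        return _jsonify(dataclasses.asdict(self))


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute all stages on synthetic data and write tables plus report.json.

    On a stage failure the report marks the stage ``failed`` and later stages
    are ``skipped``; the report is always written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    seeds = config.stage_seeds()
    report: dict[str, Any] = {"config": config.to_dict(), "stages": {}}
    state: dict[str, Any] = {}

    stage_fns = [
        ("simulate", _stage_simulate),
        ("ransac", _stage_ransac),
        ("map", _stage_map),
        ("geometry", _stage_geometry),
    ]
    failed = False
    for name, fn in stage_fns:
        if failed:
            report["stages"][name] = {"status": "skipped"}
            continue
        logger.info("stage %s: effective seed %s", name, seeds.get(name))
        try:
            metrics = fn(config, seeds, state, outdir)
            report["stages"][name] = {"status": "ok", **_jsonify(metrics)}
        except Exception as exc:  # noqa: BLE001 - reported, not swallowed silently
            logger.exception("stage %s failed", name)
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            failed = True

    (outdir / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=2) + "\n")
    return report


def _stage_simulate(config: PipelineConfig, seeds: dict[str, int],
                    state: dict[str, Any], outdir: Path) -> dict[str, Any]:
    barrel = replace(config.barrel, seed=seeds["barrel"])
    truth = synthetic_data.generate_segment_table(barrel, step_nm=config.step_nm)

    labeled = list(truth)
    for i, (region, transition) in enumerate(zip(config.regions, config.transitions)):
        in_region = [k for k, rec in enumerate(labeled)
                     if region.contains(rec.longitudinal_s)]
        sub = synthetic_data.assign_class_labels(
            [labeled[k] for k in in_region], region, transition,
            seed=seeds["labels"] + i)
        for k, rec in zip(in_region, sub):
            labeled[k] = rec

    noise = replace(config.noise, seed=seeds["noise"])
    observed, truth_mask = synthetic_data.corrupt_segments(labeled, noise)
    state["truth"] = labeled
    state["observed"] = observed
    state["truth_mask"] = truth_mask
    write_particle_table(labeled, outdir / "truth_table.csv")
    write_particle_table(observed, outdir / "observed_table.csv")
    return {
        "n_segments": len(observed),
        "n_filaments": config.barrel.n_filaments,
        "n_planted_outliers": int(truth_mask.sum()),
    }


def _stage_ransac(config: PipelineConfig, seeds: dict[str, int],
                  state: dict[str, Any], outdir: Path) -> dict[str, Any]:
    observed = state["observed"]
    truth_mask = state["truth_mask"]
    truth = state["truth"]
    filaments = group_into_filaments(observed, step_nm=config.step_nm)
    row_of = {(r.organelle_id, r.filament_id, r.segment_index): i
              for i, r in enumerate(observed)}
    truth_center = {(r.organelle_id, r.filament_id, r.segment_index): r.center
                    for r in truth}

    fits = []
    qc_rows = []
    predicted = np.zeros(len(observed), dtype=bool)
    scored = np.zeros(len(observed), dtype=bool)
    corrected_records = []
    corr_sq_err = []
    for i, fil in enumerate(filaments):
        cfg = replace(config.ransac, seed=seeds["ransac"] + i)
        fit = trajectory_ransac.fit_trajectory_ransac(fil, cfg)
        fit = trajectory_ransac.correct_or_discard(fit, cfg)
        fits.append(fit)
        n_out = (0 if fit.inlier_mask is None
                 else int(len(fit.inlier_mask) - fit.inlier_mask.sum()))
        qc_rows.append({
            "organelle_id": fil.organelle_id,
            "filament_id": fil.filament_id,
            "verdict": fit.verdict,
            "reason": fit.reason or "",
            "n_segments": len(fil),
            "n_outliers": n_out,
            "max_residual_nm": (float(np.max(fit.residuals_nm))
                                if fit.residuals_nm is not None else float("nan")),
        })
        if fit.inlier_mask is not None and fit.verdict != "discarded":
            for k, seg in enumerate(fil.segments):
                key = (seg.organelle_id, seg.filament_id, seg.segment_index)
                predicted[row_of[key]] = not fit.inlier_mask[k]
                scored[row_of[key]] = True
        if fit.corrected is not None:
            corrected_records.extend(fit.corrected)
            for seg in fit.corrected:
                key = (seg.organelle_id, seg.filament_id, seg.segment_index)
                corr_sq_err.append(float(np.sum((seg.center - truth_center[key]) ** 2)))

    precision, recall, f1 = trajectory_ransac.score_outlier_detection(
        predicted[scored], truth_mask[scored])
    import pandas as pd
    pd.DataFrame(qc_rows).to_csv(outdir / "ransac_qc.csv", index=False)
    write_particle_table(corrected_records, outdir / "corrected_table.csv")
    state["fits"] = fits
    verdicts = [f.verdict for f in fits]
    return {
        "outlier_precision": precision,
        "outlier_recall": recall,
        "outlier_f1": f1,
        "n_kept_all": verdicts.count("kept_all"),
        "n_corrected": verdicts.count("corrected"),
        "n_discarded": verdicts.count("discarded"),
        "corrected_rms_error_nm": (float(np.sqrt(np.mean(corr_sq_err)))
                                   if corr_sq_err else 0.0),
    }


def _stage_map(config: PipelineConfig, seeds: dict[str, int],
               state: dict[str, Any], outdir: Path) -> dict[str, Any]:
    import pandas as pd

    mapped = []
    for fit in state["fits"]:
        if fit.verdict == "discarded":
            continue
        mapped.extend(longitudinal_mapping.attach_arc_length(fit))
    state["mapped"] = mapped

    hist_rows = []
    estimates: dict[str, dict[str, Any]] = {}
    for region in config.regions:
        hists = longitudinal_mapping.bin_class_counts(mapped, region)
        estimates[region.name] = {}
        for hist in hists:
            est = longitudinal_mapping.weighted_average_position(hist)
            estimates[region.name][hist.class_name] = {
                "L_index": est.L_index, "L_nm": est.L_nm, "n": est.n}
            centers = region.bin_centers_nm
            for j, (count, center) in enumerate(zip(hist.counts, centers), start=1):
                hist_rows.append({"region": region.name, "class": hist.class_name,
                                  "bin_index": j, "bin_center_nm": float(center),
                                  "count": int(count)})
    pd.DataFrame(hist_rows).to_csv(outdir / "histograms.csv", index=False)

    maps = longitudinal_mapping.organelle_class_map(mapped, config.regions)
    if maps:
        pd.concat([m.to_frame() for m in maps]).to_csv(outdir / "maps.csv", index=False)

    coop = []
    target = config.transitions[0].class_b if config.transitions else None
    if target is not None:
        by_fil: dict[str, list] = {}
        for rec in sorted(mapped, key=lambda r: (r.filament_id, r.segment_index)):
            by_fil.setdefault(rec.filament_id, []).append(rec.class_label)
        for fid, labels in sorted(by_fil.items()):
            labels = [lab for lab in labels if lab is not None]
            if len(labels) < 5:
                continue
            res = longitudinal_mapping.run_length_cooperativity(
                labels, target, n_permutations=config.n_permutations,
                seed=seeds["labels"])
            coop.append({"filament_id": fid, "target_class": target,
                         "max_run": res.max_run, "mean_run": res.mean_run,
                         "p_value": res.p_value, "note": res.note})
    return {
        "n_mapped_segments": len(mapped),
        "transition_estimates": estimates,
        "cooperativity": coop,
        "region_class_fractions": {m.organelle_id: m.region_class_fractions
                                   for m in maps},
    }


def _stage_geometry(config: PipelineConfig, seeds: dict[str, int],
                    state: dict[str, Any], outdir: Path) -> dict[str, Any]:
    import pandas as pd

    metrics: dict[str, Any] = {}
    if config.lattice is not None:
        models = synthetic_data.generate_pf_lattice(config.lattice)
        core_model.write_point_model(models, outdir / "lattice_models.csv")
        rows = []
        n = len(models)
        n_junctions = n if config.lattice.closed else n - 1
        for k in range(n_junctions):
            a, b = models[k], models[(k + 1) % n]
            angle = lattice_geometry.inter_pf_angle(a, b)
            rows.append({"junction": f"{b.label}/{a.label}",
                         "generated_deg": config.lattice.inter_pf_angles_deg[k],
                         "measured_deg": angle})
        pd.DataFrame(rows).to_csv(outdir / "inter_pf_angles.csv", index=False)
        metrics["inter_pf_angles"] = rows
        if config.lattice.closed:
            metrics["angle_sum_deg"] = float(sum(r["measured_deg"] for r in rows))

    period_calls = []
    for i, p in enumerate(config.occupancy_periods_nm):
        track = synthetic_data.generate_mip_occupancy(
            config.barrel.length_nm, period_nm=p,
            noise_p=config.occupancy_noise_p, seed=seeds["labels"] + 100 + i)
        result = lattice_geometry.detect_periodicity(track)
        period_calls.append({"true_period_nm": p,
                             "detected_period_nm": result.best_period_nm,
                             "phase": result.phase,
                             "score": result.scores[result.best_period_nm]})
    metrics["periodicity"] = period_calls
    return metrics
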