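"""End-to-end study orchestration.

Runs the 2D chain (simulate → segment → population statistics → OVL →
regression) and the 3D chain (simulate volumes → internal-architecture
metrics → class/profile aggregation) over a declarative configuration.
Every stage derives its random stream from one root seed, so a run is
fully re-derivable from config + seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import micro3d, popstats, regress, segment2d, synthgen

logger = logging.getLogger(__name__)


def condition_index_string(spore_conc: float, agitation: float, talc: float, baffled: bool) -> str:
    """Format a condition as the study's index string, e.g. ``S6-AH-T0-B1``.

    S encodes the spore-titre exponent (5×10^k spores mL⁻¹ → Sk), A the
    shaking frequency (L = 150 rpm, H = 250 rpm), T the talc concentration
    in g L⁻¹ and B the baffle flag.
    """
    exponent = round(math.log10(spore_conc / 5.0))
    if agitation == 150:
        a = "L"
    elif agitation == 250:
        a = "H"
    else:
        a = f"{agitation:g}"
    t = f"{talc:g}"
    return f"S{exponent}-A{a}-T{t}-B{int(bool(baffled))}"


@dataclass
class RunConfig:
    """Configuration of a synthetic 2D study run."""

    conditions: list[tuple[float, float, float, bool]]  # (spore, rpm, talc, baffled)
    replicates: int = 3
    seed: int = 0
    pixel_size: float | None = None  # µm per px; None = calibrate per condition
    n_pellets: int = 60
    spread: float = 0.25
    spore_sensitivity: float = 0.15  # ln-diameter decrease per ln spore above 5e6
    images_per_replicate: int = 2  # the protocol images each sample twice
    noise_spec: tuple[int, int] = (20, 3)
    touching_fraction: float = 0.1
    border_fraction: float = 0.05
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["conditions"] = [tuple(c) for c in raw["conditions"]]
        return cls(**raw)


def calibrated_pixel_size(median_um: float) -> float:
    """Pixel calibration for a condition, as chosen at the microscope.

    The magnification is picked so a median pellet spans roughly 40 px,
    keeping the smallest analysable pellets (100 µm) well above the
    10 px-radius opening element while bounding image size for the largest
    populations.
    """
    return float(np.clip(median_um / 40.0, 2.5, 12.0))


def score_detections(
    population: segment2d.PelletPopulation,
    truth: synthgen.SceneGroundTruth,
    pixel_size: float,
    d_min: float = segment2d.D_MIN_UM,
    d_max: float = segment2d.D_MAX_UM,
) -> dict:
    """Match detected pellets to rendered ground truth by nearest centroid.

    Ground-truth pellets that are border-clipped or outside the analysed
    diameter range are not expected to be detected. Returns precision,
    recall and the relative ED errors of the matched pairs.
    """
    from scipy.spatial import cKDTree

    expected = (
        (truth.true_diameters >= d_min)
        & (truth.true_diameters <= d_max)
        & (~truth.border_flags)
    )
    exp_idx = np.flatnonzero(expected)
    detections = np.array([r.centroid for r in population.records]).reshape(-1, 2)
    if len(exp_idx) == 0:
        return {"tp": 0, "fp": len(detections), "fn": 0,
                "precision": float("nan") if len(detections) else 1.0,
                "recall": 1.0, "ed_errors": np.empty(0)}
    tree = cKDTree(truth.true_centroids[exp_idx])
    matched: dict[int, int] = {}
    fp = 0
    errors = []
    for k, rec in enumerate(population.records):
        dist, j = tree.query(detections[k])
        gt = exp_idx[int(j)]
        tol = truth.true_diameters[gt] / (2.0 * pixel_size) * 0.75
        if dist <= tol and gt not in matched:
            matched[gt] = k
            td = truth.true_diameters[gt]
            errors.append(abs(rec.equivalent_diameter_um - td) / td)
        else:
            fp += 1
    tp = len(matched)
    fn = len(exp_idx) - tp
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "precision": tp / (tp + fp) if tp + fp else 1.0,
        "recall": tp / (tp + fn) if tp + fn else 1.0,
        "ed_errors": np.asarray(errors),
    }


def expected_median_um(config: RunConfig, spore: float, agitation: float, talc: float) -> float:
    """Condition-dependent true median used by the study generator.

    The reduced prediction model sets the agitation/talc dependence; a
    mild ln-linear spore term emulates the observed diameter decrease with
    spore titre. Clamped to the analysable 130–3000 µm window.
    """
    b0, b_a, b_t = synthgen.PREDICTION_COEFFICIENTS
    ln_pd = (
        b0
        + b_a * math.log(agitation)
        + b_t * talc
        - config.spore_sensitivity * (math.log(spore) - math.log(5e6))
    )
    return float(np.clip(math.exp(ln_pd), 130.0, 3000.0))


def run_2d_study(config: RunConfig) -> dict:
    """Simulate, segment and summarise the full 2D study.

    Returns a report with per-replicate summaries, per-condition OVL
    matrices, the regression table, and full + backward-eliminated model
    fits. Per-condition failures are recorded and do not abort the run.
    """
    root = np.random.SeedSequence(config.seed)
    summary_rows = []
    ovl_by_condition: dict[str, popstats.ReplicateOVL] = {}
    failures: dict[str, str] = {}

    for ci, (spore, agitation, talc, baffled) in enumerate(config.conditions):
        index = condition_index_string(spore, agitation, talc, baffled)
        cond_seq = np.random.SeedSequence([config.seed, ci])
        try:
            median = expected_median_um(config, spore, agitation, talc)
            pixel_size = config.pixel_size or calibrated_pixel_size(median)
            spec = synthgen.PopulationSpec(
                components=((1.0, median, config.spread),),
                n_pellets=config.n_pellets,
            )
            replicate_diams = []
            rep_seqs = cond_seq.spawn(config.replicates)
            for rep in range(config.replicates):
                child = rep_seqs[rep].generate_state(1 + config.images_per_replicate)
                samples = []
                for img_i in range(config.images_per_replicate):
                    img_seed = int(child[img_i] % (2**31))
                    diam = synthgen.gen_population_diameters(spec, seed=img_seed)
                    rgb, _ = synthgen.render_micrograph(
                        diam,
                        pixel_size=pixel_size,
                        noise_spec=config.noise_spec,
                        touching_fraction=config.touching_fraction,
                        border_fraction=config.border_fraction,
                        seed=img_seed,
                    )
                    samples.append(
                        segment2d.ImageSample(
                            rgb=rgb,
                            pixel_size=pixel_size,
                            sample_id=f"{index}-r{rep + 1}-i{img_i + 1}",
                        )
                    )
                population = segment2d.run_replicate(samples, replicate_id=f"{index}-r{rep + 1}")
                diams = population.diameters
                replicate_diams.append(diams)
                s = popstats.summarize(diams)
                summary_rows.append(
                    {
                        "condition": index,
                        "spore_conc": spore,
                        "agitation_rpm": agitation,
                        "talc_g_per_l": talc,
                        "baffled": baffled,
                        "replicate_id": f"r{rep + 1}",
                        "median_ed_um": s.median_ed,
                        "iqr_um": s.iqr,
                        "n_pellets": s.n,
                        "excluded": s.excluded,
                        "modality": s.modality_flag,
                    }
                )
            if len(replicate_diams) >= 2:
                ovl_by_condition[index] = popstats.ovl_replicates(replicate_diams)
        except Exception as exc:  # record and continue
            logger.exception("condition %s failed", index)
            failures[index] = str(exc)

    summaries = pd.DataFrame(summary_rows)
    report: dict = {
        "replicate_summaries": summaries,
        "ovl": ovl_by_condition,
        "failures": failures,
        "model_full": None,
        "model_reduced": None,
    }
    try:
        table = summaries.rename(columns={})[
            ["spore_conc", "agitation_rpm", "talc_g_per_l", "baffled",
             "replicate_id", "median_ed_um", "n_pellets", "modality"]
        ]
        dataset = regress.build_dataset(table)
        # constant columns (a study subset may not vary every parameter)
        # cannot enter the design
        predictors = tuple(
            p for p in regress.FULL_PREDICTORS
            if dataset.frame[p].nunique() > 1
        )
        if not predictors:
            raise ValueError("no cultivation parameter varies across conditions")
        report["model_full"] = regress.fit_ols(dataset, predictors)
        report["model_reduced"] = regress.eliminate_nonsignificant(dataset, predictors=predictors)
    except ValueError as exc:
        failures["regression"] = str(exc)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summaries.to_csv(out / "replicate_summaries.csv", index=False)
        for index, ovl in ovl_by_condition.items():
            pd.DataFrame(ovl.pairwise).to_csv(out / f"ovl_{index}.csv", index=False)
        if report["model_full"] is not None:
            (out / "model_full.json").write_text(
                json.dumps(regress.model_summary_dict(report["model_full"]), indent=2)
            )
            (out / "model_reduced.json").write_text(
                json.dumps(regress.model_summary_dict(report["model_reduced"]), indent=2)
            )
        (out / "run_report.json").write_text(
            json.dumps({"failures": failures,
                        "mean_ovl": {k: v.mean_ovl for k, v in ovl_by_condition.items()},
                        "seed": config.seed}, indent=2)
        )
    return report


@dataclass
class Run3DConfig:
    """Configuration of a synthetic 3D study run."""

    volumes: list[dict] = field(default_factory=list)  # kwargs per gen_pellet_volume
    seed: int = 0
    voxel_size: float = 2.0
    eps_um: float | None = None
    out_dir: str | None = None


def run_3d_study(config: Run3DConfig) -> dict:
    """Generate/analyse a batch of 3D pellets and aggregate the results.

    Aggregates class counts and the per-shell mean ± SD solid-fraction
    profile across pellets; failed volumes are recorded under ``failures``
    and do not abort the batch.
    """
    rows = []
    profiles = []
    failures: dict[int, str] = {}
    root = np.random.SeedSequence(config.seed)
    seeds = [int(s % (2**31)) for s in root.generate_state(max(len(config.volumes), 1))]
    for i, spec in enumerate(config.volumes):
        try:
            kwargs = dict(spec)
            fused = kwargs.pop("fused", False)
            kwargs.setdefault("voxel_size", config.voxel_size)
            if fused:
                vol, truth = synthgen.gen_fused_pellet_volume(seed=seeds[i], **kwargs)
            else:
                vol, truth = synthgen.gen_pellet_volume(seed=seeds[i], **kwargs)
            metrics = micro3d.analyse_volume(vol, eps=config.eps_um)
            profile = metrics.pop("_profile")
            metrics.update({"volume_index": i, "true_n_cores": truth.n_cores,
                            "true_class": truth.class_label})
            rows.append(metrics)
            profiles.append(profile)
        except Exception as exc:
            logger.exception("volume %d failed", i)
            failures[i] = str(exc)

    metrics_df = pd.DataFrame(rows)
    class_counts = (
        metrics_df["pellet_class"].value_counts().to_dict() if len(metrics_df) else {}
    )
    profile_table = aggregate_profiles(profiles)
    report = {
        "metrics": metrics_df,
        "class_counts": class_counts,
        "profile_table": profile_table,
        "failures": failures,
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics_df.to_csv(out / "pellet_metrics.csv", index=False)
        profile_table.to_csv(out / "radial_profiles.csv", index=False)
        (out / "run_report.json").write_text(
            json.dumps({"class_counts": class_counts, "failures": failures,
                        "seed": config.seed}, indent=2)
        )
    return report


def aggregate_profiles(profiles: list[micro3d.RadialProfile]) -> pd.DataFrame:
    """Per-shell mean ± SD of solid fraction across pellets.

    Shells are aligned by their inner radius; pellets that do not extend to
    a given shell simply do not contribute to it.
    """
    if not profiles:
        return pd.DataFrame(columns=["shell_inner_um", "shell_outer_um",
                                     "mean_solid_fraction", "sd_solid_fraction", "n_pellets"])
    rows = []
    max_shells = max(len(p.solid_fraction) for p in profiles)
    ref = max(profiles, key=lambda p: len(p.solid_fraction))
    for s in range(max_shells):
        vals = [p.solid_fraction[s] for p in profiles if len(p.solid_fraction) > s]
        rows.append(
            {
                "shell_inner_um": ref.shell_bounds[s],
                "shell_outer_um": ref.shell_bounds[s + 1],
                "mean_solid_fraction": float(np.mean(vals)),
                "sd_solid_fraction": float(np.std(vals)),
                "n_pellets": len(vals),
            }
        )
    return pd.DataFrame(rows)
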