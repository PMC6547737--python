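"""Configuration-driven pipeline tying the analysis stages together.

A :class:`PipelineConfig` (constructible from a YAML mapping) selects which
stages run — forces, mutual information, prediction, degrees of freedom,
entropy, coactivation, localization, game — with the parameters that matter
for each. ``run_pipeline`` executes the enabled stages in dependency order on
a simulated subject and writes per-stage CSV/JSON artifacts plus one
machine-readable ``summary.json`` echoing every resolved parameter.
``compare_hands`` applies the study's statistical conventions (six-fingered
minus five-fingered) to two summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dimensionality, entropy, forces, independence, stats, synthetic
from .errors import ConfigError

log = logging.getLogger("polyhand")

_STAGES = ("forces", "mi", "prediction", "dof", "entropy", "coactivation",
           "localization", "game")


@dataclass
class PipelineConfig:
    """Parameters of one pipeline run (simulation-driven)."""

    preset: str = "six_finger"  # "five_finger" | "six_finger"
    seed: int = 0
    output_dir: str = "results/pipeline"
    stages: tuple[str, ...] = _STAGES
    duration_s: float = synthetic.DEFAULT_DURATION_S
    mu_factor: float = entropy.DEFAULT_MU_FACTOR
    percentiles: tuple[int, ...] = entropy.PERCENTILES
    folds: int = dimensionality.DEFAULT_FOLDS
    trim_s: float = dimensionality.DEFAULT_TRIM_S
    dof_downsample: int = 20  # decimation factor before CV-PCA (120 -> 6 Hz)
    dof_kmax: int = 12
    prediction_method: str = "linear"
    n_boot: int = 10_000
    localization_error_sd_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.preset not in ("five_finger", "six_finger"):
            raise ConfigError(f"unknown preset '{self.preset}'")
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s) {sorted(unknown)}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed must be an integer")
        if not 0 <= self.mu_factor:
            raise ConfigError("mu_factor must be >= 0")

    @classmethod
    def from_dict(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        mapping = dict(mapping)
        for key in ("stages", "percentiles"):
            if key in mapping:
                mapping[key] = tuple(mapping[key])
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            mapping = yaml.safe_load(fh) or {}
        if not isinstance(mapping, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(mapping)


def _spec_for(config: PipelineConfig) -> synthetic.HandModelSpec:
    factory = (synthetic.six_finger_spec if config.preset == "six_finger"
               else synthetic.five_finger_spec)
    return factory(seed=config.seed, duration_s=config.duration_s)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; return (and write) the summary mapping."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("run in progress\n")

    summary: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    rec, truth = synthetic.simulate_hand(_spec_for(config))
    log.info("simulated %s hand: %d fingers, %d samples",
             config.preset, rec.n_fingers, rec.n_samples)

    timings: dict[str, float] = {}
    try:
        for stage in config.stages:
            t0 = time.perf_counter()
            summary["stages"][stage] = _run_stage(stage, config, rec, truth, out)
            timings[stage] = round(time.perf_counter() - t0, 3)
            log.info("stage %-12s done in %.2f s", stage, timings[stage])
    except Exception as exc:
        log.error("stage failed: %s", exc)
        raise
    summary["timings_s"] = timings

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    marker.unlink()
    return summary


def _run_stage(stage, config, rec, truth, out: Path) -> dict:
    import pandas as pd

    seed = config.seed
    if stage == "forces":
        fingers = rec.fingers
        fspec = synthetic.ForceModelSpec(fingers=fingers, seed=seed)
        session = synthetic.simulate_force_session(fspec)
        mf = forces.maximal_force(session)
        ens = forces.enslaving_matrix(session, mf, level="MF")
        pd.DataFrame(ens.values, index=fingers, columns=fingers).to_csv(
            out / "enslaving_MF.csv")
        return {
            "mf_newtons": dict(zip(fingers, mf.mf.round(3).tolist())),
            "enslaving": ens.values.round(4).tolist(),
            "true_coupling": fspec.coupling.round(4).tolist(),
            "fingers": fingers,
        }
    if stage == "mi":
        mim = independence.mi_matrix(rec)
        pd.DataFrame(mim.values, index=rec.fingers, columns=rec.fingers).to_csv(
            out / "mi_matrix.csv")
        vals = mim.values.copy()
        return {"fingers": rec.fingers,
                "mi_bits": np.round(vals, 4).tolist(),
                "failed_pairs": mim.failed}
    if stage == "prediction":
        results = {}
        for target in rec.fingers:
            res = independence.predict_finger(rec, target, method=config.prediction_method)
            results[target] = round(res.mean_r2, 4)
        return {"method": config.prediction_method, "mean_r2": results}
    if stage == "dof":
        combined = dimensionality.effective_dof(
            rec, folds=config.folds, trim_s=config.trim_s,
            kmax=config.dof_kmax, downsample_factor=config.dof_downsample)
        from .preprocessing import downsample, smooth_recording

        data = downsample(smooth_recording(rec).as_matrix(), config.dof_downsample)
        curve = dimensionality.pca_variance_curve(data)
        return {
            "optimal_k_eigenvector": combined.eigenvector.optimal_k,
            "optimal_k_em": combined.em_imputation.optimal_k,
            "combined_dof": combined.combined_dof,
            "true_latent_dof": truth.latent_dof,
            "press_eigenvector": combined.eigenvector.press.round(4).tolist(),
            "press_em": combined.em_imputation.press.round(4).tolist(),
            "variance_curve": curve.cumulative.round(4).tolist(),
        }
    if stage == "entropy":
        states = entropy.discretize_states(rec, mu_factor=config.mu_factor)
        curve = entropy.entropy_curve(states)
        return {
            "ordering": [r.fingers[-1] for r in curve],
            "entropy_bits": [round(r.bits, 4) for r in curve],
            "max_bits": round(curve[-1].max_bits, 4),
        }
    if stage == "coactivation":
        if "S" not in rec.fingers:
            return {"skipped": "no supernumerary finger"}
        fingers, speeds = entropy.fingertip_speed(rec)
        result = {}
        for pct in config.percentiles:
            mask = entropy.moving_mask(speeds, pct)
            co = entropy.sf_coactivation(mask, fingers, pct)
            result[str(pct)] = {
                "p_thumb_and_index": round(co.p_thumb_and_index, 4),
                "p_thumb_only": round(co.p_thumb_only, 4),
                "p_index_only": round(co.p_index_only, 4),
            }
        return result
    if stage == "localization":
        data = synthetic.simulate_localization(
            error_sd=config.localization_error_sd_cm, seed=seed,
            layout=synthetic.default_localization_layout(rec.fingers))
        errs = stats.localization_error(data)
        return {"overall_cm": round(errs.overall, 4),
                "per_finger_cm": {f: round(v, 4) for f, v in errs.per_finger.items()}}
    if stage == "game":
        logs = synthetic.simulate_game(synthetic.GameModelSpec(seed=seed))
        six = stats.learning_slope(logs["six_finger"])
        five = stats.learning_slope(logs["five_plus_one"])
        test = stats.bootstrap_slope_diff(logs["six_finger"], logs["five_plus_one"],
                                          n_boot=config.n_boot, seed=seed)
        return {
            "slope_six_finger": round(six.slope, 4),
            "slope_five_plus_one": round(five.slope, 4),
            "bootstrap_p": round(test.p, 4),
        }
    raise ConfigError(f"unknown stage '{stage}'")


def compare_hands(summary_a: dict, summary_b: dict) -> dict:
    """Compare two pipeline summaries (a = six-fingered convention first).

    Emits per-quantity differences; quantities missing on either side are
    skipped with a warning entry.
    """
    out: dict = {"convention": "a_minus_b (six minus five)"}
    sa, sb = summary_a.get("stages", {}), summary_b.get("stages", {})

    def _get(summary_stages, *keys):
        node = summary_stages
        for key in keys:
            if not isinstance(node, dict) or key not in node:
                return None
            node = node[key]
        return node

    dof_a = _get(sa, "dof", "combined_dof")
    dof_b = _get(sb, "dof", "combined_dof")
    if dof_a is None or dof_b is None:
        out["dof"] = {"skipped": "combined_dof missing in one report"}
    else:
        out["dof"] = {"a": dof_a, "b": dof_b, "difference": dof_a - dof_b}

    ent_a = _get(sa, "entropy", "entropy_bits")
    ent_b = _get(sb, "entropy", "entropy_bits")
    if ent_a is None or ent_b is None:
        out["max_entropy"] = {"skipped": "entropy curve missing in one report"}
    else:
        out["max_entropy"] = {"a": ent_a[-1], "b": ent_b[-1],
                              "difference": ent_a[-1] - ent_b[-1]}

    ens_a, ens_b = _get(sa, "forces", "enslaving"), _get(sb, "forces", "enslaving")
    if ens_a is None or ens_b is None:
        out["enslaving_correlation"] = {"skipped": "enslaving missing in one report"}
    else:
        fa, fb = _get(sa, "forces", "fingers"), _get(sb, "forces", "fingers")
        common = [f for f in fa if f in fb]
        ma = forces.EnslavingMatrix(fingers=fa, values=np.array(ens_a))
        mb = forces.EnslavingMatrix(fingers=fb, values=np.array(ens_b))
        r = forces.enslaving_correlation(ma, mb, common)
        out["enslaving_correlation"] = {"r": r, "n_pairs": len(common) * (len(common) - 1)}
    return out
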