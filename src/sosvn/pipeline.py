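"""End-to-end pipeline driver: simulate -> train -> sample -> select -> evaluate.

Every stage writes its artifact into the output directory and is skipped on
rerun when an artifact with a matching configuration hash already exists, so
a pipeline is resumable stage by stage.  Stage seeds derive deterministically
from the global seed plus the stage tag.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np

from . import io as sio
from .analytic import AnalyticalConfig, solve_inverse_lbfgs
from .evaluate import rank_sum_test, roc_auc, sos_contrast
from .geometry import build_forward_model
from .phantoms import SimulationConfig, build_hr_model, make_cohort, make_dataset
from .selection import SelectionPolicy, score_frame, select_frame
from .uncertainty import MCDConfig, bvi_posterior, mcd_posterior, train_bvi
from .varnet import (
    NormalizedOperator,
    TrainingConfig,
    VNArchitecture,
    scaled_down_architecture,
    train_vn,
)


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Synthetic lesion cohort for the selection/diagnosis experiments."""

    n_ca: int = 10
    n_fa: int = 10
    n_frames: int = 4
    n_corrupted: int = 3
    corruption_scale: float = 5.0
    n_posterior_samples: int = 24


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration; ``seed`` drives every stochastic stage."""

    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    architecture: VNArchitecture = dataclasses.field(default_factory=scaled_down_architecture)
    training: TrainingConfig = dataclasses.field(default_factory=TrainingConfig)
    mcd: MCDConfig = dataclasses.field(default_factory=MCDConfig)
    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    policy: str = "SI_rel"
    uncertainty_method: str = "mcd"  # or "bvi"
    seed: int = 0
    out_dir: str = "sosvn_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = sio.load_yaml_config(path)
        kw = {}
        mapping = {
            "simulation": SimulationConfig,
            "architecture": VNArchitecture,
            "training": TrainingConfig,
            "mcd": MCDConfig,
            "cohort": CohortConfig,
        }
        for key, klass in mapping.items():
            if key in raw:
                block = dict(raw[key])
                if key == "simulation":
                    from .geometry import AcquisitionSpec, ImagingGrid

                    if "grid" in block:
                        block["grid"] = ImagingGrid(**block["grid"])
                    if "spec" in block:
                        block["spec"] = AcquisitionSpec(**block["spec"])
                kw[key] = klass(**block)
        for key in ("policy", "uncertainty_method", "seed", "out_dir"):
            if key in raw:
                kw[key] = raw[key]
        return cls(**kw)


def smoke_config(out_dir: str = "sosvn_smoke") -> RunConfig:
    """Tiny end-to-end preset (21 x 16 grid, K=3) for integration checks."""
    from .geometry import AcquisitionSpec, ImagingGrid

    sim = SimulationConfig(
        grid=ImagingGrid(n_ax=21, n_lat=16, pitch_ax=2.0, pitch_lat=2.5),
        spec=AcquisitionSpec(n_transmits=5, pair_offset=2),
        n_train=24,
        n_test=6,
    )
    return RunConfig(
        simulation=sim,
        architecture=VNArchitecture(K=3, n_priors=3, kernel_size=3, n_knots=9),
        training=TrainingConfig(iterations=30, batch_size=4),
        mcd=MCDConfig(n_samples=8),
        cohort=CohortConfig(n_ca=5, n_fa=5, n_posterior_samples=8),
        out_dir=out_dir,
    )


def _fresh(path: Path, cfg_hash: str) -> bool:
    """True if the artifact exists and was produced under the same config."""
    if not path.exists():
        return False
    try:
        import h5py

        with h5py.File(path, "r") as f:
            return f.attrs.get("config_hash", None) == cfg_hash
    except OSError:
        return False


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full study and return (and write) the evaluation report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    # the hash identifies the scientific configuration, not the output location
    chash = sio.config_hash(dataclasses.replace(config, out_dir=""))

    def stage(name):
        t0 = time.perf_counter()

        def done():
            log.append({"stage": name, "wall_s": round(time.perf_counter() - t0, 3)})

        return done

    # --- stage: simulate -------------------------------------------------
    sim_cfg = dataclasses.replace(config.simulation, seed=sio.seed_for(config.seed, "simulate"))
    ds_path = out / "dataset.h5"
    done = stage("simulate")
    if _fresh(ds_path, sio.config_hash(sim_cfg)):
        train_set, test_set = sio.load_dataset(ds_path)
    else:
        train_set, test_set = make_dataset(sim_cfg, path=ds_path)
    done()

    model = build_forward_model(sim_cfg.spec, sim_cfg.grid)
    op = NormalizedOperator.from_model(model)

    # --- stage: train -----------------------------------------------------
    tr_cfg = dataclasses.replace(config.training, seed=sio.seed_for(config.seed, "train"))
    ckpt = out / "model_vn.h5"
    done = stage("train")
    if _fresh(ckpt, sio.config_hash(tr_cfg)):
        params = sio.load_vn_params(ckpt)
        bvi_result = None
    else:
        result = train_vn(train_set, model, tr_cfg, config.architecture)
        params = result.params
        sio.save_vn_params(ckpt, params, cfg=tr_cfg, seed=tr_cfg.seed)
        np.savetxt(
            out / "training_log.csv",
            np.column_stack([np.arange(len(result.loss_history)), result.loss_history]),
            delimiter=",",
            header="iteration,loss",
            comments="",
        )
        bvi_result = None
    if config.uncertainty_method == "bvi":
        bvi_ckpt = out / "model_bvi.h5"
        if _fresh(bvi_ckpt, sio.config_hash(tr_cfg)):
            post = sio.load_bvi_posterior(bvi_ckpt)
            bparams = sio.load_vn_params(out / "model_bvi_params.h5")
        else:
            from .experiments import train_bvi_scaled
            from .varnet import VNTrainResult

            vn_like = VNTrainResult(
                params=params, loss_history=np.zeros(1), cfg=tr_cfg,
                arch=config.architecture,
            )
            bvi_result = train_bvi_scaled(train_set, vn_like, tr_cfg, model)
            post, bparams = bvi_result.posterior, bvi_result.params
            sio.save_bvi_posterior(bvi_ckpt, post, seed=tr_cfg.seed)
            sio.save_vn_params(out / "model_bvi_params.h5", bparams, cfg=tr_cfg, seed=tr_cfg.seed)
    done()

    # --- stage: cohort + posteriors --------------------------------------
    done = stage("posteriors")
    rng = np.random.default_rng(sio.seed_for(config.seed, "cohort"))
    model_hr = build_hr_model(sim_cfg)
    cases = make_cohort(
        sim_cfg,
        config.cohort.n_ca,
        config.cohort.n_fa,
        rng,
        n_frames=config.cohort.n_frames,
        n_corrupted=config.cohort.n_corrupted,
        corruption_scale=config.cohort.corruption_scale,
        model_hr=model_hr,
    )
    sample_rng = np.random.default_rng(sio.seed_for(config.seed, "posterior-sampling"))
    mcd_cfg = dataclasses.replace(config.mcd, n_samples=config.cohort.n_posterior_samples)
    summaries = []  # per case, per frame
    for case in cases:
        per_frame = []
        for frame in case.frames:
            if config.uncertainty_method == "bvi":
                summary = bvi_posterior(
                    post, bparams, frame, model, config.cohort.n_posterior_samples, sample_rng, op=op
                )
            else:
                summary = mcd_posterior(params, frame, model, mcd_cfg, sample_rng, op=op)
            per_frame.append(summary)
        summaries.append(per_frame)
    done()

    # --- stage: select + evaluate -----------------------------------------
    done = stage("select-evaluate")
    policy = SelectionPolicy(policy=config.policy, seed=sio.seed_for(config.seed, "selection"))
    sel_rng = np.random.default_rng(policy.seed)
    selections = []
    scores = []
    labels = []
    for case, per_frame in zip(cases, summaries):
        fscores = [
            score_frame(summ, mask, sim_cfg.grid, frame_index=i)
            for i, (summ, mask) in enumerate(zip(per_frame, case.masks))
        ]
        sel = select_frame(fscores, policy, rng=sel_rng)
        contrast = sos_contrast(per_frame[sel].mean_sos, case.masks[sel], sim_cfg.grid)
        selections.append(
            {
                "label": case.label,
                "selected_index": sel,
                "corrupted_frames": sorted(case.corrupted_frames),
                "delta_c": contrast.delta_c,
                "scores": [
                    {"frame": fs.frame_index, "inc_unc": fs.inc_unc, "bkg_unc": fs.bkg_unc,
                     "rel_unc": fs.rel_unc}
                    for fs in fscores
                ],
            }
        )
        scores.append(contrast.delta_c)
        labels.append(1 if case.label == "CA" else 0)
    report = roc_auc(scores, labels)
    ca = [s for s, l in zip(scores, labels) if l == 1]
    fa = [s for s, l in zip(scores, labels) if l == 0]
    rs = rank_sum_test(ca, fa)
    result = {
        "config_hash": chash,
        "seed": config.seed,
        "policy": config.policy,
        "uncertainty_method": config.uncertainty_method,
        "n_cases": len(cases),
        "auc": report.auc,
        "f1": report.f1,
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "threshold": report.threshold,
        "rank_sum_p": rs.p_value,
        "selections": selections,
    }
    done()
    result["stage_log"] = log
    with open(out / "report.json", "w") as f:
        json.dump(result, f, indent=2)
    with open(out / "run_log.json", "w") as f:
        json.dump(log, f, indent=2)
    return result
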