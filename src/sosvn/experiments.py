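"""Scaled-down study experiments: reconstruction benchmark, frame-selection
power, and the synthetic diagnosis cohort.

These routines compose the package end to end at the desk-scale study
conditions (small grid, reduced transmit count, CPU-sized training) and
return the headline quantities: test-set RMSEs of the analytical baseline,
the deterministic network and both posterior means; the clean-frame hit
rate of relative-uncertainty selection; and the cohort AUCs of informed
versus random selection.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .analytic import AnalyticalConfig, solve_inverse_lbfgs
from .evaluate import rank_sum_test, rmse, roc_auc, sos_contrast
from .geometry import DisplacementMeasurements, ForwardModel, build_forward_model
from .maps import SoSMap, slowness_to_sos
from .phantoms import (
    SimDataset,
    SimulationConfig,
    build_hr_model,
    make_cohort,
    make_dataset,
    make_lesion_case,
)
from .selection import SelectionPolicy, score_frame, select_frame
from .uncertainty import (
    BVITrainResult,
    MCDConfig,
    bvi_posterior,
    mcd_posterior,
    train_bvi,
)
from .varnet import (
    NormalizedOperator,
    TrainingConfig,
    VNArchitecture,
    VNTrainResult,
    scaled_down_architecture,
    train_vn,
    vn_forward,
)


def _meas(dataset: SimDataset, model: ForwardModel, i: int) -> DisplacementMeasurements:
    d, _, _ = dataset.record(i)
    return DisplacementMeasurements(values=d, grid=model.recon_grid, pairs=model.pairs)


def train_mcd_scaled(train_set, vn_result: VNTrainResult, cfg: TrainingConfig, model,
                     p: float = 0.25) -> VNTrainResult:
    """MCD variant of the network: trained from scratch with dropout active.

    Dropout posterior sampling presumes the network was trained under the
    same per-filter dropout it is sampled with; masking a dropout-naive
    network removes a large fraction of its learned regularizer and biases
    the posterior mean (with 6 priors per layer the effect is far larger
    than with the full-scale 16).  The dropout network gets two extra
    unrolled layers and a half-longer optimization than the deterministic
    VN: dropout both removes expected capacity and slows convergence, and
    with this compensation its posterior mean matches the deterministic
    reconstruction quality.
    """
    arch = dataclasses.replace(vn_result.arch, K=vn_result.arch.K + 2)
    mcd_cfg = dataclasses.replace(
        cfg, dropout_p=p, iterations=int(cfg.iterations * 4 / 3)
    )
    return train_vn(train_set, model, mcd_cfg, arch)


def train_bvi_scaled(train_set, vn_result: VNTrainResult, cfg: TrainingConfig, model):
    """Desk-scale Bayesian training protocol: warm start at the fitted VN.

    The posterior mean starts at the trained point-estimate filters and the
    covariance at ~10% of the filter scale with a weak KL weight — at a few
    thousand iterations the cold-start protocol (random means, unit
    covariance) cannot leave the unstable sampling regime of the unrolled
    recursion, whereas the warm start converges and yields calibrated,
    finite posteriors.
    """
    mu0 = np.concatenate([l.filters.ravel() for l in vn_result.params.layers])
    bvi_cfg = dataclasses.replace(
        cfg, beta=0.1, lr=5e-3, iterations=max(1, cfg.iterations // 2)
    )
    return train_bvi(
        train_set, vn_result.params, bvi_cfg, model, mu_init=mu0, diag_init=0.02
    )


@dataclasses.dataclass
class ReconstructionBenchmark:
    """Trained models plus mean test-set RMSEs (m/s)."""

    sim_cfg: SimulationConfig
    model: ForwardModel
    op: NormalizedOperator
    train_set: SimDataset
    test_set: SimDataset
    vn: VNTrainResult
    mcd_vn: VNTrainResult  # dropout-fine-tuned variant used for MCD sampling
    bvi: BVITrainResult
    lbfgs_rmse: float
    vn_rmse: float
    mcd_rmse: float
    bvi_rmse: float


def reconstruction_benchmark(
    seed: int,
    sim_cfg: SimulationConfig | None = None,
    train_cfg: TrainingConfig | None = None,
    arch: VNArchitecture | None = None,
    n_posterior_samples: int = 25,
    mcd_p: float = 0.25,
) -> ReconstructionBenchmark:
    """Generate data, train VN and BVI, and score every method on the test set."""
    if sim_cfg is None:
        sim_cfg = SimulationConfig(seed=seed)
    else:
        sim_cfg = dataclasses.replace(sim_cfg, seed=seed)
    if train_cfg is None:
        train_cfg = TrainingConfig(seed=seed)
    else:
        train_cfg = dataclasses.replace(train_cfg, seed=seed)
    if arch is None:
        arch = scaled_down_architecture()

    train_set, test_set = make_dataset(sim_cfg)
    model = build_forward_model(sim_cfg.spec, sim_cfg.grid)
    op = NormalizedOperator.from_model(model)
    grid = sim_cfg.grid

    def gt(i):
        return SoSMap(values=test_set.sos_gt[i], grid=grid)

    lbfgs_errs = [
        rmse(solve_inverse_lbfgs(_meas(test_set, model, i), model).sos, gt(i))
        for i in range(test_set.n)
    ]

    vn = train_vn(train_set, model, train_cfg, arch)
    vn_errs = [
        rmse(
            slowness_to_sos(vn_forward(vn.params, _meas(test_set, model, i), model, op=op).slowness),
            gt(i),
        )
        for i in range(test_set.n)
    ]

    mcd_vn = train_mcd_scaled(train_set, vn, train_cfg, model, p=mcd_p)
    mcd_cfg = MCDConfig(p=mcd_p, n_samples=n_posterior_samples, seed=seed)
    rng = np.random.default_rng(seed)
    mcd_errs = [
        rmse(
            mcd_posterior(
                mcd_vn.params, _meas(test_set, model, i), model, mcd_cfg, rng, op=op
            ).mean_sos,
            gt(i),
        )
        for i in range(test_set.n)
    ]

    bvi = train_bvi_scaled(train_set, vn, train_cfg, model)
    bvi_errs = [
        rmse(
            bvi_posterior(
                bvi.posterior, bvi.params, _meas(test_set, model, i), model,
                n_posterior_samples, rng, op=op,
            ).mean_sos,
            gt(i),
        )
        for i in range(test_set.n)
    ]

    return ReconstructionBenchmark(
        sim_cfg=sim_cfg,
        model=model,
        op=op,
        train_set=train_set,
        test_set=test_set,
        vn=vn,
        mcd_vn=mcd_vn,
        bvi=bvi,
        lbfgs_rmse=float(np.mean(lbfgs_errs)),
        vn_rmse=float(np.mean(vn_errs)),
        mcd_rmse=float(np.mean(mcd_errs)),
        bvi_rmse=float(np.mean(bvi_errs)),
    )


def frame_selection_hit_rate(
    bench: ReconstructionBenchmark,
    seed: int,
    n_cases: int = 200,
    n_frames: int = 4,
    corruption_scale: float = 5.0,
    n_posterior_samples: int = 32,
) -> dict:
    """Fraction of cases where relative-uncertainty selection finds the one
    clean frame among ``n_frames`` (all others corrupted)."""
    sim_cfg = bench.sim_cfg
    model_hr = build_hr_model(sim_cfg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    sample_rng = np.random.default_rng(np.random.SeedSequence([seed, 12]))
    mcd_cfg = MCDConfig(p=0.25, n_samples=n_posterior_samples, seed=seed)
    hits = 0
    for _ in range(n_cases):
        case = make_lesion_case(
            sim_cfg, n_frames, n_frames - 1, corruption_scale, rng, model_hr=model_hr
        )
        (clean,) = set(range(n_frames)) - case.corrupted_frames
        scores = []
        for i, frame in enumerate(case.frames):
            summ = mcd_posterior(
                bench.mcd_vn.params, frame, bench.model, mcd_cfg, sample_rng, op=bench.op
            )
            scores.append(score_frame(summ, case.masks[i], sim_cfg.grid, frame_index=i))
        sel = select_frame(scores, SelectionPolicy("SI_rel"))
        hits += sel == clean
    return {"hit_rate": hits / n_cases, "n_cases": n_cases, "chance": 1.0 / n_frames}


def cohort_diagnosis_experiment(
    bench: ReconstructionBenchmark,
    seed: int,
    n_ca: int = 30,
    n_fa: int = 30,
    n_frames: int = 4,
    n_corrupted: int = 3,
    corruption_scale: float = 5.0,
    n_posterior_samples: int = 32,
    n_sr_seeds: int = 20,
) -> dict:
    """Synthetic diagnosis cohort: contrast AUC of informed (SI_rel) versus
    random (SR) frame selection, paired over the same cases, plus the
    rank-sum test between the CA and FA contrast groups."""
    sim_cfg = bench.sim_cfg
    model_hr = build_hr_model(sim_cfg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 21]))
    sample_rng = np.random.default_rng(np.random.SeedSequence([seed, 22]))
    mcd_cfg = MCDConfig(p=0.25, n_samples=n_posterior_samples, seed=seed)
    cases = make_cohort(
        sim_cfg, n_ca, n_fa, rng, n_frames=n_frames, n_corrupted=n_corrupted,
        corruption_scale=corruption_scale, model_hr=model_hr,
    )
    labels = [1 if c.label == "CA" else 0 for c in cases]
    per_case_scores = []  # FrameScores per case
    per_case_contrasts = []  # delta_c per frame per case
    for case in cases:
        scores, contrasts = [], []
        for i, frame in enumerate(case.frames):
            summ = mcd_posterior(
                bench.mcd_vn.params, frame, bench.model, mcd_cfg, sample_rng, op=bench.op
            )
            scores.append(score_frame(summ, case.masks[i], sim_cfg.grid, frame_index=i))
            contrasts.append(
                sos_contrast(summ.mean_sos, case.masks[i], sim_cfg.grid).delta_c
            )
        per_case_scores.append(scores)
        per_case_contrasts.append(contrasts)

    si_scores = [
        per_case_contrasts[c][select_frame(per_case_scores[c], SelectionPolicy("SI_rel"))]
        for c in range(len(cases))
    ]
    si_auc = roc_auc(si_scores, labels).auc

    sr_aucs = []
    for k in range(n_sr_seeds):
        sr_rng = np.random.default_rng(np.random.SeedSequence([seed, 31, k]))
        sr_scores = [
            per_case_contrasts[c][select_frame(per_case_scores[c], SelectionPolicy("SR"), sr_rng)]
            for c in range(len(cases))
        ]
        sr_aucs.append(roc_auc(sr_scores, labels).auc)

    ca = [s for s, l in zip(si_scores, labels) if l == 1]
    fa = [s for s, l in zip(si_scores, labels) if l == 0]
    rs = rank_sum_test(ca, fa)
    return {
        "si_rel_auc": float(si_auc),
        "sr_aucs": [float(a) for a in sr_aucs],
        "sr_auc_mean": float(np.mean(sr_aucs)),
        "si_beats_sr_count": int(sum(si_auc >= a for a in sr_aucs)),
        "n_sr_seeds": n_sr_seeds,
        "rank_sum_p": rs.p_value,
        "n_cases": len(cases),
    }
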