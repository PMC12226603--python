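"""Model/results interface over the variational-network reconstructors.

Mirrors the statsmodels convention: a model object is constructed from data
(a simulated training set plus the forward operator), ``fit()`` runs the
optimization and returns a results object carrying the estimates, training
diagnostics, and methods for reconstruction, posterior sampling and a
``summary()`` table.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import DisplacementMeasurements, ForwardModel
from .maps import SoSMap, slowness_to_sos
from .phantoms import SimDataset
from .uncertainty import (
    BVIPosterior,
    BVITrainResult,
    MCDConfig,
    PosteriorSummary,
    bvi_posterior,
    mcd_posterior,
    train_bvi,
)
from .varnet import (
    NormalizedOperator,
    TrainingConfig,
    VNArchitecture,
    VNParams,
    scaled_down_architecture,
    train_vn,
    vn_forward,
)


class VariationalNetworkResults:
    """Fitted deterministic VN: parameters plus training diagnostics."""

    def __init__(self, model: "VariationalNetworkModel", params: VNParams,
                 loss_history: np.ndarray):
        self.model = model
        self.params = params
        self.loss_history = loss_history
        self._op = NormalizedOperator.from_model(model.forward_model)

    def reconstruct(self, d: DisplacementMeasurements) -> SoSMap:
        rec = vn_forward(self.params, d, self.model.forward_model, op=self._op)
        return slowness_to_sos(rec.slowness)

    def mcd_posterior(
        self, d: DisplacementMeasurements, cfg: MCDConfig, rng: np.random.Generator
    ) -> PosteriorSummary:
        """Monte Carlo Dropout posterior for one measurement set."""
        return mcd_posterior(self.params, d, self.model.forward_model, cfg, rng, op=self._op)

    def rmse_on(self, dataset: SimDataset) -> float:
        """Mean reconstruction RMSE (m/s) over a dataset."""
        from .evaluate import rmse

        grid = self.model.forward_model.recon_grid
        errs = []
        for i in range(dataset.n):
            d, sos_gt, _ = dataset.record(i)
            meas = DisplacementMeasurements(values=d, grid=grid, pairs=self.model.forward_model.pairs)
            errs.append(rmse(self.reconstruct(meas), SoSMap(values=sos_gt, grid=grid)))
        return float(np.mean(errs))

    def summary(self) -> str:
        p = self.params
        n_param = sum(
            l.filters.size + l.w.size + l.s.size + l.psi.y.size + sum(q.y.size for q in l.phi)
            for l in p.layers
        )
        lines = [
            "Variational network reconstruction results",
            "==========================================",
            f"unrolled layers (K):        {p.K}",
            f"priors per layer:           {p.layers[0].filters.shape[0]}",
            f"kernel size:                {p.layers[0].filters.shape[-1]}",
            f"trainable parameters:       {n_param}",
            f"reconstruction grid:        {p.recon_shape[0]} x {p.recon_shape[1]}",
            f"measurement pairs:          {p.n_pairs}",
            f"training iterations:        {len(self.loss_history)}",
            f"initial / final loss:       {self.loss_history[0]:.4f} / {self.loss_history[-1]:.4f}",
        ]
        return "\n".join(lines)


class VariationalNetworkModel:
    """Unrolled VN reconstructor to be fitted on simulated training data."""

    def __init__(
        self,
        train_data: SimDataset,
        forward_model: ForwardModel,
        architecture: VNArchitecture | None = None,
    ):
        self.train_data = train_data
        self.forward_model = forward_model
        self.architecture = architecture or scaled_down_architecture()

    def fit(self, cfg: TrainingConfig | None = None) -> VariationalNetworkResults:
        result = train_vn(self.train_data, self.forward_model, cfg, self.architecture)
        return VariationalNetworkResults(self, result.params, result.loss_history)


class BayesianVariationalNetworkResults(VariationalNetworkResults):
    """Fitted BVI network: Gaussian filter posterior plus point parameters."""

    def __init__(self, model, params: VNParams, posterior: BVIPosterior,
                 loss_history: np.ndarray):
        super().__init__(model, params, loss_history)
        self.posterior = posterior

    def sample_posterior(
        self, d: DisplacementMeasurements, n_samples: int, rng: np.random.Generator
    ) -> PosteriorSummary:
        return bvi_posterior(
            self.posterior, self.params, d, self.model.forward_model, n_samples, rng,
            op=self._op,
        )

    def reconstruct(self, d: DisplacementMeasurements) -> SoSMap:
        # point reconstruction at the posterior mean filters
        return super().reconstruct(d)

    def summary(self) -> str:
        base = super().summary()
        diag = np.diagonal(self.posterior.blocks, axis1=1, axis2=2)
        extra = [
            "",
            "Gaussian filter posterior",
            f"filter coefficients (t):    {self.posterior.t}",
            f"covariance blocks:          {self.posterior.blocks.shape[0]} of size "
            f"{self.posterior.blocks.shape[1]}",
            f"factor diagonal range:      [{diag.min():.3e}, {diag.max():.3e}]",
            f"prior precision alpha:      {self.posterior.alpha}",
        ]
        return base + "\n" + "\n".join(extra)


class BayesianVariationalNetworkModel(VariationalNetworkModel):
    """VN with a learned Gaussian posterior over the regularizer filters."""

    def __init__(
        self,
        train_data: SimDataset,
        forward_model: ForwardModel,
        architecture: VNArchitecture | None = None,
        init_params: VNParams | None = None,
    ):
        super().__init__(train_data, forward_model, architecture)
        self.init_params = init_params

    def fit(self, cfg: TrainingConfig | None = None) -> BayesianVariationalNetworkResults:
        from .experiments import train_bvi_scaled
        from .varnet import VNTrainResult, scaled_down_architecture

        cfg = cfg or TrainingConfig()
        if self.init_params is None:
            vn = train_vn(self.train_data, self.forward_model, cfg, self.architecture)
        else:
            vn = VNTrainResult(
                params=self.init_params, loss_history=np.zeros(1), cfg=cfg,
                arch=self.architecture,
            )
        result = train_bvi_scaled(self.train_data, vn, cfg, self.forward_model)
        return BayesianVariationalNetworkResults(
            self, result.params, result.posterior, result.loss_history
        )
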