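"""Deep factor model: a conditional CNN for multicontrast reconstruction.

The image at normalized inversion time ``tau`` is the output of a small
CNN whose intermediate feature maps are modulated channelwise by a gain
vector ``v(tau)`` produced by a three-layer MLP of the scalar condition:

    eta(tau) = U_phi(gamma, v(tau)),    v(tau) = V_theta(tau).

``gamma`` is the eight-bin zero-filled gridding reconstruction of the
same k-space data, fed as 16 real channels (real+imaginary per bin).
The CNN has three convolution blocks (16 -> 32 -> 32 -> 2 channels,
3x3(x3) kernels, Tanh after the first modulated block, leaky-ReLU 0.2
after the second); the MLP is 1 -> 64 -> 64 -> 64 with leaky-ReLU 0.1
after each layer, and its 64 outputs are split into two 32-gain vectors,
one per modulated block.  In the reference 3D configuration this model
has exactly 51,714 trainable parameters.

Both parameter sets are fit by self-supervised (single-shot) learning:
minimizing the k-space data-consistency loss of the scan being
reconstructed, with a temporal annealing schedule (few coarse TI
subgroups first, refined over stages) and optional progression in
matrix size.  Transfer learning re-runs only the final stage starting
from weights learned on a previous scan.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .operators import (CoilMaps, ImageSeries, KSpaceData, PlanCache,
                        gridding_recon, normalize_kspace)
from .trajectory import TIBinning, bin_by_ti

__all__ = [
    "DFMConfig",
    "DFMWeights",
    "Stage",
    "TrainSchedule",
    "init_dfm",
    "dfm_param_count",
    "temporal_mlp",
    "dfm_forward",
    "gamma_input",
    "render_series",
    "ssl_train",
    "transfer_learn",
    "data_consistency_loss",
    "TrainResult",
]

MLP_SLOPE = 0.1
CNN_SLOPE = 0.2


@dataclass(frozen=True)
class DFMConfig:
    """Architecture hyperparameters; defaults match the reference model."""

    ndim: int = 3
    n_input_bins: int = 8     # gamma bins; input channels = 2 * bins
    cnn_width: int = 32
    mlp_width: int = 64
    kernel: int = 3

    @property
    def in_channels(self) -> int:
        return 2 * self.n_input_bins

    @property
    def n_gains(self) -> int:
        return 2 * self.cnn_width


def dfm_param_count(config: DFMConfig = DFMConfig()) -> int:
    """Closed-form trainable-parameter count of the model."""
    k = config.kernel ** config.ndim
    cw, mw = config.cnn_width, config.mlp_width
    cnn = (cw * config.in_channels * k + cw) + (cw * cw * k + cw) + (2 * cw * k + 2)
    mlp = (mw * 1 + mw) + (mw * mw + mw) + (config.n_gains * mw + config.n_gains)
    return cnn + mlp


@dataclass
class DFMWeights:
    """Trainable parameters of the CNN (phi) and temporal MLP (theta)."""

    params: dict[str, np.ndarray]
    config: DFMConfig
    metadata: dict = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def copy(self) -> "DFMWeights":
        return DFMWeights(params={k: v.copy() for k, v in self.params.items()},
                          config=self.config,
                          metadata=copy.deepcopy(self.metadata))


def init_dfm(config: DFMConfig, seed: int = 0,
             scheme: str = "random") -> DFMWeights:
    """Seeded initialization of all trainable parameters.

    ``scheme='random'`` (default) is He initialization.
    ``scheme='routing'`` starts the first two convolution blocks as
    identity pass-through of the gamma input channels (the remaining
    feature channels stay random) so the zero-filled bins arrive
    unchanged at the last layer; kept as an experimental warm start —
    at desk scale plain He initialization trains at least as well.
    """
    if scheme not in ("routing", "random"):
        raise ValueError("scheme must be 'routing' or 'random'")
    rng = np.random.default_rng(seed)
    cw, mw, ng = config.cnn_width, config.mlp_width, config.n_gains
    cin = config.in_channels
    p = {}
    p["cnn_w1"], p["cnn_b1"] = nn.conv_init(rng, cw, cin,
                                            config.kernel, config.ndim)
    p["cnn_w2"], p["cnn_b2"] = nn.conv_init(rng, cw, cw, config.kernel, config.ndim)
    p["cnn_w3"], p["cnn_b3"] = nn.conv_init(rng, 2, cw, config.kernel, config.ndim)
    if scheme == "routing":
        center = (config.kernel // 2,) * config.ndim
        for c in range(min(cin, cw)):
            p["cnn_w1"][c] *= 0.1
            p["cnn_w1"][(c, c) + center] = 1.0
            p["cnn_w2"][c] *= 0.1
            p["cnn_w2"][(c, c) + center] = 1.0
        p["cnn_w3"] *= 0.1
    p["mlp_w1"], p["mlp_b1"] = nn.dense_init(rng, mw, 1)
    p["mlp_w2"], p["mlp_b2"] = nn.dense_init(rng, mw, mw)
    p["mlp_w3"], p["mlp_b3"] = nn.dense_init(rng, ng, mw)
    # the MLP input is the bare scalar tau: without a bias spread the first
    # layer collapses to zero at tau=0, and near-zero gains choke the CNN;
    # start the first layer with a random bias and the gains near one
    p["mlp_b1"] = rng.normal(scale=0.5, size=mw)
    p["mlp_b3"] = np.ones(ng)
    return DFMWeights(params=p, config=config, metadata={"seed": seed, "stages": []})


def temporal_mlp(tau: float, weights: DFMWeights, with_cache: bool = False):
    """Gain vector v(tau); tau outside [0,1] is clamped with a warning."""
    if not 0.0 <= tau <= 1.0:
        warnings.warn(f"tau={tau} outside [0, 1]; clamping")
        tau = float(np.clip(tau, 0.0, 1.0))
    p = weights.params
    x = np.array([tau])
    caches = []
    for i in (1, 2, 3):
        x, cd = nn.dense_forward(x, p[f"mlp_w{i}"], p[f"mlp_b{i}"])
        x, ca = nn.leaky_relu_forward(x, MLP_SLOPE)
        caches.append((cd, ca))
    return (x, caches) if with_cache else x


def _mlp_backward(gv: np.ndarray, caches, weights: DFMWeights,
                  grads: dict[str, np.ndarray]) -> None:
    g = gv
    for i, (cd, ca) in zip((3, 2, 1), reversed(caches)):
        g = nn.leaky_relu_backward(g, ca)
        g, gw, gb = nn.dense_backward(g, cd)
        grads[f"mlp_w{i}"] += gw
        grads[f"mlp_b{i}"] += gb


def dfm_forward(x16: np.ndarray, tau: float, weights: DFMWeights,
                with_cache: bool = False):
    """Render the complex image at condition ``tau``.

    ``x16`` is the gamma input as ``2 * n_input_bins`` real channels.
    """
    cfg = weights.config
    if x16.shape[0] != cfg.in_channels:
        raise ValueError(f"expected {cfg.in_channels} input channels, got {x16.shape[0]}")
    p = weights.params
    v, mlp_cache = temporal_mlp(tau, weights, with_cache=True)
    cw = cfg.cnn_width
    h1, c1 = nn.conv_forward(x16, p["cnn_w1"], p["cnn_b1"])
    f1, cf1 = nn.film_forward(h1, v[:cw])
    a1, ca1 = nn.tanh_forward(f1)
    h2, c2 = nn.conv_forward(a1, p["cnn_w2"], p["cnn_b2"])
    f2, cf2 = nn.film_forward(h2, v[cw:])
    a2, ca2 = nn.leaky_relu_forward(f2, CNN_SLOPE)
    out, c3 = nn.conv_forward(a2, p["cnn_w3"], p["cnn_b3"])
    img = out[0] + 1j * out[1]
    if not with_cache:
        return img
    cache = (mlp_cache, c1, cf1, ca1, c2, cf2, ca2, c3, cw)
    return img, cache


def dfm_backward(gimg: np.ndarray, cache, weights: DFMWeights) -> dict[str, np.ndarray]:
    """Backpropagate a complex image gradient to all parameters.

    ``gimg`` is the Wirtinger gradient dL/d(conj eta); its real and
    imaginary parts are the gradients of the two output channels.
    """
    mlp_cache, c1, cf1, ca1, c2, cf2, ca2, c3, cw = cache
    grads = {k: np.zeros_like(v) for k, v in weights.params.items()}
    gout = np.stack([gimg.real, gimg.imag])
    g, gw, gb = nn.conv_backward(gout, c3)
    grads["cnn_w3"] += gw
    grads["cnn_b3"] += gb
    g = nn.leaky_relu_backward(g, ca2)
    g, ggain2 = nn.film_backward(g, cf2)
    g, gw, gb = nn.conv_backward(g, c2)
    grads["cnn_w2"] += gw
    grads["cnn_b2"] += gb
    g = nn.tanh_backward(g, ca1)
    g, ggain1 = nn.film_backward(g, cf1)
    _, gw, gb = nn.conv_backward(g, c1)
    grads["cnn_w1"] += gw
    grads["cnn_b1"] += gb
    gv = np.concatenate([ggain1, ggain2])
    _mlp_backward(gv, mlp_cache, weights, grads)
    return grads


# ------------------------------------------------------------ training --

@dataclass(frozen=True)
class Stage:
    matrix_size: int
    n_subgroups: int
    lr: float
    n_epochs: int
    decay_epoch: int | None = None
    decay_rate: float = 0.2
    plateau: bool = False
    plateau_factor: float = 0.5
    plateau_patience: int = 3
    early_stop_patience: int = 6
    early_stop_rtol: float = 1e-3
    # exponential moving average of the weights over the stage's steps
    # (0 disables); averaging the SGD tail removes much of the
    # subgroup-stochasticity in the final rendered series
    ema_decay: float = 0.0
    # temporal subgroups aggregated per optimizer step; >1 trades more
    # data passes per update for fewer updates per epoch
    batch_subgroups: int = 1


@dataclass(frozen=True)
class TrainSchedule:
    stages: tuple[Stage, ...]

    @classmethod
    def reference_3d(cls) -> "TrainSchedule":
        """Five-stage progressive schedule of the full-scale 3D model."""
        sizes = [128, 128, 128, 256, 256]
        subgroups = [32, 64, 384, 64, 384]
        lrs = [1e-3, 5e-4, 5e-4, 5e-4, 5e-4]
        epochs = [30, 30, 60, 20, 40]
        decay = [20, 20, 40, 10, None]
        stages = tuple(
            Stage(matrix_size=s, n_subgroups=g, lr=l, n_epochs=e,
                  decay_epoch=d, plateau=(i == 4))
            for i, (s, g, l, e, d) in enumerate(zip(sizes, subgroups, lrs, epochs, decay)))
        return cls(stages=stages)

    @classmethod
    def desk(cls, matrix_size: int = 64, subgroups=(8, 48),
             epochs=(4, 10), lrs=(5e-3, 2e-3), decay_epochs=(3, 7),
             batches=(1, 2), ema_decay: float = 0.9) -> "TrainSchedule":
        """Two-stage schedule for 2D desk-scale problems (<= 300 steps).

        A short coarse stage (8 subgroups) warms the model on aggregated
        k-space; the per-contrast stage then pairs subgroups per optimizer
        step (minibatch of 2), which doubles the data passes available
        within the step budget, and averages the SGD tail (EMA) before
        rendering.  Total optimizer steps: 4*8 + 10*48/2 = 272.
        """
        stages = []
        for i, (g, e, l, d, bs) in enumerate(zip(subgroups, epochs, lrs,
                                                 decay_epochs, batches)):
            last = i == len(subgroups) - 1
            stages.append(Stage(matrix_size=matrix_size, n_subgroups=g, lr=l,
                                n_epochs=e, decay_epoch=d, plateau=last,
                                batch_subgroups=bs,
                                ema_decay=ema_decay if last else 0.0))
        return cls(stages=tuple(stages))

    @property
    def final_stage(self) -> Stage:
        return self.stages[-1]


@dataclass
class TrainResult:
    weights: DFMWeights
    series: ImageSeries
    loss_log: list[dict]
    scale: float
    gamma: np.ndarray


def gamma_input(ksp: KSpaceData, maps: CoilMaps, grid_shape,
                n_bins: int = 8, plans: PlanCache | None = None) -> np.ndarray:
    """Eight-bin zero-filled input gamma as ``2 * n_bins`` real channels."""
    binning = bin_by_ti(ksp.n_contrasts, n_bins)
    gamma = gridding_recon(ksp, binning, maps=maps, grid_shape=grid_shape,
                           plans=plans).volumes
    return np.concatenate([gamma.real, gamma.imag], axis=0)


def _subgroup_step(x16, tau_c, members, ksp, maps, plans, weights,
                   compute_grads: bool = True, sample_weights=None):
    """Data-consistency loss (and gradients) of one TI subgroup.

    The subgroup's image is rendered at the central tau and compared
    against every measured view in the subgroup.  ``sample_weights``
    (density-compensation based) turn the plain least squares into a
    preconditioned weighted least squares with the same minimizer on
    consistent data but far better conditioning, which is what makes
    short desk-scale training budgets feasible.
    """
    plan = plans.plan(members)
    y = ksp.data_for_contrasts(members)      # (M, C)
    if compute_grads:
        img, cache = dfm_forward(x16, tau_c, weights, with_cache=True)
    else:
        img = dfm_forward(x16, tau_c, weights)
    loss = 0.0
    gimg = np.zeros_like(img)
    w = 1.0 if sample_weights is None else sample_weights
    for c in range(maps.n_coils):
        r = plan.forward(img * maps.maps[c]) - y[:, c]
        loss += float(np.sum(w * np.abs(r) ** 2))
        if compute_grads:
            gimg += 2.0 * np.conj(maps.maps[c]) * plan.adjoint(w * r)
    if not compute_grads:
        return loss, None
    return loss, dfm_backward(gimg, cache, weights)


def data_consistency_loss(series_at, ksp: KSpaceData, maps: CoilMaps,
                          binning: TIBinning, plans: PlanCache | None = None,
                          tau_grid: np.ndarray | None = None) -> float:
    """Total subgroup data-consistency loss for any image provider.

    ``series_at`` maps a subgroup's central normalized inversion time to
    a complex image; each subgroup contributes the squared residual of
    that image against all of the subgroup's measured views.  When the
    underlying image series is constant within bins, refining the
    binning leaves this total unchanged (partition refinement identity).
    """
    if plans is None:
        plans = PlanCache(ksp, maps.grid_shape)
    if tau_grid is None:
        n = binning.n_contrasts
        tau_grid = np.arange(n) / max(n - 1, 1)
    total = 0.0
    for b in range(binning.n_bins):
        members = binning.members(b)
        tau_c = float(tau_grid[binning.central_contrast(b)])
        plan = plans.plan(members)
        y = ksp.data_for_contrasts(members)
        img = series_at(tau_c)
        for c in range(maps.n_coils):
            r = plan.forward(img * maps.maps[c]) - y[:, c]
            total += float(np.sum(np.abs(r) ** 2))
    return total


def _resample_maps(maps: CoilMaps, grid_shape) -> CoilMaps:
    if maps.grid_shape == tuple(grid_shape):
        return maps
    from scipy.ndimage import zoom
    factors = [g / m for g, m in zip(grid_shape, maps.grid_shape)]
    new = np.stack([zoom(m.real, factors, order=1) + 1j * zoom(m.imag, factors, order=1)
                    for m in maps.maps])
    support = zoom(maps.support.astype(float), factors, order=0) > 0.5
    return CoilMaps(maps=new, support=support)


def _run_stage(weights, stage: Stage, ksp, maps, rng, loss_log, stage_idx,
               dc_weighted: bool = True):
    """One annealing stage: SGD over TI subgroups with Adam."""
    grid_shape = (stage.matrix_size,) * weights.config.ndim
    smaps = _resample_maps(maps, grid_shape)
    plans = PlanCache(ksp, grid_shape)
    x16 = gamma_input(ksp, smaps, grid_shape, weights.config.n_input_bins, plans=plans)
    n = ksp.n_contrasts
    tau_grid = np.arange(n) / max(n - 1, 1)
    binning = bin_by_ti(n, stage.n_subgroups)
    dcf = ksp.dcf
    if dc_weighted and dcf is None:
        from .trajectory import density_compensation
        dcf = density_compensation(ksp.traj.coords, calibrate=False)
    sub_weights = {}
    if dc_weighted:
        for b in range(stage.n_subgroups):
            members = binning.members(b)
            w = ksp.dcf_for_contrasts(members) if ksp.dcf is not None else None
            if w is None:
                views = np.nonzero(np.isin(ksp.ti_index, members))[0]
                w = dcf[:, views].reshape(-1)
            sub_weights[b] = w * plans.dc_scale(members, w)
    opt = nn.Adam(weights.params, lr=stage.lr)
    ema = ({k: v.copy() for k, v in weights.params.items()}
           if stage.ema_decay > 0 else None)
    best = np.inf
    epochs_no_improve = 0
    plateau_wait = 0
    lr = stage.lr
    epoch = 0
    while epoch < stage.n_epochs:
        if stage.decay_epoch is not None and epoch == stage.decay_epoch:
            lr *= stage.decay_rate
        opt.lr = lr
        order = rng.permutation(stage.n_subgroups)
        epoch_loss = 0.0
        bs = max(1, stage.batch_subgroups)
        for i in range(0, stage.n_subgroups, bs):
            grads = None
            for b in order[i:i + bs]:
                members = binning.members(int(b))
                tau_c = float(tau_grid[binning.central_contrast(int(b))])
                loss, g = _subgroup_step(x16, tau_c, members, ksp, smaps,
                                         plans, weights,
                                         sample_weights=sub_weights.get(int(b)))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged (stage {stage_idx}, epoch {epoch}, "
                        f"subgroup {int(b)}: loss={loss})")
                grads = g if grads is None else {k: grads[k] + g[k] for k in g}
                epoch_loss += loss
            opt.step(grads)
            if ema is not None:
                a = stage.ema_decay
                for k, v in weights.params.items():
                    ema[k] = a * ema[k] + (1 - a) * v
        loss_log.append({"stage": stage_idx, "epoch": epoch, "loss": epoch_loss,
                         "lr": lr})
        if stage.plateau:
            if epoch_loss < best * (1 - stage.early_stop_rtol):
                best = epoch_loss
                epochs_no_improve = 0
                plateau_wait = 0
            else:
                epochs_no_improve += 1
                plateau_wait += 1
                if plateau_wait >= stage.plateau_patience:
                    lr *= stage.plateau_factor
                    plateau_wait = 0
                if epochs_no_improve >= stage.early_stop_patience:
                    break
        epoch += 1
    if ema is not None:
        for k in weights.params:
            weights.params[k][...] = ema[k]
    weights.metadata["stages"].append(
        {"stage": stage_idx, "matrix_size": stage.matrix_size,
         "n_subgroups": stage.n_subgroups, "epochs_run": epoch + 1})
    return x16


def render_series(weights: DFMWeights, x16: np.ndarray,
                  tau_grid: np.ndarray) -> ImageSeries:
    """Forward pass per tau on the grid; one volume per contrast."""
    vols = np.stack([dfm_forward(x16, float(t), weights) for t in np.atleast_1d(tau_grid)])
    return ImageSeries(volumes=vols)


def ssl_train(ksp: KSpaceData, maps: CoilMaps, schedule: TrainSchedule,
              seed: int = 0, config: DFMConfig | None = None,
              weights: DFMWeights | None = None,
              dc_weighted: bool = True) -> TrainResult:
    """Single-shot self-supervised training on one scan's k-space data.

    Normalizes the data (unit composite peak), then runs the annealing
    stages of ``schedule``, carrying the weights across stages; returns
    the trained weights and the rendered series at every contrast.
    """
    if config is None:
        config = DFMConfig(ndim=ksp.traj.coords.shape[-1])
    ksp, scale = normalize_kspace(ksp, maps=maps, grid_shape=maps.grid_shape)
    rng = np.random.default_rng(seed)
    if weights is None:
        weights = init_dfm(config, seed=seed)
    loss_log: list[dict] = []
    x16 = None
    for i, stage in enumerate(schedule.stages):
        x16 = _run_stage(weights, stage, ksp, maps, rng, loss_log, i,
                         dc_weighted=dc_weighted)
    weights.metadata["normalization_scale"] = scale
    n = ksp.n_contrasts
    tau_grid = np.arange(n) / max(n - 1, 1)
    series = render_series(weights, x16, tau_grid)
    return TrainResult(weights=weights, series=series, loss_log=loss_log,
                       scale=scale, gamma=x16)


def transfer_learn(pretrained: DFMWeights, ksp: KSpaceData, maps: CoilMaps,
                   seed: int = 0, schedule: TrainSchedule | None = None
                   ) -> TrainResult:
    """Adapt pretrained weights to a new scan: final schedule stage only.

    The subsampling rate of the new scan should match the pretraining
    scan so the gamma input statistics are comparable.
    """
    if schedule is None:
        schedule = TrainSchedule.desk(matrix_size=maps.grid_shape[0])
    if pretrained.config.ndim != ksp.traj.coords.shape[-1]:
        raise ValueError("architecture dimensionality mismatch")
    final_only = TrainSchedule(stages=(schedule.final_stage,))
    return ssl_train(ksp, maps, final_only, seed=seed,
                     config=pretrained.config, weights=pretrained.copy())
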