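"""Next-step prediction training with biological regularization.

The model is fit per subject and per condition by minimizing the mean
squared one-step prediction error plus a biological penalty (squared Dale
violations, squared time-constant excursions, and an L1 sparsity term on all
coupling matrices).  Optimization is decoupled-weight-decay Adam (AdamW)
over truncated-backpropagation windows, with hard constraint projections
(sign clamps, time-constant clipping, mask re-zeroing) applied after every
update so the fitted model is exactly Dale-compliant at all times.

Gradients are computed analytically by backpropagation through the unrolled
Euler dynamics (see ``_window_gradients``); the test suite checks them
against central finite differences.
"""

from __future__ import annotations

import dataclasses

import numba
import numpy as np

from .core import (
    TAU_BOUNDS,
    BIRNNParameters,
    BIRNNState,
    InitConfig,
    apply_dales_law,
    clamp_time_constants,
    init_parameters,
)
from .parcel_pipeline import NetworkProjection, ParcelTimeSeries

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "TrainingError",
    "bio_regularizer",
    "loss",
    "train_subject_condition",
    "constraint_violations",
]

#: Parameters updated by the optimizer.
LEARNABLE = (
    "W_EE", "W_EI", "W_IE", "W_net", "b_net", "W_out_gain",
    "tau_E", "tau_I", "tau_A", "beta", "readout_gain", "readout_offset",
)


class TrainingError(RuntimeError):
    def __init__(self, epoch: int, msg: str = "non-finite loss"):
        super().__init__(f"{msg} at epoch {epoch}")
        self.epoch = epoch


@dataclasses.dataclass
class TrainingConfig:
    """Optimization settings; defaults are the reference training recipe."""

    learning_rate: float = 5e-4
    weight_decay: float = 1e-5
    max_epochs: int = 150
    scheduler_patience: int = 15
    scheduler_factor: float = 0.8
    early_stop_patience: int = 20
    l1_lambda: float = 1e-3
    bio_lambda: float = 1.0
    validation_fraction: float = 0.2
    window: int = 200
    #: chronological windows with carried-over state (classic truncated
    #: backpropagation).  When True, windows are instead visited in
    #: seed-shuffled order with initial states cached from a whole-series
    #: pass at the top of the epoch.
    shuffle_windows: bool = False
    #: warm-start the network coupling matrix from a lag-1 linear
    #: autoregression of the network-aggregated training series (scaled to
    #: ``wnet_warm_scale`` max magnitude).  The linear estimate's signed
    #: pattern seeds gradient descent near the right basin; magnitudes are
    #: refined by the fit.  Set scale to 0 to start from zero instead.
    wnet_warm_scale: float = 0.5
    #: number of initial epochs during which the network coupling matrix is
    #: held at its warm start while the parcel-level parameters and readout
    #: mature around it (0 disables the freeze phase)
    wnet_freeze_epochs: int = 0
    improvement_tol: float = 1e-4  # relative val-loss decrease counting as progress
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    init: InitConfig = dataclasses.field(default_factory=InitConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0 or not 0 < self.validation_fraction < 1:
            raise ValueError("rates and fractions must be positive")
        if self.window < 2:
            raise ValueError("window must be at least 2 samples")


@dataclasses.dataclass
class TrainingHistory:
    """Per-epoch record of the fit (epoch 0 is the initial parameter set)."""

    train_loss: list[float] = dataclasses.field(default_factory=list)
    val_loss: list[float] = dataclasses.field(default_factory=list)
    learning_rate: list[float] = dataclasses.field(default_factory=list)
    violations: list[int] = dataclasses.field(default_factory=list)
    best_epoch: int = 0


def constraint_violations(params: BIRNNParameters) -> int:
    """Count of Dale-sign and time-constant-range violations (0 when the
    projections have been applied)."""
    n = int(np.sum(params.W_EE < 0)) + int(np.sum(params.W_EI < 0))
    n += int(np.sum(params.W_IE > 0))
    for pop, tau in (("E", params.tau_E), ("I", params.tau_I), ("A", params.tau_A)):
        lo, hi = TAU_BOUNDS[pop]
        n += int(np.sum((tau < lo) | (tau > hi)))
    return n


def _tau_excursion(tau: np.ndarray, pop: str) -> np.ndarray:
    lo, hi = TAU_BOUNDS[pop]
    return np.maximum(tau - hi, 0.0) + np.minimum(tau - lo, 0.0)


def bio_regularizer(params: BIRNNParameters, config: TrainingConfig) -> float:
    """Biological penalty: squared Dale violations + squared time-constant
    excursions + ``l1_lambda`` times the L1 norm of all coupling matrices.

    Zero iff the parameters are fully compliant and every coupling weight is
    zero (the L1 term's zero point).
    """
    dale = (
        np.sum(np.minimum(params.W_EE, 0.0) ** 2)
        + np.sum(np.minimum(params.W_EI, 0.0) ** 2)
        + np.sum(np.maximum(params.W_IE, 0.0) ** 2)
    )
    tau = sum(
        np.sum(_tau_excursion(t, p) ** 2)
        for t, p in ((params.tau_E, "E"), (params.tau_I, "I"), (params.tau_A, "A"))
    )
    l1 = config.l1_lambda * (
        np.abs(params.W_EE).sum()
        + np.abs(params.W_EI).sum()
        + np.abs(params.W_IE).sum()
        + np.abs(params.W_net).sum()
    )
    return float(dale + tau + l1)


def loss(
    predicted: np.ndarray,
    observed: np.ndarray,
    params: BIRNNParameters,
    config: TrainingConfig,
) -> float:
    """Objective: mean squared prediction error plus ``bio_lambda`` times the
    biological regularizer."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError(
            f"shape mismatch: predicted {predicted.shape} vs observed {observed.shape}"
        )
    mse = float(np.mean((predicted - observed) ** 2))
    return mse + config.bio_lambda * bio_regularizer(params, config)


# ---------------------------------------------------------------------------
# analytic gradients through the unrolled dynamics (numba-compiled kernels)
# ---------------------------------------------------------------------------

@numba.njit(cache=True)
def _window_kernel(
    xT,            # (L+1, P) inputs; rows 1..L are targets
    hE0, hI0, hA0, hnet0,
    W_EE, W_EI, W_IE, W_net, b_net,
    wout_gain, pattern, W_in,
    a_E, a_I, a_A, beta, r_gain, r_off,
):
    Lp1, P = xT.shape
    L = Lp1 - 1
    K = W_net.shape[0]
    W_out = pattern * wout_gain
    hE = np.empty((L + 1, P)); hI = np.empty((L + 1, P)); hA = np.empty((L + 1, P))
    hnet = np.empty((L + 1, K))
    hE[0] = hE0; hI[0] = hI0; hA[0] = hA0; hnet[0] = hnet0
    sE = np.empty((L, P)); sI = np.empty((L, P))
    resid = np.empty((L, P))
    mse = 0.0
    for t in range(L):
        I_E = (
            xT[t] + W_out @ hnet[t] + W_EE @ hE[t] + W_IE @ hI[t] - beta * hA[t]
        )
        sE[t] = 1.0 / (1.0 + np.exp(-I_E))
        sI[t] = 1.0 / (1.0 + np.exp(-(W_EI @ hE[t])))
        hE[t + 1] = hE[t] + a_E * (sE[t] - hE[t])
        hI[t + 1] = hI[t] + a_I * (sI[t] - hI[t])
        hA[t + 1] = hA[t] + a_A * (hE[t] - hA[t])
        hnet[t + 1] = np.tanh(W_in @ xT[t] + W_net @ hnet[t] + b_net)
        r = r_gain * hE[t + 1] + r_off - xT[t + 1]
        resid[t] = r
        mse += r @ r
    mse /= P * L

    gWEE = np.zeros((P, P)); gWEI = np.zeros((P, P)); gWIE = np.zeros((P, P))
    gWnet = np.zeros((K, K)); gbnet = np.zeros(K); ggain = np.zeros(K)
    g_aE = np.zeros(P); g_aI = np.zeros(P); g_aA = np.zeros(P)
    g_rg = np.zeros(P); g_ro = np.zeros(P)
    gbeta = 0.0
    dE = np.zeros(P); dI = np.zeros(P); dA = np.zeros(P); dnet = np.zeros(K)
    W_EE_T = W_EE.T.copy(); W_EI_T = W_EI.T.copy(); W_IE_T = W_IE.T.copy()
    W_net_T = W_net.T.copy(); pattern_T = pattern.T.copy()
    dl_scale = 2.0 / (P * L)
    for t in range(L - 1, -1, -1):
        dpred = dl_scale * resid[t]
        g_rg += dpred * hE[t + 1]
        g_ro += dpred
        dE_next = dE + r_gain * dpred
        dI_next = dI
        dA_next = dA
        dnet_next = dnet

        dIE = dE_next * a_E * sE[t] * (1.0 - sE[t])
        dU = dI_next * a_I * sI[t] * (1.0 - sI[t])
        dz = dnet_next * (1.0 - hnet[t + 1] ** 2)

        g_aE += dE_next * (sE[t] - hE[t])
        g_aI += dI_next * (sI[t] - hI[t])
        g_aA += dA_next * (hE[t] - hA[t])

        gWEE += np.outer(dIE, hE[t])
        gWIE += np.outer(dIE, hI[t])
        gWEI += np.outer(dU, hE[t])
        gWnet += np.outer(dz, hnet[t])
        gbnet += dz
        gbeta -= dIE @ hA[t]
        pat_dIE = pattern_T @ dIE
        ggain += pat_dIE * hnet[t]

        dE = (1.0 - a_E) * dE_next + W_EE_T @ dIE + W_EI_T @ dU + a_A * dA_next
        dI = (1.0 - a_I) * dI_next + W_IE_T @ dIE
        dA = (1.0 - a_A) * dA_next - beta * dIE
        dnet = W_net_T @ dz + wout_gain * pat_dIE
    return (
        mse, gWEE, gWEI, gWIE, gWnet, gbnet, ggain,
        g_aE, g_aI, g_aA, gbeta, g_rg, g_ro,
        hE[L], hI[L], hA[L], hnet[L],
    )


def _window_gradients(
    params: BIRNNParameters,
    projection: NetworkProjection,
    x: np.ndarray,
    init_state: BIRNNState,
    config: TrainingConfig,
):
    """Forward/backward pass over one window.

    ``x`` has shape ``(P, L+1)``: samples 0..L-1 are consumed, samples 1..L
    are prediction targets.  Returns ``(window_mse, grads)`` where ``grads``
    maps learnable names to arrays (mask-projected for the sparse matrices,
    regularizer gradients included).
    """
    a_E = params.dt / params.tau_E
    a_I = params.dt / params.tau_I
    a_A = params.dt / params.tau_A
    (
        mse, gWEE, gWEI, gWIE, gWnet, gbnet, ggain,
        g_aE, g_aI, g_aA, gbeta, g_rg, g_ro,
        fE, fI, fA, fN,
    ) = _window_kernel(
        np.ascontiguousarray(x.T),
        init_state.h_E, init_state.h_I, init_state.h_A, init_state.h_net,
        params.W_EE, params.W_EI, params.W_IE, params.W_net, params.b_net,
        params.W_out_gain, projection.W_out_pattern, projection.W_in,
        a_E, a_I, a_A, params.beta, params.readout_gain, params.readout_offset,
    )
    g = {
        "W_EE": gWEE, "W_EI": gWEI, "W_IE": gWIE, "W_net": gWnet,
        "b_net": gbnet, "W_out_gain": ggain, "beta": float(gbeta),
        "readout_gain": g_rg, "readout_offset": g_ro,
    }
    # chain rule dt/tau -> tau
    g["tau_E"] = g_aE * (-params.dt / params.tau_E ** 2)
    g["tau_I"] = g_aI * (-params.dt / params.tau_I ** 2)
    g["tau_A"] = g_aA * (-params.dt / params.tau_A ** 2)
    final_state = BIRNNState(fE, fI, fA, fN)
    mse = float(mse)

    # biological regularizer gradients
    lam = config.bio_lambda
    l1 = config.l1_lambda
    g["W_EE"] += lam * (2.0 * np.minimum(params.W_EE, 0.0) + l1 * np.sign(params.W_EE))
    g["W_EI"] += lam * (2.0 * np.minimum(params.W_EI, 0.0) + l1 * np.sign(params.W_EI))
    g["W_IE"] += lam * (2.0 * np.maximum(params.W_IE, 0.0) + l1 * np.sign(params.W_IE))
    g["W_net"] += lam * l1 * np.sign(params.W_net)
    for name, pop in (("tau_E", "E"), ("tau_I", "I"), ("tau_A", "A")):
        g[name] += lam * 2.0 * _tau_excursion(getattr(params, name), pop)

    # gradients never point out of the sparsity pattern
    g["W_EE"] *= params.mask_EE
    g["W_EI"] *= params.mask_EI
    g["W_IE"] *= params.mask_IE
    return mse, g, final_state


class _AdamW:
    """Minimal decoupled-weight-decay Adam over a dict of named arrays."""

    def __init__(self, params: BIRNNParameters, config: TrainingConfig):
        self.lr = config.learning_rate
        self.wd = config.weight_decay
        self.b1, self.b2 = config.adam_betas
        self.eps = config.adam_eps
        self.t = 0
        self.m = {n: np.zeros_like(np.asarray(getattr(params, n), dtype=float))
                  for n in LEARNABLE}
        self.v = {n: np.zeros_like(self.m[n]) for n in LEARNABLE}

    def update(self, params: BIRNNParameters, grads: dict) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for n in LEARNABLE:
            gr = np.asarray(grads[n], dtype=float)
            self.m[n] = self.b1 * self.m[n] + (1.0 - self.b1) * gr
            self.v[n] = self.b2 * self.v[n] + (1.0 - self.b2) * gr ** 2
            theta = np.asarray(getattr(params, n), dtype=float)
            step_arr = self.m[n] / c1 / (np.sqrt(self.v[n] / c2) + self.eps)
            theta = theta - self.lr * step_arr - self.lr * self.wd * theta
            setattr(params, n, float(theta) if np.ndim(theta) == 0 else theta)


def _wnet_warm_start(
    x_train: np.ndarray, projection: NetworkProjection, scale: float
) -> np.ndarray:
    """Signed warm start for the network coupling matrix.

    Least-squares lag-1 autoregression of the network-aggregated training
    series, rescaled so its largest coefficient has magnitude ``scale``.
    """
    z = projection.W_in @ x_train
    z = z - z.mean(axis=1, keepdims=True)
    sd = np.maximum(z.std(axis=1, keepdims=True), 1e-12)
    z = z / sd
    Z0, Z1 = z[:, :-1], z[:, 1:]
    gram = Z0 @ Z0.T
    gram += 1e-9 * np.eye(gram.shape[0])
    A = Z1 @ Z0.T @ np.linalg.inv(gram)
    peak = np.abs(A).max()
    if peak <= 0:
        return np.zeros_like(A)
    return A * (scale / peak)


#: bounds for the per-network feedback gain: non-negative, and capped so
#: the top-down pathway stays modulatory (an unbounded gain lets the fit
#: substitute an amplified memoryless network projection for genuine
#: recurrent coupling)
WOUT_GAIN_BOUNDS = (0.0, 2.0)


def _project(params: BIRNNParameters) -> BIRNNParameters:
    """Hard constraint projection applied after every optimizer update."""
    out = clamp_time_constants(apply_dales_law(params))
    out.W_out_gain = np.clip(out.W_out_gain, *WOUT_GAIN_BOUNDS)
    out.beta = max(float(out.beta), 0.0)
    return out


@numba.njit(cache=True)
def _full_pass_kernel(
    xT, split, starts,
    W_EE, W_EI, W_IE, W_net, b_net,
    wout_gain, pattern, W_in,
    a_E, a_I, a_A, beta, r_gain, r_off,
):
    T, P = xT.shape
    K = W_net.shape[0]
    W_out = pattern * wout_gain
    hE = np.zeros(P); hI = np.zeros(P); hA = np.zeros(P); hnet = np.zeros(K)
    n_starts = starts.shape[0]
    cE = np.empty((n_starts, P)); cI = np.empty((n_starts, P))
    cA = np.empty((n_starts, P)); cN = np.empty((n_starts, K))
    si = 0
    if n_starts > 0 and starts[0] == 0:
        cE[0] = hE; cI[0] = hI; cA[0] = hA; cN[0] = hnet
        si = 1
    sse_train = 0.0
    sse_val = 0.0
    for t in range(T - 1):
        I_E = xT[t] + W_out @ hnet + W_EE @ hE + W_IE @ hI - beta * hA
        sE = 1.0 / (1.0 + np.exp(-I_E))
        sI_ = 1.0 / (1.0 + np.exp(-(W_EI @ hE)))
        hE_new = hE + a_E * (sE - hE)
        hI = hI + a_I * (sI_ - hI)
        hA = hA + a_A * (hE - hA)
        hnet = np.tanh(W_in @ xT[t] + W_net @ hnet + b_net)
        hE = hE_new
        r = r_gain * hE + r_off - xT[t + 1]
        err = r @ r
        if t + 1 < split:
            sse_train += err
        else:
            sse_val += err
        if si < n_starts and t + 1 == starts[si]:
            cE[si] = hE; cI[si] = hI; cA[si] = hA; cN[si] = hnet
            si += 1
    return sse_train, sse_val, cE, cI, cA, cN


def _full_pass(
    params: BIRNNParameters,
    projection: NetworkProjection,
    x: np.ndarray,
    split: int,
    window_starts: list[int],
):
    """One rollout over the whole standardized series (states start at zero).

    Returns train MSE (targets before ``split``), validation MSE (targets at
    and after ``split``), and the state at each training-window start, used
    as the carried-in initial states for the next round of truncated
    backpropagation.
    """
    P, T = x.shape
    starts = np.asarray(sorted(window_starts), dtype=np.int64)
    sse_train, sse_val, cE, cI, cA, cN = _full_pass_kernel(
        np.ascontiguousarray(x.T), split, starts,
        params.W_EE, params.W_EI, params.W_IE, params.W_net, params.b_net,
        params.W_out_gain, projection.W_out_pattern, projection.W_in,
        params.dt / params.tau_E, params.dt / params.tau_I,
        params.dt / params.tau_A,
        params.beta, params.readout_gain, params.readout_offset,
    )
    cache = {
        int(s): BIRNNState(cE[i].copy(), cI[i].copy(), cA[i].copy(), cN[i].copy())
        for i, s in enumerate(starts)
    }
    n_train = split - 1
    n_val = T - split
    return (
        float(sse_train) / (P * n_train),
        float(sse_val) / (P * max(n_val, 1)),
        cache,
    )


def train_subject_condition(
    series: ParcelTimeSeries,
    projection: NetworkProjection,
    config: TrainingConfig | None = None,
    distances: np.ndarray | None = None,
) -> tuple[BIRNNParameters, TrainingHistory]:
    """Fit the model to one subject/condition recording.

    The series is z-scored per parcel using statistics of the chronological
    training split (the first ``1 - validation_fraction`` of samples; the
    held-out tail is the validation segment).  Each epoch processes
    fixed-length truncated-backpropagation windows of the training segment
    in seed-shuffled order, one AdamW update per window, with constraint
    projections after every update.  Initial window states are the states
    reached by the current model in a full pass at the start of the epoch.

    Learning rate is multiplied by ``scheduler_factor`` when the validation
    MSE fails to improve (relative decrease > ``improvement_tol``) for
    ``scheduler_patience`` consecutive epochs; training stops after
    ``early_stop_patience`` epochs without improvement and the best
    parameters (lowest validation MSE) are restored.  Deterministic given
    ``config.seed``.
    """
    config = config or TrainingConfig()
    config.validate()
    x_raw = series.values
    P, T = x_raw.shape
    split = int(round(T * (1.0 - config.validation_fraction)))
    if split < config.window + 2 or T - split < 2:
        raise ValueError("series too short for the train/validation split")
    mu = x_raw[:, :split].mean(axis=1, keepdims=True)
    sd = x_raw[:, :split].std(axis=1, keepdims=True)
    sd = np.maximum(sd, 1e-8)
    x = (x_raw - mu) / sd

    params = init_parameters(
        P, projection.n_networks, projection, config.init, seed=config.seed,
        distances=distances,
    )
    if config.wnet_warm_scale > 0:
        params.W_net = _wnet_warm_start(
            x[:, :split], projection, config.wnet_warm_scale
        )
    params = _project(params)
    opt = _AdamW(params, config)
    W = config.window
    window_starts = [s for s in range(0, split - W, W)]

    history = TrainingHistory()
    train_mse, val_mse, cache = _full_pass(params, projection, x, split, window_starts)
    reg = config.bio_lambda * bio_regularizer(params, config)
    history.train_loss.append(train_mse + reg)
    history.val_loss.append(val_mse)
    history.learning_rate.append(opt.lr)
    history.violations.append(constraint_violations(params))

    best_val = val_mse
    best_params = params.copy()
    history.best_epoch = 0
    no_improve = 0
    sched_no_improve = 0

    for epoch in range(1, config.max_epochs + 1):
        if config.shuffle_windows:
            order = np.random.default_rng([config.seed, epoch]).permutation(
                len(window_starts)
            )
        else:
            order = np.arange(len(window_starts))
        carried = BIRNNState.zeros(P, projection.n_networks)
        for wi in order:
            s = window_starts[wi]
            init = cache[s] if config.shuffle_windows else carried
            mse, grads, final_state = _window_gradients(
                params, projection, x[:, s : s + W + 1], init, config
            )
            if not np.isfinite(mse):
                raise TrainingError(epoch)
            carried = final_state
            if epoch <= config.wnet_freeze_epochs:
                grads["W_net"] = np.zeros_like(grads["W_net"])
            opt.update(params, grads)
            params = _project(params)
        train_mse, val_mse, cache = _full_pass(
            params, projection, x, split, window_starts
        )
        if not np.isfinite(val_mse):
            raise TrainingError(epoch)
        reg = config.bio_lambda * bio_regularizer(params, config)
        history.train_loss.append(train_mse + reg)
        history.val_loss.append(val_mse)
        history.learning_rate.append(opt.lr)
        history.violations.append(constraint_violations(params))

        improved = val_mse < best_val * (1.0 - config.improvement_tol)
        if improved:
            best_val = val_mse
            best_params = params.copy()
            history.best_epoch = epoch
            no_improve = 0
            sched_no_improve = 0
        else:
            no_improve += 1
            sched_no_improve += 1
            if sched_no_improve >= config.scheduler_patience:
                opt.lr *= config.scheduler_factor
                sched_no_improve = 0
            if no_improve >= config.early_stop_patience:
                break

    return best_params, history
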