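"""Constrained recurrent neural-mass model: parameters, dynamics, projections.

Each cortical parcel carries three population states — excitatory ``h_E``,
inhibitory ``h_I`` and a slow adaptation variable ``h_A`` — evolving under
first-order rate equations (forward Euler, step ``dt`` = one sample).  A
low-dimensional recurrent network state ``h_net`` (one component per
canonical large-scale network) feeds back onto the parcels, and its 4 x 4
recurrence matrix ``W_net`` is the signed, directed effective-connectivity
summary the model is trained to expose.

Architectural constraints keep the fit physiologically interpretable:
Dale's law (excitatory couplings non-negative, inhibitory-to-excitatory
non-positive), bounded population time constants, and sparsity masks on the
parcel-level coupling matrices.  The constraint projections here are applied
after every optimizer update during training.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .parcel_pipeline import NetworkProjection, ParcelTimeSeries

__all__ = [
    "TAU_BOUNDS",
    "InitConfig",
    "BIRNNParameters",
    "BIRNNState",
    "init_parameters",
    "make_sparsity_mask",
    "excitatory_input",
    "step",
    "forward",
    "apply_dales_law",
    "clamp_time_constants",
    "sigmoid",
]

#: Physiological ranges for the population time constants, in milliseconds.
#: Excitatory membrane/synaptic scales ~5-30 ms, inhibitory ~10-100 ms,
#: adaptation (after-hyperpolarization / fatigue) ~50-500 ms.
TAU_BOUNDS: dict[str, tuple[float, float]] = {
    "E": (5.0, 30.0),
    "I": (10.0, 100.0),
    "A": (50.0, 500.0),
}


class ConfigError(ValueError):
    """Invalid model or initialization configuration."""


class StabilityError(ValueError):
    """Euler step too large for the smallest time constant (dt/tau > 1)."""


class DivergenceError(FloatingPointError):
    """Non-finite state encountered during a rollout."""

    def __init__(self, t: int):
        super().__init__(f"non-finite state at time index {t}")
        self.t = t


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Logistic firing-rate nonlinearity, numerically safe for large |x|."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclasses.dataclass
class InitConfig:
    """Initialization settings for :func:`init_parameters`.

    ``weight_scale`` sets the magnitude of the half-normal draws for the
    parcel coupling matrices; ``density`` is the fraction of retained
    connections in each sparsity mask.  Time-constant init ranges must lie
    inside :data:`TAU_BOUNDS`; inhibitory kinetics are initialized slower
    than excitatory ones.
    """

    density: float = 0.3
    weight_scale: float = 0.1
    tau_E_init: tuple[float, float] = (8.0, 20.0)
    tau_I_init: tuple[float, float] = (25.0, 80.0)
    tau_A_init: tuple[float, float] = (100.0, 300.0)
    beta_init: float = 0.5
    #: initial slope of the affine observation readout (per parcel).
    readout_gain_init: float = 1.0
    #: scale of the random normal initialization of the network-coupling
    #: matrix (0 starts it at zero)
    wnet_init_scale: float = 0.0
    dt: float = 1.0

    def validate(self) -> None:
        if not 0.0 < self.density <= 1.0:
            raise ConfigError("density must lie in (0, 1]")
        for name, (lo, hi) in (
            ("tau_E_init", self.tau_E_init),
            ("tau_I_init", self.tau_I_init),
            ("tau_A_init", self.tau_A_init),
        ):
            pop = name.split("_")[1]
            blo, bhi = TAU_BOUNDS[pop]
            if not (blo <= lo < hi <= bhi):
                raise ConfigError(
                    f"{name}={lo, hi} outside physiological range {blo, bhi}"
                )
        if self.beta_init < 0:
            raise ConfigError("beta_init must be non-negative")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")


@dataclasses.dataclass
class BIRNNParameters:
    """All learnable and fixed parameters of the model.

    Matrix orientation: ``W[i, j]`` is the influence of unit ``j`` on unit
    ``i``.  ``W_EE``/``W_EI`` are non-negative, ``W_IE`` non-positive
    (Dale's law); entries removed by the sparsity masks are exactly zero.
    Time constants are in milliseconds and bounded by :data:`TAU_BOUNDS`.
    ``W_out_gain`` scales the fixed membership pattern through which network
    states drive parcels; ``readout_gain``/``readout_offset`` form the
    per-parcel affine map from ``h_E`` to observation units.
    """

    W_EE: np.ndarray
    W_EI: np.ndarray
    W_IE: np.ndarray
    W_net: np.ndarray
    b_net: np.ndarray
    W_out_gain: np.ndarray
    tau_E: np.ndarray
    tau_I: np.ndarray
    tau_A: np.ndarray
    beta: float
    mask_EE: np.ndarray
    mask_EI: np.ndarray
    mask_IE: np.ndarray
    readout_gain: np.ndarray
    readout_offset: np.ndarray
    dt: float = 1.0

    @property
    def n_parcels(self) -> int:
        return self.W_EE.shape[0]

    @property
    def n_networks(self) -> int:
        return self.W_net.shape[0]

    def copy(self) -> "BIRNNParameters":
        kw = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            kw[f.name] = v.copy() if isinstance(v, np.ndarray) else v
        return BIRNNParameters(**kw)

    def validate(self) -> None:
        if np.any(self.W_EE < 0) or np.any(self.W_EI < 0):
            raise ValueError("excitatory couplings must be non-negative")
        if np.any(self.W_IE > 0):
            raise ValueError("inhibitory-to-excitatory couplings must be non-positive")
        for pop, tau in (("E", self.tau_E), ("I", self.tau_I), ("A", self.tau_A)):
            lo, hi = TAU_BOUNDS[pop]
            if np.any(tau < lo) or np.any(tau > hi):
                raise ValueError(f"tau_{pop} outside [{lo}, {hi}] ms")
            if np.any(self.dt / tau > 1.0):
                raise StabilityError(f"dt/tau_{pop} exceeds 1")
        for name in ("EE", "EI", "IE"):
            w = getattr(self, f"W_{name}")
            m = getattr(self, f"mask_{name}")
            if np.any(w[m == 0] != 0.0):
                raise ValueError(f"W_{name} has nonzero entries outside its mask")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if np.any(self.W_out_gain < 0):
            raise ValueError("W_out_gain must be non-negative")

    def W_out(self, projection: NetworkProjection) -> np.ndarray:
        """Network-to-parcel feedback matrix: membership pattern scaled per
        network by ``W_out_gain``."""
        return projection.W_out_pattern * self.W_out_gain[None, :]


@dataclasses.dataclass
class BIRNNState:
    """Population states per parcel plus the recurrent network state."""

    h_E: np.ndarray
    h_I: np.ndarray
    h_A: np.ndarray
    h_net: np.ndarray

    def copy(self) -> "BIRNNState":
        return BIRNNState(
            self.h_E.copy(), self.h_I.copy(), self.h_A.copy(), self.h_net.copy()
        )

    @classmethod
    def zeros(cls, n_parcels: int, n_networks: int) -> "BIRNNState":
        return cls(
            np.zeros(n_parcels), np.zeros(n_parcels),
            np.zeros(n_parcels), np.zeros(n_networks),
        )


def make_sparsity_mask(
    n: int,
    density: float,
    distances: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Binary connectivity mask with exactly ``round(density * n**2)`` ones.

    The diagonal (local recurrence) is always retained within the budget.
    When a parcel-distance matrix is supplied, off-diagonal retention
    probability decays sharply with distance (decay constant = median
    distance / 4), disfavouring implausible long-range couplings; otherwise
    retention is uniform.  Deterministic given ``seed``.
    """
    if not 0.0 < density <= 1.0:
        raise ConfigError("density must lie in (0, 1]")
    k = int(round(density * n * n))
    rng = np.random.default_rng(seed)
    mask = np.zeros((n, n))
    if k >= n:
        mask[np.diag_indices(n)] = 1.0
        n_off = k - n
        rows, cols = np.where(~np.eye(n, dtype=bool))
        if n_off > 0:
            if distances is not None:
                d = np.asarray(distances, dtype=float)[rows, cols]
                scale = np.median(d[d > 0]) if np.any(d > 0) else 1.0
                w = np.exp(-4.0 * d / scale)
                p = w / w.sum()
            else:
                p = None
            chosen = rng.choice(rows.size, size=n_off, replace=False, p=p)
            mask[rows[chosen], cols[chosen]] = 1.0
    else:
        diag = rng.choice(n, size=k, replace=False)
        mask[diag, diag] = 1.0
    return mask


def init_parameters(
    n_parcels: int,
    n_networks: int,
    projection: NetworkProjection | None = None,
    config: InitConfig | None = None,
    seed: int = 0,
    distances: np.ndarray | None = None,
) -> BIRNNParameters:
    """Draw a Dale-compliant initial parameter set.

    Parcel couplings are sparse half-normal magnitudes with the correct
    signs; inhibitory time constants start slower than excitatory ones;
    ``W_net`` and ``b_net`` start at zero so that all network-level coupling
    is learned from data.  Deterministic given ``seed``.
    """
    if n_parcels <= 0 or n_networks <= 0:
        raise ConfigError("counts must be positive")
    config = config or InitConfig()
    config.validate()
    ss = np.random.SeedSequence(seed)
    s_mask, s_weights, s_tau = ss.spawn(3)
    if distances is not None:
        # the anatomical prior is a property of the atlas geometry, not of
        # the subject or fit: fixed mask seeds make every model of the same
        # atlas share one connectivity scaffold
        mask_seeds = (101, 102, 103)
    else:
        mask_seeds = s_mask.generate_state(3)
    masks = {
        name: make_sparsity_mask(n_parcels, config.density, distances, int(ms))
        for name, ms in zip(("EE", "EI", "IE"), mask_seeds)
    }
    rng = np.random.default_rng(s_weights)
    scale = config.weight_scale
    W_EE = np.abs(rng.normal(0, scale, (n_parcels, n_parcels))) * masks["EE"]
    W_EI = np.abs(rng.normal(0, scale, (n_parcels, n_parcels))) * masks["EI"]
    W_IE = -np.abs(rng.normal(0, scale, (n_parcels, n_parcels))) * masks["IE"]
    rng_tau = np.random.default_rng(s_tau)
    tau_E = rng_tau.uniform(*config.tau_E_init, n_parcels)
    tau_I = rng_tau.uniform(*config.tau_I_init, n_parcels)
    tau_A = rng_tau.uniform(*config.tau_A_init, n_parcels)
    params = BIRNNParameters(
        W_EE=W_EE,
        W_EI=W_EI,
        W_IE=W_IE,
        W_net=(
            config.wnet_init_scale
            * rng.standard_normal((n_networks, n_networks))
            if config.wnet_init_scale > 0
            else np.zeros((n_networks, n_networks))
        ),
        b_net=np.zeros(n_networks),
        W_out_gain=np.ones(n_networks),
        tau_E=tau_E,
        tau_I=tau_I,
        tau_A=tau_A,
        beta=config.beta_init,
        mask_EE=masks["EE"],
        mask_EI=masks["EI"],
        mask_IE=masks["IE"],
        readout_gain=np.full(n_parcels, config.readout_gain_init),
        readout_offset=np.zeros(n_parcels),
        dt=config.dt,
    )
    params.validate()
    return params


def excitatory_input(
    x_t: np.ndarray,
    state: BIRNNState,
    params: BIRNNParameters,
    projection: NetworkProjection,
) -> np.ndarray:
    """Total synaptic drive to the excitatory populations.

    Five sources: observed activity, top-down network feedback, recurrent
    excitation, recurrent inhibition, and subtractive adaptation::

        I_E = x_t + W_out h_net + W_EE h_E + W_IE h_I - beta * h_A
    """
    x_t = np.asarray(x_t, dtype=float)
    if not np.all(np.isfinite(x_t)):
        raise ValueError("non-finite input x_t")
    return (
        x_t
        + params.W_out(projection) @ state.h_net
        + params.W_EE @ state.h_E
        + params.W_IE @ state.h_I
        - params.beta * state.h_A
    )


def step(
    state: BIRNNState,
    x_t: np.ndarray,
    params: BIRNNParameters,
    projection: NetworkProjection,
) -> BIRNNState:
    """One forward-Euler update of all states.

    Population states integrate using the *previous* network state (which
    enters ``I_E``), then the network state updates from the current input::

        h_E += (dt/tau_E) (-h_E + sigma(I_E))
        h_I += (dt/tau_I) (-h_I + sigma(W_EI h_E))
        h_A += (dt/tau_A) (-h_A + h_E)
        h_net = tanh(W_in x_t + W_net h_net + b_net)

    With ``dt/tau <= 1`` each population update is a convex combination of
    the current state and a bounded target, so states initialized in [0, 1]
    stay there.
    """
    a_E = params.dt / params.tau_E
    a_I = params.dt / params.tau_I
    a_A = params.dt / params.tau_A
    if np.any(a_E > 1) or np.any(a_I > 1) or np.any(a_A > 1):
        raise StabilityError("dt/tau exceeds 1 for some population")
    I_E = excitatory_input(x_t, state, params, projection)
    h_E = state.h_E + a_E * (-state.h_E + sigmoid(I_E))
    h_I = state.h_I + a_I * (-state.h_I + sigmoid(params.W_EI @ state.h_E))
    h_A = state.h_A + a_A * (-state.h_A + state.h_E)
    h_net = np.tanh(
        projection.W_in @ np.asarray(x_t, dtype=float)
        + params.W_net @ state.h_net
        + params.b_net
    )
    return BIRNNState(h_E, h_I, h_A, h_net)


def forward(
    params: BIRNNParameters,
    series: ParcelTimeSeries | np.ndarray,
    projection: NetworkProjection,
    initial_state: BIRNNState | None = None,
    return_states: bool = False,
):
    """Roll the dynamics over a series and emit one-step predictions.

    The prediction for sample ``t+1`` is the affine readout of the updated
    excitatory state after consuming sample ``t``.  Returns an array of
    shape ``(n_parcels, T-1)`` (and optionally the state trajectory,
    ``T`` states including the initial one).  Deterministic given inputs;
    a non-finite state aborts with :class:`DivergenceError`.
    """
    x = series.values if isinstance(series, ParcelTimeSeries) else np.asarray(series)
    n_parcels, T = x.shape
    if T < 2:
        raise ValueError("need at least two samples")
    state = (
        initial_state.copy()
        if initial_state is not None
        else BIRNNState.zeros(n_parcels, params.n_networks)
    )
    preds = np.empty((n_parcels, T - 1))
    states = [state.copy()] if return_states else None
    for t in range(T - 1):
        state = step(state, x[:, t], params, projection)
        if not (
            np.all(np.isfinite(state.h_E)) and np.all(np.isfinite(state.h_net))
        ):
            raise DivergenceError(t)
        preds[:, t] = params.readout_gain * state.h_E + params.readout_offset
        if return_states:
            states.append(state.copy())
    if return_states:
        return preds, states
    return preds


def apply_dales_law(params: BIRNNParameters) -> BIRNNParameters:
    """Project couplings onto the Dale-compliant set (idempotent clamp).

    Negative entries of ``W_EE``/``W_EI`` and positive entries of ``W_IE``
    are set to zero; masked entries stay zero; everything else untouched.
    """
    out = params.copy()
    out.W_EE = np.maximum(out.W_EE, 0.0) * out.mask_EE
    out.W_EI = np.maximum(out.W_EI, 0.0) * out.mask_EI
    out.W_IE = np.minimum(out.W_IE, 0.0) * out.mask_IE
    return out


def clamp_time_constants(
    params: BIRNNParameters,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> BIRNNParameters:
    """Clip each time-constant vector into its physiological range."""
    bounds = bounds or TAU_BOUNDS
    for pop, (lo, hi) in bounds.items():
        if lo >= hi:
            raise ConfigError(f"inverted bounds for tau_{pop}")
    out = params.copy()
    out.tau_E = np.clip(out.tau_E, *bounds["E"])
    out.tau_I = np.clip(out.tau_I, *bounds["I"])
    out.tau_A = np.clip(out.tau_A, *bounds["A"])
    return out
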