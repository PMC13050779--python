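"""Synthetic cohorts from the model's own forward dynamics.

Ground-truth parameter sets with planted network couplings are rolled
forward (closed loop through the observation readout, plus additive white
observation noise) to produce parcel-level cohorts in which every
downstream stage — training, coupling extraction, group statistics, the
Granger baseline — can be scored against a known answer.

The generator is placed in a relaxation-oscillation regime: recurrent
excitation holds each parcel near the steep part of its firing-rate
nonlinearity while slow adaptation provides negative feedback, so the
simulated activity carries strong slow fluctuations rather than being
dominated by observation noise.  Parcels are embedded on a unit sphere in
network clusters and parcel-level couplings are drawn through
distance-informed sparsity masks, so couplings are predominantly
short-range and cross-network interaction flows through the network-state
channel — the structure the planted ``W_net`` is meant to exercise.

Default condition templates plant six strong (|w| >= 1) network couplings
mirroring the qualitative pattern the method is meant to resolve:
salience-network facilitation of both other systems, task-positive
inhibition of the default-mode network that is stronger at rest, and a
task-vs-rest sign flip of the DMN -> SN coupling.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core import (
    BIRNNParameters,
    BIRNNState,
    InitConfig,
    init_parameters,
    make_sparsity_mask,
    sigmoid,
    step,
)
from .parcel_pipeline import NetworkProjection, ParcelTimeSeries
from .synthetic_atlas import default_projection

__all__ = [
    "CohortSpec",
    "Cohort",
    "rest_template",
    "task_template",
    "network_coordinates",
    "generate_ground_truth",
    "simulate_timeseries",
    "generate_cohort",
    "generate_vviq_covariate",
    "simulate_var_pair",
]

_NETWORKS = ("DMN", "TPN", "SN", "Other")


def _template(entries: dict[tuple[str, str], float]) -> np.ndarray:
    """Build a (target, source)-oriented 4x4 template from named entries."""
    w = np.zeros((4, 4))
    for (target, source), v in entries.items():
        w[_NETWORKS.index(target), _NETWORKS.index(source)] = v
    return w


def rest_template() -> np.ndarray:
    """Planted resting-state couplings: strong TPN -> DMN inhibition,
    SN facilitation of DMN/TPN, negative DMN -> SN."""
    return _template(
        {
            ("DMN", "TPN"): -1.5,   # TPN -> DMN, stronger at rest
            ("TPN", "SN"): 1.2,     # SN -> TPN
            ("DMN", "SN"): 1.0,     # SN -> DMN
            ("SN", "DMN"): -1.0,    # DMN -> SN, negative at rest
            ("Other", "SN"): 1.0,
            ("Other", "TPN"): -1.0,
        }
    )


def task_template() -> np.ndarray:
    """Planted task couplings: DMN -> SN flips positive, TPN -> DMN
    inhibition weakens relative to rest."""
    return _template(
        {
            ("DMN", "TPN"): -1.0,
            ("TPN", "SN"): 1.2,
            ("DMN", "SN"): 1.0,
            ("SN", "DMN"): 1.0,     # DMN -> SN, positive during task
            ("Other", "SN"): 1.0,
            ("Other", "TPN"): -1.0,
        }
    )


def network_coordinates(
    projection: NetworkProjection, spread: float = 0.25, seed: int = 0
) -> np.ndarray:
    """Parcel centroids on the unit sphere, clustered by network.

    Network centers sit at tetrahedron vertices; parcels are isotropically
    jittered around their network's center and re-projected to the sphere.
    Used to build distance-informed sparsity masks and (optionally)
    distance-weighted regularization.
    """
    rng = np.random.default_rng(seed)
    centers = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    )
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    names = projection.network_names
    pts = []
    for pid in projection.parcel_ids:
        k = names.index(projection.membership[pid]) % 4
        v = centers[k] + spread * rng.standard_normal(3)
        pts.append(v / np.linalg.norm(v))
    return np.asarray(pts)


@dataclasses.dataclass
class CohortSpec:
    """Study-shaped synthetic cohort specification.

    Defaults emulate the study conditions: 15 subjects, 46 parcels mapped
    to 4 networks, two conditions with distinct planted coupling templates,
    per-subject coupling jitter, and additive white observation noise.
    ``T`` is samples per condition at the model's 1 ms step.

    The row-sum targets ``s_ee``/``s_ei``/``s_ie`` and the adaptation
    strength ``beta`` place the parcel dynamics in the oscillatory
    operating regime (excitatory drive balancing inhibition and adaptation
    at the sigmoid's steep region); ``obs_gain`` is the generation readout
    slope and ``wout_gain`` the strength of network-to-parcel feedback.
    """

    n_subjects: int = 15
    n_parcels: int = 46
    n_networks: int = 4
    T: int = 10_000
    conditions: dict[str, np.ndarray] = dataclasses.field(
        default_factory=lambda: {"task": task_template(), "rest": rest_template()}
    )
    subject_variability_sd: float = 0.2
    noise_sd: float = 0.2
    seed: int = 0
    density: float = 0.3
    s_ee: float = 5.0
    s_ei: float = 2.0
    s_ie: float = 2.7
    beta: float = 4.0
    obs_gain: float = 3.0
    wout_gain: float = 1.5
    tau_E_init: tuple[float, float] = (8.0, 20.0)
    tau_I_init: tuple[float, float] = (25.0, 80.0)
    #: per-network adaptation ranges (ms); one entry per network, all equal
    #: by default (the slow-fatigue timescale that sets the relaxation
    #: oscillation period)
    tau_A_bands: tuple[tuple[float, float], ...] = ((60.0, 120.0),) * 4
    drive: str = "closed_loop"  # or "pink"

    def validate(self) -> None:
        if min(self.n_subjects, self.n_parcels, self.n_networks, self.T) <= 0:
            raise ValueError("counts must be positive")
        if self.noise_sd < 0 or self.subject_variability_sd < 0:
            raise ValueError("noise and jitter SDs must be non-negative")
        for name, tpl in self.conditions.items():
            if np.asarray(tpl).shape != (self.n_networks, self.n_networks):
                raise ValueError(f"template for {name!r} has wrong shape")
        if self.drive not in ("closed_loop", "pink"):
            raise ValueError("drive must be 'closed_loop' or 'pink'")


@dataclasses.dataclass
class Cohort:
    """Simulated series plus the ground-truth parameter registry."""

    spec: CohortSpec
    projection: NetworkProjection
    series: dict[tuple[str, str], ParcelTimeSeries]
    registry: dict[tuple[str, str], BIRNNParameters]
    distances: np.ndarray | None = None

    @property
    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self.series})


def _condition_index(spec: CohortSpec, condition: str) -> int:
    try:
        return list(spec.conditions).index(condition)
    except ValueError:
        raise KeyError(f"condition {condition!r} not in spec") from None


def spec_distances(
    spec: CohortSpec, projection: NetworkProjection
) -> np.ndarray:
    """Pairwise parcel distances of the atlas embedding.

    The embedding is a fixed property of the atlas (like the membership
    table), not of the cohort draw, so it does not vary with the spec seed.
    """
    coords = network_coordinates(projection, seed=0)
    return np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)


def generate_ground_truth(
    spec: CohortSpec,
    condition: str,
    subject_index: int = 0,
    projection: NetworkProjection | None = None,
    distances: np.ndarray | None = None,
) -> BIRNNParameters:
    """Ground-truth parameters for one subject/condition.

    Parcel couplings are sparse half-normal draws through distance-local
    masks, scaled so that each row's expected total matches the spec's
    mean-field targets; time constants are sampled within physiological
    ranges; the network coupling matrix is the condition template plus
    N(0, jitter^2) per-subject noise on every cell.  The observation
    readout offset is calibrated to the network's noise-free operating
    point so observations are zero-mean there.

    The targeted regime is oscillatory in every network (the heterogeneity
    of parcel in-degrees supplies the pacemakers); a draw whose probe
    simulation leaves any network's activity at the observation-noise
    floor is rejected and redrawn, so every generated subject exercises
    all network couplings.  Deterministic per (seed, subject, condition).
    """
    spec.validate()
    projection = projection or default_projection()
    if distances is None:
        distances = spec_distances(spec, projection)
    cond_idx = _condition_index(spec, condition)
    for attempt in range(24):
        params = _draw_ground_truth(
            spec, condition, subject_index, projection, distances, attempt
        )
        if _draw_is_valid(params, spec, projection):
            return params
    raise RuntimeError(
        "could not draw a valid oscillatory parameter set in 24 tries"
    )


def _draw_is_valid(
    params: BIRNNParameters,
    spec: CohortSpec,
    projection: NetworkProjection,
    probe_T: int = 1200,
    min_std_factor: float = 2.0,
    min_wnet_gap: float = 0.15,
) -> bool:
    """Probe simulation validity checks for a ground-truth draw.

    Two requirements define a usable study subject: (i) every network's
    observed activity exceeds ``min_std_factor`` times the observation-
    noise floor (a silent network's couplings are unidentifiable in
    principle), and (ii) the planted network couplings actually shape the
    emitted data — zeroing ``W_net`` must raise the true model's one-step
    prediction error by at least ``min_wnet_gap`` (relative), otherwise
    the draw cannot test coupling recovery at all.
    """
    try:
        probe = simulate_timeseries(
            params, probe_T, spec.noise_sd, 2**20 + 7, projection,
            burn_in=400, drive=spec.drive,
        )
    except FloatingPointError:
        return False
    floor = max(spec.noise_sd, 1e-3) * min_std_factor
    for k in range(projection.n_networks):
        members = projection.W_out_pattern[:, k] > 0
        if probe.values[members].std() < floor:
            return False
    from .core import forward  # local import avoids cycle at module load

    x = probe.values
    preds = forward(params, x, projection)
    mse = float(np.mean((preds - x[:, 1:]) ** 2))
    ablated = params.copy()
    ablated.W_net = np.zeros_like(ablated.W_net)
    preds0 = forward(ablated, x, projection)
    mse0 = float(np.mean((preds0 - x[:, 1:]) ** 2))
    return (mse0 - mse) / mse >= min_wnet_gap


def _draw_ground_truth(
    spec: CohortSpec,
    condition: str,
    subject_index: int,
    projection: NetworkProjection,
    distances: np.ndarray,
    attempt: int,
) -> BIRNNParameters:
    cond_idx = _condition_index(spec, condition)
    ss = np.random.SeedSequence([spec.seed, subject_index, cond_idx, attempt])
    seeds = ss.generate_state(8)
    P = spec.n_parcels
    params = init_parameters(
        P,
        spec.n_networks,
        projection,
        InitConfig(
            density=spec.density,
            weight_scale=0.1,
            tau_E_init=spec.tau_E_init,
            tau_I_init=spec.tau_I_init,
        ),
        seed=int(seeds[0] % (2**31)),
        distances=distances,
    )
    # network-specific adaptation timescales (hierarchy of intrinsic
    # timescales) -> distinct slow rhythms per network
    tau_rng = np.random.default_rng(int(seeds[6] % (2**31)))
    membership_idx = np.argmax(projection.W_out_pattern, axis=1)
    tau_A = np.empty(P)
    for k in range(spec.n_networks):
        lo, hi = spec.tau_A_bands[k % len(spec.tau_A_bands)]
        sel = membership_idx == k
        tau_A[sel] = tau_rng.uniform(lo, hi, sel.sum())
    params.tau_A = tau_A
    # per-entry scale targeting the mean-field row sums in expectation;
    # the resulting degree heterogeneity across parcels is intended (it
    # spreads parcels around the oscillation threshold, as in real cortex)
    per_entry = spec.density * P * np.sqrt(2.0 / np.pi)
    rng = np.random.default_rng(int(seeds[4] % (2**31)))

    def half_normal(row_target: float) -> np.ndarray:
        return np.abs(rng.normal(0.0, row_target / per_entry, (P, P)))

    params.W_EE = half_normal(spec.s_ee) * params.mask_EE
    params.W_EI = half_normal(spec.s_ei) * params.mask_EI
    params.W_IE = -half_normal(spec.s_ie) * params.mask_IE
    params.beta = spec.beta
    template = np.asarray(spec.conditions[condition], dtype=float)
    jitter = np.random.default_rng(int(seeds[5] % (2**31))).normal(
        0.0, spec.subject_variability_sd, template.shape
    )
    params.W_net = template + (
        jitter if spec.subject_variability_sd > 0 else 0.0
    )
    params.W_out_gain = np.full(spec.n_networks, spec.wout_gain)
    params.readout_gain = np.full(P, spec.obs_gain)
    params.readout_offset = -spec.obs_gain * _operating_point(params, projection)
    return params


def _operating_point(
    params: BIRNNParameters, projection: NetworkProjection, iters: int = 4000
) -> np.ndarray:
    """Noise-free excitatory operating point by damped fixed-point
    iteration (with zero observation input, the self-consistent state when
    the readout is centred there)."""
    P = params.n_parcels
    hE = np.full(P, 0.5)
    hI = np.full(P, 0.5)
    hA = np.full(P, 0.5)
    hnet = np.zeros(params.n_networks)
    Wout = projection.W_out_pattern * params.W_out_gain[None, :]
    for _ in range(iters):
        I_E = Wout @ hnet + params.W_EE @ hE + params.W_IE @ hI - params.beta * hA
        hE = 0.98 * hE + 0.02 * sigmoid(I_E)
        hI = 0.98 * hI + 0.02 * sigmoid(params.W_EI @ hE)
        hA = 0.98 * hA + 0.02 * hE
        hnet = 0.98 * hnet + 0.02 * np.tanh(params.W_net @ hnet + params.b_net)
    return hE


def _pink_noise(rng: np.random.Generator, n_series: int, T: int) -> np.ndarray:
    """1/f-amplitude Gaussian noise, unit variance per series."""
    white = rng.standard_normal((n_series, T))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(T)
    freqs[0] = freqs[1]
    spec /= np.sqrt(freqs)
    out = np.fft.irfft(spec, n=T, axis=1)
    out -= out.mean(axis=1, keepdims=True)
    out /= out.std(axis=1, keepdims=True)
    return out


def simulate_timeseries(
    params: BIRNNParameters,
    T: int,
    noise_sd: float,
    seed: int,
    projection: NetworkProjection | None = None,
    subject_id: str = "",
    condition: str = "rest",
    drive: str = "closed_loop",
    burn_in: int = 500,
) -> ParcelTimeSeries:
    """Roll the dynamics forward and emit a noisy observed parcel series.

    In the default closed loop the observation ``x_t = readout(h_E(t)) +
    noise`` is fed back as the model input, so the generated data carries
    the temporal dependence the model assumes.  The ``pink`` drive instead
    feeds exogenous 1/f noise as input while observing the readout.  The
    first ``burn_in`` samples (initial transient) are discarded.
    Deterministic given ``seed``; states stay in their bounded ranges.
    """
    if T < 2:
        raise ValueError("T must be at least 2")
    projection = projection or default_projection()
    P = params.n_parcels
    total = T + burn_in
    rng = np.random.default_rng(seed)
    noise = (
        rng.normal(0.0, noise_sd, (P, total)) if noise_sd > 0
        else np.zeros((P, total))
    )
    exog = _pink_noise(rng, P, total) if drive == "pink" else None
    state = BIRNNState(
        np.full(P, 0.5), np.full(P, 0.5), np.full(P, 0.5),
        np.zeros(params.n_networks),
    )
    x = np.empty((P, total))
    for t in range(total):
        obs = params.readout_gain * state.h_E + params.readout_offset + noise[:, t]
        x[:, t] = obs
        drive_t = obs if drive == "closed_loop" else exog[:, t]
        state = step(state, drive_t, params, projection)
        if not np.all(np.isfinite(state.h_E)):
            raise FloatingPointError(f"simulation diverged at t={t}")
    return ParcelTimeSeries(
        x[:, burn_in:], projection.parcel_ids, 1000.0, subject_id, condition
    )


def generate_cohort(
    spec: CohortSpec, projection: NetworkProjection | None = None
) -> Cohort:
    """Simulate every subject under every condition.

    Returns the series plus the per-subject ground-truth registry used for
    parameter-recovery scoring, and the parcel distance matrix (so model
    fits can use the same anatomical prior).  Deterministic given
    ``spec.seed``.
    """
    spec.validate()
    projection = projection or default_projection()
    if projection.n_parcels != spec.n_parcels:
        raise ValueError("projection parcel count does not match spec")
    distances = spec_distances(spec, projection)
    series: dict[tuple[str, str], ParcelTimeSeries] = {}
    registry: dict[tuple[str, str], BIRNNParameters] = {}
    for s in range(spec.n_subjects):
        sid = f"sub{s:02d}"
        for condition in spec.conditions:
            params = generate_ground_truth(
                spec, condition, s, projection, distances
            )
            cond_idx = _condition_index(spec, condition)
            sim_seed = int(
                np.random.SeedSequence(
                    [spec.seed, s, cond_idx, 1]
                ).generate_state(1)[0] % (2**31)
            )
            series[(sid, condition)] = simulate_timeseries(
                params, spec.T, spec.noise_sd, sim_seed, projection,
                subject_id=sid, condition=condition, drive=spec.drive,
            )
            registry[(sid, condition)] = params
    return Cohort(spec, projection, series, registry, distances)


def generate_vviq_covariate(
    couplings: np.ndarray,
    target_r: float,
    score_range: tuple[int, int] = (16, 80),
    seed: int = 0,
    score_mean: float = 48.0,
    score_sd: float = 11.0,
) -> np.ndarray:
    """Integer questionnaire totals with a planted correlation.

    Emulates a 16-item, 1-5 scale vividness questionnaire (totals in
    [16, 80]).  Scores are an affine map of the standardized coupling
    values mixed with independent noise to hit the target population
    correlation, then rounded and clipped into range.
    """
    if not -1.0 < target_r < 1.0:
        raise ValueError("|target_r| must be < 1")
    c = np.asarray(couplings, dtype=float)
    if c.std() == 0:
        raise ValueError("degenerate coupling variance")
    z = (c - c.mean()) / c.std()
    rng = np.random.default_rng(seed)
    latent = target_r * z + np.sqrt(1.0 - target_r**2) * rng.standard_normal(c.size)
    scores = np.round(score_mean + score_sd * latent)
    return np.clip(scores, *score_range).astype(int)


def simulate_var_pair(
    coupling: float,
    lag: int = 1,
    T: int = 2000,
    seed: int = 0,
    ar: float = 0.5,
    noise_sd: float = 1.0,
    burn_in: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Unidirectional VAR pair: ``x`` white noise drives ``y`` at ``lag``.

    ``y_t = coupling * x_{t-lag} + ar * y_{t-1} + eps``.  Used as the known
    directed-structure oracle input for the Granger baseline.
    """
    if abs(ar) >= 1.0:
        raise ValueError("autoregressive root outside the unit circle")
    if lag < 1:
        raise ValueError("lag must be >= 1")
    rng = np.random.default_rng(seed)
    n = T + burn_in
    x = rng.normal(0.0, noise_sd, n)
    eps = rng.normal(0.0, noise_sd, n)
    y = np.zeros(n)
    for t in range(n):
        y[t] = ar * y[t - 1] + eps[t]
        if t >= lag:
            y[t] += coupling * x[t - lag]
    return x[burn_in:], y[burn_in:]
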