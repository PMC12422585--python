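"""Delay-coupled stochastic Wilson-Cowan network dynamics.

Each brain region k carries an excitatory and an inhibitory population
activity, :math:`E_k(t)` and :math:`I_k(t)`, evolving as

.. math::

   \\tau \\dot E_k = -E_k + (S_{E,max} - r_E E_k)\\,
       S_E\\big(C_{EE}E_k - C_{EI}I_k
       + C_E \\textstyle\\sum_j A_{jk} E_j(t-\\tau^d_{jk}) + P_k\\big)
       + \\sigma w_k(t)

and symmetrically for :math:`I_k` (couplings :math:`C_{IE}, C_{II}`,
global gain :math:`C_I = C_E/4`, no stimulus).  The sigmoid
:math:`S(x) = 1/(1+e^{-a(x-\\theta)}) - 1/(1+e^{a\\theta})` vanishes at
0, so the origin is a fixed point of the noise-free unstimulated
network.  Conduction delays :math:`\\tau^d_{jk}` are Euclidean
distances over a conduction velocity of 10 m/s.

The working point of each connectome is *calibrated to criticality*:
the excitatory global coupling :math:`C_E` is raised until the
unstimulated network leaves its fixed point, and bisection brackets
the quiescent/active boundary.  At that working point a sustained
stimulus :math:`P_k = 1.15` to a single region elicits a
Hopf-bifurcation-like oscillatory response whose spread through the
network is the object of study.

Local parameters default to the classical oscillation-capable
Wilson-Cowan set (C_EE=16, C_EI=12, C_IE=15, C_II=3, a_E=1.3,
theta_E=4, a_I=2, theta_I=3.7, tau=8 ms, r_E=r_I=1); every value is
overridable.  Times are in ms throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from ._kernels import csr_from_dense, wc_integrate
from .connectome import Connectome

__all__ = [
    "WCParams",
    "StimulusSpec",
    "SimConfig",
    "DelayMatrix",
    "StateTrajectory",
    "TuneResult",
    "sigmoid",
    "sigmoid_max",
    "build_delay_matrix",
    "simulate",
    "classify_activity",
    "tune_global_coupling",
    "stimulate_each_region",
]

logger = logging.getLogger(__name__)


class BlowupError(RuntimeError):
    """The integrator produced a non-finite state."""

    def __init__(self, step: int, region: int):
        self.step, self.region = step, region
        super().__init__(
            f"non-finite state at step {step}, region {region}; "
            "the dynamics blew up (check coupling and dt)"
        )


@dataclass(frozen=True)
class WCParams:
    """Wilson-Cowan model parameters.  Times in ms.

    ``C_I`` always equals ``C_E / 4`` (roughly four in five cortical
    neurons are excitatory); it is derived, never set directly.
    """

    tau: float = 8.0
    r_E: float = 1.0
    r_I: float = 1.0
    C_EE: float = 16.0
    C_EI: float = 12.0
    C_IE: float = 15.0
    C_II: float = 3.0
    C_E: float = 1.0
    a_E: float = 1.3
    theta_E: float = 4.0
    a_I: float = 2.0
    theta_I: float = 3.7
    sigma: float = 1e-5
    v_d: float = 10.0  # conduction velocity, m/s

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.v_d <= 0:
            raise ValueError("v_d must be > 0")

    @property
    def C_I(self) -> float:
        return self.C_E / 4.0

    def with_coupling(self, C_E: float) -> "WCParams":
        return replace(self, C_E=float(C_E))


@dataclass(frozen=True)
class StimulusSpec:
    """Constant single-region stimulation, on for the full run."""

    target_region: int
    amplitude: float = 1.15

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("stimulus amplitude must be >= 0")

    def vector(self, n_regions: int) -> np.ndarray:
        P = np.zeros(n_regions)
        P[self.target_region] = self.amplitude
        return P


@dataclass(frozen=True)
class SimConfig:
    """Integration settings.  Times in ms, ``dt`` in ms per step.

    ``transient`` is discarded before the ``record_window`` (T) used
    for all synchrony analysis.  ``record_stride`` decimates the
    recorded samples (the dynamics itself always advances at ``dt``).
    ``delay_quantum`` stores the delay history every that many steps:
    1 reproduces per-step delays exactly; coarser values (e.g. 16, i.e.
    0.016 ms jitter on ~1-17 ms delays) keep the history buffer in
    cache.  ``noise_block`` aggregates white-noise increments over
    blocks of steps; the aggregated increment has the exact summed
    variance.
    """

    dt: float = 1e-3
    transient: float = 1000.0
    record_window: float = 500.0
    initial_value: float = 0.1
    seed: int = 0
    record_stride: int = 10
    delay_quantum: int = 1
    noise_block: int = 16

    def __post_init__(self):
        if self.dt <= 0 or self.record_window <= 0 or self.transient < 0:
            raise ValueError("dt and record_window must be > 0, transient >= 0")
        if self.delay_quantum < 1 or self.noise_block < 1 or self.record_stride < 1:
            raise ValueError("strides and quanta must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round((self.transient + self.record_window) / self.dt))

    @property
    def n_transient_steps(self) -> int:
        return int(round(self.transient / self.dt))


@dataclass(frozen=True)
class DelayMatrix:
    """Pairwise conduction delays in ms (symmetric, zero diagonal)."""

    delays: np.ndarray

    def __post_init__(self):
        D = np.asarray(self.delays, dtype=float)
        if not np.allclose(D, D.T):
            raise ValueError("delay matrix must be symmetric")
        if np.diagonal(D).any():
            raise ValueError("delay matrix diagonal must be zero")
        if (D < 0).any():
            raise ValueError("delays must be nonnegative")
        D = (D + D.T) / 2
        D.setflags(write=False)
        object.__setattr__(self, "delays", D)


@dataclass(frozen=True)
class StateTrajectory:
    """Recorded excitatory/inhibitory time series of one run.

    ``E`` and ``I`` are (time x region); ``times`` holds the sample
    times in ms and ``steady_slice`` marks the post-transient window
    used for phase and synchrony analysis.
    """

    E: np.ndarray
    I: np.ndarray
    times: np.ndarray
    steady_slice: slice

    @property
    def E_steady(self) -> np.ndarray:
        return self.E[self.steady_slice]

    @property
    def I_steady(self) -> np.ndarray:
        return self.I[self.steady_slice]


def sigmoid(x, a: float, theta: float):
    """Shifted logistic activation: S(x) = 1/(1+e^{-a(x-theta)}) - 1/(1+e^{a*theta}).

    Strictly increasing with S(0) = 0; its supremum is
    ``sigmoid_max(a, theta)``.
    """
    if a <= 0:
        raise ValueError("sigmoid growth rate a must be > 0")
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-a * (x - theta))) - 1.0 / (1.0 + np.exp(a * theta))
    return out if out.ndim else float(out)


def sigmoid_max(a: float, theta: float) -> float:
    """Supremum of :func:`sigmoid`: ``1 - 1/(1+exp(a*theta))``."""
    if a <= 0:
        raise ValueError("sigmoid growth rate a must be > 0")
    return 1.0 - 1.0 / (1.0 + np.exp(a * theta))


def build_delay_matrix(coordinates: np.ndarray, v_d: float = 10.0) -> DelayMatrix:
    """Conduction delays from coordinates (mm) and velocity (m/s).

    ``tau_d[j, k] = ||x_j - x_k|| / v_d``; mm over m/s gives ms.
    """
    if v_d <= 0:
        raise ValueError("conduction velocity must be > 0")
    X = np.asarray(coordinates, dtype=float)
    diff = X[:, None, :] - X[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    return DelayMatrix(delays=dist / v_d)


def _noise_arrays(params: WCParams, config: SimConfig, n_regions: int):
    if params.sigma == 0:
        return np.zeros((1, n_regions, 2), dtype=np.float32), 0.0
    n_blocks = config.n_steps // config.noise_block + 1
    rng = np.random.default_rng(config.seed)
    noise = rng.standard_normal((n_blocks, n_regions, 2), dtype=np.float32)
    # Euler-Maruyama increment (1/tau) sqrt(sigma dt) per step, aggregated
    # over noise_block steps -> variance scales with the block length.
    amp = np.sqrt(params.sigma * config.noise_block * config.dt) / params.tau
    return noise, amp


def simulate(
    connectome: Connectome,
    params: WCParams,
    stim: StimulusSpec | None,
    config: SimConfig,
    delay_matrix: DelayMatrix | None = None,
) -> StateTrajectory:
    """Integrate the delay-coupled network for one run.

    Euler-Maruyama at ``config.dt`` with per-edge delayed inputs
    :math:`A_{jk} E_j(t-\\tau^d_{jk})` (and likewise for I, same delay
    matrix).  The pre-``t=0`` history is held constant at
    ``config.initial_value``.  With ``sigma = 0`` the run is exactly
    reproducible.

    Only the post-transient record window is recorded (decimated by
    ``record_stride``); ``steady_slice`` spans all recorded samples.
    """
    n = connectome.n_regions
    if delay_matrix is None:
        delay_matrix = build_delay_matrix(connectome.coordinates, params.v_d)
    delay_steps = delay_matrix.delays / config.dt
    max_delay = float(delay_matrix.delays.max()) if n > 1 else 0.0
    if config.transient > 0 and max_delay >= config.transient + config.record_window:
        raise ValueError(
            f"max delay {max_delay:.1f} ms exceeds the simulated duration"
        )
    indptr, src, w, qd, hist_len = csr_from_dense(
        connectome.weights, delay_steps, config.delay_quantum
    )
    P = stim.vector(n) if stim is not None else np.zeros(n)
    noise, amp = _noise_arrays(params, config, n)

    rec_start = config.n_transient_steps
    n_rec = (config.n_steps - rec_start + config.record_stride - 1) // config.record_stride
    E_rec = np.empty((n_rec, n))
    I_rec = np.empty((n_rec, n))
    ri, bad_step, bad_region = wc_integrate(
        indptr, src, w, qd,
        config.n_steps, config.dt, params.tau, params.r_E, params.r_I,
        params.C_EE, params.C_EI, params.C_IE, params.C_II,
        params.a_E, params.theta_E, params.a_I, params.theta_I,
        params.C_E, params.C_I, P,
        config.initial_value, config.delay_quantum, hist_len,
        rec_start, config.record_stride, E_rec, I_rec,
        noise, amp, config.noise_block,
    )
    if bad_step >= 0:
        raise BlowupError(bad_step, bad_region)
    times = config.transient + np.arange(ri) * config.record_stride * config.dt
    return StateTrajectory(
        E=E_rec[:ri], I=I_rec[:ri], times=times, steady_slice=slice(0, ri)
    )


def classify_activity(trajectory: StateTrajectory, epsilon: float = 1e-4) -> str:
    """Label a noise-free run ``"active"`` or ``"quiescent"``.

    Active means the standard deviation of the region-mean excitatory
    activity over the steady window exceeds ``epsilon`` — i.e. the
    network sustains oscillation rather than sitting at a fixed point.
    """
    E = trajectory.E_steady
    if E.shape[0] == 0:
        raise ValueError("trajectory has no steady-state samples")
    return "active" if float(E.mean(axis=1).std()) > epsilon else "quiescent"


@dataclass(frozen=True)
class TuneResult:
    C_E: float
    bracket: tuple[float, float]
    n_iterations: int

    @property
    def width(self) -> float:
        return self.bracket[1] - self.bracket[0]


def tune_global_coupling(
    connectome: Connectome,
    params: WCParams,
    config: SimConfig,
    tolerance: float = 1e-6,
    epsilon: float = 1e-4,
    initial_bracket: tuple[float, float] | None = None,
    coupling_cap: float = 1e6,
) -> TuneResult:
    """Calibrate ``C_E`` to the quiescent/active boundary by bisection.

    Runs are noise-free and stimulus-free from the initial value 0.1.
    Starting from ``initial_bracket`` (or from C=1 doubled until the
    network activates), the bracket is bisected until its width is at
    most ``tolerance``; the midpoint is returned and classifies as
    quiescent.  A warm bracket from a similar connectome cuts the
    iteration count roughly in half.

    The bisection predicate is *departure from the zero fixed point*:
    a run counts as beyond-critical when the region-mean excitatory
    activity either fluctuates (std > ``epsilon``) or settles at an
    elevated level (mean > 0.01).  The mean test matters far above
    criticality, where the network saturates at a high fixed point
    with vanishing variance; without it the bracketing search can
    escape upward through that regime.  Just above the boundary the
    departure is oscillatory, so the returned bracket's upper endpoint
    still classifies as active.

    Raises ``RuntimeError`` when no active state exists below
    ``coupling_cap``.
    """
    quiet = replace(params, sigma=0.0)
    delay_matrix = build_delay_matrix(connectome.coordinates, params.v_d)

    def is_active(c: float) -> bool:
        tr = simulate(connectome, quiet.with_coupling(c), None, config, delay_matrix)
        mean_e = tr.E_steady.mean(axis=1)
        return float(mean_e.std()) > epsilon or float(mean_e.mean()) > 1e-2

    n_iter = 0
    lo, hi = 0.0, None
    if initial_bracket is not None:
        b_lo, b_hi = initial_bracket
        n_iter += 1
        if is_active(b_lo):
            hi = b_lo
        else:
            lo = b_lo
            n_iter += 1
            if is_active(b_hi):
                hi = b_hi
    if hi is None:
        hi = max(1.0, 2 * lo) if lo else 1.0
        while not is_active(hi):
            lo = hi
            hi *= 2
            n_iter += 1
            if hi > coupling_cap:
                raise RuntimeError(
                    f"no bifurcation in range: still quiescent at C_E = {hi:g}"
                )
    while hi - lo > tolerance:
        mid = (lo + hi) / 2
        if is_active(mid):
            hi = mid
        else:
            lo = mid
        n_iter += 1
    # the returned coupling must itself classify quiescent; keep
    # halving toward the quiescent endpoint until the midpoint does
    c_e = (lo + hi) / 2
    while is_active(c_e) and c_e > lo:
        hi = c_e
        c_e = (lo + hi) / 2
        n_iter += 1
    logger.debug("tuned C_E = %.6f in %d runs", c_e, n_iter)
    return TuneResult(C_E=c_e, bracket=(lo, hi), n_iterations=n_iter)


def stimulate_each_region(
    connectome: Connectome,
    params: WCParams,
    config: SimConfig,
    regions=None,
    amplitude: float = 1.15,
) -> dict[int, StateTrajectory]:
    """Run the single-region stimulation protocol over ``regions``.

    Each selected region in turn receives the constant stimulus
    ``P_k = amplitude`` (all others 0) for the full run.  Per-run noise
    seeds are spawned from ``config.seed`` and the region index, so
    the map is reproducible and independent of the subset chosen.
    ``params.C_E`` must already be tuned for this connectome.
    """
    if regions is None:
        regions = range(connectome.n_regions)
    delay_matrix = build_delay_matrix(connectome.coordinates, params.v_d)
    out: dict[int, StateTrajectory] = {}
    for k in regions:
        run_seed = int(
            np.random.SeedSequence([config.seed, int(k)]).generate_state(1)[0]
            % 2**31
        )
        cfg = replace(config, seed=run_seed)
        out[int(k)] = simulate(
            connectome, params, StimulusSpec(int(k), amplitude), cfg, delay_matrix
        )
    return out
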