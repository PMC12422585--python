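"""Phase extraction and pairwise cognitive-system synchrony.

Each region's steady-state orbit in the (E, I) plane encircles a
point near the origin once per oscillation, so the four-quadrant
arctangent :math:`\\phi_k(t) = \\mathrm{atan2}(I_{k,ss}(t), E_{k,ss}(t))`
serves as an instantaneous phase.  For a pair of cognitive systems the
complex Kuramoto order parameter over the union of their regions,

.. math::

   \\rho_{s_j,s_k}(t) e^{i\\Theta(t)}
     = \\frac{1}{N_{s_j}+N_{s_k}} \\sum_{l \\in (CS_j, CS_k)} e^{i\\phi_l(t)},

measures their joint phase coherence at time t (1 = fully locked,
~0 = incoherent), and its time average over the steady window T is the
*synchrony* :math:`R_{s_j,s_k} \\in [0, 1]`.  Collecting all pairs
gives the 9 x 9 synchrony matrix of one stimulation run; its diagonal
holds the within-system order parameter (a single-system entry is not
double-counted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .connectome import CognitiveParcellation
from .dynamics import StateTrajectory

__all__ = [
    "PhaseTrajectory",
    "SynchronyMatrix",
    "phase",
    "order_parameter",
    "pair_members",
    "synchrony",
    "synchrony_matrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhaseTrajectory:
    """Per-region phases (time x region), each in (-pi, pi]."""

    phi: np.ndarray
    times: np.ndarray


@dataclass(frozen=True)
class SynchronyMatrix:
    """Symmetric matrix of pairwise cognitive-system synchrony values."""

    R: np.ndarray
    systems: tuple[str, ...]
    window: float  # ms

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float)
        if not np.allclose(R, R.T, atol=1e-12):
            raise ValueError("synchrony matrix must be symmetric")
        if R.min() < -1e-12 or R.max() > 1 + 1e-12:
            raise ValueError("synchrony values must lie in [0, 1]")
        R.setflags(write=False)
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "systems", tuple(self.systems))


def phase(trajectory: StateTrajectory, center: bool = False) -> PhaseTrajectory:
    """Instantaneous phase of every region over the steady window.

    ``phi_k(t) = atan2(I_k(t), E_k(t))`` on the raw steady-state
    series; ``center=True`` subtracts each region's temporal mean
    first (an alternative phase convention).  Samples where E and I
    are both exactly zero (a quiescent region at the fixed point) have
    no defined angle; they are set to 0 and a warning is logged.
    """
    E = trajectory.E_steady
    I = trajectory.I_steady
    if E.shape[0] == 0:
        raise ValueError("trajectory has an empty steady-state window")
    if center:
        E = E - E.mean(axis=0, keepdims=True)
        I = I - I.mean(axis=0, keepdims=True)
    undefined = (E == 0) & (I == 0)
    if undefined.any():
        logger.warning(
            "phase undefined (E=I=0) for %d samples; set to 0", int(undefined.sum())
        )
    phi = np.arctan2(I, E)
    phi[undefined] = 0.0
    return PhaseTrajectory(phi=phi, times=trajectory.times[trajectory.steady_slice])


def order_parameter(phases: np.ndarray, members) -> tuple[np.ndarray, np.ndarray]:
    """Kuramoto order parameter of a member set, per time sample.

    Returns ``(rho, Theta)``: the magnitude and argument of the mean
    unit phasor over ``members``.  ``phases`` may be a single sample
    (1-D over regions) or a (time x region) array.
    """
    members = np.asarray(list(members), dtype=int)
    if members.size == 0:
        raise ValueError("order parameter of an empty member set is undefined")
    phi = np.asarray(phases, dtype=float)
    z = np.exp(1j * phi[..., members]).mean(axis=-1)
    return np.abs(z), np.angle(z)


def pair_members(
    parcellation: CognitiveParcellation, s_j: str, s_k: str
) -> np.ndarray:
    """Region indices entering the order parameter of a system pair.

    Distinct systems contribute the disjoint union of their members
    (normalization ``N_sj + N_sk``); a system paired with itself
    contributes its members exactly once.
    """
    mj = parcellation.members(s_j)
    if s_j == s_k:
        return mj
    mk = parcellation.members(s_k)
    assert not set(mj) & set(mk), "parcellation assigns a region to two systems"
    return np.concatenate([mj, mk])


def synchrony(rho: np.ndarray) -> float:
    """Time-averaged order parameter R = <rho(t)>_T over the window."""
    rho = np.asarray(rho, dtype=float)
    if rho.size == 0:
        raise ValueError("cannot average synchrony over an empty window")
    return float(rho.mean())


def synchrony_matrix(
    phases: PhaseTrajectory, parcellation: CognitiveParcellation
) -> SynchronyMatrix:
    """Pairwise synchrony over all cognitive-system pairs.

    Evaluates rho at every recorded sample of the steady window (no
    subsampling) and time-averages.  Vectorized over pairs: with
    :math:`Z_s(t) = \\sum_{l \\in CS_s} e^{i\\phi_l(t)}`, the pair (j, k)
    order parameter is :math:`|Z_j + Z_k| / (N_{s_j} + N_{s_k})` and
    the diagonal is :math:`|Z_j| / N_{s_j}`.
    """
    systems = parcellation.systems
    n_cs = len(systems)
    z = np.exp(1j * phases.phi)
    sums = np.empty((z.shape[0], n_cs), dtype=complex)
    counts = np.empty(n_cs)
    for i, s in enumerate(systems):
        mem = parcellation.members(s)
        sums[:, i] = z[:, mem].sum(axis=1)
        counts[i] = len(mem)
    R = np.empty((n_cs, n_cs))
    for i in range(n_cs):
        R[i, i] = synchrony(np.abs(sums[:, i]) / counts[i])
        for j in range(i + 1, n_cs):
            rho = np.abs(sums[:, i] + sums[:, j]) / (counts[i] + counts[j])
            R[i, j] = R[j, i] = synchrony(rho)
    window = (
        float(phases.times[-1] - phases.times[0]) if len(phases.times) > 1 else 0.0
    )
    return SynchronyMatrix(R=R, systems=systems, window=window)
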