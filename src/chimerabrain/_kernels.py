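"""Numba integration kernel for the delay-coupled Wilson-Cowan network.

The network state is advanced with Euler-Maruyama steps.  Delayed
excitatory/inhibitory inputs are read from a per-region ring buffer of
past states; the buffer is stored at a configurable temporal quantum
``s`` (in steps) so that, for the millisecond-scale conduction delays
used here, the history stays cache-resident.  With ``s = 1`` delays
are exact to one step.  Gaussian noise increments are aggregated over
blocks of ``noise_block`` steps (the summed white-noise increment over
a block is itself Gaussian with the summed variance) and pre-generated
outside the kernel.

Connectivity is passed in CSR layout keyed by the *destination*
region: for region k, ``src[indptr[k]:indptr[k+1]]`` lists the source
regions j with A[j, k] != 0, with matching entries in ``w`` (weights)
and ``qd`` (delays in buffer quanta, minimum 1).
"""

import numpy as np
from numba import njit

__all__ = ["wc_integrate", "csr_from_dense"]


def csr_from_dense(weights: np.ndarray, delay_steps: np.ndarray, quantum: int):
    """CSR-by-destination arrays from a dense weight + delay-step matrix.

    Delays are rounded to multiples of ``quantum`` steps, with a floor
    of one quantum so a region never reads its neighbours' current
    state within the same step.
    """
    n = weights.shape[0]
    indptr = np.zeros(n + 1, dtype=np.int32)
    srcs, ws, qs = [], [], []
    for k in range(n):
        j = np.nonzero(weights[:, k])[0]
        indptr[k + 1] = indptr[k] + len(j)
        srcs.append(j)
        ws.append(weights[j, k])
        qs.append(np.maximum(1, np.rint(delay_steps[j, k] / quantum)).astype(np.int32))
    src = (np.concatenate(srcs) if srcs else np.zeros(0)).astype(np.int32)
    w = np.concatenate(ws) if ws else np.zeros(0)
    qd = (np.concatenate(qs) if qs else np.zeros(0)).astype(np.int32)
    hist_len = int(qd.max()) + 2 if len(qd) else 2
    return indptr, src, w, qd, hist_len


@njit(cache=True)
def wc_integrate(
    indptr, src, w, qd,  # CSR connectivity (by destination) + delays
    n_steps, dt, tau, r_e, r_i,
    c_ee, c_ei, c_ie, c_ii,
    a_e, th_e, a_i, th_i,
    c_glob_e, c_glob_i, P,
    x0, s, hist_len,
    rec_start, rec_stride, E_rec, I_rec,
    noise, noise_amp, noise_block,
):
    """Advance the network ``n_steps`` and fill ``E_rec``/``I_rec``.

    Returns (rows_recorded, blowup_step, blowup_region); the latter two
    are -1 when the state stayed finite.
    """
    N = len(P)
    # sigmoid offsets/maxima from the same exp as the inner loop, so
    # S(0) cancels to exactly zero and the origin is preserved bitwise
    off_e = 1.0 / (1.0 + np.exp(a_e * th_e))
    off_i = 1.0 / (1.0 + np.exp(a_i * th_i))
    s_e_max = 1.0 - off_e
    s_i_max = 1.0 - off_i
    hist = np.full((N, hist_len, 2), np.float32(x0), dtype=np.float32)
    E = np.full(N, x0)
    I = np.full(N, x0)
    have_noise = noise.shape[0] > 1
    ri = 0
    for t in range(n_steps):
        pos = (t // s) % hist_len
        for k in range(N):
            acc_e = 0.0
            acc_i = 0.0
            for e in range(indptr[k], indptr[k + 1]):
                idx = pos - qd[e]
                if idx < 0:
                    idx += hist_len
                j = src[e]
                acc_e += w[e] * hist[j, idx, 0]
                acc_i += w[e] * hist[j, idx, 1]
            x_e = c_ee * E[k] - c_ei * I[k] + c_glob_e * acc_e + P[k]
            x_i = c_ie * E[k] - c_ii * I[k] + c_glob_i * acc_i
            s_e = 1.0 / (1.0 + np.exp(-a_e * (x_e - th_e))) - off_e
            s_i = 1.0 / (1.0 + np.exp(-a_i * (x_i - th_i))) - off_i
            E[k] += dt * (-E[k] + (s_e_max - r_e * E[k]) * s_e) / tau
            I[k] += dt * (-I[k] + (s_i_max - r_i * I[k]) * s_i) / tau
        if have_noise and (t + 1) % noise_block == 0:
            b = t // noise_block
            for k in range(N):
                E[k] += noise_amp * noise[b, k, 0]
                I[k] += noise_amp * noise[b, k, 1]
        if (t + 1) % 1024 == 0:
            for k in range(N):
                if not (np.isfinite(E[k]) and np.isfinite(I[k])):
                    return ri, t, k
        nxt = ((t + 1) // s) % hist_len
        for k in range(N):
            hist[k, nxt, 0] = E[k]
            hist[k, nxt, 1] = I[k]
        if t >= rec_start and (t - rec_start) % rec_stride == 0:
            for k in range(N):
                E_rec[ri, k] = E[k]
                I_rec[ri, k] = I[k]
            ri += 1
    return ri, -1, -1
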