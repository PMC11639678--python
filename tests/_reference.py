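"""Independent scalar (triple-loop) reference implementations.

These re-derive the circuit dynamics and the plasticity rules with plain
Python loops, entirely separately from the vectorized package code, and are
used as oracles in equivalence tests. Keep them dumb and literal.
"""

import math

import numpy as np


def ref_step_single(cfg, params, state, s0, sy):
    """One synchronous step of all hidden layers for a single sample.

    ``state`` is a dict with per-layer lists: v, s, z (lists of floats) and
    v_thr (list of scalars). Reads only old state; returns a new dict.
    """
    L = cfg.n_layers
    sizes = cfg.layer_sizes
    new = {"v": [], "s": [], "z": [], "v_thr": [], "j": []}
    for l in range(L):
        J = sizes[l + 1]
        s_below = s0 if l == 0 else state["s"][l - 1]
        s_above = state["s"][l + 1] if l + 1 < L else None
        W = params.W[l]; V = params.V[l]; M = params.M[l]; B = params.B[l]
        j_vec, v_vec, s_vec = [], [], []
        for i in range(J):
            j = 0.0
            for jj in range(len(s_below)):
                j += cfg.r_e * W[i][jj] * s_below[jj]
            if V is not None:
                for jj in range(len(s_above)):
                    j += cfg.r_e * V[i][jj] * s_above[jj]
            for jj in range(J):
                if jj != i:
                    j -= cfg.r_i * M[i][jj] * state["s"][l][jj]
            if B is not None and sy is not None:
                for c in range(len(sy)):
                    j += cfg.r_e * B[i][c] * sy[c]
            v_hat = state["v"][l][i] + (cfg.dt / cfg.tau_m) * (-state["v"][l][i] + j)
            spike = 1.0 if v_hat > state["v_thr"][l] else 0.0
            j_vec.append(j)
            s_vec.append(spike)
            v_vec.append(v_hat * (1.0 - spike))
        thr = max(0.0, state["v_thr"][l] + cfg.lambda_v * (sum(s_vec) - 1.0))
        z_vec = [
            state["z"][l][i] + (cfg.dt / cfg.tau_tr) * (-state["z"][l][i] + cfg.gamma * s_vec[i])
            for i in range(J)
        ]
        new["j"].append(j_vec)
        new["v"].append(v_vec)
        new["s"].append(s_vec)
        new["z"].append(z_vec)
        new["v_thr"].append(thr)
    return new


def ref_goodness_probability(z, theta_z):
    a = sum(zi * zi for zi in z) - theta_z
    if a >= 0:
        return 1.0 / (1.0 + math.exp(-a))
    e = math.exp(a)
    return e / (1.0 + e)


def ref_contrastive_loss(z, y_type, theta_z):
    p = ref_goodness_probability(z, theta_z)
    # guard the logs for the oracle only; the package works in logit space
    p = min(max(p, 1e-300), 1.0 - 1e-16)
    return -(y_type * math.log(p) + (1.0 - y_type) * math.log(1.0 - p))


def ref_bundle_update(lead, delta, post, pre, lambda_d):
    """Batch-mean of lead*delta_i*pre_j + lambda_d*post_i*(1-pre_j)."""
    n, ni = len(delta), len(delta[0])
    nj = len(pre[0])
    out = [[0.0] * nj for _ in range(ni)]
    for b in range(n):
        for i in range(ni):
            for j in range(nj):
                out[i][j] += (
                    lead * delta[b][i] * pre[b][j]
                    + lambda_d * post[b][i] * (1.0 - pre[b][j])
                )
    return np.array(out) / n


def fd_modulator(z, y_type, theta_z, h=1e-6):
    """Central finite differences of the contrastive loss w.r.t. each trace."""
    z = list(map(float, z))
    grad = []
    for i in range(len(z)):
        zp = list(z); zp[i] += h
        zm = list(z); zm[i] -= h
        grad.append(
            (ref_contrastive_loss(zp, y_type, theta_z)
             - ref_contrastive_loss(zm, y_type, theta_z)) / (2 * h)
        )
    return np.array(grad)
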