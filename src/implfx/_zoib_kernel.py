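"""Numba kernel for the interior beta likelihood of the ZOIB model.

One pass over the interior rows computes the log likelihood, the per-cell
and per-participant gradient accumulators and the precision derivative.
"""
import math

import numba
import numpy as np


@numba.njit(cache=False, fastmath=True)
def _digamma(x):
    # recurrence to x >= 6, then the asymptotic series
    acc = 0.0
    while x < 6.0:
        acc -= 1.0 / x
        x += 1.0
    inv = 1.0 / x
    inv2 = inv * inv
    return acc + math.log(x) - 0.5 * inv - inv2 * (
        1.0 / 12.0 - inv2 * (1.0 / 120.0 - inv2 / 252.0)
    )


@numba.njit(cache=False, fastmath=True)
def beta_lik_kernel(
    log_y, log_1my, si, cell_ix, part_ix, has_part,
    cell_int, cell_slope, eff_p, b0, b1, phi, n_cells, n_part,
):
    n = log_y.shape[0]
    gg_cell = np.zeros(n_cells)
    gg_cell_s = np.zeros(n_cells)
    gg_p = np.zeros(n_part)
    loglik = 0.0
    dphi = 0.0
    lg_phi = math.lgamma(phi)
    dg_phi = _digamma(phi)
    for r in range(n):
        c = cell_ix[r]
        sv = si[r]
        eta = b0 + cell_int[c] + (b1 + cell_slope[c]) * sv
        if has_part:
            eta += eff_p[part_ix[r]]
        if eta > 30.0:
            eta = 30.0
        elif eta < -30.0:
            eta = -30.0
        mu = 1.0 / (1.0 + math.exp(-eta))
        a = mu * phi
        b = phi - a
        ly = log_y[r]
        l1y = log_1my[r]
        loglik += (a - 1.0) * ly + (b - 1.0) * l1y + lg_phi - math.lgamma(a) - math.lgamma(b)
        dga = _digamma(a)
        dgb = _digamma(b)
        grow = mu * (1.0 - mu) * phi * (ly - l1y - dga + dgb)
        gg_cell[c] += grow
        gg_cell_s[c] += grow * sv
        if has_part:
            gg_p[part_ix[r]] += grow
        dphi += mu * ly + (1.0 - mu) * l1y + dg_phi - mu * dga - (1.0 - mu) * dgb
    return loglik, gg_cell, gg_cell_s, gg_p, dphi
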