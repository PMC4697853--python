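"""Euler–Maruyama inner loop for the reduced cortical model (numba-JIT when available).

State vector (10 components):

    [he, hi, nee, mee, nei, mei, nie, mie, nii, mii]

``he``, ``hi`` are the population-mean soma potentials; each (n, m) pair is a
second-order stochastic input channel — the zero-mean fluctuation of one
subcortical input filtered by its postsynaptic-potential kernel — with ``m``
the channel's time derivative.  The deterministic synaptic feedback is slaved
(adiabatic reduction), so the drift in (he, hi) is evaluated from the
instantaneous firing rates plus the channel fluctuations.
"""

import math

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

E = math.e


@njit(cache=True)
def em_chunk(y, dt, istart, nsteps, lam, lam_dt,
             sig_ee, sig_ei, sig_ie, sig_ii, noise,
             he_rest, hi_rest, he_rev, hi_rev, tau_e, tau_i,
             gamma_e, gamma_i, Ge, Gi,
             Nee_b, Nei_b, Nie_b, Nii_b, Nee_a, Nei_a,
             smax_e, smax_i, theta_e, theta_i, slope_e, slope_i,
             p_ee, p_ei, p_ie, p_ii,
             h_lo, h_hi, rec, rec_every):
    """Advance ``nsteps`` Euler–Maruyama steps in place; record every ``rec_every`` steps.

    Returns -1 on success, else the global step index at which (he, hi) left
    the physiological bounds (h_lo, h_hi).
    """
    inv_sqrt_dt = 1.0 / math.sqrt(dt)
    abs_ee = abs(he_rev - he_rest)
    abs_ie = abs(hi_rev - he_rest)
    abs_ei = abs(he_rev - hi_rest)
    abs_ii = abs(hi_rev - hi_rest)
    ke = E * Ge / gamma_e            # steady EPSP input gain (mV·s)
    ki0 = E * Gi / gamma_i           # steady IPSP input gain at λ=1
    n_lam = lam.shape[0]
    for k in range(nsteps):
        g = istart + k
        he = y[0]
        hi = y[1]
        if he <= h_lo or he >= h_hi or hi <= h_lo or hi >= h_hi:
            return g
        t = g * dt
        il = int(t / lam_dt)
        if il >= n_lam:
            il = n_lam - 1
        lam_t = lam[il]
        gi_eff = gamma_i / lam_t
        ki = ki0 * lam_t

        se = smax_e / (1.0 + math.exp(-slope_e * (he - theta_e)))
        si = smax_i / (1.0 + math.exp(-slope_i * (hi - theta_i)))

        # slaved synaptic inputs (mean part) + stochastic channel fluctuations
        iee = ke * ((Nee_b + Nee_a) * se + p_ee) + y[2]
        iei = ke * ((Nei_b + Nei_a) * se + p_ei) + y[4]
        iie = ki * (Nie_b * si + p_ie) + y[6]
        iii = ki * (Nii_b * si + p_ii) + y[8]

        if g % rec_every == 0:
            j = g // rec_every
            rec[0, j] = he
            rec[1, j] = hi
            rec[2, j] = iee
            rec[3, j] = iei
            rec[4, j] = iie
            rec[5, j] = iii
            rec[6, j] = Nee_a * se  # slaved long-range flux φee
            rec[7, j] = Nei_a * se  # φei

        psi_ee = (he_rev - he) / abs_ee
        psi_ie = (hi_rev - he) / abs_ie
        psi_ei = (he_rev - hi) / abs_ei
        psi_ii = (hi_rev - hi) / abs_ii

        dhe = (he_rest - he + psi_ee * iee + psi_ie * iie) / tau_e
        dhi = (hi_rest - hi + psi_ei * iei + psi_ii * iii) / tau_i

        # noise channels: (d/dt + γ)² n = e G γ σ ξ(t); inhibitory rate γi/λ(t)
        w0 = sig_ee * noise[0, k] * inv_sqrt_dt
        w1 = sig_ei * noise[1, k] * inv_sqrt_dt
        w2 = sig_ie * noise[2, k] * inv_sqrt_dt
        w3 = sig_ii * noise[3, k] * inv_sqrt_dt
        dmee = -2.0 * gamma_e * y[3] - gamma_e * gamma_e * y[2] + E * Ge * gamma_e * w0
        dmei = -2.0 * gamma_e * y[5] - gamma_e * gamma_e * y[4] + E * Ge * gamma_e * w1
        dmie = -2.0 * gi_eff * y[7] - gi_eff * gi_eff * y[6] + E * Gi * gi_eff * w2
        dmii = -2.0 * gi_eff * y[9] - gi_eff * gi_eff * y[8] + E * Gi * gi_eff * w3

        y[0] += dt * dhe
        y[1] += dt * dhi
        y[2] += dt * y[3]
        y[3] += dt * dmee
        y[4] += dt * y[5]
        y[5] += dt * dmei
        y[6] += dt * y[7]
        y[7] += dt * dmie
        y[8] += dt * y[9]
        y[9] += dt * dmii
    return -1
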