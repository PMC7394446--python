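"""Numba-compiled inner loops: NB log-likelihood gradients and the HMC sweep.

These kernels mirror the numpy reference implementations in ``nb``
and ``inference`` (which remain the documented source of truth and are
cross-checked in the test suite); they exist because per-variant MCMC
across thousands of variants is dominated by small-array special
functions where interpreter overhead is the bottleneck.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Bernoulli-number coefficients of the asymptotic digamma expansion.
_DG = (1.0 / 12.0, 1.0 / 120.0, 1.0 / 252.0, 1.0 / 240.0, 1.0 / 132.0,
       691.0 / 32760.0, 1.0 / 12.0)


@njit(cache=True, inline="always")
def _digamma(z: float) -> float:
    """Digamma via upward recurrence + asymptotic series (z > 0)."""
    r = 0.0
    while z < 6.0:
        r -= 1.0 / z
        z += 1.0
    f = 1.0 / (z * z)
    s = f * (_DG[0] - f * (_DG[1] - f * (_DG[2] - f * (_DG[3] - f * (_DG[4] - f * (_DG[5] - f * _DG[6]))))))
    return r + math.log(z) - 0.5 / z - s


@njit(cache=True, fastmath=True)
def loglik_grad(x, k_dna, k_rna, d_dna, d_rna, alt, lgk1, ll_out, grad_out):
    """Batched NB log-likelihood and gradient on log-parameters.

    x: (C, B+5); counts (B, S); alt: (B,) uint8; lgk1: precomputed
    sum of lgamma(k + 1) over all cells (a constant of the data).
    Writes into ll_out (C,) and grad_out (C, B+5).
    """
    n_chains, d = x.shape
    n_bc = d - 5
    n_dna = d_dna.shape[0]
    n_rna = d_rna.shape[0]
    ex = np.empty(d)
    for c in range(n_chains):
        ll = -lgk1
        for j in range(d):
            grad_out[c, j] = 0.0

        # Reject proposals whose parameters under/overflow on the natural
        # scale before they can produce divide-by-zero in the loops below.
        valid = True
        for j in range(d):
            v = math.exp(x[c, j])
            ex[j] = v
            if not (1e-150 < v < 1e150):
                valid = False
                break
        if not valid:
            ll_out[c] = -np.inf
            continue

        phi_d = ex[n_bc + 2]
        phi_ref = ex[n_bc + 3]
        phi_alt = ex[n_bc + 4]
        mu_ref = ex[n_bc]
        mu_alt = ex[n_bc + 1]

        log_phi_d = math.log(phi_d)
        lg_phi_d = math.lgamma(phi_d)
        dg_phi_d = _digamma(phi_d)
        log_phi_ref = math.log(phi_ref)
        lg_phi_ref = math.lgamma(phi_ref)
        dg_phi_ref = _digamma(phi_ref)
        log_phi_alt = math.log(phi_alt)
        lg_phi_alt = math.lgamma(phi_alt)
        dg_phi_alt = _digamma(phi_alt)

        acc_phi_d = 0.0
        acc_phi_ref = 0.0
        acc_phi_alt = 0.0

        for b in range(n_bc):
            mu = ex[b]
            g_mu = 0.0
            for s in range(n_dna):
                m = mu * d_dna[s]
                k = k_dna[b, s]
                kp = k + phi_d
                pm = phi_d + m
                log_pm = math.log(pm)
                ll += (math.lgamma(kp) - lg_phi_d + phi_d * log_phi_d
                       - kp * log_pm)
                if k > 0.0:
                    ll += k * math.log(m)
                g_mu += k - m * kp / pm
                acc_phi_d += _digamma(kp) - dg_phi_d + log_phi_d + 1.0 - log_pm - kp / pm

            if alt[b]:
                mu_a = mu_alt
                phi_r = phi_alt
                log_phi_r = log_phi_alt
                lg_phi_r = lg_phi_alt
                dg_phi_r = dg_phi_alt
            else:
                mu_a = mu_ref
                phi_r = phi_ref
                log_phi_r = log_phi_ref
                lg_phi_r = lg_phi_ref
                dg_phi_r = dg_phi_ref

            g_allele = 0.0
            acc_phi_r = 0.0
            mm = mu * mu_a
            for s in range(n_rna):
                m = mm * d_rna[s]
                k = k_rna[b, s]
                kp = k + phi_r
                pm = phi_r + m
                log_pm = math.log(pm)
                ll += (math.lgamma(kp) - lg_phi_r + phi_r * log_phi_r
                       - kp * log_pm)
                if k > 0.0:
                    ll += k * math.log(m)
                a_sc = k - m * kp / pm
                g_mu += a_sc
                g_allele += a_sc
                acc_phi_r += _digamma(kp) - dg_phi_r + log_phi_r + 1.0 - log_pm - kp / pm

            grad_out[c, b] = g_mu
            if alt[b]:
                grad_out[c, n_bc + 1] += g_allele
                acc_phi_alt += acc_phi_r
            else:
                grad_out[c, n_bc] += g_allele
                acc_phi_ref += acc_phi_r

        grad_out[c, n_bc + 2] = phi_d * acc_phi_d
        grad_out[c, n_bc + 3] = phi_ref * acc_phi_ref
        grad_out[c, n_bc + 4] = phi_alt * acc_phi_alt
        ll_out[c] = ll if math.isfinite(ll) else -np.inf


@njit(cache=True)
def _posterior_grad(x, k_dna, k_rna, d_dna, d_rna, alt, lgk1,
                    p_shape, p_rate, ll_out, grad_out):
    """Log posterior (up to a constant) and gradient: likelihood + gamma priors."""
    loglik_grad(x, k_dna, k_rna, d_dna, d_rna, alt, lgk1, ll_out, grad_out)
    n_chains, d = x.shape
    for c in range(n_chains):
        lp = 0.0
        for j in range(d):
            e = math.exp(x[c, j])
            lp += p_shape[j] * x[c, j] - p_rate[j] * e
            grad_out[c, j] += p_shape[j] - p_rate[j] * e
        total = ll_out[c] + lp
        ll_out[c] = total if math.isfinite(total) else -np.inf


@njit(cache=True)
def hmc_sweep(x0, inv_mass, k_dna, k_rna, d_dna, d_rna, alt, lgk1,
              p_shape, p_rate, warmup, n_keep, target_accept, traj_length,
              max_leapfrog, normals, unif_accept, unif_steps):
    """Adaptive-step HMC over all chains; randomness is supplied up front.

    normals: (T, C, D) momentum draws; unif_accept: (T, C) Metropolis
    uniforms; unif_steps: (T,) uniforms for leapfrog-count jitter.
    Returns (draws (C, n_keep, D), n_divergent, mean accept prob).
    """
    n_chains, d = x0.shape
    total = warmup + n_keep
    x = x0.copy()
    sqrt_mass = np.empty(d)
    for j in range(d):
        sqrt_mass[j] = 1.0 / math.sqrt(inv_mass[j])

    logp = np.empty(n_chains)
    grad = np.empty((n_chains, d))
    _posterior_grad(x, k_dna, k_rna, d_dna, d_rna, alt, lgk1, p_shape, p_rate, logp, grad)

    # with Laplace preconditioning the posterior is near-unit-scale, so the
    # step size starts near its typical adapted value
    eps = np.full(n_chains, 0.5)
    mu_da = math.log(10.0 * 0.5)
    log_eps_bar = np.zeros(n_chains)
    h_bar = np.zeros(n_chains)
    gamma = 0.05
    t0 = 10.0
    kappa = 0.75

    xn = np.empty((n_chains, d))
    pn = np.empty((n_chains, d))
    lpn = np.empty(n_chains)
    gn = np.empty((n_chains, d))

    draws = np.empty((n_chains, n_keep, d))
    n_div = 0
    acc_sum = 0.0

    for it in range(total):
        eps_med = np.median(eps)
        denom = eps_med if eps_med > 1e-3 else 1e-3
        l_base = int(round(traj_length / denom))
        if l_base < 1:
            l_base = 1
        if l_base > max_leapfrog:
            l_base = max_leapfrog
        lo = (l_base + 1) // 2
        if lo < 1:
            lo = 1
        n_steps = lo + int(unif_steps[it] * (l_base - lo + 1))
        if n_steps > l_base:
            n_steps = l_base

        for c in range(n_chains):
            for j in range(d):
                pn[c, j] = normals[it, c, j] * sqrt_mass[j]
                xn[c, j] = x[c, j]
                gn[c, j] = grad[c, j]
        kin0 = np.empty(n_chains)
        for c in range(n_chains):
            k0 = 0.0
            for j in range(d):
                k0 += pn[c, j] * pn[c, j] * inv_mass[j]
            kin0[c] = 0.5 * k0

        # leapfrog
        for c in range(n_chains):
            for j in range(d):
                pn[c, j] += 0.5 * eps[c] * gn[c, j]
        for step in range(n_steps):
            for c in range(n_chains):
                for j in range(d):
                    xn[c, j] += eps[c] * pn[c, j] * inv_mass[j]
            _posterior_grad(xn, k_dna, k_rna, d_dna, d_rna, alt, lgk1,
                            p_shape, p_rate, lpn, gn)
            w = 1.0 if step < n_steps - 1 else 0.5
            for c in range(n_chains):
                for j in range(d):
                    pn[c, j] += w * eps[c] * gn[c, j]

        for c in range(n_chains):
            k1 = 0.0
            for j in range(d):
                k1 += pn[c, j] * pn[c, j] * inv_mass[j]
            k1 *= 0.5
            delta = (logp[c] - kin0[c]) - (lpn[c] - k1)
            # delta = energy1 - energy0; accept prob = exp(-delta)
            if not math.isfinite(delta):
                delta = np.inf
            alpha = math.exp(-delta) if delta > 0.0 else 1.0
            divergent = delta > 1000.0
            if unif_accept[it, c] < alpha:
                for j in range(d):
                    x[c, j] = xn[c, j]
                    grad[c, j] = gn[c, j]
                logp[c] = lpn[c]

            if it < warmup:
                frac = 1.0 / (it + 1.0 + t0)
                h_bar[c] = (1.0 - frac) * h_bar[c] + frac * (target_accept - alpha)
                log_eps = mu_da - math.sqrt(it + 1.0) / gamma * h_bar[c]
                wda = (it + 1.0) ** (-kappa)
                log_eps_bar[c] = wda * log_eps + (1.0 - wda) * log_eps_bar[c]
                eps[c] = math.exp(log_eps)
                if it == warmup - 1:
                    eps[c] = math.exp(log_eps_bar[c])
            else:
                if divergent:
                    n_div += 1
                acc_sum += alpha

        if it >= warmup:
            for c in range(n_chains):
                for j in range(d):
                    draws[c, it - warmup, j] = x[c, j]

    return draws, n_div, acc_sum / (n_keep * n_chains)
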