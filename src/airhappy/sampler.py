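"""Adaptive Metropolis-within-Gibbs kernel for the multilevel cumulative logit.

Update scheme per iteration, mirroring the single-site random-walk samplers of
classic multilevel software:

1. each threshold alpha_j: scalar random-walk Metropolis, proposals violating
   the strict ordering are rejected outright; only respondents in the two
   bracketing categories contribute to the acceptance ratio;
2. each regression coefficient: scalar random-walk Metropolis with the linear
   predictor updated incrementally (only rows with a non-zero covariate value
   are touched, which makes dummy covariates cheap);
3. all city intercepts u_k at once: the conditional posteriors are independent
   across cities, so K scalar proposals are evaluated in one vectorised pass;
4. sigma_u^2: conjugate inverse-gamma Gibbs draw given u.

Proposal scales adapt in batches toward a target acceptance rate during
burn-in only and are frozen afterwards, preserving detailed balance of the
retained draws. The caller is expected to pass a mean-centred design matrix
for well-conditioned mixing and to shift the thresholds back afterwards.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

_FLOOR = 1e-300
_REFRESH_EVERY = 500  # guard against float drift in the incremental eta/logp state


def _logp_full(a_hi: np.ndarray, a_lo: np.ndarray, eta: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(expit(a_hi - eta) - expit(a_lo - eta), _FLOOR))


def sample_chain(
    y0: np.ndarray,
    D: np.ndarray,
    city_index: np.ndarray,
    group_starts: np.ndarray,
    J: int,
    *,
    prior_var: float,
    ig_shape: float,
    ig_scale: float,
    n_iterations: int,
    burn_in: int,
    thin: int,
    adapt_interval: int,
    target_acceptance: float,
    alpha_init: np.ndarray,
    coef_init: np.ndarray,
    u_init: np.ndarray,
    sigma_u2_init: float,
    rng: np.random.Generator,
) -> dict:
    """Run one chain; return retained draws and post-burn-in acceptance rates.

    ``y0`` holds 0-based categories; rows must be sorted so each city is a
    contiguous block starting at ``group_starts``.
    """
    n, p = D.shape
    K = group_starts.size
    nthr = J - 1

    # Per-column access patterns: sparse columns (dummies) update only their
    # non-zero rows.
    cols: list[tuple] = []
    for m in range(p):
        c = np.ascontiguousarray(D[:, m])
        nz = np.flatnonzero(c)
        if nz.size <= 0.6 * n:
            cols.append((nz, np.ascontiguousarray(c[nz]), None))
        else:
            cols.append((None, None, c))

    idx_cat = [np.flatnonzero(y0 == j) for j in range(J)]

    alpha = np.asarray(alpha_init, dtype=float).copy()
    coef = np.asarray(coef_init, dtype=float).copy()
    u = np.asarray(u_init, dtype=float).copy()
    s2 = float(sigma_u2_init)

    def refresh_state():
        a_hi = np.where(y0 == nthr, np.inf, alpha[np.minimum(y0, nthr - 1)])
        a_lo = np.where(y0 == 0, -np.inf, alpha[np.maximum(y0 - 1, 0)])
        eta = D @ coef + u[city_index]
        return a_hi, a_lo, eta, _logp_full(a_hi, a_lo, eta)

    a_hi, a_lo, eta, logp = refresh_state()
    if not np.isfinite(logp.sum()):
        raise FloatingPointError("non-finite log-likelihood at initialization")

    # proposal scales, seeded from crude information heuristics
    col_sd = D.std(axis=0)
    col_sd[col_sd == 0] = 1.0
    s_c = 2.5 / (col_sd * np.sqrt(n))
    s_al = np.full(nthr, 2.5 / np.sqrt(max(n, 2)) * 3.0)
    s_u = np.full(K, 0.5)

    two_v = 2.0 * prior_var
    acc_al = np.zeros(nthr)
    acc_c = np.zeros(p)
    acc_u = np.zeros(K)
    post_al = np.zeros(nthr)
    post_c = np.zeros(p)
    post_u = np.zeros(K)
    batch = 0

    n_keep = max(0, -(-(n_iterations - burn_in) // thin))
    out_alpha = np.empty((n_keep, nthr))
    out_coef = np.empty((n_keep, p))
    out_u = np.empty((n_keep, K))
    out_s2 = np.empty(n_keep)
    kept = 0

    for t in range(n_iterations):
        # --- thresholds -------------------------------------------------
        for j in range(nthr):
            prop = alpha[j] + s_al[j] * rng.standard_normal()
            lo = alpha[j - 1] if j > 0 else -np.inf
            hi = alpha[j + 1] if j < nthr - 1 else np.inf
            if lo < prop < hi:
                iu = idx_cat[j]
                il = idx_cat[j + 1]
                pu = expit(prop - eta[iu]) - expit(a_lo[iu] - eta[iu])
                pl = expit(a_hi[il] - eta[il]) - expit(prop - eta[il])
                new_u_lp = np.log(np.maximum(pu, _FLOOR))
                new_l_lp = np.log(np.maximum(pl, _FLOOR))
                delta = (
                    new_u_lp.sum() + new_l_lp.sum()
                    - logp[iu].sum() - logp[il].sum()
                    + (alpha[j] ** 2 - prop ** 2) / two_v
                )
                if np.log(rng.random()) < delta:
                    alpha[j] = prop
                    a_hi[iu] = prop
                    a_lo[il] = prop
                    logp[iu] = new_u_lp
                    logp[il] = new_l_lp
                    acc_al[j] += 1.0

        # --- regression coefficients ------------------------------------
        for m in range(p):
            d = s_c[m] * rng.standard_normal()
            nz, vals, full = cols[m]
            c_old = coef[m]
            c_new = c_old + d
            dprior = (c_old * c_old - c_new * c_new) / two_v
            if full is None:
                eta_s = eta[nz] + d * vals
                pe = expit(a_hi[nz] - eta_s) - expit(a_lo[nz] - eta_s)
                new_lp = np.log(np.maximum(pe, _FLOOR))
                delta = new_lp.sum() - logp[nz].sum() + dprior
                if np.log(rng.random()) < delta:
                    coef[m] = c_new
                    eta[nz] = eta_s
                    logp[nz] = new_lp
                    acc_c[m] += 1.0
            else:
                eta_s = eta + d * full
                pe = expit(a_hi - eta_s) - expit(a_lo - eta_s)
                new_lp = np.log(np.maximum(pe, _FLOOR))
                delta = new_lp.sum() - logp.sum() + dprior
                if np.log(rng.random()) < delta:
                    coef[m] = c_new
                    eta = eta_s
                    logp = new_lp
                    acc_c[m] += 1.0

        # --- city intercepts (independent conditionals, one pass) -------
        du = s_u * rng.standard_normal(K)
        eta_s = eta + du[city_index]
        pe = expit(a_hi - eta_s) - expit(a_lo - eta_s)
        new_lp = np.log(np.maximum(pe, _FLOOR))
        d_ll = np.add.reduceat(new_lp - logp, group_starts)
        u_new = u + du
        d_prior = (u * u - u_new * u_new) / (2.0 * s2)
        acc = np.log(rng.random(K)) < (d_ll + d_prior)
        if acc.any():
            take = acc[city_index]
            eta = np.where(take, eta_s, eta)
            logp = np.where(take, new_lp, logp)
            u = np.where(acc, u_new, u)
            acc_u += acc

        # --- sigma_u^2: conjugate inverse-gamma Gibbs --------------------
        s2 = 1.0 / rng.gamma(ig_shape + 0.5 * K, 1.0 / (ig_scale + 0.5 * float(u @ u)))

        # --- adaptation (burn-in only) -----------------------------------
        if t < burn_in:
            if (t + 1) % adapt_interval == 0:
                batch += 1
                step = min(1.0, 5.0 / np.sqrt(batch))
                s_al *= np.exp(step * (acc_al / adapt_interval - target_acceptance))
                s_c *= np.exp(step * (acc_c / adapt_interval - target_acceptance))
                s_u *= np.exp(step * (acc_u / adapt_interval - target_acceptance))
                np.clip(s_al, 1e-5, 50.0, out=s_al)
                np.clip(s_c, 1e-6, 50.0, out=s_c)
                np.clip(s_u, 1e-5, 50.0, out=s_u)
                acc_al[:] = 0.0
                acc_c[:] = 0.0
                acc_u[:] = 0.0
            if t == burn_in - 1:
                acc_al[:] = 0.0
                acc_c[:] = 0.0
                acc_u[:] = 0.0
        else:
            post_al += acc_al
            post_c += acc_c
            post_u += acc_u
            acc_al[:] = 0.0
            acc_c[:] = 0.0
            acc_u[:] = 0.0

        if (t + 1) % _REFRESH_EVERY == 0:
            a_hi, a_lo, eta, logp = refresh_state()

        if t >= burn_in and (t - burn_in) % thin == 0:
            out_alpha[kept] = alpha
            out_coef[kept] = coef
            out_u[kept] = u
            out_s2[kept] = s2
            kept += 1

    n_post = max(1, n_iterations - burn_in)
    return {
        "alpha": out_alpha[:kept],
        "coef": out_coef[:kept],
        "u": out_u[:kept],
        "sigma_u2": out_s2[:kept],
        "acceptance": {
            "alpha": post_al / n_post,
            "coef": post_c / n_post,
            "u": post_u / n_post,
        },
        "scales": {"alpha": s_al, "coef": s_c, "u": s_u},
    }
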