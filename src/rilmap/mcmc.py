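"""Gibbs sampler for the saturated QTS mixed model.

Model (observation in environment h, line k):

    y_hk = mu + sum_i a_i x_ik + sum_ij aa_ij x_ik x_jk
           + e_h + sum_i ae_hi x_ik + sum_ij aae_hij x_ik x_jk + eps_hk

Fixed effects beta = (mu, a, aa) carry a diffuse normal prior
N(0, 1e6 * var(y)).  Random vectors e, ae, aae and the residual have
scaled-inverse-chi-square variance priors (nu0 = 2, with the scale s0^2
set to 1% of the initial least-squares residual variance), weakly
informative so the data dominate whenever a component is present.
All full conditionals are conjugate:

  beta  | rest ~ N over the fixed design,
  e_h   | rest ~ N (environment-block means),
  ae_h. | rest ~ N (per-environment solve over the additive columns),
  aae_h.| rest ~ N (per-environment solve over the product columns),
  sigma2_g | u ~ (nu0 s0^2 + u'u) / chi2(nu0 + q_g).

Chains are initialised at the least-squares solution for beta so the
sampler starts in the high-density region.  A small lower bound guards
against degenerate variance draws.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

NU0 = 2.0
S0_FRACTION = 0.01  # prior scale s0^2 as a fraction of var(y)
VAR_FLOOR_FRACTION = 1e-12


def _sample_mvn_from_precision(P: np.ndarray, b: np.ndarray, rng) -> np.ndarray:
    """Draw from N(P^-1 b, P^-1) via Cholesky of the precision."""
    L = np.linalg.cholesky(P)
    mean = np.linalg.solve(P, b)
    z = rng.standard_normal(len(b))
    return mean + np.linalg.solve(L.T, z)


def gibbs_fit(model, selected, iterations, burn_in, seed, keep_trace=False) -> dict:
    rng = np.random.default_rng(seed)
    y = model.y
    n = model.n_obs
    n_env = model.n_env
    vy = float(np.var(y, ddof=1)) if n > 1 else 1.0
    if vy == 0:
        vy = 1.0
    floor = VAR_FLOOR_FRACTION * vy

    snps = list(selected.snps)
    pairs = [tuple(p) for p in selected.pairs]
    k, p = len(snps), len(pairs)
    Xl = model.X[model.line_idx]
    a_cols = np.column_stack([Xl[:, model._snp_pos[s]] for s in snps]) if k else np.zeros((n, 0))
    aa_cols = (
        np.column_stack(
            [Xl[:, model._snp_pos[i]] * Xl[:, model._snp_pos[j]] for i, j in pairs]
        )
        if p
        else np.zeros((n, 0))
    )
    Xf = np.column_stack([np.ones(n), a_cols, aa_cols])
    names = ["mu"] + [f"a:{s}" for s in snps] + [f"aa:{i}|{j}" for i, j in pairs]
    m = Xf.shape[1]

    XtX = Xf.T @ Xf
    prior_prec_beta = np.eye(m) / (1e6 * vy)

    env_obs = model._env_obs
    n_h = np.array([len(idx) for idx in env_obs], dtype=float)
    # per-environment Gram matrices for the random-interaction solves
    A_ae = [a_cols[idx].T @ a_cols[idx] for idx in env_obs] if k else None
    A_aae = [aa_cols[idx].T @ aa_cols[idx] for idx in env_obs] if p else None

    # state
    beta, *_ = np.linalg.lstsq(Xf, y, rcond=None)
    e = np.zeros(n_env)
    u_ae = np.zeros((n_env, k))
    u_aae = np.zeros((n_env, p))
    r0 = y - Xf @ beta
    sig_eps = max(float(r0 @ r0) / max(n - m, 1), floor)
    # prior scale tracks the initial residual variance (empirical scaling):
    # weakly informative relative to the noise level, and collapsing with it
    # in the degenerate noise-free case
    s0sq = max(S0_FRACTION * sig_eps, floor)
    sig_e = sig_ae = sig_aae = max(s0sq, floor)

    fit_beta = Xf @ beta
    fit_e = e[model.env_idx]
    fit_ae = np.zeros(n)
    fit_aae = np.zeros(n)

    n_keep = iterations - burn_in
    beta_sum = np.zeros(m)
    beta_sq = np.zeros(m)
    vc_sum = np.zeros(4)  # e, ae, aae, eps
    trace = np.empty((n_keep, m)) if keep_trace else None

    for it in range(iterations):
        # --- fixed effects ---
        r = y - fit_e - fit_ae - fit_aae
        P = XtX / sig_eps + prior_prec_beta
        beta = _sample_mvn_from_precision(P, Xf.T @ r / sig_eps, rng)
        fit_beta = Xf @ beta

        # --- environment main effects ---
        r = y - fit_beta - fit_ae - fit_aae
        sums = np.array([r[idx].sum() for idx in env_obs])
        prec = n_h / sig_eps + 1.0 / sig_e
        mean = (sums / sig_eps) / prec
        e = mean + rng.standard_normal(n_env) / np.sqrt(prec)
        fit_e = e[model.env_idx]

        # --- additive-by-environment interactions ---
        if k:
            r = y - fit_beta - fit_e - fit_aae
            for h, idx in enumerate(env_obs):
                P = A_ae[h] / sig_eps + np.eye(k) / sig_ae
                b = a_cols[idx].T @ r[idx] / sig_eps
                u_ae[h] = _sample_mvn_from_precision(P, b, rng)
                fit_ae[idx] = a_cols[idx] @ u_ae[h]

        # --- epistasis-by-environment interactions ---
        if p:
            r = y - fit_beta - fit_e - fit_ae
            for h, idx in enumerate(env_obs):
                P = A_aae[h] / sig_eps + np.eye(p) / sig_aae
                b = aa_cols[idx].T @ r[idx] / sig_eps
                u_aae[h] = _sample_mvn_from_precision(P, b, rng)
                fit_aae[idx] = aa_cols[idx] @ u_aae[h]

        # --- variance components ---
        e_ss = float(e @ e)
        sig_e = max((NU0 * s0sq + e_ss) / rng.chisquare(NU0 + n_env), floor)
        if k:
            ss = float((u_ae**2).sum())
            sig_ae = max((NU0 * s0sq + ss) / rng.chisquare(NU0 + n_env * k), floor)
        if p:
            ss = float((u_aae**2).sum())
            sig_aae = max((NU0 * s0sq + ss) / rng.chisquare(NU0 + n_env * p), floor)
        resid = y - fit_beta - fit_e - fit_ae - fit_aae
        sig_eps = max(
            (NU0 * s0sq + float(resid @ resid)) / rng.chisquare(NU0 + n), floor
        )

        if it >= burn_in:
            beta_sum += beta
            beta_sq += beta**2
            vc_sum += (sig_e, sig_ae if k else 0.0, sig_aae if p else 0.0, sig_eps)
            if keep_trace:
                trace[it - burn_in] = beta

    mean = beta_sum / n_keep
    var = np.maximum(beta_sq / n_keep - mean**2, 0.0)
    sd = np.sqrt(var)
    vc_mean = vc_sum / n_keep
    out = {
        "mean": pd.Series(mean, index=names),
        "sd": pd.Series(sd, index=names),
        "varcomps": {
            "sigma2_e": float(vc_mean[0]),
            "sigma2_ae": float(vc_mean[1]) if k else np.nan,
            "sigma2_aae": float(vc_mean[2]) if p else np.nan,
            "sigma2_eps": float(vc_mean[3]),
        },
    }
    if keep_trace:
        out["trace"] = pd.DataFrame(trace, columns=names)
    return out
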