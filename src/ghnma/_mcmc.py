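"""MCMC kernels for the fixed-effects arm-based NMA models.

Continuous outcomes use a Gibbs sampler: with known arm standard errors the
model ``y_a ~ Normal(mu_i(a) + d_t(a) - d_b(a), se_a^2)`` with normal priors
is conditionally conjugate, so every full conditional is normal and mixing
is essentially immediate.  Binary outcomes use adaptive random-walk
Metropolis within Gibbs on the binomial-logit likelihood; the proposal scale
adapts toward ~44% acceptance during burn-in only and is frozen afterwards.

All chains are advanced in lock-step as a vectorised batch driven by one
seeded generator, which makes runs bit-reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np

# index 0 of the treatment axis is always the network reference; d[..., 0] == 0


def _prepare(trial_idx, treat_idx, base_of_trial, n_trials, n_treat):
    trial_idx = np.asarray(trial_idx, dtype=np.intp)
    treat_idx = np.asarray(treat_idx, dtype=np.intp)
    base_of_trial = np.asarray(base_of_trial, dtype=np.intp)
    base_of_arm = base_of_trial[trial_idx]
    trial_arms = [np.flatnonzero(trial_idx == i) for i in range(n_trials)]
    # per free treatment k: arms where k enters with coefficient +1 or -1
    coefs = []
    for k in range(1, n_treat):
        c = (treat_idx == k).astype(np.float64) - (base_of_arm == k)
        idx = np.flatnonzero(c != 0.0)
        coefs.append((idx, c[idx]))
    return trial_idx, treat_idx, base_of_arm, trial_arms, coefs


def gibbs_continuous(
    y,
    se,
    trial_idx,
    treat_idx,
    base_of_trial,
    n_trials,
    n_treat,
    prior_sd_d,
    prior_sd_mu,
    chains,
    iterations,
    burn_in,
    seed,
):
    """Gibbs sampler for the normal identity-link model.

    Returns ``(d, mu)`` with shapes ``(chains, kept, n_treat)`` and
    ``(chains, kept, n_trials)``; ``d[..., 0]`` is identically zero.
    """
    y = np.asarray(y, dtype=np.float64)
    w = 1.0 / np.asarray(se, dtype=np.float64) ** 2
    trial_idx, treat_idx, base_of_arm, trial_arms, coefs = _prepare(
        trial_idx, treat_idx, base_of_trial, n_trials, n_treat
    )
    prec_d = 1.0 / prior_sd_d**2
    prec_mu = 1.0 / prior_sd_mu**2
    # posterior precisions of the conditionals are data-constant
    P_mu = np.array([w[idx].sum() + prec_mu for idx in trial_arms])
    P_d = np.array([(c**2 * w[idx]).sum() + prec_d for idx, c in coefs])

    rng = np.random.default_rng(seed)
    spread = max(1.0, float(np.std(y))) if y.size else 1.0
    d = np.zeros((chains, n_treat))
    d[:, 1:] = rng.standard_normal((chains, n_treat - 1)) * spread
    mu = rng.standard_normal((chains, n_trials)) * spread + float(np.mean(y))

    kept = iterations - burn_in
    out_d = np.empty((chains, kept, n_treat))
    out_mu = np.empty((chains, kept, n_trials))
    sqrtP_mu = np.sqrt(P_mu)
    sqrtP_d = np.sqrt(P_d)

    for it in range(iterations):
        contrast = d[:, treat_idx] - d[:, base_of_arm]  # (chains, A)
        for i in range(n_trials):
            idx = trial_arms[i]
            num = ((y[idx] - contrast[:, idx]) * w[idx]).sum(axis=1)
            mu[:, i] = num / P_mu[i] + rng.standard_normal(chains) / sqrtP_mu[i]
        for j, (idx, c) in enumerate(coefs):
            k = j + 1
            partial = (
                y[idx]
                - mu[:, trial_idx[idx]]
                - (d[:, treat_idx[idx]] - d[:, base_of_arm[idx]])
                + c * d[:, k:k + 1]
            )
            num = (c * w[idx] * partial).sum(axis=1)
            d[:, k] = num / P_d[j] + rng.standard_normal(chains) / sqrtP_d[j]
        if it >= burn_in:
            out_d[:, it - burn_in] = d
            out_mu[:, it - burn_in] = mu
    return out_d, out_mu


def _loglik_delta(r, n, eta_old, eta_new):
    """Binomial log-likelihood difference, summed over the given arms."""
    return (
        r * (eta_new - eta_old)
        - n * (np.logaddexp(0.0, eta_new) - np.logaddexp(0.0, eta_old))
    ).sum(axis=1)


def metropolis_binary(
    events,
    n,
    trial_idx,
    treat_idx,
    base_of_trial,
    n_trials,
    n_treat,
    prior_sd_d,
    prior_sd_mu,
    chains,
    iterations,
    burn_in,
    seed,
):
    """Adaptive Metropolis-within-Gibbs for the binomial-logit model.

    Zero-event arms need no continuity correction: the exact binomial
    likelihood remains proper under the normal priors.
    """
    r_ev = np.asarray(events, dtype=np.float64)
    n_arr = np.asarray(n, dtype=np.float64)
    trial_idx, treat_idx, base_of_arm, trial_arms, coefs = _prepare(
        trial_idx, treat_idx, base_of_trial, n_trials, n_treat
    )
    prec_d = 1.0 / prior_sd_d**2
    prec_mu = 1.0 / prior_sd_mu**2

    rng = np.random.default_rng(seed)
    d = rng.standard_normal((chains, n_treat - 1)) * 0.5
    d = np.concatenate([np.zeros((chains, 1)), d], axis=1)
    # initialise baselines near the empirical logit of the trial event rate
    mu = np.empty((chains, n_trials))
    for i, idx in enumerate(trial_arms):
        p = (r_ev[idx].sum() + 0.5) / (n_arr[idx].sum() + 1.0)
        mu[:, i] = np.log(p / (1 - p)) + 0.5 * rng.standard_normal(chains)

    step_mu = np.full(n_trials, 0.5)
    step_d = np.full(n_treat - 1, 0.5)
    acc_mu = np.zeros(n_trials)
    acc_d = np.zeros(n_treat - 1)
    ADAPT_EVERY = 50

    kept = iterations - burn_in
    out_d = np.empty((chains, kept, n_treat))
    out_mu = np.empty((chains, kept, n_trials))

    for it in range(iterations):
        for i in range(n_trials):
            idx = trial_arms[i]
            eta = mu[:, i:i + 1] + d[:, treat_idx[idx]] - d[:, base_of_arm[idx]]
            prop = mu[:, i] + step_mu[i] * rng.standard_normal(chains)
            eta_new = eta + (prop - mu[:, i])[:, None]
            logr = _loglik_delta(r_ev[idx], n_arr[idx], eta, eta_new)
            logr -= 0.5 * prec_mu * (prop**2 - mu[:, i] ** 2)
            accept = np.log(rng.random(chains)) < logr
            mu[accept, i] = prop[accept]
            acc_mu[i] += accept.mean()
        for j, (idx, c) in enumerate(coefs):
            k = j + 1
            eta = mu[:, trial_idx[idx]] + d[:, treat_idx[idx]] - d[:, base_of_arm[idx]]
            prop = d[:, k] + step_d[j] * rng.standard_normal(chains)
            eta_new = eta + c * (prop - d[:, k])[:, None]
            logr = _loglik_delta(r_ev[idx], n_arr[idx], eta, eta_new)
            logr -= 0.5 * prec_d * (prop**2 - d[:, k] ** 2)
            accept = np.log(rng.random(chains)) < logr
            d[accept, k] = prop[accept]
            acc_d[j] += accept.mean()
        if it < burn_in and (it + 1) % ADAPT_EVERY == 0:
            step_mu *= np.exp(acc_mu / ADAPT_EVERY - 0.44)
            step_d *= np.exp(acc_d / ADAPT_EVERY - 0.44)
            np.clip(step_mu, 1e-3, 10.0, out=step_mu)
            np.clip(step_d, 1e-3, 10.0, out=step_d)
            acc_mu[:] = 0.0
            acc_d[:] = 0.0
        if it >= burn_in:
            out_d[:, it - burn_in] = d
            out_mu[:, it - burn_in] = mu
    return out_d, out_mu
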