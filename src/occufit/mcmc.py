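"""Data-augmentation MCMC for the Bayesian random-effects occupancy model.

Occupancy: logit(psi_it) = b_t + u_i with u_i ~ N(0, sigma_u).  Detection:
either constant on the logit scale, or logit(p_itj) = a_t + k log(G_itj)
with a_t ~ N(mu, sigma) when list lengths are supplied.  Latent occupancy
states z_it are Gibbs-sampled; all other parameters use random-walk
Metropolis within their prior support, with proposal scales adapted toward
0.44 acceptance during burn-in and frozen afterwards.

The annual index is the mean of the sampled latent states over sites,
stored per draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit, logit

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "ModelBChains",
    "PosteriorSummary",
    "simulation_priors",
    "sample_z_conditional",
    "mcmc_run",
    "posterior_index_summary",
]

_ADAPT_BATCH = 50
_TARGET_ACCEPT = 0.44


@dataclass(frozen=True)
class PriorSpec:
    """Prior bounds/scales: uniforms as (low, high), mu as Normal(mean, sd)."""

    b_bounds: tuple[float, float] = (-10.0, 10.0)
    sigma_u_bounds: tuple[float, float] = (0.0, 5.0)
    mu_prior: tuple[float, float] = (0.0, 10.0)
    sigma_bounds: tuple[float, float] = (0.0, 5.0)
    k_bounds: tuple[float, float] = (-10.0, 10.0)
    logit_p_bounds: tuple[float, float] = (-10.0, 10.0)

    def __post_init__(self) -> None:
        for name in ("b_bounds", "sigma_u_bounds", "sigma_bounds", "k_bounds", "logit_p_bounds"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"{name} must be finite and ordered")
        if self.mu_prior[1] <= 0:
            raise ValueError("mu prior sd must be positive")


def simulation_priors() -> PriorSpec:
    """Prior variant used for the simulation study: sigma_u ~ U(0, 25)."""
    return PriorSpec(sigma_u_bounds=(0.0, 25.0))


@dataclass(frozen=True)
class McmcConfig:
    n_chains: int = 3
    n_iter: int = 10_000
    burn_in_fraction: float = 0.2
    thin: int = 3
    seed: int = 0
    adapt: bool = True

    def __post_init__(self) -> None:
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must be in [0, 1)")
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed the burn-in length")

    @property
    def burn_in(self) -> int:
        return int(self.burn_in_fraction * self.n_iter)

    @property
    def n_stored(self) -> int:
        return len(range(self.burn_in, self.n_iter, self.thin))


@dataclass
class ModelBChains:
    """Post-burn-in, thinned draws; arrays are (n_chains, n_stored[, dim])."""

    draws: dict
    config: McmcConfig
    priors: PriorSpec
    n_years: int
    n_sites: int

    @property
    def index_draws(self) -> np.ndarray:
        return self.draws["index"]

    def stacked(self, name: str) -> np.ndarray:
        """Draws pooled over chains, shape (n_chains * n_stored[, dim])."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def to_frame(self) -> pd.DataFrame:
        """Long table (chain, iteration, parameter, value) for persistence."""
        rows = []
        for name, arr in self.draws.items():
            for c in range(arr.shape[0]):
                block = arr[c]
                if block.ndim == 1:
                    block = block[:, None]
                for d in range(block.shape[1]):
                    label = name if block.shape[1] == 1 else f"{name}[{d + 1}]"
                    rows.append(
                        pd.DataFrame(
                            {
                                "chain": c + 1,
                                "iteration": np.arange(block.shape[0]),
                                "parameter": label,
                                "value": block[:, d],
                            }
                        )
                    )
        return pd.concat(rows, ignore_index=True)


@dataclass
class PosteriorSummary:
    index_mean: np.ndarray
    index_sd: np.ndarray
    index_quantiles: pd.DataFrame
    rhat: dict
    percent_change: float | None = None
    percent_change_ci: tuple[float, float] | None = None


def sample_z_conditional(y_i_year, psi: float, p_vector, rng) -> int:
    """Draw the latent occupancy state for one site-year.

    Any detection forces z = 1; otherwise z is Bernoulli with posterior
    probability psi * prod(1 - p_j) / (psi * prod(1 - p_j) + 1 - psi),
    taken over the observed visits only.
    """
    y = np.asarray(y_i_year, dtype=float)
    mask = ~np.isnan(y)
    if np.any(y[mask] == 1):
        return 1
    p = np.broadcast_to(np.asarray(p_vector, dtype=float), y.shape)[mask]
    log_q = float(np.sum(np.log1p(-p)))
    prob = expit(logit(psi) + log_q) if 0.0 < psi < 1.0 else float(psi)
    return int(rng.random() < prob)


def _bernoulli_loglik_by_year(eta, z):
    # sum_i z*eta - log(1 + e^eta), per year
    return np.sum(z * eta - np.logaddexp(0.0, eta), axis=1)


def _bernoulli_loglik_by_site(eta, z):
    return np.sum(z * eta - np.logaddexp(0.0, eta), axis=0)


class _ScaleAdapter:
    """Batch Metropolis scale adaptation toward a target acceptance rate."""

    def __init__(self, shape, init=0.5):
        self.scale = np.full(shape, init) if shape else init
        self._acc = np.zeros(shape) if shape else 0.0
        self._n = 0

    def record(self, accepted):
        self._acc = self._acc + accepted
        self._n += 1

    def maybe_adapt(self):
        if self._n >= _ADAPT_BATCH:
            rate = self._acc / self._n
            self.scale = self.scale * np.exp(np.clip(rate - _TARGET_ACCEPT, -0.5, 0.5))
            self._acc = self._acc * 0.0
            self._n = 0


def _softplus(x):
    return np.logaddexp(0.0, x)


def _run_chain_constant_p(
    d, n, det,
    priors: PriorSpec = PriorSpec(),
    n_iter=10_000, burn=2_000, thin=3,
    random_effect=True, fixed_p=None,
    rng=None, adapt=True,
):
    """One chain with detection constant on the logit scale.

    d, n, det are (T, S) detection counts / visit counts / any-detection
    masks.  The linear predictor, its softplus and the Bernoulli log-lik
    matrix are cached and patched on acceptance, so each sweep costs three
    transcendental passes over (T, S).
    """
    T, S = d.shape
    obs = n > 0

    # initial state: empirical year effects, z = 1 wherever ambiguous
    naive = det[:, obs.any(axis=0)].mean(axis=1) if obs.any() else np.full(T, 0.5)
    b = logit(np.clip(naive, 0.05, 0.95))
    u = np.zeros(S)
    sigma_u = 1.0
    logit_p = 0.0 if fixed_p is None else float(logit(fixed_p))
    l1p = float(log_expit(-logit_p))

    ad_b = _ScaleAdapter((T,))
    ad_u = _ScaleAdapter(None)
    ad_su = _ScaleAdapter(None)
    ad_p = _ScaleAdapter(None)

    n_stored = len(range(burn, n_iter, thin))
    store = {
        "b": np.empty((n_stored, T)),
        "sigma_u": np.empty(n_stored),
        "logit_p": np.empty(n_stored),
        "index": np.empty((n_stored, T)),
    }

    eta = b[:, None] + u[None, :]
    sp = _softplus(eta)

    idx = 0
    for it in range(n_iter):
        adapting = adapt and it < burn

        # --- Gibbs update of latent occupancy states ---------------------
        prob_z = expit(eta + n * l1p)
        z = (rng.random((T, S)) < prob_z).astype(float)
        z[det] = 1.0
        M = z * eta - sp  # Bernoulli log-lik of z given eta, per cell

        # --- year effects b_t (independent conditionals; vector MH) ------
        prop = b + ad_b.scale * rng.standard_normal(T)
        inside = (prop > priors.b_bounds[0]) & (prop < priors.b_bounds[1])
        eta_p = eta + (prop - b)[:, None]
        sp_p = _softplus(eta_p)
        M_p = z * eta_p - sp_p
        acc = inside & (np.log(rng.random(T)) < M_p.sum(axis=1) - M.sum(axis=1))
        if acc.any():
            b = np.where(acc, prop, b)
            rows = acc[:, None]
            eta = np.where(rows, eta_p, eta)
            sp = np.where(rows, sp_p, sp)
            M = np.where(rows, M_p, M)
        if adapting:
            ad_b.record(acc.astype(float))
            ad_b.maybe_adapt()

        # --- site random effects u_i -------------------------------------
        if random_effect:
            prop_u = u + ad_u.scale * rng.standard_normal(S)
            eta_p = eta + (prop_u - u)[None, :]
            sp_p = _softplus(eta_p)
            M_p = z * eta_p - sp_p
            cur = M.sum(axis=0) - u**2 / (2.0 * sigma_u**2)
            new = M_p.sum(axis=0) - prop_u**2 / (2.0 * sigma_u**2)
            acc_u = np.log(rng.random(S)) < new - cur
            if acc_u.any():
                u = np.where(acc_u, prop_u, u)
                cols = acc_u[None, :]
                eta = np.where(cols, eta_p, eta)
                sp = np.where(cols, sp_p, sp)
            if adapting:
                ad_u.record(acc_u.mean())
                ad_u.maybe_adapt()

            # --- sigma_u --------------------------------------------------
            prop_s = sigma_u + ad_su.scale * rng.standard_normal()
            acc_s = 0.0
            if priors.sigma_u_bounds[0] < prop_s < priors.sigma_u_bounds[1]:
                ssq = float(np.sum(u**2))
                cur = -S * np.log(sigma_u) - ssq / (2.0 * sigma_u**2)
                new = -S * np.log(prop_s) - ssq / (2.0 * prop_s**2)
                if np.log(rng.random()) < new - cur:
                    sigma_u = prop_s
                    acc_s = 1.0
            if adapting:
                ad_su.record(acc_s)
                ad_su.maybe_adapt()

        # --- detection probability ---------------------------------------
        if fixed_p is None:
            n_det = float(np.sum(z * d))
            n_non = float(np.sum(z * (n - d)))
            prop_p = logit_p + ad_p.scale * rng.standard_normal()
            acc_p = 0.0
            if priors.logit_p_bounds[0] < prop_p < priors.logit_p_bounds[1]:
                cur = n_det * log_expit(logit_p) + n_non * log_expit(-logit_p)
                new = n_det * log_expit(prop_p) + n_non * log_expit(-prop_p)
                if np.log(rng.random()) < new - cur:
                    logit_p = prop_p
                    l1p = float(log_expit(-logit_p))
                    acc_p = 1.0
            if adapting:
                ad_p.record(acc_p)
                ad_p.maybe_adapt()

        # --- storage ------------------------------------------------------
        if it >= burn and (it - burn) % thin == 0:
            store["b"][idx] = b
            store["sigma_u"][idx] = sigma_u if random_effect else 0.0
            store["logit_p"][idx] = logit_p
            store["index"][idx] = z.mean(axis=1)
            idx += 1

    return store


def _run_chain_list_length(
    d, n, det, y, mask, logG,
    priors: PriorSpec = PriorSpec(),
    n_iter=10_000, burn=2_000, thin=3,
    random_effect=True,
    rng=None, adapt=True,
):
    """One chain with the a_t + k log(G) detection model; y, mask, logG are
    the per-visit (T, S, V) arrays."""
    T, S = d.shape
    obs = n > 0

    naive = det[:, obs.any(axis=0)].mean(axis=1) if obs.any() else np.full(T, 0.5)
    b = logit(np.clip(naive, 0.05, 0.95))
    u = np.zeros(S)
    sigma_u = 1.0
    a = np.zeros(T)
    k = 0.0
    mu = 0.0
    sigma = 1.0

    ad_b = _ScaleAdapter((T,))
    ad_u = _ScaleAdapter(None)
    ad_su = _ScaleAdapter(None)
    ad_a = _ScaleAdapter((T,))
    ad_k = _ScaleAdapter(None)
    ad_mu = _ScaleAdapter(None)
    ad_sig = _ScaleAdapter(None)

    n_stored = len(range(burn, n_iter, thin))
    store = {
        "b": np.empty((n_stored, T)),
        "sigma_u": np.empty(n_stored),
        "a": np.empty((n_stored, T)),
        "k": np.empty(n_stored),
        "mu": np.empty(n_stored),
        "sigma": np.empty(n_stored),
        "index": np.empty((n_stored, T)),
    }

    def det_loglik_terms():
        """Per-(t, s) log-lik of the data given z=1, and log prod (1 - p)."""
        eta_p = a[:, None, None] + k * logG
        ll = np.where(mask, y * log_expit(eta_p) + (1 - y) * log_expit(-eta_p), 0.0)
        return ll.sum(axis=2), np.where(mask, log_expit(-eta_p), 0.0).sum(axis=2)

    idx = 0
    for it in range(n_iter):
        adapting = adapt and it < burn

        # --- Gibbs update of latent occupancy states ---------------------
        eta = b[:, None] + u[None, :]
        _, log_q = det_loglik_terms()
        prob_z = expit(eta + log_q)
        z = (rng.random((T, S)) < prob_z).astype(float)
        z[det] = 1.0

        # --- year effects b_t (independent conditionals; vector MH) ------
        prop = b + ad_b.scale * rng.standard_normal(T)
        inside = (prop > priors.b_bounds[0]) & (prop < priors.b_bounds[1])
        cur_ll = _bernoulli_loglik_by_year(eta, z)
        new_ll = _bernoulli_loglik_by_year(prop[:, None] + u[None, :], z)
        acc = inside & (np.log(rng.random(T)) < new_ll - cur_ll)
        b = np.where(acc, prop, b)
        if adapting:
            ad_b.record(acc.astype(float))
            ad_b.maybe_adapt()

        # --- site random effects u_i -------------------------------------
        if random_effect:
            eta = b[:, None] + u[None, :]
            prop_u = u + ad_u.scale * rng.standard_normal(S)
            cur = _bernoulli_loglik_by_site(eta, z) - u**2 / (2.0 * sigma_u**2)
            new = (
                _bernoulli_loglik_by_site(b[:, None] + prop_u[None, :], z)
                - prop_u**2 / (2.0 * sigma_u**2)
            )
            acc_u = np.log(rng.random(S)) < new - cur
            u = np.where(acc_u, prop_u, u)
            if adapting:
                ad_u.record(acc_u.mean())
                ad_u.maybe_adapt()

            prop_s = sigma_u + ad_su.scale * rng.standard_normal()
            acc_s = 0.0
            if priors.sigma_u_bounds[0] < prop_s < priors.sigma_u_bounds[1]:
                ssq = float(np.sum(u**2))
                cur = -S * np.log(sigma_u) - ssq / (2.0 * sigma_u**2)
                new = -S * np.log(prop_s) - ssq / (2.0 * prop_s**2)
                if np.log(rng.random()) < new - cur:
                    sigma_u = prop_s
                    acc_s = 1.0
            if adapting:
                ad_su.record(acc_s)
                ad_su.maybe_adapt()

        # --- detection parameters ----------------------------------------
        occ_obs = (z == 1.0) & obs
        ll_ts, _ = det_loglik_terms()

        def det_ll_for(a_vec, k_val):
            eta_p = a_vec[:, None, None] + k_val * logG
            ll = np.where(
                mask, y * log_expit(eta_p) + (1 - y) * log_expit(-eta_p), 0.0
            ).sum(axis=2)
            return np.where(occ_obs, ll, 0.0).sum(axis=1)

        cur_by_year = np.where(occ_obs, ll_ts, 0.0).sum(axis=1)
        prop_a = a + ad_a.scale * rng.standard_normal(T)
        new_by_year = det_ll_for(prop_a, k)
        prior_cur = -((a - mu) ** 2) / (2.0 * sigma**2)
        prior_new = -((prop_a - mu) ** 2) / (2.0 * sigma**2)
        acc_a = np.log(rng.random(T)) < (new_by_year + prior_new) - (
            cur_by_year + prior_cur
        )
        a = np.where(acc_a, prop_a, a)
        if adapting:
            ad_a.record(acc_a.astype(float))
            ad_a.maybe_adapt()

        prop_k = k + ad_k.scale * rng.standard_normal()
        if priors.k_bounds[0] < prop_k < priors.k_bounds[1]:
            cur_tot = det_ll_for(a, k).sum()
            new_tot = det_ll_for(a, prop_k).sum()
            if np.log(rng.random()) < new_tot - cur_tot:
                k = prop_k
                acc_k = 1.0
            else:
                acc_k = 0.0
        else:
            acc_k = 0.0
        if adapting:
            ad_k.record(acc_k)
            ad_k.maybe_adapt()

        # hyper-parameters of a_t
        prop_mu = mu + ad_mu.scale * rng.standard_normal()
        cur = (
            -np.sum((a - mu) ** 2) / (2.0 * sigma**2)
            - (mu - priors.mu_prior[0]) ** 2 / (2.0 * priors.mu_prior[1] ** 2)
        )
        new = (
            -np.sum((a - prop_mu) ** 2) / (2.0 * sigma**2)
            - (prop_mu - priors.mu_prior[0]) ** 2 / (2.0 * priors.mu_prior[1] ** 2)
        )
        acc_mu = float(np.log(rng.random()) < new - cur)
        if acc_mu:
            mu = prop_mu
        if adapting:
            ad_mu.record(acc_mu)
            ad_mu.maybe_adapt()

        prop_sig = sigma + ad_sig.scale * rng.standard_normal()
        if priors.sigma_bounds[0] < prop_sig < priors.sigma_bounds[1]:
            ssq = float(np.sum((a - mu) ** 2))
            cur = -T * np.log(sigma) - ssq / (2.0 * sigma**2)
            new = -T * np.log(prop_sig) - ssq / (2.0 * prop_sig**2)
            acc_sig = float(np.log(rng.random()) < new - cur)
            if acc_sig:
                sigma = prop_sig
        else:
            acc_sig = 0.0
        if adapting:
            ad_sig.record(acc_sig)
            ad_sig.maybe_adapt()

        # --- storage ------------------------------------------------------
        if it >= burn and (it - burn) % thin == 0:
            store["b"][idx] = b
            store["sigma_u"][idx] = sigma_u if random_effect else 0.0
            store["index"][idx] = z.mean(axis=1)
            store["a"][idx] = a
            store["k"][idx] = k
            store["mu"][idx] = mu
            store["sigma"][idx] = sigma
            idx += 1

    return store


def mcmc_run(
    histories: np.ndarray,
    list_lengths: np.ndarray | None = None,
    priors: PriorSpec | None = None,
    config: McmcConfig | None = None,
    random_effect: bool = True,
    fixed_p: float | None = None,
) -> ModelBChains:
    """Run the model-B sampler on (n_years, n_sites, n_visits) histories.

    NaN history entries mark missing visits.  With ``list_lengths`` the
    detection model is a_t + k log(G); otherwise detection is constant on
    the logit scale (optionally fixed at ``fixed_p``).
    """
    priors = priors or PriorSpec()
    config = config or McmcConfig()
    y = np.asarray(histories, dtype=float)
    if y.ndim != 3:
        raise ValueError("histories must be (n_years, n_sites, n_visits)")
    mask = ~np.isnan(y)
    y0 = np.where(mask, y, 0.0)
    d = y0.sum(axis=2)
    n = mask.sum(axis=2).astype(float)
    det = d > 0

    list_length_mode = list_lengths is not None
    logG = None
    if list_length_mode:
        G = np.asarray(list_lengths, dtype=float)
        if G.shape != y.shape:
            raise ValueError("list_lengths must match histories shape")
        logG = np.where(mask, np.log(np.where(mask, G, 1.0)), 0.0)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chain_stores = []
    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        common = dict(
            priors=priors,
            n_iter=config.n_iter,
            burn=config.burn_in,
            thin=config.thin,
            random_effect=random_effect,
            rng=rng,
            adapt=config.adapt,
        )
        if list_length_mode:
            if fixed_p is not None:
                raise ValueError("fixed_p is incompatible with list-length detection")
            chain_stores.append(
                _run_chain_list_length(d, n, det, y0, mask, logG, **common)
            )
        else:
            chain_stores.append(
                _run_chain_constant_p(d, n, det, fixed_p=fixed_p, **common)
            )

    draws = {
        name: np.stack([cs[name] for cs in chain_stores])
        for name in chain_stores[0]
    }
    return ModelBChains(
        draws=draws,
        config=config,
        priors=priors,
        n_years=y.shape[0],
        n_sites=y.shape[1],
    )


def _split_rhat(arr: np.ndarray) -> float:
    """Split-chain R-hat for draws shaped (n_chains, n_stored)."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(np.asarray(arr)))


def posterior_index_summary(
    chains: ModelBChains, pct_change_years: tuple[int, int] | None = None
) -> PosteriorSummary:
    """Posterior summaries of the annual index (and optional percent change).

    ``pct_change_years`` are 1-based year positions; the percent change is
    summarised over draws of (I_to - I_from) / I_from * 100.
    """
    idx = chains.stacked("index")  # (draws, T)
    qs = np.quantile(idx, [0.025, 0.5, 0.975], axis=0)
    quantiles = pd.DataFrame(
        qs.T, columns=["q2.5", "q50", "q97.5"],
        index=pd.RangeIndex(1, chains.n_years + 1, name="year"),
    )
    rhat = {
        f"b[{t + 1}]": _split_rhat(chains.draws["b"][:, :, t])
        for t in range(chains.n_years)
    }
    if np.ptp(chains.draws["sigma_u"]) > 0:
        rhat["sigma_u"] = _split_rhat(chains.draws["sigma_u"])

    pct = pct_ci = None
    if pct_change_years is not None:
        t0, t1 = pct_change_years
        start, end = idx[:, t0 - 1], idx[:, t1 - 1]
        ok = start > 0
        changes = (end[ok] - start[ok]) / start[ok] * 100.0
        pct = float(changes.mean())
        lo, hi = np.quantile(changes, [0.025, 0.975])
        pct_ci = (float(lo), float(hi))

    return PosteriorSummary(
        index_mean=idx.mean(axis=0),
        index_sd=idx.std(axis=0, ddof=1),
        index_quantiles=quantiles,
        rhat=rhat,
        percent_change=pct,
        percent_change_ci=pct_ci,
    )
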