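"""Stochastic-search MCMC for the spike-and-slab DM regression.

One iteration comprises (i) a random-walk Metropolis sweep over the
taxon intercepts alpha_j and (ii) a joint Gibbs scan over all (xi_pj,
beta_pj) pairs in which an included coefficient receives a delete
proposal and an excluded one an add proposal drawn from a two-component
adaptive normal mixture,

    beta' ~ w N(beta_pj, 2.38^2 sigma-hat^2_pj)
            + (1 - w) N(beta_pj, 0.01),    w = 0.95,

the standard componentwise adaptive-Metropolis scaling for univariate
updates (2.38^2 is the optimal random-walk factor in one dimension;
dividing these variances by the total parameter count J*P instead
would shrink add-move steps to ~0.002 and leave the spike-and-slab
chain unable to reach effects of realistic size).  sigma-hat^2_pj is a
recursive (Welford) estimate of the slab-conditional posterior variance
of beta_pj, accumulated over the sweeps in which the coefficient was
included; until two included draws exist, the slab variance r^2 stands
in for it, so the proposal can always traverse the slab.  The fixed
mixture component adds small-step refinement and a deterministic lower
bound on the proposal density near zero.

The scan proposes only add and delete moves; an included coefficient is
revised by a delete-then-add cycle rather than a within-model refresh.

Chains are bit-reproducible: all randomness flows from the numpy
Generator seeded by ``McmcSettings.seed``, and the compiled sweeps are
deterministic given their pre-generated variates.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import _kernels
from ._kernels import VAR_FLOOR
from .model import Hyperparameters, RegressionState, Z_MAX, log_prior
from .tables import CovariateTable, TaxaCountTable, check_paired

__all__ = [
    "McmcSettings",
    "AdaptationState",
    "PosteriorChain",
    "update_alpha",
    "update_beta_xi",
    "run_mcmc",
    "geweke_z",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class McmcSettings:
    """MCMC run configuration.

    Parameters
    ----------
    n_iterations
        Total raw iterations (default 10,000).
    thin
        Keep every ``thin``-th state (default 5).
    burn_in
        Draws (post-thinning) discarded before summaries; ``None`` means
        the first half.
    seed
        Seed for the single numpy Generator driving the chain.
    alpha_step_sd
        Random-walk step t_alpha for the intercept proposals.  The
        default 0.5 targets a 20-50% acceptance rate on standardized
        covariates.
    adapt_scale_constant, adapt_fixed_constant
        Multiplier on sigma-hat^2 for the adapted mixture component
        (default 2.38^2, the univariate optimal scaling) and the
        variance of the fixed exploration component (default 0.01).
    adapt_mix_weight
        Weight on the adapted mixture component (default 0.95).
    refresh_included
        After each add/delete scan, apply a symmetric within-model
        Metropolis refresh to every included coefficient.  Without it an
        included beta_pj can only change value through a delete-then-add
        cycle, which leaves stale compromise values in place and lets
        redundant correlated covariates stay locked into the model.
    random_scan
        Visit (p, j) pairs in a fresh random order each sweep instead of
        the default fixed order (taxon-major, covariate fastest).
    prior_only
        Disable the likelihood term; the chain then targets the prior
        (used for prior-recovery diagnostics).
    fix_alpha
        Skip the intercept sweep entirely.
    """

    n_iterations: int = 10_000
    thin: int = 5
    burn_in: int | None = None
    seed: int = 0
    alpha_step_sd: float = 0.5
    adapt_scale_constant: float = 2.38**2
    adapt_fixed_constant: float = 0.01
    adapt_mix_weight: float = 0.95
    refresh_included: bool = True
    random_scan: bool = False
    prior_only: bool = False
    fix_alpha: bool = False
    progress_every: int = 1000

    def __post_init__(self) -> None:
        if self.n_iterations < 1 or self.thin < 1:
            raise ValueError("n_iterations and thin must be positive")
        if self.n_iterations < self.thin:
            raise ValueError("n_iterations must be at least thin")
        n_draws = self.n_iterations // self.thin
        if self.burn_in is not None and not 0 <= self.burn_in < n_draws:
            raise ValueError("burn_in must be a non-negative number of retained draws")
        if not 0.0 < self.adapt_mix_weight < 1.0:
            raise ValueError("adapt_mix_weight must lie in (0, 1)")
        if self.alpha_step_sd < 0:
            raise ValueError("alpha_step_sd must be non-negative")

    @property
    def n_draws(self) -> int:
        return self.n_iterations // self.thin

    def effective_burn_in(self) -> int:
        return self.n_draws // 2 if self.burn_in is None else self.burn_in


@dataclass
class AdaptationState:
    """Welford accumulators for the per-coefficient proposal variances.

    The recursion runs over the included (non-zero) draws of each
    beta_pj, so sigma-hat^2 estimates the slab-conditional posterior
    variance — the scale an add proposal has to cover.
    """

    running_mean: np.ndarray
    m2: np.ndarray
    draw_count: np.ndarray

    @classmethod
    def initial(cls, P: int, J: int) -> "AdaptationState":
        return cls(
            np.zeros((P, J)), np.zeros((P, J)), np.zeros((P, J), dtype=np.int64)
        )

    @property
    def running_var(self) -> np.ndarray:
        """sigma-hat^2 per coefficient (0 until two draws are recorded)."""
        out = np.zeros_like(self.m2)
        ok = self.draw_count >= 2
        out[ok] = self.m2[ok] / (self.draw_count[ok] - 1)
        return out

    #: pseudo-draws of prior scale blended into the variance estimate
    prior_weight: int = 50

    def effective_variance(self, slab_variance: np.ndarray) -> np.ndarray:
        """Regularized proposal-variance estimate.

        Shrinks the empirical slab-conditional variance toward the slab
        prior variance r^2_j with ``prior_weight`` pseudo-draws:

            sigma-hat^2 = (n0 r^2 + sum of squared deviations)
                          / (n0 + included draws - 1).

        Before any included draws this is exactly r^2, so the proposal
        can always traverse the slab (with the empirical variance alone
        the chain would be reducible in practice); and because a single
        new draw moves the estimate by at most ~1/n0, the adaptation is
        gentle enough not to distort the invariant distribution
        measurably.
        """
        n0 = float(self.prior_weight)
        denom = n0 + np.maximum(self.draw_count - 1, 0)
        out = (n0 * slab_variance[None, :] + self.m2) / denom
        return np.maximum(out, VAR_FLOOR)

    def update(self, beta: np.ndarray, xi: np.ndarray) -> None:
        _kernels.welford_update(
            self.running_mean, self.m2, self.draw_count, beta, xi
        )


@dataclass
class _LikelihoodCache:
    """Sufficient statistics for O(n) single-column likelihood deltas."""

    Z: np.ndarray        # n x J linear predictors
    G: np.ndarray        # n x J concentrations
    rowsum: np.ndarray   # n row sums of G
    colterm: np.ndarray  # J column lgamma sums
    S1: float            # row-total lgamma sum
    Yf: np.ndarray       # counts as float64
    ysum: np.ndarray     # row totals as float64
    const: float         # multinomial-coefficient constant of the loglik

    @classmethod
    def build(
        cls, state: RegressionState, Y: TaxaCountTable, X: CovariateTable
    ) -> "_LikelihoodCache":
        Z = state.alpha[None, :] + X.values @ state.beta
        G = np.exp(np.clip(Z, -Z_MAX, Z_MAX))
        rowsum = G.sum(axis=1)
        Yf = Y.counts.astype(np.float64)
        ysum = Y.row_totals.astype(np.float64)
        colterm = np.where(Yf > 0, gammaln(Yf + G) - gammaln(G), 0.0).sum(axis=0)
        S1 = float(np.sum(gammaln(rowsum) - gammaln(ysum + rowsum)))
        const = float(np.sum(gammaln(ysum + 1.0)) - np.sum(gammaln(Yf + 1.0)))
        return cls(np.ascontiguousarray(Z), np.ascontiguousarray(G), rowsum,
                   colterm, S1, np.ascontiguousarray(Yf), ysum, const)

    def log_likelihood(self) -> float:
        return self.const + self.S1 + float(self.colterm.sum())


def update_alpha(
    state: RegressionState,
    Y: TaxaCountTable,
    X: CovariateTable,
    hyp: Hyperparameters,
    settings: McmcSettings,
    rng: np.random.Generator,
    cache: _LikelihoodCache | None = None,
) -> tuple[RegressionState, int]:
    """One Metropolis sweep over the intercepts; mutates ``state`` in place.

    Returns the state and the number of accepted proposals.
    """
    if cache is None:
        cache = _LikelihoodCache.build(state, Y, X)
    J = state.alpha.shape[0]
    z = rng.standard_normal(J)
    log_u = np.log(rng.random(J))
    s2 = hyp.intercept_variance_vector(J)
    cache.S1, n_acc = _kernels.alpha_sweep(
        state.alpha, cache.Z, cache.G, cache.rowsum, cache.colterm, cache.S1,
        cache.Yf, cache.ysum, s2, z, log_u, settings.alpha_step_sd,
        not settings.prior_only,
    )
    return state, n_acc


def update_beta_xi(
    state: RegressionState,
    adapt: AdaptationState,
    Y: TaxaCountTable,
    X: CovariateTable,
    hyp: Hyperparameters,
    settings: McmcSettings,
    rng: np.random.Generator,
    cache: _LikelihoodCache | None = None,
) -> tuple[RegressionState, AdaptationState, dict[str, int]]:
    """One joint (xi, beta) Gibbs scan; mutates state and adapt in place.

    Returns the state, the adaptation state and a counter dict with the
    add/delete proposal and acceptance totals.
    """
    if cache is None:
        cache = _LikelihoodCache.build(state, Y, X)
    P, J = state.beta.shape
    z = rng.standard_normal((P, J))
    log_u = np.log(rng.random((P, J)))
    mix_u = rng.random((P, J))
    if settings.random_scan:
        order = rng.permutation(P * J).astype(np.int64)
    else:
        # taxon-major scan: for each j, p = 1..P
        order = np.arange(P * J, dtype=np.int64).reshape(P, J).T.reshape(-1)
    scan_p = order // J
    scan_j = order % J
    r2 = hyp.slab_variance_vector(J)
    m = hyp.prior_mean_inclusion
    log_m_ratio = float(np.log(m) - np.log1p(-m))
    v_fixed = settings.adapt_fixed_constant
    v_adapt_eff = settings.adapt_scale_constant * adapt.effective_variance(r2)
    cache.S1, add_acc, add_prop, del_acc, del_prop, n_nonfin = _kernels.beta_xi_sweep(
        state.beta, state.xi, cache.Z, cache.G, cache.rowsum, cache.colterm,
        cache.S1, cache.Yf, cache.ysum, np.ascontiguousarray(X.values), r2,
        log_m_ratio, v_adapt_eff, v_fixed,
        settings.adapt_mix_weight, scan_p, scan_j,
        z, log_u, mix_u, not settings.prior_only,
    )
    if n_nonfin:
        logger.warning("%d proposals had non-finite acceptance ratios (rejected)",
                       n_nonfin)
    ref_acc = ref_prop = 0
    if settings.refresh_included and state.xi.any():
        z_r = rng.standard_normal((P, J))
        log_u_r = np.log(rng.random((P, J)))
        mix_u_r = rng.random((P, J))
        cache.S1, ref_acc, ref_prop = _kernels.refresh_sweep(
            state.beta, state.xi, cache.Z, cache.G, cache.rowsum,
            cache.colterm, cache.S1, cache.Yf, cache.ysum,
            np.ascontiguousarray(X.values), r2, v_adapt_eff, v_fixed,
            settings.adapt_mix_weight, z_r, log_u_r, mix_u_r,
            not settings.prior_only,
        )
    adapt.update(state.beta, state.xi)
    counters = {
        "add_accepted": add_acc, "add_proposed": add_prop,
        "delete_accepted": del_acc, "delete_proposed": del_prop,
        "refresh_accepted": ref_acc, "refresh_proposed": ref_prop,
        "nonfinite": n_nonfin,
    }
    return state, adapt, counters


@dataclass
class PosteriorChain:
    """Thinned posterior draws plus traces and run metadata."""

    alpha_draws: np.ndarray       # T x J
    beta_draws: np.ndarray        # T x P x J
    xi_draws: np.ndarray          # T x P x J, uint8
    log_post_trace: np.ndarray    # T
    model_size_trace: np.ndarray  # T
    settings: McmcSettings
    acceptance_rates: dict[str, float] = field(default_factory=dict)
    runtime_seconds: float = 0.0
    taxon_ids: list[str] | None = None
    covariate_ids: list[str] | None = None

    @property
    def n_draws(self) -> int:
        return self.alpha_draws.shape[0]

    def retained(self, burn_in: int | None = None) -> slice:
        b = self.settings.effective_burn_in() if burn_in is None else burn_in
        if not 0 <= b < self.n_draws:
            raise ValueError(f"burn_in {b} leaves no retained draws of {self.n_draws}")
        return slice(b, self.n_draws)

    def save(self, out_dir: str | Path) -> None:
        """Serialize to plain TSVs plus a JSON manifest.

        ``alpha.tsv`` is wide (draw x taxon).  ``beta.tsv`` and
        ``xi.tsv`` are long-format sparse: only included (non-zero)
        entries are written, one row per (draw, covariate, taxon);
        absent entries are zero.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        T, P, J = self.beta_draws.shape
        taxa = self.taxon_ids or [f"taxon_{j}" for j in range(J)]
        covs = self.covariate_ids or [f"cov_{p}" for p in range(P)]
        pd.DataFrame(self.alpha_draws, columns=taxa).rename_axis("draw").to_csv(
            out / "alpha.tsv", sep="\t"
        )
        t_idx, p_idx, j_idx = np.nonzero(self.xi_draws)
        long = pd.DataFrame(
            {
                "draw": t_idx,
                "covariate": [covs[p] for p in p_idx],
                "taxon": [taxa[j] for j in j_idx],
                "value": self.beta_draws[t_idx, p_idx, j_idx],
            }
        )
        long.to_csv(out / "beta.tsv", sep="\t", index=False)
        long.drop(columns="value").assign(included=1).to_csv(
            out / "xi.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            {
                "log_posterior": self.log_post_trace,
                "model_size": self.model_size_trace,
            }
        ).rename_axis("draw").to_csv(out / "trace.tsv", sep="\t")
        manifest = {
            "settings": asdict(self.settings),
            "acceptance_rates": self.acceptance_rates,
            "runtime_seconds": self.runtime_seconds,
            "n_draws": T,
            "n_covariates": P,
            "n_taxa": J,
            "covariate_ids": covs,
            "taxon_ids": taxa,
        }
        (out / "chain_manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, chain_dir: str | Path) -> "PosteriorChain":
        """Reconstruct a chain saved with :meth:`save`."""
        d = Path(chain_dir)
        manifest = json.loads((d / "chain_manifest.json").read_text())
        T = manifest["n_draws"]
        P = manifest["n_covariates"]
        J = manifest["n_taxa"]
        covs = manifest["covariate_ids"]
        taxa = manifest["taxon_ids"]
        alpha = pd.read_csv(d / "alpha.tsv", sep="\t", index_col=0).to_numpy()
        beta = np.zeros((T, P, J))
        xi = np.zeros((T, P, J), dtype=np.uint8)
        long = pd.read_csv(d / "beta.tsv", sep="\t")
        if len(long):
            p_map = {c: i for i, c in enumerate(covs)}
            j_map = {t: i for i, t in enumerate(taxa)}
            ti = long["draw"].to_numpy()
            pi = long["covariate"].map(p_map).to_numpy()
            ji = long["taxon"].map(j_map).to_numpy()
            beta[ti, pi, ji] = long["value"].to_numpy()
            xi[ti, pi, ji] = 1
        trace = pd.read_csv(d / "trace.tsv", sep="\t", index_col=0)
        return cls(
            alpha, beta, xi,
            trace["log_posterior"].to_numpy(),
            trace["model_size"].to_numpy().astype(np.int64),
            McmcSettings(**manifest["settings"]),
            manifest.get("acceptance_rates", {}),
            manifest.get("runtime_seconds", 0.0),
            taxon_ids=taxa, covariate_ids=covs,
        )


def run_mcmc(
    Y: TaxaCountTable,
    X: CovariateTable,
    hyp: Hyperparameters | None = None,
    settings: McmcSettings | None = None,
) -> PosteriorChain:
    """Run the full Metropolis-within-Gibbs chain.

    Deterministic given ``settings.seed`` and the inputs: the same call
    yields a bit-identical chain.
    """
    hyp = hyp or Hyperparameters()
    settings = settings or McmcSettings()
    check_paired(Y, X)
    zero_rows = np.flatnonzero(Y.row_totals == 0)
    if zero_rows.size:
        raise ValueError(
            f"sample {Y.sample_ids[zero_rows[0]]!r} has an all-zero count row"
        )
    n, J = Y.counts.shape
    P = X.n_covariates
    rng = np.random.default_rng(settings.seed)
    state = RegressionState.initial(Y, P)
    adapt = AdaptationState.initial(P, J)
    cache = _LikelihoodCache.build(state, Y, X)

    T = settings.n_draws
    alpha_draws = np.empty((T, J))
    beta_draws = np.empty((T, P, J))
    xi_draws = np.empty((T, P, J), dtype=np.uint8)
    log_post = np.empty(T)
    model_size = np.empty(T, dtype=np.int64)

    alpha_acc = alpha_prop = 0
    add_acc = add_prop = del_acc = del_prop = 0
    ref_acc = ref_prop = 0
    t0 = time.perf_counter()
    store = 0
    for it in range(1, settings.n_iterations + 1):
        if not settings.fix_alpha:
            _, n_acc = update_alpha(state, Y, X, hyp, settings, rng, cache)
            alpha_acc += n_acc
            alpha_prop += J
        _, _, counters = update_beta_xi(
            state, adapt, Y, X, hyp, settings, rng, cache
        )
        add_acc += counters["add_accepted"]
        add_prop += counters["add_proposed"]
        del_acc += counters["delete_accepted"]
        del_prop += counters["delete_proposed"]
        ref_acc += counters["refresh_accepted"]
        ref_prop += counters["refresh_proposed"]
        if it % settings.thin == 0 and store < T:
            alpha_draws[store] = state.alpha
            beta_draws[store] = state.beta
            xi_draws[store] = state.xi
            ll = 0.0 if settings.prior_only else cache.log_likelihood()
            log_post[store] = ll + log_prior(state, hyp)
            model_size[store] = int(state.xi.sum())
            store += 1
        if settings.progress_every and it % settings.progress_every == 0:
            logger.info(
                "iteration %d/%d: model size %d, alpha acc %.2f, add acc %.3f, "
                "delete acc %.3f",
                it, settings.n_iterations, int(state.xi.sum()),
                alpha_acc / max(alpha_prop, 1), add_acc / max(add_prop, 1),
                del_acc / max(del_prop, 1),
            )
    rates = {
        "alpha": alpha_acc / max(alpha_prop, 1),
        "add": add_acc / max(add_prop, 1),
        "delete": del_acc / max(del_prop, 1),
        "refresh": ref_acc / max(ref_prop, 1),
    }
    return PosteriorChain(
        alpha_draws[:store], beta_draws[:store], xi_draws[:store],
        log_post[:store], model_size[:store], settings, rates,
        time.perf_counter() - t0,
        taxon_ids=Y.taxon_ids, covariate_ids=X.covariate_ids,
    )


def geweke_z(
    trace: np.ndarray, frac_first: float = 0.1, frac_last: float = 0.5
) -> float:
    """Geweke convergence z-score for a single chain trace.

    Compares the mean of the first ``frac_first`` of the trace with the
    mean of the last ``frac_last``; standard errors come from batch means
    with floor(sqrt(segment length)) batches, a simple estimate of the
    spectral density at frequency zero.
    """
    x = np.asarray(trace, dtype=np.float64)
    if x.ndim != 1 or x.size < 20:
        raise ValueError("trace must be 1-D with at least 20 draws")
    n = x.size
    first = x[: max(int(np.floor(frac_first * n)), 2)]
    last = x[n - max(int(np.floor(frac_last * n)), 2):]

    def _batch_se2(seg: np.ndarray) -> float:
        nb = max(int(np.sqrt(seg.size)), 2)
        blen = seg.size // nb
        means = seg[: nb * blen].reshape(nb, blen).mean(axis=1)
        return float(means.var(ddof=1) / nb)

    se2 = _batch_se2(first) + _batch_se2(last)
    if se2 == 0.0:
        logger.warning("constant trace: Geweke z defined as 0")
        return 0.0
    return float((first.mean() - last.mean()) / np.sqrt(se2))
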