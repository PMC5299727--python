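"""Synthetic data generator and replicate harness for the simulation study.

The generator emulates an overdispersed taxa-by-covariate study design:

* covariates: n draws from MVN(0, Sigma) with AR(1) correlation
  Sigma_kl = rho^|k-l| (rho = 0.4 by default);
* sparse truth: P_r relevant covariates and J_r relevant taxa carry
  ``n_assoc`` non-zero log-linear effects drawn uniformly from
  +-[0.5, 1.0]; intercepts alpha_j ~ Uniform(-2.3, 2.3);
* counts: gamma_ij = exp(alpha_j + sum_p beta_pj x_ip) is rescaled to
  gamma*_ij = (gamma_ij / gamma_i+) (1 - psi) / psi, a Dirichlet draw
  pi*_i ~ Dirichlet(gamma*_i) sets the sample's composition, and
  y_i ~ Multinomial(N_i, pi*_i) with sequencing depth
  N_i ~ DiscreteUniform[1000, 2000].

The overdispersion parameter psi in (0, 1) controls the extra-
multinomial variance: as psi -> 0 the Dirichlet concentrates and counts
approach pure Multinomial(gamma/gamma_+) sampling; larger psi spreads
the compositions.  Note sum_j gamma*_ij = (1 - psi)/psi exactly for
every sample.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import cholesky

from . import metrics as _metrics
from .inference import compute_ppi, median_model
from .model import Hyperparameters
from .preprocess import standardize
from .sampler import McmcSettings, run_mcmc
from .tables import CovariateTable, TaxaCountTable

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "gen_covariates",
    "gen_truth",
    "gen_counts",
    "simulate_dataset",
    "run_replicates",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic generator.

    Defaults reproduce the reference simulation design: 100 samples,
    50 covariates, 50 taxa, 25 true associations confined to 9 relevant
    covariates x 5 relevant taxa, AR(1) covariate correlation 0.4,
    overdispersion 0.01 and sequencing depths on [1000, 2000].
    """

    n: int = 100
    P: int = 50
    J: int = 50
    P_r: int = 9
    J_r: int = 5
    n_assoc: int = 25
    rho: float = 0.4
    psi: float = 0.01
    effect_low: float = 0.5
    effect_high: float = 1.0
    intercept_low: float = -2.3
    intercept_high: float = 2.3
    depth_low: int = 1000
    depth_high: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_assoc > self.P_r * self.J_r:
            raise ValueError("n_assoc cannot exceed P_r * J_r")
        if not 0.0 < self.psi < 1.0:
            raise ValueError("overdispersion psi must lie in (0, 1)")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("AR(1) correlation rho must lie in [0, 1)")
        if self.P_r > self.P or self.J_r > self.J:
            raise ValueError("relevant counts exceed totals")
        if not 0 < self.effect_low <= self.effect_high:
            raise ValueError("effect range must be positive and ordered")
        if self.depth_low > self.depth_high or self.depth_low < 1:
            raise ValueError("invalid depth range")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset, for recovery scoring."""

    alpha_true: np.ndarray   # J
    beta_true: np.ndarray    # P x J
    xi_true: np.ndarray      # P x J binary
    gamma_star: np.ndarray | None = None  # n x J
    pi_star: np.ndarray | None = None     # n x J simplex rows
    depths: np.ndarray | None = None      # n

    @property
    def relevant_covariates(self) -> np.ndarray:
        return np.flatnonzero(self.xi_true.any(axis=1))

    @property
    def relevant_taxa(self) -> np.ndarray:
        return np.flatnonzero(self.xi_true.any(axis=0))


def gen_covariates(
    config: SimulationConfig, rng: np.random.Generator
) -> CovariateTable:
    """AR(1)-correlated Gaussian covariates, n x P."""
    k = np.arange(config.P)
    Sigma = config.rho ** np.abs(k[:, None] - k[None, :])
    L = cholesky(Sigma, lower=True)
    values = rng.standard_normal((config.n, config.P)) @ L.T
    return CovariateTable(
        values, [f"cov_{p}" for p in range(config.P)],
        sample_ids=[f"sample_{i}" for i in range(config.n)],
    )


def gen_truth(config: SimulationConfig, rng: np.random.Generator) -> SimulationTruth:
    """Sparse ground-truth coefficients.

    Chooses J_r taxa and P_r covariates uniformly, then distributes the
    ``n_assoc`` associations inside the block by giving each relevant
    taxon an (as equal as possible) share of covariates sampled without
    replacement, resampling the placement until every relevant covariate
    and taxon carries at least one association.  Non-zero effects are
    uniform on +-[effect_low, effect_high] with a fair-coin sign.
    """
    if config.n_assoc < max(config.P_r, config.J_r):
        raise ValueError(
            "n_assoc must be at least max(P_r, J_r) so every relevant "
            "covariate and taxon can carry an association"
        )
    rel_taxa = np.sort(rng.choice(config.J, size=config.J_r, replace=False))
    rel_covs = np.sort(rng.choice(config.P, size=config.P_r, replace=False))
    # per-taxon shares, as equal as possible, each <= P_r
    base = config.n_assoc // config.J_r
    shares = np.full(config.J_r, base)
    shares[: config.n_assoc - base * config.J_r] += 1
    if np.any(shares > config.P_r):
        raise ValueError("association placement infeasible: a taxon's share exceeds P_r")
    for _ in range(10_000):
        xi = np.zeros((config.P, config.J), dtype=np.uint8)
        for t, share in zip(rel_taxa, shares):
            chosen = rng.choice(rel_covs, size=int(share), replace=False)
            xi[chosen, t] = 1
        if np.all(xi[rel_covs].any(axis=1)):
            break
    else:  # pragma: no cover - probability of reaching this is negligible
        raise RuntimeError("could not place associations covering every relevant covariate")
    magnitudes = rng.uniform(config.effect_low, config.effect_high, size=config.n_assoc)
    signs = rng.choice([-1.0, 1.0], size=config.n_assoc)
    beta = np.zeros((config.P, config.J))
    pos = np.argwhere(xi == 1)
    beta[pos[:, 0], pos[:, 1]] = magnitudes * signs
    alpha = rng.uniform(config.intercept_low, config.intercept_high, size=config.J)
    return SimulationTruth(alpha, beta, xi)


def gen_counts(
    X: CovariateTable,
    truth: SimulationTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> TaxaCountTable:
    """Overdispersed DM counts given covariates and truth.

    Fills ``truth.gamma_star``, ``truth.pi_star`` and ``truth.depths``
    with the realized latent quantities.
    """
    if not 0.0 < config.psi < 1.0:
        raise ValueError("overdispersion psi must lie in (0, 1)")
    gamma = np.exp(truth.alpha_true[None, :] + X.values @ truth.beta_true)
    gamma_star = gamma / gamma.sum(axis=1, keepdims=True) * (1.0 - config.psi) / config.psi
    pi_star = np.empty((config.n, config.J))
    for i in range(config.n):
        pi_star[i] = rng.dirichlet(gamma_star[i])
    depths = rng.integers(config.depth_low, config.depth_high + 1, size=config.n)
    counts = np.empty((config.n, config.J), dtype=np.int64)
    for i in range(config.n):
        counts[i] = rng.multinomial(depths[i], pi_star[i])
    truth.gamma_star = gamma_star
    truth.pi_star = pi_star
    truth.depths = depths
    return TaxaCountTable(
        counts,
        [f"sample_{i}" for i in range(config.n)],
        [f"taxon_{j}" for j in range(config.J)],
    )


def simulate_dataset(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[TaxaCountTable, CovariateTable, SimulationTruth]:
    """Generate one complete dataset (counts, covariates, truth)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    X = gen_covariates(config, rng)
    truth = gen_truth(config, rng)
    Y = gen_counts(X, truth, config, rng)
    return Y, X, truth


def _score_replicate(
    ppi: np.ndarray, selected: np.ndarray, truth: SimulationTruth
) -> dict[str, float]:
    out: dict[str, float] = {}
    counts = _metrics.confusion(selected, truth.xi_true)
    out.update(
        overall_acc=_metrics.acc(counts), overall_fpr=_metrics.fpr(counts),
        overall_fnr=_metrics.fnr(counts), overall_mcc=_metrics.mcc(counts),
    )
    _, out["overall_auc"] = _metrics.roc_auc(ppi, truth.xi_true)
    taxa_sel = selected.any(axis=0).astype(np.uint8)
    taxa_truth = truth.xi_true.any(axis=0).astype(np.uint8)
    tcounts = _metrics.confusion(taxa_sel, taxa_truth)
    out.update(
        taxa_acc=_metrics.acc(tcounts), taxa_fpr=_metrics.fpr(tcounts),
        taxa_fnr=_metrics.fnr(tcounts), taxa_mcc=_metrics.mcc(tcounts),
    )
    # taxon-level score: the strongest PPI among a taxon's covariates
    if 0 < taxa_truth.sum() < taxa_truth.size:
        _, out["taxa_auc"] = _metrics.roc_auc(ppi.max(axis=0), taxa_truth)
    else:
        out["taxa_auc"] = float("nan")
    return out


def run_replicates(
    config: SimulationConfig,
    n_reps: int,
    fit_settings: McmcSettings | None = None,
    hyp: Hyperparameters | None = None,
    keep_details: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, list[dict]]:
    """Generate-fit-score loop over independent replicates.

    Each replicate regenerates covariates, truth and counts from a child
    seed of ``config.seed``, standardizes the covariates, fits the model
    by MCMC and scores median-model selection against the truth at both
    the overall (P x J indicators) and taxa-wise (J taxa; a taxon is
    positive if any of its indicators is positive) granularities.

    Returns a tidy per-replicate metrics table with a trailing ``mean``
    row; with ``keep_details=True`` also a list of per-replicate dicts
    holding the chain, PPIs and truth.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    fit_settings = fit_settings or McmcSettings()
    hyp = hyp or Hyperparameters.from_mean_inclusion(0.01)
    rows = []
    details = []
    seeds = np.random.SeedSequence(config.seed).spawn(n_reps)
    for r, ss in enumerate(seeds):
        child = np.random.default_rng(ss)
        rep_cfg = replace(config, seed=int(ss.generate_state(1)[0] % (2**31)))
        Y, X, truth = simulate_dataset(rep_cfg, child)
        Xs = standardize(X)
        settings = replace(fit_settings, seed=rep_cfg.seed)
        chain = run_mcmc(Y, Xs, hyp, settings)
        ppi = compute_ppi(chain)
        selected = median_model(ppi)
        row = {"replicate": r, **_score_replicate(ppi, selected, truth)}
        rows.append(row)
        if keep_details:
            details.append(
                {"chain": chain, "ppi": ppi, "selected": selected,
                 "truth": truth, "Y": Y, "X": Xs, "seed": rep_cfg.seed}
            )
    df = pd.DataFrame(rows)
    mean_row = df.drop(columns="replicate").mean().to_dict()
    df = pd.concat(
        [df, pd.DataFrame([{"replicate": "mean", **mean_row}])], ignore_index=True
    )
    if keep_details:
        return df, details
    return df
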