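"""Posterior inference for reactivity theories.

Sampling runs in an unconstrained logit parameterisation of the unit-interval
latents, using an affine-invariant / differential-evolution ensemble MCMC
sampler (emcee) with the log-posterior vectorised across walkers.  Walkers
are treated as chains for split-R-hat and effective-sample-size diagnostics
(arviz).  A deterministic mid-point grid integrator over the unit hypercube
serves as an independent oracle for small models (<= 6 free parameters).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.special import expit, logit
from scipy.stats import beta as beta_dist

from .space import ChemicalSpace, Experiment, ObservationLog
from .theory import PROB_FLOOR, CompiledTheory, ExperimentBatch, Theory

__all__ = [
    "MCMCConfig",
    "Posterior",
    "ConvergenceWarning",
    "fit_posterior",
    "grid_posterior",
    "posterior_predictive",
]


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class MCMCConfig:
    """Ensemble-MCMC settings.

    ``chains`` x ``draws`` is the total number of retained posterior draws
    (thinned from the ensemble); ``warmup`` is the number of discarded
    adaptation steps.  The seed is mandatory: there is no silent default.
    """

    seed: int
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    target_accept: float = 0.9

    def __post_init__(self) -> None:
        if self.chains < 1 or self.warmup < 1 or self.draws < 1:
            raise ValueError("chains, warmup and draws must all be positive")
        if not (0 < self.target_accept < 1):
            raise ValueError("target acceptance must lie in (0, 1)")
        if self.seed is None:
            raise ValueError("an explicit seed is required")


def _diagnostics(chain_theta: np.ndarray) -> dict:
    """Per-parameter ESS and split-R-hat from a (chain, draw, ndim) array."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(chain_theta)
        ess = az.ess(ds)["x"].values
        rhat = az.rhat(ds)["x"].values if chain_theta.shape[1] >= 2 else np.ones(chain_theta.shape[2])
    return {"ess": ess, "rhat": rhat}


class Posterior:
    """Equal-weight posterior draws over a compiled theory's parameters.

    ``chain`` has shape (chains, draws_per_chain, ndim) in the natural (0, 1)
    parameter scale; ``draws`` is the flattened (n_draws, ndim) view.  Draws
    obtained from the prior (no data) use the same container, so predictive
    code is agnostic to where the draws came from.
    """

    def __init__(
        self,
        structure: CompiledTheory,
        chain: np.ndarray,
        seed: int,
        diagnostics: dict | None = None,
        weights: np.ndarray | None = None,
    ):
        chain = np.asarray(chain, dtype=float)
        if chain.ndim != 3:
            raise ValueError("chain must have shape (chains, draws, ndim)")
        if chain.shape[-1] != structure.ndim:
            raise ValueError(
                f"chain ndim {chain.shape[-1]} does not match theory ndim {structure.ndim}"
            )
        if np.any(chain < 0) or np.any(chain > 1):
            raise ValueError("posterior draws must lie in [0, 1]")
        self.structure = structure
        self.chain = chain
        self.seed = int(seed)
        self.diagnostics = diagnostics or {}
        self.weights = weights  # optional importance weights over flat draws

    # -- basic views --------------------------------------------------------

    @property
    def theory(self) -> Theory:
        return self.structure.theory

    @property
    def n_chains(self) -> int:
        return self.chain.shape[0]

    @property
    def n_draws(self) -> int:
        return self.chain.shape[0] * self.chain.shape[1]

    @property
    def draws(self) -> np.ndarray:
        return self.chain.reshape(-1, self.chain.shape[-1])

    @classmethod
    def from_prior(
        cls, structure: CompiledTheory, n_draws: int, seed: int, chains: int = 4
    ) -> "Posterior":
        """Independent draws from the prior, wrapped as a Posterior."""
        rng = np.random.default_rng(seed)
        per = max(1, n_draws // chains)
        draws = structure.sample_prior(chains * per, rng).reshape(chains, per, structure.ndim)
        ndim = structure.ndim
        diag = {"ess": np.full(ndim, chains * per, dtype=float), "rhat": np.ones(ndim)}
        return cls(structure, draws, seed=seed, diagnostics=diag)

    def reweighted(self, log_weights: np.ndarray) -> "Posterior":
        """Importance-reweighted view of the same draws (weights multiply any
        existing ones).  Degenerate weights (all zero) raise ValueError."""
        lw = np.asarray(log_weights, dtype=float)
        if lw.shape != (self.n_draws,):
            raise ValueError("log_weights must be one value per draw")
        top = np.max(lw)
        if not np.isfinite(top):
            raise ValueError("degenerate importance weights (all zero)")
        w = np.exp(lw - top)
        if self.weights is not None:
            w = w * self.weights
        total = w.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("degenerate importance weights (all zero)")
        return Posterior(
            self.structure, self.chain, self.seed, self.diagnostics, weights=w / total
        )

    def _weights(self) -> np.ndarray:
        if self.weights is None:
            return np.full(self.n_draws, 1.0 / self.n_draws)
        return self.weights / self.weights.sum()

    # -- predictive queries --------------------------------------------------

    def predictive_draws(
        self, experiments: Sequence[Experiment], chunk: int = 256
    ) -> np.ndarray:
        """(n_draws, n_experiments, width) per-draw bit probabilities."""
        batch = self.structure.batch(experiments)
        draws = self.draws
        out = np.empty((draws.shape[0], batch.n, self.structure.width))
        for i in range(0, draws.shape[0], chunk):
            out[i : i + chunk] = self.structure.probabilities(draws[i : i + chunk], batch)
        return out

    def predictive(self, experiments: Sequence[Experiment], chunk: int = 256) -> np.ndarray:
        """(n_experiments, width) posterior-mean bit probabilities."""
        p = self.predictive_draws(experiments, chunk=chunk)
        return np.einsum("s...,s->...", p, self._weights())

    def predictive_outcome_probability(
        self,
        experiments: Sequence[Experiment],
        outcomes: np.ndarray,
        chunk: int = 256,
        per_draw: bool = False,
    ) -> np.ndarray:
        """Predictive probability of observing the given outcome vectors.

        The probability of an outcome vector under one draw is the product of
        its per-bit Bernoulli probabilities; draws are then averaged (the
        Monte-Carlo posterior predictive).
        """
        batch = self.structure.batch(experiments)
        y = np.asarray(outcomes, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        draws = self.draws
        ll = np.empty((draws.shape[0], batch.n))
        for i in range(0, draws.shape[0], chunk):
            ll[i : i + chunk] = self.structure.per_observation_log_likelihood(
                draws[i : i + chunk], batch, y
            )
        probs = np.exp(ll)
        if per_draw:
            return probs
        return self._weights() @ probs

    def mc_standard_error(self, values: np.ndarray) -> float:
        """Monte-Carlo standard error of the mean of a per-draw scalar,
        accounting for autocorrelation via the effective sample size."""
        import arviz as az

        values = np.asarray(values, dtype=float).reshape(self.chain.shape[:2])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess = float(az.ess(values))
        ess = max(ess, 1.0)
        return float(np.std(values) / np.sqrt(ess))

    # -- persistence ---------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Columnar draws plus a JSON diagnostics manifest."""
        import pandas as pd

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        frame = pd.DataFrame(self.draws, columns=[f"p{i}" for i in range(self.structure.ndim)])
        frame.insert(0, "chain", np.repeat(np.arange(self.n_chains), self.chain.shape[1]))
        frame.to_parquet(directory / "draws.parquet")
        manifest = {
            "seed": self.seed,
            "chains": int(self.n_chains),
            "draws_per_chain": int(self.chain.shape[1]),
            "ndim": int(self.structure.ndim),
            "theory": self.structure.theory.to_dict(),
            "diagnostics": {
                k: np.asarray(v).tolist() for k, v in self.diagnostics.items()
            },
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _n_walkers(ndim: int, chains: int) -> int:
    n = max(2 * ndim + 2, 4 * chains, 32)
    return n + (n % 2)


def fit_posterior(
    theory: Theory,
    log: ObservationLog,
    config: MCMCConfig,
    space: ChemicalSpace | None = None,
) -> Posterior:
    """Sample the posterior over theory parameters given an observation log.

    Deterministic given (theory, log, config.seed).  Raises on an empty log;
    emits :class:`ConvergenceWarning` (never an error) when split-R-hat
    exceeds 1.05 or ensemble acceptance collapses.
    """
    import emcee

    if len(log) == 0:
        raise ValueError("cannot fit a posterior to an empty observation log")
    compiled = CompiledTheory(theory, space or log.space)
    batch, y = compiled.batch_for_log(log)

    ndim = compiled.ndim
    nwalkers = _n_walkers(ndim, config.chains)
    rng = np.random.RandomState(config.seed % (2**32))
    theta0 = np.clip(
        rng.beta(compiled._a, compiled._b, size=(nwalkers, ndim)),
        PROB_FLOOR,
        1 - PROB_FLOOR,
    )
    z0 = logit(theta0)

    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.StretchMove(), 0.2)]
    sampler = emcee.EnsembleSampler(
        nwalkers,
        ndim,
        lambda z: compiled.log_posterior_z(z, batch, y),
        vectorize=True,
        moves=moves,
    )
    sampler.random_state = rng.get_state()
    state = sampler.run_mcmc(z0, config.warmup, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, config.draws, progress=False)

    chain_z = sampler.get_chain()  # (steps, walkers, ndim)
    target_total = config.chains * config.draws
    kept_steps = int(np.clip(int(np.ceil(target_total / nwalkers)), 2, config.draws))
    idx = np.unique(np.linspace(0, config.draws - 1, kept_steps).round().astype(int))
    chain_theta = expit(chain_z[idx]).transpose(1, 0, 2)  # (walkers, kept, ndim)

    diagnostics = _diagnostics(chain_theta)
    diagnostics["acceptance_fraction"] = float(np.mean(sampler.acceptance_fraction))
    max_rhat = float(np.nanmax(diagnostics["rhat"]))
    if max_rhat > 1.05:
        warnings.warn(
            f"split-R-hat up to {max_rhat:.3f} (> 1.05); "
            "treat posterior summaries with caution",
            ConvergenceWarning,
            stacklevel=2,
        )
    if diagnostics["acceptance_fraction"] < 0.02:
        warnings.warn(
            f"ensemble acceptance fraction {diagnostics['acceptance_fraction']:.3f} is very low",
            ConvergenceWarning,
            stacklevel=2,
        )
    return Posterior(compiled, chain_theta, seed=config.seed, diagnostics=diagnostics)


def grid_posterior(
    theory: Theory,
    log: ObservationLog,
    resolution: int = 101,
    space: ChemicalSpace | None = None,
    max_grid: int = 10_000_000,
) -> dict:
    """Deterministic numerical-integration oracle for tiny theories.

    Mid-point quadrature of prior x likelihood over the unit hypercube,
    carried out in prior-CDF coordinates: each axis is mapped through its
    Beta quantile function, so the prior weight is exactly uniform and the
    integrable endpoint singularities of Beta(a < 1) priors cost no
    accuracy.  Returns the posterior mean of every parameter and the
    marginal likelihood.  Only feasible for <= 6 free parameters.
    """
    compiled = CompiledTheory(theory, space or log.space)
    ndim = compiled.ndim
    if ndim > 6:
        raise ValueError(f"grid oracle supports <= 6 parameters, theory has {ndim}")
    if resolution**ndim > max_grid:
        raise ValueError(f"grid of {resolution}**{ndim} points exceeds capacity {max_grid}")
    batch, y = compiled.batch_for_log(log)

    u = (np.arange(resolution) + 0.5) / resolution
    axes = [beta_dist.ppf(u, compiled._a[i], compiled._b[i]) for i in range(ndim)]
    mesh = np.meshgrid(*axes, indexing="ij")
    theta = np.stack([m.ravel() for m in mesh], axis=-1)  # (G, ndim)

    loglik = np.empty(theta.shape[0])
    chunk = 200_000
    for i in range(0, theta.shape[0], chunk):
        loglik[i : i + chunk] = compiled.log_likelihood(theta[i : i + chunk], batch, y)
    scale = np.max(loglik)
    lik = np.exp(loglik - scale)
    z_scaled = float(np.mean(lik))
    means = (theta * lik[:, None]).mean(axis=0) / z_scaled
    marginal = float(z_scaled * np.exp(scale))
    return {
        "means": means,
        "marginal_likelihood": marginal,
        "ndim": ndim,
        "resolution": resolution,
    }


def posterior_predictive(
    posterior: Posterior,
    experiments: Experiment | Sequence[Experiment],
    chunk: int = 256,
) -> np.ndarray:
    """Monte-Carlo posterior-predictive bit probabilities.

    A single experiment yields a length-``width`` vector; a sequence yields an
    (n, width) matrix.
    """
    single = isinstance(experiments, Experiment)
    exps = [experiments] if single else list(experiments)
    p = posterior.predictive(exps, chunk=chunk)
    return p[0] if single else p
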