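"""Scikit-learn style estimator wrapping theory + inference.

`BayesianReactivityModel` is the fit/predict face of the package: `fit`
samples the posterior over latent memberships, reactivity tensors and
emission weights; `predict_proba` returns posterior-mean bit probabilities
for new reagent combinations.  It accepts either the package's native
:class:`~reactoracle.space.ObservationLog` or plain (X, y) arrays, where a
row of X is a 0/1/2 compound-incidence vector (a lone entry of 2 denotes a
self-pair) and y holds outcome bits, which lets the estimator compose with
sklearn model-selection utilities.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .inference import MCMCConfig, Posterior, fit_posterior
from .space import ChemicalSpace, Experiment, Observation, ObservationLog, ReactivityVector
from .theory import CompiledTheory, Theory

__all__ = ["BayesianReactivityModel"]


def _experiments_from_incidence(x: np.ndarray, space: ChemicalSpace) -> list[Experiment]:
    ids = space.ids
    x = np.asarray(x)
    if x.ndim != 2 or x.shape[1] != len(ids):
        raise ValueError(
            f"X must be (n_experiments, {len(ids)}) compound-incidence counts, got {x.shape}"
        )
    experiments = []
    for row in x:
        if np.any((row != 0) & (row != 1) & (row != 2)):
            raise ValueError("incidence entries must be 0, 1 or 2")
        twos = np.flatnonzero(row == 2)
        ones = np.flatnonzero(row == 1)
        if twos.size == 1 and ones.size == 0:
            experiments.append(Experiment((ids[twos[0]],), self_pair=True))
        elif twos.size == 0:
            experiments.append(Experiment(tuple(ids[i] for i in ones)))
        else:
            raise ValueError(f"invalid incidence row: {row}")
    return experiments


class BayesianReactivityModel(BaseEstimator):
    """Bayesian latent-property reactivity model.

    Parameters
    ----------
    theory : Theory
        Generative theory specification (entity basis, property count,
        arities, outcome width, priors, noise).
    space : ChemicalSpace, optional
        Needed when fitting from arrays; an ObservationLog carries its own.
    chains, warmup, draws : int
        MCMC budget; ``chains * draws`` posterior draws are retained.
    seed : int
        Random seed (mandatory at fit time).

    Attributes
    ----------
    posterior_ : Posterior
        Retained draws with ESS / split-R-hat diagnostics.
    structure_ : CompiledTheory
        Theory bound to the space (parameter layout, likelihood kernels).
    n_observations_ : int
    """

    def __init__(
        self,
        theory: Theory | None = None,
        space: ChemicalSpace | None = None,
        chains: int = 4,
        warmup: int = 1000,
        draws: int = 1000,
        seed: int | None = None,
    ):
        self.theory = theory
        self.space = space
        self.chains = chains
        self.warmup = warmup
        self.draws = draws
        self.seed = seed

    # -- data marshalling ----------------------------------------------------

    def _as_log(self, x, y=None) -> ObservationLog:
        if isinstance(x, ObservationLog):
            if y is not None:
                raise ValueError("y must be None when X is an ObservationLog")
            return x
        if self.space is None:
            raise ValueError("space is required when fitting from arrays")
        experiments = _experiments_from_incidence(np.asarray(x), self.space)
        y = np.asarray(y)
        if y.ndim == 1:
            y = y[:, None]
        if y.shape[0] != len(experiments):
            raise ValueError("X and y disagree on the number of experiments")
        observations = [
            Observation(e, ReactivityVector(tuple(int(b) for b in row)), t)
            for t, (e, row) in enumerate(zip(experiments, y))
        ]
        return ObservationLog(self.space, observations)

    def _as_experiments(self, x) -> list[Experiment]:
        if isinstance(x, ObservationLog):
            return list(x.experiments)
        if len(x) and isinstance(next(iter(x)), Experiment):
            return list(x)
        space = self.space if self.space is not None else self._fit_space_
        return _experiments_from_incidence(np.asarray(x), space)

    # -- estimator API -------------------------------------------------------

    def fit(self, X, y=None) -> "BayesianReactivityModel":
        """Sample the posterior given observations.

        X is an ObservationLog (y omitted) or a compound-incidence matrix with
        y the (n, width) outcome bits.
        """
        if self.theory is None:
            raise ValueError("a Theory must be supplied")
        if self.seed is None:
            raise ValueError("an explicit seed is required")
        log = self._as_log(X, y)
        config = MCMCConfig(
            seed=self.seed, chains=self.chains, warmup=self.warmup, draws=self.draws
        )
        self._fit_space_ = log.space
        self.posterior_ = fit_posterior(self.theory, log, config)
        self.structure_ = self.posterior_.structure
        self.n_observations_ = len(log)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """(n_experiments, width) posterior-mean probabilities of each bit."""
        self._check_fitted()
        return self.posterior_.predictive(self._as_experiments(X))

    def predict(self, X) -> np.ndarray:
        """Most-probable bit values (probability >= 1/2)."""
        return (self.predict_proba(X) >= 0.5).astype(int)

    def score(self, X, y=None) -> float:
        """Mean per-observation predictive log-likelihood."""
        self._check_fitted()
        log = self._as_log(X, y)
        probs = self.posterior_.predictive_outcome_probability(
            list(log.experiments), log.outcome_matrix()
        )
        return float(np.mean(np.log(np.clip(probs, 1e-300, None))))

    def _check_fitted(self) -> None:
        if not hasattr(self, "posterior_"):
            raise AttributeError("model is not fitted; call fit first")
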