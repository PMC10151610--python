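"""Theory registry and quantitative comparison of rival theories.

Deposited theories get content-addressed identifiers (a cryptographic hash
of the canonical definition), so an identical definition always maps to the
same identifier and refinements can record their parent.  Rival theories are
compared on shared data by embedding them as components of a per-observation
mixture: the likelihood of each observation is ``w * p_a + (1 - w) * p_b``
with a uniform prior on the mixture weight, and the posterior of ``w`` reads
out the relative support — mass near 1 favours the first theory.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

from .inference import MCMCConfig, Posterior, _diagnostics, _n_walkers, ConvergenceWarning
from .oracle import ANOMALY_THRESHOLD, SurpriseTrace, anomaly_shortlist, surprise_trace
from .space import ChemicalSpace, ObservationLog, Observation, ReactivityVector
from .theory import PROB_FLOOR, CompiledTheory, Theory

__all__ = [
    "TheoryRecord",
    "TheoryRegistry",
    "MixtureComparison",
    "register_theory",
    "compare_theories",
    "reinterpret",
    "thermometer_recode",
]


def theory_identifier(theory: Theory) -> str:
    """Content-addressed identifier: SHA-256 of the canonical definition."""
    canonical = json.dumps(theory.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class TheoryRecord:
    theory: Theory
    identifier: str
    parent: str | None = None
    created: str = ""

    def to_dict(self) -> dict:
        return {
            "identifier": self.identifier,
            "parent": self.parent,
            "created": self.created,
            "theory": self.theory.to_dict(),
        }


class TheoryRegistry:
    """Registry of deposited theories with refinement lineage.

    Registration is idempotent: re-registering an identical definition
    returns the existing record.  Parent links must reference registered
    identifiers and are acyclic by construction (a record's parent must
    already exist).  Optionally persisted as a directory of JSON records.
    """

    def __init__(self, directory: str | Path | None = None):
        self._records: dict[str, TheoryRecord] = {}
        self.directory = Path(directory) if directory is not None else None
        if self.directory is not None and self.directory.exists():
            for path in sorted(self.directory.glob("*.json")):
                d = json.loads(path.read_text())
                record = TheoryRecord(
                    theory=Theory.from_dict(d["theory"]),
                    identifier=d["identifier"],
                    parent=d.get("parent"),
                    created=d.get("created", ""),
                )
                self._records[record.identifier] = record

    def register(self, theory: Theory, parent: str | None = None) -> TheoryRecord:
        identifier = theory_identifier(theory)
        if identifier in self._records:
            return self._records[identifier]
        if parent is not None and parent not in self._records:
            raise KeyError(f"parent theory {parent!r} is not registered")
        record = TheoryRecord(
            theory=theory,
            identifier=identifier,
            parent=parent,
            created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )
        self._records[identifier] = record
        if self.directory is not None:
            self.directory.mkdir(parents=True, exist_ok=True)
            (self.directory / f"{identifier}.json").write_text(
                json.dumps(record.to_dict(), indent=2)
            )
        return record

    def get(self, identifier: str) -> TheoryRecord:
        return self._records[identifier]

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, identifier: str) -> bool:
        return identifier in self._records

    def records(self) -> list[TheoryRecord]:
        return sorted(self._records.values(), key=lambda r: r.identifier)


def register_theory(
    theory: Theory, parent: str | None = None, registry: TheoryRegistry | None = None
) -> TheoryRecord:
    registry = registry if registry is not None else TheoryRegistry()
    return registry.register(theory, parent=parent)


@dataclass(frozen=True)
class MixtureComparison:
    """Posterior over the mixture weight ``w`` of theory A versus theory B."""

    labels: tuple[str, str]
    w_chain: np.ndarray  # (chains, draws)
    diagnostics: dict

    @property
    def w_draws(self) -> np.ndarray:
        return self.w_chain.reshape(-1)

    @property
    def mean(self) -> float:
        return float(np.mean(self.w_draws))

    @property
    def interval90(self) -> tuple[float, float]:
        lo, hi = np.quantile(self.w_draws, [0.05, 0.95])
        return float(lo), float(hi)

    def standard_error(self) -> float:
        import arviz as az

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess = max(float(az.ess(self.w_chain)), 1.0)
        return float(np.std(self.w_draws) / np.sqrt(ess))

    def summary(self) -> dict:
        lo, hi = self.interval90
        return {
            "labels": list(self.labels),
            "weight_mean": self.mean,
            "weight_interval90": [lo, hi],
            "weight_se": self.standard_error(),
        }


def compare_theories(
    a: Theory,
    b: Theory,
    log: ObservationLog,
    config: MCMCConfig,
    space: ChemicalSpace | None = None,
) -> MixtureComparison:
    """Mixture-based comparison of two theories on one observation log.

    The model places ``w ~ Beta(1, 1)`` on the mixture weight; each
    observation's likelihood is the per-observation mixture
    ``w * p_a + (1 - w) * p_b``.  The weight is marginalised out of the MCMC
    by Gauss-Legendre quadrature — sampling only the theories' latents avoids
    the sticky feedback where a corner value of ``w`` decouples the losing
    theory from the data — and its posterior is reconstructed by drawing one
    ``w`` from the per-draw conditional.  With an empty log the weight
    posterior is its uniform prior; swapping the theories mirrors the weight
    within Monte-Carlo error.
    """
    import emcee

    space = space if space is not None else log.space
    ca = CompiledTheory(a, space)
    cb = CompiledTheory(b, space)
    for name, compiled in (("a", ca), ("b", cb)):
        if len(log) and log.width != compiled.width:
            raise ValueError(
                f"theory {name} has width {compiled.width}, log has width {log.width}"
            )
    batch_a, y = ca.batch_for_log(log)
    batch_b, _ = cb.batch_for_log(log)
    na, nb = ca.ndim, cb.ndim
    ndim = na + nb

    # Gauss-Legendre nodes on (0, 1) for the uniform weight prior; the
    # integrand is a degree-n polynomial in w, so G nodes are exact up to
    # 2G - 1 observations and near-exact beyond
    n_nodes = int(np.clip((len(log) + 1) // 2 + 4, 16, 64))
    nodes, gl_weights = np.polynomial.legendre.leggauss(n_nodes)
    w_nodes = 0.5 * (nodes + 1.0)
    log_gl = np.log(0.5 * gl_weights)

    def mixture_terms(theta_a: np.ndarray, theta_b: np.ndarray) -> np.ndarray:
        """(..., n_nodes) log-likelihood of the log at each weight node."""
        lla = ca.per_observation_log_likelihood(theta_a, batch_a, y)
        llb = cb.per_observation_log_likelihood(theta_b, batch_b, y)
        mix = np.logaddexp(
            np.log(w_nodes) + lla[..., None], np.log1p(-w_nodes) + llb[..., None]
        )
        return mix.sum(axis=-2)

    def log_prob(z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(z)
        theta_a, theta_b = expit(z[:, :na]), expit(z[:, na:])

        def prior_part(compiled, theta):
            t = np.clip(theta, PROB_FLOOR, 1 - PROB_FLOOR)
            return np.sum(
                compiled._a * np.log(t) + compiled._b * np.log1p(-t), axis=-1
            )

        lp = prior_part(ca, theta_a) + prior_part(cb, theta_b)
        if len(log):
            from scipy.special import logsumexp

            lp += logsumexp(log_gl + mixture_terms(theta_a, theta_b), axis=-1)
        runaway = np.any(np.abs(z) > 200, axis=-1)
        return np.where(runaway, -np.inf, lp)

    # the joint surface has a slow label-swap mode (theta_a and theta_b
    # exchanging explanatory roles), so we run `chains` fully independent
    # ensembles and let between-replicate variance feed the standard error
    nwalkers = _n_walkers(ndim, 1)
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.StretchMove(), 0.2)]
    target_per_rep = max(2, int(np.ceil(config.draws / nwalkers)))
    replicate_w = []
    acceptance = []
    for rep in range(config.chains):
        rng = np.random.RandomState((config.seed + 9973 * rep) % (2**32))
        theta0 = np.concatenate(
            [
                np.clip(rng.beta(ca._a, ca._b, size=(nwalkers, na)), PROB_FLOOR, 1 - PROB_FLOOR),
                np.clip(rng.beta(cb._a, cb._b, size=(nwalkers, nb)), PROB_FLOOR, 1 - PROB_FLOOR),
            ],
            axis=1,
        )
        sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob, vectorize=True, moves=moves)
        sampler.random_state = rng.get_state()
        state = sampler.run_mcmc(logit(theta0), config.warmup, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, config.draws, progress=False)
        acceptance.append(float(np.mean(sampler.acceptance_fraction)))

        chain_z = sampler.get_chain()
        kept_steps = min(config.draws, target_per_rep)
        idx = np.unique(np.linspace(0, config.draws - 1, kept_steps).round().astype(int))
        kept_theta = expit(chain_z[idx])  # (kept, walkers, ndim)

        # one conditional draw of w per kept theta draw
        flat = kept_theta.reshape(-1, ndim)
        if len(log):
            cond = log_gl + mixture_terms(flat[:, :na], flat[:, na:])
            cond -= cond.max(axis=-1, keepdims=True)
            q = np.exp(cond)
            q /= q.sum(axis=-1, keepdims=True)
            cum = np.cumsum(q, axis=-1)
            u = rng.random(flat.shape[0])
            picks = (u[:, None] > cum).sum(axis=-1)
            w_flat = w_nodes[picks]
        else:
            w_flat = rng.random(flat.shape[0])
        replicate_w.append(w_flat)

    w_chain = np.stack(replicate_w)  # (replicates, draws)
    diagnostics = _diagnostics(w_chain[..., None])
    diagnostics["acceptance_fraction"] = float(np.mean(acceptance))
    max_rhat = float(np.nanmax(diagnostics["rhat"]))
    if max_rhat > 1.05:
        warnings.warn(
            f"mixture comparison split-R-hat up to {max_rhat:.3f}",
            ConvergenceWarning,
            stacklevel=2,
        )
    return MixtureComparison(
        labels=(theory_identifier(a), theory_identifier(b)),
        w_chain=w_chain,
        diagnostics=diagnostics,
    )


def thermometer_recode(log: ObservationLog) -> ObservationLog:
    """Re-encode each outcome as a thermometer-coded unique-event count.

    An outcome with ``c`` set bits out of width ``B`` becomes the vector with
    the first ``c`` bits set: the event definition "how many distinct new
    peaks appeared" rather than "where they appeared", kept in Bernoulli-bit
    form so the same likelihood machinery applies.
    """
    observations = []
    width = log.width
    for o in log:
        c = sum(o.outcome.bits)
        bits = tuple(1 if i < c else 0 for i in range(width))
        observations.append(Observation(o.experiment, ReactivityVector(bits), o.order))
    return ObservationLog(log.space, observations)


def reinterpret(
    log: ObservationLog,
    records: Sequence[TheoryRecord],
    config: MCMCConfig,
    anomaly_threshold: float = ANOMALY_THRESHOLD,
    online: bool = False,
    outcome_codings: Mapping[str, Callable[[ObservationLog], ObservationLog]] | None = None,
) -> dict[str, dict]:
    """Interpret the same observations under several deposited theories.

    Returns, per theory identifier, the surprise trace and anomaly shortlist
    (or an ``error`` entry if that theory cannot consume the log — the other
    theories still run).  ``outcome_codings`` optionally maps identifiers to
    log transforms, e.g. :func:`thermometer_recode` for a theory whose event
    definition is the number of unique product peaks.
    """
    report: dict[str, dict] = {}
    for record in records:
        try:
            used = log
            if outcome_codings and record.identifier in outcome_codings:
                used = outcome_codings[record.identifier](log)
            trace = surprise_trace(record.theory, used, config, online=online)
            anomalies = anomaly_shortlist(trace, threshold=anomaly_threshold)
            report[record.identifier] = {
                "trace": trace,
                "anomalies": anomalies,
                "theory_id": record.theory.id,
            }
        except Exception as exc:  # pragma: no cover - defensive per-theory isolation
            report[record.identifier] = {"error": str(exc), "theory_id": record.theory.id}
    return report
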