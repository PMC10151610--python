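"""Generative probabilistic theories of reactivity.

The model postulates that every entity (a compound, or a fingerprint bit in
the structural variant) possesses each of ``K`` abstract properties to a
degree in [0, 1] (a membership matrix ``M``), and that combinations of
properties carry a latent mutual reactivity in [0, 1] (a symmetric reactivity
tensor ``R`` per reaction arity).  For compounds a and b the component matrix

    P[I, J] = M[a, I] * M[b, J] * R[I, J]

gives the probability that a and b react *because* a belongs to property set
I and b to property set J.  A reaction fires if any property combination
fires, so component probabilities aggregate by noisy-OR:

    p(react) = 1 - prod_{I,J} (1 - P[I, J])

extended to 3- and 4-component reactions with order-3/4 symmetric tensors.
Multibit outcomes attach an emission matrix linking each reactivity mode
(unordered property multiset) to observable bits (chromatogram regions); a
small false-positive / false-negative noise floor connects the latent signal
to recorded bits.

Everything here is vectorised over arbitrary leading batch dimensions of the
parameter arrays, which is what makes ensemble MCMC over hundreds of walkers
affordable in pure numpy.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import betaln, expit

from .space import ChemicalSpace, Experiment, ObservationLog, compute_fingerprints, FingerprintScheme

__all__ = [
    "NoiseModel",
    "Theory",
    "CompiledTheory",
    "ExperimentBatch",
    "PRIOR_CONFIGS",
    "PROB_FLOOR",
    "property_modes",
    "symmetric_tensor",
    "component_matrix",
    "reaction_probability",
    "compound_membership_from_bits",
    "bit_probability",
    "log_likelihood",
]

#: Probabilities are clamped to [PROB_FLOOR, 1 - PROB_FLOOR] before logs.
PROB_FLOOR = 1e-9
_ONE_MINUS = 1.0 - 1e-12

#: Named prior configurations: Beta(a, b) per parameter block.  The
#: "conservative-v1" config is deliberately sparse (mean 1/6): few properties,
#: little reactivity, unless the data demand otherwise (Occam's razor).
PRIOR_CONFIGS: dict[str, dict[str, tuple[float, float]]] = {
    "conservative-v1": {
        "membership": (0.5, 2.5),
        "reactivity": (0.5, 2.5),
        "emission": (0.5, 2.5),
    },
    "uniform": {
        "membership": (1.0, 1.0),
        "reactivity": (1.0, 1.0),
        "emission": (1.0, 1.0),
    },
}


class ShapeError(ValueError):
    """Parameter array shapes inconsistent with the theory definition."""


@dataclass(frozen=True)
class NoiseModel:
    """Observation noise: false-positive and false-negative bit rates.

    An observed bit is on with probability ``eps_fp + (1-eps_fp-eps_fn) * s``
    where ``s`` is the latent signal probability.  Both rates must stay below
    0.5 so that detection is better than chance.
    """

    eps_fp: float = 0.01
    eps_fn: float = 0.01

    def __post_init__(self) -> None:
        if not (0 <= self.eps_fp < 0.5 and 0 <= self.eps_fn < 0.5):
            raise ValueError("noise rates must lie in [0, 0.5)")

    def apply(self, signal: np.ndarray) -> np.ndarray:
        return self.eps_fp + (1.0 - self.eps_fp - self.eps_fn) * signal


@dataclass(frozen=True)
class Theory:
    """Specification of one generative reactivity theory.

    Parameters
    ----------
    id : str
        Mnemonic token; the registry derives a content-addressed identifier
        from the full definition, so ``id`` is for humans.
    basis : {"compound", "fingerprint_bit"}
        Whether latent memberships attach to whole compounds (structure-free
        theory) or to individual fingerprint bits (structural theory).
    k : int
        Number of abstract properties (fixed truncation; sparsity comes from
        the prior, not from inferring ``k``).
    arities : tuple of int
        Reaction arities the theory models, subset of {2, 3, 4}.
    width : int
        Reactivity-vector width ``B``.  Width 1 is the binary theory, which
        bypasses the emission map (the event *is* reactivity).
    priors : str
        Name of a prior configuration in :data:`PRIOR_CONFIGS`.
    prior_overrides : mapping
        Per-block (a, b) overrides, e.g. ``{"reactivity": (0.5, 50.0)}`` for a
        null theory that expects almost nothing to react.
    noise : NoiseModel
        Fixed observation noise rates (not sampled).
    fingerprint : FingerprintScheme, optional
        Required when ``basis == "fingerprint_bit"``.
    """

    id: str
    basis: str = "compound"
    k: int = 8
    arities: tuple[int, ...] = (2,)
    width: int = 1
    priors: str = "conservative-v1"
    prior_overrides: tuple[tuple[str, tuple[float, float]], ...] = ()
    noise: NoiseModel = field(default_factory=NoiseModel)
    fingerprint: FingerprintScheme | None = None

    def __post_init__(self) -> None:
        if self.basis not in ("compound", "fingerprint_bit"):
            raise ValueError(f"unknown entity basis: {self.basis}")
        if self.k < 1:
            raise ValueError("property count k must be >= 1")
        if self.width < 1:
            raise ValueError("reactivity-vector width must be >= 1")
        object.__setattr__(self, "arities", tuple(sorted(set(self.arities))))
        if not self.arities or set(self.arities) - {2, 3, 4}:
            raise ValueError(f"arities must be a non-empty subset of {{2,3,4}}: {self.arities}")
        if self.priors not in PRIOR_CONFIGS:
            raise ValueError(f"unknown prior configuration: {self.priors}")
        if self.basis == "fingerprint_bit" and self.fingerprint is None:
            raise ValueError("fingerprint-basis theory needs a fingerprint scheme")
        if isinstance(self.prior_overrides, Mapping):
            object.__setattr__(
                self,
                "prior_overrides",
                tuple(sorted((k, (float(v[0]), float(v[1]))) for k, v in self.prior_overrides.items())),
            )

    def prior_ab(self, block: str) -> tuple[float, float]:
        overrides = dict(self.prior_overrides)
        if block in overrides:
            return overrides[block]
        return PRIOR_CONFIGS[self.priors][block]

    def to_dict(self) -> dict:
        """Canonical JSON-able definition (used for content addressing)."""
        return {
            "id": self.id,
            "basis": self.basis,
            "k": self.k,
            "arities": list(self.arities),
            "width": self.width,
            "priors": self.priors,
            "prior_overrides": {k: list(v) for k, v in self.prior_overrides},
            "noise": {"eps_fp": self.noise.eps_fp, "eps_fn": self.noise.eps_fn},
            "fingerprint": self.fingerprint.to_dict() if self.fingerprint else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Theory":
        fp = d.get("fingerprint")
        return cls(
            id=d["id"],
            basis=d.get("basis", "compound"),
            k=int(d.get("k", 8)),
            arities=tuple(d.get("arities", [2])),
            width=int(d.get("width", 1)),
            priors=d.get("priors", "conservative-v1"),
            prior_overrides=tuple(
                (k, (float(v[0]), float(v[1]))) for k, v in d.get("prior_overrides", {}).items()
            ),
            noise=NoiseModel(**d.get("noise", {})),
            fingerprint=FingerprintScheme(**fp) if fp else None,
        )

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "Theory":
        from pathlib import Path

        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# symmetric-tensor index machinery


@lru_cache(maxsize=None)
def _mode_tables(k: int, arity: int) -> tuple[np.ndarray, np.ndarray]:
    """(modes, inverse): canonical property multisets of size ``arity`` over
    ``k`` properties (lexicographic), and the map from each ordered index
    tuple (flattened C-order) to its mode id."""
    idx = np.indices((k,) * arity).reshape(arity, -1).T
    modes, inverse = np.unique(np.sort(idx, axis=1), axis=0, return_inverse=True)
    return modes, inverse.ravel()


def property_modes(k: int, arity: int) -> np.ndarray:
    """Canonical unordered property-index combinations (multisets)."""
    return _mode_tables(k, arity)[0].copy()


def n_modes(k: int, arity: int) -> int:
    return _mode_tables(k, arity)[0].shape[0]


def symmetric_tensor(unique_values: np.ndarray, k: int, arity: int) -> np.ndarray:
    """Expand unique mode entries into the full symmetric order-``arity`` tensor."""
    unique_values = np.asarray(unique_values, dtype=float)
    modes, inverse = _mode_tables(k, arity)
    if unique_values.shape[-1] != modes.shape[0]:
        raise ShapeError(
            f"expected {modes.shape[0]} unique entries for k={k}, arity={arity}, "
            f"got {unique_values.shape[-1]}"
        )
    full = unique_values[..., inverse]
    return full.reshape(unique_values.shape[:-1] + (k,) * arity)


def unique_entries(full: np.ndarray, arity: int) -> np.ndarray:
    """Extract canonical unique mode entries from a full symmetric tensor."""
    full = np.asarray(full, dtype=float)
    k = full.shape[-1]
    modes, _ = _mode_tables(k, arity)
    flat = full.reshape(full.shape[:-arity] + (k**arity,))
    mode_pos = np.ravel_multi_index(modes.T, (k,) * arity)
    return flat[..., mode_pos]


@lru_cache(maxsize=None)
def _grouping_matrix(k: int, arity: int) -> np.ndarray:
    """(k^arity, n_modes) 0/1 matrix summing ordered tuples into their mode."""
    modes, inverse = _mode_tables(k, arity)
    g = np.zeros((k**arity, modes.shape[0]))
    g[np.arange(k**arity), inverse] = 1.0
    return g


# ---------------------------------------------------------------------------
# elementary operations (spec'd building blocks; the batched machinery below
# is what inference actually calls)


def component_matrix(m_a: np.ndarray, m_b: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Probability component matrix ``P[I, J] = m_a[I] m_b[J] R[I, J]``."""
    m_a = np.asarray(m_a, dtype=float)
    m_b = np.asarray(m_b, dtype=float)
    r = np.asarray(r, dtype=float)
    k = m_a.shape[-1]
    if m_b.shape[-1] != k or r.shape[-2:] != (k, k):
        raise ShapeError(
            f"inconsistent shapes: m_a {m_a.shape}, m_b {m_b.shape}, R {r.shape}"
        )
    return m_a[..., :, None] * m_b[..., None, :] * r


def reaction_probability(memberships: Sequence[np.ndarray], r: np.ndarray) -> float | np.ndarray:
    """Noisy-OR reaction probability for one experiment.

    ``memberships`` holds one membership row per reagent (2-4 rows); ``r`` is
    the full symmetric reactivity tensor of matching arity.  Each unordered
    property combination is an independent potential cause; within a
    combination the distinct assignments of reagents to property indices are
    OR-ed, which for a symmetric tensor is equivalent to the product over all
    ordered index tuples:

        p = 1 - prod_{I1..Ik} (1 - m_1[I1] ... m_k[Ik] * R[I1..Ik])

    The result is invariant under permutation of the membership rows.
    """
    rows = [np.asarray(m, dtype=float) for m in memberships]
    arity = len(rows)
    if arity not in (2, 3, 4):
        raise ShapeError(f"arity must be 2-4, got {arity}")
    r = np.asarray(r, dtype=float)
    k = rows[0].shape[-1]
    if r.ndim < arity or r.shape[-arity:] != (k,) * arity:
        raise ShapeError(f"reactivity tensor shape {r.shape} does not match arity {arity}, k {k}")
    outer = rows[0]
    for row in rows[1:]:
        if row.shape[-1] != k:
            raise ShapeError("membership rows differ in length")
        outer = outer[..., :, None] * row[..., None, :]
        outer = outer.reshape(outer.shape[:-2] + (outer.shape[-2] * outer.shape[-1],))
    term = outer * r.reshape(r.shape[:-arity] + (k**arity,))
    term = np.clip(term, 0.0, _ONE_MINUS)
    p = -np.expm1(np.sum(np.log1p(-term), axis=-1))
    return float(p) if np.ndim(p) == 0 else p


def compound_membership_from_bits(
    bit_set: Iterable[int],
    bit_memberships: np.ndarray,
    basis: Sequence[int] | None = None,
) -> np.ndarray:
    """Membership row of a compound from the memberships of its set bits.

    Each present bit is an independent potential carrier of every property, so
    per-property degrees combine by noisy-OR: ``row[I] = 1 - prod_b (1 - M[b, I])``.
    ``basis`` maps bit ids to rows of ``bit_memberships``; when omitted, bit
    ids index rows directly.  An empty bit set yields the all-zeros row.
    """
    m = np.asarray(bit_memberships, dtype=float)
    bit_set = list(bit_set)
    if basis is not None:
        index = {b: i for i, b in enumerate(basis)}
        try:
            positions = [index[b] for b in bit_set]
        except KeyError as exc:
            raise KeyError(f"bit {exc.args[0]} not in fingerprint basis") from None
    else:
        positions = [int(b) for b in bit_set]
        if any(p < 0 or p >= m.shape[0] for p in positions):
            raise KeyError(f"bit index out of range for basis of size {m.shape[0]}")
    if not positions:
        return np.zeros(m.shape[-1])
    sub = np.clip(m[positions], 0.0, _ONE_MINUS)
    return -np.expm1(np.sum(np.log1p(-sub), axis=0))


def mode_components(memberships: Sequence[np.ndarray], r: np.ndarray) -> np.ndarray:
    """Per-mode (unordered property multiset) firing probabilities for one
    experiment: OR over the distinct reagent-to-index assignments of each
    multiset."""
    rows = [np.asarray(m, dtype=float) for m in memberships]
    arity = len(rows)
    k = rows[0].shape[-1]
    outer = rows[0]
    for row in rows[1:]:
        outer = outer[..., :, None] * row[..., None, :]
        outer = outer.reshape(outer.shape[:-2] + (-1,))
    term = outer * np.asarray(r, dtype=float).reshape((k**arity,))
    term = np.clip(term, 0.0, _ONE_MINUS)
    g = _grouping_matrix(k, arity)
    return -np.expm1(np.log1p(-term) @ g)


def bit_probability(
    memberships: Sequence[np.ndarray],
    r: np.ndarray,
    emission: np.ndarray,
    noise: NoiseModel,
    bit: int | None = None,
) -> float | np.ndarray:
    """Probability of observing a given outcome bit for one experiment.

    ``emission`` is the (n_modes, B) matrix for the experiment's arity, rows in
    canonical mode order.  The latent signal is the noisy-OR over modes of
    (mode component x emission weight); the returned probability folds in the
    false-positive / false-negative rates.  With ``bit=None`` the whole
    length-B vector is returned.
    """
    comp = mode_components(memberships, r)
    emission = np.asarray(emission, dtype=float)
    if emission.ndim == 1:
        emission = emission[:, None]
    if emission.shape[0] != comp.shape[-1]:
        raise ShapeError(
            f"emission has {emission.shape[0]} mode rows, expected {comp.shape[-1]}"
        )
    if bit is not None:
        if not (0 <= bit < emission.shape[1]):
            raise IndexError(f"bit {bit} out of range for width {emission.shape[1]}")
        emission = emission[:, bit : bit + 1]
    x = np.clip(comp[..., :, None] * emission, 0.0, _ONE_MINUS)
    signal = -np.expm1(np.sum(np.log1p(-x), axis=-2))
    p = noise.apply(signal)
    if bit is not None:
        p = p[..., 0]
    return float(p) if np.ndim(p) == 0 else p


# ---------------------------------------------------------------------------
# compiled theory: parameter packing + batched likelihood


@dataclass(frozen=True)
class _Block:
    name: str
    shape: tuple[int, ...]
    sl: slice
    prior: tuple[float, float]


class ExperimentBatch:
    """Experiments grouped by arity with compound rows pre-indexed, so the
    likelihood is a handful of dense einsum-style operations."""

    def __init__(self, compiled: "CompiledTheory", experiments: Sequence[Experiment]):
        self.experiments = tuple(experiments)
        self.n = len(self.experiments)
        space = compiled.space
        by_arity: dict[int, list[tuple[int, list[int]]]] = {}
        for pos, e in enumerate(self.experiments):
            if e.arity not in compiled.theory.arities:
                raise ShapeError(
                    f"experiment {e} has arity {e.arity}, theory models {compiled.theory.arities}"
                )
            rows = [space.index(cid) for cid in e.reagents]
            by_arity.setdefault(e.arity, []).append((pos, rows))
        self.groups: list[tuple[int, np.ndarray, np.ndarray]] = []
        for arity in sorted(by_arity):
            entries = by_arity[arity]
            positions = np.array([p for p, _ in entries], dtype=int)
            indices = np.array([r for _, r in entries], dtype=int)
            self.groups.append((arity, positions, indices))


class CompiledTheory:
    """A theory bound to a chemical space: flat parameter vector layout,
    priors, and vectorised probability / likelihood evaluation.

    Parameter blocks, in order: ``membership`` (entities x k), one
    ``reactivity{a}`` block of unique symmetric entries per arity ``a`` and,
    for multibit theories, ``emission`` (total modes x width).  All parameters
    live in (0, 1); MCMC runs in the logit parameterisation.
    """

    def __init__(self, theory: Theory, space: ChemicalSpace):
        self.theory = theory
        self.space = space
        self.k = theory.k
        self.width = theory.width
        if theory.basis == "compound":
            self.entities: tuple = space.ids
            self.incidence = None
        else:
            compounds = space.compounds
            if any(c.fingerprint is None for c in compounds):
                compounds = tuple(compute_fingerprints(compounds, theory.fingerprint))
            bits = sorted(set().union(*(c.fingerprint for c in compounds)))
            self.entities = tuple(bits)
            pos = {b: i for i, b in enumerate(bits)}
            inc = np.zeros((len(compounds), len(bits)))
            for ci, c in enumerate(compounds):
                for b in c.fingerprint:
                    inc[ci, pos[b]] = 1.0
            self.incidence = inc
        e = len(self.entities)

        blocks: list[_Block] = []
        offset = 0

        def add(name: str, shape: tuple[int, ...], prior_block: str) -> None:
            nonlocal offset
            size = int(np.prod(shape))
            blocks.append(_Block(name, shape, slice(offset, offset + size), theory.prior_ab(prior_block)))
            offset += size

        add("membership", (e, self.k), "membership")
        self.mode_offsets: dict[int, int] = {}
        total_modes = 0
        for arity in theory.arities:
            m = n_modes(self.k, arity)
            self.mode_offsets[arity] = total_modes
            total_modes += m
            add(f"reactivity{arity}", (m,), "reactivity")
        self.total_modes = total_modes
        if self.width > 1:
            add("emission", (total_modes, self.width), "emission")
        self.blocks = {b.name: b for b in blocks}
        self.ndim = offset

        a_vec = np.empty(self.ndim)
        b_vec = np.empty(self.ndim)
        for b in blocks:
            a_vec[b.sl], b_vec[b.sl] = b.prior
        self._a = a_vec
        self._b = b_vec
        self._log_beta_norm = float(np.sum(betaln(a_vec, b_vec)))

    # -- parameter layout ---------------------------------------------------

    def block(self, theta: np.ndarray, name: str) -> np.ndarray:
        b = self.blocks[name]
        theta = np.asarray(theta, dtype=float)
        return theta[..., b.sl].reshape(theta.shape[:-1] + b.shape)

    def pack(self, membership: np.ndarray, reactivity: Mapping[int, np.ndarray],
             emission: np.ndarray | None = None) -> np.ndarray:
        """Flatten structured parameter values (full symmetric tensors are
        accepted and reduced to unique entries) into one theta vector."""
        parts = [np.asarray(membership, dtype=float).reshape(-1)]
        for arity in self.theory.arities:
            r = np.asarray(reactivity[arity], dtype=float)
            expected = self.blocks[f"reactivity{arity}"].shape[0]
            if r.ndim == arity and r.shape == (self.k,) * arity:
                r = unique_entries(r, arity)
            if r.reshape(-1).shape[0] != expected:
                raise ShapeError(f"reactivity{arity}: expected {expected} unique entries")
            parts.append(r.reshape(-1))
        if self.width > 1:
            if emission is None:
                raise ShapeError("multibit theory requires an emission matrix")
            em = np.asarray(emission, dtype=float)
            if em.shape != (self.total_modes, self.width):
                raise ShapeError(
                    f"emission shape {em.shape}, expected {(self.total_modes, self.width)}"
                )
            parts.append(em.reshape(-1))
        theta = np.concatenate(parts)
        if theta.shape[0] != self.ndim:
            raise ShapeError(f"packed {theta.shape[0]} values, expected {self.ndim}")
        return theta

    def reactivity_tensor(self, theta: np.ndarray, arity: int) -> np.ndarray:
        """Full symmetric reactivity tensor for one arity."""
        return symmetric_tensor(self.block(theta, f"reactivity{arity}"), self.k, arity)

    def emission_for_arity(self, theta: np.ndarray, arity: int) -> np.ndarray:
        em = self.block(theta, "emission")
        off = self.mode_offsets[arity]
        return em[..., off : off + n_modes(self.k, arity), :]

    # -- priors -------------------------------------------------------------

    def sample_prior(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """(n, ndim) draws from the independent Beta priors."""
        return rng.beta(self._a, self._b, size=(n, self.ndim))

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        theta = np.clip(np.asarray(theta, dtype=float), PROB_FLOOR, 1 - PROB_FLOOR)
        return (
            np.sum((self._a - 1) * np.log(theta) + (self._b - 1) * np.log1p(-theta), axis=-1)
            - self._log_beta_norm
        )

    def log_posterior_z(self, z: np.ndarray, batch: ExperimentBatch, y: np.ndarray) -> np.ndarray:
        """Unnormalised log posterior in the unconstrained logit
        parameterisation (Beta prior x likelihood x Jacobian)."""
        z = np.asarray(z, dtype=float)
        theta = expit(z)
        theta_c = np.clip(theta, PROB_FLOOR, 1 - PROB_FLOOR)
        # Beta(a,b) density + logit Jacobian theta(1-theta) collapses to
        # a*log(theta) + b*log(1-theta) up to constants
        lp = np.sum(self._a * np.log(theta_c) + self._b * np.log1p(-theta_c), axis=-1)
        out = lp + self.log_likelihood(theta, batch, y)
        # keep the ensemble in a numerically sane region of the logit scale
        runaway = np.any(np.abs(z) > 200, axis=-1)
        return np.where(runaway, -np.inf, out)

    # -- likelihood ---------------------------------------------------------

    def compound_rows(self, theta: np.ndarray) -> np.ndarray:
        """(..., n_compounds, k) membership rows, resolving the fingerprint
        basis through per-property noisy-OR over each compound's set bits."""
        m = self.block(theta, "membership")
        if self.incidence is None:
            return m
        log1m = np.log1p(-np.clip(m, 0.0, _ONE_MINUS))
        return -np.expm1(np.einsum("cb,...bk->...ck", self.incidence, log1m))

    def signal(self, theta: np.ndarray, batch: ExperimentBatch) -> np.ndarray:
        """(..., n_experiments, width) latent signal probabilities (noise-free)."""
        theta = np.asarray(theta, dtype=float)
        lead = theta.shape[:-1]
        rows = self.compound_rows(theta)
        out = np.zeros(lead + (batch.n, self.width))
        for arity, positions, indices in batch.groups:
            n_a = indices.shape[0]
            outer = rows[..., indices[:, 0], :]
            for j in range(1, arity):
                rj = rows[..., indices[:, j], :]
                outer = outer[..., :, :, None] * rj[..., :, None, :]
                outer = outer.reshape(lead + (n_a, -1))
            r_flat = self.block(theta, f"reactivity{arity}")[
                ..., _mode_tables(self.k, arity)[1]
            ]
            term = np.clip(outer * r_flat[..., None, :], 0.0, _ONE_MINUS)
            log1m = np.log1p(-term)
            if self.width == 1:
                s = -np.expm1(np.sum(log1m, axis=-1))[..., None]
            else:
                g = _grouping_matrix(self.k, arity)
                comp = -np.expm1(log1m @ g)  # (..., n_a, modes)
                em = self.emission_for_arity(theta, arity)  # (..., modes, B)
                x = np.clip(comp[..., :, :, None] * em[..., None, :, :], 0.0, _ONE_MINUS)
                s = -np.expm1(np.sum(np.log1p(-x), axis=-2))
            out[..., positions, :] = s
        return out

    def probabilities(self, theta: np.ndarray, batch: ExperimentBatch) -> np.ndarray:
        """(..., n_experiments, width) observation-bit probabilities with noise."""
        return self.theory.noise.apply(self.signal(theta, batch))

    def per_observation_log_likelihood(
        self, theta: np.ndarray, batch: ExperimentBatch, y: np.ndarray
    ) -> np.ndarray:
        """(..., n_observations) Bernoulli log-likelihood per observation."""
        y = np.asarray(y, dtype=float)
        if y.shape != (batch.n, self.width):
            raise ShapeError(f"outcome matrix shape {y.shape}, expected {(batch.n, self.width)}")
        p = np.clip(self.probabilities(theta, batch), PROB_FLOOR, 1 - PROB_FLOOR)
        return np.sum(y * np.log(p) + (1 - y) * np.log1p(-p), axis=-1)

    def log_likelihood(self, theta: np.ndarray, batch: ExperimentBatch, y: np.ndarray) -> np.ndarray:
        if batch.n == 0:
            theta = np.asarray(theta, dtype=float)
            return np.zeros(theta.shape[:-1])
        return np.sum(self.per_observation_log_likelihood(theta, batch, y), axis=-1)

    def batch(self, experiments: Sequence[Experiment]) -> ExperimentBatch:
        return ExperimentBatch(self, experiments)

    def batch_for_log(self, log: ObservationLog) -> tuple[ExperimentBatch, np.ndarray]:
        if len(log) and log.width != self.width:
            raise ShapeError(f"log width {log.width} does not match theory width {self.width}")
        batch = ExperimentBatch(self, log.experiments)
        y = log.outcome_matrix() if len(log) else np.zeros((0, self.width))
        return batch, y


def log_likelihood(
    log: ObservationLog,
    theta: Mapping[str, object],
    theory: Theory,
    space: ChemicalSpace | None = None,
) -> float:
    """Log-likelihood of an observation log under explicit parameter values.

    ``theta`` maps ``"membership"`` to the entity x k matrix, ``"reactivity"``
    to a per-arity mapping of (full or unique-entry) tensors and, for multibit
    theories, ``"emission"`` to the modes x width matrix.
    """
    space = space or log.space
    compiled = CompiledTheory(theory, space)
    flat = compiled.pack(
        theta["membership"], theta["reactivity"], theta.get("emission")
    )
    batch, y = compiled.batch_for_log(log)
    return float(compiled.log_likelihood(flat, batch, y))
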