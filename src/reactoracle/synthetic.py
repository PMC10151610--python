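"""Synthetic chemical spaces with planted reactivity rules.

These fixtures generate every input the rest of the package needs without
external data: a six-compound cycloaddition space whose minimal explanation
requires four abstract properties (two of them on cyclopentadiene), a
nine-compound space hiding a binary acid-amine rule and the ternary
Passerini rule (acid + carbonyl + isocyanide), and an eleven-compound space
reproducing the 8-bit reactivity vectors of eight historically named
reactions.  A small chromatogram-to-bit-vector converter emulates how such
vectors arise from HPLC peak lists in the first place.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .space import (
    ChemicalSpace,
    Compound,
    Experiment,
    Observation,
    ObservationLog,
    ReactivityVector,
    enumerate_experiments,
)
from .theory import NoiseModel, symmetric_tensor

__all__ = [
    "PlantedRule",
    "PeakList",
    "OutcomeSource",
    "make_diels_alder_space",
    "make_passerini_space",
    "make_named_reaction_space",
    "make_planted_binary_instance",
    "simulate_log",
    "reactivity_vector_from_chromatograms",
    "NAMED_REACTION_TABLE",
]

OutcomeSource = Callable[[Experiment], ReactivityVector]


@dataclass(frozen=True)
class PlantedRule:
    """A ground-truth reactivity rule: a required compound set (arity 2-4)
    that emits certain outcome bits when fully present."""

    compounds: frozenset[str]
    bits: frozenset[int] = frozenset({0})
    fire_probability: float = 1.0
    self_pair: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "compounds", frozenset(self.compounds))
        object.__setattr__(self, "bits", frozenset(self.bits))
        arity = 2 if self.self_pair else len(self.compounds)
        if arity not in (2, 3, 4):
            raise ValueError(f"rule arity must be 2-4, got {arity}")
        if not (0 < self.fire_probability <= 1):
            raise ValueError("fire probability must lie in (0, 1]")

    def matches(self, experiment: Experiment) -> bool:
        if self.self_pair:
            return experiment.self_pair and set(experiment.ids) == set(self.compounds)
        return not experiment.self_pair and set(experiment.ids) == set(self.compounds)


def _rule_outcome_source(rules: Sequence[PlantedRule], width: int) -> OutcomeSource:
    def source(experiment: Experiment) -> ReactivityVector:
        bits = [0] * width
        for rule in rules:
            if rule.matches(experiment):
                for b in rule.bits:
                    bits[b] = 1
        return ReactivityVector(tuple(bits))

    return source


# ---------------------------------------------------------------------------
# Diels-Alder toy space


def make_diels_alder_space(unobserved: Iterable[frozenset[str]] = ()) -> dict:
    """Six-compound space around the discovery of the Diels-Alder reaction.

    Compounds: an acid, a base, two inert fillers, a dienophile-only partner
    (maleic anhydride) and cyclopentadiene, which dimerises.  Planted rules:
    acid + base react, cyclopentadiene reacts with itself, and cyclopentadiene
    reacts with the dienophile partner; everything else is unreactive.

    The observed experiment list contains all 15 cross pairs plus all six
    self-pairs (only cyclopentadiene dimerises).  The unreactive self-pairs
    are what force the minimal explanation up to four properties: without
    them a single shared property with diagonal reactivity could explain the
    acid-base pair (or let the partner "dimerise") using fewer labels.  Hence
    the expected parsimonious fit uses exactly four properties, two of them
    on cyclopentadiene (diene and dienophile).

    ``unobserved`` removes pairs (as id frozensets) from the observed list,
    mimicking not-yet-investigated combinations.
    """
    compounds = (
        Compound("aa", "acetic acid", "CC(=O)O"),
        Compound("et3n", "triethylamine", "CCN(CC)CC"),
        Compound("tol", "toluene", "Cc1ccccc1"),
        Compound("chx", "cyclohexane", "C1CCCCC1"),
        Compound("ma", "maleic anhydride", "O=C1OC(=O)C=C1"),
        Compound("cp", "cyclopentadiene", "C1C=CC=C1"),
    )
    space = ChemicalSpace(compounds, arities=(2,))
    rules = (
        PlantedRule(frozenset({"aa", "et3n"})),
        PlantedRule(frozenset({"cp"}), self_pair=True),
        PlantedRule(frozenset({"cp", "ma"})),
    )
    source = _rule_outcome_source(rules, width=1)
    experiments = enumerate_experiments(space, arities=(2,), include_self_pairs=True)
    drop = {frozenset(u) for u in unobserved}
    experiments = [e for e in experiments if frozenset(e.ids) not in drop]
    return {
        "space": space,
        "outcome_source": source,
        "rules": rules,
        "experiments": experiments,
        "expected": {"total_properties": 4, "cyclopentadiene_properties": 2},
        "cyclopentadiene": "cp",
    }


# ---------------------------------------------------------------------------
# Passerini space


def make_passerini_space() -> dict:
    """Nine-compound space hiding an acid-amine rule and the Passerini rule.

    One isocyanide, two carboxylic acids, two carbonyl compounds, two amines
    and two inert solvents.  Binary mode: any {acid, amine} pair reacts.
    Ternary mode: any {acid, carbonyl, isocyanide} triple reacts (the
    Passerini reaction).  All other combinations, including ternaries that
    merely contain an acid-amine pair, are unreactive.  Enumeration yields
    exactly 36 pairs and 84 triples.
    """
    compounds = (
        Compound("iso", "tert-butyl isocyanide", "CC(C)(C)[N+]#[C-]"),
        Compound("aca", "acetic acid", "CC(=O)O"),
        Compound("bza", "benzoic acid", "OC(=O)c1ccccc1"),
        Compound("bzh", "benzaldehyde", "O=Cc1ccccc1"),
        Compound("ace", "acetone", "CC(C)=O"),
        Compound("bua", "n-butylamine", "CCCCN"),
        Compound("ani", "aniline", "Nc1ccccc1"),
        Compound("chx", "cyclohexane", "C1CCCCC1"),
        Compound("tol", "toluene", "Cc1ccccc1"),
    )
    roles = {
        "isocyanide": frozenset({"iso"}),
        "acid": frozenset({"aca", "bza"}),
        "carbonyl": frozenset({"bzh", "ace"}),
        "amine": frozenset({"bua", "ani"}),
        "inert": frozenset({"chx", "tol"}),
    }
    space = ChemicalSpace(compounds, arities=(2, 3))

    def has(ids: set[str], role: str) -> int:
        return len(ids & roles[role])

    def source(experiment: Experiment) -> ReactivityVector:
        ids = set(experiment.ids)
        if experiment.arity == 2 and not experiment.self_pair:
            reactive = has(ids, "acid") == 1 and has(ids, "amine") == 1
        elif experiment.arity == 3:
            reactive = (
                has(ids, "acid") == 1
                and has(ids, "carbonyl") == 1
                and has(ids, "isocyanide") == 1
            )
        else:
            reactive = False
        return ReactivityVector.binary(reactive)

    passerini_triples = [
        Experiment((a, c, "iso"))
        for a in sorted(roles["acid"])
        for c in sorted(roles["carbonyl"])
    ]
    return {
        "space": space,
        "outcome_source": source,
        "roles": roles,
        "passerini_experiments": sorted(passerini_triples, key=Experiment.key),
    }


# ---------------------------------------------------------------------------
# named-reaction space (11 compounds, 8-bit reactivity vectors)

#: (name, reagent ids, full reactivity vector, unique ("bold") bit indices).
#: Non-unique bits are also emitted by proper sub-combinations of the reagent
#: set; unique bits appear only when the full set is combined.
NAMED_REACTION_TABLE: tuple[tuple[str, frozenset[str], str, frozenset[int]], ...] = (
    ("aldol_condensation", frozenset({"11", "13", "19"}), "00000001", frozenset({7})),
    ("buchwald_hartwig", frozenset({"11", "12", "18", "19"}), "00000100", frozenset({5})),
    ("heck", frozenset({"10", "11", "18", "19"}), "00000100", frozenset({5})),
    ("mannich", frozenset({"11", "12", "13", "20"}), "01000001", frozenset({7})),
    ("sonogashira", frozenset({"11", "14", "18", "19"}), "00001100", frozenset({5})),
    ("suzuki", frozenset({"11", "17", "18", "19"}), "00000110", frozenset({5})),
    ("wittig", frozenset({"13", "16", "19"}), "00000111", frozenset({6})),
    ("wittig_horner", frozenset({"13", "15", "19"}), "00000010", frozenset({6})),
)


def make_named_reaction_space() -> dict:
    """Eleven-compound space reproducing eight named reactions with 8-bit
    reactivity vectors.

    Compound ids 10-20 follow the roles the reactions require: an alkene (10),
    a bromoaryl ketone that serves both as aryl halide and enolisable ketone
    (11), an amine (12), an aldehyde (13), an alkyne (14), a phosphonate (15),
    a phosphonium salt (16), a boronic acid (17), a palladium catalyst (18), a
    carbonate base (19) and an acid catalyst (20).

    The outcome source returns each tabulated reagent set's full 8-bit vector.
    Proper sub-combinations of a tabulated set emit that set's non-unique
    bits (reactivity attributable to a smaller ensemble); combinations covered
    by no row return all zeros.  The full enumeration at arities {2, 3, 4} has
    C(11,2) + C(11,3) + C(11,4) = 550 experiments.
    """
    compounds = (
        Compound("10", "styrene", "C=Cc1ccccc1"),
        Compound("11", "4'-bromoacetophenone", "CC(=O)c1ccc(Br)cc1"),
        Compound("12", "aniline", "Nc1ccccc1"),
        Compound("13", "benzaldehyde", "O=Cc1ccccc1"),
        Compound("14", "phenylacetylene", "C#Cc1ccccc1"),
        Compound("15", "diethyl benzylphosphonate", "CCOP(=O)(OCC)Cc1ccccc1"),
        Compound(
            "16",
            "benzyltriphenylphosphonium chloride",
            "[Cl-].C(c1ccccc1)[P+](c1ccccc1)(c1ccccc1)c1ccccc1",
        ),
        Compound("17", "phenylboronic acid", "OB(O)c1ccccc1"),
        Compound("18", "palladium catalyst", None),
        Compound("19", "potassium carbonate", "[K+].[K+].[O-]C([O-])=O"),
        Compound("20", "hydrochloric acid", "Cl"),
    )
    space = ChemicalSpace(compounds, arities=(2, 3, 4))
    width = 8
    table = NAMED_REACTION_TABLE

    def source(experiment: Experiment) -> ReactivityVector:
        if experiment.self_pair:
            return ReactivityVector((0,) * width)
        ids = set(experiment.ids)
        bits = [0] * width
        for _, reagents, vector, unique_bits in table:
            if ids == reagents:
                return ReactivityVector.from_string(vector)
            if ids < reagents:
                for b, c in enumerate(vector):
                    if c == "1" and b not in unique_bits:
                        bits[b] = 1
        return ReactivityVector(tuple(bits))

    named = {
        name: (Experiment(tuple(sorted(reagents))), ReactivityVector.from_string(vector))
        for name, reagents, vector, _ in table
    }
    return {"space": space, "outcome_source": source, "named": named, "width": width}


# ---------------------------------------------------------------------------
# planted-truth binary instance for parameter recovery


def make_planted_binary_instance(k: int = 3, sharp: float = 0.95) -> dict:
    """Ground-truth instance for parameter recovery: six compounds, ``k``
    properties with sharp memberships in {0, sharp} and a single reactive
    property pair.  Pairs where one compound carries property 0 and the other
    property 1 are the reactive class; the full arity-2 space is labelled
    noise-free (label = rule fired, i.e. true signal > 1/2)."""
    compounds = tuple(Compound(f"c{i}", f"compound {i}") for i in range(6))
    space = ChemicalSpace(compounds, arities=(2,))
    membership = np.zeros((6, k))
    groups = [0, 0, 1, 1, 2, 2]
    for i, g in enumerate(groups):
        membership[i, g % k] = sharp
    r = np.zeros((k, k))
    r[0, 1] = r[1, 0] = sharp
    reactive = {
        frozenset({a.id, b.id})
        for a, b in [
            (compounds[i], compounds[j])
            for i in range(6)
            for j in range(i + 1, 6)
            if {groups[i], groups[j]} == {0, 1}
        ]
    }

    def source(experiment: Experiment) -> ReactivityVector:
        return ReactivityVector.binary(frozenset(experiment.ids) in reactive)

    return {
        "space": space,
        "outcome_source": source,
        "membership": membership,
        "reactivity": r,
        "reactive_pairs": reactive,
    }


# ---------------------------------------------------------------------------
# log simulation


def simulate_log(
    space: ChemicalSpace,
    outcome_source: OutcomeSource,
    order: str = "canonical",
    noise: NoiseModel | None = None,
    seed: int | None = None,
    experiments: Sequence[Experiment] | None = None,
    arities: Iterable[int] | None = None,
) -> ObservationLog:
    """Record the outcome of every experiment into an observation log.

    ``order`` is ``"canonical"`` (deterministic enumeration order) or
    ``"shuffled"`` (seeded permutation).  With a noise model, each recorded
    bit is flipped 0->1 at the false-positive rate and 1->0 at the
    false-negative rate; both the shuffle and the flips derive from ``seed``,
    so the log is reproducible.
    """
    if experiments is None:
        experiments = enumerate_experiments(space, arities=arities)
    experiments = list(experiments)
    rng = np.random.default_rng(seed)
    if order == "shuffled":
        rng.shuffle(experiments)
    elif order != "canonical":
        raise ValueError(f"unknown order: {order}")
    observations = []
    for t, e in enumerate(experiments):
        bits = np.array(outcome_source(e).bits, dtype=int)
        if noise is not None and (noise.eps_fp > 0 or noise.eps_fn > 0):
            u = rng.random(bits.shape)
            flip = np.where(bits == 0, u < noise.eps_fp, u < noise.eps_fn)
            bits = np.where(flip, 1 - bits, bits)
        observations.append(Observation(e, ReactivityVector(tuple(int(b) for b in bits)), t))
    return ObservationLog(space, observations)


# ---------------------------------------------------------------------------
# chromatogram peak lists -> reactivity vectors


@dataclass(frozen=True)
class PeakList:
    """Chromatogram peaks as (retention time in minutes, relative intensity)."""

    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        peaks = tuple((float(t), float(i)) for t, i in self.peaks)
        object.__setattr__(self, "peaks", peaks)
        times = [t for t, _ in peaks]
        if any(t < 0 for t in times):
            raise ValueError("retention times must be non-negative")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("retention times must be strictly increasing")
        if any(not (0 < i <= 1) for _, i in peaks):
            raise ValueError("relative intensities must lie in (0, 1]")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.peaks], dtype=float)


def reactivity_vector_from_chromatograms(
    reactants: Sequence[PeakList],
    product: PeakList,
    bins: Sequence[float],
    match_tol: float = 0.1,
) -> ReactivityVector:
    """Bin new product peaks into a reactivity vector.

    ``bins`` are strictly increasing edges defining ``len(bins) - 1`` regions.
    Bit ``b`` is set iff the product chromatogram has at least one peak inside
    region ``b`` whose retention time is farther than ``match_tol`` minutes
    from every reactant reference peak (i.e. a genuinely new peak).  Peaks
    outside all regions are ignored; an empty product list gives all zeros.
    """
    edges = np.asarray(bins, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bins must be at least two strictly increasing edges")
    width = edges.size - 1
    bits = [0] * width
    reference = (
        np.concatenate([r.times for r in reactants]) if reactants else np.empty(0)
    )
    for t in product.times:
        if reference.size and np.min(np.abs(reference - t)) <= match_tol:
            continue
        b = int(np.searchsorted(edges, t, side="right")) - 1
        if 0 <= b < width and t <= edges[-1]:
            bits[b] = 1
    return ReactivityVector(tuple(bits))
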