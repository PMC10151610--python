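"""Chemical spaces: compound rosters, combinatorial experiment enumeration,
and observation logs.

A chemical space is a fixed roster of compounds together with the set of
reaction arities (2-4 reagents) under consideration.  The enumerable set of
unordered reagent combinations at those arities is the experiment space an
autonomous platform explores.  Each performed experiment yields an
:class:`Observation` whose outcome is a fixed-width :class:`ReactivityVector`
(width 1 encodes a plain reactive / non-reactive flag; wider vectors encode
which chromatogram regions showed new product peaks).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Compound",
    "Experiment",
    "ReactivityVector",
    "Observation",
    "ObservationLog",
    "ChemicalSpace",
    "InvalidArityError",
    "UnknownCompoundError",
    "ObservationFormatError",
    "StructureError",
    "enumerate_experiments",
    "compute_fingerprints",
    "load_observations",
    "save_observations",
]

VALID_ARITIES = frozenset({2, 3, 4})


class InvalidArityError(ValueError):
    """Requested experiment arity outside the supported range {2, 3, 4}."""


class UnknownCompoundError(KeyError):
    """An observation or experiment references a compound id not in the space."""


class ObservationFormatError(ValueError):
    """Malformed observation data (inconsistent widths, duplicate order, ...)."""


class StructureError(ValueError):
    """A compound structure could not be parsed into a molecule."""


@dataclass(frozen=True)
class Compound:
    """A reagent available to the platform.

    Parameters
    ----------
    id : str
        Short unique token, e.g. ``"11"`` or ``"cp"``.
    name : str
        Human-readable name.
    smiles : str, optional
        SMILES structure.  Required for fingerprint-basis theories.
    fingerprint : frozenset of int, optional
        Indices of set bits under the configured fingerprint scheme.
    """

    id: str
    name: str = ""
    smiles: str | None = None
    fingerprint: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("compound id must be a non-empty token")


@dataclass(frozen=True, order=True)
class Experiment:
    """An unordered combination of 2-4 compounds (one candidate reaction).

    Two experiments with the same compound set are equal regardless of the
    order the ids were listed in.  The canonical form is the lexicographically
    sorted id tuple; experiments sort by ``(arity, ids)``.

    A self-combination (one compound reacted with itself, e.g. cyclopentadiene
    dimerisation) is represented by a single id with ``self_pair=True`` and
    counts as arity 2.
    """

    ids: tuple[str, ...]
    self_pair: bool = False
    condition: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        ids = tuple(sorted(self.ids))
        object.__setattr__(self, "ids", ids)
        if self.self_pair:
            if len(ids) != 1:
                raise ValueError("a self-pair experiment names exactly one compound")
        else:
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate compound ids in experiment: {ids}")
            if len(ids) not in VALID_ARITIES:
                raise InvalidArityError(
                    f"experiment size {len(ids)} outside supported arities {sorted(VALID_ARITIES)}"
                )

    @property
    def arity(self) -> int:
        return 2 if self.self_pair else len(self.ids)

    @property
    def reagents(self) -> tuple[str, ...]:
        """Reagent tuple with self-pairs expanded to (id, id)."""
        return self.ids * 2 if self.self_pair else self.ids

    def key(self) -> tuple:
        """Deterministic canonical sort key."""
        return (self.arity, self.self_pair, self.ids)

    def __str__(self) -> str:
        return "+".join(self.reagents)


@dataclass(frozen=True)
class ReactivityVector:
    """Fixed-width binary outcome of one experiment.

    Width 1 is the classic reactive / non-reactive flag.  Wider vectors record
    one bit per binned chromatogram region in which a new product peak was
    detected, rendered as a contiguous 0/1 string, e.g. ``"00000010"``.
    """

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        bits = tuple(int(b) for b in self.bits)
        if len(bits) < 1:
            raise ValueError("reactivity vector width must be >= 1")
        if any(b not in (0, 1) for b in bits):
            raise ValueError(f"reactivity vector entries must be 0/1, got {bits}")
        object.__setattr__(self, "bits", bits)

    @classmethod
    def from_string(cls, s: str) -> "ReactivityVector":
        if not s or set(s) - {"0", "1"}:
            raise ObservationFormatError(f"invalid reactivity bit string: {s!r}")
        return cls(tuple(int(c) for c in s))

    @classmethod
    def binary(cls, reactive: int | bool) -> "ReactivityVector":
        return cls((int(bool(reactive)),))

    @property
    def width(self) -> int:
        return len(self.bits)

    @property
    def reactive(self) -> bool:
        """Binary collapse: did anything at all happen?"""
        return any(self.bits)

    def __str__(self) -> str:
        return "".join(str(b) for b in self.bits)


@dataclass(frozen=True)
class Observation:
    """One recorded experiment outcome with its exploration order index."""

    experiment: Experiment
    outcome: ReactivityVector
    order: int

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("order index must be non-negative")


@dataclass(frozen=True)
class ChemicalSpace:
    """A compound roster plus the arities of combinations under study."""

    compounds: tuple[Compound, ...]
    arities: tuple[int, ...] = (2,)

    def __post_init__(self) -> None:
        compounds = tuple(self.compounds)
        arities = tuple(sorted(set(self.arities)))
        object.__setattr__(self, "compounds", compounds)
        object.__setattr__(self, "arities", arities)
        if len(compounds) < 2:
            raise ValueError("a chemical space needs at least 2 compounds")
        ids = [c.id for c in compounds]
        if len(set(ids)) != len(ids):
            raise ValueError("compound ids must be unique within a space")
        if not arities:
            raise ValueError("arities must be non-empty")
        bad = set(arities) - VALID_ARITIES
        if bad:
            raise InvalidArityError(f"unsupported arities: {sorted(bad)}")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.compounds)

    def __len__(self) -> int:
        return len(self.compounds)

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in set(self.ids)

    def compound(self, compound_id: str) -> Compound:
        for c in self.compounds:
            if c.id == compound_id:
                return c
        raise UnknownCompoundError(compound_id)

    def index(self, compound_id: str) -> int:
        try:
            return self.ids.index(compound_id)
        except ValueError:
            raise UnknownCompoundError(compound_id) from None

    def with_compounds(self, compounds: Sequence[Compound]) -> "ChemicalSpace":
        return replace(self, compounds=tuple(compounds))

    def to_dict(self) -> dict:
        return {
            "compounds": [
                {
                    "id": c.id,
                    "name": c.name,
                    **({"smiles": c.smiles} if c.smiles else {}),
                }
                for c in self.compounds
            ],
            "arities": list(self.arities),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChemicalSpace":
        compounds = tuple(
            Compound(id=c["id"], name=c.get("name", ""), smiles=c.get("smiles"))
            for c in d["compounds"]
        )
        return cls(compounds=compounds, arities=tuple(d.get("arities", [2])))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ChemicalSpace":
        return cls.from_dict(json.loads(Path(path).read_text()))


def enumerate_experiments(
    space: ChemicalSpace,
    arities: Iterable[int] | None = None,
    include_self_pairs: bool = False,
) -> list[Experiment]:
    """Enumerate all unordered compound combinations at the requested arities.

    The order is deterministic: ascending arity, then lexicographic in the
    sorted compound-id tuple.  Self-pairs are excluded unless requested
    (fixtures that model dimerisation ask for them explicitly).

    An arity larger than the roster contributes nothing (no error); an arity
    outside {2, 3, 4} raises :class:`InvalidArityError`.
    """
    if arities is None:
        arities = space.arities
    arities = sorted(set(int(a) for a in arities))
    bad = set(arities) - VALID_ARITIES
    if bad:
        raise InvalidArityError(f"unsupported arities: {sorted(bad)}")
    ids = sorted(space.ids)
    out: list[Experiment] = []
    for k in arities:
        if k == 2 and include_self_pairs:
            out.extend(Experiment(ids=(i,), self_pair=True) for i in ids)
        out.extend(Experiment(ids=combo) for combo in itertools.combinations(ids, k))
    out.sort(key=Experiment.key)
    return out


class ObservationLog:
    """An ordered collection of observations over one chemical space.

    Enforces a constant outcome width and unique exploration order indices.
    Iteration yields observations sorted by order index.
    """

    def __init__(self, space: ChemicalSpace, observations: Iterable[Observation] = ()):
        self.space = space
        self._observations: list[Observation] = sorted(observations, key=lambda o: o.order)
        self._validate()

    def _validate(self) -> None:
        orders = [o.order for o in self._observations]
        if len(set(orders)) != len(orders):
            raise ObservationFormatError("duplicate exploration order indices in log")
        widths = {o.outcome.width for o in self._observations}
        if len(widths) > 1:
            raise ObservationFormatError(
                f"inconsistent reactivity-vector widths in log: {sorted(widths)}"
            )
        known = set(self.space.ids)
        for o in self._observations:
            missing = set(o.experiment.ids) - known
            if missing:
                raise UnknownCompoundError(sorted(missing)[0])

    @property
    def width(self) -> int:
        """Outcome width; 1 for an empty log (binary convention)."""
        if not self._observations:
            return 1
        return self._observations[0].outcome.width

    @property
    def observations(self) -> tuple[Observation, ...]:
        return tuple(self._observations)

    @property
    def experiments(self) -> tuple[Experiment, ...]:
        return tuple(o.experiment for o in self._observations)

    def __len__(self) -> int:
        return len(self._observations)

    def __iter__(self) -> Iterator[Observation]:
        return iter(self._observations)

    def __getitem__(self, i: int) -> Observation:
        return self._observations[i]

    def append(self, experiment: Experiment, outcome: ReactivityVector) -> "ObservationLog":
        """Return a new log with one more observation at the next order index."""
        order = max((o.order for o in self._observations), default=-1) + 1
        return ObservationLog(
            self.space, list(self._observations) + [Observation(experiment, outcome, order)]
        )

    def head(self, n: int) -> "ObservationLog":
        return ObservationLog(self.space, self._observations[:n])

    def outcome_matrix(self) -> np.ndarray:
        """(n_observations, width) 0/1 array in order-index order."""
        if not self._observations:
            return np.zeros((0, 1), dtype=float)
        return np.array([o.outcome.bits for o in self._observations], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "order": o.order,
                "compound_ids": ";".join(o.experiment.reagents),
                "outcome": str(o.outcome),
            }
            for o in self._observations
        ]
        return pd.DataFrame(rows, columns=["order", "compound_ids", "outcome"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        records = self.to_frame().to_dict(orient="records")
        Path(path).write_text(json.dumps(records, indent=2))


def _experiment_from_field(raw: str) -> Experiment:
    parts = [p for p in str(raw).split(";") if p]
    if not parts:
        raise ObservationFormatError(f"empty compound_ids field: {raw!r}")
    if len(parts) == 2 and parts[0] == parts[1]:
        return Experiment(ids=(parts[0],), self_pair=True)
    return Experiment(ids=tuple(parts))


def load_observations(
    path: str | Path, space: ChemicalSpace, format: str | None = None
) -> ObservationLog:
    """Read an observation log from CSV or JSON.

    CSV columns: ``order``, ``compound_ids`` (semicolon-joined ids; a repeated
    id denotes a self-pair), ``outcome`` (contiguous 0/1 string).  JSON is an
    array of objects with the same keys.  Compound ids are validated against
    the space; an unknown id raises :class:`UnknownCompoundError` naming it.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        frame = pd.read_csv(path, dtype={"order": int, "compound_ids": str, "outcome": str})
        records = frame.to_dict(orient="records")
    elif format == "json":
        records = json.loads(path.read_text())
    else:
        raise ValueError(f"unsupported observation format: {format}")
    observations = []
    for rec in records:
        try:
            experiment = _experiment_from_field(rec["compound_ids"])
            outcome = ReactivityVector.from_string(str(rec["outcome"]))
        except KeyError as exc:
            raise ObservationFormatError(f"missing column {exc} in {path}") from None
        observations.append(Observation(experiment, outcome, int(rec["order"])))
    return ObservationLog(space, observations)


def save_observations(log: ObservationLog, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        log.to_csv(path)
    elif format == "json":
        log.to_json(path)
    else:
        raise ValueError(f"unsupported observation format: {format}")


@dataclass(frozen=True)
class FingerprintScheme:
    """Named molecular fingerprint configuration.

    ``maccs`` uses the 166-key MACCS substructure set; ``morgan`` uses
    extended-connectivity (circular) fingerprints with the given radius folded
    to ``nbits``.
    """

    kind: str
    radius: int = 2
    nbits: int = 1024

    def __post_init__(self) -> None:
        if self.kind not in ("maccs", "morgan"):
            raise ValueError(f"unknown fingerprint scheme: {self.kind}")

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.kind == "morgan":
            d.update(radius=self.radius, nbits=self.nbits)
        return d


def _fingerprint_fn(scheme: FingerprintScheme) -> Callable[[object], frozenset[int]]:
    # rdkit imported lazily: structure-free theories never need it
    from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

    if scheme.kind == "maccs":
        def fn(mol):
            return frozenset(MACCSkeys.GenMACCSKeys(mol).GetOnBits())
    else:
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=scheme.radius, fpSize=scheme.nbits
        )

        def fn(mol):
            return frozenset(gen.GetFingerprint(mol).GetOnBits())

    return fn


def compute_fingerprints(
    compounds: Sequence[Compound], scheme: FingerprintScheme | str
) -> list[Compound]:
    """Annotate compounds with fingerprint bit-sets under the given scheme.

    Every compound must carry a parseable SMILES structure; an unparseable or
    missing structure raises :class:`StructureError` naming the compound.  The
    union of set bits over a space defines the entity basis of a
    fingerprint-basis theory.
    """
    from rdkit import Chem

    if isinstance(scheme, str):
        scheme = FingerprintScheme(kind=scheme)
    fn = _fingerprint_fn(scheme)
    out = []
    for c in compounds:
        if not c.smiles:
            raise StructureError(f"compound {c.id!r} has no structure")
        mol = Chem.MolFromSmiles(c.smiles)
        if mol is None:
            raise StructureError(f"compound {c.id!r}: unparseable SMILES {c.smiles!r}")
        out.append(replace(c, fingerprint=fn(mol)))
    return out
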