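"""Molecules, reaction records, fingerprints, and the agent vocabulary.

All molecular structure handling goes through RDKit. Every structure is
stored as its RDKit-canonical SMILES; parse failures surface at
construction time so downstream code never sees an invalid molecule.

A reaction is represented for the models as the concatenation of two
2048-bit blocks: the bitwise OR of the Morgan fingerprints of all
reactants, followed by the same for all products.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

DEFAULT_FP_RADIUS = 2
DEFAULT_FP_BITS = 2048


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


class OutOfVocabularyError(KeyError):
    """Raised when an agent SMILES is not in the vocabulary."""

    def __init__(self, smiles: str):
        super().__init__(smiles)
        self.smiles = smiles

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"agent not in vocabulary: {self.smiles!r}"


def canonicalize_smiles(s: str) -> str:
    """Return the RDKit-canonical form of ``s``.

    Idempotent: canonicalizing a canonical SMILES returns it unchanged.
    Raises :class:`SmilesParseError` naming the offending input.
    """
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {s!r}")
    return Chem.MolToSmiles(mol)


@lru_cache(maxsize=200_000)
def _mol_from_canonical(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - canonical SMILES always parse
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    return mol


@dataclass(frozen=True, order=True)
class Molecule:
    """A molecule identified by its canonical SMILES.

    Construct with :meth:`from_smiles` so that parse failures are caught
    immediately; the plain constructor assumes ``smiles`` is already
    canonical.
    """

    smiles: str

    @classmethod
    def from_smiles(cls, s: str) -> "Molecule":
        return cls(canonicalize_smiles(s))

    @property
    def heavy_atoms(self) -> int:
        return _mol_from_canonical(self.smiles).GetNumHeavyAtoms()

    def __str__(self) -> str:
        return self.smiles


@lru_cache(maxsize=32)
def _morgan_generator(radius: int, n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


@lru_cache(maxsize=500_000)
def _fingerprint_cached(smiles: str, radius: int, n_bits: int) -> bytes:
    gen = _morgan_generator(radius, n_bits)
    arr = gen.GetFingerprintAsNumPy(_mol_from_canonical(smiles))
    return np.packbits(arr.astype(np.uint8)).tobytes()


def molecule_fingerprint(
    m: Molecule, radius: int = DEFAULT_FP_RADIUS, n_bits: int = DEFAULT_FP_BITS
) -> np.ndarray:
    """Binary Morgan (ECFP-style) fingerprint of a single molecule."""
    packed = np.frombuffer(_fingerprint_cached(m.smiles, radius, n_bits), dtype=np.uint8)
    return np.unpackbits(packed)[:n_bits]


@dataclass(frozen=True)
class ReactionRecord:
    """One literature-style reaction.

    ``reactants`` and ``agents`` are sequences of ``(Molecule, moles)``
    pairs where ``moles`` may be ``None`` when the source did not report
    a quantity. Agents are role-agnostic: catalysts, reagents and
    solvents all live in the same list.
    """

    document_id: str
    reactants: tuple[tuple[Molecule, Optional[float]], ...]
    agents: tuple[tuple[Molecule, Optional[float]], ...]
    products: tuple[Molecule, ...]
    temperature_c: Optional[float] = None
    class_id: Optional[str] = None

    def __post_init__(self):
        if not self.reactants:
            raise ValueError("reaction must have at least one reactant")
        if not self.products:
            raise ValueError("reaction must have at least one product")
        for mol, moles in list(self.reactants) + list(self.agents):
            if moles is not None and moles <= 0:
                raise ValueError(f"non-positive moles {moles} for {mol.smiles}")

    @property
    def agent_smiles(self) -> frozenset[str]:
        return frozenset(m.smiles for m, _ in self.agents)

    def rxn_smiles(self) -> str:
        """``reactants>agents>products`` with dot-separated species."""
        parts = (
            ".".join(m.smiles for m, _ in self.reactants),
            ".".join(m.smiles for m, _ in self.agents),
            ".".join(m.smiles for m in self.products),
        )
        return ">".join(parts)


def reaction_fingerprint(
    r: ReactionRecord, radius: int = DEFAULT_FP_RADIUS, n_bits: int = DEFAULT_FP_BITS
) -> np.ndarray:
    """Concatenated reactant-block ‖ product-block fingerprint.

    Each block is the bitwise OR over the species on that side, so the
    result is invariant to species order and duplication; total length
    ``2 * n_bits``.
    """
    block_r = np.zeros(n_bits, dtype=np.uint8)
    for mol, _ in r.reactants:
        block_r |= molecule_fingerprint(mol, radius, n_bits)
    block_p = np.zeros(n_bits, dtype=np.uint8)
    for mol in r.products:
        block_p |= molecule_fingerprint(mol, radius, n_bits)
    return np.concatenate([block_r, block_p])


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a∧b| / |a∨b| of two binary vectors.

    Defined as 0 when both vectors are all-zero.
    """
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    a = a.astype(bool)
    b = b.astype(bool)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return float(np.count_nonzero(a & b) / union)


class AgentVocabulary:
    """Fixed ordered set of canonical agent SMILES plus an end-of-set symbol.

    ``eos_index`` equals ``len(vocabulary)`` — one past the last agent —
    and is the extra output used by the autoregressive set decoder to
    terminate.
    """

    def __init__(self, agents: Sequence[str]):
        agents = tuple(agents)
        if len(set(agents)) != len(agents):
            raise ValueError("duplicate SMILES in vocabulary")
        self.agents = agents
        self._index = {s: i for i, s in enumerate(agents)}

    def __len__(self) -> int:
        return len(self.agents)

    def __contains__(self, smiles: str) -> bool:
        return smiles in self._index

    def __iter__(self) -> Iterator[str]:
        return iter(self.agents)

    def __eq__(self, other) -> bool:
        return isinstance(other, AgentVocabulary) and self.agents == other.agents

    @property
    def eos_index(self) -> int:
        return len(self.agents)

    def index(self, smiles: str) -> int:
        try:
            return self._index[smiles]
        except KeyError:
            raise OutOfVocabularyError(smiles) from None

    def content_hash(self) -> str:
        import hashlib

        return hashlib.sha256("\n".join(self.agents).encode()).hexdigest()[:16]

    def encode_indices(self, indices: Iterable[int]) -> np.ndarray:
        vec = np.zeros(len(self.agents), dtype=np.float64)
        for i in indices:
            if not 0 <= i < len(self.agents):
                raise IndexError(f"agent index {i} out of range")
            vec[i] = 1.0
        return vec

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for s in self.agents:
                fh.write(s + "\n")

    @classmethod
    def load(cls, path) -> "AgentVocabulary":
        with open(path) as fh:
            return cls([line.strip() for line in fh if line.strip()])


def encode_agent_set(agents: Iterable[str], v: AgentVocabulary) -> np.ndarray:
    """Multi-hot vector of length ``|v|`` for a set of canonical SMILES."""
    return v.encode_indices(v.index(s) for s in set(agents))


def decode_agent_set(vec: np.ndarray, v: AgentVocabulary) -> frozenset[str]:
    return frozenset(v.agents[i] for i in np.flatnonzero(vec))


# --- JSONL serialization -------------------------------------------------

def record_to_dict(r: ReactionRecord) -> dict:
    return {
        "document_id": r.document_id,
        "rxn_smiles": r.rxn_smiles(),
        "reactants": [{"smiles": m.smiles, "moles": q} for m, q in r.reactants],
        "agents": [{"smiles": m.smiles, "moles": q} for m, q in r.agents],
        "products": [{"smiles": m.smiles} for m in r.products],
        "temperature_c": r.temperature_c,
        "class_id": r.class_id,
    }


def record_from_dict(d: dict) -> ReactionRecord:
    return ReactionRecord(
        document_id=d["document_id"],
        reactants=tuple(
            (Molecule.from_smiles(x["smiles"]), x.get("moles")) for x in d["reactants"]
        ),
        agents=tuple(
            (Molecule.from_smiles(x["smiles"]), x.get("moles")) for x in d.get("agents", [])
        ),
        products=tuple(Molecule.from_smiles(x["smiles"]) for x in d["products"]),
        temperature_c=d.get("temperature_c"),
        class_id=d.get("class_id"),
    )


def write_jsonl(records: Iterable[ReactionRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps(record_to_dict(r)) + "\n")


def read_jsonl(path) -> list[ReactionRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(record_from_dict(json.loads(line)))
    return out
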