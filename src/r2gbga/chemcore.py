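"""Molecule representation, fingerprints, Tanimoto similarity and novelty.

A :class:`Molecule` is an immutable, canonical-SMILES-keyed record. All
structure comparison in the package goes through extended-connectivity
fingerprints (ECFP4, i.e. Morgan radius 2) and Tanimoto similarity; the
novelty of a generated molecule ``g`` against a reference set ``D`` is

    N(g; D) = 1 - max_{d in D} T(phi(g), phi(d))

where ``phi`` is the fingerprint map and ``T`` the Tanimoto similarity.
``N = 0`` means an identical molecule (identical fingerprint) already
exists in the reference set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeError",
    "FingerprintParams",
    "Fingerprint",
    "Molecule",
    "NoveltyResult",
    "canonicalize",
    "tanimoto",
    "novelty",
    "fingerprint_matrix",
    "tanimoto_matrix",
]


class MoleculeError(ValueError):
    """Raised when a SMILES string cannot be parsed or sanitized.

    Carries the offending text in ``.smiles``.
    """

    def __init__(self, smiles: str, reason: str):
        self.smiles = smiles
        self.reason = reason
        super().__init__(f"invalid SMILES {smiles!r}: {reason}")


@dataclass(frozen=True)
class FingerprintParams:
    """ECFP parameters. Radius 2 with 2048 binary bits is ECFP4, the
    de-facto default; chirality is excluded from the bit environments
    unless requested."""

    n_bits: int = 2048
    radius: int = 2
    use_chirality: bool = False


DEFAULT_FP_PARAMS = FingerprintParams()

_GENERATORS: dict = {}


def _generator(params: FingerprintParams):
    gen = _GENERATORS.get(params)
    if gen is None:
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=params.radius,
            fpSize=params.n_bits,
            includeChirality=params.use_chirality,
        )
        _GENERATORS[params] = gen
    return gen


@dataclass(frozen=True)
class Fingerprint:
    """Binary circular fingerprint (a fixed-length 0/1 vector)."""

    bits: np.ndarray
    params: FingerprintParams = DEFAULT_FP_PARAMS

    def __post_init__(self):
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=np.uint8))
        if self.bits.ndim != 1 or self.bits.shape[0] != self.params.n_bits:
            raise ValueError(
                f"fingerprint length {self.bits.shape} does not match "
                f"n_bits={self.params.n_bits}"
            )

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    @property
    def on_bits(self) -> frozenset:
        return frozenset(np.flatnonzero(self.bits).tolist())

    def __eq__(self, other) -> bool:
        if not isinstance(other, Fingerprint):
            return NotImplemented
        return self.params == other.params and bool(
            np.array_equal(self.bits, other.bits)
        )

    def __hash__(self) -> int:
        return hash((self.params, self.bits.tobytes()))


class Molecule:
    """Immutable molecule keyed by canonical SMILES.

    Two molecules are equal iff their canonical SMILES are equal. The
    RDKit graph and fingerprints are computed lazily and cached. Use
    :func:`canonicalize` to construct one from free-form SMILES text;
    the constructor assumes ``smiles`` is already canonical.
    """

    __slots__ = ("smiles", "name", "_mol", "_fps")

    def __init__(self, smiles: str, name: Optional[str] = None):
        self.smiles = smiles
        self.name = name
        self._mol = None
        self._fps: dict = {}

    @property
    def mol(self):
        """The underlying RDKit molecule (sanitized).

        Always parsed from the canonical SMILES, never taken from the
        object the molecule was built from, so the atom numbering of
        equal molecules is identical — substructure-match atom indices
        are then a pure function of the canonical SMILES.
        """
        if self._mol is None:
            m = Chem.MolFromSmiles(self.smiles)
            if m is None:  # pragma: no cover - canonical SMILES reparse
                raise MoleculeError(self.smiles, "reparse of canonical SMILES failed")
            self._mol = m
        return self._mol

    @property
    def heavy_atom_count(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    def fingerprint(self, params: FingerprintParams = DEFAULT_FP_PARAMS) -> Fingerprint:
        fp = self._fps.get(params)
        if fp is None:
            bv = _generator(params).GetFingerprint(self.mol)
            bits = np.zeros(params.n_bits, dtype=np.uint8)
            bits[list(bv.GetOnBits())] = 1
            fp = Fingerprint(bits, params)
            self._fps[params] = fp
        return fp

    def has_substructure(self, query) -> bool:
        return self.mol.HasSubstructMatch(query)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Molecule):
            return NotImplemented
        return self.smiles == other.smiles

    def __hash__(self) -> int:
        return hash(self.smiles)

    def __repr__(self) -> str:
        return f"Molecule({self.smiles!r})"


def canonicalize(smiles_text: str, name: Optional[str] = None) -> Molecule:
    """Parse, sanitize and canonicalize a SMILES string.

    Idempotent: ``canonicalize(canonicalize(x).smiles) == canonicalize(x)``.
    Raises :class:`MoleculeError` on parse or sanitization failure (e.g.
    valence violations), carrying the offending text.
    """
    if not smiles_text or not smiles_text.strip():
        raise MoleculeError(smiles_text, "empty SMILES")
    mol = Chem.MolFromSmiles(smiles_text, sanitize=False)
    if mol is None:
        raise MoleculeError(smiles_text, "parse failure")
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise MoleculeError(smiles_text, f"sanitization failure: {exc}") from exc
    return Molecule(Chem.MolToSmiles(mol), name=name)


def mol_to_molecule(mol, name: Optional[str] = None) -> Molecule:
    """Wrap an already-built RDKit molecule, sanitizing it first."""
    mol = Chem.Mol(mol)
    Chem.SanitizeMol(mol)
    return Molecule(Chem.MolToSmiles(mol), name=name)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two binary fingerprints.

    Both fingerprints must share parameters. Two all-zero fingerprints
    are defined as identical empty feature sets, similarity 1.
    """
    if a.params != b.params:
        raise ValueError(
            f"fingerprint parameter mismatch: {a.params} vs {b.params}"
        )
    inter = int(np.bitwise_and(a.bits, b.bits).sum())
    union = a.popcount + b.popcount - inter
    if union == 0:
        return 1.0
    return inter / union


@dataclass(frozen=True)
class NoveltyResult:
    """Novelty of one molecule against a reference set."""

    novelty: float
    nearest_reference: str
    max_similarity: float


def novelty(
    g: Molecule,
    reference: Iterable[Molecule],
    params: FingerprintParams = DEFAULT_FP_PARAMS,
) -> NoveltyResult:
    """Novelty N(g; D) = 1 - max Tanimoto of ``g`` to the reference set.

    Ties for the nearest reference are broken by lexicographic canonical
    SMILES so the result is reproducible. The reference set must be
    non-empty.
    """
    ref = list(reference)
    if not ref:
        raise ValueError("reference set must be non-empty")
    gfp = g.fingerprint(params)
    best_sim = -1.0
    best_smiles = None
    for d in sorted(ref, key=lambda m: m.smiles):
        s = tanimoto(gfp, d.fingerprint(params))
        if s > best_sim:
            best_sim = s
            best_smiles = d.smiles
    return NoveltyResult(
        novelty=1.0 - best_sim, nearest_reference=best_smiles, max_similarity=best_sim
    )


def fingerprint_matrix(
    mols: Sequence[Molecule], params: FingerprintParams = DEFAULT_FP_PARAMS
) -> np.ndarray:
    """Stack fingerprints into an (n, n_bits) uint8 matrix."""
    return np.stack([m.fingerprint(params).bits for m in mols]) if mols else np.zeros(
        (0, params.n_bits), dtype=np.uint8
    )


def tanimoto_matrix(X: np.ndarray, Y: Optional[np.ndarray] = None) -> np.ndarray:
    """Pairwise Tanimoto similarity between rows of two binary matrices.

    Rows with empty bit sets are treated as identical to each other
    (similarity 1), consistent with :func:`tanimoto`.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = X if Y is None else np.asarray(Y, dtype=np.float64)
    inter = X @ Y.T
    px = X.sum(axis=1)
    py = Y.sum(axis=1)
    union = px[:, None] + py[None, :] - inter
    out = np.ones_like(inter)
    np.divide(inter, union, out=out, where=union > 0)
    return out
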