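"""Path-based molecular fingerprints and similarity scoring.

Each connectivity is summarized by a fixed-width 2040-bit vector.  Bits are
set for every simple bonded path of 1-10 atoms, encoded as a canonical
alternating element/bond string (charges suffixed when nonzero), hashed with
64-bit FNV-1a modulo the width.  Cyclicity is deliberately not encoded:
hexane and cyclohexane share a fingerprint.  Typing is element based, so
e.g. fluorine and chlorine analogues are distinct.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .chem import MoleculeGraph

__all__ = [
    "FP_WIDTH",
    "MAX_PATH_ATOMS",
    "BitFingerprint",
    "atom_token",
    "bond_token",
    "enumerate_paths",
    "feature_bit",
    "fingerprint",
    "tanimoto",
    "dice",
    "similarity_search",
]

FP_WIDTH = 2040
MAX_PATH_ATOMS = 10

_BOND_SYMBOL = {1: "-", 2: "=", 3: "#"}

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3
_MASK64 = (1 << 64) - 1


def atom_token(element: str, charge: int) -> str:
    """Feature token for one atom: element plus charge suffix when nonzero
    (e.g. "C", "N+", "O-", "Fe+2")."""
    if charge == 0:
        return element
    sign = "+" if charge > 0 else "-"
    magnitude = abs(charge)
    return f"{element}{sign}" if magnitude == 1 else f"{element}{sign}{magnitude}"


def bond_token(order: int) -> str:
    return _BOND_SYMBOL[order]


def _canonical_feature(tokens: list[str]) -> str:
    """Lexicographically smaller of the two read directions."""
    forward = "".join(tokens)
    backward = "".join(reversed(tokens))
    return forward if forward <= backward else backward


def enumerate_paths(mol: MoleculeGraph, max_atoms: int = MAX_PATH_ATOMS) -> set[str]:
    """All canonical path features with 1..max_atoms atoms (set semantics)."""
    if max_atoms < 1:
        raise ValueError("max_atoms must be >= 1")
    atom_tokens = [atom_token(a.element, a.formal_charge) for a in mol.atoms]
    features: set[str] = set(atom_tokens)
    if max_atoms == 1:
        return features

    def extend(path: list[int], tokens: list[str], visited: set[int]) -> None:
        tip = path[-1]
        for nxt, bond in mol.adjacency[tip].items():
            if nxt in visited:
                continue
            tokens.append(bond_token(bond.order))
            tokens.append(atom_tokens[nxt])
            features.add(_canonical_feature(tokens))
            if len(path) + 1 < max_atoms:
                path.append(nxt)
                visited.add(nxt)
                extend(path, tokens, visited)
                visited.remove(nxt)
                path.pop()
            tokens.pop()
            tokens.pop()

    for start in range(mol.n_atoms):
        extend([start], [atom_tokens[start]], {start})
    return features


def feature_bit(feature: str, width: int = FP_WIDTH) -> int:
    """Stable, platform-independent bit index: FNV-1a 64-bit over the UTF-8
    canonical feature string, modulo *width*."""
    if width < 1:
        raise ValueError("width must be >= 1")
    h = _FNV_OFFSET
    for byte in feature.encode("utf-8"):
        h = ((h ^ byte) * _FNV_PRIME) & _MASK64
    return h % width


class BitFingerprint:
    """Fixed-width binary fingerprint backed by a Python int bit set."""

    __slots__ = ("width", "bits")

    def __init__(self, bits: int = 0, width: int = FP_WIDTH):
        self.width = width
        self.bits = bits

    @classmethod
    def from_features(cls, features: Iterable[str], width: int = FP_WIDTH) -> "BitFingerprint":
        bits = 0
        for feature in features:
            bits |= 1 << feature_bit(feature, width)
        return cls(bits, width)

    @classmethod
    def from_indices(cls, indices: Iterable[int], width: int = FP_WIDTH) -> "BitFingerprint":
        bits = 0
        for index in indices:
            if not 0 <= index < width:
                raise ValueError(f"bit index {index} outside [0, {width})")
            bits |= 1 << index
        return cls(bits, width)

    @property
    def popcount(self) -> int:
        return self.bits.bit_count()

    def __len__(self) -> int:
        return self.width

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BitFingerprint)
            and self.width == other.width
            and self.bits == other.bits
        )

    def __hash__(self) -> int:
        return hash((self.width, self.bits))

    def indices(self) -> list[int]:
        return [i for i in range(self.width) if self.bits >> i & 1]

    def contains(self, other: "BitFingerprint") -> bool:
        """True iff every set bit of *other* is set here."""
        return other.bits & ~self.bits == 0

    def to_bytes(self) -> bytes:
        return self.bits.to_bytes((self.width + 7) // 8, "little")

    @classmethod
    def from_bytes(cls, blob: bytes, width: int = FP_WIDTH) -> "BitFingerprint":
        return cls(int.from_bytes(blob, "little"), width)

    def __repr__(self) -> str:  # pragma: no cover
        return f"BitFingerprint(width={self.width}, popcount={self.popcount})"


def fingerprint(
    mol: MoleculeGraph, width: int = FP_WIDTH, max_atoms: int = MAX_PATH_ATOMS
) -> BitFingerprint:
    """Fingerprint one connectivity. Deterministic; error on empty input."""
    if mol.n_atoms == 0:
        raise ValueError("empty connectivity")
    return BitFingerprint.from_features(enumerate_paths(mol, max_atoms), width)


def _check_widths(a: BitFingerprint, b: BitFingerprint) -> None:
    if a.width != b.width:
        raise ValueError(f"fingerprint width mismatch: {a.width} != {b.width}")


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """|A n B| / |A u B|; 1.0 when both vectors are all-zero (identical)."""
    _check_widths(a, b)
    union = (a.bits | b.bits).bit_count()
    if union == 0:
        return 1.0
    return (a.bits & b.bits).bit_count() / union


def dice(a: BitFingerprint, b: BitFingerprint) -> float:
    """2|A n B| / (|A| + |B|); 1.0 when both vectors are all-zero."""
    _check_widths(a, b)
    total = a.popcount + b.popcount
    if total == 0:
        return 1.0
    return 2 * (a.bits & b.bits).bit_count() / total


_COEFFICIENTS = {"tanimoto": tanimoto, "dice": dice}


def similarity_search(
    query: MoleculeGraph,
    db,
    coefficient: str = "tanimoto",
    top_k: Optional[int] = None,
    min_coeff: float = 0.0,
) -> list[tuple[str, int, float]]:
    """Rank database connectivities by similarity to *query*.

    The query fingerprint is computed on the fly; database fingerprints are
    read from the store.  Hits are sorted by coefficient descending, ties by
    refcode then connectivity index, filtered to >= min_coeff and truncated
    to top_k.
    """
    try:
        score = _COEFFICIENTS[coefficient]
    except KeyError:
        raise ValueError(f"unknown coefficient {coefficient!r} (use tanimoto or dice)")
    config = db.config
    qfp = fingerprint(query, width=config.fingerprint_width, max_atoms=config.max_path_atoms)
    hits: list[tuple[str, int, float]] = []
    for refcode, conn_index, fp in db.iter_fingerprints():
        value = score(qfp, fp)
        if value >= min_coeff:
            hits.append((refcode, conn_index, value))
    hits.sort(key=lambda h: (-h[2], h[0], h[1]))
    if top_k is not None:
        hits = hits[:top_k]
    return hits
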