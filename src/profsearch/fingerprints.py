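"""Molecule input and hashed circular (Morgan) fingerprint computation.

This is the only module that touches a chemistry toolkit (RDKit), and RDKit
is imported lazily so that every downstream module can operate on raw binary
vectors from any source — e.g. a precomputed fingerprint file.

Fingerprints are plain ``numpy`` arrays of dtype ``uint8`` with values in
{0, 1}.  All fingerprints in one database must share a single length ``M``
(default 1024).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_LENGTH = 1024
DEFAULT_RADIUS = 2  # ECFP4-equivalent


class ParseError(ValueError):
    """A molecular structure could not be parsed."""


@dataclass
class Molecule:
    """One compound: an opaque id, an optional SMILES, and an activity label.

    ``label`` is interpreted relative to a single activity class at a time
    and is one of ``"active"``, ``"inactive"`` or ``"unknown"``.
    """

    id: str
    smiles: str | None = None
    label: str = "unknown"
    fingerprint: np.ndarray | None = field(default=None, repr=False)


def _require_rdkit():
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - rdkit is an extra
        raise ImportError(
            "RDKit is required to compute fingerprints from structures; "
            "install the 'chem' extra or supply precomputed fingerprints."
        ) from exc
    return Chem, rdFingerprintGenerator


def compute_fingerprint(
    mol: Molecule | str,
    length: int = DEFAULT_LENGTH,
    radius: int = DEFAULT_RADIUS,
) -> np.ndarray:
    """Hashed binary Morgan (circular) fingerprint of one molecule.

    Deterministic: identical structure strings give bit-identical vectors.

    Parameters
    ----------
    mol : Molecule or str
        A molecule with a SMILES structure, or a bare SMILES string.
    length : int
        Number of bits ``M`` in the hashed vector (> 0).
    radius : int
        Morgan environment radius; 2 corresponds to ECFP4.

    Returns
    -------
    numpy.ndarray of uint8, shape (length,)

    Raises
    ------
    ParseError
        If the structure cannot be parsed; the message names the molecule id
        (a silent all-zero vector is never returned).
    """
    if length <= 0:
        raise ValueError(f"fingerprint length must be positive, got {length}")
    if isinstance(mol, str):
        mol = Molecule(id=mol, smiles=mol)
    if mol.smiles is None:
        raise ParseError(f"molecule {mol.id!r} has no structure to fingerprint")
    Chem, rdFingerprintGenerator = _require_rdkit()
    rdmol = Chem.MolFromSmiles(mol.smiles)
    if rdmol is None:
        raise ParseError(f"could not parse SMILES for molecule {mol.id!r}: {mol.smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=length)
    return np.asarray(gen.GetFingerprintAsNumPy(rdmol), dtype=np.uint8)


def read_molecules(path: str | Path, format: str = "smiles", id_prop: str | None = None) -> list[Molecule]:
    """Read molecules from a SMILES or SDF file, preserving input order.

    SMILES files are whitespace-separated ``SMILES id`` per line; ``#``
    comment lines are ignored.  SDF ids come from the title line unless
    ``id_prop`` names a data field.  Per-record parse failures are logged
    and skipped; an empty file yields an empty list with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"molecule file not found: {path}")
    if format == "smiles":
        mols = _read_smiles(path)
    elif format == "sdf":
        mols = _read_sdf(path, id_prop)
    else:
        raise ValueError(f"unknown molecule format: {format!r}")
    if not mols:
        logger.warning("no molecules read from %s", path)
    return mols


def _read_smiles(path: Path) -> list[Molecule]:
    mols: list[Molecule] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"line{lineno}"
            mols.append(Molecule(id=mol_id, smiles=smiles))
    if n_skipped:
        logger.warning("skipped %d unreadable SMILES records in %s", n_skipped, path)
    return mols


def _read_sdf(path: Path, id_prop: str | None) -> list[Molecule]:
    Chem, _ = _require_rdkit()
    mols: list[Molecule] = []
    n_skipped = 0
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, rdmol in enumerate(supplier):
        if rdmol is None:
            n_skipped += 1
            logger.warning("skipping unparseable SDF record %d in %s", i, path)
            continue
        if id_prop is not None and rdmol.HasProp(id_prop):
            mol_id = rdmol.GetProp(id_prop)
        else:
            mol_id = rdmol.GetProp("_Name") or f"record{i}"
        mols.append(Molecule(id=mol_id, smiles=Chem.MolToSmiles(rdmol)))
    if n_skipped:
        logger.warning("skipped %d unparseable SDF records in %s", n_skipped, path)
    return mols


def fingerprint_molecules(
    mols: list[Molecule],
    length: int = DEFAULT_LENGTH,
    radius: int = DEFAULT_RADIUS,
) -> tuple[list[str], np.ndarray]:
    """Fingerprint a list of molecules into an (ids, n×M bit matrix) pair."""
    ids = [m.id for m in mols]
    if not mols:
        return ids, np.zeros((0, length), dtype=np.uint8)
    X = np.stack([compute_fingerprint(m, length=length, radius=radius) for m in mols])
    return ids, X


def read_fingerprints(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a precomputed fingerprint file: ``id<TAB>bitstring`` per line.

    An optional ``#length=M`` header declares the expected length; a database
    mixing lengths is rejected before any search can run.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"fingerprint file not found: {path}")
    ids: list[str] = []
    rows: list[np.ndarray] = []
    declared: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#length="):
                    declared = int(line.split("=", 1)[1])
                continue
            try:
                mol_id, bits = line.split("\t")
            except ValueError:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>bitstring'")
            vec = np.frombuffer(bits.encode("ascii"), dtype=np.uint8) - ord("0")
            if vec.size == 0 or not np.isin(vec, (0, 1)).all():
                raise ValueError(f"{path}:{lineno}: bitstring must be 0/1 characters")
            ids.append(mol_id)
            rows.append(vec)
    if not rows:
        logger.warning("no fingerprints read from %s", path)
        return ids, np.zeros((0, declared or DEFAULT_LENGTH), dtype=np.uint8)
    lengths = {r.size for r in rows}
    if len(lengths) > 1:
        raise ValueError(f"mixed fingerprint lengths in {path}: {sorted(lengths)}")
    M = lengths.pop()
    if declared is not None and declared != M:
        raise ValueError(f"{path}: header declares length {declared} but records have {M}")
    return ids, np.stack(rows).astype(np.uint8)


def write_fingerprints(path: str | Path, ids: list[str], X: np.ndarray) -> None:
    """Write fingerprints in the ``id<TAB>bitstring`` text format."""
    X = np.asarray(X)
    with open(path, "w") as fh:
        fh.write(f"#length={X.shape[1]}\n")
        for mol_id, row in zip(ids, X):
            fh.write(f"{mol_id}\t{''.join('1' if b else '0' for b in row)}\n")


def check_uniform_length(X: np.ndarray) -> int:
    """Return the shared fingerprint length of a 2-D bit matrix."""
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("fingerprint database must be a 2-D matrix")
    return X.shape[1]
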