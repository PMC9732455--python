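"""Core cheminformatics: SMILES handling, descriptors, fingerprints, similarity.

Everything downstream (reverse target fishing, generation metrics,
feasibility scoring, lead-like filtering) goes through this module, so the
conventions fixed here hold package-wide:

* molecular identity is the RDKit canonical SMILES;
* fingerprints are **binary** NumPy vectors (six families, see
  :class:`FingerprintKind`);
* the six bit-vector similarity measures are computed from the closed-form
  set arithmetic on on-bit counts, with explicit conventions for all-zero
  vectors so that batch scoring never produces NaN.

With ``a`` = on-bits of A, ``b`` = on-bits of B, ``c`` = common on-bits:

====================  =========================  ==========
measure               formula                    range
====================  =========================  ==========
Tanimoto              c / (a + b - c)            [0, 1]
Dice                  2c / (a + b)               [0, 1]
Cosine                c / sqrt(ab)               [0, 1]
Sokal                 c / (2a + 2b - 3c)         [0, 1]
Kulczynski            c (a + b) / (2ab)          [0, 1]
McConnaughey          (c (a + b) - ab) / (ab)    [-1, 1]
====================  =========================  ==========
"""

from __future__ import annotations

import csv
import enum
import functools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, MACCSkeys, rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import (
    ConfigurationError,
    InvalidSmilesError,
    SimilarityUndefinedError,
)

# Invalid SMILES are probed routinely (generation-validity metrics), so the
# per-molecule RDKit parse errors would otherwise flood stderr.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

#: Candidate compound designed in this campaign: a 4-(4-tert-butylbenzamido)-
#: 2-(piperidin-3-ylamino)benzamide, a type-I FLT-3 (D835Y) inhibitor.
PCW_A1001_SMILES = "NC(=O)c1ccc(NC(=O)c2ccc(C(C)(C)C)cc2)cc1NC1CCCNC1"

_REFERENCE_FILE = Path(__file__).parent / "data" / "references.smi"


class FingerprintKind(enum.Enum):
    """The six fingerprint families used for reverse target prediction.

    PATH is the path-enumeration topological fingerprint (maxPath 7);
    CIRCULAR / CIRCULAR_FEAT are radius-2 hashed circular fingerprints with
    connectivity / pharmacophoric-feature atom invariants. MACCS166 is the
    fixed 166-key structural-key set; all others hash into ``n_bits``
    positions (default 2048).
    """

    PATH = "path"
    MACCS166 = "maccs166"
    ATOMPAIR = "atompair"
    TORSION = "torsion"
    CIRCULAR = "circular"
    CIRCULAR_FEAT = "circular_feat"


class SimilarityMeasure(enum.Enum):
    TANIMOTO = "tanimoto"
    DICE = "dice"
    SOKAL = "sokal"
    COSINE = "cosine"
    KULCZYNSKI = "kulczynski"
    MCCONNAUGHEY = "mcconnaughey"


DEFAULT_N_BITS = 2048


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse SMILES, raising :class:`InvalidSmilesError` on failure."""
    if not isinstance(smiles, str) or not smiles.strip():
        raise InvalidSmilesError(str(smiles), "empty input")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(smiles)
    return mol


def is_valid_smiles(smiles: str) -> bool:
    return isinstance(smiles, str) and bool(smiles.strip()) and Chem.MolFromSmiles(smiles) is not None


def canonicalize(smiles: str, strip_salts: bool = False) -> str:
    """Return the canonical SMILES for ``smiles``.

    Two inputs describing the same molecule map to the same output and the
    operation is idempotent. With ``strip_salts`` the largest organic
    fragment is kept first (off by default: counterions are retained).
    """
    mol = mol_from_smiles(smiles)
    if strip_salts:
        mol = rdMolStandardize.LargestFragmentChooser().choose(mol)
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class MoleculeRecord:
    """One compound: identifier, canonical SMILES and basic descriptors.

    ``mw`` is the average molecular weight in Da, ``logp`` the Crippen
    octanol-water partition estimate (dimensionless).
    """

    id: str
    smiles_input: str
    smiles_canonical: str
    mw: float
    logp: float

    @classmethod
    def from_smiles(cls, smiles: str, id: str | None = None) -> "MoleculeRecord":
        mol = mol_from_smiles(smiles)
        canonical = Chem.MolToSmiles(mol)
        return cls(
            id=id if id is not None else canonical,
            smiles_input=smiles,
            smiles_canonical=canonical,
            mw=float(Descriptors.MolWt(mol)),
            logp=float(Crippen.MolLogP(mol)),
        )

    def mol(self) -> Chem.Mol:
        return mol_from_smiles(self.smiles_canonical)


@functools.lru_cache(maxsize=None)
def _fp_generator(kind: FingerprintKind, n_bits: int):
    if kind is FingerprintKind.PATH:
        return rdFingerprintGenerator.GetRDKitFPGenerator(maxPath=7, fpSize=n_bits)
    if kind is FingerprintKind.ATOMPAIR:
        return rdFingerprintGenerator.GetAtomPairGenerator(fpSize=n_bits)
    if kind is FingerprintKind.TORSION:
        return rdFingerprintGenerator.GetTopologicalTorsionGenerator(fpSize=n_bits)
    if kind is FingerprintKind.CIRCULAR:
        return rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    if kind is FingerprintKind.CIRCULAR_FEAT:
        return rdFingerprintGenerator.GetMorganGenerator(
            radius=2,
            fpSize=n_bits,
            atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
        )
    raise ConfigurationError(f"unknown fingerprint kind: {kind!r}")


def fingerprint(
    mol: Chem.Mol | MoleculeRecord | str,
    kind: FingerprintKind,
    n_bits: int = DEFAULT_N_BITS,
) -> np.ndarray:
    """Compute one binary fingerprint as a boolean NumPy vector.

    Deterministic for a fixed canonical SMILES and configuration. MACCS166
    has 166 positions; all other kinds ``n_bits``.
    """
    if not isinstance(kind, FingerprintKind):
        raise ConfigurationError(f"unknown fingerprint kind: {kind!r}")
    if isinstance(mol, MoleculeRecord):
        mol = mol.mol()
    elif isinstance(mol, str):
        mol = mol_from_smiles(mol)
    if kind is FingerprintKind.MACCS166:
        bv = MACCSkeys.GenMACCSKeys(mol)
        arr = np.zeros(bv.GetNumBits(), dtype=bool)
        arr[list(bv.GetOnBits())] = True
        return arr[1:]  # RDKit bit 0 is a placeholder; keys are 1..166
    gen = _fp_generator(kind, n_bits)
    return gen.GetFingerprintAsNumPy(mol).astype(bool)


def fingerprint_set(
    mol: Chem.Mol | MoleculeRecord | str, n_bits: int = DEFAULT_N_BITS
) -> dict[FingerprintKind, np.ndarray]:
    """All six fingerprints of one molecule, keyed by kind."""
    if isinstance(mol, MoleculeRecord):
        mol = mol.mol()
    elif isinstance(mol, str):
        mol = mol_from_smiles(mol)
    return {kind: fingerprint(mol, kind, n_bits) for kind in FingerprintKind}


def _counts(fp_a: np.ndarray, fp_b: np.ndarray) -> tuple[int, int, int]:
    if fp_a.shape != fp_b.shape:
        raise ValueError(
            f"fingerprint length mismatch: {fp_a.shape[0]} vs {fp_b.shape[0]}"
        )
    a = int(np.count_nonzero(fp_a))
    b = int(np.count_nonzero(fp_b))
    c = int(np.count_nonzero(np.logical_and(fp_a, fp_b)))
    return a, b, c


def similarity(
    fp_a: np.ndarray, fp_b: np.ndarray, measure: SimilarityMeasure
) -> float:
    """One of the six bit-vector similarity measures (see module docstring).

    Conventions: if either vector has no on-bits the first five measures
    return 0.0; McConnaughey is undefined there and raises
    :class:`SimilarityUndefinedError`.
    """
    a, b, c = _counts(fp_a, fp_b)
    if measure is SimilarityMeasure.MCCONNAUGHEY:
        if a == 0 or b == 0:
            raise SimilarityUndefinedError(
                "McConnaughey similarity undefined for an all-zero fingerprint"
            )
        return (c * (a + b) - a * b) / (a * b)
    if a == 0 or b == 0:
        return 0.0
    if measure is SimilarityMeasure.TANIMOTO:
        return c / (a + b - c)
    if measure is SimilarityMeasure.DICE:
        return 2.0 * c / (a + b)
    if measure is SimilarityMeasure.COSINE:
        return c / math.sqrt(a * b)
    if measure is SimilarityMeasure.SOKAL:
        return c / (2 * a + 2 * b - 3 * c)
    if measure is SimilarityMeasure.KULCZYNSKI:
        return c * (a + b) / (2.0 * a * b)
    raise ConfigurationError(f"unknown similarity measure: {measure!r}")


def maccs_tanimoto(smiles_a: str, smiles_b: str) -> float:
    """MACCS-key Tanimoto similarity between two molecules given as SMILES."""
    fa = fingerprint(smiles_a, FingerprintKind.MACCS166)
    fb = fingerprint(smiles_b, FingerprintKind.MACCS166)
    return similarity(fa, fb, SimilarityMeasure.TANIMOTO)


def load_reference_smiles(name: str) -> str:
    """Look up a named reference structure bundled with the package.

    The bundled table carries structures printed in this package's own
    documentation (e.g. ``PCW-A1001``). External database records that are
    not redistributed here (e.g. ``CHEMBL1807483``) must be supplied by the
    user; requesting one raises :class:`LookupError` explaining how.
    """
    table: dict[str, str] = {}
    if _REFERENCE_FILE.exists():
        for line in _REFERENCE_FILE.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            smiles, _, key = line.partition("\t")
            table[key.strip()] = smiles.strip()
    if name not in table:
        raise LookupError(
            f"reference structure {name!r} is not bundled with molforge "
            f"(available: {sorted(table)}); obtain its SMILES from the source "
            f"database and pass it directly, e.g. maccs_tanimoto(query, smiles)."
        )
    return table[name]


# ---------------------------------------------------------------------------
# readers / writers


def read_smiles_file(path: str | Path) -> list[MoleculeRecord]:
    """Read a SMILES list, one molecule per line, optional tab-separated id.

    Blank lines and ``#`` comments are ignored; unparseable lines raise.
    """
    records = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smiles, _, mol_id = line.partition("\t")
        records.append(
            MoleculeRecord.from_smiles(smiles.strip(), mol_id.strip() or f"mol{i}")
        )
    return records


def read_smiles_csv(path: str | Path) -> list[MoleculeRecord]:
    """Read a CSV with ``id`` and ``smiles`` columns."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"id", "smiles"} <= set(reader.fieldnames):
            raise ConfigurationError(f"{path}: expected columns 'id' and 'smiles'")
        return [MoleculeRecord.from_smiles(row["smiles"], row["id"]) for row in reader]


def read_sdf(path: str | Path) -> list[MoleculeRecord]:
    records = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"
        records.append(MoleculeRecord.from_smiles(Chem.MolToSmiles(mol), name or f"mol{i}"))
    return records


def write_records_csv(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles_canonical", "mw", "logp"])
        for rec in records:
            writer.writerow([rec.id, rec.smiles_canonical, f"{rec.mw:.3f}", f"{rec.logp:.3f}"])


def iter_valid_records(
    smiles_list: Iterable[tuple[str, str]],
) -> Iterator[tuple[MoleculeRecord | None, str, str]]:
    """Yield ``(record_or_None, id, smiles)`` for each ``(id, smiles)`` pair."""
    for mol_id, smiles in smiles_list:
        try:
            yield MoleculeRecord.from_smiles(smiles, mol_id), mol_id, smiles
        except InvalidSmilesError:
            yield None, mol_id, smiles
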