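"""Retrosynthesis-associated fragment-based synthetic feasibility (RAFSF).

A compound is cleaved at synthetically meaningful bonds (BRICS rules,
optionally extended to exocyclic amide C-N bonds). Each resulting fragment
and each broken bond type is looked up in a *fragment space* — occurrence
counts harvested from a reference corpus by the same cleavage — and converted
to a rarity penalty

    p = 1                                        if absent from the space,
    p = 1 - log10(1 + count) / log10(1 + Cmax)   otherwise,

where Cmax is the space's maximum count for that table (fragments and bonds
each use their own Cmax). The RAFSF score is

    score = 1 + 9 * max(p over all fragments and bonds),

so it runs from 1 (every piece is as common as the commonest piece of the
space) to 10 (some piece has never been seen). The max aggregation encodes
that a compound is only as synthesizable as its hardest piece; it is isolated
behind ``aggregate`` so alternatives (mean, percentile) are pluggable.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

from rdkit import Chem
from rdkit.Chem import BRICS

from . import chem
from .errors import ConfigurationError

#: SMARTS for an exocyclic amide C-N single bond (the optional extra cleavage
#: rule); both atoms acyclic so ring lactams are untouched.
_AMIDE_SMARTS = Chem.MolFromSmarts("[C;!R](=O)-[N;!R]")


def fragment_molecule(
    mol: Chem.Mol | str,
    cleave_exocyclic_amides: bool = False,
    erase_attachment_labels: bool = True,
) -> tuple[frozenset[str], frozenset[str]]:
    """Cleave one molecule; return (fragment SMILES set, broken-bond label set).

    Fragments are canonical SMILES with attachment points as dummy atoms;
    with ``erase_attachment_labels`` (default) the BRICS isotope labels are
    erased so every attachment point is the plain ``[*]`` — a coarser match
    that enlarges the effective space. Bond labels are the sorted BRICS
    environment-type pair, e.g. ``"1-5"`` (``"amide-amide"`` for the optional
    extra rule). A molecule with no cleavable bond is returned as its own
    single fragment with no bonds.
    """
    if isinstance(mol, str):
        mol = chem.mol_from_smiles(mol)
    brics_bonds = list(BRICS.FindBRICSBonds(mol))
    bond_atoms = [tuple(sorted(atoms)) for atoms, _ in brics_bonds]
    bond_labels = ["-".join(sorted(labels)) for _, labels in brics_bonds]
    if cleave_exocyclic_amides:
        seen = set(bond_atoms)
        for match in mol.GetSubstructMatches(_AMIDE_SMARTS):
            pair = tuple(sorted((match[0], match[2])))
            if pair not in seen:
                seen.add(pair)
                bond_atoms.append(pair)
                bond_labels.append("amide-amide")
    if not bond_atoms:
        return frozenset({Chem.MolToSmiles(mol)}), frozenset()
    bond_indices = [
        mol.GetBondBetweenAtoms(i, j).GetIdx() for i, j in bond_atoms
    ]
    if erase_attachment_labels:
        broken = Chem.FragmentOnBonds(
            mol, bond_indices, dummyLabels=[(0, 0)] * len(bond_indices)
        )
    else:
        # BRICS environment types as atom-map numbers on the dummies; '7a'/'7b'
        # collapse to 7, 'amide' to 99.
        def _num(lab: str) -> int:
            digits = "".join(ch for ch in lab if ch.isdigit())
            return int(digits) if digits else 99

        broken = Chem.FragmentOnBonds(
            mol,
            bond_indices,
            dummyLabels=[
                tuple(_num(x) for x in lab.split("-")) for lab in bond_labels
            ],
        )
    frags = Chem.GetMolFrags(broken, asMols=True, sanitizeFrags=True)
    frag_smiles = frozenset(Chem.MolToSmiles(f) for f in frags)
    return frag_smiles, frozenset(bond_labels)


@dataclass
class FragmentSpace:
    """Fragment / bond occurrence counts harvested from a reference corpus."""

    fragments: Counter = field(default_factory=Counter)
    bonds: Counter = field(default_factory=Counter)
    n_molecules: int = 0
    corpus_id: str = ""
    cleave_exocyclic_amides: bool = False
    erase_attachment_labels: bool = True

    @property
    def fragment_total(self) -> int:
        return sum(self.fragments.values())

    @property
    def bond_total(self) -> int:
        return sum(self.bonds.values())

    @property
    def max_fragment_count(self) -> int:
        return max(self.fragments.values(), default=0)

    @property
    def max_bond_count(self) -> int:
        return max(self.bonds.values(), default=0)

    def merge(self, other: "FragmentSpace") -> "FragmentSpace":
        """Elementwise sum of two spaces built with the same rule set."""
        if (self.cleave_exocyclic_amides, self.erase_attachment_labels) != (
            other.cleave_exocyclic_amides,
            other.erase_attachment_labels,
        ):
            raise ConfigurationError("cannot merge spaces built with different rules")
        return FragmentSpace(
            fragments=self.fragments + other.fragments,
            bonds=self.bonds + other.bonds,
            n_molecules=self.n_molecules + other.n_molecules,
            corpus_id=f"{self.corpus_id}+{other.corpus_id}",
            cleave_exocyclic_amides=self.cleave_exocyclic_amides,
            erase_attachment_labels=self.erase_attachment_labels,
        )

    def save(self, path: str | Path) -> None:
        """Versioned tab-separated text; self-describing header."""
        lines = [
            "#RAFSF-SPACE\tv1",
            f"#corpus\t{self.corpus_id}",
            f"#n_molecules\t{self.n_molecules}",
            f"#cleave_exocyclic_amides\t{int(self.cleave_exocyclic_amides)}",
            f"#erase_attachment_labels\t{int(self.erase_attachment_labels)}",
            "#FRAGMENTS",
        ]
        lines += [f"{smi}\t{n}" for smi, n in sorted(self.fragments.items())]
        lines.append("#BONDS")
        lines += [f"{lab}\t{n}" for lab, n in sorted(self.bonds.items())]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "FragmentSpace":
        space = cls()
        section = None
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("\t")
                if key == "RAFSF-SPACE" and value != "v1":
                    raise ConfigurationError(f"unsupported space-file version {value!r}")
                elif key == "corpus":
                    space.corpus_id = value
                elif key == "n_molecules":
                    space.n_molecules = int(value)
                elif key == "cleave_exocyclic_amides":
                    space.cleave_exocyclic_amides = bool(int(value))
                elif key == "erase_attachment_labels":
                    space.erase_attachment_labels = bool(int(value))
                elif key in ("FRAGMENTS", "BONDS"):
                    section = key
                continue
            token, _, count = line.rpartition("\t")
            if section == "FRAGMENTS":
                space.fragments[token] = int(count)
            elif section == "BONDS":
                space.bonds[token] = int(count)
        return space


def build_fragment_space(
    corpus: Iterable[str],
    corpus_id: str = "",
    cleave_exocyclic_amides: bool = False,
    erase_attachment_labels: bool = True,
) -> FragmentSpace:
    """Aggregate fragment/bond occurrences over a SMILES corpus.

    Each molecule contributes each of its distinct fragments and bond types
    once (per-molecule sets, corpus-level multiplicity).
    """
    space = FragmentSpace(
        corpus_id=corpus_id,
        cleave_exocyclic_amides=cleave_exocyclic_amides,
        erase_attachment_labels=erase_attachment_labels,
    )
    for smiles in corpus:
        frags, bonds = fragment_molecule(
            smiles,
            cleave_exocyclic_amides=cleave_exocyclic_amides,
            erase_attachment_labels=erase_attachment_labels,
        )
        space.fragments.update(frags)
        space.bonds.update(bonds)
        space.n_molecules += 1
    if space.n_molecules == 0:
        raise ConfigurationError("cannot build a fragment space from an empty corpus")
    return space


@dataclass
class RAFSFResult:
    compound_id: str
    score: float
    details: list[tuple[str, int, float]]  # (fragment or bond label, count, penalty)
    rarest: str

    def __repr__(self):  # keep batch logs readable
        return f"RAFSFResult({self.compound_id!r}, score={self.score:.2f}, rarest={self.rarest!r})"


def _penalty(count: int, cmax: int) -> float:
    if count <= 0 or cmax <= 0:
        return 1.0
    return 1.0 - math.log10(1 + count) / math.log10(1 + cmax)


def rafsf_score(
    mol: Chem.Mol | str,
    space: FragmentSpace,
    compound_id: str | None = None,
    aggregate: Callable[[list[float]], float] = max,
) -> RAFSFResult:
    """Score one compound against a fragment space (1 feasible .. 10 unfeasible)."""
    if space.n_molecules == 0 or not space.fragments:
        raise ConfigurationError("fragment space is empty")
    if isinstance(mol, str):
        smiles = mol
        mol = chem.mol_from_smiles(mol)
    else:
        smiles = Chem.MolToSmiles(mol)
    frags, bonds = fragment_molecule(
        mol,
        cleave_exocyclic_amides=space.cleave_exocyclic_amides,
        erase_attachment_labels=space.erase_attachment_labels,
    )
    details: list[tuple[str, int, float]] = []
    cmax_frag = space.max_fragment_count
    cmax_bond = space.max_bond_count
    for frag in sorted(frags):
        count = space.fragments.get(frag, 0)
        details.append((frag, count, _penalty(count, cmax_frag)))
    for bond in sorted(bonds):
        count = space.bonds.get(bond, 0)
        details.append((bond, count, _penalty(count, cmax_bond)))
    penalties = [p for _, _, p in details]
    rarest = max(details, key=lambda d: d[2])[0]
    score = 1.0 + 9.0 * float(aggregate(penalties))
    return RAFSFResult(
        compound_id=compound_id if compound_id is not None else smiles,
        score=score,
        details=details,
        rarest=rarest,
    )
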