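"""Deterministic synthetic data: corpora, interaction networks, BAR samples.

Everything the package needs for testing and desk-scale demonstration is
generated here from seeds — no downloads. The chemistry is a scaffold x
substituent enumeration over five drug-like two-site templates (amide, urea,
sulfonamide, piperazine amide, aminopyrimidine cores) with twelve common
substituents, giving short, valid, canonical SMILES whose distribution a
small language model can learn in minutes.

The interaction-network generator plants one ground-truth target: that
protein's ligands are single-substituent perturbations of a designated query
compound, while every other protein receives decoys from unrelated
scaffolds. Recovery of the planted protein at the top of the modified total
rank score is the package's stand-in for retrospective target-fishing
validation against real bioactivity databases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from . import chem
from .bar import WorkSamples

#: Two-site scaffold templates; {R1}/{R2} are substitution points.
DEFAULT_SCAFFOLDS: tuple[str, ...] = (
    "O=C(Nc1ccc({R1})cc1)c1ccc({R2})cc1",        # benzanilide
    "O=C(Nc1ccc({R1})cc1)Nc1ccc({R2})cc1",       # diaryl urea
    "O=S(=O)(c1ccc({R1})cc1)Nc1ccc({R2})cc1",    # sulfonanilide
    "O=C(c1ccc({R1})cc1)N1CCN(c2ccc({R2})cc2)CC1",  # piperazine benzamide
    "c1cc({R2})ccc1Nc1nccc({R1})n1",             # 2-anilinopyrimidine
)

DEFAULT_SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "O", "N", "F", "Cl", "OC", "C(C)C", "C#N", "C(F)(F)F", "CO", "N(C)C",
)


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic generators (all seed-deterministic)."""

    scaffolds: tuple[str, ...] = DEFAULT_SCAFFOLDS
    substituents: tuple[str, ...] = DEFAULT_SUBSTITUENTS
    corpus_size: int = 500
    n_proteins: int = 10
    ligands_per_protein: int = 5
    perturbation_rate: float = 1.0
    seed: int = 0
    query_scaffold: str = field(default=DEFAULT_SCAFFOLDS[0])
    query_substituents: tuple[str, str] = ("C(C)C", "Cl")


def _instantiate(template: str, r1: str, r2: str) -> str | None:
    smiles = template.replace("{R1}", r1).replace("{R2}", r2)
    if not chem.is_valid_smiles(smiles):
        return None
    return chem.canonicalize(smiles)


def generate_corpus(spec: FixtureSpec | None = None, **overrides) -> list[str]:
    """Enumerate scaffold x substituent combinations into a canonical corpus.

    Combinations are visited in a seed-shuffled deterministic order;
    duplicates (e.g. from symmetric scaffolds) are dropped; exactly
    ``corpus_size`` unique valid SMILES are returned or a ValueError is
    raised if the template space is too small.
    """
    spec = _resolve(spec, overrides)
    if spec.corpus_size < 1:
        raise ValueError("corpus_size must be >= 1")
    for scaffold in spec.scaffolds:
        if "{R1}" not in scaffold and "{R2}" not in scaffold:
            raise ValueError(f"scaffold without substitution point: {scaffold!r}")
    combos = list(product(spec.scaffolds, spec.substituents, spec.substituents))
    rng = np.random.default_rng(spec.seed)
    rng.shuffle(combos)
    corpus: list[str] = []
    seen: set[str] = set()
    for scaffold, r1, r2 in combos:
        smiles = _instantiate(scaffold, r1, r2)
        if smiles is None or smiles in seen:
            continue
        seen.add(smiles)
        corpus.append(smiles)
        if len(corpus) == spec.corpus_size:
            return corpus
    raise ValueError(
        f"template space exhausted at {len(corpus)} molecules "
        f"(requested {spec.corpus_size})"
    )


def query_compound(spec: FixtureSpec | None = None, **overrides) -> str:
    """The designated query compound of a fixture spec (canonical SMILES)."""
    spec = _resolve(spec, overrides)
    smiles = _instantiate(spec.query_scaffold, *spec.query_substituents)
    if smiles is None:
        raise ValueError("query scaffold/substituent combination is invalid")
    return smiles


def generate_network(
    spec: FixtureSpec | None = None, **overrides
) -> tuple[pd.DataFrame, str, str]:
    """Interaction table with one planted target.

    Returns ``(table, planted_protein_id, query_smiles)``. The planted
    protein's ligands are copies of the query with (at rate
    ``perturbation_rate``) one substituent swapped; decoy proteins draw
    ligands from the other scaffolds.
    """
    spec = _resolve(spec, overrides)
    if spec.n_proteins < 2:
        raise ValueError("need at least 2 proteins")
    rng = np.random.default_rng(spec.seed)
    query = query_compound(spec)
    decoy_scaffolds = [s for s in spec.scaffolds if s != spec.query_scaffold] or list(
        spec.scaffolds
    )
    planted = "P000"
    rows = []
    lig_counter = 0
    for p in range(spec.n_proteins):
        protein_id = f"P{p:03d}"
        for _ in range(spec.ligands_per_protein):
            if protein_id == planted:
                r1, r2 = spec.query_substituents
                if rng.random() < spec.perturbation_rate:
                    site = rng.integers(0, 2)
                    choices = [s for s in spec.substituents if s not in (r1, r2)]
                    new_sub = choices[rng.integers(0, len(choices))]
                    r1, r2 = (new_sub, r2) if site == 0 else (r1, new_sub)
                smiles = _instantiate(spec.query_scaffold, r1, r2)
            else:
                scaffold = decoy_scaffolds[rng.integers(0, len(decoy_scaffolds))]
                r1 = spec.substituents[rng.integers(0, len(spec.substituents))]
                r2 = spec.substituents[rng.integers(0, len(spec.substituents))]
                smiles = _instantiate(scaffold, r1, r2)
            if smiles is None:  # pragma: no cover - templates are pre-validated
                continue
            rows.append(
                {
                    "protein_id": protein_id,
                    "ligand_id": f"L{lig_counter:04d}",
                    "smiles": smiles,
                }
            )
            lig_counter += 1
    return pd.DataFrame(rows), planted, query


def generate_work_samples(
    delta_g: float,
    sigma2: float,
    n: int,
    beta: float = 1.0,
    seed: int = 0,
) -> tuple[WorkSamples, float]:
    """Crooks-consistent Gaussian forward/backward energy-difference samples.

    Forward dU ~ N(dG + beta sigma^2 / 2, sigma^2) in ensemble i and backward
    dU ~ N(-dG + beta sigma^2 / 2, sigma^2) in ensemble j satisfy the Crooks
    relation p_i(dU) / p_j(-dU) = exp(beta (dU - dG)) exactly, so the BAR
    root converges to ``delta_g``. Returns ``(samples, ground_truth)``.
    """
    if not sigma2 > 0:
        raise ValueError("sigma2 must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sd = float(np.sqrt(sigma2))
    shift = beta * sigma2 / 2.0
    forward = rng.normal(delta_g + shift, sd, n)
    backward = -(rng.normal(-delta_g + shift, sd, n))
    # ``backward`` stores dU = U_j - U_i as sampled in ensemble j: the draw
    # above is for -dU, hence the negation.
    return WorkSamples(forward, backward, beta), float(delta_g)


def _resolve(spec: FixtureSpec | None, overrides: dict) -> FixtureSpec:
    if spec is None:
        spec = FixtureSpec()
    if overrides:
        spec = FixtureSpec(**{**spec.__dict__, **overrides})
    return spec
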