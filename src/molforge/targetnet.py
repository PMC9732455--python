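"""Network-based reverse target prediction.

A query compound is scored against every ligand of a bipartite protein-ligand
interaction network with six fingerprint families x six similarity measures.
The highest-scoring ligands propagate their per-fingerprint similarity scores
to the proteins they bind; within each fingerprint, proteins are ranked and
each receives a normalized rank score

    rank score = rank value / sum(rank values),

where the rank value runs from N (most similar) down to 1. Summing rank
scores over the six fingerprints gives a protein total R, and dividing by the
best total gives the modified total rank score R~ = R / Rmax in (0, 1] — the
final target-likelihood ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem
from .chem import FingerprintKind, MoleculeRecord, SimilarityMeasure
from .errors import EmptyNetworkError, SimilarityUndefinedError

logger = logging.getLogger(__name__)


@dataclass
class InteractionNetwork:
    """Bipartite protein-ligand graph with per-ligand fingerprints cached.

    Ligands are deduplicated by canonical SMILES at construction; every
    ligand has at least one edge and a full six-kind fingerprint set.
    """

    proteins: set[str]
    ligands: dict[str, MoleculeRecord]
    fingerprints: dict[str, dict[FingerprintKind, np.ndarray]]
    edges: set[tuple[str, str]]  # (protein id, ligand id)
    n_skipped_rows: int = 0

    def ligands_of(self, protein: str) -> set[str]:
        return {lig for prot, lig in self.edges if prot == protein}

    def proteins_of(self, ligand: str) -> set[str]:
        return {prot for prot, lig in self.edges if lig == ligand}


@dataclass
class DrugSimilarityScore:
    """Similarity of the query to one network ligand.

    ``per_fingerprint[kind]`` is the sum over the six measures of the
    query-ligand similarity under that fingerprint; ``total`` sums the six
    fingerprints (36 measure values in all).
    """

    ligand_id: str
    per_fingerprint: dict[FingerprintKind, float]
    total: float = field(init=False)

    def __post_init__(self):
        self.total = float(sum(self.per_fingerprint.values()))


@dataclass
class ProteinRankTable:
    """Per-fingerprint protein scores/ranks and the aggregate R, R~ table.

    ``per_fingerprint[kind]`` is a DataFrame indexed by protein id with
    columns ``score``, ``rank_value``, ``rank_score``; ``totals`` has columns
    ``R``, ``R_tilde``, ``rank`` sorted by R~ descending.
    """

    per_fingerprint: dict[FingerprintKind, pd.DataFrame]
    totals: pd.DataFrame

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.totals.head(n)


def build_network(
    table: pd.DataFrame | str | Path, n_bits: int = chem.DEFAULT_N_BITS
) -> InteractionNetwork:
    """Build an :class:`InteractionNetwork` from an interaction table.

    ``table`` is a DataFrame (or CSV path) with columns ``protein_id``,
    ``ligand_id``, ``smiles``. Invalid-SMILES rows are logged and skipped;
    ligands are deduplicated by canonical SMILES (the lexicographically
    smallest ligand id becomes the representative); duplicate
    (protein, ligand) pairs collapse to a single edge.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, dtype=str)
    required = {"protein_id", "ligand_id", "smiles"}
    if not required <= set(table.columns):
        raise EmptyNetworkError(
            f"interaction table must have columns {sorted(required)}"
        )
    if len(table) == 0:
        raise EmptyNetworkError("interaction table is empty")

    by_canonical: dict[str, str] = {}  # canonical smiles -> representative ligand id
    ligands: dict[str, MoleculeRecord] = {}
    edges: set[tuple[str, str]] = set()
    n_skipped = 0
    rows = sorted(
        table.itertuples(index=False), key=lambda r: (str(r.ligand_id), str(r.protein_id))
    )
    for row in rows:
        try:
            rec = MoleculeRecord.from_smiles(str(row.smiles), str(row.ligand_id))
        except chem.InvalidSmilesError:
            n_skipped += 1
            logger.warning("skipping invalid SMILES for ligand %s", row.ligand_id)
            continue
        rep = by_canonical.setdefault(rec.smiles_canonical, rec.id)
        if rep == rec.id and rep not in ligands:
            ligands[rep] = rec
        edges.add((str(row.protein_id), rep))
    if not ligands:
        raise EmptyNetworkError(
            f"no valid interaction rows (skipped {n_skipped} invalid rows)"
        )
    fingerprints = {
        lig_id: chem.fingerprint_set(rec.mol(), n_bits) for lig_id, rec in ligands.items()
    }
    proteins = {prot for prot, _ in edges}
    if n_skipped:
        logger.info("network built with %d rows skipped", n_skipped)
    return InteractionNetwork(
        proteins=proteins,
        ligands=ligands,
        fingerprints=fingerprints,
        edges=edges,
        n_skipped_rows=n_skipped,
    )


def _sum_six_measures(fp_q: np.ndarray, fp_l: np.ndarray) -> float:
    """Sum of the six similarity measures for one fingerprint pair.

    An undefined McConnaughey term (all-zero vector on either side, e.g. the
    torsion fingerprint of a torsion-free molecule) contributes 0 here so
    batch scoring stays NaN-free; direct ``chem.similarity`` calls still
    raise in that case.
    """
    total = 0.0
    for measure in SimilarityMeasure:
        try:
            total += chem.similarity(fp_q, fp_l, measure)
        except SimilarityUndefinedError:
            pass
    return total


def score_query(
    query: MoleculeRecord | str, net: InteractionNetwork
) -> list[DrugSimilarityScore]:
    """Score the query against every network ligand (one record per ligand)."""
    if not net.ligands:
        raise EmptyNetworkError("cannot score against an empty network")
    if isinstance(query, str):
        query = MoleculeRecord.from_smiles(query, "query")
    n_bits = next(
        len(fps[FingerprintKind.PATH]) for fps in net.fingerprints.values()
    )
    query_fps = chem.fingerprint_set(query.mol(), n_bits)
    scores = []
    for lig_id in sorted(net.ligands):
        lig_fps = net.fingerprints[lig_id]
        per_fp = {
            kind: _sum_six_measures(query_fps[kind], lig_fps[kind])
            for kind in FingerprintKind
        }
        scores.append(DrugSimilarityScore(ligand_id=lig_id, per_fingerprint=per_fp))
    return scores


def select_drugs(
    scores: list[DrugSimilarityScore], top_k: int = 100
) -> list[DrugSimilarityScore]:
    """The ``top_k`` ligands by total similarity score.

    Ties at the cut are broken by lexicographic ligand id. Asking for more
    ligands than exist returns all of them (with a warning).
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if top_k > len(scores):
        logger.warning(
            "top_k=%d exceeds the %d network ligands; selecting all", top_k, len(scores)
        )
        top_k = len(scores)
    ordered = sorted(scores, key=lambda s: (-s.total, s.ligand_id))
    return ordered[:top_k]


def rank_proteins(
    net: InteractionNetwork, selected: list[DrugSimilarityScore]
) -> ProteinRankTable:
    """Propagate selected-drug scores to proteins and build the rank table.

    Per fingerprint: a protein's similarity score is the sum of the scores of
    the selected drugs it is connected to; proteins are sorted descending
    (ties broken by lexicographic protein id, logged) and assigned integer
    rank values N..1, then normalized rank scores summing to 1. R sums the
    six rank scores, and R~ = R / Rmax.
    """
    if not selected:
        raise EmptyNetworkError("no selected drugs to rank proteins from")
    connected: dict[str, list[DrugSimilarityScore]] = {}
    for drug in selected:
        for prot in net.proteins_of(drug.ligand_id):
            connected.setdefault(prot, []).append(drug)
    if not connected:
        raise EmptyNetworkError("no protein is connected to any selected drug")

    proteins = sorted(connected)
    n = len(proteins)
    rank_value_sum = n * (n + 1) // 2
    per_fingerprint: dict[FingerprintKind, pd.DataFrame] = {}
    r_total = pd.Series(0.0, index=proteins)
    for kind in FingerprintKind:
        score = pd.Series(
            {
                prot: sum(d.per_fingerprint[kind] for d in connected[prot])
                for prot in proteins
            }
        )
        order = sorted(proteins, key=lambda p: (-score[p], p))
        if len({score[p] for p in proteins}) < n:
            logger.info(
                "tied protein scores under %s broken lexicographically", kind.value
            )
        rank_value = pd.Series(
            {prot: n - i for i, prot in enumerate(order)}, dtype=int
        )
        rank_score = rank_value / rank_value_sum
        per_fingerprint[kind] = pd.DataFrame(
            {"score": score, "rank_value": rank_value, "rank_score": rank_score}
        ).loc[order]
        r_total += rank_score
    r_tilde = r_total / r_total.max()
    order = sorted(proteins, key=lambda p: (-r_tilde[p], p))
    totals = pd.DataFrame({"R": r_total, "R_tilde": r_tilde}).loc[order]
    totals["rank"] = np.arange(1, n + 1)
    return ProteinRankTable(per_fingerprint=per_fingerprint, totals=totals)


def predict_targets(
    query: MoleculeRecord | str,
    net: InteractionNetwork,
    top_k: int = 100,
) -> ProteinRankTable:
    """End-to-end reverse target prediction for one query compound."""
    scores = score_query(query, net)
    selected = select_drugs(scores, top_k=top_k)
    return rank_proteins(net, selected)


def write_rank_table(table: ProteinRankTable, path: str | Path) -> None:
    out = table.totals.reset_index(names="protein_id")
    out.to_csv(path, index=False, float_format="%.10g")
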