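"""Chemical-space and memorization analysis.

Quantifies how similar evaluated ligands are to each other and to a training
corpus: ECFP4 (Morgan radius-2, 2048-bit) Tanimoto similarity, maximum
common substructure percentage (MCS%), nearest pre-cutoff training neighbor,
greedy best-first clustering of chemotypes, and a 2-D PCA embedding of the
pairwise-similarity feature space.

MCS% uses element-exact atom matching, bond-order-insensitive bond matching
and ring-atoms-match-ring-atoms, with the shared heavy-atom count expressed
against the larger of the two molecules (symmetric, never above 100).
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem, DataStructs, RDLogger
from rdkit.Chem import rdFMCS, rdFingerprintGenerator
from sklearn.decomposition import PCA

RDLogger.DisableLog("rdApp.*")
logger = logging.getLogger(__name__)

FINGERPRINT_BITS = 2048
_FPGEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=FINGERPRINT_BITS)


class ChemspaceError(Exception):
    pass


@dataclass
class ChemRecord:
    ligand_id: str
    smiles: str                 # canonical
    heavy_atom_count: int
    fingerprint: DataStructs.ExplicitBitVect
    deposit_date: _dt.date | None = None
    scaffold_id: int | None = None  # planted membership, synthetic libraries only

    _mol: Chem.Mol | None = None

    @property
    def mol(self) -> Chem.Mol:
        if self._mol is None:
            self._mol = Chem.MolFromSmiles(self.smiles)
        return self._mol


def make_record(ligand_id: str, smiles: str,
                deposit_date: _dt.date | str | None = None,
                scaffold_id: int | None = None) -> ChemRecord:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemspaceError(f"{ligand_id}: SMILES does not parse: {smiles!r}")
    if isinstance(deposit_date, str):
        deposit_date = _dt.date.fromisoformat(deposit_date)
    return ChemRecord(
        ligand_id=ligand_id,
        smiles=Chem.MolToSmiles(mol),
        heavy_atom_count=mol.GetNumHeavyAtoms(),
        fingerprint=_FPGEN.GetFingerprint(mol),
        deposit_date=deposit_date,
        scaffold_id=scaffold_id,
        _mol=mol,
    )


def tanimoto(a: ChemRecord, b: ChemRecord) -> float:
    """Tanimoto coefficient |A∩B|/|A∪B| over fingerprint on-bits."""
    if a.fingerprint.GetNumOnBits() == 0 and b.fingerprint.GetNumOnBits() == 0:
        logger.warning("both fingerprints empty (%s, %s); Tc defined as 0",
                       a.ligand_id, b.ligand_id)
        return 0.0
    return float(DataStructs.TanimotoSimilarity(a.fingerprint, b.fingerprint))


_MCS_PARAMS = dict(
    atomCompare=rdFMCS.AtomCompare.CompareElements,
    bondCompare=rdFMCS.BondCompare.CompareAny,
    ringMatchesRingOnly=True,
)


def mcs_percent(a: ChemRecord, b: ChemRecord, timeout: float = 10.0) -> float:
    """Maximum-common-substructure size as % of the larger molecule's heavy atoms."""
    res = rdFMCS.FindMCS([a.mol, b.mol], timeout=int(timeout), **_MCS_PARAMS)
    if res.canceled:
        logger.warning("MCS timed out for (%s, %s); best-so-far reported",
                       a.ligand_id, b.ligand_id)
    if res.numAtoms == 0:
        logger.debug("MCS of size 0 for (%s, %s)", a.ligand_id, b.ligand_id)
        return 0.0
    denom = max(a.heavy_atom_count, b.heavy_atom_count)
    return 100.0 * res.numAtoms / denom


@dataclass
class SimilarityAnnotation:
    best_tc: float
    best_tc_partner_id: str
    best_mcs_pct: float
    best_mcs_partner_id: str
    cutoff_date_used: _dt.date | None


def nearest_training(query: ChemRecord, training: list[ChemRecord],
                     cutoff_date: _dt.date | str | None = None,
                     mcs_timeout: float = 10.0) -> SimilarityAnnotation:
    """Most similar pre-cutoff training compound by Tc and, separately, MCS%.

    Ties are broken by lexicographic partner id so the result is deterministic
    and independent of training-set order.
    """
    if isinstance(cutoff_date, str):
        cutoff_date = _dt.date.fromisoformat(cutoff_date)
    pool = [t for t in training
            if cutoff_date is None
            or (t.deposit_date is not None and t.deposit_date < cutoff_date)]
    if not pool:
        raise ChemspaceError(
            f"no training compounds deposited before cutoff {cutoff_date}")
    best_tc = max(pool, key=lambda t: (tanimoto(query, t), _neg_id(t)))
    best_mcs = max(pool, key=lambda t: (mcs_percent(query, t, mcs_timeout), _neg_id(t)))
    return SimilarityAnnotation(
        best_tc=tanimoto(query, best_tc),
        best_tc_partner_id=best_tc.ligand_id,
        best_mcs_pct=mcs_percent(query, best_mcs, mcs_timeout),
        best_mcs_partner_id=best_mcs.ligand_id,
        cutoff_date_used=cutoff_date,
    )


class _neg_id:
    """Reverse-lexicographic id wrapper so max() prefers the smaller id on ties."""

    def __init__(self, rec: ChemRecord):
        self.id = rec.ligand_id

    def __lt__(self, other: "_neg_id") -> bool:
        return self.id > other.id

    def __eq__(self, other) -> bool:
        return self.id == other.id


# ---------------------------------------------------------------------------
# pairwise matrices, clustering, embedding
# ---------------------------------------------------------------------------

def pairwise_tanimoto(records: list[ChemRecord]) -> np.ndarray:
    n = len(records)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = tanimoto(records[i], records[j])
    return out


def pairwise_mcs(records: list[ChemRecord], timeout: float = 10.0) -> np.ndarray:
    n = len(records)
    out = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = mcs_percent(records[i], records[j], timeout)
    return out


@dataclass
class Cluster:
    head: int
    members: list[int]


def best_first_cluster(similarity: np.ndarray, threshold: float,
                       higher_is_similar: bool = True) -> list[Cluster]:
    """Greedy best-first clustering of a pairwise similarity matrix.

    Repeatedly the unassigned item with the most unassigned above-threshold
    neighbors becomes a cluster head and absorbs those neighbors; ties go to
    the lowest index. Every item ends up in exactly one cluster.
    """
    sim = np.asarray(similarity, dtype=float)
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise ChemspaceError("similarity matrix must be square")
    if not np.allclose(sim, sim.T, atol=1e-8, equal_nan=True):
        raise ChemspaceError("similarity matrix must be symmetric")
    n = sim.shape[0]
    above = sim > threshold if higher_is_similar else sim < threshold
    np.fill_diagonal(above, False)
    unassigned = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while unassigned.any():
        counts = (above & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        head = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(above[head] & unassigned)
        clusters.append(Cluster(head=head, members=[head, *members.tolist()]))
        unassigned[head] = False
        unassigned[members] = False
    return clusters


def pca_embed(mcs_matrix: np.ndarray, tc_matrix: np.ndarray) -> np.ndarray:
    """2-D PCA embedding of the concatenated pairwise-similarity features.

    Per-ligand feature rows are the concatenation of that ligand's MCS% and
    Tc matrix rows, column-standardized. The sign convention makes the
    largest-magnitude loading of each component positive. A rank-deficient
    input degrades to a 1-D embedding with a warning.
    """
    X = np.hstack([np.asarray(mcs_matrix, float), np.asarray(tc_matrix, float)])
    if X.shape[0] < 3:
        raise ChemspaceError("need at least 3 items for an embedding")
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = X / sd
    rank = np.linalg.matrix_rank(X)
    n_comp = 2 if rank >= 2 else 1
    if n_comp == 1:
        logger.warning("feature matrix rank < 2; 1-D embedding returned")
    pca = PCA(n_components=n_comp, svd_solver="full")
    Y = pca.fit_transform(X)
    for k in range(n_comp):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            Y[:, k] *= -1
    return Y
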