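"""Synthetic fixtures with controlled statistical structure.

Every pipeline stage is testable without external data: an idealized rigid
receptor with a defined pocket, scaffold-structured ligand libraries with a
known clustering answer, predicted poses perturbed from reference poses to
exact target RMSDs, confidence scores with a controlled correlation to pose
error, affinity predictions with planted slope/intercept/noise, and
active/decoy hit lists with a planted score separation.

All generators are seed-deterministic: the same seed yields bit-identical
output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

from .chemspace import ChemRecord, make_record, mcs_percent
from .complex_io import Atom, ComplexStructure

RDLogger.DisableLog("rdApp.*")
logger = logging.getLogger(__name__)


class SyntheticDataError(Exception):
    pass


# ---------------------------------------------------------------------------
# receptor
# ---------------------------------------------------------------------------

@dataclass
class ReceptorSpec:
    n_residues: int = 140
    start_resnum: int = 20       # covers residues 22..157 used by pose logic
    chain: str = "A"
    jitter_sd: float = 0.05      # Å, seeded coordinate jitter

    #: residues named so pocket-state and H-bond logic is exercised
    special_names: dict[int, str] = field(default_factory=lambda: {
        22: "ASP", 23: "ILE", 129: "ALA", 130: "GLY", 156: "PHE", 157: "ASP"})


def make_receptor(spec: ReceptorSpec = ReceptorSpec(), seed: int = 0) -> ComplexStructure:
    """Idealized helical Cα trace with N/CA/C/O backbone atoms.

    Residue numbering starts at ``start_resnum`` so the Mac1-style residues of
    interest (22, 23, 129, 130, 156, 157) exist under their conventional
    author numbers.
    """
    if spec.n_residues < 5:
        raise SyntheticDataError("need at least 5 residues")
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    radius, twist, rise = 2.3, math.radians(100.0), 1.5
    for i in range(spec.n_residues):
        resnum = spec.start_resnum + i
        name = spec.special_names.get(resnum, "ALA")
        th = i * twist
        ca = np.array([radius * math.cos(th), radius * math.sin(th), i * rise])
        th_prev, th_next = (i - 0.35) * twist, (i + 0.35) * twist
        n_at = np.array([radius * math.cos(th_prev), radius * math.sin(th_prev),
                         (i - 0.35) * rise])
        c_at = np.array([radius * math.cos(th_next), radius * math.sin(th_next),
                         (i + 0.35) * rise])
        # carbonyl O ~1.23 Å from C, pointing away from the helix axis
        out_dir = np.array([math.cos(th_next), math.sin(th_next), 0.0])
        o_at = c_at + 1.23 * out_dir
        for atom_name, el, xyz in (("N", "N", n_at), ("CA", "C", ca),
                                   ("C", "C", c_at), ("O", "O", o_at)):
            xyz = xyz + rng.normal(0.0, spec.jitter_sd, 3)
            atoms.append(Atom("protein", spec.chain, name, resnum, atom_name,
                              el, tuple(float(v) for v in xyz)))
    return ComplexStructure(atoms, None, "mmCIF", None)


def pocket_center(receptor: ComplexStructure, offset: float = 8.0) -> np.ndarray:
    """A pocket-like point offset radially from the receptor midpoint."""
    ca = np.array(list(receptor.ca_map().values()))
    mid = ca.mean(axis=0)
    return mid + np.array([offset, 0.0, 0.0])


# ---------------------------------------------------------------------------
# ligand library with planted scaffolds
# ---------------------------------------------------------------------------

#: Chemically disjoint cores; each scaffold decorates with its own signature
#: substituent elements (disjoint across scaffolds) so between-scaffold common
#: substructures stay small by construction.
SCAFFOLD_CORES: list[tuple[str, tuple[str, ...]]] = [
    ("c1ncc2[nH]cnc2n1", ("F", "I")),   # N-rich fused aromatic (purine-like)
    ("c1ccc2ccccc2c1", ("Cl", "Br")),   # all-carbon fused aromatic
    ("CC1COS(=O)(=O)CC1", ("O",)),      # cyclic sulfone ether, aliphatic ring
    ("CC(C)CC(=O)NC(C)C", ("N",)),      # acyclic branched amide
]


@dataclass
class LibrarySpec:
    n_ligands: int = 40
    n_scaffolds: int = 4
    substituents_range: tuple[int, int] = (1, 3)
    mcs_threshold: float = 35.0
    max_retries: int = 50


def _decorate(core: Chem.Mol, sub_elements: tuple[str, ...], n_subs: int,
              rng: np.random.Generator) -> str | None:
    """Attach ``n_subs`` single-atom substituents at random C-H positions."""
    rw = Chem.RWMol(core)
    sites = [a.GetIdx() for a in rw.GetAtoms()
             if a.GetSymbol() == "C" and a.GetTotalNumHs() > 0]
    if len(sites) < n_subs:
        n_subs = len(sites)
    chosen = rng.choice(len(sites), size=n_subs, replace=False)
    for si in chosen:
        el = sub_elements[int(rng.integers(len(sub_elements)))]
        new_idx = rw.AddAtom(Chem.Atom(el))
        rw.AddBond(int(sites[int(si)]), new_idx, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return Chem.MolToSmiles(mol)


def make_ligand_library(spec: LibrarySpec = LibrarySpec(),
                        seed: int = 0) -> list[ChemRecord]:
    """Ligand library built from ``n_scaffolds`` cores with planted membership.

    By construction, within-scaffold MCS% exceeds the clustering threshold and
    between-scaffold MCS% stays below it; the constraint is verified on the
    generated set and violating molecules are regenerated (bounded retries).
    """
    if not 1 <= spec.n_scaffolds <= len(SCAFFOLD_CORES):
        raise SyntheticDataError(
            f"n_scaffolds must be in [1, {len(SCAFFOLD_CORES)}]")
    rng = np.random.default_rng(seed)
    cores = SCAFFOLD_CORES[: spec.n_scaffolds]
    per = [spec.n_ligands // spec.n_scaffolds] * spec.n_scaffolds
    for i in range(spec.n_ligands % spec.n_scaffolds):
        per[i] += 1

    records: list[ChemRecord] = []
    for s, ((core_smiles, sub_els), count) in enumerate(zip(cores, per)):
        core = Chem.MolFromSmiles(core_smiles)
        seen: set[str] = set()
        made = 0
        attempts = 0
        while made < count:
            if attempts > spec.max_retries * count:
                raise SyntheticDataError(
                    f"scaffold {s}: cannot generate {count} distinct ligands")
            attempts += 1
            n_subs = int(rng.integers(spec.substituents_range[0],
                                      spec.substituents_range[1] + 1))
            smi = _decorate(core, sub_els, n_subs, rng)
            if smi is None or smi in seen:
                continue
            rec = make_record(f"lig-s{s}-{made:03d}", smi, scaffold_id=s)
            # verify the planted structure against already-generated records
            ok = True
            for other in records:
                pct = mcs_percent(rec, other, timeout=10)
                same = other.scaffold_id == s
                if same and pct <= spec.mcs_threshold:
                    ok = False
                    break
                if not same and pct >= spec.mcs_threshold:
                    ok = False
                    break
            if not ok:
                continue
            seen.add(smi)
            records.append(rec)
            made += 1
    return records


# ---------------------------------------------------------------------------
# poses
# ---------------------------------------------------------------------------

def embed_ligand(smiles: str, seed: int = 0) -> tuple[list[str], np.ndarray]:
    """3-D embed a SMILES; returns heavy-atom elements and coordinates."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SyntheticDataError(f"SMILES does not parse: {smiles!r}")
    molh = Chem.AddHs(mol)
    if AllChem.EmbedMolecule(molh, randomSeed=int(seed) & 0x7FFFFFFF) != 0:
        raise SyntheticDataError(f"embedding failed for {smiles!r}")
    AllChem.MMFFOptimizeMolecule(molh, maxIters=200)
    molh = Chem.RemoveHs(molh)
    conf = molh.GetConformer()
    els = [a.GetSymbol() for a in molh.GetAtoms()]
    xyz = np.array([list(conf.GetAtomPosition(i)) for i in range(molh.GetNumAtoms())])
    return els, xyz


def perturb_pose(coords: np.ndarray, target_rmsd: float, seed: int = 0,
                 mode: str = "jitter") -> np.ndarray:
    """Perturb a reference pose to an exact identity-map heavy-atom RMSD.

    Modes:

    * ``jitter`` — i.i.d. Gaussian per-atom displacements rescaled so the
      RMSD equals ``target_rmsd`` exactly (within 1e-9);
    * ``translate`` — rigid shift of magnitude ``target_rmsd`` in a random
      direction (COM distance equals the target exactly);
    * ``rigid`` — random rotation about the centroid combined with a
      translation solved in closed form so the total RMSD is exact while the
      internal geometry (and hence chemistry perception) is preserved.
    """
    coords = np.asarray(coords, dtype=float)
    if target_rmsd < 0:
        raise SyntheticDataError("target RMSD must be nonnegative")
    if target_rmsd == 0:
        return coords.copy()
    rng = np.random.default_rng(seed)
    if mode == "jitter":
        d = rng.normal(size=coords.shape)
        scale = target_rmsd / math.sqrt(float(np.mean(np.sum(d * d, axis=1))))
        return coords + scale * d
    if mode == "translate":
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        return coords + target_rmsd * u
    if mode == "rigid":
        center = coords.mean(axis=0)
        x = coords - center
        # rotation small enough that its own RMSD stays below the target
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(0.05, 0.5)
        for _ in range(60):
            K = np.array([[0, -axis[2], axis[1]],
                          [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            R = np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * K @ K
            rot_rmsd2 = float(np.mean(np.sum((x @ R.T - x) ** 2, axis=1)))
            if rot_rmsd2 <= target_rmsd ** 2 * 0.49:
                break
            angle *= 0.5
        else:
            R = np.eye(3)
            rot_rmsd2 = 0.0
        # centered rotation and translation contribute orthogonally to RMSD^2
        t_mag = math.sqrt(target_rmsd ** 2 - rot_rmsd2)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        return x @ R.T + center + t_mag * u
    raise SyntheticDataError(f"unknown perturbation mode {mode!r}")


def place_ligand_complex(receptor: ComplexStructure, elements: list[str],
                         coords: np.ndarray, ligand_resname: str = "LIG",
                         chain: str = "L") -> ComplexStructure:
    """Attach ligand atoms to a receptor as a single het residue."""
    atoms = list(receptor.atoms)
    for i, (el, xyz) in enumerate(zip(elements, coords)):
        atoms.append(Atom("ligand", chain, ligand_resname, 1,
                          f"{el.upper()}{i + 1}", el.upper(),
                          tuple(float(v) for v in xyz)))
    return ComplexStructure(atoms, ligand_resname, receptor.source_format, None)


@dataclass
class PoseSpec:
    """Distribution of planted pose errors for a synthetic benchmark batch."""

    rmsd_low: float = 0.2
    rmsd_high: float = 6.0
    out_of_pocket_fraction: float = 0.0
    perturb_mode: str = "rigid"
    #: asymmetric by design: trivial automorphism group, so the symmetry
    #: minimum equals the planted identity-map RMSD
    smiles: str = "CC(=O)Nc1ccccc1F"


def make_pose_pair(receptor: ComplexStructure, spec: PoseSpec, target_rmsd: float,
                   seed: int, global_motion: bool = True
                   ) -> tuple[ComplexStructure, ComplexStructure]:
    """(predicted, reference) complexes with an exactly planted ligand RMSD.

    The reference ligand sits at the pocket; the predicted complex carries the
    perturbed ligand and, when ``global_motion`` is set, a random rigid motion
    of the whole complex that Cα superposition must undo.
    """
    rng = np.random.default_rng(seed)
    els, xyz = embed_ligand(spec.smiles, seed=seed)
    xyz = xyz - xyz.mean(axis=0) + pocket_center(receptor)
    ref = place_ligand_complex(receptor, els, xyz)
    pred_xyz = perturb_pose(xyz, target_rmsd, seed=seed + 1, mode=spec.perturb_mode)
    pred = place_ligand_complex(receptor, els, pred_xyz)
    if global_motion:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(0, 2 * math.pi)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * K @ K
        t = rng.uniform(-20, 20, 3)
        all_xyz = np.array([a.xyz for a in pred.atoms])
        moved = all_xyz @ R.T + t
        pred = ComplexStructure(
            [Atom(a.entity_kind, a.chain, a.res_name, a.res_seq, a.name,
                  a.element, tuple(float(v) for v in m), a.is_hydrogen)
             for a, m in zip(pred.atoms, moved)],
            pred.ligand_component_id, pred.source_format, None)
    return pred, ref


# ---------------------------------------------------------------------------
# confidence / affinity / screens
# ---------------------------------------------------------------------------

def simulate_confidence(rmsd_values, rho_target: float, noise_sd: float = 5.0,
                        seed: int = 0, center: float = 75.0
                        ) -> tuple[np.ndarray, float]:
    """pLDDT-like scores (0–100) with a target correlation to −RMSD.

    With the noise level fixed, the signal slope on −RMSD is solved so the
    population correlation equals ``rho_target``. Scores are clipped to
    [0, 100] after correlation targeting; the clipping fraction is returned
    (warned above 10%).
    """
    rmsd_values = np.asarray(rmsd_values, dtype=float)
    if not -1.0 <= rho_target <= 1.0:
        raise SyntheticDataError("|rho_target| must be ≤ 1")
    rng = np.random.default_rng(seed)
    x = -(rmsd_values - rmsd_values.mean())
    sx = float(x.std())
    if abs(rho_target) == 1.0 or noise_sd == 0.0:
        slope = 10.0  # arbitrary positive gain: correlation is scale-free
        scores = center + math.copysign(slope, rho_target) * x
    else:
        slope = 0.0 if rho_target == 0 or sx == 0 else (
            abs(rho_target) / math.sqrt(1 - rho_target ** 2) * noise_sd / sx)
        noise = rng.normal(0.0, noise_sd, size=x.shape)
        scores = center + math.copysign(1.0, rho_target) * slope * x + noise
    clipped = float(np.mean((scores < 0) | (scores > 100)))
    if clipped > 0.10:
        logger.warning("confidence clipping fraction %.1f%% exceeds 10%%",
                       100 * clipped)
    return np.clip(scores, 0.0, 100.0), clipped


def simulate_affinity_predictions(true_pic, slope: float, intercept: float,
                                  noise_sd: float, seed: int = 0) -> np.ndarray:
    """predicted = slope·true + intercept + N(0, noise_sd)."""
    true_pic = np.asarray(true_pic, dtype=float)
    if noise_sd < 0:
        raise SyntheticDataError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    return slope * true_pic + intercept + rng.normal(0.0, noise_sd, true_pic.shape)


def simulate_hitlist(n_active: int, n_inactive: int, score_shift: float,
                     seed: int = 0, threshold_ki_molar: float = 400e-6):
    """Active/decoy screen records with a planted Gaussian score separation.

    Actives score ~ N(d, 1), inactives ~ N(0, 1) (higher is better), so the
    population ROC AUC is Φ(d/√2). Apparent Ki values are drawn log-uniformly
    below (actives) or above (inactives) the threshold.
    """
    import pandas as pd

    if n_active < 1 or n_inactive < 1:
        raise SyntheticDataError("need at least one compound per class")
    rng = np.random.default_rng(seed)
    scores = np.concatenate([rng.normal(score_shift, 1.0, n_active),
                             rng.normal(0.0, 1.0, n_inactive)])
    active = np.concatenate([np.ones(n_active, bool), np.zeros(n_inactive, bool)])
    ki = np.empty(n_active + n_inactive)
    ki[:n_active] = 10 ** rng.uniform(math.log10(2.5e-9),
                                      math.log10(threshold_ki_molar * 0.999),
                                      n_active)
    ki[n_active:] = 10 ** rng.uniform(math.log10(threshold_ki_molar * 1.001),
                                      math.log10(0.1), n_inactive)
    return pd.DataFrame({
        "compound_id": [f"cmp-{i:05d}" for i in range(n_active + n_inactive)],
        "score": scores,
        "ki_molar": ki,
        "active": active,
    })


# ---------------------------------------------------------------------------
# scenario bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticScenario:
    """One fully specified synthetic study; the defaults are the study
    conditions every benchmark and acceptance run uses."""

    seed: int = 0
    receptor: ReceptorSpec = field(default_factory=ReceptorSpec)
    library: LibrarySpec = field(default_factory=LibrarySpec)
    pose: PoseSpec = field(default_factory=PoseSpec)
    n_poses: int = 50
    confidence_rho: float = 0.6
    confidence_noise_sd: float = 5.0
    affinity_slope: float = 1.0
    affinity_intercept: float = 1.2
    affinity_noise_sd: float = 0.3
    n_affinity: int = 200
    true_pic_range: tuple[float, float] = (3.3, 7.0)
    screen_n_active: int = 200
    screen_n_inactive: int = 300
    screen_shift: float = 3.0
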