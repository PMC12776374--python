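"""Reading and writing protein–ligand complexes, confidence files, and results tables.

Structures (mmCIF or PDB) are parsed with gemmi into a flat, format-agnostic
:class:`ComplexStructure`. Confidence outputs of a co-folding run — a per-atom
pLDDT vector, a PAE matrix and global scalars — are read from JSON into a
:class:`ConfidenceBundle` whose index maps from ligand atoms into the pLDDT
vector and PAE matrix are constructed and validated here, never downstream.

Conventions
-----------
* Author residue numbering is the canonical residue key (``Phe156`` style).
* Hydrogens are parsed but flagged; all geometry downstream is heavy-atom only.
* Model 1 of a multi-model file is used; extra models are ignored with a warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Waters and common crystallization additives, never picked as "the ligand"
#: by the heuristic selector.
DEFAULT_EXCLUDED_RESNAMES = frozenset(
    {"HOH", "WAT", "DOD", "GOL", "EDO", "SO4", "PO4", "CL", "NA", "K", "MG", "ZN"}
)


class ComplexIOError(Exception):
    """Base class for structure/confidence I/O failures."""


class FormatError(ComplexIOError):
    """The file could not be parsed as mmCIF or PDB."""


class NoLigandError(ComplexIOError):
    """Parsing succeeded but no ligand entity matched the selector."""


class ConfidenceAlignmentError(ComplexIOError):
    """Confidence vector/matrix shapes do not line up with the structure."""


@dataclass(frozen=True)
class Atom:
    entity_kind: str  # 'protein' | 'ligand' | 'other'
    chain: str
    res_name: str
    res_seq: int  # author numbering
    name: str
    element: str
    xyz: tuple[float, float, float]
    is_hydrogen: bool = False


@dataclass
class ComplexStructure:
    """Parsed protein+ligand coordinates with chain/residue/atom identity."""

    atoms: list[Atom]
    ligand_component_id: str | None
    source_format: str  # 'mmCIF' | 'PDB'
    source_path: str | None = None

    def __post_init__(self) -> None:
        for a in self.atoms:
            if not all(np.isfinite(a.xyz)):
                raise ComplexIOError(f"non-finite coordinates on atom {a.name}")

    # -- selections ------------------------------------------------------
    def protein_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.entity_kind == "protein"]

    def ligand_atoms(self, heavy_only: bool = True) -> list[Atom]:
        out = [a for a in self.atoms if a.entity_kind == "ligand"]
        if heavy_only:
            out = [a for a in out if not a.is_hydrogen]
        return out

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def ligand_coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.ligand_atoms()], dtype=float)

    def ligand_elements(self) -> list[str]:
        return [a.element for a in self.ligand_atoms()]

    def ca_map(self) -> dict[tuple[str, int], np.ndarray]:
        """(chain, author residue number) -> Cα coordinate."""
        out: dict[tuple[str, int], np.ndarray] = {}
        for a in self.atoms:
            if a.entity_kind == "protein" and a.name == "CA":
                out[(a.chain, a.res_seq)] = np.asarray(a.xyz, dtype=float)
        return out

    def residue_atom(self, res_seq: int, atom_name: str) -> Atom | None:
        for a in self.atoms:
            if a.entity_kind == "protein" and a.res_seq == res_seq and a.name == atom_name:
                return a
        return None

    def protein_residue_keys(self) -> list[tuple[str, int]]:
        """Ordered unique (chain, residue number) keys of protein residues."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            if a.entity_kind == "protein":
                seen.setdefault((a.chain, a.res_seq))
        return list(seen)

    def with_coords(self, protein_xyz: np.ndarray | None = None,
                    ligand_xyz: np.ndarray | None = None) -> "ComplexStructure":
        """Copy with replaced heavy-atom coordinates (used after alignment)."""
        new_atoms: list[Atom] = []
        ip = il = 0
        for a in self.atoms:
            xyz = a.xyz
            if not a.is_hydrogen and a.entity_kind == "protein" and protein_xyz is not None:
                xyz = tuple(float(v) for v in protein_xyz[ip]); ip += 1
            elif not a.is_hydrogen and a.entity_kind == "ligand" and ligand_xyz is not None:
                xyz = tuple(float(v) for v in ligand_xyz[il]); il += 1
            new_atoms.append(Atom(a.entity_kind, a.chain, a.res_name, a.res_seq,
                                  a.name, a.element, xyz, a.is_hydrogen))
        return ComplexStructure(new_atoms, self.ligand_component_id,
                                self.source_format, self.source_path)


# ---------------------------------------------------------------------------
# structure reading / writing
# ---------------------------------------------------------------------------

_STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL MSE".split()
)


def _is_amino_acid(res_name: str) -> bool:
    if res_name in _STANDARD_AA:
        return True
    info = gemmi.find_tabulated_residue(res_name)
    return bool(info and info.is_amino_acid())


def read_complex(path: str | Path, ligand_selector: str | None = None,
                 excluded_resnames: frozenset[str] = DEFAULT_EXCLUDED_RESNAMES,
                 require_ligand: bool = True) -> ComplexStructure:
    """Read an mmCIF/PDB file and partition atoms into protein and ligand.

    Ligand selection is deterministic: an explicit component id
    (``ligand_selector``, a residue name) wins; otherwise the largest
    non-polymer, non-water/buffer heavy-atom entity is chosen, with ties
    broken lexicographically by (residue name, chain, residue number) so the
    choice is independent of file order.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    fmt = "mmCIF" if path.suffix.lower() in {".cif", ".mmcif"} else "PDB"
    if len(st) == 0:
        raise FormatError(f"{path}: no models")
    if len(st) > 1:
        logger.warning("%s: %d models present; using model 1", path, len(st))
    model = st[0]

    protein: list[Atom] = []
    hetero: dict[tuple[str, str, int], list[Atom]] = {}
    for chain in model:
        for res in chain:
            is_aa = _is_amino_acid(res.name)
            for at in res:
                atom = Atom(
                    entity_kind="protein" if is_aa else "other",
                    chain=chain.name, res_name=res.name, res_seq=res.seqid.num,
                    name=at.name, element=at.element.name.upper(),
                    xyz=(at.pos.x, at.pos.y, at.pos.z),
                    is_hydrogen=at.element.is_hydrogen,
                )
                if is_aa:
                    protein.append(atom)
                else:
                    hetero.setdefault((res.name, chain.name, res.seqid.num), []).append(atom)

    # candidate ligand entities
    candidates = {
        key: atoms for key, atoms in hetero.items() if key[0] not in excluded_resnames
    }
    chosen_key = None
    if ligand_selector is not None:
        # an explicit component id wins, even over the buffer exclusion list
        matching = [k for k in hetero if k[0] == ligand_selector]
        if not matching:
            raise NoLigandError(
                f"{path}: no ligand with component id {ligand_selector!r}")
        chosen_key = sorted(
            matching,
            key=lambda k: (-sum(not a.is_hydrogen for a in hetero[k]), k))[0]
    elif candidates:
        chosen_key = sorted(
            candidates,
            key=lambda k: (-sum(not a.is_hydrogen for a in candidates[k]), k))[0]
    elif require_ligand:
        raise NoLigandError(f"{path}: no non-buffer heteroatom entity found")

    atoms = list(protein)
    ligand_id = None
    for key, group in hetero.items():
        kind = "ligand" if key == chosen_key else "other"
        if key == chosen_key:
            ligand_id = key[0]
        for a in group:
            atoms.append(Atom(kind, a.chain, a.res_name, a.res_seq,
                              a.name, a.element, a.xyz, a.is_hydrogen))

    if not any(a.entity_kind == "protein" and a.name == "CA" for a in atoms):
        raise ComplexIOError(f"{path}: no protein Cα atoms")
    return ComplexStructure(atoms, ligand_id, fmt, str(path))


def write_complex(structure: ComplexStructure, path: str | Path) -> Path:
    """Write a ComplexStructure as mmCIF (.cif) or PDB (.pdb) via gemmi.

    mmCIF output keeps full double precision (~1e-9 relative); PDB is limited
    to the format's fixed three decimals.
    """
    path = Path(path)
    st = gemmi.Structure()
    st.name = path.stem
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    current: dict[str, tuple[int, str] | None] = {}
    for a in structure.atoms:
        ch = chains.get(a.chain)
        if ch is None:
            ch = gemmi.Chain(a.chain)
            chains[a.chain] = ch
            model.add_chain(ch)
            ch = model[len(model) - 1]
            chains[a.chain] = ch
            current[a.chain] = None
        if current[a.chain] != (a.res_seq, a.res_name):
            res = gemmi.Residue()
            res.name = a.res_name
            res.seqid = gemmi.SeqId(a.res_seq, " ")
            res.het_flag = "A" if a.entity_kind == "protein" else "H"
            ch.add_residue(res)
            current[a.chain] = (a.res_seq, a.res_name)
        res = ch[len(ch) - 1]
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.xyz)
        at.occ = 1.0
        at.b_iso = 20.0
        res.add_atom(at)
    st.add_model(model)
    st.setup_entities()
    if path.suffix.lower() in {".cif", ".mmcif"}:
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))
    return path


# ---------------------------------------------------------------------------
# confidence files
# ---------------------------------------------------------------------------

@dataclass
class ConfidenceBundle:
    """Per-atom pLDDT, PAE matrix and global scalars for one prediction.

    ``ligand_plddt_idx`` / ``ligand_pae_idx`` map each ligand heavy atom to
    exactly one row of the pLDDT vector / PAE matrix (a total index map,
    validated at load time).
    """

    plddt: np.ndarray
    pae: np.ndarray | None
    iptm: float | None
    ptm: float | None
    predicted_pic50: float | None = None
    binding_probability: float | None = None
    ligand_plddt_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    ligand_pae_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.plddt = np.asarray(self.plddt, dtype=float)
        if np.any(self.plddt < 0) or np.any(self.plddt > 100):
            raise ConfidenceAlignmentError("pLDDT entries outside [0, 100]")
        if self.pae is not None:
            self.pae = np.asarray(self.pae, dtype=float)
            if self.pae.ndim != 2 or self.pae.shape[0] != self.pae.shape[1]:
                raise ConfidenceAlignmentError("PAE matrix is not square")
            if np.any(self.pae < 0):
                raise ConfidenceAlignmentError("negative PAE entries")
        for name in ("iptm", "ptm", "binding_probability"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= float(v) <= 1.0:
                raise ConfidenceAlignmentError(f"{name}={v} outside [0, 1]")


def _ligand_index_map(structure: ComplexStructure, n: int, what: str) -> np.ndarray:
    """Map ligand heavy atoms into a length/size-``n`` confidence axis.

    Two granularities are accepted: per heavy atom (protein + ligand, file
    order) and per token (one token per protein residue, then one per ligand
    heavy atom — the co-folding convention). Anything else is an alignment
    error, never a silent truncation.
    """
    heavy = structure.heavy_atoms()
    n_heavy = len(heavy)
    lig_pos = [i for i, a in enumerate(heavy) if a.entity_kind == "ligand"]
    n_res = len(structure.protein_residue_keys())
    n_lig = len(lig_pos)
    if n == n_heavy:
        return np.array(lig_pos, dtype=int)
    if n == n_res + n_lig:
        return np.arange(n_res, n_res + n_lig, dtype=int)
    raise ConfidenceAlignmentError(
        f"{what} has length {n}, but the structure has {n_heavy} heavy atoms "
        f"and {n_res + n_lig} tokens ({n_res} residues + {n_lig} ligand atoms)")


def read_confidence(path: str | Path, structure: ComplexStructure) -> ConfidenceBundle:
    """Read a JSON confidence file and validate it against a structure.

    Expected keys: ``plddt`` (list), optional ``pae`` (square list-of-lists),
    optional scalars ``iptm``, ``ptm``, ``predicted_pic50``,
    ``binding_probability``.
    """
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh)
    if "plddt" not in data:
        raise ConfidenceAlignmentError(f"{path}: missing 'plddt' key")
    plddt = np.asarray(data["plddt"], dtype=float)
    pae = np.asarray(data["pae"], dtype=float) if data.get("pae") is not None else None
    bundle = ConfidenceBundle(
        plddt=plddt,
        pae=pae,
        iptm=data.get("iptm"),
        ptm=data.get("ptm"),
        predicted_pic50=data.get("predicted_pic50"),
        binding_probability=data.get("binding_probability"),
    )
    bundle.ligand_plddt_idx = _ligand_index_map(structure, len(plddt), "plddt")
    if pae is not None:
        bundle.ligand_pae_idx = _ligand_index_map(structure, pae.shape[0], "pae")
        if pae.shape[0] != len(plddt):
            logger.warning(
                "%s: PAE (%d tokens) coarser/finer than pLDDT (%d); "
                "per-axis index maps used", path, pae.shape[0], len(plddt))
    return bundle


def write_confidence(path: str | Path, plddt, pae=None, **scalars) -> Path:
    """Write a confidence JSON in the format read_confidence expects."""
    payload = {"plddt": np.asarray(plddt, dtype=float).tolist()}
    if pae is not None:
        payload["pae"] = np.asarray(pae, dtype=float).tolist()
    for k, v in scalars.items():
        payload[k] = None if v is None else float(v)
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(payload, fh)
    return path


# ---------------------------------------------------------------------------
# results tables
# ---------------------------------------------------------------------------

def write_results(table: pd.DataFrame, path: str | Path,
                  provenance: dict | None = None) -> Path:
    """Write a results table as CSV with a stable column order.

    Missing values become empty cells (never "0"); numeric round-trip is good
    to 1e-9 via ``%.12g``. An optional provenance mapping is emitted as
    ``# key: value`` comment lines before the header.
    """
    if table.empty:
        raise ComplexIOError("refusing to write an empty results table")
    if "ligand_id" in table.columns and table["ligand_id"].duplicated().any():
        raise ComplexIOError("duplicate ligand ids in results table")
    path = Path(path)
    try:
        with open(path, "w") as fh:
            if provenance:
                for k, v in provenance.items():
                    fh.write(f"# {k}: {v}\n")
            table.to_csv(fh, index=False, na_rep="", float_format="%.12g")
    except OSError as exc:
        raise ComplexIOError(f"cannot write {path}: {exc}") from exc
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
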