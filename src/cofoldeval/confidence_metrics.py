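"""Ligand-centric confidence summaries derived from per-atom model outputs.

Co-folding models report a per-atom pLDDT vector and a PAE matrix for the
whole complex; for pose assessment what matters is the ligand. Three
summaries are derived here:

* **L-pLDDT** — arithmetic mean of pLDDT over ligand atoms (0–100);
* **L-PAE** — mean of all PAE elements that involve a ligand atom (Å);
* **mPAE** — minimum over that same element set (Å).

"Elements that involve ligand atoms" is read as the union of ligand rows and
ligand columns of the PAE matrix with each cell counted once (diagonal
included); a ``mode="rows"`` switch restricts to ligand rows only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .complex_io import ConfidenceBundle


class MetricUnavailableError(Exception):
    """The requested metric cannot be computed from this bundle."""


@dataclass
class LigandConfidence:
    l_plddt: float
    l_pae: float | None
    m_pae: float | None
    iptm: float | None
    ptm: float | None


def l_plddt(bundle: ConfidenceBundle, ligand_indices=None) -> float:
    """Unweighted arithmetic mean of pLDDT over ligand atom indices."""
    idx = bundle.ligand_plddt_idx if ligand_indices is None else np.asarray(ligand_indices)
    if idx.size == 0:
        raise MetricUnavailableError("empty ligand index set")
    if idx.min() < 0 or idx.max() >= len(bundle.plddt):
        raise MetricUnavailableError("ligand index out of bounds for pLDDT vector")
    # sorted so the summation order (hence the value) is independent of the
    # order the caller lists ligand atoms in
    return float(np.mean(bundle.plddt[np.sort(idx)]))


def _ligand_pae_cells(bundle: ConfidenceBundle, ligand_indices, mode: str) -> np.ndarray:
    if bundle.pae is None:
        raise MetricUnavailableError("PAE matrix absent")
    idx = bundle.ligand_pae_idx if ligand_indices is None else np.asarray(ligand_indices)
    if idx.size == 0:
        raise MetricUnavailableError("empty ligand index set")
    n = bundle.pae.shape[0]
    if idx.min() < 0 or idx.max() >= n:
        raise MetricUnavailableError("ligand index out of bounds for PAE matrix")
    mask = np.zeros((n, n), dtype=bool)
    mask[idx, :] = True
    if mode == "union":
        mask[:, idx] = True
    elif mode != "rows":
        raise ValueError(f"unknown PAE element mode {mode!r}")
    return bundle.pae[mask]


def l_pae(bundle: ConfidenceBundle, ligand_indices=None, mode: str = "union") -> float:
    """Mean PAE over elements involving ligand atoms, each cell counted once."""
    return float(np.mean(_ligand_pae_cells(bundle, ligand_indices, mode)))


def m_pae(bundle: ConfidenceBundle, ligand_indices=None, mode: str = "union") -> float:
    """Minimum PAE over elements involving ligand atoms."""
    return float(np.min(_ligand_pae_cells(bundle, ligand_indices, mode)))


def ligand_confidence(bundle: ConfidenceBundle, ligand_indices=None,
                      mode: str = "union") -> LigandConfidence:
    """All ligand-centric summaries for one prediction; PAE ones None if absent."""
    has_pae = bundle.pae is not None
    return LigandConfidence(
        l_plddt=l_plddt(bundle, ligand_indices),
        l_pae=l_pae(bundle, ligand_indices, mode) if has_pae else None,
        m_pae=m_pae(bundle, ligand_indices, mode) if has_pae else None,
        iptm=bundle.iptm,
        ptm=bundle.ptm,
    )
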