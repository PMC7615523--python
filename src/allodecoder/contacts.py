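"""Non-covalent contact detection, filtering, state partition and interfaces.

The contact criterion is the van der Waals gap rule: two heavy atoms are in
contact when their center distance minus the sum of their element radii is
0.5 Angstrom or less (~4.2 A maximum for a carbon-carbon pair).  Atom
contacts are aggregated into residue-residue contacts, which are then
filtered to drop pairs touching exclusively through backbone atoms and pairs
within the same secondary structure element, and restricted to residues
resolved in both states being compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc
from scipy.spatial import cKDTree

from .structures import (
    BACKBONE_ATOMS,
    DEFAULT_VDW_RADII,
    ResidueAnnotation,
    StructureModel,
    atom_residue_keys,
    _radii_for,
)

#: absolute slack on the gap comparison; coordinates are stored at single
#: precision, so a pair placed exactly at the cutoff must still register
GAP_EPS = 1e-6

__all__ = [
    "AtomContact",
    "ResidueContact",
    "ContactPartition",
    "InterfaceMatrix",
    "atom_contacts",
    "residue_contacts",
    "partition_by_state",
    "interface_residues",
    "interface_matrix",
]


@dataclass(frozen=True)
class AtomContact:
    """One atom-atom contact under the vdW-gap criterion (stored once,
    canonically ordered by (residue key, atom name))."""

    res_i: str
    res_j: str
    atom_i: str
    atom_j: str
    gap: float
    kind: str  # sidechain-sidechain | mainchain-sidechain | mainchain-mainchain


@dataclass(frozen=True)
class ResidueContact:
    res_i: str
    res_j: str
    n_atom_contacts: int
    backbone_only: bool
    same_sse: bool

    @property
    def pair(self) -> tuple[str, str]:
        return (self.res_i, self.res_j)


@dataclass
class ContactPartition:
    """Three-way split of filtered residue contacts by state membership."""

    active_only: dict[tuple[str, str], ResidueContact]
    inactive_only: dict[tuple[str, str], ResidueContact]
    shared: dict[tuple[str, str], ResidueContact]

    def counts(self) -> dict[str, int]:
        return {
            "active_only": len(self.active_only),
            "inactive_only": len(self.inactive_only),
            "shared": len(self.shared),
        }

    def residues_in(self, which: str) -> set[str]:
        part = getattr(self, which)
        return {r for pair in part for r in pair}


@dataclass
class InterfaceMatrix:
    """Receptor-residue x partner contact-count matrix with marginals."""

    counts: pd.DataFrame  # rows: receptor residue keys; cols: partner ids
    mainchain_only_rows: set[str] = field(default_factory=set)

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def _contact_kind(bb_i: bool, bb_j: bool) -> str:
    if bb_i and bb_j:
        return "mainchain-mainchain"
    if bb_i or bb_j:
        return "mainchain-sidechain"
    return "sidechain-sidechain"


def _pairs_within(
    coords_a: np.ndarray, coords_b: np.ndarray | None, max_dist: float
) -> np.ndarray:
    """Candidate index pairs within max_dist (KD-tree accelerated)."""
    tree_a = cKDTree(coords_a)
    if coords_b is None:
        pairs = tree_a.query_pairs(max_dist, output_type="ndarray")
        return pairs
    tree_b = cKDTree(coords_b)
    res = tree_a.query_ball_tree(tree_b, max_dist)
    out = [(i, j) for i, js in enumerate(res) for j in js]
    return np.array(out, dtype=int).reshape(-1, 2)


def atom_contacts(
    model: StructureModel,
    gap_cutoff: float = 0.5,
    radii: dict[str, float] | None = None,
) -> list[AtomContact]:
    """All inter-residue heavy-atom contacts with vdW gap <= ``gap_cutoff``.

    Pairs within one residue and covalently bonded backbone pairs
    (C of residue i with N of residue i+1 on the same chain) are excluded:
    covalent bonds are not non-covalent contacts.
    """
    radii = radii or DEFAULT_VDW_RADII
    atoms = model.receptor
    n = atoms.array_length()
    if n == 0:
        return []
    rad = _radii_for(atoms, radii)
    keys = atom_residue_keys(atoms)
    is_bb = np.isin(atoms.atom_name, BACKBONE_ATOMS)
    max_dist = gap_cutoff + 2.0 * float(rad.max()) + GAP_EPS

    contacts = []
    for i, j in _pairs_within(atoms.coord, None, max_dist):
        if keys[i] == keys[j]:
            continue
        gap = float(np.linalg.norm(atoms.coord[i] - atoms.coord[j]) - rad[i] - rad[j])
        if gap > gap_cutoff + GAP_EPS:
            continue
        # exclude the peptide bond C(i)-N(i+1)
        if atoms.chain_id[i] == atoms.chain_id[j]:
            d_res = int(atoms.res_id[j]) - int(atoms.res_id[i])
            names = (atoms.atom_name[i], atoms.atom_name[j])
            if (d_res == 1 and names == ("C", "N")) or (
                d_res == -1 and names == ("N", "C")
            ):
                continue
        # canonical ordering by (residue key, atom name)
        ti = (keys[i], str(atoms.atom_name[i]))
        tj = (keys[j], str(atoms.atom_name[j]))
        if tj < ti:
            i, j, ti, tj = j, i, tj, ti
        contacts.append(
            AtomContact(
                res_i=ti[0],
                res_j=tj[0],
                atom_i=ti[1],
                atom_j=tj[1],
                gap=gap,
                kind=_contact_kind(bool(is_bb[i]), bool(is_bb[j])),
            )
        )
    contacts.sort(key=lambda c: (c.res_i, c.atom_i, c.res_j, c.atom_j))
    return contacts


def residue_contacts(
    contacts: list[AtomContact],
    annotation: ResidueAnnotation | None = None,
    drop_mainchain_only: bool = True,
    drop_same_sse: bool = True,
    restrict_to: set[str] | None = None,
) -> dict[tuple[str, str], ResidueContact]:
    """Aggregate atom contacts per residue pair and apply the network filters.

    A pair is dropped when (a) every atom contact between the two residues is
    mainchain-mainchain, (b) both residues carry the same SSE label, or (c)
    either residue lies outside ``restrict_to`` (residues resolved in both
    states).  Unannotated residues keep SSE label "NA" and are never dropped
    by the same-SSE rule ("NA" labels are not considered equal).
    """
    agg: dict[tuple[str, str], list[AtomContact]] = {}
    for c in contacts:
        pair = tuple(sorted((c.res_i, c.res_j)))
        agg.setdefault(pair, []).append(c)

    out: dict[tuple[str, str], ResidueContact] = {}
    for pair, cs in agg.items():
        if restrict_to is not None and (
            pair[0] not in restrict_to or pair[1] not in restrict_to
        ):
            continue
        backbone_only = all(c.kind == "mainchain-mainchain" for c in cs)
        if annotation is not None:
            sse_i = annotation.sse_of(pair[0])
            sse_j = annotation.sse_of(pair[1])
            same_sse = sse_i == sse_j and sse_i != "NA"
        else:
            same_sse = False
        if drop_mainchain_only and backbone_only:
            continue
        if drop_same_sse and same_sse:
            continue
        out[pair] = ResidueContact(
            res_i=pair[0],
            res_j=pair[1],
            n_atom_contacts=len(cs),
            backbone_only=backbone_only,
            same_sse=same_sse,
        )
    return out


def partition_by_state(
    active: dict[tuple[str, str], ResidueContact],
    inactive: dict[tuple[str, str], ResidueContact],
) -> ContactPartition:
    """Set-algebra partition of residue contacts into active-only /
    inactive-only / shared, keyed on residue pairs."""
    a_keys, i_keys = set(active), set(inactive)
    return ContactPartition(
        active_only={k: active[k] for k in sorted(a_keys - i_keys)},
        inactive_only={k: inactive[k] for k in sorted(i_keys - a_keys)},
        shared={k: active[k] for k in sorted(a_keys & i_keys)},
    )


def interface_residues(
    model: StructureModel,
    partner: str,
    cutoff: float = 4.0,
) -> set[str]:
    """Receptor residues with any heavy atom within ``cutoff`` A of the partner.

    This is the plain-distance site definition (4 A default), distinct from
    the vdW-gap contact rule used for contact networks.
    """
    if partner not in model.partners:
        raise ValueError(
            f"partner '{partner}' not in model (have {sorted(model.partners)})"
        )
    part = model.partners[partner]
    if part.array_length() == 0:
        raise ValueError(f"partner '{partner}' selection is empty")
    rec = model.receptor
    keys = atom_residue_keys(rec)
    pairs = _pairs_within(rec.coord, part.coord, cutoff)
    out = set()
    for i, j in pairs:
        if np.linalg.norm(rec.coord[i] - part.coord[j]) <= cutoff:
            out.add(keys[i])
    return out


def interface_matrix(
    model: StructureModel,
    partner: str,
    mode: str = "ligand_atoms",
    gap_cutoff: float = 0.5,
    radii: dict[str, float] | None = None,
) -> InterfaceMatrix:
    """Receptor-residue x partner contact-count matrix (vdW-gap criterion).

    Columns are partner atom names (``mode="ligand_atoms"``) or partner
    residue keys (``mode="partner_residues"``).  Rows whose receptor contacts
    are exclusively via main-chain atoms are flagged.
    """
    if mode not in ("ligand_atoms", "partner_residues"):
        raise ValueError(f"unknown mode '{mode}'")
    radii = radii or DEFAULT_VDW_RADII
    rec, part = model.receptor, model.partners[partner]
    rad_r = _radii_for(rec, radii)
    rad_p = _radii_for(part, radii)
    keys_r = atom_residue_keys(rec)
    keys_p = atom_residue_keys(part)
    is_bb = np.isin(rec.atom_name, BACKBONE_ATOMS)
    max_dist = gap_cutoff + float(rad_r.max()) + float(rad_p.max()) + GAP_EPS

    cells: dict[tuple[str, str], int] = {}
    row_has_sidechain: dict[str, bool] = {}
    for i, j in _pairs_within(rec.coord, part.coord, max_dist):
        gap = np.linalg.norm(rec.coord[i] - part.coord[j]) - rad_r[i] - rad_p[j]
        if gap > gap_cutoff + GAP_EPS:
            continue
        row = keys_r[i]
        col = str(part.atom_name[j]) if mode == "ligand_atoms" else keys_p[j]
        cells[(row, col)] = cells.get((row, col), 0) + 1
        row_has_sidechain[row] = row_has_sidechain.get(row, False) or not is_bb[i]

    rows = sorted({r for r, _ in cells})
    cols = sorted({c for _, c in cells})
    mat = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for (r, c), v in cells.items():
        mat.loc[r, c] = v
    mainchain_only = {r for r, has_sc in row_has_sidechain.items() if not has_sc}
    return InterfaceMatrix(counts=mat, mainchain_only_rows=mainchain_only)
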