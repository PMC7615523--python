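"""Structure model, I/O and geometric features (superposition, dihedrals, ASA).

Residues are identified throughout by a key string ``"<chain>:<auth_seq_num>"``
(1-based author numbering; an insertion code, when present, is appended).
Structures are held as biotite ``AtomArray`` objects restricted to heavy atoms
with alternate locations resolved to the highest-occupancy conformer and
waters removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb_io
import biotite.structure.io.pdbx as pdbx_io
from scipy.spatial.transform import Rotation

__all__ = [
    "StructureModel",
    "ResidueAnnotation",
    "DisplacementRecord",
    "DEFAULT_VDW_RADII",
    "read_structure",
    "superpose_and_displace",
    "dihedral_deltas",
    "accessible_surface_area",
    "buried_area",
    "residue_key",
    "atom_residue_keys",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")

#: Element-wise van der Waals radii (Angstrom). Configurable via YAML; these
#: are the standard single-atom values for protein heavy atoms.
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}

WATER_NAMES = {"HOH", "WAT", "DOD"}


def residue_key(chain: str, res_id: int, icode: str = "") -> str:
    return f"{chain}:{res_id}{icode}"


def atom_residue_keys(atoms: struc.AtomArray) -> np.ndarray:
    """Residue key string for every atom in the array."""
    icodes = (
        atoms.ins_code
        if "ins_code" in atoms.get_annotation_categories()
        else np.full(atoms.array_length(), "", dtype="U1")
    )
    return np.array(
        [
            residue_key(c, int(r), str(i).strip())
            for c, r, i in zip(atoms.chain_id, atoms.res_id, icodes)
        ]
    )


@dataclass
class StructureModel:
    """A parsed structure: receptor atoms plus optional partner selections."""

    receptor: struc.AtomArray
    partners: dict[str, struc.AtomArray] = field(default_factory=dict)
    name: str = ""

    @property
    def resolved_residues(self) -> set[str]:
        return set(atom_residue_keys(self.receptor))

    def is_backbone(self) -> np.ndarray:
        return np.isin(self.receptor.atom_name, BACKBONE_ATOMS)


@dataclass(frozen=True)
class ResidueAnnotation:
    """Mapping residue key -> (GPCRdb generic number, SSE label, terminus flag)."""

    gpcrdb: dict[str, str]
    sse: dict[str, str]
    terminus: set[str] = field(default_factory=set)

    def sse_of(self, key: str, default: str = "NA") -> str:
        return self.sse.get(key, default)

    @classmethod
    def from_frame(cls, df) -> "ResidueAnnotation":
        """Build from a table with columns residue, gpcrdb, sse[, is_terminus]."""
        term = set()
        if "is_terminus" in df.columns:
            term = set(df.loc[df["is_terminus"].astype(bool), "residue"])
        return cls(
            gpcrdb=dict(zip(df["residue"], df["gpcrdb"].astype(str))),
            sse=dict(zip(df["residue"], df["sse"].astype(str))),
            terminus=term,
        )


@dataclass(frozen=True)
class DisplacementRecord:
    residue_key: str
    ca_displacement: float | None = None
    d_phi: float | None = None
    d_psi: float | None = None
    d_omega: float | None = None


def _load_atoms(path: str | Path) -> struc.AtomArray:
    path = Path(path)
    if path.suffix.lower() in {".cif", ".mmcif", ".pdbx"}:
        f = pdbx_io.CIFFile.read(str(path))
        atoms = pdbx_io.get_structure(f, model=1, altloc="occupancy")
    else:
        f = pdb_io.PDBFile.read(str(path))
        atoms = pdb_io.get_structure(f, model=1, altloc="occupancy")
    return atoms


def read_structure(
    path: str | Path,
    receptor_chains: list[str] | None = None,
    partner_selections: dict[str, dict] | None = None,
    name: str = "",
) -> StructureModel:
    """Read a PDB/mmCIF file into a :class:`StructureModel`.

    Hydrogens and waters are dropped; altlocs resolve to highest occupancy.
    ``partner_selections`` maps a partner name to a selection dict with keys
    ``chains`` and/or ``res_names`` (e.g. ``{"ligand": {"res_names": ["ALE"]}}``).
    Partner atoms are removed from the receptor selection.
    """
    atoms = _load_atoms(path)
    atoms = atoms[atoms.element != "H"]
    atoms = atoms[~np.isin(atoms.res_name, list(WATER_NAMES))]
    if not np.all(np.isfinite(atoms.coord)):
        raise ValueError(f"{path}: non-finite coordinates")

    available = sorted(set(atoms.chain_id))
    partners: dict[str, struc.AtomArray] = {}
    partner_mask = np.zeros(atoms.array_length(), dtype=bool)
    for pname, sel in (partner_selections or {}).items():
        mask = np.ones(atoms.array_length(), dtype=bool)
        if sel.get("chains"):
            mask &= np.isin(atoms.chain_id, sel["chains"])
        if sel.get("res_names"):
            mask &= np.isin(atoms.res_name, sel["res_names"])
        if not mask.any():
            raise ValueError(
                f"{path}: partner selection '{pname}' matches no atoms "
                f"(available chains: {available})"
            )
        partners[pname] = atoms[mask]
        partner_mask |= mask

    receptor = atoms[~partner_mask]
    if receptor_chains is not None:
        missing = set(receptor_chains) - set(receptor.chain_id)
        if missing:
            raise ValueError(
                f"{path}: chain(s) {sorted(missing)} not found; "
                f"available chains: {available}"
            )
        receptor = receptor[np.isin(receptor.chain_id, receptor_chains)]
    # keep amino-acid residues only for the receptor selection
    receptor = receptor[struc.filter_amino_acids(receptor)]
    return StructureModel(receptor=receptor, partners=partners, name=name or str(path))


def _ca_map(model: StructureModel) -> dict[str, np.ndarray]:
    atoms = model.receptor
    keys = atom_residue_keys(atoms)
    out = {}
    for i in np.flatnonzero(atoms.atom_name == "CA"):
        out.setdefault(keys[i], atoms.coord[i].astype(np.float64))
    return out


def superpose_and_displace(
    active: StructureModel,
    inactive: StructureModel,
    fit_on: set[str] | None = None,
) -> list[DisplacementRecord]:
    """Superpose on common C-alpha atoms and report per-residue displacement.

    A least-squares rigid-body (Kabsch) superposition over the common
    C-alpha atoms (optionally restricted to ``fit_on`` residues, e.g. a
    stable core) is applied, then the Euclidean distance between the paired
    C-alpha positions is reported for every common residue.
    """
    ca_a, ca_i = _ca_map(active), _ca_map(inactive)
    common = sorted(set(ca_a) & set(ca_i))
    fit_keys = [k for k in common if fit_on is None or k in fit_on]
    if len(fit_keys) < 3:
        raise ValueError(
            f"need at least 3 common C-alpha atoms, found {len(fit_keys)}"
        )
    xa = np.array([ca_a[k] for k in common])
    xi = np.array([ca_i[k] for k in common])
    fit_mask = np.array([k in set(fit_keys) for k in common])
    cen_a, cen_i = xa[fit_mask].mean(axis=0), xi[fit_mask].mean(axis=0)
    rot, _ = Rotation.align_vectors(xi[fit_mask] - cen_i, xa[fit_mask] - cen_a)
    xa_fit = rot.apply(xa - cen_a) + cen_i
    dist = np.linalg.norm(xa_fit - xi, axis=1)
    return [
        DisplacementRecord(residue_key=k, ca_displacement=float(d))
        for k, d in zip(common, dist)
    ]


def wrap_angle_delta(a: float, b: float) -> float:
    """Minimal signed angular difference a - b, wrapped into (-180, 180]."""
    d = (a - b + 180.0) % 360.0 - 180.0
    return d if d != -180.0 else 180.0


def _backbone_dihedrals(model: StructureModel) -> dict[str, tuple]:
    """phi/psi/omega in degrees per residue key (None where undefined)."""
    out: dict[str, tuple] = {}
    atoms = model.receptor
    for chain in sorted(set(atoms.chain_id)):
        sub = atoms[atoms.chain_id == chain]
        try:
            phi, psi, omega = struc.dihedral_backbone(sub)
        except struc.BadStructureError:
            continue
        keys = atom_residue_keys(sub)
        res_keys = [keys[i] for i in np.flatnonzero(sub.atom_name == "CA")]
        # dihedral_backbone returns one value per residue, NaN at termini
        for k, f, s, o in zip(res_keys, np.rad2deg(phi), np.rad2deg(psi), np.rad2deg(omega)):
            out[k] = (
                float(f) if np.isfinite(f) else None,
                float(s) if np.isfinite(s) else None,
                float(o) if np.isfinite(o) else None,
            )
    return out


def dihedral_deltas(
    active: StructureModel, inactive: StructureModel
) -> list[DisplacementRecord]:
    """Per-residue backbone dihedral changes, wrapped into (-180, 180].

    Deltas are active minus inactive under the minimal-angle wrap; a delta
    is reported as missing (None) whenever the angle is undefined in either
    state (chain termini, incomplete backbone).
    """
    da, di = _backbone_dihedrals(active), _backbone_dihedrals(inactive)
    records = []
    for k in sorted(set(da) & set(di)):
        deltas = []
        for ang_a, ang_i in zip(da[k], di[k]):
            if ang_a is None or ang_i is None:
                deltas.append(None)
            else:
                deltas.append(wrap_angle_delta(ang_a, ang_i))
        records.append(
            DisplacementRecord(
                residue_key=k, d_phi=deltas[0], d_psi=deltas[1], d_omega=deltas[2]
            )
        )
    return records


def _radii_for(atoms: struc.AtomArray, radii: dict[str, float]) -> np.ndarray:
    out = np.empty(atoms.array_length())
    for i, el in enumerate(atoms.element):
        key = str(el).upper()
        if key not in radii:
            raise KeyError(f"no van der Waals radius for element '{el}'")
        out[i] = radii[key]
    return out


def accessible_surface_area(
    atoms: struc.AtomArray,
    probe: float = 1.4,
    radii: dict[str, float] | None = None,
    point_number: int = 960,
) -> dict[str, float]:
    """Per-residue solvent-accessible surface area (A^2).

    Numerical (Shrake-Rupley style) quadrature with deterministic sphere
    sampling; atom radii come from the package's element table unless
    overridden.
    """
    radii = radii or DEFAULT_VDW_RADII
    atom_sasa = struc.sasa(
        atoms,
        probe_radius=probe,
        vdw_radii=_radii_for(atoms, radii),
        point_number=point_number,
    )
    keys = atom_residue_keys(atoms)
    out: dict[str, float] = {}
    for k, a in zip(keys, atom_sasa):
        if np.isfinite(a):
            out[k] = out.get(k, 0.0) + float(a)
    return out


def buried_area(
    receptor: struc.AtomArray,
    ligand: struc.AtomArray,
    probe: float = 1.4,
    radii: dict[str, float] | None = None,
    point_number: int = 960,
) -> dict[str, float]:
    """Per-residue area buried by the ligand: ASA(apo) - ASA(with ligand).

    The ligand contributes occlusion in the bound calculation but no rows of
    its own; small negative quadrature noise is clipped to zero.
    """
    apo = accessible_surface_area(receptor, probe, radii, point_number)
    complex_atoms = receptor + ligand
    with_lig_all = struc.sasa(
        complex_atoms,
        probe_radius=probe,
        vdw_radii=_radii_for(complex_atoms, radii or DEFAULT_VDW_RADII),
        point_number=point_number,
    )
    n_rec = receptor.array_length()
    keys = atom_residue_keys(receptor)
    bound: dict[str, float] = {}
    for k, a in zip(keys, with_lig_all[:n_rec]):
        if np.isfinite(a):
            bound[k] = bound.get(k, 0.0) + float(a)
    return {k: max(0.0, apo.get(k, 0.0) - bound.get(k, 0.0)) for k in apo}
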