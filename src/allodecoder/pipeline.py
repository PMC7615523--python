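"""End-to-end orchestration: one config in, a results directory out.

Stages run in dependency order — pharmacology screen processing, structure
contact analysis, residue classification and network construction, optional
enrichment — and produce a per-residue master table, tidy CSV outputs per
stage, and a run manifest with input hashes and parameters so identical
configs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
import yaml

from . import __version__
from .contacts import atom_contacts, partition_by_state, residue_contacts
from .enrichment import (
    AnnotationSet,
    compare_score_groups,
    hypergeometric_enrichment,
    site_class_composition,
)
from .pharmacology import PharmacologyCutoffs, process_screen
from .residue_classes import annotate_roles, build_network, classify_residues
from .structures import (
    DEFAULT_VDW_RADII,
    ResidueAnnotation,
    accessible_surface_area,
    dihedral_deltas,
    read_structure,
    superpose_and_displace,
)

__all__ = ["RunConfig", "run"]

#: Theoretical maximum residue ASA (A^2), Tien et al.-style reference values,
#: used for the relative-ASA surface-exposure tag.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    curves: Path
    abundance: Path
    mutant_map: Path  # CSV: mutant_id,residue
    active_structure: Path
    inactive_structure: Path
    annotation: Path  # CSV: residue,gpcrdb,sse[,is_terminus]
    cutoffs: PharmacologyCutoffs = field(default_factory=PharmacologyCutoffs)
    gap_cutoff: float = 0.5
    interface_cutoff: float = 4.0
    radii: dict = field(default_factory=lambda: dict(DEFAULT_VDW_RADII))
    snps: Path | None = None
    et_scores: Path | None = None
    sites: dict = field(default_factory=dict)  # name -> list of residue keys
    motif_residues: list = field(default_factory=list)
    x50_residues: list = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent
        paths = {}
        for key in (
            "curves", "abundance", "mutant_map",
            "active_structure", "inactive_structure", "annotation",
        ):
            if key not in raw:
                raise ValueError(f"run config missing required path '{key}'")
            paths[key] = (base / raw[key]).resolve()
        for key in ("snps", "et_scores"):
            if raw.get(key):
                paths[key] = (base / raw[key]).resolve()
        cfg = cls(
            **paths,
            cutoffs=PharmacologyCutoffs(**raw.get("cutoffs", {})),
            gap_cutoff=float(raw.get("gap_cutoff", 0.5)),
            interface_cutoff=float(raw.get("interface_cutoff", 4.0)),
            sites=raw.get("sites", {}) or {},
            motif_residues=raw.get("motif_residues", []) or [],
            x50_residues=raw.get("x50_residues", []) or [],
            seed=int(raw.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for key in (
            "curves", "abundance", "mutant_map",
            "active_structure", "inactive_structure", "annotation",
            "snps", "et_scores",
        ):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path '{key}' does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _load_annotation(path: Path) -> ResidueAnnotation:
    return ResidueAnnotation.from_frame(pd.read_csv(path))


def run(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages; returns a summary dict and writes the output tree.

    Output layout: profiles/, contacts/, classes/, enrich/ (when annotation
    tables are given), master_table.csv and manifest.json.
    """
    config.validate()
    out = Path(out_dir)
    for sub in ("profiles", "contacts", "classes", "enrich"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    log: dict = {"stages": {}}

    # --- stage 1: pharmacology ------------------------------------------------
    curves = pd.read_csv(config.curves)
    abundance = pd.read_csv(config.abundance)
    profiles = process_screen(curves, abundance, config.cutoffs)
    profiles.to_csv(out / "profiles" / "profiles.csv", index=False)
    log["stages"]["pharmacology"] = {
        "n_mutants": int(len(profiles)),
        "calls": profiles["call"].value_counts().to_dict(),
    }

    # --- stage 2: structures and contacts ------------------------------------
    annotation = _load_annotation(config.annotation)
    active = read_structure(config.active_structure, name="active")
    inactive = read_structure(config.inactive_structure, name="inactive")
    common = active.resolved_residues & inactive.resolved_residues

    parts = {}
    for name, model in (("active", active), ("inactive", inactive)):
        ac = atom_contacts(model, config.gap_cutoff, config.radii)
        rc = residue_contacts(ac, annotation, restrict_to=common)
        parts[name] = rc
        log["stages"][f"contacts_{name}"] = {
            "n_atom_contacts": len(ac),
            "n_residue_contacts": len(rc),
        }
    partition = partition_by_state(parts["active"], parts["inactive"])
    log["stages"]["partition"] = partition.counts()

    rows = []
    for state, part in (
        ("active_only", partition.active_only),
        ("inactive_only", partition.inactive_only),
        ("shared", partition.shared),
    ):
        for rc in part.values():
            rows.append(
                {
                    "res_i": rc.res_i, "res_j": rc.res_j,
                    "n_atom_contacts": rc.n_atom_contacts, "state": state,
                }
            )
    pd.DataFrame(rows).to_csv(out / "contacts" / "partition.csv", index=False)

    displ = {r.residue_key: r.ca_displacement for r in superpose_and_displace(active, inactive)}
    dihed = {r.residue_key: r for r in dihedral_deltas(active, inactive)}
    asa_active = accessible_surface_area(active.receptor, radii=config.radii)
    res_names = dict(
        zip(
            (f"{c}:{i}" for c, i in zip(active.receptor.chain_id, active.receptor.res_id)),
            active.receptor.res_name,
        )
    )
    rel_asa = {
        k: asa_active[k] / MAX_ASA[res_names[k]]
        for k in asa_active
        if res_names.get(k) in MAX_ASA
    }

    # --- stage 3: classification ---------------------------------------------
    mmap = pd.read_csv(config.mutant_map)
    mutant_to_res = dict(zip(mmap["mutant_id"].astype(str), mmap["residue"]))
    calls = {}
    for _, row in profiles.iterrows():
        res = mutant_to_res.get(str(row["mutant_id"]))
        if res is None:
            raise ValueError(f"mutant {row['mutant_id']} missing from mutant map")
        calls[res] = row["call"]

    records = classify_residues(
        calls, partition, active.resolved_residues, inactive.resolved_residues
    )
    network = build_network(records, partition)
    records = annotate_roles(
        records,
        network,
        partition,
        ligand_site=set(config.sites.get("ligand", [])),
        gprot_site=set(config.sites.get("gprot", [])),
        motif_residues=set(config.motif_residues),
        x50_residues=set(config.x50_residues),
        relative_asa=rel_asa,
    )
    class_counts = pd.Series(
        [r.residue_class for r in records.values()]
    ).value_counts().to_dict()
    log["stages"]["classification"] = class_counts
    log["stages"]["network"] = {
        "n_edges": network.n_edges,
        "n_connected_drivers": len(network.connected_drivers),
        "n_atom_contacts": network.n_atom_contacts,
    }

    nx.write_graphml(network.graph, out / "classes" / "network.graphml")
    pd.DataFrame(
        [
            {"res_i": a, "res_j": b, "n_atom_contacts": d["weight"]}
            for a, b, d in network.graph.edges(data=True)
        ]
    ).to_csv(out / "classes" / "network_edges.csv", index=False)

    # --- stage 4: enrichment (optional) --------------------------------------
    class_map = {k: r.residue_class for k, r in records.items()}
    classified_bg = frozenset(
        k for k, c in class_map.items() if c != "unclassified"
    )
    if config.snps is not None and classified_bg:
        snps = pd.read_csv(config.snps)
        snp_res = frozenset(
            str(r) for r, v in zip(snps["residue"], snps["variant_count"]) if v > 0
        ) & classified_bg
        ann = AnnotationSet("snp_positions", snp_res, classified_bg)
        enr_rows = []
        for cls in sorted(set(class_map.values()) - {"unclassified"}):
            cat = {k for k, c in class_map.items() if c == cls}
            res = hypergeometric_enrichment(ann, cat)
            enr_rows.append(
                {
                    "class": cls, "observed": res.observed,
                    "category_size": res.category_size,
                    "p_over": res.p_over, "p_under": res.p_under,
                }
            )
        pd.DataFrame(enr_rows).to_csv(out / "enrich" / "snp_enrichment.csv", index=False)
        log["stages"]["snp_enrichment"] = {"n_snp_positions": len(snp_res)}
    if config.et_scores is not None and classified_bg:
        et = pd.read_csv(config.et_scores)
        frames = []
        for col in [c for c in et.columns if c.startswith("score_")]:
            sc = dict(zip(et["residue"].astype(str), et[col].astype(float)))
            cmp_df = compare_score_groups(
                sc, {k: c for k, c in class_map.items() if c != "unclassified"}
            )
            cmp_df.insert(0, "level", col.removeprefix("score_"))
            frames.append(cmp_df)
        pd.concat(frames).to_csv(out / "enrich" / "et_comparison.csv", index=False)
    for site_name, members in config.sites.items():
        site_members = frozenset(members) & classified_bg
        if not site_members:
            continue
        comp, res = site_class_composition(
            AnnotationSet(site_name, site_members, classified_bg), class_map
        )
        comp.to_csv(out / "enrich" / f"site_{site_name}_composition.csv", index=False)

    # --- master table ---------------------------------------------------------
    profile_by_res = {
        mutant_to_res[str(r["mutant_id"])]: r for _, r in profiles.iterrows()
    }
    master_rows = []
    for res in sorted(annotation.sse):
        rec = records.get(res)
        prow = profile_by_res.get(res)
        row = {
            "residue": res,
            "gpcrdb": annotation.gpcrdb.get(res, ""),
            "sse": annotation.sse.get(res, "NA"),
            "norm_amplitude": prow["norm_amplitude"] if prow is not None else np.nan,
            "delta_logec50": prow["delta_logec50"] if prow is not None else np.nan,
            "abundance_pct": prow["abundance_pct"] if prow is not None else np.nan,
            "call": prow["call"] if prow is not None else "not_mutated",
            "ca_displacement": displ.get(res, np.nan),
            "d_phi": getattr(dihed.get(res), "d_phi", None),
            "d_psi": getattr(dihed.get(res), "d_psi", None),
            "active_specific": bool(rec.active_specific) if rec else False,
            "asa": asa_active.get(res, np.nan),
            "residue_class": rec.residue_class if rec else "not_mutated",
            "tags": ";".join(sorted(rec.tags)) if rec else "",
            "missing_reason": (
                "" if prow is not None else "no_pharmacology_profile"
            ) or (rec.reason if rec else ""),
        }
        master_rows.append(row)
    master = pd.DataFrame(master_rows)
    master.to_csv(out / "master_table.csv", index=False)

    # --- manifest -------------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "gap_cutoff": config.gap_cutoff,
            "interface_cutoff": config.interface_cutoff,
            "cutoffs": vars(config.cutoffs),
        },
        "inputs": {
            key: _sha256(getattr(config, key))
            for key in (
                "curves", "abundance", "mutant_map",
                "active_structure", "inactive_structure", "annotation",
            )
        },
        "summary": log["stages"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return log
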