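"""Ground-truth-bearing synthetic inputs for every pipeline stage.

Three generators emulate the experimental inputs without any downloads:

* :func:`generate_screen` — a mutagenesis screen of 12-point BRET
  concentration-response curves (half-log grid, batch-paired wild-type
  controls, i.i.d. Gaussian replicate noise) with programmed efficacy,
  potency and surface-abundance effects per mutant.
* :func:`generate_structure_pair` — a toy two-state four-helix bundle in
  which chosen side-chain pseudo-atom pairs are placed to satisfy the
  vdW-gap contact rule in the active state, the inactive state, or both,
  with a wide geometric margin for everything not programmed.
* :func:`generate_annotations` — SNP presence and Evolutionary-Trace-like
  conservation scores with class-dependent rates/shifts.

Every generator is a deterministic function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb_io

from .pharmacology import (
    CONC_GRID,
    MutantPharmProfile,
    PharmacologyCutoffs,
    classify_pharmacology,
    hill_curve,
)
from .structures import StructureModel, residue_key

__all__ = [
    "MutantTruth",
    "RewiringTruth",
    "WtParams",
    "generate_screen",
    "generate_structure_pair",
    "generate_annotations",
    "intended_call",
    "intended_classes",
    "example_study",
]


@dataclass(frozen=True)
class WtParams:
    """Wild-type curve parameters in raw BRET units.

    The sensor signal decreases upon activation: the pre-transition baseline
    sits above the post-transition plateau; amplitude 0.075 raw BRET and
    logEC50 -6.4 are typical for the adrenaline/Gs system emulated here.
    """

    baseline_pre: float = 0.80
    amplitude: float = 0.075
    logec50: float = -6.4


@dataclass(frozen=True)
class MutantTruth:
    """Programmed ground truth for one mutant."""

    mutant_id: str
    amplitude_factor: float = 1.0  # x WT signal amplitude
    delta_logec50: float = 0.0  # log10 units vs WT; positive = potency loss
    abundance_pct: float = 100.0


@dataclass(frozen=True)
class RewiringTruth:
    """Programmed residue contacts: (res_key_i, res_key_j, state), state in
    {active_only, inactive_only, shared}."""

    contacts: tuple

    def by_state(self, state: str) -> set:
        return {
            tuple(sorted((a, b))) for a, b, s in self.contacts if s == state
        }


def intended_call(
    truth: MutantTruth,
    wt: WtParams = WtParams(),
    cutoffs: PharmacologyCutoffs | None = None,
) -> str:
    """The pharmacology call implied by the noiseless truth values."""
    cutoffs = cutoffs or PharmacologyCutoffs()
    no_signal = truth.amplitude_factor * wt.amplitude < cutoffs.min_raw_amplitude
    profile = MutantPharmProfile(
        mutant_id=truth.mutant_id,
        n_replicates=0 if no_signal else 1,
        norm_amplitude=np.nan if no_signal else truth.amplitude_factor,
        delta_logec50=np.nan if no_signal else truth.delta_logec50,
        abundance_pct=truth.abundance_pct,
    )
    return classify_pharmacology(profile, cutoffs).call


def generate_screen(
    truths: list[MutantTruth],
    wt: WtParams = WtParams(),
    noise_sd: float = 0.003,
    n_replicates: int = 3,
    n_batches: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a tidy concentration-response screen plus abundance table.

    Replicates are assigned round-robin to batches; each batch carries one
    wild-type control replicate per mutant replicate slot.  Additive Gaussian
    noise of ``noise_sd`` raw BRET is applied per point.  Returns
    (curves, abundance) data frames in the format ``process_screen`` expects.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    batches = [f"B{i + 1}" for i in range(n_batches)]
    rows = []

    def _emit(mutant_id, rep_idx, batch, pre, post, logec50):
        resp = hill_curve(CONC_GRID, logec50, pre, post)
        resp = resp + rng.normal(0.0, noise_sd, size=resp.shape)
        for lc, r in zip(CONC_GRID, resp):
            rows.append(
                {
                    "mutant_id": mutant_id,
                    "replicate_id": f"{mutant_id}_r{rep_idx}",
                    "batch_id": batch,
                    "log_conc": float(lc),
                    "response": float(r),
                }
            )

    # wild-type controls: n_replicates per batch
    for b in batches:
        for i in range(n_replicates):
            _emit(
                "WT",
                f"{b}{i + 1}",
                b,
                wt.baseline_pre,
                wt.baseline_pre - wt.amplitude,
                wt.logec50,
            )
    for truth in truths:
        amp = wt.amplitude * truth.amplitude_factor
        for i in range(n_replicates):
            batch = batches[i % n_batches]
            _emit(
                truth.mutant_id,
                i + 1,
                batch,
                wt.baseline_pre,
                wt.baseline_pre - amp,
                wt.logec50 + truth.delta_logec50,
            )
    curves = pd.DataFrame(rows)
    abundance = pd.DataFrame(
        {
            "mutant_id": [t.mutant_id for t in truths],
            "abundance_pct": [t.abundance_pct for t in truths],
        }
    )
    return curves, abundance


# ---------------------------------------------------------------------------
# toy two-state helix bundle


def _helix_backbone(
    center_xy: np.ndarray, n_res: int, start_res: int, chain: str
) -> list[dict]:
    """Idealized helix: CA on a 2.3 A radius, 100 deg turn, 1.5 A rise, with
    N/C placed between successive CA positions (offset off-axis so backbone
    dihedrals are well defined) and a CB pseudo-sidechain pointing outward."""
    r, turn, rise = 2.3, np.deg2rad(100.0), 1.5
    cas = np.array(
        [
            [
                center_xy[0] + r * np.cos(turn * i),
                center_xy[1] + r * np.sin(turn * i),
                rise * i,
            ]
            for i in range(-1, n_res + 1)
        ]
    )
    atoms = []
    for i in range(1, n_res + 1):
        res_id = start_res + i - 1
        ca = cas[i]
        radial = ca - np.array([center_xy[0], center_xy[1], ca[2]])
        radial /= np.linalg.norm(radial)
        n_pos = 0.65 * ca + 0.35 * cas[i - 1] - 0.3 * radial
        c_pos = 0.65 * ca + 0.35 * cas[i + 1] + 0.3 * radial
        o_pos = c_pos + 0.6 * radial + np.array([0.0, 0.0, 0.4])
        cb = ca + 1.5 * radial
        for name, el, xyz in (
            ("N", "N", n_pos),
            ("CA", "C", ca),
            ("C", "C", c_pos),
            ("O", "O", o_pos),
            ("CB", "C", cb),
        ):
            atoms.append(
                dict(
                    chain=chain, res_id=res_id, res_name="ALA",
                    atom_name=name, element=el, coord=np.asarray(xyz, float),
                )
            )
    return atoms


def _to_atom_array(atom_dicts: list[dict]) -> struc.AtomArray:
    arr = struc.AtomArray(len(atom_dicts))
    arr.coord = np.array([a["coord"] for a in atom_dicts])
    arr.chain_id = np.array([a["chain"] for a in atom_dicts])
    arr.res_id = np.array([a["res_id"] for a in atom_dicts])
    arr.res_name = np.array([a["res_name"] for a in atom_dicts])
    arr.atom_name = np.array([a["atom_name"] for a in atom_dicts])
    arr.element = np.array([a["element"] for a in atom_dicts])
    arr.hetero = np.zeros(len(atom_dicts), dtype=bool)
    return arr


def generate_structure_pair(
    rewiring: RewiringTruth,
    n_helices: int = 4,
    res_per_helix: int = 20,
    helix_spacing: float = 16.0,
    out_dir: str | Path | None = None,
    seed: int = 0,
) -> tuple[StructureModel, StructureModel, pd.DataFrame]:
    """Build the active/inactive toy bundle realizing the programmed contacts.

    Each programmed contact is realized by a CG pseudo-atom pair placed 3.6 A
    apart near the midpoint between the two CA atoms (vdW gap 0.2 A for two
    carbons) in the state(s) where the contact is on, and retracted to 1.5 A
    off its own CA in states where it is off (leaving >6 A between partners).
    Residue keys are ``A:<n>`` with helix h covering residues
    ``(h-1)*res_per_helix+1 ...``; SSE labels are ``H1..Hn``.
    Optionally writes ``active.pdb``, ``inactive.pdb``, ``annotation.csv``.
    """
    corners = [
        np.array([0.0, 0.0]),
        np.array([helix_spacing, 0.0]),
        np.array([helix_spacing, helix_spacing]),
        np.array([0.0, helix_spacing]),
    ]
    if n_helices > len(corners):
        raise ValueError("toy bundle supports at most 4 helices")

    base: list[dict] = []
    sse_rows = []
    for h in range(n_helices):
        start = h * res_per_helix + 1
        base.extend(_helix_backbone(corners[h], res_per_helix, start, "A"))
        for i in range(res_per_helix):
            key = residue_key("A", start + i)
            sse_rows.append(
                {
                    "residue": key,
                    "gpcrdb": f"{h + 1}x{30 + i}",
                    "sse": f"H{h + 1}",
                    "is_terminus": i == 0 or i == res_per_helix - 1,
                }
            )
    annotation = pd.DataFrame(sse_rows)

    ca_by_key = {
        residue_key(a["chain"], a["res_id"]): a["coord"]
        for a in base
        if a["atom_name"] == "CA"
    }
    for a, b, state in rewiring.contacts:
        for k in (a, b):
            if k not in ca_by_key:
                raise ValueError(f"programmed contact names unknown residue {k}")
        if state not in ("active_only", "inactive_only", "shared"):
            raise ValueError(f"unknown contact state '{state}'")

    def _with_probes(state_name: str) -> list[dict]:
        atoms = [dict(a, coord=a["coord"].copy()) for a in base]
        for a, b, state in rewiring.contacts:
            on = state == "shared" or state == f"{state_name}_only"
            ca_a, ca_b = ca_by_key[a], ca_by_key[b]
            u = ca_b - ca_a
            dist = np.linalg.norm(u)
            if dist < 7.5:
                raise ValueError(
                    f"infeasible geometry: residues {a},{b} only {dist:.1f} A apart"
                )
            u = u / dist
            mid = 0.5 * (ca_a + ca_b)
            if on:
                pos_a, pos_b = mid - 1.8 * u, mid + 1.8 * u
            else:
                pos_a, pos_b = ca_a + 1.5 * u, ca_b - 1.5 * u
            for key, pos in ((a, pos_a), (b, pos_b)):
                chain, rid = key.split(":")
                atoms.append(
                    dict(
                        chain=chain, res_id=int(rid), res_name="ALA",
                        atom_name="CG", element="C", coord=pos,
                    )
                )
        atoms.sort(key=lambda d: (d["chain"], d["res_id"]))
        return atoms

    active = StructureModel(_to_atom_array(_with_probes("active")), name="toy_active")
    inactive = StructureModel(
        _to_atom_array(_with_probes("inactive")), name="toy_inactive"
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for model, fname in ((active, "active.pdb"), (inactive, "inactive.pdb")):
            f = pdb_io.PDBFile()
            pdb_io.set_structure(f, model.receptor)
            f.write(str(out_dir / fname))
        annotation.to_csv(out_dir / "annotation.csv", index=False)
    return active, inactive, annotation


def generate_annotations(
    classes: dict[str, str],
    snp_rate_per_class: dict[str, float] | None = None,
    et_shift_per_class: dict[str, float] | None = None,
    et_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SNP presence and conservation-score tables with class-dependent effects.

    SNP presence is Bernoulli per residue with its class rate (default 0.2
    everywhere); conservation scores are Normal(5 + shift, et_sd) per residue
    at three phylogenetic levels (lower = more conserved).
    """
    snp_rate_per_class = snp_rate_per_class or {}
    et_shift_per_class = et_shift_per_class or {}
    for rate in snp_rate_per_class.values():
        if not 0.0 <= rate <= 1.0:
            raise ValueError("SNP rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    keys = sorted(classes)
    snp_rows, et_rows = [], []
    for k in keys:
        cls = classes[k]
        rate = snp_rate_per_class.get(cls, 0.2)
        shift = et_shift_per_class.get(cls, 0.0)
        snp_rows.append(
            {"residue": k, "variant_count": int(rng.random() < rate)}
        )
        et_rows.append(
            {
                "residue": k,
                "score_adrenergic": float(rng.normal(5.0 + shift, et_sd)),
                "score_amine": float(rng.normal(5.0 + shift, et_sd)),
                "score_classA": float(rng.normal(5.0 + shift, et_sd)),
            }
        )
    return pd.DataFrame(snp_rows), pd.DataFrame(et_rows)


def example_study() -> tuple[list[MutantTruth], RewiringTruth, dict[str, str]]:
    """A reference synthetic study covering every residue class.

    One mutant per residue of the default 4x20 toy bundle (``M<res_id>`` at
    residue ``A:<res_id>``), with programmed effects chosen to produce
    connected drivers (matched efficacy pair 5-25, both/potency pair 30-50),
    disconnected drivers (effect-mismatched pair 8-28, driver 45 facing a
    passenger), modulators (including a no-signal mutant at 12), passengers,
    a low-abundance exclusion (40), one gain of function (20) and bystanders.
    Returns (mutant truths, rewiring truth, mutant_id -> residue map).
    """
    rewiring = RewiringTruth(
        (
            ("A:5", "A:25", "active_only"),
            ("A:8", "A:28", "active_only"),
            ("A:30", "A:50", "active_only"),
            ("A:45", "A:65", "active_only"),
            ("A:10", "A:70", "active_only"),
            ("A:15", "A:35", "inactive_only"),
            ("A:55", "A:75", "inactive_only"),
            ("A:18", "A:38", "shared"),
        )
    )
    effects: dict[int, dict] = {
        5: dict(amplitude_factor=0.40),
        25: dict(amplitude_factor=0.35),
        8: dict(delta_logec50=1.5),
        28: dict(amplitude_factor=0.40),
        30: dict(amplitude_factor=0.40, delta_logec50=1.5),
        50: dict(delta_logec50=1.2),
        45: dict(amplitude_factor=0.50),
        12: dict(amplitude_factor=0.0),  # no measurable signal
        15: dict(amplitude_factor=0.50),
        33: dict(delta_logec50=1.5),
        40: dict(abundance_pct=10.0),  # excluded for low surface abundance
        20: dict(amplitude_factor=1.6),  # gain of function
    }
    truths = [
        MutantTruth(mutant_id=f"M{r}", **effects.get(r, {})) for r in range(1, 81)
    ]
    mutant_map = {f"M{r}": f"A:{r}" for r in range(1, 81)}
    return truths, rewiring, mutant_map


def intended_classes(
    truths: list[MutantTruth],
    rewiring: RewiringTruth,
    mutant_to_residue: dict[str, str],
    wt: WtParams = WtParams(),
    cutoffs: PharmacologyCutoffs | None = None,
) -> dict[str, str]:
    """Ground-truth residue classes implied by the programmed screen and
    rewiring (same definitional 2x2 + connectivity rule the classifier uses,
    evaluated on the noiseless truth)."""
    from .pharmacology import IMPORTANT_CALLS
    from .residue_classes import effect_type

    active_pairs = rewiring.by_state("active_only")
    active_res = {r for p in active_pairs for r in p}
    calls = {
        mutant_to_residue[t.mutant_id]: intended_call(t, wt, cutoffs)
        for t in truths
    }
    out = {}
    for res, call in calls.items():
        important = call in IMPORTANT_CALLS
        specific = res in active_res
        if call == "excluded_low_abundance":
            out[res] = "unclassified"
        elif important and specific:
            connected = any(
                (res in pair)
                and all(r in calls for r in pair)
                and all(calls[r] in IMPORTANT_CALLS for r in pair)
                and (
                    effect_type(calls[pair[0]]) & effect_type(calls[pair[1]])
                )
                for pair in active_pairs
            )
            out[res] = "connected_driver" if connected else "disconnected_driver"
        elif important:
            out[res] = "modulator"
        elif specific:
            out[res] = "passenger"
        else:
            out[res] = "bystander"
    return out
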