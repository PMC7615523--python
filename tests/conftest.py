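import numpy as np
import pandas as pd
import pytest
import yaml

import biotite.structure as struc

from allodecoder.structures import ResidueAnnotation
from allodecoder.synthetic import (
    RewiringTruth,
    example_study,
    generate_annotations,
    generate_screen,
    generate_structure_pair,
    intended_classes,
)


def make_atoms(specs):
    """Build an AtomArray from (chain, res_id, res_name, atom_name, element, xyz)."""
    arr = struc.AtomArray(len(specs))
    arr.chain_id = np.array([s[0] for s in specs])
    arr.res_id = np.array([s[1] for s in specs])
    arr.res_name = np.array([s[2] for s in specs])
    arr.atom_name = np.array([s[3] for s in specs])
    arr.element = np.array([s[4] for s in specs])
    arr.coord = np.array([s[5] for s in specs], dtype=float)
    arr.hetero = np.zeros(len(specs), dtype=bool)
    return arr


@pytest.fixture(scope="session")
def study():
    """The reference synthetic study: truths, rewiring, mutant->residue map."""
    return example_study()


@pytest.fixture(scope="session")
def bundle(study):
    """Toy two-state bundle realizing the reference rewiring truth."""
    _, rewiring, _ = study
    active, inactive, annot_df = generate_structure_pair(rewiring)
    return active, inactive, ResidueAnnotation.from_frame(annot_df)


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory, study):
    """All study inputs written to disk, plus a pipeline config YAML."""
    truths, rewiring, mmap = study
    td = tmp_path_factory.mktemp("study")
    curves, abundance = generate_screen(truths, noise_sd=0.0, seed=11)
    curves.to_csv(td / "curves.csv", index=False)
    abundance.to_csv(td / "abundance.csv", index=False)
    pd.DataFrame(
        {"mutant_id": list(mmap), "residue": list(mmap.values())}
    ).to_csv(td / "mutants.csv", index=False)
    generate_structure_pair(rewiring, out_dir=td)
    classes = intended_classes(truths, rewiring, mmap)
    snps, et = generate_annotations(classes, seed=5)
    snps.to_csv(td / "snps.csv", index=False)
    et.to_csv(td / "et.csv", index=False)
    cfg = dict(
        curves="curves.csv",
        abundance="abundance.csv",
        mutant_map="mutants.csv",
        active_structure="active.pdb",
        inactive_structure="inactive.pdb",
        annotation="annotation.csv",
        snps="snps.csv",
        et_scores="et.csv",
        sites={"ligand": ["A:5", "A:10"], "gprot": ["A:50"]},
    )
    (td / "run.yaml").write_text(yaml.safe_dump(cfg))
    return td
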