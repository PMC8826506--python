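"""A self-contained demonstration study.

Builds a coherent synthetic dataset in the shape of a small
receptor-evolution study — eight ligands assayed against six receptors
related by a tree, an alignment of two ancestral and six extant
sequences, and feeder-bout tables — and writes it plus a matching run
configuration to disk. Receptor parameters follow a sugar/amino-acid
trade-off gradient: the two early-diverging receptors respond strongly
to amino acids, the derived ones mostly to sugars, and one derived
receptor carries a planted sucrose x glycine synergy.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from . import io as tio
from .simulate import (
    HillParams,
    LigandDef,
    PlantedSite,
    ReceptorSimParams,
    generate_bout_data,
    generate_plate_dataset,
    generate_sequence_fixture,
    generate_tree,
)

__all__ = ["DEMO_PANEL", "demo_receptor_params", "write_demo"]

DEMO_PANEL = [
    LigandDef("sucralose", "sweetener", 100.0),
    LigandDef("sucrose", "sugar", 100.0),
    LigandDef("fructose", "sugar", 100.0),
    LigandDef("glucose", "sugar", 100.0),
    LigandDef("alanine", "amino_acid", 100.0),
    LigandDef("glycine", "amino_acid", 100.0),
    LigandDef("arginine", "amino_acid", 100.0),
    LigandDef("proline", "amino_acid", 100.0),
]

#: Tip receptors ordered from amino-acid-biased (early-diverging) to
#: sugar-biased (derived); values are (sugar E_max scale, amino E_max
#: scale, planted sucrose x glycine synergy gamma).
DEMO_RECEPTORS = {
    "hermit": (120.0, 110.0, 0.0),
    "jacobin": (130.0, 80.0, 0.0),
    "mango": (140.0, 45.0, 0.0),
    "coquette": (150.0, 30.0, 0.0),
    "giant": (150.0, 10.0, 0.0),
    "bee": (160.0, 25.0, 60.0),
}


def demo_receptor_params() -> dict:
    params = {}
    for rid, (sugar_emax, amino_emax, gamma) in DEMO_RECEPTORS.items():
        hill = {
            "sucralose": HillParams(sugar_emax * 1.2, 8.0, 1.5),
            "sucrose": HillParams(sugar_emax, 25.0, 1.5),
            "fructose": HillParams(sugar_emax * 0.6, 40.0, 1.5),
            "glucose": HillParams(sugar_emax * 0.5, 45.0, 1.5),
            "alanine": HillParams(amino_emax, 30.0, 1.5),
            "glycine": HillParams(amino_emax * 0.9, 35.0, 1.5),
            "arginine": HillParams(amino_emax * 0.8, 30.0, 1.5),
            "proline": HillParams(0.0, 50.0, 1.5),
        }
        synergy = {("sucrose", "glycine"): gamma} if gamma else {}
        params[rid] = ReceptorSimParams(
            hill=hill,
            baseline=5.0,
            synergy=synergy,
            batch_scale_sd=0.15,
            noise_sd=6.0,
        )
    return params


DEMO_PLANTED_SITES = [
    PlantedSite(column=12, anc1="D", anc2="K", extant="K"),  # passes all
    PlantedSite(column=30, anc1="I", anc2="V", extant="V"),  # fails BLOSUM
    PlantedSite(column=48, anc1="E", anc2="R", extant="R", extant_variants={2: "Q"}),
]

DEMO_BOUT_WEIGHTS = {
    "sucrose": 0.55,
    "fructose": 0.25,
    "glucose": 0.20,
    "alanine": 0.45,
    "proline": 0.08,
    "water": 0.05,
}

DEMO_BEHAVIOR_PAIRS = [
    ("sucrose", "fructose"),
    ("sucrose", "glucose"),
    ("alanine", "water"),
    ("proline", "water"),
]


def write_demo(out_dir, seed: int = 0) -> Path:
    """Generate the demo dataset and configuration under ``out_dir``.

    Returns the path of the written ``config.yaml``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = demo_receptor_params()

    records = generate_plate_dataset(
        DEMO_PANEL, params, n_replicates=6, n_batches=3, seed=seed
    )
    tio.write_plate_csv(records, out_dir / "plate.csv")

    tree = generate_tree(len(DEMO_RECEPTORS), seed=seed + 1, rate_sd=0.4)
    # order tips by tree ladder so early-diverging names sit together
    for leaf, rid in zip(tree.leaf_node_iter(), DEMO_RECEPTORS):
        leaf.taxon.label = rid
    tio.write_newick(tree, out_dir / "tree.nwk")

    fixture = generate_sequence_fixture(
        n_extant=len(DEMO_RECEPTORS),
        length=60,
        planted_sites=DEMO_PLANTED_SITES,
        seed=seed + 2,
    )
    names = list(DEMO_RECEPTORS)
    with open(out_dir / "alignment.fasta", "w") as fh:
        fh.write(f">anc1\n{fixture.anc1}\n>anc2\n{fixture.anc2}\n")
        for j, (key, seq) in enumerate(fixture.extant.items()):
            fh.write(f">{names[j]}\n{seq}\n")

    bouts = generate_bout_data(
        list(DEMO_BOUT_WEIGHTS),
        DEMO_BOUT_WEIGHTS,
        n_bouts=150,
        fps=60,
        seed=seed + 3,
    )
    with open(out_dir / "bouts.csv", "w") as fh:
        fh.write("stimulus,duration_s\n")
        for stim, sample in bouts.items():
            for d in sample.durations:
                fh.write(f"{stim},{d:.6f}\n")

    config = {
        "plate_csv": "plate.csv",
        "tree_newick": "tree.nwk",
        "alignment_fasta": "alignment.fasta",
        "bouts_csv": "bouts.csv",
        "out_dir": "results",
        "sugar_set": ["sucrose", "fructose", "glucose"],
        "amino_set": ["alanine", "glycine", "arginine", "proline"],
        "reference_ligand": "sucralose",
        "alpha": 0.05,
        "synergy_alpha": 0.01,
        "anc1_id": "anc1",
        "anc2_id": "anc2",
        "domain_ranges": {"VFT": [1, 40], "CRD": [41, 50], "TMD": [51, 60]},
        "behavior_pairs": [list(p) for p in DEMO_BEHAVIOR_PAIRS],
        "fps": 60,
        "seed": seed,
    }
    config_path = out_dir / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return config_path
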