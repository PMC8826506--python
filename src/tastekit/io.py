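"""File I/O, run configuration and the end-to-end pipeline.

Conventions used throughout: alignment columns are 1-based inclusive;
edge positions are fractions in [0, 1] measured from the parent node;
bout durations are seconds. Inputs are comma-separated UTF-8 with a
header row; tabular outputs are TSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import assay, behavior, chimera, phylo, synergy
from .simulate import UNTRANSFECTED, PlateRecord

__all__ = [
    "RunConfig",
    "read_newick",
    "write_newick",
    "read_plate_csv",
    "write_plate_csv",
    "read_alignment_fasta",
    "read_bouts_csv",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

PLATE_COLUMNS = [
    "receptor_id",
    "ligand_1",
    "conc_1_mM",
    "ligand_2",
    "conc_2_mM",
    "replicate",
    "batch",
    "response",
]


class NewickError(ValueError):
    pass


def read_newick(path) -> dendropy.Tree:
    """Read a rooted Newick tree, validating labels and branch lengths.

    Tips must be uniquely labeled and every non-root edge must carry a
    branch length (the Brownian-motion machinery requires them).
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", rooting="force-rooted"
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as err:
        raise NewickError(f"{path}: duplicate tip label ({err})") from None
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise NewickError(f"{path}: unlabeled tip")
        labels.append(leaf.taxon.label)
    dupes = {lab for lab in labels if labels.count(lab) > 1}
    if dupes:
        raise NewickError(f"{path}: duplicate tip labels {sorted(dupes)}")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            who = node.taxon.label if node.taxon else node.label or "<internal>"
            raise NewickError(f"{path}: missing branch length above {who!r}")
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True)
    )


class PlateCSVError(ValueError):
    pass


def read_plate_csv(path) -> list[PlateRecord]:
    """Read well records from CSV (documented schema, header required).

    Empty ligand_2 fields yield a single-ligand mix; both ligand fields
    empty yields a no-ligand control well. Non-numeric responses or
    concentrations raise with the offending line number.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PLATE_COLUMNS if c not in frame.columns]
    if missing:
        raise PlateCSVError(f"{path}: missing columns {missing}")
    records = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        mix = []
        for lig_col, conc_col in (("ligand_1", "conc_1_mM"), ("ligand_2", "conc_2_mM")):
            name = row[lig_col].strip()
            if not name:
                continue
            try:
                conc = float(row[conc_col])
            except ValueError:
                raise PlateCSVError(
                    f"{path}:{line}: non-numeric {conc_col} {row[conc_col]!r}"
                ) from None
            mix.append((name, conc))
        try:
            rec = PlateRecord(
                receptor_id=row["receptor_id"].strip(),
                mix=tuple(mix),
                replicate_id=int(row["replicate"]),
                batch_id=int(row["batch"]),
                response=float(row["response"]),
            )
        except ValueError as err:
            raise PlateCSVError(f"{path}:{line}: {err}") from None
        records.append(rec)
    return records


def write_plate_csv(records: Sequence[PlateRecord], path) -> None:
    rows = []
    for r in records:
        mix = list(r.mix) + [("", "")] * (2 - len(r.mix))
        rows.append(
            {
                "receptor_id": r.receptor_id,
                "ligand_1": mix[0][0],
                "conc_1_mM": mix[0][1],
                "ligand_2": mix[1][0],
                "conc_2_mM": mix[1][1],
                "replicate": r.replicate_id,
                "batch": r.batch_id,
                "response": repr(r.response),
            }
        )
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, index=False)


def read_alignment_fasta(path) -> dict:
    """Read an aligned FASTA file into an ordered {name: sequence} dict."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"{path}: no sequences")
    return seqs


def read_bouts_csv(path, fps: int = 60) -> dict:
    """Read bout tables: either (stimulus, start_frame, end_frame) video
    events or pre-computed (stimulus, duration_s) rows."""
    frame = pd.read_csv(path)
    if {"start_frame", "end_frame"}.issubset(frame.columns):
        events = list(
            frame[["stimulus", "start_frame", "end_frame"]].itertuples(index=False)
        )
        return behavior.extract_bouts(events, fps=fps)
    if "duration_s" in frame.columns:
        out = {}
        for stim, sub in frame.groupby("stimulus"):
            out[stim] = behavior.BoutSample(
                str(stim), sub["duration_s"].astype(float).tolist(), fps
            )
        return out
    raise ValueError(
        f"{path}: need either start_frame/end_frame or duration_s columns"
    )


@dataclass
class RunConfig:
    """Configuration of one pipeline run (see the demo YAML for a
    worked example)."""

    plate_csv: str
    tree_newick: str
    alignment_fasta: str
    bouts_csv: str
    out_dir: str
    sugar_set: list
    amino_set: list
    reference_ligand: str = assay.REFERENCE_LIGAND
    alpha: float = 0.05
    synergy_alpha: float = 0.01
    anc1_id: str = "anc1"
    anc2_id: str = "anc2"
    domain_ranges: dict = field(default_factory=dict)
    behavior_pairs: list = field(default_factory=list)
    fps: int = 60
    pca_mode: str = "covariance"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a config; relative paths are resolved against the YAML
        file's own directory."""
        path = Path(path)
        data = yaml.safe_load(path.read_text())
        cfg = cls(**data)
        for attr in (
            "plate_csv",
            "tree_newick",
            "alignment_fasta",
            "bouts_csv",
            "out_dir",
        ):
            p = Path(getattr(cfg, attr))
            if not p.is_absolute():
                setattr(cfg, attr, str(path.parent / p))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for attr in ("plate_csv", "tree_newick", "alignment_fasta", "bouts_csv"):
            p = Path(getattr(self, attr))
            if not p.exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")
        if set(self.sugar_set) & set(self.amino_set):
            raise ValueError("sugar_set and amino_set overlap")

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _summaries_frame(summaries) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "receptor_id": s.receptor_id,
                "mix": "+".join(f"{n}@{c:g}" for n, c in s.mix) or "none",
                "n": s.n,
                "mean": s.mean,
                "se": s.se,
                "p_raw": s.p_raw,
                "p_adj": s.p_adj,
                "is_agonist": s.is_agonist,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage over the configured inputs and write the outputs.

    Outputs (TSV/JSON under ``out_dir``): agonist calls, normalized
    profiles (with the across-receptor grand mean), synergy report,
    response index + ancestral states, phylogenetic PCA report, chimera
    candidates, behavior comparisons, plus ``manifest.json`` carrying
    the config hash and seed and ``run.log``. Reruns with an identical
    config are bit-identical. A stage failure aborts with the stage
    name; outputs written so far stay on disk and the manifest flags
    the run incomplete.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root_logger = logging.getLogger("tastekit")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)

    manifest = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "outputs": {},
        "status": "incomplete",
        "failed_stage": None,
    }
    manifest_path = out_dir / "manifest.json"

    def emit(name: str, filename: str) -> Path:
        manifest["outputs"][name] = filename
        return out_dir / filename

    stage = "load_inputs"
    try:
        records = read_plate_csv(config.plate_csv)
        tree = read_newick(config.tree_newick)
        alignment = read_alignment_fasta(config.alignment_fasta)
        bout_samples = read_bouts_csv(config.bouts_csv, fps=config.fps)

        transfected = [r for r in records if r.receptor_id != UNTRANSFECTED]
        untransfected = [r for r in records if r.receptor_id == UNTRANSFECTED]

        stage = "agonist_calls"
        t_sum = assay.summarize_responses(transfected)
        u_sum = assay.summarize_responses(untransfected)
        called = assay.test_agonists(t_sum, u_sum, alpha=config.alpha)
        _summaries_frame(called).to_csv(
            emit("agonists", "agonists.tsv"), sep="\t", index=False
        )

        stage = "normalized_profiles"
        profiles = {}
        for rid in sorted({r.receptor_id for r in transfected}):
            rec_sum = [s for s in called if s.receptor_id == rid]
            profiles[rid] = assay.normalize_profile(
                rec_sum, u_sum, config.reference_ligand
            )
        prof_rows = [
            {"receptor_id": rid, "ligand": lig, "normalized": val}
            for rid, prof in profiles.items()
            for lig, val in sorted(prof.values.items())
        ]
        grand = assay.grand_mean_profile(list(profiles.values()))
        prof_rows += [
            {
                "receptor_id": "grand_mean",
                "ligand": lig,
                "normalized": row["grand_mean"],
            }
            for lig, row in grand.iterrows()
        ]
        pd.DataFrame(prof_rows).to_csv(
            emit("profiles", "profiles.tsv"), sep="\t", index=False
        )

        stage = "synergy"
        syn_rows = []
        for rid in sorted(profiles):
            rec_pool = [r for r in transfected if r.receptor_id == rid]
            mixes = sorted({r.mix_key for r in rec_pool if len(r.mix) == 2})
            background = [r for r in untransfected if r.mix == ()]
            for mix in mixes:
                (name_a, conc_a), (name_b, conc_b) = mix
                group_a = [r for r in rec_pool if r.mix_key == ((name_a, conc_a),)]
                group_b = [r for r in rec_pool if r.mix_key == ((name_b, conc_b),)]
                group_mix = [r for r in rec_pool if r.mix_key == mix]
                if len(group_a) < 2 or len(group_b) < 2 or not background:
                    logger.warning(
                        "receptor %s mix %s: missing single-ligand wells", rid, mix
                    )
                    continue
                res = synergy.test_synergy(
                    group_mix, group_a, group_b, background, config.synergy_alpha
                )
                syn_rows.append(
                    {
                        "receptor_id": rid,
                        "component_1": f"{name_a}@{conc_a:g}",
                        "component_2": f"{name_b}@{conc_b:g}",
                        "observed_mean": res.observed_mean,
                        "additive_estimate": res.additive_estimate,
                        "excess": res.excess,
                        "p": res.p,
                        "synergistic": res.synergistic,
                    }
                )
        pd.DataFrame(
            syn_rows,
            columns=[
                "receptor_id",
                "component_1",
                "component_2",
                "observed_mean",
                "additive_estimate",
                "excess",
                "p",
                "synergistic",
            ],
        ).to_csv(emit("synergy", "synergy.tsv"), sep="\t", index=False)

        stage = "response_index"
        tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        index_values = {
            rid: phylo.response_index(prof, config.sugar_set, config.amino_set)
            for rid, prof in profiles.items()
            if rid in tip_labels
        }
        missing_tips = sorted(tip_labels - set(index_values))
        if missing_tips:
            raise ValueError(
                f"tree tips without assay profiles: {missing_tips}"
            )
        trait_map = phylo.bm_ancestral_states(tree, index_values)
        phylo.edge_trait_interpolation(tree, trait_map, n_points=25)
        trait_json = {
            "index": {k: v for k, v in sorted(trait_map.tip_values.items())},
            "ancestral_states": dict(sorted(trait_map.node_states.items())),
            "sigma2": trait_map.sigma2,
            "edges": [
                {
                    "parent": e.parent,
                    "child": e.child,
                    "fractions": e.fractions.tolist(),
                    "states": e.states.tolist(),
                }
                for e in trait_map.edge_samples
            ],
        }
        emit("trait_map", "trait_map.json").write_text(
            json.dumps(trait_json, indent=1, sort_keys=True)
        )

        stage = "phylo_pca"
        matrix = pd.DataFrame(
            {rid: profiles[rid].values for rid in sorted(index_values)}
        ).T.dropna(axis=1)
        pca = phylo.phylo_pca(tree, matrix, mode=config.pca_mode)
        pca_json = {
            "mode": pca.mode,
            "phylogenetic_mean": pca.mean.to_dict(),
            "eigenvalues": pca.eigenvalues.tolist(),
            "loadings": pca.loadings.to_dict(),
            "scores": pca.scores.to_dict(),
        }
        emit("phylo_pca", "phylo_pca.json").write_text(
            json.dumps(pca_json, indent=1, sort_keys=True)
        )

        stage = "chimera_screen"
        for key in (config.anc1_id, config.anc2_id):
            if key not in alignment:
                raise KeyError(f"alignment lacks ancestral sequence {key!r}")
        extant = {
            k: v
            for k, v in alignment.items()
            if k not in (config.anc1_id, config.anc2_id)
        }
        candidates = chimera.screen_candidates(
            alignment[config.anc1_id],
            alignment[config.anc2_id],
            extant,
            domain_ranges={
                k: tuple(v) for k, v in config.domain_ranges.items()
            },
        )
        pd.DataFrame(
            [asdict(c) for c in candidates],
            columns=[
                "column",
                "domain",
                "res_anc1",
                "res_anc2",
                "radical",
                "blosum",
                "conserved",
                "passes_all",
            ],
        ).to_csv(emit("chimera", "chimera.tsv"), sep="\t", index=False)

        stage = "behavior"
        pairs = [tuple(p) for p in config.behavior_pairs]
        reports = behavior.compare_stimuli(bout_samples, pairs)
        pd.DataFrame(
            [
                {
                    "stimulus_a": a,
                    "stimulus_b": b,
                    "D": rep.d,
                    "p": rep.p,
                    "method": rep.method,
                    "n": rep.n,
                    "m": rep.m,
                    "median_a_s": rep.median_x,
                    "median_b_s": rep.median_y,
                }
                for (a, b), rep in reports.items()
            ],
            columns=[
                "stimulus_a",
                "stimulus_b",
                "D",
                "p",
                "method",
                "n",
                "m",
                "median_a_s",
                "median_b_s",
            ],
        ).to_csv(emit("behavior", "behavior.tsv"), sep="\t", index=False)

        manifest["status"] = "complete"
    except Exception:
        manifest["failed_stage"] = stage
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        root_logger.removeHandler(handler)
        handler.close()
        raise
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    root_logger.removeHandler(handler)
    handler.close()
    return manifest
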