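"""Synthetic-data generators for every stage of the pipeline.

Each generator emulates one class of experimental input — heterologous
plate assays, phylogenies with rate-variable branch lengths, protein
alignments with planted candidate sites, and feeder-visit bout tables —
with known ground-truth parameters so that downstream estimators can be
tested for recovery, type-I error and power.

All generators are deterministic: the same seed and configuration
reproduce identical output.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "LigandDef",
    "HillParams",
    "ReceptorSimParams",
    "PlateRecord",
    "PlantedSite",
    "SequenceFixture",
    "BoutSample",
    "UNTRANSFECTED",
    "generate_plate_dataset",
    "generate_tree",
    "generate_sequence_fixture",
    "generate_bout_data",
]

#: Reserved receptor id for control wells carrying the signalling
#: machinery (G-protein + photoprotein) but no receptor.
UNTRANSFECTED = "UNTRANSFECTED"

#: Mixes whose summed concentration exceeds this (mM) show a small
#: receptor-independent response in control wells, as does histidine.
ARTIFACT_CONC_THRESHOLD_MM = 175.0

#: Size of the untransfected artifact relative to a typical maximal
#: receptor response ("small response" — set to 10% of E_max scale).
ARTIFACT_FRACTION = 0.10

LIGAND_CLASSES = ("sugar", "sweetener", "amino_acid", "control")


@dataclass(frozen=True)
class LigandDef:
    """One ligand of the assay panel.

    Parameters
    ----------
    name:
        Ligand name, unique within a panel.
    ligand_class:
        One of ``sugar``, ``sweetener``, ``amino_acid``, ``control``.
    default_concentration:
        Test concentration in mM. Sugars and the strong amino-acid
        agonists are conventionally tested at 100 mM, most other amino
        acids at 50 mM and leucine at 25 mM; controls carry 0.
    """

    name: str
    ligand_class: str
    default_concentration: float

    def __post_init__(self) -> None:
        if self.ligand_class not in LIGAND_CLASSES:
            raise ValueError(f"unknown ligand class {self.ligand_class!r}")
        if self.ligand_class != "control" and not self.default_concentration > 0:
            raise ValueError(
                f"ligand {self.name!r}: default_concentration must be > 0"
            )


@dataclass(frozen=True)
class HillParams:
    """Hill dose-response parameters for one receptor-ligand pair."""

    e_max: float  # maximal response above baseline, response units
    ec50: float  # half-maximal concentration, mM
    h: float = 1.5  # Hill coefficient

    def __post_init__(self) -> None:
        if self.e_max < 0:
            raise ValueError("e_max must be >= 0")
        if not self.ec50 > 0:
            raise ValueError("ec50 must be > 0")
        if not 0.5 <= self.h <= 10:
            raise ValueError("Hill coefficient must lie in [0.5, 10]")

    def occupancy(self, conc_mm: float) -> float:
        """Fractional receptor occupancy c^h / (EC50^h + c^h)."""
        if conc_mm <= 0:
            return 0.0
        ch = conc_mm**self.h
        return ch / (self.ec50**self.h + ch)

    def response(self, conc_mm: float) -> float:
        return self.e_max * self.occupancy(conc_mm)


@dataclass
class ReceptorSimParams:
    """Generative parameters for one simulated receptor.

    ``synergy`` maps unordered ligand-name pairs to a coefficient
    gamma >= 0 (response units); a mix of two ligands a, s adds
    ``gamma * min(occ_a, occ_s)`` on top of the additive Hill terms, so
    a sub-activating concentration of one partner can still potentiate
    the other. gamma = 0 means no interaction.
    """

    hill: Mapping[str, HillParams]
    baseline: float = 0.0  # B, receptor-dependent constitutive signal
    synergy: Mapping[frozenset, float] = field(default_factory=dict)
    batch_scale_sd: float = 0.15  # lognormal sigma of transfection efficiency
    noise_sd: float = 5.0  # homoscedastic Gaussian well noise

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if self.batch_scale_sd < 0:
            raise ValueError("batch_scale_sd must be >= 0")
        self.synergy = {frozenset(k): float(v) for k, v in self.synergy.items()}
        for pair, gamma in self.synergy.items():
            if gamma < 0:
                raise ValueError(f"synergy gamma for {sorted(pair)} must be >= 0")

    def gamma(self, name_a: str, name_b: str) -> float:
        return self.synergy.get(frozenset((name_a, name_b)), 0.0)


@dataclass(frozen=True)
class PlateRecord:
    """One well: a receptor (or untransfected control), a ligand mix of
    zero to two components, and its luminescence response."""

    receptor_id: str
    mix: tuple  # tuple of (ligand name, concentration mM); () = no-ligand
    replicate_id: int
    batch_id: int
    response: float

    def __post_init__(self) -> None:
        for _, conc in self.mix:
            if not conc > 0:
                raise ValueError("mix concentrations must be > 0")
        if len(self.mix) > 2:
            raise ValueError("a mix holds at most two ligands")

    @property
    def total_concentration(self) -> float:
        return sum(c for _, c in self.mix)

    @property
    def mix_key(self) -> tuple:
        """Canonical (order-independent) identifier of the mix."""
        return tuple(sorted(self.mix))


def _expected_response(
    params: ReceptorSimParams, mix: Sequence[tuple]
) -> float:
    """Noise-free transfected response to a mix (before batch scaling)."""
    total = params.baseline
    for name, conc in mix:
        hp = params.hill.get(name)
        if hp is not None:
            total += hp.response(conc)
    for (na, ca), (nb, cb) in itertools.combinations(mix, 2):
        gamma = params.gamma(na, nb)
        if gamma > 0:
            ha, hb = params.hill.get(na), params.hill.get(nb)
            if ha is not None and hb is not None:
                total += gamma * min(ha.occupancy(ca), hb.occupancy(cb))
    return total


def _mix_has_artifact(mix: Sequence[tuple]) -> bool:
    """Control wells respond only to histidine and to very concentrated
    sugar/amino-acid mixes (total above 175 mM)."""
    if any(name.lower() == "histidine" for name, _ in mix):
        return True
    return len(mix) >= 2 and sum(c for _, c in mix) > ARTIFACT_CONC_THRESHOLD_MM


def generate_plate_dataset(
    panel: Sequence[LigandDef],
    params: Mapping[str, ReceptorSimParams],
    n_replicates: int = 6,
    n_batches: int = 3,
    seed: int = 0,
    mixes: Sequence[Sequence[tuple]] | None = None,
    untransfected_background: float = 20.0,
) -> list[PlateRecord]:
    """Simulate a plate dataset of transfected and untransfected wells.

    Parameters
    ----------
    panel:
        Ligand definitions; names must be unique.
    params:
        Per-receptor simulation parameters. Every receptor must carry
        Hill parameters for every non-control panel ligand.
    n_replicates:
        Wells per (receptor, mix); must be >= 2 so that downstream
        tests have a variance estimate. Replicates are spread over
        ``n_batches`` independent transfections.
    mixes:
        Explicit list of mixes, each a sequence of (ligand name,
        concentration) pairs. Defaults to every non-control panel
        ligand alone at its default concentration, the no-ligand
        control, and every synergy pair declared by any receptor.
    untransfected_background:
        Mean response of control wells, response units.

    Returns
    -------
    list of PlateRecord, including an ``UNTRANSFECTED`` pseudo-receptor
    measured on the same mixes. Deterministic given (seed, inputs).

    Notes
    -----
    A transfected well reads ``background + batch_scale * (B + Hill
    terms + synergy term) + noise``: the receptor-independent plate
    background is shared additively with control wells, and only the
    receptor-driven signal scales with transfection efficiency — which
    is what lets sucralose normalization of background-subtracted
    means cancel the batch factor exactly.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2 (tests need variance)")
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    names = [lig.name for lig in panel]
    if len(set(names)) != len(names):
        raise ValueError("panel ligand names must be unique")
    panel_by_name = {lig.name: lig for lig in panel}
    for rid, p in params.items():
        missing = [
            lig.name
            for lig in panel
            if lig.ligand_class != "control" and lig.name not in p.hill
        ]
        if missing:
            raise ValueError(
                f"receptor {rid!r} lacks Hill parameters for {missing}"
            )

    if mixes is None:
        mix_list: list[tuple] = [()]
        for lig in panel:
            if lig.ligand_class != "control":
                mix_list.append(((lig.name, lig.default_concentration),))
        seen = {tuple(sorted(m)) for m in mix_list}
        for p in params.values():
            for pair in sorted(p.synergy, key=sorted):
                mix = tuple(
                    (n, panel_by_name[n].default_concentration)
                    for n in sorted(pair)
                )
                if tuple(sorted(mix)) not in seen:
                    mix_list.append(mix)
                    seen.add(tuple(sorted(mix)))
    else:
        mix_list = [tuple(m) for m in mixes]

    artifact_scale = ARTIFACT_FRACTION * max(
        (hp.e_max for p in params.values() for hp in p.hill.values()),
        default=0.0,
    )

    rng = np.random.default_rng(seed)
    records: list[PlateRecord] = []

    for rid in sorted(params):
        p = params[rid]
        batch_scales = np.exp(rng.normal(0.0, p.batch_scale_sd, size=n_batches))
        for mix in mix_list:
            mu = _expected_response(p, mix)
            for rep in range(n_replicates):
                batch = rep % n_batches
                resp = (
                    untransfected_background
                    + batch_scales[batch] * mu
                    + rng.normal(0.0, p.noise_sd)
                )
                records.append(
                    PlateRecord(rid, tuple(mix), rep, batch, float(resp))
                )

    # control wells share the noise scale of the panel (median receptor)
    ctrl_noise = float(np.median([p.noise_sd for p in params.values()]))
    for mix in mix_list:
        mu = untransfected_background
        if _mix_has_artifact(mix):
            mu += artifact_scale
        for rep in range(n_replicates):
            resp = mu + rng.normal(0.0, ctrl_noise)
            records.append(
                PlateRecord(
                    UNTRANSFECTED, tuple(mix), rep, rep % n_batches, float(resp)
                )
            )
    return records


def generate_tree(
    n_tips: int, seed: int = 0, rate_sd: float = 0.5
) -> dendropy.Tree:
    """Sample a rooted pure-birth tree with rate-variable branch lengths.

    Topology and node times come from a Yule process (unit birth rate,
    started from two lineages, stopped at ``n_tips`` with a final
    exponential hang time). Each branch's duration is then multiplied
    by an independent lognormal rate factor with log-sd ``rate_sd``,
    producing non-ultrametric, substitution-rate-like branch lengths;
    ``rate_sd = 0`` leaves the tree ultrametric.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    root = tree.seed_node
    left, right = dendropy.Node(), dendropy.Node()
    root.add_child(left)
    root.add_child(right)
    active = [left, right]
    birth_times = {left: 0.0, right: 0.0}

    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        idx = rng.integers(len(active))
        parent = active.pop(int(idx))
        parent.edge.length = t - birth_times.pop(parent)
        for _ in range(2):
            child = dendropy.Node()
            parent.add_child(child)
            birth_times[child] = t
            active.append(child)
    t += rng.exponential(1.0 / len(active))
    for node in active:
        node.edge.length = t - birth_times[node]

    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(label=f"t{i}")

    if rate_sd > 0:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= float(
                    np.exp(rng.normal(-0.5 * rate_sd**2, rate_sd))
                )
    tree.seed_node.edge.length = None
    return tree


_CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

# physicochemical partition used to call a substitution "radical"
_AA_CLASS = {}
for _cls, _members in {
    "hydrophobic": "AVLIMFWY",
    "polar": "STNQ",
    "positive": "KRH",
    "negative": "DE",
    "special": "GCP",
}.items():
    for _aa in _members:
        _AA_CLASS[_aa] = _cls

# BLOSUM62 entries needed by the generator's own truth computation are
# looked up lazily from Biopython to avoid drift from the standard matrix
_BLOSUM62 = None


def _blosum62(a: str, b: str) -> int:
    global _BLOSUM62
    if _BLOSUM62 is None:
        from Bio.Align import substitution_matrices

        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return int(_BLOSUM62[a][b])


@dataclass(frozen=True)
class PlantedSite:
    """Specification of one alignment column with a designed
    ancestral difference.

    ``extant`` is the residue carried by every extant sequence unless
    ``extant_variants`` plants deviations (sequence index -> residue),
    e.g. to break conservation on purpose.
    """

    column: int  # 1-based
    anc1: str
    anc2: str
    extant: str
    extant_variants: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for res in (self.anc1, self.anc2, self.extant, *self.extant_variants.values()):
            if res != "-" and res not in _CANONICAL_AA:
                raise ValueError(f"residue {res!r} is not a canonical amino acid")


@dataclass
class SequenceFixture:
    """A generated alignment plus its ground truth.

    ``truth`` maps 1-based columns where the two ancestors differ to a
    dict with keys ``radical``, ``blosum``, ``conserved`` and
    ``passes_all`` (the conjunction), computed from the generator's own
    class partition and the standard BLOSUM62 matrix.
    """

    anc1: str
    anc2: str
    extant: dict  # name -> aligned sequence
    truth: dict  # column -> criteria dict


def generate_sequence_fixture(
    n_extant: int,
    length: int,
    planted_sites: Sequence[PlantedSite] = (),
    seed: int = 0,
) -> SequenceFixture:
    """Build an ungapped protein alignment of two ancestral sequences
    and ``n_extant`` extant sequences with planted differing columns.

    Background columns are identical across all sequences; each planted
    site sets the two ancestral residues and the extant residues, and
    the returned truth table records which screening criteria (radical
    class change, BLOSUM62 <= 0, extant conservation at the anc2
    residue) each differing column satisfies.
    """
    if n_extant < 1:
        raise ValueError("n_extant must be >= 1")
    by_col = {}
    for site in planted_sites:
        if not 1 <= site.column <= length:
            raise ValueError(f"planted column {site.column} outside [1, {length}]")
        if site.column in by_col:
            raise ValueError(f"duplicate planted column {site.column}")
        by_col[site.column] = site

    rng = np.random.default_rng(seed)
    background = rng.choice(list(_CANONICAL_AA), size=length)

    anc1 = list(background)
    anc2 = list(background)
    extant_rows = [list(background) for _ in range(n_extant)]
    for col, site in by_col.items():
        i = col - 1
        anc1[i] = site.anc1
        anc2[i] = site.anc2
        for j, row in enumerate(extant_rows):
            row[i] = site.extant_variants.get(j, site.extant)

    truth = {}
    for col, site in sorted(by_col.items()):
        if site.anc1 == site.anc2 or "-" in (site.anc1, site.anc2):
            continue
        radical = _AA_CLASS[site.anc1] != _AA_CLASS[site.anc2]
        blosum = _blosum62(site.anc1, site.anc2)
        col_res = [row[col - 1] for row in extant_rows]
        conserved = all(res == site.anc2 for res in col_res)
        truth[col] = {
            "radical": radical,
            "blosum": blosum,
            "conserved": conserved,
            "passes_all": radical and blosum <= 0 and conserved,
        }

    extant = {
        f"extant_{j + 1}": "".join(row) for j, row in enumerate(extant_rows)
    }
    return SequenceFixture("".join(anc1), "".join(anc2), extant, truth)


@dataclass
class BoutSample:
    """Drinking-bout durations for one stimulus.

    Durations are in seconds; when frame-derived each is an integer
    multiple of 1/fps.
    """

    stimulus_id: str
    durations: list
    fps: int = 60

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.durations):
            raise ValueError("bout durations must be positive")

    @property
    def median(self) -> float:
        return float(np.median(self.durations)) if self.durations else math.nan


#: Lognormal components of the bout-duration mixture: brief sampling
#: visits with a ~0.2 s mode and appetitive drinking bouts with a
#: ~1.5 s mode (longer bouts observed less frequently).
SHORT_BOUT_LOG_MODE = math.log(0.2)
LONG_BOUT_LOG_MODE = math.log(1.5)
BOUT_LOG_SD = 0.35


def generate_bout_data(
    stimuli: Sequence[str],
    mix_weights: Mapping[str, float],
    n_bouts: int = 200,
    fps: int = 60,
    seed: int = 0,
) -> dict:
    """Simulate feeder-visit bout durations per stimulus.

    ``mix_weights[s]`` is the probability that a visit to stimulus
    ``s`` is a long appetitive bout rather than a brief sampling bout.
    Durations are drawn from the two-component lognormal mixture and
    quantized to the video frame interval 1/fps (minimum one frame).
    ``n_bouts = 0`` yields empty samples.
    """
    if fps <= 0:
        raise ValueError("fps must be > 0")
    rng = np.random.default_rng(seed)
    out = {}
    for stim in stimuli:
        w = float(mix_weights[stim])
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"mix weight for {stim!r} must lie in [0, 1]")
        if n_bouts == 0:
            out[stim] = BoutSample(stim, [], fps)
            continue
        is_long = rng.random(n_bouts) < w
        log_mode = np.where(is_long, LONG_BOUT_LOG_MODE, SHORT_BOUT_LOG_MODE)
        raw = np.exp(rng.normal(log_mode, BOUT_LOG_SD))
        frames = np.maximum(1, np.rint(raw * fps).astype(int))
        out[stim] = BoutSample(stim, (frames / fps).tolist(), fps)
    return out
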