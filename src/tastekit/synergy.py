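"""Sugar x amino-acid synergy testing against an additive-response proxy.

A true additive expectation for a two-ligand mix is hard to measure, so
the estimated additive response is the sum of each ligand's response
alone minus one no-ligand background (counted once, keeping the proxy on
the raw single-well scale). The observed mix response is compared with
a replicate-paired additive pseudo-sample by Welch's two-tailed t-test;
a mix is called synergistic only when the test rejects AND the excess
(observed minus additive) is positive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .assay import holm_adjust
from .simulate import UNTRANSFECTED, PlateRecord

__all__ = [
    "SynergyResult",
    "DoseLevelResult",
    "additive_estimate",
    "test_synergy",
    "synergy_dose_profile",
]

logger = logging.getLogger(__name__)

#: Default alpha for the panel screen; dose profiles use 0.05.
PANEL_ALPHA = 0.01
DOSE_ALPHA = 0.05


@dataclass
class SynergyResult:
    """Outcome of one mix-vs-additive comparison."""

    sugar: tuple  # (name, mM)
    amino_acid: tuple  # (name, mM)
    observed_mean: float
    additive_estimate: float
    excess: float  # observed - additive
    p: float  # Welch two-tailed
    n_obs: int
    n_components: int  # paired pseudo-sample size
    synergistic: bool


@dataclass
class DoseLevelResult:
    """One rung of an amino-acid concentration ladder: the synergy call
    for sugar + amino at this level, plus whether the amino acid alone
    is an agonist here (so "synergy without solo activation" is a
    directly queryable outcome)."""

    concentration: float
    synergy: SynergyResult
    solo_agonist: bool
    solo_p_adj: float


def additive_estimate(mean_a: float, mean_s: float, background: float) -> float:
    """Additive-response proxy: sum of the two single-ligand responses
    minus the no-ligand untransfected background, counted once."""
    for v in (mean_a, mean_s, background):
        if not math.isfinite(v):
            raise ValueError("inputs must be finite")
    return mean_a + mean_s - background


def _paired_pseudo_sample(
    a_records: Sequence[PlateRecord],
    s_records: Sequence[PlateRecord],
    background_mean: float,
) -> np.ndarray:
    """Replicate-wise additive sample a_i + s_i - mean(bg).

    Pairing is within transfection batch, then by sorted replicate
    index, so the batch factor common to both single-ligand wells is
    carried into each pseudo-replicate. Unequal counts are truncated
    to the shorter side with a logged warning.
    """
    by_batch_a: dict = {}
    by_batch_s: dict = {}
    for r in a_records:
        by_batch_a.setdefault(r.batch_id, []).append(r)
    for r in s_records:
        by_batch_s.setdefault(r.batch_id, []).append(r)

    pseudo = []
    leftovers_a: list[PlateRecord] = []
    leftovers_s: list[PlateRecord] = []
    for batch in sorted(set(by_batch_a) | set(by_batch_s)):
        aa = sorted(by_batch_a.get(batch, []), key=lambda r: r.replicate_id)
        ss = sorted(by_batch_s.get(batch, []), key=lambda r: r.replicate_id)
        k = min(len(aa), len(ss))
        pseudo.extend(
            aa[i].response + ss[i].response - background_mean for i in range(k)
        )
        leftovers_a.extend(aa[k:])
        leftovers_s.extend(ss[k:])
    # cross-batch pairing as a fallback for unbalanced designs
    k = min(len(leftovers_a), len(leftovers_s))
    if k:
        leftovers_a.sort(key=lambda r: (r.batch_id, r.replicate_id))
        leftovers_s.sort(key=lambda r: (r.batch_id, r.replicate_id))
        pseudo.extend(
            leftovers_a[i].response + leftovers_s[i].response - background_mean
            for i in range(k)
        )
    dropped = max(len(leftovers_a), len(leftovers_s)) - k
    if dropped:
        logger.warning(
            "unequal single-ligand replicate counts; %d wells unpaired", dropped
        )
    return np.asarray(pseudo, dtype=float)


def test_synergy(
    mix_records: Sequence[PlateRecord],
    single_a_records: Sequence[PlateRecord],
    single_s_records: Sequence[PlateRecord],
    background_records: Sequence[PlateRecord],
    alpha: float = PANEL_ALPHA,
) -> SynergyResult:
    """Welch two-tailed test of a mix sample against its additive
    pseudo-sample.

    All record groups need >= 2 replicates. The synergistic flag
    requires both p < alpha and positive excess; a significant negative
    excess (sub-additivity) is reported but not flagged.
    """
    if min(len(mix_records), len(single_a_records), len(single_s_records)) < 2:
        raise ValueError("each well group needs >= 2 replicates")
    if len(background_records) < 1:
        raise ValueError("background (no-ligand untransfected) wells required")

    bg_mean = float(np.mean([r.response for r in background_records]))
    pseudo = _paired_pseudo_sample(single_a_records, single_s_records, bg_mean)
    observed = np.asarray([r.response for r in mix_records], dtype=float)

    res = stats.ttest_ind(observed, pseudo, equal_var=False)
    excess = float(observed.mean() - pseudo.mean())

    mix = mix_records[0].mix_key
    names_a = {r.mix_key for r in single_a_records}
    names_s = {r.mix_key for r in single_s_records}
    comp_a = next(iter(names_a))[0] if len(names_a) == 1 else ("?", math.nan)
    comp_s = next(iter(names_s))[0] if len(names_s) == 1 else ("?", math.nan)
    # report the sugar slot / amino slot in mix order when resolvable
    sugar, amino = sorted([comp_a, comp_s])
    return SynergyResult(
        sugar=sugar,
        amino_acid=amino,
        observed_mean=float(observed.mean()),
        additive_estimate=float(pseudo.mean()),
        excess=excess,
        p=float(res.pvalue),
        n_obs=observed.size,
        n_components=pseudo.size,
        synergistic=bool(res.pvalue < alpha and excess > 0),
    )


def synergy_dose_profile(
    records: Iterable[PlateRecord],
    receptor_id: str,
    sugar: tuple,
    amino_acid: str,
    ladder: Sequence[float],
    alpha: float = DOSE_ALPHA,
) -> list[DoseLevelResult]:
    """Profile synergy along an amino-acid concentration ladder at a
    fixed sugar concentration.

    For each ladder level c the mix (sugar, amino@c) is tested against
    its additive proxy, and the amino acid alone at c is tested as an
    agonist (one-tailed Welch vs untransfected wells with the same mix,
    Holm-adjusted across the ladder). Levels missing solo amino-acid
    data are skipped with a warning.

    ``sugar`` is a (name, concentration mM) pair; ``ladder`` must be
    ascending with >= 3 levels.
    """
    ladder = list(ladder)
    if len(ladder) < 3:
        raise ValueError("ladder needs >= 3 concentration levels")
    if sorted(ladder) != ladder:
        raise ValueError("ladder must be sorted ascending")

    recs = list(records)
    trans = [r for r in recs if r.receptor_id == receptor_id]
    ctrl = [r for r in recs if r.receptor_id == UNTRANSFECTED]

    def group(pool, mix_key):
        return [r for r in pool if r.mix_key == mix_key]

    sugar_key = tuple(sorted([sugar]))
    sugar_solo = group(trans, sugar_key)
    background = group(ctrl, ())

    levels = []
    for c in ladder:
        amino_key = ((amino_acid, c),)
        mix_key = tuple(sorted([sugar, (amino_acid, c)]))
        amino_solo = group(trans, amino_key)
        mix_wells = group(trans, mix_key)
        if len(amino_solo) < 2 or len(mix_wells) < 2:
            logger.warning(
                "ladder level %g mM: missing solo or mix wells; skipped", c
            )
            continue
        syn = test_synergy(mix_wells, amino_solo, sugar_solo, background, alpha)
        syn.sugar = sugar
        syn.amino_acid = (amino_acid, c)
        levels.append((c, syn, amino_solo, amino_key))

    # solo-agonist calls, Holm-adjusted across the ladder family
    solo_p = []
    for c, _, amino_solo, amino_key in levels:
        ctrl_wells = group(ctrl, amino_key) or background
        res = stats.ttest_ind(
            [r.response for r in amino_solo],
            [r.response for r in ctrl_wells],
            equal_var=False,
            alternative="greater",
        )
        solo_p.append(res.pvalue)
    solo_adj = holm_adjust(solo_p)

    return [
        DoseLevelResult(
            concentration=c,
            synergy=syn,
            solo_agonist=bool(p_adj < alpha),
            solo_p_adj=float(p_adj),
        )
        for (c, syn, _, _), p_adj in zip(levels, solo_adj)
    ]
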