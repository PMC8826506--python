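"""Agonist calling and response normalization for plate assays.

Raw luminescence wells are summarized per (receptor, ligand mix) group;
agonists are called by one-tailed Welch t-tests against untransfected
controls presented with the same mix, Holm-adjusted within each
receptor's family of tested mixes; profiles are normalized by the
sucralose response to cancel transfection-efficiency differences; and
dose series are summarized by bounded Hill fits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import UNTRANSFECTED, PlateRecord

__all__ = [
    "ResponseSummary",
    "NormalizedProfile",
    "HillFit",
    "holm_adjust",
    "summarize_responses",
    "test_agonists",
    "normalize_profile",
    "grand_mean_profile",
    "fit_hill",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
REFERENCE_LIGAND = "sucralose"


@dataclass
class ResponseSummary:
    """Mean response of one (receptor, mix) group, with test results.

    ``se`` is the standard error (sample SD / sqrt(n)); groups with a
    single replicate carry ``se = nan`` and are excluded from testing.
    ``p_raw``/``p_adj`` are filled by :func:`test_agonists`.
    """

    receptor_id: str
    mix: tuple
    n: int
    mean: float
    se: float
    p_raw: float = math.nan
    p_adj: float = math.nan
    is_agonist: bool = False

    @property
    def sd(self) -> float:
        return self.se * math.sqrt(self.n)

    @property
    def testable(self) -> bool:
        return self.n >= 2 and math.isfinite(self.se)


def summarize_responses(records: Iterable[PlateRecord]) -> list[ResponseSummary]:
    """Group wells by (receptor, canonical mix) and compute mean +/- SE.

    Single-replicate groups are reported with ``se = nan`` (untestable)
    rather than dropped. Empty input yields an empty list.
    """
    groups: dict = {}
    for rec in records:
        groups.setdefault((rec.receptor_id, rec.mix_key), []).append(rec.response)
    out = []
    for (rid, mix), values in sorted(groups.items()):
        arr = np.asarray(values, dtype=float)
        n = arr.size
        mean = float(arr.mean())
        se = float(arr.std(ddof=1) / math.sqrt(n)) if n >= 2 else math.nan
        out.append(ResponseSummary(rid, mix, n, mean, se))
    return out


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment: p_adj_(i) = max_{j<=i} min(1, (m-j+1) p_(j))."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    order = np.argsort(p, kind="stable")
    m = p.size
    stepped = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj = np.maximum.accumulate(stepped)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def test_agonists(
    transfected: Sequence[ResponseSummary],
    untransfected: Sequence[ResponseSummary],
    alpha: float = DEFAULT_ALPHA,
) -> list[ResponseSummary]:
    """Call agonists: Welch's one-tailed t-test per mix, Holm per receptor.

    Each transfected group is compared against the untransfected group
    that received the same mix, with alternative "transfected mean is
    greater". Raw p-values are Holm-adjusted within the family of all
    testable mixes of one receptor; ``is_agonist`` marks adjusted
    p < alpha. Mixes lacking an untransfected counterpart (or with < 2
    replicates on either side) are skipped with a warning and keep
    ``p_raw = nan``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    controls = {s.mix: s for s in untransfected}
    results = [replace(s) for s in transfected]

    by_receptor: dict = {}
    for s in results:
        by_receptor.setdefault(s.receptor_id, []).append(s)

    for rid, group in sorted(by_receptor.items()):
        tested = []
        for s in group:
            ctrl = controls.get(s.mix)
            if ctrl is None:
                logger.warning(
                    "receptor %s mix %s: no untransfected counterpart; skipped",
                    rid,
                    s.mix,
                )
                continue
            if not (s.testable and ctrl.testable):
                logger.warning(
                    "receptor %s mix %s: <2 replicates; untestable", rid, s.mix
                )
                continue
            tested.append((s, ctrl))
        if not tested:
            continue
        res = stats.ttest_ind_from_stats(
            mean1=np.array([s.mean for s, _ in tested]),
            std1=np.array([s.sd for s, _ in tested]),
            nobs1=np.array([s.n for s, _ in tested]),
            mean2=np.array([c.mean for _, c in tested]),
            std2=np.array([c.sd for _, c in tested]),
            nobs2=np.array([c.n for _, c in tested]),
            equal_var=False,
            alternative="greater",
        )
        p_adj = holm_adjust(res.pvalue)
        for (s, _), praw, padj in zip(tested, res.pvalue, p_adj):
            s.p_raw = float(praw)
            s.p_adj = float(padj)
            s.is_agonist = bool(padj < alpha)
    return results


def null_fwer_simulation(
    n_panels: int = 2000,
    n_mixes: int = 20,
    n: int = 6,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> float:
    """Family-wise false-positive rate of the agonist caller under a
    global null.

    Each panel draws transfected and untransfected responses for
    ``n_mixes`` ligand mixes from the same Gaussian (n wells per
    group), runs :func:`test_agonists` with Holm adjustment, and counts
    panels with at least one agonist call. With valid one-tailed tests
    and Holm step-down the returned fraction should not exceed alpha.
    """
    rng = np.random.default_rng(seed)
    mixes = [((f"lig{i}", 100.0),) for i in range(n_mixes)]
    hits = 0
    for _ in range(n_panels):
        t = rng.normal(size=(n_mixes, n))
        u = rng.normal(size=(n_mixes, n))
        t_sum = [
            ResponseSummary(
                "R", mixes[i], n, float(t[i].mean()),
                float(t[i].std(ddof=1) / math.sqrt(n)),
            )
            for i in range(n_mixes)
        ]
        u_sum = [
            ResponseSummary(
                UNTRANSFECTED, mixes[i], n, float(u[i].mean()),
                float(u[i].std(ddof=1) / math.sqrt(n)),
            )
            for i in range(n_mixes)
        ]
        called = test_agonists(t_sum, u_sum, alpha=alpha)
        hits += any(s.is_agonist for s in called)
    return hits / n_panels


class NormalizationError(ValueError):
    """Reference-ligand response not above background."""


@dataclass
class NormalizedProfile:
    """Per-receptor ligand responses on the sucralose scale.

    ``values[ligand]`` is the background-subtracted mean divided by the
    background-subtracted reference (sucralose) mean, so the value at
    the reference ligand is exactly 1 and the profile is invariant to
    any multiplicative transfection-efficiency factor shared by the
    receptor's wells.
    """

    receptor_id: str
    values: dict
    reference_ligand: str = REFERENCE_LIGAND


def _singleton_ligand(mix: tuple) -> str | None:
    return mix[0][0] if len(mix) == 1 else None


def _background_for(
    mix: tuple, controls: Mapping[tuple, ResponseSummary]
) -> float | None:
    """Untransfected mean for this mix, falling back to the no-ligand
    control when the mix lacks dedicated untransfected wells."""
    ctrl = controls.get(mix)
    if ctrl is None:
        ctrl = controls.get(())
    return None if ctrl is None else ctrl.mean


def normalize_profile(
    summaries: Sequence[ResponseSummary],
    untransfected_summaries: Sequence[ResponseSummary],
    reference_ligand: str = REFERENCE_LIGAND,
) -> NormalizedProfile:
    """Normalize one receptor's single-ligand responses by its
    reference-ligand (sucralose) response.

    value(ligand) = (mean_ligand - bg_ligand) / (mean_ref - bg_ref)
    with per-mix untransfected backgrounds. Negative numerators are
    preserved. Raises :class:`NormalizationError` when the reference
    response does not exceed its background.
    """
    receptor_ids = {s.receptor_id for s in summaries}
    if len(receptor_ids) != 1:
        raise ValueError("normalize_profile expects exactly one receptor")
    (rid,) = receptor_ids
    controls = {s.mix: s for s in untransfected_summaries}

    ref_summary = None
    singles = {}
    for s in summaries:
        name = _singleton_ligand(s.mix)
        if name is None:
            continue
        singles[name] = s
        if name == reference_ligand:
            ref_summary = s
    if ref_summary is None:
        raise NormalizationError(
            f"receptor {rid!r}: reference ligand {reference_ligand!r} missing"
        )
    ref_bg = _background_for(ref_summary.mix, controls)
    if ref_bg is None:
        raise NormalizationError(
            f"receptor {rid!r}: no untransfected background for reference"
        )
    denom = ref_summary.mean - ref_bg
    if denom <= 0:
        raise NormalizationError(
            f"receptor {rid!r}: reference response {ref_summary.mean:.3g} "
            f"not above background {ref_bg:.3g}"
        )

    values = {}
    for name, s in singles.items():
        bg = _background_for(s.mix, controls)
        if bg is None:
            logger.warning("receptor %s ligand %s: no background; dropped", rid, name)
            continue
        values[name] = (s.mean - bg) / denom
    values[reference_ligand] = 1.0
    return NormalizedProfile(rid, values, reference_ligand)


def grand_mean_profile(
    profiles: Sequence[NormalizedProfile],
) -> pd.DataFrame:
    """Unweighted grand mean +/- SE of normalized values across receptors.

    Ligands missing from some profiles are averaged over the receptors
    that carry them, with the count reported in column ``n``.
    Requires >= 2 profiles sharing at least one ligand.
    """
    if len(profiles) < 2:
        raise ValueError("grand mean requires >= 2 profiles")
    frame = pd.DataFrame({p.receptor_id: p.values for p in profiles})
    frame = frame.dropna(how="all")
    if frame.empty:
        raise ValueError("profiles share no ligands")
    n = frame.notna().sum(axis=1)
    mean = frame.mean(axis=1)
    se = frame.std(axis=1, ddof=1) / np.sqrt(n)
    out = pd.DataFrame({"grand_mean": mean, "se": se, "n": n})
    out.index.name = "ligand"
    return out


@dataclass(frozen=True)
class HillFit:
    """Bounded least-squares Hill fit B + E_max c^h / (EC50^h + c^h)."""

    e_max: float
    ec50: float
    h: float
    baseline: float
    rss: float
    converged: bool

    def predict(self, conc: np.ndarray) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        ch = np.power(conc, self.h, where=conc > 0, out=np.zeros_like(conc))
        return self.baseline + self.e_max * ch / (self.ec50**self.h + ch)


def _hill_residuals(theta: np.ndarray, conc: np.ndarray, resp: np.ndarray):
    b, emax, log_ec50, h = theta
    ch = np.power(conc, h, where=conc > 0, out=np.zeros_like(conc))
    return b + emax * ch / (np.exp(log_ec50 * h) + ch) - resp


def fit_hill(dose_series: Sequence[tuple]) -> HillFit:
    """Fit a four-parameter Hill curve to (concentration mM, response) pairs.

    Multi-start bounded least squares: baseline and E_max start from
    response quantiles, EC50 from concentration quantiles, and the Hill
    coefficient from {0.8, 1.5, 3}; the best residual sum of squares
    wins. Requires >= 4 distinct concentrations and finite responses.
    A flat series converges with E_max near 0.
    """
    conc = np.asarray([c for c, _ in dose_series], dtype=float)
    resp = np.asarray([r for _, r in dose_series], dtype=float)
    if not (np.all(np.isfinite(conc)) and np.all(np.isfinite(resp))):
        raise ValueError("non-finite concentrations or responses")
    if np.unique(conc).size < 4:
        raise ValueError("need >= 4 distinct concentrations")

    span = float(resp.max() - resp.min())
    pos = conc[conc > 0]
    log_c = np.log(pos)
    b0 = max(0.0, float(np.quantile(resp, 0.1)))
    lo = np.array([0.0, 0.0, log_c.min() - 5.0, 0.5])
    hi = np.array(
        [
            max(resp.max(), 1e-6),
            max(10.0 * span, float(resp.max()), 1e-6),
            log_c.max() + 5.0,
            10.0,
        ]
    )

    best = None
    for ec50_q in (0.25, 0.5, 0.75):
        for h0 in (0.8, 1.5, 3.0):
            theta0 = np.clip(
                np.array([b0, max(span, 1e-3), np.quantile(log_c, ec50_q), h0]),
                lo,
                hi,
            )
            sol = optimize.least_squares(
                _hill_residuals, theta0, bounds=(lo, hi), args=(conc, resp)
            )
            rss = float(2.0 * sol.cost)
            if best is None or rss < best[0]:
                best = (rss, sol)
    rss, sol = best
    b, emax, log_ec50, h = sol.x
    return HillFit(
        e_max=float(emax),
        ec50=float(np.exp(log_ec50)),
        h=float(h),
        baseline=float(b),
        rss=rss,
        converged=bool(sol.success),
    )
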