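"""Hit-list rescoring analysis for prospective virtual screens.

A docking hit list mixes true binders with high-ranking false positives.
Given per-compound scores from several methods and measured activity, this
module labels actives against a target-specific apparent-Ki cutoff, measures
active/inactive separation (ROC AUC, two-sample Kolmogorov–Smirnov), and
builds rolling-window hit-rate curves on a pProp axis (negative log10 of the
fractional rank within the tested list) with 95% Wilson confidence bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

from .affinity_eval import AffinityError, cheng_prusoff_ki


class ScreenEvalError(Exception):
    pass


@dataclass
class TargetConfig:
    """Activity-labeling rule for one screen target.

    Either a direct apparent-Ki threshold (molar) or a single-point
    displacement rule (fraction threshold + probe concentration + [S]/Km)
    that is converted per compound through Cheng–Prusoff. Records exactly at
    the cutoff are inactive (strict inequality, matching "<" cutoffs).
    """

    threshold_ki_molar: float
    displacement_threshold: float | None = None
    probe_conc_molar: float | None = None
    s_over_km: float | None = None


#: Published labeling rules for the three screens: AmpC uses a direct 400 μM
#: apparent-Ki cutoff; sigma2 and D4 use 25% single-point displacement at
#: 1 μM / 10 μM probe, giving apparent-Ki cutoffs of 2.0 μM and 7.8 μM.
TARGETS = {
    "ampc": TargetConfig(threshold_ki_molar=400e-6),
    "sigma2": TargetConfig(threshold_ki_molar=2.0e-6,
                           displacement_threshold=0.25,
                           probe_conc_molar=1e-6, s_over_km=0.5),
    "d4": TargetConfig(threshold_ki_molar=7.8e-6,
                       displacement_threshold=0.25,
                       probe_conc_molar=10e-6, s_over_km=30.0 / 7.8 - 1.0),
}


def label_actives(records: pd.DataFrame, target: TargetConfig) -> pd.DataFrame:
    """Add an ``active`` column from measured Ki or % displacement.

    Records carrying an apparent Ki (column ``ki_molar``) are active iff
    Ki < threshold. Records carrying only a displaced fraction (column
    ``displacement``) are converted to an apparent Ki via Cheng–Prusoff first.
    """
    recs = records.copy()
    has_ki = "ki_molar" in recs and recs["ki_molar"].notna()
    has_disp = "displacement" in recs and recs["displacement"].notna()
    if "ki_molar" not in recs:
        has_ki = pd.Series(False, index=recs.index)
    if "displacement" not in recs:
        has_disp = pd.Series(False, index=recs.index)
    orphans = recs.index[~(has_ki | has_disp)]
    if len(orphans):
        ids = recs.loc[orphans, "compound_id"].tolist() if "compound_id" in recs \
            else orphans.tolist()
        raise ScreenEvalError(f"records with neither Ki nor displacement: {ids}")

    ki = pd.Series(np.nan, index=recs.index, dtype=float)
    if has_ki.any():
        ki[has_ki] = recs.loc[has_ki, "ki_molar"].astype(float)
    need = has_disp & ~has_ki
    if need.any():
        if target.probe_conc_molar is None or target.s_over_km is None:
            raise ScreenEvalError(
                "displacement data present but target has no probe/[S]-Km config")
        conv = [cheng_prusoff_ki(f, target.probe_conc_molar, target.s_over_km)
                for f in recs.loc[need, "displacement"].astype(float)]
        ki[need] = conv
    recs["apparent_ki_molar"] = ki
    recs["active"] = ki < target.threshold_ki_molar
    return recs


def roc_auc(scores, labels, higher_is_better: bool = True) -> float:
    """ROC AUC = normalized Mann–Whitney U with ties credited ½."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ScreenEvalError("both classes must be present for AUC")
    s = scores if higher_is_better else -scores
    return float(roc_auc_score(labels, s))


def ks_separation(scores_active, scores_inactive) -> tuple[float, float]:
    """Two-sample KS statistic (max ECDF gap) and asymptotic two-sided p."""
    a = np.asarray(scores_active, dtype=float)
    b = np.asarray(scores_inactive, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ScreenEvalError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def pprop(rank: int, n: int) -> float:
    """Negative log10 of the fractional rank: top 0.1% of a list → 3."""
    if not 1 <= rank <= n:
        raise ScreenEvalError(f"rank {rank} outside [1, {n}]")
    return -math.log10(rank / n)


def wilson_interval(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, clipped to [0, 1]."""
    if not 0 <= k <= n or n < 1:
        raise ScreenEvalError(f"invalid counts k={k}, n={n}")
    lo, hi = proportion_confint(k, n, alpha=1 - confidence, method="wilson")
    lo = 0.0 if k == 0 else float(np.clip(lo, 0, 1))  # exactly 0 at k=0
    hi = 1.0 if k == n else float(np.clip(hi, 0, 1))
    return lo, hi


@dataclass
class HitRateCurve:
    center_rank: np.ndarray    # 1-based rank of each window center
    pprop: np.ndarray          # pProp of the window-center rank
    hit_fraction: np.ndarray
    wilson_lower: np.ndarray
    wilson_upper: np.ndarray
    window: int
    stride: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "center_rank": self.center_rank,
            "pprop": self.pprop,
            "hit_fraction": self.hit_fraction,
            "wilson_lower": self.wilson_lower,
            "wilson_upper": self.wilson_upper,
        })


def hit_rate_curve(scores, labels, window: int, stride: int = 1,
                   higher_is_better: bool = True,
                   confidence: float = 0.95) -> HitRateCurve:
    """Rolling-window hit rate along the score-sorted list.

    The list is sorted best-score-first; each window of ``window`` compounds
    contributes one point at the pProp of its center rank, with the active
    fraction and its Wilson interval.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n = scores.size
    if window > n:
        raise ScreenEvalError(f"window {window} exceeds list size {n}")
    order = np.argsort(-scores if higher_is_better else scores, kind="stable")
    lab = labels[order].astype(int)
    csum = np.concatenate([[0], np.cumsum(lab)])
    starts = np.arange(0, n - window + 1, stride)
    hits = csum[starts + window] - csum[starts]
    frac = hits / window
    centers = starts + (window + 1) // 2  # 1-based center rank
    lows = np.empty_like(frac)
    highs = np.empty_like(frac)
    for i, h in enumerate(hits):
        lows[i], highs[i] = wilson_interval(int(h), window, confidence)
    pp = np.array([pprop(int(c), n) for c in centers])
    return HitRateCurve(centers, pp, frac, lows, highs, window, stride)
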