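"""Affinity-scale conversions and affinity-prediction evaluation.

Potencies live on the pIC scale (−log10 of a molar IC50/Ki). Conversions to
free-energy units use ΔG = ln(10)·R·T per pIC unit (≈1.364 kcal/mol at
298.15 K). Single-point competition measurements are turned into apparent Ki
values with the one-site interpolation IC50 = C·(1−f)/f followed by
Cheng–Prusoff Ki = IC50/(1 + [S]/Km).

Prediction quality is summarized by Pearson correlation and by the mean
absolute error (MAE) raw, after an ordinary-least-squares linear calibration
of measured on predicted, and against a predict-the-mean baseline. Methods
are compared with a Friedman omnibus test on within-compound ranks of
absolute errors plus Conover post-hoc pairwise tests under Holm–Bonferroni
(default) or plain Bonferroni correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

R_KCAL = 1.98720425864083e-3  # gas constant, kcal/(mol*K)

#: [S]/Km defaults for single-point displacement assays, back-solved from the
#: published apparent-Ki cutoffs (probe 1 uM @ 25% displacement -> 2.0 uM for
#: the sigma2 receptor; probe 10 uM @ 25% -> 7.8 uM for dopamine D4).
S_OVER_KM_DEFAULTS = {"sigma2": 0.5, "d4": 30.0 / 7.8 - 1.0}


class AffinityError(Exception):
    pass


def pic50_from_ic50(ic50_molar: float) -> float:
    """−log10 of a molar IC50 (1 μM → 6.0)."""
    if ic50_molar <= 0:
        raise AffinityError(f"IC50 must be positive, got {ic50_molar}")
    return -math.log10(ic50_molar)


def pic_to_kcal(delta_pic: float, temperature_K: float = 298.15) -> float:
    """Convert a pIC difference into kcal/mol: Δ × ln(10)·R·T (≈1.364 at 298 K)."""
    return delta_pic * math.log(10.0) * R_KCAL * temperature_K


def cheng_prusoff_ki(fraction_displaced: float, probe_conc_molar: float,
                     s_over_km: float) -> float:
    """Apparent Ki from a single-point competition measurement.

    IC50 is interpolated from the displaced fraction f under the one-site
    competitive model, IC50 = C·(1−f)/f, then Cheng–Prusoff divides out probe
    occupancy: Ki = IC50 / (1 + [S]/Km).
    """
    f = float(fraction_displaced)
    if not 0.0 < f < 1.0:
        raise AffinityError(f"fraction displaced must be in (0,1), got {f}")
    if s_over_km < 0:
        raise AffinityError("[S]/Km must be nonnegative")
    ic50 = probe_conc_molar * (1.0 - f) / f
    return ic50 / (1.0 + s_over_km)


def mae(predicted, measured) -> float:
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.shape != measured.shape:
        raise AffinityError(
            f"length mismatch: {predicted.shape} vs {measured.shape}")
    if predicted.size == 0:
        raise AffinityError("empty vectors")
    return float(np.mean(np.abs(predicted - measured)))


def baseline_mae(measured) -> float:
    """MAE of predicting the dataset mean for every compound."""
    measured = np.asarray(measured, dtype=float)
    if measured.size == 0:
        raise AffinityError("empty vector")
    return float(np.mean(np.abs(measured - measured.mean())))


@dataclass
class CalibrationFit:
    slope: float
    intercept: float
    n_points: int

    def apply(self, predicted) -> np.ndarray:
        return self.slope * np.asarray(predicted, dtype=float) + self.intercept


def calibrate_linear(predicted, measured) -> tuple[CalibrationFit, np.ndarray]:
    """OLS of measured on predicted; calibrated predictions on the measured scale."""
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.size < 3:
        raise AffinityError("need at least 3 points for calibration")
    if np.var(predicted) == 0:
        raise AffinityError("zero-variance predictor cannot be calibrated")
    slope, intercept = np.polyfit(predicted, measured, 1)
    fit = CalibrationFit(float(slope), float(intercept), int(predicted.size))
    return fit, fit.apply(predicted)


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment r and its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise AffinityError("need at least 3 points")
    if np.var(x) == 0 or np.var(y) == 0:
        raise AffinityError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# false-positive affinity assignment
# ---------------------------------------------------------------------------

def assign_fp_affinity(measured_pic, active, scheme: str,
                       threshold_ki_molar: float = 2e-6,
                       seed: int | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Build the measured-affinity vector including inactive compounds.

    Schemes (inactives only; actives always keep their measured values):

    * ``actives_only`` — inactives are dropped;
    * ``optimistic_fixed`` — inactives are set to twice the non-binder
      threshold concentration (e.g. Ki cutoff 2 μM → assigned IC50 4 μM);
    * ``random_assigned`` — inactives draw a pKi uniformly between the
      threshold pKi and pKi = 1 (100 mM), seeded.

    Returns (measured vector, boolean keep-mask into the input).
    """
    measured_pic = np.asarray(measured_pic, dtype=float)
    active = np.asarray(active)
    if measured_pic.shape != active.shape:
        raise AffinityError("measured/active length mismatch")
    if np.any([a is None for a in active.tolist()]):
        raise AffinityError("missing active labels")
    active = active.astype(bool)
    if scheme == "actives_only":
        return measured_pic[active], active.copy()
    keep = np.ones_like(active)
    out = measured_pic.copy()
    if scheme == "optimistic_fixed":
        out[~active] = pic50_from_ic50(2.0 * threshold_ki_molar)
    elif scheme == "random_assigned":
        rng = np.random.default_rng(seed)
        threshold_pki = pic50_from_ic50(threshold_ki_molar)
        n_inactive = int((~active).sum())
        out[~active] = rng.uniform(1.0, threshold_pki, size=n_inactive)
    else:
        raise AffinityError(f"unknown scheme {scheme!r}")
    return out, keep


@dataclass
class MAEReport:
    mae_raw: float
    mae_calibrated: float
    mae_baseline: float
    scheme: str
    n: int
    seed: int | None = None
    temperature_K: float = 298.15

    @property
    def mae_raw_kcal(self) -> float:
        return pic_to_kcal(self.mae_raw, self.temperature_K)

    @property
    def mae_calibrated_kcal(self) -> float:
        return pic_to_kcal(self.mae_calibrated, self.temperature_K)

    @property
    def mae_baseline_kcal(self) -> float:
        return pic_to_kcal(self.mae_baseline, self.temperature_K)


def mae_report(predicted, measured, scheme: str = "actives_only",
               seed: int | None = None) -> MAEReport:
    """Raw, linearly calibrated, and predict-the-mean MAE for one predictor."""
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    _, calibrated = calibrate_linear(predicted, measured)
    return MAEReport(
        mae_raw=mae(predicted, measured),
        mae_calibrated=mae(calibrated, measured),
        mae_baseline=baseline_mae(measured),
        scheme=scheme, n=int(predicted.size), seed=seed,
    )


# ---------------------------------------------------------------------------
# cross-method comparison: Friedman + Conover post hoc
# ---------------------------------------------------------------------------

@dataclass
class MethodComparison:
    methods: list[str]
    friedman_statistic: float
    friedman_p: float
    pairwise_raw_p: dict[tuple[str, str], float]
    pairwise_adjusted_p: dict[tuple[str, str], float]
    n_compounds: int
    correction: str


def _friedman_ranks(errors: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, errors)


def compare_methods(abs_errors: np.ndarray, methods: list[str] | None = None,
                    correction: str = "holm") -> MethodComparison:
    """Friedman omnibus + Conover post-hoc on an (n compounds × k methods)
    matrix of absolute errors.

    Rows with any missing value are dropped (complete-case, logged). Ties are
    midranked. Pairwise Conover t statistics use the tie-adjusted rank-sum
    variance (Conover 1999); p-values are adjusted by Holm–Bonferroni
    (default) or plain Bonferroni.
    """
    E = np.asarray(abs_errors, dtype=float)
    if E.ndim != 2 or E.shape[1] < 2:
        raise AffinityError("need an n×k matrix with k ≥ 2 methods")
    if methods is None:
        methods = [f"m{i}" for i in range(E.shape[1])]
    complete = ~np.isnan(E).any(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("compare_methods: dropping %d incomplete compounds", dropped)
    E = E[complete]
    n, k = E.shape
    if n < 3:
        raise AffinityError("need at least 3 complete compounds")

    ranks = _friedman_ranks(E)
    Rj = ranks.sum(axis=0)
    A1 = float((ranks ** 2).sum())
    C1 = n * k * (k + 1) ** 2 / 4.0
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    if A1 == C1:  # every row fully tied: no information
        stat_T1, p_omni = 0.0, 1.0
        raw = {pairs_idx: 1.0 for pairs_idx in pairs}
    else:
        stat_T1 = (k - 1) * float(((Rj - n * (k + 1) / 2.0) ** 2).sum()) / (A1 - C1)
        p_omni = float(stats.chi2.sf(stat_T1, k - 1))
        df = (n - 1) * (k - 1)
        var_term = 2.0 * (A1 - C1) / df * max(1.0 - stat_T1 / (n * (k - 1)), 1e-12)
        denom = math.sqrt(var_term)
        raw = {}
        for i, j in pairs:
            t = abs(Rj[i] - Rj[j]) / denom
            raw[(i, j)] = float(2.0 * stats.t.sf(t, df))

    raw_named = {(methods[i], methods[j]): p for (i, j), p in raw.items()}
    pvals = list(raw_named.values())
    method_name = "holm" if correction == "holm" else "bonferroni"
    adjusted = multipletests(pvals, method=method_name)[1] if pvals else []
    adj_named = dict(zip(raw_named.keys(), (float(p) for p in adjusted)))
    return MethodComparison(
        methods=list(methods),
        friedman_statistic=float(stat_T1),
        friedman_p=p_omni,
        pairwise_raw_p=raw_named,
        pairwise_adjusted_p=adj_named,
        n_compounds=n,
        correction=method_name,
    )
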