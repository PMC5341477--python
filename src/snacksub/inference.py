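"""Replicate-weight survey inference: Fay-adjusted BRR, weighted t-tests,
percent change, and effect-size classification.

Variance estimation follows the balanced-repeated-replication scheme for
two-PSU-per-stratum designs with Fay's adjustment: replicate r perturbs
each stratum's two PSUs by factors (2 - rho) and rho according to a
Hadamard sign pattern, and the variance of an estimator is the scaled mean
squared deviation of the replicate estimates around the full-sample
estimate.  Modeled-vs-observed comparisons use an unequal-variance z-test
on the two BRR standard errors, and relative changes are classified as
marginal (<5%), modest/moderate (5 to <10%) or strong/dramatic (>=10%)
when statistically significant at p < 0.05.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import hadamard
from scipy.stats import norm, t as t_dist


@dataclass(frozen=True)
class ReplicateScheme:
    """Fay-BRR replicate weights for a two-PSU-per-stratum design."""
    n_replicates: int
    fay_coefficient: float
    full_weights: np.ndarray          # (n_persons,)
    replicate_weights: np.ndarray     # (n_persons, n_replicates)
    strata: np.ndarray                # stratum label per person
    n_strata: int

    def as_frame(self, person_ids) -> pd.DataFrame:
        """Replicate weights as columns brr_w_01 ... brr_w_R."""
        cols = {f"brr_w_{r + 1:02d}": self.replicate_weights[:, r]
                for r in range(self.n_replicates)}
        return pd.DataFrame({"person_id": person_ids, **cols})


@dataclass(frozen=True)
class EffectClass:
    label: str
    pct_change: float
    p_value: float


def build_brr_weights(persons: pd.DataFrame, rho: float = 0.7,
                      n_replicates: int = 32) -> ReplicateScheme:
    """Construct Fay-BRR replicate weights from strata/PSU identifiers.

    Every stratum must contain exactly 2 PSUs.  Strata are assigned to
    Hadamard-matrix columns in sorted-label order, so the construction is
    deterministic.  Replicate r multiplies the weights of a stratum's
    first PSU (sorted label order) by (2 - rho) where the Hadamard entry
    is +1, by rho where it is -1, and vice versa for the second PSU.
    """
    if not 0 <= rho <= 1:
        raise ValueError("rho must be in [0, 1]")
    strata = persons["stratum_id"].to_numpy()
    psus = persons["psu_id"].to_numpy()
    w = persons["survey_weight"].to_numpy(dtype=float)

    stratum_labels = np.array(sorted(pd.unique(strata)))
    n_strata = len(stratum_labels)
    if n_replicates < n_strata:
        raise ValueError(
            f"{n_replicates} replicates cannot balance {n_strata} strata")
    if n_replicates & (n_replicates - 1):
        raise ValueError("n_replicates must be a power of 2 (Hadamard order)")
    H = hadamard(n_replicates)

    # sign per person: +1 for first PSU in the stratum, -1 for second
    half = np.zeros(len(persons), dtype=int)
    col = np.zeros(len(persons), dtype=int)
    for j, s in enumerate(stratum_labels):
        in_s = strata == s
        psu_labels = sorted(pd.unique(psus[in_s]))
        if len(psu_labels) != 2:
            raise ValueError(
                f"stratum {s!r} has {len(psu_labels)} PSUs; BRR requires "
                "exactly 2 (collapse strata first)")
        half[in_s] = np.where(psus[in_s] == psu_labels[0], 1, -1)
        col[in_s] = j

    signs = H[:, col] * half  # (R, n_persons)
    factors = np.where(signs > 0, 2.0 - rho, rho)
    rep = (w * factors).T  # (n_persons, R)
    return ReplicateScheme(n_replicates=n_replicates, fay_coefficient=rho,
                           full_weights=w, replicate_weights=rep,
                           strata=strata, n_strata=n_strata)


def brr_variance(estimator, scheme: ReplicateScheme):
    """Full-sample estimate and Fay-BRR standard error of an estimator.

    ``estimator`` maps a weight vector to a scalar.  variance =
    sum_r (theta_r - theta)^2 / (R * (1 - rho)^2).
    """
    theta = estimator(scheme.full_weights)
    reps = np.empty(scheme.n_replicates)
    for r in range(scheme.n_replicates):
        try:
            reps[r] = estimator(scheme.replicate_weights[:, r])
        except Exception as exc:  # noqa: BLE001 - name the failing replicate
            raise RuntimeError(f"estimator failed in replicate {r + 1}") from exc
    rho = scheme.fay_coefficient
    if rho == 1.0:  # degenerate Fay: every replicate equals the full sample
        return float(theta), 0.0
    var = np.sum((reps - theta) ** 2) / (scheme.n_replicates * (1.0 - rho) ** 2)
    return float(theta), float(np.sqrt(var))


def weighted_ttest(mean0: float, se0: float, mean1: float, se1: float,
                   df: float | None = None):
    """Unequal-variance test of modeled (1) vs observed (0) means.

    t = (mean1 - mean0) / sqrt(se0^2 + se1^2); the reference distribution
    is standard normal by default (BRR degrees of freedom are large), or
    Student t with ``df`` degrees of freedom if given.
    """
    if se0 < 0 or se1 < 0:
        raise ValueError("standard errors must be nonnegative")
    denom = np.hypot(se0, se1)
    if denom == 0:
        if mean0 == mean1:
            return 0.0, 1.0
        warnings.warn("both SEs are zero with unequal means; p = 0")
        return np.inf if mean1 > mean0 else -np.inf, 0.0
    t = (mean1 - mean0) / denom
    if df is None:
        p = 2.0 * norm.sf(abs(t))
    else:
        p = 2.0 * t_dist.sf(abs(t), df)
    return float(t), float(p)


def percent_change(observed: float, modeled: float) -> float:
    """Relative change of a modeled mean vs the observed mean, in percent."""
    if observed == 0:
        raise ValueError("percent change undefined for observed = 0")
    return 100.0 * (modeled - observed) / observed


def classify_effect(pct_change: float, p_value: float) -> EffectClass:
    """Label an effect by size and significance.

    Not significant at p >= 0.05; otherwise |change| < 5% is marginal,
    5% to <10% modest/moderate, and >=10% strong/dramatic (10% being the
    cut-off for a strong effect).
    """
    if p_value >= 0.05:
        label = "not significant"
    elif abs(pct_change) < 5:
        label = "marginal"
    elif abs(pct_change) < 10:
        label = "modest/moderate"
    else:
        label = "strong/dramatic"
    return EffectClass(label=label, pct_change=pct_change, p_value=p_value)


def significance_stars(p: float) -> str:
    """Figure-legend star convention at 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
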