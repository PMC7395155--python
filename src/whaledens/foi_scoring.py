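"""Scoring and classification of satellite-image features of interest (FOIs).

Each candidate whale-like feature is scored against 13 criteria, each on a
0/1/2 conformity scale (ψ1 fluke, ψ2 fins, ψ3 footprint, ψ4 blow, ψ5..ψ13
further whale-like characteristics).  The four highly indicative criteria
carry weight 2; the weighted total

    C_s = 2(ψ1 + ψ2 + ψ3 + ψ4) + ψ5 + ... + ψ13

determines the class: "definite" (C_s > 9), "probable" (7 <= C_s <= 9) or
"unclassified" (C_s < 7).  Class proportions are treated as binomial random
variables for uncertainty; an inter-observer comparison on a rescored
subset checks whether the principal observer's scores need adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from whaledens.errors import FitError, ValidationError

N_CRITERIA = 13

#: Default criterion weights (ψ1..ψ4 doubled).
DEFAULT_WEIGHTS: tuple[int, ...] = (2, 2, 2, 2, 1, 1, 1, 1, 1, 1, 1, 1, 1)

#: Classification thresholds on the weighted total, exact integer arithmetic.
DEFINITE_ABOVE = 9   # C_s > 9  -> definite
PROBABLE_AT_LEAST = 7  # 7 <= C_s <= 9 -> probable

LABELS = ("definite", "probable", "unclassified")

#: Ordered sea-state classes, calm to rough, and their stratum assignment.
SEA_STATES = ("ideal", "good", "average", "sub-average", "poor")
STRATA = ("calmer", "rougher")
SEA_STATE_STRATUM: Mapping[str, str] = {
    "ideal": "calmer",
    "good": "calmer",
    "average": "calmer",
    "sub-average": "rougher",
    "poor": "rougher",
}


@dataclass(frozen=True)
class FOIRecord:
    """One scored feature of interest."""

    foi_id: str
    psi: tuple[int, ...]
    c_s: int
    label: str
    sea_state: str
    stratum: str
    observer: str


@dataclass(frozen=True)
class ClassifiedCounts:
    """Counts of FOIs per class."""

    n_definite: int
    n_probable: int
    n_unclassified: int

    @property
    def n_total(self) -> int:
        return self.n_definite + self.n_probable + self.n_unclassified

    @property
    def n_definite_probable(self) -> int:
        return self.n_definite + self.n_probable

    def __post_init__(self) -> None:
        if min(self.n_definite, self.n_probable, self.n_unclassified) < 0:
            raise ValidationError("class counts must be non-negative")


@dataclass
class ObserverComparison:
    """Concordance between a principal observer and a panel of reviewers."""

    deviations: dict[str, float]  # foi_id -> principal C_s - mean reviewer C_s
    mean_deviation: float
    median_deviation: float
    proportion_by_observer: dict[str, tuple[float, float]]  # obs -> (p, se)
    adjust: bool  # flag raised when |mean deviation| >= 1


def score_foi(psi: Sequence[int], weights: Iterable[int] | None = None) -> int:
    """Weighted criterion total C_s of one FOI.

    Raises :class:`ValidationError` if any criterion score is outside
    {0, 1, 2} or the vector does not have 13 entries.
    """
    w = tuple(weights) if weights is not None else DEFAULT_WEIGHTS
    psi = tuple(int(v) for v in psi)
    if len(psi) != N_CRITERIA or len(w) != N_CRITERIA:
        raise ValidationError(f"expected {N_CRITERIA} criterion scores/weights")
    for i, v in enumerate(psi):
        if v not in (0, 1, 2):
            raise ValidationError(f"psi{i + 1}={v} outside {{0,1,2}}")
    return int(sum(wi * vi for wi, vi in zip(w, psi)))


def classify(c_s: int | float) -> str:
    """Class label for a total score: definite > 9, probable in [7, 9], else unclassified."""
    if c_s < 0:
        raise ValidationError("C_s must be >= 0")
    if c_s > DEFINITE_ABOVE:
        return "definite"
    if c_s >= PROBABLE_AT_LEAST:
        return "probable"
    return "unclassified"


def proportion_se(k: int, n: int) -> tuple[float, float]:
    """Binomial proportion and its standard error sqrt(p(1-p)/n)."""
    if n <= 0:
        raise ValidationError("n must be > 0")
    if not 0 <= k <= n:
        raise ValidationError("require 0 <= k <= n")
    p = k / n
    return p, float(np.sqrt(p * (1.0 - p) / n))


def proportion_cv(k: int, n: int) -> float:
    """CV of a binomial class proportion, SE/p (requires k > 0)."""
    p, se = proportion_se(k, n)
    if p == 0:
        raise ValidationError("CV undefined for a zero proportion")
    return se / p


def count_classes(records: Sequence[FOIRecord]) -> ClassifiedCounts:
    labels = [r.label for r in records]
    return ClassifiedCounts(
        n_definite=labels.count("definite"),
        n_probable=labels.count("probable"),
        n_unclassified=labels.count("unclassified"),
    )


def fit_score_distribution(scores: Sequence[int]) -> dict:
    """Maximum-likelihood negative-binomial fit to integer FOI totals.

    Returns the NB size (dispersion) and mean parameters with log-likelihood
    and AIC.  A Poisson-like sample drives the size parameter large; a
    constant sample is flagged degenerate instead of fitted.
    """
    x = np.asarray(scores)
    if len(x) < 10:
        raise ValidationError("need at least 10 scores to fit")
    if not np.all(x == np.floor(x)) or np.any(x < 0):
        raise ValidationError("scores must be non-negative integers")
    x = x.astype(int)
    if x.var() == 0:
        return {"degenerate": True, "size": np.inf, "mean": float(x.mean())}

    def nll(theta):
        log_size, log_mean = theta
        size, mean = np.exp(log_size), np.exp(log_mean)
        p = size / (size + mean)
        return -np.sum(stats.nbinom.logpmf(x, size, p))

    m, v = x.mean(), x.var(ddof=1)
    size0 = m * m / (v - m) if v > m else 100.0
    res = optimize.minimize(
        nll,
        x0=[np.log(max(size0, 1e-3)), np.log(max(m, 1e-3))],
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    if not res.success:
        raise FitError(f"negative-binomial fit did not converge: {res.message}")
    size, mean = np.exp(res.x)
    log_lik = -res.fun
    return {
        "degenerate": False,
        "size": float(size),
        "mean": float(mean),
        "log_lik": float(log_lik),
        "aic": float(2 * 2 - 2 * log_lik),
    }


def compare_observers(
    principal: Sequence[FOIRecord],
    reviewers: Sequence[Sequence[FOIRecord]],
    adjust_threshold: float = 1.0,
) -> ObserverComparison:
    """Compare the principal observer's scores with a reviewer panel.

    Deviations (principal C_s minus the mean reviewer C_s) are computed on
    the common FOI subset only.  The ``adjust`` flag is raised when the
    absolute mean deviation reaches ``adjust_threshold``, signalling that a
    systematic rescoring of the principal's FOIs would be warranted.
    """
    principal_by_id = {r.foi_id: r for r in principal}
    reviewer_maps = [{r.foi_id: r for r in panel} for panel in reviewers]
    common = set(principal_by_id)
    for m in reviewer_maps:
        common &= set(m)
    if not common:
        raise ValidationError("no FOIs shared between principal and all reviewers")

    deviations = {
        fid: principal_by_id[fid].c_s
        - float(np.mean([m[fid].c_s for m in reviewer_maps]))
        for fid in sorted(common)
    }
    devs = np.array(list(deviations.values()))

    def _prop(records: Iterable[FOIRecord]) -> tuple[float, float]:
        subset = [r for r in records if r.foi_id in common]
        k = sum(r.label in ("definite", "probable") for r in subset)
        return proportion_se(k, len(subset))

    props = {"principal": _prop(principal)}
    for i, panel in enumerate(reviewers, start=1):
        props[f"reviewer{i}"] = _prop(panel)

    mean_dev = float(devs.mean())
    return ObserverComparison(
        deviations=deviations,
        mean_deviation=mean_dev,
        median_deviation=float(np.median(devs)),
        proportion_by_observer=props,
        adjust=abs(mean_dev) >= adjust_threshold,
    )


def stratify_counts(records: Sequence[FOIRecord]) -> dict[str, dict]:
    """Class counts and definite∪probable proportions per sea-state stratum."""
    out: dict[str, dict] = {}
    for r in records:
        if r.stratum not in STRATA:
            raise ValidationError(f"unknown stratum label {r.stratum!r}")
    for stratum in STRATA:
        subset = [r for r in records if r.stratum == stratum]
        counts = count_classes(subset)
        entry: dict = {"counts": counts}
        if counts.n_total > 0:
            p, se = proportion_se(counts.n_definite_probable, counts.n_total)
            entry["p_definite_probable"] = p
            entry["se"] = se
        out[stratum] = entry
    return out
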