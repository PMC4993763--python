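"""Cohort-level statistics and the two-feature scenario classifier.

Per-dyad metrics (synchrony ``x``, entrainment ``y``, jitter band powers,
dominance ratio) are compared between the two performance scenarios with
the Mann–Whitney U test and its rank-biserial effect size
``r = 2U/(n_a n_b) - 1``, and the scenarios are separated by a logistic
classifier in the (x, y) plane with probability function

.. math::

    P(B \\mid x, y) = \\frac{1}{1 + a\\,e^{b x + c y}}

whose parameters ``(a, b, c)`` and accuracy are estimated by resampling
dyads with replacement (bootstrap) and refitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .errors import DegenerateInputError, DomainError

#: Largest n_a * n_b for which the exact permutation p-value is computed.
EXACT_ENUMERATION_LIMIT = 64


@dataclass
class MannWhitneyResult:
    U: float          # count of (a, b) pairs with b > a, plus half-ties
    p: float
    r: float          # rank-biserial effect size, in [-1, 1]
    n_a: int
    n_b: int
    exact: bool       # True if p came from full enumeration


@dataclass
class DyadMetrics:
    """Per-dyad scalar summary used for cohort statistics."""

    dyad_id: str
    x: float                       # synchrony c(0)
    y: float                       # entrainment centre of mass (s)
    jitter_subject: float
    jitter_actor: float
    dominance_ratio: Optional[float] = None
    label: Optional[str] = None    # scenario "A" | "B"

    def __post_init__(self):
        if not -1 - 1e-9 <= self.x <= 1 + 1e-9:
            raise DomainError(f"synchrony x={self.x} outside [-1, 1]")


@dataclass
class ClassifierModel:
    """Logistic scenario classifier P(B) = 1 / (1 + a*exp(b*x + c*y)).

    ``bootstrap_samples`` holds per-replicate (a, b, c, accuracy) records
    when the model was bootstrapped; summary statistics are the mean and
    std over replicates.
    """

    a: float
    b: float
    c: float
    separation: bool = False
    n_boot: int = 0
    seed: Optional[int] = None
    oob: bool = True
    bootstrap_samples: list = field(default_factory=list)

    def __post_init__(self):
        if self.a <= 0:
            raise DomainError("parameter a must be positive")

    def summary(self) -> dict:
        out = {"a": self.a, "b": self.b, "c": self.c,
               "separation": self.separation}
        if self.bootstrap_samples:
            arr = np.array([(s["a"], s["b"], s["c"], s["accuracy"])
                            for s in self.bootstrap_samples])
            sep = np.array([s["separation"] for s in self.bootstrap_samples])
            # parameter summaries exclude replicates whose MLE was unbounded
            # (perfectly separated resamples); accuracy keeps all replicates
            clean = arr[~sep] if (~sep).any() else arr
            for i, name in enumerate(("a", "b", "c")):
                out[f"{name}_mean"] = float(clean[:, i].mean())
                out[f"{name}_std"] = float(clean[:, i].std())
            out["accuracy_mean"] = float(arr[:, 3].mean())
            out["accuracy_std"] = float(arr[:, 3].std())
            out["n_separated"] = int(sep.sum())
            out["n_boot"] = self.n_boot
            out["seed"] = self.seed
            out["oob"] = self.oob
        return out


# --- Mann-Whitney ----------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of group b: pairs with b > a plus half the ties."""
    diff = b[:, None] - a[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float],
                 alternative: str = "two-sided") -> MannWhitneyResult:
    """Mann–Whitney U test with rank-biserial effect size.

    ``U`` counts pairs in which the group-B value exceeds the group-A
    value (ties count half), so ``r = 2U/(n_a n_b) - 1`` is +1 when every
    B value beats every A value. For ``n_a * n_b <= 64`` the p-value is
    exact, by enumerating all assignments of the pooled sample to the two
    groups; otherwise the tie-corrected normal approximation with
    continuity correction is used.

    ``alternative`` is "two-sided", "greater" (B tends larger) or "less".
    """
    a = np.asarray(list(group_a), dtype=np.float64)
    b = np.asarray(list(group_b), dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise DomainError("both groups must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise DomainError(f"unknown alternative {alternative!r}")
    n_a, n_b = a.size, b.size
    u_obs = _u_statistic(a, b)
    r = 2.0 * u_obs / (n_a * n_b) - 1.0

    if n_a * n_b <= EXACT_ENUMERATION_LIMIT:
        pooled = np.concatenate([a, b])
        idx = range(n_a + n_b)
        us = []
        for a_idx in combinations(idx, n_a):
            mask = np.zeros(n_a + n_b, dtype=bool)
            mask[list(a_idx)] = True
            us.append(_u_statistic(pooled[mask], pooled[~mask]))
        us = np.asarray(us)
        eps = 1e-9
        p_ge = float((us >= u_obs - eps).mean())
        p_le = float((us <= u_obs + eps).mean())
        if alternative == "two-sided":
            # doubled smaller one-sided tail (the standard exact convention;
            # with ties the permutation distribution is asymmetric)
            p = min(1.0, 2.0 * min(p_ge, p_le))
        elif alternative == "greater":
            p = p_ge
        else:
            p = p_le
        return MannWhitneyResult(U=u_obs, p=p, r=r, n_a=n_a, n_b=n_b, exact=True)

    # normal approximation with midrank tie correction
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        raise DegenerateInputError("all pooled values identical: U variance is zero")
    mu = n_a * n_b / 2.0
    sd = math.sqrt(var)
    from scipy.stats import norm
    if alternative == "two-sided":
        z = (abs(u_obs - mu) - 0.5) / sd
        p = float(2 * norm.sf(max(z, 0.0)))
    elif alternative == "greater":
        p = float(norm.sf((u_obs - mu - 0.5) / sd))
    else:
        p = float(norm.cdf((u_obs - mu + 0.5) / sd))
    return MannWhitneyResult(U=u_obs, p=min(p, 1.0), r=r, n_a=n_a, n_b=n_b,
                             exact=False)


# --- logistic classifier ---------------------------------------------------

def predict(model: ClassifierModel, x, y):
    """Probability of scenario B at (x, y); overflow-guarded."""
    expo = np.clip(model.b * np.asarray(x, dtype=np.float64)
                   + model.c * np.asarray(y, dtype=np.float64), -700, 700)
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + model.a * np.exp(expo))
    return p if np.ndim(p) else float(p)


def _as_xy_labels(points, labels):
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DomainError(f"points must be (n, 2), got {pts.shape}")
    lab = np.asarray(labels)
    if lab.shape[0] != pts.shape[0]:
        raise DomainError("labels must match points")
    uniq = sorted(set(lab.tolist()))
    if len(uniq) != 2:
        raise DomainError(f"need exactly two label values, got {uniq}")
    return pts, (lab == uniq[1]).astype(int), uniq  # positive class = "B" by sort


def fit_classifier(points, labels) -> ClassifierModel:
    """Maximum-likelihood logistic fit of scenario on (x, y).

    The sigmoid parameterization ``P(B) = sigma(b0 + b1 x + b2 y)`` is
    reported as ``a = exp(-b0), b = -b1, c = -b2`` so that
    ``P(B) = 1 / (1 + a exp(bx + cy))``. Perfect (quasi-)separation is
    flagged: the MLE is then unbounded and coefficients are cut off by
    the solver's iteration limit.
    """
    pts, y01, _ = _as_xy_labels(points, labels)
    if pts.shape[0] < 4:
        raise DomainError("need at least 4 points to fit")
    lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000, tol=1e-10)
    lr.fit(pts, y01)
    b0 = float(lr.intercept_[0])
    b1, b2 = (float(v) for v in lr.coef_[0])
    # a hyperplane that classifies the training data perfectly proves the
    # data linearly separable, hence the MLE unbounded
    separated = bool((lr.predict(pts) == y01).all())
    # under separation the intercept is solver-limited; keep a finite and positive
    a = math.exp(-min(max(b0, -50.0), 50.0))
    return ClassifierModel(a=a, b=-b1, c=-b2, separation=separated)


def _accuracy(model: ClassifierModel, pts: np.ndarray, y01: np.ndarray) -> float:
    pred = (np.asarray(predict(model, pts[:, 0], pts[:, 1])) >= 0.5).astype(int)
    return float((pred == y01).mean())


def bootstrap_classifier(points, labels, n_boot: int = 1000,
                         seed: Optional[int] = None,
                         oob: bool = True) -> ClassifierModel:
    """Bootstrap the logistic classifier: resample dyads, refit, summarise.

    Each replicate resamples the dyads with replacement and refits;
    replicates that draw a single label (or, with ``oob=True``, leave no
    out-of-bag dyads) are redrawn so ``n_boot`` effective replicates are
    always produced. Accuracy is evaluated out-of-bag by default — on the
    dyads the replicate did not draw — or in-sample with ``oob=False``.
    Fully deterministic for a given ``seed``.
    """
    pts, y01, _ = _as_xy_labels(points, labels)
    n = pts.shape[0]
    if n < 4:
        raise DomainError("need at least 4 points to bootstrap")
    rng = np.random.default_rng(seed)
    central = fit_classifier(points, labels)
    samples = []
    redraws = 0
    for _ in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            in_bag = np.zeros(n, dtype=bool)
            in_bag[idx] = True
            if len(set(y01[idx].tolist())) < 2:
                redraws += 1
                continue
            if oob and in_bag.all():
                redraws += 1
                continue
            break
        m = fit_classifier(pts[idx], y01[idx])
        eval_pts, eval_lab = (pts[~in_bag], y01[~in_bag]) if oob else (pts[idx], y01[idx])
        samples.append({"a": m.a, "b": m.b, "c": m.c,
                        "separation": m.separation,
                        "accuracy": _accuracy(m, eval_pts, eval_lab)})
    return ClassifierModel(a=central.a, b=central.b, c=central.c,
                           separation=central.separation, n_boot=n_boot,
                           seed=seed, oob=oob, bootstrap_samples=samples)
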