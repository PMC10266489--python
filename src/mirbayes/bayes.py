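"""Two-class Gaussian Bayes classifier with analytic accuracy, and ROC tools.

The classifier scores each subject with a linear combination of ΔCt
values,

    Score = ΔCt(miR-92a-3p) + a * ΔCt(miR-320a) + b * ΔCt(miR-320b),

assumes the scores of each diagnostic class to be normally distributed,
and classifies by the larger prior-weighted class density. Under that
model the decision threshold(s) — the real roots of
``prior0 * N(x; mu0, sigma0) = prior1 * N(x; mu1, sigma1)`` — and the
classification accuracy have closed forms via the normal CDF, so the
(a, b) plane can be searched exhaustively without Monte Carlo. The grid
search sweeps both coefficients over [-50, 50] in steps of 0.1 (about
1.002 million combinations) and keeps the combination maximizing the
analytic accuracy.

Accuracy here means the prior-weighted probability of correct
classification; with empirical priors and the Bayes-optimal regions it
can never fall below the majority-class proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

_NORM = stats.norm

# relative sigma difference below which the densities are treated as
# equal-width and the threshold equation is linear, not quadratic
_EQUAL_SIGMA_RTOL = 1e-9


@dataclass
class GaussianClassModel:
    """Per-class normal fit with priors and the analytic Bayes decision."""

    mu0: float
    sigma0: float
    mu1: float
    sigma1: float
    prior0: float = 0.5
    prior1: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma0 <= 0 or self.sigma1 <= 0:
            raise ValueError("class SDs must be positive")
        if not np.isclose(self.prior0 + self.prior1, 1.0):
            raise ValueError("priors must sum to 1")

    def predict(self, x) -> np.ndarray:
        """Class (0/1) with the larger prior-weighted density at x."""
        x = np.asarray(x, dtype=float)
        log0 = np.log(self.prior0) + _NORM.logpdf(x, self.mu0, self.sigma0)
        log1 = np.log(self.prior1) + _NORM.logpdf(x, self.mu1, self.sigma1)
        return (log1 > log0).astype(int)


def analytic_accuracy(model: GaussianClassModel) -> tuple[float, list[float]]:
    """Closed-form Bayes accuracy and decision threshold(s).

    Thresholds are the real roots of prior0*phi0(x) = prior1*phi1(x).
    Equal class SDs give a linear equation (one root, the prior-shifted
    midpoint); unequal SDs give a quadratic with up to two roots whose
    sign pattern assembles the decision regions. With unequal SDs and no
    real root one class is never predicted and the accuracy degenerates
    to that class's prior.
    """
    mu0, s0, mu1, s1 = model.mu0, model.sigma0, model.mu1, model.sigma1
    p0, p1 = model.prior0, model.prior1

    if abs(s0 - s1) <= _EQUAL_SIGMA_RTOL * (s0 + s1):
        s = s0
        if mu0 == mu1:
            return max(p0, p1), []
        x = (mu0 + mu1) / 2.0 - s * s * np.log(p0 / p1) / (mu0 - mu1)
        if mu0 > mu1:  # class 0 above the threshold
            acc = p0 * _NORM.sf(x, mu0, s) + p1 * _NORM.cdf(x, mu1, s)
        else:
            acc = p0 * _NORM.cdf(x, mu0, s) + p1 * _NORM.sf(x, mu1, s)
        return float(acc), [float(x)]

    # quadratic: A x^2 + B x + C = 0, f(x) > 0 <=> predict class 0
    a2 = 0.5 / s1**2 - 0.5 / s0**2
    b = mu0 / s0**2 - mu1 / s1**2
    c = (
        np.log(p0 * s1 / (p1 * s0))
        - mu0**2 / (2 * s0**2)
        + mu1**2 / (2 * s1**2)
    )
    disc = b * b - 4 * a2 * c
    if disc <= 0:
        # f keeps the sign of A everywhere: one class always wins
        return (float(p0), []) if a2 > 0 else (float(p1), [])
    sq = np.sqrt(disc)
    r1 = (-b - sq) / (2 * a2)
    r2 = (-b + sq) / (2 * a2)
    r1, r2 = min(r1, r2), max(r1, r2)
    p0_between = _NORM.cdf(r2, mu0, s0) - _NORM.cdf(r1, mu0, s0)
    p1_between = _NORM.cdf(r2, mu1, s1) - _NORM.cdf(r1, mu1, s1)
    if a2 > 0:  # class 0 outside the roots
        acc = p0 * (1.0 - p0_between) + p1 * p1_between
    else:  # class 0 between the roots
        acc = p0 * p0_between + p1 * (1.0 - p1_between)
    return float(acc), [float(r1), float(r2)]


def _accuracy_grid(mu0, s0, mu1, s1, p0, p1):
    """Vectorized analytic accuracy over arrays of class parameters."""
    mu0, s0, mu1, s1 = (np.asarray(v, dtype=float) for v in (mu0, s0, mu1, s1))
    acc = np.empty(np.broadcast(mu0, s0, mu1, s1).shape, dtype=float)

    equal = np.abs(s0 - s1) <= _EQUAL_SIGMA_RTOL * (s0 + s1)

    with np.errstate(divide="ignore", invalid="ignore"):
        # linear branch
        s = np.where(equal, s0, 1.0)
        dmu = mu0 - mu1
        x_lin = (mu0 + mu1) / 2.0 - s * s * np.log(p0 / p1) / np.where(
            dmu == 0, np.nan, dmu
        )
        acc_above = p0 * _NORM.sf(x_lin, mu0, s) + p1 * _NORM.cdf(x_lin, mu1, s)
        acc_below = p0 * _NORM.cdf(x_lin, mu0, s) + p1 * _NORM.sf(x_lin, mu1, s)
        lin = np.where(dmu > 0, acc_above, acc_below)
        lin = np.where(dmu == 0, max(p0, p1), lin)

        # quadratic branch
        a2 = 0.5 / s1**2 - 0.5 / s0**2
        b = mu0 / s0**2 - mu1 / s1**2
        c = (
            np.log(p0 * s1 / (p1 * s0))
            - mu0**2 / (2 * s0**2)
            + mu1**2 / (2 * s1**2)
        )
        disc = b * b - 4 * a2 * c
        sq = np.sqrt(np.maximum(disc, 0.0))
        r1 = (-b - sq) / (2 * np.where(equal, np.nan, a2))
        r2 = (-b + sq) / (2 * np.where(equal, np.nan, a2))
        lo = np.minimum(r1, r2)
        hi = np.maximum(r1, r2)
        p0_between = _NORM.cdf(hi, mu0, s0) - _NORM.cdf(lo, mu0, s0)
        p1_between = _NORM.cdf(hi, mu1, s1) - _NORM.cdf(lo, mu1, s1)
        quad = np.where(
            a2 > 0,
            p0 * (1.0 - p0_between) + p1 * p1_between,
            p0 * p0_between + p1 * (1.0 - p1_between),
        )
        quad = np.where(disc <= 0, np.where(a2 > 0, p0, p1), quad)

    acc = np.where(equal, lin, quad)
    return acc


def fit_gaussian_classes(
    scores, labels, priors: str = "empirical"
) -> GaussianClassModel:
    """Per-class mean and unbiased SD from scores and binary labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    x0 = scores[labels == classes[0]]
    x1 = scores[labels == classes[1]]
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError("need >= 2 subjects per class")
    s0 = x0.std(ddof=1)
    s1 = x1.std(ddof=1)
    if s0 == 0 or s1 == 0:
        raise ValueError(
            "zero within-class variance; jitter or exclude constant scores"
        )
    if priors == "empirical":
        p0 = len(x0) / scores.size
    elif priors == "equal":
        p0 = 0.5
    else:
        raise ValueError("priors must be 'empirical' or 'equal'")
    return GaussianClassModel(
        mu0=float(x0.mean()),
        sigma0=float(s0),
        mu1=float(x1.mean()),
        sigma1=float(s1),
        prior0=p0,
        prior1=1.0 - p0,
    )


# -- ROC -------------------------------------------------------------------


@dataclass
class RocResult:
    """Empirical ROC curve with AUC, its Mann-Whitney p, and best accuracy."""

    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    thresholds: np.ndarray = field(repr=False)
    auc: float = 0.0
    auc_p_value: float = 1.0
    best_accuracy: float = 0.0
    best_accuracy_se: float = 0.0
    best_threshold: float = 0.0
    sensitivity: float = 0.0
    positive_class: object = None
    orientation: str = "high"  # positive class scores high or low


def roc_curve(scores, labels, positive_class) -> RocResult:
    """ROC analysis of one score against binary labels.

    AUC is the trapezoidal area, equal to the Mann-Whitney estimate
    U/(n0*n1) including ties; its p-value comes from the two-sided
    Mann-Whitney U test (exact for small tie-free samples, normal
    approximation otherwise). The orientation is auto-selected so that
    AUC >= 0.5 and recorded. Best accuracy is maximized over the
    empirical thresholds, with a binomial standard error, and
    sensitivity is the true-positive rate at that threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = labels == positive_class
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n0 < 2 or n1 < 2:
        raise ValueError("need >= 2 subjects in each class")

    pos, neg = scores[y], scores[~y]
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided", method="auto")
    auc_mw = u.statistic / (n0 * n1)
    orientation = "high" if auc_mw >= 0.5 else "low"
    oriented = scores if orientation == "high" else -scores

    fpr, tpr, thr = _sk_roc_curve(y, oriented, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))

    has_ties = len(np.unique(scores)) < scores.size
    method = "exact" if (n0 * n1 <= 400 and not has_ties) else "asymptotic"
    p = stats.mannwhitneyu(
        pos, neg, alternative="two-sided", method=method
    ).pvalue

    n = n0 + n1
    acc = (tpr * n1 + (1.0 - fpr) * n0) / n
    i = int(np.argmax(acc))
    best = float(acc[i])
    return RocResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auc=auc,
        auc_p_value=float(p),
        best_accuracy=best,
        best_accuracy_se=float(np.sqrt(best * (1 - best) / n)),
        best_threshold=float(thr[i]) if orientation == "high" else float(-thr[i]),
        sensitivity=float(tpr[i]),
        positive_class=positive_class,
        orientation=orientation,
    )


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p) for 3 <= n <= 5000."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if values.size > 5000:
        raise ValueError("Shapiro-Wilk is unreliable above n = 5000")
    res = stats.shapiro(values)
    return float(res.statistic), float(res.pvalue)


# -- grid search -----------------------------------------------------------


@dataclass
class ScoreCombination:
    """Best linear ΔCt combination found by the coefficient grid search."""

    a: float
    b: float
    model: GaussianClassModel
    accuracy: float
    accuracy_se: float
    thresholds: list[float]
    sensitivity: float
    shapiro: dict = field(default_factory=dict)  # class -> (W, p)
    scores: np.ndarray = field(default=None, repr=False)
    priors: str = "empirical"


def coefficient_grid(
    coeff_range: tuple[float, float] = (-50.0, 50.0), step: float = 0.1
) -> np.ndarray:
    lo, hi = coeff_range
    n = int(round((hi - lo) / step)) + 1
    # round away linspace drift so reported coefficients are clean multiples
    return np.round(np.linspace(lo, hi, n), 10)


def grid_search_combination(
    dct_matrix,
    labels,
    positive_class=None,
    coeff_range: tuple[float, float] = (-50.0, 50.0),
    step: float = 0.1,
    priors: str = "empirical",
    min_class_sd: float = 1e-9,
) -> ScoreCombination:
    """Exhaustive search of Score = x1 + a*x2 + b*x3 maximizing accuracy.

    ``dct_matrix`` holds one column per marker ΔCt (first column has the
    fixed unit coefficient). Because the score is linear, each grid
    point's class means and variances follow from the per-class mean
    vectors and covariance matrices, so the whole grid is evaluated with
    array arithmetic rather than refitting per point. Ties on accuracy
    are broken by the smallest coefficient norm, then lexicographically
    on (a, b). Grid points whose score is (numerically) constant within
    a class are rejected.
    """
    if isinstance(dct_matrix, pd.DataFrame):
        x = dct_matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(dct_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("dct_matrix must have exactly 3 marker columns")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"labels must be binary, got {classes.tolist()}")
    if positive_class is None:
        positive_class = classes[1]
    pos_class = classes[classes == positive_class][0]
    neg_class = classes[classes != positive_class][0]
    y = (labels == positive_class).astype(int)
    x0, x1 = x[y == 0], x[y == 1]
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError("need >= 2 subjects per class")
    if priors == "empirical":
        p0 = len(x0) / len(x)
    elif priors == "equal":
        p0 = 0.5
    else:
        raise ValueError("priors must be 'empirical' or 'equal'")
    p1 = 1.0 - p0

    m0, m1 = x0.mean(axis=0), x1.mean(axis=0)
    s0c = np.cov(x0, rowvar=False, ddof=1)
    s1c = np.cov(x1, rowvar=False, ddof=1)

    grid = coefficient_grid(coeff_range, step)
    a = grid[:, None]
    b = grid[None, :]

    def _moments(m, s):
        mu = m[0] + a * m[1] + b * m[2]
        var = (
            s[0, 0]
            + a**2 * s[1, 1]
            + b**2 * s[2, 2]
            + 2 * a * s[0, 1]
            + 2 * b * s[0, 2]
            + 2 * a * b * s[1, 2]
        )
        return mu, var

    mu0g, var0g = _moments(m0, s0c)
    mu1g, var1g = _moments(m1, s1c)
    valid = (var0g > min_class_sd**2) & (var1g > min_class_sd**2)
    sd0g = np.sqrt(np.where(valid, var0g, 1.0))
    sd1g = np.sqrt(np.where(valid, var1g, 1.0))
    acc = _accuracy_grid(mu0g, sd0g, mu1g, sd1g, p0, p1)
    acc = np.where(valid, acc, -np.inf)
    if not np.isfinite(acc).any():
        raise ValueError("all grid points degenerate (constant scores)")

    best = acc.max()
    # accuracies within 1e-12 are indistinguishable (ulp noise between
    # algebraically identical grid points); treat them as exact ties
    ai, bi = np.nonzero(acc >= best - 1e-12)
    cand_a, cand_b = grid[ai], grid[bi]
    order = np.lexsort((cand_b, cand_a, cand_a**2 + cand_b**2))
    a_opt, b_opt = float(cand_a[order[0]]), float(cand_b[order[0]])

    score = x[:, 0] + a_opt * x[:, 1] + b_opt * x[:, 2]
    model = fit_gaussian_classes(score, y, priors=priors)
    accuracy, thresholds = analytic_accuracy(model)
    pred = model.predict(score)
    sens = float((pred[y == 1] == 1).mean())
    shapiro = {
        str(neg_class): shapiro_wilk(score[y == 0]),
        str(pos_class): shapiro_wilk(score[y == 1]),
    }
    n = len(score)
    return ScoreCombination(
        a=a_opt,
        b=b_opt,
        model=model,
        accuracy=float(accuracy),
        accuracy_se=float(np.sqrt(accuracy * (1 - accuracy) / n)),
        thresholds=thresholds,
        sensitivity=sens,
        shapiro=shapiro,
        scores=score,
        priors=priors,
    )


def bootstrap_accuracy_se(
    dct_matrix, labels, a: float, b: float, n_boot: int = 1000,
    priors: str = "empirical", seed: int = 0,
) -> float:
    """Bootstrap SE of the analytic accuracy at fixed coefficients.

    Subjects are resampled with replacement within each class; each
    resample refits the two Gaussians and recomputes the closed-form
    accuracy.
    """
    x = np.asarray(dct_matrix, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    score = x[:, 0] + a * x[:, 1] + b * x[:, 2]
    rng = np.random.default_rng(seed)
    accs = []
    g0 = score[labels == classes[0]]
    g1 = score[labels == classes[1]]
    for _ in range(n_boot):
        b0 = rng.choice(g0, size=g0.size, replace=True)
        b1 = rng.choice(g1, size=g1.size, replace=True)
        s = np.concatenate([b0, b1])
        y = np.concatenate([np.zeros(g0.size), np.ones(g1.size)])
        try:
            m = fit_gaussian_classes(s, y, priors=priors)
        except ValueError:
            continue
        accs.append(analytic_accuracy(m)[0])
    return float(np.std(accs, ddof=1))
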