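"""Metric and hypothesis-testing stack for ordinal multiclass grading.

Covers the full report used to benchmark a grading model against
pathologists: macro one-vs-rest AUC, accuracy, macro F1/precision/
recall, per-class NPV, the clinical utility index (CUI+ = sensitivity x
PPV, CUI- = specificity x NPV, banded excellent/good/satisfactory/
poor), quadratic weighted kappa for ordinal agreement, McNemar's paired
test on discordant classifications, DeLong's test for correlated AUCs,
and the 2x2 chi-squared with Yates continuity correction.

Metrics that are undefined on a given sample (a class absent from the
fold, a zero denominator) are flagged as NaN with an ``undefined``
marker rather than silently coerced to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats as sps
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score

from .errors import InvalidInputError
from .model import GradingScheme

CUI_BANDS = (
    (0.810, "excellent"),
    (0.640, "good"),
    (0.490, "satisfactory"),
)


def cui_band(value: float) -> str:
    """Clinical-utility band: excellent >= 0.810, good >= 0.640,
    satisfactory >= 0.490, else poor."""
    if np.isnan(value):
        return "undefined"
    for thr, name in CUI_BANDS:
        if value >= thr:
            return name
    return "poor"


@dataclass
class ConfusionMatrix:
    """K x K counts, rows = truth, columns = predicted."""

    counts: np.ndarray
    class_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise InvalidInputError("confusion matrix must be square")
        if (self.counts < 0).any() or not np.issubdtype(self.counts.dtype, np.integer):
            raise InvalidInputError("confusion matrix needs nonnegative integer counts")
        if not self.class_names:
            self.class_names = tuple(str(i) for i in range(len(self.counts)))

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray, n_classes: int, class_names=()
    ) -> "ConfusionMatrix":
        cm = np.zeros((n_classes, n_classes), dtype=np.int64)
        for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
            cm[int(t), int(p)] += 1
        return cls(cm, tuple(class_names))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, class_index: int) -> tuple[int, int, int, int]:
        """(TP, FN, FP, TN) collapsing class_index against the rest."""
        c = self.counts
        tp = int(c[class_index, class_index])
        fn = int(c[class_index].sum() - tp)
        fp = int(c[:, class_index].sum() - tp)
        tn = int(c.sum() - tp - fn - fp)
        return tp, fn, fp, tn


class CUIResult(NamedTuple):
    cui_plus: float
    cui_minus: float
    band_plus: str
    band_minus: str
    undefined: bool


def cui(cm: ConfusionMatrix, class_index: int) -> CUIResult:
    """Clinical utility index for one class, one-vs-rest.

    CUI+ = sensitivity x PPV grades rule-in utility, CUI- =
    specificity x NPV rule-out utility.  Zero denominators flag the
    metric undefined instead of raising.
    """
    tp, fn, fp, tn = cm.one_vs_rest(class_index)
    def _ratio(num, den):
        return num / den if den > 0 else np.nan

    sens = _ratio(tp, tp + fn)
    ppv = _ratio(tp, tp + fp)
    spec = _ratio(tn, tn + fp)
    npv = _ratio(tn, tn + fn)
    cp = sens * ppv
    cm_ = spec * npv
    undefined = bool(np.isnan(cp) or np.isnan(cm_))
    return CUIResult(cp, cm_, cui_band(cp), cui_band(cm_), undefined)


@dataclass
class EvalReport:
    """Slide-level evaluation summary for one task."""

    macro_auc: float
    accuracy: float
    macro_f1: float
    macro_precision: float
    macro_recall: float
    per_class_auc: np.ndarray
    per_class_npv: np.ndarray
    cui_plus: np.ndarray
    cui_minus: np.ndarray
    cui_bands: tuple[str, ...]
    confusion: ConfusionMatrix

    def to_dict(self) -> dict:
        return {
            "macro_auc": self.macro_auc,
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "per_class_auc": list(self.per_class_auc),
            "per_class_npv": list(self.per_class_npv),
            "cui_plus": list(self.cui_plus),
            "cui_minus": list(self.cui_minus),
            "cui_bands": list(self.cui_bands),
            "confusion": self.confusion.counts.tolist(),
        }


def macro_auc(y_true: np.ndarray, y_prob: np.ndarray) -> float:
    """Unweighted mean of per-class one-vs-rest AUCs; absent classes are
    excluded with a warning."""
    aucs = per_class_auc(y_true, y_prob)
    if np.isnan(aucs).all():
        return float("nan")
    return float(np.nanmean(aucs))


def per_class_auc(y_true: np.ndarray, y_prob: np.ndarray) -> np.ndarray:
    y_true = np.asarray(y_true)
    y_prob = np.atleast_2d(np.asarray(y_prob, dtype=np.float64))
    k = y_prob.shape[1]
    out = np.full(k, np.nan)
    for c in range(k):
        pos = y_true == c
        if pos.all() or not pos.any():
            warnings.warn(f"class {c} absent from y_true; AUC undefined", stacklevel=2)
            continue
        out[c] = roc_auc_score(pos.astype(int), y_prob[:, c])
    return out


def compute_report(
    y_true: np.ndarray, y_prob: np.ndarray, scheme: GradingScheme
) -> EvalReport:
    """Full metric report from truth ranks and an n x K probability matrix."""
    y_true = np.asarray(y_true)
    y_prob = np.atleast_2d(np.asarray(y_prob, dtype=np.float64))
    if y_prob.shape[1] != scheme.n_classes:
        raise InvalidInputError("probability matrix width does not match scheme")
    if not np.allclose(y_prob.sum(axis=1), 1.0, atol=1e-6):
        raise InvalidInputError("probability rows must sum to 1")
    y_pred = y_prob.argmax(axis=1)
    cm = ConfusionMatrix.from_predictions(y_true, y_pred, scheme.n_classes, scheme.class_names)
    aucs = per_class_auc(y_true, y_prob)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=np.arange(scheme.n_classes), average="macro", zero_division=np.nan
        )
    npvs, cps, cms, bands = [], [], [], []
    for c in range(scheme.n_classes):
        tp, fn, fp, tn = cm.one_vs_rest(c)
        npvs.append(tn / (tn + fn) if tn + fn > 0 else np.nan)
        r = cui(cm, c)
        cps.append(r.cui_plus)
        cms.append(r.cui_minus)
        bands.append(r.band_plus)
    return EvalReport(
        macro_auc=float(np.nanmean(aucs)) if not np.isnan(aucs).all() else float("nan"),
        accuracy=float((y_pred == y_true).mean()),
        macro_f1=float(f1),
        macro_precision=float(prec),
        macro_recall=float(rec),
        per_class_auc=aucs,
        per_class_npv=np.array(npvs),
        cui_plus=np.array(cps),
        cui_minus=np.array(cms),
        cui_bands=tuple(bands),
        confusion=cm,
    )


def quadratic_weighted_kappa(r1: np.ndarray, r2: np.ndarray, n_classes: int) -> float:
    """Chance-corrected ordinal agreement with squared-distance weights.

    ``w_ij = (i - j)^2 / (K - 1)^2``; kappa = 1 - sum(w O) / sum(w E)
    with E the outer product of the marginal distributions.
    """
    r1 = np.asarray(r1, dtype=np.int64)
    r2 = np.asarray(r2, dtype=np.int64)
    if r1.shape != r2.shape:
        raise InvalidInputError("rank vectors must have equal length")
    if len(r1) == 0 or r1.min() < 0 or r2.min() < 0 or max(r1.max(), r2.max()) >= n_classes:
        raise InvalidInputError("ranks must lie in 0..K-1 and be non-empty")
    k = n_classes
    obs = np.zeros((k, k))
    for a, b in zip(r1, r2):
        obs[a, b] += 1
    obs /= len(r1)
    marg1 = obs.sum(axis=1)
    marg2 = obs.sum(axis=0)
    expected = np.outer(marg1, marg2)
    ii, jj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    w = (ii - jj) ** 2 / (k - 1) ** 2
    denom = (w * expected).sum()
    if denom == 0:
        return 1.0  # no possible disagreement under chance
    return float(1.0 - (w * obs).sum() / denom)


class TestResult(NamedTuple):
    statistic: float
    p_value: float
    undefined: bool = False


def mcnemar_test(n01: int, n10: int, correction: bool = True, exact: bool | None = None) -> TestResult:
    """McNemar's paired test on discordant counts.

    Uses the exact two-sided binomial tail when the discordant total is
    below 25 (or when ``exact=True``), otherwise the (optionally
    continuity-corrected) chi-squared form.
    """
    if n01 < 0 or n10 < 0:
        raise InvalidInputError("discordant counts must be nonnegative")
    n = n01 + n10
    if n == 0:
        return TestResult(float("nan"), float("nan"), undefined=True)
    if exact is None:
        exact = n < 25
    if exact:
        k = min(n01, n10)
        p = float(sps.binomtest(k, n, 0.5, alternative="two-sided").pvalue)
        return TestResult(float(k), min(p, 1.0))
    diff = abs(n01 - n10) - (1.0 if correction else 0.0)
    diff = max(diff, 0.0)
    stat = diff**2 / n
    return TestResult(float(stat), float(sps.chi2.sf(stat, df=1)))


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def delong_test(y_true: np.ndarray, s1: np.ndarray, s2: np.ndarray) -> tuple[float, float, float, float]:
    """DeLong's paired test for two correlated ROC AUCs.

    Fast placement-value (midrank) implementation.  Returns
    ``(auc1, auc2, z, p)``; z is 0 and p is 1 when the paired variance
    of the difference vanishes (e.g. identical score vectors).
    """
    y_true = np.asarray(y_true).astype(int)
    if len(set(y_true.tolist())) != 2:
        raise InvalidInputError("DeLong's test needs both classes present")
    order = np.argsort(-y_true, kind="stable")
    scores = np.vstack([np.asarray(s1, float), np.asarray(s2, float)])[:, order]
    m = int(y_true.sum())
    n = len(y_true) - m
    k = 2
    tx = np.empty((k, m))
    ty = np.empty((k, n))
    tz = np.empty((k, m + n))
    for r in range(k):
        tx[r] = _midrank(scores[r, :m])
        ty[r] = _midrank(scores[r, m:])
        tz[r] = _midrank(scores[r])
    aucs = (tz[:, :m].sum(axis=1) / (m * n)) - (m + 1.0) / (2.0 * n)
    v01 = (tz[:, :m] - tx) / n
    v10 = 1.0 - (tz[:, m:] - ty) / m
    if m < 2 or n < 2:  # structural components need >= 2 per class
        var = 0.0
    else:
        sx = np.cov(v01)
        sy = np.cov(v10)
        cov = sx / m + sy / n
        var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = aucs[0] - aucs[1]
    if var <= 1e-16 or abs(delta) < 1e-16:
        z = 0.0 if abs(delta) < 1e-16 else np.sign(delta) * np.inf
    else:
        z = delta / np.sqrt(var)
    p = 1.0 if z == 0.0 else float(2.0 * sps.norm.sf(abs(z)))
    return float(aucs[0]), float(aucs[1]), float(z), p


@dataclass
class ContingencyTable2x2:
    """2x2 counts with validated positive margins."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise InvalidInputError("cells must be nonnegative integers")
        for margin in (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d):
            if margin == 0:
                raise InvalidInputError("all margins must be positive for chi-squared")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_array(cls, table) -> "ContingencyTable2x2":
        t = np.asarray(table)
        if t.shape != (2, 2):
            raise InvalidInputError("table must be 2x2")
        return cls(int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1]))


def chi2_2x2(table: ContingencyTable2x2 | np.ndarray, yates: bool = True) -> TestResult:
    """Pearson chi-squared on a 2x2 table, df = 1, two-sided.

    Defaults to the Yates continuity correction, the convention for
    modest failure-case counts.
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2.from_array(table)
    a, b, c, d, n = table.a, table.b, table.c, table.d, table.n
    det = abs(a * d - b * c)
    if yates:
        det = max(det - n / 2.0, 0.0)
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    stat = n * det**2 / denom
    return TestResult(float(stat), float(sps.chi2.sf(stat, df=1)))
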