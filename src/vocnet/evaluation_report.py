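"""Clinical screening evaluation: confusion matrices, metric suite, reports.

The positive class is the LL (low-language) outcome. From a 2x2 confusion
matrix the suite derives sensitivity, specificity, balanced accuracy
((sens + spec)/2), predictive values, and the prevalence-independent
likelihood ratios LR+ = sens/(1 - spec) and LR- = (1 - sens)/spec.

Degenerate denominators follow the metrics' clinical reading: a perfect
specificity gives LR+ = +inf (serialized "Inf"), zero specificity gives
LR- = +inf, and predictive values with empty denominators are reported as
missing (NaN), never as 0. Display rounding is half-up at 2 decimals; full
precision is kept in machine-readable output.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "ScreeningMetrics",
    "TTestResult",
    "confusion",
    "screening_metrics",
    "from_rates",
    "balanced_accuracy_test",
    "significance_stars",
    "round_half_up",
    "format_metric",
    "performance_row",
    "performance_table",
    "report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count the 2x2 table; positive class is LL = 1."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    values = set(np.unique(y_true)) | set(np.unique(y_pred))
    if not values <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got values {sorted(values)}")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


@dataclass(frozen=True)
class ScreeningMetrics:
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    ppv: float
    npv: float
    lr_plus: float
    lr_minus: float

    def as_dict(self) -> dict:
        return {
            "BalAcc": self.balanced_accuracy,
            "Sens": self.sensitivity,
            "Spec": self.specificity,
            "PPV": self.ppv,
            "NPV": self.npv,
            "LR+": self.lr_plus,
            "LR-": self.lr_minus,
        }


def _ratio(num: float, den: float) -> float:
    if den == 0:
        return float("nan") if num == 0 else float("inf")
    return num / den


def screening_metrics(cm: ConfusionMatrix) -> ScreeningMetrics:
    """The seven-screening-metric suite from a confusion matrix.

    Accepts a ConfusionMatrix; use :func:`from_rates` to derive likelihood
    ratios directly from published sensitivity/specificity pairs.
    """
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    return _metrics_from(sens, spec, cm)


def from_rates(sensitivity: float, specificity: float) -> ScreeningMetrics:
    """Metric suite from a (sensitivity, specificity) pair alone.

    PPV/NPV need counts and are reported as NaN here.
    """
    return _metrics_from(sensitivity, specificity, None)


def _metrics_from(sens: float, spec: float, cm: ConfusionMatrix | None) -> ScreeningMetrics:
    bal = (sens + spec) / 2.0 if np.isfinite(sens) and np.isfinite(spec) else float("nan")
    lr_plus = _ratio(sens, 1.0 - spec) if np.isfinite(sens) and np.isfinite(spec) else float("nan")
    lr_minus = _ratio(1.0 - sens, spec) if np.isfinite(sens) and np.isfinite(spec) else float("nan")
    if cm is not None:
        ppv = _ratio(cm.tp, cm.tp + cm.fp)
        npv = _ratio(cm.tn, cm.tn + cm.fn)
        # empty denominators mean "no prediction of that class": missing, not 0
        ppv = float("nan") if np.isinf(ppv) else ppv
        npv = float("nan") if np.isinf(npv) else npv
    else:
        ppv = npv = float("nan")
    return ScreeningMetrics(
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=bal,
        ppv=ppv,
        npv=npv,
        lr_plus=lr_plus,
        lr_minus=lr_minus,
    )


@dataclass(frozen=True)
class TTestResult:
    n: int
    mean: float
    t: float
    p: float
    degenerate: bool = False

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("t-test requires at least 2 runs")


def balanced_accuracy_test(values, baseline: float = 0.5) -> TTestResult:
    """One-sided one-sample t-test of per-run balanced accuracies vs chance.

    H1: mean balanced accuracy exceeds ``baseline``. Constant inputs give an
    explicit degenerate result (t and p NaN) rather than a silent p-value.
    """
    values = np.asarray(list(values), dtype=float)
    if len(values) < 2:
        raise ValueError("need >= 2 balanced-accuracy values")
    if np.ptp(values) == 0.0:
        return TTestResult(
            n=len(values), mean=float(values.mean()), t=float("nan"), p=float("nan"),
            degenerate=True,
        )
    res = stats.ttest_1samp(values, popmean=baseline, alternative="greater")
    return TTestResult(
        n=len(values), mean=float(values.mean()), t=float(res.statistic), p=float(res.pvalue)
    )


def significance_stars(p: float) -> str:
    """Footnote convention: *** p < .0001, ** p < .001, * p < .01."""
    if not np.isfinite(p):
        return ""
    if p < 1e-4:
        return "***"
    if p < 1e-3:
        return "**"
    if p < 1e-2:
        return "*"
    return ""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), the convention of the report
    tables; NaN/inf pass through."""
    if not np.isfinite(x):
        return float(x)
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_metric(x: float, ndigits: int = 2) -> str:
    if np.isnan(x):
        return "NA"
    if np.isinf(x):
        return "Inf"
    return f"{round_half_up(x, ndigits):.{ndigits}f}"


def performance_row(name: str, y_true, y_pred, run_balanced_accuracies=None) -> dict:
    """One Train/Test row of the performance table, with significance stars
    when per-run balanced accuracies are supplied."""
    metrics = screening_metrics(confusion(y_true, y_pred))
    row = {"Train/Test": name, **metrics.as_dict()}
    if run_balanced_accuracies is not None and len(run_balanced_accuracies) >= 2:
        test = balanced_accuracy_test(run_balanced_accuracies)
        row["stars"] = "" if test.degenerate else significance_stars(test.p)
        row["p_value"] = test.p
    else:
        row["stars"] = ""
        row["p_value"] = float("nan")
    return row


def performance_table(rows: list[dict], display: bool = True) -> pd.DataFrame:
    """Assemble rows into the report table; ``display=True`` renders metric
    cells as 2-dp half-up strings ("Inf"/"NA" for degeneracies)."""
    df = pd.DataFrame(rows)
    if display:
        for col in ("BalAcc", "Sens", "Spec", "PPV", "NPV", "LR+", "LR-"):
            df[col] = df[col].map(format_metric)
        df["BalAcc"] = df["BalAcc"] + df.pop("stars")
        df = df.drop(columns=["p_value"])
    return df


def importance_figure(importance: pd.DataFrame, path: str | Path) -> bool:
    """Horizontal-bar plot of the mean importance ranking; skipped (False)
    with a warning when the report is empty."""
    import warnings

    if importance is None or importance.empty:
        warnings.warn("empty importance report; plot skipped", stacklevel=2)
        return False
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = importance.sort_values("importance")
    fig, ax = plt.subplots(figsize=(6, 0.35 * len(df) + 1.2))
    ax.barh(df["feature"], df["importance"], color="#4878a8")
    ax.set_xlabel("mean importance (accuracy percentage points)")
    ax.set_title("Drop-one feature importance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return True


def report(results: dict, out_dir: str | Path, plot: bool = True) -> dict:
    """Write the performance table, importance ranking and JSON mirror.

    ``results`` maps a row name (e.g. ``"cohortA-younger"`` or
    ``"A->B"``) to a dict with keys ``y_true``, ``y_pred``, optionally
    ``run_balanced_accuracies`` and ``importance`` (a DataFrame). Returns
    the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        performance_row(
            name, r["y_true"], r["y_pred"], r.get("run_balanced_accuracies")
        )
        for name, r in results.items()
    ]
    display = performance_table(rows, display=True)
    machine = performance_table(rows, display=False)
    paths = {}
    display_path = out_dir / "performance.csv"
    display.to_csv(display_path, index=False)
    paths["performance"] = display_path
    machine_path = out_dir / "performance_full.json"
    machine.to_json(machine_path, orient="records", indent=1)
    paths["performance_full"] = machine_path
    importances = [
        r["importance"].assign(model=name)
        for name, r in results.items()
        if r.get("importance") is not None
    ]
    if importances:
        imp = pd.concat(importances, ignore_index=True)
        imp_path = out_dir / "importance.csv"
        imp.to_csv(imp_path, index=False)
        paths["importance"] = imp_path
        if plot:
            fig_path = out_dir / "importance.png"
            if importance_figure(imp.groupby("feature", as_index=False)["importance"].mean(),
                                 fig_path):
                paths["figure"] = fig_path
    return paths
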