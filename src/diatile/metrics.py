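"""Pixel-based segmentation metrics and the additive factor-effect model.

Segmentation quality is scored per pixel against the binary ground truth:

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    Dice      = 2 TP / (2 TP + FP + FN)

A metric whose denominator is zero is *undefined* and carried as None, never
as a sentinel 0 or 1; aggregations skip undefined entries and report how many
were skipped.  The Jaccard index is deliberately omitted — it is a monotone
transform of Dice and adds no information.

Factor effects across the experimental grid (tiling method x training-set
size x score threshold, replicated over slides) are summarized by an ordinary
least-squares fit of an additive linear model with treatment (dummy) coding:
the intercept is the metric in the baseline cell and every coefficient is the
delta attached to switching one factor level, with t-based two-sided
p-values as descriptive output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

TILING_LEVELS = ("fixed_stride", "object_based", "object_based_oic")
SUBSET_LEVELS = (0.10, 0.25, 0.50, 1.00)
THRESHOLD_LEVELS = (0.90, 0.95, 0.98)
BASELINE_LEVELS = {"tiling_method": "fixed_stride", "subset_size": 0.10,
                   "threshold": 0.90}

FACTORS = ("tiling_method", "subset_size", "threshold")
RESPONSES = ("precision", "recall", "dice")


@dataclass(frozen=True)
class PixelMetrics:
    """Confusion counts and the derived pixel metrics (None = undefined)."""

    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def precision(self) -> float | None:
        d = self.TP + self.FP
        return self.TP / d if d else None

    @property
    def recall(self) -> float | None:
        d = self.TP + self.FN
        return self.TP / d if d else None

    @property
    def dice(self) -> float | None:
        d = 2 * self.TP + self.FP + self.FN
        return 2 * self.TP / d if d else None

    def as_dict(self) -> dict:
        return {
            "TP": self.TP, "FP": self.FP, "FN": self.FN, "TN": self.TN,
            "precision": self.precision, "recall": self.recall,
            "dice": self.dice,
        }


def pixel_confusion(pred: np.ndarray, gt: np.ndarray) -> PixelMetrics:
    """Exact pixel confusion counts between two same-shaped binary masks."""
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError(
            f"mask shapes differ: pred {pred.shape} vs gt {gt.shape}"
        )
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = int(pred.size - tp - fp - fn)
    return PixelMetrics(TP=tp, FP=fp, FN=fn, TN=tn)


@dataclass
class ExperimentRecord:
    """One cell of the factorial experiment for one slide replicate."""

    tiling_method: str
    subset_size: float
    threshold: float
    metrics: PixelMetrics
    model_tag: str = "oracle"
    slide_id: str = "slide0"

    def __post_init__(self) -> None:
        if self.tiling_method not in TILING_LEVELS:
            raise ValueError(f"unknown tiling method {self.tiling_method!r}")


@dataclass
class EffectsFit:
    """Treatment-coded additive-model fit, one sub-fit per response."""

    baseline_levels: dict
    baseline: dict[str, float]
    coefficients: dict[str, dict[str, float]]
    std_errors: dict[str, dict[str, float]]
    p_values: dict[str, dict[str, float]]
    n_obs: int
    n_skipped: dict[str, int] = field(default_factory=dict)

    def predicted_baseline(self, response: str) -> float:
        return self.baseline[response]

    def to_frame(self, response: str) -> pd.DataFrame:
        """Effects table: baseline row followed by delta rows."""
        rows = [{"term": "baseline", "estimate": self.baseline[response],
                 "std_error": np.nan, "p_value": np.nan}]
        for term, est in self.coefficients[response].items():
            rows.append({
                "term": term, "estimate": est,
                "std_error": self.std_errors[response][term],
                "p_value": self.p_values[response][term],
            })
        return pd.DataFrame(rows)


def records_frame(records: list[ExperimentRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "tiling_method": r.tiling_method,
            "subset_size": r.subset_size,
            "threshold": r.threshold,
            "model_tag": r.model_tag,
            "slide_id": r.slide_id,
        }
        row.update({k: r.metrics.as_dict()[k] for k in
                    ("TP", "FP", "FN", "TN", *RESPONSES)})
        rows.append(row)
    return pd.DataFrame(rows)


def fit_additive_effects(
    records: list[ExperimentRecord],
    baseline_levels: dict | None = None,
    responses: tuple[str, ...] = RESPONSES,
) -> EffectsFit:
    """OLS fit of metric ~ tiling_method + subset_size + threshold.

    Factors are treatment-coded against ``baseline_levels`` (default: fixed
    stride, 10% subset, 0.90 threshold), so the intercept is the fitted
    baseline-cell value and each coefficient the additive delta for one
    level switch.  Records with an undefined response are skipped for that
    response (counted in ``n_skipped``).
    """
    baseline_levels = dict(BASELINE_LEVELS, **(baseline_levels or {}))
    df = records_frame(records)
    for f in FACTORS:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels in the data")
        if baseline_levels[f] not in set(df[f]):
            raise ValueError(
                f"baseline level {baseline_levels[f]!r} absent for {f!r}"
            )

    baseline, coefs, ses, pvals, skipped = {}, {}, {}, {}, {}
    formula_rhs = " + ".join(
        f"C({f}, Treatment(reference={baseline_levels[f]!r}))"
        if isinstance(baseline_levels[f], str)
        else f"C({f}, Treatment(reference={baseline_levels[f]}))"
        for f in FACTORS
    )
    for resp in responses:
        sub = df[df[resp].notna()].copy()
        skipped[resp] = len(df) - len(sub)
        if sub.empty:
            raise ValueError(f"no defined values for response {resp!r}")
        try:
            fit = smf.ols(f"{resp} ~ {formula_rhs}", data=sub).fit()
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"rank-deficient design for response {resp!r}: {exc}"
            ) from exc
        if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
            raise ValueError(
                f"rank-deficient design for response {resp!r}: some factor "
                "combinations are unobserved"
            )
        baseline[resp] = float(fit.params["Intercept"])
        coefs[resp] = {}
        ses[resp] = {}
        pvals[resp] = {}
        for name in fit.params.index:
            if name == "Intercept":
                continue
            short = _shorten_term(name)
            coefs[resp][short] = float(fit.params[name])
            ses[resp][short] = float(fit.bse[name])
            pvals[resp][short] = float(fit.pvalues[name])
    return EffectsFit(
        baseline_levels=baseline_levels,
        baseline=baseline,
        coefficients=coefs,
        std_errors=ses,
        p_values=pvals,
        n_obs=len(df),
        n_skipped=skipped,
    )


def _shorten_term(name: str) -> str:
    # "C(tiling_method, Treatment(reference='fixed_stride'))[T.object_based]"
    # -> "tiling_method[object_based]"
    factor = name.split("(")[1].split(",")[0]
    level = name.split("[T.")[1].rstrip("]")
    return f"{factor}[{level}]"


def summarize_factorial(records: list[ExperimentRecord]) -> pd.DataFrame:
    """Mean metrics per factor combination, averaged over slide replicates.

    Undefined metrics are skipped in the means; ``n_defined_<metric>``
    columns report how many replicates contributed.
    """
    df = records_frame(records)
    out_rows = []
    group_cols = ["model_tag", "tiling_method", "subset_size", "threshold"]
    for key, grp in df.groupby(group_cols, sort=True):
        row = dict(zip(group_cols, key))
        row["n_replicates"] = len(grp)
        for resp in RESPONSES:
            vals = grp[resp].dropna()
            row[resp] = vals.mean() if len(vals) else np.nan
            row[f"n_defined_{resp}"] = int(len(vals))
        out_rows.append(row)
    return pd.DataFrame(out_rows)
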