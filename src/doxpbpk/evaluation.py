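"""Model-qualification arithmetic: NCA, fold error, GMFE, coverage.

Non-compartmental analysis uses the linear-up/log-down trapezoid to the
last sampled point, with the terminal slope (lambda_z) from an unweighted
log-linear regression over the last 3–5 post-peak points chosen by best
adjusted r^2, and AUC extrapolation C_last/lambda_z. The fold error is
the plain predicted/observed ratio; the geometric mean fold error is

    GMFE = 10 ** mean(|log10(pred_i / obs_i)|)

so 1.0 is perfect and the measure is symmetric under swapping predicted
and observed. Display rounding is half-up to two decimals, matching how
such comparisons are conventionally printed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from .errors import EvaluationError, NCAError

__all__ = [
    "PKMetrics",
    "EvaluationPair",
    "nca",
    "fold_error",
    "gmfe",
    "coverage_fraction",
    "evaluation_table",
    "load_observed_predicted",
    "pairs_from_frame",
    "round_half_up",
]

#: AUC extrapolation fraction above which metrics are flagged
EXTRAPOLATION_FLAG_THRESHOLD = 0.2


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (1.005 -> 1.01), as report tables print."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PKMetrics:
    """Exposure metrics of one concentration–time profile."""

    auc_inf: float          # nmol*hr/L
    auc_last: float
    cmax: float             # nmol/L
    tmax: float             # h
    lambda_z: float         # 1/h
    extrapolated_fraction: float
    n_lambda_points: int
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class EvaluationPair:
    """One predicted/observed PK-parameter comparison."""

    label: str
    compound: str
    genotype: str
    metric: str             # AUC | Cmax | Tmax | concentration
    observed: float
    predicted: float
    unit: str = ""

    def __post_init__(self):
        if self.observed <= 0 or self.predicted <= 0:
            raise EvaluationError(
                f"{self.label}/{self.compound}/{self.metric}: observed and "
                "predicted values must be > 0"
            )


def _lambda_z(times, conc, tmax_idx):
    """Terminal log-linear slope over the best 3-5 point tail window.

    Returns (lambda_z, n_points, adj_r2) or None when no window with a
    negative slope exists among the post-peak positive concentrations.
    """
    tail = np.nonzero((np.arange(len(conc)) > tmax_idx) & (conc > 0))[0]
    best = None
    for k in (3, 4, 5):
        if len(tail) < k:
            break
        idx = tail[-k:]
        t, logc = times[idx], np.log(conc[idx])
        slope, intercept = np.polyfit(t, logc, 1)
        if slope >= 0:
            continue
        fitted = slope * t + intercept
        ss_res = float(np.sum((logc - fitted) ** 2))
        ss_tot = float(np.sum((logc - logc.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
        if best is None or adj > best[2]:
            best = (-slope, k, adj)
    return best


def _auc_trapezoid(times, conc):
    """Linear-up/log-down trapezoid to the last sampled point."""
    auc = 0.0
    for i in range(len(times) - 1):
        dt = times[i + 1] - times[i]
        c1, c2 = conc[i], conc[i + 1]
        if c2 < c1 and c2 > 0:
            auc += (c1 - c2) / math.log(c1 / c2) * dt
        else:
            auc += 0.5 * (c1 + c2) * dt
    return auc


def nca(profile) -> PKMetrics:
    """Non-compartmental exposure metrics for one profile.

    Requires at least three time points and a non-zero profile. If no
    terminal slope can be estimated the metrics carry a ``no-lambda-z``
    flag and ``auc_inf`` falls back to ``auc_last``.
    """
    times = np.asarray(profile.times_h, dtype=float)
    conc = np.asarray(profile.concentrations, dtype=float)
    if len(times) < 3:
        raise NCAError("NCA needs at least three time points")
    if np.all(conc == 0):
        raise NCAError("all-zero profile")
    if np.any(conc < 0):
        raise NCAError("negative concentrations")

    tmax_idx = int(np.argmax(conc))
    cmax = float(conc[tmax_idx])
    tmax = float(times[tmax_idx])
    auc_last = _auc_trapezoid(times, conc)

    flags: list[str] = []
    fit = _lambda_z(times, conc, tmax_idx)
    if fit is None:
        flags.append("no-lambda-z")
        lam, n_pts, extrap = math.nan, 0, 0.0
        auc_inf = auc_last
    else:
        lam, n_pts, adj_r2 = fit
        if adj_r2 < 0.8:
            flags.append("poor-lambda-z-fit")
        c_last = conc[conc > 0][-1]
        tail = c_last / lam
        auc_inf = auc_last + tail
        extrap = tail / auc_inf
        if extrap >= EXTRAPOLATION_FLAG_THRESHOLD:
            flags.append("high-extrapolation")
    return PKMetrics(
        auc_inf=float(auc_inf),
        auc_last=float(auc_last),
        cmax=cmax,
        tmax=tmax,
        lambda_z=lam,
        extrapolated_fraction=float(extrap),
        n_lambda_points=n_pts,
        flags=tuple(flags),
    )


def fold_error(predicted: float, observed: float) -> float:
    """Predicted/observed ratio of a PK parameter."""
    if predicted <= 0 or observed <= 0:
        raise EvaluationError("fold error requires positive predicted and observed values")
    return predicted / observed


def gmfe(pairs) -> float:
    """Geometric mean fold error over predicted/observed pairs (>= 1)."""
    pairs = list(pairs)
    if not pairs:
        raise EvaluationError("gmfe requires at least one pair")
    x = np.mean([abs(math.log10(p.predicted / p.observed)) for p in pairs])
    return 10.0 ** x


def coverage_fraction(fold_errors, bound: float) -> float:
    """Fraction of fold errors within [1/bound, bound]."""
    fe = np.asarray(list(fold_errors), dtype=float)
    if fe.size == 0:
        raise EvaluationError("coverage_fraction requires at least one fold error")
    if bound <= 1:
        raise EvaluationError("bound must be > 1")
    return float(np.mean((fe >= 1.0 / bound) & (fe <= bound)))


def load_observed_predicted() -> pd.DataFrame:
    """Bundled observed/reported-predicted exposure table (all groups)."""
    with resources.files("doxpbpk.data").joinpath("observed_predicted.csv").open() as fh:
        return pd.read_csv(fh)


def pairs_from_frame(frame: pd.DataFrame) -> list[EvaluationPair]:
    """Rows of a label/compound/cyp2d6/metric/observed/predicted table."""
    return [
        EvaluationPair(
            label=row.label,
            compound=row.compound,
            genotype=row.cyp2d6,
            metric=row.metric,
            observed=float(row.observed),
            predicted=float(row.predicted),
            unit=getattr(row, "unit", ""),
        )
        for row in frame.itertuples(index=False)
    ]


def evaluation_table(pairs) -> pd.DataFrame:
    """Per-row fold errors plus per compound/metric GMFE summary rows.

    Fold errors are displayed half-up at two decimals; the underlying
    ratios stay full precision in the ``fold_error_raw`` column.
    """
    pairs = list(pairs)
    columns = [
        "label", "compound", "genotype", "metric",
        "observed", "predicted", "fold_error", "fold_error_raw", "gmfe",
    ]
    if not pairs:
        return pd.DataFrame(columns=columns)
    rows = []
    for p in pairs:
        fe = fold_error(p.predicted, p.observed)
        rows.append(
            {
                "label": p.label, "compound": p.compound, "genotype": p.genotype,
                "metric": p.metric, "observed": p.observed, "predicted": p.predicted,
                "fold_error": round_half_up(fe, 2), "fold_error_raw": fe,
                "gmfe": np.nan,
            }
        )
    table = pd.DataFrame(rows, columns=columns)
    summaries = []
    for (compound, metric), group in table.groupby(["compound", "metric"], sort=False):
        sub = [p for p in pairs if p.compound == compound and p.metric == metric]
        summaries.append(
            {
                "label": "GMFE", "compound": compound, "genotype": "all",
                "metric": metric, "observed": np.nan, "predicted": np.nan,
                "fold_error": np.nan, "fold_error_raw": np.nan,
                "gmfe": round_half_up(gmfe(sub), 2),
            }
        )
    return pd.concat([table, pd.DataFrame(summaries, columns=columns)], ignore_index=True)


def format_evaluation_table(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering of :func:`evaluation_table` output."""
    if table.empty:
        return " | ".join(table.columns)
    show = table.drop(columns=["fold_error_raw"]).copy()
    return show.to_string(index=False, na_rep="-", float_format=lambda v: f"{v:.2f}")
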