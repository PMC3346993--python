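"""Second-order calibration: from resolved scores to concentrations.

Because the trilinear decomposition is unique, the C-column of an
analyte is proportional to its concentration across samples even when
uncalibrated interferents are present in the unknowns (the second-order
advantage). Calibration is therefore a single proportionality fitted
through the origin on the calibration standards:

    score_k = k * y_k        (calibration samples)
    y_hat   = score / k      (prediction samples)

Accuracy is scored by per-sample recovery (100 * predicted/added), its
mean and standard deviation, and the root mean square error of
prediction, RMSEP = sqrt(sum_i (y_i - y_hat_i)^2 / m).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from tricalib.datacube import CalibrationDesign
from tricalib.decompose import LoadingSet

__all__ = [
    "PredictionReport",
    "score_regression",
    "predict_concentrations",
    "direct_prediction",
    "rmsep",
    "recovery_table",
    "round_half_up",
]


@dataclass(frozen=True)
class PredictionReport:
    """Predicted concentrations with recovery and error statistics.

    Frames are indexed by prediction-sample id with one column per
    analyte; recoveries are defined only where the added concentration
    is known and positive. ``coefficients`` holds the per-analyte
    regression coefficient k (score per concentration unit).
    """

    predicted: pd.DataFrame
    added: pd.DataFrame
    recovery_percent: pd.DataFrame
    mean_recovery: pd.Series
    recovery_sd: pd.Series
    rmsep: pd.Series
    coefficients: pd.Series
    algorithm: str = ""
    conc_unit: str = "mg/mL"

    @property
    def analyte_names(self) -> tuple[str, ...]:
        return tuple(self.predicted.columns)


def score_regression(
    C_column: np.ndarray, design: CalibrationDesign, analyte: str,
    sample_ids=None,
) -> float:
    """Proportionality k between resolved scores and known concentrations.

    Least-squares fit of score = k * y through the origin over the
    calibration samples; k converts a concentration into a score, so
    predictions are score / k. ``sample_ids`` gives the sample order of
    ``C_column`` (defaults to the design's role order).
    """
    scores = np.asarray(C_column, dtype=float)
    ids = [str(s) for s in (sample_ids if sample_ids is not None else design.roles.index)]
    if len(ids) != scores.size:
        raise ValueError("C_column length does not match the sample list")
    cal = design.sample_ids_with_role("calibration")
    y = design.known_conc.loc[cal, analyte].to_numpy(dtype=float)
    s = scores[[ids.index(c) for c in cal]]
    if len(cal) < 2 or np.unique(y).size < 2:
        raise ValueError("need at least two distinct calibration levels")
    if np.allclose(s, 0.0):
        raise ValueError(f"all calibration scores for {analyte!r} are zero")
    return float((y @ s) / (y @ y))


def predict_concentrations(
    loadings: LoadingSet, design: CalibrationDesign
) -> PredictionReport:
    """Calibrate and predict from a joint decomposition.

    Requires loadings aligned by :func:`~tricalib.decompose.align_factors`
    so that the first components correspond to the design's analytes in
    order. Fits k per analyte on the calibration samples, converts the
    prediction-sample scores to concentrations, and fills recoveries and
    RMSEP where the added concentrations are known.
    """
    if not loadings.sample_ids:
        raise ValueError("loadings carry no sample ids; decompose a DataCube first")
    names = list(design.analyte_names)
    matched = set(loadings.component_names[: len(names)])
    if matched != set(names):
        raise ValueError(
            f"loadings are not aligned to analytes {names}; run align_factors "
            "with the analyte reference spectra first"
        )
    design.roles.loc[list(loadings.sample_ids)]  # KeyError -> missing roles
    scores = loadings.scores()
    pred_ids = [s for s in loadings.sample_ids if design.role_of(s) == "prediction"]

    k = {}
    predicted = pd.DataFrame(index=pred_ids, columns=names, dtype=float)
    for a in names:
        k[a] = score_regression(
            scores[a].to_numpy(), design, a, sample_ids=loadings.sample_ids
        )
        predicted[a] = scores.loc[pred_ids, a] / k[a]

    added = design.known_conc.reindex(index=pred_ids, columns=names).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        recovery = 100.0 * predicted / added.where(added > 0)

    mean_rec, sd_rec, errs = {}, {}, {}
    for a in names:
        r = recovery[a].dropna()
        mean_rec[a] = float(r.mean()) if len(r) else math.nan
        sd_rec[a] = float(r.std(ddof=1)) if len(r) > 1 else math.nan
        known = added[a].notna()
        errs[a] = (
            rmsep(added.loc[known, a].to_numpy(), predicted.loc[known, a].to_numpy())
            if known.any()
            else math.nan
        )
    return PredictionReport(
        predicted=predicted,
        added=added,
        recovery_percent=recovery,
        mean_recovery=pd.Series(mean_rec),
        recovery_sd=pd.Series(sd_rec),
        rmsep=pd.Series(errs),
        coefficients=pd.Series(k),
        algorithm=loadings.algorithm,
        conc_unit=design.conc_unit,
    )


def direct_prediction(X_un: np.ndarray, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Score vector of one unknown sample from its own slab.

    Implements c_hat = diag(A^+ X_un (B^T)^+), the rank-annihilation
    style route. Every component present in X_un — interferents
    included — must be represented by a column of A and B, otherwise
    the estimates are biased.
    """
    X_un = np.asarray(X_un, dtype=float)
    if X_un.shape != (A.shape[0], B.shape[0]):
        raise ValueError(
            f"slab shape {X_un.shape} does not match profiles "
            f"({A.shape[0]}, {B.shape[0]})"
        )
    for M, name in ((A, "A"), (B, "B")):
        s = np.linalg.svd(M, compute_uv=False)
        if s[-1] < 1e-10 * s[0]:
            raise np.linalg.LinAlgError(f"{name} is rank-deficient")
    return np.diag(np.linalg.pinv(A) @ X_un @ np.linalg.pinv(B.T))


def rmsep(added: np.ndarray, predicted: np.ndarray) -> float:
    """Root mean square error of prediction, sqrt(sum (y - y_hat)^2 / m)."""
    y = np.asarray(added, dtype=float).ravel()
    yhat = np.asarray(predicted, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty input")
    if y.size != yhat.size:
        raise ValueError(f"length mismatch: {y.size} vs {yhat.size}")
    return float(np.sqrt(np.sum((y - yhat) ** 2) / y.size))


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal rounding with ties away from zero (report convention)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    return round_half_up(x, sig - 1 - exponent)


def recovery_table(report: PredictionReport) -> pd.DataFrame:
    """Per-sample determination table in the conventional layout.

    One block of rows per prediction sample (added, predicted, recovery
    rounded to 1 decimal), followed by summary rows with the mean +/-
    sd recovery (integer percent, sd undefined for a single sample) and
    the RMSEP (2 significant figures). Half-up rounding throughout.
    """
    rows = []
    for sid in report.predicted.index:
        row: dict = {"sample": sid}
        for a in report.analyte_names:
            row[f"{a}_added"] = report.added.loc[sid, a]
            row[f"{a}_predicted"] = round_half_up(report.predicted.loc[sid, a], 2)
            rec = report.recovery_percent.loc[sid, a]
            row[f"{a}_recovery_percent"] = (
                round_half_up(rec, 1) if pd.notna(rec) else math.nan
            )
        rows.append(row)
    summary: dict = {"sample": "mean_recovery +/- sd"}
    for a in report.analyte_names:
        mean = report.mean_recovery[a]
        sd = report.recovery_sd[a]
        mean_s = f"{round_half_up(mean):.0f}" if pd.notna(mean) else "undefined"
        sd_s = f"{round_half_up(sd):.0f}" if pd.notna(sd) else "undefined"
        summary[f"{a}_recovery_percent"] = f"{mean_s} +/- {sd_s}%"
    rows.append(summary)
    rmsep_row: dict = {"sample": f"RMSEP ({report.conc_unit})"}
    for a in report.analyte_names:
        rmsep_row[f"{a}_predicted"] = _round_sig(report.rmsep[a], 2)
    rows.append(rmsep_row)
    return pd.DataFrame(rows)
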