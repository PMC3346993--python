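"""Analytical figures of merit from resolved multiway profiles.

Based on the net analyte signal (NAS): the part of an analyte's signal
orthogonal to everything else modelled. With unit-norm profile matrices
A (chromatographic) and B (spectral) covering all N modelled species,

    SEN_n = k_n * ( [(A^T A)^-1]_nn * [(B^T B)^-1]_nn )^(-1/2)
    SEL_n =       ( [(A^T A)^-1]_nn * [(B^T B)^-1]_nn )^(-1/2)
    LOD_n = 3.3 * s0_n

where k_n is the calibration coefficient (signal per concentration
unit) and s0_n the standard deviation of the concentration estimated
for blank samples carried through the same decomposition and
calibration. Selectivity lies in (0, 1]: 1 for orthogonal profiles,
shrinking as chromatographic or spectral overlap grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FomReport", "sensitivity", "selectivity", "lod", "compute_fom"]


@dataclass(frozen=True)
class FomReport:
    """Per-analyte sensitivity, selectivity and limit of detection."""

    table: pd.DataFrame  # rows: analytes; cols: sensitivity, selectivity, lod, blank_sd
    algorithm: str = ""
    conc_unit: str = "mg/mL"
    blank_route: str = "joint decomposition + calibration coefficient"


def _gram_diag_term(A: np.ndarray, B: np.ndarray, analyte_index: int) -> float:
    n = int(analyte_index)
    for M, name in ((A, "A"), (B, "B")):
        if n >= M.shape[1]:
            raise IndexError(f"analyte_index {n} out of range for {name}")
        s = np.linalg.svd(M, compute_uv=False)
        if s[-1] < 1e-10 * s[0]:
            raise np.linalg.LinAlgError(
                f"Gram matrix of {name} is singular (collinear profiles)"
            )
    ga = np.linalg.inv(A.T @ A)[n, n]
    gb = np.linalg.inv(B.T @ B)[n, n]
    return float((ga * gb) ** -0.5)


def sensitivity(A: np.ndarray, B: np.ndarray, k: float, analyte_index: int) -> float:
    """NAS at unit concentration: k * ([(A'A)^-1]nn [(B'B)^-1]nn)^(-1/2)."""
    return float(k) * _gram_diag_term(A, B, analyte_index)


def selectivity(A: np.ndarray, B: np.ndarray, analyte_index: int) -> float:
    """Sensitivity per unit calibration coefficient (k = 1)."""
    return _gram_diag_term(A, B, analyte_index)


def lod(blank_estimates) -> float:
    """Limit of detection: 3.3 x sd of blank concentration estimates.

    Requires at least three blank estimates; the sample (m-1) standard
    deviation is used.
    """
    est = np.asarray(blank_estimates, dtype=float).ravel()
    if est.size < 3:
        raise ValueError(f"need >= 3 blank estimates, got {est.size}")
    return float(3.3 * np.std(est, ddof=1))


def compute_fom(
    loadings,
    coefficients: pd.Series,
    design,
) -> FomReport:
    """Full FOM report from aligned loadings and a fitted calibration.

    ``loadings`` must come from a joint decomposition that included the
    blank samples and be aligned so the leading components are the
    design's analytes; blank concentration estimates are the blanks'
    C-scores divided by the same per-analyte coefficient k used for
    prediction.
    """
    names = list(design.analyte_names)
    scores = loadings.scores()
    blank_ids = [s for s in loadings.sample_ids if design.role_of(s) == "blank"]
    rows = {}
    for idx, a in enumerate(names):
        k = float(coefficients[a])
        sel = selectivity(loadings.A, loadings.B, idx)
        blank_conc = scores.loc[blank_ids, a].to_numpy() / k
        s0 = float(np.std(blank_conc, ddof=1)) if len(blank_ids) >= 2 else np.nan
        rows[a] = {
            "sensitivity": k * sel,
            "selectivity": sel,
            "lod": lod(blank_conc) if len(blank_ids) >= 3 else np.nan,
            "blank_sd": s0,
        }
    return FomReport(
        table=pd.DataFrame.from_dict(rows, orient="index"),
        algorithm=loadings.algorithm,
        conc_unit=design.conc_unit,
    )
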