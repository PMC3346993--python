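"""Chemical-rank estimation via the core consistency diagnostic.

A PARAFAC model with the right number of components should reproduce
the least-squares Tucker core of the data as a superdiagonal identity
array. The core consistency (CORCONDIA) quantifies this: it stays near
100% while the trial number of components is at or below the chemical
rank and collapses (below 50%) once surplus components start modelling
noise or splitting true factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tricalib.datacube import DataCube
from tricalib.decompose import FitOptions, LoadingSet, parafac_als

__all__ = ["RankScan", "corcondia", "scan_components"]

_PINV_CUTOFF = 1e-10


@dataclass(frozen=True)
class RankScan:
    """CORCONDIA and fit traces over candidate component numbers."""

    candidate_n: tuple[int, ...]
    corcondia_percent: tuple[float, ...]
    fit_percent: tuple[float, ...]
    chosen_n: int | None
    threshold: float = 50.0
    errors: dict = field(default_factory=dict)  # candidate -> error message

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_components": self.candidate_n,
                "fit_percent": self.fit_percent,
                "corcondia_percent": self.corcondia_percent,
            }
        )


def corcondia(cube: DataCube, loadings: LoadingSet) -> float:
    """Core consistency of a fitted PARAFAC model, in percent.

    Solves the least-squares Tucker core G of the data given the fixed
    loadings (via mode-wise pseudo-inverses, cutoff 1e-10 for
    near-collinear factors) and returns

        100 * (1 - sum((g_def - t_def)^2) / sum(t_def^2))

    with T the N x N x N superdiagonal array of ones. For N = 1 the
    scalar core of a fitted model equals 1 by the ALS stationarity
    condition, so 100 is returned in closed form.
    """
    N = loadings.n_components
    if N == 1:
        return 100.0
    for M, name in ((loadings.A, "A"), (loadings.B, "B"), (loadings.C, "C")):
        s = np.linalg.svd(M, compute_uv=False)
        if s[-1] < _PINV_CUTOFF * s[0]:
            raise np.linalg.LinAlgError(
                f"loading matrix {name} is numerically rank-deficient "
                "(collinear factors); core consistency is undefined"
            )
    Ap = np.linalg.pinv(loadings.A, rcond=_PINV_CUTOFF)
    Bp = np.linalg.pinv(loadings.B, rcond=_PINV_CUTOFF)
    Cp = np.linalg.pinv(loadings.C, rcond=_PINV_CUTOFF)
    G = np.einsum("di,ej,fk,ijk->def", Ap, Bp, Cp, cube.values)
    T = np.zeros((N, N, N))
    T[np.arange(N), np.arange(N), np.arange(N)] = 1.0
    return float(100.0 * (1.0 - np.sum((G - T) ** 2) / N))


def scan_components(
    cube: DataCube,
    n_range,
    options: FitOptions | None = None,
    threshold: float = 50.0,
) -> RankScan:
    """Fit each candidate N and pick the rank by the CORCONDIA rule.

    Uses unconstrained PARAFAC-ALS fits (the diagnostic's standard
    setting, regardless of whether calibration later applies
    nonnegativity). ``chosen_n`` is the largest candidate whose core
    consistency stays at or above ``threshold`` (default 50, the
    conventional collapse level); ``None`` if no candidate qualifies.
    Failed fits are recorded per candidate, not fatal.
    """
    candidates = sorted(int(n) for n in n_range)
    if not candidates:
        raise ValueError("n_range is empty")
    base = options or FitOptions(n_components=candidates[0])
    cc, fits, errors = [], [], {}
    for n in candidates:
        opts = FitOptions(
            n_components=n,
            tol=base.tol,
            max_iter=base.max_iter,
            nonnegative=(),  # unconstrained models for the diagnostic
            init=base.init,
            n_starts=base.n_starts,
            seed=base.seed,
        )
        try:
            fit = parafac_als(cube, opts)
            cc.append(corcondia(cube, fit))
            fits.append(fit.fit_percent)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError) as exc:
            errors[n] = str(exc)
            cc.append(np.nan)
            fits.append(np.nan)
    qualifying = [n for n, c in zip(candidates, cc) if np.isfinite(c) and c >= threshold]
    chosen = max(qualifying) if qualifying else None
    return RankScan(
        candidate_n=tuple(candidates),
        corcondia_percent=tuple(cc),
        fit_percent=tuple(fits),
        chosen_n=chosen,
        threshold=threshold,
        errors=errors,
    )
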