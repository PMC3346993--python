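"""Trilinear decomposition engines: PARAFAC-ALS and SWATLD.

Both fit the trilinear model

    x_ijk = sum_n a_in * b_jn * c_kn + e_ijk

where the columns of A are chromatographic (elution) profiles, the
columns of B are spectra, and the columns of C are per-sample relative
concentrations. Under mild conditions the decomposition is unique up to
permutation, sign and scale of the components, which is what makes the
resolved C usable for calibration. The scale indeterminacy is fixed by
normalizing the columns of A and B to unit Euclidean norm and carrying
all magnitude in C; the permutation/sign indeterminacy is resolved
after the fit by :func:`align_factors` against reference spectra.

PARAFAC-ALS minimizes the residual sum of squares by alternating exact
least-squares updates of A, B and C (optionally nonnegativity-
constrained per mode); its objective is non-increasing by construction.
SWATLD alternates self-weighted updates built from diagonal extractions
of projected slabs; it is not monotone in the least-squares objective
but converges fast and is notably insensitive to overestimating the
number of components.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from tricalib.datacube import DataCube

__all__ = [
    "FitOptions",
    "LoadingSet",
    "init_loadings",
    "parafac_als",
    "swatld",
    "align_factors",
    "reconstruct",
    "normalize_loadings",
]

_NORM_GUARD = 1e-12


@dataclass(frozen=True)
class FitOptions:
    """Settings shared by both decomposition engines.

    ``tol`` is the threshold on the relative change of the residual
    sum of squares between successive sweeps (default 1e-6, the
    conventional ALS stopping rule); a residual below 1e-20 of the
    total sum of squares (an exact fit to machine precision) also
    stops the sweeps. ``nonnegative`` lists the modes ("A", "B", "C")
    constrained to nonnegative entries. All three are constrained by
    default: negative absorbances, elution intensities and
    concentrations are physically meaningless, and allowing C to go
    negative additionally opens the door to two-factor degeneracies
    (pairs of nearly collinear components with huge opposite-signed
    scores) that alternating least squares can wander into from a
    deterministic start. ``n_starts`` > 1 adds random restarts (seeded
    from ``seed``) and keeps the best fit.
    """

    n_components: int
    tol: float = 1e-6
    max_iter: int = 2000
    nonnegative: tuple[str, ...] = ("A", "B", "C")
    init: str = "svd"
    n_starts: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "nonnegative", tuple(self.nonnegative))
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.init not in ("svd", "random"):
            raise ValueError("init must be 'svd' or 'random'")
        bad = set(self.nonnegative) - {"A", "B", "C"}
        if bad:
            raise ValueError(f"unknown modes in nonnegative: {sorted(bad)}")


@dataclass(frozen=True)
class LoadingSet:
    """Fitted loading matrices with diagnostics.

    A (I x N) and B (J x N) have unit-norm columns; C (K x N) carries
    the scale. ``fit_percent`` is 100 * (1 - ||residual||^2/||data||^2).
    ``component_names`` and ``analyte_correlations`` are filled by
    :func:`align_factors`.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    n_components: int
    iterations: int
    fit_percent: float
    converged: bool
    algorithm: str
    fit_trace: tuple[float, ...] = ()
    sample_ids: tuple[str, ...] = ()
    component_names: tuple[str, ...] = ()
    analyte_correlations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.fit_percent > 100 + 1e-9:
            raise ValueError("fit_percent cannot exceed 100")
        for M, name in ((self.A, "A"), (self.B, "B"), (self.C, "C")):
            if M.ndim != 2 or M.shape[1] != self.n_components:
                raise ValueError(f"{name} must have {self.n_components} columns")

    def scores(self) -> pd.DataFrame:
        """C as a DataFrame indexed by sample id (requires sample_ids)."""
        cols = self.component_names or [f"component_{n+1}" for n in range(self.n_components)]
        index = list(self.sample_ids) if self.sample_ids else range(self.C.shape[0])
        return pd.DataFrame(self.C, index=index, columns=list(cols))


# ---------------------------------------------------------------------------
# small tensor utilities


def _khatri_rao(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker product; rows ordered (u-row, v-row)."""
    n = U.shape[1]
    return np.einsum("un,vn->uvn", U, V).reshape(-1, n)


def _unfold(X: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n unfolding matching the _khatri_rao row ordering."""
    if mode == 0:
        return X.reshape(X.shape[0], -1)  # rows i, cols (j,k)
    if mode == 1:
        return np.transpose(X, (1, 0, 2)).reshape(X.shape[1], -1)  # cols (i,k)
    return np.transpose(X, (2, 0, 1)).reshape(X.shape[2], -1)  # cols (i,j)


def _fit_percent(X: np.ndarray, A: np.ndarray, B: np.ndarray, C: np.ndarray,
                 sst: float) -> float:
    model = np.einsum("in,jn,kn->ijk", A, B, C)
    ssr = float(np.sum((X - model) ** 2))
    return 100.0 * (1.0 - ssr / sst)


def normalize_loadings(
    A: np.ndarray, B: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit-norm columns in A and B, all scale and sign pushed into C.

    Additionally flips signs so the largest-magnitude entry of each A
    and B column is positive; the reconstruction is invariant.
    """
    A, B, C = A.copy(), B.copy(), C.copy()
    for M in (A, B):
        norms = np.linalg.norm(M, axis=0)
        if np.any(norms < _NORM_GUARD):
            raise FloatingPointError("degenerate loading column (norm ~ 0)")
        signs = np.sign(M[np.argmax(np.abs(M), axis=0), np.arange(M.shape[1])])
        signs[signs == 0] = 1.0
        M /= norms * signs
        C *= (norms * signs)[None, :]
    return A, B, C


def reconstruct(
    loadings: LoadingSet, cube_shape: tuple[int, int, int] | None = None
) -> np.ndarray:
    """Model array sum_n a_n (outer) b_n (outer) c_n."""
    shape = (loadings.A.shape[0], loadings.B.shape[0], loadings.C.shape[0])
    if cube_shape is not None and tuple(cube_shape) != shape:
        raise ValueError(f"requested shape {tuple(cube_shape)} != loadings shape {shape}")
    return np.einsum("in,jn,kn->ijk", loadings.A, loadings.B, loadings.C)


# ---------------------------------------------------------------------------
# initialization


def _check_n(shape: tuple[int, int, int], n: int) -> None:
    if n > min(shape):
        raise ValueError(f"n_components={n} exceeds the smallest cube dimension {min(shape)}")


def _svd_init(
    X: np.ndarray, n: int, nonneg: Sequence[str] = ()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    A = np.linalg.svd(_unfold(X, 0), full_matrices=False)[0][:, :n]
    B = np.linalg.svd(_unfold(X, 1), full_matrices=False)[0][:, :n]
    # magnitudes of the singular vectors seed nonnegative fits; signed
    # vectors would let a whole column be zeroed on the first NNLS sweep
    if "A" in nonneg:
        A = np.abs(A)
    if "B" in nonneg:
        B = np.abs(B)
    C = _ls_update(_unfold(X, 2), A, B)
    if "C" in nonneg:
        C = np.abs(C)
    return A, B, C


def _random_init(
    shape: tuple[int, int, int], n: int, rng: np.random.Generator,
    nonneg: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mats = []
    for dim, mode in zip(shape, ("A", "B", "C")):
        M = rng.standard_normal((dim, n))
        if mode in nonneg:
            M = np.abs(M)
        mats.append(M)
    return tuple(mats)


def init_loadings(cube: DataCube, options: FitOptions) -> LoadingSet:
    """Starting loadings: truncated SVDs of the unfoldings, or random.

    Deterministic for ``init='svd'``; fully seed-determined for
    ``init='random'``. Columns are normalized per the package
    convention (unit-norm A and B).
    """
    X = cube.values
    _check_n(X.shape, options.n_components)
    if options.init == "svd":
        A, B, C = _svd_init(X, options.n_components, options.nonnegative)
    else:
        rng = np.random.default_rng(options.seed)
        A, B, C = _random_init(X.shape, options.n_components, rng, options.nonnegative)
    A, B, C = normalize_loadings(A, B, C)
    sst = float(np.sum(X**2))
    return LoadingSet(
        A=A, B=B, C=C,
        n_components=options.n_components,
        iterations=1,
        fit_percent=_fit_percent(X, A, B, C, sst),
        converged=False,
        algorithm="init",
        sample_ids=cube.sample_ids,
    )


# ---------------------------------------------------------------------------
# PARAFAC-ALS


def _ls_update(Xmode: np.ndarray, U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Unconstrained LS update: argmin_F ||Xmode - F * kr(U,V)^T||."""
    G = (U.T @ U) * (V.T @ V)
    W = Xmode @ _khatri_rao(U, V)
    return np.linalg.lstsq(G.T, W.T, rcond=None)[0].T


def _nnls_update(Xmode: np.ndarray, U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Row-wise nonnegative LS update via the Gram-reduced problem."""
    n = U.shape[1]
    G = (U.T @ U) * (V.T @ V)
    W = Xmode @ _khatri_rao(U, V)
    # ||Z f - x||^2 = ||R f - R^-T w||^2 + const, with G = R^T R
    jitter = _NORM_GUARD * max(np.trace(G) / n, 1.0)
    R = np.linalg.cholesky(G + jitter * np.eye(n)).T
    RinvT_W = np.linalg.solve(R.T, W.T)  # n x rows
    F = np.empty_like(W)
    for r in range(W.shape[0]):
        F[r], _ = nnls(R, RinvT_W[:, r])
    return F


def _als_sweeps(
    X: np.ndarray,
    A: np.ndarray, B: np.ndarray, C: np.ndarray,
    options: FitOptions,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], bool]:
    sst = float(np.sum(X**2))
    X0, X1, X2 = _unfold(X, 0), _unfold(X, 1), _unfold(X, 2)
    upd = {
        mode: (_nnls_update if mode in options.nonnegative else _ls_update)
        for mode in ("A", "B", "C")
    }
    trace: list[float] = []
    converged = False
    reinit_done = False
    for _ in range(options.max_iter):
        A = upd["A"](X0, B, C)
        B = upd["B"](X1, A, C)
        C = upd["C"](X2, A, B)
        try:
            A, B, C = normalize_loadings(A, B, C)
        except FloatingPointError:
            if reinit_done:
                raise FloatingPointError(
                    "degenerate solution: a loading column collapsed twice"
                )
            reinit_done = True
            A, B, C = _random_init(X.shape, options.n_components, rng,
                                   options.nonnegative)
            A, B, C = normalize_loadings(A, B, C)
            trace.append(_fit_percent(X, A, B, C, sst))
            continue
        fit = _fit_percent(X, A, B, C, sst)
        if not np.isfinite(fit):
            raise FloatingPointError("non-finite fit encountered (degenerate solution)")
        trace.append(fit)
        if _stopped(trace, options.tol):
            converged = True
            break
    return A, B, C, trace, converged


def _stopped(trace: list[float], tol: float) -> bool:
    """Relative-SSR stopping rule on the stored fit-percent trace."""
    ssr = 1.0 - trace[-1] / 100.0  # residual as a fraction of total SS
    if ssr <= 1e-20:
        return True
    if len(trace) < 2:
        return False
    ssr_prev = 1.0 - trace[-2] / 100.0
    return abs(ssr_prev - ssr) <= tol * max(ssr_prev, 1e-300)


def parafac_als(cube: DataCube, options: FitOptions) -> LoadingSet:
    """Fit the trilinear model by alternating least squares.

    Sweeps exact LS (or nonnegative LS, per ``options.nonnegative``)
    updates over A, B, C until the relative change of the fit
    percentage drops below ``options.tol`` or ``max_iter`` is reached.
    With ``n_starts`` > 1 the best of several seeded starts (by fit) is
    returned.
    """
    return _multistart(cube, options, _als_sweeps, "parafac_als")


# ---------------------------------------------------------------------------
# SWATLD


def _swatld_sweeps(
    X: np.ndarray,
    A: np.ndarray, B: np.ndarray, C: np.ndarray,
    options: FitOptions,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], bool]:
    sst = float(np.sum(X**2))
    trace: list[float] = []
    converged = False
    reinit_done = False

    def _wdiag(M: np.ndarray) -> np.ndarray:
        d = np.sum(M * M, axis=0)
        return np.maximum(d, _NORM_GUARD * max(d.max(), 1.0))

    for _ in range(options.max_iter):
        Ap, Bp, Cp = (np.linalg.pinv(M) for M in (A, B, C))
        dA, dB, dC = _wdiag(A), _wdiag(B), _wdiag(C)
        # each row of a factor is the average of two diagonal extractions
        # of the data projected onto the other two modes, self-weighted by
        # the column norms of those modes
        A = 0.5 * (
            np.einsum("nj,ijk,kn->in", Bp, X, C) / dC
            + np.einsum("nk,ijk,jn->in", Cp, X, B) / dB
        )
        Ap = np.linalg.pinv(A)
        dA = _wdiag(A)
        B = 0.5 * (
            np.einsum("ni,ijk,kn->jn", Ap, X, C) / dC
            + np.einsum("nk,ijk,in->jn", Cp, X, A) / dA
        )
        Bp = np.linalg.pinv(B)
        dB = _wdiag(B)
        C = 0.5 * (
            np.einsum("ni,ijk,jn->kn", Ap, X, B) / dB
            + np.einsum("nj,ijk,in->kn", Bp, X, A) / dA
        )
        try:
            A, B, C = normalize_loadings(A, B, C)
        except FloatingPointError:
            if reinit_done:
                raise FloatingPointError(
                    "degenerate solution: a loading column collapsed twice"
                )
            reinit_done = True
            A, B, C = _random_init(X.shape, options.n_components, rng,
                                   options.nonnegative)
            A, B, C = normalize_loadings(A, B, C)
            trace.append(_fit_percent(X, A, B, C, sst))
            continue
        fit = _fit_percent(X, A, B, C, sst)
        if not np.isfinite(fit):
            raise FloatingPointError("non-finite fit encountered (degenerate solution)")
        trace.append(fit)
        if _stopped(trace, options.tol):
            converged = True
            break
    if options.nonnegative:
        # The self-weighted sweeps run unconstrained (hard projection
        # inside them corrupts the fixed point); nonnegativity is
        # applied as a terminal projection. Excursions below zero are
        # tiny on trilinear data, so the fit change is marginal.
        if "A" in options.nonnegative:
            A = np.maximum(A, 0.0)
        if "B" in options.nonnegative:
            B = np.maximum(B, 0.0)
        if "C" in options.nonnegative:
            C = np.maximum(C, 0.0)
        A, B, C = normalize_loadings(A, B, C)
        trace.append(_fit_percent(X, A, B, C, sst))
    return A, B, C, trace, converged


def swatld(cube: DataCube, options: FitOptions) -> LoadingSet:
    """Fit the trilinear model by self-weighted alternating updates.

    Same contract and normalization as :func:`parafac_als`; typically
    converges in far fewer sweeps and degrades gracefully when
    ``n_components`` exceeds the true chemical rank (the surplus
    columns absorb noise without distorting the true ones). Requested
    nonnegativity is enforced by a terminal projection of the affected
    modes rather than inside the sweeps.
    """
    return _multistart(cube, options, _swatld_sweeps, "swatld")


def _multistart(cube: DataCube, options: FitOptions, sweeps, name: str) -> LoadingSet:
    X = cube.values
    _check_n(X.shape, options.n_components)
    best: LoadingSet | None = None
    for s in range(options.n_starts):
        rng = np.random.default_rng(int(options.seed) + s)
        if s == 0 and options.init == "svd":
            A0, B0, C0 = _svd_init(X, options.n_components, options.nonnegative)
        else:
            A0, B0, C0 = _random_init(X.shape, options.n_components, rng,
                                      options.nonnegative)
        A0, B0, C0 = normalize_loadings(A0, B0, C0)
        A, B, C, trace, converged = sweeps(X, A0, B0, C0, options, rng)
        result = LoadingSet(
            A=A, B=B, C=C,
            n_components=options.n_components,
            iterations=max(len(trace), 1),
            fit_percent=trace[-1] if trace else -np.inf,
            converged=converged,
            algorithm=name,
            fit_trace=tuple(trace),
            sample_ids=cube.sample_ids,
        )
        if best is None or result.fit_percent > best.fit_percent:
            best = result
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# factor alignment


def align_factors(
    result: LoadingSet,
    reference_spectra: pd.DataFrame | np.ndarray,
    reference_names: Sequence[str] | None = None,
    wavelength_axis: np.ndarray | None = None,
) -> LoadingSet:
    """Resolve the permutation/sign indeterminacy against known spectra.

    Matches B columns to the reference spectra greedily on the absolute
    Pearson correlation (ties broken by reference then column order),
    flips matched columns so the correlation is positive (compensating
    in C), places matched components first in reference order, and
    orders the leftover (interferent) factors by decreasing C-column
    norm. Per-analyte correlations are recorded on the returned set.
    """
    if isinstance(reference_spectra, pd.DataFrame):
        names = [str(c) for c in reference_spectra.columns]
        refs = reference_spectra.to_numpy(dtype=float)
        if wavelength_axis is not None and not np.allclose(
            np.asarray(reference_spectra.index, dtype=float), wavelength_axis
        ):
            raise ValueError("reference spectra wavelength grid does not match")
    else:
        refs = np.asarray(reference_spectra, dtype=float)
        names = list(reference_names or [f"analyte_{m+1}" for m in range(refs.shape[1])])
    if refs.shape[0] != result.B.shape[0]:
        raise ValueError(
            f"reference spectra have {refs.shape[0]} wavelengths, "
            f"loadings have {result.B.shape[0]}"
        )
    n_ref = refs.shape[1]
    if n_ref > result.n_components:
        raise ValueError("more reference spectra than fitted components")

    B = result.B
    corr = np.empty((n_ref, result.n_components))
    for m in range(n_ref):
        for n in range(result.n_components):
            corr[m, n] = _pearson(refs[:, m], B[:, n])

    assigned: dict[int, int] = {}
    free_refs = set(range(n_ref))
    free_cols = set(range(result.n_components))
    while free_refs:
        best_val, best_pair = -np.inf, None
        for m in sorted(free_refs):
            for n in sorted(free_cols):
                if abs(corr[m, n]) > best_val + 1e-15:
                    best_val, best_pair = abs(corr[m, n]), (m, n)
        m, n = best_pair
        assigned[m] = n
        free_refs.discard(m)
        free_cols.discard(n)

    leftover = sorted(
        free_cols, key=lambda n: -float(np.linalg.norm(result.C[:, n]))
    )
    order = [assigned[m] for m in range(n_ref)] + leftover
    A = result.A[:, order].copy()
    B = result.B[:, order].copy()
    C = result.C[:, order].copy()
    correlations = {}
    for m in range(n_ref):
        r = corr[m, assigned[m]]
        if r < 0:  # sign flip of b_n and c_n leaves a*b*c unchanged
            B[:, m] *= -1.0
            C[:, m] *= -1.0
            r = -r
        correlations[names[m]] = float(r)
    comp_names = tuple(names) + tuple(
        f"interferent_{i+1}" for i in range(result.n_components - n_ref)
    )
    return replace(
        result,
        A=A, B=B, C=C,
        component_names=comp_names,
        analyte_correlations=correlations,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)
    if denom < _NORM_GUARD:
        return 0.0
    return float(xc @ yc / denom)
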