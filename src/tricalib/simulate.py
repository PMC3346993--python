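"""Synthetic HPLC-DAD cube generator.

Emulates the measurement structure the second-order calibration
pipeline assumes: each detectable species contributes a fixed unimodal
elution profile and a fixed smooth broadband UV spectrum, scaled per
sample by its concentration (the trilinear model), plus iid additive
Gaussian noise and an optional constant baseline. Calibration standards
contain analytes only; prediction samples additionally contain
uncalibrated interferents (the "plasma" matrix), which is exactly the
regime in which the second-order advantage is exercised.

Deliberately NOT modelled: retention-time shifts between runs (the
trilinear model assumes none), peak-shape changes with concentration,
detector saturation, and heteroscedastic noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tricalib.datacube import CalibrationDesign, DataCube

__all__ = [
    "ComponentSpec",
    "SimulationConfig",
    "GroundTruth",
    "make_profile",
    "simulate_cube",
    "paperlike_dataset",
]


@dataclass(frozen=True)
class ComponentSpec:
    """Ground-truth profiles of one absorbing species.

    The elution profile is a Gaussian peak (center/width in minutes);
    ``tailing`` > 0 adds exponential tailing (exponentially modified
    Gaussian, time constant in minutes) to mimic peak broadening — off
    by default. The spectrum is a sum of Gaussian bands
    ``(center nm, sigma nm, height)``.
    """

    name: str
    elution_center: float
    elution_width: float
    spectrum_params: tuple[tuple[float, float, float], ...]
    role: str = "analyte"
    tailing: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "spectrum_params",
            tuple((float(c), float(w), float(h)) for c, w, h in self.spectrum_params),
        )
        if self.elution_width <= 0:
            raise ValueError(f"{self.name}: elution_width must be > 0")
        if not self.spectrum_params:
            raise ValueError(f"{self.name}: at least one spectral band required")
        for c, w, h in self.spectrum_params:
            if w <= 0:
                raise ValueError(f"{self.name}: band width must be > 0")
            if h < 0:
                raise ValueError(f"{self.name}: band height must be >= 0")
        if self.role not in ("analyte", "interferent"):
            raise ValueError(f"{self.name}: role must be analyte or interferent")
        if self.tailing < 0:
            raise ValueError(f"{self.name}: tailing must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a simulated calibration study.

    ``noise_sd`` is the additive Gaussian noise standard deviation as a
    fraction of the maximum noiseless signal. Interferent levels are
    drawn uniformly from ``interferent_level_range`` in prediction
    samples and are exactly zero in calibration samples and blanks.
    ``prediction_conc`` optionally pins the analyte concentrations of
    the prediction samples (otherwise drawn uniformly from
    ``concentration_ranges``). The seed fully determines the output.
    """

    components: tuple[ComponentSpec, ...]
    n_calibration: int = 10
    n_prediction: int = 6
    n_blank: int = 3
    concentration_ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    interferent_level_range: tuple[float, float] = (5.0, 15.0)
    noise_sd: float = 0.005
    baseline_offset: float = 0.0
    prediction_conc: Mapping[str, Sequence[float]] | None = None
    time_axis: tuple[float, float, int] = (0.0, 5.0, 151)
    wavelength_axis: tuple[float, float, int] = (200.0, 380.0, 91)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if not self.analytes:
            raise ValueError("at least one analyte component is required")
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("component names must be unique")
        if self.n_calibration < 2:
            raise ValueError("need at least two calibration samples")
        if self.n_prediction < 0 or self.n_blank < 0:
            raise ValueError("sample counts must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for a in self.analytes:
            if a.name not in self.concentration_ranges:
                raise ValueError(f"no concentration range for analyte {a.name!r}")
            lo, hi = self.concentration_ranges[a.name]
            if not (0 <= lo < hi):
                raise ValueError(f"bad concentration range for {a.name!r}: ({lo}, {hi})")
        if self.prediction_conc is not None:
            for a in self.analytes:
                vals = self.prediction_conc.get(a.name)
                if vals is None or len(vals) != self.n_prediction:
                    raise ValueError(
                        f"prediction_conc for {a.name!r} must list "
                        f"{self.n_prediction} values"
                    )

    @property
    def analytes(self) -> tuple[ComponentSpec, ...]:
        return tuple(c for c in self.components if c.role == "analyte")

    @property
    def interferents(self) -> tuple[ComponentSpec, ...]:
        return tuple(c for c in self.components if c.role == "interferent")


@dataclass(frozen=True)
class GroundTruth:
    """Exact factors behind a simulated cube.

    A (I x N, unit maximum per column), B (J x N, unit Euclidean norm
    per column), C (K x N, concentration units) and the noiseless cube
    values, sufficient to verify profile recovery, concentration
    recovery and the chemical rank downstream.
    """

    A: np.ndarray
    B: np.ndarray
    C: pd.DataFrame
    component_names: tuple[str, ...]
    noiseless: np.ndarray
    baseline_offset: float
    config: SimulationConfig


def make_profile(
    spec: ComponentSpec,
    time_axis: np.ndarray,
    wavelength_axis: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth elution and spectrum vectors of one species.

    The elution vector is a (optionally exponentially tailed) Gaussian
    scaled to unit maximum; the spectrum is the sum of the Gaussian
    bands scaled to unit Euclidean norm. Both are nonnegative.
    """
    t = np.asarray(time_axis, dtype=float)
    w = np.asarray(wavelength_axis, dtype=float)
    elution = np.exp(-0.5 * ((t - spec.elution_center) / spec.elution_width) ** 2)
    if spec.tailing > 0:
        # discrete convolution with a normalized exponential decay
        dt = np.diff(t).mean() if t.size > 1 else 1.0
        n_tail = max(int(np.ceil(5 * spec.tailing / dt)), 1)
        kernel = np.exp(-np.arange(n_tail + 1) * dt / spec.tailing)
        kernel /= kernel.sum()
        elution = np.convolve(elution, kernel)[: t.size]
    peak = elution.max()
    if peak <= 0:
        raise ValueError(f"{spec.name}: elution profile vanishes on this grid")
    elution = elution / peak

    spectrum = np.zeros_like(w)
    for center, sigma, height in spec.spectrum_params:
        spectrum += height * np.exp(-0.5 * ((w - center) / sigma) ** 2)
    norm = np.linalg.norm(spectrum)
    if norm <= 0:
        raise ValueError(f"{spec.name}: spectrum vanishes on this grid")
    return elution, spectrum / norm


def _calibration_levels(config: SimulationConfig) -> np.ndarray:
    """Deterministic calibration design spanning each analyte's range.

    Each analyte gets evenly spaced levels across its range; the level
    orders are cyclically staggered between analytes so the
    concentration vectors are linearly independent (a mixture design,
    not replicated single-analyte standards).
    """
    analytes = config.analytes
    n = config.n_calibration
    shift_step = max(1, n // (len(analytes) + 1))
    cols = []
    for idx, a in enumerate(analytes):
        lo, hi = config.concentration_ranges[a.name]
        levels = np.linspace(lo, hi, n)
        cols.append(np.roll(levels, idx * shift_step))
    return np.column_stack(cols)


def simulate_cube(
    config: SimulationConfig,
) -> tuple[DataCube, CalibrationDesign, GroundTruth]:
    """Generate a cube, its design, and the exact factors behind it.

    Each sample slab is ``sum_n c_kn * (elution_n outer spectrum_n)``
    plus the constant baseline and iid Gaussian noise with standard
    deviation ``noise_sd`` times the global maximum of the noiseless
    signal. Blanks contain baseline and noise only.
    """
    rng = np.random.default_rng(config.seed)
    t0, t1, nt = config.time_axis
    w0, w1, nw = config.wavelength_axis
    t = np.linspace(t0, t1, int(nt))
    w = np.linspace(w0, w1, int(nw))

    names = tuple(c.name for c in config.components)
    profiles = [make_profile(c, t, w) for c in config.components]
    A = np.column_stack([p[0] for p in profiles])
    B = np.column_stack([p[1] for p in profiles])

    n_cal, n_pred, n_blank = config.n_calibration, config.n_prediction, config.n_blank
    K = n_cal + n_pred + n_blank
    ids = (
        [f"cal{i+1:02d}" for i in range(n_cal)]
        + [f"pred{i+1:02d}" for i in range(n_pred)]
        + [f"blank{i+1:02d}" for i in range(n_blank)]
    )
    roles = ["calibration"] * n_cal + ["prediction"] * n_pred + ["blank"] * n_blank

    C = np.zeros((K, len(names)))
    analyte_names = [a.name for a in config.analytes]
    cal_levels = _calibration_levels(config)
    for j, a in enumerate(config.analytes):
        col = names.index(a.name)
        C[:n_cal, col] = cal_levels[:, j]
        if config.prediction_conc is not None:
            C[n_cal : n_cal + n_pred, col] = np.asarray(
                config.prediction_conc[a.name], dtype=float
            )
        else:
            lo, hi = config.concentration_ranges[a.name]
            C[n_cal : n_cal + n_pred, col] = rng.uniform(lo, hi, size=n_pred)
    lo_i, hi_i = config.interferent_level_range
    for intf in config.interferents:
        col = names.index(intf.name)
        C[n_cal : n_cal + n_pred, col] = rng.uniform(lo_i, hi_i, size=n_pred)

    noiseless = np.einsum("in,jn,kn->ijk", A, B, C)
    scale = np.abs(noiseless).max()
    sd = config.noise_sd * (scale if scale > 0 else 1.0)
    values = noiseless + config.baseline_offset
    if sd > 0:
        values = values + rng.normal(0.0, sd, size=noiseless.shape)

    cube = DataCube(values=values, time_axis=t, wavelength_axis=w, sample_ids=tuple(ids))
    C_frame = pd.DataFrame(C, index=ids, columns=list(names))
    known = C_frame.loc[:, analyte_names].copy()
    known.loc[[i for i, r in zip(ids, roles) if r == "blank"], :] = np.nan
    design = CalibrationDesign(
        analyte_names=tuple(analyte_names),
        known_conc=known,
        roles=pd.Series(roles, index=ids),
    )
    truth = GroundTruth(
        A=A,
        B=B,
        C=C_frame,
        component_names=names,
        noiseless=noiseless,
        baseline_offset=config.baseline_offset,
        config=config,
    )
    return cube, design, truth


# ---------------------------------------------------------------------------
# The study-like dataset

# Added analyte concentrations of the six prediction samples (mg/mL),
# matching the spiked levels of the emulated determination study.
PREDICTION_ADDED = {
    "vancomycin": (15.15, 20.20, 30.30, 20.20, 25.25, 20.20),
    "cephalexin": (15.27, 20.36, 10.18, 30.54, 25.45, 15.27),
}

# Strongly overlapped elution (analyte centers ~1 sigma apart, plasma
# interferents in between / on the shoulder) and broadband UV spectra;
# cephalexin's spectrum is the most distinct in shape, mirroring the
# selectivity ordering seen in real determinations of this drug pair.
_VANCOMYCIN = ComponentSpec(
    name="vancomycin",
    elution_center=2.00,
    elution_width=0.25,
    spectrum_params=((230.0, 25.0, 1.0), (285.0, 35.0, 0.5)),
    role="analyte",
)
_CEPHALEXIN = ComponentSpec(
    name="cephalexin",
    elution_center=2.30,
    elution_width=0.25,
    spectrum_params=((262.0, 14.0, 1.0), (222.0, 12.0, 0.6)),
    role="analyte",
)
_PLASMA_1 = ComponentSpec(
    name="plasma_1",
    elution_center=2.15,
    elution_width=0.35,
    spectrum_params=((215.0, 18.0, 1.0), (320.0, 40.0, 0.7)),
    role="interferent",
)
_PLASMA_2 = ComponentSpec(
    name="plasma_2",
    elution_center=2.60,
    elution_width=0.30,
    spectrum_params=((300.0, 30.0, 1.0), (230.0, 20.0, 0.4)),
    role="interferent",
)


def paperlike_dataset(
    seed: int = 0,
    n_interferents: int = 1,
    noise_sd: float = 0.005,
    baseline_offset: float = 0.0,
) -> tuple[DataCube, CalibrationDesign, GroundTruth]:
    """The emulated two-analyte plasma determination study.

    Ten calibration standards (vancomycin and cephalexin only, levels
    staggered across 5-40 mg/mL), six prediction samples spiked at the
    study's added levels and additionally containing 1-2 uncalibrated
    plasma interferents, and three blanks. 0.5% additive noise by
    default.
    """
    if not 1 <= n_interferents <= 2:
        raise ValueError("n_interferents must be 1 or 2")
    comps = [_VANCOMYCIN, _CEPHALEXIN, _PLASMA_1, _PLASMA_2][: 2 + n_interferents]
    config = SimulationConfig(
        components=tuple(comps),
        n_calibration=10,
        n_prediction=6,
        n_blank=3,
        concentration_ranges={
            "vancomycin": (5.0, 40.0),
            "cephalexin": (5.0, 40.0),
        },
        interferent_level_range=(8.0, 20.0),
        noise_sd=noise_sd,
        baseline_offset=baseline_offset,
        prediction_conc=PREDICTION_ADDED,
        seed=int(seed),
    )
    return simulate_cube(config)
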