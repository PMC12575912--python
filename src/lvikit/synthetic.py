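"""Synthetic inputs for the PET-IVIM-DKI biomarker pipeline.

Everything the downstream fitters and statistics consume can be produced
here: b-value acquisition schemes, noise-free diffusion signal curves from
the IVIM bi-exponential and DKI kurtosis forward models, Rician magnitude
noise, synthetic PET lesion volumes, and quantile-calibrated two-group
cohorts with two-reader replicate measurements.

The forward models are

    IVIM:  S_b / S_0 = (1 - f) * exp(-b * D) + f * exp(-b * (D* + D))
    DKI:   ln(S_b / S_0) = -b * Dapp + b^2 * Dapp^2 * Kapp / 6

with b in s/mm^2, D, D*, Dapp in mm^2/s, and f a fraction in [0, 1].

Cohort biomarkers are drawn from distributions calibrated to summary
statistics of the form median (Q1, Q3) -- or mean +/- sd for mean kurtosis
-- so that a generated cohort reproduces, in the large-sample limit, the
group-level summaries it was configured with.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BValueScheme",
    "IVIMParams",
    "DKIParams",
    "SignalCurve",
    "PETVolume",
    "SplicedLogNormal",
    "TruncatedNormalSpec",
    "CohortConfig",
    "BIOMARKERS",
    "COHORT_COLUMNS",
    "DEFAULT_CALIBRATION",
    "make_bvalue_scheme",
    "ivim_signal",
    "dki_signal",
    "dki_validity_bound",
    "add_rician_noise",
    "calibrate_quantile_distribution",
    "default_cohort_config",
    "generate_cohort",
    "generate_lesion_volume",
]


# --------------------------------------------------------------------------
# Acquisition schemes
# --------------------------------------------------------------------------

NAMED_SCHEMES: dict[str, tuple[float, ...]] = {
    "ivim": (0, 25, 50, 100, 150, 200, 400, 600, 800, 1000),
    "dki": (0, 500, 1000, 2000),
    "dwi": (0, 800),
}


@dataclass(frozen=True)
class BValueScheme:
    """An ordered diffusion-weighting scheme in s/mm^2.

    Must contain b = 0 (the unweighted reference), be strictly increasing
    and non-negative, and have at least two points.
    """

    name: str
    bvalues: tuple[float, ...]

    def __post_init__(self) -> None:
        b = np.asarray(self.bvalues, dtype=float)
        if b.size < 2:
            raise ValueError("a b-value scheme needs at least 2 b-values")
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        if np.any(np.diff(b) <= 0):
            raise ValueError("b-values must be strictly increasing")
        if b[0] != 0:
            raise ValueError("scheme must contain b = 0")
        object.__setattr__(self, "bvalues", tuple(float(x) for x in b))

    def __len__(self) -> int:
        return len(self.bvalues)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.bvalues, dtype=float)


def make_bvalue_scheme(name: str | Sequence[float]) -> BValueScheme:
    """Return a named acquisition scheme or wrap a custom b-value list.

    Named schemes: ``"ivim"`` (10 b-values, 0-1000 s/mm^2), ``"dki"``
    (0, 500, 1000, 2000 s/mm^2), ``"dwi"`` (0, 800 s/mm^2).
    """
    if isinstance(name, str):
        key = name.lower()
        if key not in NAMED_SCHEMES:
            raise ValueError(
                f"unknown scheme {name!r}; valid names: {sorted(NAMED_SCHEMES)}"
            )
        return BValueScheme(key, NAMED_SCHEMES[key])
    return BValueScheme("custom", tuple(float(b) for b in name))


# --------------------------------------------------------------------------
# Model parameter sets and signal curves
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class IVIMParams:
    """Bi-exponential IVIM parameters.

    d : true diffusion coefficient, mm^2/s (> 0)
    dstar : pseudo-diffusion coefficient, mm^2/s (>= d)
    f : perfusion fraction in [0, 1]
    """

    d: float
    dstar: float
    f: float

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError(f"D must be positive, got {self.d}")
        if self.dstar < self.d:
            raise ValueError(
                f"D* ({self.dstar}) must be >= D ({self.d}): pseudo-diffusion "
                "is faster than true diffusion"
            )
        if not 0 <= self.f <= 1:
            raise ValueError(f"f must be in [0, 1], got {self.f}")


@dataclass(frozen=True)
class DKIParams:
    """Diffusion-kurtosis parameters.

    dapp : kurtosis-corrected diffusion coefficient, mm^2/s (> 0)
    kapp : apparent kurtosis, dimensionless (>= 0); 0 recovers the
        mono-exponential (Gaussian) model
    """

    dapp: float
    kapp: float

    def __post_init__(self) -> None:
        if not self.dapp > 0:
            raise ValueError(f"Dapp must be positive, got {self.dapp}")
        if self.kapp < 0:
            raise ValueError(f"Kapp must be non-negative, got {self.kapp}")


@dataclass(frozen=True)
class SignalCurve:
    """Diffusion signal intensities over a b-value scheme (one voxel/ROI)."""

    scheme: BValueScheme
    signal: tuple[float, ...]
    s0: float

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.size != len(self.scheme):
            raise ValueError(
                f"signal length {sig.size} != scheme length {len(self.scheme)}"
            )
        if np.any(sig <= 0):
            raise ValueError("signal intensities must be positive")
        if not self.s0 > 0:
            raise ValueError("s0 must be positive")
        object.__setattr__(self, "signal", tuple(float(x) for x in sig))

    @property
    def bvalues(self) -> np.ndarray:
        return self.scheme.array

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.signal, dtype=float)


def ivim_signal(
    params: IVIMParams, scheme: BValueScheme, s0: float = 1.0
) -> SignalCurve:
    """Evaluate the bi-exponential IVIM forward model on a scheme.

    S_b = s0 * [(1 - f) * exp(-b D) + f * exp(-b (D* + D))].
    """
    if not s0 > 0:
        raise ValueError("s0 must be positive")
    b = scheme.array
    sig = s0 * (
        (1 - params.f) * np.exp(-b * params.d)
        + params.f * np.exp(-b * (params.dstar + params.d))
    )
    return SignalCurve(scheme, tuple(sig), s0)


def dki_validity_bound(params: DKIParams) -> float:
    """Largest b at which the quadratic kurtosis signal is non-increasing.

    The log-signal -b*Dapp + b^2*Dapp^2*Kapp/6 turns upward beyond
    b = 3 / (Dapp * Kapp); past that point the truncated cumulant expansion
    is no longer a physically meaningful decay.
    """
    if params.kapp == 0:
        return math.inf
    return 3.0 / (params.dapp * params.kapp)


def dki_signal(
    params: DKIParams,
    scheme: BValueScheme,
    s0: float = 1.0,
    validity: str = "warn",
) -> SignalCurve:
    """Evaluate the kurtosis forward model ln(S_b/s0) = -b Dapp + b^2 Dapp^2 Kapp / 6.

    ``validity`` controls what happens when the scheme exceeds the model
    validity bound 3/(Dapp*Kapp): "warn" (default) evaluates the quadratic
    anyway with a warning, "raise" rejects and reports the bound, "ignore"
    is silent.
    """
    if not s0 > 0:
        raise ValueError("s0 must be positive")
    if validity not in ("warn", "raise", "ignore"):
        raise ValueError(f"validity must be warn/raise/ignore, got {validity!r}")
    b = scheme.array
    bound = dki_validity_bound(params)
    if b.max() > bound:
        msg = (
            f"max b = {b.max():g} s/mm^2 exceeds the kurtosis-model validity "
            f"bound 3/(Dapp*Kapp) = {bound:g} s/mm^2"
        )
        if validity == "raise":
            raise ValueError(msg)
        if validity == "warn":
            warnings.warn(msg, stacklevel=2)
    sig = s0 * np.exp(-b * params.dapp + b**2 * params.dapp**2 * params.kapp / 6.0)
    return SignalCurve(scheme, tuple(sig), s0)


def add_rician_noise(
    curve: SignalCurve,
    snr: float,
    seed: int | np.random.Generator | None = None,
) -> SignalCurve:
    """Corrupt a signal curve with Rician magnitude noise.

    Each intensity s becomes sqrt((s + n1)^2 + n2^2) with n1, n2 independent
    zero-mean Gaussians of standard deviation s0/snr, the magnitude-image
    noise model of MR data. ``snr = inf`` returns the curve unchanged.
    Deterministic under a fixed integer seed.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    if math.isinf(snr):
        return curve
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sigma = curve.s0 / snr
    s = curve.array
    n1, n2 = rng.normal(0.0, sigma, (2, s.size))
    noisy = np.sqrt((s + n1) ** 2 + n2**2)
    # Rician magnitudes are almost surely positive; guard against exact 0.
    noisy = np.maximum(noisy, np.finfo(float).tiny)
    return SignalCurve(curve.scheme, tuple(noisy), curve.s0)


# --------------------------------------------------------------------------
# Quantile-calibrated marginal distributions
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SplicedLogNormal:
    """Positive-support distribution matched to (median, Q1, Q3).

    Built by splicing two log-normal half-distributions at the median: a
    standard-normal draw z maps to exp(log_median + sigma_lo * z) for z < 0
    and exp(log_median + sigma_hi * z) for z >= 0.  The configured median
    and both quartiles are then matched exactly, even when the quartiles are
    asymmetric about the median on the log scale (in the symmetric case the
    construction degenerates to an ordinary log-normal).

    ``implied_symmetric_median`` is the median a plain two-parameter
    log-normal matched to the same quartiles would have (sqrt(q1*q3));
    ``median_discrepancy`` is its signed gap from the configured median, a
    diagnostic of how asymmetric the configured summary is.
    """

    median: float
    q1: float
    q3: float
    log_median: float
    sigma_lo: float
    sigma_hi: float
    implied_symmetric_median: float
    median_discrepancy: float

    def from_z(self, z: np.ndarray) -> np.ndarray:
        """Map standard-normal draws to the calibrated scale (Gaussian copula hook)."""
        z = np.asarray(z, dtype=float)
        sigma = np.where(z < 0, self.sigma_lo, self.sigma_hi)
        return np.exp(self.log_median + sigma * z)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.from_z(rng.standard_normal(n))

    def quantile(self, p: np.ndarray | float) -> np.ndarray:
        return self.from_z(sps.norm.ppf(p))

    @property
    def log_sigma(self) -> float:
        """Representative log-scale spread (average of the two half-widths)."""
        return 0.5 * (self.sigma_lo + self.sigma_hi)


def calibrate_quantile_distribution(
    median: float,
    q1: float,
    q3: float,
    probs: tuple[float, float] = (0.25, 0.75),
) -> SplicedLogNormal:
    """Calibrate a positive-support distribution to median (Q1, Q3).

    ``probs`` gives the probability levels of the two flanking quantiles;
    the default (0.25, 0.75) treats them as quartiles.  Passing e.g.
    (1/(n+1), n/(n+1)) instead treats them as the expected extrema of a
    sample of size n, for summaries whose parenthetical ranges are min-max.
    """
    if not (0 < q1 < median < q3):
        raise ValueError(
            f"need 0 < q1 < median < q3, got q1={q1}, median={median}, q3={q3}"
        )
    z_lo, z_hi = sps.norm.ppf(probs[0]), sps.norm.ppf(probs[1])
    if not (z_lo < 0 < z_hi):
        raise ValueError(f"probs must straddle 0.5, got {probs}")
    log_m = math.log(median)
    sigma_lo = (log_m - math.log(q1)) / (-z_lo)
    sigma_hi = (math.log(q3) - log_m) / z_hi
    implied = math.sqrt(q1 * q3) if probs == (0.25, 0.75) else math.exp(
        (math.log(q1) * z_hi - math.log(q3) * z_lo) / (z_hi - z_lo)
    )
    return SplicedLogNormal(
        median=median,
        q1=q1,
        q3=q3,
        log_median=log_m,
        sigma_lo=sigma_lo,
        sigma_hi=sigma_hi,
        implied_symmetric_median=implied,
        median_discrepancy=implied - median,
    )


@dataclass(frozen=True)
class TruncatedNormalSpec:
    """Normal distribution truncated at 0, matched to a mean +/- sd summary.

    Used for biomarkers reported as mean +/- sd (mean kurtosis); for the
    values in question the truncation mass is negligible, so the configured
    mean and sd are reproduced essentially exactly.
    """

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (self.mean > 0 and self.sd > 0):
            raise ValueError("mean and sd must be positive")

    @property
    def _a(self) -> float:
        return (0.0 - self.mean) / self.sd

    def from_z(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        u = sps.norm.cdf(z)
        return sps.truncnorm.ppf(u, self._a, np.inf, loc=self.mean, scale=self.sd)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.from_z(rng.standard_normal(n))

    def quantile(self, p: np.ndarray | float) -> np.ndarray:
        return sps.truncnorm.ppf(p, self._a, np.inf, loc=self.mean, scale=self.sd)

    @property
    def log_sigma(self) -> float:
        # coefficient of variation stands in for the log-scale spread
        return self.sd / self.mean


MarkerSpec = SplicedLogNormal | TruncatedNormalSpec


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

#: biomarker column order of the cohort table (also the CSV dialect order)
BIOMARKERS: tuple[str, ...] = (
    "mk", "md", "suvmax", "mtv", "tlg", "adc", "d", "dstar", "f_pct",
)

COHORT_COLUMNS: tuple[str, ...] = ("subject_id", "lvi", "reader", *BIOMARKERS)

#: per-group summary calibration in table units: MK is mean +/- sd
#: (dimensionless); every other biomarker is median (Q1, Q3) --
#: MD/ADC/D/D* in 1e-3 mm^2/s, SUVmax in g/cm^3, MTV in cm^3, TLG in g,
#: f in percent.
DEFAULT_CALIBRATION: dict[str, dict[str, tuple[float, ...]]] = {
    "mk": {"pos": (0.84, 0.19), "neg": (0.70, 0.19)},
    "md": {"pos": (2.29, 1.06, 4.77), "neg": (2.69, 1.18, 4.58)},
    "suvmax": {"pos": (6.07, 0.48, 13.81), "neg": (4.19, 0.40, 13.77)},
    "mtv": {"pos": (14.75, 2.12, 75.89), "neg": (5.59, 0.62, 29.92)},
    "tlg": {"pos": (49.21, 0.69, 259.57), "neg": (13.71, 0.68, 193.55)},
    "adc": {"pos": (0.88, 0.25, 1.40), "neg": (1.27, 0.25, 4.80)},
    "d": {"pos": (0.72, 0.01, 1.28), "neg": (0.96, 0.06, 3.67)},
    "dstar": {"pos": (75.06, 3.66, 186.80), "neg": (68.19, 9.49, 148.01)},
    "f_pct": {"pos": (41.56, 13.63, 82.06), "neg": (41.00, 10.45, 73.38)},
}


@dataclass
class CohortConfig:
    """Configuration of the two-group synthetic cohort.

    n_pos, n_neg : group sizes (LVI-positive / LVI-negative)
    calibration : biomarker -> {"pos"/"neg" -> summary tuple}; a 3-tuple is
        median (Q1, Q3), a 2-tuple is mean +/- sd
    reader_icc : target inter-reader intraclass correlation used to scale
        the multiplicative reader noise; 1.0 makes the two replicates
        identical
    quantile_convention : "quartile" reads 3-tuples as median (Q1, Q3);
        "extrema" reads the flanking values as expected sample extrema
    seed : generator seed; a fixed seed reproduces the table bit for bit
    correlation : optional between-biomarker Gaussian-copula correlation
        matrix (order of BIOMARKERS); None means independent draws
    """

    n_pos: int = 26
    n_neg: int = 47
    calibration: Mapping[str, Mapping[str, tuple[float, ...]]] = field(
        default_factory=lambda: DEFAULT_CALIBRATION
    )
    reader_icc: float = 0.9
    quantile_convention: str = "quartile"
    seed: int = 0
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_pos <= 0 or self.n_neg <= 0:
            raise ValueError("group sizes must be positive")
        if not 0 < self.reader_icc <= 1:
            raise ValueError("reader_icc must be in (0, 1]")
        if self.quantile_convention not in ("quartile", "extrema"):
            raise ValueError(
                f"quantile_convention must be 'quartile' or 'extrema', "
                f"got {self.quantile_convention!r}"
            )


def default_cohort_config(seed: int = 0, **kwargs) -> CohortConfig:
    """The study-default cohort: 26 LVI+ / 47 LVI- subjects, calibrated summaries."""
    return CohortConfig(seed=seed, **kwargs)


def _marker_spec(
    summary: tuple[float, ...], convention: str, n_group: int
) -> MarkerSpec:
    if len(summary) == 2:
        return TruncatedNormalSpec(*summary)
    if len(summary) == 3:
        if convention == "extrema":
            probs = (1.0 / (n_group + 1), n_group / (n_group + 1.0))
        else:
            probs = (0.25, 0.75)
        return calibrate_quantile_distribution(*summary, probs=probs)
    raise ValueError(f"calibration summary must have 2 or 3 values, got {summary}")


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate the two-group cohort table with two reader replicates.

    Returns a DataFrame with one row per subject x reader and columns
    ``subject_id, lvi, reader, mk, md, suvmax, mtv, tlg, adc, d, dstar,
    f_pct`` (lvi coded 1 for LVI-positive, 0 for LVI-negative).  Each
    biomarker is drawn from its group's calibrated marginal (independently
    unless a copula correlation is configured).  The two reader replicates
    are equicorrelated draws from that same marginal through a Gaussian
    copula whose reader-reader correlation is ``config.reader_icc``: each
    reader's measurements then follow the calibrated distribution exactly
    (so pooled medians and quartiles are preserved), the replicates agree
    at the configured level, and ``reader_icc = 1`` makes them identical.
    """
    for marker in BIOMARKERS:
        if marker not in config.calibration:
            raise KeyError(f"missing calibration for biomarker {marker!r}")
        for grp in ("pos", "neg"):
            if grp not in config.calibration[marker]:
                raise KeyError(
                    f"missing calibration for biomarker {marker!r}, group {grp!r}"
                )

    rng = np.random.default_rng(config.seed)
    p = len(BIOMARKERS)
    if config.correlation is None:
        corr = np.eye(p)
    else:
        corr = np.asarray(config.correlation, dtype=float)
        if corr.shape != (p, p):
            raise ValueError(f"correlation matrix must be {p}x{p}")
    chol = np.linalg.cholesky(corr)

    rows = []
    sid = 0
    for grp, label, n in (("pos", 1, config.n_pos), ("neg", 0, config.n_neg)):
        specs = [
            _marker_spec(
                tuple(config.calibration[m][grp]), config.quantile_convention, n
            )
            for m in BIOMARKERS
        ]
        z = rng.standard_normal((n, p)) @ chol.T
        # reader replicates: z_r = sqrt(icc) z + sqrt(1-icc) eps_r keeps
        # each reader's marginal standard normal (hence the calibrated
        # distribution exact) with reader-reader correlation = icc
        icc = config.reader_icc
        eps = rng.standard_normal((2, n, p)) if icc < 1 else np.zeros((2, n, p))
        z_readers = math.sqrt(icc) * z[None, :, :] + math.sqrt(1 - icc) * eps
        values = np.stack(
            [
                np.column_stack(
                    [spec.from_z(z_readers[r, :, j]) for j, spec in enumerate(specs)]
                )
                for r in range(2)
            ]
        )
        # the perfusion fraction is a percentage: censor draws at the
        # physical ceiling (the calibrated median and quartiles sit well
        # below it, so the summary calibration is unaffected)
        if "f_pct" in BIOMARKERS:
            j_f = BIOMARKERS.index("f_pct")
            values[:, :, j_f] = np.minimum(values[:, :, j_f], 99.9)
        for i in range(n):
            sid += 1
            for reader in (1, 2):
                vals = values[reader - 1, i]
                rows.append(
                    {
                        "subject_id": f"S{sid:03d}",
                        "lvi": label,
                        "reader": reader,
                        **{m: vals[j] for j, m in enumerate(BIOMARKERS)},
                    }
                )
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


# --------------------------------------------------------------------------
# Synthetic PET lesion volumes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PETVolume:
    """A voxel grid of SUV values (g/cm^3 convention) with geometry.

    ``data`` is a 3-D array of non-negative SUVs; ``spacing`` the voxel
    edge lengths in mm per axis.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError("PETVolume data must be 3-D")
        if np.any(data < 0):
            raise ValueError("SUV values must be non-negative")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


def generate_lesion_volume(
    suv_peak: float,
    background: float = 0.0,
    radius: float = 10.0,
    spacing: float | tuple[float, float, float] = 2.0,
    shape: tuple[int, int, int] | None = None,
    taper: bool = False,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> PETVolume:
    """Place a spherical synthetic lesion at the center of an SUV grid.

    The lesion has the given radius (mm); uptake is uniform at ``suv_peak``
    or, with ``taper``, falls off parabolically from the peak at the center
    to the background at the rim.  Optional additive Gaussian noise
    (``noise_sd``, SUV units, clipped at 0) is drawn under ``seed``.
    """
    if not suv_peak > background:
        raise ValueError("suv_peak must exceed background")
    if background < 0:
        raise ValueError("background must be non-negative")
    sp = (spacing,) * 3 if np.isscalar(spacing) else tuple(spacing)
    if radius <= max(sp):
        raise ValueError("radius must exceed the voxel spacing")
    if shape is None:
        shape = tuple(int(2 * math.ceil(radius / s) + 5) for s in sp)
    half_extent = [s * (n - 1) / 2 for s, n in zip(sp, shape)]
    if any(radius > h for h in half_extent):
        raise ValueError(
            f"lesion radius {radius} mm does not fit in grid of shape {shape}"
        )
    axes = [
        (np.arange(n) - (n - 1) / 2) * s for n, s in zip(shape, sp)
    ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    r = np.sqrt(xx**2 + yy**2 + zz**2)
    inside = r <= radius
    data = np.full(shape, float(background))
    if taper:
        data[inside] = background + (suv_peak - background) * (
            1 - (r[inside] / radius) ** 2
        )
    else:
        data[inside] = suv_peak
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = np.maximum(data + rng.normal(0.0, noise_sd, shape), 0.0)
    return PETVolume(data, sp)
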