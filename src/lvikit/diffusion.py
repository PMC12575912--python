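"""Inversion of the diffusion signal models.

Three fitters, one per model the pipeline generates:

* :func:`fit_adc` -- mono-exponential apparent diffusion coefficient, the
  ordinary least-squares slope of ln(S) against b.
* :func:`fit_ivim_segmented` / :func:`fit_ivim_full` -- the bi-exponential
  IVIM model.  The segmented fit is the conventional answer to the
  ill-posedness of the joint problem: the true diffusion coefficient D is
  estimated first from the high-b regime (b >= 200 s/mm^2 by default),
  where the pseudo-diffusion compartment has decayed away; the perfusion
  fraction f follows from the gap between the measured b=0 signal and the
  back-extrapolated high-b intercept; D* is then the only remaining free
  parameter and is found by a bounded one-dimensional search.  The full
  fit refines all parameters (plus the scale s0) simultaneously by bounded
  nonlinear least squares, starting from the segmented solution, and can
  only decrease the residual objective.
* :func:`fit_dki` -- the kurtosis model, a linear least-squares problem in
  (Dapp, Dapp^2 Kapp / 6) on the log-signal.

Voxel-wise maps are produced by applying a fitter along the last axis of a
4-D stack; :mod:`lvikit.io` handles the NIfTI plumbing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .synthetic import BValueScheme, DKIParams, IVIMParams, SignalCurve

__all__ = [
    "IVIMFit",
    "DKIFit",
    "fit_adc",
    "fit_ivim_segmented",
    "fit_ivim_full",
    "fit_dki",
    "roi_aggregate",
    "D_BOUNDS",
    "DSTAR_MAX",
]

# parameter bounds, mm^2/s: D within physiological diffusion range,
# D* up to fast capillary pseudo-diffusion
D_BOUNDS = (1e-5, 5e-3)
DSTAR_MAX = 0.5


@dataclass(frozen=True)
class IVIMFit:
    """Result of an IVIM inversion: parameters plus fit diagnostics.

    ``clipped`` flags a parameter forced back inside its bounds;
    ``converged`` is False when a nonlinear stage failed and earlier-stage
    values were retained.
    """

    params: IVIMParams
    s0: float
    rss: float
    method: str
    clipped: bool = False
    converged: bool = True


@dataclass(frozen=True)
class DKIFit:
    params: DKIParams
    s0: float
    rss: float
    clipped: bool = False


def _ivim_model(b: np.ndarray, d: float, dstar: float, f: float, s0: float) -> np.ndarray:
    return s0 * ((1 - f) * np.exp(-b * d) + f * np.exp(-b * (dstar + d)))


def _ivim_rss(curve: SignalCurve, d: float, dstar: float, f: float, s0: float) -> float:
    return float(np.sum((_ivim_model(curve.bvalues, d, dstar, f, s0) - curve.array) ** 2))


def fit_adc(curve: SignalCurve) -> float:
    """Mono-exponential ADC in mm^2/s: negated OLS slope of ln(S) vs b.

    With exactly two b-values this is ln(S_b1/S_b2)/(b2 - b1).  The
    intercept is free, so noise at b = 0 does not propagate into the slope.
    """
    b = curve.bvalues
    if np.unique(b).size < 2:
        raise ValueError("fit_adc needs at least 2 distinct b-values")
    slope, _ = np.polyfit(b, np.log(curve.array), 1)
    return float(-slope)


def fit_ivim_segmented(
    curve: SignalCurve, b_threshold: float = 200.0
) -> IVIMFit:
    """Two-stage (segmented) inversion of the bi-exponential IVIM model.

    Stage 1 fits ln(S) vs b over b >= ``b_threshold`` (OLS; slope gives D,
    intercept gives the perfusion-free extrapolation A = (1-f) s0).
    Stage 2 takes f = 1 - A / S(0) from the intercept gap at b = 0.
    Stage 3 finds D* by a bounded 1-D minimisation of the full-curve
    residual with D and f held fixed.

    Requires >= 3 b-values at or above the threshold and >= 2 below it.
    Estimates falling outside the bounds D in [1e-5, 5e-3] mm^2/s,
    D* in [D, 0.5] mm^2/s, f in [0, 1] are clipped and flagged.
    """
    b = curve.bvalues
    s = curve.array
    hi = b >= b_threshold
    lo = ~hi
    if hi.sum() < 3:
        raise ValueError(
            f"segmented fit needs >= 3 b-values at or above {b_threshold}, "
            f"got {int(hi.sum())}"
        )
    if lo.sum() < 2:
        raise ValueError(
            f"segmented fit needs >= 2 b-values below {b_threshold}, "
            f"got {int(lo.sum())}"
        )

    clipped = False
    # stage 1: true diffusion from the perfusion-free regime
    slope, intercept = np.polyfit(b[hi], np.log(s[hi]), 1)
    d = -slope
    if not D_BOUNDS[0] <= d <= D_BOUNDS[1]:
        d = float(np.clip(d, *D_BOUNDS))
        clipped = True
    a = float(np.exp(intercept))

    # stage 2: perfusion fraction from the b=0 intercept gap
    s0_ref = float(s[b == 0][0]) if np.any(b == 0) else float(curve.s0)
    f = 1.0 - a / s0_ref
    if not 0.0 <= f <= 1.0:
        f = float(np.clip(f, 0.0, 1.0))
        clipped = True

    # stage 3: bounded 1-D search for the pseudo-diffusion coefficient
    converged = True
    dstar_lo, dstar_hi = d, DSTAR_MAX

    def objective(dstar: float) -> float:
        return _ivim_rss(curve, d, dstar, f, s0_ref)

    res = optimize.minimize_scalar(
        objective,
        bounds=(dstar_lo, dstar_hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if res.success:
        dstar = float(res.x)
    else:  # keep a defensible stage-1/2 result rather than failing outright
        dstar = dstar_lo
        converged = False
    params = IVIMParams(d=float(d), dstar=dstar, f=float(f))
    return IVIMFit(
        params=params,
        s0=s0_ref,
        rss=_ivim_rss(curve, params.d, params.dstar, params.f, s0_ref),
        method="segmented",
        clipped=clipped,
        converged=converged,
    )


def fit_ivim_full(curve: SignalCurve, init: IVIMFit | IVIMParams) -> IVIMFit:
    """Simultaneous bounded nonlinear least squares on (D, D*, f) with free s0.

    ``init`` is normally the segmented fit; the trust-region refinement
    starts there, so the residual objective never exceeds the segmented
    objective.  On solver failure the initialization is returned flagged.
    """
    if isinstance(init, IVIMParams):
        init = IVIMFit(
            params=init,
            s0=float(curve.array[curve.bvalues == 0][0]),
            rss=np.nan,
            method="init",
        )
    p0 = init.params
    x0 = np.array(
        [
            np.clip(p0.d, *D_BOUNDS),
            np.clip(p0.dstar, D_BOUNDS[0], DSTAR_MAX),
            np.clip(p0.f, 0.0, 1.0),
            init.s0,
        ]
    )
    b, s = curve.bvalues, curve.array

    def residuals(x: np.ndarray) -> np.ndarray:
        return _ivim_model(b, *x) - s

    lower = [D_BOUNDS[0], D_BOUNDS[0], 0.0, 1e-12]
    upper = [D_BOUNDS[1], DSTAR_MAX, 1.0, np.inf]
    try:
        res = optimize.least_squares(
            residuals, x0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14
        )
    except Exception:
        return IVIMFit(p0, init.s0, _ivim_rss(curve, p0.d, p0.dstar, p0.f, init.s0),
                       "full", init.clipped, converged=False)
    d, dstar, f, s0 = res.x
    clipped = init.clipped
    if dstar < d:  # enforce the pseudo-diffusion >= diffusion invariant
        dstar, clipped = d, True
    params = IVIMParams(float(d), float(dstar), float(f))
    rss = _ivim_rss(curve, params.d, params.dstar, params.f, float(s0))
    init_rss = _ivim_rss(curve, p0.d, p0.dstar, p0.f, init.s0)
    if rss > init_rss:  # refinement contract: never worse than the start
        return IVIMFit(p0, init.s0, init_rss, "full", init.clipped, converged=False)
    return IVIMFit(params, float(s0), rss, "full", clipped, converged=res.success)


def fit_dki(curve: SignalCurve) -> DKIFit:
    """Least-squares inversion of ln(S/s0) = -b Dapp + b^2 Dapp^2 Kapp / 6.

    The measured b = 0 intensity serves as s0; the positive-b log-signals
    then form a linear system in (Dapp, Dapp^2 Kapp / 6).  With exactly
    three distinct positive b-values and clean data the solution equals
    the closed-form solve of the corresponding square system.  Dapp > 0
    and Kapp >= 0 are enforced: a negative curvature estimate collapses to
    the Kapp = 0 mono-exponential refit, flagged as clipped.
    """
    b = curve.bvalues
    s = curve.array
    if np.unique(b).size < 3:
        raise ValueError("fit_dki needs at least 3 distinct b-values")
    pos = b > 0
    bp = b[pos]
    if np.unique(bp).size < 2:
        raise ValueError("degenerate design: b and b^2 are collinear")
    s0 = float(s[b == 0][0]) if np.any(b == 0) else float(curve.s0)
    y = np.log(s[pos] / s0)
    X = np.column_stack([-bp, bp**2])
    (c1, c2), *_ = np.linalg.lstsq(X, y, rcond=None)

    clipped = False
    if c1 <= 0:
        c1 = 1e-12
        clipped = True
    if c2 < 0:
        # refit the Gaussian model through the origin: y = -b * Dapp
        c1 = float(np.sum(bp * -y) / np.sum(bp**2))
        c1 = max(c1, 1e-12)
        c2 = 0.0
        clipped = True
    dapp = float(c1)
    kapp = float(6.0 * c2 / dapp**2)
    params = DKIParams(dapp=dapp, kapp=kapp)
    fitted = s0 * np.exp(X @ np.array([dapp, c2]))
    rss = float(np.sum((fitted - s[pos]) ** 2))
    return DKIFit(params=params, s0=s0, rss=rss, clipped=clipped)


def fit_stack(
    data: np.ndarray, scheme: BValueScheme, model: str = "ivim"
) -> dict[str, np.ndarray]:
    """Fit a diffusion model voxel-wise over a 4-D (x, y, z, b) stack.

    Returns one 3-D map per parameter ("adc"; "d"/"dstar"/"f"; or
    "dapp"/"kapp").  Voxels with non-positive signal anywhere along b are
    left as NaN.
    """
    if data.ndim != 4:
        raise ValueError("expected a 4-D (x, y, z, b) stack")
    if data.shape[-1] != len(scheme):
        raise ValueError(
            f"stack has {data.shape[-1]} b-frames but scheme has {len(scheme)}"
        )
    names = {
        "adc": ("adc",),
        "ivim": ("d", "dstar", "f"),
        "ivim-full": ("d", "dstar", "f"),
        "dki": ("dapp", "kapp"),
    }
    if model not in names:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(names)}")
    maps = {k: np.full(data.shape[:3], np.nan) for k in names[model]}
    for idx in np.ndindex(data.shape[:3]):
        sig = data[idx]
        if np.any(sig <= 0):
            continue
        curve = SignalCurve(scheme, tuple(sig), float(sig[0]))
        if model == "adc":
            maps["adc"][idx] = fit_adc(curve)
        elif model in ("ivim", "ivim-full"):
            fit = fit_ivim_segmented(curve)
            if model == "ivim-full":
                fit = fit_ivim_full(curve, fit)
            maps["d"][idx] = fit.params.d
            maps["dstar"][idx] = fit.params.dstar
            maps["f"][idx] = fit.params.f
        else:
            fit = fit_dki(curve)
            maps["dapp"][idx] = fit.params.dapp
            maps["kapp"][idx] = fit.params.kapp
    return maps


def roi_aggregate(values) -> float:
    """Arithmetic mean over an ROI's voxel values (the per-lesion summary)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty ROI")
    return float(arr.mean())
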