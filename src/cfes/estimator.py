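"""CFES core: weighted least-squares mixture fitting and quasi-segmentation.

The estimator extracts the grey-value histogram of a slice, fits the
five-parameter two-Gaussian mixture by minimising the weighted
least-squares distance

    S_alpha = sum_{n in G_0} (x_n(Y) - x_n(Theta))**2 * x_n(Y)**alpha

over Theta = (E_F, E_M, S_F, S_M, z), derives the fat/muscle threshold
t_FM that minimises the expected misclassified pixel count under the
fitted model, and labels every body pixel below/above the threshold as
fat/muscle.  The fat ratio z* then directly quantifies fat content
(Q_F = z* Q).

Weights use the *empirical* counts, held fixed during optimisation.
The objective is multi-modal in general, so the optimiser is restarted
from several data-driven initialisations (histogram modes, a quantile
split, and seeded jitter); the restart with the smallest final
objective wins, ties going to the lowest restart index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .model import (
    GreyBinning,
    GreyHistogram,
    MixtureParams,
    TheoreticalHistogram,
    component_bin_masses,
    mixture_bin_masses,
    theoretical_histogram,
)
from .phantom import EXCLUDED, FAT, MUSCLE, LabelMap, SliceImage

__all__ = [
    "FitConfig",
    "FitResult",
    "CFES",
    "ConvergenceError",
    "compute_histogram",
    "wls_distance",
    "fit_cfes",
    "compute_threshold",
    "quasi_segment",
    "fat_volume",
]


class ConvergenceError(RuntimeError):
    """Raised when every restart of the WLS optimisation fails."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass(frozen=True)
class FitConfig:
    """Configuration of one CFES fit."""

    alpha: float = 1.0
    binning: GreyBinning = field(default_factory=GreyBinning)
    n_restarts: int = 3
    max_iter: int = 400
    tol: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be at least 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class FitResult:
    """Outcome of a CFES fit."""

    theta_star: MixtureParams
    s_alpha: float
    ln_s_alpha: float
    t_fm: int
    q_f: float
    q_m: float
    converged: bool
    objective_trace: list
    threshold_warning: bool = False

    @property
    def z_star(self) -> float:
        return self.theta_star.z


def compute_histogram(image: SliceImage, binning: GreyBinning) -> GreyHistogram:
    """Grey-value histogram over the masked-in pixels of a slice."""
    values = image.pixels[image.mask]
    if values.size == 0:
        raise ValueError("image has no masked-in pixels")
    idx = binning.bin_of(values)
    counts = np.bincount(idx, minlength=binning.n_bins)
    return GreyHistogram(counts=counts, binning=binning)


def _weights(counts: np.ndarray, included: np.ndarray, alpha: float) -> np.ndarray:
    """Per-bin WLS weights ``x_n**alpha`` restricted to G_0.

    Zero-count bins are excluded whenever ``alpha < 0`` (the weight is
    undefined at zero); for ``alpha >= 0`` they contribute with weight
    ``0**alpha`` (0 for positive alpha, 1 for alpha = 0).
    """
    w = np.zeros_like(counts, dtype=float)
    sel = included.copy()
    if alpha < 0:
        sel &= counts > 0
    with np.errstate(divide="ignore"):
        w[sel] = np.where(counts[sel] > 0, counts[sel].astype(float) ** alpha, 0.0 if alpha > 0 else 1.0)
    return w


def wls_distance(
    empirical: GreyHistogram, theoretical: TheoreticalHistogram, alpha: float
) -> float:
    """Weighted least-squares distance S_alpha between two histograms."""
    if empirical.binning != theoretical.binning:
        raise ValueError("empirical and theoretical histograms use different binnings")
    w = _weights(empirical.counts, empirical.included, alpha)
    resid = empirical.counts - theoretical.expected
    return float(np.sum(resid**2 * w))


# ---------------------------------------------------------------------------
# parameter transforms: optimise on (e_f, e_m, log s_f, log s_m, logit z)
# so every iterate satisfies the model invariants

_LOGIT_CAP = 30.0


def _to_internal(theta: MixtureParams) -> np.ndarray:
    z = min(max(theta.z, 1e-9), 1 - 1e-9)
    return np.array(
        [theta.e_f, theta.e_m, np.log(theta.s_f), np.log(theta.s_m), np.log(z / (1 - z))]
    )


def _from_internal(p: np.ndarray) -> MixtureParams:
    lz = np.clip(p[4], -_LOGIT_CAP, _LOGIT_CAP)
    ls = np.clip(p[2:4], -20.0, 20.0)
    return MixtureParams(
        e_f=float(p[0]),
        e_m=float(p[1]),
        s_f=float(np.exp(ls[0])),
        s_m=float(np.exp(ls[1])),
        z=float(1.0 / (1.0 + np.exp(-lz))),
    )


def _initial_guesses(
    hist: GreyHistogram, n_restarts: int, rng: np.random.Generator
) -> list[MixtureParams]:
    """Data-driven multi-start initialisations.

    (i) the two tallest well-separated histogram modes, (ii) a split of
    the sample at the deepest interior histogram minimum between the
    modes, (iii)+ seeded jitter around (i).
    """
    counts = hist.counts.astype(float)
    centers = hist.binning.centers()
    q = counts.sum()
    mean = float(np.sum(counts * centers) / q)
    sd = float(np.sqrt(np.sum(counts * (centers - mean) ** 2) / q)) or hist.binning.width_hu

    # (i) mode-based: tallest bin, then tallest bin at least one pooled SD away
    i0 = int(np.argmax(counts))
    sep = max(int(round(0.5 * sd / hist.binning.width_hu)), 2)
    masked = counts.copy()
    lo, hi = max(i0 - sep, 0), min(i0 + sep + 1, len(counts))
    masked[lo:hi] = -1.0
    i1 = int(np.argmax(masked))
    if masked[i1] <= 0:
        i1 = min(i0 + 2 * sep, len(counts) - 1) if i0 < len(counts) // 2 else max(i0 - 2 * sep, 0)
    m_lo, m_hi = sorted((centers[i0], centers[i1]))
    z0 = float(counts[hist.binning.bin_of(m_lo)] / (counts[hist.binning.bin_of(m_lo)] + counts[hist.binning.bin_of(m_hi)] + 1e-12))
    z0 = min(max(z0, 0.05), 0.95)
    spread = max(sd / 2, hist.binning.width_hu / 2)
    modes = MixtureParams(e_f=m_lo, e_m=m_hi, s_f=spread, s_m=spread, z=z0)

    # (ii) quantile split at the deepest interior minimum between the modes
    j0, j1 = sorted((i0, i1))
    if j1 - j0 > 1:
        interior = counts[j0 + 1 : j1]
        cut = j0 + 1 + int(np.argmin(interior))
    else:
        cut = int(np.searchsorted(np.cumsum(counts), q / 2))
    below = counts[: cut + 1]
    above = counts[cut + 1 :]
    qb, qa = below.sum(), above.sum()
    if qb > 0 and qa > 0:
        cb, ca = centers[: cut + 1], centers[cut + 1 :]
        mb = float(np.sum(below * cb) / qb)
        ma = float(np.sum(above * ca) / qa)
        sb = float(np.sqrt(np.sum(below * (cb - mb) ** 2) / qb)) or spread
        sa = float(np.sqrt(np.sum(above * (ca - ma) ** 2) / qa)) or spread
        split = MixtureParams(e_f=mb, e_m=ma, s_f=max(sb, 1e-3), s_m=max(sa, 1e-3), z=float(qb / q))
    else:
        split = modes

    guesses = [modes, split]
    while len(guesses) < n_restarts:
        jit = rng.normal(0, 1, 5)
        guesses.append(
            MixtureParams(
                e_f=modes.e_f + jit[0] * spread,
                e_m=modes.e_m + jit[1] * spread,
                s_f=float(modes.s_f * np.exp(0.3 * jit[2])),
                s_m=float(modes.s_m * np.exp(0.3 * jit[3])),
                z=float(np.clip(modes.z + 0.1 * jit[4], 0.02, 0.98)),
            )
        )
    return guesses[:n_restarts]


class CFES(BaseEstimator):
    """Histogram-based fat estimation and quasi-segmentation.

    A scikit-learn style estimator: ``fit`` takes a :class:`SliceImage`
    (or a :class:`GreyHistogram`) and estimates the mixture parameters;
    ``predict`` labels the pixels of a slice as fat or muscle using the
    fitted threshold.

    Parameters
    ----------
    alpha : float, default 1.0
        Weight exponent of the WLS distance.
    binning : GreyBinning, optional
        HU binning convention; defaults to the 12-bit-to-8-bit mapping.
    n_restarts : int, default 3
        Number of multi-start initialisations.
    max_iter : int, default 400
        Iteration cap per restart.
    tol : float, default 1e-10
        Relative convergence tolerance on the objective.
    seed : int, default 0
        Seed of the restart jitter.

    Attributes
    ----------
    theta_ : MixtureParams
        Fitted parameter vector Theta*.
    s_alpha_, ln_s_alpha_ : float
        Achieved WLS distance and its natural log.
    t_fm_ : int
        Fat/muscle threshold bin index.
    z_ : float
        Estimated fat ratio z*.
    q_f_, q_m_ : float
        Estimated fat and muscle pixel counts (z* Q and (1 - z*) Q).
    result_ : FitResult
        Full fit record including the per-restart objective trace.
    """

    def __init__(
        self,
        alpha: float = 1.0,
        binning: GreyBinning | None = None,
        n_restarts: int = 3,
        max_iter: int = 400,
        tol: float = 1e-10,
        seed: int = 0,
    ):
        self.alpha = alpha
        self.binning = binning
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def _config(self) -> FitConfig:
        return FitConfig(
            alpha=self.alpha,
            binning=self.binning if self.binning is not None else GreyBinning(),
            n_restarts=self.n_restarts,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.seed,
        )

    def fit(self, X, y=None) -> "CFES":
        """Fit the mixture to a slice or to a pre-computed histogram."""
        config = self._config()
        if isinstance(X, GreyHistogram):
            hist = X
        elif isinstance(X, SliceImage):
            hist = compute_histogram(X, config.binning)
        else:
            raise TypeError("X must be a SliceImage or a GreyHistogram")
        self.result_ = _fit_histogram(hist, config)
        self.theta_ = self.result_.theta_star
        self.s_alpha_ = self.result_.s_alpha
        self.ln_s_alpha_ = self.result_.ln_s_alpha
        self.t_fm_ = self.result_.t_fm
        self.z_ = self.result_.theta_star.z
        self.q_f_ = self.result_.q_f
        self.q_m_ = self.result_.q_m
        return self

    def predict(self, X: SliceImage) -> LabelMap:
        """Quasi-segment a slice with the fitted threshold."""
        if not hasattr(self, "theta_"):
            raise AttributeError("CFES instance is not fitted yet; call fit first")
        return quasi_segment(X, self.t_fm_, self._config().binning)


def _fit_histogram(hist: GreyHistogram, config: FitConfig) -> FitResult:
    q = hist.q_total
    if q <= 0:
        raise ValueError("histogram is empty")
    if np.count_nonzero(hist.counts) < 2:
        raise ValueError("histogram needs at least two non-empty bins")
    counts = hist.counts.astype(float)
    w = _weights(hist.counts, hist.included, config.alpha)
    sqrt_w = np.sqrt(w)
    binning = config.binning

    def residuals(p: np.ndarray) -> np.ndarray:
        theta = _from_internal(p)
        return (counts - q * mixture_bin_masses(theta, binning)) * sqrt_w

    rng = np.random.default_rng(config.seed)
    guesses = _initial_guesses(hist, config.n_restarts, rng)
    best = None
    trace: list = []
    failures: list = []
    for i, g in enumerate(guesses):
        try:
            sol = least_squares(
                residuals,
                _to_internal(g),
                method="lm",
                max_nfev=config.max_iter * 6,
                ftol=config.tol,
                xtol=1e-12,
                gtol=1e-12,
            )
        except Exception as exc:  # pragma: no cover - defensive
            failures.append((i, repr(exc)))
            trace.append(np.inf)
            continue
        obj = float(np.sum(sol.fun**2))
        trace.append(obj)
        ok = sol.status > 0 and np.all(np.isfinite(sol.x))
        if not ok:
            failures.append((i, f"status={sol.status}"))
            continue
        if best is None or obj < best[0]:
            best = (obj, sol, i)
    if best is None:
        raise ConvergenceError("all WLS restarts failed to converge", failures)

    obj, sol, _ = best
    theta_star = _from_internal(sol.x)
    t_fm, warn = compute_threshold(theta_star, binning, warn_only=True)
    return FitResult(
        theta_star=theta_star,
        s_alpha=obj,
        ln_s_alpha=float(np.log(obj)) if obj > 0 else -np.inf,
        t_fm=t_fm,
        q_f=theta_star.z * q,
        q_m=(1.0 - theta_star.z) * q,
        converged=True,
        objective_trace=trace,
        threshold_warning=warn,
    )


def fit_cfes(empirical: GreyHistogram, config: FitConfig | None = None) -> FitResult:
    """Fit the two-Gaussian mixture to an empirical histogram by WLS."""
    return _fit_histogram(empirical, config or FitConfig())


def _expected_misclassification(theta: MixtureParams, binning: GreyBinning) -> np.ndarray:
    """Expected misclassified-pixel fraction for every threshold bin t.

    Pixels in bins ``< t`` are labelled fat, bins ``>= t`` muscle; the
    expectation under the fitted mixture is ``z P_F(bin >= t) +
    (1 - z) P_M(bin < t)``, evaluated for t = 0 .. n_bins.
    """
    mf = component_bin_masses(theta.e_f, theta.s_f, binning)
    mm = component_bin_masses(theta.e_m, theta.s_m, binning)
    cf = np.concatenate([[0.0], np.cumsum(mf)])  # P_F(bin < t)
    cm = np.concatenate([[0.0], np.cumsum(mm)])
    return theta.z * (cf[-1] - cf) + (1.0 - theta.z) * cm


def compute_threshold(
    theta_star: MixtureParams, binning: GreyBinning, warn_only: bool = False
):
    """Fat/muscle threshold bin minimising expected misclassification.

    Equivalently the crossing point of ``z f_F`` and ``(1 - z) f_M``
    between the component means, located by brute-force scan over the
    bins; ties resolve to the lower bin.  With an extreme ``z*`` the
    weighted densities may not cross between the means; the scan then
    still returns the overall argmin, flagged with a warning.
    """
    if theta_star.e_f >= theta_star.e_m:
        raise ValueError("threshold requires e_f < e_m")
    exp_mis = _expected_misclassification(theta_star, binning)
    lo = int(binning.bin_of(theta_star.e_f))
    hi = int(binning.bin_of(theta_star.e_m))
    interior = exp_mis[lo + 1 : hi + 1]
    warn = False
    if interior.size:
        t = lo + 1 + int(np.argmin(interior))
        # flag fits whose weighted densities do not cross between the
        # means (the unconstrained argmin then lies outside the interval)
        if exp_mis[t] > exp_mis.min() + 1e-12:
            warn = True
    else:
        warn = True
        t = int(np.argmin(exp_mis))
    if warn and not warn_only:
        warnings.warn(
            "weighted component densities do not cross between the means; "
            "returning the global misclassification argmin",
            RuntimeWarning,
        )
    return (t, warn) if warn_only else t


def quasi_segment(image: SliceImage, t_fm: int, binning: GreyBinning) -> LabelMap:
    """Label masked pixels with bin < t_FM as fat, the rest as muscle."""
    bins = binning.bin_of(image.pixels)
    labels = np.full(image.pixels.shape, EXCLUDED, dtype=np.uint8)
    labels[image.mask & (bins < t_fm)] = FAT
    labels[image.mask & (bins >= t_fm)] = MUSCLE
    return LabelMap(labels=labels)


def fat_volume(q_f: float, pixel_area_mm2: float, slice_spacing_mm: float) -> float:
    """Fat volume in mm^3 from a fat pixel count.

    Uses the scan's spacing-between-slices (not the slice thickness) as
    the third voxel dimension.
    """
    if pixel_area_mm2 <= 0 or slice_spacing_mm <= 0:
        raise ValueError("pixel area and slice spacing must be positive")
    if q_f < 0:
        raise ValueError("q_f must be non-negative")
    return q_f * pixel_area_mm2 * slice_spacing_mm
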