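"""Two-component Gaussian grey-value model and histogram containers.

A CT slice restricted to soft tissue is modelled as a mixture of two
Normal grey-value distributions, one for fat and one for muscle:

    f(g) = z * phi(g; E_F, S_F) + (1 - z) * phi(g; E_M, S_M)

with means ``E_F < E_M`` (fat attenuates less than muscle), standard
deviations ``S_F, S_M`` and fat pixel proportion ``z``.  Everything
downstream (fitting, quality measures, sensitivity analysis) works on
8-bit grey-value histograms of that mixture, so this module also fixes
the Hounsfield-unit binning conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

__all__ = [
    "MixtureParams",
    "GreyBinning",
    "GreyHistogram",
    "TheoreticalHistogram",
    "mixture_density",
    "theoretical_histogram",
]


@dataclass(frozen=True)
class MixtureParams:
    """Parameter vector of the two-Gaussian grey-value mixture.

    Parameters
    ----------
    e_f, e_m : float
        Fat and muscle mean grey values in HU.  The canonical orientation
        ``e_f < e_m`` is enforced: a swapped vector is re-oriented and
        ``z`` replaced by ``1 - z``.
    s_f, s_m : float
        Component standard deviations in HU; must be positive.
    z : float
        Fat pixel proportion among fat+muscle pixels, in ``[0, 1]``.
    """

    e_f: float
    e_m: float
    s_f: float
    s_m: float
    z: float

    def __post_init__(self) -> None:
        for name in ("e_f", "e_m", "s_f", "s_m", "z"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.s_f <= 0 or self.s_m <= 0:
            raise ValueError("component standard deviations must be positive")
        if not 0.0 <= self.z <= 1.0:
            raise ValueError(f"z must lie in [0, 1], got {self.z}")
        if self.e_f > self.e_m:
            # canonical orientation: fat is the darker component
            ef, em, sf, sm, z = self.e_f, self.e_m, self.s_f, self.s_m, self.z
            object.__setattr__(self, "e_f", em)
            object.__setattr__(self, "e_m", ef)
            object.__setattr__(self, "s_f", sm)
            object.__setattr__(self, "s_m", sf)
            object.__setattr__(self, "z", 1.0 - z)

    def as_array(self) -> np.ndarray:
        """Return ``(e_f, e_m, s_f, s_m, z)`` as a float array."""
        return np.array([self.e_f, self.e_m, self.s_f, self.s_m, self.z])

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "MixtureParams":
        e_f, e_m, s_f, s_m, z = (float(v) for v in theta)
        return cls(e_f=e_f, e_m=e_m, s_f=s_f, s_m=s_m, z=z)

    def shifted(self, offset_hu: float) -> "MixtureParams":
        """Translate both component means by ``offset_hu``."""
        return replace(self, e_f=self.e_f + offset_hu, e_m=self.e_m + offset_hu)


@dataclass(frozen=True)
class GreyBinning:
    """Affine HU-to-grey-value binning.

    The default maps the full 12-bit CT range [-1024, 3072) HU onto
    256 grey values (16 HU per bin), the standard 12-bit to 8-bit
    compression of CT data.  Bins are half-open ``[lo, hi)``; the two
    edge bins absorb out-of-range values.
    """

    origin_hu: float = -1024.0
    width_hu: float = 16.0
    n_bins: int = 256

    def __post_init__(self) -> None:
        if self.width_hu <= 0:
            raise ValueError("width_hu must be positive")
        if self.n_bins < 2:
            raise ValueError("need at least two bins")

    @property
    def edges(self) -> np.ndarray:
        """The ``n_bins + 1`` bin edges in HU."""
        return self.origin_hu + self.width_hu * np.arange(self.n_bins + 1, dtype=float)

    def bin_of(self, hu):
        """Bin index of HU value(s), clipped into ``[0, n_bins - 1]``."""
        hu = np.asarray(hu, dtype=float)
        idx = np.floor((hu - self.origin_hu) / self.width_hu).astype(np.int64)
        return np.clip(idx, 0, self.n_bins - 1)

    def centers(self) -> np.ndarray:
        return self.origin_hu + self.width_hu * (np.arange(self.n_bins) + 0.5)

    def shifted(self, offset_hu: float) -> "GreyBinning":
        return replace(self, origin_hu=self.origin_hu + offset_hu)


@dataclass
class GreyHistogram:
    """Empirical grey-value histogram ``x_n(Y)`` of a slice.

    ``included`` marks the bin set G_0 entering the weighted
    least-squares distance.  By default every bin is included;
    zero-count bins are dropped on the fly whenever the weight
    exponent is negative (the weight ``x_n**alpha`` is undefined at 0).
    """

    counts: np.ndarray
    binning: GreyBinning
    included: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or len(self.counts) != self.binning.n_bins:
            raise ValueError("counts must be a 1-D array of length n_bins")
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be non-negative")
        if self.included is None:
            self.included = np.ones(self.binning.n_bins, dtype=bool)
        else:
            self.included = np.asarray(self.included, dtype=bool)
            if self.included.shape != self.counts.shape:
                raise ValueError("included mask must match counts")

    @property
    def q_total(self) -> int:
        """Total pixel count Q."""
        return int(self.counts.sum())


@dataclass
class TheoreticalHistogram:
    """Model-expected histogram ``x_n(Theta) = Q * P(bin n | Theta)``."""

    expected: np.ndarray
    binning: GreyBinning
    q_total: float

    def __post_init__(self) -> None:
        self.expected = np.asarray(self.expected, dtype=float)
        if self.expected.ndim != 1 or len(self.expected) != self.binning.n_bins:
            raise ValueError("expected must be a 1-D array of length n_bins")


def mixture_density(g, theta: MixtureParams):
    """Mixture probability density (1/HU) at grey value(s) ``g``.

    ``z * phi(g; e_f, s_f) + (1 - z) * phi(g; e_m, s_m)`` with ``phi``
    the Normal density.
    """
    g = np.asarray(g, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("grey values must be finite")
    out = theta.z * norm.pdf(g, theta.e_f, theta.s_f) + (1.0 - theta.z) * norm.pdf(
        g, theta.e_m, theta.s_m
    )
    return out if out.ndim else float(out)


def component_bin_masses(
    e: float, s: float, binning: GreyBinning
) -> np.ndarray:
    """Per-bin probability mass of one Normal component.

    Exact CDF differences at the bin edges; the first and last bins
    additionally absorb the tail mass outside the binning range, so the
    masses sum to one exactly.
    """
    cdf = norm.cdf(binning.edges, e, s)
    mass = np.diff(cdf)
    mass[0] += cdf[0]
    mass[-1] += 1.0 - cdf[-1]
    return mass


def mixture_bin_masses(theta: MixtureParams, binning: GreyBinning) -> np.ndarray:
    """Per-bin probability mass of the fat/muscle mixture."""
    return theta.z * component_bin_masses(theta.e_f, theta.s_f, binning) + (
        1.0 - theta.z
    ) * component_bin_masses(theta.e_m, theta.s_m, binning)


def theoretical_histogram(
    theta: MixtureParams, q_total: float, binning: GreyBinning
) -> TheoreticalHistogram:
    """Expected histogram of ``q_total`` pixels under the mixture model."""
    if q_total <= 0:
        raise ValueError("q_total must be positive")
    expected = q_total * mixture_bin_masses(theta, binning)
    return TheoreticalHistogram(expected=expected, binning=binning, q_total=float(q_total))
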