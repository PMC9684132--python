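"""Quality measures for histogram-based fat/muscle separation.

Three complementary measures:

* the fat/muscle separability ``tau`` — a Welch-statistic-like
  signal-to-signal ratio quantifying how distinguishable the two
  grey-value peaks are,

      tau = sqrt(Q) * (E_M - E_F) / sqrt(S_F**2 / z + S_M**2 / (1 - z))

  evaluated with fitted parameters it yields ``tau*``, with ground
  truth ``tau+``;

* the binary per-slice misclassification verdict ``d`` and its means
  ``D`` (over the slices of one scan) and ``F`` (over a sample of
  scans).  On real scans ``d`` is an informed observer's judgment; here
  it is operationalised by comparing the quasi-segmentation against a
  reference label map, with a configurable pixel-disagreement tolerance
  ``epsilon`` (verdict manifests can override this oracle);

* the relative error ``RE_z = |z* - z+| / z+`` of the fat-ratio
  estimate, computable whenever ground truth is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import MixtureParams
from .phantom import EXCLUDED, LabelMap

__all__ = [
    "QualityRecord",
    "separability_tau",
    "misclassification_d",
    "misclassification_rate",
    "relative_error_z",
    "DEFAULT_EPSILON",
]

#: default pixel-disagreement tolerance standing in for expert judgment
DEFAULT_EPSILON = 0.02


@dataclass
class QualityRecord:
    """Per-slice quality summary."""

    tau_star: float
    ln_s_alpha: float
    d: int | None = None
    re_z: float | None = None


def separability_tau(theta: MixtureParams, q_total: float) -> float:
    """Fat/muscle separability of a slice with ``q_total`` body pixels.

    Undefined for degenerate mixtures (z of 0 or 1: one component has
    no pixels).
    """
    if q_total <= 0:
        raise ValueError("q_total must be positive")
    if theta.z <= 0.0 or theta.z >= 1.0:
        raise ValueError("separability is undefined for z in {0, 1}")
    denom = np.sqrt(theta.s_f**2 / theta.z + theta.s_m**2 / (1.0 - theta.z))
    return float(np.sqrt(q_total) * (theta.e_m - theta.e_f) / denom)


def misclassification_d(
    result: LabelMap,
    reference: LabelMap,
    epsilon: float = DEFAULT_EPSILON,
) -> int:
    """Binary per-slice misclassification verdict.

    ``1`` iff the fraction of reference body pixels whose labels
    disagree with the segmentation exceeds ``epsilon`` (strictly),
    else ``0``.
    """
    if result.labels.shape != reference.labels.shape:
        raise ValueError("label maps must have identical shape")
    body = reference.labels != EXCLUDED
    n = int(body.sum())
    if n == 0:
        raise ValueError("reference label map has no body pixels")
    disagree = np.count_nonzero(result.labels[body] != reference.labels[body])
    return int(disagree / n > epsilon)


def misclassification_rate(d_values: Sequence[float]) -> float:
    """Mean of binary misclassification verdicts.

    Applied to the slices of one scan this is the per-scan rate D;
    applied to per-scan D values it is the sample rate F.
    """
    d_values = list(d_values)
    if not d_values:
        raise ValueError("d_values must not be empty")
    return float(np.mean(d_values))


def relative_error_z(z_true: float, z_est: float) -> float:
    """Relative error of the fat-ratio estimate, |z* - z+| / z+."""
    if z_true <= 0:
        raise ValueError("z_true must be positive")
    return abs(z_est - z_true) / z_true


def read_verdict_manifest(path) -> dict:
    """Read an observer-verdict manifest (two columns: slice id, 0/1).

    Lines starting with '#' are comments; the verdict overrides the
    reference-comparison oracle for the listed slices.
    """
    verdicts: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2 or parts[1] not in {"0", "1"}:
                raise ValueError(f"malformed manifest line: {line!r}")
            verdicts[parts[0]] = int(parts[1])
    return verdicts
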