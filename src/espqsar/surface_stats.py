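"""Politzer surface-potential statistics.

Given the electrostatic potential V sampled on the molecular surface, this
module computes the classic GIPF (general interaction properties function)
descriptor set:

* V_s,max / V_s,min — surface extrema (kcal/mol);
* <V_s>, <V_s+>, <V_s-> — surface mean and the means over the positive and
  negative patches;
* Pi — the mean absolute deviation of V from <V_s>, an internal
  charge-separation measure;
* sigma2_plus / sigma2_minus / sigma2_tot — variances of V over the
  positive and negative patches (each about its own patch mean) and their
  sum;
* nu — the balance parameter sigma2_plus*sigma2_minus/sigma2_tot^2, which
  is at most 1/4, with equality when the two variances are equal.

Averages are area-weighted by default (triangle-area quadrature weights);
``weighting="uniform"`` reproduces the plain point averages of the printed
formulas, which depend on mesh density and are offered for comparison only.
Samples with V == 0 count as positive; this is a measure-zero convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptySurfaceError
from .surface_extract import TriangulatedSurface

__all__ = ["SurfaceDescriptors", "compute_descriptors", "reciprocal_transform"]


@dataclass
class SurfaceDescriptors:
    """The full surface-ESP statistic set for one molecule (kcal/mol units)."""

    vs_max: float
    vs_min: float
    vs_mean: float
    vs_plus_mean: float | None
    vs_minus_mean: float | None
    pi: float
    sigma2_plus: float
    sigma2_minus: float
    sigma2_tot: float
    nu: float
    n_samples: int
    positive_area_fraction: float

    def to_dict(self) -> dict:
        return {
            "vs_max": self.vs_max,
            "vs_min": self.vs_min,
            "vs_mean": self.vs_mean,
            "vs_plus_mean": self.vs_plus_mean,
            "vs_minus_mean": self.vs_minus_mean,
            "pi": self.pi,
            "sigma2_plus": self.sigma2_plus,
            "sigma2_minus": self.sigma2_minus,
            "sigma2_tot": self.sigma2_tot,
            "nu": self.nu,
            "n_samples": self.n_samples,
            "positive_area_fraction": self.positive_area_fraction,
        }


def compute_descriptors(
    surface: TriangulatedSurface, weighting: str = "area"
) -> SurfaceDescriptors:
    """Compute the descriptor set from a potential-bearing surface."""
    if surface.n_samples == 0:
        raise EmptySurfaceError("surface has no samples")
    if surface.sample_potentials is None:
        raise ValueError("surface has no sample_potentials; run sample_potential_on_surface first")
    if weighting not in ("area", "uniform"):
        raise ValueError(f"weighting must be 'area' or 'uniform', got {weighting!r}")

    v = surface.sample_potentials
    w = surface.sample_weights if weighting == "area" else np.ones_like(v)
    wsum = w.sum()

    vs_mean = float((w * v).sum() / wsum)
    pi = float((w * np.abs(v - vs_mean)).sum() / wsum)

    pos = v >= 0.0
    neg = ~pos

    def _patch(mask: np.ndarray) -> tuple[float | None, float]:
        """Patch mean and variance about the patch mean; empty patch -> (None, 0)."""
        if not mask.any():
            return None, 0.0
        ww, vv = w[mask], v[mask]
        m = float((ww * vv).sum() / ww.sum())
        var = float((ww * (vv - m) ** 2).sum() / ww.sum())
        return m, var

    vs_plus_mean, sigma2_plus = _patch(pos)
    vs_minus_mean, sigma2_minus = _patch(neg)
    sigma2_tot = sigma2_plus + sigma2_minus
    nu = 0.0 if sigma2_tot == 0.0 else sigma2_plus * sigma2_minus / sigma2_tot**2

    return SurfaceDescriptors(
        vs_max=float(v.max()),
        vs_min=float(v.min()),
        vs_mean=vs_mean,
        vs_plus_mean=vs_plus_mean,
        vs_minus_mean=vs_minus_mean,
        pi=pi,
        sigma2_plus=sigma2_plus,
        sigma2_minus=sigma2_minus,
        sigma2_tot=sigma2_tot,
        nu=nu,
        n_samples=surface.n_samples,
        positive_area_fraction=float(w[pos].sum() / wsum),
    )


def reciprocal_transform(descriptors: SurfaceDescriptors) -> tuple[float, float]:
    """The (1/V_s,max, 1/V_s,min) pair used as QSAR regressors (mol/kcal)."""
    if descriptors.vs_max == 0 or descriptors.vs_min == 0:
        raise ZeroDivisionError("surface extremum is zero; reciprocal undefined")
    return 1.0 / descriptors.vs_max, 1.0 / descriptors.vs_min
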