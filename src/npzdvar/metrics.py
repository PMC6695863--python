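"""Skill metrics and pigment-unit conversions.

Implements the normalized cost function, MAE, RMSE and the similarity
coefficient used to score assimilated phytoplankton fields against
observations, plus the chlorophyll-a -> carbon -> nitrogen conversion chain
for feeding satellite chlorophyll into a nitrogen-based model.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "MetricBundle",
    "mae",
    "rmse",
    "similarity_coefficient",
    "ncf",
    "chla_to_carbon",
    "carbon_to_nitrogen",
    "bundle_metrics",
]

#: atomic mass of carbon, g mol^-1
CARBON_MOLAR_MASS = 12.011
#: Redfield molar ratio C:N
REDFIELD_C = 106.0
REDFIELD_N = 16.0


@dataclass(frozen=True)
class MetricBundle:
    """Evaluation metrics for one model-vs-observation comparison.

    Attributes
    ----------
    ncf : float
        Final normalized cost function (J_final / J_initial).
    mae : float
        Mean absolute error, mmol N m^-3.
    rmse : float
        Root-mean-square error, mmol N m^-3.
    sc : float
        Similarity coefficient in [0, 1] for non-negative fields.
    m : int
        Number of observed grid points entering the comparison.
    """

    ncf: float
    mae: float
    rmse: float
    sc: float
    m: int

    def to_dict(self) -> dict:
        return asdict(self)


def _as_pair(x_mod, x_obs) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(x_mod, dtype=float).ravel()
    b = np.asarray(x_obs, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("empty comparison vectors")
    return a, b


def mae(x_mod, x_obs) -> float:
    """Mean absolute error over observed grids."""
    a, b = _as_pair(x_mod, x_obs)
    return float(np.mean(np.abs(a - b)))


def rmse(x_mod, x_obs) -> float:
    """Root-mean-square error over observed grids."""
    a, b = _as_pair(x_mod, x_obs)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def similarity_coefficient(x_mod, x_obs) -> float:
    """Similarity coefficient 1 - (2/pi) * angle(x_mod, x_obs).

    Equals 1 for proportional vectors and 0 for orthogonal ones.  The
    cosine is clipped to [-1, 1] before the arccos so rounding can never
    push it out of domain.

    Raises
    ------
    ValueError
        If either vector has zero norm (the angle is undefined).
    """
    a, b = _as_pair(x_mod, x_obs)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("similarity coefficient undefined for a zero-norm vector")
    cosang = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(1.0 - (2.0 / np.pi) * np.arccos(cosang))


def ncf(j_history) -> np.ndarray:
    """Normalize a cost-function history by its first element."""
    j = np.asarray(j_history, dtype=float)
    if j.size == 0:
        raise ValueError("empty cost history")
    if j[0] <= 0.0:
        raise ValueError("initial cost must be positive to normalize")
    return j / j[0]


def chla_to_carbon(chla, rho_max: float = 90.0, k_half: float = 0.477,
                   saturating: bool = False):
    """Convert chlorophyll-a (mg m^-3) to phytoplankton carbon (mg C m^-3).

    Default form: C = rho_max * chl/(chl + k_half) * chl.  With
    ``saturating=True`` the alternative reading C = rho_max * chl/(chl + k_half)
    is used instead.
    """
    c = np.asarray(chla, dtype=float)
    if np.any(c < 0):
        raise ValueError("chlorophyll-a must be non-negative")
    frac = np.where(c + k_half > 0, c / (c + k_half), 0.0)
    out = rho_max * frac if saturating else rho_max * frac * c
    return float(out) if np.isscalar(chla) else out


def carbon_to_nitrogen(carbon):
    """Convert carbon (mg C m^-3) to nitrogen (mmol N m^-3) via Redfield C:N."""
    c = np.asarray(carbon, dtype=float)
    if np.any(c < 0):
        raise ValueError("carbon must be non-negative")
    out = (c / CARBON_MOLAR_MASS) * (REDFIELD_N / REDFIELD_C)
    return float(out) if np.isscalar(carbon) else out


def bundle_metrics(x_mod, x_obs, ncf_final: float = 1.0) -> MetricBundle:
    """Assemble a :class:`MetricBundle` from a model/observation pair."""
    a, b = _as_pair(x_mod, x_obs)
    return MetricBundle(
        ncf=float(ncf_final),
        mae=mae(a, b),
        rmse=rmse(a, b),
        sc=similarity_coefficient(a, b),
        m=int(a.size),
    )
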