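"""Reference-free topographic primitives.

Scalp potential maps are only defined up to an additive constant (the
recording reference).  Every topographic quantity used downstream —
global field power (GFP), spatial correlation between maps, template
normalization — is therefore computed on average-referenced data, which
makes it invariant to the original reference choice.

Conventions
-----------
* A *map* is a vector of channel potentials at one time sample (µV).
* GFP is the spatial standard deviation of the map with the population
  (1/N) normalization: ``GFP(u) = sqrt(mean((u - mean(u))**2))``.
* Spatial correlation is the Pearson correlation across channels of two
  average-referenced maps.  It is polarity-sensitive: evoked responses
  have a meaningful, latency-locked polarity, so a map and its inverse
  correlate at −1, not +1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Montage",
    "EvokedERP",
    "TemplateMap",
    "ZeroFieldError",
    "average_reference",
    "gfp",
    "spatial_correlation",
    "normalize_map",
]

LANGUAGES = ("L1", "L2")
EMBODIMENT = ("motor", "non-motor")

#: GFP below this value (µV) is treated as a zero field.
ZERO_GFP_TOL = 1e-12


class ZeroFieldError(ValueError):
    """A map with (numerically) zero GFP was used where a non-degenerate
    topography is required."""


@dataclass(frozen=True)
class Montage:
    """An ordered electrode layout on the unit sphere.

    Parameters
    ----------
    labels : tuple of str
        Unique channel names, in data row order.
    positions : ndarray, shape (n_channels, 3)
        Unit-norm 3D electrode positions.
    """

    labels: tuple[str, ...]
    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        if pos.ndim != 2 or pos.shape != (len(self.labels), 3):
            raise ValueError(
                f"positions must be ({len(self.labels)}, 3), got {pos.shape}"
            )
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("montage positions must have unit norm (within 1e-6)")

    @property
    def n_channels(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class EvokedERP:
    """A single-subject (or grand-average) evoked response in one condition.

    ``data`` is channels × samples in µV.  ``t0_ms`` is the epoch origin
    relative to stimulus onset (negative = pre-stimulus interval present).
    """

    data: np.ndarray
    sfreq: float
    t0_ms: float
    subject_id: str
    language: str
    embodiment: str
    is_avg_ref: bool = False
    montage: Montage | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValueError("ERP data must be 2-D (channels × samples)")
        if not np.all(np.isfinite(data)):
            raise ValueError("ERP data contains non-finite values")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if self.language not in LANGUAGES:
            raise ValueError(f"language must be one of {LANGUAGES}")
        if self.embodiment not in EMBODIMENT:
            raise ValueError(f"embodiment must be one of {EMBODIMENT}")
        if self.is_avg_ref:
            colsums = data.sum(axis=0)
            if np.any(np.abs(colsums) > 1e-9 * data.shape[0]):
                raise ValueError("is_avg_ref set but columns do not sum to zero")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        return self.t0_ms + np.arange(self.n_samples) * 1000.0 / self.sfreq

    @property
    def cell(self) -> tuple[str, str]:
        """The (language, embodiment) design cell this ERP belongs to."""
        return (self.language, self.embodiment)


@dataclass(frozen=True)
class TemplateMap:
    """A microstate class topography: zero-mean, unit-GFP channel vector."""

    map_id: int
    vector: np.ndarray

    def __post_init__(self) -> None:
        vec = np.asarray(self.vector, dtype=float)
        object.__setattr__(self, "vector", vec)
        if vec.ndim != 1:
            raise ValueError("template vector must be 1-D")
        if abs(vec.mean()) > 1e-9:
            raise ValueError("template map must have zero channel mean")
        if abs(gfp(vec) - 1.0) > 1e-9:
            raise ValueError("template map must have unit GFP")


def average_reference(erp: EvokedERP) -> EvokedERP:
    """Re-reference to the average reference (zero channel mean per sample).

    Idempotent; topographic measures computed downstream are thereby
    independent of the original recording reference.
    """
    if erp.is_avg_ref:
        return erp
    data = erp.data - erp.data.mean(axis=0, keepdims=True)
    return replace(erp, data=data, is_avg_ref=True)


def _as_2d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[:, None] if x.ndim == 1 else x


def gfp(map_or_series: np.ndarray) -> float | np.ndarray:
    """Global field power: spatial standard deviation of the field.

    Accepts a single map (1-D) or a channels × samples matrix; returns a
    scalar or a per-sample series.  Average reference is applied
    internally, so the result is reference-free.  Uses the population
    (1/N) normalization.
    """
    arr = np.asarray(map_or_series, dtype=float)
    one_d = arr.ndim == 1
    x = _as_2d(arr)
    if x.shape[0] < 2:
        raise ValueError("GFP is undefined for fewer than 2 channels")
    centered = x - x.mean(axis=0, keepdims=True)
    out = np.sqrt(np.mean(centered**2, axis=0))
    return float(out[0]) if one_d else out


def spatial_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Strength-independent spatial correlation between two maps.

    Pearson correlation across channels of the average-referenced maps;
    invariant to positive rescaling of either operand, sign-preserving
    under polarity inversion.  Raises :class:`ZeroFieldError` for a
    zero-GFP operand.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("maps must share the montage (same length)")
    uc = u - u.mean()
    vc = v - v.mean()
    nu = np.linalg.norm(uc)
    nv = np.linalg.norm(vc)
    n = u.size
    if nu <= ZERO_GFP_TOL * np.sqrt(n) or nv <= ZERO_GFP_TOL * np.sqrt(n):
        raise ZeroFieldError("spatial correlation undefined for a zero-GFP map")
    return float(np.clip(uc @ vc / (nu * nv), -1.0, 1.0))


def normalize_map(u: np.ndarray, map_id: int = 0) -> TemplateMap:
    """Normalize a map to zero mean and unit GFP.

    The output correlates at exactly +1 with the input, so normalization
    discards strength and polarity-preserving scale only.
    """
    u = np.asarray(u, dtype=float)
    centered = u - u.mean()
    strength = gfp(u)
    if strength <= ZERO_GFP_TOL:
        raise ZeroFieldError("cannot normalize a zero-GFP map")
    return TemplateMap(map_id=map_id, vector=centered / strength)
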