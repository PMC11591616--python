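"""Synthetic multi-subject 2×2 ERP datasets with planted microstate structure.

The generator emulates the layout of an evoked word-processing study:
each of ``n_subjects`` subjects contributes one evoked ERP per cell of a
2×2 within-subject design (language L1/L2 × embodiment motor/non-motor),
recorded on an ``n_channels`` montage at ``sfreq`` Hz over a −100…+700 ms
epoch.  The signal is a sequence of planted template topographies, each
occupying a fixed time window with a smooth (raised-cosine) GFP envelope,
scaled per design cell by known effect multipliers and per subject by a
correlated log-normal random effect, plus additive sensor noise.  Ground
truth (templates, windows, multipliers, per-subject effects) is returned
alongside the data so that segmentation, back-fitting and the ANOVA can
be validated end-to-end.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .topography import (
    EMBODIMENT,
    LANGUAGES,
    EvokedERP,
    Montage,
    TemplateMap,
    normalize_map,
)

__all__ = [
    "TimelineEntry",
    "GroundTruthTimeline",
    "SynthConfig",
    "SynthDataset",
    "CELLS",
    "make_montage",
    "make_templates",
    "default_timeline",
    "default_multipliers",
    "simulate_subject_erp",
    "simulate_dataset",
]

#: The four design cells, in canonical order.
CELLS: tuple[tuple[str, str], ...] = tuple(
    (lang, emb) for lang in LANGUAGES for emb in EMBODIMENT
)


@dataclass(frozen=True)
class TimelineEntry:
    """One planted microstate: which template occupies which window.

    ``amplitude_uv`` is the peak GFP (µV) of the raised-cosine envelope
    inside the window, before condition and subject scaling.
    """

    map_id: int
    t_start_ms: float
    t_end_ms: float
    amplitude_uv: float


@dataclass(frozen=True)
class GroundTruthTimeline:
    entries: tuple[TimelineEntry, ...]
    templates: tuple[TemplateMap, ...]

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "templates", tuple(self.templates))
        ids = {t.map_id for t in self.templates}
        prev_end = -np.inf
        for e in entries:
            if e.t_end_ms <= e.t_start_ms:
                raise ValueError(f"empty window for map {e.map_id}")
            if e.t_start_ms < prev_end:
                raise ValueError("timeline windows must be ordered and disjoint")
            prev_end = e.t_end_ms
            if e.map_id not in ids:
                raise ValueError(f"no template for map_id {e.map_id}")
            if e.amplitude_uv <= 0:
                raise ValueError("envelope amplitude must be positive")

    @property
    def map_ids(self) -> tuple[int, ...]:
        return tuple(e.map_id for e in self.entries)

    def template_for(self, map_id: int) -> TemplateMap:
        for t in self.templates:
            if t.map_id == map_id:
                return t
        raise KeyError(map_id)


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters for the generator.

    Defaults reproduce the emulated study: 29 subjects, 128 channels,
    1024 Hz, −100…+700 ms epochs, between-cell correlation of the
    subject random effect ρ = 0.5.
    """

    seed: int = 0
    n_subjects: int = 29
    n_channels: int = 128
    sfreq: float = 1024.0
    epoch_ms: tuple[float, float] = (-100.0, 700.0)
    effect_multipliers: dict[tuple[int, tuple[str, str]], float] | None = None
    subject_sd: float = 0.2
    rho: float = 0.5
    noise_sd: float = 1.0
    noise_spatial_smooth: float = 0.0  # radians; 0 = spatially white

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be ≥ 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be ≥ 0")
        if self.effect_multipliers is not None:
            for (mid, cell), mult in self.effect_multipliers.items():
                if mult <= 0:
                    raise ValueError(f"multiplier for ({mid}, {cell}) must be > 0")
                if cell not in CELLS:
                    raise ValueError(f"unknown design cell {cell!r}")


def make_montage(n_channels: int, seed: int = 0) -> Montage:
    """Quasi-uniform electrode positions on the upper hemisphere.

    A Fibonacci lattice on the upper unit hemisphere, rotated about the
    vertical axis by a seed-dependent angle.  Deterministic for a given
    (n_channels, seed).
    """
    if n_channels < 8:
        raise ValueError("a montage needs at least 8 channels")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n_channels)
    # z in (0, 1]: upper hemisphere only, avoiding exact equator duplicates
    z = 1.0 - i / n_channels
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    theta = golden * i + phase
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    labels = tuple(f"E{j + 1:03d}" for j in range(n_channels))
    return Montage(labels=labels, positions=pos)


def _dipole_field(positions: np.ndarray, loc: np.ndarray, moment: np.ndarray) -> np.ndarray:
    """Potential of a current dipole at the electrode positions.

    Infinite-homogeneous-medium approximation: V(r) ∝ q·(r−p)/|r−p|³.
    Adequate as a smooth, physiologically-shaped spatial basis; no claim
    of forward-model realism.
    """
    d = positions - loc[None, :]
    dist = np.linalg.norm(d, axis=1)
    return d @ moment / dist**3


def make_templates(
    montage: Montage,
    k: int,
    seed: int = 0,
    min_separation: float = 0.5,
    max_tries: int = 200,
) -> tuple[TemplateMap, ...]:
    """Generate ``k`` smooth, mutually separated template topographies.

    Each template is the average-referenced, GFP-normalized field of 1–3
    random dipoles inside the head sphere.  Templates are accepted only
    if the absolute spatial correlation with every previously accepted
    template is at most ``min_separation``; after ``max_tries`` failed
    draws per slot a ``RuntimeError`` is raised.
    """
    if k < 1:
        raise ValueError("k must be ≥ 1")
    if not (-1 < min_separation < 1):
        raise ValueError("min_separation must be in (−1, 1)")
    rng = np.random.default_rng(seed)
    from .topography import spatial_correlation

    accepted: list[TemplateMap] = []
    for map_id in range(k):
        for _ in range(max_tries):
            n_dip = int(rng.integers(1, 4))
            field_vec = np.zeros(montage.n_channels)
            for _ in range(n_dip):
                loc = rng.normal(size=3)
                loc = 0.6 * loc / np.linalg.norm(loc)
                loc[2] = abs(loc[2]) * 0.7  # keep sources in the upper head
                moment = rng.normal(size=3)
                field_vec += _dipole_field(montage.positions, loc, moment)
            cand = normalize_map(field_vec, map_id=map_id)
            if all(
                abs(spatial_correlation(cand.vector, t.vector)) <= min_separation
                for t in accepted
            ):
                accepted.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place template {map_id} with pairwise "
                f"|correlation| ≤ {min_separation} after {max_tries} tries"
            )
    return tuple(accepted)


#: Planted component windows (ms) and peak GFP amplitudes (µV):
#: P1-like 100–150, N1-like 150–300, P2-like 300–400, N400-like 400–500.
DEFAULT_WINDOWS: tuple[tuple[int, float, float, float], ...] = (
    (0, 100.0, 150.0, 3.0),
    (1, 150.0, 300.0, 4.0),
    (2, 300.0, 400.0, 3.0),
    (3, 400.0, 500.0, 2.5),
)


def default_timeline(montage: Montage, seed: int = 0) -> GroundTruthTimeline:
    """The default planted timeline: four components at the windows above."""
    templates = make_templates(montage, k=4, seed=seed)
    entries = tuple(TimelineEntry(*w) for w in DEFAULT_WINDOWS)
    return GroundTruthTimeline(entries=entries, templates=templates)


def default_multipliers() -> dict[tuple[int, tuple[str, str]], float]:
    """Default condition effects on component strength.

    The pattern plants: an N1-window (map 1) main effect of embodiment
    (motor 1.3× stronger); language main effects (L2 stronger) on the
    P1 (map 0), P2 (map 2) and N400 (map 3) windows; and a P1
    language × embodiment interaction (strongest in L2 non-motor).
    Absent (map, cell) keys default to 1.0.
    """
    return {
        (0, ("L2", "motor")): 1.2,
        (0, ("L2", "non-motor")): 1.4,
        (1, ("L1", "motor")): 1.3,
        (1, ("L2", "motor")): 1.3,
        (2, ("L2", "motor")): 1.2,
        (2, ("L2", "non-motor")): 1.2,
        (3, ("L2", "motor")): 1.3,
        (3, ("L2", "non-motor")): 1.3,
    }


def _subject_rng_key(seed: int, subject_id: str) -> list[int]:
    return [seed & 0x7FFFFFFF, zlib.crc32(subject_id.encode()) & 0x7FFFFFFF]


def subject_effects(
    cfg: SynthConfig, timeline: GroundTruthTimeline, subject_id: str
) -> dict[tuple[int, tuple[str, str]], float]:
    """Multiplicative subject random effect per (map, design cell).

    Per map, a 4-vector of standard normals with equicorrelation ``rho``
    (Gaussian copula) is transformed to a mean-one log-normal; the same
    subject therefore expresses correlated strengths across the four
    cells.  Deterministic in (cfg.seed, subject_id).
    """
    rng = np.random.default_rng(_subject_rng_key(cfg.seed, subject_id))
    sd = cfg.subject_sd
    if sd == 0:
        return {(mid, cell): 1.0 for mid in timeline.map_ids for cell in CELLS}
    sigma = np.sqrt(np.log1p(sd**2))
    rho = cfg.rho
    cov = np.full((4, 4), rho) + (1 - rho) * np.eye(4)
    chol = np.linalg.cholesky(cov)
    out: dict[tuple[int, tuple[str, str]], float] = {}
    for mid in timeline.map_ids:
        z = chol @ rng.standard_normal(4)
        effects = np.exp(sigma * z - sigma**2 / 2)
        for cell, eff in zip(CELLS, effects):
            out[(mid, cell)] = float(eff)
    return out


def _envelope(times_ms: np.ndarray, entry: TimelineEntry) -> np.ndarray:
    """Raised-cosine (half-cosine ramp up/down) GFP envelope in the window."""
    x = (times_ms - entry.t_start_ms) / (entry.t_end_ms - entry.t_start_ms)
    env = np.where((x > 0) & (x < 1), np.sin(np.pi * np.clip(x, 0, 1)) ** 2, 0.0)
    return entry.amplitude_uv * env


def _noise_mixing(montage: Montage, smooth: float) -> np.ndarray | None:
    if smooth <= 0:
        return None
    cosang = np.clip(montage.positions @ montage.positions.T, -1.0, 1.0)
    ang = np.arccos(cosang)
    kernel = np.exp(-(ang**2) / (2 * smooth**2))
    # normalize rows so per-channel noise variance stays ≈ noise_sd²
    kernel /= np.linalg.norm(kernel, axis=1, keepdims=True)
    return kernel


def simulate_subject_erp(
    cfg: SynthConfig,
    timeline: GroundTruthTimeline,
    subject_id: str,
    cell: tuple[str, str],
    montage: Montage | None = None,
) -> EvokedERP:
    """Simulate one subject's evoked ERP in one design cell.

    data = Σ_windows template × envelope × condition multiplier × subject
    effect + sensor noise, then baseline-corrected against the
    pre-stimulus interval.  The pre-stimulus interval carries noise only.
    """
    if cell not in CELLS:
        raise ValueError(f"unknown design cell {cell!r}")
    multipliers = cfg.effect_multipliers or {}
    valid_ids = set(timeline.map_ids)
    for mid, _ in multipliers:
        if mid not in valid_ids:
            raise ValueError(f"effect multiplier refers to unknown map_id {mid}")

    montage = montage or make_montage(cfg.n_channels, seed=cfg.seed)
    t0, t1 = cfg.epoch_ms
    n_samples = int(round((t1 - t0) / 1000.0 * cfg.sfreq))
    times = t0 + np.arange(n_samples) * 1000.0 / cfg.sfreq

    effects = subject_effects(cfg, timeline, subject_id)
    data = np.zeros((montage.n_channels, n_samples))
    for entry in timeline.entries:
        mult = multipliers.get((entry.map_id, cell), 1.0)
        env = _envelope(times, entry)
        if not env.any():
            continue
        scale = env * mult * effects[(entry.map_id, cell)]
        data += timeline.template_for(entry.map_id).vector[:, None] * scale[None, :]

    if cfg.noise_sd > 0:
        key = _subject_rng_key(cfg.seed, subject_id) + [CELLS.index(cell) + 1]
        noise_rng = np.random.default_rng(key)
        noise = noise_rng.normal(0.0, cfg.noise_sd, size=data.shape)
        mix = _noise_mixing(montage, cfg.noise_spatial_smooth)
        if mix is not None:
            noise = mix @ noise
        data += noise

    baseline = times < 0
    if baseline.any():
        data -= data[:, baseline].mean(axis=1, keepdims=True)

    return EvokedERP(
        data=data,
        sfreq=cfg.sfreq,
        t0_ms=t0,
        subject_id=subject_id,
        language=cell[0],
        embodiment=cell[1],
        montage=montage,
    )


@dataclass(frozen=True)
class SynthDataset:
    """A complete simulated 2×2 dataset with its ground truth."""

    erps: tuple[EvokedERP, ...]
    timeline: GroundTruthTimeline
    montage: Montage
    config: SynthConfig
    multipliers: dict[tuple[int, tuple[str, str]], float] = field(default_factory=dict)
    subject_effects: dict[str, dict[tuple[int, tuple[str, str]], float]] = field(
        default_factory=dict
    )

    @property
    def subject_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for e in self.erps:
            seen.setdefault(e.subject_id, None)
        return tuple(seen)

    def erp(self, subject_id: str, cell: tuple[str, str]) -> EvokedERP:
        for e in self.erps:
            if e.subject_id == subject_id and e.cell == cell:
                return e
        raise KeyError((subject_id, cell))


def simulate_dataset(
    cfg: SynthConfig, timeline: GroundTruthTimeline | None = None
) -> SynthDataset:
    """Simulate the full crossed design: n_subjects × 4 cells evoked ERPs.

    If ``timeline`` is None the default four-component timeline is
    planted with templates generated from ``cfg.seed``, and the default
    condition multipliers are applied unless ``cfg.effect_multipliers``
    says otherwise.  Reproducible bit-for-bit from ``cfg.seed``.
    """
    montage = make_montage(cfg.n_channels, seed=cfg.seed)
    if timeline is None:
        timeline = default_timeline(montage, seed=cfg.seed)
    if cfg.effect_multipliers is None:
        cfg = SynthConfig(
            **{**cfg.__dict__, "effect_multipliers": default_multipliers()}
        )
    subjects = tuple(f"S{i + 1:03d}" for i in range(cfg.n_subjects))
    erps = tuple(
        simulate_subject_erp(cfg, timeline, sid, cell, montage=montage)
        for sid in subjects
        for cell in CELLS
    )
    return SynthDataset(
        erps=erps,
        timeline=timeline,
        montage=montage,
        config=cfg,
        multipliers=dict(cfg.effect_multipliers or {}),
        subject_effects={sid: subject_effects(cfg, timeline, sid) for sid in subjects},
    )
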