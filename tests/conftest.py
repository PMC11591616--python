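"""Shared fixtures: small montages, planted grand averages, scaled datasets.

Monte-Carlo fixtures use a reduced montage (32–64 channels) and sampling
rate (128–256 Hz) so the suite stays fast; the study-design parameters
(29 subjects, ρ = 0.5, default effect multipliers) stay at their
defaults.
"""

from __future__ import annotations

import numpy as np
import pytest

import topomicro as tm
from topomicro.topography import EvokedERP

CELLS = [("L1", "motor"), ("L1", "non-motor"), ("L2", "motor"), ("L2", "non-motor")]


def orthogonal_templates(n_channels: int, k: int, seed: int = 0):
    """Exactly orthogonal zero-mean unit-GFP maps (Gram–Schmidt)."""
    rng = np.random.default_rng(seed)
    vecs = []
    while len(vecs) < k:
        v = rng.normal(size=n_channels)
        v -= v.mean()
        for u in vecs:
            v -= (v @ u) / (u @ u) * u
        v -= v.mean()
        if np.linalg.norm(v) > 1e-8:
            vecs.append(v)
    return tuple(tm.normalize_map(v, map_id=i) for i, v in enumerate(vecs))


def tiled_grand_averages(
    templates,
    n_samples_per_block: int = 45,
    sfreq: float = 256.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    amplitude: float = 2.0,
):
    """Four identical grand averages tiling the templates in time blocks."""
    rng = np.random.default_rng(seed)
    k = len(templates)
    n = k * n_samples_per_block
    n_ch = templates[0].vector.size
    base = np.zeros((n_ch, n))
    truth = np.empty(n, dtype=int)
    for i, tmpl in enumerate(templates):
        sl = slice(i * n_samples_per_block, (i + 1) * n_samples_per_block)
        amp = amplitude + 0.5 * np.sin(np.linspace(0.1, np.pi - 0.1, n_samples_per_block))
        base[:, sl] = tmpl.vector[:, None] * amp[None, :]
        truth[sl] = i
    gas = []
    for lang, emb in CELLS:
        data = base + (rng.normal(0, noise_sd, base.shape) if noise_sd else 0.0)
        gas.append(
            EvokedERP(
                data=data,
                sfreq=sfreq,
                t0_ms=0.0,
                subject_id="grand-average",
                language=lang,
                embodiment=emb,
            )
        )
    return gas, truth


def planted_toy_instance(seed: int, k: int, n_frames: int = 12, n_channels: int = 6,
                         noise_sd: float = 0.5, max_corr: float = 0.3):
    """A small clustering instance: k separated random maps cycled over
    n_frames with varying strength plus channel noise."""
    rng = np.random.default_rng(seed)
    maps = []
    while len(maps) < k:
        v = rng.normal(size=n_channels)
        v -= v.mean()
        v /= np.linalg.norm(v)
        if all(abs(v @ u) <= max_corr for u in maps):
            maps.append(v)
    data = np.zeros((n_channels, n_frames))
    for t in range(n_frames):
        amp = rng.uniform(0.8, 2.0)
        data[:, t] = amp * np.sqrt(n_channels) * maps[t % k]
        data[:, t] += rng.normal(0, noise_sd, n_channels)
    return data


def exhaustive_best_gev(frames, k: int) -> float:
    """Best total GEV over every partition of the frames into k blocks
    (independent brute-force oracle)."""
    def partitions(items, kk):
        if kk == 1:
            yield [list(items)]
            return
        if len(items) == kk:
            yield [[x] for x in items]
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest, kk - 1):
            yield [[first]] + part
        for part in partitions(rest, kk):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1 :]

    best = 0.0
    for part in partitions(list(range(frames.n_frames)), k):
        total = 0.0
        for block in part:
            c = frames.unit[:, block].sum(axis=1)
            nc = np.linalg.norm(c)
            if nc == 0:
                continue
            total += float(
                np.sum((frames.gfp[block] * ((c / nc) @ frames.unit[:, block])) ** 2)
            )
        best = max(best, total / frames.gfp2_total)
    return best


@pytest.fixture(scope="session")
def scaled_dataset():
    """Default-design synthetic dataset at reduced spatial/temporal scale."""
    cfg = tm.SynthConfig(seed=11, n_channels=64, sfreq=256.0)
    return tm.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def scaled_analysis(scaled_dataset):
    """Full pipeline result on the scaled dataset (computed once)."""
    return tm.run_full_analysis(list(scaled_dataset.erps))
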