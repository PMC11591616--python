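"""Winner-take-all back-fitting and repeated-measures statistics.

Back-fitting projects the group-level template maps onto each subject's
condition ERP: every post-stimulus sample is assigned to the template
with the highest signed spatial correlation, and per map the global
explained variance (GEV), mean field strength (GFP) and total duration
are extracted.  These per-subject measures then enter one 2×2
repeated-measures ANOVA per map × measure, with factors language
(L1/L2) and embodiment (motor/non-motor), F tested against the
effect-by-subject interaction with (1, n−1) degrees of freedom.

The module also provides the a-priori power calculator for
within-factors repeated-measures ANOVA based on the noncentral F
distribution with noncentrality λ = f²·n·m·ε/(1−ρ).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .preprocess import grand_average
from .segmentation import (
    SegmentationParams,
    SegmentationResult,
    compute_gev,
    segment_grand_averages,
)
from .topography import EvokedERP, TemplateMap, average_reference

__all__ = [
    "PowerSpec",
    "backfit_subject",
    "backfit_dataset",
    "rm_anova_2x2",
    "rm_anova_power",
    "rm_anova_power_n",
    "run_full_analysis",
    "FullAnalysisResult",
    "MEASURES",
]

logger = logging.getLogger(__name__)

MEASURES = ("gev", "mean_gfp", "duration_ms")


def backfit_subject(
    erp: EvokedERP,
    templates: tuple[TemplateMap, ...] | list[TemplateMap],
    analysis_window_ms: tuple[float, float] = (0.0, 700.0),
    windows: dict[int, list[tuple[float, float]]] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Winner-take-all fit of the templates to one subject-condition ERP.

    Every sample in the analysis window is labeled with the template of
    maximal signed spatial correlation (ties → lower map_id).  If
    ``windows`` is given (``fit_scope = grand_average_windows``), each
    sample is instead assigned to the map whose grand-average window
    covers it, and samples outside all windows stay unlabeled.

    Returns the per-window-sample labels (−1 for zero-GFP or uncovered
    samples) and a tidy table with one row per map: gev, mean_gfp (µV),
    duration_ms.  Maps that win no sample score 0 on all three.
    """
    erp = average_reference(erp)
    t = erp.times_ms
    lo, hi = analysis_window_ms
    sel = (t >= lo) & (t < hi)
    if not sel.any():
        raise ValueError("analysis window contains no samples")
    data = erp.data[:, sel]
    centered = data - data.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    gfp_series = norms / np.sqrt(data.shape[0])
    keep = gfp_series > 1e-12
    n_skipped = int((~keep).sum())
    if n_skipped:
        logger.info("skipped %d zero-GFP samples in back-fitting", n_skipped)

    labels = np.full(data.shape[1], -1, dtype=int)
    if windows is None:
        tmat = np.stack([tm.vector for tm in templates]) / np.sqrt(data.shape[0])
        unit = np.zeros_like(centered)
        unit[:, keep] = centered[:, keep] / norms[keep]
        corr = tmat @ unit[:, keep]
        labels[keep] = np.argmax(corr, axis=0)  # argmax ties → lowest map_id
    else:
        tw = t[sel]
        for tm in templates:
            for a, b in windows.get(tm.map_id, []):
                labels[(tw >= a) & (tw < b) & keep] = tm.map_id

    gev_per_map, _ = compute_gev(data, templates, labels)
    rows = []
    for m, tm in enumerate(templates):
        won = labels == m
        rows.append(
            {
                "subject_id": erp.subject_id,
                "language": erp.language,
                "embodiment": erp.embodiment,
                "map_id": tm.map_id,
                "gev": float(gev_per_map[m]),
                "mean_gfp": float(gfp_series[won].mean()) if won.any() else 0.0,
                "duration_ms": float(won.sum() * 1000.0 / erp.sfreq),
            }
        )
    return labels, pd.DataFrame(rows)


def backfit_dataset(
    erps: list[EvokedERP],
    segmentation: SegmentationResult,
    analysis_window_ms: tuple[float, float] = (0.0, 700.0),
    fit_scope: str = "epoch",
) -> pd.DataFrame:
    """Back-fit every subject × condition ERP against the group templates.

    ``fit_scope='epoch'`` (default) lets all templates compete over the
    whole analysis window; ``'grand_average_windows'`` restricts each
    map to the time windows it occupies in that condition's
    grand-average segmentation.
    """
    if fit_scope not in ("epoch", "grand_average_windows"):
        raise ValueError(f"unknown fit_scope {fit_scope!r}")
    tables = []
    for erp in erps:
        windows = (
            segmentation.map_windows.get(erp.cell)
            if fit_scope == "grand_average_windows"
            else None
        )
        _, table = backfit_subject(
            erp, segmentation.templates, analysis_window_ms, windows=windows
        )
        tables.append(table)
    return pd.concat(tables, ignore_index=True)


def rm_anova_2x2(cell_values: pd.DataFrame, measure: str = "value") -> pd.DataFrame:
    """2×2 within-subject ANOVA by the classical sum-of-squares split.

    ``cell_values`` needs columns subject_id, language, embodiment and
    the measure column, one value per subject per cell.  Each effect
    (language, embodiment, interaction) is tested against its own
    effect-by-subject interaction: F = MS_effect / MS_{effect×subject},
    df = (1, n−1).  Both partial η² (SS_eff / (SS_eff + SS_err)) and
    generalized η² (SS_eff / (SS_eff + all subject-related SS)) are
    reported.  Zero error variance yields F = +inf, p = 0, flagged
    degenerate.
    """
    pivot = cell_values.pivot_table(
        index="subject_id", columns=["language", "embodiment"], values=measure
    )
    if pivot.isna().any().any():
        missing = pivot[pivot.isna().any(axis=1)].index.tolist()
        raise ValueError(f"incomplete design: missing cells for subjects {missing}")
    if pivot.shape[1] != 4:
        raise ValueError("expected exactly 4 design cells")
    n = pivot.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    Y = np.stack(
        [
            pivot[("L1", "motor")].to_numpy(),
            pivot[("L1", "non-motor")].to_numpy(),
            pivot[("L2", "motor")].to_numpy(),
            pivot[("L2", "non-motor")].to_numpy(),
        ],
        axis=1,
    ).reshape(n, 2, 2)  # subject × language × embodiment

    gm = Y.mean()
    subj = Y.mean(axis=(1, 2))
    a_means = Y.mean(axis=(0, 2))  # language
    b_means = Y.mean(axis=(0, 1))  # embodiment
    ab_means = Y.mean(axis=0)
    as_means = Y.mean(axis=2)  # subject × language
    bs_means = Y.mean(axis=1)  # subject × embodiment

    ss_subj = 4 * np.sum((subj - gm) ** 2)
    ss_a = 2 * n * np.sum((a_means - gm) ** 2)
    ss_b = 2 * n * np.sum((b_means - gm) ** 2)
    ss_ab = n * np.sum((ab_means - a_means[:, None] - b_means[None, :] + gm) ** 2)
    ss_as = 2 * np.sum((as_means - subj[:, None] - a_means[None, :] + gm) ** 2)
    ss_bs = 2 * np.sum((bs_means - subj[:, None] - b_means[None, :] + gm) ** 2)
    resid = (
        Y
        - as_means[:, :, None]
        - bs_means[:, None, :]
        - ab_means[None, :, :]
        + subj[:, None, None]
        + a_means[None, :, None]
        + b_means[None, None, :]
        - gm
    )
    ss_abs = np.sum(resid**2)

    subj_related = ss_subj + ss_as + ss_bs + ss_abs
    df2 = n - 1
    # numerically-zero sums of squares (identical cells up to rounding)
    ss_tol = 1e-12 * max(float(np.sum((Y - gm) ** 2)), 1.0)
    rows = []
    for effect, ss_eff, ss_err in (
        ("language", ss_a, ss_as),
        ("embodiment", ss_b, ss_bs),
        ("interaction", ss_ab, ss_abs),
    ):
        ss_eff = 0.0 if ss_eff < ss_tol else ss_eff
        ms_eff = ss_eff / 1
        ms_err = ss_err / df2
        degenerate = ss_err < ss_tol
        if degenerate:
            f_val = np.inf if ms_eff > 0 else 0.0
            p = 0.0 if ms_eff > 0 else 1.0
        else:
            f_val = ms_eff / ms_err
            p = float(sstats.f.sf(f_val, 1, df2))
        eta_p = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        eta_g = ss_eff / (ss_eff + subj_related) if (ss_eff + subj_related) > 0 else 0.0
        rows.append(
            {
                "effect": effect,
                "F": float(f_val),
                "df1": 1,
                "df2": df2,
                "p": p,
                "eta2_partial": float(eta_p),
                "eta2_generalized": float(eta_g),
                "degenerate": bool(degenerate),
            }
        )
    return pd.DataFrame(rows)


def anova_all_maps(records: pd.DataFrame) -> pd.DataFrame:
    """One 2×2 RM-ANOVA per map × measure over the back-fit records."""
    out = []
    for map_id, g in records.groupby("map_id"):
        for measure in MEASURES:
            table = rm_anova_2x2(g, measure=measure)
            table.insert(0, "map_id", map_id)
            table.insert(1, "measure", measure)
            out.append(table)
    return pd.concat(out, ignore_index=True)


@dataclass(frozen=True)
class PowerSpec:
    """Within-factors repeated-measures ANOVA power parameters."""

    alpha: float = 0.05
    f: float = 0.25
    power_target: float = 0.8
    rho: float = 0.5
    epsilon: float = 1.0
    n_groups: int = 1
    n_measurements: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.f <= 0:
            raise ValueError("effect size f must be > 0")
        if not (0 < self.power_target < 1):
            raise ValueError("power_target must be in (0, 1)")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if not (0 < self.epsilon <= 1):
            raise ValueError("epsilon must be in (0, 1]")
        if self.n_groups != 1:
            raise ValueError("only the one-group within design is supported")


def rm_anova_power(spec: PowerSpec, n: int) -> float:
    """Power of the within-factors F test at total sample size n.

    Noncentral F with λ = f²·n·m·ε/(1−ρ), df1 = (m−1)·ε and
    df2 = (n−1)·(m−1)·ε, where m is the number of repeated measurements.
    """
    m = spec.n_measurements
    lam = spec.f**2 * n * m * spec.epsilon / (1.0 - spec.rho)
    df1 = (m - 1) * spec.epsilon
    df2 = (n - 1) * (m - 1) * spec.epsilon
    crit = sstats.f.ppf(1.0 - spec.alpha, df1, df2)
    return float(sstats.ncf.sf(crit, df1, df2, lam))


def rm_anova_power_n(spec: PowerSpec, n_cap: int = 10_000) -> tuple[int, float]:
    """Smallest total n whose power reaches the target; (n, achieved power)."""
    for n in range(3, n_cap + 1):
        pw = rm_anova_power(spec, n)
        if pw >= spec.power_target:
            return n, pw
    raise RuntimeError(f"power target not reached below n = {n_cap}")


@dataclass(frozen=True)
class FullAnalysisResult:
    grand_averages: list[EvokedERP]
    segmentation: SegmentationResult
    backfit: pd.DataFrame
    anova: pd.DataFrame


def run_full_analysis(
    erps: list[EvokedERP],
    seg_params: SegmentationParams | None = None,
    fit_scope: str = "epoch",
) -> FullAnalysisResult:
    """Grand averages → segmentation → back-fitting → per-map ANOVAs.

    ``erps`` must form a complete subject × (language × embodiment)
    design at the evoked level.  Deterministic for fixed input.
    """
    seg_params = seg_params or SegmentationParams()
    cells: dict[tuple[str, str], list[EvokedERP]] = {}
    for erp in erps:
        cells.setdefault(erp.cell, []).append(average_reference(erp))
    if len(cells) != 4:
        raise ValueError(f"expected 4 design cells, got {sorted(cells)}")
    n_by_cell = {c: len(v) for c, v in cells.items()}
    if len(set(n_by_cell.values())) != 1:
        raise ValueError(f"unbalanced design: {n_by_cell}")
    gas = [grand_average(cells[c]) for c in sorted(cells)]
    segmentation = segment_grand_averages(gas, seg_params)
    backfit = backfit_dataset(
        [e for c in sorted(cells) for e in cells[c]],
        segmentation,
        analysis_window_ms=seg_params.analysis_window_ms,
        fit_scope=fit_scope,
    )
    anova = anova_all_maps(backfit)
    return FullAnalysisResult(
        grand_averages=gas, segmentation=segmentation, backfit=backfit, anova=anova
    )
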