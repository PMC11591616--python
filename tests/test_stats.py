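"""Back-fitting, repeated-measures ANOVA and the power calculator."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats as sstats

import topomicro as tm
from topomicro.stats import (
    MEASURES,
    PowerSpec,
    anova_all_maps,
    backfit_subject,
    rm_anova_2x2,
    rm_anova_power,
    rm_anova_power_n,
)
from topomicro.topography import EvokedERP

from conftest import CELLS, orthogonal_templates


def _erp_from_sequence(templates, block=40, amp=2.0, noise_sd=0.0, seed=0, sfreq=256.0):
    rng = np.random.default_rng(seed)
    k = len(templates)
    n = k * block
    data = np.zeros((templates[0].vector.size, n))
    truth = np.empty(n, dtype=int)
    for i, tmpl in enumerate(templates):
        sl = slice(i * block, (i + 1) * block)
        env = amp * (1.0 + 0.3 * np.sin(np.linspace(0.2, np.pi - 0.2, block)))
        data[:, sl] = tmpl.vector[:, None] * env[None, :]
        truth[sl] = i
    data = data + rng.normal(0, noise_sd, data.shape)
    window = (0.0, n / sfreq * 1000.0)
    erp = EvokedERP(
        data=data, sfreq=sfreq, t0_ms=0.0, subject_id="s1",
        language="L1", embodiment="motor",
    )
    return erp, truth, window


class TestBackfitSubject:
    def test_noiseless_identity(self):
        templates = orthogonal_templates(16, 4, seed=0)
        erp, truth, window = _erp_from_sequence(templates)
        labels, table = backfit_subject(erp, templates, window)
        assert np.array_equal(labels, truth)
        assert table.gev.sum() == pytest.approx(1.0, abs=1e-10)
        assert table.duration_ms.sum() == pytest.approx(
            len(truth) * 1000.0 / erp.sfreq
        )

    def test_equal_correlation_tie_goes_to_lower_map_id(self):
        templates = orthogonal_templates(16, 2, seed=1)
        mix = tm.normalize_map(
            templates[0].vector + templates[1].vector
        ).vector  # equidistant from both
        erp = EvokedERP(
            data=mix[:, None] * np.array([[2.0]]), sfreq=256.0, t0_ms=0.0,
            subject_id="s1", language="L1", embodiment="motor",
        )
        labels, _ = backfit_subject(erp, templates, (0.0, 10.0))
        assert labels[0] == 0

    def test_losing_maps_score_zero(self):
        templates = orthogonal_templates(16, 3, seed=2)
        erp, _, window = _erp_from_sequence(templates[:2])
        _, table = backfit_subject(erp, templates, window)
        row = table[table.map_id == 2].iloc[0]
        assert row.gev == 0.0 and row.duration_ms == 0.0 and row.mean_gfp == 0.0

    def test_noisy_label_accuracy_montecarlo(self):
        """≥ 90% of samples with within-window SNR ≥ 5 are correctly
        labeled, over 50 simulated subjects."""
        templates = orthogonal_templates(32, 4, seed=3)
        noise_sd = 0.3
        correct = total = 0
        for seed in range(50):
            erp, truth, window = _erp_from_sequence(
                templates, noise_sd=noise_sd, seed=seed, amp=2.0
            )
            labels, _ = backfit_subject(erp, templates, window)
            clean, _, _ = _erp_from_sequence(templates, noise_sd=0.0, amp=2.0)
            snr = tm.gfp(clean.data) / noise_sd
            strong = snr >= 5
            correct += int((labels[strong] == truth[strong]).sum())
            total += int(strong.sum())
        assert correct / total >= 0.90

    def test_gev_and_duration_conservation(self, scaled_analysis):
        """Per subject × cell, Σ GEV ≤ 1 and Σ duration ≤ window length."""
        table = scaled_analysis.backfit
        per_cell = table.groupby(["subject_id", "language", "embodiment"]).agg(
            {"gev": "sum", "duration_ms": "sum"}
        )
        assert (per_cell.gev <= 1.0 + 1e-9).all()
        assert (per_cell.duration_ms <= 700.0 + 1e-9).all()


def _long(values: np.ndarray) -> pd.DataFrame:
    n = values.shape[0]
    return pd.DataFrame(
        [
            {
                "subject_id": f"s{s}",
                "language": lang,
                "embodiment": emb,
                "value": values[s, i],
            }
            for s in range(n)
            for i, (lang, emb) in enumerate(CELLS)
        ]
    )


def _anova_oracle(values: np.ndarray) -> dict[str, float]:
    """Brute-force within-subject decomposition via full linear projection.

    Builds the effect estimates cell-mean by cell-mean from the raw data
    and accumulates sums of squares sample by sample — no shared code
    with the implementation.
    """
    n = values.shape[0]
    Y = values.reshape(n, 2, 2)
    gm = Y.mean()
    F = {}
    for name, contrast in (
        ("language", Y.mean(axis=2)),  # subject × language means
        ("embodiment", Y.mean(axis=1)),
    ):
        level = contrast.mean(axis=0)
        subj = contrast.mean(axis=1)
        ss_eff = 2 * n * np.sum((level - gm) ** 2)
        ss_err = 0.0
        for s in range(n):
            for j in range(2):
                fitted = subj[s] + level[j] - gm
                ss_err += 2 * (contrast[s, j] - fitted) ** 2
        F[name] = (ss_eff / 1) / (ss_err / (n - 1))
    inter = Y - Y.mean(axis=0)
    a = Y.mean(axis=2, keepdims=True)
    b = Y.mean(axis=1, keepdims=True)
    cellm = Y.mean(axis=0, keepdims=True)
    am = Y.mean(axis=(0, 2), keepdims=True)
    bm = Y.mean(axis=(0, 1), keepdims=True)
    sm = Y.mean(axis=(1, 2), keepdims=True)
    ss_ab = np.sum((cellm - am - bm + gm) ** 2) * n
    resid = Y - a - b - cellm + sm + am + bm - gm
    ss_abs = np.sum(resid**2)
    F["interaction"] = (ss_ab / 1) / (ss_abs / (n - 1))
    return F


class TestRmAnova2x2:
    def test_null_data_gives_zero_effects(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=5)
        values = np.tile(base[:, None], (1, 4))  # identical across cells
        table = rm_anova_2x2(_long(values), "value")
        assert (table.F == 0.0).all()
        assert (table.p == 1.0).all()

    def test_frozen_three_subject_dataset(self):
        # hand dataset: 3 subjects × 4 cells (L1m, L1n, L2m, L2n)
        values = np.array(
            [
                [4.0, 6.0, 5.0, 9.0],
                [3.0, 5.0, 6.0, 8.0],
                [5.0, 7.0, 7.0, 12.0],
            ]
        )
        table = rm_anova_2x2(_long(values), "value").set_index("effect")
        oracle = _anova_oracle(values)
        for effect in ("language", "embodiment", "interaction"):
            assert table.loc[effect, "F"] == pytest.approx(oracle[effect], abs=1e-8)
        assert (table.df1 == 1).all() and (table.df2 == 2).all()

    @pytest.mark.parametrize("n,seed", [(3, 0), (5, 1), (8, 2), (10, 3)])
    def test_matches_bruteforce_decomposition(self, n, seed):
        values = np.random.default_rng(seed).normal(size=(n, 4))
        table = rm_anova_2x2(_long(values), "value").set_index("effect")
        oracle = _anova_oracle(values)
        for effect, f_expected in oracle.items():
            assert table.loc[effect, "F"] == pytest.approx(f_expected, abs=1e-8)

    @pytest.mark.parametrize("n,seed", [(6, 4), (12, 5)])
    def test_matches_pingouin(self, n, seed):
        """Independent library cross-check of F and p."""
        pingouin = pytest.importorskip("pingouin")
        values = np.random.default_rng(seed).normal(size=(n, 4))
        df = _long(values)
        ours = rm_anova_2x2(df, "value").set_index("effect")
        theirs = pingouin.rm_anova(
            data=df, dv="value", within=["language", "embodiment"],
            subject="subject_id", detailed=True,
        )
        mapping = {"language": "language", "embodiment": "embodiment",
                   "interaction": "language * embodiment"}
        for effect, label in mapping.items():
            row = theirs[theirs.Source == label].iloc[0]
            assert ours.loc[effect, "F"] == pytest.approx(row["F"], rel=1e-8)
            assert ours.loc[effect, "p"] == pytest.approx(row["p_unc"], rel=1e-6)
            assert ours.loc[effect, "eta2_generalized"] == pytest.approx(
                row["ng2"], rel=1e-6
            )

    def test_effect_sizes_ordered_and_bounded(self):
        values = np.random.default_rng(6).normal(size=(10, 4))
        table = rm_anova_2x2(_long(values), "value")
        assert ((table.eta2_partial >= table.eta2_generalized - 1e-12)).all()
        assert table.eta2_partial.between(0, 1).all()
        assert table.eta2_generalized.between(0, 1).all()

    def test_subject_permutation_invariance(self):
        values = np.random.default_rng(7).normal(size=(9, 4))
        f1 = rm_anova_2x2(_long(values), "value").F.to_numpy()
        f2 = rm_anova_2x2(_long(values[::-1]), "value").F.to_numpy()
        assert np.allclose(f1, f2, atol=1e-10)

    def test_missing_cell_names_subject(self):
        df = _long(np.zeros((3, 4)))
        df = df[~((df.subject_id == "s1") & (df.embodiment == "motor") & (df.language == "L2"))]
        with pytest.raises(ValueError, match="s1"):
            rm_anova_2x2(df, "value")

    def test_planted_effect_detection_rate(self):
        """A 1.3× embodiment effect on a log-normal measure (ρ = 0.5,
        n = 29) is detected in ≥ 80% of 100 simulated datasets."""
        rng = np.random.default_rng(8)
        sigma = np.sqrt(np.log1p(0.2**2))
        cov = np.full((4, 4), 0.5) + 0.5 * np.eye(4)
        hits = 0
        for _ in range(100):
            z = rng.multivariate_normal(np.zeros(4), cov, size=29)
            effects = np.exp(sigma * z - sigma**2 / 2)
            mult = np.array([1.3, 1.0, 1.3, 1.0])  # motor cells boosted
            values = 4.0 * effects * mult + rng.normal(0, 0.1, size=(29, 4))
            table = rm_anova_2x2(_long(values), "value").set_index("effect")
            hits += table.loc["embodiment", "p"] < 0.05
        assert hits >= 80


class TestPower:
    def test_reference_within_design_sample_size(self):
        n, achieved = rm_anova_power_n(PowerSpec())
        assert n == 24
        assert achieved >= 0.8

    def test_minimality_against_numerical_integration(self):
        """power(n−1) < 0.8 ≤ power(n), with power recomputed by
        integrating the noncentral F density."""
        spec = PowerSpec()
        n, _ = rm_anova_power_n(spec)

        def power_by_quadrature(nn):
            m = spec.n_measurements
            lam = spec.f**2 * nn * m / (1 - spec.rho)
            df1, df2 = m - 1, (nn - 1) * (m - 1)
            crit = sstats.f.ppf(1 - spec.alpha, df1, df2)
            val, _ = integrate.quad(
                lambda x: sstats.ncf.pdf(x, df1, df2, lam), crit, np.inf, limit=200
            )
            return val

        assert power_by_quadrature(n) >= spec.power_target
        assert power_by_quadrature(n - 1) < spec.power_target

    def test_monotonicity_in_f_alpha_rho(self):
        base, _ = rm_anova_power_n(PowerSpec())
        bigger_f, _ = rm_anova_power_n(PowerSpec(f=0.5))
        assert bigger_f <= base
        looser_alpha, _ = rm_anova_power_n(PowerSpec(alpha=0.2))
        assert looser_alpha <= base
        higher_rho, _ = rm_anova_power_n(PowerSpec(rho=0.8))
        assert higher_rho <= base  # λ grows as 1/(1−ρ)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(alpha=0.0)
        with pytest.raises(ValueError):
            PowerSpec(rho=1.0)


class TestAnovaAllMaps:
    def test_one_table_row_per_map_measure_effect(self, scaled_analysis):
        anova = scaled_analysis.anova
        k = scaled_analysis.segmentation.selected_k
        assert len(anova) == k * len(MEASURES) * 3
        assert (anova.df2 == 28).all()  # n = 29 subjects
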