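"""Fingerprint corrections, normalisation invariance, positivity calls, PCA."""

import numpy as np
import pandas as pd
import pytest

from iscatflow import fingerprint as fp
from iscatflow.synthgen import simulate_fingerprint_dataset


def raw_matrix(rows, cell_lines=None):
    cols = ["IgG1", "CD9", "CD63", "CD81", "CD326", "HE4", "CA125"]
    frame = pd.DataFrame(rows, columns=cols)
    if cell_lines is not None:
        frame.insert(0, "cell_line", cell_lines)
    return fp.FingerprintMatrix.from_frame(frame, stage=fp.RAW)


class TestSubtractControl:
    def test_chipwise_subtraction_arithmetic(self):
        m = raw_matrix([[2.0, 12.0, 8.0, 6.0, 4.0, 3.0, 2.0]])
        out = fp.subtract_control(m)
        assert out.stage == fp.CONTROL_SUBTRACTED
        assert out.frame["CD9"].iloc[0] == 10.0
        assert out.frame["CA125"].iloc[0] == 0.0  # marker == IgG1 level
        assert out.frame["IgG1"].iloc[0] == 2.0   # QC column retained

    def test_negative_results_floored_at_zero(self):
        m = raw_matrix([[5.0, 3.0, 9.0, 8.0, 1.0, 0.5, 0.2]])
        out = fp.subtract_control(m)
        assert out.frame["CD9"].iloc[0] == 0.0
        assert out.frame["HE4"].iloc[0] == 0.0

    def test_missing_isotype_column_rejected(self):
        frame = pd.DataFrame({"CD9": [1.0], "CD63": [1.0], "CD81": [1.0]})
        with pytest.raises(ValueError, match="IgG1"):
            fp.FingerprintMatrix.from_frame(frame)


class TestNormaliseTetraspanin:
    def test_normalisation_arithmetic(self):
        m = raw_matrix([[0.0, 10.0, 6.0, 8.0, 3.0, 0.0, 0.0]])
        out = fp.normalise_tetraspanin(fp.subtract_control(m))
        row = out.frame.iloc[0]
        assert row["CD9"] == pytest.approx(1.25)
        assert row["CD63"] == pytest.approx(0.75)
        assert row["CD81"] == pytest.approx(1.0)
        assert row["CD326"] == pytest.approx(0.375)

    def test_tetraspanin_mean_exactly_one(self):
        rng = np.random.default_rng(0)
        rows = rng.uniform(1, 20, size=(6, 7))
        rows[:, 0] = 0.5  # low IgG1
        m = raw_matrix(rows.tolist())
        out = fp.normalise_tetraspanin(fp.subtract_control(m))
        tetra = out.frame[list(fp.TETRASPANINS)].mean(axis=1)
        np.testing.assert_allclose(tetra, 1.0, rtol=1e-12)

    def test_invariance_to_global_rescaling(self):
        """Multiplying a chip's densities by any factor (concentration or
        flow-rate change) leaves its normalised fingerprint unchanged."""
        base = [0.4, 11.0, 7.0, 9.0, 5.0, 2.0, 1.0]
        m = raw_matrix([base, [7 * v for v in base]])
        out = fp.normalise_tetraspanin(fp.subtract_control(m))
        np.testing.assert_allclose(out.frame.iloc[0].to_numpy(dtype=float),
                                   out.frame.iloc[1].to_numpy(dtype=float),
                                   rtol=1e-12)

    def test_zero_tetraspanin_mean_rejected(self):
        m = raw_matrix([[1.0, 1.0, 1.0, 1.0, 5.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="tetraspanin"):
            fp.normalise_tetraspanin(fp.subtract_control(m))

    def test_wrong_stage_rejected(self):
        m = raw_matrix([[1.0, 3.0, 3.0, 3.0, 0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="stage"):
            fp.normalise_tetraspanin(m)


class TestPositivity:
    def test_marker_at_control_level_not_distinguishable(self):
        rows = [[2.0, 2.1, 5.0, 5.0, 2.0, 2.0, 2.0] for _ in range(4)]
        m = raw_matrix(rows)
        assert fp.positivity_call(m, "CD326") == fp.NOT_DISTINGUISHABLE

    def test_strong_marker_positive(self):
        rng = np.random.default_rng(1)
        rows = [[2.0 + rng.normal(0, 0.1), 20.0, 5, 5, 2, 2, 2]
                for _ in range(4)]
        m = raw_matrix(rows)
        assert fp.positivity_call(m, "CD9") == fp.POSITIVE

    def test_single_replicate_warns(self):
        m = raw_matrix([[2.0, 20.0, 5.0, 5.0, 2.0, 2.0, 2.0]])
        with pytest.warns(UserWarning, match="single replicate"):
            assert fp.positivity_call(m, "CD9") == fp.POSITIVE

    def test_null_cancer_markers_rarely_called_positive(self):
        """With zero cancer-marker expression the three cancer markers are
        indistinguishable from the control in >= 95% of seeds.

        Six chip replicates: with fewer the sample SD of the control channel
        is itself so noisy that the mean + 2 SD rule's family-wise false-call
        rate rises to ~10-15% (see the methods note on replicate counts).
        """
        expr = pd.DataFrame({"CD9": [10.0], "CD63": [8.0], "CD81": [9.0],
                             "CD326": [0.0], "HE4": [0.0], "CA125": [0.0]},
                            index=["benign"])
        ok = 0
        n_seeds = 100
        for seed in range(n_seeds):
            df = simulate_fingerprint_dataset(expr, 1.0, n_chips=6, seed=seed)
            m = fp.FingerprintMatrix.from_frame(df)
            calls = [fp.positivity_call(m, c) for c in fp.CANCER_MARKERS]
            ok += all(c == fp.NOT_DISTINGUISHABLE for c in calls)
        assert ok >= 0.95 * n_seeds


class TestPCA:
    def normalised(self, rows, cell_lines=None):
        return fp.normalise_tetraspanin(
            fp.subtract_control(raw_matrix(rows, cell_lines)))

    def test_identical_rows_project_to_origin(self):
        rows = [[0.1, 10.0, 6.0, 8.0, 3.0, 1.0, 0.5]] * 5
        proj = fp.pca_project(self.normalised(rows))
        np.testing.assert_allclose(
            proj.scores[["PC1", "PC2"]].to_numpy(), 0.0, atol=1e-9)

    def test_variance_ratios_sorted_and_bounded(self):
        rng = np.random.default_rng(2)
        rows = rng.uniform(1, 15, size=(8, 7))
        rows[:, 0] = 0.1  # low non-specific background
        proj = fp.pca_project(self.normalised(rows.tolist()))
        evr = proj.explained_variance_ratio
        assert evr[0] >= evr[1] >= 0
        assert evr.sum() <= 1.0 + 1e-12
        # scores are column-centred
        np.testing.assert_allclose(
            proj.scores[["PC1", "PC2"]].mean(), 0.0, atol=1e-9)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        rows = rng.uniform(1, 15, size=(6, 7))
        rows[:, 0] = 0.1
        norm = self.normalised(rows.tolist())
        proj = fp.pca_project(norm)
        X = norm.frame[norm.specific_markers].to_numpy(dtype=float)
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (len(X) - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        for comp in range(2):
            ev = v[:, order[comp]]
            got = proj.loadings[f"PC{comp + 1}"].to_numpy()
            # same axis up to sign
            assert abs(abs(ev @ got) - 1.0) < 1e-9
            np.testing.assert_allclose(
                np.abs(Xc @ ev), np.abs(proj.scores[f"PC{comp + 1}"]),
                atol=1e-9)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(4)
        rows = rng.uniform(1, 15, size=(6, 7))
        rows[:, 0] = 0.1
        rows = rows.tolist()
        p1 = fp.pca_project(self.normalised(rows))
        p2 = fp.pca_project(self.normalised(rows))
        np.testing.assert_array_equal(p1.scores[["PC1", "PC2"]].to_numpy(),
                                      p2.scores[["PC1", "PC2"]].to_numpy())
        for c in ("PC1", "PC2"):
            j = p1.loadings[c].abs().idxmax()
            assert p1.loadings.loc[j, c] > 0

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fp.pca_project(self.normalised([[0.1, 5, 5, 5, 1, 1, 1]] * 2))


class TestContrastDensityCorrelation:
    def make_tables(self, medians, counts, seed=0):
        rng = np.random.default_rng(seed)
        tables = {}
        for k, (m, n) in enumerate(zip(medians, counts)):
            tables[f"M{k}"] = pd.DataFrame({
                "peak_contrast": rng.lognormal(np.log(m), 0.2, n),
                "label": "signal"})
        return tables

    def test_monotone_relation_gives_perfect_rank_correlation(self):
        medians = [0.01, 0.02, 0.04, 0.08, 0.16]
        counts = [10, 20, 40, 80, 160]
        tables = {f"M{k}": pd.DataFrame({"peak_contrast": np.full(c, m),
                                         "label": "signal"})
                  for k, (m, c) in enumerate(zip(medians, counts))}
        _, rho = fp.contrast_density_correlation(tables, area_mm2=0.2)
        assert rho == pytest.approx(1.0)

    def test_null_relation_uncorrelated(self):
        """Same contrast law in all channels: |rho| stays small across seeds."""
        rhos = []
        for seed in range(100):
            tables = self.make_tables([0.02] * 6,
                                      [50, 80, 120, 200, 300, 400], seed=seed)
            _, rho = fp.contrast_density_correlation(tables, area_mm2=0.2)
            rhos.append(abs(rho))
        assert np.median(rhos) < 0.5

    def test_single_marker_rejected(self):
        tables = self.make_tables([0.02], [50])
        with pytest.raises(ValueError):
            fp.contrast_density_correlation(tables, area_mm2=0.2)

    def test_empty_marker_excluded_with_warning(self):
        tables = self.make_tables([0.02, 0.03, 0.04], [50, 60, 70])
        tables["empty"] = pd.DataFrame({"peak_contrast": [], "label": []})
        with pytest.warns(UserWarning, match="excluded"):
            df, _ = fp.contrast_density_correlation(tables, area_mm2=0.2)
        assert len(df) == 3
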