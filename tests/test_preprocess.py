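"""QC filter hand-traces, beta/M arithmetic, BMIQ contracts, cohort QC."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methfidelity import preprocess as pre
from methfidelity import synthetic as syn

from conftest import toy_intensities, toy_manifest


class TestFilterProbes:
    def _default(self, n=10, s=20):
        intens = toy_intensities(np.full((n, s), 1000.0), np.full((n, s), 1000.0))
        man = toy_manifest(n)
        return intens, man

    def test_nothing_triggers(self):
        intens, man = self._default()
        keep, report = pre.filter_probes(intens, man)
        assert keep.all()
        assert report.n_retained == 10
        assert len(report.removed_probes) == 0

    def test_hand_traced_failures(self):
        """Probe 3 fails detection in one sample; probe 7 has <3 beads in 5%
        of 20 samples (exactly at the fraction threshold)."""
        intens, man = self._default()
        intens.detection_p.iloc[3, 5] = 0.02
        intens.beadcount.iloc[7, 0] = 2
        keep, report = pre.filter_probes(intens, man)
        removed = dict(zip(report.removed_probes["probe_id"],
                           report.removed_probes["reason"]))
        assert removed == {"cg3": "detection", "cg7": "beads"}
        assert keep.sum() == 8

    def test_first_match_reason(self):
        intens, man = self._default()
        intens.detection_p.iloc[3, 0] = 0.05
        man.loc["cg3", "blacklist_flag"] = True
        _, report = pre.filter_probes(intens, man)
        assert list(report.removed_probes["reason"]) == ["detection"]

    def test_blacklist_and_sexchrom(self):
        intens, man = self._default()
        man.loc["cg1", "blacklist_flag"] = True
        man.loc["cg2", "sex_chrom_flag"] = True
        _, report = pre.filter_probes(intens, man)
        removed = dict(zip(report.removed_probes["probe_id"],
                           report.removed_probes["reason"]))
        assert removed == {"cg1": "blacklist", "cg2": "sexchrom"}

    def test_idempotent(self):
        intens, man = self._default()
        intens.detection_p.iloc[3, 5] = 0.02
        man.loc["cg2", "blacklist_flag"] = True
        keep, _ = pre.filter_probes(intens, man)
        sub = syn.IntensitySet(
            intens.M.loc[keep], intens.U.loc[keep],
            intens.detection_p.loc[keep], intens.beadcount.loc[keep],
        )
        keep2, report2 = pre.filter_probes(sub, man.loc[keep.index[keep]])
        assert keep2.all()
        assert len(report2.removed_probes) == 0

    def test_everything_removed_errors(self):
        intens, man = self._default()
        intens.detection_p.iloc[:, 0] = 0.5
        with pytest.raises(ValueError, match="no probes survive"):
            pre.filter_probes(intens, man)


class TestBetaAndM:
    @pytest.mark.parametrize(
        "m,u,expected",
        [(0.0, 0.0, 0.0), (1000.0, 0.0, 1000 / 1100), (500.0, 500.0, 500 / 1100)],
    )
    def test_beta_arithmetic(self, m, u, expected):
        intens = toy_intensities([[m]], [[u]])
        assert pre.compute_beta(intens).iloc[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_beta_strictly_below_one(self):
        rng = np.random.default_rng(0)
        intens = toy_intensities(rng.uniform(0, 1e5, (50, 4)),
                                 rng.uniform(0, 1e5, (50, 4)))
        assert (pre.compute_beta(intens).values < 1).all()

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            toy_intensities([[-1.0]], [[0.0]])

    @pytest.mark.parametrize(
        "b,expected",
        [(0.5, 0.0), (0.8, 2.0), (0.0, np.log2(1e-6 / (1 - 1e-6)))],
    )
    def test_m_values(self, b, expected):
        beta = pd.DataFrame([[b]])
        assert pre.beta_to_m(beta).iloc[0, 0] == pytest.approx(expected, abs=1e-9)


def _two_type_frame(v1, v2):
    """Beta frame with type I values v1 and type II values v2 (one sample)."""
    vals = np.concatenate([v1, v2])
    idx = pd.Index([f"cg{i}" for i in range(len(vals))])
    beta = pd.DataFrame({"s0": vals}, index=idx)
    types = pd.Series(["I"] * len(v1) + ["II"] * len(v2), index=idx)
    return beta, types


class TestBMIQ:
    def _mixture(self, rng, n):
        comp = rng.choice(3, size=n, p=(0.45, 0.45, 0.10))
        return np.where(
            comp == 0, rng.beta(5, 45, n),
            np.where(comp == 1, rng.beta(38, 7, n), rng.beta(5, 5, n)),
        )

    def test_matched_distributions_near_identity(self):
        rng = np.random.default_rng(0)
        v1, v2 = self._mixture(rng, 5000), self._mixture(rng, 5000)
        beta, types = _two_type_frame(v1, v2)
        out, log = pre.bmiq(beta, types)
        assert all(log.values())
        moved = np.abs(out["s0"].to_numpy()[5000:] - v2)
        assert np.quantile(moved, 0.95) < 0.02

    def test_type_one_bit_identical_and_monotone(self):
        rng = np.random.default_rng(1)
        v1 = self._mixture(rng, 2000)
        v2 = 0.5 + 0.7 * (self._mixture(rng, 2000) - 0.5)  # compressed
        beta, types = _two_type_frame(v1, v2)
        out, _ = pre.bmiq(beta, types)
        assert np.array_equal(out["s0"].to_numpy()[:2000], v1)
        y = out["s0"].to_numpy()[2000:]
        order = np.argsort(v2)
        assert (np.diff(y[order]) >= -1e-12).all()
        assert (y >= 0).all() and (y <= 1).all()

    def test_ks_distance_reduced(self):
        rng = np.random.default_rng(2)
        v1 = self._mixture(rng, 5000)
        v2 = 0.5 + 0.7 * (self._mixture(rng, 5000) - 0.5)
        beta, types = _two_type_frame(v1, v2)
        out, _ = pre.bmiq(beta, types)
        before = stats.ks_2samp(v2, v1).statistic
        after = stats.ks_2samp(out["s0"].to_numpy()[5000:], v1).statistic
        assert after < before
        assert after < 0.05

    def test_requires_both_design_types(self):
        beta, types = _two_type_frame(np.full(10, 0.5), np.full(100, 0.5))
        with pytest.raises(ValueError, match="50 probes"):
            pre.bmiq(beta, types)


class TestMDS:
    def test_identical_samples_no_outliers(self):
        beta = pd.DataFrame(np.tile(np.linspace(0, 1, 50)[:, None], (1, 3)),
                            columns=list("abc"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords, outliers = pre.mds_outlier_check(beta, top_k=50)
        assert np.allclose(coords.values, 0, atol=1e-8)
        assert outliers == []

    def test_inverted_sample_flagged(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(0.1, 0.9, 300)
        cols = {f"s{i}": np.clip(base + rng.normal(0, 0.01, 300), 0, 1)
                for i in range(20)}
        cols["weird"] = 1 - base
        beta = pd.DataFrame(cols)
        _, outliers = pre.mds_outlier_check(beta, top_k=300)
        assert outliers == ["weird"]

    def test_deterministic_up_to_reflection(self):
        rng = np.random.default_rng(4)
        beta = pd.DataFrame(rng.uniform(size=(100, 8)))
        c1, _ = pre.mds_outlier_check(beta, top_k=100)
        c2, _ = pre.mds_outlier_check(beta, top_k=100)
        assert np.allclose(np.abs(c1.values), np.abs(c2.values))

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            pre.mds_outlier_check(pd.DataFrame(np.ones((10, 2))))


class TestSVDScan:
    def _beta(self, rng, n_probes=300, n_samples=30):
        return pd.DataFrame(
            rng.uniform(0.1, 0.9, (n_probes, n_samples)),
            columns=[f"s{i}" for i in range(n_samples)],
        )

    def test_covariate_tracking_pc1(self):
        rng = np.random.default_rng(5)
        beta = self._beta(rng)
        # plant a strong PC1: shift half the samples on many probes
        beta.iloc[:150, :15] += 0.08
        Xc = beta.to_numpy() - beta.to_numpy().mean(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        cov = pd.DataFrame({"grp": np.where(vt[0] > 0, "a", "b")},
                           index=beta.columns)
        table = pre.svd_covariate_scan(beta, cov)
        assert table.loc["PC1", "grp"] < 1e-4

    def test_constant_covariate_excluded(self):
        rng = np.random.default_rng(6)
        beta = self._beta(rng)
        cov = pd.DataFrame({"flat": ["x"] * 30, "ok": ["a", "b"] * 15},
                           index=beta.columns)
        with pytest.warns(UserWarning, match="constant"):
            table = pre.svd_covariate_scan(beta, cov)
        assert list(table.columns) == ["ok"]

    def test_null_covariate_type_one_error(self):
        """An i.i.d.-noise covariate is significant in roughly alpha of cells."""
        rng = np.random.default_rng(7)
        hits = total = 0
        for _ in range(40):
            beta = self._beta(rng, n_probes=120, n_samples=24)
            cov = pd.DataFrame({"noise": rng.normal(size=24)}, index=beta.columns)
            table = pre.svd_covariate_scan(beta, cov)
            hits += int((table["noise"] < 0.05).sum())
            total += len(table)
        assert hits / total < 0.12
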