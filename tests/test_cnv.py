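"""CNV inference: baseline fit, binning hand-traces, similarity tertiles,
alteration burden and group comparisons."""

import numpy as np
import pandas as pd
import pytest

from methfidelity import cnv
from methfidelity import preprocess as pre
from methfidelity import synthetic as syn

from conftest import toy_manifest


def _controls(rng, n_probes=500, n=4, level=3000.0):
    idx = pd.Index([f"cg{i}" for i in range(n_probes)])
    return pd.DataFrame(
        level * rng.lognormal(0, 0.05, (n_probes, n)),
        index=idx, columns=[f"ctrl{i}" for i in range(n)],
    )


class TestProbeLog2R:
    def test_sample_equal_to_control_mean(self):
        rng = np.random.default_rng(0)
        controls = _controls(rng)
        sample = controls.mean(axis=1).rename("s")
        log2r, fit = cnv.probe_log2r(sample, controls)
        assert np.allclose(log2r, 0, atol=1e-9)
        assert fit["slope"] == pytest.approx(1.0, abs=1e-9)

    def test_global_scaling_absorbed(self):
        rng = np.random.default_rng(1)
        controls = _controls(rng)
        sample = (controls.mean(axis=1) * 2).rename("s")
        log2r, _ = cnv.probe_log2r(sample, controls)
        assert np.allclose(log2r, 0, atol=1e-9)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(2)
        controls = _controls(rng)
        sample = (controls.mean(axis=1) * rng.lognormal(0, 0.1, 500)).rename("s")
        a, _ = cnv.probe_log2r(sample, controls)
        b, _ = cnv.probe_log2r(sample * 7.3, controls)
        assert np.allclose(a, b, atol=1e-9)

    def test_zero_intensity_probe_imputed(self):
        rng = np.random.default_rng(3)
        controls = _controls(rng)
        sample = controls.mean(axis=1).rename("s")
        sample.iloc[5] = 0.0
        log2r, fit = cnv.probe_log2r(sample, controls)
        assert log2r.iloc[5] == 0.0
        assert fit["n_probes_fit"] == 499

    def test_needs_three_controls(self):
        rng = np.random.default_rng(4)
        controls = _controls(rng, n=2)
        with pytest.raises(ValueError, match="controls"):
            cnv.probe_log2r(controls.mean(axis=1), controls)

    def test_planted_three_copy_segment(self, manifest, cohort):
        """Mean log2R inside a 3-copy segment exceeds outside by ~log2(1.5)."""
        _, intensities, sheet, truth = cohort
        seg = next(s for s in truth.cnv_segments if s.copies == 3)
        carrier = seg.samples[0]
        total = intensities.total()
        controls = total[sheet.index[sheet["role"] == "control"]]
        log2r, _ = cnv.probe_log2r(total[carrier], controls)
        sel = (
            (manifest["chrom"] == seg.chrom)
            & (manifest["pos"] >= seg.start)
            & (manifest["pos"] <= seg.end)
        ).to_numpy()
        # neutral reference: probes outside every segment this sample carries
        altered = np.zeros(len(manifest), dtype=bool)
        for s in truth.cnv_segments:
            if carrier in s.samples:
                altered |= (
                    (manifest["chrom"] == s.chrom)
                    & (manifest["pos"] >= s.start)
                    & (manifest["pos"] <= s.end)
                ).to_numpy()
        delta = log2r[sel].mean() - log2r[~altered].mean()
        assert delta == pytest.approx(np.log2(1.5), abs=0.1)


class TestMakeBins:
    def test_hand_traced_regular_spacing(self):
        """100 probes at exact 10 kb spacing: five 15-probe bins plus a
        final bin absorbing the 25-probe remainder."""
        man = toy_manifest(100, spacing=10_000)
        bins = cnv.make_bins(man)
        assert len(bins) == 6
        assert list(bins["n_probes"]) == [15, 15, 15, 15, 15, 25]
        assert not bins["undersized"].any()

    def test_bin_waits_for_span(self):
        pos = np.concatenate([np.arange(15) * 2_000 + 1, [150_000]])
        man = toy_manifest(16)
        man["pos"] = pos
        bins = cnv.make_bins(man)
        # 15 probes span only 28 kb; the bin closes only once >= 50 kb
        assert bins.iloc[0]["n_probes"] == 16

    def test_undersized_chromosome_flagged(self):
        man = toy_manifest(10, spacing=10_000)
        bins = cnv.make_bins(man)
        assert len(bins) == 1 and bins.iloc[0]["undersized"]

    def test_bins_partition_probes(self, manifest):
        bins = cnv.make_bins(manifest)
        members = [p for row in bins.itertuples() for p in row.probes]
        assert sorted(members) == sorted(manifest.index)
        for _, grp in bins.groupby("chrom"):
            starts, ends = grp["start"].to_numpy(), grp["end"].to_numpy()
            assert (starts[1:] > ends[:-1]).all()  # sorted, non-overlapping


class TestBinProfile:
    def test_constant_and_mean(self):
        man = toy_manifest(30, spacing=10_000)
        bins = cnv.make_bins(man)
        log2r = pd.Series(0.2, index=man.index, name="s")
        prof = cnv.bin_profile(log2r, bins)
        assert np.allclose(prof.log2r, 0.2)
        log2r.iloc[:15] = [0.1, 0.3] * 7 + [0.2]
        assert cnv.bin_profile(log2r, bins).log2r.iloc[0] == pytest.approx(0.2)


class TestSimilarity:
    def _profile(self, vals, name):
        return cnv.CNVProfile(name, pd.Series(vals, index=[f"b{i}" for i in range(len(vals))]))

    def test_identity_and_anticorrelation(self):
        x = self._profile([0.1, -0.2, 0.4, 0.0], "c")
        y = self._profile([-0.1, 0.2, -0.4, 0.0], "t")
        assert cnv.similarity(x, x, [0.0, 0.5, 1.0]).r == pytest.approx(1.0)
        assert cnv.similarity(x, y, [0.0, 0.5, 1.0]).r == pytest.approx(-1.0)

    def test_tertile_partition_of_nine(self):
        rng = np.random.default_rng(5)
        rs = [round(0.1 * k, 1) for k in range(1, 10)]
        cats = []
        for r in rs:
            base = rng.normal(0, 1, 50)
            noise = rng.normal(0, 1, 50)
            other = r * base + np.sqrt(1 - r**2) * noise
            # construct profiles with exactly the cohort correlation list
            cats.append(
                cnv.similarity(
                    self._profile(base, "c"), self._profile(other, "t"), rs
                )
            )
        q1, q2 = cnv.tertile_boundaries(rs)
        by_cat = pd.Series(
            ["different" if r <= q1 else "similar" if r <= q2 else "coincident"
             for r in rs]
        ).value_counts()
        assert by_cat.to_dict() == {"different": 3, "similar": 3, "coincident": 3}

    def test_flat_profile_flagged(self):
        x = self._profile([0.0, 0.0, 0.0], "c")
        y = self._profile([0.1, 0.2, 0.3], "t")
        call = cnv.similarity(x, y, [0.0, 0.5, 0.9])
        assert call.r == 0.0 and "flat_profile" in call.flags


class TestBurden:
    @pytest.mark.parametrize(
        "vals,expected",
        [
            ([0, 0, 0], 0),
            ([0.2, 0.2, 0, -0.15], 2),
            ([0.1, 0.1], 0),            # strictly greater than the threshold
            ([0.2, -0.2, 0.2], 1),      # runs are on |log2R|, sign-agnostic
            ([0.5] * 5, 1),
        ],
    )
    def test_run_counting(self, vals, expected):
        prof = cnv.CNVProfile("s", pd.Series(vals, index=[f"b{i}" for i in range(len(vals))]))
        assert cnv.alteration_burden(prof) == expected

    def test_identical_groups_p_one(self):
        out = cnv.burden_comparison([3, 3, 3], [3, 3, 3])
        assert out["p"] == 1.0

    def test_exact_rank_sum(self):
        out = cnv.burden_comparison([0, 0, 0, 0], [10, 12, 11, 13])
        assert out["p"] == pytest.approx(2 / 70, abs=1e-9)
        assert out["mean_a"] == 0.0 and out["mean_b"] == 11.5

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cnv.burden_comparison([], [1])


class TestCumulativeProfile:
    def _profiles(self, mat):
        idx = [f"b{i}" for i in range(mat.shape[0])]
        return [
            cnv.CNVProfile(f"s{j}", pd.Series(mat[:, j], index=idx))
            for j in range(mat.shape[1])
        ]

    def test_all_zero(self):
        frac, flat = cnv.cumulative_profile(self._profiles(np.zeros((5, 3))))
        assert (frac.values == 0).all() and flat == 0.0

    def test_single_gain_fraction(self):
        mat = np.zeros((4, 4))
        mat[2, 1] = 0.5
        frac, _ = cnv.cumulative_profile(self._profiles(mat))
        assert frac["frac_gained"].iloc[2] == pytest.approx(0.25)
        assert (frac["frac_lost"] == 0).all()

    def test_different_cells_flatter_than_tissues(self, manifest, cohort):
        """CNV-erased cultures show a flatter cumulative profile than the
        tumors they derive from."""
        design, intensities, sheet, truth = cohort
        total = intensities.total()
        controls = total[sheet.index[sheet["role"] == "control"]]
        bins = cnv.make_bins(manifest)

        def profiles(samples):
            out = []
            for s in samples:
                log2r, _ = cnv.probe_log2r(total[s], controls)
                out.append(cnv.bin_profile(log2r, bins, sample_id=s))
            return out

        different = [p.cell_id for p in design.paired_cells
                     if p.cnv_share == "different"]
        tissues = sorted({p.tissue_id for p in design.paired_cells
                          if p.cnv_share == "different"})
        _, flat_cells = cnv.cumulative_profile(profiles(different))
        _, flat_tissues = cnv.cumulative_profile(profiles(tissues))
        assert flat_cells < flat_tissues
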