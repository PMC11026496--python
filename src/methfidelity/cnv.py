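"""Copy-number inference from combined methylation-probe intensities.

The total intensity (methylated + unmethylated channel) of each probe is
compared to a panel of copy-neutral control samples: the sample's
log-intensity is regressed on the controls' mean log-intensity and the
median-centered residual, in log2 units, is the per-probe copy-number
ratio (log2R).  Probes are aggregated into genomic bins of at least 50 kb
and 15 probes; cell-vs-tissue similarity is the correlation of binned
profiles, categorized by cohort tertiles (different / similar /
coincident); alteration burden counts maximal runs of bins with
|log2R| > 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CNVProfile",
    "SimilarityCall",
    "probe_log2r",
    "make_bins",
    "bin_profile",
    "similarity",
    "tertile_boundaries",
    "alteration_burden",
    "burden_comparison",
    "cumulative_profile",
]


@dataclass
class CNVProfile:
    sample_id: str
    log2r: pd.Series               # indexed by bin id, excludes undersized bins
    baseline: dict = field(default_factory=dict)   # fit description


@dataclass
class SimilarityCall:
    cell_id: str
    tissue_id: str
    r: float
    category: str                  # different | similar | coincident
    flags: list[str] = field(default_factory=list)


def probe_log2r(
    sample: pd.Series, controls: pd.DataFrame
) -> tuple[pd.Series, dict]:
    """Per-probe log2 copy-number ratio against copy-neutral controls.

    ``sample`` and the columns of ``controls`` are total intensities
    (M + U) per probe.  The sample's log2-intensity is fitted on the
    controls' mean log2-intensity by least squares (intercept + slope); the
    residual, median-centered per sample, is the log2R.  Probes with zero
    total intensity are excluded from the fit and imputed at the median
    (zero after centering).  Invariant to global positive scaling of the
    sample.
    """
    if controls.shape[1] < 3:
        raise ValueError("need >= 3 copy-neutral controls")
    ref = controls.mean(axis=1)
    ok = (sample.to_numpy() > 0) & (ref.to_numpy() > 0)
    x = np.log2(ref.to_numpy()[ok])
    y = np.log2(sample.to_numpy()[ok])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    resid -= np.median(resid)
    out = pd.Series(0.0, index=sample.index, name=sample.name)
    out.iloc[np.flatnonzero(ok)] = resid
    return out, {"slope": float(slope), "intercept": float(intercept),
                 "n_probes_fit": int(ok.sum())}


def make_bins(
    manifest: pd.DataFrame, min_size: int = 50_000, min_probes: int = 15
) -> pd.DataFrame:
    """Greedy left-to-right binning: close a bin once both minima are met.

    Span is measured first-to-last member probe position.  The trailing
    remainder of each chromosome is merged into its last bin.  A chromosome
    with fewer than ``min_probes`` probes yields a single bin flagged
    undersized (excluded from correlation).  Returns a frame with columns
    chrom, start, end (1-based inclusive), n_probes, undersized, probes.
    """
    rows = []
    for chrom, grp in manifest.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        ids = grp.index.to_numpy()
        if len(pos) == 0:
            continue
        if len(pos) < min_probes:
            rows.append(dict(chrom=chrom, start=int(pos[0]), end=int(pos[-1]),
                             n_probes=len(pos), undersized=True,
                             probes=list(ids)))
            continue
        bins_here = []
        start_i = 0
        for i in range(len(pos)):
            count = i - start_i + 1
            span = pos[i] - pos[start_i]
            if count >= min_probes and span >= min_size:
                bins_here.append((start_i, i))
                start_i = i + 1
        if start_i < len(pos):  # merge remainder into last bin
            if bins_here:
                bins_here[-1] = (bins_here[-1][0], len(pos) - 1)
            else:
                bins_here.append((0, len(pos) - 1))
        for a, b in bins_here:
            rows.append(dict(chrom=chrom, start=int(pos[a]), end=int(pos[b]),
                             n_probes=b - a + 1, undersized=False,
                             probes=list(ids[a : b + 1])))
    bins = pd.DataFrame(rows)
    if len(bins):
        bins.index = [f"bin{i:05d}" for i in range(len(bins))]
    return bins


def bin_profile(log2r: pd.Series, bins: pd.DataFrame, sample_id: str | None = None,
                baseline: dict | None = None) -> CNVProfile:
    """Per-bin mean of member probes' log2R (undersized bins excluded)."""
    usable = bins[~bins["undersized"]]
    vals = {bid: float(log2r.loc[row["probes"]].mean())
            for bid, row in usable.iterrows()}
    return CNVProfile(
        sample_id=sample_id or str(log2r.name),
        log2r=pd.Series(vals, name=sample_id or log2r.name),
        baseline=baseline or {},
    )


def tertile_boundaries(cohort_correlations: list[float]) -> tuple[float, float]:
    """Type-7 1/3 and 2/3 quantiles of the cohort's pair correlations."""
    arr = np.asarray(cohort_correlations, dtype=float)
    q1, q2 = np.quantile(arr, [1 / 3, 2 / 3])  # numpy default = type 7
    return float(q1), float(q2)


def similarity(
    cell: CNVProfile, tissue: CNVProfile, cohort_correlations: list[float]
) -> SimilarityCall:
    """Pearson correlation of binned profiles, categorized by cohort tertiles.

    Lower tertile -> different, middle -> similar, top -> coincident; ties
    at a boundary go to the lower category.  A flat (zero-variance) profile
    gets r = 0 with a ``flat_profile`` flag.
    """
    a = cell.log2r.reindex(tissue.log2r.index)
    b = tissue.log2r
    flags = []
    if np.std(a.to_numpy()) == 0 or np.std(b.to_numpy()) == 0:
        r = 0.0
        flags.append("flat_profile")
    else:
        r = float(stats.pearsonr(a.to_numpy(), b.to_numpy()).statistic)
    q1, q2 = tertile_boundaries(cohort_correlations)
    category = "different" if r <= q1 else ("similar" if r <= q2 else "coincident")
    return SimilarityCall(cell.sample_id, tissue.sample_id, r, category, flags)


def alteration_burden(profile: CNVProfile, thresh: float = 0.1) -> int:
    """Number of altered regions: maximal runs of bins with |log2R| > thresh."""
    hit = np.abs(profile.log2r.to_numpy()) > thresh  # strictly greater
    if not hit.any():
        return 0
    return int(np.sum(hit & ~np.concatenate([[False], hit[:-1]])))


def burden_comparison(group_a: list[int], group_b: list[int]) -> dict:
    """Two-sided exact Wilcoxon rank-sum comparison of alteration burdens."""
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if np.all(a == a[0]) and np.all(b == a[0]):
        p = 1.0
        stat = float(len(a) * len(b) / 2)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        stat, p = float(res.statistic), float(res.pvalue)
    return {"statistic": stat, "p": p,
            "mean_a": float(a.mean()), "mean_b": float(b.mean())}


def cumulative_profile(
    profiles: list[CNVProfile],
    gain_thresh: float = 0.1,
    loss_thresh: float = -0.1,
) -> tuple[pd.DataFrame, float]:
    """Per-bin fraction of samples gained / lost, plus a flatness summary.

    Flatness is the mean absolute log2R over all bins and samples (lower =
    flatter profile).
    """
    mat = pd.concat([p.log2r.rename(p.sample_id) for p in profiles], axis=1)
    frac = pd.DataFrame(
        {
            "frac_gained": (mat > gain_thresh).mean(axis=1),
            "frac_lost": (mat < loss_thresh).mean(axis=1),
        }
    )
    flatness = float(mat.abs().to_numpy().mean())
    return frac, flatness
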