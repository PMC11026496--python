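"""Differentially methylated region (DMR) calling and the Δβ statistic.

Per-CpG moderated t statistics are computed on M-values; their squares are
smoothed along the genome with a Gaussian kernel, per-CpG p-values come
from a Satterthwaite (moment-matching) scaled chi-square approximation,
and Benjamini–Hochberg significant CpGs are grouped into regions split at
gaps larger than ``lambda`` bp, discarding regions with fewer than the
minimum number of CpGs.  Each region is assigned a Δβ: the double average
(over region probes, then test samples) of the beta difference from the
reference-group mean.  Regions are restricted to promoter-proximal probes
(TSS200 / TSS1500 / 1stExon) for the gene-level analyses, and split into
hypo-/hyper-methylated sets at |Δβ| > 0.10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import PROMOTER_CLASSES

__all__ = [
    "GroupContrast",
    "DMRRecord",
    "cpg_stats",
    "call_dmrs",
    "delta_beta",
    "annotate_dmrs",
    "promoter_filter",
    "split_hypo_hyper",
]


@dataclass
class GroupContrast:
    test: list[str]
    reference: list[str]
    label: str = ""

    def __post_init__(self) -> None:
        if set(self.test) & set(self.reference):
            raise ValueError("test and reference groups overlap")
        if len(self.test) < 2 or len(self.reference) < 2:
            raise ValueError("each group needs >= 2 samples")


@dataclass
class DMRRecord:
    chrom: str
    start: int
    end: int
    n_cpgs: int
    q: float
    probes: list[str]
    delta_beta: float | None = None
    region_classes: set = field(default_factory=set)
    genes: set = field(default_factory=set)

    @property
    def direction(self) -> str:
        if self.delta_beta is None:
            return "none"
        if self.delta_beta < -0.10:
            return "hypo"
        if self.delta_beta > 0.10:
            return "hyper"
        return "none"


def cpg_stats(
    mvals: pd.DataFrame, contrast: GroupContrast, d0: float = 4.0
) -> pd.DataFrame:
    """Moderated two-sample t per CpG on M-values.

    Pooled-variance t with empirical-Bayes shrinkage of the per-CpG variance
    toward the global mean variance, weighted by ``d0`` pseudo-observations;
    ``d0=0`` reduces to the ordinary pooled t.  Returns a frame with columns
    t, p, flagged (zero variance in both groups).
    """
    A = mvals[contrast.test].to_numpy()
    B = mvals[contrast.reference].to_numpy()
    n1, n2 = A.shape[1], B.shape[1]
    df = n1 + n2 - 2
    v1 = A.var(axis=1, ddof=1)
    v2 = B.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    flagged = s2 == 0
    if d0 > 0:
        s2_shrunk = (d0 * s2.mean() + df * s2) / (d0 + df)
        df_mod = df + d0
    else:
        s2_shrunk = s2
        df_mod = df
    diff = A.mean(axis=1) - B.mean(axis=1)
    denom = np.sqrt(s2_shrunk * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / denom, 0.0)
    p = 2 * stats.t.sf(np.abs(t), df_mod)
    p = np.where(flagged & (diff == 0), 1.0, p)
    return pd.DataFrame({"t": t, "p": p, "flagged": flagged}, index=mvals.index)


def _smooth_chisq_p(
    t: np.ndarray, pos: np.ndarray, sigma: float
) -> np.ndarray:
    """Gaussian-kernel smoothing of t^2 with Satterthwaite chi-square p-values.

    For CpG i, S_i = sum_j w_ij t_j^2 with w_ij = exp(-d^2 / 2 sigma^2)
    truncated at 3 sigma.  Under the null t_j^2 is approximately chi^2_1, so
    S_i ~ c chi^2_nu with c = sum(w^2)/sum(w), nu = sum(w)^2 / sum(w^2).
    """
    t2 = t**2
    p = np.empty_like(t2)
    halo = 3.0 * sigma
    order = np.argsort(pos, kind="stable")
    pos_s, t2_s = pos[order], t2[order]
    lo = np.searchsorted(pos_s, pos_s - halo, side="left")
    hi = np.searchsorted(pos_s, pos_s + halo, side="right")
    for k in range(len(pos_s)):
        d = pos_s[lo[k]:hi[k]] - pos_s[k]
        w = np.exp(-(d**2) / (2 * sigma**2))
        S = float((w * t2_s[lo[k]:hi[k]]).sum())
        sw, sw2 = w.sum(), (w**2).sum()
        c = sw2 / sw
        nu = sw**2 / sw2
        p[order[k]] = stats.chi2.sf(S / c, nu)
    return p


def call_dmrs(
    stats_df: pd.DataFrame,
    manifest: pd.DataFrame,
    lambda_: int = 1000,
    min_cpgs: int = 7,
    fdr: float = 0.05,
) -> list[DMRRecord]:
    """Group BH-significant smoothed CpGs into regions.

    ``stats_df`` is the output of :func:`cpg_stats` (index = probe ids);
    positions and chromosomes come from ``manifest``.  Smoothing bandwidth
    is ``sigma = lambda_ / 2``; consecutive significant CpGs more than
    ``lambda_`` bp apart start a new region; regions with fewer than
    ``min_cpgs`` significant CpGs are discarded.  Region boundaries are the
    min/max positions of member significant CpGs.
    """
    ann = manifest.loc[stats_df.index]
    chroms = ann["chrom"].to_numpy()
    pos = ann["pos"].to_numpy()
    smoothed_p = np.empty(len(stats_df))
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        smoothed_p[sel] = _smooth_chisq_p(
            stats_df["t"].to_numpy()[sel], pos[sel].astype(float), lambda_ / 2.0
        )
    _, qvals, _, _ = multipletests(smoothed_p, method="fdr_bh")

    sig = qvals < fdr
    records: list[DMRRecord] = []
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero((chroms == chrom) & sig)
        if len(sel) == 0:
            continue
        sel = sel[np.argsort(pos[sel], kind="stable")]
        breaks = np.flatnonzero(np.diff(pos[sel]) > lambda_)
        for chunk in np.split(sel, breaks + 1):
            if len(chunk) < min_cpgs:
                continue
            records.append(
                DMRRecord(
                    chrom=str(chrom),
                    start=int(pos[chunk].min()),
                    end=int(pos[chunk].max()),
                    n_cpgs=len(chunk),
                    q=float(qvals[chunk].min()),
                    probes=list(stats_df.index[chunk]),
                )
            )
    return records


def delta_beta(
    beta: pd.DataFrame, region: DMRRecord, contrast: GroupContrast
) -> float:
    """Δβ: the double average of per-sample differences from the reference.

    For each test sample, average (over region probes) the difference
    between its beta and the reference-group mean beta; then average over
    test samples.  Antisymmetric under swapping test/reference.
    """
    probes = [p for p in region.probes if p in beta.index]
    if not probes:
        raise ValueError("region has no surviving probes in the beta matrix")
    sub = beta.loc[probes]
    ref_mean = sub[contrast.reference].mean(axis=1)
    per_sample = (sub[contrast.test].sub(ref_mean, axis=0)).mean(axis=0)
    return float(per_sample.mean())


def annotate_dmrs(
    dmrs: list[DMRRecord],
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    contrast: GroupContrast,
) -> list[DMRRecord]:
    """Fill in Δβ, region classes and gene annotations from member CpGs."""
    for rec in dmrs:
        rec.delta_beta = delta_beta(beta, rec, contrast)
        ann = manifest.loc[[p for p in rec.probes if p in manifest.index]]
        rec.region_classes = set(ann["region_class"])
        rec.genes = set(g for g in ann["gene"] if g)
    return dmrs


def promoter_filter(dmrs: list[DMRRecord], manifest: pd.DataFrame) -> list[DMRRecord]:
    """Keep DMRs with >= 1 member CpG in TSS200 / TSS1500 / 1stExon."""
    kept = []
    for rec in dmrs:
        classes = set(manifest.loc[rec.probes, "region_class"])
        if classes & set(PROMOTER_CLASSES):
            kept.append(rec)
    return kept


def split_hypo_hyper(
    dmrs: list[DMRRecord], thresh: float = 0.10
) -> tuple[set[str], set[str]]:
    """Gene sets of hypo- (Δβ < -thresh) and hyper- (Δβ > thresh) DMRs."""
    hypo: set[str] = set()
    hyper: set[str] = set()
    for rec in dmrs:
        if rec.delta_beta is None:
            continue
        if rec.delta_beta < -thresh:
            hypo |= rec.genes
        elif rec.delta_beta > thresh:
            hyper |= rec.genes
    return hypo, hyper
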