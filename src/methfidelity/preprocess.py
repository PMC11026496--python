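"""Probe QC, beta/M-value computation, BMIQ normalization and cohort QC.

The QC filter removes probes in a fixed, first-match-exclusive order
(detection p-value, bead count, blacklist, sex chromosomes), after which
beta values are computed with the standard Illumina offset and type II
probes are rescaled onto the type I distribution by Beta-MIxture Quantile
dilation (BMIQ).  Cohort-level checks are a classical-MDS outlier screen on
the most variable probes and an SVD scan associating principal components
with sample covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import beta as beta_dist

__all__ = [
    "QCReport",
    "filter_probes",
    "compute_beta",
    "beta_to_m",
    "bmiq",
    "mds_outlier_check",
    "svd_covariate_scan",
]

FILTER_REASONS = ("detection", "beads", "blacklist", "sexchrom")


@dataclass
class QCReport:
    """Ledger of the probe filter plus cohort-level check results."""

    removed_probes: pd.DataFrame      # columns: probe_id, reason
    n_retained: int
    outlier_samples: list[str] = field(default_factory=list)
    svd_table: pd.DataFrame | None = None

    def counts(self) -> pd.Series:
        return self.removed_probes["reason"].value_counts()


def filter_probes(
    intensities,
    manifest: pd.DataFrame,
    detp_max: float = 0.01,
    bead_min: int = 3,
    bead_frac: float = 0.05,
) -> tuple[pd.Series, QCReport]:
    """Apply the four probe filters in order; reasons are first-match.

    1. detection p-value > ``detp_max`` in at least one sample;
    2. bead count < ``bead_min`` in at least ``bead_frac`` of samples;
    3. blacklisted probes (SNP / cross-reactive proxy);
    4. sex-chromosome probes.

    Returns a boolean keep-mask aligned to the manifest and a
    :class:`QCReport`.
    """
    if not intensities.probes.equals(manifest.index):
        raise ValueError("intensity matrices not aligned with manifest")
    n_samples = len(intensities.samples)

    fail_detp = (intensities.detection_p.values > detp_max).any(axis=1)
    fail_beads = (
        (intensities.beadcount.values < bead_min).sum(axis=1) >= bead_frac * n_samples
    )
    fail_black = manifest["blacklist_flag"].to_numpy(dtype=bool)
    fail_sex = manifest["sex_chrom_flag"].to_numpy(dtype=bool)

    reason = np.full(len(manifest), "", dtype=object)
    for flags, tag in [
        (fail_detp, "detection"),
        (fail_beads, "beads"),
        (fail_black, "blacklist"),
        (fail_sex, "sexchrom"),
    ]:
        reason[(reason == "") & flags] = tag

    keep = pd.Series(reason == "", index=manifest.index, name="keep")
    if not keep.any():
        raise ValueError("no probes survive QC")
    removed = pd.DataFrame(
        {"probe_id": manifest.index[reason != ""], "reason": reason[reason != ""]}
    ).reset_index(drop=True)
    return keep, QCReport(removed_probes=removed, n_retained=int(keep.sum()))


def compute_beta(intensities, offset: float = 100.0) -> pd.DataFrame:
    """beta = M / (M + U + offset), elementwise; strictly < 1 for offset > 0."""
    M, U = intensities.M, intensities.U
    if (M.values < 0).any() or (U.values < 0).any():
        raise ValueError("negative intensities")
    return M / (M + U + offset)


def beta_to_m(beta: pd.DataFrame, eps: float = 1e-6) -> pd.DataFrame:
    """M-value = log2(b / (1-b)) with b clipped to [eps, 1-eps]."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1 - eps)
    out = np.log2(b / (1 - b))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    return out


# ---------------------------------------------------------------------------
# BMIQ
# ---------------------------------------------------------------------------

def _beta_moments(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted method-of-moments estimate of Beta(a, b) parameters."""
    wsum = w.sum()
    m = float((w * x).sum() / wsum)
    v = float((w * (x - m) ** 2).sum() / wsum)
    m = min(max(m, 1e-4), 1 - 1e-4)
    v = max(v, 1e-8)
    common = max(m * (1 - m) / v - 1.0, 1e-2)
    a = np.clip(m * common, 1e-2, 1e4)
    b = np.clip((1 - m) * common, 1e-2, 1e4)
    return float(a), float(b)


def _fit_beta_mixture(
    x: np.ndarray, tol: float = 1e-4, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, bool]:
    """EM fit of a 3-state (unmeth / hemi / meth) beta mixture.

    Returns (params[3, 2], weights[3], converged); components ordered by mean.
    """
    x = np.clip(x, 1e-6, 1 - 1e-6)
    lab = np.digitize(x, [0.25, 0.75])  # initial hard split
    params = np.zeros((3, 2))
    weights = np.zeros(3)
    for k in range(3):
        sel = lab == k
        if sel.sum() < 2:  # degenerate start: seed from fixed prototypes
            proto = [(2.0, 18.0), (5.0, 5.0), (18.0, 2.0)][k]
            params[k] = proto
            weights[k] = max(sel.mean(), 1e-3)
        else:
            params[k] = _beta_moments(x[sel], np.ones(sel.sum()))
            weights[k] = sel.mean()
    weights /= weights.sum()

    converged = False
    prev_ll = -np.inf
    for _ in range(max_iter):
        dens = np.stack(
            [weights[k] * beta_dist.pdf(x, *params[k]) for k in range(3)]
        )
        dens = np.clip(dens, 1e-300, None)
        total = dens.sum(axis=0)
        resp = dens / total
        params = np.array([_beta_moments(x, resp[k]) for k in range(3)])
        weights = np.clip(resp.mean(axis=1), 1e-4, None)
        weights /= weights.sum()
        ll = float(np.log(total).mean())
        if abs(ll - prev_ll) < tol:  # mean log-likelihood change per probe
            converged = True
            break
        prev_ll = ll

    order = np.argsort(params[:, 0] / params.sum(axis=1))  # by component mean
    return params[order], weights[order], converged


def _state_boundaries(params: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Value-axis boundaries between the U/H and H/M states.

    Posterior-argmax crossings searched outward from the component means, so
    spurious dominance flips in the far tails (where no data lives) are
    ignored.
    """
    grid = np.linspace(1e-4, 1 - 1e-4, 2001)
    post = np.stack(
        [weights[k] * beta_dist.pdf(grid, *params[k]) for k in range(3)]
    )
    state = post.argmax(axis=0)
    means = params[:, 0] / params.sum(axis=1)
    i0 = int(np.searchsorted(grid, means[0]))
    i2 = int(np.searchsorted(grid, means[2]))
    right = np.flatnonzero(state[i0:] != 0)
    t1 = grid[i0 + right[0]] if right.size else (means[0] + means[1]) / 2
    left = np.flatnonzero(state[:i2] != 2)
    t2 = grid[left[-1]] if left.size else (means[1] + means[2]) / 2
    if not t1 < t2:
        mid = (t1 + t2) / 2
        t1, t2 = mid - 1e-3, mid + 1e-3
    return float(t1), float(t2)


def bmiq(
    beta: pd.DataFrame,
    design_types: pd.Series,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Beta-MIxture Quantile dilation normalization, per sample.

    Three-state beta mixtures are fitted by EM to the type I and type II
    probes separately.  Type II probes in the unmethylated and methylated
    states are reassigned state-wise to the type I quantile scale through
    the fitted beta CDF / inverse CDF; the hemimethylated middle state is
    dilated linearly onto the gap between the two mapped outer states.
    Type I probes are left bit-identical, and the map is monotone within
    each sample's type II probes.

    Returns the normalized matrix and a per-sample EM convergence log; a
    sample whose EM does not converge is passed through unchanged.
    """
    design_types = design_types.reindex(beta.index)
    is1 = (design_types == "I").to_numpy()
    is2 = (design_types == "II").to_numpy()
    if is1.sum() < 50 or is2.sum() < 50:
        raise ValueError("need >= 50 probes of each design type")

    out = beta.copy()
    log: dict[str, bool] = {}
    for sample in beta.columns:
        v1 = beta[sample].to_numpy()[is1]
        v2 = beta[sample].to_numpy()[is2]
        p1, w1, ok1 = _fit_beta_mixture(v1, tol, max_iter)
        p2, w2, ok2 = _fit_beta_mixture(v2, tol, max_iter)
        log[sample] = ok1 and ok2
        if not (ok1 and ok2):
            warnings.warn(f"BMIQ EM did not converge for sample {sample}; identity fallback")
            continue

        t1_i, t2_i = _state_boundaries(p1, w1)   # type I boundaries
        t1, t2 = _state_boundaries(p2, w2)       # type II boundaries
        x = np.clip(v2, 1e-6, 1 - 1e-6)
        mapped = np.empty_like(x)

        lo = x <= t1
        hi = x > t2
        mid = ~(lo | hi)
        # state-wise quantile mapping through the fitted distributions
        mapped[lo] = beta_dist.ppf(beta_dist.cdf(x[lo], *p2[0]), *p1[0])
        mapped[hi] = beta_dist.ppf(beta_dist.cdf(x[hi], *p2[2]), *p1[2])
        # dilation of the middle state onto the gap between the mapped ends
        u_end = float(beta_dist.ppf(beta_dist.cdf(t1, *p2[0]), *p1[0]))
        m_start = float(beta_dist.ppf(beta_dist.cdf(t2, *p2[2]), *p1[2]))
        if m_start <= u_end:
            u_end, m_start = min(u_end, m_start), min(u_end, m_start) + 1e-6
        mapped[mid] = u_end + (x[mid] - t1) * (m_start - u_end) / (t2 - t1)

        # guard monotonicity against ppf round-off at the state seams
        order = np.argsort(x, kind="stable")
        mapped[order] = np.maximum.accumulate(mapped[order])
        col = out[sample].to_numpy()
        col[is2] = np.clip(mapped, 0.0, 1.0)
        out[sample] = col
    return out, log


# ---------------------------------------------------------------------------
# cohort-level QC
# ---------------------------------------------------------------------------

def mds_outlier_check(
    beta: pd.DataFrame, top_k: int = 1000, z_thresh: float = 3.0
) -> tuple[pd.DataFrame, list[str]]:
    """Classical MDS on the ``top_k`` most variable probes; robust-z outliers.

    A sample is flagged when its robust z-score (median/MAD) exceeds
    ``z_thresh`` on either of the first two MDS axes.
    """
    if beta.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if top_k > len(beta):
        warnings.warn("top_k exceeds probe count; using all probes")
        top_k = len(beta)
    sel = beta.var(axis=1).nlargest(top_k).index
    X = beta.loc[sel].to_numpy().T  # samples x probes

    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh(B)
    idx = np.argsort(evals)[::-1][:2]
    coords = evecs[:, idx] * np.sqrt(np.clip(evals[idx], 0, None))

    outliers: list[str] = []
    for axis in range(coords.shape[1]):
        x = coords[:, axis]
        mad = np.median(np.abs(x - np.median(x)))
        scale = 1.4826 * mad
        if scale == 0:
            continue
        z = np.abs(x - np.median(x)) / scale
        outliers.extend(beta.columns[z > z_thresh])
    coords_df = pd.DataFrame(coords, index=beta.columns, columns=["MDS1", "MDS2"])
    return coords_df, sorted(set(outliers))


def svd_covariate_scan(
    beta: pd.DataFrame,
    covariates: pd.DataFrame,
    n_components: int = 6,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Associate top SVD components of the beta matrix with sample covariates.

    Rows of ``beta`` (probes) are mean-centered; the sample scores of the
    top ``min(n_components, n_samples - 1)`` components are tested against
    each covariate — Kruskal–Wallis for categorical, Spearman for numeric.
    Returns a components x covariates table of p-values with an attached
    boolean ``.attrs["significant"]`` mask at ``alpha``.
    """
    if not covariates.index.equals(beta.columns):
        covariates = covariates.loc[beta.columns]
    Xc = beta.to_numpy() - beta.to_numpy().mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, beta.shape[1] - 1)
    scores = (s[:k, None] * vt[:k]).T  # samples x components

    pvals: dict[str, list[float]] = {}
    for name in covariates.columns:
        col = covariates[name]
        if col.nunique(dropna=True) < 2:
            warnings.warn(f"covariate {name!r} is constant; excluded")
            continue
        ps = []
        for comp in range(k):
            y = scores[:, comp]
            if pd.api.types.is_numeric_dtype(col):
                ps.append(stats.spearmanr(col.to_numpy(dtype=float), y).pvalue)
            else:
                groups = [y[(col == g).to_numpy()] for g in col.unique()]
                groups = [g for g in groups if len(g) > 0]
                ps.append(stats.kruskal(*groups).pvalue if len(groups) > 1 else 1.0)
        pvals[name] = ps

    table = pd.DataFrame(pvals, index=[f"PC{i+1}" for i in range(k)])
    table.attrs["significant"] = table < alpha
    return table
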