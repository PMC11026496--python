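"""Class-membership scoring and the six-condition fidelity taxonomy.

A cell culture is scored against reference methylation-class centroids
(a documented surrogate for an externally trained classifier; externally
produced score tables can be supplied instead).  The maximum class score
categorizes a sample as faithful (score >= 0.84), useful (0.3 <= score
< 0.84) or unfaithful (score < 0.3); a culture whose assigned class
matches its histology with a non-unfaithful score has "maintained" DNAm.
Crossing DNAm status with the CNV similarity category (coincident /
similar / different) yields the six-condition taxonomy:

    ==========  ===========  =========
    DNAm        CNV          condition
    ==========  ===========  =========
    maintained  coincident   1
    maintained  similar      2
    maintained  different    3
    unfaithful  coincident   4
    unfaithful  similar      5
    unfaithful  different    6
    ==========  ===========  =========
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClassScore",
    "FidelityRecord",
    "FAITHFUL_MIN",
    "USEFUL_MIN",
    "CONDITION_MAP",
    "centroid_scores",
    "categorize",
    "match_assessment",
    "assign_condition",
    "fisher_exact_2x2",
    "chi_squared_test",
    "fidelity_report",
]

#: score >= FAITHFUL_MIN -> faithful; USEFUL_MIN <= score < FAITHFUL_MIN ->
#: useful; below -> unfaithful.  Boundary scores go to the upper category.
FAITHFUL_MIN = 0.84
USEFUL_MIN = 0.30

CONDITION_MAP = {
    ("maintained", "coincident"): 1,
    ("maintained", "similar"): 2,
    ("maintained", "different"): 3,
    ("unfaithful", "coincident"): 4,
    ("unfaithful", "similar"): 5,
    ("unfaithful", "different"): 6,
}


@dataclass
class ClassScore:
    sample_id: str
    scores: pd.Series        # per-class, sums to 1
    assigned: str
    max_score: float
    tied: bool = False


@dataclass
class FidelityRecord:
    cell_id: str
    tissue_id: str | None
    category: str                    # faithful | useful | unfaithful
    histology_match: bool
    dnam_status: str                 # maintained | unfaithful
    cnv_category: str | None = None  # coincident | similar | different | None
    condition: int | None = None


def centroid_scores(
    beta: pd.DataFrame, centroids: pd.DataFrame, sharpness: float = 10.0
) -> list[ClassScore]:
    """Softmax-calibrated correlation scores against class centroids.

    ``centroids`` is probes x classes over the same probe set as ``beta``.
    For sample s and class c, r_c = Pearson correlation of the sample's
    betas with centroid c, and score_c = softmax(sharpness * r)_c.
    """
    if centroids.shape[1] < 2:
        raise ValueError("need >= 2 class centroids")
    C = centroids.loc[beta.index]
    if (C.std(axis=0) == 0).any():
        raise ValueError("centroid with zero variance")
    out = []
    for sample in beta.columns:
        x = beta[sample].to_numpy()
        r = np.array(
            [stats.pearsonr(x, C[c].to_numpy()).statistic for c in C.columns]
        )
        e = np.exp(sharpness * (r - r.max()))
        scores = pd.Series(e / e.sum(), index=C.columns)
        top = scores.max()
        winners = sorted(scores.index[scores == top])
        out.append(
            ClassScore(
                sample_id=sample,
                scores=scores,
                assigned=winners[0],
                max_score=float(top),
                tied=len(winners) > 1,
            )
        )
    return out


def categorize(score: float) -> str:
    """Fidelity category from the maximum class score."""
    if not 0.0 <= score <= 1.0:
        raise ValueError("score must be in [0, 1]")
    if score >= FAITHFUL_MIN:
        return "faithful"
    if score >= USEFUL_MIN:
        return "useful"
    return "unfaithful"


def match_assessment(score: ClassScore, histology: str) -> tuple[bool, str]:
    """Does the assigned class match histology with a usable score?

    A sample matches when its assigned class equals the histology label and
    its category is not unfaithful; DNAm status is "maintained" on a match,
    "unfaithful" otherwise (wrong class or score < 0.3).
    """
    if histology not in score.scores.index:
        raise ValueError(f"unknown histology label: {histology}")
    match = (score.assigned == histology) and categorize(score.max_score) != "unfaithful"
    return match, ("maintained" if match else "unfaithful")


def assign_condition(dnam_status: str | None, cnv_category: str | None) -> int | None:
    """Map (DNAm status, CNV category) to condition 1..6; NA in -> NA out."""
    if dnam_status is None or cnv_category is None or cnv_category == "NA":
        return None
    key = (dnam_status, cnv_category)
    if key not in CONDITION_MAP:
        raise ValueError(f"undefined status combination: {key}")
    return CONDITION_MAP[key]


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Exact two-sided Fisher test for a 2x2 table.

    The two-sided p sums all hypergeometric probabilities not exceeding the
    observed table's (the minimum-likelihood method).  Returns the sample
    odds ratio and p; a zero margin gives p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        a, b, c, d = t.ravel()
        oddsratio = np.inf if b * c == 0 and a * d > 0 else (
            (a * d) / (b * c) if b * c else np.nan
        )
        return float(oddsratio) if np.isfinite(oddsratio) else oddsratio, 1.0
    res = stats.fisher_exact(t, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def chi_squared_test(table, correction: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square for an r x c table (no continuity correction by
    default; enable ``correction`` for Yates-corrected 2x2)."""
    t = np.asarray(table, dtype=float)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    res = stats.chi2_contingency(t, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def fidelity_report(
    records: list[FidelityRecord], sheet: pd.DataFrame
) -> dict[str, dict]:
    """Per-stratum fidelity summaries with association tests.

    For each culture-metadata stratification (medium, timing, dims) the
    report gives counts and whole-number percentages of faithful / useful /
    unfaithful cells and the condition distribution, plus a chi-square
    (Fisher when 2x2) p-value for faithful+useful vs unfaithful across the
    stratum levels.  Strata with zero cells are omitted with a note.
    """
    df = pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "category": [r.category for r in records],
            "condition": [r.condition for r in records],
        }
    ).set_index("cell_id")
    meta = sheet.loc[df.index]

    report: dict[str, dict] = {}
    for stratum in ("medium", "timing", "dims"):
        if stratum not in meta.columns:
            continue
        levels = [lv for lv in meta[stratum].unique() if lv != ""]
        counts = {}
        ok_rows = []
        notes = []
        for lv in levels:
            sub = df[meta[stratum] == lv]
            if len(sub) == 0:
                notes.append(f"stratum {lv!r} has zero cells; omitted")
                continue
            cat = sub["category"].value_counts().reindex(
                ["faithful", "useful", "unfaithful"], fill_value=0
            )
            pct = (cat / cat.sum() * 100).round().astype(int)
            counts[lv] = {
                "n": int(len(sub)),
                "categories": cat.to_dict(),
                "percent": pct.to_dict(),
                "conditions": sub["condition"].value_counts().sort_index().to_dict(),
            }
            ok_rows.append(
                [cat["faithful"] + cat["useful"], cat["unfaithful"]]
            )
        entry: dict = {"counts": counts, "notes": notes}
        if len(ok_rows) >= 2:
            tab = np.array(ok_rows)
            if (tab.sum(axis=0) > 0).all() and (tab.sum(axis=1) > 0).all():
                if tab.shape == (2, 2):
                    _, p = fisher_exact_2x2(tab)
                    entry["test"] = "fisher"
                else:
                    _, _, p = chi_squared_test(tab)
                    entry["test"] = "chi2"
                entry["p"] = p
        report[stratum] = entry
    return report
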