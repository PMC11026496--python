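"""Synthetic Infinium-style cohort generator with known ground truth.

Emulates the features of a methylation-array study of tumors and their
derived cell cultures that the downstream stages rely on:

* per-probe bimodal beta distributions (an unmethylated mode near 0.1 and a
  methylated mode near 0.85),
* histology-class methylation signatures over designated CpG sets,
* paired cell-line divergence — unfaithful cultures acquire a shared promoter
  hypomethylation panel and an attenuated class signature,
* copy-number segments encoded as scaling of the total probe intensity
  (methylated + unmethylated channels), with copy-neutral control samples,
* planted DMRs, detection-p and bead-count failures for QC tests.

All randomness flows from a single :func:`numpy.random.default_rng` seeded
by ``CohortDesign.seed``, so outputs are bit-identical across runs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

REGION_CLASSES = ("TSS200", "TSS1500", "1stExon", "Body", "IGR")
PROMOTER_CLASSES = ("TSS200", "TSS1500", "1stExon")

__all__ = [
    "REGION_CLASSES",
    "PROMOTER_CLASSES",
    "IntensitySet",
    "ClassSignature",
    "PairedCell",
    "PlantedDMR",
    "PlantedCNV",
    "CohortDesign",
    "GroundTruth",
    "build_manifest",
    "validate_manifest",
    "random_class_signatures",
    "default_design",
    "simulate_cohort",
    "write_dataset",
    "read_dataset",
    "write_gmt",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class IntensitySet:
    """Per-probe methylated/unmethylated channel intensities for a cohort.

    All four frames are probes x samples with identical index and columns.
    """

    M: pd.DataFrame
    U: pd.DataFrame
    detection_p: pd.DataFrame
    beadcount: pd.DataFrame

    def __post_init__(self) -> None:
        ref = self.M
        for name in ("U", "detection_p", "beadcount"):
            other = getattr(self, name)
            if not (other.index.equals(ref.index) and other.columns.equals(ref.columns)):
                raise ValueError(f"{name} is not aligned with M")
        if (self.M.values < 0).any() or (self.U.values < 0).any():
            raise ValueError("negative channel intensities")

    @property
    def samples(self) -> list[str]:
        return list(self.M.columns)

    @property
    def probes(self) -> pd.Index:
        return self.M.index

    def total(self) -> pd.DataFrame:
        """Combined intensity of both channels (the CNV signal carrier)."""
        return self.M + self.U


@dataclass
class ClassSignature:
    label: str
    cpgs: list[str]
    target_beta: float


@dataclass
class PairedCell:
    cell_id: str
    tissue_id: str
    divergence: str = "faithful"   # faithful | unfaithful
    medium: str = "serum_free"     # serum | serum_free
    timing: str = "early"          # early | late
    dims: str = "3D"               # 2D | 3D
    cnv_share: str = "coincident"  # designed CNV similarity to the tissue:
                                   # coincident (all segments) | similar
                                   # (a subset) | different (none)


@dataclass
class PlantedDMR:
    chrom: str
    start: int
    end: int
    delta_beta: float
    samples: list[str]


@dataclass
class PlantedCNV:
    chrom: str
    start: int
    end: int
    copies: int
    samples: list[str]

    def __post_init__(self) -> None:
        if self.copies not in (0, 1, 2, 3, 4):
            raise ValueError("copies must be in {0..4}")

    @property
    def log2_ratio(self) -> float:
        # copies=0 has no finite log-ratio; clip at -5 for bookkeeping
        return float(np.log2(self.copies / 2)) if self.copies else -5.0


@dataclass
class CohortDesign:
    """Everything :func:`simulate_cohort` needs besides the manifest."""

    classes: list[ClassSignature]
    n_tumors_per_class: int
    paired_cells: list[PairedCell] = field(default_factory=list)
    planted_dmrs: list[PlantedDMR] = field(default_factory=list)
    planted_cnvs: list[PlantedCNV] = field(default_factory=list)
    n_controls: int = 4
    noise_sd: float = 0.3            # logit-scale per-entry noise
    seed: int = 0
    divergence_genes: list[str] = field(default_factory=list)
    divergence_class: str | None = None  # class whose signature unfaithful
                                         # cultures acquire (drift target)
    signature_attenuation: float = 0.3   # retained fraction in unfaithful cells
    tumor_purity: float = 1.0            # attenuates planted CNV log-ratios
    total_intensity_median: float = 3000.0
    total_intensity_sigma: float = 0.25
    detp_failures: list[tuple[str, list[str]]] = field(default_factory=list)
    bead_failures: list[tuple[str, list[str]]] = field(default_factory=list)


@dataclass
class GroundTruth:
    true_class: dict[str, str]
    true_fidelity: dict[str, str]
    dmr_regions: list[PlantedDMR]
    cnv_segments: list[PlantedCNV]
    true_condition: dict[str, int] = field(default_factory=dict)


#: designed (divergence, cnv_share) -> six-condition code
_TRUE_CONDITION = {
    ("faithful", "coincident"): 1,
    ("faithful", "similar"): 2,
    ("faithful", "different"): 3,
    ("unfaithful", "coincident"): 4,
    ("unfaithful", "similar"): 5,
    ("unfaithful", "different"): 6,
}


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def build_manifest(
    n_probes: int,
    chrom_sizes: dict[str, int],
    gene_spacing: int = 100_000,
    seed: int = 0,
    promoter_frac: float = 0.25,
    type1_frac: float = 0.15,
    genic_frac: float = 0.7,
    blacklist_frac: float = 0.01,
    island_frac: float = 0.3,
    island_probes: int = 15,
    island_span: int = 1200,
) -> pd.DataFrame:
    """Place ``n_probes`` at sorted positions over the chromosomes.

    Probes are allotted to chromosomes proportionally to size.  A share
    ``island_frac`` of each chromosome's probes is grouped into dense
    CpG-island-like clusters of ``island_probes`` probes over
    ``island_span`` bp (Infinium designs concentrate probes in islands;
    dense runs are what region-level callers aggregate); the remainder is
    scattered uniformly.  Genic probes (a ``genic_frac`` share) carry a
    gene name derived from a tiling of ``gene_spacing``-bp gene
    territories; ``promoter_frac`` of them are annotated
    TSS200/TSS1500/1stExon, the rest Body; intergenic probes are IGR.
    ``type1_frac`` of probes are Infinium design type I.
    """
    if n_probes < 100:
        raise ValueError("n_probes must be >= 100")
    if not chrom_sizes:
        raise ValueError("chrom_sizes must be nonempty")
    rng = np.random.default_rng(seed)

    sizes = pd.Series(chrom_sizes, dtype=float)
    alloc = (sizes / sizes.sum() * n_probes).round().astype(int)
    # largest-remainder style fix-up so totals match exactly
    drift = n_probes - int(alloc.sum())
    if drift:
        order = sizes.sort_values(ascending=False).index
        for chrom in list(order) * (abs(drift) // len(order) + 1):
            if drift == 0:
                break
            alloc[chrom] += 1 if drift > 0 else -1
            drift += -1 if drift > 0 else 1
    for chrom, k in alloc.items():
        if k > chrom_sizes[chrom]:
            raise ValueError(
                f"chromosome {chrom} ({chrom_sizes[chrom]} bp) too small for {k} probes"
            )

    rows = []
    for chrom in chrom_sizes:
        k = int(alloc[chrom])
        if k == 0:
            continue
        n_islands = int(k * island_frac) // island_probes if island_probes else 0
        island_pos: list[np.ndarray] = []
        if n_islands and chrom_sizes[chrom] > 2 * island_span * n_islands:
            centers = np.sort(
                rng.choice(
                    chrom_sizes[chrom] - island_span, size=n_islands, replace=False
                )
            )
            for c in centers:
                offs = np.sort(
                    rng.choice(island_span, size=island_probes, replace=False)
                )
                island_pos.append(c + offs)
        n_scatter = k - sum(len(a) for a in island_pos)
        scatter = rng.choice(chrom_sizes[chrom], size=n_scatter, replace=False)
        pos = np.sort(np.concatenate([scatter, *island_pos])) + 1
        # enforce strictly increasing positions after merging
        for i in range(1, len(pos)):
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
        genic = rng.random(k) < genic_frac
        promoter = rng.random(k) < promoter_frac
        cls = rng.choice(PROMOTER_CLASSES, size=k)
        region = np.where(~genic, "IGR", np.where(promoter, cls, "Body"))
        gene = np.where(genic, [f"{chrom}g{p // gene_spacing}" for p in pos], "")
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos.astype(int),
                    "gene": gene,
                    "region_class": region,
                    "design_type": np.where(rng.random(k) < type1_frac, "I", "II"),
                    "blacklist_flag": rng.random(k) < blacklist_frac,
                    "sex_chrom_flag": chrom in ("chrX", "chrY", "X", "Y"),
                }
            )
        )
    manifest = pd.concat(rows, ignore_index=True)
    manifest.insert(0, "probe_id", [f"cg{i:08d}" for i in range(len(manifest))])
    manifest = manifest.set_index("probe_id", drop=False)
    validate_manifest(manifest)
    return manifest


def validate_manifest(manifest: pd.DataFrame) -> None:
    if manifest["probe_id"].duplicated().any():
        raise ValueError("duplicate probe ids")
    if not set(manifest["region_class"]) <= set(REGION_CLASSES):
        raise ValueError("unknown region class")
    for _, grp in manifest.groupby("chrom", sort=False):
        d = np.diff(grp["pos"].to_numpy())
        if (d <= 0).any():
            raise ValueError("positions not strictly increasing within chromosome")


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------

def random_class_signatures(
    manifest: pd.DataFrame,
    labels: list[str],
    n_cpgs: int = 60,
    rng: np.random.Generator | None = None,
) -> list[ClassSignature]:
    """Disjoint per-class CpG signatures, alternating methylated/unmethylated
    target levels so classes separate in both directions."""
    rng = rng or np.random.default_rng(0)
    pool = rng.permutation(manifest.index.to_numpy())
    if len(pool) < n_cpgs * len(labels):
        raise ValueError("manifest too small for requested signatures")
    out = []
    for i, label in enumerate(labels):
        cpgs = pool[i * n_cpgs : (i + 1) * n_cpgs].tolist()
        out.append(ClassSignature(label, cpgs, 0.85 if i % 2 == 0 else 0.10))
    return out


def find_dense_regions(
    manifest: pd.DataFrame, min_probes: int = 12, max_gap: int = 300
) -> list[tuple[str, int, int, int]]:
    """Runs of >= ``min_probes`` probes with inter-probe gaps <= ``max_gap``.

    Returns (chrom, start, end, n_probes) tuples — candidate territories for
    planting DMRs that a region caller can aggregate.
    """
    out = []
    for chrom, grp in manifest.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > max_gap)
        for chunk in np.split(np.arange(len(pos)), breaks + 1):
            if len(chunk) >= min_probes:
                out.append((chrom, int(pos[chunk[0]]), int(pos[chunk[-1]]), len(chunk)))
    return out


#: condition cycle used by :func:`default_design`: (divergence, cnv_share)
_CONDITION_PATTERN = (
    ("faithful", "coincident"),
    ("faithful", "similar"),
    ("faithful", "different"),
    ("unfaithful", "coincident"),
    ("unfaithful", "similar"),
    ("unfaithful", "different"),
)


def default_design(
    manifest: pd.DataFrame,
    seed: int = 0,
    labels: tuple[str, ...] = ("MB", "LGG", "HGG", "DMG"),
    divergence_label: str = "MNG",
    n_tumors_per_class: int = 5,
    n_pairs_per_class: int = 6,
    n_controls: int = 6,
    noise_sd: float = 0.3,
    n_divergence_genes: int = 30,
    signature_cpgs: int = 60,
    n_planted_dmrs: int = 3,
) -> CohortDesign:
    """A paired tumor / cell-culture cohort with all six fidelity conditions.

    Each histology class contributes ``n_pairs_per_class`` paired cultures
    cycling through the six (DNAm, CNV) design conditions: DNAm-maintained
    cultures are serum-free / early / 3D, divergent ones serum / late / 2D
    (divergence co-occurs with those culture conditions by design).
    Divergent cultures drift toward the ``divergence_label`` class
    (a meningioma-like attractor signature) and acquire a shared promoter
    hypomethylation panel plus planted hypomethylation DMRs.  Each class's
    tumors carry two CNV segments (a 3-copy gain and a 1-copy loss) on the
    class's own chromosome; a culture carries both, one, or none of them
    according to its designed CNV share (coincident / similar / different).
    """
    rng = np.random.default_rng(seed)
    all_labels = list(labels) + [divergence_label]
    classes = random_class_signatures(manifest, all_labels, signature_cpgs, rng)

    genes = manifest.loc[
        manifest["region_class"].isin(PROMOTER_CLASSES), "gene"
    ].unique()
    genes = genes[genes != ""]
    divergence_genes = rng.choice(
        genes, size=min(n_divergence_genes, len(genes)), replace=False
    ).tolist()

    paired, cnvs = [], []
    chroms = list(dict.fromkeys(manifest["chrom"]))
    for ci, label in enumerate(labels):
        tumors = [f"{label}_T{i+1}" for i in range(n_tumors_per_class)]
        class_cells = []
        for j in range(n_pairs_per_class):
            divergence, share = _CONDITION_PATTERN[j % len(_CONDITION_PATTERN)]
            unfaithful = divergence == "unfaithful"
            cell = PairedCell(
                cell_id=f"{label}_C{j+1}",
                tissue_id=tumors[j % n_tumors_per_class],
                divergence=divergence,
                medium="serum" if unfaithful else "serum_free",
                timing="late" if unfaithful else "early",
                dims="2D" if unfaithful else "3D",
                cnv_share=share,
            )
            paired.append(cell)
            class_cells.append(cell)
        # two planted segments on the class's chromosome: a gain and a loss
        chrom = chroms[ci % len(chroms)]
        cpos = manifest.loc[manifest["chrom"] == chrom, "pos"]
        segments = [
            (int(cpos.quantile(0.05)), int(cpos.quantile(0.35)), 3),
            (int(cpos.quantile(0.55)), int(cpos.quantile(0.85)), 1),
        ]
        for si, (lo, hi, copies) in enumerate(segments):
            carriers = list(tumors)
            for cell in class_cells:
                if cell.cnv_share == "coincident" or (
                    cell.cnv_share == "similar" and si == 0
                ):
                    carriers.append(cell.cell_id)
            cnvs.append(PlantedCNV(chrom, lo, hi, copies, carriers))

    # plant hypomethylation DMRs carried by every unfaithful culture, on
    # dense (island-like) probe runs so a region caller can aggregate them
    unfaithful_cells = [p.cell_id for p in paired if p.divergence == "unfaithful"]
    dmrs = []
    dense = find_dense_regions(manifest)
    for chrom, start, end, _ in dense[: n_planted_dmrs if unfaithful_cells else 0]:
        dmrs.append(PlantedDMR(chrom, start, end, -0.3, list(unfaithful_cells)))

    return CohortDesign(
        classes=classes,
        n_tumors_per_class=n_tumors_per_class,
        paired_cells=paired,
        planted_dmrs=dmrs,
        planted_cnvs=cnvs,
        n_controls=n_controls,
        noise_sd=noise_sd,
        seed=seed,
        divergence_genes=divergence_genes,
        divergence_class=divergence_label,
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _roster(design: CohortDesign) -> pd.DataFrame:
    rows = []
    for sig in design.classes:
        for i in range(design.n_tumors_per_class):
            rows.append(
                dict(sample_id=f"{sig.label}_T{i+1}", role="tumor",
                     histology=sig.label, medium="", timing="", dims="", pair_id="")
            )
    tumor_ids = {r["sample_id"] for r in rows}
    tumor_class = {r["sample_id"]: r["histology"] for r in rows}
    for pc in design.paired_cells:
        if pc.tissue_id not in tumor_ids:
            raise ValueError(f"paired cell {pc.cell_id} references unknown tissue {pc.tissue_id}")
        rows.append(
            dict(sample_id=pc.cell_id, role="cell",
                 histology=tumor_class[pc.tissue_id], medium=pc.medium,
                 timing=pc.timing, dims=pc.dims, pair_id=pc.tissue_id)
        )
    for i in range(design.n_controls):
        rows.append(dict(sample_id=f"CTRL_{i+1}", role="control",
                         histology="", medium="", timing="", dims="", pair_id=""))
    if not rows:
        raise ValueError("empty cohort")
    sheet = pd.DataFrame(rows).set_index("sample_id", drop=False)
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in design")
    return sheet


def simulate_cohort(
    manifest: pd.DataFrame, design: CohortDesign
) -> tuple[IntensitySet, pd.DataFrame, GroundTruth]:
    """Simulate channel intensities, a sample sheet and the ground truth.

    The generative model: a bimodal per-probe baseline beta; class
    signatures overriding designated CpGs; unfaithful cultures receive the
    shared promoter-hypomethylation divergence panel and an attenuated class
    signature; logit-normal noise; beta is converted to channels through a
    lognormal total intensity T (``M = T*beta``, ``U = T*(1-beta)``), and
    planted CNV segments scale T by ``copies/2`` (attenuated by tumor
    purity).  Copy-neutral controls carry no CNV.
    """
    validate_manifest(manifest)
    sheet = _roster(design)
    if len(sheet) == 0:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(design.seed)
    n_probes, n_samples = len(manifest), len(sheet)
    probes = manifest.index
    samples = sheet.index

    # --- baseline bimodal beta per probe
    mode = rng.choice(3, size=n_probes, p=(0.45, 0.45, 0.10))
    baseline = np.where(
        mode == 0,
        rng.beta(5.0, 45.0, size=n_probes),
        np.where(
            mode == 1,
            rng.beta(38.25, 6.75, size=n_probes),
            rng.uniform(0.25, 0.75, size=n_probes),
        ),
    )

    beta = np.tile(baseline[:, None], (1, n_samples))
    sig_by_label = {s.label: s for s in design.classes}
    probe_pos = {p: i for i, p in enumerate(probes)}

    cell_meta = {pc.cell_id: pc for pc in design.paired_cells}
    divergence_probes = manifest.index[
        manifest["gene"].isin(design.divergence_genes)
        & manifest["region_class"].isin(PROMOTER_CLASSES)
    ]
    div_idx = np.array([probe_pos[p] for p in divergence_probes], dtype=int)

    true_fidelity: dict[str, str] = {}
    for j, sid in enumerate(samples):
        row = sheet.loc[sid]
        label = row["histology"]
        if label and label in sig_by_label:
            sig = sig_by_label[label]
            idx = np.array([probe_pos[p] for p in sig.cpgs if p in probe_pos], dtype=int)
            strength = 1.0
            if row["role"] == "cell":
                fid = cell_meta[sid].divergence
                true_fidelity[sid] = fid
                if fid == "unfaithful":
                    strength = design.signature_attenuation
            beta[idx, j] = baseline[idx] + strength * (sig.target_beta - baseline[idx])
            if row["role"] == "cell" and true_fidelity[sid] == "unfaithful":
                # drift toward the attractor class signature, if designed
                att = sig_by_label.get(design.divergence_class or "")
                if att is not None:
                    aidx = np.array(
                        [probe_pos[p] for p in att.cpgs if p in probe_pos], dtype=int
                    )
                    beta[aidx, j] = baseline[aidx] + (att.target_beta - baseline[aidx])
                if len(div_idx):
                    beta[div_idx, j] = 0.07  # shared promoter hypomethylation

    # --- planted DMRs: make room for the shift in every sample's baseline so
    # the planted difference is recoverable by construction, then shift the
    # affected group; truncation (with warning) only for infeasible targets
    for dmr in design.planted_dmrs:
        in_region = (
            (manifest["chrom"] == dmr.chrom)
            & (manifest["pos"] >= dmr.start)
            & (manifest["pos"] <= dmr.end)
        ).to_numpy()
        lo = 0.01 + max(0.0, -dmr.delta_beta)
        hi = 0.99 - max(0.0, dmr.delta_beta)
        if lo > hi:
            warnings.warn("planted DMR pushes beta outside (0,1); clipping to [0.01, 0.99]")
            lo = hi = 0.5
        beta[in_region, :] = np.clip(beta[in_region, :], lo, hi)
        cols = [sheet.index.get_loc(s) for s in dmr.samples]
        shifted = beta[np.ix_(in_region, cols)] + dmr.delta_beta
        if (shifted < 0.0099).any() or (shifted > 0.9901).any():
            warnings.warn("planted DMR pushes beta outside (0,1); clipping to [0.01, 0.99]")
        beta[np.ix_(in_region, cols)] = np.clip(shifted, 0.01, 0.99)

    # --- logit-normal noise
    noisy = expit(
        logit(np.clip(beta, 1e-3, 1 - 1e-3))
        + rng.normal(0.0, design.noise_sd, size=beta.shape)
    )

    # --- channels
    T = rng.lognormal(
        mean=np.log(design.total_intensity_median),
        sigma=design.total_intensity_sigma,
        size=beta.shape,
    )
    control_ids = set(sheet.index[sheet["role"] == "control"])
    for seg in design.planted_cnvs:
        bad = control_ids & set(seg.samples)
        if bad:
            raise ValueError(f"copy-neutral controls cannot carry CNV: {sorted(bad)}")
        in_seg = (
            (manifest["chrom"] == seg.chrom)
            & (manifest["pos"] >= seg.start)
            & (manifest["pos"] <= seg.end)
        ).to_numpy()
        factor = 1.0 + design.tumor_purity * (seg.copies / 2.0 - 1.0)
        factor = max(factor, 0.025)
        cols = [sheet.index.get_loc(s) for s in seg.samples]
        T[np.ix_(in_seg, cols)] *= factor

    M = pd.DataFrame(T * noisy, index=probes, columns=samples)
    U = pd.DataFrame(T * (1.0 - noisy), index=probes, columns=samples)

    detp = pd.DataFrame(
        rng.uniform(0.0, 0.009, size=beta.shape), index=probes, columns=samples
    )
    beads = pd.DataFrame(
        rng.integers(8, 31, size=beta.shape), index=probes, columns=samples
    )
    for probe, sids in design.detp_failures:
        detp.loc[probe, sids] = 0.05
    for probe, sids in design.bead_failures:
        beads.loc[probe, sids] = 2

    truth = GroundTruth(
        true_class={s: sheet.loc[s, "histology"] for s in samples if sheet.loc[s, "histology"]},
        true_fidelity=true_fidelity,
        dmr_regions=list(design.planted_dmrs),
        cnv_segments=list(design.planted_cnvs),
        true_condition={
            pc.cell_id: _TRUE_CONDITION[(pc.divergence, pc.cnv_share)]
            for pc in design.paired_cells
        },
    )
    return IntensitySet(M, U, detp, beads), sheet, truth


# ---------------------------------------------------------------------------
# on-disk dataset
# ---------------------------------------------------------------------------

_MATRICES = ("M", "U", "detp", "beads")
_ATTRS = dict(M="M", U="U", detp="detection_p", beads="beadcount")


def write_dataset(
    outdir: str | Path,
    intensities: IntensitySet,
    manifest: pd.DataFrame,
    sheet: pd.DataFrame,
    truth: GroundTruth,
    genesets: dict[str, list[str]] | None = None,
    overwrite: bool = False,
) -> None:
    """Write the cohort as plain TSV/BED/JSON (round-trips to 1e-9)."""
    if len(intensities.samples) == 0:
        raise ValueError("empty cohort")
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} is not empty (pass overwrite=True)")
    outdir.mkdir(parents=True, exist_ok=True)

    for key in _MATRICES:
        getattr(intensities, _ATTRS[key]).to_csv(
            outdir / f"intensities_{key}.tsv", sep="\t", index_label="probe_id"
        )
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    bed = pd.DataFrame(
        {
            "chrom": manifest["chrom"],
            "start": manifest["pos"] - 1,  # BED is 0-based half-open
            "end": manifest["pos"],
            "name": manifest["probe_id"],
        }
    )
    bed.to_csv(outdir / "manifest.bed", sep="\t", index=False, header=False)
    sheet.to_csv(outdir / "samplesheet.tsv", sep="\t", index=False)
    payload = {
        "true_class": truth.true_class,
        "true_fidelity": truth.true_fidelity,
        "dmr_regions": [asdict(d) for d in truth.dmr_regions],
        "cnv_segments": [asdict(c) for c in truth.cnv_segments],
        "true_condition": truth.true_condition,
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=1))
    if genesets is not None:
        write_gmt(outdir / "genesets.gmt", genesets)


def write_gmt(path: str | Path, genesets: dict[str, list[str]],
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for term, genes in genesets.items():
            desc = descriptions.get(term, "na")
            fh.write("\t".join([term, desc, *genes]) + "\n")


def read_dataset(
    outdir: str | Path,
) -> tuple[IntensitySet, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Inverse of :func:`write_dataset` (intensities, manifest, sheet, truth)."""
    outdir = Path(outdir)
    mats = {
        key: pd.read_csv(outdir / f"intensities_{key}.tsv", sep="\t", index_col="probe_id")
        for key in _MATRICES
    }
    intensities = IntensitySet(mats["M"], mats["U"], mats["detp"], mats["beads"])
    manifest = pd.read_csv(
        outdir / "manifest.tsv", sep="\t", keep_default_na=False,
        dtype={"gene": str, "chrom": str},
    ).set_index("probe_id", drop=False)
    sheet = pd.read_csv(
        outdir / "samplesheet.tsv", sep="\t", keep_default_na=False,
        dtype=str,
    ).set_index("sample_id", drop=False)
    raw = json.loads((outdir / "truth.json").read_text())
    truth = GroundTruth(
        true_class=raw["true_class"],
        true_fidelity=raw["true_fidelity"],
        dmr_regions=[PlantedDMR(**d) for d in raw["dmr_regions"]],
        cnv_segments=[PlantedCNV(**c) for c in raw["cnv_segments"]],
        true_condition={k: int(v) for k, v in raw.get("true_condition", {}).items()},
    )
    return intensities, manifest, sheet, truth
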