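import warnings

import numpy as np
import pandas as pd
import pytest

from methfidelity import synthetic as syn


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run on the default synthetic cohort (24 pairs)."""
    from methfidelity import pipeline

    outdir = tmp_path_factory.mktemp("run")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary = pipeline.run_all(outdir, seed=7)
    return outdir, summary


@pytest.fixture(scope="session")
def manifest():
    return syn.build_manifest(
        3000, {"chr1": 8_000_000, "chr2": 6_000_000}, seed=11
    )


@pytest.fixture(scope="session")
def cohort(manifest):
    """Default paired cohort (24 pairs cycling the six conditions)."""
    design = syn.default_design(manifest, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        intensities, sheet, truth = syn.simulate_cohort(manifest, design)
    return design, intensities, sheet, truth


def toy_intensities(M, U, detp=None, beads=None, prefix="s"):
    """Small IntensitySet from arrays (probes x samples)."""
    M = np.asarray(M, dtype=float)
    probes = pd.Index([f"cg{i}" for i in range(M.shape[0])], name="probe_id")
    samples = [f"{prefix}{j}" for j in range(M.shape[1])]
    as_df = lambda x, fill: pd.DataFrame(
        np.asarray(x, dtype=float) if x is not None else np.full(M.shape, fill),
        index=probes, columns=samples,
    )
    return syn.IntensitySet(
        M=as_df(M, 0), U=as_df(U, 0),
        detection_p=as_df(detp, 0.001), beadcount=as_df(beads, 10),
    )


def toy_manifest(n, chrom="chr1", spacing=1000, **overrides):
    """Evenly spaced single-chromosome manifest for hand-traced examples."""
    df = pd.DataFrame(
        {
            "probe_id": [f"cg{i}" for i in range(n)],
            "chrom": chrom,
            "pos": np.arange(1, n + 1) * spacing,
            "gene": [f"g{i // 10}" for i in range(n)],
            "region_class": "Body",
            "design_type": "II",
            "blacklist_flag": False,
            "sex_chrom_flag": False,
        }
    )
    for key, val in overrides.items():
        df[key] = val
    return df.set_index("probe_id", drop=False)
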