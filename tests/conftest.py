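import json
from pathlib import Path

import pandas as pd
import pytest
from hypothesis import settings

from fieldamp import pipeline, simdata
from fieldamp.io_core import read_sample_sheet

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def community12():
    """A 12-species community with congeneric pairs and two bycatch taxa."""
    return simdata.simulate_references(12, divergence=0.10, seed=1, n_bycatch=2)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One full simulated workflow run shared by end-to-end tests.

    Six sites, two field replicates, one RPA replicate, 120 reads per sample,
    a third of the community absent from the base reference database.
    """
    outdir = tmp_path_factory.mktemp("run")
    config = pipeline.PipelineConfig.small(seed=1)
    report = pipeline.run_all(config, outdir)
    return {
        "config": config,
        "report": report,
        "outdir": Path(outdir),
        "sheet": read_sample_sheet(outdir / "sample_sheet.tsv"),
        "hits_base": pd.read_csv(outdir / "hits_base.tsv", sep="\t"),
        "hits_combined": pd.read_csv(outdir / "hits_combined.tsv", sep="\t"),
        "truth": pd.read_csv(outdir / "truth.tsv", sep="\t"),
    }
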