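import datetime as dt
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import sasvtrace as st


@pytest.fixture(scope="session")
def noiseless_sim():
    """Default noiseless simulation: planted curves S_75=0.829, b=-1.34 above
    250 m, b=+0.31 below."""
    return st.simulate_dataset(st.SimConfig())


@pytest.fixture(scope="session")
def noiseless_products(tmp_path_factory):
    """Full pipeline products on the default noiseless simulation."""
    outdir = tmp_path_factory.mktemp("pipeline_noiseless")
    cfg = st.PipelineConfig(simulate=st.SimConfig())
    return st.run_pipeline(cfg, outdir)


@pytest.fixture
def tiny_dataset(tmp_path: Path):
    """3 ASVs x 2 water samples on disk (counts TSV + FASTA + metadata CSV)."""
    counts = tmp_path / "counts.tsv"
    counts.write_text(
        "asv_id\tS1\tS2\n"
        "A\t2\t1\n"
        "B\t3\t0\n"
        "C\t5\t9\n"
    )
    fasta = tmp_path / "asvs.fasta"
    fasta.write_text(">A\nACGTACGT\n>B\nTTTTACGT\n>C\nGGGGACGT\n")
    meta = tmp_path / "meta.csv"
    meta.write_text(
        "sample_id,compartment,depth_m,date_start\n"
        "S1,water,75,2015-03-10\n"
        "S2,water,75,2016-03-12\n"
    )
    return {"counts": counts, "fasta": fasta, "metadata": meta,
            "dir": tmp_path}


def make_climatology(entries):
    """Build a MonthlyClimatology from {(depth, month): {asv: abundance}}."""
    data = {k: pd.Series(v, dtype=float) for k, v in entries.items()}
    return st.MonthlyClimatology(data=data,
                                 n_years={k: 1 for k in data})
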