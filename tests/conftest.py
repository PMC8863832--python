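import numpy as np
import pandas as pd
import pytest

from lfqpipe import RunDesign, RunSpec, SyntheticSpec, generate_dataset


@pytest.fixture
def tiny_design() -> RunDesign:
    """2 groups x 2 samples x 2 duplicate runs."""
    runs = []
    for g in ("ctrl", "trt"):
        for i in (1, 2):
            sid = f"{g}{i}"
            runs.append(RunSpec(f"{sid}_r1", sid, 1, g))
            runs.append(RunSpec(f"{sid}_r2", sid, 2, g))
    return RunDesign(runs=runs, groups=["ctrl", "trt"], reference="ctrl")


@pytest.fixture
def tiny_pg_file(tmp_path, tiny_design):
    """3-row proteinGroups fixture with one reverse hit and scientific
    notation in one intensity cell."""
    runs = tiny_design.run_labels
    header = [
        "Protein IDs", "Majority protein IDs", "Gene names", "Reverse",
        "Potential contaminant", "Only identified by site",
    ] + [f"LFQ intensity {r}" for r in runs]
    rows = [
        ["P1;P1b", "P1", "Alb", "", "", ""] + ["1e7"] + ["2000000"] * (len(runs) - 1),
        ["P2", "P2", "Ftl1", "", "", ""] + ["0"] + ["3000000"] * (len(runs) - 1),
        ["REV_P3", "REV_P3", "", "+", "", ""] + ["1000000"] * len(runs),
    ]
    path = tmp_path / "proteinGroups.txt"
    path.write_text(
        "\n".join("\t".join(map(str, r)) for r in [header] + rows) + "\n"
    )
    return path


@pytest.fixture(scope="session")
def small_study():
    """A 300-protein synthetic study with default-style noise and dropout."""
    spec = SyntheticSpec(n_proteins=300, seed=11)
    table, design, truth = generate_dataset(spec)
    return spec, table, design, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
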