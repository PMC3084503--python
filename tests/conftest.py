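import numpy as np
import pytest

from surfcons.pipeline import RunConfig, run_pipeline
from surfcons.synthetic import make_variant_benchmark

PDB_FIXTURE = """REMARK 465   M RES C SSSEQI
REMARK 465     GLY A     6
REMARK 465     GLY A     7
ATOM      1  N   GLY A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  GLY A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  CA AGLY A  10      11.639   6.071  -5.147  0.60  0.00           C
ATOM      4  CA BGLY A  10      12.639   6.071  -5.147  0.40  0.00           C
ATOM      5  O   HOH A  99       0.000   0.000   0.000  1.00  0.00           O
ATOM      6  H   GLY A   1       0.000   0.000   0.000  1.00  0.00           H
HETATM    7 SE   MSE B   5       1.000   2.000   3.000  1.00  0.00          SE
ATOM      8  CA  ALA B   6       5.000   2.000   3.000  1.00  0.00           C
"""


@pytest.fixture(scope="session")
def benchmark():
    """Planted-truth synthetic study, generated once per session."""
    return make_variant_benchmark(seed=1)


@pytest.fixture(scope="session")
def benchmark_run(benchmark, tmp_path_factory):
    """Full pipeline executed on the written benchmark fixture files."""
    out = tmp_path_factory.mktemp("bench")
    paths = benchmark.write(out)
    cfg = RunConfig(
        structures_dir=str(out / "structures"),
        msas={"synmsa": {"msa": str(paths["msa"]), "tree": str(paths["tree"])}},
        variant_tables=[str(paths["variants"])],
        numbering_map=str(paths["numbering"]),
        output_dir=str(out / "run"),
        seed=1,
    )
    return run_pipeline(cfg), cfg, paths
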