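import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from flipper.pipeline import calibrate_config
from flipper.synthetic import (
    CLASS_LINKER,
    SyntheticSpec,
    generate_proteome,
    make_reference_linker,
)

BENCHMARK_SEED = 1


@pytest.fixture(scope="session")
def benchmark_proteome():
    """The default planted-recovery benchmark: 10 linkers + 600 decoys."""
    spec = SyntheticSpec(seed=BENCHMARK_SEED)
    records, truth = generate_proteome(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def benchmark_config():
    """Filter config calibrated from the fixed mid-range reference linker."""
    ref = make_reference_linker(seed=10_000 + BENCHMARK_SEED)
    return calibrate_config(ref)


@pytest.fixture(scope="session")
def linker_ids(benchmark_proteome):
    _, records, truth = benchmark_proteome
    classes = {t["id"]: t["class"] for t in truth}
    return {r.id for r in records if classes[r.id] == CLASS_LINKER}


@pytest.fixture()
def write_fasta_file(tmp_path):
    def _write(text: str, name: str = "input.fasta") -> Path:
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write
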