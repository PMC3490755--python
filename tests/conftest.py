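"""Shared fixtures: hand-written toy structures and session-scoped synthetic benchmarks."""

import numpy as np
import pytest

from rnaiface.pipeline import load_benchmark
from rnaiface.synthetic import SyntheticSpec, gen_benchmark


def pdb_atom(serial, name, resname, chain, resseq, x, y, z, element, record="ATOM"):
    return (
        f"{record:<6s}{serial:5d} {name:<4s}{resname:>4s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}\n"
    )


@pytest.fixture
def toy_complex_text():
    """3 amino acids on a line + 2 RNA nucleotides; residue 2 and 3 are within
    5 A of the RNA, residue 1 is not."""
    lines = [
        pdb_atom(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C"),
        pdb_atom(2, "CA", "GLY", "A", 2, 3.8, 0.0, 0.0, "C"),
        pdb_atom(3, "CA", "SER", "A", 3, 7.6, 0.0, 0.0, "C"),
        "TER\n",
        pdb_atom(4, "P", "A", "B", 1, 3.8, 4.0, 0.0, "P"),
        pdb_atom(5, "P", "U", "B", 2, 7.6, 4.5, 0.0, "P"),
        "TER\nEND\n",
    ]
    return "".join(lines)


@pytest.fixture
def toy_complex(tmp_path, toy_complex_text):
    from rnaiface.structio import read_complex

    path = tmp_path / "toy.pdb"
    path.write_text(toy_complex_text)
    return read_complex(path)


@pytest.fixture(scope="session")
def bench(tmp_path_factory):
    """Default-condition synthetic benchmark (20 chains, delta=2) loaded as a
    sequence-variant dataset with profiles."""
    d = tmp_path_factory.mktemp("bench")
    spec = SyntheticSpec(seed=7)
    gen_benchmark(spec, d)
    dataset, profiles = load_benchmark(d, cutoff=spec.cutoff, variant="sequence")
    return {"dir": d, "spec": spec, "dataset": dataset, "profiles": profiles}


@pytest.fixture(scope="session")
def bench_unsolved(tmp_path_factory):
    """Benchmark with 20% unsolved residues for variant-bookkeeping checks."""
    d = tmp_path_factory.mktemp("bench_unsolved")
    spec = SyntheticSpec(seed=11, n_chains=6, unsolved_fraction=0.2)
    gen_benchmark(spec, d)
    dataset, profiles = load_benchmark(d, cutoff=spec.cutoff, variant="sequence")
    return {"dir": d, "spec": spec, "dataset": dataset, "profiles": profiles}


@pytest.fixture
def rng():
    return np.random.default_rng(42)
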