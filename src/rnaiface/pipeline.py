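"""End-to-end plumbing: assemble labeled datasets from a directory of inputs.

A benchmark directory holds one PDB file per complex, a single FASTA of
full-chain sequences (ids ``<pdb_id>_<chain_id>``), and one PSI-BLAST ASCII
PSSM per chain named ``<pdb_id>_<chain_id>.pssm``. This is the layout the
synthetic generator writes and the layout the cv subcommand consumes.
"""

from __future__ import annotations

from pathlib import Path

from .labeling import DEFAULT_CUTOFF, Dataset, LabeledChain, label_interface, make_dataset
from .structio import PSSMProfile, read_complex, read_fasta, read_pssm

__all__ = ["load_benchmark"]


def load_benchmark(
    directory: str | Path,
    cutoff: float = DEFAULT_CUTOFF,
    variant: str = "sequence",
    atom_policy: str = "all",
) -> tuple[Dataset, dict[tuple[str, str], PSSMProfile]]:
    """Label every protein chain of every complex in a benchmark directory.

    Returns the dataset (under the requested variant) and the per-chain PSSM
    profiles keyed by (pdb_id, chain_id).
    """
    directory = Path(directory)
    pdb_files = sorted(directory.glob("*.pdb"))
    if not pdb_files:
        raise FileNotFoundError(f"no PDB files in {directory}")
    fasta_files = sorted(directory.glob("*.fasta")) + sorted(directory.glob("*.fa"))
    sequences = {}
    for f in fasta_files:
        for rec in read_fasta(f):
            sequences[rec.id] = rec

    chains: list[LabeledChain] = []
    profiles: dict[tuple[str, str], PSSMProfile] = {}
    for pdb_path in pdb_files:
        cx = read_complex(pdb_path)
        if not cx.protein_chains() or not cx.rna_chains():
            continue
        for chain in cx.protein_chains():
            key = (cx.pdb_id, chain.chain_id)
            full = sequences.get(f"{cx.pdb_id}_{chain.chain_id}")
            labeled = label_interface(
                cx, chain.chain_id, full_seq=full, cutoff=cutoff, atom_policy=atom_policy
            )
            chains.append(labeled)
            pssm_path = directory / f"{cx.pdb_id}_{chain.chain_id}.pssm"
            if pssm_path.exists():
                profiles[key] = read_pssm(pssm_path)
    return make_dataset(chains, variant), profiles
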