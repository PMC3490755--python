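"""Deterministic synthetic protein-RNA benchmark generator.

Generates toy complexes with a planted, geometrically guaranteed interface
patch plus matching full-chain sequences and PSSM files carrying a tunable
class-conditional signal, so that every pipeline stage (parsing, labeling,
encoding, training, cross-validation) can be exercised end to end without any
downloaded data.

Geometry: the protein is a pseudo-backbone of CA atoms spaced 3.8 A along a
line, each with two slightly jittered side atoms; a pseudo-RNA strand sits at
``d_near`` (< labeling cutoff) above a contiguous patch of residues and
nowhere near the rest (the nearest non-patch residue is at least
sqrt(3.8^2 + (d_near - jitter)^2) > 5 A away for the defaults), so labeling
at the spec cutoff recovers the planted patch exactly. PSSM raw scores are
N(0, sigma^2) noise with a mean shift ``delta`` added to ``k_signal`` fixed
columns at interface positions.

These pseudo-structures are geometrically valid but not physically realistic;
every consumer in the pipeline depends only on coordinates, distances and
scores, which is what the generator controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._tables import AA1_TO_3, AA_ALPHABET
from .structio import PSSMProfile, SequenceRecord, write_fasta, write_pssm

__all__ = ["SyntheticSpec", "gen_complex", "gen_pssm", "gen_benchmark"]

BACKBONE_STEP = 3.8  # CA-CA spacing, Angstrom
SIDE_JITTER = 0.4  # max radial jitter of pseudo side atoms
RNA_STEP = 3.3


@dataclass(frozen=True)
class SyntheticSpec:
    n_chains: int = 20
    length_range: tuple[int, int] = (50, 70)
    patch_length: int = 8
    d_near: float = 4.0  # RNA offset above patch residues (< cutoff)
    d_far_min: float = 5.5  # guaranteed clearance for non-patch residues
    cutoff: float = 5.0
    delta: float = 2.0  # mean shift on signal PSSM columns at interface positions
    sigma: float = 1.0  # PSSM score noise sd
    k_signal: int = 5
    unsolved_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.d_near < self.cutoff:
            raise ValueError("d_near must be below the labeling cutoff")
        if self.delta < 0 or self.sigma <= 0:
            raise ValueError("delta must be >= 0 and sigma > 0")
        if not 0 <= self.unsolved_fraction < 1:
            raise ValueError("unsolved_fraction must be in [0, 1)")
        if self.patch_length > self.length_range[0]:
            raise ValueError("patch longer than the shortest chain")
        if self.patch_length < 3:
            raise ValueError("patch must span at least 3 residues")
        # adjacent residue clearance: one backbone step sideways, jittered side
        # atoms can close the vertical gap by at most SIDE_JITTER
        clearance = (BACKBONE_STEP**2 + (self.d_near - SIDE_JITTER) ** 2) ** 0.5
        if clearance <= self.cutoff:
            raise ValueError(
                f"geometry does not guarantee exact recovery: nearest non-patch "
                f"clearance {clearance:.2f} <= cutoff {self.cutoff}"
            )


def _chain_rng(spec: SyntheticSpec, chain_index: int, stream: int) -> np.random.Generator:
    # one generator per (chain, artifact) so fixtures are independently reproducible
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(chain_index, stream))
    )


def _pdb_atom_line(serial, name, resname, chain_id, resseq, xyz, element) -> str:
    return (
        f"ATOM  {serial:5d} {name:<4s}{resname:>4s} {chain_id}{resseq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          {element:>2s}\n"
    )


def gen_complex(
    spec: SyntheticSpec, chain_index: int
) -> tuple[str, SequenceRecord, np.ndarray]:
    """One toy complex: PDB text, full-chain sequence record, truth labels.

    Protein chain 'A' (one CA + two jittered side atoms per solved residue),
    RNA chain 'B' above the planted patch. Truth labels mark the patch; a
    seeded fraction of non-patch residues is left out of the coordinates but
    kept in the sequence (truth label 0).
    """
    rng = _chain_rng(spec, chain_index, 0)
    n = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    # patch start ranges over clipped placements (>=3 residues remain inside the
    # chain) so that every residue has near-equal marginal patch probability;
    # without clipping, termini would be systematically non-interface and window
    # padding would leak label information even with no profile signal
    L = spec.patch_length
    patch_start = int(rng.integers(3 - L, n - 2))
    lo, hi = max(0, patch_start), min(n, patch_start + L)
    patch = np.zeros(n, dtype=int)
    patch[lo:hi] = 1

    seq = "".join(rng.choice(list(AA_ALPHABET), size=n))
    non_patch = np.flatnonzero(patch == 0)
    n_unsolved = int(round(spec.unsolved_fraction * n))
    n_unsolved = min(n_unsolved, len(non_patch))
    unsolved = set(rng.choice(non_patch, size=n_unsolved, replace=False).tolist())

    lines = []
    serial = 1
    for i in range(n):
        if i in unsolved:
            continue
        resname = AA1_TO_3[seq[i]]
        ca = np.array([BACKBONE_STEP * i, 0.0, 0.0])
        lines.append(_pdb_atom_line(serial, "CA", resname, "A", i + 1, ca, "C"))
        serial += 1
        for k, name in enumerate(("CB", "CG")):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            side = ca + SIDE_JITTER * rng.uniform(0.2, 1.0) * direction
            lines.append(_pdb_atom_line(serial, name, resname, "A", i + 1, side, "C"))
            serial += 1
    lines.append("TER\n")

    patch_positions = list(range(lo, hi))
    rna_len = max(len(patch_positions), 5)
    bases = "ACGU"
    for j in range(rna_len):
        if j < len(patch_positions):
            pos = np.array([BACKBONE_STEP * patch_positions[j], spec.d_near, 0.0])
        else:  # extra nucleotides stacked upward, further from the protein
            pos = np.array(
                [
                    BACKBONE_STEP * patch_positions[0],
                    spec.d_near + RNA_STEP * (j - len(patch_positions) + 1),
                    0.0,
                ]
            )
        lines.append(_pdb_atom_line(serial, "P", bases[j % 4], "B", j + 1, pos, "P"))
        serial += 1
    lines.append("TER\nEND\n")

    record = SequenceRecord(id=f"synth{chain_index:03d}_A", seq=seq)
    return "".join(lines), record, patch


def gen_pssm(
    truth_labels: np.ndarray,
    spec: SyntheticSpec,
    chain_index: int,
    residues: str | None = None,
) -> PSSMProfile:
    """Profile with N(0, sigma^2) raw scores plus delta on the signal columns
    at interface positions; scores rounded to 3 decimals so the ASCII
    serialization round-trips exactly. ``residues`` defaults to the sequence
    gen_complex produces for the same chain index."""
    rng = _chain_rng(spec, chain_index, 1)
    truth = np.asarray(truth_labels, dtype=int)
    n = len(truth)
    raw = rng.normal(0.0, spec.sigma, size=(n, 20))
    raw[truth == 1, : spec.k_signal] += spec.delta
    raw = np.round(raw, 3)
    if residues is None:
        _, record, _ = gen_complex(spec, chain_index)
        residues = record.seq
    if len(residues) != n:
        raise ValueError("residues length must match truth labels")
    return PSSMProfile(residues=residues, raw=raw)


def gen_benchmark(spec: SyntheticSpec, out_dir: str | Path) -> Path:
    """Write a self-consistent benchmark: PDB files, one FASTA, PSSMs, truth TSV.

    Deterministic under the spec seed; two runs produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    truth_rows = ["pdb_id\tchain_id\tposition\tlabel\n"]
    for idx in range(spec.n_chains):
        pdb_text, record, truth = gen_complex(spec, idx)
        pdb_id = f"synth{idx:03d}"
        (out / f"{pdb_id}.pdb").write_text(pdb_text)
        records.append(record)
        profile = gen_pssm(truth, spec, idx, residues=record.seq)
        write_pssm(profile, out / f"{pdb_id}_A.pssm")
        for pos, lab in enumerate(truth, start=1):
            truth_rows.append(f"{pdb_id}\tA\t{pos}\t{int(lab)}\n")
    write_fasta(records, out / "sequences.fasta")
    (out / "truth.tsv").write_text("".join(truth_rows))
    return out
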