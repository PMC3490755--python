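"""Interface-residue labeling and dataset assembly.

An amino acid is an interface (RNA-binding) residue when at least one of its
atoms lies within a distance cutoff (default 5.0 A) of any atom of the bound
RNA, pooling the atoms of every RNA chain in the complex. Residues present in
the full sequence but absent from the solved coordinates are labeled
non-interface. Two dataset variants are supported: the *sequence* variant
keeps every residue of the chain, the *structure* variant keeps only solved
residues; interface counts are identical between the two by construction.

Surface residues are those with relative solvent accessibility strictly above
a threshold (default 5%); accessibility is either read from a precomputed
NACCESS-style table or estimated with a built-in Shrake-Rupley sampler
normalized by theoretical per-residue maxima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from ._tables import AA1_TO_3, MAX_ASA, VDW_DEFAULT, VDW_RADII
from .structio import (
    AtomRecord,
    ComplexStructure,
    LABEL_COLUMNS,
    RSATable,
    ResidueRecord,
    SequenceRecord,
)

__all__ = [
    "LabeledResidue",
    "LabeledChain",
    "Dataset",
    "MappingError",
    "residue_min_distance",
    "label_interface",
    "passes_inclusion_filters",
    "make_dataset",
    "compute_rsa",
    "flag_surface",
    "surface_postfilter",
    "chain_from_labels",
]

DEFAULT_CUTOFF = 5.0
SURFACE_RSA_THRESHOLD = 5.0  # percent, strict '>'


class MappingError(ValueError):
    """Solved residues could not be aligned to the full chain sequence."""


@dataclass
class LabeledResidue:
    position: int  # 1-based index in the full sequence
    one_letter: str
    solved: bool
    label: int  # 1 = interface
    min_rna_distance: float | None = None
    surface: bool | None = None  # None = unknown
    centroid: np.ndarray | None = None
    auth_seq: str | None = None


@dataclass
class LabeledChain:
    chain_key: tuple[str, str]  # (pdb_id, chain_id)
    full_sequence: str
    residues: list[LabeledResidue]
    cutoff_used: float

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.full_sequence):
            raise ValueError("residue list length must equal full sequence length")

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.residues], dtype=int)

    def solved_positions(self) -> list[int]:
        return [r.position for r in self.residues if r.solved]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain_id": self.chain_key[1],
                "position": [r.position for r in self.residues],
                "residue": list(self.full_sequence),
                "solved": [int(r.solved) for r in self.residues],
                "label": [r.label for r in self.residues],
            },
            columns=LABEL_COLUMNS,
        )


@dataclass
class Dataset:
    """A collection of labeled chains under one dataset variant.

    The sequence variant yields every residue as an instance target; the
    structure variant yields only solved residues.
    """

    variant: str  # "sequence" | "structure"
    chains: list[LabeledChain] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.variant not in ("sequence", "structure"):
            raise ValueError(f"unknown variant {self.variant!r}")
        cutoffs = {c.cutoff_used for c in self.chains}
        if len(cutoffs) > 1:
            raise ValueError(f"chains labeled with mixed cutoffs {sorted(cutoffs)}")

    def eligible_residues(self, chain: LabeledChain) -> list[LabeledResidue]:
        if self.variant == "sequence":
            return list(chain.residues)
        return [r for r in chain.residues if r.solved]

    @property
    def counts(self) -> tuple[int, int]:
        """(n_interface, n_non_interface) over eligible residues."""
        pos = neg = 0
        for chain in self.chains:
            for r in self.eligible_residues(chain):
                if r.label == 1:
                    pos += 1
                else:
                    neg += 1
        return pos, neg


# ---------------------------------------------------------------------------
# Distance labeling
# ---------------------------------------------------------------------------

def _atom_coords(atoms: Iterable[AtomRecord], policy: str) -> np.ndarray:
    if policy == "heavy":
        atoms = [a for a in atoms if a.is_heavy]
    else:
        atoms = list(atoms)
    if not atoms:
        raise ValueError("empty atom list under policy " + policy)
    return np.array([a.coords for a in atoms], dtype=float)


def residue_min_distance(
    residue: ResidueRecord, rna_atoms: list[AtomRecord], atom_policy: str = "all"
) -> float:
    """Minimum Euclidean distance between any residue atom and any RNA atom."""
    a = _atom_coords(residue.atoms, atom_policy)
    b = _atom_coords(rna_atoms, atom_policy)
    return float(cdist(a, b).min())


def _map_solved_to_full(solved: str, full: str) -> list[int]:
    """Map each solved residue to a 0-based index in the full sequence.

    First tries a unique exact ungapped substring match; otherwise falls back
    to a global alignment (identity scoring, gaps in the solved string cheap)
    and requires >=95% identity over the aligned solved residues.
    """
    idx = full.find(solved)
    if idx >= 0 and full.find(solved, idx + 1) < 0:
        return list(range(idx, idx + len(solved)))

    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    # gaps in the solved string (deletions = unsolved spans of the full
    # sequence) are cheap; gaps in the full sequence (insertions) would leave
    # solved residues unplaced and are heavily penalized
    aligner.open_insertion_score = -10.0
    aligner.extend_insertion_score = -10.0
    aligner.open_deletion_score = -0.5
    aligner.extend_deletion_score = -0.1
    aligner.end_deletion_score = 0.0
    alignment = aligner.align(full, solved)[0]

    mapping: list[int] = [-1] * len(solved)
    matches = 0
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        for off in range(q1 - q0):
            mapping[q0 + off] = t0 + off
            if full[t0 + off] == solved[q0 + off]:
                matches += 1
    if any(m < 0 for m in mapping):
        bad = [i + 1 for i, m in enumerate(mapping) if m < 0]
        raise MappingError(f"solved residues at solved-index positions {bad} could not be placed")
    if matches / len(solved) < 0.95:
        raise MappingError(
            f"solved/full alignment identity {matches / len(solved):.2f} below 0.95"
        )
    return mapping


def label_interface(
    complex_: ComplexStructure,
    protein_chain: str,
    full_seq: SequenceRecord | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    atom_policy: str = "all",
) -> LabeledChain:
    """Label each residue of a protein chain against the pooled RNA atoms.

    A solved residue gets label 1 iff its minimum atom-atom distance to any
    RNA atom in the complex is <= ``cutoff``; unsolved positions (present in
    ``full_seq`` but not in the coordinates) get label 0.
    """
    chain = complex_.get_chain(protein_chain, "protein")
    rna_atoms: list[AtomRecord] = []
    for rna in complex_.rna_chains():
        rna_atoms.extend(rna.atoms(policy=atom_policy))
    if not rna_atoms:
        raise ValueError(f"{complex_.pdb_id}: no RNA atoms available for labeling")

    full = full_seq.seq if full_seq is not None else chain.sequence
    solved_str = chain.sequence
    mapping = _map_solved_to_full(solved_str, full)

    residues: list[LabeledResidue] = [
        LabeledResidue(position=i + 1, one_letter=full[i], solved=False, label=0)
        for i in range(len(full))
    ]
    rna_coords = np.array([a.coords for a in rna_atoms], dtype=float)
    for res, full_idx in zip(chain.residues, mapping):
        a = _atom_coords(res.atoms, atom_policy)
        dmin = float(cdist(a, rna_coords).min())
        heavy = res.heavy_atoms()
        centroid = (
            np.mean([at.coords for at in heavy], axis=0) if heavy else None
        )
        residues[full_idx] = LabeledResidue(
            position=full_idx + 1,
            one_letter=full[full_idx],
            solved=True,
            label=int(dmin <= cutoff),
            min_rna_distance=dmin,
            centroid=centroid,
            auth_seq=res.auth_seq,
        )
    return LabeledChain(
        chain_key=(complex_.pdb_id, protein_chain),
        full_sequence=full,
        residues=residues,
        cutoff_used=cutoff,
    )


def passes_inclusion_filters(
    chain: LabeledChain,
    rna_lengths: list[int],
    min_len: int = 40,
    min_binding: int = 3,
    min_rna: int = 5,
) -> bool:
    """Dataset inclusion rule: >=40 residues, >=3 binding residues, RNA >=5 nt."""
    if len(chain.full_sequence) < min_len:
        return False
    if int(chain.labels.sum()) < min_binding:
        return False
    if not rna_lengths or max(rna_lengths) < min_rna:
        return False
    return True


def make_dataset(chains: list[LabeledChain], variant: str) -> Dataset:
    return Dataset(variant=variant, chains=list(chains))


# ---------------------------------------------------------------------------
# Solvent accessibility (Shrake-Rupley) and the surface post-filter
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def shrake_rupley_sasa(
    coords: np.ndarray, radii: np.ndarray, probe: float = 1.4, n_points: int = 960
) -> np.ndarray:
    """Per-atom solvent-accessible surface area by sphere-point sampling.

    Each atom's solvent sphere (radius vdW + probe) is sampled at ``n_points``
    quasi-uniform points; the accessible area is the unoccluded fraction times
    the sphere area.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    pts = _sphere_points(n_points)
    ext = radii + probe
    tree = cKDTree(coords)
    areas = np.empty(n)
    for i in range(n):
        sphere = coords[i] + ext[i] * pts
        neighbors = [j for j in tree.query_ball_point(coords[i], ext[i] + ext.max()) if j != i]
        free = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(sphere - coords[j], axis=1)
            free &= d >= ext[j]
        areas[i] = free.mean() * 4.0 * np.pi * ext[i] ** 2
    return areas


def compute_rsa(
    complex_: ComplexStructure,
    chain_id: str,
    probe: float = 1.4,
    n_points: int = 960,
) -> RSATable:
    """Relative accessibility (percent) of each solved residue of a protein chain.

    SASA is computed over the heavy atoms of the isolated chain and divided by
    a fixed per-residue-type theoretical maximum. Residue types without a
    reference value are omitted (accessibility unknown).
    """
    chain = complex_.get_chain(chain_id, "protein")
    atoms: list[AtomRecord] = []
    owner: list[int] = []
    for ri, res in enumerate(chain.residues):
        for a in res.heavy_atoms():
            atoms.append(a)
            owner.append(ri)
    if not atoms:
        raise ValueError(f"chain {chain_id}: no heavy atoms")
    coords = np.array([a.coords for a in atoms])
    radii = np.array([VDW_RADII.get(a.element.upper(), VDW_DEFAULT) for a in atoms])
    areas = shrake_rupley_sasa(coords, radii, probe=probe, n_points=n_points)

    per_res = np.zeros(len(chain.residues))
    np.add.at(per_res, owner, areas)
    entries: dict[tuple[str, str], float] = {}
    for res, sasa in zip(chain.residues, per_res):
        ref = MAX_ASA.get(res.resname) or MAX_ASA.get(AA1_TO_3.get(res.one_letter, ""))
        if not ref:
            continue
        entries[(chain_id, str(res.auth_seq))] = 100.0 * sasa / ref
    return RSATable(entries=entries)


def flag_surface(
    chain: LabeledChain, rsa: RSATable, threshold: float = SURFACE_RSA_THRESHOLD
) -> LabeledChain:
    """Mark surface residues: RSA strictly greater than ``threshold`` percent.

    Unsolved residues, and solved residues missing from the table, keep
    surface = None (unknown).
    """
    new_residues = []
    for r in chain.residues:
        if not r.solved or r.auth_seq is None:
            new_residues.append(replace(r, surface=None))
            continue
        value = rsa.get(chain.chain_key[1], r.auth_seq)
        if value is None:
            warnings.warn(
                f"no RSA value for {chain.chain_key} residue {r.auth_seq}; surface unknown",
                stacklevel=2,
            )
            new_residues.append(replace(r, surface=None))
        else:
            new_residues.append(replace(r, surface=value > threshold))
    return replace(chain, residues=new_residues)


def surface_postfilter(preds: pd.DataFrame, chain: LabeledChain) -> pd.DataFrame:
    """Demote predicted interface residues that are not surface residues.

    Rows with pred == 1 whose residue is known to be buried (surface False)
    are set to pred 0; scores and all other rows are unchanged.
    """
    surface_by_pos = {r.position: r.surface for r in chain.residues}
    out = preds.copy()
    chain_id = chain.chain_key[1]
    mask = (out["chain_id"] == chain_id) & (out["pred"] == 1)
    demote = out.loc[mask, "position"].map(lambda p: surface_by_pos.get(p) is False)
    out.loc[mask & demote.reindex(out.index, fill_value=False), "pred"] = 0
    return out


def chain_from_labels(
    df: pd.DataFrame,
    chain_key: tuple[str, str],
    cutoff: float = DEFAULT_CUTOFF,
    complex_: ComplexStructure | None = None,
) -> LabeledChain:
    """Rebuild a LabeledChain from a label TSV (optionally with coordinates).

    When ``complex_`` is given, residue centroids are restored from the
    structure so that spatial windows can be built.
    """
    df = df.sort_values("position")
    residues = [
        LabeledResidue(
            position=int(row.position),
            one_letter=str(row.residue),
            solved=bool(row.solved),
            label=int(row.label),
        )
        for row in df.itertuples()
    ]
    chain = LabeledChain(
        chain_key=chain_key,
        full_sequence="".join(str(r) for r in df["residue"]),
        residues=residues,
        cutoff_used=cutoff,
    )
    if complex_ is not None:
        struct_chain = complex_.get_chain(chain_key[1], "protein")
        mapping = _map_solved_to_full(struct_chain.sequence, chain.full_sequence)
        for res, full_idx in zip(struct_chain.residues, mapping):
            heavy = res.heavy_atoms()
            if heavy:
                chain.residues[full_idx].centroid = np.mean(
                    [a.coords for a in heavy], axis=0
                )
            chain.residues[full_idx].auth_seq = res.auth_seq
    return chain
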