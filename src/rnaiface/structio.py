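"""Readers and writers for the external formats of the pipeline.

Formats handled:

* PDB fixed-column coordinate files (via Biopython's parser), partitioned into
  protein and RNA chains by residue-name vocabulary;
* FASTA full-chain sequences;
* PSI-BLAST ASCII position-specific scoring matrices (the first 20 numeric
  columns, i.e. the log-odds block);
* NACCESS-style ``.rsa`` relative accessibility tables;
* tab-separated prediction and label tables.

Parsed coordinate models keep residues in file order; PSSM profiles carry both
the raw log-odds scores and their logistic-normalized form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from ._tables import (
    AA3_TO_1,
    AA_ALPHABET,
    ION_RESNAMES,
    MODIFIED_TO_PARENT,
    PSSM_COLUMNS,
    RNA_ONE,
    RNA_RESNAMES,
    WATER_RESNAMES,
)

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "ChainStructure",
    "ComplexStructure",
    "SequenceRecord",
    "PSSMProfile",
    "RSATable",
    "FormatError",
    "read_complex",
    "read_fasta",
    "read_pssm",
    "write_pssm",
    "read_rsa",
    "read_predictions",
    "write_predictions",
    "read_labels",
    "write_labels",
    "PREDICTION_COLUMNS",
    "LABEL_COLUMNS",
]


class FormatError(ValueError):
    """Raised when an input file does not conform to its expected dialect."""


@dataclass(frozen=True)
class AtomRecord:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    serial: int = 0

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class ResidueRecord:
    chain_id: str
    resname: str
    auth_seq: str  # author residue number + insertion code
    one_letter: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_heavy]


@dataclass
class ChainStructure:
    chain_id: str
    moltype: str  # "protein" | "rna"
    residues: list[ResidueRecord] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def atoms(self, policy: str = "all") -> list[AtomRecord]:
        out = []
        for res in self.residues:
            out.extend(res.heavy_atoms() if policy == "heavy" else res.atoms)
        return out


@dataclass
class ComplexStructure:
    pdb_id: str
    chains: list[ChainStructure] = field(default_factory=list)

    def protein_chains(self) -> list[ChainStructure]:
        return [c for c in self.chains if c.moltype == "protein"]

    def rna_chains(self) -> list[ChainStructure]:
        return [c for c in self.chains if c.moltype == "rna"]

    def get_chain(self, chain_id: str, moltype: str = "protein") -> ChainStructure:
        for c in self.chains:
            if c.chain_id == chain_id and c.moltype == moltype:
                return c
        raise KeyError(f"no {moltype} chain {chain_id!r} in {self.pdb_id}")


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    seq: str


@dataclass
class PSSMProfile:
    """Per-position 20-column log-odds profile with logistic-normalized form.

    ``raw`` holds the log-odds scores (symbol x); ``normalized`` is the
    elementwise logistic transform 1/(1+e^-x) (symbol y), strictly in (0, 1).
    """

    residues: str
    raw: np.ndarray  # (n, 20)
    column_order: str = PSSM_COLUMNS
    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 2 or self.raw.shape != (len(self.residues), 20):
            raise ValueError(
                f"raw PSSM shape {self.raw.shape} does not match "
                f"{len(self.residues)} positions x 20 columns"
            )
        if len(self.column_order) != 20:
            raise ValueError("column_order must list the 20 amino acids")
        self.normalized = expit(self.raw)

    @property
    def seq_length(self) -> int:
        return len(self.residues)


@dataclass
class RSATable:
    """Map (chain_id, auth_seq) -> relative accessible surface area in percent."""

    entries: dict[tuple[str, str], float] = field(default_factory=dict)

    def get(self, chain_id: str, auth_seq: str) -> float | None:
        return self.entries.get((chain_id, str(auth_seq)))


# ---------------------------------------------------------------------------
# PDB coordinate files
# ---------------------------------------------------------------------------

def _classify_residue(resname: str) -> tuple[str, str] | None:
    """Return (moltype, one_letter) or None for waters/ions/unknown ligands."""
    name = resname.strip().upper()
    if name in WATER_RESNAMES or name in ION_RESNAMES:
        return None
    if name in AA3_TO_1:
        return "protein", AA3_TO_1[name]
    if name in MODIFIED_TO_PARENT:
        return "protein", MODIFIED_TO_PARENT[name]
    if name in RNA_RESNAMES:
        return "rna", RNA_ONE.get(name, "X")
    return None


def read_complex(path: str | Path, first_model_only: bool = True) -> ComplexStructure:
    """Parse a PDB coordinate file into protein and RNA chains.

    Only the first MODEL is read when several are present; waters, ions and
    unrecognized ligands are excluded; altloc conflicts keep the
    highest-occupancy conformer. Residue order follows file order.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:
        raise FormatError(f"{path}: unparseable coordinate record ({exc})") from exc

    models = list(structure)
    if not models:
        return ComplexStructure(pdb_id=path.stem, chains=[])
    model = models[0] if first_model_only else models[0]

    chains: list[ChainStructure] = []
    for chain in model:
        by_type: dict[str, list[ResidueRecord]] = {"protein": [], "rna": []}
        for res in chain:
            kind = _classify_residue(res.get_resname())
            if kind is None:
                continue
            moltype, one_letter = kind
            _, resseq, icode = res.id
            atoms = []
            for atom in res.get_atoms():
                element = (atom.element or "").strip() or atom.get_name().strip()[:1]
                atoms.append(
                    AtomRecord(
                        name=atom.get_name(),
                        element=element,
                        coords=np.array(atom.get_coord(), dtype=float),
                        serial=int(atom.get_serial_number() or 0),
                    )
                )
            if not atoms:
                continue
            by_type[moltype].append(
                ResidueRecord(
                    chain_id=chain.id,
                    resname=res.get_resname().strip(),
                    auth_seq=f"{resseq}{icode.strip()}",
                    one_letter=one_letter,
                    atoms=atoms,
                )
            )
        for moltype in ("protein", "rna"):
            if by_type[moltype]:
                chains.append(
                    ChainStructure(chain_id=chain.id, moltype=moltype, residues=by_type[moltype])
                )

    cx = ComplexStructure(pdb_id=path.stem, chains=chains)
    if not cx.protein_chains() or not cx.rna_chains():
        warnings.warn(
            f"{path.stem}: complex lacks a protein or RNA chain; labeling will be unavailable",
            stacklevel=2,
        )
    return cx


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_AA_SET = set(AA_ALPHABET)


def _clean_sequence(seq: str) -> str:
    seq = "".join(seq.split()).upper()
    return "".join(c if c in _AA_SET else "X" for c in seq)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read amino-acid FASTA records; non-standard letters map to 'X'."""
    from Bio import SeqIO

    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _clean_sequence(str(rec.seq))
        if not seq:
            raise FormatError(f"empty sequence for {rec.id!r} in {path}")
        records.append(SequenceRecord(id=rec.id, seq=seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 60):
                fh.write(rec.seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def _try_float(tok: str) -> float | None:
    try:
        return float(tok)
    except ValueError:
        return None


def read_pssm(path: str | Path) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM.

    Only the log-odds block (the first 20 numeric columns of each position
    row) is used; the weighted-percentage block and trailing statistics are
    ignored. The column order is taken from the header line when present.
    """
    path = Path(path)
    column_order = PSSM_COLUMNS
    residues: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        lines = fh.readlines()

    header_seen = False
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if not tokens:
            continue
        if not header_seen:
            letters = [t for t in tokens if len(t) == 1 and t.isalpha()]
            if len(letters) >= 20 and all(t in letters for t in tokens):
                column_order = "".join(letters[:20]).upper()
                header_seen = True
                continue
        if len(tokens) >= 2 and tokens[0].isdigit() and len(tokens[1]) == 1 and tokens[1].isalpha():
            scores = [_try_float(t) for t in tokens[2:]]
            numeric = [s for s in scores if s is not None]
            if len(numeric) < 20:
                raise FormatError(
                    f"{path}:{lineno}: expected >=20 scores per position row, got {len(numeric)}"
                )
            residues.append(tokens[1].upper())
            rows.append(numeric[:20])
        elif rows and len(tokens) >= 2:
            # trailing statistics block after the matrix
            continue
    if not rows:
        raise FormatError(f"{path}: no PSSM position rows found")
    return PSSMProfile(residues="".join(residues), raw=np.array(rows), column_order=column_order)


def write_pssm(profile: PSSMProfile, path: str | Path, comment: str = "") -> None:
    """Serialize a profile in the PSI-BLAST ASCII layout (3-decimal scores)."""
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(comment or "Last position-specific scoring matrix computed\n")
        fh.write("            " + "   ".join(profile.column_order) + "\n")
        for i, letter in enumerate(profile.residues):
            scores = "  ".join(f"{v:8.3f}" for v in profile.raw[i])
            fh.write(f"{i + 1:5d} {letter}  {scores}\n")
        fh.write("\n")


# ---------------------------------------------------------------------------
# NACCESS-style .rsa tables
# ---------------------------------------------------------------------------

def read_rsa(path: str | Path) -> RSATable:
    """Read 'RES' lines of a NACCESS .rsa file; uses the all-atoms relative column."""
    path = Path(path)
    entries: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("RES"):
                continue
            tokens = line.split()
            if len(tokens) < 6:
                raise FormatError(f"{path}:{lineno}: truncated RES line")
            _, _resname, chain, auth_seq = tokens[:4]
            values = [_try_float(t) for t in tokens[4:]]
            if len(values) < 2 or values[0] is None or values[1] is None:
                raise FormatError(f"{path}:{lineno}: missing relative accessibility column")
            key = (chain, auth_seq)
            if key in entries:
                raise FormatError(f"{path}:{lineno}: duplicate residue key {key}")
            entries[key] = values[1]  # second numeric = relative all-atoms
    return RSATable(entries=entries)


def write_rsa(table: RSATable, path: str | Path, resnames: dict | None = None) -> None:
    with open(path, "w") as fh:
        for (chain, auth_seq), rel in table.entries.items():
            resname = (resnames or {}).get((chain, auth_seq), "UNK")
            fh.write(f"RES {resname:>3s} {chain} {auth_seq:>4s} {0.0:8.2f} {rel:8.2f}\n")


# ---------------------------------------------------------------------------
# Prediction / label TSV
# ---------------------------------------------------------------------------

PREDICTION_COLUMNS = ["chain_id", "position", "residue", "score", "pred", "label"]
LABEL_COLUMNS = ["chain_id", "position", "residue", "solved", "label"]


def _validate_predictions(df: pd.DataFrame, path=None) -> pd.DataFrame:
    where = f" in {path}" if path else ""
    missing = [c for c in PREDICTION_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise FormatError(f"prediction table missing columns {missing}{where}")
    if df.duplicated(subset=["chain_id", "position"]).any():
        raise FormatError(f"duplicate (chain_id, position) rows{where}")
    for col in ("pred",) + (("label",) if "label" in df.columns and df["label"].notna().all() else ()):
        vals = set(df[col].astype(int).unique())
        if not vals <= {0, 1}:
            raise FormatError(f"column {col!r} must be 0/1, found {sorted(vals)}{where}")
    return df


def write_predictions(df: pd.DataFrame, path: str | Path) -> None:
    """Write a prediction table as TSV (one header line + one row per residue)."""
    _validate_predictions(df)
    cols = [c for c in PREDICTION_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols)


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return _validate_predictions(df, path=path)


def write_labels(df: pd.DataFrame, path: str | Path) -> None:
    """Write a per-residue label table (chain_id, position, residue, solved, label)."""
    df.to_csv(path, sep="\t", index=False, columns=LABEL_COLUMNS)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"label table missing columns {missing} in {path}")
    return df
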