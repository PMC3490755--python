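"""Window feature encodings for interface-residue classification.

Six encodings are supported, crossing three per-residue channels (amino acid
identity, PSSM profile, smoothed PSSM profile) with two window types:

* sequence windows — the target residue plus (W-1)/2 flanking residues on each
  side in chain order (default W = 25, giving 25 x 20 = 500 PSSM features);
* spatial windows — the target residue plus the W-1 nearest solved residues by
  inter-residue centroid distance.

PSSM channels use the logistic-normalized scores (values in (0,1); window
padding contributes the neutral 0.5); identity channels use a 21-symbol
one-hot (20 amino acids + 'X', padding mapped to 'X'). Smoothed PSSMs sum raw
scores over a small window (default 3) before normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist
from scipy.special import expit

from ._tables import AA_ALPHABET
from .labeling import Dataset, LabeledChain
from .structio import PSSMProfile

__all__ = [
    "ENCODINGS",
    "PAD",
    "EncodingConfig",
    "EncodedInstance",
    "logistic_normalize",
    "smooth_pssm",
    "sequence_window",
    "build_spatial_index",
    "spatial_window",
    "encode_instance",
    "encode_chain",
    "encode_dataset",
    "undersample",
    "instances_to_arrays",
]

ENCODINGS = ("IDSeq", "PSSMSeq", "SmoPSSMSeq", "IDStr", "PSSMStr", "SmoPSSMStr")
PAD = 0  # sentinel window position (residue positions are 1-based)

ID_ALPHABET = AA_ALPHABET + "X"  # 21 indicator symbols per window position
_ID_INDEX = {c: i for i, c in enumerate(ID_ALPHABET)}


@dataclass(frozen=True)
class EncodingConfig:
    encoding: str = "PSSMSeq"
    window: int = 25  # W, total residues per window (odd)
    smoothing_window: int = 3  # w, for the SmoPSSM channels (odd)
    aux_channel: Mapping[tuple[str, str], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.encoding not in ENCODINGS:
            raise ValueError(f"unknown encoding {self.encoding!r}; choose from {ENCODINGS}")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window size W must be odd and positive")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing window w must be odd and positive")

    @property
    def channel(self) -> str:  # "id" | "pssm"
        return "id" if self.encoding.startswith("ID") else "pssm"

    @property
    def spatial(self) -> bool:
        return self.encoding.endswith("Str")

    @property
    def smoothed(self) -> bool:
        return self.encoding.startswith("Smo")

    @property
    def n_features(self) -> int:
        per_pos = 21 if self.channel == "id" else 20
        if self.aux_channel is not None:
            per_pos += 1
        return self.window * per_pos


@dataclass
class EncodedInstance:
    chain_key: tuple[str, str]
    position: int
    features: np.ndarray
    label: int


def logistic_normalize(x):
    """Logistic squashing y = 1/(1+e^-x), elementwise, overflow-safe."""
    return expit(x)


def smooth_pssm(profile: PSSMProfile, w: int) -> PSSMProfile:
    """Sum raw scores over a window of w positions centered on each residue.

    Out-of-range neighbors at the termini contribute zero; the normalized
    matrix is recomputed from the smoothed raw scores. w = 1 is the identity.
    """
    if w < 1 or w % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    if w == 1:
        return profile
    half = (w - 1) // 2
    padded = np.pad(profile.raw, ((half, half), (0, 0)))
    smoothed = sliding_window_view(padded, w, axis=0).sum(axis=-1)
    return PSSMProfile(residues=profile.residues, raw=smoothed, column_order=profile.column_order)


def sequence_window(chain_length: int, position: int, window: int) -> list[int]:
    """Positions p-(W-1)/2 .. p+(W-1)/2, PAD (0) outside 1..n; target at center."""
    if not 1 <= position <= chain_length:
        raise ValueError(f"position {position} outside 1..{chain_length}")
    half = (window - 1) // 2
    return [
        p if 1 <= p <= chain_length else PAD
        for p in range(position - half, position + half + 1)
    ]


def build_spatial_index(chain: LabeledChain) -> dict[int, list[tuple[int, float]]]:
    """Nearest-neighbor lists over solved residues by centroid distance.

    Centroids are heavy-atom means; neighbor lists are sorted by distance,
    ties broken by ascending sequence position; self is excluded.
    """
    solved = [r for r in chain.residues if r.solved and r.centroid is not None]
    if not solved:
        raise ValueError(f"{chain.chain_key}: no solved residues with coordinates")
    positions = np.array([r.position for r in solved])
    coords = np.array([r.centroid for r in solved])
    dmat = cdist(coords, coords)
    index: dict[int, list[tuple[int, float]]] = {}
    for i, pos in enumerate(positions):
        order = sorted(
            (j for j in range(len(solved)) if j != i),
            key=lambda j: (dmat[i, j], positions[j]),
        )
        index[int(pos)] = [(int(positions[j]), float(dmat[i, j])) for j in order]
    return index


def spatial_window(
    index: dict[int, list[tuple[int, float]]], position: int, window: int
) -> list[int]:
    """Target first, then the W-1 nearest solved residues; PAD to length W."""
    if position not in index:
        raise ValueError(f"position {position} is not a solved residue with coordinates")
    neighbors = [pos for pos, _ in index[position][: window - 1]]
    out = [position] + neighbors
    out += [PAD] * (window - len(out))
    return out


def _encode_window(
    chain: LabeledChain,
    profile: PSSMProfile | None,
    window: Sequence[int],
    config: EncodingConfig,
) -> np.ndarray:
    blocks: list[np.ndarray] = []
    aux = config.aux_channel.get(chain.chain_key) if config.aux_channel is not None else None
    for pos in window:
        if config.channel == "id":
            vec = np.zeros(21)
            letter = chain.full_sequence[pos - 1] if pos != PAD else "X"
            vec[_ID_INDEX.get(letter, _ID_INDEX["X"])] = 1.0
        else:
            assert profile is not None
            vec = profile.normalized[pos - 1] if pos != PAD else np.full(20, 0.5)
        if aux is not None:
            vec = np.append(vec, aux[pos - 1] if pos != PAD else 0.0)
        blocks.append(vec)
    return np.concatenate(blocks)


def encode_instance(
    chain: LabeledChain,
    profile: PSSMProfile | None,
    window: Sequence[int],
    config: EncodingConfig,
) -> EncodedInstance:
    """Encode one window into a fixed-length feature vector.

    The target residue is the window center for sequence windows and the
    first entry for spatial windows; its label is copied onto the instance.
    """
    if len(window) != config.window:
        raise ValueError(f"window length {len(window)} != configured W {config.window}")
    if config.channel == "pssm":
        if profile is None:
            raise ValueError(f"{config.encoding} requires a PSSM profile")
        if profile.seq_length != len(chain.full_sequence):
            raise ValueError(
                f"profile length {profile.seq_length} != chain length "
                f"{len(chain.full_sequence)} for {chain.chain_key}"
            )
    target = window[0] if config.spatial else window[(config.window - 1) // 2]
    if target == PAD:
        raise ValueError("target position cannot be PAD")
    features = _encode_window(chain, profile, window, config)
    return EncodedInstance(
        chain_key=chain.chain_key,
        position=int(target),
        features=features,
        label=int(chain.residues[target - 1].label),
    )


def encode_chain(
    chain: LabeledChain,
    profile: PSSMProfile | None,
    config: EncodingConfig,
    targets: Sequence[int],
) -> list[EncodedInstance]:
    """Encode the given target positions of one chain."""
    if config.smoothed and profile is not None:
        profile = smooth_pssm(profile, config.smoothing_window)
    n = len(chain.full_sequence)
    spatial_index = build_spatial_index(chain) if config.spatial else None
    instances = []
    for pos in targets:
        if config.spatial:
            window = spatial_window(spatial_index, pos, config.window)
        else:
            window = sequence_window(n, pos, config.window)
        instances.append(encode_instance(chain, profile, window, config))
    return instances


def encode_dataset(
    dataset: Dataset,
    profiles: Mapping[tuple[str, str], PSSMProfile] | None,
    config: EncodingConfig,
) -> list[EncodedInstance]:
    """One instance per eligible residue of every chain in the dataset.

    Sequence encodings on the sequence variant yield one instance per residue;
    on the structure variant, full-sequence windows are used but instances are
    emitted only for solved targets. Spatial encodings require the structure
    variant (windows are defined only over solved residues).
    """
    if config.spatial and dataset.variant != "structure":
        raise ValueError(f"{config.encoding} requires a structure-variant dataset")
    out: list[EncodedInstance] = []
    for chain in dataset.chains:
        profile = None
        if config.channel == "pssm":
            if profiles is None or chain.chain_key not in profiles:
                raise ValueError(f"missing PSSM profile for chain {chain.chain_key}")
            profile = profiles[chain.chain_key]
        targets = [r.position for r in dataset.eligible_residues(chain)]
        out.extend(encode_chain(chain, profile, config, targets))
    return out


def undersample(instances: list[EncodedInstance], seed: int) -> list[EncodedInstance]:
    """Balance classes by sampling the majority class down to the minority size.

    The minority class is kept whole; sampling is without replacement with a
    seeded generator, and the combined output is deterministically shuffled.
    """
    pos = [i for i in instances if i.label == 1]
    neg = [i for i in instances if i.label == 0]
    if not pos or not neg:
        raise ValueError("undersampling requires both classes present")
    rng = np.random.default_rng(seed)
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    keep_idx = rng.choice(len(majority), size=len(minority), replace=False)
    combined = minority + [majority[i] for i in sorted(keep_idx)]
    order = rng.permutation(len(combined))
    return [combined[i] for i in order]


def instances_to_arrays(
    instances: list[EncodedInstance],
) -> tuple[np.ndarray, np.ndarray, list[tuple[tuple[str, str], int]]]:
    """Stack instances into (X, y, provenance) arrays."""
    if not instances:
        raise ValueError("no instances to stack")
    X = np.stack([i.features for i in instances])
    y = np.array([i.label for i in instances], dtype=int)
    meta = [(i.chain_key, i.position) for i in instances]
    return X, y, meta
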