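"""Structural and sequence support for the D1/D2 helix-crossing analysis.

* Cα-Cα distances and nearest-partner interface profiles from PDB
  coordinates (the deposition convention for PSII puts D1 on chain A and D2
  on chain D; override as needed).
* GxxxG-like and consecutive-small motif detection on one-letter sequences,
  where "small" means group I residues (Gly/Ala/Ser/Cys/Thr, V_res <= 130 Å³).
* Conservation tallies of a three-residue window over an aligned sequence set.
* Geometric hydrogen-bond occupancy over trajectory frames: the fraction of
  snapshots in which a donor-acceptor pair satisfies distance (and, with
  hydrogens, angle) criteria.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .scales import (ResidueVolumeScale, STANDARD_AMINO_ACIDS, classify_group,
                     default_scale)

__all__ = [
    "StructureModel",
    "InterfacePair",
    "MotifHit",
    "ConservationTally",
    "HBondCriteria",
    "StructureParseError",
    "AtomLookupError",
    "read_structure",
    "ca_distance",
    "interface_profile",
    "find_small_motifs",
    "tally_conservation",
    "read_fasta_alignment",
    "hbond_occupancy",
    "read_trajectory_pdb",
]

AtomSpec = tuple[str, int, str]  # (chain, residue number, atom name)
Frame = Mapping[AtomSpec, np.ndarray]


class StructureParseError(ValueError):
    pass


class AtomLookupError(KeyError):
    def __init__(self, message: str):
        super().__init__(message)
        self.message = message

    def __str__(self):
        return self.message


@dataclass(frozen=True)
class StructureModel:
    """One model of a PDB entry, wrapping a biotite AtomArray."""

    atoms: struc.AtomArray
    model_index: int = 1

    def chains(self) -> list[str]:
        return list(dict.fromkeys(self.atoms.chain_id))

    def residue_numbers(self, chain: str) -> list[int]:
        mask = self.atoms.chain_id == chain
        return sorted(set(int(r) for r in self.atoms.res_id[mask]))

    def residue_name(self, chain: str, number: int) -> str:
        mask = (self.atoms.chain_id == chain) & (self.atoms.res_id == number)
        if not mask.any():
            raise AtomLookupError(f"no residue {chain}/{number}")
        return str(self.atoms.res_name[mask][0])

    def atom_coord(self, chain: str, number: int, atom_name: str) -> np.ndarray:
        mask = ((self.atoms.chain_id == chain) & (self.atoms.res_id == number)
                & (self.atoms.atom_name == atom_name))
        if not mask.any():
            raise AtomLookupError(
                f"residue {chain}/{number} has no atom {atom_name!r}"
            )
        return np.asarray(self.atoms.coord[mask][0], dtype=float)

    def ca_coord(self, chain: str, number: int) -> np.ndarray:
        return self.atom_coord(chain, number, "CA")


@dataclass(frozen=True)
class InterfacePair:
    res_a: tuple[str, int, str]  # (chain, number, 3-letter name)
    res_b: tuple[str, int, str]
    ca_distance: float           # Å

    def __post_init__(self):
        if self.ca_distance < 0:
            raise ValueError("distance must be non-negative")


@dataclass(frozen=True)
class MotifHit:
    kind: str       # "gxxxg_like" | "consecutive_small"
    start: int      # 1-based
    end: int        # 1-based, inclusive
    sequence: str

    def __post_init__(self):
        if self.kind == "gxxxg_like" and self.end - self.start != 4:
            raise ValueError("gxxxg_like spans positions i..i+4")
        if self.kind == "consecutive_small" and self.end < self.start + 2:
            raise ValueError("consecutive_small needs a run of >= 3")


@dataclass(frozen=True)
class ConservationTally:
    window: tuple[int, int, int]
    triplet_counts: Mapping[str, int]
    n_sequences: int
    fraction_all_small: float

    def __post_init__(self):
        if sum(self.triplet_counts.values()) != self.n_sequences:
            raise ValueError("triplet counts must sum to n_sequences")
        if not 0.0 <= self.fraction_all_small <= 1.0:
            raise ValueError("fraction_all_small must lie in [0, 1]")

    def fractions(self) -> dict[str, float]:
        return {t: c / self.n_sequences for t, c in self.triplet_counts.items()}


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric H-bond definition: donor-acceptor distance and, when
    hydrogens are available, the donor-hydrogen-acceptor angle."""

    max_da_distance: float = 3.5   # Å
    min_dha_angle: float = 120.0   # degrees
    require_hydrogens: bool = False

    def __post_init__(self):
        if self.max_da_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0.0 < self.min_dha_angle <= 180.0:
            raise ValueError("angle cutoff must lie in (0, 180]")


# ---------------------------------------------------------------------------
# coordinates


def read_structure(source: str | Path, model_index: int = 1) -> StructureModel:
    """Parse PDB-format content (text or path); select ``model_index`` (1-based)."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        pdb = PDBFile.read(io.StringIO(text))
        atoms = pdb.get_structure(model=model_index)
    except Exception as exc:
        raise StructureParseError(f"cannot parse PDB content: {exc}") from exc
    if atoms.array_length() == 0:
        raise StructureParseError("no ATOM/HETATM records found")
    return StructureModel(atoms=atoms, model_index=model_index)


def ca_distance(model: StructureModel, res_a: tuple[str, int],
                res_b: tuple[str, int]) -> float:
    """Euclidean Cα-Cα distance in Å (symmetric in its arguments).

    Report tables round this to 0.1 Å.
    """
    a = model.ca_coord(*res_a)
    b = model.ca_coord(*res_b)
    return float(np.linalg.norm(a - b))


def interface_profile(
    model: StructureModel,
    chain_a: str, range_a: Iterable[int],
    chain_b: str, range_b: Iterable[int],
) -> list[InterfacePair]:
    """For each residue of range_a, the closest Cα among range_b."""
    range_a, range_b = list(range_a), list(range_b)
    if not range_a or not range_b:
        raise ValueError("residue ranges must be non-empty")
    coords_b = np.array([model.ca_coord(chain_b, n) for n in range_b])
    out = []
    for na in range_a:
        ca = model.ca_coord(chain_a, na)
        d = np.linalg.norm(coords_b - ca, axis=1)
        j = int(np.argmin(d))
        nb = range_b[j]
        out.append(InterfacePair(
            res_a=(chain_a, na, model.residue_name(chain_a, na)),
            res_b=(chain_b, nb, model.residue_name(chain_b, nb)),
            ca_distance=float(d[j]),
        ))
    return out


# ---------------------------------------------------------------------------
# sequences


def _is_small(code: str, scale: ResidueVolumeScale) -> bool:
    return classify_group(code, scale).label == "I"


def _check_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - STANDARD_AMINO_ACIDS
    if not seq or bad:
        raise ValueError(f"invalid residue codes in sequence: {sorted(bad)}")
    return seq


def find_small_motifs(sequence: str,
                      scale: ResidueVolumeScale | None = None) -> list[MotifHit]:
    """GxxxG-like (small anchors at i, i+4) and consecutive-small (runs of
    >= 3 small residues) motif occurrences; positions are 1-based."""
    scale = scale or default_scale()
    seq = _check_sequence(sequence)
    small = [_is_small(c, scale) for c in seq]
    hits: list[MotifHit] = []
    for i in range(len(seq) - 4):
        if small[i] and small[i + 4]:
            hits.append(MotifHit(kind="gxxxg_like", start=i + 1, end=i + 5,
                                 sequence=seq[i:i + 5]))
    i = 0
    while i < len(seq):
        if small[i]:
            j = i
            while j + 1 < len(seq) and small[j + 1]:
                j += 1
            if j - i + 1 >= 3:
                hits.append(MotifHit(kind="consecutive_small", start=i + 1,
                                     end=j + 1, sequence=seq[i:j + 1]))
            i = j + 1
        else:
            i += 1
    return hits


def read_fasta_alignment(path: str | Path) -> list[str]:
    """Aligned FASTA -> list of equal-length uppercase sequences."""
    from Bio import SeqIO

    seqs = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("alignment sequences must have equal length")
    return seqs


def tally_conservation(
    sequences: Sequence[str],
    window: tuple[int, int, int],
    scale: ResidueVolumeScale | None = None,
) -> ConservationTally:
    """Count the triplet observed at three 1-based alignment positions."""
    scale = scale or default_scale()
    if not sequences:
        raise ValueError("no sequences")
    offenders = [i for i, s in enumerate(sequences) if max(window) > len(s)]
    if offenders:
        raise ValueError(
            f"window {window} out of bounds for sequence indices {offenders}"
        )
    counts: Counter[str] = Counter()
    n_small = 0
    for s in sequences:
        triplet = "".join(s[p - 1] for p in window)
        counts[triplet] += 1
        if all(c in STANDARD_AMINO_ACIDS and _is_small(c, scale) for c in triplet):
            n_small += 1
    return ConservationTally(window=tuple(window), triplet_counts=dict(counts),
                             n_sequences=len(sequences),
                             fraction_all_small=n_small / len(sequences))


# ---------------------------------------------------------------------------
# trajectories


def _frame_coord(frame: Frame, spec: AtomSpec, index: int) -> np.ndarray:
    try:
        return np.asarray(frame[spec], dtype=float)
    except KeyError:
        raise AtomLookupError(f"frame {index}: missing atom {spec}") from None


def hbond_occupancy(
    frames: Sequence[Frame],
    donor: AtomSpec,
    acceptor: AtomSpec,
    criteria: HBondCriteria | None = None,
    hydrogen: AtomSpec | None = None,
) -> float:
    """Fraction of frames in which the donor/acceptor pair is H-bonded.

    With ``criteria.require_hydrogens`` (and a hydrogen spec) both the D-A
    distance and the D-H...A angle must pass; otherwise the check is
    distance-only, which is reported as such in CLI output.
    """
    criteria = criteria or HBondCriteria()
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    if criteria.require_hydrogens and hydrogen is None:
        raise ValueError("criteria require hydrogens but no hydrogen spec given")
    bonded = 0
    for i, frame in enumerate(frames):
        d = _frame_coord(frame, donor, i)
        a = _frame_coord(frame, acceptor, i)
        ok = np.linalg.norm(d - a) <= criteria.max_da_distance
        if ok and criteria.require_hydrogens:
            h = _frame_coord(frame, hydrogen, i)
            v1 = d - h
            v2 = a - h
            cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            ok = angle >= criteria.min_dha_angle
        bonded += bool(ok)
    return bonded / len(frames)


def read_trajectory_pdb(path: str | Path) -> list[dict[AtomSpec, np.ndarray]]:
    """Multi-model PDB -> list of frames mapping (chain, resnum, atom) -> xyz."""
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()  # AtomArrayStack over models
    if stack.array_length() == 0:
        raise StructureParseError(f"no atoms in {path}")
    frames = []
    keys = list(zip(stack.chain_id, stack.res_id.astype(int), stack.atom_name))
    for m in range(stack.stack_depth()):
        coords = stack.coord[m]
        frames.append({(c, int(r), n): coords[i]
                       for i, (c, r, n) in enumerate(keys)})
    return frames
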