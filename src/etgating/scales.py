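"""Residue volume scale and the group I / group II size classification.

Transmembrane helix-helix packing at the PSII D1/D2 crossing tolerates only
small side chains.  Residues are classified by their mean volume ``V_res``
(side chain inclusive, Å³) into group I (``V_res`` ≤ 130 Å³, excluding Pro)
and group II (Pro, and everything larger than 130 Å³).  The packaged scale is
the Pontius/Wodak mean-residue-volume table; an alternative scale may be
supplied as a two-column text file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

__all__ = [
    "STANDARD_AMINO_ACIDS",
    "SMALL_RESIDUES",
    "GROUP_VOLUME_THRESHOLD",
    "UnknownResidueError",
    "ResidueVolumeScale",
    "ResidueGroup",
    "load_volume_scale",
    "default_scale",
    "residue_volume",
    "classify_group",
]

STANDARD_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: The small set that can occupy a GxxxG-like anchor position (group I).
SMALL_RESIDUES = frozenset("GASCT")

#: Volume boundary between group I and group II, Å³.  The boundary is treated
#: as inclusive (≤ 130 belongs to group I); no residue of the packaged scale
#: sits exactly at 130, so the open/closed distinction never matters there.
GROUP_VOLUME_THRESHOLD = 130.0


class UnknownResidueError(KeyError):
    """Raised when a one-letter code is absent from the volume scale."""

    def __init__(self, code: str):
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:  # KeyError quotes its arg; keep a real message
        return f"unknown amino-acid code: {self.code!r}"


@dataclass(frozen=True)
class ResidueVolumeScale:
    """Side-chain-inclusive residue volumes in Å³, keyed by one-letter code."""

    volumes: Mapping[str, float]
    source_label: str = "Pontius/Wodak mean residue volumes"

    def __post_init__(self):
        missing = STANDARD_AMINO_ACIDS - set(self.volumes)
        if missing:
            raise ValueError(f"volume scale incomplete, missing {sorted(missing)}")
        for code, v in self.volumes.items():
            if not v > 0:
                raise ValueError(f"non-positive volume for {code}: {v}")
        if min(self.volumes, key=self.volumes.get) != "G":
            raise ValueError("Gly must be the smallest residue of the scale")

    def __getitem__(self, code: str) -> float:
        try:
            return self.volumes[code]
        except KeyError:
            raise UnknownResidueError(code) from None


@dataclass(frozen=True)
class ResidueGroup:
    """Size class of a residue: 'I' (small, hinge-compatible) or 'II'."""

    label: str
    threshold: float = GROUP_VOLUME_THRESHOLD

    def __post_init__(self):
        if self.label not in ("I", "II"):
            raise ValueError(f"group label must be 'I' or 'II', got {self.label!r}")


def load_volume_scale(path: str | Path | None = None) -> ResidueVolumeScale:
    """Load a residue volume scale from a two-column text file.

    Lines are ``<one-letter code><whitespace><volume Å³>``; ``#`` starts a
    comment.  With ``path=None`` the packaged Pontius/Wodak table is loaded.
    """
    if path is None:
        text = (
            resources.files("etgating").joinpath("data/wodak_volumes.tsv").read_text()
        )
        label = "Pontius/Wodak mean residue volumes"
    else:
        text = Path(path).read_text()
        label = str(path)
    volumes: dict[str, float] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        code, value = line.split()
        volumes[code.upper()] = float(value)
    return ResidueVolumeScale(volumes=volumes, source_label=label)


_DEFAULT: ResidueVolumeScale | None = None


def default_scale() -> ResidueVolumeScale:
    """The packaged scale, loaded once per process."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_volume_scale()
    return _DEFAULT


def residue_volume(code: str, scale: ResidueVolumeScale | None = None) -> float:
    """Volume ``V_res`` in Å³ of a one-letter amino-acid code."""
    scale = scale or default_scale()
    return scale[code]


def classify_group(code: str, scale: ResidueVolumeScale | None = None) -> ResidueGroup:
    """Classify a residue as group I or group II.

    Group I: volume ≤ 130 Å³ and not proline.  Proline is always group II —
    its backbone ring rigidifies the helix regardless of its modest volume.
    """
    scale = scale or default_scale()
    volume = scale[code]
    if code != "P" and volume <= GROUP_VOLUME_THRESHOLD:
        return ResidueGroup("I")
    return ResidueGroup("II")
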