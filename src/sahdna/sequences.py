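"""Charge-pattern analysis of single alpha-helix (SAH) sequences.

SAH motifs such as the CAF-1 KER region are stabilized by networks of
oppositely charged residues spaced three or four apart (one helical turn),
and the KER additionally carries a stripe of basic residues along one helical
face.  This module quantifies those patterns: a sliding-window net-charge
profile, enumeration of candidate i,i+3 / i,i+4 ion pairs, and a
helical-wheel sector analysis of charge bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with its author residue numbering.

    ``numbering_offset`` is the residue number of the first position (e.g. 136
    for the yeast Cac1 KER construct), so reported positions match the
    numbering used for the parent protein.
    """

    id: str
    residues: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("sequence must contain at least one residue")
        bad = set(self.residues.upper()) - STANDARD_AA
        if bad:
            raise ValueError(f"non-standard residue codes: {sorted(bad)}")
        if self.numbering_offset < 1:
            raise ValueError("numbering_offset must be >= 1")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> np.ndarray:
        """Residue numbers in the sequence's own numbering."""
        return np.arange(len(self)) + self.numbering_offset


@dataclass(frozen=True)
class ChargeScheme:
    """Per-residue formal charge assignment.

    Lys/Arg are +1, Asp/Glu are -1, all others 0.  Histidine is neutral by
    default (pH ~7.4); set ``h_charge`` in [0, 1] to count it as (partially)
    basic, e.g. 1 to reproduce figure colorings that paint His blue.
    """

    h_charge: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h_charge <= 1.0:
            raise ValueError("h_charge must lie in [0, 1]")

    def charge(self, residue: str) -> float:
        r = residue.upper()
        if r in "KR":
            return 1.0
        if r in "DE":
            return -1.0
        if r == "H":
            return self.h_charge
        if r not in STANDARD_AA:
            raise ValueError(f"unknown residue {residue!r}")
        return 0.0

    def charges(self, seq: ProteinSequence) -> np.ndarray:
        return np.array([self.charge(r) for r in seq.residues])


@dataclass
class ChargeProfile:
    """Sliding-window net charge assigned to each window's centre residue."""

    positions: np.ndarray
    net_charge: np.ndarray
    window: int
    scheme: ChargeScheme
    sequence_id: str

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"position": self.positions, "net_charge": self.net_charge}
        )


@dataclass(frozen=True)
class IonPair:
    position_i: int
    position_j: int
    spacing: int
    orientation: str  # "acid-first" or "base-first"


@dataclass
class IonPairNetwork:
    pairs: list[IonPair]
    participation: dict[int, bool]
    sequence_id: str

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class FaceBiasReport:
    """Helical-wheel charge distribution.

    ``sector_start_deg``/``sector_net_charge`` describe a fixed partition of
    the wheel into 360/width bins, so the sector charges sum to the total
    sequence charge.  ``max_basic_sector`` is found by sliding a sector of the
    same width over all residue angles (ties -> smallest start angle).
    """

    sector_width_deg: float
    sector_start_deg: np.ndarray
    sector_net_charge: np.ndarray
    max_basic_sector: tuple[float, float]  # (start angle, net charge)
    bias_index: float
    residue_angles_deg: np.ndarray = field(repr=False, default=None)


def read_fasta(path: str | Path, numbering_offset: int = 1) -> list[ProteinSequence]:
    """Read a (multi-record) FASTA file into ProteinSequence objects."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [
        ProteinSequence(rec.id, str(rec.seq), numbering_offset) for rec in records
    ]


def sliding_net_charge(
    seq: ProteinSequence,
    window: int = 7,
    scheme: ChargeScheme | None = None,
) -> ChargeProfile:
    """Net charge in a sliding window, assigned to the window's centre residue.

    For the default 7-residue window the value is assigned to the fourth
    residue of each window, reported in the sequence's own numbering.
    """
    scheme = scheme or ChargeScheme()
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(seq):
        raise ValueError("sequence too short for the requested window")
    charges = scheme.charges(seq)
    # moving sum via convolution; centre index = (window-1)//2 into each window
    net = np.convolve(charges, np.ones(window), mode="valid")
    centre = (window - 1) // 2
    positions = seq.positions[centre : centre + len(net)]
    return ChargeProfile(positions, net, window, scheme, seq.id)


def predict_ion_pairs(
    seq: ProteinSequence, scheme: ChargeScheme | None = None
) -> IonPairNetwork:
    """All i,i+3 and i,i+4 position pairs with opposite nonzero charges."""
    scheme = scheme or ChargeScheme()
    if len(seq) < 4:
        raise ValueError("sequence must have at least 4 residues")
    charges = scheme.charges(seq)
    offset = seq.numbering_offset
    pairs: list[IonPair] = []
    participation = {int(p): False for p in seq.positions}
    for spacing in (3, 4):
        for i in range(len(seq) - spacing):
            ci, cj = charges[i], charges[i + spacing]
            if ci * cj < 0:
                pi, pj = i + offset, i + spacing + offset
                orientation = "acid-first" if ci < 0 else "base-first"
                pairs.append(IonPair(pi, pj, spacing, orientation))
                participation[pi] = True
                participation[pj] = True
    pairs.sort(key=lambda p: (p.position_i, p.spacing))
    return IonPairNetwork(pairs, participation, seq.id)


def helical_face_bias(
    seq: ProteinSequence,
    scheme: ChargeScheme | None = None,
    twist_deg_per_residue: float = 100.0,
    sector_width_deg: float = 60.0,
) -> FaceBiasReport:
    """Charge distribution around the helical wheel.

    Residue r (1-based within the sequence) sits at wheel angle
    ``(r - 1) * twist mod 360``.  Fixed bins of ``sector_width_deg`` partition
    the wheel (the bin charges sum to the total charge); the maximally basic
    sector is additionally located by sliding a window of the same width over
    all residue angles.
    """
    scheme = scheme or ChargeScheme()
    if not np.isclose(360.0 % sector_width_deg, 0.0) and not np.isclose(
        sector_width_deg - 360.0 % sector_width_deg, sector_width_deg
    ):
        raise ValueError("sector_width_deg must divide 360 for fixed-bin mode")
    charges = scheme.charges(seq)
    angles = (np.arange(len(seq)) * twist_deg_per_residue) % 360.0

    n_bins = int(round(360.0 / sector_width_deg))
    starts = np.arange(n_bins) * sector_width_deg
    bin_idx = np.floor(angles / sector_width_deg).astype(int) % n_bins
    sector_charge = np.zeros(n_bins)
    np.add.at(sector_charge, bin_idx, charges)

    # sliding sector: candidate starts at each distinct residue angle
    best_start, best_charge = 0.0, -np.inf
    for start in sorted(set(np.round(angles, 9))):
        rel = (angles - start) % 360.0
        q = charges[rel < sector_width_deg].sum()
        if q > best_charge + 1e-12:
            best_start, best_charge = float(start), float(q)
    if not np.isfinite(best_charge):
        best_start, best_charge = 0.0, 0.0

    bias_index = float(sector_charge.max() - sector_charge.mean())
    return FaceBiasReport(
        sector_width_deg=sector_width_deg,
        sector_start_deg=starts,
        sector_net_charge=sector_charge,
        max_basic_sector=(best_start, best_charge),
        bias_index=bias_index,
        residue_angles_deg=angles,
    )
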