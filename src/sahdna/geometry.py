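"""Helix geometry from alpha-carbon coordinates.

A long single alpha-helix is characterized by its end-to-end length, the
arc length of its local axis, its number of helical turns, and a per-residue
curvature profile locating bent regions.  The local axis is built from
sliding windows of four consecutive Cα atoms: the second-difference vectors
of the Cα trace point at the axis, their cross product gives the local axis
direction, and the angle between successive second differences gives the
local twist.  This local construction (rather than a global cylinder fit)
keeps the measurement meaningful for curved helices.

Multiple copies of the same helix are compared by optimal least-squares
rigid superposition (Kabsch) over their common residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "HelixModel",
    "HelixAxis",
    "GeometryReport",
    "RMSDMatrix",
    "read_structure",
    "write_pdb",
    "helix_axis",
    "measure_geometry",
    "kabsch",
    "pairwise_rmsd",
]


@dataclass
class HelixModel:
    """Cα trace of one helix copy, in author residue numbering."""

    chain_id: str
    residue_numbers: np.ndarray
    ca_coords: np.ndarray  # (n, 3), angstrom
    source: str = ""

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, int)
        self.ca_coords = np.asarray(self.ca_coords, float)
        if len(self.residue_numbers) < 4:
            raise ValueError("need at least 4 residues")
        if self.ca_coords.shape != (len(self.residue_numbers), 3):
            raise ValueError("ca_coords must be (n_residues, 3)")
        if np.any(np.diff(self.residue_numbers) <= 0):
            raise ValueError("residue numbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residue_numbers)

    def segments(self) -> list[slice]:
        """Runs of consecutive residue numbers (chain breaks split runs)."""
        breaks = np.nonzero(np.diff(self.residue_numbers) != 1)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(self)]])
        return [slice(int(s), int(e)) for s, e in zip(starts, ends)]

    def subset(self, residue_numbers: np.ndarray) -> "HelixModel":
        keep = np.isin(self.residue_numbers, residue_numbers)
        return HelixModel(self.chain_id, self.residue_numbers[keep], self.ca_coords[keep], self.source)


def read_structure(
    path: str | Path,
    chains: list[str] | None = None,
    residue_range: tuple[int, int] | None = None,
) -> list[HelixModel]:
    """Extract per-chain Cα traces from a PDB or mmCIF file.

    Keeps the first alternate location of each residue; ``residue_range`` is
    inclusive in author numbering.  Chains with fewer than 4 Cα in range are
    an error.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    available = [ch.name for ch in model]
    wanted = chains if chains is not None else available
    out = []
    for name in wanted:
        if name not in available:
            raise ValueError(f"chain {name!r} not in structure (has {available})")
        chain = model[name]
        nums, xyz = [], []
        for res in chain:
            num = res.seqid.num
            if residue_range and not residue_range[0] <= num <= residue_range[1]:
                continue
            ca = res.find_atom("CA", "*")  # first altloc wins
            if ca is None:
                continue
            if nums and num == nums[-1]:
                continue  # duplicate residue entry: keep first
            nums.append(num)
            xyz.append([ca.pos.x, ca.pos.y, ca.pos.z])
        if len(nums) < 4:
            raise ValueError(f"chain {name!r}: fewer than 4 Cα in the requested range")
        out.append(HelixModel(name, np.array(nums), np.array(xyz), source=str(path)))
    return out


def write_pdb(model: HelixModel, path: str | Path) -> None:
    """Write a Cα-only PDB file (poly-ALA) for a helix model."""
    st = gemmi.Structure()
    st.name = model.source or "helix"
    md = gemmi.Model("1")
    ch = gemmi.Chain(model.chain_id or "A")
    for num, pos in zip(model.residue_numbers, model.ca_coords):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(int(num), " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*pos)
        atom.occ = 1.0
        res.add_atom(atom)
        ch.add_residue(res)
    md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


@dataclass
class HelixAxis:
    """Local helix axis: one point/direction per 4-Cα window, per segment."""

    points: list[np.ndarray]  # per segment: (w, 3)
    directions: list[np.ndarray]  # per segment: (w, 3), unit vectors
    twist_deg: list[np.ndarray]  # per segment: per-step twist angles
    segment_slices: list[slice]


def _axis_for_segment(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(ca)
    v = ca[:-2] - 2.0 * ca[1:-1] + ca[2:]  # second differences, point at axis
    points, dirs, twists = [], [], []
    for i in range(n - 3):
        va, vb = v[i], v[i + 1]
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        cos_t = float(np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0))
        twists.append(np.degrees(np.arccos(cos_t)))
        d = np.cross(va, vb)
        nd = np.linalg.norm(d)
        if nd < 1e-12:  # degenerate (collinear trace): fall back to chain direction
            d = ca[i + 3] - ca[i]
            nd = np.linalg.norm(d)
        d = d / nd
        if np.dot(d, ca[i + 3] - ca[i]) < 0:
            d = -d
        dirs.append(d)
        # local radius r satisfies |v| = r (2 - 2 cos t); v points axis-ward
        denom = 2.0 - 2.0 * cos_t
        points.append(ca[i + 1] + va / denom if denom > 1e-9 else ca[i + 1])
    # one extra axis point from the trailing residue of the final window
    va = v[-1]
    cos_t = float(np.clip(np.dot(v[-2], v[-1]) / (np.linalg.norm(v[-2]) * np.linalg.norm(v[-1])), -1, 1))
    denom = 2.0 - 2.0 * cos_t
    points.append(ca[n - 2] + va / denom if denom > 1e-9 else ca[n - 2])
    return np.array(points), np.array(dirs), np.array(twists)


def helix_axis(model: HelixModel) -> HelixAxis:
    """Local axis construction from sliding windows of 4 consecutive Cα.

    Chain breaks split the axis into independent segments; each segment needs
    at least 4 residues.
    """
    points, dirs, twists, kept = [], [], [], []
    for seg in model.segments():
        ca = model.ca_coords[seg]
        if len(ca) < 4:
            continue
        p, d, t = _axis_for_segment(ca)
        points.append(p)
        dirs.append(d)
        twists.append(t)
        kept.append(seg)
    if not points:
        raise ValueError("no segment with >= 4 consecutive residues")
    return HelixAxis(points, dirs, twists, kept)


@dataclass
class GeometryReport:
    """Measured geometry of one helix copy."""

    end_to_end_A: float
    axis_arc_A: float
    n_turns: float
    mean_twist_deg: float
    curvature_deg_per_residue: pd.Series  # indexed by residue number
    curved_region: tuple[int, int] | None  # residue-number span above threshold
    curvature_threshold: float
    n_residues: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quantity": [
                    "end_to_end_A", "axis_arc_A", "n_turns",
                    "mean_twist_deg_per_residue", "curved_region",
                ],
                "value": [
                    self.end_to_end_A, self.axis_arc_A, self.n_turns,
                    self.mean_twist_deg,
                    f"{self.curved_region[0]}-{self.curved_region[1]}" if self.curved_region else "none",
                ],
            }
        )


def measure_geometry(model: HelixModel, curvature_threshold: float = 1.5) -> GeometryReport:
    """Length, turns and curvature profile of a helix.

    end_to_end is the first-to-last Cα distance; axis_arc the polyline length
    of the local axis extended to the terminal Cα projections; n_turns is the
    residue count times the mean per-step twist over 360 degrees (so a 3.6
    residue/turn helix of n residues reports n/3.6 turns).  The curvature at
    each interior residue is the local axis direction change in degrees per
    residue; ``curved_region`` is the longest contiguous run above
    ``curvature_threshold``.
    """
    ax = helix_axis(model)
    end_to_end = float(np.linalg.norm(model.ca_coords[-1] - model.ca_coords[0]))

    arc = 0.0
    for seg, pts, dirs in zip(ax.segment_slices, ax.points, ax.directions):
        ca = model.ca_coords[seg]
        start = pts[0] + dirs[0] * np.dot(ca[0] - pts[0], dirs[0])
        end = pts[-1] + dirs[-1] * np.dot(ca[-1] - pts[-1], dirs[-1])
        poly = np.vstack([start, pts, end])
        arc += float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())

    all_twists = np.concatenate(ax.twist_deg)
    mean_twist = float(all_twists.mean())
    n_turns = len(model) * mean_twist / 360.0

    # smooth local directions over ~one helical turn (4 windows) before
    # differencing: the raw per-window axis wobbles with helical phase
    curv_pos, curv_val = [], []
    smooth_w = 4
    for seg, dirs in zip(ax.segment_slices, ax.directions):
        nums = model.residue_numbers[seg]
        if len(dirs) >= smooth_w:
            kern = np.ones(smooth_w) / smooth_w
            sm = np.column_stack([np.convolve(dirs[:, j], kern, mode="valid") for j in range(3)])
            sm /= np.linalg.norm(sm, axis=1, keepdims=True)
            centre_off = 2 + smooth_w // 2  # window centre + smoothing centre
        else:
            sm = dirs
            centre_off = 2
        for j in range(len(sm) - 1):
            cosv = float(np.clip(np.dot(sm[j], sm[j + 1]), -1.0, 1.0))
            curv_pos.append(int(nums[j + centre_off]))
            curv_val.append(np.degrees(np.arccos(cosv)))
    curvature = pd.Series(curv_val, index=pd.Index(curv_pos, name="residue"), name="curvature_deg")

    curved_region = None
    above = curvature[curvature > curvature_threshold]
    if len(above):
        nums = above.index.to_numpy()
        breaks = np.nonzero(np.diff(nums) != 1)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(nums)]])
        runs = [(nums[s], nums[e - 1]) for s, e in zip(starts, ends)]
        curved_region = max(runs, key=lambda r: r[1] - r[0])
        curved_region = (int(curved_region[0]), int(curved_region[1]))

    return GeometryReport(
        end_to_end_A=end_to_end,
        axis_arc_A=arc,
        n_turns=float(n_turns),
        mean_twist_deg=mean_twist,
        curvature_deg_per_residue=curvature,
        curved_region=curved_region,
        curvature_threshold=curvature_threshold,
        n_residues=len(model),
    )


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid superposition of two matched point sets.

    Returns (rotation matrix, translation, RMSD) such that
    ``mobile @ R.T + t`` best fits ``target``; reflections are excluded.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    P, Q = mobile - cm, target - ct
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    moved = (R @ mobile.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return R, t, rmsd


@dataclass
class RMSDMatrix:
    labels: list[str]
    matrix: np.ndarray
    common_residues: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    @property
    def max_offdiagonal(self) -> float:
        m = self.matrix.copy()
        np.fill_diagonal(m, -np.inf)
        return float(m.max())

    @property
    def min_offdiagonal(self) -> float:
        m = self.matrix.copy()
        np.fill_diagonal(m, np.inf)
        return float(m.min())


def pairwise_rmsd(
    models: list[HelixModel],
    residue_range: tuple[int, int] | None = None,
) -> RMSDMatrix:
    """Pairwise Kabsch-superposition RMSD over the models' common residues."""
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    common = models[0].residue_numbers
    for m in models[1:]:
        common = np.intersect1d(common, m.residue_numbers)
    if residue_range is not None:
        common = common[(common >= residue_range[0]) & (common <= residue_range[1])]
    if len(common) < 4:
        raise ValueError("fewer than 4 common residues")
    coords = [m.subset(common).ca_coords for m in models]
    n = len(models)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, r = kabsch(coords[i], coords[j])
            mat[i, j] = mat[j, i] = r
    return RMSDMatrix([m.chain_id for m in models], mat, common)
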