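"""Interdomain hinge-angle analysis for tandem immunoglobulin domains.

Tandem Ig proteins such as titin and hemicentin-1 owe their mechanical
function to a rigid, nearly straight arrangement of consecutive Ig domains.
Each Ig domain carries a central disulfide bridge, whose cysteine pair is a
convenient per-domain landmark: for a three-domain construct the angle at
the central domain's landmark between the two flanking landmarks tracks the
hinge geometry frame by frame.  A rigid tandem keeps this angle near one
value (~150 degrees, close to extended); a destabilised hinge visits a
second, bent conformation and the angle distribution becomes bimodal.

The module post-processes coordinate trajectories (multi-model PDB, XYZ, or
simulated pseudo-atom frames): it locates disulfide pairs, computes the
per-frame angle, histograms it, and classifies the distribution as
unimodal or bimodal with a BIC-guarded Gaussian-mixture fit.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "DomainTriplet",
    "Trajectory",
    "AngleSeries",
    "AngleDistribution",
    "BimodalityResult",
    "GeometryError",
    "locate_disulfide_pairs",
    "interdomain_angle",
    "angle_series",
    "angle_distribution",
    "assess_bimodality",
    "read_pdb_trajectory",
    "write_pdb_trajectory",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "read_domains_toml",
]

DISULFIDE_SG_CUTOFF = 2.3  # Angstrom; S-S bond ~2.05


class GeometryError(ValueError):
    """Raised for malformed trajectories or degenerate geometry."""


@dataclass(frozen=True)
class DomainTriplet:
    """Three consecutive Ig domains with their disulfide cysteine pairs.

    ``domain_ranges`` are inclusive residue intervals, ordered N- to
    C-terminal and non-overlapping.  ``cys_pairs`` hold the residue indices
    of each domain's bridging cysteines and must lie inside their ranges.
    """

    domain_ranges: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    cys_pairs: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        prev_end = None
        for (start, end), (c1, c2) in zip(self.domain_ranges, self.cys_pairs):
            if start > end:
                raise GeometryError(f"inverted domain range {start}-{end}")
            if prev_end is not None and start <= prev_end:
                raise GeometryError("domain ranges must be ordered and non-overlapping")
            prev_end = end
            for c in (c1, c2):
                if not start <= c <= end:
                    raise GeometryError(f"cysteine {c} outside its domain {start}-{end}")


class Trajectory:
    """Frames of pseudo-atoms sharing one atom roster.

    ``atoms`` is a sequence of (residue_index, atom_name); ``coords`` has
    shape (n_frames, n_atoms, 3) in Angstrom.
    """

    def __init__(
        self,
        atoms: Sequence[tuple[int, str]],
        coords: np.ndarray,
        frame_times_ns: np.ndarray | None = None,
    ) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise GeometryError(f"coords must be (n_frames, n_atoms, 3), got {coords.shape}")
        if coords.shape[1] != len(atoms):
            raise GeometryError("atom roster does not match coordinate array")
        if not np.all(np.isfinite(coords)):
            raise GeometryError("non-finite coordinates")
        self.atoms = tuple((int(r), str(n)) for r, n in atoms)
        self.coords = coords
        self.frame_times_ns = (
            None if frame_times_ns is None else np.asarray(frame_times_ns, dtype=float)
        )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> "Frame":
        return Frame(self.atoms, self.coords[i])


@dataclass(frozen=True)
class Frame:
    atoms: tuple[tuple[int, str], ...]
    xyz: np.ndarray

    def positions(self, residues: Sequence[int], atom_name: str) -> np.ndarray:
        """Coordinates of `atom_name` for each residue, in the given order."""
        index = {(r, n): i for i, (r, n) in enumerate(self.atoms)}
        rows = []
        for r in residues:
            try:
                rows.append(index[(r, atom_name)])
            except KeyError:
                raise GeometryError(f"atom {atom_name} of residue {r} missing") from None
        return self.xyz[rows]


@dataclass(frozen=True)
class AngleSeries:
    angles_deg: np.ndarray
    frame_times_ns: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.angles_deg)


@dataclass(frozen=True)
class BimodalityResult:
    n_components: int
    means_deg: tuple[float, ...]
    weights: tuple[float, ...]
    delta_bic: float


@dataclass(frozen=True)
class AngleDistribution:
    bin_edges_deg: np.ndarray
    frequencies: np.ndarray
    mean_deg: float
    sd_deg: float
    modes_deg: tuple[float, ...]
    bimodality: BimodalityResult | None = field(default=None)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def locate_disulfide_pairs(
    frame: Frame,
    domain_ranges: Sequence[tuple[int, int]],
    cutoff: float = DISULFIDE_SG_CUTOFF,
) -> tuple[tuple[int, int], ...]:
    """Find, per domain, the unique cysteine pair whose SG-SG distance is
    within bonding cutoff.  Zero or multiple bonded pairs is an error."""
    pairs = []
    for d, (start, end) in enumerate(domain_ranges, start=1):
        sg = [
            (r, i)
            for i, (r, n) in enumerate(frame.atoms)
            if n == "SG" and start <= r <= end
        ]
        bonded = []
        for a in range(len(sg)):
            for b in range(a + 1, len(sg)):
                dist = np.linalg.norm(frame.xyz[sg[a][1]] - frame.xyz[sg[b][1]])
                if dist <= cutoff:
                    bonded.append((sg[a][0], sg[b][0]))
        if len(bonded) != 1:
            raise GeometryError(
                f"domain {d} ({start}-{end}): expected exactly one disulfide "
                f"pair within {cutoff} A, found {len(bonded)}"
            )
        pairs.append(tuple(sorted(bonded[0])))
    return tuple(pairs)


def _bridge_midpoints(frame: Frame, triplet: DomainTriplet, atom_name: str) -> np.ndarray:
    mids = []
    for c1, c2 in triplet.cys_pairs:
        pos = frame.positions((c1, c2), atom_name)
        mids.append(pos.mean(axis=0))
    return np.asarray(mids)


def interdomain_angle(
    frame: Frame, triplet: DomainTriplet, atom_name: str = "CA"
) -> float:
    """Hinge angle (degrees) at the central domain's disulfide landmark.

    The landmark of each domain is the midpoint of its cysteine pair's CA
    atoms (SG selectable via ``atom_name``); the angle is the vertex angle at
    the central midpoint between the two flanking midpoints.  180 degrees is
    the fully extended tandem.
    """
    m1, m2, m3 = _bridge_midpoints(frame, triplet, atom_name)
    v1 = m1 - m2
    v2 = m3 - m2
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise GeometryError("coincident disulfide midpoints: angle undefined")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def angle_series(
    trajectory: Trajectory, triplet: DomainTriplet, atom_name: str = "CA"
) -> AngleSeries:
    """Per-frame interdomain angle, order-preserving."""
    angles = np.empty(trajectory.n_frames)
    for i in range(trajectory.n_frames):
        try:
            angles[i] = interdomain_angle(trajectory.frame(i), triplet, atom_name)
        except GeometryError as exc:
            raise GeometryError(f"frame {i}: {exc}") from None
    return AngleSeries(angles_deg=angles, frame_times_ns=trajectory.frame_times_ns)


def angle_distribution(
    series: AngleSeries, bin_width_deg: float = 2.0
) -> AngleDistribution:
    """Normalised angle histogram over [0, 180] with summary statistics.

    Attaches the bimodality verdict when the series is long enough for the
    mixture fit (>= 50 frames)."""
    angles = np.asarray(series.angles_deg, dtype=float)
    if angles.size == 0:
        raise GeometryError("empty angle series")
    n_bins = int(np.ceil(180.0 / bin_width_deg))
    edges = np.linspace(0.0, n_bins * bin_width_deg, n_bins + 1)
    counts, edges = np.histogram(angles, bins=edges)
    freqs = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    # local maxima of the histogram (plateau-insensitive, strict neighbours)
    occupied = counts > 0
    modes = []
    for i in np.flatnonzero(occupied):
        left = counts[i - 1] if i > 0 else -1
        right = counts[i + 1] if i < len(counts) - 1 else -1
        if counts[i] >= left and counts[i] >= right and counts[i] > 0:
            modes.append(float(centers[i]))
    bim = assess_bimodality(series) if angles.size >= 50 else None
    return AngleDistribution(
        bin_edges_deg=edges,
        frequencies=freqs,
        mean_deg=float(angles.mean()),
        sd_deg=float(angles.std(ddof=0)),
        modes_deg=tuple(modes),
        bimodality=bim,
    )


def assess_bimodality(series: AngleSeries) -> BimodalityResult:
    """Classify an angle series as unimodal or bimodal.

    Fits 1- and 2-component Gaussian mixtures (fixed seed, 10 restarts) and
    reports two components only under strong combined evidence:
    BIC(2) < BIC(1) - 10, both weights >= 0.05, and mean separation of at
    least twice the pooled within-component SD.  The guards suppress
    spurious two-component fits on heavy-tailed unimodal data.
    """
    from sklearn.mixture import GaussianMixture

    angles = np.asarray(series.angles_deg, dtype=float).reshape(-1, 1)
    if angles.shape[0] < 50:
        raise GeometryError(f"series of {angles.shape[0]} frames too short (need >= 50)")
    if np.ptp(angles) < 1e-9:  # constant series: trivially unimodal
        return BimodalityResult(
            n_components=1,
            means_deg=(float(angles[0, 0]),),
            weights=(1.0,),
            delta_bic=0.0,
        )
    fits = {
        k: GaussianMixture(
            n_components=k, n_init=10, random_state=0, covariance_type="full"
        ).fit(angles)
        for k in (1, 2)
    }
    delta_bic = float(fits[1].bic(angles) - fits[2].bic(angles))  # >0 favours 2 comps
    g2 = fits[2]
    means = g2.means_.ravel()
    weights = g2.weights_.ravel()
    sds = np.sqrt(g2.covariances_.ravel())
    pooled_sd = float(np.sqrt(np.sum(weights * sds**2)))
    separated = abs(means[0] - means[1]) >= 2.0 * pooled_sd
    if delta_bic > 10.0 and weights.min() >= 0.05 and separated:
        order = np.argsort(-weights)
        return BimodalityResult(
            n_components=2,
            means_deg=tuple(float(means[i]) for i in order),
            weights=tuple(float(weights[i]) for i in order),
            delta_bic=delta_bic,
        )
    g1 = fits[1]
    return BimodalityResult(
        n_components=1,
        means_deg=(float(g1.means_.ravel()[0]),),
        weights=(1.0,),
        delta_bic=delta_bic,
    )


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------


def write_pdb_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB (one MODEL per frame)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_atoms = len(trajectory.atoms)
    stack = struc.AtomArrayStack(trajectory.n_frames, n_atoms)
    stack.coord = trajectory.coords
    stack.res_id = np.array([r for r, _ in trajectory.atoms])
    stack.atom_name = np.array([n for _, n in trajectory.atoms])
    stack.res_name = np.array(
        ["CYS" if n in ("SG",) else "GLY" for _, n in trajectory.atoms]
    )
    stack.chain_id = np.array(["A"] * n_atoms)
    stack.element = np.array([n[0] for _, n in trajectory.atoms])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_pdb_trajectory(path: str | Path) -> Trajectory:
    """Read a multi-model PDB into a Trajectory (residue index + atom name)."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    atoms = list(zip(stack.res_id.tolist(), stack.atom_name.tolist()))
    return Trajectory(atoms=atoms, coords=stack.coord)


def write_xyz_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write frames as concatenated XYZ blocks.

    The atom label column carries ``NAME.RESID`` (e.g. ``CA.12``) so the
    roster survives the round trip; plain element labels are accepted on
    read but lose residue indices.
    """
    lines = []
    for f in range(trajectory.n_frames):
        lines.append(str(len(trajectory.atoms)))
        lines.append(f"frame {f}")
        for (res, name), (x, y, z) in zip(trajectory.atoms, trajectory.coords[f]):
            lines.append(f"{name}.{res} {x:.3f} {y:.3f} {z:.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz_trajectory(path: str | Path) -> Trajectory:
    lines = Path(path).read_text().splitlines()
    i = 0
    frames: list[np.ndarray] = []
    atoms: list[tuple[int, str]] | None = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise GeometryError(f"{path}:{i + 1}: expected atom count") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) != n:
            raise GeometryError(f"{path}: truncated frame at line {i + 1}")
        roster = []
        xyz = np.empty((n, 3))
        for j, row in enumerate(block):
            label, x, y, z = row.split()
            if "." in label:
                name, res = label.rsplit(".", 1)
                roster.append((int(res), name))
            else:
                roster.append((j + 1, label))
            xyz[j] = (float(x), float(y), float(z))
        if atoms is None:
            atoms = roster
        elif roster != atoms:
            raise GeometryError(f"{path}: inconsistent atom roster between frames")
        frames.append(xyz)
        i += 2 + n
    if atoms is None:
        raise GeometryError(f"{path}: no frames")
    return Trajectory(atoms=atoms, coords=np.stack(frames))


def read_domains_toml(path: str | Path) -> DomainTriplet:
    """Domain definition TOML: three [[domain]] tables with ``range`` and
    ``cys_pair`` arrays."""
    data = tomllib.loads(Path(path).read_text())
    doms = data.get("domain")
    if not doms or len(doms) != 3:
        raise GeometryError(f"{path}: need exactly three [[domain]] tables")
    ranges = tuple((int(d["range"][0]), int(d["range"][1])) for d in doms)
    pairs = tuple((int(d["cys_pair"][0]), int(d["cys_pair"][1])) for d in doms)
    return DomainTriplet(domain_ranges=ranges, cys_pairs=pairs)
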