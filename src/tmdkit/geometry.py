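"""Idealized Cn-symmetric transmembrane helix bundles.

The generator places ideal alpha-helices (Crick-style parameterization:
superhelical radius, interface phase, axial offset, tilt) around a common
bundle axis taken to coincide with the membrane normal (z).  It is a
deterministic stand-in for fragment-based backbone sampling: every geometric
degree of freedom that matters for a single-span bundle — how far the
helices sit from the axis, how they are rotated about their own axes, how
much they lean — is an explicit parameter.

Coordinates are C-alpha only and live in the membrane frame: z is the
membrane normal and z = 0 the bilayer midplane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

#: Minor-helix radius of an ideal alpha-helix C-alpha trace (Angstrom).
ALPHA_HELIX_RADIUS = 2.26

#: Consecutive C-alpha distance in a protein chain (Angstrom).
CA_CA_DISTANCE = 3.8


class GeometryError(ValueError):
    """Invalid bundle parameters or malformed bundle input."""


@dataclass(frozen=True)
class MembraneFrame:
    """Implicit membrane slab: midplane position and half thickness (Angstrom)."""

    midplane_z: float = 0.0
    half_thickness: float = 15.0

    def __post_init__(self) -> None:
        if self.half_thickness <= 0:
            raise GeometryError("half_thickness must be positive")


@dataclass(frozen=True)
class CrickParams:
    """Geometric degrees of freedom of an idealized Cn helix bundle.

    Parameters
    ----------
    superhelical_radius
        Distance (Angstrom) from the bundle axis to each helix axis.
    interface_phase
        Rotation (degrees) of each helix about its own axis; selects which
        face points toward the bundle core.
    z_offset
        Axial displacement (Angstrom) of the helix midpoints from the
        membrane midplane.
    tilt
        Angle (degrees) between each helix axis and the membrane normal.
    rise_per_residue, residues_per_turn
        Minor-helix parameters; defaults are ideal alpha-helix values.
    n_chains
        Oligomeric order, 1 (monomer) through 4 (C4 tetramer).
    chain_length
        Residues per chain (single-span TMDs are ~24).
    parallel
        If False, every second chain is flipped top-to-bottom (antiparallel
        topology); exact Cn symmetry is only guaranteed for parallel bundles.
    """

    superhelical_radius: float = 5.0
    interface_phase: float = 0.0
    z_offset: float = 0.0
    tilt: float = 10.0
    rise_per_residue: float = 1.51
    residues_per_turn: float = 3.6
    n_chains: int = 2
    chain_length: int = 24
    parallel: bool = True

    def __post_init__(self) -> None:
        if self.superhelical_radius < 0:
            raise GeometryError("superhelical_radius must be >= 0")
        if self.n_chains not in (1, 2, 3, 4):
            raise GeometryError("n_chains must be in {1, 2, 3, 4}")
        if self.chain_length < 8:
            raise GeometryError("chain_length must be >= 8")
        if self.rise_per_residue <= 0:
            raise GeometryError("rise_per_residue must be positive")


@dataclass
class HelixBundle:
    """C-alpha coordinates and sequences of a (putatively) symmetric bundle.

    ``coords`` has shape ``(n_chains, chain_length, 3)`` in Angstrom, in the
    membrane frame.  All chains carry the same length; for symmetric designs
    they also carry the same sequence.
    """

    coords: np.ndarray
    sequences: list[str]
    symmetry_order: int
    frame: MembraneFrame = field(default_factory=MembraneFrame)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise GeometryError("coords must have shape (n_chains, length, 3)")
        if len(self.sequences) != self.coords.shape[0]:
            raise GeometryError("one sequence per chain required")
        if len({len(s) for s in self.sequences} | {self.coords.shape[1]}) != 1:
            raise GeometryError("all chains must have equal length")

    @property
    def n_chains(self) -> int:
        return self.coords.shape[0]

    @property
    def chain_length(self) -> int:
        return self.coords.shape[1]

    def with_sequence(self, sequence: str) -> "HelixBundle":
        """Same backbone, one new sequence applied to every chain."""
        if len(sequence) != self.chain_length:
            raise GeometryError("sequence length must match chain length")
        return HelixBundle(
            self.coords.copy(), [sequence] * self.n_chains, self.symmetry_order, self.frame
        )


def _ideal_helix(params: CrickParams) -> np.ndarray:
    """C-alpha trace of an ideal helix whose axis is +z, centered at origin."""
    i = np.arange(params.chain_length, dtype=float)
    omega = 2.0 * np.pi / params.residues_per_turn
    phase = np.deg2rad(params.interface_phase)
    z = (i - (params.chain_length - 1) / 2.0) * params.rise_per_residue
    return np.column_stack(
        [
            ALPHA_HELIX_RADIUS * np.cos(omega * i + phase),
            ALPHA_HELIX_RADIUS * np.sin(omega * i + phase),
            z,
        ]
    )


def build_symmetric_bundle(params: CrickParams, sequence: str) -> HelixBundle:
    """Construct an exactly Cn-symmetric bundle from explicit geometry.

    Chain 1 is an ideal helix tilted by ``params.tilt`` from the membrane
    normal (the lean is tangential, as in a coiled coil), placed with its
    axis at ``superhelical_radius`` from the bundle axis and its midpoint at
    ``z_offset``.  Chains 2..n are exact copies rotated by 360/n degrees
    about the bundle axis, so Cn symmetry holds to machine precision.

    For a monomer the superhelical radius is ignored and the helix sits on
    the bundle axis.
    """
    if len(sequence) != params.chain_length:
        raise GeometryError(
            f"sequence length {len(sequence)} != chain_length {params.chain_length}"
        )
    local = _ideal_helix(params)
    # Lean the helix axis tangentially (about the radial x-axis at placement).
    tilt_rot = Rotation.from_euler("x", params.tilt, degrees=True)
    local = tilt_rot.apply(local)
    radius = 0.0 if params.n_chains == 1 else params.superhelical_radius
    local = local + np.array([radius, 0.0, params.z_offset])

    chains = []
    for k in range(params.n_chains):
        chain = local
        if not params.parallel and k % 2 == 1:
            # Flip top-to-bottom about the x-axis through the midplane.
            chain = chain * np.array([1.0, -1.0, -1.0])
        rot = Rotation.from_euler("z", 360.0 * k / params.n_chains, degrees=True)
        chains.append(rot.apply(chain))

    return HelixBundle(
        np.stack(chains), [sequence] * params.n_chains, params.n_chains, MembraneFrame()
    )


def helix_tilt_angle(bundle: HelixBundle, chain_index: int = 0) -> float:
    """Angle in degrees, in [0, 90], between a chain's least-squares axis
    and the membrane normal."""
    if not 0 <= chain_index < bundle.n_chains:
        raise GeometryError(f"chain {chain_index} does not exist")
    pts = bundle.coords[chain_index]
    if pts.shape[0] < 4:
        raise GeometryError("need >= 4 residues to fit a helix axis")
    centered = pts - pts.mean(axis=0)
    # Principal direction of the C-alpha cloud = helix axis for >= one turn.
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    cos_theta = abs(axis[2]) / np.linalg.norm(axis)
    return float(np.degrees(np.arccos(np.clip(cos_theta, -1.0, 1.0))))


def crossing_angle_penalty(theta: float) -> float:
    """Cubic bias against large helix crossing angles (theta in degrees).

    penalty = 1.51e-4 * t^3 - 8.925e-3 * t^2 + 0.187 * t - 0.532

    Large tilts relative to the membrane normal are rare in natural
    single-span TMDs; this centroid-level potential penalizes them.
    """
    if theta < 0:
        raise GeometryError("crossing angle must be non-negative")
    return float(
        1.51e-4 * theta**3 - 8.925e-3 * theta**2 + 0.187 * theta - 0.532
    )


def _rotated_coords(bundle: HelixBundle) -> np.ndarray:
    angle = 360.0 / bundle.symmetry_order
    rot = Rotation.from_euler("z", angle, degrees=True)
    return rot.apply(bundle.coords.reshape(-1, 3)).reshape(bundle.coords.shape)


def symmetry_rmsd(bundle: HelixBundle) -> float:
    """Coordinate RMSD between the bundle and itself rotated by 360/n about
    the bundle axis, minimized over cyclic chain re-indexings.

    Zero (to machine precision) for generator output; grows with any
    departure from exact Cn symmetry.
    """
    n = bundle.symmetry_order
    if n < 2:
        raise GeometryError("symmetry_rmsd requires symmetry_order >= 2")
    rotated = _rotated_coords(bundle)
    best = np.inf
    for shift in range(n):
        target = bundle.coords[(np.arange(n) + shift) % n]
        rmsd = float(np.sqrt(np.mean(np.sum((rotated - target) ** 2, axis=-1))))
        best = min(best, rmsd)
    return best


def _kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between point sets after optimal rigid superposition (Kabsch)."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    u, _, vt = np.linalg.svd(b.T @ a)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return float(np.sqrt(np.mean(np.sum((b @ rot - a) ** 2, axis=1))))


def rmsd_between(a: HelixBundle, b: HelixBundle, symmetry_aware: bool = True) -> float:
    """C-alpha RMSD after optimal superposition.

    With ``symmetry_aware`` the value is additionally minimized over cyclic
    chain relabelings, so that two copies of the same Cn bundle differing
    only in chain numbering score 0.
    """
    if a.coords.shape != b.coords.shape:
        raise GeometryError("bundles must have equal chain counts and lengths")
    n = a.n_chains
    shifts = range(n) if (symmetry_aware and n > 1) else [0]
    best = np.inf
    flat_a = a.coords.reshape(-1, 3)
    for shift in shifts:
        reordered = b.coords[(np.arange(n) + shift) % n].reshape(-1, 3)
        best = min(best, _kabsch_rmsd(flat_a, reordered))
    return best


def perturbed(bundle: HelixBundle, sigma: float, seed: int) -> HelixBundle:
    """Bundle with iid Gaussian coordinate jitter (testing aid)."""
    rng = np.random.default_rng(seed)
    noisy = bundle.coords + rng.normal(0.0, sigma, size=bundle.coords.shape)
    return replace(bundle, coords=noisy)
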