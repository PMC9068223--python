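"""Surrogate membrane energy function and design/prediction filters.

The scorer reproduces the *decision structure* of a membrane-protein energy
function at centroid resolution: a soft-sphere packing term over residue
spheres, a depth-dependent lipophilicity term, and the cubic crossing-angle
bias.  It is deliberately simple and fully deterministic, and is exposed
behind a small functional surface so that an atomistic scorer can be
substituted wherever a scorer is accepted.

Energies are reported in the same (dimensionless) units in which the filter
thresholds are expressed; lipophilicity inputs are kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .geometry import GeometryError, HelixBundle, crossing_angle_penalty, helix_tilt_angle

# Effective residue-sphere radii (Angstrom), centered on C-alpha; roughly
# proportional to side-chain volume.  Calibrated once for the soft-sphere
# packing term and the Shrake-Rupley surface areas.
RESIDUE_RADII = {
    "G": 2.3, "A": 2.6, "S": 2.7, "C": 2.9, "T": 2.9, "P": 3.0, "D": 3.0,
    "V": 3.1, "N": 3.1, "I": 3.3, "L": 3.3, "E": 3.3, "M": 3.4, "Q": 3.4,
    "H": 3.4, "F": 3.5, "K": 3.5, "Y": 3.6, "R": 3.7, "W": 3.8,
}

PROBE_RADIUS = 1.4        # water probe, Angstrom
SASA_N_POINTS = 960       # Shrake-Rupley sphere points
PACKING_EPSILON = 1.0     # soft-sphere well depth
PACKING_CUTOFF = 10.0     # Angstrom
SC_DISTANCE_WEIGHT = 0.5  # Lawrence-Colman w, 1/Angstrom^2
SC_INTERFACE_CUTOFF = 8.0 # cross-chain atom distance defining the interface
SC_CONTACT_BAND = 1.0     # max |signed gap| (Angstrom) for a surface point to count
HELICALITY_SCALE = 1e-3   # (energy units) / degrees^2
INTERFACE_BURIAL_FRACTION = 0.25


class EnergyEvaluationError(ValueError):
    """Bundle or table unsuitable for scoring."""


class LipophilicityTable:
    """Piecewise-linear insertion energy vs membrane depth, per amino acid.

    File format: delimited text with columns ``aa``, ``z`` (Angstrom) and
    ``energy`` (kcal/mol); ``#`` comment lines ignored.  Values are linearly
    interpolated between knots and held constant beyond the outermost knots.
    """

    def __init__(self, profiles: dict[str, tuple[np.ndarray, np.ndarray]], source: str = "custom"):
        self.source = source
        self._profiles = {}
        for aa, (z, e) in profiles.items():
            z = np.asarray(z, dtype=float)
            e = np.asarray(e, dtype=float)
            if not (np.all(np.isfinite(z)) and np.all(np.isfinite(e))):
                raise EnergyEvaluationError(f"non-finite profile for {aa}")
            if z.min() > -22.5 or z.max() < 22.5:
                raise EnergyEvaluationError(f"profile for {aa} must cover [-22.5, 22.5] A")
            order = np.argsort(z)
            self._profiles[aa] = (z[order], e[order])

    @classmethod
    def from_file(cls, path, source: str | None = None) -> "LipophilicityTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        profiles = {
            aa: (g["z"].to_numpy(), g["energy"].to_numpy())
            for aa, g in df.groupby("aa")
        }
        return cls(profiles, source=source or str(path))

    @classmethod
    def default(cls) -> "LipophilicityTable":
        """Packaged biological-hydrophobicity-scale profile."""
        ref = resources.files("tmdkit.data") / "lipophilicity_biological.tsv"
        with resources.as_file(ref) as path:
            return cls.from_file(path, source="biological-scale default")

    def energy(self, aa: str, z: float) -> float:
        if aa not in self._profiles:
            raise EnergyEvaluationError(f"unknown residue type {aa!r}")
        knots_z, knots_e = self._profiles[aa]
        return float(np.interp(z, knots_z, knots_e))

    def covers(self, sequence: str) -> bool:
        return all(aa in self._profiles for aa in sequence)


@dataclass(frozen=True)
class FilterThresholds:
    """Structure/energy filter cutoffs for one pipeline stage.

    All comparisons are strict inequalities; a value exactly at a threshold
    fails.  The design-stage energy percentile is an ensemble-level
    criterion (see :func:`energy_percentile_mask`), not a per-model one.
    """

    stage: str = "design"
    sasa_min: float = 700.0
    sc_min: float = 0.6
    ddg_max: float = -15.0
    helicality_max: float = 0.1
    energy_percentile: float = 1.0
    energy_max: float = 0.0
    span_min: float = 25.0
    topo_min: float = 0.1

    def __post_init__(self) -> None:
        if self.stage not in ("design", "prediction"):
            raise EnergyEvaluationError("stage must be 'design' or 'prediction'")

    @classmethod
    def design(cls) -> "FilterThresholds":
        return cls(stage="design")

    @classmethod
    def prediction(cls) -> "FilterThresholds":
        return cls(stage="prediction", sasa_min=600.0)


@dataclass
class EnergyReport:
    """All scored quantities for one bundle."""

    total_energy: float
    packing_term: float
    lipophilicity_term: float
    crossing_penalty_term: float
    ddg_binding: float = math.nan
    interface_sasa: float = math.nan
    shape_complementarity: float = math.nan
    helicality: float = math.nan
    tm_span_extent: float = math.nan
    topology_match_fraction: float = math.nan

    def as_series(self) -> pd.Series:
        return pd.Series(vars(self))


# ---------------------------------------------------------------------------
# Core terms


def _atom_arrays(bundle: HelixBundle) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Flat coords, radii, chain index and residue index arrays."""
    coords = bundle.coords.reshape(-1, 3)
    try:
        radii = np.array(
            [RESIDUE_RADII[aa] for seq in bundle.sequences for aa in seq]
        )
    except KeyError as exc:
        raise EnergyEvaluationError(f"unknown residue type {exc.args[0]!r}") from None
    n, length = bundle.n_chains, bundle.chain_length
    chain_idx = np.repeat(np.arange(n), length)
    res_idx = np.tile(np.arange(length), n)
    return coords, radii, chain_idx, res_idx


def _pairwise_packing(coords, radii, chain_idx, res_idx) -> float:
    """Soft Lennard-Jones-style packing over residue spheres.

    Only cross-chain pairs count: this is an interface packing term (the
    intra-chain backbone is constrained to ideal helicality separately), so
    isolated or widely separated chains score exactly 0.
    """
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=-1))
    r0 = radii[:, None] + radii[None, :]
    same_chain = chain_idx[:, None] == chain_idx[None, :]
    mask = np.triu(np.ones_like(dist, dtype=bool), k=1)
    mask &= ~same_chain
    mask &= dist < PACKING_CUTOFF
    if not mask.any():
        return 0.0
    ratio = r0[mask] / np.maximum(dist[mask], 0.5)
    e = PACKING_EPSILON * (ratio**12 - 2.0 * ratio**6)
    return float(e.sum())


def packing_energy(bundle: HelixBundle) -> float:
    return _pairwise_packing(*_atom_arrays(bundle))


def lipophilicity_energy(bundle: HelixBundle, table: LipophilicityTable) -> float:
    total = 0.0
    for seq, chain in zip(bundle.sequences, bundle.coords):
        for aa, xyz in zip(seq, chain):
            total += table.energy(aa, xyz[2] - bundle.frame.midplane_z)
    return total


def crossing_energy(bundle: HelixBundle) -> float:
    return sum(
        crossing_angle_penalty(helix_tilt_angle(bundle, k)) for k in range(bundle.n_chains)
    )


def system_energy(bundle: HelixBundle, table: LipophilicityTable) -> float:
    """Fast path: packing + lipophilicity + crossing penalty only."""
    if bundle.coords.size == 0:
        raise EnergyEvaluationError("empty bundle")
    return packing_energy(bundle) + lipophilicity_energy(bundle, table) + crossing_energy(bundle)


def _single_chain(bundle: HelixBundle, k: int) -> HelixBundle:
    return HelixBundle(
        bundle.coords[k : k + 1].copy(), [bundle.sequences[k]], 1, bundle.frame
    )


def ddg_binding(bundle: HelixBundle, table: LipophilicityTable) -> float:
    """Association energy: complex minus isolated chains (same internal
    coordinates).  Per-chain terms cancel exactly, so this equals the
    cross-chain packing energy; chains already far apart score 0."""
    if bundle.symmetry_order < 2 or bundle.n_chains < 2:
        raise EnergyEvaluationError("ddg_binding requires an oligomer")
    total = system_energy(bundle, table)
    isolated = sum(system_energy(_single_chain(bundle, k), table) for k in range(bundle.n_chains))
    return total - isolated


# ---------------------------------------------------------------------------
# Surface areas (Shrake-Rupley on residue spheres)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + math.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


_UNIT_SPHERE = _sphere_points(SASA_N_POINTS)


def sasa_per_atom(coords: np.ndarray, radii: np.ndarray, probe: float = PROBE_RADIUS) -> np.ndarray:
    """Shrake-Rupley solvent-accessible area per sphere (Angstrom^2)."""
    coords = np.asarray(coords, dtype=float)
    expanded = np.asarray(radii, dtype=float) + probe
    n = coords.shape[0]
    areas = np.empty(n)
    for i in range(n):
        test = coords[i] + expanded[i] * _UNIT_SPHERE
        accessible = np.ones(len(test), dtype=bool)
        d_centers = np.linalg.norm(coords - coords[i], axis=1)
        neighbors = np.where((d_centers < expanded + expanded[i]) & (np.arange(n) != i))[0]
        for j in neighbors:
            d = np.linalg.norm(test - coords[j], axis=1)
            accessible &= d >= expanded[j]
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * accessible.mean()
    return areas


def _bundle_sasa(bundle: HelixBundle) -> np.ndarray:
    coords, radii, _, _ = _atom_arrays(bundle)
    return sasa_per_atom(coords, radii)


def interface_sasa(bundle: HelixBundle) -> float:
    """Buried surface area on complexation: sum of isolated-chain SASAs
    minus the complex SASA (probe 1.4 Angstrom)."""
    if bundle.n_chains < 2:
        raise EnergyEvaluationError("interface_sasa requires >= 2 chains")
    complex_area = _bundle_sasa(bundle).sum()
    isolated = sum(_bundle_sasa(_single_chain(bundle, k)).sum() for k in range(bundle.n_chains))
    return float(isolated - complex_area)


def classify_interface_positions(
    bundle: HelixBundle, burial_fraction: float = INTERFACE_BURIAL_FRACTION
) -> list[str]:
    """Per-position 'interface' / 'exposed' labels (chain 1 reported;
    symmetric bundles make all chains equivalent).

    A position is interface if its residue-sphere SASA drops by more than
    ``burial_fraction`` of its isolated-chain value upon complexation.
    """
    if bundle.n_chains < 2:
        raise EnergyEvaluationError("interface classification requires an oligomer")
    complex_areas = _bundle_sasa(bundle)[: bundle.chain_length]
    isolated_areas = _bundle_sasa(_single_chain(bundle, 0))
    labels = []
    for iso, cplx in zip(isolated_areas, complex_areas):
        drop = (iso - cplx) / iso if iso > 1e-9 else 0.0
        labels.append("interface" if drop > burial_fraction else "exposed")
    return labels


# ---------------------------------------------------------------------------
# Shape complementarity (Lawrence-Colman style on residue-sphere surfaces)


def sc_from_points(
    points_a: np.ndarray,
    normals_a: np.ndarray,
    points_b: np.ndarray,
    normals_b: np.ndarray,
    w: float = SC_DISTANCE_WEIGHT,
) -> float:
    """Median complementarity of two point/normal surface patches.

    For each point on one surface the nearest point on the other is found
    and scored as ``(-n_a . n_b) * exp(-w d^2)``; the statistic is the mean
    of the two per-side medians.  1 for perfectly apposed anti-parallel
    surfaces in contact; near 0 for unrelated surfaces.
    """
    def side(pa, na, pb, nb):
        d2 = np.sum((pa[:, None, :] - pb[None, :, :]) ** 2, axis=-1)
        nearest = np.argmin(d2, axis=1)
        dot = -np.sum(na * nb[nearest], axis=1)
        return np.median(dot * np.exp(-w * d2[np.arange(len(pa)), nearest]))

    return float(
        0.5 * (side(points_a, normals_a, points_b, normals_b)
               + side(points_b, normals_b, points_a, normals_a))
    )


def _surface_points(coords, radii, n_points=120):
    """Contact-surface points and outward normals for one side's spheres."""
    sphere = _sphere_points(n_points)
    pts, nrm = [], []
    for i in range(coords.shape[0]):
        test = coords[i] + radii[i] * sphere
        keep = np.ones(len(test), dtype=bool)
        for j in range(coords.shape[0]):
            if j == i:
                continue
            keep &= np.linalg.norm(test - coords[j], axis=1) >= radii[j]
        pts.append(test[keep])
        nrm.append(sphere[keep])
    return np.concatenate(pts), np.concatenate(nrm)


def _sc_one_side(points, normals, other_centers, other_radii, w, band):
    """Median complementarity of one side's contact band against the other
    side's sphere surface (signed gap to the nearest sphere)."""
    d = np.linalg.norm(points[:, None, :] - other_centers[None, :, :], axis=-1)
    j = np.argmin(d - other_radii[None, :], axis=1)
    gap = d[np.arange(len(points)), j] - other_radii[j]
    to_point = points - other_centers[j]
    other_normals = to_point / np.linalg.norm(to_point, axis=1, keepdims=True)
    in_band = np.abs(gap) < band
    if in_band.sum() < 3:
        raise EnergyEvaluationError("no interface contact within cutoff")
    s = -np.sum(normals * other_normals, axis=1) * np.exp(-w * gap**2)
    return float(np.median(s[in_band]))


def shape_complementarity(bundle: HelixBundle, n_points: int = 120) -> float:
    """Interface shape complementarity in [-1, 1].

    Side A is chain 1, side B the remaining chains.  Surface points of
    interface atoms (cross-side neighbor within 8 Angstrom) are scored
    against the signed gap to the nearest opposing sphere surface and the
    normal at that surface, s = (-n_a . n_b) exp(-w gap^2); the statistic
    is the mean of the two per-side medians over the contact band.
    Raises if there is no interface contact (undefined, distinct from 0).
    """
    if bundle.n_chains < 2:
        raise EnergyEvaluationError("shape complementarity requires >= 2 chains")
    coords, radii, chain_idx, _ = _atom_arrays(bundle)
    a_mask = chain_idx == 0
    ca, ra = coords[a_mask], radii[a_mask]
    cb, rb = coords[~a_mask], radii[~a_mask]
    dists = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    a_iface = dists.min(axis=1) < SC_INTERFACE_CUTOFF
    b_iface = dists.min(axis=0) < SC_INTERFACE_CUTOFF
    if not (a_iface.any() and b_iface.any()):
        raise EnergyEvaluationError("no interface contact within cutoff")
    pa, na = _surface_points(ca[a_iface], ra[a_iface], n_points)
    pb, nb = _surface_points(cb[b_iface], rb[b_iface], n_points)
    side_a = _sc_one_side(pa, na, cb, rb, SC_DISTANCE_WEIGHT, SC_CONTACT_BAND)
    side_b = _sc_one_side(pb, nb, ca, ra, SC_DISTANCE_WEIGHT, SC_CONTACT_BAND)
    return 0.5 * (side_a + side_b)


# ---------------------------------------------------------------------------
# Geometry-derived filter quantities


def tm_span_extent(bundle: HelixBundle) -> float:
    """Minimum over chains of |z(first CA) - z(last CA)| (Angstrom)."""
    if bundle.coords.size == 0:
        raise EnergyEvaluationError("empty bundle")
    spans = np.abs(bundle.coords[:, 0, 2] - bundle.coords[:, -1, 2])
    return float(spans.min())


def topology_match_fraction(bundle: HelixBundle, desired: list[str], chain_index: int = 0) -> float:
    """Fraction of positions whose z-derived compartment matches ``desired``.

    Compartments: |z| within the slab half-thickness -> 'membrane';
    below -> 'cytosolic'; above -> 'external'.
    """
    if len(desired) != bundle.chain_length:
        raise EnergyEvaluationError("label vector length must equal chain length")
    half = bundle.frame.half_thickness
    mid = bundle.frame.midplane_z
    matches = 0
    for label, xyz in zip(desired, bundle.coords[chain_index]):
        z = xyz[2] - mid
        actual = "membrane" if abs(z) <= half else ("cytosolic" if z < 0 else "external")
        matches += actual == label
    return matches / bundle.chain_length


def _ca_pseudo_torsions(chain: np.ndarray) -> np.ndarray:
    """Pseudo-dihedral over consecutive CA quadruples, degrees in (-180, 180]."""
    b1 = chain[1:-2] - chain[:-3]
    b2 = chain[2:-1] - chain[1:-2]
    b3 = chain[3:] - chain[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(m1 * n2, axis=1)
    return np.degrees(np.arctan2(y, x))


_IDEAL_TORSION_CACHE: dict[tuple[float, float], float] = {}


def _ideal_torsion(rise: float = 1.51, residues_per_turn: float = 3.6) -> float:
    key = (rise, residues_per_turn)
    if key not in _IDEAL_TORSION_CACHE:
        from .geometry import ALPHA_HELIX_RADIUS
        i = np.arange(8, dtype=float)
        omega = 2.0 * np.pi / residues_per_turn
        ref = np.column_stack(
            [ALPHA_HELIX_RADIUS * np.cos(omega * i),
             ALPHA_HELIX_RADIUS * np.sin(omega * i),
             i * rise]
        )
        _IDEAL_TORSION_CACHE[key] = float(_ca_pseudo_torsions(ref).mean())
    return _IDEAL_TORSION_CACHE[key]


def helicality(bundle: HelixBundle, scale: float = HELICALITY_SCALE) -> float:
    """Mean squared deviation of CA pseudo-torsions from the ideal helical
    value, scaled to energy units; 0 for ideal generator output, large for
    extended or kinked chains."""
    if bundle.chain_length < 4:
        raise EnergyEvaluationError("helicality requires >= 4 residues")
    ideal = _ideal_torsion()
    devs = []
    for chain in bundle.coords:
        delta = _ca_pseudo_torsions(chain) - ideal
        delta = (delta + 180.0) % 360.0 - 180.0
        devs.append(delta**2)
    return float(scale * np.mean(np.concatenate(devs)))


# ---------------------------------------------------------------------------
# Full report and filters


def score_bundle(
    bundle: HelixBundle,
    table: LipophilicityTable | None = None,
    desired_topology: list[str] | None = None,
    full: bool = True,
) -> EnergyReport:
    """Deterministic full scoring of a bundle.

    ``total_energy`` is always packing + lipophilicity + crossing penalty.
    With ``full`` the interface quantities (ddG of association, buried SASA,
    shape complementarity) and the geometric filter quantities are also
    populated; for monomers they are NaN.
    """
    table = table or LipophilicityTable.default()
    if bundle.coords.size == 0:
        raise EnergyEvaluationError("empty bundle")
    for seq in bundle.sequences:
        if not table.covers(seq):
            raise EnergyEvaluationError("lipophilicity table does not cover sequence")
    packing = packing_energy(bundle)
    lipo = lipophilicity_energy(bundle, table)
    crossing = crossing_energy(bundle)
    report = EnergyReport(
        total_energy=packing + lipo + crossing,
        packing_term=packing,
        lipophilicity_term=lipo,
        crossing_penalty_term=crossing,
    )
    if full:
        report.helicality = helicality(bundle)
        report.tm_span_extent = tm_span_extent(bundle)
        if desired_topology is not None:
            report.topology_match_fraction = topology_match_fraction(bundle, desired_topology)
        if bundle.n_chains >= 2:
            report.ddg_binding = ddg_binding(bundle, table)
            report.interface_sasa = interface_sasa(bundle)
            try:
                report.shape_complementarity = shape_complementarity(bundle)
            except EnergyEvaluationError:
                report.shape_complementarity = math.nan
    return report


@dataclass
class FilterResult:
    passed: bool
    violations: list[str] = field(default_factory=list)


def apply_design_filters(report: EnergyReport, thresholds: FilterThresholds) -> FilterResult:
    """Evaluate the per-model stage criteria (strict inequalities).

    Design stage: buried SASA > sasa_min, Sc > sc_min, ddG < ddg_max,
    helicality < helicality_max.  Prediction stage: buried SASA > sasa_min,
    energy < energy_max, TM span > span_min, topology match > topo_min.
    The design-stage energy percentile is ensemble-level; see
    :func:`energy_percentile_mask`.
    """
    checks: list[tuple[str, float, bool]]
    if thresholds.stage == "design":
        checks = [
            ("sasa", report.interface_sasa, report.interface_sasa > thresholds.sasa_min),
            ("sc", report.shape_complementarity, report.shape_complementarity > thresholds.sc_min),
            ("ddg", report.ddg_binding, report.ddg_binding < thresholds.ddg_max),
            ("helicality", report.helicality, report.helicality < thresholds.helicality_max),
        ]
    else:
        checks = [
            ("sasa", report.interface_sasa, report.interface_sasa > thresholds.sasa_min),
            ("energy", report.total_energy, report.total_energy < thresholds.energy_max),
            ("span", report.tm_span_extent, report.tm_span_extent > thresholds.span_min),
            ("topology", report.topology_match_fraction, report.topology_match_fraction > thresholds.topo_min),
        ]
    violations = []
    for name, value, ok in checks:
        if math.isnan(value):
            # Undefined Sc means no interface contact: that certainly fails
            # the complementarity criterion.  Any other missing field is a
            # contract violation by the caller.
            if name == "sc":
                violations.append(name)
                continue
            raise EnergyEvaluationError(
                f"report field {name!r} missing for stage {thresholds.stage}"
            )
        if not ok:
            violations.append(name)
    return FilterResult(passed=not violations, violations=violations)


def energy_percentile_mask(energies: np.ndarray, percentile: float = 1.0) -> np.ndarray:
    """Boolean mask selecting the lowest ``percentile`` % of an ensemble by
    energy (at least one model kept)."""
    energies = np.asarray(energies, dtype=float)
    if energies.size == 0:
        return np.zeros(0, dtype=bool)
    cutoff = np.percentile(energies, percentile)
    mask = energies <= cutoff
    if not mask.any():
        mask[np.argmin(energies)] = True
    return mask
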