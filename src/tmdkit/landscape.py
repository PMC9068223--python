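"""Multi-symmetry energy-landscape funnel analysis and state selection.

A designed TM sequence is modeled in each candidate oligomeric symmetry
(C2, C3, C4) by scoring an ensemble of randomized bundle geometries and
recording, for each decoy, its energy and its RMSD to the design model.
A landscape is *funneled* when the near-native models are distinctly
lower in energy than the alternatives, quantified by

    Z = (mean(E) - E_lowest) / std(E)

where E_lowest is the lowest energy among models within 2 Angstrom of the
reference and E ranges over models beyond 2 Angstrom whose energy lies
within 50 energy units above E_lowest.  (The sign convention is chosen so
that funneled landscapes give positive Z; the cutoff Z > 2.5 flags a
funnel.)  Negative design then selects a sequence only if its target
symmetry is funneled and none of the alternatives are.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geometry import CrickParams, HelixBundle, build_symmetric_bundle, rmsd_between

FUNNEL_Z_CUTOFF = 2.5
RMSD_CUT = 2.0
ENERGY_WINDOW = 50.0

#: Documented sampling ranges for decoy geometries.
SAMPLING_RANGES = {
    "superhelical_radius": (4.0, 10.0),
    "interface_phase": (0.0, 360.0),
    "z_offset": (-3.0, 3.0),
    "tilt": (0.0, 35.0),
}


class LandscapeError(ValueError):
    pass


class FunnelUndefinedError(LandscapeError):
    """Raised when Z cannot be computed (empty near-native set or
    zero-variance comparison set)."""


@dataclass(frozen=True)
class LandscapeSample:
    model_id: str
    symmetry: int
    rmsd: float
    energy: float

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise LandscapeError("rmsd must be >= 0")
        if not np.isfinite(self.energy):
            raise LandscapeError("energy must be finite")


@dataclass(frozen=True)
class LandscapeSummary:
    symmetry: int
    e_lowest: float
    z: float
    n_samples: int
    cutoff: float = FUNNEL_Z_CUTOFF

    @property
    def funneled(self) -> bool:
        return self.z > self.cutoff


@dataclass(frozen=True)
class StateCall:
    target: int
    selected: bool
    reason: str


def sample_landscape(
    sequence: str,
    symmetry: int,
    n_samples: int,
    seed: int,
    scorer,
    reference: HelixBundle,
) -> list[LandscapeSample]:
    """Randomized-geometry decoy ensemble for one symmetry.

    ``scorer(bundle) -> energy``.  The reference model itself is included
    as the first (zero-RMSD) sample; the remaining ``n_samples - 1`` decoys
    draw Crick parameters uniformly from :data:`SAMPLING_RANGES`.
    Deterministic for a fixed seed.
    """
    if symmetry not in (2, 3, 4):
        raise LandscapeError("symmetry must be 2, 3 or 4")
    if n_samples < 10:
        raise LandscapeError("n_samples must be >= 10")
    if len(sequence) != reference.chain_length:
        raise LandscapeError("sequence length must match the reference bundle")
    rng = np.random.default_rng(seed)
    samples = [
        LandscapeSample("ref", symmetry, 0.0, float(scorer(reference)))
    ]
    for i in range(n_samples - 1):
        draws = {k: float(rng.uniform(*v)) for k, v in SAMPLING_RANGES.items()}
        params = CrickParams(
            n_chains=symmetry, chain_length=len(sequence), **draws
        )
        decoy = build_symmetric_bundle(params, sequence)
        rmsd = rmsd_between(decoy, reference, symmetry_aware=True)
        samples.append(
            LandscapeSample(f"decoy_{i:05d}", symmetry, rmsd, float(scorer(decoy)))
        )
    return samples


def funnel_zscore(
    samples: list[LandscapeSample],
    rmsd_cut: float = RMSD_CUT,
    energy_window: float = ENERGY_WINDOW,
) -> float:
    """Funnel Z-score of a decoy ensemble.

    E_lowest = min energy at RMSD < ``rmsd_cut``; the comparison set holds
    energies of models with RMSD > ``rmsd_cut`` and energy at most
    ``energy_window`` above E_lowest; Z = (mean - E_lowest) / std with the
    population std over the comparison set.
    """
    energies = np.array([s.energy for s in samples])
    rmsds = np.array([s.rmsd for s in samples])
    near = energies[rmsds < rmsd_cut]
    if near.size == 0:
        raise FunnelUndefinedError("no sample within the near-native RMSD cut")
    e_lowest = float(near.min())
    comparison = energies[(rmsds > rmsd_cut) & (energies <= e_lowest + energy_window)]
    if comparison.size < 2:
        raise FunnelUndefinedError("comparison set has fewer than 2 samples")
    std = float(comparison.std(ddof=0))
    if std == 0.0:
        raise FunnelUndefinedError("comparison set has zero energy variance")
    return float((comparison.mean() - e_lowest) / std)


def summarize_landscape(
    samples: list[LandscapeSample], cutoff: float = FUNNEL_Z_CUTOFF
) -> LandscapeSummary:
    energies = np.array([s.energy for s in samples])
    rmsds = np.array([s.rmsd for s in samples])
    near = energies[rmsds < RMSD_CUT]
    e_lowest = float(near.min()) if near.size else float("nan")
    z = funnel_zscore(samples)
    return LandscapeSummary(
        symmetry=samples[0].symmetry,
        e_lowest=e_lowest,
        z=z,
        n_samples=len(samples),
        cutoff=cutoff,
    )


def select_oligomeric_state(
    summaries: dict[int, LandscapeSummary], target: int
) -> StateCall:
    """Negative-design rule: accept a sequence only if its target symmetry
    is funneled and no alternative symmetry is."""
    for sym in (2, 3, 4):
        if sym not in summaries:
            raise LandscapeError(f"missing summary for C{sym}")
    if target not in summaries:
        raise LandscapeError(f"no summary for target C{target}")
    if not summaries[target].funneled:
        return StateCall(target, False, "target not funneled")
    funneled_alts = [s for s in summaries if s != target and summaries[s].funneled]
    if funneled_alts:
        alts = ", ".join(f"C{s}" for s in sorted(funneled_alts))
        return StateCall(target, False, f"alternative {alts} funneled")
    return StateCall(target, True, "target funneled, alternatives flat")


# ---------------------------------------------------------------------------
# Delimited-text decoy sets (compatible with external score tables)


def samples_to_frame(samples: list[LandscapeSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model_id": [s.model_id for s in samples],
            "symmetry": [s.symmetry for s in samples],
            "rmsd": [s.rmsd for s in samples],
            "energy": [s.energy for s in samples],
        }
    )


def write_decoy_table(samples: list[LandscapeSample], path) -> None:
    samples_to_frame(samples).to_csv(path, sep="\t", index=False)


def read_decoy_table(path) -> list[LandscapeSample]:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    required = {"model_id", "symmetry", "rmsd", "energy"}
    if not required <= set(df.columns):
        raise LandscapeError(f"decoy table must have columns {sorted(required)}")
    return [
        LandscapeSample(str(r.model_id), int(r.symmetry), float(r.rmsd), float(r.energy))
        for r in df.itertuples()
    ]


def shuffled_energies(samples: list[LandscapeSample], seed: int) -> list[LandscapeSample]:
    """Same RMSDs, energies permuted across samples (null landscape)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(samples))
    return [
        replace(s, energy=samples[j].energy) for s, j in zip(samples, perm)
    ]
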