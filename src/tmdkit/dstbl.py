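"""Deep-mutational-scanning counts to apparent free energies.

The dsTbL selection reads out two phenotypes for a library of TM single
point mutants: membrane insertion (survival on ampicillin, the reference
population) and self-association (survival on ampicillin plus
chloramphenicol, the selected population).  Deep-sequencing read counts
from the two populations convert to energies in three steps:

1. propensity       p_ij = count_ij / count_wt          (per population)
2. selection coef.  s_ij = p_selected / p_reference
3. free energy      ddG_measured = -RT ln(s_ij / s_wt)  (T = 310 K)

A pseudo-count of 1 replaces a zero wild-type count.  Because survival on
chloramphenicol reflects both insertion and association (insertion counted
twice for a homodimer), the apparent association energy subtracts twice
the depth-dependent insertion contribution:

    ddG_assoc = ddG_measured - 2 * ddG_insertion

Counts are carried as tidy tables (one row per position/mutation) with
columns ``position, wt_aa, mut_aa, count_selected, count_reference``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GAS_CONSTANT_KCAL = 1.9872e-3  # kcal / (mol K)
DETRIMENTAL_THRESHOLD = 2.5    # energy units, strict inequality

COUNT_COLUMNS = ["position", "wt_aa", "mut_aa", "count_selected", "count_reference"]


class DstblError(ValueError):
    pass


@dataclass(frozen=True)
class PhysicalConstants:
    gas_constant: float = GAS_CONSTANT_KCAL
    temperature: float = 310.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise DstblError("temperature must be positive")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature


class InsertionProfile:
    """Per-amino-acid, per-position apparent insertion free energies.

    The default (flat-zero) profile makes the insertion correction an
    identity, so the pipeline runs without external insertion data.
    A measured profile is supplied as delimited text with columns
    ``aa, position, energy``.
    """

    def __init__(self, table: pd.DataFrame | None = None):
        if table is None:
            self._lookup = None
        else:
            missing = {"aa", "position", "energy"} - set(table.columns)
            if missing:
                raise DstblError(f"insertion profile missing columns {sorted(missing)}")
            if not np.isfinite(table["energy"]).all():
                raise DstblError("insertion energies must be finite")
            self._lookup = {
                (r.aa, int(r.position)): float(r.energy) for r in table.itertuples()
            }

    @classmethod
    def flat_zero(cls) -> "InsertionProfile":
        return cls(None)

    @classmethod
    def from_file(cls, path) -> "InsertionProfile":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def energy(self, aa: str, position: int) -> float:
        if self._lookup is None:
            return 0.0
        try:
            return self._lookup[(aa, int(position))]
        except KeyError:
            raise DstblError(f"insertion profile has no entry for {aa}@{position}") from None

    def ddg_insertion(self, wt_aa: str, mut_aa: str, position: int) -> float:
        return self.energy(mut_aa, position) - self.energy(wt_aa, position)


def validate_count_table(counts: pd.DataFrame) -> pd.DataFrame:
    missing = set(COUNT_COLUMNS) - set(counts.columns)
    if missing:
        raise DstblError(f"count table missing columns {sorted(missing)}")
    for col in ("count_selected", "count_reference"):
        vals = counts[col]
        if (vals < 0).any() or not np.equal(np.mod(vals, 1), 0).all():
            raise DstblError(f"{col} must hold non-negative integers")
    # every position needs a defined wild-type identity (the wt row itself)
    for pos, grp in counts.groupby("position"):
        if grp["wt_aa"].nunique() != 1:
            raise DstblError(f"conflicting wt_aa at position {pos}")
        wt = grp["wt_aa"].iloc[0]
        if wt not in set(grp["mut_aa"]):
            raise DstblError(f"no wild-type row at position {pos}")
    return counts


def read_count_table(path) -> pd.DataFrame:
    return validate_count_table(pd.read_csv(path, sep="\t", comment="#"))


def write_count_table(counts: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        counts.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Elementary steps


def mutant_propensity(count_ij: int, count_wt: int) -> float:
    """Read-count ratio of a variant to wild type; a zero wild-type count
    is replaced by the pseudo-count 1."""
    if count_ij < 0 or count_wt < 0:
        raise DstblError("counts must be non-negative")
    return count_ij / max(count_wt, 1)


def selection_coefficient(p_selected: float, p_reference: float) -> float:
    if p_reference <= 0:
        raise DstblError("reference propensity must be positive")
    return p_selected / p_reference


def ddg_measured(s_ij: float, s_wt: float, constants: PhysicalConstants | None = None) -> float:
    """Gibbs conversion of relative selection coefficients to kcal/mol."""
    constants = constants or PhysicalConstants()
    if s_ij <= 0 or s_wt <= 0:
        raise DstblError("selection coefficients must be positive")
    return -constants.rt * np.log(s_ij / s_wt)


def ddg_association(ddg_meas: float, ddg_insertion: float) -> float:
    """Subtract the doubled (homodimer) insertion contribution."""
    if not (np.isfinite(ddg_meas) and np.isfinite(ddg_insertion)):
        raise DstblError("inputs must be finite")
    return ddg_meas - 2.0 * ddg_insertion


def classify_mutation(delta_total_energy: float, threshold: float = DETRIMENTAL_THRESHOLD) -> str:
    """'detrimental' iff the energy change strictly exceeds the threshold."""
    if not np.isfinite(delta_total_energy):
        raise DstblError("energy change must be finite")
    return "detrimental" if delta_total_energy > threshold else "neutral_beneficial"


# ---------------------------------------------------------------------------
# Full pipeline


def compute_ddg_table(
    counts: pd.DataFrame,
    constants: PhysicalConstants | None = None,
    insertion: InsertionProfile | None = None,
    pseudo_count_mode: str = "floor",
) -> pd.DataFrame:
    """Counts -> propensities -> selection coefficients -> energies.

    ``pseudo_count_mode``: 'floor' also raises zero *mutant* counts to 1 so
    the log is defined everywhere (the wild-type pseudo-count rule is always
    applied); 'strict' leaves such cells as NaN and flags them missing.

    Output columns: the input keys plus ``p_sel, p_ref, s, ddg_measured,
    ddg_assoc, classification`` (classification on ddg_assoc, default
    threshold 2.5, strict).
    """
    if pseudo_count_mode not in ("floor", "strict"):
        raise DstblError("pseudo_count_mode must be 'floor' or 'strict'")
    constants = constants or PhysicalConstants()
    insertion = insertion or InsertionProfile.flat_zero()
    counts = validate_count_table(counts)

    rows = []
    for pos, grp in counts.groupby("position", sort=True):
        wt = grp["wt_aa"].iloc[0]
        wt_row = grp[grp["mut_aa"] == wt].iloc[0]
        wt_sel = int(wt_row["count_selected"])
        wt_ref = int(wt_row["count_reference"])
        # s_wt = 1 identically (propensity of wt relative to itself).
        s_wt = 1.0
        for r in grp.itertuples():
            c_sel, c_ref = int(r.count_selected), int(r.count_reference)
            missing = False
            if pseudo_count_mode == "floor":
                c_sel, c_ref = max(c_sel, 1), max(c_ref, 1)
            elif c_sel == 0 or c_ref == 0:
                missing = True
            if missing:
                p_sel = p_ref = s = dmeas = dassoc = np.nan
                label = "missing"
            else:
                p_sel = mutant_propensity(c_sel, wt_sel)
                p_ref = mutant_propensity(c_ref, wt_ref)
                s = selection_coefficient(p_sel, p_ref)
                dmeas = 0.0 if r.mut_aa == wt else ddg_measured(s, s_wt, constants)
                dassoc = ddg_association(
                    dmeas, insertion.ddg_insertion(wt, r.mut_aa, pos)
                )
                label = classify_mutation(dassoc)
            rows.append(
                {
                    "position": pos,
                    "wt_aa": wt,
                    "mut_aa": r.mut_aa,
                    "p_sel": p_sel,
                    "p_ref": p_ref,
                    "s": s,
                    "ddg_measured": dmeas,
                    "ddg_assoc": dassoc,
                    "classification": label,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SensitivitySummary:
    per_position: pd.DataFrame
    per_class: pd.DataFrame
    mannwhitney_u: float
    mannwhitney_p: float


def position_sensitivity(ddg: pd.DataFrame, labels: dict[int, str]) -> SensitivitySummary:
    """Per-position mutational sensitivity grouped by interface class.

    Positions buried at an oligomer interface are expected to be more
    sensitive to mutation than lipid-exposed ones.  Aggregates ddg_assoc
    over the mutations at each position (wild-type identity rows excluded),
    then compares the per-position means of the two classes with a
    Mann-Whitney U test.
    """
    positions = set(ddg["position"])
    if not positions <= set(labels):
        missing = sorted(positions - set(labels))
        raise DstblError(f"labels missing for positions {missing}")
    muts = ddg[ddg["mut_aa"] != ddg["wt_aa"]].dropna(subset=["ddg_assoc"])
    per_pos = (
        muts.groupby("position")["ddg_assoc"]
        .agg(["mean", "median", "std", "count"])
        .reset_index()
    )
    per_pos["label"] = per_pos["position"].map(labels)
    per_class = (
        per_pos.groupby("label")["mean"].agg(["mean", "median", "std", "count"])
    )
    iface = per_pos.loc[per_pos["label"] == "interface", "mean"]
    exposed = per_pos.loc[per_pos["label"] == "exposed", "mean"]
    if len(iface) and len(exposed) and (iface.nunique() > 1 or exposed.nunique() > 1):
        u, p = stats.mannwhitneyu(iface, exposed, alternative="two-sided")
    else:
        u, p = np.nan, np.nan
    return SensitivitySummary(per_pos, per_class, float(u), float(p))
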