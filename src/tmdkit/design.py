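"""Fuzzy-logic Monte Carlo sequence diversification.

De novo membrane-protein sequence optimization tends to converge on
Leu-dominated sequences.  This module implements the countermeasure: a
short simulated-annealing trajectory (120 steps by default) over single
point mutations restricted to the hydrophobic alphabet, scored by a
fuzzy-logic conjunction of three criteria — association energy, system
energy, and the root-mean-square deviation of the sequence's amino-acid
composition from a natural single-span TM composition.

Each raw criterion x is squashed by a sigmoid f(x) = 1/(1 + e^((x-o)s))
(so smaller is better for positive slopes) and the three transformed
criteria are combined conjunctively (product by default).  The energy
criteria are measured relative to the starting model, so the offsets
o = 3 (association) and o = 20 (system energy) describe allowed
degradation rather than absolute energies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable

import numpy as np
import pandas as pd

from .geometry import HelixBundle

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Hydrophobic mutation alphabet for TMD diversification.
DEFAULT_ALPHABET = "GAVILMFYW"

#: Sigmoid parameters (offset o, slope s) for the three criteria.
DDG_SIGMOID_DEFAULT = (3.0, 1.0)        # association energy, relative
ENERGY_SIGMOID_DEFAULT = (20.0, 0.5)    # system energy, relative
COMPOSITION_SIGMOID_DEFAULT = (0.05, 50.0)


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class SigmoidSpec:
    """Offset and slope of one criterion's squashing sigmoid."""

    offset: float
    slope: float

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise DesignError("sigmoid slope must be nonzero")


class CompositionProfile:
    """Frequencies over the 20 standard amino acids (non-negative, sum 1)."""

    def __init__(self, frequencies: dict[str, float]):
        freqs = {aa: float(frequencies.get(aa, 0.0)) for aa in STANDARD_AA}
        if any(v < 0 for v in freqs.values()):
            raise DesignError("frequencies must be non-negative")
        total = sum(freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise DesignError(f"frequencies must sum to 1 (got {total})")
        self._freqs = freqs

    def __getitem__(self, aa: str) -> float:
        return self._freqs[aa]

    def as_dict(self) -> dict[str, float]:
        return dict(self._freqs)

    @classmethod
    def uniform(cls, alphabet: str) -> "CompositionProfile":
        return cls({aa: 1.0 / len(alphabet) for aa in alphabet})

    @classmethod
    def from_file(cls, path) -> "CompositionProfile":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(dict(zip(df["aa"], df["frequency"])))

    @classmethod
    def natural_tm(cls) -> "CompositionProfile":
        """Packaged natural single-span TM helix composition."""
        ref = resources.files("tmdkit.data") / "natural_tm_composition.tsv"
        with resources.as_file(ref) as path:
            return cls.from_file(path)


def composition_report(seq: str) -> CompositionProfile:
    """Empirical amino-acid frequencies of a sequence."""
    if not seq:
        raise DesignError("empty sequence")
    if any(aa not in STANDARD_AA for aa in seq):
        raise DesignError("nonstandard residue in sequence")
    counts = {aa: seq.count(aa) / len(seq) for aa in STANDARD_AA}
    return CompositionProfile(counts)


def sequence_composition_rmsd(
    seq: str, natural: CompositionProfile, sqrt: bool = True
) -> float:
    """Deviation of a sequence's composition from a natural TM profile:

        sqrt( sum_aa (f_design(aa) - f_natural(aa))^2 / L )

    with L the sequence length.  ``sqrt=False`` returns the un-rooted sum
    (an alternative reading of the same statistic).
    """
    design = composition_report(seq)
    ss = sum((design[aa] - natural[aa]) ** 2 for aa in STANDARD_AA) / len(seq)
    return math.sqrt(ss) if sqrt else ss


def sigmoid_transform(x: float, spec: SigmoidSpec) -> float:
    """f(x) = 1 / (1 + e^((x - o) * s)); maps o to 0.5, strictly monotone."""
    if not math.isfinite(x):
        raise DesignError("criterion value must be finite")
    arg = (x - spec.offset) * spec.slope
    if arg > 700.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(arg))


def fuzzy_objective(f1: float, f2: float, f3: float, operator: str = "product") -> float:
    """Conjunction of three sigmoid-transformed criteria.

    ``product`` (default, smooth t-norm) or ``minimum``.
    """
    for f in (f1, f2, f3):
        if not 0.0 <= f <= 1.0:
            raise DesignError("sigmoid values must lie in [0, 1]")
    if operator == "product":
        return f1 * f2 * f3
    if operator == "minimum":
        return min(f1, f2, f3)
    raise DesignError(f"unknown conjunction operator {operator!r}")


@dataclass(frozen=True)
class MCSchedule:
    """Simulated-annealing schedule for the diversification trajectory.

    Geometric cooling from ``t_initial`` to ``t_final`` (objective units)
    over ``n_steps`` proposals.
    """

    n_steps: int = 120
    t_initial: float = 0.2
    t_final: float = 0.01
    cooling: str = "geometric"
    seed: int = 0
    alphabet: str = DEFAULT_ALPHABET

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise DesignError("n_steps must be >= 1")
        if self.t_initial <= 0 or self.t_final <= 0:
            raise DesignError("temperatures must be positive")
        if not set(self.alphabet) <= set(STANDARD_AA):
            raise DesignError("alphabet must be standard amino acids")
        if self.cooling not in ("geometric", "linear"):
            raise DesignError("cooling must be 'geometric' or 'linear'")

    def temperature(self, step: int) -> float:
        if self.n_steps == 1:
            return self.t_initial
        frac = step / (self.n_steps - 1)
        if self.cooling == "geometric":
            return self.t_initial * (self.t_final / self.t_initial) ** frac
        return self.t_initial + (self.t_final - self.t_initial) * frac


@dataclass
class Criterion:
    """One raw criterion: a name, an evaluator over sequences, a sigmoid."""

    name: str
    evaluate: Callable[[str], float]
    sigmoid: SigmoidSpec


@dataclass
class DesignObjectiveSpec:
    """Exactly three criteria combined conjunctively."""

    criteria: list[Criterion]
    operator: str = "product"

    def __post_init__(self) -> None:
        if len(self.criteria) != 3:
            raise DesignError("the objective takes exactly three criteria")
        if self.operator not in ("product", "minimum"):
            raise DesignError("operator must be 'product' or 'minimum'")

    def evaluate(self, seq: str) -> tuple[float, list[float], list[float]]:
        raw = [c.evaluate(seq) for c in self.criteria]
        sig = [sigmoid_transform(x, c.sigmoid) for x, c in zip(raw, self.criteria)]
        return fuzzy_objective(*sig, operator=self.operator), raw, sig


def default_objective(
    bundle: HelixBundle,
    scorer: Callable[[HelixBundle], tuple[float, float]],
    natural: CompositionProfile | None = None,
) -> DesignObjectiveSpec:
    """The standard three-criterion objective for a fixed backbone.

    ``scorer(bundle) -> (ddg_binding, system_energy)``.  Energy criteria
    are offsets from the starting model's values, per the relative-offset
    convention of the sigmoid parameters.
    """
    natural = natural or CompositionProfile.natural_tm()
    ddg0, energy0 = scorer(bundle)

    def ddg_rel(seq: str) -> float:
        return scorer(bundle.with_sequence(seq))[0] - ddg0

    def energy_rel(seq: str) -> float:
        return scorer(bundle.with_sequence(seq))[1] - energy0

    return DesignObjectiveSpec(
        [
            Criterion("ddg_binding", ddg_rel, SigmoidSpec(*DDG_SIGMOID_DEFAULT)),
            Criterion("system_energy", energy_rel, SigmoidSpec(*ENERGY_SIGMOID_DEFAULT)),
            Criterion(
                "composition_rmsd",
                lambda seq: sequence_composition_rmsd(seq, natural),
                SigmoidSpec(*COMPOSITION_SIGMOID_DEFAULT),
            ),
        ]
    )


def propose_mutation(
    seq: str, rng: np.random.Generator, alphabet: str = DEFAULT_ALPHABET
) -> tuple[str, int, str, str]:
    """Single random point mutation drawn from the allowed alphabet.

    The new residue always differs from the current one.
    """
    if not seq:
        raise DesignError("empty sequence")
    pos = int(rng.integers(len(seq)))
    current = seq[pos]
    choices = [aa for aa in alphabet if aa != current]
    if not choices:
        raise DesignError("alphabet offers no alternative residue")
    new = choices[int(rng.integers(len(choices)))]
    return seq[:pos] + new + seq[pos + 1 :], pos, current, new


@dataclass
class TraceStep:
    step: int
    position: int
    from_aa: str
    to_aa: str
    raw: list[float]
    sigmoid: list[float]
    objective: float
    accepted: bool
    temperature: float


@dataclass
class DesignTrace:
    """Per-step audit trail of a diversification trajectory."""

    steps: list[TraceStep] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.steps)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            row = {
                "step": s.step,
                "position": s.position,
                "from_aa": s.from_aa,
                "to_aa": s.to_aa,
                "objective": s.objective,
                "accepted": s.accepted,
                "temperature": s.temperature,
            }
            for i, (r, f) in enumerate(zip(s.raw, s.sigmoid), start=1):
                row[f"raw_{i}"] = r
                row[f"sigmoid_{i}"] = f
            rows.append(row)
        return pd.DataFrame(rows)


def diversify_sequence(
    bundle: HelixBundle,
    objective: DesignObjectiveSpec,
    schedule: MCSchedule,
) -> tuple[str, DesignTrace]:
    """Metropolis simulated annealing over single point mutations.

    The objective is maximized: a proposal is accepted if it does not lower
    the objective, otherwise with probability exp(delta / T).  All chains
    share one sequence (symmetric design), so the final sequence applies to
    every chain.  Fully deterministic for a fixed schedule seed.
    """
    rng = np.random.default_rng(schedule.seed)
    current = bundle.sequences[0]
    current_obj, _, _ = objective.evaluate(current)
    trace = DesignTrace()
    for step in range(schedule.n_steps):
        temp = schedule.temperature(step)
        proposal, pos, old, new = propose_mutation(current, rng, schedule.alphabet)
        obj, raw, sig = objective.evaluate(proposal)
        delta = obj - current_obj
        accepted = delta >= 0 or rng.random() < math.exp(delta / temp)
        if accepted:
            current, current_obj = proposal, obj
        trace.steps.append(
            TraceStep(step, pos, old, new, raw, sig, obj, accepted, temp)
        )
    return current, trace
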