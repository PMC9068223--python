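"""Packaged design sequences and ground-truth-bearing synthetic inputs.

Three kinds of test-without-downloads inputs live here:

* the DNA sequences of the 16 designed TMDs (twelve first-round designs
  plus the symmetric C1/C2.1/C3.1/C4.1 series) and the three assay
  controls (CLS, ErbB2, QSOX2), stored verbatim as printed;
* an inverse sampler that turns a known per-mutation ddG table into
  selected/reference deep-sequencing count tables under multinomial read
  sampling, so the counts-to-energy pipeline can be validated by
  parameter recovery;
* a synthetic decoy-landscape generator with and without an energy
  funnel, for validating the funnel Z-score.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .dstbl import COUNT_COLUMNS, PhysicalConstants, validate_count_table
from .landscape import LandscapeSample


class FixtureError(ValueError):
    pass


# DNA stored verbatim as printed (including the four headers whose labels
# appear as ">roMP"; names are normalized, raw labels kept in metadata).
_RAW_DESIGN_FASTA = """\
>proMP 1.1
CCTTTATCTTTCCTCTTAGGGATACTAGCTGCGCTGGTGGGGTTCATCATTGGCTTTTTAGCGGCCTTGATT
>proMP 1.2 (trimer; used in proCAR-3)
CCTTTGTTATTTATTCTCGTCGCAATACTTGGAGGCTTATTTGGGGCGATTGTTGCATTCCTTTTGGCGTTA
>roMP 1.3
CCGATCCTGTTCGCAATACTGGCGGCTTTCATCGGGGCATTTATAGCTGCCCTGTTCGTGCTAGTATTGGCA
>proMP 1.4
CCCTTTGGAGCTTTACTAGCAATCATAGCATTCGTCGTAGGAATGTTATTCTCAGCATTCGTTTTACTCATC
>proMP 1.5
CCCTTTAGCTTGTTTTTGGGCGTTATAGCCGGCATTATTGCTGCATTCATCGTTTTATTCCTGGCATTACTA
>proMP 1.6
CCTTTTTTATCGCTTGTTGGTGCGCTAATCGGGGCTTTCATAGCATTTATCTTGGCTTTGTTCATTTTGGTT
>proMP 1.7
CCGATTCTGATCACTTTGGCAATGCTTACGGGAGCAGTGATTGGGGCGATCTCGTCTTTTCTCCTAGTGTAT
>roMP 1.8
CCAGCCTTTTATATTATATTGGCAATTCTCACCTCGTTCATAGCCTATTTGGTGGGTCTACTCGTGTCTTTT
>proMP 1.9
CCTATTTACGTTATACTAGCCATCTTGGCCGCGGTATTCACTTGGTTCATAGTCCTTATAACTAGCCTGAGT
>roMP 1.10
CCTACGGTTACGAGTGCGATTCTTGGCGTGTCATTCGGTACCTTTATTAGCCTCGTAGCTCTGTGGCTTGCA
>proMP 1.11
CCAGTGATTGCAATCTTAACTTTTATAGTCCTCACTGCGATTTCGGGAGCGCTGCTCGCTGTTTGGTTCTCC
>roMP 1.12
CCCATCGTCTTGCTCCTCAGTCTACTCGCCAGTGTATTTGGGGCGTTCATCACATTTATTTGGGCTTACTTG
>proMP C1 (monomer; used in proCAR-1)
CTGGTGCTGATTCTGCTGACCTTTGTGCTGTTTGTGTTTATTCTGTATTGGGTGATTACCTGGTATCTGATT
>proMP C2.1 (dimer; used in proCAR-2)
CCGCTGACCGTGGCGCTGATTCTGGGCATCTTCCTGGGCACCTTTATTGCGTTTTGGGTGGTGTATCTGCTG
>proMP C3.1
ACCGCGCTGCTGGTGGCGTTTGTGGCGTATTATACCGCGCTGATTGCGCTGATTTTTGCGATTCTGGCGACC
>proMP C4.1 (tetramer; used in proCAR-4)
CCCCTTTTAGTCGCCTTATTGGCGCTGCTTGCTGTAATCGCCGCATTATTAGCAGCTATCTTTGCATTGCTG
>CLS
CCGCTGTTCATCCCGGTTGCAGTTATGGTTACCGCTTTTAGTGGATTGGGGTTTATCATCTGGCTGGCTAC
>ErbB2
TCTATCATCTCTGCGGTGGTTGGCATTCTGCTGGTCGTGGTCTTGGGCGTGGTCTTTGGCATCCTGAT
>QSOX2
AGCCTATGCGTTGTTTTATACGTGGCATCTAGTTTATTTATGGTCATGTACTTCTTC
"""

_RAW_SHA256 = "89755422be594c81045aa81741fad6a8283f26fd08364d84f52c26caa357b219"

_STATE_FROM_ANNOTATION = {"monomer": 1, "dimer": 2, "trimer": 3, "tetramer": 4}
# The C-series names carry the intended symmetry even where the printed
# header has no parenthetical annotation (C3.1).
_STATE_FROM_NAME = {"proMP C1": 1, "proMP C2.1": 2, "proMP C3.1": 3, "proMP C4.1": 4}


@dataclass(frozen=True)
class DesignFixture:
    name: str
    raw_label: str
    dna: str
    peptide: str
    role: str                      # round1 | round2_symmetric | control
    intended_state: int | None = None
    annotation: str = ""


def translate_design(dna: str) -> str:
    """Standard-genetic-code translation of a design coding sequence."""
    dna = dna.strip().upper()
    if set(dna) - set("ACGT"):
        raise FixtureError("DNA must contain only A, C, G, T")
    if len(dna) % 3 != 0:
        raise FixtureError("DNA length must be divisible by 3")
    peptide = str(Seq(dna).translate())
    if "*" in peptide:
        raise FixtureError("internal stop codon")
    return peptide


def _checksum(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def load_design_fixtures() -> list[DesignFixture]:
    """The 16 design entries plus 3 controls, parsed from the packaged DNA.

    Control DNA is reproduced exactly as printed; two controls end in a
    partial codon, which is dropped for translation.
    """
    if _checksum(_RAW_DESIGN_FASTA) != _RAW_SHA256:
        raise FixtureError("packaged fixture data corrupted (checksum mismatch)")
    fixtures = []
    blocks = _RAW_DESIGN_FASTA.strip().split(">")
    for block in blocks:
        if not block.strip():
            continue
        header, dna = block.strip().split("\n", 1)
        dna = dna.replace("\n", "").strip()
        raw_label = header.strip()
        annotation = ""
        name = raw_label
        if "(" in raw_label:
            name, annotation = raw_label.split("(", 1)
            name = name.strip()
            annotation = annotation.rstrip(")").strip()
        if name.startswith("roMP"):
            name = "p" + name
        if name.startswith("proMP 1."):
            role = "round1"
        elif name.startswith("proMP C"):
            role = "round2_symmetric"
        else:
            role = "control"
        state = _STATE_FROM_NAME.get(name)
        for word, order in _STATE_FROM_ANNOTATION.items():
            if word in annotation:
                state = order
        if role == "control":
            peptide = translate_design(dna[: len(dna) - len(dna) % 3])
        else:
            peptide = translate_design(dna)
            if len(peptide) != 24:
                raise FixtureError(f"{name}: design peptide must be 24 residues")
        fixtures.append(
            DesignFixture(name, raw_label, dna, peptide, role, state, annotation)
        )
    if len(fixtures) != 19:
        raise FixtureError("expected 19 packaged sequences")
    return fixtures


def fixtures_as_fasta(peptide: bool = True) -> str:
    records = io.StringIO()
    for fx in load_design_fixtures():
        records.write(f">{fx.name.replace(' ', '_')}\n")
        records.write((fx.peptide if peptide else fx.dna) + "\n")
    return records.getvalue()


# ---------------------------------------------------------------------------
# Synthetic dsTbL count tables (inverse of the counts-to-energy pipeline)


@dataclass(frozen=True)
class SyntheticDsTblSpec:
    """Ground truth for a synthetic deep-mutational-scanning experiment.

    ``true_ddg`` maps (1-based position, mutant amino acid) to the true
    association free energy in kcal/mol; wild-type identities are 0 by
    construction.  ``depth`` is the expected read depth per position in
    each population.
    """

    wt_sequence: str
    true_ddg: dict[tuple[int, str], float]
    depth: int = 1_000_000
    temperature: float = 310.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise FixtureError("depth must be >= 1")
        if not all(np.isfinite(v) for v in self.true_ddg.values()):
            raise FixtureError("true ddG values must be finite")
        for pos, aa in self.true_ddg:
            if not 1 <= pos <= len(self.wt_sequence):
                raise FixtureError(f"position {pos} outside wild-type sequence")
            if aa == self.wt_sequence[pos - 1]:
                raise FixtureError("true_ddg keys must be non-wild-type mutations")


def generate_dstbl_counts(spec: SyntheticDsTblSpec) -> pd.DataFrame:
    """Sample selected/reference count tables whose expectation inverts the
    counts-to-energy pipeline exactly.

    Per position, variant fractions in the reference population are uniform
    over wild type plus the specified mutants; the selected population
    re-weights each variant by its enrichment s = exp(-ddG / RT) relative
    to wild type.  Both populations draw multinomially at the specified
    depth.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    rt = PhysicalConstants(temperature=spec.temperature).rt
    rows = []
    positions = sorted({pos for pos, _ in spec.true_ddg})
    for pos in positions:
        wt = spec.wt_sequence[pos - 1]
        muts = sorted(aa for p, aa in spec.true_ddg if p == pos)
        variants = [wt] + muts
        k = len(variants)
        ref_frac = np.full(k, 1.0 / k)
        enrich = np.array(
            [1.0] + [float(np.exp(-spec.true_ddg[(pos, aa)] / rt)) for aa in muts]
        )
        sel_frac = ref_frac * enrich
        sel_frac /= sel_frac.sum()
        ref_counts = rng.multinomial(spec.depth, ref_frac)
        sel_counts = rng.multinomial(spec.depth, sel_frac)
        for aa, c_sel, c_ref in zip(variants, sel_counts, ref_counts):
            rows.append(
                {
                    "position": pos,
                    "wt_aa": wt,
                    "mut_aa": aa,
                    "count_selected": int(c_sel),
                    "count_reference": int(c_ref),
                }
            )
    return validate_count_table(pd.DataFrame(rows, columns=COUNT_COLUMNS))


# ---------------------------------------------------------------------------
# Synthetic decoy landscapes


@dataclass(frozen=True)
class SyntheticLandscapeParams:
    """Construction constants for synthetic (RMSD, energy) ensembles.

    Funneled: energy = base + slope * min(rmsd, plateau) + U(-noise, noise),
    so near-native decoys are distinctly lowest.  Flat: energies drawn
    U(base, base + slope * plateau) independently of RMSD.
    """

    base_energy: float = -60.0
    slope: float = 10.0
    plateau_rmsd: float = 4.0
    noise: float = 3.0
    rmsd_max: float = 10.0
    symmetry: int = 2


def generate_synthetic_landscape(
    funneled: bool,
    n_samples: int = 200,
    seed: int = 0,
    params: SyntheticLandscapeParams | None = None,
) -> list[LandscapeSample]:
    """Decoy ensemble with (or without) an energy funnel; deterministic per
    seed."""
    if n_samples < 50:
        raise FixtureError("n_samples must be >= 50")
    p = params or SyntheticLandscapeParams()
    rng = np.random.default_rng(seed)
    rmsds = rng.uniform(0.0, p.rmsd_max, size=n_samples)
    if funneled:
        energies = (
            p.base_energy
            + p.slope * np.minimum(rmsds, p.plateau_rmsd)
            + rng.uniform(-p.noise, p.noise, size=n_samples)
        )
    else:
        energies = p.base_energy + rng.uniform(
            0.0, p.slope * p.plateau_rmsd, size=n_samples
        )
    return [
        LandscapeSample(f"syn_{i:05d}", p.symmetry, float(r), float(e))
        for i, (r, e) in enumerate(zip(rmsds, energies))
    ]
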