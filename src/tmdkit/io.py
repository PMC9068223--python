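"""File formats, run configuration and the design-campaign orchestrator.

FASTA goes through Biopython, PDB through biotite atom arrays; everything
tabular is plain delimited text via pandas.  Every report file written by
the campaign runner carries a header with the tool version, the config
hash and the seed, so a run can be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_3to1
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from . import __version__
from .design import MCSchedule, default_objective, diversify_sequence
from .energy import (
    FilterThresholds,
    LipophilicityTable,
    apply_design_filters,
    ddg_binding,
    energy_percentile_mask,
    score_bundle,
    system_energy,
)
from .geometry import CrickParams, HelixBundle, MembraneFrame, build_symmetric_bundle
from .landscape import (
    sample_landscape,
    select_oligomeric_state,
    summarize_landscape,
    samples_to_frame,
)

logger = logging.getLogger("tmdkit")


class IOError_(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Name -> uppercase sequence; warns on empty files, normalizes case."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            logger.info("sequence %s normalized to uppercase", rec.id)
        records[rec.id] = seq.upper()
    if not records:
        logger.warning("no FASTA records in %s", path)
    return records


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# PDB (C-alpha bundles, membrane frame: z = membrane normal, midplane z = 0)

_CHAIN_IDS = "ABCD"


def write_pdb(bundle: HelixBundle, path) -> None:
    n_atoms = bundle.n_chains * bundle.chain_length
    atoms = struc.AtomArray(n_atoms)
    i = 0
    for c, (seq, chain) in enumerate(zip(bundle.sequences, bundle.coords)):
        for r, (aa, xyz) in enumerate(zip(seq, chain), start=1):
            atoms.coord[i] = xyz
            atoms.chain_id[i] = _CHAIN_IDS[c]
            atoms.res_id[i] = r
            atoms.res_name[i] = protein_letters_1to3[aa].upper()
            atoms.atom_name[i] = "CA"
            atoms.element[i] = "C"
            i += 1
    atoms.set_annotation("occupancy", np.ones(n_atoms))
    atoms.set_annotation("b_factor", np.zeros(n_atoms))
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def read_pdb(path, frame: MembraneFrame | None = None) -> HelixBundle:
    """Read a C-alpha (or full-backbone) PDB into a bundle.

    HETATM records are ignored; of a multi-model file only the first model
    is read (with a warning).
    """
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models > 1:
        logger.warning("multi-model PDB: reading model 1 of %d", n_models)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        atoms = pdb.get_structure(model=1)
    atoms = atoms[~atoms.hetero]
    atoms = atoms[atoms.atom_name == "CA"]
    if atoms.array_length() == 0:
        raise IOError_("no protein atoms (CA) in file")
    chains: dict[str, list] = {}
    seqs: dict[str, list] = {}
    for i in range(atoms.array_length()):
        cid = atoms.chain_id[i]
        chains.setdefault(cid, []).append(atoms.coord[i])
        try:
            one = protein_letters_3to1[atoms.res_name[i].capitalize()]
        except KeyError:
            raise IOError_(f"unknown residue {atoms.res_name[i]}") from None
        seqs.setdefault(cid, []).append(one)
    lengths = {len(v) for v in chains.values()}
    if len(lengths) != 1:
        raise IOError_("inconsistent chain lengths")
    coords = np.stack([np.array(chains[c]) for c in sorted(chains)])
    sequences = ["".join(seqs[c]) for c in sorted(chains)]
    return HelixBundle(coords, sequences, coords.shape[0], frame or MembraneFrame())


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Campaign configuration (paper-default thresholds pre-filled)."""

    target_symmetry: int = 2
    chain_length: int = 24
    start_sequence: str = "L" * 24
    n_bundles: int = 10
    n_decoys: int = 100
    seed: int = 0
    mc_steps: int = 120
    design_thresholds: FilterThresholds = field(default_factory=FilterThresholds.design)
    output_dir: str = "tmdkit_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        thresholds = data.pop("design_thresholds", None)
        cfg = cls(**data)
        if thresholds:
            cfg.design_thresholds = FilterThresholds(stage="design", **thresholds)
        return cfg

    def config_hash(self) -> str:
        """Hash of the scientific parameters (paths excluded)."""
        payload = {
            k: v
            for k, v in vars(self).items()
            if k != "output_dir" and not hasattr(v, "__dict__")
        }
        payload["design_thresholds"] = vars(self.design_thresholds)
        blob = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def output_header(config: RunConfig) -> list[str]:
    return [
        f"tmdkit {__version__}",
        f"config_hash {config.config_hash()}",
        f"seed {config.seed}",
    ]


def run_design_campaign(config: RunConfig) -> dict:
    """Generate -> score/filter -> diversify -> landscape -> state call.

    A deliberately small-scale, fully seeded campaign: randomized bundle
    geometries for the target symmetry are scored and filtered with the
    design-stage criteria (threshold filters first, then the ensemble
    energy percentile), the best survivor's sequence is diversified, and
    the result is evaluated on C2/C3/C4 landscapes with the negative-design
    selection rule.  All artifacts are written under ``config.output_dir``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = output_header(config)
    table = LipophilicityTable.default()
    rng = np.random.default_rng(config.seed)

    # Stage 1: bundle generation + scoring
    bundles, reports = [], []
    for _ in range(config.n_bundles):
        params = CrickParams(
            superhelical_radius=float(rng.uniform(6.5, 10.0)),
            interface_phase=float(rng.uniform(0.0, 360.0)),
            z_offset=float(rng.uniform(-2.0, 2.0)),
            tilt=float(rng.uniform(5.0, 25.0)),
            n_chains=config.target_symmetry,
            chain_length=config.chain_length,
        )
        bundle = build_symmetric_bundle(params, config.start_sequence)
        bundles.append(bundle)
        reports.append(score_bundle(bundle, table))

    results = [apply_design_filters(r, config.design_thresholds) for r in reports]
    energies = np.array([r.total_energy for r in reports])
    pct_mask = energy_percentile_mask(energies, config.design_thresholds.energy_percentile)
    survivors = [
        i for i, (res, ok) in enumerate(zip(results, pct_mask)) if res.passed and ok
    ]

    import pandas as pd

    score_table = pd.DataFrame([r.as_series() for r in reports])
    score_table["passed"] = [r.passed for r in results]
    score_table["violations"] = [";".join(r.violations) for r in results]
    score_table["in_energy_percentile"] = pct_mask
    _write_report(score_table, outdir / "design_scores.tsv", header)

    out = {"survivors": survivors, "scores": score_table}
    if not survivors:
        logger.info("no bundle passed the design filters; empty report written")
        _write_report(pd.DataFrame(), outdir / "state_calls.tsv", header)
        return out

    # Stage 2: sequence diversification on the best survivor
    best = min(survivors, key=lambda i: reports[i].total_energy)
    bundle = bundles[best]

    def scorer(b: HelixBundle) -> tuple[float, float]:
        return ddg_binding(b, table), system_energy(b, table)

    objective = default_objective(bundle, scorer)
    schedule = MCSchedule(n_steps=config.mc_steps, seed=config.seed)
    final_seq, trace = diversify_sequence(bundle, objective, schedule)
    _write_report(trace.to_frame(), outdir / "design_trace.tsv", header)
    write_fasta({"diversified": final_seq}, outdir / "designed.fasta")
    out["final_sequence"] = final_seq

    # Stage 3: multi-symmetry landscapes + negative-design call
    designed = bundle.with_sequence(final_seq)
    summaries = {}
    frames = []
    for sym in (2, 3, 4):
        params = CrickParams(n_chains=sym, chain_length=config.chain_length)
        reference = (
            designed
            if sym == config.target_symmetry
            else build_symmetric_bundle(params, final_seq)
        )
        samples = sample_landscape(
            final_seq, sym, config.n_decoys, config.seed + sym,
            lambda b: system_energy(b, table), reference,
        )
        summaries[sym] = summarize_landscape(samples)
        frames.append(samples_to_frame(samples))
    call = select_oligomeric_state(summaries, config.target_symmetry)
    _write_report(pd.concat(frames), outdir / "decoys.tsv", header)
    calls = pd.DataFrame(
        [
            {
                "symmetry": s.symmetry,
                "e_lowest": s.e_lowest,
                "z": s.z,
                "funneled": s.funneled,
                "n_samples": s.n_samples,
            }
            for s in summaries.values()
        ]
    )
    calls["target"] = call.target
    calls["selected"] = call.selected
    calls["reason"] = call.reason
    _write_report(calls, outdir / "state_calls.tsv", header)
    out["summaries"] = summaries
    out["state_call"] = call
    return out


def _write_report(df, path, header_lines) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")
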