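"""Declarative multi-stage pipeline runner.

A single validated config selects stages, sets per-stage parameters (all
defaults are the study-condition values used throughout the package), and
names the output directory. Each stage writes only inside its own
subdirectory; the resolved config and a manifest with SHA-256 checksums of
every artifact are echoed into the output directory, so deterministic
reruns can be verified byte-for-byte.

When a stage is given no input path it runs on seeded synthetic data from
:mod:`quadrufold.synth` — the built-in demo recipes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import fp_binding, fret, gq_scan, peptides, smfret, synth
from . import contacts as contacts_mod

__all__ = ["RunConfig", "run", "STAGES"]

logger = logging.getLogger("quadrufold")

STAGES = ("scan", "peptide", "unfold", "fitkd", "smfret", "contacts")

#: The designed-peptide panel assayed against the ARPC2 quadruplex.
PRINTED_PANEL = (
    ("(RQ)10", "(RQ)10"),
    ("(RQ)15", "(RQ)15"),
    ("(RQ)20", "(RQ)20"),
    ("(RGG)13", "(RGG)13"),
    ("(RP)15", "(RP)15"),
    ("(RP)20", "(RP)20"),
    ("(RE)20", "(RE)20"),
    ("R30", "R30"),
)


class _Forbid(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScanConfig(_Forbid):
    input_fasta: Optional[str] = None
    min_tract: int = 2
    max_loop: int = 7
    n_synthetic: int = 50


class PeptideConfig(_Forbid):
    input_path: Optional[str] = None
    min_arg: int = peptides.DEFAULT_MIN_ARG


class UnfoldConfig(_Forbid):
    input_csv: Optional[str] = None
    donor_nm: float = 566.0
    acceptor_nm: float = 670.0
    noise_sd: float = 0.01


class FitKdConfig(_Forbid):
    input_csv: Optional[str] = None
    lt_nm: float = 10.0
    kd_nm: float = 100.0
    noise_sd_mp: float = 2.0
    replicates: int = 3


class SmfretConfig(_Forbid):
    input_csv: Optional[str] = None
    bin_width: float = 0.02
    n: int = 6000


class ContactsConfig(_Forbid):
    input_pdb: Optional[str] = None
    hbond_distance_max: float = 3.5
    hbond_angle_min: float = 120.0
    saltbridge_distance_max: float = 4.0
    stacking_distance_max: float = 4.0
    stacking_angle_max: float = 30.0
    n_frames: int = 3


class RunConfig(_Forbid):
    """Validated pipeline configuration; unknown keys are rejected."""

    out_dir: str
    seed: int = 0
    log_level: str = "INFO"
    stages: list[Literal["scan", "peptide", "unfold", "fitkd", "smfret", "contacts"]] = list(STAGES)
    scan: ScanConfig = ScanConfig()
    peptide: PeptideConfig = PeptideConfig()
    unfold: UnfoldConfig = UnfoldConfig()
    fitkd: FitKdConfig = FitKdConfig()
    smfret: SmfretConfig = SmfretConfig()
    contacts: ContactsConfig = ContactsConfig()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.model_validate(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_scan(cfg: RunConfig, out: Path) -> list[Path]:
    c = cfg.scan
    if c.input_fasta:
        records = gq_scan.read_transcripts(c.input_fasta)
    else:
        planted = [2, 3, 4] * (c.n_synthetic // 3 + 1)
        records, truth = synth.gen_transcripts(
            n=c.n_synthetic, planted=planted[: c.n_synthetic], seed=cfg.seed
        )
        truth.to_csv(out / "planted_truth.tsv", sep="\t", index=False)
    rows = []
    for rec in records:
        motifs = gq_scan.scan_motifs(
            rec.sequence, min_tract=c.min_tract, max_loop=c.max_loop
        )
        rows.extend(gq_scan.motifs_to_table(rec.id, motifs))
    gq_scan.write_motif_table(rows, out / "motifs.tsv")
    dist = gq_scan.layer_distribution(
        records, min_tract=c.min_tract, max_loop=c.max_loop
    )
    (out / "layer_distribution.json").write_text(dist.to_json())
    return list(out.iterdir())


def _stage_peptide(cfg: RunConfig, out: Path) -> list[Path]:
    c = cfg.peptide
    if c.input_path:
        profiles = peptides.read_peptides(c.input_path)
    else:
        profiles = [peptides.profile_peptide(i, s) for i, s in PRINTED_PANEL]
    calls = [peptides.predict_unfolding(p, min_arg=c.min_arg) for p in profiles]
    df = peptides.panel_summary(profiles, calls)
    df.to_csv(out / "verdicts.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(
        json.dumps({"min_active_arg": df.attrs["min_active_arg"]})
    )
    return list(out.iterdir())


def _stage_unfold(cfg: RunConfig, out: Path) -> list[Path]:
    c = cfg.unfold
    if c.input_csv:
        spectra = fret.read_spectra_csv(c.input_csv)
    else:
        spectra, truth = synth.gen_spectra(noise_sd=c.noise_sd, seed=cfg.seed)
        truth.to_csv(out / "truth.csv", index=False)
    curve = fret.build_unfolding_curve(
        spectra, donor_ref_nm=c.donor_nm, acceptor_ref_nm=c.acceptor_nm
    )
    curve.to_frame().to_csv(out / "unfolding_curve.csv", index=False)
    return list(out.iterdir())


def _stage_fitkd(cfg: RunConfig, out: Path) -> list[Path]:
    c = cfg.fitkd
    if c.input_csv:
        series = fp_binding.TitrationSeries.from_csv(c.input_csv)
    else:
        series, truth = synth.gen_fp_curves(
            kd_nm=c.kd_nm, lt_nm=c.lt_nm, noise_sd_mp=c.noise_sd_mp,
            replicates=c.replicates, seed=cfg.seed,
        )
        (out / "truth.json").write_text(json.dumps(truth))
    report = fp_binding.fit_kd(series, lt_nm=c.lt_nm)
    (out / "fit.json").write_text(json.dumps(report.to_dict(), indent=1))
    return list(out.iterdir())


def _stage_smfret(cfg: RunConfig, out: Path) -> list[Path]:
    c = cfg.smfret
    if c.input_csv:
        df = pd.read_csv(c.input_csv)
        if "E" in df.columns:
            e = df["E"].to_numpy(float)
        else:
            e = smfret.compute_efficiency(
                df["I_D"].to_numpy(float), df["I_A"].to_numpy(float)
            ).efficiencies
    else:
        e, truth = synth.gen_smfret(n=c.n, seed=cfg.seed)
        (out / "truth.json").write_text(json.dumps(truth))
    smfret.build_histogram(e, bin_width=c.bin_width).to_csv(
        out / "histogram.csv", index=False
    )
    fit = smfret.fit_two_populations(e, seed=cfg.seed)
    (out / "fit.json").write_text(
        json.dumps(
            {
                "means": fit.means, "sds": fit.sds, "weights": fit.weights,
                "converged": fit.converged, "degenerate": fit.degenerate,
            }
        )
    )
    return list(out.iterdir())


def _stage_contacts(cfg: RunConfig, out: Path) -> list[Path]:
    c = cfg.contacts
    criteria = contacts_mod.ContactCriteria(
        hbond_distance_max=c.hbond_distance_max,
        hbond_angle_min=c.hbond_angle_min,
        saltbridge_distance_max=c.saltbridge_distance_max,
        stacking_distance_max=c.stacking_distance_max,
        stacking_angle_max=c.stacking_angle_max,
    )
    if c.input_pdb:
        frames = contacts_mod.read_frames(c.input_pdb)
    else:
        frames, truth = synth.gen_frames(n_frames=c.n_frames, seed=cfg.seed)
        (out / "truth.json").write_text(json.dumps(truth))
    report = contacts_mod.contact_report(frames, criteria)
    report.per_frame.to_csv(out / "per_frame.csv", index=False)
    (out / "summary.json").write_text(json.dumps(report.to_dict(), indent=1))
    return list(out.iterdir())


_STAGE_FUNCS = {
    "scan": _stage_scan,
    "peptide": _stage_peptide,
    "unfold": _stage_unfold,
    "fitkd": _stage_fitkd,
    "smfret": _stage_smfret,
    "contacts": _stage_contacts,
}


def run(config: RunConfig) -> dict:
    """Execute the selected stages in order; return the output manifest.

    The manifest maps every artifact path (relative to ``out_dir``) to its
    SHA-256 checksum and is also written to ``manifest.json`` alongside
    the resolved config. A stage failure raises RuntimeError naming the
    stage.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), "INFO"))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(config.model_dump_json(indent=1))
    manifest = {}
    for stage in config.stages:
        stage_out = out_dir / stage
        stage_out.mkdir(exist_ok=True)
        logger.info("running stage %s (seed=%d)", stage, config.seed)
        try:
            paths = _STAGE_FUNCS[stage](config, stage_out)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        for p in paths:
            manifest[str(p.relative_to(out_dir))] = _sha256(p)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
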