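"""Seeded synthetic-data generators with planted ground truth.

Every analysis stage in this package can be exercised without downloads:
the generators here emit the same formats the stages read, alongside
machine-readable truth tables. All randomness flows through
``numpy.random.default_rng(seed)``, so identical parameters give identical
output on any platform.

The defaults mirror the study conditions the stages are meant for: a pool
of transcripts with quadruplex motifs of 2/3/4 G-tetrad layers planted in
G-run-free background; Cy3/Cy5 two-peak emission spectra over a protein
titration; fluorescence-polarization curves on the 8000 -> 0.488 nM
two-fold ladder with 10 nM labelled RNA; smFRET efficiency mixtures at the
duplex/hairpin parameters (means 0.46/0.92, weights 0.39/0.61, n = 6000);
and toy MD frames with protein-RNA contacts placed at specified
distances/angles plus decoys just outside the cutoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .contacts import AtomRecord
from .fp_binding import BindingModel, TitrationSeries, fp_model, paper_ladder
from .fret import EmissionSpectrum
from .gq_scan import TranscriptRecord, sanitize_rna

__all__ = [
    "gen_transcripts",
    "gen_spectra",
    "two_peak_spectrum",
    "gen_fp_curves",
    "gen_smfret",
    "gen_frames",
    "ContactPlan",
    "write_transcripts_fasta",
]

_BG = np.array(list("ACGU"))
_NO_G = np.array(list("ACU"))


# ---------------------------------------------------------------------------
# transcripts with planted quadruplex motifs

PlantSpec = Union[None, int, tuple, str]


def _motif_sequence(layers: int, loops: Sequence[int], rng) -> str:
    tract = "G" * layers
    parts = [tract]
    for L in loops:
        parts.append("".join(rng.choice(_NO_G, size=L)))
        parts.append(tract)
    return "".join(parts)


def gen_transcripts(
    n: int,
    length: int = 200,
    planted: Optional[Sequence[PlantSpec]] = None,
    g_background: float = 0.15,
    min_tract: int = 2,
    seed: int = 0,
) -> tuple[list[TranscriptRecord], pd.DataFrame]:
    """Random transcripts with quadruplex motifs planted at known spans.

    ``planted[i]`` controls transcript i: ``None`` plants nothing, an int
    is a layer count (loops default to (2, 1, 3)), a ``(layers, loops)``
    tuple sets both, and a string is planted verbatim (e.g. a printed
    quadruplex sequence). Background nucleotides are drawn iid with G
    probability ``g_background``, then any G-run of length >= ``min_tract``
    outside a planted span — including runs touching one — is resampled
    away, so planted motifs are the only motifs by construction.

    Returns the records plus a truth table (id, start, end, layers; layers
    is NaN for verbatim plants, whose class is up to the caller).
    """
    if planted is None:
        planted = [None] * n
    if len(planted) > n:
        raise ValueError("more planted specs than transcripts")
    planted = list(planted) + [None] * (n - len(planted))
    rng = np.random.default_rng(seed)

    records, rows = [], []
    for i, spec in enumerate(planted):
        tid = f"synth_{i:04d}"
        if spec is None:
            motif, layers = None, None
        elif isinstance(spec, str):
            motif, layers = sanitize_rna(spec), None
        elif isinstance(spec, int):
            motif, layers = _motif_sequence(spec, (2, 1, 3), rng), spec
        else:
            layers, loops = spec
            motif = _motif_sequence(layers, loops, rng)
        if motif is not None and len(motif) + 2 > length:
            raise ValueError(
                f"planted motif of length {len(motif)} does not fit in "
                f"transcript length {length}"
            )

        probs = np.full(4, (1 - g_background) / 3)
        probs[2] = g_background  # index of G in ACGU
        seq = rng.choice(_BG, size=length, p=probs)
        span = None
        if motif is not None:
            start = int(rng.integers(1, length - len(motif)))
            span = (start, start + len(motif))
            seq[span[0]:span[1]] = list(motif)
            # non-G flanks so planted tracts stay maximal
            for j in (span[0] - 1, span[1]):
                if 0 <= j < length:
                    seq[j] = rng.choice(_NO_G)

        _mask_background_g_runs(seq, span, min_tract, rng)
        records.append(TranscriptRecord(id=tid, sequence="".join(seq)))
        rows.append(
            {
                "id": tid,
                "start": span[0] if span else -1,
                "end": span[1] if span else -1,
                "layers": layers if layers is not None else np.nan,
            }
        )
    return records, pd.DataFrame(rows)


def _mask_background_g_runs(seq, span, min_tract, rng):
    """Resample G so no background run reaches min_tract or touches the
    planted span."""
    length = len(seq)
    protected = range(span[0], span[1]) if span else range(0)
    pset = set(protected)
    run_start = None
    for j in range(length + 1):
        is_g = j < length and seq[j] == "G"
        if is_g and run_start is None:
            run_start = j
        elif not is_g and run_start is not None:
            run = [k for k in range(run_start, j) if k not in pset]
            whole = list(range(run_start, j))
            touches = any(k in pset for k in whole)
            if run and (len(whole) >= min_tract or touches):
                for k in run:
                    seq[k] = rng.choice(_NO_G)
            run_start = None


def write_transcripts_fasta(
    records: Sequence[TranscriptRecord], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.sequence}\n")


# ---------------------------------------------------------------------------
# two-peak emission spectra over a titration

WAVELENGTH_GRID = np.arange(530.0, 701.0, 1.0)


def two_peak_spectrum(
    folded_fraction: float,
    concentration_nm: float = 0.0,
    condition: str = "synthetic",
    donor_amp: float = 1.0,
    acceptor_amp: float = 0.8,
    donor_nm: float = 566.0,
    acceptor_nm: float = 670.0,
    donor_width: float = 12.0,
    acceptor_width: float = 14.0,
    scale: float = 1000.0,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> EmissionSpectrum:
    """One Cy3/Cy5 spectrum: donor peak fixed, acceptor peak proportional
    to the folded fraction (FRET from the folded quadruplex feeds Cy5)."""
    w = WAVELENGTH_GRID
    y = donor_amp * np.exp(-0.5 * ((w - donor_nm) / donor_width) ** 2)
    y = y + acceptor_amp * folded_fraction * np.exp(
        -0.5 * ((w - acceptor_nm) / acceptor_width) ** 2
    )
    y = y * scale
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        y = y + rng.normal(0.0, noise_sd * scale, size=w.size)
    return EmissionSpectrum(
        wavelengths=w, intensities=y,
        condition=condition, concentration_nm=concentration_nm,
    )


def gen_spectra(
    concentrations_nm: Sequence[float] = (0, 50, 100, 200, 400, 800, 1600),
    u_max: float = 0.9,
    ec50_nm: float = 200.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    condition: str = "synthetic",
    **peak_kwargs,
) -> tuple[list[EmissionSpectrum], pd.DataFrame]:
    """Titration of two-peak spectra under a saturating unfolding model.

    The unfolded fraction at dose c is ``u_max * c / (c + ec50)`` (0 at
    c = 0), and the folded fraction feeding the acceptor peak is its
    complement. Returns the spectra and a truth table with the true
    unfolding fraction per concentration.
    """
    conc = np.asarray(concentrations_nm, dtype=float)
    if 0.0 not in conc:
        raise ValueError("concentrations must include 0")
    rng = np.random.default_rng(seed)
    spectra, rows = [], []
    for c in conc:
        u = u_max * c / (c + ec50_nm) if c > 0 else 0.0
        spectra.append(
            two_peak_spectrum(
                folded_fraction=1.0 - u,
                concentration_nm=float(c),
                condition=condition,
                noise_sd=noise_sd,
                rng=rng,
                **peak_kwargs,
            )
        )
        rows.append(
            {"concentration_nM": c, "folded_fraction": 1.0 - u,
             "unfolding_fraction": u}
        )
    return spectra, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fluorescence-polarization titrations

def gen_fp_curves(
    kd_nm: float = 100.0,
    f_min: float = 60.0,
    f_max: float = 240.0,
    lt_nm: float = 10.0,
    ladder_nm: Optional[Sequence[float]] = None,
    noise_sd_mp: float = 2.0,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[TitrationSeries, dict]:
    """Quadratic-model FP readings plus Gaussian noise, with truth."""
    conc = np.asarray(ladder_nm if ladder_nm is not None else paper_ladder(), float)
    model = BindingModel(f_min, f_max, kd_nm, lt_nm)
    clean = fp_model(conc, model)
    rng = np.random.default_rng(seed)
    readings = clean[None, :] + rng.normal(
        0.0, noise_sd_mp, size=(replicates, conc.size)
    ) if noise_sd_mp > 0 else np.tile(clean, (replicates, 1))
    series = TitrationSeries(
        concentrations_nm=conc, readings_mp=readings, condition="synthetic"
    )
    truth = {"kd_nm": kd_nm, "f_min": f_min, "f_max": f_max, "lt_nm": lt_nm,
             "noise_sd_mp": noise_sd_mp}
    return series, truth


# ---------------------------------------------------------------------------
# smFRET efficiency mixtures

def gen_smfret(
    weights: Sequence[float] = (0.39, 0.61),
    means: Sequence[float] = (0.46, 0.92),
    sds: Sequence[float] = (0.05, 0.04),
    n: int = 6000,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Per-molecule efficiencies from a Gaussian mixture, clamped to [0, 1].

    Defaults are the DNA-RNA hybrid-duplex experiment's two states: the
    duplex at E = 0.46 holding 39% of molecules and the hairpin at
    E = 0.92 holding the rest.
    """
    w = np.asarray(weights, float)
    if w.min() < 0 or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(w), size=n, p=w)
    e = rng.normal(np.asarray(means, float)[comp], np.asarray(sds, float)[comp])
    e = np.clip(e, 0.0, 1.0)
    truth = {"weights": tuple(w), "means": tuple(map(float, means)),
             "sds": tuple(map(float, sds)), "n": n}
    return e, truth


# ---------------------------------------------------------------------------
# toy structure frames with planted contacts

@dataclass(frozen=True)
class ContactPlan:
    """How many contacts of each class to plant per frame (plus decoys)."""

    hbond_base: int = 1
    hbond_ribose: int = 0
    hbond_phosphate: int = 0
    salt_bridge: int = 1
    stacking: int = 1
    decoys: bool = True


_HEX = [
    (math.cos(math.radians(a)), math.sin(math.radians(a)))
    for a in range(0, 360, 60)
]
_RING_R = 1.39

# planar guanine: ring atoms plus O6, idealized in-plane coordinates
_GUANINE_RING = {
    "N9": (-1.289, 4.551), "C8": (0.023, 4.962), "N7": (0.870, 3.969),
    "C5": (0.071, 2.833), "C4": (-1.289, 3.176), "N3": (-2.342, 2.364),
    "C2": (-1.999, 1.087), "N1": (-0.700, 0.641), "C6": (0.424, 1.460),
}


def _atoms(res_name, res_id, chain, named_coords, element_map=None):
    out = []
    for name, xyz in named_coords.items():
        el = (element_map or {}).get(name) or (
            "H" if name.startswith("H") else name[0]
        )
        out.append(
            AtomRecord(
                name=name, element=el, res_name=res_name, res_id=res_id,
                chain_id=chain, coord=tuple(float(v) for v in xyz),
            )
        )
    return out


def _cell_contacts(plan: ContactPlan):
    """Template atoms for each planted unit, each in local coordinates.

    Every unit is a (protein residue, RNA residue) pair arranged so that
    exactly one contact of the intended class — and nothing else — holds.
    Serine is the H-bond donor throughout (it is never cationic, so no
    stray salt bridges); lone Arg NH1 atoms make salt bridges without a
    guanidinium plane or attached hydrogen.
    """
    units = []  # (class_label, [atoms in local coords])
    rid = 1

    def ser_hbond(acceptor_name, label):
        nonlocal rid
        prot = _atoms("SER", rid, "A", {"OG": (0, 0, 0), "HG": (0.97, 0, 0)})
        rna = _atoms("G", rid + 500, "B", {acceptor_name: (2.9, 0, 0)})
        rid += 1
        return (label, prot + rna)

    for _ in range(plan.hbond_base):
        units.append(ser_hbond("O6", "hbond_base"))
    for _ in range(plan.hbond_ribose):
        units.append(ser_hbond("O2'", "hbond_backbone"))
    for _ in range(plan.hbond_phosphate):
        units.append(ser_hbond("OP1", "hbond_backbone"))
    for _ in range(plan.salt_bridge):
        prot = _atoms("ARG", rid, "A", {"NH1": (0, 0, 0)})
        rna = _atoms("G", rid + 500, "B", {"OP1": (3.5, 0, 0)})
        units.append(("salt_bridge", prot + rna))
        rid += 1
    for _ in range(plan.stacking):
        ring = {
            n: (_RING_R * x, _RING_R * y, 0.0)
            for n, (x, y) in zip(
                ("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), _HEX
            )
        }
        prot = _atoms("TYR", rid, "A", ring)
        gua = {n: (x - 0.5, y - 2.8, 3.4) for n, (x, y) in _GUANINE_RING.items()}
        rna = _atoms("G", rid + 500, "B", gua)
        units.append(("stacking", prot + rna))
        rid += 1

    if plan.decoys:
        # just outside each cutoff: distance 3.8 A / angle 100 deg H-bonds,
        # 4.3 A salt bridge, 4.4 A and 45-deg-tilt stacking
        prot = _atoms("SER", rid, "A", {"OG": (0, 0, 0), "HG": (0.97, 0, 0)})
        rna = _atoms("G", rid + 500, "B", {"O6": (3.8, 0, 0)})
        units.append(("decoy", prot + rna))
        rid += 1
        h = (0.97 * math.cos(math.radians(80)), 0.97 * math.sin(math.radians(80)))
        prot = _atoms("SER", rid, "A", {"OG": (0, 0, 0), "HG": (h[0], h[1], 0)})
        rna = _atoms("G", rid + 500, "B", {"O6": (2.9, 0, 0)})
        units.append(("decoy", prot + rna))
        rid += 1
        prot = _atoms("ARG", rid, "A", {"NH1": (0, 0, 0)})
        rna = _atoms("G", rid + 500, "B", {"OP1": (4.3, 0, 0)})
        units.append(("decoy", prot + rna))
        rid += 1
        ring = {
            n: (_RING_R * x, _RING_R * y, 0.0)
            for n, (x, y) in zip(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), _HEX)
        }
        prot = _atoms("TYR", rid, "A", ring)
        gua = {n: (x - 0.5, y - 2.8, 4.4) for n, (x, y) in _GUANINE_RING.items()}
        units.append(("decoy", prot + _atoms("G", rid + 500, "B", gua)))
        rid += 1
        prot = _atoms("TYR", rid, "A", ring)
        c, s = math.cos(math.radians(45)), math.sin(math.radians(45))
        gua = {
            n: (x - 0.5, (y - 2.8) * c, 3.4 + (y - 2.8) * s)
            for n, (x, y) in _GUANINE_RING.items()
        }
        units.append(("decoy", prot + _atoms("G", rid + 500, "B", gua)))
    return units


def gen_frames(
    plan: ContactPlan = ContactPlan(),
    n_frames: int = 3,
    jitter_sd: float = 0.02,
    seed: int = 0,
) -> tuple[list[list[AtomRecord]], dict]:
    """Toy trajectory frames whose contact counts are known exactly.

    Each planted unit sits in its own 30-A grid cell, far from every other
    unit, with enough geometric margin that the per-frame Gaussian jitter
    (``jitter_sd`` A) cannot flip a contact on or off. Decoys are placed
    just outside the cutoffs. Returns frames plus the truth counts per
    frame.
    """
    units = _cell_contacts(plan)
    rng = np.random.default_rng(seed)
    truth = {
        "hbond_base": plan.hbond_base,
        "hbond_backbone": plan.hbond_ribose + plan.hbond_phosphate,
        "salt_bridge": plan.salt_bridge,
        "stacking": plan.stacking,
    }
    frames = []
    for _ in range(n_frames):
        frame = []
        for u, (label, atoms) in enumerate(units):
            ox, oy = 30.0 * (u % 8), 30.0 * (u // 8)
            for a in atoms:
                dx, dy, dz = rng.normal(0.0, jitter_sd, size=3) if jitter_sd > 0 else (0, 0, 0)
                frame.append(
                    AtomRecord(
                        name=a.name, element=a.element, res_name=a.res_name,
                        res_id=a.res_id, chain_id=a.chain_id,
                        coord=(
                            a.coord[0] + ox + dx,
                            a.coord[1] + oy + dy,
                            a.coord[2] + dz,
                        ),
                    )
                )
        frames.append(frame)
    return frames, truth
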