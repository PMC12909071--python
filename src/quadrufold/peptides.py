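"""Composition profiling and unfolding-activity calls for Arg-rich peptides.

Arginine-rich low-complexity regions (the RS regions of SR and SR-related
splicing factors, RGG boxes of RNA-binding proteins, and designed repeats
like (RQ)_n) can unfold RNA G-quadruplexes without ATP. Activity is driven
by arginine content and net positive charge: for the ARPC2 quadruplex at
least 13 Arg residues are required, and acidic residues (Asp/Glu) attenuate
activity by neutralizing the Arg charge. The binary rule implemented here is

    active  <=>  arg_count >= min_arg  AND  net_charge > 0

with net charge counted as +1 per Arg/Lys and -1 per Asp/Glu at neutral pH
(His and termini ignored; synthesized repeat peptides carry a C-terminal
amide). Context polarity (Q vs GG vs P neighbours) has only a secondary
effect and is reported as metadata, not graded.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

__all__ = [
    "PeptideProfile",
    "ActivityCall",
    "profile_peptide",
    "predict_unfolding",
    "panel_summary",
    "expand_repeat",
    "read_peptides",
    "srsf1_rs_sequence",
    "DEFAULT_MIN_ARG",
]

AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Minimum Arg count for activity against the ARPC2 quadruplex.
DEFAULT_MIN_ARG = 13


@dataclass(frozen=True)
class PeptideProfile:
    id: str
    sequence: str
    counts: dict = field(repr=False, default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def arg_count(self) -> int:
        return self.counts.get("R", 0)

    @property
    def lys_count(self) -> int:
        return self.counts.get("K", 0)

    @property
    def acidic_count(self) -> int:
        return self.counts.get("D", 0) + self.counts.get("E", 0)

    @property
    def net_charge(self) -> int:
        """+1 per R/K, -1 per D/E; His and termini ignored."""
        return self.arg_count + self.lys_count - self.acidic_count


@dataclass(frozen=True)
class ActivityCall:
    active: bool
    reasons: tuple[str, ...] = ()


def expand_repeat(text: str) -> str:
    """Expand repeat shorthand like ``(RQ)15`` or ``R30`` to a sequence.

    Plain sequences pass through unchanged.
    """
    m = re.fullmatch(r"\(([A-Za-z]+)\)(\d+)", text.strip())
    if m:
        return m.group(1).upper() * int(m.group(2))
    m = re.fullmatch(r"([A-Za-z])(\d+)", text.strip())
    if m:
        return m.group(1).upper() * int(m.group(2))
    return text.strip().upper()


def profile_peptide(id: str, sequence: str) -> PeptideProfile:
    """Exact residue composition of a one-letter-code peptide sequence."""
    seq = expand_repeat(sequence)
    for i, ch in enumerate(seq):
        if ch not in AA20:
            raise ValueError(
                f"unknown amino-acid letter {ch!r} at position {i} in {id!r}"
            )
    return PeptideProfile(id=id, sequence=seq, counts=dict(Counter(seq)))


def predict_unfolding(
    profile: PeptideProfile, min_arg: int = DEFAULT_MIN_ARG
) -> ActivityCall:
    """Binary quadruplex-unfolding call for a peptide profile.

    Active iff the peptide carries at least ``min_arg`` arginines AND a net
    positive charge. Each failed clause contributes a reason string.
    """
    reasons = []
    if profile.arg_count < min_arg:
        reasons.append(
            f"insufficient Arg ({profile.arg_count} < {min_arg})"
        )
    if profile.net_charge <= 0:
        reasons.append(
            f"charge neutralized (net charge {profile.net_charge:+d})"
        )
    return ActivityCall(active=not reasons, reasons=tuple(reasons))


def panel_summary(
    profiles: Sequence[PeptideProfile], calls: Sequence[ActivityCall]
) -> pd.DataFrame:
    """Per-peptide verdict table plus the minimal active Arg count.

    Rows are ordered by ``arg_count`` (stable). The returned frame carries
    ``min_active_arg`` in ``df.attrs`` (None when no peptide is active).
    """
    if len(profiles) != len(calls):
        raise ValueError("profiles and calls differ in length")
    rows = []
    for p, c in zip(profiles, calls):
        rows.append(
            {
                "id": p.id,
                "length": p.length,
                "arg_count": p.arg_count,
                "lys_count": p.lys_count,
                "acidic_count": p.acidic_count,
                "net_charge": p.net_charge,
                "active": c.active,
                "reasons": "; ".join(c.reasons),
            }
        )
    df = pd.DataFrame(rows).sort_values("arg_count", kind="stable")
    df = df.reset_index(drop=True)
    active_args = df.loc[df["active"], "arg_count"]
    df.attrs["min_active_arg"] = (
        int(active_args.min()) if len(active_args) else None
    )
    return df


def read_peptides(path: Union[str, Path]) -> list[PeptideProfile]:
    """Read peptides from FASTA or a TSV with (id, sequence) columns.

    TSV sequences may use repeat shorthand like ``(RQ)15``.
    """
    path = Path(path)
    if path.suffix.lower() in {".fa", ".fasta", ".faa"}:
        return [
            profile_peptide(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")
        ]
    df = pd.read_csv(path, sep="\t")
    if not {"id", "sequence"}.issubset(df.columns):
        raise ValueError("TSV peptide input needs 'id' and 'sequence' columns")
    return [
        profile_peptide(str(r["id"]), str(r["sequence"]))
        for _, r in df.iterrows()
    ]


def srsf1_rs_sequence(region: str = "RS") -> str:
    """Packaged SRSF1 RS-region sequence (synthetic reconstruction).

    The packaged FASTA is a reconstruction of the human SRSF1 C-terminal
    RS region (residues 199-248) and is labelled synthetic; it matches the
    reported arginine composition of the region (the truncated RS1,
    residues 199-225, carries 10 Arg). ``region`` selects ``"RS"``
    (199-248) or ``"RS1"`` (199-225).
    """
    ref = resources.files("quadrufold.data") / "srsf1_rs_synthetic.fasta"
    with resources.as_file(ref) as p:
        rec = next(SeqIO.parse(str(p), "fasta"))
    full = str(rec.seq)
    if region == "RS":
        return full
    if region == "RS1":
        return full[: 225 - 199 + 1]
    raise ValueError("region must be 'RS' or 'RS1'")
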