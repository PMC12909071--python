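"""RNA G-quadruplex (rGQ) motif scanning and G-tetrad layer classification.

A quadruplex-forming sequence follows the pattern ``G_x N_{1-7} G_x N_{1-7}
G_x N_{1-7} G_x``: four runs of guanine (G-tracts) joined by short loops of
any nucleotide. The number of stacked G-tetrad *layers* a motif can build is
bounded by its shortest tract, so each candidate motif is classed by
``min(tract lengths)`` capped at 4. Canonical quadruplexes need three or
more layers; two-layer quadruplexes form but are much less stable, so the
scanner defaults to ``min_tract=2`` and reports the layer class per motif,
with ``min_tract=3`` available as a strict mode.

Coordinates are 0-based half-open throughout, including the BED-like export.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO

__all__ = [
    "TranscriptRecord",
    "GTract",
    "GQMotif",
    "LayerDistribution",
    "LayerClass",
    "sanitize_rna",
    "find_g_tracts",
    "scan_motifs",
    "classify_transcript",
    "layer_distribution",
    "read_transcripts",
    "motifs_to_table",
    "write_motif_table",
]

#: Layer classes reported for a transcript: ``0`` means no motif ("none");
#: 4 means "four or more" (tract lengths are capped at 4 when classing).
LayerClass = int

LAYER_LABELS = {0: "none", 2: "2", 3: "3", 4: ">=4"}

_RNA_OK = frozenset("ACGU")


class RnaAlphabetError(ValueError):
    """Raised when a sequence contains a non-ACGU character (after T->U)."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position
        super().__init__(
            f"invalid RNA character {char!r} at position {position} "
            "(expected A, C, G, U; T is accepted and mapped to U)"
        )


def sanitize_rna(seq: str) -> str:
    """Uppercase, map T->U, and validate the alphabet.

    Raises
    ------
    RnaAlphabetError
        Naming the first offending position, if any character is outside
        {A, C, G, U, T}.
    ValueError
        If the sequence is empty after sanitization.
    """
    s = seq.strip().upper().replace("T", "U")
    if not s:
        raise ValueError("empty sequence")
    for i, ch in enumerate(s):
        if ch not in _RNA_OK:
            raise RnaAlphabetError(ch, i)
    return s


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript identifier with its sanitized RNA sequence."""

    id: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", sanitize_rna(self.sequence))


@dataclass(frozen=True, order=True)
class GTract:
    """A maximal run of G, as a 0-based half-open interval."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GQMotif:
    """Four ordered G-tracts with loop lengths and a layer class.

    ``layers`` is the minimum over the four tracts of ``min(length, 4)``:
    the number of G-tetrad layers the motif can stack, capped at 4.
    """

    tracts: tuple[GTract, GTract, GTract, GTract]
    loop_lengths: tuple[int, int, int]

    @property
    def layers(self) -> int:
        return min(min(t.length, 4) for t in self.tracts)

    @property
    def span(self) -> tuple[int, int]:
        return (self.tracts[0].start, self.tracts[3].end)


@dataclass
class LayerDistribution:
    """Per-layer-class transcript tally; each transcript counted once."""

    counts: dict[int, int] = field(
        default_factory=lambda: {0: 0, 2: 0, 3: 0, 4: 0}
    )
    total: int = 0

    def as_labels(self) -> dict[str, int]:
        return {LAYER_LABELS[k]: v for k, v in self.counts.items()}

    def to_json(self) -> str:
        return json.dumps({"total": self.total, "counts": self.as_labels()})


def find_g_tracts(seq: str, min_tract: int = 2) -> list[GTract]:
    """All maximal G-runs of length >= ``min_tract``, ascending.

    A run of length 5 yields one tract of length 5, never sub-tracts.
    """
    if min_tract < 2:
        raise ValueError("min_tract must be >= 2")
    s = sanitize_rna(seq)
    return [
        GTract(m.start(), m.end())
        for m in re.finditer("G+", s)
        if m.end() - m.start() >= min_tract
    ]


def scan_motifs(seq: str, min_tract: int = 2, max_loop: int = 7) -> list[GQMotif]:
    """Enumerate candidate quadruplex motifs in an RNA sequence.

    Every 4-combination of distinct maximal G-tracts, in sequence order,
    whose three inter-tract gaps each lie in ``[1, max_loop]``, is a motif.
    The returned list is sorted by span start, then layer count descending.
    """
    if min_tract not in (2, 3, 4):
        raise ValueError("min_tract must be one of 2, 3, 4")
    if max_loop < 1:
        raise ValueError("max_loop must be >= 1")
    tracts = find_g_tracts(seq, min_tract=min_tract)
    motifs = []
    for quad in itertools.combinations(tracts, 4):
        loops = tuple(
            quad[i + 1].start - quad[i].end for i in range(3)
        )
        if all(1 <= g <= max_loop for g in loops):
            motifs.append(GQMotif(tracts=quad, loop_lengths=loops))
    motifs.sort(key=lambda m: (m.span[0], -m.layers, m.span[1]))
    return motifs


def classify_transcript(
    seq: str, min_tract: int = 2, max_loop: int = 7
) -> LayerClass:
    """Maximal layer class over all motifs: 0 (none), 2, 3 or 4 (>=4)."""
    motifs = scan_motifs(seq, min_tract=min_tract, max_loop=max_loop)
    if not motifs:
        return 0
    return max(m.layers for m in motifs)


def layer_distribution(
    records: Iterable[TranscriptRecord], min_tract: int = 2, max_loop: int = 7
) -> LayerDistribution:
    """Tally transcripts by their maximal layer class."""
    dist = LayerDistribution()
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate transcript id: {rec.id!r}")
        seen.add(rec.id)
        cls = classify_transcript(
            rec.sequence, min_tract=min_tract, max_loop=max_loop
        )
        dist.counts[cls] += 1
        dist.total += 1
    return dist


def read_transcripts(path: Union[str, Path]) -> list[TranscriptRecord]:
    """Read a (multi-record) FASTA file of transcripts."""
    records = [
        TranscriptRecord(id=r.id, sequence=str(r.seq))
        for r in SeqIO.parse(str(path), "fasta")
    ]
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in FASTA input")
    return records


def motifs_to_table(
    record_id: str, motifs: Sequence[GQMotif]
) -> list[dict]:
    """Rows of a BED-like table (0-based half-open coordinates)."""
    rows = []
    for m in motifs:
        rows.append(
            {
                "id": record_id,
                "start": m.span[0],
                "end": m.span[1],
                "layers": m.layers,
                "loop_lengths": ",".join(map(str, m.loop_lengths)),
                "tracts": ";".join(f"{t.start}-{t.end}" for t in m.tracts),
            }
        )
    return rows


def write_motif_table(rows: Iterable[dict], path: Union[str, Path]) -> None:
    import pandas as pd

    cols = ["id", "start", "end", "layers", "loop_lengths", "tracts"]
    pd.DataFrame(list(rows), columns=cols).to_csv(path, sep="\t", index=False)
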