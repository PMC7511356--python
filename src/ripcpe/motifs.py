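"""CPE element classes and 3'-UTR motif scanning.

CPEB-family proteins recognise U-rich cytoplasmic polyadenylation elements
(CPEs) in mRNA 3'-UTRs. This module defines the four literal element classes
used throughout the package and scans UTR sequences for their occurrences:

* ``CPEC``  - consensus CPE, ``UUUUA(1-2)U`` expanded to two literals
* ``CPENC`` - non-consensus CPE variants
* ``Hex``   - the polyadenylation hexanucleotide signal
* ``PBE``   - the Pumilio-binding element

Scanning is literal, sense-strand only, with 1-based inclusive coordinates.
A class's count is the number of distinct start positions at which at least
one of its patterns matches; overlapping matches at different starts are all
counted, while two patterns of the same class sharing a start count once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

__all__ = [
    "MotifClass",
    "UTRRecord",
    "MotifMatch",
    "MotifProfile",
    "motif_catalog",
    "normalize_sequence",
    "scan_sequence",
    "scan_utrs",
    "density_per_kb",
    "motif_map",
    "read_utr_fasta",
    "write_utr_fasta",
]


@dataclass(frozen=True)
class MotifClass:
    """A named element class defined by a set of literal RNA patterns."""

    name: str
    patterns: frozenset

    def __post_init__(self):
        if not self.patterns:
            raise ValueError(f"motif class {self.name!r} has no patterns")
        object.__setattr__(self, "patterns", frozenset(self.patterns))
        for pat in self.patterns:
            if len(pat) < 4:
                raise ValueError(f"pattern {pat!r} shorter than 4 nt")
            if set(pat) - RNA_ALPHABET:
                raise ValueError(f"pattern {pat!r} has non-RNA characters")

    @property
    def min_length(self) -> int:
        return min(len(p) for p in self.patterns)


@dataclass(frozen=True)
class UTRRecord:
    """One transcript's 3'-UTR sequence, normalized to uppercase RNA."""

    transcript_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifMatch:
    """A single pattern occurrence, 1-based inclusive coordinates."""

    class_name: str
    start: int
    end: int
    pattern: str


@dataclass
class MotifProfile:
    """Per-transcript element counts, positions and per-kb densities."""

    transcript_id: str
    utr_length: int
    positions: Mapping[str, Sequence[int]] = field(default_factory=dict)

    @property
    def counts(self) -> dict:
        return {name: len(pos) for name, pos in self.positions.items()}

    @property
    def densities(self) -> dict:
        return density_per_kb(self)


def motif_catalog() -> list:
    """The four CPE-related element classes as literal RNA pattern sets.

    CPEC's ``UUUUA(1-2)U`` consensus is expanded over the repeat range of the
    A run, giving UUUUAU and UUUUAAU.
    """
    return [
        MotifClass("CPEC", frozenset({"UUUUAU", "UUUUAAU"})),
        MotifClass("CPENC", frozenset({"UUUUAAAU", "UUUUACU", "UUUUCAU"})),
        MotifClass("Hex", frozenset({"AAUAAA", "AUUAAA"})),
        MotifClass("PBE", frozenset({"UGUAAAUA", "UGUAUAUA"})),
    ]


def normalize_sequence(raw: str) -> str:
    """Uppercase and convert DNA T to RNA U.

    Characters outside {A,C,G,U} (ambiguity codes, gaps) are preserved; the
    literal scanner can never match through them. Their presence is logged.
    """
    if not raw:
        raise ValueError("empty sequence")
    seq = raw.upper().replace("T", "U")
    n_odd = sum(1 for ch in seq if ch not in RNA_ALPHABET)
    if n_odd:
        logger.warning("sequence contains %d non-ACGU characters", n_odd)
    return seq


def _class_starts(sequence: str, cls: MotifClass) -> list:
    """Sorted distinct 1-based start positions of any pattern of ``cls``."""
    starts = set()
    for pat in cls.patterns:
        i = sequence.find(pat)
        while i != -1:
            starts.add(i + 1)
            i = sequence.find(pat, i + 1)
    return sorted(starts)


def scan_sequence(utr: UTRRecord, catalog: Iterable[MotifClass] | None = None) -> MotifProfile:
    """Scan one UTR for every class in the catalog.

    Returns a :class:`MotifProfile` with, per class, the sorted distinct
    match start positions (1-based). Sequences shorter than every pattern
    yield zero counts.
    """
    if catalog is None:
        catalog = motif_catalog()
    positions = {cls.name: _class_starts(utr.sequence, cls) for cls in catalog}
    return MotifProfile(utr.transcript_id, utr.length, positions)


def scan_utrs(utrs: Iterable[UTRRecord], catalog: Iterable[MotifClass] | None = None) -> list:
    if catalog is None:
        catalog = motif_catalog()
    catalog = list(catalog)
    return [scan_sequence(u, catalog) for u in utrs]


def density_per_kb(profile: MotifProfile) -> dict:
    """Per-class element density: count per kilobase of UTR."""
    if profile.utr_length <= 0:
        raise ValueError(f"undefined density: UTR length {profile.utr_length}")
    kb = profile.utr_length / 1000.0
    return {name: len(pos) / kb for name, pos in profile.positions.items()}


def motif_map(
    utr: UTRRecord,
    catalog: Iterable[MotifClass] | None = None,
    cluster_gap: int = 400,
) -> tuple:
    """Position track and motif clusters for one UTR.

    The track lists every match of every class as (class, start, end,
    pattern) in 1-based inclusive coordinates, sorted by start. Clusters are
    maximal runs of matches (all classes pooled) in which consecutive match
    starts differ by at most ``cluster_gap`` nucleotides; each cluster
    interval spans [first match start, last match end]. The default gap of
    400 nt separates motif clusters at the distance scale seen in long
    multi-cluster UTRs while merging locally co-occurring elements.
    """
    if cluster_gap <= 0:
        raise ValueError(f"cluster_gap must be positive, got {cluster_gap}")
    if catalog is None:
        catalog = motif_catalog()
    track = []
    for cls in catalog:
        for pat in cls.patterns:
            i = utr.sequence.find(pat)
            while i != -1:
                track.append(MotifMatch(cls.name, i + 1, i + len(pat), pat))
                i = utr.sequence.find(pat, i + 1)
    track.sort(key=lambda m: (m.start, m.end, m.class_name, m.pattern))
    clusters = []
    cur_start = cur_end = last_start = None
    for m in track:
        if cur_start is None:
            cur_start, cur_end, last_start = m.start, m.end, m.start
        elif m.start - last_start <= cluster_gap:
            cur_end = max(cur_end, m.end)
            last_start = m.start
        else:
            clusters.append((cur_start, cur_end))
            cur_start, cur_end, last_start = m.start, m.end, m.start
    if cur_start is not None:
        clusters.append((cur_start, cur_end))
    return track, clusters


def read_utr_fasta(path) -> list:
    """Read a multi-record FASTA of 3'-UTRs into normalized UTR records.

    Duplicate identifiers are an error; sequences are normalized (T->U,
    uppercase).
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(UTRRecord(rec.id, normalize_sequence(str(rec.seq))))
    return records


def write_utr_fasta(utrs: Iterable[UTRRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for u in utrs:
            fh.write(f">{u.transcript_id}\n")
            for i in range(0, len(u.sequence), width):
                fh.write(u.sequence[i : i + width] + "\n")
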