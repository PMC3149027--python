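"""Scanner for Ire1-cleavable RNA stem-loops.

Ire1 cleaves conserved stem-loops in its mRNA substrates that share a
seven-nucleotide loop with consensus C-N-G-N-N-G-N closed by a stem of
about five Watson-Crick base pairs; the scissile phosphate lies 3' of
the G at loop position 3. The same features identify the anticodon
stem-loop of tRNA-Phe as a substrate — unless the scissile G carries its
post-transcriptional 2'-O-methyl mark, which blocks formation of the
2',3'-cyclic phosphate and hence cleavage.

The scanner enumerates every 7-nt window matching the consensus,
extends perfect base-pairing outward from the loop boundaries, and
reports a hit when at least ``min_stem`` consecutive pairs form.
Coordinates are 0-based, half-open; ``cleavage_site`` counts the
nucleotides 5' of the scissile phosphate. Scanning is single-strand
only: RNA secondary structure is not strand-symmetric, so a hit in a
sequence implies nothing about its reverse complement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

logger = logging.getLogger(__name__)

LOOP_LEN = 7
#: fixed consensus positions within the loop (0-based): C.G..G.
_FIXED = {0: "C", 2: "G", 5: "G"}
#: offset of the scissile G within the loop (loop position 3, 1-based)
SCISSILE_OFFSET = 2

_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class ScanConfig:
    """Scanner settings: minimum stem length and pairing rules."""

    min_stem: int = 5
    allow_wobble: bool = False

    def __post_init__(self) -> None:
        if self.min_stem < 1:
            raise ValueError("min_stem must be >= 1")


@dataclass(frozen=True)
class StemLoopHit:
    """A located CNGNNGN hairpin.

    ``loop_start`` is the 0-based index of the first loop nucleotide;
    ``cleavage_site`` the number of nucleotides 5' of the scissile
    phosphate (the cut falls 3' of the loop-position-3 G, so
    ``cleavage_site = loop_start + 3``); ``stem_len`` the number of
    consecutive closing base pairs.
    """

    sequence_id: str
    loop_start: int
    loop_seq: str
    stem_len: int
    cleavage_site: int

    @property
    def scissile_index(self) -> int:
        """0-based index of the scissile G in the full sequence."""
        return self.loop_start + SCISSILE_OFFSET


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA T to U (logged once per call)."""
    up = seq.upper()
    if "T" in up:
        logger.info("DNA-style input: converting T to U")
        up = up.replace("T", "U")
    bad = [i for i, ch in enumerate(up) if ch not in "ACGUN"]
    if bad:
        raise ValueError(
            f"illegal character {seq[bad[0]]!r} at position {bad[0]}"
        )
    return up


def _loop_matches(window: str) -> bool:
    # N in the input is ambiguous: it may match free loop positions but
    # never the fixed C/G/G consensus positions
    return all(window[i] == base for i, base in _FIXED.items())


def _pairs(a: str, b: str, allow_wobble: bool) -> bool:
    if (a, b) in _WC_PAIRS:
        return True
    return allow_wobble and (a, b) in _WOBBLE_PAIRS


def _stem_length(seq: str, loop_start: int, allow_wobble: bool) -> int:
    n = 0
    i, j = loop_start - 1, loop_start + LOOP_LEN
    while i >= 0 and j < len(seq) and _pairs(seq[i], seq[j], allow_wobble):
        n += 1
        i -= 1
        j += 1
    return n


def find_stemloops(
    seq: str,
    config: ScanConfig | None = None,
    sequence_id: str = "",
) -> list[StemLoopHit]:
    """All CNGNNGN heptaloop hairpins in a single RNA strand.

    Every consensus-matching 7-nt window seeds at most one hit (the
    maximal contiguous stem extension); overlapping hits are all
    reported, sorted by loop position.
    """
    config = config or ScanConfig()
    rna = normalize_rna(seq)
    hits = []
    for start in range(len(rna) - LOOP_LEN + 1):
        window = rna[start:start + LOOP_LEN]
        if not _loop_matches(window):
            continue
        stem = _stem_length(rna, start, config.allow_wobble)
        if stem >= config.min_stem:
            hits.append(StemLoopHit(
                sequence_id=sequence_id,
                loop_start=start,
                loop_seq=window,
                stem_len=stem,
                cleavage_site=start + SCISSILE_OFFSET + 1,
            ))
    return hits


def annotate_cleavage(
    hit: StemLoopHit,
    modified_2prime_O: list[int] | tuple[int, ...] = (),
    seq_length: int | None = None,
) -> bool:
    """Whether the hit is cleavable given 2'-O-methyl marks.

    ``modified_2prime_O`` holds 0-based sequence indices of ribose
    2'-O-methylated nucleotides. Cleavage proceeds through a 2',3'-cyclic
    phosphate at the scissile G (loop position 3), so a mark there — and
    only there — blocks cleavage.
    """
    for pos in modified_2prime_O:
        if pos < 0 or (seq_length is not None and pos >= seq_length):
            raise ValueError(f"modification position {pos} outside sequence")
    return hit.scissile_index not in set(modified_2prime_O)


def scan_fasta(
    path: str | Path, config: ScanConfig | None = None
) -> list[StemLoopHit]:
    """Scan every record of a (multi-)FASTA file."""
    hits = []
    for record in SeqIO.parse(str(path), "fasta"):
        hits.extend(find_stemloops(str(record.seq), config,
                                   sequence_id=record.id))
    return hits


def hits_to_table(hits: list[StemLoopHit]) -> str:
    """BED-like tab-delimited table (0-based coordinates), with header."""
    lines = ["sequence_id\tloop_start\tloop_seq\tstem_len\tcleavage_site"]
    for h in hits:
        lines.append(
            f"{h.sequence_id}\t{h.loop_start}\t{h.loop_seq}\t"
            f"{h.stem_len}\t{h.cleavage_site}"
        )
    return "\n".join(lines) + "\n"
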