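"""In-memory reference genome with motif-site and context indexes.

Toy and synthetic genomes are small enough to hold in memory; real
references are loaded lazily through :mod:`pyfaidx` and cached per
chromosome on first access.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping

import numpy as np

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(COMPLEMENT)[::-1]


class ReferenceGenome:
    """Random-access reference sequence keyed by chromosome name.

    Coordinates follow BED convention internally: 0-based, half-open.
    ``fetch`` clips windows that straddle chromosome ends rather than
    raising, so callers see a shorter string at boundaries.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {c: str(s).upper() for c, s in sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "ReferenceGenome":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end), clipped to chromosome bounds."""
        seq = self._seqs[chrom]
        return seq[max(0, start):min(len(seq), end)]

    def base(self, chrom: str, pos0: int) -> str:
        return self._seqs[chrom][pos0]

    def write_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self._seqs.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


def scan_motif(seq: str, pattern_plus: str, offset_plus: int,
               pattern_minus: str, offset_minus: int) -> tuple[np.ndarray, np.ndarray]:
    """Positions (0-based) of a motif's target base on each strand.

    ``pattern_plus`` is a regex for the motif read on the forward strand
    with the target base at ``offset_plus``; ``pattern_minus`` is the
    reverse complement of the motif as it appears on the forward strand,
    with the forward-strand offset of the target base. Overlapping
    occurrences are all reported (lookahead scan).
    """
    plus = np.fromiter(
        (m.start() + offset_plus for m in re.finditer(f"(?={pattern_plus})", seq)),
        dtype=np.int64)
    minus = np.fromiter(
        (m.start() + offset_minus for m in re.finditer(f"(?={pattern_minus})", seq)),
        dtype=np.int64)
    return plus, minus


# Motif definitions, pyrimidine-strand notation. For the minus strand the
# pattern is the reverse complement as seen on the forward strand and the
# offset points at the G that pairs with the mutated C.
MOTIF_PATTERNS = {
    "TCW": ("TC[AT]", 1, "[AT]GA", 1),
    "RTCA": ("[AG]TCA", 2, "TGA[CT]", 1),
    "YTCA": ("[CT]TCA", 2, "TGA[AG]", 1),
    "RTCW": ("[AG]TC[AT]", 2, "[AT]GA[CT]", 1),
    "YTCW": ("[CT]TC[AT]", 2, "[AT]GA[AG]", 1),
}


def motif_sites(seq: str, motif: str) -> tuple[np.ndarray, np.ndarray]:
    """Cytosine positions of ``motif`` on (+, -) strands of ``seq``."""
    pp, op, pm, om = MOTIF_PATTERNS[motif]
    return scan_motif(seq, pp, op, pm, om)


def encode_bases(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else -> 4, as a uint8 array."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def penta_codes(seq: str) -> np.ndarray:
    """Pyrimidine-normalized pentamer code centered on every position.

    Position i gets an integer in [0, 4**5) encoding seq[i-2:i+3] read
    5'->3' on whichever strand carries a pyrimidine at the center; -1
    where the window leaves the chromosome or contains an ambiguous base.
    The code is strand-symmetric, so a mutation and its complement
    representation share one context class.
    """
    codes = encode_bases(seq)
    n = len(codes)
    out = np.full(n, -1, dtype=np.int64)
    if n < 5:
        return out
    window = np.lib.stride_tricks.sliding_window_view(codes, 5)
    valid = (window < 4).all(axis=1)
    pow4 = 4 ** np.arange(4, -1, -1, dtype=np.int64)
    fwd = window.astype(np.int64) @ pow4
    rev = (3 - window[:, ::-1].astype(np.int64)) @ pow4
    center = window[:, 2]
    # center C(1)/T(3): forward read; center A(0)/G(2): reverse complement
    norm = np.where((center == 1) | (center == 3), fwd, rev)
    out[2:n - 2] = np.where(valid, norm, -1)
    return out


def tri_codes(seq: str) -> np.ndarray:
    """Same as :func:`penta_codes` for the +/-1 bp trinucleotide context."""
    codes = encode_bases(seq)
    n = len(codes)
    out = np.full(n, -1, dtype=np.int64)
    if n < 3:
        return out
    window = np.lib.stride_tricks.sliding_window_view(codes, 3)
    valid = (window < 4).all(axis=1)
    pow4 = 4 ** np.arange(2, -1, -1, dtype=np.int64)
    fwd = window.astype(np.int64) @ pow4
    rev = (3 - window[:, ::-1].astype(np.int64)) @ pow4
    center = window[:, 1]
    norm = np.where((center == 1) | (center == 3), fwd, rev)
    out[1:n - 1] = np.where(valid, norm, -1)
    return out


def interval_mask(length: int, intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    """Boolean occupancy array for a set of [start, end) intervals."""
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[max(0, s):min(length, e)] = True
    return mask
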