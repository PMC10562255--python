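"""Strand normalization, APOBEC motif classification and SBS96 catalogs.

Every single-base substitution is represented in pyrimidine notation: if
the reference base is a purine, both alleles are complemented and the
sequence context is read 5'->3' from the reverse strand. Motif names
(TCW, RTCA, YTCA, ...) always refer to the strand carrying the mutated
pyrimidine; W = A/T, R = A/G, Y = C/T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from ._reference import ReferenceGenome, revcomp
from .catalog_io import MutationRecord

PYRIMIDINES = {"C", "T"}
PURINES = {"A", "G"}

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
FLANKS = ("A", "C", "G", "T")

#: Canonical SBS96 channel order: substitution-major, then 5' and 3' flank.
SBS96_CHANNELS = tuple(
    f"{f5}[{sub}]{f3}"
    for sub in SUBSTITUTIONS for f5 in FLANKS for f3 in FLANKS
)
_CHANNEL_INDEX = {ch: i for i, ch in enumerate(SBS96_CHANNELS)}


@dataclass(frozen=True)
class PyrimidineContext:
    """Strand-normalized +/-2 bp context of one SBS.

    ``penta`` is the 5-mer centered on the mutated pyrimidine, read
    5'->3' on ``pyr_strand``; ``tetra`` drops the 3'-most base (one extra
    5' base plus the trinucleotide); ``tri`` is the central 3-mer.
    """

    chrom: str
    pos: int  # 1-based, as in the source record
    ref_pyr: str
    alt_pyr: str
    pyr_strand: str
    penta: str

    def __post_init__(self):
        assert self.ref_pyr in PYRIMIDINES
        assert self.penta[2] == self.ref_pyr

    @property
    def tri(self) -> str:
        return self.penta[1:4]

    @property
    def tetra(self) -> str:
        return self.penta[0:4]

    @property
    def channel(self) -> str:
        return f"{self.tri[0]}[{self.ref_pyr}>{self.alt_pyr}]{self.tri[2]}"

    @property
    def is_c_mutation(self) -> bool:
        return self.ref_pyr == "C"

    @property
    def is_apobec_class(self) -> bool:
        """C>T or C>G at a cytosine (the APOBEC deamination outcomes)."""
        return self.ref_pyr == "C" and self.alt_pyr in ("T", "G")


@dataclass
class MotifFlags:
    is_TC: bool
    is_TCW: bool
    is_RTCA: bool
    is_YTCA: bool
    is_RTCW: bool
    is_YTCW: bool


@dataclass
class MotifCounts:
    """Mutation counts (m_*) and context availability counts (c_*).

    Availability is counted on both strands: a TCA on the reverse strand
    appears as TGA on the forward strand and is still a target.
    """

    m_C: int = 0
    m_TCW: int = 0
    m_RTCA: int = 0
    m_YTCA: int = 0
    c_C: int = 0
    c_TCW: int = 0
    c_RTCA: int = 0
    c_YTCA: int = 0

    def __add__(self, other: "MotifCounts") -> "MotifCounts":
        return MotifCounts(*(a + b for a, b in
                             zip(self._astuple(), other._astuple())))

    def _astuple(self):
        return (self.m_C, self.m_TCW, self.m_RTCA, self.m_YTCA,
                self.c_C, self.c_TCW, self.c_RTCA, self.c_YTCA)


def pyrimidine_normalize(mutation: MutationRecord,
                         reference: ReferenceGenome) -> Optional[PyrimidineContext]:
    """Pyrimidine-strand context of an SBS, or None if it cannot be built.

    Mutations whose +/-2 bp window leaves the chromosome or contains an
    ambiguous base are skipped with a warning (callers count skips via
    the None return).
    """
    if not mutation.is_sbs:
        raise ValueError("pyrimidine_normalize requires an SBS record")
    i = mutation.pos - 1
    if i - 2 < 0 or i + 3 > reference.length(mutation.chrom):
        warnings.warn(f"SBS at {mutation.chrom}:{mutation.pos} too close to "
                      "chromosome end; skipped")
        return None
    penta = reference.fetch(mutation.chrom, i - 2, i + 3)
    if any(b not in "ACGT" for b in penta):
        warnings.warn(f"ambiguous base near {mutation.chrom}:{mutation.pos}; skipped")
        return None
    if penta[2] != mutation.ref:
        raise ValueError(f"ref mismatch at {mutation.chrom}:{mutation.pos}")
    if mutation.ref in PYRIMIDINES:
        return PyrimidineContext(mutation.chrom, mutation.pos,
                                 mutation.ref, mutation.alt, "+", penta)
    return PyrimidineContext(mutation.chrom, mutation.pos,
                             revcomp(mutation.ref), revcomp(mutation.alt),
                             "-", revcomp(penta))


def classify_motif(ctx: PyrimidineContext) -> MotifFlags:
    """APOBEC motif membership flags of a pyrimidine context."""
    tri, tetra = ctx.tri, ctx.tetra
    is_tc = ctx.ref_pyr == "C" and tri[0] == "T"
    is_tcw = is_tc and tri[2] in "AT"
    return MotifFlags(
        is_TC=is_tc,
        is_TCW=is_tcw,
        is_RTCA=is_tc and tetra[0] in "AG" and tri[2] == "A",
        is_YTCA=is_tc and tetra[0] in "CT" and tri[2] == "A",
        is_RTCW=is_tcw and tetra[0] in "AG",
        is_YTCW=is_tcw and tetra[0] in "CT",
    )


def _count_window(seq: str) -> MotifCounts:
    """Availability counts over one sequence window (both strands)."""
    c_c = seq.count("C") + seq.count("G")
    counts = MotifCounts(c_C=c_c)
    rc = revcomp(seq)
    for s in (seq, rc):
        for j in range(len(s) - 2):
            if s[j:j + 2] == "TC" and s[j + 2] in "AT":
                counts.c_TCW += 1
            if j + 4 <= len(s) and s[j + 1:j + 3] == "TC" and s[j + 3] == "A":
                if s[j] in "AG":
                    counts.c_RTCA += 1
                elif s[j] in "CT":
                    counts.c_YTCA += 1
    return counts


def count_motifs_window(reference: ReferenceGenome, chrom: str, pos: int,
                        halfwidth: int = 20) -> MotifCounts:
    """Motif availability within +/-halfwidth bp of a 1-based position.

    Windows straddling chromosome ends are clipped; N bases never
    contribute. Motifs are counted on both strands, each read 5'->3' on
    its own strand.
    """
    i = pos - 1
    seq = reference.fetch(chrom, i - halfwidth, i + halfwidth + 1)
    seq = seq.replace("N", "X")  # X matches nothing in the scanners
    return _count_window(seq)


def motif_counts(contexts: Iterable[PyrimidineContext],
                 reference: ReferenceGenome,
                 halfwidth: int = 20) -> MotifCounts:
    """Pooled mutation and availability counts over C>T/C>G mutations.

    Only cytosine mutations with APOBEC-class outcomes (C>T, C>G) enter
    the m_* counts; availability windows are summed over exactly those
    mutations, per the local-context normalization of the enrichment
    score.
    """
    total = MotifCounts()
    for ctx in contexts:
        if not ctx.is_apobec_class:
            continue
        flags = classify_motif(ctx)
        total.m_C += 1
        total.m_TCW += flags.is_TCW
        total.m_RTCA += flags.is_RTCA
        total.m_YTCA += flags.is_YTCA
        total = total + count_motifs_window(reference, ctx.chrom, ctx.pos,
                                            halfwidth)
    return total


def build_sbs96(mutations: Sequence[MutationRecord],
                reference: ReferenceGenome) -> pd.DataFrame:
    """Per-sample SBS96 catalog (samples x 96 channels).

    Records that cannot be normalized (chromosome-end windows, ambiguous
    bases) are excluded; the number of skipped records is stored in
    ``df.attrs["skipped"]``. Channel sums therefore equal the number of
    successfully normalized SBS per sample.
    """
    samples = sorted({m.sample_id for m in mutations})
    mat = pd.DataFrame(0, index=samples, columns=list(SBS96_CHANNELS))
    skipped = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for m in mutations:
            if not m.is_sbs:
                continue
            ctx = pyrimidine_normalize(m, reference)
            if ctx is None:
                skipped += 1
                continue
            mat.loc[m.sample_id, ctx.channel] += 1
    mat.attrs["skipped"] = skipped
    return mat


def contexts_by_sample(mutations: Sequence[MutationRecord],
                       reference: ReferenceGenome
                       ) -> dict[str, list[PyrimidineContext]]:
    """Normalize all SBS records, grouped by sample; skips are silent here."""
    out: dict[str, list[PyrimidineContext]] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for m in mutations:
            if not m.is_sbs:
                continue
            ctx = pyrimidine_normalize(m, reference)
            if ctx is not None:
                out.setdefault(m.sample_id, []).append(ctx)
    return out
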