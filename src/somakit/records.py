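"""Core in-memory records shared by every analysis stage.

Coordinates are 1-based inclusive everywhere inside the package; BED/BEDPE
half-open 0-based coordinates are converted at the I/O boundary.  Chromosome
names are stored without a ``chr`` prefix; writers can re-add it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

SV_CLASSES = ("deletion", "tandem_duplication", "inversion", "translocation",
              "unclassified")


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix; ``chrM``-style names keep the rest."""
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


@dataclass(frozen=True)
class SnvRecord:
    """One somatic single-nucleotide substitution.

    ``context`` is the reference trinucleotide centred on the mutated base
    (upper case); its middle base must equal ``ref``.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    context: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be single bases, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if len(self.context) != 3 or self.context[1] != self.ref:
            raise ValueError(
                f"context {self.context!r} must be a 3-mer centred on ref {self.ref!r}")


@dataclass
class SvRecord:
    """One somatic rearrangement as a pair of stranded breakends.

    Breakends are canonically ordered: intrachromosomal records satisfy
    ``pos1 <= pos2``; interchromosomal records have ``chrom1 < chrom2`` under a
    natural chromosome ordering.  Strand encodes read-pair orientation: ``+``
    means the joined segment ends at the breakend coming from lower
    coordinates.  Under this convention (+,-) is a deletion-type junction,
    (-,+) a tandem duplication, (+,+)/(-,-) an inversion.
    """

    sample_id: str
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    support_reads: int = 0
    control_reads: int = 0
    vaf: float = 0.0
    overhang: int = 0
    control_depth: int = 0
    in_repeat: bool = False
    sv_class: str = "unclassified"
    caller_ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.strand1 not in "+-" or self.strand2 not in "+-":
            raise ValueError(f"strands must be '+' or '-', got "
                             f"{self.strand1!r}/{self.strand2!r}")
        if self.sv_class not in SV_CLASSES:
            raise ValueError(f"unknown sv_class {self.sv_class!r}")
        if not isinstance(self.caller_ids, frozenset):
            self.caller_ids = frozenset(self.caller_ids)

    @property
    def is_intrachromosomal(self) -> bool:
        return self.chrom1 == self.chrom2

    @property
    def span(self) -> int | None:
        """Breakend separation for intrachromosomal records, else None."""
        return self.pos2 - self.pos1 if self.is_intrachromosomal else None

    def canonical(self) -> "SvRecord":
        """Return a breakend-ordered copy (swap keeps per-breakend strands)."""
        if self.is_intrachromosomal:
            swap = self.pos2 < self.pos1
        else:
            swap = chrom_sort_key(self.chrom2) < chrom_sort_key(self.chrom1)
        if not swap:
            return self
        return replace(self, chrom1=self.chrom2, pos1=self.pos2, strand1=self.strand2,
                       chrom2=self.chrom1, pos2=self.pos1, strand2=self.strand1)


@dataclass(frozen=True)
class CnSegment:
    """One copy-number segment (1-based inclusive)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: float
    log2_ratio: float

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.copy_number < 0:
            raise ValueError("copy_number must be nonnegative")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneInterval:
    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")


def chrom_sort_key(chrom: str):
    """Natural ordering: numeric chromosomes first, then X, Y, MT, others."""
    c = normalize_chrom(chrom)
    if c.isdigit():
        return (0, int(c), "")
    order = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if c.upper() in order:
        return (0, order[c.upper()], "")
    return (1, 0, c)


def sv_sort_key(r: SvRecord):
    return (r.sample_id, chrom_sort_key(r.chrom1), r.pos1,
            chrom_sort_key(r.chrom2), r.pos2, r.strand1, r.strand2)
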