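"""Alu-consensus primers: naming convention, orientation, derivation.

A convention primer name is ``<family><start><H|T><length>``, e.g.
``AluY278T18``: an 18-mer whose first paired base is position 278 (1-based)
of the AluY consensus, oriented as a Tail-type primer.  T-type primers read
the consensus in sense orientation, so their 3' extension proceeds toward
and beyond the element's poly-A tail; H-type primers are the reverse
complement of their consensus window, extending out of the head.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Tuple

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NAME_RE = re.compile(r"^([A-Za-z]+)(\d+)([HT])(\d+)$")
_SEQ_RE = re.compile(r"^[ACGTN]*$")


def revcomp(sequence: str) -> str:
    """Reverse complement of an A/C/G/T/N string (N maps to N)."""
    if not _SEQ_RE.match(sequence):
        raise ValueError(f"invalid base in sequence {sequence!r}")
    return sequence.translate(_COMPLEMENT)[::-1]


def parse_primer_name(name: str) -> Tuple[str, int, str, int]:
    """Split a convention name into (family, consensus_start, ptype, length)."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(
            f"{name!r} does not follow the <family><start><H|T><length> convention"
        )
    family, start, ptype, length = m.groups()
    return family, int(start), ptype, int(length)


def format_primer_name(family: str, consensus_start: int, ptype: str, length: int) -> str:
    return f"{family}{consensus_start}{ptype}{length}"


@dataclass(frozen=True)
class Primer:
    """An inter-Alu PCR primer.

    Convention primers carry their family and consensus offset; legacy or
    explicit-sequence primers carry only a declared ptype and sequence.
    """

    name: str
    ptype: str
    sequence: str
    family: Optional[str] = None
    consensus_start: Optional[int] = None

    def __post_init__(self):
        if self.ptype not in ("H", "T"):
            raise ValueError(f"ptype must be H or T, got {self.ptype!r}")
        if not _SEQ_RE.match(self.sequence) or not self.sequence:
            raise ValueError(f"invalid primer sequence {self.sequence!r}")
        if self.consensus_start is not None and self.consensus_start < 1:
            raise ValueError("consensus_start is 1-based and must be >= 1")

    @property
    def length(self) -> int:
        return len(self.sequence)


class ConsensusRegistry:
    """Subfamily name -> consensus sequence mapping, loaded from FASTA."""

    def __init__(self, sequences: Dict[str, str]):
        for name, seq in sequences.items():
            if not seq:
                raise ValueError(f"empty consensus for {name}")
        self._sequences = {k: v.upper() for k, v in sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "ConsensusRegistry":
        sequences = {}
        for record in SeqIO.parse(str(path), "fasta"):
            key = record.id.split()[0]
            if key in sequences:
                raise ValueError(f"duplicate consensus name {key}")
            sequences[key] = str(record.seq).upper()
        if not sequences:
            raise ValueError(f"no sequences in {path}")
        return cls(sequences)

    @classmethod
    def bundled(cls) -> "ConsensusRegistry":
        """The packaged synthetic Alu-family consensus.

        This is a synthetic stand-in, not a published consensus: an Alu-like
        311-bp sequence constructed so the documented AluY primer windows sit
        at their named offsets (position 66, H, 21 nt; position 278, T, 18 nt).
        Supply your own registry via from_fasta for real-genome work.
        """
        path = resources.files("interalu").joinpath("data/alu_consensus_synthetic.fa")
        with resources.as_file(path) as p:
            return cls.from_fasta(p)

    def __getitem__(self, family: str) -> str:
        try:
            return self._sequences[family]
        except KeyError:
            raise KeyError(f"no consensus registered for family {family!r}") from None

    def __contains__(self, family: str) -> bool:
        return family in self._sequences

    def families(self) -> List[str]:
        return sorted(self._sequences)


def derive_primer_sequence(
    registry: ConsensusRegistry,
    family: str,
    consensus_start: int,
    ptype: str,
    length: int,
) -> str:
    """Extract a primer oligo from a subfamily consensus window.

    The window is consensus positions [consensus_start, consensus_start+length-1],
    1-based inclusive.  T-type returns the window as-is (sense); H-type returns
    its reverse complement, so derive(H) == revcomp(derive(T)) on any window.
    """
    consensus = registry[family]
    if consensus_start < 1 or consensus_start + length - 1 > len(consensus):
        raise ValueError(
            f"window {consensus_start}..{consensus_start + length - 1} out of range "
            f"for {family} consensus of length {len(consensus)}"
        )
    window = consensus[consensus_start - 1 : consensus_start - 1 + length]
    if ptype == "T":
        return window
    if ptype == "H":
        return revcomp(window)
    raise ValueError(f"ptype must be H or T, got {ptype!r}")


def primer_from_name(registry: ConsensusRegistry, name: str) -> Primer:
    """Build a Primer from a convention name and a consensus registry."""
    family, start, ptype, length = parse_primer_name(name)
    sequence = derive_primer_sequence(registry, family, start, ptype, length)
    return Primer(
        name=name, ptype=ptype, sequence=sequence, family=family, consensus_start=start
    )


def read_primer_tsv(path) -> List[Primer]:
    """Read explicit-sequence primers from TSV columns (name, ptype, sequence)."""
    primers = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("name\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: need 3 columns at line {lineno}")
            name, ptype, seq = fields[0], fields[1], fields[2].upper()
            start = family = None
            m = _NAME_RE.match(name)
            if m:
                family, start = m.group(1), int(m.group(2))
            primers.append(
                Primer(name=name, ptype=ptype, sequence=seq,
                       family=family, consensus_start=start)
            )
    return primers
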