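"""Reference models: host genomes, vector models, hybrid and validation references.

A *hybrid reference* concatenates a host assembly with the vector genome so
that a single aligner pass over it reveals chimeric (vector-host) reads.  A
*validation reference* is a single synthetic chromosome with the vector
cassette inserted at a candidate junction, flanked by host sequence, used to
re-align supporting reads locally around one event.

Coordinates are 0-based half-open internally; every user-facing coordinate in
reports is 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import validate_dna

Interval = tuple[int, int]


@dataclass
class Genome:
    """An ordered collection of named uppercase DNA sequences.

    Parameters
    ----------
    sequences : dict[str, str]
        Ordered mapping of sequence name to DNA string (A/C/G/T/N only).
    source_label : str
        Free-text provenance label.
    """

    sequences: dict[str, str]
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("genome must contain at least one sequence")
        clean: dict[str, str] = {}
        for name, seq in self.sequences.items():
            if not name:
                raise ValueError("sequence names must be non-empty")
            seq = seq.upper()
            validate_dna(seq, name=f"sequence {name!r}")
            clean[name] = seq
        self.sequences = clean

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def to_fasta(self, path: str) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences.items()
        ]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def from_fasta(cls, path: str, source_label: str = "") -> "Genome":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
        return cls(seqs, source_label=source_label or str(path))


@dataclass
class VectorModel:
    """A vector genome with its ITR intervals and internal feature annotation.

    ``itr_intervals`` holds zero or exactly two half-open 0-based intervals,
    one at each end of the sequence; ``features`` are (label, interval) pairs
    for interior elements (promoter, transgene, WPRE analogs).
    """

    name: str
    sequence: str
    itr_intervals: tuple[Interval, ...] = ()
    features: list[tuple[str, Interval]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("vector name must be non-empty")
        self.sequence = self.sequence.upper()
        validate_dna(self.sequence, name=f"vector {self.name!r}")
        n = len(self.sequence)
        if self.itr_intervals:
            if len(self.itr_intervals) != 2:
                raise ValueError("expected exactly two ITR intervals (or none)")
            (a0, a1), (b0, b1) = self.itr_intervals
            if not (0 <= a0 < a1 <= n and 0 <= b0 < b1 <= n):
                raise ValueError("ITR intervals out of vector bounds")
            if a1 > b0:
                raise ValueError("ITR intervals must not overlap")
            if a0 != 0 or b1 != n:
                raise ValueError("ITR intervals must sit at the vector ends")
        for label, (s, e) in self.features:
            if not (0 <= s < e <= n):
                raise ValueError(f"feature {label!r} interval out of bounds")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class HybridReference:
    """A genome whose sequences are partitioned into host and vector names."""

    genome: Genome
    vector_names: frozenset[str]

    def __post_init__(self) -> None:
        self.vector_names = frozenset(self.vector_names)
        names = set(self.genome.sequences)
        if not self.vector_names <= names:
            raise ValueError("vector_names must be a subset of genome names")
        if not self.vector_names or self.vector_names == names:
            raise ValueError("need at least one host and one vector sequence")

    def is_vector(self, name: str) -> bool:
        return name in self.vector_names

    @property
    def host_names(self) -> list[str]:
        return [n for n in self.genome.sequences if n not in self.vector_names]


def build_hybrid_reference(host: Genome, vector: VectorModel) -> HybridReference:
    """Concatenate host assembly and vector genome into one alignment target.

    Host sequences come first (in their original order), then the vector.
    Raises ``ValueError`` on a name collision between vector and host.
    """
    if vector.name in host.sequences:
        raise ValueError(
            f"vector name {vector.name!r} collides with a host sequence name"
        )
    seqs = dict(host.sequences)
    seqs[vector.name] = vector.sequence
    genome = Genome(seqs, source_label=f"{host.source_label}+{vector.name}")
    return HybridReference(genome=genome, vector_names=frozenset({vector.name}))


def build_validation_reference(
    host: Genome,
    vector: VectorModel,
    chrom: str,
    pos1: int,
    flank: int = 5000,
    host_deletion: int = 0,
) -> Genome:
    """Host flank + vector cassette + host flank around one candidate junction.

    ``pos1`` is the 1-based host coordinate of the junction: the cassette is
    inserted after the first ``pos1`` bases of ``chrom``.  Flanks are clipped
    at the chromosome ends.  ``host_deletion`` optionally removes that many
    host bases immediately after the insertion point, modelling integrations
    that lose host sequence at the junction.
    """
    if chrom not in host.sequences:
        raise ValueError(f"chromosome {chrom!r} not found in host genome")
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if host_deletion < 0:
        raise ValueError("host_deletion must be >= 0")
    seq = host.sequences[chrom]
    if not (1 <= pos1 <= len(seq)):
        raise ValueError(f"pos1={pos1} out of range for {chrom} (len {len(seq)})")
    p = pos1  # number of retained left-flank host bases before the cassette
    left = seq[max(0, p - flank) : p]
    right = seq[p + host_deletion : p + host_deletion + flank]
    name = f"{chrom}_{pos1}_{vector.name}"
    return Genome(
        {name: left + vector.sequence + right},
        source_label=f"validation {chrom}:{pos1}",
    )


def design_capture_probes(
    target: Interval, probe_len: int = 120, step: int = 40
) -> list[Interval]:
    """Tile a target interval with fixed-length probes at a fixed step.

    Probes start at ``target.start, target.start+step, ...`` and every probe
    lies fully inside the target, so the count is
    ``floor((L - probe_len) / step) + 1`` for target length L.  The defaults
    reproduce a 71-probe panel of 120-nt probes over a 2928-bp cassette.
    """
    start, end = target
    length = end - start
    if step < 1:
        raise ValueError("step must be >= 1")
    if probe_len < 1:
        raise ValueError("probe_len must be >= 1")
    if probe_len > length:
        raise ValueError(
            f"probe_len {probe_len} exceeds target length {length}"
        )
    probes = []
    s = start
    while s + probe_len <= end:
        probes.append((s, s + probe_len))
        s += step
    return probes


def probes_to_bed(
    probes: list[Interval], ref_name: str, path: str, name_prefix: str = "probe"
) -> None:
    """Write probe intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, (s, e) in enumerate(probes, start=1):
            fh.write(f"{ref_name}\t{s}\t{e}\t{name_prefix}_{i:03d}\n")


def probes_to_fasta(
    probes: list[Interval], vector: VectorModel, path: str, name_prefix: str = "probe"
) -> None:
    records = [
        SeqRecord(Seq(vector.sequence[s:e]), id=f"{name_prefix}_{i:03d}", description="")
        for i, (s, e) in enumerate(probes, start=1)
    ]
    SeqIO.write(records, path, "fasta")
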