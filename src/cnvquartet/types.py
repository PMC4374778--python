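"""Core domain objects shared across the toolkit.

A CNV call is reduced to its interval and a gain/loss status: the numeric
copy number emitted by a caller is deliberately discarded, and only whether
the segment sits above or below the diploid state is retained.  Coordinates
are 0-based half-open (BED convention) everywhere.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence


class Status(str, enum.Enum):
    """Copy-number status relative to the diploid reference state."""

    GAIN = "gain"
    LOSS = "loss"

    def __str__(self) -> str:  # serialized form in TSV output
        return self.value


#: status strings accepted on input (case-insensitive), mapped to the enum
STATUS_SYNONYMS = {
    "gain": Status.GAIN,
    "dup": Status.GAIN,
    "duplication": Status.GAIN,
    "loss": Status.LOSS,
    "del": Status.LOSS,
    "deletion": Status.LOSS,
}


@dataclass(frozen=True)
class CNVCall:
    """One gain/loss interval on one sample's genome.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``end > start`` always.
    """

    chrom: str
    start: int
    end: int
    status: Status
    sample_id: str = ""
    source: str = ""
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "end must exceed start"
            )
        if not isinstance(self.status, Status):
            raise TypeError(f"status must be a Status enum, got {self.status!r}")

    def size(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.status.value)


def _canonical_order(call: CNVCall) -> tuple:
    return (call.chrom, call.start, call.end, call.status.value)


@dataclass(frozen=True)
class CallSet:
    """Ordered collection of calls for one sample from one source.

    Calls are kept in canonical (chrom, start, end) order regardless of the
    order they were supplied in.
    """

    calls: tuple[CNVCall, ...]
    sample_id: str = ""
    source: str = ""

    @classmethod
    def from_iter(
        cls, calls: Sequence[CNVCall], sample_id: str = "", source: str = ""
    ) -> "CallSet":
        ordered = tuple(sorted(calls, key=_canonical_order))
        if not sample_id and ordered:
            sample_id = ordered[0].sample_id
        if not source and ordered:
            source = ordered[0].source
        return cls(calls=ordered, sample_id=sample_id, source=source)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[CNVCall]:
        return iter(self.calls)

    def __getitem__(self, i: int) -> CNVCall:
        return self.calls[i]

    def with_calls(self, calls: Sequence[CNVCall]) -> "CallSet":
        return CallSet.from_iter(calls, sample_id=self.sample_id, source=self.source)

    def relabel(self, sample_id: Optional[str] = None, source: Optional[str] = None) -> "CallSet":
        new_calls = tuple(
            replace(
                c,
                sample_id=sample_id if sample_id is not None else c.sample_id,
                source=source if source is not None else c.source,
            )
            for c in self.calls
        )
        return CallSet(
            calls=new_calls,
            sample_id=sample_id if sample_id is not None else self.sample_id,
            source=source if source is not None else self.source,
        )


@dataclass(frozen=True)
class Quartet:
    """One family: a monozygotic twin pair and both parents."""

    family_id: str
    twin1: str
    twin2: str
    parent1: str
    parent2: str

    @property
    def members(self) -> tuple[str, str, str, str]:
        return (self.twin1, self.twin2, self.parent1, self.parent2)

    def __post_init__(self) -> None:
        if len(set(self.members)) != 4:
            raise ValueError(
                f"family {self.family_id}: the four member sample ids must be distinct"
            )


@dataclass(frozen=True)
class Pedigree:
    """Collection of twin quartets with globally unique sample ids."""

    families: tuple[Quartet, ...]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for fam in self.families:
            for s in fam.members:
                if s in seen:
                    raise ValueError(
                        f"sample {s!r} appears in families {seen[s]!r} and "
                        f"{fam.family_id!r}; sample ids must be unique"
                    )
                seen[s] = fam.family_id

    def __len__(self) -> int:
        return len(self.families)

    def __iter__(self) -> Iterator[Quartet]:
        return iter(self.families)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(s for fam in self.families for s in fam.members)

    def family_of(self, sample_id: str) -> Quartet:
        for fam in self.families:
            if sample_id in fam.members:
                return fam
        raise KeyError(sample_id)


@dataclass
class GenomeContext:
    """Reference-genome plumbing needed by statistics and feature annotation.

    ``centromere`` maps chromosome -> (start, end) of the centromeric
    interval; ``sequence`` optionally holds the nucleotide string per
    chromosome (required only for GC content).
    """

    chrom_lengths: dict[str, int]
    centromere: dict[str, tuple[int, int]] = field(default_factory=dict)
    sequence: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, (s, e) in self.centromere.items():
            length = self.chrom_lengths.get(chrom)
            if length is None:
                raise ValueError(f"centromere given for unknown chromosome {chrom!r}")
            if not (0 <= s < e <= length):
                raise ValueError(
                    f"centromere [{s}, {e}) outside chromosome {chrom!r} of length {length}"
                )

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def check_call(self, call: CNVCall) -> None:
        length = self.chrom_lengths.get(call.chrom)
        if length is None:
            raise KeyError(f"chromosome {call.chrom!r} absent from genome context")
        if call.end > length:
            raise ValueError(
                f"call [{call.start}, {call.end}) exceeds length {length} of {call.chrom!r}"
            )
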