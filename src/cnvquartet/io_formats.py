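"""Readers and writers for the plain-text formats the toolkit touches.

Call sets travel as BED-like TSV (chrom, start, end, status, [score]),
pedigrees as a 5-column TSV (family_id, twin1, twin2, parent1, parent2),
centromeres as UCSC cytoBand-style tables (rows with Giemsa stain "acen"),
and reference sequence as FASTA.  All coordinates are 0-based half-open on
disk and in memory; a reader flag converts 1-based inclusive input.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

from Bio import SeqIO

from .types import (
    STATUS_SYNONYMS,
    CallSet,
    CNVCall,
    GenomeContext,
    Pedigree,
    Quartet,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

CALLS_HEADER = ["chrom", "start", "end", "status", "score"]
PEDIGREE_COLUMNS = ["family_id", "twin1", "twin2", "parent1", "parent2"]


class CallParseError(ValueError):
    """A malformed record in a call TSV, carrying its 1-based line number."""

    def __init__(self, path: PathLike, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


def normalize_chrom(chrom: str, strip_chr: bool = True) -> str:
    """Normalize a chromosome name; by default the "chr" prefix is stripped
    so call sets from callers emitting different dialects compare equal."""
    if strip_chr and chrom.lower().startswith("chr"):
        return chrom[3:]
    return chrom


def _parse_status(token: str) -> Optional[object]:
    return STATUS_SYNONYMS.get(token.strip().lower())


def read_calls(
    path: PathLike,
    sample_id: Optional[str] = None,
    source: Optional[str] = None,
    one_based: bool = False,
    strip_chr: bool = True,
) -> CallSet:
    """Read a BED-like CNV call TSV into a canonical-order :class:`CallSet`.

    The file must have >= 4 tab-separated columns (chrom, start, end,
    status); a 5th numeric column is taken as a score.  A header line is
    detected by a non-numeric second column.  ``one_based`` converts 1-based
    inclusive coordinates to the internal 0-based half-open convention.

    Raises :class:`CallParseError` naming the offending line for malformed
    coordinates (non-integer, end <= start) or unknown status strings.
    """
    path = Path(path)
    calls: list[CNVCall] = []
    file_sample, file_source = "", ""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                # provenance comment written by write_calls
                for token in line[1:].strip().split():
                    if token.startswith("sample="):
                        file_sample = token[len("sample="):]
                    elif token.startswith("source="):
                        file_source = token[len("source="):]
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise CallParseError(path, lineno, f"expected >=4 columns, got {len(fields)}")
            # header detection: non-numeric start column
            try:
                start = int(fields[1])
            except ValueError:
                if lineno == 1 or not calls:
                    continue
                raise CallParseError(path, lineno, f"non-integer start {fields[1]!r}")
            try:
                end = int(fields[2])
            except ValueError:
                raise CallParseError(path, lineno, f"non-integer end {fields[2]!r}")
            if one_based:
                start -= 1
            if end <= start:
                raise CallParseError(
                    path, lineno, f"end ({end}) must exceed start ({start})"
                )
            if start < 0:
                raise CallParseError(path, lineno, f"negative start {start}")
            status = _parse_status(fields[3])
            if status is None:
                raise CallParseError(path, lineno, f"unknown status {fields[3]!r}")
            score: Optional[float] = None
            if len(fields) >= 5 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise CallParseError(path, lineno, f"non-numeric score {fields[4]!r}")
            calls.append(
                CNVCall(
                    chrom=normalize_chrom(fields[0], strip_chr=strip_chr),
                    start=start,
                    end=end,
                    status=status,
                    sample_id=sample_id if sample_id is not None else file_sample,
                    source=source if source is not None else file_source,
                    score=score,
                )
            )
    return CallSet.from_iter(
        calls,
        sample_id=sample_id if sample_id is not None else file_sample,
        source=source if source is not None else file_source,
    )


def write_calls(callset: CallSet, path: PathLike) -> None:
    """Write a CallSet as BED-like TSV (0-based half-open).

    The output round-trips through :func:`read_calls` bit-exactly: sample and
    source are recorded in a leading comment, scores in column 5 ("." when
    absent, column present only if any call carries a score).
    """
    path = Path(path)
    has_score = any(c.score is not None for c in callset)
    header = CALLS_HEADER if has_score else CALLS_HEADER[:4]
    with open(path, "w") as fh:
        fh.write(f"# sample={callset.sample_id} source={callset.source}\n")
        fh.write("\t".join(header) + "\n")
        for c in callset:
            row = [c.chrom, str(c.start), str(c.end), str(c.status)]
            if has_score:
                row.append("." if c.score is None else repr(c.score))
            fh.write("\t".join(row) + "\n")


def read_pedigree(path: PathLike) -> Pedigree:
    """Read a 5-column pedigree TSV (family_id, twin1, twin2, parent1,
    parent2).  A header row naming the columns is optional."""
    path = Path(path)
    families: list[Quartet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(
                    f"{path}:{lineno}: pedigree needs 5 columns "
                    f"({', '.join(PEDIGREE_COLUMNS)}), got {len(fields)}"
                )
            if fields[0].strip().lower() == "family_id":
                continue
            families.append(Quartet(*[f.strip() for f in fields[:5]]))
    return Pedigree(families=tuple(families))


def write_pedigree(pedigree: Pedigree, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PEDIGREE_COLUMNS) + "\n")
        for fam in pedigree:
            fh.write(
                "\t".join([fam.family_id, fam.twin1, fam.twin2, fam.parent1, fam.parent2])
                + "\n"
            )


def read_cytoband(path: PathLike, strip_chr: bool = True) -> dict[str, tuple[int, int]]:
    """Extract centromere intervals from a UCSC cytoBand-style TSV.

    Rows whose stain column is "acen" flank the centromere; the returned
    interval per chromosome spans from the first acen start to the last acen
    end.
    """
    acen: dict[str, list[int]] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5 or fields[4].strip() != "acen":
                continue
            chrom = normalize_chrom(fields[0], strip_chr=strip_chr)
            start, end = int(fields[1]), int(fields[2])
            if chrom in acen:
                acen[chrom][0] = min(acen[chrom][0], start)
                acen[chrom][1] = max(acen[chrom][1], end)
            else:
                acen[chrom] = [start, end]
    return {c: (s, e) for c, (s, e) in acen.items()}


def read_fasta(path: PathLike, strip_chr: bool = True) -> dict[str, str]:
    """Read a FASTA reference into an uppercase per-chromosome string dict."""
    return {
        normalize_chrom(rec.id, strip_chr=strip_chr): str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


def genome_context_from_files(
    fasta: Optional[PathLike] = None,
    cytoband: Optional[PathLike] = None,
    chrom_lengths: Optional[dict[str, int]] = None,
    strip_chr: bool = True,
) -> GenomeContext:
    """Assemble a :class:`GenomeContext` from a FASTA and/or cytoband table.

    Chromosome lengths come from explicit ``chrom_lengths`` or, failing that,
    from the FASTA sequence lengths.
    """
    sequence = read_fasta(fasta, strip_chr=strip_chr) if fasta else {}
    if chrom_lengths is None:
        if not sequence:
            raise ValueError("either chrom_lengths or a FASTA is required")
        chrom_lengths = {c: len(s) for c, s in sequence.items()}
    centromere = read_cytoband(cytoband, strip_chr=strip_chr) if cytoband else {}
    centromere = {c: iv for c, iv in centromere.items() if c in chrom_lengths}
    return GenomeContext(
        chrom_lengths=dict(chrom_lengths), centromere=centromere, sequence=sequence
    )


def drop_unknown_chromosomes(callset: CallSet, context: GenomeContext) -> CallSet:
    """Drop calls on chromosomes absent from the genome context, warning once
    per chromosome."""
    known = context.chrom_lengths
    kept, dropped = [], set()
    for c in callset:
        if c.chrom in known:
            kept.append(c)
        else:
            dropped.add(c.chrom)
    for chrom in sorted(dropped):
        logger.warning(
            "dropping calls on chromosome %r absent from genome context", chrom
        )
    return callset.with_calls(kept)
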