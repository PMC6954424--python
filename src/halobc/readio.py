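"""FASTQ parsing, barcode-region extraction, demultiplexing and filtering.

Sequencing reads 76 bp of the amplicon, which contain the 38-bp
identifier+tag region.  Each read is reduced to a :class:`TagObservation`:
which protein the 8-bp identifier names (Hamming match against the
identifier table, unambiguous best within ``max_mismatch``), the 30-bp
counting tag, and how many of the tag's 6 fixed bases mismatch.  Reads
with any mismatched fixed base are excluded from molecule counting.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .schema import BarcodeSchema, ProteinIdentifier, hamming

__all__ = [
    "UNASSIGNED",
    "ReadRecord",
    "TagObservation",
    "read_fastq",
    "extract_region",
    "assign_protein",
    "check_fixed_bases",
    "observe_read",
    "iter_observations",
    "observations_to_frame",
    "write_observations",
]

#: label used for reads not attributable to any identifier
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read (qualities optional, unused for filtering)."""

    read_id: str
    sequence: str
    qualities: str | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: sequence/quality length mismatch"
            )


@dataclass(frozen=True)
class TagObservation:
    """One read reduced to its barcode content.

    ``protein`` is ``None`` for unassigned reads.  ``passed_filter`` is
    true exactly when the read was assigned to a protein and its counting
    tag carries zero fixed-base mismatches.
    """

    read_id: str
    protein: ProteinIdentifier | None
    id_mismatches: int
    counting_tag: str
    fixed_mismatches: int
    passed_filter: bool
    fail_reason: str | None = None

    @property
    def protein_name(self) -> str:
        return self.protein.protein_name if self.protein is not None else UNASSIGNED


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream :class:`ReadRecord` from a FASTQ file (plain or gzip).

    A malformed record raises ``ValueError`` naming the 1-based index of
    the offending record.
    """
    with _open_text(path) as fh:
        it = FastqGeneralIterator(fh)
        i = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as e:
                raise ValueError(
                    f"malformed FASTQ at record {i + 1} in {path}: {e}"
                ) from e
            i += 1
            yield ReadRecord(read_id=title.split()[0], sequence=seq, qualities=qual)


def extract_region(read: ReadRecord, schema: BarcodeSchema) -> str | None:
    """Return the identifier+tag region of a read, or None if the read is short."""
    start = schema.read_offset
    end = start + schema.region_length
    if len(read.sequence) < end:
        return None
    return read.sequence[start:end]


def assign_protein(
    region: str, schema: BarcodeSchema, max_mismatch: int = 1
) -> tuple[ProteinIdentifier | None, int]:
    """Match the identifier segment of a region against the identifier table.

    Returns the unique identifier within Hamming distance ``max_mismatch``
    of the first ``id_length`` bases, with the distance; ``(None, d)`` when
    no identifier is close enough or two tie at the minimum distance.
    With ``max_mismatch=0`` this is exact dictionary lookup.
    """
    seg = region[: schema.id_length]
    exact = schema.identifier_by_tag.get(seg)
    if exact is not None:
        return exact, 0
    if max_mismatch == 0:
        return None, -1
    best: ProteinIdentifier | None = None
    best_d = max_mismatch + 1
    tie = False
    for ident in schema.identifiers:
        d = hamming(seg, ident.tag)
        if d < best_d:
            best, best_d, tie = ident, d, False
        elif d == best_d:
            tie = True
    if best is None or tie or best_d > max_mismatch:
        return None, best_d if best_d <= max_mismatch + 1 else -1
    return best, best_d


def check_fixed_bases(region: str, schema: BarcodeSchema) -> tuple[str, int]:
    """Split off the counting tag and count its fixed-base mismatches."""
    tag = region[schema.id_length : schema.region_length]
    return tag, schema.counting_pattern.count_fixed_mismatches(tag)


def observe_read(
    read: ReadRecord, schema: BarcodeSchema, max_mismatch: int = 1
) -> TagObservation:
    """Reduce one read to a :class:`TagObservation`."""
    region = extract_region(read, schema)
    if region is None:
        return TagObservation(
            read_id=read.read_id,
            protein=None,
            id_mismatches=-1,
            counting_tag="",
            fixed_mismatches=schema.counting_pattern.n_fixed,
            passed_filter=False,
            fail_reason="short_read",
        )
    ident, mism = assign_protein(region, schema, max_mismatch)
    tag, fixed_mm = check_fixed_bases(region, schema)
    passed = ident is not None and fixed_mm == 0
    reason = None
    if ident is None:
        reason = "unassigned_identifier"
    elif fixed_mm:
        reason = "fixed_base_mismatch"
    return TagObservation(
        read_id=read.read_id,
        protein=ident,
        id_mismatches=mism,
        counting_tag=tag,
        fixed_mismatches=fixed_mm,
        passed_filter=passed,
        fail_reason=reason,
    )


def iter_observations(
    reads: Iterable[ReadRecord], schema: BarcodeSchema, max_mismatch: int = 1
) -> Iterator[TagObservation]:
    for read in reads:
        yield observe_read(read, schema, max_mismatch)


def observations_to_frame(observations: Iterable[TagObservation]) -> pd.DataFrame:
    """Tabulate observations (protein column holds names; UNASSIGNED sentinel)."""
    rows = [
        (
            o.read_id,
            o.protein_name,
            o.id_mismatches,
            o.counting_tag,
            o.fixed_mismatches,
            o.passed_filter,
            o.fail_reason or "",
        )
        for o in observations
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "protein",
            "id_mismatches",
            "counting_tag",
            "fixed_mismatches",
            "passed_filter",
            "fail_reason",
        ],
    )


def write_observations(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)
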