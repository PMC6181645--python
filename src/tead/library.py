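"""Consensus TE reference library: records, loading, validation, clade partition.

A library is an ordered collection of consensus retrotransposon sequences
(Repbase-style), each annotated with a class (``LTR`` or ``non-LTR``) and a
clade label (L1, SINE, ERV1, ERV2, ERV3, Gypsy, Copia, ...).  Annotations
travel either embedded in the FASTA header as colon-separated
``id:clade:class`` fields, or in a sidecar TSV with columns
``te_id``, ``clade``, ``class``; the TSV takes precedence when both are given.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections import Counter
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_CLASSES = frozenset({"LTR", "non-LTR"})
_VALID_BASES = frozenset("ACGTN")


class LibraryError(ValueError):
    """Raised for structural problems in a TE library (duplicate ids, bad bases)."""


@dataclass(frozen=True)
class TERecord:
    """One consensus TE sequence with its class and clade annotation."""

    te_id: str
    sequence: str
    te_class: str
    clade: str

    def __post_init__(self) -> None:
        if not self.te_id:
            raise LibraryError("te_id must be non-empty")
        if not self.sequence:
            raise LibraryError(f"record {self.te_id!r}: sequence must be non-empty")
        if not self.clade:
            raise LibraryError(f"record {self.te_id!r}: clade must be non-empty")
        if self.te_class not in VALID_CLASSES:
            raise LibraryError(
                f"record {self.te_id!r}: class {self.te_class!r} "
                f"not one of {sorted(VALID_CLASSES)}"
            )
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise LibraryError(
                f"record {self.te_id!r}: non-nucleotide characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TELibrary:
    """Ordered collection of :class:`TERecord` with unique ids."""

    records: list[TERecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.te_id in seen:
                raise LibraryError(f"duplicate te_id {rec.te_id!r} in library")
            seen.add(rec.te_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, te_id: str) -> TERecord:
        for rec in self.records:
            if rec.te_id == te_id:
                return rec
        raise KeyError(te_id)

    @property
    def te_ids(self) -> list[str]:
        return [rec.te_id for rec in self.records]

    def class_counts(self) -> dict[str, int]:
        """Tally of records per class; values sum to ``len(self)``."""
        return dict(Counter(rec.te_class for rec in self.records))

    def lengths(self) -> dict[str, int]:
        return {rec.te_id: len(rec) for rec in self.records}


def _parse_header(header: str) -> tuple[str, str | None, str | None]:
    """Split a FASTA id of the form ``id:clade:class`` (annotation optional)."""
    parts = header.split(":")
    if len(parts) >= 3:
        return parts[0], parts[1], ":".join(parts[2:])
    return header, None, None


def load_library(
    fasta_path: str | Path,
    annotation_path: str | Path | None = None,
    strict: bool = True,
) -> TELibrary:
    """Read a consensus TE library from FASTA, with annotations.

    Parameters
    ----------
    fasta_path
        Multi-record FASTA; any line wrapping. Sequences are uppercased on
        load; characters outside ``{A,C,G,T,N}`` are a hard error naming the
        record (silent coercion would corrupt downstream k-mer indexing).
    annotation_path
        Optional TSV with columns ``te_id``, ``clade``, ``class``; overrides
        header-embedded annotation.
    strict
        If True (default), records lacking a (clade, class) annotation are a
        hard error; if False they are dropped with a logged count.
    """
    ann: dict[str, tuple[str, str]] = {}
    if annotation_path is not None:
        tab = pd.read_csv(annotation_path, sep="\t", dtype=str)
        required = {"te_id", "clade", "class"}
        if not required.issubset(tab.columns):
            raise LibraryError(
                f"annotation TSV must have columns {sorted(required)}, "
                f"got {list(tab.columns)}"
            )
        ann = {
            row["te_id"]: (row["clade"], row["class"]) for _, row in tab.iterrows()
        }

    records: list[TERecord] = []
    seen: set[str] = set()
    n_dropped = 0
    for seq_rec in SeqIO.parse(str(fasta_path), "fasta"):
        te_id, clade, te_class = _parse_header(seq_rec.id)
        if te_id in ann:
            clade, te_class = ann[te_id]
        if clade is None or te_class is None:
            if strict:
                raise LibraryError(f"record {te_id!r} lacks clade/class annotation")
            n_dropped += 1
            continue
        if te_id in seen:
            raise LibraryError(f"duplicate te_id {te_id!r} in {fasta_path}")
        seen.add(te_id)
        records.append(
            TERecord(
                te_id=te_id,
                sequence=str(seq_rec.seq).upper(),
                te_class=te_class,
                clade=clade,
            )
        )
    if n_dropped:
        logger.warning("dropped %d unannotated records (lenient mode)", n_dropped)
    return TELibrary(records)


def write_library(library: TELibrary, fasta_path: str | Path) -> None:
    """Write a library as FASTA with ``id:clade:class`` headers.

    Round-trips with :func:`load_library` modulo line wrapping.
    """
    recs = [
        SeqRecord(
            Seq(rec.sequence),
            id=f"{rec.te_id}:{rec.clade}:{rec.te_class}",
            description="",
        )
        for rec in library
    ]
    SeqIO.write(recs, str(fasta_path), "fasta")


def write_annotations(library: TELibrary, tsv_path: str | Path) -> None:
    """Write the sidecar annotation TSV (te_id, clade, class)."""
    pd.DataFrame(
        {
            "te_id": [r.te_id for r in library],
            "clade": [r.clade for r in library],
            "class": [r.te_class for r in library],
        }
    ).to_csv(tsv_path, sep="\t", index=False)


def clade_map(library: TELibrary) -> dict[str, set[str]]:
    """Partition the library's te_ids by clade.

    Every te_id lands in exactly one clade set; the union of the sets is the
    library's full id set.
    """
    out: dict[str, set[str]] = {}
    for rec in library:
        out.setdefault(rec.clade, set()).add(rec.te_id)
    return out
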