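"""Reading, validating and framing coding sequences and their annotations.

The unit of analysis is one protein's coding (mRNA/CDS) sequence together
with its structural class (all-α / all-β / α-β), kinetic class (two-state /
multistate folder) and the natural log of its experimental folding rate,
ln(kf).  Sequences are normalized to the RNA alphabet {A,C,G,U}; lengths
must be codon multiples so the three codon-position subsequences are well
defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AmbiguousBaseError,
    EmptyDatasetError,
    FramingError,
    JoinError,
    LabelError,
    MrnaLangError,
    SegmentRangeError,
)

BASES = ("A", "C", "G", "U")

#: Canonical column order of the per-protein parameter table (full-sequence
#: statistics first, then codon positions 1..3).
PARAMETER_COLUMNS = (
    "CGC", "D1", "D2",
    "CGC1", "D11", "D21",
    "CGC2", "D12", "D22",
    "CGC3", "D13", "D23",
)

ANNOTATION_COLUMNS = ("id", "structural_class", "kinetic_class", "ln_kf")

_NORMALIZE = str.maketrans("acgutT", "ACGUUU")
_STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})


class StructuralClass(str, Enum):
    """Secondary-structure content stratum."""

    ALL_ALPHA = "all_alpha"
    ALL_BETA = "all_beta"
    ALPHA_BETA = "alpha_beta"


class KineticClass(str, Enum):
    """Folding mechanism stratum: with or without a populated intermediate."""

    TWO_STATE = "two_state"
    MULTI_STATE = "multi_state"


_STRUCTURAL_ALIASES = {
    "all_alpha": StructuralClass.ALL_ALPHA,
    "alpha": StructuralClass.ALL_ALPHA,
    "all_beta": StructuralClass.ALL_BETA,
    "beta": StructuralClass.ALL_BETA,
    "alpha_beta": StructuralClass.ALPHA_BETA,
    "mixed": StructuralClass.ALPHA_BETA,
}

_KINETIC_ALIASES = {
    "two_state": KineticClass.TWO_STATE,
    "twostate": KineticClass.TWO_STATE,
    "2state": KineticClass.TWO_STATE,
    "multi_state": KineticClass.MULTI_STATE,
    "multistate": KineticClass.MULTI_STATE,
}


def normalize_sequence(raw: str) -> str:
    """Normalize a raw DNA/RNA string to uppercase {A,C,G,U}.

    Case is folded and T is mapped to U so both EMBL-style CDS entries and
    RNA FASTA files are accepted.  Any other character (including ambiguity
    codes like N) raises :class:`AmbiguousBaseError`.
    """
    if not raw:
        raise AmbiguousBaseError("empty sequence")
    seq = raw.translate(_NORMALIZE)
    bad = set(seq) - set(BASES)
    if bad:
        raise AmbiguousBaseError(
            f"sequence contains non-ACGU(T) characters: {sorted(bad)!r}"
        )
    return seq


def extract_segment(cds: str, aa_start: int, aa_end: int) -> str:
    """Return the codons for amino-acid positions ``aa_start..aa_end``.

    Coordinates are 1-based inclusive, matching how protein-segment papers
    cite residue ranges.
    """
    if len(cds) % 3 != 0:
        raise FramingError(f"CDS length {len(cds)} is not a codon multiple")
    n_aa = len(cds) // 3
    if not (1 <= aa_start <= aa_end <= n_aa):
        raise SegmentRangeError(
            f"segment {aa_start}..{aa_end} outside 1..{n_aa}"
        )
    return cds[3 * (aa_start - 1): 3 * aa_end]


def parse_structural_class(label: str) -> StructuralClass:
    key = _canon_label(label)
    if key not in _STRUCTURAL_ALIASES:
        raise LabelError(f"unknown structural class label: {label!r}")
    return _STRUCTURAL_ALIASES[key]


def parse_kinetic_class(label: str) -> KineticClass:
    key = _canon_label(label)
    if key not in _KINETIC_ALIASES:
        raise LabelError(f"unknown kinetic class label: {label!r}")
    return _KINETIC_ALIASES[key]


def _canon_label(label: str) -> str:
    s = str(label).strip().lower().replace("-", "_").replace(" ", "_")
    return s.replace("α", "alpha").replace("β", "beta")


@dataclass(frozen=True)
class MrnaRecord:
    """One protein: coding sequence, class labels and ln(folding rate)."""

    id: str
    sequence: str
    structural_class: StructuralClass
    kinetic_class: KineticClass
    ln_kf: float

    def __post_init__(self) -> None:
        if not self.id:
            raise MrnaLangError("record id must be non-empty")
        if set(self.sequence) - set(BASES):
            raise AmbiguousBaseError(
                f"{self.id}: sequence not normalized to {{A,C,G,U}}"
            )
        if len(self.sequence) < 6:
            raise FramingError(
                f"{self.id}: sequence length {len(self.sequence)} < 6"
            )
        if len(self.sequence) % 3 != 0:
            raise FramingError(
                f"{self.id}: length {len(self.sequence)} not a codon multiple"
            )
        if not math.isfinite(self.ln_kf):
            raise MrnaLangError(f"{self.id}: ln_kf is not finite")


@dataclass(frozen=True)
class StudyDataset:
    """Ordered collection of :class:`MrnaRecord` with unique ids."""

    records: tuple[MrnaRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise MrnaLangError(f"duplicate record ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MrnaRecord]:
        return iter(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def annotation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "structural_class": [r.structural_class.value for r in self.records],
                "kinetic_class": [r.kinetic_class.value for r in self.records],
                "ln_kf": [r.ln_kf for r in self.records],
            }
        )


@dataclass
class RecordFailure:
    """A per-record validation failure collected during lenient loading."""

    id: str
    error: MrnaLangError

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.id}: {self.error}"


def _frame_sequence(seq_id: str, seq: str, truncate_frame: bool, strip_stop: bool) -> str:
    if truncate_frame and len(seq) % 3 != 0:
        seq = seq[: len(seq) - len(seq) % 3]
    if len(seq) % 3 != 0:
        raise FramingError(
            f"{seq_id}: length {len(seq)} not a codon multiple "
            "(pass truncate_frame=True to drop trailing bases)"
        )
    if strip_stop and len(seq) >= 6 and seq[-3:] in _STOP_CODONS:
        seq = seq[:-3]
    return seq


def read_annotations(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read the protein annotation table (CSV or TSV, header required).

    The delimiter is auto-detected between comma and tab unless given.
    Class labels are validated against the fixed vocabularies, matched
    case-insensitively.
    """
    if delimiter is None:
        head = Path(path).open().readline()
        delimiter = "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","
    df = pd.read_csv(path, sep=delimiter, dtype={"id": str},
                     float_precision="round_trip")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise MrnaLangError(f"annotation table missing columns: {missing}")
    for idx, row in df.iterrows():
        try:
            df.at[idx, "structural_class"] = parse_structural_class(row["structural_class"]).value
            df.at[idx, "kinetic_class"] = parse_kinetic_class(row["kinetic_class"]).value
        except LabelError as exc:
            raise LabelError(f"row {idx} (id={row['id']!r}): {exc}") from exc
    return df


def _read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_dataset(
    fasta_path: str | Path,
    annotations_path: str | Path,
    *,
    truncate_frame: bool = False,
    strip_stop: bool = False,
    delimiter: str | None = None,
) -> StudyDataset:
    """Load and join sequences with annotations; raise on any invalid record."""
    dataset, failures = read_dataset_lenient(
        fasta_path,
        annotations_path,
        truncate_frame=truncate_frame,
        strip_stop=strip_stop,
        delimiter=delimiter,
    )
    if failures:
        raise failures[0].error
    return dataset


def read_dataset_lenient(
    fasta_path: str | Path,
    annotations_path: str | Path,
    *,
    truncate_frame: bool = False,
    strip_stop: bool = False,
    delimiter: str | None = None,
) -> tuple[StudyDataset, list[RecordFailure]]:
    """Like :func:`read_dataset` but collects per-record failures.

    Id mismatches between FASTA and table are structural and always raise
    :class:`JoinError`; per-record alphabet/framing problems are returned as
    :class:`RecordFailure` entries alongside the valid records.
    """
    fasta = _read_fasta(fasta_path)
    if not fasta:
        raise EmptyDatasetError(f"no FASTA records in {fasta_path}")
    ann = read_annotations(annotations_path, delimiter=delimiter)
    fasta_ids = [i for i, _ in fasta]
    table_ids = list(ann["id"])
    fasta_only = sorted(set(fasta_ids) - set(table_ids))
    table_only = sorted(set(table_ids) - set(fasta_ids))
    if fasta_only or table_only:
        raise JoinError(
            f"id mismatch: in FASTA only {fasta_only}; in table only {table_only}",
            fasta_only=fasta_only,
            table_only=table_only,
        )
    ann_by_id = ann.set_index("id")
    records: list[MrnaRecord] = []
    failures: list[RecordFailure] = []
    for seq_id, raw in fasta:
        row = ann_by_id.loc[seq_id]
        try:
            seq = normalize_sequence(raw)
            seq = _frame_sequence(seq_id, seq, truncate_frame, strip_stop)
            records.append(
                MrnaRecord(
                    id=seq_id,
                    sequence=seq,
                    structural_class=StructuralClass(row["structural_class"]),
                    kinetic_class=KineticClass(row["kinetic_class"]),
                    ln_kf=float(row["ln_kf"]),
                )
            )
        except MrnaLangError as exc:
            failures.append(RecordFailure(id=seq_id, error=exc))
    provenance = f"fasta={fasta_path} annotations={annotations_path}"
    return StudyDataset(records=tuple(records), provenance=provenance), failures


def write_dataset(
    dataset: StudyDataset,
    fasta_path: str | Path,
    annotations_path: str | Path,
    *,
    line_width: int = 60,
) -> None:
    """Write a dataset back to FASTA + annotation table (round-trip safe)."""
    records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="")
        for r in dataset.records
    ]
    with open(fasta_path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=line_width)
        writer.write_file(records)
    # repr() keeps ln_kf at full double precision for the round-trip.
    df = dataset.annotation_frame()
    df["ln_kf"] = [repr(v) for v in df["ln_kf"]]
    df.to_csv(annotations_path, index=False)


def write_parameter_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the per-protein 12-parameter table (id + fixed column order)."""
    cols = ["id", *PARAMETER_COLUMNS]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise MrnaLangError(f"parameter table missing columns: {missing}")
    table[cols].to_csv(path, index=False, float_format="%.12g")


def read_parameter_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    if delimiter is None:
        head = Path(path).open().readline()
        delimiter = "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","
    df = pd.read_csv(path, sep=delimiter, dtype={"id": str},
                     float_precision="round_trip")
    missing = [c for c in ("id", *PARAMETER_COLUMNS) if c not in df.columns]
    if missing:
        raise MrnaLangError(f"parameter table missing columns: {missing}")
    return df
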