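"""Reading, validation and partitioning of labeled peptide datasets.

The model operates exclusively on nonamers (9-residue peptides), the
canonical length presented by HLA-A2. Input tables carry one peptide per
row with a binary immunogenicity label; protein inputs for screening come
in as standard FASTA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PEPTIDE_LENGTH = 9

_AA_SET = frozenset(AMINO_ACIDS)

POSITIVE_LABELS = {"1", "immunogenic", "yes", "true", "pos", "positive"}
NEGATIVE_LABELS = {"0", "non-immunogenic", "nonimmunogenic", "no", "false",
                   "neg", "negative"}


class PeptideValidationError(ValueError):
    """Raised in strict mode when a raw sequence fails nonamer validation."""


class DataIntegrityError(ValueError):
    """Raised when a dataset violates a hard invariant (e.g. a sequence
    labeled both immunogenic and non-immunogenic)."""


def validate_peptide(raw: str, strict: bool = True) -> str | None:
    """Normalize and validate a raw peptide sequence.

    Uppercases the input and accepts it iff it is exactly 9 residues over
    the 20 canonical amino-acid letters. In strict mode invalid input
    raises :class:`PeptideValidationError`; in lenient mode it is logged
    and ``None`` is returned.
    """
    if not isinstance(raw, str) or not raw:
        reason = "empty or non-string sequence"
        if strict:
            raise PeptideValidationError(reason)
        logger.warning("skipping peptide: %s", reason)
        return None
    seq = raw.strip().upper()
    if len(seq) != PEPTIDE_LENGTH:
        reason = f"length {len(seq)} != {PEPTIDE_LENGTH}: {seq!r}"
    elif not _AA_SET.issuperset(seq):
        bad = sorted(set(seq) - _AA_SET)
        reason = f"non-canonical letter(s) {bad} in {seq!r}"
    else:
        return seq
    if strict:
        raise PeptideValidationError(reason)
    logger.warning("skipping peptide: %s", reason)
    return None


@dataclass(frozen=True)
class PeptideRecord:
    sequence: str
    label: int                # 1 = immunogenic, 0 = non-immunogenic
    source: str = ""
    split: str | None = None  # optional precomputed membership: train/test


@dataclass
class LabeledPeptideSet:
    """A validated collection of labeled nonamers.

    Invariant: no sequence appears with both labels (checked on
    construction and on every mutation path through :meth:`from_records`).
    """

    records: list[PeptideRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._check_label_consistency()

    def _check_label_consistency(self) -> None:
        seen: dict[str, int] = {}
        for rec in self.records:
            prev = seen.setdefault(rec.sequence, rec.label)
            if prev != rec.label:
                raise DataIntegrityError(
                    f"sequence {rec.sequence} carries both labels")

    @classmethod
    def from_records(cls, records: Iterable[PeptideRecord]) -> "LabeledPeptideSet":
        return cls(list(records))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def labels(self) -> list[int]:
        return [r.label for r in self.records]

    def count(self, label: int) -> int:
        return sum(1 for r in self.records if r.label == label)

    @property
    def n_positive(self) -> int:
        return self.count(1)

    @property
    def n_negative(self) -> int:
        return self.count(0)

    def subset(self, label: int) -> "LabeledPeptideSet":
        return LabeledPeptideSet([r for r in self.records if r.label == label])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "peptide": [r.sequence for r in self.records],
                "label": [r.label for r in self.records],
                "source": [r.source for r in self.records],
            }
        )
        if any(r.split is not None for r in self.records):
            df["split"] = [r.split for r in self.records]
        return df

    def write_table(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def _parse_label(raw) -> int:
    token = str(raw).strip().lower()
    if token in POSITIVE_LABELS:
        return 1
    if token in NEGATIVE_LABELS:
        return 0
    raise DataIntegrityError(f"unrecognized label value: {raw!r}")


def load_peptide_table(
    path: str | Path,
    sequence_col: str = "peptide",
    label_col: str = "label",
    source_col: str = "source",
    split_col: str = "split",
    sep: str | None = None,
    strict: bool = True,
) -> LabeledPeptideSet:
    """Read a TSV/CSV peptide table into a validated :class:`LabeledPeptideSet`.

    The separator is sniffed from the extension when not given. Labels may
    be 1/0 or immunogenic/non-immunogenic (case-insensitive). In strict
    mode any invalid row aborts the load with an error naming the row; in
    lenient mode invalid rows are skipped with a log entry.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("peptide table %s is empty", path)
        return LabeledPeptideSet()
    for col in (sequence_col, label_col):
        if col not in df.columns:
            raise KeyError(
                f"required column {col!r} missing from {path} "
                f"(found: {list(df.columns)})")
    records: list[PeptideRecord] = []
    for idx, row in df.iterrows():
        try:
            seq = validate_peptide(row[sequence_col], strict=strict)
        except PeptideValidationError as exc:
            raise PeptideValidationError(f"row {idx}: {exc}") from exc
        if seq is None:
            continue
        records.append(
            PeptideRecord(
                sequence=seq,
                label=_parse_label(row[label_col]),
                source=str(row[source_col]) if source_col in df.columns
                and pd.notna(row[source_col]) else "",
                split=str(row[split_col]) if split_col in df.columns
                and pd.notna(row[split_col]) else None,
            )
        )
    if not records:
        logger.warning("no valid peptides loaded from %s", path)
    return LabeledPeptideSet(records)


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (87.6 -> 88, 128.4 -> 128)."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def stratified_split(
    pset: LabeledPeptideSet,
    train_fraction: float = 0.6,
    seed: int = 0,
) -> tuple[LabeledPeptideSet, LabeledPeptideSet]:
    """Partition the set into train/test, stratified by label.

    Per class, the training count is the train fraction of the class size
    rounded half-away-from-zero; members are drawn uniformly at random
    given the seed. The same seed always yields the identical partition.
    """
    import numpy as np

    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[PeptideRecord] = []
    test: list[PeptideRecord] = []
    for label in (1, 0):
        members = [r for r in pset.records if r.label == label]
        if len(members) < 2:
            raise ValueError(
                f"class {label} has {len(members)} member(s); need >= 2 to split")
        n_train = _round_half_away(len(members) * train_fraction)
        order = rng.permutation(len(members))
        chosen = set(order[:n_train].tolist())
        for i, rec in enumerate(members):
            (train if i in chosen else test).append(rec)
    return LabeledPeptideSet(train), LabeledPeptideSet(test)


def split_by_column(pset: LabeledPeptideSet) -> tuple[LabeledPeptideSet, LabeledPeptideSet]:
    """Partition by a precomputed membership column (split = train/test),
    for reproducing an externally recorded partition."""
    train = [r for r in pset.records if r.split == "train"]
    test = [r for r in pset.records if r.split == "test"]
    if len(train) + len(test) != len(pset):
        raise DataIntegrityError(
            "split column must label every record as train or test")
    return LabeledPeptideSet(train), LabeledPeptideSet(test)


@dataclass(frozen=True)
class ProteinRecord:
    identifier: str
    sequence: str


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA of protein sequences.

    Sequences are uppercased; line wrapping and trailing whitespace are
    tolerated. Duplicate identifiers or empty sequence records are errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DataIntegrityError(f"duplicate FASTA identifier: {rec.id}")
        seq = str(rec.seq).strip().upper()
        if not seq:
            raise DataIntegrityError(f"empty sequence for record {rec.id}")
        seen.add(rec.id)
        records.append(ProteinRecord(identifier=rec.id, sequence=seq))
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.identifier}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")
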