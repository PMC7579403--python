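"""Virtual screening: cleave proteins into unique nonamers with origin
provenance, score them with a fitted model, and select a top fraction.

Origins use 1-based inclusive start coordinates. Exact-duplicate nonamers
(within or across proteins) merge into a single record that keeps every
origin. The selected count for a top fraction f of N candidates is
floor(N * f), never below 1 when candidates exist.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .model import PotnModel
from .peptide_io import PEPTIDE_LENGTH, ProteinRecord, read_fasta, validate_peptide

logger = logging.getLogger(__name__)


@dataclass
class NonamerRecord:
    peptide: str
    origins: list[tuple[str, int]] = field(default_factory=list)

    @property
    def occurrence_count(self) -> int:
        return len(self.origins)


def split_nonamers(
    proteins: Iterable[ProteinRecord],
    skip_invalid: bool = True,
) -> list[NonamerRecord]:
    """Sliding window of width 9, step 1, over every protein.

    Windows containing non-canonical letters are skipped with a log entry
    (or raise when ``skip_invalid`` is off); proteins shorter than 9 yield
    no windows. Duplicate peptides are merged, keeping all origins in
    encounter order.
    """
    records: dict[str, NonamerRecord] = {}
    for prot in proteins:
        n_windows = len(prot.sequence) - PEPTIDE_LENGTH + 1
        if n_windows <= 0:
            logger.warning("protein %s shorter than %d residues; no windows",
                           prot.identifier, PEPTIDE_LENGTH)
            continue
        for start in range(n_windows):
            window = prot.sequence[start:start + PEPTIDE_LENGTH]
            pep = validate_peptide(window, strict=not skip_invalid)
            if pep is None:
                continue
            rec = records.setdefault(pep, NonamerRecord(peptide=pep))
            rec.origins.append((prot.identifier, start + 1))
    return list(records.values())


@dataclass
class ScreeningReport:
    """Ranked screening output; ``table`` columns: rank, peptide, score,
    occurrences, origins, selected."""

    table: pd.DataFrame
    top_fraction: float
    n_selected: int
    n_candidates: int

    def selected(self) -> pd.DataFrame:
        return self.table[self.table["selected"]]

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def rank_and_select(
    scored: Sequence[tuple[NonamerRecord, float]],
    top_fraction: float,
    include_ties: bool = False,
) -> ScreeningReport:
    """Sort by score descending (ties broken lexicographically by peptide)
    and mark the top floor(N * fraction) candidates as selected.

    With ``include_ties`` every candidate tied with the cutoff score is
    also selected.
    """
    if not scored:
        raise ValueError("nothing to rank")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if any(not math.isfinite(s) for _, s in scored):
        raise ValueError("scores must be finite")
    ordered = sorted(scored, key=lambda item: (-item[1], item[0].peptide))
    n = len(ordered)
    n_selected = max(1, math.floor(n * top_fraction))
    if include_ties and n_selected < n:
        cutoff = ordered[n_selected - 1][1]
        while n_selected < n and ordered[n_selected][1] == cutoff:
            n_selected += 1
    table = pd.DataFrame(
        {
            "rank": range(1, n + 1),
            "peptide": [r.peptide for r, _ in ordered],
            "score": [s for _, s in ordered],
            "occurrences": [r.occurrence_count for r, _ in ordered],
            "origins": [";".join(f"{pid}:{start}" for pid, start in r.origins)
                        for r, _ in ordered],
            "selected": [i < n_selected for i in range(n)],
        }
    )
    return ScreeningReport(table=table, top_fraction=top_fraction,
                           n_selected=n_selected, n_candidates=n)


def screen(
    fasta_path: str | Path,
    model: PotnModel | str | Path,
    top_fraction: float = 0.002,
    external: pd.DataFrame | None = None,
    out: str | Path | None = None,
    include_ties: bool = False,
) -> ScreeningReport:
    """Full pipeline: FASTA -> unique nonamers -> model scores -> top-fraction
    selection. Writes a ranked TSV when ``out`` is given (only on success)."""
    if not isinstance(model, PotnModel):
        model = PotnModel.load(model)
    proteins = read_fasta(fasta_path)
    nonamers = split_nonamers(proteins, skip_invalid=True)
    logger.info("screening %d unique nonamers from %d proteins",
                len(nonamers), len(proteins))
    if not nonamers:
        logger.warning("no nonamers produced; empty report")
        empty = pd.DataFrame(columns=["rank", "peptide", "score",
                                      "occurrences", "origins", "selected"])
        return ScreeningReport(table=empty, top_fraction=top_fraction,
                               n_selected=0, n_candidates=0)
    scores = model.predict_scores([r.peptide for r in nonamers],
                                  external=external)
    report = rank_and_select(
        list(zip(nonamers, (s.score for s in scores))),
        top_fraction, include_ties=include_ties)
    if out is not None:
        report.write_tsv(out)
    return report
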