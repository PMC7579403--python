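"""Position-specific feature engineering and significance-based selection.

Each nonamer is described by 28 features: 11 positional physicochemical
descriptors (table lookups of the residue at a fixed position), 10
residue-propensity features derived from class-conditional position
frequencies on the training data, and 7 externally computed predictor
scores (binding affinity, proteasomal cleavage, pMHC stability) joined
from a TSV. Features are filtered by a two-sample t-test between the
immunogenic and non-immunogenic classes at a configurable alpha.

The residue propensity of residue i at position j contrasts the
class-conditional frequencies::

    R_ij = (P_ij - N_ij) / (P_ij + N_ij)

where P and N are the frequencies of residue i at position j among
immunogenic and non-immunogenic peptides respectively. Scores lie in
[-1, +1]; a cell where the residue is absent from both classes is
undefined and takes a configurable value (default 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .peptide_io import AMINO_ACIDS, PEPTIDE_LENGTH, LabeledPeptideSet

logger = logging.getLogger(__name__)

POSITIONS = [f"P{j}" for j in range(1, PEPTIDE_LENGTH + 1)]

#: default positional physicochemical descriptors: (property name, position)
DEFAULT_PHYSCHEM_SPEC: tuple[tuple[str, int], ...] = (
    ("ASA", 3),
    ("charge", 3),
    ("ECI", 3),
    ("entropy", 3),
    ("hydrophobicity", 3),
    ("ISA", 3),
    ("Mw", 3),
    ("organic_solvent_water", 3),
    ("organic_solvent_water", 4),
    ("PI", 5),
    ("polarity", 3),
)

#: externally computed predictor columns (binding affinity, cleavage,
#: combined processing score, pMHC stability readouts)
EXTERNAL_COLUMNS: tuple[str, ...] = (
    "Aff", "Aff_rescale", "Cle", "Combined", "Pred", "Thalf", "NB",
)

PROPENSITY_COLUMNS: tuple[str, ...] = tuple(
    f"propensity@{p}" for p in POSITIONS) + ("propensity@sum",)


@dataclass(frozen=True)
class PropertyTable:
    """A named amino-acid -> value map for one physicochemical scale."""

    name: str
    values: Mapping[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        if missing:
            raise ValueError(
                f"property table {self.name!r} missing residues {sorted(missing)}")
        if not all(np.isfinite(v) for v in self.values.values()):
            raise ValueError(f"property table {self.name!r} has non-finite values")

    def __getitem__(self, aa: str) -> float:
        return float(self.values[aa])


def load_property_tables(path: str | Path | None = None) -> dict[str, PropertyTable]:
    """Load physicochemical scales from a wide TSV (property_name, A..Y,
    optional provenance). With no path, the packaged defaults are used."""
    if path is None:
        source = resources.files("potn") / "data" / "property_tables.tsv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    tables: dict[str, PropertyTable] = {}
    for _, row in df.iterrows():
        name = str(row["property_name"])
        values = {aa: float(row[aa]) for aa in AMINO_ACIDS}
        prov = str(row["provenance"]) if "provenance" in df.columns else ""
        tables[name] = PropertyTable(name=name, values=values, provenance=prov)
    return tables


@dataclass
class FrequencyMatrix:
    """Per-position residue frequencies over a peptide collection.

    ``freq`` is a 20 x 9 DataFrame (rows = amino acids, columns P1..P9);
    each column sums to 1 when n > 0.
    """

    freq: pd.DataFrame
    n: int


def position_frequencies(peptides: Iterable[str]) -> FrequencyMatrix:
    """Tally residue frequencies at each of the 9 positions."""
    peptides = list(peptides)
    if not peptides:
        raise ValueError("cannot compute frequencies of an empty collection")
    counts = np.zeros((len(AMINO_ACIDS), PEPTIDE_LENGTH))
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for seq in peptides:
        if len(seq) != PEPTIDE_LENGTH:
            raise ValueError(f"peptide {seq!r} is not a nonamer")
        for j, aa in enumerate(seq):
            counts[aa_index[aa], j] += 1
    freq = pd.DataFrame(counts / len(peptides),
                        index=list(AMINO_ACIDS), columns=POSITIONS)
    return FrequencyMatrix(freq=freq, n=len(peptides))


@dataclass
class PropensityMatrix:
    """20 x 9 residue-propensity scores in [-1, +1].

    ``undefined_value`` records the value substituted where a residue was
    seen at a position in neither class.
    """

    scores: pd.DataFrame
    undefined_value: float = 0.0

    def score(self, aa: str, position: int) -> float:
        return float(self.scores.at[aa, f"P{position}"])

    def to_tsv(self, path: str | Path) -> None:
        self.scores.to_csv(path, sep="\t", index_label="aa")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PropensityMatrix":
        df = pd.read_csv(path, sep="\t", index_col="aa")
        return cls(scores=df[POSITIONS])


def residue_propensity(
    pos_freq: FrequencyMatrix,
    neg_freq: FrequencyMatrix,
    undefined_value: float = 0.0,
    pseudocount: float = 0.0,
) -> PropensityMatrix:
    """Contrast class-conditional frequencies into propensity scores.

    score = (P - N) / (P + N) per cell; any common positive rescaling of
    the frequencies cancels. An optional add-k pseudocount on the counts
    (off by default) regularizes rare residues.
    """
    if not pos_freq.freq.index.equals(neg_freq.freq.index) or \
            not pos_freq.freq.columns.equals(neg_freq.freq.columns):
        raise ValueError("frequency matrices have mismatched alphabets/positions")
    p = pos_freq.freq.to_numpy()
    n = neg_freq.freq.to_numpy()
    if pseudocount:
        p = (p * pos_freq.n + pseudocount) / (pos_freq.n + 20 * pseudocount)
        n = (n * neg_freq.n + pseudocount) / (neg_freq.n + 20 * pseudocount)
    denom = p + n
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(denom > 0, (p - n) / np.where(denom > 0, denom, 1.0),
                          undefined_value)
    df = pd.DataFrame(scores, index=pos_freq.freq.index,
                      columns=pos_freq.freq.columns)
    return PropensityMatrix(scores=df, undefined_value=undefined_value)


def fit_propensity(train_set: LabeledPeptideSet, **kwargs) -> PropensityMatrix:
    """Fit the propensity matrix from a labeled (training) set."""
    pos = position_frequencies(train_set.subset(1).sequences)
    neg = position_frequencies(train_set.subset(0).sequences)
    return residue_propensity(pos, neg, **kwargs)


def propensity_features(peptide: str, matrix: PropensityMatrix) -> dict[str, float]:
    """Per-position propensity of the peptide's residues plus their sum."""
    values = {f"propensity@P{j + 1}": matrix.score(peptide[j], j + 1)
              for j in range(PEPTIDE_LENGTH)}
    values["propensity@sum"] = float(sum(values.values()))
    return values


def physchem_features(
    peptide: str,
    tables: Mapping[str, PropertyTable],
    spec: Sequence[tuple[str, int]] = DEFAULT_PHYSCHEM_SPEC,
) -> dict[str, float]:
    """Positional physicochemical descriptors: table[residue at position]."""
    out: dict[str, float] = {}
    for name, pos in spec:
        if name not in tables:
            raise KeyError(f"unknown property table {name!r}")
        if not 1 <= pos <= PEPTIDE_LENGTH:
            raise ValueError(f"position {pos} outside 1..{PEPTIDE_LENGTH}")
        out[f"{name}@P{pos}"] = tables[name][peptide[pos - 1]]
    return out


def import_external_features(
    path: str | Path,
    expected_columns: Sequence[str] = EXTERNAL_COLUMNS,
) -> pd.DataFrame:
    """Read externally computed predictor scores keyed by peptide sequence.

    Returns a DataFrame indexed by peptide. Duplicate keys with
    conflicting values are an integrity error; consistent duplicates
    collapse to one row.
    """
    df = pd.read_csv(path, sep="\t")
    if "peptide" not in df.columns:
        raise KeyError("external feature file must have a 'peptide' column")
    missing = [c for c in expected_columns if c not in df.columns]
    if missing:
        raise KeyError(f"external feature file missing columns {missing}")
    df = df.set_index("peptide")
    dups = df.index[df.index.duplicated(keep=False)]
    if len(dups):
        for pep in dups.unique():
            block = df.loc[[pep], list(expected_columns)]
            if (block.nunique() > 1).any():
                raise ValueError(
                    f"peptide {pep} repeated with conflicting external values")
        df = df[~df.index.duplicated(keep="first")]
    return df[list(expected_columns)].astype(float)


def join_external(
    sequences: Sequence[str], external: pd.DataFrame,
) -> tuple[pd.DataFrame, float]:
    """Align external columns to a peptide list; report join coverage."""
    joined = external.reindex(sequences)
    coverage = float(joined.notna().all(axis=1).mean()) if len(joined) else 0.0
    if coverage < 1.0:
        logger.warning("external features cover %.1f%% of peptides",
                       100 * coverage)
    return joined, coverage


def build_feature_table(
    sequences: Sequence[str],
    matrix: PropensityMatrix,
    tables: Mapping[str, PropertyTable],
    spec: Sequence[tuple[str, int]] = DEFAULT_PHYSCHEM_SPEC,
    external: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the full per-peptide feature table.

    The 21 internally computed columns (11 physicochemical + 10
    propensity) are always present; the 7 external columns are appended
    when an external table is supplied ("full" mode), otherwise the model
    runs on the core features alone.
    """
    rows = []
    for seq in sequences:
        row = physchem_features(seq, tables, spec)
        row.update(propensity_features(seq, matrix))
        rows.append(row)
    table = pd.DataFrame(rows, index=pd.Index(sequences, name="peptide"))
    if external is not None:
        joined, coverage = join_external(list(sequences), external)
        if coverage == 0.0 and len(sequences):
            logger.warning(
                "no external features joined; model will run in core mode")
        joined.index = table.index
        table = pd.concat([table, joined], axis=1)
    return table


@dataclass
class FeatureSelectionResult:
    """Per-feature p-values and the retained mask at threshold alpha."""

    pvalues: pd.Series
    alpha: float
    retained: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.retained = self.pvalues < self.alpha

    @property
    def selected_features(self) -> list[str]:
        return list(self.pvalues.index[self.retained])


def select_features(
    table: pd.DataFrame,
    labels: Sequence[int],
    alpha: float = 0.05,
    welch: bool = False,
) -> FeatureSelectionResult:
    """Two-sided two-sample t-test per feature column.

    Pooled-variance by default (the classical two-sample test); Welch's
    unequal-variance form by option. Columns constant across both groups
    take p = 1 by convention. Features with p < alpha are retained; no
    multiple-testing correction is applied.
    """
    labels = np.asarray(labels)
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    for lab in (0, 1):
        if (labels == lab).sum() < 2:
            raise ValueError("each class needs at least 2 rows for the t-test")
    pos = table.loc[labels == 1]
    neg = table.loc[labels == 0]
    pvals = {}
    for col in table.columns:
        a, b = pos[col].dropna(), neg[col].dropna()
        if len(a) < 2 or len(b) < 2 or (a.std(ddof=1) == 0 and b.std(ddof=1) == 0):
            pvals[col] = 1.0
            continue
        _, p = stats.ttest_ind(a, b, equal_var=not welch)
        pvals[col] = float(p) if np.isfinite(p) else 1.0
    return FeatureSelectionResult(pvalues=pd.Series(pvals), alpha=alpha)


@dataclass
class Scaler:
    """Column-wise z-scoring with parameters learned from the fit rows only.

    Uses the sample standard deviation (ddof=1); zero-variance columns
    map to 0 rather than dividing by zero.
    """

    mean: pd.Series
    std: pd.Series

    @classmethod
    def fit(cls, table: pd.DataFrame) -> "Scaler":
        if table.empty:
            raise ValueError("cannot fit a scaler on an empty table")
        return cls(mean=table.mean(), std=table.std(ddof=1))

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        safe_std = self.std.replace(0.0, np.inf)
        return (table[self.mean.index] - self.mean) / safe_std


def standardize(
    table: pd.DataFrame, fit_rows: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, Scaler]:
    """Z-score the table using statistics of ``fit_rows`` (default: itself)."""
    scaler = Scaler.fit(table if fit_rows is None else fit_rows)
    return scaler.transform(table), scaler
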