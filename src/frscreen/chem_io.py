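"""Compound dataset I/O, SMILES validation and descriptor tables.

The screening pipeline consumes *decision tables*: one row per compound,
one numeric column per molecular descriptor, an optional name/id column
and an optional measured IC50 column (µg/mL).  Descriptor arithmetic is
delegated to a pluggable provider so the package runs on stubbed or
pre-computed tables without a cheminformatics toolkit present.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_NAME_COLUMN = "Drug_name"
DEFAULT_TARGET_COLUMN = "IC50"
_ID_COLUMN_ALIASES = ("Drug_name", "drug_name", "name", "Name", "id", "ID", "compound_id")


def default_descriptor_names() -> list[str]:
    """The 44-name default descriptor vocabulary shipped with the package."""
    text = resources.files("frscreen").joinpath("data/default_descriptors.txt").read_text()
    names = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return names


@dataclass(frozen=True)
class CompoundRecord:
    """One drug: identity, optional structure, optional measured potency."""

    id: str
    name: str
    smiles: str | None = None
    ic50: float | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("CompoundRecord.id must be non-empty")
        if self.ic50 is not None:
            if not np.isfinite(self.ic50) or self.ic50 <= 0:
                raise ValueError(
                    f"compound {self.id!r}: ic50 must be finite and > 0, got {self.ic50!r}"
                )


@dataclass
class DescriptorTable:
    """Compounds x descriptors matrix — the universe of the rough-set machinery.

    ``values`` holds finite reals only; rows with non-finite provider output
    are dropped at construction time by the loaders.  ``norm_params`` maps a
    feature name to its training-set (min, max) once :func:`normalize_table`
    has been applied, so candidate tables can be scaled with the same
    parameters.
    """

    compound_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    norm_params: dict[str, tuple[float, float]] | None = None
    constant_features: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (compounds x features)")
        n, f = self.values.shape
        if n != len(self.compound_ids) or f != len(self.feature_names):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with {len(self.compound_ids)} ids "
                f"and {len(self.feature_names)} feature names"
            )
        if len(set(self.feature_names)) != f:
            raise ValueError("feature_names must be unique")
        if len(set(self.compound_ids)) != n:
            raise ValueError("compound_ids must be unique")
        if n and f and not np.isfinite(self.values).all():
            raise ValueError("DescriptorTable must not contain non-finite cells")

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None
        return self.values[:, j]

    def subset(self, names: Sequence[str]) -> "DescriptorTable":
        """New table restricted to ``names`` (in the given order)."""
        idx = [self.feature_names.index(n) for n in names]
        norm = None
        if self.norm_params is not None:
            norm = {n: self.norm_params[n] for n in names}
        return DescriptorTable(
            compound_ids=list(self.compound_ids),
            feature_names=list(names),
            values=self.values[:, idx].copy(),
            norm_params=norm,
            constant_features=frozenset(n for n in self.constant_features if n in names),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.compound_ids, columns=self.feature_names)


# ---------------------------------------------------------------------------
# SMILES validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmilesVerdict:
    valid: bool
    reason: str | None = None
    canonical: str | None = None
    ring_closures: int | None = None


_BOND_CHARS = set("-=#$:/\\.")


def _scan_ring_closures(text: str) -> tuple[int, list[str]]:
    """Count paired ring-closure labels outside bracket atoms.

    Each digit (or %nn two-digit) label opens a closure on first sight and
    closes it on the second; labels may be reused once closed.  Returns the
    number of completed closures and any labels left dangling.
    """
    open_labels: dict[str, int] = {}
    closed = 0
    i, depth = 0, 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
            if depth < 0:
                break  # unbalanced; caught separately
        elif depth == 0:
            label = None
            if ch == "%" and i + 2 < len(text) + 1 and text[i + 1 : i + 3].isdigit():
                label = text[i + 1 : i + 3]
                i += 2
            elif ch.isdigit():
                label = ch
            if label is not None:
                if label in open_labels:
                    del open_labels[label]
                    closed += 1
                else:
                    open_labels[label] = i
        i += 1
    return closed, sorted(open_labels)


def parse_smiles(text: str) -> SmilesVerdict:
    """Validate a SMILES string, canonicalize it and count ring closures.

    Ring structures are written by breaking each ring once and marking the
    two detached atoms with a shared digit label: dioxane ``O1CCOCC1`` carries
    one closure, decalin ``C1CCCC2CCCCC12`` two (both ending on the final
    carbon).  Validation is structural (balanced brackets/parentheses, no
    dangling ring digit) followed by chemistry perception through RDKit.
    """
    if not text:
        return SmilesVerdict(False, reason="empty input")
    if not text.isascii():
        return SmilesVerdict(False, reason="SMILES must be ASCII")
    for opener, closer, what in (("[", "]", "square brackets"), ("(", ")", "parentheses")):
        bal = 0
        for ch in text:
            bal += ch == opener
            bal -= ch == closer
            if bal < 0:
                break
        if bal != 0:
            return SmilesVerdict(False, reason=f"unbalanced {what}")
    n_closures, dangling = _scan_ring_closures(text)
    if dangling:
        return SmilesVerdict(False, reason=f"dangling ring-closure label(s): {', '.join(dangling)}")

    from rdkit import Chem  # deferred: structural checks work without a parse
    from rdkit import rdBase

    rdBase.DisableLog("rdApp.error")
    try:
        mol = Chem.MolFromSmiles(text)
    finally:
        rdBase.EnableLog("rdApp.error")
    if mol is None:
        return SmilesVerdict(False, reason="rejected by chemistry perception")
    return SmilesVerdict(True, canonical=Chem.MolToSmiles(mol), ring_closures=n_closures)


# ---------------------------------------------------------------------------
# Descriptor providers
# ---------------------------------------------------------------------------

class DescriptorProvider:
    """Minimal provider protocol: name support query + per-SMILES computation."""

    def supports(self, name: str) -> bool:  # pragma: no cover - interface
        raise NotImplementedError

    def compute(self, smiles: str, names: Sequence[str]) -> list[float]:  # pragma: no cover
        raise NotImplementedError


class FunctionProvider(DescriptorProvider):
    """Provider backed by a mapping of descriptor name -> f(smiles) -> float."""

    def __init__(self, functions: Mapping[str, Callable[[str], float]]):
        self._functions = dict(functions)

    def supports(self, name: str) -> bool:
        return name in self._functions

    def compute(self, smiles: str, names: Sequence[str]) -> list[float]:
        return [float(self._functions[n](smiles)) for n in names]


class ConstantProvider(DescriptorProvider):
    """Stub provider returning a constant for every descriptor (tests/plumbing)."""

    def __init__(self, value: float = 0.0, names: Iterable[str] | None = None):
        self.value = float(value)
        self._names = set(names) if names is not None else None

    def supports(self, name: str) -> bool:
        return self._names is None or name in self._names

    def compute(self, smiles: str, names: Sequence[str]) -> list[float]:
        return [self.value] * len(names)


class RDKitProvider(DescriptorProvider):
    """Default provider binding to RDKit's 2-D descriptor registry."""

    def __init__(self) -> None:
        from rdkit.Chem import Descriptors

        self._registry = {name: fn for name, fn in Descriptors.descList}

    def supports(self, name: str) -> bool:
        return name in self._registry

    def compute(self, smiles: str, names: Sequence[str]) -> list[float]:
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"SMILES not parseable: {smiles!r}")
        return [float(self._registry[n](mol)) for n in names]


def compute_descriptors(
    records: Sequence[CompoundRecord],
    descriptor_names: Sequence[str],
    provider: DescriptorProvider,
) -> DescriptorTable:
    """Build a DescriptorTable from SMILES via the given provider.

    Rows whose provider output contains non-finite values are dropped and
    logged; unsupported descriptor names or records lacking SMILES raise.
    """
    if not descriptor_names:
        raise ValueError("descriptor_names must be non-empty")
    unknown = [n for n in descriptor_names if not provider.supports(n)]
    if unknown:
        raise ValueError(f"unsupported descriptor name(s): {', '.join(unknown)}")
    missing = [r.id for r in records if not r.smiles]
    if missing:
        raise ValueError(f"record(s) without SMILES: {', '.join(missing)}")

    ids, rows, dropped = [], [], 0
    for rec in records:
        row = np.asarray(provider.compute(rec.smiles, descriptor_names), dtype=float)
        if not np.isfinite(row).all():
            dropped += 1
            logger.warning("dropping compound %s: non-finite descriptor output", rec.id)
            continue
        ids.append(rec.id)
        rows.append(row)
    if dropped:
        logger.info("compute_descriptors: dropped %d/%d rows with non-finite cells",
                    dropped, len(records))
    values = np.vstack(rows) if rows else np.empty((0, len(descriptor_names)))
    return DescriptorTable(ids, list(descriptor_names), values)


# ---------------------------------------------------------------------------
# CSV decision tables
# ---------------------------------------------------------------------------

class DatasetFormatError(ValueError):
    """Raised when a CSV decision table violates the expected layout."""


def _read_header(path: Path) -> list[str]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DatasetFormatError(f"{path}: empty file (missing header)") from None
    if any(not h.strip() for h in header):
        raise DatasetFormatError(f"{path}: blank column name in header")
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise DatasetFormatError(f"{path}: duplicate column name(s): {', '.join(dupes)}")
    return header


def load_dataset(
    path: str | Path,
    target_column: str | None = None,
    id_column: str | None = None,
) -> tuple[DescriptorTable, np.ndarray | None, list[str]]:
    """Load a decision-table CSV.

    Returns ``(table, targets, names)`` where ``targets`` is None when no
    target column was requested (candidate/prediction-mode input) and
    ``names`` are the display names from the id column (or row indices).
    Numeric columns other than the target become features; any non-numeric
    column other than the single name/id column is rejected with its
    location.  Rows containing non-finite feature or target cells are
    dropped and logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header = _read_header(path)
    if target_column is not None and target_column not in header:
        raise DatasetFormatError(f"{path}: target column {target_column!r} not in header")

    df = pd.read_csv(path)
    if id_column is not None:
        if id_column not in header:
            raise DatasetFormatError(f"{path}: id column {id_column!r} not in header")
        name_col = id_column
    else:
        name_col = next((c for c in _ID_COLUMN_ALIASES if c in header), None)

    feature_cols = []
    for col in header:
        if col == name_col or col == target_column:
            continue
        series = pd.to_numeric(df[col], errors="coerce")
        bad = series.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DatasetFormatError(
                f"{path}: non-numeric cell in feature column {col!r} at data row {row} "
                f"(value {df[col].iloc[row]!r})"
            )
        df[col] = series
        feature_cols.append(col)

    names = (
        df[name_col].astype(str).tolist() if name_col is not None
        else [str(i) for i in range(len(df))]
    )
    values = df[feature_cols].to_numpy(dtype=float) if feature_cols else np.empty((len(df), 0))
    targets = None
    if target_column is not None:
        targets = pd.to_numeric(df[target_column], errors="coerce").to_numpy(dtype=float)

    finite = np.isfinite(values).all(axis=1)
    if targets is not None:
        finite &= np.isfinite(targets)
    if not finite.all():
        logger.info("load_dataset %s: dropped %d row(s) with non-finite cells",
                    path, int((~finite).sum()))
        values, names = values[finite], [n for n, k in zip(names, finite) if k]
        if targets is not None:
            targets = targets[finite]

    ids = names if len(set(names)) == len(names) else [f"{i}:{n}" for i, n in enumerate(names)]
    table = DescriptorTable(ids, feature_cols, values)
    return table, targets, names


def write_dataset(
    table: DescriptorTable,
    path: str | Path,
    targets: np.ndarray | None = None,
    names: Sequence[str] | None = None,
    target_column: str = DEFAULT_TARGET_COLUMN,
    name_column: str = DEFAULT_NAME_COLUMN,
) -> Path:
    """Write a decision table in the standard CSV layout (round-trip safe)."""
    path = Path(path)
    df = pd.DataFrame(table.values, columns=table.feature_names)
    df.insert(0, name_column, list(names) if names is not None else list(table.compound_ids))
    if targets is not None:
        df[target_column] = np.asarray(targets, dtype=float)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# Min-max normalization
# ---------------------------------------------------------------------------

def normalize_table(table: DescriptorTable) -> DescriptorTable:
    """Min-max scale each column to [0, 1], recording per-feature (min, max).

    Constant columns map to 0 everywhere and are flagged in
    ``constant_features``.  Idempotent: normalizing an already-normalized
    table leaves the values (and the original norm_params) unchanged.
    """
    if table.n_compounds < 2:
        raise ValueError("normalize_table requires at least 2 rows")
    if table.norm_params is not None:
        return replace(table)
    lo = table.values.min(axis=0)
    hi = table.values.max(axis=0)
    span = hi - lo
    constant = span == 0
    safe = np.where(constant, 1.0, span)
    values = (table.values - lo) / safe
    values[:, constant] = 0.0
    norm = {n: (float(l), float(h)) for n, l, h in zip(table.feature_names, lo, hi)}
    flagged = frozenset(n for n, c in zip(table.feature_names, constant) if c)
    if flagged:
        logger.info("normalize_table: constant column(s) mapped to 0: %s", ", ".join(sorted(flagged)))
    return DescriptorTable(
        list(table.compound_ids), list(table.feature_names), values,
        norm_params=norm, constant_features=flagged,
    )


def apply_normalization(
    table: DescriptorTable, norm_params: Mapping[str, tuple[float, float]]
) -> DescriptorTable:
    """Scale a (candidate) table with stored training-set parameters."""
    if set(norm_params) != set(table.feature_names):
        missing = sorted(set(table.feature_names) - set(norm_params))
        extra = sorted(set(norm_params) - set(table.feature_names))
        raise ValueError(
            "norm_params feature names do not match table; "
            f"missing: {missing or 'none'}; extra: {extra or 'none'}"
        )
    lo = np.array([norm_params[n][0] for n in table.feature_names])
    hi = np.array([norm_params[n][1] for n in table.feature_names])
    span = hi - lo
    constant = span == 0
    values = (table.values - lo) / np.where(constant, 1.0, span)
    values[:, constant] = 0.0
    values = np.clip(values, 0.0, 1.0)
    return DescriptorTable(
        list(table.compound_ids), list(table.feature_names), values,
        norm_params={n: (float(l), float(h)) for n, l, h in zip(table.feature_names, lo, hi)},
        constant_features=frozenset(n for n, c in zip(table.feature_names, constant) if c),
    )


def denormalize_table(table: DescriptorTable) -> DescriptorTable:
    """Invert :func:`normalize_table` using the stored parameters."""
    if table.norm_params is None:
        raise ValueError("table carries no norm_params")
    lo = np.array([table.norm_params[n][0] for n in table.feature_names])
    hi = np.array([table.norm_params[n][1] for n in table.feature_names])
    values = table.values * (hi - lo) + lo
    return DescriptorTable(list(table.compound_ids), list(table.feature_names), values)
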