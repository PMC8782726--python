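"""Compound I/O, standardization and pre-training-corpus curation.

Reads compound libraries from .smi / CSV / SDF, standardizes each entry
(largest organic fragment, charge neutralization, canonical SMILES) and
applies the curation rules used before embedding pre-training (element
whitelist, heavy-atom size window, single fragment).

Unparsable entries never abort a run: they are carried through as records
with ``status == "parse_failed"`` so per-stage counts stay honest.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import InputError

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

STATUS_OK = "ok"
STATUS_PARSE_FAILED = "parse_failed"
STATUS_FILTERED = "filtered"

#: Default element whitelist for corpus curation (organic subset + halogens).
DEFAULT_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I"}
)


@dataclass
class MoleculeRecord:
    """One parsed compound with identity and provenance flags.

    ``canonical_smiles`` is set iff ``status == "ok"``; for filtered or
    unparsable entries ``reason`` says why.
    """

    id: str
    raw_smiles: str
    canonical_smiles: str | None = None
    n_heavy_atoms: int = 0
    status: str = STATUS_OK
    reason: str | None = None

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK

    def mol(self) -> Chem.Mol | None:
        if self.canonical_smiles is None:
            return None
        return Chem.MolFromSmiles(self.canonical_smiles)


@dataclass(frozen=True)
class StandardizationPolicy:
    """Tunables for compound standardization."""

    largest_fragment: bool = True
    neutralize: bool = True
    # stereo is preserved when present; nothing requires it
    keep_stereo: bool = True


@dataclass(frozen=True)
class CorpusFilterRules:
    """Curation rules applied to the pre-training corpus."""

    elements: frozenset[str] = DEFAULT_ELEMENTS
    min_heavy_atoms: int = 3
    max_heavy_atoms: int = 100
    single_fragment: bool = True
    dedup_canonical: bool = True


def _records_from_pairs(pairs: Iterable[tuple[str | None, str]]) -> list[MoleculeRecord]:
    """Build records from (id-or-None, smiles) pairs; auto-IDs are zero-padded ordinals."""
    pairs = list(pairs)
    records = []
    for i, (rid, smi) in enumerate(pairs):
        if rid is None or rid == "":
            rid = f"{i + 1:05d}"
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            records.append(
                MoleculeRecord(id=rid, raw_smiles=smi, status=STATUS_PARSE_FAILED,
                               reason="unparsable SMILES")
            )
        else:
            records.append(
                MoleculeRecord(
                    id=rid,
                    raw_smiles=smi,
                    canonical_smiles=Chem.MolToSmiles(mol),
                    n_heavy_atoms=mol.GetNumHeavyAtoms(),
                )
            )
    return records


def _check_unique_ids(records: Sequence[MoleculeRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise InputError(f"duplicate compound ID {r.id!r}: IDs must be unique")
        seen.add(r.id)


def read_library(path: str | Path, format: str | None = None) -> list[MoleculeRecord]:
    """Read a compound library; input order is preserved.

    Parameters
    ----------
    path:
        Input file. ``.smi`` (whitespace-separated SMILES [+ ID], ``#``
        comment lines skipped), ``.csv`` (header with ``id,smiles`` columns)
        or ``.sdf`` (molecule title used as ID).
    format:
        ``"smi"``, ``"csv"`` or ``"sdf"``; inferred from the suffix when None.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    if format is None:
        format = path.suffix.lstrip(".").lower()
        if format not in {"smi", "csv", "sdf"}:
            raise InputError(f"cannot infer format from suffix of {path}")

    if format == "smi":
        pairs: list[tuple[str | None, str]] = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            pairs.append((parts[1].strip() if len(parts) > 1 else None, parts[0]))
        records = _records_from_pairs(pairs)
    elif format == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"id", "smiles"} <= set(reader.fieldnames):
                raise InputError(f"CSV {path} must have 'id' and 'smiles' columns")
            records = _records_from_pairs((row["id"], row["smiles"]) for row in reader)
    elif format == "sdf":
        records = []
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                records.append(MoleculeRecord(id=f"{i + 1:05d}", raw_smiles="",
                                              status=STATUS_PARSE_FAILED,
                                              reason="unparsable SDF entry"))
                continue
            rid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"{i + 1:05d}"
            smi = Chem.MolToSmiles(mol)
            records.append(MoleculeRecord(id=rid, raw_smiles=smi, canonical_smiles=smi,
                                          n_heavy_atoms=mol.GetNumHeavyAtoms()))
    else:
        raise InputError(f"unknown library format {format!r}")

    if not records:
        raise InputError(f"input file {path} contains no compounds")
    _check_unique_ids(records)
    return records


_LARGEST_FRAGMENT = rdMolStandardize.LargestFragmentChooser()
_UNCHARGER = rdMolStandardize.Uncharger()


def standardize(record: MoleculeRecord,
                policy: StandardizationPolicy = StandardizationPolicy()) -> MoleculeRecord:
    """Standardize one record: strip salts/solvates, neutralize, canonicalize.

    Deterministic for a fixed policy; idempotent on its own output. A tie
    between two equally large fragments is broken by the lexicographically
    smaller canonical SMILES (logged).
    """
    src = record.canonical_smiles if (record.ok and record.canonical_smiles) \
        else record.raw_smiles
    mol = Chem.MolFromSmiles(src)
    if mol is None:
        return replace(record, status=STATUS_PARSE_FAILED, canonical_smiles=None,
                       reason="unparsable SMILES")

    if policy.largest_fragment:
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
        if len(frags) > 1:
            best = max(frags, key=lambda f: (f.GetNumHeavyAtoms(),))
            ties = [f for f in frags if f.GetNumHeavyAtoms() == best.GetNumHeavyAtoms()]
            if len(ties) > 1:
                ties_smi = sorted(Chem.MolToSmiles(f) for f in ties)
                logger.warning("fragment tie for %s; keeping %s", record.id, ties_smi[0])
                mol = Chem.MolFromSmiles(ties_smi[0])
            else:
                mol = best
    if policy.neutralize:
        mol = _UNCHARGER.uncharge(mol)
    if not policy.keep_stereo:
        Chem.RemoveStereochemistry(mol)

    canonical = Chem.MolToSmiles(mol)
    return replace(record, canonical_smiles=canonical, status=STATUS_OK, reason=None,
                   n_heavy_atoms=mol.GetNumHeavyAtoms())


def standardize_all(records: Iterable[MoleculeRecord],
                    policy: StandardizationPolicy = StandardizationPolicy()) -> list[MoleculeRecord]:
    """Standardize every record, passing parse failures through unchanged."""
    out = []
    for r in records:
        if r.status == STATUS_PARSE_FAILED and Chem.MolFromSmiles(r.raw_smiles) is None:
            out.append(r)
        else:
            out.append(standardize(r, policy))
    return out


def filter_pretraining_corpus(
    records: Sequence[MoleculeRecord],
    rules: CorpusFilterRules = CorpusFilterRules(),
    return_rejected: bool = False,
):
    """Apply corpus-curation rules; order-preserving subset of the input.

    Each rejected record is returned (when asked for) with
    ``status == "filtered"`` and a ``reason`` naming the first failed rule.
    """
    kept: list[MoleculeRecord] = []
    rejected: list[MoleculeRecord] = []
    seen_smiles: set[str] = set()

    def reject(r: MoleculeRecord, reason: str) -> None:
        rejected.append(replace(r, status=STATUS_FILTERED, reason=reason))

    for r in records:
        if not r.ok:
            reject(r, r.reason or "parse_failed")
            continue
        mol = r.mol()
        if mol is None:
            reject(r, "unparsable")
            continue
        if rules.single_fragment and len(Chem.GetMolFrags(mol)) > 1:
            reject(r, "multi_fragment")
            continue
        symbols = {a.GetSymbol() for a in mol.GetAtoms()}
        if not symbols <= rules.elements:
            reject(r, "element")
            continue
        if not (rules.min_heavy_atoms <= r.n_heavy_atoms <= rules.max_heavy_atoms):
            reject(r, "size")
            continue
        if rules.dedup_canonical:
            if r.canonical_smiles in seen_smiles:
                reject(r, "duplicate")
                continue
            seen_smiles.add(r.canonical_smiles)
        kept.append(r)

    if return_rejected:
        return kept, rejected
    return kept


def rejection_counts(rejected: Sequence[MoleculeRecord]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in rejected:
        counts[r.reason or "unknown"] = counts.get(r.reason or "unknown", 0) + 1
    return counts


RESULT_COLUMNS = [
    "compound_id", "canonical_smiles",
    "s1d_raw", "s1d_ref", "s2d_raw", "s2d_ref", "s3d_raw", "s3d_ref",
    "s_aggregate", "filtered_score", "outlier_flag", "pass", "rank",
]

_FLOAT_COLUMNS = ["s1d_raw", "s2d_raw", "s3d_raw", "s_aggregate", "filtered_score"]


def write_results_table(ranking: pd.DataFrame, path: str | Path) -> None:
    """Write the ranked screening results as a TSV (floats at 6 decimals).

    Rows are emitted sorted by aggregate score descending, ties broken by
    compound ID ascending; the round-trip through :func:`read_results_table`
    reproduces scores bit-for-bit at that precision.
    """
    path = Path(path)
    df = ranking.loc[:, RESULT_COLUMNS].copy()
    df = df.sort_values(["s_aggregate", "compound_id"],
                        ascending=[False, True], kind="mergesort")
    try:
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    except OSError as exc:
        raise InputError(f"cannot write results table to {path}: {exc}") from exc


def read_results_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"results table not found: {path}")
    return pd.read_csv(path, sep="\t", dtype={"compound_id": str, "s1d_ref": str,
                                              "s2d_ref": str, "s3d_ref": str})


def write_smi(records: Iterable[MoleculeRecord], path: str | Path,
              canonical: bool = True) -> None:
    """Write records to a .smi file (SMILES then ID, one per line)."""
    lines = []
    for r in records:
        smi = r.canonical_smiles if (canonical and r.canonical_smiles) else r.raw_smiles
        lines.append(f"{smi} {r.id}")
    Path(path).write_text("\n".join(lines) + "\n")
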