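import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from mitoscreen.chem_io import (CorpusFilterRules, MoleculeRecord,
                                RESULT_COLUMNS, filter_pretraining_corpus,
                                read_library, read_results_table, standardize,
                                standardize_all, write_results_table, write_smi)
from mitoscreen.errors import InputError


def test_read_smi_preserves_order_and_ids(tmp_path):
    p = tmp_path / "lib.smi"
    p.write_text("c1ccccc1 benzene\nCCO ethanol\nC1CC1 cycloprop\n")
    recs = read_library(p)
    assert [r.id for r in recs] == ["benzene", "ethanol", "cycloprop"]
    assert all(r.ok for r in recs)


def test_read_smi_isolates_parse_failures(tmp_path):
    p = tmp_path / "lib.smi"
    p.write_text("CCO ethanol\nnotasmiles xyz\nc1ccccc1 benzene\n")
    recs = read_library(p)
    assert [r.status for r in recs] == ["ok", "parse_failed", "ok"]
    assert recs[1].canonical_smiles is None


def test_read_smi_autogenerates_zero_padded_ids(tmp_path):
    p = tmp_path / "lib.smi"
    p.write_text("# comment\nCCO\nCCN\n")
    recs = read_library(p)
    assert [r.id for r in recs] == ["00001", "00002"]


def test_read_csv_row_count_and_ids(tmp_path):
    p = tmp_path / "lib.csv"
    rows = [f"R{i:02d},{smi}" for i, smi in enumerate(["CCO", "CCN", "CCC"] * 5)][:14]
    p.write_text("id,smiles\n" + "\n".join(f"R{i:02d},CCO" for i in range(14)) + "\n")
    recs = read_library(p)
    assert len(recs) == 14
    assert recs[0].id == "R00" and recs[-1].id == "R13"


def test_missing_empty_and_duplicate_id_inputs_are_fatal(tmp_path):
    with pytest.raises(InputError):
        read_library(tmp_path / "absent.smi")
    empty = tmp_path / "empty.smi"
    empty.write_text("# nothing\n")
    with pytest.raises(InputError, match="no compounds"):
        read_library(empty)
    dup = tmp_path / "dup.smi"
    dup.write_text("CCO a\nCCN a\n")
    with pytest.raises(InputError, match="duplicate"):
        read_library(dup)


@pytest.mark.parametrize("raw, expected", [
    ("O.O.c1cc(O)ccc1", "Oc1ccccc1"),            # solvate stripped
    ("[Na+].CC(=O)[O-]", "CC(=O)O"),             # salt stripped + neutralized
    ("c1ccccc1", "c1ccccc1"),                    # already canonical
])
def test_standardize_examples(raw, expected):
    rec = standardize(MoleculeRecord(id="x", raw_smiles=raw))
    assert rec.canonical_smiles == Chem.CanonSmiles(expected)
    mol = Chem.MolFromSmiles(rec.canonical_smiles)
    assert sum(a.GetFormalCharge() for a in mol.GetAtoms()) == 0
    assert mol.GetNumHeavyAtoms() == rec.n_heavy_atoms


def test_standardize_idempotent_over_library(library_and_labels):
    records, _ = library_and_labels
    once = standardize_all(records)
    twice = standardize_all(once)
    assert [r.canonical_smiles for r in once] == [r.canonical_smiles for r in twice]


def test_standardize_fragment_tie_breaks_lexicographically():
    rec = standardize(MoleculeRecord(id="x", raw_smiles="CCO.CCN"))
    assert rec.canonical_smiles == min(Chem.CanonSmiles("CCO"), Chem.CanonSmiles("CCN"))


@pytest.mark.parametrize("smiles, reason", [
    ("[Fe]1(C2C=CC=C2)C2C=CC=C12", "element"),   # organometallic
    ("CO", "size"),                              # 2 heavy atoms, below minimum
    ("CCO.CCO", "multi_fragment"),
])
def test_corpus_filter_rejects_with_reason(smiles, reason):
    recs = standardize_all([MoleculeRecord(id="bad", raw_smiles=smiles),
                            MoleculeRecord(id="good", raw_smiles="CCO")])
    if reason == "multi_fragment":  # standardization already strips fragments
        recs[0] = MoleculeRecord(id="bad", raw_smiles=smiles,
                                 canonical_smiles=Chem.CanonSmiles(smiles),
                                 n_heavy_atoms=6)
    kept, rejected = filter_pretraining_corpus(recs, return_rejected=True)
    assert [r.id for r in kept] == ["good"]
    assert rejected[0].reason == reason


def test_corpus_filter_boundary_inclusive_and_subset(library_and_labels):
    ethanol = standardize(MoleculeRecord(id="e", raw_smiles="CCO"))
    assert filter_pretraining_corpus([ethanol]) == [ethanol]  # 3 heavy atoms kept
    records, _ = library_and_labels
    kept = filter_pretraining_corpus(records, CorpusFilterRules(dedup_canonical=False))
    ids = [r.id for r in records]
    assert [ids.index(r.id) for r in kept] == sorted(ids.index(r.id) for r in kept)
    assert set(r.id for r in kept) <= set(ids)


def test_smi_round_trip_reproduces_canonical_smiles(tmp_path, panel):
    p = tmp_path / "panel.smi"
    write_smi(panel, p)
    back = read_library(p)
    assert [r.canonical_smiles for r in back] == [r.canonical_smiles for r in panel]


def _toy_ranking(n=5):
    rows = []
    for i in range(n):
        rows.append({"compound_id": f"C{i}", "canonical_smiles": "CCO",
                     "s1d_raw": 0.9 - i * 0.1, "s1d_ref": "REF01",
                     "s2d_raw": 0.8, "s2d_ref": "REF01",
                     "s3d_raw": 0.7, "s3d_ref": "REF01",
                     "s_aggregate": 0.8 - i * 0.1, "filtered_score": 0.8 - i * 0.1,
                     "outlier_flag": False, "pass": i < 2, "rank": i + 1})
    return pd.DataFrame(rows)


def test_results_table_round_trip_and_tie_order(tmp_path):
    df = _toy_ranking()
    df.loc[1, "s_aggregate"] = df.loc[0, "s_aggregate"]  # tie -> ID ascending
    out = tmp_path / "results.tsv"
    write_results_table(df, out)
    back = read_results_table(out)
    assert list(back.columns) == RESULT_COLUMNS
    assert len(back) == 5
    assert list(back["compound_id"][:2]) == ["C0", "C1"]
    # bit-for-bit at 6-decimal precision
    assert np.array_equal(back["s_aggregate"].to_numpy(),
                          df["s_aggregate"].round(6).to_numpy())


def test_results_table_emits_all_rows_when_nothing_passes(tmp_path):
    df = _toy_ranking()
    df["pass"] = False
    out = tmp_path / "r.tsv"
    write_results_table(df, out)
    back = read_results_table(out)
    assert len(back) == 5 and not back["pass"].any()
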