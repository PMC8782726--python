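"""Synthetic inputs for desk-scale screening runs.

Everything the pipeline consumes can be generated here deterministically:
a 14-member reference-actives panel (documented stand-ins spanning
flavonoid, stilbenoid, macrolide, polyamine and small-acid chemotypes —
synthetic placeholders, not claims about any published inducer list), a
screening library with planted analogues, exact reference duplicates and
scaffold-enumeration decoys, and a pre-training corpus that covers the
substructure vocabulary of panel and library.

Identical specs produce identical files (checksum-stable).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from rdkit import Chem

from .chem_io import MoleculeRecord, write_smi
from .errors import ConfigError, InputError

#: The 14 reference stand-ins, REF01..REF14. Diverse, valid, desk-scale.
REFERENCE_PANEL_SMILES = [
    ("REF01", "O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12"),   # flavonol (quercetin-like)
    ("REF02", "Oc1ccc(/C=C/c2cc(O)cc(O)c2)cc1"),               # stilbenoid (resveratrol-like)
    ("REF03", "NCCCCNCCCN"),                                    # polyamine (spermidine-like)
    ("REF04", "NC(=O)c1cccnc1"),                                # pyridine carboxamide
    ("REF05", "O=C(O)c1cc(O)c(O)c(O)c1"),                      # trihydroxybenzoic acid
    ("REF06", "COc1cc(/C=C/C(=O)CC(=O)/C=C/c2ccc(O)c(OC)c2)ccc1O"),  # bis-feruloyl diketone
    ("REF07", "O=C(O)/C=C/c1ccc(O)c(O)c1"),                    # hydroxycinnamic acid
    ("REF08", "O=c1oc2cc(O)ccc2c2cc(O)ccc12"),                 # dibenzocoumarin (urolithin-like)
    ("REF09", "C(Nc1ncnc2[nH]cnc12)c1ccco1"),                  # furfuryl aminopurine
    ("REF10", "CN(C)C(=N)NC(=N)N"),                             # biguanide
    ("REF11", "O=C1CCCCCCCCCCO1"),                              # 12-membered macrolactone
    ("REF12", "OCc1c[nH]c2ccccc12"),                            # indole methanol
    ("REF13", "CS(=O)CCCCN=C=S"),                               # isothiocyanate sulfoxide
    ("REF14", "NCCNCCNCCN"),                                    # linear tetraamine
]

DEFAULT_DECOY_SCAFFOLDS = (
    "c1ccncc1", "c1cncnc1", "c1ccsc1", "c1ccoc1", "C1CCNCC1",
    "C1COCCN1", "C1CCCCC1", "c1ccc2ccccc2c1", "C1CCNC1", "C1CCOC1",
)

DEFAULT_SUBSTITUENTS = (
    "C", "O", "N", "F", "Cl", "OC", "CC", "C#N", "C(=O)O", "S", "C(C)C", "OCC",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study conditions."""

    seed: int = 0
    n_corpus: int = 2000
    n_decoys: int = 150
    n_analogues_per_reference: int = 2
    scaffolds: tuple[str, ...] = DEFAULT_DECOY_SCAFFOLDS
    substituents: tuple[str, ...] = DEFAULT_SUBSTITUENTS


def _canonical(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ConfigError(f"fixture SMILES failed to parse: {smiles}")
    return Chem.MolToSmiles(mol)


def make_reference_panel(spec: FixtureSpec = FixtureSpec()) -> list[MoleculeRecord]:
    """The 14-member reference-actives panel (REF01..REF14), all valid."""
    records = []
    for rid, smi in REFERENCE_PANEL_SMILES:
        can = _canonical(smi)
        records.append(MoleculeRecord(id=rid, raw_smiles=smi, canonical_smiles=can,
                                      n_heavy_atoms=Chem.MolFromSmiles(can).GetNumHeavyAtoms()))
    return records


def _attachment_sites(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms()
            if a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1]


def _attach(mol: Chem.Mol, frag_smiles: str, atom_idx: int) -> Chem.Mol | None:
    frag = Chem.MolFromSmiles(frag_smiles)
    if frag is None:
        return None
    combo = Chem.RWMol(Chem.CombineMols(mol, frag))
    combo.AddBond(atom_idx, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        out = combo.GetMol()
        Chem.SanitizeMol(out)
        return out
    except Exception:
        return None


def _decorate(base_smiles: str, n_edits: int, rng: np.random.Generator,
              substituents: tuple[str, ...], max_tries: int = 50) -> str | None:
    """Apply n substituent attachments at C-H sites; canonical SMILES or None."""
    mol = Chem.MolFromSmiles(base_smiles)
    for _ in range(n_edits):
        done = False
        for _try in range(max_tries):
            sites = _attachment_sites(mol)
            if not sites:
                return None
            site = int(rng.choice(sites))
            frag = str(rng.choice(substituents))
            new = _attach(mol, frag, site)
            if new is not None:
                mol = new
                done = True
                break
        if not done:
            return None
    return Chem.MolToSmiles(mol)


def make_screening_library(spec: FixtureSpec = FixtureSpec(),
                           panel: list[MoleculeRecord] | None = None):
    """Screening library with ground-truth labels.

    Composition: per reference, ``n_analogues_per_reference`` planted
    analogues (1-3 substituent edits, mirroring single-substituent analogue
    series) and one exact duplicate; plus ``n_decoys`` decoys enumerated from
    scaffolds disjoint from the panel's. Returns ``(records, labels)`` where
    labels is a list of dicts with compound_id, class and parent.
    """
    if panel is None:
        panel = make_reference_panel(spec)
    rng = np.random.default_rng(spec.seed)
    records: list[MoleculeRecord] = []
    labels: list[dict] = []
    seen: set[str] = {r.canonical_smiles for r in panel}

    def add(cid, smi, cls, parent=""):
        can = _canonical(smi)
        records.append(MoleculeRecord(
            id=cid, raw_smiles=smi, canonical_smiles=can,
            n_heavy_atoms=Chem.MolFromSmiles(can).GetNumHeavyAtoms()))
        labels.append({"compound_id": cid, "class": cls, "parent": parent})

    from .representations import pharm2d_fingerprint
    from .scoring import tanimoto

    for ref in panel:
        # a planted analogue must stay in its parent's analogue series, like
        # a real one-hydroxyl analogue pair: structurally edited but still in
        # the 2D-similarity neighbourhood; 0.6 is the usual similarity floor
        # of a medicinal-chemistry analogue series
        parent_bits = pharm2d_fingerprint(ref).on_bits
        made = 0
        attempt = 0
        while made < spec.n_analogues_per_reference:
            attempt += 1
            if attempt > 1000:
                raise InputError(f"could not generate analogues for {ref.id}")
            n_edits = int(rng.integers(1, 4))
            smi = _decorate(ref.canonical_smiles, n_edits, rng, spec.substituents)
            if smi is None or smi in seen:
                continue
            bits = pharm2d_fingerprint(smi).on_bits
            if bits != parent_bits and tanimoto(bits, parent_bits) < 0.6:
                continue
            seen.add(smi)
            made += 1
            add(f"ANA-{ref.id}-{made}", smi, "analogue", ref.id)

    for ref in panel:
        add(f"DUP-{ref.id}", ref.canonical_smiles, "duplicate", ref.id)

    made = 0
    attempt = 0
    while made < spec.n_decoys:
        attempt += 1
        if attempt > 50 * spec.n_decoys:
            raise InputError(
                f"decoy enumeration exhausted after {attempt} attempts "
                f"({made}/{spec.n_decoys} generated)")
        scaffold = str(rng.choice(spec.scaffolds))
        n_edits = int(rng.integers(1, 4))
        smi = _decorate(scaffold, n_edits, rng, spec.substituents)
        if smi is None or smi in seen:
            continue
        seen.add(smi)
        made += 1
        add(f"DEC{made:04d}", smi, "decoy")

    return records, labels


def make_pretraining_corpus(spec: FixtureSpec = FixtureSpec()) -> list[MoleculeRecord]:
    """Pre-training corpus: panel members, analogue series around each
    reference, and scaffold-substituent enumeration, up to ``n_corpus``
    unique valid molecules.

    The analogue series and enumeration reuse the same substituent chemistry
    as the screening library, so its substructure vocabulary covers the
    panel's and library's tokens; out-of-vocabulary tokens stay an exercised
    edge case rather than the norm.
    """
    if spec.n_corpus < 100:
        raise ConfigError(f"n_corpus must be >= 100, got {spec.n_corpus}")
    rng = np.random.default_rng(spec.seed + 1)
    panel = make_reference_panel(spec)
    smiles: list[str] = []
    seen: set[str] = set()

    def push(smi: str | None) -> None:
        if smi is not None and smi not in seen:
            seen.add(smi)
            smiles.append(smi)

    for r in panel:
        push(r.canonical_smiles)
    # dense analogue series around every reference
    per_ref = max(10, spec.n_corpus // (4 * len(panel)))
    for r in panel:
        for _ in range(per_ref):
            n_edits = int(rng.integers(1, 4))
            push(_decorate(r.canonical_smiles, n_edits, rng, spec.substituents))
    # scaffold enumeration for the rest
    guard = 0
    while len(smiles) < spec.n_corpus:
        guard += 1
        if guard > 100 * spec.n_corpus:
            raise InputError("corpus enumeration exhausted before n_corpus reached")
        scaffold = str(rng.choice(spec.scaffolds + tuple(r.canonical_smiles for r in panel)))
        n_edits = int(rng.integers(1, 4))
        push(_decorate(scaffold, n_edits, rng, spec.substituents))

    smiles = smiles[: spec.n_corpus]
    return [MoleculeRecord(id=f"CORP{i + 1:05d}", raw_smiles=s, canonical_smiles=s,
                           n_heavy_atoms=Chem.MolFromSmiles(s).GetNumHeavyAtoms())
            for i, s in enumerate(smiles)]


def write_fixture_set(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write corpus.smi, panel.smi, library.smi, labels.tsv and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = make_reference_panel(spec)
    library, labels = make_screening_library(spec, panel)
    corpus = make_pretraining_corpus(spec)
    write_smi(panel, out / "panel.smi")
    write_smi(library, out / "library.smi")
    write_smi(corpus, out / "corpus.smi")
    with open(out / "labels.tsv", "w") as fh:
        fh.write("compound_id\tclass\tparent\n")
        for row in labels:
            fh.write(f"{row['compound_id']}\t{row['class']}\t{row['parent']}\n")
    manifest = {"spec": asdict(spec),
                "counts": {"panel": len(panel), "library": len(library),
                           "corpus": len(corpus)}}
    (out / "fixtures.json").write_text(json.dumps(manifest, indent=2))
    return manifest
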