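"""The three molecular representations used by the screen.

1D — substructure-sentence embeddings: every heavy atom contributes one
circular-environment identifier per radius 0..R (Morgan hashes), the ordered
identifier list is the molecule's "sentence", and a skip-gram model trained
on a corpus of such sentences yields token vectors; a molecule's vector is
the sum of its token vectors.

2D — pharmacophore-pair fingerprint: pairs of typed features (H-bond donor /
acceptor, aromatic, hydrophobe, positively / negatively ionizable) combined
with binned topological (bond-path) distances, as a sparse count vector.

3D — conformer feature-map fingerprint: per conformer, typed feature points
are accumulated into a feature-type x radial-shell histogram around the
feature centroid with Gaussian distance smearing; conformers are averaged
and the result normalized to unit Euclidean norm.

Each representation is exposed both as a function and as an sklearn-style
transformer (fit/transform) so the channels compose with sklearn pipelines.
"""

from __future__ import annotations

import logging
import os
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem, RDConfig
from rdkit.Chem import AllChem, ChemicalFeatures, rdFingerprintGenerator
from sklearn.base import BaseEstimator, TransformerMixin

from . import word2vec
from .chem_io import MoleculeRecord
from .errors import ConfigError
from .word2vec import SgnsHyperparameters

logger = logging.getLogger(__name__)

KIND_EMBED1D = "embed1d"
KIND_PHARM2D = "pharm2d"
KIND_SHAPE3D = "shape3d"

#: Pharmacophore families used by the 2D and 3D channels, in fixed order.
FEATURE_FAMILIES = ("Donor", "Acceptor", "Aromatic", "Hydrophobe",
                    "PosIonizable", "NegIonizable")

_FEATURE_FACTORY = ChemicalFeatures.BuildFeatureFactory(
    os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
)


@dataclass
class RepresentationVector:
    """One per-molecule vector: dense (embed1d, shape3d) or sparse (pharm2d).

    For ``pharm2d`` ``values`` is a dict mapping feature index -> count;
    for the dense kinds it is a float ndarray of length ``dim``.
    """

    kind: str
    values: np.ndarray | dict[int, int]
    dim: int

    @property
    def on_bits(self) -> frozenset[int]:
        if self.kind != KIND_PHARM2D:
            raise ConfigError("on_bits is defined for pharm2d vectors only")
        return frozenset(self.values)


@dataclass(frozen=True)
class SubstructureSentence:
    """Ordered substructure tokens of one molecule (atom-major, radii interleaved)."""

    tokens: tuple[str, ...]


def _mol_from_record(mol_or_record) -> Chem.Mol:
    if isinstance(mol_or_record, MoleculeRecord):
        if not mol_or_record.ok:
            raise ConfigError(f"record {mol_or_record.id} has status {mol_or_record.status}")
        mol = mol_or_record.mol()
    elif isinstance(mol_or_record, str):
        mol = Chem.MolFromSmiles(mol_or_record)
    else:
        mol = mol_or_record
    if mol is None:
        raise ConfigError("invalid molecule input")
    return mol


def sentence(mol, radius: int = 1) -> SubstructureSentence:
    """Substructure sentence: per-atom Morgan environment identifiers, radii 0..R.

    Tokens are emitted atom-major with radii interleaved
    (atom1-r0, atom1-r1, ..., atom2-r0, ...). An atom whose environment does
    not extend to some radius (an isolated atom at r=1, say) reuses its
    deepest available identifier so the token count is always
    ``n_heavy_atoms * (radius + 1)``.
    """
    if radius < 0:
        raise ConfigError(f"substructure radius must be >= 0, got {radius}")
    m = _mol_from_record(mol)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    gen.GetSparseCountFingerprint(m, additionalOutput=ao)
    env: dict[tuple[int, int], int] = {}
    for identifier, hits in ao.GetBitInfoMap().items():
        for atom_idx, r in hits:
            env[(atom_idx, r)] = identifier
    tokens: list[str] = []
    for atom_idx in range(m.GetNumHeavyAtoms()):
        last = None
        for r in range(radius + 1):
            ident = env.get((atom_idx, r), last)
            if ident is None:  # unreachable for sanitized molecules at r=0
                ident = 0
            tokens.append(str(ident))
            last = ident
    return SubstructureSentence(tokens=tuple(tokens))


class Mol2vecEncoder(BaseEstimator, TransformerMixin):
    """Substructure-sentence embedding model (the 1D channel).

    ``fit`` trains skip-gram-with-negative-sampling token vectors on the
    substructure sentences of a corpus; ``transform`` embeds molecules by
    summing the vectors of their tokens. Out-of-vocabulary tokens are
    handled per ``unk_policy``: ``"skip"`` (contribute nothing, default) or
    ``"zero_vector"``. An all-out-of-vocabulary molecule embeds to the zero
    vector with a warning.

    Parameters
    ----------
    radius : int
        Circular-environment radius R; tokens cover radii 0..R.
    vector_size, window, min_count, epochs, negative, alpha, seed :
        Skip-gram hyperparameters; fixed seed + single worker give
        bit-reproducible training.
    """

    def __init__(self, radius: int = 1, vector_size: int = 100, window: int = 10,
                 min_count: int = 1, epochs: int = 5, negative: int = 5,
                 alpha: float = 0.025, seed: int = 0, unk_policy: str = "skip"):
        self.radius = radius
        self.vector_size = vector_size
        self.window = window
        self.min_count = min_count
        self.epochs = epochs
        self.negative = negative
        self.alpha = alpha
        self.seed = seed
        self.unk_policy = unk_policy

    def _hp(self) -> SgnsHyperparameters:
        return SgnsHyperparameters(vector_size=self.vector_size, window=self.window,
                                   min_count=self.min_count, epochs=self.epochs,
                                   negative=self.negative, alpha=self.alpha,
                                   seed=self.seed)

    def fit(self, X: Sequence, y=None):
        """Train on a corpus of molecules (records / SMILES) or pre-built sentences."""
        if self.unk_policy not in ("skip", "zero_vector"):
            raise ConfigError(f"unknown unk_policy {self.unk_policy!r}")
        sents = [s.tokens if isinstance(s, SubstructureSentence)
                 else sentence(s, self.radius).tokens for s in X]
        vocab, counts, vectors = word2vec.train_sgns(sents, self._hp())
        self.vocabulary_ = {t: i for i, t in enumerate(vocab)}
        self.counts_ = counts
        self.vectors_ = vectors
        return self

    def embed_sentence(self, s: SubstructureSentence) -> RepresentationVector:
        """Molecule vector = sum of token vectors (the summing rule)."""
        v = np.zeros(self.vectors_.shape[1])
        n_known = 0
        for tok in s.tokens:
            i = self.vocabulary_.get(tok)
            if i is not None:
                v += self.vectors_[i]
                n_known += 1
            elif self.unk_policy == "zero_vector":
                n_known += 1  # contributes an explicit zero vector
        if n_known == 0 and s.tokens:
            logger.warning("all %d tokens out of vocabulary; zero embedding", len(s.tokens))
        return RepresentationVector(kind=KIND_EMBED1D, values=v, dim=v.size)

    def transform(self, X: Sequence) -> np.ndarray:
        """Embed molecules; returns an (n, vector_size) dense array."""
        rows = []
        for x in X:
            s = x if isinstance(x, SubstructureSentence) else sentence(x, self.radius)
            rows.append(self.embed_sentence(s).values)
        return np.asarray(rows)

    def save(self, path, card_lines: Sequence[str] = ()) -> None:
        vocab = [t for t, _ in sorted(self.vocabulary_.items(), key=lambda kv: kv[1])]
        word2vec.save_model(path, vocab, self.counts_, self.vectors_, self._hp(),
                            card_lines=card_lines)

    @classmethod
    def load(cls, path, radius: int | None = None, unk_policy: str = "skip"):
        vocab, counts, vectors, hp = word2vec.load_model(path)
        enc = cls(radius=1 if radius is None else radius, vector_size=hp.vector_size,
                  window=hp.window, min_count=hp.min_count, epochs=hp.epochs,
                  negative=hp.negative, alpha=hp.alpha, seed=hp.seed,
                  unk_policy=unk_policy)
        enc.vocabulary_ = {t: i for i, t in enumerate(vocab)}
        enc.counts_ = counts
        enc.vectors_ = vectors
        return enc


def embed_molecule(model: Mol2vecEncoder, s: SubstructureSentence) -> RepresentationVector:
    """Functional wrapper over :meth:`Mol2vecEncoder.embed_sentence`."""
    return model.embed_sentence(s)


@dataclass(frozen=True)
class Pharm2DScheme:
    """2D pharmacophore-pair fingerprint scheme.

    Distances are topological (shortest bond path); bins are
    1,2,...,``n_bins - 1`` bonds plus one overflow bin for longer paths.
    Pair indices pack (type_i, type_j, bin) injectively into
    ``fingerprint_size`` positions.
    """

    fingerprint_size: int = 2048
    n_bins: int = 8


# ring hydrophobes come back as "LumpedHydrophobe"; fold them into Hydrophobe
_FAMILY_TO_TYPE = {fam: i for i, fam in enumerate(FEATURE_FAMILIES)}
_FAMILY_TO_TYPE["LumpedHydrophobe"] = FEATURE_FAMILIES.index("Hydrophobe")


def _typed_features(mol: Chem.Mol):
    feats = []
    for f in _FEATURE_FACTORY.GetFeaturesForMol(mol):
        ti = _FAMILY_TO_TYPE.get(f.GetFamily())
        if ti is not None:
            feats.append((ti, f))
    return feats


def pharm2d_fingerprint(mol, scheme: Pharm2DScheme = Pharm2DScheme()) -> RepresentationVector:
    """Sparse count vector over (feature-type pair, binned topological distance).

    A molecule with no typed features yields the all-zero fingerprint
    (flagged by a log warning); similarity against it is defined as 0.
    """
    m = _mol_from_record(mol)
    feats = _typed_features(m)
    counts: dict[int, int] = {}
    if not feats:
        logger.warning("no pharmacophoric features; empty 2D fingerprint")
        return RepresentationVector(kind=KIND_PHARM2D, values=counts,
                                    dim=scheme.fingerprint_size)
    dmat = Chem.GetDistanceMatrix(m)
    n_types = len(FEATURE_FAMILIES)
    for a in range(len(feats)):
        for b in range(a + 1, len(feats)):
            ti, fa = feats[a]
            tj, fb = feats[b]
            d = min(int(dmat[i][j]) for i in fa.GetAtomIds() for j in fb.GetAtomIds())
            # overlapping features (d == 0) fall in the 1-bond bin
            bin_idx = min(max(d, 1), scheme.n_bins) - 1
            lo, hi = sorted((ti, tj))
            idx = (lo * n_types + hi) * scheme.n_bins + bin_idx
            counts[idx] = counts.get(idx, 0) + 1
    return RepresentationVector(kind=KIND_PHARM2D, values=counts,
                                dim=scheme.fingerprint_size)


class Pharm2DFingerprinter(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer over :func:`pharm2d_fingerprint`."""

    def __init__(self, fingerprint_size: int = 2048, n_bins: int = 8):
        self.fingerprint_size = fingerprint_size
        self.n_bins = n_bins

    def fit(self, X, y=None):
        return self

    def _scheme(self) -> Pharm2DScheme:
        return Pharm2DScheme(fingerprint_size=self.fingerprint_size, n_bins=self.n_bins)

    def transform(self, X: Sequence) -> list[RepresentationVector]:
        return [pharm2d_fingerprint(x, self._scheme()) for x in X]


@dataclass(frozen=True)
class Shape3DScheme:
    """Feature-map scheme: feature types x radial shells from the feature centroid."""

    n_shells: int = 8
    shell_width: float = 0.5   # Angstrom
    sigma: float = 0.25        # Gaussian smear of feature distances, Angstrom
    n_conformers: int = 10


def molecule_seed(global_seed: int, compound_id: str) -> int:
    """Per-molecule conformer seed: global seed XOR CRC32 of the compound ID."""
    return (int(global_seed) ^ zlib.crc32(compound_id.encode())) & 0x7FFFFFFF


def shape3d_fingerprint(mol, n_conf: int | None = None, seed: int = 0,
                        scheme: Shape3DScheme = Shape3DScheme()) -> RepresentationVector | None:
    """3D conformer feature-map vector; None when the channel is unavailable.

    Embeds up to ``n_conf`` conformers (deterministic distance geometry with
    the given seed), accumulates Gaussian-weighted typed feature points into
    a feature-type x radial-shell histogram per conformer, averages over
    conformers and normalizes to unit Euclidean norm.

    Returns None — a *missing* 3D channel, not a zero score — when conformer
    embedding fails entirely or the molecule has no typed feature points.
    """
    n_conf = scheme.n_conformers if n_conf is None else n_conf
    if n_conf < 1:
        raise ConfigError(f"n_conf must be >= 1, got {n_conf}")
    m0 = _mol_from_record(mol)
    m = Chem.AddHs(m0)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    cids = AllChem.EmbedMultipleConfs(m, numConfs=n_conf, params=params)
    if len(cids) == 0:
        params.useRandomCoords = True
        cids = AllChem.EmbedMultipleConfs(m, numConfs=n_conf, params=params)
    if len(cids) == 0:
        logger.warning("conformer embedding failed; 3D channel missing")
        return None

    # type features on the heavy-atom molecule (identical typing to the 2D
    # channel); AddHs keeps heavy-atom indices, so conformer positions apply
    feats = _typed_features(m0)
    if not feats:
        logger.warning("no pharmacophoric features; 3D channel missing")
        return None

    n_types = len(FEATURE_FAMILIES)
    shell_centers = (np.arange(scheme.n_shells) + 0.5) * scheme.shell_width
    r_max = shell_centers[-1]
    acc = np.zeros((len(cids), n_types * scheme.n_shells))
    for k, cid in enumerate(cids):
        conf = m.GetConformer(cid)
        pts = []
        for ti, f in feats:
            xyz = np.mean([np.array(conf.GetAtomPosition(i)) for i in f.GetAtomIds()],
                          axis=0)
            pts.append((ti, xyz))
        centroid = np.mean([p for _, p in pts], axis=0)
        for ti, xyz in pts:
            r = min(float(np.linalg.norm(xyz - centroid)), r_max)
            w = np.exp(-((r - shell_centers) ** 2) / (2.0 * scheme.sigma ** 2))
            acc[k, ti * scheme.n_shells:(ti + 1) * scheme.n_shells] += w
    v = acc.mean(axis=0)
    norm = np.linalg.norm(v)
    if norm == 0.0:
        return None
    return RepresentationVector(kind=KIND_SHAPE3D, values=v / norm, dim=v.size)


class Shape3DFingerprinter(BaseEstimator, TransformerMixin):
    """Sklearn transformer over :func:`shape3d_fingerprint`.

    ``transform`` expects MoleculeRecords (the per-molecule conformer seed is
    derived from the compound ID so results do not depend on library order);
    unavailable channels come back as None entries.
    """

    def __init__(self, n_conformers: int = 10, n_shells: int = 8,
                 shell_width: float = 0.5, sigma: float = 0.25, seed: int = 0):
        self.n_conformers = n_conformers
        self.n_shells = n_shells
        self.shell_width = shell_width
        self.sigma = sigma
        self.seed = seed

    def fit(self, X, y=None):
        return self

    def _scheme(self) -> Shape3DScheme:
        return Shape3DScheme(n_shells=self.n_shells, shell_width=self.shell_width,
                             sigma=self.sigma, n_conformers=self.n_conformers)

    def transform(self, X: Sequence[MoleculeRecord]) -> list[RepresentationVector | None]:
        out = []
        for rec in X:
            cid = rec.id if isinstance(rec, MoleculeRecord) else str(rec)
            out.append(shape3d_fingerprint(rec, seed=molecule_seed(self.seed, cid),
                                           scheme=self._scheme()))
        return out
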