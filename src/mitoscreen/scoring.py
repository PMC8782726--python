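"""Similarity scoring, the hyper-space filter and candidate ranking.

The similarity between an inductor (reference) vector v and a compound
vector w is their dot product after normalization: cosine similarity for the
dense channels (negative cosines clamp to 0 so scores live in [0, 1]) and
the Tanimoto coefficient for the sparse 2D pharmacophore channel.

The hyper-space filter zeroes scores below the cut-off theta and zeroes
exact matches (s = 1): the screen looks for novel analogues of known
actives, so a compound identical to a reference is rejected, and weakly
similar compounds are dropped.

``VirtualScreen`` is the sklearn-style estimator tying it together: ``fit``
on the reference-actives panel, ``score_library`` on a screening library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .chem_io import MoleculeRecord, RESULT_COLUMNS
from .config import ScreeningConfig
from .errors import ConfigError, EmptyResultError, InputError
from .representations import (
    KIND_EMBED1D, KIND_PHARM2D, KIND_SHAPE3D,
    Mol2vecEncoder, Pharm2DFingerprinter, RepresentationVector,
    Shape3DFingerprinter, sentence,
)

logger = logging.getLogger(__name__)

CHANNELS = (KIND_EMBED1D, KIND_PHARM2D, KIND_SHAPE3D)
_CHANNEL_COLUMN = {KIND_EMBED1D: "s1d", KIND_PHARM2D: "s2d", KIND_SHAPE3D: "s3d"}

#: tolerance for the exact-match (s = 1) branch of the filter
EXACT_MATCH_TOL = 1e-9


@dataclass
class SimilarityScore:
    """One (compound, reference, representation) similarity."""

    compound_id: str
    reference_id: str | None
    representation: str
    s_raw: float | None
    s_filtered: float


def tanimoto(a: frozenset[int] | set[int], b: frozenset[int] | set[int]) -> float:
    """|A n B| / |A u B|; defined as 0 when either set is empty."""
    if not a or not b:
        return 0.0
    inter = len(a & b)
    return inter / (len(a) + len(b) - inter)


def cosine_clamped(v: np.ndarray, w: np.ndarray) -> float:
    """Dot product of the unit-normalized vectors, clamped to [0, 1]."""
    nv, nw = np.linalg.norm(v), np.linalg.norm(w)
    if nv == 0.0 or nw == 0.0:
        logger.warning("zero vector in dense similarity; score 0")
        return 0.0
    c = float(np.dot(v, w) / (nv * nw))
    return min(max(c, 0.0), 1.0)


def similarity(v: RepresentationVector, w: RepresentationVector) -> float:
    """Similarity in [0, 1] between two same-kind representation vectors."""
    if v.kind != w.kind:
        raise ConfigError(f"representation kind mismatch: {v.kind} vs {w.kind}")
    if v.kind == KIND_PHARM2D:
        return tanimoto(v.on_bits, w.on_bits)
    return cosine_clamped(np.asarray(v.values, dtype=float),
                          np.asarray(w.values, dtype=float))


def hyperspace_filter(s: float, theta: float) -> float:
    """The piecewise hyper-space filter: 0 at s = 1, s on [theta, 1), else 0.

    s = 1 is tested with a 1e-9 tolerance (cosines of identical vectors can
    differ in the last bits). A score outside [0, 1] beyond 1e-9 signals an
    unnormalized similarity upstream and is fatal.
    """
    if not (0.0 < theta < 1.0):
        raise ConfigError(f"theta must lie in (0, 1), got {theta}")
    if s < -EXACT_MATCH_TOL or s > 1.0 + EXACT_MATCH_TOL:
        raise ConfigError(f"similarity {s} outside [0, 1]: unnormalized input")
    s = min(max(s, 0.0), 1.0)
    if abs(s - 1.0) <= EXACT_MATCH_TOL:
        return 0.0
    if s >= theta:
        return s
    return 0.0


def best_reference_score(
    compound_id: str,
    compound_reps: dict[str, RepresentationVector | None],
    reference_reps: dict[str, Sequence[RepresentationVector | None]],
    reference_ids: Sequence[str],
    combine: str = "max",
) -> dict[str, SimilarityScore]:
    """Per channel, the best (default max) similarity over the reference panel.

    A missing representation (failed 3D embedding, say) leaves that channel's
    score as None — missing, never zero.
    """
    if not reference_ids:
        raise InputError("reference panel is empty")
    out: dict[str, SimilarityScore] = {}
    for kind in CHANNELS:
        comp = compound_reps.get(kind)
        if comp is None:
            out[kind] = SimilarityScore(compound_id, None, kind, None, 0.0)
            continue
        pair_scores = []
        for rid, ref in zip(reference_ids, reference_reps[kind]):
            if ref is None:
                continue
            pair_scores.append((similarity(ref, comp), rid))
        if not pair_scores:
            out[kind] = SimilarityScore(compound_id, None, kind, None, 0.0)
            continue
        if combine == "max":
            s, rid = max(pair_scores, key=lambda t: (t[0], t[1]))
        elif combine == "mean":
            s = float(np.mean([t[0] for t in pair_scores]))
            rid = max(pair_scores, key=lambda t: (t[0], t[1]))[1]
        else:
            raise ConfigError(f"unknown reference combine rule {combine!r}")
        out[kind] = SimilarityScore(compound_id, rid, kind, s, 0.0)
    return out


def aggregate_filtered(scores: dict[str, SimilarityScore],
                       cfg: ScreeningConfig) -> float | None:
    """Filter each channel's raw score, then combine over available channels.

    Weights renormalize over the available channels; ``min`` takes the worst
    filtered channel. Returns None when no channel is available (the compound
    is excluded from ranking upstream). ``rank_mean`` is cohort-relative and
    handled in :meth:`VirtualScreen.score_library`.
    """
    weights = dict(zip(CHANNELS, cfg.representation_weights))
    filt, w = [], []
    for kind in CHANNELS:
        sc = scores[kind]
        if sc.s_raw is None:
            continue
        sc.s_filtered = hyperspace_filter(sc.s_raw, cfg.theta)
        filt.append(sc.s_filtered)
        w.append(weights[kind])
    if not filt:
        return None
    if cfg.aggregate_rule == "min":
        return float(min(filt))
    total = sum(w)
    if total == 0.0:
        return float(np.mean(filt))
    return float(np.dot(filt, w) / total)


def _stack_space(embed: np.ndarray, pharm_sets: Sequence[frozenset[int]],
                 pharm_dim: int, shape: Sequence[np.ndarray | None],
                 shape_dim: int) -> np.ndarray:
    """Concatenated, per-channel unit-normalized representation space."""

    def unit_rows(mat):
        norms = np.linalg.norm(mat, axis=1, keepdims=True)
        norms[norms == 0.0] = 1.0
        return mat / norms

    n = len(pharm_sets)
    p = np.zeros((n, pharm_dim))
    for i, bits in enumerate(pharm_sets):
        for b in bits:
            p[i, b] = 1.0
    s = np.zeros((n, shape_dim))
    for i, v in enumerate(shape):
        if v is not None:
            s[i] = v
    return np.hstack([unit_rows(np.asarray(embed, dtype=float)), unit_rows(p), unit_rows(s)])


def mad_outliers(cohort: np.ndarray, reference: np.ndarray, k: float) -> np.ndarray:
    """Robust outlier flags: distance to the reference centroid beyond
    median + k * (scaled MAD) of the reference panel's own distances.

    A degenerate panel (MAD = 0) disables outlier detection with a warning.
    """
    centroid = reference.mean(axis=0)
    ref_d = np.linalg.norm(reference - centroid, axis=1)
    med = float(np.median(ref_d))
    mad = float(np.median(np.abs(ref_d - med))) * 1.4826
    if mad == 0.0:
        logger.warning("degenerate reference panel (MAD = 0); outlier detection disabled")
        return np.zeros(cohort.shape[0], dtype=bool)
    d = np.linalg.norm(cohort - centroid, axis=1)
    return d > med + k * mad


class VirtualScreen(BaseEstimator):
    """Three-channel ligand-based screen against a reference-actives panel.

    ``fit`` computes the three representations of the reference panel using a
    trained :class:`Mol2vecEncoder` plus the 2D/3D fingerprinters;
    ``score_library`` then scores a screening library compound-by-compound:
    per-channel best-reference similarity, hyper-space filtering at
    ``config.theta``, weighted aggregation, robust (median/MAD) outlier
    flagging in the concatenated representation space, and ranking.

    Fitted attributes carry a trailing underscore (``reference_ids_``,
    ``reference_reps_``, ...).
    """

    def __init__(self, encoder: Mol2vecEncoder | None = None,
                 config: ScreeningConfig | None = None):
        self.encoder = encoder
        self.config = config

    def _cfg(self) -> ScreeningConfig:
        return self.config if self.config is not None else ScreeningConfig()

    def _compute_reps(self, records: Sequence[MoleculeRecord]):
        cfg = self._cfg()
        if self.encoder is None:
            raise ConfigError("VirtualScreen needs a trained Mol2vecEncoder")
        embed = self.encoder.transform(records)
        pharm = Pharm2DFingerprinter(fingerprint_size=cfg.fingerprint_size).transform(records)
        shape = Shape3DFingerprinter(n_conformers=cfg.n_conformers,
                                     seed=cfg.seed).transform(records)
        reps = {
            KIND_EMBED1D: [RepresentationVector(KIND_EMBED1D, row, row.size)
                           for row in embed],
            KIND_PHARM2D: pharm,
            KIND_SHAPE3D: shape,
        }
        return reps, embed, [p.on_bits for p in pharm], \
            [None if s is None else np.asarray(s.values) for s in shape]

    def fit(self, references: Sequence[MoleculeRecord], y=None):
        refs = [r for r in references if r.ok]
        if not refs:
            raise InputError("reference panel contains no valid molecules")
        self.reference_ids_ = [r.id for r in refs]
        (self.reference_reps_, self._ref_embed, self._ref_bits,
         self._ref_shape) = self._compute_reps(refs)
        return self

    def score_library(self, library: Sequence[MoleculeRecord]) -> pd.DataFrame:
        """Full ranking table over the library (one row per scoreable compound)."""
        cfg = self._cfg()
        records = [r for r in library if r.ok]
        if not records:
            raise EmptyResultError("screening library contains no valid molecules")
        reps, embed, bits, shape = self._compute_reps(records)

        rows = []
        per_channel_filtered: dict[str, list[float | None]] = {c: [] for c in CHANNELS}
        kept_idx = []
        for i, rec in enumerate(records):
            comp = {k: reps[k][i] for k in CHANNELS}
            if all(comp[k] is None for k in CHANNELS):
                logger.warning("compound %s has no available representation; excluded",
                               rec.id)
                continue
            scores = best_reference_score(rec.id, comp, self.reference_reps_,
                                          self.reference_ids_, cfg.ref_combine)
            agg = aggregate_filtered(scores, cfg)
            row = {"compound_id": rec.id, "canonical_smiles": rec.canonical_smiles}
            for kind in CHANNELS:
                col = _CHANNEL_COLUMN[kind]
                sc = scores[kind]
                row[f"{col}_raw"] = np.nan if sc.s_raw is None else sc.s_raw
                row[f"{col}_ref"] = "" if sc.reference_id is None else sc.reference_id
                per_channel_filtered[kind].append(
                    None if sc.s_raw is None else sc.s_filtered)
            row["s_aggregate"] = agg
            rows.append(row)
            kept_idx.append(i)

        if not rows:
            raise EmptyResultError("no library compound has any available representation")
        df = pd.DataFrame(rows)

        if cfg.aggregate_rule == "rank_mean":
            df["s_aggregate"] = self._rank_mean(per_channel_filtered)

        # outlier flags in the concatenated, per-channel-normalized space
        cohort = _stack_space(embed[kept_idx], [bits[i] for i in kept_idx],
                              cfg.fingerprint_size,
                              [shape[i] for i in kept_idx],
                              Shape3DFingerprinter().n_shells * 6)
        panel = _stack_space(self._ref_embed, self._ref_bits, cfg.fingerprint_size,
                             self._ref_shape, Shape3DFingerprinter().n_shells * 6)
        df["outlier_flag"] = mad_outliers(cohort, panel, cfg.outlier_mad_k)
        self.cluster_labels_ = self._cluster(cohort, cfg)
        self._space = cohort

        df["filtered_score"] = [hyperspace_filter(a, cfg.theta) for a in df["s_aggregate"]]
        passed = df["filtered_score"] >= cfg.theta
        if cfg.threshold_mode == "per_channel":
            for kind in CHANNELS:
                ch = pd.Series(per_channel_filtered[kind], index=df.index)
                passed &= ch.isna() | (ch.astype(float) >= cfg.theta)
        df["pass"] = passed & ~df["outlier_flag"]

        df = df.sort_values(["s_aggregate", "compound_id"],
                            ascending=[False, True], kind="mergesort")
        df["rank"] = np.arange(1, len(df) + 1)
        return df.reset_index(drop=True).loc[:, RESULT_COLUMNS]

    @staticmethod
    def _rank_mean(per_channel: dict[str, list[float | None]]) -> np.ndarray:
        """Cohort-relative aggregate: mean percentile of the filtered scores."""
        n = len(next(iter(per_channel.values())))
        mat = np.full((n, len(CHANNELS)), np.nan)
        for j, kind in enumerate(CHANNELS):
            vals = per_channel[kind]
            avail = np.array([v is not None for v in vals])
            x = np.array([0.0 if v is None else v for v in vals])
            r = pd.Series(x[avail]).rank(method="average", pct=True).to_numpy()
            col = np.full(n, np.nan)
            col[avail] = r
            mat[:, j] = col
        return np.nanmean(mat, axis=1)

    def _cluster(self, cohort: np.ndarray, cfg: ScreeningConfig) -> np.ndarray:
        """Cluster labels in the aggregated space — reporting only, never a filter."""
        k = min(8, cohort.shape[0])
        km = KMeans(n_clusters=k, random_state=cfg.seed, n_init=10)
        return km.fit_predict(cohort)

    def candidates(self, ranking: pd.DataFrame) -> pd.DataFrame:
        """Passing compounds, optionally truncated at config.top_n."""
        cfg = self._cfg()
        out = ranking[ranking["pass"]]
        if cfg.top_n is not None:
            out = out.head(cfg.top_n)
        return out

    def single_channel_ranking(self, library: Sequence[MoleculeRecord],
                               representation: str, k: int) -> pd.DataFrame:
        """Ablation mode: rank by one channel's filtered best-reference score.

        Returns the top-k rows (full ranking with a warning when k exceeds
        the library size), mirroring a per-approach top-k comparison.
        """
        if representation not in CHANNELS:
            raise ConfigError(f"unknown representation {representation!r}")
        cfg = self._cfg()
        records = [r for r in library if r.ok]
        reps, _, _, _ = self._compute_reps(records)
        rows = []
        for i, rec in enumerate(records):
            comp = reps[representation][i]
            if comp is None:
                continue
            scores = best_reference_score(
                rec.id, {representation: comp}, self.reference_reps_,
                self.reference_ids_, cfg.ref_combine)
            sc = scores[representation]
            filt = hyperspace_filter(sc.s_raw, cfg.theta)
            rows.append({"compound_id": rec.id, "representation": representation,
                         "s_raw": sc.s_raw, "s_filtered": filt,
                         "best_reference": sc.reference_id})
        df = pd.DataFrame(rows).sort_values(
            ["s_filtered", "compound_id"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        if k > len(df):
            logger.warning("top-k %d exceeds library size %d; returning full ranking",
                           k, len(df))
            return df
        return df.head(k)


def rank_candidates(aggregates: pd.DataFrame, cfg: ScreeningConfig) -> pd.DataFrame:
    """Sort a scored table into the final ranking (ties by compound ID).

    ``pass`` is recomputed as filtered aggregate >= theta and not an outlier;
    lowering theta never removes a previously passing compound.
    """
    df = aggregates.copy()
    df["filtered_score"] = [hyperspace_filter(a, cfg.theta) for a in df["s_aggregate"]]
    df["pass"] = (df["filtered_score"] >= cfg.theta) & ~df["outlier_flag"].astype(bool)
    df = df.sort_values(["s_aggregate", "compound_id"],
                        ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)
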