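# Methods

## The screening model

mitoscreen implements similarity-based virtual screening for the
few-reference regime: a panel of known actives (here, mitophagy inducers),
an unlabelled pre-training corpus, and a screening library. No activity
model is fit; the assumption is the classic similarity principle — close
structural neighbours of an active are enriched in actives — sharpened by a
novelty requirement: a compound *identical* to a known active is useless as
a discovery, so exact matches are rejected rather than top-ranked.

Per library compound the screen computes, for each representation channel,
the best similarity over the reference panel (max by default; mean is
available), applies the piecewise hyper-space filter

    filter(s; θ) = 0 if s = 1,  s if θ ≤ s < 1,  0 if s < θ

and averages the filtered channel scores with configurable weights
(renormalized over the channels actually available for that compound).
A compound passes when the filtered aggregate is ≥ θ and it is not an
outlier. The similarity "dot product" is made well-defined on [0, 1] by
normalization: cosine (clamped at 0) for the dense 1D/3D channels, Tanimoto
on feature sets for the sparse 2D channel — the only reading under which
the filter's case s = 1 and bound s ≤ 1 are meaningful.

Equality with 1 is tested at tolerance 1e-9: the cosine of two identical
vectors can differ from 1 in the last bits, and the duplicate-rejection
branch must still fire. Scores outside [0, 1] beyond that tolerance are a
programming error upstream and abort the run.

### Threshold semantics

θ (default 0.75) can be applied to the combined aggregate (default) or
additionally per channel (`threshold_mode: per_channel`). Lowering θ never
shrinks the passing set: each channel's filtered score is non-decreasing as
θ decreases, hence so is the aggregate, while the pass threshold drops.

### Outlier flagging and clustering

Compounds are placed in a concatenated representation space (each channel's
vector unit-normalized: the d-dim embedding, the binarized 2048-bit 2D
fingerprint, the 48-dim feature map; a missing channel contributes zeros).
A compound is flagged when its Euclidean distance to the reference-panel
centroid exceeds median + k·MAD (scaled by 1.4826) of the panel's own
distances, k = 3.5 by default. A degenerate panel (MAD = 0) disables
flagging with a warning rather than flagging everything. KMeans cluster
labels in the same space are recorded for reporting only; no filtering
decision depends on them.

## The three channels

**1D.** Substructure sentences list one Morgan environment identifier per
heavy atom per radius 0..R (default R = 1), atom-major with radii
interleaved. RDKit omits identifiers for atoms whose environment does not
extend to a radius (an isolated atom at r = 1); such positions reuse the
atom's deepest available identifier so the token count is always
n_heavy·(R+1). Token vectors come from an in-package
skip-gram-with-negative-sampling trainer (numpy, single-threaded):
vector_size 100, window 10, min_count 1, 5 epochs, 5 negatives, linear
learning-rate decay from 0.025. Two classic word2vec ingredients are
deliberately omitted for bit-reproducibility — per-position random window
shrinking and frequent-token subsampling — and updates are mini-batch SGD
with per-parameter-row gradient averaging (summed updates for very frequent
tokens diverge). min_count defaults to 1 because desk-scale corpora are
small; raise it for large corpora. A molecule's embedding is the sum of its
token vectors; out-of-vocabulary tokens contribute nothing under the default
`skip` policy (`zero_vector` is offered for ablation), and an all-OOV
molecule embeds to the zero vector with a warning (its 1D similarity is then
0, not missing).

**2D.** Feature typing uses RDKit's default feature definitions restricted
to six families — Donor, Acceptor, Aromatic, Hydrophobe (ring hydrophobes
reported as "LumpedHydrophobe" are folded in), PosIonizable, NegIonizable.
For every feature pair the topological distance is the shortest bond path
between their atom sets, binned at 1..7 bonds plus an overflow bin (features
sharing atoms, distance 0, fall in the first bin). The (type_i, type_j, bin)
triple packs injectively into a 2048-length sparse count vector; with 6
types and 8 bins only 288 cells are addressable, so a lossy hash fold would
add collisions without benefit. Similarity binarizes to the on-bit sets
(Tanimoto). A molecule with no typed features has the empty fingerprint and
similarity 0 by definition.

**3D.** Up to 10 conformers per molecule are embedded with ETKDGv3
(hydrogens added; the per-molecule seed is the global seed XOR CRC32 of the
compound ID, so results are independent of library order). Feature typing
runs on the heavy-atom molecule — identical typing to the 2D channel. Per
conformer, each feature point (mean position of its atoms) at distance r
from the feature-point centroid adds Gaussian weight exp(−(r−c)²/2σ²) to
each shell center c (8 shells of 0.5 Å, σ = 0.25 Å, r clamped to the last
shell center); this gives a 6-type × 8-shell = 48-long map, averaged over
conformers and unit-normalized. This is one concrete member of the family of
published feature-map descriptors, chosen for testability; the interface
accepts any fixed-length alternative. Whether one or several conformers best
represents a molecule is genuinely open; averaging over up to 10 is the
default here, and a rigid molecule's aggregate equals its single-conformer
map. If conformer embedding fails entirely, or the molecule has no typed
feature points (no unit-norm map exists), the 3D channel is *missing*:
aggregation renormalizes over the remaining channels rather than punishing
the compound with a zero.

## Standardization and corpus curation

Standardization keeps the largest fragment (salts and solvates stripped;
equal-size ties broken by lexicographically smaller canonical SMILES, with a
log flag), neutralizes charges, and emits RDKit canonical SMILES; it is
idempotent, and stereochemistry is preserved when present but never
required. Corpus curation before pre-training retains molecules over the
element whitelist {H, B, C, N, O, F, P, S, Cl, Br, I} with 3–100 heavy
atoms, single-fragment, deduplicated on canonical SMILES (the dedup switch
is exposed; default on). Every rule is configurable because real corpus
curation pipelines differ; the defaults are the common ones for
embedding-corpus preparation. Canonical SMILES are engine-specific, so run
manifests and model cards record the RDKit version.

## Synthetic study conditions

The fixtures module generates all inputs, so the full pipeline is testable
offline. The reference panel is 14 documented stand-in molecules
(REF01..REF14) spanning flavonol, stilbenoid, polyamine, amide, phenolic
acid, diketone, benzocoumarin, purine, biguanide, macrolactone, indole and
isothiocyanate chemotypes — synthetic placeholders chosen for structural
diversity, not claims about any published inducer identities. The default
screening library (192 compounds) plants, per reference, two analogues and
one exact duplicate, plus 150 decoys enumerated from ten scaffolds disjoint
from the panel's (pyridine, pyrimidine, thiophene, furan, piperidine,
morpholine, cyclohexane, naphthalene, pyrrolidine, tetrahydrofuran) with
1–3 random substituents. The pre-training corpus (default 2,000 molecules)
mixes the panel, dense analogue series around each reference and the same
scaffold–substituent enumeration, which keeps out-of-vocabulary tokens an
exercised edge case rather than the norm. Labels are written to a separate
TSV; the screen never sees ground truth.

Analogues are made by attaching substituents at C–H sites, which guarantees
chemical validity, and a candidate is accepted only while it stays in its
parent's analogue series: its canonical SMILES differs but its 2D
pharmacophore fingerprint stays within Tanimoto ≥ 0.6 of the parent (or is
identical — a one-methyl edit can leave typed features unchanged). The 0.6
floor is the usual 2D-similarity neighbourhood of a medicinal-chemistry
analogue series and mirrors the one-substituent relationships (e.g. a single
hydroxyl) that real analogue pairs exhibit; without it, heavy edits on small
parents produce "analogues" that are not analogues, i.e. mislabelled ground
truth. What passing tests on these fixtures shows is that the pipeline
separates in-neighbourhood analogues from out-of-neighbourhood decoys and
rejects exact duplicates; it does not show prospective enrichment on real
vendor libraries, where activity cliffs, tautomerism, conformational
flexibility and assay noise all bite.

One empirical property of the 1D channel is worth knowing: summed
substructure embeddings give high cosine similarity even between unrelated
molecules (frequent tokens dominate the sums), so the 1D channel separates
weakly on its own; discrimination in the combined screen comes mostly from
the 2D/3D channels, with the 1D channel contributing ordering within the
similar set. This matches the motivation for combining representations
rather than trusting any single one.

## Determinism

Fixed seeds make every stage bit-reproducible: embedding training (seeded
init and shuffling, deterministic accumulation, single thread), conformer
generation (per-molecule seeds), KMeans (fixed random_state), and the
results TSV (floats at 6 decimals, ties broken by compound ID). Two
pretrain+screen runs with the same seed produce byte-identical model vectors
and results tables; this is asserted by the test suite.

## Problem sizes

Defaults used throughout the tests: 2,000-molecule corpus, 14-reference
panel, 192-compound library, 100-dim embeddings, 10 conformers — a
desk-scale configuration of the method; the implementation itself is
size-agnostic and the corpus/library sizes are spec'd in `FixtureSpec` and
the CLI flags.

## Known limitations

- The encoder is the plain summing model; no learned encoder/decoder or
  graph network variants are included.
- 2D pharmacophore pairs only (no triples); topological distances ignore
  bond order and geometry.
- The 3D channel depends on distance-geometry conformers, not bioactive
  poses; no alignment or docking is attempted.
- Reference-panel aggregation by max makes the screen sensitive to any
  single mis-chosen reference.
- No InChI input, no reaction SMILES, no depiction.
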