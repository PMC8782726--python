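# mitoscreen

Ligand-based virtual screening for discovering novel mitophagy inducers —
small molecules that stimulate the selective autophagic clearance of damaged
mitochondria. Screening campaigns for this activity start from a handful of
known inducers (too few to train a supervised activity model), so mitoscreen
takes the similarity-search route: it represents every molecule in three
complementary ways, scores each library compound against a panel of known
reference actives, and keeps compounds that are *similar but not identical*
to a known inducer.

The three representation channels are:

1. **1D — substructure-sentence embeddings.** Each heavy atom contributes a
   circular-environment (Morgan) identifier at every radius 0..R; the ordered
   identifier list is the molecule's "sentence". A skip-gram model with
   negative sampling, trained on a large unlabelled corpus of such sentences,
   yields a vector per substructure token, and a molecule's vector is the
   **sum of its token vectors**.
2. **2D — pharmacophore-pair fingerprint.** Pairs of typed features (H-bond
   donor / acceptor, aromatic, hydrophobe, positively / negatively
   ionizable) combined with binned topological (bond-path) distances, as a
   sparse count vector.
3. **3D — conformer feature-map fingerprint.** For each distance-geometry
   conformer, typed feature points are accumulated into a feature-type ×
   radial-shell histogram around the feature centroid (Gaussian distance
   smearing), averaged over conformers and normalized to unit norm.

Scoring uses the dot product of normalized vectors,

    s = v · w          (cosine for dense channels, Tanimoto for the sparse 2D channel)

where *v* is a reference ("inductor") vector and *w* a library-compound
vector, taking the best score over the reference panel per channel. Each
channel then passes through the **hyper-space filter**

    filter(s) = 0  if s = 1        (exact match: not a *novel* analogue)
                s  if θ ≤ s < 1
                0  if s < θ        (too dissimilar)

with cut-off θ = 0.75 by default. Filtered channel scores are averaged
(weights configurable), robust median/MAD outlier flagging is applied in the
concatenated representation space, and compounds with aggregate ≥ θ that are
not outliers form the ranked candidate list.

## Worked example

Everything below runs on synthetic inputs generated by the package itself —
a 14-member reference panel (`REF01..REF14`), a 192-compound screening
library (28 planted analogues, 14 exact duplicates of the references, 150
decoys) and a 2,000-molecule pre-training corpus:

```sh
mitoscreen make-fixtures scratch/fx --seed 0
mitoscreen pretrain scratch/fx/corpus.smi scratch/model --seed 0
mitoscreen screen scratch/fx/library.smi scratch/fx/panel.smi scratch/model scratch/run --seed 0 --top-n 18
mitoscreen report scratch/run --top 5
```

which prints

```
trained embedding model: |vocab|=972, d=100 -> scratch/model
{
  "read": 192,
  "standardized_ok": 192,
  "scored": 192,
  "passed": 10,
  "outliers": 0,
  "candidates": 10
}
...
top 5 of 192 compounds:
compound_id                                              canonical_smiles  s1d_raw s1d_ref  s2d_raw s2d_ref  s3d_raw s3d_ref  s_aggregate ...  pass  rank
ANA-REF06-2 CCOc1cc(/C=C/C(=O)CC(=O)/C=C/c2ccc(O)c(OC)c2)c(C(C)C)c(OC)c1O 0.998532   REF04 0.976744   REF06 0.978206   REF06     0.984494 ...  True     1
ANA-REF01-2                   O=c1c(O)c(-c2cc(O)c(O)cc2S)oc2cc(O)cc(O)c12 0.999972   REF01 0.932203   REF01 0.964558   REF01     0.965578 ...  True     2
ANA-REF05-2                                 N#Cc1c(O)c(O)c(O)c(S)c1C(=O)O 0.999278   REF06 0.925000   REF05 0.957826   REF05     0.960701 ...  True     3
ANA-REF06-1 CCO/C(=C\c1ccc(O)c(OC)c1)C(=O)CC(=O)/C=C/c1cc(OC)c(O)c(OCC)c1 0.998246   REF04 0.893617   REF06 0.979452   REF06     0.957105 ...  True     4
ANA-REF01-1            CCc1c(O)cc(O)c2c(=O)c(O)c(-c3cc(O)c(O)c(F)c3C)oc12 0.999404   REF05 0.887097   REF01 0.959782   REF01     0.948761 ...  True     5
```

Reading the columns: `s1d_raw`/`s2d_raw`/`s3d_raw` are each channel's best
similarity over the 14 references (and `s*_ref` the reference achieving it),
`s_aggregate` the mean of the filtered channel scores, and `pass` whether
the compound clears θ = 0.75 without being an outlier. All ten passing
compounds here are planted analogues; all 14 exact duplicates score `s = 1`
somewhere, are zeroed by the filter, and fail — the screen recovers novel
analogues and rejects compounds it already knows.

`--mode 1d|2d|3d` ranks by a single channel (the ablation used to compare
the combined screen against each representation alone), and
`mitoscreen screen ... --theta 0.9` tightens the neighbourhood; passing sets
shrink monotonically as θ rises.

## Library API

The channels are sklearn-style estimators and compose with sklearn
pipelines: `Mol2vecEncoder` (fit = train embeddings, transform = embed),
`Pharm2DFingerprinter`, `Shape3DFingerprinter`, and `VirtualScreen`
(fit on the reference panel, `score_library` returns the ranking as a
DataFrame). See `docs/methods.md` for the model details and design choices.

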