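"""Pipeline orchestration: pretrain -> represent -> score -> rank.

Thin library layer the CLI calls into; each step reads/writes standard
artifacts (a model directory, a results TSV, a JSON run manifest) so runs
are reproducible from the manifest plus the inputs alone.
"""

from __future__ import annotations

import hashlib
import json
import platform
import time
from pathlib import Path

import numpy as np
import rdkit
import sklearn

from . import chem_io
from .chem_io import (CorpusFilterRules, StandardizationPolicy,
                      filter_pretraining_corpus, read_library, rejection_counts,
                      standardize_all, write_results_table)
from .config import ScreeningConfig
from .errors import EmptyResultError, InputError
from .representations import Mol2vecEncoder, sentence
from .scoring import VirtualScreen


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def engine_versions() -> dict[str, str]:
    return {"python": platform.python_version(), "rdkit": rdkit.__version__,
            "numpy": np.__version__, "sklearn": sklearn.__version__}


def pretrain(corpus_path: str | Path, out_model_dir: str | Path,
             config: ScreeningConfig = ScreeningConfig(),
             rules: CorpusFilterRules = CorpusFilterRules()) -> Mol2vecEncoder:
    """Standardize + curate the corpus, build sentences, train the 1D model.

    Writes the model directory (vocab.tsv, vectors, hyperparameters, model
    card) and a run manifest next to it.
    """
    t0 = time.time()
    records = read_library(corpus_path)
    std = standardize_all(records)
    ok = [r for r in std if r.ok]
    kept, rejected = filter_pretraining_corpus(ok, rules, return_rejected=True)
    if not kept:
        raise EmptyResultError(
            "empty corpus after curation; rejections: "
            + json.dumps(rejection_counts(rejected)))

    enc = Mol2vecEncoder(radius=config.radius, vector_size=config.vector_size,
                         window=config.window, min_count=config.min_count,
                         epochs=config.epochs, seed=config.seed)
    enc.fit(kept)

    out = Path(out_model_dir)
    card = [f"{k}: {v}" for k, v in engine_versions().items()] + [f"seed: {config.seed}"]
    enc.save(out, card_lines=card)
    manifest = {
        "stage": "pretrain",
        "config": config.to_dict(),
        "inputs": {str(corpus_path): _sha256(corpus_path)},
        "engine_versions": engine_versions(),
        "counts": {"read": len(records), "standardized_ok": len(ok),
                   "corpus_filtered": len(kept),
                   "rejections": rejection_counts(rejected),
                   "vocabulary": len(enc.vocabulary_)},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return enc


def screen(library_path: str | Path, references_path: str | Path,
           model_dir: str | Path, out_dir: str | Path,
           config: ScreeningConfig = ScreeningConfig(),
           mode: str = "combined") -> dict:
    """Run the three-channel screen (or a 1d/2d/3d single-channel ablation).

    Writes results.tsv (full ranking), candidates.tsv (passing set, top-N
    truncated), manifest.json and a human-readable summary.txt into
    ``out_dir``. Returns the manifest dict.
    """
    t0 = time.time()
    refs_raw = read_library(references_path)
    refs = [r for r in standardize_all(refs_raw) if r.ok]
    if not refs:
        raise InputError(f"reference file {references_path} has no valid molecules")
    lib_raw = read_library(library_path)
    lib = standardize_all(lib_raw)

    enc = Mol2vecEncoder.load(model_dir, radius=config.radius)
    vs = VirtualScreen(encoder=enc, config=config).fit(refs)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary_lines = [
        f"references: {len(refs_raw)} read, {len(refs)} valid",
        f"library: {len(lib_raw)} read, {sum(r.ok for r in lib)} standardized ok",
    ]

    if mode in ("1d", "2d", "3d"):
        kind = {"1d": "embed1d", "2d": "pharm2d", "3d": "shape3d"}[mode]
        k = config.top_n if config.top_n is not None else 5
        top = vs.single_channel_ranking(lib, kind, k)
        top.to_csv(out / "results.tsv", sep="\t", index=False, float_format="%.6f")
        n_pass = int((top["s_filtered"] >= config.theta).sum())
        summary_lines += [f"mode: single-channel {mode}", f"top-k: {len(top)}"]
        counts = {"read": len(lib_raw), "standardized_ok": sum(r.ok for r in lib),
                  "scored": len(top), "passed": n_pass}
    else:
        ranking = vs.score_library(lib)
        write_results_table(ranking, out / "results.tsv")
        cand = vs.candidates(ranking)
        write_results_table(cand, out / "candidates.tsv")
        counts = {"read": len(lib_raw), "standardized_ok": sum(r.ok for r in lib),
                  "scored": len(ranking), "passed": int(ranking["pass"].sum()),
                  "outliers": int(ranking["outlier_flag"].sum()),
                  "candidates": len(cand)}
        summary_lines += [
            f"scored: {len(ranking)}",
            f"passing theta={config.theta}: {counts['passed']}",
            f"outliers flagged: {counts['outliers']}",
            f"candidates written: {len(cand)}",
        ]

    manifest = {
        "stage": "screen",
        "mode": mode,
        "config": config.to_dict(),
        "inputs": {str(library_path): _sha256(library_path),
                   str(references_path): _sha256(references_path)},
        "model_dir": str(model_dir),
        "engine_versions": engine_versions(),
        "counts": counts,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    return manifest
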