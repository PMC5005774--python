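"""Versioned model bundles: a directory with the model and a manifest."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import joblib

from .stack import StackModel

MODEL_FILE = "model.joblib"
MANIFEST_FILE = "manifest.json"
BUNDLE_FORMAT = 1


def save_bundle(model: StackModel, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    joblib.dump(model, outdir / MODEL_FILE)
    manifest = {
        "format": BUNDLE_FORMAT,
        "package": "quatstack",
        "classes": model.classes,
        "config": asdict(model.config),
        "db_digests": model.db_digests,
        "model_digest": model.digest(),
    }
    with open(outdir / MANIFEST_FILE, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir


def load_bundle(path: str | Path) -> StackModel:
    path = Path(path)
    model_path = path / MODEL_FILE
    manifest_path = path / MANIFEST_FILE
    if not model_path.exists() or not manifest_path.exists():
        raise FileNotFoundError(
            f"{path} is not a model bundle (expected {MODEL_FILE} and {MANIFEST_FILE})"
        )
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if manifest.get("format") != BUNDLE_FORMAT:
        raise ValueError(f"unsupported bundle format {manifest.get('format')!r}")
    model: StackModel = joblib.load(model_path)
    want = manifest.get("model_digest")
    if want and model.digest() != want:
        raise ValueError(f"{path}: model digest does not match its manifest")
    return model
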