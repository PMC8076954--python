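"""Model checkpointing: one ``.npz`` archive with weights + JSON metadata.

The archive stores every parameter array (and batch-norm running statistics)
in load order, plus a JSON header with the model kind, its configuration, the
gene schema, the covariate schema, and the standardization parameters —
enough to rebuild the model and validate any input matrix against it.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .gain import GainConfig, GainModel, NoiseConfig
from .masking import MaskSamplerConfig
from .pmi import PMIConfig, PMIModel

FORMAT_ID = "exprimpute-checkpoint-1"


def _config_to_dict(cfg) -> dict:
    return dataclasses.asdict(cfg)


def _pmi_config(d: dict) -> PMIConfig:
    d = dict(d)
    d["mask_cfg"] = MaskSamplerConfig(**d["mask_cfg"])
    if d.get("hidden") is not None:
        d["hidden"] = tuple(d["hidden"])
    return PMIConfig(**d)


def _gain_config(d: dict) -> GainConfig:
    d = dict(d)
    d["hint_cfg"] = MaskSamplerConfig(**d["hint_cfg"])
    d["pseudo_cfg"] = MaskSamplerConfig(**d["pseudo_cfg"])
    d["noise"] = NoiseConfig(**d["noise"])
    if d.get("hidden") is not None:
        d["hidden"] = tuple(d["hidden"])
    return GainConfig(**d)


def save_model(model: PMIModel | GainModel, path, extra_meta: dict | None = None) -> None:
    kind = "pmi" if isinstance(model, PMIModel) else "gain"
    meta = {
        "format": FORMAT_ID,
        "kind": kind,
        "n_genes": model.n_genes,
        "n_numeric": model.n_numeric,
        "vocab_sizes": model.vocab_sizes,
        "covariate_names": (model.embeddings if kind == "pmi" else model.emb_g).names,
        "config": _config_to_dict(model.config),
        "gene_ids": model.gene_ids,
        "standardization": None,
    }
    if model.standardization is not None:
        meta["standardization"] = {
            k: np.asarray(v).tolist() for k, v in model.standardization.items()
        }
    if extra_meta:
        meta["extra"] = extra_meta
    state = model.state()
    arrays = {f"p{i:04d}": a for i, a in enumerate(state)}
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_model(path):
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        if meta.get("format") != FORMAT_ID:
            raise ValueError(f"unrecognized checkpoint format in {path}")
        state = [z[k] for k in sorted(k for k in z.files if k.startswith("p"))]
    rng = np.random.default_rng(0)  # weights are overwritten immediately
    if meta["kind"] == "pmi":
        cfg = _pmi_config(meta["config"])
        model = PMIModel(
            meta["n_genes"], meta["n_numeric"], meta["vocab_sizes"], cfg, rng,
            covariate_names=meta["covariate_names"],
        )
    else:
        cfg = _gain_config(meta["config"])
        model = GainModel(
            meta["n_genes"], meta["n_numeric"], meta["vocab_sizes"], cfg, rng,
            covariate_names=meta["covariate_names"],
        )
    model.load_state(state)
    model.gene_ids = meta.get("gene_ids")
    std = meta.get("standardization")
    if std is not None:
        model.standardization = {k: np.asarray(v) for k, v in std.items()}
    return model, meta
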