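"""Flat-file contracts: responses, rating-scale items, embedding caches.

All inputs and outputs are plain text. Responses travel as
``responses.csv`` (participant_id, construct, format, response); each
scale as ``items_<scale>.csv`` (participant_id, item_1..item_k); an
embedding cache as a numeric CSV matrix plus a JSON sidecar carrying the
extraction metadata (mode, layer, source, row ids).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .datatypes import CONSTRUCTS, FORMATS, EmbeddingMatrix, RatingScaleData, ResponseSet
from .errors import InvalidInputError

__all__ = [
    "write_embedding_cache",
    "read_embedding_cache",
    "StudyBundle",
    "load_study",
    "write_study",
]


def write_embedding_cache(matrix: EmbeddingMatrix, path) -> None:
    """Write an embedding matrix as CSV plus a ``.meta.json`` sidecar."""
    path = Path(path)
    frame = pd.DataFrame(
        matrix.values,
        index=pd.Index(matrix.row_ids, name="participant_id"),
        columns=[f"d{j}" for j in range(matrix.dim)],
    )
    frame.to_csv(path)
    meta = {
        "mode": matrix.mode,
        "layer": matrix.layer,
        "source": matrix.source,
        "row_ids": list(matrix.row_ids),
        "dim": matrix.dim,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_embedding_cache(path) -> EmbeddingMatrix:
    """Read an embedding matrix written by :func:`write_embedding_cache`."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={"participant_id": str}).set_index("participant_id")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    else:
        meta = {"mode": "synthetic", "layer": None, "source": str(path)}
    matrix = EmbeddingMatrix(
        values=frame.to_numpy(dtype=float),
        row_ids=tuple(str(i) for i in frame.index),
        mode=meta.get("mode", "synthetic"),
        layer=meta.get("layer"),
        source=meta.get("source", str(path)),
    )
    if meta.get("row_ids") and list(matrix.row_ids) != [str(r) for r in meta["row_ids"]]:
        raise InvalidInputError(f"{path}: row ids disagree with sidecar metadata")
    return matrix


@dataclass
class StudyBundle:
    """Aligned in-memory study: responses, two scales, optional features.

    ``excluded`` logs participants dropped for not answering all four
    open-ended questions (or missing from an item table), mirroring the
    exclusion rule of the emulated survey design.
    """

    responses: ResponseSet
    items_hil: RatingScaleData
    items_swl: RatingScaleData
    embeddings: dict = field(default_factory=dict)
    excluded: list = field(default_factory=list)

    @property
    def participant_ids(self) -> list[str]:
        return self.items_hil.participant_ids

    def items(self, construct: str) -> RatingScaleData:
        return {"hil": self.items_hil, "swl": self.items_swl}[construct]


def load_study(
    responses_path,
    items_hil_path,
    items_swl_path,
    embedding_paths: dict | None = None,
    scale_range: tuple[int, int] = (1, 7),
) -> StudyBundle:
    """Load and align the flat-file study, excluding incomplete participants.

    A participant is kept only if present in both item tables and with a
    non-empty response for every (construct, format) combination; everyone
    else lands in ``excluded`` with a reason. Item values outside
    ``scale_range`` raise a validation error (via RatingScaleData).
    """
    responses = ResponseSet.from_csv(responses_path)
    items_hil = RatingScaleData.from_csv(items_hil_path, scale_range, scale_name="HILS")
    items_swl = RatingScaleData.from_csv(items_swl_path, scale_range, scale_name="SWLS")

    excluded: list[tuple[str, str]] = []
    keep: list[str] = []
    hil_ids = set(items_hil.participant_ids)
    swl_ids = set(items_swl.participant_ids)
    frame = responses.frame
    nonempty = frame["response"].astype(str).str.strip() != ""
    answered = frame.loc[nonempty].groupby("participant_id").apply(
        lambda g: {(c, f) for c, f in zip(g["construct"], g["format"])},
        include_groups=False,
    )
    required = {(c, f) for c in CONSTRUCTS for f in FORMATS}
    all_ids = sorted(
        set(map(str, frame["participant_id"])) | hil_ids | swl_ids,
        key=lambda s: (len(s), s),
    )
    for pid in all_ids:
        if pid not in hil_ids or pid not in swl_ids:
            excluded.append((pid, "missing rating-scale items"))
        elif pid not in answered.index or answered.loc[pid] != required:
            excluded.append((pid, "did not answer all four open-ended questions"))
        else:
            keep.append(pid)
    if not keep:
        raise InvalidInputError("no participant passed the completeness checks")
    keep_in_item_order = [p for p in items_hil.participant_ids if p in set(keep)]
    mask = frame["participant_id"].astype(str).isin(set(keep_in_item_order))
    bundle = StudyBundle(
        responses=ResponseSet(frame.loc[mask].reset_index(drop=True)),
        items_hil=items_hil.reorder(keep_in_item_order),
        items_swl=items_swl.reorder(keep_in_item_order),
        excluded=excluded,
    )
    for name, path in (embedding_paths or {}).items():
        bundle.embeddings[name] = read_embedding_cache(path).reorder(keep_in_item_order)
    return bundle


def write_study(study, out_dir) -> dict[str, Path]:
    """Write a synthetic study to flat files; returns the path map.

    Produces responses.csv, items_hil.csv, items_swl.csv, latents.csv
    (ground truth), one embedding cache per (construct, format), and a
    config echo in config.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["responses"] = out / "responses.csv"
    study.responses.to_csv(paths["responses"])
    for construct in CONSTRUCTS:
        p = out / f"items_{construct}.csv"
        study.items(construct).to_csv(p)
        paths[f"items_{construct}"] = p
    latents = pd.DataFrame(
        {
            "participant_id": study.participant_ids,
            "hil_latent": study.latents.hil_latent,
            "swl_latent": study.latents.swl_latent,
        }
    )
    paths["latents"] = out / "latents.csv"
    latents.to_csv(paths["latents"], index=False)
    for (construct, fmt, _mode), matrix in study.embeddings.items():
        p = out / f"embeddings_{construct}_{fmt}.csv"
        write_embedding_cache(matrix, p)
        paths[f"embeddings_{construct}_{fmt}"] = p
    cfg = study.config
    echo = {
        "n_participants": cfg.n_participants,
        "rho_latent": cfg.rho_latent,
        "n_items": cfg.n_items,
        "item_loading": cfg.loadings,
        "scale_range": list(cfg.scale_range),
        "embed_dim": cfg.embed_dim,
        "embed_signal": cfg.signals,
        "n_tokens_word_response": cfg.n_tokens_word_response,
        "n_tokens_text_response": cfg.n_tokens_text_response,
        "tilt": cfg.tilt,
        "seed": cfg.seed,
    }
    paths["config"] = out / "config.json"
    paths["config"].write_text(json.dumps(echo, indent=1))
    return paths
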