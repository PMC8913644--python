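"""Study-like synthetic data with known ground truth.

The generator is a compact statistical model of a two-construct well-being
survey: two correlated standard-normal latent traits (harmony in life and
satisfaction with life), five parallel noisy indicator items per scale on
a 1-7 agreement grid, embedding-like feature matrices whose columns carry
a controllable share of trait variance, and token streams whose sampling
weights are tilted by the trait. Because the ground truth is known, every
downstream stage — reliability, cross-validated accuracy, attenuation
ceilings, diversity — can be tested against closed forms without any
external data or model download.

All randomness flows from one integer seed through named substreams, so
identical configurations reproduce bit-identical studies and components
can be regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import CONSTRUCTS, EmbeddingMatrix, RatingScaleData, ResponseSet
from .errors import InvalidInputError, InvalidParameterError
from .utils import derive_seed

__all__ = [
    "Vocabulary",
    "SyntheticConfig",
    "LatentTraits",
    "SyntheticStudy",
    "default_vocab",
    "loading_for_inter_item_r",
    "loading_for_total_reliability",
    "total_reliability",
    "generate_latents",
    "generate_scale_items",
    "generate_response_embeddings",
    "population_multiple_r",
    "generate_token_responses",
    "generate_context_coded_responses",
    "generate_study",
]


# ---------------------------------------------------------------------------
# Vocabulary


@dataclass(frozen=True)
class Vocabulary:
    """Weighted token list with per-token valence for trait tilting.

    ``valence`` in {-1, 0, +1}: positive tokens become more likely for high
    trait levels via a logistic weight shift, negative ones less likely,
    neutral tokens are unaffected.
    """

    tokens: tuple[str, ...]
    weights: tuple[float, ...] | None = None
    valence: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.tokens) == 0:
            raise InvalidParameterError("vocabulary must contain at least one token")
        if self.weights is not None:
            if len(self.weights) != len(self.tokens):
                raise InvalidParameterError("weights and tokens differ in length")
            if any(w < 0 for w in self.weights):
                raise InvalidParameterError("vocabulary weights must be non-negative")
            if sum(self.weights) <= 0:
                raise InvalidParameterError("vocabulary weights sum to zero")
        if self.valence is not None and len(self.valence) != len(self.tokens):
            raise InvalidParameterError("valence and tokens differ in length")

    @property
    def base_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.full(len(self.tokens), 1.0 / len(self.tokens))
        w = np.asarray(self.weights, dtype=float)
        return w / w.sum()

    @property
    def valences(self) -> np.ndarray:
        if self.valence is None:
            return np.zeros(len(self.tokens))
        return np.asarray(self.valence, dtype=float)


_POSITIVE = {
    "hil": ("harmony", "peaceful", "balanced", "calm", "content", "unity",
            "serene", "stable", "whole", "connected", "grounded", "tranquil"),
    "swl": ("satisfied", "happy", "fulfilled", "successful", "grateful",
            "accomplished", "thriving", "pleased", "lucky", "rewarded",
            "comfortable", "optimistic"),
}
_NEGATIVE = {
    "hil": ("chaotic", "conflicted", "restless", "stressed", "unsettled",
            "fragmented", "tense", "discordant", "turbulent", "uneasy",
            "scattered", "strained"),
    "swl": ("dissatisfied", "unhappy", "disappointed", "struggling",
            "regretful", "frustrated", "unfulfilled", "stuck", "lacking",
            "discouraged", "failing", "bitter"),
}
_NEUTRAL = ("life", "work", "family", "time", "things", "people", "days",
            "world", "year", "home", "health", "money")


def default_vocab() -> dict[str, Vocabulary]:
    """Construct-specific vocabularies of positive/negative/neutral tokens."""
    out = {}
    for construct in CONSTRUCTS:
        tokens = _POSITIVE[construct] + _NEGATIVE[construct] + _NEUTRAL
        valence = (1,) * len(_POSITIVE[construct]) + (-1,) * len(_NEGATIVE[construct]) + (
            0,
        ) * len(_NEUTRAL)
        out[construct] = Vocabulary(tokens=tokens, valence=valence)
    return out


# ---------------------------------------------------------------------------
# Configuration


def _as_construct_map(value, name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = set(CONSTRUCTS) - set(value)
        if missing:
            raise InvalidParameterError(f"{name} mapping is missing constructs {sorted(missing)}")
        return {c: float(value[c]) for c in CONSTRUCTS}
    return {c: float(value) for c in CONSTRUCTS}


def loading_for_inter_item_r(r: float) -> float:
    """Item loading whose parallel items have population inter-item r."""
    if not 0.0 <= r <= 1.0:
        raise InvalidParameterError("inter-item r target must be in [0, 1]")
    return math.sqrt(r)


def loading_for_total_reliability(rel: float, n_items: int) -> float:
    """Item loading whose k-item total has the given reliability.

    Inverts the Spearman-Brown relation rel = k*r / (1 + (k-1)*r) with
    r = loading^2.
    """
    if not 0.0 < rel < 1.0:
        raise InvalidParameterError("total reliability target must be in (0, 1)")
    r = rel / (n_items - rel * (n_items - 1))
    return math.sqrt(r)


def total_reliability(item_loading: float, n_items: int) -> float:
    """Reliability of the k-item total score of parallel items (Spearman-Brown)."""
    r = item_loading**2
    return n_items * r / (1.0 + (n_items - 1) * r)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of one synthetic study.

    Defaults mirror the emulated survey: N = 608 participants, two latent
    traits correlated 0.85, five 1-7 items per scale with loadings set so
    the population inter-item correlations are 0.76 (harmony) and 0.73
    (satisfaction), 64-dimensional feature matrices with a small
    per-column trait signal (population multiple-R about 0.88, i.e.
    accuracies on the scale actually observed for such assessments), and
    10-token word responses beside 70-token text responses.
    """

    n_participants: int = 608
    rho_latent: float = 0.85
    n_items: int = 5
    item_loading: float | Mapping[str, float] = field(
        default_factory=lambda: {
            "hil": loading_for_inter_item_r(0.76),
            "swl": loading_for_inter_item_r(0.73),
        }
    )
    scale_range: tuple[int, int] = (1, 7)
    embed_dim: int = 64
    embed_signal: float | Mapping[str, float] = 0.05
    vocab: Mapping[str, Vocabulary] | None = None
    n_tokens_word_response: int = 10
    n_tokens_text_response: int = 70
    tilt: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_items < 1 or self.embed_dim < 1:
            raise InvalidParameterError("counts must be >= 1")
        if self.n_tokens_word_response < 1 or self.n_tokens_text_response < 1:
            raise InvalidParameterError("token counts must be >= 1")
        if not -1.0 <= self.rho_latent <= 1.0:
            raise InvalidParameterError(f"rho_latent {self.rho_latent} outside [-1, 1]")
        for name, mapping in (
            ("item_loading", self.loadings),
            ("embed_signal", self.signals),
        ):
            for c, v in mapping.items():
                if not 0.0 <= v <= 1.0:
                    raise InvalidParameterError(f"{name}[{c}] = {v} outside [0, 1]")

    @property
    def loadings(self) -> dict[str, float]:
        return _as_construct_map(self.item_loading, "item_loading")

    @property
    def signals(self) -> dict[str, float]:
        return _as_construct_map(self.embed_signal, "embed_signal")

    @property
    def vocabularies(self) -> dict[str, Vocabulary]:
        return dict(self.vocab) if self.vocab is not None else default_vocab()


@dataclass(frozen=True)
class LatentTraits:
    """Ground-truth trait levels the study never observes directly."""

    hil_latent: np.ndarray
    swl_latent: np.ndarray

    def __post_init__(self) -> None:
        hil = np.asarray(self.hil_latent, dtype=float)
        swl = np.asarray(self.swl_latent, dtype=float)
        if hil.shape != swl.shape or hil.ndim != 1:
            raise InvalidInputError("latent vectors must be 1-D and equal length")
        if not (np.all(np.isfinite(hil)) and np.all(np.isfinite(swl))):
            raise InvalidInputError("latent traits must be finite")
        object.__setattr__(self, "hil_latent", hil)
        object.__setattr__(self, "swl_latent", swl)

    @property
    def n(self) -> int:
        return len(self.hil_latent)

    def of(self, construct: str) -> np.ndarray:
        return {"hil": self.hil_latent, "swl": self.swl_latent}[construct]


@dataclass(frozen=True)
class SyntheticStudy:
    """A coherent bundle of everything one simulated study produces."""

    latents: LatentTraits
    responses: ResponseSet
    items_hil: RatingScaleData
    items_swl: RatingScaleData
    embeddings: dict
    config: SyntheticConfig

    def items(self, construct: str) -> RatingScaleData:
        return {"hil": self.items_hil, "swl": self.items_swl}[construct]

    @property
    def participant_ids(self) -> list[str]:
        return self.items_hil.participant_ids


def _participant_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"p{i + 1:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Generators


def generate_latents(n: int, rho: float, seed: int) -> LatentTraits:
    """Two standard-normal trait vectors with population correlation rho."""
    if n < 3:
        raise InvalidParameterError("need n >= 3 participants")
    if not -1.0 <= rho <= 1.0:
        raise InvalidParameterError(f"rho {rho} outside [-1, 1]")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    hil = z[:, 0]
    swl = rho * z[:, 0] + math.sqrt(1.0 - rho**2) * z[:, 1]
    return LatentTraits(hil_latent=hil, swl_latent=swl)


def generate_scale_items(
    latent,
    n_items: int,
    item_loading: float,
    scale_range: tuple[int, int],
    seed: int,
    discretize: bool = True,
    scale_name: str = "",
    participant_ids=None,
) -> RatingScaleData:
    """Parallel noisy indicator items for one latent trait.

    Each standardized item is loading * latent + sqrt(1 - loading^2) * noise,
    so the population inter-item correlation is loading^2. Items are then
    affinely mapped onto ``scale_range`` (midpoint at trait 0, six noisy-item
    SDs spanning the range) and, when ``discretize``, rounded to the integer
    grid — the slight reliability attenuation this causes is documented, not
    compensated.
    """
    latent = np.asarray(latent, dtype=float)
    if latent.size == 0:
        raise InvalidInputError("empty latent vector")
    if n_items < 2:
        raise InvalidParameterError("n_items must be >= 2")
    if not 0.0 <= item_loading <= 1.0:
        raise InvalidParameterError(f"item_loading {item_loading} outside [0, 1]")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((len(latent), n_items))
    std_items = item_loading * latent[:, None] + math.sqrt(1.0 - item_loading**2) * noise
    lo, hi = scale_range
    mid = (lo + hi) / 2.0
    spread = (hi - lo) / 6.0
    raw = np.clip(mid + spread * std_items, lo, hi)
    if discretize:
        raw = np.rint(raw).astype(int)
    ids = list(participant_ids) if participant_ids is not None else _participant_ids(len(latent))
    frame = pd.DataFrame(
        raw, index=pd.Index(ids, name="participant_id"),
        columns=[f"item_{j + 1}" for j in range(n_items)],
    )
    return RatingScaleData(items=frame, scale_range=scale_range, scale_name=scale_name)


def generate_response_embeddings(
    latent,
    dim: int,
    signal: float,
    seed: int,
    participant_ids=None,
    source: str = "simulator",
) -> EmbeddingMatrix:
    """Feature matrix whose columns carry a controlled share of trait variance.

    Column j is sqrt(signal) * w_j * latent + sqrt(1 - signal) * noise with a
    fixed random weight w_j, rescaled to unit population variance. At
    signal = 1 the trait is an exact linear function of any column; at 0 the
    matrix is pure noise.
    """
    latent = np.asarray(latent, dtype=float)
    if latent.size == 0:
        raise InvalidInputError("empty latent vector")
    if dim < 1:
        raise InvalidParameterError("dim must be >= 1")
    if not 0.0 <= signal <= 1.0:
        raise InvalidParameterError(f"signal {signal} outside [0, 1]")
    rng = np.random.default_rng(seed)
    w = rng.standard_normal(dim)
    noise = rng.standard_normal((len(latent), dim))
    values = math.sqrt(signal) * latent[:, None] * w[None, :]
    values = values + math.sqrt(1.0 - signal) * noise
    pop_sd = np.sqrt(signal * w**2 + (1.0 - signal))
    pop_sd = np.where(pop_sd > 0, pop_sd, 1.0)
    values = values / pop_sd[None, :]
    ids = list(participant_ids) if participant_ids is not None else _participant_ids(len(latent))
    return EmbeddingMatrix(values=values, row_ids=tuple(ids), mode="synthetic", source=source)


def population_multiple_r(signal: float, weights) -> float:
    """Closed-form multiple correlation between the features and the latent.

    For the generating model above with unit-variance columns, the squared
    multiple correlation is A / (1 + A) with A = sum_j s*w_j^2 / (1 - s)
    (Sherman-Morrison on the rank-one-plus-diagonal covariance).
    """
    w = np.asarray(weights, dtype=float)
    if signal >= 1.0:
        return 1.0
    a = float(np.sum(signal * w**2 / (1.0 - signal)))
    return math.sqrt(a / (1.0 + a))


def _tilted_probs(vocab: Vocabulary, latent_value: float, tilt: float) -> np.ndarray:
    shift = 1.0 / (1.0 + np.exp(-tilt * vocab.valences * latent_value))
    w = vocab.base_weights * shift
    return w / w.sum()


def generate_token_responses(
    latent,
    vocab: Vocabulary,
    n_tokens: int,
    seed: int,
    construct: str = "hil",
    format: str = "words",
    tilt: float = 1.0,
    participant_ids=None,
) -> ResponseSet:
    """Token streams whose sampling weights are tilted by the trait.

    Higher trait levels raise the odds of positive-valence tokens through a
    logistic weight shift (monotone and bounded in the trait). Word-format
    responses have exactly ``n_tokens`` tokens; text-format responses are
    simply longer streams from the same tilted distribution.
    """
    latent = np.asarray(latent, dtype=float)
    if latent.size == 0:
        raise InvalidInputError("empty latent vector")
    if n_tokens < 1:
        raise InvalidParameterError("n_tokens must be >= 1")
    rng = np.random.default_rng(seed)
    ids = list(participant_ids) if participant_ids is not None else _participant_ids(len(latent))
    tokens = np.asarray(vocab.tokens)
    rows = []
    for pid, lv in zip(ids, latent):
        p = _tilted_probs(vocab, float(lv), tilt)
        draw = rng.choice(tokens, size=n_tokens, p=p)
        rows.append((pid, construct, format, " ".join(draw)))
    frame = pd.DataFrame(rows, columns=["participant_id", "construct", "format", "response"])
    return ResponseSet(frame)


_PAIR_TOKENS = ("steady", "shifting")
_FILLER_TOKENS = ("life", "days", "things", "people", "time", "world")


def generate_context_coded_responses(
    latent,
    n_pairs: int = 12,
    n_filler: int = 3,
    tilt: float = 1.5,
    seed: int = 0,
    construct: str = "hil",
    format: str = "text",
    participant_ids=None,
) -> ResponseSet:
    """Responses whose trait signal lives only in token *order*.

    Each response consists of ``n_pairs`` ordered two-token pairs — either
    ("steady", "shifting") or ("shifting", "steady"), with the orientation
    odds logistic in the trait — plus a few random filler tokens. The
    unigram frequencies of the pair tokens are identical for every
    participant, so order-insensitive (decontextualized) features carry no
    trait information while order-sensitive (contextualized) features do.
    """
    latent = np.asarray(latent, dtype=float)
    if latent.size == 0:
        raise InvalidInputError("empty latent vector")
    if n_pairs < 1:
        raise InvalidParameterError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    ids = list(participant_ids) if participant_ids is not None else _participant_ids(len(latent))
    a, b = _PAIR_TOKENS
    rows = []
    for pid, lv in zip(ids, latent):
        p_forward = 1.0 / (1.0 + math.exp(-tilt * float(lv)))
        forward = rng.random(n_pairs) < p_forward
        toks: list[str] = []
        for f in forward:
            toks.extend((a, b) if f else (b, a))
        toks.extend(rng.choice(_FILLER_TOKENS, size=n_filler))
        rows.append((pid, construct, format, " ".join(toks)))
    frame = pd.DataFrame(rows, columns=["participant_id", "construct", "format", "response"])
    return ResponseSet(frame)


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate the full coherent study bundle from one configuration.

    Every component draws from its own named substream of ``config.seed``,
    so token responses and embeddings are conditionally independent of the
    rating-scale item noise given the latent traits, and re-running with
    the same configuration is bit-identical.
    """
    ids = _participant_ids(config.n_participants)
    latents = generate_latents(
        config.n_participants, config.rho_latent, seed=derive_seed(config.seed, "latents")
    )
    loadings = config.loadings
    signals = config.signals
    vocabs = config.vocabularies
    items = {}
    for construct in CONSTRUCTS:
        items[construct] = generate_scale_items(
            latents.of(construct),
            n_items=config.n_items,
            item_loading=loadings[construct],
            scale_range=config.scale_range,
            seed=derive_seed(config.seed, f"items-{construct}"),
            scale_name={"hil": "HILS", "swl": "SWLS"}[construct],
            participant_ids=ids,
        )
    response_parts = []
    embeddings = {}
    for construct in CONSTRUCTS:
        for fmt, n_tok in (
            ("words", config.n_tokens_word_response),
            ("text", config.n_tokens_text_response),
        ):
            response_parts.append(
                generate_token_responses(
                    latents.of(construct),
                    vocab=vocabs[construct],
                    n_tokens=n_tok,
                    seed=derive_seed(config.seed, f"tokens-{construct}-{fmt}"),
                    construct=construct,
                    format=fmt,
                    tilt=config.tilt,
                    participant_ids=ids,
                )
            )
            embeddings[(construct, fmt, "synthetic")] = generate_response_embeddings(
                latents.of(construct),
                dim=config.embed_dim,
                signal=signals[construct],
                seed=derive_seed(config.seed, f"embed-{construct}-{fmt}"),
                participant_ids=ids,
                source=f"simulator-{construct}-{fmt}",
            )
    return SyntheticStudy(
        latents=latents,
        responses=ResponseSet.concat(response_parts),
        items_hil=items["hil"],
        items_swl=items["swl"],
        embeddings=embeddings,
        config=config,
    )
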