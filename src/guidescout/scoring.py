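"""On-target efficiency scoring and the microhomology out-of-frame score.

Efficiency models live in a registry so published coefficient sets can be
dropped in as delimited tables. The fully specified default model,
``pam_proximal_gc``, captures the dominant empirical signal — PAM-proximal GC
content and a terminal G next to the PAM:

    score = 100 * (0.2 + 0.6 * GC10 / 10 + 0.2 * [terminal base is G])

where GC10 counts G/C among the ten PAM-proximal protospacer bases.

The out-of-frame score predicts how often microhomology-mediated end joining
produces deletions whose length is not a multiple of three (favouring
knockouts). Identical sequence pairs flanking the cut are enumerated within a
window; each pattern is weighted by an exponential length decay (constant 20)
and GC-weighted pattern strength, and the score is the out-of-frame share of
the total weight, on a 0-100 scale.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

from .errors import ConfigurationError, UsageError
from .guide_finder import GuideCandidate, NucleaseProfile

log = logging.getLogger(__name__)

MH_WINDOW_DEFAULT = 30   # bases each side of the cut searched for repeats
MH_MIN_LEN_DEFAULT = 2   # minimum microhomology length
MH_DECAY = 20.0          # deletion-length decay constant


# ---------------------------------------------------------------------------
# Efficiency models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EfficiencyModel:
    """A named on-target efficiency scorer.

    ``fn(protospacer, context, profile) -> float`` must return a value that
    the caller clamps to [0, 100]. ``required_context`` is the number of
    context bases the model needs on each side of the cut; when the guide has
    no such window the score is reported as unavailable (None), never 0.
    """

    name: str
    required_context: int
    fn: Callable[[str, str | None, NucleaseProfile | None], float]


_REGISTRY: dict[str, EfficiencyModel] = {}


def register_model(model: EfficiencyModel) -> None:
    if model.name in _REGISTRY:
        raise ConfigurationError(f"model {model.name!r} already registered")
    _REGISTRY[model.name] = model


def registered_models() -> list[str]:
    return sorted(_REGISTRY)


def _pam_proximal_gc(
    protospacer: str,
    context: str | None,
    profile: NucleaseProfile | None,
) -> float:
    # Ten PAM-proximal bases and the base adjacent to the PAM. For 3'-PAM
    # nucleases that is the protospacer tail; for 5'-PAM (Cpf1) the head.
    if profile is not None and profile.pam_side == "5":
        proximal, terminal = protospacer[:10], protospacer[0]
    else:
        proximal, terminal = protospacer[-10:], protospacer[-1]
    gc = sum(b in "GC" for b in proximal)
    return 100.0 * (0.2 + 0.6 * gc / 10.0 + 0.2 * (terminal == "G"))


register_model(EfficiencyModel("pam_proximal_gc", 0, _pam_proximal_gc))


def load_linear_model(name: str, path: str | Path) -> EfficiencyModel:
    """Build a linear one-hot model from a coefficient table.

    Table format (TSV): meta rows ``intercept``, ``score_min``, ``score_max``
    (2 columns) and feature rows ``position<TAB>base<TAB>weight`` with
    1-based protospacer positions. The raw linear sum is min-max scaled to
    [0, 100] and clamped. The model is returned, not auto-registered.
    """
    coef: dict[tuple[int, str], float] = {}
    meta = {"intercept": 0.0, "score_min": 0.0, "score_max": 1.0}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if row[0] in meta:
                meta[row[0]] = float(row[1])
            else:
                coef[(int(row[0]), row[1])] = float(row[2])
    if not coef:
        raise ConfigurationError(f"{path}: no coefficient rows")
    if meta["score_max"] <= meta["score_min"]:
        raise ConfigurationError(f"{path}: score_max must exceed score_min")

    def fn(protospacer: str, context, profile) -> float:
        raw = meta["intercept"] + sum(
            coef.get((i + 1, b), 0.0) for i, b in enumerate(protospacer)
        )
        return (
            100.0
            * (raw - meta["score_min"])
            / (meta["score_max"] - meta["score_min"])
        )

    return EfficiencyModel(name, 0, fn)


def efficiency_score(
    guide: GuideCandidate | str,
    model_name: str = "pam_proximal_gc",
    profile: NucleaseProfile | None = None,
) -> float | None:
    """Score a guide with a registered model, clamped to [0, 100].

    Returns None (unavailable) when the model needs context the guide lacks.
    """
    model = _REGISTRY.get(model_name)
    if model is None:
        raise UsageError(
            f"unknown efficiency model {model_name!r}; "
            f"registered: {registered_models()}"
        )
    if isinstance(guide, GuideCandidate):
        proto, context = guide.protospacer, guide.context
    else:
        proto, context = guide, None
    if model.required_context > 0 and context is None:
        return None
    raw = model.fn(proto, context, profile)
    return min(100.0, max(0.0, raw))


# ---------------------------------------------------------------------------
# Microhomology / out-of-frame
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MicrohomologyPattern:
    """An identical sequence pair flanking the cut that can template a
    deletion of ``deletion_len`` bases joining the two copies."""

    left_start: int
    right_start: int
    length: int
    deletion_len: int
    mh_seq: str


def find_microhomologies(
    context: str,
    cut: int,
    window: int = MH_WINDOW_DEFAULT,
    min_len: int = MH_MIN_LEN_DEFAULT,
) -> list[MicrohomologyPattern]:
    """Enumerate deduplicated microhomology patterns around a cut.

    ``cut`` is the 0-based between-base junction offset. A pattern is a pair
    of identical substrings of length >= ``min_len``: the left copy ends at
    or before the junction, the right copy starts at or after it, both
    within ``window`` bases of the junction (truncated at context bounds).
    A pattern positionally contained in a longer pattern with the same
    deletion length is suppressed.
    """
    if not 0 <= cut <= len(context):
        raise UsageError(f"cut {cut} outside context of length {len(context)}")
    lo = max(0, cut - window)
    hi = min(len(context), cut + window)
    raw: list[MicrohomologyPattern] = []
    for l in range(lo, cut - min_len + 1):
        for length in range(min_len, cut - l + 1):
            left = context[l : l + length]
            for r in range(max(cut, l + length), hi - length + 1):
                if context[r : r + length] == left:
                    raw.append(
                        MicrohomologyPattern(l, r, length, r - l, left)
                    )
    kept = [
        p
        for p in raw
        if not any(
            q.deletion_len == p.deletion_len
            and q.length > p.length
            and q.left_start <= p.left_start
            and p.left_start + p.length <= q.left_start + q.length
            for q in raw
        )
    ]
    kept.sort(key=lambda p: (p.deletion_len, p.left_start, p.length))
    return kept


def _pattern_weight(p: MicrohomologyPattern, decay: float = MH_DECAY) -> float:
    gc = sum(b in "GC" for b in p.mh_seq)
    at = len(p.mh_seq) - gc
    return 100.0 * round(math.exp(-p.deletion_len / decay), 3) * (2 * gc + at)


def out_of_frame_score(
    context: str,
    cut: int,
    window: int = MH_WINDOW_DEFAULT,
    min_len: int = MH_MIN_LEN_DEFAULT,
    decay: float = MH_DECAY,
) -> float | None:
    """Share (0-100) of microhomology deletion weight with length % 3 != 0.

    None (unavailable) when no pattern exists or total weight is zero.
    """
    patterns = find_microhomologies(context, cut, window, min_len)
    if not patterns:
        return None
    total = sum(_pattern_weight(p, decay) for p in patterns)
    if total == 0:
        return None
    oof = sum(
        _pattern_weight(p, decay) for p in patterns if p.deletion_len % 3 != 0
    )
    return 100.0 * oof / total


def guide_out_of_frame_score(guide: GuideCandidate) -> float | None:
    """Out-of-frame score at a guide's cut using its stored context window."""
    if guide.context is None or guide.context_cut is None:
        return None
    return out_of_frame_score(guide.context, guide.context_cut)
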