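"""Saturating-mutagenesis guide selection and barcoded oligo-pool assembly.

A saturating-mutagenesis screen tiles a region with every guide passing
minimal specificity/efficiency thresholds. The retained guides are assembled
into synthesis oligos, one per guide:

    fwd_barcode + left_adapter + insert + right_adapter + revcomp(rev_barcode)

where the insert is the prefix-adjusted protospacer and the barcodes are the
subpool's PCR-primer landing sites, so one ordered pool can be amplified into
separate libraries and every oligo decodes back to (subpool, guide) from its
sequence alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import ConfigurationError, UsageError
from .guide_finder import GuideCandidate
from .primers import adjust_prefix
from .sequence_io import InputSequence, revcomp

log = logging.getLogger(__name__)

MIN_BARCODE_LEN = 6

#: Default homology arms around the insert: the tail of a U6 vector arm and
#: the start of the sgRNA scaffold, the common layout for pooled cloning.
DEFAULT_ADAPTERS = ("GGAAAGGACGAAACACCG", "GTTTTAGAGCTAGAAATAGCAAG")


@dataclass(frozen=True)
class Subpool:
    subpool_id: str
    fwd_barcode: str
    rev_barcode: str


@dataclass(frozen=True)
class PoolOligo:
    subpool_id: str
    guide_id: str
    oligo_seq: str
    total_len: int


@dataclass
class CoverageReport:
    n_input: int
    n_selected: int
    max_gap: int | None  # largest distance between adjacent retained cuts


def saturating_selection(
    input_seq: InputSequence,
    guides: list[GuideCandidate],
    min_spec: float = 0.0,
    min_eff: float = 0.0,
) -> tuple[list[GuideCandidate], CoverageReport]:
    """Keep scored guides meeting the thresholds, ordered by position.

    Guides overlapping masked (N) positions are always dropped. The coverage
    report states the largest gap between adjacent retained cut sites — the
    screen's worst-case unmutated stretch.
    """
    selected = [
        g
        for g in guides
        if "OVERLAPS_N" not in g.flags
        and (g.spec_score is not None and g.spec_score >= min_spec)
        and (g.eff_score is not None and g.eff_score >= min_eff)
    ]
    selected.sort(key=lambda g: (g.cut, g.start, g.strand))
    if not selected:
        log.warning(
            "saturating selection empty (min_spec=%s, min_eff=%s)",
            min_spec,
            min_eff,
        )
    cuts = [g.cut for g in selected]
    max_gap = (
        max(b - a for a, b in zip(cuts, cuts[1:])) if len(cuts) > 1 else None
    )
    report = CoverageReport(len(guides), len(selected), max_gap)
    return selected, report


def _validate_subpools(subpools: list[Subpool]) -> None:
    barcodes: list[tuple[str, str]] = []
    for sp in subpools:
        for which, bc in (("fwd", sp.fwd_barcode), ("rev", sp.rev_barcode)):
            if len(bc) < MIN_BARCODE_LEN:
                raise ConfigurationError(
                    f"subpool {sp.subpool_id}: {which} barcode {bc!r} shorter "
                    f"than {MIN_BARCODE_LEN}"
                )
            if any(b not in "ACGT" for b in bc):
                raise ConfigurationError(
                    f"subpool {sp.subpool_id}: non-ACGT barcode {bc!r}"
                )
            barcodes.append((sp.subpool_id, bc))
    seen: dict[str, str] = {}
    for sid, bc in barcodes:
        if bc in seen:
            raise ConfigurationError(
                f"duplicate barcode {bc!r} (subpools {seen[bc]} and {sid})"
            )
        seen[bc] = sid
    fwd = [sp.fwd_barcode for sp in subpools]
    for i, a in enumerate(fwd):
        for b in fwd[i + 1 :]:
            if a.startswith(b) or b.startswith(a):
                raise ConfigurationError(
                    f"forward barcodes {a!r} and {b!r} are prefix-ambiguous; "
                    f"oligo decoding would not be injective"
                )


def assemble_pool(
    guides: list[GuideCandidate],
    subpools: list[Subpool],
    assignment: dict[str, list[str]],
    adapters: tuple[str, str] = DEFAULT_ADAPTERS,
    prefix_rule: str = "add_G_if_absent",
) -> list[PoolOligo]:
    """Build one synthesis oligo per guide.

    ``assignment`` maps subpool_id -> guide_ids; every guide must appear in
    exactly one subpool. The insert is the protospacer under the same
    5'-prefix rule as expression cloning. Pure function of its inputs.
    """
    _validate_subpools(subpools)
    by_id = {sp.subpool_id: sp for sp in subpools}
    guide_by_id = {g.guide_id: g for g in guides}

    seen: dict[str, str] = {}
    for sid, gids in assignment.items():
        if sid not in by_id:
            raise ConfigurationError(f"assignment names unknown subpool {sid!r}")
        for gid in gids:
            if gid in seen:
                raise UsageError(
                    f"guide {gid} assigned to subpools {seen[gid]} and {sid}"
                )
            if gid not in guide_by_id:
                raise UsageError(f"assignment names unknown guide {gid!r}")
            seen[gid] = sid
    missing = sorted(set(guide_by_id) - set(seen))
    if missing:
        raise UsageError(f"guides not assigned to any subpool: {missing}")

    left, right = adapters
    oligos: list[PoolOligo] = []
    lengths_by_subpool: dict[str, set[int]] = {}
    for sid, gids in assignment.items():
        sp = by_id[sid]
        for gid in gids:
            insert = adjust_prefix(guide_by_id[gid].protospacer, prefix_rule)
            oligo = (
                sp.fwd_barcode + left + insert + right + revcomp(sp.rev_barcode)
            )
            if oligo.count(insert) != 1:
                raise ConfigurationError(
                    f"guide {gid}: insert occurs {oligo.count(insert)} times "
                    f"in its oligo; change adapters or barcodes"
                )
            oligos.append(PoolOligo(sid, gid, oligo, len(oligo)))
            lengths_by_subpool.setdefault(sid, set()).add(len(oligo))
    for sid, lens in sorted(lengths_by_subpool.items()):
        if len(lens) > 1:
            offenders = sorted(
                o.guide_id for o in oligos
                if o.subpool_id == sid and o.total_len != min(lens)
            )
            log.warning(
                "subpool %s: unequal oligo lengths %s (guides %s)",
                sid, sorted(lens), offenders,
            )
    return oligos


def decode_oligo(
    oligo_seq: str,
    subpools: list[Subpool],
    guides: list[GuideCandidate],
    adapters: tuple[str, str] = DEFAULT_ADAPTERS,
    prefix_rule: str = "add_G_if_absent",
) -> tuple[str, str]:
    """Recover (subpool_id, guide_id) from an oligo sequence alone."""
    matches = [
        sp for sp in subpools if oligo_seq.startswith(sp.fwd_barcode)
    ]
    if len(matches) != 1:
        raise UsageError("oligo does not decode to a unique subpool")
    sp = matches[0]
    left, right = adapters
    body = oligo_seq[len(sp.fwd_barcode) :]
    if not body.startswith(left):
        raise UsageError("left adapter not found after forward barcode")
    body = body[len(left) :]
    end = body.find(right)
    if end < 0:
        raise UsageError("right adapter not found")
    insert = body[:end]
    for g in guides:
        if adjust_prefix(g.protospacer, prefix_rule) == insert:
            return sp.subpool_id, g.guide_id
    raise UsageError("insert does not match any known guide")
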