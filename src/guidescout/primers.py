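"""Primer, cloning-oligo and amplicon-manifest design.

Melting temperatures come from a nearest-neighbor enthalpy/entropy sum over
the unified duplex parameter set shipped as ``data/nn_params.tsv``:

    Tm = dH / (dS + R * ln(C/4)) - 273.15 + 16.6 * log10([Na+])

with primer concentration C = 50 nM and [Na+] = 50 mM by default.

Validation primers are picked by a deterministic greedy search: candidate
oligos of length 18-27 are scanned outward from the target site, filtered by
a minimal standard rule set (Tm within tolerance, no 4-base homopolymer run,
G/C 3' end), and the pair minimizing the summed Tm deviation subject to the
product-length range is chosen with documented tie-breaks — identical inputs
always give identical primers.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import ConfigurationError, PrimerDesignError, UsageError, ValidationError
from .guide_finder import GuideCandidate
from .offtarget import OffTargetHit
from .sequence_io import GenomeIndex, revcomp

log = logging.getLogger(__name__)

R_GAS = 1.987  # cal / (mol K)
PRIMER_LEN_RANGE = (18, 27)
ONTARGET_PRODUCT_RANGE = (600, 1000)   # Sanger-friendly validation amplicon
OFFTARGET_PRODUCT_RANGE = (200, 280)   # short amplicon-sequencing products
TM_TARGET_DEFAULT = 60.0
TM_TOL_DEFAULT = 3.0
_MAX_CANDIDATES_PER_SIDE = 200         # outward scan cap, keeps search bounded
_RUNS = ("AAAA", "TTTT", "GGGG", "CCCC")


# ---------------------------------------------------------------------------
# Melting temperature
# ---------------------------------------------------------------------------

def _load_nn_table() -> dict[str, tuple[float, float]]:
    source = resources.files("guidescout.data") / "nn_params.tsv"
    table: dict[str, tuple[float, float]] = {}
    for row in csv.reader(source.read_text().splitlines(), delimiter="\t"):
        if not row or row[0].startswith("#") or row[0] == "stack":
            continue
        table[row[0]] = (float(row[1]), float(row[2]))
    return table


_NN_TABLE: dict[str, tuple[float, float]] | None = None


def _nn_table() -> dict[str, tuple[float, float]]:
    global _NN_TABLE
    if _NN_TABLE is None:
        _NN_TABLE = _load_nn_table()
    return _NN_TABLE


def melting_temperature(
    seq: str,
    primer_nM: float = 50.0,
    na_mM: float = 50.0,
    table: dict[str, tuple[float, float]] | None = None,
) -> float:
    """Nearest-neighbor duplex Tm in degrees Celsius.

    Accepts 8-36 base A/C/G/T oligos. Symmetric under reverse complement
    (the parameter set describes duplexes).
    """
    if not 8 <= len(seq) <= 36:
        raise UsageError(f"primer length {len(seq)} outside 8..36")
    if any(b not in "ACGT" for b in seq):
        raise UsageError(f"non-ACGT base in primer {seq!r}")
    table = table or _nn_table()
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        key = "initGC" if end in "GC" else "initAT"
        h, s = table[key]
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        stack = seq[i : i + 2]
        if stack not in table:
            stack = revcomp(stack)
        if stack not in table:
            raise ConfigurationError(f"no NN parameters for stack {stack!r}")
        h, s = table[stack]
        dh += h
        ds += s
    c_eff = primer_nM * 1e-9 / 4.0
    tm = (dh * 1000.0) / (ds + R_GAS * math.log(c_eff)) - 273.15
    return tm + 16.6 * math.log10(na_mM / 1000.0)


# ---------------------------------------------------------------------------
# Primer pairs
# ---------------------------------------------------------------------------

@dataclass
class PrimerPair:
    """Two validation oligos and their plus-strand product coordinates."""

    left_seq: str
    right_seq: str
    left_start: int   # 0-based product/primer start on the plus strand
    right_end: int    # 0-based exclusive product end
    tm_left: float
    tm_right: float
    product_len: int
    name_prefix: str
    contig: str


def _primer_rules_ok(seq: str) -> bool:
    if any(run in seq for run in _RUNS):
        return False
    return seq[-1] in "GC"


def _left_candidates(seq, site_start, site_end, pmax, tm_target, tm_tol):
    """(start, length, tm, dev) for plus-strand primers upstream of the site,
    scanned outward from the site (3' end moving left)."""
    out = []
    lo_start = max(0, site_end + PRIMER_LEN_RANGE[0] - pmax)
    for end3 in range(site_start, lo_start + PRIMER_LEN_RANGE[0] - 1, -1):
        for k in range(PRIMER_LEN_RANGE[0], PRIMER_LEN_RANGE[1] + 1):
            a = end3 - k
            if a < lo_start:
                continue
            p = seq[a:end3]
            if not _primer_rules_ok(p):
                continue
            tm = melting_temperature(p)
            if abs(tm - tm_target) > tm_tol:
                continue
            out.append((a, k, tm, abs(tm - tm_target)))
            if len(out) >= _MAX_CANDIDATES_PER_SIDE:
                return out
    return out


def _right_candidates(seq, site_start, site_end, pmax, tm_target, tm_tol):
    """(start, length, tm, dev) for minus-strand primers downstream of the
    site; the primer oligo is the reverse complement of seq[start:start+k]."""
    out = []
    hi_end = min(len(seq), site_start + pmax)
    for r0 in range(site_end, hi_end - PRIMER_LEN_RANGE[0] + 1):
        for k in range(PRIMER_LEN_RANGE[0], PRIMER_LEN_RANGE[1] + 1):
            if r0 + k > hi_end:
                continue
            p = revcomp(seq[r0 : r0 + k])
            if not _primer_rules_ok(p):
                continue
            tm = melting_temperature(p)
            if abs(tm - tm_target) > tm_tol:
                continue
            out.append((r0, k, tm, abs(tm - tm_target)))
            if len(out) >= _MAX_CANDIDATES_PER_SIDE:
                return out
    return out


def design_flanking_primers(
    genome: GenomeIndex,
    contig: str,
    site_start: int,
    site_end: int,
    product_range: tuple[int, int] = ONTARGET_PRODUCT_RANGE,
    tm_target: float = TM_TARGET_DEFAULT,
    tm_tol: float = TM_TOL_DEFAULT,
    name_prefix: str = "",
) -> PrimerPair:
    """Deterministic greedy primer pair flanking [site_start, site_end).

    Chooses the candidate pair minimizing summed |Tm - target| subject to
    both Tms within tolerance, product length within range, no homopolymer
    runs, and a G/C 3' end; ties break on (product length, left start, oligo
    lengths). Raises :class:`PrimerDesignError` naming the binding constraint
    when no pair exists.
    """
    if contig not in genome.contigs:
        raise UsageError(f"unknown contig {contig!r}")
    seq = genome.contigs[contig]
    if not 0 <= site_start < site_end <= len(seq):
        raise UsageError("site outside contig")
    pmin, pmax = product_range
    lefts = _left_candidates(seq, site_start, site_end, pmax, tm_target, tm_tol)
    if not lefts:
        raise PrimerDesignError(
            f"{name_prefix or contig}: no upstream primer satisfies "
            f"Tm {tm_target}+/-{tm_tol}, run and 3'-end rules within "
            f"{pmax} bp of the site"
        )
    rights = _right_candidates(seq, site_start, site_end, pmax, tm_target, tm_tol)
    if not rights:
        raise PrimerDesignError(
            f"{name_prefix or contig}: no downstream primer satisfies "
            f"Tm {tm_target}+/-{tm_tol}, run and 3'-end rules within "
            f"{pmax} bp of the site"
        )
    best = None
    best_key = None
    for a, kl, tml, devl in lefts:
        for r0, kr, tmr, devr in rights:
            plen = (r0 + kr) - a
            if not pmin <= plen <= pmax:
                continue
            key = (devl + devr, plen, a, kl, kr)
            if best_key is None or key < best_key:
                best_key = key
                best = (a, kl, tml, r0, kr, tmr, plen)
    if best is None:
        raise PrimerDesignError(
            f"{name_prefix or contig}: primer candidates exist on both sides "
            f"but no pair falls in the product range {pmin}-{pmax} bp"
        )
    a, kl, tml, r0, kr, tmr, plen = best
    return PrimerPair(
        left_seq=seq[a : a + kl],
        right_seq=revcomp(seq[r0 : r0 + kr]),
        left_start=a,
        right_end=r0 + kr,
        tm_left=tml,
        tm_right=tmr,
        product_len=plen,
        name_prefix=name_prefix,
        contig=contig,
    )


def offtarget_primer_batch(
    hits: list[OffTargetHit],
    genome: GenomeIndex,
    product_range: tuple[int, int] = OFFTARGET_PRODUCT_RANGE,
    tm_target: float = TM_TARGET_DEFAULT,
    tm_tol: float = TM_TOL_DEFAULT,
    guide_id: str = "",
) -> tuple[list[PrimerPair], list[tuple[OffTargetHit, str]]]:
    """One primer pair per off-target where feasible.

    Hits are ranked by descending CFD (ties: mismatches, contig, start) and
    named ``<guideId>_ot<rank>``. Per-hit failures are returned in the skip
    list, not raised; pairs + skips always partition the input.
    """
    ranked = sorted(hits, key=lambda h: (-h.cfd, h.mismatches, h.contig, h.start))
    pairs: list[PrimerPair] = []
    skips: list[tuple[OffTargetHit, str]] = []
    for rank, hit in enumerate(ranked, start=1):
        span_start = min(hit.start, hit.pam_start)
        span_end = max(
            hit.start + len(hit.site_seq), hit.pam_start + len(hit.pam_seq)
        )
        gid = hit.guide_id or guide_id
        try:
            pairs.append(
                design_flanking_primers(
                    genome,
                    hit.contig,
                    span_start,
                    span_end,
                    product_range,
                    tm_target,
                    tm_tol,
                    name_prefix=f"{gid}_ot{rank}",
                )
            )
        except (PrimerDesignError, UsageError) as exc:
            skips.append((hit, str(exc)))
    return pairs, skips


# ---------------------------------------------------------------------------
# CRISPResso manifest
# ---------------------------------------------------------------------------

def crispresso_manifest(
    pairs: list[PrimerPair],
    genome: GenomeIndex,
    guides: dict[str, str],
) -> list[tuple[str, str, str]]:
    """Amplicon-analysis manifest rows (name, amplicon_seq, guide_seq).

    ``guides`` maps each pair's name_prefix to its protospacer (no PAM).
    Every guide must occur in its amplicon (either orientation) — validated
    before anything is written.
    """
    rows = []
    for pair in pairs:
        if pair.name_prefix not in guides:
            raise UsageError(f"no guide sequence for pair {pair.name_prefix!r}")
        amplicon = genome.contigs[pair.contig][pair.left_start : pair.right_end]
        guide_seq = guides[pair.name_prefix]
        if guide_seq not in amplicon and guide_seq not in revcomp(amplicon):
            raise ValidationError(
                f"row {pair.name_prefix}: guide not contained in amplicon"
            )
        rows.append((pair.name_prefix, amplicon, guide_seq))
    return rows


def write_crispresso_manifest(
    rows: list[tuple[str, str, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("name\tamplicon_seq\tguide_seq\n")
        for name, amplicon, guide_seq in rows:
            fh.write(f"{name}\t{amplicon}\t{guide_seq}\n")


# ---------------------------------------------------------------------------
# Cloning oligos
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CloningProfile:
    """Vector-specific overhangs and 5'-prefix rule for guide cloning."""

    name: str
    fwd_overhang: str
    rev_overhang: str
    prepend_g_rule: str  # none | add_G_if_absent | require_GG

    def __post_init__(self) -> None:
        if len(self.fwd_overhang) != 4 or len(self.rev_overhang) != 4:
            raise ConfigurationError("overhangs must be 4 bases")
        if self.prepend_g_rule not in {"none", "add_G_if_absent", "require_GG"}:
            raise ConfigurationError(
                f"unknown prefix rule {self.prepend_g_rule!r}"
            )


#: Built-in profiles: a BbsI/U6 expression vector (U6 transcription prefers a
#: leading G) and a generic Golden-Gate T7 in-vitro template (T7 needs GG).
BUILTIN_CLONING_PROFILES: dict[str, CloningProfile] = {
    "bbsI_U6": CloningProfile("bbsI_U6", "ACCG", "AAAC", "add_G_if_absent"),
    "t7_invitro": CloningProfile("t7_invitro", "TAGG", "AAAC", "require_GG"),
}


def adjust_prefix(protospacer: str, rule: str) -> str:
    """Apply a promoter 5'-prefix rule to a protospacer."""
    if rule == "none":
        return protospacer
    if rule == "add_G_if_absent":
        return protospacer if protospacer.startswith("G") else "G" + protospacer
    if rule == "require_GG":
        adjusted = protospacer
        while not adjusted.startswith("GG"):
            adjusted = "G" + adjusted
        return adjusted
    raise ConfigurationError(f"unknown prefix rule {rule!r}")


def cloning_oligos(
    guide: GuideCandidate | str,
    profile: str | CloningProfile = "bbsI_U6",
    profiles: dict[str, CloningProfile] | None = None,
) -> tuple[str, str]:
    """Forward/reverse annealing oligos for guide expression cloning.

    The annealed duplex's insert region is exactly the prefix-adjusted
    protospacer: fwd = fwd_overhang + insert, rev = rev_overhang +
    revcomp(insert).
    """
    if isinstance(profile, str):
        registry = profiles or BUILTIN_CLONING_PROFILES
        if profile not in registry:
            raise UsageError(
                f"unknown cloning profile {profile!r}; known: {sorted(registry)}"
            )
        profile = registry[profile]
    proto = guide.protospacer if isinstance(guide, GuideCandidate) else guide
    insert = adjust_prefix(proto, profile.prepend_g_rule)
    return profile.fwd_overhang + insert, profile.rev_overhang + revcomp(insert)
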