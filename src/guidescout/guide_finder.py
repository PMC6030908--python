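"""PAM scanning and guide-candidate annotation.

A guide candidate is a protospacer+PAM occurrence on either strand of the
target sequence. Its identifier encodes the 1-based plus-strand position of
the PAM's first base and the strand, e.g. ``33forw`` / ``12rev`` — the same
identifier later names primers and pool oligos.

Genome/input ``N`` matches no IUPAC class, so PAMs or protospacers covering a
masked position are never called (the mask flags variant positions).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import ConfigurationError, UsageError
from .sequence_io import InputSequence, revcomp, revcomp_iupac

log = logging.getLogger(__name__)

#: IUPAC nucleotide classes. Deliberately restricted to concrete A/C/G/T
#: members: a genome ``N`` is a masked base and matches nothing, not even
#: pattern ``N``.
IUPAC_CLASSES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

GC_LOW_DEFAULT = 25.0
GC_HIGH_DEFAULT = 75.0
PREFIX_MODES = ("G-", "GG-", "A-", "none")
CONTEXT_HALF = 25  # bases each side of the cut in the stored context window


def iupac_match(pattern: str, seq: str) -> bool:
    """True iff every base of ``seq`` is in the IUPAC class of ``pattern``.

    Lengths must be equal. A masked base (``N`` in ``seq``) matches nothing.
    """
    if len(pattern) != len(seq):
        raise UsageError(
            f"pattern length {len(pattern)} != sequence length {len(seq)}"
        )
    for p, s in zip(pattern, seq):
        cls = IUPAC_CLASSES.get(p)
        if cls is None:
            raise ConfigurationError(f"unknown IUPAC code {p!r} in pattern")
        if s not in cls:
            return False
    return True


# ---------------------------------------------------------------------------
# Nuclease profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleaseProfile:
    """Where a nuclease binds and cuts.

    ``cut_offset`` is a signed offset from the PAM-proximal protospacer end
    along the guide: -3 for the Cas9 blunt cut between protospacer positions
    17/18, +18 for the PAM-distal staggered Cpf1 cut placed after position 18.
    """

    name: str
    pam: str
    pam_side: str  # "3" or "5" relative to the protospacer
    guide_len: int
    cut_offset: int
    blunt: bool
    alt_pams: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.pam:
            raise ConfigurationError("empty PAM pattern")
        if self.guide_len < 17:
            raise ConfigurationError("guide_len must be >= 17")
        if self.pam_side not in {"3", "5"}:
            raise ConfigurationError("pam_side must be '3' or '5'")


BUILTIN_NUCLEASES: dict[str, NucleaseProfile] = {
    "spcas9": NucleaseProfile(
        "SpCas9", "NGG", "3", 20, -3, True, alt_pams=("NAG", "NGA")
    ),
    "sacas9": NucleaseProfile("SaCas9", "NNGRRT", "3", 20, -3, True),
    "cpf1": NucleaseProfile("Cpf1", "TTTV", "5", 23, +18, False),
}


def get_nuclease(name: str) -> NucleaseProfile:
    try:
        return BUILTIN_NUCLEASES[name.lower()]
    except KeyError:
        raise UsageError(
            f"unknown nuclease {name!r}; known: {sorted(BUILTIN_NUCLEASES)}"
        ) from None


def cut_position(start: int, strand: str, profile: NucleaseProfile) -> int:
    """Plus-strand between-base cut coordinate for a protospacer at ``start``.

    ``start`` is the 0-based plus-strand start of the protospacer interval.
    """
    glen = profile.guide_len
    if profile.pam_side == "3":
        return (
            start + glen + profile.cut_offset
            if strand == "+"
            else start - profile.cut_offset
        )
    return (
        start + profile.cut_offset
        if strand == "+"
        else start + glen - profile.cut_offset
    )


# ---------------------------------------------------------------------------
# Guide candidates
# ---------------------------------------------------------------------------

@dataclass
class GuideCandidate:
    """One protospacer+PAM occurrence on the target sequence.

    ``start``/``pam_start`` are 0-based plus-strand coordinates of the
    protospacer / PAM intervals on the input. ``context`` is a guide-oriented
    window of 2x``CONTEXT_HALF`` bases centred on the cut, present only when
    the full window fits inside the input; ``context_cut`` is the junction
    offset within it.
    """

    guide_id: str
    protospacer: str
    pam_seq: str
    strand: str
    start: int
    pam_start: int
    cut: int
    flags: set[str] = field(default_factory=set)
    context: str | None = None
    context_cut: int | None = None
    # filled by the pipeline
    spec_score: float | None = None
    eff_score: float | None = None
    oof_score: float | None = None
    mm_counts: str | None = None
    enzymes: list[str] = field(default_factory=list)


def scan_guides(
    input_seq: InputSequence, nuclease: NucleaseProfile
) -> list[GuideCandidate]:
    """Find every guide candidate on both strands of the input.

    A candidate is emitted for every PAM occurrence whose full protospacer
    lies within the input. Minus-strand candidates report the protospacer and
    PAM reverse-complemented (guide orientation, 5'->3'). Output is ordered
    by the PAM's 1-based plus-strand position, plus strand first on ties.
    """
    seq = input_seq.sequence
    L = len(seq)
    glen, pam = nuclease.guide_len, nuclease.pam
    plen = len(pam)
    if L < glen + plen:
        raise UsageError(
            f"input length {L} < guide_len + PAM length {glen + plen}"
        )
    out: list[tuple[int, int, GuideCandidate]] = []

    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for q in range(L - plen + 1):  # PAM start on the scanned strand
            if not iupac_match(pam, s[q : q + plen]):
                continue
            if nuclease.pam_side == "3":
                t = q - glen
                if t < 0:
                    continue
            else:
                t = q + plen
                if t + glen > L:
                    continue
            proto = s[t : t + glen]
            if strand == "+":
                plus_start, plus_pam_start = t, q
                pam_pos1 = q + 1
            else:
                plus_start = L - t - glen
                plus_pam_start = L - q - plen
                pam_pos1 = L - q  # 1-based plus position of the PAM's 5' base
            cut = cut_position(plus_start, strand, nuclease)
            ctx = ctx_cut = None
            if cut - CONTEXT_HALF >= 0 and cut + CONTEXT_HALF <= L:
                window = seq[cut - CONTEXT_HALF : cut + CONTEXT_HALF]
                ctx = window if strand == "+" else revcomp(window)
                ctx_cut = CONTEXT_HALF
            suffix = "forw" if strand == "+" else "rev"
            cand = GuideCandidate(
                guide_id=f"{pam_pos1}{suffix}",
                protospacer=proto,
                pam_seq=s[q : q + plen],
                strand=strand,
                start=plus_start,
                pam_start=plus_pam_start,
                cut=cut,
                context=ctx,
                context_cut=ctx_cut,
            )
            out.append((pam_pos1, 0 if strand == "+" else 1, cand))

    out.sort(key=lambda x: (x[0], x[1]))
    return [c for _, _, c in out]


def annotate_flags(
    guide: GuideCandidate,
    input_seq: InputSequence,
    gc_low: float = GC_LOW_DEFAULT,
    gc_high: float = GC_HIGH_DEFAULT,
) -> GuideCandidate:
    """Set GC-content, TTTT and N-overlap warning flags on a candidate."""
    if not (0 <= gc_low < gc_high <= 100):
        raise UsageError(f"bad GC thresholds ({gc_low}, {gc_high})")
    proto = guide.protospacer
    gc = 100.0 * sum(b in "GC" for b in proto) / len(proto)
    guide.flags.discard("HIGH_GC")
    guide.flags.discard("LOW_GC")
    if gc > gc_high:
        guide.flags.add("HIGH_GC")
    elif gc < gc_low:
        guide.flags.add("LOW_GC")
    if "TTTT" in proto:
        guide.flags.add("TTTT")
    n_set = set(input_seq.n_positions)
    covered = set(range(guide.start, guide.start + len(proto))) | set(
        range(guide.pam_start, guide.pam_start + len(guide.pam_seq))
    )
    if covered & n_set:
        guide.flags.add("OVERLAPS_N")
    return guide


def prefix_filter(guides: list[GuideCandidate], mode: str) -> list[GuideCandidate]:
    """Keep guides whose protospacer starts with the mode's literal prefix.

    Modes: ``G-``, ``GG-``, ``A-`` (useful for U6/T7/U3 promoters) or
    ``none`` (identity).
    """
    if mode not in PREFIX_MODES:
        raise UsageError(f"unknown prefix mode {mode!r}; known: {PREFIX_MODES}")
    if mode == "none":
        return list(guides)
    prefix = mode.rstrip("-")
    return [g for g in guides if g.protospacer.startswith(prefix)]


# ---------------------------------------------------------------------------
# Restriction-enzyme screening
# ---------------------------------------------------------------------------

def load_enzyme_table(path: str | Path | None = None) -> dict[str, str]:
    """Load a 2-column TSV (name, IUPAC site); default: the built-in table."""
    if path is None:
        source = resources.files("guidescout.data") / "enzymes.tsv"
        text = source.read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, str] = {}
    for row in csv.reader(text.splitlines(), delimiter="\t"):
        if not row or row[0].startswith("#"):
            continue
        name, site = row[0], row[1].upper()
        for ch in site:
            if ch not in IUPAC_CLASSES:
                raise ConfigurationError(
                    f"enzyme {name}: bad IUPAC code {ch!r} in site {site}"
                )
        table[name] = site
    return table


def _site_occurrences(site: str, context: str) -> list[int]:
    """Start offsets where the site matches either strand (deduplicated)."""
    rc = revcomp_iupac(site)
    k = len(site)
    hits = []
    for o in range(len(context) - k + 1):
        window = context[o : o + k]
        if iupac_match(site, window) or iupac_match(rc, window):
            hits.append(o)
    return hits


def restriction_overlap(
    guide: GuideCandidate, enzymes: dict[str, str]
) -> list[str]:
    """Enzymes usable to screen for cleavage at this guide's cut site.

    An enzyme qualifies when its recognition site (either strand) occurs
    exactly once in the guide's context window and that occurrence spans the
    cut junction. Without a context window the answer is an empty list.
    """
    if guide.context is None or guide.context_cut is None:
        log.info("%s: context unavailable for enzyme screening", guide.guide_id)
        return []
    cut = guide.context_cut
    found = []
    for name, site in sorted(enzymes.items()):
        occ = _site_occurrences(site, guide.context)
        if len(occ) == 1 and occ[0] < cut < occ[0] + len(site):
            found.append(name)
    return found
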