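"""Mismatch-tolerant off-target search and specificity scoring.

Every genomic site (both strands) whose PAM matches the nuclease's canonical
pattern — or an alternative pattern such as NAG/NGA for SpCas9 when enabled —
and whose protospacer is within the mismatch budget (default 4) of the guide
is reported. Sites containing masked (``N``) bases are excluded.

Two independent search routes are provided: :func:`enumerate_offtargets`
(vectorized over numpy byte arrays) and :func:`brute_force_scan` (the obvious
pure-Python position-by-position oracle). They must agree exactly; the test
suite asserts it on randomized genomes.

Per-hit scores:

* MIT hit score in [0, 100]: ``100 * prod(1 - W[p]) * 1/(((19 - dmean)/19)*4
  + 1) * 1/m**2`` over the mismatch position set (mean-pairwise-distance and
  ``1/m**2`` terms only for m >= 2), positions numbered 1 (PAM-distal) to 20
  (PAM-proximal).
* CFD in [0, 1]: product of per-(position, guide base, off base) penalties
  times a PAM-class penalty; exactly 1 only for a perfect match with a
  canonical PAM.

The guide-level specificity score aggregates MIT hit scores as
``100 * 100 / (100 + sum(hits))`` — 100 with no off-targets, strictly
decreasing in every added hit.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, UsageError
from .guide_finder import IUPAC_CLASSES, GuideCandidate, NucleaseProfile, iupac_match
from .sequence_io import ExonAnnotation, GenomeIndex, revcomp

log = logging.getLogger(__name__)

MAX_MM_DEFAULT = 4
COLOR_LOW_DEFAULT = 30.0   # below: red
COLOR_HIGH_DEFAULT = 50.0  # at or above: green
REPORT_HIT_CAP = 1000      # highest-CFD hits kept in written reports


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

@dataclass
class ScoreTables:
    """Position weights and substitution penalties driving both scores.

    ``mit_weights[i]`` is the weight of position ``i + 1`` (1 = PAM-distal).
    ``cfd_mm`` maps ``(position, guide_base, off_base)`` to a penalty in
    [0, 1]; ``cfd_pam`` maps a PAM-class key (for NGG-type PAMs, the two
    bases after the N) to a penalty. A missing PAM key falls back to 1.0 for
    a canonical PAM and ``pam_default`` otherwise.
    """

    guide_len: int
    mit_weights: tuple[float, ...]
    cfd_mm: dict[tuple[int, str, str], float] = field(default_factory=dict)
    cfd_pam: dict[str, float] = field(default_factory=dict)
    pam_default: float = 0.25

    def __post_init__(self) -> None:
        if len(self.mit_weights) != self.guide_len:
            raise ConfigurationError(
                f"{len(self.mit_weights)} MIT weights for guide_len "
                f"{self.guide_len}"
            )
        if any(not 0.0 <= w <= 1.0 for w in self.mit_weights):
            raise ConfigurationError("MIT weights must lie in [0, 1]")
        if any(not 0.0 <= p <= 1.0 for p in self.cfd_mm.values()):
            raise ConfigurationError("CFD mismatch penalties must lie in [0, 1]")
        if any(not 0.0 <= p <= 1.0 for p in self.cfd_pam.values()):
            raise ConfigurationError("CFD PAM penalties must lie in [0, 1]")

    # -- constructors ------------------------------------------------------

    @classmethod
    def uniform(
        cls,
        guide_len: int,
        weight: float = 0.5,
        mm_penalty: float = 0.5,
        pam_noncanonical: float = 0.25,
    ) -> "ScoreTables":
        """Synthetic tables with one weight/penalty everywhere (for tests and
        for nucleases whose guide length the shipped 20-mer tables do not
        cover)."""
        cfd_mm = {
            (pos, g, o): mm_penalty
            for pos in range(1, guide_len + 1)
            for g in "ACGT"
            for o in "ACGT"
            if g != o
        }
        return cls(
            guide_len=guide_len,
            mit_weights=(weight,) * guide_len,
            cfd_mm=cfd_mm,
            cfd_pam={},
            pam_default=pam_noncanonical,
        )

    @classmethod
    def load_default(cls, guide_len: int = 20) -> "ScoreTables":
        """Shipped 20-mer tables; uniform synthetic tables otherwise."""
        if guide_len != 20:
            return cls.uniform(guide_len)
        data = resources.files("guidescout.data")
        weights = _read_weight_tsv(data / "mit_weights.tsv")
        cfd_mm = _read_cfd_mm_tsv(data / "cfd_mm_synthetic.tsv")
        cfd_pam = _read_cfd_pam_tsv(data / "cfd_pam_synthetic.tsv")
        return cls(20, weights, cfd_mm, cfd_pam)

    @classmethod
    def from_files(
        cls,
        guide_len: int,
        mit_weights_path: str | Path,
        cfd_mm_path: str | Path,
        cfd_pam_path: str | Path,
    ) -> "ScoreTables":
        return cls(
            guide_len,
            _read_weight_tsv(Path(mit_weights_path)),
            _read_cfd_mm_tsv(Path(cfd_mm_path)),
            _read_cfd_pam_tsv(Path(cfd_pam_path)),
        )

    # -- PAM penalty -------------------------------------------------------

    def pam_penalty(self, pam_seq: str, profile: NucleaseProfile) -> float:
        for key in (pam_seq, pam_seq[1:]):
            if key in self.cfd_pam:
                return self.cfd_pam[key]
        if iupac_match(profile.pam, pam_seq):
            return 1.0
        return self.pam_default


def _rows(source) -> list[list[str]]:
    text = source.read_text()
    return [
        row
        for row in csv.reader(text.splitlines(), delimiter="\t")
        if row and not row[0].startswith("#")
    ]


def _read_weight_tsv(source) -> tuple[float, ...]:
    rows = _rows(source)
    weights = {int(r[0]): float(r[1]) for r in rows[1:]}
    return tuple(weights[i] for i in sorted(weights))


def _read_cfd_mm_tsv(source) -> dict[tuple[int, str, str], float]:
    rows = _rows(source)
    return {(int(r[0]), r[1], r[2]): float(r[3]) for r in rows[1:]}


def _read_cfd_pam_tsv(source) -> dict[str, float]:
    rows = _rows(source)
    return {r[0]: float(r[1]) for r in rows[1:]}


# ---------------------------------------------------------------------------
# Per-hit scores
# ---------------------------------------------------------------------------

def _mismatch_positions(
    guide_seq: str, site_seq: str, pam_side: str
) -> tuple[int, ...]:
    """1-based mismatch positions counted from the PAM-distal end."""
    glen = len(guide_seq)
    pos = []
    for i, (g, s) in enumerate(zip(guide_seq, site_seq)):
        if g != s:
            pos.append(i + 1 if pam_side == "3" else glen - i)
    return tuple(sorted(pos))


def mit_hit_score(
    guide_seq: str,
    site_seq: str,
    tables: ScoreTables,
    pam_side: str = "3",
) -> float:
    """Per-off-target penalty score in [0, 100]; 100 for a perfect match."""
    if len(guide_seq) != len(site_seq):
        raise UsageError("guide and site lengths differ")
    if len(guide_seq) != tables.guide_len:
        raise UsageError(
            f"tables sized for {tables.guide_len}-mers, got {len(guide_seq)}"
        )
    positions = _mismatch_positions(guide_seq, site_seq, pam_side)
    m = len(positions)
    score = 100.0
    for p in positions:
        score *= 1.0 - tables.mit_weights[p - 1]
    if m >= 2:
        span = tables.guide_len - 1  # 19 for 20-mers
        pairs = [
            abs(positions[i] - positions[j])
            for i in range(m)
            for j in range(i + 1, m)
        ]
        dmean = sum(pairs) / len(pairs)
        score *= 1.0 / (((span - dmean) / span) * 4.0 + 1.0)
        score *= 1.0 / (m * m)
    return score


def cfd_score(
    guide_seq: str,
    site_seq: str,
    pam_seq: str,
    tables: ScoreTables,
    profile: NucleaseProfile,
) -> float:
    """Cutting-frequency-determination score in [0, 1]."""
    if len(guide_seq) != len(site_seq):
        raise UsageError("guide and site lengths differ")
    glen = len(guide_seq)
    score = 1.0
    for i, (g, s) in enumerate(zip(guide_seq, site_seq)):
        if g == s:
            continue
        p = i + 1 if profile.pam_side == "3" else glen - i
        key = (p, g, s)
        if key not in tables.cfd_mm:
            raise ConfigurationError(f"no CFD penalty for (position, pair) {key}")
        score *= tables.cfd_mm[key]
    return score * tables.pam_penalty(pam_seq, profile)


def specificity_score(hits: list["OffTargetHit"]) -> float:
    """Guide-level specificity: 100*100 / (100 + sum of MIT hit scores).

    The on-target hit (``is_on_target``) is skipped; callers normally pass
    off-targets only.
    """
    total = sum(h.mit_hit for h in hits if not h.is_on_target)
    return 100.0 * 100.0 / (100.0 + total)


def color_class(
    spec_score: float,
    low: float = COLOR_LOW_DEFAULT,
    high: float = COLOR_HIGH_DEFAULT,
) -> str:
    """Traffic-light class: green (recommended) / yellow / red (avoid)."""
    if not 0.0 <= spec_score <= 100.0:
        raise UsageError(f"specificity score {spec_score} outside [0, 100]")
    if spec_score >= high:
        return "green"
    if spec_score < low:
        return "red"
    return "yellow"


# ---------------------------------------------------------------------------
# Hits
# ---------------------------------------------------------------------------

@dataclass
class OffTargetHit:
    """A genomic site within the mismatch budget of a guide.

    ``start``/``pam_start`` are 0-based plus-strand coordinates of the
    protospacer / PAM intervals; ``site_seq``/``pam_seq`` are in guide
    orientation (5'->3' of the matched strand).
    """

    contig: str
    start: int
    strand: str
    site_seq: str
    pam_seq: str
    pam_start: int
    mismatches: int
    mismatch_positions: tuple[int, ...]
    mit_hit: float
    cfd: float
    in_exon: bool | None = None
    same_contig: bool | None = None
    is_on_target: bool = False
    guide_id: str = ""


def _hit_sort_key(h: OffTargetHit):
    return (h.mismatches, -h.cfd, h.contig, h.start, h.strand)


def _guide_seq(guide: GuideCandidate | str) -> str:
    return guide.protospacer if isinstance(guide, GuideCandidate) else guide


def _build_hit(
    contig: str,
    scan_start: int,
    pam_scan_start: int,
    strand: str,
    L: int,
    s: str,
    guide_seq: str,
    profile: NucleaseProfile,
    tables: ScoreTables,
) -> OffTargetHit:
    glen, plen = profile.guide_len, len(profile.pam)
    site = s[scan_start : scan_start + glen]
    pam = s[pam_scan_start : pam_scan_start + plen]
    if strand == "+":
        start, pam_start = scan_start, pam_scan_start
    else:
        start = L - scan_start - glen
        pam_start = L - pam_scan_start - plen
    positions = _mismatch_positions(guide_seq, site, profile.pam_side)
    return OffTargetHit(
        contig=contig,
        start=start,
        strand=strand,
        site_seq=site,
        pam_seq=pam,
        pam_start=pam_start,
        mismatches=len(positions),
        mismatch_positions=positions,
        mit_hit=mit_hit_score(guide_seq, site, tables, profile.pam_side),
        cfd=cfd_score(guide_seq, site, pam, tables, profile),
    )


def _finish(
    hits: list[OffTargetHit],
    target_locus: tuple[str, int, str] | None,
    guide_id: str,
) -> list[OffTargetHit]:
    for h in hits:
        h.guide_id = guide_id
        if target_locus is not None and (
            h.contig,
            h.start,
            h.strand,
        ) == tuple(target_locus):
            h.is_on_target = True
    hits.sort(key=_hit_sort_key)
    return hits


def _pam_patterns(profile: NucleaseProfile, alt_pams: bool) -> list[str]:
    pats = [profile.pam]
    if alt_pams:
        pats.extend(profile.alt_pams)
    return pats


def enumerate_offtargets(
    guide: GuideCandidate | str,
    genome: GenomeIndex,
    nuclease: NucleaseProfile,
    tables: ScoreTables | None = None,
    max_mm: int = MAX_MM_DEFAULT,
    alt_pams: bool = True,
    target_locus: tuple[str, int, str] | None = None,
) -> list[OffTargetHit]:
    """All genomic sites within ``max_mm`` mismatches of the guide.

    Vectorized scan: PAM positions are located with per-class byte masks and
    protospacer mismatch counts with a sliding-window comparison. Returns
    hits sorted by (mismatches asc, CFD desc, contig, start). When
    ``target_locus`` = (contig, start, strand) is given, the matching hit is
    flagged ``is_on_target``.
    """
    guide_seq = _guide_seq(guide)
    glen, plen = nuclease.guide_len, len(nuclease.pam)
    if len(guide_seq) != glen:
        raise UsageError(
            f"guide length {len(guide_seq)} != profile guide_len {glen}"
        )
    if not 0 <= max_mm <= 5:
        raise UsageError("max_mm must be in 0..5")
    if not genome.contigs:
        raise UsageError("empty genome")
    if tables is None:
        tables = ScoreTables.load_default(glen)

    masks = {
        code: np.isin(
            np.arange(256, dtype=np.uint8),
            np.frombuffer("".join(sorted(bases)).encode(), np.uint8),
        )
        for code, bases in IUPAC_CLASSES.items()
    }
    gb = np.frombuffer(guide_seq.encode(), np.uint8)
    patterns = _pam_patterns(nuclease, alt_pams)
    hits: list[OffTargetHit] = []

    for contig, seq in genome.contigs.items():
        L = len(seq)
        if L < glen + plen:
            continue
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            arr = np.frombuffer(s.encode(), np.uint8)
            n_cum = np.concatenate(
                ([0], np.cumsum(arr == ord("N"), dtype=np.int64))
            )
            n_pam = L - plen + 1
            pam_ok = np.zeros(n_pam, bool)
            for pat in patterns:
                ok = np.ones(n_pam, bool)
                for j, ch in enumerate(pat):
                    ok &= masks[ch][arr[j : j + n_pam]]
                pam_ok |= ok
            if nuclease.pam_side == "3":
                t = np.arange(0, L - glen - plen + 1)
                cand = t[pam_ok[t + glen]]
            else:
                t = np.arange(plen, L - glen + 1)
                cand = t[pam_ok[t - plen]]
            if cand.size == 0:
                continue
            windows = sliding_window_view(arr, glen)
            mm = (windows[cand] != gb).sum(axis=1)
            n_free = (n_cum[cand + glen] - n_cum[cand]) == 0
            for scan_start in cand[(mm <= max_mm) & n_free]:
                scan_start = int(scan_start)
                pam_scan = (
                    scan_start + glen
                    if nuclease.pam_side == "3"
                    else scan_start - plen
                )
                hits.append(
                    _build_hit(
                        contig, scan_start, pam_scan, strand, L, s,
                        guide_seq, nuclease, tables,
                    )
                )

    gid = guide.guide_id if isinstance(guide, GuideCandidate) else ""
    return _finish(hits, target_locus, gid)


def brute_force_scan(
    guide: GuideCandidate | str,
    genome: GenomeIndex,
    nuclease: NucleaseProfile,
    tables: ScoreTables | None = None,
    max_mm: int = MAX_MM_DEFAULT,
    alt_pams: bool = True,
    target_locus: tuple[str, int, str] | None = None,
) -> list[OffTargetHit]:
    """Reference oracle: same contract as :func:`enumerate_offtargets`,
    implemented as the obvious position-by-position scan."""
    guide_seq = _guide_seq(guide)
    glen, plen = nuclease.guide_len, len(nuclease.pam)
    if len(guide_seq) != glen:
        raise UsageError(
            f"guide length {len(guide_seq)} != profile guide_len {glen}"
        )
    if not 0 <= max_mm <= 5:
        raise UsageError("max_mm must be in 0..5")
    if not genome.contigs:
        raise UsageError("empty genome")
    if tables is None:
        tables = ScoreTables.load_default(glen)

    pattern_sets = [
        [IUPAC_CLASSES[ch] for ch in pat]
        for pat in _pam_patterns(nuclease, alt_pams)
    ]
    hits: list[OffTargetHit] = []
    for contig, seq in genome.contigs.items():
        L = len(seq)
        if L < glen + plen:
            continue
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            if nuclease.pam_side == "3":
                t_range = range(0, L - glen - plen + 1)
            else:
                t_range = range(plen, L - glen + 1)
            for t in t_range:
                q = t + glen if nuclease.pam_side == "3" else t - plen
                pam_hit = False
                for sets in pattern_sets:
                    match = True
                    for j, allowed in enumerate(sets):
                        if s[q + j] not in allowed:
                            match = False
                            break
                    if match:
                        pam_hit = True
                        break
                if not pam_hit:
                    continue
                site = s[t : t + glen]
                if "N" in site:
                    continue
                mm = 0
                for a, b in zip(guide_seq, site):
                    if a != b:
                        mm += 1
                        if mm > max_mm:
                            break
                if mm > max_mm:
                    continue
                hits.append(
                    _build_hit(
                        contig, t, q, strand, L, s, guide_seq, nuclease, tables
                    )
                )

    gid = guide.guide_id if isinstance(guide, GuideCandidate) else ""
    return _finish(hits, target_locus, gid)


# ---------------------------------------------------------------------------
# Filtering / aggregation helpers
# ---------------------------------------------------------------------------

def filter_hits(
    hits: list[OffTargetHit],
    annotation: ExonAnnotation | None = None,
    exonic_only: bool = False,
    same_contig_only: bool = False,
    target_contig: str | None = None,
) -> list[OffTargetHit]:
    """Annotate and filter hits by exon overlap and target chromosome.

    ``in_exon``/``same_contig`` are filled (when the respective reference is
    available) on copies of the hits; the filters compose.
    """
    if exonic_only and annotation is None:
        raise UsageError("exonic_only requires an exon annotation")
    out = []
    for h in hits:
        h = replace(h)
        if annotation is not None:
            span = range(h.start, h.start + len(h.site_seq))
            h.in_exon = any(
                iv.contig == h.contig and iv.start < span.stop and h.start < iv.end
                for iv in annotation.intervals
            )
        if target_contig is not None:
            h.same_contig = h.contig == target_contig
        if exonic_only and not h.in_exon:
            continue
        if same_contig_only:
            if target_contig is None:
                raise UsageError("same_contig_only requires target_contig")
            if not h.same_contig:
                continue
        out.append(h)
    return out


def mm_counts(hits: list[OffTargetHit], max_mm: int = MAX_MM_DEFAULT) -> str:
    """Histogram string "c0-c1-...-c<max_mm>" over off-target hits."""
    counts = [0] * (max_mm + 1)
    for h in hits:
        if not h.is_on_target and h.mismatches <= max_mm:
            counts[h.mismatches] += 1
    return "-".join(str(c) for c in counts)


def cap_hits(
    hits: list[OffTargetHit], cap: int = REPORT_HIT_CAP
) -> list[OffTargetHit]:
    """Keep the ``cap`` highest-CFD hits (report bound; full count is kept
    elsewhere); stable standard ordering is restored afterwards."""
    if len(hits) <= cap:
        return list(hits)
    top = sorted(hits, key=lambda h: (-h.cfd, h.mismatches, h.contig, h.start))[:cap]
    return sorted(top, key=_hit_sort_key)
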