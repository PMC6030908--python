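"""Sequence input/output and synthetic-fixture generation.

Genomes are plain multi-FASTA files; target regions are pasted sequences or
single-record FASTA; exon annotation is BED3+. All coordinates are 0-based
half-open internally. Human-facing TSV writers convert to 1-based inclusive
and flag it with a ``1`` suffix in the column name.

Two conventions apply throughout the package:

* sequences are uppercased on ingest, ``U`` is mapped to ``T``, and any other
  IUPAC/unknown letter is mapped to ``N``;
* ``N`` means "masked/variant position" and never matches a guide base or a
  PAM class, so guides and off-target sites containing ``N`` are dropped.
"""

from __future__ import annotations

import io
import logging
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FixtureError, FormatError, SequenceInputError

log = logging.getLogger(__name__)

#: Minimum usable target length: one protospacer plus the longest built-in PAM.
MIN_INPUT_LEN = 23

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Complement map for full IUPAC patterns (used for restriction sites).
_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_VALID_IUPAC = set("ACGTUNRYSWKMBDHV")
_AMBIGUOUS = set("RYSWKMBDHV")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_iupac(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern (R<->Y, K<->M, B<->V, D<->H)."""
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


def _normalize(seq: str, origin: str) -> str:
    """Uppercase, U->T, anything non-ACGTN -> N (with one warning per record)."""
    up = seq.upper().replace("U", "T")
    cleaned = []
    n_mapped = 0
    for ch in up:
        if ch in "ACGTN":
            cleaned.append(ch)
        else:
            cleaned.append("N")
            n_mapped += 1
    if n_mapped:
        log.warning("%s: %d non-ACGTN letter(s) mapped to N", origin, n_mapped)
    return "".join(cleaned)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeIndex:
    """Named contig sequences, uppercase A/C/G/T/N."""

    contigs: dict[str, str]
    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lengths = {name: len(seq) for name, seq in self.contigs.items()}


@dataclass
class InputSequence:
    """A target sequence with its case mask and masked (N) positions.

    ``case_mask[i]`` is True where the pasted sequence was lowercase — users
    mark sub-regions that way. ``n_positions`` lists 0-based offsets of masked
    bases (pasted ``N``/``n`` or ambiguity codes mapped to N).
    """

    name: str
    sequence: str
    case_mask: tuple[bool, ...]
    n_positions: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ExonInterval:
    contig: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    name: str = "."
    strand: str = "."


@dataclass
class ExonAnnotation:
    intervals: list[ExonInterval]


@dataclass(frozen=True)
class PlantedSite:
    """Record of one site planted by :func:`generate_toy_genome`.

    ``start`` is the 0-based plus-strand start of the protospacer interval.
    """

    contig: str
    start: int
    strand: str
    mismatches: int


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeIndex:
    """Read a multi-FASTA genome.

    Record names are the first whitespace-delimited header token. Sequences
    are normalized (see module docstring). Duplicate names and empty files
    are format errors.
    """
    path = Path(path)
    contigs: dict[str, str] = {}
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: cannot parse FASTA: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    for rec in records:
        name = rec.id
        if name in contigs:
            raise FormatError(f"{path}: duplicate record name {name!r}")
        contigs[name] = _normalize(str(rec.seq), f"{path}:{name}")
    return GenomeIndex(contigs)


def write_fasta(genome: GenomeIndex, path: str | Path) -> None:
    """Write a genome as multi-FASTA, wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# Input sequence
# ---------------------------------------------------------------------------

def parse_input_sequence(text: str, name: str = "input") -> InputSequence:
    """Parse a pasted target sequence or single-record FASTA.

    Whitespace and digits are stripped (so numbered sequence dumps paste
    cleanly). Lowercase is recorded in the case mask; N/n and IUPAC ambiguity
    codes are masked positions. Anything else is an input error.
    """
    text = text.strip()
    if text.startswith(">"):
        records = list(SeqIO.parse(io.StringIO(text), "fasta"))
        if len(records) != 1:
            raise SequenceInputError(
                f"expected a single FASTA record, found {len(records)}"
            )
        name = records[0].id or name
        raw = str(records[0].seq)
    else:
        raw = text
    stripped = "".join(
        ch for ch in raw if ch not in string.whitespace and not ch.isdigit()
    )
    bad = sorted({ch for ch in stripped if ch.upper() not in _VALID_IUPAC})
    if bad:
        raise SequenceInputError(f"non-IUPAC character(s) in input: {bad}")
    if len(stripped) < MIN_INPUT_LEN:
        raise SequenceInputError(
            f"input too short: {len(stripped)} < {MIN_INPUT_LEN} bases"
        )
    case_mask = tuple(ch.islower() for ch in stripped)
    upper = stripped.upper().replace("U", "T")
    seq_chars = []
    n_positions = []
    for i, ch in enumerate(upper):
        if ch in "ACGT":
            seq_chars.append(ch)
        else:  # N or ambiguity code
            seq_chars.append("N")
            n_positions.append(i)
    return InputSequence(
        name=name,
        sequence="".join(seq_chars),
        case_mask=case_mask,
        n_positions=tuple(n_positions),
    )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> ExonAnnotation:
    """Read a BED3+ file into an exon annotation (0-based half-open kept)."""
    path = Path(path)
    intervals: list[ExonInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] else "."
            strand = fields[5] if len(fields) > 5 and fields[5] else "."
            if strand not in {"+", "-", "."}:
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            intervals.append(ExonInterval(fields[0], start, end, name, strand))
    return ExonAnnotation(intervals)


def write_bed(annotation: ExonAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in annotation.intervals:
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

def _mutate(guide: str, m: int, rng: np.random.Generator) -> str:
    """Return the guide mutated at exactly ``m`` distinct positions."""
    bases = "ACGT"
    seq = list(guide)
    if m == 0:
        return guide
    pos = rng.choice(len(seq), size=m, replace=False)
    for p in pos:
        alts = [b for b in bases if b != seq[p]]
        seq[p] = alts[rng.integers(len(alts))]
    return "".join(seq)


def _concrete_pam(pattern: str, rng: np.random.Generator) -> str:
    """Instantiate an IUPAC PAM pattern to a concrete canonical sequence."""
    from .guide_finder import IUPAC_CLASSES  # local import; no cycle at load

    out = []
    for ch in pattern:
        choices = sorted(IUPAC_CLASSES[ch])
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def generate_toy_genome(
    n_contigs: int,
    contig_len: int,
    guide: str,
    plant_plan: Sequence[tuple[int, str]],
    nuclease,
    seed: int,
    max_retries: int = 20,
) -> tuple[GenomeIndex, list[PlantedSite]]:
    """Build a random genome with off-target sites planted by plan.

    Each plan entry ``(m, strand)`` plants one guide+canonical-PAM site with
    exactly ``m`` protospacer mismatches (``m`` up to 5; the PAM is kept
    canonical). After planting, a brute-force scan (alternative PAMs included)
    verifies that no accidental site within ``max(4, max planted m)``
    mismatches exists; on collision the background is regenerated, up to
    ``max_retries`` times. Pure function of its arguments including seed.
    """
    from .offtarget import brute_force_scan  # deferred to avoid import cycle

    if contig_len < 100:
        raise FixtureError("contig_len must be >= 100")
    glen = nuclease.guide_len
    plen = len(nuclease.pam)
    site_len = glen + plen
    if len(guide) != glen:
        raise FixtureError(
            f"guide length {len(guide)} != profile guide_len {glen}"
        )
    for m, strand in plant_plan:
        if not (0 <= m <= 5) or strand not in "+-":
            raise FixtureError(f"bad plan entry ({m}, {strand!r})")

    budget = max([4] + [m for m, _ in plant_plan])
    rng = np.random.default_rng(seed)
    contig_names = [f"c{i + 1}" for i in range(n_contigs)]

    for _attempt in range(max_retries):
        contigs = {
            name: "".join(
                np.array(list("ACGT"))[rng.integers(0, 4, size=contig_len)]
            )
            for name in contig_names
        }
        # place plan entries round-robin over contigs at non-overlapping spots
        placements: list[tuple[str, int, int, str]] = []  # contig, pos, m, strand
        used: dict[str, list[tuple[int, int]]] = {n: [] for n in contig_names}
        ok = True
        for i, (m, strand) in enumerate(plant_plan):
            cname = contig_names[i % n_contigs]
            placed = False
            for _try in range(200):
                pos = int(rng.integers(1, contig_len - site_len - 1))
                if all(
                    pos + site_len + 1 <= a or pos >= b + 1
                    for a, b in used[cname]
                ):
                    used[cname].append((pos, pos + site_len))
                    placements.append((cname, pos, m, strand))
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if not ok:
            continue

        records: list[PlantedSite] = []
        for cname, pos, m, strand in placements:
            proto = _mutate(guide, m, rng)
            pam = _concrete_pam(nuclease.pam, rng)
            if nuclease.pam_side == "3":
                site = proto + pam
                proto_off = 0 if strand == "+" else plen
            else:
                site = pam + proto
                proto_off = plen if strand == "+" else 0
            if strand == "-":
                site = revcomp(site)
            seq = contigs[cname]
            contigs[cname] = seq[:pos] + site + seq[pos + site_len:]
            records.append(PlantedSite(cname, pos + proto_off, strand, m))

        genome = GenomeIndex(contigs)
        hits = brute_force_scan(
            guide, genome, nuclease, max_mm=budget, alt_pams=True
        )
        found = {(h.contig, h.start, h.strand, h.mismatches) for h in hits}
        expected = {
            (r.contig, r.start, r.strand, r.mismatches) for r in records
        }
        if found == expected:
            records.sort(key=lambda r: (r.contig, r.start))
            return genome, records
        log.debug("fixture collision on attempt %d; regenerating", _attempt + 1)

    raise FixtureError(
        f"could not satisfy plant plan after {max_retries} attempts"
    )


def write_plan(records: Iterable[PlantedSite], path: str | Path) -> None:
    """Write planted-site records as TSV (contig, start, strand, mismatches)."""
    with open(path, "w") as fh:
        fh.write("contig\tstart\tstrand\tmismatches\n")
        for r in records:
            fh.write(f"{r.contig}\t{r.start}\t{r.strand}\t{r.mismatches}\n")


def read_plan(path: str | Path) -> list[PlantedSite]:
    records = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("contig\t"):
            raise FormatError(f"{path}: missing plan header")
        for line in fh:
            c, s, st, m = line.rstrip("\n").split("\t")
            records.append(PlantedSite(c, int(s), st, int(m)))
    return records
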