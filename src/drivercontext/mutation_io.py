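"""Reading, writing and sequence-context extraction for somatic point mutations.

Mutations are single-nucleotide substitutions on the forward strand of a
reference genome, with 1-based fully-closed coordinates.  The *neighborhood*
of a mutation with window size ``n`` is the string of ``2n + 1`` reference
bases centered on the mutated position: ``n`` bases 5', the wild-type base,
and ``n`` bases 3'.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from pyfaidx import Fasta

logger = logging.getLogger("drivercontext")

BASES = ("A", "C", "G", "T")

#: Fixed enumeration of the 12 point-substitution types.  The ordering is the
#: conventional ref-major listing A>T, A>G, A>C, T>A, T>G, T>C, G>A, G>C, G>T,
#: C>T, C>A, C>G and is stable across runs.
SUBSTITUTION_ORDER = (
    ("A", "T"), ("A", "G"), ("A", "C"),
    ("T", "A"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("G", "C"), ("G", "T"),
    ("C", "T"), ("C", "A"), ("C", "G"),
)
_SUB_CODE = {pair: i for i, pair in enumerate(SUBSTITUTION_ORDER)}

MIN_WINDOW = 1
MAX_WINDOW = 10

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MutationFormatError(ValueError):
    """A mutation table is structurally invalid (e.g. missing columns)."""


class GenomeLookupError(KeyError):
    """A contig or coordinate window cannot be resolved in the genome."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MutationRecord:
    """One somatic single-nucleotide substitution.

    ``label`` is ``"driver"``, ``"passenger"`` or ``None`` (unlabeled).
    """

    chromosome: str
    position: int
    ref_base: str
    alt_base: str
    label: str | None = None
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.ref_base not in BASES or self.alt_base not in BASES:
            raise ValueError(
                f"alleles must be in {BASES}: {self.ref_base}>{self.alt_base}"
            )
        if self.ref_base == self.alt_base:
            raise ValueError(
                f"ref and alt are identical ({self.ref_base}); "
                "not one of the 12 substitution types"
            )
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.label is not None and self.label not in ("driver", "passenger"):
            raise ValueError(f"label must be driver/passenger/None, got {self.label!r}")

    @property
    def key(self) -> str:
        """Canonical identifier ``chrom:pos:ref>alt``."""
        return f"{self.chromosome}:{self.position}:{self.ref_base}>{self.alt_base}"


@dataclass(frozen=True)
class Neighborhood:
    """The raw reference-sequence context of one mutation.

    ``sequence`` has length ``2 * window_size + 1``; its center character is
    the wild-type base at the mutated position (forward strand).
    """

    mutation: MutationRecord
    window_size: int
    sequence: str
    substitution_type: int
    chromosome_code: int

    def __post_init__(self) -> None:
        if len(self.sequence) != 2 * self.window_size + 1:
            raise ValueError(
                f"sequence length {len(self.sequence)} != 2*{self.window_size}+1"
            )


def substitution_code(ref: str, alt: str) -> int:
    """Map an ordered (ref, alt) base pair to its integer code in [0, 11]."""
    if ref == alt:
        raise ValueError(f"ref and alt must differ, got {ref}>{alt}")
    try:
        return _SUB_CODE[(ref, alt)]
    except KeyError:
        raise ValueError(f"alleles must be in {BASES}: {ref}>{alt}") from None


def chromosome_code(name: str) -> int:
    """Encode a contig name as a stable integer.

    Autosomes 1-22 map to themselves, X to 23, Y to 24.  Any other contig is
    hashed into a stable bucket >= 25 (with a warning), so toy genomes with
    arbitrary contig names remain usable.
    """
    clean = name[3:] if name.lower().startswith("chr") else name
    if clean.isdigit() and 1 <= int(clean) <= 22:
        return int(clean)
    if clean.upper() == "X":
        return 23
    if clean.upper() == "Y":
        return 24
    bucket = 25 + zlib.crc32(clean.upper().encode()) % 100
    if name not in _warned_contigs:
        _warned_contigs.add(name)
        logger.warning("non-canonical contig %r encoded as hash bucket %d", name, bucket)
    return bucket


_warned_contigs: set[str] = set()


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ("chrom", "pos", "ref", "alt")


def read_mutations(
    path: str | Path,
    dialect: str = "tsv",
    deduplicate: bool = True,
) -> list[MutationRecord]:
    """Read a mutation table.

    ``dialect="tsv"`` expects a header ``chrom pos ref alt [label] [gene]``;
    ``dialect="vcf-min"`` reads CHROM/POS/REF/ALT of SNV rows from a minimal
    VCF (non-SNV rows are skipped with a logged count).  Rows with invalid
    alleles or ref == alt are skipped with a row-indexed warning.  Duplicate
    (chrom, pos, ref, alt) records are dropped by default with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        records = _read_tsv(path)
    elif dialect == "vcf-min":
        records = _read_vcf_min(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if deduplicate:
        seen: set[str] = set()
        unique = []
        for rec in records:
            if rec.key not in seen:
                seen.add(rec.key)
                unique.append(rec)
        dropped = len(records) - len(unique)
        if dropped:
            logger.info("dropped %d duplicate mutation record(s)", dropped)
        records = unique
    return records


def _parse_row(idx: int, chrom: str, pos: str, ref: str, alt: str,
               label: str | None, gene: str | None,
               rejected: list[str]) -> MutationRecord | None:
    try:
        if label is not None:
            label = label.strip().lower() or None
        return MutationRecord(
            chromosome=chrom.strip(),
            position=int(pos),
            ref_base=ref.strip().upper(),
            alt_base=alt.strip().upper(),
            label=label,
            gene=(gene.strip() or None) if gene is not None else None,
        )
    except ValueError as exc:
        rejected.append(f"row {idx}: {exc}")
        return None


def _read_tsv(path: Path) -> list[MutationRecord]:
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise MutationFormatError(f"{path}: empty file, expected a header")
        header = [h.strip().lower() for h in header_line.rstrip("\n").split("\t")]
        missing = [c for c in _TSV_COLUMNS if c not in header]
        if missing:
            raise MutationFormatError(f"{path}: missing required column(s) {missing}")
        col = {name: header.index(name) for name in header}
        records: list[MutationRecord] = []
        rejected: list[str] = []
        for idx, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            get = lambda name: fields[col[name]] if name in col and col[name] < len(fields) else None
            rec = _parse_row(
                idx, get("chrom") or "", get("pos") or "", get("ref") or "",
                get("alt") or "", get("label"), get("gene"), rejected,
            )
            if rec is not None:
                records.append(rec)
    for msg in rejected:
        logger.warning("%s: skipped %s", path, msg)
    return records


def _read_vcf_min(path: Path) -> list[MutationRecord]:
    records: list[MutationRecord] = []
    rejected: list[str] = []
    n_non_snv = 0
    with open(path) as fh:
        for idx, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                rejected.append(f"row {idx}: fewer than 5 VCF columns")
                continue
            chrom, pos, _id, ref, alt = fields[:5]
            if len(ref) != 1 or len(alt) != 1 or "," in alt:
                n_non_snv += 1
                continue
            rec = _parse_row(idx, chrom, pos, ref, alt, None, None, rejected)
            if rec is not None:
                records.append(rec)
    if n_non_snv:
        logger.info("%s: skipped %d non-SNV VCF row(s)", path, n_non_snv)
    for msg in rejected:
        logger.warning("%s: skipped %s", path, msg)
    return records


def write_mutations(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write records as the canonical TSV (header chrom pos ref alt label gene)."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tlabel\tgene\n")
        for rec in records:
            fh.write(
                f"{rec.chromosome}\t{rec.position}\t{rec.ref_base}\t{rec.alt_base}"
                f"\t{rec.label or ''}\t{rec.gene or ''}\n"
            )


# ---------------------------------------------------------------------------
# Neighborhood extraction
# ---------------------------------------------------------------------------

def open_genome(path: str | Path) -> Fasta:
    """Open an indexed FASTA (a .fai sidecar is created if absent)."""
    return Fasta(str(path), sequence_always_upper=True)


def extract_neighborhood(
    mutation: MutationRecord,
    genome: Fasta,
    window_size: int,
    on_mismatch: str = "warn",
) -> Neighborhood:
    """Extract the 2n+1-base forward-strand context of a mutation.

    The center base is taken from the genome; if it disagrees with the
    record's ref allele the genome base is kept and a warning is emitted
    (``on_mismatch="error"`` raises instead).
    """
    if not (MIN_WINDOW <= window_size <= MAX_WINDOW):
        raise ValueError(f"window_size must be in [{MIN_WINDOW}, {MAX_WINDOW}]")
    if mutation.chromosome not in genome:
        raise GenomeLookupError(f"contig {mutation.chromosome!r} not in genome")
    contig = genome[mutation.chromosome]
    n = window_size
    start = mutation.position - n       # 1-based
    end = mutation.position + n
    if start < 1 or end > len(contig):
        raise IndexError(
            f"window [{start}, {end}] overruns contig {mutation.chromosome} "
            f"(length {len(contig)})"
        )
    # 1-based closed -> 0-based half-open
    seq = str(contig[start - 1:end]).upper()
    center = seq[n]
    if center != mutation.ref_base:
        msg = (
            f"{mutation.key}: genome base {center} != record ref "
            f"{mutation.ref_base}; keeping genome base"
        )
        if on_mismatch == "error":
            raise ValueError(msg)
        logger.warning(msg)
    return Neighborhood(
        mutation=mutation,
        window_size=n,
        sequence=seq,
        substitution_type=substitution_code(mutation.ref_base, mutation.alt_base),
        chromosome_code=chromosome_code(mutation.chromosome),
    )


def extract_neighborhoods(
    mutations: Sequence[MutationRecord],
    genome: Fasta,
    window_size: int,
    on_ambiguous: str = "skip",
) -> list[Neighborhood]:
    """Extract neighborhoods for a batch of mutations.

    Windows containing ambiguous bases (N) are skipped with a warning by
    default; ``on_ambiguous="error"`` raises instead.  Boundary overruns are
    likewise skipped in batch mode (each logged).
    """
    out: list[Neighborhood] = []
    n_skipped = 0
    for mut in mutations:
        try:
            nb = extract_neighborhood(mut, genome, window_size)
        except IndexError as exc:
            logger.warning("skipping %s: %s", mut.key, exc)
            n_skipped += 1
            continue
        if any(b not in BASES for b in nb.sequence):
            if on_ambiguous == "error":
                raise ValueError(f"{mut.key}: ambiguous base in window {nb.sequence}")
            logger.warning("skipping %s: ambiguous base in window", mut.key)
            n_skipped += 1
            continue
        out.append(nb)
    if n_skipped:
        logger.info("skipped %d/%d mutations during extraction", n_skipped, len(mutations))
    return out
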