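"""Promoter sequence and SNP description input.

Reads multi-record FASTA promoter files and tab-separated SNP tables,
constructs ancestral/minor allele sequences by exact flank matching, and
builds fixed-width allele contexts centred on the edited position.

Coordinates are 0-based half-open internally; user-facing output keeps the
flank-anchored notation of the input tables.  Case is display-only: all
computation is done on upper-cased sequences.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "PromoterRecord",
    "SnpRecord",
    "AlleleContext",
    "ParseError",
    "SchemaError",
    "ContextNotFoundError",
    "AmbiguousContextError",
    "parse_inputs",
    "read_fasta",
    "read_snp_table",
    "read_vcf_subset",
    "apply_allele",
    "build_context_pair",
]

_DNA_ALPHABET = frozenset("ACGT")

#: Promoter scan window relative to the transcription start site.
REGION_START = -70
REGION_END = -20


class ParseError(ValueError):
    """A sequence field contains characters outside the DNA alphabet."""


class SchemaError(ValueError):
    """The SNP table is missing a mandatory column."""


class ContextNotFoundError(ValueError):
    """flank5 + wt + flank3 does not occur in the target sequence."""


class AmbiguousContextError(ValueError):
    """flank5 + wt + flank3 occurs more than once in the target sequence."""


def _check_dna(s: str, what: str, line: int | None = None) -> str:
    up = s.upper()
    bad = set(up) - _DNA_ALPHABET
    if bad:
        where = f" (line {line})" if line is not None else ""
        raise ParseError(
            f"non-ACGT character {sorted(bad)!r} in {what}{where}: {s!r}"
        )
    return up


@dataclass
class PromoterRecord:
    """One promoter sequence.

    ``tss_offset``, when present, is the index of the transcription start
    within ``sequence`` so that the [-70; -20] region lies inside it.
    """

    id: str
    gene: str
    sequence: str
    tss_offset: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"empty sequence for promoter {self.id!r}")
        self.sequence = _check_dna(self.sequence, f"promoter {self.id!r}")
        if self.tss_offset is not None:
            lo = self.tss_offset + REGION_START
            hi = self.tss_offset + REGION_END
            if lo < 0 or hi > len(self.sequence):
                raise ValueError(
                    f"promoter {self.id!r}: [{REGION_START};{REGION_END}] "
                    "region relative to tss_offset falls outside the sequence"
                )

    def core_region(self) -> str:
        """The [-70; -20] sub-sequence (the whole sequence if no TSS given)."""
        if self.tss_offset is None:
            return self.sequence
        return self.sequence[
            self.tss_offset + REGION_START : self.tss_offset + REGION_END + 1
        ]


@dataclass
class SnpRecord:
    """One promoter variant described by its flanks and alleles.

    ``wt`` may be multi-base, and is empty for an insertion; an empty string
    in ``minors`` denotes a deletion.  ``minors`` keeps the printed order of
    a multi-allele cell.
    """

    id: str
    flank5: str
    wt: str
    minors: list[str]
    flank3: str
    gene: str = ""
    #: original-case fields for echoing in reports
    display: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.flank5 or not self.flank3:
            raise ParseError(f"SNP {self.id!r}: flanks must be non-empty")
        self.flank5 = _check_dna(self.flank5, f"SNP {self.id!r} flank5")
        self.flank3 = _check_dna(self.flank3, f"SNP {self.id!r} flank3")
        self.wt = _check_dna(self.wt, f"SNP {self.id!r} wt") if self.wt else ""
        if not self.minors:
            raise ParseError(f"SNP {self.id!r}: needs at least one minor allele")
        self.minors = [
            _check_dna(m, f"SNP {self.id!r} minor") if m else "" for m in self.minors
        ]
        for m in self.minors:
            if m == self.wt:
                raise ParseError(f"SNP {self.id!r}: minor allele equals wt")

    @property
    def edit_type(self) -> str:
        if self.wt == "":
            return "insertion"
        if any(len(m) < len(self.wt) for m in self.minors):
            return "deletion"
        return "substitution"

    def wt_context(self) -> str:
        return self.flank5 + self.wt + self.flank3

    def minor_context(self, index: int = 0) -> str:
        return self.flank5 + self.minors[index] + self.flank3


@dataclass
class AlleleContext:
    """A fixed-width sequence context around one allele of a SNP."""

    snp_id: str
    allele_label: str
    sequence: str


# ---------------------------------------------------------------------------
# parsing

_SNP_COLUMNS = ("snp_id", "gene", "flank5", "wt", "minors", "flank3")


def read_fasta(fasta_path: str | Path) -> list[PromoterRecord]:
    path = Path(fasta_path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = rec.description.split()[1] if len(rec.description.split()) > 1 else rec.id
        records.append(PromoterRecord(id=rec.id, gene=gene, sequence=str(rec.seq)))
    return records


def _split_alleles(cell: str) -> list[str]:
    # "-" and "" both denote an absent allele (deletion/insertion notation)
    out = []
    for tok in cell.split(","):
        tok = tok.strip()
        out.append("" if tok in {"-", "−", ""} else tok)
    return out


def read_snp_table(snp_path: str | Path) -> list[SnpRecord]:
    path = Path(snp_path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    if not rows:
        return []
    header = [h.strip() for h in rows[0]]
    missing = [c for c in _SNP_COLUMNS if c not in header]
    if missing:
        raise SchemaError(f"SNP table {path} is missing mandatory columns: {missing}")
    idx = {c: header.index(c) for c in _SNP_COLUMNS}
    records = []
    for lineno, row in enumerate(rows[1:], start=2):
        cells = {c: row[idx[c]].strip() for c in _SNP_COLUMNS}
        wt_cell = cells["wt"]
        wt = "" if wt_cell in {"-", "−", ""} else wt_cell
        try:
            rec = SnpRecord(
                id=cells["snp_id"],
                flank5=cells["flank5"],
                wt=wt,
                minors=_split_alleles(cells["minors"]),
                flank3=cells["flank3"],
                gene=cells["gene"],
                display={"flank5": cells["flank5"], "wt": wt_cell, "minors": cells["minors"], "flank3": cells["flank3"]},
            )
        except ParseError as exc:
            raise ParseError(f"{path} line {lineno}: {exc}") from exc
        records.append(rec)
    return records


def parse_inputs(
    fasta_path: str | Path, snp_path: str | Path
) -> tuple[list[PromoterRecord], list[SnpRecord]]:
    """Read a promoter FASTA and a SNP table, preserving file order."""
    return read_fasta(fasta_path), read_snp_table(snp_path)


def read_vcf_subset(
    vcf_path: str | Path,
    bed_path: str | Path,
    fasta_path: str | Path,
    flank: int = 10,
) -> list[SnpRecord]:
    """Minimal VCF-subset reader (CHROM, POS, ID, REF, ALT).

    Variants falling inside a BED interval are converted to flank-anchored
    :class:`SnpRecord` objects by slicing flanks from the matching FASTA
    record (named after the BED interval).  Alleles are taken on the forward
    strand of the supplied promoter sequence; no strand flipping is done.
    """
    promoters = {p.id: p for p in read_fasta(fasta_path)}
    intervals = []
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            intervals.append((chrom, start, end, name))
    out: list[SnpRecord] = []
    with open(vcf_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, pos_s, vid, ref, alt = line.split("\t")[:5]
            pos = int(pos_s)  # 1-based
            for ichrom, start, end, name in intervals:
                if ichrom != chrom or not (start < pos <= end):
                    continue
                prom = promoters.get(name)
                if prom is None:
                    continue
                # offset of the variant inside the promoter sequence
                off = pos - 1 - start
                seq = prom.sequence
                if seq[off : off + len(ref)].upper() != ref.upper():
                    raise ParseError(
                        f"VCF {vid}: REF {ref!r} does not match promoter "
                        f"{name!r} at offset {off}"
                    )
                f5 = seq[max(0, off - flank) : off]
                f3 = seq[off + len(ref) : off + len(ref) + flank]
                out.append(
                    SnpRecord(
                        id=vid if vid != "." else f"{chrom}:{pos}",
                        flank5=f5,
                        wt=ref,
                        minors=_split_alleles(alt),
                        flank3=f3,
                        gene=name,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# allele application and context building


def apply_allele(sequence: str, snp: SnpRecord, allele: str | int = "wt") -> str:
    """Replace the wt allele at the flank-anchored locus with ``allele``.

    ``allele`` is ``"wt"``, a minor index, or a literal allele string.
    The locus flank5+wt+flank3 must occur exactly once (case-insensitive).
    """
    seq_up = sequence.upper()
    locus = snp.wt_context()
    n = seq_up.count(locus)
    if n == 0:
        raise ContextNotFoundError(
            f"SNP {snp.id!r}: context not found in target sequence"
        )
    if n > 1:
        raise AmbiguousContextError(
            f"SNP {snp.id!r}: ambiguous context ({n} matches)"
        )
    if allele == "wt":
        replacement = snp.wt
    elif isinstance(allele, int):
        replacement = snp.minors[allele]
    else:
        replacement = allele.upper()
    i = seq_up.index(locus) + len(snp.flank5)
    return seq_up[:i] + replacement + seq_up[i + len(snp.wt) :]


def _flank_takes(snp: SnpRecord, width: int) -> tuple[int, int]:
    """How many bases of each flank go into a width-targeted wt context.

    The edited position is centred, left-of-centre on ties; if one flank is
    too short the other one makes up the difference.
    """
    need = max(0, width - len(snp.wt))
    left_ideal = need // 2
    take5 = min(len(snp.flank5), left_ideal)
    take3 = min(len(snp.flank3), need - take5)
    take5 = min(len(snp.flank5), need - take3)
    return take5, take3


def build_context_pair(
    snp: SnpRecord, width: int = 26, minor_index: int = 0
) -> tuple[AlleleContext, AlleleContext]:
    """Build the wt and minor allele contexts of a SNP at a target width.

    The wt context has length ``width`` whenever the flanks allow; otherwise
    a warning is issued and the shorter context is returned.  Both contexts
    share identical flank sub-sequences, so their length difference equals
    the allele length difference.
    """
    take5, take3 = _flank_takes(snp, width)
    f5 = snp.flank5[len(snp.flank5) - take5 :]
    f3 = snp.flank3[:take3]
    wt_seq = f5 + snp.wt + f3
    if len(wt_seq) < width:
        warnings.warn(
            f"SNP {snp.id!r}: flanks too short for width {width}; "
            f"wt context has length {len(wt_seq)}",
            stacklevel=2,
        )
    minor_seq = f5 + snp.minors[minor_index] + f3
    return (
        AlleleContext(snp.id, "wt", wt_seq),
        AlleleContext(snp.id, f"minor_{minor_index + 1}", minor_seq),
    )
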