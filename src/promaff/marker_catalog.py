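"""Machine-readable catalog of the curated promoter-variant marker rows.

The packaged fixture transcribes, row by row, a curated set of 90 promoter
variants: flank-anchored alleles, measured/predicted K_D values for the
ancestral (wt) and minor alleles, the printed Z / alpha / rank columns, the
direction of the predicted expression change, candidate/known-marker flags,
and a short risk annotation.  The catalog feeds both the affinity-model
calibration (K_D anchors) and the selection-pressure statistics.

Genes MAPT, APP, APOE, PSEN1 and PSEN2 form the familial-AD group; all
other genes form the "other hereditary diseases" group.

A small number of fields are intentionally absent where the source table
prints none, and one row (rs752158054) carries an unprinted 25-bp wt allele
encoded as Ns; rows containing Ns are excluded from sequence anchors.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .promoter_io import SnpRecord

__all__ = [
    "AnchorRow",
    "MarkerCall",
    "CountsSummary",
    "FixtureCorruptionError",
    "FAMILIAL_AD_GENES",
    "load_fixture",
    "classify_row",
    "summarize",
    "anchor_pairs",
    "z_anchor_pairs",
    "significant_kd_pairs",
    "fixture_path",
]

FAMILIAL_AD_GENES = frozenset({"MAPT", "APP", "APOE", "PSEN1", "PSEN2"})

_COLUMNS = [
    "table_id",
    "gene",
    "omim",
    "snp_id",
    "flank5",
    "wt",
    "minors",
    "flank3",
    "kd_wt_nM",
    "kd_mut_nM",
    "direction",
    "z_printed",
    "alpha_printed",
    "rank_printed",
    "is_proposed_candidate",
    "is_known_marker",
    "tbp_site_effect",
    "gene_group",
    "annotation",
]

_MISSING = "."


class FixtureCorruptionError(RuntimeError):
    """The fixture content hash does not match its header."""


@dataclass(frozen=True)
class AnchorRow:
    """One transcribed catalog row."""

    table_id: int
    gene: str
    omim: str
    snp_id: str
    flank5: str
    wt: str
    minors: tuple[str, ...]
    flank3: str
    kd_wt_nM: float | None
    kd_mut_nM: float | None
    direction: str  # up | down | equal | absent
    z_printed: float | None
    alpha_printed: float | None
    rank_printed: str | None
    is_proposed_candidate: bool
    is_known_marker: bool
    tbp_site_effect: str  # significant | insignificant | not_printed
    gene_group: str  # familial_AD | other
    annotation: str

    def wt_context(self) -> str:
        return self.flank5 + self.wt + self.flank3

    def minor_context(self, index: int = 0) -> str:
        return self.flank5 + self.minors[index] + self.flank3

    @property
    def sequences_resolved(self) -> bool:
        """False when an allele was not printed in the source (N bases)."""
        return "N" not in self.wt and all("N" not in m for m in self.minors)

    def to_snp_record(self) -> SnpRecord:
        if not self.sequences_resolved:
            raise ValueError(
                f"{self.snp_id}: allele sequence not fully specified in the catalog"
            )
        return SnpRecord(
            id=self.snp_id,
            flank5=self.flank5,
            wt=self.wt,
            minors=list(self.minors),
            flank3=self.flank3,
            gene=self.gene,
        )


@dataclass(frozen=True)
class MarkerCall:
    snp_id: str
    candidate: bool
    expression_call: str
    risk_note: str


@dataclass(frozen=True)
class CountsSummary:
    n_candidates_total: int
    n_significant_other: int
    n_decrease_other: int
    n_candidates_familial: int
    n_decrease_familial: int

    def __post_init__(self) -> None:
        if self.n_decrease_other > self.n_significant_other:
            raise ValueError("n_decrease_other exceeds n_significant_other")
        if self.n_decrease_familial > self.n_candidates_familial:
            raise ValueError("n_decrease_familial exceeds n_candidates_familial")


def fixture_path() -> Path:
    return Path(str(resources.files("promaff") / "data" / "markers.tsv"))


def _opt_float(cell: str) -> float | None:
    return None if cell == _MISSING else float(cell)


def _parse_row(cells: dict[str, str]) -> AnchorRow:
    minors = tuple(
        "" if m in {"-", ""} else m.upper() for m in cells["minors"].split(",")
    )
    wt = "" if cells["wt"] == "-" else cells["wt"].upper()
    row = AnchorRow(
        table_id=int(cells["table_id"]),
        gene=cells["gene"],
        omim=cells["omim"],
        snp_id=cells["snp_id"],
        flank5=cells["flank5"].upper(),
        wt=wt,
        minors=minors,
        flank3=cells["flank3"].upper(),
        kd_wt_nM=_opt_float(cells["kd_wt_nM"]),
        kd_mut_nM=_opt_float(cells["kd_mut_nM"]),
        direction=cells["direction"],
        z_printed=_opt_float(cells["z_printed"]),
        alpha_printed=_opt_float(cells["alpha_printed"]),
        rank_printed=None if cells["rank_printed"] == _MISSING else cells["rank_printed"],
        is_proposed_candidate=cells["is_proposed_candidate"] == "1",
        is_known_marker=cells["is_known_marker"] == "1",
        tbp_site_effect=cells["tbp_site_effect"],
        gene_group=cells["gene_group"],
        annotation="" if cells["annotation"] == _MISSING else cells["annotation"],
    )
    _validate_row(row)
    return row


def _validate_row(row: AnchorRow) -> None:
    in_familial = row.gene in FAMILIAL_AD_GENES
    if (row.gene_group == "familial_AD") != in_familial:
        raise ValueError(f"{row.snp_id}: gene_group inconsistent with gene {row.gene}")
    if row.kd_wt_nM is not None and row.kd_mut_nM is not None:
        if row.direction == "down" and not row.kd_mut_nM > row.kd_wt_nM:
            raise ValueError(f"{row.snp_id}: direction=down but kd_mut <= kd_wt")
        if row.direction == "up" and not row.kd_mut_nM < row.kd_wt_nM:
            raise ValueError(f"{row.snp_id}: direction=up but kd_mut >= kd_wt")
    if row.tbp_site_effect not in {"significant", "insignificant", "not_printed"}:
        raise ValueError(f"{row.snp_id}: bad tbp_site_effect {row.tbp_site_effect!r}")
    if row.direction not in {"up", "down", "equal", "absent"}:
        raise ValueError(f"{row.snp_id}: bad direction {row.direction!r}")


def content_hash(data_lines: list[str]) -> str:
    h = hashlib.sha256()
    for line in data_lines:
        h.update(line.encode())
        h.update(b"\n")
    return h.hexdigest()


def load_fixture(path: str | Path | None = None) -> list[AnchorRow]:
    """Load and checksum-verify the packaged catalog."""
    path = Path(path) if path is not None else fixture_path()
    stated_hash = None
    data_lines: list[str] = []
    for raw in path.read_text().splitlines():
        if raw.startswith("# sha256 = "):
            stated_hash = raw.removeprefix("# sha256 = ").strip()
            continue
        if raw.startswith("#") or not raw.strip():
            continue
        data_lines.append(raw)
    if stated_hash is None or content_hash(data_lines) != stated_hash:
        raise FixtureCorruptionError(f"fixture checksum mismatch in {path}")
    header = data_lines[0].split("\t")
    if header != _COLUMNS:
        raise FixtureCorruptionError(f"unexpected fixture columns in {path}")
    rows = []
    for line in data_lines[1:]:
        cells = dict(zip(header, line.split("\t")))
        rows.append(_parse_row(cells))
    return rows


def classify_row(row: AnchorRow, result=None) -> MarkerCall:
    """Candidate/known classification with an expression-direction call.

    A row is a candidate when its TBP-site effect is significant, or via the
    annotation-based override for the proposed rows whose TBP effect is
    insignificant or unprinted.  The direction comes from the catalog unless
    a computed :class:`~promaff.significance.ComparisonResult` is supplied.
    """
    candidate = row.tbp_site_effect == "significant" or row.is_proposed_candidate
    if result is not None:
        call = result.decision
    elif row.direction == "down":
        call = "underexpression"
    elif row.direction == "up":
        call = "overexpression"
    else:
        call = "insignificant"
    return MarkerCall(
        snp_id=row.snp_id,
        candidate=candidate,
        expression_call=call,
        risk_note=row.annotation,
    )


def summarize(rows: list[AnchorRow]) -> CountsSummary:
    """Count candidates and expression-decreasing candidates per gene group."""
    candidates = [r for r in rows if r.is_proposed_candidate]
    other_sig = [
        r
        for r in candidates
        if r.gene_group == "other" and r.tbp_site_effect == "significant"
    ]
    familial = [r for r in candidates if r.gene_group == "familial_AD"]
    return CountsSummary(
        n_candidates_total=len(candidates),
        n_significant_other=len(other_sig),
        n_decrease_other=sum(r.direction == "down" for r in other_sig),
        n_candidates_familial=len(familial),
        n_decrease_familial=sum(r.direction == "down" for r in familial),
    )


# ---------------------------------------------------------------------------
# calibration inputs derived from the catalog


def anchor_pairs(rows: list[AnchorRow]) -> list[tuple[str, float]]:
    """Unique (sequence, K_D/nM) anchors from all rows with printed constants."""
    seen: dict[str, float] = {}
    for row in rows:
        if row.kd_wt_nM is not None and "N" not in row.wt:
            seen.setdefault(row.wt_context(), row.kd_wt_nM)
        if row.kd_mut_nM is not None and "N" not in row.minors[0]:
            seen.setdefault(row.minor_context(0), row.kd_mut_nM)
    return sorted(seen.items())


def z_anchor_pairs(rows: list[AnchorRow]) -> list[tuple[float, float]]:
    """(|delta ln K_D|, printed Z) pairs for the sigma0 calibration."""
    out = []
    for row in rows:
        if (
            row.kd_wt_nM is not None
            and row.kd_mut_nM is not None
            and row.z_printed is not None
            and row.z_printed > 0
        ):
            out.append(
                (abs(math.log(row.kd_mut_nM / row.kd_wt_nM)), row.z_printed)
            )
    return out


def significant_kd_pairs(rows: list[AnchorRow]) -> list[AnchorRow]:
    """Rows with a significant TBP-site effect, both K_D values printed and
    fully resolved allele sequences (excludes the N-encoded deletion row)."""
    return [
        r
        for r in rows
        if r.tbp_site_effect == "significant"
        and r.kd_wt_nM is not None
        and r.kd_mut_nM is not None
        and r.sequences_resolved
    ]
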