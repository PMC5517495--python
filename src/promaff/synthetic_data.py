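"""Synthetic promoters and SNP sets with known ground truth.

Each synthetic promoter is a 51-nt core region of i.i.d. background at a
requested GC content with one planted consensus TATA element, and carries
one SNP of a controlled truth class: ``decrease_affinity`` (a transversion
hitting a fixed consensus position of the core), ``increase_affinity`` (an
edit restoring a deliberately damaged core position to consensus) or
``neutral`` (an edit outside the planted element).  Everything is driven by
one seeded generator, so the same seed reproduces the same data set.

A dinucleotide-preserving shuffle is included as an alternative null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .promoter_io import PromoterRecord, SnpRecord
from .significance import ComparisonResult, INSIGNIFICANT, OVER, UNDER

__all__ = [
    "SyntheticTruth",
    "RecoveryReport",
    "REGION_LENGTH",
    "CONSENSUS_CORE",
    "generate_promoter_set",
    "recovery_report",
    "dinucleotide_shuffle",
]

#: length of the [-70; -20] core-promoter region
REGION_LENGTH = 51

#: planted consensus element (the fixed frame of the PWM consensus)
CONSENSUS_CORE = "TATAAAAG"
ELEMENT_WIDTH = 15

#: 8-mer core starts 3 nt into the 15-bp element frame
_CORE_IN_FRAME = 3

#: default core start: index 35 of the region, i.e. position -35
_DEFAULT_CORE_START = 35

#: consensus positions with a fixed base (W/R degeneracies excluded)
_FIXED_CORE_POSITIONS = (0, 1, 2, 3, 5)

_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}

_CLASSES = ("decrease_affinity", "increase_affinity", "neutral")


@dataclass(frozen=True)
class SyntheticTruth:
    snp_id: str
    planted_effect: str
    planted_offset: int  # start of the 15-bp element frame within the region
    magnitude_class: str  # core | flank


@dataclass
class RecoveryReport:
    rates: dict
    confusion: dict
    n_per_class: dict

    @property
    def empty(self) -> bool:
        return not self.n_per_class


def _background(rng: np.random.Generator, gc: float, length: int) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), p=p, size=length))


def generate_promoter_set(
    n: int,
    seed: int,
    gc: float = 0.5,
    tata_offset_jitter: int = 2,
) -> tuple[list[PromoterRecord], list[SnpRecord], list[SyntheticTruth]]:
    """Generate ``n`` promoters, one SNP each, with truth labels.

    Truth classes cycle deterministically (decrease, increase, neutral) so
    class sizes are balanced.  Raises for jitter values that could push the
    planted element outside the region; warns for near-degenerate GC content.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < gc < 1:
        raise ValueError("gc must lie strictly between 0 and 1")
    lo = _DEFAULT_CORE_START - tata_offset_jitter - _CORE_IN_FRAME
    hi = _DEFAULT_CORE_START + tata_offset_jitter + len(CONSENSUS_CORE)
    if tata_offset_jitter < 0 or lo < 0 or hi > REGION_LENGTH:
        raise ValueError(
            f"tata_offset_jitter={tata_offset_jitter} pushes the planted "
            f"element outside the {REGION_LENGTH}-nt region"
        )
    if gc >= 0.9 or gc <= 0.1:
        warnings.warn(
            f"near-degenerate background gc={gc}: the planted element "
            "dominates trivially",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    promoters: list[PromoterRecord] = []
    snps: list[SnpRecord] = []
    truths: list[SyntheticTruth] = []
    for i in range(n):
        effect = _CLASSES[i % len(_CLASSES)]
        for _attempt in range(100):
            core_start = _DEFAULT_CORE_START + int(
                rng.integers(-tata_offset_jitter, tata_offset_jitter + 1)
            )
            seq = _background(rng, gc, REGION_LENGTH)
            seq = (
                seq[:core_start]
                + CONSENSUS_CORE
                + seq[core_start + len(CONSENSUS_CORE) :]
            )
            frame_start = core_start - _CORE_IN_FRAME
            if effect == "decrease_affinity":
                pos = core_start + int(rng.choice(_FIXED_CORE_POSITIONS))
                wt = seq[pos]
                minor = _TRANSVERSION[wt]
            elif effect == "increase_affinity":
                # damage one fixed core position in the promoter itself;
                # the SNP's minor allele restores the consensus base
                off = int(rng.choice(_FIXED_CORE_POSITIONS))
                pos = core_start + off
                minor = CONSENSUS_CORE[off]
                wt = _TRANSVERSION[minor]
                seq = seq[:pos] + wt + seq[pos + 1 :]
            else:  # neutral: an edit outside the element frame with full flanks
                eligible = [
                    p
                    for p in range(10, REGION_LENGTH - 10)
                    if not frame_start <= p < frame_start + ELEMENT_WIDTH
                ]
                pos = int(rng.choice(eligible))
                wt = seq[pos]
                minor = str(rng.choice([b for b in "ACGT" if b != wt]))
            flank5 = seq[pos - 10 : pos]
            flank3 = seq[pos + 1 : pos + 11]
            locus = flank5 + wt + flank3
            if seq.count(locus) == 1:
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError("could not construct an unambiguous SNP locus")
        pid = f"synt{i:04d}"
        promoters.append(PromoterRecord(id=pid, gene=pid, sequence=seq))
        snps.append(
            SnpRecord(
                id=f"snp{i:04d}",
                flank5=flank5,
                wt=wt,
                minors=[minor],
                flank3=flank3,
                gene=pid,
            )
        )
        truths.append(
            SyntheticTruth(
                snp_id=f"snp{i:04d}",
                planted_effect=effect,
                planted_offset=frame_start,
                magnitude_class="core" if effect != "neutral" else "flank",
            )
        )
    return promoters, snps, truths


def recovery_report(
    calls: Mapping[str, ComparisonResult] | Iterable[tuple[str, ComparisonResult]],
    truth: Sequence[SyntheticTruth],
) -> RecoveryReport:
    """Per-class recovery rates of pipeline calls against planted truth.

    ``decrease_affinity`` counts as recovered when called underexpression at
    a rank better than E; ``increase_affinity`` symmetrically; ``neutral``
    when called insignificant.
    """
    calls = dict(calls)
    truth_ids = {t.snp_id for t in truth}
    unmatched = sorted(truth_ids ^ set(calls))
    if unmatched:
        raise ValueError(f"unmatched snp ids between calls and truth: {unmatched}")
    if not truth:
        return RecoveryReport(rates={}, confusion={}, n_per_class={})
    expected = {
        "decrease_affinity": UNDER,
        "increase_affinity": OVER,
        "neutral": INSIGNIFICANT,
    }
    confusion: dict[str, dict[str, int]] = {}
    hits: dict[str, int] = {}
    totals: dict[str, int] = {}
    for t in truth:
        res = calls[t.snp_id]
        totals[t.planted_effect] = totals.get(t.planted_effect, 0) + 1
        confusion.setdefault(t.planted_effect, {}).setdefault(res.decision, 0)
        confusion[t.planted_effect][res.decision] += 1
        if res.decision == expected[t.planted_effect]:
            hits[t.planted_effect] = hits.get(t.planted_effect, 0) + 1
    rates = {c: hits.get(c, 0) / totals[c] for c in totals}
    return RecoveryReport(rates=rates, confusion=confusion, n_per_class=totals)


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its dinucleotide composition.

    Euler-path shuffle: random edge orderings are drawn until one yields a
    valid walk, which is exact for the short sequences used here.
    """
    seq = sequence.upper()
    if len(seq) <= 2:
        return seq
    for _ in range(1000):
        edges: dict[str, list[str]] = {}
        for a, b in zip(seq, seq[1:]):
            edges.setdefault(a, []).append(b)
        for succ in edges.values():
            rng.shuffle(succ)
        out = [seq[0]]
        node = seq[0]
        try:
            for _i in range(len(seq) - 1):
                nxt = edges[node].pop(0)
                out.append(nxt)
                node = nxt
        except (KeyError, IndexError):
            continue
        if not any(edges[k] for k in edges):
            return "".join(out)
    raise RuntimeError("dinucleotide shuffle failed to converge")
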