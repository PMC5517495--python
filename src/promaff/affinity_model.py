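"""Three-component TBP binding-affinity model.

Predicts -ln K_D (K_D in nM) of a promoter sequence as a linear combination
of three sequence features mirroring the three steps of TBP-promoter
recognition: a sliding term (mean per-dinucleotide duplex-destabilisation
contribution over the sequence), a site term (maximum log-odds of a 15-bp
TATA position-weight matrix), and a bending term (mean per-dinucleotide
bending-propensity contribution).

Default coefficients are obtained by ordinary least squares against the
packaged K_D anchor set and frozen into a versioned plain-text config; the
per-comparison noise scale sigma0 is set so the derived Z statistic matches
the anchor Z values in median ratio 1.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BASES",
    "ComponentScores",
    "ModelCoefficients",
    "ModelTables",
    "AffinityEstimate",
    "CalibrationError",
    "default_tables",
    "component_scores",
    "estimate_affinity",
    "calibrate",
    "write_tables_config",
    "load_tables_config",
    "write_coefficients_config",
    "load_coefficients_config",
    "load_frozen_coefficients",
]

BASES = "ACGT"
PWM_WIDTH = 15

#: TATA consensus and its placement inside the 15-bp PWM frame.
_CONSENSUS = "TATAWAWR"
_CONSENSUS_OFFSET = 3
_IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "W": "AT", "R": "AG"}
_PSEUDOCOUNT = 0.25
_BACKGROUND = 0.25

# Nearest-neighbour duplex stacking free energies (kcal/mol, 37 C, unified
# scale).  Less negative = weaker duplex = easier strand opening while TBP
# slides; AT-rich steps score highest.
_SLIDE = {
    "AA": -1.00, "AC": -1.44, "AG": -1.28, "AT": -0.88,
    "CA": -1.45, "CC": -1.84, "CG": -2.17, "CT": -1.28,
    "GA": -1.30, "GC": -2.24, "GG": -1.84, "GT": -1.44,
    "TA": -0.58, "TC": -1.30, "TG": -1.45, "TT": -1.00,
}

# Dimer-step deformability proxy (degrees of propeller twist magnitude from
# crystallographic compilations); high values mark steps that tolerate the
# strong bend of the TBP-DNA complex.
_BEND = {
    "AA": 18.66, "AC": 13.10, "AG": 14.00, "AT": 15.01,
    "CA":  9.93, "CC":  8.11, "CG": 10.03, "CT": 14.00,
    "GA": 13.48, "GC": 11.08, "GG":  8.11, "GT": 13.10,
    "TA": 11.85, "TC": 13.48, "TG":  9.93, "TT": 18.66,
}

#: Sub-window length used when minimising K_D over a longer region; matches
#: the width of the synthetic duplexes the anchor constants refer to.
DUPLEX_WIDTH = 26


class CalibrationError(ValueError):
    """The calibration design matrix is rank deficient."""


def _consensus_pwm() -> np.ndarray:
    """15-column log-odds matrix for the TATA consensus frame."""
    counts = np.full((4, PWM_WIDTH), 0.25)
    for j, code in enumerate(_CONSENSUS):
        col = np.zeros(4)
        allowed = _IUPAC[code]
        for b in allowed:
            col[BASES.index(b)] = 1.0 / len(allowed)
        counts[:, _CONSENSUS_OFFSET + j] = col
    probs = (counts + _PSEUDOCOUNT) / (counts + _PSEUDOCOUNT).sum(axis=0)
    return np.log(probs / _BACKGROUND)


@dataclass(frozen=True)
class ModelTables:
    """PWM and dinucleotide tables the component scores are computed from."""

    pwm: np.ndarray
    slide: dict
    bend: dict

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.pwm, dtype=np.float64).tobytes())
        for table in (self.slide, self.bend):
            for k in sorted(table):
                h.update(f"{k}={table[k]:.17g};".encode())
        return h.hexdigest()[:16]


def default_tables() -> ModelTables:
    return ModelTables(pwm=_consensus_pwm(), slide=dict(_SLIDE), bend=dict(_BEND))


@dataclass(frozen=True)
class ComponentScores:
    pwm_max: float
    slide_mean: float
    bend_mean: float
    best_window_offset: int


@dataclass(frozen=True)
class ModelCoefficients:
    """Linear predictor for -ln K_D plus its calibrated noise scales."""

    a0: float
    a_pwm: float
    a_slide: float
    a_bend: float
    resid_sd: float
    sigma0: float
    provenance: str = "calibrated"

    def __post_init__(self) -> None:
        if not self.resid_sd > 0:
            raise ValueError("resid_sd must be positive")
        if not self.sigma0 > 0:
            raise ValueError("sigma0 must be positive")


@dataclass(frozen=True)
class AffinityEstimate:
    ln_kd: float
    sd: float

    @property
    def kd_nM(self) -> float:
        return math.exp(self.ln_kd)

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("sd must be positive")


def component_scores(sequence: str, tables: ModelTables | None = None) -> ComponentScores:
    """Score one sequence: best PWM window plus dinucleotide means."""
    tables = tables or default_tables()
    seq = sequence.upper()
    if len(seq) < PWM_WIDTH:
        raise ValueError(
            f"too short for site scan: {len(seq)} nt < PWM width {PWM_WIDTH}"
        )
    idx = np.fromiter((BASES.index(b) for b in seq), dtype=np.intp, count=len(seq))
    col_scores = tables.pwm[idx, :]  # (L, 15): score of base i in column j
    n_win = len(seq) - PWM_WIDTH + 1
    window_scores = np.empty(n_win)
    for off in range(n_win):
        window_scores[off] = col_scores[off : off + PWM_WIDTH, :].diagonal().sum()
    best = int(np.argmax(window_scores))  # argmax returns the leftmost maximum
    steps = [seq[i : i + 2] for i in range(len(seq) - 1)]
    slide_mean = float(np.mean([tables.slide[s] for s in steps]))
    bend_mean = float(np.mean([tables.bend[s] for s in steps]))
    return ComponentScores(
        pwm_max=float(window_scores[best]),
        slide_mean=slide_mean,
        bend_mean=bend_mean,
        best_window_offset=best,
    )


def _neg_ln_kd(scores: ComponentScores, coeffs: ModelCoefficients) -> float:
    return (
        coeffs.a0
        + coeffs.a_pwm * scores.pwm_max
        + coeffs.a_slide * scores.slide_mean
        + coeffs.a_bend * scores.bend_mean
    )


def estimate_affinity(
    sequence: str,
    coeffs: ModelCoefficients,
    tables: ModelTables | None = None,
) -> AffinityEstimate:
    """Estimate ln K_D (nM) of a sequence.

    Sequences longer than the 26-bp duplex width are scanned and the
    sub-window minimising K_D (5'-most on ties) is reported, so a promoter
    region scores its best TBP site.
    """
    tables = tables or default_tables()
    seq = sequence.upper()
    if len(seq) <= DUPLEX_WIDTH:
        scores = component_scores(seq, tables)
        best = _neg_ln_kd(scores, coeffs)
    else:
        best = -math.inf
        for off in range(len(seq) - DUPLEX_WIDTH + 1):
            scores = component_scores(seq[off : off + DUPLEX_WIDTH], tables)
            val = _neg_ln_kd(scores, coeffs)
            if val > best:  # strict: leftmost window wins ties
                best = val
    return AffinityEstimate(ln_kd=-best, sd=coeffs.sigma0 / math.sqrt(2.0))


def calibrate(
    anchors: Sequence[tuple[str, float]],
    z_anchors: Sequence[tuple[float, float]],
    tables: ModelTables | None = None,
) -> ModelCoefficients:
    """Fit the linear predictor on (sequence, K_D/nM) anchors.

    ``z_anchors`` are (|delta ln K_D|, reference Z) pairs; sigma0 is their
    median ratio so that Z = |delta ln K_D| / sigma0 matches the references
    in median ratio 1 (each allele then carries sd = sigma0 / sqrt(2)).
    """
    tables = tables or default_tables()
    if len(anchors) < 10:
        raise CalibrationError("need at least 10 anchors")
    kds = np.array([kd for _, kd in anchors], dtype=float)
    if kds.max() / kds.min() < 10.0:
        raise CalibrationError("anchors must span at least a 10-fold K_D range")
    X = np.empty((len(anchors), 4))
    y = np.empty(len(anchors))
    for i, (seq, kd) in enumerate(anchors):
        s = component_scores(seq, tables)
        X[i] = (1.0, s.pwm_max, s.slide_mean, s.bend_mean)
        y[i] = -math.log(kd)
    rank = np.linalg.matrix_rank(X)
    if rank < 4:
        # name the collinear components for the error message
        names = ["intercept", "pwm_max", "slide_mean", "bend_mean"]
        degenerate = [n for j, n in enumerate(names) if np.ptp(X[:, j]) == 0 and j > 0]
        raise CalibrationError(
            f"rank-deficient design (rank {rank} < 4); "
            f"constant components: {degenerate or 'correlated columns'}"
        )
    beta, residues, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    resid_sd = float(np.sqrt(resid @ resid / max(1, len(anchors) - 4)))
    ratios = [abs(d) / z for d, z in z_anchors if z > 0]
    if not ratios:
        raise CalibrationError("no usable z anchors (all Z are zero)")
    sigma0 = float(np.median(ratios))
    return ModelCoefficients(
        a0=float(beta[0]),
        a_pwm=float(beta[1]),
        a_slide=float(beta[2]),
        a_bend=float(beta[3]),
        resid_sd=resid_sd,
        sigma0=sigma0,
        provenance="calibrated",
    )


# ---------------------------------------------------------------------------
# plain-text config IO (key = value; matrix blocks as whitespace columns)


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_tables_config(tables: ModelTables, path: str | Path, header: str = "") -> None:
    lines = []
    if header:
        lines.extend("# " + ln for ln in header.splitlines())
    lines.append(f"format_version = 1")
    lines.append(f"pwm_width = {tables.pwm.shape[1]}")
    lines.append("pwm_logodds =")
    for bi, base in enumerate(BASES):
        lines.append(base + "  " + "  ".join(_fmt(v) for v in tables.pwm[bi]))
    lines.append("slide =")
    for k in sorted(tables.slide):
        lines.append(f"{k}  {_fmt(tables.slide[k])}")
    lines.append("bend =")
    for k in sorted(tables.bend):
        lines.append(f"{k}  {_fmt(tables.bend[k])}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_tables_config(path: str | Path) -> ModelTables:
    pwm_rows: dict[str, list[float]] = {}
    slide: dict[str, float] = {}
    bend: dict[str, float] = {}
    section = None
    width = PWM_WIDTH
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" in line and line.split("=")[0].strip() in {
            "format_version",
            "pwm_width",
            "pwm_logodds",
            "slide",
            "bend",
        }:
            key = line.split("=")[0].strip()
            val = line.split("=", 1)[1].strip()
            if key == "pwm_width" and val:
                width = int(val)
            section = key if key in {"pwm_logodds", "slide", "bend"} else None
            continue
        parts = line.split()
        if section == "pwm_logodds" and parts[0] in BASES:
            pwm_rows[parts[0]] = [float(v) for v in parts[1:]]
        elif section == "slide":
            slide[parts[0]] = float(parts[1])
        elif section == "bend":
            bend[parts[0]] = float(parts[1])
    pwm = np.array([pwm_rows[b] for b in BASES])
    if pwm.shape != (4, width):
        raise ValueError(f"malformed PWM block in {path}")
    return ModelTables(pwm=pwm, slide=slide, bend=bend)


def write_coefficients_config(
    coeffs: ModelCoefficients, path: str | Path, header: str = ""
) -> None:
    lines = []
    if header:
        lines.extend("# " + ln for ln in header.splitlines())
    for key in ("a0", "a_pwm", "a_slide", "a_bend", "resid_sd", "sigma0"):
        lines.append(f"{key} = {_fmt(getattr(coeffs, key))}")
    lines.append(f"provenance = {coeffs.provenance}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_coefficients_config(path: str | Path) -> ModelCoefficients:
    vals: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        key, val = (s.strip() for s in line.split("=", 1))
        vals[key] = val
    return ModelCoefficients(
        a0=float(vals["a0"]),
        a_pwm=float(vals["a_pwm"]),
        a_slide=float(vals["a_slide"]),
        a_bend=float(vals["a_bend"]),
        resid_sd=float(vals["resid_sd"]),
        sigma0=float(vals["sigma0"]),
        provenance=vals.get("provenance", "calibrated"),
    )


def _data_path(name: str) -> Path:
    return Path(str(resources.files("promaff") / "data" / name))


def load_frozen_coefficients() -> ModelCoefficients:
    """The packaged coefficients frozen at calibration time."""
    return load_coefficients_config(_data_path("model_coeffs.cfg"))


def load_packaged_tables() -> ModelTables:
    return load_tables_config(_data_path("model_tables.cfg"))
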