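"""Regenerate the packaged model configs and regression-pinned metrics.

Writes src/promaff/data/model_tables.cfg, model_coeffs.cfg and
frozen_metrics.json.  Run from the repository root after any deliberate
change to the model tables or the anchor catalog; the test suite enforces
that the packaged files match what this script produces.
"""

from __future__ import annotations

import json
import math
import sys
from pathlib import Path

import numpy as np
from scipy.stats import spearmanr

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from promaff import affinity_model as am  # noqa: E402
from promaff import marker_catalog as mc  # noqa: E402
from promaff import synthetic_data as sd  # noqa: E402
from promaff.promoter_io import apply_allele  # noqa: E402
from promaff.significance import compare_alleles  # noqa: E402

DATA = ROOT / "src" / "promaff" / "data"
SYNTH_SEED = 20170720
SYNTH_N = 200


def main() -> None:
    tables = am.default_tables()
    am.write_tables_config(
        tables,
        DATA / "model_tables.cfg",
        header=(
            "Default model tables.\n"
            "pwm_logodds: 15-column natural-log odds vs a uniform background,\n"
            "  TATA consensus TATAWAWR at columns 4-11, pseudocount 0.25.\n"
            "slide: nearest-neighbour duplex stacking free energies\n"
            "  (kcal/mol, 37C, unified scale); less negative = easier opening.\n"
            "bend: dimer-step propeller-twist magnitudes (degrees) as a\n"
            "  deformability proxy.\n"
            "Calibration absorbs affine rescaling of either dinucleotide scale."
        ),
    )

    rows = mc.load_fixture()
    anchors = mc.anchor_pairs(rows)
    z_anchors = mc.z_anchor_pairs(rows)
    coeffs = am.calibrate(anchors, z_anchors, tables)
    am.write_coefficients_config(
        coeffs,
        DATA / "model_coeffs.cfg",
        header=(
            "Frozen coefficients for -ln K_D (K_D in nM), ordinary least\n"
            f"squares on the {len(anchors)} packaged sequence anchors;\n"
            f"sigma0 from the median |delta ln K_D|/Z of {len(z_anchors)} anchor pairs.\n"
            f"tables hash {tables.content_hash()}"
        ),
    )

    pred = np.array([-am.estimate_affinity(s, coeffs, tables).ln_kd for s, _ in anchors])
    obs = np.array([-math.log(k) for _, k in anchors])
    spearman = float(spearmanr(pred, obs).statistic)

    sig = mc.significant_kd_pairs(rows)
    discordant = []
    for r in sig:
        res = compare_alleles(r.wt_context(), r.minor_context(0), coeffs, tables)
        pred_dir = "down" if res.delta_ln_kd > 0 else "up"
        if pred_dir != r.direction:
            discordant.append(r.snp_id)

    ok = tot = 0
    for r in rows:
        if r.kd_wt_nM and r.kd_mut_nM and r.z_printed and r.z_printed > 0:
            tot += 1
            z = abs(math.log(r.kd_mut_nM / r.kd_wt_nM)) / coeffs.sigma0
            if abs(z - r.z_printed) <= max(2.0, 0.35 * r.z_printed):
                ok += 1

    tpi = next(r for r in rows if r.snp_id == "rs1800202")
    tpi_kd = am.estimate_affinity(tpi.wt_context(), coeffs, tables).kd_nM

    promoters, snps, truths = sd.generate_promoter_set(SYNTH_N, SYNTH_SEED, gc=0.5, tata_offset_jitter=2)
    calls = {}
    offset_hits = 0
    by_id = {p.id: p for p in promoters}
    for snp, truth in zip(snps, truths):
        prom = by_id[snp.gene]
        mut = apply_allele(prom.sequence, snp, 0)
        calls[snp.id] = compare_alleles(prom.sequence, mut, coeffs, tables)
        scores = am.component_scores(prom.sequence, tables)
        if scores.best_window_offset == truth.planted_offset:
            offset_hits += 1
    report = sd.recovery_report(calls, truths)

    metrics = {
        "tables_hash": tables.content_hash(),
        "n_anchors": len(anchors),
        "anchor_spearman": round(spearman, 6),
        "n_significant_pairs": len(sig),
        "n_direction_concordant": len(sig) - len(discordant),
        "direction_discordant_snp_ids": sorted(discordant),
        "z_scale_ok": ok,
        "z_scale_total": tot,
        "z_scale_rate": round(ok / tot, 6),
        "tpi1_wt_pred_kd_nM": round(tpi_kd, 6),
        "synth_seed": SYNTH_SEED,
        "synth_n": SYNTH_N,
        "synth_recovery_rates": {k: round(v, 6) for k, v in sorted(report.rates.items())},
        "synth_offset_recovery_rate": round(offset_hits / SYNTH_N, 6),
    }
    (DATA / "frozen_metrics.json").write_text(json.dumps(metrics, indent=2) + "\n")
    print(json.dumps(metrics, indent=2))


if __name__ == "__main__":
    main()
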