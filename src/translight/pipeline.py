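"""End-to-end orchestration of the screening pipeline on synthetic inputs.

:func:`run_demo` generates every synthetic input, runs all stages, writes
fixed-schema TSV tables plus a JSON report, and computes truth-recovery
metrics against the generators' ground truth.  All randomness derives from
one global seed split into per-stage substreams, and every written file is
a pure function of the seed and parameters (re-runs are byte-identical);
wall-clock timing is only logged to the console for that reason.
"""

from __future__ import annotations

import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, assays, enrichment, io, screen, signature, synthetic

__all__ = ["run_demo", "DEMO_PARAMS"]

#: Demo stage parameters.  Thresholds default to the standard hit rules:
#: screen score > 4 with aggregated p < 0.01; CETSA |amplitude| > 0.2 with
#: BH-adjusted p < 0.05; TE classification at 2-fold with p < 0.05; the
#: "methods" dose-response responsiveness rule (EC50 < 6 uM, hill slope in
#: [-3.5, -1]).
DEMO_PARAMS: dict = {
    "signature": dict(n_transcripts=300, planted_prevalence=6, top_k=10),
    "screen": dict(n_null_wells=120, n_active_wells=8, score_threshold=4.0,
                   p_threshold=0.01, method="empirical"),
    "enrich": dict(n_genes=150, n_rbps=25, n_enriched=3, fold=3.0,
                   n_de_genes=15, background_density=4.0),
    "cetsa": dict(n_proteins=300, n_targets=6, amplitude=0.4,
                  amp_threshold=0.2, p_threshold=0.05),
    "te": dict(n_genes=400, n_affected=40, mrna_lfc=1.5, rpf_lfc=0.0,
               dispersion=0.05, n_reps=3, lfc_threshold=1.0, alpha=0.05),
    "panel": dict(n_lines=43, responsive_fraction=0.3, dependency_effect=0.4,
                  rule="methods"),
}


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def _log(msg: str) -> None:
    print(f"[translight] {msg}", file=sys.stderr)


def run_demo(seed: int, outdir: str | Path, params: dict | None = None) -> dict:
    """Generate synthetic inputs, run every stage, write tables and a report.

    Returns the report dictionary (also written to ``report.json``).
    """
    t0 = time.monotonic()
    params = params or DEMO_PARAMS
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": seed, "version": __version__, "parameters": params, "stages": {}}

    # --- codon-pair signature -------------------------------------------
    p = params["signature"]
    tx, tx_truth = synthetic.synth_transcriptome(
        n_transcripts=p["n_transcripts"], planted_prevalence=p["planted_prevalence"],
        seed=synthetic.substream_seed(seed, "transcriptome"),
    )
    io.write_fasta(tx, out / "cds.fasta")
    io.write_expression(tx, out / "expression.tsv")
    _write(tx_truth, out / "truth_transcriptome.tsv")
    target_id = tx_truth.loc[
        tx_truth["params"].str.contains("is_target=1"), "entity_id"
    ].iloc[0]
    ranked = signature.rank_signature_pairs(tx, target_id, top_k=p["top_k"])
    rank_df = pd.DataFrame(
        {
            "pair": [str(s.pair) for s in ranked],
            "prevalence": [s.prevalence for s in ranked],
            "target_occupancy": [s.target_occupancy for s in ranked],
            "background_occupancy": [s.background_occupancy for s in ranked],
            "snr": [s.snr if np.isfinite(s.snr) else "inf" for s in ranked],
        }
    )
    _write(rank_df, out / "signature_ranking.tsv")
    planted = signature.CodonPair("TCG", "CAA")
    idx = signature.build_pair_index(tx)
    report["stages"]["signature"] = {
        "target": target_id,
        "planted_pair_prevalence": idx.prevalence(planted),
        "planted_pair_snr": float(
            signature.signal_to_noise(idx, tx, target_id, planted).snr
        ),
        "top_pair": str(ranked[0].pair),
    }
    _log("signature stage done")

    # --- FRET screen ----------------------------------------------------
    p = params["screen"]
    donor, acceptor = synthetic.synth_control_cells(
        seed=synthetic.substream_seed(seed, "controls")
    )
    coeffs = screen.estimate_bleedthrough(donor, acceptor)
    cells, well_truth = synthetic.synth_fret_plate(
        n_null_wells=p["n_null_wells"], n_active_wells=p["n_active_wells"],
        seed=synthetic.substream_seed(seed, "plate"),
    )
    tf_thr, fret_thr = screen.auto_thresholds(cells, coeffs)
    profiles = screen.aggregate_plate(
        cells, coeffs, transfection_threshold=tf_thr, fret_positive_threshold=fret_thr
    )
    roles = cells.groupby("well_id")["role"].first()
    hits, _ref = screen.run_screen(
        profiles.loc[profiles["valid"], list(screen.FEATURE_NAMES)],
        roles, method=p["method"],
        score_threshold=p["score_threshold"], p_threshold=p["p_threshold"],
    )
    _write(hits, out / "screen_hits.tsv")
    truth_pos = set(well_truth.loc[well_truth["is_positive"], "entity_id"])
    called = set(hits.loc[hits["is_hit"], "well_id"])
    report["stages"]["screen"] = {
        "beta_donor": round(coeffs.beta_donor, 6),
        "alpha_acceptor": round(coeffs.alpha_acceptor, 6),
        "n_hits": int(hits["is_hit"].sum()),
        "hit_sensitivity": len(called & truth_pos) / max(len(truth_pos), 1),
        "false_hits": len(called - truth_pos),
    }
    _log("screen stage done")

    # --- RBP enrichment -------------------------------------------------
    p = params["enrich"]
    models = synthetic.synth_gene_models(
        p["n_genes"], seed=synthetic.substream_seed(seed, "genome")
    )
    io.write_gtf(models, out / "genes.gtf")
    rbps = [f"RBP{i:02d}" for i in range(p["n_rbps"])]
    rng = np.random.default_rng(synthetic.substream_seed(seed, "de_genes"))
    de_genes = sorted(rng.choice(sorted(models), p["n_de_genes"], replace=False).tolist())
    enriched = {r: p["fold"] for r in rbps[: p["n_enriched"]]}
    sites, rbp_truth = synthetic.synth_eclip(
        models, rbps, background_density=p["background_density"],
        de_genes=de_genes, enriched_rbps=enriched,
        seed=synthetic.substream_seed(seed, "eclip"),
    )
    io.write_bed(sites, out / "sites.bed")
    enr = enrichment.density_enrichment(sites, de_genes, models)
    _write(enr, out / "rbp_enrichment.tsv")
    sig = set(enr.loc[enr["p_adj"] < 0.05, "rbp"])
    report["stages"]["enrich"] = {
        "n_sites": len(sites),
        "planted_recovered": sorted(set(enriched) & sig),
        "planted_recovery": len(set(enriched) & sig) / max(len(enriched), 1),
        "false_positive_rbps": sorted(sig - set(enriched)),
        "mean_planted_fold": float(
            enr.loc[enr["rbp"].isin(enriched), "fold"].mean()
        ),
    }
    _log("enrich stage done")

    # --- CETSA ----------------------------------------------------------
    p = params["cetsa"]
    targets = {f"P{i:04d}": p["amplitude"] for i in range(p["n_targets"])}
    cetsa_table, cetsa_truth = synthetic.synth_cetsa(
        p["n_proteins"], target_amplitudes=targets,
        seed=synthetic.substream_seed(seed, "cetsa"),
    )
    _write(cetsa_table, out / "cetsa_soluble.tsv")
    fits = [assays.fit_itdr(c) for c in assays.curves_from_table(cetsa_table)]
    found, volcano = assays.cetsa_hits(fits, p["amp_threshold"], p["p_threshold"])
    _write(volcano, out / "cetsa_volcano.tsv")
    report["stages"]["cetsa"] = {
        "n_targets_called": len(found),
        "target_recovery": len({f.protein_id for f in found} & set(targets))
        / max(len(targets), 1),
        "false_targets": sorted({f.protein_id for f in found} - set(targets)),
    }
    _log("cetsa stage done")

    # --- translational efficiency ---------------------------------------
    p = params["te"]
    mrna, rpf, condition, te_truth = synthetic.synth_ribo(
        p["n_genes"], p["n_affected"], mrna_lfc=p["mrna_lfc"], rpf_lfc=p["rpf_lfc"],
        dispersion=p["dispersion"], n_reps=p["n_reps"],
        seed=synthetic.substream_seed(seed, "ribo"),
    )
    _write(mrna, out / "counts_mrna.tsv", index=True)
    _write(rpf, out / "counts_rpf.tsv", index=True)
    te = assays.classify_genes(
        assays.delta_te(mrna, rpf, condition),
        lfc_threshold=p["lfc_threshold"], alpha=p["alpha"],
    )
    _write(te, out / "te_results.tsv", index=True)
    affected = set(te_truth.loc[te_truth["is_positive"], "entity_id"])
    mrna_only = set(te.index[te["class"] == "mrna_only"])
    null_genes = set(te.index) - affected
    report["stages"]["te"] = {
        "sensitivity_mrna_only": len(mrna_only & affected) / max(len(affected), 1),
        "null_misclassification": sum(
            1 for g in null_genes if te.loc[g, "class"] != "none"
        ) / max(len(null_genes), 1),
        "mean_delta_te_affected": float(te.loc[sorted(affected), "delta_te"].mean()),
    }
    _log("te stage done")

    # --- dose-response panel --------------------------------------------
    p = params["panel"]
    via, dep, line_truth = synthetic.synth_dose_panel(
        n_lines=p["n_lines"], responsive_fraction=p["responsive_fraction"],
        dependency_effect=p["dependency_effect"],
        seed=synthetic.substream_seed(seed, "panel"),
    )
    _write(via, out / "viability.tsv")
    _write(dep, out / "dependency.tsv")
    fit_rows = []
    groups: dict[str, list[str]] = {"responsive": [], "non_responsive": []}
    for line, grp in via.groupby("cell_line", sort=True):
        fit = assays.fit_4pl(
            grp["concentration_uM"].to_numpy(), grp["viability"].to_numpy(), str(line)
        )
        responsive = assays.classify_responsiveness(fit, rule=p["rule"])
        groups["responsive" if responsive else "non_responsive"].append(str(line))
        fit_rows.append(
            dict(cell_line=line, ec50_uM=fit.ec50_um, pec50=fit.pec50, hill=fit.hill,
                 top=fit.top, bottom=fit.bottom, converged=fit.converged,
                 responsive=responsive, rule=fit.rule)
        )
    fits_df = pd.DataFrame(fit_rows)
    _write(fits_df, out / "panel_fits.tsv")
    dep_by_line = dep.set_index("cell_line")["score"]
    dep_groups = {
        g: dep_by_line.loc[lines].to_numpy() for g, lines in groups.items() if len(lines) >= 2
    }
    if len(dep_groups) == 2:
        t, df_w, p_w = assays.welch_t(
            dep_groups["responsive"], dep_groups["non_responsive"]
        )
        circles, decisions = assays.comparison_circles(dep_groups)
        _write(decisions, out / "dependency_comparison.tsv")
        welch = {"t": round(t, 6), "df": round(df_w, 4), "p": round(p_w, 6)}
    else:
        welch = None
    truth_resp = set(line_truth.loc[line_truth["is_positive"], "entity_id"])
    report["stages"]["panel"] = {
        "n_responsive_called": len(groups["responsive"]),
        "responsive_recovery": len(set(groups["responsive"]) & truth_resp)
        / max(len(truth_resp), 1),
        "welch_dependency": welch,
    }
    _log("panel stage done")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _log(f"demo complete in {time.monotonic() - t0:.1f}s -> {out}")
    return report
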