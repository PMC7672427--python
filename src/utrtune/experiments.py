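"""End-to-end experiment orchestration.

Three end-to-end experiment chains:

``reporter_panel``
    RFP/BFP reporter elements: simulate flow samples and CT tables,
    quantify protein and mRNA fold changes, fit FC against dG.
``igg_hc_tuning``
    Heavy-chain tuning: flow panel, batch productivity, SEC fractions
    and gel band ratios for the best element versus the control.
``sumf1_asa``
    Helper-factor dosing: segmented dose-response, enzyme activity,
    batch qP, western-blot normalization.

Each chain writes its stage CSVs plus a ``report.json`` holding every
headline quantity, and is deterministic for a fixed config seed.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd

from . import bioprocess, dosemodel, flow, qpcr, quality, synth

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

#: Default reporter-panel elements: planted translation dosage (truth)
#: and fold free energy used for the dose model.
REPORTER_ELEMENTS = {
    "RgE21": {"dosage": 0.02, "dg": -46.0},
    "RgE4": {"dosage": 0.05, "dg": -41.0},
    "RgE3": {"dosage": 0.35, "dg": -32.0},
    "RgE13": {"dosage": 0.50, "dg": -28.0},
    "RgE11": {"dosage": 0.65, "dg": -22.0},
    "RgE2": {"dosage": 0.85, "dg": -14.0},
    "RgE6": {"dosage": 1.10, "dg": -6.0},
}

HC_PANEL = {"RgE4": 0.05, "RgE3": 0.35, "RgE13": 0.50,
            "RgE11": 0.65, "RgE2": 0.85, "RgE6": 1.10}

SEC_FRACTIONS = {"RgE3": (2.7, 92.5, 4.8), "CMV": (25.0, 59.0, 16.0)}

DEFAULTS = {
    "reporter_panel": {"n_events": 30_000, "control": "CMV",
                       "elements": REPORTER_ELEMENTS},
    "igg_hc_tuning": {"n_events": 30_000, "control": "CMV",
                      "panel": HC_PANEL, "fs_2hc_fc": 12.4,
                      "sec_fractions": SEC_FRACTIONS},
    "sumf1_asa": {"breakpoint": 0.4, "activity_plateau": 4.5,
                  "asa_only_qp": 2.0},
}


def _quantify_flow_panel(dosages: dict, control: str, n_events: int, seed: int):
    """Simulate, gate, and quantify a named panel of flow samples."""
    gating = flow.GatingConfig()
    ref = synth.simulate_flow_sample(synth.FlowSimConfig(
        n_events=max(n_events // 2, 1000), transfected_fraction=0.0, seed=seed + 999))
    gated = {}
    all_dosages = dict(dosages)
    all_dosages.setdefault(control, 1.0)
    for i, (name, dosage) in enumerate(sorted(all_dosages.items())):
        table = synth.simulate_flow_sample(synth.FlowSimConfig(
            n_events=n_events, dosage=float(dosage), seed=seed + i))
        gated[name] = flow.gate_events(table, gating, untransfected_ref=ref)
    return flow.fc_panel(gated, control)


def run_experiment(config: dict, output_dir: str) -> dict:
    """Run one experiment chain and write stage CSVs plus report.json."""
    if "experiment" not in config:
        missing = sorted({"experiment", "seed"} - set(config))
        raise ValueError(f"config missing required fields: {missing}")
    name = config["experiment"]
    if name not in DEFAULTS:
        raise ValueError(f"unknown experiment {name!r}; "
                         f"choose from {sorted(DEFAULTS)}")
    seed = int(config.get("seed", 0))
    cfg = {**DEFAULTS[name], **{k: v for k, v in config.items()
                                if k not in ("experiment", "seed")}}
    os.makedirs(output_dir, exist_ok=True)
    runner = {"reporter_panel": _run_reporter_panel,
              "igg_hc_tuning": _run_igg_hc_tuning,
              "sumf1_asa": _run_sumf1_asa}[name]
    try:
        report = runner(cfg, seed, output_dir)
    except Exception as exc:
        raise RuntimeError(f"experiment {name!r} failed: {exc}") from exc
    report = {"schema_version": REPORT_SCHEMA_VERSION, "experiment": name,
              "seed": seed, **report}
    with open(os.path.join(output_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report


def _run_reporter_panel(cfg: dict, seed: int, outdir: str) -> dict:
    elements = cfg["elements"]
    control = cfg["control"]
    panel = _quantify_flow_panel({k: v["dosage"] for k, v in elements.items()},
                                 control, int(cfg["n_events"]), seed)
    panel.to_csv(os.path.join(outdir, "flow_panel.csv"), index=False)

    # mRNA: translation-level regulation, so RFP mRNA is planted flat
    rel_truth = {k: 1.0 for k in elements}
    cts_rfp = synth.simulate_qpcr(rel_truth, control_sample=control,
                                  target_gene="RFP", seed=seed + 1)
    cts_bfp = synth.simulate_qpcr({k: 1.0 for k in elements}, control_sample=control,
                                  target_gene="BFP", seed=seed + 2)
    pd.concat([cts_rfp, cts_bfp]).to_csv(os.path.join(outdir, "ct_table.csv"),
                                         index=False)
    rel_rfp = qpcr.delta_delta_ct(cts_rfp, "RFP", "GAPDH", control)
    rel_bfp = qpcr.delta_delta_ct(cts_bfp, "BFP", "GAPDH", control)
    mrna = qpcr.mrna_ratio_fc(rel_rfp, rel_bfp, control)
    mrna.to_csv(os.path.join(outdir, "mrna_fc.csv"), index=False)

    fc = panel.set_index("sample")["fc"]
    dg = np.array([elements[k]["dg"] for k in elements])
    fc_vec = np.array([fc[k] for k in elements])
    linear = dosemodel.fit_linear(dg, fc_vec)
    logistic = dosemodel.fit_logistic4(dg, fc_vec)
    mrna_fc = mrna.set_index("sample")["fc_mrna"]
    rna_protein = {k: qpcr.rna_protein_ratio(float(mrna_fc[k]), float(fc[k]))
                   for k in elements}
    return {
        "fold_changes": fc.to_dict(),
        "n_gated": panel.set_index("sample")["n_gated"].to_dict(),
        "mrna_fc": mrna_fc.to_dict(),
        "rna_protein_ratio": rna_protein,
        "fit_linear": {"params": linear.params, "r2": linear.r2},
        "fit_logistic4": {"params": logistic.params, "r2": logistic.r2},
    }


def _run_igg_hc_tuning(cfg: dict, seed: int, outdir: str) -> dict:
    control = cfg["control"]
    panel = _quantify_flow_panel(dict(cfg["panel"]), control,
                                 int(cfg["n_events"]), seed)
    panel.to_csv(os.path.join(outdir, "hc_flow_panel.csv"), index=False)

    # batch productivity for the best element vs control
    qp_by_sample = {}
    for i, (name, qp_true) in enumerate({"CMV": 1.0, "RgE3": 2.5}.items()):
        batch = synth.simulate_batch(synth.BatchSimConfig(
            qp_true=qp_true, seed=seed + 10 + i))
        batch.to_csv(os.path.join(outdir, f"batch_{name}.csv"), index=False)
        qp_by_sample[name] = bioprocess.specific_productivity(batch)

    sec_results = {}
    for j, (name, fracs) in enumerate(sorted(cfg["sec_fractions"].items())):
        chrom = synth.simulate_chromatogram(np.asarray(fracs) / 100.0,
                                            noise_sd=0.002, seed=seed + 20 + j)
        chrom.to_csv(os.path.join(outdir, f"sec_{name}.csv"), index=False)
        peaks = quality.classify_peaks(quality.integrate_chromatogram(chrom))
        sec_results[name] = {row["klass"]: row["fraction"]
                             for _, row in peaks.iterrows()}

    fs_fc = float(cfg["fs_2hc_fc"])
    lanes, windows = synth.simulate_gel_lanes(
        [{"fs": 100.0, "2HC": 100.0}, {"fs": 100.0 * fs_fc, "2HC": 100.0}],
        noise_sd=0.01, seed=seed + 30)
    ctrl = quality.lane_band_ratio(lanes[0], windows)
    reg = quality.lane_band_ratio(lanes[1], windows, control_ratio=ctrl["ratio"])
    return {
        "fold_changes": panel.set_index("sample")["fc"].to_dict(),
        "qp_pg_per_cell_day": qp_by_sample,
        "sec_fractions_pct": sec_results,
        "fs_2hc_ratio_fc": reg["fc"],
    }


def _run_sumf1_asa(cfg: dict, seed: int, outdir: str) -> dict:
    dr_cfg = synth.DoseResponseSimConfig(
        breakpoint=float(cfg["breakpoint"]),
        activity_plateau=float(cfg["activity_plateau"]), seed=seed)
    dose = synth.simulate_sumf1_dose_response(dr_cfg)
    dose.to_csv(os.path.join(outdir, "sumf1_dose_response.csv"), index=False)
    est = dosemodel.segmented_response(dose["level"], dose["specific_activity"],
                                       split="estimate")
    fixed = dosemodel.segmented_response(dose["level"], dose["specific_activity"],
                                         split=float(cfg["breakpoint"]))
    qp_fit = dosemodel.fit_linear(dose["level"], dose["qp"])

    assay = synth.simulate_asa_assay(float(cfg["activity_plateau"]),
                                     protein_conc_mg_ml=0.5, seed=seed + 1)
    activity = bioprocess.asa_activity(assay)

    batch = synth.simulate_batch(synth.BatchSimConfig(
        qp_true=float(cfg["asa_only_qp"]), seed=seed + 2))
    batch.to_csv(os.path.join(outdir, "batch_asa_only.csv"), index=False)

    obs = quality.Sumf1Obs(lysate_band=1200.0, supernatant_band=800.0,
                           ladder55_band=1000.0, vcd_day4=4.0e6, ccd_0_4=8.0e6)
    control = quality.Sumf1Obs(lysate_band=3000.0, supernatant_band=2000.0,
                               ladder55_band=1000.0, vcd_day4=4.0e6, ccd_0_4=8.0e6)
    return {
        "breakpoint_estimate": est["breakpoint"],
        "activity_plateau_estimate": est["plateau"],
        "segmented_r2": {"low": fixed["low"].r2, "high": fixed["high"].r2},
        "qp_vs_level": {"params": qp_fit.params, "r2": qp_fit.r2},
        "specific_activity_u_per_mg": activity["u_per_mg"],
        "activity_u_per_ml": activity["u_per_ml"],
        "asa_only_qp": bioprocess.specific_productivity(batch),
        "sumf1_relative_level_example": quality.sumf1_relative_level(obs, control),
    }


def make_fixtures(seed: int, output_dir: str) -> dict:
    """Write one small dataset per experiment, sized to run in seconds."""
    os.makedirs(output_dir, exist_ok=True)
    written = {}
    flow_table = synth.simulate_flow_sample(synth.FlowSimConfig(
        n_events=5000, dosage=0.35, seed=seed))
    synth.write_with_truth(flow_table, os.path.join(output_dir, "flow_sample.csv"),
                           {"dosage": 0.35})
    ref = synth.simulate_flow_sample(synth.FlowSimConfig(
        n_events=5000, transfected_fraction=0.0, seed=seed + 1))
    synth.write_with_truth(ref, os.path.join(output_dir, "flow_untransfected.csv"),
                           {"dosage": None})
    written["flow"] = ["flow_sample.csv", "flow_untransfected.csv"]

    cts = synth.simulate_qpcr({"RgE3": 1.0}, seed=seed)
    cts.to_csv(os.path.join(output_dir, "ct_table.csv"), index=False)
    written["qpcr"] = ["ct_table.csv"]

    batch = synth.simulate_batch(synth.BatchSimConfig(seed=seed))
    synth.write_with_truth(batch, os.path.join(output_dir, "batch.csv"))
    written["batch"] = ["batch.csv"]

    chrom = synth.simulate_chromatogram((0.05, 0.90, 0.05), noise_sd=0.002,
                                        seed=seed)
    synth.write_with_truth(chrom, os.path.join(output_dir, "sec.csv"))
    written["sec"] = ["sec.csv"]

    lanes, windows = synth.simulate_gel_lanes(
        [{"fs": 100.0, "2HC": 50.0}], noise_sd=0.01, seed=seed)
    synth.write_with_truth(lanes[0], os.path.join(output_dir, "gel_lane.csv"))
    with open(os.path.join(output_dir, "gel_windows.json"), "w") as fh:
        json.dump(windows, fh, indent=1)
    written["gel"] = ["gel_lane.csv", "gel_windows.json"]

    dose = synth.simulate_sumf1_dose_response(synth.DoseResponseSimConfig(seed=seed))
    synth.write_with_truth(dose, os.path.join(output_dir, "dose_response.csv"))
    written["dose_response"] = ["dose_response.csv"]
    return written
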