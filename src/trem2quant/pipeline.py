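"""End-to-end orchestration: demo cohorts, per-modality runs, group stats.

A cohort lives in one directory: a ``manifest.yaml`` naming every animal
(genotype WT/Het/Hom, sex) and the files of each modality, the data files
themselves (all plain text or TIFF), and ground-truth JSONs when the
cohort is synthetic. ``run_modality`` loads one modality, computes the
per-sample metrics, runs the between-genotype comparison through the study
decision rule, and writes tidy CSVs plus a JSON summary echoing the
configuration and seeds, so a fixed (seed, config) pair reproduces every
output byte for byte.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
import pandas as pd
import yaml

from . import assayquant, clearance, ephys, groupstats, histoquant, synthdata, transcript

__all__ = ["DEFAULT_CONFIG", "make_demo_cohort", "run_modality", "load_manifest"]

GENOTYPES = ("WT", "Het", "Hom")

DEFAULT_CONFIG = {
    "ephys": {
        "n_baseline_min": 5,
        "n_post_min": 10,
        "sweeps_per_min": 3,
        "baseline_slope": -1.5,
        "potentiation": {"WT": 1.45, "Hom": 1.25},  # Hom: impaired LTP
        "slope_noise": 0.05,
    },
    "clearance": {
        "baseline_conc": 10.0,
        "Ke_per_h": {"WT": 0.35, "Hom": 0.70},  # Hom: faster clearance
        "noise_cv": 0.05,
        "n_animals": 6,
        "paper_constants": False,
    },
    "histo": {
        "roi_size_um": 300.0,
        "pixel_size_um": 0.8,
        "n_plaques": {"WT": 12, "Hom": 6},  # Hom: lower plaque burden
        "plaque_diameter_um": (10.0, 16.0),
        "n_microglia": 8,
        "n_animals": 4,
        "plaque_threshold": 0.5,
        "microglia_threshold": 0.3,
        "soma_threshold": 0.5,
        "min_plaque_diameter_um": 8.0,
        "neighborhood_radius_um": 30.0,
        "image_noise": 0.03,
    },
    "assay": {
        "n_samples": 6,
        "s_fmol": {"WT": 2.0, "Hom": 4.0},  # Hom: more soluble TREM2
        "fl_fmol": {"WT": 4.0, "Hom": 4.0},
        "noise_cv": 0.08,
        "reference_group": "WT",
    },
    "transcript": {
        "n_genes": 800,
        "n_per_group": 8,
        "n_de": 40,
        "de_log2fc": 1.5,
        "n_module": 60,
        "module_loading": 1.5,
        "fdr_cut": 0.05,
        "lfc_cut": 0.25,
        "min_count": 10,
        "min_samples": 4,
        "run_modules": True,
        "beta": 12,
        "min_module_size": 40,
        "merge_cut": 0.4,
        "n_permutations": 100,
    },
    "stats": {"alpha_var": 0.05},
}


def _merge_config(user: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for section, vals in (user or {}).items():
        cfg.setdefault(section, {}).update(vals or {})
    return cfg


def load_manifest(cohort_dir) -> dict:
    cohort_dir = pathlib.Path(cohort_dir)
    with open(cohort_dir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    for i, rec in enumerate(manifest["cohort"]):
        if rec.get("genotype") not in GENOTYPES:
            raise ValueError(
                f"manifest cohort row {i} ({rec.get('animal_id', '?')}): "
                f"unknown genotype {rec.get('genotype')!r}; allowed {GENOTYPES}"
            )
    manifest["_dir"] = cohort_dir
    return manifest


def make_demo_cohort(outdir, seed: int = 0, config: dict | None = None) -> dict:
    """Write a full synthetic cohort (all five modalities) to ``outdir``.

    Planted genotype effects follow the configuration: by default the Hom
    group has faster interstitial Aβ clearance, lower plaque burden and a
    higher soluble-TREM2 amount, with differentially expressed genes and a
    genotype-correlated co-expression module planted in the counts.
    """
    cfg = _merge_config(config)
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    cohort, truth = [], {}

    # --- electrophysiology: one LTP session per animal -------------------
    ec = cfg["ephys"]
    for g in ("WT", "Hom"):
        for i in range(3):
            aid = f"{g}{i + 1}"
            cohort.append({"animal_id": aid, "genotype": g,
                           "sex": "M" if i % 2 == 0 else "F"})
            session, gt = synthdata.gen_ltp_session(
                ec["baseline_slope"], ec["potentiation"][g],
                n_baseline_min=ec["n_baseline_min"], n_post_min=ec["n_post_min"],
                sweeps_per_min=ec["sweeps_per_min"], noise=ec["slope_noise"],
                seed=int(rng.integers(2**31)),
            )
            rows = []
            for k, (sw, minute) in enumerate(zip(session.sweeps, session.minutes)):
                rows.append(pd.DataFrame({
                    "sweep": k, "minute": minute,
                    "time_ms": sw.time_ms, "voltage_mV": sw.voltage_mV,
                }))
            pd.concat(rows).to_csv(out / f"ephys_{aid}.csv", index=False)
            truth[f"ephys_{aid}"] = {"potentiation_factor": ec["potentiation"][g]}

    # --- microdialysis ---------------------------------------------------
    cc = cfg["clearance"]
    series_list = []
    for g in ("WT", "Hom"):
        for i in range(cc["n_animals"]):
            aid = f"{g}-md{i + 1}"
            s, gt = synthdata.gen_dialysis_series(
                cc["baseline_conc"], cc["Ke_per_h"][g], noise_cv=cc["noise_cv"],
                seed=int(rng.integers(2**31)), animal_id=aid)
            series_list.append((s, g))
            truth[f"clearance_{aid}"] = {"Ke_per_h": cc["Ke_per_h"][g]}
    synthdata.write_dialysis_csv([s for s, _ in series_list], out / "fractions.csv")
    pd.DataFrame([{"animal_id": s.animal_id, "genotype": g}
                  for s, g in series_list]).to_csv(out / "fractions_meta.csv", index=False)

    # --- histology: one scene per animal ---------------------------------
    hc = cfg["histo"]
    scene_map = {}
    for g in ("WT", "Hom"):
        for i in range(hc["n_animals"]):
            aid = f"{g}-hist{i + 1}"
            scene, gt = _random_scene(hc, g, rng)
            sdir = out / "scenes" / aid
            synthdata.write_scene(scene, sdir)
            scene_map[aid] = {"dir": str(sdir.relative_to(out)), "genotype": g}
            truth[f"histo_{aid}"] = {"n_plaques": len(gt.params["plaques"])}

    # --- targeted proteomics ----------------------------------------------
    ac = cfg["assay"]
    measurements = []
    for g in ("WT", "Hom"):
        for i in range(ac["n_samples"]):
            sid = f"{g}-prm{i + 1}"
            species = ({"sTREM2-WT": ac["s_fmol"]["WT"], "flTREM2-WT": ac["fl_fmol"]["WT"]}
                       if g == "WT" else
                       {"sTREM2-H157Y": ac["s_fmol"]["Hom"], "flTREM2-H157Y": ac["fl_fmol"]["Hom"]})
            ms, gt = synthdata.gen_prm_run(species, noise_cv=ac["noise_cv"],
                                           seed=int(rng.integers(2**31)),
                                           sample_id=sid, genotype=g)
            measurements.extend(ms)
    synthdata.write_prm_csv(measurements, out / "prm.csv")

    # --- RNA-seq counts ---------------------------------------------------
    tc = cfg["transcript"]
    n = tc["n_per_group"]
    cm, gt = synthdata.gen_counts(
        tc["n_genes"], ["WT"] * n + ["Hom"] * n,
        de_genes={i: tc["de_log2fc"] for i in range(tc["n_de"])},
        module_genes={i: tc["module_loading"]
                      for i in range(tc["n_de"], tc["n_de"] + tc["n_module"])},
        seed=int(rng.integers(2**31)),
    )
    synthdata.write_counts(cm, out / "counts.tsv", out / "samples.csv")
    truth["transcript"] = {"de_genes": gt.params["de_gene_names"],
                           "module_genes": gt.params["module_gene_names"]}

    manifest = {
        "cohort": cohort,
        "modalities": {
            "ephys": {"files": {r["animal_id"]: f"ephys_{r['animal_id']}.csv"
                                for r in cohort}},
            "clearance": {"file": "fractions.csv", "meta": "fractions_meta.csv"},
            "histo": {"scenes": scene_map},
            "assay": {"file": "prm.csv"},
            "transcript": {"counts": "counts.tsv", "meta": "samples.csv"},
        },
        "seed": seed,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, default=synthdata._jsonable)
    manifest["_dir"] = out
    return manifest


def _random_scene(hc: dict, genotype: str, rng) -> tuple:
    size = hc["roi_size_um"]
    dmin, dmax = hc["plaque_diameter_um"]
    margin = dmax / 2 + 2
    plaques = []
    for _ in range(hc["n_plaques"][genotype]):
        plaques.append({
            "center_um": tuple(rng.uniform(margin, size - margin, 2)),
            "diameter_um": float(rng.uniform(dmin, dmax)),
        })
    microglia = []
    for _ in range(hc["n_microglia"]):
        c = rng.uniform(25, size - 25, 2)
        branches = []
        for theta in rng.uniform(0, 2 * np.pi, 4):
            tip = c + rng.uniform(10, 20) * np.array([np.cos(theta), np.sin(theta)])
            tip = np.clip(tip, 1, size - 1)
            branches.append([tuple(c), tuple(tip)])
        microglia.append({"soma_center_um": tuple(c),
                          "soma_diameter_um": float(rng.uniform(7, 10)),
                          "branches": branches})
    return synthdata.gen_scene(size, hc["pixel_size_um"], plaques=plaques,
                               microglia=microglia, noise=hc["image_noise"],
                               seed=int(rng.integers(2**31)))


def run_modality(manifest, modality: str, config: dict | None = None,
                 outdir=None) -> dict:
    """Run one modality end to end: per-sample metrics, group comparison,
    tidy CSVs and a JSON summary (config echoed for reproducibility)."""
    if not isinstance(manifest, dict):
        manifest = load_manifest(manifest)
    cfg = _merge_config(config)
    base = pathlib.Path(manifest["_dir"])
    outdir = pathlib.Path(outdir) if outdir else base / "results"
    outdir.mkdir(parents=True, exist_ok=True)
    runner = {
        "ephys": _run_ephys,
        "clearance": _run_clearance,
        "histo": _run_histo,
        "assay": _run_assay,
        "transcript": _run_transcript,
    }.get(modality)
    if runner is None:
        raise ValueError(f"unknown modality {modality!r}")
    summary = runner(manifest, cfg, base, outdir)
    summary["modality"] = modality
    summary["config"] = cfg[modality] | {"stats": cfg["stats"]}
    summary["seed"] = manifest.get("seed")
    with open(outdir / f"{modality}_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=synthdata._jsonable)
    return summary


def _genotype_of(manifest) -> dict:
    return {r["animal_id"]: r["genotype"] for r in manifest.get("cohort", [])}


def _compare(values_by_group: dict, alpha_var: float) -> dict:
    groups = [np.asarray(v, float) for v in values_by_group.values()]
    plan, res = groupstats.run_comparison(groups, alpha_var=alpha_var)
    return {"groups": list(values_by_group), "test": plan.test,
            "rationale": plan.rationale, "p_value": res.p_value,
            "statistic": res.statistic,
            "means": {g: float(np.mean(v)) for g, v in values_by_group.items()}}


def _run_ephys(manifest, cfg, base, outdir) -> dict:
    geno = _genotype_of(manifest)
    rows = []
    for aid, fname in manifest["modalities"]["ephys"]["files"].items():
        df = pd.read_csv(base / fname)
        sweeps, minutes = [], []
        for _, sub in df.groupby("sweep", sort=True):
            sweeps.append(ephys.Sweep(sub["time_ms"].to_numpy(),
                                      sub["voltage_mV"].to_numpy(),
                                      stim_onset_ms=synthdata.STIM_ONSET_MS))
            minutes.append(sub["minute"].iloc[0])
        prof = ephys.ltp_profile(ephys.EphysSession(sweeps, np.array(minutes)))
        rows.append({"animal_id": aid, "genotype": geno[aid],
                     "last5_mean_pct": prof.last5_mean})
        pd.DataFrame({"minute": prof.minutes, "pct": prof.percent_of_baseline}
                     ).to_csv(outdir / f"ltp_{aid}.csv", index=False)
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "ephys_ltp.csv", index=False)
    by = {g: sub["last5_mean_pct"].to_numpy() for g, sub in table.groupby("genotype")}
    return {"per_animal": rows,
            "comparison": _compare(by, cfg["stats"]["alpha_var"])}


def _run_clearance(manifest, cfg, base, outdir) -> dict:
    mod = manifest["modalities"]["clearance"]
    series = clearance.read_fraction_csv(base / mod["file"])
    geno = pd.read_csv(base / mod["meta"]).set_index("animal_id")["genotype"].to_dict()
    rows = []
    for s in series:
        fit = clearance.fit_elimination(s, paper_constants=cfg["clearance"]["paper_constants"])
        rows.append({"animal_id": s.animal_id, "genotype": geno.get(s.animal_id, ""),
                     "a_log10_per_h": fit.a_log10_per_h, "Ke_per_h": fit.Ke_per_h,
                     "half_life_h": fit.half_life_h, "r2": fit.r2})
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "clearance_fits.csv", index=False)
    by = {g: sub["half_life_h"].to_numpy() for g, sub in table.groupby("genotype")}
    return {"per_animal": rows,
            "comparison": _compare(by, cfg["stats"]["alpha_var"])}


def _run_histo(manifest, cfg, base, outdir) -> dict:
    hc = cfg["histo"]
    rows = []
    for aid, rec in manifest["modalities"]["histo"]["scenes"].items():
        sdir = base / rec["dir"]
        plaque = histoquant.read_plane(sdir / "plaque.tiff", sdir / "plaque.yaml")
        mglia = histoquant.read_plane(sdir / "microglia.tiff", sdir / "microglia.yaml")
        import tifffile

        roi = histoquant.RoiMask(tifffile.imread(sdir / "roi.tiff") > 0,
                                 plaque.pixel_size_um)
        _, summ = histoquant.detect_particles(
            plaque, roi, hc["plaque_threshold"],
            min_diameter_um=hc["min_plaque_diameter_um"])
        nb = histoquant.plaque_neighborhood(
            plaque, mglia, hc["neighborhood_radius_um"],
            plaque_threshold=hc["plaque_threshold"],
            microglia_threshold=hc["microglia_threshold"],
            soma_threshold=hc["soma_threshold"], roi=roi)
        rows.append({
            "animal_id": aid, "genotype": rec["genotype"],
            "plaque_count": summ["count"],
            "plaque_density_per_mm2": summ["density_per_mm2"],
            "plaque_area_fraction_pct": histoquant.area_fraction(
                plaque, roi, hc["plaque_threshold"]),
            "microglia_per_plaque": float(nb["microglia_count"].mean())
            if len(nb) else np.nan,
        })
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "histo_metrics.csv", index=False)
    by = {g: sub["plaque_density_per_mm2"].to_numpy()
          for g, sub in table.groupby("genotype")}
    return {"per_animal": rows,
            "comparison": _compare(by, cfg["stats"]["alpha_var"])}


def _run_assay(manifest, cfg, base, outdir) -> dict:
    ms = assayquant.read_prm_manifest(base / manifest["modalities"]["assay"]["file"])
    table = assayquant.quantify_manifest(ms, reference_group=cfg["assay"]["reference_group"])
    table.to_csv(outdir / "prm_quant.csv", index=False)
    by = {g: sub["s_total_fmol"].to_numpy() for g, sub in table.groupby("genotype")}
    return {"per_sample": table.to_dict(orient="records"),
            "comparison": _compare(by, cfg["stats"]["alpha_var"])}


def _run_transcript(manifest, cfg, base, outdir) -> dict:
    tc = cfg["transcript"]
    mod = manifest["modalities"]["transcript"]
    counts = pd.read_csv(base / mod["counts"], sep="\t", index_col=0)
    meta = pd.read_csv(base / mod["meta"], index_col=0)
    cm = transcript.CountMatrix(counts, meta)
    cm, qc_report = transcript.sample_qc(cm)
    cm = transcript.filter_genes(cm, min_count=tc["min_count"],
                                 min_samples=tc["min_samples"])
    factors = transcript.tmm_factors(cm.counts)
    de = transcript.genewise_de_test(cm, factors)
    de = transcript.classify_deg(de, fdr_cut=tc["fdr_cut"], lfc_cut=tc["lfc_cut"])
    de.to_csv(outdir / "deg_table.csv")
    summary = {
        "n_samples": cm.counts.shape[1],
        "n_excluded": len(qc_report),
        "n_genes_tested": int(de.shape[0]),
        "n_up": int((de["status"] == "up").sum()),
        "n_down": int((de["status"] == "down").sum()),
    }
    if tc["run_modules"]:
        resid = transcript.residualize(
            transcript.log_cpm(cm.counts, factors),
            cm.meta[[c for c in ("sex", "strandness", "exonic_rate")
                     if c in cm.meta.columns]])
        params = transcript.CoexpressionParams(
            beta=tc["beta"], min_module_size=tc["min_module_size"],
            merge_cut=tc["merge_cut"], n_permutations=tc["n_permutations"],
            seed=manifest.get("seed", 0) or 0)
        msod = transcript.build_modules(resid, params)
        trait = (cm.meta["genotype"] == "Hom").astype(float).to_numpy()
        if msod.modules and np.ptp(trait) > 0:
            tcor = transcript.module_trait_correlation(msod, trait)
            tcor.to_csv(outdir / "module_trait.csv")
            summary["module_sizes"] = {m: len(msod.members(m)) for m in msod.modules}
            summary["module_trait_cor"] = tcor["cor"].to_dict()
        msod.labels.rename("module").to_csv(outdir / "module_assignment.csv")
        msod.eigengenes.to_csv(outdir / "module_eigengenes.csv")
    return summary
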