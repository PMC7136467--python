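"""End-to-end orchestration: config, logging, stage sequencing, manifest.

A run is driven by a single human-editable YAML config (echoed verbatim into
the output directory), executes the enabled stages in the study's order —
QC, MDS, admixture, ROH/inbreeding, F_ST + NJ tree, selection scans — and
writes a JSON manifest with a SHA-256 checksum of every artifact, so a rerun
with the same config and seed is verifiably identical.

One global seed fans out to per-stage seeds by fixed offsets, isolating
stage-level stochasticity: changing the admixture chain cannot perturb the
simulated panel.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (admixture, differentiation, genotype_io, popstructure,
               roh_inbreeding, selection_scan, synthetic_data)

log = logging.getLogger("pigpopgen")

#: fixed per-stage seed offsets from the global seed
SEED_OFFSETS = {"simulate": 0, "thin": 101, "admixture": 202, "scan": 303}

DEFAULT_STAGES = {"mds": True, "admixture": False, "roh": True, "fst": True,
                  "tree": True, "scan": False}


def _setup_logging(out_dir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers = [h for h in log.handlers
                    if not isinstance(h, logging.FileHandler)]
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        log.addHandler(sh)
    fh = logging.FileHandler(out_dir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(fh)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _simulate_from_config(cfg: dict, seed: int):
    sim = cfg.get("simulate", {})
    if sim.get("preset") == "conservation":
        sc = synthetic_data.conservation_preset(
            seed=seed, n_snps=int(sim.get("n_snps", 45000)))
    else:
        sc = synthetic_data.SimConfig(
            n_pops=int(sim.get("n_pops", 2)),
            drift=tuple(sim.get("drift", (0.2, 0.2))),
            n_per_pop=tuple(sim.get("n_per_pop", (20, 20))),
            n_snps=int(sim.get("n_snps", 5000)),
            missing_rate=float(sim.get("missing_rate", 0.0)),
            seed=seed)
    return synthetic_data.simulate_panel(sc)


def run_pipeline(config, output_dir=None) -> Path:
    """Execute the configured stage sequence; returns the output directory.

    ``config`` is a dict or a YAML path.  Any stage error aborts the run
    with the stage name, after writing a partial manifest.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(output_dir or config.get("output_dir", "pigpopgen_out"))
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    (out / "config_echo.yaml").write_text(yaml.safe_dump(config,
                                                         sort_keys=True))
    seed = int(config.get("seed", 0))
    stages = {**DEFAULT_STAGES, **config.get("stages", {})}
    manifest: dict = {"seed": seed, "stages": stages, "artifacts": {},
                      "events": []}
    t0 = time.time()

    def _event(stage, status):
        manifest["events"].append(
            {"stage": stage, "status": status,
             "elapsed_s": round(time.time() - t0, 3)})
        log.info("[%s] %s", stage, status)

    def _write_manifest():
        # run.log carries wall-clock timestamps; everything else must be
        # byte-identical across reruns with the same config and seed
        for f in sorted(out.iterdir()):
            if f.is_file() and f.name not in ("manifest.json", "run.log"):
                manifest["artifacts"][f.name] = _sha256(f)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))

    panel = None
    try:
        # ---- input / simulate -------------------------------------------
        _event("input", "start")
        if "simulate" in config:
            ds, panel, truth = _simulate_from_config(
                config, seed + SEED_OFFSETS["simulate"])
            genotype_io.write_plink(ds, str(out / "panel"), format="binary")
            panel.write_tsv(out / "haplotypes.tsv")
            if truth["roh_segments"] is not None:
                truth["roh_segments"].to_csv(out / "truth_roh.tsv", sep="\t",
                                             index=False)
        else:
            inp = config["input"]
            ds = genotype_io.read_plink(inp["plink"],
                                        format=inp.get("format", "text"),
                                        pop_table=inp.get("pop_table"))
        _event("input", "done")

        # ---- QC ----------------------------------------------------------
        _event("qc", "start")
        qc_cfg = config.get("qc", {})
        ds, reports = genotype_io.apply_qc(
            ds,
            max_snp_missing=float(qc_cfg.get("max_snp_missing", 0.10)),
            max_sample_missing=float(qc_cfg.get("max_sample_missing", 0.05)))
        pd.concat([r.to_frame() for r in reports]).to_csv(
            out / "qc_report.tsv", sep="\t", index=False)
        _event("qc", f"done ({ds.n_samples} samples x {ds.n_markers} SNPs)")

        # ---- MDS ---------------------------------------------------------
        if stages.get("mds"):
            _event("mds", "start")
            co = popstructure.ibs_matrix(ds)
            mds = popstructure.classical_mds(co, d=2)
            frame = mds.to_frame()
            frame["population"] = ds.samples["population"].to_numpy()
            frame.to_csv(out / "mds.tsv", sep="\t", index=False)
            _event("mds", "done")

        # ---- admixture ---------------------------------------------------
        if stages.get("admixture"):
            _event("admixture", "start")
            ad_cfg = config.get("admixture", {})
            ads = ds
            thin_to = ad_cfg.get("thin_to")
            if thin_to and int(thin_to) < ds.n_markers:
                ads = genotype_io.thin_snps(ds, int(thin_to),
                                            seed=seed + SEED_OFFSETS["thin"])
            evidence: dict[int, list[float]] = {}
            for K in [int(k) for k in ad_cfg.get("K", [2])]:
                spec = admixture.AdmixtureModelSpec(
                    K=K, burn_in=int(ad_cfg.get("burn_in", 10000)),
                    reps=int(ad_cfg.get("reps", 100000)),
                    n_runs=int(ad_cfg.get("n_runs", 20)),
                    seed=seed + SEED_OFFSETS["admixture"] + K)
                fits, aligned = admixture.fit_multiple(ads, spec)
                evidence[K] = [f.ln_evidence for f in fits]
                kdir = out / f"admixture_K{K}"
                kdir.mkdir(exist_ok=True)
                for r, f in enumerate(fits, start=1):
                    rdir = kdir / f"run_{r:02d}"
                    rdir.mkdir(exist_ok=True)
                    _q_table(f.Q, ads).to_csv(rdir / "Q.tsv", sep="\t",
                                              index=False)
                _q_table(aligned.Q_mean, ads).to_csv(kdir / "Q_mean.tsv",
                                                     sep="\t", index=False)
            ev_rows = [(k, r, v) for k, vs in evidence.items()
                       for r, v in enumerate(vs, start=1)]
            pd.DataFrame(ev_rows, columns=["K", "run", "ln_evidence"]).to_csv(
                out / "ln_evidence.tsv", sep="\t", index=False)
            if len(evidence) >= 3:
                admixture.delta_k(evidence).to_csv(out / "delta_k.tsv",
                                                   sep="\t", index=False)
            _event("admixture", "done")

        # ---- ROH / inbreeding -------------------------------------------
        per_class = None
        if stages.get("roh"):
            _event("roh", "start")
            roh_cfg = config.get("roh", {})
            params = roh_inbreeding.RohParams(
                min_snps=int(roh_cfg.get("min_snps", 15)),
                max_gap_mb=float(roh_cfg.get("max_gap_mb", 1.0)),
                density_mb_per_snp=float(roh_cfg.get("density", 0.1)))
            table, per_class = roh_inbreeding.inbreeding_table(ds, params)
            table.to_csv(out / "inbreeding.tsv", sep="\t", index=False)
            segs = [s for lst in per_class.values() for s in lst]
            roh_inbreeding.segments_to_frame(segs).to_csv(
                out / "roh_segments.tsv", sep="\t", index=False)
            _event("roh", "done")

        # ---- F_ST / tree -------------------------------------------------
        theta_m = None
        if stages.get("fst") or stages.get("tree"):
            _event("fst", "start")
            theta_m, per_pop, grand = differentiation.pairwise_fst_matrix(ds)
            theta_m.to_frame().to_csv(out / "fst_matrix.tsv", sep="\t")
            per_pop.to_frame().assign(grand_mean=grand).to_csv(
                out / "fst_per_population.tsv", sep="\t")
            _event("fst", f"done (mean pairwise theta {grand:.3f})")
        if stages.get("tree"):
            _event("tree", "start")
            reyn = differentiation.reynolds_distance(theta_m)
            tree = differentiation.nj_tree(reyn)
            (out / "tree.nwk").write_text(tree.newick + "\n")
            _event("tree", "done")

        # ---- selection scans --------------------------------------------
        if stages.get("scan"):
            _event("scan", "start")
            scan_cfg = config.get("scan", {})
            cfg_obj = selection_scan.ScanConfig(
                local_pop=scan_cfg.get("local_pop", ds.populations()[0]),
                commercial_pops=tuple(scan_cfg.get(
                    "commercial_pops",
                    [p for p in ds.populations()
                     if p != scan_cfg.get("local_pop",
                                          ds.populations()[0])])))
            fst_out = selection_scan.fst_outliers(
                ds, cfg_obj.local_pop, cfg_obj.commercial_pops,
                top_n=cfg_obj.top_n_fst)
            fst_out.to_csv(out / "scan_fst_outliers.tsv", sep="\t",
                           index=False)
            sets = {"fst": set(fst_out["snp"])}
            if per_class is not None:
                inc = roh_inbreeding.roh_incidence(per_class[0], ds,
                                                   cfg_obj.local_pop)
                ero, islands = selection_scan.erohi_outliers(
                    inc, ds.markers, cfg_obj)
                ero.to_csv(out / "scan_erohi.tsv", sep="\t", index=False)
                islands.to_csv(out / "scan_erohi_islands.tsv", sep="\t",
                               index=False)
                sets["erohi"] = set(ero["snp"])
            if panel is not None:
                local_panel = panel.subset_population(cfg_obj.local_pop)
                ihs = selection_scan.ihs_scan(local_panel, cfg_obj)
                ihs.to_csv(out / "scan_ihs.tsv", sep="\t", index=False)
                sets["ihs"] = set(ihs.loc[ihs["significant"], "snp"])
                comm_panel_pops = [p for p in cfg_obj.commercial_pops
                                   if p in set(panel.populations)]
                if comm_panel_pops:
                    comm = panel
                    rows = [i for i, p in enumerate(panel.populations)
                            if p in comm_panel_pops]
                    comm = synthetic_data.HaplotypePanel(
                        markers=panel.markers,
                        haplotypes=panel.haplotypes[np.sort(np.concatenate(
                            [[2 * i, 2 * i + 1] for i in rows]))],
                        sample_ids=[panel.sample_ids[i] for i in rows],
                        populations=[panel.populations[i] for i in rows])
                    rsb = selection_scan.rsb_scan(local_panel, comm, cfg_obj)
                    rsb.to_csv(out / "scan_rsb.tsv", sep="\t", index=False)
                    sets["rsb"] = set(rsb.loc[rsb["significant"], "snp"])
            if len(sets) >= 2:
                inter, windows = selection_scan.overlap_report(
                    sets, ds.markers, window_mb=cfg_obj.window_mb)
                inter.to_csv(out / "scan_overlap.tsv", sep="\t", index=False)
                windows.to_csv(out / "scan_windows.tsv", sep="\t",
                               index=False)
            _event("scan", "done")
    except Exception as exc:
        _event("error", f"{type(exc).__name__}: {exc}")
        _write_manifest()
        raise
    _write_manifest()
    return out


def _q_table(Q: np.ndarray, ds) -> pd.DataFrame:
    cols = {f"Q{k + 1}": Q[:, k] for k in range(Q.shape[1])}
    return pd.DataFrame({"sample_id": ds.samples["sample_id"],
                         "population": ds.samples["population"], **cols})


def report_summary(out_dir) -> pd.DataFrame:
    """Aggregate per-breed mean F_ROH and mean F_ST into one summary table."""
    out = Path(out_dir)
    parts = []
    inb = out / "inbreeding.tsv"
    if inb.exists():
        t = pd.read_csv(inb, sep="\t")
        parts.append(t.groupby("population")[
            ["froh_gt4", "froh_gt8", "froh_4to8", "froh_gt16"]].mean())
    fst = out / "fst_per_population.tsv"
    if fst.exists():
        t = pd.read_csv(fst, sep="\t", index_col=0)
        parts.append(t[["mean_fst"]])
    if not parts:
        raise FileNotFoundError(f"no summarizable outputs in {out}")
    summary = pd.concat(parts, axis=1)
    summary.index.name = "population"
    summary.to_csv(out / "summary.tsv", sep="\t")
    return summary
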