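"""End-to-end pipeline: simulate or load a panel, then run every analysis stage.

Stage order: io -> variant filter -> structure screen -> per-year GWAS with
peak detection and conditional classification -> haplotype coding ->
correlation/partial-correlation triage (overall and per splitter-gene
stratum) -> haplotype trajectories + Fisher transition tests -> Nei scan ->
combo-group tables.  Every stage is recorded in the report as present,
skipped (with reason), or failed; outputs and provenance are written to a run
directory, deterministically under a fixed config + seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import corr_partial, gwas_lmm, gxg, panel_io, selection_scan, sim_panel, structure

__all__ = ["PipelineReport", "run_pipeline"]


@dataclass
class PipelineReport:
    """Stage-by-stage results of one pipeline run."""

    out_dir: Path
    stages: dict[str, dict] = field(default_factory=dict)
    results: dict[str, object] = field(default_factory=dict)

    def record(self, stage: str, status: str, reason: str | None = None) -> None:
        self.stages[stage] = {"status": status, **({"reason": reason} if reason else {})}

    def ok(self, stage: str) -> bool:
        return self.stages.get(stage, {}).get("status") == "ok"


def _config_hash(config: dict) -> str:
    canon = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 seed: int = 0, make_plots: bool = True) -> PipelineReport:
    """Execute the full analysis described by a config mapping or YAML path."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(out)
    ana = config.get("analysis", {})

    # --- io ---------------------------------------------------------------
    try:
        if "simulate" in config:
            simc = config["simulate"] or {}
            gmap = sim_panel.default_genome_map(simc.get("n_neutral_per_chrom", 25))
            model = sim_panel.default_effect_model(simc.get("residual_sd", 2.5))
            plan = sim_panel.default_breeding_plan(seed)
            plan.founder_code1_freq.update(simc.get("founder_code1_freq", {}))
            panel = sim_panel.simulate_panel(plan, gmap, model, seed=seed)
            G_raw, pheno, meta = panel.genotypes, panel.phenotypes, panel.metadata
            gene_defs = panel.gene_defs
            panel.write(out / "panel")
        elif "data" in config:
            data = config["data"]
            G_raw = panel_io.read_genotypes(data["vcf"])
            pheno = panel_io.read_phenotypes(data["phenotypes"])
            meta = panel_io.read_metadata(data["metadata"]) if data.get("metadata") else None
            gene_defs = (panel_io.load_gene_defs(data["gene_defs"])
                         if data.get("gene_defs") else panel_io.default_gene_defs())
        else:
            raise ValueError("config needs a 'simulate' or 'data' block")
        report.record("io", "ok")
    except Exception as e:  # noqa: BLE001 - stage failures are data, not crashes
        report.record("io", "failed", str(e))
        _finalize(report, config, seed)
        return report

    years = [str(y) for y in ana.get("years", sorted(pheno["year"].astype(str).unique()))]

    # --- variant filter ----------------------------------------------------
    G = panel_io.filter_variants(G_raw, ana.get("maf_min", 0.05), ana.get("missing_max", 0.10))
    report.record("filter", "ok")
    report.results["genotypes"] = G

    # --- structure screen ---------------------------------------------------
    try:
        pca = structure.pca_scores(G, n_components=min(10, G.n_lines - 1, G.n_variants))
        screen = structure.pc_trait_screen(pca, pheno, years[0])
        pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        screen.to_csv(out / "structure_screen.tsv", sep="\t")
        report.record("structure", "ok")
        report.results["structure"] = screen
    except Exception as e:
        report.record("structure", "failed", str(e))

    # --- per-year GWAS + peaks + conditional classification -----------------
    try:
        K = gwas_lmm.compute_kinship(G)
        cfg = gwas_lmm.ScanConfig(clump_window=ana.get("clump_window", 1_000_000),
                                  clump_r2=ana.get("clump_r2", 0.4))
        scans = {}
        for yr in years:
            y = (pheno[pheno["year"].astype(str) == yr]
                 .set_index("line")["dth"].reindex(G.line_ids))
            scans[yr] = gwas_lmm.marker_scan(y.to_numpy(), G, K, cfg)
            scans[yr].table.to_csv(out / f"gwas_{yr}.tsv", sep="\t", index=False)
            if make_plots:
                _manhattan_plot(scans[yr], cfg, out / f"manhattan_{yr}.png")
                _qq_plot(scans[yr], out / f"qq_{yr}.png")
        peaks = gwas_lmm.detect_peaks(scans, G, cfg)
        y0 = (pheno[pheno["year"].astype(str) == years[0]]
              .set_index("line")["dth"].reindex(G.line_ids).to_numpy())
        if len(peaks) > 1:
            top = max(peaks, key=lambda p: p.max_neglog10p)
            classified = [top]
            for p in peaks:
                if p is not top:
                    classified.append(gwas_lmm.classify_peak(p, top, y0, G, K, cfg))
            peaks = classified
        _write_peaks(peaks, out / "peaks.tsv")
        report.record("gwas", "ok")
        report.results["scans"] = scans
        report.results["peaks"] = peaks
    except Exception as e:
        report.record("gwas", "failed", str(e))

    # --- haplotype coding ----------------------------------------------------
    try:
        H = panel_io.call_haplotypes(G_raw, gene_defs)
        codes, signs = panel_io.code_activity(H)
        codes.to_csv(out / "activity_codes.tsv", sep="\t")
        report.record("haplotypes", "ok")
        report.results["haplotypes"] = H
    except Exception as e:
        report.record("haplotypes", "failed", str(e))
        H = None

    # --- correlation / triage -------------------------------------------------
    splitter = ana.get("splitter_gene", "Hd1")
    if H is not None:
        try:
            strata: dict[str, pd.DataFrame] = {"overall": codes}
            if splitter in codes.columns and codes[splitter].nunique() > 1:
                strata[f"{splitter}_functional"] = codes[codes[splitter] == 1]
                strata[f"{splitter}_nonfunctional"] = codes[codes[splitter] == 0]
            reports = {}
            for name, sub_codes in strata.items():
                drop = [splitter] if name != "overall" and splitter in sub_codes else []
                use = sub_codes.drop(columns=drop)
                use = use.loc[:, use.nunique(dropna=True) > 1]
                for yr in years:
                    dth = (pheno[pheno["year"].astype(str) == yr]
                           .set_index("line")["dth"])
                    panel_cc = corr_partial.CodedPanel.from_data(use, dth, signs, yr)
                    rep = corr_partial.correlation_report(
                        panel_cc, phi_min=ana.get("phi_min", 0.25))
                    rep.to_csv(out / f"correlations_{name}_{yr}.tsv", sep="\t")
                    reports[(name, yr)] = rep
            report.record("correlations", "ok")
            report.results["correlations"] = reports
        except Exception as e:
            report.record("correlations", "failed", str(e))
    else:
        report.record("correlations", "skipped", "haplotype stage unavailable")

    # --- trajectories + Fisher + Nei scan (need metadata) ----------------------
    if meta is None:
        for st in ("trajectory", "nei_scan"):
            report.record(st, "skipped", "no line metadata provided")
    elif H is None:
        report.record("trajectory", "skipped", "haplotype stage unavailable")
        report.record("nei_scan", "skipped", "haplotype stage unavailable")
    else:
        focal = ana.get("focal", {"Hd16": "E", "Hd17": "L"})
        try:
            H_use, meta_use = H, meta
            if splitter in H.codes.columns and H.codes[splitter].nunique() > 1:
                functional = H.codes.index[H.codes[splitter] == 1]
                H_use = panel_io.HaplotypeTable(H.labels.loc[functional],
                                                H.codes.loc[functional], H.gene_defs)
                meta_use = meta[meta["line"].isin(functional)]
            traj = selection_scan.frequency_trajectory(H_use, meta_use, focal)
            traj.table.to_csv(out / "trajectory.tsv", sep="\t")
            pers = list(traj.table.index)
            fisher = {f"{a}->{b}": selection_scan.transition_fisher(traj, (a, b))
                      for a, b in zip(pers[:-1], pers[1:])}
            if len(pers) > 1:
                fisher[f"{pers[0]}->{pers[-1]}"] = selection_scan.transition_fisher(
                    traj, (pers[0], pers[-1]))
            with open(out / "transition_fisher.json", "w") as fh:
                json.dump(fisher, fh, indent=1)
            report.record("trajectory", "ok")
            report.results["trajectory"] = traj
            report.results["fisher"] = fisher
        except Exception as e:
            report.record("trajectory", "failed", str(e))
        try:
            early_p = ana.get("early_period", "I")
            late_p = ana.get("late_period", "IV")
            m = meta.set_index("line")
            lines_e = [l for l in G.line_ids if m.loc[l, "period"] == early_p]
            lines_l = [l for l in G.line_ids if m.loc[l, "period"] == late_p]
            scan = selection_scan.nei_scan(G.subset_lines(lines_e), G.subset_lines(lines_l))
            scan.table.to_csv(out / "nei_scan.tsv", sep="\t", index=False)
            scan.thresholds.to_csv(out / "nei_thresholds.tsv", sep="\t")
            report.record("nei_scan", "ok")
            report.results["nei_scan"] = scan
        except Exception as e:
            report.record("nei_scan", "failed", str(e))

    # --- combo groups -----------------------------------------------------------
    if H is not None:
        try:
            combo_genes = ana.get("combo_genes", ["Hd16", "Hd17"])
            stratum = ({splitter: 1} if splitter in H.codes.columns
                       and H.codes[splitter].nunique() > 1 else None)
            groups = gxg.combo_groups(H, pheno, stratum, combo_genes)
            rows = []
            for g in groups:
                for yr, s in g.summary.iterrows():
                    rows.append((g.group_id, json.dumps(g.combo), yr,
                                 s["mean"], s["sd"], s["n"]))
            pd.DataFrame(rows, columns=["group", "combo", "year", "mean", "sd", "n"]
                         ).to_csv(out / "combo_groups.tsv", sep="\t", index=False)
            report.record("combo_groups", "ok")
            report.results["combo_groups"] = groups
        except Exception as e:
            report.record("combo_groups", "failed", str(e))
    else:
        report.record("combo_groups", "skipped", "haplotype stage unavailable")

    _finalize(report, config, seed)
    return report


def _finalize(report: PipelineReport, config: dict, seed: int) -> None:
    provenance = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "breedscan_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "stages": report.stages,
    }
    with open(report.out_dir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1)


def _write_peaks(peaks, path: Path) -> None:
    rows = [(p.chrom, p.start, p.end, f"{p.seed[0]}:{p.seed[1]}",
             p.max_neglog10p, p.status) for p in peaks]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "seed", "max_neglog10p",
                                "status"]).to_csv(path, sep="\t", index=False)


def _manhattan_plot(result, config, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.table.dropna(subset=["neglog10p"])
    fig, ax = plt.subplots(figsize=(10, 3))
    offset, ticks = 0, []
    for c in sorted(t["chrom"].unique()):
        sub = t[t["chrom"] == c]
        ax.scatter(sub["pos"] + offset, sub["neglog10p"], s=6,
                   color="tab:blue" if c % 2 else "tab:cyan")
        ticks.append((offset + sub["pos"].max() / 2, str(c)))
        offset += sub["pos"].max()
    ax.axhline(-np.log10(config.suggestive_p), color="blue", lw=0.8, ls="--")
    ax.axhline(-np.log10(config.significance_p), color="red", lw=0.8, ls="--")
    ax.set_xticks([x for x, _ in ticks], [l for _, l in ticks])
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} P$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _qq_plot(result, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lam, qq = gwas_lmm.qq_inflation(result)
    fig, ax = plt.subplots(figsize=(3.5, 3.5))
    ax.scatter(qq["expected"], qq["observed"], s=6)
    lim = max(qq["expected"].max(), qq["observed"].max())
    ax.plot([0, lim], [0, lim], color="grey", lw=0.8)
    ax.set_xlabel("expected $-\\log_{10} P$")
    ax.set_ylabel("observed $-\\log_{10} P$")
    ax.set_title(f"$\\lambda_{{GC}}$ = {lam:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
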