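"""Reproducible benchmark scenarios exercising the full analysis stack.

Each function runs a self-contained simulation study and returns summary
rates/statistics; they back both the test suite and the reproduction script.
All randomness is controlled by an explicit seed.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import corr_partial as cp
from . import gwas_lmm as gl
from . import panel_io as pio
from . import selection_scan as ss
from . import sim_panel as sp

__all__ = [
    "masked_recovery",
    "ld_shadow_classification",
    "lmm_identity_vs_ols",
    "lmm_null_calibration",
    "fisher_enumeration_max_diff",
    "exact_statistic_errors",
    "selection_scan_rates",
    "filter_contract",
]


def masked_recovery(n_rep: int = 100, n_lines: int = 150, seed: int = 0) -> dict:
    """Type II recovery study on planted-confounding coded panels.

    Per replicate: a gated masked gene (-7 d), a confounder (+8 d) at phi 0.4
    with it, and independent null genes.  Success = the masked gene's marginal
    point-biserial is non-significant or positive while its partial
    correlation is negative and Holm-significant.  Also reports per-gene
    triage label rates for the null genes.
    """
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, n_rep)
    hits = 0
    label_hits = 0
    null_flags: dict[str, int] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in rep_seeds:
            codes, dth, signs, _ = sp.sample_coded_panel(n_lines=n_lines, seed=int(s))
            panel = cp.CodedPanel.from_data(codes, dth, signs)
            rep = cp.correlation_report(panel)
            m = rep.loc["masked"]
            ok = ((m["marginal_p_holm"] >= 0.05 or m["marginal_r"] > 0)
                  and m["partial_r"] < 0 and m["partial_p_holm"] < 0.05)
            hits += int(ok)
            label_hits += int(rep.loc["masked", "triage"] == "type-II-candidate")
            for g in rep.index:
                if g.startswith("null"):
                    null_flags[g] = null_flags.get(g, 0) + int(rep.loc[g, "triage"] != "null")
    return {
        "recovery_rate": hits / n_rep,
        "label_rate": label_hits / n_rep,
        "null_flag_rates": {g: c / n_rep for g, c in null_flags.items()},
        "max_null_flag_rate": max(c / n_rep for c in null_flags.values()),
        "n_rep": n_rep,
        "n_lines": n_lines,
    }


def ld_shadow_classification(n_rep: int = 40, seed: int = 0) -> dict:
    """Conditional-scan classification study on causal/hitchhiker panels.

    Per replicate: detect peaks in an LMM scan of a panel carrying one causal
    locus and one unlinked effect-free hitchhiker in co-selection LD, then
    classify each peak by conditioning on the other's peak-highest
    polymorphism.  Reports the rates at which the hitchhiker is called
    LD-shadow and the causal locus stays independent.
    """
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, n_rep)
    shadow = indep = detected = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in rep_seeds:
            G, dth, truth = sp.simulate_ld_panel(seed=int(s))
            K = gl.compute_kinship(G)
            cfg = gl.ScanConfig()
            res = gl.marker_scan(dth, G, K, cfg)
            peaks = gl.detect_peaks({"y": res}, G, cfg)

            def find(ch, pos):
                return next((p for p in peaks if p.chrom == ch and p.start <= pos <= p.end),
                            None)

            ca = find(truth["causal"]["chrom"], truth["causal"]["pos"])
            hb = find(truth["hitchhiker"]["chrom"], truth["hitchhiker"]["pos"])
            if ca is None or hb is None:
                continue
            detected += 1
            shadow += int(gl.classify_peak(hb, ca, dth, G, K, cfg).status == "LD-shadow")
            indep += int(gl.classify_peak(ca, hb, dth, G, K, cfg).status == "independent")
    return {
        "shadow_rate": shadow / n_rep,
        "independent_rate": indep / n_rep,
        "both_peaks_detected_rate": detected / n_rep,
        "n_rep": n_rep,
    }


def lmm_identity_vs_ols(n_lines: int = 30, n_markers: int = 40, seed: int = 0) -> float:
    """Max |P_LMM - P_OLS| over markers when K = I (should be ~0)."""
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.2, 0.8, n_markers)
    calls = (rng.random((n_lines, n_markers)) < freqs).astype(float)
    G = pio.GenotypeMatrix([f"L{i}" for i in range(n_lines)],
                           np.full(n_markers, 1), np.arange(1, n_markers + 1) * 1000,
                           np.full(n_markers, "A", object), np.full(n_markers, "T", object),
                           calls)
    y = 70 + 2 * calls[:, 3] + rng.normal(0, 2, n_lines)
    K = gl.KinshipMatrix(np.eye(n_lines), list(G.line_ids))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = gl.marker_scan(y, G, K)
    diffs = []
    for j in range(n_markers):
        x = calls[:, j]
        if np.std(x) == 0:
            continue
        p_ols = stats.linregress(x, y).pvalue
        p_lmm = 10 ** (-res.table["neglog10p"].iloc[j])
        diffs.append(abs(p_lmm - p_ols))
    return float(max(diffs))


def lmm_null_calibration(n_rep: int = 40, n_lines: int = 120, n_markers: int = 400,
                         seed: int = 0) -> dict:
    """P-value uniformity under a pure-noise phenotype with a realized kinship.

    Per replicate: iid genotypes, y ~ N(0,1), full P3D scan; a
    Kolmogorov-Smirnov test of the P values against Uniform(0,1) and the
    genomic inflation factor are recorded.
    """
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, n_rep)
    ks_pass = 0
    lambdas = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in rep_seeds:
            r = np.random.default_rng(int(s))
            freqs = r.uniform(0.1, 0.9, n_markers)
            calls = (r.random((n_lines, n_markers)) < freqs).astype(float)
            G = pio.GenotypeMatrix([f"L{i}" for i in range(n_lines)],
                                   np.full(n_markers, 1),
                                   np.arange(1, n_markers + 1) * 1000,
                                   np.full(n_markers, "A", object),
                                   np.full(n_markers, "T", object), calls)
            y = r.normal(0, 1, n_lines)
            K = gl.compute_kinship(G)
            res = gl.marker_scan(y, G, K)
            pvals = 10 ** (-res.table["neglog10p"].dropna().to_numpy())
            ks_pass += int(stats.kstest(pvals, "uniform").pvalue >= 0.01)
            lam, _ = gl.qq_inflation(res)
            lambdas.append(lam)
    return {
        "ks_pass_rate": ks_pass / n_rep,
        "lambda_gc_mean": float(np.mean(lambdas)),
        "lambda_gc_median": float(np.median(lambdas)),
        "n_rep": n_rep,
    }


def fisher_enumeration_max_diff(max_margin: int = 12) -> float:
    """Max |p_ours - p_enumeration| over all 2x2 tables with row totals
    <= max_margin, using the probability-mass two-sided rule."""
    worst = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for t1, t2 in itertools.product(range(1, max_margin + 1), repeat=2):
            for c1 in range(t1 + 1):
                for c2 in range(t2 + 1):
                    K = c1 + c2
                    rv = stats.hypergeom(t1 + t2, K, t1)
                    support = np.arange(max(0, K - t2), min(K, t1) + 1)
                    pmf = rv.pmf(support)
                    p_enum = min(float(pmf[pmf <= rv.pmf(c1) * (1 + 1e-9)].sum()), 1.0)
                    if (K == 0 or K == t1 + t2):
                        p_enum = 1.0  # degenerate margin: reported as 1 by convention
                    table = pd.DataFrame({"count": [c1, c2], "total": [t1, t2],
                                          "fraction": [c1 / t1, c2 / t2]}, index=["I", "IV"])
                    ours = ss.transition_fisher(ss.FrequencyTrajectory({}, table),
                                                ("I", "IV"))
                    worst = max(worst, abs(ours - p_enum))
    return worst


def exact_statistic_errors() -> dict:
    """Deviation of each closed-form statistic from its hand value."""
    r, _ = cp.point_biserial([0, 0, 1, 1], [1, 2, 3, 4])
    pb_err = abs(r - 2 / np.sqrt(5))
    a = np.repeat([1.0, 1, 0, 0], [40, 10, 10, 40])
    b = np.repeat([1.0, 0, 1, 0], [40, 10, 10, 40])
    phi_err = abs(cp.phi_coefficient(a, b) - 0.6)
    holm_err = float(np.max(np.abs(cp.holm_adjust([0.01, 0.02, 0.04])
                                   - np.array([0.03, 0.04, 0.04]))))
    R = np.array([[1.0, 0.5, 0.8], [0.5, 1.0, 0.8], [0.8, 0.8, 1.0]])
    P = np.linalg.inv(R)
    partial_err = abs(-P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]) - (0.5 - 0.64) / 0.36)
    nei_err = abs(float(ss.nei_distance(0.9, 0.1)) - (-np.log(0.18 / np.sqrt(0.82 * 0.82))))
    return {"point_biserial": pb_err, "phi": phi_err, "holm": holm_err,
            "partial": partial_err, "nei": nei_err,
            "max": max(pb_err, phi_err, holm_err, partial_err, nei_err)}


def selection_scan_rates(n_rep: int = 50, seed: int = 0) -> dict:
    """Selection-scan study on the default breeding panel.

    Per replicate: simulate the default four-period program, then check that
    (i) both truly selected loci exceed their chromosome's top-5% Nei
    threshold between periods I and IV, (ii) the focal inactive-Hd16 /
    late-Hd17 combination rises strictly monotonically across periods, and
    (iii) the period I->IV Fisher transition test is significant at 0.001.
    """
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, n_rep)
    gmap = sp.default_genome_map()
    model = sp.default_effect_model()
    nei_ok = mono_ok = fisher_ok = joint = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in rep_seeds:
            panel = sp.simulate_panel(sp.default_breeding_plan(int(s)), gmap, model,
                                      seed=int(s))
            H = pio.call_haplotypes(panel.genotypes, panel.gene_defs)
            traj = ss.frequency_trajectory(H, panel.metadata, {"Hd16": "E", "Hd17": "L"})
            fr = traj.table["fraction"].to_numpy()
            mono = bool(np.all(np.diff(fr) > 0))
            p_fisher = ss.transition_fisher(traj, ("I", "IV"))
            meta = panel.metadata.set_index("line")
            G = panel.genotypes
            early = [l for l in G.line_ids if meta.loc[l, "period"] == "I"]
            late = [l for l in G.line_ids if meta.loc[l, "period"] == "IV"]
            scan = ss.nei_scan(G.subset_lines(early), G.subset_lines(late))
            t = scan.table
            hit = {}
            for g in ("Hd16", "Hd17"):
                ch, pos = sp.CAUSAL_LOCI[g]
                row = t[(t["chrom"] == ch) & (t["pos"] == pos)]
                hit[g] = bool(row["above5pct"].iloc[0])
            nei_both = hit["Hd16"] and hit["Hd17"]
            nei_ok += int(nei_both)
            mono_ok += int(mono)
            fisher_ok += int(p_fisher < 1e-3)
            joint += int(nei_both and mono and p_fisher < 1e-3)
    return {
        "nei_rate": nei_ok / n_rep,
        "monotone_rate": mono_ok / n_rep,
        "fisher_rate": fisher_ok / n_rep,
        "joint_rate": joint / n_rep,
        "n_rep": n_rep,
    }


def filter_contract(tmp_vcf_path=None) -> dict:
    """The variant-QC boundary contract on a constructed 100-line panel.

    Four variants crossing the MAF {below, at} x missingness {below, at}
    boundaries; exactly the (MAF >= 0.05, missing 0.09) variant must survive
    the '<5% MAF removed, >=10% missing removed' rule.
    """
    n = 100
    specs = [
        ("keep", 5, 9),      # MAF 5/91 >= 0.05, missing 0.09
        ("maf_low", 4, 9),   # MAF 4/91 < 0.05
        ("miss_high", 5, 10),  # missing exactly 0.10
        ("both_bad", 4, 10),
    ]
    cols = []
    for _, n_alt, n_miss in specs:
        col = np.zeros(n)
        col[:n_alt] = 1.0
        col[n - n_miss:] = np.nan
        cols.append(col)
    calls = np.column_stack(cols)
    G = pio.GenotypeMatrix([f"L{i}" for i in range(n)], np.full(4, 1),
                           np.arange(1, 5) * 1000, np.full(4, "A", object),
                           np.full(4, "T", object), calls)
    if tmp_vcf_path is not None:  # optionally exercise the VCF round trip
        pio.write_genotypes(G, tmp_vcf_path)
        G = pio.read_genotypes(tmp_vcf_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = pio.filter_variants(G)
    survivors = [int(p) for p in out.pos]
    return {"n_survivors": len(survivors), "survivor_positions": survivors,
            "contract_held": survivors == [1000]}
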