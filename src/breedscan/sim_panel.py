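"""Synthetic breeding-panel simulator.

Emulates a small-station rice breeding program: fully inbred founder lines,
four breeding periods of random biparental crosses, Haldane-model
recombination, derivation of new inbred lines by doubling one recombinant
gamete, and phenotypic truncation selection of days-to-heading (DTH) into a
period-specific target window.  Because several unlinked heading-date loci
jointly set DTH — with epistatic gating among them — window selection
co-selects particular allele combinations and thereby plants *artificial*
(trans-chromosomal) linkage disequilibrium between physically unlinked loci,
the statistical structure the downstream association and correlation
machinery is designed to expose.  Full ground truth (causal codes, effect
model, per-period allele frequencies) is carried alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .panel_io import (
    GenotypeMatrix,
    GeneDef,
    HaplotypeRule,
    PERIOD_YEARS,
    write_genotypes,
)

__all__ = [
    "GenomeMap",
    "EffectModel",
    "EpistasisRule",
    "PeriodPlan",
    "BreedingPlan",
    "SimulatedPanel",
    "phenotype_dth",
    "simulate_founders",
    "breed_period",
    "simulate_panel",
    "sample_coded_panel",
    "simulate_ld_panel",
    "default_genome_map",
    "default_effect_model",
    "default_breeding_plan",
]

#: Approximate rice chromosome lengths (bp), IRGSP-style 12-chromosome genome.
RICE_CHROM_LENGTHS = (
    43_270_923, 35_937_250, 36_413_819, 35_502_694, 29_958_434, 31_248_787,
    29_697_621, 28_443_022, 23_012_720, 23_207_287, 29_021_106, 27_531_856,
)

#: Default causal loci: gene -> (chromosome, defining position).  Hd1 is
#: represented by its null-haplotype tag polymorphism.
CAUSAL_LOCI = {
    "Hd1": (6, 9_337_236),
    "Hd2": (7, 29_623_803),
    "Hd6": (3, 31_512_460),
    "Hd16": (3, 33_002_789),
    "Hd17": (6, 2_235_191),
    "Hd18": (8, 2_388_554),
}

#: Activity code carried by the alternative allele at each causal locus
#: (0 = the alt allele is the lower-activity haplotype).
CODE_OF_ALT = {"Hd1": 0, "Hd2": 0, "Hd6": 1, "Hd16": 0, "Hd17": 0, "Hd18": 0}

#: Expected sign of correlation between activity code and DTH.
EFFECT_SIGN = {"Hd1": +1, "Hd2": +1, "Hd6": +1, "Hd16": +1, "Hd17": -1, "Hd18": -1}


@dataclass
class GenomeMap:
    """Variant coordinates: neutral SNP positions per chromosome plus causal loci."""

    n_chromosomes: int
    chrom_lengths: tuple[int, ...]
    neutral_snp_positions: dict[int, np.ndarray]
    causal_loci: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.chrom_lengths) != self.n_chromosomes:
            raise ValueError("chrom_lengths must have n_chromosomes entries")
        for c, pos in self.neutral_snp_positions.items():
            pos = np.asarray(pos, dtype=int)
            if not (1 <= c <= self.n_chromosomes):
                raise ValueError(f"chromosome id {c} outside 1..{self.n_chromosomes}")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"neutral positions on chromosome {c} not strictly increasing")
            self.neutral_snp_positions[c] = pos
        for g, (c, p) in self.causal_loci.items():
            if not (1 <= c <= self.n_chromosomes):
                raise ValueError(f"causal locus {g} on chromosome {c} outside genome")
            if not (1 <= p <= self.chrom_lengths[c - 1]):
                raise ValueError(f"causal locus {g} position {p} outside chromosome {c}")

    def variants(self) -> pd.DataFrame:
        """All variants sorted by (chrom, pos) with a 'gene' column (None = neutral)."""
        rows = []
        for c in range(1, self.n_chromosomes + 1):
            for p in self.neutral_snp_positions.get(c, ()):
                rows.append((c, int(p), None))
        for g, (c, p) in self.causal_loci.items():
            rows.append((c, p, g))
        df = pd.DataFrame(rows, columns=["chrom", "pos", "gene"])
        df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
        if df.duplicated(["chrom", "pos"]).any():
            raise ValueError("causal locus collides with a neutral SNP position")
        return df

    def gene_defs(self) -> list[GeneDef]:
        """Single-SNP gene definitions matching the simulated causal loci."""
        defs = []
        for g, (c, p) in self.causal_loci.items():
            alt_code = CODE_OF_ALT.get(g, 0)
            sign = EFFECT_SIGN.get(g, +1)
            if g == "Hd1":
                labels = {0: "C", 1: "A"}  # alt tag = null Hap C, untagged = Hap A
            else:
                # haplotype labels by heading effect: active code-1 allele is
                # "L"(ate) for a +-sign gene and "E"(arly) for a --sign gene
                labels = {1: "L" if sign > 0 else "E", 0: "E" if sign > 0 else "L"}
            rules = [
                HaplotypeRule(labels[alt_code], {(c, p): 1.0}),
                HaplotypeRule(labels[1 - alt_code], {(c, p): 0.0}),
            ]
            defs.append(GeneDef(g, c, rules, {labels[0]: 0, labels[1]: 1}, sign))
        return defs


@dataclass
class EpistasisRule:
    """Multiply the target gene's effect by `multiplier` when the modifier gene
    carries `modifier_code`."""

    target: str
    modifier: str
    modifier_code: int
    multiplier: float


@dataclass
class EffectModel:
    """Additive-plus-epistatic genetic model for DTH (days)."""

    baseline_dth: float
    additive_effects: dict[str, float]
    epistasis_rules: list[EpistasisRule] = field(default_factory=list)
    year_offsets: dict[str, float] = field(default_factory=dict)
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        for r in self.epistasis_rules:
            if r.multiplier < 0:
                raise ValueError("epistasis multiplier must be >= 0")
            for g in (r.target, r.modifier):
                if g not in self.additive_effects:
                    raise ValueError(f"epistasis rule references gene {g!r} absent "
                                     "from additive_effects")

    def genetic_values(self, codes: pd.DataFrame) -> np.ndarray:
        """Vectorized noise-free genetic DTH for a line x gene code matrix."""
        missing = [g for g in self.additive_effects if g not in codes.columns]
        if missing:
            raise ValueError(f"missing activity code for gene(s): {missing}")
        total = np.full(len(codes), self.baseline_dth, dtype=float)
        for g, beta in self.additive_effects.items():
            m = np.ones(len(codes))
            for r in self.epistasis_rules:
                if r.target == g:
                    m = np.where(codes[r.modifier].to_numpy() == r.modifier_code,
                                 m * r.multiplier, m)
            total += beta * codes[g].to_numpy() * m
        return total


def phenotype_dth(codes: Mapping[str, int], model: EffectModel, year: str | None = None,
                  noise_seed: int | None = None) -> float:
    """DTH of one line: baseline + year offset + sum of gated additive effects + noise.

    ``noise_seed=None`` gives the exact noise-free value; otherwise residual
    noise ~ Normal(0, residual_sd^2) is drawn from the given seed.
    """
    for g in model.additive_effects:
        if g not in codes:
            raise ValueError(f"missing activity code for gene {g!r}")
        if codes[g] not in (0, 1):
            raise ValueError(f"code for {g!r} must be 0 or 1, got {codes[g]}")
    df = pd.DataFrame({g: [codes[g]] for g in model.additive_effects})
    dth = float(model.genetic_values(df)[0])
    if year is not None:
        if year not in model.year_offsets:
            raise KeyError(f"unknown year label {year!r}")
        dth += model.year_offsets[year]
    if noise_seed is not None:
        dth += float(np.random.default_rng(noise_seed).normal(0.0, model.residual_sd))
    return dth


@dataclass
class PeriodPlan:
    label: str
    n_lines: int
    selection_window: tuple[float, float]
    n_crosses: int
    n_progeny_per_cross: int

    def __post_init__(self) -> None:
        lo, hi = self.selection_window
        if not lo < hi:
            raise ValueError(f"period {self.label}: selection window min must be < max")
        if self.n_lines > self.n_crosses * self.n_progeny_per_cross:
            raise ValueError(f"period {self.label}: n_lines exceeds total progeny")


@dataclass
class BreedingPlan:
    periods: list[PeriodPlan]
    n_founders: int
    founder_code1_freq: dict[str, float]
    #: founder-generation code association: (gene_a, gene_b, phi) — gene_a's
    #: code is drawn conditionally on gene_b's so their phi matches the target
    #: (used for physically linked gene pairs whose LD predates the program)
    founder_ld: list[tuple[str, str, float]] = field(default_factory=list)
    neutral_freq_range: tuple[float, float] = (0.1, 0.9)
    cm_per_mb: float = 4.0
    seed: int = 0


@dataclass
class SimulatedPanel:
    """A simulated panel: genotypes + phenotypes + metadata + full ground truth."""

    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    metadata: pd.DataFrame
    truth: dict
    gene_defs: list[GeneDef] = field(repr=False, default_factory=list)

    @property
    def truth_codes(self) -> pd.DataFrame:
        return self.truth["codes"]

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_genotypes(self.genotypes, out / "genotypes.vcf")
        self.phenotypes.to_csv(out / "phenotypes.csv", index=False)
        self.metadata.to_csv(out / "metadata.csv", index=False)
        truth = dict(self.truth)
        truth["codes"] = truth["codes"].to_dict(orient="index")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, default=_json_default)
        with open(out / "gene_defs.yaml", "w") as fh:
            yaml.safe_dump(serialize_gene_defs(self.gene_defs), fh, sort_keys=False)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, EpistasisRule):
        return asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def serialize_gene_defs(defs: Sequence[GeneDef]) -> dict:
    doc = {"genes": []}
    for gd in defs:
        doc["genes"].append({
            "name": gd.name,
            "chromosome": gd.chromosome,
            "effect_sign": "+" if gd.effect_sign > 0 else "-",
            "haplotypes": [
                {"label": r.label,
                 "requires": {f"{c}:{p}": int(v) for (c, p), v in r.requires.items()}}
                for r in gd.rules
            ],
            "activity": dict(gd.activity),
        })
    return doc


# ---------------------------------------------------------------------------
# Defaults: the study conditions the simulator emulates

def default_genome_map(n_neutral_per_chrom: int = 25) -> GenomeMap:
    """12-chromosome map with evenly spaced neutral SNPs and the six default
    causal heading-date loci."""
    neutral = {}
    causal_pos = {(c, p) for c, p in CAUSAL_LOCI.values()}
    for c, length in enumerate(RICE_CHROM_LENGTHS, start=1):
        pos = np.linspace(1_000_000, length - 1_000_000, n_neutral_per_chrom).astype(int)
        pos = np.array([p + 1 if (c, int(p)) in causal_pos else int(p) for p in pos])
        neutral[c] = pos
    return GenomeMap(12, RICE_CHROM_LENGTHS, neutral, dict(CAUSAL_LOCI))


def default_effect_model(residual_sd: float = 2.5) -> EffectModel:
    """Default DTH model: additive effects sized to the observed haplotype-group
    mean differences, with the two epistatic gates — the early-heading promoter
    (Hd17) silenced under an active Hd16, and Hd18 amplified under an active
    Hd16."""
    return EffectModel(
        baseline_dth=63.0,
        additive_effects={"Hd1": 13.0, "Hd2": 0.0, "Hd6": 0.0,
                          "Hd16": 8.0, "Hd17": -7.0, "Hd18": -2.0},
        epistasis_rules=[
            EpistasisRule("Hd17", "Hd16", 1, 0.0),
            EpistasisRule("Hd18", "Hd16", 1, 2.5),
        ],
        year_offsets={"2019": 0.0, "2020": 2.0, "2021": 4.0},
        residual_sd=residual_sd,
    )


def default_breeding_plan(seed: int = 0) -> BreedingPlan:
    """Four-period plan (~250 lines) reproducing the co-selection history of the
    functional-Hd1 stratum: selection windows narrow toward the 70-80 d target,
    which jointly favours the inactive-Hd16 / low-activity-Hd17 combination."""
    periods = [
        PeriodPlan("I", 93, (65.0, 90.0), 60, 8),
        PeriodPlan("II", 55, (69.0, 80.0), 60, 8),
        PeriodPlan("III", 54, (70.0, 77.5), 60, 8),
        PeriodPlan("IV", 50, (71.5, 77.5), 60, 8),
    ]
    founder_freq = {"Hd1": 1.0, "Hd2": 0.9, "Hd6": 0.25,
                    "Hd16": 0.65, "Hd17": 0.55, "Hd18": 0.5}
    # Hd6 sits ~1.5 Mb from Hd16 on chromosome 3; their LD predates the
    # program and persists through breeding, making the effect-free Hd6 the
    # panel's built-in false-positive (Type I) candidate.
    return BreedingPlan(periods, n_founders=80, founder_code1_freq=founder_freq,
                        founder_ld=[("Hd6", "Hd16", 0.3)], seed=seed)


# ---------------------------------------------------------------------------
# Simulation machinery

def _codes_from_calls(calls: np.ndarray, variants: pd.DataFrame,
                      causal: Mapping[str, tuple[int, int]]) -> pd.DataFrame:
    """Derive per-gene activity codes from dosages at the causal loci."""
    cols = {}
    for g in causal:
        j = variants.index[variants["gene"] == g]
        if len(j) != 1:
            raise ValueError(f"causal locus {g} not uniquely present in variant table")
        dos = calls[:, int(j[0])]
        cols[g] = dos if CODE_OF_ALT.get(g, 0) == 1 else 1.0 - dos
    return pd.DataFrame(cols)


def simulate_founders(plan: BreedingPlan, gmap: GenomeMap,
                      rng: np.random.Generator) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw fully inbred founders, each variant independent at its founder
    frequency; returns (calls array, variant table with alt_freq column)."""
    variants = gmap.variants()
    freqs = np.empty(len(variants))
    lo, hi = plan.neutral_freq_range
    if not (0 <= lo <= hi <= 1):
        raise ValueError("neutral founder frequency range must lie in [0, 1]")
    for i, row in variants.iterrows():
        g = row["gene"]
        if g is None:
            freqs[i] = rng.uniform(lo, hi)
        else:
            f1 = plan.founder_code1_freq.get(g, 0.5)
            if not 0 <= f1 <= 1:
                raise ValueError(f"founder frequency for {g} outside [0, 1]: {f1}")
            freqs[i] = 1.0 - f1 if CODE_OF_ALT.get(g, 0) == 0 else f1
    calls = (rng.random((plan.n_founders, len(variants))) < freqs).astype(float)
    for ga, gb, phi in plan.founder_ld:
        ja = variants.index[variants["gene"] == ga]
        jb = variants.index[variants["gene"] == gb]
        if len(ja) != 1 or len(jb) != 1:
            raise ValueError(f"founder_ld genes {ga}/{gb} not in causal loci")
        fa = plan.founder_code1_freq.get(ga, 0.5)
        fb = plan.founder_code1_freq.get(gb, 0.5)
        cov = phi * np.sqrt(fa * (1 - fa) * fb * (1 - fb))
        p_given_1 = np.clip(fa + cov / fb, 0.0, 1.0) if fb > 0 else fa
        p_given_0 = np.clip(fa - cov / (1 - fb), 0.0, 1.0) if fb < 1 else fa
        code_b = calls[:, int(jb[0])]
        if CODE_OF_ALT.get(gb, 0) == 0:
            code_b = 1.0 - code_b
        p_code_a = np.where(code_b == 1, p_given_1, p_given_0)
        code_a = (rng.random(plan.n_founders) < p_code_a).astype(float)
        calls[:, int(ja[0])] = code_a if CODE_OF_ALT.get(ga, 0) == 1 else 1.0 - code_a
    variants = variants.assign(alt_freq=freqs)
    return calls, variants


def _make_gametes(p1: np.ndarray, p2: np.ndarray, variants: pd.DataFrame,
                  gmap: GenomeMap, cm_per_mb: float, rng: np.random.Generator,
                  n_gametes: int) -> np.ndarray:
    """Recombinant gametes from a biparental cross of two inbred parents.

    Crossover counts per chromosome are Poisson with mean = map length in
    Morgans (Haldane, no interference); positions uniform; start phase random.
    """
    out = np.empty((n_gametes, len(variants)))
    chrom_arr = variants["chrom"].to_numpy()
    pos_arr = variants["pos"].to_numpy()
    for c in range(1, gmap.n_chromosomes + 1):
        mask = chrom_arr == c
        if not mask.any():
            continue
        cpos = pos_arr[mask]
        morgans = gmap.chrom_lengths[c - 1] / 1e6 * cm_per_mb / 100.0
        for k in range(n_gametes):
            n_xo = rng.poisson(morgans) if morgans > 0 else 0
            start = rng.integers(2)
            if n_xo == 0:
                source = np.full(cpos.shape, start)
            else:
                xo = np.sort(rng.uniform(0, gmap.chrom_lengths[c - 1], n_xo))
                source = (start + np.searchsorted(xo, cpos)) % 2
            out[k, mask] = np.where(source == 0, p1[mask], p2[mask])
    return out


def breed_period(parent_calls: np.ndarray, period: PeriodPlan, gmap: GenomeMap,
                 model: EffectModel, rng: np.random.Generator,
                 variants: pd.DataFrame, cm_per_mb: float = 4.0) -> np.ndarray:
    """One breeding cycle: random biparental crosses among the parents, inbred
    progeny by gamete doubling, DTH phenotyping, and window truncation
    selection topped up with the nearest-to-window progeny; returns exactly
    ``period.n_lines`` progeny genotypes."""
    if parent_calls.shape[0] < 2:
        raise ValueError("breed_period needs at least 2 parents")
    progeny = []
    for _ in range(period.n_crosses):
        i, j = rng.choice(parent_calls.shape[0], size=2, replace=False)
        progeny.append(_make_gametes(parent_calls[i], parent_calls[j], variants,
                                     gmap, cm_per_mb, rng, period.n_progeny_per_cross))
    calls = np.vstack(progeny)
    codes = _codes_from_calls(calls, variants, gmap.causal_loci)
    dth = model.genetic_values(codes) + rng.normal(0.0, model.residual_sd, len(calls))
    lo, hi = period.selection_window
    inside = (dth >= lo) & (dth <= hi)
    idx_inside = np.flatnonzero(inside)
    if idx_inside.size >= period.n_lines:
        keep = rng.choice(idx_inside, size=period.n_lines, replace=False)
    else:
        dist = np.maximum.reduce([lo - dth, dth - hi, np.zeros_like(dth)])
        keep = np.argsort(dist, kind="stable")[: period.n_lines]
    return calls[np.sort(keep)]


def simulate_panel(plan: BreedingPlan, gmap: GenomeMap, model: EffectModel,
                   seed: int | None = None) -> SimulatedPanel:
    """Run the full multi-period breeding simulation.

    Deterministic under (plan, map, model, seed); per-period RNG streams are
    derived from the root seed by fixed offsets so that adding a period does
    not perturb earlier ones.
    """
    root = plan.seed if seed is None else seed
    rng_founder = np.random.default_rng([root, 0])
    parent_calls, variants = simulate_founders(plan, gmap, rng_founder)

    all_calls, labels = [], []
    period_freqs: dict[str, dict[str, float]] = {}
    for i, period in enumerate(plan.periods):
        rng_p = np.random.default_rng([root, 100 + i])
        selected = breed_period(parent_calls, period, gmap, model, rng_p,
                                variants, plan.cm_per_mb)
        all_calls.append(selected)
        labels.extend([period.label] * selected.shape[0])
        codes = _codes_from_calls(selected, variants, gmap.causal_loci)
        period_freqs[period.label] = {g: float(codes[g].mean()) for g in codes.columns}
        parent_calls = selected

    calls = np.vstack(all_calls)
    n = calls.shape[0]
    line_ids = [f"SIM{i + 1:04d}" for i in range(n)]
    ref = np.where(variants["gene"].isna(), "A", "G").astype(object)
    alt = np.where(variants["gene"].isna(), "T", "A").astype(object)
    G = GenotypeMatrix(line_ids, variants["chrom"].to_numpy(), variants["pos"].to_numpy(),
                       ref, alt, calls)

    codes = _codes_from_calls(calls, variants, gmap.causal_loci)
    codes.index = line_ids

    meta_rows = []
    k = 0
    for period in plan.periods:
        y0, y1 = PERIOD_YEARS.get(period.label, (0, 0))
        for j in range(period.n_lines):
            year = y0 + int(round(j * (y1 - y0) / max(period.n_lines - 1, 1)))
            hd1 = codes["Hd1"].iloc[k] if "Hd1" in codes.columns else 1.0
            meta_rows.append((line_ids[k], period.label, year,
                              "early" if hd1 == 0 else "late"))
            k += 1
    metadata = pd.DataFrame(meta_rows, columns=["line", "period", "year_established",
                                                "heading_class"])

    rng_ph = np.random.default_rng([root, 999])
    pheno_rows = []
    genetic = model.genetic_values(codes)
    years = list(model.year_offsets) or [None]
    for year in years:
        offset = model.year_offsets.get(year, 0.0) if year is not None else 0.0
        noise = rng_ph.normal(0.0, model.residual_sd, n)
        for i in range(n):
            pheno_rows.append((line_ids[i], year if year is not None else "0",
                               genetic[i] + offset + noise[i]))
    phenotypes = pd.DataFrame(pheno_rows, columns=["line", "year", "dth"])

    truth = {
        "codes": codes,
        "model": {
            "baseline_dth": model.baseline_dth,
            "additive_effects": dict(model.additive_effects),
            "epistasis_rules": [asdict(r) for r in model.epistasis_rules],
            "year_offsets": dict(model.year_offsets),
            "residual_sd": model.residual_sd,
        },
        "period_code1_freq": period_freqs,
        "founder_code1_freq": dict(plan.founder_code1_freq),
        "seed": root,
    }
    return SimulatedPanel(G, phenotypes, metadata, truth, gmap.gene_defs())


# ---------------------------------------------------------------------------
# Direct scenario generators (planted-confounding panels)

def sample_coded_panel(n_lines: int = 150, phi: float = 0.4,
                       beta_confounder: float = 8.0, beta_masked: float = -7.0,
                       n_null: int = 4, baseline: float = 63.0,
                       residual_sd: float = 2.5, seed: int = 0,
                       ) -> tuple[pd.DataFrame, pd.Series, pd.Series, dict]:
    """Coded panel with a planted masked effect.

    The confounder gene (think: an active long-day repressor, +days) and the
    masked gene (an early-heading promoter, -days, epistatically silenced when
    the confounder is active) have binary activity codes correlated at the
    target phi — the summary of breeding co-selection.  Null genes are
    independent Bernoulli(0.5) with zero effect.  Returns
    (codes, dth, expected_signs, truth).
    """
    if not 0 <= phi <= 1:
        raise ValueError("phi must be in [0, 1]")
    rng = np.random.default_rng(seed)
    conf = (rng.random(n_lines) < 0.5).astype(float)
    # P(masked=1 | conf) = 0.5 +/- phi/2 gives Pearson phi exactly at 0.5 margins
    p_m = np.where(conf == 1, 0.5 + phi / 2, 0.5 - phi / 2)
    masked = (rng.random(n_lines) < p_m).astype(float)
    codes = {"confounder": conf, "masked": masked}
    for i in range(n_null):
        codes[f"null{i + 1}"] = (rng.random(n_lines) < 0.5).astype(float)
    codes_df = pd.DataFrame(codes, index=[f"L{i + 1:03d}" for i in range(n_lines)])
    gated = masked * (conf == 0)  # masked effect expressed only on inactive-confounder background
    dth = baseline + beta_confounder * conf + beta_masked * gated \
        + rng.normal(0.0, residual_sd, n_lines)
    dth = pd.Series(dth, index=codes_df.index, name="dth")
    signs = pd.Series({"confounder": +1, "masked": -1,
                       **{f"null{i + 1}": +1 for i in range(n_null)}})
    truth = {"beta": {"confounder": beta_confounder, "masked": beta_masked},
             "phi_target": phi, "gated_by": "confounder==0"}
    return codes_df, dth, signs, truth


def simulate_ld_panel(n_lines: int = 600, phi: float = 0.4, beta_causal: float = 8.0,
                      n_neutral_per_chrom: int = 400, residual_sd: float = 2.5,
                      seed: int = 0) -> tuple[GenotypeMatrix, pd.Series, dict]:
    """Genome-wide panel with a causal locus and an unlinked hitchhiker.

    The causal locus (chromosome 3) carries the full effect; the hitchhiker
    (chromosome 6) has zero effect but its dosage is correlated with the
    causal dosage at the target phi, mimicking co-selection LD across
    chromosomes.  Neutral SNPs are independent and numerous: the kinship in a
    densely genotyped panel must not be dominated by any single locus,
    otherwise the mixed model itself soaks up the planted single-direction
    confounding (proximal contamination) and no spurious peak forms in the
    first place.  Returns (genotypes, dth, truth with locus coordinates).
    """
    rng = np.random.default_rng(seed)
    gmap = default_genome_map(n_neutral_per_chrom)
    causal = ("Hd16", *CAUSAL_LOCI["Hd16"])
    hitch = ("Hd17", *CAUSAL_LOCI["Hd17"])
    variants = gmap.variants()
    n_var = len(variants)
    calls = (rng.random((n_lines, n_var)) < rng.uniform(0.1, 0.9, n_var)).astype(float)
    a = (rng.random(n_lines) < 0.5).astype(float)
    p_b = np.where(a == 1, 0.5 + phi / 2, 0.5 - phi / 2)
    b = (rng.random(n_lines) < p_b).astype(float)
    ja = variants.index[(variants["chrom"] == causal[1]) & (variants["pos"] == causal[2])][0]
    jb = variants.index[(variants["chrom"] == hitch[1]) & (variants["pos"] == hitch[2])][0]
    calls[:, int(ja)] = a
    calls[:, int(jb)] = b
    # remaining causal-gene positions stay neutral here; zero out their effect context
    line_ids = [f"L{i + 1:03d}" for i in range(n_lines)]
    ref = np.full(n_var, "A", dtype=object)
    alt = np.full(n_var, "T", dtype=object)
    G = GenotypeMatrix(line_ids, variants["chrom"].to_numpy(), variants["pos"].to_numpy(),
                       ref, alt, calls)
    y = 63.0 + beta_causal * a + rng.normal(0.0, residual_sd, n_lines)
    dth = pd.Series(y, index=line_ids, name="dth")
    truth = {"causal": {"chrom": causal[1], "pos": causal[2], "beta": beta_causal},
             "hitchhiker": {"chrom": hitch[1], "pos": hitch[2], "beta": 0.0},
             "phi_target": phi}
    return G, dth, truth
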