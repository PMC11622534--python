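"""Genotype/phenotype I/O, variant filtering, and heading-gene haplotype calling.

The panel is a set of fully inbred lines, so genotypes are stored as
alt-allele dosages in {0, 1}; heterozygous diploid calls (which should not
occur in a fixed line and usually flag a genotyping artifact) are treated as
missing by default. Coordinates are 1-based VCF convention throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GenotypeMatrix",
    "GeneDef",
    "HaplotypeRule",
    "HaplotypeTable",
    "read_genotypes",
    "write_genotypes",
    "filter_variants",
    "call_haplotypes",
    "code_activity",
    "read_phenotypes",
    "read_metadata",
    "load_gene_defs",
    "default_gene_defs",
]

#: Breeding-period labels and their establishment-year ranges at the station.
PERIOD_YEARS = {"I": (1949, 1969), "II": (1970, 1992), "III": (1993, 2005), "IV": (2006, 2019)}


@dataclass
class GenotypeMatrix:
    """Lines x biallelic variants, alt dosage in {0, 1, missing(NaN)}.

    Variants are kept sorted by (chromosome, position) with no duplicates;
    ``calls`` has shape (n_lines, n_variants) as float64 with NaN for missing.
    """

    line_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=int)
        self.pos = np.asarray(self.pos, dtype=int)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.line_ids), len(self.pos)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.line_ids)} lines x {len(self.pos)} variants"
            )
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(len(order))):
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.ref = self.ref[order]
            self.alt = self.alt[order]
            self.calls = self.calls[:, order]
        key = self.chrom.astype(np.int64) * 10**10 + self.pos
        if len(np.unique(key)) != len(key):
            raise ValueError("duplicate (chromosome, position) in variant set")
        valid = np.isnan(self.calls) | (self.calls == 0.0) | (self.calls == 1.0) | (self.calls == 0.5)
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 0.5 (het midpoint) or missing")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    def variant_index(self, chrom: int, pos: int) -> int:
        """Index of the variant at (chrom, pos); raises KeyError if absent."""
        hits = np.flatnonzero((self.chrom == chrom) & (self.pos == pos))
        if hits.size == 0:
            raise KeyError(f"variant {chrom}:{pos} not in matrix")
        return int(hits[0])

    def alt_freq(self) -> np.ndarray:
        """Alt-allele frequency per variant over non-missing calls (NaN if all missing)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.calls, axis=0)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.calls).mean(axis=0)

    def subset_lines(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.line_ids.index(l) for l in keep]
        return GenotypeMatrix(list(keep), self.chrom.copy(), self.pos.copy(),
                              self.ref.copy(), self.alt.copy(), self.calls[idx, :].copy())

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.line_ids), self.chrom[mask], self.pos[mask],
                              self.ref[mask], self.alt[mask], self.calls[:, mask].copy())

    def imputed(self) -> np.ndarray:
        """Calls with missing entries replaced by the per-variant mean dosage."""
        X = self.calls.copy()
        p = self.alt_freq()
        p = np.where(np.isnan(p), 0.0, p)
        nan = np.isnan(X)
        X[nan] = np.broadcast_to(p, X.shape)[nan]
        return X


def read_genotypes(vcf_path: str | Path, het_policy: str = "missing") -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Homozygous ref -> 0, homozygous alt -> 1, heterozygous -> missing (or 0.5
    with ``het_policy='half'``), no-call -> missing. Multiallelic records and
    non-SNP records are skipped with a count reported via warning. An unsorted
    VCF is an error.
    """
    from cyvcf2 import VCF

    if het_policy not in ("missing", "half"):
        raise ValueError("het_policy must be 'missing' or 'half'")
    vcf = VCF(str(vcf_path), gts012=True)
    line_ids = list(vcf.samples)
    chroms, poss, refs, alts, rows = [], [], [], [], []
    n_skipped = 0
    last = (-1, -1)
    for v in vcf:
        c = _parse_chrom(v.CHROM)
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        if (c, v.POS) < last:
            raise ValueError(f"VCF not sorted at {v.CHROM}:{v.POS}")
        last = (c, v.POS)
        gt = np.asarray(v.gt_types, dtype=float)  # 0 HOM_REF, 1 HET, 2 HOM_ALT, 3 UNKNOWN
        dos = np.full(gt.shape, np.nan)
        dos[gt == 0] = 0.0
        dos[gt == 2] = 1.0
        if het_policy == "half":
            dos[gt == 1] = 0.5
        chroms.append(c)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        rows.append(dos)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-biallelic-SNP records", stacklevel=2)
    if not rows:
        raise ValueError(f"no biallelic SNP records in {vcf_path}")
    calls = np.column_stack(rows)
    return GenotypeMatrix(line_ids, np.array(chroms), np.array(poss),
                          np.array(refs, dtype=object), np.array(alts, dtype=object), calls)


def _parse_chrom(name: str) -> int:
    s = str(name)
    for prefix in ("chr", "Chr", "CHR"):
        if s.startswith(prefix):
            s = s[len(prefix):]
    try:
        return int(s)
    except ValueError as e:
        raise ValueError(f"non-numeric chromosome id {name!r}") from e


def write_genotypes(G: GenotypeMatrix, vcf_path: str | Path) -> None:
    """Write a minimal VCF v4.2; inbred dosages emitted as homozygous diploid GT."""
    path = Path(vcf_path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=breedscan\n")
        for c in sorted(set(int(x) for x in G.chrom)):
            length = int(G.pos[G.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(G.line_ids) + "\n")
        for j in range(G.n_variants):
            gts = []
            for d in G.calls[:, j]:
                if np.isnan(d):
                    gts.append("./.")
                elif d == 1.0:
                    gts.append("1/1")
                elif d == 0.0:
                    gts.append("0/0")
                else:
                    gts.append("0/1")
            fh.write(f"{G.chrom[j]}\t{G.pos[j]}\t.\t{G.ref[j]}\t{G.alt[j]}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def filter_variants(G: GenotypeMatrix, maf_min: float = 0.05, missing_max: float = 0.10) -> GenotypeMatrix:
    """Apply the panel's variant QC rule.

    A variant is retained when MAF >= ``maf_min`` (computed over non-missing
    calls) AND its missing fraction < ``missing_max``; i.e. MAF below 5% or
    missingness at/above 10% are removed, the boundary semantics read
    literally from the filtering rule. Variants with all calls missing are
    removed and counted.
    """
    maf = G.maf()
    miss = G.missing_rate()
    all_missing = np.isnan(maf)
    keep = (~all_missing) & (maf >= maf_min - 1e-12) & (miss < missing_max - 1e-12)
    n_maf = int(np.sum(~keep & ~all_missing & (maf < maf_min - 1e-12)))
    n_miss = int(np.sum(~keep & (miss >= missing_max - 1e-12)))
    if G.n_variants - int(keep.sum()):
        warnings.warn(
            f"filtered {G.n_variants - int(keep.sum())} of {G.n_variants} variants "
            f"(low MAF: {n_maf}, high missingness: {n_miss}, all-missing: {int(all_missing.sum())})",
            stacklevel=2,
        )
    return G.subset_variants(keep)


# ---------------------------------------------------------------------------
# Heading-gene haplotype definitions and calling


@dataclass
class HaplotypeRule:
    """One haplotype, defined by required alt-dosages at defining positions."""

    label: str
    requires: dict[tuple[int, int], float]  # (chrom, pos) -> required dosage


@dataclass
class GeneDef:
    """A heading-date gene: ordered haplotype rules, activity coding, DTH sign.

    ``effect_sign`` is +1 when the higher-activity (code 1) haplotype delays
    heading (expected positive correlation with days-to-heading) and -1 when
    it promotes early heading.
    """

    name: str
    chromosome: int
    rules: list[HaplotypeRule]
    activity: dict[str, int]
    effect_sign: int

    def __post_init__(self) -> None:
        labels = {r.label for r in self.rules}
        if labels != set(self.activity):
            raise ValueError(f"{self.name}: haplotype rules {labels} and activity map "
                             f"{set(self.activity)} must cover the same labels")
        if any(c not in (0, 1) for c in self.activity.values()):
            raise ValueError(f"{self.name}: activity codes must be 0/1")
        if self.effect_sign not in (+1, -1):
            raise ValueError(f"{self.name}: effect_sign must be +1 or -1")

    @property
    def defining_positions(self) -> list[tuple[int, int]]:
        seen: dict[tuple[int, int], None] = {}
        for r in self.rules:
            for key in r.requires:
                seen.setdefault(key, None)
        return list(seen)


@dataclass
class HaplotypeTable:
    """Per line x gene haplotype label and 0/1 activity code (NaN = missing)."""

    labels: pd.DataFrame  # line x gene, object dtype, None for missing
    codes: pd.DataFrame   # line x gene, float, NaN for missing
    gene_defs: list[GeneDef] = field(repr=False, default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.labels.columns)


def call_haplotypes(G: GenotypeMatrix, defs: Sequence[GeneDef]) -> HaplotypeTable:
    """Call per-line haplotypes of each gene from its defining polymorphisms.

    Rules are matched in their stated order and the first full match wins; a
    missing call at any defining position makes the haplotype missing. A gene
    whose defining position is absent from ``G`` is an error (haplotype
    calling is meant to run on the pre-filter matrix).
    """
    lab = {}
    cod = {}
    for gd in defs:
        idx = {}
        for (c, p) in gd.defining_positions:
            try:
                idx[(c, p)] = G.variant_index(c, p)
            except KeyError:
                raise KeyError(f"gene {gd.name}: defining position {c}:{p} absent from genotype matrix")
        labels = np.full(G.n_lines, None, dtype=object)
        codes = np.full(G.n_lines, np.nan)
        n_unmatched = 0
        for i in range(G.n_lines):
            row_missing = any(np.isnan(G.calls[i, idx[k]]) for k in idx)
            if row_missing:
                continue
            for rule in gd.rules:
                if all(G.calls[i, idx[k]] == v for k, v in rule.requires.items()):
                    labels[i] = rule.label
                    codes[i] = gd.activity[rule.label]
                    break
            else:
                n_unmatched += 1
        if n_unmatched:
            warnings.warn(f"gene {gd.name}: {n_unmatched} lines matched no haplotype rule",
                          stacklevel=2)
        lab[gd.name] = labels
        cod[gd.name] = codes
    labels_df = pd.DataFrame(lab, index=list(G.line_ids))
    codes_df = pd.DataFrame(cod, index=list(G.line_ids))
    return HaplotypeTable(labels_df, codes_df, list(defs))


def code_activity(H: HaplotypeTable) -> tuple[pd.DataFrame, pd.Series]:
    """Numeric line x gene 0/1 activity matrix plus expected-DTH-sign vector.

    Codes follow the convention 0 = lower activity, 1 = higher activity, so a
    gene whose active haplotype delays heading carries sign +1 and one whose
    active haplotype promotes early heading carries sign -1. All-missing gene
    columns are dropped with a warning.
    """
    codes = H.codes.copy()
    signs = pd.Series({gd.name: gd.effect_sign for gd in H.gene_defs})
    empty = [g for g in codes.columns if codes[g].isna().all()]
    if empty:
        warnings.warn(f"dropping all-missing gene columns: {empty}", stacklevel=2)
        codes = codes.drop(columns=empty)
        signs = signs.drop(index=[g for g in empty if g in signs.index])
    return codes, signs.reindex(codes.columns)


# ---------------------------------------------------------------------------
# Gene-definition file handling

def load_gene_defs(path: str | Path) -> list[GeneDef]:
    """Load gene definitions from YAML (see data/heading_genes.yaml for schema)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _parse_gene_defs(doc)


def default_gene_defs() -> list[GeneDef]:
    """The six heading-date genes (Hd1, Hd2, Hd6, Hd16, Hd17, Hd18) shipped with the package."""
    text = resources.files("breedscan.data").joinpath("heading_genes.yaml").read_text()
    return _parse_gene_defs(yaml.safe_load(text))


def _parse_gene_defs(doc: Mapping) -> list[GeneDef]:
    defs = []
    for g in doc["genes"]:
        rules = []
        for h in g["haplotypes"]:
            req = {}
            for key, dosage in (h.get("requires") or {}).items():
                c, p = str(key).split(":")
                req[(int(c), int(p))] = float(dosage)
            rules.append(HaplotypeRule(h["label"], req))
        sign = +1 if str(g["effect_sign"]) in ("+", "+1", "1") else -1
        defs.append(GeneDef(g["name"], int(g["chromosome"]), rules,
                            {k: int(v) for k, v in g["activity"].items()}, sign))
    return defs


# ---------------------------------------------------------------------------
# Phenotype and metadata tables

def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype table (line, year, dth[, traits...]); validates DTH > 0
    and uniqueness of (line, year)."""
    df = pd.read_csv(path, dtype={"line": str, "year": str})
    return validate_phenotypes(df)


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    required = {"line", "year", "dth"}
    if not required.issubset(df.columns):
        raise ValueError(f"phenotype table needs columns {sorted(required)}, got {list(df.columns)}")
    if (df["dth"] <= 0).any():
        raise ValueError("DTH must be positive")
    if df.duplicated(["line", "year"]).any():
        raise ValueError("duplicate (line, year) phenotype records")
    df = df.copy()
    df["year"] = df["year"].astype(str)
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read line metadata (line, period, year_established, heading_class)."""
    df = pd.read_csv(path, dtype={"line": str, "period": str})
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    required = {"line", "period"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata needs columns {sorted(required)}, got {list(df.columns)}")
    bad = set(df["period"]) - set(PERIOD_YEARS)
    if bad:
        raise ValueError(f"unknown breeding periods {sorted(bad)}; expected {list(PERIOD_YEARS)}")
    if "year_established" in df.columns:
        for _, row in df.iterrows():
            lo, hi = PERIOD_YEARS[row["period"]]
            if not (lo <= int(row["year_established"]) <= hi):
                raise ValueError(
                    f"line {row['line']}: year {row['year_established']} outside period "
                    f"{row['period']} range {lo}-{hi}")
    if "heading_class" in df.columns:
        bad_cls = set(df["heading_class"].dropna()) - {"early", "late"}
        if bad_cls:
            raise ValueError(f"heading_class must be early/late, got {sorted(bad_cls)}")
    return df
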