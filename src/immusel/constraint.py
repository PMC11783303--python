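"""Within-species selective constraint: degeneracy-based pN/pS with the
variant-filter cascade and coverage-based masking.

Coordinates are 0-based half-open internally; VCF-style 1-based positions
are converted on read. BED intervals keep their native convention.

pN/pS here is the ratio of nonsynonymous to synonymous polymorphism rates,
each normalized by its mutational opportunity (site counts from fold
degeneracy). A pseudo-count of one synonymous variant — p(S+1) — keeps the
ratio finite for genes without synonymous polymorphism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genetics as G

log = logging.getLogger(__name__)


# ------------------------------------------------------------- degeneracy
@dataclass
class DegeneracyProfile:
    """Counts of 0-/2-/3-/4-fold degenerate coding positions plus the
    synonymous/nonsynonymous site totals they imply."""

    f0: float
    f2: float
    f3: float
    f4: float
    folds: np.ndarray | None = None  # per-position fold (1, 2, 3, 4; -1 skipped)

    @property
    def S_sites(self) -> float:
        return count_sites(self)[0]

    @property
    def N_sites(self) -> float:
        return count_sites(self)[1]


def classify_degeneracy(cds_sequence: str) -> DegeneracyProfile:
    """Per-position fold degeneracy of a coding sequence.

    A position is x-fold degenerate when exactly x of the four nucleotides
    there (including the reference) encode the same amino acid. A final
    stop codon is allowed and excluded from counting; an internal stop is
    an error. Positions in codons with ambiguous bases are skipped (fold
    -1) and logged.
    """
    cds = cds_sequence.upper()
    if len(cds) % 3 != 0 or len(cds) == 0:
        raise ValueError("CDS length must be a positive multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons[-1] in G.STOP_CODONS:
        codons = codons[:-1]
    folds = np.full(3 * len(codons), -1, dtype=np.int8)
    counts = {1: 0, 2: 0, 3: 0, 4: 0}
    for ci, codon in enumerate(codons):
        if codon in G.STOP_CODONS:
            raise ValueError(f"internal stop codon at codon {ci}")
        if any(ch not in "ACGT" for ch in codon):
            log.debug("skipping codon %d with ambiguous base: %s", ci, codon)
            continue
        aa = G.translate_codon(codon)
        for pos in range(3):
            x = 0
            for nt in "ACGT":
                mut = codon[:pos] + nt + codon[pos + 1 :]
                if mut not in G.STOP_CODONS and G.translate_codon(mut) == aa:
                    x += 1
            folds[3 * ci + pos] = x
            counts[x] += 1
    return DegeneracyProfile(
        f0=counts[1], f2=counts[2], f3=counts[3], f4=counts[4], folds=folds
    )


def count_sites(profile: DegeneracyProfile) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts from fold-degeneracy counts:

        S = 0*f0 + 1/3*f2 + 2/3*f3 + 1*f4
        N = 1*f0 + 2/3*f2 + 1/3*f3 + 0*f4
    """
    S = profile.f2 / 3.0 + 2.0 * profile.f3 / 3.0 + profile.f4
    N = profile.f0 + 2.0 * profile.f2 / 3.0 + profile.f3 / 3.0
    return S, N


# ------------------------------------------------------------ SNP classing
def classify_snp(
    cds: str, cds_pos: int, ref: str, alt: str, strand: str = "+"
) -> str | None:
    """Classify a SNP inside a CDS as synonymous or nonsynonymous.

    ``cds_pos`` is 0-based within the coding sequence (which is given in
    its own 5'->3' orientation); for minus-strand genes the genome-strand
    alleles are complemented first. Stop-gain/loss counts as
    nonsynonymous. Returns None (logged) when the codon holds an ambiguous
    base.
    """
    cds = cds.upper()
    ref, alt = ref.upper(), alt.upper()
    if strand == "-":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        ref, alt = comp[ref], comp[alt]
    if not 0 <= cds_pos < len(cds):
        raise ValueError("SNP does not map into the CDS")
    ci, pos = divmod(cds_pos, 3)
    codon = cds[3 * ci : 3 * ci + 3]
    if any(ch not in "ACGT" for ch in codon):
        log.debug("SNP in codon with ambiguous base skipped: %s", codon)
        return None
    if codon[pos] != ref:
        raise ValueError(
            f"reference allele {ref} does not match CDS base {codon[pos]}"
        )
    mut = codon[:pos] + alt + codon[pos + 1 :]
    ref_aa = G.translate_codon(codon)
    alt_aa = G.translate_codon(mut)
    return "synonymous" if ref_aa == alt_aa else "nonsynonymous"


# ------------------------------------------------------------ site filters
@dataclass
class FilterThresholds:
    min_qual: float = 30.0
    min_saf: int = 0  # SAF > 0
    min_sar: int = 0
    min_rpl: int = 1  # RPL > 1
    min_rpr: int = 1
    allele_balance: tuple[float, float] = (0.3, 0.7)
    hwe_excess_het_p: float = 1e-4
    max_missing: int = 5  # fewer than this many missing genotypes


def hwe_excess_het_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-sided exact Hardy-Weinberg test for heterozygote excess:
    P(het >= observed) under the Levene-Haldane distribution."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    # enumerate heterozygote counts with the parity of n_rare
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logp = np.zeros(len(hets))
    from scipy.special import gammaln

    for i, h in enumerate(hets):
        hom_r = (n_rare - h) // 2
        hom_c = n - hom_r - h
        logp[i] = (
            gammaln(n + 1)
            - gammaln(hom_r + 1)
            - gammaln(hom_c + 1)
            - gammaln(h + 1)
            + h * np.log(2)
            + gammaln(n_rare + 1)
            + gammaln(2 * n - n_rare + 1)
            - gammaln(2 * n + 1)
        )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = n_het
    return float(p[hets >= obs].sum())


def _geno_counts(genotypes: np.ndarray) -> tuple[int, int, int, int]:
    g = np.asarray(genotypes)
    missing = int(np.sum(g < 0))
    return (
        int(np.sum(g == 0)),
        int(np.sum(g == 1)),
        int(np.sum(g == 2)),
        missing,
    )


def site_filters(
    variants: pd.DataFrame, thresholds: FilterThresholds | None = None
) -> pd.DataFrame:
    """Apply the site-level filter cascade: biallelic SNPs with QUAL > 30,
    strand support on both strands (SAF > 0, SAR > 0), read-position
    support (RPL > 1, RPR > 1), allele balance in [0.3, 0.7],
    heterozygote-excess HWE p > 1e-4, and fewer than ``max_missing``
    missing genotypes. Records missing a required annotation are dropped
    with a logged reason."""
    th = thresholds or FilterThresholds()
    if variants.empty:
        return variants.copy()
    required = ["qual", "SAF", "SAR", "RPL", "RPR", "allele_balance", "genotypes"]
    missing_cols = [c for c in required if c not in variants.columns]
    if missing_cols:
        log.warning("all records dropped: missing annotations %s", missing_cols)
        return variants.iloc[0:0].copy()
    df = variants
    annotated = np.ones(len(df), dtype=bool)
    for c in required[:-1]:
        annotated &= pd.notna(df[c]).values
    annotated &= np.array([g is not None for g in df["genotypes"]])
    n_unannot = int((~annotated).sum())
    if n_unannot:
        log.debug("%d records dropped: missing annotation", n_unannot)
    keep = annotated.copy()
    if "biallelic_snp" in df.columns:
        keep &= df["biallelic_snp"].fillna(False).astype(bool).values
    with np.errstate(invalid="ignore"):
        keep &= (
            (df["qual"].values > th.min_qual)
            & (df["SAF"].values > th.min_saf)
            & (df["SAR"].values > th.min_sar)
            & (df["RPL"].values > th.min_rpl)
            & (df["RPR"].values > th.min_rpr)
            & (df["allele_balance"].values >= th.allele_balance[0])
            & (df["allele_balance"].values <= th.allele_balance[1])
        )
    hwe_cache: dict[tuple[int, int, int], float] = {}
    for i in np.flatnonzero(keep):
        hom_r, het, hom_a, missing = _geno_counts(df["genotypes"].iloc[i])
        if missing >= th.max_missing:
            keep[i] = False
            continue
        key = (hom_r, het, hom_a)
        p = hwe_cache.get(key)
        if p is None:
            p = hwe_excess_het_pvalue(*key)
            hwe_cache[key] = p
        if p <= th.hwe_excess_het_p:
            keep[i] = False
    return variants.loc[keep].copy()


def maf_filter(variants: pd.DataFrame, maf_threshold: float) -> pd.DataFrame:
    """Retain variants with minor-allele frequency >= threshold among
    non-missing alleles."""
    if maf_threshold <= 0:
        return variants.copy()
    keep = np.zeros(len(variants), dtype=bool)
    for i, geno in enumerate(variants["genotypes"]):
        g = np.asarray(geno)
        g = g[g >= 0]
        n_alleles = 2 * len(g)
        if n_alleles == 0:
            continue
        alt = g.sum()
        keep[i] = min(alt, n_alleles - alt) / n_alleles >= maf_threshold
    return variants.loc[keep].copy()


def subtract_repeats(
    variants: pd.DataFrame, repeat_bed: pd.DataFrame
) -> pd.DataFrame:
    """Drop SNPs whose (0-based) position lies in any repeat interval.
    Intervals are half-open 0-based BED rows (scaffold, start, end)."""
    if len(repeat_bed) and np.any(
        repeat_bed["end"].values < repeat_bed["start"].values
    ):
        raise ValueError("malformed repeat interval (end < start)")
    keep = np.ones(len(variants), dtype=bool)
    for scaf, grp in repeat_bed.groupby("scaffold"):
        starts = np.sort(grp["start"].values)
        order = np.argsort(grp["start"].values)
        ends = grp["end"].values[order]
        mask = variants["scaffold"].values == scaf
        pos0 = variants["pos"].values[mask] - 1  # VCF 1-based -> 0-based
        idx = np.searchsorted(starts, pos0, side="right") - 1
        inside = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
        keep[np.where(mask)[0][inside]] = False
    return variants.loc[keep].copy()


# ---------------------------------------------------------------- coverage
@dataclass
class CoverageTrack:
    """Per-sample, per-window raw read depths with sample sex labels."""

    windows: pd.DataFrame  # scaffold, start, end, then one column per sample
    sample_sex: dict[str, str]

    @property
    def samples(self) -> list[str]:
        return [c for c in self.windows.columns if c in self.sample_sex]

    def normalized(self) -> pd.DataFrame:
        """Depths divided by each sample's median over all windows, so the
        normalized median per sample is one."""
        out = self.windows.copy()
        for s in self.samples:
            med = out[s].median()
            out[s] = out[s] / med if med > 0 else np.nan
        return out


def excessive_coverage_intervals(total_coverage_per_site) -> list[tuple[int, int]]:
    """Merge adjacent sites whose total coverage is at least twice the mean
    total coverage into half-open 0-based intervals."""
    cov = np.asarray(total_coverage_per_site, dtype=float)
    if cov.size == 0:
        return []
    if np.any(cov < 0):
        raise ValueError("coverage must be nonnegative")
    thr = 2.0 * cov.mean()
    high = cov >= thr
    intervals = []
    start = None
    for i, h in enumerate(high):
        if h and start is None:
            start = i
        elif not h and start is not None:
            intervals.append((start, i))
            start = None
    if start is not None:
        intervals.append((start, len(cov)))
    return intervals


def assign_sex_linked_scaffolds(
    track: CoverageTrack, ratio_window: tuple[float, float] = (1.7, 2.5)
) -> dict[str, str]:
    """Label scaffolds X when the female:male mean normalized coverage over
    their windows falls in ``ratio_window`` (around the expected 2:1),
    autosome otherwise."""
    males = [s for s, sex in track.sample_sex.items() if sex == "male"]
    females = [s for s, sex in track.sample_sex.items() if sex == "female"]
    if not males or not females:
        raise ValueError("need at least one male and one female sample")
    norm = track.normalized()
    labels = {}
    for scaf, grp in norm.groupby("scaffold"):
        f_mean = grp[females].values.mean()
        m_mean = grp[males].values.mean()
        if m_mean == 0:
            log.warning("scaffold %s has zero male coverage; labeling X", scaf)
            labels[scaf] = "X"
            continue
        ratio = f_mean / m_mean
        labels[scaf] = (
            "X" if ratio_window[0] <= ratio <= ratio_window[1] else "autosome"
        )
    return labels


def per_sample_coverage_mask(
    sample_depths: pd.DataFrame,
    sex_labels: dict[str, str],
    x_scaffolds,
) -> np.ndarray:
    """Union of per-sample depth masks: a site is removed when, for any
    sample, depth < median/3 or depth > 1.5 x median (sample-specific
    medians); on X scaffolds male thresholds are halved, female thresholds
    unchanged. ``sample_depths`` rows are sites (columns: scaffold, pos,
    then sample columns). Returns a boolean removed-row array."""
    x_set = set(x_scaffolds)
    samples = [c for c in sample_depths.columns if c in sex_labels]
    on_x = sample_depths["scaffold"].isin(x_set).values
    removed = np.zeros(len(sample_depths), dtype=bool)
    for s in samples:
        depth = sample_depths[s].values.astype(float)
        med = np.median(depth)
        if med == 0:
            log.warning("sample %s has zero median depth; fully masked", s)
            removed[:] = True
            continue
        lo, hi = med / 3.0, 1.5 * med
        if sex_labels[s] == "male":
            lo_x, hi_x = lo / 2.0, hi / 2.0
        else:
            lo_x, hi_x = lo, hi
        bad = np.where(
            on_x, (depth < lo_x) | (depth > hi_x), (depth < lo) | (depth > hi)
        )
        removed |= bad
    return removed


# ------------------------------------------------------------------- pN/pS
@dataclass
class PolymorphismSummary:
    gene_id: str
    n_syn: int
    n_nonsyn: int
    S_sites: float
    N_sites: float
    pN: float = field(init=False)
    pS_adj: float = field(init=False)
    pnps: float = field(init=False)

    def __post_init__(self):
        if self.S_sites <= 0 or self.N_sites <= 0:
            self.pN = self.pS_adj = self.pnps = float("nan")
            return
        self.pN = self.n_nonsyn / self.N_sites
        self.pS_adj = (self.n_syn + 1) / self.S_sites
        self.pnps = self.pN / self.pS_adj


def compute_pnps(
    n_syn: int, n_nonsyn: int, S_sites: float, N_sites: float, gene_id: str = ""
) -> PolymorphismSummary:
    """pN = n_nonsyn / N_sites; pS uses the p(S+1) pseudo-count,
    pS_adj = (n_syn + 1) / S_sites; pnps = pN / pS_adj."""
    return PolymorphismSummary(gene_id, n_syn, n_nonsyn, S_sites, N_sites)


def mean_ortholog_pnps(
    pnps_species1: pd.Series, pnps_species2: pd.Series, require_both: bool = True
) -> pd.Series:
    """Per-gene arithmetic mean of two species' pN/pS. By default genes
    must have a value in both species (mirroring ortholog attrition);
    with ``require_both=False`` single-species values pass through."""
    df = pd.concat(
        {"a": pnps_species1, "b": pnps_species2}, axis=1, join="outer"
    )
    if require_both:
        df = df.dropna()
        return (df["a"] + df["b"]) / 2.0
    return df.mean(axis=1)


def restrict_to_aligned_intervals(
    profile: DegeneracyProfile,
    snps: pd.DataFrame,
    aligned_intervals: list[tuple[int, int]],
    snp_pos_col: str = "cds_pos",
):
    """Restrict both the degeneracy site counts and the SNP table to
    positions inside the (0-based half-open) aligned intervals, before
    computing pN/pS. Raises when the intersection is empty."""
    if profile.folds is None:
        raise ValueError("profile must carry per-position folds")
    L = len(profile.folds)
    inside = np.zeros(L, dtype=bool)
    for start, end in aligned_intervals:
        if end < start:
            raise ValueError("malformed interval")
        inside[max(0, start) : min(L, end)] = True
    if not inside.any():
        raise ValueError("empty intersection with aligned intervals")
    folds = np.where(inside, profile.folds, -1)
    counts = {x: int(np.sum(folds == x)) for x in (1, 2, 3, 4)}
    sub_profile = DegeneracyProfile(
        f0=counts[1], f2=counts[2], f3=counts[3], f4=counts[4], folds=folds
    )
    pos = snps[snp_pos_col].values
    snp_inside = np.zeros(len(snps), dtype=bool)
    for start, end in aligned_intervals:
        snp_inside |= (pos >= start) & (pos < end)
    return sub_profile, snps.loc[snp_inside].copy()
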