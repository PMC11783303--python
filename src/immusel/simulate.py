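"""Synthetic-data generator.

Emulates every input the analysis consumes, with the statistical structure
the downstream stages assume: codon alignments evolved under mixture codon
models on two-clade trees (mirroring a two-family rodent design), SNP
tables with a target pN/pS, expression count matrices with target tissue
specificity, and coverage tracks with X-linked scaffolds at 2:1
female-male coverage.

Everything is driven by integer seeds through ``numpy.random.default_rng``;
identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genetics as G
from .alignment import CodonAlignment
from .codonmodel import MixtureCodonModel, RateMatrixBuilder, normalize_syn_rates
from .constraint import CoverageTrack, classify_degeneracy
from .expression import ExpressionMatrix
from .trees import Phylogeny


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ----------------------------------------------------------------- trees
def _yule_subtree(n: int, labels: list[str], rng: np.random.Generator):
    """Pure-birth tree with ``n`` tips, unit root-to-tip depth (ultrametric).

    Returns a nested (children, branch_length) structure."""
    # forward simulation: lineages split at rate 1 per lineage
    next_id = [0]

    def new_node():
        next_id[0] += 1
        return {"id": next_id[0], "children": [], "t_birth": 0.0}

    root = new_node()
    active = [root]
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        k = rng.integers(len(active))
        parent = active.pop(int(k))
        for _ in range(2):
            ch = new_node()
            ch["t_birth"] = t
            parent["children"].append(ch)
            active.append(ch)
    t_end = t + rng.exponential(1.0 / len(active))
    # assign labels to the surviving lineages (tips), scale depth to 1
    rng.shuffle(active)
    for nd, lab in zip(active, labels):
        nd["label"] = lab
    root_split = min(c["t_birth"] for c in root["children"])
    depth = (t_end - root_split) if t_end > root_split else 1.0

    def newick(nd, parent_t):
        end_t = t_end if not nd["children"] else min(
            c["t_birth"] for c in nd["children"]
        )
        bl = (end_t - parent_t) / depth
        if not nd["children"]:
            return f"{nd['label']}:{bl:.10f}"
        inner = ",".join(newick(c, end_t) for c in nd["children"])
        return f"({inner}):{bl:.10f}"

    # root branch length 0 so tips sit exactly one depth unit below the root
    inner = ",".join(newick(c, root_split) for c in root["children"])
    return f"({inner}):0.0000000000"


def simulate_tree(n_taxa_per_clade: int, depth: float, seed) -> Phylogeny:
    """Two-clade binary tree (pure-birth within clades, joined by a stem).

    ``depth`` is the root-to-tip path length in expected substitutions per
    codon; trees are ultrametric with all tips at exactly that depth. Tip
    labels are ``A01..`` and ``B01..`` for the two clades.
    """
    if n_taxa_per_clade < 2:
        raise ValueError("need at least 2 taxa per clade")
    if not depth > 0:
        raise ValueError("tree depth must be positive")
    rng = _rng(seed)
    stem_frac = 0.3
    clade_depth = depth * (1.0 - stem_frac)
    stem = depth * stem_frac
    parts = []
    for clade in ("A", "B"):
        labels = [f"{clade}{i + 1:02d}" for i in range(n_taxa_per_clade)]
        sub = _yule_subtree(n_taxa_per_clade, labels, rng)
        sub = _scale_newick(sub, clade_depth)
        parts.append(f"{sub[:-len(':0.0000000000')] if False else sub}")
    # each clade subtree string ends with its root branch length; replace it
    # with the stem length
    newick = "(" + _with_root_branch(parts[0], stem) + "," + _with_root_branch(
        parts[1], stem
    ) + ");"
    return Phylogeny.from_newick(newick)


def _scale_newick(nwk: str, factor: float) -> str:
    import re

    def repl(m):
        return f":{float(m.group(1)) * factor:.10f}"

    return re.sub(r":([0-9.eE+-]+)", repl, nwk)


def _with_root_branch(sub: str, stem: float) -> str:
    i = sub.rfind(":")
    return sub[:i] + f":{stem:.10f}"


# ------------------------------------------------------------- alignments
def simulate_codon_alignment(
    tree: Phylogeny,
    model: MixtureCodonModel,
    n_codons: int,
    seed,
    gene_id: str = "gene",
) -> tuple[CodonAlignment, pd.DataFrame]:
    """Evolve codon sequences down ``tree`` under the mixture model.

    Each site draws its (omega, s) class from the mixture weights; the root
    codon comes from pi; branches apply exact transition matrices
    exp(Q t). Returns the alignment and a per-site truth table with the
    omega/s class indices. No stop codons or gaps can occur (the state
    space is the 61 sense codons).
    """
    model.validate()
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = _rng(seed)
    K, M = len(model.omegas), len(model.syn_rates)
    k_idx = rng.choice(K, size=n_codons, p=model.omega_weights)
    m_idx = rng.choice(M, size=n_codons, p=model.syn_weights)

    builder = RateMatrixBuilder(model.pi, model.kappa, model.delta, model.psi)
    spectra = {}
    for k in range(K):
        for m in range(M):
            if np.any((k_idx == k) & (m_idx == m)):
                spectra[(k, m)] = builder.spectral(
                    model.omegas[k], model.syn_rates[m]
                )

    comp_of_site = k_idx * M + m_idx
    root_states = rng.choice(G.N_STATES, size=n_codons, p=model.pi)

    states = np.zeros((tree.n_nodes, n_codons), dtype=np.int32)
    states[tree.root_index] = root_states
    # walk root-to-tip (reverse postorder)
    for k in reversed(tree.postorder):
        parent_states = states[k]
        for child, bl in tree.children[k - tree.n_tips]:
            child_states = np.empty(n_codons, dtype=np.int32)
            for (kk, mm), spec in spectra.items():
                mask = (k_idx == kk) & (m_idx == mm)
                if not mask.any():
                    continue
                P = RateMatrixBuilder.transition_matrix(*spec, bl)
                rows = P[parent_states[mask]]
                rows = rows / rows.sum(axis=1, keepdims=True)
                u = rng.random(mask.sum())
                child_states[mask] = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1)
            states[child] = child_states

    seqs = [
        "".join(G.SENSE_CODONS[s] for s in states[i])
        for i in range(tree.n_tips)
    ]
    aln = CodonAlignment(list(tree.taxon_names), seqs, gene_id=gene_id)
    truth = pd.DataFrame(
        {
            "site": np.arange(n_codons),
            "omega_class": k_idx,
            "syn_class": m_idx,
            "omega": model.omegas[k_idx],
            "syn_rate": model.syn_rates[m_idx],
        }
    )
    return aln, truth


# ---------------------------------------------------------------- variants
def simulate_variants(
    cds_sequence: str,
    target_pnps: float,
    n_diploids: int,
    theta: float,
    seed,
    scaffold: str = "scaf1",
    offset: int = 0,
) -> pd.DataFrame:
    """SNP table for one coding sequence with a target (expected) pN/pS.

    Synonymous SNP positions are drawn on the synonymous mutational
    opportunity, nonsynonymous ones on the nonsynonymous opportunity;
    expected counts are ``theta * S_sites`` and
    ``target_pnps * theta * N_sites``, so the expected pN/pS before the
    pseudo-count equals the target. Allele counts follow a neutral-SFS-like
    law (P(i alt copies) proportional to 1/i). Site-level annotations
    (QUAL, strand and read-position support, allele balance) are generated
    so records pass the default filter cascade.

    Returns a VariantTable data frame with one row per SNP and a
    ``genotypes`` column holding per-sample alt-allele counts.
    """
    cds = cds_sequence.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if target_pnps < 0:
        raise ValueError("target pN/pS must be >= 0")
    prof = classify_degeneracy(cds)  # raises on internal stop
    rng = _rng(seed)

    L = len(cds)
    syn_opp = np.zeros(L)
    nonsyn_opp = np.zeros(L)
    for j in range(L):
        ci = j // 3
        codon = cds[3 * ci : 3 * ci + 3]
        if any(ch not in "ACGT" for ch in codon):
            continue
        pos = j % 3
        aa = G.translate_codon(codon)
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if mut in G.STOP_CODONS:
                nonsyn_opp[j] += 1  # stop-gain counted as nonsynonymous
            elif G.translate_codon(mut) == aa:
                syn_opp[j] += 1
            else:
                nonsyn_opp[j] += 1
    S_sites = syn_opp.sum() / 3.0
    N_sites = nonsyn_opp.sum() / 3.0

    n_syn = rng.poisson(theta * S_sites)
    n_nonsyn = rng.poisson(target_pnps * theta * N_sites)

    records = []
    taken: set[int] = set()

    def place(n, opp, snp_class, synonymous_choice):
        weights = opp.copy()
        weights[list(taken)] = 0.0
        for _ in range(int(n)):
            tot = weights.sum()
            if tot <= 0:
                break
            j = int(rng.choice(L, p=weights / tot))
            weights[j] = 0.0
            taken.add(j)
            ci, pos = j // 3, j % 3
            codon = cds[3 * ci : 3 * ci + 3]
            aa = G.translate_codon(codon)
            alts = []
            for nt in "ACGT":
                if nt == codon[pos]:
                    continue
                mut = codon[:pos] + nt + codon[pos + 1 :]
                mut_syn = (
                    mut not in G.STOP_CODONS and G.translate_codon(mut) == aa
                )
                if mut_syn == synonymous_choice:
                    alts.append(nt)
            if not alts:
                continue
            alt = alts[int(rng.integers(len(alts)))]
            records.append((j, codon[pos], alt, snp_class))

    place(n_syn, syn_opp, "synonymous", True)
    place(n_nonsyn, nonsyn_opp, "nonsynonymous", False)

    nchrom = 2 * n_diploids
    rows = []
    sfs_p = 1.0 / np.arange(1, nchrom)
    sfs_p /= sfs_p.sum()
    for j, ref, alt, cls in sorted(records):
        count = int(rng.choice(np.arange(1, nchrom), p=sfs_p))
        chroms = np.zeros(nchrom, dtype=int)
        chroms[rng.choice(nchrom, size=count, replace=False)] = 1
        geno = chroms.reshape(n_diploids, 2).sum(axis=1)
        depth = max(4, int(rng.poisson(30)))
        alt_reads = max(2, int(round(depth * 0.5)))
        rows.append(
            {
                "scaffold": scaffold,
                "pos": offset + j + 1,  # VCF 1-based
                "ref": ref,
                "alt": alt,
                "qual": float(rng.uniform(60, 2000)),
                "SAF": alt_reads // 2 + 1,
                "SAR": alt_reads - alt_reads // 2 + 1,
                "RPL": alt_reads // 2 + 2,
                "RPR": alt_reads - alt_reads // 2 + 2,
                "allele_balance": float(rng.uniform(0.4, 0.6)),
                "genotypes": geno,
                "biallelic_snp": True,
                "true_class": cls,
            }
        )
    cols = [
        "scaffold", "pos", "ref", "alt", "qual", "SAF", "SAR", "RPL", "RPR",
        "allele_balance", "genotypes", "biallelic_snp", "true_class",
    ]
    return pd.DataFrame(rows, columns=cols)


# -------------------------------------------------------------- expression
def simulate_expression(
    n_genes: int,
    n_tissues: int,
    tau_target_per_gene,
    library_sizes,
    seed,
    dispersion: float = 0.1,
) -> ExpressionMatrix:
    """Count matrix whose noiseless tissue-mean profiles hit target tau.

    A gene with target tau has one (randomly chosen) peak tissue at level
    ``mu`` and all other tissues at ``(1 - tau) * mu`` — the tissue
    specificity index of that profile is exactly tau. Counts are negative
    binomial around the profile, scaled by library size and effective
    length. Samples are assigned to tissues round-robin over
    ``library_sizes``.
    """
    if n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    tau_targets = np.asarray(tau_target_per_gene, dtype=float)
    if tau_targets.shape != (n_genes,):
        raise ValueError("tau_target_per_gene must have length n_genes")
    if np.any((tau_targets < 0) | (tau_targets > 1)):
        raise ValueError("tau targets must lie in [0, 1]")
    library_sizes = np.asarray(library_sizes, dtype=float)
    n_samples = len(library_sizes)
    if n_samples < n_tissues:
        raise ValueError("need at least one sample per tissue")
    rng = _rng(seed)

    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    tissues = [f"tissue{t + 1:02d}" for t in range(n_tissues)]
    sample_tissue = {
        f"s{j + 1:03d}": tissues[j % n_tissues] for j in range(n_samples)
    }
    eff_len = rng.lognormal(np.log(1500), 0.4, size=n_genes)
    mu = rng.lognormal(np.log(50), 1.0, size=n_genes)  # peak FPKM-scale level
    peak = rng.integers(0, n_tissues, size=n_genes)

    profiles = (1.0 - tau_targets)[:, None] * mu[:, None] * np.ones(
        (n_genes, n_tissues)
    )
    profiles[np.arange(n_genes), peak] = mu

    counts = np.zeros((n_genes, n_samples))
    for j, (sample, tissue) in enumerate(sample_tissue.items()):
        t = tissues.index(tissue)
        mean = profiles[:, t] * (eff_len / 1e3) * (library_sizes[j] / 1e6)
        if dispersion > 0:
            shape = 1.0 / dispersion
            lam = rng.gamma(shape, mean / shape)
        else:
            lam = mean
        counts[:, j] = rng.poisson(lam)

    counts_df = pd.DataFrame(
        counts, index=gene_ids, columns=list(sample_tissue)
    )
    lengths = pd.DataFrame(
        np.tile(eff_len[:, None], (1, n_samples)),
        index=gene_ids,
        columns=list(sample_tissue),
    )
    return ExpressionMatrix(
        counts=counts_df,
        effective_lengths=lengths,
        sample_tissue=sample_tissue,
        true_profiles=pd.DataFrame(profiles, index=gene_ids, columns=tissues),
    )


# ---------------------------------------------------------------- coverage
def simulate_coverage(
    scaffold_lengths: dict[str, int],
    x_scaffold_ids,
    n_males: int,
    n_females: int,
    mean_depth: float,
    seed,
    spike_rate: float = 0.01,
    window: int = 1000,
) -> CoverageTrack:
    """1-kb windowed per-sample depths with X scaffolds at half male depth.

    High-coverage spike windows (all samples multiplied by 5) are injected
    at ``spike_rate`` to exercise the excessive-coverage filter.
    """
    if len(set(scaffold_lengths)) != len(scaffold_lengths):
        raise ValueError("scaffold ids must be unique")
    if n_males + n_females == 0:
        raise ValueError("need at least one sample")
    rng = _rng(seed)
    x_set = set(x_scaffold_ids)
    samples = [f"M{i + 1}" for i in range(n_males)] + [
        f"F{i + 1}" for i in range(n_females)
    ]
    sexes = ["male"] * n_males + ["female"] * n_females
    sample_scale = rng.lognormal(0.0, 0.15, size=len(samples))

    rows = []
    for scaf, length in scaffold_lengths.items():
        n_win = max(1, length // window)
        is_x = scaf in x_set
        spikes = rng.random(n_win) < spike_rate
        for w in range(n_win):
            depths = []
            for s, (sex, scale) in enumerate(zip(sexes, sample_scale)):
                m = mean_depth * scale
                if is_x and sex == "male":
                    m *= 0.5
                d = rng.poisson(m)
                if spikes[w]:
                    d *= 5
                depths.append(d)
            rows.append([scaf, w * window, (w + 1) * window] + depths)
    df = pd.DataFrame(rows, columns=["scaffold", "start", "end"] + samples)
    return CoverageTrack(windows=df, sample_sex=dict(zip(samples, sexes)))


# ------------------------------------------------------------ world config
DEFAULT_CATEGORIES = (
    "control",
    "PRR",
    "cytokines",
    "cell_surface",
    "signaling",
    "proteases",
    "effectors",
)


@dataclass
class SimulationConfig:
    """Study conditions for a full synthetic world.

    Defaults mirror the emulated study design: two clades of 15 taxa, ten
    tissues, 8 diploids in one species and 31 in the other. Per-category
    positive-selection fractions and effect sizes are calibration choices
    (the emulated study reports none), flagged here as such.
    """

    seed: int = 0
    n_taxa_per_clade: int = 15
    tree_depth: float = 0.6
    n_codons: int = 300
    n_genes_per_category: dict = field(
        default_factory=lambda: {c: 40 for c in DEFAULT_CATEGORIES}
    )
    # calibration choice: rate at which a gene carries a positive class
    fraction_positive: dict = field(
        default_factory=lambda: {
            "control": 0.05,
            "PRR": 0.12,
            "cytokines": 0.15,
            "cell_surface": 0.13,
            "signaling": 0.04,
            "proteases": 0.08,
            "effectors": 0.10,
        }
    )
    pnps_targets: dict = field(
        default_factory=lambda: {
            "control": 0.15,
            "PRR": 0.22,
            "cytokines": 0.25,
            "cell_surface": 0.22,
            "signaling": 0.11,
            "proteases": 0.18,
            "effectors": 0.20,
        }
    )
    tau_targets: dict = field(
        default_factory=lambda: {
            "control": 0.45,
            "PRR": 0.65,
            "cytokines": 0.70,
            "cell_surface": 0.60,
            "signaling": 0.40,
            "proteases": 0.55,
            "effectors": 0.68,
        }
    )
    n_tissues: int = 10
    n_diploid_samples: tuple[int, int] = (8, 31)
    # mixture template: background omegas; positive genes add omega3 > 1
    omega_background: tuple[float, float] = (0.1, 0.9)
    omega_positive: float = 4.0
    positive_weight: float = 0.1
    kappa: float = 2.5
    syn_rate_sd: float = 0.0  # >0 turns on synonymous-rate variation
    delta: float = 0.0
    psi: float = 0.0
    theta: float = 0.04  # per-site synonymous polymorphism rate
    # how strongly low constraint (high pN/pS) boosts positive selection
    constraint_coupling: float = 0.0
    # gene-level spread (lognormal sd) of pN/pS around the category mean
    pnps_gene_sd: float = 0.3

    def validate(self) -> None:
        for d in (self.fraction_positive,):
            if any(not 0 <= v <= 1 for v in d.values()):
                raise ValueError("fraction_positive must be probabilities")
        if any(v < 1 for v in self.n_genes_per_category.values()):
            raise ValueError("gene counts must be >= 1")
        if any(not 0 <= v <= 1 for v in self.tau_targets.values()):
            raise ValueError("tau targets must lie in [0, 1]")


@dataclass
class SimulatedGene:
    gene_id: str
    category: str
    true_model: MixtureCodonModel
    alignment: CodonAlignment
    tree: Phylogeny
    true_positive: bool
    pnps_target: float
    tau_target: float


def _gene_model(cfg: SimulationConfig, positive: bool, pi, rng) -> MixtureCodonModel:
    om = np.array(
        [cfg.omega_background[0], cfg.omega_background[1],
         cfg.omega_positive if positive else 1.0]
    )
    w3 = cfg.positive_weight if positive else 0.0
    ww = np.array([0.55, 0.45 - w3 if not positive else 0.45, w3])
    ww = ww / ww.sum()
    if cfg.syn_rate_sd > 0:
        raw = np.exp(rng.normal(0.0, cfg.syn_rate_sd, size=3))
        qw = np.array([1 / 3, 1 / 3, 1 / 3])
        sr = normalize_syn_rates(raw, qw)
    else:
        sr, qw = np.array([1.0]), np.array([1.0])
    return MixtureCodonModel(
        kappa=cfg.kappa,
        pi=pi,
        omegas=om,
        omega_weights=ww,
        syn_rates=sr,
        syn_weights=qw,
        delta=cfg.delta,
        psi=cfg.psi,
    )


def simulate_world(cfg: SimulationConfig) -> list[SimulatedGene]:
    """Generate the per-gene truth for a full synthetic study.

    All genes in a world share one topology (a per-world two-clade tree);
    each gene has its own mixture model. ``true_positive`` marks genes
    whose model carries an omega > 1 class with positive weight. When
    ``constraint_coupling > 0``, the chance of carrying a positive class
    rises with the gene's pN/pS target, creating the constraint-mediated
    pathway the category statistics are meant to dissect.
    """
    cfg.validate()
    rng = _rng(cfg.seed)
    tree = simulate_tree(cfg.n_taxa_per_clade, cfg.tree_depth, rng)
    pi = np.full(G.N_STATES, 1.0 / G.N_STATES)
    genes = []
    mean_pnps = float(np.mean(list(cfg.pnps_targets.values())))
    for cat, n in cfg.n_genes_per_category.items():
        base_frac = cfg.fraction_positive.get(cat, 0.05)
        for i in range(n):
            pnps_t = float(
                np.exp(rng.normal(np.log(cfg.pnps_targets.get(cat, 0.15)),
                                  cfg.pnps_gene_sd))
            )
            frac = base_frac
            if cfg.constraint_coupling > 0:
                frac = min(
                    0.95, base_frac * (pnps_t / mean_pnps) ** cfg.constraint_coupling
                )
            positive = bool(rng.random() < frac)
            model = _gene_model(cfg, positive, pi, rng)
            aln, _ = simulate_codon_alignment(
                tree, model, cfg.n_codons, rng, gene_id=f"{cat}_{i + 1:04d}"
            )
            tau_t = float(
                np.clip(rng.normal(cfg.tau_targets.get(cat, 0.5), 0.08), 0.0, 1.0)
            )
            genes.append(
                SimulatedGene(
                    gene_id=f"{cat}_{i + 1:04d}",
                    category=cat,
                    true_model=model,
                    alignment=aln,
                    tree=tree,
                    true_positive=positive,
                    pnps_target=pnps_t,
                    tau_target=tau_t,
                )
            )
    return genes
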