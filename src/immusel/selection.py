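"""Gene-wide tests for positive selection under mixture codon models.

Three nested model variants are fitted by maximum likelihood:

* ``base`` — an omega mixture (default three classes) with a single
  synonymous rate and no multi-hit substitutions;
* ``S`` — adds a discrete mean-one synonymous-rate mixture (site-to-site
  synonymous rate variation);
* ``S_MH`` — additionally allows instantaneous double- (delta) and
  triple-hit (psi) codon changes.

For each variant the null hypothesis caps the largest omega class at one;
the alternative leaves it free. The likelihood-ratio statistic is referred
to a chi-square distribution with 2 df (conservative at the boundary). The
three alternative fits are synthesized into a model-averaged p-value with
Akaike weights, so poorly fitting variants are penalized. An M1a-vs-M2a
site-model test and a single-omega dN/dS estimator are provided for
benchmarking, and Benjamini-Hochberg q-values flag genes at q < 0.2.

Fitting uses bounded quasi-Newton (L-BFGS-B) on transformed parameters:
omega classes are ordered via a top value and descending ratios, weights
use stick-breaking logits, synonymous rates are renormalized to mixture
mean one, and a single tree-scale factor multiplies the relative branch
lengths of the input tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .alignment import (  # re-exported QC filters
    CodonAlignment,
    filter_alignment_length,
    filter_min_taxa,
)
from .codonmodel import MixtureCodonModel, normalize_syn_rates
from .genetics import f3x4_frequencies
from .likelihood import PruningEngine
from .trees import Phylogeny

__all__ = [
    "FitSettings",
    "FitResult",
    "GeneTestResult",
    "fit_model",
    "busted_like_test",
    "m1a_m2a_test",
    "fit_global_omega",
    "model_averaged_p",
    "bh_fdr",
    "run_gene_tests",
    "filter_alignment_length",
    "filter_min_taxa",
]

log = logging.getLogger(__name__)

VARIANTS = ("base", "S", "S_MH")
OMEGA_MAX = 999.0


@dataclass
class FitSettings:
    """Optimizer budget and model sizes. ``fast()`` gives the reduced
    settings used for large simulation screens."""

    n_omega_classes: int = 3
    n_syn_classes: int = 3
    n_restarts: int = 3
    maxfun: int = 400
    ftol: float = 1e-9
    restart_improvement_tol: float = 0.01

    @classmethod
    def fast(cls) -> "FitSettings":
        return cls(n_omega_classes=2, n_syn_classes=2, n_restarts=1, maxfun=35)


@dataclass
class FitResult:
    log_likelihood: float
    n_free_params: int
    parameters: dict
    model: MixtureCodonModel | None
    scale: float
    converged: bool
    n_restarts_used: int = 1

    @property
    def aic(self) -> float:
        return 2.0 * self.n_free_params - 2.0 * self.log_likelihood


# ------------------------------------------------------- parameter mapping
def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _stick_weights(logits: np.ndarray) -> np.ndarray:
    """Stick-breaking: logits of length k-1 -> k simplex weights."""
    w = []
    rest = 1.0
    for b in logits:
        v = _sigmoid(b)
        w.append(rest * v)
        rest *= 1.0 - v
    w.append(rest)
    return np.array(w)


def _stick_logits(weights) -> np.ndarray:
    weights = np.asarray(weights, dtype=float)
    logits = []
    rest = 1.0
    for w in weights[:-1]:
        v = np.clip(w / rest, 1e-9, 1 - 1e-9)
        logits.append(np.log(v / (1 - v)))
        rest *= 1.0 - v
    return np.array(logits)


class _Parameterization:
    """Maps a flat bounded vector to a MixtureCodonModel + tree scale."""

    def __init__(self, variant: str, constrained: bool, pi, settings: FitSettings):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        self.variant = variant
        self.constrained = constrained
        self.pi = pi
        self.K = settings.n_omega_classes
        self.M = settings.n_syn_classes if variant in ("S", "S_MH") else 1
        self.with_mh = variant == "S_MH"

        names = ["log_kappa", "log_scale", "omega_top"]
        bounds = [(-3.0, 4.0), (-6.0, 6.0),
                  (1e-4, 1.0 if constrained else OMEGA_MAX)]
        for i in range(self.K - 1):
            names.append(f"omega_ratio{i}")
            bounds.append((1e-6, 1.0))
        for i in range(self.K - 1):
            names.append(f"omega_wlogit{i}")
            bounds.append((-10.0, 10.0))
        if self.M > 1:
            for i in range(self.M - 1):
                names.append(f"log_syn{i}")
                bounds.append((-4.0, 4.0))
            for i in range(self.M - 1):
                names.append(f"syn_wlogit{i}")
                bounds.append((-10.0, 10.0))
        if self.with_mh:
            names += ["log_delta", "log_psi"]
            bounds += [(-14.0, 3.0), (-14.0, 3.0)]
        self.names = names
        self.bounds = bounds
        self.n_params = len(names)

    def unpack(self, x: np.ndarray) -> tuple[MixtureCodonModel, float]:
        i = 0
        kappa = float(np.exp(x[i])); i += 1
        scale = float(np.exp(x[i])); i += 1
        top = float(x[i]); i += 1
        ratios = x[i : i + self.K - 1]; i += self.K - 1
        omegas = [top]
        for r in ratios:
            omegas.append(omegas[-1] * float(r))
        omegas = np.array(omegas[::-1])
        wlogits = x[i : i + self.K - 1]; i += self.K - 1
        # stick order: weights of ascending omega classes
        oweights = _stick_weights(wlogits)
        if self.M > 1:
            logs = x[i : i + self.M - 1]; i += self.M - 1
            slogits = x[i : i + self.M - 1]; i += self.M - 1
            raw = np.append(np.exp(logs), 1.0)
            sweights = _stick_weights(slogits)
            srates = normalize_syn_rates(raw, sweights)
        else:
            srates, sweights = np.array([1.0]), np.array([1.0])
        delta = psi = 0.0
        if self.with_mh:
            delta = float(np.exp(x[i])); i += 1
            psi = float(np.exp(x[i])); i += 1
        model = MixtureCodonModel(
            kappa=kappa, pi=self.pi, omegas=omegas, omega_weights=oweights,
            syn_rates=srates, syn_weights=sweights, delta=delta, psi=psi,
            trusted=True,
        )
        return model, scale

    def initial_points(self, seed: int, n: int) -> list[np.ndarray]:
        """Deterministic seed-derived start points; the first is a fixed
        heuristic, the rest jitter it."""
        rng = np.random.default_rng(seed)
        base = {
            "log_kappa": np.log(2.0),
            "log_scale": 0.0,
            "omega_top": 0.9 if self.constrained else 1.5,
        }
        x0 = []
        for name, (lo, hi) in zip(self.names, self.bounds):
            if name in base:
                v = base[name]
            elif name.startswith("omega_ratio"):
                v = 0.4
            elif name.startswith("omega_wlogit"):
                # aim for weights ~ (0.55, 0.35, 0.10) ascending omega
                idx = int(name[-1])
                tgt = _stick_logits([0.55, 0.35, 0.10][: self.K - 1] + [0.0])
                v = tgt[idx] if idx < len(tgt) else 0.0
            elif name.startswith("log_syn"):
                v = [-0.4, 0.0, 0.0][int(name[-1]) % 3]
            elif name.startswith("syn_wlogit"):
                v = 0.0
            elif name in ("log_delta", "log_psi"):
                v = np.log(0.05)
            else:
                v = 0.0
            x0.append(float(np.clip(v, lo, hi)))
        points = [np.array(x0)]
        for _ in range(n - 1):
            jit = points[0] + rng.normal(0.0, 0.4, size=self.n_params)
            lo = np.array([b[0] for b in self.bounds])
            hi = np.array([b[1] for b in self.bounds])
            points.append(np.clip(jit, lo, hi))
        return points


# ----------------------------------------------------------------- fitting
def _optimize(engine, param: _Parameterization, starts, settings: FitSettings):
    def nll(x):
        model, scale = param.unpack(x)
        return -engine.log_likelihood(model, scale)

    best = None
    used = 0
    for x0 in starts:
        used += 1
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=param.bounds,
            options={
                "maxfun": settings.maxfun,
                "ftol": settings.ftol,
                # step large enough to dominate the numerical noise of the
                # eigendecomposition-based likelihood
                "eps": 1e-5,
            },
        )
        if best is None or res.fun < best.fun - 1e-12:
            improvement = np.inf if best is None else best.fun - res.fun
            best = res
            if used > 1 and improvement < settings.restart_improvement_tol:
                break
        elif used > 1 and best.fun - res.fun < settings.restart_improvement_tol:
            break
    return best, used


def fit_model(
    aln: CodonAlignment,
    tree: Phylogeny,
    variant: str = "base",
    constrained: bool = False,
    n_restarts: int | None = None,
    seed: int = 0,
    settings: FitSettings | None = None,
    engine: PruningEngine | None = None,
    warm_start: np.ndarray | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one model variant.

    Codon frequencies are fixed at the alignment's F3x4 values; relative
    branch lengths come from the input tree with one free scale factor.
    ``constrained=True`` caps the largest omega class at one (the null).
    ``warm_start`` adds one start point (e.g. the matching null solution
    when fitting the alternative).
    """
    settings = settings or FitSettings()
    if n_restarts is not None:
        settings = FitSettings(**{**settings.__dict__, "n_restarts": n_restarts})
    pi = f3x4_frequencies(aln.sequences)
    param = _Parameterization(variant, constrained, pi, settings)
    engine = engine or PruningEngine(aln, tree)
    if warm_start is not None:
        ws = np.clip(
            np.asarray(warm_start, dtype=float),
            [b[0] for b in param.bounds],
            [b[1] for b in param.bounds],
        )
        # the warm start counts against the restart budget
        starts = [ws] + param.initial_points(seed, settings.n_restarts)[
            : settings.n_restarts - 1
        ]
    else:
        starts = param.initial_points(seed, settings.n_restarts)
    res, used = _optimize(engine, param, starts, settings)
    model, scale = param.unpack(res.x)
    converged = bool(res.success or res.status == 1)
    if not converged:
        log.warning("fit did not converge (%s): %s", variant, res.message)
    params = dict(zip(param.names, res.x))
    params["_x"] = res.x
    return FitResult(
        log_likelihood=float(-res.fun),
        n_free_params=param.n_params,
        parameters=params,
        model=model,
        scale=scale,
        converged=converged,
        n_restarts_used=used,
    )


def _lift_vector(
    x: np.ndarray,
    src: _Parameterization,
    dst: _Parameterization,
) -> np.ndarray:
    """Embed a fitted parameter vector of a smaller variant into a larger
    variant's space at a likelihood-neutral point (synonymous rates 1,
    multi-hit rates ~0), for warm-starting the richer fit."""
    values = dict(zip(src.names, x))
    out = []
    for name, (lo, hi) in zip(dst.names, dst.bounds):
        if name in values:
            v = values[name]
        elif name.startswith("log_syn") or name.startswith("syn_wlogit"):
            v = 0.0
        elif name in ("log_delta", "log_psi"):
            v = -14.0
        else:
            v = 0.0
        out.append(float(np.clip(v, lo, hi)))
    return np.array(out)


def busted_like_test(
    aln: CodonAlignment,
    tree: Phylogeny,
    variant: str = "base",
    seed: int = 0,
    settings: FitSettings | None = None,
    engine: PruningEngine | None = None,
    warm_null: np.ndarray | None = None,
) -> dict:
    """Gene-wide test for a nonzero proportion of codons with omega > 1.

    Fits the null (largest omega class capped at 1) and the alternative
    (free); LRT = max(0, 2 * (logL_alt - logL_null)); p from chi-square
    with 2 df. The null solution warm-starts the alternative so nesting is
    respected up to optimizer noise (negative statistics are clamped).
    """
    engine = engine or PruningEngine(aln, tree)
    null = fit_model(
        aln, tree, variant, constrained=True, seed=seed,
        settings=settings, engine=engine, warm_start=warm_null,
    )
    alt_start = np.array(null.parameters["_x"], dtype=float)
    # probe the positive-selection region: lift the top omega class off the
    # boundary while keeping the fitted background parameters
    alt_start[2] = max(alt_start[2], 2.0)
    alt = fit_model(
        aln, tree, variant, constrained=False, seed=seed + 1,
        settings=settings, engine=engine,
        warm_start=alt_start,
    )
    # candidate positives get one symmetric refinement round: refit the
    # null from the alternative's solution (top class clipped to the
    # boundary) so an under-optimized null cannot inflate the statistic,
    # then re-probe the alternative from that refined null so the
    # refinement does not bias the comparison the other way
    if 2.0 * (alt.log_likelihood - null.log_likelihood) > 1.0:
        back = np.array(alt.parameters["_x"], dtype=float)
        back[2] = min(back[2], 1.0)
        null2 = fit_model(
            aln, tree, variant, constrained=True, seed=seed + 2,
            settings=settings, engine=engine, warm_start=back,
        )
        if null2.log_likelihood > null.log_likelihood:
            null = null2
            fwd = np.array(null.parameters["_x"], dtype=float)
            fwd[2] = max(fwd[2], 2.0)
            alt2 = fit_model(
                aln, tree, variant, constrained=False, seed=seed + 3,
                settings=settings, engine=engine, warm_start=fwd,
            )
            if alt2.log_likelihood > alt.log_likelihood:
                alt = alt2
    # the null solution is a feasible point of the alternative (its space
    # is a superset), so the alternative fit can always be lifted to it:
    # nesting (logL_alt >= logL_null) holds exactly in the reported fits
    if null.log_likelihood > alt.log_likelihood:
        alt = FitResult(
            log_likelihood=null.log_likelihood,
            n_free_params=alt.n_free_params,
            parameters=dict(null.parameters),
            model=null.model,
            scale=null.scale,
            converged=null.converged,
            n_restarts_used=alt.n_restarts_used,
        )
    lrt = max(0.0, 2.0 * (alt.log_likelihood - null.log_likelihood))
    p = float(stats.chi2.sf(lrt, df=2))
    return {"null": null, "alt": alt, "lrt": lrt, "p": p,
            "converged": null.converged and alt.converged}


# --------------------------------------------------------------- M1a / M2a
class _SiteModelParam(_Parameterization):
    """M1a: omega classes (omega0 in (0,1), 1) with free weight; M2a adds a
    free omega2 > 1 class. No synonymous-rate variation or multi-hit."""

    def __init__(self, positive: bool, pi):
        self.positive = positive
        self.pi = pi
        self.names = ["log_kappa", "log_scale", "omega0", "wlogit0"]
        self.bounds = [(-3.0, 4.0), (-6.0, 6.0), (1e-6, 1.0), (-10.0, 10.0)]
        if positive:
            self.names += ["omega2", "wlogit1"]
            self.bounds += [(1.0, OMEGA_MAX), (-10.0, 10.0)]
        self.n_params = len(self.names)

    def unpack(self, x):
        kappa = float(np.exp(x[0]))
        scale = float(np.exp(x[1]))
        omega0 = float(x[2])
        if self.positive:
            omegas = np.array([omega0, 1.0, float(x[4])])
            weights = _stick_weights(np.array([x[3], x[5]]))
        else:
            omegas = np.array([omega0, 1.0])
            weights = _stick_weights(np.array([x[3]]))
        model = MixtureCodonModel(
            kappa=kappa, pi=self.pi, omegas=omegas, omega_weights=weights,
            trusted=True,
        )
        return model, scale

    def initial_points(self, seed, n):
        rng = np.random.default_rng(seed)
        x0 = [np.log(2.0), 0.0, 0.2, 0.8]
        if self.positive:
            x0 += [2.0, -2.0]
        points = [np.array(x0)]
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        for _ in range(n - 1):
            points.append(
                np.clip(points[0] + rng.normal(0, 0.4, self.n_params), lo, hi)
            )
        return points


def m1a_m2a_test(
    aln: CodonAlignment,
    tree: Phylogeny,
    seed: int = 0,
    settings: FitSettings | None = None,
    engine: PruningEngine | None = None,
) -> dict:
    """Nested site-model comparison: M1a (nearly neutral) vs M2a (adds a
    free omega > 1 class); p from chi-square with 2 df."""
    settings = settings or FitSettings()
    pi = f3x4_frequencies(aln.sequences)
    engine = engine or PruningEngine(aln, tree)
    results = {}
    m1a_x = None
    for positive in (False, True):
        param = _SiteModelParam(positive, pi)
        starts = param.initial_points(seed + int(positive), settings.n_restarts)
        if positive and m1a_x is not None:
            ws = np.concatenate([m1a_x, [2.0, 1.0]])
            starts = [np.clip(ws, [b[0] for b in param.bounds],
                              [b[1] for b in param.bounds])] + starts[
                : settings.n_restarts - 1
            ]
        res, used = _optimize(engine, param, starts, settings)
        model, scale = param.unpack(res.x)
        fit = FitResult(
            log_likelihood=float(-res.fun),
            n_free_params=param.n_params,
            parameters=dict(zip(param.names, res.x)),
            model=model,
            scale=scale,
            converged=bool(res.success or res.status == 1),
            n_restarts_used=used,
        )
        results["M2a" if positive else "M1a"] = fit
        if not positive:
            m1a_x = res.x
    # M1a embeds in M2a (an omega2 = 1 class of any weight changes
    # nothing), so the reported M2a fit is lifted when the optimizer
    # landed below M1a
    if results["M2a"].log_likelihood < results["M1a"].log_likelihood:
        m1a = results["M1a"]
        results["M2a"] = FitResult(
            log_likelihood=m1a.log_likelihood,
            n_free_params=results["M2a"].n_free_params,
            parameters=dict(m1a.parameters),
            model=m1a.model,
            scale=m1a.scale,
            converged=m1a.converged,
            n_restarts_used=results["M2a"].n_restarts_used,
        )
    lrt = max(
        0.0,
        2.0 * (results["M2a"].log_likelihood - results["M1a"].log_likelihood),
    )
    p = float(stats.chi2.sf(lrt, df=2))
    return {**results, "lrt": lrt, "p": p,
            "converged": results["M1a"].converged and results["M2a"].converged}


# ------------------------------------------------------------ single omega
def fit_global_omega(
    aln: CodonAlignment,
    tree: Phylogeny,
    seed: int = 0,
    settings: FitSettings | None = None,
    engine: PruningEngine | None = None,
) -> FitResult:
    """Single-omega (K=1, M=1, no multi-hit) maximum-likelihood dN/dS for
    the whole CDS. Alignments with no variation are flagged
    unidentifiable (omega is NaN)."""
    settings = settings or FitSettings()
    states = aln.state_matrix()
    varying = False
    for col in states.T:
        obs = col[col >= 0]
        if len(obs) > 1 and len(set(obs.tolist())) > 1:
            varying = True
            break
    if not varying:
        log.warning("no variation in alignment %s: omega unidentifiable",
                    aln.gene_id)
        return FitResult(
            log_likelihood=float("nan"), n_free_params=3, parameters={},
            model=None, scale=1.0, converged=False,
        )
    pi = f3x4_frequencies(aln.sequences)
    engine = engine or PruningEngine(aln, tree)

    one = FitSettings(**{**settings.__dict__,
                         "n_omega_classes": 1, "n_syn_classes": 1})
    param = _Parameterization("base", False, pi, one)
    starts = param.initial_points(seed, one.n_restarts)
    res, used = _optimize(engine, param, starts, one)
    model, scale = param.unpack(res.x)
    fit = FitResult(
        log_likelihood=float(-res.fun),
        n_free_params=3,
        parameters=dict(zip(param.names, res.x)),
        model=model,
        scale=scale,
        converged=bool(res.success or res.status == 1),
        n_restarts_used=used,
    )
    fit.parameters["omega"] = float(model.omegas[0])
    return fit


# -------------------------------------------------------- model averaging
def model_averaged_p(variant_results: dict[str, dict]) -> tuple[float, dict]:
    """Akaike-weight average of the per-variant p-values.

    Weights w_i = exp(-(AIC_i - AIC_min)/2), normalized over the converged
    alternative-model fits; the averaged p is sum w_i p_i. Returns (p,
    weights); NaN when no variant converged.
    """
    usable = {
        v: r for v, r in variant_results.items() if r.get("converged", False)
    }
    if not usable:
        return float("nan"), {}
    aics = {v: r["alt"].aic for v, r in usable.items()}
    amin = min(aics.values())
    raw = {v: np.exp(-(a - amin) / 2.0) for v, a in aics.items()}
    tot = sum(raw.values())
    weights = {v: w / tot for v, w in raw.items()}
    p = float(sum(weights[v] * usable[v]["p"] for v in usable))
    return p, weights


def bh_fdr(p_values, q_threshold: float = 0.2):
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement,
    plus significance flags at q < ``q_threshold``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q < q_threshold


# ------------------------------------------------------------ per-gene run
@dataclass
class GeneTestResult:
    gene_id: str
    variant_results: dict = field(default_factory=dict)
    model_averaged_p: float = float("nan")
    akaike_weights: dict = field(default_factory=dict)
    paml_style_p: float = float("nan")
    global_omega: float = float("nan")
    q_value: float = float("nan")
    positive_flag: bool = False

    def as_row(self) -> dict:
        row = {"gene_id": self.gene_id}
        for v in VARIANTS:
            r = self.variant_results.get(v)
            if r is None:
                continue
            row[f"logL_null_{v}"] = r["null"].log_likelihood
            row[f"logL_alt_{v}"] = r["alt"].log_likelihood
            row[f"lrt_{v}"] = r["lrt"]
            row[f"p_{v}"] = r["p"]
            row[f"w_{v}"] = self.akaike_weights.get(v, float("nan"))
        row["model_averaged_p"] = self.model_averaged_p
        row["paml_style_p"] = self.paml_style_p
        row["global_omega"] = self.global_omega
        row["q_value"] = self.q_value
        row["positive_flag"] = self.positive_flag
        return row


def run_gene_tests(
    aln: CodonAlignment,
    tree: Phylogeny,
    variants=VARIANTS,
    seed: int = 0,
    settings: FitSettings | None = None,
    include_m1a_m2a: bool = True,
    include_global_omega: bool = True,
) -> GeneTestResult:
    """All selection tests for one gene, sharing a pruning engine."""
    engine = PruningEngine(aln, tree)
    out = GeneTestResult(gene_id=aln.gene_id or "gene")
    settings_ = settings or FitSettings()
    pi = f3x4_frequencies(aln.sequences)
    prev_null_x = None
    prev_param = None
    for i, v in enumerate(variants):
        param = _Parameterization(v, True, pi, settings_)
        warm = None
        if prev_null_x is not None:
            warm = _lift_vector(prev_null_x, prev_param, param)
        out.variant_results[v] = busted_like_test(
            aln, tree, v, seed=seed + 10 * i, settings=settings,
            engine=engine, warm_null=warm,
        )
        prev_null_x = out.variant_results[v]["null"].parameters["_x"]
        prev_param = param
    out.model_averaged_p, out.akaike_weights = model_averaged_p(
        out.variant_results
    )
    if include_m1a_m2a:
        out.paml_style_p = m1a_m2a_test(
            aln, tree, seed=seed + 91, settings=settings, engine=engine
        )["p"]
    if include_global_omega:
        fit = fit_global_omega(
            aln, tree, seed=seed + 97, settings=settings, engine=engine
        )
        out.global_omega = fit.parameters.get("omega", float("nan"))
    return out
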