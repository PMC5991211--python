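"""Simulation harness: synthetic LD panels and replicated estimation studies.

The harness mimics genome-scale summary statistics.  A set of independent
chromosomal regions is equipped with a band r² matrix from a synthetic
reference panel; mean-zero z-scores are drawn with marginal variance
beta1 + C * l_l * beta2 and correlation |r| (so the squared statistics have
correlation r², exactly the working-correlation premise of the GEE fit).
Each replication draws fresh z-scores, fits the GEE estimator — with the
correct working matrices and optionally with versions shrunk towards the
identity, emulating a misspecified reference panel — and the explicit WLS
comparator with true-parameter weights.  Summaries report empirical and
mean estimated standard errors and the relative efficiency per coordinate.

The reference panel itself comes from coalescent simulation (msprime) with
a uniform recombination map, so LD decays with genetic distance the way it
does in real panels and is effectively zero beyond 1 cM; no external data
download is needed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np
import pandas as pd

from . import gee, ldref, ldsc_compare

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticLDParams",
    "SimulationConfig",
    "SimulationResult",
    "StudyLD",
    "synthetic_haplotypes",
    "build_study_ld",
    "simulate_zscores",
    "replication_study",
]


@dataclass(frozen=True)
class SyntheticLDParams:
    """Coalescent-panel parameters for the synthetic LD generator.

    Defaults emulate a European-ancestry-sized reference panel: 200
    haplotypes, effective population size 10^4, mutation rate 1.2e-8 per bp
    per generation, and a uniform 1 cM/Mb genetic map (recombination rate
    1e-8 per bp), restricted to common variants (MAF >= 5%).
    """

    n_haplotypes: int = 200
    effective_population_size: float = 1.0e4
    mutation_rate: float = 1.2e-8
    cm_per_mb: float = 1.0
    maf_floor: float = 0.05
    hotspot_spacing_bp: float = 8e4
    hotspot_width_bp: float = 2e3
    hotspot_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.n_haplotypes < 4 or self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be an even integer >= 4")
        for name in ("effective_population_size", "mutation_rate", "cm_per_mb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.maf_floor < 0.5:
            raise ValueError("maf_floor must lie in (0, 0.5)")
        if not 0.0 <= self.hotspot_fraction < 1.0:
            raise ValueError("hotspot_fraction must lie in [0, 1)")
        if self.hotspot_width_bp >= self.hotspot_spacing_bp:
            raise ValueError("hotspot width must be smaller than hotspot spacing")


def _recombination_map(
    params: SyntheticLDParams, length: float, seed: int
) -> msprime.RateMap:
    """Hotspot recombination map with the requested total map length.

    Real genetic maps concentrate most recombination in narrow hotspots,
    which is what makes LD scores vary widely along the genome; a uniform
    map would homogenize them.  ``hotspot_fraction`` of the map length sits
    in hotspots of ``hotspot_width_bp`` spaced ``hotspot_spacing_bp`` on
    average; the remainder is uniform background.
    """
    total_morgans = length * params.cm_per_mb * 1e-8
    width = params.hotspot_width_bp
    n_hot = int(length // params.hotspot_spacing_bp)
    if params.hotspot_fraction == 0.0 or n_hot == 0:
        return msprime.RateMap(
            position=np.array([0.0, length]),
            rate=np.array([total_morgans / length]),
        )
    rng = np.random.default_rng(seed)
    starts = np.sort(rng.uniform(width, length - 2 * width, n_hot))
    starts = starts[np.concatenate([[True], np.diff(starts) > 2 * width])]
    n_hot = len(starts)
    hot_rate = params.hotspot_fraction * total_morgans / (n_hot * width)
    cold_rate = (1.0 - params.hotspot_fraction) * total_morgans / (length - n_hot * width)
    position, rate = [0.0], []
    for s in starts:
        position += [s, s + width]
        rate += [cold_rate, hot_rate]
    position.append(length)
    rate.append(cold_rate)
    return msprime.RateMap(position=np.array(position), rate=np.array(rate))


def synthetic_haplotypes(
    params: SyntheticLDParams,
    region_cm: float,
    seed: int,
    n_variants: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a phased panel for one region; returns (haplotypes, cM positions).

    Haplotypes have shape (n_haplotypes, n_variants); cM positions follow
    the region's hotspot recombination map.  Common variants (MAF >= floor)
    are thinned evenly along the region to ``n_variants`` when more are
    available.  Deterministic in ``seed``.
    """
    if region_cm <= 0:
        raise ValueError("region_cm must be positive")
    seed = int(seed)
    if not 1 <= seed < 2**31:
        raise ValueError("seed must lie in [1, 2^31)")
    length = region_cm / params.cm_per_mb * 1e6
    rate_map = _recombination_map(params, length, seed + 2)
    ts = msprime.sim_ancestry(
        samples=params.n_haplotypes // 2,
        ploidy=2,
        population_size=params.effective_population_size,
        sequence_length=length,
        recombination_rate=rate_map,
        random_seed=seed,
    )
    mts = msprime.sim_mutations(
        ts,
        rate=params.mutation_rate,
        random_seed=seed + 1,
        model=msprime.BinaryMutationModel(),
    )
    G = mts.genotype_matrix()  # (sites, haplotypes), alleles 0/1
    pos = mts.tables.sites.position
    freq = G.mean(axis=1)
    keep = np.minimum(freq, 1.0 - freq) >= params.maf_floor
    G, pos = G[keep], pos[keep]
    if n_variants is not None and len(pos) > n_variants:
        pick = np.unique(np.round(np.linspace(0, len(pos) - 1, n_variants)).astype(int))
        G, pos = G[pick], pos[pick]
    elif n_variants is not None and len(pos) < n_variants:
        logger.warning(
            "region yielded %d common variants, fewer than requested %d",
            len(pos),
            n_variants,
        )
    if G.shape[0] == 0:
        raise ValueError("no common variants simulated; increase mutation rate or region size")
    cm = rate_map.get_cumulative_mass(pos) * 100.0
    return G.T.astype(np.int8), cm


@dataclass(frozen=True)
class SimulationConfig:
    """One replicated estimation study.

    The default geometry is a desk-scale reduction of a genome-wide
    analysis: 5 independent regions of 5 cM with 500 common variants each
    (2,500 statistics in ~25 one-cM clusters).  ``shrink_factors`` lists
    the working-matrix scenarios fitted on the same draws: 1.0 means the
    working correlations equal the generation LD, smaller values shrink
    them towards the identity to emulate a misspecified reference panel.
    ``draws_per_region_set`` stacks independent copies of the region set,
    mirroring how a genome is larger than the simulated template.
    """

    beta1: float = 1.02
    beta2: float = 1e-3
    c_study: float = 1.0
    n_regions: int = 5
    region_cm: float = 5.0
    variants_per_region: int = 500
    shrink_factors: tuple[float, ...] = (1.0, 0.64)
    n_replications: int = 200
    draws_per_region_set: int = 1
    seed: int = 0
    ld: SyntheticLDParams = field(default_factory=SyntheticLDParams)

    def __post_init__(self) -> None:
        if self.n_replications < 1:
            raise ValueError("n_replications must be >= 1")
        if self.draws_per_region_set < 1:
            raise ValueError("draws_per_region_set must be >= 1")
        for s in self.shrink_factors:
            if not 0.0 <= s <= 1.0:
                raise ValueError("shrink factors must lie in [0, 1]")
        if self.n_regions < 1 or self.variants_per_region < 2:
            raise ValueError("need at least one region with >= 2 variants")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        raw = json.loads(Path(path).read_text())
        ld = SyntheticLDParams(**raw.pop("ld", {}))
        raw["shrink_factors"] = tuple(raw.get("shrink_factors", (1.0, 0.64)))
        return cls(ld=ld, **raw)

    def to_json(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class _Region:
    band: ldref.BandLDMatrix  # r^2 among regression variants (working correlations)
    scores: np.ndarray  # panel LD scores (over all common variants, 1 cM window)
    blocks: list[ldref.LDBlock]
    corr_factor: np.ndarray  # (m, m) factor F with F F' = corr(z) = signed r

    @property
    def regression_scores(self) -> np.ndarray:
        """LD scores restricted to the regression set (overcounting weights)."""
        return self.band.scores()


@dataclass
class StudyLD:
    """LD objects shared by every replication of one study."""

    regions: list[_Region]
    scores: np.ndarray  # concatenated over regions

    @property
    def n_variants(self) -> int:
        return len(self.scores)


def build_study_ld(config: SimulationConfig, r2_max: float = 0.999) -> StudyLD:
    """Simulate the panel once and precompute band LD, scores, blocks and factors.

    The regression set is an even thinning of the panel's common variants
    after collapsing groups in (near-)perfect LD (pairwise r² > ``r2_max``)
    to one representative — the same exclusion applied to real input, and
    the step that keeps the working matrices away from degeneracy.  LD
    scores are computed for each regression variant against the *full*
    common-variant panel within 1 cM, mirroring how pre-computed LD-score
    files are made, so they are larger and far more variable than row sums
    over the regression set alone.  The z-score generation uses the signed
    correlation r among regression variants (band-truncated, PSD-repaired),
    so that the squared statistics have correlation r², which is exactly
    what the working matrices assume.
    """
    from scipy import sparse as sp
    from scipy.sparse.csgraph import connected_components

    rng = np.random.default_rng(config.seed)
    region_seeds = rng.integers(1, 2**31 - 2, size=config.n_regions)
    cutoff_cm = 1.0
    regions: list[_Region] = []
    for r, s in enumerate(region_seeds):
        haps, cm_all = synthetic_haplotypes(config.ld, config.region_cm, int(s))
        Z = ldref._standardize(haps)
        n_hap, n_all = Z.shape
        # candidate regression variants: even thinning to 2x the target
        n_cand = min(n_all, 2 * config.variants_per_region)
        cand = np.unique(np.round(np.linspace(0, n_all - 1, n_cand)).astype(int))
        corr = Z[:, cand].T @ Z[:, cand] / n_hap
        corr[np.abs(cm_all[cand][:, None] - cm_all[cand][None, :]) > cutoff_cm] = 0.0
        np.fill_diagonal(corr, 1.0)
        # perfect-LD pruning: keep the first variant of each r^2-connected group
        _, labels = connected_components(
            sp.csr_matrix(corr**2 > r2_max), directed=False
        )
        keep = np.sort(np.unique(labels, return_index=True)[1])
        if len(keep) > config.variants_per_region:
            keep = keep[
                np.unique(
                    np.round(
                        np.linspace(0, len(keep) - 1, config.variants_per_region)
                    ).astype(int)
                )
            ]
        idx = cand[keep]
        corr = corr[np.ix_(keep, keep)]
        cm = cm_all[idx]
        # panel LD scores: r^2 of each kept variant against every common
        # panel variant within the window (includes itself)
        cross = Z[:, idx].T @ Z / n_hap
        window = np.abs(cm[:, None] - cm_all[None, :]) <= cutoff_cm
        scores = np.sum(cross**2 * window, axis=1)
        chrom = np.full(len(cm), f"region{r}", dtype=object)
        band = ldref.BandLDMatrix(
            r2=sp.csr_matrix(corr**2),
            chrom=chrom,
            bp=np.round(cm * 1e6).astype(int),
            cm=cm,
            cutoff_cm=cutoff_cm,
        )
        blocks = ldref.partition_blocks(cm, chrom, block_cm=1.0)
        gen_corr = ldref.psd_repair(corr)
        w, V = np.linalg.eigh(gen_corr)
        factor = V * np.sqrt(np.maximum(w, 0.0))
        regions.append(
            _Region(band=band, scores=scores, blocks=blocks, corr_factor=factor)
        )
    return StudyLD(regions=regions, scores=np.concatenate([r.scores for r in regions]))


def simulate_zscores(
    study: StudyLD,
    beta1: float,
    beta2: float,
    c_study: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One genome draw of correlated z-scores; returns (z, chi2 = z**2).

    Marginal variances are beta1 + c * l_l * beta2; the correlation within
    a region is |r| from the band LD matrix, zero across regions.
    """
    zs = []
    for reg in study.regions:
        var = beta1 + c_study * reg.scores * beta2
        if np.any(var <= 0):
            raise ValueError("variance beta1 + C l beta2 must be positive")
        eps = rng.standard_normal(reg.corr_factor.shape[1])
        zs.append(np.sqrt(var) * (reg.corr_factor @ eps))
    z = np.concatenate(zs)
    return z, z**2


def _study_problems(
    study: StudyLD, config: SimulationConfig
) -> tuple[dict[float, gee.GEEProblem], list[slice]]:
    """Per-scenario GEE problems (placeholder responses) and the stacked design."""
    base_R = [
        ldref.working_correlations(reg.band, reg.blocks) for reg in study.regions
    ]
    Xs: list[np.ndarray] = []
    slices: list[tuple[int, slice]] = []  # (region, local slice) per cluster
    for r, reg in enumerate(study.regions):
        for b in reg.blocks:
            l = reg.scores[b.start : b.stop]
            Xs.append(np.column_stack([np.ones(len(l)), config.c_study * l]))
            slices.append((r, slice(b.start, b.stop)))
    # adjacency: consecutive blocks within a region; region sets are
    # independent, and independent draws of the full set are appended as
    # additional (uncorrelated) copies of the same clusters.
    n_cluster_base = len(Xs)
    adj = set()
    offset = 0
    for reg in study.regions:
        for k in range(len(reg.blocks) - 1):
            adj.add((offset + k, offset + k + 1))
        offset += len(reg.blocks)
    D = config.draws_per_region_set
    all_X = Xs * D
    all_adj = set()
    for d in range(D):
        all_adj.update((i + d * n_cluster_base, j + d * n_cluster_base) for i, j in adj)
    problems = {}
    for s in config.shrink_factors:
        Rs = [
            ldref.shrink_correlation(R, s) if s != 1.0 else R
            for region_R in base_R
            for R in region_R
        ]
        placeholder = [np.ones(X.shape[0]) for X in all_X]
        problems[s] = gee.GEEProblem(
            placeholder, all_X, Rs * D, adjacency=frozenset(all_adj)
        )
    region_offsets = np.cumsum([0] + [len(r.scores) for r in study.regions])
    flat_slices = [
        slice(region_offsets[r] + sl.start, region_offsets[r] + sl.stop)
        for r, sl in slices
    ]
    return problems, flat_slices


@dataclass
class SimulationResult:
    """Per-replication estimates and the summaries derived from them."""

    config: SimulationConfig
    gee_estimates: dict[float, np.ndarray]  # s -> (reps, p)
    gee_se: dict[float, np.ndarray]  # s -> (reps, p), sandwich
    gee_converged: dict[float, np.ndarray]  # s -> (reps,) bool
    wls_estimates: np.ndarray  # (reps, p)

    def _ok(self, s: float) -> np.ndarray:
        return self.gee_converged[s]

    def n_failed(self, s: float) -> int:
        return int((~self._ok(s)).sum())

    def empirical_se(self, s: float) -> np.ndarray:
        return self.gee_estimates[s][self._ok(s)].std(axis=0, ddof=1)

    def mean_estimated_se(self, s: float) -> np.ndarray:
        return self.gee_se[s][self._ok(s)].mean(axis=0)

    def mean_estimate(self, s: float) -> np.ndarray:
        return self.gee_estimates[s][self._ok(s)].mean(axis=0)

    def wls_empirical_se(self) -> np.ndarray:
        return self.wls_estimates.std(axis=0, ddof=1)

    def relative_efficiency(self, s: float) -> np.ndarray:
        """100 * Var(GEE) / Var(WLS) per coordinate, on paired replications."""
        ok = self._ok(s)
        return ldsc_compare.relative_efficiency(
            self.gee_estimates[s][ok].var(axis=0, ddof=1),
            self.wls_estimates[ok].var(axis=0, ddof=1),
        )

    def wald_rejection_rate(self, s: float, coordinate: int = 1, alpha: float = 0.05) -> float:
        """Fraction of replications rejecting H0: beta_b = 0 at level alpha."""
        ok = self._ok(s)
        est = self.gee_estimates[s][ok][:, coordinate]
        se = self.gee_se[s][ok][:, coordinate]
        from scipy import stats

        pvals = stats.chi2.sf((est / se) ** 2, df=1)
        return float(np.mean(pvals < alpha))

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for s in self.config.shrink_factors:
            emp, est = self.empirical_se(s), self.mean_estimated_se(s)
            re = self.relative_efficiency(s)
            mean = self.mean_estimate(s)
            for b in range(len(emp)):
                rows.append(
                    {
                        "shrink": s,
                        "coordinate": f"beta{b + 1}",
                        "mean_estimate": mean[b],
                        "emp_se": emp[b],
                        "est_se": est[b],
                        "re_wls_pct": re[b],
                        "n_failed": self.n_failed(s),
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "config": json.loads(self.config.to_json()),
            "scenarios": {
                str(s): {
                    "estimates": self.gee_estimates[s].tolist(),
                    "se": self.gee_se[s].tolist(),
                    "converged": self.gee_converged[s].tolist(),
                }
                for s in self.config.shrink_factors
            },
            "wls_estimates": self.wls_estimates.tolist(),
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text


def replication_study(config: SimulationConfig) -> SimulationResult:
    """Run the full replication harness for one configuration.

    Builds the synthetic LD once, then per replication draws z-scores,
    fits the GEE estimator under every working-matrix scenario and the WLS
    comparator with true-parameter weights on the same data.  Deterministic
    in ``config.seed``.
    """
    study = build_study_ld(config)
    problems, cluster_slices = _study_problems(study, config)
    D = config.draws_per_region_set
    # true-parameter heteroscedasticity weights; the overcounting part uses
    # LD scores restricted to the regression set
    l_all = np.tile(study.scores, D)
    l_win = np.tile(
        np.concatenate([reg.regression_scores for reg in study.regions]), D
    )
    mu_true = config.beta1 + config.c_study * l_all * config.beta2
    w = ldsc_compare.wls_weights(l_win, mu_true)
    X_wls = np.column_stack([np.ones(len(l_all)), config.c_study * l_all])

    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    R = config.n_replications
    p = 2
    gee_est = {s: np.empty((R, p)) for s in config.shrink_factors}
    gee_se = {s: np.empty((R, p)) for s in config.shrink_factors}
    gee_ok = {s: np.zeros(R, dtype=bool) for s in config.shrink_factors}
    wls_est = np.empty((R, p))
    for rep in range(R):
        chis = []
        for _ in range(D):
            _, chi2 = simulate_zscores(
                study, config.beta1, config.beta2, config.c_study, rng
            )
            chis.append(chi2)
        y_full = np.concatenate(chis)
        ys = [
            chis[d][sl] for d in range(D) for sl in cluster_slices
        ]
        for s, prob in problems.items():
            fit = gee.solve(prob.with_responses(ys))
            gee_est[s][rep] = fit.beta
            gee_se[s][rep] = fit.se
            # fits whose corrected sandwich is indefinite (NaN SE, possible
            # at small cluster counts) are excluded alongside non-converged
            gee_ok[s][rep] = fit.converged and bool(np.isfinite(fit.se).all())
        wls_est[rep] = ldsc_compare.wls_fit(y_full, X_wls, w)
    for s in config.shrink_factors:
        nf = int((~gee_ok[s]).sum())
        if nf:
            logger.warning(
                "scenario s=%.2f: %d/%d replications excluded "
                "(non-convergence or indefinite sandwich)",
                s,
                nf,
                R,
            )
    return SimulationResult(
        config=config,
        gee_estimates=gee_est,
        gee_se=gee_se,
        gee_converged=gee_ok,
        wls_estimates=wls_est,
    )
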