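"""Marginal model for genome-wide single-variant association statistics.

A chi-square association statistic :math:`\\chi^2_l` is described by its
first two moments only,

.. math::

    E[\\chi^2_l]   = \\beta_1 + C_{study}\\, l_l\\, \\beta_2, \\qquad
    Var(\\chi^2_l) = \\phi\\, (E[\\chi^2_l])^2,

where :math:`l_l` is the LD score of variant *l* (sum of :math:`r^2` with
all variants within a 1 cM window, including itself).  The intercept
``beta1`` absorbs genome-wide confounding inflation (``1 + N a`` for a
stratification level *a*), the slope ``beta2`` carries the polygenic signal
and equals the heritability :math:`h^2` on the observed scale, and the
design constant ``C_study`` converts per-SNP heritability into the expected
inflation of the study's statistics.  ``C_study`` depends only on a-priori
known design quantities — sample sizes, case/control split, disease
prevalence, family composition and the FBAT offset — so the same estimation
machinery covers population-based studies, family-based studies and
mixtures of both.

``phi`` is a dispersion nuisance parameter; under normally distributed
genetic effects it equals 2 (the chi-square value), but nothing downstream
assumes that.
"""

from __future__ import annotations

import configparser
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "LiabilityContext",
    "ModelParams",
    "StudyDesign",
    "liability_context",
    "explained_variance",
    "c_study",
    "mean_vector",
    "read_design",
]


@dataclass(frozen=True)
class LiabilityContext:
    """Liability-threshold quantities for a disease of prevalence ``K``.

    ``t`` is the standard-normal density at the ``1 - K`` quantile and
    ``c = t / K`` the factor that scales relative-risk effects onto the
    liability scale.
    """

    K: float
    t: float
    c: float


def liability_context(K: float) -> LiabilityContext:
    """Build the liability-scale context for prevalence ``K`` in (0, 1)."""
    if not 0.0 < K < 1.0:
        raise ValueError(f"prevalence K must lie in (0, 1), got {K}")
    t = stats.norm.pdf(stats.norm.ppf(1.0 - K))
    return LiabilityContext(K=K, t=t, c=t / K)


def explained_variance(p: float, lam: float, ctx: LiabilityContext) -> float:
    """Liability-scale variance fraction explained by one causal variant.

    Under a multiplicative relative-risk model a variant with minor-allele
    frequency ``p`` and relative risk ``lam`` explains

    .. math:: q^2 = 2 p (1 - p) (\\lambda - 1)^2 / c^2

    of the liability variance.  Exactly quadratic in ``lam - 1`` and zero
    iff ``lam == 1``.
    """
    if not 0.0 < p <= 0.5:
        raise ValueError(f"minor-allele frequency must lie in (0, 0.5], got {p}")
    if lam <= 0:
        raise ValueError(f"relative risk must be positive, got {lam}")
    return 2.0 * p * (1.0 - p) * (lam - 1.0) ** 2 / ctx.c**2


@dataclass(frozen=True)
class ModelParams:
    """Fitted or true parameters of the marginal model."""

    beta1: float
    beta2: float
    phi: float = 2.0

    def __post_init__(self) -> None:
        if self.phi <= 0:
            raise ValueError(f"dispersion phi must be positive, got {self.phi}")

    def per_snp_heritability(self, M: float) -> float:
        """Average per-SNP heritability ``beta2 / M`` for ``M`` common SNPs.

        ``beta2`` itself is the total polygenic term (h² on the observed
        scale when C_study folds in 1/M).
        """
        return self.beta2 / M


_KINDS = ("case_control", "quantitative", "family", "mixture")


@dataclass(frozen=True)
class StudyDesign:
    """Everything needed to compute ``C_study`` for one design or a mixture.

    Parameters
    ----------
    kind
        One of ``case_control``, ``quantitative``, ``family``, ``mixture``.
    N
        Sample size: individuals (population designs) or families.
    M
        Number of common SNPs (MAF >= 5%) scaling per-SNP heritability.
    n_cases, n_controls
        Case/control counts; ``case_control`` only.
    K
        Disease prevalence; ``case_control`` and ``family``.
    z
        FBAT offset in [0, 1]; ``family`` only.
    n_a, n_u
        Affected / unaffected offspring per family; ``family`` only.
    components, weights
        Component designs and their weights; ``mixture`` only.  Weights
        default to being proportional to each component's sample size.
    """

    kind: str
    N: float | None = None
    M: float | None = None
    n_cases: float | None = None
    n_controls: float | None = None
    K: float | None = None
    z: float | None = None
    n_a: float | None = None
    n_u: float | None = None
    components: tuple["StudyDesign", ...] = field(default=())
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown design kind {self.kind!r}; expected one of {_KINDS}")
        if self.kind == "mixture":
            if len(self.components) < 1:
                raise ValueError("mixture design needs at least one component")
            if self.weights is not None:
                if len(self.weights) != len(self.components):
                    raise ValueError("one weight per mixture component required")
                total = float(sum(self.weights))
                if not np.isclose(total, 1.0):
                    raise ValueError(f"mixture weights must sum to 1, got {total}")
            return
        if self.N is None or self.N <= 0:
            raise ValueError("sample size N must be positive")
        if self.M is None or self.M <= 0:
            raise ValueError("common-SNP count M must be positive")
        if self.kind == "case_control":
            if self.n_cases is None or self.n_controls is None:
                raise ValueError("case_control design needs n_cases and n_controls")
            if not np.isclose(self.n_cases + self.n_controls, self.N):
                raise ValueError("n_cases + n_controls must equal N")
            self._require_prevalence()
        elif self.kind == "family":
            self._require_prevalence()
            if self.z is None or not 0.0 <= self.z <= 1.0:
                raise ValueError("family design needs FBAT offset z in [0, 1]")
            if self.n_a is None or self.n_u is None or self.n_a < 0 or self.n_u < 0:
                raise ValueError("family design needs nonnegative offspring counts n_a, n_u")
            denom = (1.0 - self.z) ** 2 * self.n_a + self.z**2 * self.n_u
            if denom <= 0:
                raise ValueError(
                    "degenerate family design: (1-z)^2 n_a + z^2 n_u must be positive"
                )

    def _require_prevalence(self) -> None:
        if self.K is None or not 0.0 < self.K < 1.0:
            raise ValueError(f"{self.kind} design needs prevalence K in (0, 1)")

    def mixture_weights(self) -> tuple[float, ...]:
        """Effective weights of a mixture (default: proportional to N)."""
        if self.kind != "mixture":
            raise ValueError("mixture_weights only applies to mixture designs")
        if self.weights is not None:
            return self.weights
        sizes = np.array([c.N for c in self.components], dtype=float)
        return tuple(sizes / sizes.sum())


def c_study(design: StudyDesign) -> float:
    """Design constant converting per-SNP heritability to statistic inflation.

    * case-control:  ``n_cases n_controls c^2 / ((1-K)^2 N M)``
    * quantitative:  ``N / M``
    * family (FBAT): ``c^2 (N/2) ((1-z) n_a + z K/(1-K) n_u)^2
      / ((1-z)^2 n_a + z^2 n_u) / M``
    * mixture:       weighted sum of the component constants.
    """
    if design.kind == "quantitative":
        return design.N / design.M
    if design.kind == "case_control":
        c2 = liability_context(design.K).c ** 2
        return (
            design.n_cases
            * design.n_controls
            * c2
            / ((1.0 - design.K) ** 2 * design.N * design.M)
        )
    if design.kind == "family":
        c2 = liability_context(design.K).c ** 2
        num = ((1.0 - design.z) * design.n_a + design.z * design.K / (1.0 - design.K) * design.n_u) ** 2
        den = (1.0 - design.z) ** 2 * design.n_a + design.z**2 * design.n_u
        return c2 * 0.5 * design.N * num / den / design.M
    # mixture
    weights = design.mixture_weights()
    return float(sum(w * c_study(c) for w, c in zip(weights, design.components)))


def mean_vector(
    beta1: float,
    beta2: float,
    ld_scores: Sequence[float] | np.ndarray,
    c: float = 1.0,
) -> np.ndarray:
    """Per-variant means ``mu_l = beta1 + c * l_l * beta2``.

    Raises if any LD score is below 1 (every variant is in perfect LD with
    itself) or if any resulting mean is nonpositive, which would break the
    quadratic variance model.
    """
    l = np.asarray(ld_scores, dtype=float)
    if np.any(l < 1.0 - 1e-9):
        raise ValueError("LD scores must be >= 1 (self r^2 is included)")
    mu = beta1 + c * l * beta2
    if np.any(mu <= 0.0):
        raise ValueError("inadmissible parameters: some mean mu_l <= 0")
    return mu


# ---------------------------------------------------------------------------
# plain-text design configuration
# ---------------------------------------------------------------------------

_FLOAT_KEYS = {"n", "m", "n_cases", "n_controls", "k", "z", "n_a", "n_u", "weight"}


def _design_from_items(items: dict[str, str]) -> tuple[StudyDesign, float | None]:
    kind = items.pop("kind", None)
    if kind is None:
        raise ValueError("design config needs a 'kind' key")
    vals: dict[str, float] = {}
    for key, raw in items.items():
        lk = key.lower()
        if lk not in _FLOAT_KEYS:
            raise ValueError(f"unknown design key {key!r}")
        vals[lk] = float(raw)
    weight = vals.pop("weight", None)
    design = StudyDesign(
        kind=kind.strip().lower(),
        N=vals.get("n"),
        M=vals.get("m"),
        n_cases=vals.get("n_cases"),
        n_controls=vals.get("n_controls"),
        K=vals.get("k"),
        z=vals.get("z"),
        n_a=vals.get("n_a"),
        n_u=vals.get("n_u"),
    )
    return design, weight


def read_design(path: str | Path) -> StudyDesign:
    """Read a study design from a ``key = value`` text file.

    A file without section headers describes a single design.  A file with
    several ``[name]`` sections describes a mixture; each section may carry
    an optional ``weight`` (all or none), otherwise weights default to
    component sample sizes.
    """
    text = Path(path).read_text()
    if not re.search(r"^\s*\[", text, re.MULTILINE):
        text = "[design]\n" + text
    cp = configparser.ConfigParser()
    cp.read_string(text)
    sections = cp.sections()
    parsed = [_design_from_items(dict(cp[s])) for s in sections]
    if len(parsed) == 1:
        return parsed[0][0]
    designs = tuple(d for d, _ in parsed)
    weights_raw = [w for _, w in parsed]
    if any(w is not None for w in weights_raw):
        if any(w is None for w in weights_raw):
            raise ValueError("either all mixture components carry a weight or none")
        weights = tuple(float(w) for w in weights_raw)
    else:
        weights = None
    return StudyDesign(kind="mixture", components=designs, weights=weights)
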