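"""Quantitative EMSA (gel mobility-shift) binding analysis.

Single-step n-mer binding model: n protein monomers P associate with one
nucleic-acid ligand R in a single step,

    Kn = [PnR] / ([R] [P]_free^n)        (units M^-n)

Log-linearising,

    ln([PnR]/[R]) = n ln[P]_free + ln Kn

so in the trace-ligand regime ([R]_total << [P]_total, where [P]_total
approximates [P]_free) an ordinary least-squares fit of ln(bound/free)
against ln[P]_total yields the stoichiometry n as the slope and ln Kn as
the intercept.  At the binding midpoint (bound = free) ln Kn = -n ln[P],
so the monomer-equivalent association constant

    K = Kn^(1/n) = exp(ln Kn / n)        (units M^-1)

is the reciprocal of the midpoint protein concentration.

For competition between two co-incubated ligands (DNA with stoichiometry m,
RNA with stoichiometry n) whose protein complexes co-migrate, the relative
affinity is computed from free-band disappearance:

    K_DNA/K_RNA = ([PmD]/([D][P]^m)) / ([PnR]/([R][P]^n))

with [PmD] = ([D]0 - [D]_free) * m and [PnR] = ([R]0 - [R]_free) * n.
The per-concentration ratio is extrapolated linearly to [P] = 0 over the
low-concentration (least-saturated) part of the series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TitrationSeries",
    "BindingFit",
    "CompetitionSeries",
    "CompetitionResult",
    "fraction_bound",
    "fit_stoichiometry_affinity",
    "monomer_equivalent_K",
    "competition_ratio",
]


def fraction_bound(p_total, n: float, K: float):
    """Noiseless fraction of ligand bound at total protein ``p_total``.

    ``K`` is the monomer-equivalent association constant (M^-1); the overall
    constant is Kn = K**n.  Vectorised over ``p_total``.
    """
    p = np.asarray(p_total, dtype=float)
    with np.errstate(divide="ignore"):
        x = np.where(p > 0, np.exp(n * (np.log(K) + np.log(np.where(p > 0, p, 1.0)))), 0.0)
    return x / (1.0 + x)


@dataclass
class TitrationSeries:
    """One gel-shift titration: ligand fraction bound vs total protein."""

    protein_M: np.ndarray          # total protein concentrations (M)
    fraction_bound: np.ndarray     # in [0, 1]
    species: str = "RNA"
    ligand_total_M: float = 5e-8
    protein_name: str = ""

    def __post_init__(self):
        self.protein_M = np.asarray(self.protein_M, dtype=float)
        self.fraction_bound = np.asarray(self.fraction_bound, dtype=float)
        if self.protein_M.shape != self.fraction_bound.shape:
            raise ValueError("protein_M and fraction_bound must have equal length")
        if np.any(self.protein_M < 0):
            raise ValueError("protein concentrations must be >= 0")
        if np.any((self.fraction_bound < 0) | (self.fraction_bound > 1)):
            raise ValueError("fractions bound must lie in [0, 1]")


@dataclass
class BindingFit:
    n: float                # stoichiometry (slope)
    ln_Kn: float            # intercept, ln of the overall constant (M^-n)
    K: float                # monomer-equivalent association constant (M^-1)
    se_n: float
    se_ln_Kn: float
    r_squared: float
    n_points_used: int
    usable_mask: np.ndarray = field(repr=False, default=None)

    @property
    def midpoint_M(self) -> float:
        """Protein concentration at which bound = free (= 1/K)."""
        return 1.0 / self.K


#: default saturation window for the log-log fit (Hill-plot convention:
#: the slope is estimated over the 20-80% bound range, where the log-odds
#: transform is well conditioned and gel bands are robustly quantifiable)
SATURATION_WINDOW = (0.2, 0.8)


def fit_stoichiometry_affinity(
    series: TitrationSeries,
    saturation_window: tuple = SATURATION_WINDOW,
) -> BindingFit:
    """OLS fit of ln(bound/free) on ln[P]_total.

    Points with fraction bound outside the saturation window are excluded
    from the regression (fractions exactly 0 or 1 make the log undefined;
    near-saturated lanes carry log-amplified quantitation noise), as are
    non-positive protein concentrations.  If fewer than three points fall
    inside the window the fit falls back to every interior point (0, 1);
    at least three of those are required.  Pass ``saturation_window=(0, 1)``
    to keep every interior point from the start.
    """
    lo, hi = saturation_window
    p = series.protein_M
    fb = series.fraction_bound
    usable = (p > 0) & (fb > max(lo, 0.0)) & (fb < min(hi, 1.0))
    if usable.sum() < 3 and (lo, hi) != (0.0, 1.0):
        usable = (p > 0) & (fb > 0.0) & (fb < 1.0)
        lo, hi = 0.0, 1.0
    if usable.sum() < 3:
        raise ValueError(
            f"need >= 3 points with fraction_bound inside ({lo}, {hi}) and "
            f"[P] > 0; got {int(usable.sum())}"
        )
    x = np.log(p[usable])
    y = np.log(fb[usable] / (1.0 - fb[usable]))
    res = stats.linregress(x, y)
    n = res.slope
    ln_kn = res.intercept
    if n <= 0:
        raise ValueError(f"fitted stoichiometry is non-positive ({n:.3g})")
    return BindingFit(
        n=n,
        ln_Kn=ln_kn,
        K=math.exp(ln_kn / n),
        se_n=res.stderr,
        se_ln_Kn=res.intercept_stderr,
        r_squared=res.rvalue**2,
        n_points_used=int(usable.sum()),
        usable_mask=usable,
    )


def monomer_equivalent_K(fit: BindingFit) -> float:
    """Monomer-equivalent association constant K = exp(ln Kn / n), M^-1."""
    if fit.n <= 0:
        raise ValueError("stoichiometry must be positive")
    return math.exp(fit.ln_Kn / fit.n)


@dataclass
class CompetitionSeries:
    """Equimolar two-ligand competition: per-species free fractions on a
    shared protein grid.  Stoichiometries m (DNA) and n (RNA) come from
    single-ligand titration fits."""

    protein_M: np.ndarray
    dna_free_fraction: np.ndarray   # [D]_free / [D]0
    rna_free_fraction: np.ndarray   # [R]_free / [R]0
    m: float = 1.0
    n: float = 1.0
    dna_total_M: float = 5e-8
    rna_total_M: float = 5e-8
    protein_name: str = ""

    def __post_init__(self):
        self.protein_M = np.asarray(self.protein_M, dtype=float)
        self.dna_free_fraction = np.asarray(self.dna_free_fraction, dtype=float)
        self.rna_free_fraction = np.asarray(self.rna_free_fraction, dtype=float)
        if not (
            len(self.protein_M)
            == len(self.dna_free_fraction)
            == len(self.rna_free_fraction)
        ):
            raise ValueError("competition series arrays must have equal length")
        if np.any(self.protein_M < 0):
            raise ValueError("protein concentrations must be >= 0")

    def swapped(self) -> "CompetitionSeries":
        """The same experiment with the DNA and RNA roles exchanged."""
        return CompetitionSeries(
            protein_M=self.protein_M,
            dna_free_fraction=self.rna_free_fraction,
            rna_free_fraction=self.dna_free_fraction,
            m=self.n,
            n=self.m,
            dna_total_M=self.rna_total_M,
            rna_total_M=self.dna_total_M,
            protein_name=self.protein_name,
        )


@dataclass
class CompetitionResult:
    protein_M: np.ndarray           # usable grid points
    ratio: np.ndarray               # per-point K_DNA/K_RNA
    k_dna_over_k_rna: float         # intercept of the linear extrapolation to P=0
    k_rna_over_k_dna: float
    slope: float                    # slope of ratio vs P over the fitted region
    n_points_used: int
    extrapolation_mask: np.ndarray = field(repr=False, default=None)


#: band-quantitation floor: a free band (or its disappearance) smaller than
#: this fraction of the total is treated as unquantifiable on the gel image
QUANTITATION_LIMIT = 0.05


def _extrapolated_ratio(
    p, a_free, a_total, m, b_free, b_total, n, q, extrapolation_fraction
):
    """Intercept at P = 0 of the per-point ratio
    ([P_m A]/[A]_free) * P^(n-m) / ([P_n B]/[B]_free) with
    [P_m A] = (A0 - A_free) * m, fitted linearly against P."""
    usable = (p > 0) & (a_free > q) & (a_free < 1 - q) & (b_free > q) & (b_free < 1 - q)
    if usable.sum() < 3 and q > 0:
        # quantitation window starved by noise: fall back to interior points
        usable = (p > 0) & (a_free > 0) & (a_free < 1) & (b_free > 0) & (b_free < 1)
        q = 0.0
    if usable.sum() < 3:
        raise ValueError(
            f"need >= 3 usable points with free fractions in ({q}, {1 - q}); "
            f"got {int(usable.sum())}"
        )
    pu = p[usable]
    af = a_free[usable] * a_total
    bf = b_free[usable] * b_total
    bound_a = (a_total - af) * m
    bound_b = (b_total - bf) * n
    ratio = (bound_a / af) * pu ** (n - m) / (bound_b / bf)
    order = np.argsort(pu)
    k = max(3, int(round(len(pu) * extrapolation_fraction)))
    low = order[:k]
    if len(np.unique(pu[low])) > 1:
        res = stats.linregress(pu[low], ratio[low])
        intercept, slope = float(res.intercept), float(res.slope)
    else:  # degenerate grid: fall back to the mean
        intercept, slope = float(np.mean(ratio[low])), 0.0
    mask = np.zeros(len(pu), dtype=bool)
    mask[low] = True
    return pu, ratio, intercept, slope, int(usable.sum()), mask


def competition_ratio(
    series: CompetitionSeries,
    extrapolation_fraction: float = 1.0,
    quantitation_limit: float = QUANTITATION_LIMIT,
) -> CompetitionResult:
    """Per-point affinity ratio and its linear extrapolation to zero protein.

    At each usable concentration P (both free fractions inside the
    band-quantitation window, P > 0):

        ratio = ([PmD]/[D]_free) * P^(n-m) / ([PnR]/[R]_free)

    The ratio is fitted linearly against P over the lowest-concentration
    ``extrapolation_fraction`` of usable points (default all of them: the
    quantitation window already restricts the fit to modestly saturated
    lanes) and the reported K_DNA/K_RNA is the intercept at P = 0.

    The RNA-preference direction K_RNA/K_DNA is estimated by refitting with
    the species roles exchanged rather than by inverting the intercept: the
    reciprocal of a noisy intercept is itself a skew-biased estimator,
    while the swapped fit stays unbiased in its own orientation.  On
    noiseless data the two directions are exact reciprocals.
    """
    p = series.protein_M
    df = series.dna_free_fraction
    rf = series.rna_free_fraction
    if not np.any((df > 0) & (rf > 0)):
        raise ValueError("all points saturated (free fractions 0)")
    q = quantitation_limit
    pu, ratio, intercept, slope, n_used, mask = _extrapolated_ratio(
        p, df, series.dna_total_M, series.m, rf, series.rna_total_M, series.n,
        q, extrapolation_fraction,
    )
    _pu, _r, rna_pref, _s, _n, _m = _extrapolated_ratio(
        p, rf, series.rna_total_M, series.n, df, series.dna_total_M, series.m,
        q, extrapolation_fraction,
    )
    return CompetitionResult(
        protein_M=pu,
        ratio=ratio,
        k_dna_over_k_rna=intercept,
        k_rna_over_k_dna=rna_pref,
        slope=slope,
        n_points_used=n_used,
        extrapolation_mask=mask,
    )


def bootstrap_fit_se(series: TitrationSeries, n_boot: int = 500, seed: int = 0):
    """Seeded case-resampling bootstrap standard errors for (n, K)."""
    rng = np.random.default_rng(seed)
    p = series.protein_M
    fb = series.fraction_bound
    usable = (p > 0) & (fb > 0) & (fb < 1)
    idx = np.flatnonzero(usable)
    ns, ks = [], []
    for _ in range(n_boot):
        take = rng.choice(idx, size=len(idx), replace=True)
        if len(np.unique(p[take])) < 3:
            continue
        try:
            fit = fit_stoichiometry_affinity(
                TitrationSeries(p[take], fb[take], species=series.species)
            )
        except ValueError:
            continue
        ns.append(fit.n)
        ks.append(fit.K)
    if len(ns) < 2:
        return float("nan"), float("nan")
    return float(np.std(ns, ddof=1)), float(np.std(ks, ddof=1))
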