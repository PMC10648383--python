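"""Permutation-based morphometric inference.

Implements the inferential layer of a wing-morphometrics study: one-way
ANOVA on centroid size (parametric and permutation p), the Procrustes
shape-on-size regression used to test allometry, Procrustes-variance
("morphological disparity") group comparisons, and observer-repeatability
summaries for replicated digitizations.

Permutation scheme: the predictor (group labels or the size covariate) is
fully randomized, which for these single-factor designs coincides with
residual randomization under the intercept-only reduced model.  The observed
statistic is counted among the permutations, giving the valid
p = (c + 1) / (N + 1) estimator, and the standardized effect size is
Z = (F_obs − mean F_perm) / sd F_perm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class PermutationTestResult:
    statistic_F: float
    df_model: int
    df_resid: int
    r_squared: float
    p_value: float | None
    z_score: float | None
    n_permutations: int
    parametric_p: float | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "F": self.statistic_F,
            "df_model": self.df_model,
            "df_resid": self.df_resid,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "z_score": self.z_score,
            "n_permutations": self.n_permutations,
            "parametric_p": self.parametric_p,
            "seed": self.seed,
        }


@dataclass
class DisparityResult:
    """Per-group Procrustes variance (mean squared distance from the group
    mean, denominator n) with pairwise absolute contrasts."""

    group_variances: dict[str, float]
    group_sizes: dict[str, int]
    pairwise_abs_differences: dict[tuple[str, str], float] = field(
        default_factory=dict
    )
    pairwise_p: dict[tuple[str, str], float] | None = None
    n_permutations: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        out = {
            "group_variances": dict(self.group_variances),
            "group_sizes": dict(self.group_sizes),
            "pairwise_abs_differences": {
                f"{a}|{b}": v for (a, b), v in self.pairwise_abs_differences.items()
            },
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }
        if self.pairwise_p is not None:
            out["pairwise_p"] = {
                f"{a}|{b}": v for (a, b), v in self.pairwise_p.items()
            }
        return out


def _anova_f(values: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float, float]:
    """One-way ANOVA F plus (SS_between, SS_within) for coded groups."""
    grand = values.mean()
    ss_total = float(np.sum((values - grand) ** 2))
    ss_within = 0.0
    for g in range(n_groups):
        v = values[codes == g]
        ss_within += float(np.sum((v - v.mean()) ** 2))
    ss_between = ss_total - ss_within
    n = values.size
    df_b, df_w = n_groups - 1, n - n_groups
    if ss_within == 0.0:
        f = np.inf if ss_between > 0 else 0.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
    return f, ss_between, ss_total


def size_anova(
    sizes: np.ndarray,
    groups,
    n_permutations: int = 0,
    seed: int | None = None,
) -> PermutationTestResult:
    """One-way ANOVA of centroid size on a categorical factor.

    Reports the classical F with its parametric p (F distribution), and, when
    ``n_permutations > 0``, a permutation p and Z score obtained by shuffling
    the group labels.
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.ndim != 1:
        raise ValueError("sizes must be a 1-D array")
    if np.any(sizes <= 0):
        raise ValueError("centroid sizes must be strictly positive")
    labels = np.asarray(groups)
    if labels.shape != sizes.shape:
        raise ValueError("groups must align with sizes")
    uniq, codes = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("grouping factor must have at least two levels")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError("every group needs at least two specimens")

    n = sizes.size
    g = uniq.size
    f_obs, ss_between, ss_total = _anova_f(sizes, codes, g)
    df_model, df_resid = g - 1, n - g
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    parametric_p = float(sps.f.sf(f_obs, df_model, df_resid)) if np.isfinite(f_obs) else 0.0
    if f_obs == 0.0:
        parametric_p = 1.0

    p_value = None
    z = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        f_perm = np.empty(n_permutations)
        for i in range(n_permutations):
            perm_codes = rng.permutation(codes)
            f_perm[i], _, _ = _anova_f(sizes, perm_codes, g)
        p_value = (np.sum(f_perm >= f_obs) + 1.0) / (n_permutations + 1.0)
        sd = f_perm.std(ddof=1)
        z = float((f_obs - f_perm.mean()) / sd) if sd > 0 else float("nan")

    return PermutationTestResult(
        statistic_F=float(f_obs),
        df_model=df_model,
        df_resid=df_resid,
        r_squared=float(r2),
        p_value=float(p_value) if p_value is not None else None,
        z_score=z,
        n_permutations=n_permutations,
        parametric_p=parametric_p,
        seed=seed,
    )


def allometry_regression(
    shapes: np.ndarray,
    sizes: np.ndarray,
    n_permutations: int = 1000,
    seed: int | None = None,
    log_size: bool = False,
) -> PermutationTestResult:
    """Procrustes regression of shape on centroid size (allometry test).

    Each of the 2k superimposed coordinate columns is regressed on the size
    covariate by least squares; the summed explained and residual sums of
    squares across columns are sums of squared Procrustes deviations, so
    R² = SS_model / SS_total is the shape variance explained by size and
    F = (SS_model / 1) / (SS_resid / (n − 2)).  Significance comes from
    permuting the specimen-to-size assignment.
    """
    shapes = np.asarray(shapes, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if shapes.ndim != 2:
        raise ValueError("shapes must be an (n, 2k) matrix of shape vectors")
    n = shapes.shape[0]
    if sizes.shape != (n,):
        raise ValueError("sizes must align with shapes")
    if n <= 2:
        raise ValueError("allometry regression needs n > 2 specimens")
    x = np.log(sizes) if log_size else sizes.copy()
    xc = x - x.mean()
    sxx = float(np.sum(xc**2))
    if sxx == 0.0:
        raise ValueError("size covariate is constant; slope undefined")

    yc = shapes - shapes.mean(axis=0)
    ss_total = float(np.sum(yc**2))
    if ss_total == 0.0:
        raise ValueError("shape matrix has no variation")

    def ss_model_for(x_centered: np.ndarray) -> float:
        # per-column SS_model = (xcᵀ y_j)² / Sxx, summed over columns
        proj = x_centered @ yc
        return float(np.sum(proj**2)) / sxx

    ss_model = ss_model_for(xc)
    ss_resid = ss_total - ss_model
    df_model, df_resid = 1, n - 2
    f_obs = (ss_model / df_model) / (ss_resid / df_resid) if ss_resid > 0 else np.inf
    r2 = ss_model / ss_total

    p_value = None
    z = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        # vectorized: rows of P are permuted centered covariates
        perm = np.empty((n_permutations, n))
        for i in range(n_permutations):
            perm[i] = rng.permutation(xc)
        ss_model_perm = np.sum((perm @ yc) ** 2, axis=1) / sxx
        ss_resid_perm = ss_total - ss_model_perm
        with np.errstate(divide="ignore"):
            f_perm = (ss_model_perm / df_model) / (ss_resid_perm / df_resid)
        p_value = (np.sum(f_perm >= f_obs) + 1.0) / (n_permutations + 1.0)
        sd = f_perm.std(ddof=1)
        z = float((f_obs - f_perm.mean()) / sd) if sd > 0 else float("nan")

    return PermutationTestResult(
        statistic_F=float(f_obs),
        df_model=df_model,
        df_resid=df_resid,
        r_squared=float(r2),
        p_value=float(p_value) if p_value is not None else None,
        z_score=z,
        n_permutations=n_permutations,
        seed=seed,
    )


def morphological_disparity(
    shapes: np.ndarray,
    groups,
    n_permutations: int = 0,
    seed: int | None = None,
) -> DisparityResult:
    """Morphological disparity: per-group Procrustes variance.

    PV_g = (1/n_g) Σ ||v_i − mean_g||² over the group's shape vectors
    (denominator n, i.e. a *mean* squared distance).  Pairwise absolute
    differences between group PVs can be tested by permuting group labels.
    """
    shapes = np.asarray(shapes, dtype=float)
    labels = np.asarray(groups)
    if shapes.ndim != 2 or labels.shape != (shapes.shape[0],):
        raise ValueError("shapes must be (n, 2k) with one group label per row")
    uniq, codes = np.unique(labels, return_inverse=True)
    counts = np.bincount(codes)
    if counts.min() < 1:
        raise ValueError("every group must be nonempty")

    def group_pvs(c: np.ndarray) -> np.ndarray:
        pvs = np.empty(uniq.size)
        for g in range(uniq.size):
            v = shapes[c == g]
            pvs[g] = np.sum((v - v.mean(axis=0)) ** 2) / v.shape[0]
        return pvs

    pv_obs = group_pvs(codes)
    names = [str(u) for u in uniq]
    pairs = [
        (names[a], names[b])
        for a in range(len(names))
        for b in range(a + 1, len(names))
    ]
    idx_pairs = [
        (a, b) for a in range(len(names)) for b in range(a + 1, len(names))
    ]
    diffs_obs = {
        pairs[j]: float(abs(pv_obs[a] - pv_obs[b]))
        for j, (a, b) in enumerate(idx_pairs)
    }

    pairwise_p = None
    if n_permutations > 0 and pairs:
        rng = np.random.default_rng(seed)
        exceed = {p: 0 for p in pairs}
        for _ in range(n_permutations):
            pv = group_pvs(rng.permutation(codes))
            for j, (a, b) in enumerate(idx_pairs):
                if abs(pv[a] - pv[b]) >= diffs_obs[pairs[j]]:
                    exceed[pairs[j]] += 1
        pairwise_p = {
            p: (exceed[p] + 1.0) / (n_permutations + 1.0) for p in pairs
        }

    return DisparityResult(
        group_variances={names[g]: float(pv_obs[g]) for g in range(uniq.size)},
        group_sizes={names[g]: int(counts[g]) for g in range(uniq.size)},
        pairwise_abs_differences=diffs_obs,
        pairwise_p=pairwise_p,
        n_permutations=n_permutations,
        seed=seed,
    )


def observer_size_effect(
    sizes: np.ndarray,
    observers,
    specimens=None,
    n_permutations: int = 500,
    seed: int | None = None,
) -> PermutationTestResult:
    """ANOVA of centroid size on observer for a replicated digitization design.

    When specimen identities are supplied, the design is checked to be fully
    crossed (every specimen measured by every observer).  The test itself is
    the plain one-way permutation ANOVA of size on observer.
    """
    observers = np.asarray(observers)
    uniq = np.unique(observers)
    if uniq.size < 2:
        raise ValueError("need at least two observer levels")
    if specimens is not None:
        specimens = np.asarray(specimens)
        for s in np.unique(specimens):
            got = set(observers[specimens == s])
            if got != set(uniq):
                raise ValueError(
                    f"specimen {s!r} was not measured by every observer"
                )
    return size_anova(sizes, observers, n_permutations=n_permutations, seed=seed)


@dataclass
class RepeatabilityResult:
    """Within-specimen (digitization) vs within-species (biological) shape
    variance; a small ratio indicates low observer bias."""

    within_specimen_pv: float
    per_specimen_pv: dict[str, float]
    within_species_pv: dict[str, float]
    ratio: float  # within-specimen PV / mean within-species PV
    n_specimens: int
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "within_specimen_pv": self.within_specimen_pv,
            "within_species_pv": dict(self.within_species_pv),
            "ratio": self.ratio,
            "n_specimens": self.n_specimens,
            "n_excluded": self.n_excluded,
        }


def observer_repeatability(
    shapes: np.ndarray,
    specimens,
    observers,
    species,
) -> RepeatabilityResult:
    """Summarize digitization repeatability from replicated measurements.

    (a) within-specimen Procrustes variance: the mean over specimens of the
    PV of each specimen's replicate measurements; (b) within-species PV on a
    single replicate per specimen (the first observer's, in sorted order).
    Unreplicated specimens are excluded with a warning.
    """
    shapes = np.asarray(shapes, dtype=float)
    specimens = np.asarray(specimens)
    observers = np.asarray(observers)
    species = np.asarray(species)
    n = shapes.shape[0]
    if not (specimens.shape == observers.shape == species.shape == (n,)):
        raise ValueError("metadata arrays must align with shapes")

    per_specimen: dict[str, float] = {}
    keep_one: list[int] = []
    n_excluded = 0
    for s in np.unique(specimens):
        rows = np.where(specimens == s)[0]
        if rows.size < 2:
            warnings.warn(
                f"specimen {s!r} has no replicate measurements; excluded",
                RuntimeWarning,
                stacklevel=2,
            )
            n_excluded += 1
            continue
        v = shapes[rows]
        per_specimen[str(s)] = float(
            np.sum((v - v.mean(axis=0)) ** 2) / rows.size
        )
        # one measurement per specimen for the biological-variance reference
        order = rows[np.argsort(observers[rows], kind="stable")]
        keep_one.append(int(order[0]))

    if not per_specimen:
        raise ValueError("no replicated specimens found")
    within_specimen = float(np.mean(list(per_specimen.values())))

    keep = np.array(keep_one)
    within_species: dict[str, float] = {}
    for sp in np.unique(species[keep]):
        rows = keep[species[keep] == sp]
        v = shapes[rows]
        within_species[str(sp)] = float(
            np.sum((v - v.mean(axis=0)) ** 2) / rows.size
        )
    mean_within_species = float(np.mean(list(within_species.values())))
    ratio = within_specimen / mean_within_species if mean_within_species > 0 else np.inf

    return RepeatabilityResult(
        within_specimen_pv=within_specimen,
        per_specimen_pv=per_specimen,
        within_species_pv=within_species,
        ratio=float(ratio),
        n_specimens=len(per_specimen),
        n_excluded=n_excluded,
    )
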