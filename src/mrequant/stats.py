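"""Condition-specific MRE selection.

Two complementary tests are intersected:

* **DTK pairwise multiple comparisons** (Dunnett's C) on normalized log2
  values across all k groups. For groups i, j with means x̄, variances s²
  (ddof 1) and sizes n, the pair (i, j) is significant at level alpha when
  0 falls outside x̄_i - x̄_j ± w_ij, with

      SE_ij = sqrt(s_i²/n_i + s_j²/n_j)
      q*_ij = [q(alpha,k,n_i-1)·s_i²/n_i + q(alpha,k,n_j-1)·s_j²/n_j] / SE_ij²
      w_ij  = q*_ij · SE_ij / sqrt(2)

  where q(alpha,k,v) is the studentized-range upper quantile. The procedure
  is valid under unequal variances and group sizes and reduces to
  Tukey-Kramer under homoscedasticity. An MRE is *target-specific* when all
  k-1 pairs involving the target group are significant with a consistent
  sign of the difference.

* **An exact negative-binomial differential test** on raw counts between the
  target tumor group and its normal-adjacent counterpart: TMM scaling
  factors, a method-of-moments common dispersion, a conditional NB exact
  test per row, and Benjamini-Hochberg FDR control, thresholded at
  FDR < 0.05 and |log2FC| >= 2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import studentized_range
from statsmodels.stats.multitest import multipletests

from .quantify import MRECountMatrix

logger = logging.getLogger(__name__)


@dataclass
class GroupDesign:
    """Sample-to-group assignment with a designated target group.

    ``de_reference_group`` names the group compared against the target in the
    count-based differential test (defaults to the target's ``*_normal``
    partner when the naming convention allows).
    """

    groups: list[str]
    sample_to_group: dict[str, str]
    target_group: str
    de_reference_group: str | None = None

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        if self.target_group not in self.groups:
            raise ValueError(f"target group {self.target_group!r} not among groups")
        extra = set(self.sample_to_group.values()) - set(self.groups)
        if extra:
            raise ValueError(f"samples assigned to unknown groups {extra}")
        if self.de_reference_group is None:
            guess = self.target_group.replace("tumor", "normal")
            if guess != self.target_group and guess in self.groups:
                self.de_reference_group = guess
        if self.de_reference_group is not None and self.de_reference_group not in self.groups:
            raise ValueError(f"DE reference group {self.de_reference_group!r} not among groups")

    def samples_of(self, group: str) -> list[str]:
        return [s for s, g in self.sample_to_group.items() if g == group]

    @classmethod
    def from_sample_sheet(
        cls, path: str | Path, target_group: str, de_reference_group: str | None = None
    ) -> "GroupDesign":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"sample_id", "group"} <= set(df.columns):
            raise ValueError(f"{path}: sample sheet needs sample_id and group columns")
        groups = list(dict.fromkeys(df["group"]))
        return cls(groups, dict(zip(df["sample_id"], df["group"])), target_group,
                   de_reference_group)


@lru_cache(maxsize=None)
def _q_crit(alpha: float, k: int, df: int) -> float:
    return float(studentized_range.ppf(1.0 - alpha, k, df))


@dataclass
class DTKResult:
    """Per-MRE, per-pair Dunnett's C outcome: difference, CI half-width, flag."""

    groups: list[str]
    alpha: float
    n_per_group: dict[str, int]
    diff: pd.DataFrame         # rows x pairs, d_ij = mean_i - mean_j
    halfwidth: pd.DataFrame
    significant: pd.DataFrame  # boolean
    degenerate: pd.DataFrame   # boolean: zero-variance pair with nonzero diff

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self.diff.columns)

    def to_frame(self) -> pd.DataFrame:
        out = {}
        for i, j in self.pairs:
            tag = f"{i}|{j}"
            out[f"diff:{tag}"] = self.diff[(i, j)]
            out[f"halfwidth:{tag}"] = self.halfwidth[(i, j)]
            out[f"significant:{tag}"] = self.significant[(i, j)].astype(int)
        return pd.DataFrame(out, index=self.diff.index)


def dtk_pairwise(
    values: pd.DataFrame, design: GroupDesign | Mapping[str, str], alpha: float = 0.05
) -> DTKResult:
    """Dunnett's C pairwise comparisons for every row of ``values``.

    ``values`` has samples as columns; each group needs n_i >= 2. A pair with
    zero variance in both groups is non-significant at d = 0 and flagged
    degenerate (and significant) at d != 0.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    s2g = design.sample_to_group if isinstance(design, GroupDesign) else dict(design)
    groups = design.groups if isinstance(design, GroupDesign) else sorted(set(s2g.values()))
    cols_by_group = {g: [s for s in values.columns if s2g.get(s) == g] for g in groups}
    for g, cols in cols_by_group.items():
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has n={len(cols)} < 2")
    k = len(groups)
    arr = values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite values in DTK input")
    mean = {}
    var_n = {}  # s_i^2 / n_i
    qvn = {}    # q(alpha, k, n_i - 1) * s_i^2 / n_i
    n_i = {}
    for g, cols in cols_by_group.items():
        sub = values[cols].to_numpy(dtype=float)
        n = sub.shape[1]
        n_i[g] = n
        mean[g] = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1) / n
        var_n[g] = v
        qvn[g] = _q_crit(alpha, k, n - 1) * v
    diff, hw, sig, dgn = {}, {}, {}, {}
    for i, j in combinations(groups, 2):
        d = mean[i] - mean[j]
        se2 = var_n[i] + var_n[j]
        with np.errstate(invalid="ignore", divide="ignore"):
            qstar = (qvn[i] + qvn[j]) / se2
            w = qstar * np.sqrt(se2) / np.sqrt(2.0)
        zero = se2 == 0
        w = np.where(zero, 0.0, w)
        diff[(i, j)] = d
        hw[(i, j)] = w
        sig[(i, j)] = np.abs(d) > w
        dgn[(i, j)] = zero & (d != 0)
    cols = pd.MultiIndex.from_tuples(diff.keys(), names=["group_i", "group_j"])
    mk = lambda d: pd.DataFrame(np.column_stack(list(d.values())), index=values.index, columns=cols)
    n_degen = int(mk({k_: v.astype(float) for k_, v in dgn.items()}).to_numpy().sum())
    if n_degen:
        logger.warning("DTK: %d degenerate zero-variance significant pairs", n_degen)
    return DTKResult(
        groups=list(groups), alpha=alpha, n_per_group=n_i,
        diff=mk(diff), halfwidth=mk(hw),
        significant=mk(sig).astype(bool), degenerate=mk(dgn).astype(bool),
    )


def select_target_specific(dtk: DTKResult, target_group: str) -> pd.Series:
    """Boolean per MRE: every pair involving the target is significant and the
    k-1 target-minus-other differences share one sign."""
    if target_group not in dtk.groups:
        raise ValueError(f"{target_group!r} not among DTK groups")
    others = [g for g in dtk.groups if g != target_group]
    sig_all = np.ones(len(dtk.diff), dtype=bool)
    signs = []
    for o in others:
        if (target_group, o) in dtk.diff.columns:
            pair, orient = (target_group, o), 1.0
        elif (o, target_group) in dtk.diff.columns:
            pair, orient = (o, target_group), -1.0
        else:
            raise ValueError(f"missing DTK pair for target vs {o!r}")
        sig_all &= dtk.significant[pair].to_numpy()
        signs.append(np.sign(orient * dtk.diff[pair].to_numpy()))
    signs = np.column_stack(signs)
    consistent = np.all(signs > 0, axis=1) | np.all(signs < 0, axis=1)
    return pd.Series(sig_all & consistent, index=dtk.diff.index, name="dtk_selected")


def tmm_factors(
    counts: pd.DataFrame,
    lib_sizes: pd.Series | None = None,
    reference: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    M and A values are computed on rows positive in both the sample and the
    reference (chosen, as in common practice, as the column whose upper
    quartile of scaled counts is closest to the mean upper quartile); 30% of
    M and 5% of A are trimmed from each tail and the remaining M values are
    averaged with inverse-asymptotic-variance weights.
    """
    c = counts.to_numpy(dtype=float)
    samples = list(counts.columns)
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    N = lib_sizes.reindex(samples).to_numpy(dtype=float)
    if (N <= 0).any():
        raise ValueError("non-positive library size in TMM")
    if reference is None:
        f75 = np.array([np.quantile(c[:, s] / N[s], 0.75) for s in range(len(samples))])
        reference = samples[int(np.argmin(np.abs(f75 - f75.mean())))]
    r = samples.index(reference)
    f = np.ones(len(samples))
    for s in range(len(samples)):
        if s == r:
            continue
        pos = (c[:, s] > 0) & (c[:, r] > 0)
        if not pos.any():
            warnings.warn(f"TMM: no co-positive rows for {samples[s]}; factor 1")
            continue
        cs, cr = c[pos, s], c[pos, r]
        ps, pr = cs / N[s], cr / N[r]
        M = np.log2(ps / pr)
        A = 0.5 * np.log2(ps * pr)
        n = len(M)
        loM, hiM = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        loA, hiA = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rM = pd.Series(M).rank().to_numpy()
        rA = pd.Series(A).rank().to_numpy()
        keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        if not keep.any():
            keep = np.ones(n, dtype=bool)
        v = (N[s] - cs) / (N[s] * cs) + (N[r] - cr) / (N[r] * cr)
        v = np.where(v <= 0, np.finfo(float).tiny, v)
        f[s] = 2 ** (np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep]))
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=samples, name="tmm_factor")


def estimate_common_dispersion(
    counts: pd.DataFrame,
    condition_a: Sequence[str],
    condition_b: Sequence[str],
    factors: pd.Series | None = None,
    lib_sizes: pd.Series | None = None,
) -> float:
    """Method-of-moments common NB dispersion across two conditions.

    Counts are scaled to a common effective library size; per row and
    condition, phi = (var - mean)/mean² (mean > 0), averaged over the two
    conditions and summarized by the median over rows, floored at 0.
    """
    cols = list(condition_a) + list(condition_b)
    if len(condition_a) < 2 or len(condition_b) < 2:
        raise ValueError("need >= 2 samples per condition")
    if lib_sizes is None:
        lib_sizes = counts[cols].sum(axis=0)
    if factors is None:
        factors = pd.Series(1.0, index=cols)
    eff = factors.reindex(cols).to_numpy() * lib_sizes.reindex(cols).to_numpy(dtype=float)
    scale = np.exp(np.mean(np.log(eff))) / eff
    scaled = counts[cols].to_numpy(dtype=float) * scale[None, :]
    na = len(condition_a)
    phis = []
    for block in (scaled[:, :na], scaled[:, na:]):
        mu = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = (v - mu) / mu**2
        phis.append(np.where(mu > 0, phi, np.nan))
    row_phi = np.nanmean(np.column_stack(phis), axis=1)
    row_phi = row_phi[np.isfinite(row_phi)]
    if row_phi.size == 0:
        warnings.warn("dispersion: all rows empty; phi = 0")
        return 0.0
    return float(max(0.0, np.median(np.maximum(0.0, row_phi))))


def _conditional_logpmf(z: int, r_t: float, r_n: float) -> np.ndarray:
    """log P(T = t | T + N = z) for t = 0..z under the conditional NB null.

    With common NB success probability the conditional law is negative
    hypergeometric with weights r_t, r_n and does not depend on the mean.
    """
    t = np.arange(z + 1, dtype=float)
    lp = (
        gammaln(t + r_t) - gammaln(t + 1.0) - gammaln(r_t)
        + gammaln(z - t + r_n) - gammaln(z - t + 1.0) - gammaln(r_n)
    )
    return lp - logsumexp(lp)


def _binomial_logpmf(z: int, p: float) -> np.ndarray:
    t = np.arange(z + 1, dtype=float)
    return (
        gammaln(z + 1.0) - gammaln(t + 1.0) - gammaln(z - t + 1.0)
        + t * np.log(p) + (z - t) * np.log1p(-p)
    )


def nb_exact_test(
    tumor: np.ndarray,
    normal: np.ndarray,
    phi: float,
    eff_tumor: np.ndarray | None = None,
    eff_normal: np.ndarray | None = None,
    pseudo: float = 0.5,
) -> tuple[float, float]:
    """Conditional NB exact test for one MRE row; returns (two-sided p, log2FC).

    Counts are scaled to a common effective library size, summed per
    condition and rounded to T and N. Given z = T + N, the null conditional
    distribution of T uses NB sizes n_T/phi and n_N/phi (binomial Poisson
    limit at phi = 0); the two-sided p-value sums the probabilities of all
    outcomes no more probable than the observed one (included once).
    log2FC = log2((T/n_T + pseudo) / (N/n_N + pseudo)).
    """
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if phi < 0:
        raise ValueError("phi must be >= 0")
    n_t, n_n = len(tumor), len(normal)
    if eff_tumor is not None or eff_normal is not None:
        eff = np.concatenate([np.asarray(eff_tumor, float), np.asarray(eff_normal, float)])
        scale = np.exp(np.mean(np.log(eff))) / eff
        tumor = tumor * scale[:n_t]
        normal = normal * scale[n_t:]
    T = int(round(tumor.sum()))
    N = int(round(normal.sum()))
    z = T + N
    lfc = float(np.log2((T / n_t + pseudo) / (N / n_n + pseudo)))
    if z == 0:
        return 1.0, 0.0
    if phi == 0:
        lp = _binomial_logpmf(z, n_t / (n_t + n_n))
    else:
        lp = _conditional_logpmf(z, n_t / phi, n_n / phi)
    obs = lp[T]
    p = float(np.exp(logsumexp(lp[lp <= obs + 1e-10])))
    return min(1.0, p), lfc


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResult:
    """Per-MRE differential-test outcome plus the fitted nuisance parameters."""

    table: pd.DataFrame            # columns log2FC, pvalue, fdr
    factors: pd.Series             # per-sample TMM factor
    dispersion: float
    tumor_samples: list[str]
    normal_samples: list[str]

    def selected(self, fdr: float = 0.05, min_abs_lfc: float = 2.0) -> pd.Series:
        return (self.table["fdr"] < fdr) & (self.table["log2FC"].abs() >= min_abs_lfc)


def de_exact_test(
    matrix: MRECountMatrix,
    tumor_samples: Sequence[str],
    normal_samples: Sequence[str],
) -> DEResult:
    """edgeR-style classic pipeline: TMM factors, common dispersion,
    conditional NB exact test per row, BH adjustment."""
    cols = list(tumor_samples) + list(normal_samples)
    counts = matrix.counts[cols]
    lib = matrix.library_sizes().reindex(cols)
    factors = tmm_factors(counts, lib_sizes=lib)
    phi = estimate_common_dispersion(
        counts, tumor_samples, normal_samples, factors=factors, lib_sizes=lib
    )
    eff = factors.to_numpy() * lib.to_numpy(dtype=float)
    n_t = len(tumor_samples)
    scale = np.exp(np.mean(np.log(eff))) / eff
    scaled = counts.to_numpy(dtype=float) * scale[None, :]
    ps, lfcs = np.empty(len(counts)), np.empty(len(counts))
    for i in range(len(counts)):
        ps[i], lfcs[i] = nb_exact_test(scaled[i, :n_t], scaled[i, n_t:], phi)
    table = pd.DataFrame(
        {"log2FC": lfcs, "pvalue": ps, "fdr": bh_adjust(ps)}, index=counts.index
    )
    return DEResult(table, factors, phi, list(tumor_samples), list(normal_samples))


@dataclass
class SelectionResult:
    """Intersection of the DTK-specific set with the differential set."""

    dtk_set: set
    de_set: set
    specific_set: set = field(init=False)

    def __post_init__(self) -> None:
        self.specific_set = self.dtk_set & self.de_set

    @property
    def counts(self) -> dict[str, int]:
        return {
            "dtk": len(self.dtk_set),
            "de": len(self.de_set),
            "intersection": len(self.specific_set),
        }

    def to_frame(self, universe: Iterable | None = None) -> pd.DataFrame:
        keys = sorted(universe) if universe is not None else sorted(self.dtk_set | self.de_set)
        return pd.DataFrame(
            {
                "in_dtk": [k in self.dtk_set for k in keys],
                "in_de": [k in self.de_set for k in keys],
                "selected": [k in self.specific_set for k in keys],
            },
            index=pd.MultiIndex.from_tuples(keys, names=["gene_id", "family_id"])
            if keys and isinstance(keys[0], tuple)
            else pd.Index(keys, name="mre"),
        )


def intersect_selections(dtk_set: Iterable, de_set: Iterable) -> SelectionResult:
    """Condition-specific MREs: those flagged by both complementary approaches."""
    return SelectionResult(set(dtk_set), set(de_set))


def select_condition_specific(
    normalized: pd.DataFrame,
    matrix: MRECountMatrix,
    design: GroupDesign,
    alpha: float = 0.05,
    fdr: float = 0.05,
    min_abs_lfc: float = 2.0,
) -> tuple[DTKResult, DEResult, SelectionResult]:
    """Full selection: DTK on normalized values across all groups, NB exact
    test on raw counts for target tumor vs its normal-adjacent group,
    intersected."""
    dtk = dtk_pairwise(normalized, design, alpha=alpha)
    dtk_flags = select_target_specific(dtk, design.target_group)
    if design.de_reference_group is None:
        raise ValueError("GroupDesign.de_reference_group is required for the DE test")
    de = de_exact_test(
        matrix,
        design.samples_of(design.target_group),
        design.samples_of(design.de_reference_group),
    )
    de_flags = de.selected(fdr=fdr, min_abs_lfc=min_abs_lfc)
    sel = intersect_selections(
        set(dtk_flags.index[dtk_flags]), set(de_flags.index[de_flags])
    )
    return dtk, de, sel
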