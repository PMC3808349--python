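"""Permutation variant of Fisher's combined probability test for SNP sets.

The observed statistic is T = sum over set SNPs of -2 ln p, with p the
allelic single-marker p-value.  Null copies of T are generated by jointly
permuting the case/control labels (which preserves inter-SNP LD) and
recomputing the per-SNP p-values.  Ties count as exceedances, and the
Monte-Carlo p-value is (r + 1) / (n_perm + 1).
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass
from math import comb
from math import log as _ln

import numpy as np
from scipy.stats import chi2 as _chi2_dist

from .genotype_core import MISSING, GenotypeDataset, allele_table_chi2
from .pathway_sets import PathwaySet

log = logging.getLogger(__name__)

P_FLOOR = 1e-300


class EnumerationBoundError(ValueError):
    """Too many distinct label arrangements to enumerate exactly."""


@dataclass
class SetResult:
    """Outcome of scoring one pathway set."""

    pathway_set: PathwaySet
    statistic: float
    n_perm: int
    exceedances: int
    p_value: float
    exhaustive: bool = False

    @property
    def p_display(self) -> str:
        """Monte-Carlo p, shown as '<=' its floor when no permutation won."""
        if not self.exhaustive and self.exceedances == 0:
            return f"<={self.p_value:.3g}"
        return f"{self.p_value:.3g}"


def fisher_combined_statistic(p_values) -> float:
    """T = sum of -2 ln p over the supplied p-values (floored at 1e-300)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    return float(-2.0 * np.log(np.maximum(p, P_FLOOR)).sum())


# ---------------------------------------------------------------------------
# vectorised permutation machinery
# ---------------------------------------------------------------------------

def _neglog_p_matrix(G: np.ndarray, case_matrix: np.ndarray) -> np.ndarray:
    """-2 ln p for every (label arrangement, SNP) pair.

    ``G`` is (n_samples, n_snps) int8; ``case_matrix`` is
    (k, n_samples) float64 of 0/1 case indicators.
    """
    nonmiss = G != MISSING
    gz = np.where(nonmiss, G, 0).astype(np.float64)
    alleles = nonmiss.astype(np.float64) * 2.0
    a_case = case_matrix @ gz
    alleles_case = case_matrix @ alleles
    a_total = gz.sum(axis=0)[None, :]
    alleles_total = alleles.sum(axis=0)[None, :]
    chi2 = allele_table_chi2(a_case, alleles_case, a_total, alleles_total)
    p = _chi2_dist.sf(chi2, 1)
    return -2.0 * np.log(np.maximum(p, P_FLOOR))


def _random_case_matrix(phenotype: np.ndarray, n_perm: int, rng) -> np.ndarray:
    """n_perm joint label permutations (case/control ratio preserved)."""
    base = phenotype.astype(np.float64)
    order = np.argsort(rng.random((n_perm, base.size)), axis=1)
    return base[order]

def _enumerated_case_matrix(n_samples: int, n_cases: int) -> np.ndarray:
    mat = np.zeros((comb(n_samples, n_cases), n_samples), dtype=np.float64)
    for i, case_idx in enumerate(itertools.combinations(range(n_samples), n_cases)):
        mat[i, list(case_idx)] = 1.0
    return mat


def _resolve_rng(seed, pset: PathwaySet, shared_permutations: bool):
    if isinstance(seed, np.random.Generator):
        return seed
    if shared_permutations or seed is None:
        return np.random.default_rng(seed)
    # per-set stream: fold a stable hash of the set identity into the seed
    mix = zlib.crc32(pset.set_id.encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), mix]))


def permutation_set_pvalue(
    pset: PathwaySet,
    ds: GenotypeDataset,
    n_perm: int = 5000,
    seed=None,
    shared_permutations: bool = True,
    exhaustive: str | bool = "auto",
    max_arrangements: int = 200_000,
) -> SetResult:
    """Permutation p-value of one pathway set.

    With ``shared_permutations`` (default) the null label stream depends
    only on ``seed``, so every set scored with the same seed sees the same
    permutations; otherwise the stream is additionally keyed by the set
    identity.  When the number of distinct case/control arrangements is at
    most ``min(n_perm, max_arrangements)`` (and ``exhaustive`` is not
    False), all arrangements are enumerated instead and the p-value is the
    exact exceedance fraction r / N.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cols = ds.snp_indices(sorted(pset.snp_ids))
    G = ds.genotypes[:, cols]
    t_obs = float(_neglog_p_matrix(G, ds.phenotype[None, :].astype(np.float64)).sum())

    n_arrangements = comb(ds.n_samples, ds.n_cases)
    use_exhaustive = exhaustive is True or (
        exhaustive == "auto" and n_arrangements <= min(n_perm, max_arrangements)
    )
    if use_exhaustive:
        if n_arrangements > max_arrangements:
            raise EnumerationBoundError(
                f"{n_arrangements} arrangements exceed the bound {max_arrangements}"
            )
        case_mat = _enumerated_case_matrix(ds.n_samples, ds.n_cases)
        t_perm = _neglog_p_matrix(G, case_mat).sum(axis=1)
        r = int((t_perm >= t_obs).sum())
        return SetResult(
            pathway_set=pset,
            statistic=t_obs,
            n_perm=n_arrangements,
            exceedances=r,
            p_value=r / n_arrangements,
            exhaustive=True,
        )

    rng = _resolve_rng(seed, pset, shared_permutations)
    case_mat = _random_case_matrix(ds.phenotype, n_perm, rng)
    t_perm = _neglog_p_matrix(G, case_mat).sum(axis=1)
    r = int((t_perm >= t_obs).sum())
    return SetResult(
        pathway_set=pset,
        statistic=t_obs,
        n_perm=n_perm,
        exceedances=r,
        p_value=(r + 1) / (n_perm + 1),
    )


def score_sets(
    psets,
    ds: GenotypeDataset,
    n_perm: int = 5000,
    seed=None,
) -> list[SetResult]:
    """Score many sets against one shared permutation stream.

    The -2 ln p matrix is computed once over the union of set SNPs, then
    summed per set, so the cost is one label permutation pass per stage.
    """
    psets = list(psets)
    if not psets:
        return []
    union = sorted(set().union(*(p.snp_ids for p in psets)))
    col_of = {sid: j for j, sid in enumerate(union)}
    cols = ds.snp_indices(union)
    G = ds.genotypes[:, cols]

    obs = _neglog_p_matrix(G, ds.phenotype[None, :].astype(np.float64))[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    case_mat = _random_case_matrix(ds.phenotype, n_perm, rng)
    perm = _neglog_p_matrix(G, case_mat)

    results = []
    for pset in psets:
        idx = np.array([col_of[s] for s in sorted(pset.snp_ids)], dtype=np.intp)
        t_obs = float(obs[idx].sum())
        t_perm = perm[:, idx].sum(axis=1)
        r = int((t_perm >= t_obs).sum())
        results.append(
            SetResult(
                pathway_set=pset,
                statistic=t_obs,
                n_perm=n_perm,
                exceedances=r,
                p_value=(r + 1) / (n_perm + 1),
            )
        )
    return results


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def _textbook_chi2(table) -> float:
    """Pearson chi-square from expected counts; 0 for degenerate margins."""
    (a, b), (c, d) = table
    row = [a + b, c + d]
    col = [a + c, b + d]
    n = row[0] + row[1]
    if n == 0 or 0 in row or 0 in col:
        return 0.0
    chi2 = 0.0
    obs = [[a, b], [c, d]]
    for i in range(2):
        for j in range(2):
            exp = row[i] * col[j] / n
            chi2 += (obs[i][j] - exp) ** 2 / exp
    return chi2


def exact_permutation_pvalue(
    pset: PathwaySet,
    ds: GenotypeDataset,
    max_arrangements: int = 200_000,
) -> SetResult:
    """Ground-truth oracle: enumerate every case/control arrangement.

    Deliberately written as a plain per-table loop, independent of the
    vectorised scoring path.  p = r / N over the full enumeration; the
    observed arrangement is part of it, so r >= 1 and p > 0.
    """
    n, k = ds.n_samples, ds.n_cases
    n_arr = comb(n, k)
    if n_arr > max_arrangements:
        raise EnumerationBoundError(
            f"{n_arr} arrangements exceed the bound {max_arrangements}"
        )
    cols = ds.snp_indices(sorted(pset.snp_ids))

    def statistic(case_indices) -> float:
        case_set = set(case_indices)
        t = 0.0
        for j in cols:
            a = b = c = d = 0
            for i in range(n):
                g = int(ds.genotypes[i, j])
                if g == MISSING:
                    continue
                if i in case_set:
                    a += g
                    b += 2 - g
                else:
                    c += g
                    d += 2 - g
            chi2 = _textbook_chi2(((a, b), (c, d)))
            p = float(_chi2_dist.sf(chi2, 1))
            t += -2.0 * _ln(max(p, P_FLOOR))
        return t

    obs_cases = tuple(np.flatnonzero(ds.case_mask).tolist())
    t_obs = statistic(obs_cases)
    r = 0
    for case_idx in itertools.combinations(range(n), k):
        if statistic(case_idx) >= t_obs:
            r += 1
    return SetResult(
        pathway_set=pset,
        statistic=t_obs,
        n_perm=n_arr,
        exceedances=r,
        p_value=r / n_arr,
        exhaustive=True,
    )
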