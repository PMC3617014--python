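"""Statistical comparisons of repeat- vs variant-encoded homo-AA tracts.

Four analyses: per-residue tract composition (exact two-tailed binomial
test against the proteome-level proportion of repeat-encoded homo-AA
proteins), per-residue tract length (Mann-Whitney U), protein interaction
degree, and genomic conservation of tract-encoding DNA (both Mann-Whitney).

The two-tailed binomial p-value follows the minimum-likelihood convention:
the sum of null probabilities of all outcomes no more probable than the one
observed.  The Mann-Whitney test is exact (rank-sum distribution over all
assignments, ties handled via midranks) when n1*n2 <= 400 and otherwise
uses the tie-corrected normal approximation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .homoaa import TNR, VARIANT, HomoAATract

log = logging.getLogger(__name__)

EXACT_MW_LIMIT = 400  # exact Mann-Whitney when n1*n2 <= this


class StatsError(ValueError):
    """Invalid input to a statistical comparison."""


def binomial_composition_test(k: int, n: int, p0: float) -> float:
    """Exact two-tailed binomial p-value (minimum-likelihood rule)."""
    if not 0 <= k <= n:
        raise StatsError("need 0 <= k <= n")
    if p0 <= 0 or p0 >= 1:
        # degenerate null: p = 1 when the observation is the only possible
        # outcome, else 0
        consistent = (p0 <= 0 and k == 0) or (p0 >= 1 and k == n)
        return 1.0 if consistent else 0.0
    return float(sps.binomtest(k, n, p0, alternative="two-sided").pvalue)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U statistic for ``x`` and its two-sided p-value.

    Exact (tie-aware rank-sum enumeration by dynamic programming) when
    n1*n2 <= 400; tie-corrected normal approximation otherwise.  The exact
    two-sided p is min(1, 2*min(lower tail, upper tail)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise StatsError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = float(r1 - n1 * (n1 + 1) / 2)
    if np.all(pooled == pooled[0]):
        return u, 1.0
    if n1 * n2 <= EXACT_MW_LIMIT:
        p = _exact_rank_sum_p(ranks, n1, r1)
    else:
        p = float(
            sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        )
    return u, p


def _exact_rank_sum_p(ranks: np.ndarray, n1: int, r1: float) -> float:
    """Two-sided exact p for the rank sum of a size-n1 subset of ``ranks``.

    Enumerates the null distribution of the rank sum over all C(N, n1)
    subsets by counting (size, sum) combinations; midranks are doubled so
    all sums are integers.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    # dp[k, s] = number of subsets of size k with doubled-rank sum s
    dp = np.zeros((n1 + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in r2:
        for k in range(n1, 0, -1):  # descending: row k reads the pre-update row k-1
            dp[k, r:] += dp[k - 1, 0 : total + 1 - r]
    dist = dp[n1]
    n_total = dist.sum()
    t_obs = int(round(2 * r1))
    lower = dist[: t_obs + 1].sum() / n_total
    upper = dist[t_obs:].sum() / n_total
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass
class CompositionResult:
    """Per-residue share of repeat-encoded tracts vs the proteome-level rate."""

    residue: str
    n_tracts_total: int
    n_tnr_tracts: int
    p0: float
    p_value: float
    log2_proportion_ratio: float | None
    significant: bool


def composition_analysis(
    tracts: Iterable[HomoAATract],
    protein_sets: tuple[set[str], set[str], set[str]],
    alpha: float = 0.05,
) -> list[CompositionResult]:
    """Binomial composition test per residue.

    For each residue, trials are that residue's tracts and successes its
    repeat-encoded tracts; the null success probability is the proportion
    of repeat-encoded homo-AA proteins among all homo-AA proteins.  The
    log ratio compares the residue's share of repeat-encoded tracts with
    its share of variant-encoded tracts (None when either share is zero).
    """
    tnr_set, _var_set, all_set = protein_sets
    if not all_set:
        return []
    p0 = len(tnr_set) / len(all_set)
    tracts = list(tracts)
    total_tnr = sum(1 for t in tracts if t.encoding_class == TNR)
    total_var = sum(1 for t in tracts if t.encoding_class == VARIANT)
    by_res: dict[str, list[HomoAATract]] = {}
    for t in tracts:
        by_res.setdefault(t.residue, []).append(t)
    out: list[CompositionResult] = []
    for res in sorted(by_res):
        ts = by_res[res]
        n = len(ts)
        k = sum(1 for t in ts if t.encoding_class == TNR)
        p = binomial_composition_test(k, n, p0)
        ratio = None
        if total_tnr and total_var and k and (n - k):
            ratio = math.log2((k / total_tnr) / ((n - k) / total_var))
        out.append(
            CompositionResult(
                residue=res,
                n_tracts_total=n,
                n_tnr_tracts=k,
                p0=p0,
                p_value=p,
                log2_proportion_ratio=ratio,
                significant=p < alpha,
            )
        )
    return out


@dataclass
class LengthComparisonResult:
    """Per-residue tract length comparison between encoding classes."""

    residue: str
    n_tnr: int
    n_variant: int
    mean_tnr: float | None
    mean_variant: float | None
    se_tnr: float | None
    se_variant: float | None
    u_statistic: float | None
    p_value: float | None
    log2_length_ratio: float | None
    significant: bool


def _mean_se(values: list[int]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    arr = np.asarray(values, dtype=float)
    se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else None
    return float(arr.mean()), se


def length_analysis(
    tracts: Iterable[HomoAATract], alpha: float = 0.05
) -> list[LengthComparisonResult]:
    """Mann-Whitney comparison of tract lengths per residue.

    Residues present in only one encoding class are reported with the
    available means but no p-value.
    """
    by_res: dict[str, dict[str, list[int]]] = {}
    for t in tracts:
        if t.encoding_class not in (TNR, VARIANT):
            continue
        by_res.setdefault(t.residue, {TNR: [], VARIANT: []})[t.encoding_class].append(
            t.length
        )
    out: list[LengthComparisonResult] = []
    for res in sorted(by_res):
        lt = by_res[res][TNR]
        lv = by_res[res][VARIANT]
        mean_t, se_t = _mean_se(lt)
        mean_v, se_v = _mean_se(lv)
        u = p = ratio = None
        if lt and lv:
            u, p = mann_whitney_u(lt, lv)
            if mean_t and mean_v:
                ratio = math.log2(mean_t / mean_v)
        out.append(
            LengthComparisonResult(
                residue=res,
                n_tnr=len(lt),
                n_variant=len(lv),
                mean_tnr=mean_t,
                mean_variant=mean_v,
                se_tnr=se_t,
                se_variant=se_v,
                u_statistic=u,
                p_value=p,
                log2_length_ratio=ratio,
                significant=p is not None and p < alpha,
            )
        )
    return out


def ppi_degrees(
    pairs: Iterable[tuple[str, str]], proteins: Iterable[str]
) -> dict[str, int]:
    """Distinct-partner counts; proteins absent from the table get degree 0."""
    partners: dict[str, set[str]] = {}
    for a, b in pairs:
        if a == b:
            continue
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
    return {p: len(partners.get(p, ())) for p in proteins}


def ppi_degree_comparison(
    pairs: Iterable[tuple[str, str]],
    protein_sets: tuple[set[str], set[str], set[str]],
) -> tuple[pd.DataFrame, float, float]:
    """Mann-Whitney comparison of interaction degree between protein classes.

    Returns (per-protein degree table, U, two-sided p).
    """
    tnr_set, var_set, all_set = protein_sets
    degrees = ppi_degrees(pairs, sorted(all_set))
    table = pd.DataFrame(
        [
            (p, degrees[p], p in tnr_set, p in var_set)
            for p in sorted(all_set)
        ],
        columns=["protein_id", "degree", "in_tnr_set", "in_variant_set"],
    )
    x = [degrees[p] for p in sorted(tnr_set)]
    y = [degrees[p] for p in sorted(var_set)]
    if not x or not y:
        return table, float("nan"), 1.0
    u, p = mann_whitney_u(x, y)
    return table, u, p


class ConservationTrack:
    """Per-base conservation scores loaded from a bedGraph file."""

    def __init__(self, intervals: Mapping[str, list[tuple[int, int, float]]]):
        self._by_chrom = {
            chrom: sorted(ivs) for chrom, ivs in intervals.items()
        }
        self._starts = {
            chrom: np.array([s for s, _, _ in ivs], dtype=np.int64)
            for chrom, ivs in self._by_chrom.items()
        }

    @classmethod
    def read_bedgraph(cls, path) -> "ConservationTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, s, e, score = line.split()[:4]
                by_chrom.setdefault(chrom, []).append((int(s), int(e), float(score)))
        return cls(by_chrom)

    def mean_score(self, chrom: str, loci: Sequence[tuple[int, int]]) -> float | None:
        """Mean per-base score over loci; bases without coverage are excluded.

        Returns None when no base is covered.
        """
        ivs = self._by_chrom.get(chrom)
        if not ivs:
            return None
        starts = self._starts[chrom]
        total = 0.0
        covered = 0
        for qs, qe in loci:
            i = int(np.searchsorted(starts, qs, side="right")) - 1
            i = max(i, 0)
            while i < len(ivs) and ivs[i][0] < qe:
                s, e, sc = ivs[i]
                lo, hi = max(s, qs), min(e, qe)
                if hi > lo:
                    total += sc * (hi - lo)
                    covered += hi - lo
                i += 1
        if covered == 0:
            return None
        return total / covered


def tract_conservation_comparison(
    tracts: Iterable[HomoAATract], scores: ConservationTrack
) -> tuple[pd.DataFrame, float, float]:
    """Mann-Whitney comparison of mean per-base tract conservation by class.

    Tracts with no covered bases are excluded from the test (and logged).
    Returns (per-tract score table, U, two-sided p).
    """
    rows = []
    for t in tracts:
        if not t.genomic_loci or t.sequence_id is None:
            continue
        m = scores.mean_score(t.sequence_id, t.genomic_loci)
        if m is None:
            log.warning(
                "tract %s:%d-%d has no conservation coverage; excluded",
                t.protein_id, t.start, t.end,
            )
            continue
        rows.append((t.protein_id, t.residue, t.start, t.end, t.encoding_class, m))
    table = pd.DataFrame(
        rows,
        columns=["protein_id", "residue", "start", "end", "encoding_class", "mean_score"],
    )
    x = table.loc[table.encoding_class == TNR, "mean_score"].tolist()
    y = table.loc[table.encoding_class == VARIANT, "mean_score"].tolist()
    if not x or not y:
        return table, float("nan"), 1.0
    u, p = mann_whitney_u(x, y)
    return table, u, p


def composition_to_frame(results: list[CompositionResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def lengths_to_frame(results: list[LengthComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
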