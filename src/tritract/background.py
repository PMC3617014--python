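"""Order-2 Markov nucleotide background and repeat-unit frequency profiling.

The background model conditions each base on the preceding dinucleotide.
Expected trinucleotide probabilities follow as P(abc) = P(ab) * P(c | ab),
renormalized over whichever unit support is profiled.  Observed repeat-unit
counts are compared with the background by a Pearson chi-squared test, and
per-unit enrichment is summarized as a log ratio of observed frequency over
expected probability.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_DINUCS = ["".join(p) for p in itertools.product(_BASES, repeat=2)]
_TRIPLETS = ["".join(p) for p in itertools.product(_BASES, repeat=3)]


class BackgroundError(ValueError):
    """Invalid input to background fitting or testing."""


@dataclass
class Markov2Model:
    """Order-2 Markov background over ACGT.

    ``context_counts[ctx][base]`` tallies occurrences of base following the
    dinucleotide context; conditionals apply the stored pseudocount.
    ``dinucleotide_freq`` is the empirical distribution of overlapping
    dinucleotides.
    """

    context_counts: np.ndarray  # shape (16, 4)
    dinucleotide_counts: np.ndarray  # shape (16,)
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.context_counts = np.asarray(self.context_counts, dtype=float)
        self.dinucleotide_counts = np.asarray(self.dinucleotide_counts, dtype=float)
        if self.context_counts.shape != (16, 4):
            raise BackgroundError("context_counts must be 16x4")

    @staticmethod
    def context_index(dinuc: str) -> int:
        return 4 * _BASE_INDEX[dinuc[0]] + _BASE_INDEX[dinuc[1]]

    @property
    def dinucleotide_freq(self) -> dict[str, float]:
        total = self.dinucleotide_counts.sum()
        if total == 0:
            raise BackgroundError("model has no dinucleotide counts")
        return {d: self.dinucleotide_counts[i] / total for i, d in enumerate(_DINUCS)}

    def conditional(self, base: str, context: str) -> float:
        """P(base | context) with the model's pseudocount."""
        i = self.context_index(context)
        row = self.context_counts[i]
        denom = row.sum() + 4 * self.pseudocount
        if denom == 0:
            return 0.25  # unseen context: uninformative
        return (row[_BASE_INDEX[base]] + self.pseudocount) / denom

    def conditionals(self) -> np.ndarray:
        """16x4 matrix of conditional probabilities."""
        denom = self.context_counts.sum(axis=1, keepdims=True) + 4 * self.pseudocount
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = (self.context_counts + self.pseudocount) / denom
        probs[np.isnan(probs).any(axis=1)] = 0.25
        return probs

    def to_frame(self) -> pd.DataFrame:
        probs = self.conditionals()
        rows = []
        for i, ctx in enumerate(_DINUCS):
            for j, b in enumerate(_BASES):
                rows.append((ctx, b, self.context_counts[i, j], probs[i, j]))
        return pd.DataFrame(rows, columns=["context", "base", "count", "prob"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def fit_markov2(sequences: Iterable[str], pseudocount: float = 0.0) -> Markov2Model:
    """Fit an order-2 background from one or more sequences.

    Every overlapping (dinucleotide, next base) occurrence is counted;
    windows containing N (or any non-ACGT symbol) are skipped, and counting
    never wraps across sequence boundaries.
    """
    if pseudocount < 0:
        raise BackgroundError("pseudocount must be >= 0")
    ctx = np.zeros((16, 4), dtype=float)
    dinuc = np.zeros(16, dtype=float)
    total_len = 0
    for seq in sequences:
        seq = seq.upper()
        total_len += len(seq)
        codes = np.array([_BASE_INDEX.get(b, -1) for b in seq], dtype=np.int64)
        ok = codes >= 0
        if len(codes) >= 2:
            m2 = ok[:-1] & ok[1:]
            d = 4 * codes[:-1][m2] + codes[1:][m2]
            np.add.at(dinuc, d, 1.0)
        if len(codes) >= 3:
            m3 = ok[:-2] & ok[1:-1] & ok[2:]
            c = 4 * codes[:-2][m3] + codes[1:-1][m3]
            np.add.at(ctx, (c, codes[2:][m3]), 1.0)
    if total_len < 3 or ctx.sum() == 0:
        raise BackgroundError("need at least one ACGT-only window of length 3")
    return Markov2Model(ctx, dinuc, pseudocount)


def expected_triplet_probs(
    model: Markov2Model, support: Iterable[str] | None = None
) -> dict[str, float]:
    """Background probability of each triplet, renormalized over ``support``.

    P(abc) = P(ab) * P(c | ab).  Units in the support with zero background
    probability are floored at 1/(10 * total context count) so observed
    units never meet an expected probability of exactly zero.
    """
    support = sorted(set(support)) if support is not None else list(_TRIPLETS)
    if not support:
        raise BackgroundError("support must be non-empty")
    for u in support:
        if len(u) != 3 or any(b not in _BASES for b in u):
            raise BackgroundError(f"support unit must be a 3-mer over ACGT: {u!r}")
    dfreq = model.dinucleotide_freq
    raw = {u: dfreq[u[:2]] * model.conditional(u[2], u[:2]) for u in support}
    floor = 1.0 / (10.0 * max(model.context_counts.sum(), 1.0))
    raw = {u: (v if v > 0 else floor) for u, v in raw.items()}
    total = sum(raw.values())
    return {u: v / total for u, v in raw.items()}


def chisq_unit_test(
    observed_counts: Mapping[str, float],
    expected_probs: Mapping[str, float],
    pool_threshold: float = 5.0,
) -> tuple[float, int, float]:
    """Pearson chi-squared test of observed unit counts against the background.

    Categories whose expected count falls below ``pool_threshold`` are pooled
    into a single category before testing (asymptotic validity); df is the
    number of categories after pooling minus one.
    """
    support = list(expected_probs)
    if len(support) < 2:
        raise BackgroundError("need at least two categories")
    total = float(sum(observed_counts.get(u, 0) for u in support))
    if total < 1:
        raise BackgroundError("total observed count must be >= 1")
    extra = set(observed_counts) - set(support)
    if extra:
        raise BackgroundError(f"observed units outside expected support: {sorted(extra)}")
    probs = np.array([expected_probs[u] for u in support], dtype=float)
    probs = probs / probs.sum()
    obs = np.array([observed_counts.get(u, 0) for u in support], dtype=float)
    exp = probs * total
    big = exp >= pool_threshold
    if big.sum() == len(support):
        obs_f, exp_f = obs, exp
    else:
        obs_f = np.concatenate((obs[big], [obs[~big].sum()]))
        exp_f = np.concatenate((exp[big], [exp[~big].sum()]))
    if len(obs_f) < 2:
        # pooling would destroy the test on small samples: test unpooled
        obs_f, exp_f = obs, exp
    stat = float(((obs_f - exp_f) ** 2 / exp_f).sum())
    df = len(obs_f) - 1
    p = float(sps.chi2.sf(stat, df))
    return stat, df, p


def log_ratio_profile(
    observed_counts: Mapping[str, float],
    expected_probs: Mapping[str, float],
    base: float = 2.0,
) -> tuple[dict[str, float], set[str]]:
    """Per-unit log ratio of observed frequency over expected probability.

    Returns (log_ratios, absent_units): units with zero observed count are
    reported in ``absent_units`` rather than as -inf values.
    """
    total = float(sum(observed_counts.get(u, 0) for u in expected_probs))
    ratios: dict[str, float] = {}
    absent: set[str] = set()
    for u, ep in expected_probs.items():
        k = observed_counts.get(u, 0)
        if k == 0:
            absent.add(u)
        else:
            ratios[u] = math.log((k / total) / ep, base)
    return ratios, absent


@dataclass
class UnitFrequencyProfile:
    """Observed vs expected repeat-unit distribution with its chi-squared test."""

    observed_counts: dict[str, float]
    expected_probs: dict[str, float]
    log_ratios: dict[str, float]
    absent_units: set[str]
    chisq_stat: float
    df: int
    p_value: float

    def to_frame(self) -> pd.DataFrame:
        total = sum(self.observed_counts.get(u, 0) for u in self.expected_probs)
        rows = []
        for u in sorted(self.expected_probs):
            k = self.observed_counts.get(u, 0)
            rows.append(
                (u, k, k / total if total else float("nan"),
                 self.expected_probs[u], self.log_ratios.get(u, float("nan")))
            )
        return pd.DataFrame(
            rows, columns=["unit", "observed", "observed_freq", "expected_prob", "log2_ratio"]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def unit_frequency_profile(
    observed_counts: Mapping[str, float],
    model: Markov2Model,
    support: Iterable[str] | None = None,
    log_base: float = 2.0,
) -> UnitFrequencyProfile:
    """Full profile for a set of observed repeat units against a background.

    Default support is the set of observed units (the units that survive the
    period filter), matching how tract units are aggregated downstream.
    """
    if support is None:
        support = [u for u, k in observed_counts.items() if k > 0]
    expected = expected_triplet_probs(model, support)
    stat, df, p = chisq_unit_test(observed_counts, expected)
    ratios, absent = log_ratio_profile(observed_counts, expected, base=log_base)
    return UnitFrequencyProfile(
        observed_counts=dict(observed_counts),
        expected_probs=expected,
        log_ratios=ratios,
        absent_units=absent,
        chisq_stat=stat,
        df=df,
        p_value=p,
    )


def tract_unit_counts(tracts, merge_revcomp: bool = False, canonical: bool = True) -> dict[str, int]:
    """Aggregate tract units into counts.

    ``canonical`` collapses rotational phases; ``merge_revcomp`` additionally
    merges reverse-complement unit classes (off by default: plus-strand
    tract units are kept distinct, e.g. CAG vs CTG).
    """
    comp = str.maketrans("ACGT", "TGCA")
    counts: dict[str, int] = {}
    for t in tracts:
        u = t.canonical_unit if canonical else t.unit
        if merge_revcomp:
            from .scanner import canonical_unit as canon

            rc = canon(u.translate(comp)[::-1])
            u = min(u, rc)
        counts[u] = counts.get(u, 0) + 1
    return counts
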