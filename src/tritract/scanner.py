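"""Detection and scoring of short-period tandem repeat tracts in DNA.

A tract is scored by a global wraparound alignment of the observed sequence
against indefinite repetition of a short unit (period 1-3): each aligned
match earns ``match_weight``, each mismatch costs ``mismatch_penalty`` and
each inserted or deleted nucleotide costs ``indel_penalty``.  A tract is
reported when its score reaches ``min_score``.  With the default weights
(2 / 7 / 7, threshold 40) the shortest reportable mismatch-free tract is
20 nt, i.e. 6 2/3 trinucleotide units.

Detection is exact under this scoring scheme: candidate regions are found by
a self-similarity seed pass, and within each region every canonical unit
class is aligned by local wraparound dynamic programming; maximal
non-overlapping candidates are extracted so that no extension or trimming of
a reported tract can increase its score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

_BASES = "ACGT"
_VALID = set("ACGTN")


class ScanError(ValueError):
    """Invalid input to the repeat scanner."""


def canonical_unit(unit: str) -> str:
    """Lexicographically smallest rotation of a repeat unit.

    Used to aggregate tracts whose observed units are rotations of each
    other (e.g. CAG / AGC / GCA all canonicalize to AGC).
    """
    if not unit or any(b not in _BASES for b in unit):
        raise ScanError(f"unit must be a non-empty string over ACGT, got {unit!r}")
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


@dataclass(frozen=True)
class ScanParams:
    """Scoring scheme for wraparound tract alignment.

    match_weight / mismatch_penalty / indel_penalty are per-nucleotide
    scores (penalties are stored positive and subtracted).  ``min_score``
    is the reporting threshold and ``max_period`` caps the repeat unit
    length (3 = trinucleotide repeats and below).
    """

    match_weight: int = 2
    mismatch_penalty: int = 7
    indel_penalty: int = 7
    min_score: int = 40
    max_period: int = 3

    def __post_init__(self) -> None:
        if min(self.match_weight, self.mismatch_penalty, self.indel_penalty) <= 0:
            raise ScanError("all alignment weights must be positive")
        if self.min_score <= 0:
            raise ScanError("min_score must be positive")
        if self.max_period not in (1, 2, 3):
            raise ScanError("max_period must be 1, 2 or 3")

    @property
    def min_pure_length(self) -> int:
        """Length of the shortest mismatch-free tract reaching min_score."""
        return math.ceil(self.min_score / self.match_weight)


@dataclass
class RepeatTract:
    """One detected tandem repeat tract (0-based half-open coordinates)."""

    sequence_id: str
    start: int
    end: int
    period: int
    unit: str
    canonical_unit: str
    copies: float
    score: int
    matches: int
    mismatches: int
    indels: int
    purity: float
    seq: str = ""
    region_class: str | None = None
    gene_id: str | None = None
    protein_id: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def _validate_seq(seq: str) -> None:
    bad = set(seq) - _VALID
    if bad:
        raise ScanError(f"sequence contains non-ACGTN characters: {sorted(bad)}")


def _col_score(c: str, u: str, params: ScanParams) -> int:
    # N never matches anything, including N.
    if c == u and c != "N":
        return params.match_weight
    return -params.mismatch_penalty


def _global_table(seq: str, unit: str, params: ScanParams) -> list[list[int]]:
    """Global wraparound DP table; state j = index of next expected unit char.

    Start phase and end phase are free; every sequence character is consumed
    (matched, mismatched, or paid for as an insertion).
    """
    p = len(unit)
    n = len(seq)
    rows = [[0] * p]
    ins = params.indel_penalty
    dele = params.indel_penalty
    for i in range(1, n + 1):
        c = seq[i - 1]
        prev = rows[-1]
        cur = [0] * p
        for j in range(p):
            pj = (j - 1) % p
            a = prev[pj] + _col_score(c, unit[pj], params)
            b = prev[j] - ins
            cur[j] = a if a >= b else b
        # within-row deletion relaxation around the phase ring
        for _ in range(2):
            for j in range(p):
                d = cur[(j - 1) % p] - dele
                if d > cur[j]:
                    cur[j] = d
        rows.append(cur)
    return rows


def score_tract(seq: str, unit: str, params: ScanParams | None = None) -> tuple[int, int, int, int]:
    """Maximum global wraparound-alignment score of ``seq`` against ``unit``^inf.

    Returns (score, matches, mismatches, indels).  Counts come from one
    optimal alignment, preferring matches, then mismatches, then indels when
    several alignments are optimal.  The empty sequence scores (0, 0, 0, 0).
    """
    params = params or ScanParams()
    if any(b not in _BASES for b in unit) or not unit:
        raise ScanError(f"unit must be over ACGT, got {unit!r}")
    if len(unit) > params.max_period:
        raise ScanError(f"unit longer than max_period={params.max_period}")
    _validate_seq(seq)
    if not seq:
        return (0, 0, 0, 0)
    p = len(unit)
    rows = _global_table(seq, unit, params)
    n = len(seq)
    score = max(rows[n])
    j = rows[n].index(score)
    i = n
    matches = mismatches = indels = 0
    while i > 0:
        pj = (j - 1) % p
        cur = rows[i][j]
        diag = rows[i - 1][pj] + _col_score(seq[i - 1], unit[pj], params)
        if cur == diag:
            if _col_score(seq[i - 1], unit[pj], params) > 0:
                matches += 1
            else:
                mismatches += 1
            i -= 1
            j = pj
        elif cur == rows[i - 1][j] - params.indel_penalty:
            indels += 1
            i -= 1
        elif cur == rows[i][pj] - params.indel_penalty:
            indels += 1
            j = pj
        else:  # pragma: no cover - DP invariant
            raise AssertionError("traceback failed")
    return (score, matches, mismatches, indels)


def unit_classes(max_period: int = 3) -> list[str]:
    """Canonical repeat unit classes up to ``max_period``.

    Homopolymeric 2-mers/3-mers are represented by their period-1 unit.
    """
    units: list[str] = list(_BASES)
    if max_period >= 2:
        units += sorted(
            {canonical_unit(a + b) for a in _BASES for b in _BASES if a != b}
        )
    if max_period >= 3:
        tri = {
            canonical_unit(a + b + c)
            for a in _BASES
            for b in _BASES
            for c in _BASES
        }
        units += sorted(u for u in tri if len(set(u)) > 1)
    return units


def _candidate_regions(
    seq: str, params: ScanParams, seed_threshold: int = 10, pad: int = 60
) -> list[tuple[int, int]]:
    """Windows that can contain a reportable tract.

    A Kadane-style local score of the sequence against itself at offsets
    1..max_period marks self-similar stretches; marked positions are padded
    and merged.  Any tract reaching min_score under the scanner's weights
    produces long self-match runs, so the seed threshold sits far below the
    reporting threshold.
    """
    n = len(seq)
    if n < params.min_pure_length:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    not_n = arr != ord("N")
    hits: list[np.ndarray] = []
    for p in range(1, params.max_period + 1):
        if n <= p:
            continue
        m = (arr[p:] == arr[:-p]) & not_n[p:] & not_n[:-p]
        vals = np.where(m, params.match_weight, -params.mismatch_penalty).astype(np.int64)
        c = np.concatenate(([0], np.cumsum(vals)))
        x = c - np.minimum.accumulate(c)
        idx = np.nonzero(x[1:] >= seed_threshold)[0]
        if idx.size:
            hits.append(idx + p)
    if not hits:
        return []
    pos = np.unique(np.concatenate(hits))
    regions: list[tuple[int, int]] = []
    start = int(pos[0])
    prev = int(pos[0])
    for q in pos[1:]:
        q = int(q)
        if q - prev > 2 * pad:
            regions.append((max(0, start - pad), min(n, prev + pad)))
            start = q
        prev = q
    regions.append((max(0, start - pad), min(n, prev + pad)))
    merged: list[tuple[int, int]] = []
    for s, e in regions:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass(frozen=True)
class _Candidate:
    score: int
    start: int
    end: int
    unit: str  # canonical class used in the DP
    start_phase: int
    matches: int
    mismatches: int
    indels: int

    @property
    def sort_key(self):
        return (-self.score, -(self.end - self.start), self.start, self.unit)


def _local_best(sub: str, unit: str, params: ScanParams) -> _Candidate | None:
    """Best-scoring tract for one unit class within ``sub`` (local DP).

    Ties on score prefer the longer tract, then the smaller start.  Returns
    None when nothing reaches min_score.
    """
    p = len(unit)
    n = len(sub)
    if n == 0:
        return None
    ins = params.indel_penalty
    rows: list[list[int]] = [[0] * p]
    for i in range(1, n + 1):
        c = sub[i - 1]
        prev = rows[-1]
        cur = [0] * p
        for j in range(p):
            pj = (j - 1) % p
            a = prev[pj] + _col_score(c, unit[pj], params)
            b = prev[j] - ins
            best = a if a >= b else b
            cur[j] = best if best > 0 else 0
        for _ in range(2):
            for j in range(p):
                d = cur[(j - 1) % p] - ins
                if d > cur[j]:
                    cur[j] = d
        rows.append(cur)
    best_score = max(max(r) for r in rows)
    if best_score < params.min_score:
        return None

    def _traceback(i: int, j: int) -> tuple[int, int, int, int, int]:
        matches = mismatches = indels = 0
        while rows[i][j] > 0:
            pj = (j - 1) % p
            cs = _col_score(sub[i - 1], unit[pj], params) if i > 0 else None
            if i > 0 and rows[i][j] == rows[i - 1][pj] + cs:
                if cs > 0:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j = pj
            elif i > 0 and rows[i][j] == rows[i - 1][j] - ins:
                indels += 1
                i -= 1
            elif rows[i][j] == rows[i][pj] - ins:
                indels += 1
                j = pj
            else:  # pragma: no cover - DP invariant
                raise AssertionError("local traceback failed")
        return i, j, matches, mismatches, indels

    best: _Candidate | None = None
    for i in range(1, n + 1):
        for j in range(p):
            if rows[i][j] != best_score:
                continue
            s, j0, ma, mi, ind = _traceback(i, j)
            # extend the start leftwards over any equal-scoring plateau
            while s > 0:
                sc, ma2, mi2, ind2 = score_tract(sub[s - 1 : i], unit, params)
                if sc == best_score:
                    s -= 1
                    # recompute phase of the earlier start
                    j0 = None
                    ma, mi, ind = ma2, mi2, ind2
                else:
                    break
            if j0 is None:
                j0 = _start_phase(sub[s:i], unit, params)
            cand = _Candidate(best_score, s, i, unit, j0, ma, mi, ind)
            if best is None or cand.sort_key < best.sort_key:
                best = cand
    return best


def _start_phase(tract_seq: str, unit: str, params: ScanParams) -> int:
    """Phase of the first aligned unit character for an optimal alignment."""
    p = len(unit)
    rows = _global_table(tract_seq, unit, params)
    n = len(tract_seq)
    score = max(rows[n])
    j = rows[n].index(score)
    i = n
    while i > 0:
        pj = (j - 1) % p
        cur = rows[i][j]
        if cur == rows[i - 1][pj] + _col_score(tract_seq[i - 1], unit[pj], params):
            i -= 1
            j = pj
        elif cur == rows[i - 1][j] - params.indel_penalty:
            i -= 1
        else:
            j = pj
    return j


def _extract(sub: str, offset: int, units: Sequence[str], params: ScanParams,
             out: list[_Candidate]) -> None:
    """Recursively pull maximal non-overlapping candidates out of ``sub``."""
    if len(sub) < params.min_pure_length:
        return
    best: _Candidate | None = None
    for unit in units:
        cand = _local_best(sub, unit, params)
        if cand is not None and (best is None or cand.sort_key < best.sort_key):
            best = cand
    if best is None:
        return
    out.append(replace(best, start=best.start + offset, end=best.end + offset))
    _extract(sub[: best.start], offset, units, params, out)
    _extract(sub[best.end :], offset + best.end, units, params, out)


def scan(seq: str, sequence_id: str = "seq", params: ScanParams | None = None) -> list[RepeatTract]:
    """All maximal non-overlapping tracts with period <= max_period and
    score >= min_score, sorted by start position.

    Reported tracts are locally optimal: neither extending nor trimming a
    tract increases its score, and overlapping candidates are resolved by
    (higher score, longer tract, smaller start, smaller canonical unit).
    """
    params = params or ScanParams()
    _validate_seq(seq)
    if len(seq) < params.min_pure_length:
        return []
    units = unit_classes(params.max_period)
    cands: list[_Candidate] = []
    for rs, re_ in _candidate_regions(seq, params):
        _extract(seq[rs:re_], rs, units, params, cands)
    tracts: list[RepeatTract] = []
    for c in sorted(cands, key=lambda c: c.start):
        p = len(c.unit)
        observed = c.unit[c.start_phase :] + c.unit[: c.start_phase]
        cols = c.matches + c.mismatches + c.indels
        tracts.append(
            RepeatTract(
                sequence_id=sequence_id,
                start=c.start,
                end=c.end,
                period=p,
                unit=observed,
                canonical_unit=c.unit,
                copies=(c.end - c.start) / p,
                score=c.score,
                matches=c.matches,
                mismatches=c.mismatches,
                indels=c.indels,
                purity=c.matches / cols if cols else 1.0,
                seq=seq[c.start : c.end],
            )
        )
    return tracts


def scan_fasta(records: Iterable[tuple[str, str]], params: ScanParams | None = None) -> list[RepeatTract]:
    """Scan (id, sequence) pairs; sequences are uppercased first."""
    out: list[RepeatTract] = []
    for sid, s in records:
        out.extend(scan(s.upper(), sequence_id=sid, params=params))
    return out


def filter_period3(tracts: Iterable[RepeatTract], params: ScanParams | None = None) -> list[RepeatTract]:
    """Keep genuine period-3 tracts.

    Drops period-1/2 tracts, period-3 units with fewer than two distinct
    bases, and period-3 tracts that a period-1 or period-2 unit explains at
    least as well (scored on the tract's own sequence when available).
    """
    params = params or ScanParams()
    kept: list[RepeatTract] = []
    for t in tracts:
        if t.period != 3 or len(set(t.unit)) < 2:
            continue
        if t.seq:
            alt_units = sorted({b for b in t.seq if b in _BASES})
            alt_units += sorted(
                {canonical_unit(a + b) for a in t.seq for b in t.seq
                 if a in _BASES and b in _BASES and a != b}
            )
            alt_best = max(
                (score_tract(t.seq, u, params)[0] for u in alt_units), default=None
            )
            if alt_best is not None and alt_best > t.score:
                continue
        kept.append(t)
    return kept


_TSV_COLUMNS = [
    "sequence_id", "start", "end", "period", "unit", "canonical_unit",
    "copies", "score", "matches", "mismatches", "indels", "purity",
    "seq", "region_class", "gene_id", "protein_id",
]


def tracts_to_frame(tracts: Iterable[RepeatTract]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in tracts], columns=_TSV_COLUMNS)


def write_tracts_tsv(tracts: Iterable[RepeatTract], path) -> None:
    tracts_to_frame(tracts).to_csv(path, sep="\t", index=False)


def read_tracts_tsv(path) -> list[RepeatTract]:
    df = pd.read_csv(path, sep="\t", dtype={"sequence_id": str})
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        for k in ("seq", "region_class", "gene_id", "protein_id"):
            if k in d and (pd.isna(d[k]) or d[k] == ""):
                d[k] = None if k != "seq" else ""
        out.append(RepeatTract(**d))
    return out


def write_tracts_bed(tracts: Iterable[RepeatTract], path) -> None:
    """BED6: name = canonical unit, score capped at 1000."""
    with open(path, "w") as fh:
        for t in tracts:
            fh.write(
                f"{t.sequence_id}\t{t.start}\t{t.end}\t{t.canonical_unit}\t"
                f"{min(t.score, 1000)}\t+\n"
            )
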