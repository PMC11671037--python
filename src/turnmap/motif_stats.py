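"""Sequence-motif grammar, matching, significance and profiles.

A motif places one to three amino acids at named positions of the
8-residue turn/tail window (-2, -1, 1, 2, 3, 4, +1, +2), e.g. "D3S+1" =
Asp at turn position 3 and Ser just past the turn. Overrepresentation of a
motif inside a cluster is scored with an exact one-sided binomial tail
against the position-specific background composition of the full turn set.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .turn_detection import TurnInstance, POSITION_LABELS

__all__ = [
    "POSITIONS",
    "AA_ALPHABET",
    "MotifSpec",
    "MotifStats",
    "parse_motif",
    "match_motif",
    "binomial_tail",
    "motif_significance",
    "fractional_overrep",
    "positional_background",
    "log_odds_profile",
    "rank_motifs",
    "ranking_to_table",
]

POSITIONS = POSITION_LABELS  # ("-2", "-1", "1", "2", "3", "4", "+1", "+2")
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_TOKEN = re.compile(r"([A-Z])\s*([+-]?[0-9]+)")


@dataclass(frozen=True)
class MotifSpec:
    """1-3 (position, amino acid) constraints over the turn/tail window."""

    constraints: tuple[tuple[str, str], ...]  # ((position, aa), ...)

    def __post_init__(self) -> None:
        if not 1 <= len(self.constraints) <= 3:
            raise ValueError("a motif takes 1 to 3 constraints")
        positions = [p for p, _ in self.constraints]
        if len(set(positions)) != len(positions):
            raise ValueError(f"duplicate motif position in {self.name}")
        for p, aa in self.constraints:
            if p not in POSITIONS:
                raise ValueError(f"invalid motif position {p!r}")
            if aa not in AA_ALPHABET:
                raise ValueError(f"invalid amino acid {aa!r}")

    @property
    def name(self) -> str:
        return "".join(f"{aa}{p}" for p, aa in self.constraints)

    def __str__(self) -> str:
        return self.name


@dataclass
class MotifStats:
    n_obs: int
    n_expected: float
    p_value: float
    score: float                  # -log10(p)
    fractional_overrep: Optional[float]  # percent, None when n_obs == 0
    heat: float = 0.0             # relative significance in [0, 1]
    p_bonferroni: Optional[float] = None


def parse_motif(s: str) -> MotifSpec:
    """Parse a motif string such as "D3S+1" or "D1R3".

    Tokens are an amino-acid letter followed by a window position; whitespace
    is ignored. Unknown letters, invalid positions and duplicate positions
    raise a ValueError naming the offending token.
    """
    if not s or not s.strip():
        raise ValueError("empty motif string")
    stripped = s.strip()
    pos = 0
    constraints = []
    for m in _TOKEN.finditer(stripped):
        between = stripped[pos:m.start()]
        if between.strip():
            raise ValueError(f"cannot parse motif token {between.strip()!r}")
        aa, position = m.group(1), m.group(2)
        if aa not in AA_ALPHABET:
            raise ValueError(f"unknown amino acid in token {m.group(0)!r}")
        if position not in POSITIONS:
            raise ValueError(f"invalid position in token {m.group(0)!r}")
        constraints.append((position, aa))
        pos = m.end()
    if stripped[pos:].strip():
        raise ValueError(f"cannot parse motif token {stripped[pos:].strip()!r}")
    if not constraints:
        raise ValueError(f"no motif tokens in {s!r}")
    return MotifSpec(constraints=tuple(constraints))


def _seq_at(sequence8: str, position: str) -> str:
    return sequence8[POSITIONS.index(position)]


def match_motif(turn: TurnInstance | str, m: MotifSpec) -> bool:
    """True iff every constrained position exists (is not '-') and carries
    the specified amino acid."""
    seq = turn if isinstance(turn, str) else turn.sequence8
    return all(_seq_at(seq, p) == aa for p, aa in m.constraints)


def _pmf_exact(n: int, k: int, p: float) -> float:
    """Binomial pmf at k, correctly rounded: exact integer C(n, k) and exact
    rational powers of the (dyadic) float p, converted to float at the end."""
    from fractions import Fraction

    fp = Fraction(p)
    fq = 1 - fp
    return float(math.comb(n, k) * fp ** k * fq ** (n - k))


def _sum_pmf_away_from_mode(n: int, p: float, start: int, step: int) -> float:
    """Sum of pmf terms from ``start`` moving by ``step`` (+1 or -1) to the
    chain end. Valid when the walk moves away from the mode, so terms are
    non-increasing; the anchor term is exact and the recurrence drift of the
    rapidly decaying later terms is negligible. fsum makes the accumulation
    exact."""
    t = _pmf_exact(n, start, p)
    if t == 0.0:
        return 0.0
    ratio = p / (1.0 - p)
    terms = []
    i = start
    while 0 <= i <= n:
        terms.append(t)
        if t < terms[0] * 1e-22:
            break
        if step > 0:
            t *= ratio * (n - i) / (i + 1)
        else:
            t *= (i / (n - i + 1)) / ratio
        i += step
    return math.fsum(terms)


def binomial_tail(n_obs: int, n: int, p: float) -> float:
    """Exact one-sided upper tail P(X >= n_obs), X ~ Binomial(n, p).

    Computed by direct summation of the probability mass on whichever side
    of the count is smaller (the complement is used when the tail itself
    would be the large side), anchored at an exactly computed term; relative
    accuracy is a few ulp for n up to ~1e5.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("background probability must lie in (0, 1)")
    if n_obs <= 0:
        return 1.0
    if n_obs > n:
        return 0.0
    if n_obs <= n * p:
        # upper tail >= ~1/2: sum the lower side and complement
        lower = _sum_pmf_away_from_mode(n, p, n_obs - 1, -1)
        return min(1.0, max(0.0, 1.0 - lower))
    return min(1.0, _sum_pmf_away_from_mode(n, p, n_obs, +1))


def motif_significance(n_obs: int, n_cluster: int, p_bg: float) -> MotifStats:
    """Exact binomial overrepresentation of a motif within a cluster.

    n_cluster trials at background probability p_bg; the p-value is the
    upper tail at the observed count and the score is -log10(p).
    """
    if not 0 <= n_obs <= n_cluster:
        raise ValueError("need 0 <= n_obs <= n_cluster")
    pval = binomial_tail(n_obs, n_cluster, p_bg)
    n_exp = n_cluster * p_bg
    return MotifStats(
        n_obs=n_obs,
        n_expected=n_exp,
        p_value=pval,
        score=-math.log10(pval) if pval > 0 else math.inf,
        fractional_overrep=fractional_overrep(n_obs, n_exp) if n_obs > 0 else None,
    )


def fractional_overrep(n_obs: int, n_expected: float) -> float:
    """(observed - expected) / observed, as a percentage.

    Bounded above by 100%; negative for underrepresented motifs. Undefined
    at zero observations.
    """
    if n_obs <= 0:
        raise ValueError("fractional overrepresentation needs n_obs > 0")
    return 100.0 * (n_obs - n_expected) / n_obs


def positional_background(
    turns: Sequence[TurnInstance | str],
) -> dict[str, dict[str, float]]:
    """Per-position amino-acid frequencies over the full turn/tail set.

    Absent tail positions ('-') are excluded from the denominators, so each
    position's frequencies are conditional on the position existing.
    """
    counts = {p: {aa: 0 for aa in AA_ALPHABET} for p in POSITIONS}
    totals = {p: 0 for p in POSITIONS}
    for t in turns:
        seq = t if isinstance(t, str) else t.sequence8
        for p, ch in zip(POSITIONS, seq):
            if ch in counts[p]:
                counts[p][ch] += 1
                totals[p] += 1
    return {
        p: {aa: (counts[p][aa] / totals[p] if totals[p] else 0.0) for aa in AA_ALPHABET}
        for p in POSITIONS
    }


def log_odds_profile(
    cluster_turns: Sequence[TurnInstance | str],
    background_freqs: dict[str, dict[str, float]],
) -> dict[str, dict[str, float]]:
    """Position-specific log-odds profile of a cluster, in bits.

    log2((f_obs + a) / (f_bg + a)) with pseudocount a = 1 / (2 * cluster
    size); an amino acid absent from both cluster and background scores 0.
    """
    n = len(cluster_turns)
    if n == 0:
        raise ValueError("empty cluster")
    alpha = 1.0 / (2.0 * n)
    obs = positional_background(cluster_turns)
    return {
        p: {
            aa: math.log2((obs[p][aa] + alpha) / (background_freqs[p][aa] + alpha))
            for aa in AA_ALPHABET
        }
        for p in POSITIONS
    }


def _scope_filter(turns: Sequence[TurnInstance], scope: str) -> list[TurnInstance]:
    if scope == "global":
        return list(turns)
    kind, _, value = scope.partition(":")
    if kind == "type":
        return [t for t in turns if t.classical_type == value]
    if kind == "bb":
        return [t for t in turns if str(t.bb_cluster) == value]
    raise ValueError(f"unknown scope {scope!r}; use 'global', 'type:X' or 'bb:X'")


def rank_motifs(
    turns: Sequence[TurnInstance],
    scope: str = "global",
    arity: int = 1,
    min_support: int = 10,
    background: Optional[dict[str, dict[str, float]]] = None,
) -> list[tuple[MotifSpec, MotifStats]]:
    """Enumerate and rank the motifs of a given arity within a scope.

    Candidate motifs are the position/amino-acid combinations actually
    observed at least ``min_support`` times in the scope; each is scored by
    the exact binomial tail against the positional background of the full
    set (independence across positions for multi-residue motifs). Results
    are sorted by p ascending, ties by count descending then name; each
    carries a Bonferroni-corrected p over the enumerated family.
    """
    if arity not in (1, 2, 3):
        raise ValueError("arity must be 1, 2 or 3")
    scoped = _scope_filter(turns, scope)
    if not scoped:
        return []
    bg = background if background is not None else positional_background(turns)

    counts: dict[tuple[tuple[str, str], ...], int] = {}
    for t in scoped:
        present = [
            (p, ch) for p, ch in zip(POSITIONS, t.sequence8) if ch in AA_ALPHABET
        ]
        for combo in itertools.combinations(present, arity):
            counts[combo] = counts.get(combo, 0) + 1

    candidates = {c: k for c, k in counts.items() if k >= min_support}
    if not candidates:
        return []
    n_family = len(candidates)

    results = []
    for combo, n_obs in candidates.items():
        # trials: scope members where every motif position exists
        n_trials = sum(
            1
            for t in scoped
            if all(_seq_at(t.sequence8, p) != "-" for p, _ in combo)
        )
        p_bg = 1.0
        for p, aa in combo:
            p_bg *= bg[p][aa]
        if not 0.0 < p_bg < 1.0:
            continue
        stats = motif_significance(n_obs, n_trials, p_bg)
        stats.p_bonferroni = min(1.0, stats.p_value * n_family)
        results.append((MotifSpec(constraints=combo), stats))

    results.sort(key=lambda r: (r[1].p_value, -r[1].n_obs, r[0].name))
    return results


def ranking_to_table(
    ranked: Sequence[tuple[MotifSpec, MotifStats]], scope: str = "global"
) -> pd.DataFrame:
    rows = [
        {
            "motif": spec.name,
            "scope": scope,
            "n_obs": st.n_obs,
            "n_expected": round(st.n_expected, 3),
            "p": st.p_value,
            "p_bonferroni": st.p_bonferroni,
            "fractional_overrep_pct": (
                round(st.fractional_overrep, 2) if st.fractional_overrep is not None else ""
            ),
        }
        for spec, st in ranked
    ]
    return pd.DataFrame(
        rows,
        columns=["motif", "scope", "n_obs", "n_expected", "p", "p_bonferroni",
                 "fractional_overrep_pct"],
    )
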