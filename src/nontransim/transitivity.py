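"""Nontransitivity detection along a genealogical chain of clones.

A chain Early -> Intermediate -> Late is transitive when the direct
long-range fitness matches the additive expectation from the stepwise
gains.  It is nontransitive when the later clone loses to the distant
ancestor despite each step being adaptive, and frequency-dependent
nontransitive when the long-range outcome changes sign with starting
frequency (the signature of toxin-mediated positive frequency dependence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx


def additive_expectation(steps: list[float], mode: str = "sum") -> float:
    """Expected long-range fitness gain from stepwise gains.

    sum mode: sigma of the per-step coefficients (the usual arithmetic for
    small s); compound mode: product of (1 + s_i) minus 1.
    """
    if not steps:
        raise ValueError("need at least one step")
    if mode == "sum":
        return float(sum(steps))
    if mode == "compound":
        prod = 1.0
        for s in steps:
            prod *= 1.0 + s
        return prod - 1.0
    raise ValueError("mode must be 'sum' or 'compound'")


@dataclass(frozen=True)
class FitnessEntry:
    s_hat: float
    stderr: float | None = None
    f0: float | None = None  # starting frequency of the later clone


@dataclass
class PairwiseFitnessMatrix:
    """Per-pair fitness of a later clone vs an earlier clone.

    ``clones`` are ordered by genealogical time; entries are indexed by
    (earlier, later) and may hold several estimates at different starting
    frequencies.
    """

    clones: list[str]
    entries: dict = field(default_factory=dict)  # (earlier, later) -> [FitnessEntry]

    def add(self, earlier: str, later: str, s_hat: float,
            stderr: float | None = None, f0: float | None = None) -> None:
        self.entries.setdefault((earlier, later), []).append(
            FitnessEntry(s_hat, stderr, f0)
        )

    def get(self, earlier: str, later: str) -> list[FitnessEntry]:
        if (earlier, later) in self.entries:
            return self.entries[(earlier, later)]
        # antisymmetry: s(i->j, f0) = -s(j->i, 1-f0)
        if (later, earlier) in self.entries:
            return [
                FitnessEntry(-e.s_hat, e.stderr,
                             None if e.f0 is None else 1.0 - e.f0)
                for e in self.entries[(later, earlier)]
            ]
        raise KeyError(f"no entry for ({earlier}, {later})")


@dataclass
class TransitivityVerdict:
    triple: tuple[str, str, str]
    expected_s_ik: float
    observed_s_ik: list[FitnessEntry]
    verdict: str  # transitive | nontransitive | frequency_dependent_nontransitive
    deviation: float  # mean observed minus additive expectation


def _sign(entry: FitnessEntry) -> int:
    """-1 / +1 when the estimate is significantly negative / positive, 0 on a tie.

    Significance: |estimate| > 2 * stderr; with no stderr the point estimate's
    sign decides.  Ties are conservative (treated as no evidence).
    """
    if entry.stderr is not None and abs(entry.s_hat) <= 2.0 * entry.stderr:
        return 0
    if entry.s_hat > 0:
        return 1
    if entry.s_hat < 0:
        return -1
    return 0


def _mean(entries: list[FitnessEntry]) -> float:
    return sum(e.s_hat for e in entries) / len(entries)


def classify_triple(
    matrix: PairwiseFitnessMatrix, triple: tuple[str, str, str],
    mode: str = "sum",
) -> TransitivityVerdict:
    """Classify a genealogical triple (i earlier, j, k later).

    Nontransitive requires a significantly negative observed s(i->k) at some
    tested frequency while both stepwise gains are positive; frequency-
    dependent nontransitive additionally requires the long-range outcome to
    change sign across tested frequencies.
    """
    i, j, k = triple
    s_ij = _mean(matrix.get(i, j))
    s_jk = _mean(matrix.get(j, k))
    obs = matrix.get(i, k)
    expected = additive_expectation([s_ij, s_jk], mode=mode)
    deviation = _mean(obs) - expected
    signs = {_sign(e) for e in obs}
    verdict = "transitive"
    if s_ij > 0 and s_jk > 0 and -1 in signs:
        verdict = (
            "frequency_dependent_nontransitive" if 1 in signs else "nontransitive"
        )
    return TransitivityVerdict(triple, expected, obs, verdict, deviation)


def dominance_cycles(outcomes: list[tuple[str, str]]) -> list[list[str]]:
    """All elementary cycles of a win/loss digraph, shortest first.

    ``outcomes`` lists (winner, loser) edges, at most one per pair.  Cycles
    are rotated to start at their smallest node and sorted by (length,
    lexicographic order).
    """
    seen_pairs = set()
    for w, l in outcomes:
        if frozenset((w, l)) in seen_pairs:
            raise ValueError(f"both orientations present for pair ({w}, {l})")
        seen_pairs.add(frozenset((w, l)))
    g = nx.DiGraph(outcomes)
    cycles = []
    for cyc in nx.simple_cycles(g):
        m = cyc.index(min(cyc))
        cycles.append(cyc[m:] + cyc[:m])
    cycles.sort(key=lambda c: (len(c), c))
    return cycles
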