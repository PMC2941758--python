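"""Independent brute-force oracles used only by the tests.

Kept deliberately naive: exact rational arithmetic from factorials for
the hypergeometric tail, and literal subset enumeration for splice
events, so they share no algorithmic path with the implementation.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import factorial
from typing import Sequence

from estsplice.events import LabeledIntron
from estsplice.model import GenomeInterval


def exact_upper_tails(N: int, K: int, n: int) -> dict[int, Fraction]:
    """P(X >= k) for every k in 0..n, as exact Fractions."""
    f = factorial

    def pmf(i: int) -> Fraction:
        if i < 0 or i > K or n - i < 0 or n - i > N - K:
            return Fraction(0)
        ways = Fraction(f(K), f(i) * f(K - i)) * \
            Fraction(f(N - K), f(n - i) * f(N - K - n + i))
        return ways / Fraction(f(N), f(n) * f(N - n))

    tails = {}
    running = Fraction(0)
    for k in range(n, -1, -1):
        running += pmf(k)
        tails[k] = running
    return tails


EventKey = tuple[str, str, frozenset, frozenset]


def event_key(kind: str, condition: str,
              inclusion: Sequence[GenomeInterval],
              skipping: Sequence[GenomeInterval]) -> EventKey:
    return (
        kind, condition,
        frozenset((iv.start, iv.end) for iv in inclusion),
        frozenset((iv.start, iv.end) for iv in skipping),
    )


def _valid_chain(chain: Sequence[GenomeInterval], start: int,
                 end: int) -> bool:
    chain = sorted(chain, key=lambda iv: (iv.start, iv.end))
    if chain[0].start != start or chain[-1].end != end:
        return False
    return all(b.start >= a.end + 2 for a, b in zip(chain, chain[1:]))


def enumerate_events(labeled: Sequence[LabeledIntron],
                     max_chain: int = 3) -> set[EventKey]:
    """All events found by testing every subset of <= 4 introns."""
    by_side = {"T": [], "N": []}
    for li in labeled:
        if li.side is not None:
            by_side[li.side].append(li.interval)

    found: set[EventKey] = set()
    for skip_side, incl_side in (("T", "N"), ("N", "T")):
        for skip in by_side[skip_side]:
            for size in range(2, max_chain + 1):
                for chain in combinations(by_side[incl_side], size):
                    if _valid_chain(chain, skip.start, skip.end):
                        kind = "cassette" if size == 2 else "double_cassette"
                        found.add(event_key(kind, incl_side,
                                            sorted(chain), [skip]))
    for t_pair in combinations(by_side["T"], 2):
        for n_pair in combinations(by_side["N"], 2):
            outer = (min(iv.start for iv in t_pair),
                     max(iv.end for iv in t_pair))
            if not _valid_chain(t_pair, *outer):
                continue
            if not _valid_chain(n_pair, *outer):
                continue
            tc = sorted(t_pair, key=lambda iv: iv.start)
            nc = sorted(n_pair, key=lambda iv: iv.start)
            t_exon = (tc[0].end + 1, tc[1].start - 1)
            n_exon = (nc[0].end + 1, nc[1].start - 1)
            if t_exon[0] <= n_exon[1] and n_exon[0] <= t_exon[1]:
                continue  # internal exons overlap
            found.add(event_key("mutually_exclusive", "T", tc, nc))
    return found


def random_labeled_introns(rng, n_introns: int,
                           n_boundaries: int = 8) -> list[LabeledIntron]:
    """Random introns on a shared boundary grid (so exact boundary
    coincidences, hence events, occur often) with random labels."""
    pts = sorted(rng.choice(range(10, 1000, 10), size=n_boundaries,
                            replace=False))
    labels = ["NN", "N", "E", "T", "TT"]
    seen = set()
    out = []
    while len(out) < n_introns:
        i, j = sorted(rng.choice(len(pts), size=2, replace=False))
        if (i, j) in seen:
            continue
        seen.add((i, j))
        out.append(LabeledIntron(
            GenomeInterval("chr1", int(pts[i]), int(pts[j])),
            labels[rng.integers(len(labels))],
        ))
    return out
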