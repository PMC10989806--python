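"""Hypergeometric over-representation analysis (ORA).

The classical comparator to the reporter score: fix a significance cutoff
(alpha, default 0.05), call every KO below it "significant", and test each
pathway for over-representation of significant KOs with the upper tail of
the hypergeometric distribution. The universe is the set of tested KOs, so
ORA and the reporter score are computed over identical universes.

Unlike the reporter score, ORA depends on the a priori cutoff; unlike the
misread of the reporter score, it never pretends to know a direction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffstats import KOStat
from .errors import ValidationError
from .reporter import DEFAULT_MIN_K, PathwaySet, _bh_qvalues

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ORARow:
    """One pathway's over-representation result."""

    pathway_id: str
    k: int          # pathway size within the universe
    n_sig: int      # significant KOs in the universe
    overlap: int    # significant KOs inside the pathway
    p_hyper: float  # upper-tail P(X >= overlap)
    q_value: float


def hypergeom_upper(x: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= x) for X ~ Hypergeometric(N, K, n).

    N: universe size; K: pathway size; n: significant-list size; x: overlap.
    Computed by exact integer summation of binomial coefficients,
    sum_{i=x}^{min(K,n)} C(K,i) C(N-K,n-i) / C(N,n).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (0 <= x <= min(K, n)):
        raise ValidationError(f"overlap x={x} outside [0, min({K}, {n})]")
    hi = min(K, n)
    lo = max(x, n - (N - K))  # terms below this have zero probability
    numer = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(lo, hi + 1))
    return numer / math.comb(N, n)


def run_ora(
    ko_stats: list[KOStat],
    sets: PathwaySet,
    alpha: float = 0.05,
    min_k: int = DEFAULT_MIN_K,
) -> list[ORARow]:
    """ORA over every retained pathway; BH q values; sorted by p_hyper.

    The significant list is {KO : p_value < alpha}. An empty significant
    list is not an error: every pathway then has overlap 0 and p_hyper 1.
    """
    if not ko_stats:
        raise ValidationError("empty KO universe")
    if len(sets) == 0:
        raise ValidationError("empty pathway set")
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    universe = {s.ko_id for s in ko_stats}
    sig = {s.ko_id for s in ko_stats if s.p_value < alpha}
    if not sig:
        logger.warning("no KOs significant at alpha=%g; all p_hyper = 1", alpha)
    retained = sets.restrict(universe, min_k=min_k)
    N, n = len(universe), len(sig)
    rows = []
    for pid in sorted(retained.pathways):
        members = retained.pathways[pid]
        x = len(members & sig)
        rows.append((pid, len(members), x, hypergeom_upper(x, len(members), n, N)))
    qvals = _bh_qvalues(np.array([r[3] for r in rows], dtype=float))
    out = [
        ORARow(pid, k, n, x, p, float(q))
        for (pid, k, x, p), q in zip(rows, qvals)
    ]
    out.sort(key=lambda r: (r.p_hyper, r.pathway_id))
    return out


def ora_to_frame(rows: list[ORARow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway": [r.pathway_id for r in rows],
            "k": [r.k for r in rows],
            "n_sig": [r.n_sig for r in rows],
            "overlap": [r.overlap for r in rows],
            "p_hyper": [r.p_hyper for r in rows],
            "q_value": [r.q_value for r in rows],
        }
    )
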