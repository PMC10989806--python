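"""The reporter-score algorithm, with correct undirected interpretation.

Per-KO P values are mapped to Z scores with the inverse standard-normal
distribution, Z_i = Phi^-1(1 - P_i); a pathway of k member KOs is scored by
the size-independent aggregate Z_pathway = (1/sqrt(k)) * sum(Z_i); and the
aggregate is background-corrected against random KO sets of the same size,

    reporter score = (Z_pathway - mu_k) / sigma_k,

where mu_k, sigma_k are the mean and standard deviation of aggregates over
random size-k subsets of the scored universe (exhaustive enumeration when
feasible, seeded Monte Carlo otherwise).

Interpretation contract
-----------------------
The undirected reporter score is a function of P values only. A *negative*
score means the pathway's members are less significant than a random set of
the same size — "no evidence of enrichment" — never "downregulated". The
widespread reading of the score's sign as a regulation direction is a
statistical error this implementation refuses to encode: the ``significant``
flag applies to the score itself, not to its absolute value.

For direction-aware analysis use ``mode="directed"``: each KO's two-sided P
value is split into one-tailed up/down P values using the sign of its test
statistic, and the up and down aggregates are scored (and background-
corrected) separately, so directionality and significance are determined
simultaneously.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffstats import KOStat
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: P values are clipped into [EPS, 1 - EPS] before the inverse-normal
#: transform so p = 0 or 1 yields a large finite Z rather than +-inf.
P_CLIP_EPS = 1e-15

#: Above this many subsets the background switches from exhaustive
#: enumeration to Monte Carlo sampling.
EXHAUSTIVE_CAP = 100_000

DEFAULT_CUTOFF = 1.64
DEFAULT_MIN_K = 3
DEFAULT_N_BACKGROUND = 1000

MODES = ("undirected", "directed")


@dataclass
class PathwaySet:
    """Named collection of pathways, each a set of KO identifiers.

    ``pathways`` maps pathway_id -> set of member KO ids; ``names`` maps
    pathway_id -> human-readable description (may equal the id).
    """

    pathways: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pathways = {pid: frozenset(m) for pid, m in self.pathways.items()}
        for pid, members in self.pathways.items():
            if not members:
                raise ValidationError(f"pathway {pid!r} has no members")
        for pid in self.pathways:
            self.names.setdefault(pid, pid)

    def __len__(self) -> int:
        return len(self.pathways)

    def restrict(self, universe: set[str], min_k: int = DEFAULT_MIN_K) -> "PathwaySet":
        """Intersect members with ``universe``; drop pathways with k < min_k."""
        kept: dict[str, frozenset[str]] = {}
        for pid in sorted(self.pathways):
            inter = self.pathways[pid] & universe
            if len(inter) >= min_k:
                kept[pid] = inter
            else:
                logger.info(
                    "dropping pathway %s: %d members in universe < min_k=%d",
                    pid, len(inter), min_k,
                )
        return PathwaySet(kept, {pid: self.names[pid] for pid in kept})


@dataclass(frozen=True)
class BackgroundEntry:
    """Background moments for one set size k."""

    k: int
    mu_k: float
    sigma_k: float
    n_samples: int
    method: str  # "monte_carlo" | "exhaustive"


@dataclass
class BackgroundModel:
    """Per-k background moments plus the seed that produced them."""

    entries: dict[int, BackgroundEntry]
    seed: int | None = None

    def __getitem__(self, k: int) -> BackgroundEntry:
        return self.entries[k]


@dataclass(frozen=True)
class ReporterRow:
    """One pathway's reporter-score result.

    ``z_corrected`` (the reporter score) and ``p_equiv`` are NaN when the
    background was degenerate (sigma_k = 0).
    """

    pathway_id: str
    mode: str  # "undirected" | "up" | "down"
    k: int
    z_pathway: float
    mu_k: float
    sigma_k: float
    z_corrected: float
    p_equiv: float
    q_value: float
    significant: bool


def p_to_z(p):
    """Inverse-normal transform Z = Phi^-1(1 - p), elementwise.

    P values are clipped into [1e-15, 1 - 1e-15] first. Strictly decreasing
    in p; positive iff p < 0.5. Scalar in, scalar out.
    """
    arr = np.asarray(p, dtype=float)
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValidationError(f"p values must lie in [0, 1], got {p!r}")
    z = stats.norm.isf(np.clip(arr, P_CLIP_EPS, 1.0 - P_CLIP_EPS))
    return float(z) if np.isscalar(p) or arr.ndim == 0 else z


def aggregate_z(z_values) -> float:
    """Size-independent aggregate (1/sqrt(k)) * sum(z) over k member Z scores."""
    arr = np.asarray(z_values, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot aggregate an empty list of Z scores")
    if not np.isfinite(arr).all():
        raise ValidationError("Z scores must be finite")
    return float(arr.sum() / math.sqrt(arr.size))


def corrected_score(z_pathway: float, mu_k: float, sigma_k: float) -> float:
    """Background-corrected reporter score (z_pathway - mu_k) / sigma_k."""
    if sigma_k <= 0:
        raise ValidationError(
            f"degenerate background: sigma_k = {sigma_k} (must be > 0)"
        )
    return (z_pathway - mu_k) / sigma_k


def score_to_p(z_corrected: float) -> float:
    """Upper-tail equivalent P value, 1 - Phi(z); e.g. 1.6449 -> 0.05."""
    return float(stats.norm.sf(z_corrected))


def split_directional(p: float, sign: int) -> tuple[float, float]:
    """Split a two-sided P value into one-tailed (p_up, p_down).

    sign > 0: p_up = p/2, p_down = 1 - p/2; sign < 0 the mirror image;
    sign = 0 (no direction information): (0.5, 0.5). Always p_up + p_down = 1.
    """
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"p value outside [0, 1]: {p}")
    if sign > 0:
        p_up = p / 2.0
    elif sign < 0:
        p_up = 1.0 - p / 2.0
    else:
        p_up = 0.5
    return p_up, 1.0 - p_up


def _aggregate_subsets_exhaustive(all_z: np.ndarray, k: int) -> np.ndarray:
    sums = np.fromiter(
        (s for s in map(sum, itertools.combinations(all_z, k))),
        dtype=float,
        count=math.comb(len(all_z), k),
    )
    return sums / math.sqrt(k)


def _aggregate_subsets_mc(
    all_z: np.ndarray, k: int, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    # Random size-k subsets without replacement: take the first k positions
    # of a random permutation (argsort of iid uniforms), vectorized over draws.
    n = len(all_z)
    idx = np.argsort(rng.random((n_samples, n)), axis=1)[:, :k]
    return all_z[idx].sum(axis=1) / math.sqrt(k)


def background_stats(
    all_z,
    k: int,
    n_samples: int = DEFAULT_N_BACKGROUND,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    exhaustive_cap: int = EXHAUSTIVE_CAP,
) -> BackgroundEntry:
    """Mean and population SD of the aggregate Z over random size-k sets.

    Enumerates all C(n, k) subsets when that count is at most
    ``exhaustive_cap``; otherwise draws ``n_samples`` subsets uniformly
    (without replacement within each subset) from the seeded generator.
    A zero sigma_k (all Z equal) is returned as-is and flagged downstream.
    """
    arr = np.asarray(all_z, dtype=float)
    if k < 1 or k > arr.size:
        raise ValidationError(f"k={k} outside [1, {arr.size}]")
    n_subsets = math.comb(arr.size, k)
    if n_subsets <= exhaustive_cap:
        aggs = _aggregate_subsets_exhaustive(arr, k)
        method, n_used = "exhaustive", n_subsets
    else:
        if n_samples < 2:
            raise ValidationError("n_samples must be >= 2 for Monte Carlo")
        if rng is None:
            rng = np.random.default_rng(seed)
        aggs = _aggregate_subsets_mc(arr, k, n_samples, rng)
        method, n_used = "monte_carlo", n_samples
    mu = float(aggs.mean())
    sigma = float(aggs.std(ddof=0))  # population SD, fixed for reproducibility
    if sigma <= 1e-12 * max(1.0, abs(mu)):
        sigma = 0.0  # snap float residue on constant universes to true zero
    if sigma == 0.0:
        logger.warning("degenerate background for k=%d: sigma_k = 0", k)
    return BackgroundEntry(k=k, mu_k=mu, sigma_k=sigma, n_samples=n_used, method=method)


def build_background(
    all_z,
    ks,
    n_samples: int = DEFAULT_N_BACKGROUND,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    exhaustive_cap: int = EXHAUSTIVE_CAP,
) -> BackgroundModel:
    """Background moments for every distinct k, drawn in sorted-k order.

    Sorted-k order from a single RNG stream makes the result independent of
    pathway input order.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    entries = {
        k: background_stats(
            all_z, k, n_samples=n_samples, rng=rng, exhaustive_cap=exhaustive_cap
        )
        for k in sorted(set(ks))
    }
    return BackgroundModel(entries=entries, seed=seed)


def _bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjustment; NaNs pass through as NaN."""
    q = np.full_like(pvals, np.nan, dtype=float)
    mask = ~np.isnan(pvals)
    if mask.any():
        q[mask] = stats.false_discovery_control(pvals[mask], method="bh")
    return q


def _score_mode(
    mode: str,
    z_universe: np.ndarray,
    ko_index: dict[str, int],
    sets: PathwaySet,
    background: BackgroundModel,
    cutoff: float,
) -> list[dict]:
    rows = []
    for pid in sorted(sets.pathways):
        members = sets.pathways[pid]
        idx = [ko_index[m] for m in members]
        zp = aggregate_z(z_universe[idx])
        bg = background[len(idx)]
        if bg.sigma_k > 0:
            zc = corrected_score(zp, bg.mu_k, bg.sigma_k)
            p_eq = score_to_p(zc)
            sig = zc > cutoff
        elif zp == bg.mu_k:
            # Degenerate background with the pathway exactly at the mean
            # (e.g. every KO at p = 0.5): no deviation, score 0.
            logger.warning(
                "pathway %s (%s): degenerate background sigma_k=0 with "
                "z_pathway == mu_k; reporter score set to 0", pid, mode,
            )
            zc, p_eq, sig = 0.0, 0.5, False
        else:
            logger.warning(
                "pathway %s (%s): degenerate background sigma_k=0; "
                "reporter score reported as missing", pid, mode,
            )
            zc, p_eq, sig = np.nan, np.nan, False
        rows.append(
            dict(
                pathway_id=pid, mode=mode, k=len(idx), z_pathway=zp,
                mu_k=bg.mu_k, sigma_k=bg.sigma_k, z_corrected=zc,
                p_equiv=p_eq, significant=sig,
            )
        )
    return rows


def run_reporter(
    ko_stats: list[KOStat],
    sets: PathwaySet,
    n_background: int = DEFAULT_N_BACKGROUND,
    seed: int | None = None,
    min_k: int = DEFAULT_MIN_K,
    cutoff: float = DEFAULT_CUTOFF,
    mode: str = "undirected",
    exhaustive_cap: int = EXHAUSTIVE_CAP,
) -> list[ReporterRow]:
    """Score every pathway against the KO universe defined by ``ko_stats``.

    Undirected mode (default): one row per retained pathway, computed from
    two-sided P values only — the result is invariant under any change of
    the KO statistics' signs. Directed mode: two rows per pathway ("up" and
    "down"), from the one-tailed split P values, each independently
    background-corrected.

    Rows carry a BH-adjusted q value across rows of the same mode, and are
    sorted by reporter score descending (NaN last), ties broken by
    pathway_id.
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")
    if not ko_stats:
        raise ValidationError("empty KO universe")
    if len(sets) == 0:
        raise ValidationError("empty pathway set")
    ko_ids = [s.ko_id for s in ko_stats]
    if len(set(ko_ids)) != len(ko_ids):
        raise ValidationError("duplicate KO ids in stats")
    ko_index = {ko: i for i, ko in enumerate(ko_ids)}
    pvals = np.array([s.p_value for s in ko_stats], dtype=float)

    retained = sets.restrict(set(ko_ids), min_k=min_k)
    if len(retained) == 0:
        logger.warning("no pathways retained after universe intersection")
        return []
    ks = [len(m) for m in retained.pathways.values()]

    rng = np.random.default_rng(seed)
    raw_rows: list[dict] = []
    if mode == "undirected":
        z = p_to_z(pvals)
        bg = build_background(
            z, ks, n_samples=n_background, rng=rng, exhaustive_cap=exhaustive_cap
        )
        raw_rows += _score_mode("undirected", z, ko_index, retained, bg, cutoff)
    else:
        signs = np.sign([s.statistic for s in ko_stats])
        split = [split_directional(p, int(sg)) for p, sg in zip(pvals, signs)]
        for sub_mode, p_dir in (
            ("up", np.array([u for u, _ in split])),
            ("down", np.array([d for _, d in split])),
        ):
            z = p_to_z(p_dir)
            bg = build_background(
                z, ks, n_samples=n_background, rng=rng, exhaustive_cap=exhaustive_cap
            )
            raw_rows += _score_mode(sub_mode, z, ko_index, retained, bg, cutoff)

    # BH within each mode
    df_modes: dict[str, np.ndarray] = {}
    for m in {r["mode"] for r in raw_rows}:
        p_eq = np.array([r["p_equiv"] for r in raw_rows if r["mode"] == m])
        df_modes[m] = _bh_qvalues(p_eq)
    counters = {m: 0 for m in df_modes}
    for r in raw_rows:
        m = r["mode"]
        r["q_value"] = float(df_modes[m][counters[m]])
        counters[m] += 1

    raw_rows.sort(
        key=lambda r: (
            np.isnan(r["z_corrected"]),
            -(r["z_corrected"] if not np.isnan(r["z_corrected"]) else 0.0),
            r["pathway_id"],
        )
    )
    return [ReporterRow(**r) for r in raw_rows]


def rows_to_frame(rows: list[ReporterRow]) -> pd.DataFrame:
    """Tabular view with the canonical output column names."""
    return pd.DataFrame(
        {
            "pathway": [r.pathway_id for r in rows],
            "mode": [r.mode for r in rows],
            "k": [r.k for r in rows],
            "z_pathway": [r.z_pathway for r in rows],
            "mu_k": [r.mu_k for r in rows],
            "sigma_k": [r.sigma_k for r in rows],
            "reporter_score": [r.z_corrected for r in rows],
            "p_equiv": [r.p_equiv for r in rows],
            "q_value": [r.q_value for r in rows],
            "significant": [r.significant for r in rows],
        }
    )
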