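"""Seeded synthetic-data generators.

Two simulators:

``simulate_replica``
    A replica of the classic demonstration that the reporter score's sign
    is not a regulation direction: 200 KOs with P values drawn uniformly
    (exactly 50 below 0.05 by stratified draws), 10 pathways of random size
    with within-pathway consistent direction of regulation, and one
    designated pathway assembled from the *least* significant KOs with all
    members "upregulated". That pathway attains the minimum reporter score
    purely because its members carry no differential signal — a naive
    sign reading would call it "significantly downregulated".

``simulate_abundance``
    A log-normal abundance simulator for end-to-end exercises of the
    differential-test -> reporter pipeline, with a chosen set of effect KOs
    shifted in the treatment group.

Both are deterministic under their seed, and ``simulate_replica`` writes a
truth table so downstream checks never re-derive ground truth from the
generated data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffstats import AbundanceTable, GroupAssignment, KOStat
from .errors import ValidationError
from .reporter import P_CLIP_EPS, PathwaySet

#: Index (0-based) of the designated least-significant pathway, when there
#: are at least that many pathways; mirrors the conventional "pathway 4".
LEAST_SIG_INDEX = 3


@dataclass
class SimConfig:
    """Parameters of the replica simulation.

    Defaults reproduce the study conditions: 200 KOs, exactly 50 of them
    significant at 0.05, 10 pathways with sizes uniform on [8, 30].
    """

    n_kos: int = 200
    n_sig: int = 50
    sig_alpha: float = 0.05
    n_pathways: int = 10
    k_range: tuple[int, int] = (8, 30)
    least_sig_pathway: bool = True
    direction_consistent: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_sig > self.n_kos:
            raise ValidationError("n_sig cannot exceed n_kos")
        lo, hi = self.k_range
        if not (1 <= lo <= hi <= self.n_kos):
            raise ValidationError(
                f"infeasible k_range {self.k_range} for n_kos={self.n_kos}"
            )
        if not (0.0 < self.sig_alpha < 1.0):
            raise ValidationError("sig_alpha must lie in (0, 1)")


def _ko_ids(n: int) -> list[str]:
    return [f"K{i + 1:05d}" for i in range(n)]


def simulate_replica(
    config: SimConfig | None = None,
) -> tuple[list[KOStat], PathwaySet, pd.DataFrame]:
    """Generate the replica dataset: (KO stats, pathways, truth table).

    P values: exactly ``n_sig`` KOs uniform on (0, sig_alpha), the rest
    uniform on (sig_alpha, 1), so the significant count is an exact
    generator contract, not a random outcome. Each pathway samples
    k ~ U{k_range} members without replacement (pathways may overlap).
    With ``direction_consistent`` every member of a pathway shares one
    random sign; with ``least_sig_pathway`` the designated pathway is the
    k KOs with the largest P values and all its members carry sign +1.

    The truth table has one row per pathway: id, k, sign, whether it is the
    designated least-significant pathway, and its members.
    """
    cfg = config if config is not None else SimConfig()
    rng = np.random.default_rng(cfg.seed)
    ids = _ko_ids(cfg.n_kos)

    pvals = np.empty(cfg.n_kos)
    sig_idx = rng.choice(cfg.n_kos, size=cfg.n_sig, replace=False)
    is_sig = np.zeros(cfg.n_kos, dtype=bool)
    is_sig[sig_idx] = True
    pvals[is_sig] = rng.uniform(0.0, cfg.sig_alpha, size=cfg.n_sig)
    pvals[~is_sig] = rng.uniform(cfg.sig_alpha, 1.0, size=cfg.n_kos - cfg.n_sig)
    signs = rng.choice([-1, 1], size=cfg.n_kos).astype(float)

    width = max(2, len(str(cfg.n_pathways)))
    pids = [f"pathway_{i + 1:0{width}d}" for i in range(cfg.n_pathways)]
    sizes = rng.integers(cfg.k_range[0], cfg.k_range[1] + 1, size=cfg.n_pathways)
    least_idx = (
        min(LEAST_SIG_INDEX, cfg.n_pathways - 1) if cfg.least_sig_pathway else -1
    )

    members: dict[str, np.ndarray] = {}
    pathway_sign: dict[str, int] = {}
    order = [i for i in range(cfg.n_pathways) if i != least_idx]
    if least_idx >= 0:
        order.append(least_idx)  # applied last so its +1 signs win conflicts
    for i in order:
        k = int(sizes[i])
        if i == least_idx:
            idx = np.argsort(pvals)[-k:]
            sign = 1
        else:
            idx = rng.choice(cfg.n_kos, size=k, replace=False)
            sign = int(rng.choice([-1, 1]))
        members[pids[i]] = np.sort(idx)
        pathway_sign[pids[i]] = sign
        if cfg.direction_consistent or i == least_idx:
            signs[idx] = sign

    magnitudes = stats.norm.isf(np.clip(pvals, P_CLIP_EPS, 1.0) / 2.0)
    ko_stats = [
        KOStat(ids[i], float(pvals[i]), float(signs[i] * magnitudes[i]), "simulated")
        for i in range(cfg.n_kos)
    ]
    sets = PathwaySet(
        {pid: frozenset(ids[j] for j in idx) for pid, idx in members.items()}
    )
    truth = pd.DataFrame(
        {
            "pathway": pids,
            "k": [len(members[p]) for p in pids],
            "sign": [pathway_sign[p] for p in pids],
            "least_significant": [pids.index(p) == least_idx for p in pids],
            "members": [";".join(ids[j] for j in members[p]) for p in pids],
        }
    )
    return ko_stats, sets, truth


def simulate_abundance(
    n_kos: int = 200,
    n_per_group: int = 10,
    effect_kos: list[str] | tuple[str, ...] = (),
    effect_size: float = 0.0,
    seed: int | None = None,
    log_sd: float = 0.5,
) -> tuple[AbundanceTable, GroupAssignment]:
    """Log-normal two-group abundance table with planted effects.

    Each feature's log abundance is N(mu_i, log_sd) with per-feature
    baseline mu_i ~ N(2, 1); in the treatment group the ``effect_kos`` have
    their log mean shifted by ``effect_size`` * log_sd (i.e. effect_size
    within-feature standard deviations). Reference group label is
    "control", treatment is "treatment".
    """
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    ids = _ko_ids(n_kos)
    unknown = set(effect_kos) - set(ids)
    if unknown:
        raise ValidationError(f"effect KOs not in feature ids: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    mu = rng.normal(2.0, 1.0, size=n_kos)
    log_abund = rng.normal(
        mu[:, None], log_sd, size=(n_kos, 2 * n_per_group)
    )
    effect_mask = np.isin(ids, list(effect_kos))
    log_abund[effect_mask, n_per_group:] += effect_size * log_sd
    samples = [f"ctrl_{j + 1:02d}" for j in range(n_per_group)] + [
        f"trt_{j + 1:02d}" for j in range(n_per_group)
    ]
    table = AbundanceTable(ids, samples, np.exp(log_abund))
    groups = GroupAssignment(
        {s: ("control" if s.startswith("ctrl") else "treatment") for s in samples},
        reference="control",
    )
    return table, groups
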