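"""Weighted running-sum enrichment with permutation NES/FDR.

The same engine serves two purposes: kinase-activity inference — predicted
substrate-site sets scored against sites ranked by log2 ratio, with the
normalized enrichment score (NES) read as an activity score and its sign
as direction — and conventional GSEA/ORA over user-supplied GMT
collections.

Because the pooled two-group design yields a single ratio per site (no
replicate columns), the permutation null is *set-membership* permutation:
random same-size item sets drawn from the ranked universe. Nominal p is
the one-sided tail frequency among same-sign null scores with a
(b+1)/(n+1) continuity correction; NES divides the observed ES by the mean
magnitude of same-sign null ES; FDR q follows the standard pooled-null NES
ratio, positive and negative sides separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from phosphokin.io_formats import SiteTable

logger = logging.getLogger(__name__)

MIN_SET_SIZE = 3
MAX_SET_SIZE = 500

POSITIVE = "positive"
NEGATIVE = "negative"
NOT_SIGNIFICANT = "not_significant"


@dataclass
class RankedList:
    """Items ordered by descending rank value with deterministic tie-break.

    Ties in ``values`` are broken by ascending item id, so the order is a
    pure function of the input.
    """

    items: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.items) != len(self.values):
            raise ValueError("items and values must have equal length")
        if len(set(self.items)) != len(self.items):
            raise ValueError("duplicate item ids in ranked list")
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.items)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, float]]) -> "RankedList":
        pairs = list(pairs)
        pairs.sort(key=lambda t: (-t[1], t[0]))
        return cls(
            items=tuple(p[0] for p in pairs),
            values=np.array([p[1] for p in pairs], dtype=float),
        )

    def index_of(self, members: Iterable[str]) -> np.ndarray:
        lookup = {item: i for i, item in enumerate(self.items)}
        return np.array(sorted(lookup[m] for m in members if m in lookup), dtype=np.intp)


def rank_sites(table: SiteTable, level: str = "site") -> RankedList:
    """Rank file from a site table.

    ``site`` level keys items as ``protein_position`` valued by the site's
    log2 ratio; ``protein`` level averages log2 ratios across each
    protein's sites.
    """
    frame = table.frame
    if level == "site":
        pairs = [
            (f"{p}_{pos}", lr)
            for p, pos, lr in zip(frame["protein_id"], frame["position"], frame["log2_ratio"])
        ]
    elif level == "protein":
        agg = frame.groupby("protein_id")["log2_ratio"].mean()
        pairs = list(agg.items())
    else:
        raise ValueError(f"level must be 'site' or 'protein': {level!r}")
    return RankedList.from_pairs(pairs)


def _es_batch(values: np.ndarray, hit_mask: np.ndarray, weight_p: float) -> tuple[np.ndarray, np.ndarray]:
    """Signed max-deviation ES for each row of hit masks.

    Returns (es, running) with running of shape (m, N). Hits increment by
    |value|^p normalized over hits; misses decrement by 1/(N - n_hits).
    Rows whose hit weights all vanish fall back to unweighted increments.
    """
    n = values.shape[0]
    w = np.abs(values) ** weight_p
    wh = hit_mask * w
    nr = wh.sum(axis=1)
    nh = hit_mask.sum(axis=1)
    if np.any(nh == 0) or np.any(nh == n):
        raise ValueError("each set must hit at least one and not all ranked items")
    degenerate = nr == 0
    if degenerate.any():
        wh = np.where(degenerate[:, None], hit_mask.astype(float), wh)
        nr = np.where(degenerate, nh.astype(float), nr)
    step = wh / nr[:, None] - (~hit_mask) / (n - nh)[:, None]
    running = np.cumsum(step, axis=1)
    # signed maximum deviation; an exact tie between the positive peak and
    # the negative trough resolves to the positive side
    peak = running.max(axis=1)
    trough = running.min(axis=1)
    es = np.where(peak + trough >= -1e-9, peak, trough)
    return es, running


def enrichment_score(
    ranked: RankedList,
    member_set: Iterable[str],
    weight_p: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted Kolmogorov-Smirnov running sum for one member set.

    Returns the signed maximum deviation (ES, in [-1, 1]) and the full
    running sum over the ranked list.
    """
    idx = ranked.index_of(member_set)
    if len(idx) == 0:
        raise ValueError("member set has no overlap with the ranked list")
    if len(idx) == len(ranked):
        raise ValueError("member set equals the ranked universe; ES undefined")
    mask = np.zeros((1, len(ranked)), dtype=bool)
    mask[0, idx] = True
    es, running = _es_batch(ranked.values, mask, weight_p)
    return float(es[0]), running[0]


@dataclass
class EnrichmentResult:
    """ES/NES/p/FDR and leading edge for one set against one ranked list."""

    set_name: str
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    leading_edge: list[str]
    n_hits: int


def _leading_edge(ranked: RankedList, hit_idx: np.ndarray, running: np.ndarray, es: float) -> list[str]:
    if es >= 0:
        peak = int(np.argmax(running))
        keep = hit_idx[hit_idx <= peak]
    else:
        trough = int(np.argmin(running))
        keep = hit_idx[hit_idx >= trough]
    return [ranked.items[i] for i in keep]


def permutation_test(
    ranked: RankedList,
    sets: Mapping[str, Iterable[str]],
    n_perm: int = 1000,
    weight_p: float = 1.0,
    seed: int | None = None,
    min_set_size: int = MIN_SET_SIZE,
    max_set_size: int = MAX_SET_SIZE,
) -> list[EnrichmentResult]:
    """Set-membership permutation test for each set against the ranked list.

    The null for a set of k overlapping items is ``n_perm`` random draws of
    k items from the universe. Deterministic given ``seed`` and the
    iteration order of ``sets``. Sets overlapping fewer than
    ``min_set_size`` or more than ``max_set_size`` items are skipped with a
    warning.
    """
    if seed is None:
        raise ValueError("seed is required for a reproducible permutation test")
    if n_perm < 100:
        logger.warning("n_perm=%d is low; p-values and FDR will be coarse", n_perm)
    rng = np.random.default_rng(seed)
    n = len(ranked)
    values = ranked.values

    kept: list[tuple[str, np.ndarray]] = []
    for name, members in sets.items():
        idx = ranked.index_of(members)
        if not min_set_size <= len(idx) <= max_set_size:
            logger.warning(
                "set %r overlaps %d ranked items (outside [%d, %d]); skipped",
                name,
                len(idx),
                min_set_size,
                max_set_size,
            )
            continue
        if len(idx) == n:
            raise ValueError(f"set {name!r} equals the ranked universe")
        kept.append((name, idx))

    results: list[EnrichmentResult] = []
    pooled_null_nes: list[np.ndarray] = []
    per_set: list[dict] = []

    for name, idx in kept:
        mask = np.zeros((1, n), dtype=bool)
        mask[0, idx] = True
        es_obs, running = _es_batch(values, mask, weight_p)
        es_obs = float(es_obs[0])

        k = len(idx)
        # random same-size sets: top-k of a random permutation per row
        null_idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
        null_mask = np.zeros((n_perm, n), dtype=bool)
        np.put_along_axis(null_mask, null_idx, True, axis=1)
        null_es, _ = _es_batch(values, null_mask, weight_p)

        pos = null_es >= 0
        neg = ~pos
        mean_pos = float(null_es[pos].mean()) if pos.any() else np.nan
        mean_neg = float(np.abs(null_es[neg]).mean()) if neg.any() else np.nan

        if es_obs >= 0:
            n_same = int(pos.sum())
            b = int((null_es[pos] >= es_obs).sum())
            norm = mean_pos
        else:
            n_same = int(neg.sum())
            b = int((null_es[neg] <= es_obs).sum())
            norm = mean_neg
        p_nom = (b + 1) / (n_same + 1)
        nes = es_obs / norm if norm and np.isfinite(norm) and norm > 0 else 0.0

        null_nes = np.where(
            null_es >= 0,
            null_es / mean_pos if np.isfinite(mean_pos) and mean_pos > 0 else 0.0,
            null_es / mean_neg if np.isfinite(mean_neg) and mean_neg > 0 else 0.0,
        )
        pooled_null_nes.append(null_nes)

        per_set.append(
            {
                "name": name,
                "idx": idx,
                "es": es_obs,
                "nes": float(nes),
                "p": float(p_nom),
                "running": running[0],
            }
        )

    if not per_set:
        return []

    pooled = np.concatenate(pooled_null_nes)
    obs_nes = np.array([d["nes"] for d in per_set])
    fdr = _pooled_null_fdr(obs_nes, pooled)

    for d, q in zip(per_set, fdr):
        hit_idx = d["idx"]
        results.append(
            EnrichmentResult(
                set_name=d["name"],
                es=d["es"],
                nes=d["nes"],
                p_nominal=d["p"],
                fdr_q=float(q),
                leading_edge=_leading_edge(ranked, hit_idx, d["running"], d["es"]),
                n_hits=len(hit_idx),
            )
        )
    return results


def _pooled_null_fdr(obs_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """GSEA-style FDR from the pooled null NES, each sign side separately.

    q(NES*) = [tail fraction of null NES beyond NES* on its side] /
    [tail fraction of observed NES beyond NES* on its side], clipped to 1,
    then monotonized so a more extreme NES never has a larger q.
    """
    q = np.ones_like(obs_nes)
    for sign in (1, -1):
        obs_side = obs_nes >= 0 if sign > 0 else obs_nes < 0
        null_side = null_nes >= 0 if sign > 0 else null_nes < 0
        n_obs_side = int(obs_side.sum())
        n_null_side = int(null_side.sum())
        if n_obs_side == 0:
            continue
        for i in np.flatnonzero(obs_side):
            nes = obs_nes[i]
            if n_null_side == 0:
                q[i] = 0.0
                continue
            if sign > 0:
                null_tail = (null_nes[null_side] >= nes).mean()
                obs_tail = (obs_nes[obs_side] >= nes).mean()
            else:
                null_tail = (null_nes[null_side] <= nes).mean()
                obs_tail = (obs_nes[obs_side] <= nes).mean()
            q[i] = min(1.0, null_tail / obs_tail) if obs_tail > 0 else 1.0
        # monotone: more extreme NES -> no larger q
        order = np.argsort(-sign * obs_nes[obs_side])
        side_idx = np.flatnonzero(obs_side)[order]
        q[side_idx] = np.minimum.accumulate(q[side_idx])
    return q


@dataclass
class KinaseActivity:
    """NES read as a kinase activity score with a direction label."""

    kinase_name: str
    nes: float
    direction: str
    n_substrates_in_rank: int
    p_nominal: float = float("nan")


def classify_kinases(
    results: Sequence[EnrichmentResult],
    p_cutoff: float = 0.05,
) -> list[KinaseActivity]:
    """Label each kinase positive/negative/not-significant.

    Positive activity means the predominant change of the kinase's
    substrates is an increase in phosphorylation (NES > 0 at nominal
    p < ``p_cutoff``); negative is the mirror image.
    """
    activities = []
    for r in results:
        if r.p_nominal < p_cutoff and r.nes > 0:
            direction = POSITIVE
        elif r.p_nominal < p_cutoff and r.nes < 0:
            direction = NEGATIVE
        else:
            direction = NOT_SIGNIFICANT
        activities.append(
            KinaseActivity(
                kinase_name=r.set_name,
                nes=r.nes,
                direction=direction,
                n_substrates_in_rank=r.n_hits,
                p_nominal=r.p_nominal,
            )
        )
    return activities


def ora(
    hit_items: Iterable[str],
    universe: Iterable[str],
    sets: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation analysis.

    For each set: overlap with the hit list, fold enrichment, exact upper
    tail P(X >= overlap) and Benjamini-Hochberg q across sets. Hits must
    be a subset of the universe.
    """
    hits = set(hit_items)
    uni = set(universe)
    stray = hits - uni
    if stray:
        raise ValueError(f"hit item(s) not in universe: {sorted(stray)[:5]}")
    m = len(uni)
    n_hits = len(hits)
    rows = []
    for name, members in sets.items():
        in_uni = set(members) & uni
        k = len(in_uni & hits)
        big_k = len(in_uni)
        p = float(stats.hypergeom.sf(k - 1, m, big_k, n_hits))
        expected = n_hits * big_k / m if m else 0.0
        fold = k / expected if expected > 0 else float("nan")
        rows.append({"set_name": name, "set_size": big_k, "overlap": k, "fold": fold, "p": p})
    frame = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "fold", "p"])
    if len(frame):
        _, qvals, _, _ = multipletests(frame["p"], method="fdr_bh")
        frame["q"] = qvals
    else:
        frame["q"] = []
    return frame


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "es": r.es,
                "nes": r.nes,
                "p_nominal": r.p_nominal,
                "fdr_q": r.fdr_q,
                "n_hits": r.n_hits,
                "leading_edge": ";".join(r.leading_edge),
            }
            for r in results
        ],
        columns=["set_name", "es", "nes", "p_nominal", "fdr_q", "n_hits", "leading_edge"],
    )


def activities_to_frame(activities: Sequence[KinaseActivity]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "kinase": a.kinase_name,
                "nes": a.nes,
                "p_nominal": a.p_nominal,
                "direction": a.direction,
                "n_substrates_in_rank": a.n_substrates_in_rank,
            }
            for a in activities
        ],
        columns=["kinase", "nes", "p_nominal", "direction", "n_substrates_in_rank"],
    )
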