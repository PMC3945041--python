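"""Hypergeometric over-representation of gene sets with FDR and pruning.

Candidate genes (e.g. the synthetic-lethal calls) are tested against
each pathway by the hypergeometric upper tail: with N universe genes of
which K lie in the pathway, and n candidates, the p-value is
P[X >= k] for the observed overlap k.  p-values are FDR-adjusted by the
Benjamini-Hochberg step-up, and redundant pathways are removed by a
greedy walk down the FDR-sorted list that drops any set whose candidate
members are more than 50% covered by sets already kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from slscreen.io import GeneSetCollection, ScreenConfigError

logger = logging.getLogger(__name__)


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P[X >= k], X ~ Hypergeometric(N, K, n).

    k observed marked draws, K marked items in the universe, n draws,
    N universe size.  Evaluated via the survival function (log-space
    internally), exact to double precision; k = 0 returns 1.0 exactly.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ScreenConfigError(f"invalid bounds: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ScreenConfigError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 5e-324), 1.0)


def bh_fdr(p_values: Sequence[float], method: str = "bh") -> np.ndarray:
    """FDR-adjusted q-values, order-preserving with the input.

    ``method="bh"`` is the Benjamini-Hochberg step-up (independent or
    positively dependent tests); ``"by"`` the more conservative
    Benjamini-Yekutieli variant.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ScreenConfigError("p-values must be in [0, 1]")
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}.get(method)
    if sm_method is None:
        raise ScreenConfigError(f"unknown FDR method {method!r}")
    return multipletests(p, method=sm_method)[1]


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's enrichment outcome."""

    set_name: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    q_value: float
    candidate_members: frozenset[str]
    members_in_universe: frozenset[str]
    kept: bool = True


def _is_sorted(results: Sequence[EnrichmentResult]) -> bool:
    keys = [(r.q_value, r.p_value, r.set_name) for r in results]
    return all(a <= b for a, b in zip(keys, keys[1:]))


def prune_overlapping(
    results: Sequence[EnrichmentResult],
    overlap_threshold: float = 0.5,
    metric: str = "candidate",
) -> list[EnrichmentResult]:
    """Greedy redundancy pruning down the FDR-sorted list.

    Input must be sorted ascending by (q, p, name) — enforced.  Walking
    the list, a set is removed when its overlap with the sets already
    kept exceeds ``overlap_threshold`` (strictly "more than", so exactly
    50% is kept at the default).  Overlap metrics:

    - ``"candidate"`` (default): fraction of the set's candidate members
      already present in kept sets' candidate members.
    - ``"full"``: same coverage fraction but on full (universe-restricted)
      memberships.
    - ``"jaccard"``: maximum Jaccard index of candidate members against
      any single kept set.
    """
    if metric not in ("candidate", "full", "jaccard"):
        raise ScreenConfigError(f"unknown overlap metric {metric!r}")
    if not _is_sorted(results):
        raise ScreenConfigError(
            "prune_overlapping requires input sorted by (q, p, name)"
        )
    kept_union: set[str] = set()
    kept_sets: list[frozenset[str]] = []
    out = []
    for r in results:
        members = (
            r.members_in_universe if metric == "full" else r.candidate_members
        )
        if metric == "jaccard":
            overlap = max(
                (
                    len(members & ks) / len(members | ks)
                    for ks in kept_sets
                    if members | ks
                ),
                default=0.0,
            )
        else:
            overlap = (
                len(members & kept_union) / len(members) if members else 0.0
            )
        keep = overlap <= overlap_threshold
        if keep:
            kept_union |= members
            kept_sets.append(frozenset(members))
        out.append(replace(r, kept=keep))
    return out


def enrich(
    candidates: set[str],
    collection: GeneSetCollection,
    universe: set[str],
    fdr_method: str = "bh",
    overlap_threshold: float = 0.5,
    overlap_metric: str = "candidate",
) -> list[EnrichmentResult]:
    """Test every gene set for candidate over-representation.

    The universe is the set of genes the screen could have called (the
    library's targets), not the pathway-annotation union; memberships
    are restricted to it.  Sets with no member in the universe are
    skipped with a warning.  Returns results sorted ascending by
    (q, p, name) with pruning flags set.
    """
    if not universe:
        raise ScreenConfigError("empty universe")
    stray = candidates - universe
    if stray:
        raise ScreenConfigError(
            f"candidates outside the universe: {sorted(stray)[:10]}"
        )
    N = len(universe)
    n = len(candidates)
    partial = []
    for s in collection:
        members_u = frozenset(s.members & universe)
        if not members_u:
            logger.warning("set %s: no members in universe; skipped", s.name)
            continue
        cand = frozenset(members_u & candidates)
        p = hypergeometric_p(len(cand), len(members_u), n, N)
        partial.append((s.name, cand, members_u, p))
    qs = bh_fdr([p for *_x, p in partial], method=fdr_method)
    results = [
        EnrichmentResult(
            set_name=name,
            k=len(cand),
            K=len(members_u),
            n=n,
            N=N,
            p_value=p,
            q_value=float(q),
            candidate_members=cand,
            members_in_universe=members_u,
        )
        for (name, cand, members_u, p), q in zip(partial, qs)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.set_name))
    return prune_overlapping(results, overlap_threshold, overlap_metric)


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Flatten results for serialization (members ';'-joined, sorted)."""
    return pd.DataFrame(
        {
            "set": [r.set_name for r in results],
            "k": [r.k for r in results],
            "K": [r.K for r in results],
            "n": [r.n for r in results],
            "N": [r.N for r in results],
            "p": [r.p_value for r in results],
            "q": [r.q_value for r in results],
            "kept": [int(r.kept) for r in results],
            "candidate_members": [
                ";".join(sorted(r.candidate_members)) for r in results
            ],
        }
    )
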