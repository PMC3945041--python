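"""Noise-calibrated construct calls and gene-level voting.

The screen carries no replicates, so significance comes from the
negative controls: the sample SD of the Luciferase control constructs'
log2 ratios in each module estimates that module's noise, and a
construct is called depleted (enriched) only when its ratio falls
strictly below -SD (strictly above +SD) of its own module.  A gene is
called synthetic lethal when at least half of its constructs vote
depleted — a deterministic vote, not a p-value — and synthetic rescue
symmetrically on enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from slscreen.io import LibraryDesign, ScreenConfigError, ScreenValidationError
from slscreen.enrichment import hypergeometric_p

logger = logging.getLogger(__name__)

DEPLETED = "DEPLETED"
ENRICHED = "ENRICHED"
NEUTRAL = "NEUTRAL"
EXCLUDED = "EXCLUDED"

SYNTHETIC_LETHAL = "SYNTHETIC_LETHAL"
SYNTHETIC_RESCUE = "SYNTHETIC_RESCUE"

CONSTRUCT_CALL_COLUMNS = ("construct_id", "gene", "module", "log2_ratio", "call")


@dataclass(frozen=True)
class Threshold:
    """Symmetric depletion/enrichment threshold for one module."""

    module: int
    sigma: float
    n_controls_used: int

    @property
    def lower(self) -> float:
        return -self.sigma

    @property
    def upper(self) -> float:
        return self.sigma


def estimate_thresholds(ratio_table: pd.DataFrame) -> dict[int, Threshold]:
    """Per-module noise SD from passing negative-control constructs.

    sigma(module) is the sample standard deviation (denominator n-1) of
    the module's control log2 ratios; controls below the read floor do
    not contribute.  Requires >=2 passing controls per module.
    """
    thresholds: dict[int, Threshold] = {}
    for module, grp in ratio_table.groupby("module"):
        ctrl = grp[grp["is_control"] & grp["passes_filter"]]
        ratios = ctrl["log2_ratio"].dropna()
        if len(ratios) < 2:
            raise ScreenValidationError(
                f"module {module}: only {len(ratios)} passing control "
                "constructs; need >=2 to estimate the noise SD"
            )
        sigma = float(ratios.std(ddof=1))
        thresholds[int(module)] = Threshold(int(module), sigma, len(ratios))
        logger.info(
            "module %s: noise SD %.4f from %d controls", module, sigma, len(ratios)
        )
    return thresholds


def call_constructs(
    ratio_table: pd.DataFrame, thresholds: dict[int, Threshold]
) -> pd.DataFrame:
    """Classify every construct against its module's threshold.

    Strict inequalities: a ratio exactly at -sigma or +sigma is NEUTRAL.
    Constructs that failed the read floor are EXCLUDED.
    """
    missing = set(ratio_table["module"].unique()) - set(thresholds)
    if missing:
        raise ScreenConfigError(f"no threshold for module(s) {sorted(missing)}")
    lower = ratio_table["module"].map({m: t.lower for m, t in thresholds.items()})
    upper = ratio_table["module"].map({m: t.upper for m, t in thresholds.items()})
    call = np.select(
        [
            ~ratio_table["passes_filter"],
            ratio_table["log2_ratio"] < lower,
            ratio_table["log2_ratio"] > upper,
        ],
        [EXCLUDED, DEPLETED, ENRICHED],
        default=NEUTRAL,
    )
    out = ratio_table[["construct_id", "gene", "module", "log2_ratio"]].copy()
    out["is_control"] = ratio_table["is_control"].values
    out["call"] = call
    return out


def call_genes(
    construct_calls: pd.DataFrame,
    design: LibraryDesign,
    vote_threshold: float = 0.5,
    strict_majority: bool = False,
    denominator: str = "passing",
) -> pd.DataFrame:
    """Aggregate construct votes into per-gene calls.

    A gene is SYNTHETIC_LETHAL when its depleted-vote fraction reaches
    ``vote_threshold`` (``>=`` by default, ``>`` with
    ``strict_majority``), SYNTHETIC_RESCUE symmetrically on enriched
    votes.  ``denominator`` is the vote base: constructs ``"passing"``
    the read floor (default) or all constructs ``"total"``.  Constructs
    of a gene may span modules; each was judged against its own module's
    threshold and the votes pool here.  If both fractions reach the
    threshold the larger wins; an exact tie is NEUTRAL with a warning.
    """
    if denominator not in ("passing", "total"):
        raise ScreenConfigError(f"unknown denominator mode {denominator!r}")
    if not 0 < vote_threshold <= 1:
        raise ScreenConfigError("vote_threshold must be in (0, 1]")
    cc = construct_calls[~construct_calls["is_control"]]
    if (cc["gene"] == "").any():
        bad = cc.loc[cc["gene"] == "", "construct_id"].tolist()
        raise ScreenValidationError(
            f"non-control construct(s) without a gene: {bad[:10]}"
        )
    known = set(design.genes)
    unknown = set(cc["gene"]) - known
    if unknown:
        raise ScreenValidationError(
            f"constructs reference gene(s) absent from the library design: "
            f"{sorted(unknown)[:10]}"
        )

    rows = []
    for gene, grp in cc.groupby("gene", sort=True):
        n_total = len(grp)
        n_passing = int((grp["call"] != EXCLUDED).sum())
        n_dep = int((grp["call"] == DEPLETED).sum())
        n_enr = int((grp["call"] == ENRICHED).sum())
        base = n_passing if denominator == "passing" else n_total
        if base == 0:
            frac_dep = frac_enr = 0.0
            call = NEUTRAL
            logger.warning("gene %s: no votable constructs; NEUTRAL", gene)
        else:
            frac_dep = n_dep / base
            frac_enr = n_enr / base
            if strict_majority:
                sl = frac_dep > vote_threshold
                rescue = frac_enr > vote_threshold
            else:
                sl = frac_dep >= vote_threshold
                rescue = frac_enr >= vote_threshold
            if sl and rescue:
                if frac_dep > frac_enr:
                    call = SYNTHETIC_LETHAL
                elif frac_enr > frac_dep:
                    call = SYNTHETIC_RESCUE
                else:
                    call = NEUTRAL
                    logger.warning(
                        "gene %s: depleted and enriched fractions tie at %.3f; "
                        "refusing to guess, NEUTRAL",
                        gene,
                        frac_dep,
                    )
            elif sl:
                call = SYNTHETIC_LETHAL
            elif rescue:
                call = SYNTHETIC_RESCUE
            else:
                call = NEUTRAL
        modules = ",".join(str(m) for m in sorted(grp["module"].unique()))
        rows.append(
            (gene, modules, n_total, n_passing, n_dep, n_enr, frac_dep, frac_enr, call)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "modules",
            "n_constructs_total",
            "n_constructs_passing",
            "n_depleted",
            "n_enriched",
            "vote_fraction_depleted",
            "vote_fraction_enriched",
            "call",
        ],
    )


def rescue_enrichment_check(
    gene_calls: pd.DataFrame, gene_family: set[str], universe_size: int
) -> float:
    """Hypergeometric enrichment of a gene family among rescue calls.

    Tests whether synthetic-rescue genes over-represent ``gene_family``
    (e.g. the cAMP phosphodiesterases): draws n = #rescue genes from a
    universe of ``universe_size`` genes containing K = |family| marked
    ones and asks P[X >= k] for the observed overlap k.
    """
    if len(gene_family) > universe_size:
        raise ScreenConfigError("gene family larger than the universe")
    rescue = set(gene_calls.loc[gene_calls["call"] == SYNTHETIC_RESCUE, "gene"])
    k = len(gene_family & rescue)
    return hypergeometric_p(k, len(gene_family), len(rescue), universe_size)
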