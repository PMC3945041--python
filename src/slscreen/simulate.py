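"""Synthetic pooled-screen generator with full ground truth.

The generative model mirrors the statistical structure the analysis
assumes, not the biology that produced it.  Each construct has a
baseline relative abundance ``a_i ~ LogNormal(0, baseline_sigma^2)``
shared between conditions.  In the treatment lane the abundance becomes
``a_i * 2**(e_i + eps_i)`` where ``e_i`` is the planted log2 effect
(negative for synthetic-lethal carriers, mirrored positive for rescue
carriers, 0 otherwise) and ``eps_i ~ Normal(0, noise_sigma^2)`` is the
screen's biological/technical ratio noise.  Each lane's read counts are
a single multinomial draw of ``reads_per_lane`` trials over the
normalized abundances, so lane totals are fixed exactly — the
fixed-depth analogue of independent Poisson sampling.

Planted effects have partial per-construct efficacy: only
``efficacy_constructs`` of an affected gene's constructs carry the
effect, emulating the reality that some hairpins of a true hit fail to
knock their target down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from slscreen.io import (
    CountTable,
    LibraryDesign,
    ScreenConfigError,
    write_count_table,
    write_library_annotation,
)

BARCODE_LENGTH = 18
_BASES = "ACGT"

SL = "SL"
RESCUE = "RESCUE"
NEUTRAL = "NEUTRAL"


@dataclass(frozen=True)
class SimulationConfig:
    """Screen-design and noise parameters for a synthetic screen.

    Defaults mirror the real screen's design at 1/10 scale — 1,000 genes
    x 5 constructs/gene split round-robin over 2 modules, 21 Luciferase
    negative controls per module, 5e5 reads per lane — so a full
    simulated screen runs in seconds.  ``noise_sigma`` defaults to 0.17,
    the middle of the 0.16-0.19 control-ratio SD band observed in the
    screen this generator emulates.  ``effect_log2 = -2`` plants a
    4-fold depletion on ``efficacy_constructs`` of each affected gene's
    constructs (rescue genes get the mirrored enrichment).
    """

    n_genes: int = 1000
    constructs_per_gene: int = 5
    n_controls_per_module: int = 21
    n_modules: int = 2
    frac_sl_genes: float = 0.03
    frac_rescue_genes: float = 0.01
    efficacy_constructs: int = 3
    effect_log2: float = -2.0
    baseline_sigma: float = 0.5
    noise_sigma: float = 0.17
    reads_per_lane: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frac_sl_genes + self.frac_rescue_genes > 1:
            raise ScreenConfigError("frac_sl_genes + frac_rescue_genes must be <= 1")
        if min(self.frac_sl_genes, self.frac_rescue_genes) < 0:
            raise ScreenConfigError("planted fractions must be >= 0")
        if self.efficacy_constructs > self.constructs_per_gene:
            raise ScreenConfigError(
                "efficacy_constructs cannot exceed constructs_per_gene"
            )
        for name in (
            "n_genes",
            "constructs_per_gene",
            "n_controls_per_module",
            "n_modules",
            "efficacy_constructs",
            "reads_per_lane",
        ):
            if getattr(self, name) <= 0:
                raise ScreenConfigError(f"{name} must be positive")
        if self.baseline_sigma < 0 or self.noise_sigma < 0:
            raise ScreenConfigError("sigma parameters must be >= 0")

    @property
    def n_constructs(self) -> int:
        return (
            self.n_genes * self.constructs_per_gene
            + self.n_modules * self.n_controls_per_module
        )

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth of a simulated screen.

    ``gene_status`` maps gene symbol -> SL / RESCUE / NEUTRAL;
    ``construct_effect`` maps construct_id -> carries_effect (controls
    and all constructs of neutral genes are False).
    """

    gene_status: pd.Series
    construct_effect: pd.Series

    def genes_with_status(self, status: str) -> set[str]:
        return set(self.gene_status.index[self.gene_status == status])


def _barcode(index: int) -> str:
    """Deterministic unique barcode: the index written in base 4."""
    digits = []
    for _ in range(BARCODE_LENGTH):
        digits.append(_BASES[index % 4])
        index //= 4
    return "".join(reversed(digits))


def generate_library(config: SimulationConfig) -> tuple[LibraryDesign, GroundTruth]:
    """Build a library design and its planted ground truth.

    Genes are assigned to modules round-robin; SL and rescue genes are
    drawn without replacement with the config seed, and each affected
    gene gets exactly ``efficacy_constructs`` effect-carrying constructs
    (chosen at random among its constructs).  Deterministic given seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    gene_module = {g: (i % config.n_modules) + 1 for i, g in enumerate(genes)}

    n_sl = round(config.frac_sl_genes * config.n_genes)
    n_rescue = round(config.frac_rescue_genes * config.n_genes)
    picked = rng.choice(config.n_genes, size=n_sl + n_rescue, replace=False)
    status = pd.Series(NEUTRAL, index=pd.Index(genes, name="gene"), dtype=object)
    status.iloc[picked[:n_sl]] = SL
    status.iloc[picked[n_sl:]] = RESCUE

    rows = []
    effect: dict[str, bool] = {}
    idx = 0
    for g in genes:
        carriers: set[int] = set()
        if status[g] != NEUTRAL:
            carriers = set(
                rng.choice(
                    config.constructs_per_gene,
                    size=config.efficacy_constructs,
                    replace=False,
                )
            )
        for j in range(config.constructs_per_gene):
            cid = f"{g}_c{j + 1}"
            rows.append((_barcode(idx), cid, g, gene_module[g], False))
            effect[cid] = j in carriers
            idx += 1
    for m in range(1, config.n_modules + 1):
        for j in range(config.n_controls_per_module):
            cid = f"Luc_m{m}_c{j + 1}"
            rows.append((_barcode(idx), cid, "", m, True))
            effect[cid] = False
            idx += 1

    table = pd.DataFrame(
        rows, columns=["barcode", "construct_id", "gene", "module", "is_control"]
    )
    design = LibraryDesign(table)
    truth = GroundTruth(
        gene_status=status,
        construct_effect=pd.Series(effect, name="carries_effect").reindex(
            table["construct_id"].values
        ),
    )
    return design, truth


def simulate_counts(
    design: LibraryDesign, truth: GroundTruth, config: SimulationConfig
) -> tuple[CountTable, CountTable]:
    """Draw one control-lane and one treatment-lane count table.

    Returns ``(control, treatment)``; each lane's counts sum to
    ``reads_per_lane`` exactly.  The planted effect acts only in the
    treatment lane.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    t = design.table
    n = len(t)
    if not truth.construct_effect.index.equals(pd.Index(t["construct_id"])):
        raise ScreenConfigError("truth does not match design (construct order)")

    log_a = rng.normal(0.0, config.baseline_sigma, size=n)
    baseline = np.exp(log_a)

    status_per_construct = truth.gene_status.reindex(t["gene"].values).fillna(NEUTRAL)
    e = np.where(
        truth.construct_effect.values & (status_per_construct.values == SL),
        config.effect_log2,
        0.0,
    )
    e = np.where(
        truth.construct_effect.values & (status_per_construct.values == RESCUE),
        -config.effect_log2,
        e,
    )
    eps = rng.normal(0.0, config.noise_sigma, size=n)
    treat_abund = baseline * np.exp2(e + eps)

    def draw(abund: np.ndarray, label: str) -> CountTable:
        p = abund / abund.sum()
        counts = rng.multinomial(config.reads_per_lane, p)
        series = pd.Series(
            counts, index=pd.Index(t["construct_id"], name="construct_id")
        ).astype(int)
        return CountTable(label, series)

    return draw(baseline, "siCTRL"), draw(treat_abund, "siFH")


def expected_control_ratio_sd(
    config: SimulationConfig, mean_count: float | None = None
) -> tuple[float, float]:
    """Generative noise SD and the larger SD observed at finite depth.

    Counting (shot) noise inflates the SD of observed log2 ratios above
    ``noise_sigma``.  By the delta method a construct sequenced to about
    ``m`` reads in each lane adds ``(1/ln 2)^2 * (1/m_ctrl + 1/m_treat)``
    to the log2-ratio variance.  Returns ``(noise_sigma, expected
    observed SD)`` so calibration tests can target the observed value.
    """
    if mean_count is None:
        mean_count = config.reads_per_lane / config.n_constructs
    shot_var = (1.0 / math.log(2)) ** 2 * (2.0 / mean_count)
    return config.noise_sigma, math.sqrt(config.noise_sigma**2 + shot_var)


def write_fixture(
    design: LibraryDesign,
    truth: GroundTruth,
    tables: tuple[CountTable, CountTable],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Serialize a complete simulated screen as four TSV files.

    ``library.tsv``, one count TSV per lane, and ``truth.tsv`` (one row
    per construct: construct_id, gene, status, carries_effect).  All are
    re-readable by :mod:`slscreen.io`; same seed gives byte-identical
    files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"library": write_library_annotation(design, out_dir / "library.tsv")}
    for table in tables:
        p = out_dir / f"counts_{table.lane_label}.tsv"
        paths[f"counts_{table.lane_label}"] = write_count_table(table, p)
    t = design.table
    status = truth.gene_status.reindex(t["gene"].values).fillna("").values
    truth_df = pd.DataFrame(
        {
            "construct_id": t["construct_id"],
            "gene": t["gene"],
            "status": status,
            "carries_effect": truth.construct_effect.values.astype(int),
        }
    )
    p = out_dir / "truth.tsv"
    truth_df.to_csv(p, sep="\t", index=False)
    paths["truth"] = p
    return paths
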