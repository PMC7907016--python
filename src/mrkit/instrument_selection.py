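"""Instrument vetting: significance filter, LD pruning, pleiotropy screen,
and instrument-strength statistics (R^2 and F).

A genetic variant qualifies as an instrumental variable only if it is
strongly associated with the exposure, independent of the other selected
variants (no linkage disequilibrium), and not associated with other traits
that could open confounding pathways.  This module implements that
pipeline over summary statistics plus two local lookup tables: a pairwise
r^2 matrix and a SNP -> secondary-trait association table (hermetic
stand-ins for online LD and phenome-scan services).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .core_io import GwasAssociation

__all__ = [
    "SelectionReport",
    "ConfigurationError",
    "filter_genome_wide",
    "ld_prune",
    "exclude_pleiotropic",
    "variance_explained",
    "f_statistic",
    "select_instruments",
    "read_ld_matrix",
    "read_trait_table",
    "GENOME_WIDE_P",
    "LD_R2_THRESHOLD",
    "WEAK_INSTRUMENT_F",
    "DEFAULT_EXPOSURE_N",
]

GENOME_WIDE_P = 5e-8
LD_R2_THRESHOLD = 0.001
WEAK_INSTRUMENT_F = 10.0
#: Study-level exposure sample size used when a record carries no n.
DEFAULT_EXPOSURE_N = 44147


class ConfigurationError(ValueError):
    """An input table does not cover the SNPs it must (e.g. missing rsID)."""


@dataclass
class SelectionReport:
    """Audit trail of the selection pipeline.

    Each input SNP appears exactly once: either in ``retained`` or in one
    of the removal lists (first failing filter wins). ``per_snp_r2`` and
    ``per_snp_f`` cover every retained SNP; ``weak`` lists retained SNPs
    whose F statistic falls at or below the conventional threshold of 10.
    """

    input_count: int
    removed_significance: list[str] = field(default_factory=list)
    removed_ld: list[tuple[str, str]] = field(default_factory=list)
    removed_pleiotropy: list[tuple[str, str]] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    per_snp_r2: dict[str, float] = field(default_factory=dict)
    per_snp_f: dict[str, float] = field(default_factory=dict)
    weak: list[str] = field(default_factory=list)

    def validate(self) -> None:
        n_removed = (
            len(self.removed_significance)
            + len(self.removed_ld)
            + len(self.removed_pleiotropy)
        )
        if self.input_count != len(self.retained) + n_removed:
            raise AssertionError("selection report does not partition the input")
        for snp in self.retained:
            if snp not in self.per_snp_r2 or snp not in self.per_snp_f:
                raise AssertionError(f"retained SNP {snp} lacks strength statistics")


def filter_genome_wide(
    associations: Sequence[GwasAssociation], threshold: float = GENOME_WIDE_P
) -> tuple[list[GwasAssociation], list[GwasAssociation]]:
    """Partition by strict genome-wide significance (p < threshold)."""
    if not (0 < threshold < 1):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    retained = [a for a in associations if a.pval < threshold]
    removed = [a for a in associations if not a.pval < threshold]
    return retained, removed


def ld_prune(
    associations: Sequence[GwasAssociation],
    r2_matrix: pd.DataFrame,
    r2_threshold: float = LD_R2_THRESHOLD,
) -> tuple[list[GwasAssociation], list[tuple[str, str]]]:
    """Greedy LD pruning: drop the most-connected / least-significant SNP.

    While any pair of remaining SNPs has r^2 above the threshold, the SNP
    removed is the one involved in the most violating pairs; ties are
    broken by the larger association p-value, then by later input order.
    Each removal is recorded as ``(rsID, reason)`` where the reason names
    the partner count and the SNP's p-rank among the removal candidates.

    ``r2_matrix`` must be symmetric with unit diagonal and cover every
    input rsID (missing rsIDs raise :class:`ConfigurationError`).
    """
    ids = [a.snp_id for a in associations]
    for snp in ids:
        if snp not in r2_matrix.index or snp not in r2_matrix.columns:
            raise ConfigurationError(f"rsID {snp} absent from the LD matrix")

    order = {a.snp_id: i for i, a in enumerate(associations)}
    pvals = {a.snp_id: a.pval for a in associations}
    alive = list(ids)
    removed: list[tuple[str, str]] = []

    def partners(snp: str) -> list[str]:
        return [
            other
            for other in alive
            if other != snp and float(r2_matrix.loc[snp, other]) > r2_threshold
        ]

    while True:
        degree = {snp: len(partners(snp)) for snp in alive}
        candidates = [snp for snp in alive if degree[snp] > 0]
        if not candidates:
            break
        max_deg = max(degree[s] for s in candidates)
        worst = [s for s in candidates if degree[s] == max_deg]
        max_p = max(pvals[s] for s in worst)
        worst = [s for s in worst if pvals[s] == max_p]
        victim = max(worst, key=lambda s: order[s])
        p_rank = 1 + sum(pvals[s] > pvals[victim] for s in candidates)
        removed.append(
            (
                victim,
                f"ld: {max_deg} violating partner(s); p-rank {p_rank} of "
                f"{len(candidates)} candidates",
            )
        )
        alive.remove(victim)

    retained = [a for a in associations if a.snp_id in set(alive)]
    return retained, removed


def exclude_pleiotropic(
    associations: Sequence[GwasAssociation],
    trait_table: Mapping[str, Sequence[tuple[str, float]]],
    threshold: float = GENOME_WIDE_P,
) -> tuple[list[GwasAssociation], list[tuple[str, str]]]:
    """Drop SNPs with a genome-wide-significant secondary-trait association.

    ``trait_table`` maps rsID to ``(trait, p)`` pairs; a SNP absent from
    the table has no known secondary traits and is retained. A removed SNP
    is annotated with the first offending trait in table order.
    """
    retained: list[GwasAssociation] = []
    removed: list[tuple[str, str]] = []
    for assoc in associations:
        offending = next(
            (
                trait
                for trait, p in trait_table.get(assoc.snp_id, ())
                if p < threshold
            ),
            None,
        )
        if offending is None:
            retained.append(assoc)
        else:
            removed.append((assoc.snp_id, offending))
    return retained, removed


def variance_explained(assoc: GwasAssociation) -> float:
    """Proportion of (unit) trait variance explained: 2 EAF (1-EAF) beta^2.

    Assumes the trait is standardized so that beta is in SD units.
    """
    if assoc.eaf is None:
        raise ValueError(
            f"{assoc.snp_id}: variance_explained requires the effect-allele frequency"
        )
    return 2.0 * assoc.eaf * (1.0 - assoc.eaf) * assoc.beta**2


def f_statistic(r2: float, n: float) -> float:
    """Single-instrument F statistic, F = r2 (n - 2) / (1 - r2).

    F <= 10 is conventionally flagged as a weak instrument.
    """
    if not 0 <= r2 < 1:
        raise ValueError(f"r2 must be in [0, 1), got {r2}")
    if n <= 2:
        raise ValueError(f"n must exceed 2, got {n}")
    return r2 * (n - 2) / (1 - r2)


def select_instruments(
    associations: Sequence[GwasAssociation],
    r2_matrix: pd.DataFrame | None = None,
    trait_table: Mapping[str, Sequence[tuple[str, float]]] | None = None,
    p_threshold: float = GENOME_WIDE_P,
    r2_threshold: float = LD_R2_THRESHOLD,
    pleiotropy_threshold: float = GENOME_WIDE_P,
    default_n: float = DEFAULT_EXPOSURE_N,
) -> tuple[list[GwasAssociation], SelectionReport]:
    """Run the full pipeline: significance -> LD pruning -> pleiotropy screen.

    Returns the retained associations plus a :class:`SelectionReport` with
    per-SNP R^2 and F for every survivor (per-record n when present, else
    ``default_n``).
    """
    report = SelectionReport(input_count=len(associations))

    sig, nonsig = filter_genome_wide(associations, p_threshold)
    report.removed_significance = [a.snp_id for a in nonsig]

    if r2_matrix is not None:
        sig, report.removed_ld = ld_prune(sig, r2_matrix, r2_threshold)

    if trait_table is not None:
        sig, report.removed_pleiotropy = exclude_pleiotropic(
            sig, trait_table, pleiotropy_threshold
        )

    report.retained = [a.snp_id for a in sig]
    for assoc in sig:
        r2 = variance_explained(assoc)
        f = f_statistic(r2, assoc.n if assoc.n is not None else default_n)
        report.per_snp_r2[assoc.snp_id] = r2
        report.per_snp_f[assoc.snp_id] = f
        if f <= WEAK_INSTRUMENT_F:
            report.weak.append(assoc.snp_id)
    report.validate()
    return sig, report


def read_ld_matrix(path) -> pd.DataFrame:
    """Read a symmetric r^2 matrix TSV (first row and column are rsIDs)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return frame


def read_trait_table(path) -> dict[str, list[tuple[str, float]]]:
    """Read a secondary-trait TSV with columns snp, trait, pval."""
    frame = pd.read_csv(path, sep="\t")
    table: dict[str, list[tuple[str, float]]] = {}
    for _, row in frame.iterrows():
        table.setdefault(str(row["snp"]), []).append((str(row["trait"]), float(row["pval"])))
    return table
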