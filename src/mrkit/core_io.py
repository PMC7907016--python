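"""Summary-statistic data model, readers/writers, allele harmonization.

Two-sample Mendelian randomization works entirely from per-SNP summary
associations: for each variant, an additive effect estimate (beta), its
standard error, and allele labels from the exposure GWAS and from the
outcome GWAS.  Because the two studies may report effects relative to
different alleles (or on different strands), the outcome association must
first be re-oriented onto the exposure study's effect allele —
"harmonization" — before any causal estimator can be applied.

This module defines the record types shared by the whole package
(:class:`GwasAssociation`, :class:`HarmonizedInstrument`,
:class:`MrEstimate`), file I/O for summary-statistic tables, the
harmonization rules, and the bundled nine-SNP homocysteine → coronary
artery disease (in diabetes) instrument set used throughout the
documentation and tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "GwasAssociation",
    "HarmonizedInstrument",
    "MrEstimate",
    "Exclusion",
    "SummaryStatsFormatError",
    "ValidationError",
    "read_summary_stats",
    "write_summary_stats",
    "harmonize_pair",
    "harmonize",
    "write_harmonized",
    "read_harmonized",
    "load_paper_fixture",
    "load_paper_associations",
    "FIXTURE_N_EXPOSURE",
]

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Exposure-GWAS sample size of the bundled fixture (homocysteine meta-analysis).
FIXTURE_N_EXPOSURE = 44147


class SummaryStatsFormatError(ValueError):
    """A summary-statistics file is malformed (missing column, bad value)."""


class ValidationError(ValueError):
    """A record violates a data-model invariant (e.g. SE <= 0)."""


@dataclass(frozen=True)
class GwasAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is the additive per-allele effect of ``effect_allele`` on the
    trait (log odds ratio for a binary trait); ``eaf`` is the effect-allele
    frequency in the study sample and may be absent.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str | None = None
    eaf: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.snp_id}: alleles must be single uppercase nucleotides, "
                f"got {self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se > 0:
            raise ValidationError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0 < self.pval <= 1):
            raise ValidationError(f"{self.snp_id}: pval must be in (0, 1], got {self.pval}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValidationError(f"{self.snp_id}: eaf must be in [0, 1], got {self.eaf}")

    @property
    def is_palindromic(self) -> bool:
        """True for strand-ambiguous allele pairs (A/T or C/G)."""
        return self.other_allele == COMPLEMENT[self.effect_allele]


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A SNP's exposure and outcome associations on a common effect allele.

    ``wald_ratio``/``wald_se`` carry the per-SNP causal estimate
    beta_out / beta_exp with its first-order delta-method standard error
    se_out / |beta_exp|; they are populated whenever beta_exp != 0.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None
    pval_exp: float | None = None
    pval_out: float | None = None
    wald_ratio: float | None = None
    wald_se: float | None = None
    palindromic_flag: bool = False

    def __post_init__(self) -> None:
        if not self.se_exp > 0 or not self.se_out > 0:
            raise ValidationError(f"{self.snp_id}: standard errors must be > 0")


@dataclass(frozen=True)
class Exclusion:
    """A SNP dropped during harmonization, with the reason."""

    snp_id: str
    reason: str


@dataclass(frozen=True)
class MrEstimate:
    """A causal estimate on the log-odds scale with its OR-scale view.

    ``beta`` is the estimated causal effect of a one-unit (one SD for the
    bundled fixture) increase in the exposure on the log odds of the
    outcome; ``or_``, ``or_ci_low`` and ``or_ci_high`` are its
    exponentiated counterparts.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValidationError(
                f"{self.method}: CI [{self.ci_low}, {self.ci_high}] does not bracket {self.beta}"
            )
        if not (0 < self.pval <= 1):
            raise ValidationError(f"{self.method}: pval must be in (0, 1], got {self.pval}")

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_ci_high(self) -> float:
        return math.exp(self.ci_high)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "n_snps": self.n_snps,
            "or": self.or_,
            "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
        }


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

DEFAULT_COLUMNS: Mapping[str, str] = {
    "snp": "snp",
    "chr": "chr",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}

_REQUIRED = ("snp", "effect_allele", "other_allele", "beta", "se", "pval")


def read_summary_stats(
    path, column_map: Mapping[str, str] | None = None
) -> list[GwasAssociation]:
    """Read a tab- or comma-separated GWAS summary-statistics table.

    Parameters
    ----------
    path
        File with a header row. Tab- and comma-delimited files are both
        accepted (delimiter sniffed from the header line).
    column_map
        Maps the canonical names (``snp``, ``effect_allele``,
        ``other_allele``, ``beta``, ``se``, ``pval``; optionally ``chr``,
        ``eaf``, ``n``) to the column names used in the file. Unmapped
        names fall back to the canonical name itself.

    Returns
    -------
    list of :class:`GwasAssociation`, one per data row, in file order,
    alleles uppercased.

    Raises
    ------
    SummaryStatsFormatError
        If a required column is missing or a numeric field fails to parse
        (the message carries the 1-based file line number).
    ValidationError
        If a row violates an invariant, e.g. se <= 0.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)

    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline()
    sep = "\t" if "\t" in header_line else ","
    frame = pd.read_csv(path, sep=sep, dtype=str)

    for canon in _REQUIRED:
        if cmap[canon] not in frame.columns:
            raise SummaryStatsFormatError(
                f"required column {cmap[canon]!r} (for {canon!r}) not found in {path}"
            )

    def _num(row_idx: int, canon: str, raw: str) -> float:
        try:
            return float(raw)
        except (TypeError, ValueError):
            raise SummaryStatsFormatError(
                f"line {row_idx + 2}: non-numeric value {raw!r} in column "
                f"{cmap[canon]!r}"
            ) from None

    out: list[GwasAssociation] = []
    for idx, row in frame.iterrows():
        kwargs = dict(
            snp_id=str(row[cmap["snp"]]),
            effect_allele=str(row[cmap["effect_allele"]]).upper(),
            other_allele=str(row[cmap["other_allele"]]).upper(),
            beta=_num(idx, "beta", row[cmap["beta"]]),
            se=_num(idx, "se", row[cmap["se"]]),
            pval=_num(idx, "pval", row[cmap["pval"]]),
        )
        for opt in ("chr", "eaf", "n"):
            col = cmap[opt]
            if col in frame.columns and pd.notna(row[col]):
                if opt == "chr":
                    kwargs["chrom"] = str(row[col])
                else:
                    kwargs[opt] = _num(idx, opt, row[col])
        out.append(GwasAssociation(**kwargs))
    return out


def write_summary_stats(associations: Sequence[GwasAssociation], path) -> None:
    """Write associations as a TSV that :func:`read_summary_stats` round-trips."""
    rows = [
        {
            "snp": a.snp_id,
            "chr": a.chrom,
            "effect_allele": a.effect_allele,
            "other_allele": a.other_allele,
            "eaf": a.eaf,
            "beta": repr(a.beta),
            "se": repr(a.se),
            "pval": repr(a.pval),
            "n": a.n,
        }
        for a in associations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------


def _first_order_wald(beta_exp: float, se_out: float, beta_out: float):
    if beta_exp == 0:
        return None, None
    return beta_out / beta_exp, se_out / abs(beta_exp)


def harmonize_pair(
    exposure: GwasAssociation,
    outcome: GwasAssociation,
    drop_palindromic_maf_threshold: float = 0.42,
) -> HarmonizedInstrument | Exclusion:
    """Orient an outcome association onto the exposure's effect allele.

    Rules, applied in order:

    * same effect/other alleles -> outcome copied as-is;
    * swapped alleles -> outcome beta negated, outcome EAF replaced by 1-EAF;
    * complementary alleles (strand flip) -> complemented, then the two
      rules above;
    * palindromic SNPs (A/T or C/G pairs): allele labels cannot resolve the
      strand, so orientation is inferred from allele frequency.  When the
      minor-allele frequency is >= ``drop_palindromic_maf_threshold`` the
      frequency signal is too weak and the SNP is excluded with reason
      ``"palindromic-ambiguous"``; otherwise the outcome effect is flipped
      iff its EAF sits on the opposite side of 0.5 from the exposure EAF.

    Returns a :class:`HarmonizedInstrument` (with Wald-ratio fields
    populated when beta_exp != 0) or an :class:`Exclusion`.
    """
    if exposure.snp_id != outcome.snp_id:
        raise ValueError(
            f"snp_id mismatch: {exposure.snp_id!r} vs {outcome.snp_id!r}"
        )
    ea, oa = exposure.effect_allele, exposure.other_allele

    def _build(beta_out: float, se_out: float) -> HarmonizedInstrument:
        ratio, ratio_se = _first_order_wald(exposure.beta, se_out, beta_out)
        return HarmonizedInstrument(
            snp_id=exposure.snp_id,
            effect_allele=ea,
            other_allele=oa,
            beta_exp=exposure.beta,
            se_exp=exposure.se,
            beta_out=beta_out,
            se_out=se_out,
            eaf_exp=exposure.eaf,
            pval_exp=exposure.pval,
            pval_out=outcome.pval,
            wald_ratio=ratio,
            wald_se=ratio_se,
            palindromic_flag=exposure.is_palindromic,
        )

    if exposure.is_palindromic:
        if exposure.eaf is None:
            raise ValidationError(
                f"{exposure.snp_id}: palindromic SNP needs exposure EAF to resolve strand"
            )
        maf = min(exposure.eaf, 1 - exposure.eaf)
        if maf >= drop_palindromic_maf_threshold:
            return Exclusion(exposure.snp_id, "palindromic-ambiguous")
        if {outcome.effect_allele, outcome.other_allele} != {ea, oa}:
            return Exclusion(exposure.snp_id, "allele-mismatch")
        if outcome.eaf is None:
            # Labels match and frequency is informative but absent on the
            # outcome side: accept the label orientation.
            flip = outcome.effect_allele != ea
        else:
            same_label = outcome.effect_allele == ea
            eaf_out = outcome.eaf if same_label else 1 - outcome.eaf
            flip = (eaf_out > 0.5) != (exposure.eaf > 0.5)
            if not same_label:
                flip = not flip
        if flip:
            return _build(-outcome.beta, outcome.se)
        return _build(outcome.beta, outcome.se)

    out_ea, out_oa = outcome.effect_allele, outcome.other_allele
    if (out_ea, out_oa) == (ea, oa):
        return _build(outcome.beta, outcome.se)
    if (out_ea, out_oa) == (oa, ea):
        return _build(-outcome.beta, outcome.se)
    comp = (COMPLEMENT[out_ea], COMPLEMENT[out_oa])
    if comp == (ea, oa):
        return _build(outcome.beta, outcome.se)
    if comp == (oa, ea):
        return _build(-outcome.beta, outcome.se)
    return Exclusion(exposure.snp_id, "allele-mismatch")


def harmonize(
    exposures: Sequence[GwasAssociation],
    outcomes: Sequence[GwasAssociation],
    drop_palindromic_maf_threshold: float = 0.42,
) -> tuple[list[HarmonizedInstrument], list[Exclusion]]:
    """Harmonize matching exposure/outcome records by rsID (exposure order)."""
    by_id = {o.snp_id: o for o in outcomes}
    instruments: list[HarmonizedInstrument] = []
    excluded: list[Exclusion] = []
    for exp in exposures:
        out = by_id.get(exp.snp_id)
        if out is None:
            excluded.append(Exclusion(exp.snp_id, "missing-in-outcome"))
            continue
        result = harmonize_pair(exp, out, drop_palindromic_maf_threshold)
        if isinstance(result, Exclusion):
            excluded.append(result)
        else:
            instruments.append(result)
    return instruments, excluded


_HARMONIZED_COLS = [
    "snp",
    "effect_allele",
    "other_allele",
    "beta_exp",
    "se_exp",
    "pval_exp",
    "beta_out",
    "se_out",
    "pval_out",
    "eaf_exp",
    "wald_ratio",
    "wald_se",
    "palindromic",
    "exclusion_reason",
]


def write_harmonized(
    instruments: Sequence[HarmonizedInstrument],
    path,
    excluded: Sequence[Exclusion] = (),
) -> None:
    """Write harmonized instruments (and exclusions) as a side-by-side TSV."""
    rows = []
    for inst in instruments:
        rows.append(
            {
                "snp": inst.snp_id,
                "effect_allele": inst.effect_allele,
                "other_allele": inst.other_allele,
                "beta_exp": repr(inst.beta_exp),
                "se_exp": repr(inst.se_exp),
                "pval_exp": None if inst.pval_exp is None else repr(inst.pval_exp),
                "beta_out": repr(inst.beta_out),
                "se_out": repr(inst.se_out),
                "pval_out": None if inst.pval_out is None else repr(inst.pval_out),
                "eaf_exp": None if inst.eaf_exp is None else repr(inst.eaf_exp),
                "wald_ratio": None if inst.wald_ratio is None else repr(inst.wald_ratio),
                "wald_se": None if inst.wald_se is None else repr(inst.wald_se),
                "palindromic": inst.palindromic_flag,
                "exclusion_reason": None,
            }
        )
    for exc in excluded:
        rows.append({"snp": exc.snp_id, "exclusion_reason": exc.reason})
    pd.DataFrame(rows, columns=_HARMONIZED_COLS).to_csv(path, sep="\t", index=False)


def read_harmonized(path) -> list[HarmonizedInstrument]:
    """Read a harmonized-instrument TSV written by :func:`write_harmonized`.

    Rows carrying an exclusion reason are skipped.
    """
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    instruments = []
    for _, row in frame.iterrows():
        if isinstance(row.get("exclusion_reason"), str):
            continue
        instruments.append(
            HarmonizedInstrument(
                snp_id=str(row["snp"]),
                effect_allele=str(row["effect_allele"]),
                other_allele=str(row["other_allele"]),
                beta_exp=float(row["beta_exp"]),
                se_exp=float(row["se_exp"]),
                beta_out=float(row["beta_out"]),
                se_out=float(row["se_out"]),
                eaf_exp=None if pd.isna(row.get("eaf_exp")) else float(row["eaf_exp"]),
                pval_exp=None if pd.isna(row.get("pval_exp")) else float(row["pval_exp"]),
                pval_out=None if pd.isna(row.get("pval_out")) else float(row["pval_out"]),
                wald_ratio=None if pd.isna(row.get("wald_ratio")) else float(row["wald_ratio"]),
                wald_se=None if pd.isna(row.get("wald_se")) else float(row["wald_se"]),
                palindromic_flag=bool(row.get("palindromic", False)),
            )
        )
    return instruments


# ---------------------------------------------------------------------------
# Bundled fixture
# ---------------------------------------------------------------------------


def _fixture_frame() -> pd.DataFrame:
    with resources.files("mrkit.data").joinpath("hcy_cad_table1.tsv").open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_paper_associations() -> tuple[list[GwasAssociation], list[GwasAssociation]]:
    """Exposure and outcome association lists for the bundled nine-SNP set.

    Exposure: SNP effects on plasma homocysteine (SD units, meta-analysis of
    up to 44,147 Europeans). Outcome: the same SNPs' log-odds effects on
    coronary artery disease among individuals with diabetes (3,968 cases,
    11,696 controls). Both studies report effects for the same effect
    allele, so harmonization leaves the outcome betas unchanged.

    The EAF values are two-decimal reconstructions (the published table
    typesets EAF and the F statistic without a separator); they are the
    unique parse consistent with the instrument-strength formula for seven
    of the nine rows.
    """
    frame = _fixture_frame()
    exposures, outcomes = [], []
    for _, row in frame.iterrows():
        common = dict(
            snp_id=row["snp"],
            chrom=str(row["chr"]),
            effect_allele=row["effect_allele"],
            other_allele=row["other_allele"],
        )
        exposures.append(
            GwasAssociation(
                beta=float(row["beta_exp"]),
                se=float(row["se_exp"]),
                pval=float(row["pval_exp"]),
                eaf=float(row["eaf"]),
                n=FIXTURE_N_EXPOSURE,
                **common,
            )
        )
        outcomes.append(
            GwasAssociation(
                beta=float(row["beta_out"]),
                se=float(row["se_out"]),
                pval=float(row["pval_out"]),
                **common,
            )
        )
    return exposures, outcomes


def load_paper_fixture() -> list[HarmonizedInstrument]:
    """The bundled nine-SNP homocysteine -> CAD-in-diabetes instrument set.

    Returns exactly nine harmonized instruments in table order with
    full-precision betas/SEs and Wald-ratio fields populated.
    """
    exposures, outcomes = load_paper_associations()
    instruments, excluded = harmonize(exposures, outcomes)
    assert not excluded, "fixture must harmonize cleanly"
    return instruments


def fixture_printed_f() -> dict[str, int]:
    """Published per-SNP F statistics of the bundled fixture (as printed)."""
    frame = _fixture_frame()
    return dict(zip(frame["snp"], frame["f_printed"].astype(int)))
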