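"""Reading, validation and harmonization of two-sample GWAS summary statistics.

A two-sample Mendelian randomization analysis consumes per-SNP association
summaries from two independent GWAS: one for the exposure trait and one for
the outcome. This module parses the tab/comma-separated tables consortia
distribute, validates them row by row, aligns the two studies on a common
effect allele (resolving strand swaps and palindromic ambiguity), and applies
the genome-wide significance filter used to select instruments.

It also ships the package's bundled instrument set: the 46 SNPs associated
with waist circumference (GIANT consortium, n = 224,459) paired with their
coronary-heart-disease associations (CARDIoGRAMplusC4D, 60,801 cases /
123,504 controls), as published. That table is printed on a shared effect
allele, so it loads pre-harmonized.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: Allele pairs that are their own reverse complement; orientation between two
#: studies cannot be resolved from the alleles alone.
PALINDROMIC_PAIRS = frozenset({frozenset({"A", "T"}), frozenset({"G", "C"})})

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default half-width of the allele-frequency window around 0.5 inside which a
#: palindromic SNP is considered unresolvable and dropped.
DEFAULT_PALINDROMIC_EAF_WINDOW = 0.08


class SummaryStatsError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(SummaryStatsError):
    """A column mapping, threshold or option is invalid."""


class ParseError(SummaryStatsError):
    """A data row could not be parsed into numbers."""


class ValidationError(SummaryStatsError):
    """The parsed table violates a structural invariant (e.g. duplicate rsids)."""


class HarmonizationError(SummaryStatsError):
    """Exposure and outcome tables cannot be aligned on shared instruments."""


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's summary association with one trait in one study.

    ``beta`` is the additive per-effect-allele association: SD units for a
    continuous trait, log-odds for a binary one. ``other_allele`` and ``eaf``
    may be missing (consortium tables do not always report them).
    """

    rsid: str
    effect_allele: str
    beta: float
    se: float
    other_allele: str | None = None
    eaf: float | None = None
    pval: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.rsid}: effect allele {self.effect_allele!r} is not one of A/C/G/T"
            )
        if self.other_allele is not None and self.other_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.rsid}: other allele {self.other_allele!r} is not one of A/C/G/T"
            )
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.rsid}: beta is not finite")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValidationError(f"{self.rsid}: se must be finite and > 0, got {self.se}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValidationError(f"{self.rsid}: eaf {self.eaf} outside [0, 1]")
        if self.pval is not None and not (0.0 < self.pval <= 1.0):
            raise ValidationError(f"{self.rsid}: p-value {self.pval} outside (0, 1]")

    @property
    def is_palindromic(self) -> bool:
        """True when the allele pair is A/T or G/C (ambiguous across strands)."""
        if self.other_allele is None:
            return False
        return frozenset({self.effect_allele, self.other_allele}) in PALINDROMIC_PAIRS

    def pval_or_computed(self) -> float:
        """Stored p-value, or the two-sided normal tail of beta/se when absent."""
        if self.pval is not None:
            return self.pval
        return float(2.0 * stats.norm.sf(abs(self.beta / self.se)))


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One SNP's paired exposure and outcome effects on a shared effect allele.

    The genetic association with the exposure (``beta_exp``, SD units) and
    with the outcome (``beta_out``, log-odds for a binary outcome) refer to
    the same allele, so their ratio is a per-SNP causal estimate.
    """

    rsid: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    effect_allele: str | None = None
    eaf: float | None = None
    pval_exp: float | None = None
    pval_out: float | None = None
    flipped: bool = False
    palindromic: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.se_exp) and self.se_exp > 0):
            raise ValidationError(f"{self.rsid}: se_exp must be > 0")
        if not (math.isfinite(self.se_out) and self.se_out > 0):
            raise ValidationError(f"{self.rsid}: se_out must be > 0")
        if self.beta_exp == 0:
            raise ValidationError(
                f"{self.rsid}: beta_exp must be nonzero for a finite Wald ratio"
            )

    def exposure_pval(self) -> float:
        if self.pval_exp is not None:
            return self.pval_exp
        return float(2.0 * stats.norm.sf(abs(self.beta_exp / self.se_exp)))

    def reoriented(self) -> "HarmonizedInstrument":
        """The same instrument expressed on the opposite allele (both betas negated)."""
        allele = _COMPLEMENT.get(self.effect_allele) if self.effect_allele else None
        eaf = None if self.eaf is None else 1.0 - self.eaf
        return replace(
            self,
            beta_exp=-self.beta_exp,
            beta_out=-self.beta_out,
            effect_allele=allele,
            eaf=eaf,
        )


@dataclass
class InstrumentSet:
    """An ordered set of harmonized instruments for one exposure–outcome pair."""

    exposure_name: str
    outcome_name: str
    instruments: tuple[HarmonizedInstrument, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # An empty set is representable (filter_instruments may empty it);
        # every estimator rejects it at point of use.
        self.instruments = tuple(self.instruments)
        rsids = [i.rsid for i in self.instruments]
        dupes = sorted({r for r in rsids if rsids.count(r) > 1})
        if dupes:
            raise ValidationError(f"duplicate rsids in instrument set: {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.instruments)

    def __iter__(self) -> Iterator[HarmonizedInstrument]:
        return iter(self.instruments)

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(i.rsid for i in self.instruments)

    def drop(self, rsid: str) -> "InstrumentSet":
        """A new set without ``rsid`` (used by leave-one-out)."""
        kept = tuple(i for i in self.instruments if i.rsid != rsid)
        if len(kept) == len(self.instruments):
            raise KeyError(rsid)
        return InstrumentSet(self.exposure_name, self.outcome_name, kept, dict(self.provenance))

    def swapped(self) -> "InstrumentSet":
        """Exposure and outcome roles exchanged (for reverse-direction MR)."""
        swapped = tuple(
            replace(
                i,
                beta_exp=i.beta_out,
                se_exp=i.se_out,
                beta_out=i.beta_exp,
                se_out=i.se_exp,
                pval_exp=i.pval_out,
                pval_out=i.pval_exp,
            )
            for i in self.instruments
        )
        return InstrumentSet(self.outcome_name, self.exposure_name, swapped, dict(self.provenance))

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with one row per instrument, in set order."""
        return pd.DataFrame(
            {
                "rsid": [i.rsid for i in self.instruments],
                "ea": [i.effect_allele for i in self.instruments],
                "eaf": [i.eaf for i in self.instruments],
                "beta_exp": [i.beta_exp for i in self.instruments],
                "se_exp": [i.se_exp for i in self.instruments],
                "pval_exp": [i.pval_exp for i in self.instruments],
                "beta_out": [i.beta_out for i in self.instruments],
                "se_out": [i.se_out for i in self.instruments],
                "pval_out": [i.pval_out for i in self.instruments],
                "flipped": [i.flipped for i in self.instruments],
                "palindromic": [i.palindromic for i in self.instruments],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "rsid": "rsid",
    "effect_allele": "ea",
    "other_allele": "oa",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
}

_REQUIRED_FIELDS = ("rsid", "effect_allele", "beta", "se")
_OPTIONAL_FIELDS = ("other_allele", "eaf", "pval")


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_summary_table(
    path: str | Path | io.TextIOBase,
    column_map: Mapping[str, str] | None = None,
) -> list[SnpAssociation]:
    """Read one study's per-SNP summary statistics from a headered TSV/CSV.

    ``column_map`` maps the canonical field names (rsid, effect_allele,
    other_allele, eaf, beta, se, pval) to the column names used in the file;
    optional fields may be omitted from the map or absent in the file. Rows
    violating the per-record invariants (se <= 0, allele not in A/C/G/T, eaf
    outside [0, 1]) are rejected with a row-numbered log message rather than
    aborting the whole read; structural problems (missing mapped column,
    non-numeric beta/se, duplicated rsid) raise.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    if isinstance(path, (str, Path)):
        handle: io.TextIOBase = open(path, "r", encoding="utf-8", newline="")
        close = True
    else:
        handle, close = path, False

    try:
        first = handle.readline()
        if not first:
            raise ParseError("empty file: no header row")
        delim = _sniff_delimiter(first)
        reader = csv.DictReader(io.StringIO(first + handle.read()), delimiter=delim)
        header = reader.fieldnames or []

        for fld in _REQUIRED_FIELDS:
            if cmap[fld] not in header:
                raise ConfigurationError(
                    f"mapped column {cmap[fld]!r} for field {fld!r} not found in header {header}"
                )
        present_optional = {f: cmap[f] for f in _OPTIONAL_FIELDS if cmap.get(f) in header}

        records: list[SnpAssociation] = []
        seen: dict[str, int] = {}
        for lineno, row in enumerate(reader, start=2):
            rsid = (row[cmap["rsid"]] or "").strip()
            try:
                beta = float(row[cmap["beta"]])
                se = float(row[cmap["se"]])
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"row {lineno} ({rsid or '?'}): non-numeric beta/se: {exc}"
                ) from None

            def _opt_float(fld: str) -> float | None:
                col = present_optional.get(fld)
                if col is None:
                    return None
                raw = (row.get(col) or "").strip()
                if raw in ("", "NA", "nan", "."):
                    return None
                try:
                    return float(raw)
                except ValueError:
                    raise ParseError(f"row {lineno} ({rsid}): non-numeric {fld}: {raw!r}") from None

            oa_col = present_optional.get("other_allele")
            oa = (row.get(oa_col) or "").strip().upper() or None if oa_col else None

            try:
                rec = SnpAssociation(
                    rsid=rsid,
                    effect_allele=(row[cmap["effect_allele"]] or "").strip().upper(),
                    other_allele=oa,
                    eaf=_opt_float("eaf"),
                    beta=beta,
                    se=se,
                    pval=_opt_float("pval"),
                )
            except ValidationError as exc:
                logger.warning("row %d rejected: %s", lineno, exc)
                continue
            seen.setdefault(rec.rsid, 0)
            seen[rec.rsid] += 1
            records.append(rec)

        dupes = sorted(r for r, n in seen.items() if n > 1)
        if dupes:
            raise ValidationError(f"duplicate rsids in table: {', '.join(dupes)}")
        if not records:
            logger.warning("summary table contained no valid data rows")
        return records
    finally:
        if close:
            handle.close()


def write_summary_table(records: Sequence[SnpAssociation], path: str | Path) -> None:
    """Write associations back out in the default TSV dialect (round-trippable)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["rsid", "ea", "oa", "eaf", "beta", "se", "pval"])
        for r in records:
            writer.writerow(
                [
                    r.rsid,
                    r.effect_allele,
                    r.other_allele or "",
                    "" if r.eaf is None else repr(r.eaf),
                    repr(r.beta),
                    repr(r.se),
                    "" if r.pval is None else repr(r.pval),
                ]
            )


def _alleles_swapped(exp: SnpAssociation, out: SnpAssociation) -> bool | None:
    """True if the outcome record is reported on the opposite allele.

    Returns None when the allele pairs cannot be reconciled at all.
    """
    if out.effect_allele == exp.effect_allele:
        if exp.other_allele and out.other_allele and out.other_allele != exp.other_allele:
            return None
        return False
    if exp.other_allele is not None and out.effect_allele == exp.other_allele:
        if out.other_allele and out.other_allele != exp.effect_allele:
            return None
        return True
    if exp.other_allele is None and out.other_allele == exp.effect_allele:
        return True
    return None


def harmonize(
    exposure: Sequence[SnpAssociation],
    outcome: Sequence[SnpAssociation],
    palindromic_eaf_window: float = DEFAULT_PALINDROMIC_EAF_WINDOW,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> InstrumentSet:
    """Align exposure and outcome summaries on a common effect allele.

    SNPs present in both studies are paired; when the outcome study reports
    the opposite allele its beta is negated (and eaf complemented) so both
    effects refer to the exposure study's effect allele. Palindromic SNPs
    (A/T or G/C) carry no strand information, so they are kept only when both
    studies' effect-allele frequencies fall outside
    ``[0.5 - window, 0.5 + window]`` *and* on the same side of 0.5 — otherwise
    the orientation is ambiguous and the SNP is dropped with a logged reason.
    SNPs with a zero exposure effect are dropped (no finite Wald ratio).
    """
    if not exposure or not outcome:
        raise HarmonizationError("both exposure and outcome tables must be nonempty")
    if not (0.0 <= palindromic_eaf_window < 0.5):
        raise ConfigurationError("palindromic_eaf_window must lie in [0, 0.5)")

    out_by_rsid = {r.rsid: r for r in outcome}
    shared = [r for r in exposure if r.rsid in out_by_rsid]
    if not shared:
        raise HarmonizationError("no shared instruments between exposure and outcome tables")

    lo, hi = 0.5 - palindromic_eaf_window, 0.5 + palindromic_eaf_window
    instruments: list[HarmonizedInstrument] = []
    for exp in shared:
        out = out_by_rsid[exp.rsid]
        swapped = _alleles_swapped(exp, out)
        if swapped is None:
            logger.warning(
                "%s dropped: alleles irreconcilable (%s/%s vs %s/%s)",
                exp.rsid, exp.effect_allele, exp.other_allele,
                out.effect_allele, out.other_allele,
            )
            continue
        palindromic = exp.is_palindromic or out.is_palindromic
        if palindromic:
            if exp.eaf is None or out.eaf is None:
                logger.warning("%s dropped: palindromic with missing eaf", exp.rsid)
                continue
            out_eaf_aligned = 1.0 - out.eaf if swapped else out.eaf
            ambiguous = (lo <= exp.eaf <= hi) or (lo <= out_eaf_aligned <= hi)
            opposite_sides = (exp.eaf - 0.5) * (out_eaf_aligned - 0.5) < 0
            if ambiguous or opposite_sides:
                logger.warning(
                    "%s dropped: palindromic with ambiguous eaf (%.3f vs %.3f)",
                    exp.rsid, exp.eaf, out_eaf_aligned,
                )
                continue
        if exp.beta == 0:
            logger.warning("%s dropped: zero exposure effect", exp.rsid)
            continue
        beta_out = -out.beta if swapped else out.beta
        instruments.append(
            HarmonizedInstrument(
                rsid=exp.rsid,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=beta_out,
                se_out=out.se,
                effect_allele=exp.effect_allele,
                eaf=exp.eaf,
                pval_exp=exp.pval,
                pval_out=out.pval,
                flipped=bool(swapped),
                palindromic=palindromic,
            )
        )

    if not instruments:
        raise HarmonizationError("all shared SNPs were dropped during harmonization")
    return InstrumentSet(
        exposure_name=exposure_name,
        outcome_name=outcome_name,
        instruments=tuple(instruments),
        provenance={"palindromic_eaf_window": palindromic_eaf_window},
    )


def filter_instruments(s: InstrumentSet, p_threshold: float = 5e-8) -> InstrumentSet:
    """Retain instruments whose exposure association passes genome-wide significance.

    The conventional instrument-selection threshold is p < 5e-8. When an
    instrument carries no stored exposure p-value it is recomputed as the
    two-sided normal tail of beta_exp/se_exp, keeping the filter total.
    May return an empty selection; downstream estimators reject empties.
    """
    if not (0.0 < p_threshold <= 1.0):
        raise ConfigurationError("p_threshold must lie in (0, 1]")
    kept = tuple(i for i in s.instruments if i.exposure_pval() < p_threshold)
    if not kept:
        logger.warning("no instruments pass p < %g", p_threshold)
    return InstrumentSet(
        s.exposure_name, s.outcome_name, kept, {**s.provenance, "p_threshold": p_threshold}
    )


FIXTURE_RESOURCE = "waist_chd_instruments.tsv"


def load_waist_chd_instruments() -> InstrumentSet:
    """The bundled 46-SNP waist-circumference → coronary-heart-disease instrument set.

    Exposure effects are per-allele waist-circumference associations in SD
    units (GIANT); outcome effects are log-odds of coronary heart disease
    (CARDIoGRAMplusC4D). The published table reports both studies on a shared
    effect allele, so the set loads pre-harmonized; it prints only the effect
    allele, so ``other_allele`` is unknown. Instruments were selected at
    p < 5e-8 with pairwise linkage disequilibrium r² < 0.1 against a reference
    panel (recorded here as provenance only; no clumping is performed by this
    package).
    """
    ref = resources.files("mrkit.data").joinpath(FIXTURE_RESOURCE)
    df = pd.read_csv(io.StringIO(ref.read_text(encoding="utf-8")), sep="\t")
    instruments = tuple(
        HarmonizedInstrument(
            rsid=row.rsid,
            beta_exp=row.beta_exp,
            se_exp=row.se_exp,
            beta_out=row.beta_out,
            se_out=row.se_out,
            effect_allele=row.ea,
            eaf=row.eaf,
            pval_exp=row.pval_exp,
            pval_out=row.pval_out,
        )
        for row in df.itertuples()
    )
    return InstrumentSet(
        exposure_name="waist_circumference",
        outcome_name="coronary_heart_disease",
        instruments=instruments,
        provenance={
            "exposure_study": "GIANT (n=224,459; WC in SD units, 1 SD = 12.5 cm)",
            "outcome_study": "CARDIoGRAMplusC4D (60,801 cases / 123,504 controls)",
            "selection": "p < 5e-8; LD r^2 < 0.1 (applied upstream, recorded only)",
        },
    )
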