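"""Instrument selection for ECG-interval Mendelian-randomisation analyses.

Variants reaching genome-wide significance for an ECG interval are pruned to
approximate linkage-equilibrium (greedy p-value clumping within a physical
window), harmonised against outcome summary statistics so that the coded
allele is always the interval-lengthening allele, and optionally restricted
to variants annotated to ion-channel genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

GENOME_WIDE_SIGNIFICANCE = 5e-8
CLUMP_R2_DEFAULT = 0.01
CLUMP_WINDOW_BP_DEFAULT = 250_000

#: effect-allele frequency window in which A/T and C/G variants are
#: strand-ambiguous and dropped during harmonisation
PALINDROME_EAF_WINDOW = (0.42, 0.58)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: columns of the tab-separated variant-weight table
VARIANT_TABLE_COLUMNS = [
    "variant_id",
    "chromosome",
    "base_pair_location",
    "effect_allele",
    "other_allele",
    "effect_allele_frequency",
    "beta",
    "standard_error",
    "p_value",
]


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNV with its published per-allele effect on an ECG interval.

    ``beta_exposure`` is in milliseconds per copy of ``effect_allele``.
    """

    id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta_exposure: float
    se_exposure: float
    p_exposure: float
    gene_annotation: Optional[str] = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.id}: identical alleles")
        if self.se_exposure <= 0:
            raise ValueError(f"{self.id}: se_exposure must be positive")
        if not (0.0 < self.p_exposure <= 1.0):
            raise ValueError(f"{self.id}: p_exposure must lie in (0, 1]")

    @property
    def is_palindromic(self) -> bool:
        return _COMPLEMENT.get(self.effect_allele) == self.other_allele


@dataclass(frozen=True)
class SummaryPair:
    """Harmonised per-variant exposure/outcome effect pair for two-sample MR.

    After harmonisation ``variant.beta_exposure >= 0`` (coded to the
    lengthening allele) and ``beta_outcome`` is the log odds ratio per copy
    of the same allele.
    """

    variant: VariantRecord
    beta_outcome: float
    se_outcome: float
    harmonised: bool = False

    @property
    def beta_exposure(self) -> float:
        return self.variant.beta_exposure

    @property
    def se_exposure(self) -> float:
        return self.variant.se_exposure


def gw_significance_filter(
    variants: Sequence[VariantRecord],
    threshold: float = GENOME_WIDE_SIGNIFICANCE,
) -> list[VariantRecord]:
    """Retain variants with exposure p-value strictly below ``threshold``.

    Order is preserved. The default is the conventional genome-wide
    significance level 5e-8; the comparison is strict, so a variant with
    p exactly equal to the threshold is removed.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    kept = [v for v in variants if v.p_exposure < threshold]
    if not kept:
        logger.warning("significance filter at %.3g retained no variants", threshold)
    return kept


LDProvider = Callable[[VariantRecord, VariantRecord], Optional[float]]


def ld_clump(
    variants: Sequence[VariantRecord],
    ld: LDProvider,
    r2_threshold: float = CLUMP_R2_DEFAULT,
    window_bp: int = CLUMP_WINDOW_BP_DEFAULT,
) -> list[VariantRecord]:
    """Greedy LD clumping seeded by ascending exposure p-value.

    Candidates are visited in ascending ``p_exposure`` order; a candidate is
    discarded when an already-selected variant on the same chromosome lies
    within ``window_bp`` base pairs and has pairwise r² at or above
    ``r2_threshold``. A missing r² for an in-window pair is treated as
    dependence (r² = 1) and logged — the conservative choice. Output order
    follows the input order of the survivors.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2_threshold must lie in (0, 1]")
    order = sorted(range(len(variants)), key=lambda i: (variants[i].p_exposure, i))
    selected_idx: list[int] = []
    for i in order:
        cand = variants[i]
        independent = True
        for j in selected_idx:
            kept = variants[j]
            if kept.chromosome != cand.chromosome:
                continue
            if abs(kept.position - cand.position) > window_bp:
                continue
            r2 = ld(kept, cand)
            if r2 is None:
                logger.warning(
                    "missing r2 for in-window pair (%s, %s); treating as dependent",
                    kept.id, cand.id,
                )
                r2 = 1.0
            if not (0.0 <= r2 <= 1.0):
                raise ValueError(f"r2 for ({kept.id}, {cand.id}) outside [0, 1]")
            if r2 >= r2_threshold:
                independent = False
                break
        if independent:
            selected_idx.append(i)
    selected_idx.sort()
    return [variants[i] for i in selected_idx]


def _orient_to_lengthening_allele(variant: VariantRecord, beta_outcome: float):
    """Flip the coded allele so the exposure effect is non-negative."""
    if variant.beta_exposure >= 0:
        return variant, beta_outcome
    flipped = replace(
        variant,
        effect_allele=variant.other_allele,
        other_allele=variant.effect_allele,
        eaf=1.0 - variant.eaf,
        beta_exposure=-variant.beta_exposure,
    )
    return flipped, -beta_outcome


def harmonise(
    exposure: Sequence[VariantRecord],
    outcome_stats: Mapping[str, tuple[str, str, float, float]],
    palindrome_eaf_window: tuple[float, float] = PALINDROME_EAF_WINDOW,
) -> list[SummaryPair]:
    """Match outcome summary statistics to exposure variants allele-by-allele.

    ``outcome_stats`` maps variant id to ``(effect_allele, other_allele,
    beta, se)`` with beta a per-allele log odds ratio. Matching tries the
    direct orientation, the swapped orientation (outcome beta negated), and
    the same two after strand complementation. Palindromic variants (A/T or
    C/G) whose effect-allele frequency falls inside
    ``palindrome_eaf_window`` are ambiguous and dropped. Finally both betas
    are jointly re-signed so every pair is coded to the interval-lengthening
    allele (``beta_exposure >= 0``).

    Dropped variants are logged with a machine-readable reason code
    (``unmatched`` / ``palindrome_ambiguous`` / ``allele_mismatch``).
    """
    lo, hi = palindrome_eaf_window
    pairs: list[SummaryPair] = []
    for variant in exposure:
        rec = outcome_stats.get(variant.id)
        if rec is None:
            logger.warning("harmonise drop id=%s reason=unmatched", variant.id)
            continue
        if variant.is_palindromic and lo <= variant.eaf <= hi:
            logger.warning("harmonise drop id=%s reason=palindrome_ambiguous", variant.id)
            continue
        o_ea, o_oa, o_beta, o_se = rec
        exp_alleles = (variant.effect_allele, variant.other_allele)
        comp = tuple(_COMPLEMENT.get(a, "N") for a in exp_alleles)
        if (o_ea, o_oa) == exp_alleles or (o_ea, o_oa) == comp:
            beta_outcome = o_beta
        elif (o_oa, o_ea) == exp_alleles or (o_oa, o_ea) == comp:
            beta_outcome = -o_beta
        else:
            logger.warning("harmonise drop id=%s reason=allele_mismatch", variant.id)
            continue
        oriented, beta_outcome = _orient_to_lengthening_allele(variant, beta_outcome)
        pairs.append(
            SummaryPair(
                variant=oriented,
                beta_outcome=beta_outcome,
                se_outcome=o_se,
                harmonised=True,
            )
        )
    return pairs


def ion_channel_subset(
    variants: Sequence[VariantRecord],
    gene_list: Iterable[str],
) -> list[VariantRecord]:
    """Restrict to variants annotated to the supplied ion-channel genes.

    Weights are left untouched; an empty result is legal but logged since a
    ratio-based estimator cannot be built on fewer than two variants.
    """
    genes = {g.upper() for g in gene_list}
    kept = [
        v
        for v in variants
        if v.gene_annotation is not None and v.gene_annotation.upper() in genes
    ]
    if len(kept) < 2:
        logger.warning(
            "ion-channel subset has %d variant(s); ratio-based estimators need >= 2",
            len(kept),
        )
    return kept


# ---------------------------------------------------------------------------
# tab-separated IO


def variants_to_frame(variants: Sequence[VariantRecord]) -> pd.DataFrame:
    rows = [
        {
            "variant_id": v.id,
            "chromosome": v.chromosome,
            "base_pair_location": v.position,
            "effect_allele": v.effect_allele,
            "other_allele": v.other_allele,
            "effect_allele_frequency": v.eaf,
            "beta": v.beta_exposure,
            "standard_error": v.se_exposure,
            "p_value": v.p_exposure,
            "gene_annotation": v.gene_annotation or "",
        }
        for v in variants
    ]
    return pd.DataFrame(rows, columns=VARIANT_TABLE_COLUMNS + ["gene_annotation"])


def frame_to_variants(df: pd.DataFrame) -> list[VariantRecord]:
    out = []
    for row in df.itertuples(index=False):
        gene = getattr(row, "gene_annotation", "") or None
        if isinstance(gene, float):  # NaN from pandas
            gene = None
        out.append(
            VariantRecord(
                id=str(row.variant_id),
                chromosome=str(row.chromosome),
                position=int(row.base_pair_location),
                effect_allele=str(row.effect_allele),
                other_allele=str(row.other_allele),
                eaf=float(row.effect_allele_frequency),
                beta_exposure=float(row.beta),
                se_exposure=float(row.standard_error),
                p_exposure=float(row.p_value),
                gene_annotation=gene,
            )
        )
    return out


def write_variant_table(variants: Sequence[VariantRecord], path) -> None:
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)


def read_variant_table(path) -> list[VariantRecord]:
    return frame_to_variants(pd.read_csv(path, sep="\t", dtype={"chromosome": str}))


def write_pairs(pairs: Sequence[SummaryPair], path) -> None:
    df = variants_to_frame([p.variant for p in pairs])
    df["beta_outcome"] = [p.beta_outcome for p in pairs]
    df["se_outcome"] = [p.se_outcome for p in pairs]
    df["harmonised"] = [int(p.harmonised) for p in pairs]
    df.to_csv(path, sep="\t", index=False)


def read_pairs(path) -> list[SummaryPair]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    variants = frame_to_variants(df)
    return [
        SummaryPair(
            variant=v,
            beta_outcome=float(b),
            se_outcome=float(s),
            harmonised=bool(h),
        )
        for v, b, s, h in zip(variants, df["beta_outcome"], df["se_outcome"], df["harmonised"])
    ]
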