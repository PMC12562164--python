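"""Cohort-level aggregation of per-mutation delta-PS effects.

Summaries per cancer type (effect-class counts, delta range), per gene
(mutation burden and fraction PS-affecting, phase-separating flag),
top-|delta| mutation ranking, and the pathogenic-fraction comparison
between PS-promoting and PS-suppressing mutations.

Counts are exact partitions of the input effects; percentages are kept
exact internally and rounded only at serialization.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .mutation_effect import MutationEffect
from .ps_scoring import PSRegion


@dataclass(frozen=True)
class CancerSummary:
    """Effect-class tallies for one cancer type."""

    cancer_type: str
    n_mutations: int
    n_on_ps_protein: int
    n_positive: int
    n_negative: int
    n_aberrant: int
    n_on_ps_region: int
    delta_min: float
    delta_max: float

    @property
    def pct_affecting_all(self) -> float:
        """PS-affecting fraction with all scored mutations as denominator."""
        return (self.n_positive + self.n_negative) / self.n_mutations

    @property
    def pct_affecting_ps_protein(self) -> float | None:
        """Same numerator with mutations on PS proteins as denominator."""
        if self.n_on_ps_protein == 0:
            return None
        return (self.n_positive + self.n_negative) / self.n_on_ps_protein


@dataclass(frozen=True)
class GeneSummary:
    """Mutation burden and PS-affecting fraction for one gene."""

    gene: str
    n_mutations: int
    n_affecting: int
    is_ps_protein: bool

    @property
    def pct_affecting(self) -> float:
        return self.n_affecting / self.n_mutations


@dataclass(frozen=True)
class PathogenicFractions:
    """Pathogenic fractions among labeled positive/negative effects.

    A fraction is None (undefined, not zero) when no mutation of that
    class carries a pathogenicity label.
    """

    fraction_among_positive: float | None
    fraction_among_negative: float | None
    n_labeled_positive: int
    n_labeled_negative: int


def summarize_by_cancer(
    effects: Sequence[MutationEffect],
    regions_by_accession: Mapping[str, Sequence[PSRegion]] | None = None,
) -> list[CancerSummary]:
    """One summary per cancer type present, sorted by cancer type.

    ``regions_by_accession`` supplies the wild-type region table used to
    count mutations on phase-separating proteins; without it that count
    falls back to the per-effect ``on_ps_region`` bit (mutations elsewhere
    on a PS protein are then not counted, which is logged).
    """
    if not effects:
        return []
    if regions_by_accession is None:
        import logging

        logging.getLogger(__name__).info(
            "summarize_by_cancer: no region table supplied; n_on_ps_protein "
            "falls back to on-region mutations only"
        )
    groups: dict[str, list[MutationEffect]] = defaultdict(list)
    for e in effects:
        groups[e.mutation.cancer_type].append(e)
    summaries = []
    for cancer in sorted(groups):
        es = groups[cancer]
        deltas = [e.delta for e in es]
        if regions_by_accession is None:
            n_ps_prot = sum(e.on_ps_region for e in es)
        else:
            n_ps_prot = sum(
                bool(regions_by_accession.get(e.mutation.accession)) for e in es
            )
        summaries.append(
            CancerSummary(
                cancer_type=cancer,
                n_mutations=len(es),
                n_on_ps_protein=n_ps_prot,
                n_positive=sum(e.affect_label == "positive" for e in es),
                n_negative=sum(e.affect_label == "negative" for e in es),
                n_aberrant=sum(e.aberrant_label != "none" for e in es),
                n_on_ps_region=sum(e.on_ps_region for e in es),
                delta_min=min(deltas),
                delta_max=max(deltas),
            )
        )
    return summaries


def gene_level_stats(
    effects: Sequence[MutationEffect],
    regions_by_accession: Mapping[str, Sequence[PSRegion]],
) -> list[GeneSummary]:
    """Per-gene burden; a gene is phase-separating iff its protein has
    >= 1 wild-type PS region. Every effect's accession must have a region
    record (possibly empty)."""
    groups: dict[str, list[MutationEffect]] = defaultdict(list)
    for e in effects:
        if e.mutation.accession not in regions_by_accession:
            raise ValidationError(
                f"no region record (even empty) for accession "
                f"{e.mutation.accession!r}"
            )
        groups[e.mutation.gene].append(e)
    out = []
    for gene in sorted(groups):
        es = groups[gene]
        out.append(
            GeneSummary(
                gene=gene,
                n_mutations=len(es),
                n_affecting=sum(e.affect_label != "neutral" for e in es),
                is_ps_protein=any(
                    bool(regions_by_accession[e.mutation.accession]) for e in es
                ),
            )
        )
    return out


def top_mutations(effects: Sequence[MutationEffect], n: int) -> list[MutationEffect]:
    """Top-``n`` effects by |delta| descending; ties broken by
    (accession, position, alt_aa) lexicographically for determinism."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    ranked = sorted(
        effects,
        key=lambda e: (
            -abs(e.delta),
            e.mutation.accession,
            e.mutation.position,
            e.mutation.alt_aa,
        ),
    )
    return ranked[:n]


def pathogenic_fraction(
    effects: Sequence[MutationEffect],
    pathogenicity_labels: Mapping[tuple, str],
) -> PathogenicFractions:
    """Pathogenic fraction among labeled positive vs negative effects.

    ``pathogenicity_labels`` maps mutation keys (accession, position,
    ref, alt) to ``pathogenic`` / ``benign`` / ``ambiguous``; ambiguous
    and unlabeled mutations enter neither numerator nor denominator.
    """
    tallies = {"positive": [0, 0], "negative": [0, 0]}  # [pathogenic, labeled]
    for e in effects:
        if e.affect_label not in tallies:
            continue
        label = pathogenicity_labels.get(e.mutation.key())
        if label not in ("pathogenic", "benign"):
            continue
        tallies[e.affect_label][1] += 1
        if label == "pathogenic":
            tallies[e.affect_label][0] += 1
    pos_path, pos_n = tallies["positive"]
    neg_path, neg_n = tallies["negative"]
    return PathogenicFractions(
        fraction_among_positive=(pos_path / pos_n) if pos_n else None,
        fraction_among_negative=(neg_path / neg_n) if neg_n else None,
        n_labeled_positive=pos_n,
        n_labeled_negative=neg_n,
    )


# ---------------------------------------------------------------------------
# Serialization helpers (rounding happens only here)
# ---------------------------------------------------------------------------

def cancer_summary_frame(summaries: Sequence[CancerSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "cancer_type": s.cancer_type,
                "n_mutations": s.n_mutations,
                "n_on_ps_protein": s.n_on_ps_protein,
                "n_positive": s.n_positive,
                "n_negative": s.n_negative,
                "n_aberrant": s.n_aberrant,
                "n_on_ps_region": s.n_on_ps_region,
                "delta_min": round(s.delta_min, 4),
                "delta_max": round(s.delta_max, 4),
                "pct_affecting_all": round(100 * s.pct_affecting_all, 2),
                "pct_affecting_ps_protein": (
                    None
                    if s.pct_affecting_ps_protein is None
                    else round(100 * s.pct_affecting_ps_protein, 2)
                ),
            }
        )
    return pd.DataFrame(rows)


def gene_summary_frame(summaries: Sequence[GeneSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": s.gene,
                "n_mutations": s.n_mutations,
                "n_affecting": s.n_affecting,
                "pct_affecting": round(100 * s.pct_affecting, 2),
                "is_ps_protein": s.is_ps_protein,
            }
            for s in summaries
        ]
    )
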