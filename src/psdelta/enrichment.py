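"""Fisher's-exact-test over-representation analysis against GMT gene sets.

For each annotation set (kinase substrates, TF targets, pathways) the 2x2
table is::

                    in set    not in set
    target             a          b
    background         c          d       (background = universe \\ target)

with set membership intersected with the universe before counting. The
default alternative is one-sided "greater" (enrichment, not depletion);
p-values are Benjamini–Hochberg adjusted across exactly the tested sets.

The default universe convention upstream is "all genes with >= 1 scored
mutation" — conservative relative to a whole-genome background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io_formats import AnnotationSetCollection


@dataclass(frozen=True)
class EnrichmentResult:
    """One Fisher 2x2 outcome for one annotation set."""

    set_id: str
    a: int  # target ∩ set
    b: int  # target \ set
    c: int  # background ∩ set
    d: int  # background \ set
    odds_ratio: float
    p_value: float
    q_value: float


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    num, den = a * d, b * c
    if den > 0:
        return num / den
    return math.inf if num > 0 else math.nan


def fisher_enrichment(
    target_genes: Iterable[str],
    universe_genes: Iterable[str],
    annotation_sets: AnnotationSetCollection,
    alternative: str = "greater",
) -> list[EnrichmentResult]:
    """Fisher enrichment of ``target_genes`` within each annotation set.

    Only sets with >= 1 universe member are tested. Results are sorted by
    p ascending (ties by set id); ``q_value`` is BH-adjusted over exactly
    the tested sets.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    target = set(target_genes)
    universe = set(universe_genes)
    if not universe:
        raise ValidationError("empty universe")
    if not target:
        raise ValidationError("empty target gene list")
    outside = target - universe
    if outside:
        raise ValidationError(
            f"target genes not in universe: {sorted(outside)[:10]}"
            + ("..." if len(outside) > 10 else "")
        )

    rows: list[tuple[str, int, int, int, int, float, float]] = []
    n_target = len(target)
    n_universe = len(universe)
    for set_id, members in annotation_sets:
        in_universe = members & universe
        if not in_universe:
            continue
        a = len(target & in_universe)
        b = n_target - a
        c = len(in_universe) - a
        d = n_universe - n_target - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        rows.append((set_id, a, b, c, d, _odds_ratio(a, b, c, d), float(p)))

    q = bh_adjust([r[6] for r in rows]) if rows else np.array([])
    results = [
        EnrichmentResult(
            set_id=r[0], a=r[1], b=r[2], c=r[3], d=r[4],
            odds_ratio=r[5], p_value=r[6], q_value=float(qv),
        )
        for r, qv in zip(rows, q)
    ]
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]):
    """Results as a DataFrame sorted by q then p (for TSV output)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "set_id": r.set_id,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "q_value": r.q_value,
            }
            for r in sorted(results, key=lambda r: (r.q_value, r.p_value, r.set_id))
        ]
    )
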