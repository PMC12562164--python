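"""Shared fixtures and independent oracle helpers.

The oracles here deliberately re-derive quantities by the dumbest correct
route (full enumeration, closed forms) so they stay independent of the
library code paths they check.
"""

from __future__ import annotations

import math
import random

import numpy as np
import pytest

from psdelta.io_formats import MissenseMutation, ProteinRecord
from psdelta.mutation_effect import MutationEffect
from psdelta.ps_scoring import PRONE_RESIDUES

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: random.Random, length: int, accession: str = "P1") -> ProteinRecord:
    return ProteinRecord(accession, "".join(rng.choice(AA) for _ in range(length)))


def random_mutation(rng: random.Random, protein: ProteinRecord, sample="S1", cancer="UCEC") -> MissenseMutation:
    pos = rng.randrange(1, len(protein) + 1)
    ref = protein.sequence[pos - 1]
    alt = rng.choice([a for a in AA if a != ref])
    return MissenseMutation(sample, f"G_{protein.accession}", protein.accession, pos, ref, alt, cancer)


def prone_fraction_oracle(window: str) -> float:
    return sum(c in PRONE_RESIDUES for c in window) / len(window)


def brute_force_delta(protein: ProteinRecord, mutation: MissenseMutation, window_size: int):
    """Full-rescoring oracle: score every window of both sequences and
    average only the windows containing the mutated position.

    Returns (wt_avg, mut_avg, delta, n_windows, wt_scores, mut_scores).
    """
    seq_wt = protein.sequence
    p = mutation.position
    assert seq_wt[p - 1] == mutation.ref_aa
    seq_mut = seq_wt[: p - 1] + mutation.alt_aa + seq_wt[p:]
    L = len(seq_wt)
    w = window_size
    if L < w:
        spans = [(1, L)]
    else:
        spans = [(s, s + w - 1) for s in range(1, L - w + 2)]
    wt_scores = [prone_fraction_oracle(seq_wt[s - 1 : e]) for s, e in spans]
    mut_scores = [prone_fraction_oracle(seq_mut[s - 1 : e]) for s, e in spans]
    containing = [i for i, (s, e) in enumerate(spans) if s <= p <= e]
    wt_avg = sum(wt_scores[i] for i in containing) / len(containing)
    mut_avg = sum(mut_scores[i] for i in containing) / len(containing)
    return wt_avg, mut_avg, mut_avg - wt_avg, len(containing), wt_scores, mut_scores


def brute_force_regions(starts, scores, window_size, seq_length, cutoff):
    """Run-scanning oracle for PS region calling: walk windows one by one."""
    regions = []
    run: list[int] = []
    for i, score in enumerate(list(scores) + [None]):
        if score is not None and score >= cutoff:
            run.append(i)
            continue
        if run:
            s = starts[run[0]]
            e = min(starts[run[-1]] + window_size - 1, seq_length)
            mean = sum(scores[j] for j in run) / len(run)
            regions.append((s, e, mean))
            run = []
    return regions


def hypergeom_tail(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for X ~ Hypergeometric: closed-form tail sum over
    binomial coefficients (the one-sided Fisher 'greater' p-value)."""
    N = a + b + c + d
    K = a + c          # genes in the set
    n = a + b          # target size
    denom = math.comb(N, n)
    total = 0
    for k in range(a, min(K, n) + 1):
        total += math.comb(K, k) * math.comb(N - K, n - k)
    return total / denom


def make_effect(
    delta: float,
    *,
    sample="S1",
    gene="G1",
    accession="P1",
    position=1,
    cancer="UCEC",
    alt="G",
    affect_cutoff=0.05,
    wt_avg=0.3,
    aberrant="none",
    region_change="unchanged",
    on_ps_region=False,
    n_windows=15,
) -> MutationEffect:
    """Build a MutationEffect directly (no scoring) for aggregation tests."""
    label = "positive" if delta > affect_cutoff else "negative" if delta < -affect_cutoff else "neutral"
    ref = "A" if alt != "A" else "C"
    return MutationEffect(
        mutation=MissenseMutation(sample, gene, accession, position, ref, alt, cancer),
        wt_avg=wt_avg,
        mut_avg=wt_avg + delta,
        delta=delta,
        n_windows=n_windows,
        affect_label=label,
        aberrant_label=aberrant,
        region_change=region_change,
        on_ps_region=on_ps_region,
    )


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20260928)


@pytest.fixture
def np_rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
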