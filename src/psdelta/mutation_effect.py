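"""Delta-PS scores for missense mutations and their effect classification.

For a mutation at residue ``p`` of a length-``L`` protein, the windows
*containing* the mutated residue are those starting in
``max(1, p - w + 1) .. min(p, L - w + 1)`` (a single full window when
``L < w``). The wild-type and mutant average scores are the means of the
scorer's scores over exactly those containment windows; the delta-PS
score is ``mut_avg - wt_avg``, so a positive delta is PS-promoting.

Classification layers on top of the delta:

* ``affect_label`` — positive/negative/neutral at a strict |delta| > 0.05
  cutoff by default;
* ``aberrant_label`` — gain/loss when the local average crosses the
  region cutoff (0.5208) between wild type and mutant;
* ``region_change`` — created/lost/extended/contracted/unchanged, from
  the residue coverage of called PS regions near the mutation;
* ``on_ps_region`` — whether the mutated residue lies inside a wild-type
  PS region.

Because every registered scorer is a pure function of window content,
windows outside the containment range are identical between wild type and
mutant; the mutant track is therefore the wild-type track with only the
containment window scores recomputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .io_formats import MissenseMutation, ProteinRecord
from .ps_scoring import (
    DEFAULT_REGION_CUTOFF,
    DEFAULT_WINDOW,
    PSRegion,
    ScorerSpec,
    WindowScoreTrack,
    call_ps_regions,
    enumerate_windows,
    get_scorer,
    score_windows,
)

logger = logging.getLogger(__name__)

#: Default |delta| threshold above which a mutation is PS-affecting.
DEFAULT_AFFECT_CUTOFF = 0.05


@dataclass(frozen=True)
class EffectConfig:
    """Cutoffs and scorer choice for delta-PS computation.

    ``aberrant_rule`` selects how threshold-crossing is judged:
    ``"local_average"`` (default) compares the containment-window averages
    against the region cutoff; ``"protein_flip"`` compares whole-protein
    phase-separating status (>= 1 called region) before and after.
    """

    scorer: str = "prone_fraction"
    window_size: int = DEFAULT_WINDOW
    region_cutoff: float = DEFAULT_REGION_CUTOFF
    affect_cutoff: float = DEFAULT_AFFECT_CUTOFF
    aberrant_rule: str = "local_average"

    def __post_init__(self) -> None:
        if self.affect_cutoff <= 0:
            raise ValidationError("affect_cutoff must be > 0")
        if self.aberrant_rule not in ("local_average", "protein_flip"):
            raise ValidationError(
                f"unknown aberrant_rule {self.aberrant_rule!r}"
            )

    def scorer_spec(self) -> ScorerSpec:
        return ScorerSpec(
            name=self.scorer,
            window_size=self.window_size,
            region_cutoff=self.region_cutoff,
        )


@dataclass(frozen=True)
class MutationEffect:
    """Wild-type/mutant average PS scores and the delta for one mutation."""

    mutation: MissenseMutation
    wt_avg: float
    mut_avg: float
    delta: float
    n_windows: int
    affect_label: str
    aberrant_label: str
    region_change: str
    on_ps_region: bool


def apply_mutation(protein: ProteinRecord, mutation: MissenseMutation) -> str:
    """Return the mutant sequence; validates position and reference residue."""
    L = len(protein)
    p = mutation.position
    if not 1 <= p <= L:
        raise ValidationError(
            f"{protein.accession} {mutation.hgvs_p}: position {p} outside 1..{L}"
        )
    observed = protein.sequence[p - 1]
    if observed != mutation.ref_aa:
        raise ValidationError(
            f"{protein.accession} {mutation.hgvs_p}: expected reference "
            f"{mutation.ref_aa!r} at position {p}, sequence has {observed!r}"
        )
    return protein.sequence[: p - 1] + mutation.alt_aa + protein.sequence[p:]


def mutation_window_starts(position: int, seq_length: int, window_size: int) -> range:
    """1-based start positions of all windows containing ``position``.

    When ``seq_length < window_size`` the single full-length window (start
    1) is the only window.
    """
    if not 1 <= position <= seq_length:
        raise ValidationError(f"position {position} outside 1..{seq_length}")
    if seq_length < window_size:
        return range(1, 2)
    lo = max(1, position - window_size + 1)
    hi = min(position, seq_length - window_size + 1)
    return range(lo, hi + 1)


def _coverage(regions: Sequence[PSRegion], lo: int, hi: int) -> int:
    """Total residues covered by regions overlapping [lo, hi].

    Overlapping regions count their full extent (region calling already
    guarantees disjointness within one protein).
    """
    total = 0
    for r in regions:
        if r.end >= lo and r.start <= hi:
            total += r.length
    return total


def classify_effect(
    wt_avg: float,
    mut_avg: float,
    wt_regions: Sequence[PSRegion],
    mut_regions: Sequence[PSRegion],
    position: int,
    config: EffectConfig,
) -> tuple[str, str, str, bool]:
    """Return (affect_label, aberrant_label, region_change, on_ps_region)."""
    delta = mut_avg - wt_avg
    if delta > config.affect_cutoff:
        affect = "positive"
    elif delta < -config.affect_cutoff:
        affect = "negative"
    else:
        affect = "neutral"

    cutoff = config.region_cutoff
    if config.aberrant_rule == "protein_flip":
        wt_ps, mut_ps = bool(wt_regions), bool(mut_regions)
        aberrant = "gain" if (not wt_ps and mut_ps) else "loss" if (wt_ps and not mut_ps) else "none"
    else:
        if wt_avg < cutoff <= mut_avg:
            aberrant = "gain"
        elif mut_avg < cutoff <= wt_avg:
            aberrant = "loss"
        else:
            aberrant = "none"

    w = config.window_size
    lo, hi = position - w + 1, position + w - 1
    wt_cov = _coverage(wt_regions, lo, hi)
    mut_cov = _coverage(mut_regions, lo, hi)
    if wt_cov == 0 and mut_cov > 0:
        region_change = "created"
    elif wt_cov > 0 and mut_cov == 0:
        region_change = "lost"
    elif mut_cov > wt_cov:
        region_change = "extended"
    elif mut_cov < wt_cov:
        region_change = "contracted"
    else:
        region_change = "unchanged"

    on_ps_region = any(r.contains(position) for r in wt_regions)
    return affect, aberrant, region_change, on_ps_region


def _mutant_track(
    wt_track: WindowScoreTrack,
    mutant_seq: str,
    position: int,
    config: EffectConfig,
) -> tuple[WindowScoreTrack, np.ndarray]:
    """Mutant score track: wild-type scores with the containment windows
    rescored on the mutant sequence. Returns (track, containment indices)."""
    scorer = get_scorer(config.scorer)
    w = config.window_size
    L = len(mutant_seq)
    starts = mutation_window_starts(position, L, w)
    idx = np.array([s - 1 for s in starts], dtype=int)
    if L < w:
        windows = [mutant_seq]
    else:
        windows = [mutant_seq[s - 1 : s - 1 + w] for s in starts]
    new_scores = wt_track.scores.copy()
    new_scores[idx] = scorer.score_many(windows)
    track = WindowScoreTrack(
        accession=wt_track.accession,
        window_size=w,
        seq_length=L,
        starts=wt_track.starts,
        scores=new_scores,
    )
    return track, idx


def delta_ps(
    protein: ProteinRecord,
    mutation: MissenseMutation,
    config: EffectConfig | None = None,
    *,
    wt_track: WindowScoreTrack | None = None,
    wt_regions: Sequence[PSRegion] | None = None,
) -> MutationEffect:
    """Delta-PS score and classification for one mutation.

    ``wt_track``/``wt_regions`` may be passed to reuse a cached wild-type
    scoring of the same protein under the same config (batch path); they
    are recomputed when absent.
    """
    config = config or EffectConfig()
    mutant_seq = apply_mutation(protein, mutation)
    if wt_track is None:
        wt_track = score_windows(protein, config.scorer_spec())
    if wt_regions is None:
        wt_regions = call_ps_regions(wt_track, config.region_cutoff)

    mut_track, idx = _mutant_track(wt_track, mutant_seq, mutation.position, config)
    mut_regions = call_ps_regions(mut_track, config.region_cutoff)

    wt_avg = float(np.mean(wt_track.scores[idx]))
    mut_avg = float(np.mean(mut_track.scores[idx]))
    delta = mut_avg - wt_avg

    affect, aberrant, region_change, on_ps = classify_effect(
        wt_avg, mut_avg, wt_regions, mut_regions, mutation.position, config
    )
    return MutationEffect(
        mutation=mutation,
        wt_avg=wt_avg,
        mut_avg=mut_avg,
        delta=delta,
        n_windows=len(idx),
        affect_label=affect,
        aberrant_label=aberrant,
        region_change=region_change,
        on_ps_region=on_ps,
    )


def delta_ps_batch(
    proteins: Mapping[str, ProteinRecord] | Iterable[ProteinRecord],
    mutations: Sequence[MissenseMutation],
    config: EffectConfig | None = None,
    *,
    skip_unknown: bool = False,
) -> list[MutationEffect]:
    """Delta-PS for many mutations, caching one wild-type scoring per protein.

    ``skip_unknown=True`` drops (and logs) mutations whose accession has no
    sequence instead of raising.
    """
    config = config or EffectConfig()
    if not isinstance(proteins, Mapping):
        proteins = {p.accession: p for p in proteins}
    tracks: dict[str, WindowScoreTrack] = {}
    regions: dict[str, list[PSRegion]] = {}
    effects: list[MutationEffect] = []
    n_skipped = 0
    for mutation in mutations:
        protein = proteins.get(mutation.accession)
        if protein is None:
            if skip_unknown:
                n_skipped += 1
                continue
            raise ValidationError(
                f"no sequence for accession {mutation.accession!r}"
            )
        if mutation.accession not in tracks:
            tracks[mutation.accession] = score_windows(protein, config.scorer_spec())
            regions[mutation.accession] = call_ps_regions(
                tracks[mutation.accession], config.region_cutoff
            )
        effects.append(
            delta_ps(
                protein,
                mutation,
                config,
                wt_track=tracks[mutation.accession],
                wt_regions=regions[mutation.accession],
            )
        )
    if n_skipped:
        logger.info("delta_ps_batch: skipped %d mutation(s) without sequence", n_skipped)
    return effects
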