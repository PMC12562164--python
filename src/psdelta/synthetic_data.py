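"""Seeded synthetic cohorts with planted ground truth.

Every generator is a pure function of its parameters and seed, so reruns
are byte-identical. Together the generators emulate the inputs of a
pan-cancer mutation/phase-separation analysis without any download:

* proteomes whose planted segments are composition-biased toward the
  PS-prone residue set (so the reference ``prone_fraction`` scorer, and
  any composition-aware classifier, can find them);
* missense mutations with planted positive / negative / neutral delta-PS
  effects, verified by scoring at generation time;
* annotation gene sets with a chosen number of planted enriched sets;
* clinical outcomes whose hazard depends on a planted log-hazard-ratio
  ``beta`` on the patient's true fraction of PS-promoting mutations.

The amino-acid background outside the prone set is uniform over the 12
non-prone letters — a deliberate simplification (see the methods note).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .io_formats import (
    AnnotationSetCollection,
    ClinicalRecord,
    MissenseMutation,
    ProteinRecord,
)
from .ps_scoring import PRONE_RESIDUES, DEFAULT_WINDOW
from .mutation_effect import DEFAULT_AFFECT_CUTOFF

PRONE = tuple(sorted(PRONE_RESIDUES))
NON_PRONE = tuple(sorted(set("ACDEFGHIKLMNPQRSTVWY") - PRONE_RESIDUES))

DEFAULT_CANCER_TYPES = ("UCEC", "SKCM", "COAD", "LUAD")

_REJECTION_CAP = 10_000


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside every generated dataset."""

    seed: int
    params: dict = field(default_factory=dict)
    #: accession -> (start, end) of the planted PS-prone segment, or None.
    segments: dict | None = None
    #: per-mutation planted effect class, aligned with the mutation list.
    mutation_classes: list | None = None
    #: set ids generated with above-chance target-gene inclusion.
    enriched_set_ids: list | None = None
    #: planted log hazard ratio on the true percent_mut.
    beta: float | None = None
    #: sample_id -> true fraction of PS-promoting mutations.
    percent_mut_true: dict | None = None

    def merged(self, other: "SyntheticTruth") -> "SyntheticTruth":
        """Combine truth fragments from successive generators."""
        out = dataclasses.replace(self)
        out.params = {**self.params, **other.params}
        for name in ("segments", "mutation_classes", "enriched_set_ids", "beta", "percent_mut_true"):
            if getattr(other, name) is not None:
                setattr(out, name, getattr(other, name))
        return out

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        with Path(path).open("w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# Proteome
# ---------------------------------------------------------------------------

def generate_proteome(
    n_proteins: int = 200,
    length_range: tuple[int, int] = (80, 250),
    segment_rate: float = 0.7,
    prone_in: float = 0.9,
    prone_out: float = 0.1,
    seed: int = 0,
    *,
    segment_length_range: tuple[int, int] = (30, 60),
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Proteins with at most one planted PS-prone segment each.

    Each protein independently carries a planted segment with probability
    ``segment_rate``; inside the segment residues are prone with
    probability ``prone_in``, outside with ``prone_out``. Segment bounds
    (1-based inclusive) are recorded in the truth.
    """
    if not 0.0 <= prone_out < prone_in <= 1.0:
        raise ValidationError("need 0 <= prone_out < prone_in <= 1")
    if segment_length_range[0] > length_range[0]:
        raise ValidationError(
            f"shortest protein ({length_range[0]}) cannot hold the shortest "
            f"planted segment ({segment_length_range[0]})"
        )
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    segments: dict[str, tuple[int, int] | None] = {}
    for i in range(n_proteins):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        has_segment = bool(rng.random() < segment_rate)
        seg = None
        if has_segment:
            seg_len = int(rng.integers(segment_length_range[0], min(segment_length_range[1], L) + 1))
            start = int(rng.integers(1, L - seg_len + 2))
            seg = (start, start + seg_len - 1)
        letters = []
        for pos in range(1, L + 1):
            inside = seg is not None and seg[0] <= pos <= seg[1]
            p = prone_in if inside else prone_out
            if rng.random() < p:
                letters.append(PRONE[int(rng.integers(len(PRONE)))])
            else:
                letters.append(NON_PRONE[int(rng.integers(len(NON_PRONE)))])
        accession = f"SYN{i:04d}"
        records.append(ProteinRecord(accession=accession, sequence="".join(letters)))
        segments[accession] = seg
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_proteins": n_proteins,
            "length_range": length_range,
            "segment_rate": segment_rate,
            "prone_in": prone_in,
            "prone_out": prone_out,
            "segment_length_range": segment_length_range,
        },
        segments=segments,
    )
    return records, truth


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

def _is_prone(letter: str) -> bool:
    return letter in PRONE_RESIDUES


def generate_mutations(
    proteome: Sequence[ProteinRecord],
    truth: SyntheticTruth | None,
    n_mutations: int = 2000,
    class_mix: tuple[float, float, float] = (0.04, 0.06, 0.90),
    seed: int = 0,
    *,
    n_samples: int = 240,
    cancer_types: Sequence[str] = DEFAULT_CANCER_TYPES,
    window_size: int = DEFAULT_WINDOW,
    affect_cutoff: float = DEFAULT_AFFECT_CUTOFF,
) -> tuple[list[MissenseMutation], SyntheticTruth]:
    """Missense mutations with planted (positive, negative, neutral)
    delta-PS classes in the given mix.

    A positive mutation substitutes a non-prone residue with a prone one
    (every containment window gains 1/w, so delta = +1/w > cutoff for the
    default w = 15); a negative mutation does the reverse; a neutral one
    preserves prone status. Each planted class is verified by scoring at
    generation time. Samples are assigned uniformly; each sample belongs
    to one cancer type (round-robin).
    """
    from .mutation_effect import EffectConfig, delta_ps  # local: avoid cycle at import
    from .ps_scoring import call_ps_regions, score_windows

    if abs(sum(class_mix) - 1.0) > 1e-9:
        raise ValidationError("class_mix proportions must sum to 1")
    if 1.0 / window_size <= affect_cutoff:
        raise ValidationError(
            "planted positive/negative classes need 1/window_size > affect_cutoff"
        )
    rng = np.random.default_rng(seed)
    config = EffectConfig(window_size=window_size, affect_cutoff=affect_cutoff)

    samples = [f"SAMPLE{j:04d}" for j in range(n_samples)]
    sample_cancer = {s: cancer_types[j % len(cancer_types)] for j, s in enumerate(samples)}

    classes = rng.choice(
        ["positive", "negative", "neutral"], size=n_mutations, p=list(class_mix)
    )
    # one wild-type scoring per protein, reused for every candidate check
    tracks = {p.accession: score_windows(p, config.scorer_spec()) for p in proteome}
    regions = {
        acc: call_ps_regions(t, config.region_cutoff) for acc, t in tracks.items()
    }
    mutations: list[MissenseMutation] = []
    planted: list[str] = []
    for k in range(n_mutations):
        wanted = str(classes[k])
        for _try in range(_REJECTION_CAP):
            protein = proteome[int(rng.integers(len(proteome)))]
            pos = int(rng.integers(1, len(protein) + 1))
            ref = protein.sequence[pos - 1]
            if wanted == "positive":
                if _is_prone(ref):
                    continue
                alt = PRONE[int(rng.integers(len(PRONE)))]
            elif wanted == "negative":
                if not _is_prone(ref):
                    continue
                alt = NON_PRONE[int(rng.integers(len(NON_PRONE)))]
            else:
                pool = PRONE if _is_prone(ref) else NON_PRONE
                pool = tuple(a for a in pool if a != ref)
                alt = pool[int(rng.integers(len(pool)))]
            sample = samples[int(rng.integers(n_samples))]
            mutation = MissenseMutation(
                sample_id=sample,
                gene=f"G_{protein.accession}",
                accession=protein.accession,
                position=pos,
                ref_aa=ref,
                alt_aa=alt,
                cancer_type=sample_cancer[sample],
            )
            effect = delta_ps(
                protein,
                mutation,
                config,
                wt_track=tracks[protein.accession],
                wt_regions=regions[protein.accession],
            )
            ok = (
                (wanted == "positive" and effect.delta > affect_cutoff)
                or (wanted == "negative" and effect.delta < -affect_cutoff)
                or (wanted == "neutral" and abs(effect.delta) <= affect_cutoff)
            )
            if ok:
                mutations.append(mutation)
                planted.append(wanted)
                break
        else:
            raise ValidationError(
                f"could not realize a {wanted!r} mutation after "
                f"{_REJECTION_CAP} tries; check proteome composition"
            )

    new_truth = SyntheticTruth(
        seed=seed,
        params={
            "n_mutations": n_mutations,
            "class_mix": class_mix,
            "n_samples": n_samples,
            "cancer_types": tuple(cancer_types),
        },
        mutation_classes=planted,
    )
    if truth is not None:
        new_truth = truth.merged(new_truth)
    return mutations, new_truth


def true_percent_mut(
    mutations: Sequence[MissenseMutation], planted_classes: Sequence[str]
) -> dict[str, float]:
    """Per-sample true fraction of PS-promoting (planted positive) mutations."""
    pos: dict[str, int] = {}
    tot: dict[str, int] = {}
    for m, cls in zip(mutations, planted_classes):
        tot[m.sample_id] = tot.get(m.sample_id, 0) + 1
        if cls == "positive":
            pos[m.sample_id] = pos.get(m.sample_id, 0) + 1
    return {s: pos.get(s, 0) / n for s, n in tot.items()}


# ---------------------------------------------------------------------------
# Annotation sets
# ---------------------------------------------------------------------------

def generate_annotations(
    genes: Sequence[str],
    n_sets: int = 50,
    planted_ids: Sequence[str] = ("SET00", "SET01", "SET02"),
    relative_risk: float = 5.0,
    seed: int = 0,
    *,
    target_genes: Sequence[str] = (),
    base_rate: float = 0.1,
) -> tuple[AnnotationSetCollection, SyntheticTruth]:
    """Annotation sets with planted target-gene enrichment.

    Non-planted sets include each gene independently with ``base_rate``;
    planted sets include target genes with ``min(1, relative_risk *
    base_rate)`` and all other genes with ``base_rate``. With
    ``relative_risk = 1`` no set is enriched beyond chance.
    """
    if relative_risk < 1:
        raise ValidationError("relative_risk must be >= 1")
    set_ids = [f"SET{j:02d}" for j in range(n_sets)]
    unknown = set(planted_ids) - set(set_ids)
    if unknown:
        raise ValidationError(f"planted_ids not among generated set ids: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    target = set(target_genes)
    p_target = min(1.0, relative_risk * base_rate)
    sets: dict[str, frozenset[str]] = {}
    for sid in set_ids:
        planted = sid in set(planted_ids)
        members: set[str] = set()
        for _try in range(_REJECTION_CAP):
            members = {
                g
                for g in genes
                if rng.random() < (p_target if (planted and g in target) else base_rate)
            }
            if members:
                break
        if not members:
            raise ValidationError(f"could not populate set {sid}")
        sets[sid] = frozenset(members)
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_sets": n_sets,
            "relative_risk": relative_risk,
            "base_rate": base_rate,
            "n_genes": len(genes),
            "n_target_genes": len(target),
        },
        enriched_set_ids=list(planted_ids) if relative_risk > 1 else [],
    )
    return AnnotationSetCollection(sets=sets), truth


# ---------------------------------------------------------------------------
# Clinical cohort
# ---------------------------------------------------------------------------

def generate_cohort(
    patients: int | Sequence[str],
    mutation_assignment: Mapping[str, Sequence[str]] | None = None,
    beta: float = 1.0,
    baseline_hazard: float = 0.001,
    censor_rate: float = 0.3,
    seed: int = 0,
    *,
    cancer_types: Sequence[str] = DEFAULT_CANCER_TYPES,
    age_beta: float = 0.01,
    sex_beta: float = 0.1,
    stage_beta: float = 0.2,
    stage_missing_rate: float = 0.0,
) -> tuple[list[ClinicalRecord], SyntheticTruth]:
    """Clinical outcomes with a planted coefficient on true percent_mut.

    Event times are exponential with hazard ``baseline_hazard *
    exp(beta * percent_mut + age_beta * (age - 60) + sex_beta * sex +
    stage_beta * (stage - 2))``; censoring is an independent exponential
    calibrated so roughly ``censor_rate`` of subjects are censored.

    ``patients`` is either a number of patients (percent_mut then drawn
    from a sparse, polarized profile: 1 + Poisson(1) scored mutations per
    patient, each PS-promoting with a patient-specific Beta(0.5, 0.5)
    probability, so patients tend to carry predominantly promoting or
    predominantly non-promoting profiles and percent_mut is well spread
    over [0, 1] — the regime in which the planted coefficient is
    identifiable at cohort scale) or a list of sample ids whose planted
    classes come from ``mutation_assignment`` (sample_id -> sequence of
    "positive"/"negative"/"neutral").
    """
    if not 0.0 <= censor_rate < 1.0:
        raise ValidationError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    if isinstance(patients, int):
        sample_ids = [f"SAMPLE{j:04d}" for j in range(patients)]
        n_mut = 1 + rng.poisson(1.0, size=len(sample_ids))
        p_pos = rng.beta(0.5, 0.5, size=len(sample_ids))
        n_pos = rng.binomial(n_mut, p_pos)
        percent_mut = {s: n_pos[j] / n_mut[j] for j, s in enumerate(sample_ids)}
        n_scored = {s: int(n_mut[j]) for j, s in enumerate(sample_ids)}
    else:
        sample_ids = list(patients)
        if mutation_assignment is None:
            raise ValidationError(
                "mutation_assignment required when patients are given as ids"
            )
        percent_mut = {}
        n_scored = {}
        for s in sample_ids:
            classes = list(mutation_assignment.get(s, []))
            n_scored[s] = len(classes)
            percent_mut[s] = (
                sum(c == "positive" for c in classes) / len(classes) if classes else 0.0
            )

    n = len(sample_ids)
    age = np.clip(rng.normal(62.0, 10.0, size=n), 30.0, 90.0)
    sex = rng.integers(0, 2, size=n)
    stage = rng.choice([1, 2, 3, 4], size=n, p=[0.3, 0.3, 0.25, 0.15])
    stage_missing = rng.random(n) < stage_missing_rate
    pm = np.array([percent_mut[s] for s in sample_ids])
    tmb = np.array([n_scored[s] for s in sample_ids], dtype=float)

    hazard = baseline_hazard * np.exp(
        beta * pm + age_beta * (age - 60.0) + sex_beta * sex + stage_beta * (stage - 2)
    )
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        censor_hazard = float(np.mean(hazard)) * censor_rate / (1.0 - censor_rate)
        censor_time = rng.exponential(1.0 / censor_hazard, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    records = [
        ClinicalRecord(
            sample_id=s,
            time=float(time[j]),
            event=int(event[j]),
            age=float(age[j]),
            sex=int(sex[j]),
            tmb=float(tmb[j]),
            stage=None if stage_missing[j] else int(stage[j]),
            cancer_type=cancer_types[j % len(cancer_types)],
        )
        for j, s in enumerate(sample_ids)
    ]
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_patients": n,
            "baseline_hazard": baseline_hazard,
            "censor_rate": censor_rate,
            "age_beta": age_beta,
            "sex_beta": sex_beta,
            "stage_beta": stage_beta,
        },
        beta=beta,
        percent_mut_true={s: float(percent_mut[s]) for s in sample_ids},
    )
    return records, truth
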