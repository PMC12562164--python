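"""Per-window phase-separation (PS) propensity scoring and region calling.

A protein of length ``L`` is split into all length-``w`` windows at step 1
(``w`` = 15 by default); a protein shorter than the window is scored as a
single full-length window. A registered scorer maps each window to a PS
score in [0, 1]. Maximal runs of consecutive windows scoring at or above
the region cutoff (0.5208 by default) are called PS regions; a protein
with at least one region is a phase-separating protein.

Two scorers ship with the package:

``prone_fraction``
    A deterministic composition scorer: the fraction of window residues
    drawn from the PS-prone set {G, S, Q, N, Y, F, P, R} — glycine/serine
    spacers, polar Q/N, aromatics and arginine, the residue classes that
    dominate low-complexity, condensate-forming sequences. It is the
    reference scorer for all delta-score arithmetic and for synthetic-data
    self-checks.

``train_scorer``
    A supervised classifier (random forest over 23 window-composition
    features) trained on labelled PS-positive/PS-negative peptides and
    registered under a caller-chosen name; it returns the class-1
    probability per window. Structure-based feature pipelines (secondary
    structure, prion-likeness, disorder predictors) are deliberately out
    of scope: the feature set is pure sequence composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .errors import InputError, ValidationError
from .io_formats import ProteinRecord

logger = logging.getLogger(__name__)

#: Residues counted as phase-separation prone by the composition scorer.
PRONE_RESIDUES = frozenset("GSQNYFPR")

#: Default sliding-window length (residues).
DEFAULT_WINDOW = 15

#: Default score cutoff at which a window is called part of a PS region.
DEFAULT_REGION_CUTOFF = 0.5208

_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_CHARGED = frozenset("DEKR")
_AROMATIC = frozenset("FWY")

#: Names of the 23 composition features used by the trainable scorer.
FEATURE_NAMES = tuple(f"freq_{aa}" for aa in _AA_ORDER) + (
    "prone_fraction",
    "charged_fraction",
    "aromatic_fraction",
)

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ScorerSpec:
    """Configuration naming a scorer and its window/cutoff contract."""

    name: str = "prone_fraction"
    window_size: int = DEFAULT_WINDOW
    region_cutoff: float = DEFAULT_REGION_CUTOFF
    parameters: Mapping[str, object] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValidationError("window_size must be >= 1")
        if not 0.0 <= self.region_cutoff <= 1.0:
            raise ValidationError("region_cutoff must lie in [0, 1]")


@dataclass(frozen=True)
class WindowScoreTrack:
    """Per-window PS scores for one protein under one scorer.

    ``starts`` are 1-based window start positions (consecutive from 1);
    window ``i`` covers residues ``starts[i] .. min(starts[i] + window_size
    - 1, seq_length)`` — the upper clip only matters for proteins shorter
    than the window, which yield a single full-length window.
    """

    accession: str
    window_size: int
    seq_length: int
    starts: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        expected = max(1, self.seq_length - self.window_size + 1)
        if len(self.starts) != expected or len(self.scores) != expected:
            raise ValidationError(
                f"track {self.accession}: expected {expected} windows, "
                f"got {len(self.scores)}"
            )
        if len(self.scores) and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValidationError(f"track {self.accession}: scores outside [0, 1]")

    @property
    def n_windows(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class PSRegion:
    """A maximal stretch of above-cutoff windows, 1-based inclusive bounds."""

    accession: str
    start: int
    end: int
    mean_score: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"region {self.accession}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class LabeledPeptide:
    """A training peptide with a binary PS label (1 = PS-positive)."""

    sequence: str
    label: int

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError("empty peptide sequence")
        if self.label not in (0, 1):
            raise ValidationError("peptide label must be 0 or 1")


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def enumerate_windows(sequence: str, window_size: int) -> list[tuple[int, int, str]]:
    """All length-``window_size`` substrings at step 1, 1-based inclusive.

    A sequence shorter than the window yields exactly one window covering
    the whole sequence.
    """
    if window_size < 1:
        raise ValidationError("window_size must be >= 1")
    if not sequence:
        raise ValidationError("empty sequence")
    L = len(sequence)
    if L < window_size:
        return [(1, L, sequence)]
    return [
        (start, start + window_size - 1, sequence[start - 1 : start + window_size - 1])
        for start in range(1, L - window_size + 2)
    ]


# ---------------------------------------------------------------------------
# Scorers
# ---------------------------------------------------------------------------

class WindowScorer:
    """A pure function of window content returning a score in [0, 1]."""

    def score(self, window: str) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def score_many(self, windows: Sequence[str]) -> np.ndarray:
        return np.array([self.score(w) for w in windows], dtype=float)


class ProneFractionScorer(WindowScorer):
    """Fraction of window residues in the PS-prone set {G,S,Q,N,Y,F,P,R}."""

    def score(self, window: str) -> float:
        return sum(c in PRONE_RESIDUES for c in window) / len(window)


def featurize_window(window: str) -> np.ndarray:
    """23 composition features: 20 residue frequencies + prone, charged and
    aromatic fractions."""
    n = len(window)
    counts = np.zeros(len(_AA_ORDER), dtype=float)
    prone = charged = aromatic = 0
    for c in window:
        idx = _AA_ORDER.find(c)
        if idx >= 0:
            counts[idx] += 1
        if c in PRONE_RESIDUES:
            prone += 1
        if c in _CHARGED:
            charged += 1
        if c in _AROMATIC:
            aromatic += 1
    return np.concatenate([counts / n, [prone / n, charged / n, aromatic / n]])


class CompositionClassifierScorer(WindowScorer):
    """Random-forest scorer over window composition features; score is the
    predicted PS-positive class probability."""

    def __init__(self, model: RandomForestClassifier, spec: ScorerSpec):
        self.model = model
        self.spec = spec

    def score(self, window: str) -> float:
        return float(self.score_many([window])[0])

    def score_many(self, windows: Sequence[str]) -> np.ndarray:
        X = np.vstack([featurize_window(w) for w in windows])
        return self.model.predict_proba(X)[:, 1]


_REGISTRY: dict[str, WindowScorer] = {"prone_fraction": ProneFractionScorer()}


def register_scorer(name: str, scorer: WindowScorer) -> None:
    _REGISTRY[name] = scorer


def get_scorer(name: str) -> WindowScorer:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValidationError(
            f"unknown scorer {name!r}; registered scorers: {sorted(_REGISTRY)}"
        ) from None


def registered_scorers() -> list[str]:
    return sorted(_REGISTRY)


def score_windows(protein: ProteinRecord, spec: ScorerSpec) -> WindowScoreTrack:
    """Score every window of ``protein`` under the scorer named in ``spec``."""
    scorer = get_scorer(spec.name)
    windows = enumerate_windows(protein.sequence, spec.window_size)
    scores = scorer.score_many([w[2] for w in windows])
    return WindowScoreTrack(
        accession=protein.accession,
        window_size=spec.window_size,
        seq_length=len(protein),
        starts=np.array([w[0] for w in windows], dtype=int),
        scores=np.asarray(scores, dtype=float),
    )


# ---------------------------------------------------------------------------
# Region calling
# ---------------------------------------------------------------------------

def call_ps_regions(track: WindowScoreTrack, region_cutoff: float | None = None) -> list[PSRegion]:
    """Maximal runs of consecutive windows with score >= cutoff.

    A run from window ``i`` to window ``j`` yields the residue region
    ``[start_i, start_j + window_size - 1]`` clipped to the sequence end;
    its ``mean_score`` is the mean of the run's window scores. Runs broken
    by any sub-cutoff window stay separate regions even when their residue
    spans overlap.
    """
    cutoff = DEFAULT_REGION_CUTOFF if region_cutoff is None else region_cutoff
    regions: list[PSRegion] = []
    above = track.scores >= cutoff
    i = 0
    n = track.n_windows
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        start = int(track.starts[i])
        end = min(int(track.starts[j]) + track.window_size - 1, track.seq_length)
        regions.append(
            PSRegion(
                accession=track.accession,
                start=start,
                end=end,
                mean_score=float(np.mean(track.scores[i : j + 1])),
            )
        )
        i = j + 1
    return regions


def is_ps_protein(track: WindowScoreTrack, region_cutoff: float | None = None) -> bool:
    """A protein is phase-separating iff it has >= 1 called PS region."""
    return bool(call_ps_regions(track, region_cutoff))


# ---------------------------------------------------------------------------
# Trainable scorer
# ---------------------------------------------------------------------------

def _windows_for_training(peptide: LabeledPeptide, window_size: int) -> list[str]:
    return [w[2] for w in enumerate_windows(peptide.sequence, window_size)]


def train_scorer(
    labeled_peptides: Sequence[LabeledPeptide],
    spec: ScorerSpec,
    *,
    n_estimators: int = 200,
    register: bool = True,
) -> CompositionClassifierScorer:
    """Train the composition random-forest scorer and register it.

    Training peptides longer than the window are split into all their
    windows, each inheriting the peptide label. Training is deterministic
    given ``spec.seed``.
    """
    labels = {p.label for p in labeled_peptides}
    if labels != {0, 1}:
        raise ValidationError(
            "training requires peptides from both classes (labels 0 and 1)"
        )
    n_per_class = {lab: sum(p.label == lab for p in labeled_peptides) for lab in (0, 1)}
    if min(n_per_class.values()) < 2:
        raise ValidationError("need >= 2 peptides per class")

    X_rows, y_rows = [], []
    for pep in labeled_peptides:
        for window in _windows_for_training(pep, spec.window_size):
            X_rows.append(featurize_window(window))
            y_rows.append(pep.label)
    X = np.vstack(X_rows)
    y = np.array(y_rows, dtype=int)

    model = RandomForestClassifier(
        n_estimators=n_estimators,
        random_state=spec.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    scorer = CompositionClassifierScorer(model=model, spec=spec)
    if register:
        register_scorer(spec.name, scorer)
    logger.info(
        "trained scorer %r on %d windows (%d peptides)", spec.name, len(y), len(labeled_peptides)
    )
    return scorer


def save_scorer(scorer: CompositionClassifierScorer, path: str | Path) -> None:
    """Persist a trained scorer with a self-describing header."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "spec": {
            "name": scorer.spec.name,
            "window_size": scorer.spec.window_size,
            "region_cutoff": scorer.spec.region_cutoff,
            "seed": scorer.spec.seed,
        },
        "feature_names": list(FEATURE_NAMES),
        "model": scorer.model,
    }
    joblib.dump(payload, path)


def load_scorer(path: str | Path, *, register: bool = True) -> CompositionClassifierScorer:
    path = Path(path)
    if not path.exists():
        raise InputError(f"model file not found: {path}")
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"model file {path}: unsupported format version "
            f"{payload.get('format_version')!r}"
        )
    if list(payload.get("feature_names", [])) != list(FEATURE_NAMES):
        raise ValidationError(f"model file {path}: feature list mismatch")
    spec_d = payload["spec"]
    spec = ScorerSpec(
        name=spec_d["name"],
        window_size=spec_d["window_size"],
        region_cutoff=spec_d["region_cutoff"],
        seed=spec_d["seed"],
    )
    scorer = CompositionClassifierScorer(model=payload["model"], spec=spec)
    if register:
        register_scorer(spec.name, scorer)
    return scorer
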